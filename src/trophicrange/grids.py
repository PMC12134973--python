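"""Equal-area raster grids and plain-text raster IO.

All spatial data in this package live on an abstract equal-area Cartesian
grid: 0-based (row, col) indices, origin at the top-left corner, square cells
of ``cell_km`` kilometres (1 km by default).  A coarse grid is an exact
``factor`` x ``factor`` block aggregation of the fine grid (trailing partial
blocks are averaged over the cells they do contain).  Working in cell
coordinates keeps every distance computation an ordinary Euclidean distance
in kilometres and removes projection machinery from the analysis.

Rasters are written as single-band ESRI ASCII grids (``.asc``), a plain-text
format readable by every major GIS.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

NODATA = -9999.0


@dataclass
class GridStack:
    """A set of co-registered named raster layers plus scenario variants.

    ``layers`` holds the current-conditions layers.  ``scenarios`` maps a
    scenario id (e.g. ``"SSP3-6.0"``) to the layers that *differ* from the
    current ones; :meth:`layers_for` overlays them on the current set.
    """

    layers: Dict[str, np.ndarray]
    cell_km: float = 1.0
    scenarios: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers are not co-registered: shapes {shapes}")

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def layer_names(self) -> Tuple[str, ...]:
        return tuple(self.layers)

    @property
    def scenario_names(self) -> Tuple[str, ...]:
        return tuple(self.scenarios)

    def layers_for(self, scenario: Optional[str] = None) -> Dict[str, np.ndarray]:
        """Current layers with the scenario's changed layers overlaid."""
        if scenario is None or scenario == "current":
            return dict(self.layers)
        if scenario not in self.scenarios:
            raise KeyError(f"unknown scenario {scenario!r}")
        out = dict(self.layers)
        out.update(self.scenarios[scenario])
        return out

    def block_reduce(self, factor: int) -> "GridStack":
        """Aggregate to a coarse grid of ``factor`` x ``factor`` blocks (mean)."""
        coarse = {k: block_mean(v, factor) for k, v in self.layers.items()}
        sc = {
            s: {k: block_mean(v, factor) for k, v in lays.items()}
            for s, lays in self.scenarios.items()
        }
        meta = dict(self.meta)
        meta["block_factor"] = factor
        return GridStack(coarse, cell_km=self.cell_km * factor, scenarios=sc, meta=meta)

    def standardization(
        self, names: Optional[Sequence[str]] = None
    ) -> Dict[str, Tuple[float, float]]:
        """Per-layer (mean, sd) over the current layers, for design scaling."""
        names = self.layer_names if names is None else names
        out = {}
        for n in names:
            a = self.layers[n]
            m = float(np.nanmean(a))
            s = float(np.nanstd(a))
            out[n] = (m, s if s > 0 else 1.0)
        return out

    def copy(self) -> "GridStack":
        return copy.deepcopy(self)


@dataclass
class RangeGrid:
    """Coarse-resolution historical range: presence (1) / extirpated-absent (0).

    Aligned to a fine grid as exact ``coarse_factor`` x ``coarse_factor``
    blocks; ``status`` uses -1 for nodata.
    """

    status: np.ndarray
    coarse_factor: int = 50

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.status.shape

    @property
    def n_presences(self) -> int:
        return int((self.status == 1).sum())

    @property
    def n_absences(self) -> int:
        return int((self.status == 0).sum())


def block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    """Mean over ``factor`` x ``factor`` blocks; output dims = ceil(dims/factor).

    Partial trailing blocks average over the cells present; NaNs are ignored.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    r, c = arr.shape
    rr, cc = -(-r // factor), -(-c // factor)
    padded = np.full((rr * factor, cc * factor), np.nan)
    padded[:r, :c] = arr
    blocks = padded.reshape(rr, factor, cc, factor).swapaxes(1, 2)
    with np.errstate(invalid="ignore"):
        return np.nanmean(blocks.reshape(rr, cc, -1), axis=2)


def moving_window_mean(arr: np.ndarray, size: int) -> np.ndarray:
    """Square moving-window mean (edge cells use nearest-value padding)."""
    return ndimage.uniform_filter(np.asarray(arr, dtype=float), size=size, mode="nearest")


def distance_to_cells(mask: np.ndarray, cell_km: float = 1.0) -> np.ndarray:
    """Euclidean distance (km) from every cell to the nearest True cell."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask) * cell_km


def make_subpop_partition(shape: Tuple[int, int], n_subpops: int) -> np.ndarray:
    """Partition a grid into contiguous rectangular subpopulations.

    Returns an int array of subpopulation ids 0..n_subpops-1.  The partition
    is a near-square tiling: ``n_subpops`` is factorized into ``ny`` x ``nx``
    with ny as close to sqrt(n) as possible.
    """
    if n_subpops < 1:
        raise ValueError("n_subpops must be >= 1")
    ny = int(np.floor(np.sqrt(n_subpops)))
    while n_subpops % ny:
        ny -= 1
    nx = n_subpops // ny
    rows, cols = shape
    ridx = np.minimum(np.arange(rows) * ny // rows, ny - 1)
    cidx = np.minimum(np.arange(cols) * nx // cols, nx - 1)
    return (ridx[:, None] * nx + cidx[None, :]).astype(np.int32)


def write_ascii_grid(
    path: str | Path, arr: np.ndarray, cell_km: float = 1.0, nodata: float = NODATA
) -> None:
    """Write a single-band ESRI ASCII grid (text) raster."""
    arr = np.asarray(arr, dtype=float)
    out = np.where(np.isfinite(arr), arr, nodata)
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {cell_km * 1000.0}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> Tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; returns (array with NaN nodata, cell_km)."""
    header: Dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            header[key.lower()] = float(val)
            pos = fh.tell()
        fh.seek(pos)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    nodata = header.get("nodata_value", NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    exp = (int(header["nrows"]), int(header["ncols"]))
    if arr.shape != exp:
        raise ValueError(f"grid shape {arr.shape} does not match header {exp}")
    return arr, header.get("cellsize", 1000.0) / 1000.0


def save_stack(outdir: str | Path, stack: GridStack) -> None:
    """Write every layer (current and scenario) as an .asc raster."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.layers.items():
        write_ascii_grid(outdir / f"{_safe(name)}.asc", arr, stack.cell_km)
    for scen, lays in stack.scenarios.items():
        for name, arr in lays.items():
            write_ascii_grid(
                outdir / f"{_safe(name)}__{_safe(scen)}.asc", arr, stack.cell_km
            )


def _safe(name: str) -> str:
    return name.replace(" ", "_").replace("/", "-")
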