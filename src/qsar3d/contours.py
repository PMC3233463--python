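"""StDev*Coeff contour fields and OpenDX export.

The interpretable output of a lattice QSAR model is the per-point
product of the training-column standard deviation and the PLS
coefficient ("StDev*Coeff"). Positive values mark regions where more
of the field property raises predicted activity (favoured; the green /
blue / magenta contours of the conventional maps), negative values
regions where it lowers it (disfavoured). Contour levels are taken as
percentiles of the nonzero StDev*Coeff distribution — the favoured
level on the positive side, the disfavoured level on the negative
side.

Maps are exported as OpenDX scalar fields readable by standard
molecular viewers (PyMOL, VMD, Chimera); the chosen iso-levels are
recorded in header comments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import ColumnMeta, GridSpec
from .pls_model import PLSModel

__all__ = [
    "ContourSet",
    "stdev_coeff",
    "contour_levels",
    "export_dx",
    "read_dx",
    "top_points",
]


@dataclass
class ContourSet:
    """Per-grid-point StDev*Coeff values with threshold levels."""

    kind: str
    values: np.ndarray  # length grid.n_points; filtered columns are 0
    grid: GridSpec
    favored_pct: float
    disfavored_pct: float
    favored_level: float | None
    disfavored_level: float | None


def stdev_coeff(
    model: PLSModel,
    X_train: np.ndarray,
    metadata: list[ColumnMeta],
    kind: str,
    grid: GridSpec,
) -> np.ndarray:
    """StDev*Coeff values of one field kind, re-embedded on the grid.

    Columns dropped by variance filtering are rendered as 0, keeping
    the volumetric grid rectangular.
    """
    X_train = np.asarray(X_train, dtype=float)
    if len(metadata) != X_train.shape[1] or len(metadata) != len(model.coefficients):
        raise ValueError("metadata does not match descriptor matrix / model columns")
    cols = [c for c, m in enumerate(metadata) if m.kind == kind]
    if not cols:
        raise ValueError(f"field kind {kind!r} not present in column metadata")
    sd = X_train[:, cols].std(axis=0, ddof=1)
    values = np.zeros(grid.n_points)
    for sd_c, c in zip(sd, cols):
        values[metadata[c].point_index] = sd_c * model.coefficients[c]
    return values


def contour_levels(
    values: np.ndarray,
    favored_pct: float = 80.0,
    disfavored_pct: float = 20.0,
) -> tuple[float | None, float | None]:
    """Threshold levels from percentiles of the nonzero values.

    The favoured level is the ``favored_pct`` percentile and must fall
    on the positive side; the disfavoured level is the
    ``disfavored_pct`` percentile on the negative side. A level on the
    wrong side (e.g. no negative values at all) is reported as absent
    with a warning.
    """
    if not (0 < disfavored_pct < favored_pct < 100):
        raise ValueError("need 0 < disfavored_pct < favored_pct < 100")
    values = np.asarray(values, dtype=float)
    nonzero = values[values != 0]
    if nonzero.size == 0:
        raise ValueError("all StDev*Coeff values are zero; no contour levels")
    favored = float(np.percentile(nonzero, favored_pct))
    disfavored = float(np.percentile(nonzero, disfavored_pct))
    if favored <= 0:
        warnings.warn("favoured level is non-positive; reported absent", stacklevel=2)
        favored = None
    if disfavored is not None and disfavored >= 0:
        warnings.warn("disfavoured level is non-negative; reported absent", stacklevel=2)
        disfavored = None
    return favored, disfavored


def make_contour_set(
    model: PLSModel,
    X_train: np.ndarray,
    metadata: list[ColumnMeta],
    kind: str,
    grid: GridSpec,
    favored_pct: float = 80.0,
    disfavored_pct: float = 20.0,
) -> ContourSet:
    values = stdev_coeff(model, X_train, metadata, kind, grid)
    favored, disfavored = contour_levels(values, favored_pct, disfavored_pct)
    return ContourSet(kind, values, grid, favored_pct, disfavored_pct, favored, disfavored)


# ---------------------------------------------------------------------------
# OpenDX I/O


def _to_dx_order(values: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    """Internal x-fastest flat order -> DX z-fastest order."""
    nx, ny, nz = dims
    arr = np.asarray(values, float).reshape((nz, ny, nx))  # [iz, iy, ix]
    return np.transpose(arr, (2, 1, 0)).ravel()  # ix outer ... iz fastest


def _from_dx_order(data: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = dims
    arr = data.reshape((nx, ny, nz))  # [ix, iy, iz], iz fastest
    return np.transpose(arr, (2, 1, 0)).ravel()


def export_dx(contour_set: ContourSet, path: str | Path) -> None:
    """Write a StDev*Coeff map as an OpenDX scalar field.

    Iso-levels and the field kind are recorded in ``#`` header
    comments; the data block uses the standard z-fastest DX ordering.
    """
    grid = contour_set.grid
    nx, ny, nz = grid.dims
    if grid.n_points != len(contour_set.values):
        raise ValueError("value count does not match grid")
    data = _to_dx_order(contour_set.values, grid.dims)
    lines = [
        "# qsar3d StDev*Coeff contour map",
        f"# kind: {contour_set.kind}",
        f"# favored_level ({contour_set.favored_pct:g}%): {contour_set.favored_level}",
        f"# disfavored_level ({contour_set.disfavored_pct:g}%): {contour_set.disfavored_level}",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(*grid.origin),
        f"delta {grid.spacing:.6f} 0.000000 0.000000",
        f"delta 0.000000 {grid.spacing:.6f} 0.000000",
        f"delta 0.000000 0.000000 {grid.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {grid.n_points} data follows",
    ]
    for start in range(0, len(data), 3):
        lines.append(" ".join(f"{v:.10e}" for v in data[start:start + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "density" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
        "",
    ]
    Path(path).write_text("\n".join(lines))


def read_dx(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Parse an OpenDX scalar field back to (values, grid).

    Values are returned in the package's x-fastest flat order. Only
    regular, axis-aligned grids (diagonal deltas, equal spacing) are
    supported.
    """
    dims: tuple[int, int, int] | None = None
    origin: tuple[float, float, float] | None = None
    deltas: list[float] = []
    data: list[float] = []
    n_items = None
    in_data = False
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if in_data:
            if s.startswith(("attribute", "object", "component")):
                in_data = False
                continue
            data.extend(float(x) for x in s.split())
            continue
        if s.startswith("object 1"):
            dims = tuple(int(x) for x in s.split()[-3:])
        elif s.startswith("origin"):
            origin = tuple(float(x) for x in s.split()[1:4])
        elif s.startswith("delta"):
            vals = [float(x) for x in s.split()[1:4]]
            nz = [v for v in vals if abs(v) > 1e-12]
            if len(nz) != 1:
                raise ValueError("only axis-aligned diagonal deltas are supported")
            deltas.append(nz[0])
        elif "data follows" in s:
            n_items = int(s.split("items")[1].split()[0])
            in_data = True
    if dims is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a regular OpenDX grid")
    if len(set(f"{d:.9f}" for d in deltas)) != 1:
        raise ValueError("anisotropic spacing not supported")
    if n_items is None or len(data) != n_items:
        raise ValueError(f"{path}: expected {n_items} data items, got {len(data)}")
    grid = GridSpec(origin=origin, spacing=deltas[0], dims=dims)
    return _from_dx_order(np.array(data), dims), grid


def top_points(contour_set: ContourSet, n: int = 20) -> pd.DataFrame:
    """The n largest-|StDev*Coeff| lattice points with coordinates."""
    values = contour_set.values
    order = np.argsort(-np.abs(values))[:n]
    pts = contour_set.grid.points()[order]
    return pd.DataFrame(
        {
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "stdev_coeff": values[order],
            "kind": contour_set.kind,
        }
    )
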