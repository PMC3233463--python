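"""Molecular interaction fields on a regular lattice.

Two descriptor families are computed for an aligned series:

* CoMFA — probe-atom interaction energies: a Lennard-Jones 6-12
  steric term (sp3-carbon probe, radii summed, well depths combined by
  geometric mean) and a Coulomb electrostatic term with a
  distance-dependent dielectric ε(r) = r, both truncated at
  ±30 kcal/mol. At lattice points where the steric energy is clamped
  (probe inside the molecule) the electrostatic value carries no
  information and is replaced by the column mean over the unclamped
  molecules.

* CoMSIA — Gaussian-attenuated similarity indices
  A_k(q) = −Σ_i ω_probe,k · ω_ik · exp(−α r_iq²) for the steric
  (ω = r_vdW³), electrostatic (ω = partial charge), hydrophobic,
  H-bond donor and acceptor (ω = 0/1 flags) properties, with a probe
  whose properties are all +1 and attenuation α = 0.3. No truncation
  is applied; the indices are smooth everywhere.

The lattice has a default spacing of 2.0 Å and is the union bounding
box of the aligned series plus a margin (default 4.0 Å), snapped
outward to whole grid steps. Grid iteration order is x fastest, then
y, then z, so column indices are stable and documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chem_io import Molecule
from .params import COMFA_PROBE, COULOMB_KCAL, lj_params

__all__ = [
    "GridSpec",
    "ProbeSpec",
    "FieldBlock",
    "ColumnMeta",
    "COMSIA_KINDS",
    "build_grid",
    "comfa_steric",
    "comfa_electrostatic",
    "comfa_blocks",
    "comsia_field",
    "comsia_block",
    "assemble_descriptor_matrix",
    "filter_columns",
    "block_labels",
]

COMSIA_KINDS = ("steric", "electrostatic", "hydrophobic", "donor", "acceptor")


@dataclass(frozen=True)
class GridSpec:
    """Regular axis-aligned lattice: origin, spacing (Å) and point counts."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("grid needs at least 2 points per axis")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = self.origin
        return tuple(
            o[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)
        )

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3); x varies fastest."""
        xs, ys, zs = self.axes()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.column_stack(
            [X.ravel(order="F"), Y.ravel(order="F"), Z.ravel(order="F")]
        )

    def point_index(self, ix: int, iy: int, iz: int) -> int:
        nx, ny, _ = self.dims
        return ix + nx * (iy + ny * iz)

    def nearest_index(self, position: Sequence[float]) -> int:
        """Flat index of the lattice point nearest to a position."""
        idx = []
        for k in range(3):
            i = int(round((position[k] - self.origin[k]) / self.spacing))
            if not 0 <= i < self.dims[k]:
                raise ValueError(f"position {position} outside grid on axis {k}")
            idx.append(i)
        return self.point_index(*idx)

    def contains(self, position: Sequence[float]) -> bool:
        for k in range(3):
            hi = self.origin[k] + self.spacing * (self.dims[k] - 1)
            if not (self.origin[k] - 1e-9 <= position[k] <= hi + 1e-9):
                return False
        return True


@dataclass(frozen=True)
class ProbeSpec:
    """Probe definition for field evaluation.

    The CoMFA probe is an sp3 carbon carrying +1 e; the CoMSIA probe has
    radius 1.0 Å and all five physicochemical properties set to +1.
    """

    kind: str = "comsia"
    charge: float = 1.0
    radius: float = 1.0
    hydrophobicity: float = 1.0
    hbd: float = 1.0
    hba: float = 1.0
    comfa_radius: float = COMFA_PROBE[0]
    comfa_well_depth: float = COMFA_PROBE[1]

    def comsia_property(self, kind: str) -> float:
        return {
            "steric": self.radius**3,
            "electrostatic": self.charge,
            "hydrophobic": self.hydrophobicity,
            "donor": self.hbd,
            "acceptor": self.hba,
        }[kind]


@dataclass
class FieldBlock:
    """n_molecules × n_points descriptor matrix for one field kind."""

    kind: str
    method: str  # "comfa" | "comsia"
    values: np.ndarray
    grid: GridSpec
    truncation: float | None = None  # kcal/mol, comfa only
    alpha: float | None = None  # comsia attenuation
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.n_points:
            raise ValueError("field block shape does not match grid")


@dataclass(frozen=True)
class ColumnMeta:
    """Provenance of one descriptor column: field kind and lattice point."""

    method: str
    kind: str
    point_index: int


# ---------------------------------------------------------------------------
# grid construction


def build_grid(
    molecules: Iterable[Molecule], spacing: float = 2.0, margin: float = 4.0
) -> GridSpec:
    """Lattice enclosing all molecules plus a margin on every face.

    The union bounding box is extended by ``margin`` and snapped
    outward to whole multiples of ``spacing``; degenerate axes are
    widened to two points.
    """
    mols = list(molecules)
    if not mols:
        raise ValueError("cannot build a grid for an empty molecule list")
    coords = np.vstack([m.coords for m in mols])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    origin = []
    dims = []
    for k in range(3):
        a = math.floor(lo[k] / spacing + 1e-9) * spacing
        b = math.ceil(hi[k] / spacing - 1e-9) * spacing
        if b <= a + 1e-9:
            b = a + spacing
        origin.append(a)
        dims.append(int(round((b - a) / spacing)) + 1)
    return GridSpec(origin=tuple(origin), spacing=spacing, dims=tuple(dims))


# ---------------------------------------------------------------------------
# CoMFA probe energies


def _dist2(mol: Molecule, points: np.ndarray) -> np.ndarray:
    """Squared atom–point distances, shape (n_atoms, n_points)."""
    diff = mol.coords[:, None, :] - points[None, :, :]
    return np.einsum("apk,apk->ap", diff, diff)


def comfa_steric(
    mol: Molecule,
    points: np.ndarray | GridSpec,
    probe: ProbeSpec | None = None,
    truncation: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Lennard-Jones 6-12 steric energy of the probe at each point.

    Returns (clamped values in kcal/mol, mask of points clamped at
    +truncation). Per atom pair: ε_ij[(R_ij/r)¹² − 2(R_ij/r)⁶] with
    R_ij the sum of probe and atom radii and ε_ij the geometric mean
    of the well depths.
    """
    probe = probe or ProbeSpec(kind="comfa")
    pts = points.points() if isinstance(points, GridSpec) else np.asarray(points, float)
    radii = np.empty(mol.n_atoms)
    depths = np.empty(mol.n_atoms)
    for i, a in enumerate(mol.atoms):
        r, e = lj_params(a.element)
        # explicit per-atom radius (synthetic series) overrides the table
        radii[i] = a.vdw_radius if a.vdw_radius is not None else r
        depths[i] = e
    r2 = np.maximum(_dist2(mol, pts), 1e-12)
    rij = radii[:, None] + probe.comfa_radius
    eij = np.sqrt(depths[:, None] * probe.comfa_well_depth)
    s6 = (rij**2 / r2) ** 3
    energy = (eij * (s6**2 - 2.0 * s6)).sum(axis=0)
    clamp_hi = energy > truncation
    return np.clip(energy, -truncation, truncation), clamp_hi


def comfa_electrostatic(
    mol: Molecule,
    points: np.ndarray | GridSpec,
    probe: ProbeSpec | None = None,
    truncation: float = 30.0,
    dielectric: str = "distance",
) -> np.ndarray:
    """Coulomb electrostatic energy of a +1 e probe at each point.

    E(q) = 332.0636 · Σ_i q_probe·q_i / (ε(r)·r) kcal/mol with the
    distance-dependent dielectric ε(r) = r by default (so the distance
    enters squared), clamped to ±truncation.
    """
    probe = probe or ProbeSpec(kind="comfa")
    pts = points.points() if isinstance(points, GridSpec) else np.asarray(points, float)
    q = mol.charges()
    r2 = np.maximum(_dist2(mol, pts), 1e-12)
    if dielectric == "distance":
        denom = r2
    elif dielectric == "constant":
        denom = np.sqrt(r2)
    else:
        raise ValueError("dielectric must be 'distance' or 'constant'")
    energy = COULOMB_KCAL * probe.charge * (q[:, None] / denom).sum(axis=0)
    return np.clip(energy, -truncation, truncation)


def comfa_blocks(
    molecules: Sequence[Molecule],
    grid: GridSpec,
    probe: ProbeSpec | None = None,
    truncation: float = 30.0,
    dielectric: str = "distance",
) -> tuple[FieldBlock, FieldBlock]:
    """Steric and electrostatic CoMFA blocks for an aligned series.

    Electrostatic entries at sterically clamped points are replaced by
    the column mean over the unclamped molecules (0 if every molecule
    is clamped there); the replacement mask is kept in block metadata.
    """
    probe = probe or ProbeSpec(kind="comfa")
    pts = grid.points()
    n = len(molecules)
    steric = np.empty((n, grid.n_points))
    electro = np.empty((n, grid.n_points))
    clamped = np.zeros((n, grid.n_points), dtype=bool)
    for j, mol in enumerate(molecules):
        steric[j], clamped[j] = comfa_steric(mol, pts, probe, truncation)
        electro[j] = comfa_electrostatic(mol, pts, probe, truncation, dielectric)
    ok = ~clamped
    with np.errstate(invalid="ignore"):
        col_mean = np.where(
            ok.any(axis=0), (electro * ok).sum(axis=0) / np.maximum(ok.sum(axis=0), 1), 0.0
        )
    electro = np.where(clamped, col_mean[None, :], electro)
    sblock = FieldBlock("steric", "comfa", steric, grid, truncation=truncation,
                        meta={"clamped": clamped})
    eblock = FieldBlock("electrostatic", "comfa", electro, grid, truncation=truncation,
                        meta={"mean_replaced": clamped, "dielectric": dielectric})
    return sblock, eblock


# ---------------------------------------------------------------------------
# CoMSIA similarity indices


def _comsia_property(mol: Molecule, kind: str) -> np.ndarray:
    vals = np.empty(mol.n_atoms)
    for i, a in enumerate(mol.atoms):
        if kind == "steric":
            if a.vdw_radius is None:
                raise ValueError(f"atom {i} of {mol.id!r} lacks a vdW radius")
            vals[i] = a.vdw_radius**3
        elif kind == "electrostatic":
            if a.partial_charge is None:
                raise ValueError(f"atom {i} of {mol.id!r} lacks a partial charge")
            vals[i] = a.partial_charge
        elif kind == "hydrophobic":
            if a.hydrophobicity is None:
                raise ValueError(f"atom {i} of {mol.id!r} lacks hydrophobicity")
            vals[i] = a.hydrophobicity
        elif kind == "donor":
            if a.is_hbd is None:
                raise ValueError(f"atom {i} of {mol.id!r} lacks donor flag")
            vals[i] = float(a.is_hbd)
        elif kind == "acceptor":
            if a.is_hba is None:
                raise ValueError(f"atom {i} of {mol.id!r} lacks acceptor flag")
            vals[i] = float(a.is_hba)
        else:
            raise ValueError(f"unknown CoMSIA property kind {kind!r}")
    return vals


def comsia_field(
    mol: Molecule,
    points: np.ndarray | GridSpec,
    kind: str,
    alpha: float = 0.3,
    probe: ProbeSpec | None = None,
) -> np.ndarray:
    """Gaussian similarity index A_k(q) = −Σ_i ω_p,k ω_ik e^(−α r_iq²).

    The leading minus sign makes the index non-positive wherever the
    molecular property is non-negative everywhere. No truncation.
    """
    probe = probe or ProbeSpec(kind="comsia")
    pts = points.points() if isinstance(points, GridSpec) else np.asarray(points, float)
    w = _comsia_property(mol, kind)
    r2 = _dist2(mol, pts)
    return -probe.comsia_property(kind) * (w[:, None] * np.exp(-alpha * r2)).sum(axis=0)


def comsia_block(
    molecules: Sequence[Molecule],
    grid: GridSpec,
    kind: str,
    alpha: float = 0.3,
    probe: ProbeSpec | None = None,
) -> FieldBlock:
    values = np.vstack([comsia_field(m, grid, kind, alpha, probe) for m in molecules])
    return FieldBlock(kind, "comsia", values, grid, alpha=alpha)


# ---------------------------------------------------------------------------
# descriptor matrix assembly


def assemble_descriptor_matrix(
    blocks: Sequence[FieldBlock],
) -> tuple[np.ndarray, list[ColumnMeta]]:
    """Concatenate field blocks column-wise into one descriptor matrix.

    All blocks must share grid and molecule (row) order. Column
    metadata records (method, kind, lattice point index) per column.
    """
    if not blocks:
        raise ValueError("no field blocks to assemble")
    grid = blocks[0].grid
    n = blocks[0].values.shape[0]
    for b in blocks:
        if b.grid != grid:
            raise ValueError("field blocks computed on different grids")
        if b.values.shape[0] != n:
            raise ValueError("field blocks have different molecule counts")
    X = np.hstack([b.values for b in blocks])
    metadata = [
        ColumnMeta(b.method, b.kind, p)
        for b in blocks
        for p in range(grid.n_points)
    ]
    return X, metadata


def block_labels(metadata: Sequence[ColumnMeta]) -> np.ndarray:
    """Integer block label per column, grouped by (method, kind)."""
    keys: dict[tuple[str, str], int] = {}
    labels = np.empty(len(metadata), dtype=int)
    for c, m in enumerate(metadata):
        labels[c] = keys.setdefault((m.method, m.kind), len(keys))
    return labels


def filter_columns(
    X: np.ndarray,
    metadata: Sequence[ColumnMeta],
    min_sigma: float,
    train_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, list[ColumnMeta], np.ndarray]:
    """Drop low-variance columns (SYBYL minimum-sigma filtering).

    Columns whose standard deviation across the training molecules is
    below ``min_sigma`` are removed. Returns (filtered X, filtered
    metadata, boolean keep mask over the original columns).
    """
    if min_sigma < 0:
        raise ValueError("min_sigma must be non-negative")
    X = np.asarray(X, dtype=float)
    rows = X if train_mask is None else X[np.asarray(train_mask, bool)]
    sd = rows.std(axis=0, ddof=1)
    if min_sigma == 0:
        keep = np.ones(X.shape[1], dtype=bool)
    else:
        keep = sd >= min_sigma
    if not keep.any():
        raise ValueError(f"min_sigma={min_sigma} drops every descriptor column")
    meta = [m for m, k in zip(metadata, keep) if k]
    return X[:, keep], meta, keep
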