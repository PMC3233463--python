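"""Synthetic congeneric series with a planted field–activity relation.

Real lattice-QSAR studies start from a hand-built series of congeneric
inhibitors; here a generator emulates that input so every pipeline
stage is testable end to end. Each synthetic molecule shares a rigid
phosphate-plus-core scaffold (the alignment anchor) and differs in
pseudo-atom substituents placed, with small jitter, at fixed sites
adjacent to lattice points. Atoms carry explicit partial charges and
per-atom properties, so no chemistry (valence models, charging) is
involved and the field→activity ground truth is exact.

Activities come from a planted "pseudo-receptor": weighted interaction
centers at lattice positions. For molecule j,

    pIC50_j = offset + Σ_c w_c · A_kind(c)(j at position_c) + ε_j,

with A the Gaussian similarity index of the center's field kind and
ε ~ N(0, noise_sd²), then affinely rescaled into the conventional
activity window 4.870–8.000. The rescaling is recorded so recovery
tests can compare fitted StDev*Coeff signs against the (positively
rescaled, hence sign-preserved) planted weights.

The first generated molecule is emitted in the canonical scaffold
frame and serves as the alignment template; all others are posed
randomly to exercise the alignment stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .chem_io import Atom, Molecule, write_sdf
from .contours import stdev_coeff
from .fields import COMSIA_KINDS, ColumnMeta, GridSpec, comsia_field
from .params import vdw_radius
from .pls_model import PLSModel

__all__ = [
    "Center",
    "ReceptorSpec",
    "SubstituentSite",
    "GroundTruth",
    "RecoveryReport",
    "default_scaffold",
    "default_sites",
    "default_receptor",
    "generate_series",
    "plant_activities",
    "make_dataset",
    "recovery_report",
    "write_synthetic_inputs",
    "ACTIVITY_RANGE",
]

#: conventional pIC50 window of the emulated inhibitor series
ACTIVITY_RANGE = (4.870, 8.000)

_ELEMENTS = ("C", "N", "O", "F", "S", "Cl")
_ELEMENT_P = (0.40, 0.15, 0.20, 0.08, 0.09, 0.08)


@dataclass(frozen=True)
class Center:
    """One planted interaction center: position, field kind, weight."""

    position: tuple[float, float, float]
    kind: str
    weight: float

    def __post_init__(self) -> None:
        if self.kind not in COMSIA_KINDS:
            raise ValueError(f"unknown field kind {self.kind!r}")


@dataclass(frozen=True)
class ReceptorSpec:
    """Planted ground truth: interaction centers plus a noise model."""

    centers: tuple[Center, ...]
    noise_sd: float = 0.1
    activity_offset: float = 6.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.centers:
            raise ValueError("receptor needs at least one center")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SubstituentSite:
    """A variable position: nominal location and scaffold attachment atom."""

    position: tuple[float, float, float]
    attach_index: int


@dataclass
class GroundTruth:
    """Planting record: the affine rescale and the effective weights."""

    scale: float
    shift: float
    effective_weights: list[float]  # w_c · scale, per center
    raw_components: np.ndarray  # n_molecules × n_centers field values


@dataclass
class RecoveryReport:
    """How well a fitted model recovered the planted receptor."""

    sign_agreement: float
    n_centers_checked: int
    per_center: list[dict]
    q2: float | None = None
    r_pred2: float | None = None


def default_scaffold() -> tuple[list[Atom], list[tuple[int, int, int]]]:
    """Rigid anchor: phosphate (P + 4 O) bonded to a three-carbon core.

    Charges approximate a deprotonated phosphate monoester; oxygens are
    flagged H-bond acceptors.
    """
    def o(x, y, z, q):  # phosphate oxygen
        return Atom("O", (x, y, z), partial_charge=q, vdw_radius=vdw_radius("O"),
                    hydrophobicity=-0.2, is_hbd=False, is_hba=True)

    def c(x, y, z):  # core carbon
        return Atom("C", (x, y, z), partial_charge=0.05, vdw_radius=vdw_radius("C"),
                    hydrophobicity=0.15, is_hbd=False, is_hba=False)

    atoms = [
        Atom("P", (0.0, 0.0, 0.0), partial_charge=1.30, vdw_radius=vdw_radius("P"),
             hydrophobicity=0.0, is_hbd=False, is_hba=False),
        o(1.48, 0.0, 0.0, -0.55),      # bridging ester oxygen
        o(-0.60, 1.35, 0.0, -0.80),
        o(-0.60, -0.68, 1.17, -0.80),
        o(-0.60, -0.68, -1.17, -0.80),
        c(2.90, 0.0, 0.0),
        c(4.20, 0.90, 0.0),
        c(5.50, 0.30, 0.40),
    ]
    bonds = [(0, 1, 1), (0, 2, 2), (0, 3, 1), (0, 4, 1),
             (1, 5, 1), (5, 6, 1), (6, 7, 1)]
    return atoms, bonds


def default_sites() -> list[SubstituentSite]:
    """Six variable sites at lattice positions around the core."""
    return [
        SubstituentSite((4.0, 2.0, 0.0), attach_index=6),
        SubstituentSite((6.0, 0.0, 2.0), attach_index=7),
        SubstituentSite((6.0, -2.0, 0.0), attach_index=7),
        SubstituentSite((2.0, -2.0, 0.0), attach_index=5),
        SubstituentSite((4.0, 0.0, -2.0), attach_index=6),
        SubstituentSite((4.0, 0.0, 2.0), attach_index=5),
    ]


def default_receptor(noise_sd: float = 0.1, seed: int = 0) -> ReceptorSpec:
    """Centers at the default substituent sites, mixed kinds and signs."""
    centers = (
        Center((4.0, 2.0, 0.0), "steric", 0.9),
        Center((6.0, 0.0, 2.0), "electrostatic", 1.6),
        Center((6.0, -2.0, 0.0), "acceptor", -1.1),
        Center((2.0, -2.0, 0.0), "steric", -0.7),
        Center((4.0, 0.0, -2.0), "electrostatic", -1.3),
        Center((4.0, 0.0, 2.0), "acceptor", 0.8),
    )
    return ReceptorSpec(centers=centers, noise_sd=noise_sd, seed=seed)


def _random_pose(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-10.0, 10.0, size=3)
    return rot, trans


def generate_series(
    n_molecules: int,
    scaffold: tuple[list[Atom], list[tuple[int, int, int]]] | None = None,
    sites: Sequence[SubstituentSite] | None = None,
    seed: int = 0,
    occupancy: float = 0.65,
    jitter_sd: float = 0.3,
) -> list[Molecule]:
    """Generate a congeneric series sharing the scaffold anchor.

    Each site is occupied independently with probability ``occupancy``
    by one pseudo-atom with randomised element, partial charge
    (N(0, 0.35²)), hydrophobicity (N(0, 0.6²)) and donor/acceptor
    flags; its position is the site jittered by N(0, jitter_sd²) per
    axis. Molecule 0 stays in the scaffold frame (the alignment
    template); the rest are emitted at random rigid poses.
    Deterministic for a given seed.
    """
    if n_molecules < 4:
        raise ValueError("need at least 4 molecules for a meaningful series")
    scaffold_atoms, scaffold_bonds = scaffold or default_scaffold()
    sites = list(default_sites() if sites is None else sites)
    coords = np.array([a.coords for a in scaffold_atoms])
    if len(scaffold_atoms) < 3 or np.linalg.svd(
        coords - coords.mean(axis=0), compute_uv=False
    )[1] < 1e-6:
        raise ValueError("degenerate scaffold: need >=3 non-collinear anchor atoms")
    for s in sites:
        if not 0 <= s.attach_index < len(scaffold_atoms):
            raise ValueError(f"site attachment index {s.attach_index} out of range")

    rng = np.random.default_rng(seed)
    molecules: list[Molecule] = []
    for j in range(n_molecules):
        atoms = list(scaffold_atoms)
        bonds = list(scaffold_bonds)
        for site in sites:
            if rng.random() >= occupancy:
                continue
            element = rng.choice(_ELEMENTS, p=_ELEMENT_P)
            pos = np.asarray(site.position) + rng.normal(0.0, jitter_sd, size=3)
            polar = element in ("N", "O")
            atoms.append(
                Atom(
                    element=str(element),
                    coords=tuple(pos),
                    partial_charge=float(rng.normal(0.0, 0.35)),
                    vdw_radius=vdw_radius(str(element)),
                    hydrophobicity=float(rng.normal(0.0, 0.6)),
                    is_hbd=bool(polar and rng.random() < 0.3),
                    is_hba=bool(element in ("N", "O", "F") and rng.random() < 0.6),
                )
            )
            bonds.append((site.attach_index, len(atoms) - 1, 1))
        mol = Molecule(id=f"syn{j:03d}", atoms=atoms, bonds=bonds)
        if j > 0:
            rot, trans = _random_pose(rng)
            mol = mol.transformed(rot, trans)
        molecules.append(mol)
    return molecules


def plant_activities(
    molecules: Sequence[Molecule],
    receptor: ReceptorSpec,
    grid: GridSpec,
    target_range: tuple[float, float] | None = ACTIVITY_RANGE,
) -> tuple[np.ndarray, GroundTruth]:
    """Assign planted pIC50 values to an aligned series.

    Activities are the weighted sum of similarity-field values at the
    receptor centers plus Gaussian noise, affinely rescaled into
    ``target_range`` (skipped when the raw spread is degenerate or
    ``target_range`` is None). Returns the activities and the planting
    record; the returned molecules are not modified.
    """
    for c in receptor.centers:
        if not grid.contains(c.position):
            raise ValueError(f"receptor center {c.position} lies outside the grid")
    n = len(molecules)
    components = np.empty((n, len(receptor.centers)))
    for ci, c in enumerate(receptor.centers):
        pos = np.asarray(c.position)[None, :]
        for j, mol in enumerate(molecules):
            components[j, ci] = comsia_field(mol, pos, c.kind)[0]
    weights = np.array([c.weight for c in receptor.centers])
    rng = np.random.default_rng(receptor.seed)
    raw = receptor.activity_offset + components @ weights
    raw = raw + rng.normal(0.0, receptor.noise_sd, size=n)
    if target_range is not None and raw.max() - raw.min() > 1e-9:
        lo, hi = target_range
        scale = (hi - lo) / (raw.max() - raw.min())
        shift = lo - raw.min() * scale
        y = raw * scale + shift
    else:
        scale, shift = 1.0, 0.0
        y = raw
    truth = GroundTruth(
        scale=float(scale),
        shift=float(shift),
        effective_weights=list(weights * scale),
        raw_components=components,
    )
    return y, truth


def recovery_report(
    model: PLSModel,
    receptor: ReceptorSpec,
    grid: GridSpec,
    X_train: np.ndarray,
    metadata: list[ColumnMeta],
    q2: float | None = None,
    r_pred2: float | None = None,
    high_weight_frac: float = 0.5,
) -> RecoveryReport:
    """Compare fitted StDev*Coeff signs against the planted weights.

    Only "high-weight" centers — |weight| at least ``high_weight_frac``
    of the largest |weight| — are scored; the fitted map value is read
    at the lattice point nearest each center. Internal (q²) and
    external (r_pred²) statistics are carried through when supplied.
    """
    kinds = sorted({c.kind for c in receptor.centers})
    maps = {k: stdev_coeff(model, X_train, metadata, k, grid) for k in kinds}
    wmax = max(abs(c.weight) for c in receptor.centers)
    per_center = []
    agree = 0
    checked = 0
    for c in receptor.centers:
        idx = grid.nearest_index(c.position)
        value = float(maps[c.kind][idx])
        high = abs(c.weight) >= high_weight_frac * wmax
        ok = bool(np.sign(value) == np.sign(c.weight)) and value != 0.0
        per_center.append(
            {
                "position": c.position,
                "kind": c.kind,
                "weight": c.weight,
                "stdev_coeff": value,
                "high_weight": high,
                "sign_match": ok,
            }
        )
        if high:
            checked += 1
            agree += ok
    return RecoveryReport(
        sign_agreement=agree / checked if checked else float("nan"),
        n_centers_checked=checked,
        per_center=per_center,
        q2=q2,
        r_pred2=r_pred2,
    )


def make_dataset(
    n_molecules: int = 105,
    seed: int = 0,
    noise_sd: float = 0.1,
    test_fraction: float = 28 / 105,
    receptor: ReceptorSpec | None = None,
    spacing: float = 2.0,
    margin: float = 4.0,
) -> dict:
    """One-call synthetic study: series, planted activities, split.

    Generates the series, aligns it on the phosphate anchor, plants
    activities from the receptor, and draws a stratified train/test
    split (defaults mirror a 105-compound, 77/28 study). Returns a
    context dict with the *posed* dataset (so downstream alignment is
    exercised), the aligned dataset, grid, receptor and ground truth.
    """
    from .alignment import DEFAULT_ANCHOR, align_molecules
    from .chem_io import split_dataset
    from .fields import build_grid

    molecules = generate_series(n_molecules, seed=seed)
    aligned, _ = align_molecules(molecules, molecules[0].id, DEFAULT_ANCHOR)
    grid = build_grid(aligned, spacing=spacing, margin=margin)
    if receptor is None:
        receptor = default_receptor(noise_sd=noise_sd, seed=seed + 1)
    y, truth = plant_activities(aligned, receptor, grid)
    activities = {m.id: float(v) for m, v in zip(molecules, y)}
    dataset = split_dataset(
        molecules, activities=activities, test_fraction=test_fraction, seed=seed + 2
    )
    aligned_ds = dataset.with_molecules(
        [m.with_coords(a.coords) for m, a in zip(dataset.molecules, aligned)]
    )
    return {
        "dataset": dataset,
        "aligned": aligned_ds,
        "grid": grid,
        "receptor": receptor,
        "truth": truth,
        "activities": activities,
    }


def write_synthetic_inputs(
    outdir: str | Path,
    molecules: Sequence[Molecule],
    activities: dict[str, float],
    test_ids: Sequence[str],
    receptor: ReceptorSpec,
) -> dict[str, Path]:
    """Write the pipeline input contract: SDF, activity CSV, split, receptor JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "molecules": outdir / "molecules.sdf",
        "activities": outdir / "activities.csv",
        "split": outdir / "test_ids.txt",
        "receptor": outdir / "receptor.json",
    }
    write_sdf(molecules, paths["molecules"])
    with open(paths["activities"], "w") as fh:
        fh.write("id,pic50\n")
        for m in molecules:
            fh.write(f"{m.id},{activities[m.id]:.6f}\n")
    paths["split"].write_text("\n".join(test_ids) + "\n")
    paths["receptor"].write_text(
        json.dumps(
            {
                "centers": [asdict(c) for c in receptor.centers],
                "noise_sd": receptor.noise_sd,
                "activity_offset": receptor.activity_offset,
                "seed": receptor.seed,
            },
            indent=2,
        )
    )
    return paths
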