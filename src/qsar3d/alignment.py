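"""Substructure-based rigid-body alignment.

Every molecule of a congeneric series is superposed onto a template by
least-squares (Kabsch) fitting of the atoms matched by a common
substructure pattern — the shared anchor, typically the phosphate
group of the inhibitor series. Only the mapped anchor atoms enter the
fit; substituents ride along. Symmetric patterns (e.g. the three
equivalent terminal P–O oxygens) yield several atom mappings; each is
evaluated and the minimal-RMSD one is kept, with a deterministic
lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from scipy.spatial.transform import Rotation

from .chem_io import Molecule, QsarDataset

__all__ = [
    "DEFAULT_ANCHOR",
    "SubstructureMatch",
    "RigidTransform",
    "match_substructure",
    "superpose",
    "align_molecules",
    "align_dataset",
]

#: phosphorus bonded to at least three oxygens — the phosphate anchor
DEFAULT_ANCHOR = "[#15](~[#8])(~[#8])~[#8]"


@dataclass(frozen=True)
class SubstructureMatch:
    """All pattern embeddings found in one molecule."""

    query: str
    matches: tuple[tuple[int, ...], ...]  # atom indices, one tuple per embedding

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    @property
    def atom_indices(self) -> tuple[int, ...]:
        """First embedding, in canonical (lexicographic) order."""
        return self.matches[0]


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ rotation·x + translation, with the RMSD over the fit atoms."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def match_substructure(mol: Molecule, query: str) -> SubstructureMatch:
    """Find all embeddings of a SMARTS pattern in the molecule.

    Automorphic matches (symmetry-equivalent atom orderings) are kept,
    since distinct orderings give distinct rigid fits.
    """
    patt = Chem.MolFromSmarts(query)
    if patt is None:
        raise ValueError(f"cannot parse SMARTS pattern {query!r}")
    rmol = mol.to_rdkit()
    raw = rmol.GetSubstructMatches(patt, uniquify=False, maxMatches=10000)
    if not raw:
        raise ValueError(f"pattern {query!r} not found in molecule {mol.id!r}")
    matches = tuple(sorted(tuple(m) for m in raw))
    return SubstructureMatch(query=query, matches=matches)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of paired point sets.

    Returns the proper rotation and translation minimising the RMSD of
    ``mobile`` onto ``reference`` over all rigid transforms (Kabsch).
    Requires ≥3 non-collinear pairs for a unique solution.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs for a rigid fit")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinearity: second singular value of either centred set ~ 0
    if min(np.linalg.svd(mob_c, compute_uv=False)[1],
           np.linalg.svd(ref_c, compute_uv=False)[1]) < 1e-8:
        raise ValueError("degenerate (collinear) geometry; rigid fit not unique")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    rmsd = float(rssd / np.sqrt(n))
    rotation = rot.as_matrix()
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    return RigidTransform(rotation=rotation, translation=translation, rmsd=rmsd)


def _best_fit(
    mol: Molecule, match: SubstructureMatch, ref_coords: np.ndarray
) -> RigidTransform:
    """Minimal-RMSD fit over all pattern embeddings (deterministic order)."""
    coords = mol.coords
    best: RigidTransform | None = None
    for mapping in match.matches:  # already lexicographically sorted
        tf = superpose(coords[list(mapping)], ref_coords)
        if best is None or tf.rmsd < best.rmsd - 1e-12:
            best = tf
    assert best is not None
    return best


def align_molecules(
    molecules: list[Molecule],
    template_id: str,
    query: str = DEFAULT_ANCHOR,
) -> tuple[list[Molecule], dict[str, float]]:
    """Superpose every molecule onto the template via the anchor pattern.

    The template molecule is left untouched; every other molecule is
    rigidly moved so its anchor best fits the template's anchor.
    Returns the aligned molecules (input order) and a per-molecule
    anchor RMSD report.
    """
    by_id = {m.id: m for m in molecules}
    if template_id not in by_id:
        raise ValueError(f"template id {template_id!r} not in dataset")
    template = by_id[template_id]
    ref_match = match_substructure(template, query)
    ref_coords = template.coords[list(ref_match.atom_indices)]

    unmatched = []
    matches: dict[str, SubstructureMatch] = {}
    for m in molecules:
        try:
            matches[m.id] = match_substructure(m, query)
        except ValueError:
            unmatched.append(m.id)
    if unmatched:
        raise ValueError(f"anchor pattern {query!r} not found in molecules: {unmatched}")

    aligned: list[Molecule] = []
    rmsds: dict[str, float] = {}
    for m in molecules:
        if m.id == template_id:
            aligned.append(m)
            rmsds[m.id] = 0.0
            continue
        tf = _best_fit(m, matches[m.id], ref_coords)
        aligned.append(m.with_coords(tf.apply(m.coords)))
        rmsds[m.id] = tf.rmsd
    return aligned, rmsds


def align_dataset(
    dataset: QsarDataset,
    template_id: str,
    query: str = DEFAULT_ANCHOR,
) -> tuple[QsarDataset, dict[str, float]]:
    """:func:`align_molecules` on a dataset, preserving train/test roles."""
    aligned, rmsds = align_molecules(dataset.molecules, template_id, query)
    return dataset.with_molecules(aligned), rmsds
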