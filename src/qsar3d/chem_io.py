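"""Molecule and activity I/O.

Molecules are carried as plain atom lists (element, 3D coordinates,
partial charge and the per-atom physicochemical properties the
similarity fields need) rather than as toolkit objects, so that
synthetic series with explicit, non-chemical property assignments flow
through the same pipeline as file-derived structures. RDKit does the
actual SDF/MOL2 parsing, Gasteiger charging and substructure chemistry
behind this surface.

Activities are pIC50 = −log10(IC50 in molar); the activity table may
supply either column.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors, rdPartialCharges

from .params import vdw_radius as _table_vdw_radius

__all__ = [
    "Atom",
    "Molecule",
    "QsarDataset",
    "read_molecules",
    "write_sdf",
    "assign_gasteiger_charges",
    "annotate_properties",
    "load_activity_table",
    "read_split_file",
    "split_dataset",
]

# SDF data-field names used for explicit per-atom properties
_TAG_CHARGES = "PARTIAL_CHARGES"
_TAG_HYDRO = "ATOM_HYDROPHOBICITY"
_TAG_RADII = "ATOM_VDW_RADII"
_TAG_HBD = "ATOM_HBD"
_TAG_HBA = "ATOM_HBA"


@dataclass(frozen=True)
class Atom:
    """One atom: element, position and field-relevant properties.

    ``hydrophobicity`` is a dimensionless per-atom contribution (Crippen
    logP contribution for file-derived molecules); ``is_hbd``/``is_hba``
    flag hydrogen-bond donor/acceptor character. Properties left as
    ``None`` are filled by :func:`annotate_properties`.
    """

    element: str
    coords: tuple[float, float, float]
    partial_charge: float | None = None
    formal_charge: int = 0
    vdw_radius: float | None = None
    hydrophobicity: float | None = None
    is_hbd: bool | None = None
    is_hba: bool | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.element}")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass
class Molecule:
    """An identified 3D structure with optional activity.

    ``bonds`` are (i, j, order) index triples; order uses the SDF
    convention (1–3, 4 = aromatic). Bonds are needed only for
    substructure matching and charge assignment, not for field
    evaluation.
    """

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    pic50: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        if self.pic50 is not None and not math.isfinite(self.pic50):
            raise ValueError(f"molecule {self.id!r} has non-finite pIC50")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """Atom coordinates as an (n_atoms, 3) array in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        """Copy of the molecule with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, coords=tuple(xyz)) for a, xyz in zip(self.atoms, coords)
        ]
        return Molecule(self.id, atoms, list(self.bonds), self.pic50)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Apply a rigid transform x ↦ R·x + t."""
        new = self.coords @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return self.with_coords(new)

    def charges(self) -> np.ndarray:
        """Partial charges as an array; raises if any are absent."""
        q = [a.partial_charge for a in self.atoms]
        if any(c is None for c in q):
            raise ValueError(f"molecule {self.id!r} has atoms without partial charges")
        return np.array(q, dtype=float)

    def to_rdkit(self, sanitize: bool = False) -> Chem.Mol:
        """Build an RDKit molecule (3D conformer, bonds, formal charges)."""
        em = Chem.RWMol()
        for a in self.atoms:
            ra = Chem.Atom(a.element)
            ra.SetFormalCharge(a.formal_charge)
            ra.SetNoImplicit(True)
            em.AddAtom(ra)
        order_map = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
            4: Chem.BondType.AROMATIC,
        }
        for i, j, order in self.bonds:
            em.AddBond(int(i), int(j), order_map.get(order, Chem.BondType.SINGLE))
        mol = em.GetMol()
        conf = Chem.Conformer(self.n_atoms)
        for k, a in enumerate(self.atoms):
            conf.SetAtomPosition(k, a.coords)
        conf.Set3D(True)
        mol.AddConformer(conf)
        mol.SetProp("_Name", self.id)
        if sanitize:
            Chem.SanitizeMol(mol)
        else:
            mol.UpdatePropertyCache(strict=False)
            Chem.FastFindRings(mol)
        return mol


@dataclass
class QsarDataset:
    """Molecules plus a train/test role for every id."""

    molecules: list[Molecule]
    role: dict[str, str]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate molecule ids in dataset")
        for m in self.molecules:
            if m.pic50 is None:
                raise ValueError(f"molecule {m.id!r} has no pIC50")
            if self.role.get(m.id) not in ("train", "test"):
                raise ValueError(f"molecule {m.id!r} has no train/test role")
        extra = set(self.role) - set(ids)
        if extra:
            raise ValueError(f"roles for unknown ids: {sorted(extra)}")

    @property
    def train(self) -> list[Molecule]:
        return [m for m in self.molecules if self.role[m.id] == "train"]

    @property
    def test(self) -> list[Molecule]:
        return [m for m in self.molecules if self.role[m.id] == "test"]

    @property
    def y_train(self) -> np.ndarray:
        return np.array([m.pic50 for m in self.train], dtype=float)

    @property
    def y_test(self) -> np.ndarray:
        return np.array([m.pic50 for m in self.test], dtype=float)

    def train_mask(self) -> np.ndarray:
        return np.array([self.role[m.id] == "train" for m in self.molecules])

    def with_molecules(self, molecules: list[Molecule]) -> "QsarDataset":
        return QsarDataset(molecules, dict(self.role))


# ---------------------------------------------------------------------------
# reading / writing


def _float_list(mol: Chem.Mol, tag: str) -> list[float] | None:
    if not mol.HasProp(tag):
        return None
    return [float(x) for x in mol.GetProp(tag).split()]


def _from_rdkit(mol: Chem.Mol, fallback_id: str) -> Molecule:
    conf = mol.GetConformer()
    if not conf.Is3D():
        raise ValueError(f"record {fallback_id!r} carries 2D-only coordinates")
    n = mol.GetNumAtoms()
    charges = _float_list(mol, _TAG_CHARGES)
    hydro = _float_list(mol, _TAG_HYDRO)
    radii = _float_list(mol, _TAG_RADII)
    hbd = _float_list(mol, _TAG_HBD)
    hba = _float_list(mol, _TAG_HBA)
    for name, vals in ((_TAG_CHARGES, charges), (_TAG_HYDRO, hydro),
                       (_TAG_RADII, radii), (_TAG_HBD, hbd), (_TAG_HBA, hba)):
        if vals is not None and len(vals) != n:
            raise ValueError(f"{name} length {len(vals)} != atom count {n}")
    if charges is None and mol.GetAtomWithIdx(0).HasProp("_TriposPartialCharge"):
        charges = [
            float(mol.GetAtomWithIdx(i).GetProp("_TriposPartialCharge"))
            for i in range(n)
        ]
    atoms = []
    for i in range(n):
        a = mol.GetAtomWithIdx(i)
        pos = conf.GetAtomPosition(i)
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                coords=(pos.x, pos.y, pos.z),
                partial_charge=None if charges is None else charges[i],
                formal_charge=a.GetFormalCharge(),
                vdw_radius=None if radii is None else radii[i],
                hydrophobicity=None if hydro is None else hydro[i],
                is_hbd=None if hbd is None else bool(hbd[i]),
                is_hba=None if hba is None else bool(hba[i]),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
         4 if b.GetBondType() == Chem.BondType.AROMATIC else int(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    mol_id = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
    pic50 = float(mol.GetProp("PIC50")) if mol.HasProp("PIC50") else None
    return Molecule(mol_id or fallback_id, atoms, bonds, pic50)


def _read_sdf(path: Path) -> list[Molecule]:
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: no records")
    if "V3000" in text:
        raise ValueError(f"{path}: V3000 SDF is not supported; supply V2000")
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols: list[Molecule] = []
    for i, raw in enumerate(supplier):
        if raw is None:
            raise ValueError(f"{path}: unreadable SDF record at index {i}")
        raw.UpdatePropertyCache(strict=False)
        mols.append(_from_rdkit(raw, fallback_id=f"mol_{i}"))
    if not mols:
        raise ValueError(f"{path}: no records")
    return mols


def _read_mol2(path: Path) -> list[Molecule]:
    text = path.read_text()
    blocks = [
        "@<TRIPOS>MOLECULE" + chunk
        for chunk in text.split("@<TRIPOS>MOLECULE")[1:]
    ]
    if not blocks:
        raise ValueError(f"{path}: no records")
    mols = []
    for i, block in enumerate(blocks):
        raw = Chem.MolFromMol2Block(block, sanitize=False, removeHs=False)
        if raw is None:
            raise ValueError(f"{path}: unreadable MOL2 record at index {i}")
        raw.UpdatePropertyCache(strict=False)
        mols.append(_from_rdkit(raw, fallback_id=f"mol_{i}"))
    return mols


def read_molecules(path: str | Path, fmt: str | None = None) -> list[Molecule]:
    """Read molecules from an SDF (V2000) or MOL2 file.

    Coordinates are taken verbatim; partial charges come from the file
    when present (MOL2 charge column, or an SDF ``PARTIAL_CHARGES``
    data field) and are otherwise left absent for later assignment.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "sdf":
        return _read_sdf(path)
    if fmt == "mol2":
        return _read_mol2(path)
    raise ValueError(f"unknown molecule format {fmt!r} (expected sdf or mol2)")


def write_sdf(molecules: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules to SDF V2000, embedding per-atom properties.

    Partial charges and the CoMSIA per-atom properties are stored as
    whitespace-separated data fields so a round trip through
    :func:`read_molecules` is lossless (1e-4 in coordinates/charges).
    """
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for m in molecules:
            mol = m.to_rdkit()
            if all(a.partial_charge is not None for a in m.atoms):
                mol.SetProp(_TAG_CHARGES, " ".join(f"{a.partial_charge:.6f}" for a in m.atoms))
            if all(a.hydrophobicity is not None for a in m.atoms):
                mol.SetProp(_TAG_HYDRO, " ".join(f"{a.hydrophobicity:.6f}" for a in m.atoms))
            if all(a.vdw_radius is not None for a in m.atoms):
                mol.SetProp(_TAG_RADII, " ".join(f"{a.vdw_radius:.6f}" for a in m.atoms))
            if all(a.is_hbd is not None for a in m.atoms):
                mol.SetProp(_TAG_HBD, " ".join(str(int(a.is_hbd)) for a in m.atoms))
            if all(a.is_hba is not None for a in m.atoms):
                mol.SetProp(_TAG_HBA, " ".join(str(int(a.is_hba)) for a in m.atoms))
            if m.pic50 is not None:
                mol.SetProp("PIC50", f"{m.pic50:.6f}")
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# charges and per-atom properties


def assign_gasteiger_charges(mol: Molecule) -> Molecule:
    """Assign Gasteiger (PEOE) partial charges.

    File-supplied charges are the caller's responsibility to prefer;
    this function always recomputes. The charge total is checked
    against the net formal charge to 1e-3.
    """
    rmol = mol.to_rdkit()
    try:
        Chem.SanitizeMol(rmol)
        rdPartialCharges.ComputeGasteigerCharges(rmol, throwOnParamFailure=True)
    except Exception as exc:  # RDKit raises several exception types here
        raise ValueError(f"cannot assign Gasteiger charges to {mol.id!r}: {exc}") from exc
    q = [rmol.GetAtomWithIdx(i).GetDoubleProp("_GasteigerCharge") for i in range(mol.n_atoms)]
    if not all(math.isfinite(c) for c in q):
        raise ValueError(f"Gasteiger charges non-finite for {mol.id!r}")
    net = sum(a.formal_charge for a in mol.atoms)
    if abs(sum(q) - net) > 1e-3:
        raise ValueError(
            f"charge total {sum(q):.4f} differs from net formal charge {net} for {mol.id!r}"
        )
    atoms = [replace(a, partial_charge=c) for a, c in zip(mol.atoms, q)]
    return Molecule(mol.id, atoms, list(mol.bonds), mol.pic50)


def annotate_properties(mol: Molecule) -> Molecule:
    """Fill missing per-atom field properties.

    vdW radii come from the element table; hydrophobicity uses Crippen
    atomic logP contributions; donor/acceptor flags use a rule-based
    assignment (donor: N/O bearing an explicit hydrogen; acceptor: N/O
    without positive formal charge). Properties already present — e.g.
    explicit assignments on synthetic molecules — are kept.
    """
    need_hydro = any(a.hydrophobicity is None for a in mol.atoms)
    contribs = None
    if need_hydro:
        rmol = mol.to_rdkit()
        try:
            Chem.SanitizeMol(rmol)
        except Exception as exc:
            raise ValueError(
                f"cannot derive hydrophobicity for {mol.id!r}: {exc}"
            ) from exc
        contribs = rdMolDescriptors._CalcCrippenContribs(rmol)
    heavy_nbrs: dict[int, list[str]] = {i: [] for i in range(mol.n_atoms)}
    for i, j, _ in mol.bonds:
        heavy_nbrs[i].append(mol.atoms[j].element)
        heavy_nbrs[j].append(mol.atoms[i].element)
    atoms = []
    for i, a in enumerate(mol.atoms):
        radius = a.vdw_radius if a.vdw_radius is not None else _table_vdw_radius(a.element)
        hydro = a.hydrophobicity if a.hydrophobicity is not None else contribs[i][0]
        is_no = a.element in ("N", "O")
        hbd = a.is_hbd if a.is_hbd is not None else (is_no and "H" in heavy_nbrs[i])
        hba = a.is_hba if a.is_hba is not None else (is_no and a.formal_charge <= 0)
        atoms.append(
            replace(a, vdw_radius=radius, hydrophobicity=hydro, is_hbd=hbd, is_hba=hba)
        )
    return Molecule(mol.id, atoms, list(mol.bonds), mol.pic50)


# ---------------------------------------------------------------------------
# activities and splits


def load_activity_table(path: str | Path) -> dict[str, float]:
    """Load ``id → pIC50`` from a CSV with ``id`` and ``ic50_M`` or ``pic50``."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("activity table needs an 'id' column")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in activity table: {dupes}")
    if "pic50" in df.columns:
        values = df["pic50"].astype(float)
    elif "ic50_M" in df.columns:
        ic50 = df["ic50_M"].astype(float)
        if (ic50 <= 0).any():
            bad = df.loc[ic50 <= 0, "id"].tolist()
            raise ValueError(f"non-positive IC50 for ids: {bad}")
        values = -np.log10(ic50)
    else:
        raise ValueError("activity table needs an 'ic50_M' or 'pic50' column")
    if not np.isfinite(values).all():
        raise ValueError("non-finite activity values")
    return dict(zip(df["id"], values.astype(float)))


def read_split_file(path: str | Path) -> list[str]:
    """Read test-set membership: one molecule id per line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [ln for ln in lines if ln and not ln.startswith("#")]


def split_dataset(
    molecules: Sequence[Molecule],
    test_ids: Sequence[str] | None = None,
    *,
    activities: Mapping[str, float] | None = None,
    test_fraction: float | None = None,
    seed: int | None = None,
) -> QsarDataset:
    """Assign train/test roles, either explicitly or by stratified draw.

    With ``test_ids`` the list is honoured verbatim. Otherwise
    ``test_fraction`` selects a test set stratified over pIC50 quantile
    bins so the test activities span the observed range; the molecules
    with the extreme (min/max) activities are always kept in training,
    so the model never extrapolates at validation time. Deterministic
    for a given seed.
    """
    mols = list(molecules)
    if activities is not None:
        mols = [
            Molecule(m.id, m.atoms, list(m.bonds), activities[m.id])
            if m.id in activities else m
            for m in mols
        ]
    missing = [m.id for m in mols if m.pic50 is None]
    if missing:
        raise ValueError(f"molecules without pIC50: {missing}")
    ids = [m.id for m in mols]
    if test_ids is not None:
        unknown = set(test_ids) - set(ids)
        if unknown:
            raise ValueError(f"unknown test ids: {sorted(unknown)}")
        test_set = set(test_ids)
    else:
        if test_fraction is None or not (0 < test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1) when test_ids is absent")
        rng = np.random.default_rng(seed)
        y = np.array([m.pic50 for m in mols])
        order = np.argsort(y, kind="stable")
        n_test = int(round(test_fraction * len(mols)))
        n_test = max(1, min(n_test, len(mols) - 2))
        candidates = order[1:-1]  # extremes stay in training
        bins = np.array_split(candidates, n_test)
        test_set = {ids[int(rng.choice(b))] for b in bins if len(b)}
    role = {i: ("test" if i in test_set else "train") for i in ids}
    return QsarDataset(mols, role)
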