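"""Lattice construction and CoMFA/CoMSIA field evaluation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from qsar3d.chem_io import Atom, Molecule
from qsar3d.fields import (
    COMSIA_KINDS,
    ColumnMeta,
    GridSpec,
    ProbeSpec,
    assemble_descriptor_matrix,
    block_labels,
    build_grid,
    comfa_blocks,
    comfa_electrostatic,
    comfa_steric,
    comsia_block,
    comsia_field,
    filter_columns,
)
from qsar3d.params import COULOMB_KCAL
from qsar3d.synthetic_data import generate_series

from conftest import comsia_bruteforce


def _atom(element="C", coords=(0.0, 0.0, 0.0), charge=0.0, **kw):
    defaults = dict(vdw_radius=1.7, hydrophobicity=0.5, is_hbd=False, is_hba=False)
    defaults.update(kw)
    return Atom(element, coords, partial_charge=charge, **defaults)


def _mol(atoms, mol_id="m"):
    return Molecule(mol_id, atoms)


class TestBuildGrid:
    def test_single_atom_margin4(self):
        grid = build_grid([_mol([_atom()])], spacing=2.0, margin=4.0)
        assert grid.origin == (-4.0, -4.0, -4.0)
        assert grid.dims == (5, 5, 5)
        assert grid.n_points == 125

    def test_zero_margin_snaps_to_two_points(self):
        grid = build_grid([_mol([_atom()])], spacing=2.0, margin=0.0)
        assert grid.dims == (2, 2, 2)

    def test_larger_margin_never_removes_points(self):
        mols = [_mol([_atom(coords=(1.3, -0.7, 2.9))])]
        sizes = [build_grid(mols, 2.0, m).n_points for m in (0.0, 2.0, 4.0, 8.0)]
        assert sizes == sorted(sizes)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_grid([])

    def test_point_order_x_fastest(self):
        grid = GridSpec((0.0, 0.0, 0.0), 1.0, (2, 2, 2))
        pts = grid.points()
        assert np.array_equal(pts[0], [0, 0, 0])
        assert np.array_equal(pts[1], [1, 0, 0])  # x advances first
        assert np.array_equal(pts[2], [0, 1, 0])
        assert np.array_equal(pts[4], [0, 0, 1])
        assert grid.nearest_index((1.2, 0.1, 0.9)) == 1 + 0 + 4


class TestComfaSteric:
    def test_far_point_negligible(self):
        vals, _ = comfa_steric(_mol([_atom()]), np.array([[25.0, 0, 0]]))
        assert abs(vals[0]) < 1e-5

    def test_clamped_at_atom_center(self):
        vals, clamped = comfa_steric(_mol([_atom()]), np.array([[0.0, 0, 0]]))
        assert vals[0] == 30.0
        assert clamped[0]

    def test_additivity_before_clamp(self):
        pts = np.array([[6.0, 0, 0], [0, 5.0, 1.0]])
        a1, a2 = _atom(coords=(0, 0, 0)), _atom(coords=(2.0, 0, 0))
        both, _ = comfa_steric(_mol([a1, a2]), pts)
        single = comfa_steric(_mol([a1]), pts)[0] + comfa_steric(_mol([a2]), pts)[0]
        assert np.allclose(both, single, atol=1e-12)

    def test_monotone_decay_beyond_minimum(self):
        # LJ minimum at r = R_ij; beyond it |E| decreases monotonically
        rij = 1.7 + 1.7
        rs = np.linspace(rij, 15, 100)
        pts = np.column_stack([rs, np.zeros_like(rs), np.zeros_like(rs)])
        vals, _ = comfa_steric(_mol([_atom()]), pts)
        assert np.all(np.diff(vals) >= -1e-12)  # rising from the well toward 0

    def test_unknown_element_errors(self):
        mol = _mol([Atom("Xx", (0, 0, 0), partial_charge=0.0)])
        with pytest.raises(KeyError, match="Xx"):
            comfa_steric(mol, np.array([[1.0, 0, 0]]))


class TestComfaElectrostatic:
    def test_closed_form_at_2A_clamps(self):
        # 332.0636·(1·1)/(ε(r)·r) = 332.0636/4 = 83.02 → clamped to +30
        vals = comfa_electrostatic(_mol([_atom(charge=1.0)]), np.array([[2.0, 0, 0]]))
        assert vals[0] == 30.0
        raw = COULOMB_KCAL / 4.0
        assert raw == pytest.approx(83.0159, abs=1e-4)

    def test_mirrored_charges_cancel(self):
        mol = _mol([_atom(charge=0.5, coords=(-1.0, 0, 0)),
                    _atom(charge=-0.5, coords=(1.0, 0, 0))])
        vals = comfa_electrostatic(mol, np.array([[0.0, 5.0, 0.0]]))
        assert vals[0] == pytest.approx(0.0, abs=1e-12)

    def test_sign_flip_negates_field(self):
        pts = np.array([[8.0, 1.0, 0.0], [0.0, 9.0, 2.0]])
        mol = _mol([_atom(charge=0.3), _atom(charge=-0.1, coords=(1.5, 0, 0))])
        flipped = _mol([_atom(charge=-0.3), _atom(charge=0.1, coords=(1.5, 0, 0))])
        assert np.allclose(
            comfa_electrostatic(mol, pts), -comfa_electrostatic(flipped, pts), atol=1e-12
        )

    def test_clamped_points_get_column_mean(self):
        # molecule b sits on the grid point: steric clamps there, so its
        # electrostatic entry becomes the mean of the others' values
        grid = GridSpec((0.0, 0.0, 0.0), 2.0, (2, 2, 2))
        mols = [
            _mol([_atom(charge=0.2, coords=(0.4, 0.2, 0.1))], "a"),
            _mol([_atom(charge=-0.5, coords=(0.0, 0.0, 0.0))], "b"),
            _mol([_atom(charge=0.1, coords=(0.3, 0.3, 0.0))], "c"),
        ]
        sblock, eblock = comfa_blocks(mols, grid)
        assert sblock.meta["clamped"][1, 0]
        expected = (eblock.values[0, 0] + eblock.values[2, 0]) / 2
        assert eblock.values[1, 0] == pytest.approx(expected)

    def test_missing_charges_error(self):
        mol = Molecule("q", [Atom("C", (0, 0, 0))])
        with pytest.raises(ValueError, match="charge"):
            comfa_electrostatic(mol, np.array([[1.0, 0, 0]]))


class TestComsia:
    def test_value_at_zero_distance(self):
        mol = _mol([_atom(vdw_radius=1.0)])  # steric ω = r³ = 1
        vals = comsia_field(mol, np.array([[0.0, 0, 0]]), "steric")
        assert vals[0] == pytest.approx(-1.0)

    def test_value_at_2A(self):
        mol = _mol([_atom(vdw_radius=1.0)])
        vals = comsia_field(mol, np.array([[2.0, 0, 0]]), "steric", alpha=0.3)
        assert vals[0] == pytest.approx(-np.exp(-1.2), abs=1e-12)

    def test_zero_properties_give_zero_field(self):
        mol = _mol([_atom(charge=0.0), _atom(charge=0.0, coords=(1.0, 1.0, 0))])
        vals = comsia_field(mol, np.random.default_rng(0).normal(size=(7, 3)), "electrostatic")
        assert np.allclose(vals, 0.0)

    def test_nonpositive_for_nonnegative_properties(self):
        mols = generate_series(5, seed=8)
        grid = build_grid(mols, 2.0, 2.0)
        assert np.all(comsia_block(mols, grid, "steric").values <= 0)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(5)
        atoms = [
            _atom(
                coords=tuple(rng.normal(0, 2, 3)),
                charge=float(rng.normal(0, 0.5)),
                vdw_radius=float(rng.uniform(1.2, 2.0)),
                hydrophobicity=float(rng.normal(0, 1)),
                is_hbd=bool(rng.random() < 0.5),
                is_hba=bool(rng.random() < 0.5),
            )
            for _ in range(6)
        ]
        mol = _mol(atoms)
        pts = rng.normal(0, 3, size=(11, 3))
        for kind in COMSIA_KINDS:
            assert np.allclose(
                comsia_field(mol, pts, kind), comsia_bruteforce(mol, pts, kind), atol=1e-12
            )

    def test_unknown_kind_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            comsia_field(_mol([_atom()]), np.array([[0.0, 0, 0]]), "magnetic")


class TestCoRotation:
    def test_fields_invariant_when_molecule_and_points_corotate(self):
        rng = np.random.default_rng(13)
        mol = _mol([
            _atom(coords=tuple(rng.normal(0, 2, 3)), charge=float(rng.normal(0, 0.4)))
            for _ in range(5)
        ])
        pts = rng.normal(0, 4, size=(9, 3))
        rot = Rotation.random(random_state=rng).as_matrix()
        trans = rng.uniform(-3, 3, 3)
        mol2 = mol.transformed(rot, trans)
        pts2 = pts @ rot.T + trans
        assert np.allclose(comfa_steric(mol, pts)[0], comfa_steric(mol2, pts2)[0], atol=1e-9)
        assert np.allclose(
            comfa_electrostatic(mol, pts), comfa_electrostatic(mol2, pts2), atol=1e-9
        )
        assert np.allclose(
            comsia_field(mol, pts, "electrostatic"),
            comsia_field(mol2, pts2, "electrostatic"),
            atol=1e-9,
        )

    def test_reproducible_bit_identical(self):
        mols = generate_series(6, seed=3)
        grid = build_grid(mols, 2.0, 2.0)
        a = comsia_block(mols, grid, "steric").values
        b = comsia_block(mols, grid, "steric").values
        assert np.array_equal(a, b)


class TestAssembly:
    def _blocks(self, n=4, seed=0):
        mols = generate_series(n, seed=seed)
        grid = build_grid(mols, 2.0, 2.0)
        return [comsia_block(mols, grid, k) for k in ("steric", "electrostatic")], grid

    def test_concatenated_shape(self):
        blocks, grid = self._blocks()
        X, meta = assemble_descriptor_matrix(blocks)
        assert X.shape == (4, 2 * grid.n_points)
        assert len(meta) == X.shape[1]

    def test_metadata_round_trips(self):
        blocks, grid = self._blocks()
        X, meta = assemble_descriptor_matrix(blocks)
        c = grid.n_points + 7
        assert meta[c] == ColumnMeta("comsia", "electrostatic", 7)
        assert X[:, c] == pytest.approx(blocks[1].values[:, 7])

    def test_reordering_blocks_permutes_columns(self):
        blocks, _ = self._blocks()
        X1, m1 = assemble_descriptor_matrix(blocks)
        X2, m2 = assemble_descriptor_matrix(blocks[::-1])
        perm = {((m.kind, m.point_index)): i for i, m in enumerate(m2)}
        idx = [perm[(m.kind, m.point_index)] for m in m1]
        assert np.array_equal(X1, X2[:, idx])

    def test_block_labels_group_by_kind(self):
        blocks, grid = self._blocks()
        _, meta = assemble_descriptor_matrix(blocks)
        labels = block_labels(meta)
        assert set(labels) == {0, 1}
        assert np.all(labels[: grid.n_points] == 0)


class TestFilterColumns:
    def _meta(self, p):
        return [ColumnMeta("comsia", "steric", i) for i in range(p)]

    def test_zero_min_sigma_keeps_all(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        Xf, _, keep = filter_columns(X, self._meta(4), 0.0)
        assert Xf.shape == X.shape and keep.all()

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.full(6, 3.0), rng.normal(size=6)])
        _, meta, keep = filter_columns(X, self._meta(2), 1e-6)
        assert list(keep) == [False, True]
        assert meta[0].point_index == 1

    def test_sd_threshold_example(self):
        # columns with sd 0, 1, 5; min_sigma 2 keeps exactly one
        base = np.array([-1.5, -0.5, 0.5, 1.5])  # sd = 1.29; scale to sd 1 and 5
        sd1 = base / base.std(ddof=1)
        X = np.column_stack([np.zeros(4), sd1, 5 * sd1])
        Xf, meta, _ = filter_columns(X, self._meta(3), 2.0)
        assert Xf.shape[1] == 1
        assert meta[0].point_index == 2

    def test_all_dropped_errors(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="every descriptor"):
            filter_columns(X, self._meta(2), 0.5)


def test_comsia_probe_properties_all_unit():
    probe = ProbeSpec()
    for kind in COMSIA_KINDS:
        assert probe.comsia_property(kind) == 1.0
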