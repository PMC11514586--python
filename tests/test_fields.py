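"""Grid construction, probe energies and cube I/O."""

import numpy as np
import pytest

from grindqsar.fields import (GridSpec, build_grid, compute_field, read_cube,
                              write_cube, Field)
from grindqsar.params import ProbeParams, load_probe_params
from grindqsar.structures import Atom, Molecule, prepare

COULOMB = 332.0636


def single_atom(q=0.0, element="C"):
    mol = Molecule("one", [Atom(element, [0.0, 0.0, 0.0], partial_charge=q)])
    return mol


def bare_probe(probe_id="O", charge=-1.0, hbond=0.0, eps=0.0):
    base = load_probe_params()[probe_id]
    from dataclasses import replace
    return replace(base, charge=charge, hbond_depth=hbond, eps=eps)


class TestBuildGrid:
    @pytest.mark.parametrize("spacing,expected", [(0.5, (21, 21, 21)),
                                                  (1.0, (11, 11, 11))])
    def test_single_atom_shapes(self, spacing, expected):
        grid = build_grid(single_atom(), spacing=spacing, margin=5.0)
        assert grid.shape == expected

    def test_two_atom_extent(self):
        mol = Molecule("two", [Atom("C", [0, 0, 0]), Atom("C", [4.0, 0, 0])])
        grid = build_grid(mol, spacing=0.5, margin=5.0)
        assert max(grid.shape) == 29  # 14 A extent along the long axis

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            build_grid(single_atom(), spacing=0.0)

    def test_box_encloses_atoms_with_margin(self, benzene_prepared):
        grid = build_grid(benzene_prepared, spacing=0.5, margin=5.0)
        pts = grid.points()
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        for xyz in benzene_prepared.coords:
            assert np.all(xyz >= lo - 0.51) and np.all(xyz <= hi + 0.51)


class TestComputeField:
    def test_electrostatic_hand_value(self):
        # q_atom=+1, q_probe=-1, eps(r)=4r, r=3 A, LJ and H-bond off
        mol = single_atom(q=1.0)
        grid = GridSpec(origin=np.array([3.0, 0.0, 0.0]), spacing=0.5,
                        shape=(2, 2, 2))
        field = compute_field(mol, bare_probe(), grid)
        expected = COULOMB * (-1.0) / (4.0 * 3.0 ** 2)
        assert field.energies[0, 0, 0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-9.22, abs=0.01)

    def test_far_field_decays(self, benzene_prepared):
        probes = load_probe_params()
        grid = GridSpec(origin=np.array([25.0, 0.0, 0.0]), spacing=0.5,
                        shape=(2, 2, 2))
        for probe in probes.values():
            field = compute_field(benzene_prepared, probe, grid)
            assert np.all(np.abs(field.energies) < 0.01)

    def test_benzene_dry_minimum_above_ring(self, benzene_prepared):
        probes = load_probe_params()
        grid = build_grid(benzene_prepared, spacing=0.25, margin=5.0)
        field = compute_field(benzene_prepared, probes["DRY"], grid)
        best = grid.points()[np.argmin(field.energies.ravel())]
        coords = benzene_prepared.coords
        ring = coords[[i for i, el in enumerate(benzene_prepared.elements)
                       if el == "C"]]
        center = ring.mean(axis=0)
        # ring normal from SVD of the centered ring coordinates
        _, _, vt = np.linalg.svd(ring - center)
        height = abs((best - center) @ vt[2])
        assert height > 1.5  # well above/below the aromatic plane

    def test_translation_equivariance(self, benzene_prepared):
        probes = load_probe_params()
        mol = benzene_prepared
        shifted = Molecule(mol.id,
                           [Atom(a.element, a.coords + np.array([3.0, -2.0, 7.0]),
                                 a.partial_charge, a.formal_charge,
                                 a.is_hydrophobic, a.is_hba, a.is_hbd)
                            for a in mol.atoms], list(mol.bonds))
        for pid in ("DRY", "O"):
            f1 = compute_field(mol, probes[pid], build_grid(mol, 1.0, 5.0))
            f2 = compute_field(shifted, probes[pid], build_grid(shifted, 1.0, 5.0))
            np.testing.assert_allclose(f1.energies, f2.energies, atol=1e-9)

    def test_superposition_pairwise_additive(self):
        # same world-frame grid; H-bond off; energies below the clamp
        a = single_atom(q=0.3)
        b = Molecule("b", [Atom("C", [2.0, 1.0, 0.0], partial_charge=-0.2)])
        ab = Molecule("ab", a.atoms + b.atoms)
        probe = bare_probe(charge=-0.25, eps=0.2)
        grid = GridSpec(origin=np.array([-4.0, -4.0, -4.0]), spacing=1.0,
                        shape=(10, 10, 10))
        e_a = compute_field(a, probe, grid).energies
        e_b = compute_field(b, probe, grid).energies
        e_ab = compute_field(ab, probe, grid).energies
        clamp = probe.energy_clamp
        mask = (e_a < clamp) & (e_b < clamp) & ((e_a + e_b) < clamp)
        np.testing.assert_allclose(e_ab[mask], (e_a + e_b)[mask], atol=1e-9)

    def test_clamp_inside_atoms(self, benzene_prepared):
        probes = load_probe_params()
        grid = build_grid(benzene_prepared, spacing=0.5, margin=2.0)
        field = compute_field(benzene_prepared, probes["O"], grid)
        assert field.energies.max() <= probes["O"].energy_clamp + 1e-12

    def test_missing_charges_rejected(self):
        mol = Molecule("two", [Atom("C", [0, 0, 0]), Atom("O", [1.2, 0, 0])],
                       [(0, 1, 2.0)])
        grid = build_grid(mol, 1.0, 3.0)
        with pytest.raises(ValueError, match="assign_partial_charges"):
            compute_field(mol, load_probe_params()["O"], grid)

    def test_tip_shell_indicator(self):
        mol = prepare(Molecule("c", [Atom("C", [0.0, 0.0, 0.0])],
                               []))
        probes = load_probe_params()
        grid = GridSpec(origin=np.array([0.0, 0.0, 0.0]), spacing=0.5,
                        shape=(13, 2, 2))
        field = compute_field(mol, probes["TIP"], grid)
        r = np.arange(13) * 0.5
        rvdw = probes["TIP"].atom_r0["C"]
        expected = np.where((r >= rvdw) & (r <= rvdw + 0.5), -1.0, 0.0)
        np.testing.assert_array_equal(field.energies[:, 0, 0], expected)


class TestCubeIO:
    def test_zero_field_round_trips(self, tmp_path):
        grid = GridSpec(origin=np.array([-1.0, 2.0, -3.0]), spacing=0.5,
                        shape=(2, 2, 2))
        field = Field(grid, "DRY", np.zeros((2, 2, 2)))
        path = tmp_path / "f.cube"
        write_cube(field, path)
        back = read_cube(path)
        np.testing.assert_array_equal(back.energies, field.energies)
        np.testing.assert_allclose(back.grid.origin, grid.origin, atol=1e-6)
        assert back.probe_id == "DRY"

    def test_round_trip_energies(self, tmp_path, benzene_prepared):
        probes = load_probe_params()
        grid = build_grid(benzene_prepared, spacing=1.0, margin=3.0)
        field = compute_field(benzene_prepared, probes["DRY"], grid)
        path = tmp_path / "benzene.cube"
        write_cube(field, path, benzene_prepared)
        back = read_cube(path)
        assert back.grid.shape == grid.shape
        np.testing.assert_allclose(back.energies, field.energies, atol=1e-4)

    def test_header_voxel_count(self, tmp_path):
        grid = GridSpec(origin=np.zeros(3), spacing=0.5, shape=(3, 4, 5))
        field = Field(grid, "TIP", np.zeros((3, 4, 5)))
        path = tmp_path / "g.cube"
        write_cube(field, path)
        lines = path.read_text().splitlines()
        counts = [int(lines[i].split()[0]) for i in (3, 4, 5)]
        assert np.prod(counts) == 60
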