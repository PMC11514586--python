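"""Node extraction and correlogram encoding against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grindqsar.fields import Field, GridSpec
from grindqsar.grind import (BLOCKS, NodeSet, Node, encode_correlogram,
                             extract_nodes, meta_to_index, n_bins,
                             variable_lookup, all_variable_meta)
from grindqsar.simulate import generate_toy_nodes


def make_field(energies, spacing=1.0):
    energies = np.asarray(energies, dtype=float)
    grid = GridSpec(origin=np.zeros(3), spacing=spacing, shape=energies.shape)
    return Field(grid, "DRY", energies)


def greedy_oracle(field, n_nodes, w):
    """Straight-line reimplementation of the stated selection rule."""
    e = field.energies.ravel()
    cand = [i for i in range(e.size) if e[i] < 0]
    er = {i: round(float(e[i]), 9) for i in cand}
    emin = min(er.values())
    inten = {i: round(er[i] / emin, 9) for i in cand}
    idx3 = {i: np.array(np.unravel_index(i, field.energies.shape), float)
            for i in cand}
    dbox = field.grid.diagonal
    first = min(cand, key=lambda i: (er[i], i))
    chosen = [first]
    while len(chosen) < min(n_nodes, len(cand)):
        best, best_score = None, -np.inf
        for i in cand:
            if i in chosen:
                continue
            d = min(np.linalg.norm(idx3[i] - idx3[j]) for j in chosen)
            score = w * inten[i] + (1 - w) * field.grid.spacing * d / dbox
            if score > best_score:
                best, best_score = i, score
        chosen.append(best)
    return chosen


class TestExtractNodes:
    def test_single_well(self):
        e = np.zeros((4, 4, 4))
        e[2, 1, 3] = -5.0
        nodes = extract_nodes(make_field(e), n_nodes=5, w=0.5)
        assert len(nodes) == 1
        np.testing.assert_array_equal(nodes[0].coords, [2.0, 1.0, 3.0])
        assert nodes[0].energy == -5.0

    def test_two_equal_wells_both_selected(self):
        e = np.zeros((11, 3, 3))
        e[0, 1, 1] = e[10, 1, 1] = -4.0
        for w in (0.0, 0.5, 1.0):
            nodes = extract_nodes(make_field(e), n_nodes=2, w=w)
            xs = sorted(n.coords[0] for n in nodes)
            assert xs == [0.0, 10.0]

    def test_no_favourable_points_empty(self):
        nodes = extract_nodes(make_field(np.ones((3, 3, 3))), n_nodes=5)
        assert nodes == []

    def test_invalid_weight(self):
        with pytest.raises(ValueError):
            extract_nodes(make_field(np.zeros((2, 2, 2))), n_nodes=1, w=1.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_greedy(self, seed):
        rng = np.random.default_rng(seed)
        e = np.zeros(27)
        picks = rng.choice(27, size=5, replace=False)
        e[picks] = -rng.uniform(0.5, 5.0, size=5)
        field = make_field(e.reshape(3, 3, 3))
        nodes = extract_nodes(field, n_nodes=3, w=0.5)
        expected = greedy_oracle(field, 3, 0.5)
        got = [int(np.ravel_multi_index(tuple(int(c) for c in n.coords),
                                        (3, 3, 3))) for n in nodes]
        assert got == expected


def brute_force_bins(nodes_a, nodes_b, auto, bw, maxd):
    nb = n_bins(bw, maxd)
    out = np.zeros(nb)
    for i, na in enumerate(nodes_a):
        for j, nbd in enumerate(nodes_b):
            if auto and j <= i:
                continue
            d = float(np.linalg.norm(na.coords - nbd.coords))
            k = int(np.floor(d / bw + 1e-9))
            if k < nb:
                out[k] = max(out[k], na.energy * nbd.energy)
    return out


class TestCorrelogram:
    def test_single_pair_product(self):
        ns = generate_toy_nodes({"DRY": [(0, 0, 0, -2.0), (5.0, 0, 0, -3.0)]})
        row = encode_correlogram(ns, bin_width=0.4, max_distance=25.0)
        nb = n_bins(0.4, 25.0)
        dd = row[:nb]
        assert dd[12] == pytest.approx(6.0)        # [4.8, 5.2)
        assert np.count_nonzero(dd) == 1
        assert np.count_nonzero(row[nb:]) == 0     # no other probes

    def test_probe_without_nodes_zero_blocks(self):
        ns = generate_toy_nodes({"DRY": [(0, 0, 0, -1.0), (3, 0, 0, -1.0)]})
        row = encode_correlogram(ns)
        nb = n_bins(0.4, 25.0)
        for b_idx, block in enumerate(BLOCKS):
            vals = row[b_idx * nb:(b_idx + 1) * nb]
            if block == "DRY-DRY":
                assert vals.sum() > 0
            else:
                assert np.all(vals == 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_cross_block_matches_bruteforce(self, seed, rng):
        r = np.random.default_rng(seed)
        dry = [Node(r.uniform(0, 12, 3), -r.uniform(0.5, 4), "DRY")
               for _ in range(4)]
        n1 = [Node(r.uniform(0, 12, 3), -r.uniform(0.5, 4), "N1")
              for _ in range(3)]
        ns = NodeSet("m", {"DRY": dry, "N1": n1})
        row = encode_correlogram(ns, 0.4, 25.0)
        nb = n_bins(0.4, 25.0)
        b = BLOCKS.index("DRY-N1")
        np.testing.assert_allclose(row[b * nb:(b + 1) * nb],
                                   brute_force_bins(dry, n1, False, 0.4, 25.0))
        b_auto = BLOCKS.index("DRY-DRY")
        np.testing.assert_allclose(row[b_auto * nb:(b_auto + 1) * nb],
                                   brute_force_bins(dry, dry, True, 0.4, 25.0))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rigid_motion_leaves_descriptors_unchanged(self, seed):
        r = np.random.default_rng(seed)
        nodes = {"DRY": [Node(r.uniform(0, 10, 3), -r.uniform(0.5, 3), "DRY")
                         for _ in range(4)],
                 "O": [Node(r.uniform(0, 10, 3), -r.uniform(0.5, 3), "O")
                       for _ in range(3)]}
        row = encode_correlogram(NodeSet("m", nodes))
        # random rotation (QR) + translation applied to every node
        q, _ = np.linalg.qr(r.normal(size=(3, 3)))
        t = r.uniform(-30, 30, 3)
        moved = {pid: [Node(q @ n.coords + t, n.energy, pid) for n in lst]
                 for pid, lst in nodes.items()}
        row2 = encode_correlogram(NodeSet("m", moved))
        np.testing.assert_allclose(row2, row, atol=1e-9)

    def test_values_are_products_of_node_energies(self):
        r = np.random.default_rng(3)
        dry = [Node(r.uniform(0, 8, 3), -r.uniform(0.5, 3), "DRY")
               for _ in range(5)]
        ns = NodeSet("m", {"DRY": dry})
        row = encode_correlogram(ns)
        energies = [n.energy for n in dry]
        products = {round(a * b, 10) for a in energies for b in energies}
        for v in row[row > 0]:
            assert round(float(v), 10) in products

    def test_monotone_coverage(self):
        r = np.random.default_rng(4)
        nodes = {"DRY": [Node(r.uniform(0, 20, 3), -r.uniform(0.5, 3), "DRY")
                         for _ in range(6)]}
        short = encode_correlogram(NodeSet("m", nodes), 0.4, 20.0)
        long = encode_correlogram(NodeSet("m", nodes), 0.4, 30.0)
        meta_s = all_variable_meta(0.4, 20.0)
        meta_l = {(m.block, round(m.bin_low, 6)): i
                  for i, m in enumerate(all_variable_meta(0.4, 30.0))}
        for i, m in enumerate(meta_s):
            assert long[meta_l[(m.block, round(m.bin_low, 6))]] == short[i]

    def test_bin_width_validation(self):
        ns = generate_toy_nodes({"DRY": [(0, 0, 0, -1.0), (1, 0, 0, -1.0)]})
        with pytest.raises(ValueError):
            encode_correlogram(ns, bin_width=0.0)


def test_nodes_export_as_pdb_pseudoatoms(tmp_path):
    from grindqsar.grind import write_nodes_pdb
    ns = generate_toy_nodes({"DRY": [(0, 0, 0, -2.0), (5, 0, 0, -3.0)],
                             "O": [(1, 1, 1, -1.5)]})
    path = tmp_path / "nodes.pdb"
    write_nodes_pdb(ns, path)
    lines = [l for l in path.read_text().splitlines() if l.startswith("HETATM")]
    assert len(lines) == 3
    assert lines[0].endswith("-2.00")  # energy in the B-factor column


class TestVariableIndexing:
    def test_first_variable(self):
        meta = variable_lookup(1, 0.4, 25.0)
        assert (meta.block, meta.bin_low, meta.bin_high) == ("DRY-DRY", 0.0, 0.4)

    def test_bijection_and_total_count(self):
        total = n_bins(0.4, 25.0) * len(BLOCKS)
        assert total == 620
        for k in range(1, total + 1):
            m = variable_lookup(k, 0.4, 25.0)
            assert meta_to_index(m.block, m.bin_low, 0.4, 25.0) == k

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            variable_lookup(0)
        with pytest.raises(IndexError):
            variable_lookup(621)

    def test_block_order_fixed(self):
        assert BLOCKS == ("DRY-DRY", "O-O", "N1-N1", "TIP-TIP", "DRY-O",
                          "DRY-N1", "DRY-TIP", "O-N1", "O-TIP", "N1-TIP")
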