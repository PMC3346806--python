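"""Scaffold-based disulfide mapping: criteria, anchors, maximum matching."""

import itertools

import numpy as np
import pytest

from ckscreen.disulfide import (
    CysPairAssessment,
    DisulfideParams,
    anchor_cysteines,
    check_pair,
    cysteine_positions,
    enumerate_bonds,
    map_disulfides,
)
from ckscreen.fixtures import FixtureSpec, make_toy_template
from ckscreen.foldlib import TemplateStructure


def _template_with_coords(ca_list, cb_list):
    n = len(ca_list)
    return TemplateStructure(
        pdb_id="geom",
        chain_id="A",
        sequence="C" * n,
        resolved=np.ones(n, dtype=bool),
        ca=np.asarray(ca_list, dtype=float),
        cb=np.asarray(cb_list, dtype=float),
        cb_virtual=np.zeros(n, dtype=bool),
    )


def _assess(i, j, ca_a, cb_a, ca_b, cb_b, **params):
    tpl = _template_with_coords([ca_a, ca_b], [cb_a, cb_b])
    return check_pair([(0, False)], [(1, False)], i, j, tpl,
                      DisulfideParams(**params))


class TestCheckPair:
    def test_hand_computed_pass(self):
        a = _assess(1, 10, (0, 0, 0), (1, 0, 0), (6, 0, 0), (5, 0, 0))
        assert (a.d_ca, a.d_cb) == (6.0, 4.0)
        assert a.possible

    def test_orientation_failure(self):
        # same CA separation but side chains pointing apart
        a = _assess(1, 10, (0, 0, 0), (-1, 0, 0), (6, 0, 0), (7, 0, 0))
        assert a.d_cb == 8.0
        assert not a.crit_orientation
        assert not a.possible

    def test_separation_failure(self):
        a = _assess(5, 7, (0, 0, 0), (1, 0, 0), (6, 0, 0), (5, 0, 0))
        assert a.crit_distance and a.crit_orientation
        assert not a.crit_separation and not a.possible

    def test_inclusive_boundaries(self):
        """All criterion bounds are inclusive: d_ca = 10.0 with d_cb = 9.0,
        a difference of exactly 1.0, and separation exactly 3 all pass."""
        # d_ca exactly 10.0 and d_cb exactly 9.0
        a = _assess(1, 4, (0, 0, 0), (0.5, 0, 0), (10.0, 0, 0), (9.5, 0, 0))
        assert a.d_ca == 10.0 and a.d_cb == 9.0
        assert a.possible
        # d_cb - d_ca exactly 1.0
        b = _assess(1, 4, (0, 0, 0), (-0.5, 0, 0), (5.0, 0, 0), (5.5, 0, 0))
        assert (b.d_cb - b.d_ca) == pytest.approx(1.0)
        assert b.possible
        # separation exactly 3
        c = _assess(1, 4, (0, 0, 0), (1, 0, 0), (6, 0, 0), (5, 0, 0))
        assert c.crit_separation and c.possible

    def test_symmetry(self):
        a = _assess(1, 10, (0, 0, 0), (1, 0, 0), (6, 0, 0), (5, 0, 0))
        tpl = _template_with_coords([(0, 0, 0), (6, 0, 0)],
                                    [(1, 0, 0), (5, 0, 0)])
        b = check_pair([(1, False)], [(0, False)], 10, 1, tpl,
                       DisulfideParams())
        assert (a.d_ca, a.d_cb, a.possible) == (b.d_ca, b.d_cb, b.possible)

    def test_missing_coordinates_error(self):
        tpl = _template_with_coords([(0, 0, 0), (6, 0, 0)],
                                    [(1, 0, 0), (5, 0, 0)])
        tpl.ca[1] = np.nan
        tpl.resolved[1] = True
        with pytest.raises(ValueError, match="position 2"):
            check_pair([(0, False)], [(1, False)], 1, 10, tpl,
                       DisulfideParams())

    def test_tightening_thresholds_monotone(self):
        """Tightening any threshold never turns an impossible pair possible."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            ca_a = rng.uniform(-5, 5, 3)
            ca_b = rng.uniform(-5, 5, 3)
            cb_a = ca_a + rng.normal(size=3)
            cb_b = ca_b + rng.normal(size=3)
            loose = _assess(1, 8, ca_a, cb_a, ca_b, cb_b)
            tight = _assess(1, 8, ca_a, cb_a, ca_b, cb_b,
                            d_ca_max=8.0, d_cb_max=7.0, d_diff_max=0.5,
                            min_sep=5)
            if tight.possible:
                assert loose.possible


class TestAnchors:
    def test_direct_anchor(self, ck_template, potentials):
        from ckscreen.threading_engine import align_sequence_to_structure

        aln = align_sequence_to_structure(ck_template.sequence, ck_template,
                                          potentials)
        anchors = anchor_cysteines(aln, ck_template, ck_template.sequence)
        for cys, anchor_list in anchors.items():
            assert anchor_list == [(cys - 1, False)]

    def test_insertion_yields_flagged_neighbors(self, ck_template):
        # manual alignment: query position 5 (a cysteine) is unaligned,
        # between template positions 20 and 21
        pairs = [(3, 19), (4, 20), (6, 21), (7, 22)]
        query = "AAAA" + "AC" + "A" * 10
        query = query[:5] + "C" + query[6:]

        class FakeAln:
            pass

        aln = FakeAln()
        aln.pairs = pairs
        anchors = anchor_cysteines(aln, ck_template, query)
        assert anchors[6] == [(20, True), (21, True)]

    def test_terminal_cysteine_single_sided(self, ck_template):
        class FakeAln:
            pairs = [(5, 10), (6, 11)]

        query = "C" + "A" * 10
        anchors = anchor_cysteines(FakeAln, ck_template, query)
        assert anchors[1] == [(10, True)]

    def test_unanchorable_warns_and_excludes(self, ck_template):
        class FakeAln:
            pairs = []

        with pytest.warns(UserWarning):
            anchors = anchor_cysteines(FakeAln, ck_template, "CAAAA")
        assert anchors == {}


def _brute_force_matching(vertices, edges):
    """Oracle: exhaustively enumerate all matchings."""
    best = 0
    for r in range(len(edges), 0, -1):
        for combo in itertools.combinations(sorted(edges), r):
            used = set()
            ok = True
            for (a, b) in combo:
                if a in used or b in used:
                    ok = False
                    break
                used.update((a, b))
            if ok:
                best = max(best, r)
        if best == r:
            break
    return best


class TestEnumerateBonds:
    def _assessments(self, edges, n_cys):
        out = []
        for i in range(1, n_cys + 1):
            for j in range(i + 1, n_cys + 1):
                possible = (i, j) in edges
                out.append(
                    CysPairAssessment(
                        i=i, j=j, anchors_i=((i - 1, False),),
                        anchors_j=((j - 1, False),),
                        d_ca=5.0, d_cb=4.0,
                        crit_distance=possible, crit_orientation=possible,
                        crit_separation=possible, possible=possible,
                    )
                )
        return out

    @pytest.mark.parametrize(
        "edges,expected",
        [
            ({(1, 4), (2, 5), (3, 6)}, 3),  # disjoint triple
            ({(1, 4), (1, 5)}, 1),          # shared vertex
            ({(1, 4), (4, 6), (2, 5)}, 2),  # chain + disjoint
        ],
    )
    def test_known_matchings(self, edges, expected):
        dmap = enumerate_bonds(self._assessments(edges, 6))
        assert dmap.bond_count == expected
        used = [v for pair in dmap.chosen_pairing for v in pair]
        assert len(used) == len(set(used))

    def test_guard_on_cysteine_count(self):
        with pytest.raises(ValueError, match="raise max_cys"):
            enumerate_bonds(self._assessments({(1, 4)}, 25))

    def test_matches_networkx_and_brute_force(self):
        """Oracle equivalence on random graphs (exhaustive + networkx)."""
        networkx = pytest.importorskip("networkx")
        rng = np.random.default_rng(7)
        for _ in range(40):
            n_cys = int(rng.integers(2, 9))
            all_pairs = [(i, j) for i in range(1, n_cys + 1)
                         for j in range(i + 1, n_cys + 1)]
            edges = {p for p in all_pairs if rng.random() < 0.4}
            dmap = enumerate_bonds(self._assessments(edges, n_cys))
            g = networkx.Graph(list(edges))
            nx_size = len(networkx.max_weight_matching(g,
                                                       maxcardinality=True))
            assert dmap.bond_count == nx_size == _brute_force_matching(
                range(1, n_cys + 1), edges
            )


class TestMapDisulfides:
    def _identity_alignment(self, template):
        class Aln:
            pairs = [(k, k) for k in range(template.n_residues)]

        return Aln

    def test_no_cysteines_zero_bonds(self, ck_template, potentials):
        from ckscreen.threading_engine import align_sequence_to_structure

        query = ck_template.sequence.replace("C", "S")
        aln = align_sequence_to_structure(query, ck_template, potentials)
        assert map_disulfides(query, ck_template, aln).bond_count == 0

    def test_planted_pairs_recovered(self, ck_template):
        aln = self._identity_alignment(ck_template)
        dmap = map_disulfides(ck_template.sequence, ck_template, aln)
        assert dmap.bond_count == 3
        planted = {(2, 60), (4, 28), (16, 40)}
        possible = {(a.i, a.j) for a in dmap.assessments if a.possible}
        assert planted <= possible
        # the chosen pairing is a maximum matching over the possible pairs
        used = [v for pair in dmap.chosen_pairing for v in pair]
        assert len(dmap.chosen_pairing) == 3 and len(used) == len(set(used))

    def test_orientation_fail_fixture_zero_bonds(self):
        spec = FixtureSpec(
            seed=3,
            sse_layout=[("C", 10), ("E", 6), ("C", 10)],
            planted_disulfides=[(2, 22, "fail_orientation")],
            name="ofail",
        )
        tpl = make_toy_template(spec)
        aln = self._identity_alignment(tpl)
        assert map_disulfides(tpl.sequence, tpl, aln).bond_count == 0

    def test_bond_count_bounded(self, ck_template):
        aln = self._identity_alignment(ck_template)
        dmap = map_disulfides(ck_template.sequence, ck_template, aln)
        n_cys = len(cysteine_positions(ck_template.sequence))
        assert dmap.bond_count <= n_cys // 2
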