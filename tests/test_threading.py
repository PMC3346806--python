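"""Potentials, sequence-to-structure alignment, z-scores and ranking."""

import numpy as np
import pytest

from ckscreen.fixtures import make_homolog
from ckscreen.threading_engine import (
    Potentials,
    align_sequence_to_structure,
    calibrate_cutoff,
    compute_thx,
    derive_potentials,
    percent_identity,
    rank_templates,
    seed_for,
    zscores,
)


class TestDerivePotentials:
    def test_symmetry(self, potentials):
        e = potentials.pair.energy
        assert np.allclose(e, np.swapaxes(e, 0, 1))

    def test_finite(self, potentials):
        assert np.all(np.isfinite(potentials.pair.energy))
        assert np.all(np.isfinite(potentials.burial.energy))

    def test_unseen_pair_has_positive_energy(self, potentials):
        """A (type, type, bin) combination never observed in training gets the
        pseudocount-bound positive energy."""
        counts_zero_mask = potentials.pair.energy >= np.log(
            1.0
        )  # E > 0 for unseen combinations wherever the bin has observations
        assert counts_zero_mask.any()

    def test_uniform_contacts_give_zero_energy(self):
        """With counts uniform over all pair types the log-odds vanish."""
        pc = 1.0
        k = 400.0
        counts = np.full((20, 20, 15), 7.0)
        n_ref = counts.sum(axis=(0, 1))
        energy = -np.log(k * (counts + pc) / (n_ref + pc * k))
        assert np.allclose(energy, 0.0)

    def test_no_training_templates_errors(self):
        with pytest.raises(ValueError):
            derive_potentials([])

    def test_json_roundtrip(self, potentials):
        from ckscreen.threading_engine import BurialPotential, PairPotential

        pp = PairPotential.from_json_dict(potentials.pair.to_json_dict())
        bp = BurialPotential.from_json_dict(potentials.burial.to_json_dict())
        assert np.allclose(pp.energy, potentials.pair.energy)
        assert np.allclose(bp.energy, potentials.burial.energy)


class TestAlignment:
    def test_self_alignment_identity(self, ck_template, potentials):
        aln = align_sequence_to_structure(
            ck_template.sequence, ck_template, potentials
        )
        assert aln.pl == ck_template.fl
        assert aln.percent_id == 100.0
        assert percent_identity(aln, ck_template.sequence, ck_template) == 100.0

    def test_pl_bounded_by_query_and_fold_length(self, ck_template, potentials):
        short = ck_template.sequence[: ck_template.fl // 2]
        aln = align_sequence_to_structure(short, ck_template, potentials)
        assert aln.pl <= min(len(short), ck_template.fl)
        assert aln.fl / aln.pl > 1.3  # short queries cannot cover the fold

    def test_reversed_query_scores_worse(self, ck_template, potentials):
        native = align_sequence_to_structure(
            ck_template.sequence, ck_template, potentials
        )
        rev = align_sequence_to_structure(
            ck_template.sequence[::-1], ck_template, potentials
        )
        assert rev.score < native.score

    def test_empty_and_short_query_error(self, ck_template, potentials):
        with pytest.raises(ValueError):
            align_sequence_to_structure("", ck_template, potentials)
        with pytest.raises(ValueError):
            align_sequence_to_structure("ACDEF", ck_template, potentials)

    def test_pairs_strictly_increasing(self, ck_template, potentials):
        seq = make_homolog(ck_template, 50.0, seed=3)
        aln = align_sequence_to_structure(seq, ck_template, potentials)
        qs = [q for q, _ in aln.pairs]
        ts = [t for _, t in aln.pairs]
        assert qs == sorted(qs) and len(set(qs)) == len(qs)
        assert ts == sorted(ts) and len(set(ts)) == len(ts)


class TestZScores:
    def test_native_sequence_positive_z_pair(self, ck_template, potentials):
        z_pair, _, _ = zscores(
            ck_template.sequence, ck_template, potentials, n_shuffles=40, seed=5
        )
        assert z_pair > 0

    def test_deterministic_under_seed(self, ck_template, potentials):
        a = zscores(ck_template.sequence, ck_template, potentials,
                    n_shuffles=20, seed=9)[:2]
        b = zscores(ck_template.sequence, ck_template, potentials,
                    n_shuffles=20, seed=9)[:2]
        assert a == b

    def test_degenerate_potential_flags_zero(self, ck_template, potentials):
        flat = Potentials(
            pair=type(potentials.pair)(
                energy=np.zeros_like(potentials.pair.energy),
                bin_edges=potentials.pair.bin_edges,
                min_separation=potentials.pair.min_separation,
                pseudocount=1.0,
            ),
            burial=type(potentials.burial)(
                energy=np.zeros_like(potentials.burial.energy)
            ),
        )
        z_pair, z_surf, aln = zscores(
            ck_template.sequence, ck_template, flat, n_shuffles=10, seed=1
        )
        assert z_pair == 0.0 and z_surf == 0.0
        assert aln.degenerate


class TestThx:
    def test_zero_inputs_zero_thx(self, ck_template, potentials):
        aln = align_sequence_to_structure(
            ck_template.sequence, ck_template, potentials
        )
        aln.z_pair = aln.z_surf = 0.0
        aln.seq_similarity = 0.0
        assert compute_thx(aln, 70) == 0.0

    def test_linearity_in_weights(self, ck_template, potentials):
        aln = align_sequence_to_structure(
            ck_template.sequence, ck_template, potentials
        )
        aln.z_pair, aln.z_surf = 2.0, 1.0
        t1 = compute_thx(aln, 70)
        t2 = compute_thx(aln, 70, w_pair=2, w_surf=2, w_seq=2)
        assert t2 == pytest.approx(2 * t1)

    def test_zero_length_errors(self, ck_template, potentials):
        aln = align_sequence_to_structure(
            ck_template.sequence, ck_template, potentials
        )
        aln.z_pair = aln.z_surf = 0.0
        with pytest.raises(ValueError):
            compute_thx(aln, 0)

    def test_calibration_returns_hc_hit_thx(self, foldspace, potentials):
        """Threading a designated remote homolog re-derives the family
        cutoff (the analogue of anchoring the cutoff at the most remote
        confirmed member)."""
        library, _ = foldspace
        ck = library.get("ckfx_A")
        calibrant = make_homolog(ck, 30.0, seed=21)
        cutoff = calibrate_cutoff(calibrant, library, potentials,
                                  seed=3, n_shuffles=30)
        assert np.isfinite(cutoff)
        hits = rank_templates(calibrant, library, potentials,
                              seed=3, n_shuffles=30)
        assert cutoff in {h.alignment.thx for h in hits}


class TestRanking:
    def test_self_recognition_all_templates(self, foldspace, potentials):
        """Every toy-library template's native sequence ranks itself #1."""
        library, _ = foldspace
        for tpl in library:
            hits = rank_templates(tpl.sequence, library, potentials,
                                  seed=13, n_shuffles=30)
            assert hits[0].template.name == tpl.name

    def test_rank_invariant_to_library_order(self, foldspace, potentials):
        from ckscreen.foldlib import FoldLibrary

        library, _ = foldspace
        rev = FoldLibrary(name="rev", kind="fold_space",
                          templates=list(library)[::-1])
        ck = library.get("ckfx_A")
        a = rank_templates(ck.sequence, library, potentials, seed=4,
                           n_shuffles=20)
        b = rank_templates(ck.sequence, rev, potentials, seed=4, n_shuffles=20)
        assert [h.template.name for h in a] == [h.template.name for h in b]
        assert [h.alignment.thx for h in a] == pytest.approx(
            [h.alignment.thx for h in b]
        )

    def test_single_template_rank_one(self, ck_template, potentials):
        from ckscreen.foldlib import FoldLibrary

        lib = FoldLibrary(name="one", kind="chemokine",
                          templates=[ck_template])
        hits = rank_templates(ck_template.sequence, lib, potentials,
                              seed=0, n_shuffles=10)
        assert hits[0].rank == 1 and len(hits) == 1

    def test_duplicate_templates_tie_break_by_id(self, ck_template, potentials):
        import copy

        from ckscreen.foldlib import FoldLibrary

        dup = copy.deepcopy(ck_template)
        dup.pdb_id = "zzzz"
        lib = FoldLibrary(name="two", kind="chemokine",
                          templates=[dup, ck_template])
        # a flat potential forces an exact score tie (z = 0, equal S_seq):
        # the ranking must then be id-lexicographic
        flat = Potentials(
            pair=type(potentials.pair)(
                energy=np.zeros_like(potentials.pair.energy),
                bin_edges=potentials.pair.bin_edges,
                min_separation=potentials.pair.min_separation,
                pseudocount=1.0,
            ),
            burial=type(potentials.burial)(
                energy=np.zeros_like(potentials.burial.energy)
            ),
        )
        hits = rank_templates(ck_template.sequence, lib, flat,
                              seed=0, n_shuffles=5)
        assert [h.template.name for h in hits] == ["ckfx_A", "zzzz_A"]


class TestPercentIdentity:
    def test_toy_counts(self, ck_template, potentials):
        aln = align_sequence_to_structure(
            ck_template.sequence, ck_template, potentials
        )
        aln.pairs = aln.pairs[:10]
        aln.pl = 10
        query = list(ck_template.sequence)
        # force exactly 3 matches among the 10 pairs
        for k, (qp, tp) in enumerate(aln.pairs):
            if k >= 3:
                query[qp] = "W" if ck_template.sequence[tp] != "W" else "Y"
        assert percent_identity(aln, "".join(query), ck_template) == 30.0

    def test_empty_alignment_errors(self, ck_template, potentials):
        aln = align_sequence_to_structure(
            ck_template.sequence, ck_template, potentials
        )
        aln.pairs, aln.pl = [], 0
        with pytest.raises(ValueError):
            percent_identity(aln, ck_template.sequence, ck_template)


def test_seed_for_stable_and_bounded():
    assert seed_for(1, "a") == seed_for(1, "a")
    assert seed_for(1, "a") != seed_for(2, "a")
    assert 0 <= seed_for(123456789, "x", "y") < 2 ** 31
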