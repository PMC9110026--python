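"""Per-base importance, site calling, PWM scanning, guarded scrambling."""

import itertools

import numpy as np
import pytest

from enhancerselect import gkm, interpret
from enhancerselect.interpret import ImportanceTrack, MotifSiteCall
from enhancerselect.seqs import random_dna, revcomp
from enhancerselect.simulate import MotifModel


def make_track(normalized, sequence=None):
    L = len(normalized)
    seq = sequence or "A" * L
    return ImportanceTrack("t", "m", seq, np.asarray(normalized, float),
                           np.zeros((4, L)), np.asarray(normalized, float))


class TestLinearImportance:
    def test_additivity_identity(self, small_model):
        model, _, val = small_model
        for seq in val[0][:20]:
            track = interpret.per_base_importance(model, seq,
                                                  with_hypothetical=False)
            score = gkm.score(model, [seq])[0]
            assert track.actual.sum() == pytest.approx(
                score - model.intercept, abs=1e-6)

    def test_self_substitution_identity(self, small_model):
        model, _, val = small_model
        seq = val[0][0]
        track = interpret.per_base_importance(model, seq)
        ref = ["ACGT".index(c) for c in seq]
        assert np.allclose(track.hypothetical[ref, np.arange(len(seq))],
                           track.actual)

    def test_hypothetical_equals_full_recomputation(self, small_model):
        """The incremental substitution path is exact (dual-route check)."""
        model, _, val = small_model
        seq = val[0][1]
        track = interpret.per_base_importance(model, seq)
        rng = np.random.default_rng(0)
        for _ in range(8):
            i = int(rng.integers(0, len(seq)))
            b = int(rng.integers(0, 4))
            mutant = seq[:i] + "ACGT"[b] + seq[i + 1:]
            full = interpret.per_base_importance(model, mutant,
                                                 with_hypothetical=False)
            assert track.hypothetical[b, i] == pytest.approx(
                full.actual[i], abs=1e-6)

    def test_ism_path_for_nonlinear_models(self):
        def fake_scorer(seqs):
            # score = count of 'A' in the first 5 bases
            return np.array([s[:5].count("A") for s in seqs], float)

        seq = "ACGTACGTACGT"
        track = interpret.per_base_importance(fake_scorer, seq)
        # position 0 (an A): alternatives all score one less
        assert track.actual[0] == pytest.approx(1.0)
        # positions beyond 5 have no influence
        assert np.allclose(track.actual[5:], 0.0)


class TestNormalizeImportance:
    def test_equal_hypotheticals_zero_out(self):
        track = ImportanceTrack("t", "m", "ACGT", np.full(4, 2.0),
                                np.full((4, 4), 2.0))
        assert np.allclose(interpret.normalize_importance(track).normalized,
                           0.0)

    def test_stated_arithmetic(self):
        hyp = np.zeros((4, 1))
        hyp[0, 0] = 2.0
        track = ImportanceTrack("t", "m", "A", np.array([2.0]), hyp)
        assert interpret.normalize_importance(track).normalized[0] == \
            pytest.approx(1.5)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(1)
        hyp = rng.normal(size=(4, 10))
        actual = hyp[0]
        t1 = interpret.normalize_importance(
            ImportanceTrack("t", "m", "A" * 10, actual, hyp))
        t2 = interpret.normalize_importance(
            ImportanceTrack("t", "m", "A" * 10, actual + 3.0, hyp + 3.0))
        assert np.allclose(t1.normalized, t2.normalized)


class TestCallSites:
    def test_single_contiguous_block(self):
        values = np.zeros(200)
        values[50:57] = 5.0
        sites = interpret.call_sites(make_track(values))
        assert sites[0].start == 50 and sites[0].end == 57

    def test_two_blocks_ranked_by_mass(self):
        values = np.zeros(200)
        values[30:36] = 10.0   # mass 60
        values[100:106] = 1.0  # mass 6
        sites = interpret.call_sites(make_track(values))
        assert (sites[0].start, sites[0].rank) == (30, 1)
        assert (sites[1].start, sites[1].rank) == (100, 2)

    def test_long_block_trimmed_to_best_window(self):
        rng = np.random.default_rng(2)
        values = np.zeros(240)
        block = 1.0 + rng.random(12)
        values[60:72] = block
        sites = interpret.call_sites(make_track(values), top_n=1)
        s, e = sites[0].start, sites[0].end
        assert e - s == 8
        # sliding-window oracle over the block
        sums = [block[i:i + 8].sum() for i in range(5)]
        assert s - 60 == int(np.argmax(sums))

    def test_site_lengths_constrained(self):
        values = np.zeros(300)
        values[10:12] = 9.0     # 2-base peak must be extended to >= 6
        sites = interpret.call_sites(make_track(values), top_n=1)
        assert 6 <= sites[0].end - sites[0].start <= 8

    def test_short_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            interpret.call_sites(make_track(np.ones(4)))

    def test_requires_normalized(self):
        track = ImportanceTrack("t", "m", "A" * 20, np.zeros(20),
                                np.zeros((4, 20)))
        with pytest.raises(ValueError):
            interpret.call_sites(track)


class TestScanPwm:
    def test_tata_log_odds_by_hand(self):
        probs = np.zeros((4, 4))
        for j, base in enumerate("TATA"):
            probs["ACGT".index(base), j] = 1.0
        motif = MotifModel("tata", probs)
        hits = interpret.scan_pwm("GGTATAGG", motif, p_threshold=1.1,
                                  pseudocount=0.0)
        best = [h for h in hits if h.strand == "+" and h.start == 2][0]
        assert best.log_odds == pytest.approx(8.0)  # 4 * log2(1/0.25)

    @pytest.mark.parametrize("width", [4, 5, 6])
    def test_p_values_match_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        probs = rng.dirichlet(np.ones(4) * 2, size=width).T
        motif = MotifModel("m", probs)
        from enhancerselect.interpret import (_SCORE_SCALE, _int_log_odds,
                                              _null_survival)
        int_lo = _int_log_odds(motif, 1e-3)
        sf, base = _null_survival(int_lo, motif.background)
        # enumerate all 4^w windows under the uniform background
        scores = {}
        for word in itertools.product(range(4), repeat=width):
            s = sum(int(int_lo[b, j]) for j, b in enumerate(word))
            scores[s] = scores.get(s, 0) + 0.25 ** width
        for s in sorted(scores):
            expected = sum(v for t, v in scores.items() if t >= s)
            idx = s - base
            assert sf[idx] == pytest.approx(expected, abs=1e-12)

    def test_minus_strand_matches_revcomp_scan(self):
        rng = np.random.default_rng(3)
        motif = MotifModel.from_consensus("m", "TGACCG", 0.95)
        seq = random_dna(rng, 100)
        plus_of_rc = [(h.start, h.log_odds) for h in
                      interpret.scan_pwm(revcomp(seq), motif, 1e-2)
                      if h.strand == "+"]
        minus = [(len(seq) - h.end, h.log_odds) for h in
                 interpret.scan_pwm(seq, motif, 1e-2) if h.strand == "-"]
        assert sorted(plus_of_rc) == sorted(minus)

    def test_planted_consensus_is_detected(self):
        rng = np.random.default_rng(4)
        motif = MotifModel.from_consensus("m", "TGACCTTG", 0.97)
        seq = random_dna(rng, 200)
        seq = seq[:96] + motif.consensus + seq[104:]
        hits = interpret.scan_pwm(seq, motif)
        assert any(h.start == 96 and h.strand == "+" for h in hits)
        assert all(h.p < 1e-4 for h in hits)

    def test_zero_background_rejected(self):
        motif = MotifModel.from_consensus("m", "TGACCT", 0.9)
        motif.background = np.array([0.0, 0.5, 0.25, 0.25])
        with pytest.raises(Exception):
            interpret.scan_pwm("ACGTACGTAC", motif)


class TestScramble:
    SITE = MotifSiteCall(start=10, end=18, rank=1, importance_mass=1.0)

    def test_composition_preserved_and_flanks_untouched(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 40)
        mutant = interpret.scramble_site(seq, self.SITE, [], seed=1)
        assert mutant[:10] == seq[:10] and mutant[18:] == seq[18:]
        assert sorted(mutant[10:18]) == sorted(seq[10:18])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        seq = random_dna(rng, 40)
        assert interpret.scramble_site(seq, self.SITE, [], seed=7) == \
            interpret.scramble_site(seq, self.SITE, [], seed=7)

    def test_guard_blocks_reintroduced_motifs(self):
        # a site of all-identical bases can only scramble to itself; with a
        # guard matching that homopolymer nothing NEW can appear, so the
        # scramble succeeds trivially — whereas an impossible guard demand
        # (every permutation creates a new hit) must raise
        motif = MotifModel.from_consensus("m", "ACGTACGT", 0.97)
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 50)
        site_seq = "ACGTACGT"
        seq = seq[:10] + site_seq + seq[18:]
        mutant = interpret.scramble_site(seq, self.SITE, [motif], seed=3)
        hits = interpret.scan_pwm(mutant[2:26], motif)
        # the original hit may be destroyed but no new strong site appears
        baseline = interpret.scan_pwm(seq[2:26], motif)
        assert len(hits) <= len(baseline)

    def test_site_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            interpret.scramble_site("ACGT", self.SITE, [], seed=1)


class TestScoreMutants:
    def test_identical_mutant_has_zero_delta(self, small_model):
        model, _, val = small_model
        seq = val[0][0]
        table = interpret.score_mutants({"m1": model}, seq, {"same": seq})
        assert table.loc["m1", "delta_same"] == pytest.approx(0.0)
        assert table.loc["mean", "delta_same"] == pytest.approx(0.0)

    def test_cross_model_mean_row(self, small_model):
        model, _, val = small_model
        seq, other = val[0][0], val[0][1]
        table = interpret.score_mutants({"a": model, "b": model}, seq,
                                        {"mut": other})
        assert table.loc["mean", "wildtype"] == pytest.approx(
            table.loc[["a", "b"], "wildtype"].mean())


class TestMemeIO:
    def test_round_trip(self, tmp_path):
        motifs = [MotifModel.from_consensus("alpha", "TGACCTTG", 0.97),
                  MotifModel.from_consensus("beta", "CTATTTAT", 0.9)]
        path = tmp_path / "motifs.meme"
        interpret.write_meme_motifs(motifs, path)
        back = interpret.read_meme_motifs(path)
        assert [m.motif_id for m in back] == ["alpha", "beta"]
        for a, b in zip(motifs, back):
            assert np.allclose(a.probs, b.probs, atol=1e-4)

    def test_importance_tsv(self, tmp_path, small_model):
        import pandas as pd

        model, _, val = small_model
        track = interpret.normalize_importance(
            interpret.per_base_importance(model, val[0][0][:40]))
        path = tmp_path / "track.tsv"
        interpret.write_importance_tsv(track, path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["position", "base", "actual", "hyp_A",
                                    "hyp_C", "hyp_G", "hyp_T", "normalized"]
        assert len(df) == 40
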