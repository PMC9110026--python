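"""Gapped k-mer featurization, kernels, SVM training and scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from enhancerselect import gkm, metrics
from enhancerselect.seqs import SequenceError, random_dna, revcomp

DNA = st.text(alphabet="ACGT", min_size=12, max_size=60)


def dense_oracle(seq, l, k, rc_collapse=False, weights=None):
    """Brute-force gapped k-mer feature map, independent of the fast path."""
    out = {}
    for s in range(len(seq) - l + 1):
        lmer = seq[s:s + l]
        w = 1.0 if weights is None else weights[s]
        for combo in itertools.combinations(range(l), k):
            pattern = "".join(lmer[i] if i in combo else "."
                              for i in range(l))
            if rc_collapse:
                rc = revcomp(pattern.replace(".", "N")) \
                    .replace("N", ".")
                pattern = min(pattern, rc, key=_pattern_key)
            out[pattern] = out.get(pattern, 0.0) + w
    return out


def _pattern_key(pattern):
    # ordering consistent with the column encoding: informative-position
    # choice first (lexicographic), then bases
    combo = tuple(i for i, c in enumerate(pattern) if c != ".")
    bases = "".join(c for c in pattern if c != ".")
    return (combo, bases)


class TestEnumeration:
    def test_total_instance_count_formula(self):
        counts = gkm.enumerate_gapped_kmers("ACGTA", 3, 2)
        assert sum(counts.values()) == 3 * 3   # (5-3+1) * C(3,2)

    def test_exhaustive_tiny_case(self):
        assert gkm.enumerate_gapped_kmers("ACG", 3, 2) == \
            {"AC.": 1, "A.G": 1, ".CG": 1}

    def test_l_equals_k_gives_contiguous_lmers(self):
        counts = gkm.enumerate_gapped_kmers("ACGTACGT", 4, 4)
        assert set(counts) == {"ACGT", "CGTA", "GTAC", "TACG"}

    def test_errors(self):
        with pytest.raises(SequenceError):
            gkm.enumerate_gapped_kmers("AC", 3, 2)
        with pytest.raises(SequenceError):
            gkm.enumerate_gapped_kmers("ACGNACG", 3, 2)


class TestFeaturize:
    @pytest.mark.parametrize("l,k", [(3, 2), (4, 2), (4, 3), (5, 3)])
    def test_matches_dense_enumeration_oracle(self, l, k):
        rng = np.random.default_rng(0)
        config = gkm.GkmConfig(l=l, k=k, kernel="gkm", rc_collapse=False)
        for _ in range(10):
            seq = random_dna(rng, 80)
            assert gkm.featurize(seq, config) == \
                pytest.approx(dense_oracle(seq, l, k))

    def test_plain_gkm_tiny_example(self):
        config = gkm.GkmConfig(l=3, k=2, kernel="gkm", rc_collapse=False)
        features = gkm.featurize("ACGTA", config)
        assert features["A.G"] == 1.0

    def test_center_weighting_matches_oracle(self):
        config = gkm.GkmConfig(l=4, k=3, kernel="wgkm", H=10.0,
                               rc_collapse=False)
        seq = "ACGTACGTACGTACGT"
        fz = gkm.GkmFeaturizer(config)
        weights = fz.window_weights(len(seq))
        assert gkm.featurize(seq, config) == \
            pytest.approx(dense_oracle(seq, 4, 3, weights=weights))
        assert weights.max() == pytest.approx(1.0)  # w(0) normalization

    @given(DNA)
    def test_rc_collapse_strand_symmetry(self, seq):
        config = gkm.GkmConfig(l=6, k=4, kernel="wgkm", rc_collapse=True)
        f1 = gkm.featurize(seq, config)
        f2 = gkm.featurize(revcomp(seq), config)
        assert f1 == pytest.approx(f2)

    def test_infinite_half_life_recovers_plain_gkm(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 100)
        wide = gkm.GkmConfig(l=6, k=4, kernel="wgkm", H=1e12)
        plain = gkm.GkmConfig(l=6, k=4, kernel="gkm")
        assert gkm.featurize(seq, wide) == pytest.approx(
            gkm.featurize(seq, plain))


class TestKernel:
    def test_self_similarity_is_one(self):
        config = gkm.GkmConfig(l=4, k=3, kernel="gkm")
        x = gkm.featurize("ACGTACGTAC", config)
        assert gkm.kernel(x, x, config) == pytest.approx(1.0)

    def test_disjoint_patterns_give_zero_and_rbf_floor(self):
        config = gkm.GkmConfig(l=4, k=4, kernel="gkm", rc_collapse=False)
        x = gkm.featurize("AAAAAA", config)
        y = gkm.featurize("CCCCCC", config)
        assert gkm.kernel(x, y, config) == 0.0
        rbf = gkm.GkmConfig(l=4, k=4, kernel="gkm_rbf", gamma=2.0,
                            rc_collapse=False)
        assert gkm.kernel(x, y, rbf) == pytest.approx(np.exp(-2.0))

    def test_hand_pair_matches_dense_dot_product(self):
        config = gkm.GkmConfig(l=4, k=3, kernel="gkm", rc_collapse=False)
        a, b = "ACGTACGT", "ACGTACGA"
        fa, fb = dense_oracle(a, 4, 3), dense_oracle(b, 4, 3)
        dot = sum(v * fb.get(key, 0.0) for key, v in fa.items())
        na = np.sqrt(sum(v * v for v in fa.values()))
        nb = np.sqrt(sum(v * v for v in fb.values()))
        expected = dot / (na * nb)
        x = gkm.featurize(a, config)
        y = gkm.featurize(b, config)
        assert gkm.kernel(x, y, config) == pytest.approx(expected)

    def test_gram_symmetric_psd_and_bounded(self):
        rng = np.random.default_rng(2)
        seqs = [random_dna(rng, 60) for _ in range(30)]
        config = gkm.GkmConfig(l=6, k=4)
        K = gkm.gram_matrix(seqs, config)
        assert np.allclose(K, K.T)
        assert (K >= -1e-12).all() and (K <= 1 + 1e-9).all()
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_gamma_zero_makes_rbf_constant(self):
        rng = np.random.default_rng(3)
        seqs = [random_dna(rng, 40) for _ in range(5)]
        config = gkm.GkmConfig(l=5, k=3, kernel="gkm_rbf", gamma=1e-12)
        assert np.allclose(gkm.gram_matrix(seqs, config), 1.0)

    def test_zero_norm_is_an_error(self):
        config = gkm.GkmConfig(l=4, k=3)
        with pytest.raises(ValueError):
            gkm.kernel({}, {}, config)


class TestTraining:
    def test_selected_model_learns_planted_motif(self, small_model):
        model, train, val = small_model
        scores = gkm.score(model, val[0])
        assert metrics.auroc(scores, val[1]) >= 0.9
        assert np.nanmean(gkm.score(model, train[0])[:60]) > 0

    def test_top_features_overlap_planted_consensus(self, small_model):
        model, _, _ = small_model
        consensus = "TGACCTTG"
        targets = (consensus, revcomp(consensus))
        hits = 0
        for pattern, _ in model.top_features(10):
            informative = pattern.replace(".", "")
            if any(informative in t for t in targets) or any(
                    _gapped_matches(pattern, t) for t in targets):
                hits += 1
        assert hits >= 1

    def test_grid_tie_breaks_prefer_simpler_model(self, small_model):
        model, train, val = small_model
        # duplicated grid point: the first occurrence wins, and equal-F1
        # ties resolve to the smaller l
        grid = [gkm.GkmConfig(l=6, k=4), gkm.GkmConfig(l=7, k=4)]
        m = gkm.train(train, val, grid)
        f1s = m.training_manifest["val_f1"]
        if f1s[0] == f1s[1]:
            assert m.config.l == 6

    def test_class_weight_raises_recall(self):
        rng = np.random.default_rng(9)
        motif = "TGACCTTG"

        def make(pos):
            s = random_dna(rng, 100)
            if pos:
                i = int(rng.integers(20, 70))
                s = s[:i] + motif + s[i + 8:]
            return s

        train = ([make(i < 25) for i in range(150)],
                 np.r_[np.ones(25), np.zeros(125)].astype(int))
        val = ([make(i < 15) for i in range(60)],
               np.r_[np.ones(15), np.zeros(45)].astype(int))
        recalls = {}
        for w in (1.0, 3.0):
            m = gkm.train(train, val, [gkm.GkmConfig(l=6, k=4, w=w)])
            s = gkm.score(m, val[0])
            recalls[w] = ((s > 0) & (val[1] == 1)).sum() / 15
        assert recalls[3.0] >= recalls[1.0]

    def test_error_conditions(self, small_model):
        _, train, val = small_model
        with pytest.raises(ValueError):
            gkm.train(train, val, [])
        one_class = (train[0][:10], np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            gkm.train(one_class, val, [gkm.GkmConfig(l=6, k=4)])


class TestScoring:
    def test_nan_for_unscorable_sequences(self, small_model):
        model, _, val = small_model
        out = gkm.score(model, [val[0][0], "ACGTNACGT" * 10, val[0][1]])
        assert np.isnan(out[1])
        assert not np.isnan(out[[0, 2]]).any()

    def test_reverse_complement_scores_identically(self, small_model):
        model, _, val = small_model
        seqs = val[0][:10]
        assert np.allclose(gkm.score(model, seqs),
                           gkm.score(model, [revcomp(s) for s in seqs]),
                           atol=1e-9)

    def test_dual_and_primal_scoring_agree(self):
        """Kernel-expansion evaluation equals collapsed primal weights."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(4)
        seqs = [random_dna(rng, 60) for _ in range(40)]
        y = np.array([1] * 20 + [0] * 20)
        config = gkm.GkmConfig(l=6, k=4, kernel="wgkm")
        fz = gkm.GkmFeaturizer(config)
        X = fz.transform(seqs, l2_normalize=True)
        K = np.asarray((X @ X.T).todense())
        clf = SVC(C=1.0, kernel="precomputed").fit(K, y)
        dual = gkm.TrainedGkmModel(
            config=config, mode="kernel_expansion",
            intercept=float(clf.intercept_[0]),
            support_matrix=X[clf.support_].tocsr(),
            dual_coef=clf.dual_coef_[0].copy(), val_score_sd=1.0)
        primal = gkm.as_explicit_linear(dual)
        probes = [random_dna(rng, 60) for _ in range(20)]
        assert np.allclose(gkm.score(dual, probes),
                           gkm.score(primal, probes), atol=1e-6)

    def test_dcd_solver_matches_reference_svm(self):
        """The in-package hinge solver agrees with an independent SVM fit."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(6)
        motif = "TGACCTTG"

        def make(pos):
            s = random_dna(rng, 80)
            if pos:
                i = int(rng.integers(10, 60))
                s = s[:i] + motif + s[i + 8:]
            return s

        seqs = [make(i < 40) for i in range(80)]
        y = np.array([1] * 40 + [0] * 40)
        config = gkm.GkmConfig(l=6, k=4)
        fz = gkm.GkmFeaturizer(config)
        X = fz.transform(seqs, l2_normalize=True)
        w, b = gkm._fit_linear_svm(X.astype(np.float32), y, 1.0, 1.0, 0)
        ours = np.asarray(X @ w).ravel() + b
        K = np.asarray((X @ X.T).todense())
        ref = SVC(C=1.0, kernel="precomputed").fit(K, y) \
            .decision_function(K)
        assert np.corrcoef(ours, ref)[0, 1] > 0.99
        assert ((ours > 0) == (ref > 0)).mean() > 0.95

    def test_variable_length_scoring(self, small_model):
        model, _, _ = small_model
        rng = np.random.default_rng(8)
        out = gkm.score(model, [random_dna(rng, n) for n in (20, 120, 300)])
        assert np.isfinite(out).all()


class TestNormalization:
    def test_arithmetic_and_identity(self, small_model):
        model, _, val = small_model
        assert model.val_score_sd > 0
        raw = gkm.score(model, val[0])
        normalized = gkm.normalize_scores(model, raw)
        assert np.std(normalized) == pytest.approx(1.0, abs=1e-9)
        model2 = gkm.TrainedGkmModel(
            config=model.config, mode=model.mode, intercept=model.intercept,
            weights=model.weights, val_score_sd=1.2)
        assert gkm.normalize_scores(model2, np.array([2.4]))[0] == \
            pytest.approx(2.0)
        assert gkm.normalize_scores(model2, np.array([0.0]))[0] == 0.0

    def test_missing_sd_is_an_error(self, small_model):
        model, _, _ = small_model
        broken = gkm.TrainedGkmModel(
            config=model.config, mode=model.mode, intercept=model.intercept,
            weights=model.weights, val_score_sd=np.nan)
        with pytest.raises(ValueError):
            gkm.normalize_scores(broken, np.array([1.0]))


class TestSerialization:
    def test_round_trip_preserves_scores(self, small_model, tmp_path):
        model, _, val = small_model
        path = tmp_path / "model.npz"
        gkm.save_model(model, path)
        back = gkm.load_model(path)
        assert back.config == model.config
        assert np.allclose(gkm.score(back, val[0][:10]),
                           gkm.score(model, val[0][:10]))
        assert back.training_manifest == model.training_manifest


def _gapped_matches(pattern, target):
    """Does the gapped pattern match anywhere in the target string?"""
    for s in range(len(target) - len(pattern) + 1):
        if all(c == "." or c == target[s + i]
               for i, c in enumerate(pattern)):
            return True
    return False
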