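"""Gapped k-mer featurization, kernels and SVM training / scoring.

A sequence is represented by the weighted counts of its gapped k-mers: every
length-``l`` substring ("l-mer") contributes one instance for each of the
C(l, k) ways of choosing ``k`` informative positions, the remaining ``l-k``
positions being wildcards.  The similarity between two sequences is the
cosine of their count vectors,

    K^(x, y) = <x, y> / sqrt(<x, x> <y, y>)  in [0, 1],

optionally passed through an RBF transform ``exp(gamma * (K^ - 1))``.
Because differential open-chromatin training windows are summit-centred,
l-mers near the window centre may be up-weighted ("center-weighted" kernels):
an l-mer starting at ``s`` in a window of length ``L`` receives weight

    w(dist) = 2 ** (-dist / H),   dist = |s + l/2 - L/2|,

normalized so w(0) = 1 (the amplitude ``M`` cancels and is recorded for
provenance only).  With ``rc_collapse`` every pattern is pooled with its
reverse complement, making features and scores strand-symmetric.

The inner product here is exact (untruncated); the mismatch parameter ``d``
of approximate implementations is recorded in the config for provenance but
does not alter the kernel.

Training fits a soft-margin SVM on the L2-normalized feature matrix — so the
linear kernel equals K^ — with per-class penalties C (negatives) and C*w
(positives), over a parameter grid; the grid point with the best validation
F1 (decision threshold 0) wins, ties broken by smaller l then smaller C.
Linear kernels are collapsed to explicit primal weights; RBF models keep
their support expansion.  The standard deviation of the validation decision
scores is stored so downstream scores can be expressed in SD units.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.svm import SVC

from .seqs import SequenceError, encode

logger = logging.getLogger(__name__)

__all__ = [
    "GkmConfig",
    "GkmFeaturizer",
    "TrainedGkmModel",
    "enumerate_gapped_kmers",
    "featurize",
    "kernel",
    "gram_matrix",
    "train",
    "score",
    "normalize_scores",
    "as_explicit_linear",
    "save_model",
    "load_model",
]

KERNELS = ("gkm", "wgkm", "gkm_rbf")


@dataclass(frozen=True)
class GkmConfig:
    """Hyperparameters of one gapped k-mer SVM."""
    l: int = 10
    k: int = 6
    d: int = 3                  # recorded mismatch parameter (provenance)
    kernel: str = "wgkm"
    gamma: float = 2.0          # rbf width (kernel == "gkm_rbf")
    M: float = 50.0             # center-weight amplitude (cancels; recorded)
    H: float = 50.0             # center-weight half-life, bp
    C: float = 1.0
    w: float = 1.0              # positive-class penalty multiplier
    rc_collapse: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.l <= 12:
            raise ValueError("require 1 <= k <= l <= 12")
        if self.C <= 0 or self.w <= 0 or self.H <= 0:
            raise ValueError("C, w and H must be positive")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")

    @property
    def center_weighted(self) -> bool:
        return self.kernel in ("wgkm", "gkm_rbf")


# ---------------------------------------------------------------------------
# Featurizer
# ---------------------------------------------------------------------------

class GkmFeaturizer:
    """Vectorized gapped k-mer counting for one :class:`GkmConfig`.

    Columns of the feature space are indexed ``combo * 4**k + code`` where
    ``combo`` enumerates the C(l, k) informative-position choices in
    lexicographic order and ``code`` is the base-4 encoding of the k
    informative bases (first position most significant).
    """

    def __init__(self, config: GkmConfig):
        self.config = config
        l, k = config.l, config.k
        self.combos = np.array(list(itertools.combinations(range(l), k)),
                               dtype=np.int64)
        self.n_combos = len(self.combos)
        self.n_kmers = 4 ** k
        self.n_columns = self.n_combos * self.n_kmers
        # int32 column arithmetic where it fits (it always does for k <= 8)
        self._dtype = np.int32 if self.n_columns < 2 ** 31 else np.int64
        self.powers = (4 ** np.arange(k - 1, -1, -1)).astype(self._dtype)
        self.combo_offset = (np.arange(self.n_combos) *
                             self.n_kmers).astype(self._dtype)

        if config.rc_collapse:
            # reverse complement of a gapped pattern: mirror the positions,
            # complement and reverse the informative bases
            combo_index = {tuple(c): i for i, c in enumerate(self.combos)}
            self.partner_offset = np.array(
                [combo_index[tuple(sorted(l - 1 - p for p in c))]
                 for c in self.combos]).astype(self._dtype) * self.n_kmers
            codes = np.arange(self.n_kmers, dtype=np.int64)
            digits = (codes[:, None] // self.powers[None, :]) % 4
            self.rc_code = ((3 - digits[:, ::-1]) *
                            self.powers[None, :]).sum(axis=1) \
                .astype(self._dtype)
        else:
            self.partner_offset = None
            self.rc_code = None

        # for each in-l-mer offset j, the (combo, slot) pairs containing j
        self._pairs_at_offset = []
        for j in range(l):
            ci, slot = np.nonzero(self.combos == j)
            self._pairs_at_offset.append((ci, slot))

    # -- low-level pieces --------------------------------------------------

    def instance_codes(self, codes: np.ndarray) -> np.ndarray:
        """k-mer codes of every (window, combo) instance; (n_win, n_combos)."""
        l = self.config.l
        if len(codes) < l:
            raise SequenceError(f"sequence shorter than l={l}")
        windows = sliding_window_view(codes, l).astype(self._dtype)
        return windows[:, self.combos] @ self.powers

    def canonical_columns(self, kcodes: np.ndarray) -> np.ndarray:
        """Column ids (rc-canonicalized if configured) for instance codes."""
        cols = self.combo_offset + kcodes
        if self.config.rc_collapse:
            cols = np.minimum(cols, self.partner_offset + self.rc_code[kcodes])
        return cols

    def window_weights(self, seq_len: int) -> np.ndarray:
        """Center weight of each l-mer start position; all ones for plain gkm."""
        n_win = seq_len - self.config.l + 1
        if not self.config.center_weighted:
            return np.ones(n_win)
        s = np.arange(n_win)
        dist = np.abs(s + self.config.l / 2.0 - seq_len / 2.0)
        return 2.0 ** (-dist / self.config.H)

    def dense_vector(self, seq: str) -> np.ndarray:
        """One sequence's aggregated feature vector, dense over all columns."""
        codes = encode(seq)
        cols = self.canonical_columns(self.instance_codes(codes))
        weights = np.broadcast_to(self.window_weights(len(codes))[:, None],
                                  cols.shape)
        return np.bincount(cols.ravel(), weights=weights.ravel(),
                           minlength=self.n_columns)

    def seq_vector(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """(columns, weights) of one sequence's aggregated feature vector."""
        codes = encode(seq)
        cols = self.canonical_columns(self.instance_codes(codes))
        flat = cols.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_cols = flat[order]
        sorted_w = np.broadcast_to(self.window_weights(len(codes))[:, None],
                                   cols.shape).ravel()[order]
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_cols) != 0])
        return sorted_cols[starts], np.add.reduceat(sorted_w, starts)

    # -- public matrix interface -------------------------------------------

    def transform(self, seqs: Sequence[str],
                  l2_normalize: bool = False,
                  dtype=np.float64) -> sp.csr_matrix:
        """Sparse feature matrix (n_seqs x n_columns) of weighted counts."""
        indptr = [0]
        indices: list[np.ndarray] = []
        data: list[np.ndarray] = []
        for seq in seqs:
            cols, agg = self.seq_vector(seq)
            indices.append(cols.astype(np.int32))
            data.append(agg.astype(dtype))
            indptr.append(indptr[-1] + len(cols))
        X = sp.csr_matrix(
            (np.concatenate(data) if data else np.empty(0, dtype),
             np.concatenate(indices) if indices else np.empty(0, np.int32),
             np.asarray(indptr, dtype=np.int64)),
            shape=(len(seqs), self.n_columns))
        if l2_normalize:
            row_nnz = np.diff(X.indptr)
            if (row_nnz == 0).any():
                raise ValueError("zero-norm feature vector (empty sequence?)")
            norms = np.sqrt(np.add.reduceat(X.data ** 2, X.indptr[:-1]))
            X.data /= np.repeat(norms, row_nnz)
        return X

    def pattern_string(self, col: int) -> str:
        """Human-readable pattern of a column id, '.' marking wildcards."""
        combo = self.combos[col // self.n_kmers]
        code = col % self.n_kmers
        bases = "ACGT"
        out = ["."] * self.config.l
        for slot, pos in enumerate(combo):
            out[pos] = bases[(code // self.powers[slot]) % 4]
        return "".join(out)


def enumerate_gapped_kmers(seq: str, l: int, k: int) -> dict[str, int]:
    """Multiset of gapped k-mer patterns, as pattern -> occurrence count.

    Every length-l substring contributes C(l, k) pattern instances; total
    multiset size is (len(seq) - l + 1) * C(l, k).
    """
    config = GkmConfig(l=l, k=k, kernel="gkm", rc_collapse=False)
    fz = GkmFeaturizer(config)
    cols = fz.canonical_columns(fz.instance_codes(encode(seq)))
    uniq, counts = np.unique(cols.ravel(), return_counts=True)
    return {fz.pattern_string(int(c)): int(n)
            for c, n in zip(uniq, counts)}


def featurize(seq: str, config: GkmConfig) -> dict[str, float]:
    """Weighted gapped k-mer feature vector as a pattern -> weight map."""
    fz = GkmFeaturizer(config)
    cols, agg = fz.seq_vector(seq)
    return {fz.pattern_string(int(c)): float(v) for c, v in zip(cols, agg)}


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def _dict_dot(x: Mapping[str, float], y: Mapping[str, float]) -> float:
    if len(y) < len(x):
        x, y = y, x
    return sum(v * y[key] for key, v in x.items() if key in y)


def kernel(x: Mapping[str, float], y: Mapping[str, float],
           config: GkmConfig) -> float:
    """Normalized gapped k-mer similarity of two feature vectors."""
    nx, ny = _dict_dot(x, x), _dict_dot(y, y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm feature vector")
    khat = _dict_dot(x, y) / np.sqrt(nx * ny)
    if config.kernel == "gkm_rbf":
        return float(np.exp(config.gamma * (khat - 1.0)))
    return float(khat)


def gram_matrix(seqs: Sequence[str], config: GkmConfig,
                seqs2: Sequence[str] | None = None) -> np.ndarray:
    """Dense kernel matrix between two sequence sets (or one with itself)."""
    fz = GkmFeaturizer(config)
    X = fz.transform(seqs, l2_normalize=True)
    Y = X if seqs2 is None else fz.transform(seqs2, l2_normalize=True)
    K = np.asarray((X @ Y.T).todense())
    if config.kernel == "gkm_rbf":
        K = np.exp(config.gamma * (K - 1.0))
    return K


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class TrainedGkmModel:
    """A fitted gapped k-mer classifier.

    ``explicit_linear`` stores collapsed primal weights over the feature
    space; ``kernel_expansion`` stores the (normalized) support vectors and
    dual coefficients.  ``val_score_sd`` is the standard deviation of the
    raw decision scores on the validation split of the training run, used
    to express scores in SD units.
    """
    config: GkmConfig
    mode: str                               # explicit_linear | kernel_expansion
    intercept: float
    val_score_sd: float
    weights: np.ndarray | None = None
    support_matrix: sp.csr_matrix | None = None
    dual_coef: np.ndarray | None = None
    training_manifest: dict = field(default_factory=dict)
    _featurizer: GkmFeaturizer | None = field(
        default=None, repr=False, compare=False)

    @property
    def featurizer(self) -> GkmFeaturizer:
        if self._featurizer is None:
            self._featurizer = GkmFeaturizer(self.config)
        return self._featurizer

    def top_features(self, n: int = 10) -> list[tuple[str, float]]:
        """The n most positively weighted gapped k-mer patterns."""
        if self.mode != "explicit_linear":
            raise ValueError("top_features requires an explicit_linear model")
        idx = np.argsort(self.weights)[::-1][:n]
        fz = self.featurizer
        return [(fz.pattern_string(int(i)), float(self.weights[i]))
                for i in idx]


@njit(cache=True)
def _dcd_hinge(indptr, indices, data, y, box, qii, w, order, seed,
               max_epochs, tol):
    """Dual coordinate descent for the L1-hinge soft-margin SVM.

    Solves min_w 0.5 ||w||^2 + sum_i C_i max(0, 1 - y_i w.x_i) over the
    rows of a CSR matrix, updating the primal weights in place.  The last
    entry of ``w`` is a regularized intercept, fed by an implicit constant
    feature of value 1 on every row (so no bias column is materialized).
    One coordinate pass per epoch in the fixed ``order``; stops when the
    largest projected gradient falls below ``tol``.
    """
    n = len(y)
    nb = len(w) - 1
    alpha = np.zeros(n)
    np.random.seed(seed)
    for _ in range(max_epochs):
        # fresh pass order each epoch (Fisher-Yates), as in liblinear
        for ii in range(n - 1, 0, -1):
            j = np.random.randint(0, ii + 1)
            tmp = order[ii]
            order[ii] = order[j]
            order[j] = tmp
        max_pg = 0.0
        for ii in range(n):
            i = order[ii]
            dot = w[nb]
            for p in range(indptr[i], indptr[i + 1]):
                dot += w[indices[p]] * data[p]
            g = y[i] * dot - 1.0
            a = alpha[i]
            c = box[i]
            if a == 0.0:
                pg = g if g < 0.0 else 0.0
            elif a == c:
                pg = g if g > 0.0 else 0.0
            else:
                pg = g
            if pg != 0.0:
                if abs(pg) > max_pg:
                    max_pg = abs(pg)
                new_a = a - g / qii[i]
                if new_a < 0.0:
                    new_a = 0.0
                elif new_a > c:
                    new_a = c
                step = (new_a - a) * y[i]
                if step != 0.0:
                    for p in range(indptr[i], indptr[i + 1]):
                        w[indices[p]] += step * data[p]
                    w[nb] += step
                    alpha[i] = new_a
        if max_pg < tol:
            break
    return alpha


def _fit_linear_svm(X: sp.csr_matrix, y01: np.ndarray, C: float,
                    w_pos: float, random_state: int,
                    max_epochs: int = 100,
                    tol: float = 1e-3) -> tuple[np.ndarray, float]:
    """Hinge SVM on L2-normalized rows; returns (weights, intercept).

    The intercept is a regularized implicit constant feature (value 1),
    as in the common liblinear formulation.
    """
    n = X.shape[0]
    y = np.where(y01 > 0, 1.0, -1.0)
    box = np.where(y01 > 0, C * w_pos, C)
    qii = np.add.reduceat(
        X.data.astype(np.float64) ** 2, X.indptr[:-1]) + 1.0
    order = np.arange(n)
    w = np.zeros(X.shape[1] + 1)
    _dcd_hinge(X.indptr, X.indices, X.data, y, box, qii, w,
               order, random_state, max_epochs, tol)
    return w[:-1], float(w[-1])


def _as_xy(dataset) -> tuple[list[str], np.ndarray]:
    """Accept (seqs, labels) or a list of PreparedExample-like objects."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        seqs, labels = dataset
        return list(seqs), np.asarray(labels, dtype=int)
    seqs = [ex.sequence for ex in dataset]
    labels = np.array([1 if ex.label == "positive" else 0 for ex in dataset])
    return seqs, labels


def _decision_scores(model: TrainedGkmModel,
                     X: sp.csr_matrix) -> np.ndarray:
    if model.mode == "explicit_linear":
        return np.asarray(X @ model.weights).ravel() + model.intercept
    K = np.asarray((X @ model.support_matrix.T).todense())
    if model.config.kernel == "gkm_rbf":
        K = np.exp(model.config.gamma * (K - 1.0))
    return K @ model.dual_coef + model.intercept


def train(train_set, val_set, grid: Sequence[GkmConfig],
          random_state: int = 0) -> TrainedGkmModel:
    """Grid-search SVM training, selecting by validation F1 at threshold 0.

    Ties in F1 are broken by smaller ``l`` then smaller ``C`` (simpler
    model first).
    """
    from .metrics import f1_at_threshold

    if not grid:
        raise ValueError("parameter grid is empty")
    seqs_tr, y_tr = _as_xy(train_set)
    seqs_val, y_val = _as_xy(val_set)
    if not seqs_tr or not seqs_val:
        raise ValueError("train and validation sets must be nonempty")
    if len(set(y_tr.tolist())) < 2:
        raise ValueError("training data must contain both classes")

    best: TrainedGkmModel | None = None
    best_key: tuple | None = None
    f1_by_config: list[float] = []
    for config in grid:
        fz = GkmFeaturizer(config)
        if config.kernel in ("gkm", "wgkm"):
            # float32 features keep the peak footprint near the matrix itself
            Xtr = fz.transform(seqs_tr, l2_normalize=True, dtype=np.float32)
            Xval = fz.transform(seqs_val, l2_normalize=True, dtype=np.float32)
            weights, intercept = _fit_linear_svm(
                Xtr, y_tr, config.C, config.w, random_state)
            model = TrainedGkmModel(
                config=config, mode="explicit_linear",
                intercept=intercept, weights=weights, val_score_sd=np.nan,
                _featurizer=fz)
        else:
            Xtr = fz.transform(seqs_tr, l2_normalize=True)
            Xval = fz.transform(seqs_val, l2_normalize=True)
            Ktr = np.asarray((Xtr @ Xtr.T).todense())
            Ktr = np.exp(config.gamma * (Ktr - 1.0))
            clf = SVC(C=config.C, kernel="precomputed",
                      class_weight={0: 1.0, 1: config.w})
            clf.fit(Ktr, y_tr)
            sup = clf.support_
            model = TrainedGkmModel(
                config=config, mode="kernel_expansion",
                intercept=float(clf.intercept_[0]),
                support_matrix=Xtr[sup].tocsr(),
                dual_coef=clf.dual_coef_[0].copy(), val_score_sd=np.nan,
                _featurizer=fz)
        val_scores = _decision_scores(model, Xval)
        f1 = f1_at_threshold(val_scores, y_val, threshold=0.0)
        f1_by_config.append(float(f1))
        key = (f1, -config.l, -config.C)
        if best_key is None or key > best_key:
            best, best_key = model, key
        del Xtr, Xval

    # the stored SD comes from the standard scoring path so that
    # downstream normalization is exactly consistent with score()
    val_raw = score(best, seqs_val)
    sd = float(np.std(val_raw))
    if not sd > 0:
        raise ValueError("validation scores have zero spread")
    best.val_score_sd = sd

    fingerprint = hashlib.sha1(
        ("\n".join(seqs_tr) + "|" + "".join(map(str, y_tr))).encode()
    ).hexdigest()[:16]
    best.training_manifest = dict(
        n_train=len(seqs_tr), n_val=len(seqs_val),
        n_train_pos=int(y_tr.sum()), n_val_pos=int(y_val.sum()),
        train_fingerprint=fingerprint, random_state=random_state,
        grid=[asdict(c) for c in grid],
        val_f1=f1_by_config,
        selected=[asdict(c) for c in grid].index(asdict(best.config)),
    )
    return best


def score(model: TrainedGkmModel, seqs: Sequence[str]) -> np.ndarray:
    """Raw decision scores; score > 0 predicts the positive class.

    Sequences that cannot be scored (containing N, or shorter than l) yield
    NaN and a logged per-sequence error; the run continues.
    """
    fz = model.featurizer
    out = np.full(len(seqs), np.nan)
    valid_idx, valid_seqs = [], []
    for i, seq in enumerate(seqs):
        try:
            encode(seq)
            if len(seq) < model.config.l:
                raise SequenceError("sequence shorter than l")
            valid_idx.append(i)
            valid_seqs.append(seq)
        except SequenceError as exc:
            logger.warning("sequence %d not scored: %s", i, exc)
    if valid_seqs:
        X = fz.transform(valid_seqs, l2_normalize=True)
        out[valid_idx] = _decision_scores(model, X)
    return out


def normalize_scores(model: TrainedGkmModel,
                     raw_scores: np.ndarray) -> np.ndarray:
    """Scores in validation-SD units: raw / val_score_sd (sign preserved)."""
    sd = model.val_score_sd
    if sd is None or not np.isfinite(sd) or sd <= 0:
        raise ValueError("model has no valid val_score_sd")
    return np.asarray(raw_scores, dtype=float) / sd


def as_explicit_linear(model: TrainedGkmModel) -> TrainedGkmModel:
    """Collapse a linear-kernel support expansion into primal weights."""
    if model.mode == "explicit_linear":
        return model
    if model.config.kernel == "gkm_rbf":
        raise ValueError("an rbf expansion cannot be collapsed to primal form")
    weights = np.asarray(
        (model.support_matrix.T @ model.dual_coef)).ravel()
    return TrainedGkmModel(
        config=model.config, mode="explicit_linear",
        intercept=model.intercept, weights=weights,
        val_score_sd=model.val_score_sd,
        training_manifest=dict(model.training_manifest),
        _featurizer=model._featurizer)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: TrainedGkmModel, path: str | Path) -> None:
    """Write a self-describing .npz archive for the model."""
    payload: dict[str, object] = dict(
        format_version=_FORMAT_VERSION,
        config=json.dumps(asdict(model.config)),
        mode=model.mode,
        intercept=model.intercept,
        val_score_sd=model.val_score_sd,
        manifest=json.dumps(model.training_manifest),
    )
    if model.mode == "explicit_linear":
        payload["weights"] = model.weights
    else:
        sm = model.support_matrix.tocsr()
        payload.update(sm_data=sm.data, sm_indices=sm.indices,
                       sm_indptr=sm.indptr, sm_shape=np.array(sm.shape),
                       dual_coef=model.dual_coef)
    np.savez_compressed(path, **payload)


def load_model(path: str | Path) -> TrainedGkmModel:
    with np.load(path, allow_pickle=False) as z:
        version = int(z["format_version"])
        if version != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        config = GkmConfig(**json.loads(str(z["config"])))
        mode = str(z["mode"])
        kwargs: dict = {}
        if mode == "explicit_linear":
            kwargs["weights"] = z["weights"]
        else:
            kwargs["support_matrix"] = sp.csr_matrix(
                (z["sm_data"], z["sm_indices"], z["sm_indptr"]),
                shape=tuple(z["sm_shape"]))
            kwargs["dual_coef"] = z["dual_coef"]
        return TrainedGkmModel(
            config=config, mode=mode,
            intercept=float(z["intercept"]),
            val_score_sd=float(z["val_score_sd"]),
            training_manifest=json.loads(str(z["manifest"])),
            **kwargs)
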