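"""Nucleotide-resolution model interpretation.

For an explicit-linear gapped k-mer model the decision score decomposes
exactly over gapped k-mer instances: each instance's contribution
(weight x center-weight / sequence norm) is split evenly over its k
informative positions, giving a per-base *actual* importance whose sum
equals the decision score minus the intercept.  The *hypothetical*
importance of base b at position i is the same per-position attribution
recomputed on the sequence with position i substituted by b (so the
reference base's hypothetical equals the actual importance).  For
non-linear models both tracks come from in-silico mutagenesis: every
single-base substitution is re-scored and each base's hypothetical is its
score minus the mean score of the three alternatives.

*Normalized* importance mean-centres the four hypothetical values at each
position: a position loses importance when other nucleotides would produce
similar scores.  Candidate motif sites are called from the top 5% of
normalized importance (segments merged across gaps <= 2 bp, constrained to
6-8 bp).  Sites are matched against PWMs with an exact log-odds scanner
whose null p-values come from dynamic programming over the 0-order
background, and perturbed by guarded random scrambling (the permuted site
must not introduce a new PWM hit) followed by re-scoring across models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import cnn as _cnn
from . import gkm as _gkm
from .seqs import encode, decode
from .simulate import ConfigurationError, MotifModel

__all__ = [
    "ImportanceTrack",
    "MotifSiteCall",
    "PwmHit",
    "per_base_importance",
    "normalize_importance",
    "call_sites",
    "scan_pwm",
    "scramble_site",
    "score_mutants",
    "read_meme_motifs",
    "write_meme_motifs",
    "write_importance_tsv",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImportanceTrack:
    sequence_id: str
    model_id: str
    sequence: str
    actual: np.ndarray                  # (L,)
    hypothetical: np.ndarray            # (4, L); rows A, C, G, T
    normalized: np.ndarray | None = None


@dataclass(frozen=True)
class MotifSiteCall:
    start: int
    end: int
    rank: int
    importance_mass: float


@dataclass(frozen=True)
class PwmHit:
    motif_id: str
    start: int
    end: int
    strand: str
    log_odds: float                     # bits
    p: float                            # exact null p-value


# ---------------------------------------------------------------------------
# Per-base importance
# ---------------------------------------------------------------------------

def _linear_importance(model: _gkm.TrainedGkmModel, seq: str,
                       with_hypothetical: bool = True,
                       ) -> tuple[np.ndarray, np.ndarray | None]:
    fz = model.featurizer
    l, k = model.config.l, model.config.k
    codes = encode(seq)
    L = len(codes)
    kcodes = fz.instance_codes(codes)                   # (n_win, n_combos)
    cols = fz.canonical_columns(kcodes)
    cw = fz.window_weights(L)
    wvec = model.weights

    flat_w = np.broadcast_to(cw[:, None], cols.shape).ravel()
    xdense = np.bincount(cols.ravel(), weights=flat_w,
                         minlength=fz.n_columns)
    norm2 = float((xdense ** 2).sum())
    norm = float(np.sqrt(norm2))

    contrib = wvec[cols] * cw[:, None] / (k * norm)     # (n_win, n_combos)
    n_win = cols.shape[0]
    pos = (np.arange(n_win)[:, None, None] + fz.combos[None, :, :])
    actual = np.bincount(
        pos.ravel(),
        weights=np.broadcast_to(contrib[:, :, None], pos.shape).ravel(),
        minlength=L)

    if not with_hypothetical:
        return actual, None

    hyp = np.zeros((4, L))
    bases = np.arange(4)
    for i in range(L):
        s_lo, s_hi = max(0, i - l + 1), min(i, n_win - 1)
        if s_hi < s_lo:
            hyp[:, i] = actual[i]
            continue
        S_list, CI_list, SLOT_list = [], [], []
        for s in range(s_lo, s_hi + 1):
            ci, slot = fz._pairs_at_offset[i - s]
            S_list.append(np.full(len(ci), s))
            CI_list.append(ci)
            SLOT_list.append(slot)
        S = np.concatenate(S_list)
        CI = np.concatenate(CI_list)
        SLOT = np.concatenate(SLOT_list)
        old_kcode = kcodes[S, CI]
        old_cols = cols[S, CI]
        cw_S = cw[S]
        ref = int(codes[i])
        for b in bases:
            if b == ref:
                hyp[b, i] = actual[i]
                continue
            new_kcode = old_kcode + (int(b) - ref) * fz.powers[SLOT]
            new_cols = fz.combo_offset[CI] + new_kcode
            if model.config.rc_collapse:
                new_cols = np.minimum(
                    new_cols, fz.partner_offset[CI] + fz.rc_code[new_kcode])
            numerator = float((wvec[new_cols] * cw_S).sum()) / k
            # exact norm of the substituted sequence's feature vector
            cat_cols = np.concatenate([old_cols, new_cols])
            cat_w = np.concatenate([-cw_S, cw_S])
            u, uinv = np.unique(cat_cols, return_inverse=True)
            delta = np.bincount(uinv.ravel(), weights=cat_w,
                                minlength=len(u))
            v = xdense[u]
            norm2_mut = norm2 + float(((v + delta) ** 2 - v ** 2).sum())
            hyp[b, i] = numerator / np.sqrt(norm2_mut)
    return actual, hyp


def _ism_importance(score_fn: Callable[[Sequence[str]], np.ndarray],
                    seq: str) -> tuple[np.ndarray, np.ndarray]:
    codes = encode(seq)
    L = len(codes)
    base_score = float(score_fn([seq])[0])
    sub = np.empty((4, L))
    mutants, where = [], []
    for i in range(L):
        for b in range(4):
            if b == int(codes[i]):
                sub[b, i] = base_score
            else:
                mutants.append(seq[:i] + "ACGT"[b] + seq[i + 1:])
                where.append((b, i))
    if mutants:
        scored = score_fn(mutants)
        for (b, i), v in zip(where, scored):
            sub[b, i] = float(v)
    # each base's hypothetical: its score minus the mean of the alternatives
    total = sub.sum(axis=0)
    hyp = sub - (total[None, :] - sub) / 3.0
    actual = hyp[codes, np.arange(L)]
    return actual, hyp


def per_base_importance(model, seq: str,
                        sequence_id: str = "",
                        model_id: str = "",
                        with_hypothetical: bool = True) -> ImportanceTrack:
    """Actual and hypothetical per-base importance of one sequence.

    Explicit-linear gapped k-mer models use the exact score decomposition;
    anything else (kernel expansions, CNNs, or a callable mapping a list of
    sequences to scores) falls back to in-silico mutagenesis.
    """
    if isinstance(model, _gkm.TrainedGkmModel) \
            and model.mode == "explicit_linear":
        actual, hyp = _linear_importance(model, seq, with_hypothetical)
        model_id = model_id or "gkm"
    else:
        if isinstance(model, _gkm.TrainedGkmModel):
            fn = lambda seqs: _gkm.score(model, seqs)  # noqa: E731
            model_id = model_id or "gkm"
        elif isinstance(model, _cnn.TrainedCnn):
            fn = lambda seqs: _cnn.predict(model, seqs)  # noqa: E731
            model_id = model_id or "cnn"
        elif callable(model):
            fn = model
            model_id = model_id or "callable"
        else:
            raise TypeError(f"cannot interpret model of type {type(model)}")
        actual, hyp = _ism_importance(fn, seq)
    return ImportanceTrack(sequence_id=sequence_id, model_id=model_id,
                           sequence=seq, actual=actual, hypothetical=hyp)


def normalize_importance(track: ImportanceTrack) -> ImportanceTrack:
    """Mean-centre the four hypothetical values: actual - mean(hypothetical)."""
    if track.hypothetical is None:
        raise ValueError("hypothetical importance not populated")
    normalized = track.actual - track.hypothetical.mean(axis=0)
    return replace(track, normalized=normalized)


# ---------------------------------------------------------------------------
# Site calling
# ---------------------------------------------------------------------------

def call_sites(track: ImportanceTrack,
               top_frac: float = 0.05,
               max_gap: int = 2,
               site_len_range: tuple[int, int] = (6, 8),
               top_n: int = 2) -> list[MotifSiteCall]:
    """Call putative motif sites from the top fraction of importance.

    The top ``top_frac`` of normalized-importance bases are merged into
    segments (bridging gaps of up to ``max_gap`` bases), segments are
    ranked by summed normalized importance over their span, and the best
    ``top_n`` are returned trimmed (to their best-sum window) or extended
    symmetrically into ``site_len_range``.
    """
    if track.normalized is None:
        raise ValueError("call normalize_importance first")
    values = track.normalized
    L = len(values)
    min_len, max_len = site_len_range
    if L < min_len:
        raise ValueError("sequence shorter than the minimum site length")
    n_top = max(1, int(np.ceil(top_frac * L)))
    order = np.argsort(-values, kind="stable")
    top_idx = np.sort(order[:n_top])

    segments: list[tuple[int, int]] = []
    start = prev = int(top_idx[0])
    for i in top_idx[1:]:
        i = int(i)
        if i - prev - 1 <= max_gap:
            prev = i
        else:
            segments.append((start, prev + 1))
            start = prev = i
    segments.append((start, prev + 1))

    scored = sorted(segments,
                    key=lambda seg: -float(values[seg[0]:seg[1]].sum()))
    calls: list[MotifSiteCall] = []
    for rank, (s, e) in enumerate(scored[:top_n], start=1):
        if e - s > max_len:
            sums = np.convolve(values[s:e], np.ones(max_len), mode="valid")
            s = s + int(np.argmax(sums))
            e = s + max_len
        while e - s < min_len:
            # grow toward the more important neighbour (ties go right)
            left = values[s - 1] if s > 0 else -np.inf
            right = values[e] if e < L else -np.inf
            if right >= left:
                e += 1
            else:
                s -= 1
        calls.append(MotifSiteCall(
            start=s, end=e, rank=rank,
            importance_mass=float(values[s:e].sum())))
    return calls


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_SCORE_SCALE = 1000  # log-odds discretized to 1/1000 bit for exact p-values


def _int_log_odds(motif: MotifModel, pseudocount: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lo = motif.log_odds(pseudocount)
    # a zero probability cell (possible only at pseudocount 0) gets a
    # finite floor: any window using it is effectively impossible
    lo = np.where(np.isneginf(lo), -100.0, lo)
    return np.round(lo * _SCORE_SCALE).astype(np.int64)


def _null_survival(int_lo: np.ndarray, background: np.ndarray,
                   ) -> tuple[np.ndarray, int]:
    """Exact distribution of the integer score under the 0-order background.

    Returns (sf, base) where sf[s - base] = P(score >= s) for s in
    [base, base + len(sf) - 1].
    """
    dist = np.array([1.0])
    base = 0
    for j in range(int_lo.shape[1]):
        col = int_lo[:, j]
        m, M = int(col.min()), int(col.max())
        new = np.zeros(len(dist) + M - m)
        for b in range(4):
            shift = int(col[b]) - m
            new[shift:shift + len(dist)] += dist * background[b]
        dist = new
        base += m
    sf = np.cumsum(dist[::-1])[::-1]
    return sf, base


def _window_scores(codes: np.ndarray, int_lo: np.ndarray) -> np.ndarray:
    w = int_lo.shape[1]
    from numpy.lib.stride_tricks import sliding_window_view
    windows = sliding_window_view(codes, w)
    return int_lo[windows, np.arange(w)].sum(axis=1)


def scan_pwm(seq: str, motif: MotifModel,
             p_threshold: float = 1e-4,
             pseudocount: float = 1e-3) -> list[PwmHit]:
    """Both-strand PWM scan with exact null p-values.

    Scores are per-position log2 odds ``log2((prob + eps) / background)``
    summed over the motif width (discretized to 1/1000 bit); the p-value of
    a score is the exact probability, by dynamic programming over motif
    positions, that a background-distributed window scores at least as
    high.  Hits with p < ``p_threshold`` are returned sorted by p.
    """
    if (motif.background <= 0).any():
        raise ConfigurationError("background frequencies must be positive")
    codes = encode(seq)
    w = motif.width
    if w > len(codes):
        raise ValueError("motif wider than sequence")
    int_lo = _int_log_odds(motif, pseudocount)
    sf, base = _null_survival(int_lo, motif.background)

    def pvalue(s: int) -> float:
        idx = s - base
        if idx < 0:
            return 1.0
        if idx >= len(sf):
            return float(sf[-1])
        return float(sf[idx])

    hits: list[PwmHit] = []
    # minus-strand occurrences equal plus-strand matches of the
    # reverse-complemented matrix (rows ACGT reversed = complement)
    for strand, lo in (("+", int_lo), ("-", int_lo[::-1, ::-1])):
        scores = _window_scores(codes, lo)
        for start in np.nonzero(
                [pvalue(int(s)) < p_threshold for s in scores])[0]:
            s = int(scores[start])
            hits.append(PwmHit(
                motif_id=motif.motif_id, start=int(start),
                end=int(start) + w, strand=strand,
                log_odds=s / _SCORE_SCALE, p=pvalue(s)))
    hits.sort(key=lambda h: (h.p, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Guarded scrambling and mutant scoring
# ---------------------------------------------------------------------------

def _guard_hits(seq: str, site_start: int, site_end: int,
                guard_motifs: Sequence[MotifModel],
                p_threshold: float) -> set[tuple[str, int, str]]:
    """PWM hits in the neighbourhood windows overlapping the site."""
    keys: set[tuple[str, int, str]] = set()
    for motif in guard_motifs:
        w = motif.width
        lo = max(0, site_start - (w - 1))
        hi = min(len(seq), site_end + (w - 1))
        if hi - lo < w:
            continue
        for hit in scan_pwm(seq[lo:hi], motif, p_threshold):
            keys.add((hit.motif_id, lo + hit.start, hit.strand))
    return keys


def scramble_site(seq: str, site: MotifSiteCall,
                  guard_motifs: Sequence[MotifModel],
                  seed: int, max_tries: int = 50,
                  p_threshold: float = 1e-4) -> str:
    """Permute the bases of a called site without creating new motif hits.

    The site's base multiset is preserved; candidate permutations are
    rejected (and redrawn, up to ``max_tries``) if re-scanning the windows
    overlapping the site reveals a guard-motif hit (p < threshold) absent
    from the wild type.  Deterministic given ``seed``.
    """
    if not 0 <= site.start < site.end <= len(seq):
        raise ValueError("site outside sequence")
    rng = np.random.default_rng(seed)
    baseline = _guard_hits(seq, site.start, site.end, guard_motifs,
                           p_threshold)
    chars = np.frombuffer(seq[site.start:site.end].encode(), dtype=np.uint8)
    for _ in range(max_tries):
        perm = chars[rng.permutation(len(chars))]
        mutant = seq[:site.start] + perm.tobytes().decode() + seq[site.end:]
        new = _guard_hits(mutant, site.start, site.end, guard_motifs,
                          p_threshold) - baseline
        if not new:
            return mutant
    introduced = sorted({m for m, _, _ in new})
    raise RuntimeError(
        f"scrambling kept introducing guard-motif hit(s) {introduced} after "
        f"{max_tries} tries; the site may be an irreducible motif")


def _normalized_score(model, seqs: Sequence[str]) -> np.ndarray:
    if isinstance(model, _gkm.TrainedGkmModel):
        return _gkm.normalize_scores(model, _gkm.score(model, seqs))
    if isinstance(model, _cnn.TrainedCnn):
        return _cnn.predict(model, seqs)
    if callable(model):
        return np.asarray(model(seqs), dtype=float)
    raise TypeError(f"cannot score with model of type {type(model)}")


def score_mutants(models: Mapping[str, object], wildtype: str,
                  mutants: Mapping[str, str]) -> pd.DataFrame:
    """Normalized scores of wild type and mutants across models.

    One row per model plus a cross-model ``mean`` row; columns are
    ``wildtype``, each mutant, and a ``delta_<mutant>`` column (mutant
    minus wild type).
    """
    names = list(mutants)
    rows = {}
    for model_name, model in models.items():
        scores = _normalized_score(model, [wildtype] + [mutants[n]
                                                        for n in names])
        row = {"wildtype": scores[0]}
        for j, n in enumerate(names, start=1):
            row[n] = scores[j]
            row[f"delta_{n}"] = scores[j] - scores[0]
        rows[model_name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["mean"] = table.mean(axis=0)
    return table


# ---------------------------------------------------------------------------
# I/O: minimal MEME motifs, importance tracks
# ---------------------------------------------------------------------------

def read_meme_motifs(path: str | Path) -> list[MotifModel]:
    """Read PWMs from a minimal MEME motif file."""
    from Bio import motifs as bio_motifs
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in "ACGT"], dtype=float)
        probs = counts / counts.sum(axis=0, keepdims=True)
        bg = rec.background or {b: 0.25 for b in "ACGT"}
        out.append(MotifModel(rec.name, probs,
                              np.array([bg[b] for b in "ACGT"])))
    return out


def write_meme_motifs(motifs: Sequence[MotifModel],
                      path: str | Path) -> None:
    """Write PWMs in the minimal MEME motif text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(bg))
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= 1000000 E= 0\n")
            for j in range(m.width):
                fh.write(" %.6f %.6f %.6f %.6f\n" % tuple(m.probs[:, j]))
            fh.write("\n")


def write_importance_tsv(track: ImportanceTrack, path: str | Path) -> None:
    """Importance track as TSV: position, base, actual, hyp_*, normalized."""
    data = dict(
        position=np.arange(len(track.sequence)),
        base=list(track.sequence),
        actual=track.actual)
    for b, row in zip("ACGT", track.hypothetical):
        data[f"hyp_{b}"] = row
    if track.normalized is not None:
        data["normalized"] = track.normalized
    pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")
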