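"""Ensemble candidate selection, ranking and probe-validation statistics.

Candidate enhancers are ranked by agreement across independent evidence:
(i) the candidate must be a positive-class differential region in *every*
pairwise comparison (consensus filter, regions matched at >= 1 bp overlap),
(ii) it must score positive in every SVM (and above 0.5 in any CNN
included), and (iii) surviving candidates are ranked by the percentile of
their SD-normalized score within each model (mean-rank ties).

The validation statistics mirror how a new sorted population is judged
against a gold standard: correlation of per-region log2 fold differences,
and hypergeometric enrichment of its enriched regions among cluster-marker
regions (markers = regions enriched in exactly one cluster), with an
explicit Bonferroni multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cnn as _cnn
from . import gkm as _gkm
from .metrics import correlate_scores
from .regions import GenomicInterval, IntervalIndex, PreparedExample

__all__ = [
    "EnrichmentResult",
    "consensus_candidates",
    "all_positive_filter",
    "percentile_rank",
    "build_candidate_table",
    "define_markers",
    "overlap_enrichment",
    "gold_standard_correlation",
]


# ---------------------------------------------------------------------------
# Ensemble filters and ranking
# ---------------------------------------------------------------------------

def consensus_candidates(window_sets: Mapping[str, Sequence[GenomicInterval]],
                         reference: str | None = None,
                         ) -> list[GenomicInterval]:
    """Reference-comparison windows differential in every other comparison.

    A window counts as differential in a comparison when it overlaps (>= 1
    bp) at least one of that comparison's positive-class regions.
    """
    if not window_sets:
        raise ValueError("no comparisons supplied")
    names = list(window_sets)
    if reference is None:
        reference = names[0]
    if reference not in window_sets:
        raise ValueError(f"reference comparison {reference!r} not present")
    others = [IntervalIndex(window_sets[name])
              for name in names if name != reference]
    return [w for w in window_sets[reference]
            if all(ix.overlaps(w.chrom, w.start, w.end) for ix in others)]


def percentile_rank(values: Sequence[float]) -> np.ndarray:
    """Percentiles in [0, 100]: 100 * mean-rank / n (ties get mean rank)."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("need at least one value")
    return 100.0 * stats.rankdata(values, method="average") / len(values)


def _is_cnn(model) -> bool:
    return isinstance(model, _cnn.TrainedCnn)


def _raw_scores(model, seqs: Sequence[str]) -> np.ndarray:
    if _is_cnn(model):
        return _cnn.predict(model, seqs)
    if isinstance(model, _gkm.TrainedGkmModel):
        return _gkm.score(model, seqs)
    if callable(model):  # custom scorer: list of sequences -> scores
        return np.asarray(model(seqs), dtype=float)
    raise TypeError(f"cannot score with model of type {type(model)}")


def _normalized(model, raw: np.ndarray) -> np.ndarray:
    if isinstance(model, _gkm.TrainedGkmModel):
        return _gkm.normalize_scores(model, raw)
    return raw  # CNN probabilities / custom scorers: already comparable


def _positive(model, raw: np.ndarray) -> np.ndarray:
    threshold = 0.5 if _is_cnn(model) else 0.0
    return raw > threshold


def all_positive_filter(score_table: pd.DataFrame,
                        model_names: Sequence[str],
                        cnn_models: Sequence[str] = (),
                        ) -> pd.Series:
    """all_positive flag from the ``raw_<model>`` columns of a score table.

    SVM scores must be strictly positive; CNN probabilities above 0.5.
    Raises if any model's score column is missing or contains NaN.
    """
    flags = pd.Series(True, index=score_table.index)
    for name in model_names:
        col = f"raw_{name}"
        if col not in score_table:
            raise ValueError(f"missing score column {col}")
        raw = score_table[col]
        if raw.isna().any():
            raise ValueError(f"missing scores (NaN) in {col}")
        threshold = 0.5 if name in cnn_models else 0.0
        flags &= raw > threshold
    return flags


def build_candidate_table(candidates: Sequence[PreparedExample],
                          models: Mapping[str, object],
                          consensus_sets: Mapping[
                              str, Sequence[GenomicInterval]] | None = None,
                          ) -> pd.DataFrame:
    """Score candidates with every model and apply the ensemble filters.

    Returns one row per candidate with raw and normalized scores per model,
    the consensus and all-positive flags, and — over the all-positive
    subset only — per-model percentile ranks of the normalized scores.
    """
    seqs = [ex.sequence for ex in candidates]
    table = pd.DataFrame(dict(
        example_id=[ex.example_id for ex in candidates],
        chrom=[ex.window.chrom for ex in candidates],
        start=[ex.window.start for ex in candidates],
        end=[ex.window.end for ex in candidates]))
    cnn_names = [n for n, m in models.items() if _is_cnn(m)]
    positive = np.ones(len(candidates), dtype=bool)
    for name, model in models.items():
        raw = _raw_scores(model, seqs)
        table[f"raw_{name}"] = raw
        table[f"norm_{name}"] = _normalized(model, raw)
        positive &= _positive(model, raw)
    if consensus_sets is not None:
        others = [IntervalIndex(v) for v in consensus_sets.values()]
        table["consensus"] = [
            all(ix.overlaps(ex.window.chrom, ex.window.start, ex.window.end)
                for ix in others) for ex in candidates]
    else:
        table["consensus"] = True
    table["all_positive"] = all_positive_filter(
        table, list(models), cnn_names) & table["consensus"]
    mask = table["all_positive"].to_numpy()
    for name in models:
        col = np.full(len(table), np.nan)
        if mask.any():
            col[mask] = percentile_rank(table.loc[mask, f"norm_{name}"])
        table[f"pct_{name}"] = col
    return table


# ---------------------------------------------------------------------------
# Marker definition and overlap enrichment
# ---------------------------------------------------------------------------

def define_markers(enriched_sets: Mapping[str, Sequence[GenomicInterval]],
                   ) -> dict[str, list[GenomicInterval]]:
    """Cluster markers: enriched regions overlapping no other cluster's set.

    Overlap is >= 1 bp; with fewer than two clusters there is nothing to
    subtract and the enriched sets are returned unchanged.
    """
    markers: dict[str, list[GenomicInterval]] = {}
    for cluster, regions in enriched_sets.items():
        others = [iv for other, regs in enriched_sets.items()
                  if other != cluster for iv in regs]
        index = IntervalIndex(others)
        markers[cluster] = [
            r for r in regions
            if not index.overlaps(r.chrom, r.start, r.end)]
    return markers


@dataclass
class EnrichmentResult:
    query_label: str
    marker_label: str
    k: int                  # query regions overlapping a marker
    n: int                  # query-set size
    K: int                  # marker-set size
    N: int                  # universe size
    overlap_fraction: float
    p: float                # hypergeometric upper tail, P(X >= k)
    p_adj: float            # Bonferroni, min(1, m * p)


def overlap_enrichment(query: Sequence[GenomicInterval],
                       markers: Sequence[GenomicInterval],
                       universe_size: int,
                       n_tests: int = 1,
                       query_label: str = "query",
                       marker_label: str = "markers") -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of marker overlap in a query set.

    k = number of query regions with >= 1 bp marker overlap;
    p = P(X >= k) for X ~ Hypergeometric(N=universe, K=|markers|, n=|query|).
    """
    n, K = len(query), len(markers)
    if universe_size < max(n, K):
        raise ValueError("universe smaller than query or marker set")
    index = IntervalIndex(markers)
    k = sum(index.overlaps(q.chrom, q.start, q.end) for q in query)
    if k > min(n, K):
        raise RuntimeError("internal inconsistency: k exceeds min(n, K)")
    p = float(stats.hypergeom.sf(k - 1, universe_size, K, n))
    return EnrichmentResult(
        query_label=query_label, marker_label=marker_label,
        k=k, n=n, K=K, N=universe_size,
        overlap_fraction=k / n if n else 0.0,
        p=p, p_adj=min(1.0, n_tests * p))


def gold_standard_correlation(lfc_query: Mapping[str, float],
                              lfc_gold: Mapping[str, float],
                              ) -> tuple[float, float, int]:
    """(Pearson, Spearman, n_shared) of per-region log2 fold differences.

    Regions present in only one of the two tables are dropped (and counted
    via the returned n); fewer than 3 shared regions is an error.
    """
    shared = [r for r in lfc_query if r in lfc_gold]
    n_dropped = (len(lfc_query) - len(shared)) + (len(lfc_gold) - len(shared))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared regions")
    x = [lfc_query[r] for r in shared]
    y = [lfc_gold[r] for r in shared]
    pearson, spearman = correlate_scores(x, y)
    if n_dropped:
        import logging
        logging.getLogger(__name__).info(
            "gold_standard_correlation: dropped %d unshared region(s)",
            n_dropped)
    return pearson, spearman, len(shared)
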