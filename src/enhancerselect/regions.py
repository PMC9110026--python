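"""From differential-accessibility tables to labelled, split sequence sets.

The SVM path turns differential open-chromatin regions (OCRs) into 500 bp
summit-centred sequences: rows passing the strict thresholds
(padj < 0.01, |log2FoldDifference| > 1) are selected per class, windows are
centred on peak summits (retaining summits > 100 bp apart within a record),
TSS-proximal windows (within 2 kb) and windows with any super-enhancer
overlap are removed, and sequences containing uncertain bases are dropped.
The CNN path labels 200 bp genome bins by the sign of their fold difference,
removes blacklist-overlapping or N-containing bins and extracts the 1000 bp
sequence around each bin centre.  Examples are assigned to train /
validation / test partitions purely by chromosome.

All coordinates are 0-based half-open (BED convention); narrowPeak summit
offsets are converted to absolute positions as ``start + offset``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqs import has_n

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "DifferentialRecord",
    "PreparedExample",
    "SplitScheme",
    "SPLIT_SCHEMES",
    "IntervalIndex",
    "read_differential_table",
    "read_narrowpeak",
    "read_bed_intervals",
    "read_tss_positions",
    "genome_lengths",
    "select_differential",
    "summit_windows",
    "filter_near_tss",
    "filter_super_enhancers",
    "extract_sequences",
    "assign_splits",
    "prepare_svm_examples",
    "bins_from_summits",
    "bin_windows_for_cnn",
    "write_examples_fasta",
    "read_examples_fasta",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom and
                self.start < other.end and other.start < self.end)


@dataclass
class DifferentialRecord:
    interval: GenomicInterval
    log2fd: float
    padj: float
    summits: list[int]

    def __post_init__(self) -> None:
        if not np.isfinite(self.padj):
            raise ValueError("padj must be finite")
        width = len(self.interval)
        for s in self.summits:
            if not 0 <= s < width:
                raise ValueError(
                    f"summit offset {s} outside interval of width {width}")


@dataclass
class PreparedExample:
    example_id: str
    window: GenomicInterval
    sequence: str
    label: str                      # "positive" | "negative"
    split: str = ""                 # "train" | "validation" | "test"
    source_comparison: str = ""


@dataclass(frozen=True)
class SplitScheme:
    """Chromosome-held-out partition into train / validation / test."""
    name: str
    train_chroms: frozenset[str]
    val_chroms: frozenset[str]
    test_chroms: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.train_chroms, self.val_chroms, self.test_chroms]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("split chromosome sets must be disjoint")

    def split_of(self, chrom: str) -> str | None:
        if chrom in self.train_chroms:
            return "train"
        if chrom in self.val_chroms:
            return "validation"
        if chrom in self.test_chroms:
            return "test"
        return None


def _chroms(*nums: int | str) -> frozenset[str]:
    return frozenset(f"chr{n}" for n in nums)


SPLIT_SCHEMES: dict[str, SplitScheme] = {
    # SVM: train chr3-7, 10-19 and X; validate chr8-9; test chr1-2.
    "svm_mouse": SplitScheme(
        "svm_mouse",
        _chroms(*range(3, 8), *range(10, 20), "X"),
        _chroms(8, 9), _chroms(1, 2)),
    "svm_human": SplitScheme(
        "svm_human",
        _chroms(*range(3, 8), *range(10, 23), "X"),
        _chroms(8, 9), _chroms(1, 2)),
    # CNN: validate chr4, test chr8-9, train everything else.
    "cnn_mouse": SplitScheme(
        "cnn_mouse",
        _chroms(1, 2, 3, *range(5, 8), *range(10, 20), "X"),
        _chroms(4), _chroms(8, 9)),
}


# ---------------------------------------------------------------------------
# Interval / point indexes
# ---------------------------------------------------------------------------

class IntervalIndex:
    """Per-chromosome interval store with >=1 bp overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval |
                                           tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                chrom, start, end = iv.chrom, iv.start, iv.end
            else:
                chrom, start, end = iv
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            arr = np.array(pairs)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._starts:
            return False
        return bool(np.any((self._starts[chrom] < end) &
                           (self._ends[chrom] > start)))


class PointIndex:
    """Per-chromosome sorted point store with nearest-distance queries."""

    def __init__(self, points: Iterable[tuple[str, int]]):
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in points:
            by_chrom.setdefault(chrom, []).append(pos)
        self._pos = {c: np.array(sorted(p)) for c, p in by_chrom.items()}

    def min_edge_distance(self, chrom: str, start: int, end: int) -> float:
        """Distance from an interval's closest edge to the nearest point.

        Points inside [start, end) are at distance 0; outside, the distance
        is ``start - pos`` (left) or ``pos - end`` (right).
        """
        pos = self._pos.get(chrom)
        if pos is None or len(pos) == 0:
            return np.inf
        i = int(np.searchsorted(pos, start))
        best = np.inf
        for j in (i - 1, i, int(np.searchsorted(pos, end))):
            if 0 <= j < len(pos):
                p = pos[j]
                if start <= p < end:
                    return 0.0
                best = min(best, start - p if p < start else p - end)
        return float(max(best, 0.0))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_differential_table(path: str | Path) -> list[DifferentialRecord]:
    """Read a differential-accessibility TSV.

    Expected columns: chrom, start, end, log2FoldDifference, padj, summits
    (comma-joined offsets within the interval).
    """
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        summits = [int(s) for s in str(row.summits).split(",") if s != ""]
        records.append(DifferentialRecord(
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            log2fd=float(row.log2FoldDifference),
            padj=float(row.padj),
            summits=summits))
    return records


def read_narrowpeak(path: str | Path) -> list[DifferentialRecord]:
    """Read narrowPeak (BED6+4); the 10th column is the summit offset."""
    df = pd.read_csv(path, sep="\t", header=None)
    records = []
    for row in df.itertuples(index=False):
        records.append(DifferentialRecord(
            interval=GenomicInterval(row[0], int(row[1]), int(row[2])),
            log2fd=0.0, padj=1.0, summits=[int(row[9])]))
    return records


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            out.append(GenomicInterval(fields[0], int(fields[1]),
                                       int(fields[2])))
    return out


def read_tss_positions(path: str | Path) -> list[tuple[str, int]]:
    """TSS as points: the start coordinate of each BED interval."""
    return [(iv.chrom, iv.start) for iv in read_bed_intervals(path)]


def genome_lengths(genome: Mapping[str, object]) -> dict[str, int]:
    return {chrom: len(genome[chrom]) for chrom in genome.keys()}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def select_differential(records: Sequence[DifferentialRecord],
                        padj_max: float = 0.01,
                        min_abs_lfc: float = 1.0,
                        direction: str = "positive_class",
                        ) -> list[DifferentialRecord]:
    """Strict differential filter: padj < padj_max and signed lfc beyond
    min_abs_lfc (both inequalities strict).  Order is preserved."""
    if not (np.isfinite(padj_max) and np.isfinite(min_abs_lfc)):
        raise ValueError("thresholds must be finite")
    if not 0 < padj_max <= 1:
        raise ValueError("padj_max must lie in (0, 1]")
    if direction not in ("positive_class", "negative_class"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "positive_class" else -1.0
    return [r for r in records
            if r.padj < padj_max and sign * r.log2fd > min_abs_lfc]


def summit_windows(records: Sequence[DifferentialRecord],
                   genome_lengths: Mapping[str, int],
                   window_len: int = 500,
                   min_summit_spacing: int = 100,
                   ) -> list[GenomicInterval]:
    """Fixed-length windows centred on retained peak summits.

    Within one record summits are retained greedily in input order, skipping
    any summit closer than ``min_summit_spacing`` bp to an already-retained
    summit of the same record.  Windows running past a chromosome end are
    dropped (shifting would break summit-centring).  Duplicate windows are
    deduplicated keeping the first.
    """
    if window_len % 2:
        raise ValueError("window_len must be even")
    half = window_len // 2
    windows: list[GenomicInterval] = []
    seen: set[tuple[str, int]] = set()
    n_dropped = 0
    for rec in records:
        if not rec.summits:
            logger.warning("record %s has no summits; dropped", rec.interval)
            continue
        retained: list[int] = []
        for offset in rec.summits:
            if all(abs(offset - r) >= min_summit_spacing for r in retained):
                retained.append(offset)
        for offset in retained:
            p = rec.interval.start + offset
            start, end = p - half, p + half
            chrom = rec.interval.chrom
            if start < 0 or end > genome_lengths.get(chrom, np.inf):
                n_dropped += 1
                continue
            key = (chrom, start)
            if key in seen:
                continue
            seen.add(key)
            windows.append(GenomicInterval(chrom, start, end))
    if n_dropped:
        logger.info("summit_windows: dropped %d window(s) extending past a "
                    "chromosome end", n_dropped)
    return windows


def filter_near_tss(windows: Sequence[GenomicInterval],
                    tss: Iterable[tuple[str, int]] | PointIndex,
                    distance: int = 2000) -> list[GenomicInterval]:
    """Drop windows whose closest edge is within ``distance`` bp of a TSS."""
    index = tss if isinstance(tss, PointIndex) else PointIndex(tss)
    return [w for w in windows
            if index.min_edge_distance(w.chrom, w.start, w.end) > distance]


def filter_super_enhancers(windows: Sequence[GenomicInterval],
                           se_intervals: Iterable | IntervalIndex,
                           ) -> list[GenomicInterval]:
    """Drop windows with >= 1 bp overlap of any super-enhancer interval."""
    index = (se_intervals if isinstance(se_intervals, IntervalIndex)
             else IntervalIndex(se_intervals))
    return [w for w in windows if not index.overlaps(w.chrom, w.start, w.end)]


def extract_sequences(windows: Sequence[GenomicInterval],
                      genome: Mapping[str, object],
                      drop_n: bool = True,
                      ) -> list[tuple[GenomicInterval, str]]:
    """Uppercased sequences for each window; N-containing dropped if asked.

    ``genome`` may be a plain chrom -> string mapping or a pyfaidx Fasta.
    """
    out: list[tuple[GenomicInterval, str]] = []
    n_dropped = 0
    for w in windows:
        chrom_len = len(genome[w.chrom])
        if w.end > chrom_len:
            raise ValueError(
                f"window {w.chrom}:{w.start}-{w.end} beyond chromosome end "
                f"({chrom_len}); clip windows first")
        seq = str(genome[w.chrom][w.start:w.end]).upper()
        if drop_n and has_n(seq):
            n_dropped += 1
            continue
        out.append((w, seq))
    if n_dropped:
        logger.info("extract_sequences: dropped %d sequence(s) containing N",
                    n_dropped)
    return out


def assign_splits(examples: Sequence[PreparedExample],
                  scheme: SplitScheme) -> list[PreparedExample]:
    """Set each example's split from its chromosome under ``scheme``."""
    missing = sorted({ex.window.chrom for ex in examples
                      if scheme.split_of(ex.window.chrom) is None})
    if missing:
        raise ValueError(
            f"chromosome(s) not assigned to any split under scheme "
            f"{scheme.name!r}: {missing}")
    return [replace(ex, split=scheme.split_of(ex.window.chrom))
            for ex in examples]


@dataclass
class PrepLog:
    """Bookkeeping for one preparation run (counts removed per filter)."""
    n_input: int = 0
    n_selected_pos: int = 0
    n_selected_neg: int = 0
    n_windows: int = 0
    n_removed_tss: int = 0
    n_removed_se: int = 0
    n_removed_n: int = 0
    n_final: int = 0
    counts: dict = field(default_factory=dict)


def prepare_svm_examples(records: Sequence[DifferentialRecord],
                         genome: Mapping[str, object],
                         tss: Iterable[tuple[str, int]],
                         super_enhancers: Iterable,
                         scheme: SplitScheme,
                         comparison: str = "",
                         window_len: int = 500,
                         tss_distance: int = 2000,
                         min_summit_spacing: int = 100,
                         padj_max: float = 0.01,
                         min_abs_lfc: float = 1.0,
                         ) -> tuple[list[PreparedExample], PrepLog]:
    """Full SVM preparation pipeline for one differential table."""
    log = PrepLog(n_input=len(records))
    lengths = genome_lengths(genome)
    tss_index = PointIndex(tss)
    se_index = IntervalIndex(super_enhancers)
    examples: list[PreparedExample] = []
    for direction, label in (("positive_class", "positive"),
                             ("negative_class", "negative")):
        selected = select_differential(records, padj_max, min_abs_lfc,
                                       direction)
        if label == "positive":
            log.n_selected_pos = len(selected)
        else:
            log.n_selected_neg = len(selected)
        windows = summit_windows(selected, lengths, window_len,
                                 min_summit_spacing)
        log.n_windows += len(windows)
        kept = filter_near_tss(windows, tss_index, tss_distance)
        log.n_removed_tss += len(windows) - len(kept)
        windows = kept
        kept = filter_super_enhancers(windows, se_index)
        log.n_removed_se += len(windows) - len(kept)
        windows = kept
        pairs = extract_sequences(windows, genome, drop_n=True)
        log.n_removed_n += len(windows) - len(pairs)
        for w, seq in pairs:
            examples.append(PreparedExample(
                example_id=f"{w.chrom}:{w.start}-{w.end}",
                window=w, sequence=seq, label=label,
                source_comparison=comparison))
    examples = assign_splits(examples, scheme)
    log.n_final = len(examples)
    return examples, log


# ---------------------------------------------------------------------------
# CNN path
# ---------------------------------------------------------------------------

def bins_from_summits(records: Sequence[DifferentialRecord],
                      bin_len: int = 200) -> list[DifferentialRecord]:
    """Turn peak-level differential records into summit-centred fixed bins.

    Convenience for running the bin-based CNN path on peak-level tables:
    each record contributes one ``bin_len`` bin centred on its first summit,
    keeping the record's statistics.
    """
    half = bin_len // 2
    out = []
    for rec in records:
        if not rec.summits:
            continue
        p = rec.interval.start + rec.summits[0]
        out.append(DifferentialRecord(
            interval=GenomicInterval(rec.interval.chrom, p - half, p + half),
            log2fd=rec.log2fd, padj=rec.padj, summits=[half]))
    return out


def bin_windows_for_cnn(differential_bins: Sequence[DifferentialRecord],
                        blacklist: Iterable | IntervalIndex,
                        genome: Mapping[str, object],
                        window_len: int = 1000,
                        bin_len: int = 200) -> list[PreparedExample]:
    """1000 bp windows around 200 bp differential bins, blacklist-filtered.

    Labels come from the sign of log2FoldDifference (> 0 positive).
    """
    index = (blacklist if isinstance(blacklist, IntervalIndex)
             else IntervalIndex(blacklist))
    lengths = genome_lengths(genome)
    half = window_len // 2
    out: list[PreparedExample] = []
    n_bl = n_n = n_edge = 0
    for rec in differential_bins:
        iv = rec.interval
        if len(iv) != bin_len:
            raise ValueError(
                f"bin {iv.chrom}:{iv.start}-{iv.end} is not {bin_len} bp wide")
        if index.overlaps(iv.chrom, iv.start, iv.end):
            n_bl += 1
            continue
        center = iv.start + bin_len // 2
        start, end = center - half, center + half
        if start < 0 or end > lengths[iv.chrom]:
            n_edge += 1
            continue
        seq = str(genome[iv.chrom][start:end]).upper()
        if has_n(seq):
            n_n += 1
            continue
        out.append(PreparedExample(
            example_id=f"{iv.chrom}:{iv.start}-{iv.end}",
            window=GenomicInterval(iv.chrom, start, end),
            sequence=seq,
            label="positive" if rec.log2fd > 0 else "negative"))
    if n_bl or n_n or n_edge:
        logger.info("bin_windows_for_cnn: removed %d blacklist, %d N, "
                    "%d edge bin(s)", n_bl, n_n, n_edge)
    return out


# ---------------------------------------------------------------------------
# Prepared-dataset I/O
# ---------------------------------------------------------------------------

def write_examples_fasta(examples: Sequence[PreparedExample],
                         fasta_path: str | Path,
                         sidecar_tsv: str | Path | None = None) -> None:
    """FASTA with structured headers ``id|chrom:start-end|label|split``."""
    with open(fasta_path, "w") as fh:
        for ex in examples:
            w = ex.window
            fh.write(f">{ex.example_id}|{w.chrom}:{w.start}-{w.end}|"
                     f"{ex.label}|{ex.split}\n{ex.sequence}\n")
    if sidecar_tsv is not None:
        rows = [dict(example_id=ex.example_id, chrom=ex.window.chrom,
                     start=ex.window.start, end=ex.window.end,
                     label=ex.label, split=ex.split,
                     source_comparison=ex.source_comparison)
                for ex in examples]
        pd.DataFrame(rows).to_csv(sidecar_tsv, sep="\t", index=False)


def read_examples_fasta(fasta_path: str | Path) -> list[PreparedExample]:
    examples: list[PreparedExample] = []
    header: str | None = None
    chunks: list[str] = []

    def _finish() -> None:
        if header is None:
            return
        example_id, loc, label, split = header.split("|")
        chrom, span = loc.rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
        examples.append(PreparedExample(
            example_id=example_id,
            window=GenomicInterval(chrom, start, end),
            sequence="".join(chunks), label=label, split=split))

    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                _finish()
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    _finish()
    return examples
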