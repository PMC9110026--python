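"""Synthetic fixture bundles for the enhancer-prioritization pipeline.

Real training data for cell type-specific enhancer models comes from
differential chromatin-accessibility analysis between two sorted (or
clustered) cell populations.  This module emulates the *statistical shape*
of those inputs so that every downstream stage — summit-centred window
extraction, filtering, gapped k-mer SVM and CNN training, ensemble ranking
and nucleotide-level interpretation — can be exercised end to end without
any external accession:

* a random i.i.d. genome at a configurable GC fraction,
* peak regions with summits, laid out on well-separated loci,
* differential tables (log2FoldDifference, padj, summit offsets) whose
  positive class carries planted PWM motif instances near the summit,
* distractor regions designed to be removed by exactly one preparation
  filter each (TSS proximity, super-enhancer overlap, uncertain bases,
  blacklist overlap for the CNN path), plus non-significant filler rows,
* a truth table of every planted motif site, and a region roster.

Everything is deterministic given the configuration seed; re-running with
the same configuration reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .seqs import BASE_ARRAY, decode, encode, revcomp

__all__ = [
    "ConfigurationError",
    "FixtureError",
    "MotifModel",
    "SimulationConfig",
    "SimRegion",
    "RegionSets",
    "FixtureBundle",
    "default_target_motifs",
    "default_decoy_motifs",
    "demo_config",
    "interpretation_config",
    "generate_genome",
    "generate_region_sets",
    "emit_fixture",
    "simulate_bundle",
    "load_manifest",
]


class ConfigurationError(ValueError):
    """A simulation configuration that cannot be honoured."""


class FixtureError(RuntimeError):
    """Generation failed (e.g. not enough genome to place all regions)."""


# ---------------------------------------------------------------------------
# Motif model
# ---------------------------------------------------------------------------

@dataclass
class MotifModel:
    """A position weight matrix over A,C,G,T with a background distribution.

    ``probs`` has shape (4, w): rows are A, C, G, T, columns are motif
    positions.  Every column sums to one.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ConfigurationError("probs must have shape (4, w)")
        if self.width < 4:
            raise ConfigurationError("motif width must be >= 4")
        if (self.probs < 0).any():
            raise ConfigurationError("probs must be non-negative")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ConfigurationError("every PWM column must sum to 1")
        if self.background.shape != (4,) or not np.isclose(
                self.background.sum(), 1.0, atol=1e-9):
            raise ConfigurationError("background must be a 4-vector summing to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return decode(self.probs.argmax(axis=0))

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str,
                       p_consensus: float = 0.9,
                       background: np.ndarray | None = None) -> "MotifModel":
        """A PWM putting ``p_consensus`` on the consensus base per column."""
        codes = encode(consensus)
        probs = np.full((4, len(codes)), (1 - p_consensus) / 3)
        probs[codes, np.arange(len(codes))] = p_consensus
        bg = np.full(4, 0.25) if background is None else background
        return cls(motif_id, probs, bg)

    def sample(self, rng: np.random.Generator) -> str:
        cols = [rng.choice(4, p=self.probs[:, j]) for j in range(self.width)]
        return decode(np.array(cols))

    def log_odds(self, pseudocount: float = 1e-3) -> np.ndarray:
        """Per-position log2 odds, ``log2((p + eps) / background)``."""
        if (self.background <= 0).any():
            raise ConfigurationError("background frequencies must be positive")
        return np.log2((self.probs + pseudocount) / self.background[:, None])

    def score(self, seq: str, pseudocount: float = 1e-3) -> float:
        codes = encode(seq)
        if len(codes) != self.width:
            raise ValueError("sequence length must equal motif width")
        lo = self.log_odds(pseudocount)
        return float(lo[codes, np.arange(self.width)].sum())

    def self_score_quantile(self, q: float = 0.5,
                            pseudocount: float = 1e-3) -> float:
        """Quantile of the log-odds score of sequences drawn from the PWM.

        Exact (full enumeration over 4**w outcomes); intended for w <= 8.
        """
        if self.width > 8:
            raise ValueError("exact enumeration supported for width <= 8 only")
        lo = self.log_odds(pseudocount)
        scores = np.zeros(1)
        probs = np.ones(1)
        for j in range(self.width):
            scores = (scores[:, None] + lo[:, j][None, :]).ravel()
            probs = (probs[:, None] * self.probs[:, j][None, :]).ravel()
        order = np.argsort(scores)
        cum = np.cumsum(probs[order])
        idx = int(np.searchsorted(cum, q))
        return float(scores[order][min(idx, len(scores) - 1)])


def default_target_motifs() -> list[MotifModel]:
    """Planted positive-class motifs (nuclear-receptor / MADS-box flavoured)."""
    return [
        MotifModel.from_consensus("errlike", "TGACCTTG", 0.97),
        MotifModel.from_consensus("madslike", "CTATTTAT", 0.97),
        MotifModel.from_consensus("homeolike", "CCATTAGC", 0.97),
    ]


def default_decoy_motifs() -> list[MotifModel]:
    """Motifs planted in the negative class (E-box flavoured)."""
    return [MotifModel.from_consensus("eboxlike", "GACAGCTG", 0.97)]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _mouse_like_chroms(length: int) -> dict[str, int]:
    names = [f"chr{i}" for i in range(1, 20)] + ["chrX"]
    return {name: length for name in names}


@dataclass
class SimulationConfig:
    """Everything that determines a fixture bundle.

    The class-imbalance fields default to a 1:1.5 positive:negative ratio,
    inside the 1:0.4-1:3.7 range seen across real sorted-population and
    single-nucleus training sets.  Positive-class effect sizes are drawn
    from a Normal truncated to log2FoldDifference > 1 with padj log-uniform
    below ``padj_scale``, so every positive passes the strict differential
    thresholds (padj < 0.01, |log2FoldDifference| > 1).
    """

    seed: int = 7
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: _mouse_like_chroms(700_000))
    n_pos: int = 800
    n_neg: int = 1200
    pos_neg_ratio_target: float | None = None
    plant_prob_pos: float = 0.9
    plant_prob_neg: float = 0.3
    plants_per_pos: int = 2
    target_motifs: list[MotifModel] = field(default_factory=default_target_motifs)
    decoy_motifs: list[MotifModel] = field(default_factory=default_decoy_motifs)
    background_gc: float = 0.45
    lfc_pos_mean: float = 2.5
    lfc_pos_sd: float = 0.8
    padj_scale: float = 1e-3
    n_tss_distractors: int = 30
    n_se_distractors: int = 30
    n_n_distractors: int = 30
    n_blacklist_distractors: int = 20
    n_null: int = 50
    n_decoy_tss: int = 5
    n_comparisons: int = 3
    consensus_frac: float = 0.8
    region_len: int = 500
    summit_jitter: int = 50
    plant_halfwidth: int = 100
    slot_pitch: int = 6000
    edge_margin: int = 2000

    def __post_init__(self) -> None:
        if not 0.0 < self.background_gc < 1.0:
            raise ConfigurationError("background_gc must lie in (0, 1)")
        for name in ("plant_prob_pos", "plant_prob_neg", "consensus_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not self.chrom_lengths:
            raise ConfigurationError("chrom_lengths must be nonempty")
        if min(self.chrom_lengths.values()) < 10_000:
            raise ConfigurationError("chromosome lengths must be >= 10,000 bp")
        if self.n_comparisons < 1:
            raise ConfigurationError("need at least one comparison")
        if self.pos_neg_ratio_target is None and self.n_pos:
            self.pos_neg_ratio_target = self.n_neg / self.n_pos
        width = max(
            (m.width for m in self.target_motifs + self.decoy_motifs), default=0)
        if width >= self.region_len:
            raise ConfigurationError("motif wider than region")

    @property
    def comparisons(self) -> list[str]:
        names = ["vs_rest", "vs_subtype_a", "vs_subtype_b", "vs_subtype_c"]
        if self.n_comparisons <= len(names):
            return names[: self.n_comparisons]
        return names + [f"vs_extra_{i}" for i in
                        range(self.n_comparisons - len(names))]


def demo_config(seed: int = 7) -> SimulationConfig:
    """The default demonstration fixture (n = 2000 labelled regions)."""
    return SimulationConfig(seed=seed)


def interpretation_config(seed: int = 7) -> SimulationConfig:
    """Fixture for nucleotide-level interpretation.

    Every positive carries three independent target-motif instances
    (plant_prob_pos = 1), so that per-base importance concentrated on the
    planted sites is measurable against a top-5% importance set of 25 bases
    in a 500 bp window.
    """
    return SimulationConfig(
        seed=seed,
        chrom_lengths=_mouse_like_chroms(420_000),
        n_pos=600,
        n_neg=600,
        plant_prob_pos=1.0,
        plant_prob_neg=0.3,
        plants_per_pos=3,
        n_tss_distractors=5,
        n_se_distractors=5,
        n_n_distractors=5,
        n_blacklist_distractors=5,
        n_null=20,
        n_comparisons=2,
        consensus_frac=1.0,
    )


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Random i.i.d. genome; chrom -> uint8 array of ASCII base codes."""
    rng = np.random.default_rng([config.seed, 0])
    gc = config.background_gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths.items():
        genome[chrom] = BASE_ARRAY[rng.choice(4, size=length, p=p)]
    return genome


def genome_as_strings(genome: dict[str, np.ndarray]) -> dict[str, str]:
    return {c: seq.tobytes().decode("ascii") for c, seq in genome.items()}


# ---------------------------------------------------------------------------
# Regions, differential tables, truth
# ---------------------------------------------------------------------------

ROLE_POSITIVE = "positive"
ROLE_NEGATIVE = "negative"
ROLE_TSS = "tss_distractor"
ROLE_SE = "se_distractor"
ROLE_N = "n_distractor"
ROLE_BLACKLIST = "blacklist_distractor"
ROLE_NULL = "null"


@dataclass
class SimRegion:
    region_id: str
    role: str
    chrom: str
    start: int
    end: int
    summit_offset: int
    label: str  # "positive", "negative" or "" for unlabelled roles
    consensus: bool
    planted: list[tuple[int, int, str, str]] = field(default_factory=list)
    # planted entries: (abs start, abs end, motif_id, strand)

    @property
    def summit(self) -> int:
        return self.start + self.summit_offset


@dataclass
class RegionSets:
    regions: list[SimRegion]
    differential: dict[str, list[dict]]
    tss: list[tuple[str, int]]
    super_enhancers: list[tuple[str, int, int]]
    blacklist: list[tuple[str, int, int]]
    truth: list[dict]


def _draw_positive_stats(rng: np.random.Generator,
                         config: SimulationConfig) -> tuple[float, float]:
    lfc = 0.0
    while lfc <= 1.0:
        lfc = rng.normal(config.lfc_pos_mean, config.lfc_pos_sd)
    padj = 10.0 ** rng.uniform(-30.0, np.log10(config.padj_scale))
    return float(lfc), float(padj)


def _plant(rng: np.random.Generator, genome: dict[str, np.ndarray],
           region: SimRegion, motif: MotifModel,
           halfwidth: int, max_tries: int = 200) -> None:
    """Write one motif sample near the region summit, on a uniform strand."""
    w = motif.width
    summit = region.summit
    lo = max(region.start, summit - halfwidth)
    hi = min(region.end, summit + halfwidth) - w
    if hi < lo:
        raise ConfigurationError("motif wider than the plantable window")
    for _ in range(max_tries):
        start = int(rng.integers(lo, hi + 1))
        if all(start + w <= s or start >= e
               for s, e, _, _ in region.planted):
            break
    else:
        raise FixtureError(
            f"could not place motif {motif.motif_id} in {region.region_id}")
    sample = motif.sample(rng)
    strand = "+" if rng.random() < 0.5 else "-"
    inserted = sample if strand == "+" else revcomp(sample)
    genome[region.chrom][start:start + w] = np.frombuffer(
        inserted.encode("ascii"), dtype=np.uint8)
    region.planted.append((start, start + w, motif.motif_id, strand))


def generate_region_sets(
        config: SimulationConfig,
        genome: dict[str, np.ndarray],
        target_motifs: list[MotifModel] | None = None,
        decoy_motifs: list[MotifModel] | None = None) -> RegionSets:
    """Place labelled regions and distractors; plant motifs; draw statistics.

    Mutates ``genome`` in place (motif planting and N patches).
    """
    targets = config.target_motifs if target_motifs is None else target_motifs
    decoys = config.decoy_motifs if decoy_motifs is None else decoy_motifs
    for m in targets + decoys:
        if m.width >= config.region_len:
            raise ConfigurationError(f"motif {m.motif_id} wider than region")
    rng = np.random.default_rng([config.seed, 1])

    # Candidate loci: slot centres on a coarse grid, globally shuffled so
    # every role is spread over all chromosomes.
    slots: list[tuple[str, int]] = []
    for chrom, length in config.chrom_lengths.items():
        lo = config.edge_margin + config.slot_pitch // 2
        hi = length - config.edge_margin
        slots.extend((chrom, int(c)) for c in
                     range(lo, hi, config.slot_pitch))
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]

    roles = ([ROLE_POSITIVE] * config.n_pos +
             [ROLE_NEGATIVE] * config.n_neg +
             [ROLE_TSS] * config.n_tss_distractors +
             [ROLE_SE] * config.n_se_distractors +
             [ROLE_N] * config.n_n_distractors +
             [ROLE_BLACKLIST] * config.n_blacklist_distractors +
             [ROLE_NULL] * config.n_null)
    n_needed = len(roles) + config.n_decoy_tss
    if n_needed > len(slots):
        raise FixtureError(
            f"genome too small: need {n_needed} loci, have {len(slots)}")

    half = config.region_len // 2
    regions: list[SimRegion] = []
    tss: list[tuple[str, int]] = []
    ses: list[tuple[str, int, int]] = []
    blacklist: list[tuple[str, int, int]] = []

    for i, role in enumerate(roles):
        chrom, center = slots[i]
        start, end = center - half, center + half
        summit_offset = half + int(rng.integers(-config.summit_jitter,
                                                config.summit_jitter + 1))
        label = {ROLE_POSITIVE: "positive", ROLE_NEGATIVE: "negative"}.get(
            role, "")
        region = SimRegion(
            region_id=f"region_{i:05d}", role=role, chrom=chrom,
            start=start, end=end, summit_offset=summit_offset, label=label,
            consensus=False)
        summit = region.summit
        if role in (ROLE_POSITIVE, ROLE_BLACKLIST, ROLE_TSS, ROLE_SE):
            # positive-class rows carry the target signal; TSS-proximal and
            # super-enhancer distractors are planted too (real promoter- or
            # SE-overlapping differential regions still contain the cell
            # type's motifs; their removal is positional, not compositional)
            if rng.random() < config.plant_prob_pos:
                for j in range(config.plants_per_pos):
                    motif = targets[j % len(targets)]
                    _plant(rng, genome, region, motif, config.plant_halfwidth)
            region.consensus = bool(rng.random() < config.consensus_frac)
        elif role == ROLE_NEGATIVE:
            if decoys and rng.random() < config.plant_prob_neg:
                _plant(rng, genome, region,
                       decoys[int(rng.integers(len(decoys)))],
                       config.plant_halfwidth)
        if role == ROLE_TSS:
            tss.append((chrom, end + 800))
        elif role == ROLE_SE:
            ses.append((chrom, summit - 100, summit + 100))
        elif role == ROLE_N:
            genome[chrom][summit + 20:summit + 25] = ord("N")
        elif role == ROLE_BLACKLIST:
            blacklist.append((chrom, summit - 120, summit + 120))
        regions.append(region)

    # TSS points far (> 2 kb) from every window: should remove nothing.
    for j in range(config.n_decoy_tss):
        chrom, center = slots[len(roles) + j]
        tss.append((chrom, center))

    chrom_rank = {c: i for i, c in enumerate(config.chrom_lengths)}
    regions.sort(key=lambda r: (chrom_rank[r.chrom], r.start))

    # Differential tables.  Positives/distractors get positive-class stats,
    # negatives mirrored negative stats; null rows fail a threshold each.
    comparisons = config.comparisons
    tables: dict[str, list[dict]] = {name: [] for name in comparisons}
    for region in regions:
        row_base = dict(chrom=region.chrom, start=region.start,
                        end=region.end, summits=str(region.summit_offset),
                        region_id=region.region_id)
        if region.role == ROLE_NULL:
            if rng.random() < 0.5:
                lfc = float(rng.uniform(-1.0, 1.0))
                padj = 10.0 ** rng.uniform(-6.0, -3.0)
            else:
                lfc, _ = _draw_positive_stats(rng, config)
                lfc *= 1 if rng.random() < 0.5 else -1
                padj = float(rng.uniform(0.02, 0.5))
            tables[comparisons[0]].append(
                dict(row_base, log2FoldDifference=lfc, padj=padj))
            continue
        in_cmps = [comparisons[0]]
        if region.role == ROLE_NEGATIVE:
            in_cmps = list(comparisons)
        elif region.role == ROLE_POSITIVE:
            if region.consensus or len(comparisons) == 1:
                in_cmps = list(comparisons)
            else:
                skip = comparisons[1 + int(rng.integers(len(comparisons) - 1))]
                in_cmps = [c for c in comparisons if c != skip]
        for name in in_cmps:
            lfc, padj = _draw_positive_stats(rng, config)
            if region.role == ROLE_NEGATIVE:
                lfc = -lfc
            tables[name].append(
                dict(row_base, log2FoldDifference=lfc, padj=padj))

    truth = [dict(chrom=r.chrom, start=s, end=e, motif_id=m, strand=st,
                  region_id=r.region_id)
             for r in regions for (s, e, m, st) in r.planted]
    tss.sort(key=lambda t: (chrom_rank[t[0]], t[1]))
    ses.sort(key=lambda t: (chrom_rank[t[0]], t[1]))
    blacklist.sort(key=lambda t: (chrom_rank[t[0]], t[1]))
    return RegionSets(regions=regions, differential=tables, tss=tss,
                      super_enhancers=ses, blacklist=blacklist, truth=truth)


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    genome_path: Path
    peaks_path: Path
    differential_paths: dict[str, Path]
    tss_path: Path
    super_enhancer_path: Path
    blacklist_path: Path
    truth_path: Path
    regions_path: Path
    manifest_path: Path


def _write_fasta(path: Path, genome: dict[str, np.ndarray],
                 width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, arr in genome.items():
            fh.write(f">{chrom}\n")
            s = arr.tobytes().decode("ascii")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("target_motifs", "decoy_motifs"):
        d[key] = [dict(motif_id=m["motif_id"],
                       probs=np.asarray(m["probs"]).round(6).tolist(),
                       background=np.asarray(m["background"]).tolist())
                  for m in d[key]]
    return d


def emit_fixture(config: SimulationConfig, genome: dict[str, np.ndarray],
                 region_sets: RegionSets, out_dir: str | Path) -> FixtureBundle:
    """Write the bundle files (0-based half-open intervals throughout)."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"fixture directory {out} is not writable: {exc}") from exc

    genome_path = out / "genome.fa"
    _write_fasta(genome_path, genome)

    peaks_path = out / "peaks.narrowPeak"
    with open(peaks_path, "w") as fh:
        for r in region_sets.regions:
            fh.write("\t".join(map(str, [
                r.chrom, r.start, r.end, r.region_id, 0, ".",
                1.0, -1, -1, r.summit_offset])) + "\n")

    differential_paths: dict[str, Path] = {}
    for name, rows in region_sets.differential.items():
        path = out / f"differential_{name}.tsv"
        differential_paths[name] = path
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tlog2FoldDifference\tpadj\tsummits\n")
            for row in rows:
                fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                         f"{row['log2FoldDifference']:.6g}\t"
                         f"{row['padj']:.6g}\t{row['summits']}\n")

    tss_path = out / "tss.bed"
    with open(tss_path, "w") as fh:
        for chrom, pos in region_sets.tss:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
    super_enhancer_path = out / "super_enhancers.bed"
    with open(super_enhancer_path, "w") as fh:
        for chrom, s, e in region_sets.super_enhancers:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    blacklist_path = out / "blacklist.bed"
    with open(blacklist_path, "w") as fh:
        for chrom, s, e in region_sets.blacklist:
            fh.write(f"{chrom}\t{s}\t{e}\n")

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("chrom\tstart\tend\tmotif_id\tstrand\tregion_id\n")
        for row in region_sets.truth:
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                     f"{row['motif_id']}\t{row['strand']}\t"
                     f"{row['region_id']}\n")

    regions_path = out / "regions.tsv"
    with open(regions_path, "w") as fh:
        fh.write("region_id\trole\tlabel\tchrom\tstart\tend\tsummit\t"
                 "consensus\tn_planted\n")
        for r in region_sets.regions:
            fh.write(f"{r.region_id}\t{r.role}\t{r.label}\t{r.chrom}\t"
                     f"{r.start}\t{r.end}\t{r.summit}\t"
                     f"{int(r.consensus)}\t{len(r.planted)}\n")

    manifest_path = out / "manifest.yaml"
    manifest = dict(
        seed=config.seed,
        config=_config_to_dict(config),
        comparisons=list(region_sets.differential),
        files=dict(
            genome="genome.fa", peaks="peaks.narrowPeak",
            differential={n: p.name for n, p in differential_paths.items()},
            tss="tss.bed", super_enhancers="super_enhancers.bed",
            blacklist="blacklist.bed", truth="truth.tsv",
            regions="regions.tsv"),
        counts=dict(
            regions=len(region_sets.regions),
            planted_sites=len(region_sets.truth),
            tss=len(region_sets.tss),
            super_enhancers=len(region_sets.super_enhancers),
            blacklist=len(region_sets.blacklist)),
    )
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return FixtureBundle(
        genome_path=genome_path, peaks_path=peaks_path,
        differential_paths=differential_paths, tss_path=tss_path,
        super_enhancer_path=super_enhancer_path,
        blacklist_path=blacklist_path, truth_path=truth_path,
        regions_path=regions_path, manifest_path=manifest_path)


def simulate_bundle(config: SimulationConfig,
                    out_dir: str | Path) -> FixtureBundle:
    """Generate genome + regions and write a complete fixture bundle."""
    genome = generate_genome(config)
    region_sets = generate_region_sets(config, genome)
    return emit_fixture(config, genome, region_sets, out_dir)


def load_manifest(bundle_dir: str | Path) -> dict:
    with open(Path(bundle_dir) / "manifest.yaml") as fh:
        return yaml.safe_load(fh)
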