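"""Synthetic genome, annotation and call-set generator with a truth ledger.

The generator emulates the situation an artifact-forensics pipeline faces on
resequencing data from a selfing plant line: a small multi-chromosome genome
whose A/T homopolymer runs are enriched in introns and intergenic space, a
centromere per chromosome, transposable elements (TEs) confined to
intergenic space, "true" mutations drawn from a CpG-elevated spectrum with
TE hypermutability, and three injected artifact classes --

* bleed errors: substitutions whose alternate allele equals the base of a
  nearby A/T run, with run-length-dependent rates, distance decay, strand
  bias and same-read co-error clusters;
* mis-mapping clusters: groups of calls within a small span, biased toward
  centromeres;
* recurrent errors: the identical call repeated across implausibly many
  samples.

Every emitted call carries a provenance tag in a :class:`TruthLedger`, so
downstream classifiers have an exact ground truth.

Background sequence is generated free of homopolymer runs at or above
``min_run_length``; the runs present are exactly the seeded ones, which makes
the configured run densities the ground truth for enrichment checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .homopolymer_artifacts import HomopolymerRun, find_runs
from .io_formats import (
    AnnotationSet,
    CallSet,
    GenomeAssembly,
    GenomicInterval,
    MutationCall,
    synthesize_intergenic,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
GENE_CLASSES = ("essential", "morphological", "cellular_biochemical", "environmental")
#: Relative gene-class sizes, proportioned like curated Arabidopsis phenotype
#: classes (essential : morphological : cellular/biochemical : environmental).
GENE_CLASS_WEIGHTS = (719, 861, 297, 522)

TAG_TRUE = "true_mutation"
TAG_BLEED = "bleed_error"
TAG_CLUSTER = "cluster_error"
TAG_RECURRENT = "recurrent_error"


@dataclass
class SimulationConfig:
    """All knobs of the simulation; defaults are the package's reference
    study conditions (a ~5 Mb, 36% GC, Arabidopsis-like miniature)."""

    n_chromosomes: int = 5
    chrom_length: int = 1_000_000
    gc_content: float = 0.36
    homopolymer_enrichment: float = 5.0
    run_density_cds: float = 5e-4      # seeded A/T runs per bp of CDS
    run_length_min: int = 4
    run_length_max: int = 12
    min_run_length: int = 4            # detection threshold; also background suppression
    n_genes: int = 1000
    n_exons_per_gene: int = 4
    exon_length: int = 300
    intron_length: int = 300
    te_fraction_intergenic: float = 0.3
    te_length: int = 400
    centromere_fraction: float = 0.1
    n_true_mutations: int = 5000
    cpg_rate_multiplier: float = 10.0
    te_rate_multiplier: float = 4.0
    essential_rate_multiplier: float = 1.0
    n_bleed_errors: int = 2500
    bleed_length_slope: float = 0.27   # per-unit-run-length increment of log10 rate
    bleed_decay_scale: float = 1.0     # bp scale of exp(-d/scale) distance decay
    bleed_strand_bias: float = 0.8     # fraction of bleed calls with one dead strand
    bleed_cluster_fraction: float = 0.3
    bleed_max_distance: int = 5
    n_cluster_errors: int = 400        # number of mis-mapping clusters
    cluster_span: int = 10
    cluster_group_size: int = 3
    cluster_centromere_fraction: float = 0.5
    n_recurrent_errors: int = 30
    recurrent_sample_count: int = 12
    n_samples: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("gc_content", "homopolymer_enrichment", "te_fraction_intergenic",
                     "centromere_fraction", "bleed_strand_bias", "bleed_cluster_fraction",
                     "cluster_centromere_fraction"):
            val = getattr(self, name)
            if name == "homopolymer_enrichment":
                if val < 0:
                    raise ValueError("homopolymer_enrichment must be >= 0")
            elif not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_true_mutations",
                     "n_bleed_errors", "n_cluster_errors", "n_recurrent_errors",
                     "n_samples", "recurrent_sample_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bleed_length_slope <= 0:
            raise ValueError("bleed_length_slope must be > 0")
        if self.cluster_span < 2:
            raise ValueError("cluster_span must be >= 2")
        if self.n_recurrent_errors > 0 and self.recurrent_sample_count > self.n_samples:
            raise ValueError("recurrent_sample_count exceeds n_samples")

    def to_dict(self) -> dict:
        return asdict(self)


class TruthLedger:
    """Per-call provenance tags for a generated call set."""

    COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id", "tag", "distance"]

    def __init__(self, rows: list[dict] | None = None):
        self.table = pd.DataFrame(rows or [], columns=self.COLUMNS)

    def add(self, call: MutationCall, tag: str, distance: float = np.nan) -> None:
        self.table.loc[len(self.table)] = [
            call.chrom, call.pos, call.ref, call.alt, call.sample_id, tag, distance]

    @classmethod
    def concat(cls, ledgers: list["TruthLedger"]) -> "TruthLedger":
        out = cls()
        out.table = pd.concat([l.table for l in ledgers], ignore_index=True)
        return out

    @property
    def counts(self) -> dict[str, int]:
        return self.table["tag"].value_counts().to_dict()

    def keys_for(self, tag: str) -> set[tuple]:
        sub = self.table[self.table["tag"] == tag]
        return set(zip(sub.chrom, sub.pos, sub.ref, sub.alt, sub.sample_id))

    def tag_of(self, call: MutationCall) -> str | None:
        m = self.table[
            (self.table.chrom == call.chrom) & (self.table.pos == call.pos)
            & (self.table.ref == call.ref) & (self.table.alt == call.alt)
            & (self.table.sample_id == call.sample_id)]
        return None if m.empty else str(m.iloc[0]["tag"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SimulationResult:
    genome: GenomeAssembly
    annotation: AnnotationSet
    truth: CallSet
    observed: CallSet
    ledger: TruthLedger
    config: SimulationConfig


def _substream(config_seed: int, index: int) -> np.random.Generator:
    """Named substream: genome=0, truth=1, bleed=2, cluster=3."""
    return np.random.default_rng([config_seed, index])


# ---------------------------------------------------------------------------
# genome + annotation


def _random_sequence(rng: np.random.Generator, length: int, gc: float,
                     max_run: int) -> np.ndarray:
    """Random sequence (S1 byte array) with no homopolymer run >= max_run."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = _BASES[rng.choice(4, size=length, p=p)]
    for _ in range(20):
        codes = seq.view(np.uint8)
        change = np.flatnonzero(np.diff(codes) != 0) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [length]))
        lens = ends - starts
        long = np.flatnonzero(lens >= max_run)
        if long.size == 0:
            return seq
        for i in long:
            s, e = int(starts[i]), int(ends[i])
            base = seq[s]
            others = _BASES[_BASES != base]
            for j in range(s + max_run - 1, e, max_run):
                seq[j] = others[rng.integers(3)]
    raise RuntimeError("failed to suppress homopolymer runs")  # pragma: no cover


def _layout_chromosome(
    chrom: str, length: int, n_genes: int, config: SimulationConfig,
    rng: np.random.Generator, gene_counter: list[int],
) -> list[GenomicInterval]:
    """Place centromere, genes (exons/CDS + introns) and TEs on one chromosome."""
    intervals: list[GenomicInterval] = []
    cen_len = int(round(config.centromere_fraction * length))
    cen_start = (length - cen_len) // 2
    if cen_len > 0:
        intervals.append(GenomicInterval(chrom, cen_start, cen_start + cen_len,
                                         ".", "centromere", {"ID": f"{chrom}_cen"}))
    gene_len = (config.n_exons_per_gene * config.exon_length
                + (config.n_exons_per_gene - 1) * config.intron_length)
    arms = [(0, cen_start), (cen_start + cen_len, length)]
    arm_lens = [e - s for s, e in arms]
    genes_in_arm = [int(round(n_genes * al / sum(arm_lens))) for al in arm_lens]
    genes_in_arm[0] += n_genes - sum(genes_in_arm)
    gene_gaps: list[tuple[int, int]] = []
    for (arm_start, arm_end), k in zip(arms, genes_in_arm):
        arm_len = arm_end - arm_start
        if k == 0:
            gene_gaps.append((arm_start, arm_end))
            continue
        spacing = (arm_len - k * gene_len) / (k + 1)
        if spacing < 50:
            raise ValueError(
                f"requested features exceed available space on {chrom} "
                f"(need {k} genes of {gene_len} bp in a {arm_len} bp arm)")
        prev_end = arm_start
        for i in range(k):
            gstart = arm_start + int(round(spacing * (i + 1) + gene_len * i))
            gene_counter[0] += 1
            gid = f"gene{gene_counter[0]:05d}"
            strand = "+" if gene_counter[0] % 2 else "-"
            gclass = GENE_CLASSES[rng.choice(
                4, p=np.array(GENE_CLASS_WEIGHTS) / sum(GENE_CLASS_WEIGHTS))]
            intervals.append(GenomicInterval(
                chrom, gstart, gstart + gene_len, strand, "gene",
                {"ID": gid, "gene_class": gclass}))
            for j in range(config.n_exons_per_gene):
                es = gstart + j * (config.exon_length + config.intron_length)
                ee = es + config.exon_length
                intervals.append(GenomicInterval(chrom, es, ee, strand, "exon",
                                                 {"Parent": gid}))
                intervals.append(GenomicInterval(chrom, es, ee, strand, "CDS",
                                                 {"Parent": gid}))
                if j < config.n_exons_per_gene - 1:
                    intervals.append(GenomicInterval(
                        chrom, ee, ee + config.intron_length, strand, "intron",
                        {"Parent": gid}))
            gene_gaps.append((prev_end, gstart))
            prev_end = gstart + gene_len
        gene_gaps.append((prev_end, arm_end))
    # TEs only in intergenic, non-centromeric gaps
    if config.te_fraction_intergenic > 0:
        te_counter = 0
        for gap_start, gap_end in gene_gaps:
            gap = gap_end - gap_start
            n_te = int(gap * config.te_fraction_intergenic / config.te_length)
            if n_te == 0:
                continue
            slot = gap / n_te
            for i in range(n_te):
                ts = gap_start + int(i * slot + (slot - config.te_length) / 2)
                te_counter += 1
                intervals.append(GenomicInterval(
                    chrom, ts, ts + config.te_length, ".", "TE",
                    {"ID": f"{chrom}_te{te_counter:05d}"}))
    return intervals


def _seed_runs(seq: np.ndarray, intervals: list[tuple[int, int]], rate: float,
               config: SimulationConfig, rng: np.random.Generator) -> int:
    """Write A/T homopolymer runs into seq at the given per-bp rate."""
    n_seeded = 0
    # margins/spacing keep every seeded run more than 2x the bleed proximity
    # window away from any other run, so a bleed call is always nearest to
    # (and unambiguously attributed to) its source run
    margin = config.run_length_max + config.bleed_max_distance + 2
    spacing = config.run_length_max + 2 * config.bleed_max_distance + 6
    for start, end in intervals:
        if end - start < 2 * margin:
            continue
        n = rng.poisson((end - start) * rate)
        if n == 0:
            continue
        positions = np.sort(rng.integers(start + margin, end - margin, size=n))
        prev = -10**9
        for pos in positions:
            if pos - prev < spacing:
                continue
            run_len = int(rng.integers(config.run_length_min, config.run_length_max + 1))
            base = b"A" if rng.random() < 0.5 else b"T"
            seq[pos:pos + run_len] = np.frombuffer(base, dtype="S1")[0]
            gc_flank = np.frombuffer(b"CG", dtype="S1")
            if seq[pos - 1] == seq[pos]:
                seq[pos - 1] = gc_flank[rng.integers(2)]
            if seq[pos + run_len] == seq[pos]:
                seq[pos + run_len] = gc_flank[rng.integers(2)]
            prev = pos
            n_seeded += 1
    return n_seeded


def generate_genome(config: SimulationConfig) -> tuple[GenomeAssembly, AnnotationSet]:
    """Generate the genome and its annotation.

    A/T runs (lengths ``run_length_min``..``run_length_max``) are seeded at
    ``run_density_cds`` per bp in CDS and ``homopolymer_enrichment`` times
    that in introns and intergenic space; the background sequence carries no
    other runs at or above ``min_run_length``.
    """
    rng = _substream(config.seed, 0)
    chromosomes: dict[str, str] = {}
    intervals: list[GenomicInterval] = []
    gene_counter = [0]
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    seqs: dict[str, np.ndarray] = {}
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = _random_sequence(rng, config.chrom_length, config.gc_content,
                               config.min_run_length)
        seqs[chrom] = seq
        intervals.extend(_layout_chromosome(
            chrom, config.chrom_length, per_chrom[ci], config, rng, gene_counter))
    # homopolymer seeding: CDS at base rate, introns+intergenic enriched
    genes = [iv for iv in intervals if iv.feature_type == "gene"]
    dummy = GenomeAssembly({c: "" for c in seqs})  # lengths come below
    dummy.chromosomes = {c: "A" * config.chrom_length for c in seqs}
    intergenic = synthesize_intergenic(genes, dummy)
    for chrom in seqs:
        cds = [(iv.start, iv.end) for iv in intervals
               if iv.chrom == chrom and iv.feature_type == "CDS"]
        soft = [(iv.start, iv.end) for iv in intervals
                if iv.chrom == chrom and iv.feature_type == "intron"]
        soft += [(iv.start, iv.end) for iv in intergenic if iv.chrom == chrom]
        _seed_runs(seqs[chrom], cds, config.run_density_cds, config, rng)
        _seed_runs(seqs[chrom], soft,
                   config.run_density_cds * config.homopolymer_enrichment, config, rng)
        chromosomes[chrom] = seqs[chrom].tobytes().decode("ascii")
    genome = GenomeAssembly(chromosomes)
    intervals.extend(synthesize_intergenic(genes, genome))
    return genome, AnnotationSet(intervals)


# ---------------------------------------------------------------------------
# true mutations


def mutation_weights(genome: GenomeAssembly, annotation: AnnotationSet,
                     config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-position sampling weight for true mutations.

    Base weight 1; C and G of every CpG dinucleotide get
    ``cpg_rate_multiplier``; TE positions get ``te_rate_multiplier``;
    essential-gene bodies get ``essential_rate_multiplier``.  Multipliers
    stack (a methylated TE CpG is both TE-weighted and CpG-weighted).
    """
    weights: dict[str, np.ndarray] = {}
    for chrom, seq in genome.chromosomes.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        w = np.ones(len(arr))
        w[arr == b"N"] = 0.0
        is_c = arr == b"C"
        is_g = arr == b"G"
        cpg_c = np.zeros(len(arr), dtype=bool)
        cpg_c[:-1] = is_c[:-1] & is_g[1:]
        cpg_g = np.zeros(len(arr), dtype=bool)
        cpg_g[1:] = is_g[1:] & is_c[:-1]
        w[cpg_c | cpg_g] *= config.cpg_rate_multiplier
        for iv in annotation.of_type("TE"):
            if iv.chrom == chrom:
                w[iv.start:iv.end] *= config.te_rate_multiplier
        if config.essential_rate_multiplier != 1.0:
            for iv in annotation.of_type("gene"):
                if iv.chrom == chrom and iv.attributes.get("gene_class") == "essential":
                    w[iv.start:iv.end] *= config.essential_rate_multiplier
        weights[chrom] = w
    return weights


def _is_cpg_c(seq: str, pos: int) -> bool:
    return seq[pos] == "C" and pos + 1 < len(seq) and seq[pos + 1] == "G"


def _is_cpg_g(seq: str, pos: int) -> bool:
    return seq[pos] == "G" and pos > 0 and seq[pos - 1] == "C"


def generate_true_mutations(
    genome: GenomeAssembly,
    annotation: AnnotationSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    occupied: set[tuple[str, int]] | None = None,
) -> tuple[CallSet, TruthLedger]:
    """Sample true mutations from the CpG/TE-weighted position distribution.

    CpG cytosines mutate to T (and CpG guanines to A, the same event on the
    other strand); all other positions mutate to a uniform alternative.
    Every true call has >= 2 supporting reads on each strand.
    """
    if rng is None:
        rng = _substream(config.seed, 1)
    occupied = occupied if occupied is not None else set()
    n = config.n_true_mutations
    if n > genome.total_bp():
        raise ValueError("n_true_mutations exceeds genome size")
    weights = mutation_weights(genome, annotation, config)
    chroms = sorted(weights)
    totals = np.array([weights[c].sum() for c in chroms])
    p_chrom = totals / totals.sum()
    wmaxes = {c: weights[c].max() for c in chroms}
    small_p = {c: weights[c] / weights[c].sum()
               for c in chroms if len(weights[c]) < 200_000}
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    calls: list[MutationCall] = []
    ledger = TruthLedger()
    rows = []
    guard = 0
    while len(calls) < n:
        guard += 1
        if guard > 50 * (n + 10):
            raise RuntimeError("could not place true mutations")  # pragma: no cover
        chrom = chroms[rng.choice(len(chroms), p=p_chrom)]
        w = weights[chrom]
        if chrom in small_p:
            pos = int(rng.choice(len(w), p=small_p[chrom]))
        else:
            # rejection sampling against the (bounded) weight profile
            wmax = wmaxes[chrom]
            while True:
                cand = int(rng.integers(len(w)))
                if rng.random() * wmax <= w[cand]:
                    pos = cand
                    break
        if (chrom, pos) in occupied:
            continue
        seq = genome.chromosomes[chrom]
        ref = seq[pos]
        if ref == "N":
            continue
        if _is_cpg_c(seq, pos):
            alt = "T"
        elif _is_cpg_g(seq, pos):
            alt = "A"
        else:
            others = [b for b in "ACGT" if b != ref]
            alt = others[rng.integers(3)]
        call = MutationCall(
            chrom, pos, ref, alt, samples[rng.integers(len(samples))],
            fwd_support=2 + int(rng.poisson(10)),
            rev_support=2 + int(rng.poisson(10)))
        occupied.add((chrom, pos))
        calls.append(call)
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                     "sample_id": call.sample_id, "tag": TAG_TRUE,
                     "distance": np.nan})
    ledger.table = pd.DataFrame(rows, columns=TruthLedger.COLUMNS)
    return CallSet("truth", calls), ledger


# ---------------------------------------------------------------------------
# bleed errors


def bleed_run_weights(runs: list[HomopolymerRun], slope: float) -> np.ndarray:
    """Per-run selection weight: length x 10^(slope x length).

    This makes the per-bp error rate within runs of length L proportional to
    10^(slope x L), so the run-length regression's estimand equals ``slope``.
    """
    lengths = np.array([r.length for r in runs], dtype=float)
    w = lengths * np.power(10.0, slope * lengths)
    return w / w.sum()


def _bleed_distance_probs(config: SimulationConfig) -> np.ndarray:
    d = np.arange(config.bleed_max_distance + 1, dtype=float)
    p = np.exp(-d / config.bleed_decay_scale)
    return p / p.sum()


def _bleed_supports(config: SimulationConfig, rng: np.random.Generator
                    ) -> tuple[int, int]:
    if rng.random() < config.bleed_strand_bias:
        live = 2 + int(rng.poisson(8))
        return (live, 0) if rng.random() < 0.5 else (0, live)
    return 2 + int(rng.poisson(6)), 2 + int(rng.poisson(6))


def inject_bleed_errors(
    genome: GenomeAssembly,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    occupied: set[tuple[str, int]] | None = None,
    runs: list[HomopolymerRun] | None = None,
) -> tuple[CallSet, TruthLedger]:
    """Inject homopolymer bleed substitution errors.

    Each error picks an A/T run (per-bp rate growing 10^(slope x length)),
    then a position at distance d in [0, bleed_max_distance] from the run
    boundary with probability proportional to exp(-d/bleed_decay_scale); the
    alternate allele is the run base.  A ``bleed_strand_bias`` fraction of
    errors have support on only one strand, and a ``bleed_cluster_fraction``
    subfraction emits same-read co-errors stepping away from the run in
    2 bp increments (the ACACA -> AAAAA pattern).
    """
    if rng is None:
        rng = _substream(config.seed, 2)
    occupied = occupied if occupied is not None else set()
    if runs is None:
        runs = find_runs(genome, config.min_run_length)
    at_runs = [r for r in runs if r.klass == "AT"]
    if not at_runs:
        raise ValueError("genome has no A/T homopolymer runs at minimum length")
    p_run = bleed_run_weights(at_runs, config.bleed_length_slope)
    cum_run = np.cumsum(p_run)
    p_dist = _bleed_distance_probs(config)
    cum_dist = np.cumsum(p_dist)
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    n = config.n_bleed_errors
    calls: list[MutationCall] = []
    rows: list[dict] = []
    # bleed errors may recur at one position in different samples (the same
    # artifact mechanism hits every sample's reads); only positions taken by
    # other provenance tags are excluded, so ledger tags stay unambiguous.
    bleed_sites: set[tuple[str, int]] = set()
    emitted: set[tuple[str, int, str]] = set()

    def try_emit(run: HomopolymerRun, pos: int, d: int, sample: str,
                 fwd: int, rev: int) -> bool:
        seq = genome.chromosomes[run.chrom]
        if not (0 <= pos < len(seq)):
            return False
        ref = seq[pos]
        if ref == "N" or ref == run.base or (run.chrom, pos) in occupied \
                or (run.chrom, pos, sample) in emitted:
            return False
        call = MutationCall(run.chrom, pos, ref, run.base, sample, fwd, rev)
        bleed_sites.add((run.chrom, pos))
        emitted.add((run.chrom, pos, sample))
        calls.append(call)
        rows.append({"chrom": run.chrom, "pos": pos, "ref": ref, "alt": run.base,
                     "sample_id": sample, "tag": TAG_BLEED, "distance": float(d)})
        return True

    guard = 0
    while len(calls) < n:
        guard += 1
        if guard > 100 * (n + 10):
            raise RuntimeError("could not place bleed errors")  # pragma: no cover
        run = at_runs[int(np.searchsorted(cum_run, rng.random()))]
        side = 1 if rng.random() < 0.5 else -1
        d = int(np.searchsorted(cum_dist, rng.random()))
        pos = run.end + d if side == 1 else run.start - 1 - d
        sample = samples[rng.integers(len(samples))]
        fwd, rev = _bleed_supports(config, rng)
        if not try_emit(run, pos, d, sample, fwd, rev):
            continue
        if rng.random() < config.bleed_cluster_fraction and len(calls) < n:
            # same-read co-errors: step 2 bp further from the run, staying
            # inside the proximity window so recall-by-construction holds
            n_extra = int(rng.integers(1, 3))
            for k in range(1, n_extra + 1):
                if len(calls) >= n or d + 2 * k > config.bleed_max_distance:
                    break
                try_emit(run, pos + side * 2 * k, d + 2 * k, sample, fwd, rev)
    occupied.update(bleed_sites)
    ledger = TruthLedger()
    ledger.table = pd.DataFrame(rows, columns=TruthLedger.COLUMNS)
    return CallSet("bleed", calls), ledger


# ---------------------------------------------------------------------------
# mis-mapping clusters and recurrent calls


def inject_cluster_and_recurrent_errors(
    genome: GenomeAssembly,
    annotation: AnnotationSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    occupied: set[tuple[str, int]] | None = None,
) -> tuple[CallSet, TruthLedger]:
    """Inject mis-mapping artifact calls.

    Cluster errors come in groups of ``cluster_group_size`` calls within
    ``cluster_span`` bp (one sample per cluster, as a mis-mapped read stack
    would produce), a ``cluster_centromere_fraction`` of them anchored inside
    centromeres.  Recurrent errors repeat the identical call across
    ``recurrent_sample_count`` samples.
    """
    if rng is None:
        rng = _substream(config.seed, 3)
    occupied = occupied if occupied is not None else set()
    centromeres = annotation.of_type("centromere")
    if config.n_cluster_errors > 0 and config.cluster_centromere_fraction > 0 \
            and not centromeres:
        raise ValueError("annotation has no centromere intervals")
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    chroms = sorted(genome.chromosomes)
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=float)
    p_chrom = lengths / lengths.sum()
    calls: list[MutationCall] = []
    rows: list[dict] = []

    def emit(chrom: str, pos: int, sample: str, tag: str) -> bool:
        seq = genome.chromosomes[chrom]
        ref = seq[pos]
        if ref == "N" or (chrom, pos) in occupied:
            return False
        alt = [b for b in "ACGT" if b != ref][rng.integers(3)]
        calls.append(MutationCall(chrom, pos, ref, alt, sample,
                                  2 + int(rng.poisson(6)), 2 + int(rng.poisson(6))))
        occupied.add((chrom, pos))
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                     "sample_id": sample, "tag": tag, "distance": np.nan})
        return True

    g = max(2, config.cluster_group_size)
    for _ in range(config.n_cluster_errors):
        for _attempt in range(1000):
            if centromeres and rng.random() < config.cluster_centromere_fraction:
                cen = centromeres[int(rng.integers(len(centromeres)))]
                anchor = int(rng.integers(cen.start, cen.end - config.cluster_span - 1))
            else:
                chrom_i = int(rng.choice(len(chroms), p=p_chrom))
                chrom = chroms[chrom_i]
                anchor = int(rng.integers(0, genome.lengths[chrom]
                                          - config.cluster_span - 1))
                if annotation.contains(chrom, anchor, "centromere"):
                    continue
                cen = None
            chrom = cen.chrom if cen is not None else chrom
            offsets = np.concatenate(
                ([0], np.sort(rng.choice(np.arange(1, config.cluster_span + 1),
                                         size=g - 1, replace=False))))
            sample = samples[rng.integers(len(samples))]
            if any((chrom, anchor + int(o)) in occupied
                   or genome.chromosomes[chrom][anchor + int(o)] == "N"
                   for o in offsets):
                continue
            for o in offsets:
                emit(chrom, anchor + int(o), sample, TAG_CLUSTER)
            break
        else:  # pragma: no cover
            raise RuntimeError("could not place cluster errors")

    for _ in range(config.n_recurrent_errors):
        for _attempt in range(1000):
            chrom = chroms[int(rng.choice(len(chroms), p=p_chrom))]
            pos = int(rng.integers(genome.lengths[chrom]))
            seq = genome.chromosomes[chrom]
            if seq[pos] == "N" or (chrom, pos) in occupied:
                continue
            ref = seq[pos]
            alt = [b for b in "ACGT" if b != ref][rng.integers(3)]
            carrier_idx = rng.choice(len(samples), size=config.recurrent_sample_count,
                                     replace=False)
            occupied.add((chrom, pos))
            for si in carrier_idx:
                calls.append(MutationCall(chrom, pos, ref, alt, samples[si],
                                          2 + int(rng.poisson(6)),
                                          2 + int(rng.poisson(6))))
                rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                             "sample_id": samples[si], "tag": TAG_RECURRENT,
                             "distance": np.nan})
            break
        else:  # pragma: no cover
            raise RuntimeError("could not place recurrent errors")

    ledger = TruthLedger()
    ledger.table = pd.DataFrame(rows, columns=TruthLedger.COLUMNS)
    return CallSet("mapping_artifacts", calls), ledger


# ---------------------------------------------------------------------------
# orchestration


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: genome, annotation, truth and observed call
    sets, and the provenance ledger.

    Four named random substreams (genome, truth, bleed, cluster) hang off
    the single configured seed, so each stage can be regenerated
    independently.  Calls never collide at a genomic position across stages
    (colliding draws are redrawn, preserving the configured counts).
    """
    genome, annotation = generate_genome(config)
    occupied: set[tuple[str, int]] = set()
    truth, truth_ledger = generate_true_mutations(
        genome, annotation, config, _substream(config.seed, 1), occupied)
    bleed, bleed_ledger = inject_bleed_errors(
        genome, config, _substream(config.seed, 2), occupied)
    mapping, mapping_ledger = inject_cluster_and_recurrent_errors(
        genome, annotation, config, _substream(config.seed, 3), occupied)
    observed = CallSet("observed", list(truth) + list(bleed) + list(mapping))
    ledger = TruthLedger.concat([truth_ledger, bleed_ledger, mapping_ledger])
    return SimulationResult(genome, annotation, truth, observed, ledger, config)
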