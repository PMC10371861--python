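"""Region-stratified mutation rates, paired dinucleotide-rate tests,
gene-class heterogeneity, and TSS/TTS metagene profiles.

Every position gets exactly one region class by precedence
(CDS > intron > TE > centromere > intergenic by default), so per-class base
counts and call counts partition the genome and the call set.  Metagene
profiles accumulate event density in strand-oriented bins around
transcription start (TSS) and termination (TTS) sites; feeding them either
real calls, simulated homopolymer errors, or TE base pairs shows which
profile features are mutational and which are artifactual or compositional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .homopolymer_artifacts import HomopolymerRun
from .io_formats import AnnotationSet, CallSet, GenomeAssembly
from .mutation_spectrum import DiSpectrum96, di_spectrum
from .synthetic_data import GENE_CLASSES, bleed_run_weights

DEFAULT_PRECEDENCE = ("CDS", "intron", "TE", "centromere", "intergenic")


# ---------------------------------------------------------------------------
# region partition


def region_label_arrays(
    annotation: AnnotationSet,
    genome: GenomeAssembly,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> dict[str, np.ndarray]:
    """Per-chromosome arrays of region-class indices (into ``precedence``).

    Painted lowest-precedence first so higher classes overwrite; unannotated
    space falls to the last (lowest) class.
    """
    labels = {chrom: np.full(length, len(precedence) - 1, dtype=np.uint8)
              for chrom, length in genome.lengths.items()}
    for rank in range(len(precedence) - 1, -1, -1):
        for iv in annotation.of_type(precedence[rank]):
            if iv.chrom in labels:
                labels[iv.chrom][iv.start:iv.end] = rank
    return labels


def region_intervals(
    annotation: AnnotationSet,
    genome: GenomeAssembly,
    classes: tuple[str, ...] | None = None,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> dict[str, list[tuple[str, int, int]]]:
    """Maximal (chrom, start, end) intervals of each region class under the
    precedence partition."""
    labels = region_label_arrays(annotation, genome, precedence)
    wanted = classes or precedence
    out: dict[str, list[tuple[str, int, int]]] = {c: [] for c in wanted}
    for chrom in sorted(labels):
        arr = labels[chrom]
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(arr)]))
        for s, e in zip(starts, ends):
            cls = precedence[arr[s]]
            if cls in out:
                out[cls].append((chrom, int(s), int(e)))
    return out


def assign_region(
    chrom: str,
    pos: int,
    annotation: AnnotationSet,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> str:
    """Region class of a single position, by precedence."""
    for cls in precedence:
        if annotation.contains(chrom, pos, cls):
            return cls
    return precedence[-1]


@dataclass
class RegionRateTable:
    table: pd.DataFrame                      # class, n_calls, bp, rate, empty flag
    spectra: dict[str, DiSpectrum96]
    precedence: tuple[str, ...]

    def rate(self, region_class: str) -> float:
        return float(self.table.set_index("class").loc[region_class, "rate"])

    @property
    def intron_cds_ratio(self) -> float:
        return self.rate("intron") / self.rate("CDS")


def region_rates(
    callset: CallSet,
    annotation: AnnotationSet,
    genome: GenomeAssembly,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
    with_spectra: bool = True,
) -> RegionRateTable:
    """Per-region-class call counts, base counts, rates per bp, and (when
    requested) the 96-class normalized dinucleotide rate vector restricted to
    each class."""
    labels = region_label_arrays(annotation, genome, precedence)
    for call in callset:
        if call.chrom not in labels:
            raise ValueError(f"call on unannotated chromosome {call.chrom}")
    bp = {cls: 0 for cls in precedence}
    for chrom, arr in labels.items():
        counts = np.bincount(arr, minlength=len(precedence))
        for i, cls in enumerate(precedence):
            bp[cls] += int(counts[i])
    n_calls = {cls: 0 for cls in precedence}
    for call in callset:
        n_calls[precedence[labels[call.chrom][call.pos]]] += 1
    rows = []
    for cls in precedence:
        rate = n_calls[cls] / bp[cls] if bp[cls] else 0.0
        rows.append({"class": cls, "n_calls": n_calls[cls], "bp": bp[cls],
                     "rate": rate, "empty": n_calls[cls] == 0 or bp[cls] == 0})
    spectra: dict[str, DiSpectrum96] = {}
    if with_spectra:
        intervals = region_intervals(annotation, genome, precedence=precedence)
        for cls in precedence:
            if intervals[cls]:
                spectra[cls] = di_spectrum(callset, genome, region=intervals[cls],
                                           label=f"{callset.label}:{cls}")
    return RegionRateTable(table=pd.DataFrame(rows), spectra=spectra,
                           precedence=precedence)


# ---------------------------------------------------------------------------
# paired dinucleotide-rate test


@dataclass
class PairedRateTest:
    ratio_per_class: pd.Series
    mean_ratio: float                  # mean of per-class ratios
    ratio_of_means: float              # ratio of mean rates (less noise-biased)
    t_statistic: float
    p_value: float
    df: int
    n_excluded: int


def paired_rate_test(vector_a: pd.Series, vector_b: pd.Series) -> PairedRateTest:
    """Paired t-test of two 96-class normalized rate vectors.

    Classes with an undefined or zero denominator rate are excluded and the
    degrees of freedom adjusted; both the mean per-class ratio and the ratio
    of mean rates are reported (they differ under sampling noise).
    """
    a = vector_a.to_numpy(dtype=float)
    b = vector_b.to_numpy(dtype=float)
    usable = np.isfinite(a) & np.isfinite(b) & (b > 0)
    n = int(usable.sum())
    if n < 10:
        raise ValueError(f"only {n} usable classes; need >= 10")
    ratios = a[usable] / b[usable]
    if np.allclose(a[usable], b[usable]):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a[usable], b[usable])
    return PairedRateTest(
        ratio_per_class=pd.Series(ratios, index=vector_a.index[usable]),
        mean_ratio=float(ratios.mean()),
        ratio_of_means=float(a[usable].mean() / b[usable].mean()),
        t_statistic=float(t), p_value=float(p), df=n - 1,
        n_excluded=int((~usable).sum()))


# ---------------------------------------------------------------------------
# gene-class heterogeneity


@dataclass
class GeneClassRateReport:
    table: pd.DataFrame                # class, n_genes, bp, n_calls, rate, sem
    chi2: float
    df: int
    p_value: float
    small_counts: bool                 # any expected count < 5: test not valid
    feature: str


def gene_class_rates(
    callset: CallSet,
    annotation: AnnotationSet,
    gene_class_map: dict[str, str] | None = None,
    feature: str = "CDS",
) -> GeneClassRateReport:
    """Mutation-rate heterogeneity across the four gene classes.

    Observed per-class call counts in the chosen feature (CDS or intron) are
    tested against expectation proportional to class feature bp (the
    rate-homogeneity null), chi-square with df = 3.  Per-gene rates give the
    class s.e.m.  A validity flag is raised when any expected count is < 5.
    """
    genes = annotation.of_type("gene")
    if gene_class_map is None:
        gene_class_map = {g.attributes.get("ID", ""): g.attributes.get("gene_class", "")
                          for g in genes}
    features = [iv for iv in annotation.of_type(feature) if "Parent" in iv.attributes]
    by_gene: dict[str, list] = {}
    for iv in features:
        by_gene.setdefault(iv.attributes["Parent"], []).append(iv)
    positions: dict[str, np.ndarray] = {}
    for chrom in {c.chrom for c in callset}:
        positions[chrom] = np.array(sorted(c.pos for c in callset if c.chrom == chrom))
    per_gene = []
    for gene in genes:
        gid = gene.attributes.get("ID", "")
        cls = gene_class_map.get(gid, "")
        if cls not in GENE_CLASSES:
            continue
        ivs = by_gene.get(gid, [])
        bp = sum(len(iv) for iv in ivs)
        n = 0
        for iv in ivs:
            arr = positions.get(iv.chrom)
            if arr is not None and len(arr):
                n += int(np.searchsorted(arr, iv.end) - np.searchsorted(arr, iv.start))
        if bp > 0:
            per_gene.append({"gene": gid, "class": cls, "bp": bp, "n_calls": n,
                             "rate": n / bp})
    if not per_gene:
        raise ValueError(f"no genes with {feature} features and a known class")
    df_genes = pd.DataFrame(per_gene)
    dup = df_genes["gene"].duplicated()
    if dup.any():  # pragma: no cover
        raise ValueError("a gene appears in two classes")
    agg = df_genes.groupby("class", sort=False).agg(
        n_genes=("gene", "size"), bp=("bp", "sum"), n_calls=("n_calls", "sum"),
        sem=("rate", lambda r: float(np.std(r, ddof=1) / np.sqrt(len(r)))
             if len(r) > 1 else float("nan")))
    agg = agg.reindex([c for c in GENE_CLASSES if c in agg.index])
    agg["rate"] = agg["n_calls"] / agg["bp"]
    observed = agg["n_calls"].to_numpy(dtype=float)
    expected = observed.sum() * agg["bp"].to_numpy(dtype=float) / agg["bp"].sum()
    if observed.sum() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.chisquare(observed, f_exp=expected)
    return GeneClassRateReport(
        table=agg.reset_index(), chi2=float(chi2), df=len(agg) - 1,
        p_value=float(p), small_counts=bool((expected < 5).any()), feature=feature)


# ---------------------------------------------------------------------------
# metagene profiles


@dataclass
class MetageneProfile:
    anchor: str                        # "TSS" or "TTS"
    offsets: np.ndarray                # bin left edges, upstream negative
    counts: np.ndarray
    density: np.ndarray                # events per bp per anchored gene
    n_anchors: int
    bin_bp: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "count": self.counts,
                             "density": self.density})


def _as_position_arrays(positions) -> dict[str, np.ndarray]:
    if isinstance(positions, dict):
        return {c: np.sort(np.asarray(p)) for c, p in positions.items()}
    by_chrom: dict[str, list[int]] = {}
    for item in positions:
        chrom, pos = (item.chrom, item.pos) if hasattr(item, "chrom") else item
        by_chrom.setdefault(chrom, []).append(pos)
    return {c: np.sort(np.array(p)) for c, p in by_chrom.items()}


def metagene_profile(
    positions,
    annotation: AnnotationSet,
    window_bp: int = 3000,
    bin_bp: int = 100,
) -> tuple[MetageneProfile, MetageneProfile]:
    """Strand-oriented event density around TSS and TTS.

    ``positions`` is any event set: MutationCalls, (chrom, pos) pairs, or a
    chrom -> positions-array mapping.  For each stranded gene, events within
    ±window_bp of the anchor accumulate into bins after flipping minus-strand
    genes, then densities normalize per bp per anchored gene.  An event in
    the windows of several genes counts once per window.
    """
    if window_bp < bin_bp:
        raise ValueError("window_bp must be >= bin_bp")
    if window_bp % bin_bp:
        raise ValueError("window_bp must be a multiple of bin_bp")
    events = _as_position_arrays(positions)
    genes = [g for g in annotation.of_type("gene") if g.strand in "+-"]
    if not genes:
        raise ValueError("no stranded genes in annotation")
    n_bins = 2 * window_bp // bin_bp
    counts = {"TSS": np.zeros(n_bins, dtype=np.int64),
              "TTS": np.zeros(n_bins, dtype=np.int64)}
    for gene in genes:
        arr = events.get(gene.chrom)
        if arr is None or not len(arr):
            continue
        sign = 1 if gene.strand == "+" else -1
        anchors = {"TSS": gene.start if sign == 1 else gene.end - 1,
                   "TTS": gene.end - 1 if sign == 1 else gene.start}
        for name, anchor in anchors.items():
            lo = np.searchsorted(arr, anchor - window_bp, side="left")
            hi = np.searchsorted(arr, anchor + window_bp, side="right")
            offsets = (arr[lo:hi] - anchor) * sign
            keep = (offsets >= -window_bp) & (offsets < window_bp)
            idx = (offsets[keep] + window_bp) // bin_bp
            counts[name] += np.bincount(idx.astype(int), minlength=n_bins)
    offsets = np.arange(-window_bp, window_bp, bin_bp)
    out = []
    for name in ("TSS", "TTS"):
        out.append(MetageneProfile(
            anchor=name, offsets=offsets, counts=counts[name],
            density=counts[name] / (bin_bp * len(genes)),
            n_anchors=len(genes), bin_bp=bin_bp))
    return out[0], out[1]


def simulate_homopolymer_errors(
    genome: GenomeAssembly,
    runs: list[HomopolymerRun],
    n_errors: int,
    length_slope: float,
    seed: int,
    decay_scale: float = 1.0,
    max_distance: int = 5,
) -> dict[str, np.ndarray]:
    """Sample error positions from the homopolymer bleed model.

    Runs are chosen with per-bp rate growing as 10^(length_slope x length)
    (with length_slope = 0 errors fall uniformly per bp of run sequence);
    positions sit at distance d in [0, max_distance] outside a run end,
    decaying as exp(-d/decay_scale).  Output feeds metagene_profile directly.
    """
    at_runs = [r for r in runs if r.klass == "AT"]
    if not at_runs:
        raise ValueError("no A/T homopolymer runs")
    rng = np.random.default_rng(seed)
    lengths = np.array([r.length for r in at_runs], dtype=float)
    if length_slope > 0:
        w = bleed_run_weights(at_runs, length_slope)
    else:
        w = lengths / lengths.sum()
    cum_w = np.cumsum(w)
    d_vals = np.arange(max_distance + 1, dtype=float)
    p_d = np.exp(-d_vals / decay_scale)
    cum_d = np.cumsum(p_d / p_d.sum())
    starts = np.array([r.start for r in at_runs])
    ends = np.array([r.end for r in at_runs])
    chrom_idx = {c: i for i, c in enumerate(sorted(genome.chromosomes))}
    chrom_of = np.array([chrom_idx[r.chrom] for r in at_runs])
    chrom_len = np.array([genome.lengths[c] for c in sorted(chrom_idx)])
    out: dict[str, list[np.ndarray]] = {c: [] for c in chrom_idx}
    n_placed = 0
    while n_placed < n_errors:
        m = min(n_errors - n_placed + 1000, 2 * (n_errors - n_placed) + 1000)
        ri = np.searchsorted(cum_w, rng.random(m))
        d = np.searchsorted(cum_d, rng.random(m))
        side = rng.random(m) < 0.5
        pos = np.where(side, ends[ri] + d, starts[ri] - 1 - d)
        ok = (pos >= 0) & (pos < chrom_len[chrom_of[ri]])
        ri, pos = ri[ok], pos[ok]
        take = min(len(pos), n_errors - n_placed)
        ri, pos = ri[:take], pos[:take]
        for c, i in chrom_idx.items():
            out[c].append(pos[chrom_of[ri] == i])
        n_placed += take
    return {c: np.sort(np.concatenate(parts)) if parts else np.array([], dtype=int)
            for c, parts in out.items()}


def te_metagene(
    annotation: AnnotationSet,
    window_bp: int = 3000,
    bin_bp: int = 100,
) -> tuple[MetageneProfile, MetageneProfile]:
    """TE base-pair density around TSS/TTS (composition, not mutation)."""
    tes = annotation.of_type("TE")
    if not tes:
        raise ValueError("no TEs in annotation")
    positions: dict[str, list[np.ndarray]] = {}
    for te in tes:
        positions.setdefault(te.chrom, []).append(np.arange(te.start, te.end))
    events = {c: np.sort(np.concatenate(parts)) for c, parts in positions.items()}
    return metagene_profile(events, annotation, window_bp, bin_bp)


def profile_correlation(a: MetageneProfile, b: MetageneProfile) -> float:
    """Pearson correlation of two per-bin density profiles."""
    if a.counts.sum() == 0 or b.counts.sum() == 0 or \
            a.density.std() == 0 or b.density.std() == 0:
        return float("nan")
    return float(np.corrcoef(a.density, b.density)[0, 1])


def plot_metagene(profiles: list[MetageneProfile], path: str) -> None:
    """Simple per-anchor density plot (PNG/PDF by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, 4))
    for prof in profiles:
        ax.plot(prof.offsets + prof.bin_bp / 2, prof.density, label=prof.anchor)
    ax.set_xlabel("offset from anchor (bp)")
    ax.set_ylabel("events / bp / gene")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
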