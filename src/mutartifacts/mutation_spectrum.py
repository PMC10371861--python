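"""Mononucleotide and 96-class dinucleotide mutation spectra.

The 96 dinucleotide mutation classes are the single-base transitions between
dinucleotides: 16 source dinucleotides x 2 mutable positions x 3 alternative
bases.  A class is written ``"CA>TA"`` — source dinucleotide to resolved
(post-mutation) dinucleotide.  Counts are normalized by the genomic
occurrence of each source dinucleotide in the evaluated region, giving
per-context mutation rates comparable across call sets and regions.

Flank convention: by default (``flank="both"``) an SNV is counted once in
the class of its 5'-side dinucleotide (second position mutated) and once in
the class of its 3'-side dinucleotide (first position mutated), so all 96
classes are populated and the derived 16x16 dinucleotide rate matrix is
irreducible.  Single-flank conventions (``"three"``/``"five"``) are
available; they populate only the 48 classes of one mutable position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationSet, CallSet, GenomeAssembly

BASES = "ACGT"
DINUCS = [a + b for a in BASES for b in BASES]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _make_class_keys() -> list[str]:
    keys = []
    for src in DINUCS:
        for pos in (0, 1):
            for alt in BASES:
                if alt != src[pos]:
                    tgt = alt + src[1] if pos == 0 else src[0] + alt
                    keys.append(f"{src}>{tgt}")
    return keys


#: The 96 class keys, in fixed (source, position, alternative) order.
CLASS_KEYS = _make_class_keys()
assert len(CLASS_KEYS) == 96


def class_parts(key: str) -> tuple[str, int, str]:
    """(source dinucleotide, mutated position 0/1, resulting base)."""
    src, tgt = key.split(">")
    pos = 0 if src[0] != tgt[0] else 1
    return src, pos, tgt[pos]


def resolved_end(key: str) -> str:
    """The dinucleotide produced by the mutation."""
    return key.split(">")[1]


def reverse_complement_class(key: str) -> str:
    src, tgt = key.split(">")
    rc = lambda d: d.translate(_COMPLEMENT)[::-1]
    return f"{rc(src)}>{rc(tgt)}"


def dinucleotide_counts(
    genome: GenomeAssembly,
    intervals: list[tuple[str, int, int]] | None = None,
) -> pd.Series:
    """Occurrences of each dinucleotide over sliding (overlapping) windows.

    Restricted to the given (chrom, start, end) intervals when supplied;
    windows containing N are skipped, as are windows spanning interval
    boundaries.
    """
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        code[ord(b)] = i
    counts = np.zeros(16, dtype=np.int64)
    if intervals is None:
        intervals = [(chrom, 0, length) for chrom, length in genome.lengths.items()]
    for chrom, start, end in intervals:
        seq = genome.chromosomes[chrom][start:end]
        arr = code[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if len(arr) < 2:
            continue
        first, second = arr[:-1], arr[1:]
        valid = (first >= 0) & (second >= 0)
        idx = first[valid] * 4 + second[valid]
        counts += np.bincount(idx, minlength=16)
    return pd.Series(counts, index=DINUCS, name="context_bp")


@dataclass
class DiSpectrum96:
    """Counts, context occurrences and normalized rates over the 96 classes."""

    counts: pd.Series                  # index: CLASS_KEYS
    context_bp: pd.Series              # index: DINUCS
    flank: str
    n_classified: int
    n_edge_excluded: int
    label: str = ""

    @property
    def normalized_rate(self) -> pd.Series:
        src = pd.Series([k[:2] for k in CLASS_KEYS], index=CLASS_KEYS)
        denom = self.context_bp.reindex(src.values).to_numpy().astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = self.counts.to_numpy() / denom
        return pd.Series(rate, index=CLASS_KEYS, name="normalized_rate")

    @property
    def relative_normalized(self) -> pd.Series:
        rate = self.normalized_rate
        total = np.nansum(rate.to_numpy())
        return rate / total if total else rate

    @property
    def resolved_ends(self) -> pd.Series:
        return pd.Series([resolved_end(k) for k in CLASS_KEYS], index=CLASS_KEYS)

    @property
    def collapsed_counts(self) -> pd.Series:
        """48-class strand-collapsed counts: each class merged with its
        reverse complement (kept separate internally)."""
        merged: dict[str, int] = {}
        for key in CLASS_KEYS:
            canonical = min(key, reverse_complement_class(key))
            merged[canonical] = merged.get(canonical, 0) + int(self.counts[key])
        return pd.Series(merged).sort_index()

    @property
    def share_aa_tt(self) -> float:
        """Percent of relative normalized mutation resolving to AA or TT."""
        rel = self.relative_normalized
        mask = self.resolved_ends.isin(["AA", "TT"])
        return float(np.nansum(rel[mask].to_numpy()) * 100)

    def to_frame(self) -> pd.DataFrame:
        src = [k[:2] for k in CLASS_KEYS]
        return pd.DataFrame({
            "class": CLASS_KEYS,
            "count": self.counts.values,
            "context_bp": self.context_bp.reindex(src).values,
            "normalized_rate": self.normalized_rate.values,
            "resolved_end": self.resolved_ends.values,
        })


@dataclass
class SpectrumComparison:
    chi2: float
    df: int
    p_value: float
    residuals: pd.DataFrame            # per-class standardized residuals, ranked
    share_aa_tt_a: float
    share_aa_tt_b: float
    n_pooled: int


def mono_spectrum(callset: CallSet) -> tuple[pd.Series, pd.Series]:
    """(6-class pyrimidine-collapsed, 12-class raw) SNV counts by ref>alt."""
    twelve = pd.Series(0, index=[f"{r}>{a}" for r in BASES for a in BASES if a != r])
    for call in callset.snvs():
        twelve[f"{call.ref}>{call.alt}"] += 1
    six_keys = [f"{r}>{a}" for r in "CT" for a in BASES if a != r]
    six = pd.Series(0, index=six_keys)
    for key, n in twelve.items():
        r, a = key.split(">")
        if r in "AG":
            r, a = r.translate(_COMPLEMENT), a.translate(_COMPLEMENT)
        six[f"{r}>{a}"] += n
    return six, twelve


def di_spectrum(
    callset: CallSet,
    genome: GenomeAssembly,
    region: list[tuple[str, int, int]] | None = None,
    flank: str = "both",
    label: str | None = None,
) -> DiSpectrum96:
    """Classify SNVs into the 96 dinucleotide mutation classes.

    ``region``: optional (chrom, start, end) intervals restricting both the
    calls and the context normalization.  Calls lacking the needed flanking
    context (chromosome ends, N bases) are excluded and counted.
    """
    if flank not in ("both", "three", "five"):
        raise ValueError(f"unknown flank convention {flank!r}")
    if region is not None and not region:
        raise ValueError("empty region")
    in_region = None
    if region is not None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in region:
            by_chrom.setdefault(chrom, []).append((start, end))
        starts = {c: np.array(sorted(s for s, _ in ivs)) for c, ivs in by_chrom.items()}
        ends = {c: np.array([e for _, e in sorted(ivs)]) for c, ivs in by_chrom.items()}

        def in_region(chrom: str, pos: int) -> bool:
            if chrom not in starts:
                return False
            i = np.searchsorted(starts[chrom], pos, side="right") - 1
            return i >= 0 and pos < ends[chrom][i]

    counts = pd.Series(0, index=CLASS_KEYS, dtype=np.int64)
    n_classified = 0
    n_edge = 0
    for call in callset.snvs():
        if in_region is not None and not in_region(call.chrom, call.pos):
            continue
        seq = genome.chromosomes[call.chrom]
        p = call.pos
        left = seq[p - 1] if p >= 1 else "N"
        right = seq[p + 1] if p + 1 < len(seq) else "N"
        keys = []
        if flank in ("both", "five"):
            if left in BASES:
                keys.append(f"{left}{call.ref}>{left}{call.alt}")
            else:
                keys = None
        if keys is not None and flank in ("both", "three"):
            if right in BASES:
                keys.append(f"{call.ref}{right}>{call.alt}{right}")
            else:
                keys = None
        if keys is None:
            n_edge += 1
            continue
        n_classified += 1
        for key in keys:
            counts[key] += 1
    context = dinucleotide_counts(genome, region)
    return DiSpectrum96(counts=counts, context_bp=context, flank=flank,
                        n_classified=n_classified, n_edge_excluded=n_edge,
                        label=label or callset.label)


def compare_spectra(a: DiSpectrum96, b: DiSpectrum96) -> SpectrumComparison:
    """Two-sample chi-square on the 2 x 96 count table.

    Classes with zero total count are pooled out (reported); with all 96
    classes populated, df = 95.  Per-class standardized (Pearson) residuals
    of call set *a* are ranked to surface the most discrepant classes.
    """
    if a.counts.sum() == 0 or b.counts.sum() == 0:
        raise ValueError("cannot compare an empty spectrum")
    table = pd.DataFrame({"a": a.counts, "b": b.counts})
    nonzero = table.sum(axis=1) > 0
    n_pooled = int((~nonzero).sum())
    table = table[nonzero]
    if table["a"].equals(table["b"]):
        chi2, p, dof = 0.0, 1.0, len(table) - 1
        expected = table.to_numpy(dtype=float).T
    else:
        chi2, p, dof, expected = stats.chi2_contingency(
            table.to_numpy().T, correction=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid_a = (table["a"].to_numpy() - expected[0]) / np.sqrt(expected[0])
    residuals = pd.DataFrame({
        "class": table.index,
        "count_a": table["a"].values,
        "count_b": table["b"].values,
        "std_residual_a": resid_a,
    }).sort_values("std_residual_a", key=np.abs, ascending=False, ignore_index=True)
    return SpectrumComparison(
        chi2=float(chi2), df=int(dof), p_value=float(p), residuals=residuals,
        share_aa_tt_a=a.share_aa_tt, share_aa_tt_b=b.share_aa_tt,
        n_pooled=n_pooled)


def cpg_tpg_rate(
    callset: CallSet,
    genome: GenomeAssembly,
    intervals: list[tuple[str, int, int]],
) -> float:
    """CpG>TpG calls per genomic CG dinucleotide within the intervals.

    Counts C>T calls at the C of a CpG and G>A calls at the G (the same
    event read on the complementary strand).
    """
    context = dinucleotide_counts(genome, intervals)
    n_cg = int(context["CG"])
    if n_cg == 0:
        raise ValueError("region contains no CG dinucleotides")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))

    def inside(chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in by_chrom.get(chrom, []))

    n = 0
    for call in callset.snvs():
        if not inside(call.chrom, call.pos):
            continue
        seq = genome.chromosomes[call.chrom]
        p = call.pos
        if call.ref == "C" and call.alt == "T" and p + 1 < len(seq) and seq[p + 1] == "G":
            n += 1
        elif call.ref == "G" and call.alt == "A" and p >= 1 and seq[p - 1] == "C":
            n += 1
    return n / n_cg


def cpg_tpg_ratio(
    callset: CallSet,
    genome: GenomeAssembly,
    annotation: AnnotationSet,
    region_a: str = "TE",
    region_b: str = "intergenic",
) -> dict:
    """CpG>TpG rate in two region classes and their ratio (a : b).

    Region classes follow the precedence partition, so ``"intergenic"``
    means non-TE, non-centromeric intergenic sequence.
    """
    from .region_rates_metagene import region_intervals
    regions = region_intervals(annotation, genome, classes=(region_a, region_b))
    rate_a = cpg_tpg_rate(callset, genome, regions[region_a])
    rate_b = cpg_tpg_rate(callset, genome, regions[region_b])
    return {"rate_" + region_a: rate_a, "rate_" + region_b: rate_b,
            "ratio": rate_a / rate_b if rate_b else float("inf")}
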