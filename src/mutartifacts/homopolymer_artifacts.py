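"""Homopolymer-run detection and bleed-artifact classification.

In Illumina short-read data a base within or near a homopolymeric run can be
mis-read as the run's base ("bleed"), e.g. AAAGAAA read as AAAAAAA, or AAAAC
read as AAAAA.  This module finds maximal single-base runs, classifies calls
as bleed-type (alt allele equal to the base of a nearby A/T run), resolves
same-read bleed clusters (AAAAACACACA read as AAAAAAAAAAA yields three
putative mutations on one run), fits the run-length error regression, and
tabulates the decay of bleed rate with distance from the run end.

Distance convention: a call inside a run has distance 0 and adjacency
``within``; a call touching the run's boundary base has distance 0 and
adjacency ``adjacent``; otherwise distance counts the bases separating the
call from the run, adjacency ``nearby``.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationSet, CallSet, GenomeAssembly, MutationCall

AT_BASES = {"A", "T"}


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of one base; [start, end) 0-based half-open."""

    chrom: str
    start: int
    end: int
    base: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def klass(self) -> str:
        return "AT" if self.base in AT_BASES else "GC"


@dataclass
class BleedCall:
    """A call attributed to a homopolymer run as a putative bleed artifact."""

    call: MutationCall
    run: HomopolymerRun
    distance: int
    adjacency: str  # within | adjacent | nearby
    in_bleed_cluster: bool = False


@dataclass
class RunLengthRegression:
    """OLS of log10(calls per bp of run sequence) on run length, bin-level."""

    lengths: list[int]
    log10_rate: list[float]
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    df: int
    dropped_bins: list[int] = field(default_factory=list)


def find_runs(genome: GenomeAssembly, min_run_length: int = 4) -> list[HomopolymerRun]:
    """All maximal single-base runs of length >= min_run_length, sorted."""
    if min_run_length < 2:
        raise ValueError("min_run_length must be >= 2")
    pattern = re.compile(
        "|".join(f"{b}{{{min_run_length},}}" for b in "ACGT"))
    runs = []
    for chrom in sorted(genome.chromosomes):
        seq = genome.chromosomes[chrom]
        for m in pattern.finditer(seq):
            runs.append(HomopolymerRun(chrom, m.start(), m.end(), m.group()[0]))
    return runs


def _run_distance(run: HomopolymerRun, pos: int) -> tuple[int, str]:
    if run.start <= pos < run.end:
        return 0, "within"
    if pos < run.start:
        d = run.start - pos - 1
    else:
        d = pos - run.end
    return d, ("adjacent" if d == 0 else "nearby")


class _RunIndex:
    """Per-chromosome sorted run starts for nearest-run queries."""

    def __init__(self, runs: list[HomopolymerRun]):
        self._by_chrom: dict[str, tuple[list[int], list[HomopolymerRun]]] = {}
        for chrom in {r.chrom for r in runs}:
            rs = sorted((r for r in runs if r.chrom == chrom), key=lambda r: r.start)
            self._by_chrom[chrom] = ([r.start for r in rs], rs)

    def candidates(self, chrom: str, pos: int, window: int) -> list[HomopolymerRun]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, rs = entry
        lo = bisect_left(starts, pos - window - 1)
        out = []
        for r in rs[max(0, lo - 50):]:
            if r.start > pos + window + 1:
                break
            d, _ = _run_distance(r, pos)
            if d <= window:
                out.append(r)
        return out


def _bleed_base(call: MutationCall) -> str | None:
    """The base the call would add to a run, or None if not a candidate.

    SNVs bleed through their alt allele; single-base indels through the
    inserted or deleted base.
    """
    if call.var_class == "SNV":
        return call.alt
    if call.var_class == "insertion" and len(call.alt) == len(call.ref) + 1:
        return call.alt[len(call.ref):]
    if call.var_class == "deletion" and len(call.ref) == len(call.alt) + 1:
        return call.ref[len(call.alt):]
    return None


def classify_bleed(
    callset: CallSet,
    runs: list[HomopolymerRun],
    proximity_window: int = 5,
    allele_match: bool = True,
    annotation: AnnotationSet | None = None,
) -> tuple[list[BleedCall], dict]:
    """Classify calls as bleed-type artifacts near A/T homopolymer runs.

    A call is bleed-type iff an A/T run whose boundary lies within
    ``proximity_window`` bp has base equal to the call's bleeding base
    (alt allele for SNVs, the inserted/deleted base for 1-bp indels).
    The nearest qualifying run is recorded; ties go to the lower start
    coordinate.  The summary separately reports the fraction of calls that
    would qualify against G/C runs, and per-region-class fractions when an
    annotation is supplied.
    """
    at_index = _RunIndex([r for r in runs if r.klass == "AT"])
    gc_index = _RunIndex([r for r in runs if r.klass == "GC"])

    def best_run(index: _RunIndex, call: MutationCall) -> tuple[HomopolymerRun, int, str] | None:
        base = _bleed_base(call)
        if base is None:
            return None
        best = None
        for r in index.candidates(call.chrom, call.pos, proximity_window):
            if allele_match and r.base != base:
                continue
            d, adj = _run_distance(r, call.pos)
            cand = (d, r.start, r, adj)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None:
            return None
        return best[2], best[0], best[3]

    bleed: list[BleedCall] = []
    n_gc = 0
    n_bleed_snv = 0
    for call in callset:
        hit = best_run(at_index, call)
        if hit is not None:
            run, d, adj = hit
            bleed.append(BleedCall(call, run, d, adj))
            if call.var_class == "SNV":
                n_bleed_snv += 1
        if best_run(gc_index, call) is not None:
            n_gc += 1

    n = len(callset)
    n_snv = len(callset.snvs())
    summary = {
        "n_calls": n,
        "n_bleed": len(bleed),
        "bleed_fraction": len(bleed) / n if n else 0.0,
        "n_bleed_snv": n_bleed_snv,
        "bleed_fraction_snv_only": n_bleed_snv / n_snv if n_snv else 0.0,
        "near_gc_fraction": n_gc / n if n else 0.0,
        "proximity_window": proximity_window,
    }
    if annotation is not None:
        from .region_rates_metagene import assign_region
        per_region_total: dict[str, int] = {}
        per_region_bleed: dict[str, int] = {}
        bleed_keys = {bc.call.key() for bc in bleed}
        for call in callset:
            region = assign_region(call.chrom, call.pos, annotation)
            per_region_total[region] = per_region_total.get(region, 0) + 1
            if call.key() in bleed_keys:
                per_region_bleed[region] = per_region_bleed.get(region, 0) + 1
        summary["bleed_fraction_by_region"] = {
            region: per_region_bleed.get(region, 0) / total
            for region, total in sorted(per_region_total.items())
        }
    return bleed, summary


def bleed_cluster_resolution(
    bleed_calls: list[BleedCall], proximity_window: int = 5
) -> tuple[list[BleedCall], dict]:
    """Flag bleed calls that cluster on the same run with the same alt.

    Calls sharing a run and a bleeding base, chained by consecutive distance
    <= proximity_window, form a cluster when the group has >= 2 members
    (the AAAAACACACA -> AAAAAAAAAAA read gives three such calls).  Counts
    report the within/adjacent calls, the remaining (nearby) calls, and how
    many of the remaining ones cluster.
    """
    groups: dict[tuple, list[BleedCall]] = {}
    for bc in bleed_calls:
        key = (bc.run.chrom, bc.run.start, bc.run.end, _bleed_base(bc.call))
        groups.setdefault(key, []).append(bc)
    for members in groups.values():
        members.sort(key=lambda bc: bc.call.pos)
        chain = [members[0]]
        chains = [chain]
        for bc in members[1:]:
            if bc.call.pos - chain[-1].call.pos <= proximity_window:
                chain.append(bc)
            else:
                chain = [bc]
                chains.append(chain)
        for c in chains:
            if len(c) >= 2:
                for bc in c:
                    bc.in_bleed_cluster = True
    n_within_adjacent = sum(1 for bc in bleed_calls if bc.distance == 0)
    remaining = [bc for bc in bleed_calls if bc.distance > 0]
    counts = {
        "n_bleed": len(bleed_calls),
        "n_within_or_adjacent": n_within_adjacent,
        "pct_within_or_adjacent": round(
            100 * n_within_adjacent / len(bleed_calls), 1) if bleed_calls else 0.0,
        "n_remaining": len(remaining),
        "n_clustered_remaining": sum(1 for bc in remaining if bc.in_bleed_cluster),
    }
    return bleed_calls, counts


def run_length_regression(
    bleed_calls: list[BleedCall],
    runs: list[HomopolymerRun],
    lengths: list[int] | None = None,
    annotation: AnnotationSet | None = None,
    region_class: str | None = None,
) -> RunLengthRegression:
    """Regress log10(bleed calls per bp of run sequence) on run length.

    One observation per run-length bin: rate = calls attributed to runs of
    that length / total bp in runs of that length.  Unweighted OLS, as the
    bin-level degrees of freedom (n_bins - 2) imply.  Zero-call bins are
    dropped and reported.  Optionally restricted to a region class (runs by
    midpoint, calls follow their runs).
    """
    at_runs = [r for r in runs if r.klass == "AT"]
    if annotation is not None and region_class is not None:
        from .region_rates_metagene import assign_region
        at_runs = [
            r for r in at_runs
            if assign_region(r.chrom, (r.start + r.end) // 2, annotation) == region_class
        ]
    kept = {(r.chrom, r.start, r.end) for r in at_runs}
    bp_by_length: dict[int, int] = {}
    for r in at_runs:
        bp_by_length[r.length] = bp_by_length.get(r.length, 0) + r.length
    calls_by_length: dict[int, int] = {}
    for bc in bleed_calls:
        if (bc.run.chrom, bc.run.start, bc.run.end) in kept:
            calls_by_length[bc.run.length] = calls_by_length.get(bc.run.length, 0) + 1
    if lengths is None:
        lengths = sorted(bp_by_length)
    usable, dropped, log_rates = [], [], []
    for length in lengths:
        bp = bp_by_length.get(length, 0)
        n = calls_by_length.get(length, 0)
        if bp == 0 or n == 0:
            dropped.append(length)
            continue
        usable.append(length)
        log_rates.append(math.log10(n / bp))
    if len(usable) < 3:
        raise ValueError(f"only {len(usable)} usable run-length bins; need >= 3")
    fit = stats.linregress(usable, log_rates)
    return RunLengthRegression(
        lengths=usable,
        log10_rate=log_rates,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        df=len(usable) - 2,
        dropped_bins=dropped,
    )


def distance_decay(bleed_calls: list[BleedCall], proximity_window: int = 5) -> pd.DataFrame:
    """Counts and rates of bleed calls per distance from the run boundary,
    with a Spearman monotonic-decay check.

    Returns a DataFrame with columns distance, count, rate and attrs
    ``spearman_rho``/``spearman_p`` (rate vs distance).
    """
    counts = np.zeros(proximity_window + 1, dtype=int)
    for bc in bleed_calls:
        if bc.distance <= proximity_window:
            counts[bc.distance] += 1
    total = counts.sum()
    table = pd.DataFrame({
        "distance": np.arange(proximity_window + 1),
        "count": counts,
        "rate": counts / total if total else np.zeros_like(counts, dtype=float),
    })
    if total and counts.std() > 0:
        rho, p = stats.spearmanr(table["distance"], table["count"])
    else:
        rho, p = float("nan"), float("nan")
    table.attrs["spearman_rho"] = float(rho)
    table.attrs["spearman_p"] = float(p)
    return table
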