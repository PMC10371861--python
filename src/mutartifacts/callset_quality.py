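"""Conventional quality filtering and call-set concordance classification.

Robust mutation calling requires multiple supporting reads on both strands
and rejects variants recurring across implausibly many samples.  This module
applies such a policy and classifies one call set against another into
concordant, uncallable (the call's own evidence fails the policy) and
discordant-but-callable — partitioning the query exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io_formats import CallSet, MutationCall


@dataclass(frozen=True)
class FilterPolicy:
    """Strand/support/recurrence thresholds for a conventional call filter.

    Unknown strand support (None) fails any strand requirement > 0.
    """

    min_support_per_strand: int = 2
    min_total_support: int = 4
    max_samples_sharing: int = 10

    def __post_init__(self):
        for name in ("min_support_per_strand", "min_total_support",
                     "max_samples_sharing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ConcordanceReport:
    n_query: int
    n_concordant: int
    n_uncallable: int
    n_discordant_callable: int
    pct_concordant: float
    pct_uncallable: float
    hq_set: CallSet
    lq_set: CallSet


def _passes_evidence(call: MutationCall, policy: FilterPolicy) -> bool:
    f, r = call.fwd_support, call.rev_support
    if policy.min_support_per_strand > 0 and (f is None or r is None):
        return False
    if (f or 0) < policy.min_support_per_strand:
        return False
    if (r or 0) < policy.min_support_per_strand:
        return False
    total = (f or 0) + (r or 0)
    if policy.min_total_support > 0 and (f is None or r is None):
        return False
    return total >= policy.min_total_support


def _site_sample_counts(callset: CallSet) -> Counter:
    counts: Counter = Counter()
    for call in callset:
        counts[call.site_key()] += 1  # callsets are duplicate-free per sample
    return counts


def call_passes(call: MutationCall, policy: FilterPolicy,
                site_counts: Counter) -> bool:
    if not _passes_evidence(call, policy):
        return False
    if policy.max_samples_sharing > 0 and \
            site_counts[call.site_key()] > policy.max_samples_sharing:
        return False
    return True


def apply_filter(callset: CallSet, policy: FilterPolicy
                 ) -> tuple[CallSet, CallSet]:
    """Partition a call set into (passing, failing) under the policy."""
    site_counts = _site_sample_counts(callset)
    passing, failing = [], []
    for call in callset:
        (passing if call_passes(call, policy, site_counts) else failing).append(call)
    return (CallSet(f"{callset.label}-pass", passing),
            CallSet(f"{callset.label}-fail", failing))


def classify_concordance(
    query: CallSet,
    reference: CallSet,
    policy: FilterPolicy | None = None,
    ignore_sample: bool = False,
) -> ConcordanceReport:
    """Classify query calls against a reference call set.

    A query call is *concordant* iff an identical call (including sample id,
    unless ``ignore_sample``) exists in the reference and passes the policy
    there; *uncallable* iff the query call's own evidence fails the policy;
    the remainder are *discordant-but-callable*.  HQ = concordant calls,
    LQ = the rest; together they partition the query exactly.
    """
    policy = policy or FilterPolicy()
    q_chroms = {c.chrom for c in query}
    r_chroms = {c.chrom for c in reference}
    if query.calls and reference.calls and not (q_chroms & r_chroms):
        raise ValueError(
            f"mismatched chromosome namespaces: query {sorted(q_chroms)[:3]} vs "
            f"reference {sorted(r_chroms)[:3]}")
    ref_site_counts = _site_sample_counts(reference)
    query_site_counts = _site_sample_counts(query)
    keyfn = (lambda c: c.site_key()) if ignore_sample else (lambda c: c.key())
    ref_passing = {keyfn(c) for c in reference
                   if call_passes(c, policy, ref_site_counts)}
    hq, lq = [], []
    n_concordant = n_uncallable = n_discordant = 0
    for call in query:
        if keyfn(call) in ref_passing:
            n_concordant += 1
            hq.append(call)
        else:
            lq.append(call)
            if not call_passes(call, policy, query_site_counts):
                n_uncallable += 1
            else:
                n_discordant += 1
    n = len(query)
    return ConcordanceReport(
        n_query=n,
        n_concordant=n_concordant,
        n_uncallable=n_uncallable,
        n_discordant_callable=n_discordant,
        pct_concordant=round(100 * n_concordant / n, 1) if n else 0.0,
        pct_uncallable=round(100 * n_uncallable / n, 1) if n else 0.0,
        hq_set=CallSet(f"{query.label}-hq", hq),
        lq_set=CallSet(f"{query.label}-lq", lq),
    )
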