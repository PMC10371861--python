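"""Mis-mapping fingerprints: clustered calls, multi-sample recurrence, and
centromere enrichment.

Incorrect mapping of short reads produces locus-level artifacts: several
putative mutations packed within a few base pairs, the identical variant
surfacing in implausibly many samples, and an excess of calls in
repeat-dense centromeric regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import AnnotationSet, CallSet, MutationCall


@dataclass
class ClusterReport:
    window: int
    sample_threshold: int
    clusters: list[list[MutationCall]] = field(default_factory=list)
    pct_clustered: float = 0.0
    pct_recurrent: float = 0.0
    pct_centromeric: float = float("nan")
    pct_clustered_or_recurrent: float = 0.0  # exclusive union of the two flags
    recurrent_sites: list[tuple] = field(default_factory=list)


def find_clusters(callset: CallSet, window: int = 10,
                  per_sample: bool = False) -> tuple[list[list[MutationCall]], float]:
    """Maximal chains of calls with consecutive positions <= window bp apart.

    Chains need >= 2 members to count as a cluster.  By default clustering is
    across samples (mis-mapping affects a locus, not a sample);
    ``per_sample`` restricts chains to calls from one sample.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    groups: dict[tuple, list[MutationCall]] = {}
    for call in callset:
        key = (call.chrom, call.sample_id) if per_sample else (call.chrom,)
        groups.setdefault(key, []).append(call)
    clusters: list[list[MutationCall]] = []
    for members in groups.values():
        members.sort(key=lambda c: c.pos)
        chain = [members[0]]
        for call in members[1:]:
            if call.pos - chain[-1].pos <= window:
                chain.append(call)
            else:
                if len({c.pos for c in chain}) >= 2:
                    clusters.append(chain)
                chain = [call]
        if len({c.pos for c in chain}) >= 2:
            clusters.append(chain)
    n_clustered = sum(len(c) for c in clusters)
    pct = 100 * n_clustered / len(callset) if len(callset) else 0.0
    return clusters, pct


def find_recurrent(callset: CallSet, sample_threshold: int = 10
                   ) -> tuple[list[tuple], float]:
    """Sites whose identical (chrom, pos, ref, alt) occurs in strictly more
    than ``sample_threshold`` distinct samples."""
    samples_by_site: dict[tuple, set[str]] = {}
    for call in callset:
        samples_by_site.setdefault(call.site_key(), set()).add(call.sample_id)
    flagged = sorted(site for site, samples in samples_by_site.items()
                     if len(samples) > sample_threshold)
    flagged_set = set(flagged)
    n_recurrent = sum(1 for c in callset if c.site_key() in flagged_set)
    pct = 100 * n_recurrent / len(callset) if len(callset) else 0.0
    return flagged, pct


def region_fraction(callset: CallSet, annotation: AnnotationSet,
                    feature_type: str) -> float:
    """Percent of calls inside any interval of the feature type (1 decimal)."""
    if feature_type not in annotation.feature_types():
        raise ValueError(f"feature type {feature_type!r} absent from annotation")
    if not len(callset):
        return 0.0
    n_inside = sum(1 for c in callset
                   if annotation.contains(c.chrom, c.pos, feature_type))
    return round(100 * n_inside / len(callset), 1)


def analyze_clusters(
    callset: CallSet,
    annotation: AnnotationSet | None = None,
    window: int = 10,
    sample_threshold: int = 10,
    per_sample: bool = False,
) -> ClusterReport:
    """Full mis-mapping report: clusters, recurrence, centromere fraction,
    plus the exclusive clustered-or-recurrent union (a call with both
    fingerprints is counted once)."""
    clusters, pct_clustered = find_clusters(callset, window, per_sample)
    recurrent_sites, pct_recurrent = find_recurrent(callset, sample_threshold)
    report = ClusterReport(window=window, sample_threshold=sample_threshold,
                           clusters=clusters, pct_clustered=pct_clustered,
                           pct_recurrent=pct_recurrent,
                           recurrent_sites=recurrent_sites)
    if len(callset):
        clustered_keys = {c.key() for chain in clusters for c in chain}
        recurrent_set = set(recurrent_sites)
        n_either = sum(1 for c in callset
                       if c.key() in clustered_keys or c.site_key() in recurrent_set)
        report.pct_clustered_or_recurrent = 100 * n_either / len(callset)
    if annotation is not None and "centromere" in annotation.feature_types():
        report.pct_centromeric = region_fraction(callset, annotation, "centromere")
    return report
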