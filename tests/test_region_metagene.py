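"""Region-stratified rates, paired tests, gene classes, metagene profiles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mutartifacts import (
    CallSet,
    MutationCall,
    find_runs,
    gene_class_rates,
    metagene_profile,
    paired_rate_test,
    region_rates,
    simulate_homopolymer_errors,
    te_metagene,
)
from mutartifacts.region_rates_metagene import (
    assign_region,
    profile_correlation,
    region_label_arrays,
)


# ---------------------------------------------------------------------------
# region partition and rates


def test_region_labels_partition_every_base(small_sim):
    labels = region_label_arrays(small_sim.annotation, small_sim.genome)
    total = sum(len(arr) for arr in labels.values())
    assert total == small_sim.genome.total_bp()


def test_assign_region_follows_precedence(small_sim):
    cds = next(iv for iv in small_sim.annotation.of_type("CDS"))
    assert assign_region(cds.chrom, cds.start, small_sim.annotation) == "CDS"
    te = next(iv for iv in small_sim.annotation.of_type("TE"))
    assert assign_region(te.chrom, te.start, small_sim.annotation) == "TE"


def test_region_rates_partition_calls_and_bp(default_sim):
    table = region_rates(default_sim.observed, default_sim.annotation,
                         default_sim.genome, with_spectra=False)
    assert table.table["n_calls"].sum() == len(default_sim.observed)
    assert table.table["bp"].sum() == default_sim.genome.total_bp()


def test_unannotated_chromosome_rejected(small_sim):
    stray = CallSet("x", [MutationCall("chrZ", 5, "A", "T", "S1", 3, 3)])
    with pytest.raises(ValueError, match="unannotated"):
        region_rates(stray, small_sim.annotation, small_sim.genome,
                     with_spectra=False)


def test_intron_cds_ratio_null_and_artifact_inflation(default_sim):
    """True mutations give intron:CDS near 1; adding bleed errors (runs are
    enriched in introns) inflates the ratio well above the truth-only one."""
    truth = region_rates(default_sim.truth, default_sim.annotation,
                         default_sim.genome, with_spectra=False)
    observed = region_rates(default_sim.observed, default_sim.annotation,
                            default_sim.genome, with_spectra=False)
    assert 0.85 <= truth.intron_cds_ratio <= 1.15
    assert observed.intron_cds_ratio > 1.2
    assert observed.intron_cds_ratio > truth.intron_cds_ratio


def test_empty_region_class_is_flagged():
    cfg_calls = CallSet("none", [])
    # reuse a tiny genome: all classes have zero calls -> flagged
    from mutartifacts.synthetic_data import SimulationConfig, generate_genome
    cfg = SimulationConfig(seed=2, n_chromosomes=1, chrom_length=60_000,
                           n_genes=5, n_true_mutations=0, n_bleed_errors=0,
                           n_cluster_errors=0, n_recurrent_errors=0)
    genome, ann = generate_genome(cfg)
    table = region_rates(cfg_calls, ann, genome, with_spectra=False)
    assert table.table["empty"].all()
    assert (table.table["rate"] == 0).all()


# ---------------------------------------------------------------------------
# paired rate test


def test_identical_vectors_give_t0_ratio1():
    v = pd.Series(np.linspace(1e-5, 1e-3, 96), index=range(96))
    t = paired_rate_test(v, v)
    assert t.t_statistic == 0.0 and t.p_value == 1.0
    assert t.mean_ratio == pytest.approx(1.0)
    assert t.df == 95      # 96 usable classes


def test_zero_denominator_classes_are_excluded():
    a = pd.Series(np.ones(96), index=range(96))
    b = a.copy()
    b.iloc[:10] = 0.0
    t = paired_rate_test(a, b)
    assert t.df == 85 and t.n_excluded == 10


def test_too_few_usable_classes_rejected():
    a = pd.Series(np.ones(8)), pd.Series(np.ones(8))
    with pytest.raises(ValueError, match="usable"):
        paired_rate_test(*a)


def test_te_multiplier_recovered_by_paired_test(default_sim):
    """TE regions carry a 4x mutation weight; the paired test on the
    96-class normalized rates recovers it."""
    table = region_rates(default_sim.truth, default_sim.annotation,
                         default_sim.genome)
    t = paired_rate_test(table.spectra["TE"].normalized_rate,
                         table.spectra["intergenic"].normalized_rate)
    assert 3.2 <= t.ratio_of_means <= 5.0
    assert 3.0 <= t.mean_ratio <= 6.0      # per-class ratios are noise-inflated
    assert t.p_value < 1e-3


# ---------------------------------------------------------------------------
# gene-class heterogeneity


def test_calls_proportional_to_bp_give_zero_chi2(small_sim):
    """Two calls in every gene's first exon: observed exactly proportional
    to class bp (all genes have equal CDS bp), so chi2 ~ 0."""
    calls = []
    for i, gene in enumerate(small_sim.annotation.of_type("gene")):
        exon = min((iv for iv in small_sim.annotation.of_type("CDS")
                    if iv.attributes.get("Parent") == gene.attributes["ID"]),
                   key=lambda iv: iv.start)
        for j, offset in enumerate((3, 7)):
            ref = small_sim.genome.base(gene.chrom, exon.start + offset)
            alt = "A" if ref != "A" else "C"
            calls.append(MutationCall(gene.chrom, exon.start + offset, ref, alt,
                                      f"S{j}", 3, 3))
    report = gene_class_rates(CallSet("prop", calls), small_sim.annotation)
    assert report.chi2 == pytest.approx(0.0, abs=1e-9)
    assert report.p_value == pytest.approx(1.0)
    assert report.df == 3


def test_gene_class_report_df3_and_small_count_flag(default_sim):
    report = gene_class_rates(default_sim.truth, default_sim.annotation,
                              feature="CDS")
    assert report.df == 3
    assert not report.small_counts
    assert set(report.table["class"]) == {"essential", "morphological",
                                          "cellular_biochemical", "environmental"}
    tiny = CallSet("tiny", list(default_sim.truth)[:8])
    tiny_report = gene_class_rates(tiny, default_sim.annotation, feature="CDS")
    assert tiny_report.small_counts


def test_doubled_essential_rate_is_detected(default_sim):
    """Power check: doubling the essential-gene rate trips the chi-square."""
    from mutartifacts.synthetic_data import generate_true_mutations
    cfg = dataclasses.replace(default_sim.config, essential_rate_multiplier=2.0)
    truth, _ = generate_true_mutations(default_sim.genome, default_sim.annotation,
                                       cfg, np.random.default_rng([77, 1]), set())
    report = gene_class_rates(truth, default_sim.annotation, feature="CDS")
    assert report.p_value < 0.05
    rates = report.table.set_index("class")["rate"]
    assert rates["essential"] > 1.5 * rates["morphological"]


# ---------------------------------------------------------------------------
# metagene profiles


def test_uniform_events_give_flat_profile(default_sim):
    rng = np.random.default_rng(3)
    events = {c: np.sort(rng.integers(0, l, size=40_000))
              for c, l in default_sim.genome.lengths.items()}
    tss, tts = metagene_profile(events, default_sim.annotation, 3000, 300)
    for prof in (tss, tts):
        rel_spread = prof.density.std() / prof.density.mean()
        assert rel_spread < 0.15


def test_events_inside_gene_bodies_leave_upstream_empty():
    from mutartifacts import AnnotationSet, GenomicInterval
    ann = AnnotationSet([GenomicInterval("chr1", 10_000, 12_000, "+", "gene",
                                         {"ID": "g1"})])
    events = {"chr1": np.arange(10_000, 12_000, 50)}
    tss, tts = metagene_profile(events, ann, 3000, 100)
    upstream = tss.density[tss.offsets < 0]
    assert (upstream == 0).all()
    assert tss.density[tss.offsets >= 0].sum() > 0


def test_minus_strand_gene_orientation_flip():
    from mutartifacts import AnnotationSet, GenomicInterval
    ann = AnnotationSet([GenomicInterval("chr1", 5_000, 7_000, "-", "gene",
                                         {"ID": "g1"})])
    # 10 bp 5' of a minus-strand TSS means 10 bp to the *right* of end-1
    tss_pos = 7_000 - 1
    tss, _ = metagene_profile({"chr1": np.array([tss_pos + 10])}, ann, 3000, 100)
    bin_of = np.flatnonzero(tss.counts)[0]
    assert tss.offsets[bin_of] == -100      # the [-100, 0) bin
    assert tss.counts.sum() == 1


def test_profile_conservation_invariant(small_sim):
    tss, tts = metagene_profile(list(small_sim.observed), small_sim.annotation,
                                2000, 100)
    for prof in (tss, tts):
        assert np.allclose(prof.density * prof.bin_bp * prof.n_anchors,
                           prof.counts)


def test_window_must_hold_bins():
    with pytest.raises(ValueError):
        metagene_profile({"chr1": np.array([5])}, None, 50, 100)


# ---------------------------------------------------------------------------
# simulated homopolymer errors


def test_zero_slope_spreads_errors_per_run_bp(default_sim, default_runs):
    positions = simulate_homopolymer_errors(default_sim.genome, default_runs,
                                            50_000, 0.0, seed=5)
    n = sum(len(p) for p in positions.values())
    assert n == 50_000
    at = [r for r in default_runs if r.klass == "AT"]
    # errors near runs of length L in proportion to total bp at L
    bp_by_len, hits_by_len = {}, {}
    run_arr = {c: [] for c in default_sim.genome.chromosomes}
    for r in at:
        bp_by_len[r.length] = bp_by_len.get(r.length, 0) + r.length
        run_arr[r.chrom].append(r)
    for chrom, rs in run_arr.items():
        starts = np.array([r.start for r in rs])
        for p in positions[chrom]:
            i = np.searchsorted(starts, p) - 1
            for r in rs[max(0, i):i + 2]:
                if r.start - 7 <= p <= r.end + 6:
                    hits_by_len[r.length] = hits_by_len.get(r.length, 0) + 1
                    break
    total_bp = sum(bp_by_len.values())
    for L, bp in bp_by_len.items():
        expected = n * bp / total_bp
        assert abs(hits_by_len.get(L, 0) - expected) < 6 * np.sqrt(expected)


def test_fixed_seed_reproduces_positions(default_sim, default_runs):
    a = simulate_homopolymer_errors(default_sim.genome, default_runs, 5000,
                                    0.27, seed=9)
    b = simulate_homopolymer_errors(default_sim.genome, default_runs, 5000,
                                    0.27, seed=9)
    assert all(np.array_equal(a[c], b[c]) for c in a)


def test_no_runs_rejected(small_sim):
    with pytest.raises(ValueError, match="runs"):
        simulate_homopolymer_errors(small_sim.genome, [], 100, 0.27, seed=1)


def test_te_density_enriched_outside_gene_bodies(default_sim):
    tss, tts = te_metagene(default_sim.annotation, 3000, 100)
    gene_len = 2100  # synthetic gene span
    inside_tss = tss.density[(tss.offsets >= 0) & (tss.offsets < gene_len - 100)]
    upstream = tss.density[tss.offsets < -200]
    assert upstream.mean() > 3 * max(inside_tss.mean(), 1e-9)
    downstream_tts = tts.density[tts.offsets >= 200]
    inside_tts = tts.density[(tts.offsets < 0) & (tts.offsets > -gene_len + 100)]
    assert downstream_tts.mean() > 3 * max(inside_tts.mean(), 1e-9)


def test_te_profile_predicts_truth_call_excess_outside_genes(default_sim):
    """TE positions carry the elevated mutation weight, so the TE composition
    profile correlates positively with the truth-call metagene."""
    te_tss, _ = te_metagene(default_sim.annotation, 3000, 100)
    call_tss, _ = metagene_profile(list(default_sim.truth),
                                   default_sim.annotation, 3000, 100)
    r = np.corrcoef(te_tss.density, call_tss.density)[0, 1]
    assert r > 0.3


def test_no_tes_rejected():
    from mutartifacts import AnnotationSet, GenomicInterval
    ann = AnnotationSet([GenomicInterval("chr1", 0, 100, "+", "gene")])
    with pytest.raises(ValueError, match="TE"):
        te_metagene(ann)
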