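"""Run detection, bleed classification, clustering, regression and decay."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mutartifacts import (
    CallSet,
    GenomeAssembly,
    MutationCall,
    bleed_cluster_resolution,
    classify_bleed,
    distance_decay,
    find_runs,
    run_length_regression,
)
from mutartifacts.homopolymer_artifacts import BleedCall, HomopolymerRun


def _brute_force_runs(seq, min_len):
    """Independent oracle: scan every position for maximal runs."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] in "ACGT":
            runs.append((i, j, seq[i]))
        i = j
    return runs


def test_find_runs_simple_and_boundary_cases():
    genome = GenomeAssembly({"chr1": "CCAAAAGG", "chr2": "AAAA"})
    runs = find_runs(genome, 4)
    assert [(r.chrom, r.start, r.end, r.base) for r in runs] == [
        ("chr1", 2, 6, "A"), ("chr2", 0, 4, "A")]
    assert runs[0].klass == "AT" and runs[0].length == 4


def test_find_runs_rejects_min_length_below_two():
    with pytest.raises(ValueError):
        find_runs(GenomeAssembly({"c": "AAAA"}), 1)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 6))
def test_find_runs_matches_brute_force_oracle(seed, min_len):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGTN"), size=10_000,
                             p=[0.3, 0.18, 0.18, 0.3, 0.04]))
    genome = GenomeAssembly({"chr1": seq})
    got = [(r.start, r.end, r.base) for r in find_runs(genome, min_len)]
    assert got == _brute_force_runs(seq, min_len)


# ---------------------------------------------------------------------------
# bleed classification


def _classify_one(seq, pos, ref, alt, window=5, min_len=4, allele_match=True):
    genome = GenomeAssembly({"chr1": seq})
    runs = find_runs(genome, min_len)
    cs = CallSet("x", [MutationCall("chr1", pos, ref, alt, "S1", 3, 3)])
    bleed, summary = classify_bleed(cs, runs, window, allele_match=allele_match)
    return bleed, summary


def test_interrupting_base_between_runs_is_bleed_at_distance_zero():
    # AAAAGAAAA read as AAAAAAAAA: the G is called G>A, touching both runs
    bleed, _ = _classify_one("CCC" + "AAAAGAAAA" + "CCC", 7, "G", "A")
    assert len(bleed) == 1
    assert bleed[0].distance == 0 and bleed[0].adjacency == "adjacent"


def test_base_adjacent_to_run_is_bleed():
    # AAAAC read as AAAAA: the C is called C>A at the run boundary
    bleed, _ = _classify_one("GGG" + "AAAAC" + "GGG", 7, "C", "A")
    assert len(bleed) == 1
    assert bleed[0].distance == 0
    assert (bleed[0].run.start, bleed[0].run.end) == (3, 7)


def test_call_far_from_any_run_is_not_bleed():
    seq = "AAAA" + "C" * 30 + "TGCTG"
    bleed, summary = _classify_one(seq, 24, "C", "T")
    assert bleed == [] and summary["n_bleed"] == 0


def test_allele_identity_required_unless_relaxed():
    seq = "GGG" + "AAAAC" + "GGG"
    bleed, _ = _classify_one(seq, 7, "C", "G")   # alt is not the run base
    assert bleed == []
    bleed, _ = _classify_one(seq, 7, "C", "G", allele_match=False)
    assert len(bleed) == 1


def test_single_base_indel_bleeds_through_inserted_base():
    seq = "GGG" + "AAAA" + "CGGGG"
    genome = GenomeAssembly({"chr1": seq})
    runs = find_runs(genome, 4)
    ins = MutationCall("chr1", 6, "A", "AA", "S1", 3, 3)     # A-insertion in run
    dele = MutationCall("chr1", 6, "AC", "A", "S1", 3, 3)    # deletes the C
    bleed, _ = classify_bleed(CallSet("x", [ins]), runs, 5)
    assert len(bleed) == 1 and bleed[0].adjacency == "within"
    bleed, _ = classify_bleed(CallSet("x", [dele]), runs, 5)
    assert len(bleed) == 0  # deleted base C is not the run base


def test_nearest_run_tie_breaks_to_lower_coordinate():
    seq = "AAAA" + "C" + "AAAA"
    bleed, _ = _classify_one(seq, 4, "C", "A")
    assert len(bleed) == 1
    assert bleed[0].run.start == 0  # equidistant: lower start wins


def test_gc_runs_are_tallied_separately_not_as_bleed():
    seq = "TAT" + "GGGG" + "C" + "TATAT"
    bleed, summary = _classify_one(seq, 7, "C", "G")
    assert bleed == []
    assert summary["near_gc_fraction"] == 1.0


def test_bleed_fraction_recovers_ledger_within_binomial_error(default_sim,
                                                              default_runs):
    bleed, summary = classify_bleed(default_sim.observed, default_runs, 5)
    n = len(default_sim.observed)
    injected = default_sim.ledger.counts["bleed_error"] / n
    sd = math.sqrt(injected * (1 - injected) / n)
    # classification may only add non-injected calls that fall near runs
    assert summary["bleed_fraction"] >= injected - 1e-12
    assert summary["bleed_fraction"] <= injected + max(4 * sd, 0.02)


def test_every_injected_bleed_call_is_recalled(default_sim, default_runs):
    """Injected bleed lies within the window by construction: recall 100%."""
    bleed, _ = classify_bleed(default_sim.observed, default_runs, 5)
    bleed_keys = {bc.call.key() for bc in bleed}
    assert default_sim.ledger.keys_for("bleed_error") <= bleed_keys


def test_flagged_bleed_always_has_a_run_within_window(default_sim, default_runs):
    bleed, _ = classify_bleed(default_sim.observed, default_runs, 5)
    for bc in bleed:
        assert bc.distance <= 5
        assert bc.run.klass == "AT"
        assert bc.call.alt == bc.run.base or bc.call.var_class != "SNV"


# ---------------------------------------------------------------------------
# bleed clusters


def test_acaca_pattern_flags_one_cluster_of_three():
    # AAAAACACACA read as AAAAAAAAAAA: three C>A calls on one run
    seq = "GGG" + "AAAAACACACA" + "GGG"
    genome = GenomeAssembly({"chr1": seq})
    runs = find_runs(genome, 4)
    calls = [MutationCall("chr1", p, "C", "A", "S1", 3, 0) for p in (8, 10, 12)]
    bleed, _ = classify_bleed(CallSet("x", calls), runs, 5)
    assert len(bleed) == 3
    bleed, counts = bleed_cluster_resolution(bleed, 5)
    assert all(bc.in_bleed_cluster for bc in bleed)
    assert counts["n_within_or_adjacent"] == 1
    assert counts["n_clustered_remaining"] == 2


def test_isolated_nearby_call_is_not_cluster_flagged():
    seq = "GGG" + "AAAA" + "GGC" + "GGGTTTGG"
    bleed, _ = _classify_one(seq, 9, "C", "A")
    assert len(bleed) == 1 and bleed[0].distance == 2
    bleed, counts = bleed_cluster_resolution(bleed, 5)
    assert not bleed[0].in_bleed_cluster
    assert counts["n_clustered_remaining"] == 0


def test_adjacency_categories_sum_to_total(default_sim, default_runs):
    bleed, _ = classify_bleed(default_sim.observed, default_runs, 5)
    bleed, counts = bleed_cluster_resolution(bleed, 5)
    assert counts["n_within_or_adjacent"] + counts["n_remaining"] == counts["n_bleed"]
    cats = {"within": 0, "adjacent": 0, "nearby": 0}
    for bc in bleed:
        cats[bc.adjacency] += 1
    assert sum(cats.values()) == len(bleed)


# ---------------------------------------------------------------------------
# run-length regression


def _synthetic_regression_inputs(slope, lengths, bp_per_bin=10_000):
    """Counts per bin follow 10^(slope*L) exactly up to integer rounding."""
    runs, bleed = [], []
    pos = 0
    for L in lengths:
        n_runs = bp_per_bin // L
        runs.extend(HomopolymerRun("chr1", pos + i * (L + 2),
                                   pos + i * (L + 2) + L, "A")
                    for i in range(n_runs))
        n_calls = round(10 ** (slope * L - 3) * n_runs * L)
        for i in range(n_calls):
            call = MutationCall("chr1", 10**7 + pos + i, "C", "A", f"S{i}", 3, 3)
            bleed.append(BleedCall(call, runs[-n_runs], 1, "nearby"))
        pos += 10 * bp_per_bin
    return bleed, runs


def test_regression_recovers_constructed_log_linear_rates():
    bleed, runs = _synthetic_regression_inputs(0.3, range(4, 12))
    reg = run_length_regression(bleed, runs)
    assert reg.df == 6                      # 8 length bins
    assert abs(reg.slope - 0.3) < 0.005     # integer rounding only
    assert reg.r_squared > 0.999


def test_regression_drops_zero_bins_and_requires_three():
    bleed, runs = _synthetic_regression_inputs(0.3, [6, 8, 10])
    extra = HomopolymerRun("chr1", 10**8, 10**8 + 12, "A")  # run with no calls
    reg = run_length_regression(bleed, runs + [extra])
    assert reg.dropped_bins == [12]
    assert reg.df == 1
    with pytest.raises(ValueError, match="usable"):
        run_length_regression(bleed[:1], runs)


# ---------------------------------------------------------------------------
# distance decay


def test_decay_table_matches_ledger_sampled_distances_exactly(default_sim,
                                                              default_runs):
    bleed, _ = classify_bleed(default_sim.observed, default_runs, 5)
    ledger_keys = default_sim.ledger.keys_for("bleed_error")
    tagged = [bc for bc in bleed if bc.call.key() in ledger_keys]
    table = distance_decay(tagged, 5)
    led = default_sim.ledger.table
    want = led.loc[led.tag == "bleed_error", "distance"].astype(int) \
        .value_counts().reindex(range(6), fill_value=0)
    assert list(table["count"]) == list(want)


def test_pure_decay_counts_decrease_monotonically():
    import dataclasses
    from mutartifacts import SimulationConfig, simulate
    from mutartifacts.synthetic_data import generate_genome, inject_bleed_errors
    cfg = SimulationConfig(seed=21, n_chromosomes=1, chrom_length=400_000,
                           n_genes=40, n_true_mutations=0, n_bleed_errors=3000,
                           bleed_cluster_fraction=0.0, n_cluster_errors=0,
                           n_recurrent_errors=0)
    genome, _ = generate_genome(cfg)
    bleed_calls, _ = inject_bleed_errors(genome, cfg)
    runs = find_runs(genome, 4)
    bleed, _ = classify_bleed(bleed_calls, runs, 5)
    table = distance_decay(bleed, 5)
    counts = list(table["count"])
    assert counts == sorted(counts, reverse=True)
    assert table.attrs["spearman_rho"] < -0.9
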