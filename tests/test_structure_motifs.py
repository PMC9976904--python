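"""Motif scanning and reactivity-window analysis tests."""

import numpy as np
import pandas as pd
import pytest

from agmotif import structure_motifs as sm
from agmotif.io_formats import ReactivityProfile, TranscriptModel, ValidationError

from conftest import brute_force_scan, random_annotated_transcript


def padded_transcript(core: str, pad5: int = 60, pad3: int = 60,
                      len_cds: int = 0, len_3utr: int = 0) -> TranscriptModel:
    """Embed a core sequence in a pyrimidine 5'UTR with generous flanks."""
    seq = "C" * pad5 + core + "T" * pad3
    return TranscriptModel("t1", "g1", seq, len(seq) - len_cds - len_3utr,
                           len_cds, len_3utr, 1.0)


# --- select_primary_transcripts ------------------------------------------

def test_most_abundant_transcript_per_gene():
    mk = lambda tid, ab: TranscriptModel(tid, "g1", "A" * 150 + "C" * 50,
                                         150, 30, 20, ab)
    kept = sm.select_primary_transcripts([mk("tA", 5.0), mk("tB", 10.0)])
    assert [t.transcript_id for t in kept] == ["tB"]


def test_5utr_length_strictly_greater():
    t100 = TranscriptModel("t1", "g1", "A" * 150, 100, 30, 20, 5.0)
    t101 = TranscriptModel("t2", "g2", "A" * 151, 101, 30, 20, 5.0)
    kept = sm.select_primary_transcripts([t100, t101])
    assert [t.transcript_id for t in kept] == ["t2"]


def test_abundance_tie_breaks_lexicographically():
    mk = lambda tid: TranscriptModel(tid, "g1", "A" * 200, 150, 30, 20, 7.0)
    kept = sm.select_primary_transcripts([mk("tB"), mk("tA")])
    assert [t.transcript_id for t in kept] == ["tA"]


def test_coverage_filter_applies_to_both_conditions():
    t = TranscriptModel("t1", "g1", "A" * 200, 150, 30, 20, 5.0)
    lo = ReactivityProfile("t1", "control", np.zeros(200), coverage=0.5)
    hi = ReactivityProfile("t1", "treated", np.zeros(200), coverage=2.0)
    kept = sm.select_primary_transcripts(
        [t], profiles={"control": {"t1": lo}, "treated": {"t1": hi}},
        min_coverage=1.0)
    assert kept == []


# --- scan_motifs ---------------------------------------------------------

def test_single_r10_hit_with_balanced_composition():
    t = padded_transcript("AAGGAGAGGA")
    hits = sm.scan_motifs(t, regions=["5UTR"])
    assert len(hits) == 1
    assert (hits[0].start, hits[0].seq) == (60, "AAGGAGAGGA")
    assert hits[0].region == "5UTR"


def test_composition_cap_rejects_near_homopolymer():
    assert sm.scan_motifs(padded_transcript("AAAAAAAAGG"), regions=["5UTR"]) == []
    assert sm.scan_motifs(padded_transcript("AAAAAAAGGG"), regions=["5UTR"]) != []
    # cap is configurable: 8 As pass at cap=8
    hits = sm.scan_motifs(padded_transcript("AAAAAAAAGG"), composition_cap=8,
                          regions=["5UTR"])
    assert len(hits) == 1


def test_pure_purine_run_of_15_gives_one_greedy_hit():
    t = padded_transcript("AGAGAGAGAGAGAGA")  # 15 nt pure purine
    hits = sm.scan_motifs(t, regions=["5UTR"])
    assert len(hits) == 1 and hits[0].start == 60


def test_edge_distance_filter():
    # motif 10 nt from the 5' end: rejected
    seq = "C" * 10 + "AAGGAGAGGA" + "C" * 120
    t = TranscriptModel("t1", "g1", seq, len(seq), 0, 0, 1.0)
    assert sm.scan_motifs(t, regions=["5UTR"]) == []


def test_gc5_class_scans_gc_alphabet():
    t = padded_transcript("GGCCGCGCCG")
    with_gc = sm.scan_motifs(t, motif_class="GC5", regions=["5UTR"])
    assert len(with_gc) == 1 and with_gc[0].motif_class == "GC5"
    assert sm.scan_motifs(t, motif_class="R10", regions=["5UTR"]) == []


@pytest.mark.parametrize("purine_prob", [0.5, 0.7])
def test_scanner_equals_brute_force_oracle(purine_prob):
    rng = np.random.default_rng(42 if purine_prob == 0.5 else 43)
    for _ in range(100):
        t = random_annotated_transcript(rng, purine_prob=purine_prob)
        got = [(h.region, h.start) for h in sm.scan_motifs(t)]
        assert got == brute_force_scan(t)


def test_no_motif_within_edge_distance_of_boundaries():
    rng = np.random.default_rng(77)
    for _ in range(50):
        t = random_annotated_transcript(rng, purine_prob=0.7)
        for h in sm.scan_motifs(t):
            lo, hi = t.region_bounds(h.region)
            assert h.start - lo >= 50 and hi - h.end >= 50


# --- reactivity windows --------------------------------------------------

def profile_from(values):
    return ReactivityProfile("t1", "control", np.asarray(values, dtype=float))


def test_window_mean_over_defined_positions():
    p = profile_from([0.2, np.nan, 0.4, np.nan])
    assert sm.window_mean_reactivity(p, 0, 4, min_defined=2) == pytest.approx(0.3)


def test_window_all_undefined_gives_nan():
    p = profile_from([np.nan] * 6)
    assert np.isnan(sm.window_mean_reactivity(p, 0, 6, min_defined=1))


def test_window_out_of_range_errors():
    with pytest.raises(ValidationError):
        sm.window_mean_reactivity(profile_from([0.1, 0.2]), 0, 5)


def test_window_mean_matches_direct_oracle():
    rng = np.random.default_rng(8)
    v = rng.uniform(0, 2, 100)
    v[rng.random(100) < 0.4] = np.nan
    p = profile_from(v)
    got = sm.window_mean_reactivity(p, 10, 60, min_defined=1)
    assert got == pytest.approx(np.nanmean(v[10:60]), abs=1e-12)


def motif_at(start, length=10):
    return sm.MotifHit("t1", "5UTR", start, length, "R10", "A" * length)


def test_delta_sign_convention_and_bounds():
    n = 200
    ctrl = profile_from(np.full(n, 0.5))
    treat = profile_from(np.full(n, 0.3))
    stat = sm.motif_window_delta(ctrl, treat, motif_at(60), "downstream")
    assert stat.delta == pytest.approx(-0.2)
    # window covers distances 31..50 3' of the last motif base
    assert sm.offset_window_bounds(motif_at(60), "downstream") == (100, 120)
    assert sm.offset_window_bounds(motif_at(60), "upstream") == (10, 30)


def test_delta_zero_when_profiles_identical():
    v = np.abs(np.random.default_rng(3).standard_normal(200))
    stat = sm.motif_window_delta(profile_from(v), profile_from(v),
                                 motif_at(60), "downstream")
    assert stat.delta == pytest.approx(0.0)


def test_window_beyond_transcript_flagged_invalid():
    n = 110  # motif ends at 70; downstream window needs up to position 120
    v = np.full(n, 0.5)
    stat = sm.motif_window_delta(profile_from(v), profile_from(v),
                                 motif_at(60), "downstream")
    assert not stat.valid and np.isnan(stat.delta)


# --- random windows ------------------------------------------------------

def transcript_for_sampling():
    return TranscriptModel("t1", "g1", "C" * 400, 400, 0, 0, 1.0)


def test_random_windows_deterministic_and_on_grid():
    t = transcript_for_sampling()
    a = sm.sample_random_windows(t, 5, rng=123)
    b = sm.sample_random_windows(t, 5, rng=123)
    assert [h.start for h in a] == [h.start for h in b]
    lo, hi = t.region_bounds("5UTR")
    for h in a:
        assert (h.start - lo) % 10 == 0
        assert h.start - lo >= 50 and hi - (h.start + 20) >= 50


def test_random_windows_exhaustive_constraint_check():
    rng = np.random.default_rng(31)
    for _ in range(30):
        t = random_annotated_transcript(rng)
        for region in ("5UTR", "CDS", "3UTR"):
            lo, hi = t.region_bounds(region)
            n_eligible = max(0, (hi - lo - 100 - 20) // 10 + 1)
            if n_eligible == 0:
                continue
            hits = sm.sample_random_windows(t, min(3, n_eligible),
                                            rng=int(rng.integers(1 << 30)),
                                            region=region)
            for h in hits:
                assert (h.start - lo) % 10 == 0
                assert h.start - lo >= 50 and hi - (h.start + 20) >= 50


def test_random_windows_insufficient_returns_all_with_warning():
    t = TranscriptModel("t1", "g1", "C" * 150, 150, 0, 0, 1.0)
    with pytest.warns(UserWarning, match="eligible"):
        hits = sm.sample_random_windows(t, 10, rng=1)
    assert len(hits) == (150 - 100 - 20) // 10 + 1


# --- comparison, classification, join ------------------------------------

def test_compare_identical_groups_surfaces_degenerate_error():
    stats = [sm.WindowStat(motif_at(60), "downstream", (31, 50),
                           0.5, 0.4, -0.1, 10) for _ in range(5)]
    with pytest.raises(ValueError, match="all differences zero"):
        sm.compare_motif_vs_random(stats, stats, paired=True)


def test_compare_empty_group_errors():
    with pytest.raises(ValidationError, match="empty group"):
        sm.compare_motif_vs_random([], [], paired=True)


@pytest.mark.parametrize("delta,expected", [(-0.1, "gain"), (0.1, "loss"),
                                            (0.0, None)])
def test_classify_structure_change(delta, expected):
    assert sm.classify_structure_change(delta) == expected


def test_classify_requires_finite():
    with pytest.raises(ValidationError):
        sm.classify_structure_change(float("nan"))


def test_join_structure_translation():
    ws = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                       "delta": [-0.2, 0.1, -0.3]})
    rates = pd.DataFrame({"gene_id": ["g1", "g2"], "log2fc": [-1.0, 0.2]})
    joined, report = sm.join_structure_translation(ws, rates)
    assert len(joined) == 2
    assert report["n_genes_dropped"] == 1
    assert set(joined["structure_class"]) == {"gain", "loss"}
    with pytest.raises(ValidationError, match="zero rows"):
        sm.join_structure_translation(
            ws, pd.DataFrame({"gene_id": ["gX"], "log2fc": [0.0]}))


def test_planted_structure_gain_associates_with_rate_decrease():
    # genes with structure gain got a planted translation decrease
    rng = np.random.default_rng(6)
    genes = [f"g{i}" for i in range(60)]
    delta = np.where(np.arange(60) < 30, -0.2, 0.2) + rng.normal(0, 0.02, 60)
    log2fc = np.where(np.arange(60) < 30, -1.0, 0.0) + rng.normal(0, 0.1, 60)
    joined, _ = sm.join_structure_translation(
        pd.DataFrame({"gene_id": genes, "delta": delta}),
        pd.DataFrame({"gene_id": genes, "log2fc": log2fc}))
    med = joined.groupby("structure_class")["delta_translation"].median()
    assert med["gain"] < med["loss"]
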