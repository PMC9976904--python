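import numpy as np
import pytest

from agmotif import synthetic as syn


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast synthetic cohort used by several module tests."""
    return syn.SimulationSpec(
        seed=11, n_genes=20,
        utr5_len_range=(150, 250), cds_len_range=(200, 400),
        utr3_len_range=(120, 200),
        planted_per_region={"5UTR": 1, "CDS": 1, "3UTR": 1},
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    transcripts, truth = syn.gen_transcriptome(small_spec)
    ctrl, treat = syn.gen_reactivity_pair(transcripts, truth, small_spec)
    return transcripts, truth, ctrl, treat


def brute_force_scan(t, motif_class="R10", length=10, composition_cap=7,
                     min_edge_distance=50, regions=("5UTR", "CDS", "3UTR")):
    """Independent re-derivation of the motif scan used as an oracle.

    Enumerates every window, filters by alphabet/composition, resolves
    non-overlap by repeatedly taking the leftmost remaining window, then
    applies the edge-distance filter.
    """
    alphabet = {"R10": {"A", "G"}, "GC5": {"G", "C"}}[motif_class]
    out = []
    for region in regions:
        lo, hi = t.region_bounds(region)
        valid = []
        for i in range(lo, hi - length + 1):
            window = t.sequence[i:i + length]
            if set(window) <= alphabet and all(
                    window.count(b) <= composition_cap for b in alphabet):
                valid.append(i)
        chosen, last_end = [], -1
        for i in valid:
            if i >= last_end:
                chosen.append(i)
                last_end = i + length
        for i in chosen:
            if i - lo >= min_edge_distance and hi - (i + length) >= min_edge_distance:
                out.append((region, i))
    return out


def random_annotated_transcript(rng, purine_prob=0.6):
    """A random TranscriptModel with adjustable purine enrichment."""
    from agmotif.io_formats import TranscriptModel
    lens = [int(rng.integers(110, 400)), int(rng.integers(150, 600)),
            int(rng.integers(110, 300))]
    probs = [purine_prob / 2, (1 - purine_prob) / 2,
             purine_prob / 2, (1 - purine_prob) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=sum(lens), p=probs))
    return TranscriptModel(
        transcript_id="tx", gene_id="gx", sequence=seq,
        len_5utr=lens[0], len_cds=lens[1], len_3utr=lens[2],
        abundance=float(rng.uniform(1, 10)))
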