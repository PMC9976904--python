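"""Polypurine-motif scanning and motif-anchored DMS-reactivity windows.

The analysis asks whether RNA structure (probed by DMS reactivity, a
single-strandedness readout at A/C nucleotides) changes in a localized
window downstream of purine-rich motifs when the eIF4A helicase is
inhibited.  Motifs are 10-nt windows of 100% purine (R10; alphabet {A,G})
with a composition cap that excludes near-homopolymers, kept only when they
lie well inside their annotated region.  Reactivity change is summarised in
20-nt windows at 31-50 nt up- and downstream of each motif and compared
against randomly placed windows from the same transcripts with a paired
two-sided Wilcoxon test.

Sign convention: DMS reactivity measures single-strandedness, so a
*negative* reactivity change (treated - control) is a *gain* of structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import REGIONS, ReactivityProfile, TranscriptModel, ValidationError
from .stats_core import wilcoxon

MOTIF_ALPHABETS = {"R10": ("A", "G"), "GC5": ("G", "C")}


@dataclass
class MotifHit:
    """A motif occurrence in 0-based transcript coordinates."""

    transcript_id: str
    region: str
    start: int
    length: int
    motif_class: str  # R10, GC5 or random
    seq: str

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class WindowStat:
    """Reactivity-change summary for one offset window of one motif.

    ``delta = mean_treat - mean_ctrl`` over positions defined (A/C) in both
    profiles; NaN when the window is out of bounds (``valid=False``) or has
    fewer than ``min_defined`` defined positions.
    """

    motif: MotifHit
    side: str  # upstream | downstream
    offset_window: tuple[int, int]
    mean_ctrl: float
    mean_treat: float
    delta: float
    n_defined: int
    valid: bool = True


@dataclass
class TestSummary:
    """Result of a motif-vs-random window comparison."""

    p_value: float
    median_motif: float
    median_random: float
    n_motif: int
    n_random: int
    paired: bool


def select_primary_transcripts(
    transcripts: Sequence[TranscriptModel],
    min_5utr_len: int = 100,
    profiles: dict[str, dict[str, ReactivityProfile]] | None = None,
    min_coverage: float = 0.0,
    min_five_prime_coverage: float = 0.0,
) -> list[TranscriptModel]:
    """Keep the most abundant transcript per gene with a 5'UTR > ``min_5utr_len``.

    The 5'UTR length comparison is strict (a transcript with exactly
    ``min_5utr_len`` nt is excluded).  When condition-keyed profiles are
    supplied, both conditions must pass the coverage thresholds.  Abundance
    ties break to the lexicographically smallest transcript id.
    """
    eligible = []
    for t in transcripts:
        if t.len_5utr <= min_5utr_len:
            continue
        if profiles is not None:
            ok = True
            for cond_profiles in profiles.values():
                p = cond_profiles.get(t.transcript_id)
                if (p is None or p.coverage < min_coverage
                        or p.five_prime_coverage < min_five_prime_coverage):
                    ok = False
                    break
            if not ok:
                continue
        eligible.append(t)
    best: dict[str, TranscriptModel] = {}
    for t in eligible:
        cur = best.get(t.gene_id)
        if (cur is None or t.abundance > cur.abundance
                or (t.abundance == cur.abundance
                    and t.transcript_id < cur.transcript_id)):
            best[t.gene_id] = t
    return sorted(best.values(), key=lambda t: t.transcript_id)


def _window_ok(window: str, alphabet: tuple[str, str], cap: int) -> bool:
    c0 = window.count(alphabet[0])
    c1 = window.count(alphabet[1])
    return c0 + c1 == len(window) and c0 <= cap and c1 <= cap


def scan_motifs(
    t: TranscriptModel,
    motif_class: str = "R10",
    length: int = 10,
    composition_cap: int = 7,
    min_edge_distance: int = 50,
    regions: Iterable[str] = REGIONS,
) -> list[MotifHit]:
    """Greedy left-to-right scan for non-overlapping motif hits per region.

    A window qualifies when all ``length`` bases come from the motif
    alphabet ({A,G} for R10, {G,C} for GC5) and neither base exceeds
    ``composition_cap`` occurrences (excluding homopolymers and
    near-homopolymers).  Greedy resolution: the scan advances one base at a
    time and jumps past each accepted window.  Hits closer than
    ``min_edge_distance`` nt to either boundary of their region (UTR/CDS
    junctions and transcript ends coincide with region boundaries) are then
    discarded.
    """
    try:
        alphabet = MOTIF_ALPHABETS[motif_class]
    except KeyError:
        raise ValidationError(f"unknown motif class {motif_class!r}") from None
    hits: list[MotifHit] = []
    for region in regions:
        lo, hi = t.region_bounds(region)
        i = lo
        while i + length <= hi:
            window = t.sequence[i:i + length]
            if _window_ok(window, alphabet, composition_cap):
                if i - lo >= min_edge_distance and hi - (i + length) >= min_edge_distance:
                    hits.append(MotifHit(
                        transcript_id=t.transcript_id, region=region,
                        start=i, length=length, motif_class=motif_class,
                        seq=window,
                    ))
                i += length
            else:
                i += 1
    return hits


def window_mean_reactivity(p: ReactivityProfile, start: int, end: int,
                           min_defined: int = 5) -> float:
    """Mean reactivity over defined (A/C) positions in [start, end).

    NaN when fewer than ``min_defined`` positions are defined; error for an
    out-of-range window.
    """
    if not (0 <= start < end <= len(p.values)):
        raise ValidationError(
            f"{p.transcript_id}: window [{start}, {end}) out of range "
            f"for length {len(p.values)}"
        )
    vals = p.values[start:end]
    defined = vals[np.isfinite(vals)]
    if defined.size < min_defined:
        return float("nan")
    return float(defined.mean())


def offset_window_bounds(m: MotifHit, side: str,
                         offsets: tuple[int, int] = (31, 50)) -> tuple[int, int]:
    """0-based half-open bounds of the offset window on one side of a motif.

    Downstream: nucleotides at (inclusive) distances ``offsets[0]..
    offsets[1]`` 3' of the motif's last base; upstream is the mirror 5' of
    its first base.
    """
    lo, hi = offsets
    if side == "downstream":
        last = m.end - 1
        return last + lo, last + hi + 1
    if side == "upstream":
        return m.start - hi, m.start - lo + 1
    raise ValidationError(f"unknown side {side!r}")


def motif_window_delta(
    ctrl: ReactivityProfile,
    treat: ReactivityProfile,
    m: MotifHit,
    side: str,
    offsets: tuple[int, int] = (31, 50),
    min_defined: int = 5,
) -> WindowStat:
    """Reactivity change (treated - control) in the offset window of a motif.

    Means are taken over positions defined in *both* profiles.  A window
    extending beyond the transcript is flagged invalid rather than dropped.
    """
    if len(ctrl.values) != len(treat.values):
        raise ValidationError(
            f"{m.transcript_id}: control/treated profile lengths differ"
        )
    start, end = offset_window_bounds(m, side, offsets)
    if not (0 <= start < end <= len(ctrl.values)):
        return WindowStat(motif=m, side=side, offset_window=tuple(offsets),
                          mean_ctrl=float("nan"), mean_treat=float("nan"),
                          delta=float("nan"), n_defined=0, valid=False)
    c = ctrl.values[start:end]
    h = treat.values[start:end]
    both = np.isfinite(c) & np.isfinite(h)
    n_defined = int(both.sum())
    if n_defined < min_defined:
        return WindowStat(motif=m, side=side, offset_window=tuple(offsets),
                          mean_ctrl=float("nan"), mean_treat=float("nan"),
                          delta=float("nan"), n_defined=n_defined, valid=True)
    mean_ctrl = float(c[both].mean())
    mean_treat = float(h[both].mean())
    return WindowStat(motif=m, side=side, offset_window=tuple(offsets),
                      mean_ctrl=mean_ctrl, mean_treat=mean_treat,
                      delta=mean_treat - mean_ctrl, n_defined=n_defined)


def sample_random_windows(
    t: TranscriptModel,
    n: int,
    rng: np.random.Generator | int,
    region: str = "5UTR",
    window_len: int = 20,
    step: int = 10,
    min_edge_distance: int = 50,
) -> list[MotifHit]:
    """Sample n random windows from the step grid of a region.

    Candidates are every start on the ``step`` grid (relative to the region
    start) whose window keeps ``min_edge_distance`` nt clear of both region
    boundaries.  Sampling is uniform without replacement and reproducible
    for a fixed seed; if fewer than n candidates exist, all are returned
    with a warning.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lo, hi = t.region_bounds(region)
    starts = [
        s for s in range(lo + min_edge_distance, hi - min_edge_distance - window_len + 1, step)
    ]
    if len(starts) < n:
        warnings.warn(
            f"{t.transcript_id}/{region}: only {len(starts)} eligible windows "
            f"for a request of {n}", stacklevel=2)
        chosen = starts
    else:
        chosen = sorted(rng.choice(len(starts), size=n, replace=False).tolist())
        chosen = [starts[i] for i in chosen]
    return [
        MotifHit(transcript_id=t.transcript_id, region=region, start=s,
                 length=window_len, motif_class="random",
                 seq=t.sequence[s:s + window_len])
        for s in chosen
    ]


def compare_motif_vs_random(
    motif_stats: Sequence[WindowStat],
    random_stats: Sequence[WindowStat],
    paired: bool = True,
) -> TestSummary:
    """Wilcoxon comparison of motif-window deltas against random-window deltas.

    In paired mode ``motif_stats[i]`` and ``random_stats[i]`` must come from
    the same transcript (the pipeline pairs them per transcript by rank);
    pairs where either delta is undefined are dropped.
    """
    if len(motif_stats) == 0 or len(random_stats) == 0:
        raise ValidationError("empty group in motif-vs-random comparison")
    dm = np.array([s.delta for s in motif_stats])
    dr = np.array([s.delta for s in random_stats])
    if paired:
        if dm.size != dr.size:
            raise ValidationError("paired comparison requires matched groups")
        keep = np.isfinite(dm) & np.isfinite(dr)
        dm, dr = dm[keep], dr[keep]
        p = wilcoxon(dm, dr, mode="paired")
    else:
        dm = dm[np.isfinite(dm)]
        dr = dr[np.isfinite(dr)]
        p = wilcoxon(dm, dr, mode="unpaired")
    return TestSummary(p_value=p, median_motif=float(np.median(dm)),
                       median_random=float(np.median(dr)),
                       n_motif=int(dm.size), n_random=int(dr.size),
                       paired=paired)


def classify_structure_change(delta: float) -> str | None:
    """Gain/loss of structure from a reactivity change.

    Reactivity measures single-strandedness, so delta < 0 is a gain of
    structure and delta > 0 a loss; delta == 0 is excluded (None).
    """
    if not np.isfinite(delta):
        raise ValidationError("delta must be finite")
    if delta < 0:
        return "gain"
    if delta > 0:
        return "loss"
    return None


def join_structure_translation(
    window_stats: pd.DataFrame,
    rate_table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Inner-join per-gene reactivity changes with translation-rate changes.

    ``window_stats`` needs columns (gene_id, delta); ``rate_table`` needs
    (gene_id, log2fc).  Returns one AssociationRecord row per (gene, window)
    with the structure class, plus a join report counting dropped genes.
    An empty join is an error.
    """
    ws = window_stats.loc[np.isfinite(window_stats["delta"])].copy()
    ws["structure_class"] = [classify_structure_change(d) for d in ws["delta"]]
    ws = ws.loc[ws["structure_class"].notna()]
    merged = ws.merge(rate_table[["gene_id", "log2fc"]], on="gene_id", how="inner")
    merged = merged.rename(columns={"delta": "delta_reactivity",
                                    "log2fc": "delta_translation"})
    report = {
        "n_windows": int(len(ws)),
        "n_joined": int(len(merged)),
        "n_genes_dropped": int(ws.loc[~ws["gene_id"].isin(rate_table["gene_id"]),
                                      "gene_id"].nunique()),
    }
    if merged.empty:
        raise ValidationError("structure/translation join produced zero rows")
    return merged, report


def window_stats_frame(stats: Iterable[WindowStat],
                       gene_ids: dict[str, str] | None = None) -> pd.DataFrame:
    """Flatten WindowStat objects into the output-table schema."""
    rows = []
    for s in stats:
        rows.append({
            "transcript_id": s.motif.transcript_id,
            "gene_id": (gene_ids or {}).get(s.motif.transcript_id,
                                            s.motif.transcript_id),
            "region": s.motif.region,
            "motif_class": s.motif.motif_class,
            "motif_start": s.motif.start,
            "motif_end": s.motif.end,
            "side": s.side,
            "window_start": offset_window_bounds(s.motif, s.side, s.offset_window)[0],
            "window_end": offset_window_bounds(s.motif, s.side, s.offset_window)[1],
            "mean_ctrl": s.mean_ctrl,
            "mean_treat": s.mean_treat,
            "delta": s.delta,
            "n_defined": s.n_defined,
            "valid": s.valid,
        })
    return pd.DataFrame(rows)
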