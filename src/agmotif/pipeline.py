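"""End-to-end orchestration of the two analysis arms, with a run manifest.

The structure arm: primary-transcript selection -> motif scan -> offset
windows on both sides -> matched random windows -> paired Wilcoxon ->
structure classification -> (optional) join with translation rates.

The pSILAC arm: peptide aggregation (if needed) -> fraction heavy ->
ln-linear rate fits in both conditions -> both-condition F-test filter ->
difference test + BH FDR -> dependence classification.

Every run writes a ``manifest.json`` recording the config (and its hash),
the seed, input checksums and the input/output counts of each filter step.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (DEFAULT_CONFIG, ReactivityProfile, TranscriptModel,
                         ValidationError, write_table)
from . import psilac, structure_motifs as sm

logger = logging.getLogger(__name__)


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _manifest(config: dict, counts: dict, inputs: dict[str, str] | None) -> dict:
    return {
        "package": "agmotif",
        "version": __version__,
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in config.items()},
        "config_hash": config_hash(config),
        "seed": config.get("seed"),
        "inputs": {name: file_checksum(p) for name, p in (inputs or {}).items()},
        "counts": counts,
    }


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_structure_pipeline(
    transcripts: list[TranscriptModel],
    profiles_ctrl: dict[str, ReactivityProfile],
    profiles_treat: dict[str, ReactivityProfile],
    config: dict | None = None,
    rate_table: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    input_paths: dict[str, str] | None = None,
) -> dict:
    """Run the motif/reactivity arm; returns tables, test summaries and counts."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    offsets = tuple(cfg["window_offsets"])
    counts: dict = {"transcripts_input": len(transcripts)}

    profiles = {"control": profiles_ctrl, "treated": profiles_treat}
    selected = sm.select_primary_transcripts(
        transcripts, min_5utr_len=cfg["min_5utr_len"], profiles=profiles,
        min_coverage=cfg["min_coverage"],
        min_five_prime_coverage=cfg["min_five_prime_coverage"])
    counts["transcripts_selected"] = len(selected)
    logger.info("selected %d/%d transcripts", len(selected), len(transcripts))

    rng = np.random.default_rng(int(cfg["seed"]))
    gene_ids = {t.transcript_id: t.gene_id for t in selected}
    motif_hits: list[sm.MotifHit] = []
    random_hits: list[sm.MotifHit] = []
    for t in selected:
        per_region: dict[str, list[sm.MotifHit]] = {}
        for hit in sm.scan_motifs(t, motif_class="R10",
                                  length=cfg["motif_length"],
                                  composition_cap=cfg["composition_cap"],
                                  min_edge_distance=cfg["min_edge_distance"],
                                  regions=cfg["regions"]):
            per_region.setdefault(hit.region, []).append(hit)
        for region, hits in per_region.items():
            motif_hits.extend(hits)
            random_hits.extend(sm.sample_random_windows(
                t, len(hits), rng, region=region,
                window_len=cfg["window_len_random"], step=cfg["random_step"],
                min_edge_distance=cfg["min_edge_distance"]))
    for region in cfg["regions"]:
        counts[f"motifs_{region}"] = sum(h.region == region for h in motif_hits)
    counts["random_windows"] = len(random_hits)

    def stats_for(hits):
        out = []
        for h in hits:
            ctrl = profiles_ctrl[h.transcript_id]
            treat = profiles_treat[h.transcript_id]
            for side in ("upstream", "downstream"):
                out.append(sm.motif_window_delta(
                    ctrl, treat, h, side, offsets=offsets,
                    min_defined=cfg["min_defined"]))
        return out

    motif_stats = stats_for(motif_hits)
    random_stats = stats_for(random_hits)

    summaries = []
    for region in cfg["regions"]:
        for side in ("upstream", "downstream"):
            ms = [s for s in motif_stats
                  if s.motif.region == region and s.side == side]
            rs = [s for s in random_stats
                  if s.motif.region == region and s.side == side]
            if not ms or not rs:
                continue
            try:
                summary = sm.compare_motif_vs_random(ms, rs, paired=True)
            except ValidationError as exc:
                logger.warning("comparison %s/%s skipped: %s", region, side, exc)
                continue
            summaries.append({"region": region, "side": side,
                              "p_value": summary.p_value,
                              "median_motif": summary.median_motif,
                              "median_random": summary.median_random,
                              "n_motif": summary.n_motif,
                              "n_random": summary.n_random})
    test_summary = pd.DataFrame(summaries)

    motifs_df = pd.DataFrame([{
        "transcript_id": h.transcript_id, "gene_id": gene_ids[h.transcript_id],
        "region": h.region, "start": h.start, "end": h.end,
        "motif_class": h.motif_class, "seq": h.seq,
    } for h in motif_hits + random_hits])
    stats_df = sm.window_stats_frame(motif_stats + random_stats, gene_ids)

    association = None
    join_report = None
    if rate_table is not None:
        down = stats_df.loc[(stats_df["side"] == "downstream")
                            & (stats_df["motif_class"] == "R10")]
        association, join_report = sm.join_structure_translation(down, rate_table)
        counts["association_rows"] = len(association)
        counts["association_genes_dropped"] = join_report["n_genes_dropped"]

    results = {"config": cfg, "counts": counts, "motifs": motifs_df,
               "window_stats": stats_df, "test_summary": test_summary,
               "association": association}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(motifs_df, out_dir / "motifs.tsv")
        write_table(stats_df, out_dir / "window_stats.tsv")
        write_table(test_summary, out_dir / "test_summary.tsv")
        if association is not None:
            write_table(association, out_dir / "association.tsv")
        _write_manifest(_manifest(cfg, counts, input_paths), out_dir)
    return results


def run_psilac_pipeline(
    table: pd.DataFrame,
    config: dict | None = None,
    out_dir: str | Path | None = None,
    input_paths: dict[str, str] | None = None,
) -> dict:
    """Run the pSILAC arm on a (peptide- or protein-level) intensity table."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    counts: dict = {}
    if "peptide_seq" in table.columns:
        table, agg_report = psilac.aggregate_peptides_to_proteins(
            table, operator=cfg["peptide_combine"])
        counts.update(agg_report)
    fits = psilac.fit_rates_table(table)
    conditions = set(fits)
    if conditions != {"control", "treated"}:
        raise ValidationError(
            f"expected conditions control/treated, found {sorted(conditions)}")
    retained, filter_counts = psilac.filter_by_fit_quality(
        fits["control"], fits["treated"], p_cut=cfg["p_cut_fit"])
    counts["input"] = filter_counts["input"]
    counts["passing_filter"] = filter_counts["retained"]
    counts["removed_by_filter"] = filter_counts["removed"]
    records = psilac.compare_conditions(fits["control"], fits["treated"],
                                        proteins=retained,
                                        method=cfg["difference_test"])
    records = psilac.classify_dependence(records,
                                         fdr_dependent=cfg["fdr_dependent"],
                                         fdr_independent=cfg["fdr_independent"])
    counts["dependent"] = int((records["label"] == "dependent").sum())
    counts["independent"] = int((records["label"] == "independent").sum())
    counts["unclassified"] = int((records["label"] == "unclassified").sum())
    logger.info("pSILAC counts: %s", counts)

    rates_rows = []
    for cond in ("control", "treated"):
        for pid, fit in sorted(fits[cond].items()):
            rates_rows.append({"protein_id": pid, "condition": cond,
                               "k_per_h": fit.k, "offset": fit.offset,
                               "p_slope": fit.p_slope, "se_slope": fit.se_slope,
                               "n_points_used": fit.n_points_used,
                               "valid": fit.valid})
    rates_df = pd.DataFrame(rates_rows)

    results = {"config": cfg, "counts": counts, "rates": rates_df,
               "dependence": records, "fits": fits}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(rates_df, out_dir / "rates.tsv")
        write_table(records, out_dir / "dependence.tsv")
        _write_manifest(_manifest(cfg, counts, input_paths), out_dir)
    return results
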