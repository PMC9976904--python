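"""Pulsed-SILAC translation-rate estimation and dependence classification.

A pulse of heavy (Lys8/Arg10) amino acids labels newly synthesised protein;
TMT reporter intensities of the heavy and light forms give the fraction
heavy F_H = I_heavy / (I_heavy + I_light) per time point.  First-order
labelling kinetics linearise to ln F_H = k*t + offset, so the apparent
translation rate k of each protein is the slope of an ordinary
least-squares fit to the log data, with an F-test against k = 0.

Proteins with a poor fit in either condition (slope p >= 0.1) are removed.
For the rest, the rate difference (treated - control) is tested per protein
and Benjamini-Hochberg FDRs computed across proteins; FDR < 0.1 labels a
protein helicase-*dependent*, FDR > 0.7 *independent*, in between
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import ValidationError
from .stats_core import bh_fdr, ols_fit

INTENSITY_COLUMNS = ["intensity_light", "intensity_heavy"]
KEY_COLUMNS = ["condition", "time_h", "replicate"]


@dataclass
class RateFit:
    """ln-linear labelling fit for one protein in one condition."""

    protein_id: str
    k: float          # per hour
    offset: float     # ln F_H at t = 0 (extrapolated)
    p_slope: float
    se_slope: float
    n_points_used: int
    valid: bool = True


def aggregate_peptides_to_proteins(peptide_rows: pd.DataFrame,
                                   operator: str = "sum") -> tuple[pd.DataFrame, dict]:
    """Collapse peptide-level intensities to protein level.

    Identical peptide sequences (within a condition/time/replicate channel)
    are combined by median; distinct peptides of one protein are then
    combined by ``operator`` (sum by default, median optionally).  Peptides
    mapping to more than one protein group are excluded and counted.
    """
    required = ["peptide_seq", "protein_id", *KEY_COLUMNS, *INTENSITY_COLUMNS]
    missing = [c for c in required if c not in peptide_rows.columns]
    if missing:
        raise ValidationError(f"peptide table missing column(s) {missing}")
    if operator not in ("sum", "median"):
        raise ValidationError(f"unknown peptide combine operator {operator!r}")
    n_groups = peptide_rows.groupby("peptide_seq")["protein_id"].nunique()
    shared = set(n_groups.index[n_groups > 1])
    kept = peptide_rows.loc[~peptide_rows["peptide_seq"].isin(shared)]
    by_peptide = (kept.groupby(["protein_id", "peptide_seq", *KEY_COLUMNS],
                               as_index=False)[INTENSITY_COLUMNS].median())
    agg = getattr(by_peptide.groupby(["protein_id", *KEY_COLUMNS],
                                     as_index=False)[INTENSITY_COLUMNS], operator)()
    report = {"n_peptides_input": int(peptide_rows["peptide_seq"].nunique()),
              "n_peptides_shared_excluded": len(shared)}
    return agg, report


def fraction_heavy(i_heavy, i_light):
    """F_H = I_heavy / (I_heavy + I_light); error when both are zero."""
    i_heavy = np.asarray(i_heavy, dtype=float)
    i_light = np.asarray(i_light, dtype=float)
    if np.any(i_heavy < 0) or np.any(i_light < 0):
        raise ValidationError("negative intensity")
    total = i_heavy + i_light
    if np.any(total == 0):
        raise ValidationError("zero total intensity (both channels zero)")
    out = i_heavy / total
    return float(out) if out.ndim == 0 else out


def fit_turnover_rate(times, f_h, protein_id: str = "") -> RateFit:
    """Apparent translation rate from ln F_H = k*t + offset.

    Points with F_H <= 0 (the t = 0 sample before any labelling) are
    excluded before taking logs.  Replicates at one time enter as separate
    points.  Fewer than 3 usable points, or all usable times equal, makes
    the fit invalid rather than raising.
    """
    times = np.asarray(times, dtype=float)
    f_h = np.asarray(f_h, dtype=float)
    if times.shape != f_h.shape:
        raise ValidationError("times and f_h must have equal length")
    usable = f_h > 0
    t, f = times[usable], f_h[usable]
    if t.size < 3 or np.ptp(t) == 0:
        return RateFit(protein_id=protein_id, k=float("nan"),
                       offset=float("nan"), p_slope=float("nan"),
                       se_slope=float("nan"), n_points_used=int(t.size),
                       valid=False)
    fit = ols_fit(t, np.log(f))
    return RateFit(protein_id=protein_id, k=fit.slope, offset=fit.intercept,
                   p_slope=fit.p_slope, se_slope=fit.se_slope,
                   n_points_used=fit.n)


def fit_rates_table(table: pd.DataFrame) -> dict[str, dict[str, RateFit]]:
    """Fit every (condition, protein) group of a protein-level TMT table."""
    missing = [c for c in ("protein_id", *KEY_COLUMNS, *INTENSITY_COLUMNS)
               if c not in table.columns]
    if missing:
        raise ValidationError(f"TMT table missing column(s) {missing}")
    fits: dict[str, dict[str, RateFit]] = {}
    for (cond, pid), grp in table.groupby(["condition", "protein_id"]):
        f_h = fraction_heavy(grp["intensity_heavy"].to_numpy(),
                             grp["intensity_light"].to_numpy())
        fits.setdefault(cond, {})[pid] = fit_turnover_rate(
            grp["time_h"].to_numpy(), f_h, protein_id=pid)
    return fits


def filter_by_fit_quality(fits_ctrl: dict[str, RateFit],
                          fits_treat: dict[str, RateFit],
                          p_cut: float = 0.1) -> tuple[list[str], dict]:
    """Retain proteins whose slope p-value beats ``p_cut`` in both conditions."""
    shared = sorted(set(fits_ctrl) & set(fits_treat))
    retained = [
        pid for pid in shared
        if fits_ctrl[pid].valid and fits_treat[pid].valid
        and fits_ctrl[pid].p_slope < p_cut and fits_treat[pid].p_slope < p_cut
    ]
    counts = {"input": len(shared), "retained": len(retained),
              "removed": len(shared) - len(retained)}
    return retained, counts


def compare_conditions(fits_ctrl: dict[str, RateFit],
                       fits_treat: dict[str, RateFit],
                       proteins: list[str] | None = None,
                       method: str = "z") -> pd.DataFrame:
    """Per-protein rate difference, log2 fold change and BH FDR.

    The difference k_treat - k_ctrl is tested with a two-sided z-test using
    the two fits' slope standard errors (``method='z'``); FDRs are BH
    across proteins.  log2fc is NaN when either rate is non-positive; the
    difference is still reported.
    """
    if method != "z":
        raise ValidationError(f"unknown difference test {method!r}")
    if proteins is None:
        proteins = sorted(set(fits_ctrl) & set(fits_treat))
    rows = []
    for pid in proteins:
        fc, ft = fits_ctrl[pid], fits_treat[pid]
        diff = ft.k - fc.k
        log2fc = (np.log2(ft.k / fc.k) if fc.k > 0 and ft.k > 0
                  else float("nan"))
        se = np.hypot(fc.se_slope, ft.se_slope)
        if se > 0:
            p = float(2 * sps.norm.sf(abs(diff) / se))
        else:
            p = 0.0 if diff != 0 else 1.0
        rows.append({"protein_id": pid, "k_ctrl": fc.k, "k_treat": ft.k,
                     "diff": diff, "log2fc": log2fc, "p_diff": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = bh_fdr(df["p_diff"].to_numpy())
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df


def classify_dependence(records: pd.DataFrame,
                        fdr_dependent: float = 0.1,
                        fdr_independent: float = 0.7) -> pd.DataFrame:
    """Label each protein dependent / independent / unclassified by FDR."""
    if "fdr" not in records.columns:
        raise ValidationError("records lack an 'fdr' column")
    out = records.copy()
    out["label"] = np.select(
        [out["fdr"] < fdr_dependent, out["fdr"] > fdr_independent],
        ["dependent", "independent"], default="unclassified")
    return out
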