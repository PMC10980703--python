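"""Within-subject mtDNA dynamics between two clinical visits.

A subject's accepted variants at visit 1 (V1) and visit 2 (V2) are matched by
(position, alt allele) into *trajectories*: variants seen at exactly one
visit are **transient** (transient_v1 / transient_v2), variants seen at both
are **persistent**, and a persistent variant's ΔVL = VL(V2) − VL(V1)
measures heteroplasmy drift. The module summarises transient proportions and
VLs per visit, tests pooled and per-subject ΔVL against zero, contrasts
transient vs persistent variants on VL / quality / pathogenicity variables,
collapses subjects to single data points (mean of both visits), and runs the
clinical grouping batteries (diagnostic evolution, NEDA-3, medication
change). Missing clinical values are censored from the affected test, never
imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import (
    ComparisonResult,
    apply_fdr,
    fisher_montecarlo,
    kruskal_by_group,
    not_testable,
    one_sample_t,
    two_sample_t,
)

DAYS_PER_YEAR = 365.25

TRAJECTORY_STATUSES = ("transient_v1", "transient_v2", "persistent")

#: variant-level variables contrasted between transient and persistent variants
TRANSIENT_VS_PERSISTENT_VARIABLES = (
    "vl", "norm_cov", "cov_ratio", "numt_mean", "edge_dist",
    "deleterious_score", "mitotip",
)


class LongitudinalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# trajectories

def match_visits(v1: pd.DataFrame, v2: pd.DataFrame) -> pd.DataFrame:
    """Partition two visit tables of one subject into variant trajectories.

    Every variant from either visit lands in exactly one row; columns other
    than the key are carried with ``_v1``/``_v2`` suffixes. Duplicate
    (pos, alt) keys within one visit are an error.
    """
    for name, df in (("V1", v1), ("V2", v2)):
        if df.duplicated(subset=["pos", "alt"]).any():
            dups = df[df.duplicated(subset=["pos", "alt"], keep=False)]
            raise LongitudinalError(
                f"duplicate variant keys within {name}: "
                + ", ".join(f"{p}:{a}" for p, a in
                            dups[["pos", "alt"]].drop_duplicates().itertuples(index=False))
            )
    merged = v1.merge(v2, on=["pos", "alt"], how="outer",
                      suffixes=("_v1", "_v2"), indicator=True)
    status = merged["_merge"].map(
        {"left_only": "transient_v1", "right_only": "transient_v2", "both": "persistent"}
    )
    merged = merged.drop(columns="_merge")
    merged["status"] = status.astype(str)
    merged["dvl"] = np.where(
        merged["status"] == "persistent",
        merged.get("vl_v2", np.nan) - merged.get("vl_v1", np.nan),
        np.nan,
    )
    merged["vl"] = merged[["vl_v1", "vl_v2"]].mean(axis=1)  # observed-visit mean
    return merged.sort_values(["pos", "alt"]).reset_index(drop=True)


def transient_summary(trajectories: pd.DataFrame, visit: int) -> tuple[float, float]:
    """(transient proportion, mean transient VL) for one visit of one subject.

    The denominator is the number of variants observed at that visit; both
    values are NaN-censored when undefined (no variants at the visit / no
    transient variants).
    """
    if visit not in (1, 2):
        raise LongitudinalError("visit must be 1 or 2")
    at_visit = trajectories[trajectories[f"vl_v{visit}"].notna()]
    if len(at_visit) == 0:
        return math.nan, math.nan
    transient = at_visit[at_visit["status"] == f"transient_v{visit}"]
    prop = len(transient) / len(at_visit)
    mean_vl = float(transient[f"vl_v{visit}"].mean()) if len(transient) else math.nan
    return prop, mean_vl


def vl_change_test(trajectories_by_subject: dict[str, pd.DataFrame]) -> list[ComparisonResult]:
    """One-sample t of persistent ΔVL against zero: pooled over all variants
    and on per-subject mean ΔVL."""
    pooled = np.concatenate([
        t.loc[t["status"] == "persistent", "dvl"].to_numpy(dtype=float)
        for t in trajectories_by_subject.values()
    ]) if trajectories_by_subject else np.array([])
    per_subject = np.array([
        t.loc[t["status"] == "persistent", "dvl"].mean()
        for t in trajectories_by_subject.values()
    ], dtype=float)
    return [
        one_sample_t(pooled, "vl_change", "pooled_dvl"),
        one_sample_t(per_subject, "vl_change", "per_subject_mean_dvl"),
    ]


def transient_vs_persistent(
    trajectories_by_subject: dict[str, pd.DataFrame],
    variables=TRANSIENT_VS_PERSISTENT_VARIABLES,
) -> list[ComparisonResult]:
    """Two-sample t of each variant-level variable, transient vs persistent,
    FDR within the family. For persistent variants a variable is the mean of
    its two visit values; for transient variants, the observed visit's value.
    Variables absent for every variant are censored from the family."""
    frames = []
    for t in trajectories_by_subject.values():
        df = pd.DataFrame({"status": t["status"]})
        for var in variables:
            c1, c2 = f"{var}_v1", f"{var}_v2"
            if c1 in t.columns or c2 in t.columns:
                df[var] = t[[c for c in (c1, c2) if c in t.columns]].mean(axis=1)
            elif var in t.columns:
                df[var] = t[var]
        frames.append(df)
    if not frames:
        return []
    pooled = pd.concat(frames, ignore_index=True)
    is_transient = pooled["status"] != "persistent"
    out = []
    for var in variables:
        if var not in pooled.columns or pooled[var].notna().sum() == 0:
            continue  # censored from the family
        res = two_sample_t(pooled.loc[is_transient, var],
                           pooled.loc[~is_transient, var],
                           "transient_vs_persistent", var)
        out.append(res)
    return apply_fdr(out)


def subject_level_wgs_metrics(
    trajectories_by_subject: dict[str, pd.DataFrame],
    burden_by_sample: pd.DataFrame | None = None,
    sample_ids: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Collapse each subject to one data point (mean of the two visits).

    Returns per-subject transient proportion and transient mean VL (averaged
    over the visits where they are defined), mean |ΔVL| of persistent
    variants, and, when ``burden_by_sample`` (indexed by sample id) and
    ``sample_ids`` (subject → (V1 id, V2 id)) are given, each burden metric
    averaged over the two visits. Subjects missing a visit are censored.
    """
    rows = []
    for subject, traj in sorted(trajectories_by_subject.items()):
        p1, mvl1 = transient_summary(traj, 1)
        p2, mvl2 = transient_summary(traj, 2)
        dvl = traj.loc[traj["status"] == "persistent", "dvl"].abs()
        row = {
            "subject_id": subject,
            "transient_proportion": np.nanmean([p1, p2]) if not (
                math.isnan(p1) and math.isnan(p2)) else math.nan,
            "transient_mean_vl": np.nanmean([mvl1, mvl2]) if not (
                math.isnan(mvl1) and math.isnan(mvl2)) else math.nan,
            "mean_abs_dvl": float(dvl.mean()) if len(dvl) else math.nan,
        }
        if burden_by_sample is not None and sample_ids is not None:
            ids = sample_ids.get(subject)
            if ids is None or any(i not in burden_by_sample.index for i in ids):
                continue  # censored: missing visit
            for col in burden_by_sample.columns:
                row[col] = float(burden_by_sample.loc[list(ids), col].mean())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clinical groupings

def evolution_group_tests(
    values: pd.DataFrame,
    evolution: pd.Series,
    mode: str,
    family: str | None = None,
    min_per_group: int = 2,
) -> list[ComparisonResult]:
    """Batch Kruskal–Wallis with diagnostic evolution as grouping variable.

    ``values`` holds one column per clinical or WGS variable, already reduced
    per subject according to ``mode`` ("mean" of V1 and V2, or "delta" =
    V2 − V1). One result row per (variable, mode); FDR within the batch.
    """
    if mode not in ("mean", "delta"):
        raise LongitudinalError("mode must be 'mean' or 'delta'")
    family = family or f"evolution_{mode}"
    out = []
    for var in values.columns:
        out.append(kruskal_by_group(values[var], evolution, family,
                                    f"{var}:{mode}", min_per_group=min_per_group))
    return apply_fdr(out)


def categorical_vs_evolution(labels: pd.Series, evolution: pd.Series,
                             n_sim: int = 100_000, seed: int | None = None) -> float:
    """Fisher Monte Carlo independence of a categorical subject label
    (haplogroup, medication change) from diagnostic evolution."""
    df = pd.DataFrame({"x": labels, "e": evolution}).dropna()
    table = pd.crosstab(df["x"], df["e"]).values
    return fisher_montecarlo(table, n_sim=n_sim, seed=seed)


# ---------------------------------------------------------------------------
# clinical primitives

def edss_worsening(edss_baseline: float, edss_followup: float) -> bool:
    """Confirmed-progression thresholds: ≥1.5 from baseline 0, ≥1.0 from
    baseline 0.5–5.5, ≥0.5 from baseline ≥6.0."""
    delta = edss_followup - edss_baseline
    if edss_baseline == 0.0:
        return delta >= 1.5
    if edss_baseline < 6.0:
        return delta >= 1.0
    return delta >= 0.5


def neda3_classify(
    relapses_between_visits: float,
    gd_lesions: float,
    new_or_enlarging_t2: bool | float,
    edss_v1: float,
    edss_v2: float,
) -> bool | None:
    """No evidence of disease activity: no relapses, no gadolinium-enhancing
    lesions, no new/enlarging T2 lesions, no EDSS worsening.

    Any missing component yields ``None`` (classification absent), not False.
    """
    components = (relapses_between_visits, gd_lesions, new_or_enlarging_t2,
                  edss_v1, edss_v2)
    if any(c is None or (isinstance(c, float) and math.isnan(c)) for c in components):
        return None
    return (
        relapses_between_visits == 0
        and gd_lesions == 0
        and not bool(new_or_enlarging_t2)
        and not edss_worsening(float(edss_v1), float(edss_v2))
    )


def annualized_relapse_rate(n_relapses: float, observation_days: float) -> float:
    """Relapses per year over the observation window (365.25-day year)."""
    if observation_days <= 0:
        raise LongitudinalError("observation period must be positive")
    return n_relapses * DAYS_PER_YEAR / observation_days
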