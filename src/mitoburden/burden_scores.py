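"""Pathogenicity annotation and per-sample / per-region burden scores.

Protein-coding variants carry two in-silico pathogenicity scores (MutPred and
APOGEE, both on [0, 1]); their mean is the *deleterious score*, and a variant
is flagged deleterious when that mean exceeds 0.5. tRNA variants carry the
raw MitoTIP score instead. From these the module computes:

* cumulative deleterious burden — per sample, Σ VL × deleterious score;
* cumulative MitoTIP score     — per sample, Σ VL × MitoTIP over tRNA variants;
* adjusted mutational rate     — per region, Σ VL / region size (per bp);
* adjusted deleterious rate and adjusted MitoTIP rate — same, with
  VL × score in the numerator.

Variants falling in multi-locus overlaps are booked under the complement
macro ``Other`` only, never under both parent genes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .region_map import MACRO_REGIONS, PROTEIN_MACROS, RegionMap

DELETERIOUS_CUTOFF = 0.5
#: raw MitoTIP score above which a tRNA variant is called likely pathogenic
#: (public quartile boundary used by MITOMAP)
MITOTIP_PATHOGENIC_THRESHOLD = 12.66


class ScoreError(ValueError):
    pass


def load_score_table(path: str | Path) -> pd.DataFrame:
    """Score table TSV keyed by (pos, ref, alt) with columns ``mutpred``,
    ``apogee``, ``mitotip`` (any may be empty)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"pos", "ref", "alt"}
    if not needed <= set(df.columns):
        raise ScoreError(f"{path}: score table needs columns {sorted(needed)}")
    for col in ("mutpred", "apogee", "mitotip"):
        if col not in df.columns:
            df[col] = np.nan
    _validate_unit_scores(df)
    return df[["pos", "ref", "alt", "mutpred", "apogee", "mitotip"]]


def _validate_unit_scores(df: pd.DataFrame) -> None:
    for col in ("mutpred", "apogee"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ScoreError(f"{col} scores outside [0, 1]")


def assign_regions(variants: pd.DataFrame, region_map: RegionMap) -> pd.DataFrame:
    """Add exclusive ``locus`` and ``macro`` columns (overlaps → Other)."""
    out = variants.copy()
    pos = out["pos"].to_numpy(dtype=np.int64)
    out["locus"] = region_map.locus_vector(pos)
    out["macro"] = region_map.macro_vector(pos)
    return out


def annotate_scores(
    variants: pd.DataFrame,
    score_table: pd.DataFrame,
    region_map: RegionMap,
) -> pd.DataFrame:
    """Attach pathogenicity scores by (pos, ref, alt), routed by locus class.

    Protein-complex variants receive MutPred/APOGEE and the derived
    deleterious score; tRNA variants receive MitoTIP; all other variants
    (rRNA, D-loop, overlaps) receive no scores.
    """
    _validate_unit_scores(score_table)
    ann = assign_regions(variants, region_map)
    merged = ann.merge(
        score_table[["pos", "ref", "alt", "mutpred", "apogee", "mitotip"]],
        on=["pos", "ref", "alt"],
        how="left",
    )
    is_protein = merged["macro"].isin(PROTEIN_MACROS)
    is_trna = merged["macro"] == "tRNA"
    merged.loc[~is_protein, ["mutpred", "apogee"]] = np.nan
    merged.loc[~is_trna, "mitotip"] = np.nan

    both = merged["mutpred"].notna() & merged["apogee"].notna()
    merged["deleterious_score"] = np.where(
        both, (merged["mutpred"] + merged["apogee"]) / 2.0, np.nan
    )
    merged["is_deleterious"] = both & (merged["deleterious_score"] > DELETERIOUS_CUTOFF)
    merged["is_pathogenic_trna"] = merged["mitotip"] > MITOTIP_PATHOGENIC_THRESHOLD
    return merged


def flag_pathogenic_trna(mitotip: float, threshold: float = MITOTIP_PATHOGENIC_THRESHOLD) -> bool:
    return bool(mitotip > threshold)


def _scored(variants: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope not in ("all_scored", "deleterious_only"):
        raise ScoreError(f"unknown burden scope {scope!r}")
    sel = variants["deleterious_score"].notna()
    if scope == "deleterious_only":
        sel &= variants["is_deleterious"]
    return variants[sel]


def cumulative_deleterious_burden(variants: pd.DataFrame, scope: str = "all_scored") -> float:
    """Σ VL × deleterious score over scored protein variants of one sample."""
    sub = _scored(variants, scope)
    return float((sub["vl"] * sub["deleterious_score"]).sum())


def cumulative_mitotip(variants: pd.DataFrame) -> float:
    """Σ VL × MitoTIP over tRNA variants of one sample."""
    sub = variants[variants["mitotip"].notna()]
    return float((sub["vl"] * sub["mitotip"]).sum())


def _region_subset(variants: pd.DataFrame, region: str, region_map: RegionMap) -> pd.DataFrame:
    if region in MACRO_REGIONS and region not in region_map.locus_names:
        return variants[variants["macro"] == region]
    if region not in region_map.locus_names:
        raise ScoreError(f"unknown region {region!r}")
    return variants[variants["locus"] == region]


def adjusted_mutational_rate(variants: pd.DataFrame, region: str, region_map: RegionMap) -> float:
    """Σ VL of the region's variants divided by its size in bp."""
    sub = _region_subset(variants, region, region_map)
    return float(sub["vl"].sum()) / region_map.region_size(region)


def adjusted_deleterious_rate(
    variants: pd.DataFrame, region: str, region_map: RegionMap, scope: str = "all_scored"
) -> float:
    """Σ VL × deleterious score in the region, divided by its size in bp."""
    sub = _scored(_region_subset(variants, region, region_map), scope)
    return float((sub["vl"] * sub["deleterious_score"]).sum()) / region_map.region_size(region)


def adjusted_mitotip_rate(variants: pd.DataFrame, region: str, region_map: RegionMap) -> float:
    """Σ VL × MitoTIP in the region, divided by its size in bp."""
    sub = _region_subset(variants, region, region_map)
    sub = sub[sub["mitotip"].notna()]
    return float((sub["vl"] * sub["mitotip"]).sum()) / region_map.region_size(region)


def burden_table(
    sample_variants: dict[str, pd.DataFrame],
    region_map: RegionMap,
    regions: Iterable[str] | None = None,
    scope: str = "all_scored",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample summary scores and a long-format per-(sample, region) table.

    ``sample_variants`` maps sample id → annotated variant frame. ``regions``
    defaults to every locus plus every macro region.
    """
    if regions is None:
        regions = list(region_map.locus_names) + [
            m for m in MACRO_REGIONS if m not in region_map.locus_names
        ]
    regions = list(regions)

    per_sample_rows = []
    long_rows = []
    for sid in sorted(sample_variants):
        df = sample_variants[sid]
        per_sample_rows.append(
            {
                "sample_id": sid,
                "n_variants": int(len(df)),
                "n_deleterious": int(df["is_deleterious"].sum()),
                "cumulative_deleterious_burden": cumulative_deleterious_burden(df, scope),
                "cumulative_mitotip": cumulative_mitotip(df),
            }
        )
        for region in regions:
            long_rows.append(
                {
                    "sample_id": sid,
                    "region": region,
                    "adjusted_mutational_rate": adjusted_mutational_rate(df, region, region_map),
                    "adjusted_deleterious_rate": adjusted_deleterious_rate(
                        df, region, region_map, scope
                    ),
                    "adjusted_mitotip_rate": adjusted_mitotip_rate(df, region, region_map),
                }
            )
    per_sample = pd.DataFrame(per_sample_rows)
    long = pd.DataFrame(
        long_rows,
        columns=["sample_id", "region", "adjusted_mutational_rate",
                 "adjusted_deleterious_rate", "adjusted_mitotip_rate"],
    ).melt(id_vars=["sample_id", "region"], var_name="metric", value_name="value")
    return per_sample, long
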