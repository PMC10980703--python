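"""End-to-end orchestration: ingest → score → cross-sectional → longitudinal.

Works either on an in-memory :class:`~mitoburden.synthetic_cohort.SyntheticCohort`
(the test and acceptance path) or on an input directory in the same dialects
(``pcp/*.tsv``, ``tss/*.vcf``, ``sample_sheet.tsv``, ``scores.tsv``,
``allowlist.tsv``, ``clinical.tsv``). All stochastic steps take their seeds
from the run configuration, and outputs carry no timestamps, so a rerun with
identical config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden_scores as bs
from . import cohort_stats as cs
from . import longitudinal as lg
from .region_map import MACRO_REGIONS, RegionMap, load_region_map
from .synthetic_cohort import SyntheticCohort
from .variant_ingest import (
    CallerRecord,
    FilterLog,
    RescueThresholds,
    consensus_filter,
    consensus_frame,
    load_allowlist,
    parse_pcp_table,
    parse_tss_vcf,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Settings of one pipeline run (YAML-serializable)."""

    seed: int = 0
    burden_scope: str = "all_scored"
    fisher_nsim: int = 100_000
    mcnemar_exact_max: int = 25
    rescue: RescueThresholds = field(default_factory=RescueThresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        rescue = RescueThresholds(**raw.pop("filter", {}))
        stats = raw.pop("stats", {})
        return cls(
            seed=int(stats.get("seed", raw.get("seed", 0))),
            burden_scope=raw.get("burden_scope", "all_scored"),
            fisher_nsim=int(stats.get("fisher_nsim", 100_000)),
            mcnemar_exact_max=int(stats.get("mcnemar_exact_max", 25)),
            rescue=rescue,
        )


# ---------------------------------------------------------------------------
# stage 1: ingest

def _records_from_frame(df: pd.DataFrame, sample_id: str, caller: str) -> list[CallerRecord]:
    recs = []
    for row in df.itertuples(index=False):
        recs.append(CallerRecord(
            sample_id=sample_id, pos=int(row.pos), ref=str(row.ref),
            alt=str(row.alt), vl=float(row.vl), caller=caller,
            norm_cov=float(getattr(row, "norm_cov", math.nan)),
            cov_ratio=float(getattr(row, "cov_ratio", math.nan)),
            numt_mean=float(getattr(row, "numt_mean", math.nan)),
            edge_dist=float(getattr(row, "edge_dist", math.nan)),
        ))
    return recs


def ingest_cohort(
    cohort: SyntheticCohort,
    rescue: RescueThresholds | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, FilterLog]]:
    """Consensus-filter every sample of an in-memory cohort."""
    rescue = rescue or RescueThresholds()
    accepted, logs = {}, {}
    for sid in cohort.sample_sheet["sample_id"]:
        pcp = _records_from_frame(cohort.pcp[sid], sid, "PCP")
        tss = _records_from_frame(cohort.tss[sid], sid, "TSS")
        kept, log = consensus_filter(pcp, tss, rescue, cohort.allowlist)
        accepted[sid] = consensus_frame(kept)
        logs[sid] = log
    return accepted, logs


def score_cohort(
    accepted: dict[str, pd.DataFrame],
    score_table: pd.DataFrame,
    region_map: RegionMap,
) -> dict[str, pd.DataFrame]:
    """Annotate every sample; one cohort-wide merge, then split per sample
    (equivalent to per-sample :func:`~mitoburden.burden_scores.annotate_scores`)."""
    ids = list(accepted)
    pooled = pd.concat([accepted[sid].assign(_sid=sid) for sid in ids],
                       ignore_index=True)
    annotated = bs.annotate_scores(pooled, score_table, region_map)
    empty = annotated.iloc[0:0].drop(columns="_sid")
    out = {sid: empty.copy() for sid in ids}
    for sid, grp in annotated.groupby("_sid", sort=False):
        out[sid] = grp.drop(columns="_sid").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# stage 2: cross-sectional paired comparisons (patient V1 vs matched HC)

def _pair_frames(sample_sheet: pd.DataFrame, annotated: dict[str, pd.DataFrame]
                 ) -> list[tuple[int, pd.DataFrame, pd.DataFrame]]:
    pairs = []
    for pair_id, grp in sample_sheet.groupby("pair_id"):
        v1 = grp.loc[grp["role"] == "V1", "sample_id"]
        hc = grp.loc[grp["role"] == "HC", "sample_id"]
        if len(v1) == 1 and len(hc) == 1:
            pairs.append((int(pair_id), annotated[v1.iloc[0]], annotated[hc.iloc[0]]))
    return pairs


def _discordant_split(df_a: pd.DataFrame, df_b: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    keys_a = set(zip(df_a["pos"], df_a["alt"]))
    keys_b = set(zip(df_b["pos"], df_b["alt"]))
    only_a = df_a[[k not in keys_b for k in zip(df_a["pos"], df_a["alt"])]]
    only_b = df_b[[k not in keys_a for k in zip(df_b["pos"], df_b["alt"])]]
    return only_a, only_b


def _region_flag_matrix(frames: list[pd.DataFrame], col: str, regions: list[str],
                        deleterious: bool) -> np.ndarray:
    """pairs × regions boolean carrier matrix for one pair member."""
    mat = np.zeros((len(frames), len(regions)), dtype=bool)
    index = {r: j for j, r in enumerate(regions)}
    for i, df in enumerate(frames):
        sub = df[df["is_deleterious"]] if deleterious else df
        for r in sub[col].unique():
            j = index.get(r)
            if j is not None:
                mat[i, j] = True
    return mat


def _region_rate_matrix(frames: list[pd.DataFrame], col: str, regions: list[str],
                        region_map: RegionMap, numerator: str) -> np.ndarray:
    """pairs × regions matrix of ΣVL (or ΣVL×score) / region size."""
    sizes = np.array([region_map.region_size(r) for r in regions], dtype=float)
    index = {r: j for j, r in enumerate(regions)}
    mat = np.zeros((len(frames), len(regions)))
    for i, df in enumerate(frames):
        if numerator == "vl":
            weights = df["vl"]
        else:
            weights = (df["vl"] * df["deleterious_score"]).fillna(0.0)
        sums = weights.groupby(df[col]).sum()
        for r, v in sums.items():
            j = index.get(r)
            if j is not None:
                mat[i, j] = v
    return mat / sizes


def cross_sectional(
    annotated: dict[str, pd.DataFrame],
    sample_sheet: pd.DataFrame,
    region_map: RegionMap,
    config: RunConfig,
    discordant_only: bool = True,
    run_fisher: bool = True,
) -> dict:
    """The full paired battery: prevalence McNemar and rate paired-t per
    locus and per macro region (all variants and deleterious variants),
    per-variant McNemar, haplogroup Kruskal–Wallis on the four per-sample
    scores, and (unless ``run_fisher`` is off) Fisher Monte Carlo of
    haplogroup × subject type."""
    pairs = _pair_frames(sample_sheet, annotated)
    if not pairs:
        raise PipelineError("no complete V1/HC pairs in sample sheet")
    loci = list(region_map.locus_names)
    macros = [m for m in MACRO_REGIONS if m not in loci]
    results: list[cs.ComparisonResult] = []

    frames_a = [a for _, a, _ in pairs]
    frames_b = [b for _, _, b in pairs]
    disc = [_discordant_split(a, b) for _, a, b in pairs]
    disc_a = [d[0] for d in disc]
    disc_b = [d[1] for d in disc]

    for family, regions, col, deleterious in (
        ("locus_prevalence", loci, "locus", False),
        ("macro_prevalence", macros, "macro", False),
        ("locus_deleterious_prevalence", loci, "locus", True),
        ("macro_deleterious_prevalence", macros, "macro", True),
    ):
        mat_a = _region_flag_matrix(frames_a, col, regions, deleterious)
        mat_b = _region_flag_matrix(frames_b, col, regions, deleterious)
        for j, region in enumerate(regions):
            results.append(cs.mcnemar_result(
                family, region, cs.discordant_prevalence(mat_a[:, j], mat_b[:, j])))

    rate_a = disc_a if discordant_only else frames_a
    rate_b = disc_b if discordant_only else frames_b
    for family, regions, col, numerator in (
        ("locus_rates", loci, "locus", "vl"),
        ("macro_rates", macros, "macro", "vl"),
        ("locus_deleterious_rates", loci, "locus", "vl_score"),
        ("macro_deleterious_rates", macros, "macro", "vl_score"),
    ):
        mat_a = _region_rate_matrix(rate_a, col, regions, region_map, numerator)
        mat_b = _region_rate_matrix(rate_b, col, regions, region_map, numerator)
        for j, region in enumerate(regions):
            results.append(cs.paired_t(mat_a[:, j], mat_b[:, j], family, region))

    # per-variant McNemar across every (pos, alt) seen in ≥1 pair member
    keys_a = [set(zip(a["pos"], a["alt"])) for a in frames_a]
    keys_b = [set(zip(b["pos"], b["alt"])) for b in frames_b]
    all_keys = sorted(set().union(*keys_a, *keys_b))
    for key in all_keys:
        fa = np.array([key in s for s in keys_a])
        fb = np.array([key in s for s in keys_b])
        results.append(cs.mcnemar_result(
            "per_variant", f"{key[0]}:{key[1]}", cs.discordant_prevalence(fa, fb)))

    # haplogroup effects on per-sample summary scores; seeded permutation
    # reference because the chi-square approximation is anticonservative on
    # the small rare-haplogroup groups and heavily tied sparse scores
    per_sample, _ = bs.burden_table({sid: annotated[sid]
                                     for sid in sample_sheet["sample_id"]},
                                    region_map, regions=[], scope=config.burden_scope)
    merged = per_sample.merge(sample_sheet, on="sample_id")
    xs = merged[merged["role"].isin(["HC", "V1"])]
    kw_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(3,)))
    for metric in ("n_variants", "n_deleterious", "cumulative_deleterious_burden",
                   "cumulative_mitotip"):
        results.append(cs.haplogroup_variant_test(
            xs[metric], xs["haplogroup"], "haplogroup", metric,
            n_perm=2000, rng=kw_rng))

    results = cs.apply_fdr(results)

    fisher_p = math.nan
    if run_fisher:
        table = pd.crosstab(xs["haplogroup"], xs["role"]).values
        fisher_p = cs.fisher_montecarlo(table, n_sim=config.fisher_nsim,
                                        seed=config.seed + 1)
    return {
        "results": results,
        "per_sample_scores": merged,
        "haplogroup_by_group_fisher_p": fisher_p,
        "n_pairs": len(pairs),
    }


# ---------------------------------------------------------------------------
# stage 3: longitudinal

def longitudinal_analysis(
    annotated: dict[str, pd.DataFrame],
    sample_sheet: pd.DataFrame,
    clinical: pd.DataFrame,
    region_map: RegionMap,
    config: RunConfig,
) -> dict:
    patients = sample_sheet[sample_sheet["group"] == "PwMS"]
    sample_ids: dict[str, tuple[str, str]] = {}
    trajectories: dict[str, pd.DataFrame] = {}
    for subject, grp in patients.groupby("subject_id"):
        v1 = grp.loc[grp["role"] == "V1", "sample_id"]
        v2 = grp.loc[grp["role"] == "V2", "sample_id"]
        if len(v1) != 1 or len(v2) != 1:
            continue  # censored: missing visit
        sample_ids[subject] = (v1.iloc[0], v2.iloc[0])
        trajectories[subject] = lg.match_visits(annotated[v1.iloc[0]],
                                                annotated[v2.iloc[0]])

    per_sample, _ = bs.burden_table(annotated, region_map, regions=[],
                                    scope=config.burden_scope)
    burden_idx = per_sample.set_index("sample_id")
    subject_metrics = lg.subject_level_wgs_metrics(trajectories, burden_idx, sample_ids)

    results = lg.vl_change_test(trajectories)
    results += lg.transient_vs_persistent(trajectories)

    # diagnostic-evolution batteries over clinical and WGS variables
    evolution = clinical.drop_duplicates("subject_id").set_index("subject_id")["evolution"]
    clin_vars = [c for c in clinical.columns
                 if c not in ("subject_id", "visit", "diagnosis", "evolution")
                 and pd.api.types.is_numeric_dtype(clinical[c])]
    wide = clinical.pivot_table(index="subject_id", columns="visit", values=clin_vars)
    sm = subject_metrics.set_index("subject_id")
    for mode in ("mean", "delta"):
        values = {}
        for var in clin_vars:
            if (var, 1) in wide.columns and (var, 2) in wide.columns:
                values[var] = (wide[(var, 1)] + wide[(var, 2)]) / 2 if mode == "mean" \
                    else wide[(var, 2)] - wide[(var, 1)]
        frame = pd.DataFrame(values)
        if mode == "mean":  # WGS variables are already per-subject means
            for col in ("transient_proportion", "transient_mean_vl", "mean_abs_dvl",
                        "cumulative_deleterious_burden", "cumulative_mitotip"):
                if col in sm.columns:
                    frame[col] = sm[col]
        results += lg.evolution_group_tests(frame, evolution.reindex(frame.index), mode)

    hg = patients.drop_duplicates("subject_id").set_index("subject_id")["haplogroup"]
    common = evolution.index.intersection(hg.index)
    fisher_p = lg.categorical_vs_evolution(hg.loc[common], evolution.loc[common],
                                           n_sim=config.fisher_nsim,
                                           seed=config.seed + 2)
    return {
        "trajectories": trajectories,
        "subject_metrics": subject_metrics,
        "results": results,
        "haplogroup_by_evolution_fisher_p": fisher_p,
    }


# ---------------------------------------------------------------------------
# in-memory end-to-end + file-based runner

def analyze_cohort(cohort: SyntheticCohort, config: RunConfig,
                   region_map: RegionMap | None = None) -> dict:
    """Run every analysis stage on an in-memory cohort."""
    region_map = region_map or load_region_map()
    accepted, logs = ingest_cohort(cohort, config.rescue)
    annotated = score_cohort(accepted, cohort.score_table, region_map)
    xs = cross_sectional(annotated, cohort.sample_sheet, region_map, config)
    long = longitudinal_analysis(annotated, cohort.sample_sheet, cohort.clinical,
                                 region_map, config)
    return {"accepted": accepted, "annotated": annotated, "filter_logs": logs,
            "cross_sectional": xs, "longitudinal": long}


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "family": r.family, "unit": r.unit, "test": r.test_name,
        "statistic": r.statistic, "p_raw": r.p_raw, "p_fdr": r.p_fdr,
        "effect": r.effect, "n": r.n, "note": r.note,
    } for r in results])


def load_cohort_dir(indir: str | Path, config: RunConfig) -> SyntheticCohort:
    """Read a cohort directory written by ``write_cohort`` (or assembled by
    hand in the same dialects) back into the in-memory container."""
    indir = Path(indir)
    for name in ("sample_sheet.tsv", "scores.tsv", "allowlist.tsv"):
        if not (indir / name).exists():
            raise PipelineError(f"missing input file: {indir / name}")
    sheet = pd.read_csv(indir / "sample_sheet.tsv", sep="\t")
    pcp, tss = {}, {}
    for sid in sheet["sample_id"]:
        pcp_path = indir / "pcp" / f"{sid}.tsv"
        vcf_path = indir / "tss" / f"{sid}.vcf"
        if not pcp_path.exists() or not vcf_path.exists():
            raise PipelineError(f"missing caller output for sample {sid}")
        pcp[sid] = pd.DataFrame(
            [{"sample_id": r.sample_id, "pos": r.pos, "ref": r.ref, "alt": r.alt,
              "vl": r.vl, "norm_cov": r.norm_cov, "cov_ratio": r.cov_ratio,
              "numt_mean": r.numt_mean, "edge_dist": r.edge_dist}
             for r in parse_pcp_table(pcp_path)],
            columns=["sample_id", "pos", "ref", "alt", "vl", "norm_cov",
                     "cov_ratio", "numt_mean", "edge_dist"])
        tss[sid] = pd.DataFrame(
            [{"pos": r.pos, "ref": r.ref, "alt": r.alt, "vl": r.vl}
             for r in parse_tss_vcf(vcf_path, sample_id=sid)],
            columns=["pos", "ref", "alt", "vl"])
    clinical_path = indir / "clinical.tsv"
    clinical = pd.read_csv(clinical_path, sep="\t") if clinical_path.exists() \
        else pd.DataFrame(columns=["subject_id", "visit", "evolution"])
    from .burden_scores import load_score_table
    truth_path = indir / "ground_truth.tsv"
    return SyntheticCohort(
        config=None, sample_sheet=sheet, pcp=pcp, tss=tss,
        score_table=load_score_table(indir / "scores.tsv"),
        clinical=clinical,
        allowlist=load_allowlist(indir / "allowlist.tsv"),
        ground_truth=pd.read_csv(truth_path, sep="\t") if truth_path.exists()
        else pd.DataFrame(),
    )


def run_pipeline(indir: str | Path, outdir: str | Path, config: RunConfig,
                 region_map_path: str | Path | None = None) -> Path:
    """File-based run: read a cohort directory, execute all stages, write the
    report bundle (accepted-variant TSVs, burden tables, comparison tables,
    summary JSON, deterministic run log)."""
    indir, outdir = Path(indir), Path(outdir)
    region_map = load_region_map(region_map_path)
    cohort = load_cohort_dir(indir, config)
    out = analyze_cohort(cohort, config, region_map)

    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    acc_dir = outdir / "accepted"
    acc_dir.mkdir(exist_ok=True)
    for sid in sorted(out["annotated"]):
        out["annotated"][sid].to_csv(acc_dir / f"{sid}.tsv", sep="\t", index=False,
                                     float_format=fmt)
    per_sample, long = bs.burden_table(out["annotated"], region_map,
                                       scope=config.burden_scope)
    per_sample.to_csv(outdir / "burden_per_sample.tsv", sep="\t", index=False,
                      float_format=fmt)
    long.to_csv(outdir / "burden_per_region.tsv", sep="\t", index=False,
                float_format=fmt)
    _results_frame(out["cross_sectional"]["results"]).to_csv(
        outdir / "cross_sectional_tests.tsv", sep="\t", index=False, float_format=fmt)
    _results_frame(out["longitudinal"]["results"]).to_csv(
        outdir / "longitudinal_tests.tsv", sep="\t", index=False, float_format=fmt)
    out["longitudinal"]["subject_metrics"].to_csv(
        outdir / "subject_metrics.tsv", sep="\t", index=False, float_format=fmt)

    cfg = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    summary = {
        "schema_version": 1,
        "config": cfg,
        "config_hash": cfg_hash,
        "n_samples": int(len(cohort.sample_sheet)),
        "n_pairs": out["cross_sectional"]["n_pairs"],
        "haplogroup_by_group_fisher_p":
            out["cross_sectional"]["haplogroup_by_group_fisher_p"],
        "haplogroup_by_evolution_fisher_p":
            out["longitudinal"]["haplogroup_by_evolution_fisher_p"],
        "filter": {sid: vars(log) for sid, log in sorted(out["filter_logs"].items())},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "run.log").write_text(
        f"config_hash={cfg_hash}\nseed={config.seed}\n"
        f"n_samples={len(cohort.sample_sheet)}\n")
    return outdir
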