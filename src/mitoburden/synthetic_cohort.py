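"""Seeded generator of synthetic matched triplet cohorts.

Each triplet holds one patient sequenced at two visits (V1, V2) and one
healthy control (HC) matched on sex and age (±5 years). The generator
emulates, at the caller-output level, the structure such a cohort shows in
practice:

* European haplogroup mix with haplogroup-defining homoplasmies, so variant
  counts are bimodal — H/HV (the reference's own clade) carry few backbone
  variants, other haplogroups many;
* private heteroplasmies at low variant level (Beta-distributed, mostly
  below the 10% dual-caller threshold, exercising the rescue path);
* transient heteroplasmies present at one visit only, at stochastically
  lower VL than persistent ones; persistent VLs drift by a small
  zero-centred Gaussian between visits;
* haplogroup-linked pathogenicity structure: J/T backbone variants draw
  higher MutPred/APOGEE scores, K/U tRNA variants higher MitoTIP, H/HV lower;
* the vendor caller (TSS) echoes the read-level caller (PCP) with a small
  dropout below 10% VL plus occasional TSS-only artifacts, exercising every
  branch of the consensus filter;
* clinical records drawn in realistic ranges with the observed diagnostic
  evolution mix (CIS–CIS 23%, CIS–RRMS 13%, RRMS–RRMS 64%).

Every variant's true status (backbone / persistent / transient / artifact /
injected), true scores, and expected post-filter fate are recorded in a
ground-truth ledger so pipeline recovery is checkable. One master seed
spawns an independent substream per triplet, so adding triplets never
perturbs existing ones.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .region_map import PROTEIN_MACROS, RegionMap, load_region_map
from .variant_ingest import CONSENSUS_VL_THRESHOLD, RescueThresholds

BASES = ("A", "C", "G", "T")

EVOLUTIONS = ("CIS-CIS", "CIS-RRMS", "RRMS-RRMS")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSpec:
    """Injected group difference in deleterious-carrier prevalence."""

    group: str  # "V1" or "HC"
    macro_region: str
    prevalence_delta: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort (all rates per sample)."""

    n_triplets: int = 61
    seed: int = 0
    haplogroup_freqs: dict = field(default_factory=lambda: {
        "H": 0.40, "HV": 0.03, "U": 0.15, "K": 0.08, "J": 0.09,
        "T": 0.09, "V": 0.05, "W": 0.04, "X": 0.03, "I": 0.04,
    })
    # haplogroup-defining homoplasmy counts: (mean, sd); H/HV sit near the
    # rCRS backbone, other clades carry ~25-35 defining variants
    backbone_counts: dict = field(default_factory=lambda: {
        "H": (5, 2), "HV": (7, 2), "V": (11, 3), "U": (28, 4), "K": (30, 4),
        "J": (32, 4), "T": (31, 4), "W": (26, 4), "X": (27, 4), "I": (29, 4),
    })
    private_het_rate: float = 3.0      # Poisson mean heteroplasmies/sample
    vl_beta: tuple = (1.0, 12.0)       # private-heteroplasmy VL distribution
    transient_rate: float = 0.30       # P(a private heteroplasmy is transient)
    transient_vl_scale: float = 0.5    # transient VLs drawn lower by this factor
    drift_sd: float = 0.01             # sd of persistent VL change V1→V2
    tss_dropout_low_vl: float = 0.05   # P(TSS misses a variant with VL < 10%)
    tss_artifact_rate: float = 0.5     # P(one TSS-only artifact per sample)
    rescue_fail_rate: float = 0.05     # P(a low-VL variant draws failing QC)
    allowlist_rate: float = 0.90       # P(a private variant is in curated DB)
    effect: EffectSpec | None = None
    # False flattens all haplogroup-linked structure (equal backbone counts
    # and score distributions) and is used together with transient_rate=0 to
    # build fully exchangeable null cohorts for type-I-error calibration
    haplogroup_structure: bool = True
    # clinical realism
    evolution_probs: tuple = (0.23, 0.13, 0.64)
    age_range: tuple = (19, 56)
    female_fraction: float = 0.66
    t2_evolution_shift: float = 6.0    # extra mean T2 lesions for RRMS-RRMS

    def __post_init__(self) -> None:
        for name, probs in (("haplogroup_freqs", tuple(self.haplogroup_freqs.values())),
                            ("evolution_probs", self.evolution_probs)):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise SimulationError(f"{name} must sum to 1")
        if self.n_triplets < 1:
            raise SimulationError("n_triplets must be positive")


@dataclass
class SyntheticCohort:
    config: SimConfig
    sample_sheet: pd.DataFrame
    pcp: dict[str, pd.DataFrame]
    tss: dict[str, pd.DataFrame]
    score_table: pd.DataFrame
    clinical: pd.DataFrame
    allowlist: set
    ground_truth: pd.DataFrame


# ---------------------------------------------------------------------------
# haplogroup variant pools (deterministic per haplogroup, independent of seed)

_SCORE_PARAMS = {  # Beta(a, b) for MutPred/APOGEE of backbone protein variants
    "J": (6.0, 4.0), "T": (6.0, 4.0),
    "H": (2.0, 8.0), "HV": (2.0, 8.0),
}
# low outside J/T so deleterious carriers stay a minority, as in real cohorts
_DEFAULT_SCORE_PARAMS = (1.5, 8.0)

_MITOTIP_PARAMS = {  # Normal(mu, sd) for MitoTIP of backbone tRNA variants
    "K": (8.0, 2.0), "U": (8.0, 2.0),
    "H": (3.0, 1.5), "HV": (3.0, 1.5),
}
_DEFAULT_MITOTIP_PARAMS = (5.0, 2.0)

_POOL_SIZE = 80


def _haplogroup_pool(haplogroup: str, region_map: RegionMap,
                     structured: bool = True) -> pd.DataFrame:
    """Fixed pool of candidate backbone variants for one haplogroup.

    The pool is seeded by the haplogroup name alone, so V1/V2 samples of one
    subject — and different cohorts — agree on what defines each clade.
    """
    seed = int.from_bytes(
        hashlib.sha256(f"mitoburden-pool-{haplogroup}".encode()).digest()[:4], "big"
    )
    rng = np.random.default_rng(seed)
    pos = rng.choice(np.arange(1, region_map.genome_length + 1), size=_POOL_SIZE,
                     replace=False)
    pos.sort()
    refs = rng.choice(BASES, size=_POOL_SIZE)
    alts = np.array([rng.choice([b for b in BASES if b != r]) for r in refs])
    macro = region_map.macro_vector(pos)
    a, b = _SCORE_PARAMS.get(haplogroup, _DEFAULT_SCORE_PARAMS) if structured \
        else _DEFAULT_SCORE_PARAMS
    mutpred = rng.beta(a, b, size=_POOL_SIZE)
    apogee = rng.beta(a, b, size=_POOL_SIZE)
    mu, sd = _MITOTIP_PARAMS.get(haplogroup, _DEFAULT_MITOTIP_PARAMS) if structured \
        else _DEFAULT_MITOTIP_PARAMS
    mitotip = np.clip(rng.normal(mu, sd, size=_POOL_SIZE), 0.0, 12.0)
    df = pd.DataFrame({
        "pos": pos.astype(int), "ref": refs, "alt": alts, "macro": macro,
        "mutpred": np.where(np.isin(macro, list(PROTEIN_MACROS)), mutpred, np.nan),
        "apogee": np.where(np.isin(macro, list(PROTEIN_MACROS)), apogee, np.nan),
        "mitotip": np.where(macro == "tRNA", mitotip, np.nan),
    })
    return df


# ---------------------------------------------------------------------------
# per-variant bookkeeping

@dataclass
class _TrueVariant:
    subject_id: str
    pos: int
    ref: str
    alt: str
    category: str       # backbone | persistent | transient_v1 | transient_v2 | injected
    vl_v1: float        # NaN when absent at that visit
    vl_v2: float
    mutpred: float
    apogee: float
    mitotip: float
    in_db: bool = True  # curated allow-list membership, fixed per variant


class _ScoreRegistry:
    """Cohort-wide (pos, ref, alt) → scores, assigned once on first use."""

    def __init__(self, region_map: RegionMap):
        self.region_map = region_map
        self.scores: dict[tuple[int, str, str], tuple[float, float, float]] = {}

    def ensure(self, pos: int, ref: str, alt: str, rng: np.random.Generator,
               mutpred: float = math.nan, apogee: float = math.nan,
               mitotip: float = math.nan) -> tuple[float, float, float]:
        key = (pos, ref, alt)
        if key in self.scores:
            return self.scores[key]
        macro = self.region_map.macro_at(pos)
        if macro in PROTEIN_MACROS:
            if math.isnan(mutpred):
                mutpred = float(rng.beta(2.0, 6.0))
            if math.isnan(apogee):
                apogee = float(rng.beta(2.0, 6.0))
            mitotip = math.nan
        elif macro == "tRNA":
            if math.isnan(mitotip):
                mitotip = float(np.clip(rng.normal(5.0, 2.0), 0.0, 12.0))
            mutpred = apogee = math.nan
        else:
            mutpred = apogee = mitotip = math.nan
        self.scores[key] = (mutpred, apogee, mitotip)
        return self.scores[key]

    def frame(self) -> pd.DataFrame:
        rows = [
            {"pos": k[0], "ref": k[1], "alt": k[2],
             "mutpred": v[0], "apogee": v[1], "mitotip": v[2]}
            for k, v in sorted(self.scores.items())
        ]
        return pd.DataFrame(rows, columns=["pos", "ref", "alt", "mutpred",
                                           "apogee", "mitotip"])


# ---------------------------------------------------------------------------
# cohort simulation

def _triplet_rng(seed: int, triplet: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(triplet, stream)))


def _draw_quality(rng: np.random.Generator, fail: bool) -> dict:
    q = {
        "norm_cov": float(rng.uniform(0.7, 1.3)),
        "cov_ratio": float(rng.uniform(0.7, 1.4)),
        "numt_mean": float(rng.uniform(0.0, 0.8)),
        "edge_dist": float(rng.uniform(6.0, 60.0)),
    }
    if fail:
        q["edge_dist"] = float(rng.uniform(0.0, 4.0))
    return q


def simulate_cohort(config: SimConfig, region_map: RegionMap | None = None) -> SyntheticCohort:
    """Generate a full synthetic triplet cohort with ground-truth ledger."""
    region_map = region_map or load_region_map()
    rescue = RescueThresholds()
    registry = _ScoreRegistry(region_map)
    if config.haplogroup_structure:
        pools = {hg: _haplogroup_pool(hg, region_map) for hg in config.haplogroup_freqs}
    else:
        # one shared pool: the haplogroup label carries no information at all
        shared = _haplogroup_pool("null", region_map, structured=False)
        pools = {hg: shared for hg in config.haplogroup_freqs}
    hg_names = list(config.haplogroup_freqs)
    hg_probs = np.array([config.haplogroup_freqs[h] for h in hg_names])

    sheet_rows, clinical_rows, truth_rows = [], [], []
    pcp: dict[str, pd.DataFrame] = {}
    tss: dict[str, pd.DataFrame] = {}
    allowlist: set[tuple[int, str]] = set()

    for i in range(config.n_triplets):
        rng = _triplet_rng(config.seed, i, 0)
        sex = "F" if rng.random() < config.female_fraction else "M"
        lo, hi = config.age_range
        age_p = int(rng.integers(lo, hi + 1))
        age_h = int(np.clip(age_p + rng.integers(-5, 6), lo, hi))
        hg_p = str(rng.choice(hg_names, p=hg_probs))
        hg_h = str(rng.choice(hg_names, p=hg_probs))
        tid = f"T{i:03d}"

        for role, subject, hg, age in (
            ("HC", f"HC{i:03d}", hg_h, age_h),
            ("PwMS", f"P{i:03d}", hg_p, age_p),
        ):
            visits = (1,) if role == "HC" else (1, 2)
            variants = _simulate_subject_variants(
                subject, hg, visits, config, pools[hg], region_map, registry, rng
            )
            truth_rows.extend(variants)
            for v in visits:
                sample_id = f"{tid}-{'HC' if role == 'HC' else f'V{v}'}"
                pcp_df, tss_df, keeps = _emit_sample(
                    sample_id, variants, v, config, rescue, allowlist, rng
                )
                pcp[sample_id] = pcp_df
                tss[sample_id] = tss_df
                for var, kept in keeps:
                    setattr(var, f"kept_v{v}", kept)
                sheet_rows.append({
                    "sample_id": sample_id, "subject_id": subject,
                    "triplet_id": tid, "pair_id": i, "role": role if role == "HC" else f"V{v}",
                    "group": role, "sex": sex, "age": age if role == "HC" else age_p,
                    "haplogroup": hg,
                })

        clinical_rows.extend(_simulate_clinical(f"P{i:03d}", rng, config))

    truth = pd.DataFrame([
        {
            "subject_id": t.subject_id, "pos": t.pos, "ref": t.ref, "alt": t.alt,
            "category": t.category, "vl_v1": t.vl_v1, "vl_v2": t.vl_v2,
            "mutpred": t.mutpred, "apogee": t.apogee, "mitotip": t.mitotip,
            "kept_v1": getattr(t, "kept_v1", False),
            "kept_v2": getattr(t, "kept_v2", False),
        }
        for t in truth_rows
    ])
    cohort = SyntheticCohort(
        config=config,
        sample_sheet=pd.DataFrame(sheet_rows),
        pcp=pcp,
        tss=tss,
        score_table=registry.frame(),
        clinical=pd.DataFrame(clinical_rows),
        allowlist=allowlist,
        ground_truth=truth,
    )
    if config.effect is not None:
        cohort = inject_effect(cohort, config.effect.group, config.effect.macro_region,
                               config.effect.prevalence_delta, region_map=region_map)
    return cohort


def _simulate_subject_variants(subject, hg, visits, config, pool, region_map,
                               registry, rng) -> list[_TrueVariant]:
    variants: list[_TrueVariant] = []
    used: set[int] = set()

    mean, sd = config.backbone_counts[hg] if config.haplogroup_structure else (20, 4)
    n_backbone = int(np.clip(round(rng.normal(mean, sd)), 1, len(pool)))
    idx = rng.choice(len(pool), size=n_backbone, replace=False)
    for j in sorted(idx):
        row = pool.iloc[j]
        registry.ensure(int(row.pos), row.ref, row.alt, rng,
                        mutpred=float(row.mutpred), apogee=float(row.apogee),
                        mitotip=float(row.mitotip))
        used.add(int(row.pos))
        variants.append(_TrueVariant(subject, int(row.pos), row.ref, row.alt,
                                     "backbone", 1.0, 1.0 if 2 in visits else math.nan,
                                     float(row.mutpred), float(row.apogee),
                                     float(row.mitotip), in_db=True))

    a, b = config.vl_beta
    n_het = int(rng.poisson(config.private_het_rate))
    for _ in range(n_het):
        pos = int(rng.integers(1, region_map.genome_length + 1))
        while pos in used:
            pos = int(rng.integers(1, region_map.genome_length + 1))
        used.add(pos)
        ref = str(rng.choice(BASES))
        alt = str(rng.choice([x for x in BASES if x != ref]))
        mp, ap, mt = registry.ensure(pos, ref, alt, rng)
        # 2% floor models the caller's limit of detection for both kinds
        base_vl = float(np.clip(rng.beta(a, b), 0.02, 1.0))
        if len(visits) == 2 and rng.random() < config.transient_rate:
            visit = 1 if rng.random() < 0.5 else 2
            vl = float(np.clip(base_vl * config.transient_vl_scale, 0.02, 1.0))
            vl_v1, vl_v2 = (vl, math.nan) if visit == 1 else (math.nan, vl)
            category = f"transient_v{visit}"
        else:
            vl_v1 = base_vl
            vl_v2 = (float(np.clip(base_vl + rng.normal(0.0, config.drift_sd),
                                   0.005, 1.0))
                     if len(visits) == 2 else math.nan)
            category = "persistent" if len(visits) == 2 else "het"
        variants.append(_TrueVariant(subject, pos, ref, alt, category,
                                     vl_v1, vl_v2, mp, ap, mt,
                                     in_db=bool(rng.random() < config.allowlist_rate)))
    return variants


def _emit_sample(sample_id, variants, visit, config, rescue, allowlist, rng):
    """PCP/TSS tables for one sequencing run; returns expected keep flags."""
    pcp_rows, tss_rows, keeps = [], [], []
    for var in variants:
        vl = var.vl_v1 if visit == 1 else var.vl_v2
        if math.isnan(vl):
            keeps.append((var, False))
            continue
        low = vl < CONSENSUS_VL_THRESHOLD
        fail_qc = low and rng.random() < config.rescue_fail_rate
        q = _draw_quality(rng, fail_qc)
        if var.in_db:
            allowlist.add((var.pos, var.alt))
        echoed = not (low and rng.random() < config.tss_dropout_low_vl)
        kept = echoed or (low and not fail_qc and var.in_db)
        keeps.append((var, kept))
        pcp_rows.append({"sample_id": sample_id, "pos": var.pos, "ref": var.ref,
                         "alt": var.alt, "vl": vl, **q})
        if echoed:
            tss_rows.append({"pos": var.pos, "ref": var.ref, "alt": var.alt, "vl": vl})
    if rng.random() < config.tss_artifact_rate:
        sample_positions = {v.pos for v in variants}
        pos = int(rng.integers(1, 16570))
        while pos in sample_positions:
            pos = int(rng.integers(1, 16570))
        ref = str(rng.choice(BASES))
        alt = str(rng.choice([x for x in BASES if x != ref]))
        tss_rows.append({"pos": pos, "ref": ref, "alt": alt,
                         "vl": float(rng.uniform(0.1, 0.5))})
    pcp_df = pd.DataFrame(pcp_rows, columns=["sample_id", "pos", "ref", "alt", "vl",
                                             "norm_cov", "cov_ratio", "numt_mean",
                                             "edge_dist"]).sort_values("pos")
    tss_df = pd.DataFrame(tss_rows, columns=["pos", "ref", "alt", "vl"]).sort_values("pos")
    return pcp_df.reset_index(drop=True), tss_df.reset_index(drop=True), keeps


_EDSS_GRID = np.arange(0.0, 4.5, 0.5)


def _simulate_clinical(subject, rng, config) -> list[dict]:
    evolution = str(rng.choice(EVOLUTIONS, p=np.asarray(config.evolution_probs)))
    diag1, diag2 = evolution.split("-")
    t2_shift = {"CIS-CIS": 0.0, "CIS-RRMS": config.t2_evolution_shift / 2,
                "RRMS-RRMS": config.t2_evolution_shift}[evolution]
    edss1 = float(rng.choice(_EDSS_GRID, p=_edss_weights()))
    edss2 = float(np.clip(edss1 + rng.choice([-0.5, 0.0, 0.5, 1.0],
                                             p=[0.2, 0.5, 0.2, 0.1]), 0.0, 9.5))
    t2_1 = int(rng.poisson(4.0 + t2_shift))
    t2_2 = t2_1 + int(rng.poisson(1.0 + t2_shift / 3))
    rows = []
    for visit, diag, edss, t2 in ((1, diag1, edss1, t2_1), (2, diag2, edss2, t2_2)):
        n_rel = int(rng.poisson(0.3))
        days = float(rng.uniform(29, 1187))
        gd = int(rng.poisson(0.25))
        rows.append({
            "subject_id": subject, "visit": visit, "diagnosis": diag,
            "evolution": evolution, "edss": edss, "n_relapses": n_rel,
            "days_to_last_relapse": days,
            "annualized_relapse_rate": n_rel * 365.25 / days,
            "msfc": float(rng.normal(0.05, 0.4)),
            "t2_lesion_count": t2,
            "t2_lesion_vol_ml": float(t2 * rng.uniform(0.15, 0.45)),
            "gd_lesion_count": gd,
            "gd_lesion_vol_ml": float(gd * rng.uniform(0.005, 0.08)),
            "gcipl_mm3": float(rng.normal(1.97, 0.15)),
            "rnfl_um": float(rng.normal(97.0, 8.0)),
            "on_treatment": bool(rng.random() < (0.26 if visit == 1 else 0.48)),
            "relapses_between_visits": int(rng.poisson(0.4)) if visit == 2 else math.nan,
            "new_or_enlarging_t2": bool(rng.random() < 0.4) if visit == 2 else math.nan,
        })
    return rows


def _edss_weights():
    w = np.array([3.0, 3.0, 2.5, 2.0, 1.5, 1.0, 0.7, 0.4, 0.2])
    return w / w.sum()


def null_config(n_triplets: int, seed: int) -> SimConfig:
    """Fully exchangeable null cohort: flat haplogroup structure, no
    transient asymmetry between visits or groups, no injected effect. Under
    this configuration every cross-sectional, haplogroup and longitudinal
    comparison family holds its null, so false-positive rates are
    interpretable."""
    return SimConfig(n_triplets=n_triplets, seed=seed, transient_rate=0.0,
                     haplogroup_structure=False)


# ---------------------------------------------------------------------------
# effect injection

def inject_effect(cohort: SyntheticCohort, group: str, macro_region: str,
                  prevalence_delta: float,
                  region_map: RegionMap | None = None,
                  rng_stream: int = 0) -> SyntheticCohort:
    """Raise deleterious-carrier prevalence in one group by ``delta``.

    A subject *carries* when any of its variants in the macro region has
    deleterious score > 0.5. Non-carriers in the target group each receive,
    with probability delta / (1 − baseline prevalence), one persistent
    moderately-heteroplasmic deleterious variant in the region, so the
    expected prevalence rises by exactly ``delta``. Injections are recorded
    in the ground-truth ledger with category ``injected``.
    """
    region_map = region_map or load_region_map()
    if group not in ("V1", "HC"):
        raise SimulationError("effect group must be 'V1' or 'HC'")
    rng = np.random.default_rng(np.random.SeedSequence(cohort.config.seed,
                                                       spawn_key=(2**20 + rng_stream,)))
    positions = region_map.positions_of(macro_region)
    if positions.size == 0:
        raise SimulationError(f"macro region {macro_region!r} has no positions")

    truth = cohort.ground_truth
    score = (truth["mutpred"] + truth["apogee"]) / 2.0
    macro = region_map.macro_vector(truth["pos"].to_numpy())
    carrier_variants = truth[(macro == macro_region) & (score > 0.5)]
    target_role = "HC" if group == "HC" else "V1"
    sheet = cohort.sample_sheet
    subjects = sheet.loc[sheet["role"] == target_role, ["sample_id", "subject_id"]]
    carriers = set(carrier_variants["subject_id"])
    baseline = np.mean([s in carriers for s in subjects["subject_id"]])
    if baseline + prevalence_delta > 1.0 or prevalence_delta < 0:
        raise SimulationError(
            f"delta {prevalence_delta} infeasible at baseline prevalence {baseline:.3f}"
        )
    p_add = prevalence_delta / (1.0 - baseline) if baseline < 1.0 else 0.0

    pcp = {k: v.copy() for k, v in cohort.pcp.items()}
    tss = {k: v.copy() for k, v in cohort.tss.items()}
    truth_new = [truth]
    scores_new = [cohort.score_table]
    for sample_id, subject in subjects.itertuples(index=False):
        if subject in carriers or rng.random() >= p_add:
            continue
        pos = int(rng.choice(positions))
        existing = set(truth.loc[truth["subject_id"] == subject, "pos"])
        while pos in existing:
            pos = int(rng.choice(positions))
        ref = str(rng.choice(BASES))
        alt = str(rng.choice([x for x in BASES if x != ref]))
        mp, ap = float(rng.uniform(0.7, 0.95)), float(rng.uniform(0.7, 0.95))
        vl = float(rng.uniform(0.2, 0.8))
        target_samples = [sample_id]
        if group == "V1":  # a real variant persists into the second visit
            v2_id = sample_id.replace("-V1", "-V2")
            if v2_id in pcp:
                target_samples.append(v2_id)
        for sid in target_samples:
            q = _draw_quality(rng, fail=False)
            pcp[sid] = pd.concat([pcp[sid], pd.DataFrame([{
                "sample_id": sid, "pos": pos, "ref": ref, "alt": alt, "vl": vl, **q
            }])], ignore_index=True).sort_values("pos").reset_index(drop=True)
            tss[sid] = pd.concat([tss[sid], pd.DataFrame([{
                "pos": pos, "ref": ref, "alt": alt, "vl": vl
            }])], ignore_index=True).sort_values("pos").reset_index(drop=True)
        truth_new.append(pd.DataFrame([{
            "subject_id": subject, "pos": pos, "ref": ref, "alt": alt,
            "category": "injected", "vl_v1": vl,
            "vl_v2": vl if len(target_samples) == 2 else math.nan,
            "mutpred": mp, "apogee": ap, "mitotip": math.nan,
            "kept_v1": True, "kept_v2": len(target_samples) == 2,
        }]))
        scores_new.append(pd.DataFrame([{
            "pos": pos, "ref": ref, "alt": alt,
            "mutpred": mp, "apogee": ap, "mitotip": math.nan,
        }]))

    return replace(
        cohort,
        pcp=pcp, tss=tss,
        ground_truth=pd.concat(truth_new, ignore_index=True),
        score_table=pd.concat(scores_new, ignore_index=True)
        .drop_duplicates(subset=["pos", "ref", "alt"]).sort_values(["pos", "ref", "alt"])
        .reset_index(drop=True),
    )


def simulate_carrier_pairs(n_pairs: int, prev_case: float, prev_control: float,
                           rng: np.random.Generator) -> tuple[int, int]:
    """Discordant counts (b, c) for one replicate of matched pairs whose
    members carry independently with the given prevalences."""
    case = rng.random(n_pairs) < prev_case
    control = rng.random(n_pairs) < prev_control
    return int((case & ~control).sum()), int((~case & control).sum())


# ---------------------------------------------------------------------------
# recovery check

def expected_trajectory_status(row) -> str | None:
    if row.kept_v1 and row.kept_v2:
        return "persistent"
    if row.kept_v1:
        return "transient_v1"
    if row.kept_v2:
        return "transient_v2"
    return None


def truth_check(cohort: SyntheticCohort,
                trajectories_by_subject: dict[str, pd.DataFrame],
                burden_by_sample: pd.DataFrame | None = None,
                expected_burden: pd.Series | None = None) -> dict:
    """Compare pipeline outputs with the ground-truth ledger.

    Returns trajectory-status accuracy over patient variants expected to
    survive the filter at ≥1 visit and, when per-sample burdens plus their
    ledger-derived expectations are supplied, the maximum absolute burden
    reconstruction error.
    """
    truth = cohort.ground_truth
    patients = truth[truth["subject_id"].str.startswith("P")]
    n_checked = n_correct = 0
    for subject, sub in patients.groupby("subject_id"):
        if subject not in trajectories_by_subject:
            raise SimulationError(f"pipeline output missing subject {subject}")
        traj = trajectories_by_subject[subject]
        observed = {(int(p), a): s for p, a, s in
                    traj[["pos", "alt", "status"]].itertuples(index=False)}
        for row in sub.itertuples(index=False):
            expected = expected_trajectory_status(row)
            if expected is None:
                continue
            n_checked += 1
            if observed.get((row.pos, row.alt)) == expected:
                n_correct += 1
    report = {
        "n_variants_checked": n_checked,
        "trajectory_accuracy": n_correct / n_checked if n_checked else math.nan,
    }
    if burden_by_sample is not None and expected_burden is not None:
        joined = burden_by_sample["cumulative_deleterious_burden"].align(
            expected_burden, join="inner")
        report["burden_max_abs_error"] = float((joined[0] - joined[1]).abs().max())
    return report


# ---------------------------------------------------------------------------
# on-disk dialects (the same files the ingest module reads)

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the cohort in the pipeline's input dialects: per-sample PCP TSV
    and TSS VCF, sample sheet, clinical table, score table, allow-list, and
    the ground-truth ledger."""
    out = Path(outdir)
    (out / "pcp").mkdir(parents=True, exist_ok=True)
    (out / "tss").mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    cohort.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False,
                           float_format=fmt)
    cohort.score_table.to_csv(out / "scores.tsv", sep="\t", index=False,
                              float_format=fmt)
    cohort.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False,
                               float_format=fmt)
    pd.DataFrame(sorted(cohort.allowlist), columns=["pos", "alt"]).assign(
        ref="N")[["pos", "ref", "alt"]].to_csv(out / "allowlist.tsv", sep="\t",
                                               index=False)
    for sid, df in cohort.pcp.items():
        df.to_csv(out / "pcp" / f"{sid}.tsv", sep="\t", index=False, float_format=fmt)
    for sid, df in cohort.tss.items():
        _write_vcf(df, out / "tss" / f"{sid}.vcf")


def _write_vcf(df: pd.DataFrame, path: Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chrM,length=16569>",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for row in df.itertuples(index=False):
        lines.append(
            f"chrM\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\tAF={row.vl:.6g}"
        )
    path.write_text("\n".join(lines) + "\n")
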