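"""Paired cross-sectional statistics for matched case/control mtDNA cohorts.

Matched pairs (one patient sample, one age- and sex-matched healthy control)
are compared with the discordant-pair machinery: per-region carrier
prevalences yield discordant counts (b, c) tested with exact McNemar;
per-region quantitative rates are compared with paired t-tests; haplogroup
effects use Kruskal–Wallis; categorical independence uses Fisher's exact
test with Monte Carlo simulation of fixed-margin tables. Each analysis batch
forms one FDR family adjusted by Benjamini–Hochberg step-up.

The module also provides the exact power of the paired design under an
alternative given by the two discordance probabilities, by enumeration over
the trinomial distribution of discordant-pair counts (the matched
case-control power calculation of Dupont).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

MCNEMAR_EXACT_MAX = 25  # exact binomial below, continuity-corrected chi2 at/above


class StatsError(ValueError):
    pass


@dataclass
class ComparisonResult:
    """One statistical test outcome within an FDR family."""

    family: str
    unit: str
    test_name: str
    statistic: float
    p_raw: float
    effect: float
    n: int
    p_fdr: float | None = None
    note: str = ""

    @property
    def testable(self) -> bool:
        return self.note != "not-testable"


def not_testable(family: str, unit: str, test_name: str, n: int = 0) -> ComparisonResult:
    return ComparisonResult(family, unit, test_name, math.nan, math.nan,
                            math.nan, n, note="not-testable")


# ---------------------------------------------------------------------------
# multiple testing

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(results: list[ComparisonResult]) -> list[ComparisonResult]:
    """Adjust p-values within each family; untestable entries pass through."""
    out = list(results)
    for family in sorted({r.family for r in out}):
        idx = [i for i, r in enumerate(out) if r.family == family and r.testable]
        if not idx:
            continue
        adj = bh_fdr([out[i].p_raw for i in idx])
        for i, q in zip(idx, adj):
            out[i] = replace(out[i], p_fdr=float(q))
    return out


# ---------------------------------------------------------------------------
# discordant pairs / McNemar

@dataclass(frozen=True)
class DiscordantResult:
    b: int  # pairs where only member A qualifies
    c: int  # pairs where only member B qualifies
    n_pairs: int

    @property
    def prevalence_a(self) -> float:
        return self.b / self.n_pairs

    @property
    def prevalence_b(self) -> float:
        return self.c / self.n_pairs


def discordant_prevalence(flags_a, flags_b) -> DiscordantResult:
    """Discordant counts for one qualifier over matched pairs.

    ``flags_a[i]``/``flags_b[i]`` say whether member A / member B of pair i
    qualifies (e.g. carries ≥1 deleterious variant in a region).
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("flag vectors must be 1-D and equal length")
    if a.size == 0:
        raise StatsError("empty pair set")
    return DiscordantResult(
        b=int((a & ~b).sum()), c=int((~a & b).sum()), n_pairs=int(a.size)
    )


def mcnemar_exact(b: int, c: int, exact_max: int = MCNEMAR_EXACT_MAX) -> float:
    """Two-sided McNemar p-value from discordant counts.

    Exact: 2·min tail of Binomial(b+c, ½), capped at 1, when b+c < exact_max;
    otherwise chi-square with continuity correction. b+c = 0 → p = 1.
    """
    if b < 0 or c < 0 or b != int(b) or c != int(c):
        raise StatsError("discordant counts must be non-negative integers")
    n = b + c
    if n == 0:
        return 1.0
    if n < exact_max:
        lo = stats.binom.cdf(min(b, c), n, 0.5)
        return float(min(1.0, 2.0 * lo))
    chi2 = (abs(b - c) - 1) ** 2 / n
    return float(stats.chi2.sf(chi2, df=1))


def mcnemar_result(family: str, unit: str, disc: DiscordantResult) -> ComparisonResult:
    return ComparisonResult(
        family=family, unit=unit, test_name="mcnemar_exact",
        statistic=float(disc.b - disc.c),
        p_raw=mcnemar_exact(disc.b, disc.c),
        effect=disc.prevalence_a - disc.prevalence_b,
        n=disc.n_pairs,
    )


def per_variant_mcnemar(carriers_a: pd.DataFrame, carriers_b: pd.DataFrame,
                        family: str = "per_variant") -> list[ComparisonResult]:
    """One McNemar test per (pos, alt) observed in ≥1 pair member.

    ``carriers_a``/``carriers_b`` are boolean frames indexed by pair id with
    one column per ``pos:alt`` key (missing keys count as non-carrier).
    """
    keys = sorted(set(carriers_a.columns) | set(carriers_b.columns))
    out = []
    for key in keys:
        fa = carriers_a[key] if key in carriers_a else pd.Series(False, index=carriers_a.index)
        fb = carriers_b[key] if key in carriers_b else pd.Series(False, index=carriers_b.index)
        out.append(mcnemar_result(family, key, discordant_prevalence(fa.to_numpy(), fb.to_numpy())))
    return apply_fdr(out)


# ---------------------------------------------------------------------------
# t-tests (paired / one-sample / two-sample) with degenerate handling

def paired_t(values_a, values_b, family: str, unit: str) -> ComparisonResult:
    """Paired t-test on per-pair differences A − B.

    Zero-variance differences are flagged degenerate rather than producing
    NaN: p = 1 for identically-zero differences, p = 0 for a constant
    non-zero shift (infinite t); the effect is always the mean difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    d = a[ok] - b[ok]
    if d.size < 2:
        return not_testable(family, unit, "paired_t", n=int(d.size))
    if np.std(d, ddof=1) == 0.0:
        mean = float(d.mean())
        return ComparisonResult(family, unit, "paired_t",
                                statistic=math.inf if mean else 0.0,
                                p_raw=0.0 if mean else 1.0,
                                effect=mean, n=int(d.size), note="degenerate")
    t, p = stats.ttest_rel(a[ok], b[ok])
    return ComparisonResult(family, unit, "paired_t", float(t), float(p),
                            effect=float(d.mean()), n=int(d.size))


def one_sample_t(values, family: str, unit: str, popmean: float = 0.0) -> ComparisonResult:
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        return not_testable(family, unit, "one_sample_t", n=int(x.size))
    if np.std(x, ddof=1) == 0.0:
        mean = float(x.mean() - popmean)
        return ComparisonResult(family, unit, "one_sample_t",
                                statistic=math.inf if mean else 0.0,
                                p_raw=0.0 if mean else 1.0,
                                effect=mean, n=int(x.size), note="degenerate")
    t, p = stats.ttest_1samp(x, popmean)
    return ComparisonResult(family, unit, "one_sample_t", float(t), float(p),
                            effect=float(x.mean() - popmean), n=int(x.size))


def two_sample_t(values_a, values_b, family: str, unit: str) -> ComparisonResult:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return not_testable(family, unit, "two_sample_t", n=int(a.size + b.size))
    effect = float(a.mean() - b.mean())
    if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
        return ComparisonResult(family, unit, "two_sample_t",
                                statistic=math.inf if effect else 0.0,
                                p_raw=0.0 if effect else 1.0,
                                effect=effect, n=int(a.size + b.size), note="degenerate")
    t, p = stats.ttest_ind(a, b)
    return ComparisonResult(family, unit, "two_sample_t", float(t), float(p),
                            effect=effect, n=int(a.size + b.size))


def paired_rate_test(metric_a: pd.Series, metric_b: pd.Series, family: str,
                     unit: str) -> ComparisonResult:
    """Paired t-test on a per-(pair, region) metric; pair ids are aligned by
    index. Callers choose whether the metric was computed from all variants
    or from pair-discordant variants only."""
    joined = pd.concat({"a": metric_a, "b": metric_b}, axis=1)
    return paired_t(joined["a"].to_numpy(), joined["b"].to_numpy(), family, unit)


# ---------------------------------------------------------------------------
# group tests

def kruskal_by_group(values, groups, family: str, unit: str,
                     min_per_group: int = 3, n_perm: int | None = None,
                     rng: np.random.Generator | None = None) -> ComparisonResult:
    """Kruskal–Wallis across groups with ≥ ``min_per_group`` members
    (midrank tie correction as in the reference implementation).

    With ``n_perm`` the p-value comes from a seeded permutation reference
    distribution of the H statistic instead of the chi-square
    approximation, which is anticonservative for small groups and heavily
    tied sparse data.
    """
    s = pd.DataFrame({"v": np.asarray(values, dtype=float), "g": np.asarray(groups)})
    s = s.dropna()
    counts = s["g"].value_counts()
    keep = counts[counts >= min_per_group].index
    s = s[s["g"].isin(keep)]
    samples = [grp["v"].to_numpy() for _, grp in s.groupby("g")]
    if len(samples) < 2:
        return not_testable(family, unit, "kruskal_wallis", n=int(len(s)))
    if len(np.unique(s["v"])) == 1:
        return ComparisonResult(family, unit, "kruskal_wallis", 0.0, 1.0,
                                effect=0.0, n=int(len(s)), note="degenerate")
    h, p = stats.kruskal(*samples)
    test_name = "kruskal_wallis"
    if n_perm is not None:
        if rng is None:
            raise StatsError("permutation Kruskal-Wallis requires an rng")
        p = _kruskal_permutation_p(s["v"].to_numpy(), s["g"].to_numpy(),
                                   float(h), n_perm, rng)
        test_name = "kruskal_wallis_perm"
    spread = float(s.groupby("g")["v"].mean().max() - s.groupby("g")["v"].mean().min())
    return ComparisonResult(family, unit, test_name, float(h), float(p),
                            effect=spread, n=int(len(s)))


def _kruskal_permutation_p(values: np.ndarray, groups: np.ndarray, h_obs: float,
                           n_perm: int, rng: np.random.Generator) -> float:
    """P(H ≥ observed) under random reassignment of group labels; the ranks
    and the tie correction are label-invariant, so only group rank sums are
    recomputed per permutation."""
    ranks = stats.rankdata(values)
    n = ranks.size
    labels, inverse = np.unique(groups, return_inverse=True)
    onehot = np.zeros((n, labels.size))
    onehot[np.arange(n), inverse] = 1.0
    sizes = onehot.sum(axis=0)
    _, tie_counts = np.unique(values, return_counts=True)
    tie = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    perm_ranks = rng.permuted(np.tile(ranks, (n_perm, 1)), axis=1)
    sums = perm_ranks @ onehot
    h_perm = (12.0 / (n * (n + 1)) * (sums**2 / sizes).sum(axis=1) - 3 * (n + 1)) / tie
    return float((1 + (h_perm >= h_obs - 1e-12).sum()) / (n_perm + 1))


def haplogroup_variant_test(metric_by_sample, haplogroup_by_sample, family: str,
                            unit: str, min_per_group: int = 3,
                            n_perm: int | None = None,
                            rng: np.random.Generator | None = None) -> ComparisonResult:
    """Kruskal–Wallis of a per-sample metric (variant count, deleterious
    count, burden, cumulative MitoTIP …) across haplogroups with ≥3 samples."""
    return kruskal_by_group(metric_by_sample, haplogroup_by_sample, family, unit,
                            min_per_group=min_per_group, n_perm=n_perm, rng=rng)


def _log_table_prob(table: np.ndarray) -> float:
    # log multivariate hypergeometric probability of a table given its margins
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum()
        - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def fisher_montecarlo(table, n_sim: int = 100_000, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> float:
    """Fisher-style exact independence test by Monte Carlo over fixed-margin
    tables (the simulate-p-value approach of R's ``fisher.test``).

    p = (1 + #{simulated tables at most as probable as observed}) / (n_sim + 1).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or (table < 0).any():
        raise StatsError("contingency table must be 2-D and non-negative")
    if n_sim < 1000:
        raise StatsError("n_sim must be at least 1000")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatsError("zero margin in contingency table")
    if rng is None:
        if seed is None:
            raise StatsError("fisher_montecarlo requires a seed or rng")
        rng = np.random.default_rng(seed)

    obs = _log_table_prob(table)
    nr, nc = table.shape
    row_labels = np.repeat(np.arange(nr), table.sum(axis=1))
    col_labels = np.repeat(np.arange(nc), table.sum(axis=0))
    const = float(gammaln(table.sum(axis=1) + 1).sum()
                  + gammaln(table.sum(axis=0) + 1).sum()
                  - gammaln(table.sum() + 1))
    hits = 0
    chunk = max(1, min(2000, int(4e6 // max(1, row_labels.size))))
    for start in range(0, n_sim, chunk):
        k = min(chunk, n_sim - start)
        perms = rng.permuted(np.tile(col_labels, (k, 1)), axis=1)
        idx = row_labels[None, :] * nc + perms
        idx += (np.arange(k) * nr * nc)[:, None]
        counts = np.bincount(idx.ravel(), minlength=k * nr * nc).reshape(k, nr * nc)
        logp = const - gammaln(counts + 1).sum(axis=1)
        hits += int((logp <= obs + 1e-9).sum())
    return (1 + hits) / (n_sim + 1)


# ---------------------------------------------------------------------------
# covariate battery

def covariate_checks(metric: pd.Series, age: pd.Series, sex: pd.Series,
                     family: str = "covariates", count_metric: bool = False,
                     carrier: pd.Series | None = None) -> list[ComparisonResult]:
    """Age and sex checks for one per-sample metric.

    Runs a linear regression of the metric on age (Kendall rank correlation
    instead when ``count_metric``), a two-sample t of the metric by sex, and,
    when a boolean carrier status is given, a chi-square test of independence
    and a two-proportion z-test of carrier rate by sex.
    """
    import statsmodels.api as sm

    out: list[ComparisonResult] = []
    df = pd.DataFrame({"m": metric, "age": age, "sex": sex}).dropna(subset=["m"])

    ok = df.dropna(subset=["age"])
    if ok["age"].nunique() < 2:
        out.append(not_testable(family, "age", "linregress", n=len(ok)))
    elif count_metric:
        tau, p = stats.kendalltau(ok["age"], ok["m"])
        out.append(ComparisonResult(family, "age", "kendall_tau", float(tau),
                                    float(p), effect=float(tau), n=len(ok)))
    else:
        X = sm.add_constant(ok["age"].to_numpy(dtype=float))
        fit = sm.OLS(ok["m"].to_numpy(dtype=float), X).fit()
        out.append(ComparisonResult(family, "age", "ols_slope",
                                    float(fit.tvalues[1]), float(fit.pvalues[1]),
                                    effect=float(fit.params[1]), n=len(ok)))

    sexes = df["sex"].dropna().unique()
    if len(sexes) == 2:
        a = df.loc[df["sex"] == sexes[0], "m"]
        b = df.loc[df["sex"] == sexes[1], "m"]
        out.append(two_sample_t(a, b, family, "sex"))
    else:
        out.append(not_testable(family, "sex", "two_sample_t", n=len(df)))

    if carrier is not None:
        cdf = pd.DataFrame({"carrier": carrier.astype(bool), "sex": sex}).dropna()
        tab = pd.crosstab(cdf["carrier"], cdf["sex"])
        if tab.shape == (2, 2) and (tab.values.sum(axis=0) > 0).all():
            chi2, p, _, _ = stats.chi2_contingency(tab.values)
            out.append(ComparisonResult(family, "carrier_by_sex", "chi2",
                                        float(chi2), float(p),
                                        effect=float(chi2), n=int(tab.values.sum())))
            counts = tab.loc[True].to_numpy() if True in tab.index else np.zeros(2, int)
            nobs = tab.sum(axis=0).to_numpy()
            if counts.sum() in (0, nobs.sum()):
                out.append(not_testable(family, "carrier_by_sex_z",
                                        "two_proportion_z", n=int(nobs.sum())))
            else:
                z, p = proportions_ztest(counts, nobs)
                out.append(ComparisonResult(family, "carrier_by_sex_z",
                                            "two_proportion_z", float(z), float(p),
                                            effect=float(counts[0] / nobs[0] - counts[1] / nobs[1]),
                                            n=int(nobs.sum())))
        else:
            out.append(not_testable(family, "carrier_by_sex", "chi2", n=len(cdf)))
    return apply_fdr(out)


# ---------------------------------------------------------------------------
# matched case-control power (exact trinomial enumeration)

def dupont_paired_power(
    n_pairs: int,
    p_discordant_case_only: float,
    p_discordant_control_only: float,
    alpha: float = 0.05,
    exact_max: int = MCNEMAR_EXACT_MAX,
) -> float:
    """Exact power of the paired McNemar comparison at ``n_pairs`` pairs.

    Each pair is independently case-only discordant with probability p10,
    control-only discordant with probability p01, and concordant otherwise.
    The power is the exact probability, under that trinomial model, that the
    two-sided McNemar test rejects at level ``alpha`` (reject iff p ≤ alpha).
    """
    p10, p01 = p_discordant_case_only, p_discordant_control_only
    if not (0 <= p10 <= 1 and 0 <= p01 <= 1 and p10 + p01 <= 1):
        raise StatsError("discordance probabilities must be in [0,1] and sum ≤ 1")
    if n_pairs < 1:
        raise StatsError("n_pairs must be positive")
    pd_tot = p10 + p01
    if pd_tot == 0:
        return 0.0
    q = p10 / pd_tot  # P(case-only | discordant)
    power = 0.0
    for m in range(n_pairs + 1):  # m discordant pairs
        pm = stats.binom.pmf(m, n_pairs, pd_tot)
        if pm == 0.0:
            continue
        bs = np.arange(m + 1)
        reject = np.array([mcnemar_exact(int(b), int(m - b), exact_max) <= alpha
                           for b in bs])
        if reject.any():
            power += pm * stats.binom.pmf(bs[reject], m, q).sum()
    return float(power)
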