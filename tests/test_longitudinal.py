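"""Visit matching, transient/persistent dynamics and clinical groupings."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitoburden.longitudinal import (
    LongitudinalError,
    annualized_relapse_rate,
    edss_worsening,
    evolution_group_tests,
    match_visits,
    neda3_classify,
    subject_level_wgs_metrics,
    transient_summary,
    transient_vs_persistent,
    vl_change_test,
)


def visit_frame(rows):
    return pd.DataFrame(rows, columns=["pos", "ref", "alt", "vl"])


class TestMatchVisits:
    def test_statuses_and_dvl(self):
        v1 = visit_frame([(100, "A", "G", 0.30), (200, "C", "T", 0.05)])
        v2 = visit_frame([(100, "A", "G", 0.35), (300, "G", "A", 0.08)])
        traj = match_visits(v1, v2).set_index("pos")
        assert traj.loc[100, "status"] == "persistent"
        assert traj.loc[100, "dvl"] == pytest.approx(0.05)
        assert traj.loc[200, "status"] == "transient_v1"
        assert traj.loc[300, "status"] == "transient_v2"

    def test_identical_tables_all_persistent(self):
        v = visit_frame([(100, "A", "G", 0.3), (200, "C", "T", 0.1)])
        traj = match_visits(v, v.copy())
        assert (traj["status"] == "persistent").all()
        assert (traj["dvl"] == 0.0).all()

    def test_duplicate_keys_rejected(self):
        v = visit_frame([(100, "A", "G", 0.3), (100, "A", "G", 0.4)])
        with pytest.raises(LongitudinalError, match="100:G"):
            match_visits(v, visit_frame([]))

    def test_partition_conserves_counts(self, rng):
        """#transient_v + #persistent equals the visit's variant count."""
        for _ in range(20):
            pos = rng.choice(16569, size=15, replace=False) + 1
            v1 = visit_frame([(int(p), "A", "G", float(rng.uniform(0.01, 1)))
                              for p in pos[:10]])
            v2 = visit_frame([(int(p), "A", "G", float(rng.uniform(0.01, 1)))
                              for p in pos[5:]])
            traj = match_visits(v1, v2)
            counts = traj["status"].value_counts()
            assert counts.get("transient_v1", 0) + counts.get("persistent", 0) == len(v1)
            assert counts.get("transient_v2", 0) + counts.get("persistent", 0) == len(v2)
            assert len(traj) == len(set(pos))

    def test_swapping_visits_negates_dvl(self, rng):
        pos = rng.choice(16569, size=12, replace=False) + 1
        v1 = visit_frame([(int(p), "A", "G", float(rng.uniform(0.01, 1)))
                          for p in pos[:8]])
        v2 = visit_frame([(int(p), "A", "G", float(rng.uniform(0.01, 1)))
                          for p in pos[4:]])
        fwd = match_visits(v1, v2).set_index("pos")
        rev = match_visits(v2, v1).set_index("pos")
        for p in fwd.index:
            if fwd.loc[p, "status"] == "persistent":
                assert rev.loc[p, "dvl"] == pytest.approx(-fwd.loc[p, "dvl"])
            elif fwd.loc[p, "status"] == "transient_v1":
                assert rev.loc[p, "status"] == "transient_v2"


class TestTransientSummary:
    def test_proportion_denominator_is_visit_count(self):
        v1 = visit_frame([(int(p), "A", "G", 0.3) for p in range(100, 110)])
        v2 = visit_frame([(int(p), "A", "G", 0.3) for p in range(100, 109)])
        traj = match_visits(v1, v2)
        prop, _ = transient_summary(traj, 1)  # 10 at V1, 1 transient
        assert prop == pytest.approx(0.10)

    def test_no_transient_censors_mean_vl(self):
        v = visit_frame([(100, "A", "G", 0.3)])
        traj = match_visits(v, v.copy())
        prop, mean_vl = transient_summary(traj, 1)
        assert prop == 0.0 and math.isnan(mean_vl)

    def test_empty_visit_censored(self):
        traj = match_visits(visit_frame([]), visit_frame([(1, "A", "G", 0.2)]))
        prop, mean_vl = transient_summary(traj, 1)
        assert math.isnan(prop) and math.isnan(mean_vl)


class TestVlChange:
    def test_symmetric_drift_mean_zero(self):
        v1 = visit_frame([(100, "A", "G", 0.3), (200, "C", "T", 0.3)])
        v2 = visit_frame([(100, "A", "G", 0.4), (200, "C", "T", 0.2)])
        res = vl_change_test({"P0": match_visits(v1, v2)})
        pooled = next(r for r in res if r.unit == "pooled_dvl")
        assert pooled.effect == pytest.approx(0.0)
        assert pooled.p_raw == 1.0

    def test_uniform_positive_drift(self):
        v1 = visit_frame([(int(p), "A", "G", 0.3) for p in (100, 200, 300)])
        v2 = v1.assign(vl=v1["vl"] + 0.1)
        res = vl_change_test({"P0": match_visits(v1, v2)})
        pooled = next(r for r in res if r.unit == "pooled_dvl")
        assert pooled.effect == pytest.approx(0.1)
        assert pooled.note == "degenerate" and pooled.p_raw == 0.0

    def test_matches_reference_one_sample_t(self, rng):
        dvl = rng.normal(0.0, 0.05, 30)
        v1 = visit_frame([(int(p) + 1, "A", "G", 0.5) for p in range(30)])
        v2 = v1.assign(vl=v1["vl"] + dvl)
        res = vl_change_test({"P0": match_visits(v1, v2)})
        pooled = next(r for r in res if r.unit == "pooled_dvl")
        t, p = stats.ttest_1samp(dvl, 0.0)
        assert pooled.statistic == pytest.approx(t, abs=1e-10)
        assert pooled.p_raw == pytest.approx(p, abs=1e-10)


class TestTransientVsPersistent:
    def _cohort(self, t_vl, p_vl):
        out = {}
        for s in range(6):
            v1 = visit_frame([(100 + s, "A", "G", p_vl), (200 + s, "C", "T", t_vl)])
            v2 = visit_frame([(100 + s, "A", "G", p_vl)])
            out[f"P{s}"] = match_visits(v1, v2)
        return out

    def test_lower_transient_vl_detected(self):
        res = transient_vs_persistent(self._cohort(t_vl=0.03, p_vl=0.30))
        vl = next(r for r in res if r.unit == "vl")
        assert vl.p_fdr < 0.05 and vl.effect < 0

    def test_identical_distributions_give_no_signal(self):
        res = transient_vs_persistent(self._cohort(t_vl=0.30, p_vl=0.30))
        vl = next(r for r in res if r.unit == "vl")
        assert vl.p_raw == 1.0  # exactly equal values → degenerate null

    def test_all_missing_variable_censored(self):
        res = transient_vs_persistent(self._cohort(0.03, 0.3))
        assert not any(r.unit == "mitotip" for r in res)  # never annotated


class TestSubjectMetrics:
    def test_mean_of_visits(self):
        v1 = visit_frame([(100, "A", "G", 0.3), (200, "C", "T", 0.05),
                          (300, "G", "A", 0.4)])
        v2 = visit_frame([(100, "A", "G", 0.3), (300, "G", "A", 0.4),
                          (400, "T", "C", 0.06)])
        burdens = pd.DataFrame({"cumulative_deleterious_burden": [2.0, 4.0]},
                               index=["S-V1", "S-V2"])
        out = subject_level_wgs_metrics({"P0": match_visits(v1, v2)},
                                        burdens, {"P0": ("S-V1", "S-V2")})
        row = out.iloc[0]
        assert row["transient_proportion"] == pytest.approx((1/3 + 1/3) / 2)
        assert row["cumulative_deleterious_burden"] == pytest.approx(3.0)

    def test_missing_visit_burden_censors_subject(self):
        traj = match_visits(visit_frame([(1, "A", "G", 0.5)]),
                            visit_frame([(1, "A", "G", 0.5)]))
        burdens = pd.DataFrame({"cumulative_deleterious_burden": [2.0]},
                               index=["S-V1"])
        out = subject_level_wgs_metrics({"P0": traj}, burdens,
                                        {"P0": ("S-V1", "S-V2")})
        assert len(out) == 0

    def test_subject_order_irrelevant(self, rng):
        trajs = {}
        for s in range(4):
            v = visit_frame([(int(p) + 1, "A", "G", 0.2) for p in range(s + 2)])
            trajs[f"P{s}"] = match_visits(v, v.copy())
        a = subject_level_wgs_metrics(dict(trajs))
        b = subject_level_wgs_metrics(dict(reversed(list(trajs.items()))))
        pd.testing.assert_frame_equal(a, b)


class TestEvolutionGroups:
    def test_identical_variable_across_groups(self):
        values = pd.DataFrame({"edss": [1.0] * 9}, index=[f"P{i}" for i in range(9)])
        evo = pd.Series(["CIS-CIS"] * 3 + ["CIS-RRMS"] * 3 + ["RRMS-RRMS"] * 3,
                        index=values.index)
        res = evolution_group_tests(values, evo, "mean")
        assert res[0].p_raw == 1.0

    def test_injected_shift_detected(self, rng):
        n = 60
        evo = pd.Series(rng.choice(["CIS-CIS", "RRMS-RRMS"], n),
                        index=[f"P{i}" for i in range(n)])
        t2 = pd.Series(rng.poisson(4, n) + np.where(evo == "RRMS-RRMS", 8, 0),
                       index=evo.index, dtype=float)
        res = evolution_group_tests(pd.DataFrame({"t2_count": t2}), evo, "mean")
        assert res[0].p_fdr < 0.05

    def test_one_row_per_variable_and_mode(self):
        values = pd.DataFrame({"a": np.arange(6.0), "b": np.arange(6.0)},
                              index=[f"P{i}" for i in range(6)])
        evo = pd.Series(["CIS-CIS"] * 3 + ["RRMS-RRMS"] * 3, index=values.index)
        res = evolution_group_tests(values, evo, "delta")
        assert [(r.unit) for r in res] == ["a:delta", "b:delta"]

    def test_bad_mode_rejected(self):
        with pytest.raises(LongitudinalError):
            evolution_group_tests(pd.DataFrame({"a": [1.0]}), pd.Series(["x"]), "sum")


class TestClinicalPrimitives:
    @pytest.mark.parametrize(
        "args, expected",
        [((0, 0, False, 1.5, 1.5), True),
         ((1, 0, False, 1.5, 1.5), False),
         ((0, 1, False, 1.5, 1.5), False),
         ((0, 0, True, 1.5, 1.5), False),
         ((0, 0, False, 1.5, 2.5), False),
         ((0, 0, False, 0.0, 1.0), True),    # below the ≥1.5 bar from EDSS 0
         ((0, 0, False, 0.0, 1.5), False),
         ((0, 0, False, 6.0, 6.5), False)],  # ≥0.5 from high baseline
    )
    def test_neda3(self, args, expected):
        assert neda3_classify(*args) is expected

    def test_neda3_missing_component_absent_not_false(self):
        assert neda3_classify(math.nan, 0, False, 1.5, 1.5) is None

    def test_neda3_monotone_in_each_component(self):
        base = (0, 0, False, 1.5, 1.5)
        assert neda3_classify(*base) is True
        worsened = [(1, 0, False, 1.5, 1.5), (0, 2, False, 1.5, 1.5),
                    (0, 0, True, 1.5, 1.5), (0, 0, False, 1.5, 3.0)]
        assert all(neda3_classify(*w) is False for w in worsened)

    def test_edss_worsening_bands(self):
        assert edss_worsening(0.0, 1.5) and not edss_worsening(0.0, 1.0)
        assert edss_worsening(2.0, 3.0) and not edss_worsening(2.0, 2.5)
        assert edss_worsening(6.0, 6.5)

    @pytest.mark.parametrize("n, days, rate",
                             [(1, 365.25, 1.0), (0, 900, 0.0), (2, 730.5, 1.0)])
    def test_annualized_relapse_rate(self, n, days, rate):
        assert annualized_relapse_rate(n, days) == pytest.approx(rate)

    def test_non_positive_period_rejected(self):
        with pytest.raises(LongitudinalError):
            annualized_relapse_rate(1, 0)
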