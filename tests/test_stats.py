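"""Mixed models with EMMs, the dip test (validated against an exact LP
oracle), and rank tests."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog
from scipy.stats import kstest

from dcblock import stats


# --------------------------------------------------------------------------
# dip statistic
# --------------------------------------------------------------------------

def dip_lp_oracle(x):
    """Exact min-sup distance from the ECDF to the set of unimodal CDFs,
    by linear programming over piecewise-linear convex-concave CDFs with a
    free modal segment (tractable for small n)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    best = np.inf
    for m in range(0, n + 1):      # mode lies in segment (x_m, x_{m+1})
        A_ub, b_ub = [], []

        def con(row, b):
            A_ub.append(row)
            b_ub.append(b)

        for i in range(1, n + 1):
            for target in (i / n, (i - 1) / n):
                r = np.zeros(n + 1)
                r[i - 1], r[n] = 1, -1
                con(r, target)
                r = np.zeros(n + 1)
                r[i - 1], r[n] = -1, -1
                con(r, -target)
        for i in range(n - 1):     # monotone
            r = np.zeros(n + 1)
            r[i], r[i + 1] = 1, -1
            con(r, 0.0)
        for i in range(n - 2):     # convex left of the mode, concave right
            dx0, dx1 = x[i + 1] - x[i], x[i + 2] - x[i + 1]
            r = np.zeros(n + 1)
            r[i], r[i + 1], r[i + 2] = -1 / dx0, 1 / dx0 + 1 / dx1, -1 / dx1
            if i + 1 <= m - 1:
                con(r, 0.0)
            if i >= m:
                con(-r, 0.0)
        c = np.zeros(n + 1)
        c[n] = 1
        res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      bounds=[(0, 1)] * n + [(0, None)], method="highs")
        if res.success:
            best = min(best, res.fun)
    return max(best, 0.5 / n)


class TestDipStatistic:
    def test_matches_exact_lp_oracle(self, rng):
        for trial in range(25):
            n = int(rng.integers(4, 11))
            if trial % 3 == 0:
                x = rng.random(n)
            elif trial % 3 == 1:
                x = np.concatenate([rng.normal(0, 0.2, n // 2),
                                    rng.normal(3, 0.2, n - n // 2)])
            else:
                x = rng.normal(0, 1, n)
            assert stats.dip_statistic(x) == pytest.approx(
                dip_lp_oracle(x), abs=1e-8)

    def test_degenerate_sample_minimal_dip(self):
        assert stats.dip_statistic([1.0, 1.0, 1.0, 1.0]) == pytest.approx(1 / 8)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.dip_statistic([1.0, 2.0, 3.0])

    def test_shift_scale_invariance(self, rng):
        x = rng.normal(0, 1, 50)
        d = stats.dip_statistic(x)
        assert stats.dip_statistic(3.0 * x - 7.0) == pytest.approx(d)


class TestDipTest:
    def test_uniform_null_rarely_rejects(self):
        ps = [stats.dip_test(np.random.default_rng(s).random(200),
                             n_boot=2000, seed=7)[1] for s in range(20)]
        assert np.mean(np.asarray(ps) > 0.05) >= 0.9

    def test_separated_bimodal_detected(self, rng):
        x = np.concatenate([rng.normal(5, 0.5, 100), rng.normal(15, 0.5, 100)])
        _, p = stats.dip_test(x, n_boot=2000, seed=7)
        assert p < 0.01

    def test_null_pvalues_approximately_uniform(self):
        ps = np.array([stats.dip_test(np.random.default_rng(1000 + s).random(200),
                                      n_boot=2000, seed=7)[1]
                       for s in range(500)])
        assert kstest(ps, "uniform").statistic < 0.1


# --------------------------------------------------------------------------
# mixed models & EMMs
# --------------------------------------------------------------------------

def simulate_lmm(seed, n_animals=6, n_units=4, n_trials=20, animal_sd=1.0,
                 unit_sd=0.5, resid_sd=1.0, phase_effect=-3.0, base=10.0):
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        ra = rng.normal(0, animal_sd)
        for u in range(n_units):
            ru = rng.normal(0, unit_sd)
            for phase in ("pre", "during"):
                mu = base + ra + ru + (phase_effect if phase == "during" else 0)
                for t in range(n_trials):
                    rows.append({"animal": f"A{a}", "unit": f"A{a}U{u}",
                                 "phase": phase, "pre_count": rng.poisson(3.0),
                                 "post_count": mu + rng.normal(0, resid_sd)})
    return pd.DataFrame(rows)


SPEC = stats.ModelSpec(
    formula="post_count ~ C(phase, Treatment('pre'))", focal="phase")


class TestMixedModel:
    def test_emms_equal_cell_means_without_random_variance(self, rng):
        # balanced two-phase data, no animal/unit variance injected
        df = simulate_lmm(0, animal_sd=0.0, unit_sd=0.0, resid_sd=1.0)
        res = stats.fit_mixed_model(df, SPEC)
        for phase in ("pre", "during"):
            cell = df[df.phase == phase].post_count.mean()
            assert res.emms[phase] == pytest.approx(cell, abs=1e-6)

    def test_row_order_invariance(self):
        df = simulate_lmm(1)
        res1 = stats.fit_mixed_model(df, SPEC)
        df2 = df.sample(frac=1.0, random_state=42)
        res2 = stats.fit_mixed_model(df2, SPEC)
        assert res1.emms["during"] == pytest.approx(res2.emms["during"], rel=1e-6)

    def test_variance_component_recovery(self):
        # 10 animals (sd 2) x 20 units (sd 1), residual sd 1.  The unit and
        # residual components are well identified (200 / 2000 levels) and
        # must come back within 25% (median over seeds); the animal component
        # has only 9 df of information, so even an exact estimator has ~30%
        # median sampling error -- it is checked at its sampling limit.
        err_unit, err_resid, err_animal = [], [], []
        for seed in range(10):
            df = simulate_lmm(seed, n_animals=10, n_units=20, n_trials=5,
                              animal_sd=2.0, unit_sd=1.0, resid_sd=1.0)
            res = stats.fit_mixed_model(df, SPEC)
            err_animal.append(abs(float(np.asarray(res.result.cov_re)[0, 0]) - 4.0) / 4.0)
            err_unit.append(abs(float(res.result.vcomp[0]) - 1.0))
            err_resid.append(abs(res.result.scale - 1.0))
        assert np.median(err_unit) < 0.25
        assert np.median(err_resid) < 0.25
        assert np.median(err_animal) < 0.75

    def test_tukey_at_least_raw_p(self):
        rng = np.random.default_rng(5)
        rows = []
        for a in range(4):
            for g in ("x", "y", "z"):
                for _ in range(30):
                    rows.append({"animal": f"A{a}", "unit": f"A{a}", "phase": g,
                                 "pre_count": 0,
                                 "post_count": rng.normal({"x": 0, "y": 0.3,
                                                           "z": 1.0}[g], 1)})
        df = pd.DataFrame(rows)
        res = stats.fit_mixed_model(df, stats.ModelSpec(
            formula="post_count ~ C(phase)", focal="phase", unit=None))
        assert np.all(res.emms.contrasts.p_tukey >= res.emms.contrasts.p_raw - 1e-12)

    def test_single_animal_rejected(self):
        df = simulate_lmm(2, n_animals=1)
        with pytest.raises(ValueError):
            stats.fit_mixed_model(df, SPEC)

    def test_agreement_with_reference_lmm_implementation(self, tmp_path):
        # independent cross-check: lmer/emmeans (REML, units in animals)
        df = simulate_lmm(7)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages({{library(lmerTest); library(emmeans)}})
            d <- read.csv("{csv}")
            m <- lmer(post_count ~ phase + (1|animal) + (1|animal:unit), data=d)
            e <- as.data.frame(emmeans(m, "phase"))
            write.csv(e, "{tmp_path / 'emm.csv'}", row.names=FALSE)
        """)
        r = subprocess.run(["Rscript", "-e", script], capture_output=True,
                           text=True, timeout=300)
        assert r.returncode == 0, r.stderr
        ref = pd.read_csv(tmp_path / "emm.csv").set_index("phase")
        res = stats.fit_mixed_model(df, SPEC)
        for phase in ("pre", "during"):
            assert res.emms[phase] == pytest.approx(
                float(ref.loc[phase, "emmean"]), abs=0.02)


class TestReductionFromCounts:
    def test_recovers_known_ratio(self):
        rng = np.random.default_rng(9)
        rows = []
        for a in range(4):
            for u in range(6):
                gain = rng.lognormal(0, 0.2)
                for phase, mu in (("pre", 10.0), ("during", 5.0)):
                    for _ in range(30):
                        rows.append({"animal": f"A{a}", "unit": f"A{a}U{u}",
                                     "phase": phase,
                                     "pre_count": rng.poisson(2.0),
                                     "post_count": rng.poisson(gain * mu)})
        out = stats.reduction_from_counts(pd.DataFrame(rows))
        assert out["pct_reduction"] == pytest.approx(50.0, abs=3.0)
        assert out["p"] < 0.001


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------

class TestRankTests:
    def test_exact_one_sided_mann_whitney(self):
        # all of group b above group a: p = 1 / C(6,3) = 0.05 exactly
        u, p = stats.mann_whitney([1, 2, 3], [10, 11, 12], alternative="less")
        assert p == pytest.approx(0.05)

    def test_identical_groups_not_significant(self):
        df = stats.rank_tests({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert df.p_adj.iloc[0] > 0.9

    def test_bonferroni_arithmetic(self):
        df = stats.rank_tests({"a": [1, 2, 3, 4, 5], "b": [2, 3, 4, 5, 6],
                               "c": [3, 4, 5, 6, 7]})
        assert len(df) == 3
        np.testing.assert_allclose(df.p_adj, np.minimum(1.0, 3 * df.p_raw))

    def test_kruskal_wallis_and_errors(self):
        h, p = stats.kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert p < 0.2
        with pytest.raises(ValueError):
            stats.kruskal_wallis({"a": [1.0], "b": []})
        with pytest.raises(ValueError):
            stats.rank_tests({"a": [], "b": [1.0]})
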