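"""Statistical machinery: linear mixed-effects models with estimated marginal
means (EMMs) and Tukey-adjusted contrasts, Hartigans' dip test of
unimodality, and rank tests with Bonferroni adjustment.

Windowed spike totals are modelled on the raw count scale with a Gaussian
linear mixed model (REML) with animal as the grouping factor and unit as a
variance component nested within animal.  EMMs are computed on a reference
grid that crosses the focal factor with the observed levels of the other
categorical fixed effects, holding numeric covariates at their means;
pairwise contrasts are adjusted with the studentized-range (Tukey) method on
residual degrees of freedom.

The dip statistic is the maximum distance between the empirical CDF and the
closest unimodal CDF, computed with the greatest-convex-minorant /
least-concave-majorant algorithm; its p-value is calibrated by bootstrap
from the uniform null distribution (cached per sample size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf


class ConvergenceError(RuntimeError):
    """Mixed-model fit failed to converge."""


# --------------------------------------------------------------------------
# linear mixed model + EMMs
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Fixed-effect formula plus random-effect grouping.

    ``formula`` is a patsy formula for the fixed effects (e.g.
    ``"post_count ~ C(phase, Treatment('pre')) + pre_count"``); ``animal``
    names the grouping column for the random intercept and ``unit`` (if
    given) adds a unit-within-animal variance component.
    """
    formula: str
    focal: str                      # focal factor column, e.g. "phase"
    animal: str = "animal"
    unit: str | None = "unit"


@dataclass
class EMMTable:
    levels: list
    emm: np.ndarray
    se: np.ndarray
    contrasts: pd.DataFrame         # pairwise, with raw and Tukey-adjusted p

    def __getitem__(self, level) -> float:
        return float(self.emm[self.levels.index(level)])


@dataclass
class MixedModelResult:
    result: object                  # statsmodels MixedLMResults
    emms: EMMTable
    converged: bool
    singular: bool
    dropped_columns: list = field(default_factory=list)

    @property
    def params(self):
        return self.result.params


def _reference_grid(data: pd.DataFrame, design_info, focal: str):
    """Rows crossing the focal factor's levels with the observed levels of
    other categorical terms; numeric covariates at their means."""
    factor_cols = []
    for fi in design_info.factor_infos.values():
        # factor code is e.g. "C(phase, Treatment('pre'))" or "pre_count";
        # map it back to the data column it references
        code = fi.factor.name()
        for c in sorted(data.columns, key=len, reverse=True):
            if c in code:
                factor_cols.append((c, fi.type == "categorical"))
                break
    factor_cols = list(dict.fromkeys(factor_cols))
    cat = [c for c, is_cat in factor_cols if is_cat]
    num = [c for c, is_cat in factor_cols if not is_cat]
    others = [c for c in cat if c != focal]
    focal_levels = list(pd.unique(data[focal]))
    grids = []
    for lev in focal_levels:
        base = {focal: lev}
        if others:
            combos = data[others].drop_duplicates()
        else:
            combos = pd.DataFrame([{}])
        g = combos.assign(**base)
        for c in num:
            g[c] = data[c].mean()
        grids.append(g)
    return focal_levels, grids


def estimate_emms(fit, data: pd.DataFrame, focal: str) -> EMMTable:
    """EMMs and Tukey-adjusted pairwise contrasts for a fitted MixedLM."""
    from patsy import build_design_matrices
    from scipy.stats import studentized_range

    design_info = fit.model.data.design_info
    levels, grids = _reference_grid(data, design_info, focal)
    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:len(beta), :len(beta)]
    rows = []
    for g in grids:
        X = np.asarray(build_design_matrices([design_info], g)[0])
        rows.append(X.mean(axis=0))
    A = np.stack(rows)
    emm = A @ beta
    # boundary (singular) fits can leave tiny negative quadratic forms
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", A, cov, A), 0.0, None))
    df = max(int(fit.model.nobs) - len(beta), 1)
    k = len(levels)
    recs = []
    for i in range(k):
        for j in range(i + 1, k):
            c = A[i] - A[j]
            est = float(c @ beta)
            cse = float(np.sqrt(c @ cov @ c))
            t = est / cse if cse > 0 else np.inf
            p_raw = 2 * sps.t.sf(abs(t), df)
            p_tukey = float(studentized_range.sf(abs(t) * np.sqrt(2.0), k, df)) \
                if k > 2 else p_raw
            recs.append({"contrast": f"{levels[i]} - {levels[j]}",
                         "estimate": est, "se": cse, "t": t, "df": df,
                         "p_raw": float(p_raw),
                         "p_tukey": float(min(1.0, max(p_tukey, p_raw)))})
    return EMMTable(levels, emm, se, pd.DataFrame(recs))


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> MixedModelResult:
    """REML linear mixed model per ``spec`` with EMMs for the focal factor.

    Raises :class:`ConvergenceError` on hard non-convergence; singular
    (boundary) fits are flagged, not hidden.
    """
    data = data.reset_index(drop=True)
    if data[spec.animal].nunique() < 2:
        raise ValueError("need at least 2 levels of the animal grouping factor")
    vc = {"unit": f"0 + C({spec.unit})"} if spec.unit else None
    model = smf.mixedlm(spec.formula, data, groups=data[spec.animal],
                        re_formula="1", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True, method=["lbfgs", "powell"], maxiter=200)
        except Exception as exc:  # noqa: BLE001
            raise ConvergenceError(f"mixed model failed to fit: {exc}") from exc
    if not getattr(fit, "converged", True):
        raise ConvergenceError("mixed model did not converge")
    singular = bool(np.any(np.diag(np.atleast_2d(fit.cov_re)) < 1e-8))
    emms = estimate_emms(fit, data, spec.focal)
    return MixedModelResult(fit, emms, bool(fit.converged), singular)


def reduction_from_counts(df: pd.DataFrame, baseline_phase: str = "pre",
                          dc_phase: str = "during",
                          include_pre_covariate: bool = True) -> dict:
    """Estimate the DC-mediated percent reduction of windowed spike totals.

    ``df`` is tidy with columns post_count, pre_count, phase, animal, unit.
    Fits the mixed model, extracts phase EMMs and returns a dict with the
    EMMs, their SEs, the percent reduction and the phase-contrast p-value.
    """
    from .evoked import percent_reduction

    rhs = f"C(phase, Treatment('{baseline_phase}'))"
    if include_pre_covariate:
        rhs += " + pre_count"
    spec = ModelSpec(formula=f"post_count ~ {rhs}", focal="phase")
    res = fit_mixed_model(df, spec)
    emm_pre = res.emms[baseline_phase]
    emm_dc = res.emms[dc_phase]
    row = res.emms.contrasts[
        res.emms.contrasts.contrast.str.contains(dc_phase)].iloc[0]
    return {
        "emm_pre": emm_pre, "emm_dc": emm_dc,
        "se_pre": float(res.emms.se[res.emms.levels.index(baseline_phase)]),
        "se_dc": float(res.emms.se[res.emms.levels.index(dc_phase)]),
        "pct_reduction": percent_reduction(emm_pre, emm_dc),
        "p": float(row.p_tukey), "model": res,
    }


# --------------------------------------------------------------------------
# Hartigans' dip test
# --------------------------------------------------------------------------

def dip_statistic(x) -> float:
    """Hartigans' dip: max |ECDF - closest unimodal CDF|.

    Computed with the greatest-convex-minorant / least-concave-majorant
    algorithm on the sorted sample; the returned value is floored at its
    sample-size minimum 1/(2n) (the conventional normalisation, under which
    a degenerate sample attains exactly 1/(2n)).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    if n < 4:
        raise ValueError("dip test requires n >= 4")
    if x[0] == x[-1]:
        return 0.5 / n

    # mn[j]: GCM predecessor of j; mj[k]: LCM successor of k (pool-adjacent)
    mn = np.empty(n, dtype=int)
    mn[0] = 0
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj = np.empty(n, dtype=int)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 0, n - 1
    dip = 1.0                      # in units of 1/(2n); 1 == the minimum
    for _ in range(n + 1):
        gcm = [high]               # change points, high -> low
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        lcm = [low]                # change points, low -> high
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_gcm, l_lcm = len(gcm), len(lcm)

        ig, ih = l_gcm, l_lcm
        ix, iv = l_gcm - 2, 1      # 0-based: gcm[ix], lcm[iv]
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcm_ix, lcm_iv = gcm[ix], lcm[iv]
                if gcm_ix > lcm_iv:
                    gcm_i1 = gcm[ix + 1]
                    dx = (lcm_iv - gcm_i1 + 1) \
                        - (x[lcm_iv] - x[gcm_i1]) * (gcm_ix - gcm_i1) / (x[gcm_ix] - x[gcm_i1])
                    iv += 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 2, iv
                else:
                    lcm_i1 = lcm[iv - 1]
                    dx = (x[gcm_ix] - x[lcm_i1]) * (lcm_iv - lcm_i1) \
                        / (x[lcm_iv] - x[lcm_i1]) - (gcm_ix - lcm_i1 - 1)
                    ix -= 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 2, iv + 1
                ix = max(ix, 0)
                iv = min(iv, l_lcm - 1)
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # max deviation of the ECDF from the GCM left of the new interval
        dl = 0.0
        if ig < l_gcm:
            for j in range(ig - 1, l_gcm - 1):
                temp = 1.0
                jb, je = gcm[j + 1], gcm[j]
                if je - jb > 1 and x[je] != x[jb]:
                    C = (je - jb) / (x[je] - x[jb])
                    for jj in range(jb, je + 1):
                        t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                        temp = max(temp, t)
                dl = max(dl, temp)
        # ... and below the LCM right of it
        du = 0.0
        if ih < l_lcm:
            for j in range(ih - 1, l_lcm - 1):
                temp = 1.0
                jb, je = lcm[j], lcm[j + 1]
                if je - jb > 1 and x[je] != x[jb]:
                    C = (je - jb) / (x[je] - x[jb])
                    for jj in range(jb, je + 1):
                        t = (x[jj] - x[jb]) * C - (jj - jb - 1)
                        temp = max(temp, t)
                du = max(du, temp)
        dip = max(dip, dl, du)
        new_low, new_high = gcm[ig - 1], lcm[ih - 1]
        if (new_low, new_high) == (low, high):
            break
        low, high = new_low, new_high
    return dip / (2.0 * n)


@lru_cache(maxsize=32)
def _null_dip_table(n: int, n_boot: int, seed: int) -> tuple:
    rng = np.random.default_rng(seed)
    return tuple(sorted(dip_statistic(rng.random(n)) for _ in range(n_boot)))


def dip_test(x, n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value.

    p is the fraction of ``n_boot`` uniform(0, 1) samples of the same size
    whose dip reaches the observed one (Hartigan & Hartigan's uniform null
    calibration).  The null table is cached per (n, n_boot, seed).
    """
    x = np.asarray(x, dtype=float)
    d = dip_statistic(x)
    table = np.asarray(_null_dip_table(int(x.size), int(n_boot), int(seed)))
    p = float(np.mean(table >= d - 1e-12))
    return d, p


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------

def kruskal_wallis(groups: dict) -> tuple[float, float]:
    vals = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(vals) < 2 or any(v.size == 0 for v in vals):
        raise ValueError("need >= 2 non-empty groups")
    h, p = sps.kruskal(*vals)
    return float(h), float(p)


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("need non-empty groups")
    u, p = sps.mannwhitneyu(a, b, alternative=alternative)
    return float(u), float(p)


def rank_tests(groups: dict, correction: str = "bonferroni",
               alternative: str = "two-sided") -> pd.DataFrame:
    """Pairwise Mann-Whitney/Wilcoxon rank-sum tests across the groups with
    Bonferroni adjustment (adjusted p = min(1, m x p))."""
    names = list(groups)
    if any(np.asarray(groups[g]).size == 0 for g in names):
        raise ValueError("every group must be non-empty")
    recs = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = len(pairs)
    for a, b in pairs:
        u, p = mann_whitney(groups[a], groups[b], alternative=alternative)
        p_adj = min(1.0, m * p) if correction == "bonferroni" else p
        recs.append({"group_a": a, "group_b": b, "U": u, "p_raw": p, "p_adj": p_adj})
    return pd.DataFrame(recs)
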