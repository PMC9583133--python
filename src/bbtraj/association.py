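"""Association testing: exact and rank tests, BH-FDR, confounder-stratified
tests, MaAsLin2-style per-feature differential abundance models, TMM
normalization and rank-test power analysis.

The per-feature models follow the MaAsLin2 default pipeline (total-sum
scaling, log transform with a per-feature half-minimum pseudo-count,
ordinary least squares per feature) for the linear route, and a negative
binomial log-link regression with TMM-scaled library-size offsets for the
count route.  Both correct across features with Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests

from .io import to_relative
from .tables import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    feature_id: str
    coefficient: float
    std_error: float
    p_value: float
    q_value: float
    n_used: int
    model: str  # lm | negbin | fisher | wilcoxon | cmh | van_elteren


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, monotone)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# exact / rank tests
# ---------------------------------------------------------------------------

def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 table -> (odds ratio, p)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("cells must be non-negative integers")
    res = stats.fisher_exact(np.round(t).astype(np.int64), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _iter_tables_fixed_margins(row_sums, col_sums):
    """Yield all non-negative integer r x c tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(row_idx, remaining_cols, rows):
        if row_idx == r - 1:
            last = remaining_cols
            if np.all(last >= 0):
                yield rows + [tuple(last)]
            return
        target = row_sums[row_idx]
        ranges = [range(0, min(target, remaining_cols[j]) + 1) for j in range(c - 1)]
        for partial in itertools.product(*ranges):
            rest = target - sum(partial)
            if rest < 0 or rest > remaining_cols[c - 1]:
                continue
            row = partial + (rest,)
            yield from rec(row_idx + 1, remaining_cols - np.array(row), rows + [row])

    yield from rec(0, np.asarray(col_sums), [])


def _table_log_prob(t, row_sums, col_sums, n):
    lg = math.lgamma
    num = sum(lg(x + 1) for x in row_sums) + sum(lg(x + 1) for x in col_sums)
    den = lg(n + 1) + sum(lg(x + 1) for x in np.ravel(t))
    return num - den


def fisher_exact_rxc(table, max_tables: int = 200_000,
                     n_mc: int = 20_000, seed: int | None = None,
                     ) -> tuple[float, str]:
    """Two-sided Fisher test for an r x c table -> (p, method).

    Sums the conditional (multivariate hypergeometric) probabilities of all
    fixed-margin tables no more probable than the observed one; falls back
    to a seeded Monte-Carlo estimate when the enumeration would exceed the
    budget.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2:
        raise ValueError("expected a 2-d contingency table")
    row_sums, col_sums = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    obs_lp = _table_log_prob(t, row_sums, col_sums, n)
    count = 0
    p = 0.0
    enumerated = True
    for cand in _iter_tables_fixed_margins(list(row_sums), list(col_sums)):
        count += 1
        if count > max_tables:
            enumerated = False
            break
        lp = _table_log_prob(cand, row_sums, col_sums, n)
        if lp <= obs_lp + 1e-9:
            p += math.exp(lp)
    if enumerated:
        return min(p, 1.0), "enumeration"
    # Monte-Carlo: permute individual column assignments, seeded
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(len(row_sums)), row_sums)
    cols = np.repeat(np.arange(len(col_sums)), col_sums)
    hits = 0
    for _ in range(n_mc):
        perm_cols = rng.permutation(cols)
        sim = np.zeros_like(t)
        np.add.at(sim, (rows, perm_cols), 1)
        if _table_log_prob(sim, row_sums, col_sums, n) <= obs_lp + 1e-9:
            hits += 1
    return (1 + hits) / (1 + n_mc), "monte_carlo"


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Unpaired two-sided Wilcoxon / Mann-Whitney test -> (U, p).

    Exact null enumeration when the pooled size is <= 20 and there are no
    ties, otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def pairwise_wilcoxon_fdr(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All unordered pairwise Wilcoxon tests with one joint BH correction.

    Returns a symmetric label-by-label DataFrame of q-values (diagonal NaN).
    """
    names = sorted(groups)
    pairs = list(itertools.combinations(names, 2))
    ps = [wilcoxon_rank_sum(groups[a], groups[b])[1] for a, b in pairs]
    qs = bh_fdr(ps)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), q in zip(pairs, qs):
        out.loc[a, b] = out.loc[b, a] = q
    return out


# ---------------------------------------------------------------------------
# stratified (confounder-controlled) tests
# ---------------------------------------------------------------------------

def cmh_test(tables) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel chi-square across 2x2 strata -> (stat, p).

    Degenerate strata (a zero row or column margin) carry no information
    and are dropped with a logged notice.
    """
    kept = []
    for t in tables:
        t = np.asarray(t, float)
        if t.shape != (2, 2):
            raise ValueError("CMH strata must be 2x2")
        if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
            logger.info("cmh_test: dropping degenerate stratum %s", t.tolist())
            continue
        kept.append(t)
    if not kept:
        raise ValueError("all strata degenerate; CMH undefined")
    st = StratifiedTable([np.asarray(t, float) for t in kept])
    res = st.test_null_odds(correction=True)
    return float(res.statistic), float(res.pvalue)


def van_elteren(values, group, stratum) -> tuple[float, float]:
    """Stratified rank test for a continuous outcome (van Elteren).

    Within each stratum a Wilcoxon rank-sum statistic is computed and
    strata are combined with weights 1/(n_s + 1); the combined statistic is
    referred to its normal null.  Strata with one group absent or zero
    variance are skipped with a logged notice.
    """
    values = np.asarray(values, float)
    group = np.asarray(group)
    stratum = np.asarray(stratum)
    glev = np.unique(group)
    if len(glev) != 2:
        raise ValueError("van Elteren test requires exactly two groups")
    num = 0.0
    var = 0.0
    used = 0
    for s in np.unique(stratum):
        m = stratum == s
        x = values[m & (group == glev[0])]
        y = values[m & (group == glev[1])]
        if x.size == 0 or y.size == 0 or np.ptp(values[m]) == 0:
            logger.info("van_elteren: skipping degenerate stratum %r", s)
            continue
        n1, n2 = x.size, y.size
        ns = n1 + n2
        w = stats.rankdata(np.concatenate([x, y]))[:n1].sum()
        weight = 1.0 / (ns + 1)
        num += weight * (w - n1 * (ns + 1) / 2.0)
        # tie-corrected variance of the rank sum within the stratum
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1.0 - (counts ** 3 - counts).sum() / (ns ** 3 - ns) if ns > 1 else 1.0
        var += weight ** 2 * n1 * n2 * (ns + 1) / 12.0 * tie
        used += 1
    if used == 0:
        raise ValueError("all strata degenerate; stratified test undefined")
    z = num / math.sqrt(var) if var > 0 else 0.0
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def stratified_categorical_test(outcome, exposure, stratum) -> AssociationResult:
    """Confounder-controlled association of an exposure with an outcome.

    Categorical outcomes go through the CMH test on per-stratum 2x2 tables;
    numeric outcomes through the stratified (van Elteren) rank test.
    """
    outcome = np.asarray(outcome)
    exposure = np.asarray(exposure)
    stratum = np.asarray(stratum)
    numeric = np.issubdtype(outcome.dtype, np.number)
    if numeric:
        z, p = van_elteren(outcome, exposure, stratum)
        return AssociationResult("outcome", float(z), math.nan, p, p,
                                 len(outcome), "van_elteren")
    olev = np.unique(outcome)
    elev = np.unique(exposure)
    if len(olev) != 2 or len(elev) != 2:
        raise ValueError("CMH route requires binary outcome and exposure")
    tables = []
    for s in np.unique(stratum):
        m = stratum == s
        t = np.array([[np.sum(m & (exposure == e) & (outcome == o))
                       for o in olev] for e in elev], float)
        tables.append(t)
    stat, p = cmh_test(tables)
    return AssociationResult("outcome", float(stat), math.nan, p, p,
                             len(outcome), "cmh")


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(counts: AbundanceTable | pd.DataFrame, ref=None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (features x samples counts).

    M-values (log2 ratios vs the reference sample) are trimmed by
    ``trim_m`` on both sides and A-values (average log2 abundance) by
    ``trim_a``; the factor is the inverse-variance-weighted mean of the
    surviving M-values.  The reference defaults to the sample whose
    upper-quartile fraction is closest to the mean, and factors are scaled
    to geometric mean 1.
    """
    df = counts.data if isinstance(counts, AbundanceTable) else counts
    mat = df.to_numpy(float)
    lib = mat.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("zero-sum sample in TMM input")
    frac = mat / lib
    if ref is None:
        uq = np.array([np.quantile(frac[:, j][frac[:, j] > 0], 0.75)
                       if (frac[:, j] > 0).any() else 0.0
                       for j in range(mat.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(df.columns).index(ref)
    fr = frac[:, ref_idx]
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        fj = frac[:, j]
        ok = (fj > 0) & (fr > 0)
        if ok.sum() < 2:
            continue
        m = np.log2(fj[ok] / fr[ok])
        a = 0.5 * np.log2(fj[ok] * fr[ok])
        # asymptotic (delta-method) variance of each M-value
        w = ((1 - fj[ok]) / (fj[ok] * lib[j])
             + (1 - fr[ok]) / (fr[ok] * lib[ref_idx]))
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, bool)
        factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# per-feature differential abundance models
# ---------------------------------------------------------------------------

def _design_matrix(metadata: pd.DataFrame, exposure: str, covariates):
    cols = [exposure] + list(covariates or [])
    X = pd.get_dummies(metadata[cols], drop_first=True, dtype=float)
    exposure_cols = [c for c in X.columns
                     if c == exposure or c.startswith(exposure + "_")]
    if len(exposure_cols) != 1:
        raise ValueError(
            f"exposure {exposure!r} must be binary or numeric "
            f"(got dummy columns {exposure_cols})")
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear covariates)")
    return X, exposure_cols[0]


def feature_lm(features: AbundanceTable, metadata: pd.DataFrame,
               exposure: str, covariates=None,
               detection: float = 1e-6, prevalence: float = 0.10,
               q_threshold: float = 0.1) -> pd.DataFrame:
    """MaAsLin2-style linear models, one per feature.

    Pipeline: prevalence/detection filter -> total-sum scaling -> log2 with
    a per-feature half-minimum pseudo-count -> OLS of the transformed
    abundance on the exposure (plus covariates) -> Wald p -> BH q.
    Negative coefficients indicate association with the reference
    (alphabetically first) exposure level.
    """
    from .io import filter_features  # local import to avoid cycle at import time
    meta = metadata.loc[features.sample_ids]
    filtered = filter_features(features, detection, prevalence)
    rel = to_relative(filtered) if filtered.value_kind != "relative" else filtered
    X, coef_col = _design_matrix(meta, exposure, covariates)
    if len(meta) <= X.shape[1]:
        raise ValueError("fewer samples than model parameters")
    rows = []
    for fid in rel.feature_ids:
        y = rel.data.loc[fid].to_numpy(float)
        positive = y[y > 0]
        pc = positive.min() / 2 if positive.size else 1e-12
        ylog = np.log2(y + pc)
        fit = sm.OLS(ylog, X.to_numpy(float)).fit()
        idx = list(X.columns).index(coef_col)
        pval = fit.pvalues[idx]
        if not np.isfinite(pval) or (fit.bse[idx] < 1e-12
                                     and abs(fit.params[idx]) < 1e-8):
            pval = 1.0  # zero residual variance: no evidence either way
        rows.append({"feature_id": fid, "coefficient": fit.params[idx],
                     "std_error": fit.bse[idx], "p_value": pval,
                     "n_used": int(len(y)), "model": "lm"})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < q_threshold
    return out[["feature_id", "coefficient", "std_error", "p_value", "q_value",
                "n_used", "model", "significant"]]


def feature_negbin(counts: AbundanceTable, metadata: pd.DataFrame,
                   exposure: str, covariates=None,
                   detection: float = 1e-5, prevalence: float = 0.01,
                   q_threshold: float = 0.1,
                   dispersion_floor: float = 1e-8) -> pd.DataFrame:
    """Per-feature negative-binomial regression with TMM offsets.

    Library sizes scaled by TMM factors enter as log offsets; the NB
    dispersion is estimated per feature by method of moments from Poisson
    residuals of the *null* model (exposure excluded, with a small-sample
    floor) and then held fixed for the Wald test on the exposure
    coefficient, which is referred to a t distribution with n - p degrees
    of freedom.  Estimating the dispersion under the null keeps the test
    from absorbing chance group separation into a too-small dispersion,
    which would otherwise make small-sample tail p-values anti-conservative.
    """
    from .io import filter_features
    meta = metadata.loc[counts.sample_ids]
    filtered = filter_features(counts, detection, prevalence)
    factors = tmm_factors(filtered)
    offset = np.log(filtered.data.sum(axis=0).to_numpy(float)
                    * factors.to_numpy(float))
    X, coef_col = _design_matrix(meta, exposure, covariates)
    idx = list(X.columns).index(coef_col)
    Xm = X.to_numpy(float)
    X0 = np.delete(Xm, idx, axis=1)
    n, p = Xm.shape
    rows = []
    for fid in filtered.feature_ids:
        y = np.round(filtered.data.loc[fid].to_numpy(float)).astype(np.int64)
        if y.sum() == 0:
            raise ValueError(f"feature {fid!r} all-zero after filtering")
        null_fit = sm.GLM(y, X0, family=sm.families.Poisson(),
                          offset=offset).fit()
        mu = null_fit.fittedvalues
        # method-of-moments dispersion: E[(y-mu)^2] = mu + alpha mu^2
        alpha = float(((y - mu) ** 2 - mu).sum() / (mu ** 2).sum())
        alpha = max(alpha, dispersion_floor)
        fit = sm.GLM(y, Xm, family=sm.families.NegativeBinomial(alpha=alpha),
                     offset=offset).fit()
        tval = fit.params[idx] / fit.bse[idx]
        pval = 2 * stats.t.sf(abs(tval), n - p)
        rows.append({"feature_id": fid, "coefficient": fit.params[idx],
                     "std_error": fit.bse[idx], "p_value": pval,
                     "n_used": int(len(y)), "model": "negbin",
                     "dispersion": alpha})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < q_threshold
    return out[["feature_id", "coefficient", "std_error", "p_value", "q_value",
                "n_used", "model", "dispersion", "significant"]]


# ---------------------------------------------------------------------------
# power sensitivity analysis
# ---------------------------------------------------------------------------

def wilcoxon_power_at(d: float, n1: int, n2: int, alpha: float = 0.05,
                      are: float = 0.955) -> float:
    """Two-sided power of the Wilcoxon rank-sum test at effect size d,
    via the A.R.E. approximation (effective sample sizes are*n)."""
    n1e, n2e = are * n1, are * n2
    df = n1e + n2e - 2
    ncp = d * math.sqrt(n1e * n2e / (n1e + n2e))
    tcrit = stats.t.isf(alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def mdes_wilcoxon(n1: int, n2: int, alpha: float = 0.05, power: float = 0.80,
                  are: float = 0.955) -> float:
    """Minimum detectable Cohen's d for the Wilcoxon rank-sum test.

    Solves the two-sided noncentral-t power equation at A.R.E.-scaled
    effective sample sizes (0.955 is the Wilcoxon-vs-t efficiency for
    normal data, the G*Power convention) to within 1e-6.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if not (0 < are <= 1):
        raise ValueError("are must lie in (0, 1]")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    f = lambda d: wilcoxon_power_at(d, n1, n2, alpha, are) - power
    hi = 1.0
    while f(hi) < 0:
        hi *= 2
        if hi > 100:
            raise ValueError("target power unattainable at these sample sizes")
    return float(optimize.brentq(f, 1e-9, hi, xtol=1e-6))
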