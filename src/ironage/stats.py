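"""Cross-sectional and dose-response statistics for cohort comparisons.

Wilson score intervals for death proportions, Hill sigmoid lethality fits
(LD50, slope), the N-1 chi-square for 2x2 tables, two-proportion z-tests,
one-way ANOVA / Kruskal-Wallis omnibus tests with post hoc corrections
(Tukey, Sidak, Dunn-Sidak) and ordinary linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProportionObs",
    "SigmoidFit",
    "OmnibusResult",
    "wilson_ci",
    "fit_sigmoid",
    "n1_chisq",
    "two_prop_z",
    "omnibus",
    "linreg",
]


@dataclass
class ProportionObs:
    successes: int
    trials: int
    group: str = ""
    dose: float | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.trials:
            raise ValueError("need 0 <= successes <= trials")


@dataclass
class SigmoidFit:
    ld50: float
    hill_slope: float
    lower_asymptote: float
    upper_asymptote: float
    ld50_ci95: tuple[float, float]
    covariance: np.ndarray | None = None

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        span = self.upper_asymptote - self.lower_asymptote
        with np.errstate(divide="ignore"):
            frac = np.where(d > 0,
                            d ** self.hill_slope
                            / (d ** self.hill_slope + self.ld50 ** self.hill_slope),
                            0.0)
        return self.lower_asymptote + span * frac


@dataclass
class OmnibusResult:
    statistic: float
    df: tuple[int, int] | int
    p: float
    kind: str
    posthoc: pd.DataFrame | None = None
    normality: pd.DataFrame | None = None


def wilson_ci(obs: ProportionObs, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    if obs.trials < 1:
        raise ValueError("at least one trial required")
    from statsmodels.stats.proportion import proportion_confint
    lo, hi = proportion_confint(obs.successes, obs.trials,
                                alpha=1 - conf, method="wilson")
    # the Wilson bounds are exactly 0 at k=0 and 1 at k=n; remove float noise
    lo = 0.0 if obs.successes == 0 else float(np.clip(lo, 0.0, 1.0))
    hi = 1.0 if obs.successes == obs.trials else float(np.clip(hi, 0.0, 1.0))
    return float(lo), float(hi)


def fit_sigmoid(observations: list[ProportionObs],
                free_asymptotes: bool = False,
                log_dose: bool = False) -> SigmoidFit:
    """Binomial-weighted Hill fit of death proportion against dose.

    The Hill curve ``P(d) = d^h / (d^h + LD50^h)`` is logistic in log dose,
    so with asymptotes fixed at 0/1 the fit is exact binomial-GLM maximum
    likelihood on log dose (zero-dose groups inform only the lower asymptote
    and drop out).  With ``free_asymptotes`` the four-parameter curve is
    fitted by weighted least squares.  The LD50 CI comes from the delta
    method on the GLM coefficients.
    """
    doses = np.array([o.dose for o in observations], dtype=float)
    k = np.array([o.successes for o in observations], dtype=float)
    n = np.array([o.trials for o in observations], dtype=float)
    if np.any(np.isnan(doses)):
        raise ValueError("every observation needs a dose")
    if len(np.unique(doses)) < 4:
        raise ValueError("at least 4 dose levels required")
    if k.sum() == 0 or np.all(k == n):
        raise ValueError("all-0 or all-1 responses: LD50 unidentifiable")

    if not free_asymptotes:
        import statsmodels.api as sm
        pos = doses > 0
        x = np.log(doses[pos])
        X = sm.add_constant(x)
        glm = sm.GLM(np.column_stack([k[pos], n[pos] - k[pos]]), X,
                     family=sm.families.Binomial())
        res = glm.fit()
        a, h = res.params  # logit p = a + h log d ; LD50 = exp(-a/h)
        if h <= 0:
            raise ValueError("non-positive fitted slope; no dose response")
        ld50 = float(np.exp(-a / h))
        # delta method on g = -a/h
        grad = np.array([-1.0 / h, a / h ** 2])
        var_log = float(grad @ res.cov_params() @ grad)
        se = np.sqrt(max(var_log, 0))
        ci = (float(np.exp(np.log(ld50) - 1.96 * se)),
              float(np.exp(np.log(ld50) + 1.96 * se)))
        return SigmoidFit(ld50=ld50, hill_slope=float(h),
                          lower_asymptote=0.0, upper_asymptote=1.0,
                          ld50_ci95=ci, covariance=np.asarray(res.cov_params()))

    from scipy.optimize import curve_fit

    def model(d, ld50, h, lo, hi):
        frac = np.where(d > 0, d ** h / (d ** h + ld50 ** h), 0.0)
        return lo + (hi - lo) * frac

    p_hat = k / n
    sigma = np.sqrt(np.clip(p_hat * (1 - p_hat), 1e-4, None) / n)
    p0 = [np.median(doses[doses > 0]), 2.0, 0.0, 1.0]
    popt, pcov = curve_fit(model, doses, p_hat, p0=p0, sigma=sigma,
                           bounds=([1e-9, 0.1, 0.0, 0.5],
                                   [1e6, 20.0, 0.5, 1.0]), maxfev=20000)
    se = float(np.sqrt(max(pcov[0, 0], 0)))
    return SigmoidFit(ld50=float(popt[0]), hill_slope=float(popt[1]),
                      lower_asymptote=float(popt[2]),
                      upper_asymptote=float(popt[3]),
                      ld50_ci95=(popt[0] - 1.96 * se, popt[0] + 1.96 * se),
                      covariance=pcov)


def n1_chisq(table) -> tuple[float, float]:
    """N-1 chi-square test for a 2x2 table: Pearson chi2 scaled by (N-1)/N."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("n1_chisq needs a 2x2 table")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    pearson = stats.chi2_contingency(tab, correction=False).statistic
    n = tab.sum()
    chi2 = float(pearson * (n - 1) / n)
    return chi2, float(stats.chi2.sf(chi2, 1))


def two_prop_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z-test (no continuity correction).

    Returns (Z, two-sided p); Z > 0 when the first group's proportion is
    larger.  |Z| equals the square root of the Pearson chi-square of the
    corresponding 2x2 table.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one trial")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = float((p1 - p2) / se)
    return z, float(2 * stats.norm.sf(abs(z)))


def _dunn_sidak(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with Sidak adjustment."""
    labels = pd.unique(groups)
    ranks = stats.rankdata(values)
    n = len(values)
    # tie correction for the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    rows = []
    m = len(labels) * (len(labels) - 1) // 2
    for a, b in combinations(labels, 2):
        ra = ranks[groups == a]
        rb = ranks[groups == b]
        na, nb = len(ra), len(rb)
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term / 12.0)
                     * (1.0 / na + 1.0 / nb))
        z = (ra.mean() - rb.mean()) / se
        p = 2 * stats.norm.sf(abs(z))
        p_adj = 1 - (1 - min(p, 1.0)) ** m
        rows.append({"group1": a, "group2": b, "statistic": float(z),
                     "p": float(p), "p_adj": float(min(p_adj, 1.0))})
    return pd.DataFrame(rows)


def _sidak_t(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Pairwise t-tests on the pooled ANOVA error with Sidak adjustment."""
    labels = pd.unique(groups)
    groups_v = [values[groups == g] for g in labels]
    n_total = len(values)
    g = len(labels)
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups_v) / (n_total - g)
    rows = []
    m = g * (g - 1) // 2
    for (la, va), (lb, vb) in combinations(zip(labels, groups_v), 2):
        se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
        tstat = (va.mean() - vb.mean()) / se
        p = 2 * stats.t.sf(abs(tstat), n_total - g)
        p_adj = 1 - (1 - min(p, 1.0)) ** m
        rows.append({"group1": la, "group2": lb, "statistic": float(tstat),
                     "p": float(p), "p_adj": float(min(p_adj, 1.0))})
    return pd.DataFrame(rows)


def _tukey(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    labels = pd.unique(groups)
    res = stats.tukey_hsd(*[values[groups == g] for g in labels])
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        rows.append({"group1": labels[i], "group2": labels[j],
                     "statistic": float(res.statistic[i, j]),
                     "p": float(res.pvalue[i, j]),
                     "p_adj": float(res.pvalue[i, j])})
    return pd.DataFrame(rows)


def omnibus(values, groups, kind: str = "anova",
            posthoc: str | None = None,
            normality_report: bool = False) -> OmnibusResult:
    """One-way omnibus comparison across groups.

    ``kind='anova'`` gives the F test with (g-1, N-g) df; ``kind='kruskal'``
    the tie-corrected Kruskal-Wallis H with g-1 df.  Post hoc options:
    ``tukey`` (ANOVA), ``sidak`` (pooled-variance pairwise t with Sidak
    adjustment) and ``dunn_sidak`` (rank-based Dunn test with Sidak
    adjustment, the usual companion to Kruskal-Wallis).  Optionally reports a
    D'Agostino-Pearson normality test per group.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("at least two groups required")
    by_group = [values[groups == g] for g in labels]
    for lab, v in zip(labels, by_group):
        if len(v) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")

    if kind == "anova":
        f, p = stats.f_oneway(*by_group)
        df = (len(labels) - 1, len(values) - len(labels))
        statistic = float(f)
        # identical groups: f_oneway returns nan for zero between+within
        if not np.isfinite(statistic):
            statistic, p = 0.0, 1.0
    elif kind == "kruskal":
        try:
            h, p = stats.kruskal(*by_group)
        except ValueError:  # all values identical
            h, p = 0.0, 1.0
        df = len(labels) - 1
        statistic = float(h)
    else:
        raise ValueError(f"unknown omnibus kind {kind!r}")

    ph = None
    if posthoc == "tukey":
        ph = _tukey(values, groups)
    elif posthoc == "sidak":
        ph = _sidak_t(values, groups)
    elif posthoc == "dunn_sidak":
        ph = _dunn_sidak(values, groups)
    elif posthoc is not None:
        raise ValueError(f"unknown posthoc {posthoc!r}")

    norm = None
    if normality_report:
        rows = []
        for lab, v in zip(labels, by_group):
            if len(v) >= 8:
                k2, pn = stats.normaltest(v)
            else:
                k2, pn = np.nan, np.nan
            rows.append({"group": lab, "k2": k2, "p": pn, "n": len(v)})
        norm = pd.DataFrame(rows)

    return OmnibusResult(statistic=statistic, df=df, p=float(p), kind=kind,
                         posthoc=ph, normality=norm)


def linreg(x, y) -> dict[str, float]:
    """Ordinary least-squares regression of y on x.

    Returns slope, intercept, R^2 and the slope t-test p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("at least 3 points required")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue ** 2), "p": float(res.pvalue),
            "slope_se": float(res.stderr)}
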