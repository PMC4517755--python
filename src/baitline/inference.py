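"""Classical ANOVA and pairwise-comparison machinery, built from first principles.

This module carries the statistical layer used to compare pest-control
treatments: one-way ANOVA on per-line population reductions, two-way
(trial x treatment) ANOVA with interaction on baiting-timing data,
Fisher's LSD and Tukey's HSD pairwise tests, and card-count-weighted
means with standard errors.

Everything is computed directly rather than delegated: sums of squares
come from explicit model comparisons, F and t tail probabilities from the
regularized incomplete beta function, and the studentized-range CDF from
numeric quadrature, so arbitrary (k, df) combinations are supported
without table lookup. Unbalanced two-way designs use Type-II sums of
squares (each main effect adjusted for the other, ignoring the
interaction), the conventional default for factorial ANOVA without an
ordering of effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "TwoWayAnovaResult",
    "f_sf",
    "f_critical",
    "t_sf_two_sided",
    "oneway_anova",
    "twoway_anova",
    "fisher_lsd",
    "tukey_hsd",
    "studentized_range_cdf",
    "studentized_range_sf",
    "studentized_range_critical",
    "weighted_mean_se",
]

ALPHA_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """One ANOVA term: F ratio, degrees of freedom, p-value and group stats.

    ``mse`` and ``df_den`` describe the error stratum the term was tested
    against, which is what the pairwise procedures below need.
    """

    term: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    mse: float
    ss_effect: float
    ss_error: float
    group_means: dict = field(default_factory=dict)
    group_ns: dict = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.f_stat < 0 and not math.isnan(self.f_stat):
            raise ValueError("F statistic cannot be negative")


@dataclass
class PairwiseComparison:
    group_a: object
    group_b: object
    mean_diff: float
    stderr: float
    statistic: float
    p_value: float
    method: str  # "LSD" or "HSD"
    significant: bool


@dataclass
class TwoWayAnovaResult:
    """Per-term results of a crossed two-factor ANOVA plus the error stratum."""

    terms: dict  # term name -> AnovaResult
    ss_error: float
    df_error: int
    mse: float
    n_obs: int
    n_cells: int

    def __getitem__(self, key: str) -> AnovaResult:
        return self.terms[key]


# ---------------------------------------------------------------------------
# tail probabilities
# ---------------------------------------------------------------------------


def f_sf(f: float, df_num: float, df_den: float) -> float:
    """Upper tail of the F distribution via the regularized incomplete beta."""
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degrees of freedom must be positive")
    if math.isnan(f):
        return math.nan
    if f <= 0:
        return 1.0
    if math.isinf(f):
        return 0.0
    x = df_den / (df_den + df_num * f)
    return float(special.betainc(df_den / 2.0, df_num / 2.0, x))


def f_critical(alpha: float, df_num: float, df_den: float) -> float:
    """Critical value f with P(F > f) = alpha, found by root bracketing."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(
        optimize.brentq(lambda f: f_sf(f, df_num, df_den) - alpha, 1e-10, 1e8)
    )


def t_sf_two_sided(t: float, df: float) -> float:
    """Two-sided p-value for a t statistic, P(|T| >= |t|)."""
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    if math.isinf(t):
        return 0.0
    x = df / (df + t * t)
    return float(special.betainc(df / 2.0, 0.5, x))


# ---------------------------------------------------------------------------
# studentized range distribution (numeric quadrature)
# ---------------------------------------------------------------------------


def _norm_pdf(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)


def _range_cdf_standard(w: float, k: int) -> float:
    # P(range of k iid standard normals <= w)
    if w <= 0:
        return 0.0

    def integrand(z):
        return k * _norm_pdf(z) * (special.ndtr(z) - special.ndtr(z - w)) ** (k - 1)

    val, _ = integrate.quad(integrand, -9.0, 9.0 + w, limit=200)
    return min(1.0, float(val))


def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized range Q = range / s for k groups and ``df``
    error degrees of freedom, by integrating the scale mixture over the
    distribution of s = sqrt(chi2_df / df)."""
    if k < 2:
        raise ValueError("studentized range requires k >= 2 groups")
    if q <= 0:
        return 0.0
    if df > 1e5:  # s degenerates at 1
        return _range_cdf_standard(q, k)
    half = df / 2.0
    log_c = math.log(2.0) + half * math.log(half) - special.gammaln(half)

    def outer(s):
        if s <= 0:
            return 0.0
        log_dens = log_c + (df - 1.0) * math.log(s) - half * s * s
        return math.exp(log_dens) * _range_cdf_standard(q * s, k)

    hi = 1.0 + 12.0 / math.sqrt(df)
    val, _ = integrate.quad(outer, 0.0, hi, limit=100)
    tail, _ = integrate.quad(outer, hi, hi + 8.0, limit=100)
    return min(1.0, float(val + tail))


def studentized_range_sf(q: float, k: int, df: float) -> float:
    return max(0.0, 1.0 - studentized_range_cdf(q, k, df))


def studentized_range_critical(alpha: float, k: int, df: float) -> float:
    """q with P(Q > q) = alpha, e.g. q(0.05; 3, 6) ~ 4.34."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(
        optimize.brentq(
            lambda q: studentized_range_sf(q, k, df) - alpha, 1e-3, 200.0, xtol=1e-7
        )
    )


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------


def oneway_anova(values, groups) -> AnovaResult:
    """Classical between/within decomposition of ``values`` labelled by ``groups``.

    Returns an :class:`AnovaResult` with F = MSB/MSW and the p-value from
    the F distribution. A zero within-group variance with non-zero
    between-group variance is reported as F = inf, p = 0 with the
    ``degenerate`` flag set (and a warning emitted).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("values and groups must be 1-D and of equal length")
    labels, inverse = np.unique(g, return_inverse=True)
    k = len(labels)
    n = len(y)
    if k < 2:
        raise ValueError("need at least two groups")
    if n <= k:
        raise ValueError("need more observations than groups")
    grand = y.mean()
    means = {}
    ns = {}
    ssb = 0.0
    ssw = 0.0
    for i, lab in enumerate(labels):
        yi = y[inverse == i]
        if yi.size == 0:
            raise ValueError(f"group {lab!r} is empty")
        mi = yi.mean()
        means[lab] = float(mi)
        ns[lab] = int(yi.size)
        ssb += yi.size * (mi - grand) ** 2
        ssw += float(((yi - mi) ** 2).sum())
    df_num = k - 1
    df_den = n - k
    msb = ssb / df_num
    msw = ssw / df_den
    degenerate = False
    if msw == 0.0:
        if msb == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            degenerate = True
            warnings.warn(
                "zero within-group variance with non-zero between-group "
                "variance; F is infinite",
                RuntimeWarning,
                stacklevel=2,
            )
            f_stat, p = math.inf, 0.0
    else:
        f_stat = msb / msw
        p = f_sf(f_stat, df_num, df_den)
    return AnovaResult(
        term="group",
        f_stat=f_stat,
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        mse=msw,
        ss_effect=ssb,
        ss_error=ssw,
        group_means=means,
        group_ns=ns,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# two-way ANOVA (Type II, via least-squares model comparison)
# ---------------------------------------------------------------------------


def _dummies(codes: np.ndarray, k: int) -> np.ndarray:
    # drop-first dummy coding
    out = np.zeros((codes.size, k - 1))
    for j in range(1, k):
        out[codes == j, j - 1] = 1.0
    return out


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return float(resid @ resid)


def twoway_anova(
    values,
    factor_a,
    factor_b,
    interaction: bool = True,
    labels: tuple[str, str] = ("A", "B"),
) -> TwoWayAnovaResult:
    """Crossed two-factor ANOVA with Type-II sums of squares.

    Each main effect is tested by comparing the additive model against the
    model with that effect dropped; the interaction (if requested) is the
    further improvement of the full cell-means model over the additive
    one. Unbalanced cell counts are allowed; an empty cell with
    ``interaction=True`` is an error because the cell-means model would be
    unidentifiable.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (y.shape == a.shape == b.shape) or y.ndim != 1:
        raise ValueError("values and both factors must be 1-D and of equal length")
    n = y.size
    lab_a, code_a = np.unique(a, return_inverse=True)
    lab_b, code_b = np.unique(b, return_inverse=True)
    ka, kb = len(lab_a), len(lab_b)
    if ka < 2 or kb < 2:
        raise ValueError("each factor needs at least two levels")
    cell_counts = np.zeros((ka, kb), dtype=int)
    np.add.at(cell_counts, (code_a, code_b), 1)
    n_cells = int((cell_counts > 0).sum())
    if interaction and (cell_counts == 0).any():
        empties = [
            (lab_a[i], lab_b[j])
            for i in range(ka)
            for j in range(kb)
            if cell_counts[i, j] == 0
        ]
        raise ValueError(f"empty cell(s) with interaction requested: {empties}")

    ones = np.ones((n, 1))
    da = _dummies(code_a, ka)
    db = _dummies(code_b, kb)
    dab = np.einsum("ni,nj->nij", da, db).reshape(n, -1)

    rss_b = _rss(np.hstack([ones, db]), y)
    rss_a = _rss(np.hstack([ones, da]), y)
    rss_add = _rss(np.hstack([ones, da, db]), y)

    if interaction:
        rss_full = _rss(np.hstack([ones, da, db, dab]), y)
        ss_error = rss_full
        df_error = n - n_cells
    else:
        ss_error = rss_add
        df_error = n - (ka + kb - 1)
    if df_error <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = ss_error / df_error

    def marginal(codes, labs):
        means = {}
        ns = {}
        for i, lab in enumerate(labs):
            sel = codes == i
            means[lab] = float(y[sel].mean())
            ns[lab] = int(sel.sum())
        return means, ns

    def make(term, ss, df_num, means, ns):
        ss = max(ss, 0.0)
        if mse == 0.0:
            degenerate = ss > 0
            f = math.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            degenerate = False
            f = (ss / df_num) / mse
            p = f_sf(f, df_num, df_error)
        return AnovaResult(
            term=term,
            f_stat=f,
            df_num=df_num,
            df_den=df_error,
            p_value=p,
            mse=mse,
            ss_effect=ss,
            ss_error=ss_error,
            group_means=means,
            group_ns=ns,
            degenerate=degenerate,
        )

    means_a, ns_a = marginal(code_a, lab_a)
    means_b, ns_b = marginal(code_b, lab_b)
    terms = {
        labels[0]: make(labels[0], rss_b - rss_add, ka - 1, means_a, ns_a),
        labels[1]: make(labels[1], rss_a - rss_add, kb - 1, means_b, ns_b),
    }
    if interaction:
        cell_means = {}
        cell_ns = {}
        for i in range(ka):
            for j in range(kb):
                if cell_counts[i, j]:
                    sel = (code_a == i) & (code_b == j)
                    cell_means[(lab_a[i], lab_b[j])] = float(y[sel].mean())
                    cell_ns[(lab_a[i], lab_b[j])] = int(sel.sum())
        terms["interaction"] = make(
            "interaction",
            rss_add - rss_full,
            (ka - 1) * (kb - 1),
            cell_means,
            cell_ns,
        )
    return TwoWayAnovaResult(
        terms=terms,
        ss_error=ss_error,
        df_error=df_error,
        mse=mse,
        n_obs=n,
        n_cells=n_cells,
    )


# ---------------------------------------------------------------------------
# pairwise comparisons
# ---------------------------------------------------------------------------


def _check_pairwise_input(anova: AnovaResult) -> None:
    if len(anova.group_means) < 2:
        raise ValueError("pairwise comparisons need at least two groups")
    if anova.mse < 0:
        raise ValueError("negative error variance")


def fisher_lsd(anova: AnovaResult, alpha: float = ALPHA_DEFAULT):
    """Fisher's (unprotected) least-significant-difference tests.

    Plain pairwise t tests on the pooled error variance, with no
    multiplicity adjustment — that is what LSD is. With two groups this
    reduces exactly to the pooled-variance two-sample t test.
    """
    _check_pairwise_input(anova)
    out = []
    degenerate = anova.mse == 0.0
    if degenerate:
        warnings.warn("zero error variance; LSD p-values are degenerate",
                      RuntimeWarning, stacklevel=2)
    for ga, gb in combinations(sorted(anova.group_means), 2):
        diff = anova.group_means[ga] - anova.group_means[gb]
        se = math.sqrt(
            anova.mse * (1.0 / anova.group_ns[ga] + 1.0 / anova.group_ns[gb])
        )
        if se == 0.0:
            t = 0.0 if diff == 0.0 else math.inf * math.copysign(1.0, diff)
            p = 1.0 if diff == 0.0 else 0.0
        else:
            t = diff / se
            p = t_sf_two_sided(t, anova.df_den)
        out.append(
            PairwiseComparison(ga, gb, diff, se, t, p, "LSD", p < alpha)
        )
    return out


def tukey_hsd(anova: AnovaResult, alpha: float = ALPHA_DEFAULT):
    """Tukey's honestly-significant-difference tests.

    The statistic q = diff / sqrt(mse/2 * (1/na + 1/nb)) (Tukey–Kramer for
    unequal n) is referred to the studentized-range distribution with k
    groups and the ANOVA's error degrees of freedom.
    """
    _check_pairwise_input(anova)
    k = len(anova.group_means)
    out = []
    if anova.mse == 0.0:
        warnings.warn("zero error variance; HSD p-values are degenerate",
                      RuntimeWarning, stacklevel=2)
    for ga, gb in combinations(sorted(anova.group_means), 2):
        diff = anova.group_means[ga] - anova.group_means[gb]
        se = math.sqrt(
            anova.mse / 2.0 * (1.0 / anova.group_ns[ga] + 1.0 / anova.group_ns[gb])
        )
        if se == 0.0:
            q = 0.0 if diff == 0.0 else math.inf
            p = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p = studentized_range_sf(q, k, anova.df_den)
        out.append(
            PairwiseComparison(ga, gb, diff, se, q, p, "HSD", p < alpha)
        )
    return out


# ---------------------------------------------------------------------------
# weighted mean and SE
# ---------------------------------------------------------------------------


def weighted_mean_se(values, weights) -> tuple[float, float]:
    """Weighted mean and its standard error.

    The SE uses the effective-sample-size form
    ``SE^2 = sum(w (x - m)^2) / (sum(w) * (n_eff - 1))`` with
    ``n_eff = (sum w)^2 / sum(w^2)``; with equal weights this reduces to the
    ordinary SE of the mean. A single value yields ``(value, nan)``.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("values and weights must be 1-D, non-empty, equal length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    mean = float(np.average(x, weights=w))
    if x.size == 1:
        warnings.warn("single value: SE undefined", RuntimeWarning, stacklevel=2)
        return mean, math.nan
    n_eff = w.sum() ** 2 / (w * w).sum()
    if n_eff <= 1:
        return mean, math.nan
    var = float((w * (x - mean) ** 2).sum() / (w.sum() * (n_eff - 1)))
    return mean, math.sqrt(var)
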