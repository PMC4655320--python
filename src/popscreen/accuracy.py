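"""Paired diagnostic accuracy for two screening policies.

All quantities reduce to the 2x2x2 table of (test A, test B, disease)
counts, so every test here has a closed form:

* ``summarize`` — the standard 2x2 metrics with Wilson (default), Wald or
  exact proportion intervals and log-method likelihood-ratio intervals;
* ``relative_sensitivity`` — paired ratio of sensitivities with a
  delta-method log interval (Bonett-Price style) and McNemar's test on the
  discordant diseased pairs (exact binomial below 25 discordants, else the
  continuity-corrected chi-square);
* ``predictive_value_test`` — the generalized score statistic for comparing
  the PPVs/NPVs of paired tests (marginal logistic model under the null
  common predictive value, working independence, robust clustering by
  subject; the simplest exactly-identified weighting of the weighted
  generalized score family);
* ``likelihood_ratio_test`` — a regression-model-style Wald test of
  log LR+ (or log LR-) equality, using paired delta-method variances for
  the sensitivity and false-positive-fraction components;
* ``roc_auc`` — the Mann-Whitney AUC with a DeLong interval.

Report-table rounding is half-up to integer percentages and one decimal
for ratios, matching clinical-journal convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from ._errors import DomainError, UndefinedMetricError

__all__ = [
    "PairedScreenData",
    "DiagnosticSummary",
    "summarize",
    "relative_sensitivity",
    "predictive_value_test",
    "likelihood_ratio_test",
    "roc_auc",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    f = 10.0**decimals
    return math.floor(abs(x) * f + 0.5) / f * (1.0 if x >= 0 else -1.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedScreenData:
    """Counts indexed by (test A result, test B result, disease status).

    ``counts[a, b, d]`` with index 1 = positive/diseased, 0 = negative/
    healthy.  Collapsing over either test axis reproduces that test's own
    2x2 table.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (2, 2, 2) or np.any(c < 0) or np.any(c != np.round(c)):
            raise DomainError("counts must be a (2,2,2) array of nonnegative integers")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_labels(cls, a_pos, b_pos, disease) -> "PairedScreenData":
        a = np.asarray(a_pos, dtype=int)
        b = np.asarray(b_pos, dtype=int)
        d = np.asarray(disease, dtype=int)
        c = np.zeros((2, 2, 2))
        np.add.at(c, (a, b, d), 1.0)
        return cls(c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def table(self, test: str) -> tuple[int, int, int, int]:
        """(tp, fp, fn, tn) for one test, collapsing over the other."""
        axis = 1 if test == "a" else 0
        c = self.counts.sum(axis=axis)  # [test result, disease]
        return int(c[1, 1]), int(c[1, 0]), int(c[0, 1]), int(c[0, 0])


@dataclass(frozen=True)
class DiagnosticSummary:
    """Point estimates and 95% CIs for the standard screening metrics."""

    sensitivity: tuple[float, float, float]
    specificity: tuple[float, float, float]
    ppv: tuple[float, float, float]
    npv: tuple[float, float, float]
    fpr: tuple[float, float, float]
    fnr: tuple[float, float, float]
    lr_pos: tuple[float, float, float]
    lr_neg: tuple[float, float, float]
    n_diseased: int
    n_healthy: int
    n_test_positive: int
    n_test_negative: int
    ci_method: str = "wilson"

    def rounded(self) -> dict[str, str]:
        """Report-table formatting: integer percentages, one-decimal ratios."""
        out = {}
        for m in ("sensitivity", "specificity", "ppv", "npv", "fpr", "fnr"):
            e, lo, hi = getattr(self, m)
            out[m] = (
                f"{round_half_up(100 * e):.0f}% "
                f"({round_half_up(100 * lo):.0f}-{round_half_up(100 * hi):.0f})"
            )
        for m in ("lr_pos", "lr_neg"):
            e, lo, hi = getattr(self, m)
            out[m] = (
                f"{round_half_up(e, 1):.1f} "
                f"({round_half_up(lo, 1):.1f}-{round_half_up(hi, 1):.1f})"
            )
        return out


# ---------------------------------------------------------------------------
# single-test summary
# ---------------------------------------------------------------------------

_CI_METHODS = {"wilson": "wilson", "wald": "normal", "exact": "beta"}


def _prop_ci(x: int, n: int, method: str) -> tuple[float, float]:
    lo, hi = proportion_confint(x, n, alpha=0.05, method=_CI_METHODS[method])
    return float(lo), float(hi)


def summarize(
    table: tuple[int, int, int, int], ci_method: str = "wilson"
) -> DiagnosticSummary:
    """Diagnostic summary of one screening test's (tp, fp, fn, tn) table.

    Proportion CIs by the requested method (Wilson score by default; Wald
    and Clopper-Pearson exact available); likelihood-ratio CIs by the log
    method.  Raises :class:`UndefinedMetricError` when a denominator is
    empty, naming the metric.
    """
    if ci_method not in _CI_METHODS:
        raise DomainError(f"ci_method must be one of {sorted(_CI_METHODS)}")
    tp, fp, fn, tn = (int(v) for v in table)
    if min(tp, fp, fn, tn) < 0:
        raise DomainError("counts must be nonnegative")
    n_dis, n_hea = tp + fn, fp + tn
    n_pos, n_neg = tp + fp, fn + tn
    if n_dis == 0:
        raise UndefinedMetricError("sensitivity undefined: no diseased subjects")
    if n_hea == 0:
        raise UndefinedMetricError("specificity undefined: no non-diseased subjects")
    if n_pos == 0:
        raise UndefinedMetricError("ppv undefined: no test-positive subjects")
    if n_neg == 0:
        raise UndefinedMetricError("npv undefined: no test-negative subjects")

    sens, spec = tp / n_dis, tn / n_hea
    ppv, npv = tp / n_pos, tn / n_neg
    fpr, fnr = fp / n_hea, fn / n_dis

    def prop(x, n):
        lo, hi = _prop_ci(x, n, ci_method)
        return (x / n, lo, hi)

    def lr_ci(num_x, num_n, den_x, den_n):
        # log-method interval; 0.5 correction only when a cell is empty
        if num_x == 0 or den_x == 0:
            num_x, num_n, den_x, den_n = num_x + 0.5, num_n + 0.5, den_x + 0.5, den_n + 0.5
        est = (num_x / num_n) / (den_x / den_n)
        se = math.sqrt(1 / num_x - 1 / num_n + 1 / den_x - 1 / den_n)
        z = stats.norm.ppf(0.975)
        return est, est * math.exp(-z * se), est * math.exp(z * se)

    lr_pos = lr_ci(tp, n_dis, fp, n_hea)
    lr_neg = lr_ci(fn, n_dis, tn, n_hea)
    lr_pos = (sens / fpr if fpr > 0 else math.inf, lr_pos[1], lr_pos[2])
    lr_neg = (fnr / spec if spec > 0 else math.inf, lr_neg[1], lr_neg[2])

    return DiagnosticSummary(
        sensitivity=prop(tp, n_dis),
        specificity=prop(tn, n_hea),
        ppv=prop(tp, n_pos),
        npv=prop(tn, n_neg),
        fpr=prop(fp, n_hea),
        fnr=prop(fn, n_dis),
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        n_diseased=n_dis,
        n_healthy=n_hea,
        n_test_positive=n_pos,
        n_test_negative=n_neg,
        ci_method=ci_method,
    )


# ---------------------------------------------------------------------------
# paired comparisons
# ---------------------------------------------------------------------------


def _paired_ratio_ci(m1: float, m2: float, both: float, alpha: float = 0.05):
    """Delta-method log CI for a ratio of paired proportions m2/m1 (shared
    denominator cancels); ``both`` is the doubly-positive count.  Cells are
    offset by one (Bonett-Price style) in the variance when small."""
    est = m2 / m1
    a1, a2, ab = m1 + 1.0, m2 + 1.0, both + 1.0
    se = math.sqrt(max(1.0 / a1 + 1.0 / a2 - 2.0 * ab / (a1 * a2), 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    return est, est * math.exp(-z * se), est * math.exp(z * se)


def mcnemar_p(b: int, c: int, exact_threshold: int = 25) -> float:
    """Two-sided McNemar p from the discordant-pair counts.

    Exact binomial when b + c < ``exact_threshold``; otherwise the
    continuity-corrected chi-square.  Invariant to concordant counts.
    """
    m = b + c
    if m == 0:
        return 1.0
    if m < exact_threshold:
        return min(1.0, 2.0 * stats.binom.cdf(min(b, c), m, 0.5))
    chi2 = (abs(b - c) - 1.0) ** 2 / m
    return float(stats.chi2.sf(chi2, 1))


def relative_sensitivity(paired: PairedScreenData) -> dict:
    """Ratio of test B's to test A's sensitivity on the paired diseased
    subjects, with a log-method CI and McNemar's test on the discordant
    diseased pairs."""
    c = paired.counts[:, :, 1]  # diseased stratum: [a result, b result]
    n_dis = c.sum()
    if n_dis == 0:
        raise UndefinedMetricError("relative sensitivity undefined: no diseased subjects")
    both = c[1, 1]
    m_a = c[1, 1] + c[1, 0]
    m_b = c[1, 1] + c[0, 1]
    if m_a == 0:
        raise UndefinedMetricError("reference test detects no diseased subjects")
    est, lo, hi = _paired_ratio_ci(m_a, m_b, both)
    return {
        "ratio": est,
        "ci": (lo, hi),
        "p_mcnemar": mcnemar_p(int(c[1, 0]), int(c[0, 1])),
        "sens_a": m_a / n_dis,
        "sens_b": m_b / n_dis,
        "n_diseased": int(n_dis),
        "discordant": (int(c[1, 0]), int(c[0, 1])),
    }


def _generalized_score(cells: np.ndarray) -> tuple[float, float]:
    """Generalized score chi-square for equal success probability of two
    paired record sets.

    ``cells[a, b, d]`` counts; a record (i, j) enters when test j is
    'selected' (positive for PPV, negative for NPV after relabelling) and
    contributes outcome d.  Closed form of the robust score test of the
    test-indicator coefficient in a marginal logistic model fitted under
    the null."""
    sel_a = cells.sum(axis=1)  # [a result, d]
    sel_b = cells.sum(axis=0)
    n_a = sel_a[1].sum()
    n_b = sel_b[1].sum()
    if n_a == 0 or n_b == 0:
        raise UndefinedMetricError(
            "one test makes no qualifying calls; use the bootstrap comparison instead"
        )
    p0 = (sel_a[1, 1] + sel_b[1, 1]) / (n_a + n_b)
    w = n_b / (n_a + n_b)
    u = 0.0
    v = 0.0
    for a in (0, 1):
        for b in (0, 1):
            for d in (0, 1):
                nk = cells[a, b, d]
                if nk == 0:
                    continue
                resid = d - p0
                ui = b * resid - w * (a + b) * resid  # efficient score per subject
                u += nk * ui
                v += nk * ui * ui
    if v == 0:
        return 0.0, 1.0
    chi2 = u * u / v
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def predictive_value_test(paired: PairedScreenData, which: str = "ppv") -> tuple[float, float]:
    """Compare the positive (or negative) predictive values of two paired
    tests with the generalized score statistic.

    Returns ``(chi2, p)``.  The statistic is 0 with p = 1 for identical
    classifications.
    """
    c = paired.counts
    if which == "ppv":
        cells = c
    elif which == "npv":
        cells = c[::-1, ::-1, ::-1]  # flip tests and disease: NPV is PPV of the negations
    else:
        raise DomainError("which must be 'ppv' or 'npv'")
    return _generalized_score(cells)


def likelihood_ratio_test(paired: PairedScreenData, which: str = "pos") -> tuple[float, float]:
    """Wald test of equality of the paired positive (or negative)
    likelihood ratios on the log scale.

    log LR+ = log sensitivity - log FPF; the sensitivity contrast uses the
    paired diseased subjects and the FPF contrast the paired healthy
    subjects, each with the delta-method paired-ratio variance; the two are
    independent, so the variances add.  Returns ``(z, p)``.
    """
    if which not in ("pos", "neg"):
        raise DomainError("which must be 'pos' or 'neg'")
    dis = paired.counts[:, :, 1]
    hea = paired.counts[:, :, 0]
    if which == "neg":
        dis, hea = dis[::-1, ::-1], hea[::-1, ::-1]  # negate both tests
    n_d, n_h = dis.sum(), hea.sum()
    if n_d == 0 or n_h == 0:
        raise UndefinedMetricError("both diseased and healthy subjects are required")
    ma_d, mb_d, both_d = dis[1, :].sum(), dis[:, 1].sum(), dis[1, 1]
    ma_h, mb_h, both_h = hea[1, :].sum(), hea[:, 1].sum(), hea[1, 1]
    if (ma_d == mb_d and dis[1, 0] == dis[0, 1] == 0) and (
        ma_h == mb_h and hea[1, 0] == hea[0, 1] == 0
    ):
        return 0.0, 1.0
    if min(ma_d, mb_d, ma_h, mb_h) == 0:
        raise UndefinedMetricError(
            "a zero detection/false-positive count leaves the log LR unbounded; "
            "use the bootstrap comparison instead"
        )
    log_ratio = math.log((mb_d / ma_d) / (mb_h / ma_h))
    var_d = 1.0 / ma_d + 1.0 / mb_d - 2.0 * both_d / (ma_d * mb_d)
    var_h = 1.0 / ma_h + 1.0 / mb_h - 2.0 * both_h / (ma_h * mb_h)
    se = math.sqrt(max(var_d + var_h, 1e-300))
    z = log_ratio / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def bootstrap_paired_p(
    paired: PairedScreenData,
    metric: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Paired-bootstrap two-sided p for a difference in ``metric`` between
    the two tests ('ppv', 'npv', 'lr_pos', 'lr_neg').

    Resamples subjects (the 8 cells as a multinomial) and inverts the
    percentile interval of the metric difference (log scale for LRs).
    Serves as the cross-check and fallback for the closed-form tests.
    """
    rng = np.random.default_rng(seed)
    c = paired.counts.reshape(-1)
    n = int(c.sum())
    probs = c / n
    draws = rng.multinomial(n, probs, size=n_boot).reshape(n_boot, 2, 2, 2).astype(float)

    def stat(cells: np.ndarray) -> np.ndarray:
        dis = cells[..., 1]
        hea = cells[..., 0]
        pos_a = dis[..., 1, :].sum(-1) + hea[..., 1, :].sum(-1)
        pos_b = dis[..., :, 1].sum(-1) + hea[..., :, 1].sum(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            if metric == "ppv":
                return dis[..., :, 1].sum(-1) / pos_b - dis[..., 1, :].sum(-1) / pos_a
            if metric == "npv":
                neg_a = dis[..., 0, :].sum(-1) + hea[..., 0, :].sum(-1)
                neg_b = dis[..., :, 0].sum(-1) + hea[..., :, 0].sum(-1)
                return hea[..., :, 0].sum(-1) / neg_b - hea[..., 0, :].sum(-1) / neg_a
            n_d = dis.sum((-2, -1))
            n_h = hea.sum((-2, -1))
            se_a, se_b = dis[..., 1, :].sum(-1) / n_d, dis[..., :, 1].sum(-1) / n_d
            fp_a, fp_b = hea[..., 1, :].sum(-1) / n_h, hea[..., :, 1].sum(-1) / n_h
            if metric == "lr_pos":
                return np.log(se_b / fp_b) - np.log(se_a / fp_a)
            if metric == "lr_neg":
                return np.log((1 - se_b) / (1 - fp_b)) - np.log((1 - se_a) / (1 - fp_a))
        raise DomainError(f"unknown metric {metric!r}")

    obs = float(stat(paired.counts[None, ...])[0])
    boot = stat(draws)
    boot = boot[np.isfinite(boot)]
    if boot.size < n_boot // 2:
        raise UndefinedMetricError("bootstrap distribution degenerate for this table")
    # percentile-interval inversion: smallest alpha at which 0 leaves the CI
    frac_below = float(np.mean(boot < 0.0)) if obs > 0 else float(np.mean(boot > 0.0))
    return min(1.0, 2.0 * max(frac_below, 0.5 / boot.size))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def roc_auc(scores, disease) -> tuple[float, tuple[float, float]]:
    """AUC via the Mann-Whitney identity with a DeLong 95% CI.

    Higher scores must indicate disease.  Raises on single-class input.
    """
    y = np.asarray(disease, dtype=bool)
    s = np.asarray(scores, dtype=float)
    x, z = s[y], s[~y]
    m, n = x.size, z.size
    if m == 0 or n == 0:
        raise UndefinedMetricError("roc_auc requires both classes present")
    order = np.concatenate([x, z])
    ranks = stats.rankdata(order)
    auc = (ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    rx = stats.rankdata(x)
    rz = stats.rankdata(z)
    v10 = (ranks[:m] - rx) / n
    v01 = 1.0 - (ranks[m:] - rz) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    se = math.sqrt(max(var, 0.0))
    zq = stats.norm.ppf(0.975)
    return float(auc), (float(max(0.0, auc - zq * se)), float(min(1.0, auc + zq * se)))
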