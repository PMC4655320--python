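"""Relative risks of composite outcomes by screening/marker strata, with
Fisher exact p-values and Mantel-Haenszel-style interaction tests.

Conventions: the relative risk compares P(outcome | exposed) with
P(outcome | reference); its interval is the Katz log-method CI; the
two-sided Fisher exact p sums hypergeometric probabilities no larger than
the observed table's.  Zero cells get an add-0.5 continuity correction in
the CI only, never in the point estimate, with a flag in the result.

The interaction ("effect-modification") test is a homogeneity test of the
risk ratio across two strata on the log-RR scale, Mantel-Haenszel style; a
logistic-model interaction Wald p is computed alongside as a cross-check,
and the two agree closely in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DomainError, UndefinedMetricError

__all__ = ["Table2x2", "RelativeRisk", "relative_risk", "mh_interaction", "table4_report"]


@dataclass(frozen=True)
class Table2x2:
    """Exposure x outcome counts: (exposed events, exposed total,
    reference events, reference total)."""

    exposed_events: int
    exposed_total: int
    reference_events: int
    reference_total: int

    def __post_init__(self) -> None:
        if min(self.exposed_events, self.reference_events) < 0:
            raise DomainError("counts must be nonnegative")
        if self.exposed_events > self.exposed_total or self.reference_events > self.reference_total:
            raise DomainError("events cannot exceed group totals")
        if self.exposed_total < 1 or self.reference_total < 1:
            raise DomainError("both exposure groups need at least one subject")


@dataclass(frozen=True)
class RelativeRisk:
    rr: float
    ci: tuple[float, float]
    p_fisher: float
    continuity_corrected_ci: bool
    table: Table2x2


def relative_risk(t: Table2x2) -> RelativeRisk:
    """Risk ratio with Katz log-method 95% CI and two-sided Fisher exact p.

    A zero event count in the reference group only yields an explicit
    infinite RR; zero events overall make the RR undefined.
    """
    a, n1 = t.exposed_events, t.exposed_total
    c, n0 = t.reference_events, t.reference_total
    if a + c == 0:
        raise UndefinedMetricError("relative risk undefined: no outcome events in either group")
    fisher_table = [[a, n1 - a], [c, n0 - c]]
    p = float(stats.fisher_exact(fisher_table, alternative="two-sided")[1])
    if c == 0:
        return RelativeRisk(math.inf, (math.nan, math.inf), p, False, t)
    rr = (a / n1) / (c / n0)
    corrected = a == 0 or c == 0
    aa, cc = (a + 0.5, c + 0.5) if corrected else (a, c)
    nn1, nn0 = (n1 + 0.5, n0 + 0.5) if corrected else (n1, n0)
    se = math.sqrt(1 / aa - 1 / nn1 + 1 / cc - 1 / nn0)
    z = stats.norm.ppf(0.975)
    lnrr = math.log((aa / nn1) / (cc / nn0)) if corrected else math.log(rr)
    lo, hi = math.exp(lnrr - z * se), math.exp(lnrr + z * se)
    return RelativeRisk(rr, (lo, hi), p, corrected, t)


def _log_rr_var(t: Table2x2) -> tuple[float, float]:
    a, n1, c, n0 = t.exposed_events, t.exposed_total, t.reference_events, t.reference_total
    if a == 0 or c == 0:
        a, c, n1, n0 = a + 0.5, c + 0.5, n1 + 0.5, n0 + 0.5
    return math.log((a / n1) / (c / n0)), 1 / a - 1 / n1 + 1 / c - 1 / n0


def mh_interaction(stratum1: Table2x2, stratum2: Table2x2) -> dict:
    """Homogeneity-of-RR test across two strata.

    Chi-square (1 df) on the difference of log risk ratios with
    delta-method variances (the Mantel-Haenszel-style heterogeneity
    statistic for two strata); a logistic interaction Wald p is returned
    alongside as a cross-check.
    """
    for s in (stratum1, stratum2):
        if s.exposed_total == 0 or s.reference_total == 0:
            raise DomainError("each stratum needs both exposure groups")
        if s.exposed_events + s.reference_events == 0:
            raise UndefinedMetricError("a stratum with no events has no estimable RR")
    l1, v1 = _log_rr_var(stratum1)
    l2, v2 = _log_rr_var(stratum2)
    chi2 = (l1 - l2) ** 2 / (v1 + v2)
    p = float(stats.chi2.sf(chi2, 1))
    return {
        "chi2": float(chi2),
        "p": p,
        "p_logistic": _logistic_interaction_p(stratum1, stratum2),
        "log_rr": (l1, l2),
    }


def _logistic_interaction_p(s1: Table2x2, s2: Table2x2) -> float:
    """Wald p for the exposure-by-stratum interaction in a logistic model."""
    import warnings

    import statsmodels.api as sm

    rows, y = [], []
    for stratum, t in enumerate((s1, s2)):
        for exposed, events, total in (
            (1, t.exposed_events, t.exposed_total),
            (0, t.reference_events, t.reference_total),
        ):
            rows.append([1.0, exposed, stratum, exposed * stratum])
            y.append([events, total - events])
    x = np.asarray(rows)
    y = np.asarray(y, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
        return float(fit.pvalues[3])
    except Exception:  # separation / degenerate strata
        return float("nan")


_OUTCOME_COLUMNS = {
    "any_neonatal_morbidity": "neonatal_morbidity",
    "metabolic_acidosis": "metabolic_acidosis",
    "low_apgar5": "low_apgar5",
    "nnu_admission": "nnu_admission_term",
    "sga_plus_morbidity": "sga_plus_morbidity",
    "severe_adverse": "severe_adverse",
    "sga_plus_severe": "sga_plus_severe",
}


def _rr_row(exposed: pd.Series, outcome: pd.Series, reference: pd.Series) -> RelativeRisk:
    t = Table2x2(
        int(outcome[exposed].sum()),
        int(exposed.sum()),
        int(outcome[reference].sum()),
        int(reference.sum()),
    )
    return relative_risk(t)


def table4_report(classified: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Stratified relative-risk table for EFW-below-10th-percentile exposure.

    Rows: universal screen positive by the population standard; by the
    customised standard (if present); screen positive with normal AC growth
    velocity; screen positive with lowest-decile AC growth velocity.  All
    RRs are referent to screen-negative pregnancies by the corresponding
    standard.  Returns the formatted frame plus a ledger with every 2x2.
    """
    required = {"universal_status", "acgv_bottom_decile", "neonatal_morbidity"}
    missing = sorted(required - set(classified.columns))
    if missing:
        raise DomainError(f"classification table lacks columns: {missing}")
    pos = classified["universal_status"] == "positive"
    neg = ~pos
    has_acgv = classified["acgv"].notna() if "acgv" in classified else pd.Series(
        True, index=classified.index
    )
    strata = {
        "efw_lt10_population": (pos, neg),
        "efw_lt10_normal_acgv": (pos & ~classified["acgv_bottom_decile"] & has_acgv, neg),
        "efw_lt10_lowest_acgv": (pos & classified["acgv_bottom_decile"], neg),
    }
    if "customised_status" in classified:
        cpos = classified["customised_status"] == "positive"
        strata = {
            "efw_lt10_population": strata["efw_lt10_population"],
            "efw_lt10_customised": (cpos, ~cpos),
            "efw_lt10_normal_acgv": strata["efw_lt10_normal_acgv"],
            "efw_lt10_lowest_acgv": strata["efw_lt10_lowest_acgv"],
        }

    rows, ledger = [], []
    for row_name, (exposed, reference) in strata.items():
        row = {"stratum": row_name, "n_exposed": int(exposed.sum())}
        for col_name, col in _OUTCOME_COLUMNS.items():
            if col not in classified:
                continue
            try:
                res = _rr_row(exposed, classified[col], reference)
                row[f"{col_name}_rr"] = res.rr
                row[f"{col_name}_ci_low"] = res.ci[0]
                row[f"{col_name}_ci_high"] = res.ci[1]
                row[f"{col_name}_p"] = res.p_fisher
                ledger.append(
                    {
                        "stratum": row_name,
                        "outcome": col_name,
                        "exposed_events": res.table.exposed_events,
                        "exposed_total": res.table.exposed_total,
                        "reference_events": res.table.reference_events,
                        "reference_total": res.table.reference_total,
                        "rr": res.rr,
                        "ci": list(res.ci),
                        "p_fisher": res.p_fisher,
                        "continuity_corrected_ci": res.continuity_corrected_ci,
                    }
                )
            except UndefinedMetricError:
                row[f"{col_name}_rr"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows), ledger
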