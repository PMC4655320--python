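"""Screen-positive/negative rules, gold standards, composite outcomes and
decile-based FGR markers.

Screen status under each policy is classified on the basis of the last
eligible scan before birth: clinically indicated scans at >= 26 weeks for
the selective policy (no eligible scan counts as screen negative), the
research 28/36-week scans for the universal policy.  Positive means an EFW
strictly below the 10th percentile; a percentile of exactly 10.0 is screen
negative.

FGR markers are cohort-level decile flags on GA-adjusted Z-scores: highest
deciles of HC/AC ratio, uterine-artery PI (20-week scan) and
umbilical-artery PI; lowest deciles of AC/FL ratio and AC growth velocity
(last scan minus 20-week scan).  Decile cuts use the standard empirical
(type-7) quantile with strict inequality beyond the cut, so ties at the cut
are never flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DomainError, MissingInputError, ValidationError
from . import growth
from .growth import EFWEquation, GrowthStandard, fit_zscore_model

__all__ = [
    "CohortExclusion",
    "classify_policy",
    "gold_standard",
    "neonatal_morbidity",
    "decile_flags",
    "classify_cohort",
]

log = logging.getLogger(__name__)

CLINICAL_GA_CUTOFF = 26.0
SCREEN_THRESHOLD = 10.0
SEVERE_THRESHOLD = 3.0


class CohortExclusion(Exception):
    """Subject cannot be classified under the universal policy (no research
    scan at >= 28 weeks; mirrors the study's exclusion of deliveries before
    the 28-week scan)."""


def classify_policy(
    scans: pd.DataFrame,
    policy: str,
    delivery_ga: float,
    efw_std: GrowthStandard,
    equation: EFWEquation | str = "hadlock_efw_hc_ac_fl",
    threshold: float = SCREEN_THRESHOLD,
    clinical_cutoff: float = CLINICAL_GA_CUTOFF,
) -> tuple[str, float]:
    """Classify one subject's scans under ``policy``.

    Returns ``(status, last_efw_percentile)``; the percentile is NaN for a
    selective-negative subject with no eligible scan.
    """
    if policy not in ("selective", "universal"):
        raise DomainError(f"unknown policy {policy!r}")
    df = scans.sort_values("scan_ga_weeks", kind="mergesort")
    df = df[df["scan_ga_weeks"] < delivery_ga]
    if policy == "selective":
        elig = df[(df["scan_policy"] == "selective") & (df["scan_ga_weeks"] >= clinical_cutoff)]
        if elig.empty:
            return "negative", float("nan")
    else:
        elig = df[df["scan_policy"].isin(["research28", "research36"])]
        if elig.empty:
            raise CohortExclusion("no research scan at >=28 weeks before delivery")
    last = elig.iloc[-1]
    eq = equation if isinstance(equation, EFWEquation) else EFWEquation.from_registry(equation)
    b = growth.BiometrySet(
        ga_weeks=float(last["scan_ga_weeks"]),
        hc_cm=float(growth.mm_to_cm(last["hc_mm"])),
        ac_cm=float(growth.mm_to_cm(last["ac_mm"])),
        fl_cm=float(growth.mm_to_cm(last["fl_mm"])),
        bpd_cm=float(growth.mm_to_cm(last["bpd_mm"])) if "bpd_mm" in last else None,
    )
    pct = float(growth.efw_percentile(growth.hadlock_efw(b, eq), b.ga_weeks, efw_std))
    return ("positive" if pct < threshold else "negative"), pct


def gold_standard(
    bw_percentile,
    threshold: float = SCREEN_THRESHOLD,
    severe_threshold: float = SEVERE_THRESHOLD,
) -> pd.DataFrame:
    """SGA / severe-SGA flags from a birthweight percentile (strict '<')."""
    pct = np.asarray(bw_percentile, dtype=float)
    if np.any((pct <= 0) | (pct >= 100)):
        raise DomainError("birthweight percentile must lie in (0, 100)")
    return pd.DataFrame({"sga": pct < threshold, "severe_sga": pct < severe_threshold})


def neonatal_morbidity(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Composite-outcome flags for each row of an outcomes table.

    Composite neonatal morbidity: 5-minute Apgar < 7, metabolic acidosis
    (cord pH < 7.1 and base deficit > 10 mmol/L, strict), or neonatal-unit
    admission at term (admission < 48 h after birth at >= 37 weeks with
    discharge >= 48 h after admission).  Severe adverse perinatal outcome:
    stillbirth, or term livebirth with neonatal death, HIE, inotropes,
    mechanical ventilation, or severe metabolic acidosis (pH < 7.0 and base
    deficit > 12).  Missing component fields count as criterion-not-met and
    are logged.
    """
    n_missing = int(
        outcomes[["apgar5", "cord_ph", "cord_base_deficit"]].isna().sum().sum()
    )
    if n_missing:
        log.info("neonatal_morbidity: %d missing component fields treated as not met", n_missing)

    apgar = pd.to_numeric(outcomes["apgar5"], errors="coerce")
    ph = pd.to_numeric(outcomes["cord_ph"], errors="coerce")
    bd = pd.to_numeric(outcomes["cord_base_deficit"], errors="coerce")
    ga = pd.to_numeric(outcomes["ga_delivery_weeks"], errors="coerce")

    low_apgar5 = (apgar < 7).fillna(False)
    acidosis = ((ph < 7.1) & (bd > 10.0)).fillna(False)
    severe_acidosis = ((ph < 7.0) & (bd > 12.0)).fillna(False)

    admit = outcomes.get("nnu_admit", pd.Series(False, index=outcomes.index)).fillna(False)
    admit_h = pd.to_numeric(outcomes.get("nnu_admit_hours_after_birth"), errors="coerce")
    stay_h = pd.to_numeric(outcomes.get("nnu_stay_hours"), errors="coerce")
    if bool((admit & (stay_h < 0)).any()):
        raise ValidationError("neonatal-unit discharge precedes admission")
    term = ga >= 37.0
    nnu_admission_term = (admit & term & (admit_h < 48.0) & (stay_h >= 48.0)).fillna(False)

    morbidity = low_apgar5 | acidosis | nnu_admission_term

    stillbirth = outcomes.get("stillbirth", pd.Series(False, index=outcomes.index)).fillna(False)
    term_live = term & ~stillbirth
    severe_components = pd.DataFrame(
        {
            c: outcomes.get(c, pd.Series(False, index=outcomes.index)).fillna(False)
            for c in ("neonatal_death", "hie", "inotropes", "mech_ventilation")
        }
    ).any(axis=1) | severe_acidosis
    severe_adverse = stillbirth | (term_live & severe_components)

    return pd.DataFrame(
        {
            "low_apgar5": low_apgar5.to_numpy(bool),
            "metabolic_acidosis": acidosis.to_numpy(bool),
            "nnu_admission_term": nnu_admission_term.to_numpy(bool),
            "neonatal_morbidity": morbidity.to_numpy(bool),
            "severe_adverse": severe_adverse.to_numpy(bool),
        },
        index=outcomes.index,
    )


def decile_flags(values, tail: str) -> np.ndarray:
    """Flag values strictly beyond the empirical 10th/90th percentile cut.

    ``tail='lowest'`` flags values strictly below the type-7 10th
    percentile; ``'highest'`` strictly above the 90th.  Missing values are
    flagged False and counted in a log line.
    """
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if ok.sum() == 0:
        raise DomainError("decile_flags: all values missing")
    if ok.sum() < 10:
        raise DomainError("decile_flags: need >=10 non-missing values")
    if (~ok).sum():
        log.info("decile_flags: %d missing values flagged False", int((~ok).sum()))
    out = np.zeros(v.shape, dtype=bool)
    if tail == "lowest":
        cut = np.quantile(v[ok], 0.10)  # type-7 (linear) quantile
        out[ok] = v[ok] < cut
    elif tail == "highest":
        cut = np.quantile(v[ok], 0.90)
        out[ok] = v[ok] > cut
    else:
        raise DomainError(f"tail must be 'lowest' or 'highest', got {tail!r}")
    return out


@dataclass
class ClassificationConfig:
    threshold: float = SCREEN_THRESHOLD
    severe_threshold: float = SEVERE_THRESHOLD
    clinical_cutoff: float = CLINICAL_GA_CUTOFF
    efw_standard: str = "hadlock_weight_for_ga"
    efw_equation: str = "hadlock_efw_hc_ac_fl"
    birthweight_reference: str = "uk_birthweight_reference_synthetic.csv"
    customisation: str = "customisation_surrogate"
    zscore_degree: int = 2


def _efw_percentiles(scans: pd.DataFrame, eq: EFWEquation, std: GrowthStandard) -> pd.Series:
    measures = {
        "hc_cm": growth.mm_to_cm(scans["hc_mm"].to_numpy()),
        "ac_cm": growth.mm_to_cm(scans["ac_mm"].to_numpy()),
        "fl_cm": growth.mm_to_cm(scans["fl_mm"].to_numpy()),
    }
    if "bpd_mm" in scans:
        measures["bpd_cm"] = growth.mm_to_cm(scans["bpd_mm"].to_numpy())
    efw = eq.weight_g({k: measures[k] for k in eq.required})
    pct = std.percentile(efw, scans["scan_ga_weeks"].to_numpy())
    return pd.Series(pct, index=scans.index), pd.Series(efw, index=scans.index)


def classify_cohort(
    scans: pd.DataFrame,
    outcomes: pd.DataFrame,
    maternal: pd.DataFrame | None = None,
    config: ClassificationConfig | None = None,
) -> pd.DataFrame:
    """Per-subject screening statuses, gold standards, outcome composites and
    FGR-marker decile flags for a whole cohort.

    Input order is irrelevant (internal sort).  Subjects with no research
    scan at >= 28 weeks before delivery are excluded with a log line,
    mirroring the study design.
    """
    cfg = config or ClassificationConfig()
    eq = EFWEquation.from_registry(cfg.efw_equation)
    efw_std = GrowthStandard.from_registry(cfg.efw_standard)
    bw_std = GrowthStandard.from_birthweight_table(cfg.birthweight_reference)

    scans = scans.sort_values(["subject_id", "scan_ga_weeks"], kind="mergesort").reset_index(
        drop=True
    )
    outcomes = outcomes.sort_values("subject_id", kind="mergesort").reset_index(drop=True)
    deliv = outcomes.set_index("subject_id")["ga_delivery_weeks"]

    scans = scans[scans["subject_id"].isin(deliv.index)].copy()
    scans["delivery_ga"] = scans["subject_id"].map(deliv).to_numpy()
    scans = scans[scans["scan_ga_weeks"] < scans["delivery_ga"]].reset_index(drop=True)
    pct, efw = _efw_percentiles(scans, eq, efw_std)
    scans["efw_percentile"] = pct
    scans["efw_g"] = efw
    scans["hc_ac"] = scans["hc_mm"] / scans["ac_mm"]
    scans["ac_fl"] = scans["ac_mm"] / scans["fl_mm"]

    research = scans[scans["scan_policy"].isin(["research20", "research28", "research36"])]
    late_research = scans[scans["scan_policy"].isin(["research28", "research36"])]
    selective = scans[
        (scans["scan_policy"] == "selective") & (scans["scan_ga_weeks"] >= cfg.clinical_cutoff)
    ]

    # last eligible scan per subject and policy
    uni_last = late_research.groupby("subject_id").tail(1).set_index("subject_id")
    sel_last = selective.groupby("subject_id").tail(1).set_index("subject_id")

    subjects = outcomes["subject_id"]
    excluded = ~subjects.isin(uni_last.index)
    if excluded.any():
        log.info(
            "classify_cohort: %d subjects excluded (no research scan >=28 weeks before birth)",
            int(excluded.sum()),
        )
    keep = subjects[~excluded]
    out = pd.DataFrame({"subject_id": keep}).set_index("subject_id")
    outcomes = outcomes.set_index("subject_id").loc[out.index]

    out["universal_pct"] = uni_last["efw_percentile"]
    out["universal_status"] = np.where(
        out["universal_pct"] < cfg.threshold, "positive", "negative"
    )
    out["selective_pct"] = sel_last["efw_percentile"]
    out["selective_status"] = np.where(
        out["selective_pct"] < cfg.threshold, "positive", "negative"
    )  # NaN comparison is False -> no eligible scan is screen negative

    # gold standard from birthweight percentile
    bw_pct = bw_std.percentile(
        outcomes["birthweight_g"].to_numpy(),
        np.clip(outcomes["ga_delivery_weeks"].to_numpy(), *bw_std.ga_domain),
        outcomes["sex"].to_numpy(),
    )
    out["bw_percentile"] = bw_pct
    gs = gold_standard(bw_pct, cfg.threshold, cfg.severe_threshold)
    out["sga"] = gs["sga"].to_numpy()
    out["severe_sga"] = gs["severe_sga"].to_numpy()

    flags = neonatal_morbidity(outcomes.reset_index())
    for c in flags.columns:
        out[c] = flags[c].to_numpy()
    out["sga_plus_morbidity"] = out["sga"] & out["neonatal_morbidity"]
    out["sga_plus_severe"] = out["sga"] & out["severe_adverse"]

    # --- GA-adjusted Z-scores and marker deciles (research scans) ----------
    z_ac = fit_zscore_model(
        research["scan_ga_weeks"], growth.mm_to_cm(research["ac_mm"]), cfg.zscore_degree
    )
    z_hcac = fit_zscore_model(research["scan_ga_weeks"], research["hc_ac"], cfg.zscore_degree)
    z_acfl = fit_zscore_model(research["scan_ga_weeks"], research["ac_fl"], cfg.zscore_degree)
    z_uta = fit_zscore_model(research["scan_ga_weeks"], research["uta_pi_mean"], 1)
    z_ua = fit_zscore_model(research["scan_ga_weeks"], research["ua_pi"], 1)

    res_last = research.groupby("subject_id").tail(1).set_index("subject_id")
    scan20 = research[research["scan_policy"] == "research20"]
    scan20 = scan20.groupby("subject_id").tail(1).set_index("subject_id")

    out["hc_ac_z"] = z_hcac.zscore(res_last["scan_ga_weeks"], res_last["hc_ac"])
    out["ac_fl_z"] = z_acfl.zscore(res_last["scan_ga_weeks"], res_last["ac_fl"])
    out["ua_z"] = z_ua.zscore(res_last["scan_ga_weeks"], res_last["ua_pi"])
    out["uta_z"] = z_uta.zscore(scan20["scan_ga_weeks"], scan20["uta_pi_mean"])

    ac_z_last = pd.Series(
        z_ac.zscore(res_last["scan_ga_weeks"], growth.mm_to_cm(res_last["ac_mm"])),
        index=res_last.index,
    )
    ac_z_20 = pd.Series(
        z_ac.zscore(scan20["scan_ga_weeks"], growth.mm_to_cm(scan20["ac_mm"])),
        index=scan20.index,
    )
    # velocity requires both a 20-week scan and a later scan
    later = res_last["scan_ga_weeks"] >= cfg.clinical_cutoff
    acgv = ac_z_last.where(later) - ac_z_20
    n_missing_acgv = int(acgv.reindex(out.index).isna().sum())
    if n_missing_acgv:
        log.info("classify_cohort: %d subjects lack an AC growth velocity", n_missing_acgv)
    out["acgv"] = acgv

    out["hc_ac_top_decile"] = decile_flags(out["hc_ac_z"], "highest")
    out["ac_fl_bottom_decile"] = decile_flags(out["ac_fl_z"], "lowest")
    out["uta_top_decile"] = decile_flags(out["uta_z"], "highest")
    out["ua_top_decile"] = decile_flags(out["ua_z"], "highest")
    out["acgv_bottom_decile"] = decile_flags(out["acgv"], "lowest")

    # --- customised percentile of the last universal EFW --------------------
    if maternal is not None:
        mat = maternal.set_index("subject_id").loc[out.index]
        cust = np.full(len(out), np.nan)
        coeffs = growth.load_standard(cfg.customisation)
        ga_arr = uni_last.loc[out.index, "scan_ga_weeks"].to_numpy()
        efw_arr = uni_last.loc[out.index, "efw_g"].to_numpy()
        for eth in pd.unique(mat["ethnicity"]):
            m = (mat["ethnicity"] == eth).to_numpy()
            # vectorised over subjects: the surrogate is linear in the profile
            tow = (
                float(coeffs["base_term_weight_g"])
                + float(coeffs["height_coef_g_per_cm"]) * (mat["height_cm"].to_numpy()[m] - 163.0)
                + float(coeffs["weight_coef_g_per_kg"]) * (mat["weight_kg"].to_numpy()[m] - 64.0)
                + float(coeffs["ethnicity_offsets_g"][eth])
            )
            curve = np.asarray(coeffs["proportion_curve"]["coefficients"], float)[::-1]
            term_ga = float(coeffs["proportion_curve"]["term_ga"])
            prop = np.exp(np.polyval(curve, ga_arr[m])) / np.exp(np.polyval(curve, term_ga))
            from scipy import stats as _st

            cust[m] = 100.0 * _st.norm.cdf(
                (efw_arr[m] - tow * prop) / (float(coeffs["cv"]) * tow * prop)
            )
        out["customised_pct"] = cust
        out["customised_status"] = np.where(
            out["customised_pct"] < cfg.threshold, "positive", "negative"
        )

    return out.reset_index()
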