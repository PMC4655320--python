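"""Configuration-driven orchestration of the full screening analysis.

Stage order is fixed: synthesize/ingest -> standards -> classify ->
paired accuracy -> stratified risk.  Every output file carries the config
hash and seed in a header comment; the JSON ledger keeps full precision
while the printed tables are rounded at the output layer only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError, ValidationError
from . import accuracy, risk
from .classification import ClassificationConfig, classify_cohort
from .synthesis import CohortParams, SyntheticCohort, generate_cohort

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "validate_input", "analyse_classified"]


@dataclass
class RunConfig:
    mode: str = "synthetic"  # 'synthetic' | 'csv'
    scans_csv: str | None = None
    outcomes_csv: str | None = None
    maternal_csv: str | None = None
    n_subjects: int = 3977
    seed: int = 0
    threshold: float = 10.0
    severe_threshold: float = 3.0
    clinical_cutoff: float = 26.0
    out_dir: str = "popscreen_out"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ConfigurationError(f"mode must be 'synthetic' or 'csv', got {self.mode!r}")
        for name in ("threshold", "severe_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ConfigurationError(f"{name}={v} must lie in (0, 100)")
        if self.clinical_cutoff < 20.0:
            raise ConfigurationError("clinical_cutoff must be >= 20 weeks")
        if self.mode == "csv" and not (self.scans_csv and self.outcomes_csv):
            raise ConfigurationError("csv mode requires scans_csv and outcomes_csv")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        # analytic configuration only: where the report lands is not part
        # of what it contains
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


_SCAN_COLUMNS = {
    "subject_id",
    "scan_ga_weeks",
    "scan_policy",
    "bpd_mm",
    "hc_mm",
    "ac_mm",
    "fl_mm",
}
_OUTCOME_COLUMNS = {"subject_id", "ga_delivery_weeks", "birthweight_g", "sex"}
_POLICIES = {"selective", "research20", "research28", "research36"}
# plausibility windows for biometry recorded in millimetres
_MM_RANGES = {"bpd_mm": (15, 120), "hc_mm": (60, 420), "ac_mm": (50, 450), "fl_mm": (8, 95)}


def validate_input(
    scans_csv: str | Path,
    outcomes_csv: str | Path,
    maternal_csv: str | Path | None = None,
) -> dict:
    """Schema / sanity validation of input CSVs.

    Returns ``{"errors": [...], "warnings": [...]}``; each message names the
    offending subject and field, with row numbers where applicable.
    """
    errors: list[str] = []
    warnings: list[str] = []
    try:
        scans = pd.read_csv(scans_csv, comment="#")
        outcomes = pd.read_csv(outcomes_csv, comment="#")
    except OSError as exc:
        raise ValidationError(f"cannot read input file: {exc}") from exc

    missing = _SCAN_COLUMNS - set(scans.columns)
    if missing:
        errors.append(f"scans: missing columns {sorted(missing)}")
    missing = _OUTCOME_COLUMNS - set(outcomes.columns)
    if missing:
        errors.append(f"outcomes: missing columns {sorted(missing)}")
    if errors:
        return {"errors": errors, "warnings": warnings}

    bad_policy = ~scans["scan_policy"].isin(_POLICIES)
    for i in scans.index[bad_policy]:
        errors.append(f"scans row {i}: unknown scan_policy {scans.at[i, 'scan_policy']!r}")
    ga = pd.to_numeric(scans["scan_ga_weeks"], errors="coerce")
    bad_ga = ~ga.between(12.0, 43.0)
    for i in scans.index[bad_ga]:
        errors.append(
            f"scans row {i}: subject {scans.at[i, 'subject_id']} scan_ga_weeks="
            f"{scans.at[i, 'scan_ga_weeks']} outside [12, 43]"
        )
    for col, (lo, hi) in _MM_RANGES.items():
        v = pd.to_numeric(scans[col], errors="coerce")
        nonpos = v <= 0
        for i in scans.index[nonpos]:
            errors.append(f"scans row {i}: subject {scans.at[i, 'subject_id']} {col}={v[i]} not positive")
        implaus = v.notna() & ~nonpos & ~v.between(lo, hi)
        for i in scans.index[implaus]:
            warnings.append(
                f"scans row {i}: {col}={v[i]} outside plausible mm range [{lo}, {hi}]"
            )

    bw = pd.to_numeric(outcomes["birthweight_g"], errors="coerce")
    for i in outcomes.index[~(bw > 0)]:
        errors.append(f"outcomes row {i}: subject {outcomes.at[i, 'subject_id']} birthweight_g not positive")

    deliv = outcomes.set_index("subject_id")["ga_delivery_weeks"]
    merged = scans.assign(_deliv=scans["subject_id"].map(deliv))
    no_outcome = merged["_deliv"].isna()
    for sid in merged.loc[no_outcome, "subject_id"].unique():
        warnings.append(f"subject {sid}: scans present but no outcome row")
    after = merged["scan_ga_weeks"] >= merged["_deliv"]
    for i in merged.index[after & ~no_outcome]:
        errors.append(
            f"scans row {i}: subject {merged.at[i, 'subject_id']} scanned at "
            f"{merged.at[i, 'scan_ga_weeks']} weeks, on/after delivery at "
            f"{merged.at[i, '_deliv']} weeks"
        )

    if maternal_csv is not None:
        maternal = pd.read_csv(maternal_csv, comment="#")
        if "subject_id" not in maternal.columns:
            errors.append("maternal: missing subject_id column")
        elif {"height_cm", "weight_kg", "bmi"}.issubset(maternal.columns):
            bmi_calc = maternal["weight_kg"] / (maternal["height_cm"] / 100.0) ** 2
            off = (bmi_calc - maternal["bmi"]).abs() > 0.15
            for i in maternal.index[off]:
                warnings.append(
                    f"maternal row {i}: BMI inconsistent with height/weight "
                    f"({maternal.at[i, 'bmi']} vs {bmi_calc[i]:.1f})"
                )
    return {"errors": errors, "warnings": warnings}


# ---------------------------------------------------------------------------


def _paired_tables(classified: pd.DataFrame, gold: str) -> accuracy.PairedScreenData:
    return accuracy.PairedScreenData.from_labels(
        (classified["selective_status"] == "positive").to_numpy(int),
        (classified["universal_status"] == "positive").to_numpy(int),
        classified[gold].to_numpy(int),
    )


def analyse_classified(classified: pd.DataFrame, seed: int = 0) -> dict:
    """Accuracy and risk stages on an already classified cohort.

    Returns a nested dict with Table 2-style counts, Table 3-style
    summaries and paired tests for SGA and severe SGA, the stratified-risk
    table with its cell ledger, and marker-interaction results.
    """
    result: dict = {"n": int(len(classified))}

    for gold in ("sga", "severe_sga"):
        paired = _paired_tables(classified, gold)
        block: dict = {"paired_counts": paired.counts.astype(int).tolist()}
        for test, label in (("a", "selective"), ("b", "universal")):
            tp, fp, fn, tn = paired.table(test)
            try:
                s = accuracy.summarize((tp, fp, fn, tn))
            except accuracy.UndefinedMetricError as exc:
                block[label] = {"table": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
                                "error": str(exc)}
                continue
            block[label] = {
                "table": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
                "metrics": {
                    m: list(getattr(s, m))
                    for m in ("sensitivity", "specificity", "ppv", "npv", "fpr", "fnr",
                              "lr_pos", "lr_neg")
                },
                "rounded": s.rounded(),
            }
        try:
            rel = accuracy.relative_sensitivity(paired)
            block["relative_sensitivity"] = {
                "ratio": rel["ratio"],
                "ci": list(rel["ci"]),
                "p_mcnemar": rel["p_mcnemar"],
            }
        except Exception as exc:
            block["relative_sensitivity"] = {"error": str(exc)}
        for which in ("ppv", "npv"):
            try:
                chi2, p = accuracy.predictive_value_test(paired, which)
                block[f"{which}_test"] = {"chi2": chi2, "p": p}
            except Exception as exc:
                block[f"{which}_test"] = {"error": str(exc)}
        for which in ("pos", "neg"):
            try:
                z, p = accuracy.likelihood_ratio_test(paired, which)
                block[f"lr_{which}_test"] = {"z": z, "p": p}
            except Exception as exc:
                block[f"lr_{which}_test"] = {"error": str(exc)}
        result[gold] = block

    for gold, key in (("sga", "auc_universal_sga"), ("severe_sga", "auc_universal_severe_sga")):
        try:
            auc, ci = accuracy.roc_auc(
                -classified["universal_pct"].to_numpy(), classified[gold].to_numpy()
            )
            result[key] = {"auc": auc, "ci": list(ci)}
        except accuracy.UndefinedMetricError as exc:
            result[key] = {"error": str(exc)}

    table4, ledger = risk.table4_report(classified)
    result["table4"] = table4.to_dict(orient="records")
    result["table4_ledger"] = ledger

    # Figure-2-style marker interactions: EFW<10 association with morbidity
    # within abnormal vs normal marker strata
    pos = classified["universal_status"] == "positive"
    morb = classified["neonatal_morbidity"]
    interactions = {}
    for marker in (
        "hc_ac_top_decile",
        "ac_fl_bottom_decile",
        "uta_top_decile",
        "ua_top_decile",
        "acgv_bottom_decile",
    ):
        if marker not in classified:
            continue
        flag = classified[marker].astype(bool)
        strata = {}
        tabs = []
        for label, m in (("abnormal", flag), ("normal", ~flag)):
            t = risk.Table2x2(
                int(morb[m & pos].sum()), max(int((m & pos).sum()), 1),
                int(morb[m & ~pos].sum()), max(int((m & ~pos).sum()), 1),
            )
            tabs.append(t)
            try:
                rr = risk.relative_risk(t)
                strata[label] = {"rr": rr.rr, "ci": list(rr.ci), "p_fisher": rr.p_fisher}
            except risk.UndefinedMetricError as exc:
                strata[label] = {"error": str(exc)}
        try:
            inter = risk.mh_interaction(tabs[0], tabs[1])
            strata["interaction"] = {"p": inter["p"], "p_logistic": inter["p_logistic"]}
        except Exception as exc:
            strata["interaction"] = {"error": str(exc)}
        interactions[marker] = strata
    result["fig2_interactions"] = interactions
    return result


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Writes table2/table3/table4/fig2 CSVs, a full-precision JSON ledger, the
    per-subject classification CSV and a run log into ``config.out_dir``.
    On any stage error the partial outputs are removed and the exception is
    re-raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    header = f"# popscreen config_hash={config.hash()} seed={config.seed}\n"

    def write_csv(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        written.append(path)

    try:
        if config.mode == "synthetic":
            cohort = generate_cohort(CohortParams(n_subjects=config.n_subjects, seed=config.seed))
            scans, outcomes, maternal = cohort.scans, cohort.outcomes, cohort.maternal
            log.info("synthesized cohort: %d subjects, %d scans", config.n_subjects, len(scans))
        else:
            report = validate_input(config.scans_csv, config.outcomes_csv, config.maternal_csv)
            if report["errors"]:
                raise ValidationError("; ".join(report["errors"][:20]))
            scans = pd.read_csv(config.scans_csv, comment="#")
            outcomes = pd.read_csv(config.outcomes_csv, comment="#")
            maternal = (
                pd.read_csv(config.maternal_csv, comment="#") if config.maternal_csv else None
            )
            log.info("ingested cohort: %d subjects, %d scans", len(outcomes), len(scans))

        cls_cfg = ClassificationConfig(
            threshold=config.threshold,
            severe_threshold=config.severe_threshold,
            clinical_cutoff=config.clinical_cutoff,
        )
        classified = classify_cohort(scans, outcomes, maternal, cls_cfg)
        log.info("classified %d of %d subjects", len(classified), len(outcomes))

        result = analyse_classified(classified, seed=config.seed)
        result["config"] = asdict(config)
        result["config_hash"] = config.hash()

        # Table 2-style counts
        t2_rows = []
        for gold in ("sga", "severe_sga"):
            for test, label in (("a", "selective"), ("b", "universal")):
                tp, fp, fn, tn = accuracy.PairedScreenData(
                    np.asarray(result[gold]["paired_counts"], dtype=float)
                ).table(test)
                t2_rows.append(
                    {"gold": gold, "policy": label, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                     "total": tp + fp + fn + tn}
                )
        write_csv("table2.csv", pd.DataFrame(t2_rows))

        t3_rows = []
        for gold in ("sga", "severe_sga"):
            for label in ("selective", "universal"):
                row = {"gold": gold, "policy": label}
                row.update(result[gold][label].get("rounded", {}))
                t3_rows.append(row)
        write_csv("table3.csv", pd.DataFrame(t3_rows))

        write_csv("table4.csv", pd.DataFrame(result["table4"]))
        fig2_rows = []
        for marker, strata in result["fig2_interactions"].items():
            for label in ("abnormal", "normal"):
                fig2_rows.append(
                    {"marker": marker, "stratum": label, **strata[label],
                     "p_interaction": strata["interaction"].get("p")}
                )
        write_csv("fig2_strata.csv", pd.DataFrame(fig2_rows))
        write_csv("classification.csv", classified)

        with open(out_dir / "estimates.json", "w") as fh:
            json.dump(result, fh, indent=1, default=float)
        written.append(out_dir / "estimates.json")
        with open(out_dir / "run.log", "w") as fh:
            fh.write(header)
            fh.write(f"subjects_in={len(outcomes)}\nsubjects_classified={len(classified)}\n")
        written.append(out_dir / "run.log")
        return result
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
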