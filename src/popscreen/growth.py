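"""Fetal growth numerics.

Estimated fetal weight (EFW) from ultrasound biometry via the Hadlock
log10-polynomial equations, EFW-for-gestational-age percentiles against a
registered reference standard, gestational-age-adjusted Z-scores fitted
within a cohort, abdominal-circumference growth velocity, simplified
customised centiles, and sex-specific birthweight percentiles.

All coefficient sets live in versioned JSON/CSV files under
``popscreen/standards`` with a citation field; see :func:`load_standard`.
Gestational age is decimal weeks throughout; biometry is stored in mm in
files and converted to cm at the equation boundary (clinical convention vs
equation convention).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import (
    ConfigurationError,
    DomainError,
    FitError,
    MissingInputError,
    RangeError,
)

GA_MIN_WEEKS = 12.0
GA_MAX_WEEKS = 43.0

__all__ = [
    "BiometrySet",
    "EFWEquation",
    "GrowthStandard",
    "ZScoreModel",
    "MaternalProfile",
    "load_standard",
    "hadlock_efw",
    "efw_percentile",
    "fit_zscore_model",
    "ac_growth_velocity",
    "customised_percentile",
    "birthweight_percentile",
    "mm_to_cm",
    "cm_to_mm",
]


def mm_to_cm(x):
    return np.asarray(x, dtype=float) / 10.0


def cm_to_mm(x):
    return np.asarray(x, dtype=float) * 10.0


@dataclass(frozen=True)
class BiometrySet:
    """One scan's biometry in centimetres at a decimal gestational age."""

    ga_weeks: float
    bpd_cm: float | None = None
    hc_cm: float | None = None
    ac_cm: float | None = None
    fl_cm: float | None = None

    def __post_init__(self) -> None:
        if not (GA_MIN_WEEKS <= self.ga_weeks <= GA_MAX_WEEKS):
            raise DomainError(
                f"ga_weeks={self.ga_weeks} outside [{GA_MIN_WEEKS}, {GA_MAX_WEEKS}]"
            )
        for name in ("bpd_cm", "hc_cm", "ac_cm", "fl_cm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DomainError(f"{name}={v} must be strictly positive")

    def as_dict(self) -> dict[str, float | None]:
        return {
            "bpd_cm": self.bpd_cm,
            "hc_cm": self.hc_cm,
            "ac_cm": self.ac_cm,
            "fl_cm": self.fl_cm,
        }


@dataclass(frozen=True)
class MaternalProfile:
    """Maternal characteristics used by the customised-centile surrogate."""

    height_cm: float
    weight_kg: float
    age_years: float | None = None
    ethnicity: str = "white"
    parity: int = 0
    smoker: bool = False
    diabetes: str = "none"

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2


# ---------------------------------------------------------------------------
# standards registry
# ---------------------------------------------------------------------------

_STANDARDS_DIR = resources.files("popscreen") / "standards"


def _read_registry_json(name_or_path: str | Path) -> dict:
    p = Path(name_or_path)
    if p.suffix == ".json" and p.exists():
        return json.loads(p.read_text())
    candidate = _STANDARDS_DIR / f"{name_or_path}.json"
    try:
        return json.loads(candidate.read_text())
    except FileNotFoundError:
        raise ConfigurationError(f"no registered standard named {name_or_path!r}")


@dataclass(frozen=True)
class EFWEquation:
    """A log10-polynomial EFW equation (Hadlock family).

    log10(weight g) = intercept + sum_k coef_k * prod(measures in vars_k),
    measures in cm.
    """

    name: str
    citation: str
    intercept: float
    terms: tuple[tuple[float, tuple[str, ...]], ...]
    required: tuple[str, ...]

    @classmethod
    def from_registry(cls, name_or_path: str | Path) -> "EFWEquation":
        d = _read_registry_json(name_or_path)
        if d.get("kind") != "efw_equation":
            raise ConfigurationError(f"{name_or_path!r} is not an efw_equation standard")
        return cls(
            name=d["name"],
            citation=d["citation"],
            intercept=float(d["intercept"]),
            terms=tuple((float(t["coef"]), tuple(t["vars"])) for t in d["terms"]),
            required=tuple(d["required"]),
        )

    def log10_weight(self, measures: Mapping[str, np.ndarray | float]) -> np.ndarray:
        total = np.asarray(self.intercept, dtype=float)
        for coef, vars_ in self.terms:
            prod = coef
            for v in vars_:
                prod = prod * np.asarray(measures[v], dtype=float)
            total = total + prod
        return total

    def weight_g(self, measures: Mapping[str, np.ndarray | float]) -> np.ndarray:
        return 10.0 ** self.log10_weight(measures)

    def scale_to_weight(
        self, measures: Mapping[str, np.ndarray | float], target_g: np.ndarray | float
    ) -> np.ndarray:
        """Factor lambda so that the equation applied to lambda-scaled
        measures returns ``target_g``.

        Because every term involves one or two measures, log10(weight) is an
        exact quadratic in lambda; the root on the ascending branch (where
        EFW increases with size) is returned.  Used by the cohort generator
        to impose a target EFW on a biometry profile.
        """
        a = np.zeros(np.broadcast(*[np.asarray(measures[k], float) for k in self.required]).shape)
        b = np.zeros_like(a)
        for coef, vars_ in self.terms:
            prod = coef
            for v in vars_:
                prod = prod * np.asarray(measures[v], dtype=float)
            if len(vars_) == 2:
                a = a + prod
            elif len(vars_) == 1:
                b = b + prod
            else:  # pragma: no cover - registry files use 1- or 2-var terms
                raise ConfigurationError("terms must involve one or two measures")
        c = self.intercept - np.log10(np.asarray(target_g, dtype=float))
        disc = b * b - 4.0 * a * c
        if np.any(disc < 0):
            raise DomainError("target weight unreachable by uniform scaling")
        sq = np.sqrt(disc)
        r1 = (-b + sq) / (2.0 * a)
        r2 = (-b - sq) / (2.0 * a)
        ascending1 = 2.0 * a * r1 + b > 0
        return np.where(ascending1, r1, r2)


def hadlock_efw(b: BiometrySet, equation: str | EFWEquation = "hadlock_efw_hc_ac_fl") -> float:
    """Estimated fetal weight in grams from one biometry set.

    The default is the three-parameter HC/AC/FL model; the BPD-inclusive
    four-parameter variant is selectable via ``equation``.
    """
    eq = equation if isinstance(equation, EFWEquation) else EFWEquation.from_registry(equation)
    measures = b.as_dict()
    for name in eq.required:
        v = measures.get(name)
        if v is None:
            raise MissingInputError(f"{eq.name} requires {name}")
        if not v > 0:
            raise DomainError(f"{name}={v} must be strictly positive")
    return float(eq.weight_g({k: measures[k] for k in eq.required}))


# ---------------------------------------------------------------------------
# growth standards (location/scale references)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthStandard:
    """A reference mapping GA (and sex, where applicable) -> location/scale.

    ``working_scale`` is the scale on which the normal model applies:
    ``natural`` (percentile from (x - loc)/scale) or ``log`` (applied to
    ln x).  Supported kinds: ``efw_for_ga`` (parametric) and
    ``birthweight_for_ga_sex`` (tabulated per week and sex, linearly
    interpolated in GA).
    """

    name: str
    kind: str
    working_scale: str
    ga_domain: tuple[float, float]
    _location: Callable[[np.ndarray, np.ndarray | None], np.ndarray] = field(repr=False)
    _scale: Callable[[np.ndarray, np.ndarray | None], np.ndarray] = field(repr=False)
    citation: str = ""

    def location(self, ga_weeks, sex=None) -> np.ndarray:
        self._check_domain(ga_weeks)
        return self._location(np.asarray(ga_weeks, dtype=float), sex)

    def scale(self, ga_weeks, sex=None) -> np.ndarray:
        self._check_domain(ga_weeks)
        return self._scale(np.asarray(ga_weeks, dtype=float), sex)

    def _check_domain(self, ga_weeks) -> None:
        ga = np.asarray(ga_weeks, dtype=float)
        lo, hi = self.ga_domain
        if np.any((ga < lo) | (ga > hi)):
            raise RangeError(
                f"gestational age outside the {self.name} domain [{lo}, {hi}] weeks"
            )

    def percentile(self, value, ga_weeks, sex=None) -> np.ndarray:
        loc = self.location(ga_weeks, sex)
        sc = self.scale(ga_weeks, sex)
        x = np.asarray(value, dtype=float)
        if self.working_scale == "log":
            z = (np.log(x) - np.log(loc)) / sc
        else:
            z = (x - loc) / sc
        return 100.0 * stats.norm.cdf(z)

    def quantile(self, percentile, ga_weeks, sex=None) -> np.ndarray:
        z = stats.norm.ppf(np.asarray(percentile, dtype=float) / 100.0)
        loc = self.location(ga_weeks, sex)
        sc = self.scale(ga_weeks, sex)
        if self.working_scale == "log":
            return np.exp(np.log(loc) + z * sc)
        return loc + z * sc

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_registry(cls, name_or_path: str | Path) -> "GrowthStandard":
        d = _read_registry_json(name_or_path)
        if d.get("kind") != "efw_for_ga":
            raise ConfigurationError(f"{name_or_path!r} is not an efw_for_ga standard")
        loc_spec, sc_spec = d["location"], d["scale"]
        if loc_spec["type"] != "exp_poly":  # pragma: no cover - single shipped form
            raise ConfigurationError(f"unknown location type {loc_spec['type']!r}")
        coeffs = np.asarray(loc_spec["coefficients"], dtype=float)

        def location(ga, sex):
            return np.exp(np.polyval(coeffs[::-1], ga))

        if sc_spec["type"] == "proportional":
            frac = float(sc_spec["fraction"])

            def scale(ga, sex):
                return frac * location(ga, sex)

        else:  # pragma: no cover
            raise ConfigurationError(f"unknown scale type {sc_spec['type']!r}")

        return cls(
            name=d["name"],
            kind="efw_for_ga",
            working_scale=d["working_scale"],
            ga_domain=tuple(d["ga_domain"]),
            _location=location,
            _scale=scale,
            citation=d.get("citation", ""),
        )

    @classmethod
    def from_birthweight_table(
        cls, path_or_df: str | Path | pd.DataFrame, name: str = "birthweight_reference"
    ) -> "GrowthStandard":
        """Build a ``birthweight_for_ga_sex`` standard from a CSV / frame with
        columns ``ga_weeks, sex, mean_g, sd_g``; GA interpolated linearly
        between tabulated weeks."""
        if isinstance(path_or_df, pd.DataFrame):
            df = path_or_df.copy()
        else:
            p = Path(path_or_df)
            if not p.exists():
                candidate = _STANDARDS_DIR / str(path_or_df)
                try:
                    df = pd.read_csv(candidate.open())
                except FileNotFoundError:
                    raise ConfigurationError(f"no birthweight reference at {path_or_df!r}")
            else:
                df = pd.read_csv(p)
        required = {"ga_weeks", "sex", "mean_g", "sd_g"}
        if not required.issubset(df.columns):
            raise ConfigurationError(f"birthweight table needs columns {sorted(required)}")
        tabs = {
            sex: g.sort_values("ga_weeks")[["ga_weeks", "mean_g", "sd_g"]].to_numpy(float)
            for sex, g in df.groupby("sex")
        }
        lo = max(t[0, 0] for t in tabs.values())
        hi = min(t[-1, 0] for t in tabs.values())

        def _interp(ga, sex, col):
            scalar = np.ndim(ga) == 0 and np.ndim(sex) == 0
            ga = np.atleast_1d(np.asarray(ga, dtype=float))
            sex_arr = np.broadcast_to(np.atleast_1d(np.asarray(sex, dtype=object)), ga.shape)
            out = np.empty_like(ga)
            for s, tab in tabs.items():
                m = sex_arr == s
                if m.any():
                    out[m] = np.interp(ga[m], tab[:, 0], tab[:, col])
            unknown = ~np.isin(sex_arr, list(tabs))
            if unknown.any():
                raise ConfigurationError(
                    f"sex value(s) {set(sex_arr[unknown])} not in reference table"
                )
            return out[0] if scalar else out

        return cls(
            name=name,
            kind="birthweight_for_ga_sex",
            working_scale="natural",
            ga_domain=(float(lo), float(hi)),
            _location=lambda ga, sex: _interp(ga, sex, 1),
            _scale=lambda ga, sex: _interp(ga, sex, 2),
        )


def load_standard(name_or_path: str | Path):
    """Load any registered standard by name or path.

    Returns an :class:`EFWEquation`, :class:`GrowthStandard` or the raw
    customisation-coefficient dict depending on the file's ``kind``.
    """
    p = Path(str(name_or_path))
    if p.suffix == ".csv":
        return GrowthStandard.from_birthweight_table(name_or_path)
    d = _read_registry_json(name_or_path)
    kind = d.get("kind")
    if kind == "efw_equation":
        return EFWEquation.from_registry(name_or_path)
    if kind == "efw_for_ga":
        return GrowthStandard.from_registry(name_or_path)
    if kind == "customised_efw":
        return d
    raise ConfigurationError(f"unknown standard kind {kind!r}")


def efw_percentile(efw_g, ga_weeks, std: GrowthStandard):
    """EFW percentile in (0, 100) against an ``efw_for_ga`` standard."""
    if std.kind != "efw_for_ga":
        raise ConfigurationError("efw_percentile requires an efw_for_ga standard")
    return std.percentile(efw_g, ga_weeks)


def birthweight_percentile(bw_g, ga_weeks, sex, std: GrowthStandard):
    """Birthweight percentile for GA and sex against a tabulated reference."""
    if std.kind != "birthweight_for_ga_sex":
        raise ConfigurationError(
            "birthweight_percentile requires a birthweight_for_ga_sex standard"
        )
    return std.percentile(bw_g, ga_weeks, sex)


# ---------------------------------------------------------------------------
# gestational-age-adjusted Z-scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZScoreModel:
    """Within-cohort GA-adjusted Z-score model for one measurement.

    Mean curve: least-squares polynomial of the measure on GA.  SD curve:
    least-squares polynomial of absolute residuals on GA scaled by
    sqrt(pi/2) (the half-normal correction), which is smoother and more
    stable than binned SDs at cohort size.
    """

    mean_coeffs: np.ndarray
    sd_coeffs: np.ndarray
    ga_range: tuple[float, float]
    degree: int
    n_fit: int
    cohort_id: str = ""

    def mean(self, ga_weeks) -> np.ndarray:
        return np.polyval(self.mean_coeffs, np.asarray(ga_weeks, dtype=float))

    def sd(self, ga_weeks) -> np.ndarray:
        return np.polyval(self.sd_coeffs, np.asarray(ga_weeks, dtype=float))

    def zscore(self, ga_weeks, value) -> np.ndarray:
        return (np.asarray(value, dtype=float) - self.mean(ga_weeks)) / self.sd(ga_weeks)


def fit_zscore_model(
    ga_weeks: Sequence[float],
    values: Sequence[float],
    degree: int = 2,
    cohort_id: str = "",
) -> ZScoreModel:
    """Fit a GA-adjusted Z-score model to cohort scans.

    Requires >= 100 observations spanning at least two weeks of GA; raises
    :class:`FitError` on degenerate designs or a nonpositive fitted SD curve
    anywhere on the fit range.
    """
    ga = np.asarray(ga_weeks, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(ga) & np.isfinite(y)
    ga, y = ga[ok], y[ok]
    if ga.size < 100:
        raise FitError(f"need >=100 observations to fit a Z-score model, got {ga.size}")
    span = ga.max() - ga.min()
    if span < 2.0:
        raise FitError(f"GA span {span:.2f} weeks too narrow (need >=2)")
    mean_coeffs = np.polyfit(ga, y, degree)
    resid = y - np.polyval(mean_coeffs, ga)
    sd_coeffs = np.polyfit(ga, np.abs(resid), degree) * math.sqrt(math.pi / 2.0)
    grid = np.linspace(ga.min(), ga.max(), 201)
    if np.any(np.polyval(sd_coeffs, grid) <= 0):
        raise FitError("fitted SD curve is not strictly positive on the fit range")
    return ZScoreModel(
        mean_coeffs=mean_coeffs,
        sd_coeffs=sd_coeffs,
        ga_range=(float(ga.min()), float(ga.max())),
        degree=degree,
        n_fit=int(ga.size),
        cohort_id=cohort_id,
    )


def ac_growth_velocity(z_20wk, z_last):
    """AC growth velocity: difference in GA-adjusted AC Z-score between the
    last scan before birth and the 20-week scan (z_last - z_20wk)."""
    z0 = np.asarray(z_20wk, dtype=float)
    z1 = np.asarray(z_last, dtype=float)
    if np.any(~np.isfinite(z0)) or np.any(~np.isfinite(z1)):
        raise MissingInputError("both the 20-week and last-scan AC Z-scores are required")
    return z1 - z0


# ---------------------------------------------------------------------------
# customised centiles (simplified surrogate)
# ---------------------------------------------------------------------------


def customised_percentile(
    efw_g,
    ga_weeks,
    profile: MaternalProfile,
    coefficients: str | Path | Mapping = "customisation_surrogate",
):
    """Customised EFW percentile from a pluggable coefficient file.

    The shipped default is a documented simplified surrogate (linear height,
    weight and ethnicity offsets around a term optimal weight), not the
    proprietary GROW coefficient set.  A term optimal weight is scaled by a
    fetal-weight proportion-of-term curve and the percentile comes from a
    proportional-SD normal model, as for the population percentile.
    """
    if isinstance(coefficients, (str, Path)):
        d = _read_registry_json(coefficients)
    else:
        d = dict(coefficients)
    if d.get("kind") != "customised_efw":
        raise ConfigurationError("customised_percentile requires a customised_efw file")
    eth = d["ethnicity_offsets_g"]
    if profile.ethnicity not in eth:
        raise ConfigurationError(f"no ethnicity offset for {profile.ethnicity!r}")
    tow = (
        float(d["base_term_weight_g"])
        + float(d["height_coef_g_per_cm"]) * (profile.height_cm - 163.0)
        + float(d["weight_coef_g_per_kg"]) * (profile.weight_kg - 64.0)
        + float(eth[profile.ethnicity])
    )
    curve = d["proportion_curve"]
    coeffs = np.asarray(curve["coefficients"], dtype=float)[::-1]
    term_ga = float(curve["term_ga"])
    prop = np.exp(np.polyval(coeffs, np.asarray(ga_weeks, dtype=float))) / np.exp(
        np.polyval(coeffs, term_ga)
    )
    expected = tow * prop
    cv = float(d["cv"])
    z = (np.asarray(efw_g, dtype=float) - expected) / (cv * expected)
    return 100.0 * stats.norm.cdf(z)
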