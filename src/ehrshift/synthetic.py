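"""Synthetic admission-level EHR cohorts with controllable temporal dataset shifts.

The generator emulates a hospital cohort observed over consecutive calendar
years: each admission carries demographics (age, gender, ethnicity), a list of
diagnosis/procedure codes grouped into clinical chapters, and a rare binary
in-hospital mortality outcome. Three kinds of temporal shift can be injected
around a changepoint year:

* covariate shift  — chapter prevalence vectors differ before/after,
* prior shift      — the target outcome prevalence p(y) steps,
* concept shift    — the outcome log-odds coefficients p(y|x) differ,

optionally together with a coding-system transition that switches the emitted
code dialect (numeric ICD-9-style before, alphanumeric ICD-10-style after)
while the underlying chapters stay the same.

Outcomes follow a logistic model ``logit p(y=1|x) = b_t + beta . x`` whose
intercept ``b_t`` is recalibrated per year by root finding so that the realized
marginal prevalence matches the configured ``prevalence_by_year``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigurationError

__all__ = [
    "CHAPTERS",
    "DIAGNOSIS_CHAPTERS",
    "PROCEDURE_CHAPTERS",
    "DemographicsSpec",
    "ConceptModel",
    "ShiftScenario",
    "AdmissionTable",
    "default_scenario",
    "generate_cohort",
    "default_code_map",
    "write_cohort",
    "read_scenario",
]

DIAGNOSIS_CHAPTERS: tuple[str, ...] = (
    "Infectious and parasitic diseases",
    "Neoplasms",
    "Endocrine nutritional and metabolic diseases",
    "Mental disorders",
    "Diseases of the nervous system",
    "Diseases of the circulatory system",
    "Diseases of the respiratory system",
    "Diseases of the digestive system",
    "Diseases of the genitourinary system",
    "Diseases of the musculoskeletal system",
    "Diseases of the skin",
    "Injury and poisoning",
    "Symptoms signs and abnormal findings",
    "Congenital and perinatal conditions",
)

PROCEDURE_CHAPTERS: tuple[str, ...] = (
    "Medical and surgical",
    "Imaging",
    "Laboratory",
    "Administration",
    "Extracorporeal or systemic assistance",
    "Measurement and monitoring",
    "Obstetrics",
    "Placement",
    "Osteopathic",
    "Other procedures",
)

CHAPTERS: tuple[str, ...] = DIAGNOSIS_CHAPTERS + PROCEDURE_CHAPTERS

# Fixed baseline Bernoulli prevalence per chapter (order follows CHAPTERS).
_BASE_RATES = np.array(
    [
        0.10, 0.18, 0.38, 0.14, 0.12, 0.45, 0.22, 0.20, 0.16, 0.15,
        0.08, 0.18, 0.30, 0.03,
        0.40, 0.12, 0.35, 0.25, 0.08, 0.20, 0.04, 0.10, 0.02, 0.50,
    ]
)

# Baseline outcome log-odds coefficients per chapter; zero for most chapters.
_BASE_COEFS = dict(
    zip(
        CHAPTERS,
        np.zeros(len(CHAPTERS)),
    )
)
_BASE_COEFS.update(
    {
        "Neoplasms": 0.7,
        "Diseases of the circulatory system": 0.9,
        "Diseases of the respiratory system": 0.6,
        "Injury and poisoning": 0.5,
        "Symptoms signs and abnormal findings": 0.4,
        "Laboratory": 0.3,
        "Extracorporeal or systemic assistance": 1.0,
        "Measurement and monitoring": 0.5,
    }
)

# Chapters whose prevalence moves by +/-0.3 in the covariate-shift presets;
# mirrors the redistribution pattern seen when a coding system is replaced.
_COVARIATE_SHIFT_DELTAS = {
    "Diseases of the circulatory system": -0.30,
    "Endocrine nutritional and metabolic diseases": -0.30,
    "Other procedures": -0.30,
    "Imaging": +0.30,
    "Extracorporeal or systemic assistance": +0.30,
}

# Coefficient changes in the concept-shift presets: the link between several
# chapters and mortality strengthens, weakens, or reverses after the changepoint.
_CONCEPT_SHIFT_COEFS_POST = {
    "Diseases of the circulatory system": 0.2,
    "Symptoms signs and abnormal findings": 1.4,
    "Administration": 1.2,
    "Extracorporeal or systemic assistance": -0.5,
    "Measurement and monitoring": -0.8,
}

DEFAULT_PREVALENCE = 0.0291  # rare in-hospital mortality outcome

_ETHNICITIES = ("White", "Black", "Hispanic", "Asian", "Other")


@dataclass(frozen=True)
class DemographicsSpec:
    """Age distribution and category probabilities for gender/ethnicity."""

    age_mean: float = 62.0
    age_sd: float = 17.0
    gender_probs: dict[str, float] = field(
        default_factory=lambda: {"F": 0.48, "M": 0.52}
    )
    ethnicity_probs: dict[str, float] = field(
        default_factory=lambda: dict(
            zip(_ETHNICITIES, (0.62, 0.14, 0.10, 0.06, 0.08))
        )
    )


@dataclass(frozen=True)
class ConceptModel:
    """Outcome log-odds model: intercept + chapter coefficients + age effect.

    ``age_coef`` applies to age standardized as (age - 60) / 15. The intercept
    is only a starting point; it is recalibrated per year to hit the target
    prevalence.
    """

    chapter_coefs: dict[str, float]
    age_coef: float = 0.6
    intercept: float = -4.0

    def coef_vector(self, chapters: tuple[str, ...]) -> np.ndarray:
        return np.array([self.chapter_coefs.get(c, 0.0) for c in chapters])


@dataclass(frozen=True)
class ShiftScenario:
    """Complete parameterization of one synthetic cohort."""

    start_year: int
    n_years: int
    n_per_year: int
    prevalence_by_year: tuple[float, ...]
    chapter_rates_pre: tuple[float, ...]
    chapter_rates_post: tuple[float, ...]
    concept_pre: ConceptModel
    concept_post: ConceptModel
    changepoint_year: int | None
    demographics: DemographicsSpec
    coding_transition: bool
    seed: int
    kind: str = "custom"

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ConfigurationError("scenario needs at least 2 years")
        if len(self.prevalence_by_year) != self.n_years:
            raise ConfigurationError(
                f"prevalence_by_year has length {len(self.prevalence_by_year)}, "
                f"expected n_years={self.n_years}"
            )
        for p in self.prevalence_by_year:
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"prevalence {p} outside (0, 1)")
        for rates in (self.chapter_rates_pre, self.chapter_rates_post):
            if len(rates) != len(CHAPTERS):
                raise ConfigurationError("chapter rate vector length mismatch")
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ConfigurationError("chapter rates must lie in [0, 1]")
        if self.changepoint_year is not None:
            lo, hi = self.start_year, self.start_year + self.n_years - 1
            if not lo < self.changepoint_year <= hi:
                raise ConfigurationError(
                    f"changepoint_year {self.changepoint_year} not strictly "
                    f"inside [{lo}, {hi}]"
                )

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    def is_post(self, year: int) -> bool:
        return self.changepoint_year is not None and year >= self.changepoint_year

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ShiftScenario":
        d = json.loads(text)
        d["concept_pre"] = ConceptModel(**d["concept_pre"])
        d["concept_post"] = ConceptModel(**d["concept_post"])
        d["demographics"] = DemographicsSpec(**d["demographics"])
        d["prevalence_by_year"] = tuple(d["prevalence_by_year"])
        d["chapter_rates_pre"] = tuple(d["chapter_rates_pre"])
        d["chapter_rates_post"] = tuple(d["chapter_rates_post"])
        return cls(**d)


@dataclass
class AdmissionTable:
    """Raw cohort: one admissions row per stay plus a long-format code table.

    ``admissions`` columns: admission_id, year, age, gender, ethnicity, outcome.
    ``codes`` columns: admission_id, coding_system, axis, code.
    """

    admissions: pd.DataFrame
    codes: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        """Value-level equality: dtype width (e.g. int8 vs int64) is ignored."""
        if not isinstance(other, AdmissionTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.admissions, other.admissions, check_dtype=False
            )
            pd.testing.assert_frame_equal(self.codes, other.codes, check_dtype=False)
        except AssertionError:
            return False
        return True


_VALID_KINDS = ("null", "covariate", "prior", "concept", "combined")


def default_scenario(
    kind: str,
    n_per_year: int = 2000,
    seed: int = 0,
    start_year: int = 2008,
    n_years: int = 12,
) -> ShiftScenario:
    """Preset scenarios mirroring the dataset-shift taxonomy.

    ``null`` has identical pre/post parameters and no changepoint; the other
    kinds inject exactly one (or, for ``combined``, covariate+concept) shift at
    the changepoint year placed at the middle of the series.
    """
    if kind not in _VALID_KINDS:
        raise ConfigurationError(
            f"unknown scenario kind {kind!r}; expected one of {_VALID_KINDS}"
        )
    if n_per_year < 50:
        raise ConfigurationError("n_per_year must be at least 50")

    changepoint = start_year + n_years // 2
    rates_pre = tuple(_BASE_RATES)
    rates_post = list(_BASE_RATES)
    prevalence = [DEFAULT_PREVALENCE] * n_years
    concept_pre = ConceptModel(chapter_coefs=dict(_BASE_COEFS))
    concept_post = concept_pre

    if kind in ("covariate", "combined"):
        for chapter, delta in _COVARIATE_SHIFT_DELTAS.items():
            idx = CHAPTERS.index(chapter)
            rates_post[idx] = float(np.clip(rates_post[idx] + delta, 0.01, 0.99))
    if kind in ("concept", "combined"):
        coefs_post = dict(_BASE_COEFS)
        coefs_post.update(_CONCEPT_SHIFT_COEFS_POST)
        concept_post = ConceptModel(chapter_coefs=coefs_post)
    if kind == "prior":
        for t, year in enumerate(range(start_year, start_year + n_years)):
            if year >= changepoint:
                prevalence[t] = 0.06

    return ShiftScenario(
        start_year=start_year,
        n_years=n_years,
        n_per_year=n_per_year,
        prevalence_by_year=tuple(prevalence),
        chapter_rates_pre=rates_pre,
        chapter_rates_post=tuple(rates_post),
        concept_pre=concept_pre,
        concept_post=concept_post,
        changepoint_year=None if kind == "null" else changepoint,
        demographics=DemographicsSpec(),
        coding_transition=kind != "null",
        seed=seed,
        kind=kind,
    )


def _icd9_prefix(axis: str, chapter_idx: int) -> str:
    if axis == "diagnosis":
        return str(140 + 5 * chapter_idx)  # 3-digit numeric blocks
    return str(10 + 7 * chapter_idx)  # 2-digit procedure blocks


def _icd10_prefix(axis: str, chapter_idx: int) -> str:
    if axis == "diagnosis":
        return chr(ord("A") + chapter_idx) + "0"
    return chr(ord("A") + chapter_idx) + "P"


def default_code_map() -> pd.DataFrame:
    """Prefix-based code→chapter map covering both emitted code dialects.

    Returns a frame with columns coding_system, axis, code, chapter; codes are
    dot-free prefixes resolved by longest-prefix match downstream.
    """
    rows = []
    for ci, chapter in enumerate(CHAPTERS):
        axis = "diagnosis" if ci < len(DIAGNOSIS_CHAPTERS) else "procedure"
        ai = ci if axis == "diagnosis" else ci - len(DIAGNOSIS_CHAPTERS)
        rows.append(("ICD-9", axis, _icd9_prefix(axis, ai), chapter))
        rows.append(("ICD-10", axis, _icd10_prefix(axis, ai), chapter))
    return pd.DataFrame(rows, columns=["coding_system", "axis", "code", "chapter"])


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Solve mean(sigmoid(b + eta)) = target for the intercept b."""

    def gap(b: float) -> float:
        return float(np.mean(expit(b + eta))) - target

    lo, hi = -30.0, 10.0
    if gap(lo) > 0 or gap(hi) < 0:  # pragma: no cover - requires extreme coefs
        raise ConfigurationError("prevalence target unreachable for this model")
    return float(brentq(gap, lo, hi, xtol=1e-12))


def generate_cohort(scenario: ShiftScenario) -> AdmissionTable:
    """Simulate the full cohort described by ``scenario``.

    One ``numpy`` Generator seeded from ``scenario.seed`` drives every draw, so
    identical scenarios produce byte-identical tables.
    """
    rng = np.random.default_rng(scenario.seed)
    n_chapters = len(CHAPTERS)
    demo = scenario.demographics

    for rates, concept in (
        (scenario.chapter_rates_pre, scenario.concept_pre),
        (scenario.chapter_rates_post, scenario.concept_post),
    ):
        active = [
            c for c, v in concept.chapter_coefs.items() if v != 0.0
        ]
        if active and all(rates[CHAPTERS.index(c)] == 0.0 for c in active):
            raise ConfigurationError(
                "degenerate scenario: outcome coefficients act only on "
                "chapters with zero prevalence"
            )

    genders = list(demo.gender_probs)
    gender_p = np.array([demo.gender_probs[g] for g in genders])
    ethnicities = list(demo.ethnicity_probs)
    ethnicity_p = np.array([demo.ethnicity_probs[e] for e in ethnicities])

    adm_rows: list[pd.DataFrame] = []
    code_rows: list[pd.DataFrame] = []
    for t, year in enumerate(scenario.years):
        post = scenario.is_post(year)
        rates = np.asarray(
            scenario.chapter_rates_post if post else scenario.chapter_rates_pre
        )
        concept = scenario.concept_post if post else scenario.concept_pre
        n = scenario.n_per_year

        age = np.clip(rng.normal(demo.age_mean, demo.age_sd, size=n), 18.0, 100.0)
        gender = rng.choice(genders, size=n, p=gender_p)
        ethnicity = rng.choice(ethnicities, size=n, p=ethnicity_p)
        x = (rng.random((n, n_chapters)) < rates).astype(np.int8)

        eta = x @ concept.coef_vector(CHAPTERS) + concept.age_coef * (age - 60.0) / 15.0
        b = _calibrate_intercept(eta, scenario.prevalence_by_year[t])
        outcome = (rng.random(n) < expit(b + eta)).astype(np.int8)

        ids = np.array([f"A{year}{i:06d}" for i in range(n)])
        adm_rows.append(
            pd.DataFrame(
                {
                    "admission_id": ids,
                    "year": year,
                    "age": np.round(age, 1),
                    "gender": gender,
                    "ethnicity": ethnicity,
                    "outcome": outcome,
                }
            )
        )

        dialect_post = post and scenario.coding_transition
        system = "ICD-10" if dialect_post else "ICD-9"
        adm_idx, chap_idx = np.nonzero(x)
        # one to three concrete codes per active chapter
        n_codes = rng.integers(1, 4, size=adm_idx.size)
        rep_adm = np.repeat(adm_idx, n_codes)
        rep_chap = np.repeat(chap_idx, n_codes)
        suffix = rng.integers(0, 10, size=rep_adm.size)
        prefixes = np.array(
            [
                (_icd10_prefix if dialect_post else _icd9_prefix)(
                    "diagnosis" if c < len(DIAGNOSIS_CHAPTERS) else "procedure",
                    c if c < len(DIAGNOSIS_CHAPTERS) else c - len(DIAGNOSIS_CHAPTERS),
                )
                for c in range(n_chapters)
            ]
        )
        code_rows.append(
            pd.DataFrame(
                {
                    "admission_id": ids[rep_adm],
                    "coding_system": system,
                    "axis": np.where(
                        rep_chap < len(DIAGNOSIS_CHAPTERS), "diagnosis", "procedure"
                    ),
                    "code": pd.Series(prefixes[rep_chap]) + suffix.astype(str),
                }
            )
        )

    admissions = pd.concat(adm_rows, ignore_index=True)
    codes = pd.concat(code_rows, ignore_index=True)
    return AdmissionTable(admissions=admissions, codes=codes)


def write_cohort(table: AdmissionTable, scenario: ShiftScenario, outdir: Path) -> dict:
    """Write admissions.csv, codes.csv and scenario.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "admissions": outdir / "admissions.csv",
        "codes": outdir / "codes.csv",
        "scenario": outdir / "scenario.json",
    }
    table.admissions.to_csv(paths["admissions"], index=False)
    table.codes.to_csv(paths["codes"], index=False)
    paths["scenario"].write_text(scenario.to_json())
    return {k: str(v) for k, v in paths.items()}


def read_scenario(path: Path) -> ShiftScenario:
    return ShiftScenario.from_json(Path(path).read_text())
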