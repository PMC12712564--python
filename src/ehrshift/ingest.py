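"""Read admission-level data, harmonize codes into chapters, build features.

The harmonization step is what makes interyear comparison possible when the
coding system changes mid-series: raw ICD-9/ICD-10 codes are collapsed onto a
common set of merged chapters through a user-supplied mapping file, and each
chapter becomes a binary indicator (1 iff the admission has at least one code
mapping to it). Demographics are one-hot encoded; age stays numeric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    InsufficientBatchesError,
    MappingConflictError,
    SchemaError,
    ValidationError,
)
from .synthetic import AdmissionTable

logger = logging.getLogger(__name__)

__all__ = [
    "CodeMap",
    "read_admissions",
    "load_code_map",
    "harmonize_codes",
    "batch_by_year",
    "feature_columns",
]

_ADMISSION_COLUMNS = ("admission_id", "year", "age", "gender", "ethnicity", "outcome")
_CODE_COLUMNS = ("admission_id", "coding_system", "axis", "code")
_MAP_COLUMNS = ("coding_system", "axis", "code", "chapter")

#: Columns of a FeatureTable that are not features.
RESERVED_COLUMNS = ("admission_id", "year", "outcome")


@dataclass(frozen=True)
class CodeMap:
    """Validated code→chapter mapping with exact and prefix entries.

    Codes in the mapping file are dot-free strings; a data code matches the
    longest mapping entry that prefixes it within its (coding_system, axis).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.table.duplicated(subset=["coding_system", "axis", "code"])
        if dup.any():
            conflicts = self.table.loc[dup, "code"].unique().tolist()
            raise MappingConflictError(
                f"codes mapped to multiple chapters: {conflicts}"
            )
        if (self.table["chapter"].astype(str).str.len() == 0).any():
            raise MappingConflictError("empty chapter label in code map")

    @property
    def chapters(self) -> list[str]:
        return sorted(self.table["chapter"].unique())

    def lookup_table(self) -> dict[tuple[str, str], dict[str, str]]:
        out: dict[tuple[str, str], dict[str, str]] = {}
        for (system, axis), grp in self.table.groupby(["coding_system", "axis"]):
            out[(system, axis)] = dict(zip(grp["code"], grp["chapter"]))
        return out


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def read_admissions(admissions_path: Path, codes_path: Path) -> AdmissionTable:
    """Load and validate the two cohort files written by the generator.

    Applies the adult inclusion criterion (age >= 18); excluded counts are
    logged. Code rows must all join to a retained admission.
    """
    admissions = pd.read_csv(admissions_path)
    codes = pd.read_csv(codes_path, dtype={"code": str})
    _require_columns(admissions, _ADMISSION_COLUMNS, "admissions table")
    _require_columns(codes, _CODE_COLUMNS, "codes table")

    if admissions["admission_id"].duplicated().any():
        raise ValidationError("duplicate admission_id values")
    if not admissions["outcome"].isin([0, 1]).all():
        raise ValidationError("outcome must be binary 0/1")

    minors = admissions["age"] < 18
    if minors.any():
        logger.info("excluding %d admissions with age < 18", int(minors.sum()))
        dropped = set(admissions.loc[minors, "admission_id"])
        admissions = admissions.loc[~minors].reset_index(drop=True)
        codes = codes.loc[~codes["admission_id"].isin(dropped)].reset_index(drop=True)

    orphans = set(codes["admission_id"]) - set(admissions["admission_id"])
    if orphans:
        sample = sorted(orphans)[:10]
        raise ValidationError(f"code rows reference unknown admission_ids: {sample}")
    return AdmissionTable(admissions=admissions, codes=codes)


def load_code_map(path: Path) -> CodeMap:
    try:
        table = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"code map {path} is empty") from exc
    _require_columns(table, _MAP_COLUMNS, "code map")
    if len(table) == 0:
        raise SchemaError(f"code map {path} has no rows")
    return CodeMap(table=table[list(_MAP_COLUMNS)].copy())


def _resolve(code: str, entries: dict[str, str]) -> str | None:
    """Longest-prefix resolution: exact match first, then shrink from the right."""
    for end in range(len(code), 0, -1):
        chapter = entries.get(code[:end])
        if chapter is not None:
            return chapter
    return None


def harmonize_codes(
    table: AdmissionTable,
    code_map: CodeMap,
    unmapped_policy: str = "error",
) -> pd.DataFrame:
    """Collapse codes onto chapter indicators and assemble the feature table.

    Returns one row per admission with columns: admission_id, year, outcome,
    one binary column per chapter, numeric age, and one-hot gender/ethnicity.
    ``unmapped_policy`` is ``"error"`` (raise, listing distinct unmapped codes)
    or ``"bucket"`` (route them to an ``"Unmapped"`` chapter).
    """
    if unmapped_policy not in ("error", "bucket"):
        raise ValueError(f"unknown unmapped_policy {unmapped_policy!r}")
    lookup = code_map.lookup_table()

    codes = table.codes
    resolved = pd.Series(index=codes.index, dtype=object)
    for (system, axis), grp in codes.groupby(["coding_system", "axis"]):
        entries = lookup.get((system, axis), {})
        uniq = {c: _resolve(c, entries) for c in grp["code"].unique()}
        resolved.loc[grp.index] = grp["code"].map(uniq)

    unmapped = resolved.isna()
    if unmapped.any():
        if unmapped_policy == "error":
            bad = sorted(codes.loc[unmapped, "code"].unique())[:20]
            raise ValidationError(f"unmapped codes under policy=error: {bad}")
        resolved = resolved.fillna("Unmapped")

    chapters = sorted(set(code_map.chapters) | set(resolved.unique()))
    adm_index = pd.Index(table.admissions["admission_id"])
    row_pos = adm_index.get_indexer(codes["admission_id"])
    col_pos = pd.Index(chapters).get_indexer(resolved)
    matrix = np.zeros((len(adm_index), len(chapters)), dtype="int8")
    matrix[row_pos, col_pos] = 1  # multiplicity collapses to a binary indicator
    indicators = pd.DataFrame(
        matrix, columns=[f"chapter::{c}" for c in chapters]
    )

    demo = pd.get_dummies(
        table.admissions[["gender", "ethnicity"]], prefix_sep="::", dtype="int8"
    )
    features = pd.concat(
        [
            table.admissions[["admission_id", "year", "outcome"]].reset_index(drop=True),
            indicators.reset_index(drop=True),
            table.admissions[["age"]].reset_index(drop=True),
            demo.reset_index(drop=True),
        ],
        axis=1,
    )
    return features


def feature_columns(features: pd.DataFrame) -> list[str]:
    """Columns of a FeatureTable that are model inputs."""
    return [c for c in features.columns if c not in RESERVED_COLUMNS]


def batch_by_year(features: pd.DataFrame) -> list[tuple[int, pd.DataFrame]]:
    """Partition a FeatureTable into per-year batches, ascending by year.

    Only observed years appear; a single-year table is an error because no
    temporal comparison is possible.
    """
    years = sorted(features["year"].unique())
    if len(years) < 2:
        raise InsufficientBatchesError(
            f"need at least 2 distinct years, found {years}"
        )
    return [
        (int(y), features.loc[features["year"] == y].reset_index(drop=True))
        for y in years
    ]
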