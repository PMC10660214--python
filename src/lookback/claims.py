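"""Claims data model: reading, cleaning, code harmonization, utilization summaries.

The canonical in-memory container for a claims stream is a pandas
:class:`~pandas.DataFrame` with one row per claim and the following columns
(the "claims schema"):

``patient_id``
    Opaque string identifier.
``sex``
    ``"male"``, ``"female"`` or missing (``NaN``).
``birth_date``
    ``datetime64[ns]``; may be ``NaT``.
``claim_type``
    ``"inpatient"`` or ``"outpatient"``. An inpatient stay is one record
    dated by its admission date.
``service_date``
    ``datetime64[ns]``; for inpatient claims, the admission date.
``diagnosis_codes``
    ``";"``-joined ICD-10 (or local dialect) code strings; empty string
    means no recorded diagnosis.

Optional pass-through columns: ``insurance_type``, ``expense_total``,
``expense_out_of_pocket``, ``expense_reimbursed``.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CORE_COLUMNS = [
    "patient_id",
    "sex",
    "birth_date",
    "claim_type",
    "service_date",
    "diagnosis_codes",
]
OPTIONAL_COLUMNS = [
    "insurance_type",
    "expense_total",
    "expense_out_of_pocket",
    "expense_reimbursed",
]

CODE_SEP = ";"

#: ICD-10 shape: letter + 2 digits, optional subcode after a dot.
ICD10_PATTERN = re.compile(r"^[A-Z]\d{2}(\.\w+)?$")


class ClaimsConfigError(ValueError):
    """Raised when an input file does not match the declared dialect."""


@dataclass(frozen=True)
class ClaimsDialect:
    """Column/delimiter configuration for delimited claims files."""

    delimiter: str = ","
    date_format: str = "%Y-%m-%d"
    #: mapping canonical column name -> column name in the file
    columns: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in CORE_COLUMNS}
    )

    def file_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


DEFAULT_DIALECT = ClaimsDialect()


class CodePredicate:
    """Prefix-based diagnosis predicate over ICD-10 codes.

    A claim matches if any of its diagnosis codes starts with one of the
    configured prefixes, so e.g. ``E11.9`` matches prefix ``E11``.
    """

    def __init__(self, prefixes: Iterable[str]):
        self.prefixes = tuple(prefixes)
        if not self.prefixes:
            raise ValueError("at least one code prefix required")
        escaped = "|".join(re.escape(p) for p in self.prefixes)
        self._regex = re.compile(rf"(?:^|{CODE_SEP})(?:{escaped})")

    def __call__(self, code: str) -> bool:
        return any(code.startswith(p) for p in self.prefixes)

    def mask(self, joined_codes: pd.Series) -> pd.Series:
        """Vectorized match over a Series of ";"-joined code strings."""
        return joined_codes.fillna("").str.contains(self._regex)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CodePredicate(prefixes={self.prefixes!r})"


#: Diabetes mellitus, ICD-10 E10-E14 (any subcode).
DIABETES = CodePredicate(("E10", "E11", "E12", "E13", "E14"))


@dataclass(frozen=True)
class CleaningReport:
    """Exclusion accounting for :func:`clean_claims`.

    A record missing both sex and diagnosis is counted once, under sex
    (filters are applied in that order).
    """

    n_input: int
    n_removed_missing_sex: int
    n_removed_missing_diagnosis: int
    n_output: int

    def __post_init__(self) -> None:
        expected = (
            self.n_input
            - self.n_removed_missing_sex
            - self.n_removed_missing_diagnosis
        )
        if self.n_output != expected:
            raise ValueError(
                f"cleaning counts do not reconcile: {self.n_output} != {expected}"
            )


class ReadResult(NamedTuple):
    claims: pd.DataFrame
    rejects: pd.DataFrame  # columns: line, reason


def read_claims(path, dialect: ClaimsDialect = DEFAULT_DIALECT) -> ReadResult:
    """Read a delimited claims file into the claims schema.

    Unparseable rows (bad or missing service date, missing patient id) are
    not silently dropped: they are collected into ``rejects`` with their
    1-based file line number.
    """
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    missing = [
        dialect.file_column(c) for c in CORE_COLUMNS
        if dialect.file_column(c) not in raw.columns
    ]
    if missing:
        raise ClaimsConfigError(f"missing mandatory column(s): {missing}")

    rename = {dialect.file_column(c): c for c in CORE_COLUMNS + OPTIONAL_COLUMNS}
    df = raw.rename(columns=rename)
    keep = [c for c in CORE_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].copy()

    service = pd.to_datetime(
        df["service_date"].replace("", None), format=dialect.date_format, errors="coerce"
    )
    birth = pd.to_datetime(
        df["birth_date"].replace("", None), format=dialect.date_format, errors="coerce"
    )
    bad_service = service.isna()
    bad_id = df["patient_id"].str.strip() == ""
    bad = bad_service | bad_id

    rejects = pd.DataFrame(
        {
            # +2: 1-based lines, header on line 1
            "line": df.index[bad] + 2,
            "reason": np.where(
                bad_id[bad], "missing patient_id", "unparseable service_date"
            ),
        }
    ).reset_index(drop=True)

    df = df.loc[~bad].copy()
    df["service_date"] = service[~bad]
    df["birth_date"] = birth[~bad]
    df["sex"] = df["sex"].replace("", np.nan)
    for col in ("expense_total", "expense_out_of_pocket", "expense_reimbursed"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
    return ReadResult(df.reset_index(drop=True), rejects)


def write_claims(df: pd.DataFrame, path, dialect: ClaimsDialect = DEFAULT_DIALECT) -> None:
    """Write claims back to delimited text, round-trippable by :func:`read_claims`."""
    out = df.copy()
    inverse = {c: dialect.file_column(c) for c in out.columns}
    for col in ("service_date", "birth_date"):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime(dialect.date_format)
    out.rename(columns=inverse).to_csv(path, sep=dialect.delimiter, index=False)


def clean_claims(df: pd.DataFrame) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop records with critical missing information.

    Removes, in order, records with missing sex and records with no
    diagnosis code; returns the cleaned frame and a reconciled
    :class:`CleaningReport`.
    """
    n_input = len(df)
    missing_sex = df["sex"].isna() | (df["sex"].astype(str).str.strip() == "")
    after_sex = df.loc[~missing_sex]
    missing_dx = after_sex["diagnosis_codes"].isna() | (
        after_sex["diagnosis_codes"].astype(str).str.strip() == ""
    )
    out = after_sex.loc[~missing_dx].reset_index(drop=True)
    report = CleaningReport(
        n_input=n_input,
        n_removed_missing_sex=int(missing_sex.sum()),
        n_removed_missing_diagnosis=int(missing_dx.sum()),
        n_output=len(out),
    )
    return out, report


def read_code_map(path) -> dict[str, str]:
    """Read a 2-column CSV (local code, ICD-10 code) into a mapping.

    Warns about target codes that do not look like ICD-10.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ClaimsConfigError("code map needs two columns: local code, ICD-10 code")
    mapping = dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))
    bad = [v for v in mapping.values() if not ICD10_PATTERN.match(v)]
    if bad:
        logger.warning("code map targets not ICD-10-shaped: %s", sorted(set(bad))[:10])
    return mapping


def map_codes(
    df: pd.DataFrame, code_map: Mapping[str, str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Harmonize diagnosis codes to ICD-10 through a local-code mapping.

    Codes present in ``code_map`` are replaced; codes absent from the map
    pass through unchanged and are tallied (returned, and logged as a
    warning). An empty map is the identity.
    """
    unmapped: Counter[str] = Counter()

    def _map_joined(joined: str) -> str:
        if not joined:
            return joined
        out = []
        for code in joined.split(CODE_SEP):
            if code in code_map:
                out.append(code_map[code])
            else:
                if code_map:
                    unmapped[code] += 1
                out.append(code)
        return CODE_SEP.join(out)

    result = df.copy()
    result["diagnosis_codes"] = (
        result["diagnosis_codes"].fillna("").map(_map_joined)
    )
    if unmapped:
        logger.warning(
            "%d diagnosis codes (%d distinct) not in code map; passed through",
            sum(unmapped.values()),
            len(unmapped),
        )
    return result, dict(unmapped)


def summarize_utilization(
    df: pd.DataFrame,
    years: Iterable[int],
    case_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Per year x claim type x subset: records, individuals, visits per capita.

    ``visits_per_capita = n_records / n_individuals``; a cell with zero
    individuals reports ``NaN`` (undefined), never zero. When ``case_ids``
    is given, a second subset restricted to those patients is added,
    mirroring the all/disease-cases split of utilization tables.
    """
    years = list(years)
    year = df["service_date"].dt.year
    subsets: list[tuple[str, pd.DataFrame]] = [("all", df)]
    if case_ids is not None:
        subsets.append(("cases", df[df["patient_id"].isin(case_ids)]))

    rows = []
    for subset_name, sub in subsets:
        sub_year = sub["service_date"].dt.year
        for y in years:
            for ctype in ("inpatient", "outpatient"):
                cell = sub[(sub_year == y) & (sub["claim_type"] == ctype)]
                n_rec = len(cell)
                n_ind = cell["patient_id"].nunique()
                rows.append(
                    {
                        "year": y,
                        "subset": subset_name,
                        "claim_type": ctype,
                        "n_records": n_rec,
                        "n_individuals": n_ind,
                        "visits_per_capita": (n_rec / n_ind) if n_ind else np.nan,
                    }
                )
    return pd.DataFrame(rows)
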