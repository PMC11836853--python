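"""Episode-level record IO and per-patient aggregation.

The input is an admitted-patient-care extract in the usual HES-APC wide
shape: one row per finished episode, with up to 20 ICD-10 diagnosis columns
(``diag_01``..``diag_20``, position 1 primary) and up to 24 OPCS-4 procedure
columns (``opertn_01``..``opertn_24``). Column names are remappable through
:class:`ColumnDialect`.

A patient's phenotyping features are ORs and counts over all their episodes:
whether any episode carries the iron-metabolism diagnosis E83.1, how many
*episodes* contain the venesection procedure X36.2 (a code repeated within
one episode counts once — venesection day cases generate one episode each),
and whether any diagnosis position of any episode matches the G1 or G2
exclusion groups.

The gold standard is a per-patient diagnosis/genotype category established
by case-note review; only C282Y homozygotes count as true haemochromatosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .codesets import ClinicalCode, CodeGroup, CodeSystem, default_groups, normalize_code

__all__ = [
    "STUDY_WINDOW",
    "ColumnDialect",
    "Episode",
    "PatientRecord",
    "GoldCategory",
    "GoldLabel",
    "SchemaError",
    "RowParseError",
    "read_episodes",
    "select_baseline",
    "aggregate_patients",
    "read_gold_labels",
    "write_episodes",
    "write_gold_labels",
]

logger = logging.getLogger(__name__)

#: Closed study window: five financial years of inpatient episodes.
STUDY_WINDOW: tuple[date, date] = (date(2018, 4, 1), date(2023, 3, 31))


class SchemaError(ValueError):
    """An input table is missing a required column."""


class RowParseError(ValueError):
    """A row of an input table could not be parsed."""


@dataclass(frozen=True)
class ColumnDialect:
    """Column naming of the episode table (defaults follow HES-APC)."""

    patient_id: str = "patient_id"
    episode_id: str = "episode_id"
    admission_date: str = "admidate"
    age: str = "startage"
    sex: str = "sex"
    diagnosis_prefix: str = "diag_"
    n_diagnosis: int = 20
    procedure_prefix: str = "opertn_"
    n_procedure: int = 24

    def diagnosis_columns(self) -> list[str]:
        return [f"{self.diagnosis_prefix}{i:02d}" for i in range(1, self.n_diagnosis + 1)]

    def procedure_columns(self) -> list[str]:
        return [f"{self.procedure_prefix}{i:02d}" for i in range(1, self.n_procedure + 1)]


DEFAULT_DIALECT = ColumnDialect()

_SEX_MAP = {"M": "M", "MALE": "M", "1": "M", "F": "F", "FEMALE": "F", "2": "F"}


@dataclass(frozen=True)
class Episode:
    """One admitted-patient-care coding record."""

    patient_id: str
    episode_id: str
    admission_date: date
    age_at_admission: int
    sex: str  # "M", "F" or "unknown"
    diagnoses: tuple[ClinicalCode, ...]
    procedures: tuple[ClinicalCode, ...]

    def __post_init__(self) -> None:
        if len(self.diagnoses) > 20:
            raise ValueError(f"episode {self.episode_id}: more than 20 diagnoses")
        if len(self.procedures) > 24:
            raise ValueError(f"episode {self.episode_id}: more than 24 procedures")


@dataclass(frozen=True)
class PatientRecord:
    """Episode-aggregated phenotyping features for one patient."""

    patient_id: str
    n_episodes: int
    has_e831: bool
    venesection_episodes: int
    has_g1_code: bool
    has_g2_code: bool
    age_at_first_episode: int
    sex: str


class GoldCategory(str, Enum):
    """Case-note review diagnosis/genotype category.

    The positive phenotype class is :attr:`C282Y_HOM`; every other category,
    including compound heterozygosity, is gold-standard negative.
    """

    C282Y_HOM = "C282Y_HOM"
    C282Y_H63D = "C282Y_H63D"
    C282Y_X = "C282Y_X"
    H63D_HOM = "H63D_HOM"
    H63D_X = "H63D_X"
    HH_GENE_UNKNOWN = "HH_GENE_UNKNOWN"
    RARER_MUTATION = "RARER_MUTATION"
    TRANSFUSION_OVERLOAD = "TRANSFUSION_OVERLOAD"
    HYPERFERRITINAEMIA = "HYPERFERRITINAEMIA"
    POLYCYTHAEMIA_VERA = "POLYCYTHAEMIA_VERA"
    SECONDARY_POLYCYTHAEMIA = "SECONDARY_POLYCYTHAEMIA"
    PCT = "PCT"
    INCORRECT_CODING = "INCORRECT_CODING"


#: Human-readable labels accepted in gold-label files (besides enum names).
CATEGORY_DISPLAY: dict[GoldCategory, str] = {
    GoldCategory.C282Y_HOM: "C282Y/C282Y",
    GoldCategory.C282Y_H63D: "C282Y/H63D",
    GoldCategory.C282Y_X: "C282Y/x",
    GoldCategory.H63D_HOM: "H63D/H63D",
    GoldCategory.H63D_X: "H63D/x",
    GoldCategory.HH_GENE_UNKNOWN: "HH gene unknown",
    GoldCategory.RARER_MUTATION: "Rarer mutations",
    GoldCategory.TRANSFUSION_OVERLOAD: "Transfusion iron overload",
    GoldCategory.HYPERFERRITINAEMIA: "Hyperferritinaemia",
    GoldCategory.POLYCYTHAEMIA_VERA: "Polycythaemia vera",
    GoldCategory.SECONDARY_POLYCYTHAEMIA: "Secondary polycythaemia",
    GoldCategory.PCT: "Porphyria cutanea tarda",
    GoldCategory.INCORRECT_CODING: "Incorrect coding",
}

_CATEGORY_LOOKUP: dict[str, GoldCategory] = {c.value.upper(): c for c in GoldCategory}
_CATEGORY_LOOKUP.update({v.upper(): k for k, v in CATEGORY_DISPLAY.items()})


def parse_category(text: str) -> GoldCategory:
    key = str(text).strip().upper()
    try:
        return _CATEGORY_LOOKUP[key]
    except KeyError:
        valid = sorted(c.value for c in GoldCategory)
        raise ValueError(
            f"unknown gold category {text!r}; valid categories: {', '.join(valid)}"
        ) from None


@dataclass(frozen=True)
class GoldLabel:
    patient_id: str
    category: GoldCategory

    @property
    def is_positive(self) -> bool:
        return self.category is GoldCategory.C282Y_HOM


def _codes_from_row(row, columns: Sequence[str], system: CodeSystem) -> tuple[ClinicalCode, ...]:
    codes = []
    for col in columns:
        value = str(row[col]).strip()
        if value and value.lower() != "nan":
            codes.append(normalize_code(value, system))
    return tuple(codes)


def read_episodes(
    path: Union[str, Path],
    dialect: ColumnDialect = DEFAULT_DIALECT,
) -> list[Episode]:
    """Read an episode-level CSV/TSV into :class:`Episode` objects.

    Blank diagnosis/procedure cells are skipped; dates must be ISO-8601.
    Raises :class:`SchemaError` naming any missing required column, and
    :class:`RowParseError` with the row index for unparseable dates or ages.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    required = [
        dialect.patient_id,
        dialect.episode_id,
        dialect.admission_date,
        dialect.age,
        dialect.sex,
        f"{dialect.diagnosis_prefix}01",
    ]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")

    diag_cols = [c for c in dialect.diagnosis_columns() if c in df.columns]
    proc_cols = [c for c in dialect.procedure_columns() if c in df.columns]

    episodes: list[Episode] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            admission = date.fromisoformat(str(row[dialect.admission_date]).strip())
        except ValueError:
            raise RowParseError(
                f"{path}: row {i}: unparseable admission date "
                f"{row[dialect.admission_date]!r}"
            ) from None
        try:
            age = int(str(row[dialect.age]).strip())
        except ValueError:
            raise RowParseError(
                f"{path}: row {i}: unparseable age {row[dialect.age]!r}"
            ) from None
        sex = _SEX_MAP.get(str(row[dialect.sex]).strip().upper(), "unknown")
        episodes.append(
            Episode(
                patient_id=str(row[dialect.patient_id]).strip(),
                episode_id=str(row[dialect.episode_id]).strip(),
                admission_date=admission,
                age_at_admission=age,
                sex=sex,
                diagnoses=_codes_from_row(row, diag_cols, CodeSystem.ICD10),
                procedures=_codes_from_row(row, proc_cols, CodeSystem.OPCS4),
            )
        )
    return episodes


def select_baseline(
    episodes: Iterable[Episode],
    window: tuple[date, date] = STUDY_WINDOW,
    min_age: int = 18,
    groups: Optional[Mapping[str, CodeGroup]] = None,
) -> list[Episode]:
    """Restrict to the baseline cohort.

    A patient qualifies if at least one in-window episode carries a diagnosis
    matching the ``E831`` group at age ``min_age`` or older. All in-window
    episodes of qualifying patients are retained (feature building needs the
    venesection and exclusion codes wherever they occur).
    """
    if groups is None:
        groups = default_groups()
    e831 = groups["E831"]
    start, end = window
    if start > end:
        raise ValueError("invalid study window: start after end")

    in_window = [e for e in episodes if start <= e.admission_date <= end]
    qualifying = {
        e.patient_id
        for e in in_window
        if e.age_at_admission >= min_age and any(e831.matches(c) for c in e.diagnoses)
    }
    selected = [e for e in in_window if e.patient_id in qualifying]
    if not selected:
        logger.warning("baseline selection produced an empty cohort")
    return selected


def aggregate_patients(
    episodes: Iterable[Episode],
    groups: Optional[Mapping[str, CodeGroup]] = None,
) -> list[PatientRecord]:
    """Aggregate episodes into one :class:`PatientRecord` per patient.

    Duplicate ``(patient_id, episode_id)`` pairs are dropped with a logged
    warning. ``venesection_episodes`` counts *episodes* containing at least
    one X36.2 procedure, never code repetitions within an episode. The result
    is sorted by patient id and independent of input episode order.
    """
    if groups is None:
        groups = default_groups()
    e831, g1, g2, x362 = groups["E831"], groups["G1"], groups["G2"], groups["X362"]

    seen: set[tuple[str, str]] = set()
    n_dupes = 0
    per_patient: dict[str, list[Episode]] = {}
    for e in episodes:
        key = (e.patient_id, e.episode_id)
        if key in seen:
            n_dupes += 1
            continue
        seen.add(key)
        per_patient.setdefault(e.patient_id, []).append(e)
    if n_dupes:
        logger.warning("dropped %d duplicate (patient_id, episode_id) episodes", n_dupes)

    records: list[PatientRecord] = []
    for pid in sorted(per_patient):
        eps = sorted(per_patient[pid], key=lambda e: (e.admission_date, e.episode_id))
        sex = next((e.sex for e in eps if e.sex != "unknown"), "unknown")
        records.append(
            PatientRecord(
                patient_id=pid,
                n_episodes=len(eps),
                has_e831=any(e831.matches(c) for e in eps for c in e.diagnoses),
                venesection_episodes=sum(
                    1 for e in eps if any(x362.matches(c) for c in e.procedures)
                ),
                has_g1_code=any(g1.matches(c) for e in eps for c in e.diagnoses),
                has_g2_code=any(g2.matches(c) for e in eps for c in e.diagnoses),
                age_at_first_episode=eps[0].age_at_admission,
                sex=sex,
            )
        )
    return records


def read_gold_labels(path: Union[str, Path]) -> list[GoldLabel]:
    """Read the two-column gold-standard table (patient_id, category).

    Categories may be enum names or display labels ("C282Y/C282Y").
    Duplicate patients and unknown categories raise errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("patient_id", "category"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    dupes = df["patient_id"][df["patient_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate patient ids: {', '.join(dupes[:5])}")
    return [
        GoldLabel(patient_id=str(pid).strip(), category=parse_category(cat))
        for pid, cat in zip(df["patient_id"], df["category"])
    ]


def write_episodes(
    episodes: Sequence[Episode],
    path: Union[str, Path],
    dialect: ColumnDialect = DEFAULT_DIALECT,
) -> None:
    """Write episodes as a wide CSV in the given dialect (raw code spellings)."""
    diag_cols = dialect.diagnosis_columns()
    proc_cols = dialect.procedure_columns()
    rows = []
    for e in episodes:
        row = {
            dialect.patient_id: e.patient_id,
            dialect.episode_id: e.episode_id,
            dialect.admission_date: e.admission_date.isoformat(),
            dialect.age: e.age_at_admission,
            dialect.sex: e.sex,
        }
        for col, code in zip(diag_cols, e.diagnoses):
            row[col] = code.raw
        for col, code in zip(proc_cols, e.procedures):
            row[col] = code.raw
        rows.append(row)
    columns = [
        dialect.patient_id,
        dialect.episode_id,
        dialect.admission_date,
        dialect.age,
        dialect.sex,
        *diag_cols,
        *proc_cols,
    ]
    pd.DataFrame(rows, columns=columns).fillna("").to_csv(path, index=False)


def write_gold_labels(labels: Sequence[GoldLabel], path: Union[str, Path]) -> None:
    """Write gold labels with display category names."""
    pd.DataFrame(
        {
            "patient_id": [l.patient_id for l in labels],
            "category": [CATEGORY_DISPLAY[l.category] for l in labels],
        }
    ).to_csv(path, index=False)
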