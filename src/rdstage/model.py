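"""Case/evidence data model and CSV readers/writers for registry extracts.

An extract is two delimited files: a case table (one row per incident
pancreatic carcinoma) and an evidence table (zero or more dated
observations per case, each from one source tier). Keeping evidence long
rather than wide means sparse multi-source data does not force column
explosion.

All dates are ISO-8601 calendar dates with no time-of-day component.
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .vocab import HistologyCode, ICD10AMCode, TopographyCode

log = logging.getLogger("rdstage")

__all__ = [
    "SourceTier",
    "TIER_RANK",
    "StagingBasis",
    "ResectabilityStatus",
    "EvidenceRecord",
    "RegistryCase",
    "StagingWindow",
    "ExtractReadResult",
    "SchemaError",
    "read_extract",
    "write_extract",
    "in_window",
]


class SourceTier(str, enum.Enum):
    """Evidence source, ranked by the registry advisory hierarchy."""

    MDT = "MDT"
    PATHOLOGY = "PATHOLOGY"
    ONCOLOGY_SYSTEM = "ONCOLOGY_SYSTEM"
    ADMISSION = "ADMISSION"
    IMAGING = "IMAGING"
    DEATH_CERTIFICATE = "DEATH_CERTIFICATE"


#: Default priority: 1 = most trusted. Multidisciplinary-team (MDT) records
#: outrank pathology, then oncology information systems, hospital
#: admissions, and imaging. Death certificates sit outside the hierarchy:
#: they are consulted for metastasis evidence only.
TIER_RANK: dict[SourceTier, int] = {
    SourceTier.MDT: 1,
    SourceTier.PATHOLOGY: 2,
    SourceTier.ONCOLOGY_SYSTEM: 3,
    SourceTier.ADMISSION: 4,
    SourceTier.IMAGING: 5,
    SourceTier.DEATH_CERTIFICATE: 6,
}


class StagingBasis(str, enum.Enum):
    CLINICAL = "CLINICAL"
    PATHOLOGICAL = "PATHOLOGICAL"
    UNKNOWN = "UNKNOWN"


class ResectabilityStatus(str, enum.Enum):
    """Surgical classification of a pancreatic tumour (NCCN terminology)."""

    RESECTABLE = "RESECTABLE"
    BORDERLINE = "BORDERLINE"
    LOCALLY_ADVANCED_UNRESECTABLE = "LOCALLY_ADVANCED_UNRESECTABLE"
    METASTATIC_UNRESECTABLE = "METASTATIC_UNRESECTABLE"
    UNKNOWN = "UNKNOWN"


class EvidenceRecord(BaseModel):
    """One dated observation about one case from one source tier."""

    case_id: str
    tier: SourceTier
    record_date: Optional[dt.date] = None
    t_statement: Optional[str] = None
    n_statement: Optional[str] = None
    m_statement: Optional[str] = None
    tumour_size_mm: Optional[float] = Field(default=None, gt=0)
    nodes_examined: Optional[int] = Field(default=None, ge=0)
    nodes_positive: Optional[int] = Field(default=None, ge=0)
    arterial_involvement: Optional[bool] = None
    icd10am_codes: list[ICD10AMCode] = Field(default_factory=list)
    stage_statement: Optional[str] = None
    resectability: Optional[ResectabilityStatus] = None
    staging_basis: StagingBasis = StagingBasis.UNKNOWN

    model_config = {"arbitrary_types_allowed": True}

    @field_validator("icd10am_codes", mode="before")
    @classmethod
    def _parse_codes(cls, v):
        if v is None:
            return []
        return [c if isinstance(c, ICD10AMCode) else ICD10AMCode.parse(c) for c in v]

    @model_validator(mode="after")
    def _nodes_consistent(self) -> "EvidenceRecord":
        if (
            self.nodes_examined is not None
            and self.nodes_positive is not None
            and self.nodes_positive > self.nodes_examined
        ):
            raise ValueError(
                f"nodes_positive ({self.nodes_positive}) exceeds nodes_examined "
                f"({self.nodes_examined})"
            )
        return self


class RegistryCase(BaseModel):
    """One incident pancreatic carcinoma with its attached evidence."""

    case_id: str
    diagnosis_date: dt.date
    histology: HistologyCode
    topography: TopographyCode
    first_treatment_date: Optional[dt.date] = None
    neoadjuvant_before_pathology: bool = False
    degree_of_spread: Optional[str] = None  # pass-through ordinal, not staged
    jurisdiction: Optional[str] = None
    evidence: list[EvidenceRecord] = Field(default_factory=list)

    model_config = {"arbitrary_types_allowed": True}

    @field_validator("histology", mode="before")
    @classmethod
    def _parse_hist(cls, v):
        return v if isinstance(v, HistologyCode) else HistologyCode.parse(v)

    @field_validator("topography", mode="before")
    @classmethod
    def _parse_topo(cls, v):
        return v if isinstance(v, TopographyCode) else TopographyCode.parse(v)


class StagingWindow(BaseModel):
    """The admissible evidence window around diagnosis.

    Evidence is admitted from ``pre_diagnosis_slack_days`` before diagnosis
    (registries time-stamp diagnosis heterogeneously, so e.g. diagnostic
    imaging can legitimately precede the formal diagnosis date) up to and
    including ``window_days`` after it, and — when ``require_pre_treatment``
    — strictly before the first treatment date.
    """

    window_days: int = Field(default=120, gt=0)
    require_pre_treatment: bool = True
    pre_diagnosis_slack_days: int = Field(default=30, ge=0)


def in_window(
    record: EvidenceRecord, case: RegistryCase, window: StagingWindow
) -> bool:
    """Is this evidence record admissible for staging this case?

    The post-diagnosis boundary is inclusive ("within 120 days"); the
    treatment boundary is exclusive ("before primary cancer treatment").
    A record with no date is never admissible.
    """
    if record.record_date is None:
        log.debug("case %s: undated %s record excluded", case.case_id, record.tier)
        return False
    d = record.record_date
    if d < case.diagnosis_date - dt.timedelta(days=window.pre_diagnosis_slack_days):
        return False
    if d > case.diagnosis_date + dt.timedelta(days=window.window_days):
        return False
    if (
        window.require_pre_treatment
        and case.first_treatment_date is not None
        and d >= case.first_treatment_date
    ):
        return False
    return True


# ---------------------------------------------------------------------------
# CSV schemas

CASE_COLUMNS = [
    "case_id",
    "diagnosis_date",
    "morphology",
    "behaviour",
    "topography",
    "first_treatment_date",
    "neoadjuvant_flag",
    "degree_of_spread",
]
_CASE_MANDATORY = ["case_id", "diagnosis_date", "morphology", "behaviour", "topography"]

EVIDENCE_COLUMNS = [
    "case_id",
    "tier",
    "record_date",
    "t",
    "n",
    "m",
    "tumour_size_mm",
    "nodes_examined",
    "nodes_positive",
    "arterial_involvement",
    "icd10am_codes",
    "stage_statement",
    "resectability",
    "staging_basis",
]
_EVIDENCE_MANDATORY = ["case_id", "tier"]


class SchemaError(ValueError):
    """A mandatory column is missing from an extract file."""


class ExtractReadResult:
    """Cases plus row-level problems collected (not fatal) during reading."""

    def __init__(self, cases: list[RegistryCase], problems: list[str]):
        self.cases = cases
        self.problems = problems

    def __iter__(self):
        return iter(self.cases)

    def __len__(self):
        return len(self.cases)


def _opt(v):
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return v


def _opt_date(v) -> Optional[dt.date]:
    v = _opt(v)
    return None if v is None else dt.date.fromisoformat(str(v))


def _opt_bool(v) -> Optional[bool]:
    v = _opt(v)
    if v is None:
        return None
    s = str(v).strip().lower()
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n"}:
        return False
    raise ValueError(f"cannot interpret {v!r} as a boolean")


def read_extract(
    case_file: Path | str,
    evidence_file: Path | str,
    window: StagingWindow | None = None,
) -> ExtractReadResult:
    """Read and validate a two-file registry extract.

    Unknown columns are preserved in the frame but ignored. Row-level
    validation failures are collected with 1-based data-row numbers and
    reported, not fatal; orphan evidence (no matching case) is dropped with
    a warning. Evidence dated before the pre-diagnosis slack of ``window``
    (default :class:`StagingWindow`) violates the case invariant and is
    dropped likewise.
    """
    window = window or StagingWindow()
    cases_df = pd.read_csv(case_file, dtype=str, keep_default_na=False)
    ev_df = pd.read_csv(evidence_file, dtype=str, keep_default_na=False)
    for col in _CASE_MANDATORY:
        if col not in cases_df.columns:
            raise SchemaError(f"{case_file}: missing mandatory column {col!r}")
    for col in _EVIDENCE_MANDATORY:
        if col not in ev_df.columns:
            raise SchemaError(f"{evidence_file}: missing mandatory column {col!r}")

    problems: list[str] = []
    cases: dict[str, RegistryCase] = {}
    for i, row in cases_df.iterrows():
        rowno = i + 1
        try:
            cid = str(row["case_id"])
            if cid in cases:
                raise ValueError(f"duplicate case_id {cid!r}")
            cases[cid] = RegistryCase(
                case_id=cid,
                diagnosis_date=dt.date.fromisoformat(row["diagnosis_date"]),
                histology=f"{row['morphology']}/{row['behaviour']}",
                topography=row["topography"],
                first_treatment_date=_opt_date(row.get("first_treatment_date")),
                neoadjuvant_before_pathology=_opt_bool(row.get("neoadjuvant_flag"))
                or False,
                degree_of_spread=_opt(row.get("degree_of_spread")),
                jurisdiction=_opt(row.get("jurisdiction")),
            )
        except Exception as exc:  # collected, not fatal
            problems.append(f"cases row {rowno}: {exc}")
    for i, row in ev_df.iterrows():
        rowno = i + 1
        try:
            cid = str(row["case_id"])
            case = cases.get(cid)
            if case is None:
                log.warning("evidence row %d: orphan case_id %s dropped", rowno, cid)
                problems.append(f"evidence row {rowno}: orphan case_id {cid!r}")
                continue
            codes = _opt(row.get("icd10am_codes"))
            rec = EvidenceRecord(
                case_id=cid,
                tier=SourceTier(row["tier"]),
                record_date=_opt_date(row.get("record_date")),
                t_statement=_opt(row.get("t")),
                n_statement=_opt(row.get("n")),
                m_statement=_opt(row.get("m")),
                tumour_size_mm=_opt(row.get("tumour_size_mm")),
                nodes_examined=_opt(row.get("nodes_examined")),
                nodes_positive=_opt(row.get("nodes_positive")),
                arterial_involvement=_opt_bool(row.get("arterial_involvement")),
                icd10am_codes=codes.split(";") if codes else [],
                stage_statement=_opt(row.get("stage_statement")),
                resectability=_opt(row.get("resectability")),
                staging_basis=_opt(row.get("staging_basis"))
                or StagingBasis.UNKNOWN,
            )
            if rec.record_date is not None and rec.record_date < (
                case.diagnosis_date
                - dt.timedelta(days=window.pre_diagnosis_slack_days)
            ):
                problems.append(
                    f"evidence row {rowno}: record_date {rec.record_date} precedes "
                    f"diagnosis by more than {window.pre_diagnosis_slack_days} days"
                )
                continue
            case.evidence.append(rec)
        except Exception as exc:
            log.warning("evidence row %d rejected: %s", rowno, exc)
            problems.append(f"evidence row {rowno}: {exc}")
    return ExtractReadResult(list(cases.values()), problems)


def write_extract(
    cases: Iterable[RegistryCase],
    case_file: Path | str,
    evidence_file: Path | str,
) -> None:
    """Write cases + evidence back to the two-file CSV schema (lossless for
    all typed fields; round-trips through :func:`read_extract`)."""
    case_rows, ev_rows = [], []
    for c in cases:
        case_rows.append(
            {
                "case_id": c.case_id,
                "diagnosis_date": c.diagnosis_date.isoformat(),
                "morphology": c.histology.morphology,
                "behaviour": c.histology.behaviour,
                "topography": c.topography.site,
                "first_treatment_date": (
                    c.first_treatment_date.isoformat()
                    if c.first_treatment_date
                    else ""
                ),
                "neoadjuvant_flag": int(c.neoadjuvant_before_pathology),
                "degree_of_spread": c.degree_of_spread or "",
                "jurisdiction": c.jurisdiction or "",
            }
        )
        for r in c.evidence:
            ev_rows.append(
                {
                    "case_id": r.case_id,
                    "tier": r.tier.value,
                    "record_date": r.record_date.isoformat() if r.record_date else "",
                    "t": r.t_statement or "",
                    "n": r.n_statement or "",
                    "m": r.m_statement or "",
                    "tumour_size_mm": (
                        "" if r.tumour_size_mm is None else f"{r.tumour_size_mm:g}"
                    ),
                    "nodes_examined": (
                        "" if r.nodes_examined is None else r.nodes_examined
                    ),
                    "nodes_positive": (
                        "" if r.nodes_positive is None else r.nodes_positive
                    ),
                    "arterial_involvement": (
                        ""
                        if r.arterial_involvement is None
                        else int(r.arterial_involvement)
                    ),
                    "icd10am_codes": ";".join(str(x) for x in r.icd10am_codes),
                    "stage_statement": r.stage_statement or "",
                    "resectability": r.resectability.value if r.resectability else "",
                    "staging_basis": r.staging_basis.value,
                }
            )
    pd.DataFrame(case_rows, columns=CASE_COLUMNS + ["jurisdiction"]).to_csv(
        case_file, index=False
    )
    pd.DataFrame(ev_rows, columns=EVIDENCE_COLUMNS).to_csv(evidence_file, index=False)
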