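"""Registry-derived TNM staging for pancreatic carcinoma.

The engine derives the metastasis (M), node (N) and tumour (T) categories —
in that order, because confirmed distant metastasis makes stage IV and
removes any need to resolve N or T — from whatever in-window evidence a
registry holds, then maps (T, N, M) to an AJCC 8th-edition prognostic
group with principled handling of unknown (X) categories.

Category derivation walks the evidence in a fixed order of source trust
(multidisciplinary-team records first, then pathology, oncology systems,
admissions, imaging); within a tier earlier records win. Death-certificate
records are consulted only as metastasis evidence.

M0 is handled under one of two policies. The default assumes M0 whenever
no clinical, coded or imaging evidence of metastasis exists, following the
AJCC rule that a patient is cM0 unless there is evidence otherwise. The
stricter "Queensland" policy refuses to assume M0 unless the patient had a
later hospital admission — more than a configurable lookback (default 120
days) after diagnosis — that carried no ICD-10-AM secondary-malignancy
code (C77–C79); otherwise M is left unresolved and the stage is Unknown.

The stage-group map never guesses: when a category is X, the group is
reported only if every consistent resolution of the X categories lands on
the same group, else the stage is Unknown.
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    TIER_RANK,
    EvidenceRecord,
    RegistryCase,
    ResectabilityStatus,
    SourceTier,
    StagingBasis,
    StagingWindow,
    in_window,
)
from .vocab import Vocabulary, is_metastatic_site_code, load_default_vocabulary

log = logging.getLogger("rdstage")

__all__ = [
    "MCategory",
    "NCategory",
    "TCategory",
    "M0PolicyKind",
    "M0Policy",
    "Group",
    "Roman",
    "StageGroup",
    "TNMResult",
    "EligibilityError",
    "derive_m",
    "derive_n",
    "derive_t",
    "stage_group",
    "derive_rd_stage",
    "ROMAN_OF_GROUP",
]


class MCategory(str, enum.Enum):
    M0_EVIDENCED = "M0_EVIDENCED"
    M0_ASSUMED = "M0_ASSUMED"
    M1 = "M1"
    UNRESOLVED = "UNRESOLVED"  # Queensland policy only

    @property
    def is_m0(self) -> bool:
        return self in (MCategory.M0_EVIDENCED, MCategory.M0_ASSUMED)


class NCategory(str, enum.Enum):
    NX = "NX"
    N0 = "N0"
    N1 = "N1"
    N2 = "N2"


class TCategory(str, enum.Enum):
    TX = "TX"
    T1 = "T1"  # T1a/b/c collapsed: stage groups do not distinguish them
    T2 = "T2"
    T3 = "T3"
    T4 = "T4"


class M0PolicyKind(str, enum.Enum):
    ASSUME_M0 = "ASSUME_M0"
    QUEENSLAND = "QUEENSLAND"


@dataclass(frozen=True)
class M0Policy:
    """How to assign M0 in the absence of metastasis evidence.

    ``c77_is_distant`` controls whether a C77 (secondary lymph-node)
    admission code counts as distant-metastasis evidence. It defaults to
    True, matching registry practice of treating the whole C77–C79 block
    as metastatic disease; set False to treat C77 as regional nodal
    disease only (AJCC terms), in which case C77 codes are ignored by M
    derivation.
    """

    kind: M0PolicyKind = M0PolicyKind.ASSUME_M0
    lookback_days: int = 120
    c77_is_distant: bool = True


class Group(str, enum.Enum):
    IA = "IA"
    IB = "IB"
    IIA = "IIA"
    IIB = "IIB"
    III = "III"
    IV = "IV"
    UNKNOWN = "UNKNOWN"
    POST_NEOADJUVANT = "POST_NEOADJUVANT"


class Roman(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNKNOWN = "UNKNOWN"
    POST_NEOADJUVANT = "POST_NEOADJUVANT"


ROMAN_OF_GROUP: dict[Group, Roman] = {
    Group.IA: Roman.I,
    Group.IB: Roman.I,
    Group.IIA: Roman.II,
    Group.IIB: Roman.II,
    Group.III: Roman.III,
    Group.IV: Roman.IV,
    Group.UNKNOWN: Roman.UNKNOWN,
    Group.POST_NEOADJUVANT: Roman.POST_NEOADJUVANT,
}


@dataclass(frozen=True)
class StageGroup:
    group: Group
    roman: Roman

    @classmethod
    def of(cls, group: Group) -> "StageGroup":
        return cls(group=group, roman=ROMAN_OF_GROUP[group])


@dataclass
class TNMResult:
    """Derived categories with per-category provenance."""

    m: MCategory
    n: NCategory = NCategory.NX
    t: TCategory = TCategory.TX
    staging_basis: str = "UNKNOWN"  # CLINICAL / PATHOLOGICAL / MIXED / UNKNOWN
    provenance_m: Optional[SourceTier] = None
    provenance_n: Optional[SourceTier] = None
    provenance_t: Optional[SourceTier] = None
    post_neoadjuvant: bool = False
    stage_statement_used: bool = False
    conflicts: list[str] = field(default_factory=list)


class EligibilityError(ValueError):
    """Case is not an eligible pancreatic carcinoma."""


# ---------------------------------------------------------------------------
# evidence selection helpers

def _sort_key(record: EvidenceRecord):
    # Tier rank first, then date, then a stable textual tiebreak so that
    # the derivation is invariant to the order evidence arrives in.
    return (
        TIER_RANK[record.tier],
        record.record_date or dt.date.max,
        record.model_dump_json(),
    )


def _usable(case: RegistryCase, window: StagingWindow) -> list[EvidenceRecord]:
    return sorted(
        (r for r in case.evidence if in_window(r, case, window)), key=_sort_key
    )


_T_RE = re.compile(r"^T\s*([1-4])[A-CX]?$", re.I)
_N_RE = re.compile(r"^N\s*([0-2X])$", re.I)
_M_RE = re.compile(r"^M\s*([01X])$", re.I)


def _parse_t(text: str) -> Optional[TCategory]:
    m = _T_RE.match(text.strip())
    return TCategory(f"T{m.group(1)}") if m else None


def _parse_n(text: str) -> Optional[NCategory]:
    m = _N_RE.match(text.strip())
    if not m or m.group(1).upper() == "X":
        return None
    return NCategory(f"N{m.group(1)}")


def _has_metastatic_code(record: EvidenceRecord, policy: M0Policy) -> bool:
    for code in record.icd10am_codes:
        if not is_metastatic_site_code(code):
            continue
        if code.category == "C77" and not policy.c77_is_distant:
            continue
        return True
    return False


# ---------------------------------------------------------------------------
# category derivation

def derive_m(
    case: RegistryCase,
    window: StagingWindow | None = None,
    policy: M0Policy | None = None,
) -> tuple[MCategory, Optional[SourceTier]]:
    """Derive the TNM-M category and the tier that evidenced it.

    M1 if any in-window record asserts distant metastasis: an explicit M1
    statement, a C77–C79 admitted-episode code, metastatic-unresectable
    resectability, or a death-certificate metastasis flag. An explicit M0
    statement yields M0 evidenced. Otherwise the policy decides between
    assuming M0 and leaving M unresolved.
    """
    window = window or StagingWindow()
    policy = policy or M0Policy()
    m0_seen: Optional[SourceTier] = None
    for r in _usable(case, window):
        if r.m_statement:
            ms = r.m_statement.strip().upper().replace(" ", "")
            if ms.startswith("M1") or ms == "1":
                return MCategory.M1, r.tier
            if (ms.startswith("M0") or ms == "0") and m0_seen is None:
                m0_seen = r.tier
        if _has_metastatic_code(r, policy):
            return MCategory.M1, r.tier
        if r.resectability == ResectabilityStatus.METASTATIC_UNRESECTABLE:
            return MCategory.M1, r.tier
    if policy.kind is M0PolicyKind.QUEENSLAND:
        # Safety: a C77-C79 coded admission at ANY date (in window or not)
        # forbids M0 under this policy, explicit statements notwithstanding.
        if any(
            r.tier is SourceTier.ADMISSION and _has_metastatic_code(r, policy)
            for r in case.evidence
        ):
            return MCategory.UNRESOLVED, None
    if m0_seen is not None:
        return MCategory.M0_EVIDENCED, m0_seen
    if policy.kind is M0PolicyKind.ASSUME_M0:
        return MCategory.M0_ASSUMED, None
    # Queensland: assume M0 only when a later metastasis-free admission
    # exists, more than lookback_days after diagnosis.
    cutoff = case.diagnosis_date + dt.timedelta(days=policy.lookback_days)
    has_late_clean = any(
        r.tier is SourceTier.ADMISSION
        and r.record_date is not None
        and r.record_date > cutoff
        for r in case.evidence
    )
    return (MCategory.M0_ASSUMED if has_late_clean else MCategory.UNRESOLVED), None


def derive_n(
    case: RegistryCase, window: StagingWindow | None = None
) -> tuple[NCategory, Optional[SourceTier]]:
    """Derive TNM-N from the best-ranked in-window evidence.

    An explicit N statement from the most trusted tier wins; failing that,
    positive regional-node counts map 0 -> N0 (only when at least one node
    was examined), 1–3 -> N1, >=4 -> N2. With no usable evidence: NX.
    """
    window = window or StagingWindow()
    explicit: Optional[tuple[NCategory, SourceTier]] = None
    counted: Optional[tuple[NCategory, SourceTier]] = None
    for r in _usable(case, window):
        if r.tier is SourceTier.DEATH_CERTIFICATE:
            continue
        if r.n_statement:
            parsed = _parse_n(r.n_statement)
            if parsed is not None:
                if explicit is None:
                    explicit = (parsed, r.tier)
                elif explicit[0] is not parsed:
                    log.info(
                        "case %s: conflicting N statements; keeping %s from %s",
                        case.case_id, explicit[0].value, explicit[1].value,
                    )
        if counted is None and r.nodes_positive is not None:
            if r.nodes_positive == 0:
                if r.nodes_examined is not None and r.nodes_examined >= 1:
                    counted = (NCategory.N0, r.tier)
            elif r.nodes_positive <= 3:
                counted = (NCategory.N1, r.tier)
            else:
                counted = (NCategory.N2, r.tier)
    if explicit is not None:
        return explicit
    if counted is not None:
        return counted
    return NCategory.NX, None


def derive_t(
    case: RegistryCase, window: StagingWindow | None = None
) -> tuple[TCategory, Optional[SourceTier]]:
    """Derive TNM-T from the best-ranked in-window evidence.

    An explicit T statement wins; otherwise arterial involvement (coeliac
    axis / superior mesenteric artery / common hepatic artery) defines T4
    irrespective of size, then greatest-dimension size maps <=20 mm -> T1,
    >20–40 mm -> T2, >40 mm -> T3 (closed upper bounds per the AJCC
    convention). With no usable evidence: TX.
    """
    window = window or StagingWindow()
    explicit: Optional[tuple[TCategory, SourceTier]] = None
    arterial: Optional[SourceTier] = None
    sized: Optional[tuple[TCategory, SourceTier]] = None
    for r in _usable(case, window):
        if r.tier is SourceTier.DEATH_CERTIFICATE:
            continue
        if r.t_statement:
            parsed = _parse_t(r.t_statement)
            if parsed is not None and explicit is None:
                explicit = (parsed, r.tier)
        if arterial is None and r.arterial_involvement:
            arterial = r.tier
        if sized is None and r.tumour_size_mm is not None:
            s = r.tumour_size_mm
            cat = TCategory.T1 if s <= 20 else TCategory.T2 if s <= 40 else TCategory.T3
            sized = (cat, r.tier)
    if explicit is not None:
        return explicit
    if arterial is not None:
        if sized is not None:
            log.info(
                "case %s: arterial involvement dominates recorded size", case.case_id
            )
        return TCategory.T4, arterial
    if sized is not None:
        return sized
    return TCategory.TX, None


# ---------------------------------------------------------------------------
# stage grouping

def _group_resolved(t: TCategory, n: NCategory, m_is_m1: bool) -> Group:
    """AJCC 8th-edition pancreas prognostic group for fully known T, N, M."""
    if m_is_m1:
        return Group.IV
    if t is TCategory.T4 or n is NCategory.N2:
        return Group.III
    if n is NCategory.N1:
        return Group.IIB
    # N0
    return {TCategory.T1: Group.IA, TCategory.T2: Group.IB, TCategory.T3: Group.IIA}[t]


_T_RESOLUTIONS = [TCategory.T1, TCategory.T2, TCategory.T3, TCategory.T4]
_N_RESOLUTIONS = [NCategory.N0, NCategory.N1, NCategory.N2]


def stage_group(t: TCategory, n: NCategory, m: MCategory) -> StageGroup:
    """Map (T, N, M) to a prognostic group, total over the whole lattice.

    M1 dominates: stage IV whatever T and N, known or not. An unresolved M
    gives Unknown. With M0, X categories are resolved conservatively: the
    group is assigned only when every consistent resolution of the X
    categories yields the same group (e.g. TX N2 M0 is III because N2
    forces III for every T), otherwise Unknown.
    """
    if m is MCategory.M1:
        return StageGroup.of(Group.IV)
    if m is MCategory.UNRESOLVED:
        return StageGroup.of(Group.UNKNOWN)
    ts = [t] if t is not TCategory.TX else _T_RESOLUTIONS
    ns = [n] if n is not NCategory.NX else _N_RESOLUTIONS
    groups = {_group_resolved(ti, ni, False) for ti in ts for ni in ns}
    if len(groups) == 1:
        return StageGroup.of(groups.pop())
    return StageGroup.of(Group.UNKNOWN)


_STAGE_STMT_RE = re.compile(
    r"^(?:STAGE\s*)?(IA|IB|IIA|IIB|III|IV|I|II|1|2|3|4)$", re.I
)
_STMT_TO_GROUP = {
    "IA": Group.IA, "IB": Group.IB, "IIA": Group.IIA, "IIB": Group.IIB,
    "III": Group.III, "IV": Group.IV,
    "I": Group.UNKNOWN, "II": Group.UNKNOWN,  # refined below: roman-only
    "1": Group.UNKNOWN, "2": Group.UNKNOWN, "3": Group.III, "4": Group.IV,
}
_STMT_TO_ROMAN = {
    "IA": Roman.I, "IB": Roman.I, "I": Roman.I, "1": Roman.I,
    "IIA": Roman.II, "IIB": Roman.II, "II": Roman.II, "2": Roman.II,
    "III": Roman.III, "3": Roman.III, "IV": Roman.IV, "4": Roman.IV,
}


def _parse_stage_statement(text: str) -> Optional[tuple[Group, Roman]]:
    m = _STAGE_STMT_RE.match(text.strip())
    if not m:
        return None
    key = m.group(1).upper()
    return _STMT_TO_GROUP[key], _STMT_TO_ROMAN[key]


def derive_rd_stage(
    case: RegistryCase,
    window: StagingWindow | None = None,
    policy: M0Policy | None = None,
    vocabulary: Vocabulary | None = None,
    check_eligibility: bool = True,
) -> tuple[StageGroup, TNMResult]:
    """Full registry-derived stage for one case.

    Order of operations: eligibility, neoadjuvant screen, M, then (only if
    M is not M1) N and T, then the prognostic-group map. An explicit
    in-window stage-group statement from the most trusted tier is used
    only when no component T/N/M evidence produced a category, so stages
    that can be derived from components stay auditable.
    """
    window = window or StagingWindow()
    policy = policy or M0Policy()
    if check_eligibility:
        vocab = vocabulary or load_default_vocabulary()
        if not vocab.is_eligible(case.histology, case.topography):
            raise EligibilityError(
                f"case {case.case_id}: {case.histology}/{case.topography} is not "
                f"an eligible pancreatic carcinoma"
            )

    # Neoadjuvant screen: pathology taken after systemic pre-treatment no
    # longer reflects stage at diagnosis.
    if case.neoadjuvant_before_pathology:
        path = [
            r for r in case.evidence
            if r.tier is SourceTier.PATHOLOGY and r.record_date is not None
        ]
        post = [
            r for r in path
            if case.first_treatment_date is not None
            and r.record_date >= case.first_treatment_date
        ]
        if path and len(post) == len(path):
            result = TNMResult(m=MCategory.UNRESOLVED, post_neoadjuvant=True)
            return StageGroup.of(Group.POST_NEOADJUVANT), result

    m, prov_m = derive_m(case, window, policy)
    result = TNMResult(m=m, provenance_m=prov_m)
    if m is MCategory.M1:
        # distant metastasis: N and T are never derived
        result.staging_basis = _basis_for(case, window, [prov_m])
        return StageGroup.of(Group.IV), result

    n, prov_n = derive_n(case, window)
    t, prov_t = derive_t(case, window)
    result.n, result.t = n, t
    result.provenance_n, result.provenance_t = prov_n, prov_t
    result.staging_basis = _basis_for(case, window, [prov_m, prov_n, prov_t])

    group = stage_group(t, n, m)
    if (
        group.group is Group.UNKNOWN
        and t is TCategory.TX
        and n is NCategory.NX
        and prov_m is None
    ):
        # no component evidence at all: fall back to an explicit statement
        for r in _usable(case, window):
            if r.stage_statement:
                parsed = _parse_stage_statement(r.stage_statement)
                if parsed:
                    g, roman = parsed
                    result.stage_statement_used = True
                    result.provenance_t = result.provenance_n = None
                    result.staging_basis = _basis_for(case, window, [r.tier])
                    return StageGroup(group=g, roman=roman), result
    return group, result


def _basis_for(
    case: RegistryCase, window: StagingWindow, tiers: list[Optional[SourceTier]]
) -> str:
    bases = set()
    used = {t for t in tiers if t is not None}
    for r in _usable(case, window):
        if r.tier in used and r.staging_basis is not StagingBasis.UNKNOWN:
            bases.add(r.staging_basis)
    if not bases:
        return "UNKNOWN"
    if bases == {StagingBasis.PATHOLOGICAL}:
        return "PATHOLOGICAL"
    if bases == {StagingBasis.CLINICAL}:
        return "CLINICAL"
    return "MIXED"
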