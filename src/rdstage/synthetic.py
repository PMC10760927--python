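"""Synthetic registry-extract generator with known ground truth.

Real registry extracts cannot be redistributed, so every analysis in this
package is exercised on synthetic extracts whose generating stage and TNM
categories are recorded in a truth table. The generator draws a true
prognostic group per case, synthesises internally consistent evidence
(tumour sizes within the generating T band, node counts within the N
band, arterial involvement exactly for T4, secondary-malignancy admission
codes for metastatic cases), then thins fields and source tiers according
to a configurable completeness profile emulating jurisdictional reporting
conditions.

Two hazards of real data are deliberately reproducible: metastatic cases
whose admission coding was never received (``m1_admission_coding_rate`` <
1) — such cases degrade to Unknown, or to a falsely assumed M0 if other
component evidence exists, under the assume-M0 policy — and neoadjuvant
cases whose only pathology post-dates treatment.

Everything is reproducible from the seed: the same configuration always
yields byte-identical extract files.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .model import (
    EvidenceRecord,
    RegistryCase,
    SourceTier,
    StagingBasis,
    write_extract,
)
from .staging import Group, NCategory, Roman, ROMAN_OF_GROUP, TCategory

__all__ = [
    "CompletenessProfile",
    "DiscordanceModel",
    "GeneratorConfig",
    "ExtractBundle",
    "generate_extract",
    "generate_reference",
    "FULL_PROFILE",
    "VICTORIA_PROFILE",
    "QUEENSLAND_PROFILE",
]

_GROUPS = [Group.IA, Group.IB, Group.IIA, Group.IIB, Group.III, Group.IV]

#: Stage-group distribution shaped on the staged portion of a Victorian
#: pancreatic-carcinoma extract (I 25, II 26, III 19, IV 213 of 283 staged
#: cases), with the sub-group splits (IA/IB, IIA/IIB) taken as even since
#: registries report at collapsed level.
DEFAULT_STAGE_DISTRIBUTION: dict[str, float] = {
    "IA": 12.5 / 283,
    "IB": 12.5 / 283,
    "IIA": 13.0 / 283,
    "IIB": 13.0 / 283,
    "III": 19.0 / 283,
    "IV": 213.0 / 283,
}


class CompletenessProfile(BaseModel):
    """Per-field presence probabilities for emitted evidence."""

    tumour_size: float = Field(ge=0, le=1)
    lymph_nodes_taken: float = Field(ge=0, le=1)
    lymph_nodes_positive: float = Field(ge=0, le=1)
    staging_basis: float = Field(ge=0, le=1)
    tnm_t: float = Field(ge=0, le=1)
    tnm_n: float = Field(ge=0, le=1)
    tnm_m: float = Field(ge=0, le=1)
    stage_group: float = Field(ge=0, le=1)
    arterial_involvement: float = Field(ge=0, le=1)
    degree_of_spread: float = Field(default=0.0, ge=0, le=1)


FULL_PROFILE = CompletenessProfile(
    tumour_size=1, lymph_nodes_taken=1, lymph_nodes_positive=1, staging_basis=1,
    tnm_t=1, tnm_n=1, tnm_m=1, stage_group=1, arterial_involvement=1,
)

#: Field availability shaped on Victorian 2018–19 reporting conditions.
VICTORIA_PROFILE = CompletenessProfile(
    tumour_size=0.17, lymph_nodes_taken=0.14, lymph_nodes_positive=0.14,
    staging_basis=0.65, tnm_t=0.17, tnm_n=0.18, tnm_m=0.49, stage_group=0.03,
    arterial_involvement=0.17,
)

#: Field availability shaped on Queensland 2018–19 reporting conditions.
QUEENSLAND_PROFILE = CompletenessProfile(
    tumour_size=0.14, lymph_nodes_taken=0.08, lymph_nodes_positive=0.05,
    staging_basis=0.76, tnm_t=0.19, tnm_n=0.19, tnm_m=0.15, stage_group=0.14,
    arterial_involvement=0.19,
)


class DiscordanceModel(BaseModel):
    """Reference-registry error process for concordance testing."""

    error_rate: float = Field(default=11 / 229, ge=0, le=1)
    unknown_rate: float = Field(default=189 / 457, ge=0, le=1)


class GeneratorConfig(BaseModel):
    n_cases: int = Field(default=1754, gt=0)
    seed: int = 0
    stage_distribution: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_STAGE_DISTRIBUTION)
    )
    completeness_profile: CompletenessProfile = Field(
        default_factory=lambda: VICTORIA_PROFILE.model_copy()
    )
    tier_availability: dict[str, float] = Field(
        default_factory=lambda: {
            "PATHOLOGY": 1.0, "ADMISSION": 1.0, "MDT": 0.0,
            "ONCOLOGY_SYSTEM": 0.0, "IMAGING": 0.0,
        }
    )
    #: probability a truly metastatic case carries a C77-C79 admission code
    m1_admission_coding_rate: float = Field(default=0.62, ge=0, le=1)
    neoadjuvant_rate: float = Field(default=9 / 457, ge=0, le=1)
    #: probability of a later, metastasis-free admission > 120 d after
    #: diagnosis (what the strict M0 policy requires before assuming M0)
    late_admission_rate: float = Field(default=0.6, ge=0, le=1)
    discordance_model: DiscordanceModel = Field(default_factory=DiscordanceModel)

    @model_validator(mode="after")
    def _probs_sum(self) -> "GeneratorConfig":
        total = sum(self.stage_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage_distribution sums to {total}, not 1")
        unknown = set(self.stage_distribution) - {g.value for g in _GROUPS}
        if unknown:
            raise ValueError(f"unknown stage groups in distribution: {unknown}")
        return self


class ExtractBundle:
    """Generated cases plus their ground-truth table."""

    def __init__(self, cases: list[RegistryCase], truth: pd.DataFrame):
        self.cases = cases
        self.truth = truth

    def write(self, out_dir: Path | str) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "cases": out / "cases.csv",
            "evidence": out / "evidence.csv",
            "truth": out / "truth.csv",
        }
        write_extract(self.cases, paths["cases"], paths["evidence"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


# weights over eligible morphologies, shaped on their national distribution
_MORPHOLOGY_CHOICES = ["8140/3", "8500/3", "8000/3", "8010/3", "8480/3",
                       "8453/3", "8560/3"]
_MORPHOLOGY_WEIGHTS = [0.55, 0.17, 0.16, 0.08, 0.02, 0.01, 0.01]
_TOPOGRAPHY_CHOICES = ["C250", "C251", "C252", "C253", "C257", "C258", "C259"]
_TOPOGRAPHY_WEIGHTS = [0.41, 0.09, 0.09, 0.01, 0.03, 0.02, 0.35]
_MET_CODES = ["C78.0", "C78.7", "C79.3", "C79.9"]

_T_SIZE_BAND = {  # mm, closed AJCC bands
    TCategory.T1: (5, 20),
    TCategory.T2: (21, 40),
    TCategory.T3: (41, 80),
}


def _true_tnm(group: Group, rng: np.random.Generator):
    if group is Group.IV:
        return TCategory.TX, NCategory.NX, "M1"
    if group is Group.IA:
        return TCategory.T1, NCategory.N0, "M0"
    if group is Group.IB:
        return TCategory.T2, NCategory.N0, "M0"
    if group is Group.IIA:
        return TCategory.T3, NCategory.N0, "M0"
    if group is Group.IIB:
        t = [TCategory.T1, TCategory.T2, TCategory.T3][rng.integers(0, 3)]
        return t, NCategory.N1, "M0"
    # III: either locally invasive T4 with any N, or node-heavy N2
    if rng.random() < 0.5:
        n = [NCategory.N0, NCategory.N1, NCategory.N2][rng.integers(0, 3)]
        return TCategory.T4, n, "M0"
    t = [TCategory.T1, TCategory.T2, TCategory.T3][rng.integers(0, 3)]
    return t, NCategory.N2, "M0"


def generate_extract(
    config: GeneratorConfig, out_dir: Path | str | None = None
) -> ExtractBundle:
    """Generate a synthetic extract with known per-case TNM ground truth.

    Evidence is always internally consistent with the generating truth, so
    any thinning can only lose information (a correct category becomes X),
    never contradict it. Optionally writes ``cases.csv``, ``evidence.csv``
    and ``truth.csv`` to ``out_dir``.
    """
    rng = np.random.default_rng(config.seed)
    profile = config.completeness_profile
    avail = {SourceTier(k): v for k, v in config.tier_availability.items()}
    group_names = sorted(config.stage_distribution)
    group_probs = np.array([config.stage_distribution[g] for g in group_names])
    group_probs = group_probs / group_probs.sum()

    cases: list[RegistryCase] = []
    truth_rows: list[dict] = []
    for i in range(config.n_cases):
        cid = f"S{i + 1:05d}"
        diag = dt.date(2018, 1, 1) + dt.timedelta(days=int(rng.integers(0, 730)))
        group = Group(group_names[rng.choice(len(group_names), p=group_probs)])
        t_true, n_true, m_true = _true_tnm(group, rng)
        neoadjuvant = bool(rng.random() < config.neoadjuvant_rate)

        path_date = diag + dt.timedelta(days=int(rng.integers(5, 31)))
        if neoadjuvant:
            treat = diag + dt.timedelta(days=int(rng.integers(10, 31)))
            path_date = treat + dt.timedelta(days=int(rng.integers(30, 91)))
        else:
            treat = (
                path_date + dt.timedelta(days=int(rng.integers(7, 31)))
                if rng.random() < 0.8
                else None
            )

        case = RegistryCase(
            case_id=cid,
            diagnosis_date=diag,
            histology=_MORPHOLOGY_CHOICES[
                rng.choice(len(_MORPHOLOGY_CHOICES), p=_MORPHOLOGY_WEIGHTS)
            ],
            topography=_TOPOGRAPHY_CHOICES[
                rng.choice(len(_TOPOGRAPHY_CHOICES), p=_TOPOGRAPHY_WEIGHTS)
            ],
            first_treatment_date=treat,
            neoadjuvant_before_pathology=neoadjuvant,
            degree_of_spread=(
                _degree_of_spread(group)
                if rng.random() < profile.degree_of_spread
                else None
            ),
        )

        if rng.random() < avail.get(SourceTier.PATHOLOGY, 0.0):
            case.evidence.append(
                _pathology_record(cid, path_date, t_true, n_true, m_true,
                                  profile, rng)
            )
        if rng.random() < avail.get(SourceTier.MDT, 0.0):
            rec = _mdt_record(cid, diag, group, m_true, profile, rng)
            if rec is not None:
                case.evidence.append(rec)
        if m_true == "M1" and rng.random() < config.m1_admission_coding_rate:
            if avail.get(SourceTier.ADMISSION, 0.0) > 0:
                case.evidence.append(
                    EvidenceRecord(
                        case_id=cid,
                        tier=SourceTier.ADMISSION,
                        record_date=diag + dt.timedelta(days=int(rng.integers(0, 21))),
                        icd10am_codes=[_MET_CODES[rng.integers(0, len(_MET_CODES))]],
                    )
                )
        if (
            m_true == "M0"
            and rng.random() < config.late_admission_rate
            and avail.get(SourceTier.ADMISSION, 0.0) > 0
        ):
            case.evidence.append(
                EvidenceRecord(
                    case_id=cid,
                    tier=SourceTier.ADMISSION,
                    record_date=diag + dt.timedelta(days=int(rng.integers(130, 300))),
                    icd10am_codes=["K86.2"],  # chronic pancreatitis follow-up
                )
            )

        cases.append(case)
        truth_rows.append(
            {
                "case_id": cid,
                "true_t": t_true.value,
                "true_n": n_true.value,
                "true_m": m_true,
                "true_group": group.value,
                "true_roman": ROMAN_OF_GROUP[group].value,
                "neoadjuvant": int(neoadjuvant),
            }
        )

    bundle = ExtractBundle(cases, pd.DataFrame(truth_rows))
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _degree_of_spread(group: Group) -> str:
    if group is Group.IV:
        return "DISTANT"
    if group in (Group.IIB, Group.III):
        return "REGIONAL"
    return "LOCALISED"


def _pathology_record(cid, date, t_true, n_true, m_true, profile, rng):
    """One pathology report; M1 cases carry only the metastasis statement
    (distant disease makes local work-up moot and keeps thinning safe)."""
    rec = dict(case_id=cid, tier=SourceTier.PATHOLOGY, record_date=date)
    if rng.random() < profile.staging_basis:
        rec["staging_basis"] = StagingBasis.PATHOLOGICAL
    if m_true == "M1":
        if rng.random() < profile.tnm_m:
            rec["m_statement"] = "M1"
        return EvidenceRecord(**rec)
    if rng.random() < profile.tnm_m:
        rec["m_statement"] = "M0"
    if rng.random() < profile.tnm_t:
        rec["t_statement"] = t_true.value
    if rng.random() < profile.tnm_n:
        rec["n_statement"] = n_true.value
    if t_true is TCategory.T4:
        if rng.random() < profile.arterial_involvement:
            rec["arterial_involvement"] = True
    elif rng.random() < profile.tumour_size:
        lo, hi = _T_SIZE_BAND[t_true]
        rec["tumour_size_mm"] = int(rng.integers(lo, hi + 1))
    positive = {
        NCategory.N0: 0,
        NCategory.N1: int(rng.integers(1, 4)),
        NCategory.N2: int(rng.integers(4, 13)),
        NCategory.NX: 0,
    }[n_true]
    examined = int(rng.integers(max(positive, 8), 25))
    if rng.random() < profile.lymph_nodes_taken:
        rec["nodes_examined"] = examined
    if rng.random() < profile.lymph_nodes_positive:
        rec["nodes_positive"] = positive
    return EvidenceRecord(**rec)


def _mdt_record(cid, diag, group, m_true, profile, rng):
    rec = dict(
        case_id=cid,
        tier=SourceTier.MDT,
        record_date=diag + dt.timedelta(days=int(rng.integers(3, 21))),
        staging_basis=StagingBasis.CLINICAL,
    )
    emitted = False
    if rng.random() < profile.stage_group:
        rec["stage_statement"] = group.value
        emitted = True
    if m_true == "M1" and rng.random() < profile.tnm_m:
        rec["m_statement"] = "M1"
        emitted = True
    return EvidenceRecord(**rec) if emitted else None


def generate_reference(
    truth: pd.DataFrame,
    discordance: DiscordanceModel | None = None,
    seed: int = 0,
    out_file: Path | str | None = None,
) -> pd.DataFrame:
    """Emulate a reference registry's stage assignment from the truth table.

    Each case keeps its true collapsed stage except for seeded
    perturbations: with ``unknown_rate`` the reference fails to stage the
    case (Unknown), and with ``error_rate`` the recorded stage shifts one
    level (clipped to I–IV). Returns a frame with columns ``case_id`` and
    ``stage``; optionally written to CSV.
    """
    discordance = discordance or DiscordanceModel()
    rng = np.random.default_rng(seed)
    order = [Roman.I, Roman.II, Roman.III, Roman.IV]
    rows = []
    for r in truth.itertuples():
        stage = Roman(r.true_roman)
        if rng.random() < discordance.unknown_rate:
            stage = Roman.UNKNOWN
        elif rng.random() < discordance.error_rate:
            idx = order.index(stage)
            step = 1 if rng.random() < 0.5 else -1
            idx = min(len(order) - 1, max(0, idx + step))
            stage = order[idx]
        rows.append({"case_id": r.case_id, "stage": stage.value})
    df = pd.DataFrame(rows)
    if out_file is not None:
        df.to_csv(out_file, index=False)
    return df
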