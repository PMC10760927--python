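"""Field-completeness and stage-assignability reporting.

Registries differ sharply in which staging inputs they actually receive;
these reports quantify that. A field counts as *available* for a case if
any in-window evidence record populates it, regardless of source tier.
Stage assignability, by contrast, is computed by actually running the
staging engine on evidence restricted to a chosen set of source tiers —
emulating jurisdictions that hold only pathology, or pathology plus
admissions, or the full multi-source hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .model import RegistryCase, SourceTier, StagingBasis, StagingWindow, in_window
from .staging import M0Policy, Roman, derive_rd_stage

__all__ = [
    "COMPLETENESS_FIELDS",
    "CompletenessReport",
    "field_completeness",
    "rd_stage_completeness",
    "completeness_table",
]

#: Report rows, in display order, with the predicate that marks a single
#: evidence record as populating the field.
_RECORD_FIELDS = {
    "lymph_nodes_taken": lambda r: r.nodes_examined is not None,
    "lymph_nodes_positive": lambda r: r.nodes_positive is not None,
    "staging_basis": lambda r: r.staging_basis is not StagingBasis.UNKNOWN,
    "tnm_t": lambda r: r.t_statement is not None,
    "tnm_n": lambda r: r.n_statement is not None,
    "tnm_m": lambda r: r.m_statement is not None,
    "tumour_size": lambda r: r.tumour_size_mm is not None,
    "stage_group": lambda r: r.stage_statement is not None,
}

COMPLETENESS_FIELDS = list(_RECORD_FIELDS) + ["degree_of_spread"]


@dataclass
class CompletenessReport:
    n_cases: int
    field_proportions: dict[str, float]
    rd_stage_assignable: float
    post_neoadjuvant: float
    tier_set: frozenset[SourceTier]
    group_label: Optional[str] = None

    def to_series(self) -> pd.Series:
        data = dict(self.field_proportions)
        data["rd_stage_assignable"] = self.rd_stage_assignable
        data["post_neoadjuvant"] = self.post_neoadjuvant
        data["n_cases"] = self.n_cases
        return pd.Series(data, name=self.group_label or "all")


def _restrict(case: RegistryCase, tier_set: frozenset[SourceTier]) -> RegistryCase:
    return case.model_copy(
        update={"evidence": [r for r in case.evidence if r.tier in tier_set]}
    )


ALL_TIERS = frozenset(SourceTier)


def field_completeness(
    cases: Iterable[RegistryCase],
    window: StagingWindow | None = None,
    policy: M0Policy | None = None,
    tier_set: frozenset[SourceTier] | None = None,
    group_label: str | None = None,
) -> CompletenessReport:
    """Per-field availability plus the proportion of cases stageable.

    Proportions are kept at full precision; round only for display. The
    stage-assignable proportion counts cases whose derived collapsed stage
    is I–IV; post-neoadjuvant cases are tallied separately, not as staged.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("field_completeness requires a non-empty case list")
    window = window or StagingWindow()
    tier_set = frozenset(tier_set) if tier_set is not None else ALL_TIERS

    props: dict[str, float] = {}
    for name, pred in _RECORD_FIELDS.items():
        hit = sum(
            any(
                pred(r)
                for r in c.evidence
                if r.tier in tier_set and in_window(r, c, window)
            )
            for c in cases
        )
        props[name] = hit / len(cases)
    props["degree_of_spread"] = sum(
        c.degree_of_spread is not None for c in cases
    ) / len(cases)

    staged = post_neo = 0
    for c in cases:
        sg, _ = derive_rd_stage(
            _restrict(c, tier_set), window, policy, check_eligibility=False
        )
        if sg.roman in (Roman.I, Roman.II, Roman.III, Roman.IV):
            staged += 1
        elif sg.roman is Roman.POST_NEOADJUVANT:
            post_neo += 1
    return CompletenessReport(
        n_cases=len(cases),
        field_proportions=props,
        rd_stage_assignable=staged / len(cases),
        post_neoadjuvant=post_neo / len(cases),
        tier_set=tier_set,
        group_label=group_label,
    )


def rd_stage_completeness(
    cases: Iterable[RegistryCase],
    window: StagingWindow | None = None,
    policy: M0Policy | None = None,
    tier_set: frozenset[SourceTier] | None = None,
) -> float:
    """Fraction of cases whose derived collapsed stage is I–IV when the
    engine sees only evidence from ``tier_set``. Monotone in the tier set:
    admitting more sources can only help."""
    return field_completeness(cases, window, policy, tier_set).rd_stage_assignable


def completeness_table(
    cases: Iterable[RegistryCase],
    window: StagingWindow | None = None,
    policy: M0Policy | None = None,
    tier_set: frozenset[SourceTier] | None = None,
    group_by: str | None = None,
) -> pd.DataFrame:
    """Completeness report as a DataFrame, optionally grouped by a case
    attribute (e.g. ``jurisdiction``): one column per group."""
    cases = list(cases)
    if group_by is None:
        return field_completeness(cases, window, policy, tier_set).to_series().to_frame()
    groups: dict[str, list[RegistryCase]] = {}
    for c in cases:
        groups.setdefault(str(getattr(c, group_by)), []).append(c)
    cols = [
        field_completeness(v, window, policy, tier_set, group_label=k)
        for k, v in sorted(groups.items())
    ]
    return pd.DataFrame({s.name: s for s in (c.to_series() for c in cols)})
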