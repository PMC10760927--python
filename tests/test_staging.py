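"""Staging engine: category derivation, stage grouping, policies."""

import datetime as dt
import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from rdstage.model import (
    ResectabilityStatus,
    SourceTier,
    StagingBasis,
    StagingWindow,
)
from rdstage.staging import (
    EligibilityError,
    Group,
    M0Policy,
    M0PolicyKind,
    MCategory,
    NCategory,
    Roman,
    TCategory,
    derive_m,
    derive_n,
    derive_rd_stage,
    derive_t,
    stage_group,
)

from conftest import DIAG, make_case, make_evidence

QLD = M0Policy(kind=M0PolicyKind.QUEENSLAND)


# ---------------------------------------------------------------------------
# independent oracle: transcribed AJCC 8th-edition pancreas tables

def oracle_t_of_size(size_mm: float) -> TCategory:
    """AJCC 8e pancreas T by greatest dimension (arterial involvement aside):
    T1 <=2 cm, T2 >2-4 cm, T3 >4 cm."""
    if size_mm <= 20:
        return TCategory.T1
    if size_mm <= 40:
        return TCategory.T2
    return TCategory.T3


def oracle_n_of_counts(positive: int) -> NCategory:
    """AJCC 8e pancreas N by positive regional nodes: 0/1-3/>=4."""
    if positive == 0:
        return NCategory.N0
    if positive <= 3:
        return NCategory.N1
    return NCategory.N2


def oracle_group(t: TCategory, n: NCategory, m1: bool) -> Group:
    """AJCC 8e pancreas prognostic groups, fully known categories."""
    table = {
        ("T1", "N0"): Group.IA, ("T2", "N0"): Group.IB, ("T3", "N0"): Group.IIA,
        ("T1", "N1"): Group.IIB, ("T2", "N1"): Group.IIB, ("T3", "N1"): Group.IIB,
        ("T1", "N2"): Group.III, ("T2", "N2"): Group.III, ("T3", "N2"): Group.III,
        ("T4", "N0"): Group.III, ("T4", "N1"): Group.III, ("T4", "N2"): Group.III,
    }
    return Group.IV if m1 else table[(t.value, n.value)]


def oracle_lattice_group(t: TCategory, n: NCategory, m: MCategory) -> Group:
    """Brute force over every consistent resolution of X categories."""
    if m is MCategory.M1:
        return Group.IV
    if m is MCategory.UNRESOLVED:
        return Group.UNKNOWN
    ts = [TCategory.T1, TCategory.T2, TCategory.T3, TCategory.T4] \
        if t is TCategory.TX else [t]
    ns = [NCategory.N0, NCategory.N1, NCategory.N2] if n is NCategory.NX else [n]
    groups = {oracle_group(ti, ni, False) for ti in ts for ni in ns}
    return groups.pop() if len(groups) == 1 else Group.UNKNOWN


# ---------------------------------------------------------------------------

class TestDeriveM:
    def test_admission_code_means_m1(self):
        case = make_case(evidence=[make_evidence(
            tier=SourceTier.ADMISSION, icd10am_codes=["C78.7"])])
        assert derive_m(case)[0] is MCategory.M1

    def test_no_evidence_assumed_m0(self):
        assert derive_m(make_case())[0] is MCategory.M0_ASSUMED

    def test_explicit_m0_statement_is_evidenced(self):
        case = make_case(evidence=[make_evidence(m_statement="M0")])
        assert derive_m(case)[0] is MCategory.M0_EVIDENCED

    def test_metastatic_unresectable_means_m1(self):
        case = make_case(evidence=[make_evidence(
            tier=SourceTier.MDT,
            resectability=ResectabilityStatus.METASTATIC_UNRESECTABLE)])
        assert derive_m(case)[0] is MCategory.M1

    def test_queensland_needs_late_clean_admission(self):
        early = make_evidence(tier=SourceTier.ADMISSION, days_after=90,
                              icd10am_codes=["Z51.1"])
        assert derive_m(make_case(evidence=[early]), policy=QLD)[0] \
            is MCategory.UNRESOLVED
        late = make_evidence(tier=SourceTier.ADMISSION, days_after=150,
                             icd10am_codes=["Z51.1"])
        assert derive_m(make_case(evidence=[late]), policy=QLD)[0] \
            is MCategory.M0_ASSUMED

    def test_queensland_lookback_is_strictly_more_than_120_days(self):
        at_120 = make_evidence(tier=SourceTier.ADMISSION, days_after=120,
                               icd10am_codes=["Z51.1"])
        assert derive_m(make_case(evidence=[at_120]), policy=QLD)[0] \
            is MCategory.UNRESOLVED

    def test_c77_configurable_as_regional(self):
        case = make_case(evidence=[make_evidence(
            tier=SourceTier.ADMISSION, icd10am_codes=["C77.2"])])
        assert derive_m(case)[0] is MCategory.M1
        lenient = M0Policy(c77_is_distant=False)
        assert derive_m(case, policy=lenient)[0] is MCategory.M0_ASSUMED


class TestDeriveN:
    @pytest.mark.parametrize("positive", range(0, 21))
    def test_counts_match_nodal_oracle(self, positive):
        case = make_case(evidence=[make_evidence(
            nodes_examined=25, nodes_positive=positive)])
        assert derive_n(case)[0] is oracle_n_of_counts(positive)

    def test_zero_positive_without_examined_is_nx(self):
        case = make_case(evidence=[make_evidence(nodes_positive=0)])
        assert derive_n(case)[0] is NCategory.NX

    def test_no_evidence_is_nx(self):
        assert derive_n(make_case())[0] is NCategory.NX

    def test_explicit_statement_outranks_counts(self):
        case = make_case(evidence=[
            make_evidence(tier=SourceTier.MDT, n_statement="N2"),
            make_evidence(nodes_examined=12, nodes_positive=1),
        ])
        n, tier = derive_n(case)
        assert n is NCategory.N2 and tier is SourceTier.MDT


class TestDeriveT:
    @pytest.mark.parametrize("size", list(range(1, 101, 3)) + [20, 40, 41])
    def test_size_matches_dimension_oracle(self, size):
        case = make_case(evidence=[make_evidence(tumour_size_mm=size)])
        assert derive_t(case)[0] is oracle_t_of_size(size)

    def test_arterial_involvement_defines_t4_despite_size(self):
        case = make_case(evidence=[make_evidence(
            tumour_size_mm=55, arterial_involvement=True)])
        assert derive_t(case)[0] is TCategory.T4

    def test_subcategory_statements_collapse(self):
        case = make_case(evidence=[make_evidence(t_statement="T1c")])
        assert derive_t(case)[0] is TCategory.T1

    def test_no_evidence_is_tx(self):
        assert derive_t(make_case())[0] is TCategory.TX


class TestStageGroup:
    def test_exhaustive_lattice_agrees_with_brute_force_oracle(self):
        """All 80 (t, n, m) combinations, including every X resolution."""
        for t, n, m in itertools.product(TCategory, NCategory, MCategory):
            assert stage_group(t, n, m).group is oracle_lattice_group(t, n, m), \
                (t, n, m)

    @pytest.mark.parametrize(
        "t, n, m, expected",
        [
            (TCategory.T1, NCategory.N0, MCategory.M0_ASSUMED, Group.IA),
            (TCategory.TX, NCategory.NX, MCategory.M1, Group.IV),
            (TCategory.TX, NCategory.N2, MCategory.M0_EVIDENCED, Group.III),
            (TCategory.T1, NCategory.NX, MCategory.M0_ASSUMED, Group.UNKNOWN),
        ],
    )
    def test_reference_points(self, t, n, m, expected):
        assert stage_group(t, n, m).group is expected

    def test_m1_dominance(self):
        for t in TCategory:
            for n in NCategory:
                assert stage_group(t, n, MCategory.M1).roman is Roman.IV

    def test_monotone_in_resolved_categories(self):
        """With the other categories fixed and known, worsening one never
        lowers the collapsed stage."""
        order = [Roman.I, Roman.II, Roman.III, Roman.IV]
        ts = [TCategory.T1, TCategory.T2, TCategory.T3, TCategory.T4]
        ns = [NCategory.N0, NCategory.N1, NCategory.N2]
        ms = [MCategory.M0_EVIDENCED, MCategory.M1]
        def rank(sg):
            return order.index(sg.roman)
        for n in ns:
            for m in ms:
                r = [rank(stage_group(t, n, m)) for t in ts]
                assert r == sorted(r)
        for t in ts:
            for m in ms:
                r = [rank(stage_group(t, n, m)) for n in ns]
                assert r == sorted(r)
        for t in ts:
            for n in ns:
                r = [rank(stage_group(t, n, m)) for m in ms]
                assert r == sorted(r)


class TestDeriveRdStage:
    def test_metastatic_admission_shortcuts_to_iv(self):
        case = make_case(evidence=[make_evidence(
            tier=SourceTier.ADMISSION, icd10am_codes=["C79.9"])])
        sg, tnm = derive_rd_stage(case)
        assert sg.group is Group.IV
        assert tnm.n is NCategory.NX and tnm.t is TCategory.TX  # never derived
        assert tnm.provenance_m is SourceTier.ADMISSION

    def test_pathology_documented_case(self):
        case = make_case(evidence=[make_evidence(
            t_statement="T2", n_statement="N1", m_statement="M0",
            staging_basis=StagingBasis.PATHOLOGICAL)])
        sg, tnm = derive_rd_stage(case)
        assert sg.group is Group.IIB and sg.roman is Roman.II
        assert tnm.staging_basis == "PATHOLOGICAL"

    def test_no_evidence_is_unknown(self):
        sg, tnm = derive_rd_stage(make_case())
        assert sg.group is Group.UNKNOWN
        assert (tnm.t, tnm.n, tnm.m) == (
            TCategory.TX, NCategory.NX, MCategory.M0_ASSUMED)

    def test_ineligible_case_raises(self):
        case = make_case(histology="8240/3")  # neuroendocrine
        with pytest.raises(EligibilityError):
            derive_rd_stage(case)

    def test_post_neoadjuvant_terminal_state(self):
        treat = DIAG + dt.timedelta(days=20)
        case = make_case(
            neoadjuvant_before_pathology=True,
            first_treatment_date=treat,
            evidence=[make_evidence(days_after=80, t_statement="T2",
                                    n_statement="N0", m_statement="M0")],
        )
        sg, tnm = derive_rd_stage(case)
        assert sg.group is Group.POST_NEOADJUVANT and tnm.post_neoadjuvant

    def test_stage_statement_used_only_without_component_evidence(self):
        stmt = make_evidence(tier=SourceTier.MDT, stage_statement="IIA")
        sg, tnm = derive_rd_stage(make_case(evidence=[stmt]))
        assert sg.group is Group.IIA and tnm.stage_statement_used
        # with component evidence present, derivation wins
        sg2, tnm2 = derive_rd_stage(make_case(evidence=[
            stmt, make_evidence(t_statement="T1", n_statement="N0",
                                m_statement="M0")]))
        assert sg2.group is Group.IA and not tnm2.stage_statement_used

    def test_tier_rank_resolves_conflicts(self):
        case = make_case(evidence=[
            make_evidence(tier=SourceTier.IMAGING, t_statement="T3"),
            make_evidence(tier=SourceTier.MDT, t_statement="T1"),
        ])
        t, tier = derive_t(case)
        assert t is TCategory.T1 and tier is SourceTier.MDT

    def test_order_independence(self):
        """Shuffling the evidence list never changes the derived stage."""
        base = [
            make_evidence(tier=SourceTier.MDT, n_statement="N1"),
            make_evidence(tier=SourceTier.PATHOLOGY, tumour_size_mm=33,
                          nodes_examined=10, nodes_positive=2),
            make_evidence(tier=SourceTier.ADMISSION, icd10am_codes=["K86.2"]),
            make_evidence(tier=SourceTier.IMAGING, t_statement="T4"),
            make_evidence(tier=SourceTier.ONCOLOGY_SYSTEM, m_statement="M0"),
        ]
        rng = random.Random(7)
        reference = derive_rd_stage(make_case(evidence=list(base)))[0]
        for _ in range(20):
            shuffled = list(base)
            rng.shuffle(shuffled)
            assert derive_rd_stage(make_case(evidence=shuffled))[0] == reference


@settings(deadline=None, max_examples=60)
@given(data=st.data())
def test_queensland_never_assumes_m0_with_metastatic_admission(data):
    """Safety invariant of the strict policy: any C77-C79 coded admission,
    whatever its date, forbids an (assumed or evidenced) M0."""
    n_records = data.draw(st.integers(min_value=1, max_value=6))
    evidence = []
    has_met_admission = False
    for i in range(n_records):
        tier = data.draw(st.sampled_from(list(SourceTier)), label=f"tier{i}")
        days = data.draw(st.integers(min_value=-10, max_value=400),
                         label=f"days{i}")
        codes = data.draw(
            st.lists(st.sampled_from(
                ["C78.7", "C79.9", "C77.1", "K86.2", "Z51.1"]), max_size=2),
            label=f"codes{i}")
        rec = make_evidence(tier=tier, days_after=days, icd10am_codes=codes)
        if tier is SourceTier.ADMISSION and any(
                c.category in {"C77", "C78", "C79"} for c in rec.icd10am_codes):
            has_met_admission = True
        evidence.append(rec)
    m, _ = derive_m(make_case(evidence=evidence), policy=QLD)
    if has_met_admission:
        assert not m.is_m0
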