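"""Inter-registry stage agreement: matching, cross-tabulation, statistics.

Validates one stage assignment (e.g. registry-derived stage) against a
reference assignment (e.g. a clinical quality registry) after exact-ID
deterministic matching. Pairs where either side is Unknown or
post-neoadjuvant are excluded from the 4x4 cross-tabulation but tallied.

Two agreement statistics over the ordinal stages I < II < III < IV are
provided. The default is the tie-corrected Kendall rank correlation
(tau-b), which is what reproduces the published concordance value on the
bundled validation pairs; Kendall's coefficient of concordance W for two
raters (tie-corrected) is available behind ``variant="w"``. Significance
is assessed by a seeded permutation test rather than the asymptotic null,
which is unreliable under heavy ties.

A reconstruction of a published 229-pair validation cross-tabulation of
registry-derived versus clinical stage for pancreatic carcinoma ships as
a package fixture (:func:`load_validation_pairs`); every statistic here is
invariant to pair order, so the reconstruction loses nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, rankdata

from .staging import Roman

__all__ = [
    "StagePair",
    "MatchResult",
    "ConcordanceReport",
    "match_pairs",
    "cross_tabulate",
    "percent_agreement",
    "kendall_coefficient",
    "load_validation_pairs",
    "DegenerateInputError",
]

STAGES = [Roman.I, Roman.II, Roman.III, Roman.IV]
_ORD = {Roman.I: 1, Roman.II: 2, Roman.III: 3, Roman.IV: 4}


class DegenerateInputError(ValueError):
    """The statistic is undefined on this input (no variation / no pairs)."""


@dataclass(frozen=True)
class StagePair:
    case_id: str
    stage_a: Roman
    stage_b: Roman


@dataclass
class MatchResult:
    pairs: list[StagePair]
    unmatched_a: int
    unmatched_b: int


@dataclass
class ConcordanceReport:
    cross_tab: pd.DataFrame  # 4x4 counts, rows = assignment A, cols = B
    n_compared: int
    n_equal: int
    n_under: int  # stage_a < stage_b
    n_over: int  # stage_a > stage_b
    unknown_a: int
    unknown_b: int
    post_neoadjuvant_a: int
    post_neoadjuvant_b: int

    @property
    def n_discordant(self) -> int:
        return self.n_compared - self.n_equal

    def to_dict(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "n_equal": self.n_equal,
            "n_discordant": self.n_discordant,
            "n_under": self.n_under,
            "n_over": self.n_over,
            "unknown_a": self.unknown_a,
            "unknown_b": self.unknown_b,
            "post_neoadjuvant_a": self.post_neoadjuvant_a,
            "post_neoadjuvant_b": self.post_neoadjuvant_b,
            "cross_tab": self.cross_tab.to_dict(),
        }


def _as_roman(v) -> Roman:
    return v if isinstance(v, Roman) else Roman(str(v).strip().upper())


def match_pairs(
    assignments_a: Mapping[str, Roman | str],
    assignments_b: Mapping[str, Roman | str],
) -> MatchResult:
    """Exact-identifier inner join of two stage assignments.

    Inputs are mappings case_id -> stage (or anything with ``.items()``);
    duplicate identifiers within one input raise, naming the identifier.
    """
    a = dict(_checked_items(assignments_a, "a"))
    b = dict(_checked_items(assignments_b, "b"))
    shared = sorted(a.keys() & b.keys())
    pairs = [
        StagePair(cid, _as_roman(a[cid]), _as_roman(b[cid])) for cid in shared
    ]
    return MatchResult(
        pairs=pairs,
        unmatched_a=len(a) - len(shared),
        unmatched_b=len(b) - len(shared),
    )


def _checked_items(assignments, label):
    if hasattr(assignments, "items"):
        return list(assignments.items())
    seen = {}
    for cid, stage in assignments:
        if cid in seen:
            raise ValueError(f"duplicate case_id {cid!r} in assignments_{label}")
        seen[cid] = stage
    return list(seen.items())


def cross_tabulate(pairs: Iterable[StagePair]) -> ConcordanceReport:
    """4x4 cross-tabulation over stages I–IV plus side tallies.

    Unknown and post-neoadjuvant assignments on either side remove the
    pair from the comparison but are counted in the report.
    """
    labels = [s.value for s in STAGES]
    tab = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    unk_a = unk_b = pn_a = pn_b = under = over = 0
    for p in pairs:
        if p.stage_a is Roman.UNKNOWN:
            unk_a += 1
        if p.stage_b is Roman.UNKNOWN:
            unk_b += 1
        if p.stage_a is Roman.POST_NEOADJUVANT:
            pn_a += 1
        if p.stage_b is Roman.POST_NEOADJUVANT:
            pn_b += 1
        if p.stage_a in _ORD and p.stage_b in _ORD:
            tab.loc[p.stage_a.value, p.stage_b.value] += 1
            if _ORD[p.stage_a] < _ORD[p.stage_b]:
                under += 1
            elif _ORD[p.stage_a] > _ORD[p.stage_b]:
                over += 1
    return ConcordanceReport(
        cross_tab=tab,
        n_compared=int(tab.to_numpy().sum()),
        n_equal=int(np.trace(tab.to_numpy())),
        n_under=under,
        n_over=over,
        unknown_a=unk_a,
        unknown_b=unk_b,
        post_neoadjuvant_a=pn_a,
        post_neoadjuvant_b=pn_b,
    )


def percent_agreement(report: ConcordanceReport) -> float:
    """Observed agreement, trace/total, as a proportion in [0, 1].

    Display convention is one decimal place as a percentage
    (``100 * percent_agreement``)."""
    if report.n_compared == 0:
        raise DegenerateInputError("no compared pairs: agreement undefined")
    return report.n_equal / report.n_compared


def _kendall_w_two_raters(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected Kendall coefficient of concordance W for two raters."""
    n = len(x)
    rx, ry = rankdata(x), rankdata(y)
    r_sum = rx + ry
    s = np.sum((r_sum - r_sum.mean()) ** 2)

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return float(np.sum(counts**3 - counts))

    denom = 4 * (n**3 - n) - 2 * (tie_term(x) + tie_term(y))
    if denom <= 0:
        raise DegenerateInputError("all pairs tied on both sides: W undefined")
    return float(12 * s / denom)


def kendall_coefficient(
    pairs: Iterable[StagePair],
    variant: str = "tau-b",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Ordinal concordance between the two stage assignments.

    Parameters
    ----------
    variant
        ``"tau-b"`` (default): tie-corrected Kendall rank correlation —
        this is the variant that reproduces the published value on the
        bundled validation pairs. ``"w"``: tie-corrected Kendall
        coefficient of concordance for two raters (0 at perfect
        disagreement, 1 at perfect agreement).
    n_permutations, seed
        Size and seed of the permutation null used for the p-value (one
        side's stages permuted, statistic recomputed).

    Returns ``(statistic, p_value)``.
    """
    scored = [
        (p.stage_a, p.stage_b)
        for p in pairs
        if p.stage_a in _ORD and p.stage_b in _ORD
    ]
    if len(scored) < 2:
        raise DegenerateInputError("need at least two compared pairs")
    x = np.array([_ORD[a] for a, _ in scored], dtype=float)
    y = np.array([_ORD[b] for _, b in scored], dtype=float)
    if len(set(x)) == 1 and len(set(y)) == 1:
        raise DegenerateInputError("all pairs tied on both sides")

    if variant == "tau-b":
        stat_fn = lambda u, v: float(kendalltau(u, v).statistic)
    elif variant == "w":
        stat_fn = _kendall_w_two_raters
    else:
        raise ValueError(f"unknown variant {variant!r}; use 'tau-b' or 'w'")
    observed = stat_fn(x, y)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if stat_fn(x, rng.permutation(y)) >= observed:
            hits += 1
    p_value = (hits + 1) / (n_permutations + 1)
    return observed, p_value


def load_validation_pairs(path: Path | str | None = None) -> list[StagePair]:
    """The bundled 229-pair registry-derived vs clinical stage fixture,
    reconstructed from a published validation cross-tabulation (pair order
    is arbitrary; no statistic here depends on it)."""
    if path is None:
        path = resources.files("rdstage") / "data" / "validation_pairs.csv"
    df = pd.read_csv(str(path))
    return [
        StagePair(str(r.case_id), _as_roman(r.stage_a), _as_roman(r.stage_b))
        for r in df.itertuples()
    ]
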