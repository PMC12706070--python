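"""Construct-level combinatorial analyses.

Order effects (forward vs reversed fusions), positional effects, copy-number
effects with inert PF fillers, and additivity of single-domain scores —
each operating on a mapping construct_id -> score from the screen scorer.
Pearson r is used for score-vs-score comparisons throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")  # correlation undefined for constant input
    return float(stats.pearsonr(x, y)[0])

from .library import Construct, PartLibrary


class InsufficientData(ValueError):
    """Raised when too few observations exist for a statistic."""


def _as_series(scores) -> pd.Series:
    s = pd.Series(scores) if not isinstance(scores, pd.Series) else scores
    return s.dropna()


def _n_ads(construct: Construct, library: PartLibrary) -> int:
    return sum(1 for pid in construct.parts if library.get(pid).klass == "AD")


def order_effect_correlation(
    scores,
    library: PartLibrary,
    arity: int,
    require_exact_n_ads: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Pearson r between scores of order-reversed construct pairs.

    Each unordered pair contributes one point (forward listed once);
    palindromic constructs, their own reversal, are excluded. By default
    only all-AD constructs are paired; require_exact_n_ads restricts to
    constructs with exactly that many ADs (e.g. 2 on tripartite data keeps
    two-AD/one-PF fusions, which should behave like bipartite ones).
    """
    s = _as_series(scores)
    rows = []
    seen: set[tuple[str, ...]] = set()
    for cid in s.index:
        c = Construct.from_id(cid)
        if c.arity != arity or c.is_palindromic or c.parts in seen:
            continue
        n_ads = _n_ads(c, library)
        if require_exact_n_ads is None:
            if n_ads != arity:  # default: all-AD constructs only
                continue
        elif n_ads != require_exact_n_ads:
            continue
        rev = c.reverse().construct_id
        if rev not in s.index:
            continue
        seen.add(c.parts)
        seen.add(c.reverse().parts)
        rows.append({"forward": cid, "reverse": rev, "score_forward": s[cid], "score_reverse": s[rev]})
    pairs = pd.DataFrame(rows, columns=["forward", "reverse", "score_forward", "score_reverse"])
    if len(pairs) < 3:
        raise InsufficientData(f"only {len(pairs)} order-reversed pairs available")
    r = _pearson(pairs["score_forward"], pairs["score_reverse"])
    return pairs, r


@dataclass(frozen=True)
class EffectSummary:
    part_id: str
    stratum: int  # position index or copy number
    median_score: float
    n_constructs: int


def position_effect(
    scores, library: PartLibrary, part_id: str, position: int
) -> EffectSummary:
    """Median score of all constructs carrying the AD at a 1-based position.

    Position 1 is closest to the recruitment scaffold. Only ADs are
    evaluated; PFs are considered inert.
    """
    if library.get(part_id).klass != "AD":
        raise ValueError(f"{part_id} is not an AD; positional effects cover ADs only")
    s = _as_series(scores)
    vals = []
    for cid in s.index:
        parts = Construct.from_id(cid).parts
        if position <= len(parts) and parts[position - 1] == part_id:
            vals.append(s[cid])
    if not vals:
        raise InsufficientData(f"no scored constructs with {part_id} at position {position}")
    return EffectSummary(
        part_id=part_id,
        stratum=position,
        median_score=float(pd.Series(vals).median()),
        n_constructs=len(vals),
    )


def copy_number_arrangements(
    part_id: str, k: int, arity: int, fillers: list[str]
) -> list[Construct]:
    """All ordered fusions with exactly k copies of the part, fillers elsewhere.

    There are C(arity, k) * len(fillers)**(arity - k) arrangements; for
    bipartite k=1 with two fillers F1/F2 these are the four constructs
    AD-F1, AD-F2, F1-AD and F2-AD.
    """
    if k > arity:
        raise ValueError(f"cannot place {k} copies in an arity-{arity} fusion")
    if k < 1:
        raise ValueError("k must be >= 1")
    out = []
    for positions in itertools.combinations(range(arity), k):
        rest = [i for i in range(arity) if i not in positions]
        for fill in itertools.product(fillers, repeat=len(rest)):
            parts = [""] * arity
            for i in positions:
                parts[i] = part_id
            for i, f in zip(rest, fill):
                parts[i] = f
            out.append(Construct(tuple(parts)))
    return out


def copy_number_effect(
    scores,
    library: PartLibrary,
    part_id: str,
    k: int,
    arity: int,
    fillers: list[str] | None = None,
) -> EffectSummary:
    """Median score at a given AD copy number, padding with inert PFs."""
    if library.get(part_id).klass != "AD":
        raise ValueError(f"{part_id} is not an AD; copy-number effects cover ADs only")
    if fillers is None:
        fillers = [p.part_id for p in library.fillers]
    arrangements = copy_number_arrangements(part_id, k, arity, fillers)
    s = _as_series(scores)
    vals = [s[c.construct_id] for c in arrangements if c.construct_id in s.index]
    if not vals:
        raise InsufficientData(f"no scored arrangements for {part_id} at copy number {k}")
    return EffectSummary(
        part_id=part_id,
        stratum=k,
        median_score=float(pd.Series(vals).median()),
        n_constructs=len(vals),
    )


def additivity_check(
    single_scores, multi_scores
) -> tuple[pd.DataFrame, float, list[str]]:
    """Predict multi-domain scores as sums of single-domain scores.

    Returns (frame with predicted/observed per construct, Pearson r,
    list of constructs skipped for missing part scores).
    """
    singles = _as_series(single_scores)
    multis = _as_series(multi_scores)
    rows = []
    skipped: list[str] = []
    for cid in multis.index:
        parts = Construct.from_id(cid).parts
        if any(p not in singles.index for p in parts):
            skipped.append(cid)
            continue
        rows.append(
            {
                "construct_id": cid,
                "predicted": float(sum(singles[p] for p in parts)),
                "observed": float(multis[cid]),
            }
        )
    frame = pd.DataFrame(rows, columns=["construct_id", "predicted", "observed"])
    if len(frame) < 3:
        raise InsufficientData("too few constructs with complete part scores")
    r = _pearson(frame["predicted"], frame["observed"])
    return frame, r, skipped


def position_effect_table(
    scores, library: PartLibrary, arity: int
) -> pd.DataFrame:
    """Tidy per-AD, per-position median-score table."""
    rows = []
    for part in library.ads:
        for pos in range(1, arity + 1):
            try:
                e = position_effect(scores, library, part.part_id, pos)
            except InsufficientData:
                continue
            rows.append(
                {
                    "part_id": e.part_id,
                    "position": e.stratum,
                    "median_score": e.median_score,
                    "n_constructs": e.n_constructs,
                }
            )
    return pd.DataFrame(rows, columns=["part_id", "position", "median_score", "n_constructs"])
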