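"""Repeat-element enrichment among expressed RNA elements.

For a repeat of interest, let R be the REs overlapping that repeat and A
the REs overlapping *any* repeat (non-repeat REs never enter the test).
Applying a per-visit expression threshold (median RPKM across the visit's
samples, default 25) yields R_expressed and A_expressed, and

    delta_ratio = R_expressed / A_expressed  -  R / A

measures how the repeat's share of the expressed repeat population shifts
relative to its unthresholded share.  Significance is a one-sided
hypergeometric test in the direction of the sign: drawing A_expressed REs
from a population of A with R marked, an enrichment tests
P(X >= R_expressed) and a depletion P(X <= R_expressed).
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .diff_expression import bh_adjust
from .study_io import ExpressionMatrix, StudyIOError, VISITS

logger = logging.getLogger(__name__)

EXPRESSED_MEDIAN_RPKM = 25.0


def expressed_filter(matrix: ExpressionMatrix, sample_ids,
                     threshold: float = EXPRESSED_MEDIAN_RPKM) -> pd.Index:
    """Features whose median expression across the given samples is at
    least ``threshold`` (boundary inclusive)."""
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise StudyIOError("expressed_filter: empty sample set")
    medians = matrix.data[sample_ids].median(axis=1)
    return matrix.feature_ids[medians >= threshold]


def delta_ratio(R: int, A: int, R_expressed: int, A_expressed: int) -> float:
    """Shift in the repeat's share of the expressed repeat population."""
    if A <= 0:
        raise StudyIOError("delta_ratio: no repeat-associated REs (A = 0)")
    if A_expressed <= 0:
        raise StudyIOError(
            "delta_ratio: no expressed repeat-associated REs (A_expressed = 0)")
    if not (0 <= R_expressed <= min(R, A_expressed) and R <= A):
        raise StudyIOError("delta_ratio: inconsistent counts")
    return R_expressed / A_expressed - R / A


def hypergeom_test(R: int, A: int, R_expressed: int, A_expressed: int,
                   direction: str) -> float:
    """One-sided hypergeometric P in the stated direction.

    Population A with R marked; A_expressed draws without replacement;
    ``enriched`` tests P(X >= R_expressed), ``depleted`` P(X <= R_expressed),
    ``none`` returns 1 by convention.
    """
    if direction == "none":
        return 1.0
    dist = stats.hypergeom(A, R, A_expressed)
    if direction == "enriched":
        return float(dist.sf(R_expressed - 1))
    if direction == "depleted":
        return float(dist.cdf(R_expressed))
    raise ValueError(f"unknown direction {direction!r}")


def _names_as_lists(annotation: pd.DataFrame) -> pd.Series:
    names = annotation["repeat_names"]
    return names.map(lambda v: v if isinstance(v, (list, tuple)) else
                     ([] if v in (".", "", None) else str(v).split(",")))


def repeat_universe(annotation: pd.DataFrame) -> tuple[pd.Index, dict[str, pd.Index]]:
    """The repeat-associated universe A and the per-repeat member sets R."""
    names = _names_as_lists(annotation)
    has_repeat = names.map(len) > 0
    universe = annotation.index[has_repeat]
    members: dict[str, list] = {}
    for re_id, reps in names[has_repeat].items():
        for rep in reps:
            members.setdefault(rep, []).append(re_id)
    return universe, {rep: pd.Index(ids) for rep, ids in members.items()}


def _sweep(annotation: pd.DataFrame, expressed: set, arm: str, visit: str,
           re_class: str | None) -> list[dict]:
    universe, members = repeat_universe(annotation)
    if re_class is not None:
        keep = annotation.loc[universe, "re_class"] == re_class
        universe = universe[keep.to_numpy()]
        members = {rep: ids[ids.isin(universe)] for rep, ids in members.items()}
    A = len(universe)
    A_expressed = sum(1 for re_id in universe if re_id in expressed)
    rows = []
    for rep, ids in sorted(members.items()):
        R = len(ids)
        if R == 0 or A == 0:
            logger.info("repeat %r: no members in universe (%s %s), skipped",
                        rep, arm, visit)
            continue
        if A_expressed == 0:
            logger.info("no expressed repeat REs at %s %s; sweep skipped", arm, visit)
            break
        R_expressed = sum(1 for re_id in ids if re_id in expressed)
        delta = delta_ratio(R, A, R_expressed, A_expressed)
        direction = "enriched" if delta > 0 else ("depleted" if delta < 0 else "none")
        rows.append({
            "arm": arm, "visit": visit, "repeat_name": rep,
            "re_class": re_class or "all",
            "R": R, "A": A, "R_expressed": R_expressed, "A_expressed": A_expressed,
            "delta_ratio": delta, "direction": direction,
            "p_hyper": hypergeom_test(R, A, R_expressed, A_expressed, direction),
        })
    return rows


def enrichment_by_visit(matrix: ExpressionMatrix, samples: pd.DataFrame,
                        annotation: pd.DataFrame,
                        threshold: float = EXPRESSED_MEDIAN_RPKM,
                        stratify_class: bool = False) -> pd.DataFrame:
    """Delta-ratio + hypergeometric sweep for every repeat at every
    arm x visit, optionally stratified by RE class, BH-adjusted within each
    sweep."""
    frames = []
    for (arm, visit), group in samples.groupby(["arm", "visit"], sort=False):
        expressed = set(expressed_filter(matrix, group["sample_id"], threshold))
        classes = (sorted(set(annotation["re_class"])) if stratify_class else [None])
        for re_class in classes:
            rows = _sweep(annotation, expressed, arm, visit, re_class)
            if rows:
                sweep = pd.DataFrame(rows)
                sweep["bh_p"] = bh_adjust(sweep["p_hyper"].to_numpy())
                frames.append(sweep)
    if not frames:
        return pd.DataFrame(columns=["arm", "visit", "repeat_name", "re_class",
                                     "R", "A", "R_expressed", "A_expressed",
                                     "delta_ratio", "direction", "p_hyper", "bh_p"])
    out = pd.concat(frames, ignore_index=True)
    order = {v: i for i, v in enumerate(VISITS)}
    return out.sort_values(["arm", "visit", "re_class", "repeat_name"],
                           key=lambda c: c.map(order) if c.name == "visit" else c
                           ).reset_index(drop=True)


def differential_repeat_counts(pattern_calls: pd.DataFrame,
                               annotation: pd.DataFrame) -> pd.DataFrame:
    """Counts of differential REs per repeat per response class.

    An RE overlapping several repeats contributes once to each repeat's
    column (documented double-count across repeats).
    """
    names = _names_as_lists(annotation)
    calls = pattern_calls.set_index("feature_id")["response_class"]
    counts: dict[tuple[str, str], int] = {}
    for re_id, cls in calls.items():
        if cls == "none":
            continue
        for rep in names.get(re_id, []):
            counts[(rep, cls)] = counts.get((rep, cls), 0) + 1
    if not counts:
        return pd.DataFrame(columns=["repeat_name", "response_class", "n"])
    out = pd.DataFrame(
        [(rep, cls, n) for (rep, cls), n in sorted(counts.items())],
        columns=["repeat_name", "response_class", "n"],
    )
    return out
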