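"""Eight-way expression-pattern classification across the two transitions.

Each feature carries an up/down/ns call for the baseline->crossover
transition (T1) and the crossover->crossback transition (T2).  The eight
significant combinations map onto named response classes:

* acute — changed at T1 only (the immediate response to the drug switch);
* recovery — changed at T2 only (the return switch);
* continuous — same direction at both transitions;
* reversal — an acute change followed by the opposite recovery change.

``(ns, ns)`` maps to ``none``.  The map is a bijection on the eight
non-null combinations.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

RESPONSE_CLASSES = (
    "acute_up", "acute_down", "recovery_up", "recovery_down",
    "continuous_up", "continuous_down", "reversal_up_down", "reversal_down_up",
    "none",
)

PATTERN_MAP = {
    ("up", "ns"): "acute_up",
    ("down", "ns"): "acute_down",
    ("ns", "up"): "recovery_up",
    ("ns", "down"): "recovery_down",
    ("up", "up"): "continuous_up",
    ("down", "down"): "continuous_down",
    ("up", "down"): "reversal_up_down",
    ("down", "up"): "reversal_down_up",
    ("ns", "ns"): "none",
}


def classify_pattern(call_t1: str, call_t2: str) -> str:
    """Map one (T1, T2) call pair to its response class."""
    try:
        return PATTERN_MAP[(call_t1, call_t2)]
    except KeyError:
        raise ValueError(f"unknown call pair ({call_t1!r}, {call_t2!r})") from None


def classify_patterns(results_t1: pd.DataFrame,
                      results_t2: pd.DataFrame) -> pd.DataFrame:
    """Join two per-transition result tables into per-feature pattern calls."""
    t1 = results_t1.set_index("feature_id")["call"]
    t2 = results_t2.set_index("feature_id")["call"]
    if not t1.index.equals(t2.index):
        raise ValueError("T1 and T2 results cover different feature sets")
    classes = [classify_pattern(a, b) for a, b in zip(t1, t2)]
    return pd.DataFrame({
        "feature_id": t1.index,
        "call_t1": t1.to_numpy(),
        "call_t2": t2.to_numpy(),
        "response_class": classes,
    })


def summarize_patterns(pattern_calls: pd.DataFrame,
                       annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Contingency table of response classes by RE class.

    Features absent from the annotation are counted under ``unannotated``.
    The returned table carries ``frac_both_transitions`` in ``attrs``: the
    fraction of features altered in *both* transitions among all features
    altered in at least one.
    """
    calls = pattern_calls.copy()
    if annotation is not None:
        re_class = annotation["re_class"]
        calls["re_class"] = (
            calls["feature_id"].map(re_class).fillna("unannotated")
        )
    else:
        calls["re_class"] = "all"
    table = (
        calls.pivot_table(index="response_class", columns="re_class",
                          values="feature_id", aggfunc="count", fill_value=0)
        .reindex(RESPONSE_CLASSES, fill_value=0)
    )
    table["total"] = table.sum(axis=1)

    non_ns = (calls["call_t1"] != "ns") | (calls["call_t2"] != "ns")
    both = (calls["call_t1"] != "ns") & (calls["call_t2"] != "ns")
    n_any = int(non_ns.sum())
    table.attrs["frac_both_transitions"] = float(both.sum() / n_any) if n_any else 0.0
    logger.info("pattern summary: %d altered features, %.1f%% in both transitions",
                n_any, 100 * table.attrs["frac_both_transitions"])
    return table
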