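"""Evaluation of single-descriptor classifiers.

Confusion-matrix bookkeeping, the six standard binary-classification metrics
(sensitivity, specificity, the two predictive values, global accuracy and the
Matthews correlation coefficient), an exhaustive-threshold grid search for
the best cutoff of one descriptor, and ranking of a whole descriptor table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drugfilters import Direction, ThresholdFilter


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ClassificationMetrics:
    """SE = TP/(TP+FN), SP = TN/(TN+FP), PRE1 = TP/(TP+FP),
    PRE2 = TN/(TN+FN), GA = (TP+TN)/total and the Matthews coefficient
    C = (TP*TN - FN*FP)/sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP)).

    Metrics with a zero denominator are NaN and listed in ``undefined``.
    """
    SE: float
    SP: float
    PRE1: float
    PRE2: float
    GA: float
    C: float
    undefined: frozenset[str] = frozenset()


def confusion(predicted: list[bool], labels: list[bool]) -> ConfusionCounts:
    """2x2 tally; label True = drug-like reference class."""
    if len(predicted) != len(labels):
        raise ValueError("predicted and labels differ in length")
    if not labels:
        raise ValueError("empty input")
    tp = tn = fp = fn = 0
    for p, y in zip(predicted, labels):
        if y:
            tp += p
            fn += not p
        else:
            fp += p
            tn += not p
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(cc: ConfusionCounts) -> ClassificationMetrics:
    if cc.total == 0:
        raise ValueError("empty confusion table")
    undefined: set[str] = set()

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    se = ratio(cc.TP, cc.TP + cc.FN, "SE")
    sp = ratio(cc.TN, cc.TN + cc.FP, "SP")
    pre1 = ratio(cc.TP, cc.TP + cc.FP, "PRE1")
    pre2 = ratio(cc.TN, cc.TN + cc.FN, "PRE2")
    ga = (cc.TP + cc.TN) / cc.total
    denom = (cc.TP + cc.FN) * (cc.TP + cc.FP) * (cc.TN + cc.FN) * (cc.TN + cc.FP)
    if denom == 0:
        undefined.add("C")
        c = math.nan
    else:
        c = (cc.TP * cc.TN - cc.FN * cc.FP) / math.sqrt(denom)
    return ClassificationMetrics(se, sp, pre1, pre2, ga, c, frozenset(undefined))


def _score(cc: ConfusionCounts, criterion: str) -> float:
    m = metrics(cc)
    val = getattr(m, criterion)
    return -math.inf if math.isnan(val) else val


def grid_search_threshold(
    values_pos: np.ndarray,
    values_neg: np.ndarray,
    direction: str | Direction = "auto",
    criterion: str = "GA",
) -> tuple[ThresholdFilter, ClassificationMetrics, int]:
    """Best single cutoff separating the positive from the negative class.

    Candidate cutoffs are the midpoints of adjacent distinct pooled values
    plus one cutoff below and one above the data range — equivalent to an
    exhaustive threshold scan, which dominates any fixed-step grid.  NaN
    (flagged-undefined) values are excluded; their count is returned.  Ties
    break toward the smaller cutoff, then toward below-is-positive.
    Descriptor-name in the returned filter is a placeholder ("FASA-" slot is
    filled by :func:`rank_descriptors`).
    """
    if criterion not in ("GA", "C"):
        raise ValueError("criterion must be GA or C")
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    n_excluded = int(np.isnan(pos).sum() + np.isnan(neg).sum())
    pos = np.sort(pos[~np.isnan(pos)])
    neg = np.sort(neg[~np.isnan(neg)])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("a class has no defined values")

    pooled = np.unique(np.concatenate([pos, neg]))
    if pooled.size == 1:
        cuts = np.array([pooled[0] - 1.0, pooled[0] + 1.0])
    else:
        mids = (pooled[:-1] + pooled[1:]) / 2.0
        cuts = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])

    if isinstance(direction, Direction):
        directions = [direction]
    elif direction == "auto":
        directions = [Direction.BELOW_IS_POSITIVE, Direction.ABOVE_IS_POSITIVE]
    else:
        directions = [Direction(direction)]

    n_pos, n_neg = pos.size, neg.size
    best = None
    for cut in cuts:
        # counts of values strictly below the cutoff
        p_below = int(np.searchsorted(pos, cut, side="left"))
        n_below = int(np.searchsorted(neg, cut, side="left"))
        for d in directions:
            if d == Direction.BELOW_IS_POSITIVE:
                cc = ConfusionCounts(TP=p_below, FN=n_pos - p_below,
                                     FP=n_below, TN=n_neg - n_below)
            else:
                # above-is-positive with strict inequality: ties negative
                p_above = n_pos - int(np.searchsorted(pos, cut, side="right"))
                n_above = n_neg - int(np.searchsorted(neg, cut, side="right"))
                cc = ConfusionCounts(TP=p_above, FN=n_pos - p_above,
                                     FP=n_above, TN=n_neg - n_above)
            key = (_score(cc, criterion), -cut, d == Direction.BELOW_IS_POSITIVE)
            if best is None or key > best[0]:
                best = (key, cut, d, cc)

    _, cut, d, cc = best
    return ThresholdFilter("FASA-", float(cut), d), metrics(cc), n_excluded


def rank_descriptors(
    table_pos: pd.DataFrame,
    table_neg: pd.DataFrame,
    criterion: str = "GA",
    descriptors: list[str] | None = None,
) -> pd.DataFrame:
    """Grid-search every descriptor column and rank by the criterion.

    ``table_pos``/``table_neg`` are descriptor tables (NaN = flagged
    undefined) for the positive (drug-like) and negative reference sets.
    Returns one row per descriptor, sorted by the criterion descending, with
    the best cutoff/direction and the full metric set.
    """
    if descriptors is None:
        descriptors = [c for c in table_pos.columns
                       if c in table_neg.columns
                       and pd.api.types.is_numeric_dtype(table_pos[c])]
    if not descriptors:
        raise ValueError("no descriptor columns to rank")
    rows = []
    for name in descriptors:
        try:
            f, m, n_excl = grid_search_threshold(
                table_pos[name].to_numpy(), table_neg[name].to_numpy(),
                direction="auto", criterion=criterion,
            )
        except ValueError:
            continue  # a class entirely undefined for this descriptor
        pos_vals = table_pos[name].to_numpy(dtype=float)
        neg_vals = table_neg[name].to_numpy(dtype=float)
        pos_vals = pos_vals[~np.isnan(pos_vals)]
        neg_vals = neg_vals[~np.isnan(neg_vals)]
        pred_pos = _apply(pos_vals, f)
        pred_neg = _apply(neg_vals, f)
        cc = ConfusionCounts(
            TP=int(pred_pos.sum()), FN=int((~pred_pos).sum()),
            FP=int(pred_neg.sum()), TN=int((~pred_neg).sum()),
        )
        rows.append({
            "descriptor": name, "direction": f.direction.value,
            "cutoff": f.cutoff, "n_excluded": n_excl,
            "TP": cc.TP, "TN": cc.TN, "FP": cc.FP, "FN": cc.FN,
            "SE": m.SE, "SP": m.SP, "PRE1": m.PRE1, "PRE2": m.PRE2,
            "GA": m.GA, "C": m.C,
        })
    df = pd.DataFrame(rows)
    return df.sort_values(criterion, ascending=False, kind="stable").reset_index(drop=True)


def _apply(values: np.ndarray, f: ThresholdFilter) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        if f.direction == Direction.BELOW_IS_POSITIVE:
            out = values < f.cutoff
        else:
            out = values > f.cutoff
    out[np.isnan(values)] = False
    return out
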