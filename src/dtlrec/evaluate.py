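"""Scoring predicted event sets against true simulated histories.

Only the events that make a gene history differ from the species history
are scored -- duplications, transfers and losses -- and only by their
species-tree location: a D matches on its branch, a T on its (donor,
receiver) branch pair, an L on the branch where the copy was lost; the
position in the gene tree is deliberately ignored.  Composite events
decompose: a TL yields one T component plus one L component on the donor
branch, an SL yields one L component on the non-surviving child branch.

With multiset matching, TP = sum over keys of min(predicted, true)
multiplicities, FP = |predicted| - TP, FN = |true| - TP.  The headline
error is the symmetric evolutionary distance D_DTL = FP + FN; precision =
TP/(TP+FP) and recall = TP/(TP+FN) support precision-recall curves over
support-filtering thresholds (true negatives are not computable in this
setting, ruling ROC curves out).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .support import EventKey
from .trees_io import DatedSpeciesTree

__all__ = [
    "EvalResult",
    "eval_components",
    "classify_events",
    "pr_curve",
    "paired_mean_difference",
]


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def d_dtl(self) -> int:
        """Symmetric evolutionary distance FP + FN."""
        return self.fp + self.fn

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None


def eval_components(
    keys: Iterable[EventKey], S: DatedSpeciesTree
) -> Counter:
    """Decompose reconciliation events into location-only D/T/L components.

    S events are not scored; SL needs the species tree to name the lost
    (non-surviving) child branch.
    """
    sibling = {}
    for i, ch in enumerate(S.children):
        if ch:
            a, b = ch
            sibling[(S.ids[i], S.ids[a])] = S.ids[b]
            sibling[(S.ids[i], S.ids[b])] = S.ids[a]
    out: Counter = Counter()
    for k in keys:
        if k.etype == "D":
            out[("D", k.where)] += 1
        elif k.etype == "T":
            out[("T", k.where, k.extra)] += 1
        elif k.etype == "TL":
            out[("T", k.where, k.extra)] += 1
            out[("L", k.where)] += 1
        elif k.etype == "SL":
            out[("L", sibling[(k.where, k.extra)])] += 1
        elif k.etype != "S":
            raise ValueError(f"cannot score event type {k.etype}")
    return out


def classify_events(predicted: Counter, truth: Counter) -> EvalResult:
    """TP/FP/FN between two D/T/L component multisets."""
    tp = sum((predicted & truth).values())
    return EvalResult(
        tp=tp,
        fp=sum(predicted.values()) - tp,
        fn=sum(truth.values()) - tp,
    )


def pr_curve(
    families: list[tuple[Mapping[EventKey, float], Counter]],
    thresholds: Iterable[float],
    S: DatedSpeciesTree,
    per_family: bool = False,
) -> list[dict]:
    """Precision/recall at each support threshold, pooled across families.

    Each family is (predicted events with their supports, true component
    multiset).  At a threshold T the prediction keeps events with support
    >= T; families whose filtered prediction is empty are excluded at that
    threshold (their precision is undefined).  ``per_family=True`` averages
    per-family precision/recall instead of pooling counts.
    """
    if not families:
        raise ValueError("need at least one family")
    rows = []
    for thr in thresholds:
        picked = []
        for supports, truth in families:
            keys = [k for k, f in supports.items() if f >= thr]
            comp = eval_components(keys, S)
            if not comp:
                continue
            picked.append(classify_events(comp, truth))
        if not picked:
            rows.append(
                {"threshold": thr, "precision": None, "recall": None, "n_families": 0}
            )
            continue
        if per_family:
            precs = [r.precision for r in picked if r.precision is not None]
            recs = [r.recall for r in picked if r.recall is not None]
            prec = sum(precs) / len(precs) if precs else None
            rec = sum(recs) / len(recs) if recs else None
        else:
            tp = sum(r.tp for r in picked)
            fp = sum(r.fp for r in picked)
            fn = sum(r.fn for r in picked)
            prec = tp / (tp + fp) if tp + fp else None
            rec = tp / (tp + fn) if tp + fn else None
        rows.append(
            {
                "threshold": thr,
                "precision": prec,
                "recall": rec,
                "n_families": len(picked),
            }
        )
    return rows


def paired_mean_difference(a: list[float], b: list[float]) -> dict:
    """Paired t-test convenience for comparing per-family errors of two
    strategies; returns mean difference, t statistic and p-value."""
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two equal-length samples, n >= 2")
    from scipy import stats

    t, p = stats.ttest_rel(a, b)
    diff = sum(x - y for x, y in zip(a, b)) / len(a)
    return {"mean_difference": diff, "t": float(t), "p_value": float(p)}
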