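"""Evaluation metrics and matching rules.

Covers per-residue confusion metrics (precision, recall/TPR, FPR, MCC,
accuracy), helix-level matching between predicted and known helices with
the 10-residue-overlap rule and its false-positive/true-negative
asymmetry, per-chain topology correctness, and stoichiometry agreement
statistics.

Helix matching asymmetry: a predicted helix that overlaps no known helix
by at least ``min_overlap`` residues counts as a false positive *if it
was called pore-lining*, but contributes nothing otherwise — spurious
helices must not inflate the true-negative count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .records import HelixSpan, ValidationError

MIN_OVERLAP = 10


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_calls(cls, y_true: Sequence[bool], y_pred: Sequence[bool]
                   ) -> "ConfusionCounts":
        t = np.asarray(y_true, dtype=bool)
        p = np.asarray(y_pred, dtype=bool)
        if t.shape != p.shape:
            raise ValueError("y_true and y_pred must have equal length")
        return cls(
            tp=int((t & p).sum()), fp=int((~t & p).sum()),
            tn=int((~t & ~p).sum()), fn=int((t & ~p).sum()),
        )


class Metrics(NamedTuple):
    precision: float
    recall: float
    tpr: float
    fpr: float
    mcc: float
    accuracy: float


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def residue_metrics(counts: ConfusionCounts) -> Metrics:
    """Standard confusion-matrix metrics (recall and TPR coincide)."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    accuracy = (tp + tn) / counts.total
    return Metrics(precision=precision, recall=tpr, tpr=tpr, fpr=fpr,
                   mcc=mcc(counts), accuracy=accuracy)


# ---------------------------------------------------------------------------
# Helix-level matching

def _check_disjoint(spans: Sequence[HelixSpan], what: str) -> None:
    ordered = sorted(spans, key=lambda h: h.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValidationError(
                f"{what} helices {a.start}-{a.end} and {b.start}-{b.end} overlap"
            )


def match_helices(predicted: Sequence[HelixSpan], known: Sequence[HelixSpan],
                  min_overlap: int = MIN_OVERLAP,
                  ) -> tuple[list[tuple[int, int]], ConfusionCounts]:
    """Pair predicted with known helices and score pore-lining calls.

    Pairing is greedy one-to-one by descending overlap (ties: earlier
    known start, then earlier predicted start) and requires an overlap of
    at least ``min_overlap`` shared residues. Paired helices are scored
    TP/FP/TN/FN from predicted versus known ``pore_lining``. Unpaired
    predicted helices count as FP only when called pore-lining; unpaired
    known helices count as FN only when labelled pore-lining.

    Returns (pairs, counts) with pairs as (predicted_idx, known_idx).
    """
    _check_disjoint(predicted, "predicted")
    candidates = []
    for pi, p in enumerate(predicted):
        for ki, k in enumerate(known):
            ov = p.overlap(k)
            if ov >= min_overlap:
                candidates.append((ov, k.start, p.start, pi, ki))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_k: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, pi, ki in candidates:
        if pi in used_p or ki in used_k:
            continue
        pairs.append((pi, ki))
        used_p.add(pi)
        used_k.add(ki)

    counts = ConfusionCounts()
    for pi, ki in pairs:
        pred_call = bool(predicted[pi].pore_lining)
        known_call = bool(known[ki].pore_lining)
        if pred_call and known_call:
            counts.tp += 1
        elif pred_call:
            counts.fp += 1
        elif known_call:
            counts.fn += 1
        else:
            counts.tn += 1
    for pi, p in enumerate(predicted):
        if pi not in used_p and p.pore_lining:
            counts.fp += 1  # spurious helix called pore-lining
    for ki, k in enumerate(known):
        if ki not in used_k and k.pore_lining:
            counts.fn += 1  # missed pore-lining helix
    return pairs, counts


def topology_correct(predicted: Sequence[HelixSpan], known: Sequence[HelixSpan],
                     min_overlap: int = MIN_OVERLAP) -> tuple[bool, int]:
    """Whether a chain's helix topology is correct, and the over/under count.

    Correct iff the predicted and known helix counts agree and every known
    helix is paired with a predicted one at >= ``min_overlap`` residues.
    ``over_under`` is n_predicted - n_known.
    """
    pairs, _ = match_helices(predicted, known, min_overlap)
    matched_known = {ki for _, ki in pairs}
    correct = len(predicted) == len(known) and len(matched_known) == len(known)
    return correct, len(predicted) - len(known)


# ---------------------------------------------------------------------------
# Stoichiometry aggregates

@dataclass
class StoichiometrySummary:
    n: int
    n_exact: int
    mean_abs_error: float
    pearson_r: float
    mono_multi_accuracy: float
    false_positive_monomers: int
    multimeric_exact: int
    multimeric_total: int

    @property
    def exact_fraction(self) -> float:
        return self.n_exact / self.n

    def __str__(self) -> str:
        return (
            f"Stoichiometry over {self.n} chains: "
            f"{self.n_exact} exact ({100 * self.exact_fraction:.0f}%), "
            f"MAE {self.mean_abs_error:.2f} subunits, "
            f"Pearson r {self.pearson_r:.2f}, "
            f"mono/multi accuracy {100 * self.mono_multi_accuracy:.0f}%, "
            f"{self.false_positive_monomers} false-positive monomers, "
            f"{self.multimeric_exact}/{self.multimeric_total} multimeric exact"
        )


def stoichiometry_summary(table: pd.DataFrame,
                          observed_col: str = "observed",
                          predicted_col: str = "predicted",
                          ) -> StoichiometrySummary:
    """Agreement statistics between observed and predicted subunit counts."""
    if table[predicted_col].isna().any():
        missing = table.loc[table[predicted_col].isna()].iloc[0]
        chain = missing.get("chain_id", missing.get("target", "<unknown>"))
        raise ValidationError(f"missing prediction for chain {chain}")
    obs = table[observed_col].to_numpy(dtype=int)
    pred = table[predicted_col].to_numpy(dtype=int)
    n = len(obs)
    if n == 0:
        raise ValueError("empty stoichiometry table")
    exact = obs == pred
    multi = obs > 1
    if np.std(obs) == 0 or np.std(pred) == 0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(obs, pred)[0, 1])
    return StoichiometrySummary(
        n=n,
        n_exact=int(exact.sum()),
        mean_abs_error=float(np.abs(obs - pred).mean()),
        pearson_r=pearson,
        mono_multi_accuracy=float(((obs == 1) == (pred == 1)).mean()),
        false_positive_monomers=int((multi & (pred == 1)).sum()),
        multimeric_exact=int((multi & exact).sum()),
        multimeric_total=int(multi.sum()),
    )


def topology_summary(correct_flags: Iterable[int]) -> tuple[int, int, float]:
    """(n_correct, n_total, fraction) from per-chain 0/1 correctness flags."""
    flags = [int(bool(f)) for f in correct_flags]
    n = len(flags)
    return sum(flags), n, (sum(flags) / n if n else float("nan"))
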