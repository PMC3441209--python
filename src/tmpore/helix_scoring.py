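"""Helix-level aggregation and calibration of residue margins.

A helix is called pore-lining when the arithmetic mean of the raw
classifier margins over its residues reaches a slightly elevated
threshold (0.3 rather than 0): between 0 and 0.3, residue-level false
positives contribute excessively to false pore-lining helix calls, so
the raised threshold suppresses them.

For a user-facing likelihood in [0, 1], mean scores within a prediction
batch are converted to Z-scores (subtract the batch mean, divide by the
batch population standard deviation) and passed through the standard
logistic function, posterior = 1 / (1 + exp(-z)). For batches too small
to estimate their own statistics, stored training-batch statistics can
be supplied as a fallback. A two-parameter logistic fitted against known
labels is available as a non-default alternative.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .records import HelixCall, HelixSpan, ResidueScoreTrack

HELIX_THRESHOLD = 0.3


def score_helix(track: ResidueScoreTrack, span: HelixSpan,
                threshold: float = HELIX_THRESHOLD) -> HelixCall:
    """Mean raw margin over the span and the >= threshold call."""
    missing = [i for i in span.residues() if i not in track]
    if missing:
        raise ValueError(
            f"{track.chain_id}: residues {missing[:5]} of helix "
            f"{span.start}-{span.end} have no classifier score"
        )
    mean = float(np.mean([track.score_at(i) for i in span.residues()]))
    return HelixCall(chain_id=track.chain_id, span=span, mean_score=mean,
                     call=mean >= threshold)


def score_helices(track: ResidueScoreTrack, spans: Sequence[HelixSpan],
                  threshold: float = HELIX_THRESHOLD) -> list[HelixCall]:
    return [score_helix(track, s, threshold) for s in spans]


def logistic(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def calibrate(calls: Sequence[HelixCall],
              fallback_stats: Optional[tuple[Optional[float], Optional[float]]] = None,
              ) -> list[HelixCall]:
    """Fill ``zscore`` and ``posterior`` for a batch of helix calls.

    z = (mean_score - batch mean) / batch population sd;
    posterior = standard logistic of z. With fewer than two calls, or a
    zero-variance batch, the fallback (training-batch) statistics are
    used if supplied; otherwise the degenerate batch is an error.
    """
    scores = np.array([c.mean_score for c in calls], dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite mean scores cannot be calibrated")
    mu: Optional[float]
    sigma: Optional[float]
    if len(scores) >= 2 and float(np.std(scores)) > 0:
        mu, sigma = float(np.mean(scores)), float(np.std(scores))
    elif fallback_stats is not None and fallback_stats[0] is not None:
        mu, sigma = fallback_stats  # type: ignore[assignment]
    elif len(scores) < 2:
        raise ValueError("need at least 2 helix calls to calibrate")
    else:
        raise ValueError("zero variance across helix mean scores")
    out = []
    for c in calls:
        z = (c.mean_score - mu) / sigma
        out.append(replace(c, zscore=z, posterior=logistic(z)))
    return out


def fit_logistic_calibration(calls: Sequence[HelixCall],
                             labels: Sequence[bool]) -> tuple[float, float]:
    """Two-parameter logistic fit of P(pore-lining | zscore) (non-default).

    Returns (intercept, slope) for posterior = logistic(a + b*z), fitted
    by logistic regression against known helix labels.
    """
    from sklearn.linear_model import LogisticRegression

    z = np.array([c.zscore for c in calls], dtype=float).reshape(-1, 1)
    if np.any(np.isnan(z)):
        raise ValueError("calls must be calibrated (zscore set) before fitting")
    clf = LogisticRegression(C=1e6)
    clf.fit(z, np.asarray(labels, dtype=int))
    return float(clf.intercept_[0]), float(clf.coef_[0][0])
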