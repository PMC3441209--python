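"""Sliding-window PSSM features and Z-score standardization.

Each transmembrane residue is represented by the 20-column profile rows of
a window of ``window_size`` residues centred on it (default 15, giving a
300-dimensional vector). Window positions falling outside the sequence
contribute all-zero rows. Features are standardized per dimension,
z = (x - mu) / sigma, with mu and sigma estimated on the training
residues only and frozen into the model; the population (divide-by-n)
standard deviation convention is used. Constant features get sigma = 1
and are flagged so the transform maps them to exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .records import ProteinRecord, PssmProfile
from .labeling import DEFAULT_OFFSETS, labelled_residues

DEFAULT_WINDOW = 15


def window_features(profile: PssmProfile, center: int,
                    window_size: int = DEFAULT_WINDOW) -> np.ndarray:
    """Raw feature vector for the residue at 1-based ``center``."""
    if window_size % 2 == 0 or window_size < 1:
        raise ValueError(f"window_size must be odd and positive, got {window_size}")
    L = len(profile)
    if not 1 <= center <= L:
        raise ValueError(f"center {center} outside [1, {L}]")
    w = (window_size - 1) // 2
    out = np.zeros((window_size, 20))
    for k, pos in enumerate(range(center - w, center + w + 1)):
        if 1 <= pos <= L:
            out[k] = profile.scores[pos - 1]
    return out.ravel()


def window_matrix(profile: PssmProfile, centers: Sequence[int],
                  window_size: int = DEFAULT_WINDOW) -> np.ndarray:
    """Stacked raw window vectors for several centre residues."""
    return np.vstack([window_features(profile, c, window_size) for c in centers])


@dataclass
class StandardizationParams:
    """Frozen per-feature mean/sd of the training windows (z = (x-mu)/sigma)."""

    mu: np.ndarray
    sigma: np.ndarray
    constant_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    sd_convention: str = "population"

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.constant_mask is None:
            self.constant_mask = np.zeros_like(self.mu, dtype=bool)
        if np.any(self.sigma <= 0):
            raise ValueError("sigma components must be > 0")


def fit_standardization(vectors: np.ndarray) -> StandardizationParams:
    """Estimate per-feature mu and population sigma from raw vectors."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 vectors to fit standardization")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)  # population convention (ddof=0)
    constant = sigma == 0
    sigma = np.where(constant, 1.0, sigma)
    return StandardizationParams(mu=mu, sigma=sigma, constant_mask=constant)


def apply_standardization(vectors: np.ndarray,
                          params: StandardizationParams) -> np.ndarray:
    """Elementwise (x - mu) / sigma; accepts a single vector or a matrix."""
    X = np.asarray(vectors, dtype=float)
    if X.shape[-1] != params.mu.shape[0]:
        raise ValueError(
            f"dimension mismatch: vector has {X.shape[-1]} features, "
            f"params have {params.mu.shape[0]}"
        )
    return (X - params.mu) / params.sigma


def training_matrix(records: Iterable[ProteinRecord],
                    profiles: Mapping[str, PssmProfile],
                    window_size: int = DEFAULT_WINDOW,
                    expand: bool = True,
                    offsets: Sequence[int] = DEFAULT_OFFSETS,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw window features and labels for all transmembrane residues.

    Returns ``(X, y, chains, centers)`` where ``y`` is the 0/1 pore-lining
    class under the requested label policy, ``chains`` the chain id per
    row, and ``centers`` the 1-based residue index per row.
    """
    blocks, ys, chains, centers = [], [], [], []
    for rec in records:
        profile = profiles[rec.chain_id]
        profile.check_against(rec.sequence)
        labelled = labelled_residues(rec, expand=expand, offsets=offsets)
        if not labelled:
            continue
        idx = [lr.index for lr in labelled]
        blocks.append(window_matrix(profile, idx, window_size))
        ys.extend(int(lr.positive) for lr in labelled)
        chains.extend([rec.chain_id] * len(idx))
        centers.extend(idx)
    if not blocks:
        raise ValueError("no transmembrane residues found in the input records")
    return (np.vstack(blocks), np.asarray(ys, dtype=int),
            np.asarray(chains, dtype=object), np.asarray(centers, dtype=int))
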