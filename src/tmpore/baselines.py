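"""Naive polarity baselines for pore-lining prediction.

Pore-lining faces are solvent-exposed, so a zero-parameter baseline calls
every polar residue pore-lining, and a helix pore-lining when it contains
at least ``min_polar`` (default 7) polar residues. The polar alphabet is
configurable; the default covers the charged and polar-uncharged side
chains (D E H K R N Q S T C Y).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .records import HelixSpan, ProteinRecord, ResidueScoreTrack

DEFAULT_POLAR = frozenset("DEHKRNQSTCY")
MIN_POLAR = 7


def _check_polar(polar: Iterable[str]) -> frozenset[str]:
    polar = frozenset(p.upper() for p in polar)
    if not polar:
        raise ValueError("polar alphabet must be non-empty")
    bad = polar - frozenset("ACDEFGHIKLMNPQRSTVWY")
    if bad:
        raise ValueError(f"polar alphabet contains non-canonical letters {sorted(bad)}")
    return polar


def naive_residue(sequence: str, helices: Sequence[HelixSpan],
                  polar: Iterable[str] = DEFAULT_POLAR,
                  chain_id: str = "?") -> ResidueScoreTrack:
    """Score +1 for polar transmembrane residues, -1 otherwise."""
    polar = _check_polar(polar)
    sequence = sequence.upper()
    indices, scores = [], []
    for h in helices:
        for i in h.residues():
            indices.append(i)
            scores.append(1.0 if sequence[i - 1] in polar else -1.0)
    return ResidueScoreTrack(chain_id, np.array(indices, dtype=int),
                             np.array(scores))


def naive_helix(sequence: str, helix: HelixSpan,
                polar: Iterable[str] = DEFAULT_POLAR,
                min_polar: int = MIN_POLAR) -> bool:
    """True iff the helix contains at least ``min_polar`` polar residues."""
    polar = _check_polar(polar)
    sequence = sequence.upper()
    count = sum(1 for i in helix.residues() if sequence[i - 1] in polar)
    return count >= min_polar


def naive_helix_calls(record: ProteinRecord,
                      polar: Iterable[str] = DEFAULT_POLAR,
                      min_polar: int = MIN_POLAR) -> list[HelixSpan]:
    """All helices of a chain relabelled by the polar-count rule."""
    return [
        h.with_label(naive_helix(record.sequence, h, polar, min_polar))
        for h in record.helices
    ]
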