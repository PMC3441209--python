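"""Global pairwise sequence identity for homology exclusion.

Identity between two chains is computed from a Needleman-Wunsch global
alignment (match 1, mismatch 0, gap open -10, gap extend -1) as
identities divided by alignment length including gap columns, expressed
as a percentage. Chains above the exclusion threshold (25% by default)
are removed from a target's training set during jackknife
cross-validation.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

IDENTITY_THRESHOLD = 25.0


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-10,
        extend_gap_score=-1,
    )


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the optimal global alignment, in [0, 100]."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length
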