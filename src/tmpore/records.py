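"""Core domain types for transmembrane pore prediction.

A *chain* is one polypeptide of a membrane-protein complex, annotated with
its transmembrane (TM) helix spans, the set of residues labelled as
pore-lining (side chain facing the solvent-filled channel), and optionally
the observed pore stoichiometry (number of subunits whose TM regions line
the pore). Residue indices are 1-based and inclusive at every interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

#: PSI-BLAST PSSM column order; the package's canonical amino-acid ordering.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
#: Accepted sequence alphabet: the 20 canonical residues plus X (unknown).
VALID_LETTERS = frozenset(AA_ORDER) | {"X"}


class ValidationError(ValueError):
    """An input object violates a documented invariant."""


@dataclass(frozen=True)
class HelixSpan:
    """One transmembrane helix, 1-based inclusive ``[start, end]``.

    ``pore_lining`` is None until a label or call has been assigned.
    """

    start: int
    end: int
    pore_lining: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"invalid helix span {self.start}-{self.end}: need 1 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, index: int) -> bool:
        return self.start <= index <= self.end

    def residues(self) -> range:
        """All residue indices in the span."""
        return range(self.start, self.end + 1)

    def overlap(self, other: "HelixSpan") -> int:
        """Number of residue positions shared with ``other``."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def with_label(self, pore_lining: bool) -> "HelixSpan":
        return replace(self, pore_lining=pore_lining)


@dataclass
class ProteinRecord:
    """One chain: sequence, TM helix annotation, pore labels, stoichiometry."""

    chain_id: str
    sequence: str
    helices: list[HelixSpan] = field(default_factory=list)
    pore_residues: frozenset[int] = field(default_factory=frozenset)
    observed_stoichiometry: Optional[int] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_LETTERS
        if bad:
            raise ValidationError(
                f"{self.chain_id}: sequence contains letters outside the "
                f"21-letter alphabet: {sorted(bad)}"
            )
        self.helices = sorted(self.helices, key=lambda h: h.start)
        length = len(self.sequence)
        prev: Optional[HelixSpan] = None
        for h in self.helices:
            if h.end > length:
                raise ValidationError(
                    f"{self.chain_id}: helix {h.start}-{h.end} exceeds sequence "
                    f"length {length}"
                )
            if prev is not None and h.start <= prev.end:
                raise ValidationError(
                    f"{self.chain_id}: helices {prev.start}-{prev.end} and "
                    f"{h.start}-{h.end} overlap"
                )
            prev = h
        self.pore_residues = frozenset(self.pore_residues)
        for idx in self.pore_residues:
            if idx < 1 or idx > length:
                raise ValidationError(
                    f"{self.chain_id}: pore residue index {idx} outside "
                    f"[1, {length}] (indices are 1-based)"
                )
        if self.observed_stoichiometry is not None and self.observed_stoichiometry < 1:
            raise ValidationError(
                f"{self.chain_id}: observed stoichiometry must be >= 1"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def helix_for(self, index: int) -> Optional[HelixSpan]:
        """The helix containing residue ``index``, or None."""
        for h in self.helices:
            if index in h:
                return h
        return None

    def tm_residues(self) -> Iterator[int]:
        """Residue indices inside any helix span, ascending."""
        for h in self.helices:
            yield from h.residues()

    @property
    def n_tm_residues(self) -> int:
        return sum(len(h) for h in self.helices)


@dataclass
class PssmProfile:
    """Per-residue evolutionary profile: L x 20 log-odds substitution scores.

    Columns follow :data:`AA_ORDER` regardless of the order in the source
    file; rows parallel the chain sequence (``residue_letters``).
    """

    chain_id: str
    scores: np.ndarray
    residue_letters: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValidationError(
                f"{self.chain_id}: PSSM must be L x 20, got {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.residue_letters):
            raise ValidationError(
                f"{self.chain_id}: PSSM has {self.scores.shape[0]} rows but "
                f"{len(self.residue_letters)} residue letters"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]

    def check_against(self, sequence: str) -> None:
        """Raise if the profile does not match ``sequence`` row for row."""
        if self.residue_letters.upper() != sequence.upper():
            raise ValidationError(
                f"{self.chain_id}: PSSM residue letters do not match the "
                f"supplied sequence"
            )


@dataclass
class ResidueScoreTrack:
    """Raw classifier margin per transmembrane residue of one chain.

    ``calls[i]`` is ``scores[i] >= threshold`` with the default residue
    decision threshold of 0 (ties positive).
    """

    chain_id: str
    indices: np.ndarray
    scores: np.ndarray
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.indices.shape != self.scores.shape:
            raise ValidationError("indices and scores must have equal length")
        order = np.argsort(self.indices)
        self.indices = self.indices[order]
        self.scores = self.scores[order]
        self._lookup = {int(i): float(s) for i, s in zip(self.indices, self.scores)}

    @property
    def calls(self) -> np.ndarray:
        return self.scores >= self.threshold

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, index: int) -> bool:
        return int(index) in self._lookup

    def score_at(self, index: int) -> float:
        try:
            return self._lookup[int(index)]
        except KeyError:
            raise KeyError(
                f"{self.chain_id}: residue {index} has no classifier score"
            ) from None

    @property
    def n_positive_calls(self) -> int:
        return int(self.calls.sum())


@dataclass(frozen=True)
class HelixCall:
    """Helix-level pore-lining call aggregated from residue margins."""

    chain_id: str
    span: HelixSpan
    mean_score: float
    call: bool
    zscore: Optional[float] = None
    posterior: Optional[float] = None


@dataclass
class StoichiometryRecord:
    """The four sequence-level regression features plus subunit counts."""

    chain_id: str
    sequence_length: int
    n_pore_residues: int
    n_tm_helices: int
    n_pore_helices: int
    observed_subunits: Optional[int] = None
    predicted_subunits: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("sequence_length", "n_pore_residues", "n_tm_helices",
                     "n_pore_helices"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.chain_id}: {name} must be >= 0")
        if self.n_pore_helices > self.n_tm_helices:
            raise ValidationError(
                f"{self.chain_id}: n_pore_helices ({self.n_pore_helices}) "
                f"exceeds n_tm_helices ({self.n_tm_helices})"
            )
        for name in ("observed_subunits", "predicted_subunits"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValidationError(f"{self.chain_id}: {name} must be >= 1")

    @property
    def features(self) -> np.ndarray:
        """Feature vector (length, pore residues, TM helices, pore helices)."""
        return np.array(
            [self.sequence_length, self.n_pore_residues,
             self.n_tm_helices, self.n_pore_helices],
            dtype=float,
        )


def permutation_to_canonical(letters: Sequence[str]) -> np.ndarray:
    """Column permutation mapping an observed amino-acid order to AA_ORDER.

    Returns ``perm`` such that ``matrix[:, perm]`` has columns in
    :data:`AA_ORDER` when ``matrix`` columns follow ``letters``.
    """
    if sorted(letters) != sorted(AA_ORDER):
        raise ValidationError(
            f"amino-acid column set {letters!r} is not the 20 canonical letters"
        )
    pos = {a: i for i, a in enumerate(letters)}
    return np.array([pos[a] for a in AA_ORDER], dtype=int)
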