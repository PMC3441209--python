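"""Label post-processing: adjacency expansion and helix-level classes.

Two rules turn raw geometric pore-lining residue labels into the classes
the machine-learning stages consume:

* **Adjacency expansion** — residues immediately adjacent (i-1, i+1) to a
  labelled residue, within the same helix, join the positive training
  class. This compensates for conformational dynamics a single crystal
  structure cannot capture and reduces class imbalance. The rejected
  wider variant (i-4, i+4, one helical turn) is available via ``offsets``
  but is off by default because it degrades performance.
* **Helix labelling** — a helix is pore-lining iff it contains at least
  ``min_pore_residues`` (default 6) *original* (pre-expansion) labels,
  roughly a quarter of a typical transmembrane helix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import HelixSpan, ProteinRecord

#: Adjacency offsets for training-label expansion (the i +/- 1 rule).
DEFAULT_OFFSETS: tuple[int, ...] = (1,)
#: Minimum original pore labels for a helix to count as pore-lining.
MIN_PORE_RESIDUES = 6


@dataclass(frozen=True)
class LabelledResidue:
    """One transmembrane residue with its training class."""

    chain_id: str
    index: int
    in_helix: bool
    positive: bool
    expanded: bool  # added by adjacency expansion, not an original label

    def __post_init__(self) -> None:
        assert not self.positive or self.in_helix
        assert not self.expanded or self.positive


def expand_labels(record: ProteinRecord,
                  offsets: Sequence[int] = DEFAULT_OFFSETS) -> frozenset[int]:
    """Original pore labels plus same-helix neighbours at ``+/- offsets``.

    Labels falling outside every helix span are dropped; expansion never
    escapes the helix containing the original label, so the operation is
    stable under re-application.
    """
    out: set[int] = set()
    for idx in record.pore_residues:
        helix = record.helix_for(idx)
        if helix is None:
            continue
        out.add(idx)
        for off in offsets:
            for j in (idx - off, idx + off):
                if j in helix:
                    out.add(j)
    return frozenset(out)


def label_helices(record: ProteinRecord,
                  min_pore_residues: int = MIN_PORE_RESIDUES) -> list[HelixSpan]:
    """Helix spans relabelled by the >= ``min_pore_residues`` original-label rule."""
    labelled = []
    for h in record.helices:
        count = sum(1 for i in record.pore_residues if i in h)
        labelled.append(h.with_label(count >= min_pore_residues))
    return labelled


def labelled_residues(record: ProteinRecord, expand: bool = True,
                      offsets: Sequence[int] = DEFAULT_OFFSETS
                      ) -> list[LabelledResidue]:
    """Per-residue training classes for every transmembrane residue."""
    original = {i for i in record.pore_residues if record.helix_for(i) is not None}
    positive = set(expand_labels(record, offsets)) if expand else original
    return [
        LabelledResidue(
            chain_id=record.chain_id,
            index=i,
            in_helix=True,
            positive=i in positive,
            expanded=i in positive and i not in original,
        )
        for i in record.tm_residues()
    ]


def class_ratio(records: Iterable[ProteinRecord], expanded: bool = True,
                offsets: Sequence[int] = DEFAULT_OFFSETS) -> tuple[int, int]:
    """(n_negative, n_positive) over all transmembrane residues."""
    n_neg = n_pos = 0
    for rec in records:
        for lr in labelled_residues(rec, expand=expanded, offsets=offsets):
            if lr.positive:
                n_pos += 1
            else:
                n_neg += 1
    return n_neg, n_pos
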