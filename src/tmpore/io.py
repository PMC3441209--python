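"""Readers and writers for every external representation the pipeline touches.

Formats
-------
FASTA
    Standard; sequences are uppercased and restricted to the 20 canonical
    amino acids plus X.
PSSM
    The PSI-BLAST ASCII matrix dump (``-Q`` style): header lines, then one
    row per residue with the residue index, the residue letter, 20 integer
    log-odds scores, and optionally further columns (weighted percentages,
    information content) which are ignored. Columns are re-ordered to the
    canonical ordering :data:`tmpore.records.AA_ORDER` on read.
Annotations
    Tab-separated records, one per line::

        HELIX  <chain> <start> <end> [pore|nonpore]
        PORE   <chain> <idx1,idx2,...>
        STOICH <chain> <n_subunits>

Reports
    TSV, one row per residue (chain, index, raw_score, call) or per helix
    (chain, start, end, mean_score, zscore, posterior, call).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    AA_ORDER,
    HelixCall,
    HelixSpan,
    ProteinRecord,
    PssmProfile,
    ResidueScoreTrack,
    ValidationError,
    VALID_LETTERS,
    permutation_to_canonical,
)


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased. Letters outside the 21-letter alphabet
    (20 canonical residues + X) are rejected with the line number.
    """
    entries: list[tuple[str, str]] = []
    header: Optional[str] = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{header_line}: record '{header}' has an empty sequence")
        entries.append((header, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunk = line.upper()
                bad = set(chunk) - VALID_LETTERS
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: invalid sequence characters {sorted(bad)}"
                    )
                chunks.append(chunk)
    flush()
    return entries


def write_fasta(entries: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSSM

def read_pssm(path, sequence: Optional[str] = None,
              chain_id: Optional[str] = None) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM into a :class:`PssmProfile`.

    The first 20 log-odds columns are kept and re-ordered into the
    canonical amino-acid ordering; trailing columns (weighted observed
    percentages, information content) are ignored, as is trailing
    whitespace. If ``sequence`` is given, the profile is checked against
    it; positions where the sequence has ``X`` but the file has no row get
    an all-zero row.
    """
    if chain_id is None:
        chain_id = Path(path).stem
    perm: Optional[np.ndarray] = None
    letters: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = raw.split()
            if perm is None:
                # header line: 20 (or 40) single-letter amino-acid columns
                if len(fields) >= 20 and all(
                    len(f) == 1 and f.isalpha() for f in fields[:20]
                ):
                    perm = permutation_to_canonical([f.upper() for f in fields[:20]])
                continue
            if not fields:
                continue
            if not fields[0].isdigit():
                break  # footer (statistics) reached
            if len(fields) < 22:
                raise ParseError(
                    f"{path}:{lineno}: truncated PSSM row "
                    f"({len(fields)} fields, need index + letter + 20 scores)"
                )
            letter = fields[1].upper()
            if len(letter) != 1 or letter not in VALID_LETTERS:
                raise ParseError(f"{path}:{lineno}: bad residue letter {fields[1]!r}")
            try:
                scores = [float(x) for x in fields[2:22]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score: {exc}") from None
            letters.append(letter)
            rows.append(scores)
    if perm is None:
        raise ParseError(f"{path}: no PSSM header line with amino-acid columns found")
    if not rows:
        raise ParseError(f"{path}: no PSSM rows found")
    matrix = np.asarray(rows, dtype=float)[:, perm]
    letter_str = "".join(letters)

    if sequence is not None:
        sequence = sequence.upper()
        if letter_str != sequence:
            matrix, letter_str = _fill_missing_x_rows(
                matrix, letter_str, sequence, path
            )
    return PssmProfile(chain_id=chain_id, scores=matrix, residue_letters=letter_str)


def _fill_missing_x_rows(matrix: np.ndarray, letters: str, sequence: str,
                         path) -> tuple[np.ndarray, str]:
    """Insert zero rows for X positions absent from the file; else raise."""
    out_rows = []
    j = 0
    for ch in sequence:
        if j < len(letters) and letters[j] == ch:
            out_rows.append(matrix[j])
            j += 1
        elif ch == "X":
            out_rows.append(np.zeros(20))
        else:
            raise ValidationError(
                f"{path}: PSSM residues {letters!r} inconsistent with "
                f"sequence {sequence!r}"
            )
    if j != len(letters):
        raise ValidationError(
            f"{path}: PSSM has {len(letters)} rows but sequence has "
            f"length {len(sequence)}"
        )
    return np.asarray(out_rows), sequence


def write_pssm(profile: PssmProfile, path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect (log-odds block only)."""
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write(" " * 11 + "  ".join(AA_ORDER) + "\n")
        for i, (letter, row) in enumerate(
            zip(profile.residue_letters, profile.scores), start=1
        ):
            cells = " ".join(f"{int(round(v)):3d}" for v in row)
            fh.write(f"{i:5d} {letter}  {cells}\n")


# ---------------------------------------------------------------------------
# Annotations

def read_annotations(path, sequences: Optional[Mapping[str, str]] = None
                     ) -> list[ProteinRecord]:
    """Read helix/pore/stoichiometry annotations into ProteinRecords.

    ``sequences`` maps chain id to amino-acid sequence (e.g. from
    :func:`read_fasta`); chains without a sequence get an ``X`` placeholder
    sequence long enough to hold their annotations.
    """
    helices: dict[str, list[HelixSpan]] = {}
    pores: dict[str, set[int]] = {}
    stoich: dict[str, int] = {}
    order: list[str] = []

    def seen(chain: str) -> None:
        if chain not in order:
            order.append(chain)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            kind = fields[0].upper()
            try:
                if kind == "HELIX":
                    chain, start, end = fields[1], int(fields[2]), int(fields[3])
                    label = fields[4].lower() if len(fields) > 4 else None
                    pore = {"pore": True, "nonpore": False, None: None}[label]
                    helices.setdefault(chain, []).append(
                        HelixSpan(start, end, pore_lining=pore)
                    )
                    seen(chain)
                elif kind == "PORE":
                    chain = fields[1]
                    idxs = {int(x) for x in fields[2].split(",") if x}
                    pores.setdefault(chain, set()).update(idxs)
                    seen(chain)
                elif kind == "STOICH":
                    chain = fields[1]
                    stoich[chain] = int(fields[2])
                    seen(chain)
                else:
                    raise ParseError(
                        f"{path}:{lineno}: unknown record type {fields[0]!r}"
                    )
            except (IndexError, ValueError, KeyError) as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(f"{path}:{lineno}: malformed {kind} record: {line!r}") from None

    records = []
    for chain in order:
        spans = helices.get(chain, [])
        if sequences is not None and chain in sequences:
            seq = sequences[chain]
        else:
            length = max(
                [h.end for h in spans] + [max(pores.get(chain, {0}), default=0)] + [1]
            )
            seq = "X" * length
        try:
            records.append(
                ProteinRecord(
                    chain_id=chain,
                    sequence=seq,
                    helices=spans,
                    pore_residues=frozenset(pores.get(chain, set())),
                    observed_stoichiometry=stoich.get(chain),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: chain {chain}: {exc}") from None
    return records


def write_annotations(records: Iterable[ProteinRecord], path) -> None:
    """Write annotations in canonical form (sorted spans, sorted indices)."""
    with open(path, "w") as fh:
        for rec in records:
            for h in rec.helices:
                label = (
                    ""
                    if h.pore_lining is None
                    else "\t" + ("pore" if h.pore_lining else "nonpore")
                )
                fh.write(f"HELIX\t{rec.chain_id}\t{h.start}\t{h.end}{label}\n")
            if rec.pore_residues:
                idx = ",".join(str(i) for i in sorted(rec.pore_residues))
                fh.write(f"PORE\t{rec.chain_id}\t{idx}\n")
            if rec.observed_stoichiometry is not None:
                fh.write(f"STOICH\t{rec.chain_id}\t{rec.observed_stoichiometry}\n")


# ---------------------------------------------------------------------------
# Stoichiometry tables and reports

def read_stoichiometry_table(path) -> pd.DataFrame:
    """Read a TSV with columns chain_id, observed, predicted ('-' = absent)."""
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str}, na_values=["-"])
    required = {"chain_id", "observed"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["observed"] < 1).any():
        bad = df.loc[df["observed"] < 1, "chain_id"].tolist()
        raise ValidationError(f"{path}: observed_subunits < 1 for {bad}")
    return df


def write_stoichiometry_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "predicted" in out.columns:
        out["predicted"] = out["predicted"].map(
            lambda v: "-" if pd.isna(v) else str(int(v))
        )
    out.to_csv(path, sep="\t", index=False)


def write_residue_report(tracks: Iterable[ResidueScoreTrack], path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tindex\traw_score\tcall\n")
        for track in tracks:
            for idx, score, call in zip(track.indices, track.scores, track.calls):
                fh.write(f"{track.chain_id}\t{idx}\t{score:.6f}\t{int(call)}\n")


def write_helix_report(calls: Iterable[HelixCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tstart\tend\tmean_score\tzscore\tposterior\tcall\n")
        for c in calls:
            z = "-" if c.zscore is None else f"{c.zscore:.6f}"
            p = "-" if c.posterior is None else f"{c.posterior:.6f}"
            fh.write(
                f"{c.chain_id}\t{c.span.start}\t{c.span.end}\t"
                f"{c.mean_score:.6f}\t{z}\t{p}\t{int(c.call)}\n"
            )


# ---------------------------------------------------------------------------
# Packaged reference table

def load_reference_table() -> pd.DataFrame:
    """The packaged per-target benchmark table (52 chains).

    Columns: target, per_residue_mcc, pore_helices_observed,
    pore_helices_predicted, topology_correct, topology_over_under,
    stoichiometry_observed, stoichiometry_predicted.
    """
    with resources.files("tmpore.data").joinpath("table2.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
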