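"""Synthetic chains, profiles and stoichiometry with planted pore signal.

The generator emulates the statistical structure the predictor exploits in
real transmembrane proteins: pore-lining helices present one face to the
solvent-filled channel, so their pore-facing residues recur with helical
periodicity (every 3-4 positions, one turn) and are enriched in aspartate,
glutamate and histidine conservation. Concretely, each pore-lining helix
gets a periodic set of pore-facing positions whose PSSM columns for D, E
and H are boosted by ``signal_strength`` over an integer-rounded Gaussian
background (sd ``noise_sd``); at zero signal strength labels and profiles
are statistically independent. The observed stoichiometry is a declared
function of the number of pore-lining helices,
``max(1, round(a * n_pore_helices + b + eps))``, so the regression stage
has a recoverable planted relationship.

Everything is reproducible from ``SyntheticConfig.seed`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import DEFAULT_POLAR
from .records import (
    AA_INDEX,
    AA_ORDER,
    HelixSpan,
    ProteinRecord,
    PssmProfile,
    StoichiometryRecord,
)

_SIGNAL_COLUMNS = [AA_INDEX[a] for a in "DEH"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator (all lengths in residues)."""

    n_chains: int = 12
    helices_per_chain: tuple[int, int] = (3, 6)
    helix_length: tuple[int, int] = (17, 25)
    linker_length: tuple[int, int] = (3, 10)
    fraction_pore_helices: float = 0.5
    pore_face_period: tuple[int, ...] = (3, 4)
    signal_strength: float = 5.0
    noise_sd: float = 1.0
    stoich_slope: float = 1.0
    stoich_intercept: float = 0.0
    stoich_noise: int = 0
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_pore_helices <= 1:
            raise ValueError("fraction_pore_helices must be in [0, 1]")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if self.helix_length[0] < 16:
            raise ValueError(
                "helix_length lower bound must be >= 16 so a pore face can "
                "carry six or more periodic positions"
            )
        for lo, hi in (self.helices_per_chain, self.helix_length,
                       self.linker_length):
            if lo > hi or lo < 1:
                raise ValueError("ranges must satisfy 1 <= lo <= hi")


def _pore_positions(rng: np.random.Generator, helix: HelixSpan,
                    periods: Sequence[int]) -> list[int]:
    """Periodic pore-face positions; at least six per helix by construction."""
    length = len(helix)
    phase = int(rng.integers(0, min(3, length - 15)))
    positions = []
    pos = helix.start + phase
    while pos <= helix.end:
        positions.append(pos)
        pos += int(rng.choice(periods))
    if len(positions) < 6:
        # fall back to the tightest period so the >= 6-residue helix rule holds
        positions = list(range(helix.start + phase, helix.end + 1, min(periods)))
    return positions


def generate(config: SyntheticConfig
             ) -> tuple[list[ProteinRecord], dict[str, PssmProfile], pd.DataFrame]:
    """Generate ``(records, profiles, stoichiometry_table)`` from the config."""
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    profiles: dict[str, PssmProfile] = {}
    stoich_rows = []
    for c in range(config.n_chains):
        chain_id = f"SYN{c:03d}_A"
        n_helices = int(rng.integers(config.helices_per_chain[0],
                                     config.helices_per_chain[1] + 1))
        helices: list[HelixSpan] = []
        pos = int(rng.integers(5, 16))  # N-terminal tail
        for _ in range(n_helices):
            length = int(rng.integers(config.helix_length[0],
                                      config.helix_length[1] + 1))
            helices.append(HelixSpan(pos + 1, pos + length))
            pos += length + int(rng.integers(config.linker_length[0],
                                             config.linker_length[1] + 1))
        L = pos + int(rng.integers(5, 16))  # C-terminal tail

        is_pore = rng.random(n_helices) < config.fraction_pore_helices
        pore_residues: set[int] = set()
        labelled_helices = []
        for h, pore in zip(helices, is_pore):
            if pore:
                pore_residues.update(_pore_positions(rng, h,
                                                     config.pore_face_period))
            labelled_helices.append(h.with_label(bool(pore)))

        letters = rng.integers(0, 20, size=L)
        if config.signal_strength > 0:
            # mirror the conservation signal in the letters themselves so
            # composition diagnostics and the polarity baseline see it too
            for i in sorted(pore_residues):
                if rng.random() < 0.6:
                    letters[i - 1] = AA_INDEX["DEH"[int(rng.integers(0, 3))]]
        sequence = "".join(AA_ORDER[i] for i in letters)

        scores = rng.normal(0.0, config.noise_sd, size=(L, 20))
        for i in sorted(pore_residues):
            scores[i - 1, _SIGNAL_COLUMNS] += config.signal_strength
        scores = np.round(scores)

        n_pore_helices = int(is_pore.sum())
        eps = int(rng.integers(-config.stoich_noise, config.stoich_noise + 1)) \
            if config.stoich_noise > 0 else 0
        subunits = max(1, int(round(config.stoich_slope * n_pore_helices
                                    + config.stoich_intercept + eps)))

        record = ProteinRecord(
            chain_id=chain_id, sequence=sequence, helices=labelled_helices,
            pore_residues=frozenset(pore_residues),
            observed_stoichiometry=subunits,
        )
        records.append(record)
        profiles[chain_id] = PssmProfile(chain_id=chain_id, scores=scores,
                                         residue_letters=sequence)
        stoich_rows.append({
            "chain_id": chain_id,
            "sequence_length": L,
            "n_pore_residues": len(pore_residues),
            "n_tm_helices": n_helices,
            "n_pore_helices": n_pore_helices,
            "observed": subunits,
        })
    return records, profiles, pd.DataFrame(stoich_rows)


def stoichiometry_records(table: pd.DataFrame) -> list[StoichiometryRecord]:
    """Regression records built from the generator's truth features."""
    return [
        StoichiometryRecord(
            chain_id=row.chain_id,
            sequence_length=int(row.sequence_length),
            n_pore_residues=int(row.n_pore_residues),
            n_tm_helices=int(row.n_tm_helices),
            n_pore_helices=int(row.n_pore_helices),
            observed_subunits=int(row.observed),
        )
        for row in table.itertuples()
    ]


def composition_report(records: Sequence[ProteinRecord],
                       polar: frozenset[str] = DEFAULT_POLAR) -> pd.DataFrame:
    """Per-class amino-acid frequencies over pore vs non-pore helices.

    Returns one row per amino acid with the residue frequency in
    pore-lining and non-pore-lining helices, plus a ``polar`` summary row
    giving the polar-set fraction of each class.
    """
    counts = {True: dict.fromkeys(AA_ORDER, 0), False: dict.fromkeys(AA_ORDER, 0)}
    for rec in records:
        for h in rec.helices:
            if h.pore_lining is None:
                continue
            for i in h.residues():
                letter = rec.sequence[i - 1]
                if letter in AA_INDEX:
                    counts[h.pore_lining][letter] += 1
    totals = {k: sum(v.values()) for k, v in counts.items()}
    rows = {}
    for aa in AA_ORDER:
        rows[aa] = {
            "pore": counts[True][aa] / totals[True] if totals[True] else 0.0,
            "nonpore": counts[False][aa] / totals[False] if totals[False] else 0.0,
            "count_pore": counts[True][aa],
            "count_nonpore": counts[False][aa],
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc["polar"] = [
        df.loc[list(polar & set(AA_ORDER)), "pore"].sum(),
        df.loc[list(polar & set(AA_ORDER)), "nonpore"].sum(),
        df.loc[list(polar & set(AA_ORDER)), "count_pore"].sum(),
        df.loc[list(polar & set(AA_ORDER)), "count_nonpore"].sum(),
    ]
    return df


def write_dataset(records: Sequence[ProteinRecord],
                  profiles: dict[str, PssmProfile],
                  stoich: pd.DataFrame, out_dir) -> None:
    """Write FASTA + per-chain PSSMs + annotations + stoichiometry TSV."""
    from pathlib import Path

    from . import io as tio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_fasta([(r.chain_id, r.sequence) for r in records],
                    out / "chains.fasta")
    tio.write_annotations(records, out / "annotations.tsv")
    stoich[["chain_id", "observed"]].to_csv(out / "stoichiometry.tsv",
                                            sep="\t", index=False)
    pssm_dir = out / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for r in records:
        tio.write_pssm(profiles[r.chain_id], pssm_dir / f"{r.chain_id}.pssm")
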