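"""Support-vector regression of pore stoichiometry.

Four sequence-level features predict the number of subunits whose
transmembrane regions line the pore: sequence length, the number of
(predicted) pore-lining residues, the topology (number of transmembrane
helices), and the number of (predicted) pore-lining helices. Feature
values are deliberately *not* standardized. The regressor uses an RBF
kernel; raw outputs are rounded to the nearest integer (half away from
zero) and clamped to at least one subunit. Hyper-parameters are chosen
to minimise the total absolute error of the rounded predictions under
leave-one-out cross-validation; ties go to the smaller parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .evaluation import StoichiometrySummary, stoichiometry_summary
from .records import HelixCall, ProteinRecord, ResidueScoreTrack, StoichiometryRecord

DEFAULT_EPSILON = 0.1
#: Grids chosen for unstandardized features whose dominant scale is the
#: sequence length (hundreds of residues): squared feature distances are
#: O(1e4-1e5), so useful kernel widths extend well below 1e-3.
DEFAULT_TRADE_OFF_GRID = (1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1)


def round_subunits(raw: float) -> int:
    """Round half away from zero, then clamp to >= 1 subunit."""
    rounded = int(np.floor(abs(raw) + 0.5)) * (1 if raw >= 0 else -1)
    return max(1, rounded)


def assemble_features(record: ProteinRecord, residue_track: ResidueScoreTrack,
                      helix_calls: Sequence[HelixCall]) -> StoichiometryRecord:
    """Build the four-feature record from per-chain predictions.

    Counts come from the *predictions* (residue calls at margin >= 0 and
    helix calls), not from gold labels, so that cross-validated
    stoichiometry uses only information available from sequence.
    """
    if len(residue_track) == 0 and not helix_calls:
        raise ValueError(f"{record.chain_id}: no predictions to assemble")
    return StoichiometryRecord(
        chain_id=record.chain_id,
        sequence_length=len(record.sequence),
        n_pore_residues=residue_track.n_positive_calls,
        n_tm_helices=len(helix_calls),
        n_pore_helices=sum(1 for c in helix_calls if c.call),
        observed_subunits=record.observed_stoichiometry,
    )


class StoichiometryModel:
    """RBF-kernel SVR over the four unstandardized stoichiometry features."""

    def __init__(self, records: Sequence[StoichiometryRecord], *,
                 epsilon: float = DEFAULT_EPSILON,
                 trade_off_grid: Sequence[float] = DEFAULT_TRADE_OFF_GRID,
                 gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
                 seed: int = 42) -> None:
        labelled = [r for r in records if r.observed_subunits is not None]
        if len(labelled) < 2:
            raise ValueError("need at least 2 records with observed subunits")
        self.records = labelled
        self.epsilon = epsilon
        self.trade_off_grid = tuple(trade_off_grid)
        self.gamma_grid = tuple(gamma_grid)
        self.seed = seed
        self._X = np.vstack([r.features for r in labelled])
        self._y = np.array([r.observed_subunits for r in labelled], dtype=float)

    def _svr(self, trade_off: float, gamma: float) -> SVR:
        return SVR(kernel="rbf", C=trade_off, gamma=gamma, epsilon=self.epsilon)

    def _loo_predictions(self, trade_off: float, gamma: float) -> np.ndarray:
        """Rounded leave-one-out predictions for the whole data set."""
        n = len(self._y)
        preds = np.empty(n, dtype=int)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if np.unique(self._y[mask]).size == 1:
                preds[i] = round_subunits(float(self._y[mask][0]))
                continue
            svr = self._svr(trade_off, gamma)
            svr.fit(self._X[mask], self._y[mask])
            preds[i] = round_subunits(float(svr.predict(self._X[i:i + 1])[0]))
        return preds

    def select_parameters(self) -> tuple[float, float, int, pd.DataFrame]:
        """Grid point minimising cross-validated total absolute error.

        Returns (trade_off, gamma, total_abs_error, cv_table); ties break
        towards smaller trade-off, then smaller gamma.
        """
        rows = []
        for trade_off in self.trade_off_grid:
            for gamma in self.gamma_grid:
                preds = self._loo_predictions(trade_off, gamma)
                rows.append({
                    "trade_off": trade_off, "gamma": gamma,
                    "total_abs_error": int(np.abs(preds - self._y).sum()),
                })
        table = pd.DataFrame(rows)
        best = table.sort_values(
            by=["total_abs_error", "trade_off", "gamma"],
            ascending=[True, True, True],
        ).iloc[0]
        return (float(best["trade_off"]), float(best["gamma"]),
                int(best["total_abs_error"]), table)

    def fit(self, trade_off: Optional[float] = None,
            gamma: Optional[float] = None) -> "StoichiometryResults":
        """Select hyper-parameters (unless given) and fit the final model."""
        degenerate = np.unique(self._y).size == 1
        if degenerate:
            import warnings
            warnings.warn("all stoichiometry targets identical; constant model")
            trade_off = trade_off or self.trade_off_grid[0]
            gamma = gamma or self.gamma_grid[0]
            cv_table = None
            cv_error = 0
            cv_preds = np.full(len(self._y), round_subunits(float(self._y[0])))
        elif trade_off is None or gamma is None:
            trade_off, gamma, cv_error, cv_table = self.select_parameters()
            cv_preds = self._loo_predictions(trade_off, gamma)
        else:
            cv_table = None
            cv_preds = self._loo_predictions(trade_off, gamma)
            cv_error = int(np.abs(cv_preds - self._y).sum())
        svr = self._svr(trade_off, gamma)
        svr.fit(self._X, self._y)
        return StoichiometryResults(
            svr=svr, trade_off=trade_off, gamma=gamma, epsilon=self.epsilon,
            records=self.records, cv_predictions=cv_preds,
            cv_total_abs_error=int(cv_error), cv_table=cv_table,
            constant=bool(degenerate),
        )


@dataclass
class StoichiometryResults:
    """Fitted stoichiometry regressor plus its cross-validation diagnostics."""

    svr: SVR
    trade_off: float
    gamma: float
    epsilon: float
    records: Sequence[StoichiometryRecord]
    cv_predictions: np.ndarray
    cv_total_abs_error: int
    cv_table: Optional[pd.DataFrame]
    constant: bool = False

    def predict_subunits(self, record: StoichiometryRecord) -> int:
        """Rounded, clamped subunit count for one chain."""
        if self.constant:
            return round_subunits(float(self.records[0].observed_subunits))
        raw = float(self.svr.predict(record.features.reshape(1, -1))[0])
        return round_subunits(raw)

    def cv_frame(self) -> pd.DataFrame:
        """Observed vs leave-one-out predicted subunit counts."""
        return pd.DataFrame({
            "chain_id": [r.chain_id for r in self.records],
            "observed": [r.observed_subunits for r in self.records],
            "predicted": self.cv_predictions,
        })

    def cv_summary(self) -> StoichiometrySummary:
        return stoichiometry_summary(self.cv_frame())

    def summary(self) -> str:
        s = self.cv_summary()
        return "\n".join([
            "Pore stoichiometry SVR",
            "=" * 44,
            f"kernel            RBF (gamma={self.gamma:g})",
            f"trade-off (C)     {self.trade_off:g}",
            f"epsilon           {self.epsilon:g}",
            f"records           {len(self.records)}",
            f"CV total |error|  {self.cv_total_abs_error}",
            f"CV exact          {s.n_exact}/{s.n} ({100 * s.exact_fraction:.0f}%)",
            f"CV MAE            {s.mean_abs_error:.2f} subunits",
            f"CV mono/multi     {100 * s.mono_multi_accuracy:.0f}%",
        ])


def classify_mono_multi(record: StoichiometryRecord) -> str:
    """'monomeric' iff a single subunit is predicted, else 'multimeric'."""
    if record.predicted_subunits is None:
        raise ValueError(f"{record.chain_id}: no predicted subunit count")
    return "monomeric" if record.predicted_subunits == 1 else "multimeric"
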