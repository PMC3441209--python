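import numpy as np
import pytest

from tmpore import (
    HelixCall,
    HelixSpan,
    ProteinRecord,
    ResidueScoreTrack,
    StoichiometryModel,
    StoichiometryRecord,
    ValidationError,
)
from tmpore.stoichiometry import (
    assemble_features,
    classify_mono_multi,
    round_subunits,
)


class TestRounding:
    @pytest.mark.parametrize("raw,expected", [
        (3.4, 3), (0.2, 1), (4.5, 5), (1.5, 2), (2.49, 2), (-0.7, 1), (6.0, 6),
    ])
    def test_half_away_from_zero_with_clamp(self, raw, expected):
        assert round_subunits(raw) == expected


def _call(start, end, call, chain="C_A"):
    return HelixCall(chain_id=chain, span=HelixSpan(start, end),
                     mean_score=1.0 if call else -1.0, call=call)


class TestAssembleFeatures:
    def test_direct_assembly(self):
        rec = ProteinRecord("C_A", "A" * 300,
                            helices=[HelixSpan(i * 40 + 1, i * 40 + 20)
                                     for i in range(6)])
        indices = np.arange(1, 81)
        scores = np.where(indices <= 40, 1.0, -1.0)
        track = ResidueScoreTrack("C_A", indices, scores)
        calls = [_call(1, 20, True), _call(41, 60, True)] + \
            [_call(81 + i * 40, 100 + i * 40, False) for i in range(4)]
        sr = assemble_features(rec, track, calls)
        assert (sr.sequence_length, sr.n_pore_residues,
                sr.n_tm_helices, sr.n_pore_helices) == (300, 40, 6, 2)

    def test_pore_helices_cannot_exceed_tm_helices(self):
        with pytest.raises(ValidationError, match="exceeds"):
            StoichiometryRecord("C_A", 100, 10, 2, 3)

    def test_zero_pore_helices_is_legal(self):
        sr = StoichiometryRecord("C_A", 100, 0, 4, 0, observed_subunits=4)
        assert sr.n_pore_helices == 0


def make_records(features, targets):
    return [
        StoichiometryRecord(f"C{i:02d}_A", int(f[0]), int(f[1]), int(f[2]),
                            int(f[3]), observed_subunits=int(t))
        for i, (f, t) in enumerate(zip(features, targets))
    ]


class TestModel:
    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(0)
        feats = np.column_stack([
            rng.integers(100, 500, 10), rng.integers(10, 60, 10),
            np.full(10, 6), rng.integers(0, 4, 10),
        ])
        with pytest.warns(UserWarning, match="identical"):
            results = StoichiometryModel(make_records(feats, [1] * 10)).fit()
        assert all(results.predict_subunits(r) == 1 for r in results.records)
        assert (results.cv_predictions == 1).all()

    def test_two_point_grid_forced_selection(self):
        rng = np.random.default_rng(1)
        n = 16
        pore_h = rng.integers(1, 6, n)
        feats = np.column_stack([
            pore_h * 30 + rng.integers(40, 80, n), pore_h * 6,
            pore_h + 2, pore_h,
        ])
        records = make_records(feats, pore_h)
        model = StoichiometryModel(records, trade_off_grid=[100.0],
                                   gamma_grid=[1e-5, 1e20])
        trade_off, gamma, err, table = model.select_parameters()
        assert gamma == 1e-5  # the degenerate width loses on absolute error
        by_gamma = table.set_index("gamma")["total_abs_error"]
        assert by_gamma[1e-5] < by_gamma[1e20]

    def test_cv_prediction_is_rounded_clamped_raw_output(self):
        rng = np.random.default_rng(2)
        n = 14
        pore_h = rng.integers(1, 5, n)
        feats = np.column_stack([pore_h * 25 + 50, pore_h * 6, pore_h + 1, pore_h])
        records = make_records(feats, pore_h + 1)
        results = StoichiometryModel(records).fit()
        # rounding is the only discretization
        for rec in records:
            raw = float(results.svr.predict(rec.features.reshape(1, -1))[0])
            assert results.predict_subunits(rec) == round_subunits(raw)


class TestMonoMulti:
    def test_monomeric(self):
        r = StoichiometryRecord("C_A", 100, 5, 3, 1, predicted_subunits=1)
        assert classify_mono_multi(r) == "monomeric"

    def test_multimeric(self):
        r = StoichiometryRecord("C_A", 100, 5, 3, 1, predicted_subunits=4)
        assert classify_mono_multi(r) == "multimeric"

    def test_missing_prediction_rejected(self):
        r = StoichiometryRecord("C_A", 100, 5, 3, 1)
        with pytest.raises(ValueError):
            classify_mono_multi(r)
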