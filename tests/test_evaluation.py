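import numpy as np
import pandas as pd
import pytest

from tmpore import (
    ConfusionCounts,
    HelixSpan,
    ValidationError,
    match_helices,
    mcc,
    residue_metrics,
    stoichiometry_summary,
    topology_correct,
)


class TestResidueMetrics:
    def test_perfect_classifier(self):
        m = residue_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert m.mcc == pytest.approx(1.0)
        assert m.accuracy == pytest.approx(1.0)

    def test_hand_computed_case(self):
        m = residue_metrics(ConfusionCounts(tp=2, fp=1, tn=3, fn=1))
        assert m.mcc == pytest.approx(5 / 12)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(5 / 7)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(tp=0, fp=0, tn=10, fn=0)) == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            residue_metrics(ConfusionCounts())

    def test_matches_brute_force_recount_on_random_calls(self):
        """Oracle equivalence: metrics from counted calls agree with
        sklearn computed directly from the call vectors."""
        from sklearn.metrics import accuracy_score, matthews_corrcoef

        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 200))
            y_true = rng.random(n) < rng.random()
            y_pred = rng.random(n) < rng.random()
            counts = ConfusionCounts.from_calls(y_true, y_pred)
            m = residue_metrics(counts)
            assert m.mcc == pytest.approx(
                float(matthews_corrcoef(y_true, y_pred)), abs=1e-12
            )
            assert m.accuracy == pytest.approx(
                float(accuracy_score(y_true, y_pred)), abs=1e-12
            )


def span(start, end, pore=None):
    return HelixSpan(start, end, pore_lining=pore)


class TestMatchHelices:
    def test_clear_match_is_tp(self):
        pairs, counts = match_helices([span(10, 30, True)], [span(12, 32, True)])
        assert pairs == [(0, 0)]
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (1, 0, 0, 0)

    def test_short_overlap_pore_call_is_fp(self):
        # overlap 7 < 10: unpaired; the pore-lining call makes it an FP
        _, counts = match_helices([span(10, 18, True)], [span(12, 32, True)])
        assert counts.fp == 1
        assert counts.fn == 1  # the known pore helix went unmatched

    def test_unpaired_nonpore_prediction_contributes_nothing(self):
        _, counts = match_helices([span(10, 18, False)], [span(40, 60, False)])
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (0, 0, 0, 0)

    def test_unpaired_known_nonpore_dropped(self):
        _, counts = match_helices([], [span(10, 30, False)])
        assert counts.total == 0

    def test_paired_label_combinations(self):
        predicted = [span(1, 20, True), span(30, 49, False),
                     span(60, 79, True), span(90, 109, False)]
        known = [span(1, 20, True), span(30, 49, False),
                 span(60, 79, False), span(90, 109, True)]
        _, counts = match_helices(predicted, known)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (1, 1, 1, 1)

    def test_input_order_invariance(self):
        predicted = [span(1, 20, True), span(25, 44, True), span(50, 69, False)]
        known = [span(3, 22, True), span(24, 43, False), span(52, 71, True)]
        _, c1 = match_helices(predicted, known)
        _, c2 = match_helices(predicted[::-1], known[::-1])
        assert (c1.tp, c1.fp, c1.tn, c1.fn) == (c2.tp, c2.fp, c2.tn, c2.fn)

    def test_one_to_one_pairing_by_descending_overlap(self):
        predicted = [span(1, 30, True)]
        known = [span(1, 12, True), span(14, 30, True)]
        pairs, counts = match_helices(predicted, known)
        assert pairs == [(0, 1)]  # overlap 17 beats overlap 12
        assert counts.fn == 1

    def test_overlapping_predictions_rejected(self):
        with pytest.raises(ValidationError):
            match_helices([span(1, 20), span(15, 35)], [span(1, 20)])


class TestTopologyCorrect:
    def test_identical_lists(self):
        spans = [span(1, 20), span(30, 50)]
        assert topology_correct(spans, spans) == (True, 0)

    def test_extra_predicted_helix(self):
        known = [span(1, 20), span(30, 50)]
        predicted = known + [span(60, 80)]
        assert topology_correct(predicted, known) == (False, 1)

    def test_four_underpredicted(self):
        known = [span(i * 30 + 1, i * 30 + 20) for i in range(6)]
        predicted = known[:2]
        assert topology_correct(predicted, known) == (False, -4)

    def test_count_match_without_overlap_is_incorrect(self):
        known = [span(1, 20)]
        predicted = [span(100, 120)]
        assert topology_correct(predicted, known) == (False, 0)


class TestStoichiometrySummary:
    def test_perfect_agreement(self):
        df = pd.DataFrame({"chain_id": list("abcd"),
                           "observed": [1, 2, 4, 6], "predicted": [1, 2, 4, 6]})
        s = stoichiometry_summary(df)
        assert s.n_exact == s.n == 4
        assert s.mean_abs_error == 0.0
        assert s.pearson_r == pytest.approx(1.0)
        assert s.mono_multi_accuracy == 1.0

    def test_two_row_hand_computation(self):
        df = pd.DataFrame({"chain_id": ["a", "b"],
                           "observed": [1, 2], "predicted": [2, 1]})
        s = stoichiometry_summary(df)
        assert s.n_exact == 0
        assert s.mean_abs_error == pytest.approx(1.0)
        assert s.mono_multi_accuracy == 0.0
        assert s.false_positive_monomers == 1

    def test_missing_prediction_names_chain(self):
        df = pd.DataFrame({"chain_id": ["a", "b"],
                           "observed": [1, 2], "predicted": [2, None]})
        with pytest.raises(ValidationError, match="b"):
            stoichiometry_summary(df)
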