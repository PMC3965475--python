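"""ROC/AUC, DeLong, NRI, IDI, and the report tables."""

import itertools

import numpy as np
import pytest
from scipy.special import expit

from lipomet.evaluation import (
    binomial_exact_compare,
    delong_compare,
    idi,
    intermediate_risk_reclassification,
    nri,
    percent_incremental_improvement,
    report_tables,
    risk_classes,
    roc_auc,
    z_test_from_delta,
)


def _brute_force_auc(scores, y):
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0)
        for p, q in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_hand_counted_example(self):
        """Cases {0.8, 0.6}, controls {0.6, 0.5}: 3 wins + 1 tie of 4
        pairs -> AUC 3.5/4."""
        p = np.array([0.8, 0.6, 0.6, 0.5])
        y = np.array([1, 1, 0, 0])
        assert roc_auc(p, y).auc == pytest.approx(0.875)

    def test_perfect_separation(self):
        p = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        r = roc_auc(p, y)
        assert r.auc == 1.0
        assert r.improvement == 0.5

    def test_improvement_is_auc_minus_half(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        y = (rng.random(200) < p).astype(int)
        r = roc_auc(p, y)
        assert r.improvement == pytest.approx(r.auc - 0.5, abs=1e-15)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_rank_formula_equals_pair_counting(self):
        """Oracle equivalence on random cohorts up to 200 subjects,
        including ties."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(20, 200)
            scores = np.round(rng.random(n), 2)  # force ties
            y = (rng.random(n) < 0.3).astype(int)
            if y.sum() in (0, n):
                continue
            assert roc_auc(scores, y).auc == pytest.approx(
                _brute_force_auc(scores, y), abs=1e-12
            )

    def test_delong_se_positive(self):
        rng = np.random.default_rng(1)
        p = rng.random(300)
        y = (rng.random(300) < 0.2).astype(int)
        assert roc_auc(p, y).se > 0


class TestDeLong:
    def test_published_z_test_pairs(self):
        """The z-test reproduces the printed p-values from (dAUC, SE):
        (0.0177, 0.00637) -> 0.0055 and (0.0354, 0.00979) -> 0.0003."""
        _, p1 = z_test_from_delta(0.0177, 0.00637)
        _, p2 = z_test_from_delta(0.0354, 0.00979)
        assert round(p1, 4) == 0.0055
        assert round(p2, 4) == 0.0003

    def test_model_vs_itself_is_null(self):
        rng = np.random.default_rng(2)
        p = rng.random(200)
        y = (rng.random(200) < 0.3).astype(int)
        d = delong_compare(p, p, y)
        assert d["delta_auc"] == 0.0
        assert d["p_value"] == 1.0

    def test_detects_clear_improvement(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-2 + 1.5 * x)).astype(int)
        p1 = expit(-2 + 0.2 * x + rng.normal(0, 1, n))
        p2 = expit(-2 + 1.5 * x)
        d = delong_compare(p1, p2, y)
        assert d["delta_auc"] > 0
        assert d["p_value"] < 0.01

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            delong_compare(np.zeros(5), np.zeros(6), np.tile([0, 1], 3))

    def test_binomial_exact_null_for_identical_models(self):
        rng = np.random.default_rng(4)
        p = rng.random(100)
        y = (rng.random(100) < 0.3).astype(int)
        assert binomial_exact_compare(p, p, y)["p_value"] == 1.0


class TestNri:
    def test_identical_classifications_zero(self):
        p = np.array([0.01, 0.10, 0.30, 0.05])
        y = np.array([1, 0, 1, 0])
        r = nri(p, p, y)
        assert r.nri == 0.0

    def test_hand_counted_example(self):
        """2 events (1 up, 1 same), 4 non-events (1 down, 1 up, 2 same):
        NRI = (0.5 - 0) + (0.25 - 0.25) = 0.5."""
        p1 = np.array([0.05, 0.10, 0.10, 0.10, 0.10, 0.10])
        p2 = np.array([0.10, 0.10, 0.05, 0.30, 0.10, 0.10])
        y = np.array([1, 1, 0, 0, 0, 0])
        r = nri(p1, p2, y)
        assert r.nri == pytest.approx(0.5)
        assert r.event_component == pytest.approx(0.5)
        assert r.nonevent_component == pytest.approx(0.0)

    def test_maximum_is_two(self):
        p1 = np.array([0.01, 0.01, 0.50, 0.50])
        p2 = np.array([0.50, 0.50, 0.01, 0.01])
        y = np.array([1, 1, 0, 0])
        assert nri(p1, p2, y).nri == pytest.approx(2.0)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(5)
        p1 = rng.random(500)
        p2 = np.clip(p1 + rng.normal(0, 0.05, 500), 0, 1)
        y = (rng.random(500) < 0.25).astype(int)
        r = nri(p1, p2, y)
        assert r.nri == pytest.approx(r.event_component + r.nonevent_component,
                                      abs=1e-12)

    def test_brute_force_counting(self):
        """NRI equals direct category counting on random cohorts."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(30, 200))
            p1 = rng.random(n)
            p2 = rng.random(n)
            y = (rng.random(n) < 0.3).astype(int)
            if y.sum() in (0, n):
                continue
            c1 = risk_classes(p1)
            c2 = risk_classes(p2)
            ev = y == 1
            exp_e = (np.mean(c2[ev] > c1[ev]) - np.mean(c2[ev] < c1[ev]))
            exp_ne = (np.mean(c2[~ev] < c1[~ev]) - np.mean(c2[~ev] > c1[~ev]))
            assert nri(p1, p2, y).nri == pytest.approx(exp_e + exp_ne, abs=1e-12)

    def test_invalid_cutoffs_rejected(self):
        p = np.array([0.1, 0.2])
        y = np.array([0, 1])
        with pytest.raises(ValueError):
            nri(p, p, y, cutoffs=(0.2, 0.06))


class TestIdi:
    def test_published_decompositions(self):
        """Constructed probability sets whose group-mean changes equal the
        printed values reproduce absolute IDI = 0.0546 and 0.0506."""
        for d_e, d_ne, expected in [(0.0506, -0.0040, 0.0546),
                                    (0.0469, -0.0037, 0.0506)]:
            p1 = np.concatenate([np.full(10, 0.30), np.full(40, 0.10)])
            p2 = np.concatenate([np.full(10, 0.30 + d_e), np.full(40, 0.10 + d_ne)])
            y = np.concatenate([np.ones(10, int), np.zeros(40, int)])
            r = idi(p1, p2, y)
            assert r.idi == pytest.approx(expected, abs=1e-12)
            assert r.delta_mean_events == pytest.approx(d_e)
            assert r.delta_mean_nonevents == pytest.approx(d_ne)

    def test_no_change_zero_idi(self):
        rng = np.random.default_rng(7)
        p = rng.random(100)
        y = (rng.random(100) < 0.3).astype(int)
        assert idi(p, p, y).idi == 0.0

    def test_relative_idi_uses_model1_slope(self):
        rng = np.random.default_rng(8)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-2 + x)).astype(int)
        p1 = expit(-2 + 0.8 * x)
        p2 = expit(-2 + 1.1 * x)
        r = idi(p1, p2, y)
        slope1 = p1[y == 1].mean() - p1[y == 0].mean()
        assert r.relative_idi == pytest.approx(r.idi / slope1, rel=1e-12)

    def test_relative_idi_consistency_across_shared_model1(self):
        """IDI / relative-IDI is the model-1 discrimination slope, hence
        constant across comparisons sharing model 1."""
        rng = np.random.default_rng(9)
        n = 500
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-2 + x)).astype(int)
        p1 = expit(-2 + 0.7 * x)
        ratios = []
        for beta in (0.9, 1.2, 1.5):
            p2 = expit(-2 + beta * x)
            r = idi(p1, p2, y)
            ratios.append(r.idi / r.relative_idi)
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-10)
        assert ratios[1] == pytest.approx(ratios[2], rel=1e-10)


class TestIntermediateRisk:
    def test_empty_subgroup_result(self):
        p1 = np.array([0.01, 0.30, 0.50])
        p2 = np.array([0.10, 0.10, 0.10])
        y = np.array([0, 1, 0])
        r = intermediate_risk_reclassification(p1, p2, y)
        assert r.empty
        assert r.nri == 0.0

    def test_all_nonevents_down_no_events_moved(self):
        """Model 2 moves every intermediate non-event to low risk and no
        event: non-event component 1, event component 0, NRI 1."""
        p1 = np.array([0.10, 0.12, 0.15, 0.10])
        p2 = np.array([0.10, 0.01, 0.01, 0.01])
        y = np.array([1, 0, 0, 0])
        r = intermediate_risk_reclassification(p1, p2, y)
        assert r.nonevent_component == pytest.approx(1.0)
        assert r.event_component == pytest.approx(0.0)
        assert r.nri == pytest.approx(1.0)

    def test_subgroup_restriction(self):
        rng = np.random.default_rng(10)
        p1 = rng.random(400)
        p2 = np.clip(p1 + rng.normal(0, 0.1, 400), 0, 1)
        y = (rng.random(400) < 0.2).astype(int)
        mask = (p1 >= 0.06) & (p1 < 0.20)
        expected = nri(p1[mask], p2[mask], y[mask], allow_empty=True)
        got = intermediate_risk_reclassification(p1, p2, y)
        assert got.nri == pytest.approx(expected.nri)
        assert got.n_events == expected.n_events


class TestReportTables:
    def test_percent_incremental_reproduces_published_rows(self):
        """The reverse-engineered formula reproduces all printed values:
        12.2, 11.0, 12.8, 17.0 from the table's AUC column."""
        base = 0.759
        expected = {0.795: 12.2, 0.791: 11.0, 0.797: 12.8, 0.812: 17.0}
        for auc, pct in expected.items():
            assert round(percent_incremental_improvement(auc, base), 1) == pct
        assert percent_incremental_improvement(base, base) == 0.0

    def test_tables_written_with_expected_schemas(self, tmp_path):
        rng = np.random.default_rng(11)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-2.4 + x)).astype(int)
        models = {
            "baseline": expit(-2.4 + 0.6 * x),
            "better": expit(-2.4 + 1.0 * x),
        }
        tables = report_tables(models, y, baseline="baseline", out_dir=tmp_path)
        assert set(tables) == {
            "table4_roc", "table5_delong", "table6_reclassification",
            "table7_intermediate",
        }
        for name in tables:
            assert (tmp_path / f"{name}.csv").exists()
        t4 = tables["table4_roc"]
        assert list(t4["Model"]) == ["baseline", "better"]
        assert t4["AUC improvement from random"].iloc[0] == pytest.approx(
            t4["AUC"].iloc[0] - 0.5
        )

    def test_missing_baseline_rejected(self):
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError):
            report_tables({"m": np.array([0.1, 0.9, 0.2, 0.8])}, y, baseline="nope")
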