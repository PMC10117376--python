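import numpy as np
import pandas as pd
import pytest

import oracles
from ppikit.bret import (
    analyze_screen,
    anova_tukey,
    background_correct,
    call_interaction,
    call_variant_plate,
    classify_variant,
    corrected_ratio,
)
from ppikit.synth import SynthConfig, gen_bret_screen, gen_variant_screen


def plate_frame(rows):
    return pd.DataFrame(
        rows, columns=["well", "condition", "construct_pair", "Blue1", "Green1"]
    )


def simple_plate():
    rows = [
        ("W1", "untransfected", "none", 100.0, 50.0),
        ("W2", "untransfected", "none", 100.0, 50.0),
        ("W3", "experimental", "X", 1100.0, 550.0),
        ("W4", "donor_only_control", "ctrl", 1100.0, 490.0),
    ]
    return plate_frame(rows)


class TestBackgroundCorrect:
    def test_arithmetic(self):
        corrected, n_floored = background_correct(simple_plate())
        well = corrected[corrected["well"] == "W3"].iloc[0]
        assert (well["Blue1"], well["Green1"]) == (1000.0, 500.0)
        assert n_floored == 0

    def test_floor_at_zero_with_warning(self):
        plate = plate_frame(
            [("W1", "untransfected", "none", 100.0, 50.0),
             ("W2", "experimental", "X", 40.0, 10.0)]
        )
        with pytest.warns(UserWarning, match="floored"):
            corrected, n_floored = background_correct(plate)
        assert n_floored == 2
        assert (corrected[["Blue1", "Green1"]] >= 0).all().all()

    def test_missing_background_wells(self):
        plate = plate_frame([("W1", "experimental", "X", 10.0, 5.0)])
        with pytest.raises(ValueError, match="untransfected"):
            background_correct(plate)


class TestCorrectedRatio:
    def test_null_case(self):
        wells = plate_frame(
            [("W1", "donor_only_control", "c", 1000.0, 400.0),
             ("W2", "donor_only_control", "c", 2000.0, 800.0)]
        )
        ratios = corrected_ratio(wells, wells)
        assert np.allclose(ratios, 0.0)

    def test_arithmetic(self):
        donor = plate_frame([("W1", "donor_only_control", "c", 1000.0, 400.0)])
        exp = plate_frame([("W2", "experimental", "X", 10000.0, 5000.0)])
        assert corrected_ratio(exp, donor) == pytest.approx([0.1])

    def test_zero_blue_excluded(self):
        donor = plate_frame([("W1", "donor_only_control", "c", 1000.0, 400.0)])
        exp = plate_frame(
            [("W2", "experimental", "X", 0.0, 5000.0),
             ("W3", "experimental", "X", 10000.0, 5000.0)]
        )
        with pytest.warns(UserWarning, match="excluded"):
            ratios = corrected_ratio(exp, donor)
        assert len(ratios) == 1

    def test_all_excluded_errors(self):
        donor = plate_frame([("W1", "donor_only_control", "c", 1000.0, 400.0)])
        exp = plate_frame([("W2", "experimental", "X", 0.0, 5000.0)])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="all wells excluded"):
                corrected_ratio(exp, donor)

    def test_generator_inversion_zero_noise(self):
        cfg = SynthConfig(seed=3, bret_noise_cv=0.0,
                          bret_truth={"X": 0.25, "Y": 0.0})
        plate = gen_bret_screen(cfg)
        corrected, _ = background_correct(plate)
        donor = corrected[corrected["condition"] == "donor_only_control"]
        x_wells = corrected[corrected["construct_pair"] == "X"]
        assert corrected_ratio(x_wells, donor) == pytest.approx([0.25] * 3)
        y_wells = corrected[corrected["construct_pair"] == "Y"]
        assert corrected_ratio(y_wells, donor) == pytest.approx([0.0] * 3, abs=1e-12)


class TestAnovaTukey:
    def test_identical_groups_p_near_one(self):
        res = anova_tukey({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.p_between("a", "b") >= 0.99

    def test_near_zero_within_variance(self):
        res = anova_tukey({"a": [0.0, 0.0, 0.0], "b": [10.0, 10.0, 10.0001]})
        assert res.p_between("a", "b") < 0.001

    def test_exactly_degenerate_groups(self):
        res = anova_tukey({"a": [0.0, 0.0], "b": [0.0, 0.0], "c": [1.0, 1.0]})
        assert res.p_between("a", "b") == 1.0
        assert res.p_between("a", "c") == 0.0

    def test_group_with_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="lonely"):
            anova_tukey({"lonely": [1.0], "b": [1.0, 2.0]})

    def test_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {
            "a": [4.2, 5.1, 3.9, 4.8],
            "b": [5.5, 6.1, 5.9, 6.3],
            "c": [4.9, 5.2, 5.0, 5.4],
        }
        res = anova_tukey(groups)
        values = np.concatenate([groups[g] for g in sorted(groups)])
        labels = np.repeat(sorted(groups), 4)
        sm = pairwise_tukeyhsd(values, labels)
        sm_pairs = {
            (row[0], row[1]): row[3] for row in sm.summary().data[1:]
        }
        for (a, b), p_sm in sm_pairs.items():
            assert res.p_between(a, b) == pytest.approx(float(p_sm), abs=1e-3)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        groups = {
            "a": [0.1, 0.5, 0.3, 0.2],
            "b": [0.4, 0.8, 0.6, 0.5],
            "c": [0.2, 0.3, 0.6, 0.4],
        }
        res = anova_tukey(groups)
        perm = oracles.permutation_tukey(groups, n_perm=4000, rng=rng)
        for pair, p_perm in perm.items():
            assert res.p_between(*pair) == pytest.approx(p_perm, abs=0.06)

    def test_invariance_label_permutation_and_shift(self):
        groups = {"a": [1.0, 2.0, 1.5], "b": [3.0, 2.5, 3.5], "c": [0.5, 0.7, 0.4]}
        base = anova_tukey(groups)
        shifted = anova_tukey({k: [x + 42.0 for x in v] for k, v in groups.items()})
        renamed = anova_tukey({"c": groups["c"], "a": groups["a"], "b": groups["b"]})
        for a, b in [("a", "b"), ("a", "c"), ("b", "c")]:
            assert base.p_between(a, b) == pytest.approx(shifted.p_between(a, b))
            assert base.p_between(a, b) == pytest.approx(renamed.p_between(a, b))


class TestCallInteraction:
    @staticmethod
    def _fake_tukey(p_map):
        import pandas as pd

        from ppikit.bret import TukeyResult

        rows = [{"group_a": a, "group_b": b, "diff": 0.1, "q": 1.0, "p_adj": p}
                for (a, b), p in p_map.items()]
        return TukeyResult(0.0, 1.0, pd.DataFrame(rows))

    def test_tier_thresholds(self):
        groups = {"ctrl": [0.0, 0.0], "weak": [0.1, 0.1], "strong": [0.2, 0.2],
                  "edge": [0.3, 0.3]}
        tukey = self._fake_tukey(
            {("ctrl", "weak"): 0.016, ("ctrl", "strong"): 0.0005,
             ("ctrl", "edge"): 0.05}
        )
        result = call_interaction(groups, "ctrl", tukey=tukey)
        assert result.at["weak", "tier"] == "*"
        assert not result.at["weak", "positive"]
        assert result.at["strong", "tier"] == "***"
        assert result.at["strong", "positive"]
        assert result.at["edge", "tier"] == "ns"  # strict inequality at 0.05

    def test_missing_control(self):
        with pytest.raises(ValueError, match="control"):
            call_interaction({"a": [1.0, 2.0], "b": [1.0, 2.0]}, "ctrl")


class TestScreenRecovery:
    def test_planted_positives_recovered(self):
        cfg = SynthConfig(seed=1)
        result = analyze_screen(gen_bret_screen(cfg))
        positives = set(result[result["positive"]].index)
        truth = {c for c, eff in cfg.effective_bret_truth().items() if eff >= 0.05}
        assert positives == truth
        assert len(positives) == 5

    def test_null_screen_centers_on_zero(self):
        cfg = SynthConfig(
            seed=5, bret_truth={f"C{i}": 0.0 for i in range(6)}, bret_noise_cv=0.02
        )
        result = analyze_screen(gen_bret_screen(cfg))
        assert not result["positive"].any()
        se = result["sd_ratio"] / np.sqrt(cfg.n_wells_per_condition)
        assert (result["mean_ratio"].abs() < 3 * se + 1e-9).all()


class TestClassifyVariant:
    def test_rule_definition(self):
        rng = np.random.default_rng(0)
        control = rng.normal(0.0, 0.01, 4)
        wt = rng.normal(0.3, 0.01, 4)
        abolished = rng.normal(0.0, 0.01, 4)
        reduced = rng.normal(0.1, 0.01, 4)
        retained = rng.normal(0.3, 0.01, 4)
        assert classify_variant(abolished, wt, control).call == "abolished"
        assert classify_variant(reduced, wt, control).call == "reduced"
        assert classify_variant(retained, wt, control).call == "retained"

    def test_truth_grid_recovery(self):
        cfg = SynthConfig(seed=2, bret_noise_cv=0.05)
        plates = gen_variant_screen(cfg)
        grid = cfg.effective_variant_truth()
        n_total = n_correct = 0
        for interactor, plate in plates.items():
            for call in call_variant_plate(plate, interactor=interactor):
                n_total += 1
                n_correct += call.call == grid[(call.variant, interactor)]
        assert n_total == 65
        assert n_correct / n_total >= 0.95
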