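import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hrdclass.core_io import ConfigurationError, FeatureMatrix, ValidationError
from hrdclass.selection import (DEFAULT_OVERRIDES, correlation_prune, lognorm,
                                normalise_new_cohort, select_features,
                                wilcoxon_pvalue, wilcoxon_screen)


def _fm(values: pd.DataFrame, block="CNA", state="raw"):
    return FeatureMatrix(values, {f: block for f in values.columns}, state)


class TestLognorm:
    def test_two_point_cohort_hand_computation(self):
        values = pd.DataFrame({"f": [0.0, math.e - 1.0]}, index=["a", "b"])
        out, params = lognorm(_fm(values))
        # ln(x+1) = (0, 1); z with sd over n-1 = (-1/sqrt(2), +1/sqrt(2))
        assert np.allclose(out.values["f"], [-0.7071067811865475,
                                             0.7071067811865475])
        assert params.mean.loc["all", "f"] == pytest.approx(0.5)

    def test_constant_feature_zeroed_with_warning(self, caplog):
        values = pd.DataFrame({"f": [3.0, 3.0, 3.0]})
        with caplog.at_level("WARNING"):
            out, _ = lognorm(_fm(values))
        assert (out.values["f"] == 0).all()
        assert any("constant" in r.message for r in caplog.records)

    def test_negative_raw_value_rejected(self):
        values = pd.DataFrame({"f": [-0.5, 1.0]})
        with pytest.raises(ValidationError):
            FeatureMatrix(values, {"f": "CNA"}, "raw")

    def test_per_cohort_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.random((40, 3)) * 10,
                              index=[f"s{i}" for i in range(40)],
                              columns=list("abc"))
        group = pd.Series(["x"] * 20 + ["y"] * 20, index=values.index)
        out, _ = lognorm(_fm(values), group)
        for cohort in ("x", "y"):
            sub = out.values[group == cohort]
            assert np.allclose(sub.mean(0), 0.0, atol=1e-9)
            assert np.allclose(sub.std(0, ddof=1), 1.0, atol=1e-9)

    def test_stored_parameters_reproduce_transform(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.random((10, 2)), columns=["a", "b"])
        out, params = lognorm(_fm(values))
        again = params.apply(values, "all")
        assert np.allclose(out.values.values, again.values)

    def test_small_new_cohort_reuses_training_parameters(self, caplog):
        rng = np.random.default_rng(2)
        train = pd.DataFrame(rng.random((30, 2)), columns=["a", "b"])
        _, params = lognorm(_fm(train))
        new = _fm(pd.DataFrame(rng.random((5, 2)), columns=["a", "b"]))
        with caplog.at_level("WARNING"):
            out = normalise_new_cohort(new, params, "all")
        assert out.state == "normalised"
        assert any("stored training" in r.message for r in caplog.records)


class TestWilcoxonScreen:
    def _matrix(self, pos, neg, name="f"):
        values = pd.DataFrame({name: pos + neg},
                              index=[f"s{i}" for i in range(len(pos) + len(neg))])
        labels = pd.Series(["positive"] * len(pos) + ["negative"] * len(neg),
                           index=values.index)
        return _fm(values, state="normalised"), labels

    def test_identical_groups_excluded(self):
        fm, labels = self._matrix([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        report = wilcoxon_screen(fm, labels)
        assert report.loc["f", "wilcoxon_p"] == pytest.approx(1.0, abs=0.05)
        assert not report.loc["f", "retained_after_screen"]

    def test_complete_separation_10v10_exact_p(self):
        fm, labels = self._matrix(list(range(11, 21)), list(range(1, 11)))
        report = wilcoxon_screen(fm, labels)
        assert report.loc["f", "wilcoxon_p"] == pytest.approx(
            2 / 184756, rel=1e-9)  # 2 / C(20,10)
        assert report.loc["f", "retained_after_screen"]

    def test_exact_p_matches_permutation_enumeration(self):
        # tiny two-group case: enumerate all C(8,4) label assignments
        pos, neg = [3.1, 0.4, 2.2, 5.0], [1.5, 0.9, 2.8, 0.1]
        data = np.array(pos + neg)
        p = wilcoxon_pvalue(np.array(pos), np.array(neg))
        obs = abs(sum(np.argsort(np.argsort(data))[:4] + 1) - 4 * 9 / 2)
        count = 0
        total = 0
        ranks = np.argsort(np.argsort(data)) + 1
        for combo in itertools.combinations(range(8), 4):
            stat = abs(sum(ranks[list(combo)]) - 4 * 9 / 2)
            total += 1
            if stat >= obs - 1e-9:
                count += 1
        assert p == pytest.approx(count / total, rel=1e-9)

    def test_unknown_samples_excluded_from_test(self):
        fm, labels = self._matrix([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        labels_with_unknown = pd.concat([
            labels, pd.Series(["unknown"], index=["extra"])])
        fm2 = _fm(pd.concat([fm.values,
                             pd.DataFrame({"f": [100.0]}, index=["extra"])]),
                  state="normalised")
        r1 = wilcoxon_screen(fm, labels)
        r2 = wilcoxon_screen(fm2, labels_with_unknown)
        assert r1.loc["f", "wilcoxon_p"] == r2.loc["f", "wilcoxon_p"]

    def test_empty_class_rejected(self):
        fm, labels = self._matrix([1.0, 2.0], [])
        with pytest.raises(ValidationError):
            wilcoxon_screen(fm, labels)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.random((30, 4)), columns=list("abcd"),
                              index=[f"s{i}" for i in range(30)])
        labels = pd.Series(rng.choice(["positive", "negative"], 30),
                           index=values.index)
        fm = _fm(values, state="normalised")
        r1 = wilcoxon_screen(fm, labels)
        perm = rng.permutation(values.index)
        fm2 = _fm(values.loc[perm], state="normalised")
        r2 = wilcoxon_screen(fm2, labels.loc[perm])
        assert np.allclose(r1["wilcoxon_p"], r2["wilcoxon_p"])


class TestCorrelationPrune:
    def _screened(self, values, labels):
        fm = _fm(values, state="normalised")
        return fm, wilcoxon_screen(fm, labels)

    def _labels(self, n):
        return pd.Series((["positive"] * (n // 2) + ["negative"] * (n - n // 2)),
                         index=[f"s{i}" for i in range(n)])

    def test_duplicated_feature_loses_to_smaller_p(self):
        rng = np.random.default_rng(0)
        n = 30
        labels = self._labels(n)
        signal = np.r_[rng.normal(2, 1, n // 2), rng.normal(0, 1, n - n // 2)]
        values = pd.DataFrame({"a": signal, "b": signal.copy()},
                              index=labels.index)
        fm, report = self._screened(values, labels)
        pruned = correlation_prune(fm, report, r_threshold=0.8)
        assert int(pruned["final_retained"].sum()) == 1
        victim = pruned.index[~pruned["final_retained"]][0]
        assert pruned.loc[victim, "pruned_by"] in ("a", "b")

    def test_sub_threshold_pair_kept(self):
        rng = np.random.default_rng(1)
        n = 200
        labels = self._labels(n)
        x = rng.normal(size=n) + np.r_[np.full(n // 2, 1.0), np.zeros(n - n // 2)]
        # construct partner with |r| just below threshold
        y = 0.62 * x + rng.normal(size=n)
        values = pd.DataFrame({"a": x, "b": y}, index=labels.index)
        fm, report = self._screened(values, labels)
        r = abs(np.corrcoef(x, y)[0, 1])
        assert r < 0.8
        pruned = correlation_prune(fm, report, r_threshold=0.8)
        assert pruned["final_retained"].sum() == report["retained_after_screen"].sum()

    def test_manual_override_names_the_victim(self):
        rng = np.random.default_rng(2)
        n = 30
        labels = self._labels(n)
        signal = np.r_[rng.normal(2, 1, n // 2), rng.normal(0, 1, n - n // 2)]
        values = pd.DataFrame({"keepme": signal + rng.normal(0, 0.01, n),
                               "SBS2": signal},
                              index=labels.index)
        blocks = {"keepme": "SNV", "SBS2": "SNV"}
        fm = FeatureMatrix(values, blocks, "normalised")
        report = wilcoxon_screen(fm, labels)
        pruned = correlation_prune(fm, report, manual_overrides=("SBS2",))
        assert not pruned.loc["SBS2", "final_retained"]
        assert pruned.loc["keepme", "final_retained"]

    def test_default_overrides_ship_documented_manual_choices(self):
        assert set(DEFAULT_OVERRIDES) == {"td_region_size", "SBS2"}

    def test_unknown_override_rejected(self):
        rng = np.random.default_rng(3)
        labels = self._labels(10)
        values = pd.DataFrame({"a": rng.random(10)}, index=labels.index)
        fm, report = self._screened(values, labels)
        with pytest.raises(ConfigurationError):
            correlation_prune(fm, report, manual_overrides=("nope",))


def test_planted_signal_passes_screen_and_noise_fails_at_alpha_rate():
    from hrdclass import SimulationConfig, simulate_feature_level
    from hrdclass.selection import lognorm as _ln
    # a screening-scale cohort: the screen must have the power to see every
    # planted shift, while pure noise passes only at the alpha rate
    fm, labels_tab, _ = simulate_feature_level(
        SimulationConfig(n_samples=800, seed=5))
    labels = labels_tab.set_index("sample_id")["hrd_status"]
    fmn, _ = _ln(fm)
    report = wilcoxon_screen(fmn, labels)
    # every feature carries planted signal in the default generator
    assert report["retained_after_screen"].all()
    # pure-noise features: false-positive rate compatible with alpha = 0.05
    rng = np.random.default_rng(0)
    n_rep, hits = 200, 0
    idx = fm.values.index[:120]
    labels = labels.iloc[:120]
    pos = labels == "positive"
    neg = labels == "negative"
    for _ in range(n_rep):
        noise = rng.normal(size=len(idx))
        if wilcoxon_pvalue(noise[pos.to_numpy()], noise[neg.to_numpy()]) <= 0.05:
            hits += 1
    # binomial(200, 0.05): central 99.9% interval roughly [1, 22]
    assert 0 <= hits <= 25
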