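"""Empirical-FDR thresholding of 5C interaction-score differences."""

import numpy as np
import pytest

from loopdiff.fivec.classify import (ClassifyConfig, background_filter,
                                     cluster_classified, difference_classify,
                                     differential_classes, efdr_map,
                                     select_threshold, significance_filter)

B = -10 * np.log2(0.8)      # ~3.219
G = -10 * np.log2(0.165)    # ~26.0


def _stack(values):
    """dict cond -> (n_reps, 1, 1) IS array from {cond: [rep values]}."""
    return {c: np.asarray(v, dtype=float).reshape(-1, 1, 1)
            for c, v in values.items()}


class TestConfig:
    def test_defaults_are_consistent(self):
        cfg = ClassifyConfig()
        assert cfg.background_threshold == pytest.approx(B)
        assert cfg.significance_threshold == pytest.approx(G)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ClassifyConfig(background_threshold=30, significance_threshold=5)
        with pytest.raises(ValueError):
            ClassifyConfig(tau=0.0)
        with pytest.raises(ValueError):
            ClassifyConfig(sweep=np.array([2.0, 1.0]))


class TestFilters:
    conds = ["A", "B", "C"]

    def test_background_max_rule(self):
        st = _stack({"A": [2.0, 2.0], "B": [2.0, 2.0], "C": [2.0, 2.0]})
        assert background_filter(st, self.conds, B)[0, 0]
        st["B"][1] = 5.0  # a single replicate above b rescues the pixel
        assert not background_filter(st, self.conds, B)[0, 0]

    def test_empty_replicate_set_rejected(self):
        with pytest.raises(ValueError):
            background_filter({}, [], B)

    def test_significance_min_over_replicates(self):
        st = _stack({"A": [30.0, 28.0], "B": [5.0, 5.0], "C": [5.0, 5.0]})
        assert significance_filter(st, self.conds, G)[0, 0]
        # every condition has one replicate below g
        st = _stack({"A": [30.0, 20.0], "B": [30.0, 20.0], "C": [30.0, 20.0]})
        assert not significance_filter(st, self.conds, G)[0, 0]

    def test_exactly_at_threshold_not_candidate(self):
        st = _stack({"A": [G, G], "B": [5.0, 5.0], "C": [5.0, 5.0]})
        assert not significance_filter(st, self.conds, G)[0, 0]


class TestDifferenceClassify:
    conds = ["A", "B", "C"]

    def test_single_condition_class(self):
        st = _stack({"A": [30.0, 31.0], "B": [10.0, 11.0], "C": [12.0, 12.0]})
        masks = difference_classify(st, self.conds, d=10.0, g=G)
        assert masks[frozenset(["A"])][0, 0]

    def test_dual_condition_class(self):
        st = _stack({"A": [30.0, 31.0], "B": [29.0, 30.0], "C": [10.0, 10.0]})
        masks = difference_classify(st, self.conds, d=10.0, g=G)
        assert masks[frozenset(["A", "B"])][0, 0]
        assert not masks[frozenset(["A"])][0, 0]

    def test_equal_conditions_constitutive(self):
        st = _stack({"A": [30.0, 30.0], "B": [30.0, 30.0], "C": [30.0, 30.0]})
        masks = difference_classify(st, self.conds, d=5.0, g=G)
        assert masks["constitutive"][0, 0]
        assert not any(masks[c][0, 0] for c in differential_classes(self.conds))

    def test_two_condition_mode(self):
        st = _stack({"A": [30.0, 31.0], "B": [10.0, 11.0]})
        masks = difference_classify(st, ["A", "B"], d=10.0, g=G)
        assert masks[frozenset(["A"])][0, 0]
        assert differential_classes(["A", "B"]) == [frozenset(["A"]),
                                                    frozenset(["B"])]


class TestThresholdSelection:
    def test_closest_below_tau(self):
        d = select_threshold([5.0, 6.0, 7.0], [0.05, 0.018, 0.004], tau=0.02)
        assert d == 6.0

    def test_none_when_no_threshold_qualifies(self):
        assert select_threshold([1.0, 2.0], [0.5, 0.3], tau=0.02) is None


def _random_stacks(rng, conds, n_reps=2, m=24, shift=None):
    """IS-like stacks with spatially smooth positive scores."""
    base = rng.gamma(2.0, 8.0, size=(m, m))
    base = (base + base.T) / 2
    out = {}
    for ci, c in enumerate(conds):
        reps = []
        for _ in range(n_reps):
            noise = rng.normal(0, 2.0, size=(m, m))
            mat = base + (noise + noise.T) / 2
            if shift is not None:
                mat = mat + shift.get(c, 0.0)
            reps.append(np.clip(mat, 0, None))
        out[c] = np.stack(reps)
    return out


class TestEFDR:
    conds = ["A", "B", "C"]

    def test_call_counts_non_increasing_in_threshold(self):
        rng = np.random.default_rng(0)
        st = {"r": _random_stacks(rng, self.conds,
                                  shift={"A": 15.0})}
        cfg = ClassifyConfig(sweep=np.arange(1.0, 20.0, 1.0))
        emap = efdr_map(st, [st], self.conds, cfg)
        for cls, counts in emap.n_exp.items():
            assert (np.diff(counts) <= 0).all()

    def test_efdr_is_one_when_experiment_equals_null(self):
        rng = np.random.default_rng(1)
        st = {"r": _random_stacks(rng, self.conds, shift={"A": 12.0})}
        cfg = ClassifyConfig(sweep=np.arange(1.0, 10.0, 1.0))
        emap = efdr_map(st, [st], self.conds, cfg)
        for cls in differential_classes(self.conds):
            called = emap.n_exp[cls] > 0
            assert np.allclose(emap.efdr[cls][called], 1.0)
            assert np.all(emap.efdr[cls][~called] == 0.0)

    def test_null_averaging_uses_mean_count(self):
        rng = np.random.default_rng(2)
        exp = {"r": _random_stacks(rng, self.conds, shift={"A": 15.0})}
        null1 = {"r": _random_stacks(rng, self.conds)}
        null2 = {"r": _random_stacks(rng, self.conds)}
        cfg = ClassifyConfig(sweep=np.array([2.0]))
        e1 = efdr_map(exp, [null1], self.conds, cfg)
        e2 = efdr_map(exp, [null2], self.conds, cfg)
        e12 = efdr_map(exp, [null1, null2], self.conds, cfg)
        for cls in differential_classes(self.conds):
            assert e12.n_null[cls][0] == pytest.approx(
                (e1.n_null[cls][0] + e2.n_null[cls][0]) / 2)

    def test_differential_shift_is_detected_and_clustered(self):
        rng = np.random.default_rng(3)
        # strong A-specific block on an otherwise shared background
        stacks = _random_stacks(rng, self.conds)
        stacks["A"] = stacks["A"] + 0.0
        block = np.zeros((24, 24))
        block[5:8, 15:18] = 40.0
        stacks["A"] = stacks["A"] + block
        for c in self.conds:
            stacks[c] = stacks[c] + 10.0  # lift everything above g occasionally
        exp = {"r": stacks}
        nulls = [{"r": _random_stacks(np.random.default_rng(40 + i),
                                      self.conds, shift={c: 10.0 for c in
                                                         self.conds})}
                 for i in range(2)]
        cfg = ClassifyConfig(sweep=np.arange(1.0, 30.0, 1.0))
        emap = efdr_map(exp, nulls, self.conds, cfg)
        a_cls = frozenset(["A"])
        if emap.selected[a_cls] is not None:
            mask = emap.final_masks[a_cls]["r"]
            assert mask[5:8, 15:18].sum() >= 6
            clusters = cluster_classified({a_cls: {"r": mask}}, min_size=3)
            assert len(clusters[a_cls]["r"]) >= 1
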