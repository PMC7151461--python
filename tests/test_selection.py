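import numpy as np
import pandas as pd
import pytest

from voitex import correlation_filter, recursive_feature_elimination, selection_sweep
from voitex.errors import SelectionError
from voitex.selection import feature_columns


def _table(features: dict[str, np.ndarray], classes=None) -> pd.DataFrame:
    n = len(next(iter(features.values())))
    if classes is None:
        classes = np.where(np.arange(n) % 2 == 0, "control", "pd")
    df = pd.DataFrame({"scan_id": [f"s{i}" for i in range(n)], "class": classes})
    for name, vals in features.items():
        df[name] = vals
    return df


def _planted_table(seed: int, n: int = 150, informative: int = 3, noise: int = 17):
    """3-class table: `informative` features carry class mean shifts."""
    rng = np.random.default_rng(seed)
    classes = np.repeat(["control", "prodromal", "pd"], n // 3)
    shift = {"control": 0.0, "prodromal": 1.5, "pd": 3.0}
    feats = {}
    for i in range(informative):
        feats[f"signal_{i}"] = np.array(
            [shift[c] for c in classes]
        ) + rng.normal(0, 1.0, size=len(classes))
    for i in range(noise):
        feats[f"noise_{i}"] = rng.normal(size=len(classes))
    return _table(feats, classes)


class TestCorrelationFilter:
    def test_exact_duplicate_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        table = _table({"a": x, "a_copy": x.copy(), "b": rng.normal(size=100)})
        reduced, log = correlation_filter(table)
        survivors = feature_columns(reduced)
        assert len(survivors) == 2
        assert "b" in survivors
        assert len([d for d, _, r in log if r > 0.999]) == 1

    def test_independent_noise_survives(self):
        rng = np.random.default_rng(1)
        table = _table({"x": rng.normal(size=200), "y": rng.normal(size=200)})
        reduced, log = correlation_filter(table, threshold=0.90)
        assert len(feature_columns(reduced)) == 2
        assert log == []

    def test_planted_block_matches_greedy_oracle(self):
        # 10 features, one correlated block of 3; oracle = hand-run greedy
        rng = np.random.default_rng(2)
        base = rng.normal(size=200)
        feats = {
            "b0": base + rng.normal(0, 0.1, 200),
            "b1": base + rng.normal(0, 0.1, 200),
            "b2": base + rng.normal(0, 0.1, 200),
        }
        for i in range(7):
            feats[f"n{i}"] = rng.normal(size=200)
        table = _table(feats)
        reduced, log = correlation_filter(table, threshold=0.90)

        # independent greedy oracle on the same |r| matrix
        cols = feature_columns(table)
        corr = np.abs(np.corrcoef(table[cols].to_numpy(float).T))
        alive = list(range(len(cols)))
        while True:
            sub = corr[np.ix_(alive, alive)].copy()
            np.fill_diagonal(sub, 0)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[i, j] <= 0.90:
                break
            mean_r = sub.sum(axis=0) / (len(alive) - 1)
            drop = i if mean_r[i] >= mean_r[j] else j
            alive.pop(drop)
        expected = {cols[i] for i in alive}
        assert set(feature_columns(reduced)) == expected

    def test_no_surviving_pair_above_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=120)
        feats = {f"f{i}": base * (i % 3) + rng.normal(size=120) for i in range(12)}
        reduced, _ = correlation_filter(_table(feats), threshold=0.90)
        cols = feature_columns(reduced)
        vals = reduced[cols].to_numpy(float)
        varying = vals.std(axis=0) > 0
        corr = np.abs(np.corrcoef(vals[:, varying].T))
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.90

    def test_idempotence(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=100)
        feats = {f"f{i}": base + rng.normal(0, 0.2 * (i + 1), 100) for i in range(6)}
        reduced, _ = correlation_filter(_table(feats))
        again, log = correlation_filter(reduced)
        assert log == []
        assert feature_columns(again) == feature_columns(reduced)

    def test_monotone_screening(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=100)
        feats = {f"f{i}": base + rng.normal(0, 0.3 * (i + 1), 100) for i in range(8)}
        table = _table(feats)
        counts = []
        for thr in (0.95, 0.8, 0.6, 0.4):
            reduced, _ = correlation_filter(table, threshold=thr)
            counts.append(len(feature_columns(reduced)))
        assert counts == sorted(counts, reverse=True)

    def test_zero_variance_retained_with_warning(self, caplog):
        rng = np.random.default_rng(6)
        table = _table({"const": np.ones(50), "x": rng.normal(size=50)})
        reduced, _ = correlation_filter(table)
        assert "const" in feature_columns(reduced)
        assert "zero-variance" in caplog.text


class TestRFE:
    def test_k_equals_all_features(self):
        table = _planted_table(0, n=60, informative=2, noise=3)
        result = recursive_feature_elimination(table, k=5)
        assert len(result.kept) == 5
        assert sorted(result.rfe_ranking.values()) == [1, 2, 3, 4, 5]

    def test_k_too_large_rejected(self):
        table = _planted_table(0, n=60, informative=2, noise=3)
        with pytest.raises(SelectionError, match="exceeds"):
            recursive_feature_elimination(table, k=6)

    def test_planted_signal_recovery(self):
        # 3 informative + 17 noise, n=150: recover all 3 in >= 90% of 20 runs
        hits = 0
        for seed in range(20):
            table = _planted_table(seed)
            result = recursive_feature_elimination(table, k=3, seed=seed)
            if set(result.kept) == {"signal_0", "signal_1", "signal_2"}:
                hits += 1
        assert hits >= 18

    def test_kept_size_20_from_65(self):
        rng = np.random.default_rng(9)
        classes = np.repeat(["control", "prodromal", "pd"], 30)
        feats = {f"f{i}": rng.normal(size=90) for i in range(65)}
        table = _table(feats, classes)
        result = recursive_feature_elimination(table, k=20)
        assert len(result.kept) == 20

    def test_scale_invariance(self):
        table = _planted_table(2)
        rescaled = table.copy()
        for i, col in enumerate(feature_columns(table)):
            rescaled[col] = table[col] * (10.0 ** (i % 5)) + i * 3.0
        r1 = recursive_feature_elimination(table, k=4)
        r2 = recursive_feature_elimination(rescaled, k=4)
        assert r1.kept == r2.kept

    def test_determinism(self):
        table = _planted_table(3)
        r1 = recursive_feature_elimination(table, k=5, seed=1)
        r2 = recursive_feature_elimination(table, k=5, seed=1)
        assert r1.kept == r2.kept
        assert r1.rfe_ranking == r2.rfe_ranking


class TestSelectionSweep:
    def test_single_k(self):
        table = _planted_table(4, n=90)
        scores = selection_sweep(table, k_list=(5,))
        assert list(scores) == [5]
        assert 0.0 <= scores[5] <= 1.0

    def test_separable_scores_stable_across_k(self):
        table = _planted_table(5, n=120)
        # triple the shift for near-separability
        for col in ("signal_0", "signal_1", "signal_2"):
            table[col] = table[col] * 3
        scores = selection_sweep(table, k_list=(3, 10, 20))
        assert max(scores.values()) - min(scores.values()) < 0.15

    def test_twenty_informative_prefers_larger_k(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            classes = np.repeat(["control", "prodromal", "pd"], 50)
            feats = {}
            shift = {"control": 0.0, "prodromal": 0.8, "pd": 1.6}
            for i in range(20):
                feats[f"s{i}"] = np.array([shift[c] for c in classes]) + rng.normal(
                    0, 1, 150
                )
            for i in range(20):
                feats[f"n{i}"] = rng.normal(size=150)
            table = _table(feats, classes)
            scores = selection_sweep(table, k_list=(10, 20), seed=seed)
            if scores[20] >= scores[10]:
                wins += 1
        assert wins >= 16
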