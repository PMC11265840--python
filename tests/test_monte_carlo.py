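"""Monte Carlo pool construction and accuracy-spread simulation."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from her2pss.classifier import forward
from her2pss.inference import (
    aggregate_max,
    derive_pss_seeds,
    kcs_select,
    make_record,
)
from her2pss.labels import ScoreLabel
from her2pss.monte_carlo import (
    PredictionPool,
    build_pool,
    load_pool,
    save_pool,
    simulate_accuracy,
    sweep,
)
from her2pss.pyramid import sample_pss
from her2pss.synthetic import CoreSpec, generate_core


def _toy_pool(per_core_probs: dict[str, list], labels: dict[str, int]):
    records = {
        cid: [make_record(i, p) for i, p in enumerate(probs)]
        for cid, probs in per_core_probs.items()
    }
    size = len(next(iter(records.values())))
    return PredictionPool(
        records=records,
        labels={c: ScoreLabel(v) for c, v in labels.items()},
        pool_size=size,
    )


@pytest.fixture(scope="module")
def tiny_pool(random_model):
    cores = []
    for i, score in enumerate([0, 1, 2, 3]):
        core, label = generate_core(
            CoreSpec(diameter_px=96, score=score, seed=40 + i), core_id=f"t{i}"
        )
        cores.append((core, label))
    return build_pool(random_model, cores, pool_size=5, seed=8), cores


def test_build_pool_counts_and_determinism(tiny_pool, random_model):
    pool, cores = tiny_pool
    assert pool.pool_size == 5
    assert sum(len(r) for r in pool.records.values()) == 20
    again = build_pool(random_model, cores, pool_size=5, seed=8)
    for cid in pool.core_ids:
        assert [r.probs for r in pool.records[cid]] == [
            r.probs for r in again.records[cid]
        ]


def test_pool_records_match_direct_inference_replay(tiny_pool, random_model):
    """Pool records replay exactly as a direct per-seed forward pass."""
    pool, cores = tiny_pool
    core_seeds = derive_pss_seeds(8, len(cores))
    core, _ = cores[2]
    expected = []
    for pss_seed in derive_pss_seeds(core_seeds[2], 5):
        pss = sample_pss(core, random_model.pyramid_config, seed=pss_seed)
        expected.append(make_record(pss_seed, forward(random_model, pss)))
    got = pool.records[core.core_id]
    assert [r.probs for r in got] == [r.probs for r in expected]
    assert [r.predicted_class for r in got] == [r.predicted_class for r in expected]


def test_full_pool_draw_has_zero_spread(tiny_pool):
    pool, _ = tiny_pool
    accs = simulate_accuracy(pool, n=pool.pool_size, k=2, reps=50, seed=0)
    assert accs.min() == accs.max()


def test_single_rep_degenerate(tiny_pool):
    pool, _ = tiny_pool
    accs = simulate_accuracy(pool, n=2, k=1, reps=1, seed=3)
    assert accs.shape == (1,)


def test_n_larger_than_pool_rejected(tiny_pool):
    pool, _ = tiny_pool
    with pytest.raises(ValueError):
        simulate_accuracy(pool, n=pool.pool_size + 1, k=1, reps=10, seed=0)


def _exact_distribution(pool: PredictionPool, n: int, k: int):
    """Enumerate every per-core subset combination exactly."""
    per_core = []
    for cid in pool.core_ids:
        recs = pool.records[cid]
        label = int(pool.labels[cid])
        outcomes = []
        for subset in itertools.combinations(recs, n):
            final = int(aggregate_max(kcs_select(list(subset), k)))
            outcomes.append(final == label)
        per_core.append(outcomes)
    dist: dict[float, float] = {}
    total = np.prod([len(o) for o in per_core])
    for combo in itertools.product(*per_core):
        acc = sum(combo) / len(combo)
        dist[acc] = dist.get(acc, 0.0) + 1.0 / total
    return dist


def test_simulated_distribution_matches_exact_enumeration():
    """On an enumerable toy pool (4 records/core, 2 cores, N=2, k=1) the
    simulated accuracy distribution converges to the exact subset
    enumeration (total variation < 0.02 at 10^4 reps)."""
    pool = _toy_pool(
        {
            "a": [
                [0.7, 0.1, 0.1, 0.1],
                [0.1, 0.6, 0.2, 0.1],
                [0.4, 0.3, 0.2, 0.1],
                [0.2, 0.2, 0.2, 0.4],
            ],
            "b": [
                [0.1, 0.1, 0.2, 0.6],
                [0.1, 0.2, 0.6, 0.1],
                [0.25, 0.25, 0.25, 0.25],
                [0.05, 0.05, 0.3, 0.6],
            ],
        },
        {"a": 0, "b": 3},
    )
    exact = _exact_distribution(pool, n=2, k=1)
    accs = simulate_accuracy(pool, n=2, k=1, reps=10_000, seed=5)
    values, counts = np.unique(accs, return_counts=True)
    empirical = dict(zip(values.tolist(), (counts / counts.sum()).tolist()))
    support = set(exact) | set(empirical)
    tv = 0.5 * sum(abs(exact.get(v, 0) - empirical.get(v, 0)) for v in support)
    assert tv < 0.02


def test_sweep_summary_and_designated_cell(tiny_pool):
    pool, _ = tiny_pool
    result = sweep(
        pool, n_grid=[2, 5], k_grid=[1, 2], reps=200, seed=9, designated_cell=(2, 1)
    )
    assert len(result.summary) == 4
    row_full = result.summary.query("N == 5 and k == 1").iloc[0]
    assert row_full["spread"] == 0.0  # N == pool_size
    for _, row in result.summary.iterrows():
        sample = result.samples[(row.N, row.k)]
        assert row["median"] == pytest.approx(np.median(sample))
        assert row["min"] <= row["median"] <= row["max"]
    assert set(result.confusion_matrices) == {"min", "median", "max"}
    for name, cm in result.confusion_matrices.items():
        assert cm.sum() == len(pool.core_ids)
    sample = result.samples[(2, 1)]
    assert result.confusion_matrices["min"].trace() / cm.sum() == pytest.approx(
        sample.min()
    )
    assert result.confusion_matrices["max"].trace() / cm.sum() == pytest.approx(
        sample.max()
    )


def test_sweep_reproducible(tiny_pool):
    pool, _ = tiny_pool
    r1 = sweep(pool, [2, 4], [1], reps=100, seed=2)
    r2 = sweep(pool, [2, 4], [1], reps=100, seed=2)
    for key in r1.samples:
        np.testing.assert_array_equal(r1.samples[key], r2.samples[key])


def test_pool_save_load_round_trip(tmp_path, tiny_pool):
    pool, _ = tiny_pool
    save_pool(tmp_path / "pool", pool)
    loaded = load_pool(tmp_path / "pool")
    assert loaded.pool_size == pool.pool_size
    assert loaded.core_ids == pool.core_ids
    for cid in pool.core_ids:
        got = [r.probs for r in loaded.records[cid]]
        want = [r.probs for r in pool.records[cid]]
        np.testing.assert_allclose(got, want, atol=1e-12)
        assert loaded.labels[cid] == pool.labels[cid]
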