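"""Monte Carlo analysis of the inference hyperparameters N and k.

The replicate protocol introduces sampling randomness: which N PSSs are
drawn, and which k of them end up in the confident set, varies between
runs. To quantify that variability without re-running the network, a
*prediction pool* of ``pool_size`` replicate predictions per test core is
built once and cached; each simulation reputation then draws, per core, N
records from its pool **without replacement**, applies the KCS/max
protocol, and records the overall accuracy. Repeating this many times
(10,000 at full scale) yields an accuracy distribution per (N, k) cell
whose min/median/max summarize the stability of the protocol. At
N = pool_size every draw is the whole pool, so the spread collapses to
exactly zero.

Desk-scale defaults (pool_size 30, 1,000 repetitions, N up to 30) keep the
sweep in CPU-seconds; the full-scale values (300 PSSs per core, 10,000
repetitions, N to 200, k to 100) remain plain configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import TrainedModel, forward
from .inference import make_record, PredictionRecord, derive_pss_seeds
from .labels import ScoreLabel, parse_score
from .pyramid import PyramidConfig, sample_pss
from .types import CoreImage

__all__ = [
    "PredictionPool",
    "SweepResult",
    "build_pool",
    "simulate_accuracy",
    "sweep",
    "save_pool",
    "load_pool",
]

DEFAULT_POOL_SIZE = 30
DEFAULT_REPS = 1_000


@dataclass
class PredictionPool:
    """Cached replicate predictions: core_id -> pool_size records + label."""

    records: dict[str, list[PredictionRecord]]
    labels: dict[str, ScoreLabel]
    pool_size: int

    def __post_init__(self) -> None:
        for cid, recs in self.records.items():
            if len(recs) != self.pool_size:
                raise ValueError(
                    f"core {cid!r} has {len(recs)} records, expected {self.pool_size}"
                )
            if cid not in self.labels:
                raise ValueError(f"core {cid!r} has records but no label")

    @property
    def core_ids(self) -> list[str]:
        return sorted(self.records)


def build_pool(
    model: TrainedModel,
    labeled_cores: list[tuple[CoreImage, ScoreLabel]],
    pool_size: int = DEFAULT_POOL_SIZE,
    pyramid_config: PyramidConfig | None = None,
    seed: int = 0,
    confidence_method: str = "margin",
) -> PredictionPool:
    """Score ``pool_size`` independent PSSs per core and cache the records.

    Replicate seeds are derived per core from ``seed`` and the core's
    position, so rebuilding with the same arguments reproduces the pool
    bit-identically.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    config = pyramid_config or model.pyramid_config
    records: dict[str, list[PredictionRecord]] = {}
    labels: dict[str, ScoreLabel] = {}
    core_seeds = derive_pss_seeds(seed, len(labeled_cores))
    for (core, label), cseed in zip(labeled_cores, core_seeds):
        recs = []
        for pss_seed in derive_pss_seeds(cseed, pool_size):
            pss = sample_pss(core, config, seed=pss_seed)
            recs.append(make_record(pss_seed, forward(model, pss), confidence_method))
        records[core.core_id] = recs
        labels[core.core_id] = ScoreLabel(int(label))
    return PredictionPool(records=records, labels=labels, pool_size=pool_size)


def _pool_arrays(pool: PredictionPool):
    """Per-core (confidence-rank, predicted-class) arrays for fast replay.

    ``rank[i]`` is the KCS order of record i (0 = most confident, ties by
    lower seed); taking the subset members with the smallest ranks is
    exactly ``kcs_select`` restricted to the subset.
    """
    out = []
    for cid in pool.core_ids:
        recs = pool.records[cid]
        order = sorted(
            range(len(recs)), key=lambda i: (-recs[i].confidence, recs[i].pss_seed)
        )
        rank = np.empty(len(recs), dtype=np.int64)
        rank[order] = np.arange(len(recs))
        preds = np.array([int(r.predicted_class) for r in recs], dtype=np.int64)
        out.append((rank, preds, int(pool.labels[cid])))
    return out


def simulate_accuracy(
    pool: PredictionPool,
    n: int,
    k: int,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    return_predictions: bool = False,
):
    """Accuracy sample over ``reps`` random replays of the (N, k) protocol.

    Each repetition draws, independently per core, ``n`` records uniformly
    without replacement from that core's pool, selects the ``k`` most
    confident and takes the maximum class; the repetition's accuracy is the
    fraction of cores whose final score matches the consensus label.
    """
    if not 1 <= n <= pool.pool_size:
        raise ValueError(f"N must be in 1..pool_size={pool.pool_size}, got {n}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    arrays = _pool_arrays(pool)
    rng = np.random.default_rng(seed)
    kk = min(k, n)
    accs = np.empty(reps)
    preds = (
        np.empty((reps, len(arrays)), dtype=np.int64) if return_predictions else None
    )
    for rep in range(reps):
        correct = 0
        for j, (rank, cls, label) in enumerate(arrays):
            idx = rng.choice(pool.pool_size, size=n, replace=False)
            chosen = idx[np.argsort(rank[idx], kind="stable")[:kk]]
            final = cls[chosen].max()
            if preds is not None:
                preds[rep, j] = final
            correct += final == label
        accs[rep] = correct / len(arrays)
    if return_predictions:
        return accs, preds
    return accs


@dataclass
class SweepResult:
    """Accuracy summaries per (N, k) cell plus designated-cell artifacts."""

    summary: pd.DataFrame
    samples: dict[tuple[int, int], np.ndarray]
    designated_cell: tuple[int, int] | None = None
    confusion_matrices: dict[str, np.ndarray] = field(default_factory=dict)


def _confusion_from_preds(labels: np.ndarray, preds: np.ndarray) -> np.ndarray:
    cm = np.zeros((4, 4), dtype=np.int64)
    np.add.at(cm, (labels, preds), 1)
    return cm


def sweep(
    pool: PredictionPool,
    n_grid,
    k_grid,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    designated_cell: tuple[int, int] | None = None,
) -> SweepResult:
    """Simulate every (N, k) cell of a grid and summarize the spreads.

    For the designated cell (default: (20, 5) when present in the grid)
    the repetitions achieving the minimum, median and maximum accuracy are
    re-materialized into 4x4 confusion matrices.
    """
    n_grid = sorted(set(int(n) for n in n_grid))
    k_grid = sorted(set(int(k) for k in k_grid))
    if not n_grid or not k_grid:
        raise ValueError("N and k grids must be non-empty")
    if max(n_grid) > pool.pool_size:
        raise ValueError(
            f"max N {max(n_grid)} exceeds pool_size {pool.pool_size}"
        )
    if designated_cell is None and (20 in n_grid and 5 in k_grid):
        designated_cell = (20, 5)

    labels = np.array(
        [int(pool.labels[cid]) for cid in pool.core_ids], dtype=np.int64
    )
    ss = np.random.SeedSequence(seed)
    cell_seeds = {
        (n, k): int(s.generate_state(1)[0] % 2**31)
        for (n, k), s in zip(
            [(n, k) for n in n_grid for k in k_grid],
            ss.spawn(len(n_grid) * len(k_grid)),
        )
    }

    rows = []
    samples: dict[tuple[int, int], np.ndarray] = {}
    matrices: dict[str, np.ndarray] = {}
    for n in n_grid:
        for k in k_grid:
            want_cm = designated_cell == (n, k)
            result = simulate_accuracy(
                pool, n, k, reps=reps, seed=cell_seeds[(n, k)],
                return_predictions=want_cm,
            )
            accs, preds = result if want_cm else (result, None)
            samples[(n, k)] = accs
            rows.append(
                {
                    "N": n,
                    "k": k,
                    "min": accs.min(),
                    "q25": np.quantile(accs, 0.25),
                    "median": np.median(accs),
                    "q75": np.quantile(accs, 0.75),
                    "max": accs.max(),
                    "spread": accs.max() - accs.min(),
                }
            )
            if want_cm:
                order = np.argsort(accs, kind="stable")
                picks = {
                    "min": order[0],
                    "median": order[len(order) // 2],
                    "max": order[-1],
                }
                for name, rep in picks.items():
                    matrices[name] = _confusion_from_preds(labels, preds[rep])
    return SweepResult(
        summary=pd.DataFrame(rows),
        samples=samples,
        designated_cell=designated_cell,
        confusion_matrices=matrices,
    )


def save_pool(directory, pool: PredictionPool) -> None:
    """Write a pool as per-core CSV record files plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for cid in pool.core_ids:
        recs = pool.records[cid]
        path = directory / f"{cid}.records.csv"
        pd.DataFrame(
            {
                "pss_seed": [r.pss_seed for r in recs],
                "p0": [r.probs[0] for r in recs],
                "p1": [r.probs[1] for r in recs],
                "p2": [r.probs[2] for r in recs],
                "p3": [r.probs[3] for r in recs],
                "pred": [str(r.predicted_class) for r in recs],
                "confidence": [r.confidence for r in recs],
            }
        ).to_csv(path, index=False)
        manifest.append(
            {"core_id": cid, "label": str(pool.labels[cid]), "path": path.name}
        )
    pd.DataFrame(manifest).to_csv(directory / "pool_manifest.csv", index=False)


def load_pool(directory) -> PredictionPool:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "pool_manifest.csv")
    records: dict[str, list[PredictionRecord]] = {}
    labels: dict[str, ScoreLabel] = {}
    pool_size = None
    for _, row in manifest.iterrows():
        df = pd.read_csv(directory / row["path"])
        recs = [
            make_record(r.pss_seed, [r.p0, r.p1, r.p2, r.p3])
            for r in df.itertuples()
        ]
        records[row["core_id"]] = recs
        labels[row["core_id"]] = parse_score(row["label"])
        pool_size = len(recs) if pool_size is None else pool_size
    return PredictionPool(records=records, labels=labels, pool_size=pool_size)
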