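"""Replicate PSS inference protocol.

A trained classifier is stochastic at test time only through the patch
sampler: each replicate PSS of the same core may see different tissue
regions. The protocol embraces this — for one core it generates ``N``
independent PSSs, keeps the ``k`` predictions with the highest confidence
(the k-Confident Selection set, KCS), and reports the **maximum** HER2
score among them:

    final score = max over the KCS of the predicted class,

under the ordinal order 0 < 1+ < 2+ < 3+. Taking the maximum of the most
confident replicates makes the call sensitive to small strongly-expressing
regions that many replicates miss — the characteristic failure mode of
heterogeneous HER2 expression. Defaults are N = 20, k = 5.

Confidence is the top-two softmax margin p(1) - p(2) (a direct measure of
"clear preference for one category"); the maximum probability is available
as an alternative via ``confidence_method="max_prob"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import TrainedModel, forward
from .labels import ScoreLabel
from .pyramid import PyramidConfig, sample_pss
from .types import CoreImage

__all__ = [
    "PredictionRecord",
    "PredictionResult",
    "confidence",
    "make_record",
    "kcs_select",
    "aggregate_max",
    "derive_pss_seeds",
    "predict_core",
    "records_to_frame",
]

DEFAULT_N = 20
DEFAULT_K = 5


@dataclass(frozen=True)
class PredictionRecord:
    """One replicate PSS prediction for a core."""

    pss_seed: int
    probs: tuple[float, float, float, float]
    predicted_class: ScoreLabel
    confidence: float


@dataclass
class PredictionResult:
    """Outcome of the full protocol on one core."""

    core_id: str
    final_score: ScoreLabel
    kcs: list[PredictionRecord]
    records: list[PredictionRecord]
    n: int
    k: int


def _validate_probs(probs) -> np.ndarray:
    p = np.asarray(probs, dtype=np.float64)
    if p.shape != (4,):
        raise ValueError(f"expected a probability 4-vector, got shape {p.shape}")
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"not a probability distribution: {p}")
    return p


def confidence(probs, method: str = "margin") -> float:
    """Prediction confidence of one softmax output.

    ``margin`` (default): largest minus second-largest probability — 0 for
    a uniform output, approaching 1 for a one-hot output. ``max_prob``: the
    largest probability alone.
    """
    p = _validate_probs(probs)
    top2 = np.sort(p)[-2:]
    if method == "margin":
        return float(top2[1] - top2[0])
    if method == "max_prob":
        return float(top2[1])
    raise ValueError(f"unknown confidence method {method!r}")


def make_record(
    pss_seed: int, probs, confidence_method: str = "margin"
) -> PredictionRecord:
    p = _validate_probs(probs)
    return PredictionRecord(
        pss_seed=int(pss_seed),
        probs=tuple(float(v) for v in p),
        predicted_class=ScoreLabel(int(np.argmax(p))),
        confidence=confidence(p, confidence_method),
    )


def kcs_select(records: list[PredictionRecord], k: int) -> list[PredictionRecord]:
    """The k most confident records, ties broken by lower ``pss_seed``.

    Asking for more records than exist returns them all with a warning
    (|KCS| = min(k, N)). The result is sorted by non-increasing confidence.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not records:
        raise ValueError("cannot select from an empty record list")
    if k > len(records):
        warnings.warn(
            f"k={k} exceeds the {len(records)} available records; using all",
            RuntimeWarning,
        )
    ordered = sorted(records, key=lambda r: (-r.confidence, r.pss_seed))
    return ordered[:k]


def aggregate_max(kcs: list[PredictionRecord]) -> ScoreLabel:
    """Final score: the maximum predicted class in the KCS (ordinal order)."""
    if not kcs:
        raise ValueError("KCS is empty")
    return ScoreLabel(max(int(r.predicted_class) for r in kcs))


def derive_pss_seeds(master_seed: int, n: int) -> list[int]:
    """``n`` distinct replicate seeds derived deterministically from one seed."""
    rng = np.random.default_rng(master_seed)
    seeds: list[int] = []
    seen: set[int] = set()
    while len(seeds) < n:
        s = int(rng.integers(0, 2**31))
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    return seeds


def predict_core(
    model: TrainedModel,
    core: CoreImage,
    pyramid_config: PyramidConfig | None = None,
    n: int = DEFAULT_N,
    k: int = DEFAULT_K,
    seed: int = 0,
    confidence_method: str = "margin",
) -> PredictionResult:
    """Run the full replicate protocol on one core.

    Samples ``n`` PSSs with seeds derived from ``seed``, scores each with
    the model, selects the ``k`` most confident predictions and returns
    their maximum class. Deterministic in all arguments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = pyramid_config or model.pyramid_config
    records = []
    for pss_seed in derive_pss_seeds(seed, n):
        pss = sample_pss(core, config, seed=pss_seed)
        records.append(make_record(pss_seed, forward(model, pss), confidence_method))
    kcs = kcs_select(records, k)
    return PredictionResult(
        core_id=core.core_id,
        final_score=aggregate_max(kcs),
        kcs=kcs,
        records=records,
        n=n,
        k=k,
    )


def records_to_frame(core_id: str, records: list[PredictionRecord]) -> pd.DataFrame:
    """Tabular form of prediction records (one row per replicate)."""
    return pd.DataFrame(
        {
            "core_id": core_id,
            "pss_seed": [r.pss_seed for r in records],
            "p0": [r.probs[0] for r in records],
            "p1": [r.probs[1] for r in records],
            "p2": [r.probs[2] for r in records],
            "p3": [r.probs[3] for r in records],
            "pred": [str(r.predicted_class) for r in records],
            "confidence": [r.confidence for r in records],
        }
    )
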