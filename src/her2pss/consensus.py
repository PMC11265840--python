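"""Consensus labeling of cores from multiple pathologists' scores.

Each core is scored independently by several raters (typically 5); a
core's label requires agreement between at least two of them. The rules,
in order:

1. if a majority of raters flag the core nondiagnostic, it is excluded;
2. if a unique score is shared by >= 2 raters (and no other score ties
   that count), it becomes the consensus;
3. otherwise — two or more scores tied at the maximal count >= 2, or no
   score reaching 2 votes — an adjudicating rater's score decides,
   provided it matches one of the candidate scores; failing that the core
   is excluded as discordant.

A lone nondiagnostic flag does not veto a core that the remaining raters
agree on: nondiagnostic quality is treated as a property of the core that
a majority must assert. An adjudicator introducing a brand-new score
cannot manufacture two-rater agreement, hence the matching requirement.

Labeled cores are split train/validation/test by *patient*, never by
core, so no patient's tissue appears in two splits.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import NONDIAGNOSTIC, ScoreLabel, parse_score

__all__ = [
    "RaterScores",
    "ConsensusResult",
    "consensus_score",
    "apply_labels",
    "consensus_from_table",
]

logger = logging.getLogger(__name__)

EXCLUDED_NONDIAGNOSTIC = "nondiagnostic"
EXCLUDED_DISCORDANT = "discordant"


@dataclass(frozen=True)
class RaterScores:
    """All ratings for one core: (rater_id, score-or-'ND') pairs."""

    core_id: str
    scores: tuple[tuple[str, ScoreLabel | str], ...]
    adjudicator_score: ScoreLabel | None = None

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError(f"core {self.core_id!r} has no ratings")
        raters = [r for r, _ in self.scores]
        if len(set(raters)) != len(raters):
            raise ValueError(f"duplicate rater ids for core {self.core_id!r}")


@dataclass(frozen=True)
class ConsensusResult:
    """Either a consensus label or an exclusion with its reason."""

    core_id: str
    label: ScoreLabel | None
    excluded: bool
    reason: str | None = None


def _parse_entry(value) -> ScoreLabel | str:
    if isinstance(value, str) and value.strip().upper() == NONDIAGNOSTIC:
        return NONDIAGNOSTIC
    return parse_score(value)


def consensus_score(rs: RaterScores) -> ConsensusResult:
    """Resolve one core's ratings into a label or an exclusion."""
    entries = [_parse_entry(v) for _, v in rs.scores]
    nd_count = sum(1 for e in entries if e == NONDIAGNOSTIC)
    if nd_count * 2 > len(entries):
        return ConsensusResult(rs.core_id, None, True, EXCLUDED_NONDIAGNOSTIC)

    votes = Counter(e for e in entries if e != NONDIAGNOSTIC)
    if not votes:
        return ConsensusResult(rs.core_id, None, True, EXCLUDED_NONDIAGNOSTIC)

    top = max(votes.values())
    modal = sorted(s for s, c in votes.items() if c == top)
    if top >= 2 and len(modal) == 1:
        return ConsensusResult(rs.core_id, modal[0], False)

    # Discordant: tie among >= 2-vote scores, or nobody reaches 2 votes.
    candidates = modal if top >= 2 else sorted(votes)
    adj = rs.adjudicator_score
    if adj is not None:
        adj = parse_score(adj)
        if adj in candidates:
            return ConsensusResult(rs.core_id, adj, False)
    return ConsensusResult(rs.core_id, None, True, EXCLUDED_DISCORDANT)


def consensus_from_table(
    ratings: pd.DataFrame, adjudications: pd.DataFrame | None = None
) -> list[ConsensusResult]:
    """Apply :func:`consensus_score` to a long-format ratings table.

    ``ratings`` columns: core_id, rater_id, score (score in
    {0, 1, 2, 3, ND}); optional ``adjudications`` columns: core_id, score.
    """
    adj_map: dict[str, ScoreLabel] = {}
    if adjudications is not None:
        adj_map = {
            str(r["core_id"]): parse_score(r["score"])
            for _, r in adjudications.iterrows()
        }
    results = []
    for core_id, group in ratings.groupby("core_id", sort=True):
        rs = RaterScores(
            core_id=str(core_id),
            scores=tuple(
                (str(r["rater_id"]), _parse_entry(r["score"]))
                for _, r in group.iterrows()
            ),
            adjudicator_score=adj_map.get(str(core_id)),
        )
        results.append(consensus_score(rs))
    return results


def apply_labels(
    manifest: pd.DataFrame,
    consensus: list[ConsensusResult],
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> pd.DataFrame:
    """Attach consensus labels and patient-disjoint split assignments.

    ``manifest`` needs columns ``core_id`` and ``patient_id``; every core
    must have a consensus result. Excluded cores are dropped. Patients are
    shuffled deterministically and assigned to train/val/test so the core
    counts approximate ``split_fractions``; a patient's cores always land
    in a single split.
    """
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {split_fractions}")
    by_core = {r.core_id: r for r in consensus}
    missing = [c for c in manifest["core_id"] if str(c) not in by_core]
    if missing:
        raise ValueError(f"cores without a consensus result: {missing[:5]}")

    kept = manifest[
        [not by_core[str(c)].excluded for c in manifest["core_id"]]
    ].copy()
    if kept.empty:
        logger.warning("all cores excluded by consensus; returning empty manifest")
        warnings.warn("all cores excluded by consensus", RuntimeWarning)
        kept["consensus"] = pd.Series(dtype=str)
        kept["split"] = pd.Series(dtype=str)
        return kept
    kept["consensus"] = [str(by_core[str(c)].label) for c in kept["core_id"]]

    rng = np.random.default_rng(seed)
    patients = sorted(set(str(p) for p in kept["patient_id"]))
    order = [patients[i] for i in rng.permutation(len(patients))]
    cores_per_patient = kept.groupby("patient_id")["core_id"].count()
    total = len(kept)
    bounds = np.cumsum(split_fractions) * total
    names = ("train", "val", "test")
    assignment: dict[str, str] = {}
    running = 0.0
    for patient in order:
        n = int(cores_per_patient[patient])
        centre = running + n / 2.0
        idx = int(np.searchsorted(bounds, centre, side="right"))
        assignment[patient] = names[min(idx, 2)]
        running += n
    kept["split"] = [assignment[str(p)] for p in kept["patient_id"]]
    return kept.reset_index(drop=True)
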