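"""Per-sample rank-sum signature scoring and median dichotomization.

The score is the pipeline's central statistic.  Within each sample, all G
matrix features are converted to ranks (rank 1 = lowest expression, midranks
for ties).  The sample's score is

    S_j = mean(rank of up-members) / G  -  mean(rank of down-members) / G,

so a sample expressing the up-members high and the down-members low scores
near +1, the mirror profile near -1.  Because the statistic sees only
within-sample ranks, it is invariant under any strictly increasing transform
of a sample's expression column — normalization differences between cohorts
cannot move a sample's score.  Dividing by G and averaging per direction (in
place of a raw rank sum) makes scores comparable across matrices of different
size and across signatures with unequal up/down counts; the rescaling is
affine per cohort, so median splits and rank correlations are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import DirectionalSignature, ExpressionMatrix

__all__ = ["ScoreVector", "GroupLabels", "rank_transform", "signature_score",
           "dichotomize_by_median"]


@dataclass(frozen=True)
class ScoreVector:
    """One signature score per sample, in normalized rank units within [-1, 1]."""

    sample_ids: tuple[str, ...]
    score: np.ndarray
    n_up_used: int
    n_down_used: int
    signature_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "score", np.asarray(self.score, dtype=float))
        if len(self.sample_ids) != len(self.score):
            raise ValueError("sample_ids and score lengths differ")

    def __len__(self) -> int:
        return len(self.score)


@dataclass(frozen=True)
class GroupLabels:
    """High/low labels from a median split, with the cutoff that produced them."""

    sample_ids: tuple[str, ...]
    label: tuple[str, ...]  # "high" or "low" per sample
    cutoff_value: float

    @property
    def high(self) -> tuple[str, ...]:
        return tuple(s for s, l in zip(self.sample_ids, self.label) if l == "high")

    @property
    def low(self) -> tuple[str, ...]:
        return tuple(s for s, l in zip(self.sample_ids, self.label) if l == "low")

    def as_bool(self) -> np.ndarray:
        """True where the label is "high"."""
        return np.array([l == "high" for l in self.label])


def rank_transform(values: np.ndarray) -> np.ndarray:
    """Rank a vector ascending: rank 1 is the lowest value; ties get midranks."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise ValueError("rank_transform expects a nonempty 1-D vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("rank_transform requires finite values")
    return rankdata(values, method="average")


def signature_score(
    mat: ExpressionMatrix,
    sig: DirectionalSignature,
    min_coverage: float = 0.5,
) -> ScoreVector:
    """Score every sample of ``mat`` against a directional signature.

    Each nonempty signature direction must have at least ``min_coverage`` of
    its members among the matrix features; below that the score is considered
    unreliable and an error naming the missing members is raised.  Members
    absent from the matrix are dropped from the mean; an empty direction
    contributes 0.
    """
    feature_index = {f: i for i, f in enumerate(mat.feature_ids)}
    g = mat.n_features

    def resolve(members: frozenset[str], direction: str) -> list[int]:
        present = [feature_index[f] for f in sorted(members) if f in feature_index]
        if members and len(present) / len(members) < min_coverage:
            missing = sorted(members - feature_index.keys())
            raise ValueError(
                f"signature {sig.name!r}: only {len(present)}/{len(members)} "
                f"{direction}-members present (min_coverage={min_coverage}); "
                f"missing: {missing}"
            )
        return present

    up_idx = resolve(sig.up, "up")
    down_idx = resolve(sig.down, "down")

    ranks = rankdata(mat.values, method="average", axis=0)  # per-sample, rank 1 lowest
    scores = np.zeros(mat.n_samples)
    if up_idx:
        scores += ranks[up_idx].mean(axis=0) / g
    if down_idx:
        scores -= ranks[down_idx].mean(axis=0) / g
    return ScoreVector(
        sample_ids=tuple(mat.sample_ids),
        score=scores,
        n_up_used=len(up_idx),
        n_down_used=len(down_idx),
        signature_name=sig.name,
    )


def dichotomize_by_median(scores: ScoreVector) -> GroupLabels:
    """Split samples into "high" (score strictly above the median) and "low".

    Samples exactly at the median go to "low"; the split is therefore exact
    halves only for even n without median ties.  A constant score vector
    carries no grouping information and is rejected.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    cutoff = float(np.median(scores.score))
    if np.all(scores.score == scores.score[0]):
        raise ValueError("all scores identical; median split is uninformative")
    labels = tuple("high" if s > cutoff else "low" for s in scores.score)
    return GroupLabels(sample_ids=scores.sample_ids, label=labels, cutoff_value=cutoff)
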