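"""Consensus signature construction from multiple published directional lists.

A feature enters the consensus in a direction when at least ``min_support``
source lists report it in that direction (each source counted once, however
often it repeats a feature).  Features reaching the support threshold in both
directions are contradictory evidence: they are excluded from the signature
and surfaced in a conflict report instead of being silently assigned a side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import DirectionalSignature, ExpressionMatrix

__all__ = ["SourceList", "ConsensusResult", "CoverageReport", "EmptyConsensusError",
           "build_consensus", "signature_coverage"]


class EmptyConsensusError(ValueError):
    """No feature survives the support threshold (conflict-excluded features attached)."""

    def __init__(self, message: str, conflicts: tuple[str, ...] = ()):
        super().__init__(message)
        self.conflicts = conflicts


@dataclass(frozen=True)
class SourceList:
    """One published differential list: up/down feature-id sets under a source name."""

    source_name: str
    up: frozenset[str] = frozenset()
    down: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        both = self.up & self.down
        if both:
            raise ValueError(
                f"source {self.source_name!r} lists features in both directions: "
                f"{sorted(both)}"
            )


@dataclass(frozen=True)
class ConsensusResult:
    signature: DirectionalSignature
    conflicts: tuple[str, ...]  # features supported in both directions, excluded
    support_up: dict[str, int] = field(default_factory=dict)
    support_down: dict[str, int] = field(default_factory=dict)


def build_consensus(sources: list[SourceList], min_support: int) -> ConsensusResult:
    """Vote features into a directional consensus signature.

    Parameters
    ----------
    sources
        Nonempty list of published directional lists.
    min_support
        Minimum number of sources that must report a feature in a direction,
        ``1 <= min_support <= len(sources)``.
    """
    if not sources:
        raise ValueError("need at least one source list")
    if not (1 <= min_support <= len(sources)):
        raise ValueError(
            f"min_support must be in [1, {len(sources)}], got {min_support}"
        )
    support_up: dict[str, int] = {}
    support_down: dict[str, int] = {}
    for src in sources:
        for f in src.up:
            support_up[f] = support_up.get(f, 0) + 1
        for f in src.down:
            support_down[f] = support_down.get(f, 0) + 1

    up = {f for f, n in support_up.items() if n >= min_support}
    down = {f for f, n in support_down.items() if n >= min_support}
    conflicts = tuple(sorted(up & down))
    up -= set(conflicts)
    down -= set(conflicts)
    name = "consensus(min_support={};{})".format(
        min_support, "+".join(sorted(s.source_name for s in sources))
    )
    if not up and not down:
        raise EmptyConsensusError(
            f"no feature reaches support {min_support} in a single direction "
            f"across {len(sources)} sources",
            conflicts=conflicts,
        )
    sig = DirectionalSignature(name=name, up=frozenset(up), down=frozenset(down))
    return ConsensusResult(
        signature=sig,
        conflicts=conflicts,
        support_up=support_up,
        support_down=support_down,
    )


@dataclass(frozen=True)
class CoverageReport:
    """Fractions of signature members present in a matrix, with missing members."""

    up_fraction: float
    down_fraction: float
    missing_up: tuple[str, ...]
    missing_down: tuple[str, ...]


def signature_coverage(sig: DirectionalSignature, mat: ExpressionMatrix) -> CoverageReport:
    """Fraction of each direction's members found among the matrix features.

    An empty direction is reported as fully covered (fraction 1.0, nothing
    missing) — there is nothing to look for.
    """
    features = set(mat.feature_ids)

    def frac(members: frozenset[str]) -> tuple[float, tuple[str, ...]]:
        if not members:
            return 1.0, ()
        missing = tuple(sorted(members - features))
        return 1.0 - len(missing) / len(members), missing

    up_frac, missing_up = frac(sig.up)
    down_frac, missing_down = frac(sig.down)
    return CoverageReport(up_frac, down_frac, missing_up, missing_down)
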