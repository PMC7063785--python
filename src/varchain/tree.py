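"""Linear filter-chain decision trees.

The classifier is a degenerate decision tree: an ordered chain of binary
features in which every neutral branch is terminal.  A variant walks the
chain level by level; the first level whose feature reads 0 exits it as
neutral, and only a variant whose features are 1 at *every* level is called
pathogenic.  The final label is therefore the conjunction of the level
features — orderings differ only in *where* neutrals exit, which is what the
per-level evaluation reports measure.
"""

from __future__ import annotations

import itertools
import json
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import FeatureVector, feature_matrix
from .variants import ConfigurationError, Label

#: The reference four-level chain.
PROPOSED_TOPOLOGY_LEVELS = ("SPP", "ExAC", "NDamage", "COMMON")


@dataclass(frozen=True)
class ChainTopology:
    """An ordered list of feature names defining a filter chain."""

    levels: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ValueError("a chain needs at least one level")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"duplicate features in chain: {self.levels}")
        if not self.name:
            object.__setattr__(self, "name", "-".join(self.levels))

    def __len__(self) -> int:
        return len(self.levels)

    def prefix(self, depth: int) -> "ChainTopology":
        return ChainTopology(self.levels[:depth])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"name": self.name, "levels": list(self.levels)}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ChainTopology":
        raw = json.loads(Path(path).read_text())
        return cls(tuple(raw["levels"]), raw.get("name", ""))


def proposed_topology() -> ChainTopology:
    return ChainTopology(PROPOSED_TOPOLOGY_LEVELS)


@dataclass(frozen=True)
class Classification:
    """Outcome for one variant: the label and the level at which it was fixed.

    ``exit_level`` is 1-based; a pathogenic call carries ``len(levels) + 1``
    (it survived every level).
    """

    label: Label
    exit_level: int


def classify(fv: FeatureVector, topology: ChainTopology) -> Classification:
    """Walk the chain; first 0 exits neutral, surviving all levels is pathogenic.

    A variant assigned neutral at level k is final — later levels never
    revisit it.
    """
    for level, feat in enumerate(topology.levels, start=1):
        try:
            value = fv.values[feat]
        except KeyError:
            raise ConfigurationError(
                f"FeatureVector lacks feature {feat!r} required by "
                f"topology {topology.name}"
            ) from None
        if value == 0:
            return Classification(Label.NEUTRAL, level)
    return Classification(Label.PATHOGENIC, len(topology) + 1)


def classify_batch(
    fvs: Sequence[FeatureVector], topology: ChainTopology
) -> tuple[list[Classification], list[int]]:
    """Element-wise classification plus per-level survivor counts.

    ``survivors[k]`` is the number of variants still held pathogenic after
    level k+1; order of results matches the input.
    """
    if not fvs:
        return [], [0] * len(topology)
    exit_levels = exit_levels_batch(fvs, topology)
    depth = len(topology)
    results = [
        Classification(
            Label.PATHOGENIC if e == depth + 1 else Label.NEUTRAL, int(e)
        )
        for e in exit_levels
    ]
    survivors = [int((exit_levels > k + 1).sum()) for k in range(depth)]
    return results, survivors


def exit_levels_batch(
    fvs: Sequence[FeatureVector], topology: ChainTopology
) -> np.ndarray:
    """Vectorized exit levels: argmin over levels of the first 0, else depth+1."""
    m = feature_matrix(fvs, topology.levels)  # (n, depth)
    zero = m == 0
    any_zero = zero.any(axis=1)
    first_zero = zero.argmax(axis=1) + 1
    return np.where(any_zero, first_zero, len(topology) + 1)


def predict_labels(
    fvs: Sequence[FeatureVector], topology: ChainTopology
) -> np.ndarray:
    """Boolean array: True where the chain calls the variant pathogenic."""
    if not fvs:
        return np.zeros(0, dtype=bool)
    m = feature_matrix(fvs, topology.levels)
    return m.all(axis=1)


def enumerate_topologies(
    features: Sequence[str], allowed_roots: Sequence[str]
) -> list[ChainTopology]:
    """All permutations of ``features`` whose root is in ``allowed_roots``.

    Deterministic lexicographic order (by the feature-name tuple).  With four
    features and the root restricted to the two consensus ensembles the list
    has exactly twelve entries — the topology family the per-level reports
    enumerate.
    """
    features = list(features)
    roots = set(allowed_roots)
    if not roots:
        raise ConfigurationError("allowed_roots must be non-empty")
    if not roots <= set(features):
        raise ConfigurationError(
            f"allowed_roots {sorted(roots - set(features))} not among features"
        )
    perms = sorted(
        p for p in itertools.permutations(features) if p[0] in roots
    )
    return [ChainTopology(p) for p in perms]
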