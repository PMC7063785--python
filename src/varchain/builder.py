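"""Greedy level-wise induction of a filter chain from labeled binary features.

At each level every remaining candidate feature is appended provisionally,
the whole-dataset accuracy of the resulting chain is computed, and the
maximizer is kept.  The root is restricted to a caller-supplied set (in the
reference construction: the two consensus ensembles, because allele-frequency
features misclassify variants from under-sequenced populations when placed at
the root).  Construction stops when no candidate strictly improves accuracy,
when ``max_depth`` is reached, or when candidates run out.  Ties break on the
lexicographically smallest feature name; the procedure contains no
randomness.
"""

from __future__ import annotations

import itertools
from collections.abc import Sequence
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .features import FeatureVector, feature_matrix
from .tree import ChainTopology
from .variants import ConfigurationError, Label


class StoppingReason(str, Enum):
    NO_IMPROVEMENT = "no_improvement"
    MAX_DEPTH = "max_depth"
    FEATURES_EXHAUSTED = "features_exhausted"


@dataclass(frozen=True)
class LevelTrace:
    """One induction step: accuracy of every candidate and the winner."""

    chosen: str
    candidate_accuracy: dict[str, float]
    survivor_accuracy: dict[str, float]


@dataclass(frozen=True)
class BuildTrace:
    levels: tuple[LevelTrace, ...]
    stopping_reason: StoppingReason


class SizeError(ValueError):
    """Exhaustive search refused: combinatorial limit exceeded."""


def _as_arrays(
    fvs: Sequence[FeatureVector],
    labels: Sequence[Label | str],
    candidates: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    y = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        val = lab.value if isinstance(lab, Label) else str(lab)
        if val == Label.PATHOGENIC.value:
            y[i] = True
        elif val == Label.NEUTRAL.value:
            y[i] = False
        else:
            raise ValueError(
                f"labels must be neutral/pathogenic, got {val!r} at index {i}"
            )
    m = feature_matrix(fvs, list(candidates)).astype(bool)
    return m, y


def _chain_accuracy(m: np.ndarray, y: np.ndarray, cols: Sequence[int]) -> float:
    """Accuracy of the chain over the given feature columns (conjunction)."""
    pred = m[:, list(cols)].all(axis=1) if cols else np.ones(len(y), dtype=bool)
    return float((pred == y).mean())


def build_greedy(
    fvs: Sequence[FeatureVector],
    labels: Sequence[Label | str],
    candidates: Sequence[str],
    allowed_roots: Sequence[str] | None = None,
    max_depth: int = 4,
    validation: tuple[Sequence[FeatureVector], Sequence[Label | str]] | None = None,
) -> tuple[ChainTopology, BuildTrace]:
    """Induce a chain greedily, one level at a time.

    Parameters
    ----------
    fvs, labels
        Discretized training variants and their neutral/pathogenic labels.
    candidates
        Feature names available to the builder.
    allowed_roots
        Features permitted at level 1 (default: all candidates).  Later
        levels consider every remaining candidate.
    max_depth
        Maximum chain length; the reference tree fixes four levels.
    validation
        Optional held-out ``(fvs, labels)`` used for candidate scoring
        instead of the training set.

    Returns the induced topology plus a :class:`BuildTrace` holding, per
    level, every candidate's whole-dataset accuracy and the accuracy
    restricted to variants still unclassified at that level (diagnostic
    only).  The root is always placed (a chain has length >= 1); the
    strict-improvement stopping rule applies from level 2 on.
    """
    if len(fvs) != len(labels) or not fvs:
        raise ValueError("need equally many (and at least one) fvs and labels")
    candidates = sorted(set(candidates))
    if not candidates:
        raise ConfigurationError("no candidate features")
    roots = sorted(set(allowed_roots)) if allowed_roots else candidates
    if not set(roots) <= set(candidates):
        raise ConfigurationError("allowed_roots must be a subset of candidates")

    m, y = _as_arrays(fvs, labels, candidates)
    if validation is not None:
        ms, ys = _as_arrays(*validation, candidates)
    else:
        ms, ys = m, y
    col = {f: i for i, f in enumerate(candidates)}

    chain: list[str] = []
    traces: list[LevelTrace] = []
    current_acc = -np.inf  # root always placed
    while len(chain) < max_depth:
        pool = roots if not chain else [f for f in candidates if f not in chain]
        if not pool:
            reason = StoppingReason.FEATURES_EXHAUSTED
            break
        cand_acc: dict[str, float] = {}
        surv_acc: dict[str, float] = {}
        cols = [col[f] for f in chain]
        surviving = ms[:, cols].all(axis=1) if cols else np.ones(len(ys), bool)
        for f in pool:
            cand_acc[f] = _chain_accuracy(ms, ys, cols + [col[f]])
            if surviving.any():
                pred_f = ms[surviving, col[f]]
                surv_acc[f] = float((pred_f == ys[surviving]).mean())
            else:
                surv_acc[f] = float("nan")
        best = min(cand_acc, key=lambda f: (-cand_acc[f], f))
        if chain and cand_acc[best] <= current_acc:
            reason = StoppingReason.NO_IMPROVEMENT
            break
        chain.append(best)
        current_acc = cand_acc[best]
        traces.append(LevelTrace(best, cand_acc, surv_acc))
    else:
        reason = StoppingReason.MAX_DEPTH
    if not chain:
        raise ConfigurationError("no admissible root feature")
    return ChainTopology(tuple(chain)), BuildTrace(tuple(traces), reason)


def exhaustive_best(
    fvs: Sequence[FeatureVector],
    labels: Sequence[Label | str],
    candidates: Sequence[str],
    allowed_roots: Sequence[str] | None = None,
    depth: int = 4,
) -> ChainTopology:
    """Accuracy-maximizing chain over all root-restricted orderings.

    Enumerates every ordered selection of 1..depth distinct candidates whose
    first element is an allowed root and returns the chain with the highest
    whole-dataset accuracy.  Tie-break mirrors the greedy builder: higher
    accuracy, then shorter chain, then lexicographically smallest feature
    tuple.  Refuses candidate sets too large to enumerate.
    """
    candidates = sorted(set(candidates))
    if len(candidates) > 6:
        raise SizeError(
            f"{len(candidates)} candidate features exceed the exhaustive limit (6)"
        )
    roots = sorted(set(allowed_roots)) if allowed_roots else candidates
    if not set(roots) <= set(candidates):
        raise ConfigurationError("allowed_roots must be a subset of candidates")
    m, y = _as_arrays(fvs, labels, candidates)
    col = {f: i for i, f in enumerate(candidates)}

    best_key: tuple | None = None
    best_chain: tuple[str, ...] | None = None
    for length in range(1, min(depth, len(candidates)) + 1):
        for perm in itertools.permutations(candidates, length):
            if perm[0] not in roots:
                continue
            acc = _chain_accuracy(m, y, [col[f] for f in perm])
            key = (-acc, length, perm)
            if best_key is None or key < best_key:
                best_key, best_chain = key, perm
    assert best_chain is not None
    return ChainTopology(best_chain)
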