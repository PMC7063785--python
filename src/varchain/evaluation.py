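"""Evaluation protocol for binary variant classifiers.

The confusion cells follow the clinical naming: with the curated class coded
0 = neutral, 1 = pathogenic and predictions N/P,

* (N, 0) True Neutral, (N, 1) False Neutral,
* (P, 0) False Pathogenic, (P, 1) True Pathogenic.

The primary per-class rates are conditional on the *true* class, so the
neutral pair ``rate_N_given_0 + rate_P_given_0`` and the pathogenic pair
``rate_N_given_1 + rate_P_given_1`` each sum to 1.  A second set of fields
(`paper_formula_*`) reports the literal sensitivity / Type I / specificity /
Type II ratios sometimes quoted for this protocol — sensitivity =
TN/(TN+FN), Type I = FN/(TN+FN), specificity = TP/(TP+FP), Type II =
FP/(TP+FP) — which normalize within *predicted* rows instead; both views are
kept because they disagree whenever the classes are unbalanced.

Resampling: stratified 10-fold cross-validation (each class split into k
folds separately) and Monte Carlo subsampling (1000 draws of 30% of the
data, without replacement within each draw) with per-metric mean and
population standard deviation.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureVector
from .tree import ChainTopology, predict_labels
from .variants import Label

METRIC_NAMES = (
    "accuracy",
    "rate_N_given_0",
    "rate_P_given_0",
    "rate_N_given_1",
    "rate_P_given_1",
)


@dataclass(frozen=True)
class ConfusionCounts:
    true_neutral: int
    false_neutral: int
    false_pathogenic: int
    true_pathogenic: int

    def __post_init__(self) -> None:
        if min(self.true_neutral, self.false_neutral,
               self.false_pathogenic, self.true_pathogenic) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return (self.true_neutral + self.false_neutral
                + self.false_pathogenic + self.true_pathogenic)


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy plus the four true-class-conditional rates (fractions).

    Undefined ratios (empty true class / empty predicted row) are NaN,
    never silently zero.
    """

    accuracy: float
    rate_N_given_0: float
    rate_P_given_0: float
    rate_N_given_1: float
    rate_P_given_1: float
    paper_formula_sensitivity: float
    paper_formula_type1: float
    paper_formula_specificity: float
    paper_formula_type2: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _labels_to_bool(labels: Sequence[Label | str]) -> np.ndarray:
    out = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        val = lab.value if isinstance(lab, Label) else str(lab)
        if val == "pathogenic":
            out[i] = True
        elif val == "neutral":
            out[i] = False
        else:
            raise ValueError(f"unexpected label {val!r} at index {i}")
    return out


def confusion(
    predictions: Sequence[Label | str], labels: Sequence[Label | str]
) -> ConfusionCounts:
    """Tally the four cells from parallel prediction/label sequences."""
    if len(predictions) != len(labels) or not labels:
        raise ValueError("predictions and labels must have equal, non-zero length")
    pred = _labels_to_bool(predictions)
    truth = _labels_to_bool(labels)
    return confusion_from_bool(pred, truth)


def confusion_from_bool(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """As :func:`confusion` but on boolean arrays (True = pathogenic)."""
    return ConfusionCounts(
        true_neutral=int((~pred & ~truth).sum()),
        false_neutral=int((~pred & truth).sum()),
        false_pathogenic=int((pred & ~truth).sum()),
        true_pathogenic=int((pred & truth).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def metrics(cc: ConfusionCounts) -> MetricsReport:
    """Derive the five primary metrics and the literal-formula quartet."""
    if cc.total == 0:
        raise ValueError("empty confusion table")
    tn, fn = cc.true_neutral, cc.false_neutral
    fp, tp = cc.false_pathogenic, cc.true_pathogenic
    n0, n1 = tn + fp, fn + tp  # true-class margins
    return MetricsReport(
        accuracy=(tn + tp) / cc.total,
        rate_N_given_0=_ratio(tn, n0),
        rate_P_given_0=_ratio(fp, n0),
        rate_N_given_1=_ratio(fn, n1),
        rate_P_given_1=_ratio(tp, n1),
        paper_formula_sensitivity=_ratio(tn, tn + fn),
        paper_formula_type1=_ratio(fn, tn + fn),
        paper_formula_specificity=_ratio(tp, tp + fp),
        paper_formula_type2=_ratio(fp, tp + fp),
    )


def evaluate_topology(
    fvs: Sequence[FeatureVector],
    labels: Sequence[Label | str],
    topology: ChainTopology,
) -> MetricsReport:
    """Classify the whole set with a fixed chain and report its metrics."""
    pred = predict_labels(fvs, topology)
    return metrics(confusion_from_bool(pred, _labels_to_bool(labels)))


@dataclass(frozen=True)
class ResamplingSummary:
    """Per-metric mean and standard deviation over replicates or folds.

    ``std`` uses the population formula (denominator = replicate count),
    matching how spread is usually quoted for such resampling summaries.
    """

    mean: dict[str, float]
    std: dict[str, float]
    replicates: int
    sample_fraction: float
    seed: int | None = None
    per_replicate: tuple[dict[str, float], ...] = field(default=(), repr=False)


def _summarize(
    rows: list[dict[str, float]], fraction: float, seed: int | None
) -> ResamplingSummary:
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = np.array([r[name] for r in rows], dtype=float)
        ok = ~np.isnan(vals)
        if not ok.any():
            mean[name] = std[name] = math.nan
            continue
        v = vals[ok]
        mean[name] = float(v.mean())
        # exact zero when replicates are identical (e.g. fraction = 1.0)
        std[name] = 0.0 if v.min() == v.max() else float(v.std())
    return ResamplingSummary(mean, std, len(rows), fraction, seed, tuple(rows))


Classifier = ChainTopology | Callable[
    [Sequence[FeatureVector], Sequence[Label]], ChainTopology
]


def _fit_or_fixed(
    classifier: Classifier,
    train_fvs: Sequence[FeatureVector],
    train_labels: Sequence[Label | str],
) -> ChainTopology:
    if isinstance(classifier, ChainTopology):
        return classifier
    return classifier(train_fvs, train_labels)


def kfold_cv(
    fvs: Sequence[FeatureVector],
    labels: Sequence[Label | str],
    k: int = 10,
    classifier: Classifier | None = None,
    seed: int = 0,
) -> ResamplingSummary:
    """Stratified k-fold cross-validation.

    Neutral and pathogenic variants are each split into k folds by a seeded
    permutation; iteration i tests on the union of the i-th neutral and i-th
    pathogenic fold.  When ``classifier`` is a builder callable it is
    re-fitted on the remaining folds each iteration; a fixed
    :class:`ChainTopology` is evaluated as-is.  Per-class fold sizes differ
    by at most one and the folds partition each class exactly.
    """
    from .tree import proposed_topology

    classifier = classifier if classifier is not None else proposed_topology()
    truth = _labels_to_bool(labels)
    idx_n = np.flatnonzero(~truth)
    idx_p = np.flatnonzero(truth)
    if min(len(idx_n), len(idx_p)) < k:
        raise ValueError(
            f"each class needs >= k={k} members "
            f"(have {len(idx_n)} neutral, {len(idx_p)} pathogenic)"
        )
    rng = np.random.default_rng(seed)
    folds_n = np.array_split(rng.permutation(idx_n), k)
    folds_p = np.array_split(rng.permutation(idx_p), k)

    rows = []
    all_idx = np.arange(len(labels))
    fvs = list(fvs)
    for i in range(k):
        test_idx = np.concatenate([folds_n[i], folds_p[i]])
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        topo = _fit_or_fixed(
            classifier,
            [fvs[j] for j in train_idx],
            [labels[j] for j in train_idx],
        )
        test_fvs = [fvs[j] for j in test_idx]
        pred = predict_labels(test_fvs, topo)
        rows.append(
            metrics(confusion_from_bool(pred, truth[test_idx])).as_dict()
        )
    return _summarize(rows, 1.0 / k, seed)


def monte_carlo(
    fvs: Sequence[FeatureVector],
    labels: Sequence[Label | str],
    classifier: Classifier | None = None,
    fraction: float = 0.3,
    replicates: int = 1000,
    seed: int = 0,
    bootstrap: bool = False,
) -> ResamplingSummary:
    """Monte Carlo subsampling evaluation of a (fixed or pre-fitted) chain.

    Each replicate draws ``round(fraction * n)`` variants uniformly without
    replacement (``bootstrap=True`` switches to with-replacement draws of
    the same size), classifies them and computes the metric set; the summary
    is the per-metric mean and population standard deviation.  With
    ``fraction=1.0`` and no bootstrap every replicate is the full dataset,
    so the std is exactly zero.
    """
    from .tree import proposed_topology

    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    classifier = classifier if classifier is not None else proposed_topology()
    topo = _fit_or_fixed(classifier, fvs, labels)
    truth = _labels_to_bool(labels)
    pred = predict_labels(fvs, topo)  # predictions are sample-independent
    n = len(labels)
    size = int(round(fraction * n))
    if size == 0:
        raise ValueError(f"sample size round({fraction} * {n}) is zero")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(replicates):
        idx = (rng.integers(0, n, size=size) if bootstrap
               else rng.permutation(n)[:size])
        rows.append(
            metrics(confusion_from_bool(pred[idx], truth[idx])).as_dict()
        )
    return _summarize(rows, fraction, seed)


def phi_coefficient(x: Sequence[int], y: Sequence[int]) -> float:
    """φ association of two binary sequences from their 2×2 table.

    φ = (n11·n00 − n10·n01) / sqrt(n1•·n0•·n•1·n•0); identical to the
    Pearson correlation of the 0/1 indicators.  Any degenerate margin (a
    sequence taking a single value) makes φ undefined → NaN.
    """
    xv = np.asarray(x, dtype=int)
    yv = np.asarray(y, dtype=int)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n11 = int(((xv == 1) & (yv == 1)).sum())
    n10 = int(((xv == 1) & (yv == 0)).sum())
    n01 = int(((xv == 0) & (yv == 1)).sum())
    n00 = int(((xv == 0) & (yv == 0)).sum())
    margins = (n11 + n10, n01 + n00, n11 + n01, n10 + n00)
    if 0 in margins:
        return math.nan
    return (n11 * n00 - n10 * n01) / math.sqrt(math.prod(margins))


def pairwise_distribution(
    fvs: Sequence[FeatureVector],
    labels: Sequence[Label | str],
    pair: tuple[str, str],
) -> dict[str, dict[tuple[int, int], float]]:
    """Per-true-class percentage tables of a feature pair's four value combos.

    Returns ``{"neutral": {(a, b): pct}, "pathogenic": {...}}`` where
    ``(a, b)`` runs over the 2×2 combinations of the pair's values; each
    class's four cells sum to 100 (NaN cells when the class is empty).  The
    off-diagonal cells quantify complementarity: the share of a class that
    one feature classifies correctly and the other does not.
    """
    fa, fb = pair
    truth = _labels_to_bool(labels)
    a = np.array([fv.values[fa] for fv in fvs], dtype=int)
    b = np.array([fv.values[fb] for fv in fvs], dtype=int)
    out: dict[str, dict[tuple[int, int], float]] = {}
    for cls_name, mask in (("neutral", ~truth), ("pathogenic", truth)):
        total = int(mask.sum())
        cells = {}
        for va in (0, 1):
            for vb in (0, 1):
                cnt = int(((a == va) & (b == vb) & mask).sum())
                cells[(va, vb)] = 100.0 * cnt / total if total else math.nan
        out[cls_name] = cells
    return out


@dataclass(frozen=True)
class LevelRow:
    level: int
    feature: str
    accuracy_pct: float
    fpr_pct: float  # false-pathogenic among true neutrals
    fnr_pct: float  # false-neutral among true pathogenics


@dataclass(frozen=True)
class LevelReport:
    topology: ChainTopology
    rows: tuple[LevelRow, ...]


def level_report(
    fvs: Sequence[FeatureVector],
    labels: Sequence[Label | str],
    topology: ChainTopology,
) -> LevelReport:
    """Accuracy/FPR/FNR (percent) of every prefix of the chain.

    Row L classifies with the chain truncated after level L, i.e. it shows
    how the running classification sharpens as deeper filters reclassify
    surviving variants to neutral: the false-pathogenic rate can only fall
    with depth, the false-neutral rate only rise.
    """
    truth = _labels_to_bool(labels)
    rows = []
    for depth in range(1, len(topology) + 1):
        pred = predict_labels(fvs, topology.prefix(depth))
        rep = metrics(confusion_from_bool(pred, truth))
        rows.append(
            LevelRow(
                level=depth,
                feature=topology.levels[depth - 1],
                accuracy_pct=100.0 * rep.accuracy,
                fpr_pct=100.0 * rep.rate_P_given_0,
                fnr_pct=100.0 * rep.rate_N_given_1,
            )
        )
    return LevelReport(topology, tuple(rows))
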