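"""Synthetic labeled variant sets with the class-conditional structure the
chain classifier assumes, plus a closed-form expected-confusion oracle.

Each variant's class (neutral / pathogenic) is drawn from a prevalence, and
every annotation is then drawn independently from its class-conditional
distribution:

* the three classical predictor calls — independent Bernoulli pathogenic
  calls with per-predictor, per-class probabilities;
* the two allele frequencies — a catalogued/uncatalogued mixture; when
  catalogued the frequency is log-uniform in a class-specific range, so the
  rarity threshold induces an exactly computable binary rate;
* the nine damage-predictor calls — independent Bernoulli per predictor;
* auxiliary flags — per-class Bernoulli rates.

Because the features are class-conditionally independent, the probability
that a chain calls a variant pathogenic factorizes over its levels, which is
what :func:`expected_confusion` evaluates in closed form.  Real annotation
variables are *not* independent (the two allele-frequency features in
particular are strongly associated), so an optional coupling parameter can
tie the two catalogued statuses together for correlation-sensitivity
experiments; the closed-form oracle covers the independent case only.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .features import (
    COMMON,
    DEFAULT_AF_THRESHOLD,
    DEFAULT_NDAMAGE_CUTOFF,
    EXAC,
    NDAMAGE,
    SPP,
)
from .tree import ChainTopology
from .variants import AnnotatedVariant, Call, ConfigurationError, Consequence, Label

DAMAGE_PREDICTORS = tuple(f"damage:dmg{i}" for i in range(1, 10))
_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass(frozen=True)
class FrequencyParams:
    """Catalogued/uncatalogued mixture for one allele-frequency annotation.

    With probability ``p_catalogued`` the variant has a frequency, drawn
    log-uniformly from ``af_range``; otherwise it is absent from the
    catalogue (downstream: pathogenic-leaning).
    """

    p_catalogued: float
    af_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.af_range
        if not (0.0 <= self.p_catalogued <= 1.0):
            raise ConfigurationError(f"p_catalogued {self.p_catalogued} not in [0,1]")
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError(f"af_range {self.af_range} invalid")

    def cdf(self, t: float) -> float:
        """P(AF <= t | catalogued) under the log-uniform draw."""
        lo, hi = self.af_range
        if lo == hi:
            return 1.0 if lo <= t else 0.0
        x = (math.log(t) - math.log(lo)) / (math.log(hi) - math.log(lo))
        return min(1.0, max(0.0, x))


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional annotation distributions for one variant class."""

    spp_call_probs: tuple[float, float, float]
    exac: FrequencyParams
    common: FrequencyParams
    ndamage_probs: tuple[float, ...]
    aux_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        probs = (*self.spp_call_probs, *self.ndamage_probs,
                 *self.aux_rates.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        if not 1 <= len(self.ndamage_probs) <= 9:
            raise ConfigurationError("ndamage_probs takes 1..9 entries")


@dataclass(frozen=True)
class GeneratorConfig:
    n_variants: int
    prevalence_pathogenic: float
    neutral: ClassParams
    pathogenic: ClassParams
    missingness: Mapping[str, float] = field(default_factory=dict)
    #: probability that the COMMON catalogued status copies the ExAC one
    #: (0 = independent; the closed-form oracle requires 0)
    exac_common_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        if not (0.0 <= self.prevalence_pathogenic <= 1.0):
            raise ConfigurationError("prevalence_pathogenic not in [0, 1]")
        if not (0.0 <= self.exac_common_coupling <= 1.0):
            raise ConfigurationError("exac_common_coupling not in [0, 1]")
        if any(not (0.0 <= m <= 1.0) for m in self.missingness.values()):
            raise ConfigurationError("missingness rates must lie in [0, 1]")

    def class_params(self, label: Label) -> ClassParams:
        return self.pathogenic if label is Label.PATHOGENIC else self.neutral


def _draw_af(
    rng: np.random.Generator, fp: FrequencyParams, n: int,
    catalogued: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (af values, catalogued mask); uncatalogued slots hold NaN."""
    if catalogued is None:
        catalogued = rng.random(n) < fp.p_catalogued
    lo, hi = fp.af_range
    u = rng.random(n)
    af = np.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))
    af = np.where(catalogued, af, np.nan)
    return af, catalogued


def generate(
    config: GeneratorConfig,
) -> tuple[list[AnnotatedVariant], list[Label]]:
    """Draw a labeled synthetic variant set; byte-reproducible from the seed.

    The output feeds the ingestion/discretization pipeline without
    special-casing: every variant is non-synonymous, carries all three
    classical predictor calls, and holds a numeric clinical-significance
    code consistent with its label.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    is_path = rng.random(n) < config.prevalence_pathogenic
    miss = dict(config.missingness)

    spp_p = np.where(
        is_path[:, None],
        np.asarray(config.pathogenic.spp_call_probs),
        np.asarray(config.neutral.spp_call_probs),
    )
    spp_calls = rng.random((n, 3)) < spp_p

    nd_max = max(len(config.neutral.ndamage_probs),
                 len(config.pathogenic.ndamage_probs))
    nd_p = np.zeros((n, nd_max))
    nd_present = np.zeros((n, nd_max), dtype=bool)
    for mask, params in ((is_path, config.pathogenic), (~is_path, config.neutral)):
        k = len(params.ndamage_probs)
        nd_p[np.ix_(mask, np.arange(k))] = params.ndamage_probs
        nd_present[np.ix_(mask, np.arange(k))] = True
    nd_calls = rng.random((n, nd_max)) < nd_p
    nd_missing = rng.random((n, nd_max)) < miss.get("damage", 0.0)

    def mixture(attr, coupled_with: np.ndarray | None = None):
        af = np.empty(n)
        cat = np.empty(n, dtype=bool)
        for mask, params in ((is_path, config.pathogenic),
                             (~is_path, config.neutral)):
            fp = getattr(params, attr)
            sub_cat = None
            if coupled_with is not None:
                copy = rng.random(int(mask.sum())) < config.exac_common_coupling
                indep = rng.random(int(mask.sum())) < fp.p_catalogued
                sub_cat = np.where(copy, coupled_with[mask], indep)
            af_m, cat_m = _draw_af(rng, fp, int(mask.sum()), sub_cat)
            af[mask], cat[mask] = af_m, cat_m
        return af, cat

    exac_af, exac_cat = mixture("exac")
    common_af, _ = mixture("common",
                           coupled_with=exac_cat
                           if config.exac_common_coupling > 0 else None)
    exac_miss = rng.random(n) < miss.get("exac_af", 0.0)
    common_miss = rng.random(n) < miss.get("common_af", 0.0)

    aux_names = sorted(set(config.neutral.aux_rates)
                       | set(config.pathogenic.aux_rates))
    aux_draws = {}
    for name in aux_names:
        p = np.where(is_path,
                     config.pathogenic.aux_rates.get(name, 0.0),
                     config.neutral.aux_rates.get(name, 0.0))
        aux_draws[name] = (rng.random(n) < p).astype(int)

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    aa_ref = rng.integers(0, 20, size=n)
    aa_alt = (aa_ref + rng.integers(1, 20, size=n)) % 20

    variants: list[AnnotatedVariant] = []
    labels: list[Label] = []
    to_call = (Call.NEUTRAL, Call.PATHOGENIC)
    for i in range(n):
        label = Label.PATHOGENIC if is_path[i] else Label.NEUTRAL
        damage = {}
        for j, name in enumerate(DAMAGE_PREDICTORS[:nd_max]):
            if not nd_present[i, j]:
                continue
            damage[name] = (Call.MISSING if nd_missing[i, j]
                            else to_call[int(nd_calls[i, j])])
        variants.append(
            AnnotatedVariant(
                chrom="1",
                pos=i + 1,
                ref=_NT[ref_idx[i]],
                alt=_NT[alt_idx[i]],
                consequence=Consequence.NON_SYNONYMOUS,
                sift_call=to_call[int(spp_calls[i, 0])],
                polyphen_call=to_call[int(spp_calls[i, 1])],
                provean_call=to_call[int(spp_calls[i, 2])],
                damage_calls=damage,
                exac_af=None if (exac_miss[i] or math.isnan(exac_af[i]))
                else float(exac_af[i]),
                common_af=None if (common_miss[i] or math.isnan(common_af[i]))
                else float(common_af[i]),
                clnsig_raw="5" if is_path[i] else "2",
                label=label,
                aux_flags={name: int(aux_draws[name][i]) for name in aux_names},
                ref_aa=_AA[aa_ref[i]],
                alt_aa=_AA[aa_alt[i]],
            )
        )
        labels.append(label)
    return variants, labels


def _poisson_binomial_tail(probs: Sequence[float], k: int) -> float:
    """P(sum of independent Bernoulli(probs) >= k) by dynamic programming."""
    dist = np.zeros(len(probs) + 1)
    dist[0] = 1.0
    for p in probs:
        dist[1:] = dist[1:] * (1 - p) + dist[:-1] * p
        dist[0] *= 1 - p
    return float(dist[k:].sum())


@dataclass(frozen=True)
class ExpectedRates:
    """Closed-form chain outcome probabilities under a generator config."""

    p_pathogenic_given_neutral: float
    p_pathogenic_given_pathogenic: float
    accuracy: float
    rate_N_given_0: float
    rate_P_given_0: float
    rate_N_given_1: float
    rate_P_given_1: float
    per_feature: dict[str, dict[str, float]]


def feature_one_probability(
    config: GeneratorConfig,
    params: ClassParams,
    feature: str,
    af_threshold: float = DEFAULT_AF_THRESHOLD,
    ndamage_cutoff: int = DEFAULT_NDAMAGE_CUTOFF,
) -> float:
    """P(discretized feature = 1 | class) in closed form."""
    miss = dict(config.missingness)
    if feature == SPP:
        return 1.0 - math.prod(1.0 - p for p in params.spp_call_probs)
    if feature in (EXAC, COMMON):
        fp = params.exac if feature == EXAC else params.common
        m = miss.get("exac_af" if feature == EXAC else "common_af", 0.0)
        p_rare = (1.0 - fp.p_catalogued) + fp.p_catalogued * fp.cdf(af_threshold)
        return m + (1.0 - m) * p_rare
    if feature == NDAMAGE:
        eff = [p * (1.0 - miss.get("damage", 0.0)) for p in params.ndamage_probs]
        return _poisson_binomial_tail(eff, ndamage_cutoff)
    if feature in params.aux_rates:
        return float(params.aux_rates[feature])
    raise ConfigurationError(
        f"no generator parameters for feature {feature!r}"
    )


def expected_confusion(
    config: GeneratorConfig,
    topology: ChainTopology,
    af_threshold: float = DEFAULT_AF_THRESHOLD,
    ndamage_cutoff: int = DEFAULT_NDAMAGE_CUTOFF,
) -> ExpectedRates:
    """Exact expected conditional rates of a chain under the generator.

    Valid because features are generated class-conditionally independent:
    P(chain says pathogenic | class) is the product over levels of
    P(feature = 1 | class).  Requires ``exac_common_coupling == 0``.
    """
    if config.exac_common_coupling != 0.0:
        raise ConfigurationError(
            "closed-form rates require exac_common_coupling = 0 "
            "(features must be class-conditionally independent)"
        )
    per_feature: dict[str, dict[str, float]] = {}
    p_path = {}
    for cls_name, params in (("neutral", config.neutral),
                             ("pathogenic", config.pathogenic)):
        factors = {
            f: feature_one_probability(config, params, f,
                                       af_threshold, ndamage_cutoff)
            for f in topology.levels
        }
        for f, v in factors.items():
            per_feature.setdefault(f, {})[cls_name] = v
        p_path[cls_name] = math.prod(factors.values())
    prev = config.prevalence_pathogenic
    acc = (1 - prev) * (1 - p_path["neutral"]) + prev * p_path["pathogenic"]
    return ExpectedRates(
        p_pathogenic_given_neutral=p_path["neutral"],
        p_pathogenic_given_pathogenic=p_path["pathogenic"],
        accuracy=acc,
        rate_N_given_0=1 - p_path["neutral"],
        rate_P_given_0=p_path["neutral"],
        rate_N_given_1=1 - p_path["pathogenic"],
        rate_P_given_1=p_path["pathogenic"],
        per_feature=per_feature,
    )


# ---------------------------------------------------------------------------
# Preset configurations


def _af_range_for_rate(rate: float, threshold: float = DEFAULT_AF_THRESHOLD
                       ) -> FrequencyParams:
    """Always-catalogued log-uniform range whose below-threshold mass is `rate`.

    With the range anchored at 1e-6 and the threshold at 1e-4 the CDF at the
    threshold is 2 / (log10(hi) + 6); solving for hi needs rate >= 1/3.
    """
    if not (1 / 3 <= rate <= 1.0):
        raise ConfigurationError(f"rate {rate} outside [1/3, 1] for this anchor")
    lo = 1e-6
    hi = 10 ** (math.log10(threshold / lo) / rate + math.log10(lo))
    return FrequencyParams(p_catalogued=1.0, af_range=(lo, min(hi, 1.0)))


def _ndamage_probs_for_rate(rate: float, cutoff: int = DEFAULT_NDAMAGE_CUTOFF,
                            n: int = 9) -> tuple[float, ...]:
    """Equal per-predictor probability p with P(Binomial(n, p) >= cutoff) = rate."""
    from scipy.optimize import brentq
    from scipy.stats import binom

    p = brentq(lambda q: binom.sf(cutoff - 1, n, q) - rate, 1e-9, 1 - 1e-9)
    return (float(p),) * n


def demo_clinvar_like_config(n_variants: int = 30_000, seed: int = 0
                             ) -> GeneratorConfig:
    """Demonstration preset shaped like a curated clinical training set.

    Class prevalence mirrors a curated non-synonymous set that skews
    pathogenic (57%), and the class-conditional feature rates are chosen so
    the reference four-level chain lands near 91% correct among neutrals and
    92% correct among pathogenics — the per-class pattern reported for this
    family of classifiers on curated data.  A demonstration of the study
    conditions, not a reproduction of any external database.
    """
    neutral = ClassParams(
        # one pathogenic call among the three flips SPP: P(SPP=1|neutral)=0.563
        spp_call_probs=(0.30, 0.22, 0.20),
        exac=FrequencyParams(p_catalogued=0.90, af_range=(1e-6, 1e-2)),
        common=FrequencyParams(p_catalogued=0.90, af_range=(1e-6, 1e-2)),
        ndamage_probs=(0.512,) * 9,  # P(NDamage=1|neutral) ~ 0.53
    )
    pathogenic = ClassParams(
        spp_call_probs=(0.90, 0.85, 0.80),  # P(SPP=1|path) ~ 0.997
        exac=FrequencyParams(p_catalogued=0.12, af_range=(1e-6, 1e-3)),
        common=FrequencyParams(p_catalogued=0.05, af_range=(1e-6, 1e-3)),
        ndamage_probs=(0.799,) * 9,  # P(NDamage=1|path) ~ 0.98
    )
    return GeneratorConfig(
        n_variants=n_variants,
        prevalence_pathogenic=0.57,
        neutral=neutral,
        pathogenic=pathogenic,
        seed=seed,
    )


def planted_chain_config(n_variants: int = 20_000, seed: int = 0
                         ) -> GeneratorConfig:
    """Preset with strictly ordered separabilities planting SPP-ExAC-NDamage-COMMON.

    Pathogenic-class rates are uniformly high (0.995 per feature) while the
    neutral-class rates increase along the planted order (0.50, 0.55, 0.60,
    0.65), so each deeper level strictly improves whole-set accuracy on the
    surviving variants and greedy induction should recover the planted
    chain.
    """
    neutral = ClassParams(
        spp_call_probs=(0.2063,) * 3,            # P(SPP=1|n) = 0.50
        exac=_af_range_for_rate(0.55),
        common=_af_range_for_rate(0.65),
        ndamage_probs=_ndamage_probs_for_rate(0.60),
    )
    high = 0.995
    pathogenic = ClassParams(
        spp_call_probs=(1 - (1 - high) ** (1 / 3),) * 3,
        exac=_af_range_for_rate(high),
        common=_af_range_for_rate(high),
        ndamage_probs=_ndamage_probs_for_rate(high),
    )
    return GeneratorConfig(
        n_variants=n_variants,
        prevalence_pathogenic=0.5,
        neutral=neutral,
        pathogenic=pathogenic,
        seed=seed,
    )


def random_config(seed: int, n_variants: int = 200_000) -> GeneratorConfig:
    """A random valid configuration with non-degenerate class margins.

    Neutral-class feature rates are drawn moderate, pathogenic-class rates
    high, keeping both classes and all four features informative; used for
    oracle-agreement checks.
    """
    rng = np.random.default_rng(seed)

    def freq():
        return FrequencyParams(
            p_catalogued=float(rng.uniform(0.3, 1.0)),
            af_range=tuple(sorted(np.exp(rng.uniform(math.log(1e-6),
                                                     math.log(1e-1), 2)))),
        )

    def cls(lo, hi):
        return ClassParams(
            spp_call_probs=tuple(rng.uniform(lo, hi, 3)),
            exac=freq(),
            common=freq(),
            ndamage_probs=tuple(rng.uniform(lo, hi, 9)),
        )

    return GeneratorConfig(
        n_variants=n_variants,
        prevalence_pathogenic=float(rng.uniform(0.3, 0.7)),
        neutral=cls(0.1, 0.6),
        pathogenic=cls(0.5, 0.98),
        missingness={"damage": float(rng.uniform(0.0, 0.1)),
                     "exac_af": float(rng.uniform(0.0, 0.05)),
                     "common_af": float(rng.uniform(0.0, 0.05))},
        seed=int(rng.integers(0, 2**31 - 1)),
    )
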