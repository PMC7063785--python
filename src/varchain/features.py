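"""Binary discretization of variant annotations into pathogenicity-leaning flags.

Every classifying variable is reduced to {0, 1}, 1 meaning pathogenic-leaning:

* ``SPP`` — consensus over SIFT/PolyPhen/PROVEAN: neutral (0) only when all
  three agree neutral; a single pathogenic call flips it to 1.
* ``ExAC`` / ``COMMON`` — rarity flags over population allele frequencies:
  1 when the frequency is at or below the threshold (default 1e-4) *or* the
  variant is absent from the catalogue; only a frequency strictly above the
  threshold is evidence of neutrality.
* ``NDamage`` — count of damage predictors (of up to nine) calling the
  variant pathogenic, thresholded at >= 5.
* auxiliary variables (domain overlap, transition/transversion, amino-acid
  class changes, pass-through flags) screened but not used by the main chain.

Missing data policy is deliberately asymmetric: an *uncatalogued* allele
frequency is pathogenic-leaning (rare variants are exactly the ones absent
from population catalogues), while a missing damage call simply does not
count toward the NDamage tally.  Imputation is recorded per feature in the
``provenance`` map so reports can quantify it.
"""

from __future__ import annotations

import json
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .variants import AnnotatedVariant, Call, ConfigurationError

SPP = "SPP"
EXAC = "ExAC"
NDAMAGE = "NDamage"
COMMON = "COMMON"
CORE_FEATURES = (SPP, EXAC, NDAMAGE, COMMON)

AUX_FEATURES = (
    "interpro_domain",
    "transition_transversion",
    "charged_uncharged",
    "hydrophobic_hydrophilic",
    "essential_nonessential",
    "initial_exon",
    "ppi",
)

# Standard biochemical partitions of the 20 amino acids.
CHARGED_AA = frozenset("DEKRH")
HYDROPHOBIC_AA = frozenset("AVLIMFWC")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

DEFAULT_AF_THRESHOLD = 1e-4
DEFAULT_NDAMAGE_CUTOFF = 5


class Provenance(str, Enum):
    OBSERVED = "observed"
    IMPUTED_MISSING = "imputed_missing"


class PreconditionError(ValueError):
    """A discretizer's input contract was violated (e.g. missing SPP call)."""


@dataclass
class FeatureVector:
    """A variant after binary discretization.

    ``values[f]`` is 0 (neutral-leaning) or 1 (pathogenic-leaning);
    ``provenance[f]`` records whether the flag was observed or imputed from a
    missing annotation.
    """

    values: dict[str, int]
    provenance: dict[str, Provenance] = field(default_factory=dict)

    def __getitem__(self, feature: str) -> int:
        return self.values[feature]


def discretize_spp(v: AnnotatedVariant) -> int:
    """Consensus of the three classical predictors: 0 iff all call neutral.

    Requires all three calls present — variants with a missing classical
    call are excluded from the training set upstream.
    """
    calls = (v.sift_call, v.polyphen_call, v.provean_call)
    if Call.MISSING in calls:
        missing = [n for n, c in zip(("SIFT", "PolyPhen", "PROVEAN"), calls)
                   if c is Call.MISSING]
        raise PreconditionError(f"SPP requires all three calls; missing: {missing}")
    return int(any(c is Call.PATHOGENIC for c in calls))


def _discretize_af(af: float | None, threshold: float) -> tuple[int, Provenance]:
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    if af is None:
        return 1, Provenance.IMPUTED_MISSING
    # boundary af == threshold goes to the pathogenic (rare) branch
    return int(af <= threshold), Provenance.OBSERVED


def discretize_exac(
    v: AnnotatedVariant, threshold: float = DEFAULT_AF_THRESHOLD
) -> int:
    """Rarity in the exome aggregate: 1 iff AF <= threshold or uncatalogued."""
    return _discretize_af(v.exac_af, threshold)[0]


def discretize_common(
    v: AnnotatedVariant, threshold: float = DEFAULT_AF_THRESHOLD
) -> int:
    """Rarity in the 1000 Genomes-derived COMMON annotation; same rule as ExAC."""
    return _discretize_af(v.common_af, threshold)[0]


def discretize_ndamage(
    v: AnnotatedVariant, cutoff: int = DEFAULT_NDAMAGE_CUTOFF
) -> int:
    """1 iff at least ``cutoff`` damage predictors call the variant pathogenic.

    Missing calls count as not-pathogenic (they lower the tally rather than
    rescale the cutoff), which keeps the feature monotone in added evidence.
    """
    if not (1 <= cutoff <= 9):
        raise ValueError(f"cutoff {cutoff} outside [1, 9]")
    count = sum(1 for c in v.damage_calls.values() if c is Call.PATHOGENIC)
    return int(count >= cutoff)


def _is_transversion(ref: str, alt: str) -> bool:
    r, a = ref.upper(), alt.upper()
    return (r in _PURINES) != (a in _PURINES) and r in _PURINES | _PYRIMIDINES \
        and a in _PURINES | _PYRIMIDINES


def discretize_auxiliary(
    v: AnnotatedVariant, feature: str
) -> tuple[int, Provenance]:
    """Discretize one of the screened auxiliary variables.

    Returns ``(flag, provenance)``; a missing required annotation yields
    ``(0, IMPUTED_MISSING)`` — auxiliary evidence never defaults to
    pathogenic.
    """
    if feature not in AUX_FEATURES:
        raise ConfigurationError(f"unknown auxiliary feature {feature!r}")

    if feature == "transition_transversion":
        if len(v.ref) == 1 and len(v.alt) == 1 and {v.ref.upper(), v.alt.upper()} \
                <= _PURINES | _PYRIMIDINES:
            return int(_is_transversion(v.ref, v.alt)), Provenance.OBSERVED
        return 0, Provenance.IMPUTED_MISSING

    if feature in ("charged_uncharged", "hydrophobic_hydrophilic"):
        aa_set = CHARGED_AA if feature == "charged_uncharged" else HYDROPHOBIC_AA
        if v.ref_aa and v.alt_aa:
            crosses = (v.ref_aa.upper() in aa_set) != (v.alt_aa.upper() in aa_set)
            return int(crosses), Provenance.OBSERVED
        return 0, Provenance.IMPUTED_MISSING

    # interpro_domain, essential_nonessential, initial_exon, ppi: pass-through
    flag = v.aux_flags.get(feature)
    if flag is None:
        return 0, Provenance.IMPUTED_MISSING
    return int(flag), Provenance.OBSERVED


@dataclass(frozen=True)
class FeatureDef:
    """One registered feature: an extractor plus its parameters."""

    name: str
    extractor: Callable[[AnnotatedVariant], tuple[int, Provenance]]
    params: Mapping[str, float | int] = field(default_factory=dict)


class FeatureRegistry:
    """Named set of binary discretizers applied to each variant.

    The default registry holds the four chain features (SPP, ExAC, NDamage,
    COMMON) at the thresholds of the reference tree; auxiliary features and
    custom thresholds are added via :meth:`register` /
    :meth:`with_thresholds`.
    """

    def __init__(self, definitions: Sequence[FeatureDef] | None = None):
        if definitions is None:
            definitions = _core_defs()
        self._defs: dict[str, FeatureDef] = {}
        for d in definitions:
            if d.name in self._defs:
                raise ConfigurationError(f"duplicate feature name {d.name!r}")
            self._defs[d.name] = d

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self._defs)

    def register(self, fdef: FeatureDef) -> "FeatureRegistry":
        if fdef.name in self._defs:
            raise ConfigurationError(f"duplicate feature name {fdef.name!r}")
        self._defs[fdef.name] = fdef
        return self

    def restricted(self, names: Sequence[str]) -> "FeatureRegistry":
        unknown = [n for n in names if n not in self._defs]
        if unknown:
            raise ConfigurationError(f"unregistered features: {unknown}")
        return FeatureRegistry([self._defs[n] for n in names])

    @classmethod
    def default(cls) -> "FeatureRegistry":
        return cls()

    @classmethod
    def with_thresholds(
        cls,
        af_threshold: float = DEFAULT_AF_THRESHOLD,
        ndamage_cutoff: int = DEFAULT_NDAMAGE_CUTOFF,
        common_threshold: float | None = None,
    ) -> "FeatureRegistry":
        return cls(_core_defs(af_threshold, ndamage_cutoff,
                              common_threshold if common_threshold is not None
                              else af_threshold))

    @classmethod
    def with_auxiliary(cls, aux: Sequence[str] = AUX_FEATURES) -> "FeatureRegistry":
        reg = cls()
        for name in aux:
            reg.register(FeatureDef(
                name,
                lambda v, name=name: discretize_auxiliary(v, name),
            ))
        return reg

    def discretize(self, v: AnnotatedVariant) -> FeatureVector:
        values: dict[str, int] = {}
        prov: dict[str, Provenance] = {}
        for name, fdef in self._defs.items():
            values[name], prov[name] = fdef.extractor(v)
        return FeatureVector(values, prov)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {name: dict(d.params) for name, d in self._defs.items()}, indent=2
        ))


def _core_defs(
    af_threshold: float = DEFAULT_AF_THRESHOLD,
    ndamage_cutoff: int = DEFAULT_NDAMAGE_CUTOFF,
    common_threshold: float = DEFAULT_AF_THRESHOLD,
) -> list[FeatureDef]:
    return [
        FeatureDef(SPP, lambda v: (discretize_spp(v), Provenance.OBSERVED)),
        FeatureDef(
            EXAC,
            lambda v: _discretize_af(v.exac_af, af_threshold),
            {"threshold": af_threshold},
        ),
        FeatureDef(
            NDAMAGE,
            lambda v: (discretize_ndamage(v, ndamage_cutoff), Provenance.OBSERVED),
            {"cutoff": ndamage_cutoff},
        ),
        FeatureDef(
            COMMON,
            lambda v: _discretize_af(v.common_af, common_threshold),
            {"threshold": common_threshold},
        ),
    ]


def discretize_variant(
    v: AnnotatedVariant, registry: FeatureRegistry | None = None
) -> FeatureVector:
    """Apply every registered discretizer; the result covers all registry features."""
    registry = registry or FeatureRegistry.default()
    return registry.discretize(v)


def discretize_all(
    variants: Sequence[AnnotatedVariant], registry: FeatureRegistry | None = None
) -> list[FeatureVector]:
    registry = registry or FeatureRegistry.default()
    return [registry.discretize(v) for v in variants]


def feature_matrix(
    fvs: Sequence[FeatureVector], feature_names: Sequence[str]
) -> np.ndarray:
    """Stack feature vectors into an (n, k) uint8 matrix in the given order."""
    try:
        return np.array(
            [[fv.values[f] for f in feature_names] for fv in fvs], dtype=np.uint8
        ).reshape(len(fvs), len(feature_names))
    except KeyError as exc:
        raise ConfigurationError(f"feature {exc.args[0]!r} absent from a "
                                 "FeatureVector") from exc
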