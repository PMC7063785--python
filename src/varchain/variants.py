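"""Annotated-variant ingestion, ClinVar-style label harmonization, training filters.

A variant arrives already annotated (dbNSFP/snpEff style): calls from the
three classical predictors (SIFT, PolyPhen, PROVEAN), calls from up to nine
further damage predictors, population allele frequencies from an ExAC-like
exome aggregate and a 1000 Genomes-derived COMMON annotation, and a clinical
significance string.  This module reads such tables from VCF or TSV, maps the
clinical significance onto {neutral, pathogenic, unlabeled}, and applies the
training-set filters (non-synonymous, fully predicted, clinically labeled).
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import pandas as pd


class Call(str, Enum):
    """A single predictor's verdict on one variant."""

    NEUTRAL = "neutral"
    PATHOGENIC = "pathogenic"
    MISSING = "missing"


class Consequence(str, Enum):
    NON_SYNONYMOUS = "non_synonymous"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Label(str, Enum):
    """Harmonized clinical-significance class."""

    NEUTRAL = "neutral"
    PATHOGENIC = "pathogenic"
    UNLABELED = "unlabeled"


class FormatError(ValueError):
    """Malformed input table (bad header, unparseable record)."""


class ConfigurationError(ValueError):
    """A field_map/registry names a column, key or feature that does not exist."""


@dataclass
class AnnotatedVariant:
    """One variant with its raw annotations, prior to discretization.

    Coordinates follow the VCF convention (1-based ``pos``).  Allele
    frequencies are fractions in [0, 1]; ``None`` means the variant is not
    catalogued in (or was not annotated against) the respective database.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence = Consequence.NON_SYNONYMOUS
    sift_call: Call = Call.MISSING
    polyphen_call: Call = Call.MISSING
    provean_call: Call = Call.MISSING
    damage_calls: dict[str, Call] = field(default_factory=dict)
    exac_af: float | None = None
    common_af: float | None = None
    clnsig_raw: str = ""
    label: Label = Label.UNLABELED
    aux_flags: dict[str, int | None] = field(default_factory=dict)
    ref_aa: str | None = None
    alt_aa: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref!r})")
        for af, name in ((self.exac_af, "exac_af"), (self.common_af, "common_af")):
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"{name}={af} outside [0, 1]")


# Default recodings of raw predictor strings, dbNSFP conventions.  PolyPhen's
# "possibly damaging" (P) counts as pathogenic by default; override via the
# call_codes argument of read_annotated_table if a stricter reading is wanted.
DEFAULT_CALL_CODES: dict[str, Mapping[str, Call]] = {
    "sift": {"D": Call.PATHOGENIC, "T": Call.NEUTRAL},
    "polyphen": {"D": Call.PATHOGENIC, "P": Call.PATHOGENIC, "B": Call.NEUTRAL},
    "provean": {"D": Call.PATHOGENIC, "N": Call.NEUTRAL},
    "damage": {"D": Call.PATHOGENIC, "T": Call.NEUTRAL, "N": Call.NEUTRAL,
               "B": Call.NEUTRAL, "P": Call.PATHOGENIC},
}


@dataclass(frozen=True)
class LabelPolicy:
    """Which clinical-significance codes count as neutral vs pathogenic.

    Historic ClinVar VCFs use numeric CLNSIG codes (2/3 benign-leaning, 4/5
    pathogenic-leaning); modern releases use text.  ``text_synonyms`` maps
    textual terms onto the numeric codes so one policy covers both dialects.
    """

    neutral_codes: frozenset[str] = frozenset({"2", "3"})
    pathogenic_codes: frozenset[str] = frozenset({"4", "5"})
    text_synonyms: Mapping[str, str] = field(
        default_factory=lambda: {
            "benign": "2",
            "likely_benign": "3",
            "likely_pathogenic": "4",
            "pathogenic": "5",
        }
    )

    def __post_init__(self) -> None:
        if self.neutral_codes & self.pathogenic_codes:
            raise ValueError("neutral and pathogenic code sets overlap")

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelPolicy":
        raw = json.loads(Path(path).read_text())
        return cls(
            neutral_codes=frozenset(raw.get("neutral_codes", ["2", "3"])),
            pathogenic_codes=frozenset(raw.get("pathogenic_codes", ["4", "5"])),
            text_synonyms=raw.get("text_synonyms", {}),
        )


_CLNSIG_SEPARATORS = str.maketrans({c: "|" for c in ",;/"})


def parse_label(clnsig_raw: str, policy: LabelPolicy | None = None) -> Label:
    """Harmonize a raw clinical-significance string into a training label.

    Multi-valued fields (pipe/comma/semicolon separated) resolve to a class
    only when every code falls on the same side of the policy; any mixture,
    unknown code, or empty field yields ``UNLABELED``.  Total function: never
    raises on data.
    """
    policy = policy or LabelPolicy()
    tokens = [
        t.strip() for t in str(clnsig_raw).translate(_CLNSIG_SEPARATORS).split("|")
    ]
    tokens = [t for t in tokens if t]
    if not tokens:
        return Label.UNLABELED
    sides = set()
    for tok in tokens:
        code = policy.text_synonyms.get(tok.lower(), tok)
        if code in policy.neutral_codes:
            sides.add(Label.NEUTRAL)
        elif code in policy.pathogenic_codes:
            sides.add(Label.PATHOGENIC)
        else:
            return Label.UNLABELED
    if len(sides) == 1:
        return sides.pop()
    return Label.UNLABELED


# Roles a field_map may bind.  The three classical predictors and the label
# are mandatory; everything else degrades to "missing" when unmapped.
_REQUIRED_ROLES = ("sift", "polyphen", "provean", "clnsig")
_SCALAR_ROLES = (
    "chrom", "pos", "ref", "alt", "consequence", "sift", "polyphen", "provean",
    "exac_af", "common_af", "clnsig", "ref_aa", "alt_aa",
)


def _recode_call(raw, codes: Mapping[str, Call]) -> Call:
    if raw is None:
        return Call.MISSING
    s = str(raw).strip()
    if not s or s in (".", "NA", "nan", "None"):
        return Call.MISSING
    return codes.get(s, codes.get(s.upper(), Call.MISSING))


def _parse_af(raw) -> float | None:
    if raw is None:
        return None
    try:
        v = float(raw)
    except (TypeError, ValueError):
        return None
    if v != v:  # NaN
        return None
    return v


def _parse_consequence(raw) -> Consequence:
    if raw is None:
        return Consequence.OTHER
    s = str(raw).strip().lower()
    if s in ("non_synonymous", "nonsynonymous", "missense", "missense_variant",
             "non-synonymous"):
        return Consequence.NON_SYNONYMOUS
    if s in ("synonymous", "synonymous_variant"):
        return Consequence.SYNONYMOUS
    return Consequence.OTHER


def _parse_flag(raw) -> int | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if s in ("", ".", "NA", "nan", "None"):
        return None
    try:
        v = int(float(s))
    except ValueError:
        return None
    return v if v in (0, 1) else None


def _build_variant(
    fetch,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    field_map: Mapping[str, str],
    policy: LabelPolicy,
    call_codes: Mapping[str, Mapping[str, Call]],
    damage_roles: Sequence[str],
    aux_roles: Sequence[str],
) -> AnnotatedVariant:
    """Assemble one AnnotatedVariant from a per-role value accessor."""
    clnsig = fetch("clnsig")
    clnsig_raw = "" if clnsig is None else str(clnsig)
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        consequence=_parse_consequence(fetch("consequence"))
        if "consequence" in field_map
        else Consequence.NON_SYNONYMOUS,
        sift_call=_recode_call(fetch("sift"), call_codes["sift"]),
        polyphen_call=_recode_call(fetch("polyphen"), call_codes["polyphen"]),
        provean_call=_recode_call(fetch("provean"), call_codes["provean"]),
        damage_calls={
            role: _recode_call(fetch(role), call_codes["damage"])
            for role in damage_roles
        },
        exac_af=_parse_af(fetch("exac_af")) if "exac_af" in field_map else None,
        common_af=_parse_af(fetch("common_af")) if "common_af" in field_map else None,
        clnsig_raw=clnsig_raw,
        label=parse_label(clnsig_raw, policy),
        aux_flags={role: _parse_flag(fetch(role)) for role in aux_roles},
        ref_aa=(str(fetch("ref_aa")) or None) if "ref_aa" in field_map and fetch("ref_aa") is not None else None,
        alt_aa=(str(fetch("alt_aa")) or None) if "alt_aa" in field_map and fetch("alt_aa") is not None else None,
    )


def _split_roles(field_map: Mapping[str, str]):
    damage = sorted(r for r in field_map if r.startswith("damage:"))
    aux = sorted(r for r in field_map if r.startswith("aux:"))
    return damage, aux


def read_annotated_table(
    path: str | Path,
    dialect: str,
    field_map: Mapping[str, str],
    policy: LabelPolicy | None = None,
    call_codes: Mapping[str, Mapping[str, Call]] | None = None,
) -> list[AnnotatedVariant]:
    """Read an annotated variant table into :class:`AnnotatedVariant` records.

    Parameters
    ----------
    path
        A VCF 4.x file or a TSV with a header row.
    dialect
        ``"vcf"`` or ``"tsv"``.
    field_map
        role → column name (TSV) or INFO key (VCF).  Roles: ``chrom``,
        ``pos``, ``ref``, ``alt`` (TSV only; VCF takes them from the fixed
        columns), ``consequence``, ``sift``, ``polyphen``, ``provean``,
        ``exac_af``, ``common_af``, ``clnsig``, ``ref_aa``, ``alt_aa``, any
        number of ``damage:<name>`` damage-predictor roles and ``aux:<name>``
        auxiliary binary flags.  The three classical predictors and
        ``clnsig`` are mandatory.
    policy, call_codes
        Label policy and predictor recodings; defaults cover numeric+textual
        CLNSIG and dbNSFP letter codes.

    Unmapped or unparseable annotations become missing, never fabricated.
    Multi-allelic VCF records are split into one variant per alt allele with
    per-allele (Number=A) INFO values index-matched.  Record order preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    missing_roles = [r for r in _REQUIRED_ROLES if r not in field_map]
    if missing_roles:
        raise ConfigurationError(
            f"field_map missing required roles: {', '.join(missing_roles)}"
        )
    policy = policy or LabelPolicy()
    codes = dict(DEFAULT_CALL_CODES)
    if call_codes:
        codes.update(call_codes)
    damage_roles, aux_roles = _split_roles(field_map)

    if dialect == "tsv":
        return _read_tsv(path, field_map, policy, codes, damage_roles, aux_roles)
    if dialect == "vcf":
        return _read_vcf(path, field_map, policy, codes, damage_roles, aux_roles)
    raise ConfigurationError(f"unknown dialect {dialect!r} (expected 'vcf' or 'tsv')")


def _read_tsv(path, field_map, policy, codes, damage_roles, aux_roles):
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed TSV {path}: {exc}") from exc
    if df.columns.size == 0 or df.columns.str.startswith("Unnamed").all():
        raise FormatError(f"malformed TSV header at {path} line 1")
    absent = sorted(
        {field_map[r] for r in field_map} - set(df.columns)
    )
    if absent:
        raise ConfigurationError(
            f"mapped columns absent from {path.name}: {', '.join(absent)}"
        )

    variants: list[AnnotatedVariant] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        record = dict(zip(df.columns, row))

        def fetch(role, record=record):
            col = field_map.get(role)
            if col is None:
                return None
            v = record.get(col, "")
            return None if v in ("", ".") else v

        try:
            variants.append(
                _build_variant(
                    fetch,
                    chrom=str(fetch("chrom") or "."),
                    pos=int(fetch("pos") or 1),
                    ref=str(fetch("ref") or "N"),
                    alt=str(fetch("alt") or "X"),
                    field_map=field_map,
                    policy=policy,
                    call_codes=codes,
                    damage_roles=damage_roles,
                    aux_roles=aux_roles,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path.name} line {idx}: {exc}") from exc
    return variants


def _read_vcf(path, field_map, policy, codes, damage_roles, aux_roles):
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad headers
        raise FormatError(f"malformed VCF header in {path}: {exc}") from exc

    variants: list[AnnotatedVariant] = []
    for rec in vcf:
        alts = rec.ALT or []
        for i, alt in enumerate(alts):

            def fetch(role, rec=rec, i=i, n=len(alts)):
                key = field_map.get(role)
                if key is None:
                    return None
                val = rec.INFO.get(key)
                if isinstance(val, (tuple, list)):
                    # Number=A annotations are index-matched to the alt allele
                    return val[i] if len(val) == n else (val[0] if val else None)
                if isinstance(val, bytes):
                    val = val.decode()
                if isinstance(val, str) and len(alts) > 1 and val.count(",") == n - 1:
                    return val.split(",")[i]
                return val

            variants.append(
                _build_variant(
                    fetch,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    field_map=field_map,
                    policy=policy,
                    call_codes=codes,
                    damage_roles=damage_roles,
                    aux_roles=aux_roles,
                )
            )
    return variants


@dataclass(frozen=True)
class FilterReport:
    """Per-criterion removal counts from :func:`filter_training_set`."""

    n_input: int
    n_not_nonsynonymous: int
    n_missing_predictor: int
    n_unlabeled: int
    n_retained: int


def filter_training_set(
    variants: Sequence[AnnotatedVariant],
) -> tuple[list[AnnotatedVariant], FilterReport]:
    """Apply the training-set criteria, in order, returning survivors + counts.

    A variant is retained iff it is (1) non-synonymous, (2) carries a
    non-missing call from each of SIFT, PolyPhen and PROVEAN, and (3) has a
    harmonized label of neutral or pathogenic.  Criteria are applied
    sequentially, so each removed variant is counted under the first
    criterion it fails; input order is preserved and the operation is
    idempotent.
    """
    kept: list[AnnotatedVariant] = []
    n_syn = n_pred = n_lab = 0
    for v in variants:
        if v.consequence is not Consequence.NON_SYNONYMOUS:
            n_syn += 1
            continue
        if Call.MISSING in (v.sift_call, v.polyphen_call, v.provean_call):
            n_pred += 1
            continue
        if v.label not in (Label.NEUTRAL, Label.PATHOGENIC):
            n_lab += 1
            continue
        kept.append(v)
    return kept, FilterReport(
        n_input=len(variants),
        n_not_nonsynonymous=n_syn,
        n_missing_predictor=n_pred,
        n_unlabeled=n_lab,
        n_retained=len(kept),
    )


def write_variants_tsv(
    variants: Iterable[AnnotatedVariant], path: str | Path
) -> None:
    """Write variants to a TSV readable back by :func:`read_annotated_table`.

    Columns use canonical role names; downstream discretization of a written
    then re-read table is identical to that of the in-memory variants.
    """
    rows = []
    damage_names: list[str] = []
    aux_names: list[str] = []
    variants = list(variants)
    for v in variants:
        for d in v.damage_calls:
            if d not in damage_names:
                damage_names.append(d)
        for a in v.aux_flags:
            if a not in aux_names:
                aux_names.append(a)

    def call_str(c: Call, neutral_code: str = "T") -> str:
        # neutral codes differ per predictor (dbNSFP conventions)
        return {Call.PATHOGENIC: "D", Call.NEUTRAL: neutral_code,
                Call.MISSING: "."}[c]

    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "consequence": v.consequence.value,
            "SIFT": call_str(v.sift_call, "T"),
            "Polyphen": call_str(v.polyphen_call, "B"),
            "PROVEAN": call_str(v.provean_call, "N"),
            "ExAC_AF": "." if v.exac_af is None else repr(v.exac_af),
            "COMMON_AF": "." if v.common_af is None else repr(v.common_af),
            "CLNSIG": v.clnsig_raw,
            "ref_aa": v.ref_aa or ".",
            "alt_aa": v.alt_aa or ".",
            "label": v.label.value,
        }
        for d in damage_names:
            row[d.removeprefix("damage:")] = call_str(
                v.damage_calls.get(d, Call.MISSING)
            )
        for a in aux_names:
            flag = v.aux_flags.get(a)
            row[a.removeprefix("aux:")] = "." if flag is None else flag
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_field_map(
    damage_predictors: Sequence[str] = (), aux_features: Sequence[str] = ()
) -> dict[str, str]:
    """field_map matching the columns written by :func:`write_variants_tsv`."""
    fm = {
        "chrom": "chrom",
        "pos": "pos",
        "ref": "ref",
        "alt": "alt",
        "consequence": "consequence",
        "sift": "SIFT",
        "polyphen": "Polyphen",
        "provean": "PROVEAN",
        "exac_af": "ExAC_AF",
        "common_af": "COMMON_AF",
        "clnsig": "CLNSIG",
        "ref_aa": "ref_aa",
        "alt_aa": "alt_aa",
    }
    for d in damage_predictors:
        fm[f"damage:{d}"] = d
    for a in aux_features:
        fm[f"aux:{a}"] = a
    return fm
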