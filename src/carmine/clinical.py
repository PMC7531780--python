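"""Discretisation of raw clinical measurements into category codes.

The study cohort carries 29 attributes spanning demographic, cardiovascular /
obesity, glycemic, lipid, periodontal and mutagenesis measurements. Each is
mapped to a small ordinal domain (e.g. fasting plasma glucose: 1 =
normoglycemic <100 mg/dL, 2 = prediabetes [100, 126), 3 = established
diabetes >=126). Waist/hip ratio additionally stratifies the cutoffs by sex
and age band (<=39, (39, 49], >49 years), and abdominal circumference by sex.

The cutoffs are data, not code: they ship in ``data/cutoffs.yaml`` inside the
package and are loaded once per process.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import yaml

from .transactions import Item

# The 17 attributes used for the clinical-features-only analyses: the
# clinically routine diagnostic markers, mutagenesis excluded.
CF17_ATTRIBUTES: tuple[str, ...] = (
    "BMI", "WHR", "AC", "FPG", "HbA1c", "HOMA-IR", "TC", "HDL", "LDL", "TG",
    "N-HDL-C", "GI", "BOP", "PPDi6mm", "CALi3-4mm", "CALi5mm", "SUPP",
)

# Periodontal disease-activity attributes among those 17, used as rule
# consequents; the remaining periodontal attributes of the full table.
PERIODONTAL_CF17: tuple[str, ...] = (
    "GI", "BOP", "PPDi6mm", "CALi3-4mm", "CALi5mm", "SUPP",
)

# Cardiovascular / obesity risk attributes allowed in antecedents of the
# cardiovascular-focused analysis.
CARDIO_ATTRIBUTES: tuple[str, ...] = ("BMI", "WHR", "AC", "FPG", "N-HDL-C")

# Accepted header spellings -> canonical attribute names.
_ALIASES = {
    "CALi34mm": "CALi3-4mm",
    "PPDi45mm": "PPDi4-5mm",
    "NHDLC": "N-HDL-C",
    "N-HDL-c": "N-HDL-C",
    "HOMA": "HOMA-IR",
}

_SEX_CODES = {"female": 1, "f": 1, "1": 1, "male": 2, "m": 2, "2": 2}


@dataclass(frozen=True)
class Bin:
    code: int
    lo: float = -math.inf
    hi: float = math.inf
    lo_incl: bool = True
    hi_incl: bool = False

    def contains(self, v: float) -> bool:
        above = v > self.lo or (self.lo_incl and v == self.lo)
        below = v < self.hi or (self.hi_incl and v == self.hi)
        return above and below


@dataclass(frozen=True)
class AttributeSpec:
    name: str
    kind: str  # categorical | interval | stratified_sex | stratified_sex_age
    codes: frozenset[int]
    unit: Optional[str] = None
    sample_range: Optional[tuple[float, float]] = None
    bins: tuple[Bin, ...] = ()
    # stratified kinds: sex -> [(age_hi or None, bins), ...]
    strata: dict = field(default_factory=dict)


def _parse_bins(raw: Iterable[dict]) -> tuple[Bin, ...]:
    out = []
    for b in raw:
        out.append(
            Bin(
                code=int(b["code"]),
                lo=float(b["lo"]) if b.get("lo") is not None else -math.inf,
                hi=float(b["hi"]) if b.get("hi") is not None else math.inf,
                lo_incl=bool(b.get("lo_incl", True)),
                hi_incl=bool(b.get("hi_incl", False)),
            )
        )
    return tuple(out)


def _load_specs() -> dict[str, AttributeSpec]:
    text = resources.files("carmine.data").joinpath("cutoffs.yaml").read_text()
    raw = yaml.safe_load(text)
    specs: dict[str, AttributeSpec] = {}
    for name, entry in raw["attributes"].items():
        kind = entry["kind"]
        rng = tuple(entry["range"]) if "range" in entry else None
        if kind == "categorical":
            specs[name] = AttributeSpec(
                name, kind, frozenset(int(c) for c in entry["codes"]),
                unit=entry.get("unit"), sample_range=rng,
            )
        elif kind == "interval":
            bins = _parse_bins(entry["bins"])
            specs[name] = AttributeSpec(
                name, kind, frozenset(b.code for b in bins),
                unit=entry.get("unit"), sample_range=rng, bins=bins,
            )
        elif kind == "stratified_sex":
            strata = {
                sex: [(None, _parse_bins(bins))]
                for sex, bins in entry["strata"].items()
            }
            codes = frozenset(
                b.code for layers in strata.values() for _, bins in layers for b in bins
            )
            specs[name] = AttributeSpec(
                name, kind, codes, unit=entry.get("unit"),
                sample_range=rng, strata=strata,
            )
        elif kind == "stratified_sex_age":
            strata = {
                sex: [
                    (layer["age_hi"], _parse_bins(layer["bins"]))
                    for layer in layers
                ]
                for sex, layers in entry["strata"].items()
            }
            codes = frozenset(
                b.code for layers in strata.values() for _, bins in layers for b in bins
            )
            specs[name] = AttributeSpec(
                name, kind, codes, unit=entry.get("unit"),
                sample_range=rng, strata=strata,
            )
        else:
            raise ValueError(f"unknown attribute kind {kind!r} for {name}")
    return specs


_SPECS: Optional[dict[str, AttributeSpec]] = None


def attribute_specs() -> dict[str, AttributeSpec]:
    global _SPECS
    if _SPECS is None:
        _SPECS = _load_specs()
    return _SPECS


def canonical_attribute(name: str) -> str:
    name = name.strip()
    if name in attribute_specs():
        return name
    if name in _ALIASES:
        return _ALIASES[name]
    raise KeyError(f"unknown clinical attribute {name!r}")


ATTRIBUTES: tuple[str, ...] = tuple(attribute_specs().keys())  # table order


def is_clinical_attribute(name: str) -> bool:
    return name in attribute_specs() or name in _ALIASES


def domain(name: str) -> frozenset[int]:
    """Valid category codes of an attribute."""
    return attribute_specs()[canonical_attribute(name)].codes


def _code_from_bins(bins: Sequence[Bin], value: float, name: str) -> int:
    for b in bins:
        if b.contains(value):
            return b.code
    raise ValueError(f"value {value} falls in no bin of {name}")  # pragma: no cover


def _sex_key(sex) -> str:
    key = str(sex).strip().lower()
    if key not in _SEX_CODES:
        raise ValueError(f"sex must be female/male or 1/2, got {sex!r}")
    return "female" if _SEX_CODES[key] == 1 else "male"


def discretize_attribute(name: str, value: float) -> int:
    """Category code of a sex/age-independent attribute per its cutoff table.

    Raises for negative measurements (all attributes here are non-negative
    quantities) and refers the caller to the dedicated functions for the
    sex/age-stratified attributes.
    """
    name = canonical_attribute(name)
    spec = attribute_specs()[name]
    if spec.kind == "stratified_sex_age":
        raise ValueError(f"{name} cutoffs depend on sex and age; use discretize_whr")
    if spec.kind == "stratified_sex":
        raise ValueError(f"{name} cutoffs depend on sex; use discretize_ac")
    if spec.kind == "categorical":
        code = int(value)
        if code not in spec.codes:
            raise ValueError(f"{name} code {value} outside domain {sorted(spec.codes)}")
        return code
    if value < 0:
        raise ValueError(f"negative measurement {value} for {name}")
    return _code_from_bins(spec.bins, float(value), name)


def discretize_whr(whr: float, sex, age: float) -> int:
    """Waist/hip-ratio code 1-4 from the sex- and age-stratified cutoffs
    (age bands <=39, (39, 49], >49 years; raw age, not the binary age code)."""
    if whr < 0:
        raise ValueError(f"negative measurement {whr} for WHR")
    layers = attribute_specs()["WHR"].strata[_sex_key(sex)]
    for age_hi, bins in layers:
        if age_hi is None or age <= age_hi:
            return _code_from_bins(bins, float(whr), "WHR")
    raise ValueError(f"age {age} matched no WHR stratum")  # pragma: no cover


def discretize_ac(ac: float, sex) -> int:
    """Abdominal-circumference risk code 1-3 (female cutoffs 80/88 cm, male
    94/102 cm)."""
    if ac < 0:
        raise ValueError(f"negative measurement {ac} for AC")
    (_, bins), = attribute_specs()["AC"].strata[_sex_key(sex)]
    return _code_from_bins(bins, float(ac), "AC")


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class RawClinicalRecord:
    """One subject's raw measurements. ``values`` maps canonical attribute
    names (all but Sex/Age, which are dedicated fields) to numbers; missing
    measurements are simply absent."""

    subject_id: str
    group: int
    sex: int  # 1 = female, 2 = male
    age: float  # years
    values: dict[str, float] = field(default_factory=dict)


@dataclass
class CodedClinicalRecord:
    """One subject's category codes, keyed by canonical attribute name."""

    subject_id: str
    group: int
    codes: dict[str, int] = field(default_factory=dict)


def validate_code(subject_id: str, name: str, code: int) -> int:
    name = canonical_attribute(name)
    if code not in domain(name):
        raise ValueError(
            f"subject {subject_id}: {name} code {code} outside domain "
            f"{sorted(domain(name))}"
        )
    return int(code)


def discretize_record(raw: RawClinicalRecord) -> CodedClinicalRecord:
    """Apply every cutoff table to one raw record. Sex and the Age code are
    derived from the dedicated fields; WHR/AC use the stratified cutoffs."""
    codes: dict[str, int] = {
        "Sex": discretize_attribute("Sex", raw.sex),
        "Age": discretize_attribute("Age", raw.age),
    }
    for name, value in raw.values.items():
        name = canonical_attribute(name)
        if value is None:
            continue
        if name == "WHR":
            codes[name] = discretize_whr(value, raw.sex, raw.age)
        elif name == "AC":
            codes[name] = discretize_ac(value, raw.sex)
        else:
            codes[name] = discretize_attribute(name, value)
    return CodedClinicalRecord(raw.subject_id, raw.group, codes)


def records_to_transactions(
    records: Sequence[CodedClinicalRecord],
    attributes: Optional[Sequence[str]] = None,
) -> tuple[list[set[Item]], list[int]]:
    """Turn coded records into item transactions over the given attribute
    subset (default: all 29). A missing attribute yields no item for that
    subject, with a warning."""
    attrs = tuple(canonical_attribute(a) for a in attributes) if attributes else ATTRIBUTES
    transactions: list[set[Item]] = []
    labels: list[int] = []
    for rec in records:
        items: set[Item] = set()
        for a in attrs:
            if a in rec.codes:
                items.add(Item(a, rec.codes[a]))
            else:
                warnings.warn(
                    f"subject {rec.subject_id}: missing value for {a}; "
                    "transaction emitted without that item"
                )
        transactions.append(items)
        labels.append(rec.group)
    return transactions, labels


def select_cf_subset(
    records: Sequence[CodedClinicalRecord],
) -> tuple[list[set[Item]], list[int]]:
    """Transactions over the 17 routine diagnostic attributes (mutagenesis
    and demographic attributes excluded)."""
    return records_to_transactions(records, CF17_ATTRIBUTES)


def select_diabetic_dyslipidemia(
    records: Sequence[RawClinicalRecord],
) -> list[RawClinicalRecord]:
    """The diabetic-dyslipidemia subset: group 1 or 2 subjects with raw
    TG >= 204 mg/dL and HDL < 38 mg/dL.

    Needs raw lipid values: the TG code 3 bin starts at 200 mg/dL and cannot
    resolve the 204 cutoff, so coded records are rejected with an explanation.
    """
    subset = []
    for r in records:
        if not isinstance(r, RawClinicalRecord):
            raise TypeError(
                "diabetic-dyslipidemia selection needs raw TG/HDL measurements; "
                "category codes cannot resolve the TG>=204 / HDL<38 cutoffs "
                "(pass an explicit subject-id list instead)"
            )
        if r.group in (1, 2):
            tg, hdl = r.values.get("TG"), r.values.get("HDL")
            if tg is not None and hdl is not None and tg >= 204 and hdl < 38:
                subset.append(r)
    return subset
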