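"""Synthetic study cohorts with known planted structure.

The generator emulates the shape of the study data so that every pipeline
stage is testable without the original subject-level files:

* a five-group clinical cohort (default sizes 28/29/29/29/28, totalling 143)
  in which each group carries a planted pattern of attribute codes — e.g. the
  poorly-controlled-diabetes group gets established-diabetes glycemic codes
  and high periodontal inflammation — held with a configurable adherence
  probability, against a uniform background; raw measurements are sampled
  uniformly inside the chosen code's cutoff bin so discretisation
  round-trips;
* a diabetic-dyslipidemia subset of exactly ``ddlp_size`` subjects planted in
  groups 1-2 with raw TG >= 204 mg/dL and HDL < 38 mg/dL;
* an expression matrix over the microarray subset (default 5/7/6/6/6,
  totalling 30) with a large low-variance probe fraction (removed by the
  range filter), noisy background profiles, and group-specific signature
  probes. A signature entry is a deterministic offset of
  ``signature_shift_sd * noise_sd`` in the group's subjects (over- or
  under-expressed), so that for shifts of at least ~3 noise-sd the ternary
  discretisation recovers the planted items exactly; background entries are
  N(0, noise_sd) draws.

All randomness flows from a single ``numpy.random.default_rng(seed)`` stream
per generated artefact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .clinical import (
    ATTRIBUTES,
    CodedClinicalRecord,
    RawClinicalRecord,
    attribute_specs,
    discretize_record,
    domain,
)
from .expression import ExpressionMatrix
from .transactions import Item


def default_patterns() -> dict[int, dict[str, int]]:
    """Planted per-group attribute codes reflecting the study's group
    definitions (1: poorly controlled diabetes + dyslipidemia + periodontitis
    ... 5: systemically and periodontally healthy controls)."""
    return {
        1: {
            "WHR": 4, "AC": 3, "FPG": 3, "HbA1c": 4, "HOMA-IR": 2,
            "TC": 4, "HDL": 1, "TG": 3, "BOP": 3, "SUPP": 2,
        },
        2: {
            "FPG": 3, "HbA1c": 3, "HOMA-IR": 2, "TC": 4, "TG": 3,
            "N-HDL-C": 5, "HDL": 1, "BOP": 3,
        },
        3: {
            "FPG": 1, "HbA1c": 1, "TC": 3, "HDL": 2, "TG": 2,
            "GI": 3, "BOP": 3, "PPDi6mm": 1,
        },
        4: {
            "BMI": 2, "FPG": 1, "HbA1c": 1, "HOMA-IR": 1, "TC": 2, "TG": 1,
            "CALi3-4mm": 3, "BOP": 3, "PPDi6mm": 1,
        },
        5: {
            "BMI": 2, "FPG": 1, "HbA1c": 1, "INS": 1, "TG": 1,
            "GI": 1, "BOP": 1, "SUPP": 1, "PPDi3mm": 3,
        },
    }


@dataclass
class SyntheticSpec:
    """Study-shaped generation parameters; defaults mirror the cohort sizes
    and data dimensions of the study."""

    group_sizes: tuple[int, ...] = (28, 29, 29, 29, 28)
    microarray_sizes: tuple[int, ...] = (5, 7, 6, 6, 6)
    adherence: float = 1.0
    patterns: dict[int, dict[str, int]] = field(default_factory=default_patterns)
    ddlp_size: int = 10
    n_probes: int = 54675
    n_low_variance: int = 50441
    signature_probes_per_group: int = 3
    signature_shift_sd: float = 3.0  # in units of noise_sd
    noise_sd: float = 0.1
    low_variance_sd: float = 0.01

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 5 or len(self.microarray_sizes) != 5:
            raise ValueError("five group sizes are required")
        if any(s < 1 for s in self.group_sizes + self.microarray_sizes):
            raise ValueError("group sizes must be >= 1")
        if any(m > g for m, g in zip(self.microarray_sizes, self.group_sizes)):
            raise ValueError("microarray subset larger than its group")
        if not 0 <= self.adherence <= 1:
            raise ValueError(f"adherence must be in [0, 1], got {self.adherence}")
        if self.signature_shift_sd <= 0:
            raise ValueError("signature shift must be positive")
        sig_total = 5 * self.signature_probes_per_group
        if self.n_low_variance + sig_total > self.n_probes:
            raise ValueError("low-variance + signature probes exceed the probe count")
        if self.ddlp_size > self.group_sizes[0] + self.group_sizes[1]:
            raise ValueError("ddlp subset larger than groups 1+2")
        for g, pattern in self.patterns.items():
            for attr, code in pattern.items():
                if attr in ("Sex", "Age"):
                    raise ValueError("Sex/Age are derived, not patternable")
                if code not in domain(attr):
                    raise ValueError(
                        f"group {g}: pattern code {attr}={code} outside domain"
                    )


@dataclass(frozen=True)
class GeneSignature:
    probe: str
    direction: int  # +1 over-expressed, -1 under-expressed
    group: int


@dataclass
class ClinicalCohort:
    raw_records: list[RawClinicalRecord]
    coded_records: list[CodedClinicalRecord]
    patterns: dict[int, dict[str, int]]
    pattern_subjects: dict[int, list[str]]  # group -> ids matching the full pattern
    ddlp_ids: list[str]
    microarray_ids: list[str]

    def pattern_itemset(self, group: int) -> frozenset[Item]:
        return frozenset(Item(a, c) for a, c in self.patterns[group].items())


@dataclass
class SyntheticCohort:
    clinical: ClinicalCohort
    expression: ExpressionMatrix
    signatures: list[GeneSignature]

    def signature_itemset(self, group: int) -> frozenset[Item]:
        return frozenset(
            Item(s.probe, s.direction) for s in self.signatures if s.group == group
        )


# ---------------------------------------------------------------------------
# Raw-value sampling inside a cutoff bin
# ---------------------------------------------------------------------------


def _bin_bounds(attr: str, code: int, sex: int, age: float) -> tuple[float, float]:
    spec = attribute_specs()[attr]
    if spec.kind == "interval":
        bins = spec.bins
    elif spec.kind == "stratified_sex":
        (_, bins), = spec.strata["female" if sex == 1 else "male"]
    elif spec.kind == "stratified_sex_age":
        layers = spec.strata["female" if sex == 1 else "male"]
        bins = next(b for hi, b in layers if hi is None or age <= hi)
    else:
        raise ValueError(f"cannot sample raw values for {attr}")
    b = next(b for b in bins if b.code == code)
    lo, hi = b.lo, b.hi
    if spec.sample_range is not None:
        lo, hi = max(lo, spec.sample_range[0]), min(hi, spec.sample_range[1])
    if not lo < hi:
        raise ValueError(f"empty sampling interval for {attr} code {code}")
    return lo, hi


def _sample_in_bin(
    rng: np.random.Generator, attr: str, code: int, sex: int, age: float
) -> float:
    lo, hi = _bin_bounds(attr, code, sex, age)
    eps = (hi - lo) * 1e-3
    # sampling strictly inside the interval sidesteps open/closed endpoints
    return float(rng.uniform(lo + eps, hi - eps))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_clinical(spec: SyntheticSpec, seed: int) -> ClinicalCohort:
    """Draw the clinical cohort: per group, each patterned attribute takes its
    target code with probability ``spec.adherence`` (a uniform background code
    otherwise), unpatterned attributes are uniform over their domain, and raw
    measurements are placed uniformly inside the chosen code's bin."""
    rng = np.random.default_rng(seed)
    raw_records: list[RawClinicalRecord] = []
    sid = 0
    sampleable = [a for a in ATTRIBUTES if a not in ("Sex", "Age")]
    for group, size in enumerate(spec.group_sizes, start=1):
        pattern = spec.patterns.get(group, {})
        for _ in range(size):
            sid += 1
            subject = f"S{sid:03d}"
            sex = int(rng.integers(1, 3))
            age = float(rng.uniform(35, 60))
            values: dict[str, float] = {}
            for attr in sampleable:
                if attr in pattern:
                    # a non-adherent draw avoids the target code, so the
                    # number of matching subjects is exactly binomial in the
                    # adherence probability
                    if rng.random() < spec.adherence:
                        code = pattern[attr]
                    else:
                        codes = sorted(domain(attr) - {pattern[attr]})
                        code = int(codes[rng.integers(len(codes))])
                else:
                    codes = sorted(domain(attr))
                    code = int(codes[rng.integers(len(codes))])
                values[attr] = _sample_in_bin(rng, attr, code, sex, age)
            raw_records.append(RawClinicalRecord(subject, group, sex, age, values))

    # plant the diabetic-dyslipidemia subset inside groups 1-2
    eligible = [r for r in raw_records if r.group in (1, 2)]
    chosen = rng.choice(len(eligible), size=spec.ddlp_size, replace=False)
    ddlp = {eligible[i].subject_id for i in chosen.tolist()}
    for r in eligible:
        if r.subject_id in ddlp:
            r.values["TG"] = float(rng.uniform(205.0, 290.0))
            r.values["HDL"] = float(rng.uniform(21.0, 37.5))
        elif r.values["TG"] >= 204 and r.values["HDL"] < 38:
            r.values["HDL"] = float(rng.uniform(38.1, 39.9))  # still code 1

    coded = [discretize_record(r) for r in raw_records]
    pattern_subjects = {
        g: [
            rec.subject_id
            for rec in coded
            if rec.group == g
            and all(rec.codes.get(a) == c for a, c in spec.patterns.get(g, {}).items())
        ]
        for g in range(1, 6)
    }
    microarray_ids = []
    for g, k in zip(range(1, 6), spec.microarray_sizes):
        microarray_ids += [r.subject_id for r in coded if r.group == g][:k]
    return ClinicalCohort(
        raw_records=raw_records,
        coded_records=coded,
        patterns={g: dict(p) for g, p in spec.patterns.items()},
        pattern_subjects=pattern_subjects,
        ddlp_ids=sorted(ddlp),
        microarray_ids=microarray_ids,
    )


def generate_expression(
    spec: SyntheticSpec,
    seed: int,
    subjects: Optional[Sequence[str]] = None,
    groups: Optional[Sequence[int]] = None,
) -> tuple[ExpressionMatrix, list[GeneSignature]]:
    """Draw the expression matrix for the microarray subset.

    Probe roles are assigned by a seeded permutation: ``n_low_variance``
    probes get a near-flat profile (baseline + tiny jitter, guaranteed range
    below the 0.1 filter), ``5 * signature_probes_per_group`` probes carry a
    group signature, the rest are N(0, noise_sd) background. Signature
    entries in the owning group's subjects are the deterministic offset
    ``direction * signature_shift_sd * noise_sd``.
    """
    if subjects is None:
        total = sum(spec.microarray_sizes)
        subjects = [f"S{i + 1:03d}" for i in range(total)]
        groups = [
            g for g, k in zip(range(1, 6), spec.microarray_sizes) for _ in range(k)
        ]
    if groups is None or len(groups) != len(subjects):
        raise ValueError("subjects and groups must align")
    n_sub = len(subjects)
    rng = np.random.default_rng(seed)
    N = spec.n_probes
    perm = rng.permutation(N)
    nlv = spec.n_low_variance
    per_group = spec.signature_probes_per_group
    lowvar_idx = perm[:nlv]
    sig_idx = perm[nlv : nlv + 5 * per_group]

    values = rng.normal(0.0, spec.noise_sd, size=(N, n_sub))
    baselines = rng.normal(0.0, 1.0, size=nlv)
    values[lowvar_idx] = baselines[:, None] + rng.normal(
        0.0, spec.low_variance_sd, size=(nlv, n_sub)
    )

    probe_ids = [f"syn{i + 1:05d}_at" for i in range(N)]
    col_of_group: dict[int, list[int]] = {g: [] for g in range(1, 6)}
    for c, g in enumerate(groups):
        col_of_group[int(g)].append(c)
    shift = spec.signature_shift_sd * spec.noise_sd
    signatures: list[GeneSignature] = []
    for block, g in enumerate(range(1, 6)):
        for j in range(per_group):
            row = int(sig_idx[block * per_group + j])
            direction = -1 if j % 3 == 1 else 1  # mostly over-expressed
            values[row, col_of_group[g]] = direction * shift
            signatures.append(GeneSignature(probe_ids[row], direction, g))

    df = pd.DataFrame(values, index=probe_ids, columns=list(subjects))
    group_map = {s: int(g) for s, g in zip(subjects, groups)}
    return ExpressionMatrix(df, group_map), signatures


def generate_cohort(spec: SyntheticSpec, seed: int) -> SyntheticCohort:
    """Clinical cohort plus a matched expression matrix for its microarray
    subset. The two stages draw from independent seeded streams (seed and
    seed+1) so either artefact can be regenerated alone."""
    clinical = generate_clinical(spec, seed)
    group_of = {r.subject_id: r.group for r in clinical.coded_records}
    expr, signatures = generate_expression(
        spec,
        seed + 1,
        subjects=clinical.microarray_ids,
        groups=[group_of[s] for s in clinical.microarray_ids],
    )
    return SyntheticCohort(clinical, expr, signatures)


def write_cohort(cohort: SyntheticCohort, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write the cohort in the formats the readers consume; returns paths."""
    from .io import write_clinical_table, write_expression_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical_raw": out / "clinical_raw.csv",
        "clinical_coded": out / "clinical_coded.csv",
        "expression": out / "expression.tsv",
    }
    write_clinical_table(cohort.clinical.raw_records, paths["clinical_raw"])
    write_clinical_table(cohort.clinical.coded_records, paths["clinical_coded"])
    write_expression_matrix(cohort.expression, paths["expression"])
    return paths
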