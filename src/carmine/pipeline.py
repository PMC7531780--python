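"""End-to-end analyses.

Four analyses mirror the study design:

``cf``      strong rules over the 17 routine clinical attributes of all 143
            subjects (min support 14, min confidence 70%), with periodontal
            disease-activity consequents;
``cardio``  the same, with antecedents restricted to the cardiovascular /
            obesity risk attributes (BMI, WHR, AC, FPG, N-HDL-C);
``ddlp``    the same rule machinery on the diabetic-dyslipidemia subset
            (groups 1-2, raw TG >= 204 and HDL < 38), any periodontal
            consequent, lift taken over the subset size;
``cfdeg``   two-phase class-association-rule mining (min support 3, min
            confidence 90%) with the patient group as target: phase 1 over
            gene items alone selects the covered, non-conflicting probes;
            phase 2 mines over those probes' items joined with all 29
            clinical codes.

Every stage logs its counts, making chains like kept/removed probes or
coverage-minus-conflicts auditable. No stage uses randomness, so repeated
runs on identical inputs write byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .clinical import (
    CARDIO_ATTRIBUTES,
    CF17_ATTRIBUTES,
    PERIODONTAL_CF17,
    CodedClinicalRecord,
    RawClinicalRecord,
    discretize_record,
    domain,
    records_to_transactions,
    select_cf_subset,
    select_diabetic_dyslipidemia,
)
from .expression import ExpressionMatrix, range_filter, ternary_discretize, znormalize
from .mining import MiningParams, mine_closed
from .rules import (
    AssociationRule,
    ClassAssociationRule,
    ConsequentConstraint,
    covered_genes,
    find_conflicting_genes,
    generate_rules,
    mine_cars,
)
from .transactions import Item, build_db

logger = logging.getLogger("carmine.pipeline")

# Study defaults: absolute support counts, confidence fractions.
CF_PARAMS = MiningParams(min_sup=14, min_conf=0.70)
CAR_PARAMS = MiningParams(min_sup=3, min_conf=0.90)

# Items marking active periodontal disease: medium/high inflammation codes
# and the deep-pocket code. A clinical rule is interesting only if its
# consequent carries at least one of them.
ACTIVE_PERIODONTAL_ITEMS: frozenset[Item] = frozenset(
    {Item("PPDi6mm", 2)}
    | {
        Item(attr, code)
        for attr in ("GI", "BOP", "CALi3-4mm", "CALi5mm", "SUPP")
        for code in (2, 3)
    }
)


def periodontal_constraint(
    relaxed: bool = False,
    antecedent_attributes: Optional[Sequence[str]] = None,
) -> ConsequentConstraint:
    """Consequents restricted to periodontal attributes; unless ``relaxed``,
    at least one active disease item is required."""
    allowed = frozenset(
        Item(attr, code) for attr in PERIODONTAL_CF17 for code in domain(attr)
    )
    return ConsequentConstraint(
        allowed=allowed,
        required=None if relaxed else ACTIVE_PERIODONTAL_ITEMS,
        mode="at_least_one",
        antecedent_attributes=(
            frozenset(antecedent_attributes) if antecedent_attributes else None
        ),
    )


def _coerce_coded(
    records: Sequence[Union[RawClinicalRecord, CodedClinicalRecord]],
) -> list[CodedClinicalRecord]:
    return [
        r if isinstance(r, CodedClinicalRecord) else discretize_record(r)
        for r in records
    ]


@dataclass
class AnalysisResult:
    rules: list[AssociationRule]
    summary: dict = field(default_factory=dict)


@dataclass
class CfDegResult:
    phase1: list[ClassAssociationRule]
    phase2: list[ClassAssociationRule]
    coverage: set[str]
    conflicts: set[str]
    universe: set[str]
    summary: dict = field(default_factory=dict)


def _rule_stage(
    transactions,
    labels,
    params: MiningParams,
    constraint: ConsequentConstraint,
    stage: str,
) -> AnalysisResult:
    db = build_db(transactions, labels)
    closed = mine_closed(db, params.min_sup)
    rules = generate_rules(closed, db, params, constraint)
    summary = {
        "stage": stage,
        "n_transactions": db.n,
        "n_items": db.m,
        "n_closed": len(closed),
        "n_rules": len(rules),
        "min_sup": params.min_sup,
        "min_conf": params.min_conf,
    }
    logger.info(
        "%s: n=%d, %d items, %d closed sets, %d rules",
        stage, db.n, db.m, len(closed), len(rules),
    )
    return AnalysisResult(rules=rules, summary=summary)


def run_cf_analysis(
    records: Sequence[Union[RawClinicalRecord, CodedClinicalRecord]],
    params: MiningParams = CF_PARAMS,
) -> AnalysisResult:
    """Clinical-features analysis over the 17 routine attributes."""
    coded = _coerce_coded(records)
    transactions, labels = select_cf_subset(coded)
    return _rule_stage(transactions, labels, params, periodontal_constraint(), "cf")


def run_cardio_analysis(
    records: Sequence[Union[RawClinicalRecord, CodedClinicalRecord]],
    params: MiningParams = CF_PARAMS,
) -> AnalysisResult:
    """Cardiovascular/obesity-risk analysis: the item universe is the 5 risk
    attributes plus the 6 periodontal ones, and antecedents may hold risk
    attributes only."""
    coded = _coerce_coded(records)
    transactions, labels = records_to_transactions(
        coded, tuple(CARDIO_ATTRIBUTES) + tuple(PERIODONTAL_CF17)
    )
    constraint = periodontal_constraint(antecedent_attributes=CARDIO_ATTRIBUTES)
    return _rule_stage(transactions, labels, params, constraint, "cardio")


def run_diabetic_dlp_analysis(
    records: Sequence[Union[RawClinicalRecord, CodedClinicalRecord]],
    params: Optional[MiningParams] = None,
    subset_ids: Optional[Sequence[str]] = None,
) -> AnalysisResult:
    """Diabetic-dyslipidemia subset analysis.

    The subset is found from raw TG/HDL values, or — when only coded records
    exist — taken from an explicit ``subset_ids`` list. Lift is computed over
    the subset size; the periodontal-consequent constraint is relaxed to any
    code. When ``params`` is not given, the cohort-level minimum support is
    scaled to the subset (14/143 of its size, at least 1) with the same 70%
    confidence: an absolute count of 14 would be unsatisfiable in a
    ten-subject subset.
    """
    if subset_ids is not None:
        wanted = set(subset_ids)
        subset = [r for r in records if r.subject_id in wanted]
    else:
        subset = select_diabetic_dyslipidemia(list(records))
    if not subset:
        raise ValueError("diabetic-dyslipidemia subset is empty")
    if params is None:
        scaled = max(1, round(CF_PARAMS.min_sup * len(subset) / 143))
        params = MiningParams(scaled, CF_PARAMS.min_conf)
    coded = _coerce_coded(subset)
    transactions, labels = select_cf_subset(coded)
    result = _rule_stage(
        transactions, labels, params, periodontal_constraint(relaxed=True), "ddlp"
    )
    result.summary["subset_ids"] = sorted(r.subject_id for r in subset)
    return result


def run_cfdeg_analysis(
    records: Sequence[Union[RawClinicalRecord, CodedClinicalRecord]],
    expression: ExpressionMatrix,
    params: MiningParams = CAR_PARAMS,
    range_threshold: float = 0.1,
    hi: float = 1.0,
    lo: float = -1.0,
    conflict_key: str = "item",
) -> CfDegResult:
    """Two-phase joint clinical + gene-expression CAR mining.

    Phase 1 mines CARs over the discretised gene items alone; the probes its
    rules cover, minus those conflicting between the control group and the
    disease groups, form the phase-2 gene universe, joined with all 29
    clinical codes.
    """
    if expression.groups is None:
        raise ValueError("expression matrix needs subject group labels")
    coded = {r.subject_id: r for r in _coerce_coded(records)}
    subjects = expression.subjects
    missing = [s for s in subjects if s not in coded]
    if missing:
        raise ValueError(f"no clinical record for subjects {missing[:5]}")
    labels = [expression.group_of(s) for s in subjects]

    kept = range_filter(expression, range_threshold)
    n_total, n_kept = expression.shape[0], kept.shape[0]
    logger.info("range filter: %d probes kept, %d removed", n_kept, n_total - n_kept)

    gene_tx = ternary_discretize(znormalize(kept), hi=hi, lo=lo) if n_kept else [
        set() for _ in subjects
    ]
    phase1_db = build_db(gene_tx, labels)
    phase1 = mine_cars(phase1_db, params)
    coverage = covered_genes(phase1)
    conflicts = find_conflicting_genes(phase1, key=conflict_key)
    universe = coverage - conflicts
    logger.info(
        "phase 1: %d CARs covering %d probes, %d conflicting, %d forwarded",
        len(phase1), len(coverage), len(conflicts), len(universe),
    )

    clinical_tx, _ = records_to_transactions([coded[s] for s in subjects])
    phase2_tx = [
        {i for i in genes if i.attribute in universe} | clin
        for genes, clin in zip(gene_tx, clinical_tx)
    ]
    phase2 = mine_cars(build_db(phase2_tx, labels), params)
    logger.info("phase 2: %d CARs", len(phase2))

    summary = {
        "stage": "cfdeg",
        "n_subjects": len(subjects),
        "probes_total": n_total,
        "probes_kept": n_kept,
        "probes_removed": n_total - n_kept,
        "phase1_cars": len(phase1),
        "coverage": len(coverage),
        "conflicts": len(conflicts),
        "universe": len(universe),
        "phase2_cars": len(phase2),
        "min_sup": params.min_sup,
        "min_conf": params.min_conf,
    }
    return CfDegResult(
        phase1=phase1,
        phase2=phase2,
        coverage=coverage,
        conflicts=conflicts,
        universe=universe,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# File-level orchestration (used by the CLI)
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """File paths and thresholds for one pipeline invocation; defaults
    reproduce the study settings."""

    clinical_path: Optional[str] = None
    clinical_mode: str = "coded"
    expression_path: Optional[str] = None
    out_dir: str = "carmine_out"
    min_sup: Optional[int] = None
    min_conf: Optional[float] = None
    subset_ids: Optional[list[str]] = None
    conflict_key: str = "item"
    range_threshold: float = 0.1
    discretize_hi: float = 1.0
    discretize_lo: float = -1.0
    seed: int = 0

    def params(self, default: MiningParams) -> MiningParams:
        return MiningParams(
            self.min_sup if self.min_sup is not None else default.min_sup,
            self.min_conf if self.min_conf is not None else default.min_conf,
        )


def run_from_config(analysis: str, config: AnalysisConfig) -> dict:
    """Load inputs, run one named analysis, write its tables under
    ``config.out_dir`` and return the summary dict."""
    from .io import read_clinical_table, read_expression_matrix, write_rules

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.clinical_path is None:
        raise ValueError("a clinical table is required")
    records = read_clinical_table(config.clinical_path, mode=config.clinical_mode)

    if analysis in ("cf", "cardio", "ddlp"):
        params = config.params(CF_PARAMS)
        if analysis == "cf":
            result = run_cf_analysis(records, params)
        elif analysis == "cardio":
            result = run_cardio_analysis(records, params)
        else:
            # without an explicit min_sup the subset analysis scales the
            # cohort threshold to the subset size itself
            ddlp_params = params if config.min_sup is not None else None
            result = run_diabetic_dlp_analysis(
                records, ddlp_params, subset_ids=config.subset_ids
            )
        write_rules(result.rules, out / f"{analysis}_rules.tsv")
        return result.summary

    if analysis == "cfdeg":
        if config.expression_path is None:
            raise ValueError("cfdeg needs an expression matrix")
        expression = read_expression_matrix(config.expression_path)
        result = run_cfdeg_analysis(
            records,
            expression,
            params=config.params(CAR_PARAMS),
            range_threshold=config.range_threshold,
            hi=config.discretize_hi,
            lo=config.discretize_lo,
            conflict_key=config.conflict_key,
        )
        write_rules(result.phase1, out / "cfdeg_phase1_cars.tsv")
        write_rules(result.phase2, out / "cfdeg_phase2_cars.tsv")
        (out / "cfdeg_conflicting_probes.txt").write_text(
            "".join(f"{p}\n" for p in sorted(result.conflicts))
        )
        return result.summary

    raise ValueError(f"unknown analysis {analysis!r}")
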