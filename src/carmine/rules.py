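"""Association rules and class association rules over closed itemsets.

Rule metrics, for antecedent J and consequent H over n transactions:

    conf(J => H) = sigma(J u H) / sigma(J)          (predictive accuracy)
    comp(J => H) = sigma(J u H) / sigma(H)          (completeness / recall)
    lift(J => H) = n * sigma(J u H) / (sigma(J) * sigma(H))

Lift is the relative-frequency form — the ratio of the observed co-occurrence
frequency to the frequency expected under independence. Percentages and lifts
are displayed rounded half-up to two decimals; the exact integer counts are
always kept alongside.

Rules are generated only from closed frequent itemsets (each closed set C is
split into antecedent C \\ H and consequent H), but every sigma is recomputed
by direct tidset intersection, so metrics are exact even when a split part is
not itself closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from itertools import chain, combinations
from typing import Callable, Iterable, Optional, Sequence

from .clinical import is_clinical_attribute
from .mining import ClosedItemset, MiningParams, mine_closed
from .transactions import Item, TransactionDB, format_itemset, item_sort_key


def round2(num: int, den: int = 1) -> float:
    """num/den rounded half-up to 2 decimals (matches the published tables,
    e.g. 22/26 -> 84.62 as a percentage)."""
    q = (Decimal(num) / Decimal(den)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(q)


def _check_counts(sigma_rule: int, sigma_head: int, sigma_tail: int, n: int) -> None:
    if min(sigma_rule, sigma_head, sigma_tail, n) < 1:
        raise ValueError(
            f"all counts must be >= 1, got rule={sigma_rule} head={sigma_head} "
            f"tail={sigma_tail} n={n}"
        )
    if sigma_rule > sigma_head or sigma_rule > sigma_tail:
        raise ValueError(
            f"sigma_rule={sigma_rule} exceeds sigma_head={sigma_head} or "
            f"sigma_tail={sigma_tail}"
        )
    if sigma_head > n or sigma_tail > n:
        raise ValueError(
            f"sigma_head={sigma_head}/sigma_tail={sigma_tail} exceed n={n}"
        )


def rule_metrics(
    sigma_rule: int, sigma_head: int, sigma_tail: int, n: int
) -> tuple[float, float, float]:
    """(confidence %, completeness %, lift), rounded half-up to 2 decimals."""
    _check_counts(sigma_rule, sigma_head, sigma_tail, n)
    conf = round2(100 * sigma_rule, sigma_head)
    comp = round2(100 * sigma_rule, sigma_tail)
    lift = round2(n * sigma_rule, sigma_head * sigma_tail)
    return conf, comp, lift


@dataclass(frozen=True)
class AssociationRule:
    """J => H with exact support counts over an n-transaction database."""

    antecedent: frozenset[Item]
    consequent: frozenset[Item]
    sigma_rule: int
    sigma_head: int
    sigma_tail: int
    n: int

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be nonempty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")
        _check_counts(self.sigma_rule, self.sigma_head, self.sigma_tail, self.n)

    @property
    def conf(self) -> Fraction:
        return Fraction(self.sigma_rule, self.sigma_head)

    @property
    def comp(self) -> Fraction:
        return Fraction(self.sigma_rule, self.sigma_tail)

    @property
    def lift(self) -> Fraction:
        return Fraction(self.n * self.sigma_rule, self.sigma_head * self.sigma_tail)

    @property
    def conf_pct(self) -> float:
        return round2(100 * self.sigma_rule, self.sigma_head)

    @property
    def comp_pct(self) -> float:
        return round2(100 * self.sigma_rule, self.sigma_tail)

    @property
    def lift_2dp(self) -> float:
        return round2(self.n * self.sigma_rule, self.sigma_head * self.sigma_tail)

    def consequent_text(self) -> str:
        return format_itemset(self.consequent)

    def __str__(self) -> str:
        return (
            f"{format_itemset(self.antecedent)} => {self.consequent_text()} "
            f"({self.sigma_rule}/{self.sigma_head}/{self.sigma_tail}, "
            f"conf {self.conf_pct}, lift {self.lift_2dp})"
        )


@dataclass(frozen=True)
class ClassAssociationRule(AssociationRule):
    """J => c: the consequent is a single class-label item (patient group)."""

    label: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        for item in self.antecedent:
            if item.attribute == "Group":
                raise ValueError("antecedent contains a class item")

    @classmethod
    def build(
        cls,
        antecedent: frozenset[Item],
        label: int,
        sigma_rule: int,
        sigma_head: int,
        sigma_tail: int,
        n: int,
    ) -> "ClassAssociationRule":
        return cls(
            antecedent=antecedent,
            consequent=frozenset({Item("Group", label)}),
            sigma_rule=sigma_rule,
            sigma_head=sigma_head,
            sigma_tail=sigma_tail,
            n=n,
            label=label,
        )


def _itemset_key(itemset: frozenset[Item]):
    return tuple(sorted(itemset, key=item_sort_key))


@dataclass(frozen=True)
class ConsequentConstraint:
    """Which consequents make a rule interesting.

    ``allowed``: the only items permitted in a consequent. ``required``: items
    of which (mode "at_least_one") at least one, or (mode "all") every one,
    must be present; ``required=None`` imposes nothing beyond ``allowed``.
    ``antecedent_attributes``, when set, restricts antecedents to those
    attribute names (used by the cardiovascular-risk analysis).
    """

    allowed: frozenset[Item]
    required: Optional[frozenset[Item]] = None
    mode: str = "at_least_one"
    antecedent_attributes: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if not self.allowed:
            raise ValueError("constraint needs a nonempty allowed-item set")
        if self.mode not in ("at_least_one", "all"):
            raise ValueError(f"unknown requirement mode {self.mode!r}")

    def consequent_ok(self, consequent: frozenset[Item]) -> bool:
        if not consequent <= self.allowed:
            return False
        if self.required is None:
            return True
        if self.mode == "at_least_one":
            return bool(consequent & self.required)
        return self.required <= consequent

    def antecedent_ok(self, antecedent: frozenset[Item]) -> bool:
        if self.antecedent_attributes is None:
            return True
        return all(i.attribute in self.antecedent_attributes for i in antecedent)


def _nonempty_subsets(items: Sequence[Item]) -> Iterable[tuple[Item, ...]]:
    return chain.from_iterable(
        combinations(items, k) for k in range(1, len(items) + 1)
    )


def generate_rules(
    closed_sets: Sequence[ClosedItemset],
    db: TransactionDB,
    params: MiningParams,
    constraint: ConsequentConstraint,
) -> list[AssociationRule]:
    """Strong rules from the closed frequent itemsets.

    Every closed set C is split into J => H for each nonempty H subset of C
    that satisfies the constraint, with J = C \\ H nonempty; supports come
    from exact tidset intersections, duplicates (same J, H) are emitted once,
    and rules below ``params.min_conf`` are dropped. Output order: confidence
    desc, rule support desc, canonical antecedent then consequent order.
    """
    min_conf = Fraction(params.min_conf).limit_denominator(10**6)
    seen: set[tuple] = set()
    out: list[AssociationRule] = []
    for cs in closed_sets:
        candidates = sorted(cs.itemset & constraint.allowed, key=item_sort_key)
        if not candidates:
            continue
        for combo in _nonempty_subsets(candidates):
            consequent = frozenset(combo)
            if not constraint.consequent_ok(consequent):
                continue
            antecedent = cs.itemset - consequent
            if not antecedent or not constraint.antecedent_ok(antecedent):
                continue
            key = (_itemset_key(antecedent), _itemset_key(consequent))
            if key in seen:
                continue
            seen.add(key)
            sigma_rule = db.support(cs.itemset)
            sigma_head = db.support(antecedent)
            sigma_tail = db.support(consequent)
            if Fraction(sigma_rule, sigma_head) >= min_conf:
                out.append(
                    AssociationRule(
                        antecedent, consequent, sigma_rule, sigma_head, sigma_tail, db.n
                    )
                )
    out.sort(
        key=lambda r: (
            -r.conf,
            -r.sigma_rule,
            _itemset_key(r.antecedent),
            _itemset_key(r.consequent),
        )
    )
    return out


def mine_cars(
    db: TransactionDB,
    params: MiningParams,
) -> list[ClassAssociationRule]:
    """Class association rules J => c for every class label in ``db``.

    For each class c, closed itemsets are mined within the class's
    transactions at ``min_sup`` (so the within-class support is
    sigma(J u {c})), while the antecedent support sigma(J) is counted over
    ALL transactions; the rule is kept iff conf >= min_conf. Completeness is
    taken against the class size and lift against the full n.
    """
    if db.labels is None:
        raise ValueError("class association rules need a labeled database")
    min_conf = Fraction(params.min_conf).limit_denominator(10**6)
    out: list[ClassAssociationRule] = []
    for label in sorted(set(db.labels)):
        tids = db.class_transactions(label)
        if len(tids) < params.min_sup:
            warnings.warn(
                f"class {label} has {len(tids)} transactions < min_sup="
                f"{params.min_sup}; no rules for it"
            )
            continue
        sub = db.restrict_transactions(tids)
        for cs in mine_closed(sub, params.min_sup):
            if not cs.itemset:
                continue
            sigma_rule = cs.support
            sigma_head = db.support(cs.itemset)
            if Fraction(sigma_rule, sigma_head) < min_conf:
                continue
            out.append(
                ClassAssociationRule.build(
                    cs.itemset, label, sigma_rule, sigma_head, len(tids), db.n
                )
            )
    out.sort(
        key=lambda r: (r.label, -r.conf, -r.sigma_rule, _itemset_key(r.antecedent))
    )
    return out


# ---------------------------------------------------------------------------
# Gene bookkeeping over CARs
# ---------------------------------------------------------------------------


def is_gene_item(item: Item) -> bool:
    """Gene items carry a probe id as attribute and a signed unit value."""
    return item.value in (1, -1) and not is_clinical_attribute(item.attribute) and (
        item.attribute != "Group"
    )


def covered_genes(cars: Iterable[ClassAssociationRule]) -> set[str]:
    """Distinct probes occurring in any rule antecedent."""
    return {
        item.attribute
        for rule in cars
        for item in rule.antecedent
        if is_gene_item(item)
    }


def find_conflicting_genes(
    cars: Iterable[ClassAssociationRule],
    control_label: int = 5,
    key: str = "item",
) -> set[str]:
    """Probes that characterise both the control group and a disease group.

    With ``key="item"`` (default) the match is at the (probe, direction)
    level: the same signed item must appear in at least one control-group
    rule and one non-control rule. ``key="gene"`` relaxes the match to the
    probe regardless of direction. Conflicting probes are meant to be removed
    entirely (both directions) from downstream universes.
    """
    if key not in ("item", "gene"):
        raise ValueError(f"key must be 'item' or 'gene', got {key!r}")
    control: set = set()
    cases: set = set()
    for rule in cars:
        bucket = control if rule.label == control_label else cases
        for item in rule.antecedent:
            if is_gene_item(item):
                bucket.add(item if key == "item" else item.attribute)
    both = control & cases
    if key == "item":
        return {item.attribute for item in both}
    return set(both)


# ---------------------------------------------------------------------------
# Expert ranking heuristic
# ---------------------------------------------------------------------------

# Category codes regarded as clinically altered, per attribute; used by the
# "altered" ranking key. Worst glycemic/lipid/anthropometric codes and the
# disease-activity periodontal codes.
DEFAULT_ALTERED_CODES: dict[str, frozenset[int]] = {
    "BMI": frozenset({4, 5}),
    "WHR": frozenset({4}),
    "AC": frozenset({3}),
    "FPG": frozenset({3}),
    "INS": frozenset({2}),
    "HbA1c": frozenset({3, 4}),
    "HOMA-IR": frozenset({2}),
    "TC": frozenset({3, 4}),
    "HDL": frozenset({1}),
    "LDL": frozenset({4, 5}),
    "TG": frozenset({3}),
    "N-HDL-C": frozenset({4, 5}),
    "VP": frozenset({2, 3}),
    "GI": frozenset({2, 3}),
    "BOP": frozenset({2, 3}),
    "TNT": frozenset({1}),
    "PPDi3mm": frozenset({2, 3}),
    "PPDi4-5mm": frozenset({2, 3}),
    "PPDi6mm": frozenset({2}),
    "CALi2mm": frozenset({2, 3}),
    "CALi3-4mm": frozenset({2, 3}),
    "CALi5mm": frozenset({2, 3}),
    "SUPP": frozenset({2, 3}),
    "NDI": frozenset({2, 3}),
    "MNCF": frozenset({2, 3}),
    "MNF": frozenset({2, 3}),
    "FNB": frozenset({2, 3}),
}

# Ranking profiles mirroring the expert selection criteria: clinical-feature
# rules are ranked by the joint presence of altered cardiovascular/glycemic/
# lipid values then confidence; joint clinical+gene rules additionally prefer
# an over-expressed probe and break remaining ties by completeness.
CF_RANKING_PROFILE: tuple[str, ...] = ("altered", "conf")
CFDEG_RANKING_PROFILE: tuple[str, ...] = ("altered", "over_gene", "conf", "comp")


def rank_rules(
    rules: Sequence[AssociationRule],
    profile: Sequence[str],
    altered_codes: Optional[dict[str, frozenset[int]]] = None,
) -> list[AssociationRule]:
    """Stable lexicographic sort over the profile's scoring keys, all
    descending. Known keys: ``altered`` (count of antecedent items whose code
    is configured as altered), ``over_gene`` (an over-expressed probe is
    present), ``conf``, ``comp``."""
    codes = DEFAULT_ALTERED_CODES if altered_codes is None else altered_codes

    def altered(rule: AssociationRule):
        return sum(
            1
            for item in rule.antecedent
            if not is_gene_item(item) and item.value in codes.get(item.attribute, ())
        )

    keyfuncs: dict[str, Callable[[AssociationRule], object]] = {
        "altered": altered,
        "over_gene": lambda r: int(
            any(is_gene_item(i) and i.value == 1 for i in r.antecedent)
        ),
        "conf": lambda r: r.conf,
        "comp": lambda r: r.comp,
    }
    for key in profile:
        if key not in keyfuncs:
            raise ValueError(f"unknown ranking key {key!r}")
    funcs = [keyfuncs[k] for k in profile]
    return sorted(rules, key=lambda r: tuple(-f(r) for f in funcs))
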