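"""Rule metrics, generation, class rules, conflicts and ranking."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carmine.mining import MiningParams, brute_force_closed, mine_closed
from carmine.rules import (
    AssociationRule,
    ClassAssociationRule,
    ConsequentConstraint,
    covered_genes,
    find_conflicting_genes,
    generate_rules,
    mine_cars,
    rank_rules,
    rule_metrics,
    round2,
)
from carmine.transactions import Item, build_db

from conftest import random_db


class TestRuleMetrics:
    @pytest.mark.parametrize(
        "counts, conf, lift",
        [
            ((14, 14, 74, 143), 100.00, 1.93),
            ((22, 26, 74, 143), 84.62, 1.64),
            ((5, 5, 5, 10), 100.00, 2.00),
            ((6, 6, 6, 10), 100.00, 1.67),
            ((4, 4, 5, 30), 100.00, 6.00),
        ],
    )
    def test_published_style_metric_values(self, counts, conf, lift):
        got_conf, _, got_lift = rule_metrics(*counts)
        assert (got_conf, got_lift) == (conf, lift)

    def test_completeness_derived_from_consequent_support(self):
        assert rule_metrics(14, 14, 74, 143)[1] == 18.92  # 14/74

    @pytest.mark.parametrize(
        "counts",
        [(15, 14, 74, 143), (15, 74, 14, 143), (5, 5, 150, 143), (0, 1, 1, 3)],
    )
    def test_count_ordering_violations_rejected(self, counts):
        with pytest.raises(ValueError):
            rule_metrics(*counts)

    def test_rounding_is_half_up(self):
        assert round2(1005, 1000) == 1.01
        assert round2(100 * 22, 26) == 84.62
        assert round2(143 * 14, 14 * 74) == 1.93


def _items(*names):
    return frozenset(Item(n, 1) for n in names)


class TestRuleInvariants:
    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        sr=st.integers(1, 30), dh=st.integers(0, 30), dt=st.integers(0, 30),
        extra=st.integers(0, 40),
    )
    def test_lift_at_least_conf_with_equality_iff_tail_is_n(
        self, sr, dh, dt, extra
    ):
        sh, tl = sr + dh, sr + dt
        n = max(sh, tl) + extra
        rule = AssociationRule(_items("x"), _items("y"), sr, sh, tl, n)
        assert rule.lift >= rule.conf
        assert (rule.lift == rule.conf) == (tl == n)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(sr=st.integers(1, 20), dh=st.integers(0, 20), dt=st.integers(0, 20))
    def test_conf_and_comp_swap_when_rule_is_reversed(self, sr, dh, dt):
        sh, tl = sr + dh, sr + dt
        n = sh + tl
        fwd = AssociationRule(_items("x"), _items("y"), sr, sh, tl, n)
        rev = AssociationRule(_items("y"), _items("x"), sr, tl, sh, n)
        assert fwd.conf == rev.comp and fwd.comp == rev.conf
        assert fwd.lift == rev.lift

    def test_disjointness_and_nonemptiness_enforced(self):
        with pytest.raises(ValueError):
            AssociationRule(_items("x"), _items("x"), 1, 1, 1, 2)
        with pytest.raises(ValueError):
            AssociationRule(frozenset(), _items("x"), 1, 1, 1, 2)


def _toy_perio_db():
    """Seven subjects; x=1 and BOP=3 co-occur in five of them."""
    x, bop = Item("x", 1), Item("BOP", 3)
    rows = [{x, bop}] * 5 + [{bop}] * 2
    return build_db(rows), x, bop


def _bop_constraint():
    return ConsequentConstraint(
        allowed=frozenset({Item("BOP", c) for c in (1, 2, 3)}),
        required=frozenset({Item("BOP", 2), Item("BOP", 3)}),
    )


class TestGenerateRules:
    def test_hand_counted_toy_rule(self):
        db, x, bop = _toy_perio_db()
        params = MiningParams(2, 0.7)
        rules = generate_rules(mine_closed(db, 2), db, params, _bop_constraint())
        assert len(rules) == 1
        (r,) = rules
        assert r.antecedent == {x} and r.consequent == {bop}
        assert (r.sigma_rule, r.sigma_head, r.sigma_tail) == (5, 5, 7)
        assert r.conf_pct == 100.00

    def test_closed_set_without_constraint_item_yields_nothing(self):
        db = build_db([{Item("x", 1), Item("y", 1)}] * 4)
        rules = generate_rules(
            mine_closed(db, 2), db, MiningParams(2, 0.5), _bop_constraint()
        )
        assert rules == []

    def test_min_conf_above_one_yields_nothing(self):
        db, *_ = _toy_perio_db()
        rules = generate_rules(
            mine_closed(db, 2), db, MiningParams(2, 1.01), _bop_constraint()
        )
        assert rules == []

    def test_antecedent_attribute_restriction(self):
        x, z, bop = Item("x", 1), Item("z", 1), Item("BOP", 3)
        db = build_db([{x, z, bop}] * 5 + [{bop}])
        constraint = ConsequentConstraint(
            allowed=frozenset({bop}),
            required=frozenset({bop}),
            antecedent_attributes=frozenset({"x"}),
        )
        rules = generate_rules(mine_closed(db, 2), db, MiningParams(2, 0.5), constraint)
        assert all(i.attribute == "x" for r in rules for i in r.antecedent)

    def test_matches_independent_split_enumerator_on_random_dbs(self):
        """Splits of brute-force closed sets with independently recomputed
        supports coincide with generate_rules."""
        from itertools import chain, combinations

        rng = np.random.default_rng(77)
        for _ in range(40):
            db = random_db(rng, int(rng.integers(2, 8)), int(rng.integers(2, 6)))
            params = MiningParams(
                int(rng.integers(1, db.n + 1)), float(rng.uniform(0.3, 1.0))
            )
            allowed = frozenset(
                it for it in db.items if int(it.attribute[1:]) % 2 == 0
            )
            if not allowed:
                continue
            constraint = ConsequentConstraint(allowed=allowed, required=allowed)
            got = {
                (r.antecedent, r.consequent, r.sigma_rule, r.sigma_head, r.sigma_tail)
                for r in generate_rules(
                    mine_closed(db, params.min_sup), db, params, constraint
                )
            }
            want = set()
            for cs in brute_force_closed(db, params.min_sup):
                items = sorted(cs.itemset & allowed)
                for k in range(1, len(items) + 1):
                    for combo in combinations(items, k):
                        h = frozenset(combo)
                        j = cs.itemset - h
                        if not j:
                            continue
                        sr, sh, st_ = (
                            db.support(cs.itemset), db.support(j), db.support(h)
                        )
                        if Fraction(sr, sh) >= Fraction(params.min_conf).limit_denominator(10**6):
                            want.add((j, h, sr, sh, st_))
            assert got == want

    def test_emitted_metrics_recompute_from_tidsets(self):
        db, *_ = _toy_perio_db()
        for r in generate_rules(
            mine_closed(db, 1), db, MiningParams(1, 0.1), _bop_constraint()
        ):
            union = r.antecedent | r.consequent
            assert r.sigma_rule == db.support(union)
            assert r.sigma_head == db.support(r.antecedent)
            assert r.sigma_tail == db.support(r.consequent)

    def test_output_sorted_by_conf_then_support(self):
        db, *_ = _toy_perio_db()
        rules = generate_rules(
            mine_closed(db, 1), db, MiningParams(1, 0.1), _bop_constraint()
        )
        keys = [(-r.conf, -r.sigma_rule) for r in rules]
        assert keys == sorted(keys)


class TestMineCars:
    def _labeled_db(self):
        sig = {Item("g1", 1), Item("g2", -1)}
        rows = [sig | {Item(f"n{i}", 1)} for i in range(4)]  # 4 of 5 in group 1
        rows.append({Item("n9", 1)})
        rows += [{Item("m", 1)} for _ in range(5)]           # group 2 background
        labels = [1] * 5 + [2] * 5
        return build_db(rows, labels), frozenset(sig)

    def test_planted_signature_found_with_conf_100_comp_80(self):
        db, sig = self._labeled_db()
        cars = mine_cars(db, MiningParams(3, 0.9))
        hit = [r for r in cars if r.label == 1 and sig <= r.antecedent]
        assert hit and all(r.conf == 1 for r in hit)
        assert any(r.comp == Fraction(4, 5) for r in hit)
        assert all(r.lift_2dp == 2.00 for r in hit)  # 10*4/(4*5)

    def test_antecedent_support_counts_all_transactions(self):
        """A pattern seen 3x in its class and once elsewhere fails 90%."""
        shared = {Item("s", 1)}
        rows = [set(shared) for _ in range(3)] + [{Item("q", 1)}, {Item("q", 1)}]
        rows += [set(shared) | {Item("q", 1)}] + [{Item("q", 1)}] * 4
        db = build_db(rows, [1] * 5 + [2] * 5)
        cars = mine_cars(db, MiningParams(3, 0.9))
        assert not any(r.antecedent == frozenset(shared) for r in cars)

    def test_small_class_warns_and_yields_no_rules(self):
        db = build_db([{Item("a", 1)}] * 5 + [{Item("a", 1)}], [1] * 5 + [2])
        with pytest.warns(UserWarning, match="class 2"):
            cars = mine_cars(db, MiningParams(3, 0.9))
        assert not any(r.label == 2 for r in cars)

    def test_unlabeled_db_rejected(self, toy_db):
        with pytest.raises(ValueError, match="label"):
            mine_cars(toy_db, MiningParams(1, 0.9))


class TestGeneBookkeeping:
    def _car(self, label, *gene_items):
        ante = frozenset(gene_items) | {Item("FPG", 3)}
        return ClassAssociationRule.build(ante, label, 3, 3, 5, 30)

    def test_covered_counts_each_probe_once(self):
        cars = [
            self._car(1, Item("p1", 1), Item("p2", -1)),
            self._car(2, Item("p1", 1)),
        ]
        assert covered_genes(cars) == {"p1", "p2"}
        assert covered_genes([]) == set()

    def test_conflict_requires_same_signed_value(self):
        cars = [self._car(5, Item("p", 1)), self._car(2, Item("p", 1))]
        assert find_conflicting_genes(cars) == {"p"}
        flipped = [self._car(5, Item("p", 1)), self._car(3, Item("p", -1))]
        assert find_conflicting_genes(flipped) == set()
        # at the gene level the direction no longer matters
        assert find_conflicting_genes(flipped, key="gene") == {"p"}

    def test_no_control_rules_no_conflicts(self):
        cars = [self._car(1, Item("p", 1)), self._car(2, Item("p", 1))]
        assert find_conflicting_genes(cars) == set()

    def test_clinical_codes_are_not_genes(self):
        cars = [self._car(5), self._car(1)]  # FPG=3 in both
        assert find_conflicting_genes(cars) == set()
        assert covered_genes(cars) == set()


class TestRankRules:
    def _rule(self, ante, sr, sh, tl=10, n=20):
        return AssociationRule(frozenset(ante), frozenset({Item("BOP", 3)}), sr, sh, tl, n)

    def test_confidence_breaks_equal_altered_count(self):
        hi = self._rule({Item("FPG", 3)}, 10, 10)
        lo = self._rule({Item("TG", 3)}, 9, 10)
        assert rank_rules([lo, hi], ("altered", "conf")) == [hi, lo]

    def test_over_expressed_gene_preferred(self):
        over = self._rule({Item("FPG", 3), Item("p1", 1)}, 9, 10)
        under = self._rule({Item("FPG", 3), Item("p2", -1)}, 9, 10)
        ranked = rank_rules([under, over], ("altered", "over_gene", "conf", "comp"))
        assert ranked[0] is over

    def test_altered_count_dominates(self):
        many = self._rule({Item("FPG", 3), Item("TG", 3), Item("HbA1c", 4)}, 7, 10)
        few = self._rule({Item("FPG", 1)}, 10, 10)
        assert rank_rules([few, many], ("altered", "conf"))[0] is many

    def test_empty_list_and_unknown_key(self):
        assert rank_rules([], ("conf",)) == []
        with pytest.raises(ValueError, match="unknown ranking key"):
            rank_rules([], ("confidence?",))
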