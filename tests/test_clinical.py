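"""Clinical cutoff tables: published boundary cases, partition properties."""

import math

import pytest

from carmine.clinical import (
    ATTRIBUTES,
    CF17_ATTRIBUTES,
    CodedClinicalRecord,
    RawClinicalRecord,
    attribute_specs,
    discretize_ac,
    discretize_attribute,
    discretize_record,
    discretize_whr,
    domain,
    records_to_transactions,
    select_cf_subset,
    select_diabetic_dyslipidemia,
)


@pytest.mark.parametrize(
    "attr, value, code",
    [
        ("FPG", 126, 3),      # established diabetes starts at 126 inclusive
        ("FPG", 125.9, 2),
        ("FPG", 99.9, 1),
        ("HbA1c", 5.7, 2),    # prediabetes band [5.7, 6.5)
        ("HbA1c", 6.5, 3),
        ("HbA1c", 8.0, 4),
        ("HDL", 40, 2),       # middle band closed on both ends [40, 60]
        ("HDL", 60, 2),
        ("HDL", 39.9, 1),
        ("HDL", 60.1, 3),
        ("BMI", 35, 5),
        ("BMI", 18.5, 2),
        ("TC", 240, 4),
        ("TG", 200, 3),
        ("N-HDL-C", 220, 5),
        ("INS", 25, 1),       # normal band is <= 25
        ("INS", 25.1, 2),
        ("HOMA-IR", 2.15, 1),
        ("SUPP", 1, 2),       # moderate suppuration [1, 16)
        ("SUPP", 0.9, 1),
        ("SUPP", 16, 3),
        ("BOP", 50, 2),       # medium band closed at 50
        ("BOP", 50.1, 3),
        ("PPDi6mm", 30, 2),   # two-bin attribute: medium-and-high >= 30
        ("PPDi6mm", 29.9, 1),
        ("TNT", 20, 1),
        ("TNT", 21, 2),
        ("NDI", 1.87, 2),
        ("MNCF", 7.2, 3),
        ("MNF", 3.5, 2),
        ("FNB", 2.7, 3),
        ("Age", 50, 1),
        ("Age", 50.5, 2),
    ],
)
def test_fixed_cutoff_codes(attr, value, code):
    assert discretize_attribute(attr, value) == code


def test_alias_header_accepted():
    assert discretize_attribute("CALi34mm", 55) == 3
    assert discretize_attribute("NHDLC", 100) == 1


def test_negative_measurement_rejected():
    with pytest.raises(ValueError, match="negative"):
        discretize_attribute("FPG", -1)


@pytest.mark.parametrize(
    "whr, sex, age, code",
    [
        (0.85, "female", 45, 3),   # female, (39, 49]: high band [0.80, 0.87]
        (0.87, "female", 45, 3),
        (0.871, "female", 45, 4),
        (1.05, "male", 55, 4),     # male over 49: very high above 1.02
        (1.02, "male", 55, 3),
        (0.72, "female", 30, 2),   # female up to 39: moderate [0.72, 0.79)
        (0.85, 1, 39, 4),          # stratum switch at age 39:
        (0.85, 1, 40, 3),          # same ratio, one stratum later
        (0.90, 2, 50, 2),          # male over 49: moderate starts at 0.90
    ],
)
def test_whr_stratified_codes(whr, sex, age, code):
    assert discretize_whr(whr, sex, age) == code


@pytest.mark.parametrize(
    "ac, sex, code",
    [(90, "female", 3), (95, "male", 2), (79.9, "female", 1), (88, 1, 3),
     (102, 2, 3), (101.9, "male", 2)],
)
def test_ac_codes(ac, sex, code):
    assert discretize_ac(ac, sex) == code


def _interval_attributes():
    return [
        (name, spec) for name, spec in attribute_specs().items()
        if spec.kind == "interval"
    ]


def test_bins_partition_the_line():
    """Every interval attribute's bins cover the half-line with no overlap:
    a fine grid plus all cutpoints each land in exactly one bin."""
    for name, spec in _interval_attributes():
        cuts = sorted(
            {b.lo for b in spec.bins if math.isfinite(b.lo)}
            | {b.hi for b in spec.bins if math.isfinite(b.hi)}
        )
        lo = min(cuts) - 10
        hi = max(cuts) + 10
        grid = [lo + (hi - lo) * k / 400 for k in range(401)]
        for v in grid + cuts + [c + 1e-9 for c in cuts] + [c - 1e-9 for c in cuts]:
            if v < 0:
                continue
            hits = [b.code for b in spec.bins if b.contains(v)]
            assert len(hits) == 1, f"{name}: value {v} in bins {hits}"


def test_stratified_bins_partition_the_line():
    for sex in ("female", "male"):
        for age in (30, 39, 40, 49, 50, 70):
            for v in [0.5 + k / 500 for k in range(500)]:
                hits = [discretize_whr(v, sex, age)]
                assert len(hits) == 1
        for v in [60 + k / 5 for k in range(400)]:
            assert discretize_ac(v, sex) in domain("AC")


def test_cutpoints_map_to_exactly_one_code_idempotently():
    for name, spec in _interval_attributes():
        for b in spec.bins:
            for cut in (b.lo, b.hi):
                if math.isfinite(cut) and cut >= 0:
                    assert discretize_attribute(name, cut) == discretize_attribute(
                        name, cut
                    )


def _raw_record(**overrides):
    values = {
        "BMI": 27, "WHR": 0.9, "AC": 90, "FPG": 130, "INS": 20, "HbA1c": 8.5,
        "HOMA-IR": 3, "TC": 250, "HDL": 35, "LDL": 150, "TG": 220,
        "N-HDL-C": 230, "VP": 40, "GI": 55, "BOP": 60, "TNT": 22,
        "PPDi3mm": 20, "PPDi4-5mm": 25, "PPDi6mm": 10, "CALi2mm": 20,
        "CALi3-4mm": 35, "CALi5mm": 20, "SUPP": 5, "NDI": 2.0, "MNCF": 5,
        "MNF": 4, "FNB": 1.5,
    }
    values.update(overrides.pop("values", {}))
    kw = dict(subject_id="S001", group=1, sex=1, age=45)
    kw.update(overrides)
    return RawClinicalRecord(values=values, **kw)


class TestRecords:
    def test_discretize_record_covers_all_attributes(self):
        coded = discretize_record(_raw_record())
        assert set(coded.codes) == set(ATTRIBUTES)
        assert coded.codes["FPG"] == 3 and coded.codes["HbA1c"] == 4
        assert coded.codes["Sex"] == 1 and coded.codes["Age"] == 1

    def test_cf_subset_has_17_items_per_subject(self):
        coded = [discretize_record(_raw_record(subject_id=f"S{i}")) for i in range(3)]
        transactions, labels = select_cf_subset(coded)
        assert all(len(t) == 17 for t in transactions)
        assert labels == [1, 1, 1]
        attrs = {i.attribute for t in transactions for i in t}
        assert attrs == set(CF17_ATTRIBUTES)
        # mutagenesis attributes stay out of the diagnostic subset
        assert attrs.isdisjoint({"NDI", "MNCF", "MNF", "FNB"})

    def test_missing_value_drops_item_with_warning(self):
        coded = discretize_record(_raw_record())
        del coded.codes["GI"]
        with pytest.warns(UserWarning, match="missing value for GI"):
            transactions, _ = records_to_transactions([coded], CF17_ATTRIBUTES)
        assert len(transactions[0]) == 16


class TestDiabeticDyslipidemia:
    def test_boundary_subject_included(self):
        rec = _raw_record(group=2, values={"TG": 204, "HDL": 37.9})
        assert select_diabetic_dyslipidemia([rec]) == [rec]

    def test_group_filter_excludes_other_groups(self):
        rec = _raw_record(group=3, values={"TG": 300, "HDL": 30})
        assert select_diabetic_dyslipidemia([rec]) == []

    def test_threshold_misses_excluded(self):
        assert select_diabetic_dyslipidemia(
            [_raw_record(values={"TG": 203.9, "HDL": 30})]
        ) == []
        assert select_diabetic_dyslipidemia(
            [_raw_record(values={"TG": 250, "HDL": 38})]
        ) == []

    def test_coded_records_rejected_with_explanation(self):
        coded = CodedClinicalRecord("S001", 1, {"TG": 3, "HDL": 1})
        with pytest.raises(TypeError, match="raw TG/HDL"):
            select_diabetic_dyslipidemia([coded])
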