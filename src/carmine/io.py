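"""Readers and writers: clinical CSV, expression matrix, rule tables.

The clinical table is a comma-separated file with one row per subject, a
``subject`` and ``group`` column, and one column per attribute using the
published aliases ("FPG", "HbA1c", ...); a ``column_map`` renames nonstandard
headers. It may hold either already-coded categories (``mode="coded"``) or
raw measurements (``mode="raw"``; requires Sex and Age columns).

The expression matrix is tab-delimited, probes x subjects, with probe ids in
the first column; an optional first data row named ``group`` carries the
subject -> group mapping (otherwise supply ``groups=``).
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .clinical import (
    ATTRIBUTES,
    CodedClinicalRecord,
    RawClinicalRecord,
    canonical_attribute,
    validate_code,
)
from .expression import ExpressionMatrix
from .rules import AssociationRule, ClassAssociationRule
from .transactions import format_itemset, parse_item

_ID_COLUMNS = ("subject", "subject_id", "id")
_GROUP_COLUMNS = ("group", "Group")

RecordList = Union[list[RawClinicalRecord], list[CodedClinicalRecord]]


def _find_column(df: pd.DataFrame, names: Sequence[str], what: str) -> str:
    for name in names:
        if name in df.columns:
            return name
    raise ValueError(f"clinical table lacks a {what} column (looked for {names})")


def read_clinical_table(
    path: Union[str, Path],
    mode: str = "coded",
    column_map: Optional[dict[str, str]] = None,
) -> RecordList:
    """Read subject records from the clinical CSV.

    ``mode="coded"``: attribute cells are category codes, validated against
    each attribute's domain (a code outside its printed domain raises, naming
    subject, attribute and value). ``mode="raw"``: cells are measurements,
    returned as :class:`RawClinicalRecord` for later discretisation. Empty
    cells mean a missing value and simply produce no entry.
    """
    if mode not in ("coded", "raw"):
        raise ValueError(f"mode must be 'coded' or 'raw', got {mode!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty clinical table: {path}") from None
    if df.empty:
        raise ValueError(f"empty clinical table: {path}")
    if column_map:
        df = df.rename(columns=column_map)
    id_col = _find_column(df, _ID_COLUMNS, "subject id")
    group_col = _find_column(df, _GROUP_COLUMNS, "group")
    attr_cols: dict[str, str] = {}
    for col in df.columns:
        if col in (id_col, group_col):
            continue
        try:
            attr_cols[col] = canonical_attribute(col)
        except KeyError:
            raise ValueError(f"unrecognised clinical column {col!r}") from None

    records: RecordList = []
    for _, row in df.iterrows():
        sid = str(row[id_col])
        group = int(row[group_col])
        if group not in (1, 2, 3, 4, 5):
            raise ValueError(f"subject {sid}: group {group} outside 1..5")
        cells = {
            canon: row[col]
            for col, canon in attr_cols.items()
            if not (isinstance(row[col], float) and math.isnan(row[col]))
        }
        if mode == "coded":
            codes = {
                name: validate_code(sid, name, int(v)) for name, v in cells.items()
            }
            records.append(CodedClinicalRecord(sid, group, codes))
        else:
            if "Sex" not in cells or "Age" not in cells:
                raise ValueError(
                    f"subject {sid}: raw mode needs Sex and Age columns"
                )
            sex = int(cells.pop("Sex"))
            age = float(cells.pop("Age"))
            values = {name: float(v) for name, v in cells.items()}
            records.append(RawClinicalRecord(sid, group, sex, age, values))
    return records


def write_clinical_table(records: RecordList, path: Union[str, Path]) -> None:
    """Write records back to CSV (raw or coded, depending on record type)."""
    path = Path(path)
    raw = isinstance(records[0], RawClinicalRecord)
    attrs = [a for a in ATTRIBUTES if not (raw and a in ("Sex", "Age"))]
    header = ["subject", "group"] + (["Sex", "Age"] if raw else []) + attrs
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for rec in records:
            row: list = [rec.subject_id, rec.group]
            if raw:
                row += [rec.sex, f"{rec.age:.2f}"]
                row += [
                    f"{rec.values[a]:.4f}" if a in rec.values else ""
                    for a in attrs
                ]
            else:
                row += [rec.codes.get(a, "") for a in attrs]
            w.writerow(row)


def read_expression_matrix(
    path: Union[str, Path],
    groups: Optional[dict[str, int]] = None,
) -> ExpressionMatrix:
    """Read the tab-delimited probeset x subject matrix.

    Probe identifiers are preserved verbatim. Errors: a non-numeric cell
    (located by probe and subject), a duplicated probe id, a missing cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ValueError(f"empty expression matrix: {path}")
    if groups is None and str(df.index[0]).lower() == "group":
        groups = {s: int(v) for s, v in df.iloc[0].items()}
        df = df.iloc[1:]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise ValueError(
            f"non-numeric cell {df.loc[r, c]!r} at probe {r!r}, subject {c!r}"
        )
    return ExpressionMatrix(numeric.astype(float), groups)


def write_expression_matrix(matrix: ExpressionMatrix, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("probe\t" + "\t".join(matrix.subjects) + "\n")
        if matrix.groups is not None:
            fh.write(
                "group\t" + "\t".join(str(matrix.groups[s]) for s in matrix.subjects) + "\n"
            )
        for probe, row in zip(matrix.probes, matrix.values.to_numpy()):
            fh.write(probe + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Rule tables
# ---------------------------------------------------------------------------

_RULE_HEADER = [
    "antecedent", "consequent", "sigma_rule", "sigma_head", "sigma_tail",
    "conf_pct", "comp_pct", "lift",
]


def write_rules(
    rules: Sequence[AssociationRule],
    path: Union[str, Path],
    fmt: str = "tsv",
) -> None:
    """Rule table with the four metrics; percentages and lift are printed
    rounded half-up to 2 decimals. An empty rule list yields a header-only
    file."""
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"format must be 'tsv' or 'csv', got {fmt!r}")
    delim = "\t" if fmt == "tsv" else ","
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(_RULE_HEADER)
        for r in rules:
            w.writerow(
                [
                    format_itemset(r.antecedent),
                    r.consequent_text(),
                    r.sigma_rule,
                    r.sigma_head,
                    r.sigma_tail,
                    f"{r.conf_pct:.2f}",
                    f"{r.comp_pct:.2f}",
                    f"{r.lift_2dp:.2f}",
                ]
            )


def read_rules(
    path: Union[str, Path], fmt: str = "tsv", n: Optional[int] = None
) -> list[AssociationRule]:
    """Read a rule table written by :func:`write_rules` (class rules come
    back as :class:`ClassAssociationRule`).

    The database size is not a table column; pass ``n`` when you know it,
    otherwise it is recovered from the printed lift (exact whenever the
    rounding slack 0.005 * head * tail / rule stays below one transaction).
    """
    delim = "\t" if fmt == "tsv" else ","
    rows = []
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        if header != _RULE_HEADER:
            raise ValueError(f"unexpected rule-table header {header}")
        rows = list(reader)
    out: list[AssociationRule] = []
    for ante_s, cons_s, sr, sh, st, conf_s, comp_s, lift_s in rows:
        antecedent = frozenset(parse_item(t) for t in ante_s.split(", "))
        consequent = frozenset(parse_item(t) for t in cons_s.split(", "))
        sr, sh, st = int(sr), int(sh), int(st)
        n_rule = n if n is not None else round(float(lift_s) * sh * st / sr)
        labels = [i.value for i in consequent if i.attribute == "Group"]
        if len(consequent) == 1 and labels:
            rule: AssociationRule = ClassAssociationRule.build(
                antecedent, labels[0], sr, sh, st, n_rule
            )
        else:
            rule = AssociationRule(antecedent, consequent, sr, sh, st, n_rule)
        out.append(rule)
    return out
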