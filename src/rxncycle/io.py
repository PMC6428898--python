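"""Read and write reaction-contingency models as SBtab-compatible tables.

Two carriers are supported: spreadsheets (``.xlsx`` via openpyxl, legacy
``.xls`` via xlrd when available) and a plain-text multi-table TSV dialect
(``.tsv``/``.txt``) in which each table starts with an ``!!SBtab`` header
line followed by a ``!``-prefixed column-header row.  Tables are discovered
by their SBtab ``TableType`` attribute, never by sheet name.  Unknown
columns are preserved row-by-row and written back on round-trip.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Iterable, Mapping

from .core import (
    ComponentSpec,
    Modifier,
    RxnconSystem,
    RxnconError,
    ReactionType,
)

REACTION_TABLE = "ReactionList"
CONTINGENCY_TABLE = "ContingencyList"
SETTINGS_TABLE = "SettingsList"

REACTION_COLUMNS = [
    "!UID:Reaction",
    "!ComponentA:Name",
    "!ComponentA:Domain",
    "!ComponentA:Residue",
    "!Reaction",
    "!ComponentB:Name",
    "!ComponentB:Domain",
    "!ComponentB:Residue",
    "!Tags",
]
CONTINGENCY_COLUMNS = ["!UID:Contingency", "!Target", "!Contingency", "!Modifier"]
SETTINGS_COLUMNS = ["!Node", "!Value"]

#: columns that must be present (the rest of REACTION_COLUMNS may be empty
#: but the parser tolerates their absence entirely only for optional ones)
_REQUIRED_REACTION = [
    "!ComponentA:Name",
    "!Reaction",
    "!ComponentB:Name",
]
_REQUIRED_CONTINGENCY = ["!Target", "!Contingency", "!Modifier"]


class ParseError(RxnconError):
    """A model table could not be parsed; carries the offending row."""


class Table:
    """One SBtab table: a type, ordered columns and string rows."""

    def __init__(self, table_type: str, columns: list[str], rows: list[list[str]]):
        self.table_type = table_type
        self.columns = columns
        self.rows = rows

    def records(self) -> Iterable[dict[str, str]]:
        for row in self.rows:
            yield {c: (row[i] if i < len(row) else "") for i, c in enumerate(self.columns)}


_TABLETYPE_RE = re.compile(r"TableType='([^']+)'")


def _header_line(table_type: str) -> str:
    return (
        f"!!SBtab TableID='{table_type}' TableType='{table_type}' "
        f"Version='1.0'"
    )


# ---------------------------------------------------------------------------
# carriers
# ---------------------------------------------------------------------------

def _read_tsv_tables(text: str) -> list[Table]:
    tables: list[Table] = []
    current: Table | None = None
    expect_header = False
    for line in text.splitlines():
        if line.startswith("!!SBtab"):
            m = _TABLETYPE_RE.search(line)
            ttype = m.group(1) if m else ""
            current = Table(ttype, [], [])
            tables.append(current)
            expect_header = True
            continue
        if current is None or not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if expect_header:
            current.columns = [c.strip() for c in cells]
            expect_header = False
        else:
            current.rows.append([c.strip() for c in cells])
    return tables


def _write_tsv_tables(tables: list[Table]) -> str:
    out = _io.StringIO()
    for i, t in enumerate(tables):
        if i:
            out.write("\n")
        out.write(_header_line(t.table_type) + "\n")
        out.write("\t".join(t.columns) + "\n")
        for row in t.rows:
            out.write("\t".join(row) + "\n")
    return out.getvalue()


def _read_xlsx_tables(path: Path) -> list[Table]:
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    tables: list[Table] = []
    for ws in wb.worksheets:
        rows = [[("" if c is None else str(c)).strip() for c in row] for row in ws.iter_rows(values_only=True)]
        i = 0
        while i < len(rows):
            first = rows[i][0] if rows[i] else ""
            if first.startswith("!!SBtab"):
                m = _TABLETYPE_RE.search(first)
                ttype = m.group(1) if m else ""
                columns = [c for c in rows[i + 1]] if i + 1 < len(rows) else []
                while columns and columns[-1] == "":
                    columns.pop()
                body: list[list[str]] = []
                j = i + 2
                while j < len(rows):
                    head = rows[j][0] if rows[j] else ""
                    if head.startswith("!!SBtab"):
                        break
                    if any(c for c in rows[j]):
                        body.append(rows[j][: len(columns)])
                    j += 1
                tables.append(Table(ttype, columns, body))
                i = j
            else:
                i += 1
    wb.close()
    return tables


def _read_xls_tables(path: Path) -> list[Table]:
    try:
        import xlrd  # type: ignore
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ParseError(
            "reading legacy .xls files requires the optional 'xlrd' package; "
            "convert the file to .xlsx or SBtab TSV instead"
        ) from exc
    book = xlrd.open_workbook(str(path))  # pragma: no cover
    tables: list[Table] = []
    for sheet in book.sheets():  # pragma: no cover
        rows = [
            [str(sheet.cell_value(r, c)).strip() for c in range(sheet.ncols)]
            for r in range(sheet.nrows)
        ]
        text = "\n".join("\t".join(r) for r in rows)
        tables.extend(_read_tsv_tables(text))
    return tables  # pragma: no cover


def read_tables(path: str | Path) -> list[Table]:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt", ".rxncon"):
        return _read_tsv_tables(path.read_text())
    if suffix == ".xlsx":
        return _read_xlsx_tables(path)
    if suffix == ".xls":
        return _read_xls_tables(path)
    raise ParseError(f"unsupported model file extension {suffix!r}")


# ---------------------------------------------------------------------------
# parse / write
# ---------------------------------------------------------------------------

def _check_columns(table: Table, required: list[str], colmap: Mapping[str, str]) -> None:
    have = set(table.columns)
    for col in required:
        if colmap.get(col, col) not in have:
            raise ParseError(
                f"{table.table_type}: missing required column {colmap.get(col, col)!r}"
            )


def parse_tables(
    tables: list[Table],
    catalogue: Mapping[str, ReactionType] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> RxnconSystem:
    """Assemble a system from SBtab tables.

    ``column_map`` remaps the declared column headers onto a file that names
    them differently (keys: canonical header, values: header in the file).
    """
    colmap = dict(column_map or {})

    def col(name: str) -> str:
        return colmap.get(name, name)

    system = RxnconSystem(catalogue=catalogue)
    reaction_tables = [t for t in tables if t.table_type == REACTION_TABLE]
    contingency_tables = [t for t in tables if t.table_type == CONTINGENCY_TABLE]
    settings_tables = [t for t in tables if t.table_type == SETTINGS_TABLE]
    if not reaction_tables:
        raise ParseError(f"no table of type {REACTION_TABLE!r} found")
    if not contingency_tables:
        raise ParseError(f"no table of type {CONTINGENCY_TABLE!r} found")

    for table in reaction_tables:
        if table.rows:
            _check_columns(table, [col(c) for c in _REQUIRED_REACTION], {})
        known = {col(c) for c in REACTION_COLUMNS}
        for i, rec in enumerate(table.records(), start=1):
            if not rec.get(col("!ComponentA:Name")) and not rec.get(col("!Reaction")):
                continue
            rtype = rec.get(col("!Reaction"), "")
            if rtype not in system.catalogue:
                raise ParseError(f"reaction row {i}: unknown reaction type {rtype!r}")
            a = ComponentSpec(
                rec.get(col("!ComponentA:Name"), ""),
                rec.get(col("!ComponentA:Domain")) or None,
                rec.get(col("!ComponentA:Residue")) or None,
            )
            b = ComponentSpec(
                rec.get(col("!ComponentB:Name"), ""),
                rec.get(col("!ComponentB:Domain")) or None,
                rec.get(col("!ComponentB:Residue")) or None,
            )
            tags = tuple(t for t in rec.get(col("!Tags"), "").split(";") if t)
            extra = tuple(
                (k, v) for k, v in rec.items() if k not in known and k and v
            )
            try:
                system.add_reaction(
                    rtype,
                    a,
                    b,
                    uid=rec.get(col("!UID:Reaction")) or None,
                    tags=tags,
                    extra=extra,
                )
            except RxnconError as exc:
                raise ParseError(f"reaction row {i}: {exc}") from exc

    for table in contingency_tables:
        if table.rows:
            _check_columns(table, [col(c) for c in _REQUIRED_CONTINGENCY], {})
        known = {col(c) for c in CONTINGENCY_COLUMNS}
        for i, rec in enumerate(table.records(), start=1):
            target = rec.get(col("!Target"), "")
            if not target:
                continue
            modifier = rec.get(col("!Modifier"), "")
            try:
                system.add_contingency(
                    target,
                    rec.get(col("!Contingency"), ""),
                    modifier,
                    uid=rec.get(col("!UID:Contingency")) or None,
                    extra=tuple(
                        (k, v) for k, v in rec.items() if k not in known and k and v
                    ),
                )
            except (RxnconError, ValueError) as exc:
                raise ParseError(f"contingency row {i}: {exc}") from exc

    for table in settings_tables:
        for rec in table.records():
            node = rec.get("!Node", "")
            value = rec.get("!Value", "").lower()
            if node and value in ("1", "true", "yes"):
                system.declare_initial_true(node)

    return system.finalise()


def parse_model(
    path: str | Path,
    catalogue: Mapping[str, ReactionType] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> RxnconSystem:
    """Parse a model spreadsheet or SBtab TSV file into a system."""
    return parse_tables(read_tables(path), catalogue=catalogue, column_map=column_map)


def system_tables(system: RxnconSystem) -> list[Table]:
    """Serialise a system into SBtab tables (inverse of :func:`parse_tables`)."""
    extra_rxn_cols: list[str] = []
    for r in system.reactions:
        for k, _ in r.extra:
            if k not in extra_rxn_cols:
                extra_rxn_cols.append(k)
    rxn_cols = REACTION_COLUMNS + extra_rxn_cols
    rxn_rows = []
    for r in system.reactions:
        extras = dict(r.extra)
        rxn_rows.append(
            [
                r.uid,
                r.a.name,
                r.a.domain or "",
                r.a.residue or "",
                r.rtype.name,
                r.b.name,
                r.b.domain or "",
                r.b.residue or "",
                ";".join(sorted(r.tags)),
            ]
            + [extras.get(k, "") for k in extra_rxn_cols]
        )

    extra_cont_cols: list[str] = []
    for c in system.contingencies:
        for k, _ in c.extra:
            if k not in extra_cont_cols:
                extra_cont_cols.append(k)
    cont_cols = CONTINGENCY_COLUMNS + extra_cont_cols
    cont_rows = []
    for c in system.contingencies:
        extras = dict(c.extra)
        effector = c.annotation if c.annotation else c.effector
        cont_rows.append(
            [c.uid, c.target, effector, c.modifier.value]
            + [extras.get(k, "") for k in extra_cont_cols]
        )

    tables = [
        Table(REACTION_TABLE, rxn_cols, rxn_rows),
        Table(CONTINGENCY_TABLE, cont_cols, cont_rows),
    ]
    if system.initial_true:
        tables.append(
            Table(
                SETTINGS_TABLE,
                SETTINGS_COLUMNS,
                [[node, "true"] for node in system.initial_true],
            )
        )
    return tables


def write_model(system: RxnconSystem, path: str | Path) -> Path:
    """Write a system to ``.tsv``/``.txt`` (SBtab text) or ``.xlsx``.

    ``parse_model(write_model(s)) `` is semantically equal to ``s``.
    """
    path = Path(path)
    tables = system_tables(system)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt", ".rxncon"):
        path.write_text(_write_tsv_tables(tables))
    elif suffix == ".xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        wb.remove(wb.active)
        for t in tables:
            ws = wb.create_sheet(title=t.table_type[:31])
            ws.append([_header_line(t.table_type)])
            ws.append(t.columns)
            for row in t.rows:
                ws.append(row)
        wb.save(path)
    else:
        raise ParseError(f"unsupported output extension {suffix!r}")
    return path


def model_to_text(system: RxnconSystem) -> str:
    """The canonical SBtab TSV serialisation of a system as a string."""
    return _write_tsv_tables(system_tables(system))
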