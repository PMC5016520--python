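"""Reading and writing clonotype tables and parsing IG/TR gene nomenclature.

The input is one tab-separated table per repertoire set, one row per
clonotype (a unique V-(D)-J rearrangement with a unique CDR3 amino-acid
junction).  Column names vary between annotation-tool exports, so the
reader is driven by a :class:`StatsDialect` that maps semantic fields to
column names; :data:`CANONICAL_DIALECT` documents the layout this package
writes.

Gene calls follow the IMGT nomenclature, e.g. ``IGHV4-34*01`` is allele
``01`` of gene ``IGHV4-34`` in group ``IGHV`` (locus IGH, gene type V).
Ambiguous assignments list several candidates separated by ``", or"`` or
plain commas; these are flagged ``is_several`` and carry the member list.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GeneCall",
    "ClonotypeRecord",
    "StatsDialect",
    "CANONICAL_DIALECT",
    "GeneCallParseError",
    "DialectError",
    "RejectedRow",
    "parse_gene_call",
    "read_stats_file",
    "write_stats_file",
    "write_rejected_report",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: locus code (IG heavy/kappa/lambda, TR alpha/beta/gamma/delta) + gene type
_GROUP_RE = re.compile(r"^(IG[HKL]|TR[ABGD])([VDJ])")

#: one gene token: group, body, optional duplicate-gene letter, optional allele
_CALL_RE = re.compile(
    r"^(?P<gene>(?:IG[HKL]|TR[ABGD])[VDJ][\w./()-]*?)(?:\*(?P<allele>\d+))?$"
)

#: functionality annotations appended to calls; metadata, not identity
_FUNCTIONALITY_RE = re.compile(r"\s+(?:F|P|ORF|\[F\]|\[P\]|\[ORF\]|\(F\)|\(P\)|\(ORF\))(?=\s|,|$)")


class GeneCallParseError(ValueError):
    """A gene/allele call string that does not follow the nomenclature."""

    def __init__(self, text: str, reason: str = ""):
        self.text = text
        super().__init__(f"unparseable gene call {text!r}" + (f": {reason}" if reason else ""))


class DialectError(ValueError):
    """Configuration error in a stats-table dialect (e.g. missing column)."""


@dataclass(frozen=True)
class GeneCall:
    """A parsed V, D or J assignment, possibly ambiguous over several genes."""

    raw_text: str
    group: str
    gene: str
    allele: str | None = None
    is_several: bool = False
    members: tuple[tuple[str, str | None], ...] = ()

    def __post_init__(self):
        if self.is_several != (len(self.members) >= 2):
            raise ValueError("is_several must hold exactly when members has length >= 2")
        for gene, _ in self.members or ((self.gene, self.allele),):
            if not gene.startswith(self.group):
                raise ValueError(f"group {self.group!r} is not a prefix of member gene {gene!r}")

    def canonical(self) -> str:
        """Canonical text form; parsing it reproduces this call."""
        def fmt(gene: str, allele: str | None) -> str:
            return f"{gene}*{allele}" if allele is not None else gene

        if self.is_several:
            return ", or ".join(fmt(g, a) for g, a in self.members)
        return fmt(self.gene, self.allele)


def parse_gene_call(text: str) -> GeneCall:
    """Parse one gene/allele call string.

    Functionality flags (``F``, ``P``, ``ORF``) are stripped.  Multiple
    candidates separated by ``", or"`` or commas yield ``is_several=True``
    with the ordered member list; ``gene``/``allele`` then refer to the
    first member.

    Raises
    ------
    GeneCallParseError
        If the text (or any member) does not match the nomenclature.
    """
    raw = text
    cleaned = _FUNCTIONALITY_RE.sub("", text.strip())
    if not cleaned:
        raise GeneCallParseError(raw, "empty after stripping annotations")

    parts = [p.strip() for p in re.split(r",\s*(?:or\s+)?|\s+or\s+", cleaned) if p.strip()]
    members: list[tuple[str, str | None]] = []
    for part in parts:
        m = _CALL_RE.match(part)
        if not m:
            raise GeneCallParseError(raw, f"token {part!r}")
        members.append((m.group("gene"), m.group("allele")))

    gene0, allele0 = members[0]
    gm = _GROUP_RE.match(gene0)
    if gm is None:  # pragma: no cover - _CALL_RE already guarantees the prefix
        raise GeneCallParseError(raw, "no locus-group prefix")
    group = gm.group(0)
    for gene, _ in members:
        if not gene.startswith(group):
            raise GeneCallParseError(raw, f"member {gene!r} outside group {group!r}")

    several = len(members) >= 2
    return GeneCall(
        raw_text=raw,
        group=group,
        gene=gene0,
        allele=allele0,
        is_several=several,
        members=tuple(members) if several else (),
    )


@dataclass(frozen=True)
class ClonotypeRecord:
    """One clonotype: gene calls, CDR amino-acid sequences, assigned-read count."""

    clonotype_id: str
    v_call: GeneCall
    j_call: GeneCall
    d_call: GeneCall | None = None
    cdr1_aa: str = ""
    cdr2_aa: str = ""
    cdr3_aa: str = ""
    cdr3_length: int = 0
    n_sequences: int = 1

    def validate(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        problems = []
        if self.cdr3_aa and self.cdr3_length != len(self.cdr3_aa):
            problems.append(
                f"cdr3_length={self.cdr3_length} != len(cdr3_aa)={len(self.cdr3_aa)}"
            )
        if self.n_sequences < 1:
            problems.append(f"n_sequences={self.n_sequences} < 1")
        bad = set(self.cdr3_aa) - STANDARD_AA
        if bad:
            problems.append(f"non-standard AA letters in cdr3_aa: {sorted(bad)}")
        return problems


@dataclass(frozen=True)
class StatsDialect:
    """Column mapping for a clonotype stats table.

    ``v_call``, ``j_call`` and ``cdr3_aa`` are mandatory; the rest are
    optional and default to absent.
    """

    column_map: dict = field(
        default_factory=lambda: dict(CANONICAL_COLUMNS)
    )
    separator: str = "\t"
    comment_prefix: str = "#"

    MANDATORY = ("v_call", "j_call", "cdr3_aa")

    def __post_init__(self):
        missing = [f for f in self.MANDATORY if f not in self.column_map]
        if missing:
            raise DialectError(f"dialect is missing mandatory field mappings: {missing}")

    def column(self, semantic: str) -> str | None:
        return self.column_map.get(semantic)


CANONICAL_COLUMNS = (
    ("clonotype_id", "clonotype_id"),
    ("v_call", "v_gene_and_allele"),
    ("d_call", "d_gene_and_allele"),
    ("j_call", "j_gene_and_allele"),
    ("cdr1_aa", "cdr1_imgt_aa"),
    ("cdr2_aa", "cdr2_imgt_aa"),
    ("cdr3_aa", "cdr3_imgt_aa"),
    ("cdr3_length", "cdr3_imgt_length"),
    ("n_sequences", "nb_sequences_assigned"),
)

#: the layout this package writes; readable back with this same dialect
CANONICAL_DIALECT = StatsDialect()


@dataclass(frozen=True)
class RejectedRow:
    line_number: int
    reason: str
    content: str


def read_stats_file(
    path: str | Path,
    dialect: StatsDialect = CANONICAL_DIALECT,
) -> tuple[list[ClonotypeRecord], list[RejectedRow]]:
    """Read a clonotype stats table.

    Returns ``(records, rejected)``: rows violating record invariants or
    failing to parse are collected in the rejected-rows report, never
    silently dropped.  Number of records + number rejected equals the
    number of data rows.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        lines = [
            (i + 1, line.rstrip("\r\n"))
            for i, line in enumerate(fh)
            if not line.startswith(dialect.comment_prefix)
        ]
    lines = [(n, l) for n, l in lines if l.strip()]
    if not lines:
        warnings.warn(f"{path}: empty stats file", stacklevel=2)
        return [], []

    header_no, header = lines[0]
    columns = header.split(dialect.separator)
    col_index = {name: i for i, name in enumerate(columns)}
    for semantic in dialect.MANDATORY:
        col = dialect.column(semantic)
        if col not in col_index:
            raise DialectError(
                f"{path}: mandatory column {col!r} (field {semantic!r}) not in header"
            )

    def get(fields: list[str], semantic: str) -> str | None:
        col = dialect.column(semantic)
        if col is None or col not in col_index:
            return None
        i = col_index[col]
        return fields[i] if i < len(fields) else None

    records: list[ClonotypeRecord] = []
    rejected: list[RejectedRow] = []
    for line_no, line in lines[1:]:
        fields = line.split(dialect.separator)
        try:
            v_call = parse_gene_call(get(fields, "v_call") or "")
            j_call = parse_gene_call(get(fields, "j_call") or "")
            d_text = get(fields, "d_call")
            d_call = parse_gene_call(d_text) if d_text else None
            cdr3_aa = (get(fields, "cdr3_aa") or "").strip()
            raw_len = get(fields, "cdr3_length")
            cdr3_length = int(raw_len) if raw_len not in (None, "") else len(cdr3_aa)
            raw_n = get(fields, "n_sequences")
            n_sequences = int(raw_n) if raw_n not in (None, "") else 1
            rec = ClonotypeRecord(
                clonotype_id=get(fields, "clonotype_id") or str(line_no),
                v_call=v_call,
                j_call=j_call,
                d_call=d_call,
                cdr1_aa=(get(fields, "cdr1_aa") or "").strip(),
                cdr2_aa=(get(fields, "cdr2_aa") or "").strip(),
                cdr3_aa=cdr3_aa,
                cdr3_length=cdr3_length,
                n_sequences=n_sequences,
            )
        except (GeneCallParseError, ValueError) as exc:
            rejected.append(RejectedRow(line_no, str(exc), line))
            continue
        problems = rec.validate()
        if problems:
            rejected.append(RejectedRow(line_no, "; ".join(problems), line))
        else:
            records.append(rec)
    if rejected:
        warnings.warn(
            f"{path}: rejected {len(rejected)} of {len(lines) - 1} data rows",
            stacklevel=2,
        )
    return records, rejected


def write_stats_file(
    records: Iterable[ClonotypeRecord],
    path: str | Path,
    dialect: StatsDialect = CANONICAL_DIALECT,
) -> Path:
    """Write records as a stats table; reading it back reproduces them."""
    path = Path(path)
    sep = dialect.separator
    semantics = [s for s, _ in CANONICAL_COLUMNS if dialect.column(s) is not None]
    header = [dialect.column(s) for s in semantics]
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(sep.join(header) + "\n")
        for rec in records:
            values = {
                "clonotype_id": rec.clonotype_id,
                "v_call": rec.v_call.canonical(),
                "d_call": rec.d_call.canonical() if rec.d_call else "",
                "j_call": rec.j_call.canonical(),
                "cdr1_aa": rec.cdr1_aa,
                "cdr2_aa": rec.cdr2_aa,
                "cdr3_aa": rec.cdr3_aa,
                "cdr3_length": str(rec.cdr3_length),
                "n_sequences": str(rec.n_sequences),
            }
            fh.write(sep.join(values[s] for s in semantics) + "\n")
    return path


def write_rejected_report(rejected: Sequence[RejectedRow], path: str | Path) -> Path:
    """Write the rejected-rows report as CSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["line_number", "reason", "content"])
        for r in rejected:
            w.writerow([r.line_number, r.reason, r.content])
    return path
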