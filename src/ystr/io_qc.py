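"""Reading, validation and writing of haplotype and pedigree tables.

Input dialect (shared by CSV and XLSX workbooks):

* haplotype tables: first column = sample identifier, first row = locus
  names, one column per locus; multi-copy genotypes comma-separated
  (``13,13`` homozygote, ``13,20`` heterozygote);
* pedigree tables: first column = pedigree identifier repeated on two
  consecutive rows, second column = ``P`` (father) / ``O`` (son), then
  locus columns; an optional ``BirthYear`` column yields the father's
  age at gametogenesis (son's birth year minus father's).

Alleles must be positive repeat numbers with at most one decimal place
(intermediate alleles such as ``23.2``).  Anything else — text, zero or
negative values, excess precision — is excluded from all downstream
statistics and logged in the QC report; nothing is ever imputed.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .locus_registry import Registry

__all__ = [
    "Allele",
    "HaplotypeDataset",
    "PairRecord",
    "QCIssue",
    "QCReport",
    "read_haplotypes",
    "read_pairs",
    "write_table",
]

# Allele values are carried as integers in tenths of a repeat unit so that
# 14 == 14.0 exactly and 23.2 is representable without float comparison
# traps.  `Allele` converts to/from the user-facing decimal form.
_ALLELE_RE = re.compile(r"^\+?(\d+)(?:\.(\d))?$")


class Allele(int):
    """An allele repeat number stored in tenths of a repeat."""

    @classmethod
    def parse(cls, text: str) -> "Allele":
        m = _ALLELE_RE.match(text.strip())
        if not m:
            raise ValueError(f"not a valid allele: {text!r}")
        whole, dec = m.group(1), m.group(2) or "0"
        value = int(whole) * 10 + int(dec)
        if value <= 0:
            raise ValueError(f"allele must be positive: {text!r}")
        return cls(value)

    @classmethod
    def from_repeats(cls, repeats: float) -> "Allele":
        return cls(round(repeats * 10))

    @property
    def repeats(self) -> float:
        return self / 10

    def __str__(self) -> str:
        if self % 10 == 0:
            return str(self // 10)
        return f"{self // 10}.{self % 10}"

    def __repr__(self) -> str:
        return f"Allele({self!s})"


Genotype = tuple[Allele, ...]  # sorted, length == copy_number


@dataclass(frozen=True)
class QCIssue:
    record: str  # sample or pedigree identifier
    locus: str | None
    raw: str
    reason: str  # non-numeric | non-positive | bad-precision | missing |
    #              unpaired-row | bad-copy-count | homozygous-expansion |
    #              dys389-inconsistent


@dataclass
class QCReport:
    """Per-cell validation log; one message per excluded cell."""

    issues: list[QCIssue] = field(default_factory=list)

    def add(self, record: str, locus: str | None, raw: object, reason: str) -> None:
        self.issues.append(QCIssue(str(record), locus, str(raw), reason))

    @property
    def counts(self) -> Counter:
        return Counter(i.reason for i in self.issues)

    def excluded(self) -> list[QCIssue]:
        """Issues that removed a cell (notes like homozygous-expansion don't)."""
        return [i for i in self.issues if i.reason != "homozygous-expansion"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.record, i.locus, i.raw, i.reason) for i in self.issues],
            columns=["record", "locus", "value", "reason"],
        )

    def __str__(self) -> str:
        lines = [f"{len(self.issues)} QC message(s)"]
        for reason, n in sorted(self.counts.items()):
            lines.append(f"  {reason}: {n}")
        return "\n".join(lines)


@dataclass
class HaplotypeDataset:
    """Samples x loci allele table; missing entries are simply absent."""

    samples: tuple[str, ...]
    loci: tuple[str, ...]
    alleles: dict[tuple[str, str], Genotype]

    def genotype(self, sample: str, locus: str) -> Genotype | None:
        return self.alleles.get((sample, locus))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def complete_samples(self, loci: Sequence[str]) -> list[str]:
        """Samples with valid data at every listed locus."""
        return [s for s in self.samples if all((s, l) in self.alleles for l in loci)]

    def to_frame(self) -> pd.DataFrame:
        data = {
            locus: [
                ",".join(str(a) for a in self.alleles[(s, locus)])
                if (s, locus) in self.alleles
                else ""
                for s in self.samples
            ]
            for locus in self.loci
        }
        return pd.DataFrame(data, index=pd.Index(self.samples, name="SampleID"))


@dataclass
class PairRecord:
    """One father-son pair with per-locus genotypes and optional father age."""

    pedigree_id: str
    father: dict[str, Genotype]
    son: dict[str, Genotype]
    father_age: float | None = None

    def loci_complete(self, locus: str) -> bool:
        return locus in self.father and locus in self.son


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_cell(
    raw: object,
    record: str,
    locus: str,
    copy_number: int,
    qc: QCReport,
) -> Genotype | None:
    """Validate one table cell; return a sorted genotype or None (logged)."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw is pd.NA:
        qc.add(record, locus, "", "missing")
        return None
    text = str(raw).strip()
    if text == "" or text.lower() in {"nan", "none"}:
        qc.add(record, locus, "", "missing")
        return None
    parts = [p.strip() for p in text.split(",")]
    alleles: list[Allele] = []
    for part in parts:
        m = _ALLELE_RE.match(part)
        if not m:
            # distinguish numeric-but-overprecise from plain text
            reason = (
                "bad-precision"
                if re.match(r"^[+-]?\d+\.\d{2,}$", part)
                else "non-positive"
                if re.match(r"^[+-]?\d+(\.\d+)?$", part)
                else "non-numeric"
            )
            qc.add(record, locus, text, reason)
            return None
        a = int(m.group(1)) * 10 + int(m.group(2) or 0)
        if a <= 0:
            qc.add(record, locus, text, "non-positive")
            return None
        alleles.append(Allele(a))
    if copy_number == 2 and len(alleles) == 1:
        # single entry at a dual-copy marker: CE single-peak convention,
        # expanded to a homozygous pair (noted, not excluded)
        qc.add(record, locus, text, "homozygous-expansion")
        alleles = alleles * 2
    if len(alleles) != copy_number:
        qc.add(record, locus, text, "bad-copy-count")
        return None
    return tuple(sorted(alleles))


def _read_raw(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm", ".xls"}:
        return pd.read_excel(path, dtype=str)
    return pd.read_csv(path, dtype=str, sep=None, engine="python")


def _locus_columns(
    columns: Sequence[str], registry: Registry, qc: QCReport
) -> list[tuple[str, str]]:
    """(column label, canonical locus name) for recognized locus headers."""
    out = []
    for col in columns:
        if registry.knows(col):
            out.append((col, registry.canonical_name(col)))
        else:
            qc.add("<header>", None, col, "unknown-locus-column")
    return out


_BIRTHYEAR_RE = re.compile(r"^birth[\s_]?year$", re.IGNORECASE)


def read_haplotypes(
    path: str | Path, registry: Registry
) -> tuple[HaplotypeDataset, QCReport]:
    """Read a haplotype table (CSV or workbook) in the documented dialect.

    Returns the validated dataset and the QC report.  Unknown locus
    columns are skipped with a warning message in the report; duplicate
    sample identifiers are an error.
    """
    qc = QCReport()
    df = _read_raw(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a sample-ID column plus locus columns")
    id_col = df.columns[0]
    ids = df[id_col].astype(str).str.strip()
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample IDs: {sorted(set(dup))}")
    locus_cols = _locus_columns(df.columns[1:], registry, qc)
    alleles: dict[tuple[str, str], Genotype] = {}
    for _, row in df.iterrows():
        sample = str(row[id_col]).strip()
        for col, locus in locus_cols:
            g = _parse_cell(
                row[col], sample, locus, registry.get_locus(locus).copy_number, qc
            )
            if g is not None:
                alleles[(sample, locus)] = g
    ds = HaplotypeDataset(
        samples=tuple(ids),
        loci=tuple(l for _, l in locus_cols),
        alleles=alleles,
    )
    return ds, qc


def read_pairs(path: str | Path, registry: Registry) -> tuple[list[PairRecord], QCReport]:
    """Read a pedigree table of father (P) / son (O) rows.

    Only complete P+O pairs are returned; orphan rows are logged as
    ``unpaired-row``.  Invalid cells are excluded per locus — the pair is
    kept and the locus simply contributes no allele transfer.
    """
    qc = QCReport()
    df = _read_raw(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected pedigree-ID, P/O and locus columns")
    id_col, role_col = df.columns[0], df.columns[1]
    birth_col = next((c for c in df.columns[2:] if _BIRTHYEAR_RE.match(str(c))), None)
    locus_cols = _locus_columns(
        [c for c in df.columns[2:] if c != birth_col], registry, qc
    )

    rows: dict[str, dict[str, pd.Series]] = {}
    for _, row in df.iterrows():
        ped = str(row[id_col]).strip()
        role = str(row[role_col]).strip().upper()
        if role not in {"P", "O"}:
            qc.add(ped, None, row[role_col], "unpaired-row")
            continue
        slot = rows.setdefault(ped, {})
        if role in slot:
            qc.add(ped, None, role, "unpaired-row")  # duplicate role row
            continue
        slot[role] = row

    pairs: list[PairRecord] = []
    for ped, slot in rows.items():
        if set(slot) != {"P", "O"}:
            qc.add(ped, None, "/".join(sorted(slot)), "unpaired-row")
            continue
        genos: dict[str, dict[str, Genotype]] = {"P": {}, "O": {}}
        for role in ("P", "O"):
            row = slot[role]
            who = f"{ped}:{role}"
            for col, locus in locus_cols:
                g = _parse_cell(
                    row[col], who, locus, registry.get_locus(locus).copy_number, qc
                )
                if g is not None:
                    genos[role][locus] = g
        age = None
        if birth_col is not None:
            try:
                age = float(slot["O"][birth_col]) - float(slot["P"][birth_col])
            except (TypeError, ValueError):
                qc.add(ped, None, "", "missing-birth-year")
        pairs.append(
            PairRecord(pedigree_id=ped, father=genos["P"], son=genos["O"], father_age=age)
        )
    return pairs, qc


def write_table(result: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as CSV or XLSX depending on the extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        result.to_excel(path, index=index)
    else:
        result.to_csv(path, index=index)
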