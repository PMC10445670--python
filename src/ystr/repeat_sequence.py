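"""Bracketed repeat-structure parsing and sequence-variant classification.

Sequenced STR alleles are conventionally written in bracket notation:
``[TAGA]11 [CAGA]2 N48 [TAGA]11 [CAGA]4`` — whitespace-separated tokens
that are either a repeat block ``[MOTIF]count``, a bare single unit
``MOTIF`` (count 1), or a fixed spacer ``Nk`` of k base pairs.
Lowercase runs (annotations of spacer sequence) are normalized to
spacers of the same length, with the raw text preserved.

The allele designation of a structure is nomenclature-driven: repeat
blocks and full-length single units are counted, spacers are not, and a
per-locus rule (see :class:`ystr.locus_registry.LocusSpec`) supplies an
optional offset and a canonical spacer length whose deviation produces
microvariant (.x) designations — e.g. a 4 bp spacer deletion at a
hexanucleotide locus turns allele 20 into 19.2.

Sequence variants between two alleles of the same locus are classified
as repeat-region (RR) variants — same length-based designation, a
different arrangement of repeat blocks (isoalleles) — or flanking-region
(FR) variants carried outside the counted repeats.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .io_qc import Allele
from .locus_registry import LocusSpec

__all__ = [
    "Block",
    "RepeatStructure",
    "SequenceAllele",
    "StructureParseError",
    "VariantClass",
    "UnitClass",
    "parse_repeat_structure",
    "allele_designation",
    "classify_variant",
    "mutated_unit_class",
    "sequence_vs_length_diversity",
]


class StructureParseError(ValueError):
    def __init__(self, token: str, position: int, why: str):
        self.token, self.position = token, position
        super().__init__(f"bad token {token!r} at position {position}: {why}")


@dataclass(frozen=True)
class Block:
    kind: str  # "repeat" | "single_unit" | "spacer"
    motif: str = ""  # repeat / single_unit
    count: int = 0  # repeat
    length_bp: int = 0  # spacer
    raw: str = ""  # original token text (annotated spacers keep theirs)

    @property
    def span_bp(self) -> int:
        if self.kind == "repeat":
            return len(self.motif) * self.count
        if self.kind == "single_unit":
            return len(self.motif)
        return self.length_bp

    def serialize(self) -> str:
        if self.kind == "repeat":
            return f"[{self.motif}]{self.count}"
        if self.kind == "single_unit":
            return self.motif
        return self.raw or f"N{self.length_bp}"


@dataclass(frozen=True)
class RepeatStructure:
    blocks: tuple[Block, ...]
    source_text: str = ""

    def serialize(self) -> str:
        return " ".join(b.serialize() for b in self.blocks)

    @property
    def total_length_bp(self) -> int:
        return sum(b.span_bp for b in self.blocks)

    @property
    def repeat_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.kind == "repeat")

    @property
    def spacer_bp(self) -> int:
        return sum(b.length_bp for b in self.blocks if b.kind == "spacer")

    def skeleton(self) -> tuple:
        """Block identity ignoring repeat counts, for comparability checks."""
        return tuple(
            (b.kind, b.motif if b.kind != "spacer" else b.length_bp)
            for b in self.blocks
        )


_REPEAT_RE = re.compile(r"^\[([ACGTacgt]+)\](\d+)$")
_SPACER_RE = re.compile(r"^N(\d+)$")
_SINGLE_RE = re.compile(r"^[ACGT]+$")
_LOWER_RE = re.compile(r"^[acgt\-–—]+$")


def parse_repeat_structure(text: str) -> RepeatStructure:
    """Parse a bracket-notation structure string into ordered blocks.

    Raises :class:`StructureParseError` on malformed tokens (unbalanced
    brackets, zero counts, non-ACGT motifs).  Lowercase tokens — spacer
    sequence annotations — become spacer blocks of their base length.
    """
    blocks: list[Block] = []
    for pos, token in enumerate(text.split()):
        if m := _REPEAT_RE.match(token):
            motif, count = m.group(1), int(m.group(2))
            if count < 1:
                raise StructureParseError(token, pos, "repeat count must be >= 1")
            if motif.islower():
                # annotated spacer written as lowercase bracket notation
                blocks.append(
                    Block("spacer", length_bp=len(motif) * count, raw=token)
                )
            else:
                blocks.append(Block("repeat", motif=motif.upper(), count=count))
        elif m := _SPACER_RE.match(token):
            length = int(m.group(1))
            if length < 1:
                raise StructureParseError(token, pos, "spacer length must be >= 1")
            blocks.append(Block("spacer", length_bp=length, raw=token))
        elif _SINGLE_RE.match(token):
            blocks.append(Block("single_unit", motif=token))
        elif _LOWER_RE.match(token):
            bases = sum(c in "acgt" for c in token)
            if bases == 0:
                raise StructureParseError(token, pos, "no bases in spacer annotation")
            blocks.append(Block("spacer", length_bp=bases, raw=token))
        else:
            raise StructureParseError(token, pos, "not [MOTIF]k, MOTIF or Nk")
    return RepeatStructure(blocks=tuple(blocks), source_text=text)


def allele_designation(st: RepeatStructure, locus: LocusSpec) -> Allele:
    """Allele designation of a structure under the locus counting rule.

    Counted units are all repeat blocks plus single units whose motif
    length equals the locus repeat-unit length, shifted by the locus
    designation offset.  If the locus declares a canonical spacer length,
    a spacer deviation is folded in at base-pair resolution and any
    remainder becomes the .x microvariant suffix.
    """
    unit = locus.unit_length_bp
    counted = sum(b.count for b in st.blocks if b.kind == "repeat")
    counted += sum(
        1 for b in st.blocks if b.kind == "single_unit" and len(b.motif) == unit
    )
    counted += locus.designation_offset
    if counted <= 0:
        raise ValueError(f"{locus.name}: no counted repeat units in {st.source_text!r}")
    if locus.canonical_spacer_bp is not None:
        deviation = st.spacer_bp - locus.canonical_spacer_bp
        total_bp = counted * unit + deviation
        whole, extra = divmod(total_bp, unit)
        if extra:
            return Allele(whole * 10 + extra)
        return Allele(whole * 10)
    return Allele(counted * 10)


@dataclass(frozen=True)
class SequenceAllele:
    """A sequenced allele: designation, repeat structure, flank variants."""

    locus: str
    designation: Allele
    structure: RepeatStructure
    flank_variants: tuple[str, ...] = ()  # opaque labels, e.g. rs numbers


class VariantClass(str, Enum):
    identical = "identical"
    length_only = "length_only"
    rr_variant = "rr_variant"
    fr_variant = "fr_variant"
    rr_and_fr = "rr_and_fr"


def classify_variant(a: SequenceAllele, b: SequenceAllele) -> VariantClass:
    """Classify the difference between two sequenced alleles of one locus."""
    if a.locus != b.locus:
        raise ValueError(f"cross-locus comparison: {a.locus} vs {b.locus}")
    fr_differs = set(a.flank_variants) != set(b.flank_variants)
    rr_differs = a.structure.serialize() != b.structure.serialize()
    if not rr_differs and not fr_differs:
        return VariantClass.identical
    if rr_differs and a.designation != b.designation:
        # plain length difference; still flag FR if the flanks also differ
        return VariantClass.rr_and_fr if fr_differs else VariantClass.length_only
    if rr_differs and fr_differs:
        return VariantClass.rr_and_fr
    if rr_differs:
        return VariantClass.rr_variant
    return VariantClass.fr_variant


class UnitClass(str, Enum):
    larger_unit = "larger_unit"
    smaller_unit = "smaller_unit"
    both = "both"
    none = "none"


class NotComparableError(ValueError):
    pass


def mutated_unit_class(f: RepeatStructure, s: RepeatStructure) -> UnitClass:
    """Which variable repeat block(s) changed between father and son.

    For compound/complex motifs, a mutation is attributed to the
    "larger" variable unit when the changed block has the greatest
    repeat count among the father's repeat blocks (ties count as
    larger), otherwise to a "smaller" unit; changes in two or more
    blocks are "both".  Structures must share a block skeleton.
    """
    if f.skeleton() != s.skeleton():
        raise NotComparableError(
            "structures differ beyond block counts: "
            f"{f.serialize()!r} vs {s.serialize()!r}"
        )
    f_rep = [b for b in f.blocks if b.kind == "repeat"]
    s_rep = [b for b in s.blocks if b.kind == "repeat"]
    changed = [i for i, (fb, sb) in enumerate(zip(f_rep, s_rep)) if fb.count != sb.count]
    if not changed:
        return UnitClass.none
    if len(changed) >= 2:
        return UnitClass.both
    max_count = max(b.count for b in f_rep)
    return (
        UnitClass.larger_unit
        if f_rep[changed[0]].count == max_count
        else UnitClass.smaller_unit
    )


def sequence_vs_length_diversity(
    ds_seq: dict[str, dict[str, object]],
    ds_len: dict[str, dict[str, object]],
) -> pd.DataFrame:
    """Per-locus gene diversity under sequence vs length allele coding.

    ``ds_seq`` / ``ds_len`` map locus -> {sample -> allele key}, where a
    key is any hashable coding (a serialized structure, a designation).
    Both datasets must cover the same samples per locus.  Returns a table
    with GD under each coding and the relative increment.
    """
    from .haplotype_stats import FrequencyTable, gene_diversity

    if set(ds_seq) != set(ds_len):
        raise ValueError("locus sets differ between sequence and length datasets")
    rows = []
    for locus in sorted(ds_seq):
        seq, length = ds_seq[locus], ds_len[locus]
        if set(seq) != set(length):
            raise ValueError(f"{locus}: sample sets differ between codings")
        from collections import Counter

        gd_seq = gene_diversity(
            FrequencyTable(locus, Counter(seq.values()), len(seq))
        )
        gd_len = gene_diversity(
            FrequencyTable(locus, Counter(length.values()), len(length))
        )
        increment = (gd_seq - gd_len) / gd_len if gd_len > 0 else 0.0
        rows.append((locus, gd_seq, gd_len, increment))
    df = pd.DataFrame(
        rows, columns=["locus", "gd_sequence", "gd_length", "relative_increment"]
    )
    return df
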