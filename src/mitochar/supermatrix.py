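"""Codon-aware supermatrix preparation for mitogenome phylogenetics.

Per-gene nucleotide alignments are checked by translation under the
mitochondrial code, stripped of terminal stop codons and gap-containing
columns, and concatenated into a single partitioned matrix.  Tree
inference itself is out of scope; the writers target the partition-file
dialects of the common ML programs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .codes import GeneticCode, as_rna

GAP_CHARS = frozenset("-.")
MISSING = "?"


@dataclass
class GeneAlignment:
    """One gene's aligned sense-strand nucleotide rows."""

    gene: str
    taxa: list[str]
    rows: list[str]
    reading_frame_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError(f"{self.gene}: taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"{self.gene}: duplicate taxa")
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError(f"{self.gene}: rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class Supermatrix:
    taxa: list[str]
    matrix: dict[str, str]  # taxon -> concatenated sequence
    partitions: list[tuple[str, int, int]]  # (gene, start, end), 1-based inclusive

    @property
    def length(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0


@dataclass(frozen=True)
class TranslationFinding:
    taxon: str
    codon_index: int  # 1-based
    codon: str


def _codons(row: str, offset: int) -> list[str]:
    trimmed = row[offset:]
    return [trimmed[i : i + 3] for i in range(0, len(trimmed) - len(trimmed) % 3, 3)]


def check_translation(
    aln: GeneAlignment, code: GeneticCode
) -> dict[str, object]:
    """Translate each row and list internal stop codons.

    Gap-only codons (``---``) translate as missing; the terminal codon of a
    row is allowed to be a stop.  Row length after the reading-frame offset
    must be divisible by 3.
    """
    if (aln.length - aln.reading_frame_offset) % 3 != 0:
        raise ValueError(f"{aln.gene}: aligned length not divisible by 3")
    translations: dict[str, str] = {}
    findings: list[TranslationFinding] = []
    for taxon, row in zip(aln.taxa, aln.rows):
        aa = []
        codons = _codons(row.upper(), aln.reading_frame_offset)
        for i, codon in enumerate(codons):
            if set(codon) <= GAP_CHARS:
                aa.append("-")
                continue
            rna = as_rna(codon)
            if not set(rna) <= set("ACGU"):  # partial gap or ambiguity code
                aa.append("X")
                continue
            if rna in code.stop_codons:
                aa.append("*")
                if i < len(codons) - 1:
                    findings.append(TranslationFinding(taxon, i + 1, codon))
            else:
                aa.append(code.codon_to_aa[rna])
        translations[taxon] = "".join(aa)
    return {"translations": translations, "internal_stops": findings}


def strip_stops_and_gaps(
    aln: GeneAlignment, code: Optional[GeneticCode] = None
) -> GeneAlignment:
    """Remove terminal stop-codon triplets and every gap-containing column.

    Trailing codon columns in which any row reads a stop are dropped as
    whole triplets (preserving frame); afterwards any column that still
    contains a gap in at least one row is removed.
    """
    code = code or GeneticCode.invertebrate_mito()
    rows = [r.upper() for r in aln.rows]
    length = aln.length
    off = aln.reading_frame_offset
    # peel terminal stop-codon triplets
    while length - off >= 3 and (length - off) % 3 == 0:
        tail = [r[length - 3 : length] for r in rows]
        if any(as_rna(c) in code.stop_codons for c in tail):
            length -= 3
        else:
            break
    rows = [r[:length] for r in rows]
    keep = [j for j in range(length) if all(r[j] not in GAP_CHARS for r in rows)]
    rows = ["".join(r[j] for j in keep) for r in rows]
    if not rows or not rows[0]:
        raise ValueError(f"{aln.gene}: nothing left after stripping")
    return GeneAlignment(aln.gene, list(aln.taxa), rows, 0)


def concatenate(
    alns: Sequence[GeneAlignment], exclude: Sequence[str] = ()
) -> Supermatrix:
    """Concatenate gene alignments in order, recording partitions.

    Exclusions are matched case-insensitively.  Taxa absent from a gene are
    padded with ``?`` across that partition.
    """
    skip = {e.lower() for e in exclude}
    used = [a for a in alns if a.gene.lower() not in skip]
    if not used:
        raise ValueError("no gene alignments left after exclusion")
    taxa: list[str] = []
    for a in used:
        for t in a.taxa:
            if t not in taxa:
                taxa.append(t)
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for a in used:
        row_of = dict(zip(a.taxa, a.rows))
        for t in taxa:
            pieces[t].append(row_of.get(t, MISSING * a.length))
        partitions.append((a.gene, pos, pos + a.length - 1))
        pos += a.length
    return Supermatrix(taxa, {t: "".join(p) for t, p in pieces.items()}, partitions)


# --- writers / readers -------------------------------------------------------


def write_fasta(sm: Supermatrix) -> str:
    return "".join(f">{t}\n{sm.matrix[t]}\n" for t in sm.taxa)


def write_phylip(sm: Supermatrix) -> str:
    """Relaxed PHYLIP (names of any length, one space separator)."""
    lines = [f" {len(sm.taxa)} {sm.length}"]
    width = max(len(t) for t in sm.taxa) + 2
    for t in sm.taxa:
        lines.append(f"{t:<{width}}{sm.matrix[t]}")
    return "\n".join(lines) + "\n"


def read_phylip(text: str) -> Supermatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n, length = (int(x) for x in lines[0].split())
    taxa, matrix = [], {}
    for ln in lines[1 : n + 1]:
        name, seq = ln.split(None, 1)
        taxa.append(name)
        matrix[name] = seq.replace(" ", "")
        if len(matrix[name]) != length:
            raise ValueError(f"{name}: row length != {length}")
    return Supermatrix(taxa, matrix, [("all", 1, length)])


def write_nexus(sm: Supermatrix) -> str:
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={len(sm.taxa)} NCHAR={sm.length};",
        "  FORMAT DATATYPE=DNA MISSING=? GAP=-;",
        "  MATRIX",
    ]
    width = max(len(t) for t in sm.taxa) + 2
    for t in sm.taxa:
        lines.append(f"    {t:<{width}}{sm.matrix[t]}")
    lines += ["  ;", "END;", "", "BEGIN SETS;"]
    for gene, start, end in sm.partitions:
        lines.append(f"  CHARSET {gene} = {start}-{end};")
    lines += ["END;"]
    return "\n".join(lines) + "\n"


def read_nexus(text: str) -> Supermatrix:
    taxa, matrix, partitions = [], {}, []
    in_matrix = False
    for raw in text.splitlines():
        line = raw.strip()
        if line.upper() == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if line == ";":
                in_matrix = False
                continue
            if line:
                name, seq = line.split(None, 1)
                taxa.append(name)
                matrix[name] = seq.replace(" ", "")
        m = re.match(r"CHARSET\s+(\S+)\s*=\s*(\d+)-(\d+);", line, re.I)
        if m:
            partitions.append((m.group(1), int(m.group(2)), int(m.group(3))))
    if not partitions and matrix:
        partitions = [("all", 1, len(next(iter(matrix.values()))))]
    return Supermatrix(taxa, matrix, partitions)


def write_raxml_partitions(sm: Supermatrix) -> str:
    return "".join(f"DNA, {g} = {s}-{e}\n" for g, s, e in sm.partitions)
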