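"""Mitogenome annotation model: feature tables, circular coordinate
arithmetic, intergenic-nucleotide accounting and annotation validation.

Coordinates are 1-based and fully inclusive throughout (a feature spanning
13380-14151 is 772 bp).  A feature whose ``end`` is smaller than its
``start`` wraps across the origin of a circular genome.  Features printed
as "n.d." in a feature table are retained as *unlocated* placeholders so
reports can state that a gene was not located; they are excluded from all
coordinate arithmetic.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from Bio.Seq import Seq

START_CODONS = frozenset({"ATT", "ATG", "ATA", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "T--", "TA-"})

_DASHES = re.compile(r"[–—−-]")
_MISSING = {"", "-", "n.d.", "nd", "na", "n/a", "."}


class FeatureKind(str, Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL = "control"


@dataclass
class GeneFeature:
    """One annotated feature of the mitogenome.

    ``strand`` is ``J`` (majority) or ``N`` (minority); the control region
    carries no strand.  ``stop_codon`` may be an incomplete terminal codon
    written ``T--`` or ``TA-``, completed to UAA by polyadenylation.
    """

    name: str
    kind: FeatureKind
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None  # "J", "N" or None
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    printed_size: Optional[int] = None
    printed_ign: Optional[int] = None

    @property
    def located(self) -> bool:
        return self.start is not None and self.end is not None

    @property
    def wraps(self) -> bool:
        """True when the feature spans the circular origin."""
        return self.located and self.end < self.start

    def validate(self) -> None:
        if self.located:
            if self.start < 1 or self.end < 1:
                raise ValueError(f"{self.name}: coordinates must be >= 1")
        if self.strand is not None and self.strand not in ("J", "N"):
            raise ValueError(f"{self.name}: strand must be J or N, got {self.strand!r}")
        if self.strand is None and self.located and self.kind is not FeatureKind.CONTROL:
            raise ValueError(f"{self.name}: only control regions may lack a strand")
        if self.located and self.kind is FeatureKind.TRNA and not self.anticodon:
            raise ValueError(f"{self.name}: tRNA features require an anticodon")
        if self.anticodon and self.kind is not FeatureKind.TRNA:
            raise ValueError(f"{self.name}: anticodon given for non-tRNA feature")


@dataclass
class MitogenomeAnnotation:
    """Ordered feature list (genome order) over a circular or linear genome."""

    features: list[GeneFeature]
    genome_length: int
    circular: bool = True

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        names = [f.name for f in self.features]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate feature names: {sorted(dup)}")
        for f in self.features:
            f.validate()
            if f.located and (f.start > self.genome_length or f.end > self.genome_length):
                raise ValueError(
                    f"{f.name}: coordinates exceed genome length {self.genome_length}"
                )

    @property
    def located_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.located]

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_kind(self, kind: FeatureKind) -> list[GeneFeature]:
        return [f for f in self.features if f.kind is kind]


@dataclass(frozen=True)
class IntergenicGap:
    """Spacing between adjacent located features; negative = overlap."""

    upstream: str
    downstream: str
    gap_bp: int
    closing: bool = False  # True for the circular closing pair


@dataclass(frozen=True)
class Finding:
    severity: str  # "info", "warning", "mismatch"
    feature: str
    message: str


def infer_kind(name: str) -> FeatureKind:
    low = name.lower()
    if low.startswith("trna") or low.startswith("trn"):
        return FeatureKind.TRNA
    if "rrna" in low or re.match(r"^1[26]\s*s", low):
        return FeatureKind.RRNA
    if "at-rich" in low or "control" in low or "d-loop" in low:
        return FeatureKind.CONTROL
    return FeatureKind.PCG


def _clean(cell: str) -> Optional[str]:
    cell = cell.strip()
    return None if cell.lower() in _MISSING else cell


def _parse_int(cell: str) -> int:
    # tolerate thousands separators and the Unicode minus sign
    return int(cell.replace(",", "").replace("−", "-").strip())


def _parse_coordinates(cell: str, row_label: str) -> tuple[int, int]:
    text = cell.replace(",", "").strip()
    parts = [p for p in _DASHES.split(text) if p.strip()]
    if len(parts) != 2:
        raise ValueError(f"row {row_label!r}: malformed coordinate string {cell!r}")
    try:
        start, end = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValueError(f"row {row_label!r}: malformed coordinate string {cell!r}") from exc
    return start, end


_HEADER_ALIASES = {
    "gene/region": "name", "gene": "name", "region": "name", "feature": "name",
    "code": "code",
    "coordinates": "coordinates", "position": "coordinates",
    "strand": "strand",
    "size": "size", "size (bp)": "size", "length": "size",
    "anticodon": "anticodon",
    "start": "start", "start codon": "start",
    "stop": "stop", "stop codon": "stop",
    "ign": "ign",
}


def parse_feature_table(
    table_text: str,
    genome_length: Optional[int] = None,
    circular: bool = True,
) -> MitogenomeAnnotation:
    """Parse a tab- or comma-separated feature table.

    The dialect follows the conventional printed mitogenome annotation
    table: columns Gene/Region, Code, Coordinates ("start-end", en-dash or
    hyphen, thousands separators allowed), Strand (J/N), Size, Anticodon,
    Start, Stop, IGN; Size and IGN are optional and, when present, are kept
    only for cross-checking (gaps and sizes are always recomputed from the
    coordinates).  Rows whose coordinates read "n.d." become unlocated
    placeholder features.
    """
    text = table_text.strip()
    if not text:
        raise ValueError("empty feature table")
    lines = text.splitlines()
    delimiter = "\t" if "\t" in lines[0] else ","
    rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    header = [h.strip().lower() for h in rows[0]]
    cols = {}
    for i, h in enumerate(header):
        key = _HEADER_ALIASES.get(h)
        if key is None and h.startswith("size"):
            key = "size"
        if key is not None and key not in cols:
            cols[key] = i
    if "name" not in cols or "coordinates" not in cols:
        raise ValueError("feature table must have Gene/Region and Coordinates columns")
    body = [r for r in rows[1:] if any(c.strip() for c in r)]
    if not body:
        raise ValueError("feature table has no data rows")

    def get(row: list[str], key: str) -> Optional[str]:
        i = cols.get(key)
        if i is None or i >= len(row):
            return None
        return _clean(row[i])

    features: list[GeneFeature] = []
    for row in body:
        name = get(row, "name")
        if name is None:
            raise ValueError(f"row without a feature name: {row!r}")
        kind = infer_kind(name)
        coords = get(row, "coordinates")
        start = end = None
        if coords is not None:
            start, end = _parse_coordinates(coords, name)
        strand = get(row, "strand")
        size_cell = get(row, "size")
        ign_cell = get(row, "ign")
        features.append(
            GeneFeature(
                name=name,
                kind=kind,
                start=start,
                end=end,
                strand=strand,
                anticodon=get(row, "anticodon"),
                start_codon=get(row, "start"),
                stop_codon=get(row, "stop"),
                printed_size=_parse_int(size_cell) if size_cell else None,
                printed_ign=_parse_int(ign_cell) if ign_cell else None,
            )
        )
    if genome_length is None:
        located = [f for f in features if f.located]
        if not located:
            raise ValueError("no located features and no genome_length given")
        genome_length = max(max(f.start, f.end) for f in located)
    return MitogenomeAnnotation(features, genome_length, circular)


def serialize_feature_table(ann: MitogenomeAnnotation) -> str:
    """Write the annotation back in the tab-separated feature-table dialect."""
    out = ["Gene/Region\tCode\tCoordinates\tStrand\tSize (bp)\tAnticodon\tStart\tStop\tIGN"]
    for f in ann.features:
        if f.located:
            coords = f"{f.start}-{f.end}"
            size = str(feature_length(f, ann))
            strand = f.strand or "-"
        else:
            coords = size = "n.d."
            strand = "n.d."
        out.append(
            "\t".join(
                [
                    f.name,
                    "-",
                    coords,
                    strand,
                    size,
                    f.anticodon or "-",
                    f.start_codon or "-",
                    f.stop_codon or "-",
                    str(f.printed_ign) if f.printed_ign is not None else "-",
                ]
            )
        )
    return "\n".join(out) + "\n"


def feature_length(f: GeneFeature, ann: MitogenomeAnnotation) -> int:
    """Length in bp under 1-based inclusive coordinates, wrap-aware."""
    if not f.located:
        raise ValueError(f"{f.name}: feature is not located")
    if f.wraps:
        if not ann.circular:
            raise ValueError(f"{f.name}: wrapping feature on a linear genome")
        return ann.genome_length - f.start + 1 + f.end
    return f.end - f.start + 1


def intergenic_gaps(ann: MitogenomeAnnotation) -> list[IntergenicGap]:
    """Gap (negative = overlap) between each adjacent pair of located
    features in genome order, plus the circular closing pair."""
    feats = ann.located_features
    if len(feats) < 2:
        raise ValueError("need at least two located features")
    gaps = []
    for up, down in zip(feats, feats[1:]):
        gaps.append(IntergenicGap(up.name, down.name, down.start - up.end - 1))
    if ann.circular:
        first, last = feats[0], feats[-1]
        gap = first.start + ann.genome_length - last.end - 1
        gaps.append(IntergenicGap(last.name, first.name, gap, closing=True))
    return gaps


def gap_summary(gaps: Iterable[IntergenicGap]) -> dict:
    """Count and total of strictly positive gaps, plus the largest gap."""
    gaps = list(gaps)
    positive = [g for g in gaps if g.gap_bp > 0]
    largest = max(gaps, key=lambda g: g.gap_bp)
    return {
        "n_positive_regions": len(positive),
        "total_intergenic_bp": sum(g.gap_bp for g in positive),
        "total_overlap_bp": -sum(g.gap_bp for g in gaps if g.gap_bp < 0),
        "largest_gap_bp": largest.gap_bp,
        "largest_gap_between": (largest.upstream, largest.downstream),
    }


def extract_feature_sequence(genome: str, f: GeneFeature) -> str:
    """Sense-strand sequence of a feature.

    J-strand features are a verbatim slice; N-strand features are
    reverse-complemented; features wrapping the origin concatenate the tail
    and head of the genome before orientation.
    """
    if not f.located:
        raise ValueError(f"{f.name}: feature is not located")
    L = len(genome)
    if f.start > L or f.end > L:
        raise ValueError(f"{f.name}: coordinates exceed genome length {L}")
    if f.wraps:
        raw = genome[f.start - 1 :] + genome[: f.end]
    else:
        raw = genome[f.start - 1 : f.end]
    if f.strand == "N":
        return str(Seq(raw).reverse_complement())
    return raw


def validate_annotation(
    ann: MitogenomeAnnotation, genome: Optional[str] = None
) -> list[Finding]:
    """Report-based consistency checks (never raises on content problems).

    For every protein-coding gene the declared start codon must be one of
    ATT/ATG/ATA/TTG and the declared stop one of TAA/TAG or the truncated
    forms T--/TA-.  With a genome supplied, declared codons are also
    checked against the extracted sense-strand sequence, and truncated
    stops against the expected length residue mod 3.
    """
    findings: list[Finding] = []
    for f in ann.features:
        if not f.located:
            findings.append(Finding("info", f.name, "feature not located (n.d.)"))
            continue
        if f.kind is not FeatureKind.PCG:
            continue
        if f.start_codon and f.start_codon.upper() not in START_CODONS:
            findings.append(
                Finding("warning", f.name, f"unusual start codon {f.start_codon}")
            )
        stop = (f.stop_codon or "").upper()
        if stop and stop not in STOP_CODONS:
            findings.append(Finding("warning", f.name, f"unusual stop codon {stop}"))
        length = feature_length(f, ann)
        if stop in ("T--", "TA-"):
            expected_rem = 1 if stop == "T--" else 2
            findings.append(
                Finding("info", f.name, f"incomplete stop codon {stop}")
            )
            if length % 3 != expected_rem:
                findings.append(
                    Finding(
                        "warning",
                        f.name,
                        f"length {length} mod 3 = {length % 3}, inconsistent with stop {stop}",
                    )
                )
        if genome is not None:
            seq = extract_feature_sequence(genome, f).upper()
            if f.start_codon and seq[:3] != f.start_codon.upper():
                findings.append(
                    Finding(
                        "mismatch",
                        f.name,
                        f"declared start {f.start_codon} != extracted {seq[:3]}",
                    )
                )
            if stop in ("TAA", "TAG") and seq[-3:] != stop:
                findings.append(
                    Finding(
                        "mismatch",
                        f.name,
                        f"declared stop {stop} != extracted {seq[-3:]}",
                    )
                )
            elif stop == "T--" and not seq.endswith("T"):
                findings.append(
                    Finding("mismatch", f.name, f"declared stop T-- but sequence ends {seq[-1]}")
                )
            elif stop == "TA-" and not seq.endswith("TA"):
                findings.append(
                    Finding("mismatch", f.name, f"declared stop TA- but sequence ends {seq[-2:]}")
                )
    return findings


def write_gff3(ann: MitogenomeAnnotation, seqid: str = "mitogenome") -> str:
    """GFF3 export (1-based inclusive; strand J -> ``+``, N -> ``-``).

    Wrapping features are written as a single record with end beyond
    genome_length, the common convention for circular genomes.
    """
    type_of = {
        FeatureKind.PCG: "gene",
        FeatureKind.TRNA: "tRNA",
        FeatureKind.RRNA: "rRNA",
        FeatureKind.CONTROL: "region",
    }
    lines = ["##gff-version 3", f"##sequence-region {seqid} 1 {ann.genome_length}"]
    for f in ann.located_features:
        end = f.end + ann.genome_length if f.wraps else f.end
        strand = {"J": "+", "N": "-"}.get(f.strand or "", ".")
        attrs = f"ID={f.name.replace(' ', '_')};Name={f.name}"
        lines.append(
            "\t".join(
                [seqid, "mitochar", type_of[f.kind], str(f.start), str(end), ".", strand, ".", attrs]
            )
        )
    return "\n".join(lines) + "\n"
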