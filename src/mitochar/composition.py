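"""Nucleotide composition and strand-skew statistics.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C), computed on
the sense (coding) strand of each feature so that signs are always
self-consistent with the reported strand.  IUPAC ambiguity codes count
toward region size but are excluded from the percentage denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd

from .annotation import FeatureKind, GeneFeature, MitogenomeAnnotation, extract_feature_sequence


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionSummary:
    region: str
    strand_reported: Optional[str]  # "J", "N", "J+N" or None
    a_pct: float
    c_pct: float
    g_pct: float
    t_pct: float
    at_pct: float
    gc_pct: float
    at_skew: Optional[float]  # None when A+T = 0
    gc_skew: Optional[float]  # None when G+C = 0
    size_bp: int
    pct_of_total: Optional[float] = None

    def rounded(self, ndigits: int = 2) -> dict:
        out = {"region": self.region, "strand": self.strand_reported, "size_bp": self.size_bp}
        for k in ("a_pct", "c_pct", "g_pct", "t_pct", "at_pct", "gc_pct", "at_skew", "gc_skew", "pct_of_total"):
            v = getattr(self, k)
            out[k] = round_half_up(v, ndigits) if v is not None else None
        return out


def base_composition(
    seq: str,
    region_name: str = "",
    strand_reported: Optional[str] = None,
    total_bp: Optional[int] = None,
) -> CompositionSummary:
    """Composition summary of one sequence (case-insensitive)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T") + s.count("U")
    unamb = a + c + g + t
    if unamb:
        a_pct, c_pct, g_pct, t_pct = (100.0 * x / unamb for x in (a, c, g, t))
    else:
        a_pct = c_pct = g_pct = t_pct = 0.0
    return CompositionSummary(
        region=region_name,
        strand_reported=strand_reported,
        a_pct=a_pct,
        c_pct=c_pct,
        g_pct=g_pct,
        t_pct=t_pct,
        at_pct=a_pct + t_pct,
        gc_pct=g_pct + c_pct,
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
        size_bp=len(s),
        pct_of_total=100.0 * len(s) / total_bp if total_bp else None,
    )


_DEFAULT_GROUPS = (
    ("PCGs (J)", FeatureKind.PCG, "J"),
    ("PCGs (N)", FeatureKind.PCG, "N"),
    ("Total PCGs", FeatureKind.PCG, None),
    ("Total rRNAs", FeatureKind.RRNA, None),
    ("Total tRNAs", FeatureKind.TRNA, None),
)


def composition_report(
    genome: str,
    ann: MitogenomeAnnotation,
    groups: Optional[list[tuple[str, list[str]]]] = None,
) -> list[CompositionSummary]:
    """One row per located feature plus aggregate rows.

    Default aggregates: protein-coding genes by strand and combined, all
    rRNAs, all tRNAs, and the whole genome.  Aggregates are computed on the
    concatenation of the members' sense-strand sequences.  ``groups`` may
    supply extra (name, [feature names]) aggregates; unlocated members are
    skipped.
    """
    total = ann.genome_length
    rows: list[CompositionSummary] = []

    def sense(f: GeneFeature) -> str:
        return extract_feature_sequence(genome, f)

    for f in ann.located_features:
        rows.append(base_composition(sense(f), f.name, f.strand, total))

    def aggregate(name: str, members: list[GeneFeature]) -> None:
        members = [m for m in members if m.located]
        if not members:
            return
        strands = {m.strand for m in members if m.strand}
        label = strands.pop() if len(strands) == 1 else "J+N"
        rows.append(base_composition("".join(sense(m) for m in members), name, label, total))

    for name, kind, strand in _DEFAULT_GROUPS:
        aggregate(name, [f for f in ann.by_kind(kind) if strand is None or f.strand == strand])
    for name, member_names in groups or []:
        feats = []
        for n in member_names:
            f = ann.feature(n)
            if f.located:
                feats.append(f)
        aggregate(name, feats)
    rows.append(base_composition(genome, "Mitogenome", None, total))
    return rows


def composition_table(rows: list[CompositionSummary], ndigits: int = 2) -> pd.DataFrame:
    """Report table in the conventional column order, display-rounded."""
    df = pd.DataFrame([r.rounded(ndigits) for r in rows])
    return df[
        ["region", "strand", "a_pct", "c_pct", "g_pct", "t_pct",
         "at_pct", "gc_pct", "at_skew", "gc_skew", "size_bp", "pct_of_total"]
    ]
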