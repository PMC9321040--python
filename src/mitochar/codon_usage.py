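"""Codon-usage bias indices for mitochondrial protein-coding genes.

Implements sense-codon counting under a mitochondrial genetic code and the
classic bias statistics:

* RSCU (relative synonymous codon usage): observed codon count divided by
  its expectation under equal use within its synonymous family,
  ``RSCU(c) = n_c * k / n_family`` for a k-fold family.
* ENC (effective number of codons, Wright 1990), generalized to the
  degeneracy-class structure of the code in use.  For the invertebrate
  mitochondrial code (twelve 2-fold, six 4-fold, one 6-fold, one 8-fold
  families) the attainable range is 20 (one codon per amino acid) to 62
  (uniform use of all sense codons).
* CBI (codon bias index, Bennetzen & Hall 1982): excess usage of a set of
  "optimal" codons over random expectation.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Optional, Sequence

import pandas as pd

from .codes import GeneticCode, as_rna

VALID_RNA = frozenset("ACGU")


@dataclass
class CodonCountTable:
    """Sense-codon counts pooled over a set of coding sequences."""

    counts: dict[str, int]
    source_genes: list[str] = field(default_factory=list)
    internal_stops: list[tuple[str, int, str]] = field(default_factory=list)
    # (gene, 1-based codon index, codon) for in-frame premature stops

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(as_rna(codon), 0)


@dataclass
class RscuTable:
    rscu: dict[str, Optional[float]]  # None when the family is unobserved

    def __getitem__(self, codon: str) -> Optional[float]:
        return self.rscu[as_rna(codon)]


@dataclass
class ThirdPositionProfile:
    """Preferred/rare codon tallies and per-codon AT3/CG3 labels."""

    n_rscu_gt1: int
    n_rscu_lt1: int
    n_ties: int
    n_undefined: int
    n_lt1_gc3: int
    per_codon: pd.DataFrame  # codon, aa, count, rscu, third_base, third_class


def count_codons(
    cds_list: Sequence[str],
    code: GeneticCode,
    gene_names: Optional[Sequence[str]] = None,
) -> CodonCountTable:
    """Count sense codons over sense-strand CDS sequences.

    Reading is in consecutive non-overlapping triplets from the first
    position.  A trailing incomplete codon of 1-2 nt (a truncated stop
    completed by polyadenylation) is discarded, as is a complete terminal
    stop codon.  Internal stop codons are excluded from the counts and
    recorded as findings.  Codons containing ambiguity codes or gaps are
    skipped.  DNA or RNA input is accepted.
    """
    if not cds_list:
        raise ValueError("empty gene list")
    names = list(gene_names) if gene_names is not None else [
        f"gene{i + 1}" for i in range(len(cds_list))
    ]
    counts: Counter[str] = Counter()
    internal: list[tuple[str, int, str]] = []
    for name, seq in zip(names, cds_list):
        rna = as_rna(seq)
        if len(rna) < 3:
            raise ValueError(f"{name}: sequence shorter than one codon")
        codons = [rna[i : i + 3] for i in range(0, len(rna) - len(rna) % 3, 3)]
        if codons and codons[-1] in code.stop_codons:
            codons.pop()
        for i, codon in enumerate(codons):
            if not set(codon) <= VALID_RNA:
                continue
            if codon in code.stop_codons:
                internal.append((name, i + 1, codon))
                continue
            counts[codon] += 1
    return CodonCountTable(dict(counts), names, internal)


def rscu(counts: CodonCountTable, code: GeneticCode) -> RscuTable:
    """RSCU for every sense codon; None for codons of unobserved families."""
    values: dict[str, Optional[float]] = {}
    for aa, family in code.family_of.items():
        total = sum(counts[c] for c in family)
        k = len(family)
        for c in family:
            values[c] = counts[c] * k / total if total else None
    return RscuTable(values)


def enc(counts: CodonCountTable, code: GeneticCode) -> float:
    """Wright's effective number of codons on this code's family structure.

    Per amino acid with family total n >= 2, the codon homozygosity is
    F = (n * sum(p_i^2) - 1) / (n - 1); F is averaged within each
    degeneracy class k and ENC = sum_k N_k / Fbar_k with N_k the number of
    amino acids in class k.  Estimates exceeding the number of sense
    codons are clamped to it, as is conventional.
    """
    class_F: dict[int, list[float]] = {}
    for aa, family in code.family_of.items():
        n = sum(counts[c] for c in family)
        if n < 2:
            continue
        s = sum((counts[c] / n) ** 2 for c in family)
        F = (n * s - 1) / (n - 1)
        class_F.setdefault(len(family), []).append(F)
    classes = code.degeneracy_classes
    value = 0.0
    for k, aas in classes.items():
        fs = class_F.get(k)
        if not fs:
            raise ValueError(
                f"ENC undefined: no amino acid of degeneracy {k} has >= 2 codons observed"
            )
        fbar = fmean(fs)
        if fbar <= 0:
            raise ValueError(f"ENC undefined: mean homozygosity of class {k} is 0")
        value += len(aas) / fbar
    n_sense = len(code.sense_codons)
    return min(value, float(n_sense))


def optimal_codons(
    counts: CodonCountTable, code: GeneticCode, rule: str = "rscu_gt1"
) -> frozenset[str]:
    """Optimal-codon set for CBI.

    ``rscu_gt1``: every codon with RSCU strictly above 1 (default).
    ``most_frequent``: the single most used codon per observed family,
    alphabetical tie-break.
    """
    if rule == "rscu_gt1":
        table = rscu(counts, code)
        return frozenset(c for c, v in table.rscu.items() if v is not None and v > 1)
    if rule == "most_frequent":
        best = set()
        for family in code.family_of.values():
            if sum(counts[c] for c in family) == 0:
                continue
            best.add(max(sorted(family), key=lambda c: counts[c]))
        return frozenset(best)
    raise ValueError(f"unknown optimal-codon rule {rule!r}")


def cbi(
    counts: CodonCountTable,
    code: GeneticCode,
    optimal_rule: str = "rscu_gt1",
) -> float:
    """Codon bias index: (N_opt - N_rand) / (N_tot - N_rand).

    N_opt is the usage of the optimal codons, N_rand the usage expected if
    each amino acid's codons were used uniformly, and N_tot the total usage
    of synonymously degenerate amino acids.  0 means uniform synonymous
    usage; 1 means only optimal codons are used.
    """
    opt = optimal_codons(counts, code, optimal_rule)
    n_tot = n_opt = 0
    n_rand = 0.0
    for family in code.family_of.values():
        if len(family) < 2:
            continue
        n_aa = sum(counts[c] for c in family)
        k_opt = sum(1 for c in family if c in opt)
        n_tot += n_aa
        n_opt += sum(counts[c] for c in family if c in opt)
        n_rand += n_aa * k_opt / len(family)
    if n_tot == 0 or n_tot == n_rand:
        raise ValueError("CBI undefined: no synonymous usage beyond random expectation basis")
    value = (n_opt - n_rand) / (n_tot - n_rand)
    if not 0.0 <= value <= 1.0:
        clamped = min(max(value, 0.0), 1.0)
        warnings.warn(f"CBI {value:.4f} outside [0, 1]; clamped to {clamped}")
        return clamped
    return value


def third_position_profile(
    counts: CodonCountTable,
    rscu_table: RscuTable,
    code: Optional[GeneticCode] = None,
    strand: Optional[str] = None,
) -> ThirdPositionProfile:
    """Tally preferred (RSCU > 1) and rare (RSCU < 1) codons and, among the
    rare set, those with G or C at the third position; per-codon AT3/CG3
    labels are emitted for plotting-style long tables."""
    records = []
    gt1 = lt1 = ties = undef = lt1_gc3 = 0
    for codon in sorted(rscu_table.rscu):
        v = rscu_table.rscu[codon]
        third = codon[2]
        third_class = "CG3" if third in "GC" else "AT3"
        if v is None:
            undef += 1
        elif v > 1:
            gt1 += 1
        elif v < 1:
            lt1 += 1
            if third in "GC":
                lt1_gc3 += 1
        else:
            ties += 1
        records.append(
            {
                "codon": codon,
                "aa": code.codon_to_aa[codon] if code else None,
                "count": counts[codon],
                "rscu": v,
                "third_base": third,
                "third_class": third_class,
                "strand": strand,
            }
        )
    return ThirdPositionProfile(gt1, lt1, ties, undef, lt1_gc3, pd.DataFrame(records))


def codon_usage_table(
    counts: CodonCountTable, code: GeneticCode, ndigits: int = 2
) -> pd.DataFrame:
    """Long-form codon/amino-acid/count/RSCU report table."""
    from .composition import round_half_up

    table = rscu(counts, code)
    rows = []
    for codon in code.sense_codons:
        v = table[codon]
        rows.append(
            {
                "codon": codon,
                "aa": code.codon_to_aa[codon],
                "count": counts[codon],
                "rscu": round_half_up(v, ndigits) if v is not None else None,
            }
        )
    return pd.DataFrame(rows)
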