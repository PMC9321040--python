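"""Synthetic mitogenomes, coding sequences and barcode haplotype samples
with known ground truth.

The generator's defaults mirror the study system: a circular ~15.5 kb
mitogenome with the ancestral arthropod gene order, whole-genome A+T
around 0.76, codon usage sampled in proportion to the weevil's observed
codon counts, and barcode samples of 23 specimens collapsing to 4
haplotypes one mutational step apart.  Randomness is seed-scoped per
operation, so tests are order-independent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotation import FeatureKind, GeneFeature, MitogenomeAnnotation
from .codes import GeneticCode, as_dna

START_CODONS = ("ATT", "ATG", "ATA", "TTG")
DNA = np.array(list("ACGT"))


def _default_gene_order() -> tuple[tuple[str, str, str | None, int], ...]:
    """(name, kind, strand, length) tuples in the ancestral arthropod
    order, with the reference annotation's located feature sizes."""
    from . import reference
    from .annotation import feature_length

    ann = reference.reference_annotation()
    return tuple(
        (f.name, f.kind.value, f.strand, feature_length(f, ann))
        for f in ann.located_features
    )


def _default_codon_profile() -> dict[str, float]:
    from . import reference

    counts = reference.reference_codon_counts()
    return {c: float(n) for c, n in counts.counts.items()}


@dataclass
class MitoSimSpec:
    """Parameters of the synthetic study system.

    ``steps_between`` gives the number of mutational steps on each edge of
    the haplotype genealogy (a path or a star); its length must be
    ``n_haplotypes - 1``.
    """

    gene_order: Sequence[tuple[str, str, Optional[str], int]] = field(
        default_factory=_default_gene_order
    )
    at_content: float = 0.76
    codon_profile: dict[str, float] = field(default_factory=_default_codon_profile)
    n_specimens: int = 23
    n_haplotypes: int = 4
    steps_between: Sequence[int] = (1, 1, 1)
    topology: str = "path"  # or "star"
    barcode_length: int = 658
    truncate_stops: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.at_content < 1:
            raise ValueError("at_content must lie in (0, 1)")
        if self.codon_profile and sum(self.codon_profile.values()) <= 0:
            raise ValueError("codon profile weights must sum to > 0")
        if self.n_haplotypes > self.n_specimens:
            raise ValueError("n_haplotypes may not exceed n_specimens")


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, salt]))


def _sample_noncoding(rng: np.random.Generator, length: int, at: float) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(rng.choice(DNA, size=length, p=p))


def _sense_profile(profile: dict[str, float], code: GeneticCode) -> tuple[list[str], np.ndarray]:
    sense = [as_dna(c) for c in code.sense_codons]
    # accept profiles keyed in either alphabet
    rna_keys = {k.upper().replace("T", "U"): v for k, v in profile.items()}
    weights = np.array([rna_keys.get(c.replace("T", "U"), 0.0) for c in sense])
    if weights.sum() <= 0:
        raise ValueError("codon profile assigns no weight to any sense codon")
    return sense, weights / weights.sum()


def _sample_pcg(
    rng: np.random.Generator,
    length: int,
    profile: dict[str, float],
    code: GeneticCode,
    truncate: bool,
) -> tuple[str, str, str]:
    """A sense-strand CDS of exactly ``length`` nt: start codon, body
    sampled from the codon profile, and a (possibly truncated) stop."""
    if length < 6:
        raise ValueError(f"PCG length {length} < 6 is infeasible")
    sense, p = _sense_profile(profile, code)
    r = length % 3
    n_body = length // 3 - (2 if r == 0 else 1)
    start = START_CODONS[rng.integers(len(START_CODONS))]
    body = "".join(rng.choice(sense, size=n_body, p=p)) if n_body else ""
    if r == 0:
        stop_seq = ("TAA", "TAG")[rng.integers(2)]
        stop_label = stop_seq
    elif r == 1:
        if not truncate:
            raise ValueError(f"PCG length {length} needs a truncated stop")
        stop_seq, stop_label = "T", "T--"
    else:
        if not truncate:
            raise ValueError(f"PCG length {length} needs a truncated stop")
        stop_seq, stop_label = "TA", "TA-"
    return start + body + stop_seq, start, stop_label


_ANTICODON = "NNN"  # placeholder anticodon for synthetic tRNAs


def simulate_mitogenome(spec: MitoSimSpec) -> tuple[str, MitogenomeAnnotation]:
    """A circular genome realizing the spec's gene order, with its exact
    annotation.  Features abut (no intergenic spacers), so feature lengths
    tile the genome; N-strand features are stored reverse-complemented."""
    from Bio.Seq import Seq

    rng = _rng(spec.seed, 1)
    code = GeneticCode.invertebrate_mito()
    pos = 1
    chunks: list[str] = []
    features: list[GeneFeature] = []
    for name, kind, strand, length in spec.gene_order:
        kind = FeatureKind(kind)
        start_codon = stop_codon = None
        if kind is FeatureKind.PCG:
            seq, start_codon, stop_codon = _sample_pcg(
                rng, length, spec.codon_profile, code, spec.truncate_stops
            )
        else:
            seq = _sample_noncoding(rng, length, spec.at_content)
        genome_piece = str(Seq(seq).reverse_complement()) if strand == "N" else seq
        chunks.append(genome_piece)
        features.append(
            GeneFeature(
                name=name,
                kind=kind,
                start=pos,
                end=pos + length - 1,
                strand=strand,
                anticodon=_ANTICODON if kind is FeatureKind.TRNA else None,
                start_codon=start_codon,
                stop_codon=stop_codon,
            )
        )
        pos += length
    genome = "".join(chunks)
    return genome, MitogenomeAnnotation(features, len(genome), circular=True)


def simulate_cds_set(
    codon_profile: dict[str, float],
    n_codons: int,
    seed: int,
    n_genes: int = 1,
) -> tuple[list[str], Counter]:
    """Sense-strand CDS set drawn codon-by-codon from a profile.

    Returns the DNA sequences (each ending in a complete TAA stop, which
    the counting routines discard) and the ground-truth histogram of the
    sampled sense codons, in the RNA alphabet.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = _rng(seed, 2)
    code = GeneticCode.invertebrate_mito()
    sense, p = _sense_profile(codon_profile, code)
    draws = rng.choice(sense, size=n_codons, p=p)
    truth = Counter(c.replace("T", "U") for c in draws)
    per_gene = np.array_split(draws, n_genes)
    cds = ["".join(g) + "TAA" for g in per_gene if len(g)]
    return cds, truth


def simulate_barcodes(spec: MitoSimSpec) -> tuple[list[tuple[str, str]], dict]:
    """Aligned barcode sample with a known haplotype structure.

    A root sequence is mutated along a path (hap1 -> hap2 -> ...) or a star
    (root -> each satellite) with the per-edge step counts of
    ``steps_between``, each step at a distinct alignment site.  Every
    haplotype receives at least one specimen; the remainder are assigned
    multinomially.  Returns (id, sequence) records and a truth dict.
    """
    k = spec.n_haplotypes
    if len(spec.steps_between) != max(k - 1, 0):
        raise ValueError("steps_between must have n_haplotypes - 1 entries")
    total_steps = sum(spec.steps_between)
    if total_steps > spec.barcode_length:
        raise ValueError("more mutational steps than sites")
    rng = _rng(spec.seed, 3)
    root = _sample_noncoding(rng, spec.barcode_length, spec.at_content)
    sites = rng.choice(spec.barcode_length, size=total_steps, replace=False)
    haps = [root]
    cursor = 0
    for steps in spec.steps_between:
        base = haps[-1] if spec.topology == "path" else root
        seq = list(base)
        for site in sites[cursor : cursor + steps]:
            alternatives = [b for b in "ACGT" if b != seq[site]]
            seq[site] = alternatives[rng.integers(3)]
        cursor += steps
        haps.append("".join(seq))
    assignment = list(range(k)) + list(rng.integers(k, size=spec.n_specimens - k))
    records = [
        (f"SP{i + 1:02d}", haps[h]) for i, h in enumerate(assignment)
    ]
    freqs = Counter(assignment)
    truth = {
        "haplotypes": haps,
        "frequencies": [freqs[i] for i in range(k)],
        "topology": spec.topology,
        "steps_between": list(spec.steps_between),
        "mutated_sites": sorted(int(s) for s in sites),
    }
    return records, truth
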