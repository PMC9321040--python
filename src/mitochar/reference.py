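"""Bundled reference tables for the olive seed weevil (*Anchonocranus
oleae*) mitogenome, GenBank ON859837: the published annotation table and
the pooled sense-codon counts of its 13 protein-coding genes.

These small text tables let the annotation arithmetic and codon-usage
indices be recomputed without network access; the full genome and barcode
sequences (ON859837, ON504300-ON504321) are not redistributed here and
must be fetched from GenBank for sequence-level analyses.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotation import MitogenomeAnnotation, parse_feature_table
from .codon_usage import CodonCountTable

GENOME_LENGTH = 15497  # bp, from the deposited annotation's last coordinate
MITOGENOME_ACCESSION = "ON859837"
BARCODE_ACCESSIONS = tuple(f"ON504{i}" for i in range(300, 322))


def _read(name: str) -> str:
    return (resources.files("mitochar.data") / name).read_text()


def reference_annotation() -> MitogenomeAnnotation:
    """The published mitogenome annotation (circular, 15,497 bp)."""
    return parse_feature_table(
        _read("anchonocranus_oleae_features.tsv"),
        genome_length=GENOME_LENGTH,
        circular=True,
    )


def reference_codon_counts() -> CodonCountTable:
    """Pooled sense-codon counts over all 13 protein-coding genes."""
    df = pd.read_csv(
        resources.files("mitochar.data") / "anchonocranus_oleae_codon_counts.tsv",
        sep="\t",
    )
    counts = dict(zip(df["codon"], df["count"].astype(int)))
    return CodonCountTable(counts, source_genes=["13 PCGs (pooled)"])
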