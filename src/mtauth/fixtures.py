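"""Packaged reference and haplogroup fixtures.

The reference is a seeded synthetic 16,569 bp circular sequence with the
placeholder base N at position 3107, standing in for the human
mitochondrial reference in offline work.  The haplogroup tree models a
U1a1a-like lineage path (50 diagnostic substitution positions, including
back-mutated ones, plus one defining insertion) with decoy sister branches;
the sample haplotype carries the full path, three private substitutions and
the three conventionally ignored tokens, i.e. 38 variants of which 35 are
counted under the default ignore set.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .haplocall import HaplogroupTree
from .refhap import CircularReference, Haplotype

TARGET_NODE = "U1a1a"
PRIVATE_VARIANTS = ("5480G", "8573A", "16129A")


def _data_path(name: str) -> Path:
    return Path(resources.files("mtauth").joinpath("data", name))


def reference() -> CircularReference:
    """The packaged synthetic rCRS-like circular reference (16,569 bp)."""
    return CircularReference.from_fasta(_data_path("reference.fasta"))


def haplogroup_tree() -> HaplogroupTree:
    return HaplogroupTree.from_tsv(_data_path("haplogroup_tree.tsv"))


def sample_haplotype() -> Haplotype:
    """The 38-variant sample haplotype (full U1a1a path + 3 private
    mutations + the 3107 / 309.1 / 309.2 tokens)."""
    return Haplotype.from_tsv(_data_path("sample_haplotype.tsv"), "reference")


def contaminant_haplotype() -> Haplotype:
    """A reference-lineage contaminant (no differences from the reference)."""
    return Haplotype("reference", ())


def decoy_contaminant_haplotype() -> Haplotype:
    """A near-reference contaminant carrying a few non-diagnostic variants."""
    return Haplotype.from_tsv(_data_path("decoy_contaminant.tsv"), "reference")


def diagnostic_sites() -> list[tuple[int, str]]:
    """All 50 diagnostic substitution positions of the target node."""
    from .contam import read_sites_tsv

    return read_sites_tsv(_data_path("diagnostic_sites.tsv"))


def informative_sites() -> list[tuple[int, str]]:
    """Diagnostic positions whose expected allele differs from the reference
    base — the subset that discriminates against a reference-lineage
    contaminant."""
    ref = reference()
    return [(p, a) for p, a in diagnostic_sites() if a != ref.base_at(p)]
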