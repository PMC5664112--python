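"""Majority-rule consensus calling from a pileup, expressed as a variant table."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .readio import Pileup
from .refhap import (
    DEFAULT_IGNORE,
    DELETED,
    CircularReference,
    Haplotype,
    diff_count,
    haplotype_from_slots,
    write_fasta,
)

DEFAULT_MIN_COV = 10
DEFAULT_MIN_FRAC = 0.7

_VOTE_BASES = "ACGT"


class ConsensusParameterError(ValueError):
    pass


@dataclass
class ConsensusCall:
    """Per-slot consensus calls and the derived haplotype.

    ``calls`` maps (position, insertion_index) to (allele, supporting
    fraction, depth); the allele is a base, the DELETED marker, or N.
    Insertion slots appear only where an inserted base was called.
    """

    reference: CircularReference
    calls: dict[tuple[int, int], tuple[str, float, int]]
    haplotype: Haplotype
    min_cov: int
    min_frac: float

    def sequence(self) -> str:
        """The consensus genome (N where no call was made, deletions removed)."""
        out: list[str] = []
        for pos in range(1, self.reference.length + 1):
            allele = self.calls[(pos, 0)][0]
            if allele != DELETED:
                out.append(allele)
            k = 1
            while (pos, k) in self.calls:
                out.append(self.calls[(pos, k)][0])
                k += 1
        return "".join(out)

    def to_fasta(self, path: str | Path, name: str = "consensus") -> None:
        write_fasta(path, name, self.sequence())


def call_consensus(
    pileup: Pileup,
    ref: CircularReference,
    min_cov: int = DEFAULT_MIN_COV,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> ConsensusCall:
    """Call the majority allele wherever depth and majority fraction suffice.

    At each reference position the top allele among A, C, G, T and deletion
    is called iff depth >= min_cov and its fraction of the depth is
    >= min_frac; otherwise N.  A two-way count tie yields N.  An insertion
    slot is called iff its top base has support >= min_frac of the anchor
    depth and >= min_cov.
    """
    if not 0.5 < min_frac <= 1.0:
        raise ConsensusParameterError(
            f"min_frac must be in (0.5, 1.0], got {min_frac} (majority undefined)"
        )
    if min_cov < 1:
        raise ConsensusParameterError(f"min_cov must be >= 1, got {min_cov}")

    calls: dict[tuple[int, int], tuple[str, float, int]] = {}
    for pos in range(1, ref.length + 1):
        row = pileup.counts[pos]
        depth = int(row.sum())
        candidates = [(int(row[i]), b) for i, b in enumerate(_VOTE_BASES)]
        candidates.append((int(row[5]), DELETED))
        candidates.sort(key=lambda t: -t[0])
        top_n, top_allele = candidates[0]
        if (
            depth < min_cov
            or top_n == 0
            or top_n < min_frac * depth
            or top_n == candidates[1][0]
        ):
            calls[(pos, 0)] = ("N", 0.0 if depth == 0 else top_n / depth, depth)
        else:
            calls[(pos, 0)] = (top_allele, top_n / depth, depth)

    for (pos, k), arr in sorted(pileup.insertions.items()):
        anchor_depth = pileup.depth(pos)
        if anchor_depth == 0:
            continue
        counts = [(int(arr[i]), b) for i, b in enumerate(_VOTE_BASES)]
        counts.sort(key=lambda t: -t[0])
        top_n, top_base = counts[0]
        if (
            top_n >= min_cov
            and top_n >= min_frac * anchor_depth
            and top_n != counts[1][0]
        ):
            # require the run of called insertion indices to be contiguous
            if k == 1 or (pos, k - 1) in calls:
                calls[(pos, k)] = (top_base, top_n / anchor_depth, anchor_depth)

    hap = haplotype_from_slots("consensus", ref, {s: a for s, (a, _, _) in calls.items()})
    return ConsensusCall(ref, calls, hap, min_cov, min_frac)


def variant_table(
    call: ConsensusCall, ignore: Iterable[str] = DEFAULT_IGNORE
) -> tuple[Haplotype, int]:
    """The consensus haplotype and its reference-difference count."""
    return call.haplotype, diff_count(call.haplotype, ignore)


def write_vcf(call: ConsensusCall, path: str | Path, sample: str = "sample") -> None:
    """Minimal VCF 4.2 with insertions as anchored ALT strings."""
    ref = call.reference
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref.name},length={ref.length}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Pileup depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Supporting fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    emitted_ins: set[int] = set()
    for v in call.haplotype:
        if v.kind == "insertion" and v.position in emitted_ins:
            continue
        if v.kind == "substitution":
            ref_a, alt_a, pos = v.ref_allele or ref.base_at(v.position), v.alt_allele, v.position
        elif v.kind == "deletion":
            # anchored on the previous reference base
            pos = v.position - 1 if v.position > 1 else v.position
            ref_a = ref.base_at(pos) + ref.base_at(v.position)
            alt_a = ref.base_at(pos)
        else:  # insertion: anchored ALT collecting the full inserted run
            pos = v.position
            inserted = []
            k = 1
            while (pos, k) in call.calls:
                inserted.append(call.calls[(pos, k)][0])
                k += 1
            ref_a = ref.base_at(pos)
            alt_a = ref_a + "".join(inserted)
        allele, frac, depth = call.calls[(v.position, v.insertion_index)]
        lines.append(
            f"{ref.name}\t{pos}\t.\t{ref_a}\t{alt_a}\t.\tPASS\tDP={depth};AF={frac:.4f}"
        )
        if v.kind == "insertion":
            emitted_ins.add(v.position)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
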