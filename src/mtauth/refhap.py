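"""Circular mitochondrial reference model, forensic variant notation, haplotypes.

Coordinates are 1-based and closed throughout, following forensic mtDNA
convention.  Variants are expressed in the compact forensic notation
``<pos><BASE>`` (substitution), ``<pos>.<k><BASE>`` (k-th inserted base after
``pos``) and ``<pos>DEL`` (deletion of the reference base at ``pos``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
CALL_BASES = frozenset("ACGT")
DELETED = "-"

#: notation tokens excluded by default from reference-difference counts:
#: the reference placeholder position 3107 and the two C-stretch insertion
#: slots 309.1 / 309.2.
DEFAULT_IGNORE = frozenset({"3107", "309.1", "309.2"})

_TOKEN_RE = re.compile(
    r"^(?P<pos>[0-9]+)"
    r"(?:\.(?P<ins>[0-9]+))?"
    r"(?P<allele>[ACGTN]|DEL)"
    r"(?P<back>!)?$",
    re.IGNORECASE,
)


class NotationError(ValueError):
    """Raised for malformed or out-of-range variant notation."""


class VariantConsistencyError(ValueError):
    """Raised when a variant contradicts the reference or another variant."""


@dataclass(frozen=True)
class CircularReference:
    """A 1-based circular nucleotide reference sequence."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        if not bases:
            raise ValueError("reference sequence is empty")
        bad = set(bases) - VALID_BASES
        if bad:
            raise ValueError(f"invalid reference bases: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.bases)

    def wrap(self, pos: int) -> int:
        """Map an arbitrary integer position onto [1, length] (circular)."""
        return (pos - 1) % self.length + 1

    def base_at(self, pos: int) -> str:
        """Reference base at a (possibly wrapping) 1-based position."""
        return self.bases[self.wrap(pos) - 1]

    def fetch(self, start: int, length: int) -> str:
        """Sequence of ``length`` bases starting at 1-based ``start``, wrapping."""
        if length < 0:
            raise ValueError("negative length")
        start0 = self.wrap(start) - 1
        end0 = start0 + length
        if end0 <= self.length:
            return self.bases[start0:end0]
        return self.bases[start0:] + self.bases[: end0 - self.length]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CircularReference":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected a single FASTA record, found {len(records)}")
        rec = records[0]
        return cls(name=rec.id, bases=str(rec.seq).upper())

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(path, self.name, self.bases)


def write_fasta(path: str | Path, name: str, seq: str, width: int = 70) -> None:
    rec = SeqRecord(Seq(seq), id=name, description="")
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file([rec])


@dataclass(frozen=True, order=True)
class Variant:
    """One difference from the reference in forensic coordinates.

    ``insertion_index`` 0 marks a substitution or deletion at ``position``;
    ``k >= 1`` marks the k-th base inserted after ``position``.  ``alt_allele``
    is the DELETED marker for deletions.  ``back_mutation`` flags tree tokens
    with a trailing ``!`` (expected state is the ancestral/reference allele);
    such tokens only appear in haplogroup definitions, never in sample
    haplotypes.
    """

    position: int
    insertion_index: int
    ref_allele: str
    alt_allele: str
    kind: str = field(compare=False)
    back_mutation: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise NotationError(f"position must be >= 1, got {self.position}")
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "substitution":
            if self.insertion_index != 0:
                raise ValueError("substitution requires insertion_index 0")
            if self.alt_allele not in VALID_BASES:
                raise ValueError(f"bad substitution allele {self.alt_allele!r}")
            if self.ref_allele and self.ref_allele == self.alt_allele and not self.back_mutation:
                raise ValueError("substitution ref and alt alleles are identical")
        elif self.kind == "insertion":
            if self.insertion_index < 1:
                raise ValueError("insertion requires insertion_index >= 1")
            if self.ref_allele:
                raise ValueError("insertion must have empty ref allele")
            if self.alt_allele not in VALID_BASES:
                raise ValueError(f"bad inserted base {self.alt_allele!r}")
        else:  # deletion
            if self.insertion_index != 0:
                raise ValueError("deletion requires insertion_index 0")
            if self.alt_allele != DELETED:
                raise ValueError("deletion alt allele must be the DELETED marker")

    @property
    def slot(self) -> tuple[int, int]:
        return (self.position, self.insertion_index)

    def notation(self) -> str:
        return format_notation(self)


def parse_notation(token: str) -> Variant:
    """Parse a forensic notation token into a :class:`Variant`.

    Accepted forms (case-insensitive): ``16129A``, ``3158.1T``, ``5DEL``,
    and haplogroup-tree back-mutation tokens like ``152T!``.
    """
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise NotationError(f"malformed variant token {token!r}")
    pos = int(m.group("pos"))
    if pos < 1:
        raise NotationError(f"position must be >= 1 in token {token!r}")
    allele = m.group("allele").upper()
    ins = m.group("ins")
    back = m.group("back") is not None
    if allele == "DEL":
        if ins is not None:
            raise NotationError(f"deletion cannot carry an insertion index: {token!r}")
        if back:
            raise NotationError(f"back-mutation marker invalid on deletion: {token!r}")
        return Variant(pos, 0, "", DELETED, "deletion")
    if ins is not None:
        k = int(ins)
        if k < 1:
            raise NotationError(f"insertion index must be >= 1 in token {token!r}")
        if back:
            raise NotationError(f"back-mutation marker invalid on insertion: {token!r}")
        return Variant(pos, k, "", allele, "insertion")
    return Variant(pos, 0, "", allele, "substitution", back_mutation=back)


def format_notation(v: Variant) -> str:
    if v.kind == "deletion":
        return f"{v.position}DEL"
    if v.kind == "insertion":
        return f"{v.position}.{v.insertion_index}{v.alt_allele}"
    suffix = "!" if v.back_mutation else ""
    return f"{v.position}{v.alt_allele}{suffix}"


def validate_position(v: Variant, ref: CircularReference) -> None:
    if not 1 <= v.position <= ref.length:
        raise NotationError(
            f"variant position {v.position} outside [1, {ref.length}]"
        )


@dataclass
class Haplotype:
    """An ordered, slot-unique collection of variants against one reference."""

    reference_name: str
    variants: tuple[Variant, ...]

    def __init__(self, reference_name: str, variants: Iterable[Variant]) -> None:
        ordered = tuple(sorted(variants, key=lambda v: v.slot))
        slots = [v.slot for v in ordered]
        if len(set(slots)) != len(slots):
            dupes = sorted({s for s in slots if slots.count(s) > 1})
            raise VariantConsistencyError(f"conflicting variants at slots {dupes}")
        self.reference_name = reference_name
        self.variants = ordered

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def notations(self) -> tuple[str, ...]:
        return tuple(v.notation() for v in self.variants)

    @classmethod
    def from_tokens(cls, reference_name: str, tokens: Iterable[str]) -> "Haplotype":
        return cls(reference_name, (parse_notation(t) for t in tokens))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("notation\tposition\tinsertion_index\tref\talt\tkind\n")
            for v in self.variants:
                fh.write(
                    f"{v.notation()}\t{v.position}\t{v.insertion_index}\t"
                    f"{v.ref_allele}\t{v.alt_allele}\t{v.kind}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, reference_name: str = "ref") -> "Haplotype":
        variants = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            try:
                col = header.index("notation")
            except ValueError as exc:
                raise ValueError(f"{path}: missing 'notation' column") from exc
            for line in fh:
                if line.strip():
                    variants.append(parse_notation(line.rstrip("\n").split("\t")[col]))
        return cls(reference_name, variants)


def _ignore_matches(v: Variant, ignore: Iterable[str]) -> bool:
    """True when a variant is covered by any ignore token.

    Ignore tokens may carry an allele (``309.1C`` matches only that exact
    variant) or be bare slots (``3107``, ``309.1``) matching any variant at
    that (position, insertion_index).
    """
    notation = v.notation()
    slot = f"{v.position}" if v.insertion_index == 0 else f"{v.position}.{v.insertion_index}"
    for token in ignore:
        t = token.strip().upper()
        if t == notation or t == slot:
            return True
    return False


def diff_count(hap: Haplotype, ignore: Iterable[str] = ()) -> int:
    """Number of haplotype variants not covered by the ignore set."""
    return sum(1 for v in hap.variants if not _ignore_matches(v, ignore))


def apply_variants(
    ref: CircularReference, hap: Haplotype, with_map: bool = False
) -> str | tuple[str, list[tuple[int, int]]]:
    """Build the sample genome by applying a haplotype to the reference.

    Substitutions replace the reference base, insertions add bases after
    their anchor position (in insertion_index order) and deletions remove the
    reference base.  With ``with_map=True`` also returns, per sample-genome
    base, its reference slot ``(position, insertion_index)`` — insertion_index
    0 for bases aligned to a reference position, k >= 1 for inserted bases.
    """
    by_slot: dict[tuple[int, int], Variant] = {}
    for v in hap.variants:
        if v.back_mutation:
            raise VariantConsistencyError(
                f"back-mutation token {v.notation()} is not applicable to a sample haplotype"
            )
        validate_position(v, ref)
        if v.kind == "substitution" and v.ref_allele:
            actual = ref.base_at(v.position)
            if v.ref_allele != actual:
                raise VariantConsistencyError(
                    f"variant {v.notation()}: recorded ref allele {v.ref_allele} "
                    f"does not match reference base {actual} at {v.position}"
                )
        by_slot[v.slot] = v

    out: list[str] = []
    smap: list[tuple[int, int]] = []
    for pos in range(1, ref.length + 1):
        v = by_slot.get((pos, 0))
        if v is None:
            out.append(ref.bases[pos - 1])
            smap.append((pos, 0))
        elif v.kind == "substitution":
            out.append(v.alt_allele)
            smap.append((pos, 0))
        # deletion: emit nothing
        k = 1
        while (pos, k) in by_slot:
            out.append(by_slot[(pos, k)].alt_allele)
            smap.append((pos, k))
            k += 1
    genome = "".join(out)
    if with_map:
        return genome, smap
    return genome


def haplotype_from_slots(
    reference_name: str,
    ref: CircularReference,
    calls: dict[tuple[int, int], str],
) -> Haplotype:
    """Build a haplotype from per-slot calls (base, DELETED, or N).

    Slots whose call equals the reference base, or is N, emit no variant;
    reference-N positions with a called base emit a substitution.
    """
    variants = []
    for (pos, k), allele in calls.items():
        if k == 0:
            ref_base = ref.base_at(pos)
            if allele == "N" or allele == ref_base:
                continue
            if allele == DELETED:
                variants.append(Variant(pos, 0, ref_base, DELETED, "deletion"))
            else:
                variants.append(Variant(pos, 0, ref_base, allele, "substitution"))
        else:
            if allele in ("N", DELETED):
                continue
            variants.append(Variant(pos, k, "", allele, "insertion"))
    return Haplotype(reference_name, variants)
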