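"""SAM input, duplicate removal, and circular pileup construction."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .refhap import CircularReference

DEFAULT_MIN_MAPQ = 30
DEFAULT_MIN_BASEQ = 20

#: SAM tag carrying the library treatment (UDG / nonUDG / unknown)
LIBRARY_TAG = "YL"
#: SAM tag carrying the part index (1 or 2) of an origin-spanning fragment
PART_TAG = "XC"

_BASE_ORDER = "ACGTN"
_CODE = {b: i for i, b in enumerate(_BASE_ORDER)}
_ENC = np.full(256, 4, dtype=np.uint8)
for _b, _i in _CODE.items():
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SamFormatError(ValueError):
    """Raised for unparseable SAM input or a missing sequence dictionary."""


class CigarError(ValueError):
    """Raised when a CIGAR walks off the reference without a circular link."""


@dataclass
class AlignedRead:
    """One mapped, merged fragment.

    ``bases``/``quals``/``cigar`` are stored in reference orientation (as in
    SAM); ``strand`` records the sequenced orientation.  For fragments that
    span the circular origin and have been re-joined, ``start + ref_span - 1``
    may exceed the reference length; positions are interpreted modulo the
    reference length.
    """

    id: str
    start: int
    strand: str  # "+" or "-"
    bases: str
    quals: tuple[int, ...]
    cigar: tuple[tuple[str, int], ...]
    library_tag: str = "unknown"
    mapq: int = 60
    part: int = 0  # 0: whole fragment; 1/2: segment of an origin-spanning one

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: bases/quals length mismatch")
        if self.strand not in "+-":
            raise ValueError(f"read {self.id}: bad strand {self.strand!r}")

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        """1-based inclusive end on the (unwrapped) reference axis."""
        return self.start + self.ref_span - 1

    @property
    def query_length(self) -> int:
        return len(self.bases)

    def aligned_columns(self) -> list[tuple[int, int, str]]:
        """Yield (position, insertion_index, read_base) per aligned read base.

        Positions are on the unwrapped axis (callers wrap modulo reference
        length).  Leading insertions are anchored at ``start - 1``.
        """
        cols: list[tuple[int, int, str]] = []
        rpos = self.start
        qidx = 0
        for op, n in self.cigar:
            if op == "M":
                for i in range(n):
                    cols.append((rpos + i, 0, self.bases[qidx + i]))
                rpos += n
                qidx += n
            elif op == "I":
                anchor = rpos - 1
                for k in range(1, n + 1):
                    cols.append((anchor, k, self.bases[qidx + k - 1]))
                qidx += n
            elif op == "D":
                rpos += n
            else:
                raise CigarError(f"read {self.id}: unsupported CIGAR op {op!r}")
        return cols


class Pileup:
    """Per-position base/deletion counts on a circular reference, with
    per-(position, insertion_index) counts for inserted bases."""

    BASES = _BASE_ORDER  # column order A,C,G,T,N; deletions in a 6th column

    def __init__(self, ref: CircularReference) -> None:
        self.ref = ref
        self.counts = np.zeros((ref.length + 1, 6), dtype=np.int64)  # 1-based rows
        self.insertions: dict[tuple[int, int], np.ndarray] = {}

    # -- accessors ---------------------------------------------------------
    def base_count(self, pos: int, base: str) -> int:
        return int(self.counts[self.ref.wrap(pos), _CODE[base]])

    def deletion_count(self, pos: int) -> int:
        return int(self.counts[self.ref.wrap(pos), 5])

    def depth(self, pos: int) -> int:
        return int(self.counts[self.ref.wrap(pos)].sum())

    def insertion_counts(self, pos: int, k: int) -> np.ndarray:
        key = (self.ref.wrap(pos), k)
        if key not in self.insertions:
            return np.zeros(5, dtype=np.int64)
        return self.insertions[key]

    def total_bases(self) -> int:
        ins = sum(int(a.sum()) for a in self.insertions.values())
        return int(self.counts[:, :5].sum()) + ins

    # -- construction ------------------------------------------------------
    def add_read(self, read: AlignedRead) -> None:
        L = self.ref.length
        rpos = read.start
        qidx = 0
        for op, n in read.cigar:
            if op == "M":
                idx = (np.arange(rpos - 1, rpos - 1 + n) % L) + 1
                codes = _ENC[np.frombuffer(
                    read.bases[qidx:qidx + n].encode(), dtype=np.uint8)]
                np.add.at(self.counts, (idx, codes), 1)
                rpos += n
                qidx += n
            elif op == "I":
                anchor = self.ref.wrap(rpos - 1)
                for k in range(1, n + 1):
                    base = read.bases[qidx + k - 1]
                    arr = self.insertions.setdefault(
                        (anchor, k), np.zeros(5, dtype=np.int64))
                    arr[_CODE[base]] += 1
                qidx += n
            elif op == "D":
                idx = (np.arange(rpos - 1, rpos - 1 + n) % L) + 1
                np.add.at(self.counts, (idx, 5), 1)
                rpos += n
            else:
                raise CigarError(f"read {read.id}: unsupported CIGAR op {op!r}")

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pos\tins_index\tA\tC\tG\tT\tN\tdel\tdepth\n")
            for pos in range(1, self.ref.length + 1):
                row = self.counts[pos]
                fh.write(
                    f"{pos}\t0\t" + "\t".join(str(int(x)) for x in row)
                    + f"\t{int(row.sum())}\n"
                )
                k = 1
                while (pos, k) in self.insertions:
                    arr = self.insertions[(pos, k)]
                    fh.write(
                        f"{pos}\t{k}\t" + "\t".join(str(int(x)) for x in arr)
                        + f"\t0\t{int(arr.sum())}\n"
                    )
                    k += 1

    @classmethod
    def from_tsv(cls, path: str | Path, ref: CircularReference) -> "Pileup":
        pileup = cls(ref)
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("pos\t"):
                raise ValueError(f"{path}: not a pileup TSV")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                pos, k = int(parts[0]), int(parts[1])
                vals = [int(x) for x in parts[2:8]]
                if k == 0:
                    pileup.counts[pos] = vals
                else:
                    pileup.insertions[(pos, k)] = np.array(vals[:5], dtype=np.int64)
        return pileup


def build_pileup(reads: Iterable[AlignedRead], ref: CircularReference) -> Pileup:
    """Tally every aligned, non-clipped base of ``reads`` into a pileup."""
    pileup = Pileup(ref)
    for read in reads:
        pileup.add_read(read)
    return pileup


def read_alignments(
    path: str | Path,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> list[AlignedRead]:
    """Load mapped reads from a SAM/BAM file.

    Unmapped, secondary and supplementary records are dropped; records below
    ``min_mapq`` are dropped; bases below ``min_baseq`` are masked to N.
    Origin-spanning fragment pairs written by the simulator (tag ``XC``) are
    re-joined into single reads whose span wraps past the reference length.
    """
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except (ValueError, OSError) as exc:
        raise SamFormatError(f"{path}: cannot parse SAM ({exc})") from exc
    with af:
        if af.header.nreferences == 0:
            raise SamFormatError(f"{path}: missing @SQ header line")
        reads: list[AlignedRead] = []
        pending: dict[str, AlignedRead] = {}  # part-1 segments awaiting part 2
        try:
            records = list(af)
        except (ValueError, OSError) as exc:
            raise SamFormatError(f"{path}: malformed SAM record ({exc})") from exc
        for lineno, rec in enumerate(records, start=1):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.query_sequence is None:
                raise SamFormatError(f"{path}: record {lineno} has no sequence")
            quals = rec.query_qualities
            if quals is None:
                quals = [min_baseq] * len(rec.query_sequence)
            bases = "".join(
                b if q >= min_baseq else "N"
                for b, q in zip(rec.query_sequence.upper(), quals)
            )
            cigar = tuple(
                ("MIDNSHP=XB"[op], n) for op, n in (rec.cigartuples or ())
            )
            if any(op not in "MID" for op, _ in cigar):
                raise SamFormatError(
                    f"{path}: record {lineno} ({rec.query_name}) has unsupported CIGAR"
                )
            try:
                library = str(rec.get_tag(LIBRARY_TAG))
            except KeyError:
                library = "unknown"
            part = int(rec.get_tag(PART_TAG)) if rec.has_tag(PART_TAG) else 0
            read = AlignedRead(
                id=rec.query_name,
                start=rec.reference_start + 1,
                strand="-" if rec.is_reverse else "+",
                bases=bases,
                quals=tuple(int(q) for q in quals),
                cigar=cigar,
                library_tag=library,
                mapq=rec.mapping_quality,
                part=part,
            )
            if part == 0:
                reads.append(read)
            elif part == 1:
                pending[read.id] = read
            else:
                first = pending.pop(read.id, None)
                if first is None:
                    raise SamFormatError(
                        f"{path}: part-2 segment {read.id} without part 1"
                    )
                reads.append(_join_parts(first, read))
        if pending:
            raise SamFormatError(
                f"{path}: unmatched origin-spanning segments: {sorted(pending)}"
            )
    return reads


def _join_parts(first: AlignedRead, second: AlignedRead) -> AlignedRead:
    """Re-join the two SAM segments of an origin-spanning fragment."""
    if second.start != 1:
        raise SamFormatError(
            f"{first.id}: part 2 starts at {second.start}, expected 1"
        )
    cigar = list(first.cigar)
    rest = list(second.cigar)
    if cigar and rest and cigar[-1][0] == rest[0][0]:
        op, n = rest.pop(0)
        cigar[-1] = (op, cigar[-1][1] + n)
    return replace(
        first,
        bases=first.bases + second.bases,
        quals=first.quals + second.quals,
        cigar=tuple(cigar + rest),
        part=0,
    )


def deduplicate(
    reads: Sequence[AlignedRead],
) -> tuple[list[AlignedRead], float]:
    """Collapse reads sharing (start, end, strand) to one representative.

    The representative is the read with the highest summed base quality,
    ties broken by lexicographically smallest id.  Returns the retained
    reads (input order) and the duplicate fraction 1 - unique/input
    (0 for empty input).
    """
    best: dict[tuple[int, int, str], AlignedRead] = {}
    for read in reads:
        key = (read.start, read.end, read.strand)
        cur = best.get(key)
        if cur is None:
            best[key] = read
            continue
        if (-sum(read.quals), read.id) < (-sum(cur.quals), cur.id):
            best[key] = read
    kept_ids = {id(r) for r in best.values()}
    kept = [r for r in reads if id(r) in kept_ids]
    fraction = 0.0 if not reads else 1.0 - len(kept) / len(reads)
    return kept, fraction
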