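"""Synthetic ancient-DNA read generation with known truth.

Fragments are drawn from an endogenous or contaminant sample genome (the
contaminant with probability ``c``), with a truncated log-normal length
model, uniform start on the circle, uniform strand, strand-specific terminal
cytosine-deamination damage with geometric decay into the read, optional
UDG attenuation, uniform sequencing error, and Poisson PCR duplication.
Damage is applied before sequencing error (lesion first, miscall second).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from scipy import stats

from .readio import AlignedRead, LIBRARY_TAG, PART_TAG
from .refhap import CircularReference, Haplotype, apply_variants

_A, _C, _G, _T, _N = 0, 1, 2, 3, 4
_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ENC = np.full(256, _N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENC[_b] = _i
_COMP = np.array([_T, _G, _C, _A, _N], dtype=np.uint8)

FRAG_MIN, FRAG_MAX = 25, 150
DEFAULT_QUALITY = 30
DEFAULT_MAPQ = 60


class SimulationParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Simulator truth parameters; all probabilities in [0, 1]."""

    n_fragments: int
    frag_len_mean: float = 70.0
    frag_len_sd: float = 15.0
    contamination: float = 0.0  # c
    delta5: float = 0.0  # P(C->T) at the 5' terminal base
    delta3: float = 0.0  # P(G->A) at the 3' terminal base
    rho: float = 0.5  # geometric decay of damage with distance from the end
    udg_residual: float = 1.0  # u, multiplier on delta5/delta3
    seq_error: float = 0.0  # eps, per-base miscall probability
    duplication_rate: float = 0.0  # Poisson mean of extra copies per fragment
    library: str = "unknown"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments < 1:
            raise SimulationParameterError("n_fragments must be >= 1")
        for name in ("contamination", "delta5", "delta3", "udg_residual", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationParameterError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.rho < 1.0:
            raise SimulationParameterError(f"rho={self.rho} outside (0, 1)")
        if self.frag_len_mean <= 0 or self.frag_len_sd <= 0:
            raise SimulationParameterError("fragment length mean/sd must be positive")
        if self.duplication_rate < 0:
            raise SimulationParameterError("duplication_rate must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    reads: dict[str, dict] = field(default_factory=dict)
    realized_contaminant_fraction: float = 0.0
    realized_mean_fragment_length: float = 0.0
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def truncated_length_mean(params: SimParams) -> float:
    """Mean of the integer-rounded truncated log-normal length model."""
    mu, sigma = _lognormal_params(params.frag_len_mean, params.frag_len_sd)
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    lo, hi = dist.cdf(FRAG_MIN), dist.cdf(FRAG_MAX)
    lengths = np.arange(FRAG_MIN, FRAG_MAX + 1)
    # probability that the continuous draw rounds to each integer length
    edges_lo = np.clip(lengths - 0.5, FRAG_MIN, FRAG_MAX)
    edges_hi = np.clip(lengths + 0.5, FRAG_MIN, FRAG_MAX)
    p = (dist.cdf(edges_hi) - dist.cdf(edges_lo)) / (hi - lo)
    return float(np.sum(lengths * p))


def _sample_lengths(params: SimParams, rng: np.random.Generator, n: int) -> np.ndarray:
    mu, sigma = _lognormal_params(params.frag_len_mean, params.frag_len_sd)
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    lo, hi = dist.cdf(FRAG_MIN), dist.cdf(FRAG_MAX)
    u = lo + rng.random(n) * (hi - lo)
    return np.clip(np.rint(dist.ppf(u)).astype(np.int64), FRAG_MIN, FRAG_MAX)


class _Genome:
    """A sample genome with a per-base map back to reference slots."""

    def __init__(self, ref: CircularReference, hap: Haplotype) -> None:
        seq, smap = apply_variants(ref, hap, with_map=True)
        self.codes = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
        self.pos = np.array([p for p, _ in smap], dtype=np.int64)
        self.ins = np.array([k for _, k in smap], dtype=np.int64)
        self.length = len(seq)
        # genome indices at which the reference-slot walk is non-trivial
        # (inserted base, or a deletion gap to the previous index); fragments
        # avoiding these and the origin take a single-M fast path
        nontrivial = self.ins != 0
        nontrivial[1:] |= np.diff(self.pos) != 1
        self.special = np.flatnonzero(nontrivial)


def _fragment_cigar(
    pos: np.ndarray, ins: np.ndarray, ref_length: int
) -> tuple[int, list[tuple[str, int]]]:
    """CIGAR for a fragment given per-base reference slots.

    Returns (start, cigar) on the unwrapped axis: a fragment crossing the
    origin keeps increasing positions (ref_length + 1, ...) and is split into
    SAM segments only at write time.
    """
    n = len(pos)
    # unwrap origin crossings
    upos = pos.copy()
    wraps = np.flatnonzero(np.diff(pos) < 0)
    for w in wraps:
        upos[w + 1:] += ref_length
    ops: list[tuple[str, int]] = []
    start = None
    prev_ref = None
    for j in range(n):
        if ins[j] > 0:
            ops.append(("I", 1))
            continue
        p = int(upos[j])
        if start is None:
            start = p
        elif prev_ref is not None and p > prev_ref + 1:
            ops.append(("D", p - prev_ref - 1))
        ops.append(("M", 1))
        prev_ref = p
    if start is None:
        raise SimulationParameterError("fragment aligns to no reference position")
    # merge adjacent identical ops
    merged: list[tuple[str, int]] = []
    for op, ln in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return start, merged


def simulate_reads(
    ref: CircularReference,
    endo: Haplotype,
    contam: Haplotype,
    params: SimParams,
) -> tuple[list[AlignedRead], SimTruth]:
    """Generate aligned reads from a two-genome mixture with damage/error.

    Returns logical reads (origin-spanning fragments are kept whole, with
    spans wrapping past the reference length) plus the per-read truth.
    """
    if ref.length <= FRAG_MAX:
        raise SimulationParameterError(
            f"reference length {ref.length} not larger than max fragment {FRAG_MAX}"
        )
    rng = np.random.default_rng(params.seed)
    genomes = (_Genome(ref, endo), _Genome(ref, contam))

    n = params.n_fragments
    origin_contam = rng.random(n) < params.contamination
    lengths = _sample_lengths(params, rng, n)
    start_u = rng.random(n)
    reverse = rng.random(n) < 0.5
    total = int(lengths.sum())
    offs = np.concatenate(([0], np.cumsum(lengths)))
    p5max = params.udg_residual * params.delta5
    p3max = params.udg_residual * params.delta3
    r5 = rng.random(total) if p5max > 0 else None
    r3 = rng.random(total) if p3max > 0 else None
    rerr = rng.random(total) if params.seq_error > 0 else None
    rchoice = rng.integers(0, 3, total) if params.seq_error > 0 else None
    ndup = (
        rng.poisson(params.duplication_rate, n)
        if params.duplication_rate > 0
        else np.zeros(n, dtype=np.int64)
    )

    u = params.udg_residual
    decay_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    reads: list[AlignedRead] = []
    truth = SimTruth(params={**asdict(params)})
    for i in range(n):
        g = genomes[1] if origin_contam[i] else genomes[0]
        L = int(lengths[i])
        s0 = int(start_u[i] * g.length)
        wrapping = s0 + L > g.length
        if wrapping:
            idx = np.arange(s0, s0 + L) % g.length
            frag_ref = g.codes[idx]  # reference-orientation codes
        else:
            frag_ref = g.codes[s0:s0 + L].copy()

        # single-M fast path: fragment touches no insertion/deletion slot
        simple = (
            not wrapping
            and g.ins[s0] == 0
            and np.searchsorted(g.special, s0, side="right")
            == np.searchsorted(g.special, s0 + L - 1, side="right")
        )

        seq = _COMP[frag_ref[::-1]] if reverse[i] else frag_ref

        # terminal deamination, geometric decay from each end
        if L not in decay_cache:
            k = np.arange(L, dtype=np.float64)
            decay_cache[L] = (params.rho ** k, params.rho ** k[::-1])
        d5, d3 = decay_cache[L]
        sl = slice(offs[i], offs[i + 1])
        damage: list[list] = []
        if r5 is not None:
            hit5 = (seq == _C) & (r5[sl] < p5max * d5)
            if hit5.any():
                seq[hit5] = _T
                damage += [[int(j), "CT5"] for j in np.flatnonzero(hit5)]
        if r3 is not None:
            hit3 = (seq == _G) & (r3[sl] < p3max * d3)
            if hit3.any():
                seq[hit3] = _A
                damage += [[int(j), "GA3"] for j in np.flatnonzero(hit3)]

        # sequencing miscalls, uniform over the three other bases
        if rerr is not None:
            err = (rerr[sl] < params.seq_error) & (seq < _N)
            if err.any():
                seq[err] = (seq[err] + 1 + rchoice[sl][err]) % 4

        bases_ref = _COMP[seq[::-1]] if reverse[i] else seq
        if simple:
            start, cigar = int(g.pos[s0]), [("M", L)]
        else:
            start, cigar = _fragment_cigar(g.pos[idx] if wrapping else g.pos[s0:s0 + L],
                                           g.ins[idx] if wrapping else g.ins[s0:s0 + L],
                                           ref.length)
        rid = f"frag{i:07d}"
        read = AlignedRead(
            id=rid,
            start=start,
            strand="-" if reverse[i] else "+",
            bases=_BASES[bases_ref].tobytes().decode(),
            quals=(DEFAULT_QUALITY,) * L,
            cigar=tuple(cigar),
            library_tag=params.library,
            mapq=DEFAULT_MAPQ,
        )
        reads.append(read)
        rec = {
            "origin": "contaminant" if origin_contam[i] else "endogenous",
            "start": start,
            "length": L,
            "strand": read.strand,
            "damage": damage,
            "duplicate_of": None,
        }
        truth.reads[rid] = rec
        for j in range(int(ndup[i])):
            did = f"{rid}_dup{j + 1}"
            reads.append(AlignedRead(
                id=did, start=start, strand=read.strand, bases=read.bases,
                quals=read.quals, cigar=read.cigar,
                library_tag=params.library, mapq=DEFAULT_MAPQ,
            ))
            truth.reads[did] = {**rec, "duplicate_of": rid}

    truth.realized_contaminant_fraction = float(origin_contam.mean())
    truth.realized_mean_fragment_length = float(lengths.mean())
    return reads, truth


def _split_at_origin(read: AlignedRead, ref_length: int) -> list[AlignedRead]:
    """Split a wrapping read into two SAM segments at the circular origin."""
    if read.end <= ref_length:
        return [read]
    ops1: list[tuple[str, int]] = []
    ops2: list[tuple[str, int]] = []
    rpos = read.start
    qidx = 0
    q_split = None
    for op, n in read.cigar:
        consumes_ref = op in "MD"
        consumes_q = op in "MI"
        if consumes_ref and rpos <= ref_length < rpos + n:
            left = ref_length - rpos + 1
            ops1.append((op, left))
            if n - left:
                ops2.append((op, n - left))
            if consumes_q:
                q_split = qidx + left
            rpos += n
            if consumes_q:
                qidx += n
            continue
        target = ops1 if rpos <= ref_length else ops2
        if not consumes_ref and q_split is not None and rpos > ref_length:
            target = ops2
        target.append((op, n))
        if consumes_ref:
            rpos += n
        if consumes_q:
            qidx += n
    if q_split is None:  # wrap point falls inside a deletion
        q_split = sum(n for op, n in ops1 if op in "MI")
    from dataclasses import replace

    part1 = replace(
        read,
        bases=read.bases[:q_split],
        quals=read.quals[:q_split],
        cigar=tuple(ops1),
        part=1,
    )
    part2 = replace(
        read,
        start=1,
        bases=read.bases[q_split:],
        quals=read.quals[q_split:],
        cigar=tuple(ops2),
        part=2,
    )
    return [part1, part2]


def write_sam(
    reads: Sequence[AlignedRead], ref: CircularReference, path: str | Path
) -> None:
    """Write reads as spec-conformant SAM (origin-spanning reads split in two)."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref.name, "LN": ref.length}],
    })
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            for seg in _split_at_origin(read, ref.length):
                rec = pysam.AlignedSegment(header)
                rec.query_name = seg.id
                rec.reference_id = 0
                rec.reference_start = seg.start - 1
                rec.mapping_quality = seg.mapq
                rec.flag = 16 if seg.strand == "-" else 0
                rec.query_sequence = seg.bases
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in seg.quals)
                )
                rec.cigarstring = "".join(f"{n}{op}" for op, n in seg.cigar)
                tags = [(LIBRARY_TAG, seg.library_tag)]
                if seg.part:
                    tags.append((PART_TAG, seg.part))
                rec.set_tags(tags)
                out.write(rec)
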