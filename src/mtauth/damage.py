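"""Misincorporation-by-offset tables and fragment-length statistics.

Only the two damage-diagnostic substitution classes are tabulated: C->T
counted from the 5' end and G->A counted from the 3' end, both in the
read's sequenced orientation (reverse-strand reads are complement-flipped
before counting, so the 5'/3' asymmetry of deamination is preserved).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .readio import AlignedRead, revcomp
from .refhap import CircularReference


class DamageParameterError(ValueError):
    pass


@dataclass
class DamageProfile:
    window: int
    five_prime_opportunities: np.ndarray  # reference-C sites per 5' offset
    five_prime_observations: np.ndarray  # C->T events per 5' offset
    three_prime_opportunities: np.ndarray  # reference-G sites per 3' offset
    three_prime_observations: np.ndarray  # G->A events per 3' offset

    @property
    def five_prime_rates(self) -> np.ndarray:
        return _rates(self.five_prime_observations, self.five_prime_opportunities)

    @property
    def three_prime_rates(self) -> np.ndarray:
        return _rates(self.three_prime_observations, self.three_prime_opportunities)

    @property
    def terminal_ct_rate(self) -> float:
        return float(self.five_prime_rates[0])

    @property
    def terminal_ga_rate(self) -> float:
        return float(self.three_prime_rates[0])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("end\toffset\topportunities\tobservations\trate\n")
            for end, opp, obs, rate in (
                ("5p", self.five_prime_opportunities,
                 self.five_prime_observations, self.five_prime_rates),
                ("3p", self.three_prime_opportunities,
                 self.three_prime_observations, self.three_prime_rates),
            ):
                for k in range(self.window):
                    fh.write(
                        f"{end}\t{k}\t{int(opp[k])}\t{int(obs[k])}\t{rate[k]:.6g}\n"
                    )

    def plot(self, path: str | Path) -> None:
        """Rate-vs-offset curves for both ends (PNG/PDF by extension)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        k = np.arange(self.window)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(k, self.five_prime_rates, "o-", color="firebrick", label="5' C>T")
        ax.plot(k, self.three_prime_rates, "s-", color="steelblue", label="3' G>A")
        ax.set_xlabel("distance from fragment end (bp)")
        ax.set_ylabel("misincorporation rate")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def _rates(obs: np.ndarray, opp: np.ndarray) -> np.ndarray:
    out = np.zeros(len(opp), dtype=float)
    nz = opp > 0
    out[nz] = obs[nz] / opp[nz]
    return out


def _oriented_columns(read: AlignedRead, ref: CircularReference) -> tuple[str, str]:
    """(read_bases, ref_bases) over aligned (M) columns, in sequenced orientation."""
    if len(read.cigar) == 1 and read.cigar[0][0] == "M":
        rb, fb = read.bases, ref.fetch(read.start, read.cigar[0][1])
        if read.strand == "-":
            return revcomp(rb), revcomp(fb)
        return rb, fb
    read_b: list[str] = []
    ref_b: list[str] = []
    rpos = read.start
    qidx = 0
    for op, n in read.cigar:
        if op == "M":
            for i in range(n):
                read_b.append(read.bases[qidx + i])
                ref_b.append(ref.base_at(rpos + i))
            rpos += n
            qidx += n
        elif op == "I":
            qidx += n
        elif op == "D":
            rpos += n
    rb, fb = "".join(read_b), "".join(ref_b)
    if read.strand == "-":
        return revcomp(rb), revcomp(fb)
    return rb, fb


def misincorporation_profile(
    reads: Iterable[AlignedRead], ref: CircularReference, window: int = 25
) -> DamageProfile:
    """Tally C->T (5') and G->A (3') mismatches by distance from the read end.

    Each aligned column whose strand-adjusted reference base is C counts one
    5' opportunity at its offset (an observation if the read base is T);
    symmetrically for G->A from the 3' end.  N read bases are skipped.
    Reads shorter than 2*window contribute to both ends independently.
    """
    if window < 1:
        raise DamageParameterError(f"window must be >= 1, got {window}")
    opp5 = np.zeros(window, dtype=np.int64)
    obs5 = np.zeros(window, dtype=np.int64)
    opp3 = np.zeros(window, dtype=np.int64)
    obs3 = np.zeros(window, dtype=np.int64)
    for read in reads:
        rb, fb = _oriented_columns(read, ref)
        L = len(rb)
        kmax = min(window, L)
        for k in range(kmax):
            if fb[k] == "C" and rb[k] in "ACGT":
                opp5[k] += 1
                if rb[k] == "T":
                    obs5[k] += 1
            j = L - 1 - k
            if fb[j] == "G" and rb[j] in "ACGT":
                opp3[k] += 1
                if rb[j] == "A":
                    obs3[k] += 1
    return DamageProfile(window, opp5, obs5, opp3, obs3)


def fit_geometric_decay(
    profile: DamageProfile, end: str = "five_prime", max_offset: int = 5
) -> tuple[float, float]:
    """Least-squares fit of rate(k) = amplitude * rho**k on log-rates.

    Returns (amplitude, rho) fitted over offsets 0..max_offset with nonzero
    rates.  Requires at least two usable offsets.
    """
    rates = (
        profile.five_prime_rates if end == "five_prime" else profile.three_prime_rates
    )
    k = np.arange(min(max_offset + 1, profile.window))
    rates = rates[: len(k)]
    usable = rates > 0
    if usable.sum() < 2:
        raise DamageParameterError("fewer than two nonzero rates; cannot fit decay")
    slope, intercept = np.polyfit(k[usable], np.log(rates[usable]), 1)
    return float(np.exp(intercept)), float(np.exp(slope))


@dataclass
class FragmentStats:
    n: int
    mean_length: float | None
    median_length: float | None
    histogram: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_length": self.mean_length,
            "median_length": self.median_length,
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
        }


def fragment_length_stats(reads: Iterable[AlignedRead]) -> FragmentStats:
    """Length statistics of the original merged fragments (sequenced bases)."""
    lengths = [read.query_length for read in reads]
    if not lengths:
        return FragmentStats(0, None, None, {})
    arr = np.array(lengths)
    return FragmentStats(
        n=len(lengths),
        mean_length=float(arr.mean()),
        median_length=float(np.median(arr)),
        histogram=dict(sorted(Counter(lengths).items())),
    )
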