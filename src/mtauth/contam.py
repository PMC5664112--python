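"""Contamination estimation.

Two estimators are provided:

* the pooled non-consensus-base rate over haplogroup-diagnostic positions,
  optionally after a damage-aware position filter (sites with a C or G
  consensus allele showing damage-type misincorporations are dropped), with
  Wilson-score or position-bootstrap confidence intervals; and
* a grid maximum-likelihood two-component read-mixture estimator with
  profile-likelihood intervals, cross-checking the first.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .damage import DamageProfile
from .readio import AlignedRead, Pileup
from .refhap import DELETED, CircularReference, Haplotype

_BASE_IDX = {b: i for i, b in enumerate("ACGTN")}
_DAMAGE_PRODUCT = {"C": "T", "G": "A"}


class SiteError(ValueError):
    pass


class CoverageError(ValueError):
    pass


class PanelError(ValueError):
    pass


@dataclass
class ContamEstimate:
    method: str  # diagnostic | diagnostic_filtered | mixture
    rate: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    n_positions: int = 0
    n_bases: int = 0
    n_nonconsensus: int = 0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.ci_low <= self.rate <= self.ci_high:
            raise ValueError(
                f"inconsistent interval: {self.ci_low} <= {self.rate} <= {self.ci_high}"
            )

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = list(self.flags)
        return d


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    centre = phat + z * z / (2 * n)
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    return ((centre - half) / denom, (centre + half) / denom)


def _site_counts(pileup: Pileup, pos: int, expected: str) -> tuple[int, int]:
    """(covering bases excluding N, non-consensus bases) at one site.

    Deletion observations count as non-consensus; N-masked bases are
    excluded from the denominator.
    """
    row = pileup.counts[pileup.ref.wrap(pos)]
    total = int(row[:4].sum() + row[5])  # A,C,G,T + deletions, excluding N
    matching = int(row[_BASE_IDX[expected]]) if expected in "ACGT" else 0
    return total, total - matching


def estimate_diagnostic(
    pileup: Pileup,
    sites: Sequence[tuple[int, str]],
    ci_method: str = "wilson",
    ci_level: float = 0.95,
    n_bootstrap: int = 2000,
    seed: int = 0,
    method_label: str = "diagnostic",
) -> ContamEstimate:
    """Pooled fraction of non-consensus bases across diagnostic sites."""
    if not sites:
        raise SiteError("empty diagnostic site list")
    totals, mismatches = [], []
    uncovered = []
    for pos, expected in sites:
        t, m = _site_counts(pileup, pos, expected)
        if t == 0:
            uncovered.append(pos)
        totals.append(t)
        mismatches.append(m)
    if uncovered:
        raise CoverageError(f"diagnostic sites with zero depth: {uncovered}")
    n_bases = int(sum(totals))
    n_mis = int(sum(mismatches))
    rate = n_mis / n_bases
    if ci_method == "wilson":
        lo, hi = wilson_interval(n_mis, n_bases, ci_level)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        t = np.array(totals)
        m = np.array(mismatches)
        idx = rng.integers(0, len(sites), size=(n_bootstrap, len(sites)))
        rates = m[idx].sum(axis=1) / np.maximum(t[idx].sum(axis=1), 1)
        alpha = (1.0 - ci_level) / 2.0
        lo, hi = np.quantile(rates, [alpha, 1.0 - alpha])
    else:
        raise ValueError(f"unknown CI method {ci_method!r}")
    return ContamEstimate(
        method=method_label,
        rate=rate,
        ci_low=float(min(lo, rate)),
        ci_high=float(max(hi, rate)),
        ci_level=ci_level,
        n_positions=len(sites),
        n_bases=n_bases,
        n_nonconsensus=n_mis,
    )


def damage_filter_sites(
    sites: Sequence[tuple[int, str]],
    pileup: Pileup,
    profile: DamageProfile | None = None,
    min_damage_count: int = 1,
) -> tuple[list[tuple[int, str]], list[tuple[int, str, str]]]:
    """Drop sites whose C/G consensus allele shows damage-type mismatches.

    A site is excluded iff its expected allele is C or G and the pileup
    holds at least ``min_damage_count`` observations of the corresponding
    deamination product (T for C, A for G).  ``profile`` is accepted for
    interface symmetry with the damage stage; the presence rule itself does
    not use it.  Returns (retained sites, excluded (pos, allele, reason)).
    """
    kept: list[tuple[int, str]] = []
    excluded: list[tuple[int, str, str]] = []
    for pos, expected in sites:
        if expected in _DAMAGE_PRODUCT:
            product = _DAMAGE_PRODUCT[expected]
            n = pileup.base_count(pos, product)
            if n >= min_damage_count:
                excluded.append(
                    (pos, expected,
                     f"consensus {expected} with {n} damage-type {product} observations")
                )
                continue
        kept.append((pos, expected))
    return kept, excluded


# ---------------------------------------------------------------------------
# likelihood-mixture estimator


def genome_slot_map(
    ref: CircularReference, genome: "Haplotype | str"
) -> dict[tuple[int, int], str]:
    """Sparse map of slots where a genome differs from the reference.

    Accepts a haplotype, or a position-aligned sequence of reference length
    (substitution-only representation of e.g. a FASTA panel member).
    Substituted slots map to the sample allele, deleted positions to the
    DELETED marker, insertion slots to the inserted base.
    """
    if isinstance(genome, Haplotype):
        out: dict[tuple[int, int], str] = {}
        for v in genome.variants:
            out[v.slot] = v.alt_allele
        return out
    seq = genome.upper()
    if len(seq) != ref.length:
        raise PanelError(
            f"panel sequence length {len(seq)} != reference length {ref.length}; "
            "provide a position-aligned sequence or a haplotype TSV"
        )
    return {
        (i + 1, 0): b
        for i, b in enumerate(seq)
        if b != ref.bases[i] and b in "ACGT" and ref.bases[i] != "N"
    }


def _genome_base(
    ref: CircularReference, slot_map: dict[tuple[int, int], str], slot: tuple[int, int]
) -> str | None:
    if slot in slot_map:
        allele = slot_map[slot]
        return None if allele == DELETED else allele
    pos, k = slot
    if k == 0:
        return ref.base_at(pos)
    return None  # insertion slot absent from this genome


def estimate_mixture(
    reads: Iterable[AlignedRead],
    ref: CircularReference,
    endo: "Haplotype | str",
    panel: Sequence["Haplotype | str"],
    eps: float = 0.01,
    grid: np.ndarray | None = None,
    ci_level: float = 0.95,
) -> ContamEstimate:
    """Grid-ML two-component mixture of endogenous vs panel read likelihoods.

    Per read and genome, the likelihood is the product over aligned non-N
    read bases of (1 - eps) for matches and eps/3 for mismatches; the
    mixture likelihood at contaminant proportion p averages the panel
    member likelihoods.  Only slots where a panel genome differs from the
    endogenous genome contribute to the estimate, so the computation keeps
    per-read log-likelihood differences at those slots only.  The interval
    is the profile-likelihood set within chi2(1)/2 log-units of the maximum.
    """
    if not panel:
        raise PanelError("empty contaminant panel")
    if not 0.0 < eps < 0.25:
        raise ValueError(f"eps={eps} outside (0, 0.25)")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 1001)
    grid = np.asarray(grid, dtype=float)

    endo_map = genome_slot_map(ref, endo)
    panel_maps = [genome_slot_map(ref, g) for g in panel]
    diff_slots: set[tuple[int, int]] = set()
    for pm in panel_maps:
        for slot in set(endo_map) | set(pm):
            e_b = _genome_base(ref, endo_map, slot)
            p_b = _genome_base(ref, pm, slot)
            if e_b != p_b and e_b != "N" and p_b != "N":
                diff_slots.add(slot)
    log_match = math.log1p(-eps)
    log_mismatch = math.log(eps / 3.0)

    # per read: log-likelihood of each panel genome relative to the endogenous
    deltas: list[np.ndarray] = []
    n_informative = 0
    for read in reads:
        cols = {
            (ref.wrap(pos), k): base
            for pos, k, base in read.aligned_columns()
            if base in "ACGT"
        }
        covered = [s for s in diff_slots if s in cols]
        if not covered:
            continue
        delta = np.zeros(len(panel_maps))
        informative = False
        for slot in covered:
            base = cols[slot]
            e_b = _genome_base(ref, endo_map, slot)
            if e_b == "N":
                continue
            ll_e = log_match if base == e_b else log_mismatch
            for gi, pm in enumerate(panel_maps):
                p_b = _genome_base(ref, panel_maps[gi], slot)
                if p_b == "N":  # uninformative for this panel member
                    ll_p = ll_e
                else:
                    ll_p = log_match if base == p_b else log_mismatch
                if ll_p != ll_e:
                    informative = True
                delta[gi] += ll_p - ll_e
        if informative:
            n_informative += 1
            deltas.append(delta)

    flags: list[str] = []
    if n_informative == 0:
        return ContamEstimate(
            method="mixture", rate=float(grid[0]), ci_low=float(grid.min()),
            ci_high=float(grid.max()), ci_level=ci_level,
            n_positions=len(diff_slots), n_bases=0, n_nonconsensus=0,
            flags=("uninformative",),
        )

    ratios = np.exp(np.stack(deltas))  # (reads, panel): L(panel)/L(endo)
    mean_ratio = ratios.mean(axis=1)  # average panel member per read
    # log L(p) - const = sum over reads log((1-p) + p * mean_ratio)
    with np.errstate(divide="ignore"):
        loglik = np.log(
            np.clip((1.0 - grid)[None, :] + grid[None, :] * mean_ratio[:, None],
                    1e-300, None)
        ).sum(axis=0)
    best = int(np.argmax(loglik))
    cutoff = loglik[best] - stats.chi2.ppf(ci_level, df=1) / 2.0
    inside = np.flatnonzero(loglik >= cutoff)
    if best in (0, len(grid) - 1):
        flags.append("boundary")
    return ContamEstimate(
        method="mixture",
        rate=float(grid[best]),
        ci_low=float(grid[inside.min()]),
        ci_high=float(grid[inside.max()]),
        ci_level=ci_level,
        n_positions=len(diff_slots),
        n_bases=n_informative,
        n_nonconsensus=0,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# site-list I/O and report


def read_sites_tsv(path: str | Path) -> list[tuple[int, str]]:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["pos", "expected_allele"]:
            raise SiteError(f"{path}: bad site list header {header}")
        for line in fh:
            if line.strip():
                pos, allele = line.split("\t")[:2]
                sites.append((int(pos), allele.strip().upper()))
    return sites


def write_sites_tsv(sites: Sequence[tuple[int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\texpected_allele\n")
        for pos, allele in sites:
            fh.write(f"{pos}\t{allele}\n")


def write_estimate_report(
    estimates: Sequence[ContamEstimate],
    path: str | Path,
    excluded_sites: Sequence[tuple[int, str, str]] = (),
) -> None:
    doc = {
        "estimates": [e.to_dict() for e in estimates],
        "excluded_sites": [
            {"pos": p, "expected_allele": a, "reason": r} for p, a, r in excluded_sites
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
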