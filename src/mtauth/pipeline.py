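"""End-to-end orchestration: simulate/load -> pileup -> damage -> consensus
-> haplogroup -> contamination, with a combined deterministic JSON report."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import consensus as consensus_mod
from . import contam as contam_mod
from . import damage as damage_mod
from . import fixtures
from . import haplocall
from . import readio
from . import simulate as simulate_mod
from .refhap import DEFAULT_IGNORE, CircularReference, Haplotype

log = logging.getLogger("mtauth")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration; all paths may be None when the
    corresponding packaged fixture should be used instead."""

    out_dir: Path
    sam_path: Path | None = None  # analysis-only input; None => simulate
    ref_path: Path | None = None
    tree_path: Path | None = None
    sites_path: Path | None = None
    endo_path: Path | None = None
    contam_path: Path | None = None
    seed: int = 0
    # simulation
    n_fragments: int = 20000
    contamination: float = 0.02
    frag_len_mean: float = 70.0
    frag_len_sd: float = 15.0
    delta5: float = 0.0
    delta3: float = 0.0
    rho: float = 0.5
    udg_residual: float = 1.0
    seq_error: float = 0.001
    duplication_rate: float = 0.0
    library: str = "unknown"
    # analysis
    min_mapq: int = readio.DEFAULT_MIN_MAPQ
    min_baseq: int = readio.DEFAULT_MIN_BASEQ
    min_cov: int = consensus_mod.DEFAULT_MIN_COV
    min_frac: float = consensus_mod.DEFAULT_MIN_FRAC
    damage_window: int = 25
    ci_method: str = "wilson"
    filter_damage: bool = True
    informative_only: bool = True
    run_mixture: bool = False
    mixture_eps: float = 0.01
    ignore_tokens: tuple[str, ...] = tuple(sorted(DEFAULT_IGNORE))
    target_node: str = fixtures.TARGET_NODE

    def validate(self) -> None:
        for name in ("sam_path", "ref_path", "tree_path", "sites_path",
                     "endo_path", "contam_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages in dependency order and return the report.

    Every stage output is written under ``config.out_dir`` and checksummed
    into the report.  Identical config + seed yields identical report
    content (no timestamps are recorded).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO,
        format="[mtauth:%(stage)s] %(message)s", force=False,
    )
    report: dict[str, Any] = {"seed": config.seed, "stages": {}, "files": {}}
    stage = "setup"

    def info(msg: str) -> None:
        log.info(msg, extra={"stage": stage})

    try:
        ref = (
            CircularReference.from_fasta(config.ref_path)
            if config.ref_path
            else fixtures.reference()
        )
        tree = (
            haplocall.HaplogroupTree.from_tsv(config.tree_path)
            if config.tree_path
            else fixtures.haplogroup_tree()
        )

        # -- simulate (or load) ------------------------------------------
        sam_path = config.sam_path
        truth = None
        if sam_path is None:
            stage = "simulate"
            endo = (
                Haplotype.from_tsv(config.endo_path)
                if config.endo_path
                else fixtures.sample_haplotype()
            )
            contam_hap = (
                Haplotype.from_tsv(config.contam_path)
                if config.contam_path
                else fixtures.contaminant_haplotype()
            )
            params = simulate_mod.SimParams(
                n_fragments=config.n_fragments,
                frag_len_mean=config.frag_len_mean,
                frag_len_sd=config.frag_len_sd,
                contamination=config.contamination,
                delta5=config.delta5,
                delta3=config.delta3,
                rho=config.rho,
                udg_residual=config.udg_residual,
                seq_error=config.seq_error,
                duplication_rate=config.duplication_rate,
                library=config.library,
                seed=config.seed,
            )
            reads, truth = simulate_mod.simulate_reads(ref, endo, contam_hap, params)
            sam_path = out / "reads.sam"
            simulate_mod.write_sam(reads, ref, sam_path)
            truth.to_json(out / "truth.json")
            info(f"simulated {len(reads)} reads -> {sam_path}")
            report["stages"]["simulate"] = {
                "n_reads": len(reads),
                "realized_contaminant_fraction": truth.realized_contaminant_fraction,
                "realized_mean_fragment_length": truth.realized_mean_fragment_length,
            }

        # -- pileup -------------------------------------------------------
        stage = "pileup"
        reads = readio.read_alignments(sam_path, config.min_mapq, config.min_baseq)
        reads, dup_fraction = readio.deduplicate(reads)
        pileup = readio.build_pileup(reads, ref)
        pileup.to_tsv(out / "pileup.tsv")
        info(f"{len(reads)} unique reads, duplicate fraction {dup_fraction:.4f}")
        report["stages"]["pileup"] = {
            "n_unique_reads": len(reads),
            "duplicate_fraction": dup_fraction,
            "total_bases": pileup.total_bases(),
        }

        # -- damage -------------------------------------------------------
        stage = "damage"
        profile = damage_mod.misincorporation_profile(reads, ref, config.damage_window)
        profile.to_tsv(out / "damage.tsv")
        frag_stats = damage_mod.fragment_length_stats(reads)
        report["stages"]["damage"] = {
            "terminal_ct_rate": profile.terminal_ct_rate,
            "terminal_ga_rate": profile.terminal_ga_rate,
            "fragment_stats": {
                k: v for k, v in frag_stats.to_dict().items() if k != "histogram"
            },
        }

        # -- consensus ----------------------------------------------------
        stage = "consensus"
        call = consensus_mod.call_consensus(pileup, ref, config.min_cov, config.min_frac)
        hap, n_diff = consensus_mod.variant_table(call, config.ignore_tokens)
        call.to_fasta(out / "consensus.fasta")
        hap.to_tsv(out / "variants.tsv")
        consensus_mod.write_vcf(call, out / "variants.vcf")
        info(f"consensus with {len(hap)} variants ({n_diff} counted)")
        report["stages"]["consensus"] = {
            "n_variants": len(hap),
            "diff_count": n_diff,
            "ignore": list(config.ignore_tokens),
        }

        # -- haplogroup ---------------------------------------------------
        stage = "haplogroup"
        scores = haplocall.score_haplogroups(hap, tree, config.ignore_tokens)
        haplocall.write_score_report(scores, out / "haplogroup.json")
        best = scores[0]
        privates = haplocall.private_mutations(hap, best, tree, config.ignore_tokens)
        report["stages"]["haplogroup"] = {
            "best": best.to_dict(),
            "ranking": [(s.name, s.fraction) for s in scores[:5]],
            "private_mutations": [v.notation() for v in privates],
        }

        # -- contamination ------------------------------------------------
        stage = "contam"
        if config.sites_path:
            sites = contam_mod.read_sites_tsv(config.sites_path)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sites = haplocall.diagnostic_positions(tree, config.target_node, ref)
        if config.informative_only:
            sites = [(p, a) for p, a in sites if a != ref.base_at(p)]
        estimates = []
        excluded: list[tuple[int, str, str]] = []
        contam_skipped = None
        try:
            estimates.append(contam_mod.estimate_diagnostic(
                pileup, sites, config.ci_method, seed=config.seed))
        except contam_mod.CoverageError as exc:
            contam_skipped = str(exc)
            info(f"diagnostic estimate skipped: {exc}")
        if estimates and config.filter_damage:
            kept, excluded = contam_mod.damage_filter_sites(sites, pileup, profile)
            if kept:
                estimates.append(
                    contam_mod.estimate_diagnostic(
                        pileup, kept, config.ci_method, seed=config.seed,
                        method_label="diagnostic_filtered",
                    )
                )
        if config.run_mixture:
            endo_for_mix = hap
            panel = [
                Haplotype.from_tsv(config.contam_path)
                if config.contam_path
                else fixtures.contaminant_haplotype()
            ]
            estimates.append(
                contam_mod.estimate_mixture(
                    reads, ref, endo_for_mix, panel, eps=config.mixture_eps)
            )
        contam_mod.write_estimate_report(estimates, out / "contam.json", excluded)
        report["stages"]["contam"] = {
            "estimates": [e.to_dict() for e in estimates],
            "n_sites": len(sites),
            "n_excluded": len(excluded),
            "skipped": contam_skipped,
        }

        stage = "finalize"
        for p in sorted(out.iterdir()):
            if p.is_file() and p.name != "report.json":
                report["files"][p.name] = _sha256(p)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
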