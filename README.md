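# mtauth

Ancient mitochondrial DNA authentication toolkit: a tested, reusable pipeline
for consensus haplotype calling against a circular mitochondrial reference,
haplogroup scoring against a defining-variant tree, terminal-deamination
damage profiling, and contamination estimation — together with a synthetic
ancient-read simulator so every stage is testable without external data.

## What it does

- **refhap** — circular 1-based reference model, forensic mtDNA variant
  notation (`16129A`, `3158.1T`, `5DEL`), haplotypes, variant application and
  reference-difference counting with a configurable ignore set (default:
  `3107`, `309.1`, `309.2`).
- **simulate** — seeded generator of aligned ancient reads: truncated
  log-normal fragment lengths, strand-specific terminal C→T / G→A
  misincorporation with geometric decay into the read, optional UDG
  attenuation, sequencing error, PCR duplication, and a contaminant haplotype
  mixed at a set fraction; emits SAM plus a JSON truth file.
- **readio** — SAM input (pysam), endpoint+strand duplicate removal, and a
  circular pileup with insertion/deletion tracking; origin-spanning fragments
  are written as two tagged SAM segments and re-joined on read.
- **damage** — MapDamage-style misincorporation-by-offset tables (5′ C→T,
  3′ G→A), geometric-decay fitting, and fragment-length statistics.
- **consensus** — majority-rule consensus calling (`min_cov`, `min_frac`)
  expressed as a variant table, FASTA, TSV and minimal VCF 4.2.
- **haplocall** — scoring against a haplogroup tree (TSV dialect with
  back-mutation `!` tokens), private-mutation reporting, and derivation of
  the diagnostic position set used for contamination estimation.
- **contam** — pooled non-consensus-base contamination rate at diagnostic
  positions with Wilson or bootstrap CIs, a damage-aware position filter
  (drops C/G-consensus sites showing damage-type mismatches), and a
  grid maximum-likelihood read-mixture estimator with profile-likelihood
  intervals as a cross-check.
- **cli / pipeline** — stage orchestration with a deterministic combined
  JSON report.

A packaged synthetic 16,569 bp reference (with the placeholder N at position
3107), a U1a1a-like haplogroup tree with 50 diagnostic substitution
positions, a 38-variant sample haplotype and a 50-site list live under
`src/mtauth/data/` and are used as defaults throughout.

## CLI

```sh
mtauth simulate --n 50000 --c 0.02 --delta5 0.25 --delta3 0.25 --rho 0.6 \
    --eps 0.001 --dup-rate 4 --seed 17 --out sim
mtauth pileup   --sam sim.sam --out pileup.tsv
mtauth damage   --sam sim.sam --out damage.tsv --plot damage.png
mtauth consensus --pileup pileup.tsv --out-prefix cons
mtauth haplogroup --variants cons.variants.tsv
mtauth contam   --pileup pileup.tsv --sites sites.tsv --filter-damage --ci wilson
mtauth contam-mix --sam sim.sam --endo cons.variants.tsv --panel panel/ --eps 0.01
mtauth run      --n 20000 --c 0.02 --seed 9 --out outdir   # full pipeline
```

Every subcommand accepts `--ref` to override the packaged reference; `mtauth
run --sam aligned.sam` runs the analysis-only path on externally mapped
reads.

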