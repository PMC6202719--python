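# railmix

Toolkit for detecting cryptic introgression between king rails (*Rallus
elegans*) and clapper rails (*R. crepitans*) from a small diagnostic marker
set: a 620-bp mtDNA fragment carrying 8 diagnostic sites and a panel of 13
diagnostic nuclear SNPs genotyped by amplicon sequencing.

The package covers the full analysis chain:

- **`railmix.simdata`** — synthetic diagnostic panels (truncated-normal
  allele-frequency differentials), Mendelian pedigree cohorts (pure, F1, F2,
  backcrosses), GT-seq-like overdispersed read counts, and mtDNA fragments
  with maternal inheritance. Everything downstream is testable without field
  data.
- **`railmix.gtseq`** — genotype calling from per-allele read counts
  (10× depth cutoff, allele-ratio thresholds) and sample-level QC
  (>30 % missingness drop, minimum-scored-loci filter).
- **`railmix.mtdna`** — diagnostic-site derivation from voucher sequences
  (reciprocally fixed columns) and species assignment by the ≥6-of-8 match
  rule.
- **`railmix.ancestry`** — per-individual admixture proportions Q: a
  supervised fixed-frequency ML estimator and an unsupervised EM admixture
  model (K clusters, multiple restarts, label anchoring), plus the
  Q ≥ 0.98 site-purity rule.
- **`railmix.introgression`** — ML hybrid index, interspecific
  heterozygosity, threshold classification into pure / backcrossed / F1-F2,
  per-site summaries, cyto-nuclear cross-tabulation, triangle-plot data.
- **`railmix.pipeline`** — end-to-end orchestration with a YAML config,
  deterministic manifest (sha256 checksums), and a self-contained demo
  dataset generator.

## Quick start

Generate and analyse a demo dataset (11 sampling sites, two admixed focal
sites with injected backcrosses):

```sh
railmix demo --seed 7 --outdir demo
```

Outputs land in `demo/out/`: called genotypes, QC report, mtDNA species
calls, Q matrix and K comparison, site purity, per-individual introgression
records, per-site summaries, cyto-nuclear table, triangle-plot TSV, and a
`manifest.json` describing every stage.

Individual stages:

```sh
railmix simulate --n-loci 13 --design PURE_KING=10 --design F1=5 --seed 1 --outdir sim
railmix call --counts sim/read_counts.tsv --out genotypes.csv --qc-out qc.tsv
railmix mtdna --seqs mtdna.fasta --king-vouchers k.fasta --clapper-vouchers c.fasta --out calls.tsv
railmix ancestry --genotypes genotypes.csv --panel panel.tsv --out q.tsv
railmix introgress --genotypes genotypes.csv --panel panel.tsv --outdir intro
railmix run --config demo/config.yaml
```

As a library:

```python
from railmix import simdata, introgression

panel = simdata.make_panel(n_loci=13, mean_diff=0.96, sd_diff=0.08, floor=0.7, seed=1)
genotypes, truth = simdata.simulate_cohort(panel, {"PURE_CLAPPER": 40, "BC1_CLAPPER": 5}, seed=2)
h = introgression.hybrid_index(genotypes, panel)
het = introgression.interspecific_het(genotypes)
records = introgression.classify_records(h, het)
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion (worked
arithmetic examples, estimator-vs-oracle agreement, EM properties, pedigree
recovery, QC and mtDNA rules, end-to-end determinism).

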