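# erosionkit

Toolkit for quantifying **genomic erosion** — the gradual loss of genetic
diversity through drift, inbreeding and shrinking population size — by
comparing whole-genome data from two sampling epochs, such as historic
museum specimens versus contemporary individuals of the same populations.
It was built around the analytical design used in temporal resequencing
studies of koala (*Phascolarctos cinereus*), but every component is generic:
it is aimed at conservation and population geneticists who work with
low-coverage and degraded-DNA resequencing data.

## What it computes

* **Genotype likelihoods** from per-site read pileups, with the GATK-style
  per-read model `P(b|a1,a2) = [P(b|a1)+P(b|a2)]/2`, `P(b|a) = 1−e` if
  `b = a` else `e/3`; per-base error rate `e` estimated from reads over a
  haploid reference (e.g. the mitochondrial genome). Site filters: minor
  allele frequency (EM under Hardy–Weinberg), a 1-df likelihood-ratio SNP
  test, minimum individuals with data, and transversions-only mode to
  sidestep post-mortem C→T/G→A damage.
* **Genome-wide heterozygosity** per individual as the heterozygous weight
  of a two-class (homozygous/heterozygous) site mixture fitted by EM in
  1 Mb windows — the per-individual analogue of a folded site-frequency
  spectrum — plus the classic **downsampling calibration**: one
  high-coverage genome is thinned to 25/40/50/60/80% of its depth, three
  replicates each (15 datasets), relative heterozygosity is regressed on
  achieved coverage with a polynomial, and low-coverage estimates are
  divided by the predicted relative heterozygosity.
* **Runs of homozygosity** with the PLINK-style 50-SNP sliding window
  (`--homozyg-snp 50 --homozyg-kb 1000 --homozyg-gap 1000` semantics),
  FROH = cumulative ROH > 1 Mb over scaffolds > 10 Mb, the five length
  classes 0.5–1 / 1–2 / 2–5 / 5–10 / >10 Mb, and length-to-age dating
  (`g = 100/(rL)` by default; the `stated` convention `g = 100/(2rL)` is
  also available — see `docs/methods.md`).
* **Mitochondrial haplotype diversity** `Hd = n/(n−1)·(1 − Σ pᵢ²)` with a
  group-label permutation test on ΔHd, and **median-joining networks**
  (minimum spanning network plus column-majority median vectors, ε = 0).
* **Population structure** from genotype likelihoods: a standardized
  expected-genotype covariance matrix with PCA, and admixture proportions
  via the NGSadmix-model EM (`h_is = Σ_k q_ik f_ks`, binomial genotype
  prior), best of many random starts.
* **Synthetic data** with recorded ground truth: a two-epoch bottleneck
  cohort (neutral-like 1/x site-frequency spectrum, Wright–Fisher drift),
  planted autozygous tracts of controlled length classes, Poisson-depth
  reads with sequencing error and strand-collapsed aDNA damage, and
  epoch-labelled mitochondrial alignments.

## Worked example

Run the full pipeline on a self-contained synthetic dataset (the config
keys mirror the simulator's parameters; everything is seeded):

```bash
erosionkit run --config demo.yaml --outdir demo_out
```

with `demo.yaml`:

```yaml
n_historic: 12
n_contemporary: 12
n_sites: 20000
n_scaffolds: 2
scaffold_length: 15000000
theta: 0.02              # expected per-site heterozygosity, historic epoch
bottleneck_factor: 0.3   # contemporary diversity = 30% of historic
coverage_historic: 6.0
coverage_contemporary: 12.3
error_rate: 0.001
damage_rate: 0.02        # C->T / G->A rate, historic libraries only
seed: 7
analysis:
  min_ind: 12
  froh_target: 0.1       # autozygous tracts planted in every individual
  admixture_starts: 3
  mt:
    n_permutations: 10000
```

This prints (and writes to `demo_out/report.json`):

```json
{
  "hd": {
    "contemporary": 0.4394,
    "historic": 0.5455,
    "permutation_p": 0.7322
  },
  "kruskal_wallis": {"H": 17.28, "p": 3.23e-05},
  "mean_froh_by_epoch": {"contemporary": 0.0957, "historic": 0.0},
  "mean_raw_het_by_epoch": {"contemporary": 0.00681, "historic": 0.02093},
  "n_sites_filtered": 629,
  "pc1_variance_fraction": 0.326
}
```

Reading the numbers: the simulated 0.3× bottleneck shows up directly —
contemporary heterozygosity (0.0068, transversion sites) is about a third
of historic (0.021), and the epoch difference is highly significant by
Kruskal–Wallis (p ≈ 3e-5). The planted FROH of 0.1 is recovered for the
deeply sequenced contemporary individuals (0.096); for the 6× historic
samples the 50-SNP windows contain too many missing hard calls on this
sparse 629-SNP panel, so their ROH go undetected — the same
coverage-sensitivity that motivates restricting ROH analyses to
well-covered genomes. At these small sample sizes (12 vs 12) the
haplotype-diversity permutation test is underpowered, so a
non-significant p here is expected even though the point estimates drop.
Alongside the report the run writes the VCF, BEAGLE-GL, heterozygosity,
ROH/FROH and network files, plus `manifest.json` recording every seed.

Each stage is also exposed on its own (`erosionkit simulate / gl / het /
calibrate / roh / hapdiv / network / pca / admix`) and as a library
(`erosionkit.gl`, `erosionkit.hetcal`, `erosionkit.rohscan`,
`erosionkit.mthap`, `erosionkit.structure`, `erosionkit.simdata`).

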