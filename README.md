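# snppanel

Conservation genetics increasingly needs to know not just how
populations are structured, but which parts of a SNP panel carry that
structure for neutral (demographic) reasons and which parts track the
environment — putative targets of divergent selection. `snppanel`
implements a multi-test procedure for making that call on diploid
biallelic SNP panels scored across many populations (the motivating
setting is a salmonid riverscape: ~50–150 populations in regional
groups, ~200 loci, per-population climate normals), and for contrasting
the population structure carried by the resulting panels.

A locus is flagged by any of three criteria — (1) Weir–Cockerham
F<sub>ST</sub> above the 99% quantile of a heterozygosity-conditioned
island-model coalescent null (FDIST-style outlier test, migration
calibrated to the observed multilocus θ), (2) a-priori precedence of
association, (3) Bonferroni-significant univariate regression of
population minor-allele frequency on a physical variable that survives a
group-exclusion robustness rerun — and then adjudicated by criterion
(4): distance-based multivariate regression (DISTLM forward, pseudo-F
with Freedman–Lane permutation of residuals) ranking environmental
variable sets against neutral-structure controls (admixture Q and PCoA
eigenvectors) on the locus's own pairwise-F<sub>ST</sub> matrix. Loci
whose top-ranked variable is environmental become **candidates**;
outlier/precedence loci that fail the ranking are **ambiguous**;
everything else is **neutral**. Downstream, the package compares the
neutral and candidate panels with Nei-distance neighbor-joining trees
(locus-bootstrap majority-rule consensus with supports), Mantel tests of
isolation by distance/environment, and a five-variable hot-dry→cold-wet
climate ranking.

Because the procedure's inputs are rarely public at full scale, the
package ships a first-class synthetic-data module: a hierarchical
Balding–Nichols riverscape with spatially structured climate, planted
logistic clines, and planted QC defects (hybrids, duplicate loci,
heterozygote-excess loci, high-missingness individuals) with a truth
table, so every stage is testable against known ground truth.

## Worked example

```sh
python analysis/01_simulate_riverscape.py   # synthesize the dataset
python analysis/02_qc_paring.py             # missingness/hybrid/HWE/LD paring
python analysis/03_full_pipeline.py         # outlier scan ... classification, trees
python analysis/04_recovery_study.py        # 20-replicate sensitivity/FDR study
```

The first two steps print:

```
simulated 1500 individuals x 205 loci in 50 populations
planted: 10 cline loci (precip_summer, beta=1.0), 30 hybrids, 2 duplicate pairs,
  1 heterozygote-excess locus

input: 1500 individuals x 205 loci
pared: 1467 individuals x 199 loci
  removed for hwe: 1
  removed for hybrid: 30
  removed for linkage: 2
  removed for missingness: 3
```

i.e. the paring stage recovered exactly the planted defects: all 30
hybrids (via the three diagnostic loci, which are then dropped), the 3
high-missingness individuals at the <10% missing-data rule, the
heterozygote-excess locus via the exact Hardy–Weinberg test with a
Benjamini–Yekutieli-adjusted threshold, and one member of each duplicated
pair (the lower-MAF copy) via the linkage permutation test.

Step 3 calibrates the 100-deme island-model null to the observed
multilocus θ, scans for outliers, builds the Q/EV controls, runs the
association scan with the wet-region exclusion, ranks flagged loci by
DISTLM and classifies:

```
populations: 50, post-QC loci: 199
multilocus theta = 0.0545; island-model null calibrated to mean FST 0.0564 (M = 12.8)
directional outliers: 9; criteria 1-3 flagged: 11
panels: neutral=189, candidate=10, ambiguous=0
planted candidates recovered: 9/10; false candidates: 1

Mantel tests (per panel):
    panel           variable        r       r2      p
  neutral migration_distance 0.349768 0.122338 0.0001
  neutral      precip_spring 0.130030 0.016908 0.0030
  neutral      precip_summer 0.094355 0.008903 0.0234
  neutral        tmax_summer 0.388847 0.151202 0.0001
candidate migration_distance 0.321719 0.103503 0.0001
candidate      precip_spring 0.840894 0.707103 0.0001
candidate      precip_summer 0.937403 0.878724 0.0001
candidate        tmax_summer 0.424109 0.179868 0.0001
```

The contrast in the Mantel rows is the method's point: pairwise
F<sub>ST</sub> over the *neutral* panel correlates mainly with stream
distance (isolation by distance, r² = 0.12), while over the *candidate*
panel it tracks pairwise differences in summer precipitation — the
planted cline variable — at r² = 0.88. Step 4 repeats the whole pipeline
on 20 fresh riverscapes; under the default study conditions it recovers
99% of planted clines with a 0.7% false-candidate rate among neutral
loci.

The same machinery is scriptable from a shell (`snppanel pipeline
--config cfg.yaml --seed 7 --out run/`, plus per-stage subcommands
`simulate`, `qc`, `stats`, `outliers`, `controls`, `assoc`, `distlm`,
`classify`, `tree`, `rank`, `mantel`) and from Python via the library
modules (`snppanel.popgen`, `.qc`, `.outliers`, `.admixture`, `.assoc`,
`.distlm`, `.classify`, `.trees`, `.simulate`, `.pipeline`).

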