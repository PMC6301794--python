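# Methods

This note records the models implemented in `macrospace`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data do and do not emulate.

## Nutrient-space phenotyping

**Data model.** A diet-grid assay is a tidy table of cumulative pupariation
counts: per genotype, diet cell (yeast % w/v × sucrose % w/v), replicate
vial and observation time `t`, the number `p_t` of the `n` seeded larvae
that have pupariated by `t`. The standard design is a 5 × 5 grid (yeast
1.25–20%, sucrose 0–20%), 5 vials of 30 larvae, scored every 24 h to 408 h.

**Pupariation index.** `Pupind = max_t p_t / t` over the observation times,
in larvae·h⁻¹; ties are broken toward the earliest attaining time, and the
statistic is invariant to observations appended after the counts saturate.
It is computed per vial and averaged per diet cell for surfaces (a pooled
mode is not provided; the replicate structure of the assay is vial-level).

**Survival and development time.** Survival is `p_final / n`. The assay
never observes individual pupariation instants, only 24-h censoring
intervals, and "development time" therefore needs a convention: we use the
earliest observation time at which `p_t` reaches half of `p_final` — the
median of survivors under interval censoring. It is undefined (NaN) for
vials with no survivors, and such vials drop out of development-time
correlations (they still contribute survival = 0).

**Diet calories.** kcal/100 g = 3.25 · (g yeast) + 4.06 · (g sucrose),
rounded half-away-from-zero to one decimal. The two energy densities
reproduce the published 25-cell calorie table exactly, including the cells
that land on exact rounding midpoints (16.25 → 16.3), which is what pins
the rounding rule.

**Correlations.** Pearson r of a per-vial metric against the numeric diet
axis, with the two-sided p from the usual t transform (scipy). Default is
vial-level points; a `level="cell"` mode first averages vials within a diet
cell, since published correlation tables do not always state their basis.

**ω² effect sizes.** From a fixed-effects factorial ANOVA with Type-I
(sequential) sums of squares (statsmodels OLS + anova_lm):
`ω² = (SS_eff − df_eff · MS_err) / (SS_tot + MS_err)`. The assay grid is
balanced, where Type-I is order-invariant; unbalanced input warns. Output
is clamped to [0, 1] by default; `clamp=False` exposes the raw estimator,
which is the approximately unbiased one (its null-effect mean over pure
noise is ~0, which the tests check; the clamped version is necessarily
biased upward at the null).

## Backcross introgression simulator

**Genome model.** A chromosome map lists name, physical length (bp),
genetic length (Morgans) and inheritance class (autosome / X /
mitochondrial). Defaults: chr2 47 Mb / 1.1 M, chr3 53 Mb / 1.1 M, X
23 Mb / 0.7 M, mitochondrion 19 kb / 0 M — round figures at the scale of
the *D. simulans*-clade genome; the dot chromosome and heterochromatin are
ignored. Each haplotype is a list of half-open ancestry tracts
(donor/recipient) tiling the chromosome; tract tiling is validated in
tests after every operation. Coordinates are 0-based half-open internally;
TSV/VCF I/O is 1-based, BED/bedGraph 0-based.

**Crossing scheme.** F1 = donor females × recipient males, so every F1 is
heterozygous everywhere and carries donor mitochondria. Then `g` (default
10) backcrosses of hybrid females × recipient males, then sib-mating
(default 3 generations). Only females recombine (Drosophila achiasmy);
male gametes are whole haplotypes. Because only hybrid females are ever
crossed, hybrid male sterility never arises in-model, matching the
protocol. Crossover counts are Poisson in the genetic length (no
interference), breakpoints uniform on physical length.

**Selection.** Offspring of a selective cross survive per a locus model at
configured tolerance loci. Default `all_required`: survival needs ≥ 1
donor allele at every locus (dominant rescue — the situation where the
high-sugar diet kills recipient homozygotes outright). An `independent`
model gives each locus a survival probability with/without the donor
allele. The true per-generation selection intensity of the original
experiment is unknowable (no census of non-survivors), so it is left a
free parameter.

**Demography.** Census per generation defaults to 200 (the protocol kept
≥ 100 females plus males; the default honours that floor). Offspring are
drawn with replacement from the available mothers until the census fills;
a generation additionally guarantees at least one offspring of each sex
the *next* cross requires, because the breeding protocol collects virgin
females (and sibs of both sexes) every generation — at the scaled-down
population sizes used in tests, an unconstrained 50:50 sex draw would
occasionally produce an all-male generation and spuriously kill the line.
A bounded attempt budget converts genuinely impossible selection into an
`ExtinctionError` carrying the generation index.

**Analytic expectations.** Without selection the expected donor fraction
halves per backcross (2^−(g+1) after g backcrosses, starting from the F1's
1/2); the female X obeys the same halving here because the paternal X is
always recipient. Both are exposed by `expected_donor_fraction` (a 2-line
dynamic program) and checked against Monte-Carlo runs. Mitochondria remain
donor in 100% of individuals in every generation.

**Pooled readout.** `pool_counts` samples females (default 30, the number
pooled for DNA extraction in this kind of experiment), computes the exact
donor allele frequency at each diagnostic SNP from their tracts, then
draws depth ~ Poisson(mean_depth) and donor reads ~ Binomial(depth, freq).
No sequencing error or reference bias is modelled.

## Introgression mapping

Diagnostic SNPs are sites where each parental genotype table shows exactly
one allele (≥ `min_count` = 5 observations) and the alleles differ;
within-species polymorphic sites are excluded. Windowed donor frequency is
the ratio of sums (Σ donor reads / Σ depth) per window — robust to uneven
depth, unlike a mean of per-SNP ratios — with windows under `min_snps` = 5
flagged missing. Defaults: 100-kb non-overlapping windows.

Region segmentation is a threshold-run rule: maximal runs of windows with
frequency ≥ 0.25, tolerating ≤ 1 sub-threshold or missing window inside,
kept at ≥ 3 above-threshold windows. The 0.25 threshold splits the two
realistic states of a pooled backcross line — absent (≈ 0) versus
heterozygous introgression (≈ 0.5). At these effect sizes a hidden-Markov
segmentation adds nothing; threshold runs are transparent and idempotent
on their own output. Gene annotation counts any ≥ 1 bp overlap between a
region and a gene interval (GFF3 `gene` features via pyranges, or BED).

## Sequence divergence

**Windows.** Mismatch density between two aligned sequences in 100-base
windows stepped by 25 bases (both configurable), laid on the alignment;
columns with a gap or non-ACGT base in either sequence are masked and
removed from both numerator and denominator; partial terminal windows are
discarded. Background correction subtracts a single pooled rate — total
differences over total comparable bases across the supplied background
regions (three 20-kb regions in the motivating design) — from every
window; corrected values may be negative.

**Codon classification.** Differences between aligned codons are split
into amino-acid-changing and silent by Nei–Gojobori (1986) equal pathway
averaging: all orderings of the differing positions are enumerated, each
single-nucleotide step classified by the genetic code, orderings that pass
through a stop codon excluded, and the counts averaged. If every ordering
is excluded the pair is averaged over all orderings anyway and flagged
(this cannot be dodged without dropping the codon). Site totals follow the
same source: per codon, each of the nine possible point mutations is
synonymous or not, with mutations to stop codons counted as
nonsynonymous; N + S = 3 × compared codons by construction, and the
per-gene totals average the two sequences. Fractional pathway-averaged
counts are reported alongside integers rounded half-away-from-zero.

**Ka/Ks.** pN = n_nonsyn/N, pS = n_syn/S, with the Jukes–Cantor correction
K = −(3/4) ln(1 − 4p/3); proportions ≥ 3/4 leave the correction undefined
(flagged), as does Ks = 0. Published per-gene Ka/Ks values cannot be
recomputed from printed substitution counts alone (they need the
gene-specific site totals of the underlying consensus sequences), so the
table writer treats such rows as count records, not as ratio oracles.
Maximum-likelihood codon models are out of scope.

**Cross-gene test.** Pearson χ² on the genes × {AA-changing, silent}
contingency table (df = genes − 1, no continuity correction), warning when
any expected count drops below 5, as it does for typical single-gene
counts — the test is reported with that caveat rather than replaced.

## Gene-set overlap

Upper-tail hypergeometric p = P(X ≥ k), inclusive, computed via
`hypergeom.logsf` so that log₁₀ p is exact even when the linear-scale
p-value underflows (overlaps of hundreds of genes give p ≈ 10⁻⁶⁹ and far
beyond); a depletion tail is available. Fold enrichment is
k·U / (|A|·|B|). Benjamini–Hochberg adjustment wraps statsmodels'
step-up implementation.

## Synthetic data: what it emulates, and what not

**Diet assays.** Each genotype is a dose-response model: median
development time linear in the diet axes (hours per % slope, floored at
18 h) with log-normal dispersion (σ_log = 0.08), and survival an
independent per-larva Bernoulli with logistic diet dependence. The
log-normal choice gives positive support and the right skew of delayed
development on sugar; no joint distribution of the two traits is imposed
because none is identified by vial-level count data. The bundled
`tolerant_model()` (flat sucrose response) and `intolerant_model()`
(+4 h per % sucrose on development; −0.25 logits per % sucrose on
survival, near-lethal at 20/20) reproduce the qualitative generalist /
specialist contrast, including the correlation sign pattern along the
sucrose axis. Vial-level random effects are off by default
(`vial_effect_sd` enables them); real assays likely carry some, so
simulated replicate variance is a floor, not a calibration.

**Parental genomes.** Fixed differences (default 10⁻³/bp — the scale of
divergence in this species pair) and within-species polymorphism (default
one tenth of that, present to exercise the diagnostic-SNP exclusion rule)
are placed as disjoint Poisson processes; genotype tables tally 20 sampled
chromosomes per species. No linkage disequilibrium, mutation-rate
heterogeneity or shared ancestral polymorphism is modelled.

**Coding pairs.** `simulate_coding_pair` places exact numbers of
single-nucleotide amino-acid-changing and silent changes in distinct
codons of a random sense-codon sequence (never creating stops), so the
classifier must recover the targets exactly — a round-trip oracle.
`simulate_neutral_coding_pair` splits its substitutions between the two
classes in proportion to the sequence's N and S site totals, making the
two per-site rates equal by construction; a naive uniform point-mutation
process with stop rejection is *not* rate-balanced (the rejected
stop-creating mutations are all nonsynonymous, depressing Ka/Ks by ~10%),
which is why the generator defines neutrality at the rate level.

## Problem sizes and numerical choices

Monte-Carlo checks in the test suite run at scaled-down sizes chosen to
keep the whole suite under a minute while leaving each assertion ≥ 3
standard errors wide of its expectation: halving law at 2,000 replicates
of 16-fly populations (g up to 10); linked-drag monotonicity at 200
replicates per g over g ∈ {2,4,6,8,10}; end-to-end mapping recovery at 200
runs of 40-fly populations on a 47-Mb chromosome with 1 SNP/kb, depth 50,
30 pooled females (recovery demanded in ≥ 95% of runs, mean boundary error
≤ 2 windows against a noise-free deep readout of the same pool);
background cancellation on a 200-kb alignment at 3% divergence against
3 × 20 kb backgrounds. `scripts/acceptance.py` re-runs the same
computations at comparable sizes from a user seed. All simulators take one
integer seed into a dedicated `numpy.random.Generator`; nothing touches
global random state, and identical seeds give identical output.

Known limitations: no crossover interference; no sequencing error in the
pooled readout; threshold-run segmentation assumes the pooled donor
frequency is near 0 or ≥ 0.5 (weak, sub-threshold introgression would need
the HMM this package deliberately omits); cross-species coordinate
lift-over is not modelled, so simulated mapping lives in a single
coordinate system.
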