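# Methods

This note records the models implemented, the defaults and why they are
set where they are, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want written down.

## Data model

A panel is a samples × SNPs matrix of alt-allele dosages (0/1/2, −1 for
missing) with a marker map (chromosome label, 1-based bp position,
ordered allele pair) and a population label per sample. Dosages always
count the *second* allele of the pair, one orientation for every
statistic. PLINK text `.map` files carry no allele letters, so the
reader orders alleles lexicographically per SNP (an explicit allele
table can override this); a monomorphic SNP's single observed allele is
stored as allele 1, which means a write→read round trip is exactly
lossless only when both alleles are observed — the one irrecoverable
case is a monomorphic SNP originally oriented at dosage 2. Allele
frequencies are always computed over called genotypes only; the missing
sentinel never enters a denominator. Autosome-only stages (F_ST, LD,
ROH) drop sex and mitochondrial chromosome labels first.

## QC filters

`filter_snps` keeps SNPs with call rate ≥ 0.90 **and** MAF ≥ 0.05, both
inclusive, both computed over all samples jointly; `maf_subset` keeps
SNPs with MAF ≥ 0.2 within *every* declared super-group, the rule used
to build a common subset that damps array ascertainment bias between
deeply diverged groups. Filtering is idempotent, and the drop report
records one reason per SNP (call rate checked first).

## Diversity

H_E is the plug-in 2p(1−p), averaged over loci, with no small-sample
correction — the correction factor 2n/(2n−1) is a near-constant at the
sample sizes this package targets and would cancel in every comparison
made with it. Allelic richness uses exact hypergeometric rarefaction per
SNP, `Σ_a [1 − C(N−N_a, g)/C(N, g)]`, with binomial coefficients in log
space (gammaln) to avoid overflow; `C(N−N_a, g)` with N−N_a < g is 0 by
convention (the allele is guaranteed in every draw). The default
rarefaction depth g standardizes across populations: the largest g valid
at every SNP of every population (reported alongside the values); any
smaller g may be requested, and A_R is non-decreasing in g.

## Distance and neighbor joining

Dst uses pairwise-complete loci, so N varies by pair; this follows from
the per-pair N in its definition and avoids discarding whole samples for
scattered missingness. NJ is the standard Saitou–Nei agglomeration on
the Q-criterion. Two numerical conventions: ties in Q are broken toward
the lexicographically smallest label pair, making output order- and
platform-deterministic; negative branch lengths (which NJ can produce on
noisy, non-additive matrices) are clamped to zero with the deficit moved
to the sister branch, preserving the path length between the joined
taxa. On additive matrices the algorithm provably recovers the
generating topology; the tests check this on random trees up to 12
leaves via Robinson–Foulds distance against an independently parsed
tree.

## PCA and LD pruning

PCA uses the smartpca normalization — centre by 2p̂, scale by
√(2p̂(1−p̂)) — because allele-frequency scaling is what makes the top
components reflect drift rather than MAF structure. Missing dosages are
mean-imputed (zero after centring); monomorphic SNPs are excluded as
zero-variance. Scores are U·S from the SVD of the normalized matrix;
variance explained is relative to the full trace.

Pruning scans 50-SNP windows stepping by 5, dropping the later SNP of
any pair at r² ≥ threshold. Because window passes cannot bound the r² of
pairs farther apart than a window — and on finite samples a distant pair
can exceed any threshold by chance — a final exhaustive pass over the
survivors enforces the postcondition globally. That pass is quadratic in
the surviving SNP count and is the default; it can be disabled for very
large panels where the windowed guarantee suffices.

## Weir–Cockerham F_ST

Per SNP, the two-level ANOVA on allele frequencies with gene-copy
sample sizes nᵢ = 2 × called diploids (the convention under which the
mean squares apply):

    p̄   = Σ nᵢpᵢ / Σ nᵢ
    MSP = Σ nᵢ(pᵢ − p̄)² / (s − 1)
    MSG = Σ nᵢpᵢ(1 − pᵢ) / Σ (nᵢ − 1)
    n_c = (Σ nᵢ − Σ nᵢ²/Σ nᵢ) / (s − 1)
    θ̂   = (MSP − MSG) / (MSP + (n_c − 1) MSG)

Negative estimates are set to 0 (no biological interpretation) and, for
numerical safety, estimates above 1 to 1. SNPs monomorphic across all
groups give 0/0 and are flagged invalid and excluded from aggregates,
as are SNPs where a group has no called genotype.

Two aggregates are provided and they are *not* interchangeable. The
arithmetic mean ± sd of per-SNP values is the conventional genome-scan
summary. The multilocus estimate Σ(MSP−MSG)/Σ(MSP+(n_c−1)MSG) — the
ratio-of-sums combination — is the consistent estimator of the
generative divergence: under a Balding–Nichols simulation at F = 0.2 it
recovers 0.200 ± 0.005, while the arithmetic mean of per-SNP ratios
converges to ≈ 0.148 *at every sample size*, because the expectation of
a ratio of skewed variance components sits below the ratio of
expectations. Parameter-recovery tests therefore check the multilocus
form; the per-SNP mean is reported for comparability with genome-scan
literature.

## LD decay and the Sved model

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples (the genotype r² of PLINK's `--r2`), not a
haplotype-EM r²; pairs are restricted to the same chromosome within
1 Mb after per-analysis filters (MAF ≥ 0.10, missingness < 0.10,
computed within the analyzed sample subset). Distance classes are the
19 fixed bins 0–4, …, 800–1,000 kb, half-open [lo, hi) so every
distance maps to exactly one class. The decay model E[r²] = 1/(1+βd)
is fit by least squares on the raw pairs by default (a binned option
weights each class equally); β is bounded below by 0, optimized on a
log scale, and the flat fit β = 0 is reported with an infinite extent
and flagged. The extent at threshold t is (1/t − 1)/β, reported for
t = 0.3; by construction the fitted curve evaluated at the reported
extent equals t exactly. Internally β is handled per bp and reported
per kb. Pooled (inter-population) LD draws a seeded subsample per
population, takes all samples from populations smaller than the quota,
and runs the identical pipeline on the pooled panel.

## Runs of homozygosity

The caller follows the SNP-array scanning-window scheme: windows of 50
consecutive SNPs, valid only when they span ≤ 5 Mb (the span cap acts
as a density guard in sparse regions); a window is homozygous when it
has ≤ 1 heterozygous and ≤ 5 missing calls; each SNP's hit rate is
homozygous ÷ valid covering windows, eligibility requires ≥ 0.05 (the
conventional default for this tool family); maximal eligible runs
spanning ≥ 500 kb are emitted, with boundaries at the outermost
eligible SNPs in 1-based inclusive coordinates. Reading the dual
"5 Mb / minimum 50 SNPs" window constraint as *span-based* windows
instead would make any tract shorter than the window undetectable in a
heterozygote-rich background — contradicting the 500-kb minimum rule —
so the count-based window with a span cap is the only self-consistent
interpretation, and the sweep test confirms 500 kb is exactly the
shortest emitted tract. Per-segment heterozygote/missing totals are
whatever the window rule admits (they scale with the number of windows
a segment spans); no separate per-segment cap is imposed. Autozygosity
fractions divide summed segment lengths by the analyzed span (first to
last autosomal SNP per chromosome, unless a genome span is supplied).

## Bayesian outlier scan

The hierarchical model: a_ij ~ Binomial(n_j, p̃_ij),
p̃_ij ~ Beta(θ_ij p_i, θ_ij(1−p_i)), θ_ij = 1/F_ij − 1,
logit(F_ij) = α_i + β_j. The Beta layer is marginalized analytically to
a beta-binomial likelihood — fewer dimensions, better mixing — and
F_ij is clamped to [10⁻⁶, 1−10⁻⁶]. Priors: α_i ~ N(0, 1),
β_j ~ N(−2, 1.8²) (logit⁻¹(−2) ≈ 0.12, a sensible baseline
divergence), p_i ~ Uniform(0,1), prior inclusion π = 0.5 — even prior
odds, the setting under which BF = 10 corresponds to posterior
probability 10/11 ≈ 0.91 and BF = 100 to ≈ 0.99. Updates per sweep:
vectorized random-walk Metropolis on every p_i (reflected at the unit
interval) and every included α_i, a reversible-jump toggle of every
locus using the α prior as the birth proposal (so prior and proposal
cancel, leaving the likelihood ratio times the inclusion odds), and
sequential random walks on the β_j. Ten pilot runs tune the three
proposal widths by ×/÷1.5 toward a 0.25–0.45 acceptance window; tuning
that still leaves acceptance outside [0.05, 0.9] aborts with
diagnostics. Default chain lengths are 10×5,000 pilot, 50,000 burn-in,
100,000 sampling (thinning 10); the `fast` profile (10×500 / 5,000 /
10,000) is used by tests and the desk-scale analysis scripts — at these
lengths a 1,000-locus two-group scan runs in well under a minute.
q_i is the thinned posterior inclusion rate; q_i ∈ {0, 1} is clipped by
half a thinned-sample weight so Bayes factors stay finite (a locus
included in every retained sample reports log₁₀BF ≈ log₁₀(2·kept), far
above the decisive threshold). Evidence classes: strong at
log₁₀BF ≥ 1, decisive at > 2.

## The synthetic-data generator

The generator emulates the statistical structure of a multi-population
chip survey, scaled to desk size: populations of 5–32 diploids, mean
SNP spacing defaulting to 55.6 kb, divergence F per population in
(0, 1), hyperbolic LD decay, admixture, planted autozygous tracts,
planted outlier loci, and missingness. Design choices:

* **Divergence** is Balding–Nichols: population frequencies are exact
  Beta(p(1−F)/F, (1−p)(1−F)/F) draws (mean p, variance Fp(1−p)), which
  is what makes Weir–Cockerham recovery a sharp test.
* **Ancestral frequencies** follow a reflected Gaussian random walk
  along each chromosome (default sd 0.0015 per √kb within
  [0.05, 0.95]) rather than i.i.d. draws. This matters: two Bernoulli
  variables can only be strongly correlated if their frequencies are
  close, so strong LD requires linked SNPs to carry similar
  frequencies, as they do in real genomes.
* **Within-population LD** comes from first-order binary Markov chains
  over haplotypes whose transition probabilities are solved per SNP to
  keep every marginal exactly at the population frequency while the
  allele correlation over a gap d inside a genomic region is
  e^(−λd/2), i.e. r² = e^(−λd). Region-wise rates λ ~ Exponential with
  mean β (stratified inverse-CDF draws, so small region counts still
  match the nominal mixture) give E[r²(d)] = 1/(1+βd) *exactly* by the
  identity E[e^(−λd)] = 1/(1+βd). Infeasible transition targets
  (Fréchet-bound violations near frequency jumps) are clipped, which
  adds a small extra decay; fitted β recovers the generative value
  within ≈10% under the validation conditions (3,000 SNPs at 10-kb
  spacing over 20 regions, ~2–3·10⁵ pairs).
* Each population's Balding–Nichols deviations are drawn through a
  Gaussian copula sharing the LD field (at a slower decay, exponent
  ¼), so frequency deviations vary smoothly along the chromosome;
  marginals remain exact Balding–Nichols, leaving F_ST recovery
  untouched.
* **Planted outliers** replace F with a boosted F* at chosen loci, use
  an intermediate ancestral frequency (0.5), and share one latent
  quantile across populations, antithetic between alternating
  populations — so alternate populations land on opposite Beta tails,
  the directional-selection contrast a scan should flag. Without these
  two constraints an extreme-F* locus frequently fixes on the *same*
  side in all populations and carries no signal.
* **Admixture** samples each haplotype of the target population from
  one of two source populations (fraction f), which makes mean PCA
  scores interpolate between the sources. **Planted autozygosity**
  copies one haplotype over the other inside the tract. **Missingness**
  is independent uniform masking.

What the generator does *not* emulate: mutation/recombination
mechanics, site-frequency-spectrum realism, shared phylogenetic
structure among populations (all populations radiate independently
from one ancestral pool, so super-groups of independently drifted
populations are not expected to be monophyletic), LD-phase persistence
across populations, and array ascertainment. Passing tests therefore
demonstrate estimator correctness and parameter recovery under the
stated generative laws — not robustness to demographic features the
generator lacks.

A deterministic fixture builder (`roh_sweep_panel`) constructs the
ROH threshold sweep: planted fully homozygous tracts of 100–1,000 kb
on one chromosome (one SNP per 5 kb) in a background alternating
heterozygous/homozygous calls with a heterozygote flanking every
tract. The alternation makes the window hit rate at tract edges
deterministic — called segments coincide exactly with the planted
tracts — so the sweep isolates the minimum-length rule from edge
sampling noise.

## Problem sizes and runtime

The analysis scripts run an 8-population, 110-sample, 3,000-SNP study;
recovery tests use 5,000 SNPs (F_ST), 3,000 SNPs × 20 regions (LD) and
1,000 loci (selection scan, fast profile). These sizes put every
recovery check within its stated tolerance while the full test suite
and the analysis scripts each complete in a few minutes on one core;
all sizes are configurable upward.

## Known limitations

* The per-SNP F_ST average is Jensen-biased below the generative F
  (see above); use the multilocus form for calibration questions.
* PLINK text round trips cannot preserve the orientation of
  monomorphic SNPs (no allele letters in `.map`).
* The LD generator's clipping makes realized decay slightly faster
  than nominal for extreme frequencies or very small λ regions; the
  documented recovery tolerance absorbs this.
* The outlier scan assumes biallelic counts and two-or-more groups; it
  does not compute q-values or FDR, and with q_i saturated at 1 the
  reported Bayes factor is a resolution-limited lower bound.
* NJ is quadratic-to-cubic in samples and the exhaustive prune pass
  quadratic in surviving SNPs; both are fine at chip-study scale but
  not for biobank-size inputs.
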