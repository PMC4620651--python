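# Methods

This note documents the models, estimators and numerical conventions
implemented in `adnapop`, the defaults chosen where the design was open,
and what the synthetic-data tests do and do not demonstrate.

## Containers and conventions

Genotypes are held as alt-allele dosage matrices (loci × samples) with NaN
for missing calls and per-sample ploidy, so a low-coverage ancient genome
can enter either as diploid calls (default) or pseudo-haploid (one allele
per locus, ploidy 1); frequency computation weights a pseudo-haploid
sample as a single allele copy. Coordinates carried by the containers are
1-based inclusive (VCF convention); window and gene inputs are BED-style
0-based half-open and converted at the boundary. Loci must be strictly
ordered within chromosome. Sites with a missing frequency in any
population required by a statistic are skipped for that statistic and
reported in a skipped-site tally.

## Contamination from diagnostic sites

Reads overlapping a panel of diagnostic SNPs (sites where the endogenous
lineage and candidate contaminating lineages carry different alleles) are
classified by the allele they carry. A read counts once regardless of how
many panel loci it spans: it is contaminant if **any** spanned locus shows
a contaminant-class allele, informative if at least one spanned locus
shows either allele class, and discarded otherwise (third alleles from
sequencing error). The estimate is the contaminant fraction of informative
reads — an upper bound, since sequencing error also produces contaminant-
class calls. Transversion-only mode restricts the panel to loci whose
every endogenous/contaminant pair is a transversion, removing inflation
by post-mortem C→T/G→A deamination. An optional Jeffreys 95 % binomial
interval (off by default) quantifies counting uncertainty. The same
contract applied per contaminating source to hemizygous-X diagnostic
sites gives nuclear contamination estimates for a male sample; the
estimator refuses non-male sex assignments, since X heterozygosity is
then expected rather than diagnostic.

## Molecular sex

Sex is called from the ratio of X to mean autosomal fold-coverage:
male < 0.6, female > 0.8, ambiguous between. The gap reflects that the
theoretical ratios (0.5 and 1.0) are approached only up to mapping and
copy-number noise; forcing a call inside the gap would be brittle. On
simulated chromosome-level depths with ~5 % coefficient of variation the
thresholds recover the simulated sex in ≥ 99 % of samples.

## Fragment lengths and damage

The fragment summary reports the lower median (an observed length, and
deterministic for even counts) and inclusive per-range proportions.
Damage profiles are empirical conditional rates: at distance d = 1..k
(default k = 25) from each read end, rate(X→Y, d) = reads with read base
Y among reads with reference base X at d. Positions with no conditioning
observations report a missing rate, never 0. No likelihood model or
quality rescaling is attempted — the curves are the diagnostic.

## Variant tabulation

SNPs are single-base substitutions; transition means A↔G or C↔T.
"Heterozygous" means exactly one ancient allele differs from the
reference, "homozygous" means both do; sites with two distinct
non-reference alleles fall outside the biallelic scheme and are dropped
with a count. The composite quality filter keeps depth ≥ 5 (inclusive)
and LOD > 2 (exclusive). Weighted means of per-cell percentages are
count-weighted; when reconstructing a published table they are taken over
the printed (rounded) percentages, and otherwise from raw membership
flags — both modes are exposed because one-decimal printing loses
information.

## D statistic, f3 and the block jackknife

The D statistic uses the symmetric, polarization-free ABBA/BABA form by
default because the outgroup (a separate species in the motivating
application) may itself be polymorphic or misassigned; a strict
outgroup-polarized mode (sites with pO ∈ {0,1} only, derived-allele terms
only) is available. Significance comes from a delete-one-block jackknife
over blocks of 50 consecutive used SNPs (the f3 blocking convention,
applied uniformly), with unequal final-block weights handled by the
delete-m pseudovalue formula; with equal weights this reduces exactly to
the ordinary delete-one jackknife, which is the tested invariant. Blocks
proxy linkage: sites within a block are not assumed independent, blocks
are. |Z| ≥ 3 is the conventional reporting threshold. f3 uses per-site
terms (x−a)(x−b) with the finite-sample correction x(1−x)/(n_x−1)
subtracted by default (requiring ≥ 2 target allele copies); the mean over
sites is jackknifed with the same blocks. The single ancient genome
enters as a population of one, diploid or pseudo-haploid.

## HKA scan

Per window, S counts sites segregating within the ingroup and Dv counts
sites where the ingroup is monomorphic for an allele differing from the
outgroup allele — the conservative fixed-difference reading of divergence
(a frequency-weighted mode exists). Sites without an unambiguous outgroup
allele (missing, or heterozygous diploid call) or with no observed
ingroup copies are excluded from L. Each window's expected S and Dv are
proportional to the genome-wide S:Dv ratio computed **excluding that
window** (leave-one-out), so a strong sweep does not dilute its own null;
the statistic is the 1-df chi-square form, with a Fisher exact fallback
when an expectation is zero. Windows come from a BED file or fixed-width
tiling (50 kb default — window size is an analysis choice, not a model
quantity). q-values are Benjamini–Hochberg over testable windows
(statsmodels implementation); when no window passes FDR, raw p ≤ 0.05
windows are to be read as suggestive only. Because every window's
expectation shares the genome totals, tests are mildly dependent; at
realistic sparse per-site rates the neutral p ≤ 0.05 fraction calibrates
to ~0.05, while dense counts (tens of percent of sites variable) make the
conditional-binomial variance visibly smaller than the chi-square
assumes and the scan conservative.

## Fixation filter and region classes

"Near fixation for different alleles" is read as both groups ≥ threshold
(default 0.95) for **opposite** alleles, with group frequencies pooling
allele copies across the group's populations, and the ancient sample
homozygous (all observed copies) for the second group's major allele.
Frequencies are allele-level, the natural scale for shallow panels.
Region classification takes the most specific class
(exon/UTR > intron > flank > intergenic); a gene model without annotated
sub-features counts as exonic throughout its body; ties across
overlapping genes go to the first gene in sorted order and are flagged.
Flanks (default 5 kb) are strand-aware: upstream is 5′ of the gene,
strand-less models fall back to coordinate order with a warning.

## Synthetic-data generators

The generators exist to give every estimator an input with known truth;
they are deliberately simple in frequency space rather than coalescent
simulations, so the expected sign and order of magnitude of D and f3 are
analytically transparent.

**Population panels.** Ancestral frequencies are Uniform(0.05, 0.95)
(SNP-panel-like ascertainment: rare and fixed sites underrepresented).
Each branch of (((P1, P2), A), O) applies one Balding–Nichols step,
p′ ~ Beta(p(1−F)/F, (1−p)(1−F)/F), with default intensities O = 0.80,
root→mid = 0.10, A = 0.20, stem = P1 = P2 = 0.05. These mirror the
motivating setting: a deep species-level outgroup (yak — mostly fixed
differences at cattle SNPs), a wild lineage at cumulative Fst ≈ 0.3 from
the domestic populations, and breed-scale differentiation (Fst ≈ 0.05)
among test populations. Introgression replaces the target's frequency
with (1−f)·p_target + f·p_A. Genotypes are binomial draws for 20 diploid
samples per modern population (matching typical per-breed panel sizes)
and one ancient sample; 15,000 loci by default, mirroring a ~15k-SNP
genotyping panel. Loci are exchangeable — no recombination or LD — so the
block jackknife is exercised structurally (contiguous blocks) but the
generator cannot validate its robustness to real LD decay.

**Ancient reads.** Each read covers one uniformly drawn diagnostic locus
and is contaminant with probability c; alleles come from the respective
haplotype and are flipped by sequencing error e = 0.001 to a uniformly
chosen different base (so any specific substitution occurs at rate e/3).
Fragment lengths are log-normal with median 50 bp (σ_log = 0.35),
truncated to ≥ 16 bp by resampling — the ancient-typical distribution.
Terminal damage acts on endogenous reads only (modern contaminant DNA is
undamaged by default): at distance i from the relevant end, reference C
(5′) or G (3′) bases read as T or A with probability
d(i) = d_max·λ^(i−1), defaults d_max = 0.3, λ = 0.5 — a strongly damaged,
clearly ancient library.

**Sweep panels.** Windows of 50 kb carry 300 candidate sites each, a
resequencing-scale density; per site the polymorphism probability is 0.5
(divided by the diversity-reduction factor, default 10, in sweep windows)
and the fixed-difference probability 0.1, unchanged by sweeps — the HKA
signature of a sweep being locally suppressed diversity with unchanged
divergence. Truth records list the sweep windows.

All generators are deterministic given a seed; emitted tables round-trip
through the package's own readers.

## What the tests show — and don't

Worked examples (contamination percentages, the published variant table,
ti/tv) are reproduced exactly from printed inputs. Statistical behaviour
is verified on the generators above: null D z-scores are approximately
standard normal over 500 replicates of 10,000 sites, f = 0.1
introgression at 15,000 sites is detected with correct sign and |z| > 3,
planted 10-fold sweeps rank at the top of the scan, injected
contamination fractions are recovered within binomial error. Problem
sizes in the test suite (10–15k SNPs, 200 windows × 300 sites, 10⁵ reads)
were chosen as the desk-scale regime the statistics themselves operate in.
Because the generators omit LD, ascertainment bias beyond the uniform
ancestral-frequency window, reference bias, and damage-driven genotype
error, passing tests demonstrate correctness of the estimators under
their stated models — not robustness to every artefact of real ancient
data. Known limitations: the X-contamination estimator assumes no
copy-number or assembly artefacts at its diagnostic sites; HKA p-values
lean on a chi-square approximation that turns conservative for dense
per-window counts; the candidate filter classifies regions only and does
not predict coding consequences.
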