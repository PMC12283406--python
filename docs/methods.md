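# Methods

`colonyphylo` analyzes whole-genome sequencing of single-cell-derived
hematopoietic stem/progenitor cell (HSPC) colonies: each colony grows from
one cell, so its somatic variants are (ideally) heterozygous at VAF 0.5 and
record that cell's lineage history. The package covers the downstream
analysis once per-colony variant calls exist: filtering, signature
attribution, phylogeny with molecular-clock scaling, clonal-diversity
statistics, bulk tumor ancestor placement, and a Moran-model simulator of
HSPC population dynamics. Everything upstream (alignment, raw calling,
copy-number analysis, de novo signature extraction) is out of scope.

## Somatic mutation filtering

Candidate variants carry per-colony alt/total read depths. Filters run in a
fixed order; each site receives exactly one status:

1. **Germline**: alt and total depths are pooled across all colonies of the
   patient and tested against a null VAF of 0.5 (0.95 on sex chromosomes in
   males) with an exact one-sided binomial test, lower tail:
   p = P(X ≤ alt_sum | depth_sum, p0). Sites with p > 1e-10 are germline.
   The lower tail is the informative side: a constitutive variant pools to
   VAF ≈ p0, whereas a somatic mutation private to a few colonies pools far
   below it. Pooled depth of zero is an error, not a classification.
2. **Proximity**: any two sites on one chromosome within 10 bp (inclusive)
   are both removed — clustered calls are typically alignment artifacts.
3. **Coverage**: genotypes at depth < 5 (autosomes, X in females) or < 3
   (X/Y in males) become missing ("NA"); a site missing in more than five
   colonies is dropped entirely.
4. **Mean VAF**: sites whose mean VAF over mutant-read-bearing colonies is
   ≤ 0.3 are removed. This targets mutations acquired during in-vitro
   culture, which are subclonal within the colony.
5. **Recurrent low VAF**: sites showing 0 < VAF < 0.1 in more than 10% of
   colonies are removed (recurrent sequencing artifacts).

Genotypes on kept sites are 1 when alt reads ≥ 2 (configurable), 0
otherwise, NA where coverage failed. The pipeline is deterministic and
idempotent on its kept output.

**Colony clonality QC.** A single-cell-derived colony shows one VAF mode
near 0.5; merged colonies show shifted or multimodal histograms. We build a
bin-width-0.05 histogram of the colony's own somatic VAFs, smooth it with a
1-2-1 kernel, and call modes as local maxima above 25% of the tallest bin.
A colony passes iff exactly one mode lies in [0.4, 0.6]; with fewer than 30
informative sites the result is *indeterminate*, not a failure. The
smoothing step matters: VAFs are ratios of small integers (depth ≈ 30), and
unsmoothed fixed-width bins produce a sawtooth whose spurious local maxima
failed ~28% of genuinely clonal colonies in simulation; with smoothing,
0/200 clonal colonies fail and 0/200 simulated two-cell merges pass. All
constants (bin width, mode fraction, window, smoothing) are configurable.

## Mutational signatures

Spectra live on the 96 pyrimidine-strand trinucleotide channels
(substitution-major order C>A…T>G, flanks alphabetical; purine-strand calls
are reverse-complement-folded). Exposure refitting is non-negative least
squares (`scipy.optimize.nnls`) against a reference catalog; exposures
below one mutation are zeroed to stabilize posteriors. A candidate
signature is *novel* when its best catalog cosine similarity is ≤ 0.80.
Per-mutation attribution uses
P(sig | channel) = e_sig · sig[channel] / Σ_s e_s · s[channel].

The packaged catalog (`default_reference_signatures`) holds **synthetic**
parametric analogs: SBS1 (C>T spikes at NpCpG from 5-methylcytosine
deamination), SBS5 (flat, clock-like) and a melphalan-like alkylator
signature (T>A-dominated with non-CpG C>T). They are adequate for
simulation and testing — pairwise cosines 0.02–0.44, well below the 0.80
novelty boundary — but a curated catalog should be supplied as TSV for real
data.

## Phylogeny

**Topology.** Colony genotypes are near-noise-free binary characters, so
the tree is built by perfect-phylogeny reasoning rather than an external
maximum-likelihood program: mutations sharing a carrier set define a
candidate clade; compatible carrier sets form a laminar family with a
unique rooted tree; the hypothetical all-reference zygote is the outgroup
root. Carrier sets conflicting with better-supported ones (possible only
under genotyping noise; ordering is by clade size, then mutation support)
do not shape topology — their mutations are placed at the carriers' MRCA
branch and flagged. Missing genotypes are treated as absence for carrier-set
formation; every kept mutation is assigned to exactly one branch, so branch
molecular lengths sum to the number of kept mutations.

Internal edges carrying zero mutations are unidentifiable from genotype
data; comparisons between inferred and generating topologies therefore use
the mutation-supported resolution of the genealogy
(`tree.collapse_unsupported_edges`). On noise-free simulated cohorts the
builder recovers that resolution exactly (Robinson–Foulds distance 0).

**Ancestral states** use minimum-change (small-parsimony) reconstruction
with the root forced to all-absent. The dynamic program is Sankoff-style
min-cost over the two states, which is exact on multifurcating nodes —
classic two-child Fitch set-folding applied pairwise across a polytomy can
exceed the minimum, which we verified against exhaustive enumeration.

**Branch signature adjustment.** Each node's implied mutation set (union of
branch mutations on its root path) is refit against the catalog; per-branch
signature counts are child-minus-parent exposure differences. Negative
differences are numerical artifacts of independent per-node refits and are
zeroed when they lie in [−1, 0) or are smaller in magnitude than 5% of the
branch's total signature count; otherwise the branch is flagged as a
genuine inconsistency rather than silently clamped.

**Clock scaling.** Treatment-related mutations distort elapsed-time
estimates, so branch clock lengths count only mutations *not* attributed
(maximum posterior ≥ threshold, default 0.5) to the excluded signature —
equivalently the clock-like SBS1+SBS5 content. Ultrametric scaling: each
tip's cumulative clock count maps linearly onto the donor's age; an
internal node's time is the mean of the times implied by its descendant
tips; a top-down pass enforces parent ≤ child. Chosen for simplicity: the
trees are displayed ultrametric and any monotone consensus of per-tip
scalings serves; topology and tip set are never altered.

**Bulk (t-MN) placement.** A bulk genome's MRCA is the deepest branch whose
entire root path is detected in the bulk sample (VAF ≥ 0.05 and ≥ 2 alt
reads, both configurable — the defaults suit ≥ 50× bulk coverage and
purity ≥ 0.1); detected mutations off that path are reported as unshared.
No detected overlap yields an explicit *no MRCA* result, mirroring cases
where the tumor lineage diverged below the sampled colonies' resolution.

## Clonal diversity

A clade partition cuts the tree at a fixed root distance (years on the
ultrametric tree, or mutation counts; default 100 clock mutations —
roughly the first years of life, where normal HSPC lineages have already
separated); each crossing lineage founds a clade. Reported indices carry
their cut parameters as metadata, since clade counts depend on the cut.
Simpson's evenness is (1/Σp²)/S ∈ (0, 1]; Shannon is −Σ p ln p; subsampling
draws uniformly without replacement (e.g. 100 cells from 100,000 emulates
sequencing a finite colony panel) and is exact at full population size.

## Moran model

`n` active HSPCs; one step = 1/n year (≈ one division per cell per year);
per step one uniformly chosen death and one fitness-proportionate division,
Pr(division of cell k) = (1 + i_k·s)/Σ_j(1 + i_j·s), where i_k counts
driver mutations acquired at rate `u` per division. Every founding cell is
its own clone (the adult clonal pool is treated as established in early
childhood) and diversity is computed on those labels, so the neutral arm
(s = 0) is run without mutation bookkeeping — label dynamics are identical.

Chemotherapy reduces the population linearly to ε·n between the start and
end ages (excess deaths only) and recovery restores it linearly to n within
β years (excess births only) — the simplest schedule consistent with a
stated bottleneck depth and recovery duration; the schedule is evaluated at
each step's end so the floor ε·n is hit exactly at chemotherapy end. In the
resistant scenario, resistance arises with probability `m` per division
(before or during chemotherapy only) and resistant cells die with relative
weight `w` < 1 during treatment.

Weighted choices in the fast path use rejection sampling (accept cell k
with probability weight_k/weight_max), which samples exactly the
fitness-proportionate and death-weight distributions; the explicit
per-cell probability vectors remain available
(`division_probabilities`, `death_probabilities`, `moran_step`) as the
small-n reference, and a chi-squared comparison ties the two paths
together in the test suite. Replicate RNGs are spawned from the master seed
via `numpy.random.SeedSequence`. Single replicates at n = 100,000 over 80
years (8×10⁶ steps) run in well under a minute.

Defaults (documented working values, not calibrated to any dataset):
s = 0.1, u = 1e-5/division, ε = 0.3, β = 1 year, chemotherapy at ages
35–40, m = 1e-6, w = 0.1. When the resistant scenario is run at reduced
population size, `m` should be scaled inversely with n so the expected
number of pre-chemotherapy resistance events (m·n·years) is preserved; the
test suite uses m = 2e-5 at n = 5,000 to represent the n = 100,000
condition.

## Synthetic cohorts

The generator produces every pipeline input with known truth labels. The
genealogy is a coalescent-like random binary tree in years: background
lineages coalesce uniformly within the first five years of life; each
driver clade is forced to coalesce at its stated origin age and carries a
labeled driver mutation on its stem. Somatic mutations accrue as a Poisson
process at the clock rate (default 17.2 SNVs/year, the normal-donor rate)
along branches; an optional melphalan-like burst adds
extra-mutations/colony uniformly between exposure age and sampling, always
drawn from the melphalan-like signature. Contaminants: germline sites
(VAF 0.5 in every colony), in-culture mutations (private, VAF uniform in
[0.1, 0.25] — below the 0.3 mean-VAF cutoff), and artifact sites (alt
fraction 0.05 recurring in 12–25% of colonies). Reads: depth
Poisson(mean 30), alt Binomial(depth, VAF). Bulk samples contain all
mutations on the root→origin path at VAF purity/2 plus private mutations.

What this does *not* emulate: copy-number change and loss of
heterozygosity (so no allele-dropping re-evaluation), mapping or
context-dependent error, index hopping, clade-size distributions calibrated
to any real cohort, or culture-growth population structure beyond a single
subclonal VAF draw. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to every
artifact of real WGS.

## Problem sizes and tolerances

The test and acceptance runs use: 6 normal donors × 38 colonies (rate
regression; recovered slope falls within the reported 95% CI
[16.3, 18.2]/year), 100 colonies at depth 30 (filter recovery ≥ 95%
both directions), 20 cohorts of 50 colonies (tree fidelity, RF = 0),
exhaustive parsimony checks on ≤ 7 tips, 2,000 sampled mutations
(exposure recovery within 0.03), Moran runs at n = 10–5,000 with
10,000/5,000 fixation replicates (3–3.5 SE bands against closed forms)
and 150–200 trajectory replicates, and 20 bulk placements at purity 0.7
(100% recovery). Numerical comparisons against the exact-rational
binomial oracle hold to 1e-12.
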