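# Methods

## Clone identity and counting conventions

The unit of analysis is the nucleotide TCRβ rearrangement string. Template
counts are genomic-DNA molecule counts, so a clone's count is a direct
estimate of its cell number; nucleotide identity (rather than CDR3 amino
acid) avoids collapsing convergent rearrangements when tracking clones
across samples. Non-productive rearrangements are parsed and retained with
a flag but excluded from every total, frequency, statistical test and
overlap index: all normalization is to the productive template total of
the sample. Two tab-separated column dialects (immunoSEQ-export style and
AIRR style) normalize to one internal representation; duplicate
rearrangement rows are merged by summing counts.

## The differential-abundance test

For a clone with counts $(c_a, c_b)$ in two samples with productive totals
$(N_a, N_b)$, the null model is $c_a \sim \mathrm{Bin}(c_a+c_b,\,
N_a/(N_a+N_b))$: the clone's templates fall into the two samples in
proportion to repertoire size. The two-sided p-value uses the
minimum-likelihood convention — the sum of all outcome probabilities not
exceeding the observed one — which is symmetric under sample swap;
tail-doubling is available as an option. Floating-point near-ties in the
point-probability comparison are resolved with a relative tolerance of
1e-7 (configurable), the common exact-test convention. Internally,
p-values for all clones sharing a combined count are answered from one
sorted, cumulated pmf, so a full pairwise comparison over ~10⁴ clones runs
in well under a second.

DRTC gates, in order: (1) combined count ≥ 5, below which no p-value is
assigned and the clone does not contribute to the Benjamini-Hochberg
multiplicity; (2) BH-adjusted q < 0.01, with multiplicity counted within
the single pairwise comparison only (analyses are per subject, never
pooled); (3) MLR frequency ≥ 2× the unstimulated frequency. A clone
undetected in the unstimulated sample satisfies the fold criterion with no
pseudocount — a pseudocount would silently move the 2-fold frontier and
suppress exactly the newly detected MLR clones the definition exists to
capture. Clones significant in the opposite direction are labelled
`enriched_unstim`; they can never be DRTC even when tested.

## Overlap indices

"Morisita index" is implemented as Morisita-Horn on template frequencies:
the classical Morisita index uses integer-count dispersion terms and can
exceed 1, whereas the 0–1 range the analysis relies on is the
Morisita-Horn property. Jaccard is computed on productive clone-key sets.
Detection anywhere in the package means ≥ 1 template; template counts are
already molecule-level, and no abundance floor is applied to presence
calls. The pairwise QC screen flags different-subject pairs with
Morisita-Horn above 0.2 (configurable) as possible swaps; same-subject
pairs are never flagged.

## Tracking and categorization

Timepoints order as pre_tx < wk2 < m3 < rejection < m6 < m12; rejection
episodes in the emulated schedule occur on average around four months, so
"rejection" sorts after the 3-month visit. Graft-detected DRTC are
partitioned exclusively into pre_only / pre_and_post / post_only /
graft_only by blood presence; the cumulative pre-transplant share
(pre_only + pre_and_post) is derived from the partition so both
presentations are available. With no post-transplant blood sample the
partition degrades to {pre_only, graft_only, undetermined} with an
explicit flag — no imputation. Per-subject proportions are summarized
across a cohort by medians with ranges. When a subject has several
biopsies, the earliest (first episode) anchors the categorization.

## Synthetic cohort

The generator emulates the structure the analysis assumes, not the
biology of V(D)J recombination. Per subject: ~10,000 clones with Zipf
(exponent 1.5) generative frequencies — the standard heavy-tailed
repertoire model, configurable since no distribution is prescribed by the
data; 2% alloreactive clones split 2:1 CD4:CD8; MLR expansion factors
log-normal with median 8 (σ = 0.6); multinomial template sampling at
depths 100,000 (PBMC), 20,000 (MLR sort), 3,000 (biopsy), 500 (urine).
Induction therapy removes a uniform random fraction of clones from the
post-transplant blood (0.9 lymphodepleting, 0.1 otherwise). Rejection
subjects (default one in four, present in both induction groups) get
(a) a 5× elevated pre-transplant CD8⁺ alloreactive frequency, (b) graft
infiltration drawn from the *pre-transplant* circulating alloreactive pool
at 20× over-representation — so graft clones trace back to the
pre-transplant blood even under lymphodepletion — and (c) urinary shedding
of half the infiltrating clones into the 2-week urine. Urine otherwise
contains only a urine-resident background pool of 50 fresh clonotypes
(half the sample mass under rejection, all of it when stable): stable
allografts shed few T cells, and this makes urine→biopsy DRTC overlap a
clean rejection signal. Clone strings are random in-frame 87-mers; CDR3/V/J
annotations are synthetic placeholders.

Randomness uses one root seed; subject *i* draws from
`SeedSequence(root, spawn_key=(i,))`, so any subject is independently
reproducible and a fixed seed yields a bit-identical cohort.

What the generator does **not** emulate: PCR amplification bias and its
correction, V/J usage structure, sequencing error and clone collapsing,
HLA-mismatch-dependent effect sizes, repertoire turnover between serial
timepoints beyond induction depletion, and the cell-type purity of sorted
populations. Passing tests therefore demonstrate the pipeline's
correctness and operating characteristics under the stated generative
model, not clinical performance on real repertoires. In particular the
absolute DRTC counts per subject are governed by `alloreactive_fraction ×
n_clones` and the sampling depths, and sit well below clinical MLR yields.

## Statistical comparisons

Group tests delegate to scipy: Mann-Whitney U (exact when combined n ≤ 20
without ties, tie-corrected normal approximation otherwise), Wilcoxon
signed-rank (zero differences dropped; exact when ≤ 15 non-zero
tie-free pairs), Kruskal-Wallis with tie correction, Fisher's exact
(minimum-likelihood two-sided; a zero margin is flagged degenerate with
p = 1). Exactness thresholds are desk-scale choices and configurable;
enumeration oracles in the test suite pin the exact paths.

## Numerical and degenerate-input choices

- Frequencies always renormalize over productive clones and must sum to 1
  within 1e-9.
- An empty repertoire cannot be written to disk, tested, or used in an
  overlap index (explicit errors); an empty DRTC set is a valid input
  everywhere downstream and yields zero metrics.
- BH on an empty vector returns an empty vector; adjusted values are
  capped at 1 and never below the raw p-values.
- Identical samples passed to the caller produce zero calls, not an error.
- Pipeline outputs contain no timestamps; identical inputs and
  configuration reproduce byte-identical files.

## Problem sizes used in validation

The test suite and acceptance script size their simulations as follows:
null false-discovery control with 200 replicate pairs of 5,000-clone
repertoires at 50,000 templates per side; spike-in recovery with 50
replicates of 2,000-clone repertoires, 50 clones expanded 8-fold at
expected MLR counts ≥ 20; qualitative cohort patterns on the default
12-subject cohort; end-to-end byte-identity on a 4-subject cohort with
2,000 clones per subject. These sizes give stable medians and error-rate
estimates at desk scale; all are parameters, not limits.
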