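# Methods

This note records the models, defaults, and design choices behind
`regfoot`, in the spirit of the methods documentation that accompanies
simulation and inference packages: what is computed, under which
assumptions, and what the synthetic validation does and does not show.

## Synthetic library generator

The generator reproduces the design of a barcoded promoter-mutagenesis
MPRA and is the ground truth for all validation.

**Window and coordinates.** A promoter window of L = 160 bp with the
assumed transcription start site (TSS) at window index 115, so the window
spans display positions −115…+44 with 0 at the TSS. All intervals are
0-based half-open in window coordinates; display coordinates are used
only for output.

**Mutagenesis.** Each base mutates independently with probability 0.10,
substituting uniformly among the three alternative bases (the real
assay's substitution spectrum is not modeled; indels, PCR bias and
sequencing errors are out of scope). Variants are regenerated until
unique, and the whole library is regenerated if its average mutation rate
leaves the 9.5–10.5% quality band, mirroring oligo-pool QC. Default
2200 variants per promoter, wild type included once.

**Barcodes.** Per-variant barcode counts are drawn from a Poisson
truncated at ≥ 1 with mean 5 (the design states only the mean; the
truncated Poisson is the simplest count model that guarantees every
variant is measurable). Barcodes are random distinct 20-mers.

**Expression model.** Each planted site carries a ground-truth energy
matrix in wildtype-zero gauge; the energy of a variant's site sequence is
the additive-matrix sum, and the site's occupancy is the logistic
(Boltzmann) function expit(e₀ − E) anchored so the wild type is bound
with probability 0.95. Sites act independently (no cooperativity):
expression = baseline × Π over sites of (1 + s·p) for RNAP/activators and
((1 − p) + p·e^(−s)) for repressors, with s the interaction strength and
p the occupancy. A fully occupied repressor thus scales expression by
e^(−s), and an unbound site leaves the baseline. This generative link is
an explicit stand-in: the real mRNA-given-sequence distribution is not
known, and only its qualitative features (monotone in occupancy, correct
polarity, saturating) matter for what the pipeline is tested on.

**Read sampling.** DNA counts are multinomial over barcodes with
log-normal-perturbed weights (σ = 0.3), so DNA abundance estimation is
non-trivially exercised; mRNA counts are multinomial with weights
proportional to DNA weight × expression. Column sums equal the requested
totals (default 5×10⁴ each) exactly. All stages consume explicit seeds
and are byte-reproducible.

**Default architecture.** The default template is a simple-repression
promoter: a 30-bp σ70-like RNAP site at display −35…−5 whose wild type
carries the consensus TTGACA/TATAAT hexamers (non-consensus penalties
~2.5 A.U. at the hexamers, near-neutral spacer), and a 15-bp repressor
operator at display +1…+16 (penalties ~2.0 A.U., strength 2.5). The RNAP
exemplar matrix shipped in `regfoot/data/rnap_sigma70_synthetic.tsv` is
this synthetic site's true matrix (the filename marks it synthetic); it
plays the role of an experimentally validated polymerase exemplar.

## Information footprint

The footprint is the plug-in mutual information of the per-position 2×2
table of read mass over (mutation state m, read origin μ), in bits, with
reads — not barcodes — as the unit of probability mass (a
`weighting="barcodes"` mode that gives each barcode unit mass is
available for abundance-skew-robust analysis). A pseudocount (default 1
read) is added to each of the four cells; because the pseudocount pulls
the joint toward the independent uniform table it shrinks MI toward
zero, controlling finite-sample bias rather than inflating it. Positions
where either mutation class has no reads are reported as 0 bits and
flagged low-support. Polarity compares the mRNA/DNA ratio of mutated
versus wild-type read mass; exact ties (essentially only in degenerate
tables) are assigned activating with a warning, keeping output
deterministic.

At the default depths the null footprint (no planted sites) has maximum
smoothed values around 10⁻⁵ bits, more than an order of magnitude below
the 2.5×10⁻⁴-bit calling threshold — the basis of the null-calibration
test.

Smoothing is a centered 15-bp moving average with shrunken windows at
the edges.

## Site calling

Calling is two-stage: the smoothed track seeds regions (positions ≥
2.5×10⁻⁴ bits, per polarity separately, so activator and repressor
regions may overlap); seeds within 4 bp join; edges are then trimmed
while the raw (unsmoothed) information is below the threshold. Raising
the threshold never expands coverage, though it can split a bridged
region in two; the tested invariant is nesting (every higher-threshold
region lies inside a lower-threshold one) plus non-increasing total
extent.

RNAP sites are found by scanning the exemplar matrix along a
whole-window inferred matrix and thresholding the Pearson correlation of
the flattened, mean-centered matrices at 0.45; overlapping hits collapse
to the best-scoring offset (ties leftmost, deterministic). The
whole-window matrix comes from the fast weighted-least-squares estimator
(below), not from a 160-bp MCMC run: scanning needs only the relative
per-base effect pattern, and the least-squares estimate recovers that
pattern accurately in a few milliseconds. Threshold-called regions that
overlap an RNAP hit are removed from the activator/repressor tally by
default (`exclude_rnap_overlap`), since a polymerase site footprints as
activator-like. The remaining counts give the (n_a, n_r) label;
promoters with no RNAP hit are "inactive".

**Speck filter.** `call_binding_sites` drops threshold-called regions
with 3 or fewer raw supra-threshold bases (`min_support=3`). Near a
strong site, the smoothing bleed-through keeps the seed track above
threshold for ~7 bp beyond the site while expression heterogeneity
across the finite variant pool lets isolated 1–2-bp raw excursions clear
the threshold, producing spurious single-base calls of arbitrary
polarity; curators discard such specks for the same reason. The filter
applies only at the pipeline level — `call_regions` itself is unfiltered
— and can be disabled with `min_support=None`. Known limitation, shared
with the underlying algorithm: two same-polarity sites closer than ~5 bp
merge into one call.

## Energy-matrix inference

`predict_energy` implements the additive model E(s) = Σᵢ ε[i, sᵢ].
Because only energy differences are identifiable, matrices carry an
explicit gauge (wildtype-zero or mean-centered) and are reported in
arbitrary units; no absolute (k_BT) calibration is attempted.

`infer_matrix` is a Metropolis sampler over matrix cells. The objective
is the plug-in MI between predicted-energy ranks, binned into 10
quantile bins by cumulative read mass, and the binary DNA/mRNA read
label (pseudocount 1 per cell). The objective depends only on energy
ranks, hence is invariant to increasing affine transforms of the matrix
— verified by test — which motivates both the gauge fixing and two
regularizing choices:

- a Gaussian prior on cells (σ = 1 A.U.): without it, the scale
  direction and low-leverage cells are exactly flat and random-walk
  unboundedly instead of shrinking to zero;
- canonicalization of recorded samples (per-position mean zero, unit
  Frobenius norm, sign aligned so mutations away from wild type have
  non-negative mean energy) before posterior averaging, since the MI
  objective is blind to sign and scale. Repressor-site fits routinely
  trigger the sign flip (weaker binding = higher energy for the
  repressor, opposite to the expression-effect sign), and a warning
  records it.

One random non-wild-type cell is perturbed per step (Gaussian proposal,
step size adapted during the 20% burn-in toward 20–40% acceptance);
acceptance uses inverse temperature β = total read count, putting
accepted MI drops on the order of the estimator's sampling noise. The
chain starts at the weighted-least-squares estimate by default: cold
starts strand single-cell Metropolis in local optima of the
finite-sample MI landscape (median recovery r ≈ 0.0–0.4 across seeds),
whereas least-squares-initialized 50k-step chains recover planted 8-bp
matrices at median r ≈ 0.99. Both the posterior mean (default) and the
maximum-objective state are returned.

`estimate_matrix_ols` regresses per-variant log₂(mRNA/DNA) ratios on
non-wild-type base indicators, weighted by total reads, and negates the
coefficients (activator sign convention). It is the MCMC initializer and
the whole-window matrix source for RNAP scanning.

**Logos.** Per-position base probabilities are Boltzmann weights
p(b) ∝ exp(−scale·ε), scaled by the position's information content
2 − H(p) bits; rendering uses matplotlib text paths.

## Enrichment statistics

Heavy/light intensity ratios are log₂-transformed (optional
pseudo-intensity for zeros). The null is fit robustly to the bulk —
center = median, scale = 1.4826×MAD — so a handful of genuine binders
does not inflate the null; each protein gets a one-sided upper-tail
normal p-value, Benjamini–Hochberg q-values, and a significance flag at
q < 0.01 (the stricter post-correction reading of a p < 0.01 criterion).
MAD = 0 is an error rather than a silent divide-by-zero. Under a
100-protein null the family-wise false-flag rate stays ≈ 1–2%, within
the tested 5% bound; a +8σ spike is always flagged. The regression-based
alternative outlier test is not implemented.

## Validation scope

Problem sizes used throughout the tests are the generator defaults
(2200 variants, ~11k barcodes, 5×10⁴ + 5×10⁴ reads), with 10–20 seeds
for recovery and calibration suites and 50k MCMC steps for matrix
recovery. Passing these suites shows the pipeline is correct and
well-calibrated *under the generator's assumptions* — substitution-only
mutagenesis, independent-site occupancy, multinomial sampling. It does
not certify performance under real-data pathologies the generator
deliberately omits: sequencing error, PCR jackpotting, barcode
collisions and hopping, condition-dependent TF activity, cooperative or
overlapping same-polarity sites, and regulation acting from outside the
160-bp window.
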