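# Methods

## The task and the response models

In the restricted-classification (triad) task three stimuli appear in a
row and the participant picks the odd one out; equivalently, the remaining
pair "goes together". The stimulus set is eight colored squares of fixed
hue varying in Munsell chroma (4–12) and brightness (2–6). Following the
standard psychophysical equivalence for this space, chroma is multiplied
by 0.5 before any distance computation, so two chroma units equal one
brightness unit; distances below are always in these common units.

Eight logical triads (1-3-7, 1-5-7, 2-4-8, 2-6-8, 1-2-3, 1-2-4, 5-7-8,
6-7-8) are used, each displayable in 6 left/middle/right orders: 48
physical arrangements. A session is 96 trials in 12 blocks of 8; each
block contains one arrangement of each logical triad, and each arrangement
occurs exactly twice per session.

Four deterministic response models map an arrangement to a predicted odd
position:

* **OS** — exclude the pair with minimum scaled Euclidean distance;
* **UD(chroma)**, **UD(brightness)** — exclude the pair with minimum
  absolute difference on that one dimension;
* **ID** — exclude the pair exactly identical on a dimension;
* **Bias(left/middle/right)** — a fixed position.

Ties in OS/UD make the model abstain rather than guess: scoring stays
deterministic and an abstention never matches a response. Identity means
*exact* coordinate equality, with no epsilon: under coordinates recovered
by similarity scaling (generic floats) the ID model therefore abstains on
every trial, which is the intended behaviour of the re-analysis in the
psychological space — a near-identity generalization is deliberately out
of scope.

### Identity resolution in the design space

The design guarantees an identical pair in every logical triad, but two of
the eight triads necessarily contain an identical pair on *each*
dimension: the quoted design facts (the {1,7} chroma identity of 1-3-7,
and the brightness-UD prediction {1,3} on triad 1-2-3, which forces
stimuli 1 and 3 to share a brightness value) cannot be satisfied by any
coordinate assignment with a single identical pair everywhere. When pairs
on both dimensions are identical, the designed identity is taken to be the
one on the dimension the triad does not span — operationally, the
dimension with the smaller within-triad scaled range. This reproduces the
published predictions (ID groups {1,7} in 1-3-7 and {2,8} in 2-4-8). Two
identical pairs on the *same* dimension, or equal ranges, raise a
design-violation error.

## Reconstructed stimulus coordinates

Exact published coordinates for the eight stimuli were not available in
machine-readable form. The shipped file
(`data/stimulus_space_reconstructed.csv`) was obtained by enumerating all
placements on the even-chroma / integer-brightness Munsell grid and
keeping layouts consistent with every published design fact: the printed
ranges with both extremes in use; the quoted identity pairs; the
worked-example OS/UD predictions (OS groups {6,8} in 6-7-8 and {1,3} in
1-2-3; brightness-UD groups {5,7} in 1-5-7; etc.); absence of OS ties;
the quadrant memberships implied by the sub-analyses (6 and 8 in the
high-chroma/low-brightness quadrant); and the reported misfit pattern of
the rating-derived configuration (stimuli 2 and 4 as the outliers). One
layout satisfies all of these:

| stimulus    | 1 | 2  | 3 | 4 | 5 | 6  | 7 | 8  |
|-------------|---|----|---|---|---|----|---|----|
| chroma      | 4 | 12 | 6 | 8 | 6 | 10 | 4 | 12 |
| brightness  | 5 | 6  | 5 | 6 | 3 | 3  | 2 | 2  |

Independent corroboration: this layout implies d(2,4) = 2 > d(5,7) =
d(6,8) = √2 in scaled units, matching the ordering of the corresponding
mean similarity ratings (7.12 < 7.66, 7.34). Two consequences are
accepted: stimulus 4 sits on the chroma midpoint (8), so the
nearest-neighbour midpoint rule assigns it to the low-chroma/high-
brightness quadrant (harmless: every triad containing 4 also contains 2,
so quadrant-removal filters are unchanged); and chroma-UD abstains on
triad 1-2-4 (|c1−c4| = |c2−c4| = 4 exactly). Any alternative transcription
can be supplied as a CSV; `load_space` re-validates the identity
structure.

## Strategy classification

For each strategy the match count is the number of trials whose response
equals the strategy's non-abstaining prediction. Family counts collapse
UD as max(UD-chroma, UD-brightness) — a unidimensional responder uses one
dimension, so summing would double-count — and Bias as the max over the
three keys. The participant-level winner is the argmax over {UD, OS, ID,
Bias}; participant-level ties are flagged and excluded from contingency
analyses, mirroring the block-level policy. Block-level fits use the same
counts over 8 trials with Bias excluded (key bias is only identifiable
once positions have been counterbalanced, i.e. over the whole session);
blocks whose family maximum is shared are marked tied and removed.
Condition-level prevalence is the mean over participants of each
participant's proportions over their non-tied blocks, so participants are
weighted equally regardless of how many of their blocks were tied; the
per-participant proportions over {UD, OS, ID} sum to exactly 1.

## Synthetic data generator

The generator emulates the study conditions: 29 participants in the
100 ms condition and 17 at 2000 ms (≈2:1, the short condition being the
noisier one), a per-*block* strategy mixture (per-block resampling is the
middle ground between erratic strategy execution and inconsistent
strategy selection, and matches the granularity of the sensitive
analysis), lapse rate 0.05 (a lapse responds uniformly over all three
positions, the standard convention), and bias probability 0.02 per
participant. Default mixtures put UD at 0.12 (100 ms) versus 0.02
(2000 ms), split evenly between the two dimensions, with ID at 0.005 —
values chosen to reproduce the order of magnitude of prevalences observed
empirically in this paradigm; all are configurable. Ratings are
`clamp(round(9.5 − 1.5·distance + N(0, 1)), 1, 9)` over two 56-trial
blocks (each pair twice per block, left/right counterbalanced).

What the generator does *not* emulate: perceptual encoding noise that
scales with presentation time, within-block strategy switches, sequential
dependencies, reaction times, and rating drift across blocks. Passing
recovery tests therefore shows the *analysis* is consistent (it recovers
what the generative model put in), not that human data meet these
assumptions.

All randomness flows from one root seed through named substreams
(design/responses/ratings per participant), so runs are bit-reproducible
and adding participants does not perturb existing ones.

## Non-metric MDS

Similarities are converted to dissimilarities by δ = 10 − s (a monotone
reflection of the 1–9 scale onto 9–1; `max − s + 1` and `9/s` are
available alternatives — only ranks matter downstream, so the choice is
inert unless it reorders pairs, which none of these do). The
configuration starts at the classical (Torgerson) scaling solution —
making the pipeline deterministic — and L-BFGS minimizes Kruskal
stress-1, `sqrt(Σ(d−d̂)²/Σd²)`, where d̂ is the isotonic regression of
configuration distances on dissimilarity ranks (primary/stable tie
handling). The gradient treats d̂ as fixed (it minimizes the inner
least-squares problem, the standard Kruskal descent direction). The
city-block variant computes configuration distances with the L1 metric
inside the same loop, with sign subgradients (0 at exact coordinate
ties). Stress is reported ×100, the percent dialect of the classical
implementations; convergence is the optimizer's relative-reduction
criterion (ftol 1e-10). A degenerate input with all dissimilarities equal
carries no rank information and is returned unoptimized and flagged
non-converged.

On the packaged mean ratings the Euclidean solution reaches stress 0.038
and the city-block solution 3.185 (percent) — the Euclidean metric fits
better, the operational criterion for integral dimensions. An independent
check against the classical R implementation of the same algorithm
(MASS::isoMDS) on identical dissimilarities agrees to the third decimal
(one test shells out to Rscript for this).

Procrustes alignment minimizes least-squares misfit to the scaled design
coordinates over rotation/reflection (SVD), uniform scale, and
translation; these preserve ratios of inter-point Euclidean distances, so
the stress of a Euclidean solution is unaffected. Per-stimulus residuals
identify where perception departs from the nominal space.

## Inference

* **Contingency BF** (Gunel–Dickey, independent multinomial, rows fixed):
  with Dirichlet(a, a) priors (a = 1, the convention of the standard
  implementation) the marginal likelihoods are Beta functions and BF₁₀ is
  closed-form; a dense quadrature oracle agrees to 1e-6 in tests. This
  variant — per-row Beta(a, a) under the alternative against one shared
  Beta(a, a) under the null — reproduces the published value (0.14) on
  the participant-level table.
* **JZS BF**: BF₁₀ = ∫ f_nct(t; ν, δ√n_eff) Cauchy(δ; 0, √2/2) dδ /
  f_t(t; ν), by adaptive quadrature; the one-sided variant renormalizes
  the prior to a half-line. A 10⁶-draw Monte-Carlo prior integration
  agrees within 1%.
* **Replication BF** (Dienes): normal likelihood of the observed effect,
  normal prior centered on the earlier effect with SD half that effect
  (the half-SD convention); numerical integral cross-checked against the
  conjugate closed form to 1e-8, falling back to log-space closed form
  when the null density underflows. The BF applied to this paradigm
  operates on the difference in mean UD block proportions, the quantity
  the by-block analysis compares.
* **Power**: noncentral chi-square (ncp = N·w²) and noncentral t
  (ncp = d·√(n₁n₂/(n₁+n₂))). These are the asymptotic forms; at small N
  with few cells the exact multinomial rejection rate can differ by a few
  points through discreteness (the simulation checks therefore match the
  noncentrality in the large-N regime). For the chi-square claim at
  w = 0.40, N = 46 the df is not uniquely determined by a 2×2 design with
  sparse cells; df = 1 gives 0.774 and df = 2 gives 0.679, and both are
  exposed rather than asserting a printed round number. The two-sample
  allocation for d = 0.83, N = 50 is likewise a parameter (25/25 gives
  0.820).
* **Block trend**: OLS of condition-level per-block UD proportions (12
  blocks × 2 conditions = 24 rows) on block, a long-condition indicator,
  and their interaction; 4 parameters leave t statistics on 20 df.
  p values are two-sided; no multiple-testing correction is applied.

## Problem sizes and test design

The test suite regenerates all fixtures programmatically. Simulation
scales chosen for the checks: 240 pure-strategy participants for the
classification-recovery bound (≥95% correct at lapse ≤0.2), one 46-
participant experiment for mixture recovery (tolerance 3 Monte-Carlo
standard errors of the generating binomial), 50 replicate experiments for
the directional claim (higher fitted UD prevalence at 100 ms with JZS
BF₁₀ > 1 in ≥80% of replicates), 10⁵ replicates for power simulations,
and 10⁶ draws for the JZS Monte-Carlo oracle. Property-based tests
(hypothesis, derandomized) cover arrangement covariance of predictions
and the chroma/brightness exchange symmetry of scaled distances.

## Known limitations

* The design coordinates are a constrained reconstruction, not a certified
  transcription; all structural conclusions are invariant over the
  admissible set we enumerated, but exact Procrustes residual magnitudes
  depend on the specific layout.
* The Gunel–Dickey implementation covers the 2×2, rows-fixed case only
  (other sampling schemes are out of scope).
* Non-metric MDS is fit for 2 dimensions from one deterministic start;
  with 8 points this reliably reaches the same solution as the classical
  implementation, but no multi-start search is attempted by default
  (random restarts are available behind a seed).
* The block-trend regression treats condition-level proportions as
  homoscedastic observations, as is conventional for this analysis; it is
  not a participant-level mixed model.
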