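# Methods

## The model

ChIP-exo and ChIP-nexus experiments digest immunoprecipitated DNA with
lambda exonuclease until it stalls at a protein–DNA crosslink, so the 5′
ends of reads pile up in narrow, strand-specific borders flanking a bound
site. `exomodes` models a set of n bound regions as a mixture of m
*binding modes*, where one mode k jointly specifies:

- a DNA motif: a PWM φ_k of width w_k (product of independent categorical
  distributions over {A,C,G,T});
- a positive-strand and a negative-strand *read window*: Bernoulli vectors
  φ_k⁺, φ_k⁻ of length w⁺ = w⁻ = 5 bp (configurable) giving the
  probability of observing a read 5′ end at each window position;
- signed offsets τ_k⁺, τ_k⁻ placing each window's start at Z + τ relative
  to the motif start Z;
- a mixture weight γ_k.

Read counts are binarized (below), so each datapoint is a sequence X_i
with two 0/1 vectors R_i⁺, R_i⁻. Given a mode and site position, sequence
and both read strands are conditionally independent; positions outside the
site follow a 2nd-order Markov sequence background φ₀ fitted to all
sequences, and positions outside the windows follow per-strand 0th-order
Bernoulli backgrounds φ₀⁺, φ₀⁻ fitted to all binarized reads. All
likelihoods are computed in log space as ratios against the background, so
they depend only on the site and window contents — the proportional form
of the model.

### Background conditioning at block edges

The background probability of a site string is evaluated with the
2nd-order chain conditioned on the *actual* two bases preceding Z (falling
back to 1st/0th order at sequence starts and next to N). A consequence is
that the sequence log-likelihood ratio is exactly invariant to all bases
outside the site *and its 2 bp context*; the context bases have a small
(≤ a few nats) effect. Masked or ambiguous bases (N) are emitted with
probability 1/4 by the background and are disallowed inside sites.

## Preprocessing

- Regions are fixed windows [summit − flank, summit + flank), flank 120 bp
  by default (240 bp windows). Soft-masked (lowercase) FASTA bases become
  N; regions with fewer than 100 non-N bases, regions truncated by a
  chromosome edge, and regions overlapping a previously accepted region
  (input order precedence) are dropped.
- Strand-specific 5′-end counts come from bedGraph or bigWig tracks.
  Optional control tracks are subtracted after scaling:
  max(0, treatment − scale·control) per position, with the library-size
  ratio as the default scale.
- Counts are binarized as count > threshold. The default threshold is the
  median of all *strictly positive* counts pooled over both strands and
  all regions — a median including zeros would usually be 0 and mark
  nearly every position with any signal; the pooled-positive median marks
  the upper half of the nonzero signal. Ties at the threshold map to 0.
- The dataset is augmented with the reverse complement of every region
  (sequence reverse-complemented; R⁺ := reverse(R⁻) and vice versa), so a
  motif on either genomic strand presents the same geometry.

## Learning: collapsed Gibbs sampling

The PWM columns, window Bernoullis and mixture weights carry conjugate
priors — symmetric Dirichlet(0.5) per PWM column, Beta(0.5, 0.5) per
window position, Dirichlet(1) over modes ("non-informative" Jeffreys-style
defaults) — and are integrated out analytically. The sampler moves only:

- per *sampling unit*: the orientation, mode label I and site position Z
  (one blocked draw over the joint enumerable grid);
- per mode: each window offset τ (a categorical draw over its grid, all
  member windows moving together), and the motif width w via ±1 bp edge
  moves (5-way choice: stay / extend / shrink at either edge).

**Sampling units and orientation.** One original region and its
reverse-complement copy form a single sampling unit that carries exactly
one site: the unit jointly chooses which copy holds the site along with
(I, Z), and the other copy contributes background only. This is the
standard two-strand treatment in Gibbs motif samplers, and it is load-
bearing here: if the two copies were treated as independent datapoints,
the mirror image of every real mode would itself be learnable structure
(the RC copies of mode-k regions contain exact mirrored sites), the
collapsed score would keep rising as modes duplicate in mirrored pairs,
and model selection would report roughly twice the true mode count. With
paired units the mirror family collapses into one mode per true mode, and
each region's final orientation is re-resolved at prediction time by
marginal likelihood.

**Width moves and offsets.** Left-edge width moves shift every member's Z
by ∓1 and compensate τ by ±1 so the read windows keep their absolute
positions — width sampling does not drag footprints. Offsets live on the
grid τ⁺ ∈ [−max_offset − w⁺, w_k − 1], τ⁻ ∈ [−w⁻ + 1, w_k + max_offset]
with max_offset = 25 bp (footprints sit within a couple of dozen bp of
sites); the τ prior is treated as uniform over the maximal grid so width
moves need no τ-normalization correction. Candidate moves that would push
any member's site or window outside its region (or over an N) are invalid.

**Scoring and stopping.** The collapsed joint score — Dirichlet-
multinomial marginals for PWM columns and γ, Beta-Bernoulli marginals for
window positions, background everywhere else — is available in closed
form. Every accepted move updates a running score by the exact difference
of enumerated weights (and the score is recomputed from sufficient
statistics once per sweep to eliminate float drift), so the state is
scored after every single-variable update at O(1) cost. A chain stops when
5 × n consecutive single-variable updates produce no new best score, where
n counts sampling units; "iteration" is read as one single-variable update.
A hard cap of 200 sweeps guards pathological inputs. Each mode count is
fitted with independent restarts (default 3); the best final score wins.

**MAP estimate.** From the best sampled state, greedy coordinate ascent
(each variable to its conditional argmax, passes until a fixed point)
yields the reported state; parameters are posterior means, e.g. PWM column
= (counts + α)/(n_k + 4α), γ_k = (n_k + δ)/(n + mδ). Empty modes are
retained with prior-predictive parameters and a warning.

## Model selection

For each candidate m the fitted model is scored by
BIC = K ln(n) − 2 ln P̂, with K = Σ_k (3 w_k + w_k⁺ + w_k⁻ + 2) free
parameters and P̂ the collapsed posterior score at the MAP state. n is the
augmented datapoint count (2 × n_original): the marginal likelihood
integrates over both copies of every region. Minimum BIC wins; ties break
toward smaller m. Because extra modes beyond the truth tend to end up
empty (their marginal contribution is pure prior), the score flattens and
the K ln(n) penalty decides.

## Prediction

For a new datapoint the site position is marginalized with a uniform prior
over *valid* placements (motif and both windows inside the region, site
N-free) — restricting "equally likely anywhere" to feasible positions
keeps the prior proper. Mode posteriors, the position-marginalized
likelihood P(D | model), and the two-model log-odds S(D) = log P(D|a) −
log P(D|b) follow directly. Posteriors can use the full joint, sequence
factors only, or read factors only; the placement grid is the same in all
three components, so restricted posteriors are exactly invariant to the
data they ignore. Per-region calls report the orientation copy with the
larger marginal likelihood (ties go forward) and map motif coordinates
back to the forward genome with a strand flag. Confusion matrices average
the posterior of mode v over datapoints MAP-assigned to mode u.

## Synthetic data

The generator plants modes according to the model's own generative story:
mode drawn by proportion (remainder pure background), site position
uniform over feasible placements, site emitted from the PWM, window reads
Bernoulli(footprint), background reads Bernoulli(bg_read_p = 0.05),
background sequence from a 1st-order chain parameterized by GC content
(40% by default, with a mild 10% same-base persistence). The fitted
background remains 2nd-order; the order mismatch is intentional and tests
robustness to background misspecification. Each region is planted in a
random orientation (probability 0.5 of reverse-complementing the whole
datapoint), exercising the orientation machinery end to end. An optional
counts mode wraps the binary reads in overdispersed counts (planted
positions ≥ 2, 20% background noise singletons) so the median-based
binarization path is exercised; the pooled-positive median then falls on
the noise level and thresholding recovers the planted binaries.

The default benchmark plants three modes in equal proportion: 9–10 bp
motifs with 0.9 consensus-base probability and 5 bp footprints at p = 0.9
versus 0.05 background, at distinct offset geometries (τ⁺ ∈ {−10, −6, +8}).
What passing these benchmarks does *not* show: real ChIP-exo data have
non-uniform crosslinking efficiency, mappability gaps, PCR duplicates,
overlapping sites and count overdispersion beyond the binary model; the
synthetic benchmarks certify the inference machinery, not robustness to
those artifacts.

## Evaluating recovery

A learned mode is matched to a planted spec over both orientations and
column shifts d ∈ [−3, 3] (the sampler may settle a column wide or
narrow); the match minimizing mean per-column PWM total variation over the
overlap wins, with a small penalty on the offset error to break the
near-ties that arise when a motif's reverse complement equals a 1-column
shift of itself. Offsets are compared in the spec frame (τ̂ + d vs τ_true);
the mirror transform is τ⁺ ↔ w − τ⁻ − w_s with windows swapped and
reversed. Label agreement uses Hungarian matching of predicted to planted
mode labels over the non-background regions.

## Numerical choices and degenerate inputs

- All mixture reductions use log-sum-exp; invalid placements carry −inf
  and never receive probability mass.
- Improvement tracking uses a 1e-9 tolerance so float noise cannot reset
  the stopping counter; audit recounts of all sufficient statistics are
  exact and tested after randomized update sequences.
- All-zero read tracks binarize to all zeros with a warning; backgrounds
  are add-one smoothed so no probability is ever 0 or 1.
- A region whose every placement is invalid at the initial width is
  reported by id at initialization rather than failing mid-chain.
- Default sampler settings: window width 5, initial motif width 12
  (wide-motif factors like CTCF warrant a larger value via
  `--init-width`), w ∈ [5, 50], max offset 25, restarts 3, stopping
  multiplier 5.

## Problem sizes used in the shipped benchmarks

The acceptance benchmarks run the full pipeline at n = 600 regions
(L = 240 bp) for three-mode recovery with a BIC sweep over m = 1..6 and
5 replicate seeds with 2 restarts per candidate, n = 300 for the
pure-background null (sweep m = 1..3, 3 seeds), and 200 training / 200
held-out regions per class for the two-class log-odds experiment — sizes
chosen so the complete benchmark suite exercises every stage at
realistic separations while remaining desk-scale. Exhaustive-enumeration
oracle checks run at n ≤ 5, L ≤ 30 where full enumeration is exact.

## Known limitations

- One site and one mode per region; no multi-site regions.
- Read windows are fixed-width and binary; count magnitudes beyond the
  threshold are discarded. Learning window width, and continuous read
  models, are natural extensions.
- The 2nd-order background is global, not region- or GC-stratified.
- BIC with the collapsed score slightly double-counts the parameter
  penalty (the marginal already includes an Occam factor); in practice
  this biases selection mildly toward parsimony, which the null-control
  benchmark confirms is the desired direction.
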