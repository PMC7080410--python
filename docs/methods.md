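# Methods

This note describes the models implemented in `naivetcr`, the synthetic data
they are exercised on, the numerical choices behind them, and what the test
suite does and does not establish about real repertoire data.

## The scientific setting

A human naive T-cell pool holds on the order of 10^10–10^11 cells, while a
blood sample yields at most a few hundred thousand of them. Two mechanisms can
make a TCR α or β nucleotide sequence appear "abundant" in such a sample even
though naive clones are small: (i) the same rearrangement can be produced
independently in many different clones when its generation probability P(σ) is
high ("identical-recombination collisions", much more frequent for α chains,
which lack a D segment), and (ii) a single sampled cell can contribute many
mRNA molecules, inflating UMI counts. The package implements the full chain of
reasoning used to disentangle these from genuinely large clones: accurate
UMI-based molecule counting, clone-size models of the pool, subsampling
theory, selection-aware chain assignment, and incidence statistics across
three disjoint subsamples of one blood draw.

## Clone-size models

**Neutral birth–death–immigration model.** A pool of N cells; every event
removes one uniformly chosen cell; with probability 1−θ another uniformly
chosen cell divides, otherwise a thymic counter advances, and after c
division-free events the thymus releases a new clone of c cells. θ is the
thymic replacement fraction (dimensionless, per event; defaults in the
analyses span 10^−4–10^−1 to reflect declining thymic output with age) and c
is the thymic introduction size (c = 10 for α-indexed runs, c = 100 for
β-indexed runs, reflecting the divisions between β and α rearrangement). The
steady state is

    F_i = N (1 − (1−θ)^i) / (i c)          1 ≤ i ≤ c
    F_i = c F_c (1−θ)^{i−c} / i            i > c

with richness R = θN·ln(θ)/(θ−1) for c = 1 and inverse Simpson diversity
S = 2θN/(2+(c−1)θ). Two event-loop simulators accompany the closed forms:
the *discrete* scheme above (default), and a *continuous-time* scheme in
which death, division and thymic introduction are independent Poisson
processes with per-cell rates referencing the nominal N. The closed forms are
the exact stationary law of the continuous-time chain; the discrete coupling
deviates from them by O(c/N), measurable at N = 10^4 (relative deviations of
order 0.1%). Oracle-equivalence tests therefore run the continuous scheme;
the discrete default is compared at a correspondingly looser tolerance.
Simulator state is a flat cell→clone array (O(1) event updates); time
averages use batch means, with batches long relative to the occupancy
autocorrelation of the rare large-size classes, and can start either from all
singletons or from a realisation of the analytic steady state (the latter
removes the slow build-up of the large-clone tail and turns the run into a
stationarity check).

**Phenomenological distributions.** Power law F_i = N·i^(−k)/ζ(k−1) (k > 2);
log-normal (sizes 10^Normal(μ, σ), σ = μ/10, rounded, replicated to conserve
N exactly); and a two-population mixture of singletons plus large clones of
equal size M holding a fraction φ of all cells. For slopes near 2 the
power-law cell mass decays so slowly that dense enumeration is impossible;
beyond size 10^4 the support is condensed onto geometrically spaced bins
whose exact Hurwitz-zeta cell masses are assigned to the bin mean, keeping
Σ i·F_i within 10^−4 of N (the documented truncation error). Clone sizes are
stored as floats for this reason. The idealised zeta normalisation puts some
cell mass on clones larger than any physical pool when k ≲ 2.2; samplers
clip realised draws at the sample size.

## Subsampling theory

Sampling a fraction s of a well-mixed pool sends a clone of j cells to
X_j ~ Binomial(j, s), giving the expected sample distribution
F̂_i = Σ_j F_j·P(X_j = i), with closed form F̂_i = F_i·(s/(s+(1−s)θ))^i for
the c = 1 neutral state. At blood-draw scale (s ≈ 10^−6, so s/θ ≈ 10^−5) the
per-unit-size attenuation makes even very large pool clones rare in a sample
— the central reason sample abundances cannot be read as clone sizes. A clone
of i cells is present in a sample of n cells with probability
p_i = 1 − (1 − i/N)^n. Sample sizes are calibrated by matching the expected
number of distinct chains (after collision collapsing through the chain
pool's sequence weights) to an observed diversity, by integer bisection on
the monotone expectation; the observed distinct-chain count bounds n from
below and the sorted cell count from above. Very large clones use Poisson or
normal limits of the conditional binomial draw.

## Synthetic recombination model with exact P(σ)

Real V(D)J generation models are too large to evaluate exhaustively, so the
generator uses a reduced, fully enumerable model: ~20 V tails × ~20 J heads
of 8 nt (stop-free in frame 0), up to 3 deletions per side, and a junction
insertion of length L with model-specific distribution. P(σ) of a sequence
(V, J, junction) is the exact sum of scenario probabilities over every
(V-deletion, J-deletion, insertion) triple consistent with the junction —
the same many-scenarios-one-sequence degeneracy that makes real pgen
computation nontrivial. The minimal insertion count over consistent
scenarios is the analogue of "minimal N-additions".

Defaults are calibrated to the study conditions:

- the pooled fraction of raw α+β rearrangements passing the productivity
  filter (length divisible by 3, no in-frame stop) is ≈28%;
- α insertions are short (0–6, geometric-like), β insertions long and bounded
  below (2–14, peaked at 7): the median log10 P(σ) gap between loci is ≈4
  orders of magnitude, and the two-draw coincidence probability p₂ is
  ~5·10^−4 (α) vs ~2·10^−6 (β), reproducing the strong α/β collision
  asymmetry;
- inserted nucleotides are drawn with slightly non-uniform base probabilities
  (A/C/G/T = 0.20/0.30/0.32/0.18). With uniform probabilities every scenario
  probability is a product of identical factors and the model's log10 P(σ)
  spectrum collapses onto a coarse lattice (~0.75-wide steps), which makes
  medians of P(σ) degenerate across incidence classes; content-dependent
  factors restore a smooth spectrum. β segment usage is near-uniform with
  slight jitter for the same reason, and to keep the β pool's weight head
  flat (no single sequence recurring in every subsample at desk scale).

## Thymic selection

Productive rearrangements survive selection with probability
p_selected = f(P(σ))·overall_factor (default 1/3, configurable 1/10–1). The
factors f are density ratios between an empirical P(σ) distribution and the
pre-selection distribution over 100 equal log10 bins on [−50, 0], with
adjacent bins merged upward from the sparse low end until every merged bin
holds ≥1% of the empirical observations. Applying the trained model to the
pre-selection pool reproduces the empirical density by construction — the
self-consistency the tests verify. Decisions are memoized per distinct
sequence by default (all copies of a rearrangement share a fate); a
per-event mode decides per copy, which lowers the surviving multiplicity of
repeated sequences. Merged bins with zero pre-selection density receive
f = 0; f·overall_factor is clipped at 1.

## From pool to measured UMI tables

`build_repertoire` realises integer clone sizes from any distribution and
assigns each clone an α and a β chain drawn with replacement from
post-selection chain pools — reproducing chain frequency ∝ P(σ) and letting
identical rearrangements collide across clones. `simulate_subsamples` draws
cells without replacement (multivariate hypergeometric over clones),
partitions them disjointly into three subsamples, and gives each sampled
cell a Poisson (or negative-binomial; the real dispersion is unknown, so the
family is a parameter) number of captured molecules with mean
`mean_molecules × capture_efficiency` (defaults 100×0.03 for α, 300×0.03
for β). Each molecule receives a fresh random 12-nt UMI and a log-normal
(rounded up) read count; `corrupt_umis` substitutes each base of each
read's UMI independently at a given rate. Every molecule is linked to its
cell and clone, so downstream estimates can be scored against exact truth.
One functional chain per clone is assumed (dual-chain cells are not
modelled).

## UMI error correction

Two random 12-mers differ at H ~ Binomial(12, 3/4) positions. For a sequence
supported by i UMIs the expected number of pairs at distance ≤ d is
C(i,2)·P(H ≤ d); the adaptive threshold D_α is the largest d keeping this
expectation ≤ α = 0.05. Merging iterates d = 1..D_α, transferring the read
count of the less frequent UMI of each close pair to the more frequent one
(ties: the lexicographically smaller string wins), with D_α computed once
from the original UMI count. Reads are conserved exactly. A fixed-threshold
single-pass mode (classically distance 2) is provided for comparison.

A limitation worth stating: under the generator's single-pass per-read
substitution errors, erroneous UMIs sit almost exclusively at distance 1–2
from their source (P(≥3 substitutions in one read) ≈ 5·10^−4 of the error
mass at 0.5%/base), so the fixed threshold-2 collapse already recovers the
truth there, and the adaptive rule's wider reach for rare sequences can only
spend its α false-merge budget. The adaptive rule's advantage on real data
comes from multi-edit erroneous UMIs produced by compounded errors across
PCR cycles, which this error model deliberately does not include. The tests
therefore show the adaptive rule is accurate (L1 error vs truth ~50× smaller
than uncorrected) and calibrated (≤α false merges), not that it dominates
every fixed threshold under every error process.

## Incidence prediction and fitting

For a candidate distribution at desk scale, three disjoint subsamples of
cells are realised; only sampled clones receive chains; identical sequences
are collapsed; incidence = number of subsamples containing the sequence. The
comparison surface is per-incidence sequence counts, median log10 P(σ) and
zero-insertion fraction. Fits minimise Σ (log(pred+1) − log(obs+1))² over
loci and incidence classes 2–3 (counts span orders of magnitude, hence the
log scale; incidence-1 counts are diversity-matched by construction).
The qualitative P(σ) check asks for median ordering 3 > 2 > 1 (α) and
2 > 1 with 2 > 3 (β); empty classes make it indeterminate rather than false.

**Desk-scale study conditions.** The working scale is N = 8·10^6 cells,
12 000 cells per subsample, chain pools of 3·10^5 (α) and 2·10^6 (β)
entries. These were chosen so the three governing dimensionless quantities
sit in the same regime as the full-scale system: (i) β collision duplets
(∝ M²p₂, M = sampled clones) comparable to large-clone duplets at power-law
slope 2.3; (ii) α collisions dominant at every incidence; (iii) recurrence
rate of the most probable chains λ = M·w_max/3 below ~0.5, so β triplets
come from large clones rather than repeated production. Under these
conditions the β inversion (incidence-2 sequences with higher median P(σ)
than incidence-3) emerges in the large majority of stochastic repeats while
α stays monotone — the mechanistic signature that collisions feed β duplets
but only large clones feed β triplets. A finite pool of P entries behaves
like a thymus that performed P productions; 1/P adds a small
uniformly-weighted collision floor, which is why the β pool is large.

## The multi-mRNA permutation test

Each sequence's UMIs are pooled across the three subsamples and re-scattered
independently and uniformly (equal thirds) into three artificial portions;
in this setting molecules of one cell can reach several portions, so the
permuted multi-incidence exceeds the observed (cell-resolved) one whenever
cells contribute several molecules. The inflation estimate is
1 − observed_multi/permuted_multi, pooled over incidence ≥ 2 with a
per-class breakdown. On synthetic data with known per-cell multiplicity the
estimator recovers the exact (ground-truth re-scattering) inflation to
within a few percentage points.

## What the synthetic data does not capture

The generator reproduces heavy-tailed clone sizes, the α/β pgen and
collision asymmetry, selection shaping, disjoint subsampling, per-cell mRNA
multiplicity and UMI errors — but not real gene segments or alleles, D-segment
recombination, PCR error cascades (see above), sequencing-depth structure,
sort contamination between subsets, or αβ pairing constraints. Because the
default β model requires ≥2 inserted bases, its minimal-insertion count is
never zero, so β zero-insertion fractions are structurally 0 in synthetic
output (real β repertoires have a small zero-insertion component). Passing tests
demonstrate the correctness and internal consistency of the estimators and
the reproducibility of the mechanism at desk scale, not biological fidelity
of any particular parameter value.

## Numerical and statistical choices

- Exact pgen by scenario enumeration; brute-force enumeration over the
  generative space is the independent oracle in tests.
- Neutral-model oracle tests use batch-means Monte-Carlo standard errors;
  batches are sized well above occupancy autocorrelation times, and the
  stationary-init option removes burn-in bias. A 3-SE bound applied to ~90
  simultaneous size/parameter cells sits near the expected maximum of the
  null distribution, so occasional single-cell exceedances at one seed are
  statistical, not mechanistic; the long-run check (4·10^8 events) bounds
  any systematic deviation of the continuous scheme below ~10^−3 relative.
- Binomial subsampling switches to Poisson/normal limits above clone size
  10^5; truncated draws use inverse-CDF sampling.
- TSV round-trips use shortest-exact float formatting and round-trip parsing.
- Every stochastic routine takes an explicit `numpy.random.Generator`; the
  CLI and scripts derive child seeds from a single `--seed`.

## Problem sizes used in the checks

Neutral oracle runs use N = 10^4 with 1.8·10^8 post-burn-in events per
(θ, c) point (18 batches of 10^7 events, stationary initialisation); sampling identities are checked over i = 1..20 at machine
precision; the UMI study uses 1000 clonotypes with true counts 1–50 at
0.5%/base UMI error; selection self-consistency uses 10^6 pre-generation
chains; sweeps cover slopes 2.05–3.0 (step 0.05) and a 5×3 mixture grid at
the desk-scale conditions above, with 10 stochastic repeats per point.
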