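# Methods

This note documents the models implemented in `uoxcoopt`, the choices made
where the design was genuinely open, and what the synthetic generators do
and do not emulate.

## Differential amino-acid composition (`orthocomp`)

**Procedure.** Orthogroups (sets of orthologous protein sequences keyed by
species, with a species → clade map) are filtered to those that are single
copy in every represented species and present in at least `min_presence`
(default 0.90) of the species universe. Presence is counted against the
explicit universe given by the clade map, not against species observed in
the data, so the filter is deterministic. For every retained sequence the
content of each of the 20 standard amino acids is computed as a fraction of
counted length; ambiguity letters (X, B, Z, U) and stops (*) are excluded
from both numerator and denominator and reported as a per-row excluded
tally. For a clade pair (A, B), each orthogroup × amino acid is tested with
a two-sided unequal-variance (Welch) *t*-test on the per-sequence fractions
and summarized by log₂(mean_A / mean_B). Rows are classified
`increased` when p < p_cut and log₂FC > lfc_cut, `decreased` when p < p_cut
and log₂FC < −lfc_cut, otherwise `ns`; defaults p_cut = 1e-16,
lfc_cut = 1.

**Choices.**

* *Fraction vs count.* Content enters the test as a length-normalized
  fraction so that fold changes are invariant to protein length; raw counts
  are retained alongside for per-sequence outputs such as cysteine counts.
  `differential_composition(..., use_fraction=False)` switches to counts.
* *Test variant.* Welch by default (`test="student"` gives the
  pooled-variance test). Verified in tests against an independently coded
  textbook Welch computation to 1e-10.
* *Degenerate rows.* Groups with n < 2, zero variance in both groups, or a
  zero mean produce NaN statistics; these rows are emitted (never silently
  dropped) and always classify `ns`. No pseudocount is applied — pseudo
  counts distort rare residues such as Trp and Cys.
* *Multiple testing.* None: the scan uses a raw p-value cutoff of 1e-16 by
  design. Annotating with BH/Bonferroni is possible downstream from the
  emitted table but never alters the volcano class.

## Ancestral cysteine gain/loss (`ancgain`)

**Model.** Each alignment column is recoded as a binary character: target
residue (default C) present vs absent, with gaps and ambiguity letters
masked. The full 20-state reconstruction is deliberately out of scope: only
per-branch gain/loss of one residue class is consumed downstream, and the
binary recoding admits exact oracles (exhaustive enumeration) for every
algorithm here.

* `mpr` / `mpr_acctran`: unit-cost parsimony. Subtree costs by a
  Sankoff-style down pass, outside costs by an up pass; the per-node MPR set
  is the set of states attaining the global minimum. A single labeling is
  obtained by a pre-order traversal taking at each node the state minimizing
  subtree cost + (change from parent); this greedy traceback always realizes
  the parsimony score. Ties are broken toward the state *differing* from the
  parent under `mpr_acctran` (changes accelerated toward the root) and
  toward the parent's state under `mpr` (changes delayed toward the leaves).
  Root ties go to absence (state 0); both rules are deterministic and
  configurable.
* `ml` / `bayes`: two-state continuous-time Markov chain with gain rate α
  and loss rate β, transition probabilities in closed form, root prior the
  stationary distribution (β, α)/(α+β) (flat prior available). `bayes`
  assigns each node its marginal highest-posterior state (sum-product
  pruning: one down pass of partial likelihoods, one up pass of above
  partials); `ml` is the joint maximum-likelihood labeling (max-product
  pruning with traceback). For event counting, marginal posteriors are
  thresholded at 0.5 with exact ties resolved to the parent's state (no
  event; root ties to 0).

Masked leaves are uninformative: state set {0, 1} in parsimony, partials
(1, 1) in likelihood. Columns with fewer than two unmasked leaves contribute
no events and are logged. Per branch, gains are columns with parent 0 →
child 1 and losses the reverse; `net = gains − losses`. The bookkeeping
identity that the net change along every root-to-leaf path equals leaf state
minus root state is asserted on every run.

A caveat inherent to rooted reconstructions: a single change on a branch
adjacent to the root is not identifiable in direction (a gain on one root
child is indistinguishable from a loss on the other when the root state is
ambiguous), so planted-history recovery is evaluated at low expected change
counts where such columns are rare.

## Uricase kinetics (`kinetics`)

**Reaction model.** Single-turnover conditions (enzyme in excess of
substrate) justify pseudo-first-order kinetics of the four chemical species
only — urate (UA), urate dianion (UA²⁻), 5-peroxyisourate (PIU), and
5-hydroxyisourate (HIU) — without explicit enzyme binding steps. The
concentration vector obeys dc/dt = A c with the tridiagonal rate matrix
built from k₁…k₃ (forward, s⁻¹) and k₋₁…k₋₃ (reverse; all zero in the
irreversible variant). The system is solved by eigen-decomposition of A;
when the eigenvector matrix is ill-conditioned or eigenvalues nearly
coincide (e.g. equal rates) the solver falls back to a per-time matrix
exponential, which is exact regardless. Mass conservation to 1e-9 relative
is a tested invariant. Hydrogen peroxide is tracked as a cumulative fifth
component fed by the forward PIU → HIU flux only (d[H₂O₂]/dt = k₃[PIU]):
the reverse step regenerates PIU without consuming peroxide, so with a
dominant back reaction H₂O₂ keeps accumulating after HIU has reached its
plateau. When k₋₃ > k₃ the HIU plateau sits at k₃/(k₃+k₋₃) of the
late-time PIU+HIU pool — with (k₃, k₋₃) = (0.5, 2.0) s⁻¹ about 20% of the
initial urate, the partial-conversion signature of the chicken enzyme.

**Spectra and SVD.** Absorbance is the Beer–Lambert mixture
A(t, λ) = Σ_s ε_s(λ) c_s(t) · path (µM and M⁻¹cm⁻¹, hence the 1e-6 scale),
with optional additive Gaussian noise. SVD is computed on the raw matrix by
default; `center=True` subtracts the final spectrum first, which isolates
the evolving difference spectrum when one step dominates the analyzed
window. SVD signs are arbitrary, so each component is flipped to make its
largest-magnitude spectral entry positive. The number of retained
components defaults to min(3, count explaining 99.9% of variance). The
isolated wavelength for a component is the grid point maximizing the ratio
of its singular-value-scaled |loading| to the summed |loadings| of the other
retained components — the wavelength where only that component contributes
to the kinetics.

**Fitting.** Chain rates are fitted to a single-wavelength trace by
trust-region nonlinear least squares with non-negativity bounds and a
deterministic multistart (8 log-spaced rate vectors spanning the trace's
timescales; when reverse rates are free, an additional start is seeded from
the nested irreversible fit). Standard errors come from the Jacobian at the
optimum; near-singular Jacobians are flagged as non-identifiable rather
than silently reported. Michaelis–Menten parameters are fitted by bounded
least squares of v = V·S/(K_M+S) with k_cat = V/[E]; the FOX standard curve
is ordinary least squares with inverse prediction (A − b)/m, negative
predictions clipped to zero and flagged.

## Synthetic data (`synthetic`)

The generators define the study conditions under which recovery is tested;
all are byte-deterministic under a fixed seed.

* *Orthogroups.* Sequences are i.i.d.-residue multinomial draws from a
  fixed realistic amino-acid frequency table (Cys ≈ 1.4%), with clade sizes
  defaulting to 50/50/50 across Sauropsida, Mammalia, and Actinopterygii
  and lengths ~N(400, 40). Planted shifts multiply one amino acid's
  frequency in one clade of one orthogroup and renormalize. This emulates
  the statistical structure the scan tests — between-clade mean shifts
  against within-clade sampling noise — but **not** phylogenetic
  autocorrelation, domain structure, or indels; passing recovery tests
  therefore validates the statistics, not robustness to correlated
  evolution. The planted-shift recovery tests use length 2000 so that the
  within-clade coefficient of variation of the Cys fraction
  (√((1−p)/(Lp)) ≈ 19%) stays at or below 20%, the regime in which a 5-fold
  shift at n = 50 per clade clears both cutoffs with certainty.
* *Character histories.* Root states are drawn from the stationary
  distribution and branch endpoints from the exact two-state transition
  matrix. Events are recorded from endpoint pairs — a single-change
  assumption appropriate at low rate × length (a warning is logged above
  0.5, where multiple hits on one branch become non-negligible).
  Recovery tests run at ≈ 0.1 expected changes per column on a 14-leaf
  tree.
* *Stopped flow.* Defaults mirror the single-turnover design: 25 µM initial
  urate, log-spaced times from 1 ms (the instrument's dead-time scale), and
  additive noise σ = 0.002 AU. The default species spectra are simple
  Gaussians engineered to the published landmarks — urate peaking at 292 nm
  with ε = 12,650 M⁻¹cm⁻¹, HIU near 301 nm, and a PIU − HIU difference
  spectrum with a negative lobe at 294 nm and a positive lobe at 314 nm
  (6 nm lobe widths keep the two lobes from displacing each other's
  extrema) — they are not measured curves.
* *Rate tables.* Michaelis–Menten rates use the 2–140 µM substrate span,
  triplicates, and 2% multiplicative noise; the assay enzyme concentration
  defaults to 0.5 µM (catalytic amounts; k_cat = V/[E] makes recovery
  invariant to this choice). FOX standards sit at 10, 25, 50, 100 µM.
  Noise defaults are chosen to keep recovery non-trivial but achievable.

## Numerical notes and limitations

* The eigen route of the chain solver switches to `expm` when the
  eigenvector condition number exceeds 1e8 or the smallest eigenvalue gap
  falls below 1e-10 (relative); tiny negative round-off concentrations are
  clamped to zero at 1e-13 of the total.
* Chain-fit identifiability is only diagnosed (smallest Jacobian singular
  value < 1e-8 of the largest), not resolved; strongly overlapping rates at
  a single wavelength are genuinely underdetermined.
* The composition scan's volcano classification is threshold-based and
  inherits the usual caveats of raw-p cutoffs; the 1e-16 default is only
  meaningful at large per-clade sample sizes.
* Tree inference, alignment construction, bootstrap support, rate
  heterogeneity across sites, 20-state substitution models, explicit
  enzyme-binding kinetics, pH dependence, and inhibitor binding are out of
  scope.
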