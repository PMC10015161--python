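# Methods

## Substitution model

The likelihood engine implements a reversible amino-acid CTMC:
Q_ij = s_ij·π_j for i ≠ j, with symmetric exchangeabilities s and
equilibrium frequencies π, diagonal set so rows sum to zero, and the
whole matrix scaled so the expected substitution rate at equilibrium is
one (branch lengths are therefore in expected substitutions per site).
Two parameterizations ship with the package:

* **JTT** — the standard published digitization of the
  Jones–Taylor–Thornton exchangeabilities and frequencies, as
  distributed with classic ML phylogenetics software (the familiar
  integer table; A↔R = 58, A↔N = 54, …; π_A = 0.076748, …).
* **Poisson** — equal rates and frequencies; kept because it admits the
  closed form P_aa(t) = 1/20 + (19/20)·e^(−20t/19) used in tests.

Rate heterogeneity follows the ubiquitous +I+G4 convention: a fraction
p_inv ∈ [0, 1) of sites is invariant; the rest draw one of k (default 4)
discrete gamma categories, the category rates being the means of the k
equal-probability bins of Gamma(α, α) (so they average one), divided by
(1 − p_inv) so the full mixture keeps mean rate one.  The per-site
likelihood is

    L(s) = p_inv·L0(s) + (1 − p_inv)/k · Σ_c L(s | r_c/(1 − p_inv)),

where L0(s) is Σ π_a over the states compatible with every observation
in the column (gaps and `X` are wildcards; a column with any two
different unambiguous residues has L0 = 0).

The same definitions drive the simulator: a column is invariant with
probability p_inv (one equilibrium draw copied to all leaves), otherwise
it picks a category uniformly and evolves by the transition kernels
P(t·r_c).  Simulation and inference therefore share a single model
object, which is what makes exact parameter-recovery tests meaningful.
Gaps are never simulated; they are an inference-side concern only.

## Likelihood computation and optimization

Per-site likelihoods are computed by Felsenstein pruning over the
alignment's distinct site patterns.  Transition kernels come from the
symmetric eigendecomposition of Q (B = D^{1/2} Q D^{−1/2} with
D = diag(π); P(t) = V e^{Λt} V^{−1}), which also gives exact first and
second derivatives in a branch length, since along one branch the
likelihood is Σ_k g_k·e^{λ_k r t} with coefficients g from the inside
("down") and outside ("up") partial vectors at that branch.

Branch-length optimization runs sweeps of safeguarded Newton updates:
one postorder (inside) and one preorder (outside) pass per sweep, then
every branch takes a Newton step computed from those shared partials,
clipped into a per-branch bisection bracket on [1e-8, 10].  Because all
branches move against partials from the sweep's start, a joint step can
overshoot; the sweep total log-likelihood is re-checked and the step
damped toward the previous lengths when needed, so the reported
objective is non-decreasing across sweeps.  Branches that have stopped
moving are frozen in later sweeps.  Sweeps run in float32 (plenty for
branch lengths at the stated tolerances; the clipped-step safeguard is
insensitive to it), while every user-facing per-site log-likelihood and
the rate-parameter profile optimization are computed in float64.  α and
p_inv are profile-optimized by bounded L-BFGS-B (α ∈ [0.02, 100] in log
space, p_inv ∈ [0, 0.99]), alternating with branch sweeps until the
round-to-round gain drops below `tol` (default 1e-4) or a round cap is
hit, in which case the best fit so far is returned with a convergence
flag rather than an exception.  Everything is deterministic for fixed
inputs.

By default α and p_inv are re-optimized per candidate topology; a flag
allows sharing one fit across candidates (both conventions exist in the
field, and per-topology refitting is the safer default).

## Candidate evaluation modes

`full` expands each OTU-level candidate to a leaf-level tree (grafting
the fixed within-OTU subtrees) and optimizes everything independently;
pendant lengths from the first candidate warm-start the rest, which
changes nothing about the optimum.  `reduced` is a two-stage mode for
exhaustive sweeps: one reference candidate is fitted in full, then the
within-OTU branch lengths and rate parameters are frozen, each OTU
subtree is collapsed into a precomputed conditional-likelihood array
("pruned leaf"), and only the OTU stems and inter-OTU branches are
re-optimized per candidate.  Totals remain full-alignment
log-likelihoods; what is shared is only the within-OTU lengths, whose
optimum is very nearly topology-independent (observed total-logL offsets
vs. the full mode are a few logL units and essentially constant across
candidates, so rankings agree).  The ranked-table defaults use `full`;
the scenario-recovery experiments use `reduced`.

## Topology space

Unrooted topologies are stored rooted at an arbitrary trifurcation.
Canonical forms reroot at the internal node adjacent to the globally
smallest leaf label and sort children recursively by smallest contained
leaf; equality of canonical strings is equality of unrooted topologies,
and branch lengths are deliberately ignored.  Enumeration is stepwise
leaf addition onto every edge ((2k−5)!! trees), verified duplicate-free
through canonical forms.  OTU constraints are a partition of the leaf
set plus one fixed Newick subtree per OTU; expansion and collapse are
exact inverses, and collapse validates monophyly.

## Resampling tests

All tests consume the per-pattern log-likelihood matrix (each row at its
topology's own optimized parameters).  RELL replicates draw
round(scale·n) sites with replacement via one multinomial over pattern
multiplicities; the same draws serve every tree, and each scale has its
own fixed sub-stream of the seed, so adding a tree or a scale never
perturbs existing replicates.  KH centers each tree's replicate-deficit
distribution on its own mean (one-sided); SH compares each observed
deficit with max_j R_j(b) − R_i(b) over centered replicate totals R,
which enforces p_SH ≥ p_KH replicate for replicate.  The AU test
computes bootstrap proportions (argmax winner per replicate, ties to the
lowest row index) at ten scales 0.5–1.4, clamps them to
[1/(B+1), 1 − 1/(B+1)], probit-transforms, and fits
z_r = d·√r + c/√r by weighted least squares with the delta-method
binomial weights B·φ(z)²/(BP(1−BP)); p_AU = 1 − Φ(d − c).  Trees whose
BP is stuck at 0 or 1 on fewer than two scales are flagged degenerate
and reported as p = 0 or 1 by the side they sit on.  The ML tree (exact
total ties broken by the lexicographically smallest tree string) anchors
ΔlogL; a zero-variance non-ML tree gets ratio = ∞ and sorts last.

Default replicate count is 10,000; the experiments in this repository
use B = 1,000, which keeps Monte-Carlo noise on p-values near 0.01
while fitting the test-suite budget.

## Scenario classification

Rules are data: a priority-ordered list of required clade sets checked
after rooting on the outgroup OTU.  The default vitellogenin rule set
declares post_split = {Cho-1, Cho-2} and {Ost-1, Ost-2} both clades;
pre_split = {Cho-1, Ost-1} or {Cho-2, Ost-2} a clade (a single
cross-split orthology clade already forces the duplication before the
split); anything else is `other`.  Over the 105 six-OTU topologies this
yields 3 / 27 / 75 members respectively — the 3 and the 27 follow from
contracting the required cherries (4-taxon and 5-taxon counts), a
useful closed-form check.

## Synthetic fixtures: what they emulate, and what not

`ScenarioSpec` defaults define the study conditions: two leaves per OTU
(12 sequences), 1,195 aligned sites, JTT with α = 1, k = 4,
p_inv = 0.1, internal (duplication/split) branches 0.12, OTU stems
0.25, within-OTU branches 0.1 — branch lengths and rate parameters in
the range typical of deep-vertebrate protein alignments of this size.
The simulator reproduces the probabilistic model exactly but not the
messiness of real data: no indels or alignment error, no gene
conversion, no model misspecification, no compositional heterogeneity.
Green recovery tests therefore demonstrate internal consistency of the
machinery at realistic signal strengths, not robustness to those
real-data effects.

The experiments' problem sizes are the package's own choices: scenario
recovery uses 50 seeded replicates per direction at 2,000 sites
(reduced evaluation mode, shape parameters fixed at the generating
values); parameter recovery uses 2,000-site fixtures with α ∈
{0.5, 1, 2}; AU calibration uses 200 datasets of 1,000 sites at
B = 1,000.

## AU calibration at the boundary: a known limitation

The defining property of the AU test is that, when the truth lies on
the boundary of the tested topology's hypothesis region (an internal
branch of length zero), P(p_AU ≤ α) should be close to α.  On the
idealized smooth-boundary problem — two hypotheses whose per-site
log-likelihood difference has mean zero, no fitting — our
implementation is calibrated: rejection at α = 0.05 sits inside the
binomial envelope, with near-uniform p-values (this is a unit test).

On actual tree data at the collapsed-branch configuration, however, the
RELL-based test is markedly conservative: across 200 simulated datasets
(both with the local NNI triple and with all 105 candidates) the true
topology's p_AU never fell below 0.09, so the type-I error is ~0 rather
than 0.05.  The cause is structural, not a coding defect: RELL re-totals
per-site log-likelihoods that were evaluated at the original data's
fitted branch lengths.  At the boundary the competing fits pin the
collapsing branch at its lower bound, the observed log-likelihood
difference is a quadratic form in the score (≈ Z²/2) while its
resampling spread scales like Z, and the resulting z-curves are shrunk
roughly twofold relative to what per-replicate refitting would give —
we verified on single datasets that refit bootstrap proportions differ
from RELL ones exactly in this regime.  RELL's validity argument
assumes the compared trees are separated hypotheses with interior
optima, which is the regime of real ranked-table analyses (deficits of
tens of logL units); there the tests behave as expected.  Users should
treat near-boundary AU p-values as conservative.

## Numerical choices

* Branch lengths clamped to [1e-8, 10]; exact zeros in input trees are
  clamped up, which perturbs log-likelihoods by ≲1e-7.
* Site likelihoods floored at the dtype's smallest normal before logs.
* Pattern compression via column uniqueness; all statistics expand over
  multiplicities.
* One global seed fans out to stage streams (simulation, resampling)
  through fixed `SeedSequence` spawn keys; every derived seed is below
  2³¹.
* Reruns with identical configuration produce byte-identical output
  files (fixed float formatting in the writers).

## Known limitations

* Tree search is out of scope: only enumerated or user-supplied
  candidate sets are evaluated (fine for k ≤ 7 OTUs; 945 topologies at
  k = 7 are still tractable, (2k−5)!! growth is not).
* One partition, amino acids only; no codon/nucleotide models, no
  partitioned or mixture models beyond +I+G.
* The reduced evaluation mode shares within-OTU branch lengths from one
  reference fit; rank orderings are robust to this but per-tree logL
  values carry a small constant offset relative to full refitting.
* AU p-values near hypothesis boundaries are conservative (above).
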