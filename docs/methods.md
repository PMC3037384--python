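# Methods

## The model

A promoter sequence x of fixed length L either contains no binding site
(occurrence indicator c = 0) or exactly one (c = 1, the ZOOPS assumption —
"zero or one occurrence per sequence"). Conditional on c = 1, a start
position u ∈ {0, …, L−w} is drawn from a positional distribution T, a
strand from a strand weight (fixed at 0.5 by default), and the w site
letters from a position weight matrix M, written on the forward strand or
as the reverse complement. All non-site letters are i.i.d. from an order-0
flanking model F. The marginal likelihood of a sequence is therefore

    P(x | θ) = (1 − p_occ) · Π_l F(x_l)
             + p_occ · Σ_u T(u) · [ Π_{l∉site} F(x_l) ]
                        · ( ½ M(x_site) + ½ M(rc(x_site)) )

computed throughout in log space with log-sum-exp.

The positional distribution T is a mixture of a uniform component (weight
γ) and a discretized skew normal with location ξ (bp, internal start
coordinates), scale ω (bp) and shape α; shape 0 recovers a Gaussian, and
positive shapes allow the asymmetric, TSS-leaning placement profiles seen
for many promoter-proximal factors. The density
f(y) = (2/ω) φ((y−ξ)/ω) Φ(α(y−ξ)/ω) is evaluated at the integer start
positions and renormalized over the valid range, so the prior is exact on
its discrete support (no bin integration; the difference is far below
learning noise). The control class is modeled by a homogeneous Markov
chain of configurable order d (default 1; see "Background order" below),
with independent per-position letter distributions for the first d
positions, where no full context exists.

## Learning: maximum supervised posterior

Given labeled sequences (x_i, y_i), all parameters — motif, flanking,
positional, occurrence, background chain, class priors — are fitted by
maximizing the supervised posterior

    Σ_i log P(y_i | x_i, θ) + log P(θ | α),

a discriminative Bayesian criterion: the first term is the conditional
log-likelihood of the labels, the second a composite prior. The prior uses
symmetric Dirichlet/Beta terms derived from equivalent sample sizes
(uniform pseudo-data; a K-simplex with ESS e gets concentration 1 + e/K
per component, default e = 4 everywhere), a broad Gaussian on ξ (mean at
the middle start, sd L/2), a Gaussian(0, 4) on the shape, a Gamma on ω
with shape 2 and mean L/4, and a Beta(2, 2) on γ. All are configurable;
none is claimed to be canonical.

Optimization runs on unconstrained transforms — log-odds against the last
letter for every probability simplex, logits for scalar probabilities,
log ω — using L-BFGS with analytic gradients (validated against central
finite differences at 1e-5), at most 500 iterations and relative tolerance
1e-6 per run. Priors are evaluated on the natural-parameter scale without
a change-of-variables correction; the objective is what it is stated to
be, not a posterior density over the transformed space.

### Width equalization of the motif prior

Supervised posteriors of models with different motif widths must be
compared (the length heuristic and restart selection both do it). A PWM
column equal to the flanking distribution leaves the ZOOPS likelihood
unchanged, so models of different widths can describe the same data law;
the only width-sensitive term is then the prior, which would add one
Dirichlet density term (≈ +3 for a diffuse column) per extra column and
systematically reward wide windows. The motif prior is therefore padded
with virtual uniform columns up to a fixed reference width (50), plus a
complexity charge of 3 log-units per real column — a column's
free-parameter count, accounting for the ~½ log-unit-per-parameter of
noise a discriminatively fitted column extracts from finite data. Both
terms are constants per width and do not affect the gradients. Without
them, selection measurably preferred wide, inaccurate motifs over
correctly trimmed ones.

## Multi-start search and initialization

The optimization is restarted from random initializations (default 50;
the simulation studies below use 6–10) and the restart with the highest
supervised posterior wins, ties broken by lowest restart index. Each
restart seeds the PWM from a foreground subsequence smoothed with uniform
pseudo-counts (ESS 4 → 0.4/0.2 letter probabilities). Because a single
random subsequence overlaps a true site only rarely (~2% at typical site
densities), each restart screens a pool of 30 random candidate
subsequences by the supervised posterior at the start point and keeps the
best — the standard seeding practice of mixture-model motif finders.
Flanking and background start from observed letter statistics, the
positional prior starts near-uniform (γ = 0.9), and p_occ at 0.5.

## Phase shift and length adjustment

Each restart alternates numerical optimization with one heuristic window
move until no admissible move remains:

1. optimize;
2. find the *insignificant positions*: the largest contiguous border
   column counts (each side probed independently) whose removal keeps the
   number of promoters predicted to contain a site within 80% of the full
   model's count;
3. propose a move — left-only insignificance shifts the window right,
   right-only shifts left, both sides truncate, neither side expands by
   one column per side (bounded by the configured min/max width);
4. apply it (overlapping columns copied, fresh columns uniform, positional
   location shifted so implied site placement is preserved) and
   re-optimize.

A history of visited (width, cumulative offset) states vetoes proposals
that would revisit a state, which bounds the number of steps and
guarantees termination. Expansions are provisional: if the freshly added
columns are still insignificant after re-optimization, the pre-expansion
optimum is restored and the restart ends (otherwise every restart would
structurally terminate on a useless expanded state, the truncation back
being vetoed by the history).

"Predicted to contain a site" is decided by the empirical p-value
machinery, not by the occurrence posterior: a promoter counts when at
least one of its positions scores above all but a fraction
`detection_pvalue` (default 1e-4) of the per-position scores on the
control set. Discriminative training inflates p_occ for classification
margin, which makes P(c=1|x) > 0.5 nearly always true and therefore
useless as a trimming signal; the relative-to-control criterion responds
to the informativeness of the motif columns.

## Reported-model polish

Once the two classes separate, the conditional likelihood carries almost
no gradient for the foreground emission parameters (the per-sequence
weights 1 − P(y|x) vanish), leaving the PWM columns, the flanking letter
frequencies and the positional parameters under-determined: only
likelihood *ratios* matter for classification. The winning restart is
therefore polished by expectation-maximization on the foreground set with
the strand weight, background chain and class priors frozen: site
posteriors are computed under the current model, then the PWM is
re-estimated from posterior-weighted site alignments, the flanking model
from the expected non-site letters, p_occ from the total site mass (all
with their pseudo-counts), and (γ, ξ, ω, α) are refitted to the posterior
start-position mass (Nelder-Mead on the four parameters, iterated to a
fixpoint). The posteriors are anchored at the discriminatively selected
motif, so the polish calibrates that motif's description rather than
drifting to merely over-represented signal — it is the model-based
analogue of building a logo from predicted sites, which is also how such
motifs are conventionally reported. Finally, when length adjustment is
on, border columns of the polished PWM with information content below
0.25 bit are trimmed (the conventional definition of a motif's effective
length) and the model re-polished.

## Site prediction

For each position of each target sequence the strand-summed joint
posterior P(c=1, u | x) is the site score; the reported strand is the
argmax strand. The same score at every position of every control sequence
yields an empirical background distribution, and the p-value of a score
is the fraction of control scores strictly exceeding it. Sites are all
positions with p-value strictly below the threshold (default 1e-3),
sorted by p-value; thresholds sweep out nested prediction sets, so
nucleotide precision-recall curves are well defined. Both strands are
pooled into one background distribution. Overlapping predictions are all
reported; evaluation works on nucleotide coverage, where overlaps are
harmless.

## Evaluation machinery

Nucleotide recall is the fraction of annotated site nucleotides covered
by predictions; nucleotide precision the fraction of predicted
nucleotides inside annotated sites (defined as 1 when nothing is
predicted; such points are degenerate and logged). PR curves sweep the
pooled ranked prediction list, one point per distinct rank score. Motifs
are compared by the normalized Euclidean distance: the minimum over
relative offsets (at least min(w_a, w_b, 5) aligned columns) and over the
reverse complement of the mean per-column Euclidean distance divided by
√2; the "motif found" threshold is configuration (default 0.18), not a
claim from this package's own validation. Consensus scanning accepts any
IUPAC pattern, requires the whole match footprint inside a TSS-relative
window on either strand, and feeds 2×2 contingency machinery: Sn =
a/(a+b), FPR = c/(c+d), precision a/(a+c), F the harmonic mean of
precision and Sn, a one-sided Fisher exact test for enrichment, and a
one-sided pooled-variance two-proportion z-test.

## Synthetic data

The implantation generator reproduces the classical benchmark protocol:
floor(n_sites / 0.7) target promoters are drawn from a pool so that 70%
carry exactly one site, implanted by substitution (lengths must stay
equal for the positional model) at a uniform or Gaussian start on a
uniformly chosen strand; an equally sized control set from the same pool
gets no implants. A decoy motif can be planted into every target *and*
control promoter (resampled on overlap with a true site), making it
over-represented but not differentially abundant. `sample_from_model`
draws sequences directly from the ZOOPS law for parameter-recovery work.
Everything is reproducible from a single seed.

What the generator does not emulate: real promoters' composition
heterogeneity (CpG islands, TATA context, repeats), correlated neighbor
structure beyond what the implant pool provides (the default pool is
i.i.d. at 40% GC, the AT-rich regime of plant promoters), multiple sites
per promoter, or motif variants beyond PWM sampling. Passing the
recovery studies therefore demonstrates correctness of the machinery and
identifiability at realistic signal strengths, not performance on real
chromatin.

## Study conditions used by the tests and the acceptance script

- Parameter recovery: 200 foreground + 200 control sequences of 250 bp;
  true motif 8 bp with per-column peak 0.85 (~0.6 bit/column); occurrence
  probability 0.7; positional law skew-normal (ξ=60, ω=30, α=3) with 10%
  uniform admixture; flanking (0.3, 0.2, 0.2, 0.3); 10 restarts, initial
  width 15 with adjustment. Checked: per-column total variation to the
  true PWM after alignment < 0.15, learned width within ±1 of the
  informative width, positional mode within 15 bp, γ within 0.2.
- Decoy resistance: 100 sites sampled from a random 0.85-peak PWM,
  implanted uniformly (→ 142 targets + 142 controls of 200 bp); a second
  such motif planted into every promoter of both classes; 6 restarts.
  Checked: the recovered motif is closer to the true PWM than to the
  decoy.
- Positional-prior benefit: 140 sites implanted with a Gaussian(60, 20)
  law (→ 200 + 200 promoters of 250 bp); 6 restarts. The trained model is
  compared against itself with γ clamped to 1 (uniform prior) at
  prediction time, isolating the positional prior's contribution from
  optimizer noise. Checked: nucleotide precision at 50% recall with the
  learned prior ≥ with the uniform clamp. This study runs at the recovery
  study's conditioning because at half the sample size discovery itself
  becomes a restart lottery and both arms measure noise.

These sizes are the package's own desk-scale choices; the original
benchmark experiments for this class of methods used promoter databases
and dozens of external tool runs at 500 bp and 50 restarts.

## Numerical choices and degenerate inputs

- All simplex parameters are kept interior by the logit/log-odds
  parameterization; packing clips at 1e-12.
- log Φ uses `scipy.special.log_ndtr`; the hazard ratio φ/Φ is computed
  as exp(logpdf − logcdf), stable far into the left tail.
- Boundary parameters (zero probabilities under concentrations > 1) give
  a log prior of −∞, reported as such, and abort an optimization start
  with a diagnostic rather than propagating NaNs.
- Equal restart objectives: lowest restart index wins (determinism).
- Empirical p-values use strict exceedance, so threshold 0 predicts
  nothing and ties with the threshold are excluded.
- The heuristic caps insignificant borders at width − 1 and never trims
  below the configured minimum width (default 4).
- Sequences with non-ACGT letters are rejected in strict mode (the
  likelihood has no emission for them) or dropped with a warning in
  lenient mode.

## Known limitations

- At most one site per sequence (ZOOPS); tandem or homotypic clusters
  violate the model.
- Equal-length input is structural: the positional prior lives on
  absolute start coordinates.
- Once classification saturates, the discriminative criterion leaves
  emission details under-determined; the polish addresses reporting, but
  the classifier itself may sit anywhere on the ratio-equivalent ridge.
- The background order default (1) reflects the sample sizes of the
  bundled studies; richer chains overfit discriminatively on hundreds of
  sequences (measured in development) but may be appropriate for larger
  corpora.
- Multi-start search is a heuristic; no global-optimality claim is made,
  and weak motifs (< ~0.4 bit/column) at low site counts routinely escape
  it at desk-scale restart budgets.
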