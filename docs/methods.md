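# Methods

## Model

Phenotypes follow a linear reaction norm over a standardized environmental
gradient `x ~ N(0, 1)`:

    P = mu + b x + A_int + A_sl x + E

with additive breeding values for intercept and slope, `(A_int, A_sl) ~
MVN(0, C)`, `C = [[s2_int, s_is], [s_is, s2_sl]]`, and homogeneous
residual variance `s2_e`.  One record per animal; no dominance, no common
environment, no heterogeneous residuals.  The breeding value expressed at
gradient value `x` is `A(x) = A_int + x A_sl`, so genetic (co)variances
between environments are quadratic forms in `x`:

    cov(A(x_i), A(x_j)) = s2_int + (x_i + x_j) s_is + x_i x_j s2_sl.

The trait is sex-limited (think milk yield or litter size): only females
carry records.

Defaults (the "basic" architecture): `s2_int = 0.3`, `s2_sl = 0.05`,
`s_is = 0`, `s2_e = 0.7`, so heritability in the average environment is
0.30 and the genetic correlation between the average and the most extreme
modelled environments is 0.72.

## Environment grid

The gradient is discretized into 13 classes: 11 equal-width slices of
(-2, 2) plus the open tails.  Class probabilities are standard-normal
interval masses; the within-class gradient value is the truncated-normal
conditional mean, computed analytically (phi-difference over
Phi-difference; inverse-Mills ratio in the tails).  Animal allocations
(reference population, commercial sibs/progeny) are probability mass
times the total and deliberately stay real-valued - they enter variance
formulas, not pens.

The 13-class grid is part of the model definition rather than a numerical
mesh.  The response in the average environment is insensitive to
refinement (< 1% moving to 41 inner classes), but slope-sensitive
quantities retain a mild discretization dependence: a finer grid gives a
goal-optimal index finer slope resolution, and the per-class genomic
reference populations (below) shrink as classes split.

## Breeding goals

The aggregate genotype is `H = v'a` over the per-class breeding values.
Two goals:

* **proportional** - `v_i` equals the class frequency: a linear profit
  equation valuing performance wherever animals produce.  On a symmetric
  grid its slope-view weight `sum v_i x_i` is exactly zero.
* **resilience** - `v_i = 0.3 exp(-0.3 (mu + b x_i))`, the derivative of
  the saturating profit function `1 - exp(-0.3 P)` at the expected
  phenotype.  Weights decline by a factor ~4.15 from the worst to the
  best class, i.e. a premium on performance under poor conditions.

The per-animal marginal values are used as printed, not re-weighted by
class frequencies; a frequency-weighted variant was evaluated during
development and reproduced the benchmark ratio tables distinctly worse.

## Index construction

An index `I = b'x` over information sources gets weights `b = P^-1 G v`;
accuracy for class `i` is `b'g_i / (sigma_I sigma_A(x_i))` with
`sigma_I = sqrt(b'Pb)`.

Phenotypic sources are means of `n` records of relatives; (G)EBV sources
are unit-variance predictors with `cov(EBV_i, A_j of a relative) = a r_i
cov_A(x_i, x_j) / sigma_A(x_i)` and, between EBVs of the same animal,
`r_i r_j r_g(x_i, x_j)` - a construction that is exact at accuracy one
and reproduces the genomic-index matrices.

Per-class GEBV accuracies follow `r_i = sqrt(N_i h_i^2 / (N_i h_i^2 +
M_e))` with `M_e = 1200` effective chromosome segments and each class's
GEBV estimated from that class's reference animals only (`N_i` =
class mass x reference size); cross-class information enters only through
the genetic correlations.  The heritability in this formula is taken from
the *base* population by default: the reference population is a standing
commercial resource, not the selected nucleus.  (`gebv_h2_basis =
"candidate"` switches to the equilibrium candidate heritability; it
lowers the genomic index accuracy by ~0.035 under the basic parameters.)

Conventional (GxE-ignoring) evaluation: progeny sources are pooled into
one across-environment mean (P averaged with weights `n_i n_j / (sum
n)^2`, G columns with `n_i / sum n`); the genomic variant solves weights
against `P_conv = [r_i r_j]`, `g = r`, then evaluates true accuracies
with the unit-scaled genetic covariances.  With zero intercept-slope
covariance the conventional class-`i` accuracy factorizes exactly into
(pooled intercept accuracy) x (genetic correlation of class `i` with the
average environment), which the tests verify.

## Breeding schemes

A nucleus of 2000 candidates (1000 per sex) in the best environment
(x = 2.37); selected proportions 5% (sires) and 20% (dams); 10 progeny
per dam; 100 commercial half-sibs (sib testing) or half-sib progeny
(progeny testing of males) spread over the classes by the grid masses.
Commercial animals are producing females, so all 100 carry records;
nucleus litters contain both sexes, so a candidate has 5 recorded full
sibs (a female candidate: 4, plus her own record as a separate source).

* **sib testing** (both sexes): 13 half-sib means, nucleus full-sib mean,
  own performance (females), sire and dam EBV in the best and worst
  environment, and one pooled EBV of the 10 unrelated commercial dams
  (zero relationship to the candidate; it only absorbs the dam component
  of the half-sib means).
* **progeny testing**: males swap half-sib means for half-sib progeny
  means (and the pooled EBV becomes that of their mates); females as in
  sib testing.  Progeny-tested sires carry a relative generation interval
  of 1.6 (others 1.0).
* **genomic selection**: the 13 GEBV only, identical for both sexes.

Parental EBV accuracies are the per-environment accuracies of the same
scheme's indices one generation earlier, closed as a fixed point together
with the Bulmer equilibrium.  EBVs of the same parent in the best and
worst environment are weakly correlated (the best-worst genetic
correlation is 0.03 under the basic parameters), so no singularities
arise; any source pair correlated above 1 - 1e-8 is resolved by pruning
the later source with zero weight, never by ridge regularization.

A reduced variant of the traditional schemes (`nucleus_information =
False`: sib/progeny means only) is used for response *profiles* across
environments; the full pseudo-BLUP indices are used for accuracies and
the scheme-comparison tables.

## Selection-aware equilibrium (Bulmer effect)

Truncation selection builds negative gametic-phase disequilibrium, and it
erodes *between-family* variance first.  Plugging a single reduced
covariance matrix into unselected-population covariance formulas misses
this and overstates sib-information accuracies at equilibrium; the engine
therefore tracks the covariance matrices of `(A_int, A_sl)` *among the
selected sires and dams*,

    C_sel = C_cand - k c c' / sigma_I^2,   c = cov((A_int, A_sl), I),
    k = i (i - z),

with the candidate generation `C_cand = 0.5 C_base + 0.25 (C_sel,m +
C_sel,f)` (Mendelian-sampling covariance is untouched by selection).
Every information source combines parental-path contributions from the
appropriate matrices: e.g. commercial half sibs carry `0.25 C_sel,m +
0.75 C_base` individually and covary `0.25 C_sel,m` between themselves
and with the candidate; a candidate's progeny (not yet selected) carry
`0.25 C_cand + 0.75 C_base`.  With no selection all matrices coincide and
the textbook formulas re-emerge.

The joint fixed point (two 2x2 matrices + parental accuracies) is
iterated to 1e-8 / 1e-6 with a guarded Aitken extrapolation along the
stabilized step direction (an extrapolated state is rejected unless both
selected-parent matrices stay positive semidefinite).  All scenarios
converge in at most 15 iterations.

One second-order consequence worth knowing: selecting on an index with
*opposite-signed* covariances to intercept and slope (a resilience goal)
induces a small *positive* intercept-slope covariance among the selected
- selection on a difference makes its components positively correlated -
which feeds back into the equilibrium response profile.

## Selection intensities and response

Intensities start from the infinite-population truncation value
`phi(z)/p`, apply Burrows' finite-candidate correction `i - (1-p) / (2 i
p (n+1))` with 1000 candidates per sex, and shrink by `sqrt(1 -
rho_bar)`, `rho_bar` being the average correlation between index values
over all candidate pairs of that sex (full-sib and paternal-half-sib
pairs share family-level sources verbatim; cross-family covariances of
individual-level sources are included through the pair relationship).
The correction is below 1% for these family sizes, so the approximation
in `rho_bar` for mixed pairs is immaterial.

Response per environment class and round:

    R_e = [ i_m cov(I_m, A_e)/sigma_I,m + i_f cov(I_f, A_e)/sigma_I,f ]
          / (L_m + L_f)

at equilibrium.  Because every `cov(I, A_e)` is linear in `x_e`, the
profile is exactly a line: `R_e = R_int + x_e R_sl`, giving the intercept
(= average-environment) and slope (environmental-sensitivity) responses
directly.  Responses are reported in within-scenario units; only ratios
and shapes are comparable across schemes.

## Heritability scenarios

The alternative scenarios `h2 in {0.1, 0.3, 0.5}` (heritability in the
average environment) scale the whole genetic covariance matrix:
`s2_int = h2`, `s2_sl = (0.05/0.3) h2`, `s2_e = 1 - h2`.  Scaling the
matrix as a whole leaves the entire between-environment genetic
correlation structure invariant - the scenarios differ in
signal-to-noise, not in the shape of the GxE - which is also why a single
genetic-correlation profile per intercept-slope-correlation value
describes all of them.  An explicit `var_sl` overrides the scaling.

## Monte-Carlo oracle

`mc_oracle` draws parent breeding values from `N(0, C)`, builds
hierarchical half/full-sib families with Mendelian sampling, assigns
progeny to classes (balanced largest-remainder allocation by default, so
the realized design matches the deterministic group sizes; multinomial
optional) and generates records with residual noise.  GEBV are emulated
as `r_i A_i / sigma_A(x_i) + independent noise`, which realizes the
genomic-index covariance structure exactly without simulating markers.
Realized index accuracies per class agree with the deterministic
predictions within 2 SE and one-generation responses within 3 SE at the
sizes used in the tests (2000 sires, 100 half-sib progeny each).

What the simulator does *not* emulate - and hence what its agreement
does not establish about real data: marker data and LD structure (GEBV
accuracy is imposed, not derived), multi-generation selection (the
Bulmer-equilibrium predictions are validated only through their
unselected-base special case), pedigree errors, heterogeneous residuals,
non-linear reaction norms, and non-normal environment distributions.

## Numerical choices

* Truncated-normal class means analytically, never by quadrature.
* Near-duplicate sources pruned at correlation 1 - 1e-8 (later source
  dropped), mirroring how redundant EBV sources are handled in practice.
* Equilibrium tolerances 1e-8 (covariances) and 1e-6 (accuracies);
  hard stop at 200 iterations with a diagnostic.
* Ratio tables flag cells whose denominator is below 1e-12 as NaN.
* Real-valued group sizes throughout; rounding only at presentation.

## Known limitations

* Ratios of slope responses divide by numbers near zero (the
  progeny-testing slope response under the resilience goal is ~1e-3 of
  the intercept response at `h2 = 0.1`); their sign and magnitude are
  intrinsically unstable to modelling details at the percent level, and
  the golden check accordingly treats them with a wide (15%) tolerance -
  two such cells still fail it, honestly reported by
  `rnbreed compare --check`.
* The progeny-testing male index accuracy at equilibrium (0.93 under the
  basic parameters) sits ~0.03 above the benchmark value; bracketing
  variants (fewer recorded daughters, no nucleus sources) move it below.
  All other benchmark accuracies agree within 0.016.
* Single breed, discrete generations (intervals enter only as relative
  scalars), no inbreeding, no optimum-contribution selection.
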