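# Methods

## Model

A continuous trait (log10-transformed where its variance scales with its
value, e.g. body mass) evolves along a rooted, time-calibrated phylogeny
by Brownian motion with variance σ² per unit time, augmented by three
kinds of sparse effect:

* **Directional effects β** attach to branches. A branch of length *t*
  carrying rate β shifts the expected trait of every descendant tip by
  the branch total β·*t*, with no effect on any variance. On the
  un-logged scale the branch total is a fold change, 10^{β·t}.
* **Evolvability multipliers υ > 0** attach to internal nodes and scale
  the Brownian variance of the entire descendant clade; computationally,
  every branch inside the clade is multiplied by υ (nested multipliers
  compose). υ > 1 widens trait-space exploration, υ < 1 narrows it.
* **A global trend β_g** relates each tip's expected deviation from the
  root state α to its *variance-adjusted time* T_i(υ), the root-to-tip
  sum of υ-scaled branch lengths — the equivalent number of years of
  evolution at the background variance.

Tip values are then jointly multivariate normal with mean
α + Σ_j β_j t_j + β_g T_i(υ) per tip (raw branch lengths in the
directional sum: the mean and variance effects are deliberately
orthogonal) and covariance V_υ, where V_υ[i,k] = σ² × shared υ-scaled
root-to-MRCA path length. The log-likelihood always includes the full
normalising constant; marginal-likelihood comparisons depend on it.

Two independent evaluations are implemented: a dense-matrix oracle
(build V_υ, Cholesky-factorise) and a linear-time peeling recursion that
merges children into conditional normal messages. They agree to 1e-8 on
a thousand random instances in the test battery; the peeling form also
detects exactly singular covariances (zero-variance paths meeting at a
node) and names the offending tips instead of returning NaN.

Zero-length branches are accepted at parse time; the likelihood errors
only when they make V singular, and an explicit `jitter` option adds a
small diagonal variance on request (never silently).

### υ and the stem branch

The stem branch of the node carrying a υ is *not* scaled by default
(the multiplier acts on the clade below the node); `include_stem=True`
is available everywhere. On an ultrametric tree with no υ, all T_i are
equal and β_g is exactly confounded with α; the package documents this
rather than reparameterising, and β_g should only be interpreted when
variance-adjusted times actually vary.

## Priors

| parameter | prior | default | notes |
|---|---|---|---|
| υ | Gamma(shape 1.2, scale 5) | mode = 1 | mode at the neutral value |
| \|β·t\| | Weibull(shape 1.5, scale 1.1) | mode ≈ 0.53 | sign ±, ½ each |
| β count | geometric, e^(−2) per effect | charge 2 nats | see below |
| υ count | geometric, e^(−2) per effect | charge 2 nats | see below |
| β_g | Normal(0, sd 0.1) | — | |
| α | Gamma(2, 0.7) shifted to −3 | mode −2.3 | lower bound −3 |
| σ² | log-uniform on [1e−8, 1e4] | — | cancels in fixed-dim moves |

The effect-configuration prior is: the number of active effects of each
kind is geometric (each effect costs its *inclusion charge* in nats),
placements are uniform given the count, and values are independent
draws from the Gamma/Weibull densities. With this structure, a birth
proposal that draws its value from the prior is accepted with
probability min{1, likelihood-ratio × e^(−charge)}: proposal densities
cancel value priors, and the uniform-placement count terms cancel the
configuration prior's combinatorial factor. Neither appears in the
acceptance ratio, and prior-only chains reproduce every prior exactly
(the KS battery in the acceptance tests).

The directional charge of 2 nats corresponds to prior inclusion odds of
about 1/7 per effect. The same charge is applied to evolvability
multipliers: 2.00 nats is, to two decimals, the negative log of the
Gamma(1.2, 5) density at its mode (−log f(1) = 2.05), so an υ here
costs what it costs in samplers whose likelihood-neutral birth
acceptance equals the prior density at the proposed value. Without this
charge a flat count prior admits junk multipliers at inclusion
frequencies near 0.5, swamping any frequency-based selection rule.

σ²'s prior is not dictated by the model; log-uniform over a wide range
is proper, scale-free in the interior, and documented for
marginal-likelihood use. Narrow the bounds in the config for
stepping-stone work on small problems — desk-scale stones mix slowly
over twelve decades of σ².

### The retention cost of one effect

Integrating the posterior odds of a single included effect over its
value gives, by a Laplace argument,

    odds ≈ exp(Δll) × f(x*) σ_post √(2π) × e^(−charge) / N_locations

so the *effective cost* of retaining one effect is about
charge + log N + 2 ≈ 9 nats on a 100-tip tree (N ≈ 100–200 eligible
placements). An effect whose data support Δll is below ~7 nats cannot
reach a stable inclusion frequency above the chance threshold — by
design: this is the model's protection against decorating the tree with
noise. The simulation scenarios (below) are sized so planted effects
clear this bar; empirically measured inclusion frequencies match the
formula's prediction at the boundary.

## Reference density f(υ)

For a clade of n tips evolving at the background variance, the sampling
distribution of the clade variance ratio is that of χ²_n/n: mean 1,
variance 2/n (at n = 2 the formula reduces algebraically to a unit
exponential). Its 5%/95% quantiles give a clade-size-specific envelope:
a fitted υ outside the envelope indicates more (or less) trait-space
exploration than sampling noise in a clade of that size could produce.
The envelope widens as n shrinks — small clades cannot evidence
modest multipliers.

## Sampler

Reversible-jump Metropolis–Hastings. Moves: add/remove/change for β and
υ (change moves are Gaussian on the β·t scale and log-normal
multiplicative on υ — a scale parameter walked additively escapes
likelihood wells near zero through rare large steps, which we observed
directly), a relocate move for υ (shift to a neighbouring eligible
node, value unchanged; adjacent placements differ only by the sibling
subtree's scaling and are otherwise separated by a barrier that plain
death/birth cannot cross at desk scale), and random-walk updates of α,
β_g and log σ² (Jacobian in the Hastings term). Step sizes auto-tune
toward 20–40% acceptance during burn-in only. Model variants gate the
move set: `brownian`, `directional`, `evolvability`, `combined`,
`combined_global`.

**Guided births.** Birth values are drawn from a 50/50 mixture of the
prior and an independence proposal centred on a deterministic
data-derived local estimate (for a node: the clade's mean squared
standardized contrast under the Brownian reference fit; for a branch:
the standardized contrast between the subtree and its siblings). The
mixture density enters the Hastings ratio exactly, so the target is
untouched; discovery of well-supported effects accelerates by orders of
magnitude. All guide statistics are computed once before sampling.

**Initialisation.** α and σ² start at the Brownian GLS fit, with σ²
anchored at the *median* squared standardized contrast (the GLS mean is
inflated by any variance-scaled clades, which would start the chain in
a relabelled chart of the σ²/υ degeneracy). A deterministic greedy
forward selection then pre-seeds effects whose grid-scored
log-likelihood gain exceeds the per-effect retention cost, with
coordinate refinement and a placement polish. This stands in for the
diffusion phase of production-scale chains (the published analyses run
orders of magnitude longer); the chain freely prunes anything seeded.
Stepping-stone chains never use it — stones start at the prior.

Chains are deterministic given the seed. Post-burn-in samples are
thinned at the smallest spacing bringing the log-likelihood lag-1
autocorrelation under the target (default 0.1; prior-only chains are
diagnosed on the log-prior series); failure to reach the target warns
and reports the achieved value. A Geweke-style early/late comparison
warns about residual non-stationarity.

## Selection

An effect is retained when its inclusion frequency p′ exceeds the
chance level p by two standard deviations,
sd = √(p′(1−p′)/(n(1−r²))), with n the thinned sample count and r the
location's inclusion-indicator lag-1 autocorrelation (the run's
log-likelihood autocorrelation when the indicator's is undefined). The
chance level is the capped acceptance probability of a likelihood-
neutral prior-drawn proposal at the location's posterior-mean value:
Weibull density × e^(−charge) for β, Gamma density for υ. This is an
interpretive reading — "prior probability" of a continuous value is not
otherwise well defined — and it is conservative for this sampler, whose
actual chance-level inclusion per location is far lower (the placement
factor): measured false-positive rates on null simulations are
essentially zero.

Consensus: a location is retained only if it passes in *every* run
(production default six; the desk-scale tests use two or three). Final
values come from the single run whose retained-parameter values
correlate best, on average, with the other runs'.

Trade-offs: where a retained branch β and the υ at the same branch's
end node co-occur in the chain less often than the product of their
frequencies predicts (2-sd deficit on the expected joint frequency),
the pair is trading off; the effect with the 2-sd-higher individual
frequency wins, otherwise both are kept as a tandem pair.

## Marginal likelihoods

Stepping-stone sampling with powers at Beta(0.3, 1) quantiles
(concentrated near the prior), the RJ kernel sampling
prior × likelihood^b, warm-started stone to stone, 20% within-stone
burn-in. Contributions are log-mean-exponential importance ratios
between adjacent powers; a bootstrap standard error over within-stone
draws is reported alongside (production practice adds a between-run SD
over independent chains; both are available). Desk default 100 stones ×
5,000 iterations; the production-scale 1000 × 50,000 is one config line.
The estimator is exact for a constant likelihood and recovers the
conjugate normal–normal marginal within Monte-Carlo error (acceptance
battery).

Note a structural property: with the geometric count prior, about 87%
of each effect class's prior mass sits on the empty configuration, so
the richer variants are penalised only ~0.3 nats on null data relative
to pure Brownian motion. Bayes factors between variants are therefore
dominated by fit, not dimension; the nesting bound
log ML(combined) ≥ log ML(brownian) + log P(no effects) is tested.

## Synthetic data and what the tests do (and do not) show

The simulator is the generative model run forward (preorder recursion,
child = parent + β t + β_g υt̃ + Normal(0, σ² υ t̃)); simulator and
likelihood are two views of one distribution, verified by moment
matching. Trees are pure-birth (Yule), extended past the final
speciation by the waiting time to the next event so pendant branches
are never zero.

Study conditions for the identifiability scenarios: 100-tip trees at
birth rate 1 (depth ≈ ln 100 ≈ 4.6), background σ² = 0.02 per unit
time, planted effects on clades of ≥ 10 tips. These numbers follow from
the retention-cost arithmetic: |β·t| = 1 on a short stem then carries
12–25 nats; a multiplier u on an m-tip clade carries ≈
(m−1)/2·(u−1−ln u) nats (independent of σ²) with a χ² spread of
≈ √((m−1)/2)·|u−1|, so u = 4 and u = 1/4 go on the largest available
clades. Placement rules are identifiability-driven: multipliers never
sit on root children (a υ there is an exact relabelling of one on its
sibling plus a σ² rescale), must split into two ≥3-tip subtrees, and
directional effects take short stems (a shift along a long branch is
masked by that branch's own Brownian noise). Effects weaker than the
retention cost — e.g. υ = 1/4 on a 10-tip clade, ~3 nats — are not
recoverable by *any* sampler of this posterior, and the suite documents
this rather than planting them.

Recovery is scored by exact branch identity for β and by clade overlap
(Jaccard ≥ 0.7 of descendant tip sets) for υ: the node placement of a
clade multiplier is soft whenever the sibling subtree at the boundary
is small, and adjacent placements are scientifically the same claim.

What passing does not show: the scenarios have a single trait,
error-free tips, correct ultrametric trees and truly Brownian
background; real comparative data violate all four, and chain lengths
here are two to three orders of magnitude below production scale.

## Numerical choices

* Prior log-densities are direct formulas (`math.lgamma` etc.), unit
  tested against scipy.stats; scipy's dispatch overhead is too large
  for the sampler's hot loop.
* The peeling kernel is compiled with numba (pure-Python fallback kept
  and used as the same code path).
* Ties in greedy placement and scenario assignment break by node id;
  everything is deterministic given the tree and seed.
* Degenerate inputs: constant traits flag the σ̂² = 0 boundary;
  constant chains flag undefined autocorrelation; n(1−r²) ≤ 0 is an
  error, never a silent division.

## Known limitations

Single trait only; no tip measurement error; no fossil (non-ultrametric)
calibration; topology fixed and known; the sampler's desk-scale
settings trade some inclusion-frequency precision (autocorrelation
warnings are common at 2×10⁵ iterations) for runtime; β effects whose
branch total is near the retention cost (~7 nats of support) sit at the
selection boundary by construction and will be found in roughly half of
realisations.
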