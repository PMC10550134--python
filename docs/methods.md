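# Methods

## Model

`vaxculture` tracks the frequencies of four phenotypes — V⁺A⁺, V⁺A⁻, V⁻A⁺,
V⁻A⁻ — combining a vaccination state V± (a childhood behavior, fixed for
life) and a vaccine attitude A± (confident/hesitant, mutable through
community influence). The population is infinite (frequencies, not counts),
generations are discrete and non-overlapping, and mating is random; there is
no assortment by belief, no age structure, and no disease-transmission
layer — σ encodes *perceived* disease risk, not an epidemic state.

One generation applies, in order:

1. **Vertical transmission** over all 16 ordered parental pairs with product
   frequencies. Pair subscripts follow the convention −×− → 0, −×+ → 1,
   +×− → 2, +×+ → 3, applied to vaccination pairs (*m*) and attitude pairs
   (*n*). Offspring are vaccinated with probability
   B<sub>m,n</sub> = c<sub>n</sub>(1 + b<sub>m</sub>)/2 and confident with
   probability C<sub>n</sub>; the two transmissions are independent given
   the pair, the only reading consistent with per-trait transmission
   probabilities that carry no joint structure.
2. **Cultural selection**: both V⁺ phenotypes are weighted by 1 + σ and the
   four frequencies renormalized. σ is evaluated at the coverage of the
   generation *entering* the iteration (the parents): perceptions lag one
   generation behind behavior.
3. **Oblique transmission**: within each vaccination class, A⁻ mass moves to
   A⁺ with probability P<sub>A→conf</sub>(v) and A⁺ mass to A⁻ with
   P<sub>A→hes</sub>(v), both evaluated at the *post-selection* offspring
   coverage. Coverage is conserved — attitude change cannot retroactively
   vaccinate anyone.

Both timing choices are recorded in `IterationSettings` so serialized runs
document them.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| initial frequencies | (V⁺A⁺, V⁺A⁻, V⁻A⁺, V⁻A⁻) | (0.81, 0.10, 0.07, 0.02) — US-like MMR-era estimates |
| C<sub>n</sub> | P(transmit confidence) per attitude pair | (0.01, 0.5, 0.5, 0.99) |
| b<sub>m</sub> | vaccination-state influence on vaccinating | (0.01, 0.5, 0.5, 0.99) |
| c<sub>n</sub> | attitude influence on vaccinating | (0.01, 0.5, 0.5, 0.99) |
| σ<sub>max</sub> | cap on the selection coefficient | 0.1 (conventional selection-coefficient scale) |
| σ family | coverage response of selection | `threshold_mid` (decline centred at 70% coverage) |
| σ steepness | logistic width of the threshold decline | 0.05 |
| oblique max | per-generation cap on attitude switching | 0.1 (small vs vertical transmission, so parental transmission dominates) |
| oblique midpoint / steepness | logistic centre / width of the transition curves | 0.5 / 0.1 |
| iteration cap / tolerance | run control | 100 / 10⁻⁸ max absolute frequency change |

The transmission vectors are "Mendelian-like": homogeneous couples
transmit their shared state near-certainly, mixed couples are coin flips.

**Scenarios** override only c<sub>n</sub>: strict mandate
(0.5, 0.9, 0.9, 0.99), less strict mandate (0.3, 0.7, 0.7, 0.99), somewhat
inaccessible (0.01, 0.3, 0.3, 0.7), inaccessible (0.01, 0.1, 0.1, 0.5).

**Response-curve calibration.** The σ families and oblique curves are
logistic parameterizations chosen to satisfy the qualitative constraints
that define them — plateau at σ<sub>max</sub> at low coverage, sign change
at the stated threshold, symmetric ±σ<sub>max</sub> range; mirrored
monotone transition curves bounded by the oblique cap. The exact functional
forms are a design choice of this package; all shape parameters are
configuration, so alternative fitted curves drop in without code changes.
Equilibria within ~1 percentage point of a decision boundary should be
read with that calibration freedom in mind.

## Sweep designs

Both sweep engines restart every grid cell from the same initial
frequencies (no warm starting), so cells are independent equilibria.

* **Mixed-couple design**: C₁ = C₂ varies on one axis (C₀, C₃ fixed),
  σ<sub>max</sub> on the other.
* **Range-shift design**: all C<sub>n</sub> slide together inside an
  interval [lo, hi] with C₀ = lo, C₁ = C₂ = midpoint, C₃ = hi. The default
  interval ladder anchors lo at 0.01 with widths 0.98·t for t uniform on
  [0, 1], so the topmost interval [0.01, 0.99] recovers the baseline C
  vector exactly and lower intervals represent uniformly more hesitant
  transmission cultures. Explicit intervals may be supplied instead.

Default grid resolution is 21×21 (CLI `--grid-size`); the landscape
features of interest (orderings, the mid-confidence transition band) are
stable on grids as coarse as 5×3, which is what the test suite uses.

## Agent-based cross-check

The deterministic recursion is exact only for an infinite population. The
ABM realizes the identical process for N agents: multinomial initial
states, random pairing (a permutation split into N/2 ordered pairs, two
offspring each), Bernoulli transmission draws, selection as weighted
resampling with weights 1 + σ for vaccinated offspring (equal in
expectation to multiply-and-renormalize), and Bernoulli attitude flips.
Replicates draw independent streams by seed sequencing. Agreement with the
recursion at the √(p(1−p)/N) scale — verified at N = 10⁵ over 50
generations, and improving from N = 10³ to 10⁵ — is an independent check of
the recursion's algebra, since the ABM never touches the frequency
equations. The ABM emulates demographic sampling noise only; it does not
add spatial structure, contact networks, or household correlation, so
ABM–recursion agreement says nothing about those features of real
populations.

## Numerical choices

* Frequencies are renormalized after vertical transmission and selection to
  absorb floating-point drift; the sum-to-one invariant holds to 10⁻⁹ over
  1000+ iterations.
* Oblique switching computes the larger post-switch attitude share directly
  and the smaller as a complement against the class total (exact by the
  Sterbenz lemma), making coverage conservation bit-exact rather than
  approximate.
* Equilibrium is declared when the largest absolute phenotype-frequency
  change falls below 10⁻⁸; the cap of 100 iterations matches the
  trajectory lengths used for the scenario comparisons. The baseline run
  reaches a bit-exact fixed point around iteration 60, so cap and tolerance
  are not binding there.
* σ ≤ −1 with vaccinated mass present is rejected (it would annihilate the
  class); the symmetric range [−σ<sub>max</sub>, σ<sub>max</sub>] is the
  default for all families.
* Degenerate inputs: a phenotype absent at baseline makes its percent
  change undefined (NaN), never infinite; a sweep interval [x, x] collapses
  all C<sub>n</sub> to x.

## Limitations

* Attitudes are binary; "fence-sitting" gradations and attitude-dependent
  mate choice are out of scope.
* The response curves are qualitative stand-ins calibrated to threshold
  behavior, not fitted to data; conclusions that hinge on equilibria within
  about a percentage point of a policy threshold (e.g. exactly 50%
  coverage) are calibration-sensitive, while orderings and decoupling
  patterns are robust across all six σ families.
* c<sub>n</sub> overrides are time-invariant: scenarios model a permanent
  policy, not adoption, repeal, or enforcement dynamics.
* No epidemiological feedback: outbreaks cannot shock perceptions beyond
  the smooth σ(v) dependence.
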