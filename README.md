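# vaxculture

A cultural-evolution simulator of vaccine hesitancy and vaccination coverage.

Public-health outcomes depend not only on vaccine supply and policy but on a
population's *vaccination culture* — the beliefs about vaccines that parents
pass to children and that communities reshape over time. `vaxculture`
implements a deterministic cultural niche-construction recursion in which
each individual carries a binary vaccination state (V⁺ vaccinated / V⁻
unvaccinated) and a binary attitude (A⁺ confident / A⁻ hesitant), giving four
phenotypes V⁺A⁺, V⁺A⁻, V⁻A⁺, V⁻A⁻ tracked as population frequencies. It is
aimed at modellers and public-health researchers who want to explore how
vaccine **mandates** and vaccine **inaccessibility** decouple beliefs from
behavior.

## The model

Each discrete generation:

1. **Random mating.** All 16 ordered parental phenotype pairs occur with
   product frequencies.
2. **Vertical transmission.** A couple with vaccination pair-subscript *m*
   and attitude pair-subscript *n* (convention −×− → 0, −×+ → 1, +×− → 2,
   +×+ → 3) vaccinates its offspring with probability

   *B*<sub>m,n</sub> = *c*<sub>n</sub> (1 + *b*<sub>m</sub>) / 2,

   where *b*<sub>m</sub> is the influence of the parents' own vaccination
   states and *c*<sub>n</sub> the influence of their attitudes, and transmits
   vaccine confidence with probability *C*<sub>n</sub> (independent draws
   given the pair).
3. **Cultural selection.** Both vaccinated phenotypes are multiplied by
   1 + σ(*v*) and frequencies renormalized, where σ is a coverage-dependent
   selection coefficient bounded by σ<sub>max</sub>: maximal when nobody is
   vaccinated and the disease is visible, declining once coverage masks the
   disease. Six σ-curve families are provided (constant, three logistic
   thresholds at 90/70/50% coverage, linear, cubic).
4. **Oblique transmission.** Community influence flips attitudes within each
   vaccination class at coverage-dependent probabilities (hesitant→confident
   falls with coverage, confident→hesitant rises), leaving coverage itself
   unchanged.

Policy scenarios act only on the attitude-influence vector *c*: mandates
raise *c* for hesitant-containing couples (hesitancy no longer prevents
vaccination); inaccessibility lowers *c* for confident-containing couples
(confidence no longer guarantees vaccination). Five presets are built in
(`baseline`, `strict_mandate`, `less_strict_mandate`,
`somewhat_inaccessible`, `inaccessible`).

A finite-population agent-based implementation of the identical process
(`vaxculture.simulate_abm`) serves as a stochastic cross-check: at
*N* = 100 000 agents its trajectories track the recursion within binomial
sampling error.

## Worked example

Compare the lenient-mandate equilibrium against the no-intervention baseline
(default parameters: initial frequencies 0.81 / 0.10 / 0.07 / 0.02,
Mendelian-like transmission vectors (0.01, 0.5, 0.5, 0.99),
σ<sub>max</sub> = 0.1 with the 70%-threshold curve):

```text
$ vaxculture compare --scenario less_strict_mandate
phenotype     baseline    scenario    change_%  direction
V+A+            0.3775      0.3225       -14.6  decrease
V+A-            0.1089      0.2140        96.5  increase
V-A+            0.2195      0.1520       -30.7  decrease
V-A-            0.2940      0.3114         5.9  increase
coverage        0.4864      0.5365
confidence      0.5971      0.4746
```

The mandate nearly doubles the vaccinated-but-hesitant (V⁺A⁻) class: it
raises coverage (0.49 → 0.54) *at the expense of* confidence (0.60 → 0.47),
because hesitant parents now vaccinate without changing their beliefs.
Inaccessibility produces the mirror image — coverage falls while confidence
rises, stranding confident families unvaccinated:

```text
$ vaxculture compare --scenario somewhat_inaccessible
phenotype     baseline    scenario    change_%  direction
V+A+            0.3775      0.3382       -10.4  decrease
V+A-            0.1089      0.0474       -56.5  decrease
V-A+            0.2195      0.4178        90.3  increase
V-A-            0.2940      0.1965       -33.2  decrease
coverage        0.4864      0.3857
confidence      0.5971      0.7560
```

Other entry points:

```bash
vaxculture run --scenario baseline -o trajectory.csv        # single trajectory
vaxculture sweep --scenario baseline --grid-size 21 \
    -o sweep.csv --heatmap sweep.png                        # equilibrium landscape
vaxculture oracle --n-agents 100000 --seed 1 -o abm.csv     # stochastic cross-check
vaxculture --list-scenarios                                 # preset c-vectors
```

or from Python:

```python
import vaxculture as vx

traj = vx.iterate(
    vx.PhenotypeDistribution(0.81, 0.10, 0.07, 0.02),
    vx.apply_scenario(vx.TransmissionParameters.baseline(), "somewhat_inaccessible"),
    vx.SelectionFunction(family="threshold_mid", sigma_max=0.1),
    vx.ObliqueFunctions(),
)
print(traj.final.coverage, traj.final.confidence)  # 0.3857 0.7560
```

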