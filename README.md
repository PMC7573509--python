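# cuspshift

Cusp-catastrophe analysis of non-linear shifts in posttraumatic distress,
for researchers studying disaster recovery with short multi-wave panels.

After a disaster, most survivors recover smoothly, but a subset shifts
abruptly into a persistently distressed state. The cusp catastrophe is the
canonical model for such discontinuous change: a state variable *y*
(distress) moves on the potential

    V(y) = ¼ y⁴ − ½ β y² − α y

where the **bifurcation factor** β controls *when* the system splits into
two attractor states (here: low coping self-efficacy pushes β up), and the
**asymmetry factor** α controls the *relative pull* of the lower versus
upper state (here: perceived loss or peritraumatic dissociation). The
system is bistable exactly when 4β³ > 27α², and under the delay convention
the state jumps — with hysteresis — only when its current basin vanishes.

`cuspshift` implements the polynomial-regression test for a cusp in
two-wave change. With residualized change scores as the dependent variable
and z = (x₁ − min x₁)/SD(x₁) built from the earlier wave, it fits

    dv ~ 1 + z³ + z² + (CSE × z) + asymmetry covariates

on standardized columns, prunes a non-significant cubic term and then
non-significant covariates (the quadratic term and the bifurcation product
are always retained), and compares the final model against a linear
baseline with ΔAIC/ΔBIC categories (meaningful > 2, moderately meaningful
> 4, considerable > 10 for AIC; bare mention ≤ 2, positive ≤ 6, strong
≤ 10, very strong > 10 for BIC) plus a verbal support verdict: a cusp is
*supported* only when a state term, the bifurcation product and at least
one asymmetry covariate are all significant.

Because no raw participant data are distributed, the package ships a
synthetic-panel generator that realizes the assumed data-generating
process: a stochastic cusp diffusion dy = −(y³ − βᵢy − αᵢ)dt + σ dW per
subject, with controls driven by covariates that load on a shared latent
vulnerability factor, calibrated so the two bundled study profiles
reproduce the published descriptive moments and key correlations. A
matched linear-null generator, MCAR missingness, attrition, and an
iterative-PCA imputer complete the pipeline, so type-I error, power and
model-selection behaviour of the whole procedure can be measured.

## Worked example

Replicate the first study design end to end on a synthetic panel:

```bash
cuspshift replicate-study1 --seed 1 --out out/
```

This generates a 189-subject, three-wave panel (with realistic missingness
and attrition), imputes 106 missing cells by iterative PCA, fits the three
wave-pair contrasts and writes `out/report.json` and `out/report.md`. The
T1–T2 block of the report reads:

```
| IV      | beta    | Std. error | p      |
|---------|---------|------------|--------|
| z^3     | -3.2973 | 0.5472     | 0.0000 |
| z^2     |  4.0848 | 0.6499     | 0.0000 |
| CSE x z | -1.7835 | 0.2354     | 0.0000 |
| loss_t1 |  0.6602 | 0.1238     | 0.0000 |

AIC = 495.0959; BIC = 514.5464; adj. R^2 = 0.2251
Pruned during fitting: time_since (p = 0.9035), gender (p = 0.3957).
...
Delta AIC (linear - cusp) = 30.4772 (considerable); verdict: cusp_supported
```

Read it as: the cubic/quadratic state terms are significant (evidence of
two coexisting distress states), the negative CSE × z coefficient says the
split sharpens as coping self-efficacy drops, and the positive loss
coefficient says greater loss pulls subjects toward the upper distress
state — so the cusp model is supported and beats the linear baseline by a
considerable AIC margin. Under the linear-null generator the same pipeline
returns `no_cusp` for almost every seed.

Library use mirrors the CLI:

```python
from cuspshift import SimConfig, simulate_panel, build_design, fit_cusp_model
from cuspshift.experiments import contrast_roles

panel = simulate_panel(SimConfig.from_profile("study1"), seed=1)
fit = fit_cusp_model(build_design(panel, contrast_roles("study1")))
print(fit.coef["bif"], fit.pvalues["bif"], fit.aic)
```

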