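# netmoments

Moment-based network meta-analysis with random inconsistency effects.

Network meta-analysis pools randomized trials that each compare a subset of
several treatments, so that every treatment can be compared with every other
— including pairs never compared head-to-head. Its main threat is
*inconsistency*: direct and indirect evidence about the same comparison may
disagree. `netmoments` fits a contrast-based model in which inconsistency is
an extra source of random variation at the level of the *design* (the set of
treatments a trial compares), alongside the usual between-study
heterogeneity. Estimation is a non-iterative, semi-parametric extension of
the DerSimonian–Laird method of moments, so it is fast, transparent, and
reduces exactly to the classical procedure for a pairwise meta-analysis.

## The model and the estimators

Study *i* of design *d* contributes a vector of estimated effects
**Y**_di (length c_d = |d| − 1, contrasts against the design's baseline
treatment) with fixed, known within-study covariance **S**_di:

    Y_di = δ_d + B_di + Ω_d + ε_di

* δ_d — linear combinations of the *c* basic parameters δ^AB, δ^AC, …
  (average effects versus the reference treatment A), assuming consistency
  holds *on average*;
* B_di ~ N(0, τβ² P_cd) — between-study heterogeneity;
* Ω_d ~ N(0, τω² P_cd) — design-level inconsistency, shared by all studies
  of a design;
* ε_di ~ N(0, S_di) — within-study sampling error;
* P_c = I + J/2 (unit diagonal, halves off-diagonal) encodes a common
  variance for every treatment comparison.

Stacking everything, **Y** ~ N(**X**δ, **S** + τβ²**P₁** + τω²**P₂**). The
network Q statistic splits exactly into within-design heterogeneity parts
and an inconsistency remainder, Q_net = Σ_d Q_het,d + Q_inc, and matching
the two quadratic forms to their expectations gives two linear estimating
equations:

    Σ_d Q_het,d = Σ_d (n_d − 1) c_d + τ̂β² Σ_d K_d
    Q_net       = Σ_d n_d c_d − c + τ̂β² tr(B P₁) + τ̂ω² tr(B P₂)

solved directly (no iteration), truncated at zero, and plugged into GLS:
δ̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹Y with V = S + τ̂β²P₁ + τ̂ω²P₂ and
Var(δ̂) = (XᵀV⁻¹X)⁻¹. Three model families are available: **RI**
(random-effects, inconsistent — both variances), **RC** (random-effects,
consistent — τω² = 0) and **CC** (common-effect, consistent). The package
also provides loop-inconsistency variants (restricting **P₂**), treatment
contrasts relative to any reference, probabilistic treatment ranking, and
R/I² statistics — the c-th-root ratio of confidence-region volumes of two
nested fits, I² = (R² − 1)/R² × 100%.

## Worked example

```python
import netmoments as nm

config = nm.SimulationConfig(layout="run1", tau_beta_sq=0.1,
                             tau_omega_sq=0.03, seed=20)
network = nm.simulate_dataset(config)          # 10 studies, 5 designs, A-D

fit = nm.fit_full_model(network)               # RI model
gls = nm.gls_estimate(network, fit)
i2 = nm.i_squared_comparisons(network)
print(nm.format_fit_report(nm.fit_report(network, fit, gls, i2=i2)))
```

prints

```
Network: 10 studies, 5 designs, 4 treatments (reference A)
Model: RI
tau_beta^2  = 0.3493 (untruncated 0.3493)
tau_omega^2 = 0 (untruncated -0.1087)
flags: truncated_omega
Q_net = 43.56 (df 11), Q_het = 28.92 (df 7), Q_inc = 14.64
Basic parameters (95% CI):
  AB: -0.4151 (SE 0.2727) [-0.9496, 0.1194]
  AC: -0.01069 (SE 0.3071) [-0.6127, 0.5913]
  AD: -0.1008 (SE 0.3535) [-0.7937, 0.5922]
I2 RI vs RC: 18% (R = 1.107)
I2 RI vs CC: 84% (R = 2.517)
I2 RC vs CC: 81% (R = 2.275)
```

The heterogeneity variance is estimated at 0.349; the inconsistency moment
estimate came out negative and was truncated to zero (flagged), so the RI
intervals here coincide with the consistency-model structure. The AB row
says treatment B lowers the outcome by 0.42 on average relative to A, with a
95% interval still crossing zero. The I² lines quantify how much of the
confidence-region volume is attributable to inconsistency (RI vs RC),
heterogeneity (RC vs CC), or both (RI vs CC).

Real datasets enter through a long-format contrast CSV (`study, base,
treat, y, v`, plus a `study, treat_i, treat_j, cov` table for multi-arm
studies) via `read_contrast_table`; `contrasts_from_binary_arms` builds
these tables from arm-level 2×2 counts. The `examples/` directory contains
short scripts for fitting, ranking, simulation and binary-outcome input,
and the same operations are scriptable from the shell:

```bash
netmoments fit --input contrasts.csv --cov cov.csv --model ri
netmoments simulate --layout run1 --reps 1000 --seed 1 --out metrics.csv
netmoments rank --input contrasts.csv --cov cov.csv --direction smaller --seed 1
```

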