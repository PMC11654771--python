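# webergrasp

Simulation and analysis of Weber-law adherence in visually guided size
responses — grip apertures in grasping (MGA, the maximum grip aperture) and
manual size estimates (MSE, a static finger-separation match to perceived
size).

## The problem

Weber's law says estimation noise grows in proportion to stimulus
magnitude. Perceptual size judgements show it clearly, yet the variability
of grip apertures across repeated grasps often does not scale with object
size. `webergrasp` implements a two-stage generative model showing that
this apparent violation can arise downstream of an intact Weber-scaled
visual estimate, purely from properties of the motor mapping.

## The model

A response to an object of size *s* (mm) is generated in two stages:

1. **Visual stage** — a noisy size estimate obeying Weber's law:
   *ŝ = s + ε_V*, with *ε_V ~ N(0, (W_V · s)²)* and *W_V* the visual Weber
   fraction.
2. **Motor stage** — a linear mapping plus implementation noise:
   *GA\* = k · ŝ + overshoot + ε*, with *ε ~ N(0, σ²)*.

With independent noise sources, the response SD is

SD(*GA\**) = √((k · W_V · s)² + σ²),     E[*GA\**] = k · s + overshoot.

The *apparent* Weber fraction *W* — measured as the OLS slope of the
within-subject response SD on object size — is therefore attenuated by a
shallow mapping slope *k* and diluted by implementation noise σ. Grasping
(*k* = 0.7, overshoot = 18 mm, σ = 6 mm) can hide Weber scaling that
manual estimation (*k* = 1.0, overshoot = 4 mm, σ = 2 mm) exposes, even
when both are driven by identical visual estimates with *W_V* = 0.06.

The analysis half of the package mirrors a standard within-subject
psychophysics pipeline: trial-level outlier exclusion (2.5 SD within each
subject × condition × size cell), optional removal of initial repetitions
per block, per-cell means/SDs, per-subject slope measures (*k* and *W*),
subject-level outlier exclusion, paired and Welch contrasts with Cohen's
d, random-intercept mixed-model ANOVA (Wald χ²), and JZS Bayes-factor
t-tests (Cauchy prior on effect size, default scale √2/2) that can
quantify evidence both for and against Weber scaling.

## Worked example

```bash
webergrasp dissociation --replicates 100 --seed 1 --outdir out/
```

prints

```
MGA: mean Weber fraction 0.0080 (between-subject SE 0.0142), median BF10 0.315 -> absent
MSE: mean Weber fraction 0.0411 (between-subject SE 0.0066), median BF10 3.47e+03 -> present
```

Each of the 100 replicate cohorts simulates 20 subjects × 20 repetitions
per size at {21, 28, 35, 42} mm under both parameterizations. The manual
size estimates recover a Weber fraction near the asymptotic value 0.041
(the OLS slope of √((0.06·s)² + 4) over the four sizes) and the Bayes
factor finds Weber scaling *present*; the grasping responses, built on the
same Weber-scaled visual noise, yield a fraction near 0.009 that the Bayes
factor classifies as *absent*. That is the dissociation: the motor
mapping, not the visual estimate, controls whether Weber's law is visible
in the output.

The same machinery is scriptable:

```python
import webergrasp as wg

table = wg.generate_mga_mse_cohort(seed=1)           # tidy trial table
bundle = wg.run_full_analysis(wg.RunConfig(seed=1), table)
print(bundle["slopes"].groupby("condition")["weber_fraction"].mean())
```

`webergrasp simulate` generates trial CSVs from a design JSON, and
`webergrasp analyze` runs the full filter → summarize → infer chain on any
tidy trial table (columns
`subject,group,condition,block,size_mm,repetition,response_mm`).

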