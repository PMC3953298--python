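# gnrherk

Simulation and analysis of pulsatile GnRH signaling to ERK and ERK-driven
transcription.

Gonadotropin-releasing hormone (GnRH) is secreted in pulses, and pituitary
gonadotropes decode pulse frequency, width, and amplitude into graded
transcriptional responses.  `gnrherk` implements a reduced 10-state kinetic
model of this pathway — square-wave GnRH input → receptor occupancy (HR) →
Gq-effector activation (E) → algebraic Michaelis–Menten MEK activation →
distributive dual phosphorylation of ERK with nucleocytoplasmic shuttling →
an ERK-dependent transcription factor (TF1) and its transcript (TF1DT) —
together with the in-silico experiments that probe how information moves
down the cascade:

* **Protocols**: pulse trains (amplitude, width, interval), single pulses
  terminated by washout or by MEK inhibition (PD184352-style), and
  receptor-number variants.
* **Simulator**: piecewise stiff integration across pulse edges with
  exact ERK-amount conservation, plus an independent fixed-step
  Runge–Kutta oracle.
* **Metrics**: integrated (area-under-curve) responses vs. pulse frequency
  and width, post-pulse ppERK fractions, frequency-vs-width sensitivity
  ratios, and inhibitor/washout termination ratios.
* **Fitting**: the genetic algorithm used to estimate the fitted parameter
  subset (multiplicative mutation, rank-proportional selection, elitism),
  accelerated by a numba-compiled integrator.
* **Synthetic data**: generators that emulate ERK2-GFP
  nuclear:cytoplasmic (N:C) imaging traces and dose–response endpoints,
  so the whole pipeline is testable without experimental data.

It is a library first (`import gnrherk`), with a thin `gnrherk` CLI
(`simulate`, `freq-response`, `width-response`, `post-pulse`,
`termination-ratio`, `fit`, `synth`, `battery`).

## Worked example

```python
import gnrherk as gk

params = gk.ParameterSet()          # published defaults (uM, min)

# A single 1-min pulse of 1e-7 M GnRH, removed by washout at t = 1 min.
frac = gk.post_pulse_fraction(params, width=1.0, amplitude_molar=1e-7,
                              horizon=30.0)
print(f"post-pulse ppERK fraction: {frac:.3f}")

# How much transcriptional output survives when signaling is cut at the
# pulse end by a MEK inhibitor instead of washout?
table = gk.termination_ratio(params, widths=(1, 5, 15, 30, 60),
                             total_time=360.0)
print(table[["width_min", "ratio"]].round(3).to_string(index=False))
```

prints

```
post-pulse ppERK fraction: 0.962
 width_min  ratio
         1  0.042
         5  0.745
        15  0.914
        30  0.948
        60  0.965
```

Read: after a 1-min pulse, 96% of the integrated whole-cell ppERK response
occurs *after* the hormone is gone — MEK stays active because the upstream
effector decays slowly.  Consequently, blocking MEK at the end of a 1-min
pulse removes ~96% of the 6-h transcript output (ratio 0.04), while for a
60-min pulse the termination method barely matters (ratio ≈ 1).  This is
the model's explanation for why the transcriptional tier is robust to
pulse width but sensitive to pulse frequency.

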