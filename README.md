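# prawnvision

Quantifying camouflage of chameleon prawns (*Hippolyte varians*) against
seaweed backgrounds, as seen by their fish predators.

Chameleon prawns occur in green and red colour forms living on green sea
lettuce (*Ulva lactuca*) and red dulse (*Palmaria palmata*). Whether a prawn
is camouflaged is a question about the *predator's* visual system, not ours.
This package implements the full analysis chain for that question:

1. **Calibration** — raw multispectral photographs are linearised with grey
   reflectance standards and equalised with a dark/light standard pair, so
   ROI means are reflectance estimates through the camera's bands.
2. **Visual modelling** — reflectances are converted into normalised cone
   quantum catches of two fish predators: the dichromatic pollack
   (*Pollachius pollachius*; cone peaks 436/521 nm, abundance ratio 0.70:1)
   and the trichromatic two-spotted goby (*Gobiusculus flavescens*;
   456/531/553 nm, ratios 0.72:1:0.60), each with a 410 nm ocular-media
   cutoff, under D65 illumination. Camera colour space is mapped to cone
   space with a fitted degree-2 polynomial transform.
3. **Discrimination** — the receptor-noise-limited (RNL) model of Vorobyev &
   Osorio turns a prawn–background pair into a chromatic distance ΔS in
   just-noticeable-difference (JND) units. With receptor contrasts
   Δf_i = ln(q_i(a)/q_i(b)) and Weber fractions ω_i = ν/√η_i (ν = 0.05):

       dichromat:  ΔS = |Δf₁ − Δf₂| / √(ω₁² + ω₂²)
       trichromat: ΔS = √( [ω₁²(Δf₂−Δf₃)² + ω₂²(Δf₁−Δf₃)² + ω₃²(Δf₁−Δf₂)²]
                           / [(ω₁ω₂)² + (ω₁ω₃)² + (ω₂ω₃)²] )

   ΔS < 1 predicts the pair cannot be discriminated.
4. **Colour metrics** — hue as a catch-ratio channel (SWS/LWS for the
   dichromat, SWS/(MWS+LWS) for the trichromat, the latter motivated by a
   PCA of standardised cone catches), tracked over a 30-day colour-change
   experiment.
5. **Statistics** — exact two-sided binomial tests (small-probability-mass
   convention, as in R's `binom.test`) for Y-maze substrate choices, and
   mean ± SE group summaries.

A first-class synthetic-data module generates every input with known ground
truth — reflectance spectra of both colour forms and seaweeds, 7-timepoint
colour-change trajectories with front-loaded kinetics and realistic
attrition, rendered raw camera fixtures, and behavioural trial tables — so
the whole chain is testable offline.

## Worked example

```python
>>> import numpy as np
>>> import prawnvision as pv
>>> p = pv.pollack()
>>> pv.weber_fractions(p)
array([0.05976143, 0.05      ])
>>> from prawnvision.visual_systems import ConeCatchRecord
>>> a = ConeCatchRecord("prawn", p.channel_names, np.array([0.50, 0.50]), p.name)
>>> b = ConeCatchRecord("algae", p.channel_names, np.array([0.55, 0.45]), p.name)
>>> pv.jnd(a, b, p).delta_s
2.575363348988639
```

The two records differ by about 10% in each channel in opposite directions;
to pollack vision that is a contrast of ≈ 2.6 JND — above the discrimination
threshold of 1, so the prawn is predicted to be visible against that
background.

Running the synthetic field comparison:

```python
>>> summary = pv.run_field_camouflage(pv.RunConfig(seed=11))["summary"]
>>> summary[["colour_type", "substrate", "system", "mean"]].round(2)
  colour_type    substrate   system   mean
0       green        dulse     goby   9.92
1       green        dulse  pollack  13.92
2       green  sea_lettuce     goby   2.74
3       green  sea_lettuce  pollack   1.35
4         red        dulse     goby   1.51
5         red        dulse  pollack   1.09
6         red  sea_lettuce     goby  10.89
7         red  sea_lettuce  pollack  13.75
```

Each prawn type sits near the discrimination threshold on its own seaweed
(mean JND ≈ 1–3) and is conspicuous on the other (≈ 10–14), for both
predators — background matching in the predator's eye, not the human one.

A thin CLI wraps the same pipeline:

```sh
prawnvision run-all --seed 11 --out results/
```

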