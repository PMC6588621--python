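# Methods

This note documents the models, parameter choices and numerical conventions
behind `prawnvision`, and what the synthetic-data generator does and does not
emulate.

## Spectral representation

All spectral quantities live on a common integer-nanometre grid, by default
400–700 nm at 1 nm. Visible-band converted cameras pass roughly 420–680 nm
and neither modelled predator has UV-sensitive cones, so 400–700 nm covers
every pigment peak (436–553 nm) and the 410 nm ocular cutoff with margin.
Resampling is linear interpolation (errors if the target grid overhangs the
source support — no silent extrapolation); all spectral integrals use the
trapezoid rule. Everything is relative: reflectances and transmissions are
fractions, irradiance and sensitivities are in arbitrary units that cancel
in the catch normalisation.

## Visual systems

Two fish predators ship as YAML configs:

| system  | channels (λmax, nm) | abundance ratio | cutoff | ν    |
|---------|---------------------|-----------------|--------|------|
| pollack | 436, 521            | 0.70 : 1        | 410 nm | 0.05 |
| goby    | 456, 531, 553       | 0.72 : 1 : 0.60 | 410 nm | 0.05 |

Each double-cone member is treated as an independent chromatic channel. The
pollack's 521 nm double-cone channel is stored as the long channel (named
`LWS` in the config) so the dichromat hue ratio SWS/LWS denominates on it;
both medium- and long-wave labels are encountered for this channel in the
literature.

**Pigment template.** Receptor sensitivities use the Govardovskii A1
nomogram — the standard α-band closed form parameterised solely by λmax,
plus the near-UV β band (amplitude 0.26). The curve is renormalised to peak
1 on the working grid; the peak stays within 1 nm of λmax.

**Ocular media.** A logistic transmission curve with its 50% point at the
cutoff and a 10–90% rise of 30 nm — only the 50% point is constrained by
measurement; the slope is a smoothness choice, and the long-wave limit is 1.

**Quantum catches.** q_i = ∫R·I·T·S_i dλ / ∫I·T·S_i dλ (von Kries
normalisation to the illuminant catch). This makes a flat reflectance c map
to catch c in every channel under *any* positive illuminant, so JNDs measure
reflectance contrast, not illuminant scale. D65 ships as the standard CIE
10-nm relative table, interpolated to the working grid.

**Weber fractions.** ω_i = ν/√η_i with abundances normalised so the most
abundant class has η = 1 and therefore ω = ν = 0.05 exactly. The printed
cone ratios are read as relative abundances feeding this formula — the
standard receptor-noise treatment.

## Discrimination (RNL model)

Receptor contrasts are log catch ratios, Δf_i = ln(q_i(a)/q_i(b)) — the
log-linear receptor code dominant in RNL applications. Closed forms for the
dichromat and trichromat ΔS are implemented directly; the test suite checks
the trichromat form against an independently coded equivalent — the
noise-weighted distance of Δf from the nearest achromatic point,
min_c Σ(Δf_i − c)²/ω_i² — to 1e-10 on random inputs. ΔS is symmetric,
invariant to common scaling of both records, linear along contrast rays, and
zero exactly when all Δf_i are equal. The discrimination threshold is
ΔS = 1. Random prawn–background pairing is without replacement when the pool
is at least as large as the subject list, with replacement otherwise; a seed
is mandatory.

## Calibration

Linearisation curves are polynomials in log–log space (log reflectance as a
polynomial in log pixel value), degree ≤ 3 chosen by leave-one-out
cross-validation per channel; a pure gamma response is exactly degree 1 in
this space, so gamma-encoded fixtures invert analytically. Fits must
reproduce every calibration standard within 2% absolute reflectance and be
monotone over the sample hull. Equalisation is the per-channel affine map
sending the dark and light standard means to their nominal reflectances;
any linear relighting cancels exactly, and equalising an equalised image
with its own standards is the identity. Pixels at ≥ 99% of bit depth are
flagged at linearisation time and excluded from all patch and ROI means
(with a logged count). UV planes are accepted but unused by the shipped fish
systems.

## Camera → cone mapping

The default camera model is three Gaussian bands (peaks 460/530/600 nm,
σ 35 nm) — a plausible stand-in for a converted DSLR's visible channels;
measured sensitivities can be supplied as CSV spectra. Each cone catch is
regressed on degree-2 polynomial terms (with interactions) of the camera
band catches, trained on a ≥ 50-spectrum library; the reported diagnostic is
*held-out* R² (25% random holdout), refit on all spectra afterwards.
Predicted catches at or below zero are clamped to 1e-4 so log-ratios stay
defined. On the 200-spectrum synthetic library, held-out R² exceeds 0.99
per channel; residuals of a few 0.001 catch units remain, which matters at
small catches: log-ratio amplification inflates small (matched-pair) JNDs by
up to ~1 JND while large contrasts agree to within ~15%. The spectral route
(direct integration) is therefore the default in the pipeline; the camera
route is a config switch.

## Synthetic data: what it emulates, and what it does not

Green coloration is a Gaussian reflectance peak (545 nm, σ 36 nm, amplitude
0.32, baseline 0.04); red coloration a long-pass sigmoid edge (588 nm, width
20 nm, amplitude 0.42, baseline 0.14). The higher red baseline encodes the
observed premise that red animals carry more short-wave reflectance than
green ones, so green↔red convergence produces a short-wave crossover and a
PCA of standardised catches yields an opponent first axis (short-wave
loading opposite medium+long) — the construction that motivates the
SWS/(MWS+LWS) hue ratio. Seaweeds use the same families (sea lettuce
555/34/0.28/0.035; dulse 600/18/0.36/0.12), with smaller between-sample
jitter (±4 nm peak, 8% amplitude) than prawns (±6 nm, 10%); pointwise
measurement noise is sd 0.005. With these one-time choices, matched
prawn–seaweed JNDs land at ≈ 1–3 and mismatched at ≈ 10–14.

Colour change mixes start and target spectra in reflectance space with
m(d) = m_max(1 − e^{−kd}), k = 0.15/day, m_max = 0.8 — exponential approach
encodes change that is fastest in the first 10 days. Rate couples to body
size as k_i = k·e^{−β(size−8 mm)} with β = 0.05/mm (sizes ~N(8, 1.5²) mm),
so larger individuals change more slowly. Dropout hazards per 5-day interval
are (0, 0, 0.05, 0.06, 0.15, 0.25): survival is complete through day 10 and
falls to ≈ 57% by day 30. Day-wise summaries use survivors only. In the
trajectory pipeline each individual keeps one randomly drawn background
partner across days by default ("fixed" pairing): a common-random-numbers
choice that removes background-sampling noise from the trajectory estimate
without biasing the day means; per-day re-pairing is available as
`pairing_mode="per_day"`. Rendered fixtures place flat grey standards
(2–99% for linearisation, 8.5%/95% for equalisation) and subject patches on
a tile grid, gamma-encode (default 2.2) the gain-scaled camera catches, add
Gaussian sensor noise (sd 0.003 of full scale) and quantise to 14 bits.
Choice trials are Bernoulli: a decision is made with probability 0.44
(emulating 79 decisions in 180 trials) and matches the prawn's own colour
with probability 0.8.

Not emulated: chromatophore physiology (mixing is phenomenological, in
reflectance space), spatial pattern and predator acuity, underwater light
fields (D65 throughout), UV reflectance, and seasonal algal dynamics.
Passing tests therefore demonstrate correctness of the measurement chain
and the qualitative experiment-level phenomena — background matching,
front-loaded convergence, hue crossover, choice preference — not
quantitative agreement with any particular field population.

## Statistics

The exact binomial test uses the two-sided small-probability-mass
convention (sum of point masses ≤ the observed outcome's mass), matching
R's `binom.test`; the suite verifies it against full enumeration for all
n ≤ 12 at p0 = 0.5 and 0.3. Group summaries report mean ± SE with
SE = s/√n (n−1 denominator); single-value groups report SE as missing and
empty groups are dropped with a warning. Linear mixed-effects modelling and
post-hoc contrasts are deliberately out of scope: they are standard
machinery for the resulting tidy tables (one row per observation), not part
of this package's computation.

## Problem sizes and determinism

Default problem sizes mirror the emulated study design: 64 prawns per type
and 64-image background pools in the field comparison; 25 individuals per
type, 7 sampling days and 26-image pools in the colour-change experiment;
90 trials per type in the choice experiment; 200 spectra for mapping fits.
Everything runs in seconds. All randomness flows from
`numpy.random.default_rng` seeds carried in `RunConfig`; reruns with the
same config are identical, and every output table carries the package
version and a config hash.
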