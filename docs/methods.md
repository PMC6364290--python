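# Methods

## Data model

A run is a phase-labelled multichannel time series: each row carries an
absolute timestamp (second resolution), a phase label (`F#`, `W#`, `M#` for
flush/wait/measurement with cycle index), one temperature and one dissolved
oxygen value per chamber. Phase segmentation is a partition of the rows into
contiguous runs of identical labels; only measurement phases, during which
the chamber is sealed, are eligible for slope fitting. Within a phase, time
is measured in seconds from the phase's first point, which makes slope units
unambiguous ((do-unit/L)/h after the ×3600 rescale). Sampling need not be
1 Hz — all computations use actual timestamps, though the importers and the
simulator default to 1 s spacing because that is what the common logger
software emits.

Chamber metadata are validated at construction: mass, volume and body
density positive, and the effective volume V − m·(1000/D) (mL) strictly
positive. More than 8 chambers warns (the capacity of typical multichannel
systems) but is not rejected, since nothing in the maths depends on it.
Sensor dropouts (missing O₂) are dropped pointwise per chamber; a phase is
flagged unusable for a chamber when fewer than 50% of its points survive —
a conservative default for a situation the source designs leave unspecified.

## Import and windowing

The generic exchange format is tab-delimited `Date.Time, Phase, Temp,
Ox.1..Ox.N` with `DD/MM/YYYY HH:MM:SS` timestamps (DMY default; MDY/YMD
selectable); reads tolerate whitespace delimiters and European decimal
commas. Vendor layouts (AutoResp-style paired temp/O₂ columns, Q-box Aqua
single-channel) are configurable column-mapping profiles rather than
hard-coded parsers, because vendor exports drift between versions — the
shipped defaults are validated against synthetic fixtures only, and no
bit-exact vendor parity is claimed. AquaResp runs are converted by
reconstructing F/W/M labels from the summary file's cycle timing.

Measurement imports accept a clock window (≤ 24 h, midnight-aware; equal
start and stop mean the full day). A phase is retained iff both its first
and last timestamps fall inside the window — partially truncated phases
would bias slopes — and retained phases are re-labelled `M1..Mn` in time
order. Retention is monotone: widening the window never drops a phase.

## Background correction

Blank tests are fitted by OLS over their measurement phase(s), pooled per
chamber; an r² below 0.9 triggers a warning because an unstable blank
undermines every downstream number. The six correction methods evaluate a
background slope b per (chamber, phase):

- `pre.test`, `post.test`: the respective blank slope, constant in time.
- `average`: (pre + post)/2.
- `linear`, `exponential`: interpolation at the phase's temporal midpoint
  with τ normalised over the span from the start of the first retained
  measurement phase (τ = 0) to the end of the last (τ = 1). The
  exponential form is b(τ) = pre·(post/pre)^τ, log-linear in τ, appropriate
  when microbial growth is roughly exponential; it requires same-signed,
  non-zero pre/post slopes and otherwise raises with advice to use
  `linear`. Anchoring τ to the measurement span (rather than to the blank
  tests' wall-clock times) is this package's reading of "progressively
  changing between the tests"; other implementations may anchor
  differently, which matters only when the blanks are far from the
  measurement span.
- `parallel`: the designated empty chamber is fitted independently for every
  measurement phase, so non-monotone background is tracked at phase
  resolution rather than through one pooled slope.

The correction is applied to the trace, not only to fitted slopes: within a
phase, corrected O₂(t) = raw O₂(t) − b·(t − t_start). Consequently a
corrected slope over *any* window equals the raw slope over that window
minus b, window-shortening and diagnostics operate on corrected data, and
correcting with −b restores the raw series exactly. The raw series is kept
alongside (`<chamber>.raw`) for visual comparison, and the background share
of total uptake is reported as 100·b/raw-slope (undefined when the raw
slope is essentially zero, |raw| < 10⁻¹² of the background's scale).

## Slope extraction and selection

Each (chamber, measurement-phase) is summarised by the OLS slope and r² of
O₂ against time over the first `window_s` seconds of the phase (half-open:
t < window_s; windows are always anchored at the phase start — arbitrary
sub-windows are out of scope). A zero-variance (flat) trace gets slope 0
and r² defined as 0, so it can never pass the linearity filter: a flat
trace carries no uptake signal. Records with r² below the threshold
(default 0.95) are discarded; if a chamber loses every phase, extraction
fails with the per-phase r² listed.

Selection operates per chamber on the survivors with uptake ≡ −slope:
`all`; `min`/`max` take the `n_slope` records with smallest/largest uptake
(ties broken by phase order, earlier wins — deterministic); `quantile`
keeps records at or below the p-quantile of uptake, with quantiles computed
by linear interpolation between order statistics, h = (n−1)p + 1 (the
common "type 7" rule, pinned for reproducibility). `min` corresponds to the
SMR use case: the phases where the animal was quietest.

Regression diagnostics (fitted values, residuals, standardised residuals
with leverage correction, leverage) are computed for the current and an
alternative window, mirroring the workflow of shortening the window when an
artefact — e.g. a fish that stops swimming — bends the trace late in the
phase. No automated artefact classifier is provided: r² can stay high
through a leak, so the judgement stays with the user, supported by the
diagnostics and optional plots. Manual removal marks a (chamber, phase)
unusable without touching other chambers.

## Metabolic rates

absMO₂ = −slope · V_eff with V_eff = (V_mL − m_g·(1000/D))/1000 litres;
massMO₂ = absMO₂/m_kg. The effective-volume form is the dimensionally
consistent reading of the volume correction (body displacement m/D); with
the default D = 1000 kg/m³ it reduces to the universal V(mL) − m(g) rule.
MO₂ is reported positive for declining O₂; a rising corrected trace yields
a negative MO₂ with a warning rather than an error, because over-correction
is information worth surfacing.

SMR estimators run on mass-specific values (per fish, the mass-specific
transform is monotone, so ordering-based estimators agree with slope-based
ones): `mlnd` fits normal mixtures with 1–4 components by EM (5
restarts, fixed configurable seed — mixture-library determinism is not
portable, so the seed is pinned here), selects the count by BIC and returns
the lowest component mean; `quant` the p-quantile (type-7); `low10` the
mean of the 10 smallest; `low10pc` the mean of the smallest 10% with count
ceil(0.1·n), minimum 1. MLND and low10 require ≥ 10 values. Metabolic
scope per fish: absolute scope AMR − SMR on both bases, factorial scope
AMR/SMR (undefined at SMR ≤ 0).

## Synthetic experiments

The simulator emulates the two canonical designs (swim-tunnel SMR/AMR runs
with 420/180/1200 s or 420/180/600 s cycles; small static chambers with
300/180/720 s cycles) at 1 Hz by default. During a measurement phase, O₂
declines at animal slope + background, where the animal slope derives from
the prescribed true mass-specific MO₂ through the same effective-volume
equations the analysis inverts, and the background follows a constant,
linear or exponential (log-linear) trajectory over the measurement span.
The total rate is held constant within each phase at the background's
midpoint value, so the matching correction method recovers the truth
exactly in the noise-free limit — the end-to-end tests assert < 1%
relative bias without noise and < 5% at 0.02 mg/L Gaussian sensor noise
over 8 cycles, and that correcting a growing background with the pre-test
alone overestimates MO₂. Flush phases relax exponentially toward air
saturation (60 s time constant) purely for realism; slopes are never
fitted there. Wait phases hold the last value. Generation fails before
writing anything if the spec would drive O₂ negative.

Three artefacts can be scripted: `swim_stop` (animal slope drops to 20%
after onset — upward inflection, full-window r² below the short-window
r²), `blocked_sensor` (triangular 60 s dip in the reading), `leak` (animal
contribution decays with a 300 s time constant). Identical specs, including
the seed, produce byte-identical files (fixed number formats, one
`default_rng` stream).

What the simulator does **not** emulate: chamber mixing dynamics, sensor
drift and calibration error, temperature-dependent uptake, animal
behaviour beyond the scripted artefacts, or background that depends on O₂
level or temperature. Passing recovery tests therefore demonstrates the
correctness of the pipeline's arithmetic and the identifiability of the
simulated designs — not robustness to every failure mode of real systems.

## Numerical choices and defaults

- r² threshold 0.95 (lower, e.g. 0.9, when heavy background correction
  degrades linearity); quantile SMR default p = 0.25.
- Solubility: García & Gordon (1992) combined fit (Benson–Krause data),
  output mg/L via the O₂ molar mass 31.9988 g/mol and molar volume
  22.3916 L/mol (both pinned); barometric scaling by (P − p_w)/(1 − p_w)
  with Antoine water-vapour pressure; dry-air O₂ fraction 0.20946.
  Conversions all route through mg/L, so round trips and compositions are
  exact to floating point. At 16.5 °C fresh water this model gives
  9.767 mg/L at full air saturation; note that 61% of that is 5.958 mg/L,
  which rounds to 5.96 — a system whose sensor reports 5.95 at "61%" is
  within a fraction of a percent of the model.
- Water conditions are validated to 0–40 °C, salinity ≥ 0, pressure > 0;
  the case-study-style analyses assume fresh water at 1 atm, since
  salinity and barometric pressure are rarely logged.
- Unit labels are case-insensitive with documented synonyms
  ("mgO2/L" ≡ "mg/L").

## Pipeline runner

The CLI chains the stages from a YAML config, persists intermediates as
self-describing text files (so stages compose and can be inspected), and
writes a `run.log` where every line is `stage<TAB>JSON-parameters` — enough
to reconstruct the exact command sequence. Exit codes: 0 success, 2
validation error (caught before any I/O), 3 data error. Reruns of the same
config and seed are byte-identical.

## Known limitations

- Vendor dialects are best-effort profiles; verify against your own files.
- The interpolating corrections assume the blank tests are valid exactly at
  the edges of the measurement span (see anchoring note above).
- The `parallel` method corrects all chambers, including the blank itself,
  whose corrected slope is then ≈ 0; exclude it from rate summaries.
- No Q₁₀/temperature normalisation or allometric scaling — downstream
  concerns.
- MLND on small samples (10–20 values) is sensitive to initialisation even
  with pinned seeds; prefer `quant` or `low10pc` there.
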