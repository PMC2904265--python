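# Methods

This note documents the models, parameter choices, and numerical
conventions behind `erpspeller`, and states what the synthetic-data tests
do and do not establish about real recordings.

## Stimulus model

A copy-spelling trial presents, per selection level, a stream of
intensification events at a stimulus onset asynchrony (SOA) of 166 ms,
each intensification lasting 100 ms. The core of the stream is
`n_sequences` (default 10) randomized sequences in which every selection
group — 6 rows and 5 columns for the Matrix, 6 discs for the Hex-o-Spell —
appears exactly once. Pseudo-randomization enforces, across the entire
core including sequence boundaries, at least `min_gap = 2` intervening
events between two intensifications of the same group. The constraint is
satisfied by rejection sampling: each successive permutation is redrawn
(cap 10 000, then an error naming the seed) until its head is compatible
with the tail of the block so far. For ≤ `min_gap` + 1 elements this
forces every sequence to repeat the first one — the test suite verifies
this against exhaustive enumeration for the 3-element case.

The core is framed by a prequel and a sequel of one sequence-length of
uniform draws with repeats allowed and no gap constraint; they mask the
stream edges, are never analyzed, and are the sole source of the trial-to-
trial variation in total target count that makes the counting task
meaningful. Totals: 11·12 = 132 events per Matrix trial; 6·12 = 72 per
Hex-o-Spell level, 144 per trial. Core target counts are equal across
spellers: 2 per sequence (row + column) for the Matrix, 1 per sequence per
level for the Hex-o-Spell — 20 per trial either way.

Hex-o-Spell ground truth assumes offline copy-spelling semantics: level 2
is built as if the correct group had been chosen at level 1, with the
target's disc among five group symbols plus the empty backdoor disc.
Decoding that selects the backdoor yields a no-symbol outcome and counts
as an error.

Display geometry converts pixels to visual angle assuming square pixels
(pitch = physical diagonal / pixel diagonal), a flat screen, and central
viewing at 60 cm. Under the default 19-inch, 1280×1024 display this
reproduces the printed stimulus angles to within ±0.05°; the two printed
values for a square stimulus (e.g. 4.15° × 4.14°) cannot both be
reproduced by a square-pixel model, and we match them within ±0.1°.

## Synthetic EEG

The generator produces 64-channel recordings at 1000 Hz in microvolts.
Channel labels follow a schematic 10-10 montage ordered anterior to
posterior; each label is assigned a schematic 2-D scalp position parsed
from the label itself (row letters → anterior-posterior coordinate,
terminating digit → laterality). These positions parameterize smooth
topographies and spatial noise correlation; they are not digitized
electrode coordinates.

Every intensification event contributes five evoked components. Each
component is a temporal Gaussian (truncated at ±3σ) times a spatial weight
map with unit maximum:

| component | polarity | latency (ms) | FWHM (ms) | amplitude (µV) | topography peak |
|-----------|----------|--------------|-----------|----------------|-----------------|
| P1 | + | 115 | 50 | 3 | P5/P6/PO7/PO8 |
| N1 | − | 190 | 50 | 4 | P5/P6/PO7/PO8 |
| P2 | + | 250 | 60 | 4 | Fz/Cz/Pz |
| N2 | − | 320 | 60 | 3 | P5/P6/PO7/PO8 |
| P3 | + | 395 | 80 | 5 | Fz/Cz/Pz |

Latencies sit at the centers of the component measurement windows so every
simulated peak falls inside its detection window. Widths are typical
empirical FWHMs and deliberately narrower than the measurement windows:
the windows overlap their neighbors (e.g. N2 280–360 ms vs P3 350–440 ms),
and window-wide kernels would bleed one component's modulation into the
adjacent component's measurement strongly enough to scramble the
qualitative modulation pattern the generator is supposed to encode.
Amplitudes are free parameters — published grand averages convey component
magnitudes only graphically and they vary widely across individuals — so
the defaults are ordinary adult visual-oddball values, and no acceptance
check depends on absolute simulated microvolts.

Attention enters as a multiplicative per-component gain applied to target
events only (nontarget gain is always 1). The presets encode the
following qualitative modulation pattern:

| condition | P1 | N1 | P2 | N2 | P3 |
|---|---|---|---|---|---|
| overt / Matrix | 1.7 | 2.0 | 1.8 | 1.6 | 1.8 |
| overt / Hex | 1.9 | 2.0 | 2.0 | 1.6 | 1.8 |
| covert / Matrix | 1 | 1 | 1 | 1.2 | 1.32 |
| covert / Hex | 1 | 1.12 | 1.2 | 0.85 | 1.42 |

i.e. overt attention enhances all five components (slightly more so for
the Hex-o-Spell on P1/P2), covert attention modulates only the late
components for the Matrix and additionally N1/P2 for the Hex-o-Spell, with
the Hex-o-Spell's covert N2 *reversed* (targets less negative than
nontargets). Magnitudes were chosen once so that, with the default noise,
decoding lands where such experiments report it qualitatively: overt
at ceiling within a few sequences, covert intermediate between chance and
ceiling with the Hex-o-Spell above the Matrix.

Background noise is per-channel Gaussian shaped to a 1/f^α amplitude
spectrum (α = 1, unit-variance preserving), mixed across channels with a
row-normalized Gaussian spatial kernel over the schematic positions
(`channel_mixing` = 0.5), and scaled to 10 µV rms per channel in
expectation. A global seed drives the noise; schedules carry their own
seed, so signal and noise are independently reproducible.

What the generator does **not** model: volume conduction / realistic
forward fields, latency jitter (all latencies fixed), amplitude
habituation, eye or muscle artifacts, and any nonlinearity or refractory
interaction between overlapping responses (superposition is exactly
linear). Passing tests therefore demonstrate that the *analysis chain* is
correct and recovers known ground truth under overlap and colored noise —
not that it would attain any particular accuracy on real recordings.

## Preprocessing

Resampling is integer-factor decimation with a zero-phase FIR anti-alias
filter (`scipy.signal.decimate`); event indices rescale by the factor, and
non-integer factors are rejected. The ERP path runs at 250 Hz, the
classification path at 100 Hz — two configurations of the same operations.

Epochs span [−170, +670] ms around each event (≈ one SOA before to four
after); baseline correction subtracts the per-channel mean of the −170–0 ms
interval. Events too close to the recording edges are flagged
`boundary` and excluded rather than dropped silently.

The ERP contamination filters operate purely on the event stream, per
level: a target epoch is kept iff the nearest preceding and following
targets are ≥ 3 stream positions (≈ 500 ms) away; a nontarget epoch is
kept iff no target occupies the 3 preceding or 2 following positions (the
asymmetric ranges are applied verbatim; they truncate at stream
edges, and an event is not checked against itself). Because Hex-o-Spell
cores have one target per 6-long sequence plus the min-gap constraint,
core hex targets are always ≥ 3 apart and survive entirely; Matrix trials,
where a target's row and column can flash in close succession, lose
strictly more target epochs — both properties are asserted over seeded
schedules. The classification path deliberately uses all epochs.

A subtlety worth recording: the filters do not make overlap cancel exactly
in the target-minus-nontarget average. A kept target may have another
target at exactly −3 SOA (−498 ms), whose P3 reaches into the [−170, 0] ms
baseline, while the nontarget rule forbids that configuration; the
residual asymmetry biases zero-noise single-trial difference amplitudes by
a few percent (occasionally up to ~20% of a component's amplitude on
unlucky schedules). The test suite therefore checks the filtered average
against an analytic superposition oracle that models the neighbor contexts
exactly, plus a coarse (12%) bound on raw ground-truth recovery.

## ERP measurement

Component amplitudes are measured on per-condition averages over kept
epochs. The peak is the largest strict 3-point local extremum of the
component's polarity inside its window; window endpoints never qualify, and
a window without a same-polarity local extremum falls back to the window
mean with no latency reported. P1/N1/N2 are read at {P5, P6, PO7, PO8},
P2/P3 at {Fz, Cz, Pz}; measures are exported per electrode in a tidy
long-format table (component, electrode, status, amplitude, latency,
method), leaving any across-electrode or inferential aggregation to the
consumer. Statistical testing (repeated-measures ANOVA and friends) is out
of scope by design.

## Classification

Features are mean amplitudes per (channel, temporal window), channel-major,
over a configurable channel subset (default 55 of 64; the excluded nine —
Fp1, Fpz, Fp2, AF7, AF8, F7, F8, T7, T8 — are the anterior/temporal
periphery most prone to ocular and muscular artifacts in practice, and the
subset is a config parameter). Temporal windows (default seven, 40 ms wide,
≥ 50 ms apart — the separation makes default windows non-overlapping) are
placed greedily on peaks of the point-biserial correlation map collapsed
over channels (max |r|), post-onset samples only; fewer pickable peaks
yield fewer windows with a warning. Default dimensionality:
55 × 7 = 385.

The discriminant is binary LDA with the pooled class-centered covariance
shrunk toward ν·I, ν = tr(Σ̂)/d. The automatic shrinkage intensity is the
analytic Ledoit–Wolf estimate, γ* = Σᵢⱼ V̂ar(Σ̂ᵢⱼ) / Σᵢⱼ (Σ̂ᵢⱼ − νIᵢⱼ)²,
clipped to [0, 1] (formula implemented in
`classification._ledoit_wolf_gamma`); a fixed γ can be configured. γ = 0
reproduces classical LDA exactly (verified against an independent direct
solve and against scikit-learn's lsqr solver); γ = 1 gives the spherical
closed form (μ₁−μ₀)/ν. The bias places the decision threshold midway
between the projected class means. One classifier is trained per condition
on pooled target/nontarget epochs; the Hex-o-Spell uses the same
classifier for both levels.

Decoding averages (not sums) classifier outputs per selection group over
the first *n* core sequences — equivalent for the equal counts the design
guarantees, robust otherwise — and takes the argmax per decision stage,
ties resolving to the lowest group id. The Matrix maximizes rows and
columns separately and intersects; the Hex-o-Spell counts a trial correct
only if both stages are correct. Accuracy curves follow the offline
protocol: the first block trains, the remaining blocks test, for
*n* = 1…10.

Discriminability maps report 5-fold stratified cross-validated error (a
package-level convention; no single standard exists), as
1 − balanced accuracy — the mean of the two class-wise error rates —
because the ~1:5 target:nontarget imbalance would pin raw error near the
base rate; shuffled labels then sit at 50% as expected. The per-electrode
map uses one electrode's post-onset time samples as features; the temporal
map uses all electrodes' means of a 40 ms window slid in 10 ms steps,
reported at window centers.

## Experiment runner and problem sizes

`run_experiment` simulates each configured speller × attention condition:
blocks of copy-spelled words (word identity reduced to random target
letters; default 3 blocks × 3 words × 5 letters), per-trial schedule +
recording synthesis, both epoching paths, training on block 1, decoding
the rest. Per-condition seeds spawn deterministically from the experiment
seed; provenance (seeds, config) is emitted alongside results. The test
suite and acceptance checks run the same pipeline at reduced trial counts
(typically 3 blocks × 1 word × 3 letters, 20 seeds for the 2×2
qualitative reproduction; 3000 trials per speller for the chance-level
Monte Carlo), chosen to keep the full suite within a few minutes on one
CPU while leaving Monte-Carlo margins comfortable.

Serialization: recordings as HDF5 (µV, sampling rate and labels as
attributes) with a human-readable TSV event sidecar; epochs as HDF5;
schedules and result tables as TSV; models and provenance as JSON; configs
as JSON or YAML.

## Known limitations

- The generator's independence of noise across trials understates the
  autocorrelated artifacts of real sessions; accuracies here are not
  forecasts of online performance.
- The qualitative 2×2 reproduction is a property of the preset gains; it
  validates the pipeline, not the neuroscience.
- Component measurement windows overlap by construction, so measured
  amplitudes of neighboring components are not fully independent even at
  zero noise (see the baseline-residual note above).
- The 55-channel subset and the discriminability-map validation scheme
  are package-level conventions; both are configurable.
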