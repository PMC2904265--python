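# erpspeller

Simulation and offline decoding of visual ERP spellers under overt and
covert attention.

An ERP-based brain–computer interface spells text by flashing
("intensifying") groups of symbols in an oddball sequence and detecting the
attention-enhanced event-related potentials (P1, N1, P2, N2, P3) that
target intensifications evoke. This package re-implements the complete
offline analysis chain for two speller designs — a 6×5 symbol **Matrix**
(row/column intensification, symbol = best row ∩ best column) and the
two-level **Hex-o-Spell** (six discs on an invisible hexagon; level 1
selects a 5-symbol group, level 2 a symbol, with an empty "backdoor" disc)
— and pairs it with a synthetic-EEG generator so every stage is testable
against known ground truth without access to recordings. It is aimed at
BCI researchers who want a reproducible, fully specified reference pipeline
for ERP-speller decoding experiments.

## What it implements

**Stimulus scheduling** (`erpspeller.paradigm`). Trials of
`n` = 10 core sequences per level; each sequence intensifies every group
exactly once; across the whole core any two intensifications of the same
group are separated by ≥ 2 others; a prequel and sequel (one
sequence-length of unconstrained uniform draws) frame the core. A Matrix
trial comprises (6+5)·(10+2) = 132 intensifications, a Hex-o-Spell trial
6·(10+2)·2 = 144, at an SOA of 166 ms. Chance levels are 1/30 (Matrix) and
1/36 (Hex-o-Spell).

**Synthetic EEG** (`erpspeller.synth`). 64-channel, 1000 Hz recordings:
each intensification adds five Gaussian-bump components (temporal kernel ×
smooth scalp topography; P1/N1/N2 parieto-occipital, P2/P3 midline)
superposed linearly — at 166 ms SOA neighboring responses overlap heavily,
as in real data. Attention modulates target events multiplicatively via
preset per-component gains (overt: all five enhanced; covert: N2/P3 only
for the Matrix, N1/P2/P3 plus a *reversed* N2 for the Hex-o-Spell).
Background activity is spatially smoothed 1/f noise.

**Preprocessing** (`erpspeller.preprocessing`). FIR anti-aliased
decimation (250 Hz for ERP measurement, 100 Hz for classification),
epoching to [−170, 670] ms with 170 ms baseline correction, and the
stream-based contamination filters: target epochs require the nearest
other target ≥ 3 intensifications away; nontarget epochs require no target
among the 3 preceding / 2 following events.

**ERP measurement** (`erpspeller.erp`). Grand averages over kept epochs;
per-component peak amplitude/latency by largest same-polarity local
extremum within fixed windows (P1 80–150, N1 150–230, P2 210–290,
N2 280–360, P3 350–440 ms) with window-mean fallback; target-minus-
nontarget difference amplitudes on the posterior {P5, P6, PO7, PO8} and
midline {Fz, Cz, Pz} electrode subsets.

**Classification** (`erpspeller.classification`). A single binary
target/nontarget discriminant on 55 spatial × 7 temporal = 385 features
(mean amplitude per channel × automatically selected 40 ms window; windows
placed on peaks of the point-biserial correlation between classes). The
classifier is LDA with covariance shrinkage toward a scaled identity,

    Σ(γ) = (1 − γ) Σ̂ + γ ν I,   ν = tr(Σ̂)/d,   w = Σ(γ)⁻¹ (μ₁ − μ₀),

with γ either fixed or set by the analytic Ledoit–Wolf estimator. Symbols
are decoded by averaging classifier outputs per group over the first *n*
sequences and taking the argmax per decision stage; accuracy-vs-sequences
curves follow the offline protocol (block 1 trains, blocks 2–3 test).
Spatial and temporal discriminability maps (per-electrode and sliding
40 ms-window cross-validated error) round out the analysis.

## Worked example

```python
from erpspeller.experiment import ExperimentConfig, run_experiment

cfg = ExperimentConfig(n_blocks=3, words_per_block=1, word_length=3,
                       run_erp=False, seed=7)
bundle = run_experiment(cfg)
print(bundle.accuracy_frame().query("n_sequences in (1, 5, 10)"))
```

prints (one small run; 3 training and 6 test trials per condition):

```
speller attention  n_sequences  accuracy
 matrix     overt            1  1.000000
 matrix     overt            5  1.000000
 matrix     overt           10  1.000000
 matrix    covert            1  0.000000
 matrix    covert            5  0.166667
 matrix    covert           10  0.333333
    hex     overt            1  1.000000
    hex     overt            5  1.000000
    hex     overt           10  1.000000
    hex    covert            1  0.166667
    hex    covert            5  0.833333
    hex    covert           10  1.000000
```

Overt attention decodes perfectly from a single sequence at these signal
levels, while covert attention starts near chance (3.3% / 2.8%) and climbs
with the number of sequences — faster for the Hex-o-Spell than for the
Matrix, reproducing the qualitative pattern the pipeline is built around.
The fitted model for each condition reports its feature layout and
shrinkage, e.g. `dimensionality = 385`, `gamma ≈ 0.02`, and the seven
selected temporal windows (here centered near 10, 120, 190, 260, 340, 400
and 480 ms — the component latencies plus noise-driven picks).

The same pipeline is scriptable from the shell:

```sh
erpspeller simulate --config config.json --out sim/ --speller matrix --attention overt
erpspeller epoch --in sim/ --fs 100
erpspeller classify --in sim/ --train-block 0 --out results/
erpspeller run --config config.json --out results/   # everything at once
```

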