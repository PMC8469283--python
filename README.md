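# cortemg

Encoding and decoding of bilateral hindlimb EMG from unilateral
motor-cortex ensembles across spinal-hemisection recovery.

## The problem

After a lateral spinal hemisection, the hindlimb on the lesioned side loses
most of its crossed corticospinal drive and walking collapses on that side;
over weeks, function partially returns. Chronic recordings taken while a
subject walks bipedally on a treadmill — sorted cortical spike trains from
the motor cortex opposite the lesion, multi-channel hindlimb EMG at 1 kHz,
and step annotations — make it possible to ask two quantitative questions:

1. **Encoding** — how much information does a cortical unit carry about a
   muscle's activation, and how does that change across lesion and
   recovery? Measured by the *maximal information coefficient* (MIC):

       MIC(D) = max_{r·m < B(n)}  I*(D, r, m) / log2 min(r, m)

   the maximal normalised mutual information over all r-by-m grid
   partitions of the paired sample D = {(r_i, m_i)}, with grid resolution
   bounded by B(n) = n^0.6. MIC is in [0, 1], symmetric, 1 for a noiseless
   functional relationship and 0 under independence, and captures
   nonlinear as well as linear dependence.

2. **Decoding** — can muscle activity be reconstructed from the population?
   Spike counts in 20 ms bins are square-root transformed, smoothed with a
   50 ms Gaussian, and stacked over a 200 ms lag window (p = 4 past, q = 5
   future bins). The decoder is ridge regression,
   `beta = (X'X + lambda I)^-1 X'y`, with lambda chosen in closed form as
   the smallest value capping the condition number of the penalised Gram at
   10^3. Performance is the variance accounted for,
   `VAF = 1 - SSE/SST`, under 5-fold blocked (contiguous) cross-validation.

Session-level statistics tie the two together: Kruskal-Wallis for the drop
at the lesion, Spearman rank correlation against day index for the
monotonic recovery trend.

Because such animal recordings are not publicly deposited, the package
ships a first-class synthetic generator that emulates the study's
structure — gait-phase-tuned Poisson units, burst-like EMG envelopes driven
by a unit-muscle coupling matrix, an abrupt side-asymmetric coupling drop
at a simulated lesion with gradual exponential recovery, declining unit
counts, run/rest walking behaviour and broadband artifacts — so the whole
chain is testable end to end. It is aimed at researchers in motor
neuroscience and BCI who want a reproducible reference implementation of
this analysis style.

## Worked example

```python
import numpy as np
from cortemg import GeneratorConfig, RunConfig, run_study

cfg = GeneratorConfig(seed=7, n_sessions=13, lesion_session=3,
                      session_duration=150.0, n_units_initial=12,
                      unit_dropout_rate=0.0)
result = run_study(RunConfig(generator=cfg, mic_max_n=400), out_dir="out")
tc = result.timecourse
for s in tc.sessions:
    print(f"{s.session_id}  day {s.day_index:+3d}  {s.phase:4s} "
          f"MIC {np.mean(list(s.mic_mean.values())):.3f}  "
          f"VAF {np.mean(list(s.vaf_mean.values())):+.3f}  "
          f"steps {s.total_steps:3d}")
rho, p = tc.mic_trend["RS"]
print(f"post-lesion MIC trend (RS):  rho = {rho:+.3f}, p = {p:.2g}")
rho, p = tc.vaf_trend["RS"]
print(f"post-lesion VAF trend (RS):  rho = {rho:+.3f}, p = {p:.2g}")
```

prints

```
S00  day -21  pre  MIC 0.299  VAF +0.723  steps 115
S01  day -14  pre  MIC 0.301  VAF +0.725  steps 118
S02  day  -7  pre  MIC 0.294  VAF +0.717  steps 117
S03  day +21  post MIC 0.225  VAF -0.310  steps  15
S04  day +28  post MIC 0.245  VAF +0.180  steps  26
S05  day +35  post MIC 0.252  VAF +0.316  steps  43
S06  day +42  post MIC 0.255  VAF +0.352  steps  35
S07  day +49  post MIC 0.274  VAF +0.499  steps  61
S08  day +56  post MIC 0.277  VAF +0.536  steps  61
S09  day +63  post MIC 0.277  VAF +0.581  steps  46
S10  day +70  post MIC 0.291  VAF +0.606  steps  66
S11  day +77  post MIC 0.278  VAF +0.619  steps  72
S12  day +84  post MIC 0.295  VAF +0.653  steps  72
post-lesion MIC trend (RS):  rho = +0.842, p = 0.0022
post-lesion VAF trend (RS):  rho = +0.952, p = 2.3e-05
```

Read it as the experiment would be read: before the lesion the unit
population carries a MIC of ~0.30 per muscle and the decoder explains ~72 %
of EMG variance. At the first post-lesion session (day +21) walking has
collapsed to 15 steps, MIC has dropped, and held-out prediction of the
(ipsilesional) right-side muscles is worse than predicting their mean
(negative VAF). Across the ten post-lesion sessions both measures rise
monotonically — the significant positive Spearman trends — without fully
regaining pre-lesion levels. `run_study` also writes tidy result tables
(`results.tsv`, per-session MIC matrices, `decoding.tsv`, `trends.json`)
and a machine-readable run log into the output directory.

## Layout

| module | contents |
|---|---|
| `cortemg.data` | containers (SpikeTrain, EMGTrace, GaitAnnotation, Session) and the delimited-text session layout |
| `cortemg.synthetic` | the multi-session study generator |
| `cortemg.preprocess` | spike extraction, ISI QC, EMG envelopes, artifact exclusion, step normalisation, step statistics |
| `cortemg.features` | binning, variance stabilisation, smoothing, lagged design |
| `cortemg.mic` | MIC: grid MI, exhaustive and DP search, bootstrap |
| `cortemg.decoder` | condition-capped ridge, VAF, blocked CV |
| `cortemg.recovery` | session summaries, Kruskal-Wallis, Spearman trends |
| `cortemg.pipeline` | end-to-end orchestration |
| `cortemg.cli` | command-line verbs |

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
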