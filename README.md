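# gaitmmse

Multiscale complexity analysis of muscle coactivation during gait.

Surface EMG recorded from many muscles at once carries information that
channel-by-channel analysis misses: how the muscles fire *together*.
`gaitmmse` quantifies that joint behaviour for gait data — e.g. comparing
children with cerebral palsy to typically developing controls — by
combining two multivariate tools:

- **MEMD** (multivariate empirical mode decomposition) decomposes all EMG
  channels jointly into intrinsic mode functions (IMFs) that are
  *mode-aligned* across channels, producing comparable per-channel scales.
  Six white-noise helper channels are added before decomposition to
  counter mode mixing (16 EMG channels → a 22-channel composite).
- **MSampEn** (multivariate sample entropy) scores the irregularity of a
  multichannel segment: with composite delay vectors X_m(i) built from all
  channels (m_k = 2, τ_k = 1 per channel by default),

      MSampEn(M, τ, r, N) = −ln( B^{m+1}(r) / B^m(r) ),

  where B^m and B^{m+1} are the fractions of vector pairs within Chebyshev
  distance r at m and m+1 points, self-matches excluded, and
  r = 0.2 × (sum of the raw per-channel SDs of the segment).

Scales are cumulative IMFs, c^n = Σ_{i=n}^{N} c_i: scale 1 is the raw
signal, higher scales successively remove the finest modes (default: 6
modes + residual = 7 scales).  Evaluating MSampEn per scale gives an
**MMSE curve** per gait cycle; 14 muscle-combination schemes (whole leg /
lower leg / thigh, full cycle / stance / swing, left / right) probe
different muscle groups and phases.  Cycle curves average into subject
curves, subject curves into group mean ± SD curves, and a mixed-design
repeated-measures ANOVA (scale within × group between, Bonferroni
post-hocs) tests group differences per scheme.

Gait cycles come from shank accelerometry: heel strikes are peaks in the
gravity-axis trace; a cycle spans consecutive ipsilateral strikes and the
intervening contralateral strike splits stance from swing.

A synthetic gait-EMG generator (phase-locked band-limited bursts on 8
named muscles per leg, tunable cross-muscle coupling, heel-strike
accelerometer pulses, full ground truth) drives the tests and examples.
See `docs/methods.md` for the model details and estimator fine print.

## Worked example

```python
from gaitmmse import (make_cohort, load_dataset, run_analysis, AnalysisConfig)

cohort = make_cohort({"control": 2}, "demo_cohort", master_seed=7, n_cycles=2)
dataset = load_dataset(cohort)          # detects heel strikes, builds cycles
result = run_analysis(dataset, config=AnalysisConfig(seed=7))

print(f"{len(result.cycle_curves)} cycle-level MMSE curves")
gs = result.summaries[(1, "control")]   # scheme 1: left leg, 8 muscles, full cycle
for sf, mu, sd in zip(range(1, 8), gs.mean, gs.sd):
    print(f"  scale {sf}: MSampEn = {mu:.3f} +/- {sd:.3f}")
```

Output:

```
56 cycle-level MMSE curves
  scale 1: MSampEn = 0.051 +/- 0.001
  scale 2: MSampEn = 0.043 +/- 0.004
  scale 3: MSampEn = 0.015 +/- 0.004
  scale 4: MSampEn = 0.001 +/- 0.000
  scale 5: MSampEn = 0.000 +/- 0.000
  scale 6: MSampEn = 0.000 +/- 0.000
  scale 7: MSampEn = 0.000 +/- 0.000
```

56 curves = 14 schemes × 2 subjects × 2 cycles per side.  The curve
decreases with scale factor and approaches zero by scale 7: the joint
irregularity of the 8 muscles lives almost entirely in the finest modes,
so successively removing them drains the entropy — the canonical MMSE
signature of broadband EMG.  (Entropy magnitudes shrink as more channels
enter a scheme, because the tolerance r sums all involved channels' SDs.)

The same pipeline is available from the shell:

```sh
gaitmmse simulate --profile spastic --cycles 12 --seed 7 --out subj01
gaitmmse segment  --emg subj01/emg.tsv --acc-left subj01/acc_left.tsv \
                  --acc-right subj01/acc_right.tsv --out cycles.tsv
gaitmmse analyze  --dataset demo_cohort --out results/
gaitmmse stats    --curves results/curves_subject.tsv --out anova.tsv
```

All interchange formats are tab-separated text; every run writes its
resolved configuration and a log beside its outputs.

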