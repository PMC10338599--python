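# plcalds

Detection and one-day-ahead forecasting of COPD symptom episodes from
multichannel personal environmental sensor streams, using probabilistic
latent component analysis (PLCA) over spectral template dictionaries combined
with a linear dynamic system (LDS) tracker.

## Who this is for

Researchers in remote health monitoring who want to test whether personal
air-pollution exposure (NO, CO, PM1, PM2.5, PM10), meteorology, activity and
daily peak expiratory flow can flag the onset, recovery (transient) and
offset of respiratory symptom episodes — and forecast them one day ahead —
without access to the original (non-public) cohort data. The package ships a
synthetic cohort generator with the statistical structure the method assumes
(episodic multi-label diaries coupled to lagged pollutant exposure, personal
peak-flow series that dip during lung-capacity episodes, whole-day coverage
gaps), so every stage can be exercised and validated end to end.

## The model

Sensor streams are summarised into a nonnegative feature tensor
`V[f, t]` with one frame per 8-day sliding window (1-day step). Writing
`P(t) = Σ_f V[f, t]` for the frame energy, the frames are modelled as a
mixture of fixed spectral templates:

```
3D:  P(f, t) = P(t) Σ_{s,a}   P(f|s,a)   P(s|t) P(a|s,t)
4D:  P(f, t) = P(t) Σ_{m,s,a} P(f|m,s,a) P(s|t) P(a|s,t) P(m|s,t)
```

with `s` the symptom class, `a ∈ {onset, transient, offset}` the temporal
state, and `m` the season (4D, population model). The dictionary `P(f|s,a)`
is built once from annotated training frames by KL-divergence NMF and then
held fixed; EM estimates the activations, with a sparsity exponent
`κ = 1.1` applied to the symptom masses in each M-step to lower the entropy
of `P(s|t)`. The detector output `P(s,t) = P(t) P(s|t)` is treated as a noisy
observation of a latent state that stacks per-symptom activation levels and
their velocities; transition and observation matrices are learned by least
squares from ground-truth-initialised training activations
(`Q = αI, R = βI` with `α = 0.2, β = 0.1`), and a forward Kalman filter
yields temporally smoothed symptom tracks. Decisions are cut at
per-(symptom, state) thresholds chosen on training frames by maximising
`TPR + (1 − FPR)` and scored with frame-wise F1.

## Worked example

```python
import plcalds as P

cfg = P.CohortConfig(n_participants=4, n_days=120, seed=11, coupling_strength=3.0)
cohort = P.generate_cohort(cfg)
print("coverages:", [round(r.coverage, 2) for r in cohort])

ecfg = P.ExperimentConfig(model="PLCA-LDS-3D", regime="personalised", seed=11)
report = P.run_experiment(ecfg, cohort)
print(report.summary().round(3))
```

prints

```
coverages: [0.55, 0.7, 0.85, 1.0]
            mean    std  count
target
offset     0.107  0.095     15
onset      0.079  0.078     15
overall    0.450  0.129     15
transient  0.298  0.156     15
```

The four participants span the coverage range seen in free-living cohorts.
Each row is the macro mean (± sd) frame-wise F1 over the 15 retained
(participant, symptom) pairs on test frames, one day ahead: whole-episode
presence is detected far better (0.45) than the exact onset/offset days
(~0.08–0.11), with the recovery period in between — the same ordering the
method exhibits on real cohort data, where single-day states are intrinsically
hard. `report.table` holds the per-participant long-format rows
(participant, symptom, target, precision, recall, f1, support).

The same pipeline is scriptable from the shell:

```bash
plcalds simulate --participants 4 --days 120 --seed 11 --out cohort/
plcalds run --config experiment.yaml --cohort cohort/ --out run/
```

## Documentation

`docs/methods.md` describes the model, the synthetic-data assumptions, every
tunable parameter with its default and rationale, and known limitations.
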