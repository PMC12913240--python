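# pairlg — paired-stimulus local–global auditory ERP study, in silico

Clinical assessment of auditory processing needs paradigms that elicit the
whole sequence of auditory event-related potentials — the obligatory
P1–N1–P2 complex, the mismatch negativity (MMN), the involuntary-attention
P3a and the voluntary-attention P3b — in a single session, with sensitivity
at the *individual* level rather than only in group averages.  The
paired-stimulus local–global design does this by nesting two levels of
regularity: acoustic deviance *within* a pair (local effect: S–F and S–T
pairs, where every pair starts with a 1000-Hz standard S) and pattern
violations *across* pairs (global effect: a train-deviant pair interrupting
a run of same-type pairs), presented once under active target counting and
once under passive listening.

`pairlg` is a tested, reusable implementation of that entire study with no
recorded data: it generates paradigm-exact stimulus schedules, simulates
64-channel EEG containing the hypothesized component structure, and runs
the full analysis battery —

* **paradigm** — schedules with exact composition (1380 pairs; 1350
  analyzed = 555 S–S + 540 S–F + 255 S–T; ≥3 intervening pairs between
  train deviants; 121/134 global-context split), BIDS-style events TSV I/O;
* **simulate** — Gaussian-component ERPs with frontocentral/centroparietal
  topographies on spatially correlated 1/f + alpha noise, online-reference
  (CPz) construction, paired active/passive cohorts;
* **preprocess** — 50-Hz notch → 1-Hz high-pass → 30-Hz low-pass
  (zero-phase FIR), mastoid re-reference, 250-Hz resampling, the five
  condition contrasts, matched ±100 µV rejection;
* **cluster** — paired sign-flip permutation testing with threshold-free
  cluster enhancement (TFCE), ≥2-adjacent-channel and ≥20-ms reporting
  filters, Fz/Pz representative summaries;
* **decoding** — 50-block averaging, windowed linear-SVM classification
  with stratified fivefold CV and the dual permutation significance
  framework (true-label vs shuffled-label distributions, 95th-percentile
  threshold);
* **sweep** — the 4×4 sensor-count × epoch-fraction factorial with
  Spearman/bootstrap inference;
* **pipeline** — one-config orchestration (`run_study`) with hash-based
  seed fan-out and full reproducibility.

## Worked example

```python
from pairlg import ParadigmConfig, generate_session

session = generate_session(ParadigmConfig(seed=1), condition="passive")
types = session.pair_types(analyzed_only=True)
print(len(types), types.count("SS"), types.count("SF"), types.count("ST"))
print(f"{session.duration_ms() / 60000:.1f} min")
```

prints

```
1350 555 540 255
39.2 min
```

— one session with the exact analyzed composition and a ~39-minute
duration.  A miniature end-to-end study (2 synthetic participants,
106-pair sessions):

```bash
pairlg run-all --scale unit --seed 0 --out results/unit
```

```
      Local_ST            active: 2/2 detected, mean accuracy 0.78
      Local_ST           passive: 0/2 detected, mean accuracy 0.53
        P1N1P2            active: 1/2 detected, mean accuracy 0.69
        P1N1P2           passive: 0/2 detected, mean accuracy 0.51
```

(abridged; one row per contrast × condition)

Each row is one contrast × condition: how many synthetic participants'
mean cross-validated accuracy exceeded the 95th percentile of their
shuffled-label null, and the cohort-mean accuracy.  At this toy scale only
the strongest effects (e.g. the MMN–P3a complex of Local_ST) reach
detection; the numbered scripts under `analysis/` run the same stages at
the larger smoke scale, where group-level clusters recover the injected
component windows (e.g. an MMN cluster at ~120–168 ms and a P3a cluster at
~216–300 ms for Local_ST) and the sweep attributes active-passive
discrimination to epoch count rather than sensor count.

The `analysis/` directory is the study as a narrative: `01` schedule
combinatorics, `02` cohort simulation and trial accounting, `03` group
cluster statistics, `04` individual sensitivity (Table-style detection
counts), `05` the sensor × epoch sweep.  Each writes its tables under
`results/`.

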