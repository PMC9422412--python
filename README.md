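# cisim — intraoperative ECochG simulation and CI insertion morphometry

`cisim` is a research toolkit for studying **hearing preservation during
cochlear implantation** in the guinea-pig model.  It reproduces, as tested
and reusable code, the two analysis arms of an intraoperative
electrocochleography (ECochG) experiment:

1. **Electrophysiology.**  Extracochlear compound action potentials (CAPs)
   are recorded at the round window in three surgical conditions —
   baseline, after cochleostomy, and after electrode insertion — on a
   2–32 kHz (4 steps/octave) × 0–90 dB SPL (10 dB steps) × two-polarity
   stimulus lattice.  The offline chain averages condensation and
   rarefaction responses (cancelling the cochlear microphonic), band-passes
   200 Hz–5 kHz (zero-phase 6th-order Butterworth), measures the N1–P1
   peak-to-peak amplitude in the 0–10 ms window, and calls threshold at the
   lowest level whose response is at least twice the pre-stimulus baseline
   amplitude.  Threshold shifts (TS, post − pre) and suprathreshold
   amplitude changes at 50/60/70 dB SPL quantify insertion trauma; paired
   Wilcoxon, Mann–Whitney (exact for small n) and OLS regressions provide
   the group statistics.
2. **Morphometry.**  A conical logarithmic spiral models the basilar
   membrane (18.5 mm arc length, 4.25 turns).  Electrode contacts
   (6 contacts, 700 µm spacing, 4.5 mm tip-to-last-contact) are converted
   into arc-length insertion depth, percent of basilar-membrane length, and
   insertion angle relative to the summit-point/mid-modiolar-axis
   reference; the species place-frequency scaling (2.59 mm/octave, or the
   full Greenwood form `f = A(10^{ax} − k)`) maps depth to characteristic
   frequency.

Because no raw recordings are deposited for such experiments, the package
includes a first-class, seeded **synthetic cohort generator** with known
ground truth: CAP waveforms grow at `cap_gain` µV per dB above threshold,
trauma is injected as a rising logistic threshold shift in log-frequency
(deep 6-contact insertions larger and broader than shallow 5-contact ones,
sparing ≤ 4 kHz), and every estimator can be validated against what was
injected.

## Worked example

Insertion morphometry for a deep (6-contact) insertion whose apical
contact sits at the deep-group mean depth:

```bash
cisim geometry --tip-depth 6339.56 --out metrics.json
```

```json
{
  "depth_ch1_um": 5339.560013080029,
  "depth_reference_um": 5339.560013080029,
  "endpoint_convention": "apical_contact",
  "insertion_angle_deg": 206.31835546199025,
  "lowest_cf_hz": 8048.852655745657,
  "n_contacts_in": 6,
  "percent_bm": 28.86248655718935
}
```

The apical contact lies 5.34 mm along the basilar membrane (28.9% of its
length), 206° around the modiolar axis — below the ~270° ceiling of
optimal deep implantations — and the electrode tip reaches the cochlear
place tuned near 8.0 kHz: frequencies below that remain acoustically
usable if the insertion caused no trauma.

Simulating and analysing the default calibrated 24-ear cohort from Python:

```python
from cisim import CohortConfig
from cisim.cap_pipeline import simulate_and_analyze, ear_max_ts

truths, cohort = simulate_and_analyze(CohortConfig(), master_seed=1)
summary = ear_max_ts(cohort.shifts)
print(summary.groupby("group")["max_ts_db"].agg(["mean", "sem", "count"]).round(2))
```

```
        mean   sem  count
group
5Ch     3.33  2.25     12
6Ch    29.17  3.79     12
```

Per-ear maximal threshold shifts recovered end-to-end by the CAP pipeline:
deep insertions cause substantially more high-frequency hearing loss than
shallow ones (this seed drew an unusually quiet shallow group; the
generator's calibration targets are 23 and 10 dB).  The same pipeline is
available from the shell as `cisim simulate`, `cisim analyze` and
`cisim report`, which write per-ear recording bundles and tidy CSV tables
(thresholds, shifts, contrasts) with an embedded configuration hash.

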