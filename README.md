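# saccsync

Analysis toolkit for **spontaneous temporal grouping of synchronized
saccades**: when a subject tracks a visual target that steps at a fixed
interval (SOA) around six landmarks on a circle, the timing of the eye
movements is not perfectly uniform — inter-saccadic intervals (ISIs) are
modulated by the absolute target location, the motion direction, and, most
interestingly, by a task-irrelevant rectangular contour (the *inducer*)
covering three of the six landmarks.  Delays locked to the position of a
target *relative to the inducer* reveal that the sequence of movements is
spontaneously segmented into chunks.  `saccsync` is aimed at oculomotor /
sensorimotor-synchronization labs that want to simulate this paradigm,
extract saccade events from gaze traces, and quantify inducer effects with
calibrated resampling statistics.

The package provides:

* **Paradigm simulation** (`saccsync.paradigm`, `saccsync.simulate`) — six
  landmarks 7° from the screen centre (so neighbours are also 7° apart),
  target stepping every 400/600 ms for 12 s (30/20 steps), deterministic
  inducer-presence cycles reproducing the published 6-of-7 (monkey) and
  66-of-100 (human) trial splits, and named latency phenotypes
  (`NULL`, `BOUNDARY_DELAY_3`, `MIDDLE_DELAY_2`, `INSIDE_SLOW`) emulating
  the qualitative grouping patterns seen across subjects.  Continuous gaze
  traces can be rendered for detector validation.
* **Event extraction and filtering** (`saccsync.preprocess`) — saccade
  onsets at the 50 °/s angular-velocity criterion, landmark assignment
  within a 3° capture radius, latency/ISI computation, the predictive and
  reactive exclusion rules, and sorting of ISIs by relative target
  location (In1–In3 inside the inducer, Out1–Out3 outside).
* **Inducer statistics** (`saccsync.vectorstats`, `saccsync.decomposition`)
  — the two resultant-vector statistics with label-shuffling permutation
  nulls, the category-mean mean-squares decomposition
  (MS_seq, MS_io, MS_int, normalized to sum to 1) with ternary-plot
  coordinates, and a classical two-way ANOVA on individual ISIs.

## The statistics in brief

For a session's labelled ISIs, write the six category means
m(In₁)…m(Out₃).  The **sequence statistic** arranges the six vectors at
equal intervals — Inₖ and Outₖ share direction θₖ, with θ₁, θ₂, θ₃ 120°
apart — and sums them; constants cancel, so the resultant's length measures
how strongly ISI depends on sequence position after the inducer boundary
and its angle points at the delayed position.  The **inside–outside
statistic** aligns In and Out means in opposite directions, giving the
signed value Σm(Inₖ) − Σm(Outₖ) (> 0 ⇒ slower inside).  Significance comes
from shuffling the relative-location labels over individual ISIs
(1000 permutations by default): one-sided at the 95th percentile of null
lengths for the sequence mode, two-sided against the middle 95% for the
inside–outside mode.

The mean-squares decomposition works on the 3 × 2 grid of cell means
X̄ᵢⱼ (sequence i = 1..3 × inside/outside j):

    MS_seq = ½ Σᵢ (X̄ᵢ. − X̄)²      MS_io = Σⱼ (X̄.ⱼ − X̄)²
    MS_int = ½ [ Σᵢⱼ (X̄ᵢⱼ − X̄)² − SS_seq − SS_io ]

normalized so MS_seq + MS_io + MS_int = 1 and plotted in a ternary
triangle; the dominant component classifies the session's grouping style.

## Worked example

Simulate a human-style session (100 trials, inducer on 66, 600-ms SOA)
from a subject who pauses just before crossing the inducer boundary, then
run the full analysis:

```python
import saccsync as sc

schedule = sc.make_schedule(100, "human_2_of_3", 600, seed=7)
events = sc.sample_session(schedule, sc.get_phenotype("BOUNDARY_DELAY_3"), seed=8)
model = sc.InducerEffectModel.from_events(events, condition="predictive")
results = model.fit(n_perm=1000, seed=9)
print(results.summary())
```

```
Inducer-effect session summary
==============================================================
labelled ISIs: 990    permutations: 1000    seed: 9

Mean ISI by relative target location (ms)
  category      n      mean       sd
       In1    160     549.9      7.9
       In2    164     599.5      7.5
       In3    163     649.7      7.6
      Out1    170     548.9      7.4
      Out2    166     599.9      7.3
      Out3    167     650.7      7.4

sequence resultant: length   174.50 ms  angle  300.1 deg  location 3  p = 0.0010*
inside-outside:        -0.29 ms (outside slower)  p = 0.9690

normalized mean squares: seq 1.000  io 0.000  int 0.000  -> dominant: sequence

two-way ANOVA (individual ISIs, type-II SS)
          effect    df         F          p
        sequence     2  14784.34   0.00e+00
  inside_outside     1      0.04   8.37e-01
     interaction     2      1.44   2.37e-01
        residual   984
```

Reading the output: the interval ending at the third relative location is
~50 ms longer than baseline (and the following interval correspondingly
shorter, since the next saccade re-synchronizes), so the summed vector
points at location 3 with a length far beyond the permutation null
(p ≈ 0.001); the inside–outside contrast is null; and essentially all
between-category variance loads on the sequence factor — a
"boundary-delay" subject.

The same pipeline is scriptable from the shell:

```bash
saccsync full --seed 7 --n-trials 100 --pattern human_2_of_3 \
    --phenotype BOUNDARY_DELAY_3 --out runs/demo
```

which writes `events.csv`, `schedule.csv`, `manifest.json`,
`isi_table.csv`, `results.json` and `summary.txt`; identical configurations
produce byte-identical files.  Real recordings enter the pipeline as CSV
event tables with the documented header (see `saccsync.io.EVENT_COLUMNS`)
via `saccsync analyze --events ...`.

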