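# emgchrono

EMG-based decomposition of two-choice reaction times into premotor and
motor components, with covert partial-error detection and conditional
accuracy analysis.

## The problem

In a two-choice task (here: lexical decision with one response hand per
choice, run under neutral, accuracy-stressed and speed-stressed
instruction regimes), the button-press reaction time conflates two very
different stages.  Surface EMG from the two thenar eminences lets you
split each trial at the muscle-activation onset:

* **PMT** (premotor time): stimulus onset → EMG burst onset of the
  responding hand — pre-motor processing;
* **MT** (motor time): EMG onset → button press — motor execution;
  `RT = PMT + MT` by construction.

The non-responding hand's channel additionally reveals **partial
errors**: covert activations of the incorrect hand that are caught and
corrected before a press, the signature of online response control.
From these, the package builds **CAFs** (conditional accuracy functions:
accuracy across RT quantiles), **CIAFs** (proportion of incorrect EMG
activations — overt plus partial errors — across pooled latency
quantiles), correction likelihood, and amplitude/rising-flank-slope
metrics of onset-locked EMG curves.

It is aimed at researchers in psycholinguistics and response-control
psychophysiology who want the full measurement chain — from continuous
recordings to model-ready trial tables — as tested, scriptable code,
plus a ground-truth synthetic generator to validate every stage.

## The measurement chain

1. **Filtering**: 10-Hz order-2 Butterworth high-pass (zero-phase) and a
   50-Hz notch on the continuous recording.
2. **Epoching**: stimulus-locked epochs from −500 ms to the condition's
   response deadline + 1000 ms (neutral 2500 / speed 1800 / accuracy
   6000 ms post-stimulus).
3. **Onset detection** (integrated profile): with `c_i = Σ_{j≤i} |x_j|`
   and the chord `L_i = c_0 + (c_{n−1} − c_0)·i/(n−1)`, the burst onset
   is `argmin_i (c_i − L_i)`.
4. **Activity windows**: samples with `|x|` above baseline mean + 3.5 SD
   (baseline = [−500, 0) ms); runs merged across gaps < 25 ms; windows
   < 50 ms or starting after the press discarded.  An onset is valid
   only if it falls inside the last window before the press — the
   automatic stand-in for visual epoch screening.
5. **Covert activations**: the same rules on the non-responding channel
   yield partial errors (correct trials) / partial corrects (overt-error
   trials), with their own integrated-profile latencies.
6. **Outputs**: per-trial decompositions (`trials.tsv`), CAF/CIAF tables
   with equal-count quantile bins, per-cell descriptive rates,
   onset-locked curve metrics, and a model-ready long table with
   orthogonal quantile polynomials for external (G)LMM fitting.
   Within-participant CI half-widths (Cousineau–Morey) and the
   BIC-based Bayes-factor approximation `exp(ΔBIC/2)` are provided for
   summarizing such fits.

## Worked example

```python
from emgchrono import GeneratorSpec, generate_dataset, run_arrays

spec = GeneratorSpec(n_participants=2, trials_per_cell=25)
recordings, events, truth = generate_dataset(spec, seed=7)
results = run_arrays(recordings, events)

trials = results["trials"]
print(trials["trial_class"].value_counts().to_string())
```

```
trial_class
pure_correct             279
partial_error_trial        9
overt_error                6
excluded                   3
partial_correct_trial      3
```

Of 300 simulated trials, 279 end in a clean correct press, 9 carry a
covert incorrect-hand activation that was corrected online, 6 are overt
errors, and 3 epochs fail onset validation (1%, emulating the ~2%
visual-screening loss of real recordings).  The trial table holds the
decomposition:

```python
print(trials[["participant", "trial", "sat", "lexicality",
              "rt_ms", "pmt_ms", "mt_ms", "trial_class"]].head(5))
```

```
participant  trial     sat lexicality      rt_ms  pmt_ms      mt_ms         trial_class
        p01      1 neutral       word 593.591401   481.0 112.591401 partial_error_trial
        p01      2 neutral pseudoword 676.315153   529.0 147.315153        pure_correct
        p01      3 neutral       word 662.108525   518.0 144.108525        pure_correct
        p01      4 neutral pseudoword 549.514164   434.0 115.514164        pure_correct
        p01      5 neutral       word 677.839617   543.0 134.839617        pure_correct
```

PMT and MT sum to RT on every retained trial.  Cell summaries show the
expected speed–accuracy pattern (lower accuracy and more covert errors
under speed pressure):

```
          accuracy  partial_error_rate
sat
accuracy      0.98               0.022
neutral       0.99               0.041
speed         0.94               0.032
```

The same run can be driven from the shell:

```bash
emgchrono simulate --config sim.yaml --seed 7 --out data/
emgchrono run --recording-dir data/ --events data/events.tsv --out results/
```

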