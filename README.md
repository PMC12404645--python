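# maskmvpa

Multivariate decoding, time-frequency and representational-similarity
analysis for backward-masking EEG/fMRI experiments.

## The problem

Visual recognition rests on a fast feedforward sweep through the
ventral stream followed by recurrent processing. Backward masking
dissociates the two: an *early* mask (target–mask ISI ≈ 17 ms)
interrupts recurrence while sparing the feedforward volley, a *late*
mask (ISI ≈ 600 ms) leaves both intact. Contrasting multivariate object
decoding between the two masking conditions therefore isolates the
signal contributed by recurrent processing — in time (EEG decoding and
temporal generalization), in space (fMRI ROI and searchlight decoding),
in representational format (RSA against layered model geometries with
noise ceilings and commonality analysis), and in the spectral domain
(Morlet power and phase decoding).

`maskmvpa` is the complete analysis machinery for such experiments,
built for analysts who want every stage testable: a synthetic-data
generator emulates the experimental design (24 objects × 2 masking
conditions, 53 EEG trials per cell on 64 channels, −200…800 ms epochs;
12 fMRI runs × 2 presentations per condition), so the whole chain is
verified against planted ground truth without any real recordings.

## The core statistic

At each time point (or ROI, voxel sphere, time–frequency bin), object
identity is decoded pairwise with linear SVMs on pseudo-trials — random
averages of 4 bins of trials — using leave-one-pseudo-trial-out
cross-validation, repeated 100 times with fresh assignments. The
accuracies form a symmetric K×K matrix A (diagonal undefined); its
off-diagonal mean is the grand-average accuracy (chance 50%), and A
itself is the neural RDM for RSA. Cross-condition decoding (train on
one masking condition, test on the other, both directions averaged)
tests whether the representational geometry is shared. Group inference
uses sign-permutation tests (10,000 flips), cluster-size correction
over contiguous grids (CDT p < 0.005, cluster p < 0.05), FDR for small
families, bootstrap peak CIs, and paired peak-shift tests with
Hedges' g. See `docs/methods.md` for the full model description.

## Worked example

Simulate a small group, decode within each masking condition, and test
whether late-mask decoding exceeds early-mask decoding in the window
where recurrent processing should dominate:

```python
import numpy as np
from maskmvpa import (DesignSpec, GroundTruth, simulate_eeg_dataset,
                      baseline_correct, mnn_whiten, decode_timecourse,
                      sign_perm_test)
from maskmvpa.design import NoiseModel

design = DesignSpec(n_objects=6, trials_per_cell=12, n_channels=32,
                    tstep_ms=40.0, n_subjects=6)
truth = GroundTruth(noise=NoiseModel(scale=3.0))
subjects = simulate_eeg_dataset(design, truth, seed=0)

curves = {}
for scheme in ("within-early", "within-late"):
    per_subj = []
    for s in subjects:
        e = mnn_whiten(baseline_correct(s))
        per_subj.append(decode_timecourse(e, scheme, n_reps=2,
                                          rng=0).grand_average())
    curves[scheme] = np.stack(per_subj)

t = subjects[0].time_ms
for scheme, c in curves.items():
    mean = c.mean(axis=0)
    print(f"{scheme}: peak {mean.max():.1f}% at {t[mean.argmax()]:.0f} ms")
diff = curves["within-late"] - curves["within-early"]
late_win = (t >= 300) & (t <= 600)
p = sign_perm_test(diff[:, late_win].mean(axis=1), n_perm=10000, rng=1)
print(f"late > early (300-600 ms): mean difference "
      f"{diff[:, late_win].mean():.1f} points, p = {p:.4f}")
```

Output:

```
within-early: peak 99.8% at 120 ms
within-late: peak 100.0% at 120 ms
late > early (300-600 ms): mean difference 36.5 points, p = 0.0149
```

Both conditions decode perfectly around the feedforward peak (~120 ms),
but only the late-mask condition sustains decoding through the
recurrent window — the 36-point difference at 300–600 ms is the
signature of recurrent processing that the generator planted
(`amplitude_by_mask = {"early": 0.2, "late": 1.0}`) and the pipeline
recovers, significant by sign-permutation test across the six simulated
subjects.

## Command line

A thin CLI wraps the library:

```sh
maskmvpa simulate --seed 1 --out sim/
maskmvpa preprocess sim/sub-00_epochs.h5 prep.h5
maskmvpa decode prep.h5 --scheme cross --reps 100 --seed 1 --out acc.tsv
maskmvpa tfr prep.h5 tfr.h5
maskmvpa select evc.tsv it.tsv -k 24 --out subset
maskmvpa run --config run.yaml --out results/
```

Epochs and TFR sets travel as HDF5 (`/data`, `/labels/object`,
`/labels/mask`, `/time_ms`, `/channels`), RDMs as square TSV,
volumetric maps as NIfTI-1, configurations as YAML.

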