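# rest2task

Zero-training translation of EEG spatial filters from the resting state to
motor-imagery classification.

Motor-imagery brain-computer interfaces (BCIs) detect the event-related
desynchronization (ERD) of the sensorimotor mu (~10 Hz) and beta (~20 Hz)
rhythms that accompanies imagined hand movements: left-hand imagery
suppresses the rhythm over the right motor cortex and vice versa.  Spatial
filters — weight vectors **w** over the electrodes whose product **w x**(t)
with the multichannel EEG isolates a single source — dramatically improve
the signal-to-noise ratio of these rhythms, but the standard supervised
filters (common spatial patterns, CSP) need a labeled calibration session
for every user and every day.

`rest2task` implements an unsupervised alternative for researchers working
on calibration-free BCIs.  Because the mu/beta generators in sensorimotor
cortex are spatially stable across mental states, the independent-component
decomposition of a few minutes of *unlabeled resting* EEG already contains
the motor spatial filters.  The package:

1. decomposes resting EEG with PCA (to 15 dimensions) + ICA, giving spatial
   filters **W** (rows) and scalp patterns (columns of the generalized
   **W**⁻¹);
2. identifies the left/right motor components automatically: components
   whose equivalent-dipole fit leaves more than 20 % residual variance are
   rejected, the survivors are ranked per hemisphere on template-dipole
   distance, template-pattern correlation, and mu/beta power ratio
   (10–15 Hz over 15–20 Hz), and the ranks are combined into a motor index

       f = 3 · I_dist + 1 · I_corr + 2 · I_ratio

   with the smallest f winning each hemisphere (f = 6 is the best possible
   score);
3. applies the rest-trained filters to single imagery trials and classifies
   left vs right hand from two band-power (8–30 Hz) features with Fisher
   discriminant analysis — or with a fully zero-training rule that compares
   the two component powers after dividing by their resting-state means;
4. benchmarks against monopolar C3/C4 band power, imagery-trained ICA,
   fold-trained CSP, and session-to-session filter transfer.

A seeded simulator provides sessions with known ground truth: dipolar
mu+beta sources under C3/C4 (contralateral ERD −0.5, ipsilateral ERS
+0.15), a strong lateralized posterior alpha confound, a frontal
low-frequency artifact and sensor noise, mixed through an analytic
single-sphere head model.

## Worked example

```sh
python examples/02_motor_index_worked_example.py
```

scores the bundled 15-component reference table (dipole residual variance,
power ratio, and per-hemisphere template distance/correlation) and prints:

```
rejected (RV > 20%): [11, 12, 13, 15]
selected left motor component:  5 (f = 6)
selected right motor component: 7 (f = 8)
```

Component 5 is rank 1 on all three left-hemisphere criteria
(f = 3·1 + 1·1 + 2·1 = 6); component 7 wins the right hemisphere with
f = 3·1 + 1·1 + 2·2 = 8.  The other examples simulate full sessions:
`03_rest_to_task_classification.py` shows rest-trained filters classifying
within a few points of imagery-trained ones while both beat the monopolar
baseline, and `04_zero_training_classifier.py` shows the resting-power
weighting rescuing the sign rule on a hemispherically asymmetric subject
(65.8 % → 90.0 % in the shipped configuration).

A thin CLI wraps the same stages:

```sh
rest2task simulate --out session/ --seed 1
rest2task run-rest2task --recording session/recording.txt \
    --events session/events.tsv --montage session/montage.sfp --out report/
```

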