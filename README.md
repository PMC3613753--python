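# alffconn

Does the *amplitude* of a brain region's spontaneous BOLD fluctuations
shape how strongly that region appears functionally connected to the rest
of the brain? `alffconn` is a tested, reusable pipeline for answering that
question with resting-state fMRI: it computes the amplitude of
low-frequency fluctuations (ALFF, 0.01–0.08 Hz) and two families of
connectivity measures — group spatial ICA network strengths and
spherical-ROI correlation matrices — and then correlates them *across
subjects*, voxel by voxel and ROI by ROI. It is aimed at researchers who
study resting-state connectivity and need ALFF either as a variable of
interest or as a confound to control.

Because suitable multi-subject datasets are rarely shareable, the package
ships a synthetic cohort generator that plants sign-controlled coupling
between regional amplitude and connectivity, so every stage of the pipeline
is verifiable against ground truth.

## The statistics

For subject i, voxel v, the detrended BOLD series x(t) gives

    ALFF_v = mean over band bins of 2|X_k|/T,   0.01 ≤ f_k ≤ 0.08 Hz,

normalized by the whole-brain mean. Functional connectivity is Pearson
correlation, Fisher-z transformed: z = atanh(r). The core inter-subject
statistics are

* **voxel-matched coupling** — at each voxel, corr_i(IC strength_iv,
  ALFF_iv) across the N subjects, where IC strength is the subject's
  dual-regression back-reconstructed component map;
* **ROI coupling** — entry (j, k) is corr_i(ALFF_ij, z_i(j,k)): a region's
  amplitude against its own edges, an intentionally *asymmetric* matrix;
* **hubs** — ROIs whose ALFF couples significantly (|r| above the exact
  two-tailed p < 0.001 threshold, r* = t*/√(t*²+df), df = n−2) to more than
  30 of their edges, tallied by sign;
* a Monte-Carlo **cluster-extent threshold** for smoothed Gaussian null
  fields (26-connectivity).

Preprocessing follows the standard recipe: discard 2 volumes, regress out
6 motion parameters + 5 white-matter + 5 CSF principal components, smooth
at 8 mm FWHM.

## Worked example

Simulate a 79-subject cohort with one planted positive mechanism (a
12-ROI network whose per-subject gain varies, raising amplitude and
connectivity together) and one planted negative mechanism (a
physiological-noise hotspot at one ROI of a second network), then run the
whole analysis:

```sh
alffconn run-all --seed 3 --out results/demo --cohort recovery --n-subjects 79
```

prints

```
coupling threshold |r| > 0.3633; hubs: 23 positive, 1 negative
```

and `results/demo/hubs.tsv` begins

```
label    network  sign  count
netA_00  netA     1     11
netA_01  netA     1     11
...
```

Reading: at N = 79 the exact two-tailed p < 0.001 threshold on an
inter-subject Pearson correlation is |r| > 0.3633. All twelve planted
network-A ROIs surface as positive hubs (their amplitude drives their
edges), the noise-hotspot ROI surfaces as the sole negative hub, and the
extra positive hubs are network-B peers picked up through a real
finite-sample mechanism (shared realized signal energy moves amplitude and
correlation together) — see `docs/methods.md`. The output directory also
contains the full coupling matrix, the signed thresholded matrix, per-ROI
ALFF, the planted ground truth, and BrainNet-style `.node`/`.edge` files.

The same stages are available individually (`simulate`, `preprocess`,
`alff`, `ica`, `connectivity`, `couple`, `cluster-thresh`) and as library
functions (`alffconn.compute_alff_map`, `alffconn.roi_alff_coupling`, …).

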