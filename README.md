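# neuroband

Individually anchored EEG band-power biomarkers with companion neuroimaging
statistics, plus synthetic-data generators so every stage is testable without
any external dataset.

The package implements one analysis pipeline in five stages:

1. **spectral** — resting multichannel EEG → consecutive 2-s epochs →
   Hann-windowed Welch periodograms averaged over epochs and channels →
   one channel-collapsed power spectrum per subject (0.5 Hz bins, 2–45 Hz),
   with a head-vs-tail spectral stability (stationarity) control.
2. **bands** — detection of the individual alpha frequency (IAF; power
   maximum in 5–14 Hz) and the theta/alpha transition frequency (TF; power
   minimum below the alpha peak), construction of the eight per-subject
   frequency bands anchored on TF/IAF (plus beta/gamma peaks and
   boundaries), relative band powers normalized by the 2–45 Hz mean, and
   the **alpha3/alpha2 ratio** (upper-alpha over upper-low-alpha relative
   power).
3. **stratify** — low / middle / high alpha3/alpha2 group assignment
   (fixed cutoffs 1.0 and 1.17, or empirical tertiles) and group
   demographics comparisons (ANOVA, χ², Levene-selected Games-Howell or
   Bonferroni post hoc).
4. **wmh** — white-matter-hyperintensity segmentation of FLAIR-like volumes
   by a Gaussian intensity model (threshold mean + 3.5 SD), lesion
   volumetry (voxel count × voxel volume), and T1 intensity correction of
   lesion voxels from the surrounding normal-tissue shell.
5. **morphostats** — vertex-wise cortical-thickness GLM (group indicator +
   age, sex, education, MMSE, WMH covariates), cluster-extent thresholding
   (p < 0.001 uncorrected, ≥30 mm² for contrasts, ≥15 mm² for correlation
   maps), total atrophy extent, and within-group thickness–memory Pearson
   correlation maps.

The **synth** module generates seed-deterministic synthetic EEG (1/f
background, planted TF trough, Gaussian alpha peak with calibratable
upper/low-alpha shoulders), cohorts with target alpha3/alpha2 group
structure (18/38/18), lesion volumes with known truth masks, and thickness
datasets with planted group effects and memory correlations.

## Command line

```sh
# spectrum from an EDF or delimited-text recording
neuroband psd --input rec.edf --out spectrum.csv

# anchors, individual bands, relative powers, alpha3/alpha2
neuroband bands --spectrum spectrum.csv --out bands.json

# group assignment on a cohort table
neuroband stratify --cohort cohort.csv --mode fixed

# WMH segmentation and lesion volume
neuroband wmh --flair flair.nii.gz --mask brain.nii.gz --k 3.5 --voxel-volume 1.44

# vertex-wise group contrast and correlation maps on a thickness dataset dir
neuroband glm --dataset d/ --contrast high,low --p 0.001 --min-area 30 --out clusters.csv
neuroband correlate --dataset d/ --score babcock --group high --out corr.csv

# synthetic data with ground truth sidecars
neuroband simulate eeg|cohort|volume|thickness --seed 1 --out sim/

# full synthetic end-to-end run (three contrasts + three correlation maps)
neuroband run --seed 1 --out run/
```

Text formats: EEG as CSV (one row per sample, header = channel labels) or
EDF; spectra, cohorts, surfaces (vertex id, area, neighbor list) and
cluster reports as CSV; volumes as NIfTI; configuration as YAML
(`RunConfig.to_yaml` / `from_yaml`); epoch masks as a text file of retained
0-based epoch indices.

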