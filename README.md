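# threatflow

Analysis toolkit for safe/threat block-design neuroimaging experiments, with
a synthetic-cohort generator so every stage can be validated against known
injected effects. Three arms:

- **fMRI** — per-condition global brain connectivity (GBC: per-voxel mean
  Fisher-Z correlation with every other in-mask voxel), seed-based follow-up
  connectivity, motion/shock censoring with motion-matched safe censoring,
  nuisance regression, within-mask smoothing, and Monte-Carlo cluster-size
  thresholds matched to a fitted Gaussian-plus-mono-exponential spatial ACF.
- **MEG** — epoch conditioning (detrend, 90 Hz low-pass, 60 Hz notch,
  decimation to 300 Hz), muscle-artifact rejection, multitaper (Slepian)
  spectra, individual-alpha-frequency detection with cohort-mean fallback,
  IAF-band power, sign-flip permutation cluster-mass tests over sensors, and
  a DICS beamformer (single-sphere Sarvas forward model, common spatial
  filter, per-condition source power).
- **Physiology** — startle-EMG scoring (band-pass, rectify, 20 ms smoothing,
  peak in the 20–100 ms window), within-subject T-scoring, condition means,
  anxiety-potentiated startle (APS), and continuous anxiety-rating summaries.

The `synthio` subpackage generates cohorts with the block structure of the
paradigm (alternating 2-min safe/threat blocks, startle probes at 6–14 s
intervals, rare shocks confined to threat blocks) and returns the injected
ground truth (hub voxels, Δcorrelation, per-subject alpha frequencies, alpha
modulation, startle multipliers) for recovery testing.

## CLI

```sh
threatflow simulate fmri --seed 1 --out out/      # NIfTI + confounds TSV
threatflow simulate meg  --seed 1 --out out/      # HDF5 epoch container
threatflow simulate emg  --seed 1 --out out/      # EMG + events TSV
threatflow run all --seed 1 --out out/            # full report bundle
threatflow run meg --seed 1 --n-perm 500 --voxel-p 0.005 --alpha 0.05
threatflow report --results out/results.json
```

Runs are reproducible: identical config + seed produces byte-identical
`results.json` (provenance hash and seed are embedded in every report).

A YAML config can replace the CLI flags (`--config run.yaml`); top-level
keys `arm, seed, out_dir, voxel_p, alpha, n_perm, n_iter, lam` plus `fmri:`,
`meg:`, `emg:` blocks mirroring `FmriSimConfig`, `MegSimConfig`,
`EmgSimConfig`.

## Layout

```
src/threatflow/
  synthio/            cohort generators (schedules, fMRI, MEG, EMG, file I/O)
  fmri_conn.py        censoring, nuisance regression, smoothing, GBC, seed maps
  cluster_inference.py ACF fit, Monte-Carlo cluster thresholds, permutation tests
  meg_spectral.py     preprocessing, artifact rejection, multitaper, IAF
  dics_source.py      spherical forward model, CSD, DICS filters, source power
  physio.py           startle scoring, T-scores, condition summaries
  stats_core.py       Fisher Z, paired t, Pearson r, ANCOVA, within-subject SEM
  pipeline.py, cli.py orchestration and command line
```
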