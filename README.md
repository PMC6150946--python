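# opmlat

Simulation and analysis pipeline for wearable-magnetometer (OPM) language
lateralisation: generate on-scalp magnetometer recordings containing a
lateralised beta-band (15–30 Hz) desynchronizing source, clean them with
reference-array synthetic gradiometry, characterize the sensor-level
spectral response, localize the source with a scalar LCMV beamformer, and
quantify hemispheric dominance with threshold-indexed laterality curves.

No real recordings ship with this package; everything runs on synthetic
data whose ground truth is known, which is what makes the recovery
experiments in the test suite possible.

## What is implemented

| module | contents |
| --- | --- |
| `opmlat.geometry` | sensor arrays (TSV/JSON), least-squares conductor-sphere fit, volumetric source grids with ball ROIs, stand-in 26+4 helmet generator |
| `opmlat.forward` | analytic current-dipole-in-a-sphere forward model (radial projection), lead-field sets, HDF5 export |
| `opmlat.simulate` | trial-epoched synthetic recordings: band-limited stochastic source with task-locked amplitude envelope, rank-limited environmental interference (drifts + 50/77 Hz lines) shared with the reference array, white sensor noise, ±1.5 nT range flagging |
| `opmlat.dataset` | HDF5 trial container with provenance log and bit-exact round trips |
| `opmlat.preprocess` | anti-aliased decimation (1000→200 Hz), zero-phase 50 Hz notch and 75–79 Hz band-stop, per-trial Moore–Penrose reference regression (synthetic gradiometry) |
| `opmlat.spectral` | sliding-window Slepian multitaper spectrograms, percent change from rest, trial-bootstrap SE with corrected significance, max-modulated-sensor selection |
| `opmlat.beamformer` | scalar LCMV with max-power orientation (silent radial direction excluded), active-vs-baseline F maps with BH-FDR, bootstrap confidence volumes (2×SD of peak locations), virtual-channel time courses, TSV/NIfTI export |
| `opmlat.laterality` | LI(τ) = (countL − countR)/(countL + countR) over homologous ROIs for thresholds 1–15, trial-bootstrap CIs |
| `opmlat.pipeline` / `opmlat.cli` | config-driven end-to-end runs with provenance hashing, fixture generator, `opmlat` console entry point |

Notable modelling conventions (see module docstrings for details):

* One coordinate frame: MNI-aligned millimetres everywhere.
* The conductor is a homogeneous sphere fitted to the scalp sensors minus a
  15 mm margin; for a spherical boundary this coincides with single-shell
  models. Purely radial dipoles are silent; only radial field components
  are sensed.
* The default helmet layout is a stand-in (no published coordinates exist):
  two quasi-uniform frontotemporal patches of 13 sensors plus 4 references
  30 cm behind the head, exactly mirror-symmetric in x.
* "3 Hz multitaper bandwidth with 1 s resolution" is read as full smoothing
  bandwidth (2 tapers) by default; pass `half_bandwidth=3.0` for the
  5-taper reading.
* A desynchronization drives the active/baseline F below 1, so supra-
  threshold counting and peak picking use the magnitude `max(F, 1/F)`.

## CLI

```sh
opmlat run --config run.yaml --out runs/demo     # full pipeline
opmlat simulate --seed 1 --out data.h5
opmlat preprocess --in data.h5 --out clean.h5 --rate 200
opmlat spectral --in clean.h5 --band 15 30 --rest -2 0 --task 0 3 --nboot 100 --seed 1 --out course.tsv
opmlat localize --in clean.h5 --band 15 30 --baseline -1 0 --active 0 1 --out statmap.tsv
opmlat laterality --in clean.h5 --nboot 100 --seed 1 --out laterality.tsv
opmlat fixtures --seed 0 --out fixtures/
```

A run directory contains `data.h5`, `clean.h5`, `spec.h5`, `statmap.tsv`,
`laterality.tsv`, `confidence_volume.json`, `source_course.tsv`, `run.log`
and `resolved-config.yaml`; every output embeds the config hash and seed.

Minimal `run.yaml` (all keys optional; unknown keys are rejected):

```yaml
seed: 1
simulation: {n_trials: 120, desync_depth: 0.4}
geometry: {grid_spacing_mm: 10.0}
localize: {regularization: 0.05, fdr_q: 0.05}
laterality: {n_boot: 100}
```

## HDF5 container schema (version 1)

`/data` trials×channels×samples (float64, tesla) · `/times` seconds relative
to task onset · `/events` per-trial (onset, offset) · `/channels/{labels,
positions, orientations, roles}` · `/provenance` JSON operation log · root
attrs `schema_version`, `sampling_rate`, `seed`. Lead fields are stored
under `/leadfields` with unit annotations.
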