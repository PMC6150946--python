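"""Scalar LCMV beamforming, F-statistic mapping, bootstrap confidence volumes.

The data covariance is pooled over whole band-filtered trials.  At each grid
point the source orientation is the direction of maximal beamformed power:
with M = L^T C^-1 L, power along unit orientation theta is 1/(theta^T M
theta), so the chosen orientation is the eigenvector of M with the smallest
*non-silent* eigenvalue.  For a spherical conductor the radial direction is
magnetically silent, producing a near-null eigenvalue of M that must be
excluded, otherwise the "max power" direction is pure noise blow-up;
eigenvalues below 1e-7 of the largest are treated as silent.  Weights are
unit-gain: w^T L(theta) = 1.

The F map is the ratio of trial-mean beamformed variance in an active window
to a baseline window of equal length.  Because windows are band-limited, the
F null dof are not the sample counts; per-window dof default to
trials * 2*B*T (B band width, T window length) with an optional
moment-matched empirical mode.  These choices are artifact-level defaults,
not prescribed by the method chain they implement.  The map is two-sided on
log F and FDR-controlled (Benjamini-Hochberg) across grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from ._exceptions import ConditioningError, ConfigurationError, DegenerateError
from .dataset import TrialDataset
from .forward import LeadFieldSet
from .geometry import SensorArray, SourceGrid

#: eigenvalue ratio below which a lead-field direction is considered silent
SILENT_EIG_RATIO = 1e-7


@dataclass
class BeamformerWeights:
    """Unit-gain scalar-LCMV weights and chosen orientations per grid point."""

    weights: np.ndarray       # (n_points, n_scalp)
    orientations: np.ndarray  # (n_points, 3)
    regularization: float
    conditioning: dict        # eigenvalue spread of the (regularized) covariance
    grid: SourceGrid


@dataclass
class StatMap:
    """Per-grid-point F statistic of active vs baseline band power."""

    F: np.ndarray          # active/baseline ratio, >= 0
    p: np.ndarray          # two-sided on log F, in (0, 1]
    fdr_pass: np.ndarray   # bool, Benjamini-Hochberg at q
    q: float
    dof: float             # per-window denominator/numerator dof actually used
    baseline_window: tuple[float, float]
    active_window: tuple[float, float]
    grid: SourceGrid
    meta: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        """max(F, 1/F): size of the power change regardless of direction.

        Supra-threshold counts and peak picking use this, since a
        desynchronization drives F below 1.
        """
        with np.errstate(divide="ignore"):
            return np.maximum(self.F, 1.0 / self.F)


@dataclass
class ConfidenceVolume:
    """Spread of bootstrap-resampled ROI peak locations."""

    roi_name: str
    peaks: np.ndarray     # (n_boot, 3) mm
    extents: np.ndarray   # (3,) 95% extent per axis = 2 * SD, mm
    n_boot: int
    seed: int


def band_filter(
    ds: TrialDataset, band: tuple[float, float] = (15.0, 30.0), order: int = 5
) -> TrialDataset:
    """Zero-phase Butterworth band-pass (bidirectional, default 5th order)."""
    nyq = ds.sampling_rate / 2.0
    if band[1] >= nyq:
        raise ConfigurationError(f"band edge {band[1]} Hz is at/above Nyquist {nyq} Hz")
    sos = signal.butter(order, band, btype="bandpass", fs=ds.sampling_rate, output="sos")
    data = signal.sosfiltfilt(sos, ds.data, axis=-1)
    return ds.with_data(data, step={"op": "band_filter", "band": list(band), "order": order})


def trial_covariances(ds: TrialDataset, window: tuple[float, float] | None = None) -> np.ndarray:
    """(n_trials, n_scalp, n_scalp) per-trial scalp covariance, per-trial mean removed."""
    sl = slice(None) if window is None else ds.sample_slice(window)
    x = ds.scalp_data()[:, :, sl]
    x = x - x.mean(axis=2, keepdims=True)
    n = x.shape[2]
    return np.einsum("tcs,tds->tcd", x, x) / (n - 1)


def _regularized_inverse(cov: np.ndarray, regularization: float) -> tuple[np.ndarray, dict]:
    eigvals = np.linalg.eigvalsh(cov)
    if regularization == 0.0 and eigvals[0] <= eigvals[-1] * 1e-12:
        raise ConditioningError(
            "pooled covariance is numerically singular; pass a nonzero regularization "
            "(e.g. 0.05 of the mean sensor variance)"
        )
    creg = cov + regularization * np.mean(np.diag(cov)) * np.eye(cov.shape[0])
    report = {
        "regularization": regularization,
        "eig_min": float(eigvals[0]),
        "eig_max": float(eigvals[-1]),
        "condition_number": float(eigvals[-1] / max(eigvals[0], 1e-300)),
    }
    return np.linalg.inv(creg), report


def _point_weights(cinv: np.ndarray, L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-gain weight vector and max-power orientation for one point's (n_ch, 3) lead field."""
    K = cinv @ L                       # (n_ch, 3)
    M = L.T @ K                        # (3, 3)
    vals, vecs = np.linalg.eigh(M)     # ascending
    valid = vals > SILENT_EIG_RATIO * vals[-1]
    if not valid.any():
        raise DegenerateError("lead field is (numerically) zero at this grid point")
    theta = vecs[:, int(np.argmax(valid))]  # smallest non-silent eigenvalue
    denom = float(theta @ M @ theta)
    w = (K @ theta) / denom
    # fix the physical +/- ambiguity: first significant weight positive
    lead = w[np.argmax(np.abs(w) > 1e-3 * np.abs(w).max())]
    if lead < 0:
        w, theta = -w, -theta
    return w, theta


def lcmv_weights(
    ds_filtered: TrialDataset,
    lf: LeadFieldSet,
    regularization: float = 0.05,
    cov: np.ndarray | None = None,
    point_indices: np.ndarray | None = None,
) -> BeamformerWeights:
    """Scalar LCMV weights from the whole-trial pooled covariance.

    ``cov`` overrides the covariance (used by bootstrap resampling);
    ``point_indices`` restricts computation to a subset of grid points (the
    returned arrays still span the full grid, with zeros elsewhere).
    """
    if cov is None:
        cov = trial_covariances(ds_filtered).mean(axis=0)
    cinv, report = _regularized_inverse(cov, regularization)
    n_points = lf.grid.n_points
    weights = np.zeros((n_points, cov.shape[0]))
    orientations = np.zeros((n_points, 3))
    indices = np.arange(n_points) if point_indices is None else np.asarray(point_indices)
    for p in indices:
        weights[p], orientations[p] = _point_weights(cinv, lf.fields[:, p, :])
    return BeamformerWeights(
        weights=weights,
        orientations=orientations,
        regularization=regularization,
        conditioning=report,
        grid=lf.grid,
    )


def _window_dof(
    ds: TrialDataset,
    window: tuple[float, float],
    band: tuple[float, float],
    mode: str,
    window_covs: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray | float:
    t_len = window[1] - window[0]
    if mode == "fixed":
        return ds.n_trials * 2.0 * (band[1] - band[0]) * t_len
    if mode == "empirical":
        # per-point moment matching: per-trial window variance ~ Gamma; the
        # equivalent chi^2 dof is 2 mean^2 / var, summed over trials
        v = np.einsum("pc,tcd,pd->tp", weights, window_covs, weights)  # (trials, points)
        mean, var = v.mean(axis=0), v.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            nu = np.where(var > 0, 2.0 * mean**2 / var, np.inf)
        return ds.n_trials * nu
    raise ConfigurationError(f"unknown dof mode {mode!r}")


def f_map(
    ds_filtered: TrialDataset,
    w: BeamformerWeights,
    baseline_window: tuple[float, float] = (-1.0, 0.0),
    active_window: tuple[float, float] = (0.0, 1.0),
    q: float = 0.05,
    band: tuple[float, float] = (15.0, 30.0),
    dof_mode: str = "fixed",
    baseline_covs: np.ndarray | None = None,
    active_covs: np.ndarray | None = None,
) -> StatMap:
    """F statistic of beamformed band power, active vs baseline window.

    F_i = (w_i^T Ca w_i) / (w_i^T Cb w_i) with Ca, Cb trial-mean window
    covariances; p two-sided on log F; FDR over grid points.
    """
    if abs((active_window[1] - active_window[0]) - (baseline_window[1] - baseline_window[0])) > 1e-9:
        raise ConfigurationError("baseline and active windows must have equal length")
    if baseline_covs is None:
        baseline_covs = trial_covariances(ds_filtered, baseline_window)
    if active_covs is None:
        active_covs = trial_covariances(ds_filtered, active_window)
    ca, cb = active_covs.mean(axis=0), baseline_covs.mean(axis=0)
    va = np.einsum("pc,cd,pd->p", w.weights, ca, w.weights)
    vb = np.einsum("pc,cd,pd->p", w.weights, cb, w.weights)
    if np.any(vb <= 0):
        bad = int(np.argmin(vb))
        raise DegenerateError(f"zero baseline variance at grid point {bad}")
    F = va / vb

    dof_a = _window_dof(ds_filtered, active_window, band, dof_mode, active_covs, w.weights)
    dof_b = _window_dof(ds_filtered, baseline_window, band, dof_mode, baseline_covs, w.weights)
    dist = stats.f(dof_a, dof_b)
    p = 2.0 * np.minimum(dist.sf(F), dist.cdf(F))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fdr_pass = multipletests(p, alpha=q, method="fdr_bh")[0]
    return StatMap(
        F=F,
        p=p,
        fdr_pass=fdr_pass,
        q=q,
        dof=float(np.atleast_1d(dof_a).mean()),
        baseline_window=baseline_window,
        active_window=active_window,
        grid=w.grid,
        meta={"dof_mode": dof_mode, "band": list(band)},
    )


def confidence_volume(
    ds_filtered: TrialDataset,
    lf: LeadFieldSet,
    roi_mask: np.ndarray,
    baseline_window: tuple[float, float] = (-1.0, 0.0),
    active_window: tuple[float, float] = (0.0, 1.0),
    n_boot: int = 50,
    seed: int = 0,
    regularization: float = 0.05,
    roi_name: str = "roi",
) -> ConfidenceVolume:
    """Trial-bootstrap spread of the ROI peak (largest |log F|) location.

    Each resample recomputes covariance, weights, and the ROI F values; the
    95% extent per axis is twice the SD of the peak coordinates.
    """
    if n_boot < 2:
        raise ConfigurationError("n_boot must be >= 2")
    roi_idx = np.flatnonzero(roi_mask)
    if len(roi_idx) == 0:
        raise ConfigurationError("empty ROI")
    whole = trial_covariances(ds_filtered)
    bl = trial_covariances(ds_filtered, baseline_window)
    ac = trial_covariances(ds_filtered, active_window)
    rng = np.random.default_rng(seed)
    peaks = np.empty((n_boot, 3))
    for b in range(n_boot):
        idx = rng.integers(0, ds_filtered.n_trials, ds_filtered.n_trials)
        w = lcmv_weights(
            ds_filtered, lf, regularization, cov=whole[idx].mean(axis=0), point_indices=roi_idx
        )
        wr = w.weights[roi_idx]
        va = np.einsum("pc,cd,pd->p", wr, ac[idx].mean(axis=0), wr)
        vb = np.einsum("pc,cd,pd->p", wr, bl[idx].mean(axis=0), wr)
        if not np.all(np.isfinite(va / vb)):
            raise DegenerateError("non-finite F inside ROI during bootstrap")
        peak = roi_idx[int(np.argmax(np.abs(np.log(va / vb))))]
        peaks[b] = lf.grid.points[peak]
    return ConfidenceVolume(
        roi_name=roi_name,
        peaks=peaks,
        extents=2.0 * peaks.std(axis=0, ddof=1),
        n_boot=n_boot,
        seed=seed,
    )


def source_timecourse(
    ds: TrialDataset, w: BeamformerWeights, point_index: int
) -> TrialDataset:
    """Virtual-channel dataset (one scalp channel) at a grid point.

    Applies the location-specific weights to the scalp data of ``ds`` (which
    may be broadband-clean or band-filtered); the spectral module's
    operations then yield the percent-change course of the source.
    """
    vc = np.einsum("c,tcs->ts", w.weights[point_index], ds.scalp_data())
    virtual = SensorArray(
        labels=[f"vc_{point_index}"],
        positions=w.grid.points[point_index][None, :],
        orientations=w.orientations[point_index][None, :] /
        max(np.linalg.norm(w.orientations[point_index]), 1e-30),
        roles=["scalp"],
        sampling_rate=ds.sampling_rate,
    )
    return TrialDataset(
        data=vc[:, None, :],
        sampling_rate=ds.sampling_rate,
        times=ds.times,
        events=ds.events,
        array=virtual,
        provenance=list(ds.provenance) + [{"op": "source_timecourse", "point": int(point_index)}],
        seed=ds.seed,
    )


def statmap_to_nifti(statmap: StatMap, path, value: str = "magnitude") -> None:
    """Embed the grid in a regular lattice and write a NIfTI volume (MNI mm affine)."""
    import nibabel as nib

    grid = statmap.grid
    s = grid.spacing
    mins = grid.points.min(axis=0)
    ijk = np.round((grid.points - mins) / s).astype(int)
    shape = ijk.max(axis=0) + 1
    vol = np.full(shape, np.nan)
    vals = getattr(statmap, value) if value != "magnitude" else statmap.magnitude
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = vals
    affine = np.diag([s, s, s, 1.0])
    affine[:3, 3] = mins
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def statmap_to_tsv(statmap: StatMap, path) -> None:
    """TSV export: x, y, z, F, p, fdr_pass (one row per grid point)."""
    import pandas as pd

    pd.DataFrame(
        {
            "x_mm": statmap.grid.points[:, 0],
            "y_mm": statmap.grid.points[:, 1],
            "z_mm": statmap.grid.points[:, 2],
            "F": statmap.F,
            "p": statmap.p,
            "fdr_pass": statmap.fdr_pass.astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
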