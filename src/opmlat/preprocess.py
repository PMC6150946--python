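"""Preprocessing: downsampling, line/stop-band filters, synthetic gradiometry.

Filter realizations (the acquisition chain names none, so these live in
config and provenance): zero-phase 2nd-order IIR notch (Q=35) at 50 Hz, a
4th-order Butterworth band-stop at 75-79 Hz, and an 8th-order Butterworth
anti-aliasing low-pass before integer decimation.  All filters are applied
forward-backward.

Synthetic gradiometry fits, per trial, an ordinary least-squares mixture of
the reference channels (plus an intercept by default) to each scalp channel
via the Moore-Penrose pseudoinverse and subtracts it.  Fitting per trial
tracks non-stationary interference at the cost of a small O(k/n) leakage of
brain signal variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from ._exceptions import ConfigurationError
from .dataset import TrialDataset


@dataclass
class InterferenceWeights:
    """Per-trial reference-regression weights and fit diagnostics."""

    weights: np.ndarray            # (n_trials, n_regressors, n_scalp)
    variance_explained: np.ndarray  # (n_trials, n_scalp), in [0, 1]
    intercept: bool


def _apply_sos(data: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def downsample_and_filter(
    ds: TrialDataset,
    target_rate: float = 200.0,
    notch_freqs: tuple[float, ...] = (50.0,),
    bandstop: tuple[float, float] | None = (75.0, 79.0),
    notch_q: float = 35.0,
) -> TrialDataset:
    """Notch + band-stop filtering followed by anti-aliased integer decimation.

    The band-stop is applied before downsampling (its band may exceed the
    post-decimation Nyquist); the operation order is recorded in provenance.
    """
    fs = ds.sampling_rate
    nyq = fs / 2.0
    for f0 in notch_freqs:
        if f0 >= nyq:
            raise ConfigurationError(f"notch at {f0} Hz is at/above Nyquist {nyq} Hz")
    data = ds.data
    for f0 in notch_freqs:
        b, a = signal.iirnotch(f0, Q=notch_q, fs=fs)
        data = signal.filtfilt(b, a, data, axis=-1)
    if bandstop is not None:
        if bandstop[1] >= nyq:
            raise ConfigurationError(f"band-stop edge {bandstop[1]} Hz is at/above Nyquist {nyq} Hz")
        sos = signal.butter(4, bandstop, btype="bandstop", fs=fs, output="sos")
        data = _apply_sos(data, sos)

    if target_rate > fs:
        raise ConfigurationError("target rate exceeds the current sampling rate")
    if target_rate < fs:
        ratio = fs / target_rate
        factor = int(round(ratio))
        if abs(ratio - factor) > 1e-9:
            raise ConfigurationError(
                f"target rate {target_rate} Hz must divide the sampling rate {fs} Hz"
            )
        sos_aa = signal.butter(8, 0.8 * target_rate / 2.0, btype="lowpass", fs=fs, output="sos")
        data = _apply_sos(data, sos_aa)[..., ::factor]
        times = ds.times[::factor]
    else:
        times = ds.times

    return ds.with_data(
        data,
        sampling_rate=target_rate,
        times=times,
        step={
            "op": "downsample_and_filter",
            "target_rate": target_rate,
            "notch_freqs": list(notch_freqs),
            "notch_q": notch_q,
            "bandstop": list(bandstop) if bandstop else None,
            "order": "notch, bandstop, anti-alias low-pass, decimate",
        },
    )


def synthetic_gradiometry(
    ds: TrialDataset, intercept: bool = True, rank_tol: float = 1e-10
) -> tuple[TrialDataset, InterferenceWeights]:
    """Regress the reference channels out of the scalp channels, per trial.

    For trial t with reference design matrix X_t (samples x regressors) and
    scalp data Y_t (samples x scalp channels):
    beta_t = pinv(X_t) Y_t, cleaned Y_t <- Y_t - X_t beta_t.
    Reference channels stay in the dataset, marked consumed in provenance.
    """
    ref_idx = ds.array.reference_indices
    scalp_idx = ds.array.scalp_indices
    if len(ref_idx) == 0:
        raise ConfigurationError("synthetic gradiometry needs at least one reference channel")
    k = len(ref_idx) + int(intercept)
    if ds.n_samples <= k:
        raise ConfigurationError(
            f"per-trial sample count {ds.n_samples} must exceed {k} regressors"
        )

    data = ds.data.copy()
    n_scalp = len(scalp_idx)
    weights = np.empty((ds.n_trials, k, n_scalp))
    var_explained = np.empty((ds.n_trials, n_scalp))
    for t in range(ds.n_trials):
        X = ds.data[t, ref_idx, :].T  # samples x references
        if intercept:
            X = np.column_stack([X, np.ones(X.shape[0])])
        # column scales differ by ~10 orders (tesla vs intercept); normalize
        # before the rank check so it detects true collinearity only
        norms = np.linalg.norm(X, axis=0)
        nz = norms > 0
        deficient = not np.all(nz)
        if nz.any():
            xn = X[:, nz] / norms[nz]
            deficient = deficient or (
                np.linalg.matrix_rank(xn, tol=rank_tol * xn.shape[0]) < int(nz.sum())
            )
        if deficient:
            warnings.warn(f"rank-deficient reference design matrix in trial {t}", stacklevel=2)
        Y = ds.data[t, scalp_idx, :].T  # samples x scalp
        # equilibrate columns before the pseudoinverse: tesla-scale reference
        # columns next to a unit intercept otherwise cost ~10 digits
        scale = np.where(norms > 0, norms, 1.0)
        beta = (np.linalg.pinv(X / scale) @ Y) / scale[:, None]
        resid = Y - X @ beta
        data[t, scalp_idx, :] = resid.T
        weights[t] = beta
        total = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
        removed = total - np.sum((resid - resid.mean(axis=0)) ** 2, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ve = np.where(total > 0, removed / total, 0.0)
        var_explained[t] = np.clip(ve, 0.0, 1.0)

    cleaned = ds.with_data(
        data,
        step={
            "op": "synthetic_gradiometry",
            "intercept": intercept,
            "n_references": len(ref_idx),
            "references_consumed": True,
        },
    )
    return cleaned, InterferenceWeights(
        weights=weights, variance_explained=var_explained, intercept=intercept
    )
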