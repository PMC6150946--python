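"""Trial-epoched recordings and their HDF5 container.

Schema (version 1): ``/data`` trials x channels x samples (float64, tesla),
``/times`` seconds relative to task onset, ``/events`` per-trial (onset,
offset) seconds, ``/channels`` sensor table columns, ``/provenance`` JSON
string (applied-operation log), root attrs ``schema_version``,
``sampling_rate``, optional ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from ._exceptions import ContainerError, ValidationError
from .geometry import SensorArray

SCHEMA_VERSION = 1

#: sensor dynamic range (tesla); exceeding samples are flagged, never clipped
DYNAMIC_RANGE_T = 1.5e-9


@dataclass
class TrialDataset:
    """Trials x channels x samples field measurements with timing metadata."""

    data: np.ndarray           # (n_trials, n_channels, n_samples) tesla
    sampling_rate: float       # Hz
    times: np.ndarray          # (n_samples,) s relative to task onset
    events: np.ndarray         # (n_trials, 2): task onset, task offset (s)
    array: SensorArray
    provenance: list[dict] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("data must be (trials, channels, samples)")
        n_trials, n_channels, n_samples = self.data.shape
        if n_channels != self.array.n_channels:
            raise ValidationError(
                f"data has {n_channels} channels but the sensor array has {self.array.n_channels}"
            )
        if len(self.times) != n_samples:
            raise ValidationError("times length must match the sample count")
        if self.events.shape != (n_trials, 2):
            raise ValidationError("events must be (n_trials, 2) onset/offset seconds")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def scalp_data(self) -> np.ndarray:
        """(trials, n_scalp, samples) view of the scalp channels."""
        return self.data[:, self.array.scalp_indices, :]

    def reference_data(self) -> np.ndarray:
        return self.data[:, self.array.reference_indices, :]

    def with_data(self, data: np.ndarray, sampling_rate: float | None = None,
                  times: np.ndarray | None = None, step: dict | None = None) -> "TrialDataset":
        """Copy with new data and an optional provenance entry appended."""
        prov = list(self.provenance) + ([step] if step else [])
        return replace(
            self,
            data=data,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            times=self.times if times is None else times,
            provenance=prov,
        )

    def sample_slice(self, window: tuple[float, float]) -> slice:
        """Slice of sample indices whose times fall in [window[0], window[1])."""
        i0 = int(np.searchsorted(self.times, window[0], side="left"))
        i1 = int(np.searchsorted(self.times, window[1], side="left"))
        if i1 <= i0:
            raise ValidationError(f"window {window} contains no samples")
        return slice(i0, i1)

    def range_violations(self) -> np.ndarray:
        """(trial, channel) index pairs where |value| exceeds the dynamic range."""
        t, c, _ = np.nonzero(np.abs(self.data) > DYNAMIC_RANGE_T)
        return np.unique(np.column_stack([t, c]), axis=0) if len(t) else np.empty((0, 2), int)


def write_dataset(ds: TrialDataset, path: str | Path) -> None:
    """Write a bit-exact container (see module docstring for the schema)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["sampling_rate"] = ds.sampling_rate
        if ds.seed is not None:
            f.attrs["seed"] = int(ds.seed)
        f.create_dataset("data", data=ds.data)
        f.create_dataset("times", data=ds.times)
        f.create_dataset("events", data=ds.events)
        ch = f.create_group("channels")
        ch.create_dataset("labels", data=np.array(ds.array.labels, dtype="S"))
        ch.create_dataset("positions", data=ds.array.positions)
        ch.create_dataset("orientations", data=ds.array.orientations)
        ch.create_dataset("roles", data=np.array(ds.array.roles, dtype="S"))
        f.create_dataset("provenance", data=json.dumps(ds.provenance))


def read_dataset(path: str | Path) -> TrialDataset:
    """Read a container; raises :class:`ContainerError` on corruption or version mismatch."""
    try:
        f = h5py.File(path, "r")
    except (OSError, ValueError) as exc:
        raise ContainerError(f"cannot open {path}: {exc}") from exc
    with f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ContainerError(
                f"unsupported container schema version {version!r} (expected {SCHEMA_VERSION})"
            )
        try:
            array = SensorArray(
                labels=[s.decode() for s in f["channels/labels"][()]],
                positions=f["channels/positions"][()],
                orientations=f["channels/orientations"][()],
                roles=[s.decode() for s in f["channels/roles"][()]],
                sampling_rate=float(f.attrs["sampling_rate"]),
            )
            return TrialDataset(
                data=f["data"][()],
                sampling_rate=float(f.attrs["sampling_rate"]),
                times=f["times"][()],
                events=f["events"][()],
                array=array,
                provenance=json.loads(f["provenance"][()]),
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )
        except KeyError as exc:
            raise ContainerError(f"container {path} is missing {exc}") from exc
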