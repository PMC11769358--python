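"""Domain types for paired scalp/intracranial EEG segments and cohort storage.

A *paired segment* is a time-aligned pair of windows, one from the scalp
montage (L time samples x M sensors) and one from the intracranial
(foramen-ovale) montage (L x Mbar sensors), labeled IED or non-IED.  Segments
are stored amplitude-normalized to [-1, 1] (per-recording min-max scaling is
applied upstream by :mod:`eegtranslate.preprocess`), matching the bounded
tanh output range of the generator.

Cohorts round-trip bit-exactly through a single HDF5 file (one group per
subject) or an NPZ mirror.  Continuous real recordings can be brought in
from EDF via :func:`import_edf`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "ScalpSegment",
    "IntracranialSegment",
    "PairedSegment",
    "SubjectRecord",
    "SubjectCohort",
    "write_cohort",
    "read_cohort",
    "import_edf",
]

LABELS = ("IED", "nonIED")
_AMP_TOL = 1e-9


def _check_samples(samples: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(samples, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name}: expected a 2-D (time x sensors) array, got {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name}: samples contain non-finite values")
    if np.abs(arr).max(initial=0.0) > 1.0 + _AMP_TOL:
        raise ValueError(f"{name}: amplitudes exceed the normalized range [-1, 1]")
    return arr


@dataclass
class ScalpSegment:
    """One scalp window: (L, M) normalized samples at ``sampling_rate`` Hz.

    ``onset_index`` is the sample index of the IED onset inside the window,
    or None for windows without an annotated event.
    """

    samples: np.ndarray
    sampling_rate: float = 200.0
    onset_index: int | None = None

    def __post_init__(self):
        self.samples = _check_samples(self.samples, "scalp segment")

    @property
    def L(self) -> int:
        return self.samples.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.samples.shape[1]


@dataclass
class IntracranialSegment:
    """One intracranial window: (L, Mbar) samples; provenance marks whether it
    was recorded ('real') or produced by the generator ('estimated')."""

    samples: np.ndarray
    provenance: str = "real"

    def __post_init__(self):
        self.samples = _check_samples(self.samples, "intracranial segment")
        if self.provenance not in ("real", "estimated"):
            raise ValueError(f"provenance must be 'real' or 'estimated', got {self.provenance!r}")

    @property
    def L(self) -> int:
        return self.samples.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.samples.shape[1]


@dataclass
class PairedSegment:
    scalp: ScalpSegment
    intracranial: IntracranialSegment
    label: str
    subject_id: str = "subject"

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.scalp.L != self.intracranial.L:
            raise ValueError(
                f"subject {self.subject_id}: scalp window has {self.scalp.L} samples but "
                f"intracranial has {self.intracranial.L} (segments must be time-aligned)"
            )


@dataclass
class SubjectRecord:
    """All paired segments of one subject plus its IED annotation counts."""

    subject_id: str
    segments: list[PairedSegment]
    n_ied_total: int = 0
    n_ied_visible: int = 0

    def __post_init__(self):
        for i, seg in enumerate(self.segments):
            if seg.subject_id != self.subject_id:
                raise ValueError(
                    f"segment {i} carries subject_id {seg.subject_id!r} inside record "
                    f"{self.subject_id!r}"
                )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stack segments into (scalp (n,L,M), intracranial (n,L,Mbar), labels (n,))."""
        if not self.segments:
            raise ValueError(f"subject {self.subject_id}: no segments")
        shapes_sc = {s.scalp.samples.shape for s in self.segments}
        shapes_ic = {s.intracranial.samples.shape for s in self.segments}
        if len(shapes_sc) > 1 or len(shapes_ic) > 1:
            raise ValueError(f"subject {self.subject_id}: inconsistent segment shapes "
                             f"(scalp {shapes_sc}, intracranial {shapes_ic})")
        scalp = np.stack([s.scalp.samples for s in self.segments])
        intra = np.stack([s.intracranial.samples for s in self.segments])
        labels = np.array([1 if s.label == "IED" else 0 for s in self.segments], dtype=np.int8)
        return scalp, intra, labels


@dataclass
class SubjectCohort:
    subjects: list[SubjectRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate subject ids in cohort: {ids}")

    def __len__(self) -> int:
        return len(self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for rec in self.subjects:
            if rec.subject_id == subject_id:
                return rec
        raise KeyError(subject_id)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


# ---------------------------------------------------------------------------
# storage


def _record_to_payload(rec: SubjectRecord) -> dict:
    scalp, intra, labels = rec.arrays()
    onsets = np.array(
        [-1 if s.scalp.onset_index is None else s.scalp.onset_index for s in rec.segments],
        dtype=np.int64,
    )
    prov = np.array([1 if s.intracranial.provenance == "estimated" else 0
                     for s in rec.segments], dtype=np.int8)
    return {
        "scalp": scalp,
        "intracranial": intra,
        "labels": labels,
        "onset_indices": onsets,
        "provenance": prov,
        "sampling_rate": float(rec.segments[0].scalp.sampling_rate),
        "n_ied_total": int(rec.n_ied_total),
        "n_ied_visible": int(rec.n_ied_visible),
    }


def _record_from_payload(subject_id: str, p: dict) -> SubjectRecord:
    scalp, intra = np.asarray(p["scalp"]), np.asarray(p["intracranial"])
    labels, onsets = np.asarray(p["labels"]), np.asarray(p["onset_indices"])
    prov = np.asarray(p["provenance"])
    if scalp.shape[0] != intra.shape[0]:
        raise ValueError(f"subject {subject_id}: {scalp.shape[0]} scalp segments but "
                         f"{intra.shape[0]} intracranial segments")
    if scalp.shape[1] != intra.shape[1]:
        raise ValueError(
            f"subject {subject_id}: scalp window length {scalp.shape[1]} does not match "
            f"intracranial window length {intra.shape[1]} (segments must be time-aligned)"
        )
    segments = []
    for i in range(scalp.shape[0]):
        segments.append(PairedSegment(
            scalp=ScalpSegment(scalp[i], sampling_rate=float(p["sampling_rate"]),
                               onset_index=None if onsets[i] < 0 else int(onsets[i])),
            intracranial=IntracranialSegment(
                intra[i], provenance="estimated" if prov[i] else "real"),
            label="IED" if labels[i] else "nonIED",
            subject_id=subject_id,
        ))
    return SubjectRecord(subject_id, segments,
                         n_ied_total=int(p["n_ied_total"]),
                         n_ied_visible=int(p["n_ied_visible"]))


def write_cohort(cohort: SubjectCohort, path, format: str | None = None):
    """Write a cohort to one HDF5 (default) or NPZ file; returns the path.

    HDF5 layout: one group per subject under ``/subjects`` with datasets
    ``scalp`` (n, L, M), ``intracranial`` (n, L, Mbar), ``labels`` (n,),
    ``onset_indices`` (n,), ``provenance`` (n,) and attributes
    ``sampling_rate``, ``n_ied_total``, ``n_ied_visible``.  Cohort metadata is
    stored as JSON in a root attribute.  Round trips are bit-exact.
    """
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "hdf5"
    if format not in ("hdf5", "npz"):
        raise ValueError(f"unknown format {format!r} (expected 'hdf5' or 'npz')")
    payloads = {rec.subject_id: _record_to_payload(rec) for rec in cohort.subjects}

    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["metadata"] = json.dumps(cohort.metadata)
            f.attrs["subject_order"] = json.dumps(cohort.subject_ids)
            grp = f.create_group("subjects")
            for sid, p in payloads.items():
                g = grp.create_group(sid)
                for key in ("scalp", "intracranial", "labels", "onset_indices", "provenance"):
                    g.create_dataset(key, data=p[key])
                for key in ("sampling_rate", "n_ied_total", "n_ied_visible"):
                    g.attrs[key] = p[key]
    else:
        flat: dict[str, np.ndarray] = {
            "__metadata__": np.bytes_(json.dumps(cohort.metadata)),
            "__subject_order__": np.bytes_(json.dumps(cohort.subject_ids)),
        }
        for sid, p in payloads.items():
            for key, val in p.items():
                flat[f"{sid}::{key}"] = np.asarray(val)
        np.savez(path, **flat)
    return path


def read_cohort(path) -> SubjectCohort:
    """Inverse of :func:`write_cohort`; validates all type invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            metadata = json.loads(bytes(data["__metadata__"]).decode())
            order = json.loads(bytes(data["__subject_order__"]).decode())
            records = []
            for sid in order:
                keys = ("scalp", "intracranial", "labels", "onset_indices",
                        "provenance", "sampling_rate", "n_ied_total", "n_ied_visible")
                missing = [k for k in keys if f"{sid}::{k}" not in data]
                if missing:
                    raise ValueError(f"subject {sid}: missing datasets {missing}")
                payload = {k: data[f"{sid}::{k}"] for k in keys}
                records.append(_record_from_payload(sid, payload))
        return SubjectCohort(records, metadata=metadata)

    with h5py.File(path, "r") as f:
        metadata = json.loads(f.attrs.get("metadata", "{}"))
        # unknown extra root attributes are preserved as metadata entries
        for key, val in f.attrs.items():
            if key not in ("metadata", "subject_order"):
                metadata.setdefault(key, val.item() if hasattr(val, "item") else str(val))
        order = json.loads(f.attrs.get("subject_order", "null")) or sorted(f["subjects"])
        records = []
        for sid in order:
            g = f["subjects"][sid]
            missing = [k for k in ("scalp", "intracranial", "labels", "onset_indices",
                                   "provenance") if k not in g]
            if missing:
                raise ValueError(f"subject {sid}: missing datasets {missing}")
            payload = {k: g[k][()] for k in ("scalp", "intracranial", "labels",
                                             "onset_indices", "provenance")}
            for k in ("sampling_rate", "n_ied_total", "n_ied_visible"):
                payload[k] = g.attrs[k]
            records.append(_record_from_payload(sid, payload))
    return SubjectCohort(records, metadata=metadata)


# ---------------------------------------------------------------------------
# EDF import


def _edf_samples_per_record(path: Path) -> dict[str, int]:
    """Read per-channel samples-per-record counts from the EDF header (used to
    reject files whose requested channels run at different rates)."""
    with open(path, "rb") as f:
        header = f.read(256)
        ns = int(header[252:256].decode().strip())
        f.seek(256)
        labels = [f.read(16).decode().strip() for _ in range(ns)]
        f.seek(256 + ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80))
        nsamp = [int(f.read(8).decode().strip()) for _ in range(ns)]
    return dict(zip(labels, nsamp))


def import_edf(path, scalp_channel_names, intracranial_channel_names):
    """Load a continuous paired recording from an EDF file.

    Returns ``(scalp (T, M), intracranial (T, Mbar), sampling_rate)``.  All
    requested channels must exist and share one sampling rate (resampling is
    out of scope).
    """
    import mne

    path = Path(path)
    requested = list(scalp_channel_names) + list(intracranial_channel_names)
    per_record = _edf_samples_per_record(path)
    available = [ch for ch in per_record if ch.lower() != "edf annotations"]
    missing = [ch for ch in requested if ch not in per_record]
    if missing:
        raise ValueError(f"channels {missing} not in EDF file; available: {available}")
    rates = {per_record[ch] for ch in requested}
    if len(rates) > 1:
        raise ValueError(
            f"requested channels have different sampling rates (samples/record {sorted(rates)}); "
            "resampling is not supported"
        )
    raw = mne.io.read_raw_edf(path, include=requested, preload=True, verbose="error")
    data = raw.get_data(picks=requested)  # (n_channels, T), ordered as requested
    m = len(scalp_channel_names)
    return data[:m].T.copy(), data[m:].T.copy(), float(raw.info["sfreq"])
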