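"""Shared fixtures: tiny synthetic cohorts and a from-scratch EDF writer."""

import numpy as np
import pytest

from eegtranslate.segment_store import (
    IntracranialSegment,
    PairedSegment,
    ScalpSegment,
    SubjectCohort,
    SubjectRecord,
)


def make_cohort(n_subjects=2, n_segments=10, L=64, M=20, M_bar=12, seed=0) -> SubjectCohort:
    """Hand-built cohort with valid invariants (no simulator involved)."""
    rng = np.random.default_rng(seed)
    subjects = []
    for s in range(n_subjects):
        sid = f"S{s + 1}"
        segments = []
        for i in range(n_segments):
            ied = i % 2 == 0
            segments.append(PairedSegment(
                scalp=ScalpSegment(rng.uniform(-1, 1, (L, M)),
                                   onset_index=L // 2 if ied else None),
                intracranial=IntracranialSegment(rng.uniform(-1, 1, (L, M_bar))),
                label="IED" if ied else "nonIED",
                subject_id=sid,
            ))
        subjects.append(SubjectRecord(sid, segments, n_ied_total=n_segments // 2,
                                      n_ied_visible=1))
    return SubjectCohort(subjects, metadata={"note": "fixture"})


@pytest.fixture
def tiny_cohort() -> SubjectCohort:
    return make_cohort()


def write_edf(path, channels: dict[str, np.ndarray], rates: dict[str, int],
              record_duration: float = 1.0) -> None:
    """Write a minimal EDF file (text header + 16-bit little-endian records).

    ``channels`` maps label -> 1-D float signal (treated as microvolts);
    per-channel rates are samples per record.  All signals must span the same
    number of whole records.
    """
    labels = list(channels)
    ns = len(labels)
    n_records = {len(channels[ch]) // rates[ch] for ch in labels}
    assert len(n_records) == 1, "all channels must cover the same duration"
    n_rec = n_records.pop()

    def pad(text, width):
        b = str(text).encode("ascii")
        assert len(b) <= width
        return b + b" " * (width - len(b))

    phys_min, phys_max, dig_min, dig_max = -1000.0, 1000.0, -32768, 32767
    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(256 + ns * 256, 8), pad("", 44), pad(n_rec, 8),
        pad(f"{record_duration:g}", 8), pad(ns, 4),
    ])
    header += b"".join(pad(ch, 16) for ch in labels)
    header += b"".join(pad("", 80) for _ in labels)
    header += b"".join(pad("uV", 8) for _ in labels)
    header += b"".join(pad(f"{phys_min:g}", 8) for _ in labels)
    header += b"".join(pad(f"{phys_max:g}", 8) for _ in labels)
    header += b"".join(pad(dig_min, 8) for _ in labels)
    header += b"".join(pad(dig_max, 8) for _ in labels)
    header += b"".join(pad("", 80) for _ in labels)
    header += b"".join(pad(rates[ch], 8) for ch in labels)
    header += b"".join(pad("", 32) for _ in labels)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            for ch in labels:
                rate = rates[ch]
                chunk = channels[ch][r * rate:(r + 1) * rate]
                digital = np.clip(np.round(chunk * scale), dig_min, dig_max).astype("<i2")
                f.write(digital.tobytes())
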