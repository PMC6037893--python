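"""Recording I/O: EDF read/write and cohort ground-truth manifests.

Reading goes through MNE's EDF reader. Writing uses a minimal EDF writer
implemented here (16-bit samples, physical units µV, 1-s data records):
the format's header is fixed-width ASCII and the payload is little-endian
int16, so a compact writer is straightforward and round-trips through any
standard reader within one quantization step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from qeeg.recording import EEGRecording
from qeeg.synthetic import CohortSpec, SubjectSpec, generate_cohort

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(field: str, width: int) -> bytes:
    s = field[:width].ljust(width)
    return s.encode("ascii")


def write_edf(recording: EEGRecording, path) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    Requires an integer sampling rate, whole-second recording length and
    channel labels of at most 16 characters.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    if recording.n_times % fs != 0:
        raise ValueError("recording length must be a whole number of seconds")
    for lab in recording.channel_labels:
        if len(lab) > 16:
            raise ValueError(f"channel label {lab!r} exceeds 16 characters")
    n_rec = recording.n_times // fs
    n_sig = recording.n_channels

    pmin = recording.samples.min(axis=1)
    pmax = recording.samples.max(axis=1)
    flat = pmax <= pmin
    pmax = np.where(flat, pmin + 1.0, pmax)

    header = b"".join([
        _ascii("0", 8),
        _ascii(recording.subject_id or "X", 80),
        _ascii("Startdate 01-JAN-2000", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(str(256 * (n_sig + 1)), 8),
        _ascii("", 44),
        _ascii(str(n_rec), 8),
        _ascii("1", 8),
        _ascii(str(n_sig), 4),
    ])
    per_signal = b"".join([
        b"".join(_ascii(lab, 16) for lab in recording.channel_labels),
        b"".join(_ascii("AgAgCl electrode", 80) for _ in range(n_sig)),
        b"".join(_ascii("uV", 8) for _ in range(n_sig)),
        b"".join(_ascii(f"{v:.6g}"[:8], 8) for v in pmin),
        b"".join(_ascii(f"{v:.6g}"[:8], 8) for v in pmax),
        b"".join(_ascii(str(_DIG_MIN), 8) for _ in range(n_sig)),
        b"".join(_ascii(str(_DIG_MAX), 8) for _ in range(n_sig)),
        b"".join(_ascii("", 80) for _ in range(n_sig)),
        b"".join(_ascii(str(fs), 8) for _ in range(n_sig)),
        b"".join(_ascii("", 32) for _ in range(n_sig)),
    ])

    # physical range as re-parsed from the truncated header fields, so the
    # stored digital samples invert exactly what a reader will apply
    pmin_r = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_r = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    scale = (pmax_r - pmin_r) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((recording.samples - pmin_r[:, None]) / scale[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_rec):
            for c in range(n_sig):
                fh.write(digital[c, r * fs:(r + 1) * fs].tobytes())


def read_edf(path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (samples in µV)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"malformed EDF {path}: header truncated at byte {len(head)}")
        try:
            n_sig = int(head[252:256].decode("ascii").strip())
        except ValueError as err:
            raise ValueError(f"malformed EDF {path}: bad signal count at byte 252") from err
        labels = [fh.read(16).decode("ascii", "replace").strip() for _ in range(n_sig)]
    data_labels = [l for l in labels if not l.lower().startswith("edf annotations")]
    if len(set(data_labels)) != len(data_labels):
        raise ValueError(f"EDF {path} contains duplicate channel labels")

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # MNE loads EEG in volts
    return EEGRecording(samples, float(raw.info["sfreq"]), list(raw.ch_names),
                        subject_id=path.stem)


def spec_to_row(spec: SubjectSpec, subject_id: str, group: str) -> dict:
    row = {
        "subject_id": subject_id,
        "group": group,
        "dominant_freq": spec.dominant_freq,
        "noise_sd": spec.noise_sd,
        "rhythm_fraction": spec.rhythm_fraction,
        "signal_rms": spec.signal_rms,
        "fs": spec.fs,
        "epoch_length_s": spec.epoch_length_s,
        "n_epochs": spec.n_epochs,
        "seed": spec.seed,
        "n_coupling": len(spec.coupling),
        "mean_coupling_strength":
            float(np.mean([c[3] for c in spec.coupling])) if spec.coupling else 0.0,
    }
    for name, frac in spec.band_fractions.items():
        row[f"frac_{name}"] = frac
    return row


def write_cohort(cohort: CohortSpec, out_dir, write_recordings: bool = True
                 ) -> pd.DataFrame:
    """Generate a cohort, optionally write per-subject EDFs, and return the
    ground-truth manifest (also written as ``manifest.csv``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, spec in generate_cohort(cohort):
        if write_recordings:
            write_edf(rec, out_dir / f"{rec.subject_id}.edf")
        rows.append(spec_to_row(spec, rec.subject_id, cohort.group_label))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
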