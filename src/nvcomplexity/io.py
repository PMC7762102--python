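"""Standard-format I/O: EDF for EEG, SNIRF for optical data, JSON manifests.

EEG is written as plain EDF (16-bit, 1-second data records) and read back
through MNE.  Optical intensities are written as SNIRF 1.0 (HDF5,
continuous-wave amplitude, ``dataType=1``) with one source-detector pair per
channel; geometry encodes the 35 mm long / 15 mm short separations.  The
cohort manifest (subject ids, labels, ages, seeds, phase markers, file
names) is a JSON document next to the data files.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np

from .containers import LONG, SHORT, MultichannelSeries, OpticalRecording, SubjectRecording

__all__ = [
    "write_edf",
    "read_edf",
    "write_snirf",
    "read_snirf",
    "write_cohort",
    "read_cohort",
]


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    series: MultichannelSeries,
    patient_id: str = "X",
    recording_id: str = "synthetic",
) -> None:
    """Write a multichannel series as plain EDF (int16, 1 s data records)."""
    rate = series.rate
    spr = int(round(rate))
    if abs(rate - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = series.n_samples // spr
    if n_records * spr != series.n_samples:
        warnings.warn("EDF write truncates a partial final record", stacklevel=2)
    data = series.data[:, : n_records * spr]
    n_sig = series.n_channels

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    header = bytearray()
    header += _ascii_field("0", 8)
    header += _ascii_field(patient_id, 80)
    header += _ascii_field(recording_id, 80)
    header += _ascii_field("01.01.20", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(256 * (1 + n_sig), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(n_records, 8)
    header += _ascii_field(1, 8)
    header += _ascii_field(n_sig, 4)
    for label in series.labels:
        header += _ascii_field(label, 16)
    header += b" " * (80 * n_sig)  # transducer
    for _ in range(n_sig):
        header += _ascii_field(series.units, 8)
    for v in pmin:
        header += _ascii_field(f"{v:.6g}"[:8], 8)
    for v in pmax:
        header += _ascii_field(f"{v:.6g}"[:8], 8)
    for _ in range(n_sig):
        header += _ascii_field(dmin, 8)
    for _ in range(n_sig):
        header += _ascii_field(dmax, 8)
    header += b" " * (80 * n_sig)  # prefiltering
    for _ in range(n_sig):
        header += _ascii_field(spr, 8)
    header += b" " * (32 * n_sig)

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")
    # (channels, records, spr) -> records-major interleaving
    blocks = digital.reshape(n_sig, n_records, spr).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(blocks.tobytes())


def read_edf(path) -> MultichannelSeries:
    """Read an EDF file into a MultichannelSeries (microvolt units)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    data = raw.get_data() * 1e6  # MNE returns volts for uV channels
    return MultichannelSeries(
        data=data, rate=float(raw.info["sfreq"]), labels=list(raw.ch_names), units="uV"
    )


_STR = h5py.string_dtype(encoding="utf-8")


def write_snirf(path, optical: OpticalRecording, subject_id: str = "X") -> None:
    """Write a two-wavelength intensity recording as SNIRF 1.0 (CW amplitude)."""
    n_ch = optical.n_channels
    n_wl = len(optical.wavelengths)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("formatVersion", data="1.0", dtype=_STR, track_times=False)
        nirs = fh.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        for key, val in (
            ("SubjectID", subject_id),
            ("MeasurementDate", "2020-01-01"),
            ("MeasurementTime", "00:00:00"),
            ("LengthUnit", "mm"),
            ("TimeUnit", "s"),
            ("FrequencyUnit", "Hz"),
        ):
            meta.create_dataset(key, data=val, dtype=_STR, track_times=False)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(optical.wavelengths, float), track_times=False)
        src = np.array([[50.0 * c, 0.0, 0.0] for c in range(n_ch)])
        det = src + np.column_stack(
            [optical.distances, np.zeros(n_ch), np.zeros(n_ch)]
        )
        probe.create_dataset("sourcePos3D", data=src, track_times=False)
        probe.create_dataset("detectorPos3D", data=det, track_times=False)
        probe.create_dataset(
            "sourceLabels", data=[f"S{c + 1}" for c in range(n_ch)], dtype=_STR, track_times=False
        )
        probe.create_dataset(
            "detectorLabels", data=[f"D{c + 1}" for c in range(n_ch)], dtype=_STR, track_times=False
        )
        data1 = nirs.create_group("data1")
        # columns: channel-major, wavelength-minor
        series = optical.intensities.reshape(n_ch * n_wl, optical.n_samples).T
        data1.create_dataset("dataTimeSeries", data=series, track_times=False)
        data1.create_dataset("time", data=np.array([0.0, 1.0 / optical.rate]), track_times=False)
        k = 0
        for c in range(n_ch):
            for w in range(n_wl):
                k += 1
                ml = data1.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=np.int32(c + 1), track_times=False)
                ml.create_dataset("detectorIndex", data=np.int32(c + 1), track_times=False)
                ml.create_dataset("wavelengthIndex", data=np.int32(w + 1), track_times=False)
                ml.create_dataset("dataType", data=np.int32(1), track_times=False)
                ml.create_dataset("dataTypeIndex", data=np.int32(1), track_times=False)


def read_snirf(path, long_threshold_mm: float = 25.0) -> OpticalRecording:
    """Read a CW-amplitude SNIRF file back into an OpticalRecording.

    Channels at source-detector distance >= ``long_threshold_mm`` are marked
    long, the rest short.
    """
    with h5py.File(path, "r") as fh:
        nirs = fh["nirs"] if "nirs" in fh else fh["nirs1"]
        probe = nirs["probe"]
        wavelengths = probe["wavelengths"][()]
        src = probe["sourcePos3D"][()]
        det = probe["detectorPos3D"][()]
        data1 = nirs["data1"]
        series = data1["dataTimeSeries"][()]
        time = data1["time"][()]
        if time.size == 2:
            rate = 1.0 / (time[1] - time[0])
        else:
            rate = 1.0 / np.median(np.diff(time))
        n_meas = series.shape[1]
        chans: dict[tuple[int, int], dict[int, int]] = {}
        for k in range(1, n_meas + 1):
            ml = data1[f"measurementList{k}"]
            key = (int(ml["sourceIndex"][()]), int(ml["detectorIndex"][()]))
            chans.setdefault(key, {})[int(ml["wavelengthIndex"][()])] = k - 1
        n_wl = len(wavelengths)
        intensities = np.empty((len(chans), n_wl, series.shape[0]))
        distances = np.empty(len(chans))
        for c, (key, by_wl) in enumerate(sorted(chans.items())):
            for w in range(n_wl):
                intensities[c, w] = series[:, by_wl[w + 1]]
            s_idx, d_idx = key
            distances[c] = np.linalg.norm(src[s_idx - 1] - det[d_idx - 1])
    roles = [LONG if d >= long_threshold_mm else SHORT for d in distances]
    return OpticalRecording(
        intensities=intensities,
        rate=float(rate),
        wavelengths=wavelengths,
        distances=distances,
        roles=roles,
    )


def write_cohort(out_dir, subjects: list[SubjectRecording], seeds=None) -> Path:
    """Write EDF + SNIRF per subject plus a JSON cohort manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": []}
    for i, subject in enumerate(subjects):
        edf_name = f"{subject.subject_id}_eeg.edf"
        snirf_name = f"{subject.subject_id}_nirs.snirf"
        write_edf(out_dir / edf_name, subject.eeg, patient_id=subject.subject_id)
        write_snirf(out_dir / snirf_name, subject.optical, subject_id=subject.subject_id)
        manifest["subjects"].append(
            {
                "subject_id": subject.subject_id,
                "group": subject.group,
                "age": subject.age,
                "seed": None if seeds is None else int(seeds[i]),
                "phase_markers": [list(m) for m in subject.phase_markers],
                "eeg_file": edf_name,
                "snirf_file": snirf_name,
            }
        )
    manifest_path = out_dir / "cohort_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_cohort(manifest_path) -> list[SubjectRecording]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    subjects = []
    for entry in manifest["subjects"]:
        eeg = read_edf(base / entry["eeg_file"])
        optical = read_snirf(base / entry["snirf_file"])
        subjects.append(
            SubjectRecording(
                subject_id=entry["subject_id"],
                group=int(entry["group"]),
                age=float(entry["age"]),
                eeg=eeg,
                optical=optical,
                phase_markers=[tuple(m) for m in entry["phase_markers"]],
            )
        )
    return subjects
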