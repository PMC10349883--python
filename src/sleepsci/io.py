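"""Readers, writers and core containers.

Signals travel as EDF (written by a small built-in 16-bit EDF writer, read
back through MNE so the round trip crosses an independent reader); hypnograms,
cohort tables, feature tables and predictions travel as plain CSV.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import log_stage
from .features import CENTRAL_CHANNELS, expected_n_features, feature_manifest

STAGE_ALPHABET = ("W", "N1", "N2", "N3", "R")
_STAGE_SYNONYMS = {
    "W": "W", "WAKE": "W",
    "N1": "N1", "N2": "N2", "N3": "N3",
    "R": "R", "REM": "R",
}

SCORE_NAMES = ("PV", "ORR", "ICA", "DCCS", "LSWM", "PSM", "PCPS",
               "total", "fluid", "crystallized")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel referenced EEG/ECG block, amplitudes in microvolts."""

    channel_labels: list[str]
    signal: np.ndarray          # channels x samples, float64, uV
    fs: float                   # Hz
    start_time: datetime.datetime | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_sec(self) -> float:
        return self.n_samples / self.fs

    def pick(self, labels) -> "Recording":
        idx = [self.channel_labels.index(l) for l in labels]
        return Recording(list(labels), self.signal[idx].copy(), self.fs,
                         self.start_time)


@dataclass
class Hypnogram:
    """One AASM stage label per 30-s epoch plus lights-off/on markers.

    ``lights_on_epoch`` is exclusive: the in-bed interval covers epochs
    [lights_off_epoch, lights_on_epoch).  When markers are absent the whole
    record is treated as in bed.
    """

    stages: list[str]
    lights_off_epoch: int = 0
    lights_on_epoch: int | None = None
    epoch_sec: float = 30.0

    def __post_init__(self):
        if self.lights_on_epoch is None:
            self.lights_on_epoch = len(self.stages)
        bad = [s for s in self.stages if s not in STAGE_ALPHABET]
        if bad:
            raise ValueError(f"stages outside alphabet {STAGE_ALPHABET}: {bad[:5]}")
        if not (0 <= self.lights_off_epoch <= self.lights_on_epoch
                <= len(self.stages)):
            raise ValueError("need 0 <= lights_off <= lights_on <= n_epochs")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def stage_array(self) -> np.ndarray:
        return np.asarray(self.stages, dtype=object)


@dataclass
class FeatureTable:
    """Subjects x named features with missingness encoded as NaN."""

    df: pd.DataFrame            # index: subject_id, columns: feature names
    electrode_set: str | None = None

    def __post_init__(self):
        if self.df.index.has_duplicates:
            raise ValueError("duplicate subject IDs in feature table")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate feature names")
        if self.electrode_set is not None:
            want = expected_n_features(self.electrode_set)
            if self.df.shape[1] != want:
                raise ValueError(
                    f"{self.electrode_set} tables need {want} features, "
                    f"got {self.df.shape[1]}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def subject_ids(self) -> list:
        return list(self.df.index)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.df.isna().to_numpy()


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path, physical_dim: str = "uV") -> None:
    """Write a uniform-rate 16-bit EDF file.

    Requires an integer sampling rate and a signal length divisible by it
    (whole 1-s data records); synthetic recordings built from whole 30-s
    epochs always satisfy both.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_samples = recording.n_samples
    if n_samples % fs != 0:
        raise ValueError("signal length must be a whole number of seconds")
    n_records = n_samples // fs
    n_sig = len(recording.channel_labels)
    start = recording.start_time or datetime.datetime(2000, 1, 1, 22, 0, 0)

    phys_min, phys_max, digital = [], [], []
    for ch in recording.signal:
        lo, hi = float(np.min(ch)), float(np.max(ch))
        if hi - lo < 1e-6:      # flat channel: avoid a degenerate gain
            lo, hi = lo - 1.0, hi + 1.0
        # shorten to fit 8-char ASCII header fields without losing range
        lo, hi = np.floor(lo * 100) / 100 - 0.01, np.ceil(hi * 100) / 100 + 0.01
        gain = (hi - lo) / (32767 - (-32768))
        dig = np.round((ch - lo) / gain + (-32768)).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)
        digital.append(dig)

    def fmt8(x: float) -> str:
        for spec in (f"{x:.2f}", f"{x:.1f}", f"{x:.0f}", f"{x:.3g}"):
            if len(spec) <= 8:
                return spec
        return f"{x:.2e}"[:8]

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field(start.strftime("%d.%m.%y"), 8),
        _edf_field(start.strftime("%H.%M.%S"), 8),
        _edf_field(256 * (1 + n_sig), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_sig, 4),
    ])
    sig_header = b"".join([
        b"".join(_edf_field(l, 16) for l in recording.channel_labels),
        b"".join(_edf_field("", 80) for _ in range(n_sig)),
        b"".join(_edf_field(physical_dim, 8) for _ in range(n_sig)),
        b"".join(_edf_field(fmt8(phys_min[i]), 8) for i in range(n_sig)),
        b"".join(_edf_field(fmt8(phys_max[i]), 8) for i in range(n_sig)),
        b"".join(_edf_field(-32768, 8) for _ in range(n_sig)),
        b"".join(_edf_field(32767, 8) for _ in range(n_sig)),
        b"".join(_edf_field("", 80) for _ in range(n_sig)),
        b"".join(_edf_field(fs, 8) for _ in range(n_sig)),
        b"".join(_edf_field("", 32) for _ in range(n_sig)),
    ])

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec in range(n_records):
            sl = slice(rec * fs, (rec + 1) * fs)
            for i in range(n_sig):
                fh.write(digital[i][sl].tobytes())
    log_stage("write_edf", path=str(path), n_channels=n_sig,
              n_samples=n_samples, fs=fs)


def read_edf(path, require_central: bool = True) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` in microvolts.

    Channels recorded at different rates are resampled by the reader to a
    single common rate.  When ``require_central`` is set, at least one
    central derivation (C3-M2 or C4-M1) must be present.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    if require_central:
        have = {l.upper().replace("EEG ", "").strip() for l in labels}
        if not any(c in have for c in CENTRAL_CHANNELS):
            raise ValueError(
                "no central EEG channel (C3-M2 or C4-M1) found; "
                f"available channels: {labels}")
    data = raw.get_data()
    # MNE stores EDF 'uV' channels in volts; misc/unknown types keep the
    # original units.  Use the recorded original units to return uV uniformly.
    orig = getattr(raw, "_orig_units", {}) or {}
    for i, lab in enumerate(labels):
        unit = str(orig.get(lab, "uV")).lower()
        if unit in ("v", "volt", "volts"):
            data[i] *= 1e6
        elif unit in ("uv", "µv", "microvolt", "microvolts", "n/a", "none"):
            # MNE rescales EEG-typed channels to volts internally
            if raw.get_channel_types([lab])[0] in ("eeg", "ecg", "eog", "emg"):
                data[i] *= 1e6
        elif unit in ("mv", "millivolt", "millivolts"):
            data[i] *= 1e3
    meas = raw.info.get("meas_date")
    start = None
    if meas is not None:
        start = meas.replace(tzinfo=None) if meas.tzinfo else meas
    rec = Recording(labels, data, float(raw.info["sfreq"]), start)
    log_stage("read_edf", path=str(path), n_channels=len(labels),
              n_samples=rec.n_samples, fs=rec.fs)
    return rec


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    pd.DataFrame({
        "epoch_index": np.arange(hypnogram.n_epochs),
        "stage": hypnogram.stages,
    }).to_csv(path, index=False)


def read_hypnogram(path, lights_off_epoch: int = 0,
                   lights_on_epoch: int | None = None) -> Hypnogram:
    """Read a (epoch_index, stage) CSV; synonyms REM->R and Wake->W accepted.

    Lights markers are not part of the CSV convention and default to the
    first/last epoch; pass them explicitly when known.
    """
    df = pd.read_csv(path)
    if "stage" not in df.columns:
        raise ValueError("hypnogram CSV needs a 'stage' column")
    stages = []
    for row_no, tok in enumerate(df["stage"].astype(str), start=2):
        key = tok.strip().upper()
        if key not in _STAGE_SYNONYMS:
            raise ValueError(
                f"unknown stage token {tok!r} at row {row_no} of {path}")
        stages.append(_STAGE_SYNONYMS[key])
    return Hypnogram(stages, lights_off_epoch, lights_on_epoch)


# ---------------------------------------------------------------------------
# Feature / cohort CSV
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path) -> None:
    """One row per subject, one column per feature; missing -> empty cell."""
    out = table.df.copy()
    out.index.name = "subject_id"
    out.to_csv(path)


def read_feature_table(path, electrode_set: str | None = None) -> FeatureTable:
    df = pd.read_csv(path, index_col="subject_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject IDs in {path}: {dups}")
    if electrode_set is None:
        for es in ("central", "all", "frontal", "occipital"):
            if list(df.columns) == feature_manifest(es):
                electrode_set = es
                break
    return FeatureTable(df.astype(float), electrode_set)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Cohort CSV: subject_id, age, sex (F/M), education, cognitive scores."""
    df = pd.read_csv(path)
    for col in ("subject_id", "age", "sex", "education"):
        if col not in df.columns:
            raise ValueError(f"cohort table missing required column {col!r}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject IDs in cohort table")
    bad = set(df["sex"].astype(str)) - {"F", "M"}
    if bad:
        raise ValueError(f"sex must be F or M, found {sorted(bad)}")
    return df
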