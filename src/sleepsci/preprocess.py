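"""Bring raw recordings to analysis-ready form.

The analysis form is: 200 Hz sampling, zero-phase 0.1-20 Hz band-pass
(4th-order Butterworth forward-backward), 30-s epochs subdivided into 15
2-s subepochs, and a per-epoch, per-channel artifact mask.  The artifact
mask is a simple amplitude/flat-line rule standing in for production
artifact removal; its thresholds are configuration-exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .config import PreprocessConfig, log_stage
from .io import Hypnogram, Recording

logger = logging.getLogger("sleepsci")

EPOCH_SEC = 30.0
SUBEPOCH_SEC = 2.0
SUBEPOCHS_PER_EPOCH = 15


@dataclass
class EpochGrid:
    """30-s epoch / 2-s subepoch boundaries plus the artifact mask."""

    n_epochs: int
    fs: float
    artifact_mask: np.ndarray   # epochs x channels, True = contaminated

    @property
    def epoch_samples(self) -> int:
        return int(round(EPOCH_SEC * self.fs))

    @property
    def subepoch_samples(self) -> int:
        return int(round(SUBEPOCH_SEC * self.fs))

    def epoch_slice(self, k: int) -> slice:
        n = self.epoch_samples
        return slice(k * n, (k + 1) * n)


def resample_to_analysis_rate(recording: Recording,
                              target_fs: float = 200.0) -> Recording:
    """Polyphase resampling to the analysis rate (default 200 Hz).

    A recording already at the target rate is returned unchanged.  Rates
    below 100 Hz cannot represent the sigma band and are rejected.
    """
    if recording.fs < 100.0:
        raise ValueError(
            f"sampling rate {recording.fs} Hz is below 100 Hz; the sigma "
            "band (11-15 Hz) needs more bandwidth headroom")
    if recording.fs == target_fs:
        return recording
    frac = Fraction(target_fs / recording.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(recording.signal, up, down, axis=1)
    log_stage("resample", fs_in=recording.fs, fs_out=target_fs,
              n_in=recording.n_samples, n_out=out.shape[1])
    return Recording(recording.channel_labels, out, target_fs,
                     recording.start_time)


def zero_phase_bandpass(x: np.ndarray, fs: float, low: float, high: float,
                        order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    The squared magnitude response of an ``order``-th Butterworth band-pass
    (the response a forward-backward pass realizes) is applied in the
    frequency domain after odd-reflection padding.  Unlike recursive
    forward-backward filtering, whose sub-Hz poles sit so close to the unit
    circle that round-off breaks time symmetry at the 1e-2 level, this is
    exactly linear-phase-free and symmetric under time reversal to machine
    precision, with no start-up transients.
    """
    x = np.asarray(x, float)
    n = x.shape[-1]
    npad = int(min(n - 1, round(3.0 * fs / low)))
    left = 2.0 * x[..., :1] - x[..., npad:0:-1]
    right = 2.0 * x[..., -1:] - x[..., -2:-npad - 2:-1]
    z = np.concatenate([left, x, right], axis=-1)
    m = z.shape[-1]
    freqs = np.fft.rfftfreq(m, 1.0 / fs)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs,
                     output="sos")
    _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
    gain = np.abs(h) ** 2
    y = np.fft.irfft(np.fft.rfft(z, axis=-1) * gain, n=m, axis=-1)
    return y[..., npad:npad + n]


def bandpass_eeg(recording: Recording, low: float = 0.1, high: float = 20.0,
                 order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of all channels."""
    out = zero_phase_bandpass(recording.signal, recording.fs, low, high,
                              order)
    log_stage("bandpass", low=low, high=high, order=order)
    return Recording(recording.channel_labels, out, recording.fs,
                     recording.start_time)


def build_epoch_grid(recording: Recording, hypnogram: Hypnogram) -> EpochGrid:
    n_from_signal = recording.n_samples // int(round(EPOCH_SEC * recording.fs))
    n_epochs = min(hypnogram.n_epochs, n_from_signal)
    mask = np.zeros((n_epochs, len(recording.channel_labels)), dtype=bool)
    return EpochGrid(n_epochs, recording.fs, mask)


def mask_artifacts(recording: Recording, grid: EpochGrid,
                   amp_thresh_uv: float = 500.0,
                   flat_sec: float = 5.0) -> EpochGrid:
    """Flag epochs with extreme amplitude or long flat stretches.

    An epoch/channel is flagged when any |sample| exceeds ``amp_thresh_uv``
    or when the signal is constant for longer than ``flat_sec`` seconds.
    Flagged epochs are excluded from every downstream feature average.
    """
    fs = recording.fs
    flat_n = int(round(flat_sec * fs))
    mask = np.zeros_like(grid.artifact_mask)
    for k in range(grid.n_epochs):
        seg = recording.signal[:, grid.epoch_slice(k)]
        mask[k] = np.abs(seg).max(axis=1) > amp_thresh_uv
        for c in range(seg.shape[0]):
            if mask[k, c]:
                continue
            const = np.abs(np.diff(seg[c])) < 1e-12
            if const.any():
                # longest run of constant samples
                run, best = 0, 0
                for v in const:
                    run = run + 1 if v else 0
                    best = max(best, run)
                if best + 1 > flat_n:
                    mask[k, c] = True
    n_flagged = int(mask.any(axis=1).sum())
    log_stage("mask_artifacts", amp_thresh_uv=amp_thresh_uv,
              flat_sec=flat_sec, n_epochs=grid.n_epochs, n_flagged=n_flagged)
    return EpochGrid(grid.n_epochs, grid.fs, mask)


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak sample indices from a band-passed ECG trace.

    Robust amplitude rule: peaks more than 4 scaled-MAD above the median,
    at least 0.3 s apart.  Returns an empty array when nothing plausible is
    found.
    """
    med = np.median(ecg)
    mad = np.median(np.abs(ecg - med)) * 1.4826
    if mad < 1e-12:
        return np.array([], dtype=int)
    height = med + 4.0 * mad
    peaks, _ = sps.find_peaks(ecg, height=height,
                              distance=int(0.3 * fs))
    return peaks


def ecg_correct(recording: Recording, ecg: np.ndarray,
                ecg_fs: float | None = None) -> Recording:
    """Subtract the QRS-locked average artifact template from each channel.

    The ECG trace is zero-phase band-pass filtered 0.3-40 Hz, R peaks are
    detected, and for each EEG channel the mean waveform in a +-0.2 s window
    around the R peaks is subtracted at every beat.  If no physiologically
    plausible R peaks are found the recording is returned unchanged with a
    warning.
    """
    fs = recording.fs
    ecg = np.asarray(ecg, float)
    if ecg_fs is not None and ecg_fs != fs:
        frac = Fraction(fs / ecg_fs).limit_denominator(10000)
        ecg = sps.resample_poly(ecg, frac.numerator, frac.denominator)
    ecg = ecg[:recording.n_samples]
    high = min(40.0, 0.45 * fs)
    sos = sps.butter(4, [0.3, high], btype="bandpass", fs=fs, output="sos")
    if np.ptp(ecg) < 1e-9:
        logger.warning("flat ECG channel; skipping ECG correction")
        return recording
    ecg_f = sps.sosfiltfilt(sos, ecg)
    peaks = detect_r_peaks(ecg_f, fs)
    dur_min = recording.duration_sec / 60.0
    if len(peaks) < max(3, 20 * dur_min):   # < 20 bpm: implausible
        logger.warning("no plausible R peaks detected; "
                       "skipping ECG correction")
        return recording
    half = int(round(0.2 * fs))
    valid = peaks[(peaks >= half) & (peaks < recording.n_samples - half)]
    out = recording.signal.copy()
    for c in range(out.shape[0]):
        segs = np.stack([out[c, p - half:p + half] for p in valid])
        template = segs.mean(axis=0)
        template = template - template.mean()
        # skip channels whose template is indistinguishable from the
        # averaging noise floor (no actual cardiac contamination)
        noise_floor = out[c].std() / np.sqrt(len(valid))
        if template.std() < 3.0 * noise_floor:
            continue
        for p in valid:
            out[c, p - half:p + half] -= template
    log_stage("ecg_correct", n_beats=len(valid))
    return Recording(recording.channel_labels, out, fs, recording.start_time)


def preprocess_recording(recording: Recording, hypnogram: Hypnogram,
                         cfg: PreprocessConfig | None = None):
    """Full preprocessing chain -> (clean Recording, EpochGrid).

    Resample to the analysis rate, optionally ECG-correct (when an ECG
    channel is present and enabled), band-pass, epoch and mask artifacts.
    The returned recording contains the EEG channels only.
    """
    cfg = cfg or PreprocessConfig()
    rec = resample_to_analysis_rate(recording, cfg.analysis_fs)
    eeg_labels = [l for l in rec.channel_labels if l.upper() != "ECG"]
    eeg = rec.pick(eeg_labels)
    if cfg.apply_ecg_correction and "ECG" in [l.upper()
                                              for l in rec.channel_labels]:
        i = [l.upper() for l in rec.channel_labels].index("ECG")
        eeg = ecg_correct(eeg, rec.signal[i])
    eeg = bandpass_eeg(eeg, cfg.bandpass_low, cfg.bandpass_high,
                       cfg.filter_order)
    grid = build_epoch_grid(eeg, hypnogram)
    grid = mask_artifacts(eeg, grid, cfg.amp_thresh_uv, cfg.flat_sec)
    return eeg, grid
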