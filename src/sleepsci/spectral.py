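"""Waveform and frequency features (the brain-age feature subset).

Per stage and electrode region this module produces 160 features:

* waveform, per channel: line length (mean absolute successive difference)
  and Pearson kurtosis of the 30-s epoch signal;
* frequency, channel-averaged within the region: relative delta/theta/alpha
  band power and the delta/theta, delta/alpha, theta/alpha ratios of
  absolute power, each summarized as {p95, min, mean, sd} across the 15
  2-s Hann-tapered subepochs of an epoch; and the Pearson kurtosis of the
  per-subepoch absolute band-power series (delta/theta/alpha/sigma) pooled
  over the stage ("spectrogram kurtosis").

Every epoch-level quantity is averaged over the stage's artifact-free
epochs; a stage with no usable epochs yields missing (NaN) features, later
imputed at the cohort level.  Relative powers are normalized by total power
in 0.5-20 Hz, the analysis band.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .config import SpectralConfig
from .features import (BANDS3, BANDS4, RATIOS, REGION_CHANNELS, STAGES, STATS,
                       spectral_feature_names)
from .io import Hypnogram, Recording
from .preprocess import SUBEPOCHS_PER_EPOCH, EpochGrid

RATIO_PAIRS = {"dt": ("delta", "theta"), "da": ("delta", "alpha"),
               "ta": ("theta", "alpha")}


def line_length(x: np.ndarray) -> float:
    """Mean absolute successive difference, in uV per sample."""
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("line length needs at least 2 samples")
    return float(np.abs(np.diff(x)).mean())


def pearson_kurtosis(x: np.ndarray) -> float:
    """m4 / m2^2 (normal -> 3); NaN for zero-variance input."""
    x = np.asarray(x, float)
    if x.size == 0 or np.ptp(x) == 0:
        return float("nan")
    c = x - x.mean()
    m2 = np.mean(c ** 2)
    if m2 == 0:
        return float("nan")
    return float(np.mean(c ** 4) / m2 ** 2)


def waveform_kurtosis(x: np.ndarray) -> float:
    return pearson_kurtosis(x)


def subepoch_band_powers(epoch_signal: np.ndarray, fs: float,
                         cfg: SpectralConfig | None = None) -> dict:
    """Absolute band powers per 2-s subepoch of one 30-s epoch.

    Returns a dict band -> array of SUBEPOCHS_PER_EPOCH values plus a
    'total' entry (power in the 0.5-20 Hz analysis band).  Powers are
    Hann-tapered periodogram sums over half-open bands [lo, hi).
    """
    cfg = cfg or SpectralConfig()
    n_sub = int(round(cfg.subepoch_sec * fs))
    x = np.asarray(epoch_signal, float)
    n_full = (x.size // n_sub) * n_sub
    subs = x[:n_full].reshape(-1, n_sub)
    freqs, psd = sps.periodogram(subs, fs=fs, window="hann", axis=1)
    out = {}
    for band, (lo, hi) in cfg.bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        out[band] = psd[:, sel].sum(axis=1)
    lo, hi = cfg.total_band
    sel = (freqs >= lo) & (freqs < hi)
    out["total"] = psd[:, sel].sum(axis=1)
    return out


def relative_band_powers(epoch_signal: np.ndarray, fs: float,
                         cfg: SpectralConfig | None = None) -> np.ndarray:
    """SUBEPOCHS x 3 relative delta/theta/alpha powers for one epoch."""
    p = subepoch_band_powers(epoch_signal, fs, cfg)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.stack([p[b] / p["total"] for b in BANDS3], axis=1)
    return rel


def two_stage_summary(values: np.ndarray) -> dict:
    """{p95, min, mean, sd} across subepochs per epoch, then epoch-averaged.

    ``values`` is (n_epochs, n_subepochs); NaN rows (epochs) are excluded.
    """
    values = np.asarray(values, float)
    ok = ~np.isnan(values).any(axis=1)
    values = values[ok]
    if values.size == 0:
        return {s: float("nan") for s in STATS}
    return {
        "p95": float(np.percentile(values, 95, axis=1).mean()),
        "min": float(values.min(axis=1).mean()),
        "mean": float(values.mean(axis=1).mean()),
        "sd": float(values.std(axis=1, ddof=1).mean()),
    }


def spectrogram_kurtosis(band_power_series: np.ndarray) -> float:
    """Pearson kurtosis of pooled subepoch band powers; NaN below 4 values."""
    x = np.asarray(band_power_series, float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        return float("nan")
    return pearson_kurtosis(x)


def extract_region_spectral(recording: Recording, hypnogram: Hypnogram,
                            grid: EpochGrid, region: str,
                            cfg: SpectralConfig | None = None) -> dict:
    """All 160 waveform/frequency features for one region (C, F or O)."""
    cfg = cfg or SpectralConfig()
    fs = recording.fs
    chans = REGION_CHANNELS[region]
    ch_idx = {c: recording.channel_labels.index(c) for c in chans}
    stages_arr = np.asarray(hypnogram.stages[:grid.n_epochs], dtype=object)

    feats = dict.fromkeys(spectral_feature_names(region), float("nan"))
    for stage in STAGES:
        ep_ids = [k for k in range(grid.n_epochs) if stages_arr[k] == stage]

        # --- waveform: per channel, unmasked epochs only ---
        for ch in chans:
            ci = ch_idx[ch]
            ll, ku = [], []
            for k in ep_ids:
                if grid.artifact_mask[k, ci]:
                    continue
                seg = recording.signal[ci, grid.epoch_slice(k)]
                ll.append(line_length(seg))
                ku.append(pearson_kurtosis(seg))
            if ll:
                feats[f"wave_{stage}_{ch}_linelength"] = float(np.mean(ll))
                feats[f"wave_{stage}_{ch}_kurtosis"] = float(np.nanmean(ku)) \
                    if not np.all(np.isnan(ku)) else float("nan")

        # --- frequency: region-averaged band powers per subepoch ---
        rel = {b: [] for b in BANDS3}
        rat = {r: [] for r in RATIOS}
        pooled = {b: [] for b in BANDS4}
        for k in ep_ids:
            use = [ch_idx[c] for c in chans
                   if not grid.artifact_mask[k, ch_idx[c]]]
            if not use:
                continue
            powers = None
            for ci in use:
                p = subepoch_band_powers(
                    recording.signal[ci, grid.epoch_slice(k)], fs, cfg)
                if powers is None:
                    powers = {b: v.astype(float) for b, v in p.items()}
                else:
                    for b in powers:
                        powers[b] += p[b]
            for b in powers:
                powers[b] /= len(use)
            with np.errstate(invalid="ignore", divide="ignore"):
                for b in BANDS3:
                    rel[b].append(powers[b] / powers["total"])
                for r, (num, den) in RATIO_PAIRS.items():
                    rat[r].append(powers[num] / powers[den])
            for b in BANDS4:
                pooled[b].append(powers[b])

        for b in BANDS3:
            if rel[b]:
                s = two_stage_summary(np.stack(rel[b]))
                for st in STATS:
                    feats[f"freq_{stage}_{region}_relpow_{b}_{st}"] = s[st]
        for r in RATIOS:
            if rat[r]:
                s = two_stage_summary(np.stack(rat[r]))
                for st in STATS:
                    feats[f"freq_{stage}_{region}_ratio_{r}_{st}"] = s[st]
        for b in BANDS4:
            if pooled[b]:
                series = np.concatenate(pooled[b])
                feats[f"freq_{stage}_{region}_speckurt_{b}"] = \
                    spectrogram_kurtosis(series)
    return feats
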