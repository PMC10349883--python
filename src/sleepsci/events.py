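"""Spindle and slow-oscillation detection and the derived feature block.

Slow oscillations follow the classical zero-crossing rule: band-pass
0.2-4.5 Hz, delimit candidates by consecutive positive-to-negative
zero-crossings, keep candidates lasting 0.8-2 s whose negative-peak
magnitude and peak-to-peak amplitude both strictly exceed the respective
medians over all duration-qualified candidates.  Detection is restricted to
artifact-free N2/N3 epochs.

The spindle detector is an envelope-threshold method (the feature contract
is the per-night spindle feature vector, not equivalence with any specific
reference detector): band-pass 11-15 Hz, analytic-signal magnitude smoothed
with a 0.1-s moving average, events where the envelope exceeds
mean + k*sd (k = 1.5 by default) of the N2/N3 envelope, gaps < 0.25 s
merged, durations confined to 0.5-3 s.

Because all thresholds are data-relative (medians, envelope z-scores), the
detectors are invariant to overall amplitude scaling.

Coupling: the slow-oscillation phase is the instantaneous (analytic) phase
of the 0.2-4.5 Hz filtered signal; a spindle overlaps an SO when its peak
falls inside the SO's zero-crossing span.  Over the n overlapping spindles
the circular mean direction, the intra-trial phase clustering magnitude
R = |mean unit phasor| and the asymptotic Rayleigh p-value exp(-n R^2) are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import SlowOscConfig, SpindleConfig, log_stage
from .features import COUPLING_FIELDS, SO_FIELDS, SPINDLE_FIELDS
from .io import Hypnogram
from .preprocess import EpochGrid


@dataclass
class SpindleEvent:
    channel: str
    start: float            # s
    end: float              # s
    peak: float             # s, envelope maximum
    amplitude: float        # uV, max peak-to-peak of band-passed segment
    mean_frequency: float   # Hz, zero-crossings / (2 * duration)
    fwhm: float             # s, envelope width at half event maximum
    n_oscillations: int
    symm2: float            # folded peak-position symmetry in [0, 1]

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SlowOscillationEvent:
    channel: str
    down_zero: float        # s, + to - crossing opening the cycle
    up_zero: float          # s, - to + crossing
    end_zero: float         # s, + to - crossing closing the cycle
    t_neg_peak: float
    t_pos_peak: float
    neg_peak_amp: float     # uV, negative
    pos_peak_amp: float     # uV, positive

    @property
    def duration(self) -> float:
        return self.end_zero - self.down_zero

    @property
    def neg_duration(self) -> float:
        return self.up_zero - self.down_zero

    @property
    def pos_duration(self) -> float:
        return self.end_zero - self.up_zero

    @property
    def slopes(self) -> dict:
        return {
            "SO_SLOPE_NEG1": self.neg_peak_amp / (self.t_neg_peak - self.down_zero),
            "SO_SLOPE_NEG2": -self.neg_peak_amp / (self.up_zero - self.t_neg_peak),
            "SO_SLOPE_POS1": self.pos_peak_amp / (self.t_pos_peak - self.up_zero),
            "SO_SLOPE_POS2": -self.pos_peak_amp / (self.end_zero - self.t_pos_peak),
        }


@dataclass
class CouplingStats:
    coupl_angle: float      # radians in (-pi, pi]
    coupl_mag: float        # ITPC in [0, 1]
    coupl_overlap: int
    coupl_pv: float         # asymptotic Rayleigh p-value


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def n2n3_sample_mask(hypnogram: Hypnogram, grid: EpochGrid,
                     channel_index: int) -> np.ndarray:
    """Boolean per-sample mask of artifact-free N2/N3 samples."""
    n = grid.n_epochs * grid.epoch_samples
    mask = np.zeros(n, dtype=bool)
    for k in range(grid.n_epochs):
        if (hypnogram.stages[k] in ("N2", "N3")
                and not grid.artifact_mask[k, channel_index]):
            mask[grid.epoch_slice(k)] = True
    return mask


def minutes_n2n3(hypnogram: Hypnogram, grid: EpochGrid,
                 channel_index: int) -> float:
    n_ep = sum(1 for k in range(grid.n_epochs)
               if hypnogram.stages[k] in ("N2", "N3")
               and not grid.artifact_mask[k, channel_index])
    return n_ep * 0.5


def _bandpass(x: np.ndarray, fs: float, band, order: int = 4) -> np.ndarray:
    from .preprocess import zero_phase_bandpass
    return zero_phase_bandpass(x, fs, band[0], band[1], order)


def so_filter(x: np.ndarray, fs: float,
              cfg: SlowOscConfig | None = None) -> np.ndarray:
    cfg = cfg or SlowOscConfig()
    return _bandpass(x, fs, cfg.band)


def so_phase(x: np.ndarray, fs: float,
             cfg: SlowOscConfig | None = None) -> np.ndarray:
    """Instantaneous phase of the SO-band filtered signal."""
    return np.angle(sps.hilbert(so_filter(x, fs, cfg)))


# ---------------------------------------------------------------------------
# slow-oscillation detection
# ---------------------------------------------------------------------------

def detect_slow_oscillations(channel_signal: np.ndarray, fs: float,
                             sample_mask: np.ndarray | None = None,
                             cfg: SlowOscConfig | None = None,
                             channel: str = "") -> list[SlowOscillationEvent]:
    """Median-threshold zero-crossing slow-oscillation detector."""
    cfg = cfg or SlowOscConfig()
    x = so_filter(np.asarray(channel_signal, float), fs, cfg)
    if sample_mask is None:
        sample_mask = np.ones(x.size, dtype=bool)

    sign = x > 0
    down = np.flatnonzero(sign[:-1] & ~sign[1:])       # + to -
    candidates = []
    for a, b in zip(down[:-1], down[1:]):
        dur = (b - a) / fs
        if not (cfg.min_duration_sec <= dur <= cfg.max_duration_sec):
            continue
        if not sample_mask[a:b + 1].all():
            continue
        seg = x[a:b + 1]
        i_neg = int(np.argmin(seg))
        # negative phase must come first: the up crossing follows the trough
        up_rel = np.flatnonzero(~sign[a:b][:-1] & sign[a:b][1:])
        up_rel = up_rel[up_rel > i_neg - 1]
        if up_rel.size == 0:
            continue
        i_up = int(up_rel[0]) + 1
        i_pos = i_up + int(np.argmax(seg[i_up:]))
        if not (0 < i_neg < i_up <= i_pos < seg.size - 1):
            continue
        neg_amp = float(seg[i_neg])
        pos_amp = float(seg[i_pos])
        if pos_amp <= 0 or neg_amp >= 0:
            continue
        candidates.append(SlowOscillationEvent(
            channel, a / fs, (a + i_up) / fs, b / fs,
            (a + i_neg) / fs, (a + i_pos) / fs, neg_amp, pos_amp))

    events = apply_median_criteria(candidates)
    log_stage("detect_slow_oscillations", n_candidates=len(candidates),
              n_events=len(events))
    return events


def apply_median_criteria(candidates: list) -> list:
    """Keep candidates strictly above both median amplitude thresholds.

    Strict inequality means a perfectly homogeneous candidate pool yields
    no events: nothing stands out from its own median.
    """
    if not candidates:
        return []
    neg_mags = np.array([-c.neg_peak_amp for c in candidates])
    p2p = np.array([c.pos_peak_amp - c.neg_peak_amp for c in candidates])
    med_neg, med_p2p = np.median(neg_mags), np.median(p2p)
    return [c for c, nm, pp in zip(candidates, neg_mags, p2p)
            if nm > med_neg and pp > med_p2p]


def so_features(events: list[SlowOscillationEvent],
                minutes: float) -> dict:
    """Count, medians of morphology and slopes, and rate per minute."""
    out = dict.fromkeys(SO_FIELDS, float("nan"))
    if not events:
        return out
    out["SO"] = float(len(events))
    out["SO_AMP"] = float(np.median([e.neg_peak_amp for e in events]))
    out["SO_DUR"] = float(np.median([e.duration for e in events]))
    out["SO_NEG_DUR"] = float(np.median([e.neg_duration for e in events]))
    out["SO_POS_DUR"] = float(np.median([e.pos_duration for e in events]))
    out["SO_RATE"] = len(events) / minutes if minutes > 0 else float("nan")
    for key in ("SO_SLOPE_NEG1", "SO_SLOPE_NEG2",
                "SO_SLOPE_POS1", "SO_SLOPE_POS2"):
        out[key] = float(np.median([e.slopes[key] for e in events]))
    return out


# ---------------------------------------------------------------------------
# spindle detection
# ---------------------------------------------------------------------------

def detect_spindles(channel_signal: np.ndarray, fs: float,
                    sample_mask: np.ndarray | None = None,
                    cfg: SpindleConfig | None = None,
                    channel: str = "") -> list[SpindleEvent]:
    """Envelope-threshold spindle detector on artifact-free N2/N3."""
    cfg = cfg or SpindleConfig()
    x = _bandpass(np.asarray(channel_signal, float), fs, cfg.band)
    if sample_mask is None:
        sample_mask = np.ones(x.size, dtype=bool)
    env = np.abs(sps.hilbert(x))
    w = max(int(round(cfg.envelope_smooth_sec * fs)), 1)
    env = np.convolve(env, np.ones(w) / w, mode="same")

    ref = env[sample_mask]
    if ref.size == 0:
        return []
    thresh = ref.mean() + cfg.threshold_sd * ref.std()
    above = (env > thresh) & sample_mask

    # contiguous runs
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)

    # merge gaps shorter than merge_gap_sec
    merged = []
    gap = cfg.merge_gap_sec * fs
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_n = int(round(cfg.min_duration_sec * fs))
    max_n = int(round(cfg.max_duration_sec * fs))
    events = []
    for s, e in merged:
        if e - s < min_n:
            continue
        if e - s > max_n:   # truncate around the envelope peak
            pk = s + int(np.argmax(env[s:e]))
            s = max(s, pk - max_n // 2)
            e = s + max_n
        seg = x[s:e]
        seg_env = env[s:e]
        i_peak = int(np.argmax(seg_env))
        dur = (e - s) / fs
        zc_idx = np.flatnonzero(np.diff(np.signbit(seg)))
        zc = int(zc_idx.size)
        if zc >= 2:
            # crossing-span rate: unbiased by partial edge periods
            span = (zc_idx[-1] - zc_idx[0]) / fs
            freq = (zc - 1) / (2.0 * span) if span > 0 else float("nan")
        else:
            freq = float("nan")
        peak_env = seg_env[i_peak]
        half = peak_env / 2.0
        lo = i_peak
        while lo > 0 and seg_env[lo] > half:
            lo -= 1
        hi = i_peak
        while hi < seg_env.size - 1 and seg_env[hi] > half:
            hi += 1
        fwhm = (hi - lo) / fs
        symm = i_peak / max(seg.size - 1, 1)
        events.append(SpindleEvent(
            channel=channel,
            start=s / fs, end=e / fs, peak=(s + i_peak) / fs,
            amplitude=float(np.ptp(seg)),
            mean_frequency=freq,
            fwhm=fwhm,
            n_oscillations=zc // 2,
            symm2=2.0 * abs(symm - 0.5),
        ))
    log_stage("detect_spindles", n_events=len(events),
              threshold=round(float(thresh), 3))
    return events


def spindle_features(events: list[SpindleEvent], minutes: float) -> dict:
    """Means across events; DENS = count per minute of N2/N3."""
    out = dict.fromkeys(SPINDLE_FIELDS, float("nan"))
    if not events:
        return out
    out["AMP"] = float(np.mean([e.amplitude for e in events]))
    out["DENS"] = len(events) / minutes if minutes > 0 else float("nan")
    out["DUR"] = float(np.mean([e.duration for e in events]))
    out["FFT"] = float(np.mean([e.mean_frequency for e in events]))
    out["FWHM"] = float(np.mean([e.fwhm for e in events]))
    out["NOSC"] = float(np.mean([e.n_oscillations for e in events]))
    out["SYMM2"] = float(np.mean([e.symm2 for e in events]))
    return out


# ---------------------------------------------------------------------------
# coupling
# ---------------------------------------------------------------------------

def circular_stats(phases: np.ndarray) -> CouplingStats:
    """Circular mean, ITPC magnitude and asymptotic Rayleigh p-value."""
    phases = np.asarray(phases, float)
    n = phases.size
    if n == 0:
        return CouplingStats(float("nan"), float("nan"), 0, float("nan"))
    phasor = np.exp(1j * phases).mean()
    r = float(np.abs(phasor))
    return CouplingStats(float(np.angle(phasor)), r, n,
                         float(np.exp(-n * r ** 2)))


def spindle_so_coupling(spindles: list[SpindleEvent],
                        sos: list[SlowOscillationEvent],
                        phase_signal: np.ndarray, fs: float) -> CouplingStats:
    """Coupling statistics over spindles whose peak lies inside an SO."""
    if not spindles or not sos:
        return CouplingStats(float("nan"), float("nan"), 0, float("nan"))
    intervals = [(e.down_zero, e.end_zero) for e in sos]
    phases = []
    for sp in spindles:
        if any(a <= sp.peak <= b for a, b in intervals):
            i = min(int(round(sp.peak * fs)), phase_signal.size - 1)
            phases.append(phase_signal[i])
    return circular_stats(np.asarray(phases))


def coupling_features(stats: CouplingStats) -> dict:
    return {
        "COUPL_ANGLE": stats.coupl_angle,
        "COUPL_MAG": stats.coupl_mag,
        "COUPL_OVERLAP": float(stats.coupl_overlap),
        "COUPL_PV": stats.coupl_pv,
    }


def extract_event_features(recording, hypnogram: Hypnogram, grid: EpochGrid,
                           spindle_cfg: SpindleConfig | None = None,
                           so_cfg: SlowOscConfig | None = None) -> dict:
    """The 42-entry spindle/coupling/SO block on the two central channels."""
    from .features import CENTRAL_CHANNELS
    feats = {}
    for ch in CENTRAL_CHANNELS:
        ci = recording.channel_labels.index(ch)
        x = recording.signal[ci]
        mask = n2n3_sample_mask(hypnogram, grid, ci)
        mins = minutes_n2n3(hypnogram, grid, ci)
        sps_events = detect_spindles(x, recording.fs, mask, spindle_cfg, ch)
        so_events = detect_slow_oscillations(x, recording.fs, mask, so_cfg, ch)
        phase = so_phase(x, recording.fs, so_cfg)
        cp = spindle_so_coupling(sps_events, so_events, phase, recording.fs)
        for k, v in spindle_features(sps_events, mins).items():
            feats[f"sp_{ch}_{k}"] = v
        for k, v in coupling_features(cp).items():
            feats[f"coupl_{ch}_{k}"] = v
        for k, v in so_features(so_events, mins).items():
            feats[f"so_{ch}_{k}"] = v
    assert len(feats) == 2 * (len(SPINDLE_FIELDS) + len(COUPLING_FIELDS)
                              + len(SO_FIELDS))
    return feats


def events_to_frame(events) -> "pd.DataFrame":
    """Per-event table for CSV export / detector benchmarking."""
    import pandas as pd
    rows = []
    for e in events:
        row = {"type": type(e).__name__}
        row.update(vars(e))
        rows.append(row)
    return pd.DataFrame(rows)
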