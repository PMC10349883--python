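"""Canonical feature-name manifest.

The full feature vector concatenates three blocks in a fixed order:

1. 10 sleep-macrostructure features from the hypnogram.
2. 42 spindle / coupling / slow-oscillation features, computed on the two
   central channels only (21 per channel), regardless of electrode set.
3. 160 waveform + frequency features per electrode region (central; plus
   frontal and occipital in the all-electrode set).  Per region:
   2 channels x 5 stages x 2 waveform features (20), 4 statistics x 3 bands
   x 5 stages relative powers (60), 4 statistics x 3 ratios x 5 stages (60),
   and 4 bands x 5 stages spectrogram kurtosis (20).  Waveform features are
   per channel; frequency features are averaged over the region's channels —
   the only split consistent with the 160-per-region accounting.

Totals: 10 + 42 + 160 = 212 (central only) and 10 + 42 + 3*160 = 532 (all).
"""

from __future__ import annotations

STAGES = ("W", "N1", "N2", "N3", "R")
BANDS3 = ("delta", "theta", "alpha")
BANDS4 = ("delta", "theta", "alpha", "sigma")
RATIOS = ("dt", "da", "ta")  # delta/theta, delta/alpha, theta/alpha
STATS = ("p95", "min", "mean", "sd")

REGION_CHANNELS = {
    "C": ("C3-M2", "C4-M1"),
    "F": ("F3-M2", "F4-M1"),
    "O": ("O1-M2", "O2-M1"),
}
CENTRAL_CHANNELS = REGION_CHANNELS["C"]

MACRO_FEATURES = (
    "TST", "WASO", "SE", "TTB", "SL", "RL",
    "Perc_N1", "Perc_N2", "Perc_N3", "Perc_R",
)

SPINDLE_FIELDS = ("AMP", "DENS", "DUR", "FFT", "FWHM", "NOSC", "SYMM2")
COUPLING_FIELDS = ("COUPL_ANGLE", "COUPL_MAG", "COUPL_OVERLAP", "COUPL_PV")
SO_FIELDS = (
    "SO", "SO_AMP", "SO_DUR", "SO_NEG_DUR", "SO_POS_DUR", "SO_RATE",
    "SO_SLOPE_NEG1", "SO_SLOPE_NEG2", "SO_SLOPE_POS1", "SO_SLOPE_POS2",
)

# Feature domains of the brain-age comparator: waveform + frequency only.
BAI_PREFIXES = ("wave_", "freq_")


def event_feature_names() -> list[str]:
    """42 spindle/coupling/SO names, central channels only."""
    names = []
    for ch in CENTRAL_CHANNELS:
        names += [f"sp_{ch}_{f}" for f in SPINDLE_FIELDS]
        names += [f"coupl_{ch}_{f}" for f in COUPLING_FIELDS]
        names += [f"so_{ch}_{f}" for f in SO_FIELDS]
    return names


def spectral_feature_names(region: str) -> list[str]:
    """160 waveform/frequency names for one region code (C, F or O)."""
    if region not in REGION_CHANNELS:
        raise KeyError(f"unknown region {region!r}; expected one of C, F, O")
    names = []
    for stage in STAGES:
        for ch in REGION_CHANNELS[region]:
            names.append(f"wave_{stage}_{ch}_linelength")
            names.append(f"wave_{stage}_{ch}_kurtosis")
    for stage in STAGES:
        for band in BANDS3:
            for stat in STATS:
                names.append(f"freq_{stage}_{region}_relpow_{band}_{stat}")
    for stage in STAGES:
        for ratio in RATIOS:
            for stat in STATS:
                names.append(f"freq_{stage}_{region}_ratio_{ratio}_{stat}")
    for stage in STAGES:
        for band in BANDS4:
            names.append(f"freq_{stage}_{region}_speckurt_{band}")
    return names


#: Spectral regions included per electrode set.  The spindle/coupling/SO
#: block always comes from the central channels (ablation sets swap only
#: the waveform/frequency region).
ELECTRODE_SETS = {
    "central": ("C",),
    "frontal": ("F",),
    "occipital": ("O",),
    "all": ("C", "F", "O"),
}


def feature_manifest(electrode_set: str = "central") -> list[str]:
    """Deterministic ordered feature names for an electrode set.

    'central'/'frontal'/'occipital' -> 212 names; 'all' -> 532 names.
    """
    regions = ELECTRODE_SETS.get(electrode_set)
    if regions is None:
        raise ValueError(
            f"electrode_set must be one of {sorted(ELECTRODE_SETS)}, "
            f"got {electrode_set!r}")
    names = list(MACRO_FEATURES) + event_feature_names()
    for region in regions:
        names += spectral_feature_names(region)
    return names


def expected_n_features(electrode_set: str) -> int:
    return {"central": 212, "frontal": 212, "occipital": 212,
            "all": 532}[electrode_set]
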