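"""Hypnogram-derived sleep-architecture features.

Ten AASM-style macrostructure measures computed from the staged 30-s epochs
within the lights-off/lights-on interval: total sleep time (TST), wake after
sleep onset (WASO), sleep efficiency (SE = TST / time in bed), total time in
bed (TTB), sleep latency (SL), REM latency (RL, measured from lights off),
and the percentage of TST spent in N1/N2/N3/R.

Degenerate nights are reported honestly: with no sleep epochs TST = 0,
SE = 0 and both latencies are missing (NaN), to be imputed downstream.
"""

from __future__ import annotations

import math

import numpy as np

from .features import MACRO_FEATURES
from .io import Hypnogram

EPOCH_MIN = 0.5  # one 30-s epoch in minutes

SLEEP_STAGES = ("N1", "N2", "N3", "R")


def compute_macrostructure(hypnogram: Hypnogram,
                           rem_latency_from_onset: bool = False) -> dict:
    """Compute the 10 macrostructure features; missing values are NaN."""
    lo, hi = hypnogram.lights_off_epoch, hypnogram.lights_on_epoch
    in_bed = hypnogram.stages[lo:hi]
    ttb = EPOCH_MIN * len(in_bed)

    sleep_flags = [s in SLEEP_STAGES for s in in_bed]
    tst = EPOCH_MIN * sum(sleep_flags)

    out = dict.fromkeys(MACRO_FEATURES, math.nan)
    out["TTB"] = ttb
    out["TST"] = tst
    out["SE"] = tst / ttb if ttb > 0 else 0.0

    if tst == 0:
        out["WASO"] = 0.0
        out["SE"] = 0.0
        return out

    first_sleep = sleep_flags.index(True)
    out["SL"] = EPOCH_MIN * first_sleep
    rem_positions = [i for i, s in enumerate(in_bed) if s == "R"]
    if rem_positions:
        origin = first_sleep if rem_latency_from_onset else 0
        out["RL"] = EPOCH_MIN * (rem_positions[0] - origin)
    out["WASO"] = EPOCH_MIN * sum(
        1 for s in in_bed[first_sleep:] if s == "W")
    for stage in ("N1", "N2", "N3", "R"):
        t = EPOCH_MIN * sum(1 for s in in_bed if s == stage)
        out[f"Perc_{stage}"] = 100.0 * t / tst
    return out


def macrostructure_vector(hypnogram: Hypnogram, **kw) -> np.ndarray:
    feats = compute_macrostructure(hypnogram, **kw)
    return np.array([feats[k] for k in MACRO_FEATURES])
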