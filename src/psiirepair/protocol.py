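"""Shared light-treatment protocol constants.

The standard photoinactivation/repair assay exposes a concentrated cell
suspension to ten sequential 330-s periods of actinic light: one dark period,
one at the 30 umol photons m-2 s-1 acclimation level, then eight at the
260 umol photons m-2 s-1 treatment level, for a cumulative 2640 s of
treatment light.  Fluorescence decay series are expressed on the
treatment-light clock (t = 0 at the start of the first 260-umol period).
"""

from __future__ import annotations

import numpy as np

PERIOD_S = 330.0
HL_PERIODS = 8
N_PERIODS = 10

DARK_LIGHT = 0.0
ACCLIMATION_LIGHT = 30.0  # umol photons m-2 s-1
TREATMENT_LIGHT = 260.0  # umol photons m-2 s-1

#: Cumulative seconds of treatment light over the protocol (8 x 330 s).
TREATMENT_S = HL_PERIODS * PERIOD_S

#: Irradiance applied during each of the ten 330-s periods, in protocol order.
IRRADIANCE_SCHEDULE = (DARK_LIGHT, ACCLIMATION_LIGHT) + (TREATMENT_LIGHT,) * HL_PERIODS


def decay_times() -> np.ndarray:
    """Measurement times on the treatment-light clock, in seconds.

    One point at t = 0 (the last measurement before treatment light) plus one
    at the end of each of the eight treatment-light periods.
    """
    return np.arange(HL_PERIODS + 1, dtype=float) * PERIOD_S


def irradiance_segments() -> list[tuple[float, float, float]]:
    """(start_s, end_s, irradiance) segments on the full protocol clock."""
    segments = []
    t = 0.0
    for irradiance in IRRADIANCE_SCHEDULE:
        segments.append((t, t + PERIOD_S, irradiance))
        t += PERIOD_S
    return segments
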