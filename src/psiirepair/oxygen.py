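"""Oxygen-based PSII quantitation and steady-state exchange rates.

A saturating single-turnover flash advances every active centre's S-state
cycle once; four advances evolve one O2, so [PSII] = 4 x (O2 per flash).
Flash-yield PSII concentrations (umol mL-1) convert to fmol per ug total
protein through the extract geometry:

    fmol ug-1 = umol PSII mL-1 * mL culture pelleted * 1e9 fmol/umol
                / uL extract volume / (ug protein uL-1)

Steady-state O2 exchange is the slope of dissolved O2 versus time within a
constant-irradiance segment (evolution positive, consumption negative);
a Theil-Sen slope is the default because optode traces carry drift spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import TREATMENT_S

__all__ = [
    "ExtractGeometry",
    "psii_from_flash_yield",
    "psii_per_ug",
    "psii_conc_from_per_ug",
    "steady_state_rate",
    "o2_per_psii",
    "analyze_oxygen",
]

#: electrons (= S-state advances) required per O2 evolved
TURNOVERS_PER_O2 = 4.0
FMOL_PER_UMOL = 1e9


@dataclass(frozen=True)
class ExtractGeometry:
    """Volumes and protein concentration linking culture to extract."""

    culture_volume_ml: float = 2.0
    extract_volume_ul: float = 400.0
    protein_conc_ug_per_ul: float = 0.5

    def __post_init__(self):
        for f in ("culture_volume_ml", "extract_volume_ul",
                  "protein_conc_ug_per_ul"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def psii_from_flash_yield(o2_per_flash: float) -> float:
    """[PSII] in umol mL-1 from O2 evolved per saturating flash (umol mL-1)."""
    if o2_per_flash < 0:
        raise ValueError("flash yield must be >= 0")
    return TURNOVERS_PER_O2 * o2_per_flash


def psii_per_ug(psii_umol_per_ml: float, geom: ExtractGeometry) -> float:
    """Convert a PSII concentration to fmol per ug total protein."""
    return (psii_umol_per_ml * geom.culture_volume_ml * FMOL_PER_UMOL
            / geom.extract_volume_ul / geom.protein_conc_ug_per_ul)


def psii_conc_from_per_ug(content_fmol_per_ug: float,
                          geom: ExtractGeometry) -> float:
    """Inverse of :func:`psii_per_ug` (used by the synthetic generator)."""
    return (content_fmol_per_ug * geom.extract_volume_ul
            * geom.protein_conc_ug_per_ul
            / geom.culture_volume_ml / FMOL_PER_UMOL)


def steady_state_rate(times_s, o2_umol_per_ml, method: str = "theil") -> float:
    """O2 exchange rate within one irradiance segment, umol mL-1 s-1."""
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(o2_umol_per_ml, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 points in the segment")
    if method == "theil":
        return float(stats.theilslopes(y, t).slope)
    if method == "ols":
        return float(stats.linregress(t, y).slope)
    raise ValueError(f"unknown slope method {method!r}")


def o2_per_psii(rate: float, psii_umol_per_ml: float) -> float:
    """O2 evolved per PSII per second (both sides in umol mL-1 units)."""
    if psii_umol_per_ml <= 0:
        raise ValueError("PSII concentration must be positive")
    return rate / psii_umol_per_ml


def analyze_oxygen(series: pd.DataFrame, flash_yields: pd.DataFrame,
                   geom: ExtractGeometry | None = None,
                   treatment_s: float = TREATMENT_S,
                   method: str = "theil") -> pd.DataFrame:
    """Per-replicate oxygen metrics from optode series and flash yields.

    ``series`` columns: replicate_id, strain_id, growth_light, time_s,
    o2_umol_per_ml, segment_label.  ``flash_yields`` columns: replicate_id,
    strain_id, growth_light, when (pre|post), lincomycin, o2_per_flash,
    n_flashes.

    Returns one row per replicate with pre/post PSII concentrations (and per
    ug contents), the PSII-loss constant k_PSII from the +lincomycin flash
    yields, and O2 per PSII at the start (acclimation segment over the
    pre-treatment PSII pool) and end (last treatment segment over the
    remaining, -lincomycin pool) of the time course.
    """
    geom = geom or ExtractGeometry()
    rows = []
    keys = ["strain_id", "growth_light", "replicate_id"]
    for (strain, light, rep), fy in flash_yields.groupby(keys, sort=True):

        def _yield(when, linco):
            sel = fy[(fy["when"] == when)
                     & (fy["lincomycin"].astype(bool) == linco)]
            return float(sel["o2_per_flash"].iloc[0]) if len(sel) else np.nan

        psii_pre = psii_from_flash_yield(_yield("pre", False))
        post_linco_fy = _yield("post", True)
        post_nolinco_fy = _yield("post", False)
        psii_post_linco = (psii_from_flash_yield(post_linco_fy)
                           if np.isfinite(post_linco_fy) else np.nan)
        psii_post = (psii_from_flash_yield(post_nolinco_fy)
                     if np.isfinite(post_nolinco_fy) else np.nan)

        k_psii = np.nan
        if psii_pre > 0 and psii_post_linco > 0:
            k_psii = (np.log(psii_pre) - np.log(psii_post_linco)) / treatment_s

        seg = series[(series["strain_id"] == strain)
                     & (series["growth_light"] == light)
                     & (series["replicate_id"] == rep)]
        def _slope(label):
            s = seg[seg["segment_label"] == label]
            if len(s) < 5:
                return np.nan
            return steady_state_rate(s["time_s"], s["o2_umol_per_ml"], method)

        rate_start = _slope("acclimation")
        rate_end = _slope(f"treatment_8")
        o2_psii_start = (o2_per_psii(rate_start, psii_pre)
                         if psii_pre > 0 and np.isfinite(rate_start) else np.nan)
        o2_psii_end = (o2_per_psii(rate_end, psii_post)
                       if psii_post > 0 and np.isfinite(rate_end) else np.nan)

        rows.append({
            "replicate_id": rep, "strain_id": strain, "growth_light": light,
            "psii_pre_umol_ml": psii_pre,
            "psii_post_umol_ml": psii_post,
            "psii_pre_fmol_ug": psii_per_ug(psii_pre, geom),
            "psii_post_fmol_ug": (psii_per_ug(psii_post, geom)
                                  if np.isfinite(psii_post) else np.nan),
            "k_psii": k_psii,
            "o2_per_psii_start": o2_psii_start,
            "o2_per_psii_end": o2_psii_end,
            "rate_dark": _slope("dark_pre"),
        })
    return pd.DataFrame(rows)
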