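"""Quantitative immunoblot calibration, stoichiometry and turnover rates.

Band signals are calibrated against fmol standards loaded on the same blot
(7-250 fmol design range), expressed as fmol target per ug total protein,
and combined into the stoichiometry ratios (PsbA:PsbD, FtsH hexamer:PsbA)
and the lincomycin-chase turnover quantities:

    k_removal       = (ln c_T0 - ln c_Tlinco) / T_treatment        (s-1)
    removal rate    = k_removal * c_T0                (fmol ug-1 s-1)
    synthesis rate  = (c_T,-linco - c_T,+linco) / T   (fmol ug-1 s-1)
    accumulation    = (c_final - c_initial) / T       (fmol ug-1 s-1)

Negative values are meaningful (net accumulation under lincomycin) and are
never clipped.  Calibration is strictly per blot and per target: ECL
detection does not transfer across membranes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import TREATMENT_S

__all__ = [
    "TARGETS",
    "StandardCurve",
    "fit_standard_curve",
    "quantify",
    "QuantResult",
    "hexamer_content",
    "stoichiometry",
    "StoichiometryResult",
    "removal_rate_constant",
    "removal_rate",
    "synthesis_rate",
    "accumulation_rate",
    "qc_flag_extracts",
    "calibrate_blots",
    "protein_rates",
    "stoichiometry_table",
]

TARGETS = ("PsbA", "PsbD", "FtsH")

#: design range of the fmol standards (per load)
STANDARD_FMOL_MIN = 7.0
STANDARD_FMOL_MAX = 250.0

#: quantitation refuses silently beyond this multiple of the calibrated range
EXTRAPOLATION_FACTOR = 1.5


@dataclass(frozen=True)
class StandardCurve:
    """Per-blot linear calibration of band signal against fmol load."""

    target: str
    slope: float  # signal per fmol
    intercept: float  # background signal
    r_squared: float
    fmol_min: float
    fmol_max: float
    blot_id: str = ""


def fit_standard_curve(fmol, signal, target: str = "PsbA",
                       blot_id: str = "") -> StandardCurve:
    """Ordinary least-squares line of band signal on fmol standard load.

    Requires >= 3 standards with positive loads spanning at least one order
    of magnitude; a non-positive slope means a non-responsive blot.
    """
    fmol = np.asarray(fmol, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if fmol.size < 3:
        raise ValueError("need at least 3 standard points")
    if np.any(fmol <= 0):
        raise ValueError("standard loads must be positive fmol")
    if fmol.max() / fmol.min() < 10.0:
        raise ValueError("standards must span at least one order of magnitude")
    res = stats.linregress(fmol, signal)
    if res.slope <= 0:
        raise ValueError("non-responsive blot: calibration slope <= 0")
    return StandardCurve(target=target, slope=float(res.slope),
                         intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2),
                         fmol_min=float(fmol.min()), fmol_max=float(fmol.max()),
                         blot_id=blot_id)


class QuantResult(NamedTuple):
    content: float  # fmol per ug total protein
    extrapolated: bool


def quantify(signal: float, curve: StandardCurve, load_ug: float) -> QuantResult:
    """Invert the calibration: content = ((signal - b)/m) / load.

    Signals implying fmol beyond ``EXTRAPOLATION_FACTOR`` x the calibrated
    range are flagged but the value is still returned.
    """
    if load_ug <= 0:
        raise ValueError("protein load must be positive")
    fmol = (signal - curve.intercept) / curve.slope
    out_of_range = (fmol > curve.fmol_max * EXTRAPOLATION_FACTOR
                    or fmol < curve.fmol_min / EXTRAPOLATION_FACTOR)
    return QuantResult(content=float(fmol / load_ug),
                       extrapolated=bool(out_of_range))


def hexamer_content(ftsh_monomer_content: float) -> float:
    """FtsH hexamer content inferred from total monomer content (/6)."""
    if ftsh_monomer_content < 0:
        raise ValueError("monomer content must be >= 0")
    return ftsh_monomer_content / 6.0


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class StoichiometryResult:
    psba_psbd_ratio: float | None
    ftsh_hexamer_content: float
    hexamer_per_psba: float | None
    psii_per_hexamer: int | None


def stoichiometry(psba: float, psbd: float,
                  ftsh_hexamer: float) -> StoichiometryResult:
    """Stoichiometry ratios from per-ug contents of one extract.

    ``psii_per_hexamer`` is the nearest integer (half away from zero) of
    1/(hexamer:PsbA); undefined ratios are reported as None, not NaN.
    """
    psba_psbd = psba / psbd if psbd > 0 else None
    if psba > 0:
        hex_per_psba = ftsh_hexamer / psba
        psii_per_hex = (_round_half_away(1.0 / hex_per_psba)
                        if hex_per_psba > 0 else None)
    else:
        hex_per_psba = None
        psii_per_hex = None
    return StoichiometryResult(psba_psbd_ratio=psba_psbd,
                               ftsh_hexamer_content=ftsh_hexamer,
                               hexamer_per_psba=hex_per_psba,
                               psii_per_hexamer=psii_per_hex)


def removal_rate_constant(c_t0: float, c_tlinco: float, t_s: float) -> float:
    """First-order removal constant, (ln c_T0 - ln c_Tlinco)/T, s-1.

    Negative when content rose under lincomycin (net accumulation).
    """
    if c_t0 <= 0 or c_tlinco <= 0:
        raise ValueError("contents must be positive (log undefined otherwise)")
    if t_s <= 0:
        raise ValueError("treatment time must be positive")
    return (math.log(c_t0) - math.log(c_tlinco)) / t_s


def removal_rate(k: float, c_t0: float) -> float:
    """Removal rate = rate constant x initial content, fmol ug-1 s-1."""
    return k * c_t0


def synthesis_rate(c_nolinco_t: float, c_linco_t: float, t_s: float) -> float:
    """(content without lincomycin - content with lincomycin) / T."""
    if t_s <= 0:
        raise ValueError("treatment time must be positive")
    return (c_nolinco_t - c_linco_t) / t_s


def accumulation_rate(c_final: float, c_initial: float, t_s: float) -> float:
    """(final content - initial content) / T, sign preserved."""
    if t_s <= 0:
        raise ValueError("treatment time must be positive")
    return (c_final - c_initial) / t_s


def qc_flag_extracts(psba: float, psii_active: float,
                     qc_factor: float = 1.0) -> str:
    """Flag extracts whose active-PSII count exceeds the PsbA copy number.

    One PsbA copy per active centre is a physical ceiling; measurements beyond
    ``qc_factor`` x PsbA indicate an unreliable protein determination (e.g.
    incomplete cell disruption).  The boundary is inclusive: equality keeps.
    """
    return "flag" if psii_active > qc_factor * psba else "keep"


_BLOT_COLUMNS = ["blot_id", "target", "lane_type", "fmol_load", "replicate_id",
                 "strain_id", "growth_light", "timepoint", "lincomycin",
                 "band_signal", "ug_load"]


def calibrate_blots(blots: pd.DataFrame) -> pd.DataFrame:
    """Calibrate every sample lane against its own blot's standards.

    Input is the long blot table (one row per lane, ``lane_type`` standard or
    sample).  Sample lanes of the same physical sample (same blot, replicate,
    timepoint, lincomycin status) may appear at several protein loads; their
    calibrated contents are averaged.  Returns one row per sample with
    ``content_fmol_per_ug`` and an extrapolation flag.
    """
    missing = [c for c in _BLOT_COLUMNS if c not in blots.columns]
    if missing:
        raise ValueError(f"blot table missing columns: {missing}")

    out_rows = []
    for (blot_id, target), grp in blots.groupby(["blot_id", "target"],
                                                sort=True):
        std = grp[grp["lane_type"] == "standard"]
        samples = grp[grp["lane_type"] == "sample"]
        curve = fit_standard_curve(std["fmol_load"].to_numpy(),
                                   std["band_signal"].to_numpy(),
                                   target=target, blot_id=str(blot_id))
        keys = ["replicate_id", "strain_id", "growth_light", "timepoint",
                "lincomycin"]
        for key_vals, lanes in samples.groupby(keys, sort=True, dropna=False):
            quants = [quantify(row.band_signal, curve, row.ug_load)
                      for row in lanes.itertuples()]
            rec = dict(zip(keys, key_vals))
            rec.update({
                "blot_id": blot_id, "target": target,
                "content_fmol_per_ug": float(np.mean([q.content
                                                      for q in quants])),
                "extrapolated": bool(any(q.extrapolated for q in quants)),
                "n_lanes": len(quants),
                "curve_r_squared": curve.r_squared,
            })
            out_rows.append(rec)
    return pd.DataFrame(out_rows)


def protein_rates(contents: pd.DataFrame,
                  treatment_s: float = TREATMENT_S) -> pd.DataFrame:
    """Per-replicate turnover quantities for PsbA and PsbD.

    ``contents`` is the calibrated table from :func:`calibrate_blots`; needs
    timepoints ``T0`` (pre-treatment), and ``T`` with and without lincomycin.
    Rows with non-positive contents where a log is required get NaN constants
    and a flag, never an exception at table level.
    """
    rows = []
    keys = ["strain_id", "growth_light", "replicate_id", "target"]
    for (strain, light, rep, target), grp in contents.groupby(keys, sort=True):
        if target not in ("PsbA", "PsbD"):
            continue

        def _content(timepoint, linco=None):
            sel = grp[grp["timepoint"] == timepoint]
            if linco is not None:
                sel = sel[sel["lincomycin"].astype(bool) == linco]
            return float(sel["content_fmol_per_ug"].iloc[0]) if len(sel) else np.nan

        c0 = _content("T0")
        cl = _content("T", True)
        cn = _content("T", False)
        flags = []
        if np.isnan(c0) or np.isnan(cl) or np.isnan(cn):
            flags.append("incomplete_timepoints")
        if c0 > 0 and cl > 0:
            k = removal_rate_constant(c0, cl, treatment_s)
            rate = removal_rate(k, c0)
        else:
            k = rate = np.nan
            flags.append("nonpositive_content")
        rows.append({
            "strain_id": strain, "growth_light": light, "replicate_id": rep,
            "target": target, "c_t0": c0, "c_t_linco": cl, "c_t_nolinco": cn,
            "k_removal": k, "removal_rate": rate,
            "synthesis_rate": (cn - cl) / treatment_s,
            "accumulation_rate": (cn - c0) / treatment_s,
            "flags": ";".join(flags),
        })
    return pd.DataFrame(rows)


def protein_rates_summary(rates: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SEM of the turnover quantities over replicates."""
    def sem(x):
        x = np.asarray(x, float)
        x = x[np.isfinite(x)]
        return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan

    agg = {}
    for col in ("k_removal", "removal_rate", "synthesis_rate",
                "accumulation_rate"):
        agg[f"{col}_mean"] = (col, "mean")
        agg[f"{col}_sem"] = (col, sem)
    agg["n"] = ("removal_rate", "size")
    return (rates.groupby(["strain_id", "growth_light", "target"])
            .agg(**agg).reset_index())


def stoichiometry_table(contents: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate T0 stoichiometry (PsbA:PsbD, hexamer:PsbA) table."""
    t0 = contents[contents["timepoint"] == "T0"]
    wide = t0.pivot_table(index=["strain_id", "growth_light", "replicate_id"],
                          columns="target", values="content_fmol_per_ug",
                          aggfunc="mean")
    rows = []
    for (strain, light, rep), rec in wide.iterrows():
        psba = float(rec.get("PsbA", np.nan))
        psbd = float(rec.get("PsbD", np.nan))
        ftsh_mono = float(rec.get("FtsH", np.nan))
        hexa = hexamer_content(ftsh_mono) if np.isfinite(ftsh_mono) else np.nan
        res = stoichiometry(psba if np.isfinite(psba) else 0.0,
                            psbd if np.isfinite(psbd) else 0.0,
                            hexa if np.isfinite(hexa) else 0.0)
        rows.append({
            "strain_id": strain, "growth_light": light, "replicate_id": rep,
            "psba": psba, "psbd": psbd, "ftsh_hexamer": hexa,
            "psba_psbd_ratio": res.psba_psbd_ratio,
            "hexamer_per_psba": res.hexamer_per_psba,
            "psii_per_hexamer": res.psii_per_hexamer,
        })
    return pd.DataFrame(rows)
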