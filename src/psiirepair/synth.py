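"""Synthetic matched experiments: every assay of the study from one preset.

The generator forward-simulates the models that the analysis modules fit —
the two-state photoinactivation/repair kinetics for fluorescence decay
series, exponential protein loss under lincomycin for the blots, flash-yield
and steady-state oxygen exchange, modified-Gompertz growth, and 1/E^Cq
transcript pools — so that with zero noise every downstream estimator
recovers the preset's parameters exactly, and with the default noise model
group SEMs land on the scale of the published tables.

Noise structure (all components optional, all zero in ``NoiseModel.zero()``):

* fluorescence: additive Gaussian on F_V'/F_M' and flashlet yields;
* blots: mean-one multiplicative lognormal on band signals (densitometry is
  scale-proportional), plus a mean-one lognormal *biological* factor shared
  by all contents of one replicate — published SEMs imply between-replicate
  scatter far larger than densitometry error;
* Cq: Gaussian in cycle space (technical) plus a per-replicate offset;
* oxygen: additive Gaussian on optode readings, lognormal on flash yields.

Identical seed + preset => bit-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .frr import FRRFit, FRRProtocol, simulate_induction
from .growth import gompertz_predict
from .kinetics import predict_active
from .oxygen import ExtractGeometry, psii_conc_from_per_ug
from .presets import ISOFORMS, StrainLightPreset, preset_hash
from .protocol import (PERIOD_S, TREATMENT_S, decay_times,
                       irradiance_segments)

__all__ = ["NoiseModel", "SyntheticDataset", "generate_dataset",
           "generate_decay_pairs", "generate_blots", "generate_oxygen",
           "generate_growth", "generate_qpcr", "generate_frr"]

#: protein loads (ug) used for each sample; duplicate lanes per sample
SAMPLE_LOADS_UG = (0.5, 1.0)

#: fmol standards loaded on every blot (within the 7-250 fmol design range)
STANDARD_FMOL = (10.0, 25.0, 50.0, 100.0, 200.0)

_TRUE_SLOPE = 1000.0  # band signal per fmol
_TRUE_INTERCEPT = 200.0  # membrane background signal

_O2_BASELINE = 0.25  # umol O2 mL-1, near air saturation
_O2_POINTS_PER_SEGMENT = 12
_RT_MINUS_OFFSET = 12.0  # cycles; residual gDNA far below threshold
_QPCR_EFFICIENCY = 2.0
_GROWTH_DAYS = 14


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes for the synthetic generator (all sds >= 0)."""

    fluor_sd: float = 0.005    # additive, on relative fluorescence yields
    blot_cv: float = 0.08      # multiplicative lognormal, band signals
    bio_cv: float = 0.60       # multiplicative lognormal, per-replicate contents
    cq_sd: float = 0.15        # cycles, technical
    cq_bio_sd: float = 0.30    # cycles, per biological replicate
    o2_sd: float = 1.0e-4      # umol mL-1, optode readings
    flash_cv: float = 0.05     # multiplicative lognormal, flash yields
    growth_sd: float = 0.01    # AU, absorbance readings
    seed: int = 0

    def __post_init__(self):
        for f in ("fluor_sd", "blot_cv", "bio_cv", "cq_sd", "cq_bio_sd",
                  "o2_sd", "flash_cv", "growth_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseModel":
        """Noise-free model (round-trip/recovery testing)."""
        return cls(fluor_sd=0.0, blot_cv=0.0, bio_cv=0.0, cq_sd=0.0,
                   cq_bio_sd=0.0, o2_sd=0.0, flash_cv=0.0, growth_sd=0.0,
                   seed=seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    s = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * s * s, s, size))


def _rep_id(i: int) -> str:
    return f"rep{i + 1}"


def generate_decay_pairs(preset: StrainLightPreset, noise: NoiseModel,
                         n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Paired +/- lincomycin F_V'/F_M' decay series on the treatment clock."""
    t = decay_times()
    a0 = preset.fvfm0
    rows = []
    for i in range(n):
        for linco in (True, False):
            if linco:
                y = a0 * np.exp(-preset.k_pi * t)
            else:
                y = predict_active(a0, preset.k_pi, preset.k_rec, t)
            y = y + rng.normal(0.0, noise.fluor_sd, t.size)
            for tj, yj in zip(t, y):
                rows.append({
                    "replicate_id": _rep_id(i), "strain_id": preset.strain_id,
                    "growth_light": preset.growth_light, "lincomycin": linco,
                    "time_s": tj, "fvfm": yj,
                    "measurement_state": "post_actinic",
                })
    return pd.DataFrame(rows)


def _blot_contents(preset: StrainLightPreset) -> dict:
    """True fmol-per-ug contents per (target, timepoint, lincomycin)."""
    T = TREATMENT_S
    psba_l = preset.psba0 * np.exp(-preset.k_psba * T)
    psbd_l = preset.psbd0 * np.exp(-preset.k_psbd * T)
    return {
        ("PsbA", "T0", False): preset.psba0,
        ("PsbA", "T", True): psba_l,
        ("PsbA", "T", False): psba_l + preset.psba_synthesis_rate * T,
        ("PsbD", "T0", False): preset.psbd0,
        ("PsbD", "T", True): psbd_l,
        ("PsbD", "T", False): psbd_l + preset.psbd_synthesis_rate * T,
        ("FtsH", "T0", False): preset.ftsh_monomer0,
    }


def generate_blots(preset: StrainLightPreset, noise: NoiseModel, n: int,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Immunoblot lanes (standards + samples) for PsbA, PsbD and FtsH.

    One blot per replicate x target; each sample runs at duplicate loads.
    A per-replicate lognormal factor scales every true content of that
    replicate (biological scatter); band signals then carry multiplicative
    densitometry noise.
    """
    contents = _blot_contents(preset)
    rows = []
    for i in range(n):
        rep = _rep_id(i)
        bio = _lognormal_factor(rng, noise.bio_cv)
        for target in ("PsbA", "PsbD", "FtsH"):
            blot_id = f"{preset.name}-{rep}-{target}"
            for fmol in STANDARD_FMOL:
                signal = ((_TRUE_SLOPE * fmol + _TRUE_INTERCEPT)
                          * _lognormal_factor(rng, noise.blot_cv))
                rows.append({
                    "blot_id": blot_id, "target": target,
                    "lane_type": "standard", "fmol_load": fmol,
                    "replicate_id": "", "strain_id": preset.strain_id,
                    "growth_light": preset.growth_light, "timepoint": "",
                    "lincomycin": False, "band_signal": signal,
                    "ug_load": np.nan,
                })
            for (tgt, timepoint, linco), c_true in contents.items():
                if tgt != target:
                    continue
                c_rep = c_true * bio
                for load in SAMPLE_LOADS_UG:
                    fmol_on_gel = c_rep * load
                    signal = ((_TRUE_SLOPE * fmol_on_gel + _TRUE_INTERCEPT)
                              * _lognormal_factor(rng, noise.blot_cv))
                    rows.append({
                        "blot_id": blot_id, "target": target,
                        "lane_type": "sample", "fmol_load": np.nan,
                        "replicate_id": rep, "strain_id": preset.strain_id,
                        "growth_light": preset.growth_light,
                        "timepoint": timepoint, "lincomycin": linco,
                        "band_signal": signal, "ug_load": load,
                    })
    return pd.DataFrame(rows)


def generate_oxygen(preset: StrainLightPreset, noise: NoiseModel, n: int,
                    rng: np.random.Generator,
                    geom: ExtractGeometry | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dissolved-O2 series plus flash-yield measurements per replicate.

    Segment slopes follow O2-per-PSII ramping linearly from the pre- to the
    post-treatment value across the eight treatment periods, multiplied by
    the remaining (-lincomycin) PSII pool; flash yields are [PSII]/4 before
    treatment and after treatment in both cuvettes.
    """
    geom = geom or ExtractGeometry()
    psii_conc0 = psii_conc_from_per_ug(preset.psii_active0, geom)
    series_rows, flash_rows = [], []
    for i in range(n):
        rep = _rep_id(i)
        # piecewise-linear O2 trace: slope per 330-s protocol segment
        labels = (["dark_pre", "acclimation"]
                  + [f"treatment_{j}" for j in range(1, 9)])
        slopes = []
        for j, (label, seg) in enumerate(zip(labels, irradiance_segments())):
            if label == "dark_pre":
                slopes.append(-0.3 * preset.o2_per_psii_pre * psii_conc0)
            elif label == "acclimation":
                slopes.append(preset.o2_per_psii_pre * psii_conc0)
            else:
                step = j - 1  # 1..8
                o2pp = (preset.o2_per_psii_pre
                        + (preset.o2_per_psii_post - preset.o2_per_psii_pre)
                        * step / 8.0)
                t_hl = step * PERIOD_S  # treatment clock at segment end
                psii_t = predict_active(psii_conc0, preset.k_psii,
                                        preset.k_rec, t_hl)
                slopes.append(o2pp * psii_t)
        o2_level = _O2_BASELINE
        for (start, end, _), label, slope in zip(irradiance_segments(),
                                                 labels, slopes):
            ts = np.linspace(start, end, _O2_POINTS_PER_SEGMENT)
            ys = o2_level + slope * (ts - start)
            o2_level = float(ys[-1])
            ys = ys + rng.normal(0.0, noise.o2_sd, ts.size)
            for tj, yj in zip(ts, ys):
                series_rows.append({
                    "replicate_id": rep, "strain_id": preset.strain_id,
                    "growth_light": preset.growth_light,
                    "time_s": tj, "o2_umol_per_ml": yj,
                    "segment_label": label,
                })
        psii_post_linco = psii_conc0 * np.exp(-preset.k_psii * TREATMENT_S)
        psii_post_nolinco = predict_active(psii_conc0, preset.k_psii,
                                           preset.k_rec, TREATMENT_S)
        for when, linco, psii in (("pre", False, psii_conc0),
                                  ("post", True, psii_post_linco),
                                  ("post", False, psii_post_nolinco)):
            fy = (psii / 4.0) * _lognormal_factor(rng, noise.flash_cv)
            flash_rows.append({
                "replicate_id": rep, "strain_id": preset.strain_id,
                "growth_light": preset.growth_light, "when": when,
                "lincomycin": linco, "o2_per_flash": fy, "n_flashes": 20,
            })
    return pd.DataFrame(series_rows), pd.DataFrame(flash_rows)


def generate_growth(preset: StrainLightPreset, noise: NoiseModel, n: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Daily absorbance-peak series from the preset's Gompertz parameters."""
    days = np.arange(_GROWTH_DAYS, dtype=float)
    rows = []
    for i in range(n):
        y = gompertz_predict(days, preset.growth_lag_d,
                             preset.growth_rate_per_d,
                             preset.growth_capacity_au,
                             preset.growth_baseline_au)
        y = y + rng.normal(0.0, noise.growth_sd, days.size)
        for d, a in zip(days, y):
            rows.append({
                "strain_id": preset.strain_id, "replicate_id": _rep_id(i),
                "growth_light": preset.growth_light, "day": d,
                "absorbance_peak": a,
            })
    return pd.DataFrame(rows)


def generate_qpcr(preset: StrainLightPreset, noise: NoiseModel, n: int,
                  rng: np.random.Generator) -> pd.DataFrame:
    """qPCR Cq triplicates (RT+ and RT-) satisfying abundance = 1/E^Cq."""
    if preset.transcript_pool_gl is None:
        return pd.DataFrame(columns=[
            "strain_id", "isoform", "condition", "rt",
            "biological_replicate_id", "cq1", "cq2", "cq3", "efficiency"])
    rows = []
    log_e = np.log(_QPCR_EFFICIENCY)
    pools = {"GL": preset.transcript_pool_gl, "HL": preset.transcript_pool_hl}
    for i in range(n):
        rep = _rep_id(i)
        bio_offset = rng.normal(0.0, noise.cq_bio_sd)
        for condition, pool in pools.items():
            for iso in ISOFORMS:
                cq_true = -np.log(pool[iso]) / log_e
                for rt, offset in (("plus", 0.0), ("minus", _RT_MINUS_OFFSET)):
                    trip = (cq_true + offset + bio_offset
                            + rng.normal(0.0, noise.cq_sd, 3))
                    rows.append({
                        "strain_id": preset.strain_id, "isoform": iso,
                        "condition": condition, "rt": rt,
                        "biological_replicate_id": rep,
                        "cq1": trip[0], "cq2": trip[1], "cq3": trip[2],
                        "efficiency": _QPCR_EFFICIENCY,
                    })
    return pd.DataFrame(rows)


def generate_frr(preset: StrainLightPreset, noise: NoiseModel, n: int,
                 rng: np.random.Generator
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flashlet-resolved induction traces plus steady-yield table for qp.

    Two states per replicate: light-acclimated at the growth light, and the
    first treatment-light step.  The treatment state carries mild
    non-photochemical quenching of FM' and a raised F0'.
    """
    proto = FRRProtocol()
    states = {
        "growth_light": (preset.f0_base, preset.fm_base, preset.qp_growth),
        "treatment_step1": (preset.f0_base * 1.1, preset.fm_base * 0.9,
                            preset.qp_treatment),
    }
    trace_rows, yield_rows = [], []
    for i in range(n):
        rep = _rep_id(i)
        for state, (f0, fm, qp) in states.items():
            truth = FRRFit(f0=f0, fm=fm, sigma_psii=preset.sigma_psii,
                           connectivity_p=preset.connectivity_p,
                           residual_ss=0.0, converged=True)
            trace = simulate_induction(proto, truth,
                                       actinic_state="under-actinic-light")
            y = trace.fluorescence + rng.normal(0.0, noise.fluor_sd,
                                                trace.fluorescence.size)
            for tj, yj in zip(trace.times_us, y):
                trace_rows.append({
                    "replicate_id": rep, "strain_id": preset.strain_id,
                    "growth_light": preset.growth_light, "state": state,
                    "time_us": tj, "fluorescence": yj,
                    "segment": "induction",
                })
            f_prime = fm - qp * (fm - f0)
            jit = rng.normal(0.0, noise.fluor_sd, 3)
            yield_rows.append({
                "replicate_id": rep, "strain_id": preset.strain_id,
                "growth_light": preset.growth_light, "state": state,
                "f0_prime": f0 + jit[0], "fm_prime": fm + jit[1],
                "f_prime": f_prime + jit[2],
            })
    return pd.DataFrame(trace_rows), pd.DataFrame(yield_rows)


@dataclass
class SyntheticDataset:
    """One complete matched synthetic experiment from one preset."""

    preset: StrainLightPreset
    noise: NoiseModel
    n_replicates: int
    decay: pd.DataFrame
    blots: pd.DataFrame
    oxygen: pd.DataFrame
    flash_yields: pd.DataFrame
    growth: pd.DataFrame
    qpcr: pd.DataFrame
    frr_traces: pd.DataFrame
    frr_yields: pd.DataFrame
    geometry: ExtractGeometry = field(default_factory=ExtractGeometry)

    @property
    def provenance(self) -> dict:
        return {
            "preset": self.preset.name,
            "preset_hash": preset_hash(self.preset),
            "seed": self.noise.seed,
            "n_replicates": self.n_replicates,
            "noise": asdict(self.noise),
            "version": __version__,
        }

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "decay": self.decay, "blots": self.blots, "oxygen": self.oxygen,
            "flash_yields": self.flash_yields, "growth": self.growth,
            "qpcr": self.qpcr, "frr_traces": self.frr_traces,
            "frr_yields": self.frr_yields,
        }

    def to_csv(self, outdir) -> dict[str, str]:
        """Write every assay table plus a provenance JSON; returns paths."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in self.tables().items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        prov = outdir / "provenance.json"
        prov.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))
        paths["provenance"] = str(prov)
        return paths


def generate_dataset(preset: StrainLightPreset, noise: NoiseModel | None = None,
                     n: int = 5,
                     geometry: ExtractGeometry | None = None
                     ) -> SyntheticDataset:
    """Generate a complete matched experiment (all assays, ``n`` replicates).

    Deterministic: identical preset + noise (including seed) + n yields
    bit-identical tables.  Each assay consumes an independent child stream of
    the seed, so adding replicates to one assay does not perturb another.
    """
    noise = noise if noise is not None else NoiseModel()
    if n < 1:
        raise ValueError("replicate count n must be >= 1")
    geometry = geometry or ExtractGeometry()
    streams = [np.random.Generator(np.random.PCG64(s))
               for s in np.random.SeedSequence(noise.seed).spawn(6)]
    decay = generate_decay_pairs(preset, noise, n, streams[0])
    blots = generate_blots(preset, noise, n, streams[1])
    oxygen, flash = generate_oxygen(preset, noise, n, streams[2], geometry)
    growth = generate_growth(preset, noise, n, streams[3])
    qpcr = generate_qpcr(preset, noise, n, streams[4])
    frr_traces, frr_yields = generate_frr(preset, noise, n, streams[5])
    return SyntheticDataset(preset=preset, noise=noise, n_replicates=n,
                            decay=decay, blots=blots, oxygen=oxygen,
                            flash_yields=flash, growth=growth, qpcr=qpcr,
                            frr_traces=frr_traces, frr_yields=frr_yields,
                            geometry=geometry)
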