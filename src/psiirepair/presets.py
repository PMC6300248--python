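"""Strain x growth-light presets for the synthetic experiment generator.

Each preset bundles the published group-mean rate constants (photoinactivation
k_PI, repair k_REC, PSII loss k_PSII, PsbA removal k_PsbA), protein turnover
rates, and stoichiometry ratios for one picocyanobacterial strain grown at one
light level, together with calibration constants (fluorescence baselines,
effective absorption cross-section, qp levels, O2 per PSII, growth-curve and
transcript-pool parameters) chosen to reproduce the published derived
quantities.

Initial protein contents are derived rather than stored, which keeps every
printed ratio self-consistent::

    psbA0        = removal_rate(PsbA) / k_PsbA          (fmol ug-1)
    psbD0        = psbA0 / (PsbA:PsbD ratio)
    k_PsbD       = removal_rate(PsbD) / psbD0
    FtsH monomer = 6 * (hexamer:PsbA ratio) * psbA0
    PSII_active0 = psbD0   (active centres bounded by the scarcer core subunit)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "StrainLightPreset",
    "available_presets",
    "make_preset",
    "preset_hash",
]

_PRESET_NAMES = (
    "MIT9313_30",
    "MIT9313_90",
    "MED4_30",
    "MED4_260",
    "WH8102_30",
    "WH8102_260",
    "custom",
)

#: ftsH isoform labels used throughout the transcript module.
ISOFORMS = ("FtsH1", "FtsH2", "FtsH3", "FtsH4")


@dataclass(frozen=True)
class StrainLightPreset:
    """Complete parameter set for one simulated strain x growth-light condition.

    Rate constants are s-1, protein contents fmol per ug total protein,
    turnover rates fmol ug-1 s-1, fluorescence yields relative units,
    sigma_psii in reciprocal flashlet-photon-dose units.
    """

    name: str
    strain_id: str
    growth_light: float

    # first-order rate constants (s-1)
    k_pi: float
    k_rec: float
    k_psii: float
    k_psba: float
    k_psbd: float

    # initial contents (fmol ug-1)
    psba0: float
    psbd0: float
    ftsh_monomer0: float
    psii_active0: float

    # turnover rates (fmol ug-1 s-1); negative values mean net accumulation
    psba_removal_rate: float
    psbd_removal_rate: float
    psba_synthesis_rate: float
    psbd_synthesis_rate: float

    # fluorescence / FRR calibration
    f0_base: float
    fm_base: float
    sigma_psii: float
    connectivity_p: float

    # fraction of open centres at growth light and in the first treatment step
    qp_growth: float
    qp_treatment: float

    # O2 evolved per PSII per second before / after the treatment time course
    o2_per_psii_pre: float
    o2_per_psii_post: float

    # modified-Gompertz growth parameters
    growth_lag_d: float
    growth_rate_per_d: float
    growth_capacity_au: float
    growth_baseline_au: float

    # relative ftsH transcript abundances (1/E^Cq units) or None when the
    # strain/light was not assayed by qRT-PCR
    transcript_pool_gl: dict | None
    transcript_pool_hl: dict | None

    def __post_init__(self):
        for field in ("k_pi", "k_rec", "k_psii", "k_psba", "k_psbd"):
            if not math.isfinite(getattr(self, field)):
                raise ValueError(f"{field} must be finite")
        for field in ("psba0", "psbd0", "ftsh_monomer0", "psii_active0"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")
        if self.psii_active0 > self.psba0 + 1e-12:
            raise ValueError("psii_active0 cannot exceed psba0 "
                             "(one active centre per PsbA copy)")
        if not (self.fm_base > self.f0_base > 0):
            raise ValueError("need fm_base > f0_base > 0")
        if not (0 <= self.connectivity_p < 1):
            raise ValueError("connectivity_p must lie in [0, 1)")

    @property
    def fvfm0(self) -> float:
        """Initial F_V'/F_M' implied by the fluorescence baselines."""
        return (self.fm_base - self.f0_base) / self.fm_base

    @property
    def ftsh_hexamer0(self) -> float:
        """FtsH hexamer content, fmol ug-1 (monomer content / 6)."""
        return self.ftsh_monomer0 / 6.0

    @property
    def hexamer_per_psba(self) -> float:
        return self.ftsh_hexamer0 / self.psba0 if self.psba0 > 0 else float("nan")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_raw(name: str) -> dict:
    path = resources.files("psiirepair").joinpath(f"data/presets/{name}.yaml")
    with path.open("r") as fh:
        return yaml.safe_load(fh)


def _build(raw: dict) -> StrainLightPreset:
    kin = raw["kinetics"]
    rem = raw["removal_rates"]
    syn = raw["synthesis_rates"]
    ratio = float(raw["psba_psbd_ratio"])
    hex_ratio = float(raw["ftsh_hexamer_per_psba"])

    if "contents" in raw:  # explicit contents (rates may be zero)
        cont = raw["contents"]
        psba0 = float(cont["psba0"])
        psbd0 = float(cont["psbd0"])
        ftsh0 = float(cont["ftsh_monomer0"])
        psii0 = float(cont["psii_active0"])
        k_psbd = rem["psbd"] / psbd0 if psbd0 > 0 and kin["k_psba"] != 0 else 0.0
    else:
        psba0 = rem["psba"] / kin["k_psba"]
        psbd0 = psba0 / ratio
        ftsh0 = 6.0 * hex_ratio * psba0
        psii0 = psbd0
        k_psbd = rem["psbd"] / psbd0

    fl = raw["fluorescence"]
    qp = raw["qp"]
    o2 = raw["o2_per_psii"]
    gr = raw["growth_curve"]
    pools = raw.get("transcript_pools")

    return StrainLightPreset(
        name=raw["name"],
        strain_id=raw["strain_id"],
        growth_light=float(raw["growth_light"]),
        k_pi=float(kin["k_pi"]),
        k_rec=float(kin["k_rec"]),
        k_psii=float(kin["k_psii"]),
        k_psba=float(kin["k_psba"]),
        k_psbd=float(k_psbd),
        psba0=float(psba0),
        psbd0=float(psbd0),
        ftsh_monomer0=float(ftsh0),
        psii_active0=float(psii0),
        psba_removal_rate=float(rem["psba"]),
        psbd_removal_rate=float(rem["psbd"]),
        psba_synthesis_rate=float(syn["psba"]),
        psbd_synthesis_rate=float(syn["psbd"]),
        f0_base=float(fl["f0_base"]),
        fm_base=float(fl["fm_base"]),
        sigma_psii=float(fl["sigma_psii"]),
        connectivity_p=float(fl["connectivity_p"]),
        qp_growth=float(qp["growth"]),
        qp_treatment=float(qp["treatment"]),
        o2_per_psii_pre=float(o2["pre"]),
        o2_per_psii_post=float(o2["post"]),
        growth_lag_d=float(gr["lag_d"]),
        growth_rate_per_d=float(gr["rate_per_d"]),
        growth_capacity_au=float(gr["capacity_au"]),
        growth_baseline_au=float(gr["baseline_au"]),
        transcript_pool_gl=dict(pools["gl"]) if pools else None,
        transcript_pool_hl=dict(pools["hl"]) if pools else None,
    )


def available_presets() -> tuple[str, ...]:
    """Names accepted by :func:`make_preset`."""
    return _PRESET_NAMES


def make_preset(name: str, **overrides) -> StrainLightPreset:
    """Load a named strain x growth-light preset.

    Parameters
    ----------
    name:
        One of :func:`available_presets`.  ``"custom"`` is a zero-rate template
        meant to be specialised through keyword overrides.
    **overrides:
        Field values replacing the stored ones (field names of
        :class:`StrainLightPreset`).

    Raises
    ------
    ValueError
        If the preset name is unknown (the message lists the valid names).
    """
    if name not in _PRESET_NAMES:
        raise ValueError(
            f"unknown preset {name!r}; available presets: "
            + ", ".join(_PRESET_NAMES)
        )
    preset = _build(_load_raw(name))
    if overrides:
        preset = dataclasses.replace(preset, **overrides)
    return preset


def preset_hash(preset: StrainLightPreset) -> str:
    """Stable short hash of all preset fields, for provenance records."""
    payload = json.dumps(preset.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
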