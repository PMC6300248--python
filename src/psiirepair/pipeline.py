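"""End-to-end orchestration: data in, publication-style summary tables out.

``run`` takes either a list of synthetic presets or a directory of assay CSV
files, executes every analysis stage (paired kinetics, blot calibration and
turnover rates, oxygen metrics, QC cross-check of active PSII against PsbA,
qp, growth fits, transcript pools) and writes long-format summary tables plus
rejects tables and a provenance record.  Every input record lands in exactly
one of summaries or rejects (record conservation), and reruns on the same
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .frr import fraction_open
from .growth import GompertzGrowthFitter
from .kinetics import pair_and_fit
from .oxygen import ExtractGeometry, analyze_oxygen
from .presets import make_preset
from .proteins import (calibrate_blots, protein_rates, protein_rates_summary,
                       qc_flag_extracts, stoichiometry_table)
from .protocol import TREATMENT_S
from .synth import NoiseModel, SyntheticDataset, generate_dataset
from .transcripts import CQ_MAX, fold_induction, pool_composition, rt_minus_screen

__all__ = ["FitOptions", "RunConfig", "RunReport", "run", "validate"]

_ASSAY_FILES = ("decay", "blots", "oxygen", "flash_yields", "growth", "qpcr",
                "frr_yields")

_REQUIRED_COLUMNS = {
    "decay": ["replicate_id", "strain_id", "growth_light", "lincomycin",
              "time_s", "fvfm"],
    "blots": ["blot_id", "target", "lane_type", "fmol_load", "replicate_id",
              "strain_id", "growth_light", "timepoint", "lincomycin",
              "band_signal", "ug_load"],
    "oxygen": ["replicate_id", "strain_id", "growth_light", "time_s",
               "o2_umol_per_ml", "segment_label"],
    "flash_yields": ["replicate_id", "strain_id", "growth_light", "when",
                     "lincomycin", "o2_per_flash", "n_flashes"],
    "growth": ["strain_id", "replicate_id", "growth_light", "day",
               "absorbance_peak"],
    "qpcr": ["strain_id", "isoform", "condition", "rt",
             "biological_replicate_id", "cq1", "cq2", "cq3", "efficiency"],
    "frr_yields": ["replicate_id", "strain_id", "growth_light", "state",
                   "f0_prime", "fm_prime", "f_prime"],
}


@dataclass(frozen=True)
class FitOptions:
    """Analysis-stage switches exposed through config and CLI."""

    co_fit_a0: bool = False
    connectivity_free: bool = True
    qc_factor: float = 1.0
    rt_minus_threshold: float = 5.0
    slope_method: str = "theil"


@dataclass
class RunConfig:
    """One run: synthetic presets XOR a directory of assay CSVs."""

    outdir: pathlib.Path
    presets: list[str] | None = None
    n: int = 5
    noise: NoiseModel = field(default_factory=NoiseModel)
    input_dir: pathlib.Path | None = None
    fit: FitOptions = field(default_factory=FitOptions)
    geometry: ExtractGeometry = field(default_factory=ExtractGeometry)

    def __post_init__(self):
        self.outdir = pathlib.Path(self.outdir)
        if (self.presets is None) == (self.input_dir is None):
            raise ValueError("exactly one of presets / input_dir must be set")
        if self.input_dir is not None:
            self.input_dir = pathlib.Path(self.input_dir)
            missing = [f for f in _ASSAY_FILES
                       if not (self.input_dir / f"{f}.csv").exists()]
            if missing:
                raise FileNotFoundError(
                    f"input_dir lacks assay files: {missing}")


@dataclass
class RunReport:
    """Summary tables, rejects, and provenance for one pipeline run."""

    tables: dict[str, pd.DataFrame]
    rejects: dict[str, pd.DataFrame]
    record_counts: dict[str, dict[str, int]]
    provenance: dict
    paths: dict[str, str] = field(default_factory=dict)


def _load_tables(config: RunConfig) -> dict[str, pd.DataFrame]:
    if config.input_dir is not None:
        tables = {name: pd.read_csv(config.input_dir / f"{name}.csv")
                  for name in _ASSAY_FILES}
        findings = validate_tables(tables)
        if len(findings):
            raise ValueError(
                "input validation failed:\n"
                + findings.to_string(index=False))
        return tables

    parts: dict[str, list[pd.DataFrame]] = {k: [] for k in _ASSAY_FILES}
    base_seed = np.random.SeedSequence(config.noise.seed)
    preset_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                    for s in base_seed.spawn(len(config.presets))]
    for name, seed in zip(config.presets, preset_seeds):
        preset = make_preset(name)
        noise = dataclasses.replace(config.noise, seed=seed)
        ds: SyntheticDataset = generate_dataset(preset, noise, config.n,
                                                config.geometry)
        for key, df in ds.tables().items():
            if key in parts:
                parts[key].append(df)
    out = {}
    for k, v in parts.items():
        frames = [df for df in v if len(df)]
        out[k] = (pd.concat(frames, ignore_index=True) if frames
                  else (v[0] if v else pd.DataFrame()))
    return out


def _sem(x) -> float:
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan


def run(config: RunConfig) -> RunReport:
    """Execute every analysis stage and write the output tables."""
    tables = _load_tables(config)
    out: dict[str, pd.DataFrame] = {}
    rejects: dict[str, pd.DataFrame] = {}
    counts: dict[str, dict[str, int]] = {}

    # --- paired lincomycin-chase kinetics (k_PI, k_REC) ---
    kin = pair_and_fit(tables["decay"], co_fit_a0=config.fit.co_fit_a0)
    out["kinetic_fits"] = kin.fits
    rejects["decay"] = kin.rejects
    counts["decay"] = {
        "input_series": int(tables["decay"]
                            .groupby(["strain_id", "growth_light",
                                      "replicate_id", "lincomycin"]).ngroups),
        "fitted_series": 2 * len(kin.fits),
        "rejected_series": int(kin.rejects["n_rows"].notna().sum()),
    }

    # --- blot calibration, turnover rates, stoichiometry ---
    contents = calibrate_blots(tables["blots"])
    rates = protein_rates(contents, TREATMENT_S)
    out["protein_contents"] = contents.sort_values(
        ["strain_id", "growth_light", "replicate_id", "target",
         "timepoint"]).reset_index(drop=True)
    out["protein_rates"] = rates
    out["protein_rates_summary"] = protein_rates_summary(rates)

    # --- oxygen metrics ---
    oxy = analyze_oxygen(tables["oxygen"], tables["flash_yields"],
                         config.geometry, TREATMENT_S,
                         method=config.fit.slope_method)
    out["oxygen_metrics"] = oxy

    # --- QC: active PSII cannot exceed PsbA copies in the same extract ---
    psba_t0 = (contents[(contents["target"] == "PsbA")
                        & (contents["timepoint"] == "T0")]
               [["strain_id", "growth_light", "replicate_id",
                 "content_fmol_per_ug"]]
               .rename(columns={"content_fmol_per_ug": "psba_t0"}))
    qc = oxy.merge(psba_t0, on=["strain_id", "growth_light", "replicate_id"],
                   how="left")
    qc["qc"] = [
        qc_flag_extracts(row.psba_t0, row.psii_pre_fmol_ug,
                         config.fit.qc_factor)
        if np.isfinite(row.psba_t0) else "keep"
        for row in qc.itertuples()]
    flagged = qc[qc["qc"] == "flag"]
    kept = qc[qc["qc"] == "keep"]
    rejects["extracts"] = flagged[["strain_id", "growth_light",
                                   "replicate_id", "psba_t0",
                                   "psii_pre_fmol_ug"]].assign(
        reason="active PSII exceeds PsbA copy number")
    counts["extracts"] = {"input": len(qc), "kept": len(kept),
                          "rejected": len(flagged)}

    # stoichiometry summary over QC-passing extracts only
    stoich = stoichiometry_table(contents)
    stoich = stoich.merge(kept[["strain_id", "growth_light", "replicate_id"]],
                          on=["strain_id", "growth_light", "replicate_id"],
                          how="inner") if len(kept) else stoich
    out["stoichiometry"] = stoich
    if len(stoich):
        out["stoichiometry_summary"] = (
            stoich.groupby(["strain_id", "growth_light"])
            .agg(psba_psbd_mean=("psba_psbd_ratio", "mean"),
                 psba_psbd_sem=("psba_psbd_ratio", _sem),
                 hexamer_per_psba_mean=("hexamer_per_psba", "mean"),
                 hexamer_per_psba_sem=("hexamer_per_psba", _sem),
                 n=("psba_psbd_ratio", "size"))
            .reset_index())
    else:
        out["stoichiometry_summary"] = pd.DataFrame()

    # --- rate-constant summary in the published four-constant layout ---
    kin_sum = kin.summary.copy()
    oxy_k = (oxy.groupby(["strain_id", "growth_light"])
             .agg(k_psii_mean=("k_psii", "mean"), k_psii_sem=("k_psii", _sem))
             .reset_index())
    psba_k = (rates[rates["target"] == "PsbA"]
              .groupby(["strain_id", "growth_light"])
              .agg(k_psba_mean=("k_removal", "mean"),
                   k_psba_sem=("k_removal", _sem))
              .reset_index())
    rate_constants = kin_sum.merge(oxy_k, on=["strain_id", "growth_light"],
                                   how="outer")
    rate_constants = rate_constants.merge(psba_k,
                                          on=["strain_id", "growth_light"],
                                          how="outer")
    out["rate_constants_summary"] = rate_constants.sort_values(
        ["strain_id", "growth_light"]).reset_index(drop=True)

    # --- qp at growth light vs first treatment step ---
    qp_rows = []
    for row in tables["frr_yields"].itertuples():
        qp = fraction_open(row.f_prime, row.f0_prime, row.fm_prime)
        qp_rows.append({
            "strain_id": row.strain_id, "growth_light": row.growth_light,
            "replicate_id": row.replicate_id, "state": row.state,
            "qp": qp.value, "clamped": qp.clamped,
        })
    qp_df = pd.DataFrame(qp_rows)
    out["qp"] = qp_df
    if len(qp_df):
        out["qp_summary"] = (qp_df.groupby(["strain_id", "growth_light",
                                            "state"])
                             .agg(qp_mean=("qp", "mean"), qp_sem=("qp", _sem),
                                  n=("qp", "size"))
                             .reset_index())
    else:
        out["qp_summary"] = pd.DataFrame()

    # --- growth fits ---
    growth_rows = []
    for (strain, light, rep), grp in tables["growth"].groupby(
            ["strain_id", "growth_light", "replicate_id"], sort=True):
        est = GompertzGrowthFitter().fit(grp["day"].to_numpy(),
                                         grp["absorbance_peak"].to_numpy())
        growth_rows.append({
            "strain_id": strain, "growth_light": light, "replicate_id": rep,
            "lag_d": est.lag_d_, "rate_per_d": est.rate_,
            "capacity_au": est.capacity_, "baseline_au": est.baseline_,
            "converged": est.converged_, "flags": ";".join(est.flags_),
        })
    out["growth_fits"] = pd.DataFrame(growth_rows)

    # --- transcript pools ---
    qpcr = tables["qpcr"]
    pool_rows, fold_rows = [], []
    screen = (rt_minus_screen(qpcr, config.fit.rt_minus_threshold)
              if len(qpcr) else pd.DataFrame())
    rejects["qpcr"] = (screen[screen["outcome"] == "fail"]
                       if len(screen) else pd.DataFrame())
    if len(screen):
        counts["qpcr"] = {
            "input": len(screen),
            "kept": int((screen["outcome"] == "pass").sum()),
            "rejected": int((screen["outcome"] == "fail").sum()),
        }
        passing = screen[screen["outcome"] == "pass"]
        qpcr_pass = qpcr.merge(
            passing[["strain_id", "isoform", "condition",
                     "biological_replicate_id"]],
            on=["strain_id", "isoform", "condition",
                "biological_replicate_id"], how="inner")
        # keep both RT arms of passing records; pools use RT+ only
        for strain in sorted(qpcr_pass["strain_id"].unique()):
            pools = {}
            for condition in ("GL", "HL"):
                pool = pool_composition(qpcr_pass, strain, condition)
                pools[condition] = pool
                for iso, ab in pool.abundances.items():
                    pool_rows.append({
                        "strain_id": strain, "condition": condition,
                        "isoform": iso, "abundance": ab,
                        "fraction": pool.fractions[iso],
                        "n_biological": pool.n_biological,
                    })
            if pools["GL"].total > 0:
                fold_rows.append({
                    "strain_id": strain,
                    "fold_induction": fold_induction(pools["GL"], pools["HL"]),
                })
    out["transcript_pools"] = pd.DataFrame(pool_rows)
    out["transcript_fold_induction"] = pd.DataFrame(fold_rows)

    provenance = {
        "version": __version__,
        "mode": "synthetic" if config.presets else "files",
        "presets": config.presets,
        "n": config.n if config.presets else None,
        "seed": config.noise.seed if config.presets else None,
        "fit_options": dataclasses.asdict(config.fit),
        "config_hash": hashlib.sha256(
            json.dumps({
                "presets": config.presets, "n": config.n,
                "noise": dataclasses.asdict(config.noise),
                "fit": dataclasses.asdict(config.fit),
            }, sort_keys=True, default=str).encode()).hexdigest()[:16],
    }

    report = RunReport(tables=out, rejects=rejects, record_counts=counts,
                       provenance=provenance)
    _write_report(report, config.outdir)
    return report


def _write_report(report: RunReport, outdir: pathlib.Path) -> None:
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in sorted(report.tables.items()):
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        report.paths[name] = str(path)
    rej_dir = outdir / "rejects"
    rej_dir.mkdir(exist_ok=True)
    for name, df in sorted(report.rejects.items()):
        path = rej_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        report.paths[f"rejects/{name}"] = str(path)
    prov = outdir / "provenance.json"
    prov.write_text(json.dumps(report.provenance | {
        "record_counts": report.record_counts}, indent=2, sort_keys=True))
    report.paths["provenance"] = str(prov)


def validate_tables(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Schema / range / pairing checks; reports findings, never raises."""
    findings = []

    def add(file, row, column, message):
        findings.append({"file": file, "row": row, "column": column,
                         "message": message})

    for name, required in _REQUIRED_COLUMNS.items():
        if name not in tables:
            add(name, None, None, "missing table")
            continue
        df = tables[name]
        for col in required:
            if col not in df.columns:
                add(name, None, col, "missing column")

    decay = tables.get("decay")
    if decay is not None and {"replicate_id", "strain_id", "growth_light",
                              "lincomycin", "time_s",
                              "fvfm"}.issubset(decay.columns):
        for idx in decay.index[~np.isfinite(
                pd.to_numeric(decay["fvfm"], errors="coerce"))]:
            add("decay", int(idx), "fvfm", "non-finite F_V'/F_M'")
        for (strain, light, rep), grp in decay.groupby(
                ["strain_id", "growth_light", "replicate_id"]):
            arms = set(grp["lincomycin"].astype(bool))
            if arms != {True, False}:
                missing_arm = "+lincomycin" if True not in arms else "-lincomycin"
                add("decay", None, "lincomycin",
                    f"{strain}/{light}/{rep}: missing {missing_arm} partner")
            for linco, series in grp.groupby(grp["lincomycin"].astype(bool)):
                t = series["time_s"].to_numpy(float)
                if np.any(t < 0):
                    add("decay", None, "time_s",
                        f"{strain}/{light}/{rep}: negative times")

    qpcr = tables.get("qpcr")
    if qpcr is not None and {"cq1", "cq2", "cq3"}.issubset(qpcr.columns):
        for col in ("cq1", "cq2", "cq3"):
            vals = pd.to_numeric(qpcr[col], errors="coerce")
            for idx in qpcr.index[(vals <= 0) | (vals >= CQ_MAX)]:
                add("qpcr", int(idx), col,
                    f"Cq outside (0, {CQ_MAX:g})")

    blots = tables.get("blots")
    if blots is not None and {"lane_type", "ug_load"}.issubset(blots.columns):
        samp = blots[blots["lane_type"] == "sample"]
        loads = pd.to_numeric(samp["ug_load"], errors="coerce")
        for idx in samp.index[(loads < 0.25) | (loads > 4.0)]:
            add("blots", int(idx), "ug_load",
                "protein load outside the 0.25-4.0 ug design")

    return pd.DataFrame(findings, columns=["file", "row", "column", "message"])


def validate(input_dir) -> pd.DataFrame:
    """Validate a directory of assay CSVs; returns the findings table."""
    input_dir = pathlib.Path(input_dir)
    tables = {}
    for name in _ASSAY_FILES:
        path = input_dir / f"{name}.csv"
        if path.exists():
            tables[name] = pd.read_csv(path)
    return validate_tables(tables)
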