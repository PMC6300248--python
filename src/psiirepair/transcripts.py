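"""Relative ftsH transcript quantitation from qPCR Cq values.

Template abundance relative to the whole reaction scales as 1/E^Cq for a
per-cycle amplification efficiency E in (1, 2].  Pools are assembled per
strain and light condition by averaging technical triplicates in Cq space
first (after a median-distance outlier drop), converting to abundance, then
averaging biological replicates.  RT- (no reverse transcriptase) reactions
guard against genomic-DNA signal: a record passes when the RT- Cq trails the
RT+ Cq by at least 5 cycles (>= 32-fold separation at E = 2) or is
undetected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from importlib import resources

from .presets import ISOFORMS

__all__ = [
    "relative_abundance",
    "triplicate_mean_cq",
    "TranscriptPool",
    "pool_composition",
    "fold_induction",
    "rt_minus_check",
    "rt_minus_screen",
    "load_primer_table",
]

#: minimum RT+/RT- separation in cycles for a clean record
RT_MINUS_THRESHOLD = 5.0

#: technical replicates further than this from the triplicate median are dropped
TRIPLICATE_OUTLIER_CYCLES = 0.5

CQ_MAX = 45.0


def relative_abundance(cq: float, efficiency: float = 2.0) -> float:
    """Relative transcript abundance, 1/E^Cq."""
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must lie in (1, 2]")
    if not np.isfinite(cq):
        raise ValueError("Cq must be finite")
    return float(efficiency ** (-cq))


def triplicate_mean_cq(cq_values) -> tuple[float, int]:
    """Mean Cq after dropping replicates > 0.5 cycles from the median.

    Returns (mean, replicates kept).  NaN entries (undetected wells) are
    ignored; all-NaN triplicates return (nan, 0).
    """
    cq = np.asarray(cq_values, dtype=float)
    cq = cq[np.isfinite(cq)]
    if cq.size == 0:
        return float("nan"), 0
    med = float(np.median(cq))
    kept = cq[np.abs(cq - med) <= TRIPLICATE_OUTLIER_CYCLES]
    if kept.size == 0:  # pathological spread: keep the median itself
        kept = np.array([med])
    return float(np.mean(kept)), int(kept.size)


@dataclass(frozen=True)
class TranscriptPool:
    """Per-isoform relative abundances for one strain x condition."""

    strain_id: str
    condition: str
    abundances: dict  # isoform -> mean 1/E^Cq over biological replicates
    n_biological: int
    flags: tuple = ()

    @property
    def total(self) -> float:
        return float(sum(self.abundances.values()))

    @property
    def fractions(self) -> dict:
        tot = self.total
        if tot <= 0:
            return {iso: 0.0 for iso in self.abundances}
        return {iso: a / tot for iso, a in self.abundances.items()}


def pool_composition(records: pd.DataFrame, strain_id: str,
                     condition: str) -> TranscriptPool:
    """Assemble the ftsH transcript pool for one strain x condition.

    ``records`` is the long qPCR table (columns strain_id, isoform, condition,
    rt, biological_replicate_id, cq1..cq3, efficiency); only RT+ rows enter
    the pool.  Missing isoforms are recorded with zero abundance and flagged.
    """
    sel = records[(records["strain_id"] == strain_id)
                  & (records["condition"] == condition)
                  & (records["rt"] == "plus")]
    abundances, flags = {}, []
    n_bio = 0
    for iso in ISOFORMS:
        iso_rows = sel[sel["isoform"] == iso]
        if iso_rows.empty:
            abundances[iso] = 0.0
            flags.append(f"missing_isoform:{iso}")
            continue
        per_rep = []
        for row in iso_rows.itertuples():
            mean_cq, kept = triplicate_mean_cq([row.cq1, row.cq2, row.cq3])
            if kept >= 2 and np.isfinite(mean_cq):
                per_rep.append(relative_abundance(mean_cq, row.efficiency))
        if not per_rep:
            abundances[iso] = 0.0
            flags.append(f"no_usable_replicates:{iso}")
            continue
        abundances[iso] = float(np.mean(per_rep))
        n_bio = max(n_bio, len(per_rep))
    return TranscriptPool(strain_id=strain_id, condition=condition,
                          abundances=abundances, n_biological=n_bio,
                          flags=tuple(flags))


def fold_induction(pool_gl: TranscriptPool, pool_hl: TranscriptPool) -> float:
    """Total-pool ratio, high-light over growth-light."""
    if pool_gl.total <= 0:
        raise ValueError("growth-light pool total must be positive")
    return pool_hl.total / pool_gl.total


def rt_minus_check(cq_rt_plus, cq_rt_minus,
                   threshold: float = RT_MINUS_THRESHOLD) -> str:
    """'pass' when mean Cq(RT-) - mean Cq(RT+) >= threshold or RT- undetected."""
    plus_mean, _ = triplicate_mean_cq(cq_rt_plus)
    minus_mean, n_minus = triplicate_mean_cq(cq_rt_minus)
    if n_minus == 0:  # RT- undetected: no genomic-DNA signal
        return "pass"
    return "pass" if (minus_mean - plus_mean) >= threshold else "fail"


def rt_minus_screen(records: pd.DataFrame,
                    threshold: float = RT_MINUS_THRESHOLD) -> pd.DataFrame:
    """Run the RT- contamination check over a full qPCR table.

    Returns one row per RT+ record with its check outcome; records lacking an
    RT- partner are retained with a warning flag.
    """
    plus = records[records["rt"] == "plus"]
    minus = records[records["rt"] == "minus"]
    keys = ["strain_id", "isoform", "condition", "biological_replicate_id"]
    rows = []
    for row in plus.itertuples():
        partner = minus
        for key in keys:
            partner = partner[partner[key] == getattr(row, key)]
        if partner.empty:
            outcome, flag = "pass", "missing_rt_minus_partner"
        else:
            p = partner.iloc[0]
            outcome = rt_minus_check([row.cq1, row.cq2, row.cq3],
                                     [p["cq1"], p["cq2"], p["cq3"]],
                                     threshold)
            flag = ""
        rows.append({key: getattr(row, key) for key in keys}
                    | {"outcome": outcome, "flag": flag})
    return pd.DataFrame(rows)


def load_primer_table() -> pd.DataFrame:
    """Sequence-specific ftsH qRT-PCR primer metadata (documentation/tests)."""
    path = resources.files("psiirepair").joinpath("data/primers.csv")
    with path.open("r") as fh:
        return pd.read_csv(fh)
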