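"""Absolute qPCR quantification: standard curves, QC gates, enrichment tests.

A dilution series of known template amounts gives the standard curve

    Ct = slope * log10(copies) + intercept

fitted by ordinary least squares.  Amplification efficiency is
E = 10^(-1/slope) - 1 (E = 1.0, i.e. 100%, means perfect doubling per cycle;
the canonical slope is -3.3219).  Quality gates follow common assay
practice: efficiency within 90-110%, r^2 > 0.99, and replicate Ct <= 30;
gates produce flags rather than hard failures, except a non-negative slope,
which is physically invalid.

Unknowns are converted via log10 Q = (Ct - intercept) / slope, scaled by
dilution factor and matrix mass/volume to gene copies per gram or per mL.
Samples are called biologically relevant when the replicate-mean abundance
reaches 1e3 copies per unit.  Enrichment across timepoints is tested on
log10-transformed replicate copies (variance stabilization for an
exponential assay): one-way ANOVA across all timepoints plus a two-sided
t-test between the first and last.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import QpcrRun

__all__ = [
    "StandardCurve",
    "QuantResult",
    "fit_standard_curve",
    "quantify",
    "enrichment_test",
    "efficiency_from_slope",
]

logger = logging.getLogger(__name__)

CT_GATE = 30.0
RELEVANCE_COPIES = 1e3
EFFICIENCY_BOUNDS = (0.90, 1.10)
R2_GATE = 0.99


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10^(-1/slope) - 1."""
    return 10.0 ** (-1.0 / slope) - 1.0


@dataclass
class StandardCurve:
    """OLS calibration of Ct against log10 template copies, with QC verdicts."""

    slope: float
    intercept: float
    r2: float
    efficiency: float
    qc: dict

    @property
    def qc_passed(self) -> bool:
        return self.qc["efficiency_ok"] and self.qc["r2_ok"]

    def summary(self) -> str:
        lo, hi = EFFICIENCY_BOUNDS
        return (
            "qPCR standard curve\n"
            f"  slope      {self.slope:10.4f}  Ct per log10 copies\n"
            f"  intercept  {self.intercept:10.4f}  Ct at 1 copy\n"
            f"  r^2        {self.r2:10.4f}  (gate: > {R2_GATE})\n"
            f"  efficiency {self.efficiency * 100:9.1f}%  "
            f"(gate: {lo * 100:.0f}-{hi * 100:.0f}%)\n"
            f"  QC         {'PASS' if self.qc_passed else 'FAIL'}"
        )


@dataclass
class QuantResult:
    """Per-sample/timepoint absolute abundances with relevance flags.

    ``replicates`` has one row per replicate (sample_id, timepoint, ct,
    copies_per_unit, ct_flagged); ``means`` one row per (sample_id,
    timepoint) with the replicate-mean copies and the relevance flag.
    """

    replicates: pd.DataFrame
    means: pd.DataFrame
    curve: StandardCurve


def fit_standard_curve(standards: QpcrRun | pd.DataFrame) -> StandardCurve:
    """Fit the Ct ~ log10(copies) calibration line of a dilution series."""
    std = standards.standards if isinstance(standards, QpcrRun) else standards
    x = pd.to_numeric(std["known_log10_copies"]).to_numpy(dtype=float)
    y = pd.to_numeric(std["ct"]).to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("standard curve needs >= 3 distinct concentrations")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"invalid standard curve: slope {fit.slope:.3f} is not negative"
        )
    eff = efficiency_from_slope(fit.slope)
    r2 = float(fit.rvalue ** 2)
    lo, hi = EFFICIENCY_BOUNDS
    qc = {"efficiency_ok": bool(lo <= eff <= hi), "r2_ok": bool(r2 > R2_GATE)}
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        efficiency=float(eff),
        qc=qc,
    )


def quantify(curve: StandardCurve, unknowns: QpcrRun | pd.DataFrame,
             force: bool = False) -> QuantResult:
    """Convert unknown Ct values to gene copies per gram or per mL.

    Requires the curve to have passed QC unless ``force`` is given (logged).
    Replicates with Ct above the gate (30) are flagged, not dropped; the
    per-(sample, timepoint) aggregate is the arithmetic mean of per-replicate
    copy numbers (not the mean Ct).
    """
    if not curve.qc_passed:
        if not force:
            raise ValueError(
                "standard curve failed QC "
                f"(efficiency_ok={curve.qc['efficiency_ok']}, "
                f"r2_ok={curve.qc['r2_ok']}); pass force=True to quantify anyway"
            )
        logger.warning("quantifying against a curve that failed QC (forced)")

    unk = unknowns.unknowns if isinstance(unknowns, QpcrRun) else unknowns
    frame = unk.copy()
    ct = pd.to_numeric(frame["ct"]).to_numpy(dtype=float)
    dilution = pd.to_numeric(frame.get("dilution_factor", 1.0)).to_numpy(dtype=float)
    mass = pd.to_numeric(frame.get("mass_or_volume", 1.0)).to_numpy(dtype=float)
    if (dilution <= 0).any() or (mass <= 0).any():
        raise ValueError("dilution_factor and mass_or_volume must be positive")

    log10_q = (ct - curve.intercept) / curve.slope
    copies = 10.0 ** log10_q * dilution / mass
    frame["copies_per_unit"] = copies
    frame["ct_flagged"] = ct > CT_GATE

    if "timepoint" not in frame.columns:
        frame["timepoint"] = 0
    means = (
        frame.groupby(["sample_id", "timepoint"], sort=True)["copies_per_unit"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "copies_per_unit", "count": "n_replicates"})
    )
    means["relevance_flag"] = means["copies_per_unit"] >= RELEVANCE_COPIES
    return QuantResult(replicates=frame, means=means, curve=curve)


def enrichment_test(quant: QuantResult | pd.DataFrame,
                    sample_id: str | None = None) -> dict:
    """Test for enrichment across timepoints of one sample series.

    Returns ``log10_fold_change`` (last vs first timepoint, on linear-scale
    means), ``p_anova`` (one-way ANOVA across all timepoints) and ``p_ttest``
    (two-sided t-test, first vs last), both computed on log10 replicate
    copies.
    """
    frame = quant.replicates if isinstance(quant, QuantResult) else quant
    if sample_id is not None:
        frame = frame[frame["sample_id"] == sample_id]
    groups = {
        t: g["copies_per_unit"].to_numpy(dtype=float)
        for t, g in frame.groupby("timepoint", sort=True)
    }
    if len(groups) < 2:
        raise ValueError("need >= 2 timepoints for an enrichment test")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 replicates at every timepoint")

    times = sorted(groups)
    first, last = groups[times[0]], groups[times[-1]]
    mean_first, mean_last = first.mean(), last.mean()
    if mean_first == 0:
        warnings.warn("zero mean at first timepoint; fold change is infinite",
                      stacklevel=2)
        fold = float("inf")
    else:
        fold = float(np.log10(mean_last / mean_first))

    logged = {t: np.log10(np.maximum(v, np.finfo(float).tiny))
              for t, v in groups.items()}
    p_anova = float(stats.f_oneway(*(logged[t] for t in times)).pvalue)
    p_ttest = float(stats.ttest_ind(logged[times[0]], logged[times[-1]]).pvalue)
    return {"log10_fold_change": fold, "p_anova": p_anova, "p_ttest": p_ttest}
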