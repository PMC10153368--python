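"""Quantitative assay computations.

Covers the wet-lab arithmetic downstream of the virtual screen: MTT
viability normalization to vehicle control, four-parameter logistic (Hill)
IC50 fitting, transwell blood-brain-barrier permeability
P = V_A * C_A / (t * S * C_L) with TEER normalization, and the
tumor-exposure ratio (tissue concentration over IC50).

All concentrations are in µM throughout; permeability inputs use mL, s and
cm² so that P comes out in cm/s (1 mL = 1 cm³).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

from .errors import AssayError

__all__ = [
    "DoseResponseDataset",
    "FitResult",
    "PermeabilityMeasurement",
    "normalize_viability",
    "summarize_viability",
    "fit_ic50",
    "permeability",
    "teer_normalize",
    "exposure_ratio",
]


@dataclass
class DoseResponseDataset:
    """MTT viability measurements for one compound.

    ``points`` rows are (concentration µM, replicate index, signal); the
    signal may be raw absorbance (then ``vehicle_signal`` is the matching
    vehicle absorbance) or already a percent of control (vehicle = 100).
    """

    compound_id: str
    points: list[tuple[float, int, float]]
    vehicle_signal: float = 100.0
    concentration_unit: str = "uM"

    def __post_init__(self) -> None:
        if not self.points:
            raise AssayError(f"{self.compound_id}: empty dose-response dataset")
        concs = {c for c, _, _ in self.points}
        if any(c <= 0 for c in concs):
            raise AssayError(f"{self.compound_id}: concentrations must be positive")
        self.n_concentrations = len(concs)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["concentration", "replicate", "signal"])


@dataclass
class FitResult:
    """Four-parameter logistic fit of viability vs concentration."""

    compound_id: str
    ic50: float
    hill: float
    top: float
    bottom: float
    converged: bool
    residual_sd: float
    diagnostics: dict = field(default_factory=dict)


def normalize_viability(raw_signals, vehicle_signal: float) -> np.ndarray:
    """Per-replicate viability as percent of vehicle control."""
    if vehicle_signal <= 0:
        raise AssayError("vehicle signal must be positive")
    return 100.0 * np.asarray(raw_signals, dtype=float) / vehicle_signal


def summarize_viability(dataset: DoseResponseDataset) -> pd.DataFrame:
    """Mean ± sample SD percent-of-control per concentration."""
    df = dataset.as_frame()
    df["cv_pct"] = normalize_viability(df["signal"], dataset.vehicle_signal)
    out = (
        df.groupby("concentration")["cv_pct"]
        .agg(mean="mean", sd=lambda s: float(np.std(s, ddof=1)) if len(s) > 1 else 0.0, n="count")
        .reset_index()
        .sort_values("concentration")
    )
    return out.reset_index(drop=True)


def _hill(logc: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_ic50(dataset: DoseResponseDataset, fit_config: dict | None = None) -> FitResult:
    """Least-squares 4PL fit in log-concentration space.

    CV = bottom + (top - bottom) / (1 + (c / IC50)^hill), with bounds
    0 <= bottom < top <= 120 and IC50 constrained to [min conc / 10,
    max conc * 10]. Initialization: top = max CV, bottom = min CV, IC50 at
    the concentration bracketing the 50%-of-span crossing, hill = 1.
    Non-convergence (or a viability trend that rises with dose, violating
    the inhibition model) is reported via ``converged=False`` with
    diagnostics, never as a silent number.
    """
    cfg = fit_config or {}
    if dataset.n_concentrations < 4:
        raise AssayError(
            f"{dataset.compound_id}: need >=4 distinct concentrations, "
            f"got {dataset.n_concentrations}"
        )
    df = dataset.as_frame()
    cv = normalize_viability(df["signal"].to_numpy(), dataset.vehicle_signal)
    logc = np.log10(df["concentration"].to_numpy(dtype=float))

    means = pd.DataFrame({"logc": logc, "cv": cv}).groupby("logc")["cv"].mean()
    rho = spearmanr(means.index.to_numpy(), means.to_numpy()).statistic
    increasing = bool(rho is not None and not math.isnan(rho) and rho > 0.5)

    top0 = float(np.max(cv))
    bottom0 = float(np.min(cv))
    span = max(top0 - bottom0, 1e-6)
    half = bottom0 + span / 2.0
    crossing = means.index[np.argmin(np.abs(means.to_numpy() - half))]
    lo_ic50 = float(df["concentration"].min()) / 10.0
    hi_ic50 = float(df["concentration"].max()) * 10.0
    p0 = [
        max(bottom0, 0.0),
        min(max(top0, bottom0 + 1.0), 120.0),
        float(np.clip(crossing, math.log10(lo_ic50), math.log10(hi_ic50))),
        1.0,
    ]
    bounds = (
        [0.0, 0.0, math.log10(lo_ic50), cfg.get("hill_min", 0.05)],
        [119.999, 120.0, math.log10(hi_ic50), cfg.get("hill_max", 20.0)],
    )
    try:
        popt, _ = curve_fit(_hill, logc, cv, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return FitResult(
            compound_id=dataset.compound_id,
            ic50=float("nan"),
            hill=float("nan"),
            top=float("nan"),
            bottom=float("nan"),
            converged=False,
            residual_sd=float("nan"),
            diagnostics={"error": str(exc), "monotone_increasing": increasing},
        )
    bottom, top, log_ic50, hill = (float(v) for v in popt)
    resid = cv - _hill(logc, *popt)
    residual_sd = float(np.sqrt(np.mean(resid**2)))
    converged = top > bottom and not increasing
    return FitResult(
        compound_id=dataset.compound_id,
        ic50=10.0**log_ic50,
        hill=hill,
        top=top,
        bottom=bottom,
        converged=converged,
        residual_sd=residual_sd,
        diagnostics={"monotone_increasing": increasing, "spearman_rho": float(rho)},
    )


@dataclass
class PermeabilityMeasurement:
    """One transwell well: geometry, concentrations, TEER and derived P.

    v_receiver mL, concentrations µM (receiver C_A, donor C_L), t s,
    s_area cm², teer Ω·cm². ``p`` is filled by :func:`permeability`;
    ``p_teer_normalized`` by :func:`teer_normalize`.
    """

    v_receiver: float
    c_receiver: float
    c_donor: float
    t: float
    s_area: float
    teer: float | None = None
    p: float | None = None
    p_teer_normalized: float | None = None

    def compute(self, reference_teer: float | None = None) -> "PermeabilityMeasurement":
        self.p = permeability(self.v_receiver, self.c_receiver, self.t, self.s_area, self.c_donor)
        if self.teer is not None and reference_teer is not None:
            self.p_teer_normalized = teer_normalize(self.p, self.teer, reference_teer)
        return self


def permeability(
    v_receiver: float, c_receiver: float, t: float, s_area: float, c_donor: float
) -> float:
    """Apparent permeability P = V_A * C_A / (t * S * C_L) in cm/s.

    C_A = 0 legitimately gives P = 0 (nothing crossed); every other input
    must be strictly positive.
    """
    if v_receiver <= 0 or t <= 0 or s_area <= 0 or c_donor <= 0 or c_receiver < 0:
        raise AssayError("permeability inputs must be positive (c_receiver >= 0)")
    return v_receiver * c_receiver / (t * s_area * c_donor)


def teer_normalize(p: float, teer: float, reference_teer: float) -> float:
    """Scale P by the well's barrier tightness: p * (TEER / reference TEER).

    Multiplicative convention — a well tighter than reference up-weights the
    observed flux. Wells normalized to their batch-mean TEER preserve the
    batch-mean P.
    """
    if teer <= 0 or reference_teer <= 0:
        raise AssayError("TEER values must be positive")
    return p * (teer / reference_teer)


def exposure_ratio(tissue_conc_um: float, ic50_um: float) -> float:
    """Fold-excess of measured tissue concentration over the cellular IC50."""
    if tissue_conc_um <= 0 or ic50_um <= 0:
        raise AssayError("tissue concentration and IC50 must be positive")
    return tissue_conc_um / ic50_um
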