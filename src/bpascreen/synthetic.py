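"""Seeded generators for every input the pipeline consumes.

These emulate the study's experimental designs so every stage can be tested
end to end without external data: triplicate MTT dose-response tables on a
log-spaced concentration ladder with Gaussian replicate noise, scored
reference-drug panels with a known acceptability box (the calibration
input), and transwell donor/receiver concentration pairs implied by a chosen
permeability coefficient. All generators are pure functions of their
parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioassay import DoseResponseDataset, PermeabilityMeasurement
from .errors import AssayError

__all__ = [
    "SimConfig",
    "DEFAULT_ACCEPTABLE_BOX",
    "gen_dose_response",
    "gen_reference_panel",
    "gen_permeability_wells",
]

DEFAULT_SEED = 20230420


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation settings.

    Defaults mirror the study conditions: triplicates, 8-point log ladder,
    5% replicate noise, IC50s on the low-µM scale of the active series, and
    a 15-drug reference panel of which 6 are acceptable.
    """

    seed: int = DEFAULT_SEED
    n_compounds: int = 15
    n_concentrations: int = 8
    replicates: int = 3
    noise_sd_pct: float = 5.0
    ic50_range: tuple[float, float] = (0.5, 5.0)
    hill_range: tuple[float, float] = (0.8, 1.5)
    acceptable_fraction: float = 6.0 / 15.0

    def __post_init__(self) -> None:
        if self.n_concentrations < 4 or self.replicates < 1:
            raise AssayError("need >=4 concentrations and >=1 replicate")
        if self.ic50_range[0] <= 0 or self.ic50_range[0] >= self.ic50_range[1]:
            raise AssayError("ic50_range must be positive and increasing")
        if not 0 < self.acceptable_fraction <= 1:
            raise AssayError("acceptable_fraction must be in (0, 1]")


def gen_dose_response(
    true_params: dict,
    config: SimConfig | None = None,
    compound_id: str = "sim",
    concentrations: np.ndarray | None = None,
) -> DoseResponseDataset:
    """Hill-curve viability data with Gaussian replicate noise.

    ``true_params``: ic50 (µM, required), hill (default 1), top (default
    100), bottom (default 0). Concentrations default to a log ladder
    spanning ic50/30 .. ic50*30; the true IC50 must lie within
    [min conc * 0.1, max conc * 10]. Noise SD is ``noise_sd_pct`` percent of
    top; values are left unclipped (MTT readouts can exceed control).
    """
    config = config or SimConfig()
    ic50 = float(true_params["ic50"])
    hill = float(true_params.get("hill", 1.0))
    top = float(true_params.get("top", 100.0))
    bottom = float(true_params.get("bottom", 0.0))
    if ic50 <= 0:
        raise AssayError("true ic50 must be positive")
    if concentrations is None:
        concentrations = np.geomspace(ic50 / 30.0, ic50 * 30.0, config.n_concentrations)
    concentrations = np.asarray(concentrations, dtype=float)
    if not concentrations.min() * 0.1 <= ic50 <= concentrations.max() * 10.0:
        raise AssayError("true ic50 outside the concentration range * [0.1, 10]")
    rng = np.random.default_rng(config.seed)
    sd = config.noise_sd_pct / 100.0 * top
    points = []
    for conc in concentrations:
        mean = bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)
        for rep in range(config.replicates):
            noise = rng.normal(0.0, sd) if sd > 0 else 0.0
            points.append((float(conc), rep, float(mean + noise)))
    return DoseResponseDataset(compound_id=compound_id, points=points, vehicle_signal=100.0)


#: Acceptability box mirroring the reference-drug criteria: soluble
#: (logS < 0), low lipophilicity (logD < 3), CNS-MPO and BBB score in the
#: favorable bands, hERG at most 5.5.
DEFAULT_ACCEPTABLE_BOX: dict[str, tuple[float, float]] = {
    "logs": (-4.0, 0.0),
    "clogd": (-1.0, 3.0),
    "cns_mpo": (3.0, 5.0),
    "bbb_score": (4.0, 5.0),
    "herg_pic50": (3.0, 5.5),
    "neg_logs": (0.0, 4.0),
    "mpa": (30.0, 60.0),
}


def gen_reference_panel(
    config: SimConfig | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Scored reference panel with acceptability flags.

    Exactly ``round(acceptable_fraction * n_compounds)`` members are drawn
    uniformly inside the acceptable box; the rest are pushed outside the box
    in at least one coordinate. Columns: drug id, every box coordinate, and
    the ``acceptable`` flag.
    """
    config = config or SimConfig()
    bounds = bounds or DEFAULT_ACCEPTABLE_BOX
    for name, (lo, hi) in bounds.items():
        if not lo <= hi:
            raise AssayError(f"empty acceptability box on {name!r}")
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    n_acc = int(round(config.acceptable_fraction * n))
    rows = []
    names = list(bounds)
    for i in range(n):
        acceptable = i < n_acc
        row = {"drug": f"ref{i + 1:02d}", "acceptable": acceptable}
        for name in names:
            lo, hi = bounds[name]
            row[name] = float(rng.uniform(lo, hi))
        if not acceptable:
            # violate >=1 coordinate, pushed beyond the box by 10-60% of span
            k = int(rng.integers(1, max(2, len(names) // 2)))
            viol = rng.choice(len(names), size=k, replace=False)
            for idx in viol:
                name = names[int(idx)]
                lo, hi = bounds[name]
                span = max(hi - lo, 1e-6)
                off = float(rng.uniform(0.1, 0.6)) * span
                row[name] = hi + off if rng.random() < 0.5 else lo - off
        rows.append(row)
    return pd.DataFrame(rows)


def gen_permeability_wells(
    p_true: float,
    geometry: dict | None = None,
    config: SimConfig | None = None,
    n_wells: int = 6,
    reference_teer: float = 150.0,
) -> list[PermeabilityMeasurement]:
    """Transwell wells whose receiver concentration is implied by ``p_true``.

    The receiver concentration is obtained by inverting
    P = V_A*C_A/(t*S*C_L): C_A = P*t*S*C_L/V_A, then perturbed by relative
    Gaussian noise (``noise_sd_pct``). TEER is drawn around
    ``reference_teer`` with 10% relative SD, truncated positive. Default
    geometry matches a 24-well transwell: 0.5 mL receiver, 0.33 cm²
    membrane, 3 h, donor 25 µM.
    """
    if p_true < 0:
        raise AssayError("p_true must be nonnegative")
    geometry = {
        "v_receiver": 0.5,
        "t": 10800.0,
        "s_area": 0.33,
        "c_donor": 25.0,
        **(geometry or {}),
    }
    if min(geometry["v_receiver"], geometry["t"], geometry["s_area"], geometry["c_donor"]) <= 0:
        raise AssayError("geometry values must be positive")
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    c_a_true = (
        p_true * geometry["t"] * geometry["s_area"] * geometry["c_donor"] / geometry["v_receiver"]
    )
    wells = []
    for _ in range(n_wells):
        rel = rng.normal(0.0, config.noise_sd_pct / 100.0) if config.noise_sd_pct > 0 else 0.0
        c_a = max(c_a_true * (1.0 + rel), 0.0)
        teer = abs(rng.normal(reference_teer, 0.1 * reference_teer))
        wells.append(
            PermeabilityMeasurement(
                v_receiver=geometry["v_receiver"],
                c_receiver=c_a,
                c_donor=geometry["c_donor"],
                t=geometry["t"],
                s_area=geometry["s_area"],
                teer=teer,
            )
        )
    return wells
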