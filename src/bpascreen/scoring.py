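"""Brain-penetration scores: CNS-MPO, BBB score and logBB.

CNS-MPO (Wager et al., ACS Chem. Neurosci. 2010, 1, 435) sums six
piecewise-linear desirability transforms of ClogP, ClogD(7.4), MW, TPSA, HBD
and the most-basic pKa; each component lies in [0, 1], the score in [0, 6],
and values >= 4 are conventionally read as CNS-favorable.

The BBB score (Gupta et al., J. Med. Chem. 2019, 62, 9824) is a weighted sum
of five component functions of aromatic-ring count, heavy atoms, MWHBN
( = (HBD+HBA)/sqrt(MW) ), TPSA and basic pKa, also on a 0-6 scale with 4 as
the usual cut-off. Its coefficients are data, not code: they live in
``data/bbb_score_table.json`` and may be substituted per run.

logBB is simply log10 of the brain:plasma concentration ratio; a drug whose
CNS exposure is 20% of plasma has logBB = -0.7.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .descriptors import DescriptorSet
from .errors import ScoringError

__all__ = [
    "ScoreSet",
    "cns_mpo",
    "bbb_score",
    "logbb",
    "load_bbb_table",
    "score_descriptors",
]


@dataclass
class ScoreSet:
    """The per-compound score panel consumed by the screening gate."""

    cns_mpo: float
    cns_mpo_components: dict[str, float]
    bbb_score: float
    bbb_components: dict[str, float]
    mwhbn: float
    neg_logs: float | None = None
    herg_pic50: float | None = None
    extras: dict[str, float] = field(default_factory=dict)


def _ramp_down(x: float, lo: float, hi: float) -> float:
    """Monotone desirability: 1 at/below ``lo``, 0 at/above ``hi``."""
    if x <= lo:
        return 1.0
    if x >= hi:
        return 0.0
    return (hi - x) / (hi - lo)


def _hump(x: float, zero_lo: float, one_lo: float, one_hi: float, zero_hi: float) -> float:
    """Unimodal desirability with a plateau of 1 on [one_lo, one_hi]."""
    if x <= zero_lo or x >= zero_hi:
        return 0.0
    if x < one_lo:
        return (x - zero_lo) / (one_lo - zero_lo)
    if x <= one_hi:
        return 1.0
    return (zero_hi - x) / (zero_hi - one_hi)


def cns_mpo(descriptors: DescriptorSet) -> tuple[float, dict[str, float]]:
    """CNS-MPO score and its six named components.

    Sharp piecewise-linear ramps ("T0" form): ClogP 1 below 3 / 0 above 5;
    ClogD 2/4; MW 360/500; TPSA a 20-40-90-120 hump; HBD 0.5/3.5; pKa 8/10.
    A compound with no basic center is maximally desirable on the pKa axis
    (component = 1): a non-basic amide cannot be penalized for basicity.
    """
    required = {
        "clogp": descriptors.clogp,
        "clogd_74": descriptors.clogd_74,
        "mw": descriptors.mw,
        "tpsa": descriptors.tpsa,
        "hbd": descriptors.hbd,
    }
    for name, value in required.items():
        if value is None:
            raise ScoringError(f"CNS-MPO requires descriptor {name!r}")
    components = {
        "clogp": _ramp_down(descriptors.clogp, 3.0, 5.0),
        "clogd": _ramp_down(descriptors.clogd_74, 2.0, 4.0),
        "mw": _ramp_down(descriptors.mw, 360.0, 500.0),
        "tpsa": _hump(descriptors.tpsa, 20.0, 40.0, 90.0, 120.0),
        "hbd": _ramp_down(descriptors.hbd, 0.5, 3.5),
        "pka": 1.0 if descriptors.pka_basic is None else _ramp_down(descriptors.pka_basic, 8.0, 10.0),
    }
    return sum(components.values()), components


_DEFAULT_TABLE: dict | None = None


def load_bbb_table(path: str | Path | None = None) -> dict:
    """Load the BBB-score coefficient table (default: packaged version)."""
    global _DEFAULT_TABLE
    if path is not None:
        return json.loads(Path(path).read_text())
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = json.loads(
            resources.files("bpascreen.data").joinpath("bbb_score_table.json").read_text()
        )
    return _DEFAULT_TABLE


def _poly_component(x: float | None, spec: dict) -> float:
    if x is None:
        return 0.0
    lo, hi = spec["range"]
    if not lo < x <= hi:
        # outside the fitted range the published component is zero
        if not (lo == 0 and x == 0):
            return 0.0
    value = 0.0
    for coeff in spec["poly"]:
        value = value * x + coeff
    value /= spec["scale"]
    return min(1.0, max(0.0, value))


def bbb_score(
    descriptors: DescriptorSet, table: dict | None = None
) -> tuple[float, dict[str, float]]:
    """BBB score and its five named components, clamped to [0, 6].

    pKa is optional: with no supplied basic pKa the pKa component contributes
    zero (the neutral molecule forgoes the basicity bonus), per the packaged
    table's ``missing_policy``.
    """
    table = table or load_bbb_table()
    for name in ("aromatic_rings", "heavy_atoms", "mw", "hbd", "hba", "tpsa"):
        if getattr(descriptors, name, None) is None:
            raise ScoringError(f"BBB score requires descriptor {name!r}")
    step = table["aromatic_rings_step"]
    p_aro = step.get(str(descriptors.aromatic_rings), step["default"])
    components = {
        "aromatic_rings": p_aro,
        "heavy_atoms": _poly_component(float(descriptors.heavy_atoms), table["heavy_atoms"]),
        "mwhbn": _poly_component(descriptors.mwhbn, table["mwhbn"]),
        "tpsa": _poly_component(descriptors.tpsa, table["tpsa"]),
        "pka": _poly_component(descriptors.pka_basic, table["pka"]),
    }
    weights = table["weights"]
    score = sum(weights[k] * v for k, v in components.items())
    return min(6.0, max(0.0, score)), components


def logbb(cns_fraction_of_plasma: float) -> float:
    """log10 brain:plasma ratio; 0.20 (20% of plasma) gives -0.70."""
    if cns_fraction_of_plasma <= 0:
        raise ScoringError("CNS fraction of plasma must be positive")
    return math.log10(cns_fraction_of_plasma)


def score_descriptors(
    descriptors: DescriptorSet,
    herg_pic50: float | None = None,
    table: dict | None = None,
) -> ScoreSet:
    """Bundle CNS-MPO and BBB score (plus pass-through hERG) for the gate."""
    mpo, mpo_parts = cns_mpo(descriptors)
    bbb, bbb_parts = bbb_score(descriptors, table)
    return ScoreSet(
        cns_mpo=mpo,
        cns_mpo_components=mpo_parts,
        bbb_score=bbb,
        bbb_components=bbb_parts,
        mwhbn=descriptors.mwhbn,
        neg_logs=descriptors.neg_logs,
        herg_pic50=herg_pic50,
    )
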