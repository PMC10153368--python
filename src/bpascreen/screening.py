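"""Multi-criteria candidate selection.

The screen applies a calibrated gate to each scored compound: predicted hERG
pIC50 below 5.5, estimated -logS below 7.5, CNS-MPO over 3, BBB score inside
[4, 5] and minimal projection area below 60 Å². "Below"/"over" bounds are
strict, the BBB band is a closed interval, and criteria whose inputs are
missing are skipped and reported, never silently passed. Thresholds can also
be calibrated from a scored reference-drug panel flagged acceptable /
unacceptable, taking the observed range of the acceptable subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ScoringError

__all__ = [
    "GateThresholds",
    "GateResult",
    "default_candidate_gate",
    "calibrate",
    "apply_gate",
    "rank_candidates",
    "nucleophilicity_rank",
]


@dataclass(frozen=True)
class GateThresholds:
    """Bounds for the candidate gate plus the reference-panel criteria.

    ``clogd_max`` and ``logs_max`` describe reference-panel acceptability
    (logD < 3, logS < 0) used during calibration; they are not enforced on
    candidates, whose synthesized series intentionally exceeds ClogD 3.
    """

    herg_max: float = 5.5
    neg_logs_max: float = 7.5
    cns_mpo_min: float = 3.0
    bbb_min: float = 4.0
    bbb_max: float = 5.0
    mpa_max: float = 60.0
    clogd_max: float = 3.0
    logs_max: float = 0.0
    provenance: str = "default candidate gate"

    def __post_init__(self) -> None:
        if not self.bbb_min < self.bbb_max:
            raise ScoringError("bbb_min must be below bbb_max")
        values = [
            self.herg_max, self.neg_logs_max, self.cns_mpo_min,
            self.bbb_min, self.bbb_max, self.mpa_max, self.clogd_max, self.logs_max,
        ]
        if not all(np.isfinite(values)):
            raise ScoringError("gate thresholds must be finite")


@dataclass
class GateResult:
    """Verdict for one compound: pass iff every *evaluated* criterion passes."""

    compound_id: str
    verdict: bool
    per_criterion: dict[str, tuple[float, str, bool]]  # value, bound text, passed
    missing: list[str] = field(default_factory=list)


def default_candidate_gate() -> GateThresholds:
    """The published candidate gate: hERG<5.5, -logS<7.5, MPO>3, BBB in [4,5], MPA<60."""
    return GateThresholds()


#: criterion name -> (record key, kind); kind: 'lt' strict upper, 'gt' strict
#: lower, 'interval' closed band.
_CRITERIA = {
    "herg": ("herg_pic50", "lt"),
    "neg_logs": ("neg_logs", "lt"),
    "cns_mpo": ("cns_mpo", "gt"),
    "bbb_score": ("bbb_score", "interval"),
    "mpa": ("mpa", "lt"),
}


def apply_gate(record: Mapping[str, float | None], thresholds: GateThresholds) -> GateResult:
    """Evaluate one compound record against the gate.

    ``record`` must carry ``compound_id`` and any of ``herg_pic50``,
    ``neg_logs``, ``cns_mpo``, ``bbb_score``, ``mpa``; missing/None values
    skip that criterion and are listed in the result.
    """
    bounds = {
        "herg": thresholds.herg_max,
        "neg_logs": thresholds.neg_logs_max,
        "cns_mpo": thresholds.cns_mpo_min,
        "bbb_score": (thresholds.bbb_min, thresholds.bbb_max),
        "mpa": thresholds.mpa_max,
    }
    per: dict[str, tuple[float, str, bool]] = {}
    missing: list[str] = []
    for crit, (key, kind) in _CRITERIA.items():
        value = record.get(key)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            missing.append(crit)
            continue
        value = float(value)
        if kind == "lt":
            ok = value < bounds[crit]
            bound_text = f"< {bounds[crit]}"
        elif kind == "gt":
            ok = value > bounds[crit]
            bound_text = f"> {bounds[crit]}"
        else:
            lo, hi = bounds[crit]
            ok = lo <= value <= hi
            bound_text = f"in [{lo}, {hi}]"
        per[crit] = (value, bound_text, ok)
    verdict = all(ok for _, _, ok in per.values()) and bool(per)
    return GateResult(
        compound_id=str(record.get("compound_id", record.get("id", "?"))),
        verdict=verdict,
        per_criterion=per,
        missing=missing,
    )


def _widen(lo: float, hi: float, policy: str) -> tuple[float, float]:
    if policy == "range":
        # one ulp of slack so panel members sitting exactly at the observed
        # extreme still pass the strict gate
        return float(np.nextafter(lo, -np.inf)), float(np.nextafter(hi, np.inf))
    if policy.startswith("widen:"):
        frac = float(policy.split(":", 1)[1])
        span = max(hi - lo, 1e-12)
        return lo - frac * span, hi + frac * span
    raise ScoringError(f"unknown quantile policy {policy!r}")


def calibrate(
    reference_panel_scores: pd.DataFrame,
    quantile_policy: str = "range",
) -> GateThresholds:
    """Derive gate thresholds from a scored, acceptability-flagged drug panel.

    The panel must carry an ``acceptable`` boolean column plus score columns
    (``herg_pic50``, ``neg_logs``, ``cns_mpo``, ``bbb_score`` and optionally
    ``mpa``, ``clogd``, ``logs``). Thresholds are the observed extremes of
    the acceptable subset, optionally widened (``"widen:<frac>"``).
    """
    df = pd.DataFrame(reference_panel_scores)
    if "acceptable" not in df.columns:
        raise ScoringError("reference panel needs an 'acceptable' flag column")
    if len(df) < 2:
        raise ScoringError("reference panel needs at least 2 scored drugs")
    acc = df[df["acceptable"].astype(bool)]
    if acc.empty:
        raise ScoringError("no acceptable reference drugs to calibrate from")

    def _span(col: str) -> tuple[float, float] | None:
        if col in acc.columns and acc[col].notna().any():
            vals = acc[col].dropna().astype(float)
            return _widen(float(vals.min()), float(vals.max()), quantile_policy)
        return None

    def hi(col: str, default: float) -> float:
        span = _span(col)
        return default if span is None else span[1]

    def lo(col: str, default: float) -> float:
        span = _span(col)
        return default if span is None else span[0]

    base = GateThresholds()
    bbb_lo, bbb_hi = base.bbb_min, base.bbb_max
    if "bbb_score" in acc.columns and acc["bbb_score"].notna().any():
        bbb_lo, bbb_hi = _widen(
            float(acc["bbb_score"].min()), float(acc["bbb_score"].max()), quantile_policy
        )
    return GateThresholds(
        herg_max=hi("herg_pic50", base.herg_max),
        neg_logs_max=hi("neg_logs", base.neg_logs_max),
        cns_mpo_min=lo("cns_mpo", base.cns_mpo_min),
        bbb_min=bbb_lo,
        bbb_max=bbb_hi,
        mpa_max=hi("mpa", base.mpa_max),
        clogd_max=hi("clogd", base.clogd_max),
        logs_max=hi("logs", base.logs_max),
        provenance=(
            f"calibrated from {int(acc.shape[0])}/{len(df)} acceptable reference "
            f"drugs, policy={quantile_policy}"
        ),
    )


def rank_candidates(
    results: Sequence[GateResult],
    scores: Mapping[str, Mapping[str, float | None]],
) -> pd.DataFrame:
    """Order gate results: passing compounds first, by (CNS-MPO desc,
    BBB desc, -logS asc), stable id tie-break; failures follow in id order."""
    if not results:
        raise ScoringError("no gate results to rank")
    rows = []
    for r in results:
        s = scores.get(r.compound_id, {})
        rows.append(
            {
                "compound_id": r.compound_id,
                "verdict": "pass" if r.verdict else "fail",
                "cns_mpo": s.get("cns_mpo"),
                "bbb_score": s.get("bbb_score"),
                "neg_logs": s.get("neg_logs"),
                "missing": ";".join(r.missing),
            }
        )
    df = pd.DataFrame(rows)
    df["_mpo"] = -df["cns_mpo"].astype(float).fillna(-np.inf)
    df["_bbb"] = -df["bbb_score"].astype(float).fillna(-np.inf)
    df["_nls"] = df["neg_logs"].astype(float).fillna(np.inf)
    passing = df[df["verdict"] == "pass"].sort_values(
        ["_mpo", "_bbb", "_nls", "compound_id"], kind="stable"
    )
    failing = df[df["verdict"] == "fail"].sort_values("compound_id", kind="stable")
    out = pd.concat([passing, failing]).drop(columns=["_mpo", "_bbb", "_nls"])
    return out.reset_index(drop=True)


def nucleophilicity_rank(
    entries: Iterable[tuple[str, float]],
) -> list[tuple[str, float]]:
    """Order compounds most-to-least nucleophilic by supplied HOMO energy.

    Frontier-orbital comparison is only meaningful between structurally
    similar scaffolds; callers comparing dissimilar chemotypes are outside
    the contract of this ranking (the ordering is still returned).
    Descending E_HOMO; ties keep input order (stable sort).
    """
    entries = list(entries)
    return sorted(entries, key=lambda t: -t[1])
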