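"""End-to-end screen: descriptors -> scores -> gate -> ranked shortlist.

``run_screen`` wires the stages together for a whole panel and writes a
reproducible report bundle: per-compound descriptor and score tables, the
gate report, the ranked shortlist, and a JSON audit trail carrying every
criterion with its value, bound and provenance. With a fixed seed a rerun
produces byte-identical outputs (no timestamps enter the reports).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compounds import CompoundPanel, builtin_fixture, load_panel
from .descriptors import DEFAULT_MPA_SEED, MpaConfig, full_descriptors
from .errors import BpaScreenError
from .scoring import score_descriptors
from .screening import GateThresholds, apply_gate, default_candidate_gate, rank_candidates

__all__ = ["RunConfig", "ScreenReport", "run_screen"]


@dataclass
class RunConfig:
    """Configuration for one screening run.

    ``panel`` is a path to a .smi/.csv/.sdf panel or the name of a built-in
    fixture (``hr_named``, ``controls``); ``thresholds`` is "default" or a
    JSON file of gate bounds; ``with_mpa=False`` skips the conformer stage
    (the gate then reports the MPA criterion as missing).
    """

    panel: str = "hr_named"
    thresholds: str = "default"
    outdir: str = "screen_out"
    seed: int = DEFAULT_MPA_SEED
    with_mpa: bool = True
    mpa: MpaConfig = field(default_factory=MpaConfig)
    log_level: str = "INFO"


@dataclass
class ScreenReport:
    descriptors: pd.DataFrame
    scores: pd.DataFrame
    gate: pd.DataFrame
    shortlist: pd.DataFrame
    audit: dict
    outdir: Path


def _load_input_panel(spec: str) -> CompoundPanel:
    if spec in ("hr_named", "controls"):
        return builtin_fixture(spec)
    path = Path(spec)
    if not path.exists():
        raise BpaScreenError(f"panel {spec!r}: no such fixture or file")
    return load_panel(path)


def _load_thresholds(spec: str) -> GateThresholds:
    if spec == "default":
        return default_candidate_gate()
    payload = json.loads(Path(spec).read_text())
    payload.setdefault("provenance", f"loaded from {Path(spec).name}")
    return GateThresholds(**payload)


def run_screen(config: RunConfig) -> ScreenReport:
    """Run the full screen for a panel and write the report bundle."""
    panel = _load_input_panel(config.panel)
    thresholds = _load_thresholds(config.thresholds)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    desc_rows, score_rows, gate_results, audit_compounds = [], [], [], {}
    for compound in panel:
        try:
            ds = full_descriptors(
                compound, mpa_config=config.mpa, seed=config.seed, with_mpa=config.with_mpa
            )
            scores = score_descriptors(ds, herg_pic50=compound.overrides.get("herg_pic50"))
        except BpaScreenError as exc:
            raise BpaScreenError(
                f"stage descriptors/scores failed for compound {compound.id!r}: {exc}"
            ) from exc
        desc_rows.append(
            {
                "compound_id": compound.id,
                "group": compound.group,
                "mw": ds.mw,
                "tpsa": ds.tpsa,
                "hbd": ds.hbd,
                "hba": ds.hba,
                "aromatic_rings": ds.aromatic_rings,
                "heavy_atoms": ds.heavy_atoms,
                "rotatable_bonds": ds.rotatable_bonds,
                "clogp": ds.clogp,
                "clogd_74": ds.clogd_74,
                "logs": ds.logs,
                "neg_logs": ds.neg_logs,
                "polarizability": ds.polarizability,
                "mpa": ds.mpa,
            }
        )
        record = {
            "compound_id": compound.id,
            "cns_mpo": scores.cns_mpo,
            "bbb_score": scores.bbb_score,
            "mwhbn": scores.mwhbn,
            "neg_logs": scores.neg_logs,
            "herg_pic50": scores.herg_pic50,
            "mpa": ds.mpa,
        }
        score_rows.append(record)
        result = apply_gate(record, thresholds)
        gate_results.append(result)
        audit_compounds[compound.id] = {
            "smiles": compound.smiles,
            "group": compound.group,
            "inferred": compound.inferred,
            "descriptors": {
                k: v for k, v in desc_rows[-1].items() if k not in ("compound_id", "group")
            },
            "scores": {
                "cns_mpo": scores.cns_mpo,
                "cns_mpo_components": scores.cns_mpo_components,
                "bbb_score": scores.bbb_score,
                "bbb_components": scores.bbb_components,
                "mwhbn": scores.mwhbn,
            },
            "gate": {
                "verdict": "pass" if result.verdict else "fail",
                "criteria": {
                    crit: {"value": val, "bound": bound, "pass": ok}
                    for crit, (val, bound, ok) in result.per_criterion.items()
                },
                "missing": result.missing,
            },
        }

    descriptors = pd.DataFrame(desc_rows)
    scores_df = pd.DataFrame(score_rows)
    gate_df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "verdict": "pass" if r.verdict else "fail",
                **{
                    crit: val for crit, (val, _, _) in r.per_criterion.items()
                },
                "failed": ";".join(
                    crit for crit, (_, _, ok) in r.per_criterion.items() if not ok
                ),
                "missing": ";".join(r.missing),
            }
            for r in gate_results
        ]
    )
    shortlist = rank_candidates(
        gate_results, {row["compound_id"]: row for row in score_rows}
    )

    config_payload = {
        "panel": config.panel,
        "thresholds": dataclasses.asdict(thresholds),
        "seed": config.seed,
        "with_mpa": config.with_mpa,
        "mpa": dataclasses.asdict(config.mpa),
    }
    config_hash = hashlib.sha256(
        json.dumps(config_payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    audit = {
        "tool": {"name": "bpascreen", "version": __version__},
        "config": config_payload,
        "config_hash": config_hash,
        "panel_provenance": panel.provenance,
        "compounds": audit_compounds,
    }

    descriptors.to_csv(outdir / "descriptors.csv", index=False, float_format="%.6g")
    scores_df.to_csv(outdir / "scores.csv", index=False, float_format="%.6g")
    gate_df.to_csv(outdir / "gate_report.csv", index=False, float_format="%.6g")
    shortlist.to_csv(outdir / "shortlist.csv", index=False, float_format="%.6g")
    (outdir / "audit.json").write_text(json.dumps(audit, indent=2, sort_keys=True) + "\n")
    (outdir / "run_log.txt").write_text(
        "\n".join(
            [
                f"bpascreen {__version__}",
                f"config_hash {config_hash}",
                f"panel {config.panel} ({len(panel)} compounds)",
                f"gate {thresholds.provenance}",
                f"passing {int((gate_df['verdict'] == 'pass').sum())}/{len(gate_df)}",
            ]
        )
        + "\n"
    )
    return ScreenReport(descriptors, scores_df, gate_df, shortlist, audit, outdir)
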