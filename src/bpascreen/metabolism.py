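"""Rule-based phase-I metabolite enumeration and re-scoring.

Phase-I functionalization (hydrolysis, oxidation, reduction) is modeled as a
small set of SMARTS reaction transforms applied at every matching site of
the parent. The default rule set covers amide and ester hydrolysis, aromatic
and benzylic hydroxylation, diaryl/dialkyl ketone reduction and aryl-ether
O-dealkylation; rules are plain data and can be replaced per run. Every
hydrolysis product pair is checked for mass balance (parent + H2O) by
molecular formula. Enumerated products are pushed back through the
descriptor and scoring stack so a metabolite's solubility and
CNS-penetration profile can be compared with its parent, and supplied hERG
predictions below the alert bound raise a ``herg_alert`` flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdChemReactions

from .compounds import Compound, parse_compound
from .descriptors import aromatic_proportion, esol_logs, physchem
from .errors import RuleError
from .scoring import ScoreSet, score_descriptors

__all__ = [
    "DEFAULT_RULES",
    "HERG_ALERT_BOUND",
    "MetaboliteRecord",
    "enumerate_phase1",
    "score_metabolites",
]

#: Default phase-I transformation patterns. Hydroxylation is restricted to
#: aromatic CH and benzylic positions (plus the degenerate single-carbon
#: case) to bound combinatorics.
DEFAULT_RULES: dict[str, str] = {
    "amide_hydrolysis": (
        "[CX3;!R:1](=[OX1:2])[NX3;!$([N]=*):3]>>[CX3:1](=[OX1:2])[OX2H1].[NX3:3]"
    ),
    "ester_hydrolysis": (
        "[CX3;!R:1](=[OX1:2])[OX2:3][#6:4]>>[CX3:1](=[OX1:2])[OX2H1].[OX2H1:3][#6:4]"
    ),
    "aromatic_hydroxylation": "[cH1:1]>>[c:1][OX2H1]",
    "aliphatic_hydroxylation": (
        "[CX4;!H0;$([CX4]c),$([CH4]):1]>>[CX4:1][OX2H1]"
    ),
    "ketone_reduction": (
        "[#6:3][CX3:1](=[OX1:2])[#6:4]>>[#6:3][CX4H1:1]([OX2H1:2])[#6:4]"
    ),
    "o_dealkylation": "[c:1][OX2:2][CX4;!H0:3]>>[c:1][OX2H1:2].[CX3H1:3]=[OX1]",
}

#: Supplied hERG predictions below this pIC50-like bound raise `herg_alert`
#: on a metabolite row (lower-bound convention of the upstream predictor).
HERG_ALERT_BOUND = 4.5

_HYDROLYSIS_RULES = {"amide_hydrolysis", "ester_hydrolysis"}


@dataclass
class MetaboliteRecord:
    """Products of one rule applied at one site of one parent."""

    parent_id: str
    rule: str
    products: list[str]  # canonical SMILES
    site: int = 0
    scores: dict[str, ScoreSet] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _formula_counts(mol: Chem.Mol) -> Counter:
    mol = Chem.AddHs(mol)
    return Counter(a.GetSymbol() for a in mol.GetAtoms())


def _check_hydrolysis_balance(parent: Chem.Mol, products: list[Chem.Mol], rule: str) -> None:
    if len(products) != 2:
        raise RuleError(f"{rule}: expected 2 products, got {len(products)}")
    lhs = _formula_counts(parent) + Counter({"H": 2, "O": 1})
    rhs = Counter()
    for p in products:
        rhs += _formula_counts(p)
    if lhs != rhs:
        raise RuleError(
            f"{rule}: mass balance violated (parent+H2O {dict(lhs)} vs products {dict(rhs)})"
        )


def enumerate_phase1(
    compound: Compound, rules: dict[str, str] | None = None
) -> list[MetaboliteRecord]:
    """Apply each phase-I rule at every matching site of the parent.

    Duplicate product sets (by canonical SMILES) within a rule are merged;
    ordering is deterministic by (rule order, site index), so re-running on
    the same parent yields an identical list. A rule with no matching site
    simply contributes nothing.
    """
    rules = rules if rules is not None else DEFAULT_RULES
    parent = compound.mol()
    records: list[MetaboliteRecord] = []
    for rule_name, smarts in rules.items():
        rxn = rdChemReactions.ReactionFromSmarts(smarts)
        if rxn is None:
            raise RuleError(f"invalid reaction SMARTS for rule {rule_name!r}")
        seen: set[tuple[str, ...]] = set()
        site = 0
        for product_set in rxn.RunReactants((parent,)):
            mols = []
            ok = True
            for p in product_set:
                try:
                    Chem.SanitizeMol(p)
                except Exception:  # noqa: BLE001 - unsanitizable product
                    ok = False
                    break
                mols.append(p)
            if not ok:
                continue
            key = tuple(sorted(Chem.MolToSmiles(m) for m in mols))
            if key in seen:
                continue
            seen.add(key)
            if rule_name in _HYDROLYSIS_RULES:
                _check_hydrolysis_balance(parent, mols, rule_name)
            records.append(
                MetaboliteRecord(
                    parent_id=compound.id,
                    rule=rule_name,
                    products=[Chem.MolToSmiles(m) for m in mols],
                    site=site,
                )
            )
            site += 1
    return records


def _score_structure(smiles: str, pid: str) -> ScoreSet:
    c = parse_compound(pid, smiles)
    ds = physchem(c)
    ds = replace(
        ds,
        clogd_74=ds.clogp,  # metabolite pKa unknown -> treated non-ionizable
        logs=esol_logs(ds, aromatic_proportion=aromatic_proportion(c)),
    )
    return score_descriptors(ds)


def score_metabolites(
    records: list[MetaboliteRecord],
    parent: Compound | None = None,
    herg_by_smiles: dict[str, float] | None = None,
    herg_alert_bound: float = HERG_ALERT_BOUND,
) -> pd.DataFrame:
    """Push every enumerated product through descriptors and scores.

    Returns one row per product with ClogP, logS, CNS-MPO and BBB score,
    deltas versus the parent when it is supplied, any supplied hERG value
    and a ``herg_alert`` flag when that value falls below
    ``herg_alert_bound``. A product that fails scoring is flagged and the
    run continues.
    """
    herg_by_smiles = herg_by_smiles or {}
    parent_scores = None
    parent_ds = None
    if parent is not None:
        # parent re-scored under the metabolite convention (no supplied pKa)
        # so deltas compare like with like
        parent_ds = physchem(parent)
        parent_ds = replace(
            parent_ds,
            pka_basic=None,
            pka_acidic=None,
            clogd_74=parent_ds.clogp,
            logs=esol_logs(parent_ds, aromatic_proportion=aromatic_proportion(parent)),
        )
        parent_scores = score_descriptors(parent_ds)
    rows = []
    for rec in records:
        for j, smi in enumerate(rec.products):
            row: dict = {
                "parent_id": rec.parent_id,
                "rule": rec.rule,
                "site": rec.site,
                "product": smi,
            }
            try:
                pid = f"{rec.parent_id}:{rec.rule}:{rec.site}.{j}"
                scores = _score_structure(smi, pid)
                rec.scores[smi] = scores
                c = parse_compound(pid, smi)
                ds = physchem(c)
                row.update(
                    clogp=ds.clogp,
                    logs=esol_logs(ds, aromatic_proportion=aromatic_proportion(c)),
                    cns_mpo=scores.cns_mpo,
                    bbb_score=scores.bbb_score,
                )
                if parent_scores is not None and parent_ds is not None:
                    row["delta_clogp"] = ds.clogp - parent_ds.clogp
                    row["delta_logs"] = row["logs"] - parent_ds.logs
                    row["delta_cns_mpo"] = scores.cns_mpo - parent_scores.cns_mpo
                    row["delta_bbb_score"] = scores.bbb_score - parent_scores.bbb_score
            except Exception as exc:  # noqa: BLE001 - keep scoring the rest
                rec.flags.append(f"scoring_failed:{j}")
                row["flags"] = f"scoring_failed ({exc})"
                rows.append(row)
                continue
            flags = []
            herg = herg_by_smiles.get(smi)
            if herg is not None:
                row["herg_pic50"] = herg
                if herg < herg_alert_bound:
                    flags.append("herg_alert")
                    rec.flags.append("herg_alert")
            row["flags"] = ";".join(flags)
            rows.append(row)
    return pd.DataFrame(rows)
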