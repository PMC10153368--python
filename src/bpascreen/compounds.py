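"""Compound identity, structure parsing, fixture panels and tabular I/O.

A :class:`Compound` couples a canonical SMILES structure with externally
supplied quantities that the open descriptor stack does not compute de novo
(basic/acidic pKa, predicted hERG pIC50, frontier-orbital energies). Panels
are ordered collections with unique ids and round-trip through CSV, .smi and
SDF.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from rdkit import Chem

from .errors import PanelError, StructureParseError

#: Compound structural groups used by the screen (pyridine-to-amide topology).
GROUPS = (
    "pyridine",
    "methylenepyridine",
    "ethylenepyridine",
    "benzopyridine",
    "hydroxypyridine",
    "reference",
    "other",
)

#: Permitted keys for externally supplied per-compound quantities.
OVERRIDE_KEYS = ("pka_basic", "pka_acidic", "herg_pic50", "e_homo_ev", "e_lumo_ev")


@dataclass(frozen=True)
class Compound:
    """A single screening candidate or reference drug.

    Parameters
    ----------
    id : str
        Short unique identifier within a panel (e.g. ``"HR67"``).
    smiles : str
        Canonical SMILES; always produced by :func:`parse_compound`.
    name : str
        Free-text name (IUPAC or trivial).
    group : str
        One of :data:`GROUPS`.
    overrides : mapping
        Externally supplied quantities, keys restricted to
        :data:`OVERRIDE_KEYS`.
    inferred : bool
        True when the exact structure was inferred rather than stated by its
        source (e.g. a positional isomer whose attachment point was never
        named).
    """

    id: str
    smiles: str
    name: str = ""
    group: str = "other"
    overrides: Mapping[str, float] = field(default_factory=dict)
    inferred: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise PanelError(f"unknown group {self.group!r} for compound {self.id!r}")
        bad = set(self.overrides) - set(OVERRIDE_KEYS)
        if bad:
            raise PanelError(
                f"compound {self.id!r}: unknown override keys {sorted(bad)}"
            )

    def mol(self) -> Chem.Mol:
        """Return the RDKit molecule for this compound."""
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - smiles is canonical by construction
            raise StructureParseError(self.smiles)
        return m


def parse_compound(
    cid: str,
    smiles_text: str,
    name: str = "",
    group: str = "other",
    overrides: Mapping[str, float] | None = None,
    inferred: bool = False,
) -> Compound:
    """Parse a SMILES string into a :class:`Compound` with canonical structure.

    Stereo descriptors present in the input are preserved by
    canonicalization. Disconnected structures (salts, mixtures) are rejected:
    every downstream descriptor assumes a single covalent species.
    """
    if not smiles_text or not smiles_text.strip():
        raise StructureParseError(smiles_text, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles_text)
    if mol is None:
        raise StructureParseError(smiles_text)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise StructureParseError(smiles_text, "structure is not a single connected molecule")
    canonical = Chem.MolToSmiles(mol)
    return Compound(
        id=cid,
        smiles=canonical,
        name=name,
        group=group,
        overrides=dict(overrides or {}),
        inferred=inferred,
    )


@dataclass
class CompoundPanel:
    """An ordered, id-unique collection of compounds."""

    compounds: list[Compound]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.compounds:
            raise PanelError("panel is empty")
        seen: dict[str, int] = {}
        for c in self.compounds:
            seen[c.id] = seen.get(c.id, 0) + 1
        dups = sorted(k for k, v in seen.items() if v > 1)
        if dups:
            raise PanelError(f"duplicate compound ids: {dups}")

    def __iter__(self) -> Iterator[Compound]:
        return iter(self.compounds)

    def __len__(self) -> int:
        return len(self.compounds)

    def __getitem__(self, cid: str) -> Compound:
        for c in self.compounds:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"smi", "csv", "sdf"}:
        return suffix
    raise PanelError(f"cannot infer panel format from {path.name!r}; pass format=")


def load_panel(path: str | Path, format: str | None = None) -> CompoundPanel:
    """Load a panel from a .smi, CSV or SDF file.

    CSV dialect: UTF-8, comma separated, header row with ``id,smiles`` plus
    optional ``name``, ``group`` and override columns (:data:`OVERRIDE_KEYS`).
    The .smi dialect is whitespace-separated ``smiles id`` per line.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in {"smi", "csv", "sdf"}:
        raise PanelError(f"unsupported panel format {fmt!r}")
    compounds: list[Compound] = []
    if fmt == "smi":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"cmpd{lineno}"
            compounds.append(parse_compound(cid, smiles))
    elif fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
                raise PanelError(f"{path.name}: CSV needs 'id' and 'smiles' columns")
            for row in reader:
                overrides = {
                    k: float(row[k])
                    for k in OVERRIDE_KEYS
                    if row.get(k) not in (None, "", "NA", "nan")
                }
                compounds.append(
                    parse_compound(
                        row["id"],
                        row["smiles"],
                        name=row.get("name", "") or "",
                        group=row.get("group", "") or "other",
                        overrides=overrides,
                        inferred=str(row.get("inferred", "")).lower() in ("1", "true", "yes"),
                    )
                )
    else:  # sdf
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise StructureParseError(f"{path.name} record {i}")
            cid = mol.GetProp("_Name") if mol.GetProp("_Name") else f"cmpd{i + 1}"
            compounds.append(parse_compound(cid, Chem.MolToSmiles(mol)))
    if not compounds:
        raise PanelError(f"{path.name}: no compounds found")
    return CompoundPanel(compounds, provenance=f"loaded from {path.name} ({fmt})")


def write_panel(panel: CompoundPanel, path: str | Path, format: str = "csv") -> Path:
    """Write a panel as CSV or as a JSON manifest. Returns the path written."""
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "smiles", "name", "group", "inferred", *OVERRIDE_KEYS])
            for c in panel:
                writer.writerow(
                    [c.id, c.smiles, c.name, c.group, int(c.inferred)]
                    + [c.overrides.get(k, "") for k in OVERRIDE_KEYS]
                )
    elif format == "json":
        payload = {
            "provenance": panel.provenance,
            "compounds": [
                {
                    "id": c.id,
                    "smiles": c.smiles,
                    "name": c.name,
                    "group": c.group,
                    "inferred": c.inferred,
                    "overrides": dict(c.overrides),
                }
                for c in panel
            ],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise PanelError(f"unsupported output format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Built-in fixtures
#
# Structures are pre-encoded from the published preparative names of the HR
# series (HR67, HR80, HR89) and from the standard structures of the reference
# drugs. HR66/HR68/HR71 attachment points were never named in the source text
# and are flagged inferred. pka_basic overrides are literature-informed
# estimates of the pyridinium conjugate-acid pKa standing in for an external
# pKa engine's output.
# ---------------------------------------------------------------------------

_BPA_CORE = "CC(C)(Oc1ccc(cc1)C(=O)c1ccc(Cl)cc1)C(=O)"

_HR_FIXTURES = [
    # (id, smiles, name, group, overrides, inferred)
    (
        "HR66",
        _BPA_CORE + "Nc1ccccn1",
        "2-[4-(4-chlorobenzoyl)phenoxy]-2-methyl-N-(pyridin-2-yl)propanamide",
        "pyridine",
        {"pka_basic": 3.0},
        True,
    ),
    (
        "HR67",
        _BPA_CORE + "Nc1cccnc1",
        "2-[4-(4-chlorobenzoyl)phenoxy]-2-methyl-N-(pyridin-3-yl)propanamide",
        "pyridine",
        {"pka_basic": 4.6},
        False,
    ),
    (
        "HR68",
        _BPA_CORE + "Nc1ccncc1",
        "2-[4-(4-chlorobenzoyl)phenoxy]-2-methyl-N-(pyridin-4-yl)propanamide",
        "pyridine",
        {"pka_basic": 5.9},
        True,
    ),
    (
        "HR71",
        _BPA_CORE + "NCc1ccncc1",
        "2-[4-(4-chlorobenzoyl)phenoxy]-2-methyl-N-(pyridin-4-ylmethyl)propanamide",
        "methylenepyridine",
        {"pka_basic": 5.6},
        True,
    ),
    (
        "HR80",
        _BPA_CORE + "NCCc1ccncc1",
        "2-(4-(4-chlorobenzoyl)phenoxy)-2-methyl-N-(2-(pyridin-4-yl)ethyl)propanamide",
        "ethylenepyridine",
        {"pka_basic": 6.0},
        False,
    ),
    (
        "HR89",
        _BPA_CORE + "NC1=CC=CNC1=O",
        "2-(4-(4-chlorobenzoyl)phenoxy)-2-methyl-N-(2-oxo-1,2-dihydropyridin-3-yl)propanamide",
        "hydroxypyridine",
        {},
        False,
    ),
]

_CONTROL_FIXTURES = [
    (
        "FF",
        "CC(C)OC(=O)C(C)(C)Oc1ccc(cc1)C(=O)c1ccc(Cl)cc1",
        "fenofibrate",
        "reference",
        {},
        False,
    ),
    (
        "FFA",
        "OC(=O)C(C)(C)Oc1ccc(cc1)C(=O)c1ccc(Cl)cc1",
        "fenofibric acid",
        "reference",
        {"pka_acidic": 3.1},
        False,
    ),
    (
        "TMZ",
        "CN1C(=O)N2C=NC(C(N)=O)=C2N=N1",
        "temozolomide",
        "reference",
        {},
        False,
    ),
    (
        "CAF",
        "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
        "caffeine",
        "reference",
        {"pka_basic": 0.6},
        False,
    ),
]


def builtin_fixture(name: str) -> CompoundPanel:
    """Return one of the built-in fixture panels.

    ``"hr_named"`` holds the HR-series amides whose structures follow from
    their printed preparative names (inferred positional isomers flagged);
    ``"controls"`` holds fenofibrate, fenofibric acid, temozolomide and
    caffeine.
    """
    if name == "hr_named":
        rows, prov = _HR_FIXTURES, (
            "HR-series fixtures encoded from preparative names; HR66/HR68/HR71 "
            "attachment points inferred; pka_basic values are supplied estimates"
        )
    elif name == "controls":
        rows, prov = _CONTROL_FIXTURES, "reference drugs (standard structures)"
    else:
        raise PanelError(f"unknown fixture {name!r}; choose 'hr_named' or 'controls'")
    return CompoundPanel(
        [
            parse_compound(cid, smi, name=nm, group=grp, overrides=ov, inferred=inf)
            for cid, smi, nm, grp, ov, inf in rows
        ],
        provenance=prov,
    )
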