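"""Physicochemical descriptors for the screen.

Topology-only quantities (MW, TPSA, Lipinski HBD/HBA, aromatic rings, heavy
atoms, Crippen ClogP) come straight from RDKit. On top of those this module
provides:

* ``clogd`` — Henderson–Hasselbalch correction of ClogP for monoprotic
  ionization at a given pH,
* ``esol_logs`` — the ESOL linear aqueous-solubility estimate of Delaney
  (J. Chem. Inf. Comput. Sci. 2004, 44, 1000),
* ``polarizability`` — the additive atomic-hybrid scheme of Miller
  (J. Am. Chem. Soc. 1990, 112, 8533),
* ``minimal_projection_area`` — the smallest area of the molecule's
  van-der-Waals silhouette over all projection directions, evaluated on the
  lowest-energy embedded conformer, with a brute-force exact-geometry oracle
  (``mpa_oracle``) for verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, rdMolDescriptors

from .compounds import Compound
from .errors import DescriptorError

__all__ = [
    "DescriptorSet",
    "MpaConfig",
    "physchem",
    "clogd",
    "esol_logs",
    "aromatic_proportion",
    "polarizability",
    "embed_conformer",
    "minimal_projection_area",
    "mpa_oracle",
    "full_descriptors",
]


@dataclass
class DescriptorSet:
    """The physicochemical panel tabulated for every screening candidate.

    Units: mw g/mol; tpsa Å²; logs log10(mol/L); polarizability Å³; mpa Å².
    ``clogd_74`` is the pH 7.4 distribution coefficient; ``pka_basic`` /
    ``pka_acidic`` are externally supplied (None = treated non-ionizable).
    """

    mw: float
    tpsa: float
    hbd: int
    hba: int
    aromatic_rings: int
    heavy_atoms: int
    clogp: float
    rotatable_bonds: int = 0
    clogd_74: float | None = None
    pka_basic: float | None = None
    pka_acidic: float | None = None
    logs: float | None = None
    polarizability: float | None = None
    mpa: float | None = None

    @property
    def neg_logs(self) -> float | None:
        """-logS, the positive 'insolubility' used by the screening gate."""
        return None if self.logs is None else -self.logs

    @property
    def mwhbn(self) -> float:
        """(HBD + HBA) / sqrt(MW), the combined H-bonding/size descriptor."""
        return (self.hbd + self.hba) / math.sqrt(self.mw)


def physchem(compound: Compound) -> DescriptorSet:
    """Topology-only descriptors; deterministic for a fixed structure."""
    mol = compound.mol()
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        hbd=Lipinski.NHOHCount(mol),  # Lipinski convention: OH + NH hydrogens
        hba=Lipinski.NOCount(mol),  # N + O heavy atoms
        aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        clogp=Crippen.MolLogP(mol),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        pka_basic=compound.overrides.get("pka_basic"),
        pka_acidic=compound.overrides.get("pka_acidic"),
    )


def clogd(
    clogp: float,
    pka_basic: float | None = None,
    pka_acidic: float | None = None,
    ph: float = 7.4,
) -> float:
    """Distribution coefficient logD at ``ph`` from logP and monoprotic pKa.

    Henderson–Hasselbalch: a monoprotic base loses
    ``log10(1 + 10**(pka_basic - ph))`` of apparent lipophilicity, an acid
    ``log10(1 + 10**(ph - pka_acidic))``; with both centers present both
    corrections are subtracted, with neither logD = logP. The corrections are
    nonnegative, so logD ≤ logP always.
    """
    if not 0.0 <= ph <= 14.0:
        raise DescriptorError(f"pH {ph} outside [0, 14]")
    value = clogp
    if pka_basic is not None:
        value -= math.log10(1.0 + 10.0 ** (pka_basic - ph))
    if pka_acidic is not None:
        value -= math.log10(1.0 + 10.0 ** (ph - pka_acidic))
    return value


def aromatic_proportion(compound: Compound) -> float:
    """Fraction of heavy atoms that are aromatic (the ESOL 'AP' term)."""
    mol = compound.mol()
    heavy = mol.GetNumHeavyAtoms()
    if heavy == 0:
        return 0.0
    return sum(a.GetIsAromatic() for a in mol.GetAtoms()) / heavy


def esol_logs(
    descriptors: DescriptorSet,
    rotatable_bonds: int | None = None,
    aromatic_proportion: float = 0.0,
) -> float:
    """ESOL estimated aqueous solubility, log10(mol/L).

    logS = 0.16 - 0.63*ClogP - 0.0062*MW + 0.066*RB - 0.74*AP (Delaney 2004).
    """
    rb = descriptors.rotatable_bonds if rotatable_bonds is None else rotatable_bonds
    return (
        0.16
        - 0.63 * descriptors.clogp
        - 0.0062 * descriptors.mw
        + 0.066 * rb
        - 0.74 * aromatic_proportion
    )


# ---------------------------------------------------------------------------
# Miller additive atomic-hybrid polarizability (Å³)
# ---------------------------------------------------------------------------

# Atomic hybrid contributions, Miller 1990 Table III. Keys are
# (symbol, hybrid class); hybrid classes: TE tetrahedral, TR trigonal,
# BR aromatic bridgehead (ring-fusion) carbon, DI linear, PI2 π-lone-pair
# nitrogen/oxygen (aromatic or amide N, ether O in conjugation handled as TE).
_MILLER_AHP = {
    ("H", ""): 0.387,
    ("C", "TE"): 1.061,
    ("C", "TR"): 1.352,
    ("C", "BR"): 1.896,
    ("C", "DI"): 1.283,
    ("N", "TE"): 0.964,
    ("N", "TR2"): 1.030,
    ("N", "PI2"): 1.090,
    ("N", "DI"): 0.956,
    ("O", "TE"): 0.637,
    ("O", "TR4"): 0.569,
    ("F", ""): 0.296,
    ("Cl", ""): 2.315,
    ("Br", ""): 3.013,
    ("I", ""): 5.415,
    ("S", "TE"): 3.000,
    ("S", "TR4"): 3.729,
    ("P", "TE"): 1.538,
}


def _miller_class(atom: Chem.Atom) -> tuple[str, str]:
    sym = atom.GetSymbol()
    if sym in {"H", "F", "Cl", "Br", "I"}:
        return (sym, "")
    hyb = atom.GetHybridization()
    if sym == "C":
        if atom.GetIsAromatic():
            # bridgehead of two fused aromatic rings
            n_arom_ring = sum(
                1 for b in atom.GetBonds() if b.GetIsAromatic()
            )
            return ("C", "BR") if n_arom_ring >= 3 else ("C", "TR")
        if hyb == Chem.HybridizationType.SP:
            return ("C", "DI")
        if hyb == Chem.HybridizationType.SP2:
            return ("C", "TR")
        return ("C", "TE")
    if sym == "N":
        if atom.GetIsAromatic() or _conjugated_to_pi(atom):
            return ("N", "PI2")
        if hyb == Chem.HybridizationType.SP:
            return ("N", "DI")
        if hyb == Chem.HybridizationType.SP2:
            return ("N", "TR2")
        return ("N", "TE")
    if sym == "O":
        if hyb == Chem.HybridizationType.SP2 and not atom.GetIsAromatic():
            return ("O", "TR4")  # carbonyl-type oxygen
        return ("O", "TE")
    if sym == "S":
        if hyb == Chem.HybridizationType.SP2:
            return ("S", "TR4")
        return ("S", "TE")
    if sym == "P":
        return ("P", "TE")
    return (sym, "?")


def _conjugated_to_pi(atom: Chem.Atom) -> bool:
    """True for a trivalent N attached to a carbonyl or aromatic system."""
    for nbr in atom.GetNeighbors():
        if nbr.GetIsAromatic():
            return True
        for b in nbr.GetBonds():
            if b.GetBondType() == Chem.BondType.DOUBLE:
                return True
    return False


def polarizability(compound: Compound) -> float:
    """Additive molecular polarizability in Å³ (Miller atomic-hybrid sum)."""
    mol = Chem.AddHs(compound.mol())
    total = 0.0
    for atom in mol.GetAtoms():
        key = _miller_class(atom)
        if key not in _MILLER_AHP:
            raise DescriptorError(
                f"no polarizability contribution for element {atom.GetSymbol()!r}"
            )
        total += _MILLER_AHP[key]
    return total


# ---------------------------------------------------------------------------
# Minimal projection area
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MpaConfig:
    """Settings for the minimal-projection-area search.

    ``n_conformers`` distance-geometry embeddings are force-field relaxed and
    the lowest-energy one kept; projection directions are scanned on a
    ``orientation_grid``-degree spherical grid; each silhouette is the union
    of the atoms' van-der-Waals disks rasterized at ``raster_resolution`` Å
    per pixel; ``refine=True`` adds a finer local grid pass around the best
    direction.
    """

    n_conformers: int = 10
    orientation_grid: float = 10.0
    raster_resolution: float = 0.1
    refine: bool = True

    def __post_init__(self) -> None:
        if self.n_conformers <= 0 or self.orientation_grid <= 0 or self.raster_resolution <= 0:
            raise DescriptorError("MpaConfig values must be positive")
        if self.orientation_grid > 30.0:
            raise DescriptorError("orientation grid step must be <= 30 degrees")


DEFAULT_MPA_SEED = 20230420


def embed_conformer(
    compound: Compound, config: MpaConfig | None = None, seed: int = DEFAULT_MPA_SEED
) -> tuple[np.ndarray, np.ndarray]:
    """Embed the compound in 3D and return (coords, vdW radii) in Å.

    ``n_conformers`` ETKDG embeddings are MMFF-relaxed (UFF fallback) and the
    lowest-energy conformer is returned, hydrogens included. Reproducible for
    a fixed seed.
    """
    config = config or MpaConfig()
    mol = Chem.AddHs(compound.mol())
    if mol.GetNumAtoms() == 0:
        raise DescriptorError("zero-atom input")
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    cids = AllChem.EmbedMultipleConfs(mol, numConfs=config.n_conformers, params=params)
    if not cids:
        raise DescriptorError(f"3D embedding failed for {compound.id!r}")
    try:
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
    except Exception:  # noqa: BLE001 - MMFF typing gaps on exotic atoms
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=500)
    energies = [e if conv == 0 else math.inf for conv, e in results]
    if all(math.isinf(e) for e in energies):
        energies = [e for _, e in results]
    best = list(cids)[int(np.argmin(energies))]
    coords = mol.GetConformer(best).GetPositions()
    table = Chem.GetPeriodicTable()
    radii = np.array([table.GetRvdw(a.GetAtomicNum()) for a in mol.GetAtoms()])
    return coords, radii


def _direction(theta_deg: float, phi_deg: float) -> np.ndarray:
    t, p = math.radians(theta_deg), math.radians(phi_deg)
    return np.array([math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), math.cos(t)])


def _projection_area_raster(
    coords: np.ndarray, radii: np.ndarray, axis: np.ndarray, resolution: float
) -> float:
    """Raster area of the union of vdW disks projected along ``axis``."""
    helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    xy = coords @ np.column_stack([e1, e2])
    lo = (xy - radii[:, None]).min(axis=0) - resolution
    hi = (xy + radii[:, None]).max(axis=0) + resolution
    nx = max(1, int(math.ceil((hi[0] - lo[0]) / resolution)))
    ny = max(1, int(math.ceil((hi[1] - lo[1]) / resolution)))
    gx = lo[0] + (np.arange(nx) + 0.5) * resolution
    gy = lo[1] + (np.arange(ny) + 0.5) * resolution
    xg, yg = np.meshgrid(gx, gy, indexing="ij")
    covered = np.zeros((nx, ny), dtype=bool)
    for (cx, cy), r in zip(xy, radii):
        covered |= (xg - cx) ** 2 + (yg - cy) ** 2 <= r * r
    return float(covered.sum()) * resolution * resolution


def _grid_directions(step: float) -> list[tuple[float, float]]:
    # Projections along u and -u coincide, so the upper hemisphere suffices.
    thetas = np.arange(0.0, 90.0 + 1e-9, step)
    out = []
    for th in thetas:
        phis = [0.0] if th == 0.0 else np.arange(0.0, 360.0, step)
        out.extend((float(th), float(ph)) for ph in phis)
    return out


def minimal_projection_area(
    compound: Compound,
    config: MpaConfig | None = None,
    seed: int = DEFAULT_MPA_SEED,
) -> float:
    """Minimal projection area (Å²) of the lowest-energy conformer.

    The search scans projection directions on a spherical grid, rasterizing
    the van-der-Waals silhouette for each; with ``refine=True`` a second pass
    scans a 5x finer local grid at half the raster step around the best
    direction. MPA < 60 Å² is the screen's passive-CNS-diffusion criterion.
    """
    config = config or MpaConfig()
    coords, radii = embed_conformer(compound, config, seed)
    return mpa_from_coords(coords, radii, config)


def mpa_from_coords(
    coords: np.ndarray, radii: np.ndarray, config: MpaConfig | None = None
) -> float:
    """MPA search on explicit coordinates (shared by tests and the pipeline)."""
    config = config or MpaConfig()
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.size == 0:
        raise DescriptorError("zero-atom input")
    best_area = math.inf
    best_dir = (0.0, 0.0)
    for th, ph in _grid_directions(config.orientation_grid):
        area = _projection_area_raster(coords, radii, _direction(th, ph), config.raster_resolution)
        if area < best_area:
            best_area, best_dir = area, (th, ph)
    if config.refine:
        step = config.orientation_grid
        fine = config.raster_resolution / 2.0
        th0, ph0 = best_dir
        for dth in np.linspace(-step, step, 11):
            for dph in np.linspace(-step, step, 11):
                th = min(max(th0 + dth, 0.0), 180.0)
                area = _projection_area_raster(
                    coords, radii, _direction(th, ph0 + dph), fine
                )
                best_area = min(best_area, area)
    return best_area


def mpa_oracle(
    coords: np.ndarray, radii: np.ndarray, fine_grid_step: float = 3.0
) -> float:
    """Brute-force MPA on explicit coordinates, for verification only.

    Exhaustive orientation grid at ``fine_grid_step`` degrees with the
    projected union of disks measured exactly as a polygon union (shapely
    buffered points), independent of the raster code path.
    """
    from shapely.geometry import Point
    from shapely.ops import unary_union

    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    best = math.inf
    for th, ph in _grid_directions(fine_grid_step):
        axis = _direction(th, ph)
        helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(axis, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        xy = coords @ np.column_stack([e1, e2])
        union = unary_union(
            [Point(x, y).buffer(r, quad_segs=64) for (x, y), r in zip(xy, radii)]
        )
        best = min(best, union.area)
    return best


def full_descriptors(
    compound: Compound,
    ph: float = 7.4,
    mpa_config: MpaConfig | None = None,
    seed: int = DEFAULT_MPA_SEED,
    with_mpa: bool = True,
) -> DescriptorSet:
    """Compute the complete descriptor panel for one compound.

    Fills the topology descriptors, the Henderson–Hasselbalch ClogD at
    ``ph`` (pKa read from the compound's overrides; absent = non-ionizable),
    ESOL logS, Miller polarizability and, when ``with_mpa``, the minimal
    projection area from the seeded conformer search.
    """
    ds = physchem(compound)
    ds = replace(
        ds,
        clogd_74=clogd(ds.clogp, ds.pka_basic, ds.pka_acidic, ph),
        logs=esol_logs(ds, aromatic_proportion=aromatic_proportion(compound)),
        polarizability=polarizability(compound),
    )
    if with_mpa:
        ds = replace(ds, mpa=minimal_projection_area(compound, mpa_config, seed))
    return ds
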