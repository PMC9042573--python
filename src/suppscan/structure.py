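"""Structure-based annotation of suppressor sites and domain-rotation geometry.

Parses mmCIF/PDB coordinates (via gemmi) into a light heavy-atom model, finds
inter-chain residue contacts classified as van der Waals / hydrogen-bond /
salt-bridge by distance rules, detects buried hydrophobic residues with a
neighbor-count burial proxy, maps suppressor substitution records onto those
structural categories, and measures rigid-body superpositions (Kabsch) and
the rotation angle of a structural segment (e.g. an SMC coiled coil pivoting
on the ATPase head) between two conformational states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .aminoacids import HYDROPHOBIC_AA, THREE_TO_ONE
from .records import SubstitutionRecord

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
#: Side-chain oxygens of Asp/Glu usable as salt-bridge acceptors.
ACIDIC_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
#: Side-chain nitrogens of Lys/Arg/His usable as salt-bridge donors.
BASIC_N = {
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray


@dataclass
class Residue:
    number: int
    icode: str
    name: str  # 3-letter code
    atoms: list[Atom]

    @property
    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.name)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def side_chain_centroid(self) -> np.ndarray:
        """Centroid of non-backbone heavy atoms; falls back to CA (glycine)."""
        side = [a.xyz for a in self.atoms if a.name not in BACKBONE_ATOMS]
        if side:
            return np.mean(side, axis=0)
        ca = self.atom("CA")
        if ca is None:
            return np.mean(self.coords(), axis=0)
        return ca.xyz


@dataclass
class StructureModel:
    """Heavy-atom coordinate model: chain id -> ordered residues."""

    chains: dict[str, list[Residue]]

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(
                f"chain {chain_id!r} not present; available chains: "
                f"{sorted(self.chains)}"
            )
        return self.chains[chain_id]

    def residue(self, chain_id: str, number: int) -> Residue | None:
        for res in self.chain(chain_id):
            if res.number == number:
                return res
        return None

    def has_residue(self, chain_id: str, number: int) -> bool:
        return chain_id in self.chains and self.residue(chain_id, number) is not None


def _from_gemmi(st: gemmi.Structure) -> StructureModel:
    st.setup_entities()
    model = st[0]  # first model only
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            # resolve altlocs to highest occupancy per atom name
            best: dict[str, tuple[float, gemmi.Atom]] = {}
            for atom in res:
                if atom.element.name in ("H", "D"):
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev[0]:
                    best[atom.name] = (atom.occ, atom)
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for _, a in best.values()
            ]
            if not atoms:
                continue
            for a in atoms:
                if not np.all(np.isfinite(a.xyz)):
                    raise ValueError(
                        f"non-finite coordinates in {chain.name} {res.seqid.num}"
                    )
            residues.append(
                Residue(res.seqid.num, res.seqid.icode.strip(), res.name, atoms)
            )
        if residues:
            chains[chain.name] = residues
    return StructureModel(chains)


def read_structure(path: Union[str, Path], fmt: str | None = None) -> StructureModel:
    """Read mmCIF or PDB coordinates into a heavy-atom :class:`StructureModel`.

    The first model is used; hydrogens are dropped; alternate locations
    resolve to the highest-occupancy conformer. ``fmt`` may force
    ``"mmcif"`` or ``"pdb"``; by default the format is detected.
    """
    path = str(path)
    if fmt is None:
        st = gemmi.read_structure(path)
    elif fmt == "pdb":
        st = gemmi.read_pdb(path)
    elif fmt == "mmcif":
        st = gemmi.make_structure_from_block(gemmi.cif.read(path).sole_block())
    else:
        raise ValueError(f"format must be 'mmcif' or 'pdb', got {fmt!r}")
    return _from_gemmi(st)


# ---------------------------------------------------------------------------
# contacts


@dataclass(frozen=True)
class ContactThresholds:
    """Heavy-atom distance cutoffs (Angstrom) for contact classification."""

    vdw: float = 4.0
    hbond: float = 3.5
    salt_bridge: float = 4.0


@dataclass(frozen=True)
class ResidueContact:
    chain_a: str
    number_a: int
    name_a: str
    chain_b: str
    number_b: int
    name_b: str
    min_distance: float
    category: str  # vdw | hbond | salt_bridge


def _chain_atoms(residues: Sequence[Residue]):
    coords, meta = [], []
    for ridx, res in enumerate(residues):
        for atom in res.atoms:
            coords.append(atom.xyz)
            meta.append((ridx, res, atom))
    return np.array(coords), meta


def inter_chain_contacts(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    thresholds: ContactThresholds = ContactThresholds(),
) -> list[ResidueContact]:
    """Residue pairs across two chains within the van der Waals cutoff.

    Classification, applied to the closest qualifying atom pair: salt bridge
    if an Asp/Glu side-chain oxygen lies within the salt cutoff of a
    Lys/Arg/His side-chain nitrogen; else hydrogen bond if any N/O...N/O pair
    lies within the hbond cutoff; else van der Waals. The pair list is
    symmetric under swapping the two chains.
    """
    res_a, res_b = model.chain(chain_a), model.chain(chain_b)
    if not res_a or not res_b:
        raise ValueError("empty chain")
    coords_a, meta_a = _chain_atoms(res_a)
    coords_b, meta_b = _chain_atoms(res_b)
    cutoff = max(thresholds.vdw, thresholds.hbond, thresholds.salt_bridge)
    tree = cKDTree(coords_b)
    pairs: dict[tuple[int, int], dict] = {}
    for ia, (ridx_a, ra, atom_a) in enumerate(meta_a):
        for ib in tree.query_ball_point(coords_a[ia], cutoff):
            ridx_b, rb, atom_b = meta_b[ib]
            d = float(np.linalg.norm(coords_a[ia] - coords_b[ib]))
            key = (ridx_a, ridx_b)
            rec = pairs.setdefault(
                key, {"min": math.inf, "hbond": math.inf, "salt": math.inf}
            )
            rec["min"] = min(rec["min"], d)
            if atom_a.element in ("N", "O") and atom_b.element in ("N", "O"):
                rec["hbond"] = min(rec["hbond"], d)
            ao = (ra.name, atom_a.name) in ACIDIC_O and (rb.name, atom_b.name) in BASIC_N
            ob = (rb.name, atom_b.name) in ACIDIC_O and (ra.name, atom_a.name) in BASIC_N
            if ao or ob:
                rec["salt"] = min(rec["salt"], d)

    contacts = []
    for (ridx_a, ridx_b), rec in sorted(pairs.items()):
        if rec["min"] > thresholds.vdw:
            continue
        if rec["salt"] <= thresholds.salt_bridge:
            category = "salt_bridge"
        elif rec["hbond"] <= thresholds.hbond:
            category = "hbond"
        else:
            category = "vdw"
        ra, rb = res_a[ridx_a], res_b[ridx_b]
        contacts.append(
            ResidueContact(
                chain_a, ra.number, ra.name, chain_b, rb.number, rb.name,
                rec["min"], category,
            )
        )
    return contacts


# ---------------------------------------------------------------------------
# hydrophobic core


@dataclass(frozen=True)
class CoreParams:
    """Burial-proxy parameters: neighbor heavy atoms within ``radius`` Angstrom
    of the side-chain centroid; residues with at least ``burial_min`` neighbors
    count as buried."""

    radius: float = 7.5
    burial_min: int = 30
    hydrophobic: frozenset[str] = HYDROPHOBIC_AA


def hydrophobic_core_residues(
    model: StructureModel, chain_id: str, params: CoreParams = CoreParams()
) -> dict[int, int]:
    """Buried hydrophobic residues of a chain, with burial scores.

    The burial proxy counts heavy atoms belonging to *other* residues (any
    chain) within ``params.radius`` of the residue's side-chain centroid
    (CA for glycine). Deterministic; returns {residue number: burial score}
    for hydrophobic residues meeting ``burial_min``.
    """
    residues = model.chain(chain_id)
    if len(residues) < 3:
        raise ValueError("chain has fewer than 3 residues; burial is meaningless")
    all_coords, owner = [], []
    for cid, chain_res in model.chains.items():
        for res in chain_res:
            for atom in res.atoms:
                all_coords.append(atom.xyz)
                owner.append((cid, res.number, res.icode))
    all_coords = np.array(all_coords)
    tree = cKDTree(all_coords)

    out: dict[int, int] = {}
    for res in residues:
        one = res.one_letter
        if one is None or one not in params.hydrophobic:
            continue
        centroid = res.side_chain_centroid()
        idx = tree.query_ball_point(centroid, params.radius)
        score = sum(
            1 for i in idx if owner[i] != (chain_id, res.number, res.icode)
        )
        if score >= params.burial_min:
            out[res.number] = score
    return out


# ---------------------------------------------------------------------------
# site annotation


@dataclass(frozen=True)
class ChainMap:
    """How a protein's numbering maps onto a structure chain:
    structure residue number = record position + offset."""

    chain_id: str
    offset: int = 0


@dataclass(frozen=True)
class SiteAnnotation:
    position: int
    categories: frozenset[str]  # subset of {interface, hydrophobic_core, other, unresolved}
    supporting_contacts: tuple[ResidueContact, ...] = ()
    burial_score: int | None = None


def annotate_sites(
    records: Sequence[SubstitutionRecord],
    contacts: Sequence[ResidueContact],
    core_set: Mapping[int, int],
    chain_map: ChainMap,
    model: StructureModel | None = None,
) -> list[SiteAnnotation]:
    """Label each record's position as interface / hydrophobic core / other.

    ``core_set`` is keyed by structure residue number (as returned by
    :func:`hydrophobic_core_residues`). A position missing from the structure
    (disordered) is labeled ``unresolved`` and excluded from category
    fractions. One annotation is returned per record, so the downstream
    summary reports fractions of substitutions, not of positions.
    """
    contact_index: dict[int, list[ResidueContact]] = {}
    for c in contacts:
        if c.chain_a == chain_map.chain_id:
            contact_index.setdefault(c.number_a, []).append(c)
        if c.chain_b == chain_map.chain_id:
            contact_index.setdefault(c.number_b, []).append(c)

    annotations = []
    for rec in records:
        resnum = rec.position + chain_map.offset
        if model is not None and not model.has_residue(chain_map.chain_id, resnum):
            annotations.append(SiteAnnotation(rec.position, frozenset({"unresolved"})))
            continue
        cats = set()
        supp: tuple[ResidueContact, ...] = ()
        if resnum in contact_index:
            cats.add("interface")
            supp = tuple(contact_index[resnum])
        burial = core_set.get(resnum)
        if burial is not None:
            cats.add("hydrophobic_core")
        if not cats:
            cats.add("other")
        annotations.append(
            SiteAnnotation(rec.position, frozenset(cats), supp, burial)
        )
    return annotations


def annotation_summary(annotations: Sequence[SiteAnnotation]) -> dict[str, float]:
    """Fractions of substitutions in each structural category.

    Unresolved records are excluded from the denominator. Categories are not
    exclusive, so fractions need not sum to 1.
    """
    resolved = [a for a in annotations if "unresolved" not in a.categories]
    n = len(resolved)
    if n == 0:
        raise ValueError("no resolved annotations")
    out = {"n_resolved": float(n), "n_unresolved": float(len(annotations) - n)}
    for cat in ("interface", "hydrophobic_core", "other"):
        out[f"fraction_{cat}"] = sum(1 for a in resolved if cat in a.categories) / n
    return out


# ---------------------------------------------------------------------------
# superposition and rotation


@dataclass(frozen=True)
class Selection:
    """Residue selection ``chain:start-end[,start-end...]`` on one chain."""

    chain_id: str
    ranges: tuple[tuple[int, int], ...]

    @classmethod
    def parse(cls, text: str) -> "Selection":
        chain, _, spec = text.partition(":")
        if not spec:
            raise ValueError(f"selection {text!r} must look like 'A:1-10,20-30'")
        ranges = []
        for part in spec.split(","):
            lo, _, hi = part.partition("-")
            lo_i = int(lo)
            hi_i = int(hi) if hi else lo_i
            if hi_i < lo_i:
                raise ValueError(f"bad range {part!r} in selection {text!r}")
            ranges.append((lo_i, hi_i))
        return cls(chain.strip(), tuple(ranges))

    def numbers(self) -> list[int]:
        out = []
        for lo, hi in self.ranges:
            out.extend(range(lo, hi + 1))
        return out


def _paired_ca(
    model_a: StructureModel, model_b: StructureModel, selection: Selection
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    xa, xb, numbers = [], [], []
    res_a = {r.number: r for r in model_a.chain(selection.chain_id)}
    res_b = {r.number: r for r in model_b.chain(selection.chain_id)}
    for num in selection.numbers():
        ra, rb = res_a.get(num), res_b.get(num)
        if ra is None or rb is None:
            continue
        ca_a, ca_b = ra.atom("CA"), rb.atom("CA")
        if ca_a is None or ca_b is None:
            continue
        xa.append(ca_a.xyz)
        xb.append(ca_b.xyz)
        numbers.append(num)
    return np.array(xa), np.array(xb), numbers


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform (R, t) minimizing |R @ moving + t - fixed|.

    The reflection branch is excluded (det R = +1). Returns (R, t, rmsd).
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (n, 3)")
    if len(moving) < 3:
        raise ValueError("need at least 3 paired atoms for superposition")
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    diff = (moving @ R.T + t) - fixed
    rmsd = float(np.sqrt((diff**2).sum() / len(moving)))
    return R, t, rmsd


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @property
    def rotation_angle_deg(self) -> float:
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def superpose(
    model_a: StructureModel,
    model_b: StructureModel,
    selection: Union[str, Selection, Sequence[Union[str, Selection]]],
) -> SuperpositionResult:
    """Kabsch superposition of ``model_b`` onto ``model_a``.

    CA atoms are paired by author residue number over the selection (one or
    more ``chain:start-end,...`` selections). Fewer than 3 common atoms is an
    error.
    """
    selections = _as_selections(selection)
    xa_all, xb_all = [], []
    for sel in selections:
        xa, xb, _ = _paired_ca(model_a, model_b, sel)
        if len(xa):
            xa_all.append(xa)
            xb_all.append(xb)
    if not xa_all:
        raise ValueError("selection matched no common CA atoms")
    fixed = np.concatenate(xa_all)
    moving = np.concatenate(xb_all)
    R, t, rmsd = kabsch(moving, fixed)
    return SuperpositionResult(R, t, rmsd, len(fixed))


def _as_selections(
    selection: Union[str, Selection, Sequence[Union[str, Selection]]]
) -> list[Selection]:
    if isinstance(selection, (str, Selection)):
        selection = [selection]
    return [Selection.parse(s) if isinstance(s, str) else s for s in selection]


def _segment_axis(coords: np.ndarray) -> np.ndarray:
    """Dominant principal direction of CA coordinates, oriented N->C."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if axis @ (coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def segment_rotation_angle(
    model_a: StructureModel,
    model_b: StructureModel,
    align_selection: Union[str, Selection, Sequence[Union[str, Selection]]],
    segment_selection: Union[str, Selection],
) -> float:
    """Angle (degrees, in [0, 180]) between a segment's axis in two models.

    ``model_b`` is first superposed onto ``model_a`` over ``align_selection``
    (e.g. the invariant ATPase head), then each model's segment axis is taken
    as the dominant principal direction of the segment's CA coordinates,
    oriented N->C, and the angle between the two axes is returned. Only the
    magnitude of the rotation is reported; directionality (inward/outward) is
    not assigned.
    """
    seg = _as_selections(segment_selection)[0]
    sup = superpose(model_a, model_b, align_selection)

    def seg_coords(model: StructureModel) -> np.ndarray:
        res = {r.number: r for r in model.chain(seg.chain_id)}
        pts = [
            res[n].atom("CA").xyz
            for n in seg.numbers()
            if n in res and res[n].atom("CA") is not None
        ]
        return np.array(pts)

    ca_a, ca_b = seg_coords(model_a), seg_coords(model_b)
    if len(ca_a) < 4 or len(ca_b) < 4:
        raise ValueError("segment must resolve at least 4 CA atoms in both models")
    axis_a = _segment_axis(ca_a)
    axis_b = _segment_axis(sup.apply(ca_b))
    cos = float(np.clip(axis_a @ axis_b, -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))
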