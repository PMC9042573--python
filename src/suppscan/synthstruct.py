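"""Synthetic coordinate models for exercising the structure pipeline.

Every structure operation in this package also runs on packaged synthetic
coordinates, so the analysis is testable without downloading deposited
models. The builders here produce idealized geometry — straight CA traces,
alpha-helical CA spirals, packed side-chain clusters and two-state hinge
pairs with a known rotation angle — as :class:`~suppscan.structure.StructureModel`
objects, and can round-trip them through gemmi to PDB/mmCIF files. All
objects produced here are synthetic stand-ins, not representations of any
deposited structure.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence, Union

import gemmi
import numpy as np

from .aminoacids import ONE_TO_THREE
from .structure import Atom, Residue, StructureModel

#: Canonical alpha-helix CA parameters: rise per residue, radius, twist.
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST_DEG = 100.0


def make_residue(
    name3: str,
    number: int,
    ca_xyz: Sequence[float],
    extra_atoms: Iterable[tuple[str, str, Sequence[float]]] = (),
) -> Residue:
    """A residue with a CA atom plus optional (name, element, xyz) atoms."""
    atoms = [Atom("CA", "C", np.asarray(ca_xyz, dtype=float))]
    for aname, element, xyz in extra_atoms:
        atoms.append(Atom(aname, element, np.asarray(xyz, dtype=float)))
    return Residue(number, "", name3, atoms)


def make_ca_line(
    sequence: str,
    chain_id: str = "A",
    start: int = 1,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    direction: Sequence[float] = (0.0, 0.0, 1.0),
    spacing: float = 3.8,
) -> StructureModel:
    """Straight CA-only trace along ``direction`` (exact principal axis)."""
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    residues = [
        make_residue(ONE_TO_THREE[aa], start + i, origin + i * spacing * d)
        for i, aa in enumerate(sequence)
    ]
    return StructureModel({chain_id: residues})


def make_helix(
    sequence: str,
    chain_id: str = "A",
    start: int = 1,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> StructureModel:
    """Idealized alpha-helical CA spiral along +z starting at ``origin``."""
    origin = np.asarray(origin, dtype=float)
    residues = []
    for i, aa in enumerate(sequence):
        theta = math.radians(HELIX_TWIST_DEG * i)
        xyz = origin + np.array(
            [HELIX_RADIUS * math.cos(theta), HELIX_RADIUS * math.sin(theta), HELIX_RISE * i]
        )
        residues.append(make_residue(ONE_TO_THREE[aa], start + i, xyz))
    return StructureModel({chain_id: residues})


def merge_models(*models: StructureModel) -> StructureModel:
    chains: dict[str, list[Residue]] = {}
    for m in models:
        for cid, residues in m.chains.items():
            chains.setdefault(cid, []).extend(residues)
    return StructureModel(chains)


def rotation_about_axis(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (unit-normalized) axis by ``angle_deg``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def transform_model(
    model: StructureModel, rotation: np.ndarray, translation: Sequence[float] = (0, 0, 0)
) -> StructureModel:
    translation = np.asarray(translation, dtype=float)
    chains = {}
    for cid, residues in model.chains.items():
        chains[cid] = [
            Residue(
                r.number, r.icode, r.name,
                [Atom(a.name, a.element, rotation @ a.xyz + translation) for a in r.atoms],
            )
            for r in residues
        ]
    return StructureModel(chains)


def make_hinge_pair(
    angle_deg: float,
    base_length: int = 20,
    arm_length: int = 12,
    chain_id: str = "A",
    hinge_axis: Sequence[float] = (1.0, 0.0, 0.0),
) -> tuple[StructureModel, StructureModel, str, str]:
    """Two-state model pair whose arm segment differs by a known rotation.

    State A: a straight base (residues 1..base_length along +z) continued by a
    straight arm (residues base_length+1..base_length+arm_length). State B:
    identical base, arm rotated by ``angle_deg`` about ``hinge_axis`` through
    the hinge point at the end of the base. Returns (model_a, model_b,
    align_selection, segment_selection) ready for
    :func:`~suppscan.structure.segment_rotation_angle`.
    """
    base_seq = "A" * base_length
    arm_seq = "L" * arm_length
    hinge = np.array([0.0, 0.0, 3.8 * base_length])
    base = make_ca_line(base_seq, chain_id, 1)
    arm = make_ca_line(arm_seq, chain_id, base_length + 1, origin=hinge)
    model_a = merge_models(base, arm)

    R = rotation_about_axis(hinge_axis, angle_deg)
    arm_b = transform_model(arm, R, hinge - R @ hinge)
    model_b = merge_models(base, arm_b)
    align = f"{chain_id}:1-{base_length}"
    segment = f"{chain_id}:{base_length + 1}-{base_length + arm_length}"
    return model_a, model_b, align, segment


def make_packed_cluster(
    n: int = 6,
    residue: str = "L",
    chain_id: str = "A",
    spacing: float = 3.0,
) -> StructureModel:
    """Tightly packed cluster of identical residues with stub side chains.

    Residues sit on a compact 3D grid with CB/CG side-chain atoms, so each
    side-chain centroid sees many neighboring heavy atoms — a synthetic
    hydrophobic core.
    """
    name3 = ONE_TO_THREE[residue]
    residues = []
    for i in range(n):
        # compact grid positions
        pos = np.array([(i % 2) * spacing, ((i // 2) % 2) * spacing, (i // 4) * spacing])
        ca = pos
        cb = pos + np.array([0.8, 0.8, 0.5])
        cg = pos + np.array([1.4, 1.2, 1.0])
        cd1 = pos + np.array([2.0, 1.0, 1.6])
        cd2 = pos + np.array([1.2, 2.0, 1.6])
        residues.append(
            make_residue(
                name3, i + 1, ca,
                [("CB", "C", cb), ("CG", "C", cg), ("CD1", "C", cd1), ("CD2", "C", cd2)],
            )
        )
    return StructureModel({chain_id: residues})


def to_gemmi(model: StructureModel, name: str = "synthetic") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.xyz)
                ga.occ = 1.0
                gr.add_atom(ga)
            chain.add_residue(gr)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_model(model: StructureModel, path: Union[str, Path], fmt: str | None = None) -> None:
    """Write a synthetic model as PDB or mmCIF (inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = to_gemmi(model)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"format must be 'mmcif' or 'pdb', got {fmt!r}")
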