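"""Geometrically ideal helix fixtures with known knob-socket ground truth.

Backbone atoms are placed on a parametric alpha-helix (default 1.5 A rise,
100 deg twist, 2.3 A C-alpha radius).  The offsets of N, C, O, C-beta and
the Leu/Ile/Val rotamer atoms relative to the local C-alpha frame are
derived once, at import, from a reference helix built with ideal internal
coordinates (phi -57, psi -47), so generated helices carry realistic
i -> i+4 hydrogen bonds and side-chain contact geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import THREE_TO_ONE, AtomRecord, Residue, Structure

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

DEFAULT_RISE = 1.5       # Angstrom per residue
DEFAULT_TWIST = 100.0    # degrees per residue
DEFAULT_RADIUS = 2.3     # C-alpha distance from the axis

CLASH_DISTANCE = 2.5     # heavy-atom overlap threshold between chains

# ideal internal coordinates (Engh-Huber-like) for the reference helix
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

# side-chain internal coordinates: atom -> (frame atoms, bond, angle, torsion)
_SIDECHAINS = {
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.521, 110.5, 175.0),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, -65.0),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, -60.0),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, 180.0),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, 60.0),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, -60.0),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, 60.0),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.9, 170.0),
    ],
}


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position d with |c-d| = bond, angle(b,c,d) and torsion(a,b,c,d) given."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about ``axis`` by ``angle_deg``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def _reference_backbone(n_res: int) -> list[dict]:
    """Ideal-dihedral poly-backbone used only to derive frame offsets."""
    residues = []
    n = np.array([0.0, 0.0, 0.0])
    ca = n + np.array([_B_N_CA, 0.0, 0.0])
    c = place_atom(n + np.array([0.0, 1.0, 0.0]), n, ca, _B_CA_C, _A_N_CA_C, 60.0)
    for i in range(n_res):
        if i > 0:
            prev = residues[-1]
            n = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, _PSI)
            ca = place_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, _OMEGA)
            c = place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, _PHI)
        # carbonyl O is trans to the next amide N: torsion N-CA-C-O = psi + 180
        o = place_atom(n, ca, c, _B_C_O, _A_CA_C_O, _PSI + 180.0)
        residues.append({"N": n, "CA": ca, "C": c, "O": o})
    for res in residues:
        res["CB"] = place_atom(res["N"], res["C"], res["CA"], _B_CA_CB, 110.5, 123.0)
        for res3, atoms in _SIDECHAINS.items():
            local = dict(res)
            for name, frame, bond, angle, torsion in atoms:
                local[name] = place_atom(
                    local[frame[0]], local[frame[1]], local[frame[2]], bond, angle, torsion
                )
                res[(res3, name)] = local[name]
    return residues


def _helix_axis_fit(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Axis point/direction plus rise, twist and radius of an ideal CA trace."""
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    t = (ca - center) @ axis
    radial = ca - center - np.outer(t, axis)
    radius = float(np.linalg.norm(radial, axis=1).mean())
    rise = float(np.diff(t).mean())
    angles = []
    for i in range(len(ca) - 1):
        u, v = radial[i], radial[i + 1]
        cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
        sign = np.sign(np.cross(u, v) @ axis)
        angles.append(sign * math.degrees(math.acos(np.clip(cosang, -1, 1))))
    twist = float(np.mean(angles))
    return center, axis, rise, twist, radius


def _local_frame(axis, radial_unit, rise, twist_deg, radius) -> np.ndarray:
    """Orthonormal frame columns (tangent, radial, binormal) at a CA."""
    twist = math.radians(twist_deg)
    binorm_dir = np.cross(axis, radial_unit)
    tangent = rise * axis + radius * twist * binorm_dir
    tangent /= np.linalg.norm(tangent)
    radial = radial_unit - (radial_unit @ tangent) * tangent
    radial /= np.linalg.norm(radial)
    binormal = np.cross(tangent, radial)
    return np.column_stack([tangent, radial, binormal])


def _derive_frame_offsets() -> dict[str, np.ndarray]:
    """Average local-frame offsets of every atom type on the reference helix."""
    n_res = 19
    ref = _reference_backbone(n_res)
    ca = np.array([r["CA"] for r in ref])
    center, axis, rise, twist, radius = _helix_axis_fit(ca)
    t = (ca - center) @ axis
    offsets: dict[str, list] = {}
    for i in range(4, n_res - 4):  # mid-helix residues only
        radial_vec = ca[i] - center - t[i] * axis
        radial_unit = radial_vec / np.linalg.norm(radial_vec)
        frame = _local_frame(axis, radial_unit, rise, twist, radius)
        for name, coord in ref[i].items():
            if name == "CA":
                continue
            offsets.setdefault(name, []).append(frame.T @ (coord - ca[i]))
    return {name: np.mean(vals, axis=0) for name, vals in offsets.items()}


_FRAME_OFFSETS = _derive_frame_offsets()


@dataclass(frozen=True)
class HelixSpec:
    sequence: str
    rise: float = DEFAULT_RISE
    twist: float = DEFAULT_TWIST
    radius: float = DEFAULT_RADIUS
    origin: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (0.0, 0.0, 1.0)
    phase: float = 0.0  # rotation of residue 0 about the axis, degrees
    chain_id: str = "A"
    first_seq_num: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not (0.0 < abs(self.twist) < 180.0):
            raise ValueError("twist must be in (0, 180) degrees")
        if len(self.sequence) < 1:
            raise ValueError("sequence must not be empty")
        for aa in self.sequence:
            if aa not in ONE_TO_THREE:
                raise ValueError(f"unknown residue letter {aa!r}")


def _helix_residues(spec: HelixSpec) -> list[Residue]:
    axis = np.asarray(spec.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    seed_vec = np.array([0.0, 0.0, 1.0])
    if abs(axis @ seed_vec) > 0.9:
        seed_vec = np.array([1.0, 0.0, 0.0])
    u0 = np.cross(axis, seed_vec)
    u0 /= np.linalg.norm(u0)
    u0 = rotation_matrix(axis, spec.phase) @ u0
    origin = np.asarray(spec.origin, dtype=float)

    residues = []
    for i, aa in enumerate(spec.sequence):
        theta = i * spec.twist
        radial_unit = rotation_matrix(axis, theta) @ u0
        ca = origin + spec.rise * i * axis + spec.radius * radial_unit
        frame = _local_frame(axis, radial_unit, spec.rise, spec.twist, spec.radius)
        name3 = ONE_TO_THREE[aa]
        res = Residue(
            chain_id=spec.chain_id,
            seq_num=spec.first_seq_num + i,
            icode="",
            name3=name3,
            ordinal=i,
        )
        atom_names = ["N", "CA", "C", "O"]
        if name3 != "GLY":
            atom_names.append("CB")
        if name3 in _SIDECHAINS:
            atom_names.extend(entry[0] for entry in _SIDECHAINS[name3])
        for name in atom_names:
            offset_key = name if name in ("N", "CA", "C", "O", "CB") else (name3, name)
            coord = ca if name == "CA" else ca + frame @ _FRAME_OFFSETS[offset_key]
            res.atoms[name] = AtomRecord(
                name=name,
                element=name[0],
                coord=coord.copy(),
                residue=res,
            )
        residues.append(res)
    return residues


def make_ideal_helix(spec: HelixSpec) -> Structure:
    """A single-chain structure of one ideal helix."""
    residues = _helix_residues(spec)
    return Structure(
        source_id=f"helix-{spec.chain_id}", model_index=1,
        chains={spec.chain_id: residues},
    )


@dataclass(frozen=True)
class GroundTruthMotif:
    """Expected knob-socket: knob (chain, seq) filling socket residues (chain, seqs)."""

    knob_chain: str
    knob_seq: int
    socket_chain: str
    socket_seqs: tuple[int, ...]

    @classmethod
    def of(cls, knob, socket):
        return cls(knob[0], knob[1], socket[0], tuple(sorted(socket[1])))


@dataclass(frozen=True)
class PackingFixtureSpec:
    helices: tuple[HelixSpec, ...]
    ground_truth: tuple[GroundTruthMotif, ...] = ()
    name: str = "fixture"
    seed: int = 0


def make_packing_fixture(spec: PackingFixtureSpec):
    """Multi-helix structure plus its declared ground-truth motif list.

    Helices sharing a chain id are concatenated into one chain (ordinals
    keep increasing; seq numbering follows each helix spec).  Chains closer
    than the clash threshold raise.
    """
    chains: dict[str, list[Residue]] = {}
    for hspec in spec.helices:
        residues = _helix_residues(hspec)
        existing = chains.setdefault(hspec.chain_id, [])
        offset = len(existing)
        if existing and residues[0].seq_num <= existing[-1].seq_num:
            raise ValueError(
                f"chain {hspec.chain_id}: helix segments must have increasing seq numbers"
            )
        for res in residues:
            res.ordinal += offset
        existing.extend(residues)

    structure = Structure(source_id=spec.name, model_index=1, chains=chains)
    _check_clashes(structure)
    return structure, list(spec.ground_truth)


def _check_clashes(structure: Structure) -> None:
    from scipy.spatial import cKDTree

    chain_ids = list(structure.chains)
    coords = {
        cid: np.array([a.coord for r in structure.chains[cid] for a in r.atoms.values()])
        for cid in chain_ids
    }
    for i, ci in enumerate(chain_ids):
        tree = cKDTree(coords[ci])
        for cj in chain_ids[i + 1:]:
            hits = tree.query_ball_point(coords[cj], CLASH_DISTANCE)
            if any(hits):
                raise ValueError(
                    f"steric clash (< {CLASH_DISTANCE} A) between chains {ci} and {cj}"
                )


# --- PDB output -----------------------------------------------------------

_PDB_ATOM = (
    "ATOM  {serial:5d} {name:^4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _pdb_atom_name(name: str) -> str:
    # single-letter elements are right-padded starting at column 14
    return f" {name:<3s}" if len(name) < 4 else name


def write_pdb(structure: Structure, path) -> None:
    """Write standard ATOM/TER records; round-trips through read_structure."""
    if structure.n_atoms == 0:
        raise ValueError("refusing to write a structure with no atoms")
    serial = 0
    with open(path, "w") as fh:
        for chain_id, residues in structure.chains.items():
            for res in residues:
                for atom in res.atoms.values():
                    serial += 1
                    x, y, z = atom.coord
                    fh.write(
                        _PDB_ATOM.format(
                            serial=serial,
                            name=_pdb_atom_name(atom.name),
                            altloc="",
                            resname=res.name3,
                            chain=chain_id,
                            resseq=res.seq_num,
                            icode=res.icode or " ",
                            x=x, y=y, z=z,
                            occ=atom.occupancy, b=0.0,
                            element=atom.element,
                        )
                    )
            serial += 1
            last = residues[-1]
            fh.write(
                f"TER   {serial:5d}      {last.name3:>3s} {chain_id:1s}"
                f"{last.seq_num:4d}{last.icode or ' '}\n"
            )
        fh.write("END\n")


def transform_structure(structure: Structure, rotation, translation) -> Structure:
    """Rigid-body copy of a structure (used heavily by invariance tests)."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    chains: dict[str, list[Residue]] = {}
    for cid, residues in structure.chains.items():
        new_residues = []
        for res in residues:
            clone = Residue(
                chain_id=res.chain_id, seq_num=res.seq_num, icode=res.icode,
                name3=res.name3, ordinal=res.ordinal,
            )
            for name, atom in res.atoms.items():
                clone.atoms[name] = AtomRecord(
                    name=atom.name, element=atom.element,
                    coord=rotation @ atom.coord + translation,
                    occupancy=atom.occupancy, altloc=atom.altloc, residue=clone,
                )
            new_residues.append(clone)
        chains[cid] = new_residues
    return Structure(
        source_id=structure.source_id, model_index=structure.model_index, chains=chains
    )


# --- canned fixtures ------------------------------------------------------
# Geometries tuned once against the default pipeline parameters and frozen
# together with their detected-and-hand-checked motif lists (side-chain
# proxy distances verified against the contact cutoff).

_TWO_HELIX_GT = (
    ("A", 7, "B", (5, 6, 9)),
    ("A", 7, "B", (6, 9, 10)),
    ("B", 2, "A", (10, 11, 14)),
    ("B", 6, "A", (7, 8, 11)),
    ("B", 6, "A", (8, 11, 12)),
    ("B", 9, "A", (3, 4, 7)),
)

_GROOVE_GT = (
    ("A", 4, "B", (106, 109, 110)),
    ("A", 4, "B", (109, 110, 113)),
    ("A", 11, "B", (102, 103, 106)),
    ("A", 23, "B", (106, 107, 110)),
    ("A", 24, "B", (107, 110, 111)),
    ("A", 27, "B", (103, 106, 107)),
    ("A", 27, "B", (106, 107, 110)),
    ("A", 30, "B", (102, 103, 106)),
    ("A", 43, "B", (107, 110, 111)),
    ("B", 103, "A", (27, 30, 31)),
    ("B", 106, "A", (4, 7, 8)),
    ("B", 106, "A", (7, 8, 11)),
    ("B", 107, "A", (23, 24, 27)),
    ("B", 107, "A", (43, 46, 47)),
    ("B", 110, "A", (23, 24, 27)),
    ("B", 110, "A", (23, 26, 27)),
)


def _freeze(raw) -> tuple[GroundTruthMotif, ...]:
    return tuple(
        GroundTruthMotif(kc, ks_, sc, seqs) for kc, ks_, sc, seqs in raw
    )


def two_helix_spec(separation: float = 9.5) -> PackingFixtureSpec:
    """Antiparallel helix pair with an engineered Leu knob on chain B.

    At the default 9.5 A axial separation the Leu fills two contiguous
    sockets on chain A (residues 7,8,11 and 8,11,12 -> the 7-8-11-12
    pocket).  Ground truth is declared only for the tuned separation;
    pulling the helices far apart yields an empty interface.
    """
    ground_truth = _freeze(_TWO_HELIX_GT) if abs(separation - 9.5) < 1e-9 else ()
    return PackingFixtureSpec(
        helices=(
            HelixSpec(sequence="A" * 14, chain_id="A"),
            HelixSpec(
                sequence="AAAAALAAAAAA", chain_id="B", axis=(0.0, 0.0, -1.0),
                origin=(separation, 0.0, 18.0), phase=330.0,
            ),
        ),
        ground_truth=ground_truth,
        name=f"two-helix-{separation:g}A",
    )


def groove_spec() -> PackingFixtureSpec:
    """Three-helix receptor groove (one chain) binding a ligand helix.

    The middle receptor helix carries Gly27; the ligand's central Gly107
    packs the H2 socket containing it (the central glycine-glycine motif),
    and ligand knobs reach all three receptor helices.
    """
    return PackingFixtureSpec(
        helices=(
            HelixSpec(sequence="A" * 13, chain_id="A", origin=(3.0, -8.0, 0.0),
                      first_seq_num=1, phase=0.0),
            HelixSpec(sequence="AAAAAAGAAAAAA", chain_id="A", origin=(0.0, 0.0, 0.0),
                      first_seq_num=21, phase=30.0),
            HelixSpec(sequence="A" * 13, chain_id="A", origin=(3.0, 8.0, 0.0),
                      first_seq_num=41, phase=0.0),
            HelixSpec(sequence="AAAAAAGAAAAAA", chain_id="B", axis=(0.0, 0.0, -1.0),
                      origin=(8.0, 0.0, 17.0), phase=240.0, first_seq_num=101),
        ),
        ground_truth=_freeze(_GROOVE_GT),
        name="three-helix-groove",
    )


def detected_ground_truth(knob_sockets) -> tuple[GroundTruthMotif, ...]:
    """Canonical cross-chain motif tuple for comparison with ground truth."""
    out = []
    for ks_ in knob_sockets:
        chain = ks_.socket.members[0].chain_id
        if ks_.knob.chain_id == chain:
            continue
        out.append(
            GroundTruthMotif(
                ks_.knob.chain_id, ks_.knob.seq_num, chain,
                tuple(sorted(r.seq_num for r in ks_.socket.members)),
            )
        )
    return tuple(sorted(out, key=lambda g: (g.knob_chain, g.knob_seq, g.socket_seqs)))
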