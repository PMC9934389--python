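"""Align BH3 ligands on the central-glycine reference and build consensus models.

Every complex in the set packs a ligand residue (almost always Gly) into
the receptor-H5 pocket that contains the receptor's own conserved glycine.
That residue anchors the alignment: it sits at relative offset 0 and at
index 20 of the fixed 27-position helical lattice, so offsets and lattice
indices always differ by exactly 20.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

from .interface_analysis import InterfaceMap, _motif_socket_members
from .knob_socket import Pocket
from .structure_io import Residue

LATTICE_SIZE = 27
CENTRAL_LATTICE_INDEX = 20
OFFSET_TO_LATTICE = CENTRAL_LATTICE_INDEX  # lattice = offset + 20

ROLE_KNOB = "knob"
ROLE_SOCKET = "socket-member"
ROLE_NONE = "non-participant"

CLASS_CENTRAL = "central"
CLASS_CONSERVED = "conserved"
CLASS_VARIABLE = "variable"
CLASS_NON_ESSENTIAL = "non-essential"


@dataclass(frozen=True)
class CentralReference:
    residue: Residue
    amino_acid: str
    substituted: bool  # True when the central residue is not glycine
    complex_id: str


def find_central_reference(
    imap: InterfaceMap, h5_label: str = "H5"
) -> CentralReference:
    """The ligand knob anchoring the complex: it packs the receptor-H5
    socket/pocket that contains the receptor's conserved Gly.

    A glycine knob is preferred; when no ligand Gly packs that pocket the
    knob that does is returned with ``substituted=True``.
    """
    candidates = []
    for motif in imap.ligand_to_receptor:
        if imap.helix_labels.get(motif.key, "") != h5_label:
            continue
        members = _motif_socket_members(motif)
        if any(r.name3 == "GLY" for r in members):
            candidates.append(motif)
    if not candidates:
        seen = [
            f"{m.knob.code1}{m.knob.seq_num}->{imap.helix_labels.get(m.key, '?')}"
            for m in imap.ligand_to_receptor
        ]
        raise ValueError(
            f"{imap.complex_id}: no ligand knob packs a Gly-containing "
            f"{h5_label} socket; candidates were {seen}"
        )
    gly_knobs = [m for m in candidates if m.knob.name3 == "GLY"]
    pool = gly_knobs or candidates
    # deterministic choice: pockets (two filled contiguous sockets) beat
    # lone sockets, then lowest ligand sequence position
    pool = sorted(
        pool, key=lambda m: (not isinstance(m, Pocket), m.knob.ordinal)
    )
    chosen = pool[0]
    return CentralReference(
        residue=chosen.knob,
        amino_acid=chosen.knob.code1,
        substituted=chosen.knob.name3 != "GLY",
        complex_id=imap.complex_id,
    )


@dataclass
class AlignedLigand:
    complex_id: str
    reference: CentralReference
    positions: dict = field(default_factory=dict)
    # lattice index -> {"aa", "seq", "offset", "role"}
    overflow: list = field(default_factory=list)  # residues outside lattice 1..27

    def role_at(self, lattice_index: int) -> str:
        entry = self.positions.get(lattice_index)
        return entry["role"] if entry else ROLE_NONE


def _ligand_roles(imap: InterfaceMap) -> dict:
    """Per ligand-residue participation; knob outranks socket membership."""
    roles: dict = {}
    for motif in imap.ligand_to_receptor:
        roles[motif.knob.key] = ROLE_KNOB
    for motif in imap.receptor_to_ligand:
        for res in _motif_socket_members(motif):
            roles.setdefault(res.key, ROLE_SOCKET)
    return roles


def align_ligands(
    maps: list[InterfaceMap],
    refs: list[CentralReference],
    structures: dict | None = None,
) -> list[AlignedLigand]:
    """Map each ligand onto the 27-position lattice, reference at index 20."""
    if len(maps) != len(refs):
        raise ValueError("one central reference required per interface map")
    structures = structures or {}
    aligned = []
    for imap, ref in zip(maps, refs):
        roles = _ligand_roles(imap)
        ligand_residues = _collect_ligand_residues(imap, structures.get(imap.complex_id))
        item = AlignedLigand(complex_id=imap.complex_id, reference=ref)
        for res in ligand_residues:
            offset = res.ordinal - ref.residue.ordinal
            lattice = offset + OFFSET_TO_LATTICE
            entry = {
                "aa": res.code1,
                "seq": res.seq_num,
                "offset": offset,
                "role": roles.get(res.key, ROLE_NONE),
            }
            if 1 <= lattice <= LATTICE_SIZE:
                item.positions[lattice] = entry
            else:
                item.overflow.append(dict(entry, lattice=lattice))
        assert item.positions[CENTRAL_LATTICE_INDEX]["offset"] == 0
        aligned.append(item)
    return aligned


def _collect_ligand_residues(imap: InterfaceMap, structure=None) -> list[Residue]:
    # with the structure at hand the full ligand chain is aligned, so
    # non-participating positions appear on the lattice; otherwise only the
    # residues referenced by interface motifs are available
    if structure is not None:
        return list(structure.chains[imap.ligand_chain])
    seen = {}
    for motif in imap.ligand_to_receptor:
        seen[motif.knob.key] = motif.knob
    for motif in imap.receptor_to_ligand:
        for res in _motif_socket_members(motif):
            seen[res.key] = res
    return sorted(seen.values(), key=lambda r: r.ordinal)


@dataclass
class ConsensusModel:
    scope: str
    positions: dict = field(default_factory=dict)
    # lattice index -> {"class", "consensus", "counts", "n_participating"}
    n_ligands: int = 0

    def classes(self) -> dict:
        return {i: entry["class"] for i, entry in sorted(self.positions.items())}

    def conserved_positions(self) -> list[int]:
        return [i for i, e in sorted(self.positions.items())
                if e["class"] in (CLASS_CONSERVED, CLASS_CENTRAL)]

    def to_json(self) -> str:
        return json.dumps(
            {"scope": self.scope, "n_ligands": self.n_ligands,
             "positions": {str(k): v for k, v in sorted(self.positions.items())}},
            indent=1, sort_keys=True,
        )

    def to_tsv(self) -> str:
        lines = ["lattice\tclass\tconsensus\tn_participating\tresidues"]
        for i in range(1, LATTICE_SIZE + 1):
            e = self.positions.get(i)
            if e is None:
                lines.append(f"{i}\t{CLASS_NON_ESSENTIAL}\t\t0\t")
                continue
            counts = ",".join(f"{aa}:{n}" for aa, n in sorted(e["counts"].items()))
            lines.append(
                f"{i}\t{e['class']}\t{e['consensus']}\t{e['n_participating']}\t{counts}"
            )
        return "\n".join(lines) + "\n"


def consensus_residue(column) -> str:
    """Strict-plurality residue of a column multiset; 'X' on tie or empty."""
    counts = Counter(column)
    if not counts:
        return "X"
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "X"
    return ranked[0][0]


def classify_positions(
    aligned: list[AlignedLigand],
    scope: str = "all",
    knob_only: bool = False,
) -> ConsensusModel:
    """Classify each lattice position over a set of aligned ligands.

    conserved: participates in every ligand of the scope (as knob when
    ``knob_only``); variable: participates in some but not all; the
    reference position is reported as ``central``; positions never
    participating are non-essential.  Residue identity at a conserved
    position may still vary (the central Gly itself is substituted in some
    complexes); the consensus residue is reported alongside.
    """
    if not aligned:
        raise ValueError("at least one aligned ligand required")
    participating_roles = (ROLE_KNOB,) if knob_only else (ROLE_KNOB, ROLE_SOCKET)
    model = ConsensusModel(scope=scope, n_ligands=len(aligned))
    for i in range(1, LATTICE_SIZE + 1):
        participants = []
        observed = []
        for item in aligned:
            entry = item.positions.get(i)
            if entry is None:
                continue
            observed.append(entry["aa"])
            if entry["role"] in participating_roles:
                participants.append(entry["aa"])
        if not observed and not participants:
            continue
        n = len(participants)
        if i == CENTRAL_LATTICE_INDEX:
            cls = CLASS_CENTRAL
        elif n == len(aligned) and n > 0:
            cls = CLASS_CONSERVED
        elif n > 0:
            cls = CLASS_VARIABLE
        else:
            cls = CLASS_NON_ESSENTIAL
        model.positions[i] = {
            "class": cls,
            "consensus": consensus_residue(participants) if n else "",
            "counts": dict(Counter(participants)),
            "n_participating": n,
        }
    return model


def alignment_fasta(aligned: list[AlignedLigand]) -> str:
    """Lattice-window FASTA of the aligned ligand segments ('-' = unobserved)."""
    records = []
    for item in aligned:
        seq = "".join(
            item.positions.get(i, {}).get("aa", "-")
            for i in range(1, LATTICE_SIZE + 1)
        )
        records.append(f">{item.complex_id}\n{seq}")
    return "\n".join(records) + "\n"
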