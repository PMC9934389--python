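"""Interface maps, socket centroids, groove distance tables, groove models.

The interface map restricts knob-socket motifs to those crossing the
receptor/ligand chain boundary and splits them by knob direction.  Socket
centroids are the mean of member C-beta coordinates (C-alpha for glycine);
helix-grouped centroid distances give the binding-groove geometry, and
intersecting the filled receptor sockets across a paralog's complexes
yields the conserved groove model.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .knob_socket import KnobSocket, Pocket, Socket, motif_label, structured_label
from .structure_io import HelixAnnotation, Residue, Structure, secondary_label

CHEMISTRY = {
    "aliphatic": set("AVLIMG"),
    "aromatic": set("FWY"),
    "polar": set("STNQCP"),
    "charged": set("DEKRH"),
}


def residue_chemistry(code1: str) -> str:
    for kind, members in CHEMISTRY.items():
        if code1 in members:
            return kind
    return "other"


def _motif_socket_members(motif) -> tuple[Residue, ...]:
    if isinstance(motif, KnobSocket):
        return motif.socket.members
    return motif.members


@dataclass
class InterfaceMap:
    complex_id: str
    receptor_chains: tuple[str, ...]
    ligand_chain: str
    ligand_to_receptor: list = field(default_factory=list)  # ligand knob -> receptor socket
    receptor_to_ligand: list = field(default_factory=list)  # receptor knob -> ligand socket
    helix_labels: dict = field(default_factory=dict)        # motif key -> receptor label
    receptor_paralog: str = ""
    ligand_name: str = ""

    @property
    def is_empty(self) -> bool:
        return not self.ligand_to_receptor and not self.receptor_to_ligand

    def motifs(self):
        return list(self.ligand_to_receptor) + list(self.receptor_to_ligand)


def map_interface(
    structure: Structure,
    receptor_chains,
    ligand_chain: str,
    motifs: list,
    helices: list[HelixAnnotation] | None = None,
    label_map: dict | None = None,
    receptor_paralog: str = "",
    ligand_name: str = "",
) -> InterfaceMap:
    """Partition knob-socket/pocket motifs by knob direction across the interface.

    Intra-receptor and intra-ligand motifs are excluded.  ``label_map``
    translates detected per-chain helix labels into the nomenclature used
    for the receptor paralog (e.g. detected H2 -> published H3).
    """
    receptor_chains = tuple(receptor_chains)
    if ligand_chain not in structure.chains:
        raise ValueError(
            f"ligand chain {ligand_chain!r} absent from {structure.source_id}; "
            f"available: {sorted(structure.chains)}"
        )
    imap = InterfaceMap(
        complex_id=structure.source_id,
        receptor_chains=receptor_chains,
        ligand_chain=ligand_chain,
        receptor_paralog=receptor_paralog,
        ligand_name=ligand_name,
    )
    helices = helices or []

    def translate(raw_label: str, chain_id: str) -> str:
        if label_map:
            return label_map.get(f"{chain_id}:{raw_label}", raw_label)
        return raw_label

    for motif in motifs:
        knob = getattr(motif, "knob", None)
        if knob is None:
            continue
        socket_chains = {r.chain_id for r in _motif_socket_members(motif)}
        if knob.chain_id == ligand_chain and socket_chains <= set(receptor_chains):
            imap.ligand_to_receptor.append(motif)
            helix = motif.socket.helix if isinstance(motif, KnobSocket) else motif.helix
            imap.helix_labels[motif.key] = translate(helix.label, helix.chain_id)
        elif knob.chain_id in receptor_chains and socket_chains == {ligand_chain}:
            imap.receptor_to_ligand.append(motif)
            raw = secondary_label(knob, helices)
            imap.helix_labels[motif.key] = translate(raw, knob.chain_id)
    return imap


@dataclass(frozen=True)
class SocketCentroid:
    motif_key: object
    coord: np.ndarray

    def __sub__(self, other) -> float:
        return float(np.linalg.norm(self.coord - other.coord))


def socket_centroid(motif, structure: Structure | None = None) -> SocketCentroid:
    """Mean of member C-beta coordinates, substituting C-alpha for glycine."""
    members = _motif_socket_members(motif)
    coords = []
    for res in members:
        atom = "CA" if res.name3 == "GLY" else "CB"
        if atom not in res.atoms:
            raise ValueError(f"residue {res!r} lacks {atom}; cannot place centroid")
        coords.append(res.atoms[atom].coord)
    return SocketCentroid(
        motif_key=getattr(motif, "key", None), coord=np.mean(coords, axis=0)
    )


@dataclass
class GrooveDistanceTable:
    """Min/max centroid distances within and between helix groups (Angstrom)."""

    entries: dict  # (label_a, label_b) sorted tuple -> (min, max) or None

    def get(self, a: str, b: str):
        return self.entries.get(tuple(sorted((a, b))))

    def to_tsv(self, which: str = "min") -> str:
        labels = sorted({l for pair in self.entries for l in pair})
        idx = {"min": 0, "max": 1}[which]
        lines = ["\t" + "\t".join(labels)]
        for a in labels:
            row = [a]
            for b in labels:
                entry = self.get(a, b)
                row.append("-" if entry is None else f"{entry[idx]:.2f}")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def groove_distance_table(sockets_by_helix: dict) -> GrooveDistanceTable:
    """Min and max pairwise centroid distance per helix-group pair.

    Self-pairs use distinct sockets only; groups with a single socket get no
    self entry (absent, not zero), and empty groups are simply absent.
    """
    centroids = {
        label: [socket_centroid(m) for m in motifs]
        for label, motifs in sockets_by_helix.items()
        if motifs
    }
    entries = {}
    for a, b in itertools.combinations_with_replacement(sorted(centroids), 2):
        if a == b:
            pairs = list(itertools.combinations(centroids[a], 2))
        else:
            pairs = list(itertools.product(centroids[a], centroids[b]))
        if not pairs:
            entries[(a, b)] = None
            continue
        dists = [p - q for p, q in pairs]
        entries[(a, b)] = (min(dists), max(dists))
    return GrooveDistanceTable(entries=entries)


def receptor_socket_identity(motif) -> frozenset:
    """Chain-independent identity of a receptor socket across complexes."""
    return frozenset((r.seq_num, r.icode) for r in _motif_socket_members(motif))


@dataclass
class GrooveModel:
    paralog: str
    conserved: list = field(default_factory=list)  # socket descriptors
    specific: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"paralog": self.paralog, "conserved": self.conserved,
             "specific": self.specific},
            indent=1, sort_keys=True,
        )


def conserved_groove_model(
    maps: list[InterfaceMap], paralog: str = "", offsets: dict | None = None
) -> GrooveModel:
    """Partition a paralog's groove sockets into conserved and specific.

    A receptor socket position is conserved when a motif with the same
    receptor residues is filled in every map.  ``offsets`` optionally maps
    complex_id -> integer added to that complex's receptor numbering so
    different constructs of one paralog can be reconciled.
    """
    if not maps:
        raise ValueError("at least one interface map required")
    offsets = offsets or {}

    def identity(imap, motif):
        shift = offsets.get(imap.complex_id, 0)
        return frozenset(
            (r.seq_num + shift, r.icode) for r in _motif_socket_members(motif)
        )

    per_map = []
    motif_info: dict = {}
    for imap in maps:
        idents = set()
        for motif in imap.ligand_to_receptor:
            ident = identity(imap, motif)
            idents.add(ident)
            info = motif_info.setdefault(
                ident,
                {
                    "label": motif_label(motif),
                    "helix": imap.helix_labels.get(motif.key, ""),
                    "residues": sorted(
                        (r.seq_num + offsets.get(imap.complex_id, 0), r.code1)
                        for r in _motif_socket_members(motif)
                    ),
                    "chemistry": sorted(
                        {residue_chemistry(r.code1)
                         for r in _motif_socket_members(motif)}
                    ),
                    "knobs": [],
                    "complexes": [],
                },
            )
            info["knobs"].append(f"{imap.complex_id}:{motif.knob.code1}{motif.knob.seq_num}")
            info["complexes"].append(imap.complex_id)
        per_map.append(idents)

    conserved_idents = frozenset.intersection(*(frozenset(s) for s in per_map))
    model = GrooveModel(paralog=paralog or maps[0].receptor_paralog)
    for ident in sorted(motif_info, key=sorted):
        entry = dict(motif_info[ident], position=sorted(ident))
        if ident in conserved_idents:
            model.conserved.append(entry)
        else:
            model.specific.append(entry)
    return model


def interface_to_json(imap: InterfaceMap) -> str:
    def encode(motif):
        entry = structured_label(motif)
        entry["receptor_label"] = imap.helix_labels.get(motif.key, "")
        return entry

    return json.dumps(
        {
            "complex_id": imap.complex_id,
            "receptor_chains": list(imap.receptor_chains),
            "ligand_chain": imap.ligand_chain,
            "receptor_paralog": imap.receptor_paralog,
            "ligand_name": imap.ligand_name,
            "ligand_to_receptor": [encode(m) for m in imap.ligand_to_receptor],
            "receptor_to_ligand": [encode(m) for m in imap.receptor_to_ligand],
        },
        indent=1,
        sort_keys=True,
    )


def interface_to_tsv(imap: InterfaceMap) -> str:
    lines = [
        "complex\tdirection\tknob_chain\tknob_res\tknob_aa\t"
        "socket_label\tsocket_residues\treceptor_label\tkind"
    ]
    for direction, motifs in (
        ("ligand->receptor", imap.ligand_to_receptor),
        ("receptor->ligand", imap.receptor_to_ligand),
    ):
        for motif in motifs:
            members = _motif_socket_members(motif)
            res_str = ",".join(f"{r.chain_id}{r.seq_num}{r.code1}" for r in members)
            kind = "pocket" if isinstance(motif, Pocket) else "socket"
            lines.append(
                f"{imap.complex_id}\t{direction}\t{motif.knob.chain_id}\t"
                f"{motif.knob.seq_num}\t{motif.knob.code1}\t{motif_label(motif)}\t"
                f"{res_str}\t{imap.helix_labels.get(motif.key, '')}\t{kind}"
            )
    return "\n".join(lines) + "\n"
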