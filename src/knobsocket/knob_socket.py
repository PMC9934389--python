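"""Classify cliques into sockets, knob-sockets and pockets; build lattice maps.

A socket is a 3-residue 2:1 clique on one helix: sequence neighbours X,Y
joined by the peptide bond, with H tied to X by the helical i -> i+4
backbone hydrogen bond (Y and H are three apart in sequence and share a
contact-graph edge).  A knob-socket adds a fourth residue B from another
helix or chain that contacts all three socket residues.  One knob filling
two contiguous sockets (sharing two residues) defines a 4-residue pocket.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx

from .structure_io import BackboneHBond, HelixAnnotation, Residue, Structure

log = logging.getLogger(__name__)

XY_H = "XY:H"
H_YX = "H:YX"


@dataclass
class Socket:
    x: Residue
    y: Residue
    h: Residue
    orientation: str  # XY_H or H_YX
    helix: HelixAnnotation
    filled: bool = False

    @property
    def members(self) -> tuple[Residue, Residue, Residue]:
        """Members in sequence order."""
        return tuple(sorted((self.x, self.y, self.h), key=lambda r: r.ordinal))

    @property
    def key(self) -> frozenset:
        return frozenset(r.key for r in (self.x, self.y, self.h))

    @property
    def hbonded(self) -> frozenset:
        """Keys of motif residues marked by ':' in labels (the H residue)."""
        return frozenset({self.h.key})

    def __repr__(self):
        return f"Socket({motif_label(self)} {list(self.members)})"


@dataclass
class KnobSocket:
    socket: Socket
    knob: Residue

    @property
    def key(self):
        return (self.knob.key, self.socket.key)

    def __repr__(self):
        return f"KnobSocket({self.knob!r} -> {self.socket!r})"


@dataclass
class Pocket:
    first: Socket
    second: Socket
    knob: Residue

    @property
    def members(self) -> tuple[Residue, ...]:
        seen = {}
        for r in self.first.members + self.second.members:
            seen[r.key] = r
        return tuple(sorted(seen.values(), key=lambda r: r.ordinal))

    @property
    def key(self):
        return (self.knob.key, self.first.key | self.second.key)

    @property
    def hbonded(self) -> frozenset:
        return self.first.hbonded | self.second.hbonded

    @property
    def helix(self) -> HelixAnnotation:
        return self.first.helix

    def __repr__(self):
        return f"Pocket({motif_label(self)} <- {self.knob!r})"


def _helical_bond_index(hbonds: list[BackboneHBond]) -> set[tuple[str, int]]:
    """(chain, acceptor ordinal) for every i -> i+4 backbone bond."""
    return {
        (b.acceptor.chain_id, b.acceptor.ordinal) for b in hbonds if b.is_helical
    }


def _host_helix(members, helices: list[HelixAnnotation]) -> HelixAnnotation | None:
    """Helix hosting a socket; one member may sit one position past a terminus."""
    best = None
    best_inside = 0
    for helix in helices:
        if any(r.chain_id != helix.chain_id for r in members):
            continue
        if not all(helix.start - 1 <= r.ordinal <= helix.end + 1 for r in members):
            continue
        inside = sum(1 for r in members if r in helix)
        if inside >= 2 and inside > best_inside:
            best, best_inside = helix, inside
    return best


def classify_sockets(
    cliques3: list[frozenset],
    helices: list[HelixAnnotation],
    hbonds: list[BackboneHBond],
    graph: nx.Graph,
    structure: Structure,
) -> list[Socket]:
    """Oriented 2:1 sockets among the 3-cliques.

    Sequence pattern (i, i+1, i+4) gives an XY:H socket and (i, i+3, i+4)
    an H:YX socket, each requiring the i -> i+4 backbone hydrogen bond.
    Hybrid sockets may extend one residue past an annotated helix terminus.
    """
    helical = _helical_bond_index(hbonds)
    sockets = []
    for clique in cliques3:
        members = sorted(
            (structure.residue_by_key(k) for k in clique), key=lambda r: r.ordinal
        )
        if len({r.chain_id for r in members}) != 1:
            continue
        r0, r1, r2 = members
        o = r0.ordinal
        if (r0.chain_id, o) not in helical or r2.ordinal != o + 4:
            continue
        if not all(r.is_complete for r in members):
            continue
        helix = _host_helix(members, helices)
        if helix is None:
            continue
        if r1.ordinal == o + 1:
            x, y, h, orientation = r0, r1, r2, XY_H
        elif r1.ordinal == o + 3:
            h, y, x, orientation = r0, r1, r2, H_YX
        else:
            continue
        # peptide bond X-Y and contact edge Y-H are implied by the clique;
        # assert the structural relations the orientation rule relies on.
        assert abs(x.ordinal - y.ordinal) == 1 and abs(y.ordinal - h.ordinal) == 3
        assert graph.has_edge(y.key, h.key)
        sockets.append(Socket(x=x, y=y, h=h, orientation=orientation, helix=helix))
    sockets.sort(key=lambda s: (s.members[0].chain_id, s.members[0].ordinal,
                                s.members[-1].ordinal, s.orientation))
    return sockets


def find_knob_sockets(
    cliques4: list[frozenset],
    sockets: list[Socket],
    helices: list[HelixAnnotation],
    structure: Structure,
) -> list[KnobSocket]:
    """2:1+1 motifs: a socket plus an external knob completing a 4-clique.

    The knob must come from another chain, or from the same chain outside
    the socket's host helix and not sequence-adjacent to any socket member.
    Sockets are marked filled in place; roles are relative, so one residue
    may be a knob in one motif and a socket member in another.
    """
    by_key = {}
    for socket in sockets:
        by_key.setdefault(socket.key, []).append(socket)

    found: dict = {}
    for clique in cliques4:
        for knob_key in clique:
            socket_key = clique - {knob_key}
            for socket in by_key.get(frozenset(socket_key), ()):
                knob = structure.residue_by_key(knob_key)
                if not _knob_is_external(knob, socket):
                    continue
                socket.filled = True
                ks = KnobSocket(socket=socket, knob=knob)
                found.setdefault(ks.key, ks)
    return sorted(
        found.values(),
        key=lambda ks: (ks.knob.chain_id, ks.knob.ordinal,
                        sorted(ks.socket.key)),
    )


def _knob_is_external(knob: Residue, socket: Socket) -> bool:
    if knob.chain_id != socket.helix.chain_id:
        return True
    if socket.helix.start <= knob.ordinal <= socket.helix.end:
        return False
    return all(abs(knob.ordinal - r.ordinal) >= 2 for r in socket.members)


def merge_pockets(knob_sockets: list[KnobSocket]) -> list:
    """Merge pairs of knob-sockets sharing one knob and two socket residues.

    Returns pockets plus the knob-sockets that did not merge.  A knob
    filling three contiguous sockets legitimately yields two pockets that
    share the middle socket (logged).
    """
    by_knob: dict = {}
    for ks in knob_sockets:
        by_knob.setdefault(ks.knob.key, []).append(ks)

    merged = []
    for group in by_knob.values():
        group = sorted(group, key=lambda ks: sorted(ks.socket.key))
        used = set()
        n_pockets = 0
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                if len(a.socket.key & b.socket.key) == 2:
                    first, second = sorted(
                        (a.socket, b.socket), key=lambda s: s.members[0].ordinal
                    )
                    merged.append(Pocket(first=first, second=second, knob=a.knob))
                    used.update((i, j))
                    n_pockets += 1
        if n_pockets >= 2 and len(used) < 2 * n_pockets:
            log.info("knob %r fills >2 contiguous sockets; pockets share a socket",
                     group[0].knob)
        merged.extend(group[i] for i in range(len(group)) if i not in used)
    return sorted(merged, key=_motif_sort_key)


def _motif_sort_key(motif):
    knob = getattr(motif, "knob", None)
    members = motif.socket.members if isinstance(motif, KnobSocket) else motif.members
    return (
        members[0].chain_id,
        members[0].ordinal,
        members[-1].ordinal,
        (knob.chain_id, knob.ordinal) if knob else ("", -1),
    )


def motif_label(motif) -> str:
    """One-letter codes in sequence order, ':' marking H-bonded residues.

    The ':' sits immediately before each backbone-H-bonded member, or after
    it when that member comes first ("VM:V", "H:YX", "S:RV:H").
    """
    if isinstance(motif, KnobSocket):
        return motif_label(motif.socket)
    members = motif.members
    hbonded = motif.hbonded
    out = []
    for idx, res in enumerate(members):
        if res.key in hbonded:
            if idx == 0:
                out.append(res.code1 + ":")
            else:
                out.append(":" + res.code1)
        else:
            out.append(res.code1)
    return "".join(out).replace("::", ":")


def parse_label(label: str) -> tuple[str, tuple[int, ...]]:
    """Recover one-letter codes and the indices of H-bonded members."""
    codes, hbonded = [], []
    mark_next = False
    for ch in label:
        if ch == ":":
            mark_next = True
            if len(codes) == 1 and not hbonded:
                hbonded.append(0)  # leading member marked by a trailing ':'
                mark_next = False
        else:
            if mark_next:
                hbonded.append(len(codes))
                mark_next = False
            codes.append(ch)
    return "".join(codes), tuple(hbonded)


def structured_label(motif) -> dict:
    """Unambiguous structured form of a motif label."""
    if isinstance(motif, KnobSocket):
        base = structured_label(motif.socket)
        base["knob"] = _res_dict(motif.knob)
        return base
    members = motif.members
    hb = motif.hbonded
    entry = {
        "kind": "pocket" if isinstance(motif, Pocket) else "socket",
        "label": motif_label(motif),
        "residues": [
            dict(_res_dict(r), hbonded=r.key in hb, role=_role_of(motif, r))
            for r in members
        ],
    }
    if isinstance(motif, Pocket):
        entry["knob"] = _res_dict(motif.knob)
    return entry


def _res_dict(res: Residue) -> dict:
    return {"chain": res.chain_id, "seq": res.seq_num, "icode": res.icode,
            "aa": res.code1, "name3": res.name3}


def _role_of(motif, res: Residue) -> str:
    sockets = (motif,) if isinstance(motif, Socket) else (motif.first, motif.second)
    roles = []
    for s in sockets:
        for role, member in (("X", s.x), ("Y", s.y), ("H", s.h)):
            if member.key == res.key:
                roles.append(role)
    return "/".join(roles)


# --- lattice map ----------------------------------------------------------

LATTICE_PERIOD = 4  # residues per lattice row; i and i+4 are vertical neighbours


@dataclass
class LatticeMap:
    """2D placement of one helix's residues with socket cells and knobs.

    Residue i (counted from the helix start) occupies column ``i mod 4``,
    row ``i // 4``; the column axis is periodic (the unrolled cylinder), so
    sequence neighbours and i/i+4 pairs are always grid-adjacent.
    """

    helix: HelixAnnotation
    cells: list = field(default_factory=list)    # residue placements
    sockets: list = field(default_factory=list)  # socket cell descriptors
    knobs: list = field(default_factory=list)    # knob overlays

    def to_json(self) -> str:
        return json.dumps(
            {
                "helix": {"chain": self.helix.chain_id, "label": self.helix.label,
                          "length": self.helix.length},
                "period": LATTICE_PERIOD,
                "cells": self.cells,
                "sockets": self.sockets,
                "knobs": self.knobs,
            },
            indent=1,
            sort_keys=True,
        )


def _grid_position(offset: int) -> tuple[int, int]:
    return offset % LATTICE_PERIOD, offset // LATTICE_PERIOD


def build_lattice_map(
    helix: HelixAnnotation,
    motifs: list,
    structure: Structure,
    origin_labels: dict | None = None,
) -> LatticeMap:
    """Deterministic lattice of one helix with its sockets and filled knobs.

    ``motifs`` may mix Socket/KnobSocket/Pocket; only those hosted on
    ``helix`` are drawn.  ``origin_labels`` maps knob residue keys to the
    label of their helix/coil of origin (used for colour tagging).
    """
    chain = structure.chains[helix.chain_id]
    lattice = LatticeMap(helix=helix)
    for offset in range(helix.length):
        res = chain[helix.start + offset]
        col, row = _grid_position(offset)
        lattice.cells.append(
            {"chain": res.chain_id, "seq": res.seq_num, "aa": res.code1,
             "col": col, "row": row}
        )

    def add_socket(socket: Socket, filled: bool):
        entry = {
            "label": motif_label(socket),
            "orientation": socket.orientation,
            "filled": filled,
            "residues": [
                dict(zip(("col", "row"), _grid_position(r.ordinal - helix.start)),
                     seq=r.seq_num, aa=r.code1)
                for r in socket.members
            ],
        }
        if entry not in lattice.sockets:
            lattice.sockets.append(entry)

    for motif in motifs:
        sockets = []
        knob = None
        if isinstance(motif, Socket):
            sockets = [motif]
        elif isinstance(motif, KnobSocket):
            sockets, knob = [motif.socket], motif.knob
        elif isinstance(motif, Pocket):
            sockets, knob = [motif.first, motif.second], motif.knob
        for socket in sockets:
            if socket.helix != helix:
                continue
            add_socket(socket, socket.filled)
            if knob is not None:
                origin = (origin_labels or {}).get(knob.key, knob.chain_id)
                center = [
                    sum(c) / len(socket.members)
                    for c in zip(*(
                        _grid_position(r.ordinal - helix.start)
                        for r in socket.members
                    ))
                ]
                overlay = {
                    "knob_chain": knob.chain_id, "knob_seq": knob.seq_num,
                    "knob_aa": knob.code1, "origin": origin,
                    "col": center[0], "row": center[1],
                    "socket": motif_label(socket),
                }
                if overlay not in lattice.knobs:
                    lattice.knobs.append(overlay)
    lattice.sockets.sort(key=lambda s: (s["residues"][0]["seq"], s["label"]))
    lattice.knobs.sort(key=lambda k: (k["knob_chain"], k["knob_seq"], k["socket"]))
    return lattice


_ORIGIN_PALETTE = [
    "#d62728", "#1f77b4", "#2ca02c", "#ff7f0e", "#9467bd",
    "#8c564b", "#e377c2", "#17becf", "#bcbd22", "#7f7f7f",
]


def lattice_svg(lattice: LatticeMap, cell: int = 46) -> str:
    """Plain SVG rendering of a lattice map (no external dependencies)."""
    pad = cell
    n_rows = max((c["row"] for c in lattice.cells), default=0) + 1
    width = pad * 2 + LATTICE_PERIOD * cell
    height = pad * 2 + n_rows * cell + 24
    origins = sorted({k["origin"] for k in lattice.knobs})
    color = {o: _ORIGIN_PALETTE[i % len(_ORIGIN_PALETTE)] for i, o in enumerate(origins)}

    def cx(col):
        return pad + col * cell + cell // 2

    def cy(row):
        return pad + row * cell + cell // 2

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
        f'<text x="{pad}" y="{pad - 18}" font-family="monospace" font-size="14">'
        f'{lattice.helix.chain_id}:{lattice.helix.label}</text>',
    ]
    for s in lattice.sockets:
        pts = " ".join(f"{cx(r['col'])},{cy(r['row'])}" for r in s["residues"])
        fill = "#ffe8c4" if s["filled"] else "#eeeeee"
        parts.append(
            f'<polygon points="{pts}" fill="{fill}" stroke="#888" stroke-width="1"/>'
        )
    for c in lattice.cells:
        parts.append(
            f'<circle cx="{cx(c["col"])}" cy="{cy(c["row"])}" r="12" '
            f'fill="white" stroke="black"/>'
            f'<text x="{cx(c["col"])}" y="{cy(c["row"]) + 4}" text-anchor="middle" '
            f'font-family="monospace" font-size="11">{c["aa"]}{c["seq"]}</text>'
        )
    for k in lattice.knobs:
        x, y = cx(k["col"]), cy(k["row"])
        parts.append(
            f'<circle cx="{x:.1f}" cy="{y:.1f}" r="9" fill="{color[k["origin"]]}" '
            f'stroke="black"/>'
            f'<text x="{x:.1f}" y="{y + 3.5:.1f}" text-anchor="middle" fill="white" '
            f'font-family="monospace" font-size="9">{k["knob_aa"]}</text>'
        )
    legend_y = height - 8
    for i, origin in enumerate(origins):
        parts.append(
            f'<circle cx="{pad + i * 90}" cy="{legend_y - 4}" r="6" '
            f'fill="{color[origin]}"/>'
            f'<text x="{pad + 10 + i * 90}" y="{legend_y}" font-family="monospace" '
            f'font-size="11">{origin}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts)
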