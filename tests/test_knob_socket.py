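import random

import pytest

from knobsocket.knob_socket import (
    H_YX,
    XY_H,
    KnobSocket,
    Pocket,
    Socket,
    build_lattice_map,
    lattice_svg,
    merge_pockets,
    motif_label,
    parse_label,
    structured_label,
)
from knobsocket.pipeline import analyze_structure
from knobsocket.structure_io import HelixAnnotation
from knobsocket.synthetic_data import HelixSpec, make_ideal_helix

from .conftest import make_residue


def brute_force_sockets(analysis):
    """Enumerate all (i, i+1, i+4) and (i, i+3, i+4) triples whose H-bond
    and contact-graph conditions hold; independent of classify_sockets."""
    structure = analysis.structure
    graph = analysis.graph
    helical = {
        (b.acceptor.chain_id, b.acceptor.ordinal)
        for b in analysis.hbonds if b.is_helical
    }
    def hosted(triple, chain_id):
        for h in analysis.helices:
            if h.chain_id != chain_id:
                continue
            if not all(h.start - 1 <= r.ordinal <= h.end + 1 for r in triple):
                continue
            if sum(1 for r in triple if h.start <= r.ordinal <= h.end) >= 2:
                return True
        return False

    out = set()
    for chain_id, chain in structure.chains.items():
        for i in range(len(chain)):
            if (chain_id, i) not in helical or i + 4 >= len(chain):
                continue
            for mid in (i + 1, i + 3):
                triple = [chain[i], chain[mid], chain[i + 4]]
                if not all(r.is_complete for r in triple):
                    continue
                keys = [r.key for r in triple]
                if not all(graph.has_edge(a, b)
                           for a, b in [(keys[0], keys[1]), (keys[0], keys[2]),
                                        (keys[1], keys[2])]):
                    continue
                if hosted(triple, chain_id):
                    out.add(frozenset(keys))
    return out


def test_isolated_helix_matches_brute_force(params):
    helix = make_ideal_helix(HelixSpec(sequence="AVLAMAVLAMAVLA"))
    analysis = analyze_structure(helix, params)
    assert {s.key for s in analysis.sockets} == brute_force_sockets(analysis)
    assert analysis.sockets, "ideal helix must expose sockets"


def test_socket_orientations_on_ideal_helix(two_helix_analysis):
    for socket in two_helix_analysis.sockets:
        o = [r.ordinal for r in (socket.x, socket.y, socket.h)]
        if socket.orientation == XY_H:
            assert o[1] == o[0] + 1 and o[2] == o[0] + 4
            assert socket.members[0] is socket.x
        else:
            assert socket.orientation == H_YX
            assert o[1] == o[0] - 1 and o[2] == o[0] - 4
            assert socket.members[0] is socket.h
        assert abs(socket.y.ordinal - socket.h.ordinal) == 3


def test_multi_chain_clique_is_not_a_socket(groove_analysis):
    for socket in groove_analysis.sockets:
        assert len({r.chain_id for r in socket.members}) == 1


def test_same_helix_knob_rejected(groove_analysis):
    for ks in groove_analysis.knob_sockets:
        helix = ks.socket.helix
        if ks.knob.chain_id == helix.chain_id:
            assert not (helix.start <= ks.knob.ordinal <= helix.end)
            assert all(abs(ks.knob.ordinal - r.ordinal) >= 2
                       for r in ks.socket.members)


def test_engineered_leu_knob_found(two_helix, two_helix_analysis):
    _, ground_truth = two_helix
    leu = [
        (g.knob_chain, g.knob_seq, g.socket_seqs)
        for g in ground_truth if g.knob_chain == "B" and g.knob_seq == 6
    ]
    detected = [
        (ks.knob.chain_id, ks.knob.seq_num,
         tuple(sorted(r.seq_num for r in ks.socket.members)))
        for ks in two_helix_analysis.knob_sockets
        if ks.knob.chain_id == "B" and ks.knob.name3 == "LEU"
    ]
    assert sorted(detected) == sorted(leu)


def test_every_knob_socket_is_4clique(two_helix_analysis):
    graph = two_helix_analysis.graph
    for ks in two_helix_analysis.knob_sockets:
        keys = [ks.knob.key] + [r.key for r in ks.socket.members]
        assert len(set(keys)) == 4
        for i in range(4):
            for j in range(i + 1, 4):
                assert graph.has_edge(keys[i], keys[j])


def _dummy_helix(chain="A", start=0, end=20, label="H1"):
    return HelixAnnotation(chain_id=chain, start=start, end=end, label=label)


def _socket(seqs, names, orientation, chain="A"):
    residues = [
        make_residue(chain, seq, name, seq - 1, {"CB": (seq, 0, 0)})
        for seq, name in zip(seqs, names)
    ]
    if orientation == XY_H:
        x, y, h = residues
    else:
        h, y, x = residues
    return Socket(x=x, y=y, h=h, orientation=orientation, helix=_dummy_helix())


class TestMergePockets:
    def knob(self, seq=99):
        return make_residue("B", seq, "LEU", seq - 1, {"CB": (0, 5, 0)})

    def make_pair(self):
        s1 = _socket((4, 7, 8), ("SER", "ARG", "VAL"), H_YX)
        s2 = _socket((7, 8, 11), ("ARG", "VAL", "HIS"), XY_H)
        knob = self.knob()
        return [KnobSocket(socket=s1, knob=knob), KnobSocket(socket=s2, knob=knob)]

    def test_two_contiguous_sockets_merge(self):
        merged = merge_pockets(self.make_pair())
        assert len(merged) == 1
        (pocket,) = merged
        assert isinstance(pocket, Pocket)
        assert [r.seq_num for r in pocket.members] == [4, 7, 8, 11]

    def test_single_socket_passes_through(self):
        s1 = _socket((4, 7, 8), ("SER", "ARG", "VAL"), H_YX)
        ks = KnobSocket(socket=s1, knob=self.knob())
        assert merge_pockets([ks]) == [ks]

    def test_disjoint_knobs_no_pocket(self):
        s1 = _socket((4, 7, 8), ("SER", "ARG", "VAL"), H_YX)
        s2 = _socket((14, 17, 18), ("SER", "ARG", "VAL"), H_YX)
        motifs = [KnobSocket(socket=s1, knob=self.knob(99)),
                  KnobSocket(socket=s2, knob=self.knob(88))]
        assert all(isinstance(m, KnobSocket) for m in merge_pockets(motifs))

    def test_order_independence(self):
        pair = self.make_pair()
        s3 = _socket((14, 15, 18), ("ALA", "GLY", "MET"), XY_H)
        motifs = pair + [KnobSocket(socket=s3, knob=self.knob(88))]
        reference = merge_pockets(list(motifs))

        def canonical(out):
            return [
                (type(m).__name__,
                 tuple(r.seq_num for r in
                       (m.members if isinstance(m, Pocket) else m.socket.members)),
                 m.knob.seq_num)
                for m in out
            ]

        rng = random.Random(3)
        for _ in range(10):
            shuffled = list(motifs)
            rng.shuffle(shuffled)
            assert canonical(merge_pockets(shuffled)) == canonical(reference)

    def test_three_chained_sockets_give_two_pockets(self):
        knob = self.knob()
        s1 = _socket((4, 7, 8), ("SER", "ARG", "VAL"), H_YX)
        s2 = _socket((7, 8, 11), ("ARG", "VAL", "HIS"), XY_H)
        s3 = _socket((8, 11, 12), ("VAL", "HIS", "ALA"), H_YX)
        merged = merge_pockets([KnobSocket(socket=s, knob=knob) for s in (s1, s2, s3)])
        pockets = [m for m in merged if isinstance(m, Pocket)]
        assert len(pockets) == 2


class TestMotifLabel:
    def test_xy_h_socket(self):
        s = _socket((10, 11, 14), ("VAL", "MET", "VAL"), XY_H)
        assert motif_label(s) == "VM:V"

    def test_h_yx_all_ala(self):
        s = _socket((10, 13, 14), ("ALA", "ALA", "ALA"), H_YX)
        assert motif_label(s) == "A:AA"

    def test_pocket_label(self):
        s1 = _socket((4, 7, 8), ("SER", "ARG", "VAL"), H_YX)
        s2 = _socket((7, 8, 11), ("ARG", "VAL", "HIS"), XY_H)
        knob = make_residue("B", 99, "GLU", 98, {"CB": (0, 5, 0)})
        (pocket,) = merge_pockets(
            [KnobSocket(socket=s1, knob=knob), KnobSocket(socket=s2, knob=knob)]
        )
        assert motif_label(pocket) == "S:RV:H"

    def test_knob_socket_label_delegates(self):
        s = _socket((10, 11, 14), ("VAL", "MET", "VAL"), XY_H)
        ks = KnobSocket(socket=s, knob=make_residue("B", 1, "LEU", 0, {"CB": (0, 0, 0)}))
        assert motif_label(ks) == "VM:V"

    @pytest.mark.parametrize(
        "label,codes,hbonded",
        [("VM:V", "VMV", (2,)), ("A:AA", "AAA", (0,)), ("S:RV:H", "SRVH", (0, 3))],
    )
    def test_label_roundtrip(self, label, codes, hbonded):
        assert parse_label(label) == (codes, hbonded)

    def test_roundtrip_on_fixture_motifs(self, groove_analysis):
        for socket in groove_analysis.sockets:
            codes, hb = parse_label(motif_label(socket))
            assert codes == "".join(r.code1 for r in socket.members)
            assert {socket.members[i].key for i in hb} == set(socket.hbonded)

    def test_structured_label_disambiguates(self, groove_analysis):
        for motif in groove_analysis.motifs:
            entry = structured_label(motif)
            assert entry["kind"] in ("socket", "pocket")
            assert entry["label"] == motif_label(motif)
            roles = [r["role"] for r in entry["residues"]]
            assert all(roles)


class TestLatticeMap:
    def test_five_residue_helix_socket_count(self, params):
        helix = make_ideal_helix(HelixSpec(sequence="AVLAM"))
        analysis = analyze_structure(helix, params)
        assert {s.key for s in analysis.sockets} == brute_force_sockets(analysis)
        (h,) = analysis.helices
        lattice = build_lattice_map(h, analysis.sockets, helix)
        assert len(lattice.sockets) == len(analysis.sockets)

    def test_bare_lattice_without_motifs(self, helix12):
        h = HelixAnnotation(chain_id="A", start=0, end=11, label="H1")
        lattice = build_lattice_map(h, [], helix12)
        assert lattice.sockets == [] and lattice.knobs == []
        assert len(lattice.cells) == 12

    def test_each_residue_exactly_once(self, groove_analysis):
        for h in groove_analysis.helices:
            lattice = build_lattice_map(h, groove_analysis.motifs,
                                        groove_analysis.structure)
            seen = [(c["chain"], c["seq"]) for c in lattice.cells]
            assert len(seen) == len(set(seen)) == h.length

    def test_deterministic_and_json_svg_emittable(self, groove_analysis):
        h = groove_analysis.helices[1]
        origin = groove_analysis.origin_labels()
        l1 = build_lattice_map(h, groove_analysis.motifs, groove_analysis.structure, origin)
        l2 = build_lattice_map(h, groove_analysis.motifs, groove_analysis.structure, origin)
        assert l1.to_json() == l2.to_json()
        svg = lattice_svg(l1)
        assert svg.startswith("<svg") and svg.endswith("</svg>")
        assert l1.knobs, "groove middle helix should carry knob overlays"

    def test_knob_origin_tags(self, groove_analysis):
        origin = groove_analysis.origin_labels()
        h2 = groove_analysis.helices[1]
        lattice = build_lattice_map(h2, groove_analysis.motifs,
                                    groove_analysis.structure, origin)
        origins = {k["origin"] for k in lattice.knobs}
        # the middle receptor helix receives knobs both from the ligand and
        # from the flanking receptor helices, each tagged with its origin
        assert any(o.startswith("B:") for o in origins)
        assert origins <= set(origin.values())
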