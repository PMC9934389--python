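"""Atomic contacts from a Delaunay tessellation, lifted to a residue graph.

A pair of heavy atoms is in contact when the two atoms are Delaunay
neighbours (share a Voronoi facet) and lie within a distance cutoff; the
cutoff suppresses the spurious long edges along the convex hull.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError

from .structure_io import AtomRecord, Structure

log = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 6.0  # Angstrom
JITTER_SCALE = 1e-6
JITTER_SEED = 0

# residue contact classes
MM = "mm"  # main chain - main chain
MS = "ms"  # main chain - side chain
SS = "ss"  # side chain - side chain


@dataclass(frozen=True)
class AtomContact:
    a: AtomRecord
    b: AtomRecord
    distance: float
    shares_facet: bool = True


def _delaunay_edges(coords: np.ndarray) -> set[tuple[int, int]]:
    try:
        tri = Delaunay(coords)
    except QhullError:
        log.warning(
            "degenerate point configuration; retrying with %g jitter (seed %d)",
            JITTER_SCALE, JITTER_SEED,
        )
        rng = np.random.default_rng(JITTER_SEED)
        tri = Delaunay(coords + rng.normal(scale=JITTER_SCALE, size=coords.shape))
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for i, j in itertools.combinations(sorted(simplex.tolist()), 2):
            edges.add((i, j))
    return edges


def atomic_contacts(
    structure: Structure, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> list[AtomContact]:
    """Heavy-atom pairs that share a Voronoi facet and are within ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atoms = list(structure.atoms())
    if len(atoms) < 4:
        return []
    coords = np.array([a.coord for a in atoms])
    contacts = []
    for i, j in sorted(_delaunay_edges(coords)):
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        if dist <= cutoff:
            contacts.append(AtomContact(a=atoms[i], b=atoms[j], distance=dist))
    return contacts


def _atom_class(atom: AtomRecord) -> str:
    # Gly has no side chain; its CA stands in for one in packing classes
    if atom.name == "CA" and atom.residue is not None and atom.residue.name3 == "GLY":
        return "s"
    return "m" if atom.is_backbone else "s"


def contact_class(contact: AtomContact) -> str:
    return "".join(sorted(_atom_class(contact.a) + _atom_class(contact.b)))


def residue_contact_graph(contacts: list[AtomContact], structure: Structure) -> nx.Graph:
    """Lift atomic contacts to an undirected residue graph.

    Nodes are residue keys ``(chain_id, ordinal)``.  Edge attributes:
    ``classes`` (subset of {mm, ms, ss}), ``n_atomic`` (supporting atomic
    contacts) and ``adjacent`` (True for |delta ordinal| == 1 within a
    chain, so knob detection can skip trivial sequence neighbours).
    """
    graph = nx.Graph()
    for res in structure.residues():
        graph.add_node(res.key, residue=res)
    for contact in contacts:
        ra, rb = contact.a.residue, contact.b.residue
        if ra is None or rb is None or ra.key == rb.key:
            continue  # intra-residue: no self-edges
        u, v = ra.key, rb.key
        if graph.has_edge(u, v):
            data = graph.edges[u, v]
            data["classes"].add(contact_class(contact))
            data["n_atomic"] += 1
        else:
            adjacent = ra.chain_id == rb.chain_id and abs(ra.ordinal - rb.ordinal) == 1
            graph.add_edge(
                u, v,
                classes={contact_class(contact)},
                n_atomic=1,
                adjacent=adjacent,
            )
    return graph


def enumerate_cliques(graph: nx.Graph, size: int) -> list[frozenset]:
    """All complete subgraphs of exactly ``size`` residues (3 or 4)."""
    if size not in (3, 4):
        raise ValueError("clique size must be 3 or 4")
    cliques = []
    for clique in nx.enumerate_all_cliques(graph):
        if len(clique) > size:
            break  # enumerate_all_cliques yields in nondecreasing size
        if len(clique) == size:
            cliques.append(frozenset(clique))
    return sorted(cliques, key=lambda c: sorted(c))


def write_contacts_tsv(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tordinal\tpartner_chain\tpartner_ordinal\tclasses\tn_atomic\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(
                f"{u[0]}\t{u[1]}\t{v[0]}\t{v[1]}\t"
                f"{','.join(sorted(data['classes']))}\t{data['n_atomic']}\n"
            )
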