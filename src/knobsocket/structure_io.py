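"""Read protein structures, detect backbone hydrogen bonds, annotate helices.

Only heavy atoms of polymer residues are retained: hydrogens, waters and
hetero/ligand groups never enter the packing analysis.  One altloc is kept
per atom (highest occupancy, ties broken toward 'A').
"""

from __future__ import annotations

import os
import urllib.request
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from scipy.spatial import cKDTree

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: backbone heavy atoms; everything else is side chain (Gly CA is
#: re-classified as side chain where packing classes are assigned).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

DEFAULT_HBOND_CUTOFF = 3.5  # O...N distance, Angstrom
MIN_HELIX_LENGTH = 5


@dataclass
class AtomRecord:
    """A single heavy atom with resolved altloc."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    residue: "Residue | None" = field(default=None, repr=False, compare=False)

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class Residue:
    """A polymer residue: identity (ResidueRef fields) plus its heavy atoms."""

    chain_id: str
    seq_num: int
    icode: str
    name3: str
    ordinal: int  # 0-based index along the chain, strictly increasing
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def code1(self) -> str:
        return THREE_TO_ONE.get(self.name3, "X")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.ordinal)

    @property
    def is_complete(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C", "O"))

    def __hash__(self):
        return hash(self.key)

    def __eq__(self, other):
        return isinstance(other, Residue) and self.key == other.key

    def __repr__(self):
        return f"{self.chain_id}/{self.name3}{self.seq_num}{self.icode.strip()}"


@dataclass
class Structure:
    source_id: str
    model_index: int
    chains: dict[str, list[Residue]]

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def atoms(self):
        for res in self.residues():
            yield from res.atoms.values()

    def residue_by_key(self, key: tuple[str, int]) -> Residue:
        return self.chains[key[0]][key[1]]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


@dataclass(frozen=True)
class BackboneHBond:
    """Backbone carbonyl-O (acceptor) to amide-N (donor) hydrogen bond."""

    acceptor: Residue
    donor: Residue
    distance: float

    @property
    def is_helical(self) -> bool:
        """True for the intra-chain i -> i+4 bond that defines the helix."""
        return (
            self.acceptor.chain_id == self.donor.chain_id
            and self.donor.ordinal - self.acceptor.ordinal == 4
        )


@dataclass(frozen=True)
class HelixAnnotation:
    chain_id: str
    start: int  # ordinal of first residue
    end: int    # ordinal of last residue (inclusive)
    label: str  # H1...Hn in sequence order per chain

    def __contains__(self, residue: Residue) -> bool:
        return residue.chain_id == self.chain_id and self.start <= residue.ordinal <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class PDBReadError(ValueError):
    pass


def _pick_altloc(atoms: list) -> "object":
    # highest occupancy wins; ties resolved toward altloc 'A' (then lexical)
    return sorted(atoms, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))[0]


def read_structure(path: str | os.PathLike, model_index: int = 1) -> Structure:
    """Parse a PDB file into a heavy-atom :class:`Structure`.

    ``model_index`` is the 1-based MODEL number; single-model crystal
    structures use the default.  Waters, hetero residues and hydrogens are
    discarded; exactly one altloc is kept per atom name per residue.
    """
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure(os.path.basename(str(path)), str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise PDBReadError(f"cannot parse PDB file {path!r}: {exc}") from exc

    models = list(bio_structure.get_models())
    if not models:
        raise PDBReadError(f"no models found in {path!r}")
    by_serial = {m.serial_num: m for m in models}
    if model_index in by_serial:
        model = by_serial[model_index]
    elif 1 <= model_index <= len(models):
        model = models[model_index - 1]
    else:
        avail = sorted(by_serial) or list(range(1, len(models) + 1))
        raise PDBReadError(
            f"model {model_index} not present in {path!r}; available models: {avail}"
        )

    source_id = os.path.splitext(os.path.basename(str(path)))[0]
    chains: dict[str, list[Residue]] = {}
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetfield, seq_num, icode = bio_res.id
            if hetfield.strip():  # waters and hetero/ligand groups
                continue
            res = Residue(
                chain_id=bio_chain.id,
                seq_num=seq_num,
                icode=icode.strip(),
                name3=bio_res.get_resname().strip(),
                ordinal=len(residues),
            )
            for name, bio_atom in _iter_resolved_atoms(bio_res):
                element = (bio_atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                coord = np.asarray(bio_atom.get_coord(), dtype=float)
                if not np.all(np.isfinite(coord)):
                    raise PDBReadError(f"non-finite coordinates for atom {name} in {res!r}")
                res.atoms[name] = AtomRecord(
                    name=name,
                    element=element,
                    coord=coord,
                    occupancy=float(bio_atom.get_occupancy() or 1.0),
                    altloc=bio_atom.get_altloc().strip(),
                    residue=res,
                )
            if res.atoms:
                residues.append(res)
        if residues:
            chains[bio_chain.id] = residues
    if not chains:
        raise PDBReadError(f"no polymer residues found in {path!r}")
    return Structure(source_id=source_id, model_index=model_index, chains=chains)


def _iter_resolved_atoms(bio_res):
    for atom in bio_res:
        if atom.is_disordered():
            yield atom.get_id(), _pick_altloc(atom.disordered_get_list())
        else:
            yield atom.get_id(), atom


def detect_backbone_hbonds(
    structure: Structure, max_ON: float = DEFAULT_HBOND_CUTOFF
) -> list[BackboneHBond]:
    """All carbonyl-O to amide-N pairs within ``max_ON`` Angstrom.

    The covalent O(i)-N(i+1) peptide-bond pair and same-residue pairs are
    excluded; donor/acceptor roles are fixed (O is always the acceptor).
    """
    acceptors = [r for r in structure.residues() if "O" in r.atoms]
    donors = [r for r in structure.residues() if "N" in r.atoms]
    if not acceptors or not donors:
        return []
    o_coords = np.array([r.atoms["O"].coord for r in acceptors])
    n_coords = np.array([r.atoms["N"].coord for r in donors])
    tree = cKDTree(n_coords)
    bonds = []
    for ai, neighbors in enumerate(tree.query_ball_point(o_coords, max_ON)):
        acc = acceptors[ai]
        for di in neighbors:
            don = donors[di]
            if acc.chain_id == don.chain_id and don.ordinal - acc.ordinal in (0, 1):
                continue
            dist = float(np.linalg.norm(acc.atoms["O"].coord - don.atoms["N"].coord))
            bonds.append(BackboneHBond(acceptor=acc, donor=don, distance=dist))
    bonds.sort(key=lambda b: (b.acceptor.chain_id, b.acceptor.ordinal,
                              b.donor.chain_id, b.donor.ordinal))
    return bonds


def assign_helices(
    structure: Structure,
    hbonds: list[BackboneHBond],
    min_length: int = MIN_HELIX_LENGTH,
) -> list[HelixAnnotation]:
    """Annotate maximal alpha-helical runs from i -> i+4 backbone H-bonds.

    Each helical bond at residue i marks the span i..i+4; overlapping spans
    are merged and runs shorter than ``min_length`` residues are dropped.
    Labels are H1...Hn per chain in sequence order.
    """
    starts: dict[str, list[int]] = {}
    for bond in hbonds:
        if bond.is_helical:
            starts.setdefault(bond.acceptor.chain_id, []).append(bond.acceptor.ordinal)

    annotations = []
    for chain_id in structure.chains:
        spans = []
        for i in sorted(set(starts.get(chain_id, ()))):
            if spans and i <= spans[-1][1]:
                spans[-1][1] = max(spans[-1][1], i + 4)
            else:
                spans.append([i, i + 4])
        chain = structure.chains[chain_id]
        label_no = 0
        for start, end in spans:
            end = min(end, len(chain) - 1)
            if end - start + 1 < min_length:
                continue
            if not all(chain[j].is_complete for j in range(start, end + 1)):
                # trim incomplete termini rather than reject the whole run
                while start <= end and not chain[start].is_complete:
                    start += 1
                while end >= start and not chain[end].is_complete:
                    end -= 1
                if end - start + 1 < min_length:
                    continue
            label_no += 1
            annotations.append(
                HelixAnnotation(chain_id=chain_id, start=start, end=end, label=f"H{label_no}")
            )
    return annotations


def secondary_label(residue: Residue, helices: list[HelixAnnotation]) -> str:
    """Helix label for helical residues, ``Ci-j`` for coil between Hi and Hj."""
    chain_helices = sorted(
        (h for h in helices if h.chain_id == residue.chain_id), key=lambda h: h.start
    )
    before = 0
    for h in chain_helices:
        if residue in h:
            return h.label
        if h.end < residue.ordinal:
            before = int(h.label[1:])
    return f"C{before}-{before + 1}"


def write_summary_tsv(structure: Structure, helices: list[HelixAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tstart_res\tend_res\tn_residues\tlabel\n")
        for h in sorted(helices, key=lambda h: (h.chain_id, h.start)):
            chain = structure.chains[h.chain_id]
            fh.write(
                f"{h.chain_id}\t{chain[h.start].seq_num}\t{chain[h.end].seq_num}"
                f"\t{h.length}\t{h.label}\n"
            )


PDB_DOWNLOAD_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch_pdb(pdb_id: str, cache_dir: str | os.PathLike) -> str:
    """Download a PDB entry into ``cache_dir`` (no-op if already cached)."""
    os.makedirs(cache_dir, exist_ok=True)
    path = os.path.join(str(cache_dir), f"{pdb_id.lower()}.pdb")
    if os.path.exists(path):
        return path
    url = PDB_DOWNLOAD_URL.format(pdb_id=pdb_id.upper())
    with urllib.request.urlopen(url, timeout=30) as resp, open(path, "wb") as out:
        out.write(resp.read())
    return path
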