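"""End-to-end orchestration: per-complex analysis and aggregate models."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from importlib import resources

from . import consensus as cns
from . import contacts as ct
from . import interface_analysis as ia
from . import knob_socket as ks
from . import structure_io as sio

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    contact_cutoff: float = ct.DEFAULT_CONTACT_CUTOFF
    hbond_cutoff: float = sio.DEFAULT_HBOND_CUTOFF
    min_helix_length: int = sio.MIN_HELIX_LENGTH

    def __post_init__(self):
        if not (0 < self.contact_cutoff <= 12.0):
            raise ValueError("contact_cutoff must be in (0, 12] Angstrom")
        if not (2.0 <= self.hbond_cutoff <= 5.0):
            raise ValueError("hbond_cutoff must be in [2, 5] Angstrom")
        if self.min_helix_length < 5:
            raise ValueError("min_helix_length must be at least 5")


@dataclass
class AnalysisResult:
    """Everything the packing analysis derives from one structure."""

    structure: sio.Structure
    params: PipelineParams
    hbonds: list
    helices: list
    graph: object
    sockets: list
    knob_sockets: list
    motifs: list  # pockets + unmerged knob-sockets

    def origin_labels(self) -> dict:
        labels = {}
        for res in self.structure.residues():
            labels[res.key] = f"{res.chain_id}:{sio.secondary_label(res, self.helices)}"
        return labels


def analyze_structure(
    structure: sio.Structure, params: PipelineParams = PipelineParams()
) -> AnalysisResult:
    """Run the full knob-socket detection chain on one structure."""
    hbonds = sio.detect_backbone_hbonds(structure, params.hbond_cutoff)
    helices = sio.assign_helices(structure, hbonds, params.min_helix_length)
    contacts = ct.atomic_contacts(structure, params.contact_cutoff)
    graph = ct.residue_contact_graph(contacts, structure)
    cliques3 = ct.enumerate_cliques(graph, 3)
    cliques4 = ct.enumerate_cliques(graph, 4)
    sockets = ks.classify_sockets(cliques3, helices, hbonds, graph, structure)
    knob_sockets = ks.find_knob_sockets(cliques4, sockets, helices, structure)
    motifs = ks.merge_pockets(knob_sockets)
    return AnalysisResult(
        structure=structure, params=params, hbonds=hbonds, helices=helices,
        graph=graph, sockets=sockets, knob_sockets=knob_sockets, motifs=motifs,
    )


@dataclass(frozen=True)
class ComplexEntry:
    pdb_id: str
    paralog: str
    ligand_name: str
    receptor_chains: tuple[str, ...] = ("A",)
    ligand_chain: str = "B"
    helix_label_map: dict = field(default_factory=dict, hash=False, compare=False)
    numbering_offset: int = 0
    point_mutant: bool = False
    model_index: int = 1
    path: str = ""  # explicit file path; otherwise resolved from a cache dir


@dataclass
class RunConfig:
    complexes: list[ComplexEntry]
    params: PipelineParams = PipelineParams()
    pdb_dir: str = ""
    output_dir: str = "ks-output"
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        params = PipelineParams(**raw.get("params", {}))
        complexes = []
        for entry in raw["complexes"]:
            entry = dict(entry)
            entry["receptor_chains"] = tuple(entry.get("receptor_chains", ("A",)))
            complexes.append(ComplexEntry(**entry))
        ids = [c.pdb_id for c in complexes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate complex ids in configuration")
        return cls(
            complexes=complexes,
            params=params,
            pdb_dir=raw.get("pdb_dir", ""),
            output_dir=raw.get("output_dir", "ks-output"),
            seed=int(raw.get("seed", 0)),
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_config() -> RunConfig:
    """The shipped 19-complex BCL-2:BH3 configuration."""
    raw = json.loads(
        resources.files("knobsocket.data").joinpath("bcl2_complexes.json").read_text()
    )
    return RunConfig.from_dict(raw)


def resolve_structure_path(entry: ComplexEntry, pdb_dir: str = "") -> str:
    if entry.path:
        return entry.path
    candidates = []
    for d in filter(None, [pdb_dir, os.environ.get("KNOBSOCKET_PDB_DIR", "")]):
        candidates.append(os.path.join(d, f"{entry.pdb_id.lower()}.pdb"))
    for c in candidates:
        if os.path.exists(c):
            return c
    raise FileNotFoundError(
        f"structure file for {entry.pdb_id} not found; looked in "
        f"{candidates or '[no pdb_dir configured]'}"
    )


def run_complex(
    entry: ComplexEntry,
    params: PipelineParams = PipelineParams(),
    outdir: str | None = None,
    pdb_dir: str = "",
    structure: sio.Structure | None = None,
):
    """Analyze one complex and (optionally) write its per-complex artifacts."""
    if structure is None:
        path = resolve_structure_path(entry, pdb_dir)
        structure = sio.read_structure(path, model_index=entry.model_index)
    missing = [c for c in (*entry.receptor_chains, entry.ligand_chain)
               if c not in structure.chains]
    if missing:
        raise ValueError(
            f"{entry.pdb_id}: configured chains {missing} absent from structure "
            f"(has {sorted(structure.chains)})"
        )
    result = analyze_structure(structure, params)
    imap = ia.map_interface(
        structure,
        entry.receptor_chains,
        entry.ligand_chain,
        result.motifs,
        helices=result.helices,
        label_map=entry.helix_label_map,
        receptor_paralog=entry.paralog,
        ligand_name=entry.ligand_name,
    )
    if outdir:
        write_complex_outputs(entry, result, imap, outdir)
    return result, imap


def write_complex_outputs(entry, result: AnalysisResult, imap, outdir) -> None:
    cdir = os.path.join(outdir, entry.pdb_id)
    os.makedirs(cdir, exist_ok=True)
    with open(os.path.join(cdir, "interface.json"), "w") as fh:
        fh.write(ia.interface_to_json(imap))
    with open(os.path.join(cdir, "interface.tsv"), "w") as fh:
        fh.write(ia.interface_to_tsv(imap))
    sio.write_summary_tsv(
        result.structure, result.helices, os.path.join(cdir, "helices.tsv")
    )
    ct.write_contacts_tsv(result.graph, os.path.join(cdir, "contacts.tsv"))
    origin = result.origin_labels()
    for helix in result.helices:
        if helix.chain_id not in entry.receptor_chains:
            continue
        lattice = ks.build_lattice_map(helix, result.motifs, result.structure, origin)
        stem = os.path.join(cdir, f"lattice_{helix.chain_id}_{helix.label}")
        with open(stem + ".json", "w") as fh:
            fh.write(lattice.to_json())
        with open(stem + ".svg", "w") as fh:
            fh.write(ks.lattice_svg(lattice))
    with open(os.path.join(cdir, "run.json"), "w") as fh:
        json.dump(
            {
                "complex": entry.pdb_id,
                "params": dataclasses.asdict(result.params),
                "counts": {
                    "residues": sum(len(c) for c in result.structure.chains.values()),
                    "helices": len(result.helices),
                    "sockets": len(result.sockets),
                    "knob_sockets": len(result.knob_sockets),
                    "interface_motifs": len(imap.motifs()),
                },
            },
            fh, indent=1, sort_keys=True,
        )


def _paralog_distance_table(exemplar_map, groove_model):
    """Centroid distance table over the exemplar's conserved groove sockets."""
    conserved = {frozenset(tuple(p) for p in e["position"])
                 for e in groove_model.conserved}
    groups: dict = {}
    for motif in exemplar_map.ligand_to_receptor:
        if ia.receptor_socket_identity(motif) not in conserved:
            continue
        label = exemplar_map.helix_labels.get(motif.key, "")
        groups.setdefault(label, []).append(motif)
    if not groups:
        return None
    return ia.groove_distance_table(groups)


def run_aggregate(
    per_complex: dict,
    config: RunConfig,
    outdir: str | None = None,
):
    """Aggregate per-complex results into groove and consensus models.

    ``per_complex`` maps pdb_id -> (AnalysisResult, InterfaceMap).  Returns
    a dict with groove models per paralog, consensus models (all-complex
    and per-paralog), central references and aligned ligands.
    """
    if not per_complex:
        raise ValueError("no per-complex results to aggregate")
    entries = {e.pdb_id: e for e in config.complexes if e.pdb_id in per_complex}

    maps, refs, structures = [], [], {}
    central = {}
    for pdb_id, (result, imap) in per_complex.items():
        ref = cns.find_central_reference(imap)
        maps.append(imap)
        refs.append(ref)
        central[pdb_id] = ref
        structures[imap.complex_id] = result.structure

    aligned = cns.align_ligands(maps, refs, structures)
    models = {
        "all": cns.classify_positions(aligned, scope="all"),
        "all_knob_only": cns.classify_positions(aligned, scope="all", knob_only=True),
    }
    by_paralog: dict = {}
    for imap, item in zip(maps, aligned):
        paralog = entries[imap.complex_id].paralog if imap.complex_id in entries \
            else imap.receptor_paralog
        by_paralog.setdefault(paralog, []).append((imap, item))

    groove_models = {}
    distance_tables = {}
    for paralog, pairs in by_paralog.items():
        paralog_maps = [p[0] for p in pairs]
        groove_models[paralog] = ia.conserved_groove_model(paralog_maps, paralog=paralog)
        models[f"paralog:{paralog}"] = cns.classify_positions(
            [p[1] for p in pairs], scope=paralog
        )
        distance_tables[paralog] = _paralog_distance_table(
            paralog_maps[0], groove_models[paralog]
        )

    out = {
        "central_references": central,
        "aligned": aligned,
        "consensus": models,
        "groove": groove_models,
        "distance_tables": distance_tables,
    }
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        for name, model in models.items():
            safe = name.replace(":", "_").replace("/", "-")
            with open(os.path.join(outdir, f"consensus_{safe}.json"), "w") as fh:
                fh.write(model.to_json())
            with open(os.path.join(outdir, f"consensus_{safe}.tsv"), "w") as fh:
                fh.write(model.to_tsv())
        for paralog, model in groove_models.items():
            safe = paralog.replace("/", "-").replace(" ", "_")
            with open(os.path.join(outdir, f"groove_{safe}.json"), "w") as fh:
                fh.write(model.to_json())
            table = distance_tables[paralog]
            if table is not None:
                for which in ("min", "max"):
                    with open(os.path.join(outdir, f"distances_{safe}_{which}.tsv"),
                              "w") as fh:
                        fh.write(table.to_tsv(which))
        for paralog, pairs in by_paralog.items():
            safe = paralog.replace("/", "-").replace(" ", "_")
            shown = [
                item for _, item in pairs
                if not entries.get(item.complex_id, ComplexEntry("", "", "")).point_mutant
            ]
            if shown:
                with open(os.path.join(outdir, f"aligned_{safe}.fasta"), "w") as fh:
                    fh.write(cns.alignment_fasta(shown))
        display = [
            item for item in aligned
            if not entries.get(item.complex_id, ComplexEntry("", "", "")).point_mutant
        ]
        with open(os.path.join(outdir, "aligned_ligands.fasta"), "w") as fh:
            fh.write(cns.alignment_fasta(display))
        with open(os.path.join(outdir, "central_references.tsv"), "w") as fh:
            fh.write("complex\tresidue\taa\tsubstituted\n")
            for pdb_id in sorted(central):
                ref = central[pdb_id]
                fh.write(
                    f"{pdb_id}\t{ref.residue.chain_id}{ref.residue.seq_num}\t"
                    f"{ref.amino_acid}\t{str(ref.substituted).lower()}\n"
                )
    return out
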