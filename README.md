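# knobsocket

Knob-Socket packing analysis of α-helical protein–peptide interfaces,
packaged as a reusable pipeline for BCL-2:BH3 co-crystal complexes.

The Knob-Socket model organizes a helical binding interface into 4-residue
units: a 3-residue **socket** on one helix (peptide-bonded neighbours X,Y
plus residue H joined to X by the helical i→i+4 backbone hydrogen bond)
packing a single **knob** residue B from another helix or chain.  A knob
filling two contiguous sockets defines a 4-residue **pocket**.  From these
motifs the pipeline builds per-complex interface maps and lattice diagrams,
binding-groove centroid distance tables, conserved/specific groove models
per receptor paralog, and consensus models of BH3 ligands aligned on the
central glycine reference (lattice position 20 of a 27-position window).

## Layout

| module | role |
| --- | --- |
| `knobsocket.structure_io` | PDB reading (model/altloc policy), backbone H-bond detection, helix annotation |
| `knobsocket.contacts` | Delaunay/Voronoi atomic contacts, typed residue contact graph, 3-/4-clique enumeration |
| `knobsocket.knob_socket` | socket classification (XY:H / H:YX), knob-socket detection, pocket merging, motif labels, lattice maps (JSON + SVG) |
| `knobsocket.interface_analysis` | receptor↔ligand interface maps, socket centroids (mean Cβ, Cα for Gly), groove distance tables, conserved groove models |
| `knobsocket.consensus` | central-Gly reference finding, 27-position ligand alignment, conserved/variable/non-essential classification, consensus residues |
| `knobsocket.synthetic_data` | ideal-helix generators and packing fixtures with frozen ground truth (no downloads needed) |
| `knobsocket.cli` | `knobsocket analyze / aggregate / simulate / fetch` |

## CLI

```sh
# synthetic fixture with known ground truth, then analyze it
knobsocket simulate --fixture groove --out groove.pdb
knobsocket analyze groove.pdb --out results/

# the full curated 19-complex set (after fetching the PDB files)
knobsocket fetch --cache pdb-cache
knobsocket analyze --pdb-dir pdb-cache --out results/
knobsocket aggregate --pdb-dir pdb-cache --out results/
```

Per-complex outputs: `interface.{json,tsv}`, `helices.tsv`, `contacts.tsv`,
one `lattice_<chain>_<helix>.{json,svg}` per receptor helix, and `run.json`
recording all parameters.  Aggregate outputs: consensus lattice tables
(all-complex and per-paralog), conserved/specific groove models, aligned
ligand FASTA, and the central-reference table.

Defaults (all configurable via flags or a config JSON; precedence
flags > config > defaults): contact cutoff 6.0 Å on Delaunay neighbours,
backbone O···N H-bond cutoff 3.5 Å, minimum helix length 5.  The shipped
configuration (`knobsocket/data/bcl2_complexes.json`) encodes the curated
19-complex BCL-2:BH3 set.

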