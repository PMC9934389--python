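{
  "comment": "Curated set of 19 BCL-2:BH3 co-crystal/NMR complexes. Chain assignments follow the common deposition convention (receptor chain A, BH3 peptide chain B) and should be verified against fetched files; helix_label_map translates detected per-chain helix labels (chain:Hn) into the published receptor helix nomenclature where they differ.",
  "params": {"contact_cutoff": 6.0, "hbond_cutoff": 3.5, "min_helix_length": 5},
  "complexes": [
    {"pdb_id": "2pqk", "paralog": "Mcl-1", "ligand_name": "Bim", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "3pk1", "paralog": "Mcl-1", "ligand_name": "Bax", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "2kbw", "paralog": "Mcl-1", "ligand_name": "Bid", "receptor_chains": ["A"], "ligand_chain": "B", "model_index": 1},
    {"pdb_id": "3kj0", "paralog": "Mcl-1", "ligand_name": "Bim I2dY", "receptor_chains": ["A"], "ligand_chain": "B", "point_mutant": true},
    {"pdb_id": "3kj2", "paralog": "Mcl-1", "ligand_name": "Bim F4aE", "receptor_chains": ["A"], "ligand_chain": "B", "point_mutant": true},
    {"pdb_id": "3mqp", "paralog": "BFL-1/A1", "ligand_name": "Noxa", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "2voi", "paralog": "BFL-1/A1", "ligand_name": "Bid", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "2vm6", "paralog": "BFL-1/A1", "ligand_name": "Bim", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "2voh", "paralog": "BFL-1/A1", "ligand_name": "Bak", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "2vog", "paralog": "Murine BFL-1", "ligand_name": "BMF", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "2vof", "paralog": "Murine BFL-1", "ligand_name": "Puma", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "2wh6", "paralog": "BHRF1", "ligand_name": "Bim", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "2xpx", "paralog": "BHRF1", "ligand_name": "Bak", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "3fdl", "paralog": "BCL-xL", "ligand_name": "Bim", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "1bxl", "paralog": "BCL-xL", "ligand_name": "Bak", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "1g5j", "paralog": "BCL-xL", "ligand_name": "Bad", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "3io8", "paralog": "BCL-xL", "ligand_name": "Bim L12F", "receptor_chains": ["A"], "ligand_chain": "B", "point_mutant": true},
    {"pdb_id": "2pon", "paralog": "BCL-xL", "ligand_name": "Beclin-1", "receptor_chains": ["A"], "ligand_chain": "B"},
    {"pdb_id": "2xa0", "paralog": "BCL-2", "ligand_name": "Bax", "receptor_chains": ["A"], "ligand_chain": "B"}
  ]
}
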