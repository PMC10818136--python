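"""On-disk dataset layout: the CSV/PDB/JSON formats the CLI reads and writes.

A dataset directory contains::

    smiles.csv      drug_id,smiles
    proteins/*.pdb  one structure per target
    sites.json      precomputed binding-site graphs (portable JSON dialect)
    edges.csv       source_id,target_id,edge_type,weight
    pairs.csv       drug_id,target_id,label
    spec.yaml       generator spec (including the seed), for provenance
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bio_graph import DRUG, build_hetero_graph
from .evaluation import PairRecord
from .protein_encoder import read_structure, sites_from_json_file, sites_to_json_file
from .synthetic_data import DrugRecord, SyntheticDataset, SyntheticSpec, TargetRecord

__all__ = ["write_dataset", "load_dataset"]


def write_dataset(ds: SyntheticDataset, out_dir) -> Path:
    out = Path(out_dir)
    (out / "proteins").mkdir(parents=True, exist_ok=True)
    pd.DataFrame([(d.drug_id, d.smiles) for d in ds.drugs],
                 columns=["drug_id", "smiles"]).to_csv(out / "smiles.csv", index=False)
    for t in ds.targets:
        (out / "proteins" / f"{t.target_id}.pdb").write_text(t.pdb_text)
    sites_to_json_file({t.target_id: t.sites for t in ds.targets}, out / "sites.json")

    g = ds.graph
    rows = []
    n = g.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            if g.interaction[i, j]:
                rows.append((g.node_ids[i], g.node_ids[j], "interaction", 1.0))
            if g.similarity[i, j] > 0:
                kind = "drug_similarity" if g.node_type[i] == DRUG else "target_similarity"
                rows.append((g.node_ids[i], g.node_ids[j], kind, float(g.similarity[i, j])))
    pd.DataFrame(rows, columns=["source_id", "target_id", "edge_type", "weight"]).to_csv(
        out / "edges.csv", index=False)
    pd.DataFrame([(p.drug_id, p.target_id, p.label) for p in ds.pairs],
                 columns=["drug_id", "target_id", "label"]).to_csv(out / "pairs.csv", index=False)
    with open(out / "spec.yaml", "w") as f:
        yaml.safe_dump(asdict(ds.spec), f)
    return out


def load_dataset(in_dir) -> SyntheticDataset:
    """Rebuild an in-memory dataset from a directory written by
    :func:`write_dataset` (the planted true probabilities are not persisted)."""
    src = Path(in_dir)
    raw_spec = yaml.safe_load((src / "spec.yaml").read_text())
    raw_spec["atoms_per_pocket"] = tuple(raw_spec.get("atoms_per_pocket", (10, 16)))
    spec = SyntheticSpec(**raw_spec)

    sm = pd.read_csv(src / "smiles.csv")
    drugs = [DrugRecord(drug_id=str(r.drug_id), smiles=str(r.smiles), motifs=frozenset())
             for r in sm.itertuples()]

    sites = sites_from_json_file(src / "sites.json")
    targets = []
    for tid in sorted(sites):
        pdb_path = src / "proteins" / f"{tid}.pdb"
        pdb_text = pdb_path.read_text() if pdb_path.exists() else ""
        res_names: list[str] = []
        if pdb_text:
            structure = read_structure(str(pdb_path))
            res_names = [r.get_resname() for r in structure.get_residues() if r.id[0] == " "]
        targets.append(TargetRecord(target_id=tid, pdb_text=pdb_text, motifs=frozenset(),
                                    sites=sites[tid], residue_names=res_names))

    edges = pd.read_csv(src / "edges.csv")
    drug_ids = [d.drug_id for d in drugs]
    target_ids = [t.target_id for t in targets]
    interactions = [(str(r.source_id), str(r.target_id))
                    for r in edges.itertuples() if r.edge_type == "interaction"]
    idx_d = {d: i for i, d in enumerate(drug_ids)}
    idx_t = {t: i for i, t in enumerate(target_ids)}
    dsim = np.zeros((len(drug_ids), len(drug_ids)))
    tsim = np.zeros((len(target_ids), len(target_ids)))
    for r in edges.itertuples():
        s, t, w = str(r.source_id), str(r.target_id), float(r.weight)
        if r.edge_type == "drug_similarity" and s in idx_d and t in idx_d:
            dsim[idx_d[s], idx_d[t]] = dsim[idx_d[t], idx_d[s]] = w
        elif r.edge_type == "target_similarity" and s in idx_t and t in idx_t:
            tsim[idx_t[s], idx_t[t]] = tsim[idx_t[t], idx_t[s]] = w
    graph = build_hetero_graph(interactions, drug_ids, target_ids, drug_sim=dsim,
                               target_sim=tsim, sim_threshold=0.0 + 1e-12)

    pr = pd.read_csv(src / "pairs.csv")
    pairs = [PairRecord(drug_id=str(r.drug_id), target_id=str(r.target_id), label=int(r.label))
             for r in pr.itertuples()]
    return SyntheticDataset(spec=spec, drugs=drugs, targets=targets, graph=graph,
                            pairs=pairs, true_prob=np.full(len(pairs), np.nan))
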