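"""Self-contained synthetic benchmark: toy drugs, pockets, network and labels.

The generator emulates the shape of a real interaction benchmark (SMILES
strings, PDB structures with ligand-marked pockets, a heterogeneous
drug/target network, labeled pairs) while planting a known interaction rule,
so that learnability is verifiable without downloads:

* every drug may carry up to two *token motifs* (marker heteroatoms S, P, N,
  O woven into an otherwise carbon/halogen SMILES);
* every pocket may carry up to two *element motifs* (marker atoms S, P, Se,
  Zn placed on marker residues inside the pocket), motif k on the pocket side
  pairing with motif k on the drug side;
* drugs and targets belong to latent communities; similarity edges
  concentrate within communities and also correlate with motif sharing, so
  the network branch carries real signal;
* the interaction probability is sigmoid(w_motif * |shared motifs| +
  w_net * same_community - bias); labels are Bernoulli draws, then flipped at
  the label-noise rate.

Three study conditions are provided: the default *mixed* spec (both signal
channels), a *network-signal* spec (w_motif = 0, labels carried by the graph
alone) and a *motif-position* spec, where a drug is reactive iff its two
marker nitrogens sit within a short token distance of each other and the
pocket carries the sulfur motif — a signal aimed at the relative-distance
pathway of the drug encoder.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bio_graph import HeteroGraph, build_hetero_graph
from .drug_encoder import DrugEmbeddingConfig, tokenize
from .evaluation import PairRecord
from .protein_encoder import BindingSiteGraph, ProteinConfig, extract_binding_sites, featurize_site, read_structure

__all__ = [
    "SyntheticSpec",
    "DrugRecord",
    "TargetRecord",
    "SyntheticDataset",
    "gen_drugs",
    "gen_pockets",
    "gen_network_and_labels",
    "generate_dataset",
]

N_MOTIFS = 4
_DRUG_MARKERS = ("S", "P", "N", "O")
_POCKET_MARKERS = ("S", "P", "SE", "ZN")
_MARKER_RESNAMES = ("MS0", "MS1", "MS2", "MS3")


@dataclass
class SyntheticSpec:
    """Study conditions of a synthetic benchmark.

    mode: 'mixed' (motif + network signal), 'network' (graph signal only) or
    'motif_position' (drug-internal token-distance signal gated by a pocket
    motif). Weights/bias parameterize the planted sigmoid rule; noise_rate is
    the label-flip probability.
    """

    n_drugs: int = 200
    n_targets: int = 50
    n_pairs: int = 2000
    grammar_depth: int = 2
    atoms_per_pocket: tuple[int, int] = (10, 16)  # residues per site, pre-featurization
    network_density: float = 0.6
    n_communities: int = 4
    motif_prob: float = 0.35
    w_motif: float = 6.0
    w_net: float = 6.0
    bias: float = 3.0
    noise_rate: float = 0.03
    mode: str = "mixed"
    max_smiles_len: int = 36
    position_threshold: int = 4  # motif_position mode: reactive iff N-N token distance <= this
    seed: int = 7

    @classmethod
    def default(cls) -> "SyntheticSpec":
        return cls()

    @classmethod
    def network_signal(cls, **kw) -> "SyntheticSpec":
        base = dict(mode="network", w_motif=0.0, w_net=6.0, bias=3.0,
                    n_drugs=150, n_targets=40, n_pairs=1000)
        base.update(kw)
        return cls(**base)

    @classmethod
    def motif_position(cls, **kw) -> "SyntheticSpec":
        base = dict(mode="motif_position", w_motif=6.0, w_net=0.0, bias=2.5,
                    n_drugs=150, n_targets=40, n_pairs=1000)
        base.update(kw)
        return cls(**base)

    def validate(self):
        if min(self.n_drugs, self.n_targets, self.n_pairs) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise rate must be in [0, 0.5)")


@dataclass
class DrugRecord:
    drug_id: str
    smiles: str
    motifs: frozenset[int]
    community: int = 0
    marker_distance: int | None = None  # motif_position mode: N-N token distance


@dataclass
class TargetRecord:
    target_id: str
    pdb_text: str
    motifs: frozenset[int]
    community: int = 0
    sites: list[BindingSiteGraph] = field(default_factory=list)
    residue_names: list[str] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    drugs: list[DrugRecord]
    targets: list[TargetRecord]
    graph: HeteroGraph
    pairs: list[PairRecord]
    true_prob: np.ndarray  # planted interaction probability per pair

    def drug_by_id(self) -> dict[str, DrugRecord]:
        return {d.drug_id: d for d in self.drugs}

    def target_by_id(self) -> dict[str, TargetRecord]:
        return {t.target_id: t for t in self.targets}


# ---------------------------------------------------------------------------
# drugs
# ---------------------------------------------------------------------------

def _base_chain(rng: np.random.Generator, depth: int, length: int) -> list[str]:
    """Branched carbon/halogen token chain; aromatic rings at depth >= 2."""
    tokens: list[str] = []
    n = 0
    while n < length:
        r = rng.random()
        if depth >= 2 and r < 0.08 and n + 8 <= length:
            tokens.extend(["c", "1", "c", "c", "c", "c", "c", "1"])
            n += 8
        elif r < 0.16 and n + 1 <= length:
            tokens.append(str(rng.choice(["F", "Cl", "Br"])))
            n += 1
        elif depth >= 1 and 0.16 <= r < 0.28 and n + 3 <= length:
            inner = _base_chain(rng, depth - 1, int(rng.integers(1, 4)))
            tokens.extend(["("] + inner + [")"])
            n += 2 + len(inner)
        else:
            tokens.append("C")
            n += 1
    return tokens


def _insert_markers(tokens: list[str], motifs: frozenset[int], rng: np.random.Generator) -> list[str]:
    out = list(tokens)
    for m in sorted(motifs):
        for _ in range(2):  # two marker atoms per motif for a robust signal
            # insert next to a chain carbon so the string stays chemically shaped
            slots = [i for i, t in enumerate(out) if t == "C"]
            pos = int(rng.choice(slots)) if slots else 0
            out.insert(pos, _DRUG_MARKERS[m])
    return out


def gen_drugs(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> list[DrugRecord]:
    """Grammar-generated SMILES carrying 0-2 planted token motifs each; every
    string tokenizes against the package vocabulary."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    cfg = DrugEmbeddingConfig(max_len=spec.max_smiles_len)
    out: list[DrugRecord] = []
    for i in range(spec.n_drugs):
        if spec.mode == "motif_position":
            # Four nitrogens in a carbon chain. A drug is "reactive" iff some
            # pair of them sits within position_threshold tokens; otherwise
            # all pairs are kept >= 6 apart. The distractors force a genuinely
            # pairwise-distance computation rather than mere N detection.
            length = int(rng.integers(26, min(35, spec.max_smiles_len - 1) + 1))
            tokens = ["C"] * length
            close = bool(rng.random() < 0.5)
            thr = spec.position_threshold
            while True:
                pos = np.sort(rng.choice(length, size=4, replace=False))
                gaps = np.sort(np.diff(pos))
                if close and gaps[0] >= 2 and gaps[0] <= thr and gaps[1] >= 6:
                    break  # exactly one close pair, the rest well separated
                if not close and gaps[0] >= 6:
                    break
            dist = int(np.diff(pos).min())
            for p in pos:
                tokens[int(p)] = "N"
            rec = DrugRecord(drug_id=f"D{i:04d}", smiles="".join(tokens),
                             motifs=frozenset(), marker_distance=dist)
        else:
            length = int(rng.integers(8, 20))
            tokens = _base_chain(rng, spec.grammar_depth, length)
            motifs = frozenset(m for m in range(N_MOTIFS) if rng.random() < spec.motif_prob)
            if len(motifs) > 2:
                motifs = frozenset(sorted(motifs)[:2])
            tokens = _insert_markers(tokens, motifs, rng)
            rec = DrugRecord(drug_id=f"D{i:04d}", smiles="".join(tokens)[: spec.max_smiles_len],
                             motifs=motifs)
        tokenize(rec.smiles, cfg)  # generation contract: always accepted
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# pockets
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial: int, name: str, resname: str, chain: str, resseq: int,
                   xyz: np.ndarray, element: str, hetatm: bool = False,
                   occ: float = 1.0, bfac: float = 20.0) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    if len(element) == 1:
        name_f = f" {name:<3s}"
    else:
        name_f = f"{name:<4s}"
    return (f"{record}{serial:>5d} {name_f} {resname:<3s} {chain}{resseq:>4d}    "
            f"{xyz[0]:>8.3f}{xyz[1]:>8.3f}{xyz[2]:>8.3f}{occ:>6.2f}{bfac:>6.2f}"
            f"          {element:>2s}")


def _rotation(axis_angle: float) -> np.ndarray:
    c, s = np.cos(axis_angle), np.sin(axis_angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_pocket_pdb(motifs: frozenset[int], n_residues: int, n_sites: int,
                     rng: np.random.Generator) -> tuple[str, list[str]]:
    """Emit PDB text for a peptide-like chain with marker residues and one
    HETATM ligand per site. Backbone bond lengths sit in 1.2-1.6 A; the
    ligands let the proximity rule recover the sites."""
    lines: list[str] = []
    serial = 1
    resnames: list[str] = []
    # marker residues: two per motif, seated mid-stretch so each falls inside
    # the proximity neighborhood of its stretch's ligand
    marker_slots: dict[int, int] = {}
    stretch = max(1, n_residues // n_sites)
    preferred = []
    for s in range(n_sites):
        mid = min(s * stretch + stretch // 2, n_residues - 1)
        preferred.extend([mid, max(mid - 1, 0), min(mid + 1, n_residues - 1)])
    preferred.extend(int(x) for x in rng.permutation(n_residues))
    slots = list(dict.fromkeys(preferred))  # unique, preference-ordered
    for k, m in enumerate(sorted(motifs)):
        for rep in range(2):
            marker_slots[slots[(2 * k + rep) % len(slots)]] = m

    direction = np.array([1.0, 0.0, 0.0])
    turn = _rotation(0.35)
    lift = np.array([0.0, 0.0, 0.75])  # pitch separates helix turns beyond the contact cutoff
    pos = np.zeros(3)
    ca_coords = []
    atoms_per_res: list[list[tuple[str, np.ndarray, str]]] = []
    for i in range(n_residues):
        m = marker_slots.get(i)
        resname = "GLY" if m is None else _MARKER_RESNAMES[m]
        resnames.append(resname)
        n_pos = pos + 1.33 * direction
        perp = np.cross(direction, [0.0, 0.0, 1.0])
        perp = perp / (np.linalg.norm(perp) + 1e-12)
        ca_pos = n_pos + 1.46 * (0.8 * direction + 0.6 * perp) / np.linalg.norm(0.8 * direction + 0.6 * perp)
        c_pos = ca_pos + 1.52 * (0.8 * direction - 0.6 * perp) / np.linalg.norm(0.8 * direction - 0.6 * perp)
        o_pos = c_pos + 1.23 * np.array([0.0, 0.0, 1.0])
        res_atoms = [("N", n_pos, "N"), ("CA", ca_pos, "C"), ("C", c_pos, "C"), ("O", o_pos, "O")]
        if m is not None:
            radial = np.array([ca_pos[0], ca_pos[1], 0.0])
            nrm = np.linalg.norm(radial)
            outward = radial / nrm if nrm > 1e-6 else np.array([0.0, 1.0, 0.0])
            side = ca_pos + (1.85 if m < 2 else 2.1) * outward  # points away from the helix
            el = _POCKET_MARKERS[m]
            res_atoms.append((el, side, el))
        atoms_per_res.append(res_atoms)
        ca_coords.append(ca_pos)
        pos = c_pos
        direction = turn @ direction
        pos = pos + lift

    for i, res_atoms in enumerate(atoms_per_res):
        for name, xyz, el in res_atoms:
            lines.append(_pdb_atom_line(serial, name, resnames[i], "A", i + 1, xyz, el))
            serial += 1

    ca_coords = np.array(ca_coords)
    # one ligand per site, anchored at the stretch midpoint where the marker
    # residues sit, so proximity extraction and centroid truncation keep them
    for s in range(n_sites):
        mid = min(s * stretch + stretch // 2, n_residues - 1)
        center = ca_coords[mid] + np.array([0.0, 2.8, 0.6])
        for k in range(3):
            lines.append(_pdb_atom_line(serial, f"C{k + 1}", "LIG", "L", 900 + s,
                                        center + np.array([1.4 * k, 0.0, 0.0]), "C", hetatm=True))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n", resnames


def gen_pockets(spec: SyntheticSpec, rng: np.random.Generator | None = None,
                protein_config: ProteinConfig | None = None) -> list[TargetRecord]:
    """Synthetic proteins: PDB text plus binding-site graphs recovered by the
    real extraction + featurization pipeline (ligand-proximity rule)."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed + 1)
    pc = protein_config or ProteinConfig(max_sites=3, max_atoms_per_site=60, ligand_cutoff=8.0)
    out: list[TargetRecord] = []
    for i in range(spec.n_targets):
        if spec.mode == "motif_position":
            motifs = frozenset([0]) if rng.random() < 0.5 else frozenset()
        else:
            motifs = frozenset(m for m in range(N_MOTIFS) if rng.random() < spec.motif_prob)
            if len(motifs) > 2:
                motifs = frozenset(sorted(motifs)[:2])
        lo, hi = spec.atoms_per_pocket
        n_res = int(rng.integers(lo, hi + 1))
        n_sites = int(rng.integers(1, 3))
        pdb_text, resnames = build_pocket_pdb(motifs, n_res, n_sites, rng)
        structure = read_structure(io.StringIO(pdb_text), name=f"T{i:03d}")
        sites = extract_binding_sites(structure, config=pc)
        graphs = [featurize_site(s.heavy_atoms(), site_index=s.site_index,
                                 max_atoms=pc.max_atoms_per_site) for s in sites]
        out.append(TargetRecord(target_id=f"T{i:03d}", pdb_text=pdb_text, motifs=motifs,
                                sites=graphs, residue_names=resnames))
    return out


# ---------------------------------------------------------------------------
# network and labels
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _similarity_matrix(items, rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    n = len(items)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = items[i], items[j]
            inter = len(a.motifs & b.motifs)
            union = len(a.motifs | b.motifs)
            jac = inter / union if union else 0.0
            s = 0.25 * jac + 0.55 * (a.community == b.community) + rng.normal(0.0, 0.08)
            if rng.random() > spec.network_density:
                s = 0.0
            sim[i, j] = sim[j, i] = float(np.clip(s, 0.0, 1.0))
    return sim


def gen_network_and_labels(
    spec: SyntheticSpec,
    drugs: list[DrugRecord],
    targets: list[TargetRecord],
    rng: np.random.Generator | None = None,
) -> tuple[HeteroGraph, list[PairRecord], np.ndarray]:
    """Assign communities, build similarity matrices, sample labeled pairs
    from the planted rule and assemble the heterogeneous graph (whose
    interaction edges are the positive pairs)."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed + 2)
    for d in drugs:
        d.community = int(rng.integers(spec.n_communities))
    for t in targets:
        t.community = int(rng.integers(spec.n_communities))

    drug_sim = _similarity_matrix(drugs, rng, spec)
    target_sim = _similarity_matrix(targets, rng, spec)

    n_possible = len(drugs) * len(targets)
    n_pairs = min(spec.n_pairs, n_possible)
    flat = rng.choice(n_possible, size=n_pairs, replace=False)
    pair_idx = [(int(f) // len(targets), int(f) % len(targets)) for f in flat]

    def planted_logit(d: DrugRecord, t: TargetRecord) -> float:
        if spec.mode == "motif_position":
            close = d.marker_distance is not None and d.marker_distance <= spec.position_threshold
            return spec.w_motif * float(close and 0 in t.motifs) - spec.bias
        match = len(d.motifs & t.motifs)
        same = float(d.community == t.community)
        return spec.w_motif * match + spec.w_net * same - spec.bias

    bias_shift = 0.0
    for _ in range(8):
        probs = np.array([_sigmoid(planted_logit(drugs[i], targets[j]) + bias_shift)
                          for i, j in pair_idx])
        labels = (rng.random(n_pairs) < probs).astype(int)
        flip = rng.random(n_pairs) < spec.noise_rate
        labels = np.where(flip, 1 - labels, labels)
        if 0 < labels.sum() < n_pairs:
            break
        bias_shift += -1.0 if labels.sum() == 0 else 1.0
        warnings.warn(f"degenerate label draw; adjusting rule bias by {bias_shift:+.1f}")

    pairs = [PairRecord(drug_id=drugs[i].drug_id, target_id=targets[j].target_id,
                        label=int(y)) for (i, j), y in zip(pair_idx, labels)]
    positives = [(p.drug_id, p.target_id) for p in pairs if p.label == 1]
    graph = build_hetero_graph(
        interactions=positives,
        drug_ids=[d.drug_id for d in drugs],
        target_ids=[t.target_id for t in targets],
        drug_sim=drug_sim,
        target_sim=target_sim,
        sim_threshold=0.5,
        profile_width=16,
    )
    return graph, pairs, probs


def generate_dataset(spec: SyntheticSpec,
                     protein_config: ProteinConfig | None = None) -> SyntheticDataset:
    """End-to-end synthetic benchmark, reproducible from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    drugs = gen_drugs(spec, np.random.default_rng(spec.seed))
    targets = gen_pockets(spec, np.random.default_rng(spec.seed + 1), protein_config)
    graph, pairs, probs = gen_network_and_labels(spec, drugs, targets,
                                                 np.random.default_rng(spec.seed + 2))
    return SyntheticDataset(spec=spec, drugs=drugs, targets=targets, graph=graph,
                            pairs=pairs, true_prob=probs)
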