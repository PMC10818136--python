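"""Protein branch input: binding-site extraction and pocket-graph featurization.

A target protein enters as a 3D structure (PDB). Binding sites are turned into
peptide fragments — maximal runs of consecutive residues whose C-alpha falls
inside a user-supplied bounding box, or (fallback) within a distance cutoff of
a bound HETATM ligand. Each site becomes an atom graph: heavy atoms are nodes
carrying a fixed 38-dimensional feature schema, and edges are covalent
(distance below an element-pair covalent threshold) or spatial contacts
(<= 4.5 A). All sites of a protein are flattened into one token sequence for
the transformer, with the union adjacency carried alongside as an attention
bias; a site id per token records provenance.

Precomputed site graphs can bypass PDB parsing entirely through a portable
JSON dialect (see :func:`site_from_json`).
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from scipy.spatial.distance import cdist

__all__ = [
    "AtomRecord",
    "BindingSiteGraph",
    "BindingSite",
    "ProteinInputEmbedding",
    "ProteinConfig",
    "read_structure",
    "extract_binding_sites",
    "featurize_site",
    "embed_protein",
    "site_to_json",
    "site_from_json",
]

CONTACT_CUTOFF = 4.5  # Angstrom, spatial-contact edge threshold
COVALENT_TOLERANCE = 1.3  # multiplier on summed covalent radii

# single-bond covalent radii in Angstrom (Cordero et al. values, rounded)
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
    "ZN": 1.22, "FE": 1.32, "MG": 1.41, "CA": 1.76, "MN": 1.39, "NA": 1.66, "K": 2.03,
}
_DEFAULT_RADIUS = 1.0

_ELEMENTS = ("C", "N", "O", "S", "P", "F", "CL", "BR", "I", "SE")  # + metal + OTHER
_METALS = frozenset({"ZN", "FE", "MG", "MN", "CA", "NA", "K", "CU", "NI", "CO"})
_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})
_AROMATIC_RING_ELEMENTS = frozenset({"C", "N", "O", "S"})

K_FEAT = 38  # length of the per-atom feature schema below


@dataclass
class ProteinConfig:
    """Limits of the protein branch.

    max_sites: most binding sites kept per protein (ranked by atom count).
    max_atoms_per_site: per-site atom cap, nearest-to-centroid first.
    max_tokens: cap on the concatenated token sequence over all sites.
    ligand_cutoff: C-alpha-to-ligand distance (A) for the proximity fallback.
    """

    max_sites: int = 3
    max_atoms_per_site: int = 60
    max_tokens: int = 1200
    ligand_cutoff: float = 8.0


@dataclass
class AtomRecord:
    element: str
    x: float
    y: float
    z: float
    name: str = ""
    formal_charge: int = 0
    bfactor: float = 0.0
    occupancy: float = 1.0
    is_backbone: bool = False

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class BindingSiteGraph:
    """Atom graph of one binding site with featurized nodes."""

    atoms: list[AtomRecord]
    features: np.ndarray  # (n, K_FEAT)
    edges: list[tuple[int, int, str]]  # undirected, i < j, kind in {covalent, contact}
    site_index: int = 0

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self, kinds: tuple[str, ...] = ("covalent", "contact")) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms), dtype=bool)
        for i, j, kind in self.edges:
            if kind in kinds:
                a[i, j] = a[j, i] = True
        return a


@dataclass
class BindingSite:
    """Peptide fragments (runs of consecutive residues) forming one site."""

    fragments: list[list]  # list of runs of Bio.PDB Residue objects
    site_index: int = 0

    @property
    def residues(self) -> list:
        return [r for frag in self.fragments for r in frag]

    def heavy_atoms(self) -> list[AtomRecord]:
        out = []
        for res in self.residues:
            for atom in res.get_atoms():
                el = (atom.element or "").strip().upper()
                if el == "H":
                    continue
                x, y, z = atom.coord
                out.append(AtomRecord(
                    element=el or "C", x=float(x), y=float(y), z=float(z),
                    name=atom.get_name(),
                    bfactor=float(atom.get_bfactor() or 0.0),
                    occupancy=float(atom.get_occupancy() if atom.get_occupancy() is not None else 1.0),
                    is_backbone=atom.get_name() in _BACKBONE_NAMES,
                ))
        return out


@dataclass
class ProteinInputEmbedding:
    """All sites of one protein flattened into a single token sequence."""

    tokens: np.ndarray  # (n_tot, d_p) projected features
    features: np.ndarray  # (n_tot, K_FEAT) raw features
    site_ids: np.ndarray  # (n_tot,)
    adjacency: np.ndarray  # (n_tot, n_tot) bool, union over sites (block diagonal)
    site_count: int = 0


# ---------------------------------------------------------------------------
# structure reading
# ---------------------------------------------------------------------------

def read_structure(source, name: str = "protein"):
    """Parse a PDB file (path or file-like). Rejects structures without any
    standard residue; malformed records raise ValueError."""
    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        if hasattr(source, "read"):
            structure = parser.get_structure(name, source)
        else:
            structure = parser.get_structure(name, str(source))
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"malformed PDB input: {exc}") from exc
    n_std = sum(1 for res in structure.get_residues() if res.id[0] == " ")
    if n_std == 0:
        raise ValueError("structure contains no standard residues (only HETATM/water records)")
    return structure


def read_structure_from_text(text: str, name: str = "protein"):
    return read_structure(io.StringIO(text), name=name)


def ligand_atoms(structure) -> list:
    """HETATM atoms excluding waters."""
    out = []
    for res in structure.get_residues():
        hetflag = res.id[0]
        if hetflag != " " and hetflag != "W":
            out.extend(res.get_atoms())
    return out


# ---------------------------------------------------------------------------
# binding-site extraction
# ---------------------------------------------------------------------------

def _fragments_from_residues(residues: list) -> list[list]:
    """Group residues into maximal runs of consecutive numbering.

    Runs break across chains and on insertion codes.
    """
    keyed = []
    for res in residues:
        chain = res.get_parent().id
        _, resseq, icode = res.id
        keyed.append(((chain, resseq, icode), res))
    keyed.sort(key=lambda kr: (kr[0][0], kr[0][1], kr[0][2]))
    fragments: list[list] = []
    prev = None
    for (chain, resseq, icode), res in keyed:
        contiguous = (
            prev is not None
            and chain == prev[0]
            and resseq == prev[1] + 1
            and icode == " " == prev[2]
        )
        if contiguous:
            fragments[-1].append(res)
        else:
            fragments.append([res])
        prev = (chain, resseq, icode)
    return fragments


def _ca_coord(res):
    if "CA" in res:
        return res["CA"].coord
    return None


def extract_binding_sites(structure, boxes: list | None = None,
                          config: ProteinConfig | None = None) -> list[BindingSite]:
    """Select binding-site residues and group them into peptide fragments.

    With explicit ``boxes`` (each (xmin, ymin, zmin, xmax, ymax, zmax)), a
    residue belongs to a box iff its C-alpha lies inside; each box yields one
    site. Without boxes, every non-water HETATM residue acts as a ligand and
    residues whose C-alpha is within ``config.ligand_cutoff`` A of any of its
    atoms form one site. At most ``config.max_sites`` sites are kept, ranked
    by atom count. An empty result is a warning, not an error.
    """
    config = config or ProteinConfig()
    std_residues = [r for r in structure.get_residues() if r.id[0] == " "]
    groups: list[list] = []
    if boxes is not None:
        for box in boxes:
            xmin, ymin, zmin, xmax, ymax, zmax = box
            sel = []
            for res in std_residues:
                ca = _ca_coord(res)
                if ca is None:
                    continue
                if xmin <= ca[0] <= xmax and ymin <= ca[1] <= ymax and zmin <= ca[2] <= zmax:
                    sel.append(res)
            if sel:
                groups.append(sel)
    else:
        lig_residues = [res for res in structure.get_residues()
                        if res.id[0] not in (" ", "W")]
        for lig in lig_residues:
            lig_xyz = np.array([a.coord for a in lig.get_atoms()])
            sel = []
            for res in std_residues:
                ca = _ca_coord(res)
                if ca is None:
                    continue
                if cdist(ca[None, :], lig_xyz).min() <= config.ligand_cutoff:
                    sel.append(res)
            if sel:
                groups.append(sel)
    if not groups:
        warnings.warn("no residues fell inside any binding-site box or ligand neighborhood")
        return []
    sites = [BindingSite(fragments=_fragments_from_residues(g)) for g in groups]
    sites.sort(key=lambda s: -sum(1 for res in s.residues for _ in res.get_atoms()))
    sites = sites[: config.max_sites]
    for k, s in enumerate(sites):
        s.site_index = k
    return sites


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def _element_channel(element: str) -> int:
    el = element.strip().upper()
    if el in _ELEMENTS:
        return _ELEMENTS.index(el)
    if el in _METALS:
        return 10  # metal channel
    return 11  # OTHER


def _covalent_threshold(el_a: str, el_b: str) -> float:
    ra = _COVALENT_RADII.get(el_a.upper(), _DEFAULT_RADIUS)
    rb = _COVALENT_RADII.get(el_b.upper(), _DEFAULT_RADIUS)
    return COVALENT_TOLERANCE * (ra + rb)


def _ring_flags(n: int, covalent: list[tuple[int, int]]) -> np.ndarray:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(covalent)
    in_ring = np.zeros(n, dtype=bool)
    for cycle in nx.cycle_basis(g):
        for i in cycle:
            in_ring[i] = True
    return in_ring


def featurize_site(atoms: list[AtomRecord], site_index: int = 0,
                   max_atoms: int | None = None) -> BindingSiteGraph:
    """Build the atom graph and the 38-dim node feature matrix for one site.

    Feature schema (fixed order, length 38): element one-hot over
    {C,N,O,S,P,F,Cl,Br,I,Se,metal,OTHER} (12) | degree one-hot 0-5 (6) |
    formal charge clipped to [-2,2] one-hot (5) | attached-H one-hot 0-4 (5) |
    aromatic flag (1) | ring flag (1) | hybridization one-hot
    {sp,sp2,sp3,other} (4) | backbone flag (1) | B-factor/100 (1) |
    occupancy (1) | normalized centroid distance (1).

    Hydrogens are not graph nodes; they are counted into the attached-H
    channel of their nearest covalently bonded heavy atom. Aromaticity and
    hybridization are geometric heuristics (ring membership of 5/6-cycles of
    C/N/O/S; neighbor counts), since a coordinate file carries no bond orders.
    """
    if not atoms:
        raise ValueError("cannot featurize an empty fragment")
    hydrogens = [a for a in atoms if a.element.upper() == "H"]
    heavy = [a for a in atoms if a.element.upper() != "H"]
    if not heavy:
        raise ValueError("fragment contains no heavy atoms")
    xyz = np.array([[a.x, a.y, a.z] for a in heavy], dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("non-finite atom coordinates")
    if len(heavy) > 1 and float(cdist(xyz, xyz).max()) == 0.0:
        raise ValueError("all atom coordinates coincide")

    centroid = xyz.mean(axis=0)
    if max_atoms is not None and len(heavy) > max_atoms:
        order = np.argsort(np.linalg.norm(xyz - centroid, axis=1), kind="stable")
        keep = np.sort(order[:max_atoms])
        heavy = [heavy[i] for i in keep]
        xyz = xyz[keep]
        centroid = xyz.mean(axis=0)

    n = len(heavy)
    dist = cdist(xyz, xyz)
    covalent: list[tuple[int, int]] = []
    contact: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= _covalent_threshold(heavy[i].element, heavy[j].element):
                covalent.append((i, j))
            elif dist[i, j] <= CONTACT_CUTOFF:
                contact.append((i, j))

    degree = np.zeros(n, dtype=int)
    for i, j in covalent:
        degree[i] += 1
        degree[j] += 1

    attached_h = np.zeros(n, dtype=int)
    if hydrogens:
        h_xyz = np.array([[a.x, a.y, a.z] for a in hydrogens])
        dh = cdist(h_xyz, xyz)
        for hi in range(len(hydrogens)):
            j = int(np.argmin(dh[hi]))
            if dh[hi, j] <= _covalent_threshold("H", heavy[j].element):
                attached_h[j] += 1

    in_ring = _ring_flags(n, covalent)
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(covalent)
    aromatic = np.zeros(n, dtype=bool)
    for cycle in nx.cycle_basis(g):
        if len(cycle) in (5, 6) and all(heavy[i].element.upper() in _AROMATIC_RING_ELEMENTS for i in cycle):
            for i in cycle:
                aromatic[i] = True

    feats = np.zeros((n, K_FEAT))
    cdists = np.linalg.norm(xyz - centroid, axis=1)
    for i, a in enumerate(heavy):
        col = 0
        feats[i, _element_channel(a.element)] = 1.0
        col += 12
        feats[i, col + min(degree[i], 5)] = 1.0
        col += 6
        feats[i, col + int(np.clip(a.formal_charge, -2, 2)) + 2] = 1.0
        col += 5
        feats[i, col + min(attached_h[i], 4)] = 1.0
        col += 5
        feats[i, col] = float(aromatic[i])
        feats[i, col + 1] = float(in_ring[i])
        col += 2
        nb = degree[i] + attached_h[i]
        hyb = {2: 0, 3: 1, 4: 2}.get(nb, 3) if nb >= 2 else 3  # sp, sp2, sp3, other
        feats[i, col + hyb] = 1.0
        col += 4
        feats[i, col] = float(a.is_backbone)
        feats[i, col + 1] = float(np.clip(a.bfactor / 100.0, 0.0, 1.0))
        feats[i, col + 2] = float(np.clip(a.occupancy, 0.0, 1.0))
        feats[i, col + 3] = float(np.clip(cdists[i] / 10.0, 0.0, 1.0))

    edges = [(i, j, "covalent") for i, j in covalent] + [(i, j, "contact") for i, j in contact]
    return BindingSiteGraph(atoms=heavy, features=feats, edges=edges, site_index=site_index)


# ---------------------------------------------------------------------------
# dense input embedding
# ---------------------------------------------------------------------------

def embed_protein(graphs: list[BindingSiteGraph], W_P: np.ndarray,
                  max_tokens: int = 1200) -> ProteinInputEmbedding:
    """Project every site's node features with W_P (d_p x K_FEAT) and
    concatenate all sites into one token sequence (capped at max_tokens),
    carrying per-token site ids and the block-diagonal union adjacency."""
    if not graphs or sum(g.n_atoms for g in graphs) == 0:
        raise ValueError("no atoms to embed")
    if W_P.shape[1] != K_FEAT:
        raise ValueError(f"W_P expects {W_P.shape[1]} features, schema has {K_FEAT}")
    feats, sids, blocks = [], [], []
    total = 0
    for g in graphs:
        take = min(g.n_atoms, max_tokens - total)
        if take <= 0:
            break
        feats.append(g.features[:take])
        sids.append(np.full(take, g.site_index))
        blocks.append(g.adjacency()[:take, :take])
        total += take
    x = np.concatenate(feats, axis=0)
    site_ids = np.concatenate(sids)
    adj = np.zeros((total, total), dtype=bool)
    ofs = 0
    for b in blocks:
        k = b.shape[0]
        adj[ofs : ofs + k, ofs : ofs + k] = b
        ofs += k
    tokens = x @ W_P.T
    return ProteinInputEmbedding(tokens=tokens, features=x, site_ids=site_ids,
                                 adjacency=adj, site_count=len(blocks))


# ---------------------------------------------------------------------------
# portable JSON site dialect
# ---------------------------------------------------------------------------

def site_to_json(graph: BindingSiteGraph) -> dict:
    return {
        "site_index": graph.site_index,
        "atoms": [
            {
                "element": a.element, "x": a.x, "y": a.y, "z": a.z,
                "name": a.name, "charge": a.formal_charge,
                "bfactor": a.bfactor, "occupancy": a.occupancy,
                "is_backbone": a.is_backbone,
            }
            for a in graph.atoms
        ],
        "edges": [[i, j, kind] for i, j, kind in graph.edges],
    }


def site_from_json(obj: dict, recompute_edges: bool = False,
                   max_atoms: int | None = None) -> BindingSiteGraph:
    """Load a site from the portable JSON dialect. Features are always
    recomputed from the atom records; stored edges are kept unless
    ``recompute_edges`` (or absent), in which case the distance rules apply."""
    atoms = [
        AtomRecord(
            element=a["element"], x=float(a["x"]), y=float(a["y"]), z=float(a["z"]),
            name=a.get("name", ""), formal_charge=int(a.get("charge", 0)),
            bfactor=float(a.get("bfactor", 0.0)), occupancy=float(a.get("occupancy", 1.0)),
            is_backbone=bool(a.get("is_backbone", False)),
        )
        for a in obj["atoms"]
    ]
    graph = featurize_site(atoms, site_index=int(obj.get("site_index", 0)), max_atoms=max_atoms)
    if not recompute_edges and obj.get("edges") and max_atoms is None:
        graph.edges = [(int(i), int(j), str(k)) for i, j, k in obj["edges"]]
    return graph


def sites_to_json_file(graphs_by_target: dict[str, list[BindingSiteGraph]], path) -> None:
    payload = {tid: [site_to_json(g) for g in gs] for tid, gs in graphs_by_target.items()}
    with open(path, "w") as f:
        json.dump(payload, f)


def sites_from_json_file(path, max_atoms: int | None = None) -> dict[str, list[BindingSiteGraph]]:
    with open(path) as f:
        payload = json.load(f)
    return {tid: [site_from_json(o, max_atoms=max_atoms) for o in objs] for tid, objs in payload.items()}
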