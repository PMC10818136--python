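"""Binding-site extraction and pocket-graph featurization."""

import io

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from sagdti.protein_encoder import (
    AtomRecord,
    K_FEAT,
    ProteinConfig,
    embed_protein,
    extract_binding_sites,
    featurize_site,
    read_structure,
    site_from_json,
    site_to_json,
)


def _atom_line(serial, name, resname, chain, resseq, x, y, z, element, hetatm=False):
    rec = "HETATM" if hetatm else "ATOM  "
    name_f = f" {name:<3s}" if len(element) == 1 else f"{name:<4s}"
    return (f"{rec}{serial:>5d} {name_f} {resname:<3s} {chain}{resseq:>4d}    "
            f"{x:>8.3f}{y:>8.3f}{z:>8.3f}{1.00:>6.2f}{20.00:>6.2f}          {element:>2s}")


def _make_pdb(residues, het=(), chain="A"):
    """residues: list of (resseq, [(name, x, y, z, element), ...])."""
    lines, serial = [], 1
    for resseq, atoms in residues:
        ch = chain if not isinstance(resseq, tuple) else resseq[0]
        rs = resseq if not isinstance(resseq, tuple) else resseq[1]
        for name, x, y, z, el in atoms:
            lines.append(_atom_line(serial, name, "GLY", ch, rs, x, y, z, el))
            serial += 1
    for name, x, y, z, el in het:
        lines.append(_atom_line(serial, name, "LIG", "L", 900, x, y, z, el, hetatm=True))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _simple_residue(resseq, x0):
    return (resseq, [("N", x0, 0.0, 0.0, "N"), ("CA", x0 + 1.4, 0.5, 0.0, "C"),
                     ("C", x0 + 2.8, 0.0, 0.0, "C"), ("O", x0 + 2.8, 1.2, 0.0, "O")])


class TestReadStructure:
    def test_three_residue_fixture_roundtrip(self):
        text = _make_pdb([_simple_residue(i, 4.0 * i) for i in range(1, 4)])
        s = read_structure(io.StringIO(text))
        residues = [r for r in s.get_residues() if r.id[0] == " "]
        assert len(residues) == 3
        assert all(len(list(r.get_atoms())) == 4 for r in residues)

    def test_hetatm_only_rejected(self):
        text = _make_pdb([], het=[("C1", 0, 0, 0, "C")])
        with pytest.raises(ValueError, match="no standard residues"):
            read_structure(io.StringIO(text))

    def test_two_chains_enumerated(self):
        text = _make_pdb([_simple_residue(("A", 1), 0.0), _simple_residue(("B", 1), 50.0)])
        s = read_structure(io.StringIO(text))
        assert sorted(c.id for c in s.get_chains()) == ["A", "B"]

    def test_malformed_input_raises(self):
        with pytest.raises(ValueError, match="malformed|no standard"):
            read_structure(io.StringIO("ATOM this is not a pdb\nEND\n"))


class TestExtractBindingSites:
    def test_box_yields_fragments_of_consecutive_residues(self):
        residues = [_simple_residue(i, 4.0 * i) for i in (10, 11, 12, 13, 14, 20, 21)]
        text = _make_pdb(residues)
        s = read_structure(io.StringIO(text))
        # every CA x-coordinate is 4*resseq + 1.4; one box covering all
        sites = extract_binding_sites(s, boxes=[(-1e6, -1e6, -1e6, 1e6, 1e6, 1e6)])
        assert len(sites) == 1
        runs = [[r.id[1] for r in frag] for frag in sites[0].fragments]
        assert runs == [[10, 11, 12, 13, 14], [20, 21]]

    def test_empty_box_warns_and_returns_nothing(self):
        text = _make_pdb([_simple_residue(1, 0.0)])
        s = read_structure(io.StringIO(text))
        with pytest.warns(UserWarning, match="no residues"):
            assert extract_binding_sites(s, boxes=[(100, 100, 100, 200, 200, 200)]) == []

    def test_ligand_proximity_matches_brute_force_distance_scan(self):
        rng = np.random.default_rng(42)
        residues = []
        cas = []
        for i in range(1, 21):
            x, y, z = rng.uniform(-12, 12, 3)
            residues.append((i, [("CA", x, y, z, "C")]))
            cas.append((i, np.array([x, y, z])))
        text = _make_pdb(residues, het=[("C1", 0.0, 0.0, 0.0, "C")])
        s = read_structure(io.StringIO(text))
        sites = extract_binding_sites(s, config=ProteinConfig(ligand_cutoff=8.0))
        got = sorted(r.id[1] for r in sites[0].residues) if sites else []
        want = sorted(i for i, ca in cas if np.linalg.norm(ca) <= 8.0)
        assert got == want

    def test_extraction_deterministic(self):
        residues = [_simple_residue(i, 4.0 * i) for i in range(1, 8)]
        text = _make_pdb(residues, het=[("C1", 10.0, 0.0, 0.0, "C")])
        s1 = read_structure(io.StringIO(text))
        s2 = read_structure(io.StringIO(text))
        r1 = [[r.id[1] for r in f] for st in extract_binding_sites(s1) for f in st.fragments]
        r2 = [[r.id[1] for r in f] for st in extract_binding_sites(s2) for f in st.fragments]
        assert r1 == r2


class TestFeaturizeSite:
    def test_single_carbon(self):
        g = featurize_site([AtomRecord("C", 0, 0, 0)])
        assert g.n_atoms == 1 and g.edges == []
        f = g.features[0]
        assert f[0] == 1.0  # C one-hot
        assert f[12] == 1.0  # degree 0
        assert len(f) == K_FEAT

    @pytest.mark.parametrize("d,kind", [(1.5, "covalent"), (4.0, "contact"), (5.0, None)])
    def test_distance_thresholds(self, d, kind):
        g = featurize_site([AtomRecord("C", 0, 0, 0), AtomRecord("C", d, 0, 0)])
        kinds = [k for _, _, k in g.edges]
        assert kinds == ([kind] if kind else [])

    def test_edges_match_pairwise_distance_oracle(self, rng):
        atoms = [AtomRecord("C", *xyz) for xyz in rng.uniform(0, 8, (10, 3))]
        g = featurize_site(atoms)
        xyz = np.array([[a.x, a.y, a.z] for a in atoms])
        d = cdist(xyz, xyz)
        want = set()
        for i in range(10):
            for j in range(i + 1, 10):
                if d[i, j] <= 1.3 * (0.76 + 0.76):
                    want.add((i, j, "covalent"))
                elif d[i, j] <= 4.5:
                    want.add((i, j, "contact"))
        assert set(g.edges) == want

    def test_edge_symmetry_and_no_self_loops(self, rng):
        atoms = [AtomRecord("N", *xyz) for xyz in rng.uniform(0, 6, (8, 3))]
        g = featurize_site(atoms)
        adj = g.adjacency()
        assert np.array_equal(adj, adj.T)
        assert not adj.diagonal().any()

    def test_coincident_coordinates_rejected(self):
        atoms = [AtomRecord("C", 1, 1, 1), AtomRecord("O", 1, 1, 1)]
        with pytest.raises(ValueError, match="coincide"):
            featurize_site(atoms)

    def test_unknown_element_goes_to_other_channel(self):
        g = featurize_site([AtomRecord("XX", 0, 0, 0)])
        assert g.features[0, 11] == 1.0

    def test_truncation_monotone_in_max_atoms(self, rng):
        atoms = [AtomRecord("C", *xyz) for xyz in rng.uniform(0, 10, (12, 3))]
        sizes = [featurize_site(atoms, max_atoms=k).n_atoms for k in (4, 8, 12)]
        assert sizes == [4, 8, 12]

    def test_hydrogens_counted_not_nodes(self):
        atoms = [AtomRecord("C", 0, 0, 0), AtomRecord("H", 1.0, 0, 0), AtomRecord("H", -1.0, 0, 0)]
        g = featurize_site(atoms)
        assert g.n_atoms == 1
        assert g.features[0, 23 + 2] == 1.0  # attached-H == 2 one-hot


class TestEmbedProtein:
    def test_identity_projection_returns_raw_features(self, rng):
        atoms = [AtomRecord("C", *xyz) for xyz in rng.uniform(0, 5, (4, 3))]
        g = featurize_site(atoms)
        out = embed_protein([g], np.eye(K_FEAT))
        assert np.allclose(out.tokens, g.features)

    def test_two_sites_concatenated_with_site_ids(self, rng):
        gs = []
        for s in range(2):
            atoms = [AtomRecord("C", *xyz) for xyz in rng.uniform(0, 5, (3, 3)) + 20 * s]
            gs.append(featurize_site(atoms, site_index=s))
        out = embed_protein(gs, np.eye(K_FEAT))
        assert out.tokens.shape[0] == 6
        assert out.site_ids.tolist() == [0, 0, 0, 1, 1, 1]
        # union adjacency is block diagonal: no cross-site edges
        assert not out.adjacency[:3, 3:].any()

    def test_site_order_permutes_blocks_not_content(self, rng):
        gs = []
        for s in range(2):
            atoms = [AtomRecord("C", *xyz) for xyz in rng.uniform(0, 5, (3, 3)) + 20 * s]
            gs.append(featurize_site(atoms, site_index=s))
        w = rng.standard_normal((7, K_FEAT))
        ab = embed_protein(gs, w)
        ba = embed_protein(gs[::-1], w)
        assert np.allclose(ab.tokens[:3], ba.tokens[3:])
        assert np.allclose(ab.tokens[3:], ba.tokens[:3])

    def test_zero_atoms_is_error(self):
        with pytest.raises(ValueError, match="no atoms"):
            embed_protein([], np.eye(K_FEAT))


def test_json_site_dialect_roundtrip(rng):
    atoms = [AtomRecord("S" if i == 0 else "C", *xyz, name=f"A{i}")
             for i, xyz in enumerate(rng.uniform(0, 6, (5, 3)))]
    g = featurize_site(atoms, site_index=2)
    g2 = site_from_json(site_to_json(g))
    assert g2.site_index == 2
    assert np.allclose(g.features, g2.features)
    assert set(g.edges) == set(g2.edges)
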