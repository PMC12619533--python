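import numpy as np
import pytest

from sedlipidomics.network import (
    Edge,
    MolecularNetwork,
    NetworkParams,
    build_network,
    export_graph,
    modified_cosine,
    pairwise_similarities,
    read_edge_list,
    subnetworks,
)
from sedlipidomics.spectra import Ms2Spectrum, Peak

from .conftest import random_spectrum
from .oracles import UnionFind, brute_force_modified_cosine


def spec(fid, prec, pairs):
    return Ms2Spectrum(fid, prec, 10.0, tuple(Peak(m, i) for m, i in pairs))


def test_self_similarity_is_one():
    rng = np.random.default_rng(1)
    for i in range(20):
        s = random_spectrum(rng, fid=f"s{i}")
        r = modified_cosine(s, s)
        assert r.score == pytest.approx(1.0, abs=1e-9)
        assert r.n_matched == len(s.peaks)


def test_disjoint_spectra_score_zero():
    a = spec("a", 500.0, [(100.0, 1.0), (110.0, 1.0)])
    b = spec("b", 500.0, [(300.0, 1.0), (310.0, 1.0)])
    r = modified_cosine(a, b)
    assert r.score == 0.0 and r.n_matched == 0


def test_precursor_shifted_copy_scores_one():
    rng = np.random.default_rng(2)
    for _ in range(10):
        a = random_spectrum(rng, fid="a")
        delta = float(rng.uniform(5.0, 60.0))
        b = Ms2Spectrum(
            "b", a.precursor_mz + delta, a.retention_time,
            tuple(Peak(p.mz + delta, p.intensity) for p in a.peaks),
        )
        r = modified_cosine(b, a)
        assert r.score == pytest.approx(1.0, abs=1e-9)


def test_symmetry():
    rng = np.random.default_rng(3)
    for _ in range(50):
        a, b = random_spectrum(rng, fid="a"), random_spectrum(rng, fid="b")
        assert modified_cosine(a, b).score == pytest.approx(
            modified_cosine(b, a).score, abs=1e-9
        )


def test_empty_spectrum_rejected():
    a = spec("a", 500.0, [(100.0, 1.0)])
    with pytest.raises(Exception):
        modified_cosine(a, Ms2Spectrum("b", 400.0, 1.0, ()))


def test_matches_exhaustive_enumeration():
    """Optimal-pairing score equals brute-force enumeration over all pairings."""
    rng = np.random.default_rng(4)
    for k in range(200):
        a, b = random_spectrum(rng, fid="a"), random_spectrum(rng, fid="b")
        if k % 3 == 0:  # force overlapping peaks so matches exist
            shift = a.precursor_mz - b.precursor_mz
            peaks = list(b.peaks)
            for p in list(a.peaks)[:3]:
                peaks.append(Peak(p.mz + rng.uniform(-0.005, 0.005), rng.uniform(1, 100)))
                shifted = p.mz - shift + rng.uniform(-0.005, 0.005)
                if shifted > 0:
                    peaks.append(Peak(shifted, rng.uniform(1, 100)))
            b = Ms2Spectrum("b", b.precursor_mz, b.retention_time, tuple(peaks))
        got = modified_cosine(a, b)
        want_score, _ = brute_force_modified_cosine(a, b)
        assert got.score == pytest.approx(want_score, abs=1e-9)


def test_cross_check_against_matchms():
    """Independent reference: matchms ModifiedCosine agrees on random pairs
    where its greedy pairing is optimal (well-separated candidate matches)."""
    matchms = pytest.importorskip("matchms")
    from matchms import Spectrum as MSpectrum
    from matchms.similarity import ModifiedCosine

    rng = np.random.default_rng(17)
    mc = ModifiedCosine(tolerance=0.01, intensity_power=0.5)  # sqrt-intensity weighting
    for _ in range(25):
        a = random_spectrum(rng, fid="a")
        shift = float(rng.uniform(5, 50))
        # partner shares a subset directly and a subset shifted, far apart
        keep = list(a.peaks)[:: 2]
        moved = [Peak(p.mz - shift, p.intensity * 2) for p in list(a.peaks)[1::2] if p.mz > shift + 1]
        b = Ms2Spectrum("b", a.precursor_mz - shift, 1.0, tuple(keep + moved))
        ours = modified_cosine(a, b)
        ma = MSpectrum(mz=a.mz, intensities=a.intensities,
                       metadata={"precursor_mz": a.precursor_mz}, metadata_harmonization=False)
        mb = MSpectrum(mz=b.mz, intensities=b.intensities,
                       metadata={"precursor_mz": b.precursor_mz}, metadata_harmonization=False)
        res = mc.pair(ma, mb)
        assert ours.score == pytest.approx(float(res["score"]), abs=1e-6)
        assert ours.n_matched == int(res["matches"])


# ---------------------------------------------------------------------------
# network construction


def near_identical_family(n, prec0=600.0):
    rng = np.random.default_rng(7)
    base = [(100.0 + 30 * k, 50.0 + 5 * k) for k in range(8)]
    out = []
    for i in range(n):
        peaks = [(m, inten * float(np.exp(rng.normal(0, 0.05)))) for m, inten in base]
        out.append(spec(f"n{i}", prec0 + i * 0.5, peaks))
    return out


def test_triangle_from_three_near_identical():
    net = build_network(near_identical_family(3))
    assert len(net.edges) == 3
    assert len(set(net.component_of.values())) == 1


def test_min_matched_blocks_edge():
    # two spectra sharing only 5 peaks: high cosine but below the 6-ion rule
    shared = [(100.0 + 10 * k, 10.0) for k in range(5)]
    a = spec("a", 500.0, shared)
    b = spec("b", 500.0, shared)
    sim = modified_cosine(a, b)
    assert sim.score > 0.9 and sim.n_matched == 5
    net = build_network([a, b])
    assert net.edges == []


def test_mutual_top1_matches_exhaustive_rule():
    """With hand-set scores and top_k=1 only mutually-top-1 pairs survive."""
    from sedlipidomics.network import SimilarityResult

    ids = ["a", "b", "c", "d"]
    spectra = [spec(i, 500.0, [(100.0, 1.0)]) for i in ids]
    scores = {
        ("a", "b"): 0.9, ("a", "c"): 0.8, ("a", "d"): 0.7,
        ("b", "c"): 0.85, ("b", "d"): 0.65, ("c", "d"): 0.95,
    }
    sims = {k: SimilarityResult(v, 6, 0.0) for k, v in scores.items()}
    params = NetworkParams(top_k=1)
    net = build_network(spectra, params, similarities=sims)
    got = {(e.node_a, e.node_b) for e in net.edges}
    # exhaustive rule application: a's best is b, b's best is a -> mutual;
    # c's best is d, d's best is c -> mutual
    assert got == {("a", "b"), ("c", "d")}


def test_retained_edges_satisfy_all_constraints(default_bundle):
    params = NetworkParams()
    spectra = default_bundle.spectra[:200]
    sims = pairwise_similarities(spectra, params)
    net = build_network(spectra, params, similarities=sims)
    deg = {}
    for e in net.edges:
        assert e.score >= params.cosine_threshold
        assert e.n_matched >= params.min_matched
        deg[e.node_a] = deg.get(e.node_a, 0) + 1
        deg[e.node_b] = deg.get(e.node_b, 0) + 1
    assert all(d <= params.top_k for d in deg.values())


def test_threshold_monotonicity(default_bundle):
    spectra = default_bundle.spectra[:120]
    sims = pairwise_similarities(spectra, NetworkParams())
    edges = {}
    for thr in (0.5, 0.6, 0.7, 0.9):
        net = build_network(spectra, NetworkParams(cosine_threshold=thr), similarities=sims)
        edges[thr] = {(e.node_a, e.node_b) for e in net.edges}
    assert edges[0.9] <= edges[0.7] <= edges[0.6] <= edges[0.5]


def test_max_component_size_enforced():
    spectra = near_identical_family(6)
    net = build_network(spectra, NetworkParams(max_component_size=3))
    sizes = {}
    for cid in net.component_of.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    assert max(sizes.values()) <= 3


# ---------------------------------------------------------------------------
# subnetworks


def test_edgeless_network_all_singletons():
    net = MolecularNetwork({f"n{i}": 500.0 for i in range(5)}, [])
    comp = subnetworks(net)
    assert len(set(comp.values())) == 5


def test_triangle_plus_isolate_sizes():
    net = MolecularNetwork(
        {"a": 1.0, "b": 1.0, "c": 1.0, "z": 1.0},
        [Edge("a", "b", 0.9, 6), Edge("b", "c", 0.9, 6), Edge("a", "c", 0.9, 6)],
    )
    comp = subnetworks(net)
    sizes = sorted(
        [sum(1 for v in comp.values() if v == c) for c in set(comp.values())], reverse=True
    )
    assert sizes == [3, 1]
    assert comp["a"] == 0  # largest component labelled first


def test_components_match_union_find_oracle():
    rng = np.random.default_rng(12)
    ids = [f"n{i}" for i in range(50)]
    edges = []
    uf = UnionFind(ids)
    for _ in range(40):
        i, j = rng.choice(50, size=2, replace=False)
        edges.append(Edge(ids[i], ids[j], 0.8, 6))
        uf.union(ids[i], ids[j])
    net = MolecularNetwork({i: 500.0 for i in ids}, edges)
    comp = subnetworks(net)
    ours = {}
    for nid, cid in comp.items():
        ours.setdefault(cid, set()).add(nid)
    assert sorted(map(sorted, ours.values())) == sorted(map(sorted, uf.groups()))


# ---------------------------------------------------------------------------
# export


def test_export_round_trip_tsv(tmp_path):
    spectra = near_identical_family(3)
    net = build_network(spectra)
    p = tmp_path / "edges.tsv"
    export_graph(net, p, "tsv")
    back = read_edge_list(p)
    assert {(e.node_a, e.node_b, e.n_matched) for e in back} == {
        (e.node_a, e.node_b, e.n_matched) for e in net.edges
    }
    for a, b in zip(sorted(back, key=lambda e: (e.node_a, e.node_b)),
                    sorted(net.edges, key=lambda e: (e.node_a, e.node_b))):
        assert a.score == pytest.approx(b.score, abs=1e-9)


def test_export_empty_and_graphml(tmp_path):
    net = MolecularNetwork({"a": 1.0}, [])
    net.component_of = subnetworks(net)
    export_graph(net, tmp_path / "e.tsv", "tsv")
    assert (tmp_path / "e.tsv").read_text().strip().splitlines() == ["node_a\tnode_b\tscore\tn_matched"]
    import networkx as nx

    spectra = near_identical_family(3)
    full = build_network(spectra)
    export_graph(full, tmp_path / "g.graphml", "graphml")
    g = nx.read_graphml(tmp_path / "g.graphml")
    assert g.number_of_edges() == len(full.edges)
    with pytest.raises(ValueError):
        export_graph(full, tmp_path / "x", "dot")
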