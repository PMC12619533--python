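"""Modified-cosine spectral similarity and mutual-top-K molecular networking.

The modified cosine aligns two MS² spectra by letting each fragment pair
match either directly (|Δm/z| ≤ tol) or shifted by the precursor mass
difference, with every peak used at most once. Peak weights are
sqrt(intensity), L2-normalised per spectrum, and the score is the maximum
total weight product over all one-to-one pairings — computed exactly as a
maximum-weight bipartite assignment.

Edges of the molecular network must (i) score at least the cosine threshold,
(ii) share at least ``min_matched`` fragment pairs, and (iii) rank within
both endpoints' top-K candidate lists. Connected components of the retained
graph are the "subnetworks" interpreted as structural lipid families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra import Ms2Spectrum


@dataclass(frozen=True)
class NetworkParams:
    fragment_tol: float = 0.01  # Da
    min_matched: int = 6
    cosine_threshold: float = 0.6
    top_k: int = 10
    max_component_size: int | None = None
    sqrt_intensity: bool = True

    def __post_init__(self):
        if self.min_matched < 1:
            raise ValueError("min_matched must be >= 1")
        if not 0.0 <= self.cosine_threshold <= 1.0:
            raise ValueError("cosine_threshold must be in [0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.fragment_tol <= 0:
            raise ValueError("fragment_tol must be positive")


@dataclass(frozen=True)
class SimilarityResult:
    score: float
    n_matched: int
    shift_used: float


@dataclass(frozen=True)
class Edge:
    node_a: str
    node_b: str
    score: float
    n_matched: int


@dataclass
class MolecularNetwork:
    nodes: dict[str, float]  # feature id -> precursor m/z
    edges: list[Edge]
    component_of: dict[str, int] = field(default_factory=dict)

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in (e.node_a, e.node_b))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for nid, pmz in self.nodes.items():
            g.add_node(nid, precursor_mz=float(pmz), component=int(self.component_of.get(nid, -1)))
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, score=float(e.score), n_matched=int(e.n_matched))
        return g


def _weights(spec: Ms2Spectrum, sqrt_intensity: bool) -> np.ndarray:
    w = spec.intensities.astype(float)
    if sqrt_intensity:
        w = np.sqrt(w)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def modified_cosine(a: Ms2Spectrum, b: Ms2Spectrum, params: NetworkParams = NetworkParams()) -> SimilarityResult:
    """Modified-cosine similarity between two spectra.

    A fragment pair (i of a, j of b) is a candidate if it matches directly or
    displaced by Δprecursor = precursor_a − precursor_b. The score is the
    exact maximum-weight one-to-one pairing over candidates, clipped to
    [0, 1]; ``n_matched`` counts pairs with positive product in the optimum.
    """
    if not a.peaks or not b.peaks:
        raise ValueError("modified_cosine requires non-empty spectra")
    mza, mzb = a.mz, b.mz
    if not (np.isfinite(mza).all() and np.isfinite(mzb).all()):
        raise ValueError("non-finite fragment m/z")
    wa = _weights(a, params.sqrt_intensity)
    wb = _weights(b, params.sqrt_intensity)
    if not (np.isfinite(wa).all() and np.isfinite(wb).all()):
        raise ValueError("non-finite intensities")
    shift = a.precursor_mz - b.precursor_mz
    diff = mza[:, None] - mzb[None, :]
    eligible = (np.abs(diff) <= params.fragment_tol) | (np.abs(diff - shift) <= params.fragment_tol)
    if not eligible.any():
        return SimilarityResult(0.0, 0, shift)
    products = np.where(eligible, wa[:, None] * wb[None, :], 0.0)
    rows, cols = linear_sum_assignment(products, maximize=True)
    chosen = products[rows, cols]
    score = float(np.clip(chosen.sum(), 0.0, 1.0))
    n_matched = int(np.count_nonzero(chosen > 0))
    return SimilarityResult(score, n_matched, shift)


def pairwise_similarities(
    spectra: Sequence[Ms2Spectrum], params: NetworkParams = NetworkParams()
) -> dict[tuple[str, str], SimilarityResult]:
    """All pairwise modified-cosine results keyed by (id_a, id_b), a < b order."""
    out = {}
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            out[(spectra[i].feature_id, spectra[j].feature_id)] = modified_cosine(
                spectra[i], spectra[j], params
            )
    return out


def build_network(
    spectra: Sequence[Ms2Spectrum],
    params: NetworkParams = NetworkParams(),
    similarities: dict[tuple[str, str], SimilarityResult] | None = None,
) -> MolecularNetwork:
    """Build the mutual-top-K molecular network from spectra.

    Candidate edges require score ≥ threshold and n_matched ≥ min_matched;
    an edge survives only if each endpoint is among the other's top-K
    candidates ranked by (score desc, n_matched desc, partner id asc). If
    ``max_component_size`` is set, the weakest edge of any oversized
    component is removed iteratively.
    """
    if not spectra:
        raise ValueError("no spectra")
    ids = [s.feature_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids among spectra")
    if similarities is None:
        similarities = pairwise_similarities(spectra, params)

    candidates: dict[str, list[tuple[float, int, str]]] = {i: [] for i in ids}
    edge_info: dict[tuple[str, str], SimilarityResult] = {}
    for (ia, ib), sim in similarities.items():
        if sim.score >= params.cosine_threshold and sim.n_matched >= params.min_matched:
            candidates[ia].append((sim.score, sim.n_matched, ib))
            candidates[ib].append((sim.score, sim.n_matched, ia))
            edge_info[(ia, ib)] = sim

    top: dict[str, set[str]] = {}
    for nid, cands in candidates.items():
        cands.sort(key=lambda t: (-t[0], -t[1], t[2]))
        top[nid] = {partner for _, _, partner in cands[: params.top_k]}

    edges = [
        Edge(ia, ib, sim.score, sim.n_matched)
        for (ia, ib), sim in sorted(edge_info.items())
        if ib in top[ia] and ia in top[ib]
    ]

    net = MolecularNetwork({s.feature_id: s.precursor_mz for s in spectra}, edges)
    if params.max_component_size is not None:
        _trim_components(net, params.max_component_size)
    net.component_of = subnetworks(net)
    return net


def _trim_components(net: MolecularNetwork, max_size: int) -> None:
    """Iteratively drop the weakest edge of any component above ``max_size``."""
    while True:
        comp = subnetworks(net)
        sizes: dict[int, int] = {}
        for cid in comp.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        oversized = {cid for cid, n in sizes.items() if n > max_size}
        if not oversized:
            return
        removable = [
            e for e in net.edges if comp[e.node_a] in oversized
        ]
        worst = min(removable, key=lambda e: (e.score, e.n_matched, e.node_a, e.node_b))
        net.edges.remove(worst)


def subnetworks(net: MolecularNetwork) -> dict[str, int]:
    """Connected-component labels; ids by descending size, ties by smallest member."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((e.node_a, e.node_b) for e in net.edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return {nid: cid for cid, members in enumerate(comps) for nid in members}


def export_graph(net: MolecularNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network as GraphML or a TSV edge list with edge attributes."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), str(path))
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tscore\tn_matched\n")
            for e in net.edges:
                fh.write(f"{e.node_a}\t{e.node_b}\t{e.score:.9f}\t{e.n_matched}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r} (use 'graphml' or 'tsv')")


def read_edge_list(path: str | Path) -> list[Edge]:
    """Parse a TSV edge list written by :func:`export_graph`."""
    edges = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("node_a"):
            raise ValueError("not an edge-list file")
        for line in fh:
            na, nb, score, nm = line.rstrip("\n").split("\t")
            edges.append(Edge(na, nb, float(score), int(nm)))
    return edges
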