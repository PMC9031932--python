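"""MS/MS molecular networking with an exact modified-cosine score.

Spectra are clustered into consensus nodes, scored pairwise with a
square-root-intensity cosine whose fragment pairing is the exact
maximum-weight one-to-one matching (``scipy.optimize.linear_sum_assignment``),
and linked into a network when the score and the matched-fragment count
clear the thresholds (defaults: cosine 0.7, 4 matched fragments).
Components smaller than the minimum cluster size are dropped.  The modified
variant additionally allows fragment pairs offset by the precursor mass
difference, so analogues differing by one substituent still connect.

Nodes from unit-resolution data can silently merge isomers — same precursor,
same fragments, different retention time — summing their intensities.
:func:`split_nodes_by_rt` undoes that by re-clustering node members on
retention time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .spectra_features import FragmentSpectrum

__all__ = [
    "SpectralEdge",
    "NetworkNode",
    "MolecularNetwork",
    "cosine_score",
    "cluster_spectra",
    "build_network",
    "split_nodes_by_rt",
    "write_graphml",
    "group_share_table",
]


@dataclass(frozen=True)
class SpectralEdge:
    node_a: str
    node_b: str
    cosine: float
    n_matched: int


@dataclass(frozen=True)
class NetworkNode:
    """Consensus node: one (de-isomerised) precursor ion across groups."""

    node_id: str
    mz: float
    rt: float
    total_intensity: float
    group_shares: Mapping[str, float]
    members: tuple[FragmentSpectrum, ...]

    @property
    def representative(self) -> FragmentSpectrum:
        """Highest-TIC member; used for edge scoring."""
        return max(self.members, key=lambda s: (s.total_intensity, s.spectrum_id))


@dataclass(frozen=True)
class MolecularNetwork:
    nodes: tuple[NetworkNode, ...]
    edges: tuple[SpectralEdge, ...]
    polarity: str = "positive"

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                node.node_id,
                mz=node.mz,
                rt=node.rt,
                total_intensity=node.total_intensity,
                **{f"share_{k}": v for k, v in sorted(node.group_shares.items())},
            )
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, cosine=e.cosine, n_matched=e.n_matched)
        return g

    @property
    def total_intensity(self) -> float:
        return sum(n.total_intensity for n in self.nodes)


def cosine_score(
    a: FragmentSpectrum,
    b: FragmentSpectrum,
    frag_tol: float = 0.3,
    allow_precursor_shift: bool = True,
) -> tuple[float, int]:
    """Modified cosine between two MS/MS spectra.

    Fragments pair when |d(m/z)| <= frag_tol, or — with
    ``allow_precursor_shift`` — when the difference additionally offset by
    the precursor mass delta is within tolerance.  Intensities are
    square-root weighted; the one-to-one pairing maximising the summed
    products is found exactly.  Returns (cosine in [0, 1], matched pairs).
    """
    if a.polarity != b.polarity:
        raise ValueError(
            f"cannot compare spectra of opposite polarity ({a.polarity} vs {b.polarity})"
        )
    mz_a, int_a = a.mz_array, np.sqrt(a.intensity_array)
    mz_b, int_b = b.mz_array, np.sqrt(b.intensity_array)
    if len(mz_a) == 0 or len(mz_b) == 0:
        raise ValueError("cannot score an empty spectrum")
    norm = float(np.linalg.norm(int_a) * np.linalg.norm(int_b))
    if norm == 0:
        return 0.0, 0
    shift = a.precursor_mz - b.precursor_mz
    diff = mz_a[:, None] - mz_b[None, :]
    eligible = np.abs(diff) <= frag_tol
    if allow_precursor_shift:
        eligible |= np.abs(diff - shift) <= frag_tol
    weights = np.where(eligible, int_a[:, None] * int_b[None, :], 0.0)
    if not weights.any():
        return 0.0, 0
    row, col = linear_sum_assignment(weights, maximize=True)
    matched = weights[row, col] > 0
    score = float(weights[row, col].sum() / norm)
    return min(score, 1.0), int(matched.sum())


def cluster_spectra(
    spectra: Sequence[FragmentSpectrum],
    precursor_tol: float = 0.3,
    merge_cosine: float = 0.95,
    frag_tol: float = 0.3,
) -> list[NetworkNode]:
    """Greedily merge near-identical spectra into consensus nodes.

    Two spectra join one node when their precursors agree within
    ``precursor_tol`` and their plain cosine is at least ``merge_cosine``.
    Node m/z and rt are intensity-weighted means; per-group shares sum the
    member TICs, so a node's shares always add up to its total intensity.
    """
    clusters: list[list[FragmentSpectrum]] = []
    for spec in sorted(spectra, key=lambda s: (-s.total_intensity, s.spectrum_id)):
        placed = False
        for members in clusters:
            anchor = members[0]
            if anchor.polarity != spec.polarity:
                continue
            if abs(anchor.precursor_mz - spec.precursor_mz) > precursor_tol:
                continue
            cos, _ = cosine_score(anchor, spec, frag_tol, allow_precursor_shift=False)
            if cos >= merge_cosine:
                members.append(spec)
                placed = True
                break
        if not placed:
            clusters.append([spec])
    return [_make_node(f"N{i + 1}", members) for i, members in enumerate(clusters)]


def _make_node(node_id: str, members: Sequence[FragmentSpectrum]) -> NetworkNode:
    tics = np.array([s.total_intensity for s in members])
    w = tics if tics.sum() > 0 else np.ones(len(members))
    mz = float(np.average([s.precursor_mz for s in members], weights=w))
    rt = float(np.average([s.retention_time for s in members], weights=w))
    shares: dict[str, float] = {}
    for s in members:
        shares[s.group_id] = shares.get(s.group_id, 0.0) + s.total_intensity
    return NetworkNode(
        node_id=node_id,
        mz=mz,
        rt=rt,
        total_intensity=float(tics.sum()),
        group_shares=shares,
        members=tuple(members),
    )


def build_network(
    spectra: Sequence[FragmentSpectrum] | Sequence[NetworkNode],
    cosine_min: float = 0.7,
    min_matched: int = 4,
    min_cluster: int = 2,
    frag_tol: float = 0.3,
    allow_precursor_shift: bool = True,
    polarity: str | None = None,
) -> MolecularNetwork:
    """Build a molecular network from spectra (or pre-clustered nodes).

    Edges require cosine >= ``cosine_min`` and >= ``min_matched`` matched
    fragments; connected components with fewer than ``min_cluster`` nodes
    are removed entirely.
    """
    if not spectra:
        return MolecularNetwork(nodes=(), edges=(), polarity=polarity or "positive")
    if isinstance(spectra[0], NetworkNode):
        nodes = list(spectra)
    else:
        nodes = cluster_spectra(spectra, precursor_tol=frag_tol, frag_tol=frag_tol)
    if polarity is None:
        polarity = nodes[0].members[0].polarity
    edges = []
    for na, nb in itertools.combinations(nodes, 2):
        cos, n_matched = cosine_score(
            na.representative, nb.representative, frag_tol, allow_precursor_shift
        )
        if cos >= cosine_min and n_matched >= min_matched:
            edges.append(SpectralEdge(na.node_id, nb.node_id, round(cos, 4), n_matched))
    g = nx.Graph()
    g.add_nodes_from(n.node_id for n in nodes)
    g.add_edges_from((e.node_a, e.node_b) for e in edges)
    keep = set()
    for component in nx.connected_components(g):
        if len(component) >= min_cluster:
            keep |= component
    nodes = [n for n in nodes if n.node_id in keep]
    edges = [e for e in edges if e.node_a in keep and e.node_b in keep]
    return MolecularNetwork(nodes=tuple(nodes), edges=tuple(edges), polarity=polarity)


def split_nodes_by_rt(
    network: MolecularNetwork,
    rt_tol: float = 0.5,
    cosine_min: float = 0.7,
    min_matched: int = 4,
    frag_tol: float = 0.3,
    allow_precursor_shift: bool = True,
) -> MolecularNetwork:
    """Split nodes whose members span more than ``rt_tol`` minutes in rt.

    Members are re-clustered along retention time (1-D single linkage: a
    break wherever the gap between consecutive members exceeds ``rt_tol``),
    so co-eluting spectra stay together while true isomers separate and
    stop pooling their intensities.  Edges are re-evaluated between the
    resulting sub-nodes; min_cluster pruning is NOT re-applied (sub-nodes of
    a retained component remain reported).
    """
    new_nodes: list[NetworkNode] = []
    for node in network.nodes:
        members = sorted(node.members, key=lambda s: s.retention_time)
        rts = [s.retention_time for s in members]
        if not rts or max(rts) - min(rts) <= rt_tol:
            new_nodes.append(node)
            continue
        subclusters: list[list[FragmentSpectrum]] = [[members[0]]]
        for prev, cur in zip(members, members[1:]):
            if cur.retention_time - prev.retention_time > rt_tol:
                subclusters.append([])
            subclusters[-1].append(cur)
        for j, sub in enumerate(subclusters):
            new_nodes.append(_make_node(f"{node.node_id}.{j + 1}", sub))
    edges = []
    for na, nb in itertools.combinations(new_nodes, 2):
        cos, n_matched = cosine_score(
            na.representative, nb.representative, frag_tol, allow_precursor_shift
        )
        if cos >= cosine_min and n_matched >= min_matched:
            edges.append(SpectralEdge(na.node_id, nb.node_id, round(cos, 4), n_matched))
    return MolecularNetwork(nodes=tuple(new_nodes), edges=tuple(edges), polarity=network.polarity)


def write_graphml(network: MolecularNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph(), str(path))


def group_share_table(network: MolecularNetwork) -> pd.DataFrame:
    """Per-node group intensity shares (pie-chart input), one row per node."""
    groups = sorted({g for n in network.nodes for g in n.group_shares})
    records = []
    for n in network.nodes:
        rec = {"node_id": n.node_id, "mz": n.mz, "rt": n.rt, "total_intensity": n.total_intensity}
        for g in groups:
            rec[g] = n.group_shares.get(g, 0.0)
        records.append(rec)
    return pd.DataFrame(records)
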