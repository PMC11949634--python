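"""Annual troop-level grooming and spatial association networks.

Grooming networks are directed and weighted: the weight of edge A->B is the
number of scan records in which A was observed grooming B.  Spatial networks
are undirected: the weight of edge {A, B} is the number of scan records in
which one of the pair was recorded within 3 m of the other.  Networks are
built per group and year; every roster member of the group is a node, so
individuals never observed interacting appear as isolates.

Eigenvector centrality (EC) is the leading eigenvector of the weighted
adjacency matrix, computed by shifted power iteration per connected
component and normalized so the maximum score in each component is 1;
isolated nodes score 0.  A node therefore scores highly when its partners
are themselves well connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConvergenceError

__all__ = ["SocialNetwork", "build_networks", "eigenvector_centrality", "centrality_table"]


@dataclass
class SocialNetwork:
    """A weighted group-year network in one of the two observation modes."""

    year: int
    group_id: str
    mode: str  # "grooming" | "spatial"
    graph: nx.Graph | nx.DiGraph = field(repr=False)

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def adjacency(self, directed: bool = False) -> tuple[np.ndarray, list[str]]:
        """Weighted adjacency matrix (optionally keeping direction) and node order.

        With ``directed=False`` a grooming digraph is symmetrized as
        ``weight = in + out`` for each dyad.
        """
        nodes = self.nodes()
        g = self.graph
        a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        if g.is_directed() and not directed:
            a = a + a.T
        return a, nodes

    def edge_list(self) -> pd.DataFrame:
        rows = [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["from", "to", "weight"])


def build_networks(
    scans: pd.DataFrame,
    roster: pd.DataFrame,
    year: int,
    group_id: str,
    days_per_year: int = 365,
) -> tuple[SocialNetwork, SocialNetwork]:
    """Build the (grooming, spatial) network pair for one group-year.

    ``scans`` columns used: ``day, group_id, individual_id, activity,
    partner_id, partner_role, neighbours_3m`` (neighbours as a
    semicolon-joined id string or list).  Records are assigned to years by
    integer division of the day index.
    """
    members = roster.loc[roster["group_id"].astype(str) == str(group_id), "id"].astype(str)
    lo, hi = year * days_per_year, (year + 1) * days_per_year
    sub = scans[
        (scans["group_id"].astype(str) == str(group_id))
        & (scans["day"] >= lo)
        & (scans["day"] < hi)
    ]

    groom = nx.DiGraph()
    spatial = nx.Graph()
    groom.add_nodes_from(members)
    spatial.add_nodes_from(members)

    grooming_rows = sub[sub["activity"] == "grooming"]
    for row in grooming_rows.itertuples(index=False):
        ind, partner = str(row.individual_id), str(row.partner_id)
        # partner_role names the partner's role in the bout
        src, dst = (partner, ind) if row.partner_role == "groomer" else (ind, partner)
        w = groom.get_edge_data(src, dst, default={"weight": 0})["weight"]
        groom.add_edge(src, dst, weight=w + 1)

    for row in sub.itertuples(index=False):
        nbrs = row.neighbours_3m
        if isinstance(nbrs, str):
            nbrs = [n for n in nbrs.split(";") if n]
        elif not isinstance(nbrs, (list, tuple)) or (
            isinstance(nbrs, float) and np.isnan(nbrs)
        ):
            nbrs = []
        ind = str(row.individual_id)
        for n in nbrs:
            n = str(n)
            if n == ind:
                continue
            w = spatial.get_edge_data(ind, n, default={"weight": 0})["weight"]
            spatial.add_edge(ind, n, weight=w + 1)

    return (
        SocialNetwork(year=year, group_id=str(group_id), mode="grooming", graph=groom),
        SocialNetwork(year=year, group_id=str(group_id), mode="spatial", graph=spatial),
    )


def _power_iteration(a: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    """Leading eigenvector of a symmetric non-negative matrix, max-normalized.

    A shift ``a + rI`` (r = max row sum) makes the spectrum non-negative, so
    the iteration cannot oscillate on bipartite components; the shift leaves
    eigenvectors unchanged.
    """
    n = a.shape[0]
    if n == 1:
        return np.ones(1)
    r = float(a.sum(axis=1).max())
    if r == 0:
        return np.zeros(n)
    b = a + r * np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = b @ v
        nw = np.linalg.norm(w)
        w /= nw
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    else:
        # Rayleigh-quotient gap estimate for the error message
        lam = float(v @ (b @ v))
        resid = float(np.linalg.norm(b @ v - lam * v))
        raise ConvergenceError(
            f"power iteration did not reach tol={tol} in {max_iter} iterations "
            f"(residual {resid:.3e}; spectral gap may be near zero)"
        )
    v = np.abs(v)
    return v / v.max()


def eigenvector_centrality(
    net: SocialNetwork,
    directed: bool = False,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """EC scores for every node of ``net``.

    Scores are computed per connected component of the (symmetrized)
    adjacency, each component normalized so its maximum is 1; isolated
    nodes score 0.  With ``directed=True`` on a grooming network the left
    eigenvector of the directed adjacency is used (prestige: being groomed
    by the well-groomed), computed on ``A^T A``-free power iteration over
    the symmetrized component mask but directed weights.
    """
    a, nodes = net.adjacency(directed=directed)
    sym = a if not directed else a + a.T
    n = len(nodes)
    scores = np.zeros(n)
    g = nx.from_numpy_array((sym > 0).astype(float))
    for comp in nx.connected_components(g):
        idx = np.fromiter(comp, dtype=int)
        if len(idx) == 1:
            continue  # isolate: EC 0
        sub = a[np.ix_(idx, idx)]
        if directed:
            sub = sub.T  # left eigenvector: incoming weight confers centrality
            r = float(np.abs(sub).sum(axis=1).max())
            b = sub + r * np.eye(len(idx))
            v = np.full(len(idx), 1.0 / np.sqrt(len(idx)))
            for _ in range(max_iter):
                w = b @ v
                nw = np.linalg.norm(w)
                if nw == 0:
                    break
                w /= nw
                if np.linalg.norm(w - v) < tol:
                    v = w
                    break
                v = w
            v = np.abs(v)
            scores[idx] = v / v.max() if v.max() > 0 else 0.0
        else:
            scores[idx] = _power_iteration(sub, tol=tol, max_iter=max_iter)
    return dict(zip(nodes, scores.tolist()))


def centrality_table(networks: list[tuple[SocialNetwork, SocialNetwork]]) -> pd.DataFrame:
    """(individual, year, grooming_EC, spatial_EC) rows for network pairs."""
    rows = []
    for groom_net, spatial_net in networks:
        gec = eigenvector_centrality(groom_net)
        sec = eigenvector_centrality(spatial_net)
        for node in groom_net.nodes():
            rows.append(
                {
                    "individual_id": node,
                    "year": groom_net.year,
                    "group_id": groom_net.group_id,
                    "grooming_EC": gec[node],
                    "spatial_EC": sec.get(node, 0.0),
                }
            )
    return pd.DataFrame(rows)
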