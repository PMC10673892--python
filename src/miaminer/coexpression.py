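"""Joint gene-metabolite co-expression network via highest reciprocal ranks.

For every feature pair (transcript-transcript, transcript-metabolite,
metabolite-metabolite over the paired samples) the Pearson correlation is
computed; each feature ranks all others by descending r, and the highest
reciprocal rank HRR(i, j) = max(rank_i(j), rank_j(i)).  Small HRR means the
two features are robustly mutual top co-expression partners; an edge is
drawn when HRR is strictly below the threshold (the published criterion is
HRR < 30).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


class ValidationError(ValueError):
    pass


def pearson_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation over rows (features) of a features x
    samples matrix.  Constant rows are excluded with a warning; the result
    has exact unit diagonal and is clipped to [-1, 1].
    """
    if features.shape[1] < 3:
        raise ValidationError("need at least 3 paired samples")
    sd = features.values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(features.index[~keep])
        warnings.warn(f"constant features excluded: {dropped[:5]}")
    kept = features.loc[keep]
    r = np.atleast_2d(np.corrcoef(kept.values))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=kept.index, columns=kept.index)


def hrr_matrix(corr: pd.DataFrame) -> pd.DataFrame:
    """Integer highest-reciprocal-rank matrix from a correlation matrix.

    rank_i(j) is the 1-based position of j in i's descending-r ordering over
    all other features, ties broken by ascending feature id;
    HRR(i, j) = max(rank_i(j), rank_j(i)).  The diagonal carries sentinel 0.
    """
    if corr.shape[0] != corr.shape[1]:
        raise ValidationError("correlation matrix must be square")
    n = corr.shape[0]
    r = corr.values
    ids = corr.index.to_numpy()
    # tie-break key: rank of the feature id in ascending lexicographic order
    id_rank = np.empty(n, dtype=np.int64)
    id_rank[np.argsort(ids, kind="stable")] = np.arange(n)
    rank = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        others = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        order = others[np.lexsort((id_rank[others], -r[i, others]))]
        rank[i, order] = np.arange(1, n)
    hrr = np.maximum(rank, rank.T)
    np.fill_diagonal(hrr, 0)
    return pd.DataFrame(hrr, index=corr.index, columns=corr.index)


@dataclass
class HRRNetwork:
    """Undirected feature network with per-edge HRR and Pearson r."""

    graph: nx.Graph
    threshold: int
    inclusive: bool = False

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_table(self, drop_isolated: bool = False) -> pd.DataFrame:
        rows = [
            {
                "node_a": a,
                "node_b": b,
                "kind_a": self.graph.nodes[a].get("kind", "transcript"),
                "kind_b": self.graph.nodes[b].get("kind", "transcript"),
                "r": d["r"],
                "hrr": d["hrr"],
            }
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(
            rows, columns=["node_a", "node_b", "kind_a", "kind_b", "r", "hrr"]
        )


def build_network(
    hrr: pd.DataFrame,
    corr: pd.DataFrame,
    threshold: int = 30,
    inclusive: bool = False,
    node_kinds: dict[str, str] | None = None,
) -> HRRNetwork:
    """Assemble the network: edge (i, j) iff HRR(i, j) < threshold (strict by
    default, matching the published "below 30"; ``inclusive`` covers <=).
    All features become nodes; isolated nodes are retained.
    """
    if list(hrr.index) != list(corr.index):
        raise ValidationError("hrr and corr must share the same feature order")
    g = nx.Graph()
    kinds = node_kinds or {}
    for node in hrr.index:
        g.add_node(node, kind=kinds.get(node, "transcript"))
    h = hrr.values
    iu, ju = np.triu_indices(h.shape[0], k=1)
    mask = (h[iu, ju] <= threshold) if inclusive else (h[iu, ju] < threshold)
    ids = hrr.index.to_numpy()
    rvals = corr.values
    for i, j in zip(iu[mask], ju[mask]):
        g.add_edge(ids[i], ids[j], hrr=int(h[i, j]), r=float(rvals[i, j]))
    return HRRNetwork(g, threshold=threshold, inclusive=inclusive)


def bait_neighborhood(
    net: HRRNetwork,
    baits: set[str],
    adh_family: dict[str, str] | None = None,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Induced subgraph on the baits and their direct neighbours, plus a
    candidate table of non-bait neighbours with their best HRR to any bait.

    Unknown baits are warned about and skipped.
    """
    known = baits & net.nodes
    missing = baits - known
    if missing:
        warnings.warn(f"baits absent from the network skipped: {sorted(missing)[:5]}")
    neighbours: set[str] = set()
    for b in known:
        neighbours.update(net.graph.neighbors(b))
    sub = net.graph.subgraph(known | neighbours).copy()
    fam = adh_family or {}
    rows = []
    for cand in sorted(neighbours - known):
        best = min(
            (
                (net.graph.edges[cand, b]["hrr"], net.graph.edges[cand, b]["r"], b)
                for b in known
                if net.graph.has_edge(cand, b)
            ),
            default=None,
        )
        if best is None:
            continue
        rows.append(
            {
                "candidate": cand,
                "best_hrr": best[0],
                "r": best[1],
                "bait": best[2],
                "kind": net.graph.nodes[cand].get("kind", "transcript"),
                "adh_family": fam.get(cand, "none"),
            }
        )
    table = pd.DataFrame(
        rows, columns=["candidate", "best_hrr", "r", "bait", "kind", "adh_family"]
    )
    return sub, table
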