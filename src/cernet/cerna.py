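"""Shared-miRNA ceRNA pair testing and network assembly.

Two transcripts are candidate competing endogenous RNAs when they are
targeted by many of the same miRNAs.  For an anchor lncRNA with K
targeting miRNAs out of a universe of N, and a candidate mRNA with n
targeting miRNAs of which k are shared, the shared count under the null
of independent target sets follows Hypergeometric(N, K, n); each pair
is scored with the upper-tail probability P(X >= k), computed in
log-space so that tiny enrichment p-values do not underflow.  Tested
pairs are corrected with Benjamini-Hochberg across exactly the tested
family, and pairs with q below threshold form the
lncRNA-miRNA-mRNA network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .targets import TargetMap

__all__ = [
    "CeRNAEdge",
    "CeRNANetwork",
    "shared_mirnas",
    "hypergeom_pvalue",
    "bh_adjust",
    "build_cerna_network",
    "write_edge_table",
    "to_networkx",
    "write_graphml",
    "write_edge_list",
]


def shared_mirnas(targetmap: TargetMap, rna_a: str, rna_b: str) -> set[str]:
    """miRNAs targeting both transcripts.

    An id absent from the map contributes an empty target set (and a
    warning): untargeted is a valid state, a typo should still surface.
    """
    for rna in (rna_a, rna_b):
        if rna not in targetmap.targets:
            warnings.warn(f"{rna!r} has no entry in the target map", stacklevel=2)
    return targetmap.mirnas_targeting(rna_a) & targetmap.mirnas_targeting(rna_b)


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log-space.

    Exact to floating precision for any practical universe size; bounds
    violations raise rather than being clipped silently.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"K and n must not exceed N (N={N}, K={K}, n={n})")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    denom = _log_comb(N, n)
    xs = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, xs) + _log_comb(N - K, n - xs) - denom
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)) or np.any(~np.isfinite(ps)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(ps, method="fdr_bh")[1])


@dataclass(frozen=True)
class CeRNAEdge:
    """One tested (lncRNA, mRNA) pair with its shared-miRNA statistics."""

    lncrna_id: str
    mrna_id: str
    shared_mirna_ids: frozenset[str]
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.k != len(self.shared_mirna_ids):
            raise ValueError("k must equal |shared_mirna_ids|")
        if self.k > min(self.K, self.n) or max(self.K, self.n) > self.N:
            raise ValueError("hypergeometric bounds violated")


@dataclass
class CeRNANetwork:
    """Retained edges around one anchor lncRNA, plus the tested family."""

    anchor: str
    edges: list[CeRNAEdge]
    tested: list[CeRNAEdge] = field(default_factory=list)

    @property
    def mrna_ids(self) -> list[str]:
        return [e.mrna_id for e in self.edges]

    @property
    def mirna_ids(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out |= e.shared_mirna_ids
        return out


def build_cerna_network(
    targetmap: TargetMap,
    anchor: str,
    candidate_mrnas: Sequence[str],
    min_shared: int = 3,
    max_q: float = 0.05,
    universe_size: int | None = None,
) -> CeRNANetwork:
    """Test every candidate mRNA against the anchor and keep enriched pairs.

    Candidates sharing at least ``min_shared`` miRNAs with the anchor are
    tested (this defines the BH family m); pairs with q < ``max_q`` are
    retained.  N defaults to the full miRNA set supplied to the
    prediction run, the sampling frame from which target sets are drawn.
    Edges are ordered by (q ascending, k descending, mrna_id).
    """
    if anchor not in targetmap.targets:
        raise ValueError(f"anchor {anchor!r} has no predicted targeting miRNAs")
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    N = universe_size if universe_size is not None else len(targetmap.universe)
    anchor_set = targetmap.mirnas_targeting(anchor)
    K = len(anchor_set)
    if K > N:
        raise ValueError("anchor target count exceeds the miRNA universe")

    tested: list[tuple[str, set[str], int, float]] = []
    for mrna in candidate_mrnas:
        mset = targetmap.mirnas_targeting(mrna)
        shared = anchor_set & mset
        if len(shared) >= min_shared:
            p = hypergeom_pvalue(N, K, len(mset), len(shared))
            tested.append((mrna, shared, len(mset), p))

    qs = bh_adjust([t[3] for t in tested])
    all_edges = [
        CeRNAEdge(
            lncrna_id=anchor,
            mrna_id=mrna,
            shared_mirna_ids=frozenset(shared),
            k=len(shared),
            K=K,
            n=n,
            N=N,
            p_value=p,
            q_value=q,
        )
        for (mrna, shared, n, p), q in zip(tested, qs)
    ]
    key = lambda e: (e.q_value, -e.k, e.mrna_id)
    all_edges.sort(key=key)
    retained = [e for e in all_edges if e.q_value < max_q]
    return CeRNANetwork(anchor=anchor, edges=retained, tested=all_edges)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_edge_table(path: str | Path, network: CeRNANetwork, tested: bool = False) -> None:
    """Edge statistics TSV (retained edges, or the whole tested family)."""
    edges = network.tested if tested else network.edges
    with open(path, "w") as fh:
        fh.write("lncrna_id\tmrna_id\tk\tK\tn\tN\tp_value\tq_value\tshared_mirna_ids\n")
        for e in edges:
            fh.write(
                f"{e.lncrna_id}\t{e.mrna_id}\t{e.k}\t{e.K}\t{e.n}\t{e.N}\t"
                f"{e.p_value:.6g}\t{e.q_value:.6g}\t"
                f"{';'.join(sorted(e.shared_mirna_ids))}\n"
            )


def to_networkx(network: CeRNANetwork) -> nx.Graph:
    """Tripartite lncRNA-miRNA-mRNA graph of the retained network."""
    g = nx.Graph()
    g.add_node(network.anchor, kind="lncRNA")
    for e in network.edges:
        g.add_node(e.mrna_id, kind="mRNA")
        for mid in sorted(e.shared_mirna_ids):
            g.add_node(mid, kind="miRNA")
            g.add_edge(network.anchor, mid, edge_type="lncRNA-miRNA")
            g.add_edge(mid, e.mrna_id, edge_type="miRNA-mRNA")
    return g


def write_graphml(path: str | Path, network: CeRNANetwork) -> None:
    nx.write_graphml(to_networkx(network), str(path))


def write_edge_list(path: str | Path, network: CeRNANetwork) -> None:
    g = to_networkx(network)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tedge_type\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['edge_type']}\n")
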