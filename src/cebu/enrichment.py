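"""Pair-level enrichment statistics and the buffering network.

Three questions about the high-C-score pair set:

* are duplicated gene pairs over-represented above a cutoff
  (upper-tail hypergeometric test on the pair universe)?
* are annotated pairs (same pathway / gene set, PPI, same complex)
  enriched — measured as log[(e_ac/e_a) / (e_c/e_t)] with e_ac the pairs
  both annotated and buffering, e_a annotated, e_c buffering, e_t the
  full universe (self-pairs excluded)?
* what does the directed buffering network (edges G2 -> G1) look like?
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from cebu.datatypes import PairList

__all__ = [
    "EnrichmentCounts",
    "duplicated_enrichment",
    "pair_set_enrichment",
    "enrichment_curve",
    "build_network",
    "pairs_from_gene_sets",
]


@dataclass(frozen=True)
class EnrichmentCounts:
    """Counts entering the pair-set enrichment ratio."""

    e_ac: int  #: annotated AND buffering pairs
    e_a: int   #: annotated pairs in the universe
    e_c: int   #: buffering pairs (above cutoff)
    e_t: int   #: total pair universe (self-pairs excluded)

    def __post_init__(self) -> None:
        if self.e_ac > min(self.e_a, self.e_c):
            raise ValueError("e_ac cannot exceed min(e_a, e_c)")
        if max(self.e_a, self.e_c) > self.e_t:
            raise ValueError("e_a and e_c cannot exceed e_t")


def _annotated_mask(records: pd.DataFrame, annotated: PairList) -> np.ndarray:
    members = annotated.pairs()
    if annotated.symmetric:
        keys = [(min(a, b), max(a, b))
                for a, b in zip(records["g1"], records["g2"])]
    else:
        keys = list(zip(records["g1"], records["g2"]))
    return np.fromiter((k in members for k in keys), dtype=bool,
                       count=len(keys))


def duplicated_enrichment(records: pd.DataFrame, duplicated: PairList,
                          cutoff: float,
                          universe_size: int | None = None) -> dict:
    """Hypergeometric enrichment of duplicated pairs above a cutoff.

    Universe: the N scored pairs (``universe_size`` when the record table
    is thresholded), containing K duplicated pairs; draw = the n pairs
    with C-score >= cutoff; observed = k duplicated among them.  Returns
    the upper-tail p-value P[X >= k].
    """
    is_dup = _annotated_mask(records, duplicated)
    K = int(is_dup.sum())
    if K == 0:
        raise ValueError("no duplicated pair occurs in the scored universe")
    N = int(universe_size if universe_size is not None else len(records))
    above = records["c_score"].to_numpy() >= cutoff
    n = int(above.sum())
    k = int((above & is_dup).sum())
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return {"p": p, "N": N, "K": K, "n": n, "k": k}


def pair_set_enrichment(counts: EnrichmentCounts,
                        log_base: float = 2.0) -> float:
    """log[(e_ac/e_a) / (e_c/e_t)] — 0 means no enrichment.

    Returns ``-inf`` when no annotated pair clears the cutoff (e_ac = 0).
    """
    if counts.e_a <= 0 or counts.e_c <= 0:
        raise ValueError("e_a and e_c must be positive")
    if counts.e_ac == 0:
        return float("-inf")
    ratio = (counts.e_ac / counts.e_a) / (counts.e_c / counts.e_t)
    return math.log(ratio, log_base)


def count_enrichment(records: pd.DataFrame, annotated: PairList,
                     cutoff: float, universe_size: int,
                     annotated_in_universe: int | None = None
                     ) -> EnrichmentCounts:
    """Assemble EnrichmentCounts for one cutoff over a scored table.

    ``annotated_in_universe`` defaults to the annotated pairs found in
    ``records`` — pass the universe-wide count when records are
    pre-thresholded.
    """
    is_ann = _annotated_mask(records, annotated)
    above = records["c_score"].to_numpy() >= cutoff
    e_a = int(annotated_in_universe if annotated_in_universe is not None
              else is_ann.sum())
    return EnrichmentCounts(e_ac=int((above & is_ann).sum()), e_a=e_a,
                            e_c=int(above.sum()), e_t=int(universe_size))


def enrichment_curve(records: pd.DataFrame, annotated: PairList,
                     cutoffs, universe_size: int,
                     annotated_in_universe: int | None = None,
                     log_base: float = 2.0) -> pd.DataFrame:
    """Pair-set enrichment across an ascending ladder of cutoffs."""
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly ascending")
    rows = []
    for cut in cutoffs:
        counts = count_enrichment(records, annotated, cut, universe_size,
                                  annotated_in_universe)
        rows.append({"cutoff": cut, "e_ac": counts.e_ac, "e_a": counts.e_a,
                     "e_c": counts.e_c, "e_t": counts.e_t,
                     "enrichment": pair_set_enrichment(counts, log_base)})
    return pd.DataFrame(rows)


def pairs_from_gene_sets(gene_sets: dict[str, set[str]]) -> PairList:
    """Co-membership pair list: (a, b) annotated when some set holds both."""
    seen: set[tuple[str, str]] = set()
    for genes in gene_sets.values():
        ordered = sorted(genes)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                seen.add((a, b))
    table = pd.DataFrame(sorted(seen), columns=["gene_a", "gene_b"])
    return PairList(table, kind="annotation")


def build_network(records: pd.DataFrame, cutoff: float) -> nx.DiGraph:
    """Directed buffering network: one edge G2 -> G1 per pair >= cutoff.

    Node attribute ``role`` partitions nodes into ``buffered`` (G1 only),
    ``buffering`` (G2 only) and ``both``.  Graph attributes carry the
    summary counts.
    """
    kept = records[records["c_score"] >= cutoff]
    g = nx.DiGraph()
    for row in kept.itertuples():
        g.add_edge(row.g2, row.g1, c_score=float(row.c_score))
    g1s = set(kept["g1"])
    g2s = set(kept["g2"])
    for node in g.nodes:
        if node in g1s and node in g2s:
            g.nodes[node]["role"] = "both"
        elif node in g1s:
            g.nodes[node]["role"] = "buffered"
        else:
            g.nodes[node]["role"] = "buffering"
    roles = nx.get_node_attributes(g, "role")
    g.graph.update(
        n_nodes=g.number_of_nodes(), n_edges=g.number_of_edges(),
        n_buffered=sum(r == "buffered" for r in roles.values()),
        n_buffering=sum(r == "buffering" for r in roles.values()),
        n_both=sum(r == "both" for r in roles.values()),
        cutoff=cutoff)
    if g.number_of_edges() == 0:
        import logging
        logging.getLogger(__name__).warning(
            "no pair reaches cutoff %.3g; empty network", cutoff)
    return g


def write_network(g: nx.DiGraph, path, fmt: str = "sif") -> None:
    """Export the network as SIF (``g2 buffers g1``) or GraphML."""
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in g.edges:
                fh.write(f"{u}\tbuffers\t{v}\n")
    else:
        raise ValueError(f"unknown network format: {fmt!r}")
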