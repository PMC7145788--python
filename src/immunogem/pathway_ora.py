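"""Metabolite pathway over-representation analysis and pathway impact scores.

Over-representation uses the one-sided hypergeometric upper tail against the
measured-and-mapped universe, with Benjamini-Hochberg control across
pathways.  The pathway impact score (PIS) weights the hit metabolites by
their relative betweenness centrality inside the pathway's own graph, so a
hit at a topological bottleneck counts for more than a peripheral one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats

from .differential import bh_fdr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwaySet:
    name: str
    members: frozenset[str]
    graph: nx.Graph | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")
        if self.graph is not None:
            extra = set(self.graph.nodes) - set(self.members)
            if extra:
                raise ValueError(
                    f"pathway {self.name!r}: graph nodes outside member set: {sorted(extra)[:5]}"
                )


@dataclass
class OraResult:
    pathway: str
    k: int   # hits in pathway
    K: int   # pathway size (within universe)
    n: int   # total hits
    N: int   # universe size
    p: float
    fdr: float = float("nan")
    pis: float | None = None
    significant: bool = False


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one pathway per line, name <tab> description <tab> members..."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        out[fields[0]] = [m for m in fields[2:] if m]
    return out


def read_pathway_edges(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Edge-list TSV with columns pathway, source, target."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[str, str]]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["pathway"], []).append((row["source"], row["target"]))
    return out


def build_pathway_sets(sets: dict[str, list[str]],
                       edges: dict[str, list[tuple[str, str]]] | None = None
                       ) -> list[PathwaySet]:
    pathways = []
    for name, members in sets.items():
        graph = None
        if edges and name in edges:
            graph = nx.Graph()
            graph.add_nodes_from(members)
            graph.add_edges_from(edges[name])
        pathways.append(PathwaySet(name=name, members=frozenset(members), graph=graph))
    return pathways


def hypergeom_ora(hits, pathways: list[PathwaySet], universe,
                  fdr_threshold: float = 0.05) -> list[OraResult]:
    """One-sided hypergeometric ORA with BH-FDR flagging.

    Hit sets and pathway member sets are intersected with the universe
    before testing; pathways ending up empty are skipped.  p = P(X >= k)
    for X ~ Hypergeom(N, K, n).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    N, n = len(universe), len(hits)
    results = []
    for pw in pathways:
        members = pw.members & universe
        if not members:
            logger.info("pathway %s has no members in the universe; skipped", pw.name)
            continue
        K = len(members)
        k = len(hits & members)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append(OraResult(pathway=pw.name, k=k, K=K, n=n, N=N,
                                 p=min(p, 1.0),
                                 pis=pathway_impact(pw, hits)))
    if results:
        q = bh_fdr([r.p for r in results])
        for r, qv in zip(results, q):
            r.fdr = float(qv)
            r.significant = r.fdr < fdr_threshold
    return results


def pathway_impact(pathway: PathwaySet, hits) -> float | None:
    """PIS: centrality-weighted share of the pathway hit by altered metabolites.

    Sum of relative betweenness centralities of the hit members divided by
    the sum over all members, computed on the pathway's own graph.  Returns
    ``None`` (undefined) when the pathway has no graph, and 0 when no member
    carries centrality mass.
    """
    if pathway.graph is None:
        return None
    bc = nx.betweenness_centrality(pathway.graph, normalized=True)
    denom = sum(bc.get(m, 0.0) for m in pathway.members)
    if denom == 0:
        return 0.0
    num = sum(bc.get(m, 0.0) for m in set(hits) & pathway.members)
    return num / denom


def ora_table(results: list[OraResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"pathway": r.pathway, "hits_k": r.k, "size_K": r.K,
          "total_hits_n": r.n, "universe_N": r.N, "p": r.p, "fdr": r.fdr,
          "pis": r.pis, "significant": r.significant}
         for r in results]
    ).sort_values("p", kind="mergesort").reset_index(drop=True)
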