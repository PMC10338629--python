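"""Tolerance-module extraction, centrality ranking, enrichment, concordance.

Modules are found by taking the phase-specific seed features (the uniquely
dysregulated genes and proteins of the tolerance phase), inducing the
consensus subgraph on the seeds plus their distance-1 neighbors, and keeping
every connected component with at least two nodes.  Nodes are ranked by
unnormalized betweenness centrality on the undirected, unweighted graph.
Modules are annotated against gene-set collections with a one-sided
hypergeometric test, BH-corrected per module, and cross-cohort direction
concordance is scored through an ortholog map against external differential
expression tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import adjust_bh

logger = logging.getLogger(__name__)

__all__ = [
    "Module",
    "ModuleSet",
    "EnrichmentResult",
    "extract_modules",
    "betweenness",
    "enrich_module",
    "read_gmt",
    "concordance",
]


@dataclass
class Module:
    members: set[str]
    edges: list[tuple[str, str]]
    betweenness: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ModuleSet:
    """Maximal connected components (>= 2 nodes) of the extracted subgraph.

    ``singletons`` lists seeds that survived in the network but kept no
    surviving edge; they are reported, never counted as modules.
    """

    modules: list[Module]
    singletons: set[str] = field(default_factory=set)

    def __post_init__(self):
        seen: set[str] = set()
        for m in self.modules:
            if len(m.members) < 2:
                raise ValueError("modules must have at least 2 nodes")
            if m.members & seen:
                raise ValueError("modules must be pairwise disjoint")
            seen |= m.members
        self.modules = sorted(self.modules, key=lambda m: (-m.size, sorted(m.members)[0]))

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def n_nodes(self) -> int:
        return sum(m.size for m in self.modules)

    def all_members(self) -> set[str]:
        return set().union(*(m.members for m in self.modules)) if self.modules else set()


def extract_modules(net, seeds: set[str], radius: int = 1) -> ModuleSet:
    """Seed features plus their network neighbors, split into components.

    The subgraph is induced on the seeds together with every node within
    ``radius`` steps of a seed in the undirected view of ``net``; connected
    components with >= 2 nodes become modules, seed components of size 1 are
    reported as singletons.
    """
    if not seeds:
        raise ValueError("no seed features given")
    g = net.to_networkx(directed=False)
    present = {s for s in seeds if s in g}
    if not present:
        logger.warning("none of the %d seeds occur in the network", len(seeds))
        return ModuleSet(modules=[], singletons=set())
    keep = set(present)
    frontier = set(present)
    for _ in range(radius):
        frontier = {n for f in frontier for n in g.neighbors(f)} - keep
        keep |= frontier
    sub = g.subgraph(keep)
    bc = betweenness(sub)
    modules, singles = [], set()
    for comp in nx.connected_components(sub):
        if len(comp) < 2:
            singles |= comp & present
            continue
        comp_edges = [tuple(sorted(e)) for e in sub.subgraph(comp).edges()]
        modules.append(
            Module(members=set(comp), edges=sorted(comp_edges),
                   betweenness={n: bc[n] for n in comp})
        )
    return ModuleSet(modules=modules, singletons=singles)


def betweenness(graph) -> dict[str, float]:
    """Unnormalized betweenness centrality on the undirected, unweighted graph.

    For each node v, the sum over unordered pairs {s, t} (s, t != v) of the
    fraction of shortest s-t paths passing through v.  Isolated nodes score 0.
    """
    if isinstance(graph, nx.DiGraph):
        graph = graph.to_undirected()
    elif not isinstance(graph, nx.Graph):
        g = nx.Graph()
        g.add_edges_from(graph)
        graph = g
    return {n: float(v) for n, v in nx.betweenness_centrality(graph, normalized=False).items()}


@dataclass
class EnrichmentResult:
    module_id: int
    gene_set: str
    overlap: int
    set_size: int
    module_size: int
    p: float
    fdr: float = np.nan

    @property
    def significant(self) -> bool:
        return bool(self.fdr < 0.05)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set collection: name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ValueError(f"{path}:{ln}: GMT lines need name, description, members")
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def enrich_module(
    module_members: set[str],
    genesets: dict[str, set[str]],
    universe: set[str],
    module_id: int = 0,
    fdr_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of one module, BH across sets.

    With universe size N, set size K, module size n and overlap k, the
    p-value is P[X >= k] for X ~ Hypergeom(N, K, n).
    """
    if not universe:
        raise ValueError("empty universe")
    mod = module_members & universe
    results = []
    for name, members in sorted(genesets.items()):
        s = members & universe
        k = len(mod & s)
        p = float(hypergeom.sf(k - 1, len(universe), len(s), len(mod)))
        results.append(
            EnrichmentResult(module_id, name, k, len(s), len(mod), min(p, 1.0))
        )
    fdrs = adjust_bh([r.p for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results


def concordance(
    mouse_de: pd.DataFrame,
    external_de: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Direction concordance of mouse features with an external cohort.

    ``mouse_de`` needs columns (feature, log2fc); ``external_de`` columns
    (id, log2fc, fdr); ``ortholog_map`` columns (mouse_id, external_id).
    A feature is concordant iff an ortholog exists, the external gene passes
    the FDR cutoff, and the two fold-change signs agree.  Unmapped features
    are kept in the table with concordant=False and mapped=False.
    """
    omap = dict(zip(ortholog_map.iloc[:, 0].astype(str), ortholog_map.iloc[:, 1].astype(str)))
    ext = external_de.set_index(external_de.columns[0])
    rows = []
    for row in mouse_de.itertuples(index=False):
        feat = str(row[0])
        m_dir = int(np.sign(row[1]))
        orth = omap.get(feat)
        e_dir, e_fdr, conc = None, None, False
        if orth is not None and orth in ext.index:
            e_dir = int(np.sign(ext.loc[orth].iloc[0]))
            e_fdr = float(ext.loc[orth].iloc[1])
            conc = e_fdr < fdr and m_dir == e_dir and m_dir != 0
        rows.append((feat, orth, m_dir, e_dir, e_fdr, orth is not None and orth in ext.index, conc))
    out = pd.DataFrame(
        rows,
        columns=["feature", "ortholog", "mouse_dir", "external_dir", "external_fdr",
                 "mapped", "concordant"],
    )
    n_unmapped = int((~out["mapped"]).sum())
    if n_unmapped:
        logger.info("concordance: %d features without a mapped external gene", n_unmapped)
    return out
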