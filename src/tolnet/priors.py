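"""Predictor-candidate priors for network inference.

Each node model only considers predictors that some prior relation nominates:

1. the direct gene-to-protein annotation (a gene and its coding protein),
2. protein-protein interactions (PPI),
3. the indirect map: a gene annotated to PPI partners of its coding protein,
4. a derived clinical prior, built from the transcript- and protein-centered
   networks after they are inferred: every feature showing an effect with a
   clinical variable there becomes a candidate predictor for that variable.

Priors are plain file inputs (two-column TSVs); nothing is fetched from
annotation services at run time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSet",
    "build_direct_prior",
    "build_indirect_prior",
    "build_clinical_prior",
]

Pair = tuple[str, str]


def _canon(a: str, b: str) -> Pair:
    """Canonical (sorted) form of an undirected pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class PriorSet:
    """The three candidate-predictor maps plus the derived clinical prior.

    ``direct_map`` holds (gene, protein) pairs; ``ppi`` holds undirected
    protein pairs in canonical sorted order; ``indirect_map`` holds
    (gene, protein) pairs reached through one PPI hop and never duplicates
    ``direct_map``.  ``clinical_candidates`` maps each clinical variable to
    its candidate predictor features (empty until derived).
    """

    direct_map: set[Pair] = field(default_factory=set)
    ppi: set[Pair] = field(default_factory=set)
    indirect_map: set[Pair] = field(default_factory=set)
    clinical_candidates: dict[str, set[str]] = field(default_factory=dict)

    def has_ppi(self, a: str, b: str) -> bool:
        return _canon(a, b) in self.ppi

    def ppi_partners(self, p: str) -> set[str]:
        out = set()
        for a, b in self.ppi:
            if a == p:
                out.add(b)
            elif b == p:
                out.add(a)
        return out

    def proteins_of_gene(self, g: str) -> set[str]:
        return {p for gg, p in self.direct_map if gg == g}

    def genes_of_protein(self, p: str) -> set[str]:
        return {g for g, pp in self.direct_map if pp == p}

    def indirect_of_gene(self, g: str) -> set[str]:
        return {p for gg, p in self.indirect_map if gg == g}

    def counts(self) -> dict[str, int]:
        return {
            "direct_map": len(self.direct_map),
            "ppi": len(self.ppi),
            "indirect_map": len(self.indirect_map),
            "clinical_candidates": sum(len(v) for v in self.clinical_candidates.values()),
        }


def _as_pairs(table) -> list[Pair]:
    if isinstance(table, pd.DataFrame):
        if table.shape[1] < 2:
            raise ValueError("prior table needs two id columns")
        return [(str(a), str(b)) for a, b in table.iloc[:, :2].itertuples(index=False)]
    return [(str(a), str(b)) for a, b in table]


def build_direct_prior(
    mapping_table, universe: set[str] | None = None
) -> tuple[set[Pair], int]:
    """Deduplicated gene-protein pairs, restricted to the dataset's features.

    Many-to-many mappings are allowed.  Returns the pair set and the number of
    input pairs dropped because an endpoint is absent from ``universe``.
    """
    pairs = set(_as_pairs(mapping_table))
    if universe is None:
        return pairs, 0
    kept = {(g, p) for g, p in pairs if g in universe and p in universe}
    dropped = len(pairs) - len(kept)
    if dropped:
        logger.info("direct prior: dropped %d pairs outside the feature universe", dropped)
    if not kept:
        logger.warning("direct prior empty after restriction to the dataset")
    return kept, dropped


def build_ppi_prior(edge_table, universe: set[str] | None = None) -> tuple[set[Pair], int]:
    """Symmetric, self-loop-free PPI pairs in canonical order."""
    pairs = {_canon(a, b) for a, b in _as_pairs(edge_table) if a != b}
    if universe is None:
        return pairs, 0
    kept = {pr for pr in pairs if pr[0] in universe and pr[1] in universe}
    return kept, len(pairs) - len(kept)


def build_indirect_prior(direct_map: set[Pair], ppi: set[Pair]) -> set[Pair]:
    """Genes annotated to the PPI partners of their coding protein.

    (g, q) is included iff some protein p satisfies (g, p) in the direct map
    and {p, q} in the PPI, with q != p; pairs already present in the direct
    map are excluded.
    """
    partners: dict[str, set[str]] = {}
    for a, b in ppi:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    out: set[Pair] = set()
    for g, p in direct_map:
        for q in partners.get(p, ()):
            if q != p and (g, q) not in direct_map:
                out.add((g, q))
    return out


def build_clinical_prior(
    transcript_network,
    protein_network,
    clinical_vars: Iterable[str],
) -> dict[str, set[str]]:
    """Candidate predictors for each clinical variable.

    Taken from the untrimmed transcript- and protein-centered networks: every
    feature incident to an edge involving the clinical variable in either
    network, plus all other clinical variables.  A variable with no edge in
    either network keeps only the other clinical variables (logged).
    """
    clinical_vars = list(clinical_vars)
    cand: dict[str, set[str]] = {c: set(clinical_vars) - {c} for c in clinical_vars}
    for net in (transcript_network, protein_network):
        for src, tgt in zip(net.edges["source"], net.edges["target"]):
            if src in cand and tgt not in cand[src]:
                cand[src].add(tgt)
            if tgt in cand and src not in cand[tgt]:
                cand[tgt].add(src)
    for c in clinical_vars:
        if cand[c] <= (set(clinical_vars) - {c}):
            logger.info("clinical variable %s has no omic edges; candidates are clinical only", c)
    return cand
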