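"""Gene hierarchy and coordination-network construction.

The Gene Commanding Height combines expression control (low variability
relative to the transcriptome) with expression coordination:

    GCH_i = (<REV>/REV_i) * exp((4/N) * sum_{j != i} COR_ij^2 - 1)

where <REV> is the mean REV over the quantified universe of N genes. With
4 replicas the null expectation of a squared pairwise correlation is 1/3,
so an average, uncoordinated gene scores near exp(1/3 * 4/... ) ~ O(1);
strongly controlled, widely coordinated genes rise far above it. The
top-ranked gene is the Gene Master Regulator (GMR) of the phenotype.

Fabric networks classify every gene pair across two pathways into
synergistic / antagonistic / independent / not-significant; the
interaction-consistency check tests whether KEGG-style activator/inhibitor
annotations agree with the observed coordination signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import GeneSet, InteractionList
from .quantifiers import (
    CoordinationAnalysis,
    PhenotypeQuantifiers,
    compute_quantifiers,
)

__all__ = [
    "distinct_pair_count",
    "GCHTable",
    "compute_gch",
    "gch_from_tensor",
    "rank_gmr",
    "CoordinationNetwork",
    "build_fabric_network",
    "ConsistencyReport",
    "evaluate_interaction_consistency",
]


def distinct_pair_count(n: int) -> int:
    """Number of distinct unordered gene pairs in a universe of n genes."""
    return n * (n - 1) // 2


@dataclass
class GCHTable:
    """GCH scores and ranking for one phenotype."""

    phenotype: str
    table: pd.DataFrame  # index gene; columns rev_ratio, coord_exponent, GCH, rank
    #: genes with REV = 0 (infinite control), reported separately
    infinite_control: list[str] = field(default_factory=list)

    @property
    def gmr(self) -> str:
        return self.table.index[self.table["rank"] == 1][0]


def compute_gch(
    quantifiers: PhenotypeQuantifiers,
    cor_sq_sums: pd.Series,
    rev_center: str = "mean",
) -> GCHTable:
    """GCH from per-gene REV and the per-gene sum of squared correlations.

    ``cor_sq_sums`` must hold sum_{j != i} COR_ij^2 over the same universe
    as the quantifier table (see :meth:`CoordinationAnalysis.sq_sums`).
    """
    q = quantifiers.table
    if not q.index.equals(cor_sq_sums.index):
        cor_sq_sums = cor_sq_sums.reindex(q.index)
        if cor_sq_sums.isna().any():
            raise ValueError("cor_sq_sums does not cover the quantified universe")
    rev = q["REV"]
    N = len(q)
    center = float(rev.mean()) if rev_center == "mean" else float(rev.median())
    zero = rev == 0
    exponent = (4.0 / N) * cor_sq_sums - 1.0
    with np.errstate(divide="ignore"):
        gch = (center / rev) * np.exp(exponent)
    finite = ~zero
    table = pd.DataFrame(
        {
            "rev_ratio": center / rev[finite],
            "coord_exponent": exponent[finite],
            "GCH": gch[finite],
        }
    )
    # descending GCH, ties broken lexicographically by symbol
    ranked = sorted(table.index, key=lambda g: (-table.at[g, "GCH"], g))
    table["rank"] = pd.Series(np.arange(1, len(ranked) + 1), index=pd.Index(ranked))
    return GCHTable(
        phenotype=quantifiers.phenotype,
        table=table,
        infinite_control=list(q.index[zero]),
    )


def gch_from_tensor(tensor, alpha: float = 0.05, rev_center: str = "mean") -> GCHTable:
    """Convenience: quantifiers + all-pairs coordination + GCH in one call."""
    quant = compute_quantifiers(tensor)
    coan = CoordinationAnalysis(tensor, alpha=alpha)
    return compute_gch(quant, coan.sq_sums(), rev_center=rev_center)


def rank_gmr(table: GCHTable, top_k: int = 15) -> pd.DataFrame:
    """Top-k genes by GCH, descending (rank 1 = GMR)."""
    if table.table.empty:
        raise ValueError("empty GCH table")
    return (
        table.table.sort_values("rank", kind="stable").head(top_k)
    )


@dataclass
class CoordinationNetwork:
    """Classified pairwise coordination across two gene sets."""

    name_a: str
    name_b: str
    partitions: dict[str, str]  # gene -> a_only | b_only | both
    edges: pd.DataFrame  # gene_a, gene_b, cor, n_eff, cutoff, class
    class_counts: dict[str, int]
    missing: list[str] = field(default_factory=list)

    def to_networkx(self, significant_only: bool = True) -> nx.Graph:
        g = nx.Graph(name=f"{self.name_a}~{self.name_b}")
        for gene, part in self.partitions.items():
            g.add_node(gene, partition=part)
        for rec in self.edges.itertuples(index=False):
            if significant_only and rec[5] not in ("synergistic", "antagonistic"):
                continue
            g.add_edge(rec[0], rec[1], cor=rec[2], klass=rec[5])
        return g


def _resolve_symbols(coan: CoordinationAnalysis, symbols: list[str]):
    """Case-insensitive match of external symbols to tensor gene names."""
    lookup = {g.casefold(): g for g in coan.tensor.genes}
    found, missing = {}, []
    for s in symbols:
        hit = lookup.get(s.casefold())
        if hit is None:
            missing.append(s)
        else:
            found[s] = hit
    return found, missing


def build_fabric_network(
    coan: CoordinationAnalysis, set_a: GeneSet, set_b: GeneSet
) -> CoordinationNetwork:
    """Classify every distinct pair within the union of two pathways.

    Nodes are partitioned into a-only / b-only / both; undefined
    (zero-variance) pairs are excluded from the counts.
    """
    found_a, missing_a = _resolve_symbols(coan, set_a.genes)
    found_b, missing_b = _resolve_symbols(coan, set_b.genes)
    a_ci = {g.casefold() for g in found_a.values()}
    b_ci = {g.casefold() for g in found_b.values()}
    union = sorted(set(found_a.values()) | set(found_b.values()))
    partitions = {}
    for g in union:
        in_a, in_b = g.casefold() in a_ci, g.casefold() in b_ci
        partitions[g] = "both" if (in_a and in_b) else ("a_only" if in_a else "b_only")
    edges = coan.pairs(union)
    counted = edges[edges["class"] != "undefined"]
    class_counts = counted["class"].value_counts().to_dict()
    for k in ("synergistic", "antagonistic", "independent", "not_significant"):
        class_counts.setdefault(k, 0)
    return CoordinationNetwork(
        name_a=set_a.name,
        name_b=set_b.name,
        partitions=partitions,
        edges=edges,
        class_counts=class_counts,
        missing=sorted(set(missing_a) | set(missing_b)),
    )


_EXPECTED_SIGN = {
    "upstream_activator": +1,
    "downstream_activated": +1,
    "upstream_inhibitor": -1,
    "downstream_inhibited": -1,
}


@dataclass
class ConsistencyReport:
    """Sign-consistency of observed coordination against annotated roles."""

    center_block: list[str]
    table: pd.DataFrame  # center, partner, role, expected_sign, cor, class, verdict
    #: per role: counts of synergistic / antagonistic / independent pairs
    group_counts: pd.DataFrame
    missing: list[str] = field(default_factory=list)

    @property
    def n_contradictions(self) -> int:
        return int((self.table["verdict"] == "contradicts").sum())

    @property
    def n_confirmations(self) -> int:
        return int((self.table["verdict"] == "confirms").sum())


def evaluate_interaction_consistency(
    coan: CoordinationAnalysis, interactions: InteractionList
) -> ConsistencyReport:
    """Verdict per (center, partner) pair.

    Activator/activated partners are expected synergistic with the center
    block, inhibitor/inhibited partners antagonistic. A pair contradicts
    the annotation only when its coordination is significant AND of the
    opposite sign; independent or not-significant pairs are unresolved.
    """
    centers, miss_c = _resolve_symbols(coan, interactions.center_block)
    partner_syms = list(interactions.partners["gene"])
    partners, miss_p = _resolve_symbols(coan, partner_syms)
    role_of = dict(zip(interactions.partners["gene"], interactions.partners["role"]))

    rows = []
    for p_sym, p_gene in partners.items():
        role = role_of[p_sym]
        expected = _EXPECTED_SIGN[role]
        for c_sym, c_gene in centers.items():
            if c_gene == p_gene:
                continue
            res = coan.pairs([c_gene, p_gene]).iloc[0]
            klass = res["class"]
            if klass == "synergistic":
                verdict = "confirms" if expected > 0 else "contradicts"
            elif klass == "antagonistic":
                verdict = "confirms" if expected < 0 else "contradicts"
            else:
                verdict = "unresolved"
            rows.append(
                (c_sym, p_sym, role, expected, res["cor"], klass, verdict)
            )
    table = pd.DataFrame(
        rows,
        columns=["center", "partner", "role", "expected_sign", "cor", "class", "verdict"],
    )
    if table.empty:
        group_counts = pd.DataFrame(
            columns=["synergistic", "antagonistic", "independent"]
        )
    else:
        group_counts = (
            table.pivot_table(
                index="role", columns="class", values="partner", aggfunc="count",
                fill_value=0,
            )
            .reindex(columns=["synergistic", "antagonistic", "independent"], fill_value=0)
        )
    return ConsistencyReport(
        center_block=list(interactions.center_block),
        table=table,
        group_counts=group_counts,
        missing=sorted(set(miss_c) | set(miss_p)),
    )
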