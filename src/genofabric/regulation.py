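"""Differential regulation between two phenotypes.

A gene counts as significantly regulated only if its absolute expression
ratio |x| exceeds a gene-specific cut-off combining the variabilities of
both phenotypes, AND the heteroscedastic (Welch) t-test of the means'
equality gives p < alpha:

    CUT = 1 + (1/100) * sqrt(2 * (REV_P^2 + REV_Q^2))      (REV in percent)

The Weighted Individual Regulation damps the net fold-change by the
reference expression level and the statistical confidence:

    WIR = AVE(Q) * sign(x) * (|x| - 1) * (1 - p)

and the Weighted Pathway Regulation is the mean squared WIR over a
pathway's quantified genes. No multiple-testing correction is applied
anywhere: conservatism comes from CUT, not from FDR machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSet
from .preprocess import GeneSpotTensor
from .quantifiers import compute_quantifiers

__all__ = [
    "compute_cut",
    "wir",
    "compute_regulation_table",
    "PathwayRegulation",
    "compute_wpr",
]


def compute_cut(rev_p, rev_q):
    """Gene-specific fold-change threshold; REVs in percent, CUT >= 1."""
    rev_p = np.asarray(rev_p, dtype=float)
    rev_q = np.asarray(rev_q, dtype=float)
    if (rev_p < 0).any() or (rev_q < 0).any():
        raise ValueError("REV must be non-negative")
    out = 1.0 + np.sqrt(2.0 * (rev_p**2 + rev_q**2)) / 100.0
    return float(out) if out.ndim == 0 else out


def wir(ave_q, x, p):
    """Weighted individual regulation from reference AVE, signed ratio x, p-value."""
    x = np.asarray(x, dtype=float)
    out = np.asarray(ave_q, dtype=float) * np.sign(x) * (np.abs(x) - 1.0) * (
        1.0 - np.asarray(p, dtype=float)
    )
    return float(out) if out.ndim == 0 else out


def compute_regulation_table(
    tensor_p: GeneSpotTensor, tensor_q: GeneSpotTensor, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene regulation records for the contrast P vs Q.

    The Welch test runs on the per-replica spot-averaged expressions
    (biological replicas are the experimental unit; spots are technical).
    Genes present in only one phenotype are flagged ``absent`` and carry
    no statistics; they are excluded from pathway aggregation.
    """
    if tensor_p.n_replicas != tensor_q.n_replicas:
        raise ValueError("phenotypes must share the replica count")
    qp = compute_quantifiers(tensor_p).table
    qq = compute_quantifiers(tensor_q).table
    common = qp.index.intersection(qq.index)
    only = qp.index.symmetric_difference(qq.index)

    ave_p = qp.loc[common, "AVE"].to_numpy()
    ave_q = qq.loc[common, "AVE"].to_numpy()
    rev_p = qp.loc[common, "REV"].to_numpy()
    rev_q = qq.loc[common, "REV"].to_numpy()

    up = ave_p >= ave_q
    x = np.where(up, ave_p / ave_q, -ave_q / ave_p)
    cut = compute_cut(rev_p, rev_q)

    ip = [tensor_p.gene_index(g) for g in common]
    iq = [tensor_q.gene_index(g) for g in common]
    ep = tensor_p.replica_means()[ip]  # (genes, n_replicas)
    eq = tensor_q.replica_means()[iq]
    with np.errstate(invalid="ignore", divide="ignore"):
        pvals = stats.ttest_ind(ep, eq, axis=1, equal_var=False).pvalue
    # identical constant samples: no evidence of difference
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    significant = (np.abs(x) > cut) & (pvals < alpha)
    wirs = wir(ave_q, x, pvals)
    uniform = np.where(significant, np.sign(x), 0.0).astype(int)

    contrast = f"{tensor_p.phenotype} vs {tensor_q.phenotype}"
    table = pd.DataFrame(
        {
            "contrast": contrast,
            "AVE_P": ave_p,
            "AVE_Q": ave_q,
            "REV_P": rev_p,
            "REV_Q": rev_q,
            "x": x,
            "CUT": cut,
            "p": pvals,
            "significant": significant,
            "uniform": uniform,
            "WIR": wirs,
            "absent": False,
        },
        index=pd.Index(common, name="gene"),
    )
    if len(only):
        missing = pd.DataFrame(
            {"contrast": contrast, "absent": True},
            index=pd.Index(only, name="gene"),
        )
        table = pd.concat([table, missing]).sort_index()
    return table


@dataclass
class PathwayRegulation:
    """Pathway-level aggregation of a regulation table."""

    pathway: str
    card: int  # number of quantified pathway genes
    wpr: float
    pct_up: float
    pct_down: float


def compute_wpr(records: pd.DataFrame, gene_set: GeneSet) -> PathwayRegulation:
    """WPR = mean squared WIR over the quantified genes of a pathway.

    Gene symbols are matched case-insensitively. Raises if no pathway gene
    was quantified in the contrast.
    """
    quantified = records[~records["absent"].astype(bool)]
    members = gene_set.symbols_ci()
    in_set = quantified.index.astype(str).str.casefold().isin(members)
    sub = quantified[in_set]
    if sub.empty:
        raise ValueError(
            f"no quantified gene from pathway {gene_set.name!r} in this contrast"
        )
    card = len(sub)
    wpr_val = float((sub["WIR"] ** 2).mean())
    sig = sub["significant"].astype(bool)
    pct_up = 100.0 * float((sig & (sub["x"] > 0)).sum()) / card
    pct_down = 100.0 * float((sig & (sub["x"] < 0)).sum()) / card
    return PathwayRegulation(
        pathway=gene_set.name, card=card, wpr=wpr_val, pct_up=pct_up, pct_down=pct_down
    )
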