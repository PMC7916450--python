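"""Per-gene expression quantifiers and pairwise coordination.

Three independent characteristics per gene and phenotype:

* AVE — average expression level over redundant spots and replicas, in
  units of the phenotype's median gene;
* REV — relative expression variability: the mid-interval chi-square
  estimate of the pooled coefficient of variation across replicas, in
  percent, with r = n_replicas * R - 1 degrees of freedom;
* COR — Pearson correlation of spot-centered expression deviations with
  every other gene, classified against redundancy-dependent critical
  values (0.95 for one spot, 0.707 for two, ... 0.273 for thirteen) into
  synergistic / antagonistic / independent / not-significant.

Spot centering removes the spot-specific technical bias, so COR reflects
how two genes co-vary across biological replicas. For pairs probed with
equal redundancy the correlation runs over all spot-by-replica deviations
with spots paired by index; for unequal redundancy it runs over the
per-replica spot-averaged deviations, whose effective sample size is the
number of replicas.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import GeneSpotTensor

__all__ = [
    "UndefinedCVError",
    "PhenotypeQuantifiers",
    "CoordinationResult",
    "chi2_correction",
    "compute_ave",
    "compute_rev",
    "compute_quantifiers",
    "compute_cor",
    "cor_cutoff",
    "critical_r",
    "classify_coordination",
    "CoordinationAnalysis",
]

CLASSES = ("synergistic", "antagonistic", "independent", "not_significant")


class UndefinedCVError(ValueError):
    pass


def chi2_correction(r: np.ndarray | int) -> np.ndarray | float:
    """Mid-interval chi-square correction: (r/chi2_lo + r/chi2_hi) / 2.

    chi2_lo/hi are the 2.5% and 97.5% quantiles for r degrees of freedom,
    so the factor exceeds 1 for finite r and tends to 1 as r grows.
    """
    r = np.asarray(r, dtype=float)
    lo = stats.chi2.ppf(0.025, r)
    hi = stats.chi2.ppf(0.975, r)
    return 0.5 * (r / lo + r / hi)


def compute_ave(tensor: GeneSpotTensor) -> pd.Series:
    """AVE_i = (1/R_i) sum_k mu_{i,k}."""
    return pd.Series(tensor.ave(), index=tensor.genes, name="AVE")


def compute_rev(tensor: GeneSpotTensor) -> pd.Series:
    """REV_i in percent; raises if any spot mean is zero."""
    mu = tensor.spot_means
    if np.any(mu == 0):
        bad = tensor.genes[int(tensor.gene_of_spot[np.argmax(mu == 0)])]
        raise UndefinedCVError(f"zero spot mean for gene {bad!r}: CV undefined")
    cv2 = (tensor.spot_sds / mu) ** 2
    R = tensor.R
    pooled_cv = np.sqrt(np.add.reduceat(cv2, tensor.gene_ptr[:-1]) / R)
    r = tensor.n_replicas * R - 1
    rev = chi2_correction(r) * pooled_cv * 100.0
    return pd.Series(rev, index=tensor.genes, name="REV")


@dataclass
class PhenotypeQuantifiers:
    """Per-gene AVE, REV, redundancy and chi-square correction for one phenotype."""

    phenotype: str
    table: pd.DataFrame  # index gene; columns R, AVE, REV, df, chi2_correction

    @classmethod
    def from_tensor(cls, tensor: GeneSpotTensor) -> "PhenotypeQuantifiers":
        R = tensor.R
        r = tensor.n_replicas * R - 1
        table = pd.DataFrame(
            {
                "R": R,
                "AVE": compute_ave(tensor),
                "REV": compute_rev(tensor),
                "df": r,
                "chi2_correction": chi2_correction(r),
            },
            index=pd.Index(tensor.genes, name="gene"),
        )
        return cls(phenotype=tensor.phenotype, table=table)


def compute_quantifiers(tensor: GeneSpotTensor) -> PhenotypeQuantifiers:
    return PhenotypeQuantifiers.from_tensor(tensor)


# ---------------------------------------------------------------------------
# coordination


@lru_cache(maxsize=None)
def critical_r(df: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Pearson correlation at the given degrees of freedom."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    t_c = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_c / np.sqrt(t_c**2 + df))


def cor_cutoff(
    R_a: int, R_b: int | None = None, alpha: float = 0.05, n_replicas: int = 4
) -> float:
    """Significance threshold on |COR| for a pair of genes.

    Equal redundancy R: df = n_replicas * R - 2, reproducing the printed
    ladder 0.95 (R=1), 0.707 (R=2), ..., 0.273 (R=13). Unequal redundancy:
    the correlation is taken over the n_replicas spot-averaged deviations,
    so df = n_replicas - 2.
    """
    if R_b is None:
        R_b = R_a
    if min(R_a, R_b) < 1:
        raise ValueError("redundancy must be >= 1")
    if R_a == R_b:
        df = n_replicas * R_a - 2
    else:
        df = n_replicas - 2
    return critical_r(df, alpha)


def classify_coordination(
    cor: float, cutoff: float, independence_band: float = 0.025
) -> str:
    """Synergistic / antagonistic / independent / not-significant."""
    if np.isnan(cor):
        return "not_significant"
    if cor > cutoff:
        return "synergistic"
    if cor < -cutoff:
        return "antagonistic"
    if abs(cor) < independence_band:
        return "independent"
    return "not_significant"


@dataclass
class CoordinationResult:
    gene_a: str
    gene_b: str
    cor: float
    n_eff: int
    cutoff: float | None = None
    klass: str | None = None
    defined: bool = True


def compute_cor(tensor: GeneSpotTensor, gene_a: str, gene_b: str) -> CoordinationResult:
    """COR for one gene pair (no classification)."""
    n = tensor.n_replicas
    if gene_a == gene_b:
        return CoordinationResult(gene_a, gene_b, 1.0, n_eff=n * int(
            tensor.R[tensor.gene_index(gene_a)]))
    va = tensor.values_for(gene_a)
    vb = tensor.values_for(gene_b)
    da = va - va.mean(axis=1, keepdims=True)
    db = vb - vb.mean(axis=1, keepdims=True)
    if da.shape[0] == db.shape[0]:  # spots paired by index
        x, y = da.ravel(), db.ravel()
        n_eff = da.size
    else:  # per-replica spot-averaged deviations
        x, y = da.mean(axis=0), db.mean(axis=0)
        n_eff = n
    sx, sy = np.sqrt((x**2).sum()), np.sqrt((y**2).sum())
    if sx == 0.0 or sy == 0.0:
        return CoordinationResult(gene_a, gene_b, np.nan, n_eff, defined=False)
    cor = float((x * y).sum() / (sx * sy))
    return CoordinationResult(gene_a, gene_b, cor, n_eff)


class CoordinationAnalysis:
    """All-pairs coordination machinery for one phenotype tensor.

    Precomputes spot-centered deviation vectors once; correlations are then
    produced in row blocks so the full matrix is never required in memory
    for large universes. Zero-variance genes yield undefined correlations
    (NaN) and are excluded from significance counts and networks.
    """

    def __init__(
        self,
        tensor: GeneSpotTensor,
        alpha: float = 0.05,
        independence_band: float = 0.025,
    ):
        self.tensor = tensor
        self.alpha = alpha
        self.independence_band = independence_band
        n = tensor.n_replicas
        D = tensor.values - tensor.values.mean(axis=1, keepdims=True)
        self._R = tensor.R
        # per-replica spot-averaged deviations, normalized rows
        U = np.add.reduceat(D, tensor.gene_ptr[:-1], axis=0) / self._R[:, None]
        unorm = np.sqrt((U**2).sum(axis=1))
        self.defined = unorm > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            self._Un = np.where(self.defined[:, None], U / unorm[:, None], 0.0)
        # per-R-group stacked flat deviation vectors, normalized rows
        self._groups: dict[int, np.ndarray] = {}
        self._group_members: dict[int, np.ndarray] = {}
        for Rv in np.unique(self._R):
            members = np.flatnonzero(self._R == Rv)
            rows = np.concatenate(
                [np.arange(tensor.gene_ptr[i], tensor.gene_ptr[i + 1]) for i in members]
            )
            V = D[rows].reshape(len(members), Rv * n)
            vnorm = np.sqrt((V**2).sum(axis=1))
            keep = vnorm > 0
            self.defined[members] &= keep
            with np.errstate(invalid="ignore", divide="ignore"):
                Vn = np.where(keep[:, None], V / vnorm[:, None], 0.0)
            self._groups[int(Rv)] = Vn
            self._group_members[int(Rv)] = members
        self._pos_in_group = np.empty(tensor.n_genes, dtype=np.int64)
        for Rv, members in self._group_members.items():
            self._pos_in_group[members] = np.arange(len(members))
        # cutoff per pair depends only on whether R matches
        self._cut_same = {
            int(Rv): critical_r(n * int(Rv) - 2, alpha) for Rv in np.unique(self._R)
        }
        self._cut_diff = critical_r(n - 2, alpha)

    # -- block production -------------------------------------------------
    def cor_rows(self, rows: np.ndarray) -> np.ndarray:
        """COR[rows, :] against the whole universe (NaN where undefined)."""
        rows = np.asarray(rows)
        C = self._Un[rows] @ self._Un.T
        for Rv, members in self._group_members.items():
            in_block = np.flatnonzero(np.isin(rows, members))
            if in_block.size == 0:
                continue
            Vn = self._groups[Rv]
            pos = self._pos_in_group[rows[in_block]]
            C[np.ix_(in_block, members)] = Vn[pos] @ Vn.T
        undef = ~self.defined
        C[:, undef] = np.nan
        C[undef[rows], :] = np.nan
        for j, gi in enumerate(rows):
            C[j, gi] = 1.0 if self.defined[gi] else np.nan
        return C

    def cutoff_rows(self, rows: np.ndarray) -> np.ndarray:
        """Significance cutoffs aligned with :meth:`cor_rows`."""
        R = self._R
        same = R[rows][:, None] == R[None, :]
        cut = np.full((len(rows), len(R)), self._cut_diff)
        for Rv, c in self._cut_same.items():
            mask = same & (R[None, :] == Rv)
            cut[mask] = c
        return cut

    def matrix(self, genes: list[str] | None = None) -> pd.DataFrame:
        """Dense COR matrix (symmetric, unit diagonal)."""
        if genes is None:
            rows = np.arange(self.tensor.n_genes)
            names = self.tensor.genes
        else:
            rows = np.array([self.tensor.gene_index(g) for g in genes])
            names = list(genes)
        C = self.cor_rows(rows)[:, rows]
        return pd.DataFrame(C, index=names, columns=names)

    def classify_block(self, rows: np.ndarray) -> np.ndarray:
        """Class codes for COR[rows, :]: 0 syn, 1 ant, 2 indep, 3 ns, -1 undefined."""
        C = self.cor_rows(rows)
        cut = self.cutoff_rows(rows)
        cls = np.full(C.shape, 3, dtype=np.int8)
        cls[C > cut] = 0
        cls[C < -cut] = 1
        cls[np.abs(C) < self.independence_band] = 2
        cls[np.isnan(C)] = -1
        return cls

    def pair_class_counts(self, block: int = 512) -> dict[str, int]:
        """Counts over all distinct defined pairs in the universe."""
        N = self.tensor.n_genes
        counts = np.zeros(4, dtype=np.int64)
        for start in range(0, N, block):
            rows = np.arange(start, min(start + block, N))
            cls = self.classify_block(rows)
            for j, gi in enumerate(rows):  # strict upper triangle only
                row = cls[j, gi + 1 :]
                for c in range(4):
                    counts[c] += int((row == c).sum())
        return dict(zip(CLASSES, counts.tolist()))

    def sq_sums(self, block: int = 512) -> pd.Series:
        """sum_{j != i} COR_ij^2 per gene (undefined pairs contribute 0)."""
        N = self.tensor.n_genes
        out = np.zeros(N)
        for start in range(0, N, block):
            rows = np.arange(start, min(start + block, N))
            C = self.cor_rows(rows)
            C2 = np.nan_to_num(C) ** 2
            C2[np.arange(len(rows)), rows] = 0.0
            out[rows] = C2.sum(axis=1)
        return pd.Series(out, index=self.tensor.genes, name="cor_sq_sum")

    def pairs(self, genes: list[str]) -> pd.DataFrame:
        """Edge list over all distinct pairs within ``genes``."""
        idx = np.array([self.tensor.gene_index(g) for g in genes])
        C = self.cor_rows(idx)[:, idx]
        cut = self.cutoff_rows(idx)[:, idx]
        n = self.tensor.n_replicas
        recs = []
        for a in range(len(genes)):
            for b in range(a + 1, len(genes)):
                cor = C[a, b]
                klass = (
                    "undefined"
                    if np.isnan(cor)
                    else classify_coordination(cor, cut[a, b], self.independence_band)
                )
                Ra, Rb = int(self._R[idx[a]]), int(self._R[idx[b]])
                n_eff = n * Ra if Ra == Rb else n
                recs.append(
                    (genes[a], genes[b], cor, n_eff, cut[a, b], klass)
                )
        return pd.DataFrame(
            recs, columns=["gene_a", "gene_b", "cor", "n_eff", "cutoff", "class"]
        )
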