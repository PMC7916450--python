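"""Spot-quality filtering and iterative median-gene normalization.

A spot survives only if it is uncorrupted AND its foreground is at least
twice its background in every profiled sample; a gene survives if at least
one of its spots does. Background-subtracted intensities are then brought
onto a common scale by iterative normalization to the expression level of
the median gene, stopping when the overall maximum error of estimate (the
largest relative change of any sample's scaling factor between iterations)
drops below ``tol`` percent. Each phenotype's tensor is finally expressed
in units of its median gene's AVE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import SpotTable, ValidationError, parse_sample_label

__all__ = [
    "StructuralError",
    "NonConvergenceError",
    "GeneSpotTensor",
    "FilterReport",
    "NormalizedData",
    "filter_spots",
    "normalize",
    "preprocess_experiment",
    "write_tensor",
    "read_tensor",
]


class StructuralError(ValueError):
    """Spot universes disagree between arrays."""


class NonConvergenceError(RuntimeError):
    """Normalization failed to reach the tolerance within max_iter."""

    def __init__(self, trace: list[float]):
        super().__init__(
            f"normalization did not converge in {len(trace)} iterations "
            f"(last error {trace[-1]:.3g}%)"
        )
        self.trace = trace


class GeneSpotTensor:
    """Normalized expression a[i, k, xi] for one phenotype.

    Ragged over genes (gene i has R_i spots), stored flat: ``values`` is a
    (total_spots, n_replicas) array and ``gene_ptr`` gives CSR-style offsets
    so gene i occupies rows ``gene_ptr[i]:gene_ptr[i+1]``. All values are
    positive, in units of the phenotype's median gene.
    """

    def __init__(
        self,
        phenotype: str,
        genes: list[str],
        gene_ptr: np.ndarray,
        values: np.ndarray,
        spot_ids: list[str] | None = None,
    ):
        self.phenotype = phenotype
        self.genes = list(genes)
        self.gene_ptr = np.asarray(gene_ptr, dtype=np.int64)
        self.values = np.asarray(values, dtype=float)
        self.spot_ids = spot_ids or [
            f"{g}_k{k + 1}"
            for i, g in enumerate(self.genes)
            for k in range(self.gene_ptr[i + 1] - self.gene_ptr[i])
        ]
        self._index = {g: i for i, g in enumerate(self.genes)}

    # -- basic shape ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_replicas(self) -> int:
        return self.values.shape[1]

    @property
    def R(self) -> np.ndarray:
        """Spot redundancy per gene."""
        return np.diff(self.gene_ptr)

    @property
    def gene_of_spot(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_genes), self.R)

    def gene_index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in {self.phenotype} tensor") from None

    def values_for(self, gene: str) -> np.ndarray:
        """(R_i, n_replicas) block for one gene."""
        i = self.gene_index(gene)
        return self.values[self.gene_ptr[i] : self.gene_ptr[i + 1]]

    # -- derived statistics ----------------------------------------------
    @property
    def spot_means(self) -> np.ndarray:
        """mu[i,k]: replica mean per spot (flat)."""
        return self.values.mean(axis=1)

    @property
    def spot_sds(self) -> np.ndarray:
        """s[i,k]: replica standard deviation per spot (ddof=1, flat)."""
        return self.values.std(axis=1, ddof=1)

    def replica_means(self) -> np.ndarray:
        """(n_genes, n_replicas): per-replica spot-averaged expression."""
        sums = np.add.reduceat(self.values, self.gene_ptr[:-1], axis=0)
        return sums / self.R[:, None]

    def ave(self) -> np.ndarray:
        """Per-gene AVE: mean over spots of the spot means."""
        mu = self.spot_means
        return np.add.reduceat(mu, self.gene_ptr[:-1]) / self.R

    def validate(self, tol: float = 1e-6) -> None:
        if not np.all(np.isfinite(self.values)) or not np.all(self.values > 0):
            raise ValidationError(f"{self.phenotype}: tensor values must be positive")
        if np.any(self.R < 1):
            raise ValidationError(f"{self.phenotype}: every gene needs >= 1 spot")
        med = np.median(self.ave())
        if abs(med - 1.0) > tol:
            raise ValidationError(
                f"{self.phenotype}: median AVE is {med:.8f}, expected 1"
            )

    def rescaled(self, factor: float) -> "GeneSpotTensor":
        return GeneSpotTensor(
            self.phenotype, self.genes, self.gene_ptr, self.values * factor,
            spot_ids=self.spot_ids,
        )


@dataclass
class FilterReport:
    """Outcome of the spot-quality filter."""

    n_spots: int = 0
    n_kept: int = 0
    n_corrupted: int = 0
    n_low_signal: int = 0
    n_rejected: int = 0
    n_nonpositive: int = 0
    genes_lost: list[str] = field(default_factory=list)
    rerejected_spots: list[str] = field(default_factory=list)


def _spot_universe(tables: list[SpotTable]) -> list[str]:
    universe = tables[0].spot_ids
    ref = set(universe)
    for t in tables[1:]:
        ids = set(t.spot_ids)
        if ids != ref:
            diff = sorted((ref ^ ids))[:5]
            raise StructuralError(
                f"array {t.array_id}: spot universe mismatch (e.g. {diff})"
            )
    return universe


def filter_spots(tables: list[SpotTable]) -> tuple[list[str], FilterReport]:
    """Keep spots that are flag=ok AND fg >= 2*bg in every sample."""
    if not tables:
        raise ValueError("no spot tables given")
    universe = _spot_universe(tables)
    order = pd.Index(universe)
    ok_all = np.ones(len(universe), dtype=bool)
    signal_all = np.ones(len(universe), dtype=bool)
    gene_of: pd.Series | None = None
    for t in tables:
        df = t.data.set_index("spot_id").loc[order]
        ok_all &= (df["flag"] == "ok").to_numpy()
        signal_all &= (df["fg"].to_numpy() >= 2.0 * df["bg"].to_numpy())
        if gene_of is None:
            gene_of = df["gene"]
    kept_mask = ok_all & signal_all
    kept = [s for s, m in zip(universe, kept_mask) if m]

    genes = gene_of.to_numpy()
    real = genes != ""  # control spots carry no gene symbol
    lost = sorted(
        set(genes[real & ~kept_mask]) - set(genes[real & kept_mask])
    )
    report = FilterReport(
        n_spots=len(universe),
        n_kept=len(kept),
        n_corrupted=int((~ok_all).sum()),
        n_low_signal=int((~signal_all).sum()),
        n_rejected=int((~kept_mask).sum()),
        genes_lost=lost,
    )
    return kept, report


@dataclass
class NormalizedData:
    """Per-phenotype tensors plus the normalization convergence trace."""

    tensors: dict[str, GeneSpotTensor]
    trace: list[float]
    report: FilterReport

    def __getitem__(self, phenotype: str) -> GeneSpotTensor:
        return self.tensors[phenotype]

    def __iter__(self):
        return iter(self.tensors)

    def items(self):
        return self.tensors.items()


def _median_gene_value(values: np.ndarray, gene_ptr: np.ndarray, R: np.ndarray) -> float:
    """Expression of the median gene: lower median of per-gene spot averages."""
    gene_means = np.add.reduceat(values, gene_ptr[:-1]) / R
    order = np.argsort(gene_means, kind="stable")
    return float(gene_means[order[(len(gene_means) - 1) // 2]])


def normalize(
    tables: list[SpotTable],
    kept_spots: list[str] | None = None,
    tol: float = 5.0,
    max_iter: int = 100,
) -> NormalizedData:
    """Iterative intra-/inter-array normalization to the median gene.

    Because each two-color channel is treated as an independent sample, the
    intra-array (between channels) and inter-array (between arrays) median
    alignments collapse into one median-gene scaling per sample; iteration
    stops when every sample's scaling factor is within ``tol`` percent of
    unity. Non-positive background-subtracted intensities cause the whole
    spot to be re-rejected (never silently clipped).
    """
    if kept_spots is None:
        kept_spots, report = filter_spots(tables)
    else:
        _, report = filter_spots(tables)
        report = FilterReport(
            n_spots=report.n_spots,
            n_kept=len(kept_spots),
            n_corrupted=report.n_corrupted,
            n_low_signal=report.n_low_signal,
            n_rejected=report.n_spots - len(kept_spots),
            genes_lost=report.genes_lost,
        )
    kept_index = pd.Index(kept_spots)
    if len(kept_index) == 0:
        raise ValidationError("no spots survive the quality filter")

    samples: list[str] = []
    cols: list[np.ndarray] = []
    gene_of: pd.Series | None = None
    for t in tables:
        for sample, df in t.data.groupby("sample", sort=False):
            df = df.set_index("spot_id").loc[kept_index]
            samples.append(sample)
            cols.append((df["fg"] - df["bg"]).to_numpy(dtype=float))
            if gene_of is None:
                gene_of = df["gene"]
    if len(samples) < 2:
        raise ValidationError("normalization needs >= 2 samples")
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate sample labels across arrays")
    V = np.column_stack(cols)  # (spots, samples)

    # re-reject spots with non-positive background-subtracted intensity
    bad = (V <= 0).any(axis=1)
    rerejected = [s for s, b in zip(kept_index, bad) if b]
    if bad.any():
        V = V[~bad]
        kept_index = kept_index[~bad]
        gene_of = gene_of[~bad]
    report.n_nonpositive = len(rerejected)
    report.rerejected_spots = rerejected

    # drop control spots (no gene symbol) and sort by gene for CSR layout
    real = (gene_of != "").to_numpy()
    V = V[real]
    gene_of = gene_of[real]
    kept_index = kept_index[real]
    order = np.argsort(gene_of.to_numpy(), kind="stable")
    V = V[order]
    gene_arr = gene_of.to_numpy()[order]
    spot_arr = kept_index.to_numpy()[order]
    genes, first, counts = np.unique(gene_arr, return_index=True, return_counts=True)
    # np.unique sorts; with the pre-sort above first indices are the CSR starts
    gene_ptr = np.concatenate([[0], np.cumsum(counts)])
    R = counts

    trace: list[float] = []
    for _ in range(max_iter):
        factors = np.array(
            [_median_gene_value(V[:, s], gene_ptr, R) for s in range(len(samples))]
        )
        V = V / factors[None, :]
        err = float(np.max(np.abs(factors - 1.0)) * 100.0)
        trace.append(err)
        if err < tol:
            break
    else:
        raise NonConvergenceError(trace)

    # split into per-phenotype tensors, replicas ordered by index
    parsed = [parse_sample_label(s) for s in samples]
    phens = list(dict.fromkeys(p for p, _ in parsed))
    tensors: dict[str, GeneSpotTensor] = {}
    for phen in phens:
        cols_idx = sorted(
            (k, j) for j, (p, k) in enumerate(parsed) if p == phen
        )
        sub = V[:, [j for _, j in cols_idx]]
        tensor = GeneSpotTensor(
            phen, list(genes), gene_ptr, sub, spot_ids=list(spot_arr)
        )
        med = np.median(tensor.ave())
        tensors[phen] = tensor.rescaled(1.0 / med)
    return NormalizedData(tensors=tensors, trace=trace, report=report)


def preprocess_experiment(
    tables: list[SpotTable], tol: float = 5.0, max_iter: int = 100
) -> NormalizedData:
    """Filter then normalize, the standard entry point."""
    kept, _ = filter_spots(tables)
    return normalize(tables, kept_spots=kept, tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# tensor (de)serialization: long TSV with columns phenotype,gene,spot,replica,value

def write_tensor(tensor: GeneSpotTensor, path: str) -> None:
    rows = []
    gene_of = tensor.gene_of_spot
    for flat, sid in enumerate(tensor.spot_ids):
        g = tensor.genes[gene_of[flat]]
        for xi in range(tensor.n_replicas):
            rows.append((tensor.phenotype, g, sid, xi + 1, tensor.values[flat, xi]))
    pd.DataFrame(
        rows, columns=["phenotype", "gene", "spot", "replica", "value"]
    ).to_csv(path, sep="\t", index=False)


def read_tensor(path: str) -> GeneSpotTensor:
    df = pd.read_csv(path, sep="\t")
    phen = df["phenotype"].iloc[0]
    piv = df.pivot_table(
        index=["gene", "spot"], columns="replica", values="value", sort=True
    )
    gene_level = piv.index.get_level_values("gene")
    genes, first, counts = np.unique(gene_level, return_index=True, return_counts=True)
    gene_ptr = np.concatenate([[0], np.cumsum(counts)])
    return GeneSpotTensor(
        phen,
        list(genes),
        gene_ptr,
        piv.to_numpy(),
        spot_ids=list(piv.index.get_level_values("spot")),
    )
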