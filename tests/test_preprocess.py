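import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genofabric.io_formats import SpotTable
from genofabric.preprocess import (
    StructuralError,
    filter_spots,
    normalize,
    preprocess_experiment,
    read_tensor,
    write_tensor,
)
from genofabric.synthetic_data import DesignConfig, generate_experiment


def _tables(spot_rows):
    """Build one single-sample SpotTable per sample from
    {sample: [(spot_id, gene, fg, bg, flag), ...]}."""
    out = []
    for sample, rows in spot_rows.items():
        df = pd.DataFrame(
            rows, columns=["spot_id", "gene", "fg", "bg", "flag"]
        )
        df.insert(2, "sample", sample)
        out.append(SpotTable(array_id=sample, data=df))
    return out


def _grid(fg_by_sample, bg_by_sample=None, flag_by_sample=None, n=4):
    samples = [f"P.{k}" for k in range(1, n + 1)] + [f"Q.{k}" for k in range(1, n + 1)]
    rows = {}
    for s in samples:
        fg = fg_by_sample.get(s, fg_by_sample.get("*", 100.0))
        bg = (bg_by_sample or {}).get(s, (bg_by_sample or {}).get("*", 10.0))
        fl = (flag_by_sample or {}).get(s, "ok")
        rows[s] = [("s1", "GeneA", fg, bg, fl), ("s2", "GeneB", 200.0, 10.0, "ok")]
    return _tables(rows)


def test_spot_kept_when_fg_twice_bg_everywhere():
    kept, report = filter_spots(_grid({"*": 100.0}, {"*": 49.0}))
    assert "s1" in kept and report.n_rejected == 0


def test_spot_rejected_if_low_signal_in_any_single_sample():
    tables = _grid({"*": 100.0}, {"*": 49.0})
    # push bg over fg/2 in exactly one of the samples
    tables[3].data.loc[tables[3].data["spot_id"] == "s1", "bg"] = 51.0
    kept, report = filter_spots(tables)
    assert "s1" not in kept and "s2" in kept
    assert report.n_low_signal == 1
    assert report.genes_lost == ["GeneA"]


def test_spot_rejected_if_corrupted_anywhere():
    tables = _grid({"*": 100.0}, flag_by_sample={})
    tables[0].data.loc[tables[0].data["spot_id"] == "s1", "flag"] = "corrupted"
    kept, report = filter_spots(tables)
    assert "s1" not in kept
    assert report.n_corrupted == 1


def test_mismatched_spot_universe_is_structural_error():
    tables = _grid({"*": 100.0})
    tables[1].data = tables[1].data[tables[1].data["spot_id"] != "s2"]
    with pytest.raises(StructuralError, match="s2"):
        filter_spots(tables)


def test_corrupted_counts_match_generator_oracle():
    cfg = DesignConfig(n_genes=150, corrupted_rate=0.1, seed=5)
    tables, truth = generate_experiment(cfg)
    kept, report = filter_spots(tables)
    # the generator's corrupted list is the oracle
    corrupted_spots = {sid for _, sid in truth.corrupted}
    assert report.n_corrupted == len(corrupted_spots)
    assert corrupted_spots.isdisjoint(kept)
    # per-(spot,sample) flags are Bernoulli(0.1): check 99% binomial bounds
    n_flags = sum(len(t.data) for t in tables)
    n_corrupt_flags = len(truth.corrupted)
    lo, hi = stats.binom.ppf([0.005, 0.995], n_flags, 0.1)
    assert lo <= n_corrupt_flags <= hi


def test_already_normalized_input_is_a_fixed_point():
    # median gene (GeneA) at exactly 1 after bg subtraction in every sample
    samples = [f"P.{k}" for k in range(1, 5)] + [f"Q.{k}" for k in range(1, 5)]
    tables = _tables(
        {
            s: [
                ("s1", "GeneA", 1.25, 0.25, "ok"),
                ("s2", "GeneB", 0.75, 0.25, "ok"),
                ("s3", "GeneC", 192.25, 0.25, "ok"),
            ]
            for s in samples
        }
    )
    result = normalize(tables)
    assert len(result.trace) == 1 and result.trace[0] == 0.0
    for phen in ("P", "Q"):
        tensor = result[phen]
        np.testing.assert_array_equal(tensor.values_for("GeneA"), 1.0)
        np.testing.assert_array_equal(tensor.values_for("GeneB"), 0.5)


def test_scale_invariance_of_normalization(tiny_experiment):
    tables, _ = tiny_experiment
    direct = preprocess_experiment(tables)
    scaled_tables = []
    for i, t in enumerate(tables):
        df = t.data.copy()
        if i == 0:  # one sample globally multiplied by a constant
            df[["fg", "bg"]] *= 10.0
        scaled_tables.append(SpotTable(array_id=t.array_id, data=df))
    rescaled = preprocess_experiment(scaled_tables)
    for phen in direct:
        np.testing.assert_allclose(
            rescaled[phen].values, direct[phen].values, rtol=1e-6
        )


def test_median_gene_ave_is_one_per_phenotype(tiny_normalized):
    for phen, tensor in tiny_normalized.items():
        tensor.validate()
        assert abs(np.median(tensor.ave()) - 1.0) < 1e-6


def test_error_trace_monotone_after_first_iteration(tiny_normalized):
    trace = tiny_normalized.trace
    assert len(trace) >= 1
    assert all(b <= a for a, b in zip(trace[1:], trace[2:]))
    assert trace[-1] < 5.0


def test_nonpositive_background_subtracted_spot_rerejected():
    # fg == bg == 0 passes the fg >= 2*bg filter but has no positive signal
    samples = [f"P.{k}" for k in range(1, 5)] + [f"Q.{k}" for k in range(1, 5)]
    tables = _tables(
        {
            s: [
                ("s1", "GeneA", 0.0, 0.0, "ok"),
                ("s2", "GeneB", 200.0, 10.0, "ok"),
                ("s3", "GeneC", 400.0, 10.0, "ok"),
            ]
            for s in samples
        }
    )
    result = normalize(tables)
    assert result.report.n_nonpositive == 1
    assert "s1" in result.report.rerejected_spots
    assert "GeneA" not in result["P"].genes


def test_tensor_round_trip(tmp_path, tiny_tensor):
    p = tmp_path / "t.tsv"
    write_tensor(tiny_tensor, p)
    back = read_tensor(p)
    assert back.phenotype == tiny_tensor.phenotype
    assert back.genes == tiny_tensor.genes
    np.testing.assert_allclose(
        np.sort(back.values, axis=0), np.sort(tiny_tensor.values, axis=0), rtol=1e-12
    )
    np.testing.assert_allclose(np.sort(back.ave()), np.sort(tiny_tensor.ave()))


def test_replica_means_match_spot_means(tiny_tensor):
    mu = tiny_tensor.spot_means
    np.testing.assert_allclose(mu, tiny_tensor.values.mean(axis=1))
    ave = tiny_tensor.ave()
    np.testing.assert_allclose(ave, tiny_tensor.replica_means().mean(axis=1))
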