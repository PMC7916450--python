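import itertools
import math

import numpy as np
import pandas as pd
import pytest

from genofabric.io_formats import GeneSet, InteractionList
from genofabric.networks import (
    build_fabric_network,
    compute_gch,
    distinct_pair_count,
    evaluate_interaction_consistency,
    gch_from_tensor,
    rank_gmr,
)
from genofabric.quantifiers import CoordinationAnalysis, PhenotypeQuantifiers

from _helpers import make_tensor


@pytest.mark.parametrize("n", range(1, 9))
def test_pair_count_matches_enumeration(n):
    brute = sum(1 for _ in itertools.combinations(range(n), 2))
    assert distinct_pair_count(n) == brute


def _fake_quantifiers(revs):
    genes = [f"g{i}" for i in range(len(revs))]
    table = pd.DataFrame(
        {"R": 1, "AVE": 1.0, "REV": revs, "df": 3, "chi2_correction": 7.1},
        index=pd.Index(genes, name="gene"),
    )
    return PhenotypeQuantifiers(phenotype="P", table=table)


def test_gch_closed_form_uncoordinated_average_gene():
    # REV equal to the universe mean and zero coordination -> GCH = 1/e
    q = _fake_quantifiers([20.0] * 10)
    sq = pd.Series(0.0, index=q.table.index)
    g = compute_gch(q, sq)
    np.testing.assert_allclose(g.table["GCH"], math.exp(-1.0), rtol=1e-12)


def test_gch_closed_form_quarter_squared_correlation():
    # COR^2 = 1/4 against every other gene -> exponent (4/N)(N-1)/4 - 1 = -1/N
    N = 400
    q = _fake_quantifiers([20.0] * N)
    sq = pd.Series((N - 1) / 4.0, index=q.table.index)
    g = compute_gch(q, sq)
    np.testing.assert_allclose(g.table["GCH"], math.exp(-1.0 / N), rtol=1e-12)
    np.testing.assert_allclose(g.table["GCH"], 1.0, atol=2.0 / N)


def test_halving_rev_doubles_gch():
    q = _fake_quantifiers([10.0, 20.0, 20.0, 20.0, 20.0, 20.0, 20.0, 30.0])
    sq = pd.Series(1.0, index=q.table.index)
    g = compute_gch(q, sq).table
    assert g.loc["g0", "GCH"] == pytest.approx(2 * g.loc["g1", "GCH"])


def test_gch_flags_zero_rev_separately():
    q = _fake_quantifiers([0.0, 20.0, 30.0])
    sq = pd.Series(1.0, index=q.table.index)
    g = compute_gch(q, sq)
    assert g.infinite_control == ["g0"]
    assert "g0" not in g.table.index
    assert set(g.table["rank"]) == {1, 2}


def test_gch_invariant_under_global_rescaling(tiny_tensor):
    base = gch_from_tensor(tiny_tensor)
    scaled = gch_from_tensor(tiny_tensor.rescaled(3.7))
    np.testing.assert_allclose(
        scaled.table["GCH"], base.table["GCH"], rtol=1e-9
    )
    assert list(scaled.table["rank"]) == list(base.table["rank"])


def test_ranking_permutation_invariant_and_tie_broken_by_symbol():
    q = _fake_quantifiers([20.0, 20.0, 10.0])
    sq = pd.Series(1.0, index=q.table.index)
    g1 = compute_gch(q, sq)
    shuffled = PhenotypeQuantifiers(
        phenotype="P", table=q.table.iloc[[2, 0, 1]]
    )
    g2 = compute_gch(shuffled, sq)
    assert g1.gmr == g2.gmr == "g2"  # lowest REV wins
    top = rank_gmr(g1, top_k=3)
    assert list(top.index) == ["g2", "g0", "g1"]  # g0/g1 tie -> lexicographic


def test_low_rev_coordinated_hub_becomes_gmr():
    """A gene with the tightest expression control that is also strongly
    coordinated with a fifth of the universe must top the hierarchy."""
    rng = np.random.default_rng(42)
    z = rng.standard_normal(4)
    data = {}
    data["Hub"] = [list(1.0 + 0.02 * z)]
    for j in range(20):  # coordinated followers, slightly noisier than the hub
        noise = rng.normal(0, 0.01, 4)
        data[f"M{j:02d}"] = [list(1.0 + 0.08 * z + noise)]
    for j in range(79):  # uncoordinated background with loose control
        data[f"B{j:02d}"] = [list(1.0 + rng.normal(0, 0.3, 4))]
    t = make_tensor(data)
    g = gch_from_tensor(t)
    assert g.gmr == "Hub"
    top = set(rank_gmr(g, top_k=21).index)
    assert sum(name.startswith(("Hub", "M")) for name in top) >= 18


# --- fabric networks ---------------------------------------------------


def test_network_partitions_and_count_conservation(module_normalized):
    t = module_normalized["MRLp"]
    coan = CoordinationAnalysis(t)
    set_a = GeneSet(name="A", genes=[f"G{i:05d}" for i in range(1, 16)])
    set_b = GeneSet(name="B", genes=[f"G{i:05d}" for i in range(11, 26)])
    net = build_fabric_network(coan, set_a, set_b)
    assert set(net.partitions.values()) <= {"a_only", "b_only", "both"}
    expected_both = len(
        {f"G{i:05d}" for i in range(11, 16)} & set(t.genes)
    )
    assert sum(p == "both" for p in net.partitions.values()) == expected_both
    n_nodes = len(net.partitions)
    assert len(net.edges) == distinct_pair_count(n_nodes)
    counted = sum(net.class_counts.values())
    n_undef = int((net.edges["class"] == "undefined").sum())
    assert counted + n_undef == len(net.edges)
    assert not (net.edges["gene_a"] == net.edges["gene_b"]).any()


def test_network_same_set_has_single_partition(module_normalized):
    t = module_normalized["MRLp"]
    coan = CoordinationAnalysis(t)
    s = GeneSet(name="A", genes=[f"G{i:05d}" for i in range(1, 11)])
    net = build_fabric_network(coan, s, s)
    assert set(net.partitions.values()) == {"both"}
    n = len(net.partitions)
    assert len(net.edges) == distinct_pair_count(n)  # no duplicated pairs


def test_planted_module_dominates_synergistic_count(module_normalized):
    t = module_normalized["MRLp"]
    coan = CoordinationAnalysis(t)
    # module 1 genes split across the two sets, plus unrelated background genes
    set_a = GeneSet(name="A", genes=[f"G{i:05d}" for i in range(1, 6)] + ["G00101", "G00102"])
    set_b = GeneSet(name="B", genes=[f"G{i:05d}" for i in range(6, 11)] + ["G00103", "G00104"])
    net = build_fabric_network(coan, set_a, set_b)
    module = {f"G{i:05d}" for i in range(1, 11)}
    syn = net.edges[net.edges["class"] == "synergistic"]
    in_module = syn["gene_a"].isin(module) & syn["gene_b"].isin(module)
    assert in_module.sum() >= 0.8 * len(syn)
    assert net.class_counts["synergistic"] >= distinct_pair_count(8)


def test_networkx_export(module_normalized):
    t = module_normalized["MRLp"]
    coan = CoordinationAnalysis(t)
    s = GeneSet(name="A", genes=[f"G{i:05d}" for i in range(1, 11)])
    net = build_fabric_network(coan, s, s)
    g = net.to_networkx()
    assert g.number_of_nodes() == len(net.partitions)
    assert g.number_of_edges() == net.class_counts["synergistic"] + net.class_counts["antagonistic"]


# --- interaction-list sign consistency ---------------------------------


def _consistency_fixture():
    """Center gene plus partners engineered to known coordination classes."""
    tensor = make_tensor(
        {
            "Akt2": [[1.0, 2.0, 3.0, 4.0]],
            "SynPartner": [[2.0, 4.0, 6.0, 8.0]],     # COR = +1
            "AntPartner": [[4.0, 3.0, 2.0, 1.0]],     # COR = -1
            "IndPartner": [[5.0, 3.0, 3.0, 5.0]],     # orthogonal -> COR = 0
            "FlatPartner": [[5.0, 5.0, 5.0, 5.0]],    # zero variance -> undefined
        }
    )
    coan = CoordinationAnalysis(tensor)
    return coan


@pytest.mark.parametrize(
    "partner,role,verdict",
    [
        ("SynPartner", "upstream_activator", "confirms"),
        ("SynPartner", "downstream_inhibited", "contradicts"),
        ("AntPartner", "upstream_inhibitor", "confirms"),
        ("AntPartner", "downstream_activated", "contradicts"),
        ("IndPartner", "upstream_activator", "unresolved"),
        ("FlatPartner", "upstream_activator", "unresolved"),
    ],
)
def test_consistency_verdicts(partner, role, verdict):
    coan = _consistency_fixture()
    ilist = InteractionList(
        center_block=["Akt2"],
        partners=pd.DataFrame({"gene": [partner], "role": [role]}),
    )
    report = evaluate_interaction_consistency(coan, ilist)
    assert list(report.table["verdict"]) == [verdict]


def test_all_independent_partners_resolve_nothing():
    coan = _consistency_fixture()
    ilist = InteractionList(
        center_block=["Akt2"],
        partners=pd.DataFrame(
            {
                "gene": ["IndPartner"],
                "role": ["downstream_activated"],
            }
        ),
    )
    report = evaluate_interaction_consistency(coan, ilist)
    assert report.n_confirmations == 0 and report.n_contradictions == 0
    assert report.group_counts.loc["downstream_activated", "independent"] == 1


def test_missing_partner_reported_not_fatal():
    coan = _consistency_fixture()
    ilist = InteractionList(
        center_block=["Akt2"],
        partners=pd.DataFrame(
            {"gene": ["SynPartner", "NotOnChip"], "role": ["upstream_activator"] * 2}
        ),
    )
    report = evaluate_interaction_consistency(coan, ilist)
    assert report.missing == ["NotOnChip"]
    assert len(report.table) == 1
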