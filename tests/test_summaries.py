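import math

import numpy as np
import pytest

from conftest import make_matrix

from barcodegap import (
    BarcodeDataset,
    SequenceRecord,
    SpecimenMetadata,
    diagnose_species,
    distance_matrix,
    fold_ratio,
    level_partition,
    midpoint_root,
    neighbor_joining,
    nearest_neighbors,
    render_fold,
)
from barcodegap.summaries import LevelSummary, assign_bin, level_table


def dataset(rows):
    """rows: (id, species, genus, family, clade). Sequences are placeholders;
    tests pair this with a hand-built distance matrix."""
    recs = [SequenceRecord(id=r[0], seq="ACGTACGT") for r in rows]
    meta = [
        SpecimenMetadata(id=r[0], species=r[1], genus=r[2],
                         family=r[3] if len(r) > 3 else "F",
                         order="O", clade=r[4] if len(r) > 4 else "unassigned")
        for r in rows
    ]
    return BarcodeDataset(records=recs, meta=meta)


def test_two_identical_conspecifics():
    ds = dataset([("a", "sp1", "G"), ("b", "sp1", "G")])
    m = make_matrix(["a", "b"], [[0, 0], [0, 0]])
    rows = {r.level: r for r in level_partition(m, ds)}
    r = rows["within_species"]
    assert (r.n_comparisons, r.min, r.mean, r.max) == (1, 0.0, 0.0, 0.0)


def test_two_species_hand_count():
    # 2 species x 2 individuals, one genus: intra 0.01, cross 0.05
    ds = dataset([("a1", "sp1", "G"), ("a2", "sp1", "G"), ("b1", "sp2", "G"), ("b2", "sp2", "G")])
    D = np.full((4, 4), 0.05)
    D[0, 1] = D[1, 0] = 0.01
    D[2, 3] = D[3, 2] = 0.01
    np.fill_diagonal(D, 0)
    rows = {r.level: r for r in level_partition(make_matrix(["a1", "a2", "b1", "b2"], D), ds)}
    ws, wg = rows["within_species"], rows["within_genus_among_species"]
    assert (ws.n_comparisons, ws.mean) == (2, pytest.approx(1.0))  # percent
    assert (wg.n_comparisons, wg.mean) == (4, pytest.approx(5.0))
    assert fold_ratio(list(rows.values())) == pytest.approx(5.0)


def test_partition_is_complete(scenario, scenario_matrix):
    ds, _ = scenario
    rows = level_partition(scenario_matrix, ds)
    n = len(ds)
    assert sum(r.n_comparisons for r in rows) == n * (n - 1) // 2 - scenario_matrix.n_missing


def test_level_means_are_ordered(scenario, scenario_matrix):
    ds, _ = scenario
    rows = {r.level: r for r in level_partition(scenario_matrix, ds)}
    assert rows["within_species"].mean < rows["within_genus_among_species"].mean
    assert rows["within_genus_among_species"].mean < rows["within_family_among_genera"].mean
    df = level_table(level_partition(scenario_matrix, ds))
    assert list(df.index) == [
        "within_species", "within_genus_among_species",
        "within_family_among_genera", "within_order_among_families",
    ]


def test_fold_ratio_rendering_and_degenerate_cases():
    def rows(ws_mean, wg_mean):
        mk = lambda lvl, mean: LevelSummary(lvl, 2, 2, 1, 0, mean, mean, 0.001)
        return [mk("within_species", ws_mean), mk("within_genus_among_species", wg_mean)]

    assert fold_ratio(rows(0.65, 9.20)) == pytest.approx(14.1538, abs=1e-3)
    assert render_fold(fold_ratio(rows(0.65, 9.20))) == "14-fold"
    assert fold_ratio(rows(1.0, 1.0)) == pytest.approx(1.0)
    with pytest.raises(ZeroDivisionError):
        fold_ratio(rows(0.0, 9.2))


def test_bin_edges_half_open():
    assert assign_bin(0.0) == "<0.1"
    assert assign_bin(0.0999) == "<0.1"
    assert assign_bin(0.1) == "0.1-1.0"
    assert assign_bin(1.0) == "1.0-2.7"
    assert assign_bin(2.7) == ">2.7"


def test_nearest_neighbors_hand_assignment():
    # 3 singleton species at pairwise min distances 0.5%, 3%, 3%
    ds = dataset([("a", "sp1", "G"), ("b", "sp2", "G"), ("c", "sp3", "G")])
    D = np.array([[0, 0.005, 0.03], [0.005, 0, 0.03], [0.03, 0.03, 0.0]])
    rep = nearest_neighbors(make_matrix(["a", "b", "c"], D), ds)
    bins = {r.species: r.bin for r in rep.records}
    assert bins == {"sp1": "0.1-1.0", "sp2": "0.1-1.0", "sp3": ">2.7"}
    nn = {r.species: r.nn_species for r in rep.records}
    assert nn["sp1"] == "sp2" and nn["sp2"] == "sp1"  # mutual nearest neighbours
    assert rep.by_genus.loc["G", "n_species"] == 3


def test_shared_haplotype_pair_binned_at_zero():
    ds = dataset([("a", "sp1", "G"), ("b", "sp2", "G")])
    rep = nearest_neighbors(make_matrix(["a", "b"], [[0, 0], [0, 0]]), ds)
    assert all(r.nn_distance == 0 and r.bin == "<0.1" for r in rep.records)


def _diag_by_species(m, t, ds, **kw):
    return {d.species: d for d in diagnose_species(m, t, ds, **kw)}


def test_haplotype_sharing_makes_both_mixed():
    ds = dataset([
        ("a1", "sp1", "G"), ("a2", "sp1", "G"),
        ("b1", "sp2", "G"), ("c1", "sp3", "G"),
    ])
    # sp1's a2 shares a haplotype with sp2's b1 (distance 0)
    D = np.array([
        [0.0, 0.002, 0.002, 0.05],
        [0.002, 0.0, 0.0, 0.05],
        [0.002, 0.0, 0.0, 0.05],
        [0.05, 0.05, 0.05, 0.0],
    ])
    m = make_matrix(["a1", "a2", "b1", "c1"], D)
    t = midpoint_root(neighbor_joining(m))
    diags = _diag_by_species(m, t, ds)
    assert diags["sp1"].status == "mixed" and diags["sp2"].status == "mixed"
    assert diags["sp1"].shares_haplotype_with == frozenset({"sp2"})
    assert diags["sp1"].min_interspecific == 0.0
    assert diags["sp3"].status == "captured"


def test_scenario_diagnosis_recovers_planted_lineages(scenario, scenario_matrix, scenario_tree):
    ds, gt = scenario
    diags = diagnose_species(scenario_matrix, scenario_tree, ds, new_localities=gt.new_lineages)
    flagged = {d.species for d in diags if d.status == "new_lineage_candidate"}
    assert flagged == set(gt.new_lineages)
    assert all(d.status == "captured" for d in diags if d.species not in gt.new_lineages)


def test_diagnosis_invariant_to_individual_order(scenario, scenario_matrix, scenario_tree):
    ds, gt = scenario
    perm = np.random.default_rng(0).permutation(len(ds))
    recs = [ds.records[i] for i in perm]
    meta = [ds.meta[i] for i in perm]
    ds2 = BarcodeDataset(records=recs, meta=meta)
    m2 = distance_matrix(ds2)
    d1 = _diag_by_species(scenario_matrix, scenario_tree, ds, new_localities=gt.new_lineages)
    d2 = _diag_by_species(m2, scenario_tree, ds2, new_localities=gt.new_lineages)
    assert {s: d.status for s, d in d1.items()} == {s: d.status for s, d in d2.items()}


def test_nn_distance_bounded_by_mean_between_species(scenario, scenario_matrix):
    ds, _ = scenario
    rep = nearest_neighbors(scenario_matrix, ds)
    mf = ds.meta_frame()
    sp_of = mf["species"]
    for r in rep.records[:10]:
        mask_a = (sp_of == r.species).to_numpy()
        mask_b = (sp_of == r.nn_species).to_numpy()
        block = scenario_matrix.d[np.ix_(mask_a, mask_b)]
        assert r.nn_distance / 100 <= np.nanmean(block) + 1e-12
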