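import numpy as np
import pytest

from conftest import make_matrix

from barcodegap import (
    BarcodeDataset,
    CladePairStat,
    GeologicalEvent,
    RateHypothesis,
    SequenceRecord,
    SpecimenMetadata,
    age_estimate,
    calibrate_rate,
    clade_stats,
    dating_report,
)
from barcodegap.dating import LENGGURU, MOK, RATE_HYPOTHESES, round_rate


def stat(pair, mean_d):
    return CladePairStat(pair=pair, mean_d=mean_d, se_d=0.0, n_pairs=1)


def test_age_is_distance_over_rate():
    assert age_estimate(stat("I vs II", 0.137), RateHypothesis("minimum", 0.005)).age == pytest.approx(27.4)
    assert age_estimate(stat("III vs IV", 0.105), RateHypothesis("fish", 0.012)).age == pytest.approx(8.75, abs=1e-9)
    assert age_estimate(stat("x", 0.0), RateHypothesis("any", 0.01)).age == 0.0


def test_age_linearity_properties():
    h = RateHypothesis("r", 0.01)
    a1 = age_estimate(stat("p", 0.05), h).age
    a2 = age_estimate(stat("p", 0.10), h).age
    assert a2 == pytest.approx(2 * a1)
    assert age_estimate(stat("p", 0.05), RateHypothesis("r2", 0.02)).age == pytest.approx(a1 / 2)


def test_calibration_bounds():
    cal = calibrate_rate(stat("I vs II", 0.137), GeologicalEvent("lengguru", 8, 11))
    assert round_rate(cal.rate_min, cal.rate_max) == (0.012, 0.017)
    cal2 = calibrate_rate(stat("within IB", 0.032), GeologicalEvent("mok", 1.65, 3.4))
    assert round_rate(cal2.rate_min, cal2.rate_max) == (0.0094, 0.0194)
    cal3 = calibrate_rate(stat("p", 0.1), GeologicalEvent("pt", 5, 5))
    assert cal3.rate_min == cal3.rate_max


def test_calibration_rejects_bad_ages():
    with pytest.raises(ValueError):
        GeologicalEvent("bad", 0, 4)
    with pytest.raises(ValueError):
        GeologicalEvent("bad", 5, 3)


def test_age_rate_round_trip():
    # dating a divergence under rate r and calibrating on the resulting age
    # must return r exactly (pre-rounding)
    s = stat("p", 0.0821)
    for h in RATE_HYPOTHESES:
        age = age_estimate(s, h).age
        cal = calibrate_rate(s, GeologicalEvent("ev", age, age))
        assert cal.rate_min == pytest.approx(h.rate, rel=1e-12)


def _clade_dataset():
    # clade A: 2 species x 1 individual, clade B: 1 species
    rows = [
        ("a1", "sp1", "A"), ("a2", "sp1", "A"), ("a3", "sp2", "A"),
        ("b1", "sp3", "B"),
    ]
    recs = [SequenceRecord(id=r[0], seq="ACGTACGT") for r in rows]
    meta = [SpecimenMetadata(id=r[0], species=r[1], genus="G", family="F",
                             order="O", clade=r[2]) for r in rows]
    return BarcodeDataset(records=recs, meta=meta)


def test_clade_stats_use_heterospecific_pairs_only():
    ds = _clade_dataset()
    D = np.array([
        [0.0, 0.004, 0.02, 0.10],
        [0.004, 0.0, 0.03, 0.10],
        [0.02, 0.03, 0.0, 0.12],
        [0.10, 0.10, 0.12, 0.0],
    ])
    stats = {s.pair: s for s in clade_stats(make_matrix(["a1", "a2", "a3", "b1"], D), ds)}
    # conspecific a1-a2 (0.004) excluded; within A = mean(0.02, 0.03)
    assert stats["within A"].mean_d == pytest.approx(0.025)
    assert stats["within A"].n_pairs == 2
    # clade B has a single species: no within stat
    assert "within B" not in stats
    assert stats["A vs B"].mean_d == pytest.approx(np.mean([0.10, 0.10, 0.12]))
    assert stats["A vs B"].n_pairs == 3


def test_within_clade_hand_mean():
    rows = [("a", "sp1", "A"), ("b", "sp2", "A"), ("c", "sp3", "A")]
    recs = [SequenceRecord(id=r[0], seq="ACGTACGT") for r in rows]
    meta = [SpecimenMetadata(id=r[0], species=r[1], genus="G", clade=r[2]) for r in rows]
    ds = BarcodeDataset(records=recs, meta=meta)
    D = np.array([[0, 0.02, 0.03], [0.02, 0, 0.04], [0.03, 0.04, 0.0]])
    stats = {s.pair: s for s in clade_stats(make_matrix(["a", "b", "c"], D), ds)}
    assert stats["within A"].mean_d == pytest.approx(0.03)


def test_dating_report_concordance_attachment():
    stats = [stat("I vs II", 0.137), stat("within IB", 0.032), stat("within I", 0.059)]
    rep = dating_report(stats)
    assert rep.concordance["I vs II"] == ["fish"]
    assert "within I" not in rep.concordance  # no event attached
    row = rep.table.loc["I vs II"]
    assert row["age_minimum_Myr"] == 27.4
    assert row["age_fish_Myr"] == 11.4
    assert (row["rate_min"], row["rate_max"]) == (0.012, 0.017)
    mok_row = rep.table.loc["within IB"]
    assert (mok_row["rate_min"], mok_row["rate_max"]) == (0.0094, 0.0194)


def test_dating_report_without_events_has_ages_only():
    rep = dating_report([stat("I vs II", 0.137)], events=())
    assert rep.concordance == {}
    assert "rate_min" not in rep.table.columns
    assert rep.table.loc["I vs II", "age_vertebrate_Myr"] == pytest.approx(6.9, abs=0.051)


def test_simulated_clade_depth_recovered():
    """Cross-clade mean_d recovers the planted divergence without bias.

    Within one cohort all cross-clade pairs share the two deep branches, so
    mean_d carries single-realization noise no matter how many pairs enter
    the average; the unbiasedness check therefore averages replicate cohorts
    and uses their empirical Monte-Carlo error.
    """
    from barcodegap import distance_matrix
    from barcodegap.simulate import SimulationConfig, evolve_sequences, simulate_tree

    vals = []
    for rep in range(12):
        cfg = SimulationConfig(seed=500 + rep, n_clades=2, species_per_clade=3,
                               individuals_per_species=2, n_new_lineages=0,
                               seq_length=2000, stop_free=False)
        gt = simulate_tree(cfg)
        ds = evolve_sequences(gt, cfg)
        stats = {s.pair: s for s in clade_stats(distance_matrix(ds), ds)}
        vals.append(stats["I vs II"].mean_d)
    expected = 2 * 0.0685
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - expected) <= 3 * se


def test_calibration_interval_covers_true_rate():
    """Simulated clades dated by the true event recover the true rate."""
    from barcodegap.simulate import SimulationConfig, evolve_sequences, simulate_tree
    from barcodegap import distance_matrix

    hits = 0
    n_rep = 30
    for rep in range(n_rep):
        cfg = SimulationConfig(seed=1000 + rep, n_clades=2, species_per_clade=3,
                               individuals_per_species=2, n_new_lineages=0,
                               seq_length=5000, stop_free=False,
                               true_rate=0.012, true_event_age=10.0)
        gt = simulate_tree(cfg)
        ds = evolve_sequences(gt, cfg)
        m = distance_matrix(ds)
        stats = {s.pair: s for s in clade_stats(m, ds)}
        cal = calibrate_rate(stats["I vs II"], GeologicalEvent("ev", 8, 11))
        if cal.rate_min <= 0.012 <= cal.rate_max:
            hits += 1
    assert hits >= 0.9 * n_rep
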