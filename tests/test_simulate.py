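"""Simulator determinism, identifiability and recovery properties."""

from __future__ import annotations

import pytest

from ttgedyn import (PERSISTENT, GelSimParams, GlotuSimParams, SimConfig,
                     analyze_cohort, colonization_status,
                     evaluate_recovery, render_gels, reconcile_bands,
                     simulate_cohort, truth_timeline)
from ttgedyn.errors import ConfigError
from ttgedyn.simulate import HETERODUPLEX

NOISELESS = GelSimParams(slope_range=(1.0, 1.0),
                         intercept_range=(0.0, 0.0), jitter_sd=0.0,
                         heteroduplex_prob=0.0, spurious_rate=0.0,
                         failure_prob=0.0)


def run_pipeline(config):
    truth = simulate_cohort(config)
    rendered = render_gels(truth, config)
    timeline, assignments = analyze_cohort(
        rendered, list(config.standards_reference), config.ladder())
    return truth, rendered, timeline, assignments


def test_determinism_same_seed_same_gels():
    a = render_gels(simulate_cohort(SimConfig(seed=5)), SimConfig(seed=5))
    b = render_gels(simulate_cohort(SimConfig(seed=5)), SimConfig(seed=5))
    assert len(a) == len(b)
    for (ia, da, fa), (ib, db, fb) in zip(a, b):
        assert (ia, da, fa.sample_id) == (ib, db, fb.sample_id)
        assert [(x.distance_raw, x.intensity_class) for x in fa.bands] \
            == [(x.distance_raw, x.intensity_class) for x in fb.bands]


def test_different_seeds_differ():
    a = render_gels(simulate_cohort(SimConfig(seed=5)), SimConfig(seed=5))
    b = render_gels(simulate_cohort(SimConfig(seed=6)), SimConfig(seed=6))
    assert [f.sample_id for _, _, f in a] != \
        [f.sample_id for _, _, f in b] or \
        [x.distance_raw for _, _, f in a for x in f.bands] != \
        [x.distance_raw for _, _, f in b for x in f.bands]


def test_config_validation():
    with pytest.raises(ConfigError):
        SimConfig(seed=1, dropout_prob=1.5)
    with pytest.raises(ConfigError):
        GlotuSimParams({1: 0.7, 2: 0.6}, 0.5,
                       {1: 1.0}).validate("bad")
    with pytest.raises(ConfigError):
        SimConfig(seed=1, gel=GelSimParams(heteroduplex_prob=-0.1))


def test_onset_beyond_study_window_never_colonizes():
    config = SimConfig(
        seed=3, n_infants=10, gel=NOISELESS, dropout_prob=0.0,
        glotus={"Enterococcus": GlotuSimParams({9: 1.0}, 0.9,
                                               {3: 1.0})},
        slotu_pool={"Enterococcus": [("Enterococcus faecalis", 35.0)]})
    truth = simulate_cohort(config)
    assert all(not scores for scores in truth.scores.values())


def test_persistence_one_forces_persistent_status():
    config = SimConfig(
        seed=3, n_infants=8, gel=NOISELESS, dropout_prob=0.0,
        glotus={"Staphylococcus": GlotuSimParams({1: 1.0}, 1.0,
                                                 {3: 1.0})},
        slotu_pool={"Staphylococcus": [
            ("Staphylococcus epidermidis group", 20.0)]})
    truth, _, timeline, _ = run_pipeline(config)
    for infant in timeline.infant_ids:
        st = colonization_status(timeline, infant,
                                 "Staphylococcus epidermidis group")
        assert st.status == PERSISTENT


def test_single_taxon_sample_never_gets_heteroduplex():
    config = SimConfig(
        seed=11, n_infants=10,
        gel=GelSimParams(heteroduplex_prob=1.0, spurious_rate=0.0,
                         failure_prob=0.0, jitter_sd=0.0,
                         slope_range=(1.0, 1.0),
                         intercept_range=(0.0, 0.0)),
        glotus={"Staphylococcus": GlotuSimParams({1: 1.0}, 1.0,
                                                 {3: 1.0})},
        slotu_pool={"Staphylococcus": [
            ("Staphylococcus epidermidis group", 20.0)]})
    truth = simulate_cohort(config)
    render_gels(truth, config)
    assert all(p != HETERODUPLEX
               for p, _ in truth.provenance.values())


def test_zero_noise_round_trip_is_lossless():
    """With no jitter, artifacts or failures the pipeline reproduces the
    ground truth exactly: presence, scores and colonization statuses."""
    config = SimConfig(seed=42, gel=NOISELESS)
    truth, rendered, timeline, assignments = run_pipeline(config)
    for (infant, day), scores in truth.scores.items():
        rec = [r for r in timeline.records
               if (r.infant_id, r.day) == (infant, day)]
        assert len(rec) == 1 and rec[0].scores == scores
    report = evaluate_recovery(assignments, timeline, truth)
    assert report.affiliation_precision == 1.0
    assert report.affiliation_recall == 1.0
    assert report.score_agreement == 1.0
    assert report.status_agreement == 1.0
    assert report.nd_rate == 0.0


def test_affine_distortion_restored_through_standards():
    """Per-gel affine stretches are removed exactly (up to jitter, here
    zero) because the three standards pin the warp."""
    config = SimConfig(seed=9, n_infants=6, gel=GelSimParams(
        slope_range=(1.15, 1.25), intercept_range=(2.0, 3.0),
        jitter_sd=0.0, heteroduplex_prob=0.0, spurious_rate=0.0,
        failure_prob=0.0))
    truth, rendered, timeline, assignments = run_pipeline(config)
    positions = {s: p for pool in config.slotu_pool.values()
                 for s, p in pool}
    flat = [a for v in assignments.values() for a in v]
    assert flat and all(a.status == "affiliated" for a in flat)
    for a in flat:
        assert a.match_delta == pytest.approx(0.0, abs=1e-9)
    report = evaluate_recovery(assignments, timeline, truth)
    assert report.affiliation_recall == 1.0
    assert positions  # ladder defined for every simulated SLOTU


def test_default_artifact_and_nd_rates_are_realistic():
    """Default gel model produces roughly a quarter artifact bands and a
    small not-determined fraction, the regime the pipeline targets."""
    config = SimConfig(seed=1)
    truth, rendered, timeline, assignments = run_pipeline(config)
    flat = [a for v in assignments.values() for a in v]
    acc = reconcile_bands(flat)
    artifact_frac = acc.n_artifact / acc.n_detected
    nd_frac = acc.n_unassigned / acc.n_detected
    assert 0.15 <= artifact_frac <= 0.35
    assert 0.02 <= nd_frac <= 0.14
    # sampling depth matches the emulated cohort: 4-15 samples per infant
    per_infant = {}
    for infant, _, _ in rendered:
        per_infant[infant] = per_infant.get(infant, 0) + 1
    assert 3 <= min(per_infant.values())
    assert max(per_infant.values()) <= 16
    assert 9 <= sum(per_infant.values()) / len(per_infant) <= 14


def test_artifact_flagging_quality_under_default_noise():
    config = SimConfig(seed=2)
    truth, _, timeline, assignments = run_pipeline(config)
    report = evaluate_recovery(assignments, timeline, truth)
    assert report.artifact_sensitivity > 0.9
    assert report.artifact_specificity > 0.95
    assert report.affiliation_precision > 0.98


def test_jitter_degrades_affiliation():
    """Positional jitter far beyond the matching tolerance must hurt
    recall relative to mild jitter."""
    def recall(jitter):
        config = SimConfig(seed=4, n_infants=15, gel=GelSimParams(
            jitter_sd=jitter, heteroduplex_prob=0.0, spurious_rate=0.0,
            failure_prob=0.0))
        truth, _, timeline, assignments = run_pipeline(config)
        return evaluate_recovery(assignments, timeline,
                                 truth).affiliation_recall

    assert recall(0.05) > recall(2.5) + 0.2


def test_parameter_recovery_at_n100():
    """Onset-week shares and persistence estimated from pipeline output
    sit within binomial sampling error of the generator's values."""
    glotu = "Staphylococcus"
    config = SimConfig(seed=2024, n_infants=100, dropout_prob=0.0,
                       gel=NOISELESS)
    truth, rendered, timeline, assignments = run_pipeline(config)
    params = config.glotus[glotu]
    members = {s for s, _ in config.slotu_pool[glotu]}
    n_pos = n_tot = 0
    onset_week1 = colonized = 0
    for infant in timeline.infant_ids:
        series = []
        for rec in timeline.samples_of(infant):
            pos = any(rec.scores.get(m, 0) > 0 for m in members)
            series.append((rec.day, int(pos)))
        first = next((i for i, (_, p) in enumerate(series) if p), None)
        if first is None:
            continue
        colonized += 1
        from ttgedyn import week_of_life
        if week_of_life(series[first][0]) == 1:
            onset_week1 += 1
        subsequent = series[first + 1:]
        n_pos += sum(p for _, p in subsequent)
        n_tot += len(subsequent)
    assert colonized == 100  # onset distribution sums to 1
    est_persistence = n_pos / n_tot
    # ~1000 Bernoulli draws -> se ~ 0.01; allow 4 se
    assert est_persistence == pytest.approx(params.persistence,
                                            abs=0.04)
    est_week1 = onset_week1 / colonized
    # 100 draws at p = 0.85 -> se ~ 0.036; allow ~4 se
    assert est_week1 == pytest.approx(params.onset_week[1], abs=0.15)
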