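"""Synthetic cohort generator: power-law calibration, determinism,
distributional structure, note rendering."""

import numpy as np
import pytest

from excurves.errors import CalibrationError, GenerationError
from excurves.simulate import (
    CohortConfig,
    calibrate_zipf,
    esi_tilted_probs,
    expected_bucket_fractions,
    expected_topics_per_encounter,
    generate_cohort,
    render_note,
    write_cohort,
    zipf_probs,
)


class TestCalibrateZipf:
    def test_uniform_targets_give_exponent_zero(self):
        # two topics, draws split evenly -> both land in the same bucket;
        # the flat exponent is the smallest solution on the grid
        f = expected_bucket_fractions(2, 0.0, 40)
        s = calibrate_zipf(2, 40, f)
        assert s == 0.0

    def test_objective_matches_direct_summation_oracle(self):
        # oracle: sum the truncated power law by hand at s=1, n=10
        n, s, total = 10, 1.0, 1000
        weights = np.array([1 / k for k in range(1, n + 1)])
        probs = weights / weights.sum()
        counts = total * probs
        oracle = (
            float((counts > 100).sum()) / n,
            float(((counts >= 10) & (counts <= 100)).sum()) / n,
            float((counts < 10).sum()) / n,
        )
        assert expected_bucket_fractions(n, s, total) == pytest.approx(oracle)

    def test_returned_exponent_minimizes_grid_objective(self):
        targets = (0.055, 0.317, 0.628)
        s = calibrate_zipf(895, 244255, targets, error_threshold=1.0)

        def err(x):
            f = expected_bucket_fractions(895, x, 244255)
            return sum((a - b) ** 2 for a, b in zip(f, targets))

        best = err(s)
        for x in np.arange(0.0, 3.0001, 0.01):
            assert best <= err(float(x)) + 1e-15

    def test_unattainable_targets_raise_with_best_exponent(self):
        with pytest.raises(CalibrationError) as exc:
            calibrate_zipf(895, 244255, (0.055, 0.317, 0.628), error_threshold=1e-8)
        assert 0.0 <= exc.value.best_exponent <= 3.0
        assert exc.value.best_error > 1e-8

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            calibrate_zipf(10, 0, (0.1, 0.2, 0.3))
        with pytest.raises(ValueError):
            calibrate_zipf(10, 100, (0.5, 0.5, 0.5))


class TestHelpers:
    def test_zipf_probs_normalized_and_monotone(self):
        p = zipf_probs(50, 1.3)
        assert p.sum() == pytest.approx(1.0)
        assert (np.diff(p) < 0).all()

    def test_expected_topics_per_encounter_cap(self):
        # with no cap the shifted-Poisson mean is 1 + lambda
        assert expected_topics_per_encounter(2.0, 1000) == pytest.approx(3.0)
        assert expected_topics_per_encounter(2.0, 8) < 3.0
        assert expected_topics_per_encounter(2.0, 8) > 2.9

    def test_esi_tilt_hits_target_mean(self):
        base = (1.2, 24.1, 65.7, 8.2, 0.8)
        for target in (2.94, 2.87, 2.85, 2.79):
            p = esi_tilted_probs(base, target)
            assert p.sum() == pytest.approx(1.0)
            assert float((p * np.arange(1, 6)).sum()) == pytest.approx(target, abs=1e-9)


class TestRenderNote:
    def test_affirmed_mention_appears_in_mdm(self):
        note = render_note(["chest pain"], [])
        assert "chest pain" in note["MDM"].lower()
        assert list(note.keys()) == ["HPI", "MDM", "ED_COURSE"]

    def test_negated_distractor_carries_trigger(self):
        note = render_note(["fever"], [("negated", "chest pain")], enc_index=0)
        assert "no chest pain" in note["MDM"].lower()

    def test_historical_and_uncertain_templates(self):
        note = render_note(["fever"], [("historical", "stroke"), ("uncertain", "sepsis")])
        assert "history of stroke" in note["MDM"].lower()
        assert "possible sepsis" in note["MDM"].lower()

    def test_stable_across_calls(self):
        a = render_note(["fever", "syncope"], [("negated", "chest pain")], enc_index=7)
        b = render_note(["fever", "syncope"], [("negated", "chest pain")], enc_index=7)
        assert a == b

    def test_requires_at_least_one_affirmed_mention(self):
        with pytest.raises(GenerationError):
            render_note([], [("negated", "chest pain")])


class TestGenerateCohort:
    def test_identical_seed_gives_byte_identical_files(self, vocabulary, tmp_path):
        catalog, lexicon, crosswalk = vocabulary
        cfg = CohortConfig(class_sizes=(1, 1, 1, 1), zipf_exponent=1.0,
                           pgy_volume_means=(15.0, 20.0, 25.0, 30.0), seed=42)
        p1 = write_cohort(generate_cohort(cfg, catalog, lexicon, crosswalk), tmp_path / "a")
        p2 = write_cohort(generate_cohort(cfg, catalog, lexicon, crosswalk), tmp_path / "b")
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_roster_structure(self, small_cohort):
        data = small_cohort
        assert len(data.residents) == 8
        years = sorted({r.class_year for r in data.residents})
        assert years == [2020, 2021, 2022, 2023]
        for r in data.residents:
            assert r.start_date.year == r.class_year - 4
            assert all(
                s.start.date() >= r.start_date
                for s in data.shifts[data.shifts["resident_id"] == r.resident_id].itertuples()
            )

    def test_total_volume_near_configured_expectation(self, default_cohort):
        data = default_cohort
        expected = 62 * (445.7 + 772.1 + 1193.4 + 1528.4)
        assert abs(len(data.encounters) - expected) / expected < 0.10

    def test_per_pgy_volume_recovery_within_two_se(self, medium_cohort):
        from excurves.model import assign_pgy

        data = medium_cohort
        cfg = data.config
        by_id = {r.resident_id: r for r in data.residents}
        counts: dict[tuple[str, int], int] = {}
        prim = data.truth.intended_primary
        arr = data.encounters.set_index("encounter_id")["arrival_time"]
        for enc_id, rid in prim.items():
            pgy = assign_pgy(by_id[rid], arr.loc[enc_id])
            if pgy:
                counts[(rid, pgy)] = counts.get((rid, pgy), 0) + 1
        for pgy in range(1, 5):
            vols = [v for (rid, p), v in counts.items() if p == pgy]
            assert len(vols) >= 30
            mean, target = np.mean(vols), cfg.pgy_volume_means[pgy - 1]
            se = np.std(vols, ddof=1) / np.sqrt(len(vols))
            assert abs(mean - target) <= 2 * se + 1e-9

    def test_mean_esi_monotone_nonincreasing_by_pgy(self, default_cohort):
        from excurves.model import assign_pgy

        data = default_cohort
        by_id = {r.resident_id: r for r in data.residents}
        enc = data.encounters
        pgys = np.array(
            [
                assign_pgy(by_id[data.truth.intended_primary[e.encounter_id]], e.arrival_time)
                or -1
                for e in enc.itertuples()
            ]
        )
        esi = enc["esi"].to_numpy(dtype=float)
        means = [np.nanmean(np.where(pgys == p, esi, np.nan)) for p in range(1, 5)]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_realized_topic_histogram_matches_calibrated_power_law(self, default_cohort):
        """The sampled per-topic encounter counts reproduce the bucket
        structure expected under the generator's calibrated exponent.

        Oracle: the per-topic probability of appearing in one encounter
        is 1 - (1-p_k)^m averaged over the capped shifted-Poisson m
        (within-encounter draws are deduplicated), plus the uncertain-
        distractor mention rate.  Bucket boundaries near expected count
        10 carry Poisson crossing noise over ~100 ranks, hence the wider
        band there.
        """
        from scipy import stats

        data = default_cohort
        cfg = data.config
        counts = np.zeros(895)
        tid_idx = {f"T{k + 1:04d}": k for k in range(895)}
        for topics in data.truth.exposure_topics.values():
            for t in topics:
                counts[tid_idx[t]] += 1
        n_enc = len(data.encounters)
        p = zipf_probs(895, data.zipf_exponent)
        ms = np.arange(0, 60)
        pm = stats.poisson.pmf(ms, cfg.topics_per_encounter_mean)
        m_eff = np.minimum(1 + ms, cfg.topics_per_encounter_max)
        presence = np.array([np.sum(pm * (1 - (1 - pk) ** m_eff)) for pk in p])
        expected = n_enc * presence + n_enc * cfg.uncertain_rate * p * (1 - presence)
        exp_b = np.array(
            [(expected > 100).sum(), ((expected >= 10) & (expected <= 100)).sum(),
             (expected < 10).sum()]
        )
        real_b = np.array(
            [(counts > 100).sum(), ((counts >= 10) & (counts <= 100)).sum(),
             (counts < 10).sum()]
        )
        assert abs(real_b[0] - exp_b[0]) <= 10
        assert abs(real_b[1] - exp_b[1]) <= 30
        assert abs(real_b[2] - exp_b[2]) <= 30
        # heavy tail: mean count decreases across the rank blocks
        order = np.sort(counts)[::-1]
        assert order[:49].mean() > order[49:333].mean() > order[333:].mean()

    def test_zero_distractor_rates_make_all_mentions_affirmed(self, vocabulary):
        catalog, lexicon, crosswalk = vocabulary
        cfg = CohortConfig(
            class_sizes=(1, 0, 0, 0),
            zipf_exponent=1.0,
            pgy_volume_means=(30.0, 30.0, 30.0, 30.0),
            negation_rate=0.0,
            historical_rate=0.0,
            uncertain_rate=0.0,
            seed=1,
        )
        data = generate_cohort(cfg, catalog, lexicon, crosswalk)
        kinds = {k for ms in data.truth.mentions.values() for _, k in ms}
        assert kinds == {"affirmed"}

    def test_every_encounter_has_affirmed_ground_truth(self, small_cohort):
        for ms in small_cohort.truth.mentions.values():
            assert any(k == "affirmed" for _, k in ms)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(negation_rate=1.5)
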