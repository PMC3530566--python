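import numpy as np
import pytest
from scipy import stats

from daytrace import synthetic as syn
from daytrace.core import MISSING
from daytrace.ingest import ingest_events
from daytrace.locstats import fit_power_law

from conftest import make_matrix  # noqa: F401  (shared fixture plumbing)


class TestLocationAlphabet:
    def test_degenerate_single_location(self, rng):
        np.testing.assert_allclose(syn.sample_location_alphabet(1, 1.7, rng), [1.0])

    def test_power_law_shape(self, rng):
        f = syn.sample_location_alphabet(100, 1.7, rng)
        assert f.sum() == pytest.approx(1.0)
        assert (np.diff(f) < 0).all()
        np.testing.assert_allclose(f[0] / f[3], 4.0**1.7, rtol=1e-12)

    def test_alpha_one_rejected(self, rng):
        with pytest.raises(ValueError):
            syn.sample_location_alphabet(3, 1.0, rng)
        with pytest.raises(ValueError):
            syn.sample_location_alphabet(0, 1.7, rng)

    def test_mle_recovers_exponent(self, rng):
        f = syn.sample_location_alphabet(1000, 1.7, rng)
        visits = rng.choice(np.arange(1, 1001), size=100_000, p=f)
        fit = fit_power_law(visits, xmin=1, xmax=1000)
        assert fit.ci95[0] <= 1.7 <= fit.ci95[1]


class TestGenerateDay:
    def test_no_noise_identity(self, rng):
        tpl = np.array(["L001"] * 24, dtype=object)
        w = syn.noise_distribution(10)
        assert (syn.generate_day(tpl, 0.0, w, rng) == tpl).all()

    def test_full_noise_binomial_oracle(self, rng):
        n = 10_000
        tpl = np.array(["L001"] * n, dtype=object)
        w = syn.noise_distribution(50, "rank")
        day = syn.generate_day(tpl, 1.0, w, rng)
        p_hit = 1.0 - w[0]  # noise draw differs from the template label
        mismatch = (day != tpl).mean()
        sigma = np.sqrt(p_hit * (1 - p_hit) / n)
        assert abs(mismatch - p_hit) < 3 * sigma

    def test_partial_noise_mean_mismatches(self, rng):
        eps, reps = 0.1, 10_000
        tpl = np.array(["L001"] * 24, dtype=object)
        w = syn.noise_distribution(1000, "rank")
        expected = 24 * eps * (1.0 - w[0])  # ~2.4 for a large alphabet
        counts = [
            (syn.generate_day(tpl, eps, w, rng) != tpl).sum() for _ in range(reps)
        ]
        sigma = np.sqrt(24 * eps * (1 - eps) / reps)
        assert abs(np.mean(counts) - expected) < 3 * sigma

    def test_template_with_missing_rejected(self, rng):
        tpl = np.array(["L001", MISSING], dtype=object)
        with pytest.raises(ValueError):
            syn.generate_day(tpl, 0.1, syn.noise_distribution(5), rng)


class TestGeneratorConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            syn.GeneratorConfig(alpha=1.0).validate()
        with pytest.raises(ValueError):
            syn.GeneratorConfig(noise_rate=1.5).validate()
        with pytest.raises(ValueError):
            syn.GeneratorConfig(templates_per_user=0).validate()
        syn.GeneratorConfig().validate()

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "gen.yaml"
        p.write_text(
            "n_users: 2\nn_days: 5\nnoise_rate: 0.1\n"
            "gap_spec: {night_prob: 0.0, random_rate: 0.0}\n"
            "departure_params: null\n"
        )
        cfg = syn.GeneratorConfig.from_yaml(p)
        assert cfg.n_users == 2 and cfg.departure_params is None


class TestGeneratePanel:
    def _small_cfg(self, **kw):
        base = dict(
            n_users=2,
            n_days=8,
            n_locations=20,
            templates_per_user=2,
            noise_rate=0.0,
            seed=3,
            departure_params=None,
            gap_spec=syn.GapSpec(night_prob=0.0, random_rate=0.0),
        )
        base.update(kw)
        return syn.GeneratorConfig(**base)

    def test_deterministic_event_stream(self):
        cfg = self._small_cfg()
        e1, _ = syn.generate_panel(cfg)
        e2, _ = syn.generate_panel(cfg)
        assert e1.equals(e2)
        assert e1.to_csv(index=False) == e2.to_csv(index=False)

    def test_noiseless_round_trip_to_templates(self):
        cfg = self._small_cfg()
        events, truth = syn.generate_panel(cfg)
        res = ingest_events(events, min_days=1)
        for user, dm in res.matrices.items():
            tpls = truth.templates[user]
            assign = truth.assignments[user]
            assert dm.n_days == cfg.n_days
            for d in range(cfg.n_days):
                assert (dm.slots[d] == tpls[assign[d]]).all()

    def test_every_day_has_one_assignment(self):
        cfg = self._small_cfg()
        _, truth = syn.generate_panel(cfg)
        for user in truth.assignments:
            assert len(truth.assignments[user]) == cfg.n_days

    def test_night_gaps_appear_and_pad_back(self):
        cfg = self._small_cfg(gap_spec=syn.GapSpec(night_prob=1.0, random_rate=0.0))
        events, truth = syn.generate_panel(cfg)
        # raw slots 01-05 never observed
        hours = events["timestamp"].str.slice(11, 13).astype(int)
        assert not hours.isin([1, 2, 3, 4]).any()
        # padding restores them (home flanks both sides)
        res = ingest_events(events, min_days=1)
        for user, dm in res.matrices.items():
            assert (dm.slots != MISSING).all()

    def test_noise_slots_are_rarer_locations(self):
        cfg = self._small_cfg(
            n_users=1, n_days=60, noise_rate=0.15, templates_per_user=1
        )
        _, truth = syn.generate_panel(cfg)
        user = "u000"
        tpl = truth.templates[user][0]
        days = truth.realized_days[user]
        noise_mask = days != tpl[None, :]
        ranks = np.vectorize(lambda s: int(s[1:]))(days)
        noise_ranks = ranks[noise_mask]
        pattern_ranks = ranks[~noise_mask]
        stat = stats.mannwhitneyu(noise_ranks, pattern_ranks, alternative="greater")
        assert stat.pvalue < 1e-6

    def test_ground_truth_json_serializes(self, tmp_path):
        cfg = self._small_cfg()
        _, truth = syn.generate_panel(cfg)
        path = tmp_path / "gt.json"
        syn.write_ground_truth(truth, path)
        import json

        payload = json.loads(path.read_text())
        assert set(payload["users"]) == {"u000", "u001"}


class TestSampleDepartureTime:
    def test_rejects_bad_rates(self, rng):
        with pytest.raises(ValueError):
            syn.sample_departure_time(8.0, 0.0, 0.1, rng)

    def test_matches_analytic_pdf_moments(self, rng):
        from daytrace.workday import DepartureModel, departure_pdf

        grid = np.arange(1.0, 32.0)
        p = departure_pdf(DepartureModel(16.0, 0.25, 0.25, h0=0.25), grid)
        mean = float((grid * p).sum())
        var = float(((grid - mean) ** 2 * p).sum())
        n = 4000
        draws = np.array(
            [
                syn.sample_departure_time(16.0, 0.25, 0.25, rng, h0=0.25, grid=grid)
                for _ in range(n)
            ],
            dtype=float,
        )
        assert abs(draws.mean() - mean) < 4 * np.sqrt(var / n)


class TestExpectedEntropy:
    def test_noiseless_clustered_zero(self):
        cfg = TestGeneratePanel._small_cfg(TestGeneratePanel())
        _, truth = syn.generate_panel(cfg)
        exp = syn.expected_entropy(truth, "u000")
        assert exp["s_clustered"] == pytest.approx(0.0, abs=1e-12)
        assert exp["delta_s_rel"] == pytest.approx(100.0)

    def test_single_template_no_drop(self):
        cfg = TestGeneratePanel._small_cfg(
            TestGeneratePanel(), templates_per_user=1, noise_rate=0.1
        )
        _, truth = syn.generate_panel(cfg)
        exp = syn.expected_entropy(truth, "u000")
        assert exp["delta_s_rel"] == pytest.approx(0.0, abs=1e-9)
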