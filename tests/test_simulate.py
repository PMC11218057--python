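"""Synthetic campaign generator: determinism, conservation, recovery."""

import dataclasses
import hashlib
import math

import numpy as np
import pytest

from aggdoe.design import interaction_model
from aggdoe.kinetics import GeometryConstants, stability_from_series
from aggdoe.modeling import fit_campaign, normalize_to_center_points
from aggdoe.pipeline import assemble_responses, default_normalized_columns
from aggdoe.simulate import (
    LINEAR_TRUTH_RESPONSES,
    SimTruth,
    _grow_and_mix,
    default_truth,
    make_fixture,
    paper_shape_design,
    simulate_campaign,
    simulate_reactor,
)

INTERVAL_GEOM = GeometryConstants(horizon_days=2.0)


class TestReactorSimulation:
    def test_same_seed_is_bit_identical(self):
        t = default_truth()
        a = simulate_reactor(np.zeros(5), t, seed=5)
        b = simulate_reactor(np.zeros(5), t, seed=5)
        for day in a.counts:
            np.testing.assert_array_equal(a.counts[day], b.counts[day])
        for day in a.diameters:
            np.testing.assert_array_equal(a.diameters[day], b.diameters[day])

    def test_zero_noise_zero_fusion_pct_error_vanishes(self):
        """Growth-only populations show no unexplained size change."""
        t = default_truth().zero_noise()
        s = simulate_reactor(np.zeros(5), t, seed=1)
        stab = stability_from_series(s, INTERVAL_GEOM)
        assert stab.pct_error == pytest.approx(0.0, abs=1e-6)

    def test_mean_diameter_growth_law(self):
        """Without fusion, volume grows as e^{K dt}, diameter as e^{K dt/3}."""
        t = default_truth().zero_noise()
        K = t.growth_rate(np.zeros(5))
        s = simulate_reactor(np.zeros(5), t, seed=2)
        d1 = s.diameters[1].mean()
        for day in (2, 3, 4):
            expect = d1 * math.exp(K * (day - 1) / 3.0)
            assert s.diameters[day].mean() == pytest.approx(expect, rel=1e-9)

    def test_pct_error_monotone_in_fusion_rate(self):
        """More fusion -> more unexplained growth, over a 5-point rate grid."""
        base = default_truth()
        means = []
        for lam in (0.0, 0.1, 0.2, 0.4, 0.8):
            t = dataclasses.replace(
                base, fusion_lam0=lam, count_cv=0.0, diameter_meas_sigma=0.0
            )
            vals = [
                stability_from_series(
                    simulate_reactor(np.zeros(5), t, seed=s), INTERVAL_GEOM
                ).pct_error
                for s in range(25)
            ]
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_fragmentation_drives_pct_error_negative(self):
        t = dataclasses.replace(
            default_truth(), fusion_lam0=0.0, frag_lam0=0.4,
            count_cv=0.0, diameter_meas_sigma=0.0,
        )
        vals = [
            stability_from_series(
                simulate_reactor(np.zeros(5), t, seed=s), INTERVAL_GEOM
            ).pct_error
            for s in range(25)
        ]
        assert np.mean(vals) < -0.05

    def test_needs_two_days(self):
        with pytest.raises(ValueError):
            simulate_reactor(np.zeros(5), default_truth(), days=1)


class TestFusionMechanics:
    def test_fusion_conserves_cells_and_removes_one_aggregate_per_event(self, rng):
        cells = rng.uniform(100, 1000, size=200)
        total = cells.sum() * math.exp(0.4)  # growth applied inside
        out = _grow_and_mix(cells.copy(), 0.4, lam_f=0.3, lam_b=0.0, rng=rng)
        assert out.sum() == pytest.approx(total, rel=1e-12)
        assert len(out) < 200  # only fusions happened

    def test_fragmentation_conserves_cells_and_adds_aggregates(self, rng):
        cells = rng.uniform(100, 1000, size=200)
        out = _grow_and_mix(cells.copy(), 0.0, lam_f=0.0, lam_b=0.3, rng=rng)
        assert out.sum() == pytest.approx(cells.sum(), rel=1e-12)
        assert len(out) > 200


class TestCampaign:
    def test_noise_free_campaign_recovers_truth_exactly(self, campaign_design):
        """With all noise off, the fitted coefficients equal the generating
        coefficients for every linear-truth response."""
        truth = default_truth().zero_noise()
        c = simulate_campaign(campaign_design, truth, seed=0)
        resp = assemble_responses(campaign_design, c.series, c.endpoints)
        model = interaction_model(campaign_design.factors)
        fits = fit_campaign(campaign_design, resp, model, transforms={})
        cases = {
            "growth_rate": (truth.K0, truth.beta_K),
            "viability": (truth.viability0, truth.beta_viability),
            **{r: (truth.qpcr_base[r], truth.beta_qpcr[r]) for r in truth.qpcr_base},
        }
        for resp_name, (base, beta) in cases.items():
            f = fits[resp_name]
            assert f.coef[0] == pytest.approx(base, rel=1e-6)
            for term, tv in beta.items():
                got = f.coef[f.terms.index(term)]
                assert got == pytest.approx(tv, rel=1e-6, abs=1e-8)

    def test_center_points_share_settings_but_not_noise(self, campaign):
        d = campaign.design
        centers = [r for r, c in zip(d.run_ids, d.is_center) if c]
        vals = campaign.endpoints.loc[centers, "OCT4_flow"]
        assert vals.nunique() == len(centers)

    def test_normalization_shrinks_between_batch_center_gap(self, campaign_design):
        """Center-point normalization removes most of the batch effect."""
        truth = dataclasses.replace(default_truth(), batch_sigma=0.15)
        gaps_raw, gaps_norm = [], []
        for seed in range(10):
            c = simulate_campaign(campaign_design, truth, seed=seed)
            resp = assemble_responses(campaign_design, c.series, c.endpoints)
            norm = normalize_to_center_points(
                resp, campaign_design, columns=default_normalized_columns(resp)
            )
            d = campaign_design
            centers = [r for r, f in zip(d.run_ids, d.is_center) if f]
            batch = {r: b for r, b in zip(d.run_ids, d.batch)}
            for df, acc in ((resp, gaps_raw), (norm, gaps_norm)):
                by_batch = {}
                for r in centers:
                    by_batch.setdefault(batch[r], []).append(df.loc[r, "OCT4_qpcr"])
                ms = [np.mean(v) for v in by_batch.values()]
                acc.append(abs(ms[0] - ms[1]))
        assert np.mean(gaps_norm) < np.mean(gaps_raw)

    def test_coefficient_rmse_shrinks_with_more_runs(self):
        """Doubling the run budget improves coefficient recovery (root-n)."""
        truth = default_truth()
        model = interaction_model(paper_shape_design(seed=0).factors)

        def rmse(n_runs, seeds):
            d = paper_shape_design(n_runs=n_runs, seed=0)
            errs = []
            for seed in seeds:
                c = simulate_campaign(d, truth, seed=seed)
                resp = assemble_responses(d, c.series, c.endpoints)
                f = fit_campaign(d, resp[["growth_rate"]], model)["growth_rate"]
                for term, tv in truth.beta_K.items():
                    errs.append((f.coef[f.terms.index(term)] - tv) ** 2)
            return math.sqrt(np.mean(errs))

        seeds = range(12)
        assert rmse(32, seeds) < rmse(16, seeds)


class TestFixtures:
    def test_paper_shape_layout(self, tmp_path):
        out = make_fixture("paper-shape", seed=0, outdir=tmp_path)
        import pandas as pd

        design = pd.read_csv(out / "design.csv")
        assert len(design) == 19
        assert design["is_center"].sum() == 3
        assert design["batch"].nunique() == 2

    def test_same_tag_and_seed_identical_files(self, tmp_path):
        a = make_fixture("clean", seed=3, outdir=tmp_path / "a")
        b = make_fixture("clean", seed=3, outdir=tmp_path / "b")
        for name in ("design.csv", "series.csv", "responses.csv", "truth.json"):
            ha = hashlib.sha256((a / name).read_bytes()).hexdigest()
            hb = hashlib.sha256((b / name).read_bytes()).hexdigest()
            assert ha == hb, name

    def test_clean_fixture_fits_tightly(self, tmp_path):
        """Low-noise scenario: every response model reaches R2 > 0.9."""
        import pandas as pd

        from aggdoe.design import DesignTable, default_factors

        out = make_fixture("clean", seed=0, outdir=tmp_path)
        factors = default_factors()
        design = DesignTable.read_csv(out / "design.csv", factors)
        resp = pd.read_csv(out / "responses.csv").set_index("run_id")
        fits = fit_campaign(design, resp, interaction_model(factors))
        assert min(f.r2 for f in fits.values()) > 0.9

    def test_unknown_tag_raises(self, tmp_path):
        with pytest.raises(ValueError, match="tag"):
            make_fixture("nope", outdir=tmp_path)

    def test_truth_json_round_trip(self):
        t = default_truth()
        again = SimTruth.from_json(t.to_json())
        assert again.beta_K == t.beta_K
        assert again.model.term_names == t.model.term_names
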