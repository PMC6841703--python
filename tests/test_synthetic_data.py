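import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from primingkit import (
    cumulative_priming,
    generate_transect,
    read_covariates_table,
    read_incubation_table,
    simulate_incubation,
    simulate_transect,
    write_fixtures,
)
from primingkit.synthetic_data import TransectConfig, truth_frame


class TestGenerateTransect:
    def test_default_design_counts(self, transect):
        assert len(transect) == 30
        eco = [t.ecosystem for t in transect]
        assert eco.count("steppe") == 18
        assert eco.count("meadow") == 12

    def test_deterministic_under_seed(self):
        a = generate_transect(10, seed=9)
        b = generate_transect(10, seed=9)
        assert truth_frame(a).equals(truth_frame(b))
        c = generate_transect(10, seed=10)
        assert not truth_frame(a).equals(truth_frame(c))

    def test_covariates_respect_ranges(self):
        cfg = TransectConfig()
        truths = generate_transect(200, seed=3, config=cfg)
        soc = [t.covariates["soil"]["soc"] for t in truths]
        mbc = [t.covariates["microbial"]["mbc"] for t in truths]
        ph = [t.covariates["soil"]["ph"] for t in truths]
        assert min(soc) >= cfg.soc_range[0] and max(soc) <= cfg.soc_range[1]
        assert min(mbc) >= cfg.mbc_range[0] and max(mbc) <= cfg.mbc_range[1]
        assert min(ph) >= cfg.ph_range[0] and max(ph) <= cfg.ph_range[1]

    def test_glucose_dose_equals_mbc(self, transect):
        for t in transect:
            assert t.glucose_dose == t.covariates["microbial"]["mbc"]

    def test_priming_signal_recoverable(self):
        """Regressing pi0 on its generating covariates over 500 sites
        recovers the stated coefficients within 2 SE."""
        cfg = TransectConfig()
        truths = generate_transect(500, seed=21, config=cfg)
        recal = np.array(
            [t.covariates["som_stability"]["recalcitrant_pool"] for t in truths]
        )
        feal = np.array(
            [t.covariates["som_stability"]["feal_soc"] for t in truths]
        )
        pi0 = np.array([t.priming_amplitude for t in truths])

        def z(v):
            return (v - v.mean()) / v.std(ddof=0)

        x = np.column_stack([np.ones(500), z(recal), z(feal)])
        beta, res, *_ = np.linalg.lstsq(x, pi0, rcond=None)
        resid = pi0 - x @ beta
        sigma2 = resid @ resid / (500 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(x.T @ x)))
        expect = (cfg.pi0_intercept, cfg.pi0_beta_recalcitrance,
                  cfg.pi0_beta_protection)
        for b, s, e in zip(beta, se, expect):
            assert abs(b - e) < 2 * s, (b, e, s)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            generate_transect(5, seed=0,
                              config=TransectConfig(soc_range=(10.0, 1.0)))
        with pytest.raises(ValueError):
            generate_transect(0, seed=0)


class TestSimulateIncubation:
    def test_replicate_and_blank_counts(self, design, transect):
        recs = simulate_incubation(transect[0], design, seed=0)
        per_day = [r for r in recs if r.day == 1.0]
        assert sum(r.treatment == "control" for r in per_day) == 3
        assert sum(r.treatment == "glucose" for r in per_day) == 3
        assert sum(r.treatment == "blank" for r in per_day) == 5

    def test_deterministic_under_seed(self, design, transect):
        a = simulate_incubation(transect[1], design, seed=5)
        b = simulate_incubation(transect[1], design, seed=5)
        assert all(
            x.co2_conc == y.co2_conc and x.atom_pc == y.atom_pc
            for x, y in zip(a, b)
        )

    def test_noiseless_pipeline_inverts_truth(self, design, transect,
                                              noiseless_partition):
        """Zero measurement noise: recovered priming equals generator truth
        to 1e-8 relative at every timepoint."""
        by_site = {t.site_id: t for t in transect}
        for r in noiseless_partition.itertuples():
            truth = by_site[r.site_id]
            expect = float(truth.priming_rate(r.day))
            assert r.priming == pytest.approx(expect, rel=1e-8)
            # glucose fraction as well
            gluc = float(truth.glucose_flux(r.day))
            total = gluc + float(truth.control_flux(r.day)) * (
                1 + truth.priming_amplitude
                * np.exp(-truth.priming_decay * r.day)
            )
            assert r.f_glucose == pytest.approx(gluc / total, rel=1e-8, abs=1e-12)

    def test_analytic_cumulative_vs_quadrature(self, transect):
        """Closed-form cumulative priming agrees with adaptive quadrature
        of the rate function to 0.1%."""
        for truth in transect[:5]:
            numeric, _ = integrate.quad(
                lambda t: float(truth.priming_rate(t)), 0.0, 65.0,
                limit=200,
            )
            assert truth.cumulative_priming_analytic(65.0) == \
                pytest.approx(numeric, rel=1e-3)

    def test_relative_priming_spans_field_scale(self, transect):
        """Amplitudes cover suppression through strong stimulation
        (order 10-150% of basal respiration)."""
        pi0 = np.array([t.priming_amplitude for t in transect])
        assert pi0.min() < 0.1
        assert pi0.max() > 0.8

    def test_negative_noise_rejected(self, design, transect):
        with pytest.raises(ValueError):
            simulate_incubation(transect[0], design, seed=0,
                                flux_noise_rel=-0.1)


class TestFixtures:
    def test_round_trip(self, tmp_path, design, transect):
        records = simulate_transect(transect[:3], design, seed=7)
        paths = write_fixtures(transect[:3], records, tmp_path)
        again = read_incubation_table(paths["incubation"], design)
        assert len(again) == len(records)
        for a, b in zip(records, again):
            assert a.bottle_id == b.bottle_id
            assert a.co2_conc == pytest.approx(b.co2_conc, rel=1e-12)
            assert a.atom_pc == pytest.approx(b.atom_pc, rel=1e-12)
        covs = read_covariates_table(paths["covariates"])
        assert {c.site_id for c in covs} == {t.site_id for t in transect[:3]}

    def test_truth_table_complete(self, tmp_path, design, transect):
        records = simulate_transect(transect[:2], design, seed=7)
        paths = write_fixtures(transect[:2], records, tmp_path)
        truth = pd.read_csv(paths["truth"])
        assert {"site_id", "ecosystem", "f1", "k1", "k2", "c_tot",
                "priming_amplitude", "priming_decay", "glucose_dose",
                "glucose_k", "glucose_mineralized", "som_atom_pc",
                "soc_g_kg"} <= set(truth.columns)

    def test_regeneration_byte_identical(self, tmp_path, design):
        for sub in ("a", "b"):
            truths = generate_transect(4, seed=42)
            records = simulate_transect(truths, design, seed=42)
            write_fixtures(truths, records, tmp_path / sub)
        for name in ("incubation.csv", "covariates.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
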