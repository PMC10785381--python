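"""The synthetic experiment generator: determinism, genetics, allocation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from semifieldgp import (
    ConfigurationError,
    SimulationConfig,
    compute_grm,
    filter_snps,
    simulate_experiment,
    simulate_genotypes,
)
from semifieldgp.pipeline import summarize_root_table
from semifieldgp.simulate import assign_lines
from semifieldgp.layout import build_layout


def small_cfg(**kw):
    base = dict(seed=1, n_lines=24, n_snps=500, rows_per_unit=30,
                units_per_bed=2, beds=2)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_full_inbreeding_only_homozygous(self):
        g = simulate_genotypes(small_cfg(inbreeding=1.0))
        vals = set(np.unique(g.dosages.to_numpy()))
        assert vals <= {0.0, 2.0}

    def test_mean_maf_near_configured_range(self):
        """Sample MAF centres on the configured spectrum (founder drift
        widens it but does not shift the mean much)."""
        cfg = small_cfg(n_snps=4000, maf_range=(0.1, 0.5))
        g = simulate_genotypes(cfg)
        assert g.maf.mean() == pytest.approx(0.3, abs=0.05)

    def test_injected_missingness_drives_qc(self):
        """With per-entry missing rate m, a SNP is dropped when its missing
        count exceeds 10%; the expected number removed is the binomial tail
        (independent oracle via scipy)."""
        cfg = small_cfg(n_lines=40, n_snps=2000, missing_rate=0.05)
        g = simulate_genotypes(cfg)
        _, report = filter_snps(g, max_missing=0.10, min_maf=0.0)
        p_drop = stats.binom.sf(4, 40, 0.05)  # P(X > 4) = P(rate > 10%)
        expect = 2000 * p_drop
        sd = np.sqrt(2000 * p_drop * (1 - p_drop))
        assert abs(report["snps_removed_missing"] - expect) <= 4 * sd

    def test_avg_diag_near_inbred_value(self):
        cfg = SimulationConfig(seed=2, n_lines=70, n_snps=3000, rows_per_unit=10)
        G = compute_grm(simulate_genotypes(cfg))
        assert G.avg_diag == pytest.approx(1.86, abs=0.08)

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed=1, vcs_root={"g": -1.0})


class TestDeterminism:
    def test_identical_seed_identical_tables(self):
        s1 = simulate_experiment(small_cfg())
        s2 = simulate_experiment(small_cfg())
        pd.testing.assert_frame_equal(s1.above, s2.above)
        pd.testing.assert_frame_equal(s1.root_images, s2.root_images)
        pd.testing.assert_frame_equal(s1.geno.dosages, s2.geno.dosages)

    def test_different_seed_differs(self):
        s1 = simulate_experiment(small_cfg(seed=1))
        s2 = simulate_experiment(small_cfg(seed=2))
        assert not s1.above["GY"].equals(s2.above["GY"])

    def test_seed_mandatory(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed=None)


class TestAboveGround:
    def test_pure_noise_when_only_residual(self):
        vcs = {"g": 0.0, "l": 0.0, "ng": 0.0, "nl": 0.0, "r": 0.0,
               "tg": 0.0, "tl": 0.0, "s1": 0.0, "s2": 0.0, "residual": 1.0}
        cfg = small_cfg(vcs_above={"GY": vcs}, traits=("GY",), unit_bed_sd=0.0)
        sim = simulate_experiment(cfg)
        wet = sim.above[sim.above.treatment == "wet"]["GY"]
        assert wet.std() == pytest.approx(1.0, abs=0.1)
        assert wet.mean() == pytest.approx(7.20, abs=0.15)

    def test_intraclass_correlation_from_genomic_term(self):
        """With only genomic variance, replicate records of one line are
        correlated by d(G) sg2 / (d(G) sg2 + se2) on average."""
        vcs = {"g": 1.0, "l": 0.0, "ng": 0.0, "nl": 0.0, "r": 0.0,
               "tg": 0.0, "tl": 0.0, "s1": 0.0, "s2": 0.0, "residual": 1.0}
        cfg = SimulationConfig(seed=9, n_lines=40, n_snps=800, rows_per_unit=60,
                               units_per_bed=2, beds=2,
                               vcs_above={"GY": vcs}, traits=("GY",),
                               unit_bed_sd=0.0)
        sim = simulate_experiment(cfg)
        df = sim.above
        d_g = sim.grm.avg_diag
        # one-way ANOVA intraclass correlation over lines
        grand = df["GY"].mean()
        groups = df.groupby("line")["GY"]
        n_bar = groups.size().mean()
        msb = (groups.size() * (groups.mean() - grand) ** 2).sum() / (groups.ngroups - 1)
        msw = groups.apply(lambda x: ((x - x.mean()) ** 2).sum()).sum() / (len(df) - groups.ngroups)
        icc = (msb - msw) / (msb + (n_bar - 1) * msw)
        expect = d_g * 1.0 / (d_g * 1.0 + 1.0)
        assert icc == pytest.approx(expect, abs=0.12)

    def test_spatial_field_variance_matches_component(self):
        """The drawn spatial field has variance ~ sigma_s^2 under the
        trace-normalised kernel."""
        vcs = {"g": 0.0, "l": 0.0, "ng": 0.0, "nl": 0.0, "r": 0.0,
               "tg": 0.0, "tl": 0.0, "s1": 2.0, "s2": 2.0, "residual": 1e-6}
        fields = []
        for seed in range(4):
            cfg = small_cfg(seed=seed, rows_per_unit=80,
                            vcs_above={"GY": vcs}, traits=("GY",))
            sim = simulate_experiment(cfg)
            fields.append(sim.above_truth.spatial_fields["GY_s1"].to_numpy())
        var = np.concatenate(fields).var()
        assert var == pytest.approx(2.0, rel=0.3)

    def test_gnr_and_tkw_consistency(self):
        sim = simulate_experiment(small_cfg())
        df = sim.above
        assert np.allclose(df["GNR"],
                           df["GY"].clip(lower=0) * df["GPC"].clip(lower=0) / 6.25 * 10)
        assert np.allclose(df["TKW"], df["sample_weight"] / df["seed_count"] * 1000)


class TestRootImages:
    def test_allocation_conserves_latent_total(self):
        sim = simulate_experiment(small_cfg())
        sums = sim.root_images.groupby(["bed", "unit", "tube", "time"])["length"].sum()
        latent = sim.root_truth.latent_roots.set_index(["bed", "unit", "tube", "time"])
        assert np.allclose(sums, latent["latent_trl"].loc[sums.index])

    def test_summarise_recovers_latent_trl(self):
        sim = simulate_experiment(small_cfg())
        roots = summarize_root_table(sim.root_images)
        latent = sim.root_truth.latent_roots
        merged = roots.merge(latent, on=["bed", "unit", "tube", "time"])
        assert np.allclose(merged["TRL"], merged["latent_trl"])

    def test_deep_fraction_increases_with_time(self):
        sim = simulate_experiment(small_cfg(seed=3))
        roots = summarize_root_table(sim.root_images)
        frac = roots.groupby("time").apply(
            lambda d: d["DRL"].sum() / d["TRL"].sum(), include_groups=False
        )
        assert frac[1] < frac[2] < frac[3]

    def test_zero_latent_zero_images(self):
        cfg = small_cfg(root_means=(0.0, 0.0, 0.0),
                        vcs_root={"g": 0.0, "l": 0.0, "r": 0.0, "s1": 0.0,
                                  "s2": 0.0, "s3": 0.0, "residual": 0.0})
        sim = simulate_experiment(cfg)
        assert (sim.root_images["length"] == 0).all()

    def test_depth_grid_5cm(self):
        sim = simulate_experiment(small_cfg())
        depths = np.sort(sim.root_images["depth"].unique())
        assert depths[0] == 40.0 and depths[-1] == 270.0
        assert np.allclose(np.diff(depths), 5.0)


class TestLineAssignment:
    def test_every_real_row_has_a_line(self):
        cfg = small_cfg()
        lay = build_layout(beds=2, units_per_bed=2, rows_per_unit=30, k_neighbors=5)
        lay = assign_lines(cfg, lay, [f"L{i}" for i in range(24)])
        assert all(r.line is not None for r in lay.real_rows)

    def test_lines_balanced_within_units(self):
        cfg = small_cfg()
        lay = build_layout(beds=1, units_per_bed=1, rows_per_unit=30, k_neighbors=5)
        lay = assign_lines(cfg, lay, [f"L{i}" for i in range(10)])
        counts = pd.Series([r.line for r in lay.real_rows]).value_counts()
        assert counts.max() == 3  # 30 rows / 10 lines
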