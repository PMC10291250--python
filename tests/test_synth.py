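"""Synthetic-study generator: determinism, calibration, parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest

import xylemflow as xf
from xylemflow import synth
from xylemflow.anatomy import hydraulic_diameter


class TestCalibration:
    def test_lognormal_solved_from_trait_triple(self):
        """The (D_h, CD, F) triple identifies the lognormal exactly: the
        solved parameters reproduce all three analytically."""
        m, s, cd = synth.lognormal_from_traits(dh_um=68.0, cd_mm2=80.0, f_pct=21.0)
        assert m * math.exp(4.5 * s * s) == pytest.approx(68.0, rel=1e-9)
        f = cd * 1e-6 * math.pi / 4 * m**2 * math.exp(2 * s * s) * 100
        assert f == pytest.approx(21.0, rel=1e-9)

    def test_infeasible_triple_rejected(self):
        # F larger than the D_h/CD combination can ever give (needs gsd < 1)
        with pytest.raises(ValueError):
            synth.lognormal_from_traits(dh_um=30.0, cd_mm2=50.0, f_pct=40.0)

    def test_derived_heterogeneity_in_valid_range(self, default_cfg):
        assert 0.0 < default_cfg.sigma_species_sq < 0.2
        assert 0.0 < default_cfg.rho_organ < 1.0


class TestDeterminism:
    def test_same_seed_same_bytes(self):
        a = xf.generate_study(xf.default_config(seed=123))
        b = xf.generate_study(xf.default_config(seed=123))
        for name, df in a.tables().items():
            assert df.to_csv(index=False) == b.tables()[name].to_csv(index=False)

    def test_different_seed_differs(self):
        a = xf.generate_study(xf.default_config(seed=1))
        b = xf.generate_study(xf.default_config(seed=2))
        assert not a.conduits.equals(b.conduits)


class TestGenerateConduits:
    def test_deciduous_root_mean_dh(self, default_cfg):
        """Across many fresh sectors the deciduous-root mean D_h approaches
        the calibrated group value of 68 µm."""
        dhs = []
        for seed in range(1000):
            cs = synth.generate_conduits(
                default_cfg, "Croton macrostachyus", "root", seed
            )
            dhs.append(hydraulic_diameter(cs.diameters()))
        assert np.mean(dhs) == pytest.approx(68.0, rel=0.05)

    def test_degenerate_gsd_collapses_to_median(self, default_cfg):
        cs = synth._draw_sector(
            default_cfg, np.random.default_rng(0), "s", "root",
            median_um=50.0, sigma_w=1e-9, cd_mm2=100.0,
        )
        assert hydraulic_diameter(cs.diameters()) == pytest.approx(50.0, rel=1e-6)

    def test_lumen_fits_sector(self, default_cfg):
        for seed in range(20):
            cs = synth.generate_conduits(default_cfg, "Ekebergia capensis", "root", seed)
            assert cs.lumen_areas.sum() <= cs.sector_area


class TestParameterRecovery:
    def test_lognormal_parameters_recovered(self, default_cfg):
        """Median and geometric SD recovered from 10³ conduits by
        log-moments (the lognormal MLE) within 2 %."""
        rng = np.random.default_rng(7)
        median, sigma = 42.0, 0.24
        cfg = xf.default_config(
            seed=0, conduits_per_sector_median=1000.0, conduits_per_sector_log_sd=1e-9
        )
        cs = synth._draw_sector(cfg, rng, "s", "root", median, sigma, 100.0)
        logs = np.log(cs.diameters())
        assert math.exp(logs.mean()) == pytest.approx(median, rel=0.02)
        assert math.exp(logs.std(ddof=1)) == pytest.approx(math.exp(sigma), rel=0.02)

    def test_flow_ratio_recovered(self, default_study):
        """The generating ratio r = KS_hydr/KS_pot is recovered from the
        emitted flow records against the retained tree-level truth."""
        res = xf.pipeline.flow_table(
            default_study.flow, default_study.segments, default_study.leaf_areas
        )
        gt = default_study.ground_truth.set_index(["species", "tree_id", "organ"])
        merged = res.merge(
            default_study.ground_truth[["species", "tree_id", "organ", "kspot_tree"]],
            on=["species", "tree_id", "organ"],
        )
        r_hat = (merged["KS_hydr"] / merged["kspot_tree"]).mean()
        assert r_hat == pytest.approx(0.25, rel=0.03)


class TestGenerateFlow:
    def test_zero_noise_ratio_exact(self):
        cfg = xf.default_config(seed=0, flow_noise_sd=1e-12)
        study = xf.generate_study(cfg)
        res = xf.pipeline.flow_table(study.flow, study.segments, study.leaf_areas)
        merged = res.merge(
            study.ground_truth[["species", "tree_id", "organ", "kspot_tree"]],
            on=["species", "tree_id", "organ"],
        )
        ratios = merged["KS_hydr"] / merged["kspot_tree"]
        assert np.allclose(ratios, 0.25, rtol=1e-9)

    def test_plugging_factor_one_means_no_initial_deficit(self):
        cfg = xf.default_config(seed=3, plugging_range=(1.0, 1.0))
        study = xf.generate_study(cfg)
        piv = study.flow.pivot_table(
            index="sample_id", columns="stage", values="flow_g_per_h"
        )
        last_flush = piv[[c for c in piv.columns if c.startswith("flush")]].max(axis=1)
        assert np.allclose(piv["initial"], last_flush, rtol=1e-9)

    def test_flush_sequence_rises_to_plateau(self, default_study):
        one = default_study.flow[
            default_study.flow.sample_id == default_study.flow.sample_id.iloc[0]
        ]
        flushes = one[one.stage.str.startswith("flush")].sort_values("stage")
        assert flushes["flow_g_per_h"].is_monotonic_increasing


class TestStudyStructure:
    def test_design_counts(self, default_study, default_cfg):
        assert len(default_study.trees) == 14 * 6
        # 2 root + 3 branch segments per tree, plus stem cores
        n_seg = default_study.segments.groupby("organ").size()
        assert n_seg["root"] == 14 * 6 * 2
        assert n_seg["branch"] == 14 * 6 * 3
        # anatomy on the first 3 trees of each species, both organs
        anat = default_study.conduits.groupby(["species", "organ"]).tree_id.nunique()
        assert (anat == default_cfg.n_anatomy_trees).all()

    def test_deliberate_missing_cells(self, default_study, default_cfg):
        flows = default_study.flow
        dropped = flows[
            (flows.species == default_cfg.discard_root_flow_species)
            & (flows.organ == "root")
        ]
        assert len(dropped) == 0
        # but the segments (used for wood density) are retained
        segs = default_study.segments
        assert len(segs[(segs.species == default_cfg.discard_root_flow_species)
                        & (segs.organ == "root")]) == 12
        cores = segs[segs.organ == "stem_core"]
        assert default_cfg.no_stem_core_species not in set(cores.species)

    def test_single_tree_config_passes_through(self):
        cfg = xf.default_config(seed=5, n_trees=1, n_anatomy_trees=1)
        study = xf.generate_study(cfg)
        assert study.trees.groupby("species").size().eq(1).all()


def test_group_mean_calibration_recovered_from_truth():
    """Over several study replicates the retained ground truth reproduces
    the calibrated group structure (organ means of the measured-conductivity
    scale within Monte-Carlo tolerance)."""
    roots, branches = [], []
    for seed in range(12):
        gt = xf.generate_study(xf.default_config(seed=seed)).ground_truth
        ang = gt[gt.leaf_habit != "gymnosperm"]
        sp = ang.groupby(["species", "organ"]).kshydr_tree.mean().unstack()
        roots.append(sp["root"].mean())
        branches.append(sp["branch"].mean())
    assert np.mean(roots) == pytest.approx(9.5, rel=0.25)
    assert np.mean(branches) == pytest.approx(2.3, rel=0.25)
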