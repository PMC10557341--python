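"""Summary-statistic estimators against brute-force oracles; diagnostics."""

import numpy as np
import pandas as pd
import pytest

from sleepmr.sensitivity import (
    confounder_scan,
    ivw,
    mr_egger,
    per_snp_associations,
    ph_schoenfeld_test,
    read_assoc_tsv,
    weighted_median,
    weighted_mode,
    write_assoc_tsv,
)
from sleepmr.synth import GenotypeMatrix


def make_assoc(gamma, Gamma, se_gamma=None, se_Gamma=None):
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    m = len(gamma)
    return pd.DataFrame(
        {
            "variant_id": [f"rs{j}" for j in range(m)],
            "gamma": gamma,
            "se_gamma": se_gamma if se_gamma is not None else np.full(m, 0.01),
            "Gamma": Gamma,
            "se_Gamma": se_Gamma if se_Gamma is not None else np.full(m, 0.05),
        }
    )


# ---------------------------------------------------------------------------
# independent oracles


def wls_origin_oracle(g, G, w):
    """Exact weighted least squares through the origin."""
    A = (np.sqrt(w) * g)[:, None]
    b = np.sqrt(w) * G
    return float(np.linalg.lstsq(A, b, rcond=None)[0][0])


def wls_intercept_oracle(g, G, w):
    A = np.sqrt(w)[:, None] * np.column_stack([np.ones_like(g), g])
    b = np.sqrt(w) * G
    return np.linalg.lstsq(A, b, rcond=None)[0]


def weighted_median_oracle(b, w):
    """Step-function inversion of the weighted cumulative distribution."""
    order = np.argsort(b)
    b, w = b[order], w[order] / w.sum()
    cum = np.cumsum(w) - w / 2
    if 0.5 <= cum[0]:
        return float(b[0])
    if 0.5 >= cum[-1]:
        return float(b[-1])
    for j in range(len(b) - 1):
        if cum[j] <= 0.5 <= cum[j + 1]:
            frac = (0.5 - cum[j]) / (cum[j + 1] - cum[j])
            return float(b[j] + frac * (b[j + 1] - b[j]))
    raise AssertionError("unreachable")


def mode_grid_oracle(b, w, h, grid_size=40_001):
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, grid_size)
    dens = np.zeros_like(grid)
    for bj, wj in zip(b, w):
        dens += wj * np.exp(-0.5 * ((grid - bj) / h) ** 2)
    return float(grid[np.argmax(dens)])


# ---------------------------------------------------------------------------


class TestIVW:
    def test_single_variant_is_ratio(self):
        assoc = make_assoc([0.2], [0.05])
        assert ivw(assoc).beta == pytest.approx(0.25, abs=1e-12)

    def test_noise_free_exact_recovery(self):
        g = np.array([0.1, 0.2, 0.3, 0.15])
        assoc = make_assoc(g, 0.7 * g)
        assert ivw(assoc).beta == pytest.approx(0.7, abs=1e-10)

    def test_matches_wls_origin_oracle(self):
        rng = np.random.default_rng(0)
        g = rng.normal(0.1, 0.03, size=8)
        G = rng.normal(0.0, 0.05, size=8)
        seG = rng.uniform(0.02, 0.1, size=8)
        assoc = make_assoc(g, G, se_Gamma=seG)
        oracle = wls_origin_oracle(g, G, 1 / seG**2)
        assert ivw(assoc).beta == pytest.approx(oracle, abs=1e-10)

    def test_all_zero_gamma_rejected(self):
        with pytest.raises(ValueError):
            ivw(make_assoc([0.0, 0.0], [0.1, 0.2]))


class TestEgger:
    def test_exact_fit_slope_and_zero_intercept(self):
        g = np.array([0.1, 0.2, 0.3])
        out = mr_egger(make_assoc(g, 0.5 * g))
        assert out["slope"] == pytest.approx(0.5, abs=1e-10)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_affine_shift_lands_in_intercept(self):
        g = np.array([0.1, 0.2, 0.3, 0.25])
        out = mr_egger(make_assoc(g, 0.5 * g + 0.01))
        assert out["intercept"] == pytest.approx(0.01, abs=1e-10)
        assert out["slope"] == pytest.approx(0.5, abs=1e-10)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0.05, 0.3, size=9)
        G = 0.4 * g + rng.normal(0, 0.03, size=9)
        seG = rng.uniform(0.02, 0.08, size=9)
        assoc = make_assoc(g, G, se_Gamma=seG)
        icpt, slope = wls_intercept_oracle(g, G, 1 / seG**2)
        out = mr_egger(assoc)
        assert out["slope"] == pytest.approx(slope, abs=1e-10)
        assert out["intercept"] == pytest.approx(icpt, abs=1e-10)

    def test_constrained_intercept_equals_ivw(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(0.05, 0.3, size=7)
        G = 0.4 * g + rng.normal(0, 0.05, size=7)
        seG = rng.uniform(0.02, 0.08, size=7)
        assoc = make_assoc(g, G, se_Gamma=seG)
        oracle = wls_origin_oracle(g, G, 1 / seG**2)
        assert ivw(assoc).beta == pytest.approx(oracle, abs=1e-10)

    def test_too_few_variants_rejected(self):
        with pytest.raises(ValueError):
            mr_egger(make_assoc([0.1, 0.2], [0.05, 0.1]))


class TestMedian:
    def test_odd_count_equal_weights(self):
        g = np.ones(3)
        assoc = make_assoc(g, [1.0, 2.0, 3.0])
        est = weighted_median(assoc, mode="simple", n_boot=100, seed=0)
        assert est.beta == pytest.approx(2.0, abs=1e-12)

    def test_two_ratios_interpolate_to_midpoint(self):
        assoc = make_assoc([1.0, 1.0], [1.0, 3.0])
        est = weighted_median(assoc, mode="simple", n_boot=100, seed=0)
        assert est.beta == pytest.approx(2.0, abs=1e-12)

    def test_matches_cumulative_weight_oracle(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(0.05, 0.3, size=7)
        G = rng.normal(0.05, 0.05, size=7)
        seG = rng.uniform(0.02, 0.08, size=7)
        assoc = make_assoc(g, G, se_Gamma=seG)
        est = weighted_median(assoc, mode="weighted", n_boot=100, seed=0)
        oracle = weighted_median_oracle(G / g, g**2 / seG**2)
        assert est.beta == pytest.approx(oracle, abs=1e-10)

    def test_equal_weights_equal_simple_median(self):
        rng = np.random.default_rng(4)
        G = rng.normal(size=9)
        assoc = make_assoc(np.ones(9), G)
        simple = weighted_median(assoc, mode="simple", n_boot=100, seed=0)
        # with identical gammas and se_Gammas the weighted weights are
        # all equal, so both flavours coincide
        weighted = weighted_median(assoc, mode="weighted", n_boot=100,
                                   seed=0)
        assert simple.beta == pytest.approx(weighted.beta, abs=1e-12)

    def test_zero_gamma_dropped_with_warning(self):
        assoc = make_assoc([0.0, 0.1, 0.2], [0.1, 0.05, 0.1])
        with pytest.warns(UserWarning, match="gamma = 0"):
            est = weighted_median(assoc, mode="simple", n_boot=100, seed=0)
        assert est.n_used == 2


class TestMode:
    def test_point_mass_returns_the_constant(self):
        g = np.array([0.1, 0.2, 0.3])
        assoc = make_assoc(g, 0.5 * g)
        est = weighted_mode(assoc, n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_majority_cluster_wins(self):
        g = np.ones(9)
        ratios = np.array([0.48, 0.5, 0.5, 0.51, 0.52, 0.49, 2.0, 2.0, 2.1])
        assoc = make_assoc(g, ratios)
        est = weighted_mode(assoc, bandwidth_factor=1.0, n_boot=100, seed=0)
        assert abs(est.beta - 0.5) < 0.05

    def test_matches_dense_grid_oracle(self):
        from sleepmr.sensitivity import _mode_bandwidth

        rng = np.random.default_rng(5)
        g = rng.uniform(0.05, 0.3, size=9)
        G = rng.normal(0.05, 0.05, size=9)
        seG = rng.uniform(0.02, 0.08, size=9)
        assoc = make_assoc(g, G, se_Gamma=seG)
        est = weighted_mode(assoc, n_boot=100, seed=0)
        b = G / g
        w = g**2 / seG**2
        h = _mode_bandwidth(b, 1.0)
        oracle = mode_grid_oracle(b, w / w.sum(), h)
        grid_step = (np.ptp(b) + 6 * h) / 2048
        assert est.beta == pytest.approx(oracle, abs=2 * grid_step)

    def test_halving_bandwidth_keeps_majority_cluster(self):
        g = np.ones(9)
        ratios = np.array([0.48, 0.5, 0.5, 0.51, 0.52, 0.49, 2.0, 2.0, 2.1])
        assoc = make_assoc(g, ratios)
        wide = weighted_mode(assoc, bandwidth_factor=1.0, n_boot=100, seed=0)
        narrow = weighted_mode(assoc, bandwidth_factor=0.5, n_boot=100,
                               seed=0)
        assert abs(wide.beta - narrow.beta) < 0.1


def test_orientation_invariance_of_all_estimators():
    """Flipping the coded allele of any variant leaves estimates alone."""
    rng = np.random.default_rng(6)
    g = rng.uniform(0.05, 0.3, size=8)
    G = 0.4 * g + rng.normal(0, 0.03, size=8)
    seG = rng.uniform(0.02, 0.08, size=8)
    assoc = make_assoc(g, G, se_Gamma=seG)
    flip = np.array([1, -1, 1, -1, -1, 1, 1, -1], dtype=float)
    flipped = make_assoc(g * flip, G * flip, se_Gamma=seG)
    assert ivw(assoc).beta == pytest.approx(ivw(flipped).beta, abs=1e-12)
    assert mr_egger(assoc)["slope"] == pytest.approx(
        mr_egger(flipped)["slope"], abs=1e-12
    )
    for mode in ("simple", "weighted"):
        a = weighted_median(assoc, mode=mode, n_boot=100, seed=0)
        b = weighted_median(flipped, mode=mode, n_boot=100, seed=0)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
    a = weighted_mode(assoc, n_boot=100, seed=0)
    b = weighted_mode(flipped, n_boot=100, seed=0)
    assert a.beta == pytest.approx(b.beta, abs=1e-12)


def test_single_ratio_consensus_across_estimators():
    """When every variant carries the same ratio, all estimators agree on
    it (the single-instrument ratio limit)."""
    g = np.array([0.1, 0.2, 0.3])
    assoc = make_assoc(g, 0.7 * g)
    assert ivw(assoc).beta == pytest.approx(0.7, abs=1e-10)
    est_m = weighted_median(assoc, mode="weighted", n_boot=100, seed=0)
    assert est_m.beta == pytest.approx(0.7, abs=1e-10)
    est_mode = weighted_mode(assoc, n_boot=100, seed=0)
    assert est_mode.beta == pytest.approx(0.7, abs=1e-10)


class TestPerSnpAssociations:
    def test_recovers_constructed_snp_effect(self, null_effect_cohort):
        sc, cohort, geno, variants = null_effect_cohort
        cohort = cohort.copy()
        rng = np.random.default_rng(7)
        dose = geno.dosage[:, 0]
        cohort["exposure"] = 0.2 * dose + rng.normal(size=len(cohort))
        small = GenotypeMatrix(
            sample_ids=geno.sample_ids,
            variant_ids=geno.variant_ids[:3],
            dosage=geno.dosage[:, :3],
        )
        assoc = per_snp_associations(cohort, small, "exposure")
        row = assoc.iloc[0]
        assert abs(row["gamma"] - 0.2) < 3 * row["se_gamma"]

    def test_monomorphic_variant_dropped(self, null_effect_cohort):
        sc, cohort, geno, variants = null_effect_cohort
        mono = GenotypeMatrix(
            sample_ids=geno.sample_ids,
            variant_ids=["rs_mono", geno.variant_ids[0]],
            dosage=np.column_stack(
                [np.full(len(cohort), 2.0), geno.dosage[:, 0]]
            ),
        )
        with pytest.warns(UserWarning, match="monomorphic"):
            assoc = per_snp_associations(cohort, mono, "exposure")
        assert list(assoc["variant_id"]) == [geno.variant_ids[0]]

    def test_roundtrip_tsv(self, tmp_path):
        assoc = make_assoc([0.1, 0.2], [0.05, 0.07])
        write_assoc_tsv(assoc, tmp_path / "a.tsv")
        back = read_assoc_tsv(tmp_path / "a.tsv")
        pd.testing.assert_frame_equal(assoc, back)


class TestSchoenfeld:
    def test_detects_decaying_hazard_ratio(self):
        rng = np.random.default_rng(8)
        n = 20_000
        x = rng.normal(size=n)
        # effect reverses after t=3: flagrant non-proportionality
        lam1 = 0.2 * np.exp(0.8 * x)
        t1 = rng.exponential(1 / lam1)
        lam2 = 0.2 * np.exp(-0.8 * x)
        t2 = 3.0 + rng.exponential(1 / lam2)
        t = np.where(t1 <= 3.0, t1, t2)
        df = pd.DataFrame(
            {
                "x": x,
                "time": np.minimum(t, 12.0),
                "event": (t <= 12.0).astype(int),
            }
        )
        out = ph_schoenfeld_test(df, ["x"])
        assert out.loc[0, "p_value"] < 0.05

    def test_proportional_data_usually_passes(self):
        rng = np.random.default_rng(9)
        n = 5000
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.3 * x)))
        df = pd.DataFrame(
            {
                "x": x,
                "time": np.minimum(t, 12.0),
                "event": (t <= 12.0).astype(int),
            }
        )
        out = ph_schoenfeld_test(df, ["x"])
        assert out.loc[0, "p_value"] > 0.01

    def test_too_few_events_rejected(self):
        df = pd.DataFrame(
            {"x": [0.1, 0.2, 0.3], "time": [1.0, 2.0, 3.0],
             "event": [1, 0, 0]}
        )
        with pytest.raises(ValueError, match="2 events"):
            ph_schoenfeld_test(df, ["x"])


class TestConfounderScan:
    def test_bonferroni_threshold_arithmetic(self):
        rng = np.random.default_rng(10)
        n = 200
        grs = pd.DataFrame(rng.normal(size=(n, 5)),
                           columns=[f"g{j}" for j in range(5)])
        covs = pd.DataFrame(rng.normal(size=(n, 17)),
                            columns=[f"c{j}" for j in range(17)])
        out = confounder_scan(grs, covs)
        assert out["bonferroni_threshold"].unique() == pytest.approx(
            0.05 / 85
        )
        assert len(out) == 85

    def test_single_pair_threshold_is_alpha(self):
        rng = np.random.default_rng(11)
        grs = pd.DataFrame({"g": rng.normal(size=100)})
        covs = pd.DataFrame({"c": rng.normal(size=100)})
        out = confounder_scan(grs, covs)
        assert out.loc[0, "bonferroni_threshold"] == pytest.approx(0.05)

    def test_real_association_is_flagged(self):
        rng = np.random.default_rng(12)
        g = rng.normal(size=2000)
        covs = pd.DataFrame(
            {
                "bmi": 0.5 * g + rng.normal(size=2000),
                "noise": rng.normal(size=2000),
            }
        )
        out = confounder_scan(pd.DataFrame({"g": g}), covs)
        assert out.set_index("covariate").loc["bmi", "flagged"]

    def test_binary_covariate_uses_logistic(self):
        rng = np.random.default_rng(13)
        g = rng.normal(size=1000)
        covs = pd.DataFrame(
            {"smoker": (rng.random(1000) < 0.3).astype(float)}
        )
        out = confounder_scan(pd.DataFrame({"g": g}), covs)
        assert out.loc[0, "model"] == "logistic"

    def test_constant_covariate_skipped_with_warning(self):
        rng = np.random.default_rng(14)
        grs = pd.DataFrame({"g": rng.normal(size=50)})
        covs = pd.DataFrame(
            {"flat": np.ones(50), "ok": rng.normal(size=50)}
        )
        with pytest.warns(UserWarning, match="constant"):
            out = confounder_scan(grs, covs)
        assert list(out["covariate"]) == ["ok"]
        assert out.loc[0, "bonferroni_threshold"] == pytest.approx(0.05)
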