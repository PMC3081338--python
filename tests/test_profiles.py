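"""Binned profiles, Hill fitting, boundary interpolation and bootstrap."""

import numpy as np
import pandas as pd
import pytest

from bcdburst import (BinProfile, HillFitError, bin_profile, binomial_eta,
                      boundary_position, bootstrap_noise, hill_fit)
from bcdburst.profiles import hill_curve
from conftest import make_disc_nucleus


def profile_from_arrays(mids, rho, N=50, bnuc=None):
    """Assemble a BinProfile directly from per-bin values."""
    w = float(mids[1] - mids[0]) if len(mids) > 1 else 0.02
    t = pd.DataFrame({
        "bin_lo": np.asarray(mids) - w / 2, "bin_hi": np.asarray(mids) + w / 2,
        "bin_mid": mids, "n": (np.asarray(rho) * N).astype(int), "N": N,
        "rho": rho, "sigma": 0.0, "eta": 0.0,
        "mean_bnuc": bnuc if bnuc is not None else np.ones(len(mids)),
        "low_N": False})
    return BinProfile(t, w, [np.zeros(N)] * len(mids))


def nuclei_with_counts(counts, x=0.21, bnuc=10.0):
    out = []
    for i, c in enumerate(counts):
        n = make_disc_nucleus(i, (8, 8), 3, (16, 16))
        n.x_over_L, n.b_nuc, n.dot_count = x, bnuc, int(c)
        out.append(n)
    return out


class TestBinProfile:
    def test_direct_arithmetic(self):
        prof = bin_profile(nuclei_with_counts([0, 1, 1, 2]), bin_width=0.02)
        row = prof.table.iloc[0]
        assert row["rho"] == pytest.approx(1.0)
        assert row["sigma"] == pytest.approx(0.8165, abs=1e-4)
        assert row["eta"] == pytest.approx(0.8165, abs=1e-4)
        assert row["n"] == 4 and row["N"] == 4

    def test_equal_counts_zero_noise(self):
        prof = bin_profile(nuclei_with_counts([2, 2, 2, 2]))
        assert prof.table.iloc[0]["eta"] == 0.0

    def test_total_dots_and_nuclei_conserved(self, processed_small):
        prof = processed_small.profile
        t = prof.table
        n_total = sum(n.dot_count for n in processed_small.nuclei)
        assert t["n"].sum() == n_total
        assert t["N"].sum() == len(processed_small.nuclei)

    def test_empty_range_raises(self):
        with pytest.raises(ValueError):
            bin_profile(nuclei_with_counts([1, 1], x=0.9), x_range=(0.0, 0.5))

    def test_binomial_counts_match_closed_form_eta(self):
        rng = np.random.default_rng(4)
        q = 0.3
        counts = rng.binomial(2, q, size=4000)
        prof = bin_profile(nuclei_with_counts(counts))
        assert prof.table.iloc[0]["eta"] == pytest.approx(
            binomial_eta(q), rel=0.05)


class TestHillFit:
    def test_exact_recovery_noiseless(self):
        b = np.linspace(2, 40, 12)
        rho = hill_curve(b, 1.0, 4.0, 10.0)
        fit = hill_fit(profile_from_arrays(
            np.linspace(0.1, 0.5, 12), rho, bnuc=b))
        assert fit.rho_max == pytest.approx(1.0, rel=1e-5)
        assert fit.n_hill == pytest.approx(4.0, rel=1e-4)
        assert fit.K == pytest.approx(10.0, rel=1e-4)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        b = np.linspace(4, 36, 10)
        rho = hill_curve(b, 1.6, 5.0, 15.0) + rng.normal(0, 0.05, 10)
        fit = hill_fit(profile_from_arrays(
            np.linspace(0.1, 0.5, 10), rho, bnuc=b))

        # independent brute-force grid search over the same model
        best = (np.inf, None)
        for rm in np.linspace(1.2, 2.0, 33):
            for nh in np.linspace(2, 9, 57):
                for K in np.linspace(10, 22, 49):
                    sse = ((rho - hill_curve(b, rm, nh, K)) ** 2).sum()
                    if sse < best[0]:
                        best = (sse, (rm, nh, K))
        sse_fit = (fit.residuals ** 2).sum()
        assert sse_fit <= best[0] + 1e-4
        assert fit.n_hill == pytest.approx(best[1][1], abs=0.3)

    def test_wrong_orientation_rejected(self):
        b = np.linspace(2, 40, 10)
        rho = hill_curve(b, 1.0, 4.0, 10.0)[::-1]    # decreasing in B
        with pytest.raises(HillFitError):
            hill_fit(profile_from_arrays(
                np.linspace(0.1, 0.5, 10), rho, bnuc=b))

    def test_too_few_bins_rejected(self):
        b = np.array([5.0, 10.0, 20.0])
        with pytest.raises(HillFitError):
            hill_fit(profile_from_arrays(
                np.array([0.1, 0.2, 0.3]), hill_curve(b, 1, 4, 10), bnuc=b))


class TestBoundary:
    def test_midpoint_interpolation(self):
        prof = profile_from_arrays(np.array([0.1, 0.3, 0.5, 0.7]),
                                   np.array([1.0, 1.0, 0.0, 0.0]))
        assert boundary_position(prof) == pytest.approx(0.4)
        assert boundary_position(prof, smooth_window=1) == pytest.approx(0.4)

    def test_flat_profile_errors(self):
        prof = profile_from_arrays(np.linspace(0.1, 0.7, 8), np.ones(8))
        with pytest.raises(ValueError):
            boundary_position(prof)

    def test_synthetic_recovery_within_bin_width(self, processed_small,
                                                 small_spec):
        res = processed_small
        xb = boundary_position(res.profile.select(0.05, 0.6))
        assert abs(xb - small_spec.true_boundary) <= 2 * 0.02 + 0.01


class TestBootstrap:
    def test_identical_counts_zero_width(self):
        ci = bootstrap_noise(np.full(30, 2.0), reps=200, seed=0)
        assert ci.rho_lo == ci.rho_hi == 2.0

    def test_deterministic_given_seed(self):
        counts = np.random.default_rng(1).binomial(2, 0.4, 100)
        a = bootstrap_noise(counts, reps=300, seed=9)
        b = bootstrap_noise(counts, reps=300, seed=9)
        assert (a.rho_lo, a.rho_hi, a.eta_lo, a.eta_hi) == \
               (b.rho_lo, b.rho_hi, b.eta_lo, b.eta_hi)

    def test_ci_width_scales_inverse_sqrt_N(self):
        rng = np.random.default_rng(3)
        widths = []
        for N in (100, 400, 1600):
            counts = rng.binomial(2, 0.4, N)
            ci = bootstrap_noise(counts, reps=400, seed=5)
            widths.append(ci.rho_hi - ci.rho_lo)
        # quadrupling N should roughly halve the CI width
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.35)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.35)

    def test_single_rep_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            bootstrap_noise(np.array([0, 1, 2.0]), reps=1, seed=0)
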