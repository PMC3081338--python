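"""Embryonic-scale statistics: binned dot density, Hill response, boundary,
and bursting noise.

Nuclei are binned along the A-P axis; per bin the dot density is
rho = n/N (n detected nuclear dots, N nuclei), the noise is
eta = sigma/rho with sigma the sample SD of per-nucleus dot counts, and the
mean nuclear Bcd gives the input coordinate for the Hill fit

    rho(B) = rho_max * B^n_H / (B^n_H + K^n_H).

The expression boundary x_b is the A-P position where rho falls to half of
its maximum on the posterior flank of the anterior domain; it is read from
the x/L profile, not from the fit. Error bars on rho and eta come from
bootstrap resampling of nuclei within a bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import HillFitError
from .segment import NucleusRecord


@dataclass
class BinProfile:
    """Per-A-P-bin statistics, stored as a DataFrame in ``table``.

    Columns: bin_lo, bin_hi, bin_mid, n, N, rho, sigma, eta, mean_bnuc,
    low_N (flag). Optional bootstrap CI columns are added by
    ``bootstrap_profile``.
    """

    table: pd.DataFrame
    bin_width: float
    counts_per_bin: list[np.ndarray] = field(repr=False, default_factory=list)

    def select(self, x_lo: float, x_hi: float) -> "BinProfile":
        """Restrict to bins whose midpoint lies in [x_lo, x_hi)."""
        m = (self.table["bin_mid"] >= x_lo) & (self.table["bin_mid"] < x_hi)
        counts = [c for c, k in zip(self.counts_per_bin, m) if k]
        return BinProfile(self.table[m].reset_index(drop=True),
                          self.bin_width, counts)

    def __len__(self):
        return len(self.table)


def _profile_row(counts, bnuc):
    n_dots = int(counts.sum())
    N = len(counts)
    rho = n_dots / N
    sigma = float(counts.std(ddof=1)) if N > 1 else float("nan")
    eta = sigma / rho if rho > 0 else float("nan")
    return n_dots, N, rho, sigma, eta, float(np.mean(bnuc))


def bin_profile(nuclei: list[NucleusRecord], bin_width: float = 0.02,
                x_range=(0.0, 1.0), min_nuclei: int = 5) -> BinProfile:
    """Bin nuclei along x/L and summarize dot counts per bin.

    Bins with fewer than ``min_nuclei`` nuclei are kept but flagged
    ``low_N``; empty bins are dropped. Raises ValueError when no nucleus
    falls in the range.
    """
    x = np.array([r.x_over_L for r in nuclei])
    counts_all = np.array([r.dot_count for r in nuclei], dtype=float)
    bnuc_all = np.array([r.b_nuc for r in nuclei])
    lo, hi = x_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        raise ValueError("empty x/L range")
    idx = np.digitize(x, edges) - 1

    rows, counts_per_bin = [], []
    for b in range(len(edges) - 1):
        m = idx == b
        if not m.any():
            continue
        counts = counts_all[m]
        n_dots, N, rho, sigma, eta, mb = _profile_row(counts, bnuc_all[m])
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1],
            "bin_mid": (edges[b] + edges[b + 1]) / 2,
            "n": n_dots, "N": N, "rho": rho, "sigma": sigma, "eta": eta,
            "mean_bnuc": mb, "low_N": N < min_nuclei,
        })
        counts_per_bin.append(counts)
    if not rows:
        raise ValueError("no nuclei fall in the requested x/L range")
    return BinProfile(pd.DataFrame(rows), bin_width, counts_per_bin)


def value_profile(values, x, bin_width: float = 0.02,
                  x_range=(0.0, 1.0)) -> pd.DataFrame:
    """Mean/SD/CV profile of a continuous per-nucleus quantity (e.g. a
    protein channel readout) along x/L; the CV column is the analogue of
    eta for gene products."""
    values = np.asarray(values, dtype=float)
    x = np.asarray(x, dtype=float)
    lo, hi = x_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.digitize(x, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        m = idx == b
        if not m.any():
            continue
        v = values[m]
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if len(v) > 1 else float("nan")
        rows.append({"bin_lo": edges[b], "bin_hi": edges[b + 1],
                     "bin_mid": (edges[b] + edges[b + 1]) / 2,
                     "N": len(v), "mean": mean, "sd": sd,
                     "cv": sd / mean if mean > 0 else float("nan")})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hill response


@dataclass
class HillFit:
    """Least-squares Hill fit of rho against mean nuclear Bcd."""

    n_hill: float
    K: float
    rho_max: float
    residuals: np.ndarray
    cov: np.ndarray | None

    @property
    def n_hill_se(self) -> float:
        if self.cov is None:
            return float("nan")
        return float(math.sqrt(self.cov[1, 1]))


def hill_curve(b, rho_max, n_hill, K):
    b = np.asarray(b, dtype=float)
    bn = np.power(np.clip(b, 1e-12, None), n_hill)
    return rho_max * bn / (bn + K ** n_hill)


def hill_fit(profile: BinProfile, min_bins: int = 5) -> HillFit:
    """Fit the Hill response of dot density to nuclear Bcd.

    Uses the (mean B_nuc, rho) pairs of usable bins. The response must be
    increasing in B (equivalently decreasing along x); data with the
    opposite orientation raise HillFitError.
    """
    t = profile.table
    usable = t[np.isfinite(t["rho"]) & np.isfinite(t["mean_bnuc"])]
    if len(usable) < min_bins:
        raise HillFitError(
            f"only {len(usable)} usable bins (< {min_bins}) for Hill fit")
    b = usable["mean_bnuc"].to_numpy()
    rho = usable["rho"].to_numpy()

    if len(np.unique(rho)) > 2:
        corr = stats.spearmanr(b, rho).statistic
        if np.isfinite(corr) and corr < 0:
            raise HillFitError(
                "response decreases with B_nuc (increases along x); the "
                "Hill model expects an increasing response to the input",
                diagnostics={"spearman": float(corr)})

    rho_max0 = float(rho.max())
    half = rho_max0 / 2.0
    k0 = float(b[np.argmin(np.abs(rho - half))])
    p0 = (rho_max0, 4.0, max(k0, 1e-3))
    try:
        popt, pcov = optimize.curve_fit(
            hill_curve, b, rho, p0=p0,
            bounds=([1e-9, 0.05, 1e-6], [10 * rho_max0 + 1, 50.0,
                                         10 * float(b.max())]),
            maxfev=20000)
    except RuntimeError as exc:
        raise HillFitError(f"Hill fit did not converge: {exc}",
                           diagnostics={"b": b, "rho": rho}) from exc
    resid = rho - hill_curve(b, *popt)
    return HillFit(rho_max=float(popt[0]), n_hill=float(popt[1]),
                   K=float(popt[2]), residuals=resid, cov=pcov)


def boundary_position(profile: BinProfile, smooth_window: int = 3,
                      plateau_frac: float = 0.75) -> float:
    """x/L where rho is half-maximal on the posterior flank.

    The profile is lightly smoothed with a centered running mean
    (``smooth_window`` bins; 1 disables). The maximal density rho_max is
    the mean over the plateau — all bins whose smoothed density reaches
    ``plateau_frac`` of the smoothed maximum — rather than the single
    maximal bin, whose upward noise bias would inflate the half-max level
    and drag the crossing anterior. The first posterior crossing of
    rho_max/2 is linearly interpolated between the bracketing bins. Raises
    ValueError when the profile never crosses half of its maximum.
    """
    t = profile.table
    x = t["bin_mid"].to_numpy()
    rho = t["rho"].to_numpy(dtype=float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(rho, pad, mode="edge")
        rho_s = np.convolve(padded, kernel, mode="valid")
    else:
        rho_s = rho
    i_max = int(np.argmax(rho_s))
    if rho_s[i_max] <= 0:
        raise ValueError("profile has no expression maximum")
    plateau = rho_s >= plateau_frac * rho_s[i_max]
    half = float(rho_s[plateau].mean()) / 2.0
    start = i_max
    for i in range(start, len(rho_s) - 1):
        if rho_s[i] >= half > rho_s[i + 1]:
            frac = (rho_s[i] - half) / (rho_s[i] - rho_s[i + 1])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    raise ValueError("profile never falls below half-max posterior to its "
                     "maximum; boundary undefined")


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapCI:
    rho_lo: float
    rho_hi: float
    eta_lo: float
    eta_hi: float


def bootstrap_noise(counts, reps: int = 1000, seed: int = 0,
                    ci: float = 95.0) -> BootstrapCI:
    """Percentile bootstrap CI on rho and eta for one bin of nuclei.

    Resamples per-nucleus dot counts with replacement; deterministic given
    ``seed``. Replicates where the resampled rho is zero contribute no eta.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 2:
        raise ValueError("bootstrap requires N >= 2 nuclei")
    if reps < 2:
        warnings.warn("reps < 2 gives a degenerate bootstrap CI",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    samples = rng.integers(0, len(counts), size=(max(reps, 1), len(counts)))
    res = counts[samples]
    rho = res.mean(axis=1)
    sigma = res.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = np.where(rho > 0, sigma / rho, np.nan)
    alpha = (100.0 - ci) / 2.0
    rho_lo, rho_hi = np.percentile(rho, [alpha, 100 - alpha])
    if np.isfinite(eta).any():
        eta_lo, eta_hi = np.nanpercentile(eta, [alpha, 100 - alpha])
    else:
        eta_lo = eta_hi = float("nan")
    return BootstrapCI(float(rho_lo), float(rho_hi),
                       float(eta_lo), float(eta_hi))


def bootstrap_profile(profile: BinProfile, reps: int = 500,
                      seed: int = 0) -> BinProfile:
    """Attach bootstrap CI columns to every bin of a profile."""
    los, his, elos, ehis = [], [], [], []
    for i, counts in enumerate(profile.counts_per_bin):
        if len(counts) >= 2:
            ci = bootstrap_noise(counts, reps=reps, seed=seed + i)
            los.append(ci.rho_lo); his.append(ci.rho_hi)
            elos.append(ci.eta_lo); ehis.append(ci.eta_hi)
        else:
            los.append(float("nan")); his.append(float("nan"))
            elos.append(float("nan")); ehis.append(float("nan"))
    t = profile.table.copy()
    t["rho_ci_lo"], t["rho_ci_hi"] = los, his
    t["eta_ci_lo"], t["eta_ci_hi"] = elos, ehis
    return BinProfile(t, profile.bin_width, profile.counts_per_bin)


def binomial_eta(q: float) -> float:
    """Closed-form eta for per-nucleus counts ~ Binomial(2, q)."""
    if q <= 0:
        return float("nan")
    return math.sqrt((1.0 - q) / (2.0 * q))
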