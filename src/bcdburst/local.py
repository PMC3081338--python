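"""Nuclear- and local-scale Bcd statistics.

Nuclear scale: within each A-P bin, nuclei with at least one intron dot
(active) are compared against dot-free (inactive) nuclei by their mean
nuclear Bcd, with a pooled-variance two-sample Student's t-test.

Local scale: pixel-intensity histograms P(B_pix) are built for three
populations per bin — pixels of inactive nuclei, pixels of active nuclei,
and the thresholded cluster pixels of detected dots mapped onto the Bcd
channel — and compared by their modes, two-sample Kolmogorov-Smirnov tests,
and the pointwise dot-site / active-nucleus density ratio (baseline 1;
values above/below 1 mark enrichment/deficit of Bcd at transcription sites).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dots import IntronDot
from .segment import NucleusRecord


def pooled_ttest(mean1, sd1, n1, mean2, sd2, n2):
    """Two-sample pooled-variance Student's t-test from summary statistics.

    Returns (t, p) two-tailed. This is the test used throughout for
    group comparisons (Welch available via ``scipy`` directly).
    """
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=True)
    return float(res.statistic), float(res.pvalue)


def active_inactive_compare(nuclei: list[NucleusRecord],
                            bin_width: float = 0.02,
                            x_range=(0.0, 1.0),
                            min_burst_prob: float = 0.05,
                            welch: bool = False) -> pd.DataFrame:
    """Per-bin comparison of B_nuc between active and inactive nuclei.

    Bins where the fraction of active nuclei falls below
    ``min_burst_prob`` report the inactive mean only (the active mean is
    unreliable there); groups smaller than 2 leave the p-value NaN.
    """
    x = np.array([r.x_over_L for r in nuclei])
    b = np.array([r.b_nuc for r in nuclei])
    act = np.array([r.active for r in nuclei])
    lo, hi = x_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.digitize(x, edges) - 1
    rows = []
    for k in range(len(edges) - 1):
        m = idx == k
        if not m.any():
            continue
        ba, bi = b[m & act], b[m & ~act]
        frac_active = len(ba) / m.sum()
        row = {"bin_lo": edges[k], "bin_hi": edges[k + 1],
               "bin_mid": (edges[k] + edges[k + 1]) / 2,
               "N": int(m.sum()), "n_active": len(ba),
               "n_inactive": len(bi),
               "frac_active": frac_active,
               "mean_inactive": float(bi.mean()) if len(bi) else float("nan"),
               "mean_active": float("nan"), "t": float("nan"),
               "p": float("nan")}
        if frac_active >= min_burst_prob and len(ba) >= 1:
            row["mean_active"] = float(ba.mean())
            if len(ba) >= 2 and len(bi) >= 2:
                res = stats.ttest_ind(ba, bi, equal_var=not welch)
                row["t"], row["p"] = float(res.statistic), float(res.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pixel histograms


@dataclass
class PixelHistogram:
    """Normalized histogram of 8-bit Bcd pixel intensities."""

    label: str                       # inactive | active | dot_sites
    counts: np.ndarray               # length 256
    mode_tied: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (256,):
            raise ValueError("counts must cover intensities 0..255")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def density(self) -> np.ndarray:
        s = self.counts.sum()
        return self.counts / s if s > 0 else self.counts

    @property
    def mode(self) -> int:
        peak = self.counts.max()
        ties = np.flatnonzero(self.counts == peak)
        return int(ties[0])

    @classmethod
    def from_samples(cls, samples, label: str) -> "PixelHistogram":
        counts = np.bincount(np.asarray(samples, dtype=np.int64).ravel(),
                             minlength=256)[:256]
        h = cls(label=label, counts=counts.astype(float))
        peak = h.counts.max()
        h.mode_tied = (h.counts == peak).sum() > 1
        if h.mode_tied:
            warnings.warn(f"histogram {label!r} has a tied mode; lowest "
                          "intensity reported", stacklevel=2)
        return h


@dataclass
class BinHistograms:
    """P(B_pix) triplet for one A-P bin, with K-S comparisons."""

    bin_lo: float
    bin_hi: float
    inactive: PixelHistogram | None
    active: PixelHistogram | None
    dot_sites: PixelHistogram | None
    ks_active_vs_inactive: tuple[float, float] | None   # (D, p)
    ks_dots_vs_active: tuple[float, float] | None
    samples: dict = field(default_factory=dict, repr=False)


def _bin_pixel_samples(bcd, nuclei, dots, lo, hi):
    """Raw pixel samples for the three populations of one bin.

    Dot-site pixels are clipped to their nucleus mask: a cluster touching
    the nuclear boundary may spill a few cytoplasmic pixels, which belong
    to neither population of the nuclear dataset.
    """
    inact, act = [], []
    ids_in_bin = set()
    nuc_mask = np.zeros(bcd.shape, dtype=bool)
    for rec in nuclei:
        if not (lo <= rec.x_over_L < hi):
            continue
        ids_in_bin.add(rec.id)
        nuc_mask[rec.pixels] = True
        vals = bcd[rec.pixels]
        (act if rec.active else inact).append(vals)
    dot_vals = []
    for d in dots:
        if d.nucleus_id not in ids_in_bin:
            continue
        keep = nuc_mask[d.pixels]
        if keep.any():
            dot_vals.append(bcd[d.pixels[0][keep], d.pixels[1][keep]])
    cat = lambda chunks: (np.concatenate(chunks) if chunks
                          else np.array([], dtype=bcd.dtype))
    return cat(inact), cat(act), cat(dot_vals)


def pixel_histograms(bcd: np.ndarray, nuclei: list[NucleusRecord],
                     dots: list[IntronDot],
                     bins=((0.2, 0.22), (0.3, 0.32), (0.4, 0.42)),
                     min_dot_pixels: int = 50) -> list[BinHistograms]:
    """P(B_pix) histograms per A-P bin for inactive nuclei, active nuclei
    and detected dot sites, with two-sample K-S tests.

    The dot-site population is exactly the thresholded cluster pixels of
    dots owned by nuclei in the bin, read on the Bcd channel. Dot-site
    histograms with fewer than ``min_dot_pixels`` pixels are suppressed.
    """
    out = []
    for lo, hi in bins:
        inact, act, dsite = _bin_pixel_samples(bcd, nuclei, dots, lo, hi)
        h_in = PixelHistogram.from_samples(inact, "inactive") if inact.size else None
        h_ac = PixelHistogram.from_samples(act, "active") if act.size else None
        h_ds = (PixelHistogram.from_samples(dsite, "dot_sites")
                if dsite.size >= min_dot_pixels else None)
        ks_ai = ks_da = None
        if inact.size and act.size:
            r = stats.ks_2samp(act, inact)
            ks_ai = (float(r.statistic), float(r.pvalue))
        if h_ds is not None and act.size:
            r = stats.ks_2samp(dsite, act)
            ks_da = (float(r.statistic), float(r.pvalue))
        out.append(BinHistograms(
            bin_lo=lo, bin_hi=hi, inactive=h_in, active=h_ac, dot_sites=h_ds,
            ks_active_vs_inactive=ks_ai, ks_dots_vs_active=ks_da,
            samples={"inactive": inact, "active": act, "dot_sites": dsite}))
    return out


def enrichment_ratio(dot_hist: PixelHistogram, active_hist: PixelHistogram,
                     density_floor: float = 1e-4) -> np.ndarray:
    """Pointwise P(B_pix) ratio, dot sites over active nuclei.

    Intensities where the active-nucleus density falls below
    ``density_floor`` are masked (NaN) rather than divided. A fully masked
    ratio (disjoint supports) triggers a warning.
    """
    num = dot_hist.density
    den = active_hist.density
    ratio = np.full(256, np.nan)
    ok = den >= density_floor
    if not ok.any() or num[ok].sum() == 0:
        warnings.warn("enrichment ratio fully masked: histogram supports "
                      "do not overlap above the density floor", stacklevel=2)
        return ratio
    ratio[ok] = num[ok] / den[ok]
    return ratio


def single_embryo_enrichment(bcd: np.ndarray, nuclei: list[NucleusRecord],
                             dots: list[IntronDot],
                             bin_width: float = 0.02,
                             x_range=(0.1, 0.5)) -> pd.DataFrame:
    """Within-embryo mean-intensity ratio profiles along x/L.

    Per bin: (mean B_pix at dot sites) / (mean B_pix in active nuclei), and
    (mean B_nuc of inactive nuclei) / (mean B_nuc of active nuclei). Bins
    lacking a population are dropped from the respective profile.
    """
    lo, hi = x_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    rows = []
    for k in range(len(edges) - 1):
        inact, act, dsite = _bin_pixel_samples(bcd, nuclei, dots,
                                               edges[k], edges[k + 1])
        bn_act = [r.b_nuc for r in nuclei
                  if edges[k] <= r.x_over_L < edges[k + 1] and r.active]
        bn_inact = [r.b_nuc for r in nuclei
                    if edges[k] <= r.x_over_L < edges[k + 1] and not r.active]
        if not act.size:
            continue
        row = {"bin_lo": edges[k], "bin_hi": edges[k + 1],
               "bin_mid": (edges[k] + edges[k + 1]) / 2,
               "dot_over_active": (float(dsite.mean() / act.mean())
                                   if dsite.size else float("nan")),
               "inactive_over_active": (float(np.mean(bn_inact)
                                              / np.mean(bn_act))
                                        if bn_inact and bn_act
                                        else float("nan"))}
        rows.append(row)
    return pd.DataFrame(rows)
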