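"""Sex classification and dosage-compensation comparison for X-linked genes.

Female nuclei carry two copies of an X-linked target gene and can therefore
show two intron dots; males carry one. An embryo is called female when the
ratio of two-dot to one-dot nuclei in the expression region exceeds a
decision threshold (default 0.10, midway between the reported female and
male ratios of 0.19 and 0.04). Dosage compensation is then assessed by
comparing, per A-P bin and across embryos, the dot density rho and the mean
raw dot intensity between the sexes with pooled Student's t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dots import IntronDot
from .segment import NucleusRecord


@dataclass
class SexCall:
    two_dot_ratio: float
    n_two_dot: int
    n_one_dot: int
    label: str | None            # "female" | "male" | None (no call)
    threshold: float


def classify_sex(nuclei: list[NucleusRecord],
                 region=(0.05, 0.40),
                 threshold: float = 0.10) -> SexCall:
    """Call embryo sex from the two-dot/one-dot nucleus ratio.

    Only nuclei in the expression-region window contribute; the default
    window spans the anterior expression domain (pole excluded) where the
    burst probability sits near its plateau, so the ratio estimate uses
    every informative nucleus. Returns a no-call (label None, ratio NaN)
    when there are no one-dot nuclei.
    """
    lo, hi = region
    in_region = [r for r in nuclei if lo <= r.x_over_L < hi]
    n2 = sum(1 for r in in_region if r.dot_count == 2)
    n1 = sum(1 for r in in_region if r.dot_count == 1)
    if n1 == 0:
        return SexCall(float("nan"), n2, n1, None, threshold)
    ratio = n2 / n1
    return SexCall(ratio, n2, n1,
                   "female" if ratio >= threshold else "male", threshold)


@dataclass
class EmbryoDotSummary:
    """Per-embryo inputs to the dosage comparison."""

    embryo_id: str
    nuclei: list[NucleusRecord]
    dots: list[IntronDot]


def _per_embryo_bins(summary: EmbryoDotSummary, edges):
    """Per-bin (rho, mean raw dot intensity) for one embryo."""
    x = np.array([r.x_over_L for r in summary.nuclei])
    counts = np.array([r.dot_count for r in summary.nuclei], dtype=float)
    idx = np.digitize(x, edges) - 1
    by_id = {r.id: i for i, r in enumerate(summary.nuclei)}
    dot_bin, dot_I = [], []
    for d in summary.dots:
        if d.nucleus_id is None or d.nucleus_id not in by_id:
            continue
        dot_bin.append(idx[by_id[d.nucleus_id]])
        dot_I.append(d.raw_intensity)
    dot_bin = np.asarray(dot_bin)
    dot_I = np.asarray(dot_I, dtype=float)
    rho, meanI = {}, {}
    for k in range(len(edges) - 1):
        m = idx == k
        if m.any():
            rho[k] = counts[m].mean()
        if dot_bin.size and (dot_bin == k).any():
            meanI[k] = float(dot_I[dot_bin == k].mean())
    return rho, meanI


def dosage_compare(females: list[EmbryoDotSummary],
                   males: list[EmbryoDotSummary],
                   bin_width: float = 0.05,
                   x_range=(0.0, 0.6)) -> pd.DataFrame:
    """Between-sex comparison of rho and mean raw dot intensity per bin.

    Per-embryo values are the units of replication; pooled-variance
    Student's t-tests are two-tailed. Raises ValueError when either sex has
    fewer than 2 embryos (the comparison is then skipped by callers).
    """
    if len(females) < 2 or len(males) < 2:
        raise ValueError("dosage comparison needs >= 2 embryos per sex")
    lo, hi = x_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)

    f_bins = [_per_embryo_bins(e, edges) for e in females]
    m_bins = [_per_embryo_bins(e, edges) for e in males]

    rows = []
    for k in range(len(edges) - 1):
        fr = np.array([b[0][k] for b in f_bins if k in b[0]])
        mr = np.array([b[0][k] for b in m_bins if k in b[0]])
        fI = np.array([b[1][k] for b in f_bins if k in b[1]])
        mI = np.array([b[1][k] for b in m_bins if k in b[1]])
        row = {"bin_lo": edges[k], "bin_hi": edges[k + 1],
               "bin_mid": (edges[k] + edges[k + 1]) / 2,
               "rho_female": float(fr.mean()) if fr.size else float("nan"),
               "rho_male": float(mr.mean()) if mr.size else float("nan"),
               "I_female": float(fI.mean()) if fI.size else float("nan"),
               "I_male": float(mI.mean()) if mI.size else float("nan"),
               "p_rho": float("nan"), "p_I": float("nan")}
        if len(fr) >= 2 and len(mr) >= 2:
            res = stats.ttest_ind(fr, mr, equal_var=True)
            row["p_rho"] = float(res.pvalue)
        if len(fI) >= 2 and len(mI) >= 2:
            res = stats.ttest_ind(fI, mI, equal_var=True)
            row["p_I"] = float(res.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
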