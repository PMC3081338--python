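"""Ground-truth evaluation helpers for synthetic cohorts.

These functions compare pipeline output against the generator's
SyntheticTruth: spot-caller recall, per-embryo parameter recovery, pooled
pixel populations for local-enrichment statistics, and sex-call accuracy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .dosage import classify_sex
from .local import _bin_pixel_samples


def dot_recall(result, truth, match_radius_px: float = 4.0) -> float:
    """Fraction of true dots (in segmented nuclei) recovered by detection.

    True dots are restricted to nuclei that the segmentation found (matched
    by centroid), so border-excluded nuclei do not count against the
    spot caller.
    """
    seg_tree = cKDTree([n.centroid for n in result.nuclei])
    planted = truth.nuclei[["center_row", "center_col"]].to_numpy()
    owner_found = seg_tree.query(planted[truth.dots.nucleus],
                                 distance_upper_bound=3.0)[0] < 3.0
    true_pts = truth.dots[["row", "col"]].to_numpy()[owner_found]
    if len(true_pts) == 0:
        return float("nan")
    det = [d.centroid for d in result.dots if d.nucleus_id is not None]
    if not det:
        return 0.0
    dist = cKDTree(det).query(true_pts,
                              distance_upper_bound=match_radius_px)[0]
    return float(np.isfinite(dist).mean())


def pooled_pixel_samples(results, bin_range) -> dict:
    """Pool inactive / active / dot-site Bcd pixel samples across embryos."""
    lo, hi = bin_range
    pools = {"inactive": [], "active": [], "dot_sites": []}
    for res in results:
        bcd = res.image.channels["bcd"]
        inact, act, dsite = _bin_pixel_samples(bcd, res.nuclei, res.dots,
                                               lo, hi)
        pools["inactive"].append(inact)
        pools["active"].append(act)
        pools["dot_sites"].append(dsite)
    return {k: np.concatenate(v) if v else np.array([])
            for k, v in pools.items()}


def cohort_recovery(results) -> dict:
    """Mean +- SD of per-embryo Hill coefficients and boundary positions."""
    hills = np.array([r.hill.n_hill for r in results if r.hill is not None])
    bounds = np.array([r.boundary for r in results
                       if np.isfinite(r.boundary)])
    out = {"n_embryos": len(results),
           "n_hill_fits": int(hills.size),
           "n_boundaries": int(bounds.size)}
    if hills.size:
        out["hill_n_mean"] = float(hills.mean())
        out["hill_n_sd"] = float(hills.std(ddof=1)) if hills.size > 1 else 0.0
    if bounds.size:
        out["boundary_mean"] = float(bounds.mean())
        out["boundary_sd"] = (float(bounds.std(ddof=1))
                              if bounds.size > 1 else 0.0)
    return out


def sex_call_accuracy(results, region=(0.05, 0.40), threshold=0.10) -> dict:
    """Classify each embryo and score against the generator's true sex."""
    calls, truths, ratios = [], [], []
    for res in results:
        call = classify_sex(res.nuclei, region=region, threshold=threshold)
        calls.append(call.label)
        truths.append(res.truth.sex)
        ratios.append(call.two_dot_ratio)
    ok = [c == t for c, t in zip(calls, truths) if c is not None]
    return {
        "accuracy": float(np.mean(ok)) if ok else float("nan"),
        "n_called": len(ok),
        "calls": calls,
        "true_sexes": truths,
        "ratios": ratios,
        "female_ratio_mean": float(np.nanmean(
            [r for r, t in zip(ratios, truths) if t == "female"]) )
        if "female" in truths else float("nan"),
        "male_ratio_mean": float(np.nanmean(
            [r for r, t in zip(ratios, truths) if t == "male"]))
        if "male" in truths else float("nan"),
    }
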