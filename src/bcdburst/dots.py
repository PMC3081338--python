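"""Intron-dot calling by a joint intensity/size threshold, plus QC.

A nascent-transcript spot ("intron dot") is a connected cluster of pixels
that are all at or above a pixel-intensity threshold, where the cluster also
meets a pixel-count threshold. The intensity threshold is chosen by scanning
it while the size threshold is held fixed and locating the plateau of the
dot-density difference between two expression regions: a stable difference
means the detected pattern has stopped depending on the threshold, and the
smallest threshold on the plateau maximizes the number of nuclear dots.

Three QC error criteria accompany a threshold choice: the dot rate in a
non-expression window of the A-P axis, the ratio of cytoplasmic (false) dots
to nuclear dots, and the fraction of nuclei carrying more than two dots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .exceptions import PlateauNotFoundError
from .segment import AxisFrame, NucleusRecord, label_image


@dataclass(frozen=True)
class DotThresholds:
    """Joint threshold pair: pixel intensity and cluster pixel count."""

    t_intensity: float = 32.0
    t_size: int = 4

    def __post_init__(self):
        if self.t_intensity <= 0 or self.t_size <= 0:
            raise ValueError("thresholds must be strictly positive")
        if not 0 <= self.t_intensity <= 255:
            raise ValueError("t_intensity must lie in [0, 255]")


@dataclass
class IntronDot:
    """One detected nascent-transcript spot."""

    pixels: tuple[np.ndarray, np.ndarray]     # (rows, cols) of the cluster
    size: int
    centroid: tuple[float, float]             # (row, col)
    raw_intensity: float                      # summed pixel intensities
    norm_intensity: float = float("nan")      # fraction of per-embryo max
    nucleus_id: int | None = None             # None = cytoplasmic


@dataclass
class QCReport:
    """Detection-error estimates at a given threshold setting.

    Values are NaN (undefined, not zero) when their denominator population
    is empty.
    """

    nonexpression_dots_per_nucleus: float
    cytoplasm_to_nuclear_ratio: float
    frac_nuclei_gt2: float


_STRUCTURES = {
    1: ndi.generate_binary_structure(2, 1),   # 4-connectivity
    2: ndi.generate_binary_structure(2, 2),   # 8-connectivity
}


def detect_dots(intron: np.ndarray, thresholds: DotThresholds,
                connectivity: int = 2) -> list[IntronDot]:
    """Detect intron dots on a single 8-bit channel.

    Connected components (8-connectivity by default) of the pixel set
    ``{p : intron[p] >= t_intensity}``; components smaller than ``t_size``
    pixels are discarded. Returns an empty list when nothing passes.
    """
    img = np.asarray(intron)
    mask = img >= thresholds.t_intensity
    lbl, n = ndi.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return []
    sizes = np.bincount(lbl.ravel())
    keep = np.flatnonzero(sizes >= thresholds.t_size)
    keep = keep[keep > 0]
    if keep.size == 0:
        return []
    dots = []
    objects = ndi.find_objects(lbl)
    for lab in keep:
        sl = objects[lab - 1]
        m = lbl[sl] == lab
        rows, cols = np.nonzero(m)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        dots.append(IntronDot(
            pixels=(rows, cols),
            size=int(len(rows)),
            centroid=(float(rows.mean()), float(cols.mean())),
            raw_intensity=float(img[rows, cols].sum()),
        ))
    _normalize_intensities(dots)
    return dots


def _normalize_intensities(dots: list[IntronDot]) -> None:
    """Set norm_intensity = raw / per-embryo maximum raw intensity."""
    if not dots:
        return
    peak = max(d.raw_intensity for d in dots)
    for d in dots:
        d.norm_intensity = d.raw_intensity / peak if peak > 0 else float("nan")


def assign_dots(dots: list[IntronDot], nuclei: list[NucleusRecord],
                shape=None) -> list[IntronDot]:
    """Assign each dot to the nucleus whose pixel set contains its centroid.

    Dots whose centroid falls between nuclei keep ``nucleus_id=None``
    (cytoplasmic; retained for QC only). Updates ``dot_count`` on the
    nucleus records.
    """
    for rec in nuclei:
        rec.dot_count = 0
    if not dots:
        return dots
    if shape is None:
        h = max(int(d.centroid[0]) for d in dots) + 2
        w = max(int(d.centroid[1]) for d in dots) + 2
        for rec in nuclei:
            h = max(h, int(rec.pixels[0].max()) + 1)
            w = max(w, int(rec.pixels[1].max()) + 1)
        shape = (h, w)
    lbl = label_image(nuclei, shape)
    by_id = {rec.id: rec for rec in nuclei}
    for d in dots:
        r = int(round(d.centroid[0]))
        c = int(round(d.centroid[1]))
        if 0 <= r < shape[0] and 0 <= c < shape[1] and lbl[r, c] > 0:
            d.nucleus_id = int(lbl[r, c] - 1)
            by_id[d.nucleus_id].dot_count += 1
        else:
            d.nucleus_id = None
    return dots


def _region_density(dots, nuclei, lo, hi):
    """Dots per nucleus over an x/L window (NaN when no nuclei there)."""
    ids = {rec.id for rec in nuclei if lo <= rec.x_over_L < hi}
    if not ids:
        return float("nan")
    n_dots = sum(1 for d in dots if d.nucleus_id in ids)
    return n_dots / len(ids)


def optimize_threshold(intron: np.ndarray, nuclei: list[NucleusRecord],
                       axis: AxisFrame | None = None,
                       t_size: int = 4,
                       t_range=range(14, 62, 2),
                       plateau_tol: float = 0.01,
                       plateau_k: int = 3,
                       regions=((0.3, 0.4), (0.2, 0.3)),
                       qc_window=(0.55, 0.65),
                       connectivity: int = 2,
                       ) -> tuple[DotThresholds, pd.DataFrame]:
    """Scan the intensity threshold and pick the start of the stable plateau.

    For each candidate threshold the difference in dot density between two
    expression regions, delta_rho = rho(0.3-0.4) - rho(0.2-0.3), is
    computed; the chosen threshold is the smallest candidate from which
    successive changes in delta_rho stay below ``plateau_tol`` for
    ``plateau_k`` consecutive steps (thereby maximizing the total number of
    nuclear dots among plateau members). The full scan table (including the
    three QC criteria per threshold) is always returned; if no plateau is
    found a PlateauNotFoundError carrying the table is raised.

    Nuclei must already carry x/L coordinates (``annotate_nuclei``).
    """
    if any(math.isnan(rec.x_over_L) for rec in nuclei):
        if axis is None:
            raise ValueError("nuclei lack x/L and no axis frame was given")
        for rec in nuclei:
            rec.x_over_L = float(axis.x_over_L(rec.centroid))

    (hi_lo, hi_hi), (lo_lo, lo_hi) = regions
    rows = []
    shape = np.asarray(intron).shape
    for t in t_range:
        dots = detect_dots(intron, DotThresholds(float(t), t_size),
                           connectivity=connectivity)
        assign_dots(dots, nuclei, shape=shape)
        qc = qc_metrics(dots, nuclei, qc_window=qc_window)
        rho_hi = _region_density(dots, nuclei, hi_lo, hi_hi)
        rho_lo = _region_density(dots, nuclei, lo_lo, lo_hi)
        rows.append({
            "t_intensity": float(t),
            "n_dots_total": len(dots),
            "n_dots_nuclear": sum(1 for d in dots if d.nucleus_id is not None),
            "rho_region_hi": rho_hi,
            "rho_region_lo": rho_lo,
            "delta_rho": rho_hi - rho_lo,
            "nonexpression_rate": qc.nonexpression_dots_per_nucleus,
            "cytoplasm_ratio": qc.cytoplasm_to_nuclear_ratio,
            "frac_nuclei_gt2": qc.frac_nuclei_gt2,
        })
    table = pd.DataFrame(rows)

    delta = table["delta_rho"].to_numpy()
    diffs = np.abs(np.diff(delta))
    chosen = None
    for i in range(len(diffs) - plateau_k + 1):
        if np.all(diffs[i:i + plateau_k] < plateau_tol):
            chosen = float(table["t_intensity"].iloc[i])
            break
    if chosen is None:
        raise PlateauNotFoundError(
            "no plateau in delta_rho within the scanned threshold range",
            scan_table=table)
    return DotThresholds(chosen, t_size), table


def qc_metrics(dots: list[IntronDot], nuclei: list[NucleusRecord],
               qc_window=(0.55, 0.65)) -> QCReport:
    """Three detection-error criteria at the current threshold setting."""
    lo, hi = qc_window
    window_ids = {r.id for r in nuclei if lo <= r.x_over_L < hi}
    if window_ids:
        n_in_window = sum(1 for d in dots if d.nucleus_id in window_ids)
        nonexpr = n_in_window / len(window_ids)
    else:
        nonexpr = float("nan")

    n_nuclear = sum(1 for d in dots if d.nucleus_id is not None)
    n_cyto = sum(1 for d in dots if d.nucleus_id is None)
    cyto_ratio = n_cyto / n_nuclear if n_nuclear > 0 else float("nan")

    if nuclei:
        gt2 = sum(1 for r in nuclei if r.dot_count > 2) / len(nuclei)
    else:
        gt2 = float("nan")
    return QCReport(nonexpression_dots_per_nucleus=nonexpr,
                    cytoplasm_to_nuclear_ratio=cyto_ratio,
                    frac_nuclei_gt2=gt2)


def dots_table(dots: list[IntronDot], embryo_id: str = "embryo"):
    """Per-dot summary DataFrame (the CSV surface of this module)."""
    return pd.DataFrame({
        "embryo_id": [embryo_id] * len(dots),
        "nucleus_id": [d.nucleus_id for d in dots],
        "row": [d.centroid[0] for d in dots],
        "col": [d.centroid[1] for d in dots],
        "size_px": [d.size for d in dots],
        "raw_I": [d.raw_intensity for d in dots],
        "norm_I": [d.norm_intensity for d in dots],
    })
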