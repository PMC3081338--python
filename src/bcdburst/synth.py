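"""Synthetic embryo generator with ground truth.

Renders multi-channel 8-bit images of a syncytial-blastoderm *Drosophila*
embryo at nuclear cycle 14, embodying the statistical assumptions the
downstream analysis relies on:

* a smooth exponential anterior-posterior (A-P) Bicoid (Bcd) gradient with
  punctate within-nucleus texture and nucleus-to-nucleus fluctuation;
* per-gene-copy stochastic transcriptional bursts whose probability is a
  Hill function of the nuclear Bcd concentration;
* one nascent-transcript ("intron dot") spot per bursting gene copy, placed
  uniformly at random on the nuclear transverse disc, with a spot intensity
  that is independent of position and of Bcd;
* 1 vs 2 X-linked gene copies by sex, and an optional Bcd-independent
  posterior expression domain;
* an optional local enrichment of Bcd at actively transcribing loci, and an
  optional protein channel that reads out Hill(B_nuc) with low noise.

Channels are rendered in the fixed order (envelope, bcd, intron[, protein]).
All randomness flows from a single seed; output is byte-identical for
identical specs.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import GenerationError

CHANNEL_ORDER = ("envelope", "bcd", "intron", "protein")


@dataclass
class EmbryoSpec:
    """Parameters of one synthetic embryo.

    Geometry is in pixels (0.16 um/pixel by default); concentrations are in
    8-bit intensity units. ``gradient_length_constant`` is a fraction of the
    embryo length L, so the per-nucleus Bcd input is

        B(x) = gradient_amplitude * exp(-(x/L) / lambda) + background_offset

    and each gene copy bursts independently with probability

        q(B) = q_max * B^hill_n / (B^hill_n + hill_K^hill_n).
    """

    # canvas
    width: int = 2048
    height: int = 512
    pixel_size: float = 0.16          # um / pixel
    # nuclei
    nucleus_diameter_mean: float = 6.06   # um
    nucleus_diameter_sd: float = 0.80     # um
    nucleus_spacing_factor: float = 1.45  # grid pitch / mean diameter
    placement_jitter_px: float = 3.0
    nucleus_gap_px: float = 1.0
    ring_width_px: float = 2.0
    # Bcd gradient and its noise
    gradient_amplitude: float = 120.0
    gradient_length_constant: float = 0.2     # fraction of L
    background_offset: float = 2.0
    nuclear_fluctuation_cv: float = 0.15      # nucleus-to-nucleus lognormal CV
    bcd_texture_shape: float = 8.0            # gamma shape of punctate texture
    cytoplasm_bcd_fraction: float = 0.4
    # bursting
    hill_n: float = 6.0
    hill_K: float = 16.0
    q_max: float = 0.85
    copies_per_nucleus: int = 2
    sex: str = "autosomal"                    # female | male | autosomal
    posterior_domain: tuple[float, float, float] | None = (0.82, 0.96, 0.3)
    # intron dots
    dot_radius: float = 0.30                  # um, Gaussian sigma of the spot
    dot_peak_median: float = 120.0            # lognormal median peak intensity
    dot_peak_sigma: float = 0.20              # lognormal sigma (log scale)
    # local Bcd enrichment at bursting loci (amplitude of a Gaussian bump,
    # sigma = dot_radius); the magnitude of the real effect is unquantified,
    # this default is simply large enough to be detectable at realistic
    # pixel counts
    enrichment_amplitude: float = 10.0
    # nuclear "haze" on the intron channel (dim intranuclear background that
    # breaks up only above a finite intensity threshold, giving the
    # threshold scan a non-trivial plateau)
    nuclear_haze_mean: float = 14.0
    nuclear_haze_sd: float = 2.0              # between nuclei
    haze_pixel_sd: float = 3.0
    intron_background_mean: float = 3.0
    intron_background_sd: float = 1.5
    # envelope channel
    envelope_intensity: float = 200.0
    envelope_background: float = 12.0
    envelope_noise_sd: float = 1.5
    bcd_background_noise_sd: float = 1.0
    # optional protein (gene-product) channel = Hill(B_nuc) with low noise
    protein_channel: bool = False
    protein_amplitude: float = 150.0
    protein_baseline: float = 5.0
    protein_noise_sd: float = 3.0
    saturation_max_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.gradient_length_constant <= 0:
            raise ValueError("gradient_length_constant must be > 0")
        if not 0.0 <= self.q_max <= 1.0:
            raise ValueError("q_max must lie in [0, 1]")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")
        if self.copies_per_nucleus not in (1, 2):
            raise ValueError("copies_per_nucleus must be 1 or 2")
        if self.sex not in ("female", "male", "autosomal"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.sex == "male" and self.copies_per_nucleus != 1:
            raise ValueError("male X-linked mode implies copies_per_nucleus=1")
        if self.sex == "female" and self.copies_per_nucleus != 2:
            raise ValueError("female X-linked mode implies copies_per_nucleus=2")
        if self.posterior_domain is not None:
            lo, hi, q = self.posterior_domain
            if not (0 <= lo < hi <= 1 and 0 <= q <= 1):
                raise ValueError("posterior_domain must be (lo, hi, q) with "
                                 "0<=lo<hi<=1 and 0<=q<=1")

    # -- model pieces -----------------------------------------------------

    def gradient(self, x_over_L):
        """Mean Bcd input at normalized A-P position(s) x/L."""
        x = np.asarray(x_over_L, dtype=float)
        return (self.gradient_amplitude
                * np.exp(-x / self.gradient_length_constant)
                + self.background_offset)

    def hill(self, b):
        """Per-copy burst probability q(B)."""
        b = np.asarray(b, dtype=float)
        bn = np.power(np.clip(b, 0.0, None), self.hill_n)
        return self.q_max * bn / (bn + self.hill_K ** self.hill_n)

    @property
    def true_boundary(self) -> float:
        """x/L at which the per-copy burst probability is half of q_max."""
        ratio = self.gradient_amplitude / max(self.hill_K - self.background_offset, 1e-12)
        return self.gradient_length_constant * math.log(ratio)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["posterior_domain"] is not None:
            d["posterior_domain"] = list(d["posterior_domain"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EmbryoSpec":
        d = dict(d)
        if d.get("posterior_domain") is not None:
            d["posterior_domain"] = tuple(d["posterior_domain"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated embryo.

    ``nuclei`` has one row per planted nucleus (center, radius, x/L, the
    pre-quantization Bcd input ``b_true``, and per-copy burst states);
    ``dots`` has one row per rendered intron dot.
    """

    nuclei: pd.DataFrame
    dots: pd.DataFrame
    sex: str
    axis_length_px: float
    anterior_px: tuple[float, float]
    posterior_px: tuple[float, float]
    spec: EmbryoSpec

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    @property
    def n_dots(self) -> int:
        return len(self.dots)


@dataclass
class EmbryoImage:
    """Registered multi-channel 8-bit raster with pixel-size metadata.

    ``channels`` maps channel name -> (H, W) uint8 array. The A-P axis runs
    along image columns for generated embryos; for real input images it is
    re-estimated from the embryo mask.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float

    def __post_init__(self):
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def stack(self) -> np.ndarray:
        names = [n for n in CHANNEL_ORDER if n in self.channels]
        return np.stack([self.channels[n] for n in names])

    def channel_names(self) -> list[str]:
        return [n for n in CHANNEL_ORDER if n in self.channels]


def sample_burst_states(b_nuc, spec: EmbryoSpec, rng, x_over_L=None):
    """Draw burst indicators for each gene copy of one nucleus.

    Each copy bursts independently with probability
    ``q(B) = q_max * B^n / (B^n + K^n)``; inside the posterior domain (if
    configured) the per-copy probability is raised to the Bcd-independent
    posterior value when that is larger.
    """
    if b_nuc < 0:
        raise ValueError("b_nuc must be >= 0")
    q = float(spec.hill(b_nuc))
    if spec.posterior_domain is not None and x_over_L is not None:
        lo, hi, q_post = spec.posterior_domain
        if lo <= x_over_L <= hi:
            q = max(q, q_post)
    return rng.random(spec.copies_per_nucleus) < q


# ---------------------------------------------------------------------------
# nucleus placement


def _place_nuclei(spec: EmbryoSpec, rng):
    """Jittered hexagonal packing of nuclei inside an elliptical embryo.

    Returns (centers[N,2] as (row, col), radii_px[N]). Raises
    GenerationError when the requested diameters cannot be placed without
    overlap.
    """
    h, w = spec.height, spec.width
    cy, cx = h / 2.0, w / 2.0
    a = w / 2.0 - 4.0   # semi-axis along A-P (columns)
    b = h / 2.0 - 4.0
    d_mean_px = spec.nucleus_diameter_mean / spec.pixel_size
    pitch = spec.nucleus_spacing_factor * d_mean_px
    dy = pitch * math.sqrt(3.0) / 2.0

    rows = np.arange(cy - b, cy + b + 1e-9, dy)
    centers = []
    for i, y in enumerate(rows):
        x0 = cx - a + (pitch / 2.0 if i % 2 else 0.0)
        xs = np.arange(x0, cx + a + 1e-9, pitch)
        for x in xs:
            centers.append((y, x))
    centers = np.asarray(centers, dtype=float)
    centers += rng.uniform(-spec.placement_jitter_px, spec.placement_jitter_px,
                           size=centers.shape)

    lo = spec.nucleus_diameter_mean - 2.5 * spec.nucleus_diameter_sd
    hi = spec.nucleus_diameter_mean + 2.5 * spec.nucleus_diameter_sd
    diam_um = np.clip(
        rng.normal(spec.nucleus_diameter_mean, spec.nucleus_diameter_sd,
                   size=len(centers)),
        max(lo, 1.0), hi)
    radii = diam_um / spec.pixel_size / 2.0

    # keep nuclei (plus ring and a margin) fully inside the ellipse
    margin = radii + spec.ring_width_px + 2.0
    ry = (centers[:, 0] - cy) / np.maximum(b - margin, 1.0)
    rx = (centers[:, 1] - cx) / np.maximum(a - margin, 1.0)
    keep = (rx ** 2 + ry ** 2) <= 1.0
    centers, radii = centers[keep], radii[keep]
    if len(centers) == 0:
        raise GenerationError("embryo canvas too small: no nucleus fits")

    # resolve residual overlaps by shrinking the larger partner
    min_radius = max(lo, 1.0) / spec.pixel_size / 2.0 * 0.8
    tree = cKDTree(centers)
    sep = spec.ring_width_px + spec.nucleus_gap_px
    for i, j in sorted(tree.query_pairs(r=float(2 * radii.max() + sep))):
        dist = float(np.hypot(*(centers[i] - centers[j])))
        excess = radii[i] + radii[j] + sep - dist
        if excess > 0:
            k = i if radii[i] >= radii[j] else j
            radii[k] -= excess
            if radii[k] < min_radius:
                raise GenerationError(
                    f"cannot place nucleus near {tuple(centers[k])} without "
                    f"overlap; reduce diameters or increase spacing")
    return centers, radii


# ---------------------------------------------------------------------------
# rendering helpers


def _embryo_ellipse_mask(spec: EmbryoSpec):
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    a = w / 2.0 - 4.0
    b = h / 2.0 - 4.0
    return ((xx - w / 2.0) / a) ** 2 + ((yy - h / 2.0) / b) ** 2 <= 1.0


def _disc_patch(shape, center, radius):
    """Bounding-box slices and boolean disc mask for one nucleus."""
    h, w = shape
    cy, cx = center
    r = int(math.ceil(radius)) + 1
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 2, h)
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 2, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - cy, xx - cx)
    return (slice(y0, y1), slice(x0, x1)), dist


def _add_gaussian_bump(img, center, sigma, amplitude):
    h, w = img.shape
    cy, cx = center
    r = int(math.ceil(4 * sigma)) + 1
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 2, h)
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2))


def _quantize(img, mask):
    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    out[~mask] = 0
    return out


# ---------------------------------------------------------------------------
# main entry point


def generate_embryo(spec: EmbryoSpec) -> tuple[EmbryoImage, SyntheticTruth]:
    """Render one synthetic embryo and its ground truth.

    Deterministic given ``spec.seed``: identical specs produce byte-identical
    channel arrays and truth tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = _embryo_ellipse_mask(spec)

    centers, radii = _place_nuclei(spec, rng)
    n = len(centers)
    a = w / 2.0 - 4.0
    anterior = (h / 2.0, w / 2.0 - a)
    posterior = (h / 2.0, w / 2.0 + a)
    L = 2.0 * a
    x_over_L = (centers[:, 1] - anterior[1]) / L

    # per-nucleus Bcd input: exponential gradient with lognormal fluctuation
    sigma_ln = math.sqrt(math.log(1.0 + spec.nuclear_fluctuation_cv ** 2))
    fluct = rng.lognormal(mean=-0.5 * sigma_ln ** 2, sigma=sigma_ln, size=n)
    b_true = spec.gradient(x_over_L) * fluct

    # burst states per gene copy
    states = np.zeros((n, spec.copies_per_nucleus), dtype=bool)
    for i in range(n):
        states[i] = sample_burst_states(b_true[i], spec, rng,
                                        x_over_L=x_over_L[i])

    # dot placement: uniform on the nuclear transverse disc
    dot_rows = []
    sigma_dot_px = spec.dot_radius / spec.pixel_size
    for i in range(n):
        for c in range(spec.copies_per_nucleus):
            if not states[i, c]:
                continue
            u = math.sqrt(rng.random())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            rr = u * (radii[i] - 0.5)
            dy, dx = rr * math.sin(theta), rr * math.cos(theta)
            peak = rng.lognormal(math.log(spec.dot_peak_median),
                                 spec.dot_peak_sigma)
            dot_rows.append((i, c, centers[i, 0] + dy, centers[i, 1] + dx,
                             peak))

    # ---- envelope channel ----
    env = np.full((h, w), spec.envelope_background, dtype=float)
    env += rng.normal(0.0, spec.envelope_noise_sd, size=(h, w))
    for i in range(n):
        sl, dist = _disc_patch((h, w), centers[i], radii[i] + 1)
        ring = (dist <= radii[i]) & (dist > radii[i] - spec.ring_width_px)
        env[sl][ring] = spec.envelope_intensity

    # ---- Bcd channel ----
    col_xL = np.clip((np.arange(w) - anterior[1]) / L, 0.0, 1.0)
    cyto = spec.cytoplasm_bcd_fraction * spec.gradient(col_xL)
    k = spec.bcd_texture_shape
    bcd = np.broadcast_to(cyto, (h, w)) * rng.gamma(k, 1.0 / k, size=(h, w))
    bcd = bcd + rng.normal(0.0, spec.bcd_background_noise_sd, size=(h, w))
    for i in range(n):
        sl, dist = _disc_patch((h, w), centers[i], radii[i])
        inside = dist <= radii[i]
        texture = rng.gamma(k, 1.0 / k, size=dist.shape)
        patch = bcd[sl]
        patch[inside] = b_true[i] * texture[inside]
    if spec.enrichment_amplitude > 0:
        for (_, _, dy, dx, _) in dot_rows:
            _add_gaussian_bump(bcd, (dy, dx), sigma_dot_px,
                               spec.enrichment_amplitude)

    # ---- intron channel ----
    intron = np.full((h, w), spec.intron_background_mean, dtype=float)
    intron += rng.normal(0.0, spec.intron_background_sd, size=(h, w))
    haze_means = rng.normal(spec.nuclear_haze_mean, spec.nuclear_haze_sd,
                            size=n)
    for i in range(n):
        sl, dist = _disc_patch((h, w), centers[i], radii[i])
        inside = dist <= radii[i]
        noise = rng.normal(0.0, spec.haze_pixel_sd, size=dist.shape)
        patch = intron[sl]
        patch[inside] = haze_means[i] + noise[inside]
    for (_, _, dy, dx, peak) in dot_rows:
        _add_gaussian_bump(intron, (dy, dx), sigma_dot_px, peak)

    channels = {
        "envelope": _quantize(env, mask),
        "bcd": _quantize(bcd, mask),
        "intron": _quantize(intron, mask),
    }

    # ---- optional protein channel ----
    if spec.protein_channel:
        prot = np.full((h, w), spec.protein_baseline, dtype=float)
        prot_val = (spec.protein_baseline
                    + spec.protein_amplitude * spec.hill(b_true) / max(spec.q_max, 1e-9))
        prot += rng.normal(0.0, spec.protein_noise_sd, size=(h, w))
        for i in range(n):
            sl, dist = _disc_patch((h, w), centers[i], radii[i])
            inside = dist <= radii[i]
            patch = prot[sl]
            patch[inside] += prot_val[i] - spec.protein_baseline
        channels["protein"] = _quantize(prot, mask)

    sat = sum(int((c == 255).sum()) for c in channels.values())
    total = mask.sum() * len(channels)
    if sat / total > spec.saturation_max_fraction:
        warnings.warn(
            f"saturated fraction {sat / total:.3%} exceeds "
            f"saturation_max_fraction={spec.saturation_max_fraction:.3%}",
            stacklevel=2)

    nuclei = pd.DataFrame({
        "nucleus": np.arange(n),
        "center_row": centers[:, 0],
        "center_col": centers[:, 1],
        "radius_px": radii,
        "diameter_um": 2.0 * radii * spec.pixel_size,
        "x_over_L": x_over_L,
        "b_true": b_true,
        "n_dots": states.sum(axis=1),
    })
    for c in range(spec.copies_per_nucleus):
        nuclei[f"burst_copy{c}"] = states[:, c]
    dots = pd.DataFrame(dot_rows,
                        columns=["nucleus", "copy", "row", "col", "peak"])

    truth = SyntheticTruth(nuclei=nuclei, dots=dots, sex=spec.sex,
                           axis_length_px=L, anterior_px=anterior,
                           posterior_px=posterior, spec=spec)
    return EmbryoImage(channels=channels, pixel_size=spec.pixel_size), truth


def write_embryo(image: EmbryoImage, truth: SyntheticTruth, outdir,
                 name: str = "embryo") -> dict:
    """Write a multi-page TIFF plus truth sidecars (CSV + JSON echo)."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tiff_path = outdir / f"{name}.tif"
    tifffile.imwrite(tiff_path, image.stack(), photometric="minisblack")
    truth.nuclei.to_csv(outdir / f"{name}_truth_nuclei.csv", index=False,
                        float_format="%.6g")
    truth.dots.to_csv(outdir / f"{name}_truth_dots.csv", index=False,
                      float_format="%.6g")
    params = {
        "sex": truth.sex,
        "axis_length_px": truth.axis_length_px,
        "anterior_px": list(truth.anterior_px),
        "posterior_px": list(truth.posterior_px),
        "channels": image.channel_names(),
        "spec": truth.spec.to_dict(),
    }
    with open(outdir / f"{name}_truth.json", "w") as fh:
        json.dump(params, fh, indent=2)
    return {"tiff": str(tiff_path)}
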