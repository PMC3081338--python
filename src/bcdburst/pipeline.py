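"""Pipeline orchestration: generate -> segment -> detect -> quantify ->
analyze, as a configurable, logged, reproducible run.

``process_embryo`` performs the full per-embryo analysis in memory and is
the unit the tests and the acceptance script drive; ``run_pipeline`` wraps
it with cohort handling, CSV/JSON outputs and a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dosage import EmbryoDotSummary, classify_sex, dosage_compare
from .dots import (DotThresholds, assign_dots, detect_dots, dots_table,
                   optimize_threshold, qc_metrics)
from .exceptions import BcdBurstError, HillFitError, PipelineError
from .geometry import pairwise_distances, radial_distribution
from .io import read_embryo_tiff, write_table
from .local import active_inactive_compare, single_embryo_enrichment
from .profiles import (BinProfile, bin_profile, boundary_position,
                       bootstrap_profile, hill_fit)
from .segment import (annotate_nuclei, embryo_mask, estimate_axis,
                      nuclei_table, segment_nuclei)
from .synth import EmbryoImage, EmbryoSpec, generate_embryo, write_embryo

log = logging.getLogger("bcdburst")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips losslessly to YAML."""

    # synthesis mode: number of embryos and spec overrides; or input TIFFs
    n_embryos: int = 14
    spec_overrides: dict = field(default_factory=dict)
    sexes: list | None = None            # per-embryo sex labels, or None
    input_tiffs: list = field(default_factory=list)
    channel_order: list = field(
        default_factory=lambda: ["envelope", "bcd", "intron"])
    pixel_size: float = 0.16
    # detection
    thresholds: str | list = "auto"      # "auto" or [t_intensity, t_size]
    auto_threshold_per_embryo: bool = False
    connectivity: int = 2
    # analysis
    bin_width: float = 0.02
    anterior_window: list = field(default_factory=lambda: [0.1, 0.6])
    bootstrap_reps: int = 300
    # bookkeeping
    seed: int = 0
    outdir: str = "bcdburst_out"
    write_images: bool = False
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class EmbryoResult:
    """All per-embryo artifacts of one pass through the pipeline."""

    embryo_id: str
    image: EmbryoImage
    nuclei: list
    dots: list
    thresholds: DotThresholds
    axis: object
    qc: object
    profile: BinProfile
    truth: object = None
    scan_table: pd.DataFrame | None = None
    hill: object = None
    boundary: float = float("nan")
    hill_error: str = ""

    def summary(self) -> EmbryoDotSummary:
        return EmbryoDotSummary(self.embryo_id, self.nuclei, self.dots)


def process_embryo(image: EmbryoImage, embryo_id: str = "embryo",
                   thresholds="auto",
                   bin_width: float = 0.02,
                   anterior_window=(0.1, 0.6),
                   connectivity: int = 2,
                   anterior: str = "auto",
                   truth=None) -> EmbryoResult:
    """Segment, detect and analyze a single embryo image."""
    env = image.channels["envelope"]
    bcd = image.channels["bcd"]
    intron = image.channels["intron"]

    mask = embryo_mask(env)
    axis = estimate_axis(mask, bcd=bcd, anterior=anterior)
    nuclei = segment_nuclei(env, pixel_size=image.pixel_size)
    annotate_nuclei(nuclei, axis, bcd=bcd)

    if thresholds == "auto":
        thresholds, scan = optimize_threshold(intron, nuclei,
                                              connectivity=connectivity)
    else:
        scan = None
        if not isinstance(thresholds, DotThresholds):
            thresholds = DotThresholds(*thresholds)
    dots = detect_dots(intron, thresholds, connectivity=connectivity)
    assign_dots(dots, nuclei, shape=image.shape)
    qc = qc_metrics(dots, nuclei)

    profile = bin_profile(nuclei, bin_width=bin_width)
    result = EmbryoResult(embryo_id=embryo_id, image=image, nuclei=nuclei,
                          dots=dots, thresholds=thresholds, axis=axis,
                          qc=qc, profile=profile, truth=truth,
                          scan_table=scan)
    anterior_profile = profile.select(*anterior_window)
    try:
        result.hill = hill_fit(anterior_profile)
    except (HillFitError, ValueError) as exc:
        result.hill_error = str(exc)
    try:
        result.boundary = boundary_position(anterior_profile)
    except ValueError as exc:
        result.hill_error = (result.hill_error + "; " if result.hill_error
                             else "") + f"boundary: {exc}"
    return result


def synthesize_cohort(config: RunConfig):
    """Yield (EmbryoImage, SyntheticTruth, embryo_id) per configured embryo."""
    for i in range(config.n_embryos):
        overrides = dict(config.spec_overrides)
        if config.sexes is not None:
            sex = config.sexes[i % len(config.sexes)]
            overrides["sex"] = sex
            overrides["copies_per_nucleus"] = 1 if sex == "male" else 2
        overrides.setdefault("pixel_size", config.pixel_size)
        spec = EmbryoSpec(seed=config.seed + i, **overrides)
        image, truth = generate_embryo(spec)
        yield image, truth, f"embryo_{i:02d}"


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full cohort run; returns the manifest dictionary.

    Every stage failure is re-raised as PipelineError naming the stage and
    embryo. Re-running with the same config produces byte-identical CSVs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.verbosity)
    log.info("run start: %d embryo(s), seed=%d, hash=%s",
             config.n_embryos if not config.input_tiffs
             else len(config.input_tiffs),
             config.seed, config.config_hash())

    stages: list[dict] = []
    results: list[EmbryoResult] = []
    fixed_thresholds = (None if config.thresholds == "auto"
                        else DotThresholds(*config.thresholds))

    def embryos():
        if config.input_tiffs:
            for p in config.input_tiffs:
                yield (read_embryo_tiff(p, tuple(config.channel_order),
                                        config.pixel_size),
                       None, Path(p).stem)
        else:
            yield from synthesize_cohort(config)

    for image, truth, eid in embryos():
        try:
            thr = ("auto" if fixed_thresholds is None else fixed_thresholds)
            res = process_embryo(
                image, embryo_id=eid, thresholds=thr,
                bin_width=config.bin_width,
                anterior_window=tuple(config.anterior_window),
                connectivity=config.connectivity, truth=truth)
        except BcdBurstError as exc:
            raise PipelineError(f"stage failure on {eid}: {exc}") from exc
        if (fixed_thresholds is None
                and not config.auto_threshold_per_embryo):
            # one threshold for the whole cohort, chosen on the first embryo
            fixed_thresholds = res.thresholds
        results.append(res)
        log.info("%s: %d nuclei, %d dots, T=(%g, %d), boundary=%.4g",
                 eid, len(res.nuclei), len(res.dots),
                 res.thresholds.t_intensity, res.thresholds.t_size,
                 res.boundary)
        stages.append({"embryo": eid, "n_nuclei": len(res.nuclei),
                       "n_dots": len(res.dots),
                       "t_intensity": res.thresholds.t_intensity,
                       "t_size": res.thresholds.t_size})
        if config.write_images and truth is not None:
            write_embryo(image, truth, outdir / "images", name=eid)

    # ---- per-embryo outputs ----
    for res in results:
        edir = outdir / res.embryo_id
        write_table(nuclei_table(res.nuclei), edir / "nuclei.csv")
        write_table(dots_table(res.dots, res.embryo_id), edir / "dots.csv")
        prof = bootstrap_profile(res.profile, reps=config.bootstrap_reps,
                                 seed=config.seed)
        write_table(prof.table, edir / "profile.csv")
        if res.scan_table is not None:
            write_table(res.scan_table, edir / "threshold_scan.csv")
        bcd = res.image.channels["bcd"]
        write_table(active_inactive_compare(res.nuclei,
                                            bin_width=config.bin_width),
                    edir / "active_inactive.csv")
        write_table(single_embryo_enrichment(bcd, res.nuclei, res.dots,
                                             bin_width=config.bin_width),
                    edir / "enrichment_profile.csv")
        pd_res = pairwise_distances(res.dots, res.nuclei,
                                    pixel_size=config.pixel_size)
        u = radial_distribution(res.dots, res.nuclei)
        summary = {
            "embryo_id": res.embryo_id,
            "n_nuclei": len(res.nuclei),
            "n_dots": len(res.dots),
            "mean_pair_distance_um": pd_res.mean,
            "sd_pair_distance_um": pd_res.sd,
            "n_radial_samples": int(u.size),
            "boundary_x_over_L": res.boundary,
            "hill_n": res.hill.n_hill if res.hill else None,
            "hill_K": res.hill.K if res.hill else None,
            "hill_rho_max": res.hill.rho_max if res.hill else None,
            "hill_error": res.hill_error,
            "qc": dataclasses.asdict(res.qc),
        }
        with open(edir / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2)

    # ---- cohort-level outputs ----
    cohort: dict = {"n_embryos": len(results)}
    hills = [r.hill.n_hill for r in results if r.hill is not None]
    bounds = [r.boundary for r in results if np.isfinite(r.boundary)]
    if hills:
        cohort["hill_n_mean"] = float(np.mean(hills))
        cohort["hill_n_sd"] = float(np.std(hills, ddof=1)) if len(hills) > 1 else 0.0
    if bounds:
        cohort["boundary_mean"] = float(np.mean(bounds))
        cohort["boundary_sd"] = float(np.std(bounds, ddof=1)) if len(bounds) > 1 else 0.0
    sex_rows = []
    for r in results:
        call = classify_sex(r.nuclei)
        truth_sex = r.truth.sex if r.truth is not None else ""
        sex_rows.append({"embryo_id": r.embryo_id,
                         "two_dot_ratio": call.two_dot_ratio,
                         "n_two_dot": call.n_two_dot,
                         "n_one_dot": call.n_one_dot,
                         "call": call.label or "none",
                         "true_sex": truth_sex})
    write_table(pd.DataFrame(sex_rows), outdir / "sex_calls.csv")

    females = [r.summary() for r, s in zip(results, sex_rows)
               if s["call"] == "female"]
    males = [r.summary() for r, s in zip(results, sex_rows)
             if s["call"] == "male"]
    if len(females) >= 2 and len(males) >= 2:
        write_table(dosage_compare(females, males),
                    outdir / "dosage_compare.csv")
    else:
        log.info("dosage comparison skipped: need >= 2 embryos per sex "
                 "(found %d female, %d male)", len(females), len(males))

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "embryos": stages,
        "cohort": cohort,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)
    config.to_yaml(outdir / "config.yaml")
    log.info("run complete: outputs in %s", outdir)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _setup_logging(outdir: Path, verbosity: str) -> None:
    log.setLevel(getattr(logging, verbosity.upper(), logging.INFO))
    have_file = any(isinstance(h, logging.FileHandler) for h in log.handlers)
    if not have_file:
        fh = logging.FileHandler(outdir / "run.log")
        fh.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in log.handlers):
        log.addHandler(logging.StreamHandler())
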