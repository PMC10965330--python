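"""End-to-end reproducible runs: phantoms → segmentation → morphometry →
stats → transport, with one output directory per run.

A :class:`RunConfig` fixes the input source (a synthetic cohort spec or
user-supplied TIFF paths), the enabled stages, all stage parameters and the
seed. ``run_pipeline`` executes the enabled stages in order and writes CSV
tables, a machine-readable ``report.json`` (group means ± SD, test results,
uptake ratios) and the artifacts each stage produced. Identical config + seed
give identical summaries.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, morphometry, phantoms, segmentation, stats
from . import transport as transport_mod
from .errors import ConfigurationError

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one input source: a phantom cohort (default study design when
    ``cohort_spec`` is None) or pre-segmented label TIFFs on disk.
    """

    out_dir: str | Path = "villimorph_run"
    seed: int = 0
    # input source (exactly one)
    use_phantom_cohort: bool = True
    cohort_spec: phantoms.CohortSpec | None = None
    label_volume_paths: dict[str, list[str]] = field(default_factory=dict)
    cross_section_paths: dict[str, list[str]] = field(default_factory=dict)
    # stage toggles
    run_segmentation_check: bool = True
    run_morphometry: bool = True
    run_stats: bool = True
    run_transport: bool = True
    # stage parameters
    noise_sd: float = 10.0
    class_means: dict[int, float] = field(
        default_factory=lambda: {0: 50.0, 1: 200.0, 2: 200.0, 3: 200.0})
    min_component_voxels: int = 1000
    surface_method: str = "mesh"
    alpha: float = 0.05
    vmax_values: tuple[float, ...] = ()  # default: membrane numbers 0.1/1/10
    km: float = 0.5
    write_artifacts: bool = False  # TIFFs for every phantom (large); tables always

    def validate(self) -> None:
        sources = int(self.use_phantom_cohort) + int(
            bool(self.label_volume_paths) or bool(self.cross_section_paths))
        if sources != 1:
            raise ConfigurationError(
                "exactly one input source: phantom cohort or TIFF paths")
        if not (self.run_segmentation_check or self.run_morphometry
                or self.run_stats or self.run_transport):
            raise ConfigurationError("all pipeline stages are disabled")
        if self.run_stats and not self.run_morphometry:
            raise ConfigurationError("stats stage requires morphometry tables")


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)
    payload = asdict(config)
    payload.pop("out_dir")  # output location is not part of the run identity
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stamp(df: pd.DataFrame, config: RunConfig, cfg_hash: str) -> pd.DataFrame:
    df = df.copy()
    df["software_version"] = __version__
    df["seed"] = config.seed
    df["config_hash"] = cfg_hash
    return df


def _segmentation_check(volume, config: RunConfig) -> dict:
    """Round-trip sanity check: render → threshold → compare to the labels."""
    rendered = phantoms.render_intensity(volume, config.class_means,
                                         noise_sd=config.noise_sd,
                                         seed=config.seed)
    seg = segmentation.threshold_segment(
        rendered, segmentation.SegmentationConfig(threshold="otsu"))
    truth = volume.foreground()
    predicted = seg.labels > 0
    inter = np.logical_and(truth, predicted).sum()
    union = np.logical_or(truth, predicted).sum()
    return {"iou": float(inter / union) if union else 1.0,
            "noise_sd": config.noise_sd}


def _transport_stage(config: RunConfig, out: Path) -> dict:
    """Smooth vs invaginated representative pair swept over V_max."""
    # Representative sections at the emulated equid-like group P:A mean.
    invag_spec = phantoms._cross_section_for_pa(
        0.24, invagination_count=12, pixel_size=0.5, seed=config.seed)
    smooth_spec = phantoms.matched_smooth_spec(invag_spec)
    invag, _ = phantoms.make_cross_section(invag_spec)
    smooth, _ = phantoms.make_cross_section(smooth_spec)
    if config.vmax_values:
        vmax_values = list(config.vmax_values)
    else:
        # membrane numbers V_max·r_o/(D·c_ref) of 0.1, 1, 10 — the low /
        # medium / high permeability regimes
        r_o = invag_spec.outer_radius
        vmax_values = [b / r_o for b in (0.1, 1.0, 10.0)]
    sweep = transport_mod.permeability_sweep(smooth, invag, vmax_values,
                                             K_m=config.km)
    sweep.to_csv(out / "permeability_sweep.csv", index=False)
    return {
        "vmax_values": [float(v) for v in vmax_values],
        "uptake_ratio_invaginated_vs_smooth":
            dict(zip((f"{v:g}" for v in vmax_values),
                     sweep["uptake_ratio"].round(6).tolist())),
        "membrane_length_ratio": float(sweep["membrane_length_ratio"].iloc[0]),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; write tables and report.json; return report."""
    config.validate()
    cfg_hash = _config_hash(config)
    out = Path(config.out_dir)
    for sub in ("morphometry", "stats", "transport"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    report: dict = {"software_version": __version__, "seed": config.seed,
                    "config_hash": cfg_hash, "stages": {}}

    # --- input stage -------------------------------------------------------
    if config.use_phantom_cohort:
        spec = config.cohort_spec or phantoms.study_cohort_spec(seed=config.seed)
        cohort = phantoms.make_cohort(spec, rasterize=True)
        meta = cohort.table[["group", "placenta_id", "villus_id"]]
        volumes = list(zip(meta.itertuples(index=False), cohort.volumes))
        sections = list(zip(meta.itertuples(index=False), cohort.cross_sections))
        _stamp(cohort.table, config, cfg_hash).to_csv(
            out / "morphometry" / "ground_truth.csv", index=False)
        logger.info("phantom cohort: %d villi in %d groups",
                    len(cohort.table), cohort.table["group"].nunique())
    else:
        volumes, sections = [], []
        for group, paths in config.label_volume_paths.items():
            for i, p in enumerate(paths):
                vol = io.read_label_stack(p, allow_default=True)
                meta = pd.Series({"group": group, "placenta_id": Path(p).stem,
                                  "villus_id": f"{Path(p).stem}_{i}"})
                volumes.append((meta, vol))
        for group, paths in config.cross_section_paths.items():
            for i, p in enumerate(paths):
                cross = io.read_cross_section(p, allow_default=True)
                meta = pd.Series({"group": group, "placenta_id": Path(p).stem,
                                  "villus_id": f"{Path(p).stem}_{i}"})
                sections.append((meta, cross))

    # --- segmentation self-check ------------------------------------------
    if config.run_segmentation_check and volumes:
        report["stages"]["segmentation_check"] = _segmentation_check(
            volumes[0][1], config)

    # --- morphometry --------------------------------------------------------
    table_3d = table_2d = None
    if config.run_morphometry:
        recs3 = [morphometry.measure_volume_and_area(
                    vol, method=config.surface_method,
                    sample_id=m.villus_id, placenta_id=m.placenta_id,
                    group=m.group)
                 for m, vol in volumes]
        recs2 = [morphometry.measure_cross_section(
                    cross, sample_id=m.villus_id, placenta_id=m.placenta_id,
                    group=m.group)
                 for m, cross in sections]
        if recs3:
            table_3d = morphometry.records_to_frame(recs3)
            _stamp(table_3d, config, cfg_hash).to_csv(
                out / "morphometry" / "morphometry_3d.csv", index=False)
        if recs2:
            table_2d = morphometry.records_to_frame(recs2)
            _stamp(table_2d, config, cfg_hash).to_csv(
                out / "morphometry" / "morphometry_2d.csv", index=False)
        report["stages"]["morphometry"] = {
            "n_volumes": len(recs3), "n_cross_sections": len(recs2),
            "surface_method": config.surface_method}

    # --- stats ---------------------------------------------------------------
    if config.run_stats:
        stats_report = {}
        for name, table, col in (("sa_to_v", table_3d, "sa_to_v"),
                                 ("pa", table_2d, "pa")):
            if table is None or table["group"].nunique() != 2:
                continue
            samples = stats.aggregate_per_placenta(table, col)
            (g1, s1), (g2, s2) = sorted(samples.items())
            comparison = stats.compare_groups(s1, s2, alpha=config.alpha)
            stats_report[name] = {
                "group_means": comparison.group_means,
                "group_sds": comparison.group_sds,
                "test_used": comparison.test_used,
                "p_value": comparison.p_value,
                "assumptions": comparison.assumption_report,
            }
        (out / "stats" / "comparisons.json").write_text(
            json.dumps(stats_report, indent=2, sort_keys=True))
        report["stages"]["stats"] = stats_report

    # --- transport -----------------------------------------------------------
    if config.run_transport:
        report["stages"]["transport"] = _transport_stage(config, out / "transport")

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
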