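"""End-to-end orchestration: simulate -> quantify -> differential ->
annotate -> coloc -> ci, with a single reproducible JSON report.

The run report echoes the configuration and seed, so a report fully
determines a re-run; identical config + seed produce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, annotation, coloc, differential, drugcomb, io as pio, quant, synth

logger = logging.getLogger(__name__)

ALL_STAGES = ("quantify", "differential", "annotate", "coloc", "ci")


@dataclasses.dataclass
class ImageConfig:
    n_spots: int = 20
    overlap_fraction: float = 0.5
    spot_sigma: float = 2.0
    noise_sd: float = 5.0
    amplitude: float = 1000.0
    background: float = 100.0
    size: tuple[int, int] = (256, 256)
    threshold: float | str = "otsu"   # fixed value or "otsu"
    min_area: int = 4
    max_area: int = 10_000

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")


@dataclasses.dataclass
class DoseConfig:
    m_a: float = 1.5
    dm_a: float = 10.0
    m_b: float = 2.0
    dm_b: float = 5.0
    alpha: float = 0.7
    ratio: float = 1.0
    doses: tuple[float, ...] = (1.25, 2.5, 5.0, 10.0, 20.0, 40.0)
    replicates: int = 3
    noise_sd: float = 0.02
    fa_levels: tuple[float, ...] = (0.5, 0.75, 0.9)
    form: str = "exclusive"


@dataclasses.dataclass
class FlowConfig:
    n_events: int = 10_000
    positive_fraction: float = 0.3
    gate_threshold: float = 400.0


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    seed: int = 0
    outdir: str = "pipeline_out"
    stages: tuple[str, ...] = ALL_STAGES
    counts: synth.SynthCountConfig = dataclasses.field(
        default_factory=lambda: synth.SynthCountConfig(categorize=True)
    )
    control_mode: str = "mean"
    min_detect: float = 1.0
    min_replicates: int | None = None
    log2_threshold: float = 1.0
    pairing: str = "by_index"
    strict: bool = True
    image: ImageConfig = dataclasses.field(default_factory=ImageConfig)
    dose: DoseConfig = dataclasses.field(default_factory=DoseConfig)
    flow: FlowConfig = dataclasses.field(default_factory=FlowConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.log2_threshold <= 0:
            raise ValueError("log2_threshold must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "counts" in kw:
            kw["counts"] = synth.SynthCountConfig(**kw["counts"])
        if "image" in kw:
            img = dict(kw["image"])
            if "size" in img:
                img["size"] = tuple(img["size"])
            kw["image"] = ImageConfig(**img)
        if "dose" in kw:
            d = dict(kw["dose"])
            for key in ("doses", "fa_levels"):
                if key in d:
                    d[key] = tuple(d[key])
            kw["dose"] = DoseConfig(**d)
        if "flow" in kw:
            kw["flow"] = FlowConfig(**kw["flow"])
        if "stages" in kw:
            kw["stages"] = tuple(kw["stages"])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["image"]["size"] = list(d["image"]["size"])
        d["dose"]["doses"] = list(d["dose"]["doses"])
        d["dose"]["fa_levels"] = list(d["dose"]["fa_levels"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------


def _stage_seed(seed: int, offset: int) -> int:
    return (seed + offset) % (2**31 - 1)


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Execute the enabled stages in order and return the run report.

    Stage outputs (per-stage matrices, differential table, coefficient
    and CI tables) are written under ``config.outdir`` together with
    ``report.json``; pass ``write_outputs=False`` to keep everything in
    memory.
    """
    cfg = config
    outdir = pio.ensure_dir(cfg.outdir) if write_outputs else None
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    logger.info("pipeline start: hash=%s seed=%d", cfg.config_hash(), cfg.seed)

    normalized = subtracted = truth = None
    result = None
    if "quantify" in cfg.stages or "differential" in cfg.stages or "annotate" in cfg.stages:
        counts_cfg = dataclasses.replace(cfg.counts, seed=_stage_seed(cfg.seed, 1))
        raw, truth = synth.generate_tube_counts(counts_cfg)
        subtracted = quant.subtract_background(raw, control_mode=cfg.control_mode)
        logged = quant.log2_with_floor(subtracted)
        normalized = quant.quantile_normalize(logged)
        detect = quant.call_detected_proteins(
            subtracted, min_value=cfg.min_detect, min_replicates=cfg.min_replicates
        )
        report["stages"]["quantify"] = {
            "n_proteins": int(raw.data.shape[0]),
            "n_samples": int(raw.data.shape[1]),
            "detected_sizes": {k: int(v) for k, v in detect.sizes.items()},
        }
        if write_outputs:
            pio.write_counts_tsv(raw, outdir / "counts_raw.tsv", outdir / "samples.tsv")
            pio.write_matrix_tsv(subtracted, outdir / "matrix_subtracted.tsv")
            pio.write_matrix_tsv(normalized, outdir / "matrix_normalized.tsv")
        logger.info("quantify: %s", report["stages"]["quantify"])

    if "differential" in cfg.stages:
        fc = differential.replicate_fold_changes(
            normalized,
            condition_a=cfg.counts.condition_a,
            condition_b=cfg.counts.condition_b,
            pairing=cfg.pairing,
        )
        result = differential.reproducible_differential(
            fc, log2_threshold=cfg.log2_threshold, strict=cfg.strict
        )
        recovery = differential.recovery_report(result, truth)
        report["stages"]["differential"] = {**result.summary(), "recovery": recovery}
        if write_outputs:
            result.to_frame().to_csv(outdir / "differential.tsv", sep="\t")
            (outdir / "differential_summary.json").write_text(
                json.dumps(result.summary(), sort_keys=True, indent=2) + "\n"
            )
        logger.info("differential: %s", result.summary())

    if "annotate" in cfg.stages:
        if "category" not in truth.columns:
            raise ValueError("annotate stage needs categorize=True in the count config")
        ann = synth.truth_annotation(truth)
        per_cond = {
            cond: normalized.data[normalized.condition_columns(cond)].mean(axis=1)
            for cond in normalized.conditions()
        }
        values = pd.DataFrame(per_cond)
        cm = annotation.category_summary(values, ann, by="subcategory")
        diff_col = cm.difference(cfg.counts.condition_b, cfg.counts.condition_a)
        universe = set(values.index)
        enr = annotation.enrichment_table(
            result.differential if result is not None else set(),
            ann,
            universe,
            by="category",
        )
        report["stages"]["annotate"] = {
            "category_difference": {k: float(v) for k, v in diff_col.items()},
            "member_counts": {k: int(v) for k, v in cm.counts.items()},
            "enrichment": {
                row["category"]: {"p_value": float(row["p_value"]), "odds_ratio": float(row["odds_ratio"])}
                for _, row in enr.iterrows()
            },
        }
        if write_outputs:
            cm.means.to_csv(outdir / "category_matrix.tsv", sep="\t")
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        logger.info("annotate: differences %s", dict(diff_col.round(3)))

    if "coloc" in cfg.stages:
        img_cfg = cfg.image
        image, img_truth = synth.generate_two_channel_image(
            n_spots=img_cfg.n_spots,
            overlap_fraction=img_cfg.overlap_fraction,
            spot_sigma=img_cfg.spot_sigma,
            noise_sd=img_cfg.noise_sd,
            size=img_cfg.size,
            amplitude=img_cfg.amplitude,
            background=img_cfg.background,
            seed=_stage_seed(cfg.seed, 2),
        )
        rois = coloc.detect_puncta(
            image.reference,
            threshold_method=img_cfg.threshold,
            min_area=img_cfg.min_area,
            max_area=img_cfg.max_area,
        )
        mres = coloc.manders(
            image, rois, partner_threshold=img_cfg.threshold, reference_threshold=img_cfg.threshold
        )
        report["stages"]["coloc"] = {
            "n_rois": len(rois),
            "planted_overlap_fraction": img_truth.overlap_fraction,
            "pooled_m1": round(mres.m1, 6),
            "pooled_m2": round(mres.m2, 6),
        }
        if write_outputs:
            pio.write_two_channel_tiff(
                image, outdir / "channel_reference.tif", outdir / "channel_partner.tif"
            )
            pd.DataFrame(
                {"roi": range(1, len(rois) + 1), "m1": mres.per_roi_m1, "m2": mres.per_roi_m2}
            ).to_csv(outdir / "manders_per_roi.csv", index=False)
        logger.info("coloc: %s", report["stages"]["coloc"])

    if "ci" in cfg.stages:
        d = cfg.dose
        dr_truth = synth.DoseResponseTruth(
            m_a=d.m_a, dm_a=d.dm_a, m_b=d.m_b, dm_b=d.dm_b, alpha=d.alpha, ratio=d.ratio
        )
        dr = synth.generate_dose_response(
            dr_truth,
            doses=d.doses,
            replicates=d.replicates,
            noise_sd=d.noise_sd,
            seed=_stage_seed(cfg.seed, 3),
        )
        ci_res = drugcomb.ci_analysis(
            dr, ratio=d.ratio, fa_levels=d.fa_levels, form=d.form
        )
        events = synth.generate_flow_events(
            n_events=cfg.flow.n_events,
            positive_fraction=cfg.flow.positive_fraction,
            seed=_stage_seed(cfg.seed, 4),
        )
        gate = drugcomb.gate_apoptosis(events, cfg.flow.gate_threshold)
        report["stages"]["ci"] = {
            "fa_levels": list(d.fa_levels),
            "ci_mean": [round(v, 6) for v in ci_res.ci],
            "ci_sd": [round(v, 6) for v in (ci_res.ci_sd or [])],
            "planted_alpha": d.alpha,
            "apoptosis_fraction": gate["fraction"],
            "apoptosis_planted_fraction": cfg.flow.positive_fraction,
        }
        if write_outputs:
            pio.write_dose_response_csv(dr, outdir / "dose_response.csv")
            pio.write_events_csv(events, outdir / "flow_events.csv")
        logger.info("ci: %s", report["stages"]["ci"])

    validate_report(report)
    if write_outputs:
        (outdir / "report.json").write_text(report_json(report))
    return report


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON serialization of a run report."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"


# ---------------------------------------------------------------------------
# light-weight schema validation (subset of JSON Schema)


def _load_schema() -> dict:
    ref = importlib.resources.files("proteaphagy.data") / "report_schema.json"
    return json.loads(ref.read_text())


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _check(instance, schema: dict, path: str = "$") -> list[str]:
    errors = []
    typ = schema.get("type")
    if typ is not None and not isinstance(instance, _TYPES[typ]):
        errors.append(f"{path}: expected {typ}, got {type(instance).__name__}")
        return errors
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                errors.extend(_check(instance[key], sub, f"{path}.{key}"))
    return errors


def validate_report(report: dict) -> None:
    """Validate a run report against the shipped schema; raise on failure."""
    errors = _check(report, _load_schema())
    if errors:
        raise ValueError("invalid run report: " + "; ".join(errors))
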