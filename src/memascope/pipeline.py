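"""End-to-end orchestration: simulate -> segment -> gate -> stats -> report.

Every stage writes its tabular outputs as CSV into the run directory and
registers them in a manifest (stage, path, sha256, seed), so re-running
with the same configuration reproduces identical manifests and each
stage can be re-run from its persisted inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, design as design_mod, gating, imaging, stats, synthetic
from .design import ArrayLayout, Design, build_layout, default_design
from .synthetic import ConditionEffectModel, DEFAULT_EFFECTS

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_fixture", "FIXTURE_PROFILES"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "memascope_run"
    # design / simulation
    n_conditions: int | None = None  # None -> packaged 228-condition design
    replicates: int = 5
    spot_diameter_px: int = 64
    density_mean: float = 25.0
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    baseline_logit: float = -2.0
    # imaging
    smoothing_sigma: float = 2.0
    min_distance: int = 5
    min_area: int = 20
    # gating
    gate_k: float = 1.0
    min_ref_cells: int = 50
    # stats
    alpha: float = 0.05
    perplexity: float = 30.0
    linkage: str = "average"
    run_embedding: bool = True
    # reproducibility
    seed: int = 0
    write_images: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def subset_design(design: Design, n_conditions: int) -> Design:
    """A backbone-spanning subset: every backbone-alone condition first
    (the COL4 gating reference must survive), then factor conditions in
    round-robin over backbones."""
    alone = [c for c in design.conditions if not c.soluble_factors]
    rest = [c for c in design.conditions if c.soluble_factors]
    by_backbone: dict[frozenset, list] = {}
    for c in rest:
        by_backbone.setdefault(c.ecm_backbone, []).append(c)
    interleaved = []
    queues = list(by_backbone.values())
    while any(queues):
        for q in queues:
            if q:
                interleaved.append(q.pop(0))
    chosen = (alone + interleaved)[:n_conditions]
    return Design(components=design.components, conditions=chosen)


def _build_inputs(config: RunConfig) -> tuple[Design, ArrayLayout, ConditionEffectModel]:
    dsn = default_design()
    if config.n_conditions is not None:
        dsn = subset_design(dsn, config.n_conditions)
    n_spots = len(dsn.conditions) * config.replicates
    cols = int(np.ceil(np.sqrt(n_spots)))
    rows = int(np.ceil(n_spots / cols))
    layout = build_layout(
        dsn.conditions, config.replicates, rows, cols,
        seed=config.seed, spot_diameter_px=config.spot_diameter_px,
    )
    model = ConditionEffectModel(
        baseline_logit=config.baseline_logit,
        component_effects=dict(config.effects),
        density_mean=config.density_mean,
    )
    return dsn, layout, model


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run every stage and return the manifest DataFrame."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows: list[dict] = []

    def register(stage: str, path: Path) -> None:
        manifest_rows.append(
            {
                "stage": stage,
                "path": str(path.relative_to(out)),
                "sha256": _sha256(path),
                "seed": config.seed,
                "version": __version__,
            }
        )

    def write_csv(stage: str, name: str, df: pd.DataFrame) -> Path:
        path = out / name
        df.to_csv(path, index=False)
        register(stage, path)
        return path

    # -- stage: simulate ---------------------------------------------------
    stage = "simulate"
    try:
        dsn, layout, model = _build_inputs(config)
        design_path = out / "design.csv"
        design_mod.design_to_csv(dsn, design_path)
        register(stage, design_path)
        layout_path = out / "layout.csv"
        design_mod.layout_to_csv(layout, layout_path)
        register(stage, layout_path)
        images, ground_truth, _ = synthetic.render_array(
            dsn, layout, model,
            seed=config.seed,
            out_dir=out / "images" if config.write_images else None,
        )
        write_csv(stage, "ground_truth.csv", ground_truth)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - halt with stage name
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: segment ----------------------------------------------------
    stage = "segment"
    try:
        params = imaging.SegmentationParams(
            smoothing_sigma=config.smoothing_sigma,
            min_distance=config.min_distance,
            min_area=config.min_area,
        )
        frames = [
            imaging.process_spot(img, layout.spot_assignments[idx], params)
            for idx, img in images.items()
        ]
        cells = pd.concat(frames, ignore_index=True)
        if cells.empty:
            raise ValueError("segmentation produced no cells")
        write_csv(stage, "cells.csv", cells)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: gate -------------------------------------------------------
    stage = "gate"
    try:
        gate = gating.fit_gate(
            cells, dsn, k=config.gate_k, min_ref_cells=config.min_ref_cells
        )
        write_csv(stage, "gates.csv", gate.to_frame())
        called = gating.call_cells(cells, gate)
        spots = gating.summarize_spots(called)
        write_csv(stage, "spots.csv", spots)
        conditions = gating.summarize_conditions(spots)
        write_csv(stage, "conditions.csv", conditions)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: stats ------------------------------------------------------
    stage = "stats"
    try:
        fit = stats.fit_component_glm(spots, dsn)
        write_csv(stage, "glm_coefficients.csv", fit.coef_frame)
        contrasts = stats.posthoc_contrasts(fit, alpha=config.alpha)
        write_csv(stage, "contrasts.csv", contrasts)
        if fit.factor_names:
            ranking = stats.rank_factor_effects(fit, alpha=config.alpha)
            write_csv(stage, "factor_ranking.csv", ranking)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: embed ------------------------------------------------------
    stage = "embed"
    try:
        pheno = conditions[~conditions["flagged"]].set_index("condition_id")[
            gating.PHENOTYPE_FEATURES
        ].dropna(axis=1, how="all").dropna()
        clustering = stats.zscore_cluster(pheno, linkage_method=config.linkage)
        zpath = out / "zscores.csv"
        clustering["z"].to_csv(zpath)
        register(stage, zpath)
        if config.run_embedding and len(pheno) >= 3 * config.perplexity:
            coords = stats.embed_conditions(
                pheno, perplexity=config.perplexity, seed=config.seed
            )
            epath = out / "embedding.csv"
            coords.rename_axis("condition_id").to_csv(epath)
            register(stage, epath)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    config.to_yaml(out / "config.yaml")
    return manifest


FIXTURE_PROFILES = {
    # profile: (n_conditions or None for packaged 228, replicates, density)
    "tiny": {"n_conditions": 6, "replicates": 3, "density_mean": 20.0},
    "default": {"n_conditions": None, "replicates": 10, "density_mean": 25.0},
    "stress": {"n_conditions": None, "replicates": 20, "density_mean": 40.0},
}


def make_fixture(profile: str, seed: int, out_dir: str | Path) -> Path:
    """Write design, layout, effect model, images and ground truth."""
    if profile not in FIXTURE_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {list(FIXTURE_PROFILES)}")
    spec = FIXTURE_PROFILES[profile]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dsn = default_design()
    if spec["n_conditions"] is not None:
        dsn = subset_design(dsn, spec["n_conditions"])
    n_spots = len(dsn.conditions) * spec["replicates"]
    cols = int(np.ceil(np.sqrt(n_spots)))
    rows = int(np.ceil(n_spots / cols))
    layout = build_layout(dsn.conditions, spec["replicates"], rows, cols, seed=seed)
    model = ConditionEffectModel(
        component_effects=dict(DEFAULT_EFFECTS), density_mean=spec["density_mean"]
    )
    design_mod.design_to_csv(dsn, out / "design.csv")
    design_mod.layout_to_csv(layout, out / "layout.csv")
    with open(out / "effect_model.json", "w") as fh:
        json.dump(
            {
                "baseline_logit": model.baseline_logit,
                "component_effects": model.component_effects,
                "density_mean": model.density_mean,
                "intensity_params": {
                    ch: {st: list(v) for st, v in states.items()}
                    for ch, states in model.intensity_params.items()
                },
                "background_level": model.background_level,
                "noise_sd": model.noise_sd,
            },
            fh,
            indent=2,
        )
    synthetic.render_array(dsn, layout, model, seed=seed, out_dir=out / "images")
    return out
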