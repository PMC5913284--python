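"""Synthetic MEMA arrays with ground truth.

Generates multichannel spot images (nuclei + two receptor-marker channels,
AXL and cKIT) whose statistical structure matches what the analysis chain
assumes: Poisson cell counts per spot, a double-positive subpopulation
whose log-odds are additive in the microenvironment components, lognormal
marker intensities for positive and negative cells, and additive
background plus Gaussian read noise.  Every image comes with a ground
truth table, so segmentation, gating and effect-decoupling can all be
scored against planted values.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ArrayLayout, Design, DesignError, MicroenvironmentCondition

__all__ = [
    "ConditionEffectModel",
    "GroundTruthCell",
    "SpotImage",
    "plant_fractions",
    "render_spot",
    "render_array",
    "CHANNELS",
]

CHANNELS = ("dna", "axl", "ckit")


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ConditionEffectModel:
    """Generative model for planted subpopulation structure.

    The probability that a cell is AXL+/cKIT+ (double-positive) in a
    condition is ``logistic(baseline_logit + sum of component effects)``,
    i.e. microenvironment components act additively on the log-odds scale
    — the same scale on which the downstream GLM decouples them.

    intensity_params maps marker channel -> state -> (log_mean, log_sd)
    of the lognormal mean fluorescence of a cell in that state.
    """

    baseline_logit: float = -2.0
    component_effects: dict[str, float] = field(default_factory=dict)
    density_mean: float = 25.0
    intensity_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "axl": {"negative": (np.log(60.0), 0.35), "positive": (np.log(600.0), 0.35)},
            "ckit": {"negative": (np.log(60.0), 0.35), "positive": (np.log(600.0), 0.35)},
        }
    )
    background_level: float = 100.0
    noise_sd: float = 10.0
    nucleus_radius_px: float = 5.0
    nucleus_amplitude: float = 1200.0
    min_separation_factor: float = 2.2
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.density_mean <= 0:
            raise ValueError("density_mean must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for channel, states in self.intensity_params.items():
            if states["positive"][0] < states["negative"][0]:
                raise ValueError(
                    f"channel {channel!r}: positive-state log-mean below negative-state"
                )

    def condition_logit(self, condition: MicroenvironmentCondition) -> float:
        return self.baseline_logit + sum(
            self.component_effects.get(name, 0.0) for name in condition.components
        )


#: Synthetic defaults mirroring the study's qualitative structure: the
#: COL4 backbone is the suppressive reference; COL1 raises the double-
#: positive log-odds by 1.6; OPN, IL-8 and COL6A3 are the planted
#: plasticity-inductive soluble factors.
DEFAULT_EFFECTS: dict[str, float] = {
    "COL1": 1.6,
    "LAM1": 0.7,
    "LAM5": -0.2,
    "OPN": 1.2,
    "IL-8": 1.0,
    "COL6A3": 0.9,
}


@dataclass(frozen=True)
class GroundTruthCell:
    spot_index: int
    row: float
    col: float
    radius_px: float
    state: str  # "double_positive" | "negative"
    true_axl: float
    true_ckit: float


@dataclass
class SpotImage:
    """Multichannel pixel data for one spot (0-based, row-major coords)."""

    spot_index: int
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def plant_fractions(
    design: Design, effect_model: ConditionEffectModel
) -> dict[str, float]:
    """Per-condition double-positive probability implied by the model."""
    unknown = set(effect_model.component_effects) - set(design.components)
    if unknown:
        raise DesignError(f"effect model names unknown components: {sorted(unknown)}")
    return {
        cond.condition_id: _logistic(effect_model.condition_logit(cond))
        for cond in design.conditions
    }


def _place_cells(
    rng: np.random.Generator,
    n: int,
    center: float,
    spot_radius: float,
    cell_radius: float,
    min_sep: float,
    overlap_fraction: float,
    max_tries: int = 2000,
) -> np.ndarray:
    """Rejection-sample cell centers in the spot disk.

    Centers keep a minimum pairwise distance ``min_sep`` except for a
    fraction deliberately placed touching an existing cell to exercise
    watershed splitting.
    """
    placed: list[tuple[float, float]] = []
    margin = spot_radius - cell_radius - 1.0
    for _ in range(n):
        make_overlap = placed and rng.random() < overlap_fraction
        for _ in range(max_tries):
            if make_overlap:
                base = placed[rng.integers(len(placed))]
                theta = rng.uniform(0, 2 * np.pi)
                d = 1.2 * cell_radius
                r, c = base[0] + d * np.sin(theta), base[1] + d * np.cos(theta)
                if (r - center) ** 2 + (c - center) ** 2 > margin**2:
                    continue
                ok = all(
                    (r - pr) ** 2 + (c - pc) ** 2 >= (0.9 * d) ** 2
                    for pr, pc in placed
                    if (pr, pc) != base
                )
            else:
                theta = rng.uniform(0, 2 * np.pi)
                rad = margin * np.sqrt(rng.random())
                r, c = center + rad * np.sin(theta), center + rad * np.cos(theta)
                ok = all(
                    (r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in placed
                )
            if ok:
                placed.append((r, c))
                break
        # spot saturated: silently stop adding (density capped by geometry)
        else:
            break
    return np.asarray(placed, dtype=float).reshape(-1, 2)


def render_spot(
    condition: MicroenvironmentCondition,
    pi: float,
    effect_model: ConditionEffectModel,
    seed: int | np.random.SeedSequence,
    spot_index: int = 0,
    spot_diameter_px: int = 64,
    image_margin_px: int = 4,
) -> tuple[SpotImage, list[GroundTruthCell]]:
    """Render one spot and its ground truth.

    Nuclei are anti-aliased disks in the DNA channel; marker channels put
    each cell's drawn lognormal mean uniformly over its footprint, then
    add the flat background and Gaussian read noise.  Pixel values are
    clipped to [0, 65535] and stored 16-bit.  Same seed, same bytes.
    """
    rng = np.random.default_rng(seed)
    m = effect_model
    side = spot_diameter_px + 2 * image_margin_px
    center = (side - 1) / 2.0
    spot_radius = spot_diameter_px / 2.0
    radius = m.nucleus_radius_px

    n = int(rng.poisson(m.density_mean))
    centers = _place_cells(
        rng, n, center, spot_radius, radius,
        m.min_separation_factor * radius, m.overlap_fraction,
    )
    n = len(centers)
    states = rng.random(n) < pi  # True -> double positive

    true_means = {}
    for ch in ("axl", "ckit"):
        mu_neg, sd_neg = m.intensity_params[ch]["negative"]
        mu_pos, sd_pos = m.intensity_params[ch]["positive"]
        vals = np.where(
            states,
            rng.lognormal(mu_pos, sd_pos, size=n),
            rng.lognormal(mu_neg, sd_neg, size=n),
        )
        true_means[ch] = vals

    rr, cc = np.mgrid[0:side, 0:side]
    dna = np.zeros((side, side), dtype=float)
    axl = np.zeros((side, side), dtype=float)
    ckit = np.zeros((side, side), dtype=float)
    for i in range(n):
        dist = np.hypot(rr - centers[i, 0], cc - centers[i, 1])
        # anti-aliased nucleus disk: 1 inside, linear falloff over 1 px
        cover = np.clip(radius + 0.5 - dist, 0.0, 1.0)
        dna = np.maximum(dna, m.nucleus_amplitude * cover)
        footprint = dist <= radius
        axl[footprint] = np.maximum(axl[footprint], true_means["axl"][i])
        ckit[footprint] = np.maximum(ckit[footprint], true_means["ckit"][i])

    channels: dict[str, np.ndarray] = {}
    for name, signal in (("dna", dna), ("axl", axl), ("ckit", ckit)):
        img = signal + m.background_level
        if m.noise_sd > 0:
            img = img + rng.normal(0.0, m.noise_sd, size=img.shape)
        channels[name] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    cells = [
        GroundTruthCell(
            spot_index=spot_index,
            row=float(centers[i, 0]),
            col=float(centers[i, 1]),
            radius_px=radius,
            state="double_positive" if states[i] else "negative",
            true_axl=float(true_means["axl"][i]),
            true_ckit=float(true_means["ckit"][i]),
        )
        for i in range(n)
    ]
    return SpotImage(spot_index=spot_index, channels=channels), cells


def ground_truth_frame(cells: list[GroundTruthCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spot_index": c.spot_index,
                "row": c.row,
                "col": c.col,
                "radius_px": c.radius_px,
                "state": c.state,
                "true_axl": c.true_axl,
                "true_ckit": c.true_ckit,
            }
            for c in cells
        ],
        columns=["spot_index", "row", "col", "radius_px", "state", "true_axl", "true_ckit"],
    )


def simulate_spot_counts(
    design: Design,
    effect_model: ConditionEffectModel,
    replicates: int,
    cells_per_spot: float,
    seed: int | np.random.Generator,
    condition_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate per-spot (cells, double-positive) counts without images.

    Cell counts are Poisson(cells_per_spot); double-positive counts are
    binomial with the condition's planted probability.  Output matches
    the spot-summary schema consumed by the GLM stage, so statistical
    calibration studies can bypass rendering and segmentation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fractions = plant_fractions(design, effect_model)
    if condition_ids is None:
        condition_ids = list(fractions)
    rows = []
    spot_index = 0
    for cid in condition_ids:
        for _ in range(replicates):
            n = int(rng.poisson(cells_per_spot))
            k = int(rng.binomial(n, fractions[cid])) if n else 0
            rows.append(
                {
                    "spot_index": spot_index,
                    "condition_id": cid,
                    "n_cells": n,
                    "n_double_positive": k,
                    "fraction_dp": k / n if n else np.nan,
                }
            )
            spot_index += 1
    return pd.DataFrame(rows)


def render_array(
    design: Design,
    layout: ArrayLayout,
    effect_model: ConditionEffectModel,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[dict[int, SpotImage], pd.DataFrame, pd.DataFrame]:
    """Render every assigned spot of a layout.

    Returns (images by spot index, ground-truth cell table, manifest).
    Per-spot streams are spawned from one seed sequence keyed by spot
    index, so the array is reproducible spot-by-spot.  If ``out_dir`` is
    given, 16-bit single-channel TIFFs named ``{spot_index}_{channel}.tif``
    are written along with the two CSV tables.
    """
    fractions = plant_fractions(design, effect_model)
    root = np.random.SeedSequence(seed)
    images: dict[int, SpotImage] = {}
    all_cells: list[GroundTruthCell] = []
    manifest_rows = []
    for spot_index in sorted(layout.spot_assignments):
        cid = layout.spot_assignments[spot_index]
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(spot_index,))
        image, cells = render_spot(
            design.condition(cid),
            fractions[cid],
            effect_model,
            ss,
            spot_index=spot_index,
            spot_diameter_px=layout.spot_diameter_px,
        )
        images[spot_index] = image
        all_cells.extend(cells)
        row = {"spot_index": spot_index, "condition_id": cid, "n_cells_true": len(cells)}
        manifest_rows.append(row)
    del root

    gt = ground_truth_frame(all_cells)
    manifest = pd.DataFrame(manifest_rows)

    if out_dir is not None:
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for spot_index, image in images.items():
            for ch, arr in image.channels.items():
                fname = out / f"{spot_index}_{ch}.tif"
                tifffile.imwrite(fname, arr)
        for i, row in enumerate(manifest_rows):
            digests = []
            for ch in CHANNELS:
                data = (out / f"{row['spot_index']}_{ch}.tif").read_bytes()
                digests.append(hashlib.sha256(data).hexdigest()[:12])
            manifest_rows[i]["checksums"] = ";".join(digests)
        manifest = pd.DataFrame(manifest_rows)
        gt.to_csv(out / "ground_truth.csv", index=False)
        manifest.to_csv(out / "manifest.csv", index=False)
    return images, gt, manifest
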