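import pandas as pd
import pytest
from hypothesis import settings

from memascope.design import Design, build_layout, default_design
from memascope.synthetic import (
    ConditionEffectModel,
    DEFAULT_EFFECTS,
    render_array,
)
from memascope import gating, imaging

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def packaged_design() -> Design:
    return default_design()


@pytest.fixture(scope="session")
def small_design(packaged_design) -> Design:
    """All 4 backbones alone plus 5 factors at printed concentration."""
    factors = {"OPN", "IL-8", "COL6A3", "EGF", "HGF"}
    keep = [
        c
        for c in packaged_design.conditions
        if not c.soluble_factors
        or (
            next(iter(c.soluble_factors)) in factors
            and not c.condition_id.endswith("@lo")
        )
    ]
    return Design(components=packaged_design.components, conditions=keep)


@pytest.fixture(scope="session")
def effect_model() -> ConditionEffectModel:
    return ConditionEffectModel(component_effects=dict(DEFAULT_EFFECTS))


@pytest.fixture(scope="session")
def rendered_small_array(small_design, effect_model):
    """5-replicate rendered array over the 24-condition small design."""
    layout = build_layout(small_design.conditions, 5, 12, 10, seed=3)
    images, ground_truth, manifest = render_array(
        small_design, layout, effect_model, seed=11
    )
    return {
        "design": small_design,
        "layout": layout,
        "images": images,
        "ground_truth": ground_truth,
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def segmented_cells(rendered_small_array) -> pd.DataFrame:
    arr = rendered_small_array
    frames = [
        imaging.process_spot(img, arr["layout"].spot_assignments[idx])
        for idx, img in arr["images"].items()
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def spot_summaries(segmented_cells, small_design) -> pd.DataFrame:
    gate = gating.fit_gate(segmented_cells, small_design)
    called = gating.call_cells(segmented_cells, gate)
    return gating.summarize_spots(called)
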