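"""Combinatorial microenvironment array design.

A MEMA (MicroEnvironment MicroArray) prints a grid of protein spots on a
polyacrylamide-coated slide.  Each spot carries one *condition*: an ECM
backbone (one or more structural matrix proteins such as COL1, COL4, LAM1,
LAM1+LAM5) optionally co-printed with a single soluble factor (growth
factor, cytokine, or matricellular protein).  Cells cultured on the array
experience each condition in 5-20 replicate spots, giving per-condition
single-cell statistics.

This module models components, conditions and layouts, enumerates
combinatorial condition sets, builds seeded replicate layouts, validates
designs, and round-trips everything through CSV.  The packaged default
design (228 conditions) lives in :func:`default_design`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComponentClass",
    "MicroenvironmentComponent",
    "MicroenvironmentCondition",
    "Design",
    "ArrayLayout",
    "DesignError",
    "CapacityError",
    "Violation",
    "condition_id_for",
    "enumerate_conditions",
    "build_layout",
    "validate_design",
    "default_design",
    "design_to_csv",
    "design_from_csv",
    "layout_to_csv",
    "layout_from_csv",
]


class DesignError(ValueError):
    """Invalid design input (duplicate names, unknown components, ...)."""


class CapacityError(DesignError):
    """Layout grid too small for the requested replication."""


class ComponentClass(str, Enum):
    ECM = "ECM"
    SOLUBLE = "soluble"


@dataclass(frozen=True)
class MicroenvironmentComponent:
    """One printable protein with its printing concentration."""

    name: str
    component_class: ComponentClass
    concentration: float
    unit: str = "ug/ml"

    def __post_init__(self) -> None:
        if not self.name:
            raise DesignError("component name must be non-empty")
        if not np.isfinite(self.concentration) or self.concentration <= 0:
            raise DesignError(
                f"component {self.name!r}: concentration must be > 0, "
                f"got {self.concentration}"
            )


@dataclass(frozen=True)
class MicroenvironmentCondition:
    """One printed combination: ECM backbone set + soluble factor set.

    ``concentrations`` overrides the design's catalogue concentration for
    named components (used for conditions that print the same pair at a
    different dilution; such duplicates carry distinct condition_ids).
    """

    condition_id: str
    ecm_backbone: frozenset[str]
    soluble_factors: frozenset[str] = frozenset()
    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ecm_backbone:
            raise DesignError(
                f"condition {self.condition_id!r}: ECM backbone must be non-empty"
            )

    @property
    def components(self) -> frozenset[str]:
        return self.ecm_backbone | self.soluble_factors


def condition_id_for(
    backbone: Iterable[str],
    factors: Iterable[str] = (),
    suffix: str = "",
) -> str:
    """Deterministic, human-readable condition id.

    Sorted backbone names joined by "+", then "|", then sorted factor
    names; an optional suffix distinguishes concentration variants.
    """
    bb = "+".join(sorted(backbone))
    fx = "+".join(sorted(factors))
    cid = f"{bb}|{fx}"
    return cid + suffix


@dataclass
class Design:
    """A component catalogue plus the condition list printed on the array."""

    components: dict[str, MicroenvironmentComponent]
    conditions: list[MicroenvironmentCondition]

    def __post_init__(self) -> None:
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DesignError(f"duplicate condition_ids: {dup}")
        for cond in self.conditions:
            unknown = cond.components - self.components.keys()
            if unknown:
                raise DesignError(
                    f"condition {cond.condition_id!r} references unknown "
                    f"components: {sorted(unknown)}"
                )

    @property
    def condition_ids(self) -> list[str]:
        return [c.condition_id for c in self.conditions]

    def condition(self, condition_id: str) -> MicroenvironmentCondition:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)

    def ecm_level(self, condition_id: str) -> str:
        """The backbone label of a condition (sorted names joined by '+')."""
        return "+".join(sorted(self.condition(condition_id).ecm_backbone))


@dataclass
class ArrayLayout:
    """Grid of printed spots mapping row-major spot index -> condition."""

    rows: int
    cols: int
    spot_assignments: dict[int, str]
    spot_diameter_px: int = 64
    spot_pitch_px: int = 80
    replicate_min: int = 5
    replicate_max: int = 20

    @property
    def n_spots(self) -> int:
        return self.rows * self.cols

    def spot_rc(self, spot_index: int) -> tuple[int, int]:
        return divmod(spot_index, self.cols)

    def replicate_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cid in self.spot_assignments.values():
            counts[cid] = counts.get(cid, 0) + 1
        return counts


def enumerate_conditions(
    ecm_backbones: Sequence[Iterable[str]],
    factors: Sequence[str],
    scheme: str = "both",
) -> list[MicroenvironmentCondition]:
    """Enumerate combinatorial conditions from backbones and factors.

    scheme:
        ``ecm_alone`` -- each backbone by itself;
        ``ecm_plus_single_factor`` -- each backbone x each single factor;
        ``both`` -- union of the two.

    Output is deduplicated and sorted by condition_id.
    """
    if scheme not in {"ecm_alone", "ecm_plus_single_factor", "both"}:
        raise DesignError(f"unknown scheme {scheme!r}")
    if not ecm_backbones:
        raise DesignError("at least one ECM backbone required")
    if len(set(factors)) != len(factors):
        dup = sorted({f for f in factors if list(factors).count(f) > 1})
        raise DesignError(f"duplicate factor names: {dup}")
    backbone_sets = [frozenset(b) for b in ecm_backbones]
    for b in backbone_sets:
        if not b:
            raise DesignError("empty ECM backbone set")
    if len(set(backbone_sets)) != len(backbone_sets):
        raise DesignError("duplicate ECM backbone sets")

    out: dict[str, MicroenvironmentCondition] = {}
    if scheme in {"ecm_alone", "both"}:
        for b in backbone_sets:
            cid = condition_id_for(b)
            out[cid] = MicroenvironmentCondition(cid, b)
    if scheme in {"ecm_plus_single_factor", "both"}:
        for b in backbone_sets:
            for f in factors:
                cid = condition_id_for(b, [f])
                out[cid] = MicroenvironmentCondition(cid, b, frozenset([f]))
    return [out[cid] for cid in sorted(out)]


def build_layout(
    conditions: Sequence[MicroenvironmentCondition],
    replicates: int,
    rows: int,
    cols: int,
    seed: int,
    spot_diameter_px: int = 64,
    spot_pitch_px: int = 80,
) -> ArrayLayout:
    """Assign each condition to exactly ``replicates`` spots.

    The (condition, replicate) pairs are placed on the grid by a seeded
    permutation, so the same seed always yields the identical layout.
    """
    needed = len(conditions) * replicates
    if rows * cols < needed:
        raise CapacityError(
            f"grid {rows}x{cols} = {rows * cols} spots cannot hold "
            f"{len(conditions)} conditions x {replicates} replicates = {needed}"
        )
    slots = [c.condition_id for c in conditions for _ in range(replicates)]
    rng = np.random.default_rng(seed)
    positions = rng.permutation(rows * cols)[:needed]
    assignments = {int(pos): cid for pos, cid in zip(positions, slots)}
    return ArrayLayout(
        rows=rows,
        cols=cols,
        spot_assignments=assignments,
        spot_diameter_px=spot_diameter_px,
        spot_pitch_px=spot_pitch_px,
    )


@dataclass(frozen=True)
class Violation:
    rule: str
    offending_id: str
    message: str


def validate_design(design: Design, layout: ArrayLayout | None = None) -> list[Violation]:
    """Check design/layout invariants; violations are data, not exceptions."""
    violations: list[Violation] = []
    seen_pairs: dict[tuple, str] = {}
    for cond in design.conditions:
        key = (cond.ecm_backbone, cond.soluble_factors, tuple(sorted(cond.concentrations.items())))
        if key in seen_pairs:
            violations.append(
                Violation(
                    "unique_combination",
                    cond.condition_id,
                    f"(backbone, factors, concentrations) duplicates {seen_pairs[key]!r}",
                )
            )
        else:
            seen_pairs[key] = cond.condition_id
        for name in cond.components:
            if name not in design.components:
                violations.append(
                    Violation("unknown_component", cond.condition_id, f"component {name!r} not in catalogue")
                )
    if layout is not None:
        known = set(design.condition_ids)
        counts = layout.replicate_counts()
        for cid in counts:
            if cid not in known:
                violations.append(
                    Violation("unknown_condition", cid, "layout references condition not in design")
                )
        for cid, n in counts.items():
            if not layout.replicate_min <= n <= layout.replicate_max:
                violations.append(
                    Violation(
                        "replicate_bounds",
                        cid,
                        f"{n} replicate spots outside [{layout.replicate_min}, {layout.replicate_max}]",
                    )
                )
        if max(layout.spot_assignments, default=0) >= layout.n_spots:
            violations.append(
                Violation("spot_index_range", str(max(layout.spot_assignments)), "spot index beyond grid")
            )
    return violations


# ---------------------------------------------------------------------------
# Packaged default design
# ---------------------------------------------------------------------------

# Printing concentrations per component (µg/ml).  ECM backbones are printed
# at structural concentrations; soluble factors at 1 µg/ml except the
# high-molecular-weight matrix components.  LAM1 is printed at two
# concentrations: 100 µg/ml as a standalone backbone and 80 µg/ml within
# the LAM1+LAM5 composite backbone.
_ECM_CATALOG: list[tuple[str, float]] = [
    ("COL1", 100.0),
    ("COL4", 100.0),
    ("LAM1", 100.0),
    ("LAM5", 20.0),
]

_FACTOR_CATALOG: list[tuple[str, float]] = [
    ("OPN", 1.0),
    ("HA", 100.0),
    ("TNC", 1.0),
    ("FN1", 100.0),
    ("BMP-2/7", 1.0),
    ("BMP-4", 1.0),
    ("CEACAM6", 1.0),
    ("CEACAM8", 1.0),
    ("CD44", 1.0),
    ("COL23A1", 1.0),
    ("COL6A3", 1.0),
    ("ECAD", 1.0),
    ("EGF", 1.0),
    ("FGF-2", 1.0),
    ("GAS-6", 1.0),
    ("HGF", 1.0),
    ("IGF1", 1.0),
    ("IFN-g", 1.0),
    ("IL-1b", 1.0),
    ("IL-6", 1.0),
    ("IL-8", 1.0),
    ("Leptin", 1.0),
    ("GRO1", 1.0),
    ("Nidogen1", 1.0),
    ("Lumican", 1.0),
    ("OPG", 1.0),
    ("SCF", 1.0),
    ("SDF-1b", 1.0),
]

#: Backbone composition of the four ECM levels.
DEFAULT_BACKBONES: list[frozenset[str]] = [
    frozenset({"COL1"}),
    frozenset({"COL4"}),
    frozenset({"LAM1"}),
    frozenset({"LAM1", "LAM5"}),
]

_DILUTION = 10.0  # low-concentration factor series is a 10-fold dilution


def default_design() -> Design:
    """The packaged 228-condition combinatorial design.

    Construction: 4 ECM backbones (COL1, COL4, LAM1, LAM1+LAM5) each
    printed alone (4 conditions) and paired with each of 28 soluble
    factors at the catalogue concentration (112) and at a 10-fold
    dilution (112), totalling 228 unique conditions.  The raw condition
    table of the original arrays was never published; this constructive
    rule is the package's declared reconstruction, consistent with the
    published component list and condition count.
    """
    components = {
        name: MicroenvironmentComponent(name, ComponentClass.ECM, conc)
        for name, conc in _ECM_CATALOG
    }
    components.update(
        {
            name: MicroenvironmentComponent(name, ComponentClass.SOLUBLE, conc)
            for name, conc in _FACTOR_CATALOG
        }
    )
    factor_conc = dict(_FACTOR_CATALOG)

    conditions: list[MicroenvironmentCondition] = []
    for backbone in DEFAULT_BACKBONES:
        bb_conc = {"LAM1": 80.0} if "LAM5" in backbone else {}
        cid = condition_id_for(backbone)
        conditions.append(MicroenvironmentCondition(cid, backbone, concentrations=bb_conc))
        for fname, _ in _FACTOR_CATALOG:
            for suffix, scale in (("", 1.0), ("@lo", 1.0 / _DILUTION)):
                conc = dict(bb_conc)
                if scale != 1.0:  # only true overrides of the catalogue value
                    conc[fname] = factor_conc[fname] * scale
                cid = condition_id_for(backbone, [fname], suffix=suffix)
                conditions.append(
                    MicroenvironmentCondition(cid, backbone, frozenset([fname]), conc)
                )
    conditions.sort(key=lambda c: c.condition_id)
    return Design(components=components, conditions=conditions)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def _conc_str(design: Design, cond: MicroenvironmentCondition) -> str:
    parts = []
    for name in sorted(cond.components):
        comp = design.components[name]
        value = cond.concentrations.get(name, comp.concentration)
        parts.append(f"{name}={value:g} {comp.unit}")
    return ";".join(parts)


def design_to_csv(design: Design, path: str | Path | io.TextIOBase) -> None:
    rows = []
    for cond in design.conditions:
        rows.append(
            {
                "condition_id": cond.condition_id,
                "ecm_backbone": ";".join(sorted(cond.ecm_backbone)),
                "soluble_factors": ";".join(sorted(cond.soluble_factors)),
                "concentrations": _conc_str(design, cond),
            }
        )
    comp_rows = [
        {
            "condition_id": f"#component:{c.name}",
            "ecm_backbone": c.component_class.value,
            "soluble_factors": "",
            "concentrations": f"{c.name}={c.concentration:g} {c.unit}",
        }
        for c in design.components.values()
    ]
    pd.DataFrame(comp_rows + rows).to_csv(path, index=False)


def _parse_conc(text: str) -> dict[str, tuple[float, str]]:
    out: dict[str, tuple[float, str]] = {}
    if not text:
        return out
    for part in text.split(";"):
        name, rest = part.split("=", 1)
        value, unit = rest.split(" ", 1)
        out[name] = (float(value), unit)
    return out


def design_from_csv(path: str | Path | io.TextIOBase) -> Design:
    df = pd.read_csv(path, keep_default_na=False)
    components: dict[str, MicroenvironmentComponent] = {}
    conditions: list[MicroenvironmentCondition] = []
    for _, row in df.iterrows():
        cid = row["condition_id"]
        if cid.startswith("#component:"):
            name = cid.removeprefix("#component:")
            (value, unit), = _parse_conc(row["concentrations"]).values()
            components[name] = MicroenvironmentComponent(
                name, ComponentClass(row["ecm_backbone"]), value, unit
            )
        else:
            backbone = frozenset(row["ecm_backbone"].split(";"))
            factors = (
                frozenset(row["soluble_factors"].split(";"))
                if row["soluble_factors"]
                else frozenset()
            )
            conc = {k: v for k, (v, _) in _parse_conc(row["concentrations"]).items()}
            conditions.append(MicroenvironmentCondition(cid, backbone, factors, conc))
    design = Design(components=components, conditions=conditions)
    # strip concentration entries that just repeat the catalogue value
    cleaned = []
    for cond in design.conditions:
        conc = {
            k: v
            for k, v in cond.concentrations.items()
            if abs(v - components[k].concentration) > 1e-12
        }
        cleaned.append(
            MicroenvironmentCondition(cond.condition_id, cond.ecm_backbone, cond.soluble_factors, conc)
        )
    return Design(components=components, conditions=cleaned)


def layout_to_csv(layout: ArrayLayout, path: str | Path | io.TextIOBase) -> None:
    rows = []
    for idx in sorted(layout.spot_assignments):
        r, c = layout.spot_rc(idx)
        rows.append({"spot_index": idx, "row": r, "col": c, "condition_id": layout.spot_assignments[idx]})
    df = pd.DataFrame(rows)
    df.attrs["layout"] = (layout.rows, layout.cols)
    header = (
        f"#rows={layout.rows};cols={layout.cols};"
        f"spot_diameter_px={layout.spot_diameter_px};spot_pitch_px={layout.spot_pitch_px};"
        f"replicate_min={layout.replicate_min};replicate_max={layout.replicate_max}\n"
    )
    if isinstance(path, (str, Path)):
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    else:
        path.write(header)
        df.to_csv(path, index=False)


def layout_from_csv(path: str | Path) -> ArrayLayout:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#")
        meta = dict(kv.split("=") for kv in header.split(";"))
        df = pd.read_csv(fh)
    return ArrayLayout(
        rows=int(meta["rows"]),
        cols=int(meta["cols"]),
        spot_assignments=dict(zip(df["spot_index"].astype(int), df["condition_id"])),
        spot_diameter_px=int(meta["spot_diameter_px"]),
        spot_pitch_px=int(meta["spot_pitch_px"]),
        replicate_min=int(meta["replicate_min"]),
        replicate_max=int(meta["replicate_max"]),
    )
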