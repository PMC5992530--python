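"""Attribute schema for pollen grain morphometry tables.

The default schema describes 13 morphological attributes measured on
single pollen grains under a light microscope, plus the taxon class
label.  Twelve attributes are numeric (micrometres or pore counts), one
is nominal (the position of the grain on the slide).  Two attributes are
derived: the axes difference is the maximum minus the minimum axis, and
the total pore count is the sum of the top, lateral and oblique pore
counts.  Attributes obtained in the same measurement act (e.g. widths of
all onci, which yield both the maximum and the minimum oncus width)
share a ``measurement_group``; the group drives "low-cost" subset
augmentation during feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AttributeSpec",
    "Schema",
    "default_schema",
    "POSITION_LEVELS",
    "TAXA",
    "BEST6",
    "EASIEST4",
]

CONTINUOUS = "continuous"
COUNT = "count"
NOMINAL = "nominal"

#: Grain position on the slide: polar, equatorial, intermediate,
#: nearly-equatorial and nearly-polar.
POSITION_LEVELS = ("P", "E", "I", "NE", "NP")

#: Default taxa (birch, hazel, alder); order is the tie-break order.
TAXA = ("Betula", "Corylus", "Alnus")

#: The six most discriminative attributes of the reference study.
BEST6 = (
    "n_pores",
    "max_axis",
    "min_axis",
    "axes_diff",
    "max_oncus_width",
    "n_lateral_pores",
)

#: The four attributes easiest to extract automatically from an image.
EASIEST4 = ("n_lateral_pores", "min_axis", "max_axis", "axes_diff")


@dataclass(frozen=True)
class AttributeSpec:
    """Metadata for one morphological attribute.

    Parameters
    ----------
    name
        Attribute identifier (column name in tables).
    kind
        ``"continuous"`` (µm measurement), ``"count"`` (non-negative
        integer) or ``"nominal"``.
    unit
        Physical unit, ``"µm"`` or ``""``.
    categories
        Category labels; non-empty iff the attribute is nominal.
    derived_from
        Names of constituent attributes when this attribute is computed
        rather than measured (empty for directly measured attributes).
    derivation
        ``"difference"`` (first minus second constituent) or ``"sum"``;
        ``None`` for measured attributes.
    measurement_group
        Label shared by attributes obtained from the same measurement
        act.
    """

    name: str
    kind: str
    unit: str = ""
    categories: tuple[str, ...] = ()
    derived_from: tuple[str, ...] = ()
    derivation: str | None = None
    measurement_group: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, COUNT, NOMINAL):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if (self.kind == NOMINAL) != bool(self.categories):
            raise ValueError(
                f"attribute {self.name!r}: nominal iff categories non-empty"
            )
        if self.derivation is not None and self.derivation not in ("difference", "sum"):
            raise ValueError(f"unknown derivation {self.derivation!r}")

    @property
    def is_numeric(self) -> bool:
        return self.kind in (CONTINUOUS, COUNT)


@dataclass(frozen=True)
class Schema:
    """An ordered attribute list plus the class attribute."""

    attributes: tuple[AttributeSpec, ...]
    class_name: str = "taxon"
    class_labels: tuple[str, ...] = TAXA

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate attribute names")
        if self.class_name in names:
            raise ValueError("class attribute shadows a feature attribute")
        known = set(names)
        for a in self.attributes:
            for dep in a.derived_from:
                if dep not in known:
                    raise ValueError(
                        f"{a.name!r} derived from unknown attribute {dep!r}"
                    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    def __getitem__(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(a.name == name for a in self.attributes)

    def index(self, name: str) -> int:
        for i, a in enumerate(self.attributes):
            if a.name == name:
                return i
        raise KeyError(name)

    def columns(self) -> list[str]:
        """Column order for tabular serialisation (class last)."""
        return [*self.names, self.class_name]


def default_schema() -> Schema:
    """The 13-attribute morphometry schema plus the taxon class.

    Groups: both axes and their difference come from the same size
    measurement; the four pore counts from the same pore count; oncus
    widths and heights each from measuring all onci once.
    """
    um = "µm"
    attrs = (
        AttributeSpec("min_axis", CONTINUOUS, um, measurement_group="axes"),
        AttributeSpec("max_axis", CONTINUOUS, um, measurement_group="axes"),
        AttributeSpec(
            "axes_diff", CONTINUOUS, um,
            derived_from=("max_axis", "min_axis"), derivation="difference",
            measurement_group="axes",
        ),
        AttributeSpec("wall", CONTINUOUS, um, measurement_group="wall"),
        AttributeSpec("n_top_pores", COUNT, measurement_group="pores"),
        AttributeSpec("n_lateral_pores", COUNT, measurement_group="pores"),
        AttributeSpec("n_oblique_pores", COUNT, measurement_group="pores"),
        AttributeSpec(
            "n_pores", COUNT,
            derived_from=("n_top_pores", "n_lateral_pores", "n_oblique_pores"),
            derivation="sum", measurement_group="pores",
        ),
        AttributeSpec("min_oncus_height", CONTINUOUS, um, measurement_group="oncus_height"),
        AttributeSpec("max_oncus_height", CONTINUOUS, um, measurement_group="oncus_height"),
        AttributeSpec("min_oncus_width", CONTINUOUS, um, measurement_group="oncus_width"),
        AttributeSpec("max_oncus_width", CONTINUOUS, um, measurement_group="oncus_width"),
        AttributeSpec("position", NOMINAL, categories=POSITION_LEVELS,
                      measurement_group="position"),
    )
    return Schema(attributes=attrs, class_name="taxon", class_labels=TAXA)
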