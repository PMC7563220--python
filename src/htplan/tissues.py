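"""Tissue dielectric registry and segmentation-reduction schemes.

The dielectric contrast between tissues is what drives specific absorption
rate (SAR) differences in radiofrequency hyperthermia.  This module holds the
per-tissue material constants at the 100 MHz operating frequency of annular
phased-array applicators (relative permittivity ``eps_r``, effective
conductivity ``sigma_eff`` in S/m, mass density ``rho`` in kg/m^3) and the
*segmentation schemes* that merge a detailed anatomical label set into the
coarser categories a clinic would actually delineate on CT.

Two conventions baked in here:

* the urine of a full bladder is assigned muscle-equivalent properties in
  every scheme that does not delineate the bladder separately (clinical
  auto-segmentation cannot distinguish it);
* subcutaneous adipose tissue (SAT) and visceral fat are distinct anatomical
  labels but always share the fat dielectric properties.  This is expressed
  as a *property alias* so that the "detailed" benchmark scheme remains a
  strict identity mapping over the label set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "TissueProperties",
    "PropertyTable",
    "SegmentationScheme",
    "SCHEME_NAMES",
    "DETAILED_LABELS",
    "load_property_table",
    "default_property_table",
    "build_scheme",
    "default_schemes",
]


class TissueValidationError(ValueError):
    """A tissue record or scheme violates a registry invariant."""


@dataclass(frozen=True)
class TissueProperties:
    """Material constants of one tissue at the operating frequency.

    ``eps_r`` must be >= 1 for biological tissues and water; the applicator
    casing is a synthetic low-permittivity shell and is exempt from that
    bound (it still must be positive).
    """

    tissue_id: str
    eps_r: float
    sigma_eff: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("eps_r", "sigma_eff", "rho"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise TissueValidationError(
                    f"tissue {self.tissue_id!r}: {name} must be finite, got {v!r}"
                )
        if self.rho <= 0:
            raise TissueValidationError(
                f"tissue {self.tissue_id!r}: rho must be > 0, got {self.rho}"
            )
        if self.sigma_eff < 0:
            raise TissueValidationError(
                f"tissue {self.tissue_id!r}: sigma_eff must be >= 0, got {self.sigma_eff}"
            )
        if self.eps_r <= 0:
            raise TissueValidationError(
                f"tissue {self.tissue_id!r}: eps_r must be > 0, got {self.eps_r}"
            )
        if self.eps_r < 1.0 and self.tissue_id != "applicator_shell":
            raise TissueValidationError(
                f"tissue {self.tissue_id!r}: eps_r must be >= 1 for tissues/water"
            )


# Anatomical labels that alias another tissue's dielectric properties.
PROPERTY_ALIASES: dict[str, str] = {
    "sat": "fat",
    "visceral_fat": "fat",
}

# Detailed phantom label set (property-table rows plus the two fat aliases).
DETAILED_LABELS: tuple[str, ...] = (
    "sat",
    "visceral_fat",
    "muscle",
    "cortical_bone",
    "cancellous_bone",
    "bone_marrow",
    "bladder_wall",
    "urine",
    "small_intestine_wall",
    "small_intestine_lumen",
    "large_intestine_wall",
    "large_intestine_lumen",
    "gtv",
)

SCHEME_NAMES: tuple[str, ...] = (
    "detailed",
    "clinical",
    "bone_type",
    "bladder",
    "intestine",
    "bladder_and_intestine",
    "combined",
)

# Water-content classes used to collapse labels in the reduced schemes.
_HIGH_WATER = {
    "muscle",
    "bladder_wall",
    "urine",
    "small_intestine_wall",
    "small_intestine_lumen",
    "large_intestine_wall",
    "large_intestine_lumen",
}
_LOW_WATER = {"fat", "sat", "visceral_fat"}
_BONE = {"cortical_bone", "cancellous_bone", "bone_marrow"}

# Labels each scheme keeps as themselves (beyond fat/muscle/cortical bone/GTV).
_SCHEME_EXTRA_RETAINED: dict[str, frozenset[str]] = {
    "clinical": frozenset(),
    "bone_type": frozenset({"cancellous_bone", "bone_marrow"}),
    "bladder": frozenset({"urine", "bladder_wall"}),
    "intestine": frozenset(
        {
            "small_intestine_wall",
            "small_intestine_lumen",
            "large_intestine_wall",
            "large_intestine_lumen",
        }
    ),
}
_SCHEME_EXTRA_RETAINED["bladder_and_intestine"] = (
    _SCHEME_EXTRA_RETAINED["bladder"] | _SCHEME_EXTRA_RETAINED["intestine"]
)
_SCHEME_EXTRA_RETAINED["combined"] = (
    _SCHEME_EXTRA_RETAINED["bone_type"]
    | _SCHEME_EXTRA_RETAINED["bladder"]
    | _SCHEME_EXTRA_RETAINED["intestine"]
)


class PropertyTable:
    """Immutable lookup of :class:`TissueProperties` by tissue id.

    ``resolve`` follows anatomical property aliases (SAT and visceral fat
    share the fat row), so phantom labels can be richer than the table.
    """

    def __init__(
        self,
        tissues: Iterable[TissueProperties],
        aliases: Mapping[str, str] | None = None,
    ):
        self._tissues: dict[str, TissueProperties] = {}
        for t in tissues:
            if t.tissue_id in self._tissues:
                raise TissueValidationError(f"duplicate tissue_id {t.tissue_id!r}")
            self._tissues[t.tissue_id] = t
        self.aliases = dict(PROPERTY_ALIASES if aliases is None else aliases)
        for src, dst in self.aliases.items():
            if dst not in self._tissues:
                raise TissueValidationError(
                    f"alias {src!r} -> {dst!r}: target not in property table"
                )

    def __contains__(self, tissue_id: str) -> bool:
        return tissue_id in self._tissues or tissue_id in self.aliases

    def __len__(self) -> int:
        return len(self._tissues)

    def __iter__(self):
        return iter(self._tissues.values())

    def __getitem__(self, tissue_id: str) -> TissueProperties:
        return self._tissues[tissue_id]

    def resolve(self, tissue_id: str) -> TissueProperties:
        """Properties for a label, following SAT/visceral-fat style aliases."""
        if tissue_id in self._tissues:
            return self._tissues[tissue_id]
        if tissue_id in self.aliases:
            return self._tissues[self.aliases[tissue_id]]
        raise KeyError(f"tissue {tissue_id!r} not in property table")

    @property
    def tissue_ids(self) -> tuple[str, ...]:
        return tuple(self._tissues)


def load_property_table(path: str | Path) -> PropertyTable:
    """Load a property table from a JSON list of tissue records.

    Each record must carry ``tissue_id``, ``eps_r``, ``sigma_eff`` and
    ``rho``.  A missing field or a physically impossible value raises
    :class:`TissueValidationError` naming the offending tissue.
    """
    with open(path) as fh:
        records = json.load(fh)
    return _table_from_records(records)


def _table_from_records(records: list[dict]) -> PropertyTable:
    tissues = []
    required = ("tissue_id", "eps_r", "sigma_eff", "rho")
    for rec in records:
        missing = [k for k in required if k not in rec]
        if missing:
            who = rec.get("tissue_id", "<unnamed>")
            raise TissueValidationError(
                f"tissue {who!r}: missing field(s) {', '.join(missing)}"
            )
        tissues.append(
            TissueProperties(
                tissue_id=rec["tissue_id"],
                eps_r=float(rec["eps_r"]),
                sigma_eff=float(rec["sigma_eff"]),
                rho=float(rec["rho"]),
            )
        )
    return PropertyTable(tissues)


def default_property_table() -> PropertyTable:
    """The shipped 14-tissue table of 100 MHz dielectric properties."""
    data = resources.files("htplan.data").joinpath("tissue_properties.json")
    return _table_from_records(json.loads(data.read_text()))


@dataclass(frozen=True)
class SegmentationScheme:
    """Total mapping from detailed tissue labels to a retained label set.

    The "detailed" scheme is the identity (the benchmark model); every
    reduced scheme collapses labels into the categories its name says it
    delineates.  GTV always maps to itself: the tumor is delineated in every
    clinical workflow.
    """

    name: str
    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))
        if "gtv" in self.mapping and self.mapping["gtv"] != "gtv":
            raise TissueValidationError(
                f"scheme {self.name!r}: GTV must map to itself"
            )

    def apply(self, tissue_id: str) -> str:
        try:
            return self.mapping[tissue_id]
        except KeyError:
            raise TissueValidationError(
                f"scheme {self.name!r}: no mapping rule for label {tissue_id!r}"
            ) from None

    @property
    def retained(self) -> frozenset[str]:
        return frozenset(self.mapping.values())


def build_scheme(
    name: str,
    detailed_labels: Iterable[str] = DETAILED_LABELS,
    extra_classes: Mapping[str, str] | None = None,
) -> SegmentationScheme:
    """Construct one of the seven segmentation schemes over a label set.

    Reduction rules: high-water labels (organs, bladder wall, urine,
    intestine walls and lumina) collapse to muscle; low-water labels (SAT,
    visceral fat) to fat; all bone compartments to cortical bone; GTV is
    preserved.  Each named scheme then re-retains its own labels (e.g. the
    "bladder" scheme keeps urine and bladder wall as themselves).

    Labels outside the built-in anatomy (user-supplied extra organs) need a
    water-content class via ``extra_classes`` (values ``high_water``,
    ``low_water`` or ``bone``); an unclassified label raises.
    """
    if name not in SCHEME_NAMES:
        raise TissueValidationError(
            f"unknown scheme {name!r}; expected one of {SCHEME_NAMES}"
        )
    labels = list(detailed_labels)
    extra = dict(extra_classes or {})
    if name == "detailed":
        return SegmentationScheme(name, {lab: lab for lab in labels})

    retained_extra = _SCHEME_EXTRA_RETAINED[name]
    mapping: dict[str, str] = {}
    for lab in labels:
        if lab == "gtv":
            mapping[lab] = "gtv"
        elif lab in retained_extra:
            mapping[lab] = lab
        elif lab in _HIGH_WATER:
            mapping[lab] = "muscle"
        elif lab in _LOW_WATER:
            mapping[lab] = "fat"
        elif lab in _BONE:
            mapping[lab] = "cortical_bone"
        elif lab in extra:
            cls = extra[lab]
            if cls == "high_water":
                mapping[lab] = "muscle"
            elif cls == "low_water":
                mapping[lab] = "fat"
            elif cls == "bone":
                mapping[lab] = "cortical_bone"
            else:
                raise TissueValidationError(
                    f"scheme {name!r}: unknown class {cls!r} for label {lab!r}"
                )
        else:
            raise TissueValidationError(
                f"scheme {name!r}: no mapping rule for label {lab!r}"
            )
    # retained ids map to themselves so scheme application is idempotent
    for retained in set(mapping.values()):
        mapping.setdefault(retained, retained)
    return SegmentationScheme(name, mapping)


def default_schemes() -> dict[str, SegmentationScheme]:
    """The seven shipped schemes over the default detailed label set."""
    data = resources.files("htplan.data").joinpath("schemes.json")
    raw = json.loads(data.read_text())
    return {
        entry["name"]: SegmentationScheme(entry["name"], entry["mapping"])
        for entry in raw
    }
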