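"""The 17 helical base-pair parameters measured along a DNA duplex.

Six intra-base-pair parameters describe geometry within one base pair,
six inter-base-pair (step) parameters describe the stacking of successive
pairs, four axis parameters locate a pair relative to the curvilinear
helical axis, and one parameter measures the overall axis bend.  Each
parameter is either rotational (degrees) or translational (angstrom).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ParameterDef",
    "REGISTRY",
    "PARAMETER_ORDER",
    "PARAMETERS",
    "ROTATIONAL",
    "get_parameter",
]

INTRA = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")
INTER = ("shift", "slide", "rise", "tilt", "roll", "twist")
AXIS = ("xdisp", "ydisp", "inclination", "tip")
BEND = ("axisbend",)

#: Parameters expressing an angle; everything else is a displacement.
ROTATIONAL = frozenset(
    {"buckle", "propeller", "opening", "tilt", "roll", "twist",
     "inclination", "tip", "axisbend"}
)


@dataclass(frozen=True)
class ParameterDef:
    """Definition of one helical parameter."""

    name: str
    category: str  # intra | inter | axis | bend
    nature: str    # rotational | translational
    units: str     # degrees | angstrom


def _build_registry() -> tuple[ParameterDef, ...]:
    defs = []
    for category, names in (("intra", INTRA), ("inter", INTER),
                            ("axis", AXIS), ("bend", BEND)):
        for name in names:
            nature = "rotational" if name in ROTATIONAL else "translational"
            units = "degrees" if nature == "rotational" else "angstrom"
            defs.append(ParameterDef(name, category, nature, units))
    return tuple(defs)


#: Canonical ordering: intra, inter, axis, bend.  Feature vectors follow it.
REGISTRY: tuple[ParameterDef, ...] = _build_registry()
PARAMETER_ORDER: tuple[str, ...] = tuple(p.name for p in REGISTRY)
PARAMETERS: dict[str, ParameterDef] = {p.name: p for p in REGISTRY}

# Display spellings seen in the literature mapped onto registry tokens.
_ALIASES = {
    "axis bend": "axisbend",
    "axis-bend": "axisbend",
    "x displacement": "xdisp",
    "x-displacement": "xdisp",
    "y displacement": "ydisp",
    "y-displacement": "ydisp",
    "incline": "inclination",
}


def get_parameter(name: str) -> ParameterDef:
    """Look up a parameter by registry token or common display spelling."""
    token = name.strip().lower()
    token = _ALIASES.get(token, token)
    try:
        return PARAMETERS[token]
    except KeyError:
        raise KeyError(f"unknown helical parameter: {name!r}") from None
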