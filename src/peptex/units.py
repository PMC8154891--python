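"""Concentration unit handling.

All concentrations inside the package are stored in molar (M).  User-facing
parsers accept strings with pM/nM/uM(µM)/mM/M suffixes so configuration files
can carry explicit units.
"""

from __future__ import annotations

import re

__all__ = ["parse_concentration", "format_concentration", "NM", "UM", "MM", "PM"]

PM = 1e-12
NM = 1e-9
UM = 1e-6
MM = 1e-3

_SUFFIXES = {
    "pm": PM,
    "nm": NM,
    "um": UM,
    "µm": UM,
    "μm": UM,  # greek mu
    "mm": MM,
    "m": 1.0,
}

_NUMBER_RE = re.compile(r"^\s*([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)\s*([a-zA-Zµμ]*)\s*$")


def parse_concentration(value: "str | float | int") -> float:
    """Parse a concentration into molar.

    Numbers pass through unchanged (assumed molar); strings may carry a unit
    suffix, e.g. ``"40.2 nM"`` -> ``4.02e-8``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _NUMBER_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse concentration {value!r}")
    number, suffix = m.groups()
    if suffix == "":
        return float(number)
    try:
        scale = _SUFFIXES[suffix.lower()]
    except KeyError:
        raise ValueError(f"unknown concentration unit {suffix!r} in {value!r}") from None
    return float(number) * scale


def format_concentration(molar: float) -> str:
    """Render a molar concentration with a human-friendly suffix."""
    a = abs(molar)
    if a == 0:
        return "0 M"
    for suffix, scale in (("mM", MM), ("uM", UM), ("nM", NM), ("pM", PM)):
        if a >= scale:
            return f"{molar / scale:g} {suffix}"
    return f"{molar:g} M"
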