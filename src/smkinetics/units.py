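"""Physical constants and small unit helpers used across the package."""

from __future__ import annotations

#: Gas constant, J/(mol K).
R = 8.314

#: Reference temperature (K) at which rate matrices with attached Arrhenius
#: parameters are interpreted (37 C, pseudo-physiological).
T_REF = 310.15

_MOLAR_PREFIX = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # µM
    "nM": 1e-9,
    "pM": 1e-12,
}


def parse_concentration(value) -> float:
    """Parse a concentration into mol/L.

    Accepts plain floats (already molar) or strings like ``"5 nM"``,
    ``"1 uM"``, ``"2e-7 M"``.
    """
    if isinstance(value, (int, float)):
        conc = float(value)
    elif isinstance(value, str):
        s = value.strip()
        for suffix, scale in sorted(_MOLAR_PREFIX.items(), key=lambda kv: -len(kv[0])):
            if s.endswith(suffix):
                try:
                    conc = float(s[: -len(suffix)].strip()) * scale
                    break
                except ValueError:
                    continue
        else:
            try:
                conc = float(s)
            except ValueError:
                raise ValueError(f"cannot parse concentration {value!r}") from None
    else:
        raise TypeError(f"cannot parse concentration from {type(value).__name__}")
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    return conc


def celsius_to_kelvin(t_c: float) -> float:
    return float(t_c) + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return float(t_k) - 273.15
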