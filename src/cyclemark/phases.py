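"""Cell-cycle phase labels.

Three phases are distinguished: G1 (gap 1), S (DNA synthesis) and G2M
(gap 2 and mitosis merged, as FUCCI-style reporters cannot separate them).
Labels are a closed enumeration; every cell carries exactly one.
"""

from __future__ import annotations

PHASES: tuple[str, str, str] = ("G1", "S", "G2M")
"""Canonical phase order used for reporting and tie-breaking."""

_ALIASES = {
    "G1": "G1",
    "S": "S",
    "G2M": "G2M",
    "G2/M": "G2M",
}


class UnknownPhaseError(ValueError):
    """Raised when a phase string is not one of G1 / S / G2M (or G2/M)."""


def normalize_phase(raw: str) -> str:
    """Map a phase string (case-insensitive, 'G2/M' accepted) onto the closed set."""
    key = str(raw).strip().upper()
    try:
        return _ALIASES[key]
    except KeyError:
        raise UnknownPhaseError(f"unknown phase: {raw!r} (expected one of G1, S, G2M)") from None
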