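"""Depth-class conventions for macrophyte transect surveys.

Water Framework Directive macrophyte mappings record species per transect in
four fixed depth ranges below the surface.  All downstream computation uses
the signed midpoint depth (metres, negative downward) of each range, never
the label, so the module pins the label -> midpoint mapping in one place.
"""

from __future__ import annotations

# Canonical depth-class labels, shallow to deep, and their signed midpoints.
# The open-ended ">4" class is assigned -5.0 m by convention.
DEPTH_MIDPOINTS: dict[str, float] = {
    "0-1": -0.5,
    "1-2": -1.5,
    "2-4": -3.0,
    ">4": -5.0,
}

DEPTH_LABELS: tuple[str, ...] = tuple(DEPTH_MIDPOINTS)
MIDPOINTS: tuple[float, ...] = tuple(DEPTH_MIDPOINTS.values())


def depth_midpoint(label: str) -> float:
    """Return the signed midpoint depth (m) of a canonical depth-class label.

    Raises
    ------
    ValueError
        If `label` is not one of the four canonical classes.
    """
    try:
        return DEPTH_MIDPOINTS[label]
    except KeyError:
        raise ValueError(
            f"unknown depth class label {label!r}; expected one of {DEPTH_LABELS}"
        ) from None


def midpoint_label(midpoint: float) -> str:
    """Inverse of :func:`depth_midpoint` (exact float match)."""
    for lab, mid in DEPTH_MIDPOINTS.items():
        if mid == midpoint:
            return lab
    raise ValueError(f"{midpoint!r} is not a canonical depth midpoint")
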