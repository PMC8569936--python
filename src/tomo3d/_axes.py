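"""Axis and sectioning-plane conventions shared across the package.

Volumes are indexed ``(sagittal, horizontal, transverse)``. Section ids are
1-based and follow the sectioning orientation used throughout: transverse
sections are numbered posterior to anterior, horizontal sections dorsal to
ventral, and sagittal sections left to right.
"""

from __future__ import annotations

#: Planes in iterative-fitting update order.
UPDATE_ORDER = ("transverse", "horizontal", "sagittal")

#: All recognized plane labels.
PLANES = ("transverse", "horizontal", "sagittal")

#: Array axis indexed by each plane's section number.
PLANE_AXIS = {"sagittal": 0, "horizontal": 1, "transverse": 2}

AXIS_PLANE = {axis: plane for plane, axis in PLANE_AXIS.items()}

ORIENTATION = {
    "transverse": "posterior to anterior",
    "horizontal": "dorsal to ventral",
    "sagittal": "left to right",
}


def check_plane(plane: str) -> str:
    if plane not in PLANE_AXIS:
        raise ValueError(
            f"unknown plane {plane!r}; expected one of {sorted(PLANE_AXIS)}"
        )
    return plane


def plane_axis(plane: str) -> int:
    """Array axis whose index runs over the sections of ``plane``."""
    return PLANE_AXIS[check_plane(plane)]


def other_axes(axis: int) -> tuple[int, int]:
    """The two axes a slab sum collapses for a plane indexed by ``axis``."""
    return tuple(a for a in range(3) if a != axis)  # type: ignore[return-value]


def section_labels(n: int) -> list[str]:
    """Column labels ``section_001 .. section_NNN`` in plane order."""
    return [f"section_{i:03d}" for i in range(1, n + 1)]
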