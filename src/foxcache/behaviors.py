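"""Behaviour categories used throughout the pipeline.

The ethogram is collapsed to four categories: running (fast travel),
walking (slow transitional movement), digging (head-down food handling at
a fixed location — the acceleration signature of food caching), and
motionless (standing, sitting or lying down).
"""

from __future__ import annotations

RUNNING = "running"
WALKING = "walking"
DIGGING = "digging"
MOTIONLESS = "motionless"

#: Canonical category order used for confusion matrices and reports.
CATEGORIES: tuple[str, ...] = (RUNNING, WALKING, DIGGING, MOTIONLESS)

#: Locomotor states simulated by the dwell-time process; digging is
#: overlaid on top of these by the caching model (see synthetic module).
LOCOMOTOR_STATES: tuple[str, ...] = (RUNNING, WALKING, MOTIONLESS)


def validate_behavior(name: str) -> str:
    if name not in CATEGORIES:
        raise ValueError(
            f"unknown behaviour {name!r}; expected one of {CATEGORIES}"
        )
    return name
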