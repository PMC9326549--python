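"""Health states of the SCID disease-course model.

The disease course is described by six states: newborns with SCID are
asymptomatic at birth (``PRE_SYMPTOMATIC``), undergo hematopoietic stem
cell transplantation (``HSCT``), and survivors settle into one of three
chronic post-transplant states (``WELL``, ``MODERATE``, ``POOR``) that
differ in ongoing care needs and quality of life. ``DEAD`` is absorbing.
"""

from __future__ import annotations

import enum


class HealthState(enum.IntEnum):
    """States of the SCID cohort model, in canonical matrix order."""

    PRE_SYMPTOMATIC = 0
    HSCT = 1
    WELL = 2
    MODERATE = 3
    POOR = 4
    DEAD = 5

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    HealthState.PRE_SYMPTOMATIC: "Pre-symptomatic",
    HealthState.HSCT: "HSCT",
    HealthState.WELL: "SCID Well",
    HealthState.MODERATE: "SCID Moderate",
    HealthState.POOR: "SCID Poor",
    HealthState.DEAD: "Dead",
}

#: Canonical state ordering used by every transition matrix in the package.
STATE_ORDER = tuple(HealthState)
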