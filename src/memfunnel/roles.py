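"""GO-keyword functional role binning of membrane proteins.

Five roles in strict precedence order; a protein with terms matching several
roles is counted once, under the highest-precedence role:

1. TRANSPORT          - term contains "transport", "symport" or "v-type atpase"
2. SENSING_SIGNALING  - term contains "receptor", "signal" or "sensor"
3. CATALYSIS          - a term whose final word ends in "-ase"
4. OTHER              - annotated, but matching none of the above
5. UNKNOWN            - no GO terms at all

Matching is case-insensitive substring matching on GO term names - keyword
parsing, not ontology traversal.  The blunt "-ase" suffix rule will also
catch final words such as "base" or "phase"; that imprecision is accepted
and documented.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable

import pandas as pd

from .annotation import GoAnnotation


class Role(str, Enum):
    TRANSPORT = "transport"
    SENSING_SIGNALING = "sensing_signaling"
    CATALYSIS = "catalysis"
    OTHER = "other"
    UNKNOWN = "unknown"


ROLE_PRECEDENCE = (
    Role.TRANSPORT,
    Role.SENSING_SIGNALING,
    Role.CATALYSIS,
    Role.OTHER,
    Role.UNKNOWN,
)

_TRANSPORT_KEYS = ("transport", "symport", "v-type atpase")
_SENSING_KEYS = ("receptor", "signal", "sensor")


def assign_role(annotations: Iterable[GoAnnotation]) -> Role:
    names = [a.go_name.lower() for a in annotations]
    if any(k in n for n in names for k in _TRANSPORT_KEYS):
        return Role.TRANSPORT
    if any(k in n for n in names for k in _SENSING_KEYS):
        return Role.SENSING_SIGNALING
    for n in names:
        words = n.split()
        if words and words[-1].endswith("ase"):
            return Role.CATALYSIS
    if names:
        return Role.OTHER
    return Role.UNKNOWN


def role_distribution(records: pd.DataFrame) -> pd.DataFrame:
    """Per-strain role counts and percentages over membrane proteins only.

    ``records`` needs columns ``strain``, ``localization`` and ``role``; rows
    whose localization is not a membrane class are ignored.  Percentages per
    strain sum to 100 up to rounding.
    """
    from .funnel import MEMBRANE_CLASSES

    membrane_values = {c.value for c in MEMBRANE_CLASSES}
    mem = records[records["localization"].isin(membrane_values)]
    rows = []
    for strain, grp in mem.groupby("strain", sort=True):
        n = len(grp)
        for role in ROLE_PRECEDENCE:
            c = int((grp["role"] == role.value).sum())
            rows.append(
                {
                    "strain": strain,
                    "role": role.value,
                    "count": c,
                    "percent": 100.0 * c / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["strain", "role", "count", "percent"])
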