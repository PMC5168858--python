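"""The filtering funnel: transcriptome -> trafficked -> membrane proteome.

Each transcript (via its representative protein) is placed in exactly one of
five localisation classes.  A protein is "trafficked" (enters the secretory
pathway) when it has a predicted signal peptide and/or at least one
transmembrane segment; trafficked proteins without a non-cleaved TM segment
are completely secreted, those with exactly one are bitopic membrane
proteins, and those with two or more are polytopic.
"""

from __future__ import annotations

from enum import Enum

import pandas as pd

from .topology import TopologyProfile, noncleaved_tm_count


class LocalizationClass(str, Enum):
    ANTISENSE_NONCODING = "antisense_noncoding"
    SOLUBLE = "soluble"
    SECRETED = "secreted"
    BITOPIC_MEMBRANE = "bitopic_membrane"
    POLYTOPIC_MEMBRANE = "polytopic_membrane"


MEMBRANE_CLASSES = frozenset(
    {LocalizationClass.BITOPIC_MEMBRANE, LocalizationClass.POLYTOPIC_MEMBRANE}
)
TRAFFICKED_CLASSES = MEMBRANE_CLASSES | {LocalizationClass.SECRETED}


def classify_localization(
    topology: TopologyProfile | None, antisense: bool
) -> tuple[LocalizationClass, bool]:
    """Classify one transcript's representative protein.

    Returns ``(class, no_profile_flag)``.  Antisense overrides everything;
    otherwise the non-cleaved TM count k decides: k=0 with a signal peptide
    is SECRETED, k=0 without is SOLUBLE, k=1 BITOPIC, k>=2 POLYTOPIC.
    A transcript with no topology profile at all is binned SOLUBLE (keeping
    the funnel a partition) and flagged.
    """
    if antisense:
        return LocalizationClass.ANTISENSE_NONCODING, topology is None
    if topology is None:
        return LocalizationClass.SOLUBLE, True
    k = noncleaved_tm_count(topology)
    if k == 0:
        if topology.signal.present:
            return LocalizationClass.SECRETED, False
        return LocalizationClass.SOLUBLE, False
    if k == 1:
        return LocalizationClass.BITOPIC_MEMBRANE, False
    return LocalizationClass.POLYTOPIC_MEMBRANE, False


def funnel_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Per-strain funnel summary from a per-transcript record table.

    ``records`` needs columns ``strain`` and ``localization`` (class values).
    Levels reported: total -> trafficked (secreted + membrane) ->
    membrane (bitopic + polytopic), with bitopic broken out, plus the
    filtered-away soluble and antisense arms.  Fractions are of the strain
    total.
    """
    rows = []
    strains = sorted(records["strain"].unique()) if len(records) else []
    for strain, grp in records.groupby("strain", sort=True):
        loc = grp["localization"]
        n = len(grp)
        counts = {
            "total": n,
            "antisense": int((loc == LocalizationClass.ANTISENSE_NONCODING.value).sum()),
            "soluble": int((loc == LocalizationClass.SOLUBLE.value).sum()),
            "secreted": int((loc == LocalizationClass.SECRETED.value).sum()),
            "bitopic": int((loc == LocalizationClass.BITOPIC_MEMBRANE.value).sum()),
            "polytopic": int((loc == LocalizationClass.POLYTOPIC_MEMBRANE.value).sum()),
        }
        counts["membrane"] = counts["bitopic"] + counts["polytopic"]
        counts["trafficked"] = counts["secreted"] + counts["membrane"]
        for level, c in counts.items():
            rows.append(
                {
                    "strain": strain,
                    "level": level,
                    "count": c,
                    "fraction_of_total": c / n if n else 0.0,
                }
            )
    out = pd.DataFrame(
        rows, columns=["strain", "level", "count", "fraction_of_total"]
    )
    return out
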