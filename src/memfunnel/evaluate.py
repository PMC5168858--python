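"""Recovery scoring of pipeline output against a planted truth table."""

from __future__ import annotations

import pandas as pd

_DIMENSIONS = {
    # column -> truth column defining which rows carry a planted label
    "localization": None,  # every transcript
    "role": "role",
    "category": "tc_id",
    "substrate": "tc_id",
    "sugar_family": "tc_id",
    "gpcr_class": "gpcr_class",
    "gpcr_flags": "gpcr_class",
}


def score_recovery(truth: pd.DataFrame, records: pd.DataFrame) -> dict[str, float]:
    """Per-dimension label-recovery accuracy plus their mean.

    For each dimension, accuracy is measured over the transcripts whose
    truth row defines that label (every transcript for localisation,
    membrane proteins for role, TC-tagged transcripts for the transporter
    bins, planted GPCRs for class and architecture flags).
    """
    m = truth.merge(
        records, on="transcript_id", suffixes=("_true", "_obs"), validate="1:1"
    )
    out: dict[str, float] = {}
    for col, gate in _DIMENSIONS.items():
        sel = m if gate is None else m[m[f"{gate}_true"].astype(str) != ""]
        if not len(sel):
            continue
        t = sel[f"{col}_true"].astype(str).fillna("")
        o = sel[f"{col}_obs"].astype(str).fillna("")
        out[col] = float((t.values == o.values).mean())
    out["mean"] = sum(out.values()) / len(out)
    return out
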