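"""GPCR discovery: keyword entry filter, 7-9 TM gate, N-terminal domain
architecture.

Candidates must carry a 'GPCR' / 'G-protein coupled receptor' keyword in a
functional annotation AND have 7-9 predicted transmembrane segments.  The
gate deliberately uses the *raw* TM count (before signal-peptide
discounting): it is widened from 7 to 9 precisely to tolerate hydrophobic
signal sequences and N-terminal helices that TM predictors also report.

The heptahelical bundle is taken to be the 7 most C-terminal TM segments
(class C receptors carry their seven helices at the C-terminus); the
extracellular N-terminal region is everything before the bundle, and only
domains wholly contained in that region count toward the architecture flags
(ANF, pectin lyase fold, parallel beta-helix, EGF-like, SBP Type II).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import DomainHit
from .topology import TopologyProfile

GPCR_KEYWORDS = ("g-protein coupled receptor", "gpcr")
TM_GATE = (7, 9)


class GpcrClass(str, Enum):
    RHODOPSIN_DICTY_CAR = "rhodopsin_dicty_car"
    CLASS_C = "class_c"
    UNCLASSIFIED = "unclassified"


class ArchitectureFlag(str, Enum):
    ANF = "anf"
    PECTIN_LYASE = "pectin_lyase"
    BETA_HELIX = "beta_helix"
    EGF_LIKE = "egf_like"
    SBP_TYPE_II = "sbp_type_ii"


class SignatureTable:
    """Editable table mapping signature/InterPro IDs to GPCR classes and
    N-terminal architecture flags."""

    def __init__(self, class_rules: dict, flag_rules: dict):
        # rules: {(match_on, id): label}
        self.class_rules = class_rules
        self.flag_rules = flag_rules

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureTable":
        class_rules, flag_rules = {}, {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns")
            sid, kind, label, match_on = f[0], f[1], f[2], f[3]
            if match_on not in {"interpro", "signature"}:
                raise ValueError(f"{path}:{lineno}: bad match_on {match_on!r}")
            if kind == "class":
                class_rules[(match_on, sid)] = GpcrClass(label)
            elif kind == "flag":
                flag_rules[(match_on, sid)] = ArchitectureFlag(label)
            else:
                raise ValueError(f"{path}:{lineno}: bad kind {kind!r}")
        return cls(class_rules, flag_rules)

    @classmethod
    def default(cls) -> "SignatureTable":
        with resources.as_file(
            resources.files("memfunnel.data") / "gpcr_signatures.tsv"
        ) as p:
            return cls.from_tsv(p)

    def _labels(self, rules: dict, hit: DomainHit):
        out = []
        if hit.interpro_id and ("interpro", hit.interpro_id) in rules:
            out.append(rules[("interpro", hit.interpro_id)])
        if ("signature", hit.signature_id) in rules:
            out.append(rules[("signature", hit.signature_id)])
        return out

    def classes_of(self, hit: DomainHit) -> list[GpcrClass]:
        return self._labels(self.class_rules, hit)

    def flags_of(self, hit: DomainHit) -> list[ArchitectureFlag]:
        return self._labels(self.flag_rules, hit)


@dataclass
class GpcrCandidate:
    protein_id: str
    tm_count: int
    gpcr_class: GpcrClass = GpcrClass.UNCLASSIFIED
    n_terminal_domains: list[DomainHit] = field(default_factory=list)
    architecture_flags: frozenset[ArchitectureFlag] = frozenset()
    has_signal_peptide: bool = False
    n_terminal_length: int = 0
    class_conflict: bool = False

    def __post_init__(self):
        if self.tm_count < 1:
            raise ValueError(f"{self.protein_id}: TM count must be >= 1")


def _has_keyword(texts: Iterable[str]) -> bool:
    return any(k in t.lower() for t in texts for k in GPCR_KEYWORDS)


def find_gpcr_candidates(
    annotations: Mapping[str, Sequence[str]],
    topologies: Mapping[str, TopologyProfile],
    gate: tuple[int, int] = TM_GATE,
) -> list[GpcrCandidate]:
    """Entry filter: keyword match in any annotation description AND raw TM
    count within the (default 7-9) gate.

    The raw count is used on purpose: the gate's upper bound exists to
    tolerate hydrophobic signal sequences that TM predictors also call as
    helices.  ``annotations`` maps protein_id to the functional annotation
    description strings searched for the keywords.
    """
    out = []
    for pid in sorted(annotations):
        if not _has_keyword(annotations[pid]):
            continue
        prof = topologies.get(pid)
        if prof is None:
            continue
        if gate[0] <= prof.tm_count <= gate[1]:
            out.append(
                GpcrCandidate(
                    pid,
                    prof.tm_count,
                    has_signal_peptide=prof.signal.present,
                )
            )
    return out


def delimit_n_terminal_region(
    candidate: GpcrCandidate, topology: TopologyProfile
) -> tuple[int, int]:
    """Residue interval (1-based inclusive) of the extracellular N-terminal
    region: everything before the first helix of the heptahelical bundle,
    the bundle being the 7 most C-terminal TM segments."""
    segs = topology.tm_segments
    if len(segs) < 7:
        raise RuntimeError(
            f"{candidate.protein_id}: {len(segs)} TMs at architecture stage "
            "(gate violated)"
        )
    bundle_start = segs[-7].start
    return (1, bundle_start - 1)


def classify_gpcr(
    candidate: GpcrCandidate,
    topology: TopologyProfile,
    domain_hits: Sequence[DomainHit],
    signatures: SignatureTable | None = None,
) -> GpcrCandidate:
    """Assign the receptor class from signature IDs anywhere in the protein
    and the architecture flags from domains wholly inside the N-terminal
    region (end strictly before the bundle start).

    A protein carrying both class signatures is CLASS_C (the focal class)
    with ``class_conflict`` set.
    """
    signatures = signatures or SignatureTable.default()
    region_start, region_end = delimit_n_terminal_region(candidate, topology)
    bundle_start = region_end + 1
    classes = set()
    for hit in domain_hits:
        classes.update(signatures.classes_of(hit))
    if GpcrClass.CLASS_C in classes:
        gcls, conflict = GpcrClass.CLASS_C, GpcrClass.RHODOPSIN_DICTY_CAR in classes
    elif GpcrClass.RHODOPSIN_DICTY_CAR in classes:
        gcls, conflict = GpcrClass.RHODOPSIN_DICTY_CAR, False
    else:
        gcls, conflict = GpcrClass.UNCLASSIFIED, False
    nterm = [h for h in domain_hits if h.end < bundle_start]
    flags = frozenset(f for h in nterm for f in signatures.flags_of(h))
    candidate.gpcr_class = gcls
    candidate.class_conflict = conflict
    candidate.n_terminal_domains = nterm
    candidate.architecture_flags = flags
    candidate.n_terminal_length = region_end
    return candidate


def gpcr_report(candidates: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-strain class counts (receptor-census table shape), architecture
    flag fractions, and N-terminal region length summary.

    ``candidates`` needs columns ``strain``, ``gpcr_class``, ``flags``
    (comma-joined flag values, possibly empty), ``n_terminal_length`` and
    ``has_signal_peptide``.
    """
    order = [c.value for c in GpcrClass]
    if len(candidates):
        classes = (
            candidates.pivot_table(
                index="gpcr_class", columns="strain", aggfunc="size", fill_value=0
            )
            .reindex(order, fill_value=0)
            .astype(int)
        )
        classes.columns.name = None
    else:
        classes = pd.DataFrame(index=pd.Index(order, name="gpcr_class"))
    classes["total"] = classes.sum(axis=1, numeric_only=True)
    classes.loc["total"] = classes.sum(axis=0)

    rows = []
    for strain, grp in candidates.groupby("strain", sort=True):
        n = len(grp)
        flag_lists = grp["flags"].map(
            lambda s: set(s.split(",")) - {""} if isinstance(s, str) else set()
        )
        row = {"strain": strain, "n_candidates": n}
        for f in ArchitectureFlag:
            row[f"frac_{f.value}"] = (
                sum(f.value in fl for fl in flag_lists) / n if n else 0.0
            )
        row["frac_signal_peptide"] = (
            float(grp["has_signal_peptide"].mean()) if n else 0.0
        )
        lens = grp["n_terminal_length"]
        row.update(
            nterm_min=int(lens.min()) if n else 0,
            nterm_mean=float(lens.mean()) if n else 0.0,
            nterm_max=int(lens.max()) if n else 0,
        )
        rows.append(row)
    arch = pd.DataFrame(rows)
    return {"classes": classes, "architecture": arch}
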