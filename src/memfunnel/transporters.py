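"""TCDB-homology transporter classification.

Every transcript is eligible regardless of its funnel class - many transport
systems contain subunits only peripherally associated with the membrane, and
beta-barrel proteins escape hydrophobicity-based TM prediction entirely.

The assignment rule is: keep alignment hits that cover at least 70% of
*both* the query and the subject sequence (reciprocal coverage), then take
the hit with the smallest E-value subject to the inclusive cutoff
E <= 1e-3; parse the five-tier TC identity tag (class.subclass.family.
subfamily.system) from the subject and bin it by longest-prefix lookup into
functional categories, substrate classes and sugar families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation import AlignmentHit

DEFAULT_MIN_COVERAGE = 0.70
DEFAULT_MAX_EVALUE = 1e-3


class TransporterCategory(str, Enum):
    SOLUTE_TRANSPORT = "solute_transport"
    PROTEIN_BIOGENESIS_SECRETION = "protein_biogenesis_secretion"
    NUCLEAR_TRANSPORT = "nuclear_transport"
    PEROXISOMAL_IMPORT = "peroxisomal_import"
    ORGANELLE_IMPORT = "organelle_import"
    OTHER = "other"


class SubstrateClass(str, Enum):
    SUGARS_METABOLITES = "sugars_metabolites"
    DRUGS_LIPIDS = "drugs_lipids"
    INORGANIC_IONS_METALS = "inorganic_ions_metals"
    UNASSIGNED = "unassigned"


class SugarFamily(str, Enum):
    MFS = "mfs"
    SSS = "sss"
    SWEET = "sweet"
    ABC_SBP = "abc_sbp"
    NONE = "none"


class TcParseError(ValueError):
    pass


_TC_RE = re.compile(
    r"(?<![\d.])([1-9])\.([A-Za-z])(?:\.(\d+)(?:\.(\d+)(?:\.(\d+))?)?)?(?![\d.]?\d)"
)


@dataclass(frozen=True)
class TcId:
    """A transporter-classification identity tag of up to five tiers,
    e.g. 3.A.1.201.5 = class.subclass.family.subfamily.system; tags may be
    truncated at family or subfamily level."""

    class_tier: int
    subclass_tier: str
    family_tier: int | None = None
    subfamily_tier: int | None = None
    system_tier: int | None = None

    def __post_init__(self):
        if not 1 <= self.class_tier <= 9:
            raise ValueError(f"TC class tier {self.class_tier} outside 1..9")
        if not self.subclass_tier.isalpha():
            raise ValueError(f"TC subclass {self.subclass_tier!r} not a letter")
        tiers = (self.family_tier, self.subfamily_tier, self.system_tier)
        seen_absent = False
        for t in tiers:
            if t is None:
                seen_absent = True
            elif seen_absent:
                raise ValueError("TC tiers must be contiguous from the left")

    @property
    def tiers(self) -> tuple:
        out = [str(self.class_tier), self.subclass_tier.upper()]
        for t in (self.family_tier, self.subfamily_tier, self.system_tier):
            if t is None:
                break
            out.append(str(t))
        return tuple(out)

    def __str__(self) -> str:
        return ".".join(self.tiers)

    def prefixes(self) -> list[str]:
        """All dotted prefixes, longest first."""
        t = self.tiers
        return [".".join(t[:k]) for k in range(len(t), 0, -1)]


def parse_tc_id(text: str) -> TcId:
    """Extract a TC identity tag from a subject id or description.

    Accepts full five-tier tags and family/subfamily-level truncations
    (e.g. ``2.A.123``), embedded in arbitrary text such as
    ``gnl|TC-DB|P0AE06|3.A.1.201.5``.
    """
    best = None
    for m in _TC_RE.finditer(text):
        groups = m.groups()
        n = sum(g is not None for g in groups)
        if best is None or n > best[0]:
            best = (n, groups)
    if best is None:
        raise TcParseError(f"no TC identity tag in {text!r}")
    g = best[1]
    return TcId(
        class_tier=int(g[0]),
        subclass_tier=g[1],
        family_tier=int(g[2]) if g[2] else None,
        subfamily_tier=int(g[3]) if g[3] else None,
        system_tier=int(g[4]) if g[4] else None,
    )


# ---------------------------------------------------------------------------
# Filtering and best-hit selection


def passes_reciprocal_coverage(
    hit: AlignmentHit, min_cov: float = DEFAULT_MIN_COVERAGE
) -> bool:
    """True iff the alignment span covers >= min_cov of BOTH query and subject."""
    if hit.q_len < 1 or hit.s_len < 1:
        raise ValueError("sequence lengths must be positive")
    return hit.query_coverage >= min_cov and hit.subject_coverage >= min_cov


def best_tcdb_hit(
    hits: Sequence[AlignmentHit],
    min_cov: float = DEFAULT_MIN_COVERAGE,
    max_e: float = DEFAULT_MAX_EVALUE,
) -> AlignmentHit | None:
    """Best surviving hit for one query: reciprocal-coverage filter first,
    then smallest E-value with the inclusive E <= max_e gate; ties broken by
    larger bit score, then lexicographic subject id (for determinism)."""
    if not hits:
        return None
    qids = {h.query_id for h in hits}
    if len(qids) != 1:
        raise ValueError(f"hits span multiple queries: {sorted(qids)}")
    surviving = [
        h
        for h in hits
        if passes_reciprocal_coverage(h, min_cov) and h.e_value <= max_e
    ]
    if not surviving:
        return None
    return min(surviving, key=lambda h: (h.e_value, -h.bit_score, h.subject_id))


# ---------------------------------------------------------------------------
# Category map


class CategoryMap:
    """Ordered longest-prefix-wins map from TC prefixes to
    (category, substrate, sugar_family)."""

    def __init__(self, rules: dict[str, tuple[TransporterCategory, SubstrateClass, SugarFamily]]):
        self.rules = dict(rules)
        for prefix, (cat, sub, fam) in self.rules.items():
            if fam is not SugarFamily.NONE and sub is not SubstrateClass.SUGARS_METABOLITES:
                raise ValueError(
                    f"rule {prefix}: sugar family {fam.value} outside sugars_metabolites"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CategoryMap":
        rules = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns")
            prefix = f[0].strip()
            if prefix in rules:
                raise ValueError(f"{path}:{lineno}: duplicate prefix {prefix!r}")
            rules[prefix] = (
                TransporterCategory(f[1]),
                SubstrateClass(f[2]),
                SugarFamily(f[3]),
            )
        return cls(rules)

    @classmethod
    def default(cls) -> "CategoryMap":
        with resources.as_file(
            resources.files("memfunnel.data") / "category_map.tsv"
        ) as p:
            return cls.from_tsv(p)

    def lookup(
        self, tc_id: TcId
    ) -> tuple[TransporterCategory, SubstrateClass, SugarFamily]:
        for prefix in tc_id.prefixes():
            if prefix in self.rules:
                return self.rules[prefix]
        return (
            TransporterCategory.OTHER,
            SubstrateClass.UNASSIGNED,
            SugarFamily.NONE,
        )


def categorize(
    tc_id: TcId, cmap: CategoryMap | None = None
) -> tuple[TransporterCategory, SubstrateClass, SugarFamily]:
    return (cmap or CategoryMap.default()).lookup(tc_id)


@dataclass(frozen=True)
class TcdbAssignment:
    protein_id: str
    best_hit: AlignmentHit
    tc_id: TcId
    category: TransporterCategory
    substrate: SubstrateClass
    sugar_family: SugarFamily


def assign_transporters(
    hits: Iterable[AlignmentHit],
    cmap: CategoryMap | None = None,
    min_cov: float = DEFAULT_MIN_COVERAGE,
    max_e: float = DEFAULT_MAX_EVALUE,
) -> tuple[list[TcdbAssignment], list[str]]:
    """Group hits by query, select the best surviving hit per query and bin
    it.  Returns (assignments, queries whose best hit had no parsable TC tag).
    """
    cmap = cmap or CategoryMap.default()
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    assignments, unparsable = [], []
    for qid in sorted(by_query):
        best = best_tcdb_hit(by_query[qid], min_cov=min_cov, max_e=max_e)
        if best is None:
            continue
        try:
            tc = parse_tc_id(best.subject_id)
        except TcParseError:
            try:
                tc = parse_tc_id(best.subject_desc)
            except TcParseError:
                unparsable.append(qid)
                continue
        cat, sub, fam = cmap.lookup(tc)
        assignments.append(TcdbAssignment(qid, best, tc, cat, sub, fam))
    return assignments, unparsable


# ---------------------------------------------------------------------------
# Report tables


def add_cross_strain_total(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``total`` column summing the per-strain count columns."""
    out = table.copy()
    out["total"] = out.sum(axis=1, numeric_only=True)
    return out


def _pivot(df: pd.DataFrame, index: str, order: list[str]) -> pd.DataFrame:
    tab = (
        df.pivot_table(
            index=index, columns="strain", aggfunc="size", fill_value=0
        )
        .reindex(order, fill_value=0)
        .astype(int)
    )
    tab.columns.name = None
    return add_cross_strain_total(tab)


def tabulate_transporters(assignments: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-strain report tables from an assignment table with columns
    ``strain``, ``category``, ``substrate``, ``sugar_family``.

    Returns ``categories`` (all assignments), ``substrates`` (solute
    transporters only) and ``sugar_families`` (sugar/metabolite transporters
    by family, with a Total row - the sugar-uptake-systems table shape).
    Every table carries a cross-strain ``total`` column.
    """
    cats = _pivot(
        assignments, "category", [c.value for c in TransporterCategory]
    )
    solute = assignments[
        assignments["category"] == TransporterCategory.SOLUTE_TRANSPORT.value
    ]
    subs = _pivot(
        solute,
        "substrate",
        [
            SubstrateClass.SUGARS_METABOLITES.value,
            SubstrateClass.DRUGS_LIPIDS.value,
            SubstrateClass.INORGANIC_IONS_METALS.value,
        ],
    )
    sugar = assignments[
        assignments["sugar_family"] != SugarFamily.NONE.value
    ]
    fam = _pivot(
        sugar,
        "sugar_family",
        [
            SugarFamily.MFS.value,
            SugarFamily.SSS.value,
            SugarFamily.SWEET.value,
            SugarFamily.ABC_SBP.value,
        ],
    )
    fam.loc["total"] = fam.sum(axis=0)
    return {"categories": cats, "substrates": subs, "sugar_families": fam}
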