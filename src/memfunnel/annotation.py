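"""Readers for alignment tabular and domain/GO annotation files.

Two dialects are consumed: BLAST tabular (outfmt-6 order, optionally with
qlen/slen appended as columns 13-14 and a free-text subject description as
column 15) and an InterProScan-style TSV whose GO column carries entries of
the form ``GO:0055085(transmembrane transport)`` separated by ``|``.
Annotation significance uses the inclusive gate E <= 1e-3 throughout.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path

DEFAULT_MAX_EVALUE = 1e-3

_GO_RE = re.compile(r"^GO:\d{7}$")
_GO_FIELD_RE = re.compile(r"(GO:\d{7})(?:\(([^)]*)\))?(?:\[([^\]]*)\])?")


class AnnotationParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    """One query-vs-subject alignment record (coordinates 1-based inclusive,
    normalised ascending; ``reverse_subject`` records a descending input
    subject span)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    q_len: int
    s_len: int
    subject_desc: str = ""
    mismatches: int = 0
    gap_opens: int = 0
    frame: int | None = None
    reverse_subject: bool = False

    def __post_init__(self):
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError("alignment coordinates must be ascending")
        if self.e_value < 0:
            raise ValueError("negative E-value")
        if self.q_len < 1 or self.s_len < 1:
            raise ValueError("sequence lengths must be >= 1")

    @property
    def query_coverage(self) -> float:
        return (self.q_end - self.q_start + 1) / self.q_len

    @property
    def subject_coverage(self) -> float:
        return (self.s_end - self.s_start + 1) / self.s_len


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    signature_id: str
    description: str = ""
    interpro_id: str | None = None
    start: int = 1
    end: int = 1
    e_value: float = 0.0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("domain coordinates must be ascending")


@dataclass(frozen=True)
class GoAnnotation:
    protein_id: str
    go_id: str
    go_name: str = ""
    namespace: str = ""

    def __post_init__(self):
        if not _GO_RE.match(self.go_id):
            raise ValueError(f"malformed GO accession {self.go_id!r}")
        object.__setattr__(self, "go_name", self.go_name.lower())


def read_length_table(path: str | Path) -> dict[str, int]:
    """Two-column TSV: sequence id, length."""
    out: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 2:
            raise AnnotationParseError(f"{path}:{lineno}: expected 2 columns")
        out[f[0]] = int(f[1])
    return out


def read_alignment_table(
    path: str | Path, lengths: dict[str, int] | None = None
) -> list[AlignmentHit]:
    """Parse BLAST tabular hits (12, 14 or 15 columns).

    With 12 columns, query/subject lengths must come from ``lengths``.
    Descending subject spans are normalised ascending with
    ``reverse_subject=True``.
    """
    hits: list[AlignmentHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) not in (12, 14, 15):
            raise AnnotationParseError(
                f"{path}:{lineno}: expected 12, 14 or 15 columns, got {len(f)}"
            )
        try:
            qid, sid = f[0], f[1]
            pident = float(f[2])
            alen = int(f[3])
            mism, gaps = int(f[4]), int(f[5])
            qs, qe, ss, se = (int(x) for x in f[6:10])
            ev, bits = float(f[10]), float(f[11])
        except ValueError as e:
            raise AnnotationParseError(f"{path}:{lineno}: {e}") from None
        if len(f) >= 14:
            qlen, slen = int(f[12]), int(f[13])
        else:
            if lengths is None:
                raise AnnotationParseError(
                    f"{path}:{lineno}: 12-column table requires a length table"
                )
            try:
                qlen, slen = lengths[qid], lengths[sid]
            except KeyError as e:
                raise AnnotationParseError(
                    f"{path}:{lineno}: no length for {e.args[0]!r}"
                ) from None
        desc = f[14] if len(f) == 15 else sid
        rev = ss > se
        if rev:
            ss, se = se, ss
        if qs > qe:
            qs, qe = qe, qs
        hits.append(
            AlignmentHit(
                query_id=qid,
                subject_id=sid,
                pct_identity=pident,
                aln_length=alen,
                mismatches=mism,
                gap_opens=gaps,
                q_start=qs,
                q_end=qe,
                s_start=ss,
                s_end=se,
                e_value=ev,
                bit_score=bits,
                q_len=qlen,
                s_len=slen,
                subject_desc=desc,
                reverse_subject=rev,
            )
        )
    return hits


def write_alignment_table(hits: list[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            ss, se = (h.s_end, h.s_start) if h.reverse_subject else (h.s_start, h.s_end)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, h.pct_identity, h.aln_length,
                        h.mismatches, h.gap_opens, h.q_start, h.q_end, ss, se,
                        f"{h.e_value:.3g}", h.bit_score, h.q_len, h.s_len,
                        h.subject_desc,
                    )
                )
                + "\n"
            )


def _parse_go_field(pid: str, field: str) -> list[GoAnnotation]:
    out = []
    if not field or field in {"-", ""}:
        return out
    for part in field.split("|"):
        part = part.strip()
        if not part:
            continue
        m = _GO_FIELD_RE.match(part)
        if not m:
            raise ValueError(f"malformed GO entry {part!r}")
        out.append(
            GoAnnotation(pid, m.group(1), m.group(2) or "", m.group(3) or "")
        )
    return out


def read_domain_table(
    path: str | Path, max_evalue: float = DEFAULT_MAX_EVALUE
) -> tuple[list[DomainHit], list[GoAnnotation]]:
    """Parse an InterProScan-style TSV into domain hits and GO annotations.

    Columns: protein_id, md5, seq_len, analysis, signature_id, signature_desc,
    start, end, e_value, status, date[, interpro_id, interpro_desc[, GO[, pathways]]].
    Rows with E-value above ``max_evalue`` (inclusive gate) are dropped; a
    ``-`` score (analyses that report none) is treated as significant.
    """
    domains: list[DomainHit] = []
    gos: list[GoAnnotation] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 11:
            raise AnnotationParseError(
                f"{path}:{lineno}: expected >=11 columns, got {len(f)}"
            )
        pid = f[0]
        try:
            start, end = int(f[6]), int(f[7])
        except ValueError:
            raise AnnotationParseError(
                f"{path}:{lineno}: malformed domain coordinates"
            ) from None
        ev = 0.0 if f[8] in {"-", ""} else float(f[8])
        if ev > max_evalue:
            continue
        ipr = f[11] if len(f) > 11 and f[11] not in {"-", ""} else None
        try:
            domains.append(
                DomainHit(
                    protein_id=pid,
                    signature_id=f[4],
                    description=f[5],
                    interpro_id=ipr,
                    start=start,
                    end=end,
                    e_value=ev,
                )
            )
            if len(f) > 13:
                gos.extend(_parse_go_field(pid, f[13]))
        except ValueError as e:
            raise AnnotationParseError(f"{path}:{lineno}: {e}") from None
    return domains, gos


def write_domain_table(
    domains: list[DomainHit],
    gos_by_row: list[list[GoAnnotation]] | None,
    path: str | Path,
) -> None:
    """Serialise domain hits back into the TSV dialect read_domain_table reads."""
    if gos_by_row is None:
        gos_by_row = [[] for _ in domains]
    with open(path, "w") as fh:
        for d, gos in zip(domains, gos_by_row):
            go_field = (
                "|".join(f"{g.go_id}({g.go_name})" for g in gos) if gos else "-"
            )
            fh.write(
                "\t".join(
                    [
                        d.protein_id, "-", "-", "mock", d.signature_id,
                        d.description, str(d.start), str(d.end),
                        f"{d.e_value:.3g}", "T", "-", d.interpro_id or "-",
                        "-", go_field,
                    ]
                )
                + "\n"
            )
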