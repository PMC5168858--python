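"""Per-protein membrane topology: signal peptides and transmembrane segments.

Profiles come either from standard predictor output files (TMHMM short,
SignalP short, Phobius short dialects) or from a built-in Kyte-Doolittle
hydropathy fallback, and multiple predictions for one protein are combined
(union by default, maximising sensitivity).

The quantity used by downstream classification is the *non-cleaved* TM
count: a predicted helix whose start lies within the predicted signal
peptide is taken to be the signal peptide itself, not a membrane anchor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "TmSegment",
    "SignalPeptideCall",
    "TopologyProfile",
    "read_topology_files",
    "predict_topology_fallback",
    "merge_predictions",
    "noncleaved_tm_count",
    "KYTE_DOOLITTLE",
]


class TopologyParseError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class TmSegment:
    """One transmembrane segment, 1-based inclusive residue coordinates."""

    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid TM segment {self.start}-{self.end}")


@dataclass(frozen=True)
class SignalPeptideCall:
    present: bool = False
    cleavage_after: int | None = None

    def __post_init__(self):
        if self.present and (self.cleavage_after is None or self.cleavage_after < 1):
            raise ValueError("signal peptide present requires cleavage_after >= 1")


@dataclass(frozen=True)
class TopologyProfile:
    protein_id: str
    signal: SignalPeptideCall = SignalPeptideCall()
    tm_segments: tuple[TmSegment, ...] = ()
    sources: frozenset[str] = frozenset()
    warning: str | None = None

    def __post_init__(self):
        segs = tuple(sorted(self.tm_segments))
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.protein_id}: overlapping TM segments {a} / {b}"
                )
        object.__setattr__(self, "tm_segments", segs)

    @property
    def tm_count(self) -> int:
        return len(self.tm_segments)


# ---------------------------------------------------------------------------
# Predictor-output parsing


_TOPO_SEG = re.compile(r"[io](\d+)-(\d+)")
_RANGE = re.compile(r"(\d+)-(\d+)")


def _parse_tmhmm_short(path: Path) -> dict[str, TopologyProfile]:
    """TMHMM short format: one line per protein with key=value fields,
    e.g. ``id  len=500  ExpAA=151.1  First60=0.1  PredHel=7  Topology=o10-32i44-66o``.
    """
    out: dict[str, TopologyProfile] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        pid = fields[0]
        kv = {}
        for f in fields[1:]:
            if "=" in f:
                k, v = f.split("=", 1)
                kv[k.lower()] = v
        if "predhel" not in kv or "topology" not in kv:
            raise TopologyParseError(f"{path}:{lineno}: not a TMHMM short line")
        try:
            n_hel = int(kv["predhel"])
            segs = tuple(
                TmSegment(int(a), int(b))
                for a, b in _TOPO_SEG.findall(kv["topology"])
            )
        except ValueError as e:
            raise TopologyParseError(f"{path}:{lineno}: {e}") from None
        if len(segs) != n_hel:
            raise TopologyParseError(
                f"{path}:{lineno}: PredHel={n_hel} but topology lists {len(segs)}"
            )
        out[pid] = TopologyProfile(pid, tm_segments=segs, sources=frozenset({"tmhmm"}))
    return out


def _parse_signalp_short(path: Path) -> dict[str, TopologyProfile]:
    """SignalP short tabular: ``name Cmax pos Ymax pos Smax pos Smean D ? Dmaxcut net``
    with ``?`` in {Y, N}; the Ymax position is the first residue of the mature
    protein, so cleavage_after = pos - 1.
    """
    out: dict[str, TopologyProfile] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 10:
            raise TopologyParseError(f"{path}:{lineno}: expected >=10 columns")
        pid = f[0]
        sp_flag = f[9].upper()
        if sp_flag not in {"Y", "N"}:
            raise TopologyParseError(f"{path}:{lineno}: SP flag {f[9]!r} not Y/N")
        try:
            ypos = int(f[4])
        except ValueError:
            raise TopologyParseError(f"{path}:{lineno}: bad Ymax position") from None
        sig = (
            SignalPeptideCall(True, max(1, ypos - 1))
            if sp_flag == "Y"
            else SignalPeptideCall()
        )
        out[pid] = TopologyProfile(pid, signal=sig, sources=frozenset({"signalp"}))
    return out


def _parse_phobius_short(path: Path) -> dict[str, TopologyProfile]:
    """Phobius short tabular: ``id  TM  SP  PREDICTION`` where PREDICTION is a
    topology string like ``n8-22c27/28o35-55i...`` (signal) or ``o10-32i44-66o``.
    """
    out: dict[str, TopologyProfile] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        if line.upper().split()[:2] == ["SEQENCE", "ID"] or line.upper().startswith(
            "SEQUENCE"
        ):
            continue  # header
        f = line.split()
        if len(f) != 4:
            raise TopologyParseError(f"{path}:{lineno}: expected 4 columns")
        pid, tm_s, sp_s, pred = f
        try:
            n_tm = int(tm_s)
        except ValueError:
            raise TopologyParseError(f"{path}:{lineno}: bad TM count") from None
        sig = SignalPeptideCall()
        body = pred
        if sp_s.upper() == "Y":
            m = re.match(r"n\d+-\d+c(\d+)/(\d+)", pred, flags=re.IGNORECASE)
            if not m:
                raise TopologyParseError(
                    f"{path}:{lineno}: SP=Y but no n..c../.. region in {pred!r}"
                )
            sig = SignalPeptideCall(True, int(m.group(1)))
            body = pred[m.end() :]
        segs = tuple(TmSegment(int(a), int(b)) for a, b in _RANGE.findall(body))
        if len(segs) != n_tm:
            raise TopologyParseError(
                f"{path}:{lineno}: TM={n_tm} but prediction lists {len(segs)}"
            )
        out[pid] = TopologyProfile(
            pid, signal=sig, tm_segments=segs, sources=frozenset({"phobius"})
        )
    return out


_DIALECTS = {
    "tmhmm-short": _parse_tmhmm_short,
    "signalp-short": _parse_signalp_short,
    "phobius-short": _parse_phobius_short,
}


def read_topology_files(path: str | Path, dialect: str) -> dict[str, TopologyProfile]:
    """Parse one predictor output file into per-protein profile fragments.

    Proteins absent from the file are simply absent from the result; they are
    never defaulted to an empty topology.
    """
    if dialect not in _DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        )
    return _DIALECTS[dialect](Path(path))


# ---------------------------------------------------------------------------
# Fallback hydropathy predictor

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0, "*": 0.0, "U": 0.0, "B": -3.5, "Z": -3.5,
}

_SMALL_CLEAVAGE = set("AGS")


def predict_topology_fallback(
    protein_id: str,
    aa_sequence: str,
    window: int = 19,
    threshold: float = 1.6,
) -> TopologyProfile:
    """Sliding-window Kyte-Doolittle hydropathy TM/SP prediction.

    Mean hydropathy is computed over every window of ``window`` residues;
    maximal runs of above-threshold windows become TM segments (the union of
    the residue spans of the windows in the run).  A segment starting within
    the first 30 residues that is followed within 8 residues by a small
    residue (A/G/S, the typical signal-peptidase -1/-3 requirement) is also
    reported as a signal-peptide candidate with cleavage at that residue.
    This is a deliberately simple hydropathy heuristic, not a reimplementation
    of the HMM predictors.
    """
    seq = aa_sequence.upper()
    n = len(seq)
    if n < window:
        return TopologyProfile(
            protein_id, sources=frozenset({"fallback"}), warning="sequence shorter than window"
        )
    scores = [KYTE_DOOLITTLE.get(a, 0.0) for a in seq]
    csum = [0.0]
    for s in scores:
        csum.append(csum[-1] + s)
    n_win = n - window + 1
    above = [
        (csum[i + window] - csum[i]) / window > threshold for i in range(n_win)
    ]
    raw: list[TmSegment] = []
    i = 0
    while i < n_win:
        if above[i]:
            j = i
            while j + 1 < n_win and above[j + 1]:
                j += 1
            # union of window spans [i+1 .. j+window] in 1-based residues
            raw.append(TmSegment(i + 1, j + window))
            i = j + 1
        else:
            i += 1
    # runs closer than one window give overlapping spans: interval-union them
    segs = list(_union_segments(raw))
    signal = SignalPeptideCall()
    if segs and segs[0].start <= 30:
        # cleavage site: nearest small residue (A/G/S, the signal-peptidase
        # -1/-3 preference) at the segment tail or just downstream; the tail
        # is searched first because alanine-rich cleavage motifs score as
        # hydrophobic and end up inside the detected segment
        end = segs[0].end
        for off in list(range(0, -9, -1)) + list(range(1, 9)):
            pos = end + off
            if 1 <= pos <= n and seq[pos - 1] in _SMALL_CLEAVAGE:
                signal = SignalPeptideCall(True, pos)
                break
    return TopologyProfile(
        protein_id,
        signal=signal,
        tm_segments=tuple(segs),
        sources=frozenset({"fallback"}),
    )


# ---------------------------------------------------------------------------
# Combination and counting


def _union_segments(segments) -> tuple[TmSegment, ...]:
    segs = sorted(segments)
    merged: list[list[int]] = []
    for s in segs:
        if merged and s.start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], s.end)
        else:
            merged.append([s.start, s.end])
    return tuple(TmSegment(a, b) for a, b in merged)


def _intersect_segments(profiles) -> tuple[TmSegment, ...]:
    # residues predicted TM by every source that reports any segment
    sets = [
        set().union(*(range(s.start, s.end + 1) for s in p.tm_segments))
        for p in profiles
        if p.tm_segments
    ]
    if len(sets) < len(profiles):
        return ()
    common = set.intersection(*sets) if sets else set()
    if not common:
        return ()
    runs = []
    for r in sorted(common):
        if runs and r == runs[-1][1] + 1:
            runs[-1][1] = r
        else:
            runs.append([r, r])
    return tuple(TmSegment(a, b) for a, b in runs)


def merge_predictions(
    profiles: list[TopologyProfile], mode: str = "union"
) -> TopologyProfile:
    """Combine profiles for one protein across predictors.

    union (default): TM segments interval-unioned; SP present if any source
    calls it, cleavage_after = max over sources.  ``intersection`` and
    ``priority`` (first profile wins per feature) exist for sensitivity
    analysis.
    """
    if not profiles:
        raise ValueError("no profiles to merge")
    ids = {p.protein_id for p in profiles}
    if len(ids) != 1:
        raise ValueError(f"conflicting protein ids in merge: {sorted(ids)}")
    pid = profiles[0].protein_id
    sources = frozenset().union(*(p.sources for p in profiles))
    if mode == "union":
        segs = _union_segments(s for p in profiles for s in p.tm_segments)
        sp = [p.signal for p in profiles if p.signal.present]
        signal = (
            SignalPeptideCall(True, max(s.cleavage_after for s in sp))
            if sp
            else SignalPeptideCall()
        )
    elif mode == "intersection":
        segs = _intersect_segments(profiles)
        sp = [p.signal for p in profiles if p.signal.present]
        signal = (
            SignalPeptideCall(True, min(s.cleavage_after for s in sp))
            if len(sp) == len(profiles)
            else SignalPeptideCall()
        )
    elif mode == "priority":
        with_tm = next((p for p in profiles if p.tm_segments), profiles[0])
        segs = with_tm.tm_segments
        signal = next(
            (p.signal for p in profiles if p.signal.present), SignalPeptideCall()
        )
    else:
        raise ValueError(f"unknown merge mode {mode!r}")
    return TopologyProfile(pid, signal=signal, tm_segments=segs, sources=sources)


def noncleaved_tm_count(profile: TopologyProfile) -> int:
    """Number of TM segments that are not the (cleaved) signal peptide.

    A segment whose start lies at or before the signal-peptide cleavage site
    is the signal peptide itself as seen by a hydrophobicity-based predictor
    and is discounted.  Without a signal peptide all segments count.
    """
    if not profile.signal.present:
        return profile.tm_count
    ca = profile.signal.cleavage_after
    return sum(1 for s in profile.tm_segments if s.start > ca)
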