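"""Six-frame ORF extraction and antisense flagging for strand-specific transcripts.

A strand-specific assembly means the forward strand of each transcript is the
sense strand of the underlying mRNA.  A transcript whose best annotation
nevertheless lies in a negative reading frame is therefore not a sense mRNA
for that protein and is treated as a non-coding antisense transcript.

Frames follow the BLAST/EMBOSS convention: +1/+2/+3 start at bases 1/2/3 of
the forward strand; -1/-2/-3 start at bases 1/2/3 of the reverse complement.
All nucleotide coordinates are 1-based inclusive on the *forward* strand; the
frame sign carries the strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

VALID_FRAMES = (1, 2, 3, -1, -2, -3)
_FRAME_ORDER = {f: i for i, f in enumerate(VALID_FRAMES)}

STOP = "*"

_NT = set("ACGTN")


@dataclass(frozen=True)
class Transcript:
    """One strand-specific assembled transcript."""

    id: str
    sequence: str
    strain: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - _NT
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: invalid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class Orf:
    """An open reading frame on a transcript.

    ``nt_start``/``nt_end`` are 1-based inclusive forward-strand coordinates
    of the codon span (including the terminating stop codon when present).
    ``aa_sequence`` excludes the terminal stop.  ``partial_5p``/``partial_3p``
    mark ORFs truncated by the transcript end (missing start / missing stop).
    """

    id: str
    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int
    aa_sequence: str
    partial_5p: bool = False
    partial_3p: bool = False

    @property
    def partial(self) -> bool:
        return self.partial_5p or self.partial_3p

    @property
    def codon_count(self) -> int:
        return (self.nt_end - self.nt_start + 1) // 3


def translate(nt_sequence: str, frame: int = 1) -> str:
    """Translate one reading frame with the standard genetic code.

    Codons containing N become ``X``; stop codons are rendered as ``*``.
    Trailing bases that do not fill a codon are ignored.
    """
    if frame not in VALID_FRAMES:
        raise ValueError(f"invalid frame {frame}; expected one of {VALID_FRAMES}")
    seq = nt_sequence.upper()
    bad = set(seq) - _NT
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    if frame < 0:
        seq = str(Seq(seq).reverse_complement())
    offset = abs(frame) - 1
    sub = seq[offset : offset + 3 * ((len(seq) - offset) // 3)]
    if not sub:
        return ""
    aa = str(Seq(sub).translate())
    if "N" in sub:
        # any codon containing N is X here, even when the ambiguity would
        # resolve to a single residue (e.g. ACN)
        aa = "".join(
            "X" if "N" in sub[3 * i : 3 * i + 3] else a for i, a in enumerate(aa)
        )
    return aa


def _frame_coords_to_forward(frame: int, cstart: int, cend: int, length: int):
    """Map 1-based coordinates on the reading strand to forward-strand coords."""
    if frame > 0:
        return cstart, cend
    return length - cend + 1, length - cstart + 1


def extract_orfs(transcript: Transcript, min_len_codons: int = 50) -> list[Orf]:
    """Extract all ORFs from a transcript in all six frames.

    An ORF is either a closed ATG-to-in-frame-stop span (stop codon included
    in the nucleotide span, excluded from the protein), or an open-ended span
    truncated by a transcript end: a 5'-partial run from the frame start to
    the first stop when that run does not itself begin with ATG, and a
    3'-partial run from an ATG (or the frame start) to the transcript end
    when no downstream in-frame stop exists.  Every internal ATG opens its
    own ORF.  Results are sorted by descending codon count, ties broken by
    frame order (+1,+2,+3,-1,-2,-3) then nt_start.
    """
    if min_len_codons < 1:
        raise ValueError("min_len_codons must be >= 1")
    seq = transcript.sequence.upper()
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    orfs: list[Orf] = []
    for frame in VALID_FRAMES:
        s = seq if frame > 0 else rc
        offset = abs(frame) - 1
        n_codons = (L - offset) // 3
        if n_codons <= 0:
            continue
        sub = s[offset : offset + 3 * n_codons]
        aa = translate(sub, 1)
        # standard code: M <=> ATG exactly, so starts come from the protein
        starts = [i for i, a in enumerate(aa) if a == "M"]
        next_stop = [n_codons] * n_codons  # codon index of next stop at/after i
        nxt = n_codons
        for i in range(n_codons - 1, -1, -1):
            if aa[i] == STOP:
                nxt = i
            next_stop[i] = nxt

        def emit(c0: int, c1: int, p5: bool, p3: bool):
            # c0..c1 inclusive codon indices on reading strand
            ncod = c1 - c0 + 1
            if ncod < min_len_codons:
                return
            cstart = offset + 3 * c0 + 1
            cend = offset + 3 * c1 + 3
            fs, fe = _frame_coords_to_forward(frame, cstart, cend, L)
            aa_seq = "".join(aa[c0 : c1 + 1]).rstrip(STOP) if not p3 else "".join(
                aa[c0 : c1 + 1]
            )
            orfs.append(
                Orf(
                    id="",
                    transcript_id=transcript.id,
                    frame=frame,
                    nt_start=fs,
                    nt_end=fe,
                    aa_sequence=aa_seq,
                    partial_5p=p5,
                    partial_3p=p3,
                )
            )

        for c0 in starts:
            ns = next_stop[c0]
            if ns < n_codons:
                emit(c0, ns, p5=False, p3=False)
            else:
                emit(c0, n_codons - 1, p5=False, p3=True)
        # 5'-partial: frame start to first stop, unless it starts with ATG
        if n_codons and aa[0] != "M":
            ns = next_stop[0]
            if ns < n_codons:
                emit(0, ns, p5=True, p3=False)
            else:
                emit(0, n_codons - 1, p5=True, p3=True)

    orfs.sort(key=lambda o: (-o.codon_count, _FRAME_ORDER[o.frame], o.nt_start))
    return [
        Orf(
            id=f"{transcript.id}.orf{i + 1}",
            transcript_id=o.transcript_id,
            frame=o.frame,
            nt_start=o.nt_start,
            nt_end=o.nt_end,
            aa_sequence=o.aa_sequence,
            partial_5p=o.partial_5p,
            partial_3p=o.partial_3p,
        )
        for i, o in enumerate(orfs)
    ]


def representative_orf(transcript: Transcript, min_len_codons: int = 50) -> Orf | None:
    """Longest ORF of the transcript (conventional representative protein)."""
    orfs = extract_orfs(transcript, min_len_codons)
    return orfs[0] if orfs else None


def flag_antisense(best_hit_frame: int | None) -> bool:
    """A transcript is antisense iff its best annotation hit frame is negative.

    In a strand-specific assembly a negative annotation frame means the
    transcript is the reverse complement of a coding mRNA.  Transcripts
    without any annotation hit cannot be called antisense.
    """
    if best_hit_frame is None:
        return False
    if best_hit_frame not in VALID_FRAMES:
        raise ValueError(f"invalid frame {best_hit_frame}")
    return best_hit_frame < 0
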