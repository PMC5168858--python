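"""Independent brute-force oracles used to cross-check the implementation.

Each oracle restates the intended definition in the most literal way
possible (per-position scans, residue-set arithmetic, exhaustive
filter-and-sort) and deliberately shares no code with the package.
"""

from __future__ import annotations

# --- standard genetic code, written out independently -----------------------

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def translate_oracle(nt: str, frame: int) -> str:
    s = nt.upper() if frame > 0 else revcomp(nt.upper())
    off = abs(frame) - 1
    out = []
    for i in range(off, len(s) - 2, 3):
        out.append(CODON_TABLE.get(s[i : i + 3], "X"))
    return "".join(out)


def orf_scan_oracle(seq: str, min_len_codons: int):
    """Literal per-position six-frame ORF scan.

    Returns a set of (frame, nt_start, nt_end, aa, partial_5p, partial_3p)
    tuples with forward-strand 1-based coordinates, matching the stated ORF
    definition: every ATG opens an ORF running to the next in-frame stop
    (stop codon included in the span) or to the transcript end (3'-partial);
    each frame additionally yields a 5'-partial ORF from its first codon
    when that codon is not ATG.
    """
    seq = seq.upper()
    L = len(seq)
    found = set()
    for frame in (1, 2, 3, -1, -2, -3):
        s = seq if frame > 0 else revcomp(seq)
        off = abs(frame) - 1
        n = (L - off) // 3
        codons = [s[off + 3 * i : off + 3 * i + 3] for i in range(n)]
        aas = [CODON_TABLE.get(c, "X") for c in codons]

        def fwd_coords(c0, c1):
            a, b = off + 3 * c0 + 1, off + 3 * c1 + 3
            if frame > 0:
                return a, b
            return L - b + 1, L - a + 1

        def record(c0, c1, p5, p3):
            if c1 - c0 + 1 < min_len_codons:
                return
            aa = "".join(aas[c0 : c1 + 1])
            if not p3 and aa.endswith("*"):
                aa = aa[:-1]
            a, b = fwd_coords(c0, c1)
            found.add((frame, a, b, aa, p5, p3))

        for p in range(n):
            if codons[p] == "ATG":
                q = p
                while q < n and aas[q] != "*":
                    q += 1
                if q < n:
                    record(p, q, False, False)
                else:
                    record(p, n - 1, False, True)
        if n and codons[0] != "ATG":
            q = 0
            while q < n and aas[q] != "*":
                q += 1
            if q < n:
                record(0, q, True, False)
            else:
                record(0, n - 1, True, True)
    return found


def sliding_window_oracle(seq: str, kd: dict, window: int, threshold: float):
    """Independent recomputation of windowed-mean hydropathy segments:
    per-window means by direct summation, above-threshold windows expanded
    to residue sets, unioned, and read back as maximal runs."""
    n = len(seq)
    if n < window:
        return []
    residues = set()
    for i in range(n - window + 1):
        mean = sum(kd.get(a, 0.0) for a in seq[i : i + window]) / window
        if mean > threshold:
            residues.update(range(i + 1, i + window + 1))
    runs = []
    for r in sorted(residues):
        if runs and r == runs[-1][1] + 1:
            runs[-1][1] = r
        else:
            runs.append([r, r])
    return [tuple(r) for r in runs]


def interval_union_oracle(segments):
    """Residue-set union of (start, end) intervals, read back as runs."""
    residues = set()
    for s, e in segments:
        residues.update(range(s, e + 1))
    runs = []
    for r in sorted(residues):
        if runs and r == runs[-1][1] + 1:
            runs[-1][1] = r
        else:
            runs.append([r, r])
    return [tuple(r) for r in runs]


def best_hit_oracle(hits, min_cov, max_e):
    """Exhaustive filter-then-sort over (q_span, q_len, s_span, s_len, e,
    bits, subject) tuples mirroring the alignment-hit fields."""
    surviving = []
    for h in hits:
        qcov = (h.q_end - h.q_start + 1) / h.q_len
        scov = (h.s_end - h.s_start + 1) / h.s_len
        if qcov >= min_cov and scov >= min_cov and h.e_value <= max_e:
            surviving.append(h)
    if not surviving:
        return None
    surviving.sort(key=lambda h: (h.e_value, -h.bit_score, h.subject_id))
    return surviving[0]


def noncleaved_recount_oracle(sp_present, cleavage_after, segments):
    if not sp_present:
        return len(segments)
    return len([s for s, _ in segments if s > cleavage_after])
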