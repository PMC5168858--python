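"""Synthetic transcriptomes with planted, fully known classifications.

The study's raw transcriptome assemblies are not redistributable, so this
module emulates them: strand-specific transcript FASTA plus mock annotation
bundles (TMHMM/SignalP/Phobius-style topology files, a BLAST-tabular
TCDB alignment table, an InterProScan-style domain/GO TSV) in exactly the
dialects the pipeline parses, with a truth table recording every planted
label.  Default proportions mirror the study conditions: roughly 20% of
transcripts trafficked, a third of those completely secreted, almost half
of the membrane proteins bitopic, a few percent transporter-tagged and
about 1% GPCRs, across three simulated strains.

Planted membrane segments are drawn from a strongly hydrophobic alphabet so
that the built-in hydropathy fallback predictor also detects them, letting
the pipeline run with no annotation files at all.  Noise corrupts exactly
one field of each selected record (a TM count, a signal-peptide call, an
E-value across the 1e-3 boundary, an alignment span across the 70% coverage
boundary, or a domain/GO annotation) rather than deleting records, keeping
file parse-ability separate from classification robustness.

Not emulated: realistic codon usage, the extreme AT-richness of these
genomes, and expression levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .orfs import Transcript, extract_orfs

# ---------------------------------------------------------------------------
# Planted classes and their downstream labels

TRANSPORTER_CLASSES = {
    # planted class -> (tc tag templates, category, substrate, sugar_family,
    #                   membrane?)
    "transporter_mfs": (["2.A.1.1.{n}"], "solute_transport", "sugars_metabolites", "mfs", True),
    "transporter_sss": (["2.A.2.3.{n}"], "solute_transport", "sugars_metabolites", "sss", True),
    "transporter_sweet": (["2.A.123.1.{n}"], "solute_transport", "sugars_metabolites", "sweet", True),
    "transporter_abc_sbp": (["3.A.1.1.{n}"], "solute_transport", "sugars_metabolites", "abc_sbp", False),
    "transporter_drug": (
        ["2.A.1.2.{n}", "2.A.1.3.{n}", "2.A.66.1.{n}", "3.A.1.201.{n}", "3.A.1.211.{n}", "3.A.3.8.{n}"],
        "solute_transport", "drugs_lipids", "none", True),
    "transporter_ion": (
        ["1.A.1.2.{n}", "2.A.40.1.{n}", "3.A.2.2.{n}", "3.A.3.1.{n}", "2.A.59.1.{n}", "1.A.26.1.{n}", "2.A.5.1.{n}", "2.A.89.1.{n}"],
        "solute_transport", "inorganic_ions_metals", "none", True),
    "transporter_biogenesis": (
        ["3.A.5.8.{n}", "1.A.33.1.{n}", "3.A.16.1.{n}", "1.F.1.1.{n}", "1.A.55.1.{n}", "1.A.31.1.{n}"],
        "protein_biogenesis_secretion", "unassigned", "none", True),
    "transporter_nuclear": (
        ["1.I.1.1.{n}", "3.A.18.1.{n}", "3.A.22.1.{n}", "9.A.50.1.{n}"],
        "nuclear_transport", "unassigned", "none", True),
    "transporter_peroxisomal": (["3.A.20.1.{n}"], "peroxisomal_import", "unassigned", "none", True),
    "transporter_organelle": (
        ["1.B.33.1.{n}", "1.B.8.1.{n}", "3.A.8.1.{n}", "3.A.9.1.{n}"],
        "organelle_import", "unassigned", "none", True),
    "transporter_other": (
        ["3.D.1.6.{n}", "4.C.1.1.{n}", "8.A.1.1.{n}", "9.B.2.1.{n}"],
        "other", "unassigned", "none", True),
}

GPCR_CLASSES = {
    # planted class -> (gpcr_class, architecture flags)
    "gpcr_class_c_anf": ("class_c", ("anf",)),
    "gpcr_class_c_sbp": ("class_c", ("sbp_type_ii",)),
    "gpcr_class_c_pectin": ("class_c", ("beta_helix", "pectin_lyase")),
    "gpcr_rhodopsin": ("rhodopsin_dicty_car", ()),
}

PLANTED_CLASSES = (
    ["soluble", "secreted", "bitopic", "polytopic", "antisense"]
    + list(TRANSPORTER_CLASSES)
    + list(GPCR_CLASSES)
)

DEFAULT_CLASS_MIX = {
    "soluble": 0.730, "antisense": 0.050, "secreted": 0.068,
    "bitopic": 0.065, "polytopic": 0.032,
    "transporter_mfs": 0.006, "transporter_sss": 0.004,
    "transporter_sweet": 0.004, "transporter_abc_sbp": 0.006,
    "transporter_drug": 0.005, "transporter_ion": 0.005,
    "transporter_biogenesis": 0.004, "transporter_nuclear": 0.003,
    "transporter_peroxisomal": 0.002, "transporter_organelle": 0.003,
    "transporter_other": 0.003,
    "gpcr_class_c_sbp": 0.004, "gpcr_class_c_pectin": 0.003,
    "gpcr_class_c_anf": 0.002, "gpcr_rhodopsin": 0.001,
}

_GO_TERMS = {
    "transport": [
        ("GO:0055085", "transmembrane transport"),
        ("GO:0008643", "carbohydrate transport"),
        ("GO:0015293", "sugar:proton symporter activity"),
        ("GO:0046961", "v-type atpase, proton-transporting mechanism"),
    ],
    "sensing_signaling": [
        ("GO:0004930", "g-protein coupled receptor activity"),
        ("GO:0007165", "signal transduction"),
        ("GO:0004673", "two-component sensor activity"),
    ],
    "catalysis": [
        ("GO:0004672", "protein kinase"),
        ("GO:0008422", "beta-glucosidase"),
        ("GO:0046933", "atp synthase"),
    ],
    "other": [
        ("GO:0007155", "cell adhesion"),
        ("GO:0005199", "structural constituent of cell wall"),
    ],
}

_ROLE_DESCS = {
    "transport": "sugar transporter family protein",
    "sensing_signaling": "two-component system sensing protein",
    "catalysis": "glycoside hydrolase family protein",
    "other": "adhesin-like cell surface protein",
}

# Rare V/L in the hydrophilic pool: far too sparse to fake a TM window, but
# (with the biased codon choice below) they plant out-of-frame stop codons so
# spurious ORFs in shifted/reverse frames stay short.
_HYDROPHILIC = "DEKNQSTGRHPVL"
_HYDROPHILIC_W = np.array(
    [2, 2, 2, 1.5, 1.5, 2, 2, 1.5, 1, 0.5, 1, 0.7, 0.7], float
)
_HYDROPHOBIC = "LIVFA"
_HYDROPHOBIC_W = np.array([3, 2, 2, 1, 1], float)

_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for cods in _AA_TO_CODONS.values():
    cods.sort()
_STOP_CODONS = sorted(standard_dna_table.stop_codons)

# codons that create stop codons in shifted (GTA, TTA/CTA) or reverse-strand
# (TTA, CTA, TCA) reading frames; chosen half the time for these residues
_STOP_SEEDING = {"V": "GTA", "L": ("TTA", "CTA"), "S": "TCA"}


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated dataset."""

    n_transcripts: int = 1000
    strain_names: tuple[str, ...] = ("neocallimastix", "anaeromyces", "piromyces")
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    orf_len_range: tuple[int, int] = (120, 400)  # codons, soluble-type ORFs
    tm_count_range: tuple[int, int] = (2, 8)  # polytopic proteins
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        unknown = set(self.class_mix) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes {sorted(unknown)}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions sum to {total}, not 1")
        if any(p < 0 for p in self.class_mix.values()):
            raise ValueError("class_mix proportions must be >= 0")
        for name, rng_ in (("orf_len_range", self.orf_len_range),
                           ("tm_count_range", self.tm_count_range)):
            lo, hi = rng_
            if lo > hi or lo < 1:
                raise ValueError(f"{name} {rng_} is empty or invalid")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be in [0, 1]")


# ---------------------------------------------------------------------------
# Protein and transcript construction


def _pick(rng, letters, weights, n):
    w = weights / weights.sum()
    return "".join(rng.choice(list(letters), size=n, p=w))


def _philic(rng, n: int) -> str:
    return _pick(rng, _HYDROPHILIC, _HYDROPHILIC_W, n)


def _phobic(rng, n: int) -> str:
    return _pick(rng, _HYDROPHOBIC, _HYDROPHOBIC_W, n)


def _signal_peptide(rng) -> tuple[str, int]:
    """Hydrophobic core plus an A-X-A signal-peptidase motif; returns the
    SP sequence (without the initiator M) and cleavage_after (counting M)."""
    h = int(rng.integers(12, 19))
    sp = _phobic(rng, h) + "ASA"
    return sp, 1 + h + 3


def _protein_for_class(rng, cls: str, cfg: GeneratorConfig):
    """Build the planted protein.  Returns (aa, sp_present, cleavage_after,
    tm_segments list of (start, end))."""
    lo, hi = cfg.orf_len_range
    if cls in ("soluble", "antisense"):
        n = int(rng.integers(lo, hi + 1))
        return "M" + _philic(rng, n - 1), False, 0, []
    if cls == "secreted" or cls == "transporter_abc_sbp":
        n = int(rng.integers(max(lo, 150), hi + 1))
        sp, ca = _signal_peptide(rng)
        rest = n - 1 - len(sp)
        return "M" + sp + _philic(rng, rest), True, ca, []
    if cls == "bitopic" or cls == "polytopic" or cls in TRANSPORTER_CLASSES:
        if cls == "bitopic":
            k = 1
        elif cls == "polytopic":
            k = int(rng.integers(cfg.tm_count_range[0], cfg.tm_count_range[1] + 1))
        else:
            k = 6
        parts = ["M" + _philic(rng, int(rng.integers(32, 45)))]
        tms = []
        pos = len(parts[0])
        for _ in range(k):
            t = int(rng.integers(18, 26))
            tms.append((pos + 1, pos + t))
            parts.append(_phobic(rng, t))
            pos += t
            loop = int(rng.integers(18, 31))
            parts.append(_philic(rng, loop))
            pos += loop
        return "".join(parts), False, 0, tms
    if cls in GPCR_CLASSES:
        sp_present = cls.startswith("gpcr_class_c") and rng.random() < 0.30
        head = "M"
        ca = 0
        if sp_present:
            sp, ca = _signal_peptide(rng)
            head += sp
        nterm = int(rng.integers(250, 501)) if cls != "gpcr_rhodopsin" else int(
            rng.integers(45, 90)
        )
        parts = [head, _philic(rng, nterm)]
        pos = len(head) + nterm
        tms = []
        for i in range(7):
            t = int(rng.integers(18, 26))
            tms.append((pos + 1, pos + t))
            parts.append(_phobic(rng, t))
            pos += t
            loop = int(rng.integers(12, 26)) if i < 6 else int(rng.integers(20, 40))
            parts.append(_philic(rng, loop))
            pos += loop
        return "".join(parts), sp_present, ca, tms
    raise ValueError(f"unknown planted class {cls!r}")


def _encode(rng, aa: str) -> str:
    out = []
    for a in aa:
        seed = _STOP_SEEDING.get(a)
        if seed is not None and rng.random() < 0.5:
            out.append(seed if isinstance(seed, str) else seed[rng.integers(0, 2)])
        else:
            cods = _AA_TO_CODONS[a]
            out.append(cods[rng.integers(0, len(cods))])
    return "".join(out)


def _reverse_complement(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _build_transcript(rng, tid: str, strain: str, aa: str, antisense: bool,
                      min_len_codons: int = 50) -> Transcript:
    """Assemble a transcript whose longest ORF is exactly the planted one.

    Flanks are TTAA repeats (stop codons in all six frames; TTAA is its own
    reverse complement), and codon choice is re-sampled in the rare case a
    spurious ORF in another frame outgrows the planted one.
    """
    for _ in range(50):
        orf_nt = _encode(rng, aa) + _STOP_CODONS[rng.integers(0, 3)]
        f5 = "TTAA" * int(rng.integers(2, 7))
        f3 = "TTAA" * int(rng.integers(2, 7))
        seq = f5 + orf_nt + f3
        if antisense:
            seq = _reverse_complement(seq)
        t = Transcript(tid, seq, strain)
        orfs = extract_orfs(t, min_len_codons)
        if not orfs:
            continue
        rep = orfs[0]
        if rep.aa_sequence == aa and (rep.frame < 0) == antisense and not rep.partial:
            return t
    raise RuntimeError(f"could not assemble transcript {tid}")


# ---------------------------------------------------------------------------
# Generation


def generate_transcriptome(
    config: GeneratorConfig,
) -> tuple[dict[str, list[Transcript]], pd.DataFrame]:
    """Generate per-strain transcripts and the planted truth table.

    The truth table has one row per transcript with the planted localisation
    class, GO role, TC identity tag and its category/substrate/sugar-family
    bins, GPCR class and architecture flags, frame sign, and the planted
    topology (signal peptide and TM coordinates).  Same config (including
    seed) gives byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes], float)
    probs = probs / probs.sum()
    transcripts: dict[str, list[Transcript]] = {}
    rows = []
    for strain in config.strain_names:
        ts: list[Transcript] = []
        drawn = rng.choice(len(classes), size=config.n_transcripts, p=probs)
        for i, ci in enumerate(drawn):
            cls = classes[int(ci)]
            tid = f"{strain}_t{i:05d}"
            aa, sp, ca, tms = _protein_for_class(rng, cls, config)
            antisense = cls == "antisense"
            t = _build_transcript(rng, tid, strain, aa, antisense)
            ts.append(t)
            row = {
                "transcript_id": tid,
                "strain": strain,
                "planted_class": cls,
                "frame_sign": -1 if antisense else 1,
                "sp_present": sp,
                "cleavage_after": ca,
                "tm_starts": ",".join(str(s) for s, _ in tms),
                "tm_ends": ",".join(str(e) for _, e in tms),
                "protein_len": len(aa),
                "localization": "", "role": "", "go_names": "", "desc": "",
                "tc_id": "", "category": "", "substrate": "", "sugar_family": "",
                "gpcr_class": "", "gpcr_flags": "",
            }
            _plant_labels(rng, row, cls, sp, ca, tms)
            rows.append(row)
        transcripts[strain] = ts
    truth = pd.DataFrame(rows)
    return transcripts, truth


def _plant_labels(rng, row, cls, sp, ca, tms):
    k_noncleaved = sum(1 for s, _ in tms if s > ca) if sp else len(tms)
    if cls == "antisense":
        row["localization"] = "antisense_noncoding"
        row["desc"] = "hypothetical conserved protein"
        return
    if k_noncleaved == 0:
        row["localization"] = "secreted" if sp else "soluble"
    elif k_noncleaved == 1:
        row["localization"] = "bitopic_membrane"
    else:
        row["localization"] = "polytopic_membrane"

    def set_go(role, n_terms=1):
        pool = _GO_TERMS[role]
        idx = rng.integers(0, len(pool))
        terms = [pool[int(idx)]]
        row["go_names"] = "|".join(f"{gid}({name})" for gid, name in terms)
        row["desc"] = _ROLE_DESCS[role]

    if cls in ("soluble", "secreted"):
        # non-membrane: annotated or not, never enters the role table
        r = rng.random()
        if r < 0.5:
            set_go("catalysis")
        elif r < 0.75:
            set_go("other")
        return
    if cls in ("bitopic", "polytopic"):
        role = ["transport", "sensing_signaling", "catalysis", "other", "unknown"][
            int(rng.integers(0, 5))
        ]
        row["role"] = role
        if role != "unknown":
            set_go(role)
        return
    if cls in TRANSPORTER_CLASSES:
        templates, cat, sub, fam, membrane = TRANSPORTER_CLASSES[cls]
        tmpl = templates[int(rng.integers(0, len(templates)))]
        row["tc_id"] = tmpl.format(n=int(rng.integers(1, 40)))
        row["category"], row["substrate"], row["sugar_family"] = cat, sub, fam
        if membrane:
            row["role"] = "transport"
        gid, name = _GO_TERMS["transport"][int(rng.integers(0, 3))]
        row["go_names"] = (
            f"{gid}({name})|GO:0004672(protein kinase)"  # precedence exercised
        )
        row["desc"] = "putative transporter component"
        return
    if cls in GPCR_CLASSES:
        gcls, flags = GPCR_CLASSES[cls]
        row["gpcr_class"] = gcls
        row["gpcr_flags"] = ",".join(flags)
        row["role"] = "sensing_signaling"
        row["go_names"] = "GO:0004930(g-protein coupled receptor activity)"
        row["desc"] = "putative G-protein coupled receptor"
        return


# ---------------------------------------------------------------------------
# Mock annotation emission


def _topology_string(tms) -> str:
    parts, lead = [], "o"
    for s, e in tms:
        parts.append(f"{lead}{s}-{e}")
        lead = "i" if lead == "o" else "o"
    parts.append(lead)
    return "".join(parts)


def _tm_list(row) -> list[tuple[int, int]]:
    if not row["tm_starts"]:
        return []
    ss = [int(x) for x in str(row["tm_starts"]).split(",")]
    ee = [int(x) for x in str(row["tm_ends"]).split(",")]
    return list(zip(ss, ee))


def _mutate_tms(rng, tms, L):
    """Add or drop one TM segment (the planted noise for TM-count records)."""
    tms = list(tms)
    add = not tms or rng.random() < 0.5
    if add:
        start = (tms[-1][1] + 6) if tms else max(35, L // 2)
        if start + 20 <= L:
            tms.append((start, start + 20))
            return tms
        if tms:
            return tms[:-1]
        return [(max(1, L - 25), max(21, L - 5))]
    return tms[:-1]


def _domain_rows(rng, row):
    """Planted InterProScan-style rows for one protein: list of
    (signature, interpro or None, desc, start, end, e_value, go_field)."""
    L = int(row["protein_len"])
    cls = row["planted_class"]
    out = []
    if cls == "antisense":
        out.append(("PF99999", None, row["desc"], 5, min(80, L - 1), 1e-6, "-"))
        return out
    if cls in GPCR_CLASSES:
        tms = _tm_list(row)
        bundle = tms[-7][0]
        out.append(
            ("BLASTP", None, row["desc"], 1, L, 1e-30, row["go_names"] or "-")
        )
        if row["gpcr_class"] == "class_c":
            out.append(
                ("PF00003", "IPR017978", "gpcr, family 3, seven-transmembrane domain",
                 bundle, L - 2, 1e-40, "-")
            )
            arch = {
                "gpcr_class_c_anf": [
                    ("PF01094", "IPR001828", "receptor family ligand-binding region",
                     30, bundle - 20)],
                "gpcr_class_c_sbp": [
                    ("SSF53850", None, "periplasmic binding protein-like II",
                     25, bundle - 15)],
                "gpcr_class_c_pectin": [
                    ("SSF51126", "IPR011050", "pectin lyase fold", 25, bundle - 30),
                    ("SM00710", "IPR006626", "parallel beta-helix repeat",
                     40, bundle - 25)],
            }[cls]
            for sig, ipr, desc, s, e in arch:
                out.append((sig, ipr, desc, s, max(s + 10, e), 1e-12, "-"))
        else:
            out.append(
                ("PF00001", "IPR017452",
                 "seven transmembrane receptor, rhodopsin-like",
                 bundle, L - 2, 1e-35, "-")
            )
        return out
    if row["go_names"] or row["desc"]:
        sig = f"PF{int(rng.integers(10000, 99999)):05d}"
        out.append(
            (sig, None, row["desc"] or "uncharacterised protein",
             5, min(150, L - 1), 1e-8, row["go_names"] or "-")
        )
    return out


def _alignment_rows(rng, row):
    """Planted TCDB BLAST-tabular rows: list of 14-column tuples."""
    qid = row["transcript_id"]
    L = int(row["protein_len"])
    out = []
    if row["tc_id"]:
        acc = f"Q{int(rng.integers(10000, 99999))}"
        slen = int(L / 0.9)
        sspan = int(0.95 * slen)
        ev = 10.0 ** -int(rng.integers(10, 80))
        out.append(
            (qid, f"gnl|TC-DB|{acc}|{row['tc_id']}",
             round(30 + 60 * rng.random(), 1), L, int(0.3 * L), 2,
             1, L, 1, sspan, ev, round(200 + 800 * rng.random(), 1), L, slen)
        )
        if rng.random() < 0.5:
            # decoy: smaller E-value but fails reciprocal coverage
            out.append(
                (qid, f"gnl|TC-DB|Q00001|9.B.99.1.1",
                 55.0, L // 2, L // 10, 1,
                 1, L // 2, 1, slen // 2, ev / 100, 999.0, L, slen)
            )
    elif row["planted_class"] in ("soluble", "secreted"):
        r = rng.random()
        if r < 0.15:
            # coverage failure: spans half the query
            out.append(
                (qid, "gnl|TC-DB|Q11111|2.A.1.1.1", 60.0, L // 2, L // 10, 1,
                 1, L // 2, 1, L // 2, 1e-20, 300.0, L, L)
            )
        elif r < 0.25:
            # E-value failure: full coverage, insignificant hit
            out.append(
                (qid, "gnl|TC-DB|Q22222|1.A.1.1.1", 25.0, L, L // 2, 5,
                 1, L, 1, L, 0.05, 40.0, L, L)
            )
    return out


def emit_mock_annotations(
    truth: pd.DataFrame,
    transcripts: dict[str, list[Transcript]],
    outdir: str | Path,
    noise: float = 0.0,
    seed: int = 0,
) -> dict[str, dict[str, Path]]:
    """Write the per-strain FASTA and annotation bundle.

    Returns {strain: {kind: path}} with kinds fasta/tmhmm/signalp/phobius/
    tcdb/domains.  With noise=0 every record is consistent with the truth
    table; with noise=p each record is independently corrupted (one field
    changed) with probability p.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth_ids = set(truth["transcript_id"])
    t_ids = {t.id for ts in transcripts.values() for t in ts}
    if truth_ids != t_ids:
        raise ValueError("truth table and transcripts disagree on transcript ids")
    bundles: dict[str, dict[str, Path]] = {}

    def corrupted() -> bool:
        return noise > 0 and rng.random() < noise

    for strain, ts in transcripts.items():
        sub = {
            r["transcript_id"]: r
            for r in truth[truth["strain"] == strain].to_dict("records")
        }
        paths = {k: outdir / f"{strain}.{ext}" for k, ext in [
            ("fasta", "fasta"), ("tmhmm", "tmhmm.txt"),
            ("signalp", "signalp.txt"), ("phobius", "phobius.txt"),
            ("tcdb", "tcdb.tsv"), ("domains", "domains.tsv"),
        ]}
        with open(paths["fasta"], "w") as fh:
            for t in ts:
                fh.write(f">{t.id}\n")
                for i in range(0, len(t.sequence), 70):
                    fh.write(t.sequence[i : i + 70] + "\n")

        tm_lines, sp_lines, ph_lines, al_lines, dom_lines = [], [], [], [], []
        for t in ts:
            row = sub[t.id]
            L = int(row["protein_len"])
            tms = _tm_list(row)
            sp = bool(row["sp_present"])
            ca = int(row["cleavage_after"])

            tm_emit = _mutate_tms(rng, tms, L) if corrupted() else tms
            tm_lines.append(
                f"{t.id}\tlen={L}\tExpAA={sum(e - s + 1 for s, e in tm_emit):.2f}"
                f"\tFirst60=0.00\tPredHel={len(tm_emit)}"
                f"\tTopology={_topology_string(tm_emit)}"
            )

            sp_emit, ca_emit = (not sp, 20 if not sp else 0) if corrupted() else (sp, ca)
            if sp_emit:
                sp_lines.append(
                    f"{t.id}\t0.52\t{ca_emit + 1}\t0.61\t{ca_emit + 1}"
                    f"\t0.73\t{ca_emit}\t0.55\t0.60\tY\t0.45\tSignalP-noTM"
                )
            else:
                sp_lines.append(
                    f"{t.id}\t0.10\t1\t0.08\t1\t0.09\t1\t0.05\t0.06\tN\t0.45\tSignalP-noTM"
                )

            ph_tms, ph_sp, ph_ca = tms, sp, ca
            if corrupted():
                if rng.random() < 0.5:
                    ph_tms = _mutate_tms(rng, tms, L)
                else:
                    ph_sp, ph_ca = not sp, 20 if not sp else 0
            body = _topology_string(ph_tms) if ph_tms else "o"
            if ph_sp:
                pred = f"n1-{max(1, ph_ca - 3)}c{ph_ca}/{ph_ca + 1}" + body
                ph_lines.append(f"{t.id}\t{len(ph_tms)}\tY\t{pred}")
            else:
                ph_lines.append(f"{t.id}\t{len(ph_tms)}\t0\t{body}")

            for rec in _alignment_rows(rng, row):
                rec = list(rec)
                if corrupted():
                    if rng.random() < 0.5:
                        # push the E-value across the significance boundary
                        rec[10] = 1e-2 if rec[10] <= 1e-3 else 1e-4
                    else:
                        # shrink the query span below reciprocal coverage
                        rec[6], rec[7] = 1, int(0.5 * rec[12])
                        rec[3] = rec[7]
                rec[10] = f"{rec[10]:.2e}"
                al_lines.append("\t".join(str(x) for x in rec))

            for sig, ipr, desc, s, e, ev, go in _domain_rows(rng, row):
                if corrupted():
                    sig, ipr, desc, go = "PF99998", None, "hypothetical protein", "-"
                dom_lines.append(
                    "\t".join(
                        [t.id, "-", str(L), "mock", sig, desc, str(s), str(e),
                         f"{ev:.2e}", "T", "-", ipr or "-", "-", go]
                    )
                )

        paths["tmhmm"].write_text("\n".join(tm_lines) + "\n")
        paths["signalp"].write_text("\n".join(sp_lines) + "\n")
        paths["phobius"].write_text(
            "SEQENCE ID\tTM\tSP\tPREDICTION\n" + "\n".join(ph_lines) + "\n"
        )
        paths["tcdb"].write_text("\n".join(al_lines) + ("\n" if al_lines else ""))
        paths["domains"].write_text("\n".join(dom_lines) + "\n")
        bundles[strain] = paths
    return bundles


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
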