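"""End-to-end orchestration: ORFs -> topology -> funnel -> roles ->
transporters -> GPCRs -> report bundle.

All thresholds default to the reference configuration: reciprocal coverage
0.70, inclusive E <= 1e-3, GPCR TM gate 7-9, union topology merging,
minimum ORF length 50 codons.  Each transcript is represented by its
longest ORF and counted exactly once in every table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .annotation import (
    read_alignment_table,
    read_domain_table,
    read_length_table,
)
from .funnel import classify_localization, funnel_counts
from .gpcr import (
    SignatureTable,
    TM_GATE,
    classify_gpcr,
    find_gpcr_candidates,
    gpcr_report,
)
from .orfs import Transcript, extract_orfs, flag_antisense
from .roles import assign_role, role_distribution
from .topology import (
    merge_predictions,
    predict_topology_fallback,
    read_topology_files,
)
from .transporters import (
    CategoryMap,
    assign_transporters,
    tabulate_transporters,
)


@dataclass
class StrainInput:
    """Input files for one strain.  ``topology_files`` is a list of
    (path, dialect) pairs; with none given the built-in hydropathy fallback
    predictor is used."""

    name: str
    fasta: str | Path
    topology_files: list[tuple[str | Path, str]] = field(default_factory=list)
    alignment: str | Path | None = None
    domains: str | Path | None = None
    lengths: str | Path | None = None


@dataclass
class RunConfig:
    strains: list[StrainInput]
    min_orf_codons: int = 50
    min_coverage: float = 0.70
    max_evalue: float = 1e-3
    gpcr_tm_gate: tuple[int, int] = TM_GATE
    merge_mode: str = "union"
    category_map: str | Path | None = None
    gpcr_signatures: str | Path | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.strains:
            raise ValueError("at least one strain input is required")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")
        if self.min_orf_codons < 1:
            raise ValueError("min_orf_codons must be >= 1")


@dataclass
class PipelineResult:
    records: pd.DataFrame
    reports: dict[str, pd.DataFrame]
    manifest: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"[{stage}] {context}: {cause}")
        self.stage = stage


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _read_fasta(path: str | Path, strain: str) -> list[Transcript]:
    return [
        Transcript(rec.id, str(rec.seq).upper(), strain)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage for every strain and assemble the report bundle."""
    cmap = (
        CategoryMap.from_tsv(config.category_map)
        if config.category_map
        else CategoryMap.default()
    )
    sigtab = (
        SignatureTable.from_tsv(config.gpcr_signatures)
        if config.gpcr_signatures
        else SignatureTable.default()
    )
    rows = []
    gpcr_rows = []
    tc_rows = []
    input_hashes = {}
    for strain in config.strains:
        try:
            transcripts = _read_fasta(strain.fasta, strain.name)
        except Exception as e:  # noqa: BLE001
            raise StageError("orf_extraction", f"reading {strain.fasta}", e)
        input_hashes[str(strain.fasta)] = _sha256(strain.fasta)

        # representative (longest) ORF per transcript
        reps = {}
        for t in transcripts:
            orfs = extract_orfs(t, config.min_orf_codons)
            if orfs:
                reps[t.id] = orfs[0]

        # topology: parse predictor files, or fall back to hydropathy
        frags: dict[str, list] = {}
        if strain.topology_files:
            for path, dialect in strain.topology_files:
                try:
                    for pid, prof in read_topology_files(path, dialect).items():
                        frags.setdefault(pid, []).append(prof)
                except Exception as e:  # noqa: BLE001
                    raise StageError("topology", f"parsing {path}", e)
                input_hashes[str(path)] = _sha256(path)
            profiles = {
                pid: merge_predictions(ps, config.merge_mode)
                for pid, ps in frags.items()
            }
        else:
            profiles = {
                pid: predict_topology_fallback(pid, orf.aa_sequence)
                for pid, orf in reps.items()
            }

        # annotations
        domains, gos = [], []
        if strain.domains:
            try:
                domains, gos = read_domain_table(
                    strain.domains, max_evalue=config.max_evalue
                )
            except Exception as e:  # noqa: BLE001
                raise StageError("annotation_io", f"parsing {strain.domains}", e)
            input_hashes[str(strain.domains)] = _sha256(strain.domains)
        hits = []
        if strain.alignment:
            lengths = read_length_table(strain.lengths) if strain.lengths else None
            try:
                hits = read_alignment_table(strain.alignment, lengths)
            except Exception as e:  # noqa: BLE001
                raise StageError("annotation_io", f"parsing {strain.alignment}", e)
            input_hashes[str(strain.alignment)] = _sha256(strain.alignment)

        domains_by: dict[str, list] = {}
        for d in domains:
            domains_by.setdefault(d.protein_id, []).append(d)
        gos_by: dict[str, list] = {}
        for g in gos:
            gos_by.setdefault(g.protein_id, []).append(g)
        hit_queries = {h.query_id for h in hits}

        # transporters: every transcript eligible, funnel class irrelevant
        assignments, unparsable = assign_transporters(
            hits, cmap, min_cov=config.min_coverage, max_e=config.max_evalue
        )
        tc_by = {a.protein_id: a for a in assignments}
        for a in assignments:
            tc_rows.append(
                {
                    "strain": strain.name,
                    "protein_id": a.protein_id,
                    "tc_id": str(a.tc_id),
                    "category": a.category.value,
                    "substrate": a.substrate.value,
                    "sugar_family": a.sugar_family.value,
                    "best_subject": a.best_hit.subject_id,
                    "best_evalue": a.best_hit.e_value,
                }
            )

        # GPCRs
        ann_texts = {
            pid: [d.description for d in ds] for pid, ds in domains_by.items()
        }
        candidates = find_gpcr_candidates(
            ann_texts, profiles, gate=config.gpcr_tm_gate
        )
        gpcr_by = {}
        for cand in candidates:
            cand = classify_gpcr(
                cand, profiles[cand.protein_id],
                domains_by.get(cand.protein_id, []), sigtab,
            )
            gpcr_by[cand.protein_id] = cand
            gpcr_rows.append(
                {
                    "strain": strain.name,
                    "protein_id": cand.protein_id,
                    "tm_count": cand.tm_count,
                    "gpcr_class": cand.gpcr_class.value,
                    "flags": ",".join(
                        sorted(f.value for f in cand.architecture_flags)
                    ),
                    "n_terminal_length": cand.n_terminal_length,
                    "has_signal_peptide": cand.has_signal_peptide,
                    "class_conflict": cand.class_conflict,
                }
            )

        # per-transcript classification records
        for t in transcripts:
            rep = reps.get(t.id)
            prof = profiles.get(t.id)
            has_annotation = (
                t.id in domains_by or t.id in gos_by or t.id in hit_queries
            )
            frame = rep.frame if rep else 0
            antisense = flag_antisense(
                frame if (rep and has_annotation) else None
            )
            loc, no_profile = classify_localization(prof, antisense)
            role = ""
            if loc.value in ("bitopic_membrane", "polytopic_membrane"):
                role = assign_role(gos_by.get(t.id, [])).value
            a = tc_by.get(t.id)
            g = gpcr_by.get(t.id)
            rows.append(
                {
                    "transcript_id": t.id,
                    "strain": strain.name,
                    "frame": frame,
                    "protein_len": len(rep.aa_sequence) if rep else 0,
                    "localization": loc.value,
                    "no_profile": no_profile,
                    "tm_count": prof.tm_count if prof else 0,
                    "sp_present": bool(prof.signal.present) if prof else False,
                    "role": role,
                    "tc_id": str(a.tc_id) if a else "",
                    "category": a.category.value if a else "",
                    "substrate": a.substrate.value if a else "",
                    "sugar_family": a.sugar_family.value if a else "",
                    "gpcr_class": g.gpcr_class.value if g else "",
                    "gpcr_flags": ",".join(
                        sorted(f.value for f in g.architecture_flags)
                    )
                    if g
                    else "",
                }
            )

    records = pd.DataFrame(rows).sort_values(
        ["strain", "transcript_id"], kind="mergesort", ignore_index=True
    )
    tc_df = pd.DataFrame(
        tc_rows,
        columns=[
            "strain", "protein_id", "tc_id", "category", "substrate",
            "sugar_family", "best_subject", "best_evalue",
        ],
    )
    gpcr_df = pd.DataFrame(
        gpcr_rows,
        columns=[
            "strain", "protein_id", "tm_count", "gpcr_class", "flags",
            "n_terminal_length", "has_signal_peptide", "class_conflict",
        ],
    )
    reports = {"funnel": funnel_counts(records), "roles": role_distribution(records)}
    reports.update(tabulate_transporters(tc_df))
    reports.update(
        {f"gpcr_{k}": v for k, v in gpcr_report(gpcr_df).items()}
    )
    reports["transporter_assignments"] = tc_df
    reports["gpcr_candidates"] = gpcr_df
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_orf_codons": config.min_orf_codons,
            "min_coverage": config.min_coverage,
            "max_evalue": config.max_evalue,
            "gpcr_tm_gate": list(config.gpcr_tm_gate),
            "merge_mode": config.merge_mode,
        },
        "inputs_sha256": dict(sorted(input_hashes.items())),
    }
    return PipelineResult(records=records, reports=reports, manifest=manifest)


def write_reports(result: PipelineResult, outdir: str | Path) -> list[Path]:
    """Persist the record table, every report table (TSV), a combined JSON
    report and the run manifest.  Output is byte-deterministic for a given
    config and inputs."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise StageError("report", f"output directory {outdir}", e)
    written = []

    def _save(df: pd.DataFrame, name: str, index: bool):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index)
        written.append(p)

    _save(result.records, "records", index=False)
    combined = {}
    for name, df in result.reports.items():
        indexed = name in {"categories", "substrates", "sugar_families", "gpcr_classes"}
        _save(df, name, index=indexed)
        combined[name] = json.loads(
            df.to_json(orient="table" if indexed else "records")
        )
    p = outdir / "report.json"
    p.write_text(json.dumps(combined, indent=2, sort_keys=True) + "\n")
    written.append(p)
    p = outdir / "manifest.json"
    p.write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written


def run_synthetic(
    gen_config,
    workdir: str | Path,
    noise: float | None = None,
    use_fallback_topology: bool = False,
    **thresholds,
):
    """Generate a synthetic dataset under ``workdir`` and run the full
    pipeline on it.  Returns (result, truth table).

    ``noise`` overrides the generator config's noise level for the emitted
    annotation bundle; with ``use_fallback_topology`` the topology files are
    withheld so the built-in hydropathy predictor is exercised.
    """
    from .simulate import emit_mock_annotations, generate_transcriptome

    workdir = Path(workdir)
    transcripts, truth = generate_transcriptome(gen_config)
    p = noise if noise is not None else gen_config.noise
    bundles = emit_mock_annotations(
        truth, transcripts, workdir, noise=p, seed=gen_config.seed + 1
    )
    strains = []
    for name, paths in bundles.items():
        topo = (
            []
            if use_fallback_topology
            else [
                (paths["tmhmm"], "tmhmm-short"),
                (paths["signalp"], "signalp-short"),
                (paths["phobius"], "phobius-short"),
            ]
        )
        strains.append(
            StrainInput(
                name=name,
                fasta=paths["fasta"],
                topology_files=topo,
                alignment=paths["tcdb"],
                domains=paths["domains"],
            )
        )
    config = RunConfig(strains=strains, seed=gen_config.seed, **thresholds)
    return run_pipeline(config), truth
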