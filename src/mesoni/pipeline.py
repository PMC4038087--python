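"""End-to-end orchestration: annotate genomes, demarcate species.

``annotate_genome`` runs poly-A trimming, ORF discovery, canonical-plan
assignment, slippery/TRS scanning, -1 PRF conceptual translation, cleavage
and protein-feature computation, and (against an optional reference)
ORF1a block-insertion detection, producing a JSON-serializable report and
GFF3.  Per-genome failures are isolated: one bad record does not abort the
run.  ``demarcate_set`` chains annotation, replicase-domain extraction, ML
pairwise distances and threshold clustering into a species partition.

Every report embeds the resolved configuration hash, and all coordinates
refer to the poly-A-trimmed genome.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

from . import __version__
from .config import PipelineConfig
from .demarcation import (
    DistanceMatrix,
    DomainSet,
    SpeciesPartition,
    cluster_species,
    distance_matrix,
    extract_domains,
    load_reference_domains,
    parse_reference_fasta,
)
from .errors import FrameshiftError, MesoniError
from .genome_io import Feature, GenomeRecord, read_fasta, trim_polya, write_gff3
from .motifs import (
    TRS_PATTERNS,
    find_cleavage_sites,
    find_slippery,
    protein_features,
    scan_motif,
)
from .orf_architecture import Architecture, FusionProduct, assign_architecture, translate_prf
from .pairwise import InsertionBlock, detect_insertions

log = logging.getLogger("mesoni")


@dataclass
class AnnotationReport:
    """Per-genome annotation results (all coordinates poly-A-trimmed)."""

    genome_id: str
    genome_length: int
    polya_len: int
    architecture: Architecture
    trs_hits: list  # [(pattern_id, start, matched_text, "leader"|"body")]
    pp1ab: FusionProduct | None
    p3ab: FusionProduct | None
    warnings: list[str]
    cleavage_sites: list
    n_protein: dict
    insertions: list[InsertionBlock] = field(default_factory=list)
    config_hash: str = ""
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "genome_length": self.genome_length,
            "polya_len": self.polya_len,
            "architecture": self.architecture.to_dict(),
            "trs_hits": [list(h) for h in self.trs_hits],
            "pp1ab": _fusion_dict(self.pp1ab),
            "p3ab": _fusion_dict(self.p3ab),
            "cleavage_sites": [
                {"kind": s.kind, "cut_after": s.cut_after, "context": s.context}
                for s in self.cleavage_sites
            ],
            "n_protein": self.n_protein,
            "insertions": [
                {
                    "query_span": list(b.query_span),
                    "length_nt": b.length_nt,
                    "length_aa": b.length_aa,
                    "repeats": [
                        {"position": r.position, "mismatches": r.mismatches}
                        for r in b.repeats
                    ],
                }
                for b in self.insertions
            ],
            "warnings": self.warnings,
            "config_hash": self.config_hash,
            "version": self.version,
        }

    def features(self) -> list[Feature]:
        feats = self.architecture.features()
        for pid, start, text, role in self.trs_hits:
            feats.append(
                Feature(
                    seqid=self.genome_id,
                    name=f"{pid}_{role}_{start}",
                    start=start,
                    end=start + len(text),
                    ftype="sequence_motif",
                    attributes={"pattern": pid, "role": role},
                )
            )
        for b in self.insertions:
            feats.append(
                Feature(
                    seqid=self.genome_id,
                    name=f"insertion_{b.query_span[0]}",
                    start=b.query_span[0],
                    end=b.query_span[1],
                    ftype="insertion",
                    attributes={"length_nt": str(b.length_nt)},
                )
            )
        return feats


def _fusion_dict(f: FusionProduct | None) -> dict | None:
    if f is None:
        return None
    return {
        "name": f.name,
        "join_pos": f.join_pos,
        "slippery_motif": f.slippery_motif,
        "protein_length": len(f.protein),
        "protein": f.protein,
    }


def annotate_record(
    rec: GenomeRecord,
    config: PipelineConfig | None = None,
    reference: GenomeRecord | None = None,
) -> AnnotationReport:
    """Annotate one genome record (already read, not yet trimmed)."""
    cfg = config or PipelineConfig()
    warnings: list[str] = []
    rec = trim_polya(rec, cfg.polya_min_run)
    arch = assign_architecture(rec, params=cfg.arch_params())

    slips: list[tuple[str, int]] = []
    ov1 = arch.overlap_1a1b()
    for pos in find_slippery(rec, ov1, "GGATTTT"):
        slips.append(("GGATTTT", pos))
    ov3 = arch.overlap_3a3b()
    for pos in find_slippery(rec, ov3, "CACTTTT"):
        slips.append(("CACTTTT", pos))
    arch.slippery_sites = slips

    pp1ab = p3ab = None
    g_sites = [p for m, p in slips if m == "GGATTTT"]
    if not g_sites:
        warnings.append("no GGATTTT slippery heptamer in the ORF1a/1b overlap")
    else:
        try:
            pp1ab = translate_prf(rec, arch.orf1a, arch.orf1b, g_sites[0], name="pp1ab")
        except FrameshiftError as exc:
            warnings.append(f"pp1ab: {exc}")
    c_sites = [p for m, p in slips if m == "CACTTTT"]
    if c_sites:
        try:
            p3ab = translate_prf(rec, arch.orf3a, arch.orf3b, c_sites[0], name="p3ab")
        except FrameshiftError as exc:
            warnings.append(f"p3ab: {exc}")

    utr5_end = arch.utr5[1]
    trs_hits = []
    for pid, pattern in TRS_PATTERNS.items():
        for h in scan_motif(rec.seq, pattern, pid):
            role = "leader" if h.end <= utr5_end else "body"
            trs_hits.append((pid, h.start, h.matched_text, role))
    trs_hits.sort(key=lambda t: t[1])

    cleavage = find_cleavage_sites(arch.orf2a.protein)
    npf = protein_features(arch.orf2b.protein)
    n_protein = {
        "length_aa": npf.length_aa,
        "mw_kda": round(npf.mw_kda, 2),
        "pi": round(npf.pi, 2),
        "n_cys": len(npf.cys_positions),
        "n_sequons": len(npf.sequons),
    }

    insertions: list[InsertionBlock] = []
    if reference is not None:
        ref = trim_polya(reference, cfg.polya_min_run)
        ref_arch = assign_architecture(ref, params=cfg.arch_params())
        span = (arch.orf1a.start, min(arch.orf1a.end, arch.orf1a.start + cfg.insertion_scan_nt))
        ref_span = (
            ref_arch.orf1a.start,
            min(ref_arch.orf1a.end, ref_arch.orf1a.start + cfg.insertion_scan_nt),
        )
        insertions = detect_insertions(
            rec,
            ref,
            region=span,
            ref_region=ref_span,
            params=cfg.align_params(),
            min_block=cfg.insertion_min_block,
            min_identity=cfg.insertion_min_identity,
            band=None if cfg.exact else cfg.band,
            frame_start=arch.orf1a.start,
            repeat_seed=cfg.repeat_seed,
            repeat_max_mismatch=cfg.repeat_max_mismatch,
        )

    return AnnotationReport(
        genome_id=rec.id,
        genome_length=len(rec.seq),
        polya_len=rec.polya_len,
        architecture=arch,
        trs_hits=trs_hits,
        pp1ab=pp1ab,
        p3ab=p3ab,
        warnings=warnings,
        cleavage_sites=cleavage,
        n_protein=n_protein,
        insertions=insertions,
        config_hash=cfg.hash,
    )


@dataclass
class AnnotationRun:
    reports: list[AnnotationReport]
    failures: dict[str, str]  # genome id -> error message

    @property
    def all_failed(self) -> bool:
        return not self.reports


def annotate_genome(
    fasta,
    config: PipelineConfig | None = None,
    reference_fasta=None,
    out_dir=None,
) -> AnnotationRun:
    """Annotate every genome in a FASTA file; write JSON + GFF3 if asked."""
    cfg = config or PipelineConfig()
    records = read_fasta(fasta, allow_ambiguous=cfg.allow_ambiguous)
    reference = None
    if reference_fasta is not None:
        reference = read_fasta(reference_fasta, allow_ambiguous=cfg.allow_ambiguous)[0]
    reports, failures = [], {}
    for rec in records:
        t0 = time.perf_counter()
        try:
            reports.append(annotate_record(rec, cfg, reference))
            log.info("annotated %s in %.2fs", rec.id, time.perf_counter() - t0)
        except MesoniError as exc:
            failures[rec.id] = str(exc)
            log.warning("failed %s: %s", rec.id, exc)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        payload = {
            "config": cfg.to_dict(),
            "config_hash": cfg.hash,
            "reports": [r.to_dict() for r in reports],
            "failures": failures,
        }
        with open(os.path.join(out_dir, "annotation.json"), "w") as fh:
            json.dump(payload, fh, indent=1, default=list, sort_keys=True)
        for r in reports:
            write_gff3(r.features(), os.path.join(out_dir, f"{r.genome_id}.gff3"))
    return AnnotationRun(reports=reports, failures=failures)


def demarcate_records(
    records: list[GenomeRecord],
    config: PipelineConfig | None = None,
) -> tuple[DistanceMatrix, SpeciesPartition, list[str]]:
    """Annotation -> pp1ab -> domain extraction -> PED matrix -> clustering."""
    cfg = config or PipelineConfig()
    if cfg.reference_domains:
        with open(cfg.reference_domains) as fh:
            refset = parse_reference_fasta(fh.read())
    else:
        refset = load_reference_domains()
    warnings: list[str] = []
    sets: list[DomainSet] = []
    for rec in records:
        try:
            report = annotate_record(rec, cfg)
            if report.pp1ab is None:
                raise MesoniError("; ".join(report.warnings) or "no pp1ab")
            sets.append(
                extract_domains(report.pp1ab.protein, refset, taxon=rec.id)
            )
        except MesoniError as exc:
            warnings.append(f"{rec.id} excluded: {exc}")
    if len(sets) < 2:
        raise MesoniError("fewer than 2 genomes with extractable domains")
    m = distance_matrix(sets, model=cfg.model)
    part = cluster_species(m, t=cfg.species_threshold, linkage=cfg.linkage)
    return m, part, warnings


def demarcate_set(
    fastas: list,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> tuple[DistanceMatrix, SpeciesPartition, list[str]]:
    """File-level wrapper over :func:`demarcate_records`; writes TSV outputs."""
    cfg = config or PipelineConfig()
    records: list[GenomeRecord] = []
    for path in fastas:
        records.extend(read_fasta(path, allow_ambiguous=cfg.allow_ambiguous))
    m, part, warnings = demarcate_records(records, cfg)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        m.to_tsv(os.path.join(out_dir, "distances.tsv"))
        part.to_tsv(os.path.join(out_dir, "species.tsv"))
        meta = {
            "config": cfg.to_dict(),
            "config_hash": cfg.hash,
            "model": cfg.model + ("" if cfg.gamma_shape is None else "+G4"),
            "threshold": cfg.species_threshold,
            "linkage": cfg.linkage,
            "warnings": warnings,
        }
        with open(os.path.join(out_dir, "demarcation.json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True, default=list)
    return m, part, warnings
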