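"""End-to-end orchestration: simulate -> catalog -> peaks -> structure ->
WGS (SNPs, density, introgressions, TEIs) -> report.

Each stage is a plain function over files so it can run standalone (the
CLI exposes one subcommand per stage); :func:`run_all` chains them with a
single config, structured logging, and a JSON + markdown summary that
scores recovery against the simulation truth when ``truth.json`` exists.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from . import align, catalog, peaks, simulate, structure, wgs
from .seq import read_fasta, read_fastq, write_fasta, write_fastq

log = logging.getLogger("mobilome")


@dataclass
class RunConfig:
    """Effective configuration of a full pipeline run."""

    outdir: str = "mobilome_out"
    seed: int = 1
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    # ecc peaks
    min_overlap: int = 100
    min_reads: int = 10
    alpha: float = 0.01
    correction: str = "bh"
    # structure
    max_reads_per_element: int = 60
    identity_floor: float = 96.0
    min_margin: float = 1.0
    # wgs
    snp_min_depth: int = 5
    snp_min_af: float = 0.7
    window_size: int = 100_000
    fold_threshold: float = 5.0
    min_windows: int = 3
    max_gap: int = 1
    min_insert: int = 500
    min_support: int = 3
    cluster_radius: int = 50

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        sim_doc = doc.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(simulate.SimConfig)}
        unknown = set(sim_doc) - sim_known
        if unknown:
            raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
        for key in ("chrom_lengths", "ltr_len", "internal_len",
                    "planted_orf_lengths", "error_rates", "introgression"):
            if key in sim_doc and sim_doc[key] is not None:
                sim_doc[key] = tuple(sim_doc[key])
        cfg = cls(**doc, sim=simulate.SimConfig(**sim_doc))
        return cfg

    def echo(self, outdir: Path) -> None:
        doc = dataclasses.asdict(self)
        with open(outdir / "effective_config.json", "w") as fh:
            json.dump(doc, fh, indent=1, default=str)
        log.info("effective config: %s", json.dumps(doc, default=str))


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logging(outdir: Path, verbosity: int = 1) -> None:
    level = logging.DEBUG if verbosity > 1 else logging.INFO
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=[logging.StreamHandler(),
                  logging.FileHandler(outdir / "run.log")],
        force=True)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    t0 = time.time()
    genome, elements, truth = simulate.simulate_reference(cfg.sim)
    write_fasta(outdir / "genome.fa", genome.items())
    catalog.write_te_bed(elements, outdir / "te_annotation.bed")
    for cond in ("treatment", "control"):
        reads = simulate.simulate_eccdna_reads(cfg.sim, truth, cond)
        write_fastq(outdir / f"ecc_{cond}.fastq", reads.items())
    wgs_reads = simulate.simulate_wgs_reads(cfg.sim, truth, genome)
    write_fastq(outdir / "wgs.fastq", wgs_reads.items())
    panel = simulate.simulate_panel(truth, cfg.sim)
    (outdir / "panel").mkdir(exist_ok=True)
    for name, g in panel.items():
        write_fasta(outdir / "panel" / f"{name}.fa", g.items())
    truth.to_json(outdir / "truth.json")
    with open(outdir / "element_seqs.fa", "w") as fh:
        for eid, seq in truth.element_seqs.items():
            fh.write(f">{eid}\n{seq}\n")
    log.info("simulate: %d elements, inputs written (%.1fs)",
             len(elements), time.time() - t0)


def stage_catalog(genome_fa, out_bed, out_tsv, out_nwk=None,
                  min_ltr_len: int = 100, max_element_len: int = 15000,
                  min_identity: float = 85.0,
                  linkage_threshold: float = 80.0) -> List[catalog.TEElement]:
    genome = read_fasta(genome_fa)
    elements = catalog.detect_ltr_pairs(genome, min_ltr_len=min_ltr_len,
                                        max_element_len=max_element_len,
                                        min_identity=min_identity)
    catalog.cluster_families(elements, genome,
                             linkage_threshold=linkage_threshold)
    catalog.write_te_bed(elements, out_bed)
    catalog.write_families_tsv(elements, genome, out_tsv)
    if out_nwk and len(elements) >= 3:
        with open(out_nwk, "w") as fh:
            fh.write(catalog.nj_tree_newick(elements, genome) + "\n")
    log.info("te-catalog: %d elements in %d families", len(elements),
             len({e.family for e in elements}))
    return elements


def map_library(reads: Mapping[str, str], index: align.ReferenceIndex,
                params: Optional[align.AlignerParams] = None
                ) -> Dict[str, List[align.AlignmentRecord]]:
    params = params or align.AlignerParams()
    return {rid: align.map_long_read(seq, index, params, query_id=rid)
            for rid, seq in reads.items()}


def stage_ecc_peaks(treat_fq, ctrl_fq, genome_fa, annotation_bed, out_tsv,
                    cfg: Optional[RunConfig] = None,
                    paf_dir: Optional[Path] = None) -> List[peaks.PeakRecord]:
    cfg = cfg or RunConfig()
    genome = read_fasta(genome_fa)
    annotation = catalog.read_te_bed(annotation_bed)
    index = align.ReferenceIndex(genome)
    counts = {}
    totals = {}
    for cond, path in (("treatment", treat_fq), ("control", ctrl_fq)):
        reads = read_fastq(path)
        if not reads:
            raise ValueError(f"empty library: {path}")
        totals[cond] = len(reads)
        recs = map_library(reads, index)
        flat = [r for rs in recs.values() for r in rs]
        if paf_dir is not None:
            align.write_paf(flat, Path(paf_dir) / f"ecc_{cond}.paf")
        counts[cond], unassigned = peaks.count_reads_per_element(
            flat, annotation, min_overlap=cfg.min_overlap)
        log.info("ecc-peaks %s: %d reads, %d unassigned", cond,
                 totals[cond], unassigned)
    records = peaks.call_differential(
        counts["treatment"], counts["control"],
        (totals["treatment"], totals["control"]),
        min_reads=cfg.min_reads, alpha=cfg.alpha, correction=cfg.correction)
    peaks.write_peaks_tsv(records, out_tsv)
    n_sig = sum(1 for r in records if r.status == "significant")
    log.info("ecc-peaks: %d/%d elements significant", n_sig, len(records))
    return records


def stage_ecc_structure(treat_fq, genome_fa, annotation_bed, element_fa,
                        panel_dir, outdir: Path,
                        element_ids: Sequence[str],
                        cfg: Optional[RunConfig] = None) -> dict:
    """Structure, divergence and origin for the given (active) elements."""
    cfg = cfg or RunConfig()
    genome = read_fasta(genome_fa)
    annotation = {e.id: e for e in catalog.read_te_bed(annotation_bed)}
    elem_seqs = read_fasta(element_fa)
    index = align.ReferenceIndex(genome)
    reads = read_fastq(treat_fq)
    recs = map_library(reads, index)
    # assign reads to elements by primary alignment overlap
    flat = [r for rs in recs.values() for r in rs]
    assignment: Dict[str, List[str]] = {eid: [] for eid in element_ids}
    counts, _ = peaks.count_reads_per_element(
        flat, list(annotation.values()), min_overlap=cfg.min_overlap)
    by_read = {}
    for r in flat:
        if r.is_primary:
            by_read[r.query_id] = r
    for rid, rec in by_read.items():
        best, best_ov = None, 0
        for eid in element_ids:
            e = annotation[eid]
            if e.chrom != rec.target_id:
                continue
            ov = min(rec.target_end, e.end) - max(rec.target_start, e.start)
            if ov > best_ov:
                best, best_ov = eid, ov
        if best is not None and best_ov >= cfg.min_overlap:
            assignment[best].append(rid)

    panel = {}
    if panel_dir is not None:
        for p in sorted(Path(panel_dir).glob("*.fa")):
            panel[p.stem] = read_fasta(p)

    calls: List[structure.EccStructureCall] = []
    decomps_by_read: Dict[str, structure.MonomerDecomposition] = {}
    div_rows = []
    origin_rows = []
    for eid in element_ids:
        elem = annotation[eid]
        eseq = elem_seqs[eid]
        decomps = []
        for rid in assignment[eid][:cfg.max_reads_per_element]:
            d = structure.decompose_concatemer(reads[rid], eseq, read_id=rid,
                                               element_id=eid)
            if d.empty:
                continue
            decomps.append(d)
            decomps_by_read[rid] = d
            # only concatemer reads (>=1 full monomer) carry reliable
            # structure; a lone partial monomer of a long circle would
            # masquerade as truncated
            if d.n_full_monomers >= 1:
                calls.append(structure.classify_structure(d, elem))
        if not decomps:
            continue
        rep = structure.consensus_divergence(decomps, elem, eseq,
                                             min_depth=cfg.snp_min_depth)
        div_rows.append(rep)
        # origin of the consensus LTR
        if panel:
            ltr = _consensus_ltr(decomps, elem, eseq)
            if ltr:
                oc = structure.assign_origin(
                    ltr, panel, identity_floor=cfg.identity_floor,
                    min_margin=cfg.min_margin, query_id=f"{eid}_LTR")
                origin_rows.append(oc)
    structure.write_structures_tsv(calls, decomps_by_read,
                                   outdir / "structures.tsv")
    with open(outdir / "divergence.tsv", "w") as fh:
        fh.write("element_id\tsnp_count\tltr_covered\tltr_deletion\t"
                 "mean_depth\n")
        for r in div_rows:
            dele = f"{r.ltr_deletion[0]}-{r.ltr_deletion[1]}" \
                if r.ltr_deletion else "."
            fh.write(f"{r.element_id}\t{r.snp_count}\t{r.ltr_covered}\t"
                     f"{dele}\t{r.mean_depth:.1f}\n")
    with open(outdir / "origin.tsv", "w") as fh:
        fh.write("query\tassigned\tmargin\t" "per_genome\n")
        for oc in origin_rows:
            per = ";".join(f"{g}:{v[0]:.2f}" for g, v in
                           sorted(oc.per_genome.items()))
            fh.write(f"{oc.query_id}\t{oc.assigned}\t{oc.margin:.2f}\t"
                     f"{per}\n")
    log.info("ecc-structure: %d reads classified, %d elements profiled",
             len(calls), len(div_rows))
    return {"calls": calls, "divergence": div_rows, "origin": origin_rows}


def _consensus_ltr(decomps: Sequence[structure.MonomerDecomposition],
                   elem: catalog.TEElement, eseq: str) -> str:
    """Majority-vote LTR sequence from the eccDNA pileup on the element."""
    from .seq import encode_seq

    n = len(eseq)
    counts = np.zeros((4, n), dtype=np.int32)
    for d in decomps:
        rcodes = encode_seq(d.read)
        for rec in d.records:
            qpos, tpos = structure._aligned_columns(rec)
            bases = rcodes[tpos]
            ok = bases < 4
            np.add.at(counts, (bases[ok], qpos[ok]), 1)
    depth = counts.sum(axis=0)
    best = counts.argmax(axis=0)
    s, e = elem.ltr5 if elem.ltr5 else (0, 0)
    if depth[s:e].mean() < 1:
        s, e = elem.ltr3 if elem.ltr3 else (0, 0)
    if e <= s or depth[s:e].mean() < 1:
        return ""
    out = []
    ref_codes = encode_seq(eseq)
    for i in range(s, e):
        out.append("ACGT"[best[i]] if depth[i] > 0 else "ACGT"[ref_codes[i]])
    return "".join(out)


def stage_wgs(wgs_fq, genome_fa, te_library_fa, outdir: Path,
              cfg: Optional[RunConfig] = None) -> dict:
    cfg = cfg or RunConfig()
    genome = read_fasta(genome_fa)
    library = read_fasta(te_library_fa) if te_library_fa else {}
    reads = read_fastq(wgs_fq)
    index = align.ReferenceIndex(genome)
    aln_by_read = map_library(reads, index)
    flat = [r for rs in aln_by_read.values() for r in rs]
    variants = wgs.call_snps_naive(flat, reads, genome,
                                   min_depth=cfg.snp_min_depth,
                                   min_af=cfg.snp_min_af)
    contigs = {c: len(s) for c, s in genome.items()}
    wgs.write_vcf(variants, contigs, outdir / "snps.vcf")
    tracks = wgs.snp_density_windows(variants, contigs,
                                     window_size=cfg.window_size)
    wgs.write_density_tsv(tracks, outdir / "density.tsv")
    segments = []
    for t in tracks.values():
        segments.extend(wgs.segment_introgressions(
            t, fold_threshold=cfg.fold_threshold,
            min_windows=cfg.min_windows, max_gap=cfg.max_gap))
    wgs.write_introgressions_bed(segments, outdir / "introgressions.bed")
    teis = wgs.call_teis(aln_by_read, reads, library, genome,
                         min_insert=cfg.min_insert,
                         min_support=cfg.min_support,
                         cluster_radius=cfg.cluster_radius)
    wgs.write_teis_tsv(teis, outdir / "teis.tsv")
    log.info("wgs: %d SNPs, %d introgression segments, %d TEIs",
             len(variants), len(segments), len(teis))
    return {"variants": variants, "segments": segments, "teis": teis}


# ---------------------------------------------------------------------------
# run-all + report


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage on a synthetic scenario and write the report.

    Any stage failure aborts the run with the failing stage named; outputs
    written so far are kept alongside a ``.partial`` marker.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    cfg.echo(outdir)
    marker = outdir / ".partial"
    marker.touch()
    stage = "simulate"
    try:
        stage_simulate(cfg, outdir)
        for f in ("genome.fa", "te_annotation.bed", "ecc_treatment.fastq"):
            log.info("input %s md5=%s", f, _md5(outdir / f))
        stage = "te-catalog"
        stage_catalog(outdir / "genome.fa", outdir / "catalog.bed",
                      outdir / "families.tsv", outdir / "families.nwk")
        stage = "ecc-peaks"
        peak_records = stage_ecc_peaks(
            outdir / "ecc_treatment.fastq", outdir / "ecc_control.fastq",
            outdir / "genome.fa", outdir / "te_annotation.bed",
            outdir / "peaks.tsv", cfg, paf_dir=outdir)
        significant = [r.element_id for r in peak_records
                       if r.status == "significant"]
        stage = "ecc-structure"
        structure_out = stage_ecc_structure(
            outdir / "ecc_treatment.fastq", outdir / "genome.fa",
            outdir / "te_annotation.bed", outdir / "element_seqs.fa",
            outdir / "panel", outdir, significant, cfg)
        stage = "wgs"
        wgs_out = stage_wgs(outdir / "wgs.fastq", outdir / "genome.fa",
                            outdir / "element_seqs.fa", outdir, cfg)
        stage = "report"
        report = build_report(cfg, outdir, peak_records, structure_out,
                              wgs_out)
    except Exception:
        log.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}")
    marker.unlink(missing_ok=True)
    return report


def build_report(cfg: RunConfig, outdir: Path,
                 peak_records: Sequence[peaks.PeakRecord],
                 structure_out: dict, wgs_out: dict) -> dict:
    significant = sorted(r.element_id for r in peak_records
                         if r.status == "significant")
    class_tally: Dict[str, int] = {}
    for c in structure_out["calls"]:
        class_tally[c.structure_class] = \
            class_tally.get(c.structure_class, 0) + 1
    report = {
        "significant_elements": significant,
        "n_tested_elements": len(peak_records),
        "structure_class_tally": class_tally,
        "origin_calls": {o.query_id: o.assigned
                         for o in structure_out["origin"]},
        "introgression_segments": [
            dataclasses.asdict(s) for s in wgs_out["segments"]],
        "n_snps": len(wgs_out["variants"]),
        "teis": [dataclasses.asdict(t) for t in wgs_out["teis"]],
    }
    truth_path = outdir / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
        active = sorted(truth["active_elements"])
        report["recovery"] = {
            "true_active": active,
            "active_recovered": sorted(set(significant) & set(active)),
            "false_positives": sorted(set(significant) - set(active)),
            "tei_truth_positions": [i["position"]
                                    for i in truth["insertion_sites"]],
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    lines = ["# Mobilome pipeline report", "",
             f"Significant (active) elements: {', '.join(significant) or 'none'}",
             "", "## Structure classes", ""]
    for k in sorted(class_tally):
        lines.append(f"- {k}: {class_tally[k]}")
    lines += ["", "## Origin calls", ""]
    for q, a in sorted(report["origin_calls"].items()):
        lines.append(f"- {q}: {a}")
    lines += ["", f"## Introgressions: {len(wgs_out['segments'])}",
              f"## TEIs: {len(wgs_out['teis'])}", ""]
    (outdir / "report.md").write_text("\n".join(lines))
    return report
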