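"""Whole-genome long-read analysis: SNP pileup, windowed SNP density,
introgression segmentation, and non-reference TE insertion (TEI) calling.

An interspecific introgression appears as a long run of 1 Mb windows
whose SNP density is several-fold above the genome median.  A TEI shows
up as reads whose alignment splits around a breakpoint with a long
unaligned middle that re-aligns to a TE library element; the short
overlap of the two flanking alignments on the reference is the
target-site duplication (TSD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .align import AlignerParams, AlignmentRecord, ReferenceIndex, map_long_read
from .seq import encode_seq, revcomp_codes
from .structure import _expand_cigar


@dataclass
class Variant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    depth: int
    af: float


@dataclass
class SnpDensityTrack:
    chrom: str
    window_size: int
    counts: np.ndarray      # per-window SNP counts
    density: np.ndarray     # per-window SNPs per Mb (partial window scaled)
    genome_median: float = 0.0


@dataclass
class IntrogressionSegment:
    chrom: str
    start: int  # window-aligned, 0-based half-open
    end: int
    mean_fold: float
    n_windows: int


@dataclass
class InsertionCall:
    chrom: str
    position: int  # 0-based reference base immediately left of the insertion
    support: int
    inserted_len: int
    family: str = "unassigned"
    family_identity: float = 0.0
    tsd: Optional[str] = None


# ---------------------------------------------------------------------------
# naive pileup SNP caller


def call_snps_naive(alignments: Iterable[AlignmentRecord],
                    reads: Mapping[str, str],
                    reference: Mapping[str, str],
                    min_depth: int = 5, min_af: float = 0.7) -> List[Variant]:
    """Per-column pileup SNP calling for haploid-style long-read data.

    A SNP is emitted where the non-reference allele fraction reaches
    ``min_af`` at depth >= ``min_depth`` (defaults suit a haploid donor
    sequenced at moderate depth with noisy reads).
    """
    counts: Dict[str, np.ndarray] = {}
    for chrom, seq in reference.items():
        counts[chrom] = np.zeros((4, len(seq)), dtype=np.int32)
    for rec in alignments:
        if not rec.is_primary:
            continue
        if rec.target_id not in counts:
            raise ValueError(f"alignment chromosome {rec.target_id!r} "
                             "not in reference")
        read = reads[rec.query_id]
        codes = encode_seq(read)
        if rec.strand == "-":
            codes = revcomp_codes(codes)
            q0 = len(read) - rec.query_end
        else:
            q0 = rec.query_start
        ops = _expand_cigar(rec.cigar)
        qstep = (ops == _kernels.OP_EQ) | (ops == _kernels.OP_X) | \
            (ops == _kernels.OP_I)
        tstep = (ops == _kernels.OP_EQ) | (ops == _kernels.OP_X) | \
            (ops == _kernels.OP_D)
        qpos = q0 + np.cumsum(qstep) - qstep
        tpos = rec.target_start + np.cumsum(tstep) - tstep
        aligned = (ops == _kernels.OP_EQ) | (ops == _kernels.OP_X)
        bases = codes[qpos[aligned]]
        ok = bases < 4
        np.add.at(counts[rec.target_id], (bases[ok], tpos[aligned][ok]), 1)

    out: List[Variant] = []
    for chrom, seq in reference.items():
        c = counts[chrom]
        depth = c.sum(axis=0)
        enough = depth >= min_depth
        if not enough.any():
            continue
        ref_codes = encode_seq(seq)
        top = c.argmax(axis=0).astype(np.uint8)
        topn = c.max(axis=0)
        af = np.where(depth > 0, topn / np.maximum(depth, 1), 0.0)
        mask = enough & (af >= min_af) & (top != ref_codes)
        for p in np.nonzero(mask)[0]:
            out.append(Variant(chrom, int(p), seq[p], "ACGT"[top[p]],
                               int(depth[p]), float(af[p])))
    return out


def write_vcf(variants: Sequence[Variant],
              contigs: Mapping[str, int], path) -> None:
    """Minimal VCFv4.2 (CHROM POS ID REF ALT QUAL FILTER INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mobilome\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description='
                 '"Allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                     f"DP={v.depth};AF={v.af:.3f}\n")


def read_vcf(path) -> List[Variant]:
    """Read a VCF (minimal subset; external caller output accepted)."""
    import pysam

    out: List[Variant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else "."
            dp = int(rec.info.get("DP", 0))
            af = rec.info.get("AF", 0.0)
            if isinstance(af, tuple):
                af = af[0] if af else 0.0
            out.append(Variant(rec.chrom, rec.pos - 1, rec.ref, alt, dp,
                               float(af)))
    return out


# ---------------------------------------------------------------------------
# SNP density and introgression segmentation


def snp_density_windows(variants: Sequence[object],
                        chrom_lengths: Mapping[str, int],
                        window_size: int = 1_000_000
                        ) -> Dict[str, SnpDensityTrack]:
    """Tile each chromosome with fixed windows and count SNPs per window.

    Density is SNPs/Mb; the last partial window is scaled by its true
    width.  ``genome_median`` (shared by all tracks) is the median density
    over all full windows genome-wide.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    positions: Dict[str, List[int]] = {c: [] for c in chrom_lengths}
    for v in variants:
        chrom, pos = (v.chrom, v.pos) if hasattr(v, "chrom") else (v[0], v[1])
        if chrom not in chrom_lengths:
            raise ValueError(f"variant on unknown chromosome {chrom!r}")
        if pos >= chrom_lengths[chrom]:
            raise ValueError(f"variant at {chrom}:{pos} beyond chromosome end")
        positions[chrom].append(pos)

    tracks: Dict[str, SnpDensityTrack] = {}
    full_densities: List[np.ndarray] = []
    for chrom, L in chrom_lengths.items():
        n_win = -(-L // window_size)
        counts = np.zeros(n_win, dtype=np.int64)
        if positions[chrom]:
            idx = np.asarray(positions[chrom]) // window_size
            np.add.at(counts, idx, 1)
        widths = np.full(n_win, window_size, dtype=np.float64)
        if L % window_size:
            widths[-1] = L % window_size
        density = counts * (1e6 / widths)
        tracks[chrom] = SnpDensityTrack(chrom, window_size, counts, density)
        n_full = n_win - (1 if L % window_size else 0)
        if n_full > 0:
            full_densities.append(density[:n_full])
    med = float(np.median(np.concatenate(full_densities))) \
        if full_densities else 0.0
    for t in tracks.values():
        t.genome_median = med
    return tracks


def segment_introgressions(track: SnpDensityTrack,
                           fold_threshold: float = 5.0,
                           min_windows: int = 3, max_gap: int = 1,
                           abs_threshold: float = 50.0
                           ) -> List[IntrogressionSegment]:
    """Maximal runs of windows with density >= fold_threshold x median.

    Up to ``max_gap`` consecutive sub-threshold windows are tolerated
    inside a run; runs shorter than ``min_windows`` are dropped.  When the
    genome median is 0 the ``abs_threshold`` (SNPs/Mb) is used instead,
    with a warning.
    """
    med = track.genome_median
    if med <= 0:
        warnings.warn("genome median density is 0; using absolute threshold",
                      stacklevel=2)
        cutoff = abs_threshold
        med = 0.0
    else:
        cutoff = fold_threshold * med
    above = track.density >= cutoff
    segs: List[IntrogressionSegment] = []
    n = len(above)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        last_above = i
        gap = 0
        while j + 1 < n:
            if above[j + 1]:
                j += 1
                last_above = j
                gap = 0
            elif gap < max_gap:
                j += 1
                gap += 1
            else:
                break
        j = last_above
        n_win = j - i + 1
        if n_win >= min_windows:
            w = track.window_size
            dens = track.density[i:j + 1]
            mean_fold = float(dens.mean() / med) if med > 0 else float("inf")
            segs.append(IntrogressionSegment(
                track.chrom, i * w, (j + 1) * w, mean_fold, n_win))
        i = j + 1
    return segs


def write_density_tsv(tracks: Mapping[str, SnpDensityTrack], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\twin_start\twin_end\tcount\tdensity\n")
        for chrom, t in tracks.items():
            for i, (c, d) in enumerate(zip(t.counts, t.density)):
                fh.write(f"{chrom}\t{i * t.window_size}\t"
                         f"{(i + 1) * t.window_size}\t{c}\t{d:.2f}\n")


def write_introgressions_bed(segments: Sequence[IntrogressionSegment],
                             path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t"
                     f"fold={s.mean_fold:.1f};windows={s.n_windows}\n")


# ---------------------------------------------------------------------------
# TE insertion calling


def _library_match(seq: str, library: Mapping[str, str],
                   params: AlignerParams,
                   min_cov: float = 0.8) -> Tuple[str, float, int]:
    """Best TE-library assignment of an inserted/clipped sequence.

    Returns (family, identity, offset) where ``offset`` is how far into
    the library element the sequence starts — i.e. how many element bases
    the flanking reference alignment absorbed through junction
    micro-homology.
    """
    if not library or len(seq) < params.min_aln_len:
        return "unassigned", 0.0, (0, 0)
    idx = ReferenceIndex(library, k=params.k, max_seed_occ=params.max_seed_occ)
    recs = map_long_read(seq, idx, params, query_id="insert")
    # orient the fragment to the element's forward strand so that query
    # offsets translate directly into element offsets
    if recs and next(r for r in recs if r.is_primary).strand == "-":
        from .seq import revcomp

        seq = revcomp(seq)
        recs = map_long_read(seq, idx, params, query_id="insert")
    best_name, best_ident, best_off = "unassigned", 0.0, (0, 0)
    cov: Dict[str, float] = {}
    for r in recs:
        cov[r.target_id] = cov.get(r.target_id, 0.0) + r.target_span()
    for r in recs:
        if not r.is_primary:
            continue
        # a clipped fragment can only ever cover part of the element, so
        # coverage is judged against the shorter of (element, query)
        need = min_cov * min(r.target_len, len(seq))
        if cov.get(r.target_id, 0) >= need and r.identity() >= 80.0:
            best_name, best_ident = r.target_id, r.identity()
            frags = [x for x in recs if x.target_id == r.target_id]
            first = min(frags, key=lambda x: x.query_start)
            last = max(frags, key=lambda x: x.query_end)
            best_off = (max(0, first.target_start - first.query_start),
                        max(0, (last.target_len - last.target_end)
                            - (len(seq) - last.query_end)))
    return best_name, best_ident, best_off


def call_teis(alignments_by_read: Mapping[str, Sequence[AlignmentRecord]],
              reads: Mapping[str, str],
              te_library: Mapping[str, str],
              reference: Mapping[str, str],
              min_insert: int = 500, min_support: int = 3,
              cluster_radius: int = 50,
              params: Optional[AlignerParams] = None) -> List[InsertionCall]:
    """Call non-reference TE insertions from split/gapped read alignments.

    Evidence per read: (a) an insertion cigar operation >= ``min_insert``;
    (b) two same-strand alignments whose read interval skips
    >= ``min_insert`` bases while the reference barely advances — the
    skipped bases must re-align to a TE library element.  Breakpoints are
    clustered within ``cluster_radius``; the reported position is the
    median, the TSD is the flank duplication implied by the overlap of
    the two reference intervals.
    """
    params = params or AlignerParams()
    evidence: List[tuple] = []
    # (chrom, pos, inserted_len, seq, tsd_len, kind, flank_left, flank_right)
    for rid, recs in alignments_by_read.items():
        read = reads[rid]
        # (a) insertion operations inside a single alignment
        for rec in recs:
            if not rec.is_primary:
                continue
            tp = rec.target_start
            qp = 0
            for op, ln in rec.cigar:
                if op == "I" and ln >= min_insert:
                    seq = _oriented_read_segment(read, rec, qp, qp + ln)
                    evidence.append((rec.target_id, tp, ln, seq, 0, "cigar",
                                     0, 0))
                if op in "M=XI":
                    qp += ln
                if op in "M=XD":
                    tp += ln
        # (b) split alignments around an unaligned middle that is a TE.
        # All same-chrom/strand pairs are considered (not just adjacent in
        # read order: the insert itself may align to its source locus and
        # sit between the two flank records).
        read_evi: List[tuple] = []
        by_key: Dict[Tuple[str, str], List[AlignmentRecord]] = {}
        for rec in recs:
            by_key.setdefault((rec.target_id, rec.strand), []).append(rec)
        for (chrom, strand), group in by_key.items():
            group = sorted(group, key=lambda r: r.query_start)
            for x in range(len(group)):
                for y in range(x + 1, len(group)):
                    a, b = group[x], group[y]
                    qgap = b.query_start - a.query_end
                    if qgap < min_insert:
                        continue
                    left, right = (a, b) if strand == "+" else (b, a)
                    tgap = right.target_start - left.target_end
                    if tgap > cluster_radius or tgap < -20:
                        continue
                    # junction segment oriented to the reference forward
                    # strand: ~60 bp left flank + insert + ~60 bp right.
                    # Segment ends are re-anchored by exact flank 30-mers
                    # (alignment endpoints can be a few bases off when the
                    # junction absorbs element bases with indels).
                    qlen = len(read)
                    if strand == "+":
                        rstar = read
                        le_idx, rs_idx = a.query_end, b.query_start
                    else:
                        from .seq import revcomp as _rc

                        rstar = _rc(read)
                        le_idx = qlen - b.query_start
                        rs_idx = qlen - a.query_end
                    ref_seq = reference[chrom]
                    lend = left.target_end
                    rstart = right.target_start
                    fl = min(60, le_idx)
                    fr = min(60, qlen - rs_idx)
                    lo = le_idx - fl
                    hi = rs_idx + fr
                    if fl == 60 and lend >= 60:
                        j = rstar.find(ref_seq[lend - 60:lend - 30],
                                       max(0, lo - 12), lo + 45)
                        if j >= 0:
                            lo = j
                    if fr == 60 and rstart + 60 <= len(ref_seq):
                        j = rstar.find(ref_seq[rstart + 30:rstart + 60],
                                       max(0, rs_idx + 18), rs_idx + 75)
                        if j >= 0:
                            hi = j + 30
                    seg = rstar[lo:hi]
                    ins_seq = seg[fl:len(seg) - fr] if fr else seg[fl:]
                    fam, _, _ = _library_match(ins_seq, te_library, params)
                    if fam == "unassigned" and te_library:
                        continue
                    read_evi.append((chrom, left.target_end, qgap, seg,
                                     max(0, -tgap), "span", fl, fr))
        # (c) clipped-tail evidence when no spanning pair was found: a read
        # end >= min_insert that re-aligns to the TE library votes for a
        # breakpoint at the adjacent alignment end.  The clip is stored
        # with 60 bp of adjacent aligned flank, oriented to the reference
        # forward strand, so the junction can still be fit exactly.
        if not read_evi and te_library:
            from .seq import revcomp as _rc

            for rec in recs:
                if not rec.is_primary:
                    continue
                qlen = len(read)
                rstar = read if rec.strand == "+" else _rc(read)
                if rec.strand == "+":
                    a0, a1 = rec.query_start, rec.query_end
                else:
                    a0, a1 = qlen - rec.query_end, qlen - rec.query_start
                # right clip of the oriented read = element side of the
                # LEFT junction flank; left clip = RIGHT junction flank
                ref_seq = reference[rec.target_id]
                for side, clip in (("clipL", qlen - a1), ("clipR", a0)):
                    if clip < min_insert:
                        continue
                    if side == "clipL":
                        fl = min(60, a1)
                        lo = a1 - fl
                        if fl == 60 and rec.target_end >= 60:
                            j = rstar.find(
                                ref_seq[rec.target_end - 60:
                                        rec.target_end - 30],
                                max(0, lo - 12), lo + 45)
                            if j >= 0:
                                lo = j
                        seg = rstar[lo:]
                        seq = rstar[a1:]
                        pos = rec.target_end
                        flanks = (fl, 0)
                    else:
                        fr = min(60, qlen - a0)
                        hi = a0 + fr
                        if fr == 60 and rec.target_start + 60 <= len(ref_seq):
                            j = rstar.find(
                                ref_seq[rec.target_start + 30:
                                        rec.target_start + 60],
                                max(0, a0 + 18), a0 + 75)
                            if j >= 0:
                                hi = j + 30
                        seg = rstar[:hi]
                        seq = rstar[:a0]
                        pos = rec.target_start
                        flanks = (0, fr)
                    fam, _, _ = _library_match(seq, te_library, params,
                                               min_cov=0.0)
                    if fam == "unassigned":
                        continue
                    read_evi.append((rec.target_id, pos, clip, seg, 0,
                                     side, flanks[0], flanks[1]))
        # one vote per read per junction
        seen_junctions: List[Tuple[str, int]] = []
        for ev in read_evi:
            if any(ev[0] == c and abs(ev[1] - p) <= cluster_radius
                   for c, p in seen_junctions):
                continue
            seen_junctions.append((ev[0], ev[1]))
            evidence.append(ev)

    # cluster by breakpoint
    evidence.sort(key=lambda e: (e[0], e[1]))
    calls: List[InsertionCall] = []
    i = 0
    while i < len(evidence):
        chrom = evidence[i][0]
        cluster = [evidence[i]]
        j = i + 1
        while j < len(evidence) and evidence[j][0] == chrom \
                and evidence[j][1] - cluster[-1][1] <= cluster_radius:
            cluster.append(evidence[j])
            j += 1
        i = j
        if len(cluster) < min_support:
            continue

        def _mode(values: List[int]) -> int:
            vals, cnts = np.unique(values, return_counts=True)
            return int(vals[np.argmax(cnts)])

        # spanning evidence nails the junction; clip evidence is offset by
        # the (unknown) TSD, so prefer spans when present
        spans = [c for c in cluster if c[5] == "span"]
        core = spans or cluster
        pos = _mode([c[1] for c in core])
        ins_len = int(np.median([c[2] for c in core]))
        def _bare(c) -> str:  # evidence sequence with aligned flank removed
            return c[3][c[6]:len(c[3]) - c[7]] if c[7] else c[3][c[6]:]

        inserts = [_bare(c) for c in (spans or cluster) if c[3]]
        fam, ident = "unassigned", 0.0
        tsd = None
        if inserts:
            rep = max(inserts, key=len)
            fam, ident, _ = _library_match(rep, te_library, params)
        if fam != "unassigned":
            # fit the junction model ref[..p]+element+TSD+ref[p..] to the
            # evidence reads; the median fit gives an exact breakpoint
            # (and TSD, when the right side is observed) on clean reads
            # and stays robust to noise.  Spanning reads constrain both
            # sides; one-sided clips still pin the breakpoint.
            elem = te_library[fam]
            fits_p: List[int] = []
            fits_tl: List[int] = []
            if spans:
                evs = sorted(spans,
                             key=lambda c: (-(c[6] + c[7]), -len(c[3])))
                for ev in evs[:5]:
                    fp, ft = _refine_junction(ev[3], ev[6], ev[7], ev[1],
                                              reference[chrom], elem)
                    fits_p.append(fp)
                    fits_tl.append(ft)
            else:
                fits_b: List[int] = []  # element->reference boundary p-tsd
                for ev in [c for c in cluster if c[5] == "clipL"][:5]:
                    fits_p.append(_refine_clip_left(
                        ev[3], ev[6], ev[1], reference[chrom], elem))
                for ev in [c for c in cluster if c[5] == "clipR"][:5]:
                    fits_b.append(_refine_clip_right(
                        ev[3], ev[7], ev[1], reference[chrom], elem))
                if fits_p and fits_b:
                    fits_tl = [int(np.median(fits_p)) - int(np.median(fits_b))]
                elif fits_b and not fits_p:
                    fits_p = fits_b  # boundary: within a TSD of the truth
            if fits_p:
                p_ref = int(np.median(fits_p))
                if abs(p_ref - pos) <= cluster_radius:
                    pos = p_ref
                    ins_len = len(elem)
                    if fits_tl:
                        tl = int(np.median(fits_tl))
                        if 3 <= tl <= 8:
                            tsd = reference[chrom][pos - tl:pos]
        calls.append(InsertionCall(chrom, pos, len(cluster), ins_len,
                                   fam, ident, tsd))
    return calls


def _refine_junction(seg: str, fl: int, fr: int, lend: int, ref_seq: str,
                     elem: str, search: int = 30,
                     max_tsd: int = 8) -> Tuple[int, int]:
    """Fit breakpoint p and TSD length to one spanning junction segment.

    ``seg`` is (left flank of fl bp) + insert + (right flank of fr bp)
    oriented to the reference forward strand; ``lend`` is the reference
    position where the left flank alignment ended.  The candidate donor
    ``ref[lend-fl:p] + elem + ref[p-tl:p] + ref[p:]`` is scored against
    ``seg`` from both ends; the best (p, tl) is returned.  Micro-homology
    at the junction makes naive flank endpoints ambiguous; this model fit
    is exact on error-free reads.
    """
    sc = encode_seq(seg)
    n = len(seg)
    best = (-1.0, lend, 0)
    for p in range(max(lend - search, lend - fl + 1), lend + max_tsd + 1):
        if p <= 0 or p > len(ref_seq):
            continue
        left = ref_seq[lend - fl:p]
        for tl in range(0, max_tsd + 1):
            if p - tl < 0:
                continue
            cand = left + elem + ref_seq[p - tl:p] + \
                ref_seq[p:p + (n - len(left) - len(elem) - tl)]
            cc = encode_seq(cand)
            m = min(len(cc), n)
            if m <= 0:
                continue
            score = (float((cc[:m] == sc[:m]).mean())
                     + float((cc[-m:] == sc[-m:]).mean())
                     + (1.0 if len(cc) == n else 0.0))
            if score > best[0]:
                best = (score, p, tl)
    return best[1], best[2]


def _refine_clip_left(seg: str, fl: int, lend: int, ref_seq: str, elem: str,
                      search: int = 30, max_tsd: int = 8) -> int:
    """Breakpoint fit for a left-junction clip (flank + element prefix)."""
    sc = encode_seq(seg)
    n = len(seg)
    best = (-1.0, lend)
    for p in range(max(lend - search, lend - fl + 1), lend + max_tsd + 1):
        if p <= 0 or p > len(ref_seq):
            continue
        left = ref_seq[lend - fl:p]
        cand = left + elem[:max(0, n - len(left))]
        cc = encode_seq(cand)
        m = min(len(cc), n)
        if m == 0:
            continue
        score = float((cc[:m] == sc[:m]).mean())
        if score > best[0]:
            best = (score, p)
    return best[1]


def _refine_clip_right(seg: str, fr: int, rstart: int, ref_seq: str,
                       elem: str, search: int = 30,
                       max_tsd: int = 8) -> int:
    """Element-to-reference boundary fit for a right-junction clip.

    One-sided evidence cannot separate breakpoint and TSD (the TSD equals
    the reference there); what it pins exactly is the boundary
    ``p - tsd_len`` where the element suffix meets the reference again.
    """
    sc = encode_seq(seg)
    n = len(seg)
    best = (-1.0, rstart)
    for b in range(max(1, rstart - max_tsd), rstart + search + 1):
        if b > rstart + fr or b > len(ref_seq):
            continue
        right = ref_seq[b:rstart + fr]
        elen = n - len(right)
        if elen < 0:
            continue
        cand = elem[len(elem) - elen:] + right
        cc = encode_seq(cand)
        m = min(len(cc), n)
        if m == 0:
            continue
        score = float((cc[-m:] == sc[-m:]).mean())
        if score > best[0]:
            best = (score, b)
    return best[1]


def _oriented_read_segment(read: str, rec: AlignmentRecord,
                           aln_q0: int, aln_q1: int) -> str:
    """Read bases for alignment-orientation offsets [aln_q0, aln_q1)."""
    from .seq import revcomp

    if rec.strand == "+":
        s = rec.query_start + aln_q0
        return read[s:s + (aln_q1 - aln_q0)]
    rc = revcomp(read)
    s = (len(read) - rec.query_end) + aln_q0
    return rc[s:s + (aln_q1 - aln_q0)]


def write_teis_tsv(calls: Sequence[InsertionCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition_1based\tsupport\tinserted_len\tfamily\t"
                 "family_identity\ttsd\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.position + 1}\t{c.support}\t"
                     f"{c.inserted_len}\t{c.family}\t"
                     f"{c.family_identity:.1f}\t{c.tsd or '.'}\n")


# ---------------------------------------------------------------------------
# flanked-locus presence check (element +- flank joined, vs another assembly)


def flank_check(element_seq: str, flank_left: str, flank_right: str,
                assembly: Mapping[str, str], flank: int = 2000,
                min_identity: float = 90.0,
                params: Optional[AlignerParams] = None) -> Dict[str, object]:
    """Is the element present at the same (flank-defined) locus elsewhere?

    Queries the flank-joined sequences: ``flank_left + element + flank_right``
    (occupied locus) and ``flank_left + flank_right`` (empty locus) against
    an assembly; reports which configuration is found.
    """
    params = params or AlignerParams()
    idx = ReferenceIndex(assembly, k=params.k, max_seed_occ=params.max_seed_occ)

    def _best(q: str) -> float:
        recs = map_long_read(q, idx, params)
        best = 0.0
        for r in recs:
            if r.query_span() >= 0.9 * len(q):
                best = max(best, r.identity())
        return best

    occupied = _best(flank_left + element_seq + flank_right)
    empty = _best(flank_left + flank_right)
    state = "absent"
    if occupied >= min_identity:
        state = "occupied"
    elif empty >= min_identity:
        state = "empty"
    return {"state": state, "occupied_identity": occupied,
            "empty_identity": empty}
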