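"""eccDNA structure from rolling-circle concatemer reads.

One nanopore read of an RCA-amplified circle contains several tandem
copies (monomers) of that circle.  Mapping the originating element onto
the read yields one or more alignment records per monomer; the spacing of
repeated element positions along the read gives the monomer (= circle)
length, per-column voting over full monomers gives a circle consensus,
and projecting monomers back onto the element classifies the circle
(solo LTR, full-length with one or two LTRs, truncated) and reveals
divergence from the reference copy — the key signal when the circles
originate from an element absent from the reference assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from ._kernels import banded_global
from .align import (AlignerParams, AlignmentRecord, ReferenceIndex,
                    map_long_read)
from .catalog import TEElement
from .seq import decode_seq, encode_seq, revcomp

_OP_CODE = {"=": _kernels.OP_EQ, "X": _kernels.OP_X, "I": _kernels.OP_I,
            "D": _kernels.OP_D, "M": _kernels.OP_EQ}


@dataclass
class MonomerDecomposition:
    read_id: str
    element_id: str
    monomer_len: float
    n_full_monomers: int
    monomer_intervals: List[Tuple[int, int]]
    junction_supported: List[bool]
    consensus: str
    records: List[AlignmentRecord] = field(default_factory=list)
    read: str = ""  # read oriented to the element's forward strand
    element_len: int = 0

    @property
    def empty(self) -> bool:
        return not self.records


@dataclass
class EccStructureCall:
    element_id: str
    read_id: str
    structure_class: str  # solo_LTR | full_1LTR | full_2LTR | truncated | other
    internal_coverage: float
    n_ltr_copies: int
    deletions: List[Tuple[int, int]] = field(default_factory=list)


@dataclass
class DivergenceReport:
    element_id: str
    snp_count: int
    snp_positions: List[int]
    ltr_covered: bool
    ltr_deletion: Optional[Tuple[int, int]]
    mean_depth: float


@dataclass
class OriginCall:
    query_id: str
    per_genome: Dict[str, Tuple[float, Optional[Tuple[str, int, int]]]]
    assigned: str  # genome name or "ambiguous"
    margin: float


# ---------------------------------------------------------------------------
# cigar projection helpers


def _expand_cigar(cigar) -> np.ndarray:
    if not cigar:
        return np.empty(0, dtype=np.int8)
    return np.concatenate([np.full(n, _OP_CODE[op], dtype=np.int8)
                           for op, n in cigar])


def _aligned_columns(rec: AlignmentRecord, mask_near_gaps: int = 0
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """(query_positions, target_positions) of the =/X columns of a record.

    With ``mask_near_gaps`` > 0, aligned columns within that many columns
    of an indel are dropped — bases next to a gap are the ones alignment
    jitter misplaces, so pileup-based consensus calling excludes them
    (the long-read analogue of base-alignment-quality masking).
    """
    ops = _expand_cigar(rec.cigar)
    qstep = (ops == _kernels.OP_EQ) | (ops == _kernels.OP_X) | (ops == _kernels.OP_I)
    tstep = (ops == _kernels.OP_EQ) | (ops == _kernels.OP_X) | (ops == _kernels.OP_D)
    qpos = rec.query_start + np.cumsum(qstep) - qstep
    tpos = rec.target_start + np.cumsum(tstep) - tstep
    aligned = (ops == _kernels.OP_EQ) | (ops == _kernels.OP_X)
    if mask_near_gaps > 0:
        gap = ops >= _kernels.OP_I
        near = gap.copy()
        for _ in range(mask_near_gaps):
            near[1:] |= gap[:-1]
            near[:-1] |= gap[1:]
            gap = near.copy()
        aligned = aligned & ~near
    return qpos[aligned], tpos[aligned]


def _coverage_intervals(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as half-open intervals."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [len(mask)]
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# monomer decomposition


def _dedup_records(records: Sequence[AlignmentRecord]) -> List[AlignmentRecord]:
    """Keep the best record per read region (ties -> lowest element offset).

    Alternative placements of the same read span (the two identical LTRs
    of an element) collapse to one; tandem monomer copies at distinct read
    spans are all kept.
    """
    chosen: List[AlignmentRecord] = []
    for rec in sorted(records, key=lambda r: (-r.score, r.query_start,
                                              r.target_start)):
        ok = True
        for c in chosen:
            ov = min(rec.target_end, c.target_end) - \
                max(rec.target_start, c.target_start)
            if ov > 0.5 * min(rec.target_span(), c.target_span()):
                ok = False
                break
        if ok:
            chosen.append(rec)
    chosen.sort(key=lambda r: r.target_start)
    return chosen


def decompose_concatemer(read: str, element_seq: str, read_id: str = "read",
                         element_id: str = "element",
                         params: Optional[AlignerParams] = None
                         ) -> MonomerDecomposition:
    """Decompose one RCA concatemer read against its element sequence.

    The element is mapped onto the read (read as target); tandem hits
    define monomer copies.  ``monomer_len`` is the median spacing of
    repeated element positions along the read; a full monomer is a period
    window covered >=90%; internal boundaries are ``junction_supported``
    when coverage is continuous within 50 bp; the consensus is a
    per-column majority over full monomers (>=2 required, else empty).
    """
    if len(element_seq) == 0:
        raise ValueError("empty element sequence")
    if len(read) < 200:
        raise ValueError("read shorter than 200 bp")
    params = params or AlignerParams()

    def _map(r: str) -> List[AlignmentRecord]:
        idx = ReferenceIndex({read_id: r}, k=params.k,
                             max_seed_occ=params.max_seed_occ)
        return map_long_read(element_seq, idx, params, query_id=element_id)

    recs = _map(read)
    if recs and next(r for r in recs if r.is_primary).strand == "-":
        read = revcomp(read)
        recs = _map(read)
    recs = [r for r in recs if r.strand == "+"]
    if not recs:
        return MonomerDecomposition(read_id, element_id, 0.0, 0, [], [], "",
                                    [], read, len(element_seq))
    copies = _dedup_records(recs)

    # Cluster copies by the element region they show.  Clusters whose
    # element subsequences are near-identical (e.g. the two LTRs of one
    # element) are alternative placements of the same circle fragment and
    # merge, otherwise spacings would double when the aligner alternates
    # between the equivalent placements.
    reps: List[Tuple[int, int]] = []
    cl_of: List[int] = []
    for r in copies:
        for ci, (rs, re_) in enumerate(reps):
            if min(r.query_end, re_) - max(r.query_start, rs) >= 50:
                cl_of.append(ci)
                break
        else:
            reps.append((r.query_start, r.query_end))
            cl_of.append(len(reps) - 1)
    merged = list(range(len(reps)))
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            if merged[j] != j:
                continue
            (s1, e1), (s2, e2) = reps[i], reps[j]
            la, lb = e1 - s1, e2 - s2
            if not 0.7 <= la / lb <= 1.43:
                continue
            from .align import global_identity as _gid
            if _gid(element_seq[s1:e1], element_seq[s2:e2],
                    abs(la - lb) + 32) >= 80.0:
                merged[j] = merged[i]
    group = [merged[c] for c in cl_of]

    # monomer length: target spacing between successive copies showing the
    # same (or an equivalent) element region, compared at a shared offset.
    spacings: List[float] = []
    for j in range(1, len(copies)):
        b = copies[j]
        # walk back to the nearest preceding copy in the same group
        for i in range(j - 1, -1, -1):
            if group[i] != group[j]:
                continue
            a = copies[i]
            ofs_a = a.query_start - reps[cl_of[i]][0]
            ofs_b = b.query_start - reps[cl_of[j]][0]
            est = (b.target_start - ofs_b) - (a.target_start - ofs_a)
            if est > 0:
                spacings.append(float(est))
            break
    if spacings:
        monomer_len = float(np.median(spacings))
    else:
        # <2 comparable copies: best available lower-bound estimate
        qcov = np.zeros(len(element_seq), dtype=bool)
        for r in copies:
            qcov[r.query_start:r.query_end] = True
        monomer_len = float(max(int(qcov.sum()),
                                max(r.target_span() for r in copies)))

    # full-monomer period windows on the read
    read_len = len(read)
    cov = np.zeros(read_len, dtype=bool)
    for r in copies:
        cov[r.target_start:r.target_end] = True
    t0 = copies[0].target_start
    P = monomer_len
    windows: List[Tuple[int, int]] = []
    if P >= 50:
        j = -int(t0 // P) - 1
        while True:
            a = int(round(t0 + j * P))
            b = int(round(t0 + (j + 1) * P))
            if a >= read_len:
                break
            if a >= 0 and b <= read_len:
                windows.append((a, b))
            j += 1
    full = [w for w in windows if cov[w[0]:w[1]].mean() >= 0.9]
    junctions: List[bool] = []
    for i in range(len(full) - 1):
        b = full[i][1]
        lo, hi = max(0, b - 50), min(read_len, b + 50)
        # supported when coverage around the boundary has no gap > 50 bp
        gap_run = 0
        max_gap = 0
        for v in cov[lo:hi]:
            gap_run = 0 if v else gap_run + 1
            max_gap = max(max_gap, gap_run)
        junctions.append(max_gap <= 50 and cov[max(0, b - 1)])

    consensus = ""
    if len(full) >= 2:
        consensus = _vote_consensus(read, full[:20], params)

    return MonomerDecomposition(
        read_id=read_id, element_id=element_id, monomer_len=monomer_len,
        n_full_monomers=len(full), monomer_intervals=full,
        junction_supported=junctions, consensus=consensus, records=copies,
        read=read, element_len=len(element_seq))


def _vote_consensus(read: str, windows: Sequence[Tuple[int, int]],
                    params: AlignerParams) -> str:
    codes = encode_seq(read)
    a0, b0 = windows[0]
    anchor = codes[a0:b0]
    n = len(anchor)
    votes = np.zeros((5, n), dtype=np.int32)  # A C G T gap
    votes[anchor, np.arange(n)] += 1
    for a, b in windows[1:]:
        w = codes[a:b]
        band = max(32, int(0.05 * n))
        ops, _ = banded_global(w, anchor, band, params.match, params.mismatch,
                               params.gap_open, params.gap_extend)
        qp = 0
        tp = 0
        for op in ops:
            if op == _kernels.OP_EQ or op == _kernels.OP_X:
                if w[qp] < 4:
                    votes[w[qp], tp] += 1
                qp += 1
                tp += 1
            elif op == _kernels.OP_I:
                qp += 1
            else:
                votes[4, tp] += 1
                tp += 1
    best = votes.argmax(axis=0)
    top = votes.max(axis=0)
    anchor_vote = votes[anchor, np.arange(n)]
    # ties resolve to the anchor base
    best = np.where(anchor_vote == top, anchor, best)
    keep = best < 4
    return decode_seq(best[keep].astype(np.uint8))


# ---------------------------------------------------------------------------
# structure classification


def _element_coverage(decomp: MonomerDecomposition,
                      window: Optional[Tuple[int, int]] = None) -> np.ndarray:
    covered = np.zeros(decomp.element_len, dtype=bool)
    for rec in decomp.records:
        qpos, tpos = _aligned_columns(rec)
        if window is not None:
            sel = (tpos >= window[0]) & (tpos < window[1])
            qpos = qpos[sel]
        covered[qpos] = True
    return covered


def classify_structure(decomp: MonomerDecomposition, element: TEElement,
                       internal_full: float = 0.9,
                       solo_internal: float = 0.1,
                       min_del: int = 20) -> EccStructureCall:
    """Classify the circle structure of one decomposed read.

    The consensus monomer (or the best monomer window) is projected onto
    the element; the internal-region coverage fraction and the number of
    LTR copies per monomer decide the class.
    """
    if element.ltr5 is None or element.ltr3 is None:
        raise ValueError(f"element {element.id} lacks LTR sub-intervals")
    if decomp.empty:
        return EccStructureCall(element.id, decomp.read_id, "other", 0.0, 0)
    if decomp.monomer_intervals:
        window = max(decomp.monomer_intervals,
                     key=lambda w: int(np.sum([
                         min(w[1], r.target_end) - max(w[0], r.target_start)
                         for r in decomp.records])))
    else:
        best = max(decomp.records, key=lambda r: r.score)
        window = (best.target_start, best.target_end)
    covered = _element_coverage(decomp, window)

    i0, i1 = element.ltr5[1], element.ltr3[0]
    internal_cov = float(covered[i0:i1].mean()) if i1 > i0 else 0.0
    # LTR copies are counted over distinct READ positions: a monomer split
    # across two records projects its one LTR onto both (identical) element
    # LTRs, which must not double-count.
    ltr_elem = np.zeros(decomp.element_len, dtype=bool)
    ltr_elem[element.ltr5[0]:element.ltr5[1]] = True
    ltr_elem[element.ltr3[0]:element.ltr3[1]] = True
    read_ltr = np.zeros(window[1] - window[0], dtype=bool)
    for rec in decomp.records:
        qpos, tpos = _aligned_columns(rec)
        sel = (tpos >= window[0]) & (tpos < window[1]) & ltr_elem[qpos]
        read_ltr[tpos[sel] - window[0]] = True
    mean_ltr = 0.5 * ((element.ltr5[1] - element.ltr5[0])
                      + (element.ltr3[1] - element.ltr3[0]))
    n_ltr = int(round(read_ltr.sum() / mean_ltr)) if mean_ltr else 0

    if internal_cov <= solo_internal and n_ltr >= 1:
        klass = "solo_LTR"
    elif internal_cov >= internal_full and n_ltr == 1:
        klass = "full_1LTR"
    elif internal_cov >= internal_full and n_ltr >= 2:
        klass = "full_2LTR"
    elif solo_internal < internal_cov < internal_full:
        klass = "truncated"
    else:
        klass = "other"

    deletions: List[Tuple[int, int]] = []
    idx = np.nonzero(covered)[0]
    if len(idx):
        span0, span1 = int(idx[0]), int(idx[-1]) + 1
        for s, e in _coverage_intervals(~covered[span0:span1]):
            if e - s >= min_del:
                deletions.append((span0 + s, span0 + e))
    return EccStructureCall(element.id, decomp.read_id, klass, internal_cov,
                            n_ltr, deletions)


# ---------------------------------------------------------------------------
# divergence of eccDNA consensus from the reference element


def consensus_divergence(decomps: Sequence[MonomerDecomposition],
                         element: TEElement, element_seq: str,
                         min_depth: int = 5, min_agree: float = 0.8,
                         min_del: int = 20) -> DivergenceReport:
    """Pile monomer copies onto element coordinates and call SNPs.

    A SNP is called where depth >= ``min_depth``, the majority base
    reaches ``min_agree`` agreement, and it differs from the reference
    base.  ``ltr_covered`` is False when mean LTR depth < 1; a contiguous
    uncovered LTR stretch >= ``min_del`` bp inside an otherwise covered
    LTR is reported as an LTR deletion.
    """
    n = len(element_seq)
    ref = encode_seq(element_seq)
    counts = np.zeros((4, n), dtype=np.int32)
    raw_depth = np.zeros(n, dtype=np.int32)  # unmasked, for coverage flags
    for d in decomps:
        if d.empty:
            continue
        rcodes = encode_seq(d.read)
        for rec in d.records:
            qpos, tpos = _aligned_columns(rec, mask_near_gaps=2)
            bases = rcodes[tpos]
            ok = bases < 4
            np.add.at(counts, (bases[ok], qpos[ok]), 1)
            qall, _ = _aligned_columns(rec)
            np.add.at(raw_depth, qall, 1)
    depth = counts.sum(axis=0)
    mean_depth = float(raw_depth.mean()) if n else 0.0
    snps: List[int] = []
    called = depth >= min_depth
    if called.any():
        top = counts.argmax(axis=0)
        topn = counts.max(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            agree = np.where(depth > 0, topn / np.maximum(depth, 1), 0.0)
        snp_mask = called & (agree >= min_agree) & (top.astype(np.uint8) != ref)
        snps = [int(p) for p in np.nonzero(snp_mask)[0]]

    ltr_pos = np.zeros(n, dtype=bool)
    if element.ltr5:
        ltr_pos[element.ltr5[0]:element.ltr5[1]] = True
    if element.ltr3:
        ltr_pos[element.ltr3[0]:element.ltr3[1]] = True
    ltr_covered = bool(ltr_pos.any()) and \
        float(raw_depth[ltr_pos].mean()) >= 1.0

    ltr_deletion: Optional[Tuple[int, int]] = None
    for iv in (element.ltr5, element.ltr3):
        if iv is None:
            continue
        seg = raw_depth[iv[0]:iv[1]]
        if len(seg) == 0 or seg.mean() < 1.0:
            continue
        for s, e in _coverage_intervals(seg == 0):
            if e - s >= min_del:
                cand = (iv[0] + s, iv[0] + e)
                if ltr_deletion is None or (cand[1] - cand[0]
                                            > ltr_deletion[1] - ltr_deletion[0]):
                    ltr_deletion = cand
    return DivergenceReport(element.id, len(snps), snps, ltr_covered,
                            ltr_deletion, mean_depth)


def _locus_identity(query: str, target_seq: str, rec: AlignmentRecord,
                    params: AlignerParams) -> Tuple[float, int, int]:
    """Optimal global identity of the whole query against its locus.

    The seed-and-extend hit may clip diverged query ends, so the locus is
    re-derived: the query is globally aligned against a padded window,
    target overhangs (long terminal D runs plus a few chance-matched
    columns outside them) are stripped to delimit the homologous locus,
    and the identity reported is that of an optimal (band auto-widened)
    global alignment of query vs locus.  Returns (identity, t0, t1).
    """
    pad_l = rec.query_start + 16
    pad_r = (len(query) - rec.query_end) + 16
    w0 = max(0, rec.target_start - pad_l)
    w1 = min(len(target_seq), rec.target_end + pad_r)
    qor = query if rec.strand == "+" else revcomp(query)
    qc = encode_seq(qor)
    tc = encode_seq(target_seq[w0:w1])
    band = max(64, abs(len(tc) - len(qc)) + 32)
    ops, _ = banded_global(qc, tc, band, params.match, params.mismatch,
                           params.gap_open, params.gap_extend)
    runs: List[Tuple[int, int]] = []
    for op in ops:
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((int(op), 1))

    def _cut(rs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
        # trailing D runs are locus overhang by definition; short non-D
        # islands between them are chance matches inside the padding
        rs = list(rs)
        while rs:
            op, ln = rs[-1]
            if op == _kernels.OP_D:
                rs.pop()
            elif ln <= 3 and len(rs) >= 2 and rs[-2][0] == _kernels.OP_D:
                rs.pop()
            else:
                break
        return rs

    def _tspan(rs) -> int:
        return sum(ln for op, ln in rs
                   if op in (_kernels.OP_EQ, _kernels.OP_X, _kernels.OP_D))

    total_t = _tspan(runs)
    kept = _cut(runs)
    tail_cut = total_t - _tspan(kept)
    kept = _cut(kept[::-1])[::-1]
    head_cut = total_t - tail_cut - _tspan(kept)
    t0 = w0 + head_cut
    t1 = w1 - tail_cut
    if t1 <= t0:
        return 0.0, w0, w1
    from .align import global_alignment

    def _score(a: int, b: int):
        cigar, matches, cols, score = global_alignment(
            qor, target_seq[a:b], band_slack=64, params=params)
        return cigar, matches, cols, score

    cigar, matches, cols, score = _score(t0, t1)
    # terminal query-overhang (I) runs mean the boundary landed inside a
    # co-optimally placed gap: try extending the locus by that much
    d0 = cigar[0][1] if cigar and cigar[0][0] == "I" else 0
    d1 = cigar[-1][1] if cigar and cigar[-1][0] == "I" else 0
    if d0 or d1:
        n0 = max(0, t0 - d0)
        n1 = min(len(target_seq), t1 + d1)
        cig2, m2, c2, s2 = _score(n0, n1)
        if s2 > score:
            t0, t1, matches, cols = n0, n1, m2, c2
    return 100.0 * matches / cols, t0, t1


# ---------------------------------------------------------------------------
# species-of-origin assignment of a consensus LTR against a genome panel


def assign_origin(query: str, panel: Mapping[str, Mapping[str, str]],
                  identity_floor: float = 96.0, min_margin: float = 1.0,
                  params: Optional[AlignerParams] = None,
                  query_id: str = "query") -> OriginCall:
    """Best-hit identity of the query (consensus LTR) per panel genome.

    The genome with the highest best-hit identity is assigned when that
    identity reaches ``identity_floor`` and leads the runner-up by
    ``min_margin`` points; otherwise the call is ambiguous.  Ties break
    deterministically by genome name.
    """
    if not panel:
        raise ValueError("empty genome panel")
    if not query:
        raise ValueError("empty query sequence")
    # divergent homologs (>=20% divergence) still need dense seed hits:
    # shorter seeds at every query position
    params = params or AlignerParams(k=11, seed_stride=1)
    per_genome: Dict[str, Tuple[float, Optional[Tuple[str, int, int]]]] = {}
    for name in sorted(panel):
        idx = ReferenceIndex(panel[name], k=params.k,
                             max_seed_occ=params.max_seed_occ)
        recs = map_long_read(query, idx, params, query_id=query_id)
        good = [r for r in recs if r.query_span() >= 0.8 * len(query)]
        pool = good or recs
        if pool:
            best = max(pool, key=lambda r: (r.identity(), -r.target_start))
            ident, t0, t1 = _locus_identity(
                query, panel[name][best.target_id], best, params)
            per_genome[name] = (ident, (best.target_id, t0, t1))
        else:
            per_genome[name] = (0.0, None)
    ranked = sorted(per_genome.items(), key=lambda kv: (-kv[1][0], kv[0]))
    top_name, (top_id, _) = ranked[0]
    second = ranked[1][1][0] if len(ranked) > 1 else 0.0
    margin = top_id - second
    assigned = top_name if (top_id >= identity_floor
                            and margin >= min_margin) else "ambiguous"
    return OriginCall(query_id, per_genome, assigned, margin)


# ---------------------------------------------------------------------------
# output tables


def write_structures_tsv(calls: Sequence[EccStructureCall],
                         decomps: Mapping[str, MonomerDecomposition],
                         path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\telement_id\tclass\tinternal_coverage\t"
                 "n_ltr_copies\tmonomer_len\tn_full_monomers\tdeletions\n")
        for c in calls:
            d = decomps.get(c.read_id)
            dels = ";".join(f"{s}-{e}" for s, e in c.deletions) or "."
            fh.write(f"{c.read_id}\t{c.element_id}\t{c.structure_class}\t"
                     f"{c.internal_coverage:.3f}\t{c.n_ltr_copies}\t"
                     f"{d.monomer_len if d else 0:.1f}\t"
                     f"{d.n_full_monomers if d else 0}\t{dels}\n")


def write_dotplot_coords(decomp: MonomerDecomposition, path,
                         stride: int = 10) -> None:
    """(element_pos, read_pos) pairs of aligned columns, for dot plots."""
    with open(path, "w") as fh:
        fh.write("element_pos\tread_pos\n")
        for rec in decomp.records:
            qpos, tpos = _aligned_columns(rec)
            for q, t in zip(qpos[::stride], tpos[::stride]):
                fh.write(f"{q}\t{t}\n")
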