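"""Shared pairwise-alignment machinery.

Two entry points serve the whole pipeline:

* :func:`map_long_read` — a seed–chain–extend local aligner for long noisy
  reads against an indexed reference.  Tandem copies of a target (as in
  rolling-circle concatemer reads) are reported as separate records, which
  downstream monomer decomposition relies on.
* :func:`global_identity` — banded global (Gotoh affine) percent identity
  between two comparable-length sequences, with automatic band widening.

All coordinates are 0-based half-open.  Identity uses alignment columns
(matches + mismatches + gap columns) as the denominator, i.e. "BLAST
identity" as printed in PAF, so added gaps always lower identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from ._kernels import banded_global, chain_dp
from .seq import encode_seq, kmer_codes, revcomp_codes

_OP_CHARS = "=XID"
_PAD = 1024  # spacing between chromosomes in the concatenated coordinate space

Cigar = List[Tuple[str, int]]


@dataclass
class AlignerParams:
    """Tuning knobs of the built-in long-read aligner.

    Defaults are adequate for <=10% uniform read error at desk scale:
    exact 13-mer seeds, co-linear chaining with a 500 bp gap ceiling, and
    affine gap scores 2/1 with match +1 / mismatch -2.
    """

    k: int = 13
    max_seed_gap: int = 500
    band_width: int = 100
    match: int = 1
    mismatch: int = -2
    gap_open: int = 2
    gap_extend: int = 1
    min_chain_seeds: int = 3
    min_aln_len: int = 50
    max_seed_occ: int = 64
    seed_stride: int = 3  # query k-mer subsampling (1 = every position)

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        for name in ("max_seed_gap", "band_width", "min_chain_seeds",
                     "min_aln_len", "max_seed_occ"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AlignmentRecord:
    """One local alignment of a query against a target.

    For ``strand == '-'`` the query interval is given on the original
    (forward) query sequence, PAF style, while the cigar describes the
    reverse-complemented query walked along the forward target.
    """

    query_id: str
    query_start: int
    query_end: int
    target_id: str
    target_start: int
    target_end: int
    strand: str
    matches: int
    aln_columns: int
    cigar: Cigar
    score: int
    is_primary: bool = False
    query_len: int = 0
    target_len: int = 0

    def identity(self) -> float:
        """Percent identity over alignment columns, in [0, 100]."""
        if self.aln_columns == 0:
            return 0.0
        return 100.0 * self.matches / self.aln_columns

    def query_span(self) -> int:
        return self.query_end - self.query_start

    def target_span(self) -> int:
        return self.target_end - self.target_start

    def validate(self) -> None:
        if not (0 <= self.query_start < self.query_end):
            raise ValueError("bad query interval")
        if not (0 <= self.target_start < self.target_end):
            raise ValueError("bad target interval")
        if self.matches > self.aln_columns:
            raise ValueError("matches exceed alignment columns")
        qlen = sum(n for op, n in self.cigar if op in "M=XI")
        tlen = sum(n for op, n in self.cigar if op in "M=XD")
        if qlen != self.query_span() or tlen != self.target_span():
            raise ValueError("cigar inconsistent with intervals")


class ReferenceIndex:
    """Exact k-mer index over a set of sequences (forward strand).

    Sequences are concatenated into one coordinate space with padding so a
    chain can never straddle two targets; hits are mapped back to
    per-target coordinates when records are built.
    """

    def __init__(self, sequences: Mapping[str, str], k: int = 13,
                 max_seed_occ: int = 64):
        if not sequences:
            raise ValueError("reference is empty")
        self.k = k
        self.max_seed_occ = max_seed_occ
        self.names: List[str] = list(sequences)
        self.codes: Dict[str, np.ndarray] = {
            n: encode_seq(s) for n, s in sequences.items()
        }
        self.lengths: Dict[str, int] = {n: len(c) for n, c in self.codes.items()}
        offsets = []
        off = 0
        for n in self.names:
            offsets.append(off)
            off += self.lengths[n] + _PAD
        self._offsets = np.array(offsets, dtype=np.int64)
        keys_all, pos_all = [], []
        for n, o in zip(self.names, offsets):
            keys, pos = kmer_codes(self.codes[n], k)
            keys_all.append(keys)
            pos_all.append(pos + o)
        keys_cat = np.concatenate(keys_all) if keys_all else np.empty(0, np.uint64)
        pos_cat = np.concatenate(pos_all) if pos_all else np.empty(0, np.int64)
        order = np.argsort(keys_cat, kind="stable")
        self._keys = keys_cat[order]
        self._pos = pos_cat[order]
        # bucket prefix table on the high bits of the packed k-mer key
        bits = min(13, 2 * k - 1)
        self._shift = np.uint64(2 * k - bits)
        bounds = np.arange(1, (1 << bits) + 1, dtype=np.uint64) << self._shift
        self._bucket_starts = np.concatenate(
            ([0], np.searchsorted(self._keys, bounds, side="left"))
        ).astype(np.int64)

    def seed_hits(self, qkeys: np.ndarray, qpos: np.ndarray
                  ) -> Tuple[np.ndarray, np.ndarray]:
        """Return (query_pos, global_target_pos) hit arrays.

        K-mers occurring more than ``max_seed_occ`` times in the reference
        are skipped as repeats.
        """
        if len(qkeys) == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        return _kernels.lookup_hits(self._keys, self._pos, self._bucket_starts,
                                    self._shift, qkeys, qpos,
                                    self.max_seed_occ)

    def locate(self, gpos: int) -> Tuple[str, int]:
        """Map a global concatenated position to (name, local position)."""
        i = int(np.searchsorted(self._offsets, gpos, side="right")) - 1
        name = self.names[i]
        local = int(gpos - self._offsets[i])
        if local >= self.lengths[name]:
            raise ValueError("position falls into inter-sequence padding")
        return name, local


# ---------------------------------------------------------------------------
# cigar / ops helpers


def _ops_to_cigar(ops: np.ndarray) -> Cigar:
    if len(ops) == 0:
        return []
    breaks = np.nonzero(np.diff(ops))[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [len(ops)]))
    return [(_OP_CHARS[ops[s]], int(e - s)) for s, e in zip(starts, ends)]


def _column_scores(ops: np.ndarray, p: AlignerParams) -> np.ndarray:
    sc = np.empty(len(ops), dtype=np.int32)
    sc[ops == _kernels.OP_EQ] = p.match
    sc[ops == _kernels.OP_X] = p.mismatch
    gap = ops >= _kernels.OP_I
    sc[gap] = -p.gap_extend
    # gap open charged on the first column of each gap run (I and D separately)
    opens = gap & np.concatenate(([True], ops[1:] != ops[:-1]))
    sc[opens & gap] -= p.gap_open
    return sc


def _trim_ops(ops: np.ndarray, p: AlignerParams) -> Tuple[np.ndarray, int, int]:
    """Strip terminal negatively-scoring runs (soft-clip equivalent).

    Returns (trimmed ops, columns cut at front, columns cut at back).
    """
    front = back = 0
    for _ in range(4):  # converges quickly; re-check after each cut
        if len(ops) == 0:
            break
        cum = np.cumsum(_column_scores(ops, p))
        i = int(np.argmin(cum))
        if cum[i] < 0:
            ops = ops[i + 1:]
            front += i + 1
            continue
        rev = np.cumsum(_column_scores(ops[::-1], p))
        j = int(np.argmin(rev))
        if rev[j] < 0:
            ops = ops[: len(ops) - j - 1]
            back += j + 1
            continue
        break
    return ops, front, back


def _ops_stats(ops: np.ndarray, p: AlignerParams) -> Tuple[int, int, int, int, int]:
    """(matches, columns, query_consumed, target_consumed, affine_score)."""
    matches = int(np.count_nonzero(ops == _kernels.OP_EQ))
    cols = len(ops)
    qcons = int(np.count_nonzero(ops <= _kernels.OP_I))  # =, X, I
    tcons = int(np.count_nonzero((ops <= _kernels.OP_X) | (ops == _kernels.OP_D)))
    score = int(_column_scores(ops, p).sum())
    return matches, cols, qcons, tcons, score


# ---------------------------------------------------------------------------
# map_long_read


def _extract_chains(dp: np.ndarray, parent: np.ndarray, min_seeds: int,
                    max_chains: int = 200) -> List[np.ndarray]:
    order = np.argsort(dp, kind="stable")[::-1]
    used = np.zeros(len(dp), dtype=bool)
    chains: List[np.ndarray] = []
    for i in order:
        if used[i] or dp[i] < min_seeds:
            continue
        node = int(i)
        members = []
        while node != -1 and not used[node]:
            members.append(node)
            used[node] = True
            node = int(parent[node])
        if len(members) >= min_seeds:
            chains.append(np.array(members[::-1], dtype=np.int64))
        if len(chains) >= max_chains:
            break
    return chains


_TAIL_LIMIT = 64  # bp of unseeded read end that extension still aligns


def _gap_ops(qseg: np.ndarray, tseg: np.ndarray, p: AlignerParams) -> np.ndarray:
    """Align the (short) region between two exact anchor runs."""
    if len(qseg) == 0 and len(tseg) == 0:
        return np.empty(0, dtype=np.int8)
    if len(qseg) == 0:
        return np.full(len(tseg), _kernels.OP_D, dtype=np.int8)
    if len(tseg) == 0:
        return np.full(len(qseg), _kernels.OP_I, dtype=np.int8)
    band = abs(len(qseg) - len(tseg)) + 8
    ops, _ = banded_global(qseg, tseg, band, p.match, p.mismatch,
                           p.gap_open, p.gap_extend)
    return ops


def _align_chain(codes_q: np.ndarray, hq: np.ndarray, ht: np.ndarray,
                 chain: np.ndarray, reference: ReferenceIndex,
                 params: AlignerParams) -> Optional[dict]:
    """Anchored extension: exact seed runs stitched with small gap DPs.

    The chain's seeds are already co-linear; consecutive seeds on one
    diagonal merge into exact-match runs, and only the short stretches
    between runs (where sequencing errors broke the seeds) are aligned by
    DP.  Read ends beyond the outermost seeds are extended up to
    ``_TAIL_LIMIT`` bp and then score-trimmed, so non-homologous tails
    (e.g. reads running into an insertion) stay soft-clipped.
    """
    k = params.k
    qsd = hq[chain]
    tsd = ht[chain]
    try:
        chrom, toff = reference.locate(int(tsd.min()))
        chrom2, _ = reference.locate(int(tsd.max()) + k - 1)
    except ValueError:
        return None
    if chrom != chrom2:
        return None
    toff = int(tsd.min()) - toff  # global -> local shift
    tcodes = reference.codes[chrom]
    tlen = reference.lengths[chrom]
    qlen = len(codes_q)

    pieces: List[np.ndarray] = []
    # merged exact runs
    q0 = qr0 = int(qsd[0])
    tr0 = int(tsd[0]) - toff
    t0 = tr0
    qr1, tr1 = qr0 + k, tr0 + k
    for x in range(1, len(chain)):
        q, t = int(qsd[x]), int(tsd[x]) - toff
        if t - q == tr1 - qr1 and q <= qr1:
            qr1 = max(qr1, q + k)
            tr1 = max(tr1, t + k)
            continue
        if q < qr1 or t < tr1:
            continue  # conflicting overlap; drop seed
        pieces.append(np.full(qr1 - qr0, _kernels.OP_EQ, dtype=np.int8))
        pieces.append(_gap_ops(codes_q[qr1:q], tcodes[tr1:t], params))
        qr0, tr0, qr1, tr1 = q, t, q + k, t + k
    pieces.append(np.full(qr1 - qr0, _kernels.OP_EQ, dtype=np.int8))

    # end extension
    lq = min(q0, _TAIL_LIMIT)
    lt = min(t0, lq + 16)
    rq = min(qlen - qr1, _TAIL_LIMIT)
    rt = min(tlen - tr1, rq + 16)
    head_ops = _gap_ops(codes_q[q0 - lq:q0], tcodes[t0 - lt:t0], params)
    tail_ops = _gap_ops(codes_q[qr1:qr1 + rq], tcodes[tr1:tr1 + rt], params)
    ops = np.concatenate([head_ops] + pieces + [tail_ops])

    q0 -= lq
    t0 -= lt
    full = ops
    ops, front, back = _trim_ops(ops, params)
    if len(ops) == 0:
        return None
    _, _, fq, ft, _ = _ops_stats(full[:front], params) if front else (0, 0, 0, 0, 0)
    _, _, bq, bt, _ = _ops_stats(full[len(full) - back:], params) if back else (0, 0, 0, 0, 0)
    matches, cols, qcons, tcons, score = _ops_stats(ops, params)
    if matches == 0 or score <= 0:
        return None
    return {
        "chrom": chrom,
        "q0": q0 + fq, "q1": q0 + fq + qcons,
        "t0": t0 + ft, "t1": t0 + ft + tcons,
        "ops": ops, "matches": matches, "cols": cols, "score": score,
        "tlen": tlen,
    }


def map_long_read(read: str, reference: ReferenceIndex,
                  params: Optional[AlignerParams] = None,
                  query_id: str = "query") -> List[AlignmentRecord]:
    """Map one long read against the indexed reference.

    Returns zero or more local alignments with exactly one flagged primary
    (highest affine score; ties broken by lowest (target_id, target_start)).
    Multiple tandem hits to the same target are separate records.
    """
    if len(read) == 0:
        raise ValueError("empty query")
    params = params or AlignerParams()
    if params.k != reference.k:
        raise ValueError("params.k differs from reference index k")
    codes_f = encode_seq(read)
    qlen = len(codes_f)
    candidates = []  # (n_seeds, fwd_qs, fwd_qe, ts, te, strand, codes, hq, ht, chain)
    for strand, codes in (("+", codes_f), ("-", revcomp_codes(codes_f))):
        qkeys, qpos = kmer_codes(codes, params.k)
        if params.seed_stride > 1 and len(qpos):
            sel = qpos % params.seed_stride == 0
            qkeys, qpos = qkeys[sel], qpos[sel]
        hq, ht = reference.seed_hits(qkeys, qpos)
        if len(hq) == 0:
            continue
        order = np.lexsort((ht, hq))
        hq, ht = hq[order], ht[order]
        dp, parent = chain_dp(hq, ht, params.max_seed_gap,
                              params.band_width, 128)
        for chain in _extract_chains(dp, parent, params.min_chain_seeds):
            qs, qe = int(hq[chain].min()), int(hq[chain].max()) + params.k
            if strand == "-":
                qs, qe = qlen - qe, qlen - qs
            candidates.append((len(chain), qs, qe, int(ht[chain].min()),
                               int(ht[chain].max()), strand, codes, hq, ht,
                               chain))

    # Far-secondary suppression: a chain whose read interval is mostly
    # explained by a stronger chain mapping to a distant locus is an
    # alternative placement (e.g. another family copy) and is dropped;
    # nearby placements (tandem monomer copies, the two LTRs of one
    # element) are kept.
    candidates.sort(key=lambda c: -c[0])
    accepted = []
    raw: List[Tuple[str, dict]] = []
    for cand in candidates:
        _, qs, qe, ts, te, strand, codes, hq, ht, chain = cand
        suppressed = False
        for (aqs, aqe, ats, ate) in accepted:
            qov = min(qe, aqe) - max(qs, aqs)
            if qov < 0.5 * min(qe - qs, aqe - aqs):
                continue
            span = max(te - ts, ate - ats)
            gap = max(ats - te, ts - ate, 0)
            if gap > 4 * span:
                suppressed = True
                break
        if suppressed:
            continue
        res = _align_chain(codes, hq, ht, chain, reference, params)
        if res is not None:
            accepted.append((qs, qe, ts, te))
            raw.append((strand, res))

    records: List[AlignmentRecord] = []
    seen = set()
    for strand, r in raw:
        if strand == "+":
            q0, q1 = r["q0"], r["q1"]
        else:
            q0, q1 = qlen - r["q1"], qlen - r["q0"]
        if q1 - q0 < params.min_aln_len:
            continue
        key = (strand, r["chrom"], r["t0"], r["t1"], q0, q1)
        if key in seen:
            continue
        seen.add(key)
        records.append(AlignmentRecord(
            query_id=query_id, query_start=q0, query_end=q1,
            target_id=r["chrom"], target_start=r["t0"], target_end=r["t1"],
            strand=strand, matches=r["matches"], aln_columns=r["cols"],
            cigar=_ops_to_cigar(r["ops"]), score=r["score"],
            query_len=qlen, target_len=r["tlen"]))
    if records:
        best = min(range(len(records)),
                   key=lambda i: (-records[i].score, records[i].target_id,
                                  records[i].target_start))
        for i, rec in enumerate(records):
            rec.is_primary = (i == best)
        records.sort(key=lambda r: (not r.is_primary, -r.score,
                                    r.target_id, r.target_start))
    return records


# ---------------------------------------------------------------------------
# global identity


def global_alignment(a: str, b: str, band_slack: int = 32,
                     params: Optional[AlignerParams] = None
                     ) -> Tuple[Cigar, int, int, int]:
    """Optimal banded global alignment; returns (cigar, matches, columns, score).

    The band is widened (with a warning) until doubling it no longer
    improves the score, so the result equals the unbanded optimum.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty input sequence")
    params = params or AlignerParams()
    ca, cb = encode_seq(a), encode_seq(b)
    band = max(8, band_slack)
    cap = max(len(a), len(b))
    ops, score = banded_global(ca, cb, band, params.match, params.mismatch,
                               params.gap_open, params.gap_extend)
    while band < cap:
        wider = min(2 * band, cap)
        ops2, score2 = banded_global(ca, cb, wider, params.match,
                                     params.mismatch, params.gap_open,
                                     params.gap_extend)
        if score2 <= score:
            break
        warnings.warn("alignment band too narrow; widened automatically",
                      stacklevel=2)
        ops, score, band = ops2, score2, wider
    matches, cols, _, _, _ = _ops_stats(ops, params)
    return _ops_to_cigar(ops), matches, cols, score


def global_identity(a: str, b: str, band_slack: int = 32,
                    params: Optional[AlignerParams] = None) -> float:
    """Percent identity of an optimal global alignment.

    Arguments are ordered canonically first: co-optimal alignments can
    differ in their match count depending on tie-breaking, so computing
    on a fixed ordering keeps the function exactly symmetric.
    """
    if b < a:
        a, b = b, a
    _, matches, cols, _ = global_alignment(a, b, band_slack, params)
    return 100.0 * matches / cols


# ---------------------------------------------------------------------------
# PAF-compatible TSV


def write_paf(records: Sequence[AlignmentRecord], path) -> None:
    """Emit 12-column PAF with a cg:Z: cigar tag."""
    with open(path, "w") as fh:
        for r in records:
            cg = "".join(f"{n}{op}" for op, n in r.cigar)
            mapq = 60 if r.is_primary else 0
            fh.write("\t".join(map(str, (
                r.query_id, r.query_len, r.query_start, r.query_end,
                r.strand, r.target_id, r.target_len, r.target_start,
                r.target_end, r.matches, r.aln_columns, mapq,
                f"tp:A:{'P' if r.is_primary else 'S'}", f"cg:Z:{cg}",
            ))) + "\n")


def read_paf(path) -> List[AlignmentRecord]:
    """Read a PAF(-like) TSV produced by this package or an external mapper."""
    import re

    out: List[AlignmentRecord] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            cigar: Cigar = []
            primary = True
            for tag in f[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = [(m[1], int(m[0])) for m in
                             re.findall(r"(\d+)([MIDNSHP=X])", tag[5:])]
                elif tag.startswith("tp:A:"):
                    primary = tag[5] == "P"
            out.append(AlignmentRecord(
                query_id=f[0], query_len=int(f[1]), query_start=int(f[2]),
                query_end=int(f[3]), strand=f[4], target_id=f[5],
                target_len=int(f[6]), target_start=int(f[7]),
                target_end=int(f[8]), matches=int(f[9]),
                aln_columns=int(f[10]), cigar=cigar, score=int(f[9]),
                is_primary=primary))
    return out
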