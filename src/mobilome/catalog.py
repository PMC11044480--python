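"""LTR retrotransposon catalog: de novo LTR-pair detection, family
clustering on LTR identity, and open-reading-frame scanning.

An LTR retrotransposon is modelled as 5'LTR - internal (GAG/POL) - 3'LTR.
A young insertion carries two near-identical LTRs, so elements are found
as same-strand repeat pairs bounding an internal region, and the identity
of the two LTRs dates the insertion (99-100% identity means recent
activity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .align import global_identity
from .seq import encode_seq, kmer_codes, revcomp

Interval = Tuple[int, int]

_STOPS = frozenset((48, 50, 56))  # TAA, TAG, TGA with A=0,C=1,G=2,T=3 packing
_ATG = 14  # 0*16 + 3*4 + 2


@dataclass
class TEElement:
    """An annotated LTR retrotransposon copy.

    ``start``/``end`` are 0-based half-open genome coordinates; ``ltr5`` and
    ``ltr3`` are element-relative sub-intervals (5' LTR first in element
    orientation).  ``orfs`` entries are ``(frame, start, end, codons)`` with
    frame in {1,2,3,-1,-2,-3} and coordinates on the forward element
    sequence.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    ltr5: Optional[Interval] = None
    ltr3: Optional[Interval] = None
    ltr_identity: float = math.nan
    family: str = "unassigned"
    orfs: List[Tuple[int, int, int, int]] = field(default_factory=list)
    tsd: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError("bad element interval")
        for ltr in (self.ltr5, self.ltr3):
            if ltr is not None and not (0 <= ltr[0] < ltr[1] <= self.length):
                raise ValueError("LTR sub-interval outside element")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, genome: Mapping[str, str]) -> str:
        s = genome[self.chrom][self.start:self.end]
        return revcomp(s) if self.strand == "-" else s

    def ltr5_sequence(self, genome: Mapping[str, str]) -> str:
        if self.ltr5 is None:
            raise ValueError(f"element {self.id} has no LTR sub-intervals")
        s, e = self.ltr5
        return self.sequence(genome)[s:e]

    def internal_interval(self) -> Interval:
        if self.ltr5 is None or self.ltr3 is None:
            raise ValueError(f"element {self.id} has no LTR sub-intervals")
        return (self.ltr5[1], self.ltr3[0])


# ---------------------------------------------------------------------------
# ORF scanning


def scan_orfs(seq: str, min_codons: int = 300) -> List[Tuple[int, int, int, int]]:
    """Scan all six frames for ORFs (ATG..stop), longest first.

    Lengths are in codons excluding the stop.  Coordinates are on the
    forward sequence, 0-based half-open, spanning ATG through stop codon.
    IUPAC ambiguity codes are tolerated (they are never ATG or stop);
    anything else raises.
    """
    bad = set(seq.upper()) - set("ACGTRYSWKMBDVHNU")
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")
    out: List[Tuple[int, int, int, int]] = []
    n = len(seq)
    for strand in (1, -1):
        s = seq if strand == 1 else revcomp(seq)
        codes = encode_seq(s)
        for f in range(3):
            m = (n - f) // 3
            if m == 0:
                continue
            tri = codes[f:f + 3 * m].reshape(m, 3)
            ok = (tri < 4).all(axis=1)
            vals = tri[:, 0] * 16 + tri[:, 1] * 4 + tri[:, 2]
            vals = np.where(ok, vals, 99)
            start_codon = -1
            for i in range(m):
                v = vals[i]
                if v == _ATG and start_codon < 0:
                    start_codon = i
                elif v in _STOPS:
                    if start_codon >= 0:
                        codons = i - start_codon
                        if codons >= min_codons:
                            a = f + 3 * start_codon
                            b = f + 3 * (i + 1)
                            if strand == -1:
                                a, b = n - b, n - a
                            out.append((strand * (f + 1), a, b, codons))
                    start_codon = -1
    out.sort(key=lambda o: (-o[3], o[1], o[0]))
    return out


def longest_orf_codons(seq: str, min_codons: int = 1) -> int:
    orfs = scan_orfs(seq, min_codons=min_codons)
    return orfs[0][3] if orfs else 0


# ---------------------------------------------------------------------------
# de novo LTR-pair detection


def _candidate_repeats(codes: np.ndarray, k: int, min_ltr_len: int,
                       max_element_len: int, min_internal: int = 500,
                       max_occ: int = 40) -> List[Tuple[int, int, int]]:
    """Find (start1, start2, repeat_span) candidates from self k-mer pairs.

    Pairs of identical k-mers at a distance compatible with an LTR pair
    are binned by distance; a run of near-constant-distance seeds whose
    positions span >= ~min_ltr_len is a candidate terminal-repeat pair.
    """
    keys, pos = kmer_codes(codes, k)
    order = np.argsort(keys, kind="stable")
    keys, pos = keys[order], pos[order]
    starts = np.nonzero(np.diff(keys))[0] + 1
    bounds = np.concatenate(([0], starts, [len(keys)]))
    p1s, p2s = [], []
    dmin = min_ltr_len + min_internal
    for a, b in zip(bounds[:-1], bounds[1:]):
        cnt = b - a
        if cnt < 2 or cnt > max_occ:
            continue
        grp = np.sort(pos[a:b])
        for i in range(cnt - 1):
            for j in range(i + 1, cnt):
                d = grp[j] - grp[i]
                if d > max_element_len:
                    break
                if d >= dmin:
                    p1s.append(grp[i])
                    p2s.append(grp[j])
    if not p1s:
        return []
    p1 = np.array(p1s)
    d = np.array(p2s) - p1
    # cluster by distance bin, then by contiguity of p1
    bin_w = 50
    out = []
    order = np.lexsort((p1, d // bin_w))
    p1, d = p1[order], d[order]
    cur: List[int] = []
    for idx in range(len(p1)):
        if cur and (d[idx] // bin_w != d[cur[0]] // bin_w
                    or p1[idx] - p1[cur[-1]] > 200):
            out.append(cur)
            cur = []
        cur.append(idx)
    if cur:
        out.append(cur)
    cands = []
    for grp in out:
        span = int(p1[grp[-1]] - p1[grp[0]]) + k
        if span >= 0.6 * min_ltr_len:
            cands.append((int(p1[grp[0]]), int(p1[grp[0]] + int(np.median(d[grp]))), span))
    return cands


def detect_ltr_pairs(genome: Mapping[str, str], min_ltr_len: int = 100,
                     max_element_len: int = 15000, min_identity: float = 85.0,
                     k: int = 13, tsd_range: Tuple[int, int] = (4, 6)
                     ) -> List[TEElement]:
    """De novo prediction of LTR retrotransposons from terminal repeat pairs.

    Candidates are same-strand near-identical repeats >= ``min_ltr_len``
    within ``max_element_len``, bounding an internal region >= 500 bp;
    overlapping candidates resolve to the highest-LTR-identity one.  A
    matching 4-6 bp flank duplication is recorded as the TSD when present,
    but is not required.
    """
    elements: List[TEElement] = []
    n_id = 0
    for chrom, seq in genome.items():
        codes = encode_seq(seq)
        cands = []
        for s1, s2, span in _candidate_repeats(codes, k, min_ltr_len,
                                               max_element_len):
            if span < min_ltr_len:
                continue
            e1, e2 = s1 + span, s2 + span
            if e2 > len(seq) or e2 - s1 > max_element_len:
                continue
            if s2 - e1 < 500:  # internal region too short
                continue
            ident = global_identity(seq[s1:e1], seq[s2:e2])
            if ident >= min_identity:
                cands.append((ident, s1, e1, s2, e2))
        cands.sort(key=lambda c: (-c[0], c[1]))
        taken: List[Interval] = []
        for ident, s1, e1, s2, e2 in cands:
            if any(s1 < te and ts < e2 for ts, te in taken):
                continue
            taken.append((s1, e2))
            tsd = None
            for tl in range(tsd_range[1], tsd_range[0] - 1, -1):
                if s1 >= tl and e2 + tl <= len(seq):
                    left = seq[s1 - tl:s1]
                    if left == seq[e2:e2 + tl]:
                        tsd = left
                        break
            n_id += 1
            elements.append(TEElement(
                id=f"RTE{n_id}", chrom=chrom, start=s1, end=e2, strand="+",
                ltr5=(0, e1 - s1), ltr3=(s2 - s1, e2 - s1),
                ltr_identity=ident, tsd=tsd))
    elements.sort(key=lambda e: (e.chrom, e.start))
    return elements


# ---------------------------------------------------------------------------
# family clustering


def pairwise_ltr_identity(elements: Sequence[TEElement],
                          genome: Mapping[str, str]) -> np.ndarray:
    seqs = [e.ltr5_sequence(genome) for e in elements]
    n = len(seqs)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            slack = abs(len(seqs[i]) - len(seqs[j])) + 32
            mat[i, j] = mat[j, i] = global_identity(seqs[i], seqs[j], slack)
    return mat


def cluster_families(elements: Sequence[TEElement], genome: Mapping[str, str],
                     linkage_threshold: float = 80.0,
                     identity: Optional[np.ndarray] = None) -> Dict[str, str]:
    """Single-linkage clustering of elements on pairwise 5' LTR identity.

    Edges join elements with identity >= ``linkage_threshold``; connected
    components are families, labelled FAM1, FAM2, ... in order of their
    leftmost member.  Updates ``element.family`` in place and returns the
    {element_id: family} map.
    """
    if not elements:
        return {}
    if identity is None:
        identity = pairwise_ltr_identity(elements, genome)
    n = len(elements)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if identity[i, j] >= linkage_threshold:
                parent[find(i)] = find(j)
    comps: Dict[int, List[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    ordered = sorted(comps.values(),
                     key=lambda m: min((elements[i].chrom, elements[i].start)
                                       for i in m))
    labels: Dict[str, str] = {}
    for rank, members in enumerate(ordered, start=1):
        for i in members:
            elements[i].family = f"FAM{rank}"
            labels[elements[i].id] = f"FAM{rank}"
    return labels


def nj_tree_newick(elements: Sequence[TEElement],
                   genome: Mapping[str, str]) -> str:
    """Neighbor-joining tree on 100-identity LTR distances (reporting aid)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(elements) < 3:
        raise ValueError("need >= 3 elements for a tree")
    dist = 100.0 - pairwise_ltr_identity(elements, genome)
    np.fill_diagonal(dist, 0.0)
    dm = DistanceMatrix(dist, ids=[e.id for e in elements])
    return str(nj(dm)).strip()


# ---------------------------------------------------------------------------
# annotation I/O (BED 6 + family + LTR sub-intervals)


def write_te_bed(elements: Sequence[TEElement], path) -> None:
    with open(path, "w") as fh:
        for e in elements:
            ltr = "."
            if e.ltr5 and e.ltr3:
                ltr = (f"ltr5:{e.ltr5[0]}-{e.ltr5[1]};"
                       f"ltr3:{e.ltr3[0]}-{e.ltr3[1]}")
            fh.write("\t".join(map(str, (
                e.chrom, e.start, e.end, e.id, 0, e.strand, e.family, ltr,
            ))) + "\n")


def read_te_bed(path) -> List[TEElement]:
    out: List[TEElement] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            ltr5 = ltr3 = None
            if len(f) > 7 and f[7] != ".":
                for part in f[7].split(";"):
                    name, iv = part.split(":")
                    a, b = map(int, iv.split("-"))
                    if name == "ltr5":
                        ltr5 = (a, b)
                    elif name == "ltr3":
                        ltr3 = (a, b)
            out.append(TEElement(
                id=f[3], chrom=f[0], start=int(f[1]), end=int(f[2]),
                strand=f[5] if len(f) > 5 else "+",
                family=f[6] if len(f) > 6 else "unassigned",
                ltr5=ltr5, ltr3=ltr3))
    return out


def write_families_tsv(elements: Sequence[TEElement],
                       genome: Mapping[str, str], path,
                       min_codons: int = 300) -> None:
    with open(path, "w") as fh:
        fh.write("element_id\tfamily\tltr_identity\tlongest_orf_codons\n")
        for e in elements:
            n = longest_orf_codons(e.sequence(genome), min_codons=1)
            ident = "" if math.isnan(e.ltr_identity) else f"{e.ltr_identity:.2f}"
            fh.write(f"{e.id}\t{e.family}\t{ident}\t{n}\n")
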