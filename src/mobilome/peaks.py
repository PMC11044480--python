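"""Differential eccDNA activity per annotated element.

Reads from two libraries (treatment under epigenetic de-repression vs
control) are intersected with the TE annotation; per-element counts are
normalised per 100,000 sequenced reads and compared with a two-sided
Fisher exact test, Benjamini-Hochberg corrected over the elements that
clear the minimum read-support filter.  An element is called significant
("active") when the adjusted p-value is below alpha AND the normalised
treatment count exceeds the control count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .align import AlignmentRecord
from .catalog import TEElement


@dataclass
class PeakRecord:
    element_id: str
    reads_treat: int
    reads_ctrl: int
    total_treat: int
    total_ctrl: int
    cpm100k_treat: float
    cpm100k_ctrl: float
    p_value: float
    p_adj: float
    status: str  # significant | tested | low_count


def count_reads_per_element(alignments: Iterable[AlignmentRecord],
                            annotation: Sequence[TEElement],
                            min_overlap: int = 100
                            ) -> Tuple[Dict[str, int], int]:
    """Count each read once, toward the element its primary alignment
    overlaps most (ties -> leftmost element); overlap must be
    >= ``min_overlap`` bp.  Returns (counts per element id, n unassigned).
    """
    by_chrom: Dict[str, List[TEElement]] = {}
    for e in sorted(annotation, key=lambda e: (e.chrom, e.start)):
        by_chrom.setdefault(e.chrom, []).append(e)
    starts = {c: np.array([e.start for e in es])
              for c, es in by_chrom.items()}
    ends = {c: np.array([e.end for e in es]) for c, es in by_chrom.items()}
    known_chroms = set(by_chrom)

    counts: Dict[str, int] = {e.id: 0 for e in annotation}
    unassigned = 0
    seen_queries = set()
    for rec in alignments:
        if not rec.is_primary:
            continue
        if rec.query_id in seen_queries:
            raise ValueError(f"read {rec.query_id} has two primary alignments")
        seen_queries.add(rec.query_id)
        if rec.target_id not in known_chroms:
            raise ValueError(f"alignment references unknown chromosome "
                             f"{rec.target_id!r}")
        es = by_chrom[rec.target_id]
        s, e = starts[rec.target_id], ends[rec.target_id]
        lo = int(np.searchsorted(e, rec.target_start, side="right"))
        hi = int(np.searchsorted(s, rec.target_end, side="left"))
        best_id = None
        best_ov = 0
        for i in range(lo, hi):
            ov = min(rec.target_end, ends[rec.target_id][i]) - \
                max(rec.target_start, starts[rec.target_id][i])
            if ov > best_ov:  # ties keep the earlier (leftmost) element
                best_ov = ov
                best_id = es[i].id
        if best_id is not None and best_ov >= min_overlap:
            counts[best_id] += 1
        else:
            unassigned += 1
    return counts, unassigned


def normalize_cpm100k(count: int, library_total: int) -> float:
    """Reads per 100,000 sequenced reads in the library."""
    if library_total <= 0:
        raise ValueError("empty library")
    return 100_000.0 * count / library_total


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def call_differential(counts_treat: Mapping[str, int],
                      counts_ctrl: Mapping[str, int],
                      totals: Tuple[int, int],
                      min_reads: int = 10,
                      alpha: float = 0.01,
                      correction: str = "bh") -> List[PeakRecord]:
    """Two-sided Fisher exact test per element with multiple-test correction.

    The 2x2 table per element is
    ``[[reads_treat, total_treat - reads_treat],
    [reads_ctrl, total_ctrl - reads_ctrl]]``.  Correction (BH by default,
    Bonferroni via ``correction='bonferroni'``) runs over the elements with
    combined support > ``min_reads``; the rest are reported as
    ``low_count``.  Output is sorted by (p_adj, element_id).
    """
    total_t, total_c = totals
    if total_t <= 0 or total_c <= 0:
        raise ValueError("empty library")
    ids = sorted(set(counts_treat) | set(counts_ctrl))
    rows = []
    for eid in ids:
        a = int(counts_treat.get(eid, 0))
        b = int(counts_ctrl.get(eid, 0))
        if a < 0 or b < 0:
            raise ValueError("negative count")
        if a > total_t or b > total_c:
            raise ValueError("count exceeds library total")
        p = stats.fisher_exact([[a, total_t - a], [b, total_c - b]],
                               alternative="two-sided")[1]
        rows.append((eid, a, b, min(p, 1.0)))

    tested = [r for r in rows if r[1] + r[2] > min_reads]
    if correction == "bh":
        adj = _bh_adjust(np.array([r[3] for r in tested]))
    elif correction == "bonferroni":
        adj = np.minimum(1.0, np.array([r[3] for r in tested]) * len(tested))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    adj_map = {r[0]: float(q) for r, q in zip(tested, adj)}

    out: List[PeakRecord] = []
    for eid, a, b, p in rows:
        cpm_t = normalize_cpm100k(a, total_t)
        cpm_c = normalize_cpm100k(b, total_c)
        if eid in adj_map:
            q = adj_map[eid]
            status = "significant" if (q < alpha and cpm_t > cpm_c) else "tested"
        else:
            q = 1.0
            status = "low_count"
        out.append(PeakRecord(eid, a, b, total_t, total_c, cpm_t, cpm_c,
                              p, q, status))
    out.sort(key=lambda r: (r.p_adj, r.element_id))
    return out


def write_peaks_tsv(records: Sequence[PeakRecord], path) -> None:
    cols = ("element_id", "reads_treat", "reads_ctrl", "total_treat",
            "total_ctrl", "cpm100k_treat", "cpm100k_ctrl", "p_value",
            "p_adj", "status")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join(str(getattr(r, c)) for c in cols) + "\n")
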