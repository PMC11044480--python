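"""Synthetic mobilome-seq data: reference genome with planted LTR
retrotransposon families, eccDNA circles amplified into concatemeric
nanopore-like reads, and WGS long reads carrying an elevated-SNP
introgressed segment plus non-reference TE insertions.

Every generator is deterministic under a fixed seed and emits a
machine-readable truth set so recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .catalog import TEElement
from .seq import decode_seq, encode_seq, revcomp_codes

STRUCTURE_CLASSES = ("solo_LTR", "full_1LTR", "full_2LTR", "truncated")

_DEFAULT_MIX = {"solo_LTR": 0.25, "full_1LTR": 0.35, "full_2LTR": 0.25,
                "truncated": 0.15}


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic scenario.

    The defaults emulate the shape of the underlying experiment: two LTR
    retrotransposon families whose active members are ~10x enriched for
    eccDNA reads under epigenetic de-repression (treatment) versus
    control; planted ORFs of 1302, 352 and 1173 codons; 5 bp target-site
    duplications; ~10% total read error (5% substitution, 2.5% insertion,
    2.5% deletion).
    """

    seed: int = 1
    chrom_lengths: Tuple[int, ...] = (2_000_000,)
    gc: float = 0.38
    n_families: int = 2
    ltr_len: Tuple[int, int] = (400, 600)
    internal_len: Tuple[int, int] = (3800, 4600)
    copies_per_family: int = 3
    planted_orf_lengths: Tuple[int, ...] = (1302, 352, 1173)
    copy_divergence: float = 0.03
    ltr_divergence: float = 0.0
    tsd_len: int = 5
    # eccDNA read simulation
    ecc_mix: Optional[Dict[str, Dict[str, float]]] = None
    reads_per_condition: int = 5000
    enrichment_fold: float = 10.0
    n_active_per_family: int = 1
    read_len_mu: float = 8.0
    read_len_sigma: float = 0.4
    error_rates: Tuple[float, float, float] = (0.05, 0.025, 0.025)
    ecc_divergence_snps: int = 0
    # WGS simulation
    background_snp_rate: float = 1e-4
    introgression: Optional[Tuple[str, int, int, float]] = ("chr1", 400_000,
                                                            1_400_000, 20.0)
    insertions: Optional[List[Tuple[str, str, int, int]]] = None
    n_default_insertions: int = 4
    wgs_depth: float = 15.0
    wgs_read_len_mu: float = 8.9
    wgs_read_len_sigma: float = 0.35

    def __post_init__(self) -> None:
        if self.ecc_mix is None:
            self.ecc_mix = {"treatment": dict(_DEFAULT_MIX),
                            "control": dict(_DEFAULT_MIX)}
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be a fraction")
        for cond, mix in self.ecc_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"ecc_mix for {cond!r} must sum to 1")
            if any(f < 0 for f in mix.values()):
                raise ValueError("ecc_mix fractions must be >= 0")
        if not 4 <= self.tsd_len <= 6:
            raise ValueError("tsd_len must be 4-6 bp")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if any(r < 0 for r in self.error_rates) or sum(self.error_rates) >= 1:
            raise ValueError("error rates must be fractions summing to < 1")


@dataclass
class TruthSet:
    """Ground truth emitted alongside synthetic data."""

    te_catalog: List[TEElement] = field(default_factory=list)
    active_elements: List[str] = field(default_factory=list)
    family_consensus: Dict[str, str] = field(default_factory=dict)
    element_seqs: Dict[str, str] = field(default_factory=dict)
    circle_structures: Dict[str, dict] = field(default_factory=dict)
    divergent_sites: Dict[str, List[int]] = field(default_factory=dict)
    snps: List[Tuple[str, int, str, str]] = field(default_factory=list)
    introgression_segments: List[Tuple[str, int, int]] = field(default_factory=list)
    insertion_sites: List[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        doc = {
            "te_catalog": [dataclasses.asdict(e) for e in self.te_catalog],
            "active_elements": self.active_elements,
            "circle_structures": self.circle_structures,
            "divergent_sites": self.divergent_sites,
            "snps": self.snps,
            "introgression_segments": self.introgression_segments,
            "insertion_sites": self.insertion_sites,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# helpers


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


_STOP_TRIPLETS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}


def _orf_codes(rng: np.random.Generator, codons: int) -> np.ndarray:
    """In-frame stop, ATG, ``codons``-1 non-stop codons, stop codon."""
    out = [3, 0, 0, 0, 3, 2]  # TAA then ATG
    need = codons - 1
    while need > 0:
        tri = tuple(rng.integers(0, 4, 3))
        if tri in _STOP_TRIPLETS:
            continue
        out.extend(tri)
        need -= 1
    out.extend((3, 2, 0))  # TGA
    return np.array(out, dtype=np.uint8)


def mutate_substitutions(codes: np.ndarray, rate: float,
                         rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Substitute bases at ``rate``; returns (mutated, positions)."""
    out = codes.copy()
    mask = rng.random(len(codes)) < rate
    pos = np.nonzero(mask)[0]
    out[pos] = (out[pos] + rng.integers(1, 4, len(pos))) % 4
    return out, pos


def apply_read_errors(codes: np.ndarray, rng: np.random.Generator,
                      rates: Tuple[float, float, float]) -> np.ndarray:
    """Per-base independent substitution/insertion/deletion errors."""
    sub, ins, dele = rates
    n = len(codes)
    u = rng.random(n)
    is_del = u < dele
    is_ins = (u >= dele) & (u < dele + ins)
    is_sub = (u >= dele + ins) & (u < dele + ins + sub)
    out = codes.copy()
    spos = np.nonzero(is_sub)[0]
    out[spos] = (out[spos] + rng.integers(1, 4, len(spos))) % 4
    counts = np.ones(n, dtype=np.int64)
    counts[is_del] = 0
    counts[is_ins] = 2
    expanded = np.repeat(out, counts)
    ins_at = np.cumsum(counts)[is_ins] - 1
    expanded[ins_at] = rng.integers(0, 4, len(ins_at))
    return expanded


# ---------------------------------------------------------------------------
# reference genome with planted elements


def simulate_reference(config: SimConfig) -> Tuple[Dict[str, str],
                                                   List[TEElement], TruthSet]:
    """Build the genome, plant TE families, return (genome, annotation, truth).

    Each planted element is LTR + internal + (identical or diverged) LTR
    flanked by a ``tsd_len`` bp target-site duplication.  Copy 0 of each
    family equals the family consensus (and is the designated "active"
    element); other copies carry ``copy_divergence`` substitutions, so
    families stay mutually <80% identical while within-family copies stay
    >=90% identical.
    """
    rng = np.random.default_rng([config.seed, 101])
    truth = TruthSet()

    # family consensus sequences with planted ORFs
    fam_parts: List[Tuple[np.ndarray, np.ndarray, int]] = []
    orf_plan: List[Tuple[int, ...]] = []
    orfs = list(config.planted_orf_lengths)
    for f in range(config.n_families):
        if f == 0 and orfs:
            orf_plan.append((orfs[0],))
        elif f == 1 and len(orfs) > 1:
            orf_plan.append(tuple(orfs[1:]))
        else:
            orf_plan.append(())
    for f in range(config.n_families):
        ltr = _random_codes(rng, rng.integers(*config.ltr_len, endpoint=True),
                            config.gc)
        # internal region must hold the planted ORFs plus spacers
        required = 60 + sum(3 * c + 6 + 60 for c in orf_plan[f])
        drawn = int(rng.integers(*config.internal_len, endpoint=True))
        internal = _random_codes(rng, max(drawn, required), config.gc)
        pos = 30
        for codons in orf_plan[f]:
            block = _orf_codes(rng, codons)
            if pos + len(block) + 30 > len(internal):
                raise ValueError("planted ORFs exceed internal region")
            internal[pos:pos + len(block)] = block
            pos += len(block) + 60
        fam_parts.append((ltr, internal, len(ltr)))

    n_copies = config.n_families * config.copies_per_family
    per_chrom = -(-n_copies // len(config.chrom_lengths))  # ceil
    elem_len_max = 2 * config.ltr_len[1] + config.internal_len[1]
    for L in config.chrom_lengths:
        if per_chrom * (elem_len_max + 2000) > L:
            raise ValueError("planted elements exceed chromosome capacity")

    # assign copies to chromosomes round-robin, positions spaced evenly
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    slots: Dict[str, List[int]] = {c: [] for c in chrom_names}
    copy_ids = [(f, c) for f in range(config.n_families)
                for c in range(config.copies_per_family)]
    for i, _ in enumerate(copy_ids):
        slots[chrom_names[i % len(chrom_names)]].append(i)

    genome: Dict[str, str] = {}
    elements: List[TEElement] = []
    tsd = config.tsd_len
    for ci, chrom in enumerate(chrom_names):
        L = config.chrom_lengths[ci]
        bg = _random_codes(rng, L, config.gc)
        mine = slots[chrom]
        # insertion points, evenly spread with jitter, sorted
        pts = np.sort(((np.arange(len(mine)) + 0.5) / max(len(mine), 1) * (L - elem_len_max)
                       ).astype(np.int64) + rng.integers(-5000, 5000, len(mine)))
        pieces: List[np.ndarray] = []
        prev = 0
        out_len = 0
        for slot_i, p in zip(mine, pts):
            f, copy = copy_ids[slot_i]
            ltr, internal, ltr_n = fam_parts[f]
            ltr3 = ltr.copy()
            if config.ltr_divergence > 0:
                ltr3, _ = mutate_substitutions(ltr3, config.ltr_divergence, rng)
            elem = np.concatenate([ltr, internal, ltr3])
            if copy > 0 and config.copy_divergence > 0:
                elem, _ = mutate_substitutions(elem, config.copy_divergence,
                                               rng)
            p = int(p)
            pieces.append(bg[prev:p + tsd])  # includes the left TSD copy
            out_len += p + tsd - prev
            start = out_len
            pieces.append(elem)
            out_len += len(elem)
            prev = p  # right flank restarts at p -> bg[p:p+tsd] duplicated
            eid = f"TE_f{f + 1}c{copy + 1}"
            elements.append(TEElement(
                id=eid, chrom=chrom, start=start, end=start + len(elem),
                strand="+", ltr5=(0, ltr_n),
                ltr3=(len(elem) - len(ltr3), len(elem)),
                ltr_identity=100.0 if config.ltr_divergence == 0 else float("nan"),
                family=f"FAM{f + 1}",
                tsd=decode_seq(bg[p:p + tsd])))
            truth.element_seqs[eid] = decode_seq(elem)
            if copy == 0:
                truth.family_consensus.setdefault(f"FAM{f + 1}",
                                                  decode_seq(elem))
            if copy < config.n_active_per_family:
                truth.active_elements.append(eid)
        pieces.append(bg[prev:])
        genome[chrom] = decode_seq(np.concatenate(pieces))

    truth.te_catalog = elements
    return genome, elements, truth


# ---------------------------------------------------------------------------
# eccDNA circles and RCA concatemer reads


def _build_circle(elem: np.ndarray, ltr5: Tuple[int, int],
                  ltr3: Tuple[int, int], klass: str,
                  rng: np.random.Generator) -> np.ndarray:
    internal = elem[ltr5[1]:ltr3[0]]
    if klass == "solo_LTR":
        return elem[ltr5[0]:ltr5[1]].copy()
    if klass == "full_1LTR":
        return np.concatenate([elem[ltr5[0]:ltr5[1]], internal])
    if klass == "full_2LTR":
        return elem.copy()
    if klass == "truncated":
        frac = rng.uniform(0.1, 0.9)
        n = max(60, int(frac * len(internal)))
        off = rng.integers(0, len(internal) - n + 1)
        return internal[off:off + n].copy()
    raise ValueError(f"unknown structure class {klass!r}")


def simulate_eccdna_reads(config: SimConfig, truth: TruthSet,
                          condition: str) -> Dict[str, str]:
    """RCA concatemer reads for one condition; updates truth per read.

    Circles are tandem-amplified from a uniform random phase, read length
    drawn from the lognormal model, then corrupted by the error model.
    Active elements are ``enrichment_fold``-times over-represented in the
    treatment library.
    """
    if condition not in ("treatment", "control"):
        raise ValueError("condition must be 'treatment' or 'control'")
    rng = np.random.default_rng(
        [config.seed, 211 if condition == "treatment" else 223])
    elements = truth.te_catalog
    weights = np.array([
        config.enrichment_fold
        if condition == "treatment" and e.id in truth.active_elements else 1.0
        for e in elements])
    weights /= weights.sum()
    mix = config.ecc_mix[condition]
    classes = sorted(mix)
    class_p = np.array([mix[c] for c in classes])

    # per-element planted divergence (circles come from a non-reference copy)
    templates: Dict[str, np.ndarray] = {}
    for e in elements:
        codes = encode_seq(truth.element_seqs[e.id])
        if config.ecc_divergence_snps > 0 and e.id in truth.active_elements:
            if e.id not in truth.divergent_sites:
                # divergent sites go in the internal region: a site inside
                # one LTR would be diluted by the other (identical) LTR
                # during pileup and stop being exactly countable
                i0, i1 = e.internal_interval()
                pos = np.sort(rng.choice(
                    np.arange(i0 + 20, i1 - 20),
                    config.ecc_divergence_snps, replace=False))
                truth.divergent_sites[e.id] = [int(p) for p in pos]
            pos = np.array(truth.divergent_sites[e.id])
            codes = codes.copy()
            codes[pos] = (codes[pos] + rng.integers(1, 4, len(pos))) % 4
        templates[e.id] = codes

    reads: Dict[str, str] = {}
    eidx = rng.choice(len(elements), config.reads_per_condition, p=weights)
    cidx = rng.choice(len(classes), config.reads_per_condition, p=class_p)
    lens = np.maximum(
        300, rng.lognormal(config.read_len_mu, config.read_len_sigma,
                           config.reads_per_condition).astype(np.int64))
    for i in range(config.reads_per_condition):
        e = elements[eidx[i]]
        klass = classes[cidx[i]]
        circle = _build_circle(templates[e.id], e.ltr5, e.ltr3, klass, rng)
        if len(circle) < 50:
            raise ValueError("circle shorter than 50 bp")
        L = int(lens[i])
        phase = int(rng.integers(0, len(circle)))
        reps = -(-(phase + L) // len(circle))
        template = np.tile(circle, reps)[phase:phase + L]
        if rng.random() < 0.5:
            template = revcomp_codes(template)
        read = apply_read_errors(template, rng, config.error_rates)
        rid = f"ecc_{condition}_{i:05d}"
        reads[rid] = decode_seq(read)
        truth.circle_structures[rid] = {
            "element": e.id, "class": klass, "circle_len": int(len(circle)),
            "condition": condition,
        }
    return reads


def simulate_panel(truth: TruthSet, config: SimConfig,
                   divergences: Tuple[float, ...] = (0.02, 0.08, 0.20),
                   genome_len: int = 120_000) -> Dict[str, Dict[str, str]]:
    """Panel of relative-species assemblies for origin assignment.

    Each panel genome carries one copy of every active element diverged by
    the genome's divergence rate, embedded in unrelated sequence.  The
    least-diverged genome (``panel_A``) is the true origin of the eccDNA
    consensus sequences.
    """
    rng = np.random.default_rng([config.seed, 401])
    panel: Dict[str, Dict[str, str]] = {}
    for gi, div in enumerate(divergences):
        name = f"panel_{chr(ord('A') + gi)}"
        bg = _random_codes(rng, genome_len, config.gc)
        pos = 10_000
        for eid in truth.active_elements:
            elem = encode_seq(truth.element_seqs[eid])
            mutated, _ = mutate_substitutions(elem, div, rng)
            bg[pos:pos + len(mutated)] = mutated
            pos += len(mutated) + 20_000
        panel[name] = {f"{name}_chr1": decode_seq(bg)}
    return panel


# ---------------------------------------------------------------------------
# WGS reads: introgression SNPs + TE insertions


def _junction_ambiguous(ref: str, p: int, tsd_len: int, elem: str,
                        flank: int = 60, window: int = 10) -> bool:
    """True when the planted junction admits more than one exact
    (breakpoint, TSD) representation.

    Micro-homology between the element ends and the flanking reference can
    make two donor strings identical for different breakpoints; such
    degenerate junctions are skipped so planted truth stays identifiable.
    """
    seg = ref[p - flank:p] + elem + ref[p - tsd_len:p] + ref[p:p + flank]
    n = len(seg)
    exact = 0
    for pp in range(p - window, p + window + 1):
        for tl in range(0, 9):
            if pp - tl < 0 or pp <= p - flank:
                continue
            cand = ref[p - flank:pp] + elem + ref[pp - tl:pp] + \
                ref[pp:pp + (n - (pp - (p - flank)) - len(elem) - tl)]
            if cand == seg:
                exact += 1
                if exact > 1:
                    return True
    return exact != 1


def simulate_snp_landscape(chrom_lengths: Mapping[str, int],
                           background_rate: float,
                           introgression: Optional[Tuple[str, int, int, float]],
                           rng: np.random.Generator
                           ) -> Tuple[List[Tuple[str, int]],
                                      List[Tuple[str, int, int]]]:
    """Sample SNP positions only (no sequence): background rate everywhere,
    ``fold``-times elevated inside the introgressed segment.

    Returns (variants as (chrom, pos), true segments).  This is the
    variant-level path used to exercise density segmentation at realistic
    chromosome sizes without materialising sequence.
    """
    variants: List[Tuple[str, int]] = []
    segments: List[Tuple[str, int, int]] = []
    for chrom, L in chrom_lengths.items():
        n = rng.binomial(L, background_rate)
        pos = rng.integers(0, L, n)
        extra = np.empty(0, dtype=np.int64)
        if introgression and introgression[0] == chrom:
            _, s, e, fold = introgression
            seg_len = e - s
            n2 = rng.binomial(seg_len, background_rate * (fold - 1))
            extra = rng.integers(s, e, n2)
            segments.append((chrom, s, e))
        allpos = np.unique(np.concatenate([pos, extra]))
        variants.extend((chrom, int(p)) for p in allpos)
    return variants, segments


def simulate_wgs_reads(config: SimConfig, truth: TruthSet,
                       genome: Mapping[str, str]) -> Dict[str, str]:
    """WGS long reads from a donor haplotype.

    The donor differs from the reference by background SNPs, an
    introgressed elevated-SNP segment, and planted full-element TE
    insertions with target-site duplications.  Truth records every SNP and
    insertion.  Insertions are never placed inside annotated elements.
    """
    rng = np.random.default_rng([config.seed, 307])
    elements = truth.te_catalog

    insertions = config.insertions
    if insertions is None:
        insertions = []
        # mirror the study's shape: several insertions from one family,
        # one from the other (when a second family exists)
        fams = ["FAM1"] * config.n_default_insertions
        if config.n_families > 1 and config.n_default_insertions > 1:
            fams[-1] = "FAM2"
        chrom = list(genome)[0]
        L = len(genome[chrom])
        blocked = [(e.start - 20000, e.end + 20000) for e in elements
                   if e.chrom == chrom]
        k = 0
        while len(insertions) < config.n_default_insertions and k < 10000:
            k += 1
            p = int(rng.integers(50000, L - 50000))
            if any(s <= p < e for s, e in blocked):
                continue
            if any(c == chrom and abs(p - q) < 50000
                   for _, c, q, _ in insertions):
                continue
            fam = fams[len(insertions)]
            elem_seq = truth.family_consensus[fam]
            if _junction_ambiguous(genome[chrom], p, config.tsd_len,
                                   elem_seq):
                continue
            insertions.append((fam, chrom, p, config.tsd_len))
    for fam, chrom, p, _t in insertions:
        for e in elements:
            if e.chrom == chrom and e.start <= p < e.end:
                raise ValueError("insertion position inside annotated element")

    donor: Dict[str, np.ndarray] = {}
    # donor->reference coordinate bookkeeping per chromosome
    for ci, (chrom, seq) in enumerate(genome.items()):
        codes = encode_seq(seq)
        L = len(codes)
        # background SNPs
        n_bg = rng.binomial(L, config.background_snp_rate)
        snp_pos = rng.integers(0, L, n_bg)
        if config.introgression and config.introgression[0] == chrom:
            _, s, e, fold = config.introgression
            s, e = max(0, s), min(L, e)
            if e > s:
                n_seg = rng.binomial(
                    e - s, config.background_snp_rate * (fold - 1))
                snp_pos = np.concatenate([snp_pos,
                                          rng.integers(s, e, n_seg)])
                truth.introgression_segments.append((chrom, s, e))
        snp_pos = np.unique(snp_pos)
        # keep junction neighbourhoods SNP-free so planted insertion
        # breakpoints stay exactly identifiable
        for _f, c_ins, p_ins, _tl in insertions:
            if c_ins == chrom:
                snp_pos = snp_pos[np.abs(snp_pos - p_ins) > 70]
        hap = codes.copy()
        shift = rng.integers(1, 4, len(snp_pos)).astype(np.uint8)
        ref_base = hap[snp_pos]
        hap[snp_pos] = (ref_base + shift) % 4
        for p, rb, ab in zip(snp_pos, ref_base, hap[snp_pos]):
            truth.snps.append((chrom, int(p), decode_seq(np.array([rb])),
                               decode_seq(np.array([ab]))))
        # TE insertions (coordinates on the reference)
        here = sorted([ins for ins in insertions if ins[1] == chrom],
                      key=lambda x: x[2])
        pieces = []
        prev = 0
        for fam, _c, p, tl in here:
            elem_id = next(e.id for e in elements
                           if e.family == fam and e.id.endswith("c1"))
            elem = encode_seq(truth.element_seqs[elem_id])
            pieces.append(hap[prev:p])
            pieces.append(elem)
            pieces.append(hap[p - tl:p])  # TSD: duplicate of left flank
            prev = p
            truth.insertion_sites.append({
                "chrom": chrom, "position": int(p), "family": fam,
                "element": elem_id, "tsd": decode_seq(codes[p - tl:p]),
                "tsd_len": int(tl),
            })
        pieces.append(hap[prev:])
        donor[chrom] = np.concatenate(pieces)

    reads: Dict[str, str] = {}
    i = 0
    for chrom, codes in donor.items():
        L = len(codes)
        mean_len = float(np.exp(config.wgs_read_len_mu
                                + config.wgs_read_len_sigma ** 2 / 2))
        n_reads = int(round(config.wgs_depth * L / mean_len))
        lens = np.maximum(500, rng.lognormal(
            config.wgs_read_len_mu, config.wgs_read_len_sigma,
            n_reads).astype(np.int64))
        starts = rng.integers(0, np.maximum(1, L - lens))
        for j in range(n_reads):
            template = codes[starts[j]:starts[j] + lens[j]]
            if rng.random() < 0.5:
                template = revcomp_codes(template)
            read = apply_read_errors(template, rng, config.error_rates)
            reads[f"wgs_{i:06d}"] = decode_seq(read)
            i += 1
    return reads
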