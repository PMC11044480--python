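"""Sequence encoding and FASTA/FASTQ I/O helpers.

DNA is held internally as ``uint8`` code arrays (A=0, C=1, G=2, T=3, IUPAC
ambiguity letters get distinct codes >= 4).  An ambiguity code matches only
itself in alignments, so stretches of N never score as identity.
"""

from __future__ import annotations

from typing import Dict, Iterable, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = "ACGTRYSWKMBDVHN"
_COMPLEMENT = "TGCAYRSWMKVHDBN"

ENCODE = np.full(256, 14, dtype=np.uint8)  # unknown -> N
for _i, _c in enumerate(_ALPHABET):
    ENCODE[ord(_c)] = _i
    ENCODE[ord(_c.lower())] = _i
ENCODE[ord("U")] = 3
ENCODE[ord("u")] = 3

DECODE = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)
COMP = np.array([_ALPHABET.index(c) for c in _COMPLEMENT], dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array (case-insensitive)."""
    return ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode_seq(revcomp_codes(encode_seq(seq)))


def kmer_codes(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Pack every k-mer into a uint64 key (2 bits/base).

    Returns ``(keys, positions)`` for the k-mers made only of A/C/G/T;
    k-mers containing ambiguity codes are skipped.  Requires k <= 31.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    keys = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        keys = (keys << np.uint64(2)) | window.astype(np.uint64)
        valid &= window < 4
    pos = np.nonzero(valid)[0].astype(np.int64)
    return keys[pos], pos


def read_fasta(path) -> Dict[str, str]:
    """Read a multi-record FASTA into an ordered {name: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[Tuple[str, str]]) -> None:
    recs = (SeqRecord(Seq(s), id=name, description="") for name, s in records)
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")}


def write_fastq(path, records: Iterable[Tuple[str, str]]) -> None:
    """Write reads with constant base quality (quality is unused downstream)."""
    with open(path, "w") as fh:
        for name, s in records:
            fh.write(f"@{name}\n{s}\n+\n{'I' * len(s)}\n")


def read_fastx(path) -> Dict[str, str]:
    """Dispatch on extension: .fq/.fastq as FASTQ, else FASTA."""
    p = str(path)
    if p.endswith((".fq", ".fastq")):
        return read_fastq(p)
    return read_fasta(p)
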