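"""FASTA input/output and abundance-filtered spectra."""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from pathlib import Path

from Bio import SeqIO

from .dna import DNA, ComplementMap, canonical, clean_fragments, kmer_sequence
from .pipeline import SPSS

logger = logging.getLogger(__name__)

__all__ = ["read_fasta", "write_fasta", "abundance_filtered_kmers"]


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file into (header, sequence) pairs.

    Sequences are uppercased; multi-line records are joined.  A non-empty
    file whose first record line is not a header raises with the line
    number; an empty file yields an empty list with a warning.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header, got "
                    f"{line.strip()[:40]!r}"
                )
            break
        else:
            logger.warning("%s: empty FASTA file", path)
            return []
    with _open_text(path) as fh:
        records = [
            (rec.description, str(rec.seq).upper())
            for rec in SeqIO.parse(fh, "fasta")
        ]
    return records


def write_fasta(path, spss: SPSS) -> None:
    """Write an SPSS with deterministic headers; round-trips via read_fasta."""
    if not spss.strings:
        logger.warning("%s: writing empty SPSS", path)
    with open(path, "wt") as fh:
        for i, s in enumerate(spss.strings):
            fh.write(f">eulertig_{i} k={spss.k} len={len(s)}\n{s}\n")


def abundance_filtered_kmers(
    strings: list[str],
    k: int,
    min_abundance: int = 1,
    cmap: ComplementMap = DNA,
) -> list[str]:
    """Canonical k-mers occurring at least ``min_abundance`` times.

    Occurrences of a k-mer and its reverse complement are pooled (the
    count is per canonical form, across all fragments of all strings).
    Returned in first-seen order for deterministic graph construction.
    """
    if min_abundance < 1:
        raise ValueError("min_abundance must be >= 1")
    counts: Counter[str] = Counter()
    order: list[str] = []
    for frag in clean_fragments(strings, k, cmap):
        for kmer in kmer_sequence(frag, k):
            can = canonical(kmer, cmap)
            if can not in counts:
                order.append(can)
            counts[can] += 1
    return [km for km in order if counts[km] >= min_abundance]
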