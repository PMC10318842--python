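"""Alphabet, reverse complement, canonicalisation and k-mer spectra.

A k-mer is considered equal to its reverse complement throughout the
package; the *canonical* form of a k-mer is the lexicographically smaller
of the k-mer and its reverse complement.  A k-mer that equals its own
reverse complement is *self-complemental* (possible only for even k).
These string-level semantics underpin the bidirected de Bruijn graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = [
    "ComplementMap",
    "DNA",
    "CanonicalKmer",
    "Spectrum",
    "reverse_complement",
    "canonicalize",
    "canonical_spectrum",
    "kmer_sequence",
    "split_into_fragments",
    "clean_fragments",
]


class AlphabetError(ValueError):
    """A character outside the configured alphabet was encountered."""


@dataclass(frozen=True)
class ComplementMap:
    """A self-inverse character complement over an alphabet.

    Parameters
    ----------
    mapping : dict
        Character-to-character map.  Must be an involution
        (``mapping[mapping[x]] == x``) and total on its own key set,
        which defines the alphabet.
    """

    mapping: dict[str, str] = field(
        default_factory=lambda: {"A": "T", "T": "A", "C": "G", "G": "C"}
    )

    def __post_init__(self) -> None:
        for x, y in self.mapping.items():
            if len(x) != 1 or len(y) != 1:
                raise ValueError("complement map must map single characters")
            if y not in self.mapping or self.mapping[y] != x:
                raise ValueError(
                    f"complement map is not an involution at {x!r} -> {y!r}"
                )
        object.__setattr__(self, "_table", str.maketrans(self.mapping))

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(self.mapping)

    def comp(self, char: str) -> str:
        try:
            return self.mapping[char]
        except KeyError:
            raise AlphabetError(f"character {char!r} not in alphabet") from None

    def validate(self, s: str) -> None:
        """Raise :class:`AlphabetError` naming the first offending character."""
        for i, ch in enumerate(s):
            if ch not in self.mapping:
                raise AlphabetError(
                    f"invalid character {ch!r} at position {i} of {s[:50]!r}"
                )

    def rc(self, s: str) -> str:
        """Reverse complement of ``s`` (validated)."""
        self.validate(s)
        return s.translate(self._table)[::-1]


#: Default DNA alphabet with the Watson-Crick complement A<->T, C<->G.
DNA = ComplementMap()


def reverse_complement(s: str, cmap: ComplementMap = DNA) -> str:
    """Return the reversed, character-complemented string.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    return cmap.rc(s)


@dataclass(frozen=True)
class CanonicalKmer:
    """A k-mer reduced to its canonical (lexicographically <= rc) form."""

    text: str
    was_reversed: bool
    self_complemental: bool


def canonicalize(kmer: str, cmap: ComplementMap = DNA) -> CanonicalKmer:
    """Canonicalise a k-mer: ``min(kmer, rc(kmer))`` lexicographically.

    ``was_reversed`` is True iff the input was not already canonical;
    for a self-complemental k-mer it is defined as False.
    """
    rc = cmap.rc(kmer)
    if kmer == rc:
        return CanonicalKmer(kmer, was_reversed=False, self_complemental=True)
    if rc < kmer:
        return CanonicalKmer(rc, was_reversed=True, self_complemental=False)
    return CanonicalKmer(kmer, was_reversed=False, self_complemental=False)


def canonical(kmer: str, cmap: ComplementMap = DNA) -> str:
    """Shorthand for the canonical text of a k-mer."""
    rc = cmap.rc(kmer)
    return rc if rc < kmer else kmer


def kmer_sequence(s: str, k: int) -> list[str]:
    """The ``len(s) - k + 1`` consecutive k-mers of ``s``, not canonicalised.

    The k-mer at offset ``i`` covers the half-open interval ``[i, i + k)``.
    """
    if len(s) < k:
        raise ValueError(f"string of length {len(s)} is shorter than k={k}")
    return [s[i : i + k] for i in range(len(s) - k + 1)]


def split_into_fragments(s: str, cmap: ComplementMap = DNA) -> list[str]:
    """Split at every non-alphabet character into maximal valid fragments.

    Input is uppercased first (FASTA soft-masking convention).  ``N`` runs,
    IUPAC ambiguity codes and any other foreign character act as separators.
    """
    s = s.upper()
    fragments: list[str] = []
    start = None
    for i, ch in enumerate(s):
        if ch in cmap.mapping:
            if start is None:
                start = i
        else:
            if start is not None:
                fragments.append(s[start:i])
                start = None
    if start is not None:
        fragments.append(s[start:])
    return fragments


def clean_fragments(
    strings: list[str], k: int, cmap: ComplementMap = DNA
) -> list[str]:
    """Uppercase, split at non-alphabet characters, drop fragments < k.

    Dropped fragments are logged as warnings rather than raised, since
    real FASTA files routinely contain short or masked records.
    """
    out: list[str] = []
    for s in strings:
        for frag in split_into_fragments(s, cmap):
            if len(frag) >= k:
                out.append(frag)
            else:
                logger.warning(
                    "dropping fragment %r shorter than k=%d", frag[:30], k
                )
    return out


@dataclass(frozen=True)
class Spectrum:
    """The canonical k-spectrum of an input: a set of canonical k-mers."""

    k: int
    kmers: frozenset[str]

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return self.k == other.k and self.kmers == other.kmers

    def __hash__(self) -> int:
        return hash((self.k, self.kmers))


def canonical_spectrum(
    strings: list[str], k: int, cmap: ComplementMap = DNA
) -> Spectrum:
    """The set of canonical forms of every length-k substring of the input.

    Substrings of the reverse complements contribute nothing new because
    every k-mer is reduced to its canonical form.  Strings (fragments)
    shorter than k are skipped with a warning.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    kmers: set[str] = set()
    for frag in clean_fragments(strings, k, cmap):
        for kmer in kmer_sequence(frag, k):
            kmers.add(canonical(kmer, cmap))
    return Spectrum(k=k, kmers=frozenset(kmers))
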