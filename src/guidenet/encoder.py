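"""Guide-window encoding: 23 positions x 8 channels.

A guide window is the 20-nt protospacer (positions 1-20, 5'->3') followed
by the 3-nt NGG PAM (positions 21-23). The window is encoded as an
image-like matrix with a fixed channel order: four one-hot nucleotide
channels (A, C, G, T) followed by four epigenetic channels (CTCF peak,
DNase accessibility, H3K4me3 peak, RRBS methylation beta). Binary marks
are per-position 0/1 peak overlap; RRBS is a continuous beta in [0, 1].

Coordinates are 0-based half-open on the reference. Minus-strand guides
store the 5'->3' protospacer-strand sequence, and their epigenetic window
is reported in protospacer orientation (i.e. reversed relative to the
reference). Ambiguity codes (N) are rejected, not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("A", "C", "G", "T", "CTCF", "DNase", "H3K4me3", "RRBS")
NUCLEOTIDES = "ACGT"
GUIDE_LEN = 23
PROTOSPACER_LEN = 20
_NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_sequence(sequence: str) -> None:
    if len(sequence) != GUIDE_LEN:
        raise ValueError(
            f"guide window must be {GUIDE_LEN} nt, got {len(sequence)}")
    for i, base in enumerate(sequence):
        if base not in _NT_INDEX:
            raise ValueError(
                f"non-ACGT character {base!r} at position {i + 1}")


@dataclass(frozen=True)
class GuideSequence:
    """A 23-nt guide window (protospacer + PAM) anchored on the reference."""

    sequence: str
    chrom: str = "chr1"
    start: int = 0
    end: int = GUIDE_LEN
    strand: str = "+"
    cell_type: str = ""

    def __post_init__(self):
        _check_sequence(self.sequence)
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != GUIDE_LEN:
            raise ValueError("end - start must equal 23")

    @property
    def protospacer(self) -> str:
        return self.sequence[:PROTOSPACER_LEN]

    @property
    def pam(self) -> str:
        return self.sequence[PROTOSPACER_LEN:]

    @property
    def canonical_pam(self) -> bool:
        return self.sequence[21:23] == "GG"


@dataclass(frozen=True)
class EpigeneticWindow:
    """Per-position epigenetic values over the 23-nt window."""

    ctcf: np.ndarray
    dnase: np.ndarray
    h3k4me3: np.ndarray
    rrbs: np.ndarray

    def __post_init__(self):
        for name in ("ctcf", "dnase", "h3k4me3", "rrbs"):
            vec = np.asarray(getattr(self, name), dtype=np.float64)
            object.__setattr__(self, name, vec)
            if vec.shape != (GUIDE_LEN,):
                raise ValueError(f"{name} must have length {GUIDE_LEN}")
        for name in ("ctcf", "dnase", "h3k4me3"):
            vec = getattr(self, name)
            if not np.isin(vec, (0.0, 1.0)).all():
                raise ValueError(f"{name} values must be binary 0/1")
        if ((self.rrbs < 0) | (self.rrbs > 1)).any():
            raise ValueError("rrbs beta values must lie in [0, 1]")

    @classmethod
    def zeros(cls) -> "EpigeneticWindow":
        z = np.zeros(GUIDE_LEN)
        return cls(z, z.copy(), z.copy(), z.copy())


@dataclass(frozen=True)
class EncodedGuide:
    """23 x 8 matrix; nucleotide channels one-hot, all entries in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        if vals.shape != (GUIDE_LEN, len(CHANNELS)):
            raise ValueError(f"encoding must be {GUIDE_LEN}x{len(CHANNELS)}")


@dataclass(frozen=True)
class EncodedPair:
    """Two-part encoding of (on-target guide, candidate off-target site)."""

    guide_part: EncodedGuide
    site_part: EncodedGuide


def encode_guide(g: GuideSequence, e: EpigeneticWindow | None = None) -> EncodedGuide:
    """One-hot the sequence and copy epigenetic values positionally."""
    if e is None:
        e = EpigeneticWindow.zeros()
    values = np.zeros((GUIDE_LEN, len(CHANNELS)))
    for i, base in enumerate(g.sequence):
        values[i, _NT_INDEX[base]] = 1.0
    values[:, 4] = e.ctcf
    values[:, 5] = e.dnase
    values[:, 6] = e.h3k4me3
    values[:, 7] = e.rrbs
    return EncodedGuide(values)


def decode_guide(x: EncodedGuide) -> str:
    """Invert the one-hot nucleotide channels back to a 23-nt string."""
    nuc = x.values[:, :4]
    if not np.allclose(nuc.sum(axis=1), 1.0) or not np.isin(nuc, (0.0, 1.0)).all():
        bad = int(np.flatnonzero(~np.isclose(nuc.sum(axis=1), 1.0)
                                 | (~np.isin(nuc, (0.0, 1.0))).any(axis=1))[0])
        raise ValueError(f"nucleotide channels not one-hot at position {bad + 1}")
    return "".join(NUCLEOTIDES[i] for i in nuc.argmax(axis=1))


def protospacer_hamming(a: str, b: str) -> int:
    """Mismatch count over protospacer positions 1-20 (PAM excluded)."""
    if len(a) != GUIDE_LEN or len(b) != GUIDE_LEN:
        raise ValueError("both sequences must be 23 nt")
    return sum(x != y for x, y in zip(a[:PROTOSPACER_LEN], b[:PROTOSPACER_LEN]))


def encode_pair(guide: GuideSequence, site: GuideSequence,
                eg: EpigeneticWindow | None = None,
                es: EpigeneticWindow | None = None,
                max_mm: int = 6) -> EncodedPair:
    """Encode a guide/candidate-site pair as two independent 23x8 parts."""
    d = protospacer_hamming(guide.sequence, site.sequence)
    if d > max_mm:
        raise ValueError(
            f"candidate site has {d} protospacer mismatches (> {max_mm})")
    return EncodedPair(encode_guide(guide, eg), encode_guide(site, es))


def extract_epigenetics(g: GuideSequence, tracks: dict) -> EpigeneticWindow:
    """Project interval/bedGraph tracks onto the guide window.

    ``tracks`` maps mark name ('ctcf', 'dnase', 'h3k4me3', 'rrbs') to a
    per-chromosome dict of :class:`intervaltree.IntervalTree`. Binary marks
    get 1 at positions covered by any peak interval; 'rrbs' takes the beta
    value stored as interval data (0 where uncovered). Positions are in
    protospacer orientation: for a minus-strand guide the vector runs from
    the reference end backwards.
    """
    vectors = {}
    for mark in ("ctcf", "dnase", "h3k4me3", "rrbs"):
        vec = np.zeros(GUIDE_LEN)
        trees = tracks.get(mark)
        if trees is not None:
            if g.chrom not in trees:
                raise KeyError(
                    f"chromosome {g.chrom!r} absent from {mark} track")
            tree = trees[g.chrom]
            for iv in tree.overlap(g.start, g.end):
                lo = max(iv.begin, g.start)
                hi = min(iv.end, g.end)
                value = iv.data if mark == "rrbs" and iv.data is not None else 1.0
                vec[lo - g.start: hi - g.start] = value
        if g.strand == "-":
            vec = vec[::-1].copy()
        vectors[mark] = vec
    return EpigeneticWindow(vectors["ctcf"], vectors["dnase"],
                            vectors["h3k4me3"], vectors["rrbs"])


def stack_encodings(encodings: list[EncodedGuide]) -> np.ndarray:
    """Stack EncodedGuides into an (N, 23, 8) array for the nets."""
    return np.stack([e.values for e in encodings])
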