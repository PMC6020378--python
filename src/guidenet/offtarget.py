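"""Genome-wide candidate off-target enumeration and pair-dataset assembly.

A candidate off-target locus is any 23-nt window carrying a canonical GG
at PAM positions 22-23 on its protospacer strand whose protospacer
differs from the guide at <= 6 positions. The PAM's variable nucleotide is
free and PAM positions never count toward the mismatch distance. Windows
overlapping an N are skipped and counted. The scan is a vectorized naive
pass over both strands; it is checked against a brute-force oracle in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoder import (GUIDE_LEN, PROTOSPACER_LEN, EncodedPair, EpigeneticWindow,
                      GuideSequence, encode_pair, reverse_complement)

__all__ = [
    "PamSite",
    "OffTargetCandidate",
    "OffTargetPairRecord",
    "scan_pam_sites",
    "enumerate_candidates",
    "mismatch_profile",
    "assemble_pair_dataset",
    "split_leave_guides_out",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PamSite:
    chrom: str
    start: int
    end: int
    strand: str
    sequence23: str

    def __post_init__(self):
        if self.sequence23[21:23] != "GG":
            raise ValueError("PAM site must carry GG at positions 22-23")


@dataclass(frozen=True)
class OffTargetCandidate:
    site: PamSite
    mismatch_count: int
    mismatch_profile: tuple[tuple[int, str, str], ...]

    def profile_string(self) -> str:
        return ";".join(f"{p}:{a}>{b}" for p, a, b in self.mismatch_profile)


@dataclass
class OffTargetPairRecord:
    pair: EncodedPair
    detected: int
    guide_id: str
    indel_frequency: float | None = None
    assay: str = ""
    candidate: OffTargetCandidate | None = None


def _encode_seq(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes; anything non-ACGT becomes 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def scan_pam_sites(genome: dict[str, str], return_report: bool = False):
    """All 23-nt NGG windows on both strands, ordered (chrom, start, strand).

    On the plus strand a window starting at i qualifies when reference
    positions i+21, i+22 are GG; on the minus strand when i, i+1 are CC
    (the protospacer-strand read is then the reverse complement). Windows
    containing an N are skipped and tallied in the report.
    """
    if not genome:
        raise ValueError("genome is empty")
    sites: list[PamSite] = []
    skipped = 0
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        L = len(seq)
        if L < GUIDE_LEN:
            continue
        codes = _encode_seq(seq)
        n_window = np.convolve((codes == 4).astype(np.int32),
                               np.ones(GUIDE_LEN, dtype=np.int32), mode="valid")
        clean = n_window == 0
        starts = np.arange(L - GUIDE_LEN + 1)
        plus = starts[(codes[21:L - 1] == 2) & (codes[22:L] == 2) & clean]
        minus = starts[(codes[: L - GUIDE_LEN + 1] == 1)
                       & (codes[1: L - GUIDE_LEN + 2] == 1) & clean]
        skipped += int((~clean & ((codes[21:L - 1] == 2) & (codes[22:L] == 2))).sum())
        skipped += int((~clean & ((codes[: L - GUIDE_LEN + 1] == 1)
                                  & (codes[1: L - GUIDE_LEN + 2] == 1))).sum())
        per_chrom: list[PamSite] = []
        for i in plus:
            per_chrom.append(PamSite(chrom, int(i), int(i) + GUIDE_LEN, "+",
                                     seq[i: i + GUIDE_LEN]))
        for i in minus:
            per_chrom.append(PamSite(chrom, int(i), int(i) + GUIDE_LEN, "-",
                                     reverse_complement(seq[i: i + GUIDE_LEN])))
        per_chrom.sort(key=lambda s: (s.start, s.strand))
        sites.extend(per_chrom)
    if return_report:
        return sites, {"windows_skipped_n": skipped}
    return sites


def mismatch_profile(guide: str, site: str) -> list[tuple[int, str, str]]:
    """Substitutions (1-based position, guide base, site base) over 1-20."""
    if len(guide) != GUIDE_LEN or len(site) != GUIDE_LEN:
        raise ValueError("both sequences must be 23 nt")
    return [(i + 1, guide[i], site[i])
            for i in range(PROTOSPACER_LEN) if guide[i] != site[i]]


def enumerate_candidates(guide: GuideSequence, genome: dict[str, str],
                         max_mm: int = 6) -> list[OffTargetCandidate]:
    """All PAM sites within ``max_mm`` protospacer mismatches of the guide."""
    if not 0 <= max_mm <= 6:
        raise ValueError("max_mm must lie in [0, 6]")
    sites = scan_pam_sites(genome)
    if not sites:
        return []
    guide_codes = _encode_seq(guide.sequence[:PROTOSPACER_LEN])
    mat = np.stack([_encode_seq(s.sequence23[:PROTOSPACER_LEN]) for s in sites])
    dists = (mat != guide_codes).sum(axis=1)
    out = []
    for idx in np.flatnonzero(dists <= max_mm):
        site = sites[idx]
        prof = tuple(mismatch_profile(guide.sequence, site.sequence23))
        out.append(OffTargetCandidate(site, int(dists[idx]), prof))
    return out


def assemble_pair_dataset(
    guides: dict[str, GuideSequence],
    candidates: dict[str, list[OffTargetCandidate]],
    detections: pd.DataFrame | None = None,
    epigenetics: dict | None = None,
) -> tuple[list[OffTargetPairRecord], list[dict]]:
    """Label candidates against a detection table.

    ``detections`` columns: guide_id, chrom, start, strand, assay,
    indel_frequency. Candidates matching a detection row (keyed on
    guide_id/chrom/start/strand, deduplicated) are labeled 1 and carry the
    indel frequency; everything else is labeled 0. Detection rows matching
    no candidate are returned in the second element, never silently
    dropped. ``epigenetics`` optionally maps guide_id -> (guide window,
    site window) EpigeneticWindow pairs; zeros otherwise.
    """
    det_map: dict[tuple, dict] = {}
    if detections is not None:
        for _, row in detections.iterrows():
            key = (row["guide_id"], row["chrom"], int(row["start"]), row["strand"])
            det_map.setdefault(key, dict(row))  # keyed dedup, first wins
    matched: set[tuple] = set()
    records: list[OffTargetPairRecord] = []
    for guide_id, guide in guides.items():
        eg, es = (epigenetics or {}).get(guide_id, (None, None))
        for cand in candidates.get(guide_id, []):
            s = cand.site
            key = (guide_id, s.chrom, s.start, s.strand)
            site_guide = GuideSequence(s.sequence23, s.chrom, s.start, s.end,
                                       s.strand, guide.cell_type)
            pair = encode_pair(guide, site_guide, eg, es)
            if key in det_map:
                matched.add(key)
                row = det_map[key]
                freq = row.get("indel_frequency")
                freq = None if freq is None or pd.isna(freq) else float(freq)
                records.append(OffTargetPairRecord(
                    pair, 1, guide_id, freq, str(row.get("assay", "")), cand))
            else:
                records.append(OffTargetPairRecord(pair, 0, guide_id, None, "", cand))
    unmatched = [det_map[k] for k in det_map if k not in matched]
    return records, unmatched


def split_leave_guides_out(records: list[OffTargetPairRecord], k_guides: int,
                           seed: int = 0
                           ) -> tuple[list[OffTargetPairRecord], list[OffTargetPairRecord]]:
    """Hold out all pair records of ``k_guides`` randomly chosen guides."""
    guide_ids = sorted({r.guide_id for r in records})
    if k_guides >= len(guide_ids):
        raise ValueError(
            f"k_guides={k_guides} too large for {len(guide_ids)} guides")
    rng = np.random.default_rng(seed)
    held = set(rng.choice(guide_ids, size=k_guides, replace=False))
    test = [r for r in records if r.guide_id in held]
    train = [r for r in records if r.guide_id not in held]
    return train, test
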