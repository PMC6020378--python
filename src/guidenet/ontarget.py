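"""On-target training-set construction.

Labels come from knockout screens where efficacy is a log-fold change.
Two labeling schemes are supported:

* classification — binarize at a log-fold-change cutoff (default 1.0,
  boundary inclusive);
* regression — integrate efficacies measured in different experiments via
  a collaborative-filtering style normalization
  ``y_norm = y_ij - (m_row + m_column + m_all) / 3`` (all three means over
  observed entries only), followed by a rank-based normalization
  ``(rank - 0.5) / n`` with average ranks for ties.

Data augmentation exploits the observation that two mismatches at the two
PAM-distal protospacer positions leave cleavage efficacy essentially
unchanged: each seed guide spawns the 3x3 = 9 variants with exactly one
substitution at position 1 and one at position 2, inheriting the seed's
epigenetic profile and labels. Split schemes purge any sequence overlap
between train and test so augmented siblings of a test seed never leak
into training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .encoder import (GUIDE_LEN, NUCLEOTIDES, EpigeneticWindow, GuideSequence)

__all__ = [
    "OnTargetRecord",
    "EfficacyMatrix",
    "binarize_efficacy",
    "normalize_efficacy_matrix",
    "rank_normalize",
    "augment_guides",
    "split_stratified",
    "split_leave_cell_type_out",
]


@dataclass
class OnTargetRecord:
    guide: GuideSequence
    experiment_id: str = ""
    cell_type: str = ""
    raw_efficacy: float = 0.0
    binary_label: int | None = None
    normalized_label: float | None = None
    epigenetics: EpigeneticWindow | None = None
    seed_sequence: str | None = None  # provenance for augmented variants

    def __post_init__(self):
        if not math.isfinite(self.raw_efficacy):
            raise ValueError("raw_efficacy must be finite")
        if not self.cell_type:
            self.cell_type = self.guide.cell_type

    @property
    def family(self) -> str:
        """Leakage-guard key: the seed this record descends from."""
        return self.seed_sequence or self.guide.sequence


def binarize_efficacy(raw: float, cutoff: float = 1.0) -> int:
    """1 iff the log-fold change reaches the cutoff (boundary inclusive)."""
    if not math.isfinite(raw):
        raise ValueError("efficacy must be finite")
    return int(raw >= cutoff)


@dataclass
class EfficacyMatrix:
    """Experiments x guides efficacy table; NaN marks missing entries."""

    Y: pd.DataFrame

    def __post_init__(self):
        self.Y = pd.DataFrame(self.Y).astype(float)

    @property
    def m_row(self) -> pd.Series:
        return self.Y.mean(axis=1)

    @property
    def m_column(self) -> pd.Series:
        return self.Y.mean(axis=0)

    @property
    def m_all(self) -> float:
        return float(np.nanmean(self.Y.to_numpy()))


def normalize_efficacy_matrix(matrix: EfficacyMatrix | pd.DataFrame) -> pd.DataFrame:
    """Cross-experiment normalization on observed entries.

    ``y_norm = y_ij - (m_row_i + m_column_j + m_all) / 3``, every mean
    taken over observed entries only. Raises if a row or column is fully
    missing (its mean would be undefined), naming the offender.
    """
    if not isinstance(matrix, EfficacyMatrix):
        matrix = EfficacyMatrix(matrix)
    Y = matrix.Y
    empty_rows = Y.index[Y.isna().all(axis=1)]
    if len(empty_rows):
        raise ValueError(f"experiment row {empty_rows[0]!r} has no observed entries")
    empty_cols = Y.columns[Y.isna().all(axis=0)]
    if len(empty_cols):
        raise ValueError(f"guide column {empty_cols[0]!r} has no observed entries")
    baseline = (np.add.outer(matrix.m_row.to_numpy(), matrix.m_column.to_numpy())
                + matrix.m_all) / 3.0
    return Y - pd.DataFrame(baseline, index=Y.index, columns=Y.columns)


def rank_normalize(values) -> np.ndarray:
    """Map values order-preservingly into (0, 1) via ``(rank - 0.5)/n``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("rank_normalize requires at least one value")
    return (rankdata(values) - 0.5) / values.size


def augment_guides(seeds: list[OnTargetRecord], include_seed: bool = True,
                   include_singles: bool = False) -> list[OnTargetRecord]:
    """Expand seeds with PAM-distal mismatch variants, labels copied.

    Default emits the 9 double-substitution variants (one substitution at
    protospacer position 1 and one at position 2). ``include_singles`` adds
    the 6 single-substitution variants. Output is deduplicated on
    (sequence, cell_type), first occurrence wins, in deterministic order
    (seed order, then lexicographic variant bases).
    """
    out: list[OnTargetRecord] = []
    seen: set[tuple[str, str]] = set()

    def emit(rec: OnTargetRecord):
        key = (rec.guide.sequence, rec.cell_type)
        if key not in seen:
            seen.add(key)
            out.append(rec)

    for seed in seeds:
        s = seed.guide.sequence
        if len(s) < GUIDE_LEN:
            raise ValueError("seed guide shorter than 23 nt")
        if include_seed:
            emit(seed)
        variants: list[str] = []
        if include_singles:
            for pos in (0, 1):
                for b in NUCLEOTIDES:
                    if b != s[pos]:
                        variants.append(s[:pos] + b + s[pos + 1:])
        for b1 in NUCLEOTIDES:
            if b1 == s[0]:
                continue
            for b2 in NUCLEOTIDES:
                if b2 == s[1]:
                    continue
                variants.append(b1 + b2 + s[2:])
        for var in variants:
            emit(replace(
                seed,
                guide=replace(seed.guide, sequence=var),
                seed_sequence=seed.family,
            ))
    return out


def _purge_overlap(train: list[OnTargetRecord],
                   test: list[OnTargetRecord]) -> list[OnTargetRecord]:
    test_seqs = {r.guide.sequence for r in test}
    return [r for r in train if r.guide.sequence not in test_seqs]


def _label_of(rec: OnTargetRecord) -> int:
    if rec.binary_label is not None:
        return rec.binary_label
    return binarize_efficacy(rec.raw_efficacy)


def split_stratified(records: list[OnTargetRecord], test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[list[OnTargetRecord], list[OnTargetRecord]]:
    """Per-cell-type, per-label stratified split with a leakage guard.

    Splitting operates on seed families (a seed and its augmented variants
    move together), and any residual sequence overlap is purged from the
    training side.
    """
    rng = np.random.default_rng(seed)
    strata: dict[tuple[str, int], dict[str, list[OnTargetRecord]]] = {}
    for rec in records:
        fam = strata.setdefault((rec.cell_type, _label_of(rec)), {})
        fam.setdefault(rec.family, []).append(rec)
    train: list[OnTargetRecord] = []
    test: list[OnTargetRecord] = []
    for key in sorted(strata):
        families = strata[key]
        n_records = sum(len(v) for v in families.values())
        if n_records < 2:
            raise ValueError(
                f"stratum {key} has {n_records} record(s); cannot stratify")
        target = int(round(n_records * test_fraction))
        fam_keys = sorted(families)
        rng.shuffle(fam_keys)
        taken = 0
        for fk in fam_keys:
            if taken >= target:
                train.extend(families[fk])
            else:
                test.extend(families[fk])
                taken += len(families[fk])
    return _purge_overlap(train, test), test


def split_leave_cell_type_out(records: list[OnTargetRecord], held_out: str
                              ) -> tuple[list[OnTargetRecord], list[OnTargetRecord]]:
    """Hold out every record of one cell type; purge sequence overlap."""
    cell_types = {r.cell_type for r in records}
    if held_out not in cell_types:
        raise ValueError(f"unknown cell type {held_out!r}")
    if len(cell_types) < 2:
        raise ValueError("need at least two cell types to hold one out")
    test = [r for r in records if r.cell_type == held_out]
    train = [r for r in records if r.cell_type != held_out]
    return _purge_overlap(train, test), test
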