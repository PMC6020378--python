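"""Seeded synthetic data: genomes, tracks, labeled sets with planted rules.

Every generator is a pure function of (config, seed), so the whole
pipeline — encoding, normalization, augmentation, training, search,
interpretation — is exercisable with no external download. Planted rules
are linear-logistic: simple enough that recovery can be checked directly
(a position's favored base, a zone's sign), rich enough to exercise
saliency and zone recovery end to end.

What the generator emulates, and what it does not: labeled guide windows
are i.i.d. sequences at a fixed GC content with NGG PAMs; the unlabeled
pretraining corpus additionally carries position-specific base-composition
biases (the structure representation learning exploits); epigenetic marks
are window-scale (peaks are much wider than 23 nt, so a window is either
covered or not); off-target detection is a Bernoulli draw from a logistic
model over the planted positional mismatch effects, calibrated so that
roughly 1 candidate locus in ``imbalance_ratio`` (default 250) is a
detected site. Real chromatin structure and assay-specific sensitivities
are deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoder import (GUIDE_LEN, NUCLEOTIDES, PROTOSPACER_LEN, EncodedPair,
                      EncodedGuide, EpigeneticWindow, GuideSequence,
                      encode_guide)
from .ontarget import EfficacyMatrix, OnTargetRecord, binarize_efficacy
from .offtarget import OffTargetPairRecord, mismatch_profile

__all__ = [
    "PlantedRule",
    "SyntheticConfig",
    "gen_genome",
    "gen_tracks",
    "gen_ontarget_set",
    "gen_unlabeled_set",
    "gen_offtarget_set",
    "gen_efficacy_matrix",
    "default_zone_effects",
    "OffTargetSet",
    "ontarget_arrays",
]

_NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}
CELL_TYPES = ("cellA", "cellB", "cellC", "cellD")


@dataclass
class SyntheticConfig:
    seed: int
    n_guides: int = 2000
    genome_length: int = 100_000
    gc_content: float = 0.41
    imbalance_ratio: float = 250.0
    n_experiments: int = 4
    missing_rate: float = 0.3
    n_pairs: int = 20_000
    n_pair_guides: int = 30
    noise_sd: float = 0.1
    cell_types: tuple = CELL_TYPES

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.imbalance_ratio < 1:
            raise ValueError("imbalance_ratio must be >= 1")


def gen_genome(length: int, gc: float = 0.41, seed: int = 0,
               chrom: str = "chr1") -> dict[str, str]:
    """I.i.d. random genome at the requested GC fraction."""
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc content must lie in (0, 1), got {gc}")
    if length < GUIDE_LEN:
        raise ValueError(f"genome must be at least {GUIDE_LEN} nt")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.array(list(NUCLEOTIDES))[
        rng.choice(4, size=length, p=probs)])
    return {chrom: seq}


def gen_tracks(genome: dict[str, str], cell_type: str = "cellA", seed: int = 0,
               peak_density: float = 1 / 2000, peak_len: tuple[int, int] = (150, 600),
               cpg_density: float = 1 / 100) -> dict[str, pd.DataFrame]:
    """Random peak intervals (BED) + CpG methylation betas (bedGraph).

    Returns a dict keyed 'ctcf'/'dnase'/'h3k4me3' -> BED-like frames
    (chrom, start, end) and 'rrbs' -> a bedGraph-like frame with a
    ``value`` beta column.
    """
    rng = np.random.default_rng(seed)
    tracks: dict[str, pd.DataFrame] = {}
    for mark in ("ctcf", "dnase", "h3k4me3"):
        rows = []
        for chrom, seq in sorted(genome.items()):
            n_peaks = rng.poisson(len(seq) * peak_density)
            starts = np.sort(rng.integers(0, max(1, len(seq) - peak_len[1]),
                                          size=n_peaks))
            lens = rng.integers(peak_len[0], peak_len[1], size=n_peaks)
            rows += [{"chrom": chrom, "start": int(s), "end": int(s + l)}
                     for s, l in zip(starts, lens)]
        tracks[mark] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    rows = []
    for chrom, seq in sorted(genome.items()):
        n_cpg = rng.poisson(len(seq) * cpg_density)
        starts = np.sort(rng.integers(0, len(seq) - 1, size=n_cpg))
        betas = rng.beta(0.4, 0.4, size=n_cpg)
        rows += [{"chrom": chrom, "start": int(s), "end": int(s + 1),
                  "value": float(round(b, 4))} for s, b in zip(starts, betas)]
    tracks["rrbs"] = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return tracks


# ---------------------------------------------------------------------------
# Planted rules
# ---------------------------------------------------------------------------

@dataclass
class PlantedRule:
    """Linear-logistic ground-truth rule over the 23x8 encoding."""

    nucleotide_weights: np.ndarray          # (23, 4)
    epigenetic_weights: np.ndarray          # (4,) applied to channel means
    intercept: float = 0.0
    label_noise: float = 0.0
    logistic_link: bool = True

    def __post_init__(self):
        self.nucleotide_weights = np.asarray(self.nucleotide_weights, float)
        self.epigenetic_weights = np.asarray(self.epigenetic_weights, float)
        if self.nucleotide_weights.shape != (GUIDE_LEN, 4):
            raise ValueError("nucleotide_weights must be (23, 4)")
        if self.epigenetic_weights.shape != (4,):
            raise ValueError("epigenetic_weights must be (4,)")
        if not (np.isfinite(self.nucleotide_weights).all()
                and np.isfinite(self.epigenetic_weights).all()):
            raise ValueError("weights must be finite")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")

    def score(self, X: np.ndarray) -> np.ndarray:
        """Rule score for encoded guides (N, 23, 8)."""
        X = np.asarray(X, float)
        seq_part = np.einsum("npc,pc->n", X[:, :, :4], self.nucleotide_weights)
        epi_part = X[:, :, 4:].mean(axis=1) @ self.epigenetic_weights
        return seq_part + epi_part + self.intercept

    @property
    def planted_positions(self) -> np.ndarray:
        """0-based positions whose nucleotide weights are not all equal."""
        w = self.nucleotide_weights
        return np.flatnonzero(np.ptp(w, axis=1) > 0)

    @property
    def favored_bases(self) -> dict[int, str]:
        """Per planted position (0-based), the base with maximal weight."""
        return {int(p): NUCLEOTIDES[int(self.nucleotide_weights[p].argmax())]
                for p in self.planted_positions}

    @classmethod
    def random(cls, seed: int, n_positions: int = 6, weight: float = 3.0,
               epi_weight: float = 0.5, label_noise: float = 0.02
               ) -> "PlantedRule":
        """A rule favoring one base at each of ``n_positions`` protospacer
        positions (favored base +weight, alternatives -weight/3, so the
        per-position mean contribution is zero)."""
        rng = np.random.default_rng(seed)
        w = np.zeros((GUIDE_LEN, 4))
        positions = rng.choice(PROTOSPACER_LEN, size=n_positions, replace=False)
        for p in positions:
            fav = rng.integers(0, 4)
            w[p, :] = -weight / 3.0
            w[p, fav] = weight
        epi = np.full(4, epi_weight) * np.array([1, 1, 1, -1.0])
        return cls(w, epi, label_noise=label_noise)

    @classmethod
    def single_position(cls, position: int, base: str, weight: float = 4.0
                        ) -> "PlantedRule":
        w = np.zeros((GUIDE_LEN, 4))
        w[position, :] = -weight / 3.0
        w[position, _NT_INDEX[base]] = weight
        return cls(w, np.zeros(4))


def _random_guide_windows(rng: np.random.Generator, n: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, GUIDE_LEN))
    codes[:, 21] = _NT_INDEX["G"]
    codes[:, 22] = _NT_INDEX["G"]
    bases = np.array(list(NUCLEOTIDES))
    return ["".join(bases[row]) for row in codes]


def _random_epigenetics(rng: np.random.Generator, p_on: float = 0.3
                        ) -> EpigeneticWindow:
    # window-scale marks: the 23-nt window is either inside a peak or not
    on = rng.random(3) < p_on
    vecs = [np.full(GUIDE_LEN, float(o)) for o in on]
    beta = float(rng.beta(0.4, 0.4)) if rng.random() < p_on else 0.0
    return EpigeneticWindow(vecs[0], vecs[1], vecs[2],
                            np.full(GUIDE_LEN, beta))


def gen_unlabeled_set(n: int, seed: int, concentration: float = 0.25
                      ) -> np.ndarray:
    """Encoded unlabeled guide windows (n, 23, 8) for pretraining.

    Genome-wide guide populations are far from uniform: positional base
    composition is strongly biased (GC structure, PAM-adjacent context).
    This corpus emulates that with per-position base frequencies drawn
    once from a symmetric Dirichlet (low ``concentration`` = strongly
    biased positions); a denoising autoencoder can exploit those biases,
    whereas uniform random sequence is incompressible and undeniable.
    PAM positions 22-23 stay GG. Epigenetic channels carry window-scale
    marks as in the labeled generators.
    """
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(4, concentration), size=GUIDE_LEN)
    codes = np.stack([rng.choice(4, size=n, p=probs[p])
                      for p in range(GUIDE_LEN)], axis=1)
    codes[:, 21] = _NT_INDEX["G"]
    codes[:, 22] = _NT_INDEX["G"]
    X = np.zeros((n, GUIDE_LEN, 8))
    X[:, :, :4] = np.eye(4)[codes]
    marks = (rng.random((n, 3)) < 0.3).astype(float)
    beta = np.where(rng.random(n) < 0.3, rng.beta(0.4, 0.4, n), 0.0)
    X[:, :, 4:7] = marks[:, None, :]
    X[:, :, 7] = beta[:, None]
    return X


def gen_ontarget_set(rule: PlantedRule, config: SyntheticConfig
                     ) -> list[OnTargetRecord]:
    """Guides with planted continuous efficacies and binary labels.

    The rule score is mean-centered over the sampled set; the continuous
    efficacy is ``1.0 + z + noise`` on the log-fold-change scale (so the
    standard binarization cutoff of 1 matches the planted decision
    boundary), and the binary label is a Bernoulli draw through the
    logistic link (or a hard threshold), then flipped at the label-noise
    rate.
    """
    rng = np.random.default_rng(config.seed)
    seqs = _random_guide_windows(rng, config.n_guides)
    epis = [_random_epigenetics(rng) for _ in range(config.n_guides)]
    X = np.stack([encode_guide(GuideSequence(s), e).values
                  for s, e in zip(seqs, epis)])
    z = rule.score(X)
    z = z - z.mean()
    p = 1.0 / (1.0 + np.exp(-z))
    if rule.logistic_link:
        labels = (rng.random(config.n_guides) < p).astype(int)
    else:
        labels = (z >= 0).astype(int)
    flip = rng.random(config.n_guides) < rule.label_noise
    labels = np.where(flip, 1 - labels, labels)
    raw = 1.0 + z + rng.normal(0.0, config.noise_sd, size=config.n_guides)
    records = []
    for i, (s, e) in enumerate(zip(seqs, epis)):
        ct = config.cell_types[i % len(config.cell_types)]
        records.append(OnTargetRecord(
            guide=GuideSequence(s, "chr1", 0, GUIDE_LEN, "+", ct),
            experiment_id=f"exp{i % config.n_experiments + 1}",
            cell_type=ct, raw_efficacy=float(raw[i]),
            binary_label=int(labels[i]), epigenetics=e))
    return records


def ontarget_arrays(records: list[OnTargetRecord], task: str = "classification"
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Stack records into (X, y) for the nets."""
    X = np.stack([encode_guide(r.guide, r.epigenetics).values for r in records])
    if task == "classification":
        y = np.array([r.binary_label if r.binary_label is not None
                      else binarize_efficacy(r.raw_efficacy) for r in records])
    else:
        y = np.array([r.normalized_label if r.normalized_label is not None
                      else r.raw_efficacy for r in records], dtype=float)
    return X, y


# ---------------------------------------------------------------------------
# Off-target pair sets
# ---------------------------------------------------------------------------

def default_zone_effects() -> np.ndarray:
    """Planted positional effects: preference 1-3, neutral 4-15, avoiding 16-20.

    Magnitudes are strong because genuine off-target detection is highly
    separable from mismatch position and count (empirical mismatch scores
    alone rank detected sites with ROC-AUC well above 0.95): a detected
    site essentially never carries several PAM-proximal mismatches. The
    positive preference effect means sites mismatched only at PAM-distal
    positions 1-3 can be *more* detectable than average — under this truth
    the matched locus outranks sites carrying avoiding-zone mismatches,
    not every mismatched site.
    """
    eff = np.zeros(PROTOSPACER_LEN)
    eff[0:3] = 2.0
    eff[15:20] = -5.0
    return eff


@dataclass
class OffTargetSet:
    """Array-backed pair dataset with planted ground truth attached."""

    Xg: np.ndarray                 # (N, 23, 8) guide parts
    Xs: np.ndarray                 # (N, 23, 8) site parts
    detected: np.ndarray           # (N,) 0/1
    indel_frequency: np.ndarray    # (N,) NaN where undetected
    guide_ids: list[str]
    profiles: list[tuple]          # mismatch profiles per pair
    zone_effects: np.ndarray
    intercept: float

    @property
    def positive_fraction(self) -> float:
        return float(self.detected.mean())

    def records(self) -> list[OffTargetPairRecord]:
        out = []
        for i in range(len(self.detected)):
            freq = self.indel_frequency[i]
            out.append(OffTargetPairRecord(
                pair=EncodedPair(EncodedGuide(self.Xg[i]), EncodedGuide(self.Xs[i])),
                detected=int(self.detected[i]),
                guide_id=self.guide_ids[i],
                indel_frequency=None if np.isnan(freq) else float(freq),
                assay="synthetic" if self.detected[i] else ""))
        return out


_MM_COUNT_WEIGHTS = np.array([0.002, 0.008, 0.04, 0.10, 0.20, 0.30, 0.35])


def gen_offtarget_set(zone_effects: np.ndarray | None = None,
                      config: SyntheticConfig | None = None,
                      seed: int | None = None) -> OffTargetSet:
    """Pairs with 0-6 planted mismatches and logistic detection labels.

    Detection probability is ``sigmoid(c + sum of positional effects over
    the pair's mismatches)``; the intercept c is calibrated by bisection
    so the mean detection probability equals ``1/imbalance_ratio``.
    Detected pairs draw a positive indel frequency.
    """
    config = config or SyntheticConfig(seed=seed if seed is not None else 0)
    effects = (default_zone_effects() if zone_effects is None
               else np.asarray(zone_effects, float))
    if effects.shape != (PROTOSPACER_LEN,):
        raise ValueError(f"zone effects must have length {PROTOSPACER_LEN}")
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    guide_seqs = _random_guide_windows(rng, config.n_pair_guides)
    guide_codes = np.stack([[_NT_INDEX[b] for b in s] for s in guide_seqs])
    which = rng.integers(0, config.n_pair_guides, size=n)
    site_codes = guide_codes[which].copy()
    mm_counts = rng.choice(7, size=n, p=_MM_COUNT_WEIGHTS)
    logits = np.zeros(n)
    profiles: list[tuple] = []
    bases = np.array(list(NUCLEOTIDES))
    for i in range(n):
        m = mm_counts[i]
        pos = rng.choice(PROTOSPACER_LEN, size=m, replace=False)
        pos.sort()
        prof = []
        for p in pos:
            old = site_codes[i, p]
            new = (old + rng.integers(1, 4)) % 4
            site_codes[i, p] = new
            prof.append((int(p) + 1, NUCLEOTIDES[old], NUCLEOTIDES[new]))
            logits[i] += effects[p]
        profiles.append(tuple(prof))
    # calibrate the intercept to the target positive rate
    target = 1.0 / config.imbalance_ratio
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if np.mean(1.0 / (1.0 + np.exp(-(logits + mid)))) > target:
            hi = mid
        else:
            lo = mid
    intercept = (lo + hi) / 2
    p_detect = 1.0 / (1.0 + np.exp(-(logits + intercept)))
    detected = (rng.random(n) < p_detect).astype(int)
    indel = np.full(n, np.nan)
    n_pos = int(detected.sum())
    indel[detected == 1] = rng.lognormal(mean=-2.0, sigma=1.0, size=n_pos)

    onehot = np.eye(4)
    Xg = np.zeros((n, GUIDE_LEN, 8))
    Xs = np.zeros((n, GUIDE_LEN, 8))
    Xg[:, :, :4] = onehot[guide_codes[which]]
    Xs[:, :, :4] = onehot[site_codes]
    # window-scale epigenetics per guide / per site
    epi_g = (rng.random((config.n_pair_guides, 3)) < 0.3).astype(float)
    beta_g = np.where(rng.random(config.n_pair_guides) < 0.3,
                      rng.beta(0.4, 0.4, config.n_pair_guides), 0.0)
    Xg[:, :, 4:7] = epi_g[which][:, None, :]
    Xg[:, :, 7] = beta_g[which][:, None]
    epi_s = (rng.random((n, 3)) < 0.3).astype(float)
    beta_s = np.where(rng.random(n) < 0.3, rng.beta(0.4, 0.4, n), 0.0)
    Xs[:, :, 4:7] = epi_s[:, None, :]
    Xs[:, :, 7] = beta_s[:, None]

    return OffTargetSet(
        Xg=Xg, Xs=Xs, detected=detected, indel_frequency=indel,
        guide_ids=[f"sg{w + 1:02d}" for w in which], profiles=profiles,
        zone_effects=effects, intercept=float(intercept))


# ---------------------------------------------------------------------------
# Efficacy matrices
# ---------------------------------------------------------------------------

@dataclass
class SyntheticEfficacyMatrix(EfficacyMatrix):
    planted_guide_effects: np.ndarray = field(default_factory=lambda: np.zeros(0))
    planted_experiment_offsets: np.ndarray = field(default_factory=lambda: np.zeros(0))


def gen_efficacy_matrix(n_experiments: int, n_guides: int,
                        missing_rate: float = 0.3, seed: int = 0,
                        noise_sd: float = 0.1) -> SyntheticEfficacyMatrix:
    """Additive experiments x guides matrix with a missingness mask.

    ``y_ij = guide_effect_j + experiment_offset_i + noise``; entries are
    masked at ``missing_rate`` but every row and column keeps at least one
    observation (a deterministic repair un-masks one entry if needed).
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    guide_eff = rng.normal(0.0, 1.0, size=n_guides)
    # modest offsets: the normalization removes only a third of the row
    # effect per entry, so huge offsets would leak through missingness
    exp_off = rng.normal(0.0, 1.0, size=n_experiments)
    Y = (exp_off[:, None] + guide_eff[None, :]
         + rng.normal(0.0, noise_sd, size=(n_experiments, n_guides)))
    mask = rng.random(Y.shape) < missing_rate
    for i in range(n_experiments):           # repair empty rows
        if mask[i].all():
            mask[i, int(rng.integers(n_guides))] = False
    for j in range(n_guides):                # repair empty columns
        if mask[:, j].all():
            mask[int(rng.integers(n_experiments)), j] = False
    Y = pd.DataFrame(np.where(mask, np.nan, Y),
                     index=[f"exp{i + 1}" for i in range(n_experiments)],
                     columns=[f"g{j + 1}" for j in range(n_guides)])
    return SyntheticEfficacyMatrix(Y, planted_guide_effects=guide_eff,
                                   planted_experiment_offsets=exp_off)
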