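"""Feature-saliency interpretation of trained models.

Three complementary views:

* **Activation maximization** — gradient ascent on the class score
  ``S_c(g) - lambda * ||g||^2`` over a synthetic input ``g`` whose
  per-position nucleotide block is constrained to the probability simplex
  and whose epigenetic channels are clipped to [0, 1]. The optimized input
  is a class-representative "synthetic guide": which bases (and chromatin
  states) the model considers characteristic of, e.g., efficacious guides.

* **Substitution effect maps** — for the pair model, the mean change in
  predicted off-target probability when the candidate site's base at
  protospacer position p is substituted X->Y, relative to the matched
  (X->X) site, averaged over background pairs: a 20 x (4x4) grid. Because
  detected off-target counts are small, cells are filtered by a two-sided
  Fisher exact test on (substitution present/absent) x (detected/not)
  counts; non-significant cells render as hyphens.

* **Zones** — the per-position averaged map partitions positions 1-20
  into contiguous preference / undetermined / avoiding ranges around a
  threshold (default: half the map's standard deviation).

The duplex rX:dY notation used by mismatch heatmaps fixes the guide (RNA)
base and names the DNA target-strand base; a protospacer-strand
substitution X->Y corresponds to rX:dZ with Z the Watson-Crick complement
of Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .encoder import NUCLEOTIDES, PROTOSPACER_LEN

__all__ = [
    "SaliencyConfig",
    "SaliencyMap",
    "SubstitutionEffectMap",
    "ZonePartition",
    "activation_maximize",
    "substitution_effect_map",
    "substitution_count_tables",
    "fisher_filter",
    "substitution_to_duplex_notation",
    "duplex_to_substitution",
    "zone_partition",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


def project_simplex_rows(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n = V.shape[1]
    U = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ind = np.arange(1, n + 1)
    cond = U - css / ind > 0
    rho = n - 1 - cond[:, ::-1].argmax(axis=1)
    theta = css[np.arange(len(V)), rho] / (rho + 1)
    return np.maximum(V - theta[:, None], 0.0)


@dataclass
class SaliencyConfig:
    iterations: int = 500
    step: float = 0.1
    l2: float = 1e-3
    seed: int = 0


@dataclass
class SaliencyMap:
    g: np.ndarray           # optimized synthetic input, (23, 8)
    c: int                  # class of interest
    score: float            # final S_c
    trace: list[float]      # S_c per iteration

    def top_bases(self) -> str:
        return "".join(NUCLEOTIDES[i] for i in self.g[:, :4].argmax(axis=1))


def _project(g: np.ndarray) -> np.ndarray:
    g = g.copy()
    g[:, :4] = project_simplex_rows(g[:, :4])
    g[:, 4:] = np.clip(g[:, 4:], 0.0, 1.0)
    return g


def activation_maximize(model, c: int = 1,
                        config: SaliencyConfig | None = None) -> SaliencyMap:
    """Synthesize the class-representative input by projected gradient ascent.

    ``model`` needs ``class_score(X, c)`` and ``input_grad(X, c)`` (any
    trained on-target model qualifies; a toy scorer exposing the same two
    methods works for testing). Starts from the uniform input (nucleotide
    channels 0.25, epigenetic channels 0.5); each accepted step must not
    decrease the penalized objective (backtracking halves the step
    otherwise), so the score trace is non-decreasing up to tolerance.
    """
    config = config or SaliencyConfig()
    L, C = 23, 8
    g = np.full((L, C), 0.5)
    g[:, :4] = 0.25

    def objective(x):
        s = float(model.class_score(x[None], c)[0])
        return s, s - config.l2 * float((x ** 2).sum())

    score, obj = objective(g)
    trace = [score]
    for _ in range(config.iterations):
        grad = model.input_grad(g[None], c)[0] - 2.0 * config.l2 * g
        if not np.isfinite(grad).all():
            raise RuntimeError(
                f"non-finite gradient during ascent; trace: {trace}")
        step = config.step
        accepted = False
        for _try in range(8):
            cand = _project(g + step * grad)
            cand_score, cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                g, score, obj = cand, cand_score, cand_obj
                accepted = True
                break
            step *= 0.5
        trace.append(score)
        if not accepted:
            break
    return SaliencyMap(g=g, c=c, score=score, trace=trace)


@dataclass
class SubstitutionEffectMap:
    """Positions 1-20 x (guide base -> site base) effect grid."""

    effects: np.ndarray          # (20, 4, 4); diagonal fixed at 0
    counts: np.ndarray           # (20, 4, 4) background pairs per cell
    pvalues: np.ndarray | None = None
    significant: np.ndarray | None = None

    def averaged(self) -> np.ndarray:
        """Per-position mean effect over the 12 mismatch cells."""
        off = ~np.eye(4, dtype=bool)
        return self.effects[:, off].mean(axis=1)

    def to_frame(self, masked: bool = False) -> pd.DataFrame:
        """Long-format table; non-significant cells become '-' if masked."""
        rows = []
        for p in range(PROTOSPACER_LEN):
            for xi, X in enumerate(NUCLEOTIDES):
                for yi, Y in enumerate(NUCLEOTIDES):
                    if xi == yi:
                        continue
                    val = self.effects[p, xi, yi]
                    shown: object = val
                    if masked and self.significant is not None \
                            and not self.significant[p, xi, yi]:
                        shown = "-"
                    rows.append({
                        "position": p + 1, "substitution": f"{X}>{Y}",
                        "duplex": substitution_to_duplex_notation(X, Y),
                        "effect": shown, "n": int(self.counts[p, xi, yi]),
                    })
        return pd.DataFrame(rows)


def substitution_effect_map(model, Xg: np.ndarray, Xs: np.ndarray
                            ) -> SubstitutionEffectMap:
    """Model-based substitution effects averaged over background pairs.

    For each background pair, position p and site base Y, the effect is
    ``score(site with base Y at p) - score(matched site with the guide's
    base at p)``; contributions are binned by the pair's guide base X.
    """
    Xg = np.asarray(Xg, dtype=np.float64)
    Xs = np.asarray(Xs, dtype=np.float64)
    if Xg.shape[0] == 0:
        raise ValueError("empty background pair set")
    n = Xg.shape[0]
    guide_bases = Xg[:, :, :4].argmax(axis=2)  # (n, 23)
    effects = np.zeros((PROTOSPACER_LEN, 4, 4))
    counts = np.zeros((PROTOSPACER_LEN, 4, 4), dtype=np.int64)
    eye = np.eye(4)
    for p in range(PROTOSPACER_LEN):
        base_site = Xs.copy()
        base_site[:, p, :4] = eye[guide_bases[:, p]]
        matched = model.predict(Xg, base_site)
        for yi in range(4):
            sub_site = Xs.copy()
            sub_site[:, p, :4] = eye[yi]
            delta = model.predict(Xg, sub_site) - matched
            for xi in range(4):
                if xi == yi:
                    continue
                sel = guide_bases[:, p] == xi
                if sel.any():
                    effects[p, xi, yi] += delta[sel].sum()
                    counts[p, xi, yi] += int(sel.sum())
    with np.errstate(invalid="ignore"):
        effects = np.where(counts > 0, effects / np.maximum(counts, 1), 0.0)
    return SubstitutionEffectMap(effects=effects, counts=counts)


def substitution_count_tables(profiles, detected) -> np.ndarray:
    """2x2 tables (substitution present/absent x detected/not) per cell.

    ``profiles`` is a list of mismatch profiles (tuples of
    (1-based position, guide base, site base)); ``detected`` the matching
    0/1 labels. Returns a (20, 4, 4, 2, 2) array where
    ``table[p,x,y] = [[a, b], [c, d]]`` with a = detected pairs carrying
    the substitution, b = undetected carrying it, c/d = the rest.
    """
    detected = np.asarray(detected)
    n_pos = int(detected.sum())
    n_neg = int(len(detected) - n_pos)
    tables = np.zeros((PROTOSPACER_LEN, 4, 4, 2, 2), dtype=np.int64)
    for prof, lab in zip(profiles, detected):
        for pos, X, Y in prof:
            tables[pos - 1, _NT_INDEX[X], _NT_INDEX[Y], 0, 0 if lab else 1] += 1
    tables[..., 1, 0] = n_pos - tables[..., 0, 0]
    tables[..., 1, 1] = n_neg - tables[..., 0, 1]
    return tables


def fisher_filter(tables: np.ndarray, alpha: float = 0.05,
                  bh_correct: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher exact p-value per 2x2 table + significance mask."""
    tables = np.asarray(tables)
    if (tables < 0).any():
        raise ValueError("counts must be non-negative")
    flat = tables.reshape(-1, 2, 2)
    pvals = np.array([fisher_exact(t, alternative="two-sided")[1] for t in flat])
    if bh_correct:
        m = len(pvals)
        order = np.argsort(pvals)
        adj = pvals[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        padj = np.empty_like(pvals)
        padj[order] = np.minimum(adj, 1.0)
        mask = padj < alpha
    else:
        mask = pvals < alpha
    shape = tables.shape[:-2]
    return pvals.reshape(shape), mask.reshape(shape)


def substitution_to_duplex_notation(X: str, Y: str) -> str:
    """Protospacer-strand substitution X->Y as RNA:DNA duplex ``rX:dZ``.

    The guide keeps its base as RNA; the DNA target-strand base is the
    Watson-Crick complement of the substituted site base, so G->C maps to
    rG:dG and G->T to rG:dA. The identity X->X maps to the perfect-match
    duplex rX:d(complement X).
    """
    if X not in _COMP or Y not in _COMP:
        raise ValueError(f"invalid base in substitution {X!r}->{Y!r}")
    return f"r{X}:d{_COMP[Y]}"


def duplex_to_substitution(duplex: str) -> tuple[str, str]:
    """Inverse of :func:`substitution_to_duplex_notation`."""
    try:
        r, d = duplex.split(":")
        X, Z = r.removeprefix("r"), d.removeprefix("d")
    except ValueError as exc:
        raise ValueError(f"malformed duplex notation {duplex!r}") from exc
    if X not in _COMP or Z not in _COMP:
        raise ValueError(f"invalid base in duplex notation {duplex!r}")
    return X, _COMP[Z]


ZONE_LABELS = ("preference", "undetermined", "avoiding")


@dataclass
class ZonePartition:
    """Contiguous labeled ranges partitioning protospacer positions 1-20."""

    ranges: list[tuple[int, int, str]]  # (start, end, label), 1-based inclusive

    def label_at(self, position: int) -> str:
        for lo, hi, lab in self.ranges:
            if lo <= position <= hi:
                return lab
        raise ValueError(f"position {position} outside 1-20")


def zone_partition(avg_map, tau: float | None = None) -> ZonePartition:
    """Label positions by mean substitution effect and merge runs.

    effect > tau -> preference (substitutions there still permit
    off-target cleavage); effect < -tau -> avoiding; else undetermined.
    ``tau`` defaults to half the map's standard deviation.
    """
    avg = np.asarray(avg_map, dtype=float)
    if avg.shape != (PROTOSPACER_LEN,):
        raise ValueError(f"need {PROTOSPACER_LEN} per-position values")
    if tau is None:
        tau = float(avg.std()) / 2.0
    labels = np.where(avg > tau, "preference",
                      np.where(avg < -tau, "avoiding", "undetermined"))
    ranges: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, PROTOSPACER_LEN + 1):
        if i == PROTOSPACER_LEN or labels[i] != labels[start]:
            ranges.append((start + 1, i, str(labels[start])))
            start = i
    return ZonePartition(ranges)
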