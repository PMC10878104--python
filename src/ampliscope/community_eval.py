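"""Community profiles, dissimilarity, PCoA and diagnostic concordance.

Species-level relative-abundance profiles built from classifications are
compared across sequencing strategies with four ecological dissimilarities
(Bray–Curtis, Euclidean, quantitative Jaccard, quantitative Kulczynski) and
embedded by classical principal-coordinates analysis.  Diagnostic agreement
between sequencing-based presence calls (relative abundance ≥ 0.1%) and an
external PCR test is summarized by the full confusion-matrix metric panel,
including Cohen's kappa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifiers import ClassificationResult

UNCLASSIFIED = "unclassified"


@dataclass
class AbundanceProfile:
    """Relative species abundances for one sample; sums to 1.

    Mass from reads not classified to species level is held under the
    explicit ``unclassified`` key rather than discarded.
    """

    sample_id: str
    abundances: dict[str, float]
    n_reads: int = 0

    def __post_init__(self) -> None:
        for sp, a in self.abundances.items():
            if a < 0:
                raise ValueError(f"negative abundance for {sp!r}: {a}")
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, not 1")

    def get(self, species: str) -> float:
        return self.abundances.get(species, 0.0)

    def species(self, include_unclassified: bool = True) -> list[str]:
        return [s for s in self.abundances
                if include_unclassified or s != UNCLASSIFIED]


def profile_from_classifications(results: Sequence[ClassificationResult],
                                 sample_id: str) -> AbundanceProfile:
    """Normalize species counts into a profile; sub-species truncations pool
    into ``unclassified``."""
    if not results:
        raise ValueError("cannot build a profile from zero classifications")
    counts: dict[str, int] = {}
    for r in results:
        sp = r.species or UNCLASSIFIED
        counts[sp] = counts.get(sp, 0) + 1
    n = len(results)
    return AbundanceProfile(sample_id,
                            {sp: c / n for sp, c in sorted(counts.items())},
                            n_reads=n)


def profile_from_counts(counts: Mapping[str, float], sample_id: str
                        ) -> AbundanceProfile:
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("counts must sum to a positive value")
    return AbundanceProfile(sample_id,
                            {sp: c / total for sp, c in sorted(counts.items())},
                            n_reads=int(total))


METRICS = ("bray-curtis", "euclidean", "jaccard", "kulczynski")


def _aligned(x: AbundanceProfile, y: AbundanceProfile,
             drop_unclassified: bool) -> tuple[np.ndarray, np.ndarray]:
    keys = sorted(set(x.abundances) | set(y.abundances))
    if drop_unclassified:
        keys = [k for k in keys if k != UNCLASSIFIED]
    xv = np.array([x.get(k) for k in keys])
    yv = np.array([y.get(k) for k in keys])
    return xv, yv


def dissimilarity(x: AbundanceProfile, y: AbundanceProfile, metric: str,
                  drop_unclassified: bool = False,
                  binary_jaccard: bool = False) -> float:
    """Dissimilarity between two profiles aligned on the union of species.

    * ``bray-curtis``: Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)
    * ``euclidean``:  √Σ(xᵢ−yᵢ)²
    * ``jaccard``:    2B/(1+B) with B the Bray–Curtis value (abundance-weighted
      form; ``binary_jaccard=True`` switches to presence/absence)
    * ``kulczynski``: 1 − ½(Σmin/Σx + Σmin/Σy)

    All four are symmetric and zero on identical profiles.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    xv, yv = _aligned(x, y, drop_unclassified)
    sx, sy = xv.sum(), yv.sum()
    if sx == 0 or sy == 0:
        raise ValueError("dissimilarity undefined for an all-zero profile")
    if metric == "euclidean":
        return float(np.sqrt(((xv - yv) ** 2).sum()))
    if metric == "jaccard" and binary_jaccard:
        a = (xv > 0) & (yv > 0)
        union = (xv > 0) | (yv > 0)
        return float(1.0 - a.sum() / union.sum())
    bray = float(np.abs(xv - yv).sum() / (sx + sy))
    if metric == "bray-curtis":
        return bray
    if metric == "jaccard":
        return 2.0 * bray / (1.0 + bray)
    smin = np.minimum(xv, yv).sum()
    return float(1.0 - 0.5 * (smin / sx + smin / sy))


def distance_matrix(profiles: Sequence[AbundanceProfile], metric: str,
                    **kwargs) -> tuple[list[str], np.ndarray]:
    ids = [p.sample_id for p in profiles]
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dissimilarity(profiles[i], profiles[j],
                                              metric, **kwargs)
    return ids, d


@dataclass
class PCoAResult:
    coordinates: np.ndarray          # (n_samples, n_axes), axes sorted by eigenvalue
    eigenvalues: np.ndarray          # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # over positive eigenvalues only
    sample_ids: list[str] = field(default_factory=list)


def pcoa(distances: np.ndarray, sample_ids: Sequence[str] | None = None,
         cailliez: bool = False) -> PCoAResult:
    """Classical metric scaling of a dissimilarity matrix.

    Double-centers −½D², eigendecomposes, and keeps positive-eigenvalue axes
    sorted descending.  Negative eigenvalues are reported, not corrected, by
    default; ``cailliez=True`` applies the Cailliez constant-addition
    correction first.  Axis signs are fixed by making each axis's
    largest-magnitude loading positive.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")

    if cailliez:
        d = _cailliez(d)

    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    tol = max(1e-12, 1e-12 * max(abs(vals[0]), 1.0))
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    for a in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, a])))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    pos_sum = vals[pos].sum()
    prop = vals[pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    return PCoAResult(coordinates=coords, eigenvalues=vals,
                      proportion_explained=prop,
                      sample_ids=list(sample_ids) if sample_ids else [])


def _cailliez(d: np.ndarray) -> np.ndarray:
    """Smallest constant c making d + c (off-diagonal) Euclidean-embeddable."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b1 = -0.5 * j @ (d ** 2) @ j
    b2 = -0.5 * j @ d @ j
    zero = np.zeros((n, n))
    m = np.block([[zero, 2 * b1], [-np.eye(n), -4 * b2]])
    c = float(np.max(np.linalg.eigvals(m).real))
    if c <= 0:
        return d
    out = d + c
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# STI positivity and confusion-matrix metrics
# ---------------------------------------------------------------------------

#: default positivity threshold: relative abundance ≥ 0.1%
POSITIVITY_THRESHOLD = 0.001


def sti_positivity(profile: AbundanceProfile, pathogens: Iterable[str],
                   threshold: float = POSITIVITY_THRESHOLD) -> dict[str, str]:
    """Call each pathogen positive iff its relative abundance ≥ threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return {p: ("positive" if profile.get(p) >= threshold else "negative")
            for p in pathogens}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_calls(seq_calls: Mapping[str, str],
                         reference_calls: Mapping[str, str]) -> ConfusionMatrix:
    """Cross-tabulate sequencing-based calls against a reference test.

    Both maps are sample-id → "positive"/"negative"; only shared samples are
    counted.
    """
    tp = fp = tn = fn = 0
    for sid, call in seq_calls.items():
        if sid not in reference_calls:
            continue
        ref = reference_calls[sid]
        pos, refpos = call == "positive", ref == "positive"
        if pos and refpos:
            tp += 1
        elif pos and not refpos:
            fp += 1
        elif not pos and refpos:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, tn, fn)


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float
    accuracy: float
    kappa: float


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: denominator is zero; reporting NaN", stacklevel=3)
        return math.nan
    return num / den


def confusion_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The seven standard confusion-matrix metrics.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); precision = TP/(TP+FP);
    recall ≡ sensitivity; F1 = 2·precision·recall/(precision+recall);
    accuracy = (TP+TN)/total; kappa = (accuracy − Pe)/(1 − Pe) with
    Pe = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / total².  Undefined cells yield
    NaN with a warning.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is all zero")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    n = cm.total
    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    prec = _ratio(tp, tp + fp, "precision")
    recall = sens
    if math.isnan(prec) or math.isnan(recall) or (prec + recall) == 0:
        warnings.warn("F1: undefined; reporting NaN", stacklevel=2)
        f1 = math.nan
    else:
        f1 = 2 * prec * recall / (prec + recall)
    acc = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n ** 2
    if abs(1 - pe) < 1e-15:
        warnings.warn("kappa: Pe = 1, chance-corrected agreement undefined; "
                      "reporting NaN", stacklevel=2)
        kappa = math.nan
    else:
        kappa = (acc - pe) / (1 - pe)
    return MetricsReport(sensitivity=sens, specificity=spec, precision=prec,
                         recall=recall, f1=f1, accuracy=acc, kappa=kappa)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def profiles_to_tsv(profiles: Sequence[AbundanceProfile], path: str | Path) -> None:
    """Samples × species TSV (union of species, zero-filled)."""
    species = sorted({s for p in profiles for s in p.abundances})
    df = pd.DataFrame([[p.get(s) for s in species] for p in profiles],
                      index=[p.sample_id for p in profiles], columns=species)
    df.to_csv(path, sep="\t", index_label="sample_id")


def profiles_from_tsv(path: str | Path) -> list[AbundanceProfile]:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    out = []
    for sid, row in df.iterrows():
        ab = {sp: float(v) for sp, v in row.items() if v > 0}
        total = sum(ab.values())
        ab = {sp: v / total for sp, v in ab.items()}
        out.append(AbundanceProfile(str(sid), ab, n_reads=0))
    return out


def read_pcr_tsv(path: str | Path) -> dict[str, dict[str, str]]:
    """PCR validation TSV (sample_id, pathogen, result {pos,neg}) →
    pathogen → {sample_id → "positive"/"negative"}."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, str]] = {}
    for r in df.itertuples():
        res = str(r.result).lower()
        call = "positive" if res in ("pos", "positive", "1", "true") else "negative"
        out.setdefault(str(r.pathogen), {})[str(r.sample_id)] = call
    return out
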