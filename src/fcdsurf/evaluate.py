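"""Patient-level evaluation statistics.

Patients count as true positive when the major (highest-peak) detected
cluster overlaps the surgical resection label; controls count as true
negative when no cluster is flagged at all.  Sensitivity, specificity and
accuracy follow the usual ratios; agreement between the automated calls
and the resection-defined ground truth is summarized by Cohen's kappa with
the conventional qualitative bands.  Group comparisons use Pearson's
chi-square (no continuity correction), Fisher's exact test, or the
Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import DetectionCluster
from .surface import VertexLabel

KAPPA_BANDS = (  # inclusive upper edges
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Patient-level confusion counts: TP/FN over patients, FP/TN controls."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_patients(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    def as_table(self) -> np.ndarray:
        """2x2 agreement table: rows = truth (patient/control), columns =
        automated call (positive-at-truth / negative)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy overall.

    A metric with a zero denominator is returned as NaN.
    """
    out = {}
    out["sensitivity"] = c.tp / c.n_patients if c.n_patients else np.nan
    out["specificity"] = c.tn / c.n_controls if c.n_controls else np.nan
    total = c.n_patients + c.n_controls
    out["accuracy"] = (c.tp + c.tn) / total if total else np.nan
    return out


def cohens_kappa(table: np.ndarray) -> dict:
    """Chance-corrected agreement kappa = (Po - Pe)/(1 - Pe) on a 2x2
    agreement table, with the qualitative band (inclusive upper edges:
    exactly 0.20 is 'slight', 0.40 'fair', ...)."""
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    po = np.trace(t) / n
    pe = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / n ** 2
    if abs(1.0 - pe) < 1e-15:
        return {"kappa": np.nan, "band": "undefined"}
    kappa = (po - pe) / (1.0 - pe)
    band = KAPPA_BANDS[-1][1]
    for upper, name in KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            band = name
            break
    return {"kappa": float(kappa), "band": band}


def pearson_chi_square(table: np.ndarray) -> dict:
    """Pearson chi-square without continuity correction, df=1 for 2x2."""
    t = np.asarray(table, dtype=np.float64)
    if (t < 0).any() or t.sum() <= 0:
        raise ValueError("table must be non-negative with positive total")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected <= 0).any():
        raise ValueError("zero expected count; chi-square undefined")
    if (expected < 5).any():
        warnings.warn("expected count below 5; consider Fisher's exact test")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return {"statistic": float(stat), "df": int(dof), "p": float(p)}


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided hypergeometric exact p for a 2x2 table."""
    t = np.asarray(table)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def mann_whitney_u(x, y) -> dict:
    """Two-sided Mann-Whitney U with normal approximation and tie
    correction; U counts wins of x over y."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic")
    return {"U": float(u), "p": float(p)}


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two vertex index sets."""
    a = np.unique(np.asarray(a))
    b = np.unique(np.asarray(b))
    if a.size + b.size == 0:
        return np.nan
    inter = np.intersect1d(a, b).size
    return 2.0 * inter / (a.size + b.size)


def concordance(clusters: list[DetectionCluster],
                resection: VertexLabel,
                hemisphere: str | None = None) -> dict:
    """Concordant iff the major (highest-peak) cluster shares at least one
    vertex with the resection label.

    Only the major cluster counts; a lower-ranked overlapping cluster does
    not rescue a discordant call.  When the clusters carry hemisphere tags,
    ``hemisphere`` restricts the overlap test to the resection hemisphere.
    Returns the boolean call plus the Dice overlap of the major cluster as
    an auxiliary quantity.
    """
    if resection is None or len(resection) == 0:
        raise ValueError("empty resection label")
    if not clusters:
        return {"concordant": False, "dice": 0.0}
    top = max(clusters, key=lambda c: c.peak_probability)
    if hemisphere is not None and top.hemisphere is not None \
            and top.hemisphere != hemisphere:
        return {"concordant": False, "dice": 0.0}
    d = dice(top.vertices, resection.indices)
    overlap = np.intersect1d(top.vertices, resection.indices).size > 0
    return {"concordant": bool(overlap), "dice": float(d)}
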