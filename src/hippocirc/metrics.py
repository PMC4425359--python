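"""Evaluation statistics: recall correlations, confusion, separation, spatial firing.

Memory performance is pattern completion: the Pearson correlation between a
recalled pattern and its stored original, averaged over all stored patterns
and plotted against cue quality.  A cue counts as *confused* when its
reconstruction correlates more with some other stored pattern than with its
own original.  Pattern separation is summarised by the slope of the
regression of pairwise CA3 correlations on pairwise EC correlations — the
flatter, the better the separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .dynamics import PatternSet
from .plasticity import ActivationDecomposition

__all__ = [
    "pearson",
    "rowwise_pearson",
    "cross_correlations",
    "recall_curve",
    "confusion",
    "SeparationResult",
    "separation_index",
    "SpatialFiringMap",
    "conditional_firing",
    "overlap_vs_distance",
    "activation_histograms",
]

log = logging.getLogger(__name__)


def pearson(p: np.ndarray, q: np.ndarray) -> float:
    """Sample Pearson correlation; 0 for zero-variance input (logged)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("length mismatch")
    if p.size < 2:
        raise ValueError("need at least two entries")
    pc = p - p.mean()
    qc = q - q.mean()
    denom = np.linalg.norm(pc) * np.linalg.norm(qc)
    if denom == 0.0:
        log.debug("pearson: zero-variance input, returning 0 (degenerate)")
        return 0.0
    return float(pc @ qc / denom)


def _standardize_rows(a: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ac, axis=1, keepdims=True)
    ok = norms[:, 0] > 0
    out = np.zeros_like(ac)
    out[ok] = ac[ok] / norms[ok]
    return out


def rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of corresponding rows of two (M, n) arrays."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return np.einsum("ij,ij->i", _standardize_rows(a), _standardize_rows(b))


def cross_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs Pearson matrix between rows of a (M, n) and rows of b (K, n)."""
    return _standardize_rows(np.atleast_2d(a)) @ _standardize_rows(np.atleast_2d(b)).T


def recall_curve(report: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-cue rows into one row per cue-quality level.

    Expects columns `n_wrong`, `cue_quality` and any of `corr_ca3`,
    `corr_ca1`, `corr_ec`, `correct`.  Returns per-level means plus an
    `above_diagonal` flag (mean output correlation exceeds mean cue quality).
    """
    value_cols = [c for c in ("cue_quality", "corr_ca3", "corr_ca1", "corr_ec",
                              "correct") if c in report.columns]
    curve = report.groupby("n_wrong", sort=True)[value_cols].mean().reset_index()
    if "corr_ec" in curve:
        curve["above_diagonal"] = curve["corr_ec"] > curve["cue_quality"]
    return curve


def confusion(
    reconstructions: np.ndarray,
    stored: PatternSet,
    own_indices: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray]:
    """Fraction of cues whose reconstruction best matches its own original.

    A reconstruction is correct iff its Pearson correlation with its own
    stored pattern is the *strict* maximum over all stored patterns; ties
    count as confusion.  Returns (fraction correct, per-cue boolean array).
    """
    reconstructions = np.atleast_2d(reconstructions)
    M = len(stored)
    if own_indices is None:
        own_indices = np.arange(reconstructions.shape[0])
    corr = cross_correlations(reconstructions, stored.rates)  # (n_cues, M)
    own = corr[np.arange(corr.shape[0]), own_indices]
    others = corr.copy()
    others[np.arange(corr.shape[0]), own_indices] = -np.inf
    correct = own > others.max(axis=1)
    return float(correct.mean()), correct


@dataclass
class SeparationResult:
    """Pairwise correlations in EC and CA3 plus their regression summary."""

    ec_correlations: np.ndarray
    ca3_correlations: np.ndarray
    slope: float
    intercept: float
    r_value: float

    @property
    def reliable(self) -> bool:
        """The slope only measures separation when the fit is decent."""
        return abs(self.r_value) >= 0.2


def _pairwise_upper(a: np.ndarray) -> np.ndarray:
    c = cross_correlations(a, a)
    iu = np.triu_indices(c.shape[0], k=1)
    return c[iu]


def separation_index(ec_set: PatternSet, ca3_set: PatternSet) -> SeparationResult:
    """OLS slope of pairwise CA3 correlations against pairwise EC correlations.

    A perfect separator would make CA3 correlations independent of EC
    correlations (slope 0); no separation at all copies them (slope 1).
    The r value flags regimes where the line fits poorly and the index is
    not reliable.
    """
    if len(ec_set) != len(ca3_set):
        raise ValueError("sets must be aligned")
    if len(ec_set) < 3:
        raise ValueError("need at least 3 patterns")
    x = _pairwise_upper(ec_set.rates)
    y = _pairwise_upper(ca3_set.rates)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate EC correlations: regression undefined")
    if np.allclose(y, y[0]) and np.allclose(x, x[0]):
        raise ValueError("degenerate correlation lists")
    fit = stats.linregress(x, y)
    return SeparationResult(
        ec_correlations=x,
        ca3_correlations=y,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
    )


@dataclass
class SpatialFiringMap:
    """Post-WTA firing of one region's cells at every stored location."""

    rates: np.ndarray  # (n_cells, M) post-WTA values at stored locations
    locations: np.ndarray  # (M, 2)

    def __post_init__(self):
        self.rates = np.atleast_2d(self.rates)
        self.locations = np.asarray(self.locations, dtype=float)
        if self.locations.shape != (self.rates.shape[1], 2):
            raise ValueError("locations must align with pattern columns")

    @property
    def firing(self) -> np.ndarray:
        """'Fires' means a nonzero post-WTA value (CA3 is binary anyway)."""
        return self.rates > 0

    @classmethod
    def from_pattern_set(cls, ps: PatternSet) -> "SpatialFiringMap":
        if ps.locations is None:
            raise ValueError("pattern set has no location tags")
        return cls(ps.rates.T, ps.locations)


def conditional_firing(
    fmap: SpatialFiringMap, bin_width: float = 0.05
) -> pd.DataFrame:
    """P(fire at s | fire at t) and P(fire at s | silent at t) vs distance.

    Computed over all ordered location pairs s != t, pooled over cells, and
    binned by the Euclidean distance between the two locations (default 5 cm
    bins, the lattice pitch).  Empty bins are reported as NaN.
    """
    F = fmap.firing.astype(float)  # (n_cells, M)
    M = F.shape[1]
    if M < 2:
        raise ValueError("need at least 2 stored locations")
    both = F.T @ F  # both[t, s] = # cells firing at t and s
    n_fire = F.sum(axis=0)  # per location
    n_silent = F.shape[0] - n_fire
    fire_given_silent_counts = (1 - F).T @ F  # [t, s]: silent at t, fire at s
    dists = squareform(pdist(fmap.locations))
    off = ~np.eye(M, dtype=bool)
    d = dists[off]
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ff = (both / n_fire[:, None])[off]
        p_fs = (fire_given_silent_counts / n_silent[:, None])[off]
    bins = np.arange(0.0, d.max() + bin_width, bin_width)
    idx = np.digitize(d, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        sel = idx == b
        rows.append(dict(
            distance=(bins[b] + bins[b + 1]) / 2.0,
            p_fire_given_fire=np.nanmean(p_ff[sel]) if sel.any() else np.nan,
            p_fire_given_silent=np.nanmean(p_fs[sel]) if sel.any() else np.nan,
            n_pairs=int(sel.sum()),
        ))
    return pd.DataFrame(rows)


def overlap_vs_distance(ec_set: PatternSet, bin_width: float = 0.05) -> pd.DataFrame:
    """Mean mean-subtracted overlap (p^s - mean)^T p^t binned by |s - t| distance."""
    if ec_set.locations is None:
        raise ValueError("location tags required")
    P = ec_set.rates
    centered = P - P.mean(axis=0, keepdims=True)
    O = centered @ P.T  # O[s, t]
    dists = squareform(pdist(ec_set.locations))
    d = dists.ravel()
    o = O.ravel()
    bins = np.arange(0.0, d.max() + bin_width, bin_width)
    idx = np.digitize(d, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        sel = idx == b
        rows.append(dict(distance=(bins[b] + bins[b + 1]) / 2.0,
                         overlap=o[sel].mean() if sel.any() else np.nan,
                         n_pairs=int(sel.sum())))
    return pd.DataFrame(rows)


def activation_histograms(
    decompositions: list[ActivationDecomposition],
    outputs: PatternSet,
    n_bins: int = 50,
) -> dict:
    """Recall-activation distributions split by storage-time firing.

    Pools, over cues t and target cells i, the raw activation h_i(t) and the
    crosstalk-only sum, split by whether cell i fired in the stored output
    pattern t.  Returns long-format histogram data, the overlap area of the
    fire/silent activation distributions, and the mean signal shift
    S = <S_t>_t.
    """
    h_fire, h_silent, x_fire, x_silent, signals = [], [], [], [], []
    for dec in decompositions:
        fired = outputs.rates[dec.cue_index] > 0
        h = dec.total
        x = dec.crosstalk_sum
        h_fire.append(h[fired])
        h_silent.append(h[~fired])
        x_fire.append(x[fired])
        x_silent.append(x[~fired])
        fired_signals = dec.signal[fired]
        if fired_signals.size:
            signals.append(fired_signals.mean())
    h_fire = np.concatenate(h_fire)
    h_silent = np.concatenate(h_silent)
    x_fire = np.concatenate(x_fire)
    x_silent = np.concatenate(x_silent)
    all_vals = np.concatenate([h_fire, h_silent])
    lo, hi = all_vals.min(), all_vals.max()
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    dens_fire, _ = np.histogram(h_fire, bins=edges, density=True)
    dens_silent, _ = np.histogram(h_silent, bins=edges, density=True)
    width = edges[1] - edges[0]
    overlap_area = float(np.minimum(dens_fire, dens_silent).sum() * width)
    rows = []
    for kind, fire_vals, silent_vals in (
        ("activation", h_fire, h_silent),
        ("crosstalk", x_fire, x_silent),
    ):
        vals = np.concatenate([fire_vals, silent_vals])
        vmin, vmax = vals.min(), vals.max()
        if vmin == vmax:
            vmax = vmin + 1.0
        e = np.linspace(vmin, vmax, n_bins + 1)
        for group, v in (("fire", fire_vals), ("silent", silent_vals)):
            counts, _ = np.histogram(v, bins=e)
            centers = (e[:-1] + e[1:]) / 2.0
            rows.extend(dict(kind=kind, group=group, bin=c, count=int(n))
                        for c, n in zip(centers, counts))
    return {
        "histogram": pd.DataFrame(rows),
        "overlap_area": overlap_area,
        "mean_signal": float(np.mean(signals)) if signals else 0.0,
        "mean_shift": float(h_fire.mean() - h_silent.mean()),
        "crosstalk_fire": x_fire,
        "crosstalk_silent": x_silent,
    }
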