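"""The three Hebbian rules that write memories into projections.

* Hetero-association (Stent–Singer rule): batch outer-product learning of
  input->output pairs with the input mean subtracted, used for EC->CA3,
  CA3->CA1 and CA1->EC.  Mean subtraction models LTD alongside LTP and is
  what keeps crosstalk between stored patterns zero-mean.
* Auto-association (covariance rule): the symmetric analogue on the CA3
  recurrent collaterals.
* One-shot competitive learning: a sequential Hebbian increment followed by
  row normalization, used on EC->DG so granule cells compete for input
  features; this is the rule hypothesised to produce pattern separation.
"""

from __future__ import annotations

import logging
from dataclasses import InitVar, dataclass

import numpy as np

from .dynamics import PatternSet, propagate
from .topology import ConnectivityMatrix

__all__ = [
    "WeightMatrix",
    "LearningConfig",
    "hetero_associate",
    "auto_associate",
    "competitive_init",
    "competitive_update",
    "decompose_activation",
    "ActivationDecomposition",
]

log = logging.getLogger(__name__)


@dataclass
class WeightMatrix:
    """Learned synaptic strengths on a fixed binary wiring mask.

    w_ij is identically zero wherever the mask has no connection.  Set
    `check=False` to skip the O(n^2) mask-support validation when the
    caller guarantees it (hot loops).
    """

    weights: np.ndarray  # (n_target, n_source) float
    mask: ConnectivityMatrix
    check: InitVar[bool] = True

    def __post_init__(self, check: bool = True):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.mask.shape:
            raise ValueError("weights and mask shapes differ")
        if check and np.any(self.weights[~self.mask.entries] != 0.0):
            raise ValueError("nonzero weight outside the connectivity mask")

    @property
    def shape(self):
        return self.weights.shape


@dataclass(frozen=True)
class LearningConfig:
    """Competitive-rule hyperparameter: the learning rate gamma."""

    gamma: float = 0.1

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _check_pair(mask: ConnectivityMatrix, inputs: PatternSet, outputs: PatternSet):
    if len(inputs) == 0 or len(outputs) == 0:
        raise ValueError("pattern sets must be non-empty")
    if len(inputs) != len(outputs):
        raise ValueError("input and output sets must have equal length")
    n_t, n_s = mask.shape
    if inputs.n_cells != n_s or outputs.n_cells != n_t:
        raise ValueError("pattern dimensions do not match the mask")


def hetero_associate(
    mask: ConnectivityMatrix, inputs: PatternSet, outputs: PatternSet
) -> WeightMatrix:
    """Batch hetero-association: w_ij = c_ij * sum_s (p_j^s - mean_j) q_i^s.

    The mean is taken over exactly the M stored patterns.  With a single
    stored pattern the mean equals the pattern and all weights are zero.
    """
    _check_pair(mask, inputs, outputs)
    centered = inputs.rates - inputs.rates.mean(axis=0, keepdims=True)
    w = outputs.rates.T @ centered
    w[~mask.entries] = 0.0
    return WeightMatrix(w, mask, check=False)


def auto_associate(mask: ConnectivityMatrix, patterns: PatternSet) -> WeightMatrix:
    """Covariance-rule auto-association: v_ij = c_ij * sum_s (p_j^s - mean_j)(p_i^s - mean_i)."""
    n_t, n_s = mask.shape
    if n_t != n_s:
        raise ValueError("auto-association requires a square mask")
    if len(patterns) == 0:
        raise ValueError("pattern set must be non-empty")
    if patterns.n_cells != n_s:
        raise ValueError("pattern dimension does not match the mask")
    centered = patterns.rates - patterns.rates.mean(axis=0, keepdims=True)
    v = centered.T @ centered
    v[~mask.entries] = 0.0
    return WeightMatrix(v, mask, check=False)


def competitive_init(
    mask: ConnectivityMatrix, rng: np.random.Generator
) -> WeightMatrix:
    """Random positive weights on the mask with unit-norm rows.

    The competitive rule renormalizes each updated row to unit Euclidean
    norm, so the first stored pattern competes fairly only if the initial
    rows are normalized too.
    """
    w = np.where(mask.entries, rng.uniform(0.0, 1.0, size=mask.shape), 0.0)
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    np.divide(w, norms, out=w, where=norms > 0)
    return WeightMatrix(w, mask, check=False)


def competitive_update(
    w_old: WeightMatrix,
    p: np.ndarray,
    q: np.ndarray,
    cfg: LearningConfig,
) -> WeightMatrix:
    """One-shot competitive step: w_i += gamma * q_i * p, then unit-normalize row i.

    `q` must be the post-WTA response that `p` triggered through `w_old`;
    only rows of cells that fired change.  Rows that end up all-zero are
    logged and left at zero.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    w = w_old.weights.copy()
    _competitive_step(w, w_old.mask.entries, p, q, cfg.gamma)
    return WeightMatrix(w, w_old.mask, check=False)


def _competitive_step(
    w: np.ndarray, mask: np.ndarray, p: np.ndarray, q: np.ndarray, gamma: float
) -> None:
    """In-place competitive update; touches only the rows of firing cells."""
    active = np.flatnonzero(q)
    if not active.size:
        return
    rows = w[active] + gamma * q[active, None] * p[None, :]
    rows[~mask[active]] = 0.0
    norms = np.linalg.norm(rows, axis=1)
    zero = norms == 0
    if zero.any():
        log.warning("competitive_update: %d all-zero rows left at zero", zero.sum())
        norms[zero] = 1.0
    w[active] = rows / norms[:, None]


@dataclass
class ActivationDecomposition:
    """Exact split of a recall activation into own-pattern signal and crosstalk.

    For weights learned by hetero-association and cue pattern t,
    h_i(t) = signal_i + sum_{s != t} crosstalk_{i,s}, exactly.  The scalar
    approximation replaces the per-cell connectivity sum by its expectation
    c * (p^t - mean)^T p^t with c the connection fraction; it is reported as
    a diagnostic only.
    """

    cue_index: int
    signal: np.ndarray  # (n_target,)
    crosstalk: np.ndarray  # (n_target, M) with column t zero
    signal_scalar_approx: float

    @property
    def crosstalk_sum(self) -> np.ndarray:
        return self.crosstalk.sum(axis=1)

    @property
    def total(self) -> np.ndarray:
        return self.signal + self.crosstalk_sum


def decompose_activation(
    weights: WeightMatrix,
    inputs: PatternSet,
    outputs: PatternSet,
    t: int,
) -> ActivationDecomposition:
    """Signal/crosstalk decomposition of the raw activation for stored cue t.

    Expanding the hetero-associative weights, the activation of target cell
    i under the (noiseless) cue p^(t) splits into the term contributed by
    the storage of pattern t itself (the signal, proportional to q_i^(t))
    and one crosstalk term per other stored pattern s, proportional to
    q_i^(s) times the masked overlap of p^(s) (mean-subtracted) with p^(t).
    The terms sum to propagate(W, p^(t)) to machine precision.
    """
    _check_pair(weights.mask, inputs, outputs)
    M = len(inputs)
    if not 0 <= t < M:
        raise IndexError(f"cue index {t} out of range for {M} patterns")
    p_t = inputs.rates[t]
    centered = inputs.rates - inputs.rates.mean(axis=0, keepdims=True)  # (M, n_s)
    # overlap[i, s] = sum_j c_ij (p_j^s - mean_j) p_j^t
    masked_pt = weights.mask.entries * p_t[None, :]  # (n_t, n_s)
    overlap = masked_pt @ centered.T  # (n_t, M)
    terms = outputs.rates.T * overlap  # (n_t, M): q_i^s * overlap[i, s]
    signal = terms[:, t].copy()
    crosstalk = terms.copy()
    crosstalk[:, t] = 0.0
    n_t, n_s = weights.shape
    c_frac = weights.mask.fan_in / n_s
    signal_scalar = float(c_frac * centered[t] @ p_t)
    return ActivationDecomposition(
        cue_index=t,
        signal=signal,
        crosstalk=crosstalk,
        signal_scalar_approx=signal_scalar,
    )
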