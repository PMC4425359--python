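"""Feedforward activation and k-winner-take-all competition.

All regions share exactly two primitives: a weighted sum of presynaptic
rates (`propagate`) and population-level inhibition modeled as k-WTA
(`kwta`): after computing all activations in a region, the k most activated
cells keep firing (at their activation value for continuous regions, at 1
for the binary CA3) and every other cell is silenced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .topology import RegionSpec

__all__ = ["ActivityPattern", "PatternSet", "propagate", "kwta", "topk_indices"]

log = logging.getLogger(__name__)


@dataclass
class ActivityPattern:
    """A nonnegative rate vector over one region's cells."""

    region: str
    rates: np.ndarray
    is_post_wta: bool = False

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 1:
            raise ValueError("rates must be a 1-d vector")

    @property
    def n_cells(self) -> int:
        return self.rates.size

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.rates)


@dataclass
class PatternSet:
    """An ordered collection of M patterns of one region, stored as (M, n) array.

    Optionally tagged with the arena location and environment each pattern
    was sampled at.
    """

    region: str
    rates: np.ndarray  # (M, n_cells)
    locations: Optional[np.ndarray] = None  # (M, 2) in meters
    environments: Optional[np.ndarray] = None  # (M,) int ids

    def __post_init__(self):
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if self.locations is not None:
            self.locations = np.asarray(self.locations, dtype=float)
            if self.locations.shape != (len(self), 2):
                raise ValueError("locations must be (M, 2)")
        if self.environments is not None:
            self.environments = np.asarray(self.environments)
            if self.environments.shape != (len(self),):
                raise ValueError("environments must be (M,)")

    def __len__(self) -> int:
        return self.rates.shape[0]

    @property
    def n_cells(self) -> int:
        return self.rates.shape[1]

    def pattern(self, s: int) -> ActivityPattern:
        return ActivityPattern(self.region, self.rates[s], is_post_wta=True)

    def subset(self, indices) -> "PatternSet":
        indices = np.asarray(indices)
        return PatternSet(
            self.region,
            self.rates[indices],
            locations=None if self.locations is None else self.locations[indices],
            environments=(None if self.environments is None
                          else self.environments[indices]),
        )

    def concat(self, other: "PatternSet") -> "PatternSet":
        if other.region != self.region or other.n_cells != self.n_cells:
            raise ValueError("pattern sets are not compatible")
        def _cat(a, b):
            return None if a is None or b is None else np.concatenate([a, b])
        return PatternSet(
            self.region,
            np.concatenate([self.rates, other.rates]),
            locations=_cat(self.locations, other.locations),
            environments=_cat(self.environments, other.environments),
        )

    def save(self, path) -> None:
        """Persist to an .npz array container plus a CSV sidecar of tags."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), rates=self.rates,
                            region=np.array(self.region))
        tags = pd.DataFrame(index=pd.RangeIndex(len(self), name="pattern"))
        if self.locations is not None:
            tags["x"] = self.locations[:, 0]
            tags["y"] = self.locations[:, 1]
        if self.environments is not None:
            tags["environment"] = self.environments
        tags.to_csv(path.with_suffix(".tags.csv"))

    @classmethod
    def load(cls, path) -> "PatternSet":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        tags = pd.read_csv(path.with_suffix(".tags.csv"), index_col=0)
        locations = tags[["x", "y"]].to_numpy() if "x" in tags else None
        environments = tags["environment"].to_numpy() if "environment" in tags else None
        return cls(str(arrays["region"]), arrays["rates"],
                   locations=locations, environments=environments)


def propagate(weights: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Raw activations h = W @ p (no thresholding).

    `rates` may be a single pattern (n_source,) or a batch (n_source, M);
    the result has matching shape (n_target,) or (n_target, M).
    """
    weights = np.asarray(weights)
    rates = np.asarray(rates)
    if weights.shape[1] != rates.shape[0]:
        raise ValueError(
            f"dimension mismatch: weights {weights.shape} vs rates {rates.shape}"
        )
    return weights @ rates


def topk_indices(h: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest entries; ties broken toward the lowest index.

    For batched input (n, M) returns (k, M) winner indices per column.
    """
    # stable sort of -h yields descending h with ascending index among ties
    order = np.argsort(-h, axis=0, kind="stable")
    return order[:k]


def kwta(h: np.ndarray, region: RegionSpec, k: Optional[int] = None) -> np.ndarray:
    """k-winner-take-all: silence all but the region's k most activated cells.

    Winners keep their raw activation (continuous regions) or are set to 1
    (binary regions).  Negative winning activations — possible once weights
    have been mean-subtracted by learning — are clamped to zero so rates
    stay nonnegative.  Ties at the k-th activation go to the lowest index.

    Accepts a single vector (n,) or a batch (n, M), columnwise.
    """
    h = np.asarray(h, dtype=float)
    if k is None:
        k = region.k_winners
    n = h.shape[0]
    if n != region.n_cells:
        raise ValueError(f"activation length {n} != region size {region.n_cells}")
    single = h.ndim == 1
    hb = h[:, None] if single else h
    winners = topk_indices(hb, k)
    out = np.zeros_like(hb)
    cols = np.arange(hb.shape[1])[None, :]
    if region.value_kind == "binary":
        out[winners, cols] = 1.0
    else:
        vals = hb[winners, cols]
        n_neg = int((vals < 0).sum())
        if n_neg:
            log.debug("kwta clamped %d negative winning activations to 0", n_neg)
            vals = np.maximum(vals, 0.0)
        out[winners, cols] = vals
    return out[:, 0] if single else out
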