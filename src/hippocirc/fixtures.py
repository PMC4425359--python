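"""Deterministic tiny instances for fast, exactly-checkable tests and demos.

Everything here rebuilds identically from (name, seed); scenarios are small
enough (tens of cells) that recall and learning can be verified by brute
force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dynamics import PatternSet
from .inputs import GridModule, SpatialInputModel, build_population, sample_locations
from .rng import substream
from .topology import NetworkConfig, ProjectionSpec, RegionSpec

__all__ = ["ToyScenario", "toy_orthogonal", "toy_config", "mini_grid_world",
           "disjoint_support_pearson"]


@dataclass
class ToyScenario:
    """A named, fully deterministic miniature setup."""

    name: str
    config: Optional[NetworkConfig] = None
    pattern_sets: dict = field(default_factory=dict)
    input_model: Optional[SpatialInputModel] = None
    locations: Optional[np.ndarray] = None
    expected: dict = field(default_factory=dict)


def disjoint_support_pearson(n: int, k: int) -> float:
    """Closed-form Pearson correlation of two disjoint k-of-n binary patterns.

    Both patterns have mean k/n; their covariance sum is -k^2/n and each
    variance sum is k(1 - k/n), giving r = -k / (n - k).
    """
    return -k / (n - k)


def toy_orthogonal(n: int, k: int, M: int, region: str = "CA3") -> ToyScenario:
    """M binary k-of-n patterns with pairwise disjoint supports.

    Supports are consecutive blocks, so recall through full-mask
    hetero/auto-association is exactly solvable by hand.
    """
    if M * k > n:
        raise ValueError("disjoint supports need M * k <= n")
    rates = np.zeros((M, n))
    for s in range(M):
        rates[s, s * k : (s + 1) * k] = 1.0
    ps = PatternSet(region, rates)
    return ToyScenario(
        name=f"orthogonal_n{n}_k{k}_M{M}",
        pattern_sets={region: ps},
        expected={"pairwise_pearson": disjoint_support_pearson(n, k)},
    )


def toy_config(seed: int = 0, variant: str = "full") -> NetworkConfig:
    """A <=50-cell network with the full wiring diagram, for protocol tests."""
    regions = {
        "EC": RegionSpec("EC", 16, 0.35),
        "DG": RegionSpec("DG", 14, 0.15),
        "CA3": RegionSpec("CA3", 10, 0.2, value_kind="binary"),
        "CA1": RegionSpec("CA1", 10, 0.3),
    }
    fan = {
        ("EC", "DG"): 8, ("EC", "CA3"): 8, ("EC", "CA1"): 8,
        ("DG", "CA3"): 4, ("CA3", "CA3"): 6, ("CA3", "CA1"): 5,
        ("CA1", "EC"): 5,
    }
    rules = {
        ("EC", "DG"): "competitive", ("EC", "CA3"): "hetero",
        ("EC", "CA1"): "none", ("DG", "CA3"): "none",
        ("CA3", "CA3"): "auto", ("CA3", "CA1"): "hetero",
        ("CA1", "EC"): "hetero",
    }
    projections = {
        key: ProjectionSpec(key[0], key[1], fan[key],
                            plastic=rules[key] != "none", rule=rules[key])
        for key in fan
    }
    return NetworkConfig(regions=regions, projections=projections,
                         seed=seed, variant=variant)


def mini_grid_world(
    n_cells: int = 40, n_locations: int = 25, seed: int = 0
) -> ToyScenario:
    """A 50 cm arena with two grid modules, for fast spatial-metric tests."""
    modules = (
        GridModule(1, 0.15, 15.0, spacing_sd=0.02),
        GridModule(2, 0.25, 40.0, spacing_sd=0.02),
    )
    rng = substream(seed, f"mini_grid_world:{n_cells}:{n_locations}")
    model = build_population(n_cells, 0, rng, modules=modules, arena=0.5)
    locations = sample_locations(0.5, n_locations)
    region = RegionSpec("EC", n_cells, 0.35)
    patterns = model.pattern_set_at(locations, region)
    return ToyScenario(
        name=f"mini_grid_world_{n_cells}_{n_locations}_{seed}",
        pattern_sets={"EC": patterns},
        input_model=model,
        locations=locations,
    )
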