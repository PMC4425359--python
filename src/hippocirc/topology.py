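"""Regions, wiring, and the arithmetic that maps anatomy onto model parameters.

The network models four subregions of the rodent hippocampal formation:
entorhinal cortex (EC), dentate gyrus (DG), CA3 and CA1.  Cell counts are
rat anatomical estimates scaled down by 100; per-cell connection counts are
scaled down by 10 (the square root of the cell scaling), which scales the
total number of synapses between two regions by 100 while keeping each cell
connected.  Each region fires sparsely: at any moment only a fraction ``a``
of its cells (the sparsity) is active, enforced by k-winner-take-all
competition.  Sparsities are derived from reported fractions of active
cells per environment multiplied by the fraction of the environment a
single active cell covers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

from .rng import substream

__all__ = [
    "RegionSpec",
    "ProjectionSpec",
    "ConnectivityMatrix",
    "NetworkConfig",
    "derive_sparsity",
    "derive_coverage",
    "grandmother_capacity",
    "build_connectivity",
    "paper_default_config",
    "minimal_config",
    "rolls_sweep_configs",
    "preset_config",
    "check_scaling",
    "LITERATURE_CELL_COUNTS",
    "LITERATURE_FAN_IN",
]

REGIONS = ("EC", "DG", "CA3", "CA1")

# Rat anatomical estimates the default configuration is scaled from:
# cell counts / 100, per-cell afferent counts / 10.
LITERATURE_CELL_COUNTS = {"EC": 110_000, "DG": 1_200_000, "CA3": 250_000, "CA1": 390_000}
LITERATURE_FAN_IN = {
    ("EC", "DG"): 4_000,
    ("EC", "CA3"): 4_000,
    ("DG", "CA3"): 46,  # mossy fibers: few, strong
    ("CA3", "CA3"): 12_000,
    ("CA3", "CA1"): 12_000,
    ("EC", "CA1"): 4_000,  # temporoammonic
    ("CA1", "EC"): 4_000,
}
CELL_SCALE = 100
FAN_IN_SCALE = 10


@dataclass(frozen=True)
class RegionSpec:
    """One subregion: size, sparsity and value type of its rate code.

    CA3 is the only binary region (its cells fire 0/1); all other regions
    carry continuous nonnegative rates.
    """

    name: str
    n_cells: int
    sparsity_a: float
    value_kind: str = "continuous"  # "continuous" | "binary"

    def __post_init__(self):
        if self.name not in REGIONS:
            raise ValueError(f"unknown region {self.name!r}; expected one of {REGIONS}")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if not 0.0 < self.sparsity_a <= 1.0:
            raise ValueError("sparsity_a must be in (0, 1]")
        if self.value_kind not in ("continuous", "binary"):
            raise ValueError("value_kind must be 'continuous' or 'binary'")

    @property
    def k_winners(self) -> int:
        """Number of cells left active by the WTA competition (>= 1)."""
        return max(1, round(self.sparsity_a * self.n_cells))


@dataclass(frozen=True)
class ProjectionSpec:
    """One projection between regions: wiring density and plasticity rule."""

    source: str
    target: str
    fan_in: int
    plastic: bool = False
    rule: str = "none"  # "hetero" | "auto" | "competitive" | "none"

    def __post_init__(self):
        if self.rule not in ("hetero", "auto", "competitive", "none"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.fan_in <= 0:
            raise ValueError("fan_in must be positive")

    @property
    def is_recurrent(self) -> bool:
        return self.source == self.target

    def validate_against(self, regions: dict[str, RegionSpec]) -> None:
        n_src = regions[self.source].n_cells
        avail = n_src - 1 if self.is_recurrent else n_src
        if self.fan_in > avail:
            raise ValueError(
                f"fan_in {self.fan_in} exceeds available sources ({avail}) "
                f"for {self.source}->{self.target}"
            )


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Binary wiring mask c_ij in {0,1}, shape (n_target, n_source).

    Every row sums exactly to the projection's fan-in; the recurrent CA3
    mask has a zero diagonal (no self-connections).
    """

    entries: np.ndarray  # bool, (n_target, n_source)
    fan_in: int

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=bool)
        object.__setattr__(self, "entries", e)
        sums = e.sum(axis=1)
        if not np.all(sums == self.fan_in):
            raise ValueError("every row of a ConnectivityMatrix must sum to fan_in")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


def derive_sparsity(
    active_fraction_values: Sequence[float | tuple[float, float]],
    coverage: float,
) -> tuple[float, float]:
    """Sparsity ``a`` from reported active-cell percentages and spatial coverage.

    Each entry of `active_fraction_values` is a percentage (or a
    ``(low, high)`` percentage range, replaced by its midpoint) of cells
    active somewhere in an environment.  The mean of those percentages,
    multiplied by the fraction of the environment one active cell covers,
    gives the fraction active at a single location.

    Returns ``(sparsity_a, mean_active_percent)`` — the sparsity as a
    fraction and the intermediate across-environment mean in percent.
    """
    vals = list(active_fraction_values)
    if not vals:
        raise ValueError("need at least one reported active-fraction value")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    mids = []
    for v in vals:
        if isinstance(v, (tuple, list)):
            lo, hi = v
            mids.append((float(lo) + float(hi)) / 2.0)
        else:
            mids.append(float(v))
    mean_percent = float(np.mean(mids))
    return mean_percent / 100.0 * coverage, mean_percent


def derive_coverage(n_fields: float, field_area: float, arena_area: float) -> float:
    """Fraction of the arena one cell's firing fields cover (capped at 1).

    `field_area` and `arena_area` share units (cm^2 by convention).
    """
    if arena_area <= 0:
        raise ValueError("arena_area must be positive")
    if n_fields <= 0 or field_area <= 0:
        raise ValueError("n_fields and field_area must be positive")
    return min(1.0, n_fields * field_area / arena_area)


def grandmother_capacity(sparsity_a: float) -> int:
    """Pattern capacity of one-pattern-per-cell coding: floor(1 / a).

    If each cell participates in exactly one stored pattern, a region with
    sparsity ``a`` runs out of cells after 1/a patterns.
    """
    if not 0.0 < sparsity_a <= 1.0:
        raise ValueError("sparsity_a must be in (0, 1]")
    return int(np.floor(1.0 / sparsity_a))


def build_connectivity(
    spec: ProjectionSpec,
    n_source: int,
    n_target: int,
    rng: np.random.Generator,
) -> ConnectivityMatrix:
    """Random fixed wiring: each target cell draws `fan_in` distinct sources.

    Sampling is uniform without replacement per target row; the recurrent
    projection never wires a cell to itself.
    """
    avail = n_source - 1 if spec.is_recurrent else n_source
    if spec.fan_in > avail:
        raise ValueError("fan_in exceeds available sources")
    # rank i.i.d. uniforms per row: the fan_in smallest form a uniform
    # random subset without replacement
    keys = rng.random((n_target, n_source))
    if spec.is_recurrent:
        np.fill_diagonal(keys, np.inf)
    chosen = np.argpartition(keys, spec.fan_in - 1, axis=1)[:, : spec.fan_in]
    mask = np.zeros((n_target, n_source), dtype=bool)
    np.put_along_axis(mask, chosen, True, axis=1)
    return ConnectivityMatrix(mask, spec.fan_in)


PROJECTION_ORDER = (
    ("EC", "DG"),
    ("EC", "CA3"),
    ("EC", "CA1"),
    ("DG", "CA3"),
    ("CA3", "CA3"),
    ("CA3", "CA1"),
    ("CA1", "EC"),
)


@dataclass(frozen=True)
class NetworkConfig:
    """Everything that defines one simulation: anatomy, rules, protocol constants."""

    regions: dict[str, RegionSpec]
    projections: dict[tuple[str, str], ProjectionSpec]
    alpha: float = 1.0
    beta: float = 3.0
    n_cycles: int = 15
    gamma: float = 0.1
    seed: int = 0
    variant: str = "full"  # "full" | "no_recurrence" | "minimal_ec_ca1_ec"

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.variant not in ("full", "no_recurrence", "minimal_ec_ca1_ec"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for proj in self.projections.values():
            proj.validate_against(self.regions)

    def region(self, name: str) -> RegionSpec:
        return self.regions[name]

    def projection(self, source: str, target: str) -> ProjectionSpec:
        return self.projections[(source, target)]

    def with_variant(self, variant: str) -> "NetworkConfig":
        return replace(self, variant=variant)

    def with_seed(self, seed: int) -> "NetworkConfig":
        return replace(self, seed=seed)

    def rng(self, name: str) -> np.random.Generator:
        return substream(self.seed, name)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "regions": {
                r.name: {
                    "n_cells": r.n_cells,
                    "sparsity_a": r.sparsity_a,
                    "value_kind": r.value_kind,
                }
                for r in self.regions.values()
            },
            "projections": {
                f"{s}->{t}": {
                    "fan_in": p.fan_in,
                    "plastic": p.plastic,
                    "rule": p.rule,
                }
                for (s, t), p in self.projections.items()
            },
            "recall": {"alpha": self.alpha, "beta": self.beta, "n_cycles": self.n_cycles},
            "learning": {"gamma": self.gamma},
            "seed": self.seed,
            "variant": self.variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        regions = {
            name: RegionSpec(name=name, **spec) for name, spec in d["regions"].items()
        }
        projections = {}
        for key, spec in d["projections"].items():
            s, t = key.split("->")
            projections[(s, t)] = ProjectionSpec(source=s, target=t, **spec)
        return cls(
            regions=regions,
            projections=projections,
            alpha=d["recall"]["alpha"],
            beta=d["recall"]["beta"],
            n_cycles=d["recall"]["n_cycles"],
            gamma=d["learning"]["gamma"],
            seed=d.get("seed", 0),
            variant=d.get("variant", "full"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def paper_default_config(seed: int = 0, variant: str = "full") -> NetworkConfig:
    """The default scaled-down network.

    Cell counts are rat anatomy / 100; fan-ins are rat anatomy / 10.
    Sparsities come from `derive_sparsity` on reported activity levels:
    EC 0.35 (grid-cell coverage), DG 0.029 x 0.27, CA3 0.227 x 0.14,
    CA1 0.427 x 0.21.
    """
    a_dg, _ = derive_sparsity([3, (3, 4), 2.2], coverage=0.27)
    a_ca3, _ = derive_sparsity([18, (17, 32), 26], coverage=0.14)
    a_ca1, _ = derive_sparsity([35, (48, 66), 36], coverage=0.21)
    regions = {
        "EC": RegionSpec("EC", LITERATURE_CELL_COUNTS["EC"] // CELL_SCALE, 0.35),
        "DG": RegionSpec("DG", LITERATURE_CELL_COUNTS["DG"] // CELL_SCALE, a_dg),
        "CA3": RegionSpec(
            "CA3", LITERATURE_CELL_COUNTS["CA3"] // CELL_SCALE, a_ca3, value_kind="binary"
        ),
        "CA1": RegionSpec("CA1", LITERATURE_CELL_COUNTS["CA1"] // CELL_SCALE, a_ca1),
    }
    rules = {
        ("EC", "DG"): ("competitive", True),
        ("EC", "CA3"): ("hetero", True),
        ("EC", "CA1"): ("none", False),  # temporoammonic: static driver in the full model
        ("DG", "CA3"): ("none", False),
        ("CA3", "CA3"): ("auto", True),
        ("CA3", "CA1"): ("hetero", True),
        ("CA1", "EC"): ("hetero", True),
    }
    projections = {}
    for (s, t) in PROJECTION_ORDER:
        rule, plastic = rules[(s, t)]
        projections[(s, t)] = ProjectionSpec(
            source=s,
            target=t,
            fan_in=round(LITERATURE_FAN_IN[(s, t)] / FAN_IN_SCALE),
            plastic=plastic,
            rule=rule,
        )
    return NetworkConfig(
        regions=regions, projections=projections, seed=seed, variant=variant
    )


def minimal_config(seed: int = 0) -> NetworkConfig:
    """EC-CA1-EC variant: only EC->CA1 and CA1->EC are plastic."""
    cfg = paper_default_config(seed=seed, variant="minimal_ec_ca1_ec")
    projections = dict(cfg.projections)
    projections[("EC", "CA1")] = replace(
        projections[("EC", "CA1")], plastic=True, rule="hetero"
    )
    for key in (("EC", "DG"), ("EC", "CA3"), ("CA3", "CA3")):
        projections[key] = replace(projections[key], plastic=False, rule="none")
    projections[("CA3", "CA1")] = replace(
        projections[("CA3", "CA1")], plastic=False, rule="none"
    )
    return replace(cfg, projections=projections)


def rolls_sweep_configs(seed: int = 0) -> dict[str, NetworkConfig]:
    """Configurations probing grandmother coding in CA1.

    A qualitative sweep over CA1 sparsity (0.01 vs 0.1) and CA1->EC
    connectivity (full vs diluted), not a reproduction of any historical
    parameter set.
    """
    base = paper_default_config(seed=seed)
    out = {}
    n_ca1 = base.region("CA1").n_cells
    n_ec = base.region("EC").n_cells
    for a_ca1 in (0.01, 0.1):
        for conn in ("full", "diluted"):
            regions = dict(base.regions)
            regions["CA1"] = replace(regions["CA1"], sparsity_a=a_ca1)
            projections = dict(base.projections)
            fan = n_ca1 if conn == "full" else min(
                base.projection("CA1", "EC").fan_in, n_ca1
            )
            projections[("CA1", "EC")] = replace(
                projections[("CA1", "EC")], fan_in=fan
            )
            out[f"a{a_ca1}_{conn}"] = replace(
                base, regions=regions, projections=projections
            )
    return out


def preset_config(name: str, seed: int = 0) -> NetworkConfig:
    """Resolve a named preset: paper-default, minimal, or rolls-sweep base."""
    if name == "paper-default":
        return paper_default_config(seed=seed)
    if name == "minimal":
        return minimal_config(seed=seed)
    if name == "rolls-sweep":
        return rolls_sweep_configs(seed=seed)["a0.01_full"]
    raise ValueError(f"unknown preset {name!r}")


def check_scaling(config: NetworkConfig) -> bool:
    """Verify the 1/100 cell and 1/10 fan-in scaling against the literature table.

    The check is symbolic: every region's cell count must equal its
    literature count divided by 100, and every projection's fan-in the
    literature per-cell count divided by 10 (rounded).  Dividing fan-ins by
    100 instead would leave CA3 cells without mossy-fiber input; keeping
    them unscaled would triple-connect cell pairs.
    """
    for name, spec in config.regions.items():
        if spec.n_cells != LITERATURE_CELL_COUNTS[name] // CELL_SCALE:
            return False
    for key, proj in config.projections.items():
        if proj.fan_in != round(LITERATURE_FAN_IN[key] / FAN_IN_SCALE):
            return False
    return True
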