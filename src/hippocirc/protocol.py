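"""Storage and cued-recall protocols, and the three network variants.

Storage: each EC pattern triggers DG (optionally updating the competitive
EC->DG weights pattern by pattern), DG triggers the binary CA3 pattern via
the sparse mossy fibers, and EC drives CA1 directly through the static
temporoammonic projection.  The realized patterns are then written in one
batch: EC->CA3, CA3->CA1 and CA1->EC by hetero-association, the CA3
recurrent collaterals by the covariance rule.

Recall: a corrupted EC cue drives CA3 through the learned EC->CA3 weights,
the recurrent network runs 15 clamped activation cycles
(h = alpha * feedforward + beta * recurrent, alpha=1, beta=3), and the
resulting CA3 pattern is decoded through CA3->CA1 and CA1->EC.  The DG
plays no part in recall.

Variants: `no_recurrence` skips the recurrent cycles (the initial CA3
response goes straight to CA1); `minimal_ec_ca1_ec` stores only the two
hetero-associations EC->CA1 and CA1->EC, with CA1 driven during storage by
a completely static EC->DG->CA3->CA1 chain, and recalls through CA1 alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import ActivityPattern, PatternSet, kwta, propagate
from .inputs import (
    SpatialInputModel,
    build_population,
    make_cue_set,
    random_pattern_set,
    remap,
    sample_locations,
)
from .metrics import confusion, cross_correlations, recall_curve, rowwise_pearson
from .plasticity import (
    LearningConfig,
    WeightMatrix,
    auto_associate,
    competitive_init,
    competitive_update,
    hetero_associate,
)
from .topology import ConnectivityMatrix, NetworkConfig, build_connectivity

__all__ = [
    "TrainedNetwork",
    "RecallConfig",
    "store",
    "recall",
    "recall_trajectory",
    "minimal_store",
    "minimal_recall",
    "run_recall_sweep",
    "build_ec_patterns",
    "run_experiment",
    "default_cue_sweep",
    "save_network",
    "load_network",
]

log = logging.getLogger(__name__)

DG_MODES = ("plastic", "static", "perfect_separator")


@dataclass(frozen=True)
class RecallConfig:
    """Recall protocol constants and the cue-corruption sweep."""

    alpha: float = 1.0
    beta: float = 3.0
    n_cycles: int = 15
    n_wrong_sweep: tuple = ()


def default_cue_sweep(n_ec: int) -> list[int]:
    """Default corruption sweep: 0%, 10%, ..., 90% of EC cells set wrong."""
    return [round(f * n_ec) for f in np.arange(0.0, 0.91, 0.1)]


@dataclass
class TrainedNetwork:
    """A network after one storage pass: wiring, weights, realized patterns."""

    config: NetworkConfig
    masks: dict
    weights: dict
    stored: dict  # region name -> PatternSet
    dg_mode: str

    def stored_patterns(self, region: str) -> PatternSet:
        return self.stored[region]


def _build_masks(config: NetworkConfig) -> dict:
    masks = {}
    for (s, t), proj in config.projections.items():
        rng = config.rng(f"wiring:{s}->{t}")
        masks[(s, t)] = build_connectivity(
            proj, config.region(s).n_cells, config.region(t).n_cells, rng
        )
    return masks


def _static_weights(
    config: NetworkConfig, mask: ConnectivityMatrix, name: str
) -> WeightMatrix:
    rng = config.rng(f"static:{name}")
    w = np.where(mask.entries, rng.uniform(0.0, 1.0, size=mask.shape), 0.0)
    return WeightMatrix(w, mask)


def _dg_responses(
    config: NetworkConfig,
    ec: PatternSet,
    w_ecdg: WeightMatrix,
    plastic: bool,
) -> tuple[np.ndarray, WeightMatrix]:
    """DG patterns for every EC pattern; sequential updates if plastic.

    With plasticity each pattern responds through weights already updated
    by all earlier patterns (storage is strictly sequential).
    """
    dg_region = config.region("DG")
    if not plastic:
        q = kwta(propagate(w_ecdg.weights, ec.rates.T), dg_region)
        return q.T, w_ecdg
    from .plasticity import _competitive_step

    out = np.zeros((len(ec), dg_region.n_cells))
    w = w_ecdg.weights.copy()
    mask = w_ecdg.mask.entries
    for s in range(len(ec)):
        p = ec.rates[s]
        q = kwta(propagate(w, p), dg_region)
        _competitive_step(w, mask, p, q, config.gamma)
        out[s] = q
    return out, WeightMatrix(w, w_ecdg.mask, check=False)


def _random_binary(
    n_cells: int, k: int, M: int, rng: np.random.Generator
) -> np.ndarray:
    out = np.zeros((M, n_cells))
    for s in range(M):
        out[s, rng.choice(n_cells, size=k, replace=False)] = 1.0
    return out


def store(
    config: NetworkConfig,
    ec_patterns: PatternSet,
    dg_mode: str = "static",
) -> TrainedNetwork:
    """One storage pass over a set of EC patterns.

    `dg_mode` selects how CA3 codes arise: "plastic" runs the one-shot
    competitive rule on EC->DG during the pass, "static" leaves EC->DG at
    its random initialization, and "perfect_separator" bypasses the
    EC-DG-CA3 pathway entirely and assigns CA3 a random uncorrelated binary
    code (the idealized pattern separator).
    """
    if ec_patterns.region != "EC":
        raise ValueError("store expects EC patterns")
    if dg_mode not in DG_MODES:
        raise ValueError(f"unknown dg_mode {dg_mode!r}")
    if config.variant == "minimal_ec_ca1_ec":
        if dg_mode != "static":
            raise ValueError("the minimal variant has no plastic or bypassed DG")
        return minimal_store(config, ec_patterns)
    masks = _build_masks(config)
    ca3_region = config.region("CA3")
    ca1_region = config.region("CA1")

    stored: dict[str, PatternSet] = {"EC": ec_patterns}
    weights: dict[tuple[str, str], WeightMatrix] = {}

    # EC -> DG -> CA3 (storage-time CA3 is driven by the mossy fibers only)
    w_ecdg = competitive_init(masks[("EC", "DG")], config.rng("static:EC->DG"))
    if dg_mode == "perfect_separator":
        weights[("EC", "DG")] = w_ecdg
        ca3_rates = _random_binary(
            ca3_region.n_cells, ca3_region.k_winners, len(ec_patterns),
            config.rng("ca3_random"),
        )
    else:
        dg_rates, w_ecdg = _dg_responses(
            config, ec_patterns, w_ecdg, plastic=(dg_mode == "plastic")
        )
        weights[("EC", "DG")] = w_ecdg
        stored["DG"] = PatternSet("DG", dg_rates,
                                  locations=ec_patterns.locations,
                                  environments=ec_patterns.environments)
        w_dgca3 = _static_weights(config, masks[("DG", "CA3")], "DG->CA3")
        weights[("DG", "CA3")] = w_dgca3
        ca3_rates = kwta(propagate(w_dgca3.weights, dg_rates.T), ca3_region).T
    stored["CA3"] = PatternSet("CA3", ca3_rates,
                               locations=ec_patterns.locations,
                               environments=ec_patterns.environments)

    # EC -> CA1 via the static temporoammonic projection
    w_ecca1 = _static_weights(config, masks[("EC", "CA1")], "EC->CA1")
    weights[("EC", "CA1")] = w_ecca1
    ca1_rates = kwta(propagate(w_ecca1.weights, ec_patterns.rates.T), ca1_region).T
    stored["CA1"] = PatternSet("CA1", ca1_rates,
                               locations=ec_patterns.locations,
                               environments=ec_patterns.environments)

    # batch Hebbian writes
    weights[("EC", "CA3")] = hetero_associate(
        masks[("EC", "CA3")], ec_patterns, stored["CA3"]
    )
    weights[("CA3", "CA3")] = auto_associate(masks[("CA3", "CA3")], stored["CA3"])
    weights[("CA3", "CA1")] = hetero_associate(
        masks[("CA3", "CA1")], stored["CA3"], stored["CA1"]
    )
    weights[("CA1", "EC")] = hetero_associate(
        masks[("CA1", "EC")], stored["CA1"], ec_patterns
    )
    return TrainedNetwork(config, masks, weights, stored, dg_mode)


def _as_matrix(cues) -> np.ndarray:
    if isinstance(cues, PatternSet):
        return cues.rates
    if isinstance(cues, ActivityPattern):
        return cues.rates[None, :]
    return np.atleast_2d(np.asarray(cues, dtype=float))


def recall(
    net: TrainedNetwork,
    cues,
    use_recurrence: Optional[bool] = None,
    ec_output: str = "wta",
) -> dict:
    """Cued recall for one or many EC cues; returns per-region (M, n) arrays.

    `use_recurrence` overrides the config variant (False reproduces the
    no-recurrence ablation on the same trained weights).  `ec_output`
    selects whether the EC reconstruction is thresholded by k-WTA ("wta",
    default) or left as raw activations ("raw").
    """
    cfg = net.config
    if cfg.variant == "minimal_ec_ca1_ec":
        return minimal_recall(net, cues, ec_output=ec_output)
    if use_recurrence is None:
        use_recurrence = cfg.variant != "no_recurrence"
    X = _as_matrix(cues).T  # (n_EC, M)
    ca3_region, ca1_region, ec_region = (
        cfg.region("CA3"), cfg.region("CA1"), cfg.region("EC"))
    h_ff = propagate(net.weights[("EC", "CA3")].weights, X)
    q = kwta(h_ff, ca3_region)
    if use_recurrence:
        V = net.weights[("CA3", "CA3")].weights
        for _ in range(cfg.n_cycles):
            q = kwta(cfg.alpha * h_ff + cfg.beta * propagate(V, q), ca3_region)
    ca1 = kwta(propagate(net.weights[("CA3", "CA1")].weights, q), ca1_region)
    h_ec = propagate(net.weights[("CA1", "EC")].weights, ca1)
    ec = h_ec if ec_output == "raw" else kwta(h_ec, ec_region)
    return {"CA3": q.T, "CA1": ca1.T, "EC": ec.T}


def recall_trajectory(net: TrainedNetwork, cue) -> list[np.ndarray]:
    """CA3 state after each clamped recurrent cycle (for convergence checks)."""
    cfg = net.config
    x = _as_matrix(cue).T
    ca3_region = cfg.region("CA3")
    h_ff = propagate(net.weights[("EC", "CA3")].weights, x)
    q = kwta(h_ff, ca3_region)
    V = net.weights[("CA3", "CA3")].weights
    states = [q.copy()]
    for _ in range(cfg.n_cycles):
        q = kwta(cfg.alpha * h_ff + cfg.beta * propagate(V, q), ca3_region)
        states.append(q.copy())
    return [s[:, 0] for s in states]


def minimal_store(config: NetworkConfig, ec_patterns: PatternSet) -> TrainedNetwork:
    """EC-CA1-EC storage: only EC->CA1 and CA1->EC are plastic.

    CA1 patterns are produced by the static random EC->DG->CA3->CA1 chain,
    then hetero-associated with the EC input in both directions.  The CA3
    recurrent collaterals are never built or consulted.
    """
    if config.variant != "minimal_ec_ca1_ec":
        raise ValueError("config variant must be 'minimal_ec_ca1_ec'")
    masks = _build_masks(config)
    dg_region, ca3_region, ca1_region = (
        config.region("DG"), config.region("CA3"), config.region("CA1"))
    weights: dict[tuple[str, str], WeightMatrix] = {}
    w_ecdg = competitive_init(masks[("EC", "DG")], config.rng("static:EC->DG"))
    w_dgca3 = _static_weights(config, masks[("DG", "CA3")], "DG->CA3")
    w_ca3ca1 = _static_weights(config, masks[("CA3", "CA1")], "CA3->CA1")
    weights[("EC", "DG")] = w_ecdg
    weights[("DG", "CA3")] = w_dgca3
    weights[("CA3", "CA1")] = w_ca3ca1
    dg = kwta(propagate(w_ecdg.weights, ec_patterns.rates.T), dg_region)
    ca3 = kwta(propagate(w_dgca3.weights, dg), ca3_region)
    ca1 = kwta(propagate(w_ca3ca1.weights, ca3), ca1_region)
    stored = {
        "EC": ec_patterns,
        "DG": PatternSet("DG", dg.T, locations=ec_patterns.locations,
                         environments=ec_patterns.environments),
        "CA3": PatternSet("CA3", ca3.T, locations=ec_patterns.locations,
                          environments=ec_patterns.environments),
        "CA1": PatternSet("CA1", ca1.T, locations=ec_patterns.locations,
                          environments=ec_patterns.environments),
    }
    weights[("EC", "CA1")] = hetero_associate(
        masks[("EC", "CA1")], ec_patterns, stored["CA1"]
    )
    weights[("CA1", "EC")] = hetero_associate(
        masks[("CA1", "EC")], stored["CA1"], ec_patterns
    )
    return TrainedNetwork(config, masks, weights, stored, dg_mode="static")


def minimal_recall(net: TrainedNetwork, cues, ec_output: str = "wta") -> dict:
    """EC-CA1-EC recall: cue -> CA1 (learned temporoammonic) -> EC."""
    cfg = net.config
    X = _as_matrix(cues).T
    ca1 = kwta(propagate(net.weights[("EC", "CA1")].weights, X),
               cfg.region("CA1"))
    h_ec = propagate(net.weights[("CA1", "EC")].weights, ca1)
    ec = h_ec if ec_output == "raw" else kwta(h_ec, cfg.region("EC"))
    return {"CA1": ca1.T, "EC": ec.T}


def run_recall_sweep(
    net: TrainedNetwork,
    n_wrong_values: Sequence[int],
    rng: np.random.Generator,
    use_recurrence: Optional[bool] = None,
    ec_output: str = "wta",
) -> pd.DataFrame:
    """Recall every stored pattern at every corruption level.

    Returns one row per (corruption level, stored pattern) with the realized
    cue quality, the recall correlations per region, and the confusion flag
    (the reconstruction is most correlated with its own original, strictly).
    """
    stored_ec = net.stored["EC"]
    rows = []
    for n_wrong in n_wrong_values:
        cues, qualities = make_cue_set(stored_ec, int(n_wrong), rng)
        out = recall(net, cues, use_recurrence=use_recurrence, ec_output=ec_output)
        corr_ec = rowwise_pearson(out["EC"], stored_ec.rates)
        corr_ca1 = rowwise_pearson(out["CA1"], net.stored["CA1"].rates)
        if "CA3" in out:
            corr_ca3 = rowwise_pearson(out["CA3"], net.stored["CA3"].rates)
        else:
            corr_ca3 = np.full(len(stored_ec), np.nan)
        _, correct = confusion(out["EC"], stored_ec)
        for s in range(len(stored_ec)):
            rows.append(dict(
                n_wrong=int(n_wrong), pattern=s, cue_quality=qualities[s],
                corr_ca3=corr_ca3[s], corr_ca1=corr_ca1[s],
                corr_ec=corr_ec[s], correct=bool(correct[s]),
            ))
    return pd.DataFrame(rows)


def build_ec_patterns(
    config: NetworkConfig,
    kind: str,
    seed: int,
    M: int = 252,
    n_locations: int = 400,
    n_environments: int = 1,
    lec_fraction: float = 0.0,
) -> tuple[PatternSet, Optional[SpatialInputModel]]:
    """Input ensemble for one run.

    kind: "random" (sparse Normal(1,1) patterns), "grid" (pure MEC
    population at stored arena locations), "grid+lec" (mixed population,
    `lec_fraction` of EC cells are LEC), "lec" (pure LEC), "multi-env"
    (grid patterns drawn evenly from `n_environments` remapped maps).
    M patterns are stored, drawn from `n_locations` lattice points.
    """
    ec_region = config.region("EC")
    if kind == "random":
        return random_pattern_set(ec_region, M, config.rng("random_input")), None
    if kind == "grid":
        n_lec = 0
    elif kind == "grid+lec":
        n_lec = round(lec_fraction * ec_region.n_cells)
    elif kind == "lec":
        n_lec = ec_region.n_cells
    elif kind == "multi-env":
        n_lec = 0
    else:
        raise ValueError(f"unknown input kind {kind!r}")
    model = build_population(
        ec_region.n_cells - n_lec, n_lec, config.rng("grid_params")
    )
    locations = sample_locations(model.arena, n_locations)
    subset_rng = config.rng("storage_subset")
    if kind == "multi-env":
        env_rng = config.rng("remap")
        for e in range(1, n_environments):
            remap(model, e, env_rng)
        per_env = np.full(n_environments, M // n_environments)
        per_env[: M % n_environments] += 1
        parts = None
        for e in range(n_environments):
            idx = subset_rng.choice(n_locations, size=per_env[e], replace=False)
            ps = model.pattern_set_at(locations[idx], ec_region, env_id=e)
            parts = ps if parts is None else parts.concat(ps)
        return parts, model
    idx = subset_rng.choice(n_locations, size=M, replace=False)
    return model.pattern_set_at(locations[idx], ec_region), model


def run_experiment(
    config: NetworkConfig,
    input_kind: str = "grid",
    dg_mode: str = "static",
    n_wrong_values: Optional[Sequence[int]] = None,
    n_seeds: int = 1,
    M: int = 252,
    n_environments: int = 1,
    lec_fraction: float = 0.0,
    ec_output: str = "wta",
) -> dict:
    """End to end: build inputs, store, sweep cues, aggregate.

    Returns `report` (one row per seed/corruption/pattern), `curve` (means
    per corruption level), `separation` (one row per seed: separation index
    slope and r), plus the last TrainedNetwork and input model for
    inspection.
    """
    from .metrics import separation_index  # local import avoids cycle at module load

    if n_wrong_values is None:
        n_wrong_values = default_cue_sweep(config.region("EC").n_cells)
    reports, seps = [], []
    net = model = None
    for i in range(n_seeds):
        cfg = config.with_seed(config.seed + i)
        ec, model = build_ec_patterns(
            cfg, input_kind, cfg.seed, M=M,
            n_environments=n_environments, lec_fraction=lec_fraction,
        )
        net = store(cfg, ec, dg_mode=dg_mode)
        rep = run_recall_sweep(
            net, n_wrong_values, cfg.rng("cues"), ec_output=ec_output
        )
        rep.insert(0, "seed", cfg.seed)
        reports.append(rep)
        try:
            si = separation_index(net.stored["EC"], net.stored["CA3"])
            seps.append(dict(seed=cfg.seed, slope=si.slope, r_value=si.r_value))
        except (KeyError, ValueError):
            pass
    report = pd.concat(reports, ignore_index=True)
    curve = recall_curve(report)
    return {
        "report": report,
        "curve": curve,
        "separation": pd.DataFrame(seps),
        "network": net,
        "input_model": model,
    }


def save_network(net: TrainedNetwork, path) -> None:
    """Persist weights to an .npz container; masks as sparse index lists."""
    path = Path(path)
    arrays = {}
    for (s, t), wm in net.weights.items():
        key = f"{s}->{t}"
        arrays[f"W:{key}"] = wm.weights
        arrays[f"mask_idx:{key}"] = np.flatnonzero(wm.mask.entries)
        arrays[f"shape:{key}"] = np.array(wm.mask.shape)
        arrays[f"fan_in:{key}"] = np.array(wm.mask.fan_in)
    np.savez_compressed(path, **arrays)


def load_network_weights(path) -> dict:
    """Load the weight matrices written by `save_network` (weights only)."""
    data = np.load(path)
    out = {}
    for name in data.files:
        if not name.startswith("W:"):
            continue
        key = name[2:]
        s, t = key.split("->")
        shape = tuple(data[f"shape:{key}"])
        mask = np.zeros(shape, dtype=bool)
        mask.flat[data[f"mask_idx:{key}"]] = True
        out[(s, t)] = WeightMatrix(
            data[name], ConnectivityMatrix(mask, int(data[f"fan_in:{key}"]))
        )
    return out


# backwards-friendly alias matching save_network
load_network = load_network_weights
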