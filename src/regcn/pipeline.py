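"""End-to-end orchestration: seed -> refine -> expand -> final train.

``run_regcn`` executes the full method on a :class:`Network` and
returns the final partition together with a refinement trace and a
report of every stage.  The two core stages can be ablated
independently (``refine``/``expand`` flags) to reproduce the four
model variants; ``run_ablation_suite`` and ``tau_sweep`` wrap the
corresponding seed-ensemble experiments on generated benchmarks.

Seed schedule: the density-peak seeding is deterministic; refinement
round r trains with seed ``base_seed + r`` and the final classifier
with ``base_seed + 1000``, so any run is replayable from its config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from regcn.errors import ParameterError
from regcn.expansion import expand_affinity, expand_topk, tau_lower_bound
from regcn.gcn_engine import TrainConfig, predict_partition, train
from regcn.graph_core import (
    Network,
    normalize_adjacency,
    one_hot_features,
    shortest_path_distances,
)
from regcn.metrics import score_partition
from regcn.refinement import RefinementTrace, SLPWeights, refine_centers
from regcn.seeding import SeedSet, centrality_profile, select_initial_centers
from regcn.synthetic import SBMSpec, generate_sbm

logger = logging.getLogger(__name__)

FINAL_SEED_OFFSET = 1000


@dataclass
class RunConfig:
    """Full configuration of one community-detection run.

    ``tau`` is either the string ``"auto"`` (lower bound from
    K·tau·d̄² ≈ N) or a positive integer; ``expansion`` picks the
    affinity (default) or top-k strategy; the ``refine``/``expand``
    flags switch the two core stages for ablation.
    """

    k: int = 2
    d_c: int = 1
    slp_weights: SLPWeights = field(default_factory=SLPWeights)
    train: TrainConfig = field(default_factory=TrainConfig)
    tau: object = "auto"
    expansion: str = "affinity"
    max_refine_iter: int = 20
    refine: bool = True
    expand: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("K must be >= 1")
        if self.expansion not in ("affinity", "topk"):
            raise ParameterError(f"unknown expansion strategy {self.expansion!r}")
        if self.tau != "auto" and (not isinstance(self.tau, int) or self.tau < 1):
            raise ParameterError("tau must be 'auto' or a positive integer")


def run_regcn(network: Network, config: RunConfig):
    """Run the full pipeline; returns (partition, trace, report).

    Stages: one-hot feature fallback, adjacency normalization, hop
    distances, density-peak seeding, iterative center refinement
    (optional), affinity/top-k pseudo-label expansion (optional) and a
    final freshly initialized GCN trained on the pseudo-labeled set.
    Metrics appear in the report when the network carries truth labels.
    """
    if config.k > network.n_nodes:
        raise ParameterError("K cannot exceed the number of nodes")
    net = network if network.features is not None else one_hot_features(network)
    a_hat = normalize_adjacency(net)

    distances = shortest_path_distances(net)
    profile = centrality_profile(distances, config.d_c)
    seeds = select_initial_centers(profile.phi, config.k)
    report = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "k": config.k,
        "initial_centers": list(seeds.centers),
    }

    base_train = replace(config.train, seed=config.seed)
    trace = RefinementTrace(stop_reason="refinement disabled")
    z = None
    partition = None
    if config.refine:
        seeds, partition, z, trace = refine_centers(
            net,
            seeds,
            weights=config.slp_weights,
            train_cfg=base_train,
            max_iter=config.max_refine_iter,
        )
        report["refined_centers"] = list(seeds.centers)
        report["refine_iterations"] = len(trace)
        report["refine_stop_reason"] = trace.stop_reason

    if config.expand:
        if z is None:
            # no refinement pass: a preliminary GCN supplies the Z and
            # temporary partition that the expansion step reads
            _, z = train(a_hat, net.features, seeds, config.k,
                         replace(base_train, seed=config.seed + 1))
            partition = predict_partition(z)
        if config.tau == "auto":
            tau = tau_lower_bound(net.n_nodes, config.k, net.mean_degree)
        else:
            tau = int(config.tau)
        report["tau"] = tau
        if config.expansion == "affinity":
            pseudo = expand_affinity(z, partition, seeds, tau)
        else:
            pseudo = expand_topk(z, tau)
        report["pseudo_labeled_per_community"] = [len(s) for s in pseudo.sets]
    else:
        pseudo = seeds
        report["tau"] = 1

    final_cfg = replace(base_train, seed=config.seed + FINAL_SEED_OFFSET)
    _, z_final = train(a_hat, net.features, pseudo, config.k, final_cfg)
    final_partition = predict_partition(z_final)

    sizes = np.bincount(final_partition, minlength=config.k + 1)[1:]
    report["community_sizes"] = [int(s) for s in sizes]
    empty = int(np.sum(sizes == 0))
    if empty:
        logger.warning("%d final community(ies) are empty", empty)
        report["empty_communities"] = empty
    if net.truth_labels is not None:
        report["metrics"] = score_partition(
            net.truth_labels, final_partition, as_percent=True
        )
    return final_partition, trace, report


_VARIANTS = (
    ("w/o ReSC & PLSet", False, False),
    ("w/o ReSC", False, True),
    ("w/o PLSet", True, False),
    ("Full model", True, True),
)


def run_ablation_suite(spec: SBMSpec, config: RunConfig, n_seeds: int = 1) -> list:
    """Run the four model variants on matched generated instances.

    For each of ``n_seeds`` draws, the same graph and the same base
    seed feed all four variants, so differences reflect only the
    ablated stages.  Returns one row per variant with mean and standard
    deviation of ACC/NMI/ARI in percent.
    """
    if n_seeds < 1:
        raise ParameterError("n_seeds must be >= 1")
    per_variant = {name: [] for name, _, _ in _VARIANTS}
    for s in range(n_seeds):
        net = generate_sbm(replace(spec, seed=spec.seed + s))
        for name, refine, expand in _VARIANTS:
            cfg = replace(config, k=spec.k, refine=refine, expand=expand,
                          seed=config.seed + s)
            _, _, report = run_regcn(net, cfg)
            per_variant[name].append(report["metrics"])
    rows = []
    for name, _, _ in _VARIANTS:
        scores = per_variant[name]
        row = {"variant": name, "n_seeds": n_seeds}
        for m in ("acc", "nmi", "ari"):
            vals = np.array([s[m] for s in scores])
            row[f"{m}_mean"] = float(vals.mean())
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if n_seeds > 1 else 0.0
        rows.append(row)
    return rows


def tau_sweep(network: Network, config: RunConfig, tau_values) -> list:
    """Evaluate both expansion strategies across a grid of tau values.

    Returns one row per (tau, strategy) with metrics in percent; each
    row also records the computed lower bound for reference.
    """
    tau_values = [int(t) for t in tau_values]
    if any(t < 1 for t in tau_values):
        raise ParameterError("tau values must be positive")
    bound = tau_lower_bound(network.n_nodes, config.k, network.mean_degree)
    rows = []
    for tau in tau_values:
        for strategy in ("affinity", "topk"):
            cfg = replace(config, tau=tau, expansion=strategy, expand=True)
            _, _, report = run_regcn(network, cfg)
            row = {
                "tau": tau,
                "strategy": strategy,
                "tau_lower_bound": bound,
                **report.get("metrics", {}),
            }
            rows.append(row)
    return rows
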