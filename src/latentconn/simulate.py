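"""Synthetic two-group connectome samples with planted differential networks.

The generator emulates the analysis-ready object of a two-group resting-state
connectivity study: per subject, a symmetric Fisher-Z connectivity matrix over
a shared node table.  Group A is the reference ("control-like") group; planted
mean shifts apply to group B only, so ``delta < 0`` plants hypoconnectivity in
group B and ``delta > 0`` hyperconnectivity.

Two modes are provided.  The direct-matrix mode draws every edge independently
as ``Normal(mu0 + delta_g_ij, sigma^2)`` — exactly the exchangeable,
cross-edge-independent null the downstream permutation test assumes, and the
tractable oracle for calibration studies.  The time-series mode instead draws
correlated Gaussian ROI signals whose population correlation matrix encodes
the planted structure, exercising the Pearson/Fisher-Z front-end and giving
cross-edge dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import ConnectomeSample, default_node_table, edge_index_pairs, write_sample

CLIQUE = "clique"
K_PARTITE = "k_partite"


@dataclass(frozen=True)
class PlantedNetwork:
    """A planted differential subnetwork.

    ``nodes`` are 1-based node ids (atlas indices of the generated node
    table).  For ``clique`` topology every within-``nodes`` pair is affected;
    for ``k_partite`` exactly the between-set pairs of ``partition`` are
    affected and within-set pairs carry no shift.  ``delta`` is the group-B
    mean shift in Fisher-Z units on every affected edge; ``sign_pattern``
    optionally overrides its sign (``uniform_hypo`` forces -|delta|,
    ``uniform_hyper`` +|delta|, ``mixed`` uses the explicit per-edge
    ``sign_map``).
    """

    nodes: tuple[int, ...]
    topology: str
    delta: float
    partition: tuple[tuple[int, ...], ...] | None = None
    sign_pattern: str | None = None
    sign_map: dict[tuple[int, int], int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(int(v) for v in self.nodes))
        if self.topology not in (CLIQUE, K_PARTITE):
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        if self.delta == 0:
            raise ConfigurationError("planted delta must be nonzero")
        if len(set(self.nodes)) != len(self.nodes):
            raise ConfigurationError("planted node list contains duplicates")
        if self.topology == K_PARTITE:
            if self.partition is None or len(self.partition) < 2:
                raise ConfigurationError("k_partite network needs a partition with >= 2 sets")
            part = tuple(tuple(int(v) for v in block) for block in self.partition)
            object.__setattr__(self, "partition", part)
            flat = [v for block in part for v in block]
            if sorted(flat) != sorted(self.nodes) or len(set(flat)) != len(flat):
                raise ConfigurationError(
                    "k_partite partition must be disjoint sets covering the node list"
                )
            if any(len(block) == 0 for block in part):
                raise ConfigurationError("k_partite partition sets must be nonempty")
        elif self.partition is not None:
            raise ConfigurationError("partition is only meaningful for k_partite topology")
        if self.sign_pattern not in (None, "uniform_hypo", "uniform_hyper", "mixed"):
            raise ConfigurationError(f"unknown sign_pattern {self.sign_pattern!r}")
        if self.sign_pattern == "mixed" and not self.sign_map:
            raise ConfigurationError("mixed sign_pattern requires an explicit sign_map")

    def affected_edges(self) -> list[tuple[int, int]]:
        """Affected unordered node-id pairs (i < j), derived from topology alone."""
        if self.topology == CLIQUE:
            pairs = combinations(sorted(self.nodes), 2)
        else:
            pairs = (
                (u, v)
                for a, block_a in enumerate(self.partition)
                for block_b in self.partition[a + 1 :]
                for u in block_a
                for v in block_b
            )
        return sorted(tuple(sorted(p)) for p in pairs)

    def edge_deltas(self) -> dict[tuple[int, int], float]:
        """Per affected edge, the true group-B minus group-A mean difference."""
        out: dict[tuple[int, int], float] = {}
        for edge in self.affected_edges():
            if self.sign_pattern == "uniform_hypo":
                d = -abs(self.delta)
            elif self.sign_pattern == "uniform_hyper":
                d = abs(self.delta)
            elif self.sign_pattern == "mixed":
                if edge not in self.sign_map:
                    raise ConfigurationError(f"sign_map is missing edge {edge}")
                d = int(np.sign(self.sign_map[edge])) * abs(self.delta)
            else:
                d = self.delta
            out[edge] = d
        return out


@dataclass
class GeneratorConfig:
    """Study-level configuration for the synthetic generator.

    Defaults mirror a two-group resting-state study over the 90-region AAL
    parcellation with 48 case-like and 65 control-like subjects.  Baseline
    edge mean 0.3 and subject noise 0.3 keep Fisher-Z values in the range
    typical of resting-state functional connectivity.
    """

    n_nodes: int = 90
    n_subjects_a: int = 65
    n_subjects_b: int = 48
    baseline_mean: float = 0.3
    subject_sd: float = 0.3
    planted_networks: tuple[PlantedNetwork, ...] = ()
    group_labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_networks = tuple(self.planted_networks)
        if self.n_nodes < 3:
            raise ConfigurationError("n_nodes must be >= 3")
        if min(self.n_subjects_a, self.n_subjects_b) < 2:
            raise ConfigurationError("each group needs >= 2 subjects")
        if self.subject_sd <= 0:
            raise ConfigurationError("subject_sd must be positive")
        seen: set[int] = set()
        for net in self.planted_networks:
            bad = [v for v in net.nodes if not 1 <= v <= self.n_nodes]
            if bad:
                raise ConfigurationError(f"planted node ids {bad} outside 1..{self.n_nodes}")
            overlap = seen & set(net.nodes)
            if overlap:
                raise ConfigurationError(
                    f"planted node sets overlap on nodes {sorted(overlap)}"
                )
            seen |= set(net.nodes)


@dataclass
class GroundTruthNetwork:
    nodes: tuple[int, ...]
    topology: str
    partition: tuple[tuple[int, ...], ...] | None
    edge_deltas: dict[tuple[int, int], float]


@dataclass
class GroundTruth:
    """Planted structure emitted alongside each sample, for scoring recovery."""

    networks: list[GroundTruthNetwork] = field(default_factory=list)

    def to_json(self) -> str:
        payload = [
            {
                "nodes": list(net.nodes),
                "topology": net.topology,
                "partition": None if net.partition is None else [list(b) for b in net.partition],
                "edge_deltas": {f"{i}-{j}": d for (i, j), d in sorted(net.edge_deltas.items())},
            }
            for net in self.networks
        ]
        return json.dumps(payload, indent=2, sort_keys=True)


def _group_mean_edges(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Per-edge population means for groups A and B, plus the ground truth."""
    n = config.n_nodes
    iu, ju = edge_index_pairs(n)
    flat = {(int(i) + 1, int(j) + 1): k for k, (i, j) in enumerate(zip(iu, ju))}
    mean_a = np.full(iu.size, config.baseline_mean)
    mean_b = mean_a.copy()
    truth = GroundTruth()
    for net in config.planted_networks:
        deltas = net.edge_deltas()
        for (u, v), d in deltas.items():
            mean_b[flat[(u, v)]] += d
        truth.networks.append(
            GroundTruthNetwork(net.nodes, net.topology, net.partition, deltas)
        )
    return mean_a, mean_b, truth


def _stack_symmetric(edge_vals: np.ndarray, n_nodes: int) -> np.ndarray:
    iu, ju = edge_index_pairs(n_nodes)
    mats = np.zeros((edge_vals.shape[0], n_nodes, n_nodes))
    mats[:, iu, ju] = edge_vals
    mats[:, ju, iu] = edge_vals
    return mats


def generate_sample(config: GeneratorConfig) -> tuple[ConnectomeSample, GroundTruth]:
    """Draw a two-group sample of symmetric Fisher-Z matrices.

    Each edge of each subject is drawn independently as
    ``Normal(mu0 + delta_g, sigma^2)`` where the shift ``delta_g`` is nonzero
    only on affected edges of planted networks and only for group B.  Equal
    ``(config, seed)`` pairs give bit-identical samples.
    """
    mean_a, mean_b, truth = _group_mean_edges(config)
    rng = np.random.default_rng(config.seed)
    vals_a = rng.normal(mean_a, config.subject_sd, size=(config.n_subjects_a, mean_a.size))
    vals_b = rng.normal(mean_b, config.subject_sd, size=(config.n_subjects_b, mean_b.size))
    mats = _stack_symmetric(np.vstack([vals_a, vals_b]), config.n_nodes)
    la, lb = config.group_labels
    ids = [f"{la}{k:03d}" for k in range(1, config.n_subjects_a + 1)] + [
        f"{lb}{k:03d}" for k in range(1, config.n_subjects_b + 1)
    ]
    groups = np.array([la] * config.n_subjects_a + [lb] * config.n_subjects_b, dtype=object)
    sample = ConnectomeSample(
        node_table=default_node_table(config.n_nodes),
        subject_ids=ids,
        groups=groups,
        matrices=mats,
        group_names=(la, lb),
    )
    return sample, truth


@dataclass
class TimeseriesSample:
    """Per-subject ROI x time signal matrices with shared node table."""

    node_table: pd.DataFrame
    subject_ids: list[str]
    groups: np.ndarray
    series: list[np.ndarray]
    group_names: tuple[str, str]


def _population_correlations(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Group A and B population correlation matrices implied by the config."""
    mean_a, mean_b, _ = _group_mean_edges(config)
    iu, ju = edge_index_pairs(config.n_nodes)
    out = []
    for means, label in ((mean_a, "A"), (mean_b, "B")):
        r = np.tanh(means)
        if np.any(np.abs(r) > 0.999):
            k = int(np.argmax(np.abs(r)))
            raise ConfigurationError(
                f"group {label}: Fisher-Z mean {means[k]:.3g} on edge "
                f"({iu[k] + 1}, {ju[k] + 1}) implies a near-singular correlation "
                f"{r[k]:.4f}; reduce the planted delta or baseline"
            )
        R = np.eye(config.n_nodes)
        R[iu, ju] = r
        R[ju, iu] = r
        eig = np.linalg.eigvalsh(R)
        if eig.min() <= 1e-10:
            raise ConfigurationError(
                f"group {label}: implied population correlation matrix is not "
                f"positive-definite (min eigenvalue {eig.min():.3g}); the planted "
                "deltas are too large for the baseline correlation"
            )
        out.append(R)
    return out[0], out[1]


def generate_timeseries_sample(
    config: GeneratorConfig, n_timepoints: int
) -> tuple[TimeseriesSample, GroundTruth]:
    """Draw correlated Gaussian ROI time series encoding the planted structure.

    Subjects in group g share the population correlation matrix whose
    Fisher-Z image has the group means implied by ``config``; sampling noise
    from the finite series provides between-subject variability.  The implied
    correlation matrix is verified positive-definite before sampling.
    """
    if n_timepoints < 10:
        raise ConfigurationError("n_timepoints must be >= 10")
    _, _, truth = _group_mean_edges(config)
    R_a, R_b = _population_correlations(config)
    chol = {0: np.linalg.cholesky(R_a), 1: np.linalg.cholesky(R_b)}
    rng = np.random.default_rng(config.seed)
    la, lb = config.group_labels
    ids, groups, series = [], [], []
    for gi, (label, n_subj) in enumerate(
        ((la, config.n_subjects_a), (lb, config.n_subjects_b))
    ):
        for k in range(1, n_subj + 1):
            x = rng.standard_normal((n_timepoints, config.n_nodes)) @ chol[gi].T
            series.append(x.T)  # ROI x time
            ids.append(f"{label}{k:03d}")
            groups.append(label)
    ts = TimeseriesSample(
        node_table=default_node_table(config.n_nodes),
        subject_ids=ids,
        groups=np.array(groups, dtype=object),
        series=series,
        group_names=(la, lb),
    )
    return ts, truth


def connectome_from_timeseries(ts: TimeseriesSample) -> ConnectomeSample:
    """Apply the Pearson/Fisher-Z front-end to every subject's series."""
    from .io import correlation_to_z

    mats = np.stack([correlation_to_z(x) for x in ts.series])
    return ConnectomeSample(
        node_table=ts.node_table,
        subject_ids=list(ts.subject_ids),
        groups=ts.groups.copy(),
        matrices=mats,
        group_names=ts.group_names,
    )


def write_generated(
    sample: ConnectomeSample, truth: GroundTruth, out_dir: str | Path
) -> Path:
    """Write a generated sample plus its ground truth under ``out_dir``."""
    out = write_sample(sample, out_dir)
    (out / "ground_truth.json").write_text(truth.to_json() + "\n")
    return out


def config_from_dict(raw: dict) -> GeneratorConfig:
    """Build a GeneratorConfig from a plain (e.g. YAML-loaded) mapping."""
    nets = []
    for item in raw.get("planted_networks", []) or []:
        sign_map = item.get("sign_map")
        if sign_map is not None:
            sign_map = {
                tuple(sorted(int(x) for x in key.split("-"))): int(val)
                for key, val in sign_map.items()
            }
        nets.append(
            PlantedNetwork(
                nodes=tuple(item["nodes"]),
                topology=item.get("topology", CLIQUE),
                delta=float(item["delta"]),
                partition=None
                if item.get("partition") is None
                else tuple(tuple(b) for b in item["partition"]),
                sign_pattern=item.get("sign_pattern"),
                sign_map=sign_map,
            )
        )
    kwargs = {
        key: raw[key]
        for key in (
            "n_nodes",
            "n_subjects_a",
            "n_subjects_b",
            "baseline_mean",
            "subject_sd",
            "seed",
        )
        if key in raw
    }
    if "group_labels" in raw:
        kwargs["group_labels"] = tuple(raw["group_labels"])
    return GeneratorConfig(planted_networks=tuple(nets), **kwargs)
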