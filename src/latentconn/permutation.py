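"""Network-level significance by max-statistic permutation of group labels.

Each permutation reruns the *entire* pipeline — edgewise tests on relabeled
subjects, then the full detection pass — and records the best detected
network's score (0 when nothing positive is found).  Comparing every observed
network against this distribution of maxima controls the family-wise error
over the enormous implicit family of candidate subgraphs, including the
selection step itself.  p-values use the add-one estimator
``(1 + #{max_b >= score}) / (B + 1)`` and are therefore never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import DetectedNetwork, DetectionConfig, max_network_score
from .edgewise import _LOG_BASES, P_FLOOR, _test_edges
from .exceptions import ConfigurationError
from .io import ConnectomeSample, edge_index_pairs

MIN_PERMUTATIONS = 19  # below this, alpha = 0.05 cannot be resolved


@dataclass
class NullDistribution:
    """Per-permutation maxima of the network score."""

    n_permutations: int
    max_scores: np.ndarray
    seed: int

    def write(self, path: str | Path) -> None:
        np.savetxt(path, self.max_scores, fmt="%.17g")


@dataclass
class InferenceResult:
    networks: list[DetectedNetwork]
    alpha: float
    significant: list[bool]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, (net, sig) in enumerate(zip(self.networks, self.significant), start=1):
            rows.append(
                {
                    "rank": rank,
                    "size": len(net.nodes),
                    "topology": net.topology,
                    "k": net.k,
                    "score": net.score,
                    "p_value": net.p_value,
                    "significant": sig,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["rank", "size", "topology", "k", "score", "p_value", "significant"],
        )


def _weights_from_labels(
    edge_vals: np.ndarray,
    mask_a: np.ndarray,
    n_nodes: int,
    welch: bool,
    log_base: str,
) -> np.ndarray:
    """Dense W recomputed for an arbitrary group-A membership mask."""
    t, p = _test_edges(edge_vals[mask_a], edge_vals[~mask_a], welch)
    p = np.clip(p, P_FLOOR, 1.0)
    w = -np.log(p) / np.log(_LOG_BASES[log_base])
    iu, ju = edge_index_pairs(n_nodes)
    W = np.zeros((n_nodes, n_nodes))
    W[iu, ju] = w
    W[ju, iu] = w
    return W


def permutation_test(
    sample: ConnectomeSample,
    networks: list[DetectedNetwork],
    config: DetectionConfig,
    B: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    welch: bool = False,
    log_base: str = "e",
) -> tuple[InferenceResult, NullDistribution]:
    """Assign a network-level p-value to every observed network.

    ``networks`` must come from the same detection configuration on the
    unpermuted sample.  Label permutations preserve group sizes; each
    permutation draws from an independently spawned RNG stream so results do
    not depend on execution order.  Deterministic for fixed
    ``(sample, config, B, seed)``.
    """
    if B < MIN_PERMUTATIONS:
        raise ConfigurationError(
            f"need at least {MIN_PERMUTATIONS} permutations to resolve alpha = 0.05"
        )
    mask_a, _ = sample.group_masks()
    n_a = int(mask_a.sum())
    n_subj = sample.n_subjects
    edge_vals = sample.edge_values()
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(B)]
    max_scores = np.empty(B)
    for b, rng in enumerate(streams):
        perm = rng.permutation(n_subj)
        pmask = np.zeros(n_subj, dtype=bool)
        pmask[perm[:n_a]] = True
        W = _weights_from_labels(edge_vals, pmask, sample.n_nodes, welch, log_base)
        max_scores[b] = max_network_score(W, config)
    null = NullDistribution(n_permutations=B, max_scores=max_scores, seed=seed)
    scored = []
    flags = []
    for net in networks:
        p = (1.0 + float((max_scores >= net.score - 1e-12).sum())) / (B + 1.0)
        scored.append(replace(net, p_value=p))
        flags.append(p < alpha)
    return InferenceResult(networks=scored, alpha=alpha, significant=flags), null


def summarize_inference(result: InferenceResult) -> pd.DataFrame:
    """One report row per network: rank, size, topology, score, p, flag."""
    return result.to_frame()
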