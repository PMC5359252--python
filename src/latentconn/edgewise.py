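"""Edgewise two-sample tests and the weighted evidence graph W.

For each of the n(n-1)/2 unordered node pairs, connectivity values are
compared between the two groups with a two-sample t test (pooled-variance
Student by default, Welch optionally) and the edge is weighted by
``W_ij = -log(p_ij)``: the larger the weight, the stronger the evidence that
the edge is differentially expressed.  No edgewise multiplicity correction is
applied here — multiplicity is handled downstream by the network-level
max-statistic permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .io import ConnectomeSample, edge_index_pairs, read_node_table, validate_node_table

#: p-values are clipped here before the log so W is always finite
P_FLOOR = float(np.finfo(np.float64).tiny)

_LOG_BASES = {"e": np.e, "10": 10.0}


@dataclass
class EdgeEvidence:
    """Per-edge test results over all unordered node pairs (i < j).

    ``node_i``/``node_j`` are 0-based node-table positions; ``sign`` is the
    sign of mean(group A) - mean(group B), so +1 marks edges where the
    reference group is more strongly connected.  ``w = -log(p)`` in the
    configured base (natural log by default).
    """

    node_i: np.ndarray
    node_j: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sign: np.ndarray
    w: np.ndarray
    n_a: int
    n_b: int
    group_names: tuple[str, str]
    node_table: pd.DataFrame
    log_base: str = "e"
    n_clipped: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.node_table)

    @property
    def n_edges(self) -> int:
        return self.p.size

    def to_frame(self) -> pd.DataFrame:
        """Edge list with 1-based atlas indices, for serialization."""
        atlas = self.node_table["index"].to_numpy()
        return pd.DataFrame(
            {
                "node_i": atlas[self.node_i],
                "node_j": atlas[self.node_j],
                "t": self.t,
                "p": self.p,
                "sign": self.sign,
                "W": self.w,
            }
        )


def _test_edges(
    vals_a: np.ndarray, vals_b: np.ndarray, welch: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample t over columns; returns (t, two-sided p)."""
    na, nb = vals_a.shape[0], vals_b.shape[0]
    mean_a, mean_b = vals_a.mean(axis=0), vals_b.mean(axis=0)
    var_a = vals_a.var(axis=0, ddof=1)
    var_b = vals_b.var(axis=0, ddof=1)
    if welch:
        se2 = var_a / na + var_b / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1))
    else:
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        se2 = pooled * (1.0 / na + 1.0 / nb)
        df = np.full_like(se2, na + nb - 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def edgewise_tests(
    sample: ConnectomeSample, welch: bool = False, log_base: str = "e"
) -> EdgeEvidence:
    """Run the two-sample test on every edge and assemble the evidence graph.

    Raises on a group with fewer than 2 subjects and on any edge whose
    within-group variance is zero in both groups (the test statistic is
    undefined there).  p-values are clipped below at the smallest positive
    normal double before the log so every weight is finite; the number of
    clipped edges is recorded on the result.
    """
    if log_base not in _LOG_BASES:
        raise ConfigurationError(f"log_base must be one of {sorted(_LOG_BASES)}")
    mask_a, mask_b = sample.group_masks()
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if min(na, nb) < 2:
        raise ValidationError(f"each group needs >= 2 subjects (got {na} and {nb})")
    vals = sample.edge_values()
    vals_a, vals_b = vals[mask_a], vals[mask_b]
    var_a = vals_a.var(axis=0, ddof=1)
    var_b = vals_b.var(axis=0, ddof=1)
    iu, ju = edge_index_pairs(sample.n_nodes)
    dead = (var_a == 0) & (var_b == 0)
    if dead.any():
        k = int(np.argwhere(dead)[0][0])
        atlas = sample.node_table["index"].to_numpy()
        raise ValidationError(
            f"edge ({atlas[iu[k]]}, {atlas[ju[k]]}) has zero variance in both groups"
        )
    t, p = _test_edges(vals_a, vals_b, welch)
    n_clipped = int((p < P_FLOOR).sum())
    p = np.clip(p, P_FLOOR, 1.0)
    w = -np.log(p) / np.log(_LOG_BASES[log_base])
    sign = np.sign(t).astype(int)
    return EdgeEvidence(
        node_i=iu,
        node_j=ju,
        t=t,
        p=p,
        sign=sign,
        w=w,
        n_a=na,
        n_b=nb,
        group_names=sample.group_names,
        node_table=sample.node_table,
        log_base=log_base,
        n_clipped=n_clipped,
    )


def weight_matrix(evidence: EdgeEvidence) -> np.ndarray:
    """Dense symmetric W with zero diagonal, in node-table order."""
    n = evidence.n_nodes
    W = np.zeros((n, n))
    W[evidence.node_i, evidence.node_j] = evidence.w
    W[evidence.node_j, evidence.node_i] = evidence.w
    return W


def write_evidence(evidence: EdgeEvidence, out_dir: str | Path) -> Path:
    """Write the edge list (CSV), dense weight matrix and node table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    evidence.to_frame().to_csv(out / "edges.csv", index=False, float_format="%.17g")
    np.savetxt(out / "weights.txt", weight_matrix(evidence), fmt="%.17g")
    validate_node_table(evidence.node_table).to_csv(out / "nodes.csv", index=False)
    meta = pd.DataFrame(
        {
            "group_a": [evidence.group_names[0]],
            "group_b": [evidence.group_names[1]],
            "n_a": [evidence.n_a],
            "n_b": [evidence.n_b],
            "log_base": [evidence.log_base],
            "n_clipped": [evidence.n_clipped],
        }
    )
    meta.to_csv(out / "meta.csv", index=False)
    return out


def read_evidence(evidence_dir: str | Path) -> EdgeEvidence:
    d = Path(evidence_dir)
    table = read_node_table(d / "nodes.csv")
    edges = pd.read_csv(d / "edges.csv")
    meta = pd.read_csv(d / "meta.csv", dtype={"group_a": str, "group_b": str})
    atlas = table["index"].to_numpy()
    pos = {int(v): k for k, v in enumerate(atlas)}
    return EdgeEvidence(
        node_i=edges["node_i"].map(pos).to_numpy(),
        node_j=edges["node_j"].map(pos).to_numpy(),
        t=edges["t"].to_numpy(float),
        p=edges["p"].to_numpy(float),
        sign=edges["sign"].to_numpy(int),
        w=edges["W"].to_numpy(float),
        n_a=int(meta["n_a"][0]),
        n_b=int(meta["n_b"][0]),
        group_names=(str(meta["group_a"][0]), str(meta["group_b"][0])),
        node_table=table,
        log_base=str(meta["log_base"][0]),
        n_clipped=int(meta["n_clipped"][0]),
    )
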