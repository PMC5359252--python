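"""Reading and writing of the pipeline's on-disk objects.

All user-facing files are plain delimited text: subject connectivity
matrices are dense whitespace-delimited ``n x n`` blocks with no header
(row/column order fixed by the node table), the node table and subject
manifest are small CSVs, and reports are CSV plus a JSON summary.  Atlas
indices are 1-based in every file; 0-based row positions are an internal
convention only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

NODE_TABLE_COLUMNS = ["name", "abbrev", "index", "x", "y", "z"]

#: matrices with a larger max |M - M.T| entry are rejected rather than symmetrized
ASYMMETRY_TOLERANCE = 1e-6
#: a validated sample must be symmetric at least this tightly
SYMMETRY_TOLERANCE = 1e-8


def default_node_table(n_nodes: int) -> pd.DataFrame:
    """Generic node table for synthetic data: 1-based indices, zero coordinates."""
    return pd.DataFrame(
        {
            "name": [f"Region {k}" for k in range(1, n_nodes + 1)],
            "abbrev": [f"R{k}" for k in range(1, n_nodes + 1)],
            "index": np.arange(1, n_nodes + 1),
            "x": 0.0,
            "y": 0.0,
            "z": 0.0,
        }
    )


def validate_node_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in NODE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"node table is missing columns {missing}")
    if table["index"].duplicated().any():
        dupes = sorted(table.loc[table["index"].duplicated(), "index"].tolist())
        raise ValidationError(f"node table has duplicate atlas indices {dupes}")
    return table.reset_index(drop=True)


@dataclass
class ConnectomeSample:
    """Two labeled groups of symmetric per-subject Fisher-Z matrices.

    ``matrices`` has shape ``(n_subjects, n_nodes, n_nodes)`` and shares the
    row/column order of ``node_table``.  ``group_names`` lists the two labels
    in order of first appearance in the manifest; the first is the reference
    group ("A") for every directional statistic downstream.
    """

    node_table: pd.DataFrame
    subject_ids: list[str]
    groups: np.ndarray
    matrices: np.ndarray
    group_names: tuple[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.node_table = validate_node_table(self.node_table)
        self.groups = np.asarray(self.groups, dtype=object)
        labels = list(dict.fromkeys(self.groups.tolist()))
        if len(labels) != 2:
            raise ValidationError(
                f"expected exactly 2 group labels, found {len(labels)}: {labels}"
            )
        if self.group_names is None:
            self.group_names = (labels[0], labels[1])
        n = len(self.node_table)
        if self.matrices.shape != (len(self.subject_ids), n, n):
            raise ValidationError(
                f"matrix stack shape {self.matrices.shape} does not match "
                f"{len(self.subject_ids)} subjects over {n} nodes"
            )
        for sid, mat in zip(self.subject_ids, self.matrices):
            if not np.isfinite(mat).all():
                r, c = np.argwhere(~np.isfinite(mat))[0]
                raise ValidationError(
                    f"subject {sid!r}: non-finite value at cell ({r + 1}, {c + 1})"
                )
            asym = np.abs(mat - mat.T).max()
            if asym > SYMMETRY_TOLERANCE:
                raise ValidationError(
                    f"subject {sid!r}: matrix asymmetry {asym:.3g} exceeds "
                    f"{SYMMETRY_TOLERANCE:g}"
                )
        # diagonal is definitionally zero (self-connectivity is not an edge)
        self.matrices[:, np.arange(n), np.arange(n)] = 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.node_table)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        a, b = self.group_names
        return self.groups == a, self.groups == b

    def edge_values(self) -> np.ndarray:
        """Upper-triangle edge values, shape ``(n_subjects, n_edges)``.

        Edge order is row-major over pairs (i, j) with i < j in node-table
        position, matching :func:`edge_index_pairs`.
        """
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return self.matrices[:, iu, ju]


def edge_index_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """0-based (i, j) positions of the n(n-1)/2 unordered edges, i < j."""
    return np.triu_indices(n_nodes, k=1)


def read_node_table(path: str | Path) -> pd.DataFrame:
    return validate_node_table(pd.read_csv(path))


def write_node_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_node_table(table)[NODE_TABLE_COLUMNS].to_csv(path, index=False)


def read_sample(
    matrix_dir: str | Path, manifest: str | Path, node_table: str | Path
) -> ConnectomeSample:
    """Load and validate a two-group sample of connectivity matrices.

    Each subject's matrix lives in ``matrix_dir/<subject_id>.txt`` as a dense
    whitespace- or comma-delimited block.  Mild asymmetries (below
    ``ASYMMETRY_TOLERANCE``) are repaired as ``(M + M.T) / 2``; anything
    larger is an error.
    """
    table = read_node_table(node_table)
    man = pd.read_csv(manifest, dtype=str)
    if not {"subject_id", "group"} <= set(man.columns):
        raise ValidationError("manifest must have columns subject_id,group")
    labels = list(dict.fromkeys(man["group"].tolist()))
    if len(labels) != 2:
        raise ValidationError(
            f"expected exactly 2 group labels in manifest, found {len(labels)}: {labels}"
        )
    n = len(table)
    matrix_dir = Path(matrix_dir)
    mats = np.empty((len(man), n, n))
    for k, sid in enumerate(man["subject_id"]):
        path = matrix_dir / f"{sid}.txt"
        try:
            mat = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",")
        except OSError as exc:
            raise ValidationError(f"subject {sid!r}: cannot read {path}") from exc
        if mat.shape != (n, n):
            raise ValidationError(
                f"subject {sid!r}: matrix shape {mat.shape} does not match "
                f"{n}-node table"
            )
        if not np.isfinite(mat).all():
            r, c = np.argwhere(~np.isfinite(mat))[0]
            raise ValidationError(
                f"subject {sid!r}: non-finite value at cell ({r + 1}, {c + 1})"
            )
        asym = np.abs(mat - mat.T).max()
        if asym >= ASYMMETRY_TOLERANCE:
            raise ValidationError(
                f"subject {sid!r}: matrix asymmetry {asym:.3g} exceeds "
                f"{ASYMMETRY_TOLERANCE:g}"
            )
        mats[k] = (mat + mat.T) / 2.0
    return ConnectomeSample(
        node_table=table,
        subject_ids=man["subject_id"].tolist(),
        groups=man["group"].to_numpy(dtype=object),
        matrices=mats,
        group_names=(labels[0], labels[1]),
    )


def _is_whitespace(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return "," not in first


def write_sample(sample: ConnectomeSample, out_dir: str | Path) -> Path:
    """Write a sample as matrices/, manifest.csv and nodes.csv under ``out_dir``."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    write_node_table(sample.node_table, out / "nodes.csv")
    pd.DataFrame({"subject_id": sample.subject_ids, "group": sample.groups}).to_csv(
        out / "manifest.csv", index=False
    )
    for sid, mat in zip(sample.subject_ids, sample.matrices):
        np.savetxt(out / "matrices" / f"{sid}.txt", mat, fmt="%.17g")
    return out


def read_sample_dir(sample_dir: str | Path) -> ConnectomeSample:
    d = Path(sample_dir)
    return read_sample(d / "matrices", d / "manifest.csv", d / "nodes.csv")


def correlation_to_z(roi_timeseries: np.ndarray) -> np.ndarray:
    """Fisher-Z connectivity matrix of an ROI x time signal matrix.

    Off-diagonal entry (i, j) is ``atanh(r_ij)`` where r is the Pearson
    product-moment correlation of ROI rows i and j; the diagonal is zero.
    Perfect correlations (|r| = 1) have no finite Fisher-Z image and are
    rejected, as are constant ROI signals (undefined correlation).
    """
    ts = np.asarray(roi_timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValidationError("expected a 2-D ROI x time matrix")
    if ts.shape[1] < 3:
        raise ValidationError("need at least 3 timepoints")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        roi = int(np.argwhere(sd == 0)[0][0])
        raise ValidationError(f"ROI {roi + 1} has a constant signal")
    r = np.corrcoef(ts)
    np.fill_diagonal(r, 0.0)
    if np.any(np.abs(r) >= 1.0 - 1e-12):
        i, j = np.argwhere(np.abs(r) >= 1.0 - 1e-12)[0]
        raise ValidationError(
            f"ROIs {i + 1} and {j + 1} are perfectly correlated (|r| = 1); "
            "Fisher-Z is infinite"
        )
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return (z + z.T) / 2.0


def write_network_report(
    networks: Sequence,
    evidence,
    node_table: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Emit the presentation bundle for a list of detected networks.

    Writes ``heatmap_order.csv`` (node ordering placing detected networks
    first), one ``network_<k>_edges.csv`` per network (node pair, t, p, W,
    direction) and ``networks_summary.json`` (score, p-value, topology,
    partition).
    """
    # local import: report builds on io types but io only needs its functions here
    from .report import directional_edge_table, heatmap_order

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = validate_node_table(node_table)
    order = heatmap_order(list(networks), table)
    ordered = table.iloc[order].reset_index(drop=True)
    ordered.insert(0, "heatmap_position", np.arange(1, len(ordered) + 1))
    ordered.to_csv(out / "heatmap_order.csv", index=False)

    summary = []
    for k, net in enumerate(networks, start=1):
        rows = directional_edge_table(net, evidence, table)
        rows.to_csv(out / f"network_{k}_edges.csv", index=False)
        atlas = table["index"].to_numpy()
        summary.append(
            {
                "rank": k,
                "topology": net.topology,
                "nodes": [int(atlas[v]) for v in sorted(net.nodes)],
                "partition": None
                if net.partition is None
                else [[int(atlas[v]) for v in sorted(block)] for block in net.partition],
                "n_edges": len(net.scoring_edges),
                "score": float(net.score),
                "p_value": None if net.p_value is None else float(net.p_value),
            }
        )
    with open(out / "networks_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
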