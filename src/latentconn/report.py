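"""Presentation artifacts and classification-based validation.

``heatmap_order`` produces the node permutation that places detected
networks in leading diagonal blocks of a reordered evidence heatmap;
``directional_edge_table`` lists each network's scoring edges with the
direction of the group difference (labels built from the manifest's group
names, never hardcoded); ``classify_loocv`` validates detected networks by
leave-one-out classification of subjects from their edge features with a
margin-based kernel classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .detect import DetectedNetwork, DetectionConfig, detect_all
from .edgewise import EdgeEvidence, edgewise_tests, weight_matrix
from .exceptions import ValidationError
from .io import ConnectomeSample, validate_node_table

_KERNELS = {"linear_kernel": "linear", "rbf_kernel": "rbf"}


@dataclass
class ClassificationReport:
    feature_edges: tuple[tuple[int, int], ...]
    classifier_kind: str
    n_correct: int
    n_total: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


def heatmap_order(
    networks: list[DetectedNetwork], node_table: pd.DataFrame
) -> np.ndarray:
    """Node ordering (0-based positions) listing detected networks first.

    Networks appear in descending score order; within a clique, nodes sort by
    atlas index, and within a k-partite network block 1 precedes block 2,
    each block in atlas order.  Remaining nodes follow in atlas order.  The
    result is always a permutation of all node positions.
    """
    table = validate_node_table(node_table)
    atlas = table["index"].to_numpy()
    seen: set[int] = set()
    for net in networks:
        overlap = seen & set(net.nodes)
        if overlap:
            raise ValidationError(f"networks overlap on node positions {sorted(overlap)}")
        bad = [v for v in net.nodes if not 0 <= v < len(table)]
        if bad:
            raise ValidationError(f"network references unknown node positions {bad}")
        seen |= set(net.nodes)
    order: list[int] = []
    by_atlas = lambda vs: sorted(vs, key=lambda v: atlas[v])  # noqa: E731
    for net in sorted(networks, key=lambda nw: (-nw.score, nw.nodes)):
        if net.partition is not None:
            for block in net.partition:
                order.extend(by_atlas(block))
        else:
            order.extend(by_atlas(net.nodes))
    order.extend(by_atlas(v for v in range(len(table)) if v not in seen))
    return np.array(order, dtype=int)


def directional_edge_table(
    network: DetectedNetwork, evidence: EdgeEvidence, node_table: pd.DataFrame
) -> pd.DataFrame:
    """One row per scoring edge with abbreviations and a direction label.

    Direction is ``'<A>><B>'`` when the reference group's mean is larger
    (sign +1) and ``'<B>><A>'`` when smaller; a zero test statistic yields
    ``'equal'``.  Rows sort by W descending with a stable node-index
    tie-break.
    """
    table = validate_node_table(node_table)
    abbrev = table["abbrev"].to_numpy()
    atlas = table["index"].to_numpy()
    lut = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(evidence.node_i, evidence.node_j))}
    ga, gb = evidence.group_names
    rows = []
    for i, j in network.scoring_edges:
        k = lut[(min(i, j), max(i, j))]
        sign = int(evidence.sign[k])
        rows.append(
            {
                "node_i": int(atlas[i]),
                "node_j": int(atlas[j]),
                "abbrev_i": abbrev[i],
                "abbrev_j": abbrev[j],
                "t": float(evidence.t[k]),
                "p": float(evidence.p[k]),
                "W": float(evidence.w[k]),
                "direction": f"{ga}>{gb}" if sign > 0 else f"{gb}>{ga}" if sign < 0 else "equal",
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["node_i", "node_j", "abbrev_i", "abbrev_j", "t", "p", "W", "direction"],
    )
    return frame.sort_values(
        ["W", "node_i", "node_j"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)


def _edge_features(sample: ConnectomeSample, feature_edges) -> np.ndarray:
    edges = [(min(i, j), max(i, j)) for i, j in feature_edges]
    if not edges:
        raise ValidationError("feature edge list is empty")
    ii = np.array([e[0] for e in edges])
    jj = np.array([e[1] for e in edges])
    return sample.matrices[:, ii, jj]


def classify_loocv(
    sample: ConnectomeSample,
    feature_edges,
    classifier_kind: str = "rbf_kernel",
    C: float = 1.0,
    standardize: bool = True,
    nested_config: DetectionConfig | None = None,
) -> ClassificationReport:
    """Leave-one-out accuracy of a kernel SVM on subject edge features.

    Features are each subject's Fisher-Z values on ``feature_edges``,
    standardized on the training fold.  By default the feature edges are
    fixed across folds (mirroring post-hoc validation of networks detected on
    the full sample, which is optimistic because selection leaks into the
    folds); pass ``nested_config`` to re-detect networks within every
    training fold for an honest estimate — folds where nothing is detected
    fall back to the supplied edge list.
    """
    if classifier_kind not in _KERNELS:
        raise ValidationError(f"classifier_kind must be one of {sorted(_KERNELS)}")
    mask_a, mask_b = sample.group_masks()
    if min(mask_a.sum(), mask_b.sum()) < 2:
        raise ValidationError("LOOCV requires >= 2 subjects per group")
    y = (sample.groups == sample.group_names[1]).astype(int)
    n = sample.n_subjects
    edges = tuple((min(i, j), max(i, j)) for i, j in feature_edges)
    X_fixed = _edge_features(sample, edges)
    n_correct = 0
    for held in range(n):
        train = np.ones(n, dtype=bool)
        train[held] = False
        if len(np.unique(y[train])) < 2:
            raise ValidationError("training fold contains a single class")
        if nested_config is not None:
            fold_edges = _fold_edges(sample, train, nested_config) or edges
            X = _edge_features(sample, fold_edges)
        else:
            X = X_fixed
        X_train, X_test = X[train], X[held : held + 1]
        if standardize:
            scaler = StandardScaler().fit(X_train)
            X_train = scaler.transform(X_train)
            X_test = scaler.transform(X_test)
        clf = SVC(kernel=_KERNELS[classifier_kind], C=C, gamma="scale")
        clf.fit(X_train, y[train])
        n_correct += int(clf.predict(X_test)[0] == y[held])
    return ClassificationReport(
        feature_edges=edges,
        classifier_kind=classifier_kind,
        n_correct=n_correct,
        n_total=n,
    )


def _fold_edges(
    sample: ConnectomeSample, train: np.ndarray, config: DetectionConfig
) -> tuple[tuple[int, int], ...]:
    """Union of scoring edges of networks re-detected on a training fold."""
    fold = ConnectomeSample(
        node_table=sample.node_table,
        subject_ids=[s for s, keep in zip(sample.subject_ids, train) if keep],
        groups=sample.groups[train],
        matrices=sample.matrices[train],
        group_names=sample.group_names,
    )
    evidence = edgewise_tests(fold)
    networks = detect_all(weight_matrix(evidence), config)
    edges: set[tuple[int, int]] = set()
    for net in networks:
        edges |= set(net.scoring_edges)
    return tuple(sorted(edges))
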