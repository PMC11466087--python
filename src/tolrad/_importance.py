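"""Out-of-bag permutation importance (mean decrease in accuracy) for forests.

scikit-learn does not expose per-tree bootstrap masks, but each fitted
tree stores the integer seed of its bootstrap draw, which is defined as
``RandomState(seed).randint(0, n, n)`` (int32).  The masks are
reconstructed from those seeds; the test-suite cross-checks the
reconstruction against the forest's own OOB aggregation.

The engine evaluates every permuted design in a single ``forest.apply``
call per repeat and converts leaf ids to per-tree class votes with array
indexing, keeping the cost linear in trees rather than
trees × features × Python-call overhead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils import check_random_state

__all__ = ["oob_masks", "oob_accuracy", "oob_mda", "tree_votes"]


def oob_masks(forest: RandomForestClassifier, n_samples: int) -> np.ndarray:
    """Boolean (n_trees, n_samples) array: True where a sample is OOB for a tree."""
    masks = np.ones((len(forest.estimators_), n_samples), dtype=bool)
    for t, est in enumerate(forest.estimators_):
        rs = check_random_state(est.random_state)
        # sklearn draws bootstrap indices as int32; the stream is dtype-dependent
        idx = rs.randint(0, n_samples, n_samples, dtype=np.int32)
        masks[t, idx] = False
    return masks


def tree_votes(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Per-tree predicted class indices, shape (n_rows, n_trees).

    One ``forest.apply`` call resolves every row to a leaf in every tree;
    leaf ids are mapped to the majority class stored at each leaf.
    """
    if hasattr(forest, "feature_names_in_"):
        # forests fit on DataFrames expect named columns in the same order
        X = pd.DataFrame(X, columns=forest.feature_names_in_)
    leaves = forest.apply(X)
    preds = np.empty(leaves.shape, dtype=np.int64)
    for t, est in enumerate(forest.estimators_):
        value = est.tree_.value  # (n_nodes, 1, n_classes) class proportions
        preds[:, t] = value[leaves[:, t], 0, :].argmax(axis=1)
    return preds


def _encode_labels(forest: RandomForestClassifier, y) -> np.ndarray:
    classes = list(forest.classes_)
    return np.asarray([classes.index(v) for v in y], dtype=np.int64)


def oob_accuracy(forest: RandomForestClassifier, X, y) -> float:
    """Mean per-tree OOB accuracy under the reconstructed bootstrap masks."""
    X = np.asarray(X, dtype=np.float32)
    y_enc = _encode_labels(forest, y)
    masks = oob_masks(forest, X.shape[0])
    preds = tree_votes(forest, X)
    accs = [
        float(np.mean(preds[masks[t], t] == y_enc[masks[t]]))
        for t in range(preds.shape[1])
        if masks[t].any()
    ]
    if not accs:
        raise RuntimeError("no tree had out-of-bag samples; increase sample size")
    return float(np.mean(accs))


def oob_mda(
    forest: RandomForestClassifier,
    X,
    y,
    rng: np.random.Generator,
    n_repeats: int = 1,
) -> np.ndarray:
    """Per-feature OOB mean decrease in accuracy (fraction scale).

    For each repeat, every column is permuted once across all samples and
    each tree is scored on its OOB rows; MDA for a feature is the mean
    over trees (and repeats) of baseline OOB accuracy minus permuted OOB
    accuracy.  Permuting a constant column yields exactly 0.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=np.float32)
    n, n_feat = X.shape
    y_enc = _encode_labels(forest, y)
    masks = oob_masks(forest, n)
    n_trees = len(forest.estimators_)
    mda = np.zeros(n_feat)
    for _ in range(n_repeats):
        # stacked design: block 0 = original, block f+1 = column f permuted
        stacked = np.tile(X, (n_feat + 1, 1, 1))
        for f in range(n_feat):
            stacked[f + 1, :, f] = X[rng.permutation(n), f]
        flat = stacked.reshape((n_feat + 1) * n, n_feat)
        # (F+1, n, T) correctness of every tree's vote on every block
        correct = (
            tree_votes(forest, flat).reshape(n_feat + 1, n, n_trees)
            == y_enc[None, :, None]
        )
        diffs = np.zeros(n_feat)
        n_trees_used = 0
        for t in range(n_trees):
            oob = masks[t]
            if not oob.any():
                continue
            base = correct[0, oob, t].mean()
            perm = correct[1:, oob, t].mean(axis=1)
            diffs += base - perm
            n_trees_used += 1
        if n_trees_used == 0:
            raise RuntimeError("no tree had out-of-bag samples; increase sample size")
        mda += diffs / n_trees_used
    return mda / n_repeats
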