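"""Voxelwise encoding models.

Model features are reduced by PCA to the smallest number of components
retaining 99% of the variance; those component scores are the regressors
of a per-voxel ordinary-least-squares model, evaluated by leave-one-out
cross-validation over conditions.  Accuracy per voxel is the Pearson
correlation between the assembled held-out predictions and the actual
activation series.  For response-stage encoding the stimulus and probe
feature rows are concatenated trial-wise before the PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.decomposition import PCA


@dataclass
class EncodingDesign:
    """PC-score regressor matrix X [n_cond x p] plus provenance."""

    X: np.ndarray
    variance_retained: float
    n_components: int
    source_layer: str = ""
    stage: str = "memory"


@dataclass
class EncodingResult:
    per_voxel_accuracy: np.ndarray
    predictions: np.ndarray
    per_region_mean: dict[str, float]


def reduce_features(
    features: np.ndarray,
    var_target: float = 0.99,
    source_layer: str = "",
    stage: str = "memory",
) -> EncodingDesign:
    """PCA-reduce a feature table to PCs retaining >= ``var_target`` variance.

    The PCA is fitted on the analysis conditions themselves; scores are
    centered by construction.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("features must be a nonempty 2-D array")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 conditions")
    pca = PCA(svd_solver="full").fit(X)
    evr = pca.explained_variance_ratio_
    # guard rank deficiency: drop numerically-zero components
    nonzero = evr > 1e-12
    cum = np.cumsum(evr[nonzero])
    k = int(np.searchsorted(cum, var_target) + 1)
    k = min(k, nonzero.sum())
    scores = pca.transform(X)[:, :k]
    return EncodingDesign(
        X=scores,
        variance_retained=float(cum[k - 1]),
        n_components=k,
        source_layer=source_layer,
        stage=stage,
    )


def concat_stage_features(
    stim_features: np.ndarray, probe_features: np.ndarray
) -> np.ndarray:
    """Trial-aligned row-wise concatenation of stimulus and probe features."""
    a = np.asarray(stim_features, dtype=float)
    b = np.asarray(probe_features, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"row mismatch: {a.shape[0]} stimulus vs {b.shape[0]} probe rows"
        )
    return np.concatenate([a, b], axis=1)


def loocv_encode(
    design: EncodingDesign,
    Y: np.ndarray,
    region_labels: np.ndarray | None = None,
) -> EncodingResult:
    """Leave-one-condition-out OLS encoding of voxel activations.

    For each fold an intercept-augmented OLS model is fitted on the
    remaining conditions and predicts the held-out condition; the
    assembled prediction series is correlated with the actual series per
    voxel.  The per-fold intercept is estimated but excluded from the
    assembled predictions: Pearson accuracy is location-invariant, and the
    intercept tracks the training-fold mean, which would inject a spurious
    negative correlation into leave-one-out series under the null.
    ``region_labels`` (one label per voxel) yields per-region mean
    accuracies.
    """
    X = design.X
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise ValueError("Y must be [n_cond x n_voxels] aligned with the design")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(
            f"n_cond={n} too small for p={p} regressors + intercept per "
            "LOOCV fold; lower var_target"
        )
    Xi = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(Xi)
    if rank < Xi.shape[1]:
        raise ValueError(
            "rank-deficient design matrix; lower var_target to drop "
            "redundant components"
        )
    preds = np.empty_like(Y)
    for held in range(n):
        mask = np.arange(n) != held
        beta, *_ = np.linalg.lstsq(Xi[mask], Y[mask], rcond=None)
        preds[held] = X[held] @ beta[1:]
    acc = np.empty(Y.shape[1])
    for v in range(Y.shape[1]):
        if Y[:, v].std() == 0 or preds[:, v].std() == 0:
            acc[v] = 0.0
        else:
            acc[v] = pearsonr(preds[:, v], Y[:, v]).statistic
    per_region: dict[str, float] = {}
    if region_labels is not None:
        region_labels = np.asarray(region_labels)
        for region in np.unique(region_labels):
            per_region[str(region)] = float(acc[region_labels == region].mean())
    else:
        per_region["all"] = float(acc.mean())
    return EncodingResult(
        per_voxel_accuracy=acc, predictions=preds, per_region_mean=per_region
    )


def accuracy_table(result: EncodingResult) -> pd.DataFrame:
    return pd.DataFrame(
        {"voxel": np.arange(len(result.per_voxel_accuracy)),
         "accuracy": result.per_voxel_accuracy}
    )
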