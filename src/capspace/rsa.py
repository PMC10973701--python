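"""Representational similarity analysis (RSA).

A representational dissimilarity matrix (RDM) summarizes a system's
geometry as the pairwise dissimilarity of its condition patterns.
Euclidean distance is used for hand-drawn features and computational
models; correlation distance (1 - Pearson r between patterns) for
brain-like activation tables.  Two RDMs are compared by correlating their
strict upper triangles — Spearman when hand-feature RDMs are involved
(their entries are not normally distributed), Pearson between
computational-model and brain RDMs.

Significance comes from condition-label permutation tests (default 1000
permutations) with the add-one p-value estimator; the stricter
"observed exceeds the null maximum" criterion is reported as a separate
boolean.  Noise ceilings treat the group-mean RDM as a proxy for the ideal
model: the upper bound correlates each subject's RDM with the group mean,
the lower bound with the leave-one-subject-out group mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

Metric = Literal["euclidean", "correlation_distance"]
Method = Literal["pearson", "spearman"]


@dataclass(frozen=True)
class RDM:
    matrix: np.ndarray
    metric: str
    condition_ids: tuple

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM matrix must be square")
        if len(self.condition_ids) != m.shape[0]:
            raise ValueError("condition_ids length must match matrix size")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("RDM must be symmetric")

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]

    def triangle(self) -> np.ndarray:
        """The vectorized strict upper triangle."""
        iu = np.triu_indices(self.n_conditions, k=1)
        return self.matrix[iu]

    def subset(self, indices: Sequence[int]) -> "RDM":
        """Restrict to a subset of conditions (e.g. one memory-load split)."""
        idx = np.asarray(indices)
        return RDM(
            matrix=self.matrix[np.ix_(idx, idx)],
            metric=self.metric,
            condition_ids=tuple(self.condition_ids[i] for i in idx),
        )


@dataclass(frozen=True)
class RSAResult:
    r: float
    method: str
    p_perm: float | None = None
    n_perm: int | None = None
    exceeds_null_max: bool | None = None


@dataclass(frozen=True)
class NoiseCeiling:
    upper: float
    lower: float


def compute_rdm(
    features: np.ndarray,
    metric: Metric = "euclidean",
    condition_ids: Sequence | None = None,
) -> RDM:
    """Pairwise-dissimilarity matrix of condition patterns (rows).

    ``correlation_distance`` is 1 - Pearson r between rows and requires
    every row to have nonzero variance.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D [n_conditions x d]")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 conditions")
    if condition_ids is None:
        condition_ids = tuple(range(n))
    if metric == "euclidean":
        d = pdist(X, metric="euclidean")
    elif metric == "correlation_distance":
        if X.shape[1] < 2:
            raise ValueError("correlation_distance needs at least 2 features")
        stds = X.std(axis=1)
        bad = np.flatnonzero(stds == 0)
        if bad.size:
            raise ValueError(
                f"zero-variance rows {bad.tolist()} are incompatible with "
                "correlation distance"
            )
        d = pdist(X, metric="correlation")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    mat = squareform(d)
    np.fill_diagonal(mat, 0.0)
    return RDM(matrix=mat, metric=metric, condition_ids=tuple(condition_ids))


def _check_aligned(a: RDM, b: RDM) -> None:
    if a.condition_ids != b.condition_ids:
        raise ValueError("RDMs have mismatched condition sets/order")


def _corr(x: np.ndarray, y: np.ndarray, method: Method) -> float:
    if x.std() == 0 or y.std() == 0:
        raise ValueError("RDM triangle has zero variance; correlation undefined")
    if method == "pearson":
        return float(pearsonr(x, y).statistic)
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def compare_rdms(rdm_a: RDM, rdm_b: RDM, method: Method = "pearson") -> RSAResult:
    """Correlation between two RDMs over their strict upper triangles."""
    _check_aligned(rdm_a, rdm_b)
    r = _corr(rdm_a.triangle(), rdm_b.triangle(), method)
    return RSAResult(r=r, method=method)


def permutation_test(
    rdm_model: RDM,
    rdm_target: RDM,
    method: Method = "pearson",
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> RSAResult:
    """Condition-label permutation test of an RDM correlation.

    The null is built by jointly permuting rows and columns of the target
    RDM and recomputing the correlation; p uses the add-one estimator
    p = (1 + #{null >= observed}) / (1 + n_perm).  ``exceeds_null_max``
    reports the stricter criterion that the observed correlation exceeds
    the largest null correlation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_aligned(rdm_model, rdm_target)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = rdm_model.triangle()
    observed = _corr(x, rdm_target.triangle(), method)
    n = rdm_target.n_conditions
    null = np.empty(n_perm)
    tm = rdm_target.matrix
    for k in range(n_perm):
        perm = rng.permutation(n)
        shuffled = tm[np.ix_(perm, perm)]
        iu = np.triu_indices(n, k=1)
        null[k] = _corr(x, shuffled[iu], method)
    p = (1 + np.sum(null >= observed)) / (1 + n_perm)
    return RSAResult(
        r=observed,
        method=method,
        p_perm=float(p),
        n_perm=n_perm,
        exceeds_null_max=bool(observed > null.max()),
    )


def noise_ceiling(
    subject_rdms: Sequence[RDM], method: Method = "pearson"
) -> NoiseCeiling:
    """Upper/lower noise ceiling from inter-subject RDM variability."""
    if len(subject_rdms) < 3:
        raise ValueError("need at least 3 subjects for a noise ceiling")
    for r in subject_rdms[1:]:
        _check_aligned(subject_rdms[0], r)
    tris = np.stack([r.triangle() for r in subject_rdms])
    group = tris.mean(axis=0)
    n = tris.shape[0]
    upper = np.mean([_corr(tris[i], group, method) for i in range(n)])
    lower = np.mean(
        [
            _corr(
                tris[i],
                (group * n - tris[i]) / (n - 1),
                method,
            )
            for i in range(n)
        ]
    )
    return NoiseCeiling(upper=float(upper), lower=float(lower))


def behavior_correlation(
    per_subject_similarity: np.ndarray,
    per_subject_accuracy: np.ndarray,
    roi_labels: Sequence | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation between model-brain similarity and accuracy.

    ``per_subject_similarity`` is [n_subjects] (overall) or
    [n_subjects x n_rois]; with multiple ROIs the p-values are
    Benjamini-Hochberg adjusted across ROIs.  Returns one row per ROI with
    columns r, p, p_fdr, significant.
    """
    sim = np.asarray(per_subject_similarity, dtype=float)
    acc = np.asarray(per_subject_accuracy, dtype=float)
    if sim.ndim == 1:
        sim = sim[:, None]
    if sim.shape[0] != acc.shape[0]:
        raise ValueError("similarity and accuracy must have equal lengths")
    if sim.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    if acc.std() == 0:
        raise ValueError("accuracy has zero variance")
    if roi_labels is None:
        roi_labels = (
            ["overall"] if sim.shape[1] == 1 else list(range(sim.shape[1]))
        )
    rows = []
    for j, label in enumerate(roi_labels):
        col = sim[:, j]
        if col.std() == 0:
            raise ValueError(f"similarity for ROI {label!r} has zero variance")
        res = pearsonr(col, acc)
        rows.append({"roi": label, "r": float(res.statistic), "p": float(res.pvalue)})
    df = pd.DataFrame(rows)
    reject, p_fdr, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
    df["p_fdr"] = p_fdr
    df["significant"] = reject
    return df


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg adjustment; returns (reject flags, adjusted p)."""
    reject, p_adj, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def rdm_to_frame(rdm: RDM) -> pd.DataFrame:
    """Square TSV-friendly view with condition labels."""
    labels = [str(c) for c in rdm.condition_ids]
    return pd.DataFrame(rdm.matrix, index=labels, columns=labels)
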