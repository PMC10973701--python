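"""Representational-change analysis.

The change of representation between two systems (e.g. between the
capsule vectors and the capsule norms of the same layer, or between two
brain regions) is the difference of their z-scored RDMs: each RDM's
strict upper triangle is standardized to mean 0 / sd 1 before the
subtraction, so the difference is invariant to affine rescaling of either
source.  "Change from X to Y" means z(RDM_Y) - z(RDM_X).

``repchange_rsa`` correlates a model change-RDM with region-pair
change-RDMs per subject (Pearson over the triangle, condition-label
permutation p), and reports for each region pair the fraction of subjects
significant at alpha, flagging pairs at or above a 90% threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rsa import RDM, permutation_test


@dataclass(frozen=True)
class DiffRDM:
    matrix: np.ndarray
    source_a: str
    source_b: str
    condition_ids: tuple

    def triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu]


def zscore_rdm(rdm: RDM) -> RDM:
    """Standardize the strict upper triangle to mean 0, sd 1 (ddof=1).

    The standardized triangle is mirrored back symmetrically; the diagonal
    stays 0.  Raises on a zero-variance triangle.
    """
    n = rdm.n_conditions
    if n < 3:
        raise ValueError("need at least 3 conditions")
    tri = rdm.triangle()
    sd = tri.std(ddof=1)
    if sd == 0:
        raise ValueError("RDM triangle has zero variance; z-score undefined")
    z = (tri - tri.mean()) / sd
    mat = np.zeros_like(rdm.matrix)
    iu = np.triu_indices(n, k=1)
    mat[iu] = z
    mat = mat + mat.T
    return RDM(matrix=mat, metric=f"zscored_{rdm.metric}", condition_ids=rdm.condition_ids)


def diff_rdm(rdm_a: RDM, rdm_b: RDM, name_a: str = "a", name_b: str = "b") -> DiffRDM:
    """z(rdm_a) - z(rdm_b)."""
    if rdm_a.condition_ids != rdm_b.condition_ids:
        raise ValueError("RDMs have mismatched conditions")
    za = zscore_rdm(rdm_a)
    zb = zscore_rdm(rdm_b)
    return DiffRDM(
        matrix=za.matrix - zb.matrix,
        source_a=name_a,
        source_b=name_b,
        condition_ids=rdm_a.condition_ids,
    )


def change_rdm(rdm_from: RDM, rdm_to: RDM, name_from: str = "from", name_to: str = "to") -> DiffRDM:
    """Representational change from one system to another: z(to) - z(from)."""
    return diff_rdm(rdm_to, rdm_from, name_a=name_to, name_b=name_from)


def _to_rdm(d: DiffRDM) -> RDM:
    # DiffRDM entries are signed; wrap without the nonnegativity semantics
    return RDM(matrix=d.matrix, metric="diff", condition_ids=d.condition_ids)


def repchange_rsa(
    model_diff: DiffRDM,
    subject_region_pairs: Sequence[Mapping[tuple[str, str], DiffRDM]],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    subject_fraction: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate a model change-RDM with region-pair change-RDMs per subject.

    ``subject_region_pairs``: one mapping {(regionA, regionB): DiffRDM} per
    subject.  Returns (per_subject, aggregate): a long-format table
    (subject, region_pair, r, p, significant) and a per-pair summary with
    the mean r, the fraction of significant subjects and the
    >= ``subject_fraction`` flag.
    """
    if not subject_region_pairs or not subject_region_pairs[0]:
        raise ValueError("empty region-pair map")
    model = _to_rdm(model_diff)
    rng = np.random.default_rng(seed)
    rows = []
    pairs = list(subject_region_pairs[0].keys())
    for s, per_pair in enumerate(subject_region_pairs):
        for pair in pairs:
            res = permutation_test(
                model, _to_rdm(per_pair[pair]), method="pearson",
                n_perm=n_perm, seed=rng,
            )
            rows.append(
                {
                    "subject": s,
                    "region_pair": f"{pair[0]}->{pair[1]}",
                    "r": res.r,
                    "p": res.p_perm,
                    "significant": res.p_perm < alpha,
                }
            )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("region_pair")
        .agg(r=("r", "mean"), frac_significant=("significant", "mean"))
        .reset_index()
    )
    agg["flagged"] = agg["frac_significant"] >= subject_fraction
    return df, agg
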