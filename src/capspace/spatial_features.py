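"""Hand-defined high-level spatial features of circle arrays.

Spatial location features (SLFs): the number of circle centers in each of
the four 90-degree quadrants around the fixation cross, plus the centroid
(x, y) of the circle centers.  Spatial distance features (SDFs): mean
distance of circles to the fixation cross, mean distance to the origin
(bottom-left corner), and mean pairwise inter-circle distance (defined as 0
for a single circle).  The abstract descriptor VFN & SFN concatenates the
L2 norms of (a) the image's principal-component scores, (b) the SLF vector
and (c) the SDF vector.

All SLF/SDF values are computed exactly from the generating ``CircleSpec``
lists, never from pixels, so they carry no rasterization error.  Distances
are in pixel units of the 30x30 canvas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .stimuli import FIXATION_CENTER, CircleSpec, RenderedImage

ORIGIN = (0.0, 0.0)


@dataclass(frozen=True)
class SLF:
    quadrant_counts: tuple[int, int, int, int]
    centroid_x: float
    centroid_y: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [*self.quadrant_counts, self.centroid_x, self.centroid_y],
            dtype=float,
        )


@dataclass(frozen=True)
class SDF:
    mean_dist_fixation: float
    mean_dist_origin: float
    mean_pairwise_dist: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.mean_dist_fixation,
                self.mean_dist_origin,
                self.mean_pairwise_dist,
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class VFNSFN:
    vfn: float
    slfn: float
    sdfn: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.vfn, self.slfn, self.sdfn], dtype=float)


def _centers(circles: Sequence[CircleSpec]) -> np.ndarray:
    if not circles:
        raise ValueError("need at least one circle")
    return np.array([[c.x, c.y] for c in circles], dtype=float)


def quadrant_index(dx: float, dy: float) -> int:
    """Quadrant (0..3, counter-clockwise from the positive x axis) of a point.

    A center exactly on an axis belongs to the quadrant that starts at that
    axis going counter-clockwise (e.g. the positive x axis belongs to
    quadrant 0, the positive y axis to quadrant 1).  A center exactly at
    the anchor falls in quadrant 0.
    """
    theta = np.arctan2(dy, dx) % (2 * np.pi)
    return int(theta // (np.pi / 2)) % 4


def compute_slf(
    circles: Sequence[CircleSpec],
    fixation: tuple[float, float] = FIXATION_CENTER,
) -> SLF:
    """Quadrant counts around the fixation plus the centroid of the centers."""
    centers = _centers(circles)
    counts = [0, 0, 0, 0]
    fx, fy = fixation
    for x, y in centers:
        counts[quadrant_index(x - fx, y - fy)] += 1
    cx, cy = centers.mean(axis=0)
    return SLF(
        quadrant_counts=tuple(counts), centroid_x=float(cx), centroid_y=float(cy)
    )


def compute_sdf(
    circles: Sequence[CircleSpec],
    fixation: tuple[float, float] = FIXATION_CENTER,
    origin: tuple[float, float] = ORIGIN,
) -> SDF:
    """Mean Euclidean distances to the fixation, to the origin, and pairwise."""
    centers = _centers(circles)
    d_fix = np.hypot(centers[:, 0] - fixation[0], centers[:, 1] - fixation[1])
    d_org = np.hypot(centers[:, 0] - origin[0], centers[:, 1] - origin[1])
    n = len(centers)
    if n == 1:
        pairwise = 0.0
    else:
        diffs = centers[:, None, :] - centers[None, :, :]
        dists = np.hypot(diffs[..., 0], diffs[..., 1])
        iu = np.triu_indices(n, k=1)
        pairwise = float(dists[iu].mean())
    return SDF(
        mean_dist_fixation=float(d_fix.mean()),
        mean_dist_origin=float(d_org.mean()),
        mean_pairwise_dist=pairwise,
    )


@dataclass
class ImagePCABasis:
    """PCA basis over flattened 2700-dim pixel vectors of training images."""

    pca: PCA
    n_pixels: int
    degenerate: bool

    @property
    def n_components(self) -> int:
        return self.pca.n_components_

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    def transform(self, images: Sequence[RenderedImage]) -> np.ndarray:
        X = np.stack([im.flat() for im in images])
        if X.shape[1] != self.n_pixels:
            raise ValueError(
                f"images have {X.shape[1]} pixels, basis expects {self.n_pixels}"
            )
        return self.pca.transform(X)


def fit_image_pca(
    training_images: Sequence[RenderedImage],
    n_components: int | float = 0.95,
) -> ImagePCABasis:
    """Fit a PCA basis to flattened training images.

    ``n_components`` may be an int (exact count) or a float in (0, 1)
    (retain that fraction of variance; default 0.95).  Raises if an integer
    request exceeds the feasible rank.  A degenerate training set (total
    pixel variance ~ 0, e.g. identical images) is flagged.
    """
    X = np.stack([im.flat() for im in training_images])
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if isinstance(n_components, (int, np.integer)):
        if n_components > max_rank:
            raise ValueError(
                f"n_components={n_components} exceeds feasible rank {max_rank}"
            )
        if n_components < 1:
            raise ValueError("integer n_components must be >= 1")
    total_var = float(X.var(axis=0).sum())
    degenerate = total_var < 1e-12
    if degenerate:
        # PCA with a variance target is undefined on zero variance; keep 1 comp
        with np.errstate(invalid="ignore"):
            pca = PCA(n_components=1, svd_solver="full").fit(X)
    else:
        pca = PCA(n_components=n_components, svd_solver="full").fit(X)
    return ImagePCABasis(pca=pca, n_pixels=X.shape[1], degenerate=degenerate)


def compute_vfn_sfn(
    image: RenderedImage,
    circles: Sequence[CircleSpec],
    basis: ImagePCABasis,
    fixation: tuple[float, float] = FIXATION_CENTER,
) -> VFNSFN:
    """The 3-vector of L2 norms: image PC scores, SLF vector, SDF vector."""
    scores = basis.transform([image])[0]
    slf = compute_slf(circles, fixation)
    sdf = compute_sdf(circles, fixation)
    return VFNSFN(
        vfn=float(np.linalg.norm(scores)),
        slfn=float(np.linalg.norm(slf.as_vector())),
        sdfn=float(np.linalg.norm(sdf.as_vector())),
    )


def feature_table(
    images: Sequence[RenderedImage],
    basis: ImagePCABasis,
    fixation: tuple[float, float] = FIXATION_CENTER,
) -> pd.DataFrame:
    """Per-image hand-feature table: 6 SLF, 3 SDF and 3 VFN&SFN columns."""
    rows = []
    for im in images:
        slf = compute_slf(im.source, fixation)
        sdf = compute_sdf(im.source, fixation)
        vs = compute_vfn_sfn(im, im.source, basis, fixation)
        rows.append(
            {
                "q1": slf.quadrant_counts[0],
                "q2": slf.quadrant_counts[1],
                "q3": slf.quadrant_counts[2],
                "q4": slf.quadrant_counts[3],
                "centroid_x": slf.centroid_x,
                "centroid_y": slf.centroid_y,
                "mean_dist_fixation": sdf.mean_dist_fixation,
                "mean_dist_origin": sdf.mean_dist_origin,
                "mean_pairwise_dist": sdf.mean_pairwise_dist,
                "vfn": vs.vfn,
                "slfn": vs.slfn,
                "sdfn": vs.sdfn,
            }
        )
    return pd.DataFrame(rows)


SLF_COLUMNS = ["q1", "q2", "q3", "q4", "centroid_x", "centroid_y"]
SDF_COLUMNS = ["mean_dist_fixation", "mean_dist_origin", "mean_pairwise_dist"]
VFNSFN_COLUMNS = ["vfn", "slfn", "sdfn"]
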