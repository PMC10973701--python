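"""Synthetic multi-subject brain-like activations with planted geometry.

Real fMRI is out of scope; this module generates per-subject region ->
(condition x voxel) activation tables whose representational geometry is a
controllable mixture of a planted target RDM and independent structure,
plus per-subject behavioral accuracies tied to the planted model-brain
similarity.  That gives every downstream analysis (RSA, noise ceilings,
encoding, mediation, representational change, behavior correlation) a
known ground truth to recover.

Embedding construction: a target correlation-distance RDM D is turned
into patterns whose *sample* correlation matrix equals C = 1 - D exactly:
C is factored as X X^T (eigenvalue factor, with small negative
eigenvalues clipped and reported) and X is expanded into voxel space by a
random orthonormal, zero-mean column basis — orthonormality makes the
pattern covariance reproduce C, and the zero-mean columns make the
sample-mean corrections vanish.

A desk-scale general-linear-model simulator mirrors the activation-
estimation step of task fMRI: stage timings convolved with the canonical
double-gamma hemodynamic response (peak 6 s, undershoot 16 s,
peak:undershoot 6), sampled at TR = 2 s, plus white noise; betas are
re-estimated by OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .rsa import RDM, compute_rdm
from .stimuli import Paradigm

DEFAULT_REGIONS = ("frontal", "ventral", "dorsal", "early_visual", "hippocampus")


@dataclass
class SubjectActivation:
    subject_id: str
    regions: dict[str, np.ndarray]
    planted: dict


class EmbeddingError(ValueError):
    """Raised when a target RDM cannot be embedded as correlation geometry."""


def _correlation_factor(
    target_rdm: RDM, tol: float = 0.05
) -> tuple[np.ndarray, float]:
    """Factor C = 1 - D as X X^T with unit diagonal; returns (X, residual).

    Small negative eigenvalues (indefiniteness up to ``tol`` of the top
    eigenvalue, in Frobenius terms) are clipped; beyond that the RDM is
    declared non-embeddable.
    """
    D = target_rdm.matrix
    C = 1.0 - D
    np.fill_diagonal(C, 1.0)
    w, V = np.linalg.eigh(C)
    resid = float(np.linalg.norm(np.minimum(w, 0.0)) / max(np.linalg.norm(w), 1e-12))
    if resid > tol:
        raise EmbeddingError(
            f"target RDM is not embeddable as a correlation geometry: "
            f"negative-eigenvalue residual {resid:.4f} > tol {tol}"
        )
    w = np.clip(w, 0.0, None)
    X = V * np.sqrt(w)
    # renormalize rows so self-correlations are exactly 1 after clipping
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    X = X / np.where(norms > 0, norms, 1.0)
    return X, resid


def _zero_mean_orthonormal(
    rng: np.random.Generator, n_voxels: int, k: int
) -> np.ndarray:
    """[n_voxels x k] matrix with orthonormal, zero-mean columns."""
    if n_voxels < k + 1:
        raise ValueError(f"need n_voxels >= {k + 1} to embed {k} dimensions")
    G = rng.standard_normal((n_voxels, k))
    G -= G.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(G)
    Q -= Q.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(Q)
    return Q[:, :k]


def embed_rdm(
    target_rdm: RDM, n_voxels: int, rng: np.random.Generator, tol: float = 0.05
) -> np.ndarray:
    """Patterns [n_cond x n_voxels] whose sample correlation RDM equals the target."""
    X, _ = _correlation_factor(target_rdm, tol=tol)
    Q = _zero_mean_orthonormal(rng, n_voxels, X.shape[1])
    return X @ Q.T


def simulate_region(
    target_rdm: RDM,
    n_voxels: int,
    lam: float,
    noise_sd: float,
    rng: np.random.Generator,
    tol: float = 0.05,
) -> np.ndarray:
    """Condition x voxel patterns mixing planted and independent geometry.

    output = lam * signal + (1 - lam) * distractor + noise, where signal
    embeds ``target_rdm`` exactly and the distractor embeds an independent
    random geometry.  At lam=1, noise_sd=0 the correlation-distance RDM of
    the output reproduces the target.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    n_cond = target_rdm.n_conditions
    signal = embed_rdm(target_rdm, n_voxels, rng, tol=tol)
    distractor = rng.standard_normal((n_cond, n_voxels))
    distractor -= distractor.mean(axis=1, keepdims=True)
    distractor /= np.linalg.norm(distractor, axis=1, keepdims=True)
    out = lam * signal + (1.0 - lam) * distractor
    if noise_sd > 0:
        # scale noise relative to the unit-norm pattern rows
        out = out + noise_sd / np.sqrt(n_voxels) * rng.standard_normal(out.shape)
    return out


def _region_rdm(patterns: np.ndarray, condition_ids) -> RDM:
    return compute_rdm(
        patterns, metric="correlation_distance", condition_ids=condition_ids
    )


def simulate_cohort(
    n_subjects: int,
    target_rdms: Mapping[str, RDM],
    per_region_lambda: Mapping[str, float] | float = 0.7,
    n_voxels: int | Mapping[str, int] = 60,
    noise_sd: float = 0.3,
    subject_lambda_sd: float = 0.15,
    behavior_slope: float = 0.5,
    behavior_intercept: float = 1.4,
    behavior_noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[list[SubjectActivation], np.ndarray, dict]:
    """Generate a multi-subject cohort with planted geometry and behavior.

    Each subject's mixing weight per region is the region's lambda plus a
    subject-level offset (sd ``subject_lambda_sd``), so subjects vary in
    how faithfully their activations express the planted RDM.  Accuracy is
    a logistic function of the subject's standardized planted similarity
    (mean correlation of the subject's region RDMs with the targets) plus
    noise — so behavior correlates with representational similarity by
    construction.

    Returns (subjects, accuracies, manifest); the manifest records every
    planted parameter and per-subject similarity (the ground truth).
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    regions = list(target_rdms)
    if isinstance(per_region_lambda, (int, float)):
        per_region_lambda = {r: float(per_region_lambda) for r in regions}
    if isinstance(n_voxels, int):
        n_voxels = {r: n_voxels for r in regions}
    root = np.random.SeedSequence(seed)
    subj_seeds = root.spawn(n_subjects)
    offset_rng = np.random.default_rng(root.spawn(1)[0])
    offsets = offset_rng.normal(0.0, subject_lambda_sd, size=n_subjects)
    subjects: list[SubjectActivation] = []
    similarities = np.empty(n_subjects)
    for i in range(n_subjects):
        rng = np.random.default_rng(subj_seeds[i])
        region_data: dict[str, np.ndarray] = {}
        sims = []
        lams = {}
        for r in regions:
            lam = float(np.clip(per_region_lambda[r] + offsets[i], 0.0, 1.0))
            lams[r] = lam
            patterns = simulate_region(
                target_rdms[r], n_voxels[r], lam, noise_sd, rng
            )
            region_data[r] = patterns
            obs = _region_rdm(patterns, target_rdms[r].condition_ids)
            x, y = obs.triangle(), target_rdms[r].triangle()
            sims.append(np.corrcoef(x, y)[0, 1])
        similarities[i] = np.mean(sims)
        subjects.append(
            SubjectActivation(
                subject_id=f"sub-{i:03d}",
                regions=region_data,
                planted={
                    "lambda": lams,
                    "noise_sd": noise_sd,
                    "similarity": float(similarities[i]),
                },
            )
        )
    z = (similarities - similarities.mean()) / max(similarities.std(), 1e-12)
    acc_rng = np.random.default_rng(root.spawn(2)[1])
    logits = behavior_intercept + behavior_slope * z
    accuracies = 1.0 / (1.0 + np.exp(-logits))
    accuracies = np.clip(
        accuracies + acc_rng.normal(0.0, behavior_noise_sd, n_subjects), 0.0, 1.0
    )
    manifest = {
        "n_subjects": n_subjects,
        "regions": regions,
        "per_region_lambda": {k: float(v) for k, v in per_region_lambda.items()},
        "n_voxels": {k: int(v) for k, v in n_voxels.items()},
        "noise_sd": noise_sd,
        "subject_lambda_sd": subject_lambda_sd,
        "behavior": {
            "slope": behavior_slope,
            "intercept": behavior_intercept,
            "noise_sd": behavior_noise_sd,
        },
        "similarities": similarities.tolist(),
        "seed": seed,
    }
    return subjects, accuracies, manifest


def subject_rdms(
    subject: SubjectActivation, condition_ids=None
) -> dict[str, RDM]:
    """Correlation-distance RDM per region of one subject."""
    out = {}
    for r, patterns in subject.regions.items():
        ids = condition_ids or tuple(range(patterns.shape[0]))
        out[r] = _region_rdm(patterns, ids)
    return out


def write_cohort(
    subjects: Sequence[SubjectActivation],
    accuracies: np.ndarray,
    manifest: dict,
    out_dir: str | Path,
) -> None:
    """Per-subject long-format TSVs plus the planted-parameter manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for subj, acc in zip(subjects, accuracies):
        frames = []
        for region, patterns in subj.regions.items():
            df = pd.DataFrame(
                patterns,
                columns=[f"voxel{v}" for v in range(patterns.shape[1])],
            )
            df.insert(0, "condition", np.arange(patterns.shape[0]))
            df.insert(0, "region", region)
            frames.append(df)
        pd.concat(frames).to_csv(
            out / f"{subj.subject_id}_activation.tsv", sep="\t", index=False
        )
    with open(out / "manifest.json", "w") as f:
        json.dump(
            {**manifest, "accuracies": np.asarray(accuracies).tolist()}, f, indent=2
        )


# -- GLM beta simulation -------------------------------------------------


@dataclass
class GLMSim:
    """Event timing + HRF + noise for a desk-scale GLM recovery check."""

    onsets: list[np.ndarray]
    durations: list[np.ndarray]
    true_betas: np.ndarray
    total_time: float
    TR: float = 2.0
    noise_sd: float = 0.0
    hrf_peak: float = 6.0
    hrf_undershoot: float = 16.0
    hrf_ratio: float = 6.0


def double_gamma_hrf(
    t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0, ratio: float = 6.0
) -> np.ndarray:
    """The canonical double-gamma hemodynamic response function."""
    t = np.asarray(t, dtype=float)
    pos = gamma_dist.pdf(t, peak, scale=1.0)
    neg = gamma_dist.pdf(t, undershoot, scale=1.0)
    h = pos - neg / ratio
    peak_val = h.max()
    return h / peak_val if peak_val > 0 else h


def glm_design_matrix(sim: GLMSim, dt: float = 0.1) -> np.ndarray:
    """HRF-convolved design sampled at the TR grid, with an intercept column."""
    n_scans = int(np.floor(sim.total_time / sim.TR))
    t_hi = np.arange(0.0, sim.total_time + 32.0, dt)
    hrf = double_gamma_hrf(
        np.arange(0.0, 32.0, dt), sim.hrf_peak, sim.hrf_undershoot, sim.hrf_ratio
    )
    cols = []
    for onsets, durations in zip(sim.onsets, sim.durations):
        box = np.zeros_like(t_hi)
        for o, d in zip(onsets, durations):
            box[(t_hi >= o) & (t_hi < o + d)] = 1.0
        conv = np.convolve(box, hrf)[: len(t_hi)] * dt
        scan_times = np.arange(n_scans) * sim.TR
        cols.append(np.interp(scan_times, t_hi, conv))
    X = np.column_stack([np.ones(n_scans)] + cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient GLM design matrix")
    return X


def simulate_glm_and_recover(
    sim: GLMSim, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Simulate BOLD = design @ betas + noise; re-estimate betas by OLS.

    Returns (estimated betas without the intercept, max absolute error).
    """
    X = glm_design_matrix(sim)
    beta_full = np.concatenate([[0.0], np.asarray(sim.true_betas, dtype=float)])
    y = X @ beta_full
    if sim.noise_sd > 0:
        y = y + rng.normal(0.0, sim.noise_sd, size=y.shape)
    est, *_ = np.linalg.lstsq(X, y, rcond=None)
    est_betas = est[1:]
    err = float(np.max(np.abs(est_betas - sim.true_betas)))
    return est_betas, err


def glm_from_paradigm(
    paradigm: Paradigm,
    stage: str = "memory",
    true_betas: np.ndarray | None = None,
    iti_s: float = 2.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GLMSim:
    """One regressor per trial for the chosen stage of the SWM timeline.

    Trial timeline: 2 s target array (memory), the trial's delay, 3 s
    response window, then ``iti_s`` of fixation.
    """
    if stage not in ("memory", "response"):
        raise ValueError("stage must be 'memory' or 'response'")
    onsets, durations = [], []
    t = 0.0
    for trial in paradigm.trials:
        if stage == "memory":
            onsets.append(np.array([t]))
            durations.append(np.array([2.0]))
        else:
            onsets.append(np.array([t + 2.0 + trial.delay_s]))
            durations.append(np.array([3.0]))
        t += 2.0 + trial.delay_s + 3.0 + iti_s
    if true_betas is None:
        gen = rng or np.random.default_rng(0)
        true_betas = gen.normal(1.0, 0.5, size=len(onsets))
    return GLMSim(
        onsets=onsets,
        durations=durations,
        true_betas=np.asarray(true_betas, dtype=float),
        total_time=t + 16.0,
        noise_sd=noise_sd,
    )
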