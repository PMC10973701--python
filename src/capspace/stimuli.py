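"""Spatial working memory (SWM) stimulus generation.

The change-detection paradigm: on each trial a target array of 1, 3, 5 or 7
yellow circles is shown around a central fixation cross, followed after a
delay of 1.5, 3 or 4.5 s by a single green probe circle.  The observer
reports whether the probe occupies the position of one of the targets.
Half the trials are true-positive (probe reuses a target position), half
true-negative (probe at least ``d_min`` pixels from every target).

Images are generated natively on a 30x30 RGB canvas with intensities in
[0, 1].  Coordinates are 0-based pixel indices; x grows rightward and y
grows upward, so the origin (0, 0) is the bottom-left corner of the canvas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CANVAS = 30
SET_SIZES = (1, 3, 5, 7)
DELAYS_S = (1.5, 3.0, 4.5)
TRIALS_PER_SET_SIZE = 12
TRIALS_PER_CELL = 4
N_TRIALS = 48

#: RGB triples used by the rasterizer.
COLORS = {
    "yellow": (1.0, 1.0, 0.0),
    "green": (0.0, 1.0, 0.0),
    "white": (1.0, 1.0, 1.0),
}

DEFAULT_RADIUS = 2
#: Fixation cross center in (x, y-from-bottom) pixel coordinates.
FIXATION_CENTER = (15.0, 15.0)
#: Half-length of the fixation cross arms (3 px total extent).
FIXATION_HALF = 1


class Truth(str, Enum):
    TRUE_POSITIVE = "true_positive"
    TRUE_NEGATIVE = "true_negative"


@dataclass(frozen=True)
class CircleSpec:
    """A circle on the canvas: center (x, y), radius (pixels) and color."""

    x: float
    y: float
    radius: float
    color: str

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.color not in ("yellow", "green"):
            raise ValueError(f"unknown circle color {self.color!r}")
        for c in (self.x, self.y):
            if c - self.radius < 0 or c + self.radius >= CANVAS:
                raise ValueError(
                    f"circle at ({self.x}, {self.y}) r={self.radius} "
                    f"extends outside the {CANVAS}x{CANVAS} canvas"
                )

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class TrialSpec:
    set_size: int
    delay_s: float
    truth: Truth
    targets: tuple[CircleSpec, ...]
    probe: CircleSpec

    def __post_init__(self) -> None:
        if self.set_size not in SET_SIZES:
            raise ValueError(f"set_size must be one of {SET_SIZES}")
        if self.delay_s not in DELAYS_S:
            raise ValueError(f"delay_s must be one of {DELAYS_S}")
        if len(self.targets) != self.set_size:
            raise ValueError("len(targets) must equal set_size")
        if self.probe.color != "green":
            raise ValueError("probe must be green")
        centers = [t.center for t in self.targets]
        if self.truth == Truth.TRUE_POSITIVE:
            if self.probe.center not in centers:
                raise ValueError("true-positive probe must reuse a target center")


@dataclass(frozen=True)
class Paradigm:
    trials: tuple[TrialSpec, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.trials) != N_TRIALS:
            raise ValueError(f"paradigm must contain {N_TRIALS} trials")


@dataclass(frozen=True)
class RenderedImage:
    """A rasterized stimulus: 30x30x3 float array in [0,1] plus provenance."""

    pixels: np.ndarray
    source: tuple[CircleSpec, ...]
    has_fixation: bool

    def __post_init__(self) -> None:
        if self.pixels.shape != (CANVAS, CANVAS, 3):
            raise ValueError("pixels must have shape (30, 30, 3)")

    def flat(self) -> np.ndarray:
        """Flattened 2700-dim pixel vector (row-major, channel-last)."""
        return self.pixels.reshape(-1)


@dataclass
class PlacementConfig:
    """Constraints for rejection-sampled circle placement."""

    radius: float = DEFAULT_RADIUS
    fixation: tuple[float, float] = FIXATION_CENTER
    #: minimum center distance from fixation so circles never overlap the cross
    fixation_clearance: float | None = None
    #: minimum probe-to-target center distance for true-negative probes
    d_min: float | None = None
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.fixation_clearance is None:
            self.fixation_clearance = self.radius + FIXATION_HALF + 1
        if self.d_min is None:
            self.d_min = 2 * self.radius + 1


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the placement constraints."""


def _sample_center(rng: np.random.Generator, radius: float) -> tuple[float, float]:
    lo, hi = radius, CANVAS - 1 - radius
    return (rng.uniform(lo, hi), rng.uniform(lo, hi))


def place_circles(
    set_size: int,
    rng: np.random.Generator,
    constraints: PlacementConfig | None = None,
) -> list[CircleSpec]:
    """Pseudo-randomly place ``set_size`` yellow target circles.

    Circles are mutually non-overlapping (center distance > 2*radius), stay
    clear of the fixation cross, and lie fully inside the canvas.  Placement
    uses rejection sampling capped at ``constraints.max_attempts``.
    """
    if set_size not in SET_SIZES:
        raise ValueError(f"set_size must be one of {SET_SIZES}")
    cfg = constraints or PlacementConfig()
    placed: list[CircleSpec] = []
    attempts = 0
    fx, fy = cfg.fixation
    while len(placed) < set_size:
        if attempts >= cfg.max_attempts:
            raise PlacementError(
                f"could not place {set_size} circles of radius {cfg.radius} "
                f"after {cfg.max_attempts} attempts"
            )
        attempts += 1
        x, y = _sample_center(rng, cfg.radius)
        if np.hypot(x - fx, y - fy) <= cfg.fixation_clearance:
            continue
        if any(np.hypot(x - c.x, y - c.y) <= 2 * cfg.radius for c in placed):
            continue
        placed.append(CircleSpec(x=x, y=y, radius=cfg.radius, color="yellow"))
    return placed


def make_probe(
    trial_targets: Sequence[CircleSpec],
    truth: Truth | str,
    rng: np.random.Generator,
    constraints: PlacementConfig | None = None,
) -> CircleSpec:
    """Sample the green probe circle for a trial.

    True-positive probes reuse one target center exactly; true-negative
    probes are at least ``d_min`` from every target center.
    """
    if not trial_targets:
        raise ValueError("trial_targets must be non-empty")
    truth = Truth(truth)
    cfg = constraints or PlacementConfig(radius=trial_targets[0].radius)
    if truth == Truth.TRUE_POSITIVE:
        t = trial_targets[rng.integers(len(trial_targets))]
        return CircleSpec(x=t.x, y=t.y, radius=cfg.radius, color="green")
    fx, fy = cfg.fixation
    for _ in range(cfg.max_attempts):
        x, y = _sample_center(rng, cfg.radius)
        if np.hypot(x - fx, y - fy) <= cfg.fixation_clearance:
            continue
        if all(np.hypot(x - t.x, y - t.y) >= cfg.d_min for t in trial_targets):
            return CircleSpec(x=x, y=y, radius=cfg.radius, color="green")
    raise PlacementError("could not sample a valid true-negative probe location")


def build_paradigm(
    seed: int, constraints: PlacementConfig | None = None
) -> Paradigm:
    """Build the 48-trial SWM design.

    12 trials per set size, 4 per (set size x delay) cell, each cell split
    2/2 between true-positive and true-negative so the design has 24 of
    each.  Trial order is a seeded shuffle.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    for set_size in SET_SIZES:
        for delay in DELAYS_S:
            for truth in (
                Truth.TRUE_POSITIVE,
                Truth.TRUE_POSITIVE,
                Truth.TRUE_NEGATIVE,
                Truth.TRUE_NEGATIVE,
            ):
                targets = place_circles(set_size, rng, constraints)
                probe = make_probe(targets, truth, rng, constraints)
                trials.append(
                    TrialSpec(
                        set_size=set_size,
                        delay_s=delay,
                        truth=truth,
                        targets=tuple(targets),
                        probe=probe,
                    )
                )
    order = rng.permutation(len(trials))
    return Paradigm(trials=tuple(trials[i] for i in order), seed=seed)


def _pixel_grid() -> tuple[np.ndarray, np.ndarray]:
    # pixel-center coordinates in (x, y-from-bottom) convention
    cols = np.arange(CANVAS, dtype=float)
    rows = np.arange(CANVAS, dtype=float)
    px = np.broadcast_to(cols[None, :], (CANVAS, CANVAS))
    py = np.broadcast_to((CANVAS - 1 - rows)[:, None], (CANVAS, CANVAS))
    return px, py


def render(
    circles: Sequence[CircleSpec], with_fixation: bool = False
) -> RenderedImage:
    """Rasterize circles (and optionally the fixation cross) to 30x30x3.

    Pure function of its inputs: a pixel is painted with a circle's color if
    its center lies within the circle's radius; later circles overwrite
    earlier ones.  Background is black, yellow = (1,1,0), green = (0,1,0),
    fixation cross = white.
    """
    img = np.zeros((CANVAS, CANVAS, 3), dtype=np.float64)
    px, py = _pixel_grid()
    if with_fixation:
        fx, fy = FIXATION_CENTER
        frow = int(round(CANVAS - 1 - fy))
        fcol = int(round(fx))
        img[frow, fcol - FIXATION_HALF : fcol + FIXATION_HALF + 1, :] = 1.0
        img[frow - FIXATION_HALF : frow + FIXATION_HALF + 1, fcol, :] = 1.0
    for c in circles:
        mask = (px - c.x) ** 2 + (py - c.y) ** 2 <= c.radius**2
        img[mask] = COLORS[c.color]
    return RenderedImage(
        pixels=img, source=tuple(circles), has_fixation=with_fixation
    )


def render_trial(
    trial: TrialSpec, with_fixation: bool = True
) -> tuple[RenderedImage, RenderedImage]:
    """Render the (target-array, probe) image pair of one trial."""
    stim = render(trial.targets, with_fixation=with_fixation)
    probe = render([trial.probe], with_fixation=with_fixation)
    return stim, probe


def paradigm_images(
    paradigm: Paradigm, with_fixation: bool = True
) -> tuple[list[RenderedImage], list[RenderedImage]]:
    """Stimulus (yellow) and probe (green) images for all 48 trials, in order."""
    stims, probes = [], []
    for t in paradigm.trials:
        s, p = render_trial(t, with_fixation=with_fixation)
        stims.append(s)
        probes.append(p)
    return stims, probes


def build_training_set(
    n_per_class: int = 100,
    seed: int = 0,
    constraints: PlacementConfig | None = None,
) -> list[RenderedImage]:
    """Generate the model training set: yellow circles on black.

    ``n_per_class`` images for each set size in {1, 3, 5, 7} (400 total at
    the default), rendered without a fixation cross.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images: list[RenderedImage] = []
    for set_size in SET_SIZES:
        for _ in range(n_per_class):
            circles = place_circles(set_size, rng, constraints)
            images.append(render(circles, with_fixation=False))
    return images


def images_to_array(images: Sequence[RenderedImage]) -> np.ndarray:
    """Stack images into an (N, 3, 30, 30) float32 channels-first array."""
    arr = np.stack([im.pixels for im in images]).astype(np.float32)
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def paradigm_manifest(paradigm: Paradigm) -> pd.DataFrame:
    """Tabular view of the design: one row per trial, circles as JSON."""
    rows = []
    for i, t in enumerate(paradigm.trials):
        rows.append(
            {
                "trial_id": i,
                "set_size": t.set_size,
                "delay_s": t.delay_s,
                "truth": t.truth.value,
                "targets_json": json.dumps(
                    [[c.x, c.y, c.radius] for c in t.targets]
                ),
                "probe_json": json.dumps([t.probe.x, t.probe.y, t.probe.radius]),
            }
        )
    return pd.DataFrame(rows)


def write_stimuli(
    paradigm: Paradigm, out_dir: str | Path, n_train_per_class: int = 100
) -> None:
    """Write PNG stimuli, the paradigm manifest TSV and the training set."""
    from PIL import Image

    out = Path(out_dir)
    (out / "trials").mkdir(parents=True, exist_ok=True)
    (out / "train").mkdir(parents=True, exist_ok=True)

    def _save(im: RenderedImage, path: Path) -> None:
        arr = (im.pixels * 255).round().astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(path)

    stims, probes = paradigm_images(paradigm)
    for i, (s, p) in enumerate(zip(stims, probes)):
        _save(s, out / "trials" / f"trial{i:02d}_stim.png")
        _save(p, out / "trials" / f"trial{i:02d}_probe.png")
    paradigm_manifest(paradigm).to_csv(
        out / "paradigm.tsv", sep="\t", index=False
    )
    for j, im in enumerate(
        build_training_set(n_train_per_class, seed=paradigm.seed + 1)
    ):
        _save(im, out / "train" / f"train{j:04d}.png")
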