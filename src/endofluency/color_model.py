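"""Dominant-color classification in the SRB-G space.

Under operative illumination the scene decomposes into three color
populations: nasal/sellar mucosa and anatomy are red-pinkish (R), the
surgical drape — visible when the endoscope is out of the nostril — is
blue-greenish (B-G), and instruments and gauze are silverish-whitish (S).
Every pixel is assigned exactly one of the three labels (its *dominant
color*), and each frame is reduced to the percentage of pixels per label.

Two classifiers are provided:

* a calibrated nearest-centroid classifier whose three centroids come from
  k-means (k=3) on a seeded subsample of pixels, and
* a calibration-free rule classifier on saturation and hue, used as a
  fallback (and as an independent cross-check in tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv
from sklearn.cluster import KMeans

from .errors import CalibrationError, ConfigurationError, ValidationError
from .types import FrameColorProfile, FrameRecord

#: Label code order. Classification ties are broken by this priority
#: (S > R > BG), which argmin over distances in this order gives for free.
LABELS = ("S", "R", "BG")
S, R, BG = 0, 1, 2

#: Default hue windows (degrees) for the rule classifier. The red window
#: wraps through 0°; the blue-green window covers green through blue.
DEFAULT_RED_HUE_WINDOW = (295.0, 65.0)
DEFAULT_BG_HUE_WINDOW = (75.0, 270.0)
DEFAULT_SATURATION_CUTOFF = 60.0  # max(channel) - min(channel), 8-bit units


@dataclass(frozen=True)
class ColorReference:
    """Calibrated SRB-G centroids.

    ``centroids`` is a (3, 3) float array in RGB, ordered (S, R, BG) to
    match :data:`LABELS`; ``seed`` records the calibration seed.
    """

    centroids: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float)
        if c.shape != (3, 3):
            raise ValidationError(f"centroids must be (3, 3), got {c.shape}")
        for i in range(3):
            for j in range(i + 1, 3):
                if np.allclose(c[i], c[j]):
                    raise ValidationError("centroids must be pairwise distinct")
        object.__setattr__(self, "centroids", c)

    def centroid(self, label: str) -> np.ndarray:
        return self.centroids[LABELS.index(label)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "centroids": self.centroids.tolist(),
                    "labels": {name: i for i, name in enumerate(LABELS)},
                    "seed": self.seed,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ColorReference":
        data = json.loads(Path(path).read_text())
        centroids = np.asarray(data["centroids"], dtype=float)
        labels = data.get("labels")
        if labels:  # reorder to canonical (S, R, BG)
            order = [labels[name] for name in LABELS]
            centroids = centroids[order]
        return cls(centroids=centroids, seed=int(data.get("seed", 0)))


def _label_centroids(raw: np.ndarray) -> np.ndarray:
    """Order raw k-means centroids as (S, R, BG).

    S is the centroid with the lowest saturation (max channel - min
    channel); of the remaining two, the one whose red channel most exceeds
    both green and blue is R, the other is BG.
    """
    saturation = raw.max(axis=1) - raw.min(axis=1)
    s_idx = int(np.argmin(saturation))
    rest = [i for i in range(3) if i != s_idx]
    red_dominance = [raw[i, 0] - max(raw[i, 1], raw[i, 2]) for i in rest]
    r_idx = rest[int(np.argmax(red_dominance))]
    bg_idx = next(i for i in rest if i != r_idx)
    return raw[[s_idx, r_idx, bg_idx]]


def calibrate_color_references(
    frames: Sequence[FrameRecord],
    sample_pixels: int = 5000,
    seed: int = 0,
) -> ColorReference:
    """Calibrate SRB-G centroids by k-means on a seeded pixel subsample.

    From each frame, ``sample_pixels`` pixels are drawn uniformly at random
    (with a generator seeded by ``seed``), pooled, and clustered with
    k-means, k=3 (seeded k-means++ initialization, 300-iteration cap,
    tolerance 1e-4). Cluster identities are mapped to labels by the
    saturation / red-dominance rule of :func:`_label_centroids`.

    Deterministic: identical frames, sample size, and seed yield an
    identical reference.

    Raises
    ------
    CalibrationError
        If the pooled sample holds fewer than three distinct colors; the
        rule classifier (:func:`classify_dominant_colors_rule`) is the
        calibration-free fallback in that case.
    """
    if not frames:
        raise CalibrationError("no frames supplied for calibration")
    rng = np.random.default_rng(seed)
    pools = []
    for rec in frames:
        flat = rec.pixels.reshape(-1, 3)
        k = min(sample_pixels, flat.shape[0])
        idx = rng.choice(flat.shape[0], size=k, replace=False)
        pools.append(flat[idx])
    sample = np.concatenate(pools).astype(float)
    if np.unique(sample, axis=0).shape[0] < 3:
        raise CalibrationError(
            "pixel sample has fewer than 3 distinct colors; "
            "use classify_dominant_colors_rule instead"
        )
    km = KMeans(
        n_clusters=3,
        init="k-means++",
        n_init=10,
        max_iter=300,
        tol=1e-4,
        random_state=seed,
    ).fit(sample)
    return ColorReference(centroids=_label_centroids(km.cluster_centers_), seed=seed)


def classify_dominant_colors(frame: FrameRecord, reference: ColorReference) -> np.ndarray:
    """Label each pixel with its nearest centroid (squared Euclidean in RGB).

    Returns an (H, W) uint8 grid of label codes (0=S, 1=R, 2=BG). Distance
    ties go to the higher-priority label, S > R > BG.
    """
    flat = frame.pixels.reshape(-1, 3).astype(np.float32)
    c = reference.centroids.astype(np.float32)
    # ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2; the ||x||^2 term is constant
    # per pixel, so argmin over (-2 x.c + ||c||^2) ranks identically.
    scores = flat @ (-2.0 * c.T)
    scores += (c * c).sum(axis=1)
    labels = np.argmin(scores, axis=1).astype(np.uint8)  # first min → priority order
    return labels.reshape(frame.shape)


def classify_dominant_colors_rule(
    frame: FrameRecord,
    saturation_cutoff: float = DEFAULT_SATURATION_CUTOFF,
    red_hue_window: tuple[float, float] = DEFAULT_RED_HUE_WINDOW,
    bg_hue_window: tuple[float, float] = DEFAULT_BG_HUE_WINDOW,
) -> np.ndarray:
    """Calibration-free classifier on saturation and hue.

    Pixels with chroma (max channel - min channel) below
    ``saturation_cutoff`` are S; the rest are R or B-G by hue-window
    membership (degrees, windows may wrap through 0°). Pixels in neither
    window take the label of the nearest window boundary on the hue circle.
    """
    if _windows_overlap(red_hue_window, bg_hue_window):
        raise ConfigurationError(
            f"hue windows overlap: R {red_hue_window}, B-G {bg_hue_window}"
        )
    pixels = frame.pixels
    chroma = pixels.max(axis=2).astype(np.int16) - pixels.min(axis=2).astype(np.int16)
    hue = rgb2hsv(pixels)[..., 0] * 360.0
    in_r = _in_window(hue, red_hue_window)
    in_bg = _in_window(hue, bg_hue_window)
    neither = ~(in_r | in_bg)
    labels = np.full(pixels.shape[:2], BG, dtype=np.uint8)
    labels[in_r] = R
    if np.any(neither):
        d_r = _window_distance(hue[neither], red_hue_window)
        d_bg = _window_distance(hue[neither], bg_hue_window)
        labels[neither] = np.where(d_r <= d_bg, R, BG)
    labels[chroma < saturation_cutoff] = S
    return labels


def _in_window(hue: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo <= hi:
        return (hue >= lo) & (hue <= hi)
    return (hue >= lo) | (hue <= hi)  # wraps through 0°


def _window_distance(hue: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    def circ(a: np.ndarray, b: float) -> np.ndarray:
        d = np.abs(a - b) % 360.0
        return np.minimum(d, 360.0 - d)

    return np.minimum(circ(hue, window[0]), circ(hue, window[1]))


def _windows_overlap(w1: tuple[float, float], w2: tuple[float, float]) -> bool:
    def expand(w):
        lo, hi = w
        return [(lo, hi)] if lo <= hi else [(lo, 360.0), (0.0, hi)]

    for a_lo, a_hi in expand(w1):
        for b_lo, b_hi in expand(w2):
            if max(a_lo, b_lo) <= min(a_hi, b_hi):
                return True
    return False


def profile_frame(labels: np.ndarray, frame_index: int, time_s: float) -> FrameColorProfile:
    """Reduce a label grid to S/R/B-G percentages of the frame."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("empty label grid")
    counts = np.bincount(labels.ravel(), minlength=3)
    total = labels.size
    return FrameColorProfile(
        frame_index=frame_index,
        time_s=time_s,
        s_pct=100.0 * counts[S] / total,
        r_pct=100.0 * counts[R] / total,
        bg_pct=100.0 * counts[BG] / total,
    )
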