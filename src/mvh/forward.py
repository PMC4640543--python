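"""Sensory forward models: orthographic renderer and grasp surrogate.

Both models consume an :class:`~mvh.grammar.ObjectRepresentation`, place
the part templates at their absolute positions, and produce deterministic
feature vectors with the model's dimensionality contracts:

* visual: three orthographic binary silhouettes (+x, +y, +z views) of
  ``r x r`` pixels each, concatenated row-major; ``3 r^2`` features
  (120,000 at the default r = 200);
* haptic: a simulated "enclosing grasp" repeated from 24 orientations
  (8 rotations of 45 deg about each of the three axes).  Each grasp casts
  a 4x4 grid of 16 parallel rays from a palm plane toward the object and
  converts the first-contact distance into a pseudo joint angle in
  ``[0, pi/2]`` (farther contact = more finger closure; no contact = full
  closure).  16 x 24 = 384 features.

A multisensory vector concatenates the per-modality vectors after
scaling each by ``1 / sqrt(dim)`` so neither modality swamps the shared
Gaussian likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grammar import ObjectRepresentation, absolute_part_positions
from .stimuli import PART_TEMPLATES

VISUAL = "visual"
HAPTIC = "haptic"
MULTISENSORY = "multisensory"

#: Half-extent of the rendered/grasped workspace window.  Parts can reach
#: |coordinate| ~ 0.61 at workspace edge 1, so the window leaves a margin.
WINDOW_HALF = 0.75


@dataclass(frozen=True)
class RenderConfig:
    """Orthographic renderer settings.

    ``shading`` selects ``"depth"`` (default): 8-bit grayscale where a
    pixel encodes the depth of the nearest surface toward the camera
    (brighter = closer, 0 = background), like a flat-lit rendering; or
    ``"silhouette"``: binary occupancy masks.  Depth shading makes the
    Gaussian likelihood sensitive to *which* surface covers a pixel, not
    just whether one does, which is what lets inference separate
    overlapping part hypotheses.
    """

    resolution: int = 200
    #: projection axes, in output order
    view_axes: tuple[int, int, int] = (0, 1, 2)
    #: camera side per view; the -y camera looks at the underside, where
    #: the lowest part slot sits, so every slot faces at least one camera
    view_signs: tuple[int, int, int] = (1, -1, 1)
    shading: str = "depth"

    def __post_init__(self) -> None:
        if self.resolution < 8:
            raise ValueError("resolution must be at least 8")
        if self.shading not in ("depth", "silhouette"):
            raise ValueError("shading must be 'depth' or 'silhouette'")

    @property
    def dim(self) -> int:
        return 3 * self.resolution**2

    @property
    def pixel_levels(self) -> int:
        """Maximum pixel value of the integer image (gray levels - 1)."""
        return 255 if self.shading == "depth" else 1


def _rotation(axis: int, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    if axis == 0:
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == 1:
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass(frozen=True)
class GraspConfig:
    """Grasp surrogate settings: 24 orientations x 16 rays.

    Each orientation's 4x4 finger lattice is shifted by a deterministic
    low-discrepancy offset (golden-ratio sequence, at most half the
    lattice spacing).  Without the shifts every grasp probes the same
    palm-plane lattice and laterally displaced shapes can produce
    identical contact sets; the offsets emulate fingers meeting different
    surface points from every approach direction and make the feature
    map sensitive to sub-lattice displacements.
    """

    n_steps: int = 8  # rotations per axis, 45 deg apart
    #: palm-plane ray offsets; spacing 0.28 < w/3, so any feature spanning a
    #: full part cube in both transverse directions meets at least one ray
    grid: tuple[float, ...] = (-0.42, -0.14, 0.14, 0.42)
    #: per-orientation lattice shift amplitude (fraction of the spacing)
    jitter: float = 1.0
    palm_height: float = 1.0
    max_depth: float = 2.0

    @property
    def n_orientations(self) -> int:
        return 3 * self.n_steps

    @property
    def n_rays(self) -> int:
        return len(self.grid) ** 2

    @property
    def dim(self) -> int:
        return self.n_orientations * self.n_rays

    def ray_bundle(self) -> tuple[np.ndarray, np.ndarray]:
        """All rays of all orientations, pre-rotated into the object frame.

        The palm plane sits at ``z = palm_height`` with rays pointing down
        ``-z``; rotating the *object* by R is implemented by rotating the
        rays by R^T.  Returns (origins, directions), each of shape
        (n_orientations * n_rays, 3), in fixed orientation-major, ray
        row-major order.
        """
        base_origins = np.array(
            [(gx, gy, self.palm_height) for gx in self.grid for gy in self.grid]
        )
        spacing = self.grid[1] - self.grid[0] if len(self.grid) > 1 else 0.0
        base_dir = np.array([0.0, 0.0, -1.0])
        phi = (math.sqrt(5) - 1) / 2  # golden-ratio sequence
        origins, dirs = [], []
        index = 0
        for axis in range(3):
            for k in range(self.n_steps):
                rot = _rotation(axis, k * (2 * math.pi / self.n_steps))
                shift = np.array(
                    [
                        ((index * phi) % 1.0 - 0.5) * spacing * self.jitter,
                        ((index * phi * phi) % 1.0 - 0.5) * spacing * self.jitter,
                        0.0,
                    ]
                )
                origins.append((base_origins + shift) @ rot)  # rot.T applied
                dirs.append(
                    np.repeat((rot.T @ base_dir)[None, :], len(base_origins), 0)
                )
                index += 1
        return np.concatenate(origins), np.concatenate(dirs)


@dataclass
class SensoryData:
    """A feature vector tagged with its modality and provenance."""

    modality: str
    vector: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.vector.size


# ---------------------------------------------------------------------------
# geometry assembly


def object_boxes(
    rep: ObjectRepresentation, templates: dict[str, np.ndarray] | None = None
) -> np.ndarray:
    """World-frame axis-aligned boxes (n, 2, 3) for all placed parts."""
    templates = templates if templates is not None else PART_TEMPLATES
    boxes = []
    for part, pos in absolute_part_positions(rep):
        if part not in templates:
            raise KeyError(f"no template for part {part!r}")
        boxes.append(templates[part] + pos[None, None, :])
    if not boxes:
        return np.zeros((0, 2, 3))
    return np.concatenate(boxes)


# ---------------------------------------------------------------------------
# visual forward model


def render_images(
    rep: ObjectRepresentation,
    cfg: RenderConfig | None = None,
    templates: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Grayscale images, shape (3, r, r) uint8.

    View v is an orthographic projection along axis ``view_axes[v]`` with
    the camera on the positive side; image rows map to the first remaining
    axis and columns to the second (e.g. the +x view has rows = y,
    cols = z).  In depth mode a covered pixel holds the quantized depth of
    the closest surface, ``round(255 * (near + W) / 2W)`` with ``W`` the
    window half-extent; in silhouette mode it holds 1.  Background is 0.
    """
    cfg = cfg or RenderConfig()
    r = cfg.resolution
    boxes = object_boxes(rep, templates)
    images = np.zeros((3, r, r), dtype=np.uint8)
    scale = r / (2 * WINDOW_HALF)
    depth_mode = cfg.shading == "depth"
    for v, axis in enumerate(cfg.view_axes):
        sign = cfg.view_signs[v]
        keep = [a for a in range(3) if a != axis]
        img = images[v]
        for lo, hi in boxes:
            r0 = int(math.floor((lo[keep[0]] + WINDOW_HALF) * scale))
            r1 = int(math.ceil((hi[keep[0]] + WINDOW_HALF) * scale))
            c0 = int(math.floor((lo[keep[1]] + WINDOW_HALF) * scale))
            c1 = int(math.ceil((hi[keep[1]] + WINDOW_HALF) * scale))
            r0, r1 = max(r0, 0), min(max(r1, 0), r)
            c0, c1 = max(c0, 0), min(max(c1, 0), r)
            if depth_mode:
                near = hi[axis] if sign > 0 else -lo[axis]
                shade = int(round(255 * (near + WINDOW_HALF) / (2 * WINDOW_HALF)))
                region = img[r0:r1, c0:c1]
                np.maximum(region, min(max(shade, 1), 255), out=region)
            else:
                img[r0:r1, c0:c1] = 1
    return images


def render_views(
    rep: ObjectRepresentation,
    cfg: RenderConfig | None = None,
    templates: dict[str, np.ndarray] | None = None,
) -> SensoryData:
    """Visual feature vector: the three images flattened row-major, with
    pixel values normalized to [0, 1]."""
    cfg = cfg or RenderConfig()
    images = render_images(rep, cfg, templates)
    return SensoryData(
        VISUAL,
        images.reshape(-1).astype(np.float64) / cfg.pixel_levels,
        {"resolution": cfg.resolution, "shading": cfg.shading},
    )


# ---------------------------------------------------------------------------
# haptic forward model


def _ray_box_hits(
    origins: np.ndarray, dirs: np.ndarray, boxes: np.ndarray
) -> np.ndarray:
    """First-contact distance per ray against a box set; inf if no hit.

    Slab method, vectorized over (rays, boxes).  Rays are assumed to start
    outside every box (the palm plane clears the workspace).
    """
    if boxes.shape[0] == 0:
        return np.full(origins.shape[0], np.inf)
    lo = boxes[None, :, 0, :]  # (1, nb, 3)
    hi = boxes[None, :, 1, :]
    o = origins[:, None, :]  # (nr, 1, 3)
    d = dirs[:, None, :]
    parallel = np.abs(d) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - o) / d
        t2 = (hi - o) / d
    near = np.minimum(t1, t2)
    far = np.maximum(t1, t2)
    inside = (o > lo) & (o < hi)
    near = np.where(parallel, np.where(inside, -np.inf, np.inf), near)
    far = np.where(parallel, np.where(inside, np.inf, -np.inf), far)
    tmin = near.max(axis=2)
    tmax = far.min(axis=2)
    hit = (tmax >= tmin) & (tmax >= 0)
    t = np.where(hit, np.maximum(tmin, 0.0), np.inf)
    return t.min(axis=1)


def haptic_features(
    rep: ObjectRepresentation,
    cfg: GraspConfig | None = None,
    templates: dict[str, np.ndarray] | None = None,
) -> SensoryData:
    """Haptic feature vector: 16 pseudo joint angles per grasp x 24 grasps.

    Feature = ``(pi/2) * min(contact_distance, max_depth) / max_depth``:
    a finger that travels farther before touching the object closes more;
    a ray that never touches closes fully to pi/2.
    """
    cfg = cfg or GraspConfig()
    boxes = object_boxes(rep, templates)
    origins, dirs = _ray_cache(cfg)
    t = _ray_box_hits(origins, dirs, boxes)
    angles = (math.pi / 2) * np.minimum(t, cfg.max_depth) / cfg.max_depth
    return SensoryData(
        HAPTIC,
        angles.astype(np.float64),
        {"n_orientations": cfg.n_orientations, "n_rays": cfg.n_rays},
    )


_RAY_CACHE: dict[GraspConfig, tuple[np.ndarray, np.ndarray]] = {}


def _ray_cache(cfg: GraspConfig) -> tuple[np.ndarray, np.ndarray]:
    if cfg not in _RAY_CACHE:
        _RAY_CACHE[cfg] = cfg.ray_bundle()
    return _RAY_CACHE[cfg]


# ---------------------------------------------------------------------------
# combined forward map


def forward(
    rep: ObjectRepresentation,
    modalities: tuple[str, ...] = (VISUAL, HAPTIC),
    render_cfg: RenderConfig | None = None,
    grasp_cfg: GraspConfig | None = None,
    templates: dict[str, np.ndarray] | None = None,
) -> SensoryData:
    """Predicted sensory features F(T, S) for a set of modalities.

    Each modality block is scaled by ``1/sqrt(dim)`` and blocks are
    concatenated visual-first, so Euclidean distances weight modalities
    comparably under a single likelihood variance.
    """
    if not modalities:
        raise ValueError("at least one modality is required")
    unknown = set(modalities) - {VISUAL, HAPTIC}
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    blocks = []
    if VISUAL in modalities:
        vec = render_views(rep, render_cfg, templates).vector
        blocks.append(vec / math.sqrt(vec.size))
    if HAPTIC in modalities:
        vec = haptic_features(rep, grasp_cfg, templates).vector
        blocks.append(vec / math.sqrt(vec.size))
    tag = MULTISENSORY if len(blocks) > 1 else modalities[0]
    return SensoryData(tag, np.concatenate(blocks), {"modalities": tuple(modalities)})


def save_images_png(images: np.ndarray, paths) -> None:
    """Write (3, r, r) images as 8-bit grayscale PNGs."""
    from PIL import Image

    for img, path in zip(images, paths):
        arr = img.astype(np.uint8)
        if arr.max() <= 1:
            arr = arr * 255
        Image.fromarray(arr, mode="L").save(path)
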