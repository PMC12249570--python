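"""Synthetic vascular image generation.

Two kinds of input are produced for the analysis pipeline:

* stochastic vascular networks grown by a discrete-time branching random
  walk (``grow_network``), with a ground-truth record of every bifurcation
  and terminal event so extraction accuracy can be measured;
* deterministic geometric fixtures (``make_fixture``) whose morphometric
  and topological properties are known in closed form.

The growth model is a persistent random walk: each active tip advances a
fixed step length per iteration, its heading perturbed by Gaussian jitter;
with a fixed per-step probability the tip bifurcates into two daughters
whose headings straddle the parent heading by a half-angle.  Tips die on
boundary contact or when the iteration cap is reached.  Vessels are
rendered as the union of discs of a fixed radius stamped along every tip
trajectory; overlapping discs may fuse nearby vessels, which mirrors the
loops seen in real vascular images.  Anastomosis is not modelled as a rule
and growth is strictly 2-D.

Treatment presets (``preset``) map the pro-/anti-angiogenic conditions of
a transparent-organism vessel assay onto frozen parameter sets, calibrated
so that cohort means of vessel coverage and junction count rank in the
order pro-angiogenic > partial inhibitors > baseline/full inhibitor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from skimage.draw import line as _draw_line
from skimage.morphology import dilation, disk

__all__ = [
    "GrowthParams",
    "VascularImage",
    "GroundTruth",
    "grow_network",
    "preset",
    "PRESET_LABELS",
    "make_fixture",
    "FIXTURE_NAMES",
    "write_image",
    "read_image",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VascularImage:
    """A 2-D binary vessel mask with an isotropic pixel scale.

    ``mask`` is boolean, row-major, origin top-left, 0-based.  ``scale`` is
    the physical length of one pixel side in arbitrary units (default 1;
    the source assay states no magnification-to-pixel calibration).
    """

    mask: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 2 or mask.shape[0] < 8 or mask.shape[1] < 8:
            raise ValueError("mask must be 2-D and at least 8x8")
        if mask.dtype != bool:
            raise TypeError("mask must be strictly boolean")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def vessel_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class GrowthParams:
    """Parameter set for one stochastic branching simulation.

    Attributes
    ----------
    n_seeds : int
        Number of initial tips, placed uniformly at random in the canvas
        interior with uniform random headings.
    branch_prob : float
        Per-step probability that a tip bifurcates (in [0, 1]).
    step_len : float
        Tip advance per iteration, in pixels (>= 1).
    angle_sigma : float
        Standard deviation of the per-step Gaussian heading jitter (rad).
    branch_angle : float
        Half-angle between the two daughter headings at a bifurcation (rad).
    max_steps : int
        Iteration cap; surviving tips are terminated there.
    contact_inhibition : bool
        When set, a tip also dies on approaching vessel territory laid
        down more than three iterations earlier (anastomotic stopping),
        which suppresses vessel crossings; off by default, where loops
        can arise freely.
    contact_radius : float
        Proximity distance (pixels) triggering contact inhibition.
    radius : int
        Vessel half-thickness in pixels (>= 1); trajectories are dilated by
        a disc of this radius.
    width, height : int
        Canvas size in pixels.
    rng_seed : int
        Seed of the simulation's random generator.
    label : str
        Free-form preset / treatment name recorded in output metadata.
    """

    n_seeds: int = 3
    branch_prob: float = 0.05
    step_len: float = 4.0
    angle_sigma: float = 0.25
    branch_angle: float = 0.55
    max_steps: int = 60
    radius: int = 2
    width: int = 384
    height: int = 384
    rng_seed: int = 0
    label: str = "custom"
    contact_inhibition: bool = False
    contact_radius: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        if self.step_len < 1:
            raise ValueError("step_len must be >= 1")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass
class GroundTruth:
    """Event record of one simulation.

    ``points`` holds (row, col) integer coordinates; ``kinds[i]`` is
    ``"branch"`` or ``"terminal"``.  ``segments`` are ``(i, j, length)``
    triples referencing ``points`` by index, with ``length`` the polyline
    length of the tip trajectory between the two events.  Seed origins are
    recorded as terminal points, so an unbranched single-seed run has
    exactly two terminal points: origin and death site.
    """

    points: list[tuple[int, int]] = field(default_factory=list)
    kinds: list[str] = field(default_factory=list)
    segments: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def branch_points(self) -> list[tuple[int, int]]:
        return [p for p, k in zip(self.points, self.kinds) if k == "branch"]

    @property
    def terminal_points(self) -> list[tuple[int, int]]:
        return [p for p, k in zip(self.points, self.kinds) if k == "terminal"]

    def validate(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for r, c in self.points:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"ground-truth point ({r}, {c}) outside canvas")
        n = len(self.points)
        for i, j, _length in self.segments:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("segment references missing point")

    def to_json(self) -> str:
        return json.dumps(
            {
                "points": [list(p) for p in self.points],
                "kinds": self.kinds,
                "segments": [[i, j, length] for i, j, length in self.segments],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            points=[tuple(p) for p in obj["points"]],
            kinds=list(obj["kinds"]),
            segments=[(int(i), int(j), float(d)) for i, j, d in obj["segments"]],
        )


# ---------------------------------------------------------------------------
# Stochastic growth
# ---------------------------------------------------------------------------

@dataclass
class _Tip:
    r: float
    c: float
    heading: float
    origin_idx: int          # ground-truth point where this segment started
    seg_len: float = 0.0


def grow_network(params: GrowthParams) -> tuple[VascularImage, GroundTruth]:
    """Run one branching-growth simulation.

    Returns the rasterised binary vessel image and the ground-truth event
    record.  The map ``(params, rng_seed) -> mask`` is a pure function:
    identical inputs yield bit-identical masks.
    """
    h, w = params.height, params.width
    margin = params.radius + 1
    lo_r, hi_r = margin, h - 1 - margin
    lo_c, hi_c = margin, w - 1 - margin
    if hi_r - lo_r < params.step_len or hi_c - lo_c < params.step_len:
        raise ValueError(
            f"canvas {w}x{h} too small for radius {params.radius} and "
            f"step length {params.step_len}"
        )

    rng = np.random.default_rng(params.rng_seed)
    path = np.zeros((h, w), dtype=bool)
    age = np.full((h, w), -1, dtype=np.int32)   # iteration a pixel was laid down
    gt = GroundTruth()

    cr = int(math.ceil(params.contact_radius))
    dr_off, dc_off = np.nonzero(
        (np.arange(-cr, cr + 1)[:, None] ** 2 + np.arange(-cr, cr + 1) ** 2)
        <= params.contact_radius**2
    )
    dr_off, dc_off = dr_off - cr, dc_off - cr

    def add_point(r: float, c: float, kind: str) -> int:
        ri = int(round(min(max(r, 0), h - 1)))
        ci = int(round(min(max(c, 0), w - 1)))
        gt.points.append((ri, ci))
        gt.kinds.append(kind)
        path[ri, ci] = True
        return len(gt.points) - 1

    def stamp(r0: float, c0: float, r1: float, c1: float, step: int) -> None:
        rr, cc = _draw_line(
            int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1))
        )
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc = rr[keep], cc[keep]
        path[rr, cc] = True
        fresh = age[rr, cc] < 0
        age[rr[fresh], cc[fresh]] = step

    def near_old_vessel(r: float, c: float, step: int) -> bool:
        rr = np.clip(int(round(r)) + dr_off, 0, h - 1)
        cc = np.clip(int(round(c)) + dc_off, 0, w - 1)
        ages = age[rr, cc]
        return bool(np.any((ages >= 0) & (ages <= step - 4)))

    tips: list[_Tip] = []
    for _ in range(params.n_seeds):
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        heading = rng.uniform(0.0, 2.0 * math.pi)
        idx = add_point(r, c, "terminal")   # origin counts as a terminal
        tips.append(_Tip(r, c, heading, idx))

    for step in range(params.max_steps):
        if not tips:
            break
        survivors: list[_Tip] = []
        for tip in tips:
            tip.heading += rng.normal(0.0, params.angle_sigma)
            nr = tip.r + params.step_len * math.sin(tip.heading)
            nc = tip.c + params.step_len * math.cos(tip.heading)
            if params.contact_inhibition and near_old_vessel(nr, nc, step):
                idx = add_point(tip.r, tip.c, "terminal")
                gt.segments.append((tip.origin_idx, idx, tip.seg_len))
                continue
            stamp(tip.r, tip.c, nr, nc, step)
            tip.seg_len += params.step_len
            if not (lo_r <= nr <= hi_r and lo_c <= nc <= hi_c):
                # boundary death: terminal at the (clipped) exit point
                idx = add_point(nr, nc, "terminal")
                gt.segments.append((tip.origin_idx, idx, tip.seg_len))
                continue
            if rng.random() < params.branch_prob:
                idx = add_point(nr, nc, "branch")
                gt.segments.append((tip.origin_idx, idx, tip.seg_len))
                for sign in (+1.0, -1.0):
                    survivors.append(
                        _Tip(nr, nc, tip.heading + sign * params.branch_angle, idx)
                    )
            else:
                tip.r, tip.c = nr, nc
                survivors.append(tip)
        tips = survivors

    for tip in tips:            # iteration cap reached
        idx = add_point(tip.r, tip.c, "terminal")
        gt.segments.append((tip.origin_idx, idx, tip.seg_len))

    mask = dilation(path, disk(params.radius))
    gt.validate((h, w))
    return VascularImage(mask), gt


# ---------------------------------------------------------------------------
# Treatment presets
# ---------------------------------------------------------------------------

# Frozen constants calibrated once so that, over 30-replicate cohorts, group
# mean vessel coverage and junction count rank in the order
# pge1 > amino8 > amino3 > amino5 > hydroxy8 > control > quinoline,
# the ordering of the reference assay's treatment groups.  The biological
# groups give no growth parameters; these values are this package's.
_PRESETS: dict[str, GrowthParams] = {
    "pge1": GrowthParams(
        n_seeds=6, branch_prob=0.100, step_len=4.0, angle_sigma=0.26,
        branch_angle=0.58, max_steps=42, radius=2, label="pge1",
    ),
    "amino8": GrowthParams(
        n_seeds=6, branch_prob=0.070, step_len=4.0, angle_sigma=0.26,
        branch_angle=0.58, max_steps=43, radius=2, label="amino8",
    ),
    "amino3": GrowthParams(
        n_seeds=5, branch_prob=0.066, step_len=4.0, angle_sigma=0.26,
        branch_angle=0.58, max_steps=45, radius=2, label="amino3",
    ),
    "amino5": GrowthParams(
        n_seeds=5, branch_prob=0.063, step_len=4.0, angle_sigma=0.26,
        branch_angle=0.58, max_steps=44, radius=2, label="amino5",
    ),
    "hydroxy8": GrowthParams(
        n_seeds=5, branch_prob=0.054, step_len=4.0, angle_sigma=0.26,
        branch_angle=0.58, max_steps=45, radius=2, label="hydroxy8",
    ),
    "control": GrowthParams(
        n_seeds=4, branch_prob=0.055, step_len=4.0, angle_sigma=0.26,
        branch_angle=0.58, max_steps=46, radius=2, label="control",
    ),
    "quinoline": GrowthParams(
        n_seeds=3, branch_prob=0.050, step_len=4.0, angle_sigma=0.26,
        branch_angle=0.58, max_steps=46, radius=2, label="quinoline",
    ),
}

PRESET_LABELS: tuple[str, ...] = tuple(_PRESETS)

# Extraction-validation condition: thin (radius 1) sparse vessels, wide
# branch angle, near-straight walks and anastomotic stopping, on a large
# canvas.  Ground-truth branch events are then resolvable at a few-pixel
# matching tolerance, so extraction accuracy measures the tracing itself
# rather than rasterization limits.  Used by the accuracy checks; distinct
# from the treatment presets, which trade resolvability for density realism.
EXTRACTION_VALIDATION = GrowthParams(
    n_seeds=2, branch_prob=0.07, step_len=5.0, angle_sigma=0.06,
    branch_angle=1.0, max_steps=30, radius=1, width=768, height=768,
    contact_inhibition=True, label="validation",
)


def preset(label: str, rng_seed: int | None = None) -> GrowthParams:
    """Return the frozen growth-parameter set for a treatment preset.

    ``rng_seed``, if given, overrides the preset's default seed (used when
    simulating replicate cohorts).
    """
    try:
        params = _PRESETS[label]
    except KeyError:
        raise ValueError(
            f"unknown preset {label!r}; choose from {', '.join(_PRESETS)}"
        ) from None
    if rng_seed is not None:
        params = replace(params, rng_seed=int(rng_seed))
    return params


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES: tuple[str, ...] = (
    "empty", "filled", "half", "line", "diagonal", "cross", "ystem",
    "hbar", "ring", "grid", "checkerboard", "sierpinski_carpet",
)


def _sierpinski(depth: int) -> np.ndarray:
    n = 3 ** depth
    r = np.arange(n)
    keep = np.ones((n, n), dtype=bool)
    for d in range(depth):
        digit = (r // 3 ** d) % 3
        keep &= ~((digit[:, None] == 1) & (digit[None, :] == 1))
    return keep


def make_fixture(name: str, size: int = 64) -> VascularImage:
    """Return one of the named deterministic validation patterns.

    The thin patterns (line, diagonal, cross, ystem, hbar, ring) are
    single-pixel wide and hence valid skeletons as drawn.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {', '.join(FIXTURE_NAMES)}"
        )
    if size < 16:
        raise ValueError("fixture size must be >= 16")
    m = np.zeros((size, size), dtype=bool)
    c = size // 2
    if name == "empty":
        pass
    elif name == "filled":
        m[:] = True
    elif name == "half":
        m[: size // 2, :] = True
    elif name == "line":
        m[c, :] = True
    elif name == "diagonal":
        idx = np.arange(size)
        m[idx, idx] = True
    elif name == "cross":
        m[c, :] = True
        m[:, c] = True
    elif name == "ystem":
        m[c:, c] = True                       # stem: center down to bottom edge
        for i in range(1, c + 1):             # two diagonal arms going up
            m[c - i, c - i] = True
            m[c - i, min(c + i, size - 1)] = True
    elif name == "hbar":
        a, b = size // 4, 3 * size // 4
        m[:, a] = True
        m[:, b] = True
        m[c, a:b + 1] = True
    elif name == "ring":
        m[1, 1:-1] = True
        m[-2, 1:-1] = True
        m[1:-1, 1] = True
        m[1:-1, -2] = True
    elif name == "grid":
        step = max(4, size // 6)
        for i in range(2, size - 2, step):
            m[i, 2:size - 2] = True
            m[2:size - 2, i] = True
    elif name == "checkerboard":
        rr, cc = np.indices((size, size))
        m = (rr + cc) % 2 == 0
    elif name == "sierpinski_carpet":
        depth = int(math.floor(math.log(size) / math.log(3) + 1e-9))
        carpet = _sierpinski(depth)
        n = carpet.shape[0]
        off = (size - n) // 2
        m[off:off + n, off:off + n] = carpet
    return VascularImage(m)


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------

def write_image(img: VascularImage, path: str | Path,
                ground_truth: GroundTruth | None = None) -> None:
    """Write an 8-bit PNG (0 background / 255 vessel); optionally a JSON
    ground-truth sidecar next to it (same stem, ``.json``)."""
    path = Path(path)
    iio.imwrite(path, (img.mask.astype(np.uint8) * 255))
    if ground_truth is not None:
        path.with_suffix(".json").write_text(ground_truth.to_json())


def read_image(path: str | Path, scale: float = 1.0) -> np.ndarray:
    """Read an image file as a 2-D grayscale array (RGB is averaged)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return np.asarray(arr)


def simulate_cohort(
    label: str, n: int = 30, base_seed: int = 0
) -> list[tuple[VascularImage, GroundTruth]]:
    """Simulate ``n`` replicate images of one preset with seeds
    ``base_seed .. base_seed + n - 1``."""
    out = []
    for i in range(n):
        out.append(grow_network(preset(label, rng_seed=base_seed + i)))
    return out


__all__.append("simulate_cohort")
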