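"""Synthetic tooth phantoms: star-convex silhouettes with stage-graded roots.

Real premolar crops cannot be redistributed, so the test suite and the
worked examples run on phantoms that reproduce the geometry the pipeline
relies on: a bright, roughly tooth-shaped star-convex silhouette centered
in a 250x250 frame, over a darker background with smooth low-frequency
clutter and salt-and-pepper impulse noise (the latter is what the 7x7
median filter is there to remove).

Demirjian stages C-H are encoded geometrically, following the qualitative
stage descriptions: the root lengthens monotonically from C to H and the
apex, forked open in early stages, closes completely at H. "Sex" in the
source data becomes two geometry-scale cohorts. None of this models
radiographic physics; see the methods note for what that implies.

The silhouette is built directly as a radial function r(theta) about the
image center, which makes star-convexity true by construction — every ray
from the seed point crosses the boundary exactly once, the shape family the
radial DP contour can represent exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from toothstage.classifier import STAGES
from toothstage.dpac import contour_to_mask

# stage -> (root length as a fraction of crown height, apex gap in pixels)
# Root grows C -> H; the apex notch shrinks and closes exactly at H. The
# steps are sized to stay resolvable after the 250 -> 90 classifier resize,
# so the generator carries enough stage signal for any reasonable classifier.
STAGE_GEOMETRY: dict[str, tuple[float, float]] = {
    "C": (0.20, 18.0),
    "D": (0.45, 15.0),
    "E": (0.70, 12.0),
    "F": (1.00, 9.0),
    "G": (1.20, 6.0),
    "H": (1.35, 0.0),
}

#: geometry scale factors for the two cohorts standing in for sex
COHORT_SCALE = {"F": 1.0, "M": 1.12}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + appearance parameters of one phantom."""

    stage: str
    image_side: int = 250
    crown_width: float = 52.0          # full width of the crown ellipse, px
    crown_height: float = 34.0         # full height of the crown ellipse, px
    root_length_fraction: float | None = None  # None -> stage default
    apex_gap: float | None = None              # None -> stage default
    root_width: float = 22.0           # angular width of the root lobe, px at base
    contrast: float = 0.45             # tooth minus background intensity
    clutter_level: float = 0.08        # low-frequency background amplitude
    impulse_noise_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.image_side < 32:
            raise ValueError(f"image_side too small: {self.image_side}")

    @property
    def effective_root_fraction(self) -> float:
        return (STAGE_GEOMETRY[self.stage][0]
                if self.root_length_fraction is None else self.root_length_fraction)

    @property
    def effective_apex_gap(self) -> float:
        return (STAGE_GEOMETRY[self.stage][1]
                if self.apex_gap is None else self.apex_gap)


@dataclass
class PhantomCase:
    """One generated sample: image, ground-truth mask, label, provenance."""

    image: np.ndarray
    truth_mask: np.ndarray
    label: str
    cohort: str
    spec: PhantomSpec


def _radial_profile(spec: PhantomSpec, thetas: np.ndarray) -> np.ndarray:
    """Boundary radius r(theta) of the silhouette about the image center.

    Crown: ellipse with semi-axes (crown_width/2, crown_height/2). Root: a
    smooth downward lobe (theta = pi/2 in (row, col) convention points down)
    whose length is root_fraction * crown_height, minus a narrow apex notch
    of depth apex_gap that splits the tip into two prongs while it is open.
    """
    a = spec.crown_width / 2.0
    b = spec.crown_height / 2.0
    r_crown = (a * b) / np.sqrt((b * np.cos(thetas)) ** 2 + (a * np.sin(thetas)) ** 2)

    root_len = spec.effective_root_fraction * spec.crown_height
    # angular half-width of the root lobe, from its base width at crown distance
    sigma = np.arctan2(spec.root_width / 2.0, b + root_len / 2.0) * 1.6
    down = np.pi / 2.0  # +row direction
    dth = np.arctan2(np.sin(thetas - down), np.cos(thetas - down))
    lobe = root_len * np.exp(-0.5 * (dth / max(sigma, 1e-6)) ** 2)

    gap = spec.effective_apex_gap
    notch = gap * np.exp(-0.5 * (dth / (max(sigma, 1e-6) * 0.5)) ** 2)

    r = r_crown + lobe - notch
    return np.maximum(r, 4.0)


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom, its exact polygon-rasterized mask, and its label."""
    side = spec.image_side
    center = ((side - 1) / 2.0, (side - 1) / 2.0)
    rng = np.random.default_rng(spec.seed)

    thetas = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    r = _radial_profile(spec, thetas)
    max_r = float(r.max())
    if max_r >= side / 2.0 - 2.0:
        raise ValueError(
            f"phantom geometry (max radius {max_r:.1f}) exceeds the "
            f"{side}x{side} frame; shrink the crown or root"
        )
    boundary = np.column_stack([
        center[0] + r * np.sin(thetas),
        center[1] + r * np.cos(thetas),
    ])
    mask = contour_to_mask(boundary, (side, side))

    base = 0.25
    img = np.full((side, side), base)
    if spec.clutter_level > 0:
        yy, xx = np.meshgrid(np.linspace(0, 1, side), np.linspace(0, 1, side),
                             indexing="ij")
        clutter = np.zeros((side, side))
        for _ in range(4):
            fy, fx = rng.uniform(1.0, 4.0, size=2)
            py, px = rng.uniform(0, 2 * np.pi, size=2)
            clutter += np.cos(2 * np.pi * fy * yy + py) * np.cos(2 * np.pi * fx * xx + px)
        clutter *= spec.clutter_level / max(np.abs(clutter).max(), 1e-9)
        img += clutter
    img = np.where(mask > 0, base + spec.contrast, img)

    n_imp = int(round(spec.impulse_noise_fraction * side * side))
    if n_imp > 0:
        rs = rng.integers(0, side, n_imp)
        cs = rng.integers(0, side, n_imp)
        img[rs, cs] = rng.choice([0.0, 1.0], n_imp)

    return PhantomCase(image=np.clip(img, 0.0, 1.0), truth_mask=mask,
                       label=spec.stage, cohort="F", spec=spec)


def generate_dataset(
    n_per_stage_per_cohort: int = 20,
    seed: int = 0,
    image_side: int = 250,
    jitter: float = 0.08,
    clutter_level: float = 0.08,
    impulse_noise_fraction: float = 0.02,
) -> list[PhantomCase]:
    """6 stages x 2 cohorts x n cases with seeded geometric jitter.

    ``n_per_stage_per_cohort=20`` reproduces the source study's 240-image
    set. ``jitter`` is the relative s.d. of the per-case scatter applied to
    crown size, root length and apex gap, truncated at two s.d. so the
    stage-defining morphology (root/crown ratio ordering, closed apex at H)
    survives the scatter; gap stays exactly 0 at stage H.
    """
    rng = np.random.default_rng(seed)

    def jittered(v: float) -> float:
        z = float(np.clip(rng.normal(0.0, 1.0), -2.0, 2.0))
        return float(v * (1.0 + jitter * z))

    cases: list[PhantomCase] = []
    for stage in STAGES:
        root_frac0, gap0 = STAGE_GEOMETRY[stage]
        for cohort, scale in COHORT_SCALE.items():
            for _ in range(n_per_stage_per_cohort):
                spec = PhantomSpec(
                    stage=stage,
                    image_side=image_side,
                    crown_width=jittered(52.0 * scale),
                    crown_height=jittered(36.0 * scale),
                    root_length_fraction=max(0.05, jittered(root_frac0)),
                    apex_gap=0.0 if gap0 == 0.0 else max(0.5, jittered(gap0)),
                    contrast=float(np.clip(0.45 + rng.normal(0, 0.04), 0.2, 0.7)),
                    clutter_level=clutter_level,
                    impulse_noise_fraction=impulse_noise_fraction,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                case = generate_phantom(spec)
                case.cohort = cohort
                cases.append(case)
    return cases
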