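"""Dynamic-programming active contour (DP-AC) on a radial candidate grid.

A seed point inside a star-convex object is given. M radial lines leave the
seed at uniform angles; each carries N discrete candidate positions
("graduations") at uniform spacing. A closed contour picks one graduation
per line, and its cost is the sum over lines of

    E_i(v_i, v_{i+1}) = -g(v_i)   if D(v_i, v_{i+1}) <= delta
                        sentinel  otherwise,

where ``g`` is the image gradient projected on the line's outward direction
and the wrap pair (v_M, v_1) is included. Minimizing the total therefore
finds the closed contour of maximal directional gradient strength whose
consecutive points stay within ``delta`` of each other. The minimum is found
globally by dynamic programming — no contour initialization or gradient
descent is involved; the seed point is the only manual input.

Cyclic closure is solved exactly by running the open-chain DP for every
possible first-line graduation at once (a start-state dimension on the DP
table), or by a cheaper documented two-pass approximation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

from toothstage.image import as_gray


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RadialGrid:
    """M uniformly-angled radial lines, N graduations per line.

    Graduation j on line i sits at ``center + (j+1)*spacing*u_i`` where
    ``u_i = (sin(angle_i), cos(angle_i))`` in (row, col); angle 0 points
    along +col and angles increase toward +row.
    """

    center: tuple[float, float]
    n_lines: int
    radius_length: float
    spacing: float = 1.0

    @property
    def n_graduations(self) -> int:
        return int(np.floor(self.radius_length / self.spacing + 1e-9))

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_lines) * (2.0 * np.pi / self.n_lines)

    @property
    def radii(self) -> np.ndarray:
        """Radius of each graduation: (j+1)*spacing, j = 0..N-1."""
        return (np.arange(self.n_graduations) + 1.0) * self.spacing

    def points(self) -> np.ndarray:
        """All candidate coordinates, shape (M, N, 2) as (row, col)."""
        ang = self.angles[:, None]
        rad = self.radii[None, :]
        rows = self.center[0] + rad * np.sin(ang)
        cols = self.center[1] + rad * np.cos(ang)
        return np.stack([rows, cols], axis=-1)


def build_radial_grid(
    center: tuple[float, float],
    n_lines: int,
    radius_length: float,
    spacing: float = 1.0,
) -> RadialGrid:
    """Construct the M x N candidate lattice around ``center``."""
    if n_lines < 3:
        raise ValueError(f"need at least 3 radial lines, got {n_lines}")
    if radius_length < 2 * spacing:
        raise ValueError(
            f"radius_length {radius_length} must be >= 2*spacing ({2 * spacing})"
        )
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    return RadialGrid(center=tuple(center), n_lines=int(n_lines),
                      radius_length=float(radius_length), spacing=float(spacing))


# --------------------------------------------------------------------------
# Cost field
# --------------------------------------------------------------------------

def directional_gradient(image: np.ndarray, grid: RadialGrid) -> np.ndarray:
    """Outward radial derivative of the image at every grid point.

    Central-difference image gradients are sampled at the (generally
    sub-pixel) grid coordinates with bilinear interpolation and projected
    onto each line's outward unit vector. Points outside the image are
    sampled with edge replication. Returns an (M, N) float array.
    """
    img = as_gray(image)
    g_row, g_col = np.gradient(img)
    pts = grid.points()  # (M, N, 2)
    coords = pts.reshape(-1, 2).T  # (2, M*N) as (row, col)
    sr = ndimage.map_coordinates(g_row, coords, order=1, mode="nearest")
    sc = ndimage.map_coordinates(g_col, coords, order=1, mode="nearest")
    ang = grid.angles
    u_row, u_col = np.sin(ang), np.cos(ang)
    M, N = grid.n_lines, grid.n_graduations
    proj = (sr.reshape(M, N) * u_row[:, None] + sc.reshape(M, N) * u_col[:, None])
    return proj


# --------------------------------------------------------------------------
# DP solver
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DpConfig:
    """Solver settings.

    delta            maximum Euclidean distance between consecutive contour
                     points, wrap pair included (pixels)
    closure          "exact" (open-chain DP per candidate first point, run
                     for all first points at once) or "two_pass" (fix the
                     unconstrained open-chain optimum's first point, then
                     re-solve the cycle through it)
    bright_object    the target is brighter than its surround, so the true
                     boundary has a negative outward derivative; the gradient
                     field is negated before costing
    infeasible_cost  finite sentinel standing for the infinite cost of a
                     delta violation; None = choose M*max|g| + 1 at solve time
    """

    delta: float = 3.0
    closure: str = "exact"
    bright_object: bool = True
    infeasible_cost: float | None = None

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.closure not in ("exact", "two_pass"):
            raise ValueError(f"closure must be 'exact' or 'two_pass', got {self.closure!r}")


@dataclass
class ContourSolution:
    """DP result: one graduation per line, its coordinates, cost and status."""

    selection: np.ndarray          # (M,) graduation indices
    points: np.ndarray             # (M, 2) contour coordinates (row, col)
    energy: float                  # sum of the M stage costs of the selection
    feasible: bool                 # every wrap-inclusive pair within delta
    delta: float = field(default=3.0)


def stage_cost(g_value: float, point_i, point_next, config: DpConfig) -> float:
    """Cost of one contour edge: -g if the two points are within delta."""
    d = float(np.hypot(point_i[0] - point_next[0], point_i[1] - point_next[1]))
    if d <= config.delta:
        return -float(g_value)
    sentinel = config.infeasible_cost
    if sentinel is None:
        raise ValueError("stage_cost with D > delta needs an explicit infeasible_cost")
    return float(sentinel)


def _adjacent_feasibility(grid: RadialGrid, delta: float) -> np.ndarray:
    """(N, N) boolean: may graduation j on one line follow graduation k on the next?

    Uniform angles and spacing make this matrix identical for every adjacent
    pair of lines, including the wrap pair: the distance between radius R_j
    on one line and R_k on the next depends only on (R_j, R_k, 2*pi/M).
    """
    R = grid.radii
    dtheta = 2.0 * np.pi / grid.n_lines
    d2 = R[:, None] ** 2 + R[None, :] ** 2 - 2.0 * np.outer(R, R) * np.cos(dtheta)
    return d2 <= delta * delta + 1e-12


def _banded_offsets(F: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """Decompose a feasibility matrix into its nonzero diagonals.

    Returns (offset d, row indices j with F[j, j+d]) for each populated
    diagonal; the DP transition then touches only feasible pairs.
    """
    N = F.shape[0]
    out = []
    for d in range(-(N - 1), N):
        j = np.arange(max(0, -d), min(N, N - d))
        mask = F[j, j + d]
        if mask.any():
            out.append((d, j[mask]))
    return out


def _min_over_feasible(G_next: np.ndarray, offsets, N: int, big: float) -> np.ndarray:
    """out[..., j] = min over feasible k of G_next[..., k], banded transition."""
    out = np.full_like(G_next, big)
    for d, js in offsets:
        # fancy-indexed setitem: out[..., js] is a copy, so assign, don't `out=`
        out[..., js] = np.minimum(out[..., js], G_next[..., js + d])
    return out


def solve_closed_contour(
    cost: np.ndarray,
    grid: RadialGrid,
    config: DpConfig,
) -> ContourSolution:
    """Globally minimize the closed-contour cost over the candidate lattice.

    ``cost`` is the (M, N) directional-gradient field g. With
    ``closure="exact"`` the returned selection attains the true minimum of
    the wrap-inclusive sum over all N^M tuples satisfying the delta
    constraint (infeasible edges carry the finite sentinel, so when no tuple
    is fully feasible the least-bad selection is returned with
    ``feasible=False``). Ties are broken toward the lexicographically
    smallest selection.
    """
    g = np.asarray(cost, dtype=float)
    M, N = grid.n_lines, grid.n_graduations
    if g.shape != (M, N):
        raise ValueError(f"cost field shape {g.shape} does not match grid ({M}, {N})")
    if config.bright_object:
        g = -g
    node = -g  # per-point stage cost
    sentinel = config.infeasible_cost
    if sentinel is None:
        sentinel = M * float(np.abs(g).max()) + 1.0
    F = _adjacent_feasibility(grid, config.delta)
    offsets = _banded_offsets(F)
    if not offsets:
        # no pair of consecutive graduations is ever within delta: every
        # edge costs the sentinel; report the per-line node-cost argmin
        sel = node.argmin(axis=1)
        pts = grid.points()[np.arange(M), sel]
        return ContourSolution(sel, pts, float(M * sentinel), False, config.delta)

    if config.closure == "exact":
        sel = _solve_all_starts(node, F, offsets, M, N, sentinel)
    else:
        sel = _solve_two_pass(node, F, offsets, M, N, sentinel)

    pts_all = grid.points()
    pts = pts_all[np.arange(M), sel]
    nxt = np.roll(pts, -1, axis=0)
    dists = np.hypot(*(pts - nxt).T)
    violated = dists > config.delta + 1e-9
    feasible = bool(~violated.any())
    # edge costs per the cost rule: -g(v_i) on feasible edges, the sentinel
    # (not on top) where the delta bound is broken
    energy = float(np.where(violated, sentinel, node[np.arange(M), sel]).sum())
    return ContourSolution(sel, pts, energy, feasible, config.delta)


def _solve_all_starts(node, F, offsets, M, N, sentinel):
    """Exact cyclic DP: suffix tables carry a start-state (v_1) dimension.

    S[i][s, j] = min cost of edges i..M-1 given v_i = j and v_1 = s (edge
    M-1 wraps back to s). Edge i costs node[i, v_i] when feasible and the
    sentinel otherwise, so a least-bad tuple always exists and any optimal
    fully-feasible tuple beats every violating one.
    """
    big = (M + 2) * (abs(sentinel) + 1.0)
    # wrap edge M-1: from v_{M-1} = j back to v_0 = s
    S_next = np.where(F.T, node[M - 1][None, :], sentinel)   # [s, j]
    stages = [None] * M
    stages[M - 1] = S_next
    for i in range(M - 2, -1, -1):
        best_feas = _min_over_feasible(S_next, offsets, N, big)
        fallback = S_next.min(axis=-1, keepdims=True) + sentinel
        S_next = np.minimum(node[i][None, :] + best_feas, fallback)
        if i > 0:
            stages[i] = S_next
    start_costs = np.diagonal(S_next).copy()       # S_0[s, s]
    s = int(np.argmin(start_costs))                # first argmin = smallest index

    # forward reconstruction, lexicographically smallest among optima
    sel = np.empty(M, dtype=int)
    sel[0] = s
    for i in range(1, M):
        S_i = stages[i][s]                         # suffix costs given v_i = k
        feas = F[sel[i - 1]]                       # feasible successors of v_{i-1}
        cand = np.where(feas, node[i - 1][sel[i - 1]], sentinel) + S_i
        sel[i] = int(np.argmin(cand))
    return sel


def _solve_two_pass(node, F, offsets, M, N, sentinel):
    """Open-chain DP, then re-solve the cycle through the fixed first point."""
    big = (M + 2) * (abs(sentinel) + 1.0)
    # pass 1: open chain (wrap edge ignored; line M-1 contributes its node cost)
    S = node[M - 1].astype(float)
    for i in range(M - 2, -1, -1):
        best_feas = _min_over_feasible(S[None, :], offsets, N, big)[0]
        S = np.minimum(node[i] + best_feas, S.min() + sentinel)
    v1 = int(np.argmin(S))
    # pass 2: exact cycle restricted to the single start state v1
    S_next = np.where(F[:, v1], node[M - 1], sentinel)
    stages = [None] * M
    stages[M - 1] = S_next
    for i in range(M - 2, 0, -1):
        best_feas = _min_over_feasible(S_next[None, :], offsets, N, big)[0]
        S_next = np.minimum(node[i] + best_feas, S_next.min() + sentinel)
        stages[i] = S_next
    sel = np.empty(M, dtype=int)
    sel[0] = v1
    for i in range(1, M):
        feas = F[sel[i - 1]]
        cand = np.where(feas, node[i - 1][sel[i - 1]], sentinel) + stages[i]
        sel[i] = int(np.argmin(cand))
    return sel


# --------------------------------------------------------------------------
# Mask, superimposition, metrics
# --------------------------------------------------------------------------

def contour_to_mask(contour: ContourSolution | np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed contour to a {0, 1} mask of the given shape.

    A pixel is foreground when its center lies inside or on the polygon
    (boundary-inclusive point-in-polygon on pixel centers).
    """
    pts = contour.points if isinstance(contour, ContourSolution) else np.asarray(contour, float)
    if pts.shape[0] < 3:
        raise ValueError(f"polygon needs at least 3 points, got {pts.shape[0]}")
    poly = Polygon(np.column_stack([pts[:, 1], pts[:, 0]]))  # (x=col, y=row)
    if poly.area == 0:
        raise ValueError("degenerate polygon with zero area")
    if not poly.is_valid:
        poly = poly.buffer(0)
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
    r0, r1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
    mask = np.zeros((h, w), dtype=np.uint8)
    if c0 > c1 or r0 > r1:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pts_geom = shapely.points(cols.ravel(), rows.ravel())
    shapely.prepare(poly)
    inside = shapely.covers(poly, pts_geom).reshape(rows.shape)
    mask[r0:r1 + 1, c0:c1 + 1] = inside.astype(np.uint8)
    return mask


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Superimpose: keep intensities inside the mask, zero the background."""
    img = as_gray(image)
    m = np.asarray(mask)
    if m.shape != img.shape:
        raise ValueError(f"mask shape {m.shape} does not match image {img.shape}")
    return img * (m > 0)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient (F1 overlap) 2|A∩B|/(|A|+|B|); 1 if both masks empty."""
    A, B = np.asarray(a) > 0, np.asarray(b) > 0
    sa, sb = int(A.sum()), int(B.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((A & B).sum()) / (sa + sb)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard similarity |A∩B|/|A∪B|; 1 if both masks empty."""
    A, B = np.asarray(a) > 0, np.asarray(b) > 0
    union = int((A | B).sum())
    if union == 0:
        return 1.0
    return int((A & B).sum()) / union


def grade_segmentation(pred: np.ndarray, truth: np.ndarray, tol: float = 0.2) -> str:
    """Qualitative output state: "under", "well" or "over" segmented.

    ``over`` when the spurious area |pred \\ truth| exceeds ``tol`` of the
    true area; ``under`` when the missed area |truth \\ pred| does; ``well``
    otherwise. Spillover takes precedence when both are large.
    """
    P, T = np.asarray(pred) > 0, np.asarray(truth) > 0
    t_area = int(T.sum())
    if t_area == 0:
        raise ValueError("truth mask is empty; grading undefined")
    extra = int((P & ~T).sum()) / t_area
    missed = int((T & ~P).sum()) / t_area
    if extra > tol:
        return "over"
    if missed > tol:
        return "under"
    return "well"


# --------------------------------------------------------------------------
# High-level segmentation + parameter sweep
# --------------------------------------------------------------------------

def segment(
    image: np.ndarray,
    center: tuple[float, float] | None = None,
    n_lines: int = 1200,
    radius_length: float = 100.0,
    spacing: float = 1.0,
    config: DpConfig | None = None,
) -> tuple[ContourSolution, np.ndarray]:
    """Segment a star-convex bright object around ``center`` (default: image center).

    Returns the DP contour and its rasterized binary mask. The defaults are
    the recommended operating point for 250x250 premolar crops: 1200 radial
    lines of 100 px at 1 px graduation spacing.
    """
    img = as_gray(image)
    if center is None:
        center = ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)
    cfg = config or DpConfig()
    grid = build_radial_grid(center, n_lines, radius_length, spacing)
    g = directional_gradient(img, grid)
    sol = solve_closed_contour(g, grid, cfg)
    mask = contour_to_mask(sol, img.shape)
    return sol, mask


def parameter_sweep(
    cases: list[tuple[np.ndarray, tuple[float, float], np.ndarray]],
    radius_lengths=(80, 100, 120, 140),
    line_counts=(800, 1000, 1200),
    config: DpConfig | None = None,
    grade_tol: float = 0.2,
) -> pd.DataFrame:
    """Mean Dice/Jaccard/wall-time and majority grade per (radius, lines) setting.

    ``cases`` holds (image, seed point, truth mask) triples. One row per
    grid setting, columns: radius_length, n_lines, time_s, dice, jaccard,
    grade — the layout of the reference accuracy-vs-parameters sweep.
    """
    if not cases:
        raise ValueError("parameter_sweep needs at least one case")
    cfg = config or DpConfig()
    rows = []
    for radius in radius_lengths:
        for n_lines in line_counts:
            dices, jacs, times, grades = [], [], [], []
            for img, center, truth in cases:
                t0 = time.perf_counter()
                _, mask = segment(img, center, n_lines=n_lines,
                                  radius_length=radius, config=cfg)
                times.append(time.perf_counter() - t0)
                dices.append(dice(mask, truth))
                jacs.append(jaccard(mask, truth))
                grades.append(grade_segmentation(mask, truth, tol=grade_tol))
            majority = max(("under", "well", "over"), key=grades.count)
            rows.append({
                "radius_length": radius, "n_lines": n_lines,
                "time_s": float(np.mean(times)),
                "dice": float(np.mean(dices)), "jaccard": float(np.mean(jacs)),
                "grade": majority,
            })
    return pd.DataFrame(rows)
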