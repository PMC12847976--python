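"""Ground-truthed synthetic vascular networks.

The growth model is a border-seeded persistent random walk with Bernoulli
branching: trunk walkers start on the frame border pointing inward, step a
fixed distance per tick with angular jitter, and at each step spawn a child
branch with a fixed probability. A walker that runs into a previously drawn
vessel fuses there (an anastomosis) and stops. Every branch event and fusion
is recorded both in the truth (junction list) and in an event log, so the
junction count can be audited by replaying the log.

This is deliberately simple — it produces a connected-per-seed, loopy,
mixed-width network resembling a self-organized microvascular bed, with exact
branch polylines and junction coordinates as ground truth for validating the
measurement pipeline.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from ..types import (
    BACKGROUND,
    THICK,
    THIN,
    ChipGeometry,
    ChipImage,
    EmptyNetworkError,
    ParameterError,
    VesselMask,
)

# width >= this (px) is a "thick" vessel; mirrors segment.classify_thickness
DEFAULT_THICK_CUTOFF = 4.0


@dataclass
class Branch:
    points: np.ndarray  # (k, 2) float (row, col) polyline vertices
    width: float  # stroke width in px
    kind: str  # "thick" | "thin"

    @property
    def arc_length(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class NetworkTruth:
    """Exact ground truth for one synthetic vascular network."""

    branches: list[Branch]
    junctions: np.ndarray  # (m, 2) float junction coordinates
    total_length: float  # sum of branch arc lengths, px
    thick_area: int = 0  # px², filled in by rasterize()
    thin_area: int = 0
    event_log: list[dict] = field(default_factory=list)

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def total_area(self) -> int:
        return self.thick_area + self.thin_area


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the vessel growth model.

    branch_prob
        Per-step probability that a walker spawns a child branch.
    step_length
        Distance covered per step, px.
    persistence
        Directional persistence in [0, 1]; 1 means perfectly straight,
        lower values increase angular jitter (std = (1-p) * turn_scale rad).
    n_seeds
        Number of trunk walkers seeded on the compartment border.
    max_steps
        Maximum steps per walker.
    thin_width / thick_width
        Uniform sampling ranges (lo, hi) for branch stroke widths; kept clear
        of the thick/thin cutoff so nominal and rasterized class agree.
    trunk_thick_prob
        Probability a trunk (seed) walker is thick.
    min_branch_length
        Branches shorter than this (px) are discarded along with their
        branch-point record (they would be pruned as spurs downstream anyway).
    """

    branch_prob: float = 0.02
    step_length: float = 4.0
    persistence: float = 0.9
    n_seeds: int = 6
    max_steps: int = 180
    thin_width: tuple[float, float] = (1.5, 3.5)
    thick_width: tuple[float, float] = (5.0, 8.0)
    trunk_thick_prob: float = 0.7
    turn_scale: float = 1.2
    branch_angle: float = math.radians(55.0)
    min_branch_length: float = 14.0
    branch_cooldown: int = 4
    max_walkers: int = 60

    def __post_init__(self) -> None:
        for p in (self.branch_prob, self.persistence, self.trunk_thick_prob):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("probabilities must lie in [0, 1]")
        if self.step_length <= 0:
            raise ParameterError("step_length must be > 0")
        for lo, hi in (self.thin_width, self.thick_width):
            if lo <= 0 or hi < lo:
                raise ParameterError("width ranges must be positive and ordered")


def replay_junction_count(event_log: list[dict]) -> int:
    """Junction count implied by a generator event log.

    Junctions are branch points of confirmed children plus anastomosis
    (fusion) points of confirmed walkers; ``cancel`` and ``drop`` events
    retract them. Used as an audit oracle against ``NetworkTruth.junctions``.
    """
    branched: set[int] = set()
    fused: dict[int, int] = {}
    gone: set[int] = set()
    for ev in event_log:
        kind = ev["event"]
        if kind == "branch":
            branched.add(ev["child"])
        elif kind == "fuse":
            fused[ev["walker"]] = ev["into"]
        elif kind in ("cancel", "drop"):
            gone.add(ev["walker"])
    n = sum(1 for w in branched if w not in gone)
    n += sum(1 for w, tgt in fused.items() if w not in gone and tgt not in gone)
    return n


def generate_network(
    params: GrowthParams = GrowthParams(),
    geometry: ChipGeometry = ChipGeometry(),
    seed: Optional[int] = None,
    thick_cutoff: float = DEFAULT_THICK_CUTOFF,
) -> NetworkTruth:
    """Grow a synthetic vascular network; deterministic given ``seed``.

    Raises
    ------
    EmptyNetworkError
        If ``n_seeds`` or ``max_steps`` is zero.
    """
    if seed is None:
        raise ParameterError("seed must be set explicitly")
    if params.n_seeds < 1 or params.max_steps < 1:
        raise EmptyNetworkError("need at least one seed and one step")
    rng = np.random.default_rng(seed)
    nr, nc = geometry.shape
    margin = 2.0

    # occupancy grid: -1 free, else walker id that painted near the pixel.
    # Painted as squares (cheap); used only for collision detection.
    owner = np.full(geometry.shape, -1, dtype=np.int32)

    def paint(wid: int, p: np.ndarray, width: float) -> None:
        rad = int(max(1.0, round(width / 2.0)))
        r0, c0 = int(round(p[0])), int(round(p[1]))
        owner[
            max(0, r0 - rad) : min(nr, r0 + rad + 1),
            max(0, c0 - rad) : min(nc, c0 + rad + 1),
        ] = wid

    def hit(wid: int, ignore: int, p: np.ndarray) -> int:
        r0, c0 = int(round(p[0])), int(round(p[1]))
        if not (0 <= r0 < nr and 0 <= c0 < nc):
            return -1
        o = int(owner[r0, c0])
        return o if (o >= 0 and o != wid and o != ignore) else -1

    center = np.array([nr / 2.0, nc / 2.0])
    log: list[dict] = []
    # per-walker state collected during growth
    walker_branch: dict[int, Branch] = {}
    walker_children: dict[int, list[int]] = {}
    walker_points: dict[int, np.ndarray] = {}  # raw polylines for fusion snapping
    start_junction: dict[int, np.ndarray] = {}  # child id -> branch point
    fuse_junction: dict[int, tuple[np.ndarray, int]] = {}  # walker -> (pt, target)

    def project_on_target(p: np.ndarray, target: int):
        """(closest point, distance, segment direction) on target's polyline."""
        pts = walker_points.get(target)
        if pts is None or len(pts) < 2:
            return None
        a, b = pts[:-1], pts[1:]
        d = b - a
        l2 = np.einsum("ij,ij->i", d, d)
        l2[l2 == 0] = 1.0
        t = np.clip(np.einsum("ij,ij->i", p - a, d) / l2, 0.0, 1.0)
        proj = a + t[:, None] * d
        dist2 = np.einsum("ij,ij->i", proj - p, proj - p)
        i = int(np.argmin(dist2))
        seg = d[i] / math.sqrt(float(l2[i]))
        return proj[i], math.sqrt(float(dist2[i])), seg

    # seed trunk walkers on the frame border, heading inward with jitter
    queue: list[tuple] = []  # (walker id, parent id, start, angle, width, grace)
    perimeter = 2 * (nr + nc)
    offsets = rng.uniform(0, perimeter, size=params.n_seeds)
    for i, t in enumerate(sorted(offsets)):
        if t < nc:
            p = np.array([margin, t])
        elif t < nc + nr:
            p = np.array([t - nc, nc - 1 - margin])
        elif t < 2 * nc + nr:
            p = np.array([nr - 1 - margin, t - nc - nr])
        else:
            p = np.array([t - 2 * nc - nr, margin])
        ang = math.atan2(*(center - p)) + rng.normal(0.0, 0.3)
        is_thick = rng.random() < params.trunk_thick_prob
        lo, hi = params.thick_width if is_thick else params.thin_width
        queue.append((i, -1, p, ang, float(rng.uniform(lo, hi)), 0))
        log.append({"event": "seed", "walker": i, "pos": tuple(p)})

    next_id = params.n_seeds
    jitter_sd = (1.0 - params.persistence) * params.turn_scale
    qi = 0
    while qi < len(queue):
        wid, parent, p, ang, width, grace = queue[qi]
        qi += 1
        pts = [p.copy()]
        paint(wid, p, width)
        pending: list[tuple] = []  # children, confirmed only if walker survives
        half = width / 2.0
        cooldown = params.branch_cooldown  # no branching right at the start
        last_branch_idx = 0  # never retreat past the latest branch point
        for step in range(params.max_steps):
            if jitter_sd > 0:
                ang += rng.normal(0.0, jitter_sd)
            step_vec = params.step_length * np.array([math.sin(ang), math.cos(ang)])
            p_new = p + step_vec
            if not (
                margin <= p_new[0] < nr - margin and margin <= p_new[1] < nc - margin
            ):
                break  # stop at the frame; nothing needs clipping later
            ignore = parent if step < grace else -1
            # sample the step midpoint and endpoint, each with +-half-width
            # lateral offsets, so strokes about to touch are always detected
            normal = np.array([step_vec[1], -step_vec[0]])
            normal /= max(np.linalg.norm(normal), 1e-9)
            other = -1
            for base in (p + 0.5 * step_vec, p_new):
                for off in (0.0, half, -half):
                    other = hit(wid, ignore, base + off * normal)
                    if other >= 0:
                        break
                if other >= 0:
                    break
            if other >= 0:
                heading = step_vec / params.step_length
                proj = project_on_target(p_new, other)
                steep = False
                if proj is not None:
                    fuse_pt, _, seg = proj
                    # approach angle vs target's local direction
                    cosang = abs(float(heading @ seg))
                    steep = cosang < math.cos(math.radians(30.0))
                if steep:
                    # anastomosis: snap the tip onto the target's centerline
                    # so the strokes genuinely meet in a clean T junction
                    if np.linalg.norm(fuse_pt - p) > 1e-6:
                        pts.append(fuse_pt.copy())
                    fuse_junction[wid] = (fuse_pt.copy(), other)
                    log.append(
                        {"event": "fuse", "walker": wid, "into": other,
                         "pos": tuple(fuse_pt)}
                    )
                else:
                    # shallow (near-parallel) encounter: back off until the
                    # strokes cannot touch, then stop without a junction
                    t_width = (
                        walker_branch[other].width if other in walker_branch else width
                    )
                    clearance = (width + t_width) / 2.0 + 1.0
                    while len(pts) > max(2, last_branch_idx + 1):
                        pr = project_on_target(pts[-1], other)
                        if pr is None or pr[1] > clearance:
                            break
                        pts.pop()
                break
            p = p_new
            pts.append(p.copy())
            paint(wid, p, width)
            cooldown = max(0, cooldown - 1)
            if (
                cooldown == 0
                and rng.random() < params.branch_prob
                and len(queue) + len(pending) < params.max_walkers
            ):
                cooldown = params.branch_cooldown
                side = 1.0 if rng.random() < 0.5 else -1.0
                child_ang = ang + side * params.branch_angle + rng.normal(0.0, 0.15)
                c_is_thick = rng.random() < 0.15
                lo, hi = params.thick_width if c_is_thick else params.thin_width
                c_width = float(min(rng.uniform(lo, hi), max(width, lo)))
                child_grace = int(math.ceil((width + c_width) / params.step_length)) + 2
                last_branch_idx = len(pts) - 1
                pending.append((next_id, wid, p.copy(), child_ang, c_width, child_grace))
                log.append(
                    {"event": "branch", "walker": wid, "child": next_id, "pos": tuple(p)}
                )
                next_id += 1
        if len(pts) >= 2:
            kind = "thick" if width >= thick_cutoff else "thin"
            walker_branch[wid] = Branch(points=np.array(pts), width=width, kind=kind)
            walker_points[wid] = np.array(pts)
            walker_children.setdefault(wid, [])
            if parent >= 0:
                walker_children.setdefault(parent, []).append(wid)
                start_junction[wid] = pts[0]
            queue.extend(pending)
        else:
            fuse_junction.pop(wid, None)
            log.append({"event": "cancel", "walker": wid})
            for rec in pending:
                log.append({"event": "cancel", "walker": rec[0]})

    if not walker_branch:
        raise EmptyNetworkError("growth produced no branches; relax parameters")

    # Drop stub branches (< min_branch_length) unless they carry surviving
    # children; children always have larger ids, so one descending pass works.
    kept_ids: set[int] = set()
    for wid in sorted(walker_branch, reverse=True):
        b = walker_branch[wid]
        has_kept_child = any(c in kept_ids for c in walker_children.get(wid, ()))
        if b.arc_length >= params.min_branch_length or has_kept_child:
            kept_ids.add(wid)
        else:
            log.append({"event": "drop", "walker": wid})

    branches = [walker_branch[w] for w in sorted(kept_ids)]
    junc: list[np.ndarray] = []
    for w, pt in start_junction.items():
        if w in kept_ids:
            junc.append(pt)
    for w, (pt, tgt) in fuse_junction.items():
        if w in kept_ids and tgt in kept_ids:
            junc.append(pt)
    total = float(sum(b.arc_length for b in branches))
    return NetworkTruth(
        branches=branches,
        junctions=np.array(junc).reshape(-1, 2),
        total_length=total,
        event_log=log,
    )


def _stroke_mask(shape: tuple[int, int], poly: np.ndarray, width: float) -> np.ndarray:
    """Pixels whose centers lie within (width-1)/2 of the polyline.

    The (width-1)/2 half-width makes a horizontal stroke of nominal width w
    cover exactly 2*floor((w-1)/2)+1 rows, i.e. w rows for odd integer w, with
    round end caps from the point-to-segment distance. The half-width is
    floored at 0.5 px so even hairline strokes stay 8-connected on diagonals.
    """
    half = max(0.5, (width - 1.0) / 2.0)
    nr, nc = shape
    out = np.zeros(shape, dtype=bool)
    pad = half + 1.5
    for a, b in zip(poly[:-1], poly[1:]):
        lo_r = int(max(0, math.floor(min(a[0], b[0]) - pad)))
        hi_r = int(min(nr - 1, math.ceil(max(a[0], b[0]) + pad)))
        lo_c = int(max(0, math.floor(min(a[1], b[1]) - pad)))
        hi_c = int(min(nc - 1, math.ceil(max(a[1], b[1]) + pad)))
        if hi_r < lo_r or hi_c < lo_c:
            continue
        rr, cc = np.mgrid[lo_r : hi_r + 1, lo_c : hi_c + 1]
        d = b - a
        l2 = float(d @ d)
        pr, pc = rr - a[0], cc - a[1]
        if l2 == 0.0:
            dist2 = pr**2 + pc**2
        else:
            t = np.clip((pr * d[0] + pc * d[1]) / l2, 0.0, 1.0)
            dist2 = (pr - t * d[0]) ** 2 + (pc - t * d[1]) ** 2
        out[lo_r : hi_r + 1, lo_c : hi_c + 1] |= dist2 <= half * half + 1e-12
    return out


def rasterize(
    network: NetworkTruth,
    geometry: ChipGeometry = ChipGeometry(),
    foreground: float = 3000.0,
    background: float = 300.0,
    bit_depth: int = 16,
) -> tuple[ChipImage, np.ndarray]:
    """Draw the network as an intensity image plus a pixel-exact label grid.

    Thin branches are painted first and thick branches second, so thick wins
    ties at overlaps. ``network.thick_area``/``thin_area`` are set from the
    resulting grid. Polyline parts outside the frame are clipped with a
    warning.

    Returns
    -------
    (ChipImage, labels) where labels is a uint8 grid in {0, 1, 2}.
    """
    vmax = 2**bit_depth - 1
    if not (0 <= background <= vmax and 0 <= foreground <= vmax):
        raise ParameterError("intensities must lie within the bit depth")
    nr, nc = geometry.shape
    labels = np.zeros(geometry.shape, dtype=np.uint8)
    clipped = False
    for kind, value in (("thin", THIN), ("thick", THICK)):
        for b in network.branches:
            if b.kind != kind:
                continue
            if (b.points[:, 0].min() < 0 or b.points[:, 0].max() > nr - 1
                    or b.points[:, 1].min() < 0 or b.points[:, 1].max() > nc - 1):
                clipped = True
            labels[_stroke_mask(geometry.shape, b.points, b.width)] = value
    if clipped:
        warnings.warn("polyline extends outside the frame; stroke clipped", stacklevel=2)
    network.thick_area = int((labels == THICK).sum())
    network.thin_area = int((labels == THIN).sum())
    img = np.where(labels != BACKGROUND, foreground, background).astype(np.float64)
    return (
        ChipImage(data=img, bit_depth=bit_depth, geometry=geometry),
        labels,
    )


@dataclass(frozen=True)
class CorruptionParams:
    """Imaging imperfections layered onto a clean rasterization.

    background_field
        ``None``, ``("planar", a, b, c)`` for a + b*(row/nr) + c*(col/nc), or
        ``("blobs", n, amplitude, sigma)`` for n Gaussian bumps.
    noise_sigma
        Std of additive Gaussian read noise (intensity units).
    n_specks / speck_size
        Number and pixel-size range of small bright debris blobs placed off
        the vessels (sub-threshold artifacts the cleanup step must remove).
    """

    background_field: Optional[tuple] = ("planar", 0.0, 400.0, 250.0)
    noise_sigma: float = 30.0
    n_specks: int = 10
    speck_size: tuple[int, int] = (3, 8)
    speck_intensity: float = 2500.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise sigma must be >= 0")
        if self.n_specks < 0:
            raise ParameterError("speck count must be >= 0")


def _grow_blob(rng: np.random.Generator, size: int) -> np.ndarray:
    """Random 4-connected blob of exactly ``size`` pixels, offsets from (0,0)."""
    cells = {(0, 0)}
    frontier = [(0, 0)]
    moves = ((1, 0), (-1, 0), (0, 1), (0, -1))
    while len(cells) < size:
        r, c = frontier[rng.integers(len(frontier))]
        dr, dc = moves[rng.integers(4)]
        nxt = (r + dr, c + dc)
        if nxt not in cells:
            cells.add(nxt)
            frontier.append(nxt)
    return np.array(sorted(cells))


def corrupt(
    image: ChipImage,
    params: CorruptionParams = CorruptionParams(),
    seed: Optional[int] = None,
    clip: bool = True,
) -> ChipImage:
    """Add a slowly varying background field, read noise and speck artifacts.

    Deterministic given ``seed``. Specks are rejection-placed so they touch
    neither the vessels nor each other (each one is a distinct off-vessel
    connected component, which the postprocessing stage is expected to drop).
    """
    if seed is None:
        raise ParameterError("seed must be set explicitly")
    rng = np.random.default_rng(seed)
    nr, nc = image.shape
    out = image.data.astype(np.float64).copy()

    bf = params.background_field
    if bf is not None:
        kind = bf[0]
        rr, cc = np.mgrid[0:nr, 0:nc]
        if kind == "planar":
            _, a, b, c = bf
            out += a + b * (rr / nr) + c * (cc / nc)
        elif kind == "blobs":
            _, n, amp, sig = bf
            for _ in range(int(n)):
                r0, c0 = rng.uniform(0, nr), rng.uniform(0, nc)
                out += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sig**2))
        else:
            raise ParameterError(f"unknown background field kind: {kind!r}")

    if params.noise_sigma > 0:
        out += rng.normal(0.0, params.noise_sigma, size=out.shape)

    if params.n_specks > 0:
        bg_level = np.median(image.data)
        vessel = image.data > bg_level  # clean raster: vessels are bright
        forbidden = ndimage.binary_dilation(vessel, iterations=6)
        placed = 0
        attempts = 0
        while placed < params.n_specks and attempts < 10_000:
            attempts += 1
            size = int(rng.integers(params.speck_size[0], params.speck_size[1] + 1))
            blob = _grow_blob(rng, size)
            r0 = int(rng.integers(8, nr - 8))
            c0 = int(rng.integers(8, nc - 8))
            pix = blob + (r0, c0)
            if (pix < 0).any() or (pix[:, 0] >= nr).any() or (pix[:, 1] >= nc).any():
                continue
            if forbidden[pix[:, 0], pix[:, 1]].any():
                continue
            out[pix[:, 0], pix[:, 1]] += params.speck_intensity
            # keep later specks clear of this one
            blk = np.zeros((nr, nc), dtype=bool)
            blk[pix[:, 0], pix[:, 1]] = True
            forbidden |= ndimage.binary_dilation(blk, iterations=4)
            placed += 1
        if placed < params.n_specks:
            warnings.warn(
                f"placed only {placed}/{params.n_specks} specks", stacklevel=2
            )

    if clip:
        out = np.clip(out, 0.0, 2**image.bit_depth - 1)
        return image.with_data(out)
    res = image.with_data(np.zeros_like(out))
    res.data = out  # bypass range validation when caller wants pre-clip values
    return res
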