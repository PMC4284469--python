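"""Agent-based 2D plate simulator of gliding filaments and spiral formation.

Filaments are polyline agents gliding back and forth on an agar surface.
Motion follows three rules distilled from plate observations:

* a previously laid sheath trail guides movement — repeated passes retrace
  the same path;
* on virgin substrate the helical mucilage flow that rotates the filament
  about its axis slides it laterally, curving the path counterclockwise at
  rate ``kappa`` (rad/um).  The slide side is fixed in the filament's body
  frame, so both ends curve the same way on the plate whichever one leads;
* an encounter with another filament (or a foreign trail) deflects the tip
  counterclockwise — a left turn — in fixed angular increments until the
  way is clear, or the filament stalls for the step.

Together with growth by cell division these rules let spirals emerge on
solid agar; on submerged substrates (below 1.1% agar) filaments leave the
surface and no spirals form.

Coordinates: right-handed plane viewed from above, angles
counterclockwise-positive.  Rasters are row-major, row 0 at the top
(maximum y), pixel centres at half-integer offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString

from . import kinetics
from .kinetics import KineticParams, instantaneous_speed

__all__ = [
    "SubstrateParams",
    "Filament",
    "SheathTrailStore",
    "PlateState",
    "Raster",
    "SpiralRecord",
    "agar_to_params",
    "make_filament",
    "make_plate",
    "step",
    "run_plate",
    "resolve_encounter",
    "grow",
    "detect_spirals",
    "rasterize",
    "radial_spread_stats",
]

SUBMERGED_BELOW_PERCENT = 1.1
DEFAULT_KAPPA = 0.002  # rad/um, counterclockwise
DEFAULT_WIDTH_UM = 5.0
ENCOUNTER_STEP_RAD = math.radians(5.0)
ENCOUNTER_MAX_RAD = math.radians(170.0)


@dataclass(frozen=True)
class SubstrateParams:
    """Agar-dependent parameters of the plate surface."""

    kinetics: KineticParams
    kappa: float  # lateral curvature rate, rad/um, >= 0 (counterclockwise)
    submerged: bool
    agar_percent: float

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


def agar_to_params(
    concentration: float,
    kappa: float = DEFAULT_KAPPA,
    period_min: float = 300.0,
    period_max: float = 600.0,
) -> SubstrateParams:
    """Substrate parameters for an agar concentration (% w/v, 0 < c <= 3).

    Kinetics interpolate between the measured 1.5% / 2.0% anchors; below
    1.1% agar filaments become submerged within the gel.
    """
    kin = kinetics.params_for_agar(concentration, period_min, period_max)
    return SubstrateParams(
        kinetics=kin,
        kappa=kappa,
        submerged=concentration < SUBMERGED_BELOW_PERCENT,
        agar_percent=float(concentration),
    )


@dataclass
class Filament:
    """Polyline agent.  Vertices are ordered; ``direction`` picks the leading
    end (+1: last vertex leads, -1: first vertex leads)."""

    vertices: np.ndarray  # (n, 2) um
    direction: int
    phase: float  # s since last reversal
    next_reversal: float  # absolute clock time, s
    params: KineticParams
    width: float = DEFAULT_WIDTH_UM
    fid: int = 0
    # current gliding direction; None right after a reversal.  Kept as state
    # so curvature integrates exactly instead of re-deriving a lagging chord
    # direction from the polyline each step.
    motion_heading: np.ndarray | None = None

    @property
    def length(self) -> float:
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def leading_tip(self) -> np.ndarray:
        return self.vertices[-1] if self.direction == 1 else self.vertices[0]

    def heading(self) -> np.ndarray:
        """Unit vector of motion at the leading end (points outward)."""
        if self.direction == 1:
            d = self.vertices[-1] - self.vertices[-2]
        else:
            d = self.vertices[0] - self.vertices[1]
        n = float(np.hypot(*d))
        if n == 0:
            raise ValueError("degenerate leading segment")
        return d / n


class SheathTrailStore:
    """Deposited sheath-trail points with tangents and a spatial index."""

    def __init__(self, radius: float):
        self.radius = float(radius)
        self._pts: list[np.ndarray] = []
        self._tangents: list[np.ndarray] = []
        self._owners: list[int] = []
        self._tree: cKDTree | None = None
        self._tree_size = 0

    def __len__(self) -> int:
        return len(self._pts)

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self._pts).reshape(-1, 2)

    @property
    def tangents(self) -> np.ndarray:
        return np.asarray(self._tangents).reshape(-1, 2)

    @property
    def owners(self) -> np.ndarray:
        return np.asarray(self._owners, dtype=int)

    def deposit(self, point, tangent, owner: int) -> None:
        self._pts.append(np.asarray(point, dtype=float))
        t = np.asarray(tangent, dtype=float)
        n = float(np.hypot(*t))
        self._tangents.append(t / n if n > 0 else t)
        self._owners.append(int(owner))

    def query(self, point, r: float) -> np.ndarray:
        """Indices of all deposited points within ``r`` of ``point``."""
        point = np.asarray(point, dtype=float)
        idx: list[int] = []
        # indexed portion
        if self._tree_size > 0:
            if self._tree is None:
                self._tree = cKDTree(np.asarray(self._pts[: self._tree_size]))
            idx.extend(self._tree.query_ball_point(point, r))
        # linear scan over the unindexed buffer
        for k in range(self._tree_size, len(self._pts)):
            if np.hypot(*(self._pts[k] - point)) <= r:
                idx.append(k)
        # fold the buffer into the tree once it grows
        if len(self._pts) - self._tree_size > 512:
            self._tree = None
            self._tree_size = len(self._pts)
        return np.asarray(sorted(idx), dtype=int)


@dataclass
class PlateState:
    """Full simulator state: filaments, trail store, substrate, clock, RNG."""

    filaments: list[Filament]
    trails: SheathTrailStore
    substrate: SubstrateParams
    clock: float
    rng: np.random.Generator
    seed: int | None = None
    segment_length: float = 2.0
    encounters_enabled: bool = True
    foreign_trails_block: bool = True  # False: foreign trails ignored (guide mode off)
    plate_radius: float | None = None


def make_filament(
    start,
    heading_rad: float,
    length: float,
    params: KineticParams,
    width: float = DEFAULT_WIDTH_UM,
    segment_length: float = 2.0,
    fid: int = 0,
    next_reversal: float = 0.0,
    direction: int = 1,
) -> Filament:
    """Straight filament whose head is at ``start`` pointing along ``heading_rad``."""
    n_seg = max(1, int(math.ceil(length / segment_length)))
    ss = np.linspace(-length, 0.0, n_seg + 1)
    u = np.array([math.cos(heading_rad), math.sin(heading_rad)])
    vertices = np.asarray(start, dtype=float) + ss[:, None] * u[None, :]
    return Filament(
        vertices=vertices,
        direction=direction,
        phase=0.0,
        next_reversal=next_reversal,
        params=params,
        width=width,
        fid=fid,
    )


def make_plate(scenario: dict, extra_kinetics: KineticParams | None = None) -> PlateState:
    """Build a PlateState from a scenario config dict (see io.validate_scenario)."""
    seed = scenario.get("seed")
    rng = np.random.default_rng(seed)
    substrate = agar_to_params(
        scenario["agar_percent"],
        kappa=scenario.get("kappa_per_um", DEFAULT_KAPPA),
        period_min=scenario.get("period_min_s", 300.0),
        period_max=scenario.get("period_max_s", 600.0),
    )
    kin = extra_kinetics or substrate.kinetics
    width = scenario.get("width_um", DEFAULT_WIDTH_UM)
    seg_len = scenario.get("segment_length_um", 2.0)
    trails = SheathTrailStore(radius=width / 2.0)
    filaments = []
    for k, f in enumerate(scenario["filaments"]):
        fil = make_filament(
            (f["x_um"], f["y_um"]),
            math.radians(f["heading_deg"]),
            f["length_um"],
            kin,
            width=width,
            segment_length=seg_len,
            fid=k,
            next_reversal=float(rng.uniform(kin.period_min, kin.period_max)),
        )
        filaments.append(fil)
        _deposit_along_polyline(trails, fil)
    return PlateState(
        filaments=filaments,
        trails=trails,
        substrate=substrate,
        clock=0.0,
        rng=rng,
        seed=seed,
        segment_length=seg_len,
        plate_radius=scenario.get("plate_radius_um"),
    )


def _deposit_along_polyline(trails: SheathTrailStore, fil: Filament) -> None:
    """Seed the trail store along a filament's initial body (its sheath)."""
    spacing = trails.radius / 2.0
    verts = fil.vertices
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    if total == 0:
        return
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    targets = np.arange(0.0, total + spacing / 2, spacing)
    for s in targets:
        i = min(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
        frac = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        p = verts[i] + frac * seg[i]
        tangent = seg[i] / seg_len[i] if seg_len[i] > 0 else np.array([1.0, 0.0])
        trails.deposit(p, tangent, fil.fid)


def _rotate(vec: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def _trail_guidance(
    state: PlateState, fil: Filament, tip: np.ndarray, heading: np.ndarray
) -> np.ndarray | None:
    """Heading dictated by the filament's own sheath trail ahead of the tip.

    Only trail points strictly ahead (positive projection on the heading)
    guide; the trail just laid behind a frontier tip must not suppress the
    virgin-substrate curvature.  The guided direction blends the stored
    tangent (sign-matched to the motion) with a pull toward the trail point,
    which keeps retraced paths locked within one deposit radius.
    """
    idx = state.trails.query(tip, state.trails.radius)
    if len(idx) == 0:
        return None
    pts = state.trails.points[idx]
    owners = state.trails.owners[idx]
    own = owners == fil.fid
    if not np.any(own):
        return None
    pts = pts[own]
    tg = state.trails.tangents[idx][own]
    rel = pts - tip
    ahead = rel @ heading > 1e-9
    if not np.any(ahead):
        return None
    rel, pts, tg = rel[ahead], pts[ahead], tg[ahead]
    dist = np.hypot(rel[:, 0], rel[:, 1])
    k = int(np.argmin(dist))
    tangent = tg[k] * (1.0 if float(tg[k] @ heading) >= 0 else -1.0)
    pull = rel[k] / state.trails.radius
    d = tangent + 0.5 * pull
    n = float(np.hypot(*d))
    return d / n if n > 0 else tangent


def _obstacle_geoms(state: PlateState, fil: Filament) -> list[LineString]:
    geoms = []
    for other in state.filaments:
        if other.fid == fil.fid:
            continue
        if len(other.vertices) >= 2:
            geoms.append(LineString(other.vertices))
    return geoms


def _step_blocked(
    state: PlateState,
    fil: Filament,
    tip: np.ndarray,
    direction: np.ndarray,
    advance: float,
    obstacles: list[LineString],
) -> bool:
    new_tip = tip + advance * direction
    if obstacles:
        seg = LineString([tip, new_tip])
        pad = fil.width / 2.0
        for g in obstacles:
            if seg.distance(g) < pad:
                return True
    if state.foreign_trails_block and len(state.trails) > 0:
        idx = state.trails.query(new_tip, state.trails.radius)
        if len(idx) and np.any(state.trails.owners[idx] != fil.fid):
            return True
    return False


def resolve_encounter(
    state: PlateState,
    fil: Filament,
    tip: np.ndarray,
    heading: np.ndarray,
    advance: float,
    obstacles: list[LineString] | None = None,
) -> tuple[np.ndarray | None, float]:
    """Left-turn rule at encounters.

    If the proposed step segment would hit another filament's body (or a
    foreign sheath trail in blocking mode), rotate the heading
    counterclockwise in fixed increments until the step is clear.  Returns
    (new heading, total turn rad); heading is None when no clear direction
    exists within the maximum turn — the filament stalls for this step.
    """
    if obstacles is None:
        obstacles = _obstacle_geoms(state, fil)
    if not _step_blocked(state, fil, tip, heading, advance, obstacles):
        return heading, 0.0
    turn = 0.0
    while turn < ENCOUNTER_MAX_RAD - 1e-12:
        turn += ENCOUNTER_STEP_RAD
        cand = _rotate(heading, turn)
        if not _step_blocked(state, fil, tip, cand, advance, obstacles):
            return cand, turn
    return None, turn


def _advance_polyline(fil: Filament, new_tip: np.ndarray, seg_len: float) -> None:
    """Move the leading tip to ``new_tip`` keeping arc length fixed.

    The leading vertex slides with the tip and is frozen into a new vertex
    once its segment reaches ``seg_len``; the trailing end is trimmed by the
    same arc length (the body follows the head along its own path).
    """
    L = fil.length
    V = fil.vertices
    if fil.direction == 1:
        if len(V) >= 2 and np.hypot(*(new_tip - V[-2])) > seg_len:
            V = np.vstack([V, new_tip])
        else:
            V = V.copy()
            V[-1] = new_tip
        fil.vertices = _trim_tail(V, L, tail_first=True)
    else:
        if len(V) >= 2 and np.hypot(*(new_tip - V[1])) > seg_len:
            V = np.vstack([new_tip, V])
        else:
            V = V.copy()
            V[0] = new_tip
        fil.vertices = _trim_tail(V, L, tail_first=False)


def _trim_tail(V: np.ndarray, target_len: float, tail_first: bool) -> np.ndarray:
    """Cut the trailing end of a polyline so its arc length equals target_len.

    ``tail_first``: the trailing end is V[0] (head is last); otherwise the
    trailing end is V[-1].
    """
    W = V[::-1] if tail_first else V  # W: head first, tail last
    seg = np.diff(W, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    if cum[-1] <= target_len:
        out = W
    else:
        i = int(np.searchsorted(cum, target_len, side="right") - 1)
        i = min(i, len(lens) - 1)
        frac = (target_len - cum[i]) / lens[i] if lens[i] > 0 else 0.0
        end_pt = W[i] + frac * seg[i]
        out = np.vstack([W[: i + 1], end_pt])
    return out[::-1] if tail_first else out


def step(state: PlateState, dt: float) -> PlateState:
    """Advance the plate by ``dt`` seconds (mutates and returns ``state``).

    Per filament: the speed comes from the decay law at the current phase;
    the leading tip follows its own trail when one lies ahead, otherwise it
    curves counterclockwise at rate kappa and deposits new trail; encounters
    deflect it left or stall it; scheduled reversals flip the leading end
    and reset the phase.  Requires speed*dt below the trail deposit radius
    so trail-following cannot skip over deposited points.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    vmax = max((f.params.v_max for f in state.filaments), default=0.0)
    if vmax * dt >= state.trails.radius:
        raise ValueError(
            f"unstable step: v_max*dt = {vmax * dt:.3g} um must stay below "
            f"the trail deposit radius {state.trails.radius:.3g} um"
        )
    kappa = state.substrate.kappa
    spacing = state.trails.radius / 2.0
    for fil in state.filaments:
        if state.clock >= fil.next_reversal:
            fil.direction *= -1
            fil.phase = 0.0
            fil.motion_heading = None
            fil.next_reversal = state.clock + float(
                state.rng.uniform(fil.params.period_min, fil.params.period_max)
            )
        speed = instantaneous_speed(fil.params, fil.phase)
        advance = speed * dt
        if advance > 0 and len(fil.vertices) >= 2:
            tip = fil.leading_tip().copy()
            geom_heading = fil.heading()
            if (
                fil.motion_heading is not None
                and float(fil.motion_heading @ geom_heading) > 0
            ):
                heading = fil.motion_heading
            else:
                heading = geom_heading
            guided_dir = _trail_guidance(state, fil, tip, heading)
            if guided_dir is not None:
                direction = guided_dir
                on_virgin = False
            else:
                # body-frame curvature: vertex-order curvature is +kappa,
                # so the motion-frame turn sign flips with the leading end
                direction = _rotate(heading, fil.direction * kappa * advance)
                on_virgin = True
            if state.encounters_enabled and len(state.filaments) > 1:
                obstacles = _obstacle_geoms(state, fil)
                direction, _ = resolve_encounter(
                    state, fil, tip, direction, advance, obstacles
                )
            if direction is not None:  # None -> stalled this step
                fil.motion_heading = direction
                new_tip = tip + advance * direction
                _advance_polyline(fil, new_tip, state.segment_length)
                if on_virgin:
                    idx = state.trails.query(new_tip, spacing)
                    own_near = len(idx) and np.any(
                        state.trails.owners[idx] == fil.fid
                    )
                    if not own_near:
                        state.trails.deposit(new_tip, direction, fil.fid)
        fil.phase += dt
    state.clock += dt
    return state


def grow(
    fil: Filament,
    dt: float,
    doubling_time: float,
    kappa: float = 0.0,
    state: PlateState | None = None,
    end_bias: float = 0.5,
    segment_length: float = 2.0,
) -> Filament:
    """Elongate a filament by cell division: length x 2^(dt/doubling_time).

    New arc length is appended at both ends (fraction ``end_bias`` at the
    head-side end).  Each extension follows an existing sheath trail when
    one lies ahead of that end, else continues the end tangent with
    body-frame curvature ``kappa`` — the same rules that govern motion.
    Mutates and returns ``fil``.
    """
    if not doubling_time > 0:
        raise ValueError("doubling_time must be > 0")
    if dt == 0:
        return fil
    L0 = fil.length
    dL = L0 * (2.0 ** (dt / doubling_time) - 1.0)
    _extend_end(fil, dL * end_bias, head_end=True, kappa=kappa, state=state,
                segment_length=segment_length)
    _extend_end(fil, dL * (1.0 - end_bias), head_end=False, kappa=kappa,
                state=state, segment_length=segment_length)
    return fil


def _extend_end(
    fil: Filament,
    dL: float,
    head_end: bool,
    kappa: float,
    state: PlateState | None,
    segment_length: float,
) -> None:
    if dL <= 0:
        return
    V = fil.vertices
    if head_end:
        tip, neighbor = V[-1], V[-2]
    else:
        tip, neighbor = V[0], V[1]
    d = tip - neighbor
    n = float(np.hypot(*d))
    u = d / n if n > 0 else np.array([1.0, 0.0])
    # vertex-order curvature +kappa: walking outward from the head turns
    # +kappa, walking outward from the tail turns -kappa
    sign = 1.0 if head_end else -1.0
    new_pts = []
    pos = tip.copy()
    remaining = dL
    while remaining > 1e-12:
        ds = min(segment_length, remaining)
        guided = None
        if state is not None:
            guided = _trail_guidance(state, fil, pos, u)
        if guided is not None:
            u = guided
        else:
            u = _rotate(u, sign * kappa * ds)
        pos = pos + ds * u
        new_pts.append(pos.copy())
        if state is not None:
            idx = state.trails.query(pos, state.trails.radius / 2.0)
            if not (len(idx) and np.any(state.trails.owners[idx] == fil.fid)):
                state.trails.deposit(pos, u, fil.fid)
        remaining -= ds
    block = np.asarray(new_pts)
    fil.vertices = np.vstack([V, block]) if head_end else np.vstack([block[::-1], V])


@dataclass
class SpiralRecord:
    fid: int
    winding_rad: float
    is_spiral: bool


def winding_angle(vertices: np.ndarray) -> float:
    """Total signed turning (rad) along a polyline, counterclockwise positive."""
    seg = np.diff(np.asarray(vertices, dtype=float), axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    seg = seg[lens > 1e-12]
    if len(seg) < 2:
        return 0.0
    ang = np.arctan2(seg[:, 1], seg[:, 0])
    turns = np.diff(ang)
    turns = (turns + np.pi) % (2.0 * np.pi) - np.pi
    return float(turns.sum())


def detect_spirals(
    state: PlateState,
    min_turns: float = 2.0,
    compactness: float = 0.5,
) -> list[SpiralRecord]:
    """Classify filaments as spirals by winding and compactness.

    A filament is a spiral when |total turning| >= 2*pi*min_turns and its
    minimum bounding circle diameter is below ``compactness`` times its arc
    length.  On submerged substrates spiral classification is disabled
    (filaments leave the surface) and an empty list is returned.
    """
    if state.substrate.submerged:
        return []
    out = []
    for fil in state.filaments:
        if len(fil.vertices) < 3:
            continue
        w = winding_angle(fil.vertices)
        diam = 2.0 * shapely.minimum_bounding_radius(LineString(fil.vertices))
        is_spiral = abs(w) >= 2.0 * math.pi * min_turns and diam < compactness * fil.length
        out.append(SpiralRecord(fid=fil.fid, winding_rad=w, is_spiral=is_spiral))
    return out


@dataclass
class Raster:
    """Binary raster with world-coordinate mapping.

    ``pixels[r, c]`` covers the pixel whose centre is at
    (x_min + (c + 0.5) * pixel_size, y_max - (r + 0.5) * pixel_size).
    """

    pixels: np.ndarray  # bool, row-major, row 0 at top (max y)
    pixel_size: float  # um
    x_min: float
    y_max: float

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.pixels.shape
        xs = self.x_min + (np.arange(cols) + 0.5) * self.pixel_size
        ys = self.y_max - (np.arange(rows) + 0.5) * self.pixel_size
        return xs, ys


def rasterize(
    state: PlateState,
    pixel_size: float,
    bounds: tuple[float, float, float, float] | None = None,
) -> Raster:
    """Binary raster of the plate: pixels within width/2 of any filament.

    ``bounds`` is (x_min, y_min, x_max, y_max) in um; by default the
    filament bounding box padded by one filament width (or the plate disc if
    a plate radius is set and smaller).  Deterministic for a fixed state.
    """
    if not pixel_size > 0:
        raise ValueError("pixel size must be > 0")
    geoms = [
        LineString(f.vertices).buffer(f.width / 2.0)
        for f in state.filaments
        if len(f.vertices) >= 2
    ]
    if bounds is None:
        if geoms:
            allb = np.array([g.bounds for g in geoms])
            pad = max(f.width for f in state.filaments)
            bounds = (
                allb[:, 0].min() - pad,
                allb[:, 1].min() - pad,
                allb[:, 2].max() + pad,
                allb[:, 3].max() + pad,
            )
        else:
            r = state.plate_radius or 100.0
            bounds = (-r, -r, r, r)
    x_min, y_min, x_max, y_max = bounds
    n_cols = max(1, int(math.ceil((x_max - x_min) / pixel_size)))
    n_rows = max(1, int(math.ceil((y_max - y_min) / pixel_size)))
    y_top = y_min + n_rows * pixel_size
    pixels = np.zeros((n_rows, n_cols), dtype=bool)
    if geoms:
        union = shapely.union_all(geoms)
        xs = x_min + (np.arange(n_cols) + 0.5) * pixel_size
        ys = y_top - (np.arange(n_rows) + 0.5) * pixel_size
        XX, YY = np.meshgrid(xs, ys)
        pixels = shapely.contains_xy(union, XX.ravel(), YY.ravel()).reshape(
            n_rows, n_cols
        )
    return Raster(pixels=pixels, pixel_size=pixel_size, x_min=x_min, y_max=y_top)


def radial_spread_stats(raster: Raster, origin) -> tuple[float, float]:
    """Mean and population SD (um) of foreground-pixel distances from origin.

    The plate-level spread statistic: distances of all filament pixels from
    the inoculation point; its mean and SD shrink with rising agar
    concentration as movement is restricted.
    """
    rows, cols = np.nonzero(raster.pixels)
    if len(rows) == 0:
        raise ValueError("empty mask: no foreground pixels")
    ox, oy = float(origin[0]), float(origin[1])
    xs = raster.x_min + (cols + 0.5) * raster.pixel_size
    ys = raster.y_max - (rows + 0.5) * raster.pixel_size
    d = np.hypot(xs - ox, ys - oy)
    return float(d.mean()), float(d.std(ddof=0))


def desk_scale_state(
    agar_percent: float = 1.5,
    seed: int | None = 0,
    kappa: float = 0.02,
    initial_length: float = 60.0,
    encounters_enabled: bool = False,
) -> PlateState:
    """Single-filament plate at desk scale for spiral-emergence runs.

    Desk scale shrinks the spatial scale of a plate experiment about
    tenfold (so kappa rises from 0.002 to 0.02 rad/um) and compresses the
    two-week growth of a plug culture into hours via a short doubling time;
    the kinetic parameters are the unmodified anchor values for the given
    agar concentration.  Run with ``run_plate(state, 5*3600, 5.0,
    doubling_time=3600)``.
    """
    substrate = agar_to_params(agar_percent, kappa=kappa)
    rng = np.random.default_rng(seed)
    fil = make_filament(
        (0.0, 0.0),
        float(rng.uniform(0.0, 2.0 * math.pi)),
        initial_length,
        substrate.kinetics,
        next_reversal=float(
            rng.uniform(substrate.kinetics.period_min, substrate.kinetics.period_max)
        ),
    )
    state = PlateState(
        filaments=[fil],
        trails=SheathTrailStore(radius=fil.width / 2.0),
        substrate=substrate,
        clock=0.0,
        rng=rng,
        seed=seed,
        encounters_enabled=encounters_enabled,
    )
    _deposit_along_polyline(state.trails, fil)
    return state


def run_plate(
    state: PlateState,
    duration: float,
    dt: float,
    doubling_time: float | None = None,
) -> PlateState:
    """Run ``step`` (and growth, if a doubling time is given) for ``duration`` s."""
    n_steps = int(round(duration / dt))
    kappa = state.substrate.kappa
    for _ in range(n_steps):
        step(state, dt)
        if doubling_time is not None:
            for fil in state.filaments:
                grow(
                    fil,
                    dt,
                    doubling_time,
                    kappa=kappa,
                    state=state,
                    segment_length=state.segment_length,
                )
    return state
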