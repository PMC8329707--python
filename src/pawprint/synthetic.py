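"""Synthetic open-field cohorts with planted group differences.

The generator emulates two-group cohorts of short open-field clips of a
single small animal (a rat pup), differing in exactly the contrasts the
analysis pipeline is meant to discover:

* **posture** — the initial spread between front and hind limbs, drawn
  per trial from a group-specific normal distribution;
* **stereotypy** — optional periodic "return" movements: every
  ``period_frames`` effective frames the body is pulled back toward the
  position and movement phase it had at the start of the cycle
  (``return_fidelity`` = 1 makes the trajectory exactly periodic);
* **activity** — the expected rate of grid-square entries.

Each trial yields a rendered grayscale frame stack (white ellipse body
with limb/nose/tail dots on black) and a matching keypoint track, with
the rendered body parts lying at the track coordinates.  Everything is
deterministic under the master seed; per-trial seeds come from a
counter scheme (master seed, group index, trial index) so enlarging a
cohort never reshuffles existing trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import OpenFieldGrid
from .video_io import FrameSequence

__all__ = [
    "GroupParams",
    "SynthConfig",
    "KeypointTrack",
    "SynthTrial",
    "PART_NAMES",
    "generate_cohort",
    "render_trial",
    "render_frames",
    "simulate_grid_walk",
    "write_cohort",
    "read_dlc_csv",
]

PART_NAMES = (
    "nose",
    "left_fore",
    "right_fore",
    "left_hind",
    "right_hind",
    "tail_base",
    "body_center",
)

FRONT_PAWS = ("left_fore", "right_fore")


@dataclass(frozen=True)
class GroupParams:
    """Planted behavioral parameters of one cohort group.

    ``limb_spread_px`` is the (mean, sd) of the frame-1 front–hind limb
    distance in pixels.  ``period_frames`` (effective frames) plants a
    repetitive return movement; ``return_fidelity`` in [0, 1] is the
    fraction of each cycle's displacement undone by the cycle's end (how
    reliably the body pose *returns*), while ``pattern_fidelity`` is the
    correlation of the movement pattern across cycles (how exactly the
    in-between movement *repeats*; default: equal to return_fidelity).
    ``locomotion_rate`` is the expected number of grid squares entered
    per second; ``start_latency_frames`` is how long the animal stays
    still before its first movement.
    """

    limb_spread_px: tuple[float, float] = (87.57, 10.0)
    period_frames: int | None = None
    return_fidelity: float = 0.0
    pattern_fidelity: float | None = None
    locomotion_rate: float = 0.95
    start_latency_frames: int = 0
    nose_osc_period: int = 8
    nose_osc_amp_px: float = 12.0

    def __post_init__(self) -> None:
        if self.period_frames is not None and self.period_frames < 2:
            raise ValueError("period_frames must be >= 2 when present")
        if not 0.0 <= self.return_fidelity <= 1.0:
            raise ValueError("return_fidelity must lie in [0, 1]")
        if self.pattern_fidelity is not None and not 0.0 <= self.pattern_fidelity <= 1.0:
            raise ValueError("pattern_fidelity must lie in [0, 1]")
        if self.locomotion_rate < 0:
            raise ValueError("locomotion_rate must be >= 0")
        if self.limb_spread_px[0] <= 0 or self.limb_spread_px[1] < 0:
            raise ValueError("limb_spread_px mean must be > 0 and sd >= 0")
        if self.start_latency_frames < 0:
            raise ValueError("start_latency_frames must be >= 0")


# Default study conditions: a control-like group (immediate movement, no
# stereotypy) vs. a treated-like group (larger limb spread = reduced
# postural support, delayed movement onset, hypoactivity, and an
# 11-frame repetitive return movement).
CONTROL_PARAMS = GroupParams(
    limb_spread_px=(87.57, 10.0),
    period_frames=None,
    return_fidelity=0.0,
    locomotion_rate=0.95,
    start_latency_frames=0,
)
TREATED_PARAMS = GroupParams(
    limb_spread_px=(96.2, 10.0),
    period_frames=11,
    return_fidelity=0.9,
    locomotion_rate=0.70,
    start_latency_frames=10,
)


def temporal_contrast_params(
    period_frames: int = 11,
    return_fidelity: float = 0.9,
    pattern_fidelity: float | None = None,
) -> tuple[GroupParams, GroupParams]:
    """Two groups differing *only* in planted periodicity.

    Posture, activity and latency are identical, so per-trial summary
    measures carry no group signal — the contrast lives purely in the
    temporal structure that only a sequence model can exploit: the
    stereotypic group repeats its movement cycle (pose and movement
    pattern) while the other wanders with the same step statistics.
    """
    base = replace(CONTROL_PARAMS)
    periodic = replace(
        CONTROL_PARAMS, period_frames=period_frames,
        return_fidelity=return_fidelity, pattern_fidelity=pattern_fidelity,
    )
    return base, periodic


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level configuration; identical seed gives a bit-identical cohort."""

    n_trials_per_group: int = 40
    arena_px: tuple[int, int] = (400, 350)  # (width, height)
    fps_raw: float = 30.0
    clip_seconds: float = 50.0
    subsample_step: int = 10
    group_params: tuple[GroupParams, GroupParams] = (CONTROL_PARAMS, TREATED_PARAMS)
    group_names: tuple[str, str] = ("control", "mpne")
    seed: int = 0
    pixel_noise_sd: float = 2.0  # grayscale units on the 0-255 scale
    keypoint_jitter_px: float = 0.5
    litter_size: int = 10
    box_cm: tuple[float, float] = (20.0, 30.0)

    def __post_init__(self) -> None:
        if self.n_trials_per_group < 1:
            raise ValueError("n_trials_per_group must be >= 1")
        if self.fps_raw <= 0 or self.clip_seconds <= 0:
            raise ValueError("fps_raw and clip_seconds must be positive")
        if self.subsample_step < 1:
            raise ValueError("subsample_step must be >= 1")
        # the arena image must be able to contain the agent body
        if self.px_per_cm * min(self.box_cm) < 120:
            raise ValueError(
                f"arena {self.arena_px} px is too small to contain the agent"
            )

    @property
    def n_frames(self) -> int:
        """Effective (analysis-rate) frames per clip."""
        return int(round(self.clip_seconds * self.fps_raw / self.subsample_step))

    @property
    def fps_effective(self) -> float:
        return self.fps_raw / self.subsample_step

    @property
    def px_per_cm(self) -> float:
        w, h = self.arena_px
        bw, bh = self.box_cm
        return min((w - 8) / bw, (h - 8) / bh)

    @property
    def box_origin_px(self) -> tuple[float, float]:
        """Pixel position of the arena box's (0, 0) cm corner (box centered)."""
        w, h = self.arena_px
        bw, bh = self.box_cm
        return ((w - bw * self.px_per_cm) / 2.0, (h - bh * self.px_per_cm) / 2.0)


@dataclass
class KeypointTrack:
    """Named body-part coordinate time series (pixels)."""

    coords: np.ndarray  # (n_frames, n_parts, 2)
    likelihood: np.ndarray  # (n_frames, n_parts)
    fps: float
    part_names: tuple[str, ...] = PART_NAMES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.likelihood = np.asarray(self.likelihood, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n_frames, n_parts, 2)")
        if self.coords.shape[1] != len(self.part_names):
            raise ValueError("coords part axis must match part_names")
        if self.likelihood.shape != self.coords.shape[:2]:
            raise ValueError("likelihood must have shape (n_frames, n_parts)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if np.any((self.likelihood < 0) | (self.likelihood > 1)):
            raise ValueError("likelihood must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def part(self, name: str) -> np.ndarray:
        return self.coords[:, self.part_names.index(name), :]

    def part_likelihood(self, name: str) -> np.ndarray:
        return self.likelihood[:, self.part_names.index(name)]

    def to_dlc_dataframe(self, scorer: str = "pawprint") -> pd.DataFrame:
        """DeepLabCut-dialect table: (scorer, bodypart, coord) column header."""
        cols = pd.MultiIndex.from_tuples(
            [
                (scorer, part, coord)
                for part in self.part_names
                for coord in ("x", "y", "likelihood")
            ],
            names=["scorer", "bodyparts", "coords"],
        )
        data = np.empty((self.n_frames, len(self.part_names) * 3))
        for j in range(len(self.part_names)):
            data[:, 3 * j] = self.coords[:, j, 0]
            data[:, 3 * j + 1] = self.coords[:, j, 1]
            data[:, 3 * j + 2] = self.likelihood[:, j]
        return pd.DataFrame(data, columns=cols)

    def to_dlc_csv(self, path, scorer: str = "pawprint") -> None:
        self.to_dlc_dataframe(scorer).to_csv(path, index=True, index_label=None)

    def to_dlc_hdf(self, path, scorer: str = "pawprint", key: str = "df_with_missing") -> None:
        self.to_dlc_dataframe(scorer).to_hdf(path, key=key, mode="w")


def read_dlc_csv(path, fps: float = 3.0) -> KeypointTrack:
    """Read a DeepLabCut-dialect CSV (scorer/bodyparts/coords header rows)."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    parts = list(dict.fromkeys(df.columns.get_level_values(1)))
    T = len(df)
    coords = np.empty((T, len(parts), 2))
    lik = np.ones((T, len(parts)))
    scorer = df.columns.get_level_values(0)[0]
    for j, part in enumerate(parts):
        coords[:, j, 0] = df[(scorer, part, "x")].to_numpy()
        coords[:, j, 1] = df[(scorer, part, "y")].to_numpy()
        if (scorer, part, "likelihood") in df.columns:
            lik[:, j] = df[(scorer, part, "likelihood")].to_numpy()
    return KeypointTrack(coords=coords, likelihood=lik, fps=fps, part_names=tuple(parts))


@dataclass
class SynthTrial:
    """One generated trial: identity, planted parameters and keypoint track."""

    trial_id: str
    animal_id: str
    litter_id: str
    group: str
    params: GroupParams
    track: KeypointTrack
    config: SynthConfig
    seed_key: tuple[int, int, int]
    frames: FrameSequence | None = None

    def render(self) -> FrameSequence:
        """Render (and cache) the grayscale frame stack for this trial."""
        if self.frames is None:
            rng = np.random.default_rng(
                np.random.SeedSequence(list(self.seed_key) + [1])
            )
            self.frames = render_frames(
                self.track,
                arena_px=self.config.arena_px,
                pixel_noise_sd=self.config.pixel_noise_sd,
                rng=rng,
                fps_effective=self.config.fps_effective,
            )
        return self.frames

    def front_paws_cm(self) -> tuple[np.ndarray, np.ndarray]:
        """Front-paw tracks converted to arena-cm coordinates for grid scoring."""
        ox, oy = self.config.box_origin_px
        s = self.config.px_per_cm
        bw, bh = self.config.box_cm
        out = []
        for name in FRONT_PAWS:
            p = (self.track.part(name) - np.array([ox, oy])) / s
            out.append(np.clip(p, 0.0, [bw, bh]))
        return out[0], out[1]


# ---------------------------------------------------------------------------
# trajectory model
# ---------------------------------------------------------------------------


def _body_geometry(limb_spread: float) -> dict:
    """Body-frame part offsets whose frame-1 limb spread equals ``limb_spread``.

    With paw half-width ``w`` equal for fore and hind pairs and the
    fore/hind paws at +/- L/2 along the body axis, the mean of the four
    fore x hind pair distances is (L + sqrt(L^2 + 4 w^2)) / 2; solving
    for L gives L = S - w^2 / S for a target mean S.
    """
    w = 10.0
    S = float(limb_spread)
    L = S - w * w / S
    half = L / 2.0
    return {
        "paw_halfwidth": w,
        "axis_half": half,
        "nose_len": half + 14.0,
        "tail_len": half + 10.0,
        "body_a": half + 6.0,  # ellipse semi-axis along heading
        "body_b": 16.0,
    }


def _parts_from_state(pos, heading, nose_side, geom) -> np.ndarray:
    """(n_parts, 2) pixel coordinates from body position/heading state."""
    u = np.array([np.cos(heading), np.sin(heading)])
    v = np.array([-np.sin(heading), np.cos(heading)])  # left-hand perpendicular
    h, w = geom["axis_half"], geom["paw_halfwidth"]
    parts = {
        "nose": pos + geom["nose_len"] * u + nose_side * v,
        "left_fore": pos + h * u + w * v,
        "right_fore": pos + h * u - w * v,
        "left_hind": pos - h * u + w * v,
        "right_hind": pos - h * u - w * v,
        "tail_base": pos - geom["tail_len"] * u,
        "body_center": pos,
    }
    return np.stack([parts[name] for name in PART_NAMES])


def _simulate_track(
    params: GroupParams,
    config: SynthConfig,
    n_frames: int,
    rng: np.random.Generator,
) -> KeypointTrack:
    """Simulate the keypoint track of one trial at the effective frame rate.

    The body follows a bounded persistent random walk; the nose makes
    lateral oscillations about the body axis.  For a periodic group the
    per-frame motion increments of cycle *k* are a ``return_fidelity``-
    weighted blend of a fixed base cycle and fresh randomness, and the
    cycle-start position is pulled back toward the trial's start
    position by the same weight — fidelity 1 therefore replays the base
    cycle exactly, making the whole track periodic.
    """
    px_per_cm = config.px_per_cm
    ox, oy = config.box_origin_px
    bw, bh = config.box_cm
    geom = _body_geometry(rng.normal(*params.limb_spread_px))

    # keep the whole body inside the arena image
    margin_px = geom["nose_len"] + 6.0
    lo = np.array([ox + margin_px, oy + margin_px])
    hi = np.array([ox + bw * px_per_cm - margin_px, oy + bh * px_per_cm - margin_px])

    # Mean-reverting wander around the placement point (infant warm-up
    # movements happen largely in place).  The per-frame displacement sd
    # is calibrated so the expected grid-square crossing rate of a paw
    # matches locomotion_rate: crossings/frame over a 2 cm grid in each
    # axis ~ E|dx| / 2 cm summed over axes, with E|dx| = sd sqrt(2/pi).
    sd_cm = (params.locomotion_rate / config.fps_effective) / np.sqrt(2.0 / np.pi)
    sd_px = sd_cm * px_per_cm
    # Persistence of the positional/heading wander.  Chosen so the
    # stationary spread, sd/sqrt(1 - rho^2) ~ 1.58 sd, matches the peak
    # excursion spread of an 11-frame closed movement cycle
    # (sqrt(j (1 - j/(P-1))) sd ~ 1.58 sd at mid-cycle): planted and
    # unplanted animals then occupy comparably sized patches of the
    # arena and differ in movement *timing*, not range.
    rho = 0.775

    start = (lo + hi) / 2.0
    heading0 = rng.uniform(0, 2 * np.pi)
    lat = params.start_latency_frames
    P = params.period_frames
    r = params.return_fidelity

    n_moving = max(n_frames - lat, 0)
    turn_sd = 0.3  # radians per effective frame

    # one lateral swing per stereotypy cycle when a period is planted
    # (completing on the cycle's last frame), otherwise the free
    # lateral-movement rhythm
    osc_mu = 2 * np.pi / (P - 1 if P is not None else params.nose_osc_period)

    def draw_increments(n, rng_):
        # dphi: zero-mean drift of the lateral nose-oscillation phase, so
        # an unplanted animal's lateral movements are not strictly periodic
        return {
            "turn": rng_.normal(0.0, turn_sd, size=n),
            "eta": rng_.normal(0.0, sd_px, size=(n, 2)),
            "dphi": rng_.normal(0.0, 0.3, size=n),
            "jitter": rng_.normal(0.0, config.keypoint_jitter_px, size=(n, len(PART_NAMES), 2)),
        }

    if P is not None and n_moving > 0:
        # Cycle k's increments are a correlation-r blend of a fixed base
        # cycle and fresh randomness; the sqrt weight keeps the marginal
        # step variance identical to an unplanted animal's.  Each cycle
        # is closed before blending: an undo of fraction r of its net
        # displacement (and heading/phase drift) is spread smoothly over
        # the first P-1 steps, so the body is back at its cycle-start
        # state ON the cycle's last frame and holds through the cycle
        # boundary (no teleporting).  At fidelity 1 the poses at frames
        # 0, P-1, P, 2P-1, ... therefore coincide exactly.
        # The bridge correction and the pause step shrink the mean step
        # magnitude; kappa rescales so a periodic animal still delivers
        # its nominal locomotion_rate (expected square entries / s).
        shrink = np.sqrt(max(1.0 - (2 * r - r * r) / (P - 1), 0.0))
        kappa = P / ((P - 1) * shrink + (1.0 - r)) if P > 1 else 1.0

        def close_cycle(inc):
            for key in ("eta", "turn", "dphi"):
                v = inc[key]
                v[: P - 1] -= r * v[: P - 1].sum(axis=0) / (P - 1)
                v[P - 1] *= 1.0 - r  # pause step between cycles
                if key in ("eta", "turn"):
                    v *= kappa
            return inc

        base = close_cycle(draw_increments(P, np.random.default_rng(rng.integers(2**31))))
        r_pat = params.pattern_fidelity if params.pattern_fidelity is not None else r
        w = np.sqrt(max(1.0 - r_pat * r_pat, 0.0))
        n_cycles = -(-n_moving // P)
        turn = np.empty(n_moving)
        eta = np.empty((n_moving, 2))
        dphi = np.empty(n_moving)
        jitter_mv = np.empty((n_moving, len(PART_NAMES), 2))
        for k in range(n_cycles):
            fresh = close_cycle(
                draw_increments(P, np.random.default_rng(rng.integers(2**31)))
            )
            s = slice(k * P, min((k + 1) * P, n_moving))
            m = s.stop - s.start
            turn[s] = r_pat * base["turn"][:m] + w * fresh["turn"][:m]
            eta[s] = r_pat * base["eta"][:m] + w * fresh["eta"][:m]
            dphi[s] = r_pat * base["dphi"][:m] + w * fresh["dphi"][:m]
            jitter_mv[s] = r_pat * base["jitter"][:m] + w * fresh["jitter"][:m]
    else:
        inc = draw_increments(n_moving, rng)
        turn, eta, dphi, jitter_mv = inc["turn"], inc["eta"], inc["dphi"], inc["jitter"]

    # latency-phase jitter (the animal is still but observation noise remains)
    jitter_lat = rng.normal(
        0.0, config.keypoint_jitter_px, size=(lat, len(PART_NAMES), 2)
    )
    if P is not None and lat > 0 and r > 0:
        # blend toward the first base jitter values so fidelity-1 tracks
        # are exactly constant during latency
        r_j = params.pattern_fidelity if params.pattern_fidelity is not None else r
        w_lat = np.sqrt(max(1.0 - r_j * r_j, 0.0))
        jitter_lat = w_lat * jitter_lat + r_j * base["jitter"][:1] if n_moving > 0 else jitter_lat * w_lat

    coords = np.empty((n_frames, len(PART_NAMES), 2))
    pos, heading, osc_angle = start.copy(), heading0, 0.0

    for t in range(n_frames):
        if t < lat:
            parts = _parts_from_state(pos, heading, 0.0, geom)
            coords[t] = parts + (jitter_lat[t] if lat else 0.0)
            continue
        tm = t - lat  # moving-phase index
        osc = params.nose_osc_amp_px * np.sin(osc_angle)
        parts = _parts_from_state(pos, heading, osc, geom)
        coords[t] = parts + jitter_mv[tm]
        # advance
        pause = P is not None and tm % P == P - 1
        osc_angle = osc_angle + (0.0 if pause else osc_mu) + dphi[tm]
        if P is not None:
            # the cycle-closed increments already carry the body (and
            # heading) back by each cycle's last frame
            heading = heading + turn[tm]
            nxt = pos + eta[tm]
        else:
            # mean-reverting wander around the placement point and
            # placement orientation
            heading = heading0 + rho * (heading - heading0) + turn[tm]
            nxt = start + rho * (pos - start) + eta[tm]
        pos = np.clip(nxt, lo, hi)

    likelihood = np.full((n_frames, len(PART_NAMES)), 0.99)
    return KeypointTrack(
        coords=coords, likelihood=likelihood, fps=config.fps_effective
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_frames(
    track: KeypointTrack,
    arena_px: tuple[int, int] = (400, 350),
    pixel_noise_sd: float = 2.0,
    rng: np.random.Generator | None = None,
    fps_effective: float = 3.0,
) -> FrameSequence:
    """Render grayscale frames with the body parts at the track coordinates.

    The body is a filled ellipse at the body-center coordinate oriented
    along the body-center → nose axis; the nose and four limbs are small
    bright disks at their track coordinates.
    """
    from skimage.draw import disk, ellipse

    if rng is None:
        rng = np.random.default_rng(0)
    W, H = arena_px
    T = track.n_frames
    frames = np.zeros((T, H, W), dtype=np.uint8)
    nose_i = track.part_names.index("nose")
    center_i = track.part_names.index("body_center")
    tail_i = track.part_names.index("tail_base")
    fore = [track.part_names.index(n) for n in ("left_fore", "right_fore")]
    hind = [track.part_names.index(n) for n in ("left_hind", "right_hind")]
    body_len = np.linalg.norm(
        track.coords[0, fore[0]] - track.coords[0, hind[0]]
    )
    a = body_len / 2 + 6.0
    for t in range(T):
        img = frames[t]
        cx, cy = track.coords[t, center_i]
        nx, ny = track.coords[t, nose_i]
        tx, ty = track.coords[t, tail_i]
        rot = np.arctan2(ny - ty, nx - tx)
        # skimage's ellipse rotation is counter-clockwise in (row, col)
        rr, cc = ellipse(cy, cx, 16.0, a, shape=img.shape, rotation=-rot)
        img[rr, cc] = 200
        for j, val in [(nose_i, 255), (fore[0], 255), (fore[1], 255),
                       (hind[0], 255), (hind[1], 255)]:
            x, y = track.coords[t, j]
            rr, cc = disk((y, x), 2.5, shape=img.shape)
            img[rr, cc] = val
    if pixel_noise_sd > 0:
        noise = rng.normal(0.0, pixel_noise_sd, size=frames.shape)
        frames = np.clip(frames.astype(np.float64) + noise, 0, 255).astype(np.uint8)
    return FrameSequence(frames=frames, fps_effective=fps_effective)


def render_trial(
    params: GroupParams,
    arena_px: tuple[int, int] = (400, 350),
    n_frames: int = 150,
    seed: int = 0,
    config: SynthConfig | None = None,
) -> tuple[FrameSequence, KeypointTrack]:
    """Simulate and render a single trial (frames + matching track)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if config is None:
        config = SynthConfig(arena_px=arena_px, group_params=(params, params))
    rng = np.random.default_rng(seed)
    track = _simulate_track(params, config, n_frames, rng)
    frames = render_frames(
        track,
        arena_px=arena_px,
        pixel_noise_sd=config.pixel_noise_sd,
        rng=np.random.default_rng(seed + 1),
        fps_effective=config.fps_effective,
    )
    return frames, track


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def generate_cohort(
    config: SynthConfig, render: bool = False
) -> tuple[pd.DataFrame, list[SynthTrial]]:
    """Generate a balanced two-group cohort of trials.

    Returns the trial manifest (trial_id, animal_id, litter_id, group,
    video_path, track_path, start_offset_frames) and the trial objects.
    Frames are rendered lazily via ``SynthTrial.render`` unless
    ``render=True``; tracks are always generated.  Identical configs
    give bit-identical cohorts; per-trial seeds are derived from
    (seed, group index, trial index) so enlarging the cohort leaves
    existing trials unchanged.
    """
    trials: list[SynthTrial] = []
    rows = []
    for g, (gname, gpar) in enumerate(zip(config.group_names, config.group_params)):
        for i in range(config.n_trials_per_group):
            key = (config.seed, g, i)
            rng = np.random.default_rng(np.random.SeedSequence(list(key) + [0]))
            track = _simulate_track(gpar, config, config.n_frames, rng)
            trial_id = f"{gname}_{i:03d}"
            trial = SynthTrial(
                trial_id=trial_id,
                animal_id=f"{gname}_a{i:03d}",
                litter_id=f"{gname}_L{i // config.litter_size:02d}",
                group=gname,
                params=gpar,
                track=track,
                config=config,
                seed_key=key,
            )
            if render:
                trial.render()
            trials.append(trial)
            rows.append(
                {
                    "trial_id": trial.trial_id,
                    "animal_id": trial.animal_id,
                    "litter_id": trial.litter_id,
                    "group": gname,
                    "video_path": f"frames/{trial_id}",
                    "track_path": f"tracks/{trial_id}.csv",
                    "start_offset_frames": 0,
                }
            )
    return pd.DataFrame(rows), trials


def simulate_grid_walk(
    grid: OpenFieldGrid,
    locomotion_rate: float,
    n_frames: int,
    seed: int = 0,
    fps: float = 3.0,
) -> np.ndarray:
    """Continuous paw trajectory (cm) over the arena grid.

    Starts at the centre of a start square; at each frame the paw hops
    to an adjacent square's centre with probability ``rate / fps``, so
    the expected number of square entries is ~ rate x duration.
    """
    if locomotion_rate < 0:
        raise ValueError("locomotion_rate must be >= 0")
    rng = np.random.default_rng(seed)
    sq = min(grid.start_squares)
    p_move = min(locomotion_rate / fps, 1.0)
    path = np.empty((n_frames, 2))
    for t in range(n_frames):
        path[t] = grid.square_center_cm(sq)
        if rng.random() < p_move:
            c, r = sq
            nbrs = [
                (c + dc, r + dr)
                for dc, dr in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= c + dc < grid.n_cols and 0 <= r + dr < grid.n_rows
            ]
            sq = nbrs[rng.integers(len(nbrs))]
    return path


def cohort_feature_matrices(trials, backend=None) -> dict:
    """Render each trial, extract its feature matrix, and free the frames.

    Streaming keeps memory bounded: only one trial's frame stack exists
    at a time.  Returns ``{trial_id: FeatureMatrix}``.
    """
    from .features import PatchFeatureBackend, extract_features

    if backend is None:
        backend = PatchFeatureBackend()
    out = {}
    for trial in trials:
        frames = trial.render()
        out[trial.trial_id] = extract_features(frames, backend, trial_id=trial.trial_id)
        trial.frames = None
    return out


def write_cohort(config: SynthConfig, out_dir, write_hdf: bool = False) -> pd.DataFrame:
    """Materialize a cohort to disk: PNG frame directories, DeepLabCut-
    dialect CSV tracks (optionally HDF5) and a manifest CSV."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    manifest, trials = generate_cohort(config, render=False)
    for trial in trials:
        frames = trial.render()
        fdir = out / "frames" / trial.trial_id
        fdir.mkdir(exist_ok=True)
        for t, frame in enumerate(frames.frames):
            iio.imwrite(fdir / f"frame_{t:05d}.png", frame)
        trial.track.to_dlc_csv(out / "tracks" / f"{trial.trial_id}.csv")
        if write_hdf:
            trial.track.to_dlc_hdf(out / "tracks" / f"{trial.trial_id}.h5")
        trial.frames = None  # keep memory bounded
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
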