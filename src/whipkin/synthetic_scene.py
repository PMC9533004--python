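"""Synthetic whip-throwing scenes with known ground truth.

The generator produces marker datasets with the statistical and kinematic
structure the analysis pipeline assumes, so that every stage can be tested
against planted values without any recordings:

* a hand/handle trajectory whose tangential-speed profile has two peaks,
  the second invariably higher (the throw);
* a 10-marker whip modelled as a kinematic chain of fixed-length segments
  whose orientation angles follow the handle schedule with a per-segment
  time lag, so per-marker speed peaks propagate handle -> tip (the
  "cascade") and adjacent markers keep their arclength spacing exactly;
* a planted whip extension and azimuth realized exactly at the
  peak-hand-speed instant of a nominal trial (the chain forms a circular
  arc there; the arc's bend is solved from the planted extension and its
  orientation from the planted azimuth);
* a springy target whose free-end marker rings with a damped oscillation
  after planted contacts, and per-trial hitting errors realized by the
  thrower standing farther from the target (radial fall-short misses; in
  the rhythmic style the repositioning is absorbed into each cycle's own
  backswing);
* additive isotropic marker noise and scheduled gaps, applied last.

The generator is kinematic — scripted configurations satisfying the chain
constraint — not a dynamics simulation; the analysis needs controlled
ground truth, not physical fidelity.  Ground truth is recorded from the
noise-free twin of each scene: planted quantities (extension, azimuth,
error, interval variability, trial counts) are inputs; quantities that
emerge from the kinematics (tip speeds, per-marker peak times, hand
azimuth per trial) are measured on the noiseless data and recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import segmentation, whip_metrics
from .geometry import fit_line_svd, polyline_segment_distance
from .mocap_io import MarkerDataset, MarkerSchema, default_schema

__all__ = [
    "SceneParams",
    "CohortParams",
    "SceneGroundTruth",
    "simulate_trial",
    "simulate_block",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class SceneParams:
    """Shape and noise parameters of a synthetic scene.

    Defaults emulate the study conditions per style: hand speed peaks of
    6.1 (discrete) / 4.5 (rhythmic) m/s, whip extension 1.45 / 1.43 m and
    whip azimuth -10.9 / +28.4 deg at peak hand speed, inter-trial
    intervals of 5.45 s (CoV 0.12) / 1.2 s (CoV 0.06), and a tip-to-hand
    peak-speed gain around 5.  ``use :meth:`for_style` to get the
    style-appropriate defaults.
    """

    style: str = "discrete"
    sampling_rate: float = 500.0
    schema: MarkerSchema = field(default_factory=default_schema)
    # hand speed profile (m/s): first (lift/backswing) and second (throw) peak
    hand_peak1: float = 1.8
    hand_peak2: float = 6.1
    # whip unfolding
    cascade_lag: float = 0.02  # s per chain segment
    tip_gain: float = 4.9  # approximate peak tip / peak hand speed ratio
    planted_extension: float = 1.45  # m at peak hand speed (nominal trial)
    planted_azimuth: float = -10.9  # deg at peak hand speed (nominal trial)
    planted_hand_azimuth: float = 24.3  # deg
    # single-trial error plant and block-level error distribution
    planted_error: float = 0.05  # m (simulate_trial)
    error_median: float = 0.12  # m, miss-trial lognormal median
    error_spread: float = 0.6  # lognormal sigma
    hit_probability: float = 0.35
    # timing
    period: float = 5.45  # s start-to-start
    interval_cov: float = 0.12
    # target
    target_spring_hz: float = 3.5
    target_decay: float = 0.25  # s, oscillation decay time constant
    hit_amplitude: float = 0.05  # m, initial oscillation amplitude
    contact_threshold: float = 0.025  # m, closest approach counting as contact
    # measurement imperfections
    noise_sd: float = 0.0003  # m, isotropic per marker per frame
    gap_schedule: tuple = ()  # (marker, start_frame, length) triples
    seed: int = 0

    @classmethod
    def for_style(cls, style: str, **overrides) -> "SceneParams":
        if style == "rhythmic":
            defaults = dict(
                style="rhythmic",
                hand_peak1=2.6,
                hand_peak2=4.5,
                tip_gain=5.35,
                planted_extension=1.43,
                planted_azimuth=28.4,
                planted_hand_azimuth=36.1,
                period=1.2,
                interval_cov=0.06,
            )
        elif style == "discrete":
            defaults = {"style": "discrete"}
        else:
            raise ValueError(f"unknown style {style!r}")
        defaults.update(overrides)
        return cls(**defaults)

    def validate(self) -> None:
        if self.hand_peak2 <= self.hand_peak1:
            raise ValueError("the second hand-speed peak must be the higher one")
        chain = self.schema.chain_length()
        if not (0.0 < self.planted_extension <= chain):
            raise ValueError("planted_extension must be in (0, chain length]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.planted_error < 0:
            raise ValueError("planted_error must be >= 0")


@dataclass
class CohortParams:
    """Generative parameters for trial-level cohort metric tables.

    Metrics are drawn from the additive mixed-model form
    ``Y = (b0+P0) + (bS+PS) S + (bB+PB) B + bSB S B + e`` with style S in
    {0: discrete, 1: rhythmic}, block B in 1..5, per-participant Gaussian
    random effects P and i.i.d. residuals.  When ``beta_x`` or ``beta_sx``
    is non-zero a covariate X ~ N(x_mean, x_sd) enters as
    ``... + (bX+PX) X + bSX S X``.
    """

    n_participants: int = 16
    trials_per_block: int = 33
    n_blocks: int = 5
    intercept: float = 0.15
    beta_style: float = 0.10
    beta_block: float = -0.009
    beta_interaction: float = 0.0
    beta_x: float = 0.0
    beta_sx: float = 0.0
    sd_intercept: float = 0.05
    sd_style: float = 0.03
    sd_block: float = 0.005
    sd_x: float = 0.0
    x_mean: float = 0.0
    x_sd: float = 1.0
    with_covariate: bool = False  # force an X column even with null effects
    residual_sd: float = 0.08
    family: str = "gaussian"  # or "binomial"
    seed: int = 0


# ---------------------------------------------------------------------------
# Small numeric helpers
# ---------------------------------------------------------------------------


def _smoothstep(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    u = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _gauss(t: np.ndarray, mu: float, sig: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sig) ** 2)


def _hermite(
    t: np.ndarray, t0: float, t1: float, y0: float, y1: float, s0: float, s1: float
) -> np.ndarray:
    h = t1 - t0
    u = np.clip((t - t0) / h, 0.0, 1.0)
    h00 = 2 * u**3 - 3 * u**2 + 1
    h10 = u**3 - 2 * u**2 + u
    h01 = -2 * u**3 + 3 * u**2
    h11 = u**3 - u**2
    return h00 * y0 + h10 * h * s0 + h01 * y1 + h11 * h * s1


# ---------------------------------------------------------------------------
# Plant solving: chain bend, orientation, handle angle
# ---------------------------------------------------------------------------


def _chord_length(seg_lengths: np.ndarray, delta: float) -> float:
    ang = delta * np.arange(1, len(seg_lengths) + 1)
    return float(np.hypot((seg_lengths * np.cos(ang)).sum(), (seg_lengths * np.sin(ang)).sum()))


def _solve_bend(seg_lengths: np.ndarray, extension: float) -> float:
    """Per-segment angle increment realizing the planted h1->w1 chord."""
    full = seg_lengths.sum()
    if extension >= full - 1e-12:
        return 0.0
    return float(
        optimize.brentq(lambda d: _chord_length(seg_lengths, d) - extension, 1e-9, 0.5)
    )


def _chain_shape(seg_lengths: np.ndarray, alpha2: float, delta: float) -> np.ndarray:
    """Planar 11-point chain (h1, w10..w1) for angles alpha2 + j*delta."""
    ang = alpha2 + delta * np.arange(1, len(seg_lengths) + 1)
    steps = np.stack([seg_lengths * np.cos(ang), seg_lengths * np.sin(ang)], axis=1)
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return np.column_stack([pts, np.zeros(len(pts))])


def _solve_orientation(seg_lengths: np.ndarray, delta: float, azimuth_deg: float) -> float:
    """Handle-schedule angle at peak so the SVD line fit has the planted azimuth."""
    pts = _chain_shape(seg_lengths, 0.0, delta)
    _, v = fit_line_svd(pts)
    if np.dot(v[:2], pts[-1, :2] - pts[0, :2]) < 0:
        v = -v
    chi0 = np.arctan2(v[1], v[0])
    return float(np.pi + np.deg2rad(azimuth_deg) - chi0)


def _solve_handle_angle(
    handle_length: float, first_seg: float, alpha1: float, hand_azimuth_deg: float
) -> float:
    """Handle angle so the hand-handle axis azimuth matches the plant.

    The axis runs from the hand markers to the mean of w10 and h1, i.e.
    ``L u(a0) + (l1/2) u(a1)`` horizontally; solve for ``a0``.
    """
    phi = np.pi + np.deg2rad(hand_azimuth_deg)  # desired polar angle of the axis
    ratio = (first_seg / 2.0) / handle_length
    s = -ratio * np.sin(alpha1 - phi)
    return float(phi + np.arcsin(np.clip(s, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# Style templates (all times in seconds within one trial/cycle)
# ---------------------------------------------------------------------------


@dataclass
class _Timeline:
    """Knot times of the canonical throw, per style."""

    seq: float  # active-sequence duration (discrete) / cycle period (rhythmic)
    bump1: tuple[float, float]  # (centre, sigma) of backswing speed bump
    bump2: tuple[float, float]  # (centre, sigma) of throw speed bump
    recock: tuple[float, float]  # window raising the whip angle
    lin_margin: float = 0.02  # linear-angle margin around the lag window
    # discrete only
    z_lift: tuple[float, float] | None = None
    elev_drop: tuple[float, float] | None = None
    z_down: tuple[float, float] | None = None
    ret: tuple[float, float] | None = None
    bump3: tuple[float, float] | None = None
    # rhythmic only
    elev_bump: tuple[float, float, float] | None = None  # (t0, t1, peak rad)

    @property
    def t2(self) -> float:
        return self.bump2[0]


def _timeline(params: SceneParams) -> _Timeline:
    lagspan = 10 * params.cascade_lag
    if params.style == "discrete":
        t2 = 1.05
        return _Timeline(
            seq=3.1,
            bump1=(0.70, 0.15),
            bump2=(t2, 0.07),
            recock=(0.30, t2 - lagspan - 0.02),
            z_lift=(0.25, 0.75),
            elev_drop=(0.35, 0.80),
            # lower the whip to the floor before swinging it back, so the
            # return pass stays far from the target
            z_down=(1.55, 2.15),
            ret=(1.70, 2.60),
            bump3=(1.95, 0.18),
        )
    t2 = 0.66
    return _Timeline(
        seq=1.2,
        # wide backswing bump: its area absorbs the per-trial stand-back
        # repositioning while its peak stays well below the throw peak
        bump1=(0.26, 0.14),
        bump2=(t2, 0.08),
        recock=(0.06, t2 - lagspan - 0.02),
        elev_bump=(0.06, 0.42, -0.65),
    )


@dataclass
class _Plants:
    delta: float
    omega: float
    alpha2: float
    alpha0: float  # handle angle at the peak
    psi_top: float
    psi_end: float
    sweep_time: float  # base (handle-segment) unfolding duration
    sweep_taper: float = 0.8  # tip segment unfolds in (1 - taper) of the base time


def _solve_plants(params: SceneParams, tl: _Timeline) -> _Plants:
    seg = params.schema.whip_segment_lengths()
    delta = _solve_bend(seg, params.planted_extension)
    alpha2 = _solve_orientation(seg, delta, params.planted_azimuth)
    alpha0 = _solve_handle_angle(
        params.schema.handle_length, seg[0], alpha2 + delta, params.planted_hand_azimuth
    )
    omega = -delta / params.cascade_lag if delta > 0 else -0.5
    psi_top = alpha2 - omega * (tl.t2 - tl.recock[1])
    # sweep well past the target azimuth so the tip crosses its closest
    # approach at speed, giving a sharp minimum-distance event
    psi_end = -0.55
    v0 = alpha2 + omega * tl.lin_margin
    dpsi = max(v0 - psi_end, 0.5)
    # base unfolding time chosen so the distal segments (which unfold in
    # (1 - taper) of it) drive the tip to roughly tip_gain * hand peak speed
    sweep_time = 3.3 * dpsi / (params.tip_gain * params.hand_peak2)
    if tl.ret is None:
        # rhythmic: every segment's sweep must finish inside the cycle
        sweep_time = min(sweep_time, tl.seq - (tl.t2 + tl.lin_margin) - 0.04)
    return _Plants(delta, omega, alpha2, alpha0, psi_top, psi_end, sweep_time)


# rest-pose heights (m) of the chain points h1, w10, w9, w8, w7..w1 used to
# lay the whip on the floor in the discrete style
_REST_Z = np.array([0.042, 0.025, 0.015, 0.011] + [0.010] * 7)
_HAND_REST_Z = 0.25
_HAND_THROW_Z = 1.35
_HAND_MARKER_DROP = 0.02
_REST_X = 0.30


def _rest_elevations(schema: MarkerSchema) -> np.ndarray:
    """Downward segment angles putting the whip on the floor at rest."""
    seg = np.concatenate([[schema.handle_length], schema.whip_segment_lengths()])
    z = np.concatenate([[_HAND_REST_Z], _REST_Z])
    return np.arcsin(np.clip(np.diff(z[: len(seg) + 1]) / -seg, -1.0, 1.0))


def _segment_angle_sequence(
    u: np.ndarray,
    j: int,
    lag: float,
    length_ratio: float,
    tl: _Timeline,
    pl: _Plants,
) -> np.ndarray:
    """Azimuth-angle schedule of chain segment ``j`` over one sequence.

    All segments share the recock and constant-rate phases delayed by
    ``j * lag`` (template time), which realizes the planted bend at the
    peak-hand-speed instant.  Each segment then unfolds toward the target
    in its own sweep: the sweep envelope tapers toward the tip (distal
    segments rotate faster) and each segment's sweep duration scales with
    its length so every segment contributes a comparable speed bump to the
    markers beyond it — together producing the handle -> tip cascade of
    speed peaks.
    """
    t2 = tl.t2
    lin0, lin1 = tl.recock[1], t2 + tl.lin_margin
    t_env = pl.sweep_time * (1.0 - pl.sweep_taper * j / 10.0)
    # shorter segments unfold somewhat faster (sqrt compensation), but the
    # burst stays long enough that marker trajectories remain band-limited
    # below the whip filter cutoff
    t_seg = t_env * float(np.clip(np.sqrt(length_ratio), 0.7, 1.0))
    w_start = lin1 + 0.5 * (t_env - t_seg)
    v_start = pl.alpha2 + pl.omega * (w_start - t2)
    start_val = np.pi if tl.ret is not None else pl.psi_end
    w = u - j * lag
    psi = np.full_like(w, start_val)
    m = (w >= tl.recock[0]) & (w < lin0)
    psi[m] = _hermite(w[m], tl.recock[0], lin0, start_val, pl.psi_top, 0.0, pl.omega)
    m = (w >= lin0) & (w < w_start)
    psi[m] = pl.alpha2 + pl.omega * (w[m] - t2)
    m = (w >= w_start) & (w < w_start + t_seg)
    psi[m] = _hermite(w[m], w_start, w_start + t_seg, v_start, pl.psi_end, pl.omega, 0.0)
    psi[w >= w_start + t_seg] = pl.psi_end
    if tl.ret is not None:  # discrete: swing back to the rest angle
        m = (u >= tl.ret[0]) & (u < tl.ret[1])
        psi[m] = _hermite(u[m], tl.ret[0], tl.ret[1], pl.psi_end, np.pi, 0.0, 0.0)
        psi[u >= tl.ret[1]] = np.pi
    return psi


def _handle_offset_sequence(t: np.ndarray, tl: _Timeline, pl: _Plants) -> np.ndarray:
    """Smooth handle-vs-whip angle offset realizing the hand-azimuth plant.

    In the discrete style the hand cocks during the backswing and uncocks
    on the return; in the rhythmic style it stays cocked throughout the
    cycle (the offset is constant, keeping cycles continuous).
    """
    c2 = pl.alpha0 - pl.alpha2
    if tl.ret is None:
        return np.full_like(t, c2)
    ramp = _smoothstep(t, tl.recock[0], tl.recock[1])
    ramp = ramp * (1.0 - _smoothstep(t, tl.ret[0], tl.ret[1]))
    return c2 * ramp


def _speed_bumps(
    t: np.ndarray, tl: _Timeline, params: SceneParams, extra_back: float = 0.0
) -> np.ndarray:
    """Forward (x) hand velocity over one sequence (template time).

    Discrete: backswing, throw and return bumps; the return amplitude is
    solved so the hand comes back to its starting point exactly.
    Rhythmic: the backswing area is set so the cycle's net displacement is
    ``-extra_back`` metres — the backswing itself repositions the thrower
    (per-trial stand-back distance) without any extra movement phase.
    """
    if tl.bump3 is not None:
        vx = -params.hand_peak1 * _gauss(t, *tl.bump1) + params.hand_peak2 * _gauss(
            t, *tl.bump2
        )
        g3 = _gauss(t, *tl.bump3)
        a3 = vx.sum() / g3.sum()
        return vx - a3 * g3
    g1 = _gauss(t, *tl.bump1)
    g2 = _gauss(t, *tl.bump2)
    du = float(t[1] - t[0]) if len(t) > 1 else 1.0 / 500.0
    a1 = (params.hand_peak2 * g2.sum() + extra_back / du) / g1.sum()
    return -a1 * g1 + params.hand_peak2 * g2


def _elevation_scale(t: np.ndarray, tl: _Timeline) -> np.ndarray:
    """Discrete: 1 on the floor -> 0 airborne -> 1 once lowered again."""
    return 1.0 - _smoothstep(t, *tl.elev_drop) + _smoothstep(t, *tl.z_down)


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------


class _SceneBuilder:
    """Assembles one block's noiseless marker arrays from the schedules."""

    def __init__(self, params: SceneParams):
        params.validate()
        self.p = params
        self.tl = _timeline(params)
        self.pl = _solve_plants(params, self.tl)
        self.fs = params.sampling_rate
        self.lag_frames = max(1, int(round(params.cascade_lag * self.fs)))
        self.seg_whip = params.schema.whip_segment_lengths()
        self.rest_elev = _rest_elevations(params.schema)
        self._calibrate_tip_speed()

    def _measure_tip_peak(self) -> float:
        pts = self.nominal_template()
        v = np.gradient(pts["w2"], 1.0 / self.fs, axis=0)
        return float(np.linalg.norm(v, axis=1).max())

    def _calibrate_tip_speed(self) -> None:
        """Scale the sweep time so the nominal tip (w2) peak speed matches
        tip_gain * peak hand speed; in the rhythmic style the sweep is
        additionally capped so every segment settles within the cycle."""
        target = self.p.tip_gain * self.p.hand_peak2
        cap = self.tl.seq - (self.tl.t2 + self.tl.lin_margin) - 0.04
        for _ in range(3):
            realized = self._measure_tip_peak()
            if abs(realized - target) / target < 0.03:
                break
            new_t = self.pl.sweep_time * realized / target
            if self.tl.ret is None:
                new_t = min(new_t, cap)
            if abs(new_t - self.pl.sweep_time) < 1e-4:
                break
            self.pl.sweep_time = new_t

    # -- schedule assembly over a whole block ---------------------------------

    def block_schedules(
        self,
        starts: np.ndarray,
        scales: np.ndarray,
        n_frames: int,
        offsets: np.ndarray | None = None,
    ):
        """Sample the per-trial templates onto the block's frame grid.

        ``starts`` are sequence-start times (s), ``scales`` per-trial time
        scale factors (warping that changes speeds but not the spatial
        path), ``offsets`` the per-trial stand-back distances (m) realized
        in the rhythmic style by modulating each cycle's backswing area.
        Returns per-segment angle arrays plus hand schedules.
        """
        p, tl, pl = self.p, self.tl, self.pl
        if offsets is None:
            offsets = np.zeros(len(starts))
        t = np.arange(n_frames) / self.fs
        if p.style == "discrete":
            base = np.pi
            alpha = np.full((n_frames, 11), base)
        else:
            # before the first cycle the chain rests at its unfolded pose
            alpha = np.full((n_frames, 11), pl.psi_end)
        coff = (
            np.zeros(n_frames)
            if p.style == "discrete"
            else np.full(n_frames, pl.alpha0 - pl.alpha2)
        )
        vx = np.zeros(n_frames)
        if p.style == "discrete":
            elev = np.ones(n_frames)
            zs = np.zeros(n_frames)
        else:
            elev = np.zeros(n_frames)
        seg_len = np.concatenate([[p.schema.handle_length], self.seg_whip])
        ref = self.seg_whip.max()
        for i, (s0, sc) in enumerate(zip(starts, scales)):
            u = (t - s0) / sc
            last = i == len(starts) - 1
            m = (u >= 0) & ((u < tl.seq) | last)
            um = u[m]
            extra = offsets[i] - (offsets[i - 1] if i > 0 else 0.0)
            for j in range(11):
                ratio = 1.0 if j < 2 else seg_len[j] / ref
                alpha[m, j] = _segment_angle_sequence(
                    um, j, p.cascade_lag, ratio, tl, pl
                )
            coff[m] = _handle_offset_sequence(um, tl, pl)
            vx[m] = _speed_bumps(um, tl, p, extra_back=extra) / sc
            if p.style == "discrete":
                elev[m] = _elevation_scale(um, tl)
                zs[m] = _smoothstep(um, *tl.z_lift) - _smoothstep(um, *tl.z_down)
            else:
                e0, e1, epeak = tl.elev_bump
                elev[m] = epeak * _gauss(um, (e0 + e1) / 2.0, (e1 - e0) / 4.4)
        if p.style == "discrete":
            z = _HAND_REST_Z + (_HAND_THROW_Z - _HAND_REST_Z) * zs
        else:
            z = np.full(n_frames, _HAND_THROW_Z)
        x = _REST_X + np.cumsum(vx) / self.fs
        return {"t": t, "alpha": alpha, "coff": coff, "x": x, "z": z, "elev": elev}

    # -- marker positions ------------------------------------------------------

    def chain_positions(self, sched: dict, y_offset: np.ndarray) -> dict:
        """Whip/handle/hand marker trajectories from the schedules."""
        p = self.p
        alpha, coff, elev = sched["alpha"], sched["coff"], sched["elev"]
        anchor = np.stack([sched["x"], y_offset, sched["z"]], axis=1)
        if p.style == "discrete":
            elev_angles = np.outer(elev, self.rest_elev)  # (frames, 11)
        else:
            elev_angles = np.repeat(elev[:, None], 11, axis=1)
        seg_len = np.concatenate([[p.schema.handle_length], self.seg_whip])
        pts = {}
        pos = anchor.copy()
        names = ["h1", "w10", "w9", "w8", "w7", "w6", "w5", "w4", "w3", "w2", "w1"]
        for j in range(11):
            a = alpha[:, j] + coff if j == 0 else alpha[:, j]
            e = elev_angles[:, j]
            u = np.stack(
                [np.cos(e) * np.cos(a), np.cos(e) * np.sin(a), -np.sin(e)], axis=1
            )
            pos = pos + seg_len[j] * u
            pts[names[j]] = pos
        pts["h2"] = anchor
        pts["hand"] = anchor + np.array([0.0, 0.0, -_HAND_MARKER_DROP])
        return pts

    # -- target placement ------------------------------------------------------

    def nominal_template(self) -> dict:
        """Noiseless single nominal trial/cycle (the spatial path is the
        same for every warped repetition)."""
        tl = self.tl
        starts = np.array([0.3])
        n = int(round((0.3 + tl.seq + 0.6) * self.fs))
        sched = self.block_schedules(starts, np.ones(1), n)
        return self.chain_positions(sched, np.zeros(n))

    def place_target(self) -> np.ndarray:
        """Position t1 so the nominal whip path grazes the target (error 0)."""
        pts = self.nominal_template()
        w = np.stack([pts["w1"], pts["w2"], pts["w3"]], axis=1)
        t1 = np.array([pts["w1"][:, 0].max() + 0.05, 0.0, _HAND_THROW_Z])
        for _ in range(6):
            t2 = t1 + np.array([0.15, 0.0, 0.0])
            d = polyline_segment_distance(
                w, np.broadcast_to(t1, w[:, 0].shape), np.broadcast_to(t2, w[:, 0].shape)
            )
            f = int(np.nanargmin(d))
            # closest pair by dense sampling of the two chains at this frame
            wsamp = _dense_polyline(w[f], 0.002)
            tsamp = t1 + np.linspace(0, 1, 80)[:, None] * (t2 - t1)
            dd = np.linalg.norm(wsamp[:, None, :] - tsamp[None, :, :], axis=2)
            i, j = np.unravel_index(np.argmin(dd), dd.shape)
            gap = wsamp[i] - tsamp[j]
            if np.linalg.norm(gap) < 5e-4:
                break
            t1 = t1 + gap
        self._template_whip = w
        self._template_start = 0.3
        return t1

    def error_to_offset(
        self, target1: np.ndarray, errors: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Stand-back distances realizing the planted per-trial errors.

        A thrower standing farther from the target along -x makes the whip
        fall short radially, which maps almost one-to-one and sharply onto
        the closest-approach distance.  Returns ``(offsets, event_times)``
        where ``event_times`` are the template times (s from sequence
        start) of each trial's minimum-distance event (standing back
        shifts the event slightly within the cycle).
        """
        w = self._template_whip
        t2v = target1 + np.array([0.15, 0.0, 0.0])

        def measure(dx: float) -> tuple[float, float]:
            shifted = w - np.array([dx, 0.0, 0.0])
            d = polyline_segment_distance(
                shifted,
                np.broadcast_to(target1, w[:, 0].shape),
                np.broadcast_to(t2v, w[:, 0].shape),
            )
            f = int(np.nanargmin(d))
            return float(np.nanmin(d)), f / self.fs - self._template_start

        grid = np.linspace(0.0, 0.45, 19)
        gvals, taus = map(np.array, zip(*[measure(k) for k in grid]))
        offsets = np.zeros(len(errors))
        for i, e in enumerate(errors):
            if gvals[0] >= e:
                continue
            if e >= gvals[-1]:
                offsets[i] = grid[-1]
                continue
            hi = int(np.searchsorted(gvals, e))
            try:
                offsets[i] = optimize.brentq(
                    lambda k: measure(k)[0] - e, grid[hi - 1], grid[hi], xtol=1e-5
                )
            except ValueError:
                offsets[i] = grid[hi]
        event_times = np.interp(offsets, grid, taus)
        return offsets, event_times


def _dense_polyline(vertices: np.ndarray, step: float) -> np.ndarray:
    """Sample a polyline at roughly ``step`` spacing (includes vertices)."""
    out = []
    for a, b in zip(vertices[:-1], vertices[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / step)) + 1)
        out.append(a + np.linspace(0, 1, n, endpoint=False)[:, None] * (b - a))
    out.append(vertices[-1:])
    return np.vstack(out)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class SceneGroundTruth:
    """Planted and realized (noise-free twin) truth for one scene."""

    trials: pd.DataFrame
    events: np.ndarray
    planted: dict
    marker_peak_frames: list[dict]


def _ground_truth(
    clean: MarkerDataset,
    params: SceneParams,
    planted: dict,
    contact_frames: np.ndarray | None = None,
) -> SceneGroundTruth:
    fs = clean.sampling_rate
    vel = np.gradient(clean.positions, 1.0 / fs, axis=0)
    speeds = np.linalg.norm(vel, axis=2)
    hand_speed = speeds[:, clean.schema.index("hand")]
    tip_speed = speeds[:, clean.schema.index("w2")]
    distance = segmentation.whip_target_distance(clean)
    events = segmentation.detect_minimum_distance_events(
        distance, fs, max_distance=0.6
    )
    if params.style == "discrete":
        trials = segmentation.parse_discrete(clean, hand_speed, events)
    else:
        trials = segmentation.parse_rhythmic(events)
    target_ref = 0.5 * (
        np.nanmean(clean.marker("t2"), axis=0) + np.nanmean(clean.marker("t3"), axis=0)
    )
    rows = []
    peak_frames: list[dict] = []
    whip_names = [f"w{i}" for i in range(10, 0, -1)]
    for t in trials:
        lm = segmentation.find_landmarks(
            t, clean.marker("hand"), hand_speed, target_ref
        )
        t.landmarks = lm
        # error over the throw interval; in the rhythmic style the full
        # trial interval starts at the previous minimum-distance event,
        # where the distance still equals the previous trial's error
        err = float(np.nanmin(distance[lm.throw_onset : t.end_frame + 1]))
        if contact_frames is None:
            hit = err < params.contact_threshold
        else:
            # a trial's contact happens at its own minimum-distance event
            hit = bool(
                np.any(np.abs(contact_frames - t.end_frame) <= 10)
            )
        ext, ratio = whip_metrics.whip_extension(clean, t)
        az = whip_metrics.whip_azimuth(clean, t)
        haz = whip_metrics.hand_azimuth(clean, t)
        phs, pts_ = whip_metrics.peak_speeds(t, hand_speed, tip_speed)
        rows.append(
            {
                "trial": t.trial_index,
                "style": params.style,
                "start_frame": t.start_frame,
                "end_frame": t.end_frame,
                "throw_onset": lm.throw_onset,
                "peak_hand_speed_frame": lm.peak_hand_speed,
                "error": err,
                "hit": hit,
                "extension": ext,
                "extension_ratio": ratio,
                "whip_azimuth": az,
                "hand_azimuth": haz,
                "peak_hand_speed": phs,
                "peak_tip_speed": pts_,
            }
        )
        marker_peaks = {}
        for name in ["hand"] + whip_names:
            sp = speeds[lm.throw_onset : t.end_frame + 1, clean.schema.index(name)]
            marker_peaks[name] = int(np.argmax(sp)) + lm.throw_onset
        peak_frames.append(marker_peaks)
    return SceneGroundTruth(
        trials=pd.DataFrame(rows),
        events=np.asarray(events, dtype=int),
        planted=planted,
        marker_peak_frames=peak_frames,
    )


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------


def _apply_noise_and_gaps(
    positions: np.ndarray, params: SceneParams, rng: np.random.Generator, schema
) -> MarkerDataset:
    noisy = positions.copy()
    if params.noise_sd > 0:
        noisy = noisy + rng.normal(0.0, params.noise_sd, size=noisy.shape)
    mask = np.zeros(noisy.shape[:2], dtype=bool)
    for marker, start, length in params.gap_schedule:
        j = schema.index(marker)
        mask[start : start + length, j] = True
    noisy[mask] = np.nan
    return MarkerDataset(noisy, params.sampling_rate, mask, schema)


def _assemble(
    builder: _SceneBuilder,
    starts: np.ndarray,
    scales: np.ndarray,
    offsets: np.ndarray,
    n_frames: int,
    target1: np.ndarray,
    params: SceneParams,
    rng: np.random.Generator,
    planted: dict,
) -> tuple[MarkerDataset, SceneGroundTruth]:
    if params.style == "rhythmic":
        # the backswing of each cycle repositions the thrower
        sched = builder.block_schedules(starts, scales, n_frames, offsets=offsets)
    else:
        # repositioning happens during the rest phase before each throw
        sched = builder.block_schedules(starts, scales, n_frames)
        tgrid = np.arange(n_frames) / builder.fs
        dx = np.full(n_frames, offsets[0])
        for i in range(1, len(starts)):
            ramp = _smoothstep(tgrid, starts[i] - 0.7, starts[i] - 0.2)
            dx = dx + (offsets[i] - offsets[i - 1]) * ramp
        sched["x"] = sched["x"] - dx
    pts = builder.chain_positions(sched, np.zeros(n_frames))
    schema = params.schema
    n_markers = len(schema.marker_names)
    positions = np.zeros((n_frames, n_markers, 3))
    for name in ("hand", "h1", "h2") + tuple(f"w{i}" for i in range(1, 11)):
        positions[:, schema.index(name), :] = pts[name]
    t2v = target1 + np.array([0.15, 0.0, 0.0])
    t3v = target1 + np.array([0.30, 0.0, 0.0])
    for name, v in (("t1", target1), ("t2", t2v), ("t3", t3v)):
        positions[:, schema.index(name), :] = v
    # determine contacts from the static-target noiseless scene, then ring
    clean0 = MarkerDataset(
        positions.copy(), params.sampling_rate, np.zeros((n_frames, n_markers), bool), schema
    )
    distance = segmentation.whip_target_distance(clean0)
    events = segmentation.detect_minimum_distance_events(
        distance, builder.fs, max_distance=0.6
    )
    tgrid_full = np.arange(n_frames) / builder.fs
    osc = np.zeros(n_frames)
    contact_frames = []
    planted_hits = np.asarray(planted.get("hits", []), dtype=bool)
    for k, ev in enumerate(events):
        if k < len(planted_hits):
            contact = bool(planted_hits[k])
        else:  # fallback for unplanned events: threshold on closest approach
            lo = max(0, ev - int(0.1 * builder.fs))
            contact = bool(np.nanmin(distance[lo : ev + 1]) < params.contact_threshold)
        if contact:
            tt = tgrid_full - tgrid_full[ev]
            ring = np.where(
                tt >= 0,
                params.hit_amplitude
                * np.exp(-np.maximum(tt, 0) / params.target_decay)
                * np.sin(2 * np.pi * params.target_spring_hz * tt),
                0.0,
            )
            osc = osc + ring
            contact_frames.append(int(ev))
    positions[:, schema.index("t1"), 1] += osc
    positions[:, schema.index("t2"), 1] += 0.3 * osc
    clean = MarkerDataset(
        positions.copy(), params.sampling_rate, np.zeros((n_frames, n_markers), bool), schema
    )
    gt = _ground_truth(clean, params, planted, np.asarray(contact_frames, dtype=int))
    dataset = _apply_noise_and_gaps(positions, params, rng, schema)
    return dataset, gt


def simulate_block(
    params: SceneParams,
    duration: float | None = None,
    n_trials: int | None = None,
) -> tuple[MarkerDataset, SceneGroundTruth]:
    """Simulate one recording block of the given style.

    ``duration`` (s) defaults to 180 s (discrete) / 40 s (rhythmic);
    ``n_trials`` overrides the trial count directly.  Returns the noisy
    dataset and the scene ground truth (planted and realized values).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    builder = _SceneBuilder(params)
    tl = builder.tl
    if duration is None and n_trials is None:
        duration = 180.0 if params.style == "discrete" else 40.0

    # draw the inter-trial interval sequence (start-to-start periods)
    cov = params.interval_cov
    sigma = np.sqrt(np.log(1.0 + cov**2)) if cov > 0 else 0.0
    mu = np.log(params.period) - 0.5 * sigma**2

    periods: list[float] = []
    min_period = tl.seq + 0.25 if params.style == "discrete" else 0.6 * tl.seq
    total = 1.0 if params.style == "discrete" else 0.1
    while True:
        if n_trials is not None and len(periods) >= n_trials:
            break
        nxt = float(np.exp(rng.normal(mu, sigma))) if sigma > 0 else params.period
        nxt = max(nxt, min_period)
        if n_trials is None and total + nxt + tl.seq + 1.0 > duration:
            break
        periods.append(nxt)
        total += nxt
        if n_trials is None and len(periods) > 10000:
            break
    if not periods:
        n_frames = int(round((duration or 1.0) * params.sampling_rate))
        empty = _apply_noise_and_gaps(
            np.zeros((max(n_frames, 10), len(params.schema.marker_names), 3)),
            params,
            rng,
            params.schema,
        )
        return empty, SceneGroundTruth(pd.DataFrame(), np.array([], int), {}, [])

    target1 = builder.place_target()
    periods = np.asarray(periods)
    n = len(periods)

    # planted per-trial errors -> stand-back offsets (standing back also
    # shifts each trial's event time slightly within its cycle)
    hits = rng.random(n) < params.hit_probability
    sigma_e = params.error_spread
    errors = np.where(
        hits,
        np.abs(rng.normal(0.008, 0.004, n)),
        np.clip(
            np.exp(rng.normal(np.log(params.error_median), sigma_e, n)), 0.04, 0.30
        ),
    )
    offsets, event_times = builder.error_to_offset(target1, errors)

    intervals = periods.copy()
    if len(periods) >= 4 and cov > 0:
        # standardize the drawn intervals so their sample mean and sample
        # CoV equal the planted values exactly (the plant is the realized
        # variability, not just a distribution parameter); with n cycles
        # the trials span events 0..n-1, so n-2 start-to-start intervals
        # are realized in the rhythmic style (n-1 in the discrete style,
        # where the subset is exact anyway)
        k = len(periods) - 2 if params.style == "rhythmic" else len(periods) - 1
        head = periods[:k]
        z = (head - head.mean()) / head.std(ddof=1)
        rescaled = np.concatenate(
            [params.period * (1.0 + cov * z), np.full(len(periods) - k, params.period)]
        )
        if rescaled.min() >= min_period:
            intervals = rescaled
    if params.style == "discrete":
        # start-to-start intervals equal the period lengths exactly: each
        # trial starts at a fixed offset within its sequence
        periods = intervals
        starts = np.concatenate([[1.0], 1.0 + np.cumsum(periods[:-1])])
        scales = np.ones(len(starts))
        total_t = starts[-1] + tl.seq + 1.2
    else:
        # rhythmic trials are bounded by minimum-distance events, which
        # fall at a per-trial fraction u_k of each cycle (u depends weakly
        # on the trial's residual bend); an event-to-event interval mixes
        # adjacent cycle durations: I_k = (1-u_k) T_k + u_{k+1} T_{k+1}.
        # Solve the cycle durations from the planted interval sequence so
        # the realized trial intervals carry the planted CoV exactly.
        u = np.clip(event_times / tl.seq, 0.05, 0.999)
        cycles = np.empty(len(intervals))
        cycles[0] = float(np.mean(intervals))
        for k in range(len(intervals) - 1):
            cycles[k + 1] = (intervals[k] - (1.0 - u[k]) * cycles[k]) / u[k + 1]
        if cycles.min() < 0.6 * tl.seq or cycles.max() > 1.6 * tl.seq:
            cycles = intervals  # fall back for extreme draws
        periods = cycles
        scales = periods / tl.seq
        starts = np.concatenate([[0.1], 0.1 + np.cumsum(periods[:-1])])
        total_t = starts[-1] + periods[-1] + 0.6
    n_frames = int(round(total_t * params.sampling_rate))

    planted = {
        "style": params.style,
        "extension": params.planted_extension,
        "azimuth": params.planted_azimuth,
        "hand_azimuth": params.planted_hand_azimuth,
        "errors": errors,
        "hits": hits,
        "periods": np.asarray(periods),
        "intervals": np.asarray(intervals),
        "interval_cov": cov,
        "n_trials": n,
        "hand_peak2": params.hand_peak2,
    }
    return _assemble(
        builder, starts, scales, offsets, n_frames, target1, params, rng, planted
    )


def simulate_trial(
    params: SceneParams | None = None, **overrides
) -> tuple[MarkerDataset, SceneGroundTruth]:
    """Simulate a single nominal discrete throw with exact plants.

    The planted error (``params.planted_error``), extension and azimuth are
    realized exactly (up to frame discretization) because a single trial
    uses the nominal, unwarped template.
    """
    if params is None:
        params = SceneParams.for_style("discrete", **overrides)
    params.validate()
    rng = np.random.default_rng(params.seed)
    builder = _SceneBuilder(params)
    tl = builder.tl
    starts = np.array([0.5])
    scales = np.ones(1)
    n_frames = int(round((0.5 + tl.seq + 1.2) * params.sampling_rate))
    target1 = builder.place_target()
    offsets, _ = builder.error_to_offset(target1, np.array([params.planted_error]))
    planted = {
        "style": params.style,
        "error": params.planted_error,
        "extension": params.planted_extension,
        "azimuth": params.planted_azimuth,
        "hand_azimuth": params.planted_hand_azimuth,
        "hit": params.planted_error < params.contact_threshold,
        "hits": np.array([params.planted_error < params.contact_threshold]),
        "n_trials": 1,
    }
    return _assemble(
        builder, starts, scales, offsets, n_frames, target1, params, rng, planted
    )


def simulate_cohort(params: CohortParams) -> tuple[pd.DataFrame, dict]:
    """Draw a trial-level cohort metric table from the mixed-model form.

    Returns the table (columns participant, style, S, block, B, y and
    optionally x) and a dict of the planted effects.  For
    ``family="binomial"`` the linear predictor is on the logit scale and
    ``y`` is a Bernoulli draw.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    use_x = (
        params.with_covariate
        or params.beta_x != 0
        or params.beta_sx != 0
        or params.sd_x > 0
    )
    for i in range(params.n_participants):
        p0 = rng.normal(0.0, params.sd_intercept)
        ps = rng.normal(0.0, params.sd_style)
        pb = rng.normal(0.0, params.sd_block)
        px = rng.normal(0.0, params.sd_x) if params.sd_x > 0 else 0.0
        for s_code, style in ((0.0, "discrete"), (1.0, "rhythmic")):
            for b in range(1, params.n_blocks + 1):
                n = params.trials_per_block
                eta = (
                    params.intercept
                    + p0
                    + (params.beta_style + ps) * s_code
                    + (params.beta_block + pb) * b
                    + params.beta_interaction * s_code * b
                )
                x = rng.normal(params.x_mean, params.x_sd, n) if use_x else np.zeros(n)
                eta_t = eta + (params.beta_x + px) * x + params.beta_sx * s_code * x
                if params.family == "binomial":
                    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta_t))).astype(float)
                else:
                    y = eta_t + rng.normal(0.0, params.residual_sd, n)
                for k in range(n):
                    row = {
                        "participant": f"P{i + 1:02d}",
                        "style": style,
                        "S": s_code,
                        "block": b,
                        "B": float(b),
                        "y": y[k],
                    }
                    if use_x:
                        row["x"] = x[k]
                    rows.append(row)
    table = pd.DataFrame(rows)
    planted = {
        "intercept": params.intercept,
        "beta_style": params.beta_style,
        "beta_block": params.beta_block,
        "beta_interaction": params.beta_interaction,
        "beta_x": params.beta_x,
        "beta_sx": params.beta_sx,
        "family": params.family,
    }
    return table, planted
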