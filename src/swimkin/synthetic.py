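"""Synthetic traveling-wave swimmer with ground truth.

Forward model of an undulating, anguilliform-style swimmer that emits what
the experimental pipeline consumes: analytic midlines, rendered binary
silhouettes, and pose-estimation-style landmark tracks, plus a whole-study
generator emulating the experimental design (5 individuals × 2 viscosities ×
2 light levels × 2 lateral-line states × 2 trials, filmed at 500 frames/s,
fish ≈ 128 mm long).

The body is parameterized by arc length s ∈ [0, 1] (s·BL pixels of body).
Lateral displacement in the swimming frame follows an amplitude-enveloped
traveling wave

    y(s, t) = A·BL·E(s) · sin(2π(f·t − s/λ)),

with an amplitude envelope that grows exponentially over the anterior body
and saturates smoothly ahead of the tail: the relative growth rate is
g(s) = α·sigmoid((b − s)/w), giving E(s) = exp(−∫ₛ¹ g) in closed form via
softplus.  The envelope shape is load-bearing, not cosmetic.  An envelope
gradient modulates the body-curvature wave in two ways: a varying relative
gradient g(s) disperses the wave (curvature extrema drift apart from the
displacement wave's λ), and at realistic amplitudes a nonzero gradient
under the tail combines with the arc-length constraint to accelerate
curvature crests well beyond f·λ exactly where the pipeline tracks them
(75–95% BL).  Exponential growth (constant g) kills the first effect over
the anterior body; the saturation (g → 0 past b) kills the second in the
tracking window.  The axial coordinate is obtained by integrating
dx/ds = sqrt(BL² − (dy/ds)²), so the midline arc length is exactly one body
length in every frame (the lateral wave bends the body rather than
stretching it).  The whole fish additionally translates forward at U BL/s.
Viscosity, light and lateral-line state have no physics here: they are
labels whose kinematic consequences are injected through an effect
specification.

Image convention: origin top-left, y increases downward; with the fish
heading in +x, "fish-left" is the −y (upper) side of the image.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from skimage.draw import disk

from .exceptions import TrialRejected
from .io import BinaryFrameStack, PointTrack
from .midline import Midline, MidlineSequence

__all__ = [
    "SwimmerParams",
    "TrialDesign",
    "default_halfwidth",
    "generate_midline_sequence",
    "render_silhouette",
    "emit_tracks",
    "default_study_design",
    "default_effect_spec",
    "generate_study",
    "StudyTrial",
]

FACTOR_LEVELS = {
    "viscosity": (1, 40),
    "light": ("light", "dark"),
    "lateral_line": ("intact", "blocked"),
}


def default_halfwidth(s: np.ndarray, body_length_px: float) -> np.ndarray:
    """Half-width profile (px): blunt elliptical head tapering to a point at the tail."""
    s = np.asarray(s, dtype=float)
    return 0.05 * body_length_px * np.sqrt(np.clip(1.0 - s**2, 0.0, None))


@dataclass
class SwimmerParams:
    """Ground-truth parameters of one synthetic trial.

    Units follow the measured variables: U in BL/s, f and fin_freq in Hz,
    λ and A in BL, lengths in px, rates in frames/s.
    """

    body_length_px: float = 300.0
    swim_speed_U: float = 0.5
    wave_freq_f: float = 2.5
    wavelength_lambda: float = 0.6
    tail_amp_A: float = 0.08
    amp_envelope_growth: float = 0.9  # α: anterior exponential growth rate
    amp_envelope_saturation: float = 0.60  # b: where growth shuts off
    amp_envelope_width: float = 0.06  # w: softness of the shut-off
    fin_freq: float | None = 3.5
    fin_state: str = "On"
    fps: float = 500.0
    duration: float = 2.0
    jitter_sd: float = 1.0
    body_halfwidth_profile: Callable | None = None
    rng_seed: int = 0

    def validate(self) -> "SwimmerParams":
        if not self.wave_freq_f > 0:
            raise ValueError(f"wave_freq_f must be > 0, got {self.wave_freq_f}")
        if not self.wavelength_lambda > 0:
            raise ValueError(
                f"wavelength_lambda must be > 0, got {self.wavelength_lambda}"
            )
        if self.tail_amp_A < 0:
            raise ValueError(f"tail_amp_A must be ≥ 0, got {self.tail_amp_A}")
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.jitter_sd < 0:
            raise ValueError(f"jitter_sd must be ≥ 0, got {self.jitter_sd}")
        if (self.fin_freq is None) != (self.fin_state == "Off"):
            raise ValueError(
                f"fin_freq ({self.fin_freq}) must be absent iff fin_state is "
                f"'Off' (got {self.fin_state!r})"
            )
        return self

    @property
    def halfwidth(self) -> Callable:
        if self.body_halfwidth_profile is not None:
            return self.body_halfwidth_profile
        return lambda s: default_halfwidth(s, self.body_length_px)


@dataclass(frozen=True)
class TrialDesign:
    """One experimental trial: individual × condition × replicate."""

    fish_id: str
    viscosity: int
    light: str
    lateral_line: str
    trial_index: int = 1

    def __post_init__(self):
        for factor in FACTOR_LEVELS:
            value = getattr(self, factor)
            if value not in FACTOR_LEVELS[factor]:
                raise ValueError(
                    f"{factor}={value!r} not in {FACTOR_LEVELS[factor]}"
                )

    @property
    def condition(self) -> tuple:
        return (self.viscosity, self.light, self.lateral_line)

    @property
    def trial_id(self) -> str:
        return (
            f"{self.fish_id}_v{self.viscosity}_{self.light}_"
            f"{self.lateral_line}_t{self.trial_index}"
        )


def _envelope(params: SwimmerParams, s: np.ndarray):
    """Saturating-exponential amplitude envelope E(s) and its derivative.

    Relative growth rate g(s) = α·sigmoid((b−s)/w); E(s) = exp(−∫ₛ¹ g ds′)
    evaluated in closed form through softplus, so E(1) = 1 exactly.
    """
    alpha = params.amp_envelope_growth
    b = params.amp_envelope_saturation
    w = params.amp_envelope_width
    softplus = lambda z: np.logaddexp(0.0, z)
    integral = alpha * w * (softplus((b - s) / w) - softplus((b - 1.0) / w))
    env = np.exp(-integral)
    g = alpha / (1.0 + np.exp((s - b) / w))
    return env, g * env


def _lateral_wave(params: SwimmerParams, s: np.ndarray, t: float):
    """y(s, t) and dy/ds (px and px per unit s) of the traveling wave."""
    bl = params.body_length_px
    amp = params.tail_amp_A * bl
    k = 2.0 * np.pi / params.wavelength_lambda  # phase per unit s
    phase = 2.0 * np.pi * params.wave_freq_f * t - k * s
    env, denv = _envelope(params, s)
    y = amp * env * np.sin(phase)
    dy_ds = amp * (denv * np.sin(phase) - env * k * np.cos(phase))
    return y, dy_ds


def generate_midline_sequence(
    params: SwimmerParams,
    n_points: int = 100,
    origin: tuple = (60.0, 128.0),
) -> MidlineSequence:
    """Analytic midlines of the traveling-wave swimmer, one per frame.

    The head starts at ``origin`` (x, y) and moves in +x at U BL/s.  Refuses
    trials shorter than 3 locomotor cycles, mirroring the experimental trial
    acceptance rule.

    Raises
    ------
    TrialRejected
        If ``duration < 3 / wave_freq_f``.
    ValueError
        If the lateral slope reaches 1 (amplitude too large for the
        arc-length-preserving construction).
    """
    params.validate()
    if params.duration < 3.0 / params.wave_freq_f - 1e-12:
        raise TrialRejected(
            f"trial duration {params.duration} s holds fewer than 3 cycles at "
            f"f={params.wave_freq_f} Hz (needs ≥ {3.0 / params.wave_freq_f:.3g} s)"
        )
    bl = params.body_length_px
    n_frames = int(round(params.duration * params.fps))
    s = np.linspace(0.0, 1.0, n_points)
    x0, y0 = origin
    midlines = []
    for i in range(n_frames):
        t = i / params.fps
        y, dy_ds = _lateral_wave(params, s, t)
        slope = np.abs(dy_ds) / bl
        if np.any(slope >= 0.98):
            raise ValueError(
                "tail amplitude too large for arc-length-preserving midline "
                f"(max lateral slope {slope.max():.2f})"
            )
        dx_ds = np.sqrt(bl**2 - dy_ds**2)
        x = np.concatenate(
            [[0.0], np.cumsum(0.5 * (dx_ds[1:] + dx_ds[:-1]) * np.diff(s))]
        )
        head_x = x0 + params.swim_speed_U * bl * t
        pts = np.column_stack([head_x + x, y0 + y])
        midlines.append(Midline(pts))
    return MidlineSequence(midlines=midlines, fps=params.fps, body_length_px=bl)


def render_silhouette(
    midlines: MidlineSequence,
    params: SwimmerParams,
    shape: tuple = (256, 1024),
) -> BinaryFrameStack:
    """Render midlines to boolean silhouette frames.

    Foreground is the union of disks of radius ``halfwidth(s)`` centred on
    the midline points; because point spacing (BL/N) is below the half-width
    over the body, the union is 8-connected.

    Raises
    ------
    ValueError
        If any disk leaves the image bounds (names the frame), or the
        half-width profile is not strictly positive away from the tail tip.
    """
    h, w = shape
    frames = np.zeros((len(midlines), h, w), dtype=bool)
    for i, ml in enumerate(midlines):
        pts = ml.points
        if len(pts) < 2:
            raise ValueError(f"frame {i}: zero-length midline")
        sf = ml.s_frac
        radii = np.asarray(params.halfwidth(sf), dtype=float)
        if np.any(radii[:-1] <= 0):
            raise ValueError(
                "half-width profile must be strictly positive except at the tail tip"
            )
        if (
            np.any(pts[:, 0] - radii < 0)
            or np.any(pts[:, 0] + radii > w - 1)
            or np.any(pts[:, 1] - radii < 0)
            or np.any(pts[:, 1] + radii > h - 1)
        ):
            raise ValueError(
                f"frame {i}: midline leaves image bounds {shape} "
                f"(x range {pts[:, 0].min():.0f}–{pts[:, 0].max():.0f})"
            )
        frame = frames[i]
        for (x, y), r in zip(pts, radii):
            if r < 0.5:
                continue
            rr, cc = disk((y, x), r, shape=(h, w))
            frame[rr, cc] = True
    return BinaryFrameStack(frames=frames, fps=midlines.fps, px_per_bl=params.body_length_px)


def emit_tracks(midlines: MidlineSequence, params: SwimmerParams) -> PointTrack:
    """Landmark tracks (nose, tail, fin tips) with digitization jitter.

    Fin tips sit on lateral offsets from the body at 25% BL; when the fins
    are beating (``fin_state='On'``) the offset oscillates at ``fin_freq``
    between an adducted and an abducted extreme, otherwise it stays adducted.
    Gaussian jitter of sd ``jitter_sd`` px is added to every coordinate;
    deterministic given ``rng_seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    bl = params.body_length_px
    fin_s = 0.25
    fin_reach = 0.08 * bl

    n = len(midlines)
    names = ["nose", "tail", "fin_left", "fin_right"]
    xy = {name: np.empty((n, 2)) for name in names}
    for i, ml in enumerate(midlines):
        t = i / midlines.fps
        pts = ml.points
        xy["nose"][i] = pts[0]
        xy["tail"][i] = pts[-1]
        base = ml.point_at(fin_s)
        ahead = ml.point_at(min(fin_s + 0.05, 1.0))
        tangent = ahead - base
        tangent = tangent / max(np.linalg.norm(tangent), 1e-9)
        normal = np.array([-tangent[1], tangent[0]])  # fish-right (+y side)
        if params.fin_state == "On":
            d = fin_reach * (0.55 + 0.45 * math.cos(2 * math.pi * params.fin_freq * t))
        else:
            d = 0.3 * fin_reach
        body_edge = params.halfwidth(fin_s)
        xy["fin_right"][i] = base + (body_edge + d) * normal
        xy["fin_left"][i] = base - (body_edge + d) * normal

    confidence = {}
    for name in names:
        if params.jitter_sd > 0:
            xy[name] = xy[name] + rng.normal(0.0, params.jitter_sd, size=(n, 2))
        confidence[name] = rng.uniform(0.9, 1.0, size=n)
    return PointTrack(fps=midlines.fps, xy=xy, confidence=confidence)


def default_study_design(n_fish: int = 5, n_trials: int = 2) -> list:
    """The full factorial design: n_fish × 8 conditions × n_trials."""
    design = []
    for fish, (visc, light, ll), trial in itertools.product(
        range(1, n_fish + 1),
        itertools.product(*FACTOR_LEVELS.values()),
        range(1, n_trials + 1),
    ):
        design.append(
            TrialDesign(
                fish_id=f"fish{fish}",
                viscosity=visc,
                light=light,
                lateral_line=ll,
                trial_index=trial,
            )
        )
    return design


def default_effect_spec() -> dict:
    """Condition → kinematic-shift map emulating the study's treatments.

    Raised viscosity drives the swimmer toward faster body waves, slower
    progress and less fin use; a blocked lateral line and darkness nudge wave
    frequency.  Values are additive shifts on SwimmerParams fields;
    ``fin_off_prob`` shifts the per-trial probability of an all-off fin trial.
    """
    return {
        ("viscosity", 40): {
            "wave_freq_f": 0.5,
            "swim_speed_U": -0.12,
            "fin_off_prob": 0.45,
        },
        ("lateral_line", "blocked"): {"wave_freq_f": 0.2},
        ("light", "dark"): {"wave_freq_f": 0.1},
    }


DEFAULT_FISH_SD = {"wave_freq_f": 0.15, "swim_speed_U": 0.05}
DEFAULT_TRIAL_SD = {"wave_freq_f": 0.10, "swim_speed_U": 0.04}
# fixed draw order: iteration feeds the RNG, so this must never be a set
_SHIFTABLE = (
    "swim_speed_U",
    "wave_freq_f",
    "wavelength_lambda",
    "tail_amp_A",
    "fin_freq",
)


@dataclass
class StudyTrial:
    design: TrialDesign
    params: SwimmerParams


def generate_study(
    design: Iterable[TrialDesign] | None = None,
    effect_spec: dict | None = None,
    base: SwimmerParams | None = None,
    seed: int = 0,
    fish_sd: dict | None = None,
    trial_sd: dict | None = None,
    base_fin_off_prob: float = 0.15,
) -> tuple:
    """Generate per-trial ground-truth parameters for a whole study.

    Per trial: ``params = base + condition shifts + per-fish normal random
    intercept (sd per parameter from fish_sd) + per-trial normal residual
    (trial_sd)``.  Fin state is drawn Bernoulli from a shifted off
    probability.  Returns ``(trials, truth)`` where ``trials`` is a list of
    StudyTrial and ``truth`` the ground-truth DataFrame keyed by trial id;
    fully reproducible from ``seed``.

    Raises
    ------
    ValueError
        If a shifted parameter violates the SwimmerParams invariants (names
        the trial).
    """
    design = list(design) if design is not None else default_study_design()
    effect_spec = default_effect_spec() if effect_spec is None else effect_spec
    base = base or SwimmerParams()
    fish_sd = DEFAULT_FISH_SD if fish_sd is None else fish_sd
    trial_sd = DEFAULT_TRIAL_SD if trial_sd is None else trial_sd

    for cond_key, shifts in effect_spec.items():
        for value in shifts.values():
            if not np.isfinite(value):
                raise ValueError(f"non-finite shift in effect_spec[{cond_key}]")

    rng = np.random.default_rng(seed)
    fish_ids = sorted({d.fish_id for d in design})
    intercepts = {
        fish: {p: rng.normal(0.0, sd) for p, sd in fish_sd.items()}
        for fish in fish_ids
    }

    trials = []
    rows = []
    for d in design:
        shifts: dict = {}
        fin_off = base_fin_off_prob
        for factor in FACTOR_LEVELS:
            key = (factor, getattr(d, factor))
            for param, delta in effect_spec.get(key, {}).items():
                if param == "fin_off_prob":
                    fin_off += delta
                else:
                    shifts[param] = shifts.get(param, 0.0) + delta
        values = {}
        for param in _SHIFTABLE:
            v = getattr(base, param)
            if v is None:
                continue
            v = (
                v
                + shifts.get(param, 0.0)
                + intercepts[d.fish_id].get(param, 0.0)
                + (rng.normal(0.0, trial_sd[param]) if param in trial_sd else 0.0)
            )
            values[param] = v
        fins_on = rng.uniform() >= np.clip(fin_off, 0.0, 1.0)
        trial_seed = int(rng.integers(0, 2**31 - 1))
        fin_freq = values.pop("fin_freq", base.fin_freq)
        p = replace(
            base,
            **values,
            fin_freq=fin_freq if fins_on else None,
            fin_state="On" if fins_on else "Off",
            rng_seed=trial_seed,
        )
        try:
            p.validate()
        except ValueError as exc:
            raise ValueError(f"trial {d.trial_id}: {exc}") from exc
        trials.append(StudyTrial(design=d, params=p))
        rows.append(
            {
                "trial_id": d.trial_id,
                "fish_id": d.fish_id,
                "viscosity": d.viscosity,
                "light": d.light,
                "lateral_line": d.lateral_line,
                "trial_index": d.trial_index,
                "swim_speed_U": p.swim_speed_U,
                "wave_freq_f": p.wave_freq_f,
                "wavelength_lambda": p.wavelength_lambda,
                "tail_amp_A": p.tail_amp_A,
                "fin_freq": p.fin_freq if p.fin_freq is not None else np.nan,
                "fin_state": p.fin_state,
                "rng_seed": trial_seed,
            }
        )
    return trials, pd.DataFrame(rows)
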