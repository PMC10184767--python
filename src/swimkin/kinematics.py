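"""The seven magnitude variables of undulatory swimming.

From filtered landmark tracks and a midline sequence, one trial yields:

* swimming speed U (BL/s) — net displacement of the nose–tail midpoint over
  whole locomotor cycles;
* pectoral fin frequency (Hz) — fin-beat cycles per second, a cycle running
  between consecutive adductions of the right pectoral fin; not recorded
  (missing, never zero) when no beats occur;
* pectoral fin state — On iff a fin frequency was recorded;
* tail amplitude A (BL) — half the perpendicular distance from an
  intervening fish-right tail peak to the chord through the two flanking
  fish-left peaks (the chord construction removes forward drift);
* body wave frequency f (Hz) — locomotor cycles per second, a cycle running
  between consecutive same-side maximum tail excursions;
* body wave speed V (%BL/s) — transit speed of a tracked body-curvature
  extremum from 75% to 95% BL;
* body wavelength λ (BL) — chord distance between consecutive same-sign
  curvature extrema along the body.

Trials with fewer than 3 locomotor cycles are rejected, mirroring the
experimental trial-acceptance rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .exceptions import FilterError, FlatSeries, TrialRejected
from .filtering import ScalarSeries, dominant_frequency, lowpass_adaptive
from .io import PointTrack
from .midline import (
    CurvatureField,
    Midline,
    MidlineSequence,
    curvature_field,
    estimate_body_length,
)

__all__ = [
    "PeakEvent",
    "TrialKinematics",
    "tail_lateral_series",
    "detect_tail_peaks",
    "swimming_speed",
    "tail_amplitude",
    "body_wave_frequency",
    "pectoral_fin_frequency",
    "fin_state",
    "conditioned_curvature_field",
    "body_wave_speed",
    "body_wavelength",
    "assemble_trial",
]

LEFT, RIGHT = "fish-left", "fish-right"


def _cross2(a, b):
    """z-component of the 2D cross product (broadcasting)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

# absolute floor (px) on fin-beat excursion: filtered digitization jitter on a
# non-beating fin must never register as adduction events
MIN_FIN_EXCURSION_PX = 3.0


@dataclass(frozen=True)
class PeakEvent:
    """One maximum tail excursion (or fin event): when, which side, how far."""

    frame: int
    time: float
    side: str
    lateral_excursion: float  # signed, px


@dataclass
class TrialKinematics:
    """One trial's magnitude variables; one row of the statistical table."""

    swim_speed_U: float
    fin_freq: float | None
    fin_state: str
    tail_amp_A: float
    wave_freq_f: float
    wave_speed_V: float | None  # %BL/s; None if no complete 75→95% transit
    wavelength_lambda: float | None
    wavelength_fullwave_diag: float | None = None
    n_cycles: int = 0
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "swim_speed_U": self.swim_speed_U,
            "fin_freq": np.nan if self.fin_freq is None else self.fin_freq,
            "fin_state": self.fin_state,
            "tail_amp_A": self.tail_amp_A,
            "wave_freq_f": self.wave_freq_f,
            "wave_speed_V": np.nan if self.wave_speed_V is None else self.wave_speed_V,
            "wavelength_lambda": (
                np.nan if self.wavelength_lambda is None else self.wavelength_lambda
            ),
            "wavelength_fullwave_diag": (
                np.nan
                if self.wavelength_fullwave_diag is None
                else self.wavelength_fullwave_diag
            ),
            "n_cycles": self.n_cycles,
        }
        d.update(self.metadata)
        return d


def _pca_heading(points: np.ndarray) -> tuple:
    """Least-squares (total) heading line through 2D points: (centroid, unit direction)."""
    c = points.mean(axis=0)
    d = points - c
    cov = d.T @ d
    w, v = np.linalg.eigh(cov)
    u = v[:, np.argmax(w)]
    return c, u


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with reflect padding (length preserved)."""
    window = max(1, int(window))
    if window % 2 == 0:
        window += 1
    if window <= 1 or window >= 2 * len(x):
        return np.full_like(x, x.mean())
    pad = window // 2
    xp = np.pad(x, pad, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")


def tail_lateral_series(
    track: PointTrack, window_cycles: float = 1.0, f_hint: float | None = None
) -> ScalarSeries:
    """Signed lateral excursion of the tail about the swimming axis.

    The heading is the total-least-squares line through the *cycle-averaged*
    nose–tail midpoint trajectory (averaging over one locomotor cycle first,
    so the lateral oscillation cannot tilt the fit), and the resulting
    excursion signal is detrended by its own one-cycle moving average so
    residual drift and gentle path curvature do not leak into peak
    detection.  Sign: positive = fish-left (the −y side under the y-down
    raster convention when heading in +x).
    """
    nose = track.require("nose")
    tail = track.require("tail")
    center = 0.5 * (nose + tail)
    c0, u0 = _pca_heading(center)
    # a stationary fish's center trajectory is dominated by the lateral
    # oscillation itself, so the PCA axis turns perpendicular to the body;
    # when that happens the mean body axis is the trustworthy heading
    body_axis = (nose - tail).mean(axis=0)
    body_axis = body_axis / max(np.linalg.norm(body_axis), 1e-9)
    if abs(np.dot(u0, body_axis)) < 0.7:
        u0 = body_axis
    net = center[-1] - center[0]
    ref = net if np.linalg.norm(net) > 1e-9 else body_axis
    if np.dot(u0, ref) < 0:
        u0 = -u0
    n0 = np.array([u0[1], -u0[0]])  # fish-left normal (y-down raster)

    lateral = (tail - c0) @ n0
    if f_hint is None:
        try:
            f_hint = dominant_frequency(ScalarSeries(lateral, track.fps))
        except FlatSeries:
            f_hint = None
    if f_hint is None:
        return ScalarSeries(lateral - lateral.mean(), track.fps)

    period = int(round(window_cycles * track.fps / f_hint))
    smoothed = np.column_stack(
        [_moving_average(center[:, 0], period), _moving_average(center[:, 1], period)]
    )
    c1, u1 = _pca_heading(smoothed)
    if abs(np.dot(u1, body_axis)) < 0.7:
        u1 = body_axis
    if np.dot(u1, u0) < 0:
        u1 = -u1
    n1 = np.array([u1[1], -u1[0]])
    lateral = (tail - c1) @ n1
    return ScalarSeries(lateral - _moving_average(lateral, period), track.fps)


def detect_tail_peaks(
    tail_lateral: ScalarSeries,
    f_est: float | None = None,
    prominence_frac: float = 0.10,
    min_spacing_cycles: float = 0.3,
) -> list:
    """Maximum tail excursions on both sides, alternation enforced.

    Local extrema with prominence ≥ 10% of the series range and spacing
    ≥ 0.3 periods of the estimated frequency; of two consecutive same-side
    peaks the larger excursion is kept so sides alternate.

    Raises
    ------
    TrialRejected
        If fewer than 3 same-side peaks remain (the steady-swimming rule).
    """
    v = tail_lateral.values
    if f_est is None:
        try:
            f_est = dominant_frequency(tail_lateral)
        except FlatSeries as exc:
            raise TrialRejected(str(exc)) from exc
    rng_v = np.ptp(v)
    if rng_v <= 0:
        raise TrialRejected("flat tail excursion: no locomotor cycles")
    distance = max(1, int(round(min_spacing_cycles / f_est * tail_lateral.fps)))
    prom = prominence_frac * rng_v
    peaks_l, _ = find_peaks(v, prominence=prom, distance=distance)
    peaks_r, _ = find_peaks(-v, prominence=prom, distance=distance)

    events = [
        PeakEvent(int(i), i / tail_lateral.fps, LEFT, float(v[i])) for i in peaks_l
    ] + [PeakEvent(int(i), i / tail_lateral.fps, RIGHT, float(v[i])) for i in peaks_r]
    events.sort(key=lambda e: e.time)

    cleaned: list = []
    for ev in events:
        if cleaned and cleaned[-1].side == ev.side:
            if abs(ev.lateral_excursion) > abs(cleaned[-1].lateral_excursion):
                cleaned[-1] = ev
        else:
            cleaned.append(ev)

    n_left = sum(e.side == LEFT for e in cleaned)
    n_right = len(cleaned) - n_left
    if max(n_left, n_right) < 3:
        raise TrialRejected(
            f"only {max(n_left, n_right)} same-side tail peaks: fewer than 3 "
            "steady locomotor cycles in a row"
        )
    return cleaned


def _same_side_times(peaks, side):
    return np.array([e.time for e in peaks if e.side == side])


def n_locomotor_cycles(peaks: list) -> int:
    """Completed same-side-to-same-side cycles (max over sides)."""
    return max(
        len(_same_side_times(peaks, LEFT)) - 1,
        len(_same_side_times(peaks, RIGHT)) - 1,
    )


def swimming_speed(
    track: PointTrack, body_length_px: float, peaks: list | None = None
) -> float:
    """Swimming speed U in BL/s from the nose–tail midpoint trajectory.

    With detected peaks, positions are averaged over the first and last
    whole cycles so the lateral oscillation does not bias the net
    displacement; otherwise the full record is used.
    """
    nose = track.require("nose")
    tail = track.require("tail")
    center = 0.5 * (nose + tail)
    fps = track.fps

    if peaks is not None:
        side = (
            LEFT
            if len(_same_side_times(peaks, LEFT)) >= len(_same_side_times(peaks, RIGHT))
            else RIGHT
        )
        t = _same_side_times(peaks, side)
        # peaks within ~a period of the record edges are displaced by the
        # detrending's edge handling; drop them when enough cycles remain
        if len(t) >= 4:
            T = float(np.median(np.diff(t)))
            t_end = (len(center) - 1) / fps
            if t[0] < 0.75 * T and len(t) >= 4:
                t = t[1:]
            if t_end - t[-1] < 0.75 * T and len(t) >= 4:
                t = t[:-1]
        if len(t) >= 3:
            f0, f1 = int(round(t[0] * fps)), int(round(t[1] * fps))
            g0, g1 = int(round(t[-2] * fps)), int(round(t[-1] * fps))
            # half-open windows: a whole period of the oscillation averages out
            p_start = center[f0:f1].mean(axis=0)
            p_end = center[g0:g1].mean(axis=0)
            dt = 0.5 * (t[-2] + t[-1]) - 0.5 * (t[0] + t[1])
            if dt > 0:
                return float(np.linalg.norm(p_end - p_start) / dt / body_length_px)
    dt = (len(center) - 1) / fps
    return float(np.linalg.norm(center[-1] - center[0]) / dt / body_length_px)


def tail_amplitude(
    peaks: list, tail_xy: np.ndarray, body_length_px: float
) -> float:
    """Tail amplitude A in BL via the drift-free chord construction.

    For every left–right–left peak triple, the perpendicular distance from
    the right-peak tail position to the line through the two left-peak tail
    positions, halved and normalized by BL; the trial value is the mean over
    triples.

    Raises
    ------
    TrialRejected
        If no valid (left, right, left) triple exists.
    """
    vals = []
    for a, b, c in zip(peaks, peaks[1:], peaks[2:]):
        if not (a.side == LEFT and b.side == RIGHT and c.side == LEFT):
            continue
        p1, p2 = tail_xy[a.frame], tail_xy[c.frame]
        q = tail_xy[b.frame]
        chord = p2 - p1
        L = np.linalg.norm(chord)
        if L < 1e-9:
            dist = np.linalg.norm(q - p1)
        else:
            dist = abs(_cross2(chord, q - p1)) / L
        vals.append(0.5 * dist / body_length_px)
    if not vals:
        raise TrialRejected("no left–right–left tail-peak triple for amplitude")
    return float(np.mean(vals))


def body_wave_frequency(peaks: list) -> float:
    """Body wave frequency f (Hz): mean of 1/Δt over consecutive same-side peaks."""
    rates = []
    for side in (LEFT, RIGHT):
        t = _same_side_times(peaks, side)
        if len(t) >= 2:
            rates.extend(1.0 / np.diff(t))
    if not rates:
        raise TrialRejected("no same-side peak pair for wave frequency")
    return float(np.mean(rates))


def _fin_body_distance(
    track: PointTrack,
    fin: str,
    midlines: MidlineSequence | None = None,
    fin_station: float = 0.25,
) -> ScalarSeries:
    """Per-frame perpendicular distance of a fin tip to the local body axis.

    With midlines available the distance is measured to the midline curve
    itself (nearest point over the anterior body, 5–55% BL).  This equals
    the fin's abduction exactly regardless of how the body is bent — a
    chord or tangent-line axis picks up the bending wave's sagitta, which
    at study amplitudes dwarfs a resting fin's jitter and would turn every
    fins-off trial into a false fin beat at the body frequency.  Without
    midlines the nose–tail chord serves as a fallback axis.
    """
    tip = track.require(fin)
    if midlines is not None and len(midlines) == len(tip):
        d = np.empty(len(tip))
        lo, hi = max(0.0, fin_station - 0.2), min(1.0, fin_station + 0.3)
        for i, ml in enumerate(midlines):
            sf = ml.s_frac
            seg = ml.points[(sf >= lo) & (sf <= hi)]
            d[i] = np.min(np.linalg.norm(seg - tip[i], axis=1))
        return ScalarSeries(d, track.fps)
    nose = track.require("nose")
    tail = track.require("tail")
    axis = nose - tail
    L = np.linalg.norm(axis, axis=1)
    L = np.where(L < 1e-9, 1.0, L)
    d = np.abs(_cross2(axis, tip - tail)) / L
    return ScalarSeries(d, track.fps)


def pectoral_fin_frequency(
    track: PointTrack,
    midlines: MidlineSequence | None = None,
    body_freq: float | None = None,
    fin: str = "fin_right",
    filter_multiple: float = 5.0,
    min_excursion_px: float = MIN_FIN_EXCURSION_PX,
) -> float | None:
    """Pectoral fin frequency (Hz) from right-fin adduction events, or None.

    Adductions are local minima of the fin tip's perpendicular distance to
    the body axis, found with the same prominence/spacing rules as tail-peak
    detection on a series filtered at 5× the fin frequency (5× the body
    frequency when the fin tone is undetectable).  Fewer than two adductions,
    or a fin excursion below the absolute jitter floor, means no fin beats:
    the frequency is *absent*, never zero.
    """
    raw = _fin_body_distance(track, fin, midlines)
    try:
        f_fin = dominant_frequency(raw)
    except FlatSeries:
        return None
    # gate on the amplitude of the detected tone itself: broadband jitter on
    # a resting fin can still put its largest spectral peak anywhere, but
    # that peak's amplitude is tiny compared with a real fin beat
    x = raw.values - raw.values.mean()
    t = np.arange(len(x)) / raw.fps
    tone_amp = 2.0 * abs(np.sum(x * np.exp(-2j * np.pi * f_fin * t))) / len(x)
    if tone_amp < 0.5 * min_excursion_px:
        return None
    base = f_fin if f_fin > 0 else body_freq
    if base is None:
        return None
    cutoff_base = base
    if filter_multiple * cutoff_base >= raw.fps / 2 and body_freq:
        cutoff_base = body_freq
    filt = lowpass_adaptive(raw, cutoff_base, filter_multiple)
    if np.ptp(filt.values) < min_excursion_px:
        return None
    distance = max(1, int(round(0.3 / f_fin * raw.fps)))
    prom = 0.10 * np.ptp(filt.values)
    minima, _ = find_peaks(-filt.values, prominence=prom, distance=distance)
    if len(minima) < 2:
        return None
    dt = np.diff(minima) / raw.fps
    return float(np.mean(1.0 / dt))


def fin_state(fin_freq: float | None) -> str:
    """'On' iff a fin frequency was recorded for the trial."""
    return "On" if fin_freq is not None else "Off"


def conditioned_curvature_field(
    midlines: MidlineSequence,
    body_freq: float | None = None,
    filter_multiple: float = 5.0,
    spatial_cutoff_bl: float = 4.0,
) -> CurvatureField:
    """Curvature field with the noise conditioning the wave variables need.

    Midline coordinates are zero-phase low-passed in *time* at 5× the body
    wave frequency (the same adaptive rule applied to digitized points), and
    the resulting κ(s, t) rows are zero-phase low-passed in *space* at
    ``spatial_cutoff_bl`` cycles per body length.  The spatial cutoff sits
    well above the body wave's spatial frequency (1/λ ≈ 1.5–2.5 cycles/BL)
    and well below the pixel-quantization ripple of extracted midlines
    (≳10 cycles/BL); without it, broad curvature extrema split into
    doublets and wavelength/wave-speed tracking falls apart on real
    silhouettes.  Analytic midlines pass through essentially unchanged.
    """
    from scipy import signal as sps

    n = len(midlines[0].points)
    xy = np.array([m.resample(n).points if len(m.points) != n else m.points for m in midlines])
    fps = midlines.fps
    if body_freq is not None and len(midlines) > 30:
        cutoff = filter_multiple * body_freq
        if cutoff < fps / 2.0:
            sos = sps.butter(4, cutoff, btype="low", fs=fps, output="sos")
            padlen = min(int(round(fps / cutoff)), xy.shape[0] - 1)
            xy = sps.sosfiltfilt(sos, xy, axis=0, padtype="even", padlen=padlen)
    seq = MidlineSequence([Midline(p) for p in xy], fps)
    cf = curvature_field(seq)
    if spatial_cutoff_bl and spatial_cutoff_bl < n / 2.0:
        sos_s = sps.butter(4, spatial_cutoff_bl, btype="low", fs=float(n), output="sos")
        cf.kappa = sps.sosfiltfilt(sos_s, cf.kappa, axis=1, padtype="even")
    return cf


def _frame_extrema(
    kappa_row: np.ndarray, s: np.ndarray, sign: int, prom: float, height: float | None = None
):
    """Refined s positions of local extrema of sign*κ along the body.

    Peaks qualify by prominence, or by absolute height when ``height`` is
    given: a crest approaching the tail end of the body has no right-hand
    saddle, so its prominence collapses even though it is the strongest
    feature on the body.
    """
    v = sign * kappa_row
    idx, _ = find_peaks(v, prominence=prom)
    if height is not None:
        idx_h, _ = find_peaks(v, height=height, distance=max(2, len(v) // 50))
        idx = np.union1d(idx, idx_h)
    out = []
    ds = s[1] - s[0]
    for j in idx:
        if 0 < j < len(v) - 1:
            a, b, c = v[j - 1], v[j], v[j + 1]
            denom = a - 2 * b + c
            delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        out.append(s[j] + delta * ds)
    return out


def _track_extrema(positions_per_frame: list, max_jump: float, max_gap: int = 2):
    """Greedy nearest-position continuity tracking of extrema across frames.

    Returns a list of tracks, each a list of (frame, s) samples.
    """
    tracks: list = []
    active: list = []  # [track_idx, last_frame, last_s]
    all_tracks: list = []
    for fr, positions in enumerate(positions_per_frame):
        positions = sorted(positions)
        used = [False] * len(positions)
        for rec in active:
            _, last_fr, last_s = rec
            best, best_d = None, max_jump
            for i, s in enumerate(positions):
                if used[i]:
                    continue
                d = abs(s - last_s)
                if d < best_d:
                    best, best_d = i, d
            if best is not None:
                used[best] = True
                all_tracks[rec[0]].append((fr, positions[best]))
                rec[1], rec[2] = fr, positions[best]
        active = [rec for rec in active if fr - rec[1] <= max_gap]
        for i, s in enumerate(positions):
            if not used[i]:
                all_tracks.append([(fr, s)])
                active.append([len(all_tracks) - 1, fr, s])
    return all_tracks


def body_wave_speed(
    curv: CurvatureField,
    fps: float | None = None,
    s_lo: float = 0.75,
    s_hi: float = 0.95,
    max_jump: float = 0.1,
    prominence_frac: float = 0.05,
) -> float | None:
    """Body wave speed V in %BL/s: curvature-crest transit from 75% to 95% BL.

    Local extrema of κ(s) of each bending sign are tracked frame-to-frame by
    nearest-position continuity; for every tracked extremum that crosses
    both stations tailward, the transit speed is (s_hi − s_lo)/(t95 − t75) ×
    100, and the trial value averages all complete crossings of both signs.
    Returns None (with a warning) when no extremum completes the transit —
    e.g. a standing flexion.
    """
    fps = fps or curv.fps
    s = curv.s_frac
    prom = prominence_frac * np.max(np.abs(curv.kappa))
    if prom == 0:
        warnings.warn("curvature field is identically zero; no wave to track")
        return None
    height = 0.5 * np.max(np.abs(curv.kappa))
    speeds = []
    for sign in (+1, -1):
        per_frame = [
            _frame_extrema(row, s, sign, prom, height=height) for row in curv.kappa
        ]
        for trk in _track_extrema(per_frame, max_jump=max_jump):
            if len(trk) < 3:
                continue
            frames = np.array([p[0] for p in trk], dtype=float)
            pos = np.array([p[1] for p in trk], dtype=float)
            t75 = _crossing_time(frames, pos, s_lo)
            t95 = _crossing_time(frames, pos, s_hi)
            if t75 is not None and t95 is not None and t95 > t75:
                speeds.append((s_hi - s_lo) / ((t95 - t75) / fps) * 100.0)
    if not speeds:
        warnings.warn(
            f"no curvature extremum completed the {s_lo:.0%}→{s_hi:.0%} BL transit; "
            "wave speed missing"
        )
        return None
    return float(np.mean(speeds))


def _crossing_time(frames: np.ndarray, pos: np.ndarray, station: float):
    """Interpolated frame time at which a tailward-moving track crosses a station."""
    for i in range(len(pos) - 1):
        if pos[i] <= station <= pos[i + 1] and pos[i + 1] > pos[i]:
            frac = (station - pos[i]) / (pos[i + 1] - pos[i])
            return frames[i] + frac * (frames[i + 1] - frames[i])
    return None


def body_wavelength(
    curv: CurvatureField,
    body_length_px: float,
    prominence_frac: float = 0.05,
) -> tuple:
    """Body wavelength λ in BL from curvature-extrema spacing.

    Primary reading: per frame, twice the chord (straight-line) distance
    between *adjacent opposite-sign* curvature extrema along the midline,
    normalized by BL, averaged over frames and pairs.  A companion
    diagnostic reports the consecutive *same-sign* spacing (the full-wave
    chord).  On a body bent at realistic amplitudes the full-wave chord is
    systematically compressed — the axial span of one wavelength of arc
    shrinks by the mean of √(1−y′²) while the endpoints' lateral offsets
    cancel (same phase); in the half-wave chord the endpoints sit on
    opposite sides, and their lateral separation compensates the axial
    compression almost exactly, so ×2 it is the less biased wavelength
    estimate.  Returns ``(lambda, samesign_diagnostic)``; both None (with a
    warning) when no frame carries two extrema.
    """
    s = curv.s_frac
    prom = prominence_frac * np.max(np.abs(curv.kappa))
    if prom == 0:
        warnings.warn("curvature field is identically zero; wavelength missing")
        return None, None
    full, half = [], []
    for row, pts in zip(curv.kappa, curv.xy):
        ext = []
        for sign in (+1, -1):
            ext.extend((p, sign) for p in _frame_extrema(row, s, sign, prom))
        ext.sort()

        def chord(s1, s2):
            p1 = np.column_stack(
                [np.interp(s1, s, pts[:, 0]), np.interp(s1, s, pts[:, 1])]
            )[0]
            p2 = np.column_stack(
                [np.interp(s2, s, pts[:, 0]), np.interp(s2, s, pts[:, 1])]
            )[0]
            return np.linalg.norm(p2 - p1) / body_length_px

        for sign in (+1, -1):
            same = [p for p, sgn in ext if sgn == sign]
            full.extend(chord(a, b) for a, b in zip(same, same[1:]))
        half.extend(
            2.0 * chord(a[0], b[0])
            for a, b in zip(ext, ext[1:])
            if a[1] != b[1]
        )
    if not full and not half:
        warnings.warn("no frame with two curvature extrema; wavelength missing")
        return None, None
    lam = float(np.mean(half)) if half else None
    diag = float(np.mean(full)) if full else None
    if lam is None:
        warnings.warn(
            "no opposite-sign curvature-extrema pair; only the full-wave "
            "chord diagnostic is available"
        )
    return lam, diag


def assemble_trial(
    track: PointTrack,
    midlines: MidlineSequence,
    metadata: dict | None = None,
    filter_multiple: float = 5.0,
    min_cycles: int = 3,
    min_tail_excursion_bl: float = 0.01,
) -> TrialKinematics:
    """Run the whole per-trial pipeline and assemble the seven variables.

    Steps: body length from midlines → tail lateral excursion about the
    local heading → dominant frequency → 5× zero-phase low-pass → peak
    detection and the ≥3-cycle acceptance rule → U, A, f from the track →
    fin frequency/state from the right fin → V and λ from the curvature
    field.  A missing fin frequency propagates as missing; any rejected
    sub-computation raises TrialRejected with its reasons.
    """
    bl = midlines.body_length_px or estimate_body_length(midlines)
    raw = tail_lateral_series(track)
    try:
        f0 = dominant_frequency(raw)
        filt = lowpass_adaptive(raw, f0, filter_multiple)
    except (FlatSeries, FilterError) as exc:
        # a flat trace, or a "dominant" tone so high that the 5× cutoff hits
        # Nyquist, both mean there is no coherent body oscillation
        raise TrialRejected(f"no body oscillation: {exc}") from exc
    if np.ptp(filt.values) < min_tail_excursion_bl * bl:
        raise TrialRejected(
            f"tail excursion {np.ptp(filt.values):.2f} px below "
            f"{min_tail_excursion_bl:.0%} BL: no locomotor cycles"
        )
    peaks = detect_tail_peaks(filt, f_est=f0)
    ncyc = n_locomotor_cycles(peaks)
    if ncyc < min_cycles:
        raise TrialRejected(
            f"{ncyc} locomotor cycles: fewer than the required {min_cycles}"
        )
    f = body_wave_frequency(peaks)
    A = tail_amplitude(peaks, track.require("tail"), bl)
    U = swimming_speed(track, bl, peaks)
    ffin = pectoral_fin_frequency(track, midlines, body_freq=f)
    curv = conditioned_curvature_field(midlines, body_freq=f, filter_multiple=filter_multiple)
    V = body_wave_speed(curv, fps=midlines.fps)
    lam, lam_diag = body_wavelength(curv, bl)
    return TrialKinematics(
        swim_speed_U=U,
        fin_freq=ffin,
        fin_state=fin_state(ffin),
        tail_amp_A=A,
        wave_freq_f=f,
        wave_speed_V=V,
        wavelength_lambda=lam,
        wavelength_fullwave_diag=lam_diag,
        n_cycles=ncyc,
        metadata=metadata or {},
    )
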