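"""Synthetic microscopy data with planted ground truth.

Every generator emulates one acquisition used by the analysis pipeline:

- bead movies: 20 nm fluorescent beads undergoing Brownian motion
  (Stokes-Einstein diffusivity) superposed on a planted flow profile inside
  the canal, imaged at 10 Hz for 30 s with 189 nm pixels, Gaussian PSF and
  Gaussian camera noise;
- cilia movies: 100 Hz, 3 s recordings of cilia oscillating at planted
  frequencies, rendered as elliptical footprints (length, tilt) whose
  intensity is modulated sinusoidally at the beat frequency;
- dye-filled canal z-stack phantoms of known width for diameter
  measurement;
- transmitted-light intensity series with contraction artifacts paired with
  a flow series (fast pulse followed by a slower exponential counter-flow);
- widefield front-tracking series rendered from transport-simulation
  marginals.

All generators take an integer ``seed`` and are byte-for-byte reproducible;
each returns its planted ground truth alongside the images.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .hydro import AnalyticalProfile, evaluate_profile
from .transport import ConcentrationField, stokes_einstein
from .videoflow import BeadVideo
from .ciliamap import CiliaVideo

__all__ = [
    "SyntheticSpec",
    "make_bead_video",
    "make_cilia_video",
    "make_canal_phantom",
    "make_contraction_series",
    "make_front_series",
]


@dataclass
class SyntheticSpec:
    """Acquisition and physics parameters for a synthetic bead movie.

    Defaults reproduce the reference recording conditions: 10 Hz for 30 s,
    189 nm pixels, 20 nm beads at 301 K in a 8.9 um canal.
    """

    seed: int
    d_um: float = 8.9
    length_um: float = 48.0
    pixel_size_um: float = 0.189
    frame_interval_s: float = 0.1
    duration_s: float = 30.0
    n_beads: int = 80
    bead_radius_m: float = 20e-9
    temperature_K: float = 301.0
    viscosity_Pa_s: float = 1e-3
    # Effective bead diffusivity in CSF.  Free-water Stokes-Einstein for
    # 20 nm beads (~11 um^2/s) would sweep a bead across the whole canal in
    # seconds; the recorded bead videos instead show Brownian displacements
    # of the same order as the flow displacement per frame (~0.5 um), i.e.
    # strongly hindered diffusion.  The default reproduces that observed
    # dynamics; set to None to use Stokes-Einstein, or supply any value.
    D_um2_s: float | None = 1.25
    bead_amp: float = 30.0
    psf_sigma_px: float = 1.2
    read_noise: float = 6.0
    background: float = 100.0
    margin_px: int = 10  # dark rows beyond each canal wall

    def __post_init__(self) -> None:
        if self.D_um2_s is None:
            self.D_um2_s = (
                stokes_einstein(self.bead_radius_m, self.temperature_K, self.viscosity_Pa_s)
                * 1e12
            )


def _render_spots(ny, nx, ys, xs, amp, sigma):
    """Sum of Gaussian spots at subpixel positions (ys, xs) in pixels."""
    frame = np.zeros((ny, nx))
    r = int(np.ceil(4 * sigma))
    for y, x in zip(ys, xs):
        iy, ix = int(round(y)), int(round(x))
        y0, y1 = max(iy - r, 0), min(iy + r + 1, ny)
        x0, x1 = max(ix - r, 0), min(ix + r + 1, nx)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        frame[y0:y1, x0:x1] += amp * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
        )
    return frame


def make_bead_video(
    spec: SyntheticSpec, profile: AnalyticalProfile | None = None
) -> tuple[BeadVideo, pd.DataFrame]:
    """Simulate and render a bead movie over a planted flow profile.

    Bead dynamics per frame: advection by v(y) dt plus independent Brownian
    steps N(0, 2 D dt) per axis, reflective canal walls in y, periodic in x.
    Returns the rendered video (ventral wall at the top of the canal band,
    i.e. at row ``margin_px``) and a truth table with per-frame positions
    (um, canal coordinates) and each bead's mean planted velocity.
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    nt = int(round(spec.duration_s / spec.frame_interval_s))
    d, L = spec.d_um, spec.length_um
    ny = int(round(d / px)) + 2 * spec.margin_px
    nx = int(round(L / px))
    dt = spec.frame_interval_s
    sig_step = np.sqrt(2 * spec.D_um2_s * dt)

    y = rng.uniform(0.0, d, spec.n_beads)
    x = rng.uniform(0.0, L, spec.n_beads)

    def v_um_s(yy):
        if profile is None:
            return np.zeros_like(yy)
        return np.asarray(evaluate_profile(profile, np.clip(yy * 1e-6, 0, profile.d))) * 1e6

    frames = np.empty((nt, ny, nx))
    recs = []
    vsum = np.zeros(spec.n_beads)
    for t in range(nt):
        vt = v_um_s(y)
        vsum += vt
        for b in range(spec.n_beads):
            recs.append((t, b, x[b], y[b], vt[b]))
        rows = spec.margin_px + y / px
        cols = np.mod(x, L) / px
        clean = spec.background + _render_spots(
            ny, nx, rows, cols, spec.bead_amp, spec.psf_sigma_px
        )
        frames[t] = clean + rng.normal(0.0, spec.read_noise, (ny, nx))
        # advance: advection + Brownian, reflective walls
        x = x + vt * dt + rng.normal(0.0, sig_step, spec.n_beads)
        y = y + rng.normal(0.0, sig_step, spec.n_beads)
        y = np.abs(y)
        y = d - np.abs(d - y)
        x = np.mod(x, L)

    truth = pd.DataFrame(recs, columns=["frame", "bead", "x_um", "y_um", "v_um_s"])
    truth.attrs["mean_velocity_um_s"] = vsum / nt
    truth.attrs["margin_px"] = spec.margin_px
    truth.attrs["D_um2_s"] = spec.D_um2_s
    video = BeadVideo(frames, pixel_size_um=px, frame_interval_s=dt)
    return video, truth


def make_cilia_video(
    cilia: list[dict],
    *,
    seed: int,
    shape_px: tuple = (96, 256),
    frame_rate_hz: float = 100.0,
    duration_s: float = 3.0,
    pixel_size_um: float = 0.189,
    midline_row: float | None = None,
    beat_width_um: float = 2.4,
    amp: float = 40.0,
    noise: float = 1.0,
) -> tuple[CiliaVideo, pd.DataFrame]:
    """Render oscillating cilia and return the video plus a truth table.

    Each entry of ``cilia`` is a dict with keys ``base_row``, ``base_col``
    (px, the anchoring point), ``length_um``, ``theta_deg`` (signed tilt
    from the dorso-ventral axis, + = caudal), ``freq_hz`` and optional
    ``phase``.  The cilium occupies an elliptical footprint whose major
    axis follows the tilt; its intensity is modulated sinusoidally at the
    beat frequency, emulating the periodic fluorescence signal of a beating
    filament.  Frequencies must stay below Nyquist.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape_px
    nt = int(round(duration_s * frame_rate_hz))
    if midline_row is None:
        midline_row = ny / 2
    for c in cilia:
        if c["freq_hz"] >= frame_rate_hz / 2:
            raise ValueError(
                f"planted frequency {c['freq_hz']} Hz is at or above Nyquist"
            )

    yy, xx = np.mgrid[:ny, :nx].astype(float)
    t = np.arange(nt) / frame_rate_hz
    stack = np.full((nt, ny, nx), 10.0)
    rows = []
    for c in cilia:
        L_px = c["length_um"] / pixel_size_um
        B_px = beat_width_um / pixel_size_um / 2
        th = np.radians(c["theta_deg"])
        # major-axis unit vector measured from the row (D-V) axis;
        # positive theta tilts toward larger column index (caudal)
        ur, uc = np.cos(th), np.sin(th)
        cy = c["base_row"] + ur * L_px / 2
        cx = c["base_col"] + uc * L_px / 2
        # coordinates along/across the major axis
        par = (yy - cy) * ur + (xx - cx) * uc
        per = -(yy - cy) * uc + (xx - cx) * ur
        inside = (par / (L_px / 2)) ** 2 + (per / B_px) ** 2 <= 1.0
        phase = c.get("phase", rng.uniform(0, 2 * np.pi))
        mod = 0.55 + 0.45 * np.sin(2 * np.pi * c["freq_hz"] * t + phase)
        stack[:, inside] += amp * mod[:, None]
        side = "ventral" if cy < midline_row else "dorsal"
        rows.append(
            {
                "freq_hz": c["freq_hz"],
                "theta_deg": c["theta_deg"],
                "length_um": c["length_um"],
                "height_um": c["length_um"] * abs(np.cos(th)),
                "side": side,
                "area_px": int(inside.sum()),
            }
        )
    stack += rng.normal(0.0, noise, stack.shape)
    video = CiliaVideo(
        stack,
        frame_rate_hz=frame_rate_hz,
        pixel_size_um=pixel_size_um,
        midline_row=midline_row,
    )
    return video, pd.DataFrame(rows)


def make_canal_phantom(
    d_um: float,
    *,
    seed: int,
    tilt_deg: float = 0.0,
    noise: float = 2.0,
    pixel_size_um: float = 0.189,
    shape_px: tuple = (128, 256),
    n_slices: int = 15,
    amp: float = 50.0,
) -> tuple[np.ndarray, float]:
    """Dye-filled canal z-stack phantom of known width.

    A straight band of width ``d_um`` crosses the field at ``tilt_deg``; a
    few central z slices carry the dye signal with Gaussian noise
    everywhere.  Returns (zstack, planted width in um).
    """
    if d_um <= 0:
        raise ValueError("d_um must be positive")
    rng = np.random.default_rng(seed)
    ny, nx = shape_px
    yy, xx = np.mgrid[:ny, :nx].astype(float)
    th = np.radians(tilt_deg)
    # signed distance (px) to the canal axis through the image center
    dist = (yy - ny / 2) * np.cos(th) - (xx - nx / 2) * np.sin(th)
    half_px = d_um / pixel_size_um / 2
    band = (np.abs(dist) <= half_px).astype(float)
    stack = np.zeros((n_slices, ny, nx))
    z_weights = np.exp(-0.5 * ((np.arange(n_slices) - n_slices / 2) / (n_slices / 5)) ** 2)
    for z in range(n_slices):
        stack[z] = amp * z_weights[z] * band
    stack += rng.normal(0.0, noise, stack.shape)
    return stack, d_um


def make_contraction_series(
    events: list[dict],
    *,
    seed: int,
    duration_s: float = 30.0,
    frame_interval_s: float = 0.1,
    counterflow_fraction: float = 0.6,
    counterflow_tau_s: float = 1.0,
    noise: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transmitted-light intensity series with contraction artifacts plus a
    paired flow series.

    Each event dict has ``time_s``, ``amplitude`` (per-frame |dI/dt| during
    the contraction), ``duration_frames`` and optional ``flow_peak_um_s``.
    The flow series shows a fast pulse during the contraction followed by a
    slower exponential counter-flow of opposite sign whose integral is
    ``counterflow_fraction`` of the pulse integral.

    Returns (times, intensity, flow).
    """
    rng = np.random.default_rng(seed)
    nt = int(round(duration_s / frame_interval_s))
    times = np.arange(nt) * frame_interval_s
    dI = np.zeros(nt - 1)
    flow = np.zeros(nt)
    for ev in events:
        i0 = int(round(ev["time_s"] / frame_interval_s))
        nfr = int(ev["duration_frames"])
        if i0 + nfr >= nt:
            raise ValueError(f"event at {ev['time_s']} s exceeds the recording")
        # alternate ramp direction so intensity stays bounded
        dI[i0 : i0 + nfr] = ev["amplitude"]
        peak = ev.get("flow_peak_um_s", 5.0)
        dur_s = nfr * frame_interval_s
        flow[i0 : i0 + nfr] += peak
        tail = times[i0 + nfr :] - times[i0 + nfr]
        pulse_integral = peak * dur_s
        cf_amp = counterflow_fraction * pulse_integral / counterflow_tau_s
        flow[i0 + nfr :] += -cf_amp * np.exp(-tail / counterflow_tau_s)
    signs = np.resize([1.0, -1.0], dI.size)  # keep intensity bounded
    intensity = 100.0 + np.concatenate([[0.0], np.cumsum(dI * signs)])
    if noise:
        intensity = intensity + rng.normal(0.0, noise, nt)
    return times, intensity, flow


def make_front_series(
    field: ConcentrationField,
    *,
    seed: int,
    frame_indices=None,
    pixel_size_um: float = 1.5,
    canal_row: int = 20,
    ny: int = 40,
    gain: float = 1000.0,
    noise: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Widefield image series of a spreading bolus along the canal.

    The transport simulation's axial marginal is resampled onto a coarse
    widefield pixel grid and painted along a horizontal canal at
    ``canal_row``, with optional camera noise.  Only x >= 0 (caudal of the
    injection site) is rendered.  Returns (stack, times).
    """
    rng = np.random.default_rng(seed)
    if frame_indices is None:
        frame_indices = np.arange(field.times.size)
    frame_indices = np.asarray(frame_indices)
    x_um = field.x * 1e6
    sel = x_um >= 0
    nx = int(x_um[sel].max() // pixel_size_um)
    xs = (np.arange(nx) + 0.5) * pixel_size_um
    stack = np.zeros((frame_indices.size, ny, nx))
    for i, fi in enumerate(frame_indices):
        prof = np.interp(xs, x_um[sel], field.marginal[fi][sel])
        frame = np.zeros((ny, nx))
        frame[canal_row - 1 : canal_row + 2, :] = gain * prof[None, :]
        if noise:
            frame = frame + rng.normal(0.0, noise, frame.shape)
        stack[i] = frame
    return stack, field.times[frame_indices]
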