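"""Per-pixel beat-frequency mapping of cilia videos and per-cilium properties.

GFP-labeled motile cilia produce a locally periodic fluorescence signal at
their beat frequency.  A 4x4 spatial sliding average raises the local SNR,
then the temporal Fourier transform of every pixel yields its dominant
non-DC frequency and spectral amplitude.  Contiguous regions of constant
frequency — the area a single cilium sweeps during one beat cycle — are
segmented within successive 5 Hz bands (5-10, 10-15, ... 45-50 Hz) and kept
when larger than 200 pixels.  Each region is fitted with an ellipse: the
major axis estimates the cilium length L, the signed angle Theta between
the major axis and the dorso-ventral axis its caudal tilt, and the beating
height L |cos Theta| the dorso-ventral extent it occupies.  Regions are
classed dorsal or ventral by their centroid relative to the canal midline.

Frequencies are only reportable below Nyquist (frame rate / 2): a 100 Hz,
3 s movie resolves up to 50 Hz with 1/3 Hz bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.measure import label, regionprops

__all__ = [
    "CiliaVideo",
    "FrequencyMap",
    "CiliaRegion",
    "frequency_map",
    "segment_cilia_regions",
    "cilium_properties",
    "summarize_cilia",
    "FREQUENCY_BANDS_HZ",
]

#: 5 Hz analysis bands from 5 to 50 Hz
FREQUENCY_BANDS_HZ = tuple((lo, lo + 5.0) for lo in np.arange(5.0, 50.0, 5.0))

#: minimum region area (px) to count as one cilium
MIN_REGION_AREA_PX = 200

#: drift cutoff: dominant-peak search excludes bins below this frequency
MIN_PEAK_HZ = 2.0


@dataclass
class CiliaVideo:
    """Cilia movie (t, y, x); y is dorso-ventral with ventral at row 0."""

    stack: np.ndarray
    frame_rate_hz: float = 100.0
    pixel_size_um: float = 0.189
    midline_row: float | None = None  # dorsal/ventral separator (row index)

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.ndim != 3:
            raise ValueError("stack must be (t, y, x)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")
        if self.midline_row is None:
            self.midline_row = self.stack.shape[1] / 2

    @property
    def nyquist_hz(self) -> float:
        return self.frame_rate_hz / 2


@dataclass
class FrequencyMap:
    """Per-pixel dominant temporal frequency and spectral amplitude."""

    frequency_hz: np.ndarray  # NaN where masked (no oscillation)
    amplitude: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    midline_row: float
    bin_hz: float  # frequency resolution frame_rate / n_frames


def frequency_map(
    video: CiliaVideo, spatial_window: int = 4, amplitude_k_mad: float = 3.0
) -> FrequencyMap:
    """Dominant-beat-frequency map of a cilia movie.

    After a ``spatial_window`` x ``spatial_window`` sliding average, the FFT
    magnitude of each pixel's time course is searched for its largest peak
    above the drift cutoff (2 Hz).  Pixels whose peak amplitude is below
    ``amplitude_k_mad`` robust standard deviations of the typical spectral
    noise are masked (NaN frequency, amplitude kept).
    """
    nt = video.stack.shape[0]
    if nt < 32:
        raise ValueError(f"need at least 32 frames for a usable spectrum, got {nt}")
    sm = uniform_filter(video.stack, size=(1, spatial_window, spatial_window))
    spec = np.abs(np.fft.rfft(sm, axis=0))
    freqs = np.fft.rfftfreq(nt, d=1.0 / video.frame_rate_hz)
    searchable = freqs >= MIN_PEAK_HZ
    spec_s = spec[searchable]
    idx = np.argmax(spec_s, axis=0)
    amp = np.take_along_axis(spec_s, idx[None], axis=0)[0]
    freq = freqs[searchable][idx]

    # robust noise floor of the per-pixel peak amplitude: with oscillating
    # cilia covering a minority of the field, the median peak amplitude is
    # the background's, and genuine beating pixels sit far above it
    med = np.median(amp)
    mad = np.median(np.abs(amp - med)) / 0.6745
    masked = amp <= med + amplitude_k_mad * mad
    freq = np.where(masked, np.nan, freq)
    return FrequencyMap(
        frequency_hz=freq,
        amplitude=amp,
        frame_rate_hz=video.frame_rate_hz,
        pixel_size_um=video.pixel_size_um,
        midline_row=float(video.midline_row),
        bin_hz=video.frame_rate_hz / nt,
    )


@dataclass
class CiliaRegion:
    """One constant-frequency region, interpreted as a single beating cilium."""

    label: int
    band_hz: tuple
    frequency_hz: float  # mean dominant frequency within the region
    theta_deg: float  # signed tilt from the dorso-ventral axis (+ = caudal)
    length_um: float  # ellipse major axis
    height_um: float  # L |cos Theta|, dorso-ventral extent
    area_px: int
    centroid_row: float
    centroid_col: float
    side: str  # "ventral" or "dorsal"


def cilium_properties(
    reg, fmap: FrequencyMap, band: tuple, region_label: int
) -> CiliaRegion:
    """Complete a labeled region into a CiliaRegion via its ellipse fit.

    ``reg`` is a skimage regionprops entry.  The ellipse major axis (in
    pixels, converted with the pixel size) estimates the cilium length; its
    orientation is the signed angle to the dorso-ventral (row) axis.  For
    degenerate regions (zero minor axis) the orientation falls back to the
    principal axis of the raw pixel coordinates.
    """
    L_px = reg.axis_major_length
    theta = reg.orientation  # angle to the row (D-V) axis
    if not np.isfinite(theta) or reg.axis_minor_length == 0:
        coords = reg.coords.astype(float)
        coords -= coords.mean(axis=0)
        _, _, Vt = np.linalg.svd(coords, full_matrices=False)
        theta = float(np.arctan2(Vt[0, 1], Vt[0, 0]))
        L_px = float(np.ptp(coords @ Vt[0])) + 1.0
    L = L_px * fmap.pixel_size_um
    height = L * abs(np.cos(theta))
    rows, cols = reg.coords[:, 0], reg.coords[:, 1]
    in_region = fmap.frequency_hz[rows, cols]
    freq = float(np.nanmean(in_region))
    cy, cx = reg.centroid
    side = "ventral" if cy < fmap.midline_row else "dorsal"
    return CiliaRegion(
        label=region_label,
        band_hz=band,
        frequency_hz=freq,
        theta_deg=float(np.degrees(theta)),
        length_um=float(L),
        height_um=float(height),
        area_px=int(reg.num_pixels),
        centroid_row=float(cy),
        centroid_col=float(cx),
        side=side,
    )


def segment_cilia_regions(
    fmap: FrequencyMap, min_area_px: int = MIN_REGION_AREA_PX
) -> list[CiliaRegion]:
    """Segment constant-frequency regions per 5 Hz band.

    For each band a mask of pixels whose dominant frequency falls inside it
    is labeled (8-connectivity); components with at least ``min_area_px``
    pixels become cilia regions.  A cilium whose in-region frequencies
    straddle a band edge is assigned per pixel and may split.
    """
    out: list[CiliaRegion] = []
    counter = 0
    for band in FREQUENCY_BANDS_HZ:
        lo, hi = band
        mask = (fmap.frequency_hz >= lo) & (fmap.frequency_hz < hi)
        if not mask.any():
            continue
        for reg in regionprops(label(mask, connectivity=2)):
            if reg.num_pixels < min_area_px:
                continue
            counter += 1
            out.append(cilium_properties(reg, fmap, band, counter))
    return out


def summarize_cilia(regions: list[CiliaRegion]) -> pd.DataFrame:
    """Per-side cohort summary of cilia properties.

    Medians of frequency, |Theta|, length and beating height per side, with
    dispersion as both the plain standard deviation and half of it (the
    half-s.d. convention commonly used to display spread around medians),
    plus counts and the ventral:dorsal count ratio.
    """
    if not regions:
        return pd.DataFrame()
    df = pd.DataFrame(
        {
            "side": [r.side for r in regions],
            "frequency_hz": [r.frequency_hz for r in regions],
            "abs_theta_deg": [abs(r.theta_deg) for r in regions],
            "length_um": [r.length_um for r in regions],
            "height_um": [r.height_um for r in regions],
        }
    )
    rows = []
    for side, grp in df.groupby("side"):
        row = {"side": side, "n": len(grp)}
        for colname in ("frequency_hz", "abs_theta_deg", "length_um", "height_um"):
            vals = grp[colname].to_numpy()
            sd = float(vals.std(ddof=0)) if vals.size > 1 else 0.0
            row[f"{colname}_median"] = float(np.median(vals))
            row[f"{colname}_sd"] = sd
            row[f"{colname}_half_sd"] = 0.5 * sd
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("side")
    nv = int((df["side"] == "ventral").sum())
    nd = int((df["side"] == "dorsal").sum())
    summary.attrs["ventral_dorsal_ratio"] = nv / nd if nd else np.inf
    return summary
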