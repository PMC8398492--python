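"""Wavelet coherence of BOLD signal pairs and scalogram-image rendering.

Dynamic functional connectivity between two brain nodes is measured with the
squared wavelet coherence

    WCT_xy(a, b) = |S(W_x*(a,b) W_y(a,b))|^2
                   / ( S(|W_x(a,b)|^2) S(|W_y(a,b)|^2) ),

where ``W`` is the continuous wavelet transform with a complex Morlet mother
wavelet and ``S`` a smoothing operator in time and scale.  Without smoothing
the expression degenerates to 1 everywhere, so S is what turns the identity
into an estimator: here a Gaussian in time whose width is proportional to
scale, and a boxcar over log-scale, in the style of Torrence & Webster.

The CWT is evaluated in the Fourier domain on a zero-padded signal with L2
(1/sqrt(a)) normalisation.  For the Morlet wavelet with dimensionless centre
frequency ``omega0`` the equivalent Fourier period of scale ``a`` is

    lambda = a * 4*pi / (omega0 + sqrt(2 + omega0^2)),

which for omega0 = 6 gives the period/scale ratio ~= 1.03 that makes scales
directly readable as periods.

Coherence maps are rendered as fixed-palette RGB rasters (default 224 x 224)
anchored to the full [0, 1] coherence range, suitable as CNN input images.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import matplotlib
import scipy.ndimage
from scipy.interpolate import RegularGridInterpolator

from .dataset import RoiTimeSeries

MORLET_OMEGA0 = 6.0


class CoherenceError(ValueError):
    """Raised for inputs on which the transform or coherence is undefined."""


def morlet_fourier_factor(omega0: float = MORLET_OMEGA0) -> float:
    """Fourier period per unit scale for the complex Morlet wavelet."""
    if omega0 <= 0:
        raise CoherenceError("omega0 must be > 0")
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


@dataclasses.dataclass(frozen=True)
class CoherenceConfig:
    """Scale grid, smoothing and rendering parameters.

    ``period_range_seconds=None`` resolves, per signal, to periods from
    ``2*TR`` (Nyquist) to a quarter of the record length.  Smoothing: the
    time kernel is Gaussian with SD = ``smoothing_time_factor * scale``; the
    scale kernel is a boxcar spanning ``smoothing_scale_decades`` decades of
    scale.  ``smoothing_enabled=False`` is a diagnostic mode (S = identity)
    that exposes the known coherence == 1 degeneracy.
    """

    omega0: float = MORLET_OMEGA0
    voices_per_octave: int = 12
    period_range_seconds: Optional[tuple[float, float]] = None
    smoothing_time_factor: float = 1.0
    smoothing_scale_decades: float = 0.6
    smoothing_enabled: bool = True
    image_size: tuple[int, int] = (224, 224)
    colormap_name: str = "viridis"

    def resolve_period_range(self, tr_seconds: float, n_timepoints: int) -> tuple[float, float]:
        if self.period_range_seconds is None:
            pmin, pmax = 2.0 * tr_seconds, n_timepoints * tr_seconds / 4.0
        else:
            pmin, pmax = self.period_range_seconds
        if pmin < 2.0 * tr_seconds - 1e-12:
            raise CoherenceError(
                f"min period {pmin} s below Nyquist period {2 * tr_seconds} s"
            )
        if pmax > n_timepoints * tr_seconds + 1e-12:
            raise CoherenceError(
                f"max period {pmax} s exceeds record length {n_timepoints * tr_seconds} s"
            )
        if not pmin < pmax:
            raise CoherenceError("period range must satisfy min < max")
        return pmin, pmax

    @property
    def scale_smoothing_width(self) -> int:
        """Boxcar length (odd, in scale-grid rows) covering the decade span."""
        decade_step = np.log10(2.0) / self.voices_per_octave
        n = int(round(self.smoothing_scale_decades / decade_step))
        return max(1, n | 1)


@dataclasses.dataclass
class CwtResult:
    """Complex Morlet CWT coefficients on a log-spaced scale grid."""

    coefficients: np.ndarray  # (n_scales, n_timepoints), complex
    scales: np.ndarray  # (n_scales,), seconds
    periods: np.ndarray  # (n_scales,), Fourier periods, seconds
    times: np.ndarray  # (n_timepoints,), seconds
    coi: np.ndarray  # (n_timepoints,), cone-of-influence period, seconds
    tr_seconds: float
    omega0: float

    @property
    def n_scales(self) -> int:
        return self.scales.size


def _scale_grid(config: CoherenceConfig, pmin: float, pmax: float) -> tuple[np.ndarray, np.ndarray]:
    ff = morlet_fourier_factor(config.omega0)
    n_octaves = np.log2(pmax / pmin)
    n_scales = int(np.floor(n_octaves * config.voices_per_octave)) + 1
    periods = pmin * 2.0 ** (np.arange(n_scales) / config.voices_per_octave)
    return periods / ff, periods


def cwt_morlet(
    signal: np.ndarray,
    tr_seconds: float,
    config: CoherenceConfig = CoherenceConfig(),
) -> CwtResult:
    """Continuous wavelet transform with a complex Morlet mother wavelet.

    FFT implementation on a zero-padded copy (next power of two >= 2N), with
    1/sqrt(a) (L2) normalisation so coefficient magnitudes are comparable
    across scales.  The cone of influence records, per time point, the period
    above which edge effects (e-folding of the wavelet envelope) matter.
    """
    x = np.asarray(signal, dtype=float).ravel()
    n = x.size
    if n < 16:
        raise CoherenceError("signal too short for CWT (need >= 16 samples)")
    if not np.all(np.isfinite(x)):
        raise CoherenceError("signal contains non-finite values")
    if not tr_seconds > 0:
        raise CoherenceError("tr_seconds must be > 0")

    pmin, pmax = config.resolve_period_range(tr_seconds, n)
    scales, periods = _scale_grid(config, pmin, pmax)

    n_pad = int(2 ** np.ceil(np.log2(2 * n)))
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=tr_seconds)
    x_hat = np.fft.fft(x, n=n_pad)

    # Morlet daughter in the Fourier domain, analytic (positive freqs only)
    arg = scales[:, None] * omega[None, :]
    daughter = (
        np.pi**-0.25
        * np.sqrt(2.0 * np.pi * scales[:, None] / tr_seconds)
        * np.exp(-0.5 * (arg - config.omega0) ** 2)
        * (omega[None, :] > 0)
    )
    coeffs = np.fft.ifft(x_hat[None, :] * daughter, axis=1)[:, :n]

    ff = morlet_fourier_factor(config.omega0)
    idx = np.arange(n)
    coi = ff * np.sqrt(2.0) * tr_seconds * np.minimum(idx, n - 1 - idx)
    return CwtResult(
        coefficients=coeffs,
        scales=scales,
        periods=periods,
        times=idx * tr_seconds,
        coi=coi,
        tr_seconds=tr_seconds,
        omega0=config.omega0,
    )


def _smooth(matrix: np.ndarray, scales: np.ndarray, tr_seconds: float,
            config: CoherenceConfig) -> np.ndarray:
    """Apply S: per-row Gaussian in time (SD prop. to scale), boxcar in scale."""
    if not config.smoothing_enabled:
        return matrix
    out = np.empty_like(matrix)
    for i, a in enumerate(scales):
        sigma = config.smoothing_time_factor * a / tr_seconds
        if np.iscomplexobj(matrix):
            out[i] = (
                scipy.ndimage.gaussian_filter1d(matrix[i].real, sigma, mode="nearest")
                + 1j * scipy.ndimage.gaussian_filter1d(matrix[i].imag, sigma, mode="nearest")
            )
        else:
            out[i] = scipy.ndimage.gaussian_filter1d(matrix[i], sigma, mode="nearest")
    width = config.scale_smoothing_width
    if width > 1:
        if np.iscomplexobj(out):
            out = (
                scipy.ndimage.uniform_filter1d(out.real, width, axis=0, mode="nearest")
                + 1j * scipy.ndimage.uniform_filter1d(out.imag, width, axis=0, mode="nearest")
            )
        else:
            out = scipy.ndimage.uniform_filter1d(out, width, axis=0, mode="nearest")
    return out


def smooth_cross_spectrum(
    cwt_x: CwtResult,
    cwt_y: CwtResult,
    config: CoherenceConfig = CoherenceConfig(),
) -> np.ndarray:
    """Smoothed cross-wavelet spectrum S(W_x* W_y) on the shared grid."""
    if cwt_x.coefficients.shape != cwt_y.coefficients.shape or not np.allclose(
        cwt_x.scales, cwt_y.scales
    ):
        raise CoherenceError("CWT grids do not match")
    cross = np.conj(cwt_x.coefficients) * cwt_y.coefficients
    return _smooth(cross, cwt_x.scales, cwt_x.tr_seconds, config)


@dataclasses.dataclass
class CoherenceMap:
    """Squared wavelet coherence in [0, 1] over (scale x time)."""

    values: np.ndarray  # (n_scales, n_timepoints), in [0, 1]
    periods: np.ndarray
    times: np.ndarray
    coi: np.ndarray

    @property
    def coi_mask(self) -> np.ndarray:
        """True where the period exceeds the cone of influence (unreliable)."""
        return self.periods[:, None] > self.coi[None, :]


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    tr_seconds: float,
    config: CoherenceConfig = CoherenceConfig(),
) -> CoherenceMap:
    """Squared wavelet coherence of two equal-length signals."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise CoherenceError(f"signal lengths differ: {x.size} vs {y.size}")
    for name, s in (("x", x), ("y", y)):
        if np.std(s) == 0:
            raise CoherenceError(f"signal {name} is constant: coherence undefined")

    wx = cwt_morlet(x, tr_seconds, config)
    wy = cwt_morlet(y, tr_seconds, config)
    cross = smooth_cross_spectrum(wx, wy, config)
    sx = _smooth(np.abs(wx.coefficients) ** 2, wx.scales, tr_seconds, config)
    sy = _smooth(np.abs(wy.coefficients) ** 2, wy.scales, tr_seconds, config)

    denom = sx * sy
    eps = np.finfo(float).tiny
    wct = np.abs(cross) ** 2 / np.maximum(denom, eps)
    np.clip(wct, 0.0, 1.0, out=wct)
    return CoherenceMap(values=wct, periods=wx.periods, times=wx.times, coi=wx.coi)


@dataclasses.dataclass
class ScalogramImage:
    """RGB raster of a coherence map plus provenance metadata."""

    pixels: np.ndarray  # (H, W, 3), uint8
    subject_id: str = ""
    seed_node: int = -1
    partner_node: int = -1
    group: str = ""
    site: str = ""


def render_scalogram(
    cmap: CoherenceMap,
    config: CoherenceConfig = CoherenceConfig(),
    subject_id: str = "",
    seed_node: int = -1,
    partner_node: int = -1,
    group: str = "",
    site: str = "",
) -> ScalogramImage:
    """Rasterise a coherence map to a fixed-size RGB image.

    The period axis is log-scaled (top row = shortest period), the colour
    scale is anchored to the full [0, 1] coherence range, and the map is
    bilinearly resampled to ``config.image_size``.  Byte-deterministic for a
    given map and config.
    """
    height, width = config.image_size
    log_p = np.log2(cmap.periods)
    interp = RegularGridInterpolator(
        (log_p, cmap.times), cmap.values, bounds_error=False, fill_value=None
    )
    rows = np.linspace(log_p[0], log_p[-1], height)
    cols = np.linspace(cmap.times[0], cmap.times[-1], width)
    grid = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1)
    vals = np.clip(interp(grid), 0.0, 1.0)

    palette = matplotlib.colormaps[config.colormap_name]
    rgba = palette(vals)  # anchored: vals already in [0, 1]
    pixels = (rgba[..., :3] * 255.0 + 0.5).astype(np.uint8)
    return ScalogramImage(
        pixels=pixels,
        subject_id=subject_id,
        seed_node=seed_node,
        partner_node=partner_node,
        group=group,
        site=site,
    )


def pairwise_scalograms(
    recording: RoiTimeSeries,
    seed_nodes: Sequence[int],
    config: CoherenceConfig = CoherenceConfig(),
) -> list[ScalogramImage]:
    """Coherence scalograms between each seed node and every other node.

    For one seed node on an N-node recording this yields N-1 images (the
    self-pair is skipped); with several seed nodes the per-seed lists are
    concatenated.  CWTs and smoothed auto-spectra are computed once per node.
    """
    n_nodes = recording.n_nodes
    for s in seed_nodes:
        if not 0 <= s < n_nodes:
            raise CoherenceError(f"seed node {s} out of range [0, {n_nodes})")

    cwts: dict[int, CwtResult] = {}
    autos: dict[int, np.ndarray] = {}

    def node_cwt(j: int) -> tuple[CwtResult, np.ndarray]:
        if j not in cwts:
            sig = recording.data[:, j]
            if np.std(sig) == 0:
                raise CoherenceError(
                    f"subject {recording.subject_id}: node {j} signal is constant"
                )
            w = cwt_morlet(sig, recording.tr_seconds, config)
            cwts[j] = w
            autos[j] = _smooth(np.abs(w.coefficients) ** 2, w.scales,
                               recording.tr_seconds, config)
        return cwts[j], autos[j]

    eps = np.finfo(float).tiny
    images: list[ScalogramImage] = []
    for s in seed_nodes:
        ws, auto_s = node_cwt(s)
        for j in range(n_nodes):
            if j == s:
                continue
            wj, auto_j = node_cwt(j)
            cross = smooth_cross_spectrum(ws, wj, config)
            wct = np.abs(cross) ** 2 / np.maximum(auto_s * auto_j, eps)
            np.clip(wct, 0.0, 1.0, out=wct)
            cmap = CoherenceMap(values=wct, periods=ws.periods, times=ws.times, coi=ws.coi)
            images.append(
                render_scalogram(
                    cmap,
                    config,
                    subject_id=recording.subject_id,
                    seed_node=s,
                    partner_node=j,
                    group=recording.group,
                    site=recording.site,
                )
            )
    return images


def scalogram_count(n_nodes: int, n_seed_nodes: int = 1) -> int:
    """Images per subject: each seed node pairs with every other node."""
    if n_nodes < 2 or n_seed_nodes < 1 or n_seed_nodes > n_nodes:
        raise CoherenceError("invalid node counts")
    return n_seed_nodes * (n_nodes - 1)


def unique_pair_count(n_nodes: int) -> int:
    """Number of unordered node pairs (all-pairs scalogram budget)."""
    return n_nodes * (n_nodes - 1) // 2


def images_per_class(n_subjects_per_class: int, n_nodes: int, n_seed_nodes: int = 1) -> int:
    """Scalogram images contributed by one diagnostic class."""
    return n_subjects_per_class * scalogram_count(n_nodes, n_seed_nodes)
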