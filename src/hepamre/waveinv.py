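"""Multifrequency wavenumber-based inversion of harmonic shear-wave fields.

Implements the processing chain used for in vivo liver MRE: temporal Fourier
extraction of the fundamental harmonic from 8 phase offsets, Butterworth
low-pass filtering (order 3, 250 cycles/m) ahead of gradient-based phase
unwrapping, slice-wise directional decomposition with a radial Butterworth
band-pass (order 3, 15-300 cycles/m) and raised-cosine angular wedges that
sum to unity, local wavenumber estimation k' = |grad phi| / 2pi, and
amplitude-weighted frequency compounding into shear-wave-speed (SWS, m/s)
and penetration-rate (PR, m/s) maps with ROI statistics.

Conventions: spatial frequencies are cycles per meter; a damped plane wave
has amplitude ~ exp(-kappa'' x) along propagation, with SWS = f/k' and
PR = f/kappa''.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FilterSettings",
    "PhaseOffsetSeries",
    "WaveFieldSet",
    "ParameterMap",
    "extract_harmonic",
    "unwrap_gradient",
    "directional_filter",
    "bandpass_field",
    "directional_wavenumber_maps",
    "wavenumber_maps",
    "compound_sws",
    "compound_pr",
    "roi_stats",
    "invert_wavefield",
]

N_PHASE_OFFSETS = 8


@dataclass(frozen=True)
class FilterSettings:
    """Spatial filter configuration of the inversion chain.

    Thresholds are spatial frequencies in cycles per meter.  Setting
    ``lowpass_threshold`` to None disables the pre-unwrapping low-pass.
    """

    lowpass_threshold: float | None = 250.0
    lowpass_order: int = 3
    bandpass: tuple[float, float] = (15.0, 300.0)
    bandpass_order: int = 3
    n_directions: int = 8

    def __post_init__(self):
        lo, hi = self.bandpass
        if not (0 < lo < hi):
            raise ValueError("band-pass thresholds must satisfy 0 < low < high")
        if self.lowpass_order < 1 or self.bandpass_order < 1:
            raise ValueError("filter order must be >= 1")
        if self.n_directions < 4:
            raise ValueError("need at least 4 angular wedges")


@dataclass(frozen=True)
class PhaseOffsetSeries:
    """Raw wrapped phase images over one vibration cycle.

    ``images`` is (8, nz, ny, nx) in radians; offsets sample the cycle
    uniformly.  Phase values are wrapped to (-pi, pi].
    """

    images: np.ndarray
    frequency_hz: float
    direction: str
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        img = np.asarray(self.images)
        if img.shape[0] != N_PHASE_OFFSETS:
            raise ValueError(
                f"expected {N_PHASE_OFFSETS} phase offsets, got {img.shape[0]}"
            )
        if not np.all(np.isfinite(img)):
            raise ValueError("phase images contain non-finite values")


@dataclass(frozen=True)
class WaveFieldSet:
    """Complex harmonic displacement fields, (n_freq, n_enc, nz, ny, nx)."""

    fields: np.ndarray
    frequencies_hz: tuple[float, ...]
    voxel_spacing_mm: tuple[float, float, float]
    encoding_directions: tuple[str, ...] = ("HF",)

    def __post_init__(self):
        f = np.asarray(self.fields)
        if f.ndim != 5:
            raise ValueError("fields must be (freq, encoding, z, y, x)")
        if f.shape[0] != len(self.frequencies_hz):
            raise ValueError("frequency axis mismatch")
        if f.shape[1] != len(self.encoding_directions):
            raise ValueError("encoding axis mismatch")
        if not np.all(np.isfinite(f)):
            raise ValueError("wave fields contain non-finite values")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")


@dataclass(frozen=True)
class ParameterMap:
    """Scalar SWS or PR map; NaN outside the validity mask."""

    values: np.ndarray
    kind: str  # "SWS" or "PR"
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - phi, 2.0 * np.pi)


def extract_harmonic(series: PhaseOffsetSeries) -> np.ndarray:
    """Complex amplitude of the fundamental vibration harmonic.

    Normalised such that images_t = a*cos(2 pi t/8 + phi0) yields a field of
    magnitude a and phase phi0; the DC component is rejected.
    """
    img = np.asarray(series.images, dtype=float)
    t = np.arange(N_PHASE_OFFSETS)
    basis = np.exp(-2j * np.pi * t / N_PHASE_OFFSETS)
    return (2.0 / N_PHASE_OFFSETS) * np.tensordot(basis, img, axes=(0, 0))


def _radial_kgrid(shape: tuple[int, int], spacing_m: tuple[float, float]):
    ky = np.fft.fftfreq(shape[0], d=spacing_m[0])
    kx = np.fft.fftfreq(shape[1], d=spacing_m[1])
    return np.meshgrid(ky, kx, indexing="ij")


def _butter_lowpass(k: np.ndarray, cutoff: float, order: int) -> np.ndarray:
    return 1.0 / (1.0 + (k / cutoff) ** (2 * order))


def _pad_reflect(u: np.ndarray):
    """Mirror-pad the two in-plane axes by half their size.

    Spectral filters assume periodicity; a strongly attenuated wave is
    anything but periodic, and the wrap-around discontinuity rings across
    the whole field of view.  Mirror padding removes the discontinuity.
    """
    ny, nx = u.shape[-2:]
    pad = [(0, 0)] * (u.ndim - 2) + [(ny // 2, ny // 2), (nx // 2, nx // 2)]
    return np.pad(u, pad, mode="reflect"), (ny, nx)


def _crop(u: np.ndarray, shape: tuple[int, int]):
    ny, nx = shape
    py, px = ny // 2, nx // 2
    return u[..., py : py + ny, px : px + nx]


def _lowpass_complex(u: np.ndarray, settings: FilterSettings, spacing_m) -> np.ndarray:
    """Radial Butterworth low-pass applied slice-wise to a complex field."""
    if settings.lowpass_threshold is None:
        return u
    up, shape = _pad_reflect(np.asarray(u, dtype=complex))
    ky, kx = _radial_kgrid(up.shape[-2:], spacing_m)
    k = np.hypot(ky, kx)
    H = _butter_lowpass(k, settings.lowpass_threshold, settings.lowpass_order)
    return _crop(np.fft.ifft2(np.fft.fft2(up, axes=(-2, -1)) * H, axes=(-2, -1)), shape)


def _wrapped_gradient(phase: np.ndarray, spacing_m: tuple[float, float]):
    """Phase gradient (rad/m) from wrapped finite differences, slice-wise.

    Interior voxels average the wrapped forward and backward differences
    (equivalent to a central difference that is immune to 2*pi jumps for
    true gradients below pi per voxel); edges use one-sided differences.
    """
    out = []
    for axis, d in ((-2, spacing_m[0]), (-1, spacing_m[1])):
        fwd = wrap_phase(np.diff(phase, axis=axis))  # fwd[i] = phi[i+1]-phi[i]

        def sl(s):
            idx = [slice(None)] * phase.ndim
            idx[axis] = s
            return tuple(idx)

        g = np.empty_like(phase)
        g[sl(slice(1, -1))] = 0.5 * (fwd[sl(slice(1, None))] + fwd[sl(slice(None, -1))])
        g[sl(slice(0, 1))] = fwd[sl(slice(0, 1))]
        g[sl(slice(-1, None))] = fwd[sl(slice(-1, None))]
        out.append(g / d)
    return out[0], out[1]  # d/dy, d/dx


def unwrap_gradient(
    phase: np.ndarray,
    settings: FilterSettings,
    spacing_m: tuple[float, float],
):
    """Spatial phase-derivative fields without explicit unwrapping.

    The wrapped phase is low-pass filtered through its complex representation
    exp(i*phase) (Butterworth, slice-wise) and differentiated with wrapped
    finite differences.  Returns (d/dy, d/dx) in rad/m and an ``aliased``
    flag set when any wrapped difference comes within 10% of pi per voxel
    (true gradients at or beyond pi/voxel are not recoverable).
    """
    phase = np.asarray(phase, dtype=float)
    z = _lowpass_complex(np.exp(1j * phase), settings, spacing_m)
    phi = np.angle(z)
    gy, gx = _wrapped_gradient(phi, spacing_m)
    # true gradients at or beyond pi/voxel fold back below pi; gradients in
    # the top 10% of the representable range are treated as likely aliased
    limit = 0.9 * np.pi
    aliased = bool(
        np.any(np.abs(gy) * spacing_m[0] >= limit)
        or np.any(np.abs(gx) * spacing_m[1] >= limit)
    )
    return gy, gx, aliased


def _angular_windows(theta: np.ndarray, n_directions: int) -> list[np.ndarray]:
    """Raised-cosine wedges centred at 2*pi*j/n that sum to one everywhere."""
    width = 2.0 * np.pi / n_directions
    windows = []
    for j in range(n_directions):
        centre = j * width
        d = np.angle(np.exp(1j * (theta - centre)))  # wrapped angular distance
        w = np.where(np.abs(d) < width, np.cos(np.pi * d / (2.0 * width)) ** 2, 0.0)
        windows.append(w)
    return windows


def directional_filter(
    u: np.ndarray,
    settings: FilterSettings,
    spacing_m: tuple[float, float],
) -> np.ndarray:
    """Band-pass and angular decomposition of a complex field, slice-wise.

    Returns an array (n_directions, ...) whose components sum to the radially
    band-passed input (the angular windows form a partition of unity).
    Wedge j selects spectral energy propagating near the in-plane angle
    2*pi*j/n measured from +x toward +y.
    """
    up, shape = _pad_reflect(np.asarray(u, dtype=complex))
    ky, kx = _radial_kgrid(up.shape[-2:], spacing_m)
    k = np.hypot(ky, kx)
    lo, hi = settings.bandpass
    n = settings.bandpass_order
    with np.errstate(divide="ignore"):
        highpass = 1.0 - _butter_lowpass(np.where(k > 0, k, np.inf), lo, n)
    bandpass = _butter_lowpass(k, hi, n) * highpass
    theta = np.arctan2(ky, kx)
    spectrum = np.fft.fft2(up, axes=(-2, -1)) * bandpass
    comps = []
    for w in _angular_windows(theta, settings.n_directions):
        w = w.copy()
        w[0, 0] = 1.0 / settings.n_directions  # share the (filtered-out) DC bin
        comps.append(_crop(np.fft.ifft2(spectrum * w, axes=(-2, -1)), shape))
    return np.stack(comps)


def bandpass_field(u: np.ndarray, settings: FilterSettings, spacing_m) -> np.ndarray:
    """Radially band-passed field; the directional components sum to this."""
    up, shape = _pad_reflect(np.asarray(u, dtype=complex))
    ky, kx = _radial_kgrid(up.shape[-2:], spacing_m)
    k = np.hypot(ky, kx)
    lo, hi = settings.bandpass
    n = settings.bandpass_order
    with np.errstate(divide="ignore"):
        highpass = 1.0 - _butter_lowpass(np.where(k > 0, k, np.inf), lo, n)
    bandpass = _butter_lowpass(k, hi, n) * highpass
    return _crop(
        np.fft.ifft2(np.fft.fft2(up, axes=(-2, -1)) * bandpass, axes=(-2, -1)), shape
    )


def wavenumber_maps(
    component: np.ndarray,
    frequency_hz: float,
    spacing_m: tuple[float, float],
):
    """Local real wavenumber, attenuation and weight maps for one component.

    k' (cycles/m) is |grad phi| / 2*pi of the component's phase; the
    attenuation coefficient kappa'' (1/m) is the negative directional
    derivative of ln|u| along the local propagation direction grad phi /
    |grad phi|; the weight is the component amplitude.  An all-zero
    component yields zero weights (not an error).
    """
    component = np.asarray(component, dtype=complex)
    amp = np.abs(component)
    weight = amp.copy()
    if not np.any(amp > 0):
        zeros = np.zeros_like(amp)
        return zeros, zeros, zeros
    phase = np.angle(component)
    gy, gx = _wrapped_gradient(phase, spacing_m)
    k_rad = np.hypot(gy, gx)  # rad/m
    k_map = k_rad / (2.0 * np.pi)  # cycles/m
    # log-amplitude gradient; tiny amplitudes are floored to keep logs finite
    floor = max(amp.max() * 1e-12, np.finfo(float).tiny)
    ln_a = np.log(np.maximum(amp, floor))
    gay = np.gradient(ln_a, spacing_m[0], axis=-2)
    gax = np.gradient(ln_a, spacing_m[1], axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        att = -(gay * gy + gax * gx) / np.where(k_rad > 0, k_rad, np.inf)
    att = np.where(np.isfinite(att), att, 0.0)
    return k_map, att, weight


def _erode_edges(weight: np.ndarray, n_voxels: int = 2) -> np.ndarray:
    """Zero the in-plane border where finite differences are one-sided."""
    w = weight.copy()
    if n_voxels <= 0:
        return w
    w[..., :n_voxels, :] = 0.0
    w[..., -n_voxels:, :] = 0.0
    w[..., :, :n_voxels] = 0.0
    w[..., :, -n_voxels:] = 0.0
    return w


def compound_sws(
    k_maps: Sequence[np.ndarray],
    weights: Sequence[np.ndarray],
    frequencies_hz: Sequence[float],
    provenance: dict | None = None,
    k_min: float = 1.0,
) -> ParameterMap:
    """Amplitude-weighted frequency compounding of SWS = f / k'.

    Entries with k' below ``k_min`` cycles/m carry zero weight (a vanishing
    wavenumber means no resolvable wave, not an infinite speed).  Voxels with
    zero total weight are masked NaN.
    """
    if len(k_maps) == 0:
        raise ValueError("no wavenumber maps to compound")
    num = np.zeros_like(np.asarray(k_maps[0], dtype=float))
    den = np.zeros_like(num)
    for k_map, w, f in zip(k_maps, weights, frequencies_hz):
        k_map = np.asarray(k_map, dtype=float)
        w = np.where(k_map >= k_min, np.asarray(w, dtype=float), 0.0)
        with np.errstate(divide="ignore"):
            sws = np.where(k_map > 0, f / np.maximum(k_map, 1e-300), 0.0)
        num += w * sws
        den += w
    mask = den > 0
    values = np.full(num.shape, np.nan)
    values[mask] = num[mask] / den[mask]
    return ParameterMap(values=values, kind="SWS", mask=mask, provenance=provenance or {})


def compound_pr(
    att_maps: Sequence[np.ndarray],
    weights: Sequence[np.ndarray],
    frequencies_hz: Sequence[float],
    provenance: dict | None = None,
    att_min: float = 1.0,
) -> ParameterMap:
    """Amplitude-weighted frequency compounding of PR = f / kappa''.

    Voxels where no entry shows positive attenuation (kappa'' <= att_min,
    1/m) are masked rather than reported as infinite penetration.
    """
    if len(att_maps) == 0:
        raise ValueError("no attenuation maps to compound")
    num = np.zeros_like(np.asarray(att_maps[0], dtype=float))
    den = np.zeros_like(num)
    for att, w, f in zip(att_maps, weights, frequencies_hz):
        att = np.asarray(att, dtype=float)
        w = np.where(att >= att_min, np.asarray(w, dtype=float), 0.0)
        pr = np.where(att > 0, f / np.maximum(att, 1e-300), 0.0)
        num += w * pr
        den += w
    mask = den > 0
    values = np.full(num.shape, np.nan)
    values[mask] = num[mask] / den[mask]
    return ParameterMap(values=values, kind="PR", mask=mask, provenance=provenance or {})


def roi_stats(pmap: ParameterMap, roi: np.ndarray) -> dict:
    """Mean, sample SD and voxel count of a map over an ROI mask."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != pmap.values.shape:
        raise ValueError("ROI shape does not match the parameter map")
    sel = roi & pmap.mask & np.isfinite(pmap.values)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("ROI does not intersect the valid region of the map")
    vals = pmap.values[sel]
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if n > 1 else 0.0,
        "n_voxels": n,
    }


def _weighted_smooth(x: np.ndarray, w: np.ndarray, sigma_vox: float) -> np.ndarray:
    """In-plane weight-carrying Gaussian smoothing (edge-extended)."""
    from scipy.ndimage import gaussian_filter

    sig = (0.0,) * (x.ndim - 2) + (sigma_vox, sigma_vox)
    num = gaussian_filter(x * w, sig, mode="nearest")
    den = gaussian_filter(w, sig, mode="nearest")
    return num / np.maximum(den, 1e-300)


def directional_wavenumber_maps(
    field: np.ndarray,
    frequency_hz: float,
    spacing_m: tuple[float, float],
    settings: FilterSettings,
    amplitude_threshold: float = 0.2,
    dominance_threshold: float = 0.6,
    edge_erosion_m: float = 0.006,
):
    """Per-wedge k', kappa'' and weight maps for one low-passed field.

    The directional decomposition decides, voxel by voxel, which propagation
    direction dominates and how much it dominates; the phase and
    log-amplitude gradients themselves are taken on the (low-passed) field
    — the narrow radial band-pass distorts the amplitude decay of strongly
    damped waves, so the components serve as direction and weight oracles
    only.  Gradients are projected on each wedge's nominal direction and
    ripple from residual wave interference is suppressed by a
    dominance-weighted local average over half the dominant wavelength.
    Voxels below ``amplitude_threshold`` (relative) or whose wedge carries
    less than ``dominance_threshold`` of the local amplitude get weight 0.
    """
    ulp = _lowpass_complex(field, settings, spacing_m)
    amp_lp = np.abs(ulp)
    gy, gx = _wrapped_gradient(np.angle(ulp), spacing_m)
    floor = max(amp_lp.max() * 1e-12, np.finfo(float).tiny)
    ln_a = np.log(np.maximum(amp_lp, floor))
    gay = np.gradient(ln_a, spacing_m[0], axis=-2)
    gax = np.gradient(ln_a, spacing_m[1], axis=-1)
    comps = directional_filter(ulp, settings, spacing_m)
    total = np.sum(np.abs(comps), axis=0)
    out = []
    n = settings.n_directions
    for j in range(n):
        comp_amp = np.abs(comps[j])
        ang = 2.0 * np.pi * j / n
        dxj, dyj = np.cos(ang), np.sin(ang)
        k_proj = (gx * dxj + gy * dyj) / (2.0 * np.pi)  # cycles/m along wedge
        att_proj = -(gax * dxj + gay * dyj)
        dom = comp_amp / np.maximum(total, 1e-300)
        # steep weighting keeps the local average anchored to voxels where
        # this wedge's wave is both strong and clean
        w2 = (comp_amp * dom) ** 4
        k_med = np.median(k_proj[comp_amp > 0.5 * comp_amp.max()]) if comp_amp.max() > 0 else 0.0
        # a wedge misaligned with the local propagation has a near-zero
        # projected wavenumber; no resolvable wavelength, no smoothing scale
        if k_med >= settings.bandpass[0]:
            sigma_vox = 1.0 / (2.0 * k_med * spacing_m[0])
            k_s = _weighted_smooth(k_proj, w2, sigma_vox)
            att_s = _weighted_smooth(att_proj, w2, sigma_vox)
        else:
            k_s, att_s = k_proj, att_proj
        w = _erode_edges(comp_amp.copy(), max(2, round(edge_erosion_m / spacing_m[0])))
        w[(comp_amp < amplitude_threshold * max(comp_amp.max(), 1e-300))] = 0.0
        w[dom < dominance_threshold] = 0.0
        out.append((k_s, att_s, w))
    return out


def invert_wavefield(
    wfs: WaveFieldSet,
    settings: FilterSettings | None = None,
) -> tuple[ParameterMap, ParameterMap]:
    """Full inversion: directional filtering, wavenumber estimation and
    frequency compounding over all frequencies, encoding directions and
    angular components of a wave-field set.
    """
    settings = settings or FilterSettings()
    spacing_m = (
        wfs.voxel_spacing_mm[1] * 1e-3,
        wfs.voxel_spacing_mm[2] * 1e-3,
    )
    k_maps: list[np.ndarray] = []
    att_maps: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    freqs: list[float] = []
    for fi, f in enumerate(wfs.frequencies_hz):
        for ei in range(len(wfs.encoding_directions)):
            for k_map, att, w in directional_wavenumber_maps(
                wfs.fields[fi, ei], f, spacing_m, settings
            ):
                k_maps.append(k_map)
                att_maps.append(att)
                weights.append(w)
                freqs.append(f)
    prov = {
        "lowpass_threshold": settings.lowpass_threshold,
        "lowpass_order": settings.lowpass_order,
        "bandpass": list(settings.bandpass),
        "bandpass_order": settings.bandpass_order,
        "n_directions": settings.n_directions,
        "frequencies_hz": list(wfs.frequencies_hz),
    }
    sws = compound_sws(k_maps, weights, freqs, provenance=prov)
    pr = compound_pr(att_maps, weights, freqs, provenance=prov)
    return sws, pr
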