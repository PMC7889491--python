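"""PRF-shift thermometry reconstruction.

The measurement chain implemented here:

1.  k-space apodisation (separable 3D Hann) and symmetric zero-padding
    (64x64x30 acquisitions are padded to 128x128x60 by default).
2.  Coil combination: the receive channels of the two interleaved RF
    shim modes are concatenated (2 x 8 = 16 channels) and reduced to a
    single complex series per voxel by projecting onto the principal
    left singular vector of the channel-by-observation data matrix,
    computed from all echoes and repetitions.
3.  First-echo phasing: every later echo is multiplied by the unit
    conjugate phase of echo 1 of the same repetition, cancelling any
    phase common to all echoes of a repetition (transmit/receive chain
    instabilities).
4.  Phase differencing against a reference repetition, then conversion
    to temperature change:

        dT = (dphi - dphi_drift) / (2*pi * gamma * alpha * B0 * TE_eff)

    with gamma = 42.576 MHz/T, alpha = -0.00988 ppm/degC, B0 = 7 T.
    After first-echo phasing the thermal phase of echo e is
    proportional to TE_e - TE_1, so TE_eff defaults to that difference.
5.  Multi-echo combination, weighting each echo map by TE * |I|.
6.  Drift correction: either a scalar offset from fibre-optic probe
    readings, or a first-order spatial (bulk + X/Y/Z plane) model
    fitted per repetition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants
from .series import MultiEchoSeries

__all__ = [
    "ReconConfig",
    "TemperatureMap",
    "DriftModel",
    "ReconResult",
    "reconstruct_images",
    "combine_coils_svd",
    "phase_with_first_echo",
    "phase_to_temperature",
    "combine_echo_maps",
    "fit_drift_model",
    "probe_drift_correct",
    "stability_report",
    "temporal_std_map",
    "rmse_map",
    "reconstruct_temperature",
]


@dataclass
class ReconConfig:
    """Reconstruction settings; defaults follow the scanner protocol."""

    apodise: bool = True
    zero_pad_shape: tuple[int, int, int] | None = (128, 128, 60)
    reference_rep: int = 20           # 1-based, as in scan protocols
    echoes_for_temp: tuple[int, ...] = (2, 3, 4, 5)  # 1-based echo labels
    gamma_hz_per_t: float = constants.GAMMA_HZ_PER_T
    alpha_ppm_per_c: float = constants.ALPHA_PPM_PER_C
    b0_t: float = constants.B0_T
    te_convention: str = "effective"  # "effective" (TE_e - TE_1) | "nominal"
    drift_correction: str = "none"    # "none" | "probe" | "plane"
    tiamo: bool = True                # combine both shim modes
    mode_index: int = 0               # used when tiamo=False
    mask_threshold: float = 0.1       # fraction of robust max magnitude

    def __post_init__(self) -> None:
        if self.alpha_ppm_per_c >= 0:
            raise ValueError("alpha must be negative (PRF convention)")
        if self.te_convention not in ("effective", "nominal"):
            raise ValueError("te_convention must be 'effective' or 'nominal'")
        if self.drift_correction not in ("none", "probe", "plane"):
            raise ValueError("unknown drift_correction mode")


@dataclass
class TemperatureMap:
    """Per-voxel temperature change with provenance."""

    delta_T: np.ndarray
    mask: np.ndarray
    repetition: int                    # 1-based label
    echoes_used: tuple[int, ...]
    drift_applied: str = "none"

    def masked(self) -> np.ndarray:
        out = np.where(self.mask, self.delta_T, np.nan)
        return out


@dataclass
class DriftModel:
    """Per-repetition bulk and first-order spatial drift coefficients.

    ``coeffs[r] = (a0, ax, ay, az)`` in degC and degC/mm; coordinates
    are phantom-frame mm about the grid centre.
    """

    coeffs: np.ndarray                 # [n_reps, 4]
    rep_labels: np.ndarray             # 1-based repetition labels
    times_s: np.ndarray | None = None

    def evaluate(self, coords) -> np.ndarray:
        X, Y, Z = coords
        out = np.empty((self.coeffs.shape[0], *X.shape))
        for r, (a0, ax, ay, az) in enumerate(self.coeffs):
            out[r] = a0 + ax * X + ay * Y + az * Z
        return out

    def gradient_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.coeffs[:, 1:], axis=1)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "rep": self.rep_labels,
            "a0_C": self.coeffs[:, 0],
            "ax_C_per_mm": self.coeffs[:, 1],
            "ay_C_per_mm": self.coeffs[:, 2],
            "az_C_per_mm": self.coeffs[:, 3],
        }).to_csv(path, index=False)


def _centered_window(n: int) -> np.ndarray:
    # Hann taper, unity at the k-space centre (index n//2 after fftshift)
    i = np.arange(n)
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (i - n // 2) / n))


def reconstruct_images(images: np.ndarray,
                       target_shape: tuple[int, int, int] | None = None,
                       apodise: bool = True) -> np.ndarray:
    """Hann-filter and zero-pad the k-space of complex images.

    Operates on the trailing three axes; any leading axes (mode, coil,
    echo, repetition) are carried through.  Unitary FFTs are used, so
    image energy equals (windowed) k-space energy.
    """
    images = np.asarray(images)
    in_shape = images.shape[-3:]
    if target_shape is not None and any(
            t < s for t, s in zip(target_shape, in_shape)):
        raise ValueError("zero-pad target smaller than acquisition matrix")
    axes = (-3, -2, -1)
    k = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(images, axes=axes),
                                    axes=axes, norm="ortho"), axes=axes)
    if apodise:
        wx, wy, wz = (_centered_window(n) for n in in_shape)
        k = k * wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
    if target_shape is not None and tuple(target_shape) != tuple(in_shape):
        padded = np.zeros(images.shape[:-3] + tuple(target_shape),
                          dtype=k.dtype)
        sl = tuple(slice((t - s) // 2, (t - s) // 2 + s)
                   for t, s in zip(target_shape, in_shape))
        padded[(..., *sl)] = k
        k = padded
    out = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(k, axes=axes),
                                       axes=axes, norm="ortho"), axes=axes)
    return out


def combine_coils_svd(channel_data: np.ndarray) -> np.ndarray:
    """SVD coil combination over concatenated receive channels.

    Parameters
    ----------
    channel_data : complex array [channel, echo, rep, x, y, z]
        All receive channels (both shim modes concatenated for the
        two-mode reconstruction).

    Returns
    -------
    complex array [echo, rep, x, y, z]
        Per voxel, the projection of the channel data onto the
        principal left singular vector of its channel x (echo*rep)
        matrix.  For rank-1 noiseless input this preserves
        inter-repetition phase differences exactly.  All-zero voxels
        combine to zero.
    """
    nc, ne, nr = channel_data.shape[:3]
    spatial = channel_data.shape[3:]
    X = channel_data.reshape(nc, ne * nr, -1)          # [c, obs, vox]
    # per-voxel channel covariance, [vox, c, c]
    C = np.einsum("cov,dov->vcd", X, np.conj(X))
    vals, vecs = np.linalg.eigh(C)
    u = vecs[..., -1]                                   # [vox, c], top eigvec
    # fix the arbitrary per-voxel phase: largest component real positive
    lead = np.take_along_axis(u, np.argmax(np.abs(u), axis=1)[:, None], axis=1)
    phase = np.where(np.abs(lead) > 0, lead / np.abs(lead).clip(min=1e-300), 1.0)
    u = u * np.conj(phase)
    combined = np.einsum("vc,cov->ov", np.conj(u), X)   # [obs, vox]
    return combined.reshape(ne, nr, *spatial)


def phase_with_first_echo(combined: np.ndarray, eps: float = 0.0):
    """Remove per-repetition common-mode phase using echo 1.

    Each echo ``e >= 2`` is multiplied by the unit-magnitude conjugate
    phase of echo 1 of the same repetition.  Returns the phased later
    echoes ``[echo-1, rep, ...]`` and a validity mask flagging voxels
    whose echo-1 magnitude is zero.
    """
    if combined.shape[0] < 2:
        raise ValueError("first-echo phasing needs at least 2 echoes")
    e1 = combined[0]
    mag = np.abs(e1)
    valid = mag > eps
    ref_phase = np.where(valid, e1 / np.where(valid, mag, 1.0), 1.0)
    phased = combined[1:] * np.conj(ref_phase)[None]
    return phased, valid


def phase_to_temperature(dphi: np.ndarray | float, te_eff_s: float,
                         config: ReconConfig | None = None,
                         dphi_drift: np.ndarray | float = 0.0):
    """Convert phase difference (radians) to temperature change (degC).

    dT = (dphi - dphi_drift) / (2*pi*gamma*alpha*B0*TE_eff); with the
    negative alpha, heating corresponds to negative phase accrual.
    """
    config = config or ReconConfig()
    if te_eff_s <= 0:
        raise ValueError("TE_eff must be positive")
    denom = constants.phase_per_degC(te_eff_s, config.gamma_hz_per_t,
                                     config.alpha_ppm_per_c, config.b0_t)
    return (np.asarray(dphi) - dphi_drift) / denom


def combine_echo_maps(echo_maps: np.ndarray, magnitudes: np.ndarray,
                      te_ms) -> tuple[np.ndarray, np.ndarray]:
    """Combine per-echo temperature maps weighted by TE * |I|.

    Returns the convex combination and a mask of voxels where at least
    one weight is positive (elsewhere the output is zero and masked).
    """
    echo_maps = np.asarray(echo_maps, dtype=float)
    te = np.asarray(te_ms, dtype=float).reshape(
        (-1,) + (1,) * (echo_maps.ndim - 1))
    if echo_maps.shape[0] != te.size:
        raise ValueError("one TE per echo map required")
    w = te * np.abs(magnitudes)
    wsum = w.sum(axis=0)
    ok = wsum > 0
    combined = np.zeros(echo_maps.shape[1:])
    np.divide((w * echo_maps).sum(axis=0), wsum, out=combined, where=ok)
    return combined, ok


def fit_drift_model(maps: np.ndarray, mask: np.ndarray, coords,
                    rep_labels=None, times_s=None) -> DriftModel:
    """Per-repetition OLS fit of dT = a0 + ax*x + ay*y + az*z over mask."""
    X, Y, Z = coords
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty drift-fit mask")
    A = np.column_stack([np.ones(mask.sum()), X[mask], Y[mask], Z[mask]])
    if np.linalg.matrix_rank(A) < 4:
        raise ValueError("degenerate mask: drift plane is not identifiable")
    n_reps = maps.shape[0]
    coeffs = np.empty((n_reps, 4))
    AtA_inv_At = np.linalg.pinv(A)
    for r in range(n_reps):
        coeffs[r] = AtA_inv_At @ maps[r][mask]
    if rep_labels is None:
        rep_labels = np.arange(1, n_reps + 1)
    return DriftModel(coeffs=coeffs, rep_labels=np.asarray(rep_labels),
                      times_s=None if times_s is None else np.asarray(times_s))


def probe_drift_correct(delta_T: np.ndarray, probe_values, probe_rois):
    """Remove the scalar drift offset implied by fibre-optic probes.

    ``probe_rois`` are boolean masks (typically ~4 voxels around each
    probe tip).  The map is shifted by minus the mean over probes of
    (ROI-mean - probe reading), so with one probe the corrected ROI
    mean equals the probe value exactly.
    """
    probe_values = np.atleast_1d(np.asarray(probe_values, dtype=float))
    offsets = []
    for val, roi in zip(probe_values, probe_rois):
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            raise ValueError("probe ROI is empty or outside the mask")
        offsets.append(float(np.mean(delta_T[roi])) - val)
    return delta_T - float(np.mean(offsets))


@dataclass
class StabilityReport:
    """Drift stabilisation diagnostics of a no-heating scan."""

    rep_labels: np.ndarray
    bulk_C: np.ndarray                 # a0 per repetition
    gradient_C_per_mm: np.ndarray      # [rep, 3], |ax|,|ay|,|az|
    rate_C_per_mm_per_window: np.ndarray  # [rep - w, 3]
    window_reps: int
    threshold_C_per_mm: float
    stabilised_rep: int | None         # 1-based label, None if never

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rep": self.rep_labels,
            "a0_C": self.bulk_C,
            "gx_C_per_mm": self.gradient_C_per_mm[:, 0],
            "gy_C_per_mm": self.gradient_C_per_mm[:, 1],
            "gz_C_per_mm": self.gradient_C_per_mm[:, 2],
        })


def stability_report(drift_model: DriftModel, tr_s: float,
                     window_s: float = 600.0,
                     threshold_C_per_mm: float = 0.001) -> StabilityReport:
    """Locate when the spatial drift gradients stop evolving.

    The gradient rate at repetition r is the change of each axis
    coefficient over the following ``window_s`` of scanning; the scan
    is 'stabilised' at the first repetition from which the maximum axis
    rate stays below ``threshold_C_per_mm`` (per window) for the rest
    of the series.  The bulk offset is reported but not thresholded
    (on real systems it keeps growing).
    """
    coeffs = drift_model.coeffs
    n = coeffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 repetitions")
    w = max(1, int(round(window_s / tr_s)))
    w = min(w, n - 1)
    rates = np.abs(coeffs[w:, 1:] - coeffs[:-w, 1:])   # [n-w, 3]
    below = rates.max(axis=1) < threshold_C_per_mm
    stabilised = None
    for r in range(below.size):
        if below[r:].all():
            stabilised = int(drift_model.rep_labels[r])
            break
    return StabilityReport(
        rep_labels=drift_model.rep_labels,
        bulk_C=coeffs[:, 0],
        gradient_C_per_mm=np.abs(coeffs[:, 1:]),
        rate_C_per_mm_per_window=rates,
        window_reps=w,
        threshold_C_per_mm=threshold_C_per_mm,
        stabilised_rep=stabilised)


def temporal_std_map(maps: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Unbiased per-voxel standard deviation over the repetition axis."""
    maps = np.asarray(maps)
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 repetitions for a std map")
    return maps.std(axis=0, ddof=ddof)


def rmse_map(delta_T: np.ndarray, reference: np.ndarray,
             mask: np.ndarray | None = None):
    """Masked RMSE between two temperature maps; returns (scalar, diff)."""
    delta_T = np.asarray(delta_T, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if delta_T.shape != reference.shape:
        raise ValueError("temperature maps must have matching shapes")
    diff = delta_T - reference
    m = np.ones(delta_T.shape, bool) if mask is None else np.asarray(mask, bool)
    return float(np.sqrt(np.mean(diff[m] ** 2))), diff


@dataclass
class ReconResult:
    """Output of the full reconstruction pipeline."""

    delta_T: np.ndarray                # [rep, x, y, z], combined echoes
    per_echo_delta_T: np.ndarray       # [echo, rep, x, y, z]
    echo_magnitudes: np.ndarray        # [echo, rep, x, y, z]
    mask: np.ndarray
    te_eff_ms: np.ndarray
    echoes_used: tuple[int, ...]
    config: ReconConfig
    voxel_size_mm: tuple[float, float, float]
    drift_model: DriftModel | None = None

    def coordinates_mm(self):
        shape = self.delta_T.shape[1:]
        ax = [(np.arange(n) - (n - 1) / 2) * d
              for n, d in zip(shape, self.voxel_size_mm)]
        return np.meshgrid(*ax, indexing="ij")

    def temperature_map(self, rep: int) -> TemperatureMap:
        """Map for a 1-based repetition label."""
        return TemperatureMap(delta_T=self.delta_T[rep - 1], mask=self.mask,
                              repetition=rep, echoes_used=self.echoes_used,
                              drift_applied=self.config.drift_correction)


def reconstruct_temperature(series: MultiEchoSeries,
                            config: ReconConfig | None = None,
                            probe_delta_T: np.ndarray | None = None,
                            probe_rois=None,
                            drift_mask: np.ndarray | None = None) -> ReconResult:
    """Run the full thermometry pipeline on a multi-echo series.

    Parameters
    ----------
    series : MultiEchoSeries
    config : ReconConfig
    probe_delta_T : array [rep, probe], optional
        Fibre-optic probe readings for ``drift_correction='probe'``.
    probe_rois : list of boolean masks, optional
        ROI per probe on the reconstructed grid.
    drift_mask : boolean mask, optional
        Region used for the plane-drift fit (``'plane'`` mode); defaults
        to the signal mask.
    """
    config = config or ReconConfig()
    data = series.data if config.tiamo else \
        series.data[config.mode_index:config.mode_index + 1]
    nm, nc, ne, nr = data.shape[:4]
    channels = data.reshape(nm * nc, ne, nr, *data.shape[4:])

    target = config.zero_pad_shape
    if target is not None or config.apodise:
        channels = reconstruct_images(channels, target_shape=target,
                                      apodise=config.apodise)
    recon_shape = channels.shape[-3:]
    voxel_size = tuple(v * a / r for v, a, r in
                       zip(series.voxel_size_mm, series.matrix, recon_shape))

    combined = combine_coils_svd(channels)
    del channels

    phased, valid = phase_with_first_echo(combined)
    mags = np.abs(combined[1:])

    # signal mask from the reference repetition's echo-1 magnitude
    ref = config.reference_rep - 1
    if not 0 <= ref < nr:
        raise ValueError("reference repetition outside the series")
    e1mag = np.abs(combined[0, ref])
    robust_max = np.percentile(e1mag, 99.5)
    mask = valid.all(axis=0) & (e1mag > config.mask_threshold * robust_max)
    del combined

    # phase difference against the reference repetition
    ref_conj = np.conj(phased[:, ref] /
                       np.abs(phased[:, ref]).clip(min=1e-300))
    dphi = np.angle(phased * ref_conj[:, None])

    te = np.asarray(series.te_ms)
    echo_idx = [e - 2 for e in config.echoes_for_temp]  # into phased array
    if any(i < 0 or i >= ne - 1 for i in echo_idx):
        raise ValueError("echoes_for_temp must be later echoes (>= 2)")
    if config.te_convention == "effective":
        te_eff_ms = te[1:] - te[0]
    else:
        te_eff_ms = te[1:].copy()

    per_echo = np.stack([
        phase_to_temperature(dphi[i], te_eff_ms[i] * 1e-3, config)
        for i in echo_idx])
    echo_mags = np.stack([mags[i] for i in echo_idx])
    te_used = np.array([te[i + 1] for i in echo_idx])   # nominal TE weights

    delta_T = np.empty((nr, *recon_shape))
    for r in range(nr):
        delta_T[r], _ = combine_echo_maps(per_echo[:, r], echo_mags[:, r],
                                          te_used)

    drift_model = None
    ax_ = [(np.arange(n) - (n - 1) / 2) * d
           for n, d in zip(recon_shape, voxel_size)]
    coords = np.meshgrid(*ax_, indexing="ij")
    if config.drift_correction == "plane":
        fit_region = mask if drift_mask is None else drift_mask
        drift_model = fit_drift_model(delta_T, fit_region, coords)
        drift_fields = drift_model.evaluate(coords)
        delta_T = delta_T - drift_fields
    elif config.drift_correction == "probe":
        if probe_delta_T is None or probe_rois is None:
            raise ValueError("probe drift correction needs probe readings "
                             "and ROIs")
        probe_rel = probe_delta_T - probe_delta_T[ref]
        for r in range(nr):
            delta_T[r] = probe_drift_correct(delta_T[r], probe_rel[r],
                                             probe_rois)

    return ReconResult(delta_T=delta_T, per_echo_delta_T=per_echo,
                       echo_magnitudes=echo_mags, mask=mask,
                       te_eff_ms=np.array([te_eff_ms[i] for i in echo_idx]),
                       echoes_used=tuple(config.echoes_for_temp),
                       config=config, voxel_size_mm=voxel_size,
                       drift_model=drift_model)
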