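"""Classical perfusion-map engine.

Converts a DSC signal series to contrast concentration and computes the five
standard maps: CBV as the area under the tissue curve relative to the AIF
area, CBF and Tmax from the residue curve recovered by block-circulant SVD
(cSVD) deconvolution, MTT from the central volume theorem CBV/CBF, and TTP
directly from the tissue curve (the one map that needs no deconvolution).

The block-circulant formulation zero-pads both curves to L = factor * T and
inverts the circulant AIF convolution matrix through a truncated SVD, which
makes the recovered residue curve insensitive to bolus arrival delay: a
delayed tissue curve shows up as a shifted peak in k(t) rather than a
corrupted amplitude, which is exactly what Tmax reads out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyResultError, InvalidParameterError, ShapeError, SingularInputError
from .phantom import AcquisitionParams, Phantom4D


@dataclass(frozen=True)
class DeconvolutionConfig:
    svd_threshold_fraction: float = 0.10  # fraction of the largest singular value
    circulant_padding_factor: int = 2

    def __post_init__(self):
        if not 0.0 <= self.svd_threshold_fraction < 1.0:
            raise InvalidParameterError("svd threshold fraction must be in [0, 1)")
        if self.circulant_padding_factor < 2:
            raise InvalidParameterError("circulant padding factor must be >= 2")


@dataclass
class ConcentrationSeries:
    conc: np.ndarray          # (slice, h, w, t), concentration a.u.
    times: np.ndarray
    baseline_frames: int
    mask: np.ndarray          # voxels with a usable baseline


@dataclass
class PerfusionMaps:
    cbf: np.ndarray   # relative flow, 1/s
    cbv: np.ndarray   # relative volume, dimensionless
    mtt: np.ndarray   # seconds
    tmax: np.ndarray  # seconds (multiples of tr)
    ttp: np.ndarray   # seconds (multiples of tr)
    mask: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"cbf": self.cbf, "cbv": self.cbv, "mtt": self.mtt,
                "tmax": self.tmax, "ttp": self.ttp}


def signal_to_concentration(signal: np.ndarray, acq: AcquisitionParams) -> ConcentrationSeries:
    """C(t) = -ln(S/S0) / (k * TE) with S0 the prebolus mean.

    Voxels whose baseline is non-positive (air/background) are flagged out of
    the mask.  The signal is floored at machine-epsilon * S0 before the log;
    negative concentrations from noise are kept to preserve noise statistics
    in the integrals.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 4:
        raise ShapeError("signal must be 4D (slice, h, w, t)")
    if signal.shape[-1] < acq.n_prebolus:
        raise ShapeError("fewer frames than prebolus baseline frames")
    s0 = signal[..., : acq.n_prebolus].mean(axis=-1)
    mask = s0 > 0
    floor = np.finfo(float).eps * np.where(mask, s0, 1.0)
    safe = np.maximum(signal, floor[..., None])
    conc = np.zeros_like(signal)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc[mask] = -np.log(safe[mask] / s0[mask, None]) / (acq.k_conversion * acq.te)
    return ConcentrationSeries(conc=conc, times=acq.times, baseline_frames=acq.n_prebolus, mask=mask)


def _circulant_inverse(aif_curve: np.ndarray, tr: float, cfg: DeconvolutionConfig) -> np.ndarray:
    """Regularized inverse of the padded circulant AIF convolution matrix."""
    aif_curve = np.asarray(aif_curve, dtype=float)
    if not np.any(aif_curve):
        raise SingularInputError("AIF curve is identically zero")
    t_len = aif_curve.size
    pad = cfg.circulant_padding_factor * t_len
    ca = np.zeros(pad)
    ca[:t_len] = aif_curve
    idx = (np.arange(pad)[:, None] - np.arange(pad)[None, :]) % pad
    a = tr * ca[idx]
    u, s, vt = np.linalg.svd(a)
    keep = s >= cfg.svd_threshold_fraction * s[0]
    s_inv = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    s_inv[s <= 0] = 0.0
    return (vt.T * s_inv) @ u.T


def csvd_deconvolve(
    voxel_conc: np.ndarray,
    aif_curve: np.ndarray,
    tr: float,
    cfg: DeconvolutionConfig | None = None,
) -> np.ndarray:
    """Recover k(t) = CBF' * R(t - delay) for one voxel; returns the first T
    lags of the padded solution (the physically meaningful support)."""
    cfg = cfg or DeconvolutionConfig()
    voxel_conc = np.asarray(voxel_conc, dtype=float)
    aif_curve = np.asarray(aif_curve, dtype=float)
    if voxel_conc.shape != aif_curve.shape:
        raise ShapeError("tissue curve and AIF must have equal length")
    inv = _circulant_inverse(aif_curve, tr, cfg)
    padded = np.zeros(inv.shape[0])
    padded[: voxel_conc.size] = voxel_conc
    return (inv @ padded)[: voxel_conc.size]


def compute_cbv(voxel_conc: np.ndarray, aif_curve: np.ndarray, times: np.ndarray) -> float:
    """Relative CBV: area under the tissue curve over area under the AIF.

    Areas use the rectangle rule — the same quadrature as the discrete
    convolution forward model — which makes the ratio exactly invariant to
    the ordering of the frames.
    """
    denom = float(np.sum(aif_curve))
    if denom == 0:
        raise SingularInputError("AIF has zero area")
    return float(np.sum(voxel_conc) / denom)


def compute_cbf(residue_curve: np.ndarray) -> float:
    """CBF' as the height of the deconvolved curve (max over lags, which is
    delay-insensitive in the circulant formulation)."""
    return float(np.max(residue_curve))


def compute_mtt(cbv: float, cbf: float, eps: float = 1e-12) -> float:
    """Central volume theorem CBV/CBF; NaN marks a masked-invalid voxel."""
    if cbf <= eps:
        return float("nan")
    return cbv / cbf


def compute_tmax(residue_curve: np.ndarray, tr: float) -> float:
    """Time of the residue-curve maximum (earliest frame on ties)."""
    return float(np.argmax(residue_curve) * tr)


def compute_ttp(voxel_conc: np.ndarray, tr: float) -> tuple[float, bool]:
    """Time-to-peak of the tissue curve; flags voxels with no contrast swing."""
    voxel_conc = np.asarray(voxel_conc, dtype=float)
    low_contrast = bool(np.ptp(voxel_conc) == 0.0)
    return float(np.argmax(voxel_conc) * tr), low_contrast


def compute_all_maps(
    signal_or_phantom: np.ndarray | Phantom4D,
    aif_curve: np.ndarray | None = None,
    acq: AcquisitionParams | None = None,
    cfg: DeconvolutionConfig | None = None,
    mask: np.ndarray | None = None,
) -> PerfusionMaps:
    """Run the full classical pipeline over a masked 4D grid.

    Accepts either a raw 4D signal plus AIF/acquisition, or a
    :class:`Phantom4D` (whose known AIF and acquisition are used).
    """
    if isinstance(signal_or_phantom, Phantom4D):
        ph = signal_or_phantom
        signal = ph.signal
        aif_curve = ph.aif_curve if aif_curve is None else aif_curve
        acq = ph.acquisition if acq is None else acq
        mask = ph.brain_mask if mask is None else mask
    else:
        signal = np.asarray(signal_or_phantom, dtype=float)
        if aif_curve is None or acq is None:
            raise InvalidParameterError("raw signal input requires aif_curve and acq")
    cfg = cfg or DeconvolutionConfig()

    series = signal_to_concentration(signal, acq)
    valid = series.mask if mask is None else (series.mask & mask)
    if not valid.any():
        raise EmptyResultError("no valid voxels inside the mask")

    tr = acq.tr
    t_len = signal.shape[-1]
    conc_flat = series.conc[valid]                       # (V, T)
    inv = _circulant_inverse(aif_curve, tr, cfg)         # (L, L)
    padded = np.zeros((conc_flat.shape[0], inv.shape[0]))
    padded[:, :t_len] = conc_flat
    k = padded @ inv.T
    k = k[:, :t_len]                                     # meaningful support

    cbf_v = k.max(axis=1)
    tmax_v = k.argmax(axis=1) * tr
    aif_area = float(np.sum(aif_curve))
    if aif_area == 0:
        raise SingularInputError("AIF has zero area")
    cbv_v = conc_flat.sum(axis=1) / aif_area
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt_v = np.where(cbf_v > 1e-12, cbv_v / np.where(cbf_v > 1e-12, cbf_v, 1.0), np.nan)
    ttp_v = conc_flat.argmax(axis=1) * tr

    def to_map(vals):
        out = np.zeros(signal.shape[:3])
        out[valid] = vals
        return out

    # voxels with no recoverable flow carry an undefined MTT: drop from mask
    final_mask = np.zeros(signal.shape[:3], dtype=bool)
    final_mask[valid] = cbf_v > 1e-12
    return PerfusionMaps(
        cbf=to_map(cbf_v), cbv=to_map(cbv_v), mtt=to_map(mtt_v),
        tmax=to_map(tmax_v), ttp=to_map(ttp_v), mask=final_mask,
    )
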