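"""Digital DSC-MRI perfusion phantom.

Simulates bolus passage through brain tissue with known per-voxel
hemodynamics, producing a 4D signal series plus the ground-truth parameter
maps that generated it.  The forward model is standard indicator-dilution
theory:

    C_a(t)         gamma-variate arterial input function
    R(t)           tissue residue function, R(0) = 1, non-increasing
    C_v(t)         = CBF' * (C_a (*) R)(t - delay)      (causal convolution)
    S(t)           = S0 * exp(-k * TE * C_v(t))         (T2* signal model)

with CBF' the relative flow in 1/s and the dimensionless relative blood
volume CBV' = CBF' * MTT (central volume theorem).  A focal "lesion" region
carries reduced flow and prolonged transit/arrival delay, mimicking the
hypoperfusion patterns of acute stroke.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import BoundsError, InvalidParameterError, ShapeError

# clinical <-> relative unit conversions
# CBF [ml/100g/min] -> relative flow [1/s]; CBV [ml/100g] -> dimensionless fraction.
# With these, MTT [s] = CBV'/CBF' = 60 * CBV/CBF.


def cbf_to_relative(cbf_ml_100g_min: float) -> float:
    return cbf_ml_100g_min / 6000.0


def cbv_to_relative(cbv_ml_100g: float) -> float:
    return cbv_ml_100g / 100.0


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate arterial input function, normalized so the peak value
    equals ``amplitude`` (reached at ``t0 + alpha * beta``)."""

    amplitude: float = 5.0   # peak concentration, a.u. (mM-scale)
    t0: float = 17.76        # bolus arrival, s (= 8 prebolus frames at TR 2.22 s)
    alpha: float = 3.0       # shape, dimensionless
    beta: float = 1.5        # timescale, s

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise InvalidParameterError("gamma-variate alpha and beta must be positive")
        if self.t0 < 0:
            raise InvalidParameterError("bolus arrival t0 must be non-negative")


@dataclass(frozen=True)
class VoxelHemodynamics:
    """Ground-truth hemodynamic state of one voxel (relative units)."""

    cbf: float               # relative flow, 1/s
    mtt: float               # mean transit time, s
    delay: float = 0.0       # bolus arrival delay, s
    residue_model: str = "exponential"  # or "boxcar"

    def __post_init__(self):
        if self.cbf < 0 or self.mtt < 0 or self.delay < 0:
            raise InvalidParameterError("hemodynamic parameters must be non-negative")

    @property
    def cbv(self) -> float:
        """Relative blood volume via the central volume theorem."""
        return self.cbf * self.mtt


@dataclass(frozen=True)
class AcquisitionParams:
    tr: float = 2.22          # repetition time, s
    te: float = 0.036         # echo time, s
    n_frames: int = 60        # dynamic measurements (acute-stroke protocol: 50-75)
    n_prebolus: int = 8       # baseline frames before bolus arrival
    s0: float = 100.0         # baseline signal, a.u.
    k_conversion: float = 40.0  # susceptibility proportionality, 1/(mM*s)
    noise_sd: float = 1.0     # additive Gaussian signal noise, a.u.
    grid: tuple[int, int, int] = (21, 128, 128)  # (slices, height, width)

    def __post_init__(self):
        if self.tr <= 0 or self.te <= 0:
            raise InvalidParameterError("tr and te must be positive")
        if self.n_prebolus < 8:
            raise InvalidParameterError("at least eight prebolus frames are required")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr


# Small-grid preset for fast end-to-end runs; full-size default mirrors the
# 21 x 128 x 128 clinical grid.
PRESETS: dict[str, AcquisitionParams] = {
    "default": AcquisitionParams(),
    "ci": AcquisitionParams(n_frames=32, grid=(4, 32, 32)),
}


@dataclass(frozen=True)
class LesionSpec:
    """Ellipsoidal hypoperfused region: fractions of the grid extent."""

    center: tuple[float, float, float] = (0.5, 0.45, 0.32)  # (slice, y, x) fractions
    radii: tuple[float, float, float] = (0.45, 0.22, 0.22)  # fractions of each extent
    cbf_scale: float = 0.35
    mtt_scale: float = 2.0
    delay_add: float = 6.0  # extra arrival delay inside the lesion, s

    def __post_init__(self):
        if not all(0.0 <= c <= 1.0 for c in self.center):
            raise BoundsError("lesion center fractions must lie inside [0, 1]")
        if self.cbf_scale <= 0 or self.mtt_scale <= 0 or self.delay_add < 0:
            raise InvalidParameterError("lesion multipliers must be positive")


@dataclass
class Phantom4D:
    """Synthetic 4D DSC series plus the truth maps that generated it."""

    signal: np.ndarray            # (slice, h, w, t)
    truth: dict[str, np.ndarray]  # cbf, cbv, mtt, delay, tmax, ttp as 3D maps
    aif: AifParams
    aif_curve: np.ndarray         # C_a sampled at acquisition times
    acquisition: AcquisitionParams
    brain_mask: np.ndarray
    lesion_mask: np.ndarray
    seed: int = 0


def gamma_variate_aif(params: AifParams, times: np.ndarray) -> np.ndarray:
    """Sample the gamma-variate bolus curve; zero for t <= t0, peak at t0+alpha*beta."""
    times = np.asarray(times, dtype=float)
    tau = (times - params.t0) / (params.alpha * params.beta)
    with np.errstate(invalid="ignore"):
        curve = params.amplitude * np.power(np.clip(tau, 0.0, None), params.alpha) * np.exp(
            params.alpha * (1.0 - tau)
        )
    curve[times <= params.t0] = 0.0
    return curve


def residue_function(model: str, mtt: float, times: np.ndarray) -> np.ndarray:
    """Residue curve R(t): fraction of tracer still present t seconds after
    an instantaneous arterial impulse.

    The exponential variant uses a decay constant calibrated so that the
    left-rectangle discrete integral over the sampling grid equals MTT
    exactly; at fine sampling this converges to exp(-t/MTT).  This keeps the
    discrete forward model consistent with the central volume theorem even
    at the coarse TR of a clinical acquisition.
    """
    if mtt <= 0:
        raise InvalidParameterError("mtt must be positive")
    times = np.asarray(times, dtype=float)
    if model == "boxcar":
        return (times < mtt).astype(float)
    if model != "exponential":
        raise InvalidParameterError(f"unknown residue model {model!r}")
    dt = times[1] - times[0] if times.size > 1 else 0.0
    if 0.0 < dt < mtt:
        tau = -dt / np.log1p(-dt / mtt)  # discrete-area-preserving decay constant
    else:
        tau = mtt
    return np.exp(-times / tau)


def _delay_frames(delay: float, tr: float) -> int:
    return int(round(delay / tr))


def tissue_concentration(
    voxel: VoxelHemodynamics, aif_curve: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Forward model for one voxel: CBF' * (C_a (*) R)(t - delay), rectangle rule."""
    aif_curve = np.asarray(aif_curve, dtype=float)
    times = np.asarray(times, dtype=float)
    if aif_curve.shape != times.shape:
        raise ShapeError("AIF curve and time grid must have equal length")
    t_len = times.size
    tr = times[1] - times[0] if t_len > 1 else 1.0
    if voxel.cbf == 0.0:
        return np.zeros(t_len)
    r = residue_function(voxel.residue_model, voxel.mtt, times)
    conv = np.convolve(aif_curve, r)[:t_len] * tr
    conc = voxel.cbf * conv
    d = _delay_frames(voxel.delay, tr)
    if d:
        conc = np.concatenate([np.zeros(d), conc[: t_len - d]])
    return conc


def concentration_to_signal(conc: np.ndarray, acq: AcquisitionParams) -> np.ndarray:
    """T2*-weighted signal: S = S0 * exp(-k * TE * C)."""
    if acq.s0 <= 0:
        raise InvalidParameterError("baseline signal s0 must be positive")
    return acq.s0 * np.exp(-acq.k_conversion * acq.te * np.asarray(conc, dtype=float))


def _ellipsoid_mask(grid, center_frac, radii_frac) -> np.ndarray:
    nz, ny, nx = grid
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = (c * (n - 1) for c, n in zip(center_frac, (nz, ny, nx)))
    rz, ry, rx = (max(r * n, 1e-9) for r, n in zip(radii_frac, (nz, ny, nx)))
    return ((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def _brain_mask(grid) -> np.ndarray:
    """Stack of shrinking ellipses, a crude head: every slice non-empty."""
    nz, ny, nx = grid
    z = np.arange(nz)
    f = np.sqrt(np.clip(1.0 - ((z - (nz - 1) / 2) / (nz / 2 + 0.5)) ** 2, 0.0, None))
    yy, xx = np.ogrid[:ny, :nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    mask = np.zeros(grid, dtype=bool)
    for k in range(nz):
        ry, rx = 0.44 * ny * f[k], 0.44 * nx * f[k]
        mask[k] = ((yy - cy) / max(ry, 1e-9)) ** 2 + ((xx - cx) / max(rx, 1e-9)) ** 2 <= 1.0
    return mask


def _smooth_field(rng: np.random.Generator, grid, rel_sd: float = 0.10) -> np.ndarray:
    """Mildly heterogeneous multiplicative field, mean ~1."""
    noise = rng.standard_normal(grid)
    smooth = ndimage.gaussian_filter(noise, sigma=(0.5, 2.0, 2.0))
    sd = smooth.std() or 1.0
    return np.clip(1.0 + rel_sd * smooth / sd, 0.3, None)


def _vectorized_concentration(
    cbf: np.ndarray, mtt: np.ndarray, delay_frames: np.ndarray,
    aif_curve: np.ndarray, times: np.ndarray,
) -> np.ndarray:
    """FFT convolution of one AIF with per-voxel exponential residues.

    Same quadrature as :func:`tissue_concentration` (rectangle rule, causal,
    integer-frame delay); inputs are flat arrays over voxels.
    """
    t_len = times.size
    tr = times[1] - times[0]
    pad = 2 * t_len
    ca_f = np.fft.rfft(aif_curve, pad)
    out = np.zeros((cbf.size, t_len))
    chunk = 8192
    for lo in range(0, cbf.size, chunk):
        hi = min(lo + chunk, cbf.size)
        m = mtt[lo:hi, None]
        ratio = np.where(m > tr, tr / np.maximum(m, 1e-12), 0.5)  # dummy in else-branch
        tau = np.where(m > tr, -tr / np.log1p(-ratio), np.maximum(m, 1e-12))
        r = np.exp(-times[None, :] / tau)
        conv = np.fft.irfft(np.fft.rfft(r, pad, axis=1) * ca_f[None, :], pad, axis=1)[:, :t_len]
        out[lo:hi] = cbf[lo:hi, None] * conv * tr
    # integer-frame arrival delays
    for d in np.unique(delay_frames):
        if d <= 0:
            continue
        idx = delay_frames == d
        shifted = np.zeros_like(out[idx])
        shifted[:, d:] = out[idx][:, : t_len - d]
        out[idx] = shifted
    return out


def build_phantom(
    seed: int,
    acq: AcquisitionParams | None = None,
    lesion: LesionSpec | None = None,
    aif: AifParams | None = None,
    background_delay: float | None = None,
) -> Phantom4D:
    """Deterministically assemble a phantom: tissue classes, truth maps,
    forward-model signal and additive Gaussian noise."""
    acq = acq or PRESETS["default"]
    lesion = lesion if lesion is not None else LesionSpec()
    if aif is None:
        aif = AifParams(t0=acq.n_prebolus * acq.tr)
    rng = np.random.default_rng(seed)
    grid = acq.grid
    times = acq.times

    brain = _brain_mask(grid)
    # gray matter shell around a white-matter core
    wm = _ellipsoid_mask(grid, (0.5, 0.5, 0.5), (0.8, 0.28, 0.28)) & brain

    cbf = np.zeros(grid)
    mtt = np.zeros(grid)
    cbf[brain] = cbf_to_relative(60.0)   # gray matter: 60 ml/100g/min, MTT 4 s
    mtt[brain] = 4.0
    cbf[wm] = cbf_to_relative(25.0)      # white matter: 25 ml/100g/min, MTT 4.8 s
    mtt[wm] = 4.8
    cbf *= _smooth_field(rng, grid)
    mtt *= _smooth_field(rng, grid)

    delay = np.zeros(grid)
    if background_delay is None:
        background_delay = acq.tr  # one-frame arrival lag everywhere in brain
    delay[brain] = background_delay

    lesion_mask = np.zeros(grid, dtype=bool)
    if lesion is not None:
        lesion_mask = _ellipsoid_mask(grid, lesion.center, lesion.radii) & brain
        if not lesion_mask.any():
            raise BoundsError("lesion region does not intersect the brain mask")
        cbf[lesion_mask] *= lesion.cbf_scale
        mtt[lesion_mask] *= lesion.mtt_scale
        delay[lesion_mask] += lesion.delay_add

    # snap delays to the frame grid (they are applied as whole-frame shifts)
    dframes = np.round(delay / acq.tr).astype(int)
    delay = dframes * acq.tr
    cbv = cbf * mtt  # central volume theorem holds exactly by construction

    aif_curve = gamma_variate_aif(aif, times)
    conc = np.zeros(grid + (acq.n_frames,))
    flat = brain.ravel()
    conc.reshape(-1, acq.n_frames)[flat] = _vectorized_concentration(
        cbf.ravel()[flat], mtt.ravel()[flat], dframes.ravel()[flat], aif_curve, times
    )

    signal = np.zeros_like(conc)
    signal[brain] = concentration_to_signal(conc[brain], acq)
    if acq.noise_sd > 0:
        signal = signal + rng.normal(0.0, acq.noise_sd, signal.shape)
        signal = np.clip(signal, 0.0, None)

    ttp = np.argmax(conc, axis=-1) * acq.tr
    ttp[~brain] = 0.0
    truth = {
        "cbf": cbf, "cbv": cbv, "mtt": mtt, "delay": delay,
        "tmax": delay.copy(), "ttp": ttp,
    }
    return Phantom4D(
        signal=signal, truth=truth, aif=aif, aif_curve=aif_curve,
        acquisition=acq, brain_mask=brain, lesion_mask=lesion_mask, seed=seed,
    )


def generate_cohort(
    n_patients: int,
    seed: int,
    acq: AcquisitionParams | None = None,
    delay_rich: bool = False,
) -> dict[str, Phantom4D]:
    """A cohort of phantoms with per-patient lesion geometry and severity.

    ``delay_rich`` draws wide per-patient arrival delays (variable background
    lag plus 2-8 s extra inside the lesion), emulating the acute-occlusion
    regime where the timing maps (Tmax, TTP) carry most of the contrast
    between patients.
    """
    acq = acq or PRESETS["ci"]
    rng = np.random.default_rng(seed)
    cohort: dict[str, Phantom4D] = {}
    for i in range(n_patients):
        lesion = LesionSpec(
            center=(
                float(rng.uniform(0.3, 0.7)),
                float(rng.uniform(0.3, 0.65)),
                float(rng.uniform(0.25, 0.45)) if rng.random() < 0.5 else float(rng.uniform(0.55, 0.75)),
            ),
            radii=(
                float(rng.uniform(0.3, 0.6)),
                float(rng.uniform(0.15, 0.3)),
                float(rng.uniform(0.15, 0.3)),
            ),
            cbf_scale=float(rng.uniform(0.25, 0.5)),
            mtt_scale=float(rng.uniform(1.5, 2.5)),
            delay_add=float(rng.uniform(2.0, 8.0)) if delay_rich else 6.0,
        )
        background_delay = acq.tr * int(rng.integers(0, 3)) if delay_rich else acq.tr
        cohort[f"p{i:03d}"] = build_phantom(
            seed=int(rng.integers(0, 2**31 - 1)),
            acq=acq,
            lesion=lesion,
            background_delay=background_delay,
        )
    return cohort


def save_phantom(phantom: Phantom4D, out_dir: str | Path) -> Path:
    """Write signal + truth maps as NIfTI plus a JSON sidecar."""
    from .io import write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(out_dir / "dsc.nii.gz", phantom.signal)
    for name, vol in phantom.truth.items():
        write_volume(out_dir / f"truth_{name}.nii.gz", vol)
    write_volume(out_dir / "brain_mask.nii.gz", phantom.brain_mask.astype(np.uint8))
    write_volume(out_dir / "lesion_mask.nii.gz", phantom.lesion_mask.astype(np.uint8))
    meta = {
        "seed": phantom.seed,
        "aif": dataclasses.asdict(phantom.aif),
        "acquisition": dataclasses.asdict(phantom.acquisition),
        "aif_curve": phantom.aif_curve.tolist(),
    }
    (out_dir / "phantom.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def load_phantom(in_dir: str | Path) -> Phantom4D:
    from .io import read_volume

    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "phantom.json").read_text())
    acq_d = meta["acquisition"]
    acq_d["grid"] = tuple(acq_d["grid"])
    acq = AcquisitionParams(**acq_d)
    truth = {
        name: read_volume(in_dir / f"truth_{name}.nii.gz")[0]
        for name in ("cbf", "cbv", "mtt", "delay", "tmax", "ttp")
    }
    return Phantom4D(
        signal=read_volume(in_dir / "dsc.nii.gz")[0],
        truth=truth,
        aif=AifParams(**meta["aif"]),
        aif_curve=np.asarray(meta["aif_curve"]),
        acquisition=acq,
        brain_mask=read_volume(in_dir / "brain_mask.nii.gz")[0].astype(bool),
        lesion_mask=read_volume(in_dir / "lesion_mask.nii.gz")[0].astype(bool),
        seed=meta["seed"],
    )
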