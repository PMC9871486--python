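"""Pairwise image-comparison metrics and paired model comparison.

All four metrics (MAE, NRMSE, SSIM, PSNR) are computed per slice in the
normalized [-1, 1] representation the GANs operate in, so the dynamic range
L and the maximal pixel value MAX_I both default to 2.  Models are compared
slice-by-slice with the paired two-sided Wilcoxon signed-rank test at the
0.05 level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import InvalidParameterError, ShapeError
from .preprocess import SliceSample

METRIC_NAMES = ("mae", "nrmse", "ssim", "psnr")


@dataclass(frozen=True)
class SsimConstants:
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 2.0  # L for data in [-1, 1]

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def _check(y, y_hat):
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ShapeError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return y, y_hat


def mae(y, y_hat) -> float:
    """Mean absolute voxel-wise error."""
    y, y_hat = _check(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


def nrmse(y, y_hat) -> float:
    """RMSE normalized by the quadratic mean of the true image."""
    y, y_hat = _check(y, y_hat)
    denom = math.sqrt(float(np.mean(y**2)))
    if denom == 0.0:
        raise InvalidParameterError("NRMSE undefined: reference image is identically zero")
    return math.sqrt(float(np.mean((y - y_hat) ** 2))) / denom


def ssim(y, y_hat, constants: SsimConstants | None = None, mode: str = "global", window: int = 8) -> float:
    """Structural similarity: luminance * contrast * structure.

    ``global`` evaluates the formula once over the whole slice; ``windowed``
    averages it over a sliding window (uniform filter) of the given size.
    """
    y, y_hat = _check(y, y_hat)
    c = constants or SsimConstants()
    if mode == "global":
        mu_y, mu_h = y.mean(), y_hat.mean()
        var_y, var_h = y.var(), y_hat.var()
        cov = ((y - mu_y) * (y_hat - mu_h)).mean()
        return float(
            (2 * mu_y * mu_h + c.c1) * (2 * cov + c.c2)
            / ((mu_y**2 + mu_h**2 + c.c1) * (var_y + var_h + c.c2))
        )
    if mode != "windowed":
        raise InvalidParameterError(f"unknown ssim mode {mode!r}")
    f = lambda a: ndimage.uniform_filter(a, size=window, mode="reflect")
    mu_y, mu_h = f(y), f(y_hat)
    var_y = f(y * y) - mu_y**2
    var_h = f(y_hat * y_hat) - mu_h**2
    cov = f(y * y_hat) - mu_y * mu_h
    smap = ((2 * mu_y * mu_h + c.c1) * (2 * cov + c.c2)) / (
        (mu_y**2 + mu_h**2 + c.c1) * (var_y + var_h + c.c2)
    )
    return float(smap.mean())


def psnr(y, y_hat, max_value: float = 2.0, as_printed: bool = False) -> float:
    """Peak signal-to-noise ratio in dB: 10*log10(MAX_I^2 / MSE).

    ``as_printed`` switches to the literal 10*log10(MAX_I / MSE) variant
    (MAX_I not squared).  Identical images yield the +inf sentinel, which
    aggregation excludes with a count.
    """
    y, y_hat = _check(y, y_hat)
    mse = float(np.mean((y - y_hat) ** 2))
    if mse == 0.0:
        return float("inf")
    peak = max_value if as_printed else max_value**2
    return 10.0 * math.log10(peak / mse)


@dataclass
class ComparisonResult:
    metric: str
    n_pairs: int
    n_nonzero: int
    statistic: float | None
    p_value: float | None
    significant: bool | None
    direction: str | None  # which report has the lower mean metric value
    message: str = ""


@dataclass
class MetricReport:
    """Per-slice metric records plus aggregates for one model run."""

    records: pd.DataFrame  # columns: patient, slice, map_type, variant, mae, nrmse, ssim, psnr
    map_type: str
    variant: str

    def aggregate(self) -> pd.DataFrame:
        rows = []
        for m in METRIC_NAMES:
            vals = self.records[m].to_numpy(dtype=float)
            finite = np.isfinite(vals)
            rows.append({
                "metric": m,
                "mean": float(vals[finite].mean()) if finite.any() else float("nan"),
                "sd": float(vals[finite].std(ddof=1)) if finite.sum() > 1 else float("nan"),
                "n": int(finite.sum()),
                "n_infinite": int((~finite).sum()),
            })
        return pd.DataFrame(rows)

    def per_patient(self) -> pd.DataFrame:
        return self.records.groupby("patient")[list(METRIC_NAMES)].mean().reset_index()


def compare_models(
    report_a: MetricReport, report_b: MetricReport, metric: str = "ssim", alpha: float = 0.05
) -> ComparisonResult:
    """Two-sided paired Wilcoxon signed-rank test on per-slice metric values,
    paired by (patient, slice).  Zero differences are dropped (classic
    Wilcoxon); fewer than 5 nonzero pairs yields a warning and no p-value.
    """
    key = ["patient", "slice"]
    a = report_a.records.set_index(key)[metric]
    b = report_b.records.set_index(key)[metric]
    if not a.index.equals(b.index):
        raise ShapeError("reports are not paired: (patient, slice) keys differ")
    diffs = (a - b).to_numpy(dtype=float)
    diffs = diffs[np.isfinite(diffs)]
    nonzero = diffs[diffs != 0.0]
    if nonzero.size < 5:
        return ComparisonResult(
            metric=metric, n_pairs=diffs.size, n_nonzero=int(nonzero.size),
            statistic=None, p_value=None, significant=None, direction=None,
            message="insufficient nonzero-difference pairs for a signed-rank test",
        )
    res = stats.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided", method="auto")
    direction = "a" if float(np.mean(nonzero)) < 0 else "b"
    return ComparisonResult(
        metric=metric, n_pairs=diffs.size, n_nonzero=int(nonzero.size),
        statistic=float(res.statistic), p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha), direction=direction,
    )


def evaluate_model(
    generator_fn,
    samples: list[SliceSample],
    variant: str = "",
    map_type: str = "",
    ssim_mode: str = "global",
    psnr_as_printed: bool = False,
) -> MetricReport:
    """Compute all four metrics per test slice.

    ``generator_fn`` maps a list of samples to an (N, h, w) array of
    generated slices — either a trained model wrapped by
    :func:`perfsyn.train.generate` or any oracle callable.
    """
    if not samples:
        raise InvalidParameterError("no samples to evaluate")
    preds = np.asarray(generator_fn(samples))
    rows = []
    for s, p in zip(samples, preds):
        rows.append({
            "patient": s.patient, "slice": s.slice_index,
            "map_type": map_type or s.map_type, "variant": variant,
            "mae": mae(s.target, p),
            "nrmse": nrmse(s.target, p),
            "ssim": ssim(s.target, p, mode=ssim_mode),
            "psnr": psnr(s.target, p, as_printed=psnr_as_printed),
        })
    return MetricReport(records=pd.DataFrame(rows), map_type=map_type or samples[0].map_type, variant=variant)
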