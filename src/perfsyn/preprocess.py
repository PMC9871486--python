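"""Dataset preparation for the GANs.

Turns 4D DSC series and 3D target maps into normalized 2D slice samples:
time axis padded to 80 frames by repeating the final (post-bolus baseline)
frame, values affinely mapped to [-1, 1] with statistics fitted on the
training split only, volumes split into axial slices, and patients assigned
to disjoint train/validation/test sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateNormalizationError, InvalidParameterError, ShapeError

MAP_TYPES = ("cbf", "cbv", "mtt", "tmax", "ttp")
TARGET_FRAMES = 80


def rescale_time(series: np.ndarray, target_frames: int = TARGET_FRAMES) -> np.ndarray:
    """Pad the time axis to ``target_frames`` by repeating the last frame.

    The repeated frame is post-bolus baseline, so this prolongs the tail
    without touching the informative part of the curve.  Longer series are
    refused (they are never truncated).
    """
    series = np.asarray(series)
    t = series.shape[-1]
    if t > target_frames:
        raise ShapeError(f"series has {t} frames; only up to {target_frames} supported")
    if t == target_frames:
        return series.copy()
    pad = np.repeat(series[..., -1:], target_frames - t, axis=-1)
    return np.concatenate([series, pad], axis=-1)


@dataclass(frozen=True)
class NormalizationParams:
    """Invertible affine map of [vmin, vmax] onto [-1, +1]."""

    vmin: float
    vmax: float
    map_type: str = "dsc"

    def apply(self, x: np.ndarray, clip: bool = False) -> np.ndarray:
        y = 2.0 * (np.asarray(x, dtype=float) - self.vmin) / (self.vmax - self.vmin) - 1.0
        return np.clip(y, -1.0, 1.0) if clip else y

    def invert(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) + 1.0) * (self.vmax - self.vmin) / 2.0 + self.vmin


def fit_normalization(arrays: list[np.ndarray] | np.ndarray, map_type: str = "dsc") -> NormalizationParams:
    """Global min/max over every image of one map type (training split)."""
    if isinstance(arrays, np.ndarray):
        arrays = [arrays]
    vmin = min(float(np.min(a)) for a in arrays)
    vmax = max(float(np.max(a)) for a in arrays)
    if vmax <= vmin:
        raise DegenerateNormalizationError(f"constant data for map {map_type!r}: min == max == {vmin}")
    return NormalizationParams(vmin=vmin, vmax=vmax, map_type=map_type)


@dataclass
class SliceSample:
    """One axial slice: the 80-frame source sequence and its target map."""

    source: np.ndarray   # (80, h, w), normalized
    target: np.ndarray   # (h, w), normalized
    patient: str
    slice_index: int
    map_type: str


def make_slices(
    source_4d: np.ndarray,
    target_3d: np.ndarray,
    patient: str,
    map_type: str,
    brain_mask: np.ndarray | None = None,
) -> list[SliceSample]:
    """Split an aligned (volume, map) pair into per-slice samples; slices
    with an empty brain mask carry no anatomy and are dropped."""
    source_4d = np.asarray(source_4d)
    target_3d = np.asarray(target_3d)
    if source_4d.shape[:3] != target_3d.shape:
        raise ShapeError("source and target grids are not aligned")
    samples = []
    for k in range(source_4d.shape[0]):
        if brain_mask is not None and not brain_mask[k].any():
            continue
        samples.append(
            SliceSample(
                source=np.ascontiguousarray(np.moveaxis(source_4d[k], -1, 0)),
                target=target_3d[k].copy(),
                patient=patient,
                slice_index=k,
                map_type=map_type,
            )
        )
    return samples


def reassemble_slices(samples: list[SliceSample]) -> np.ndarray:
    """Stack targets back into a 3D map (inverse of make_slices on targets)."""
    order = sorted(samples, key=lambda s: s.slice_index)
    return np.stack([s.target for s in order], axis=0)


def split_patients(
    patients: list[str],
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Disjoint patient-level split; sizes floor(n*f_train), floor(n*f_val),
    remainder test (203 patients at the default fractions -> 142/20/41)."""
    if len(patients) < 3:
        raise InvalidParameterError("need at least one patient per split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidParameterError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    n = len(order)
    n_train = int(n * fractions[0])
    n_val = int(n * fractions[1])
    return {
        "train": sorted(order[:n_train]),
        "val": sorted(order[n_train : n_train + n_val]),
        "test": sorted(order[n_train + n_val :]),
    }


@dataclass
class PerfusionDataset:
    """Slice samples per split plus the normalization fitted on train."""

    splits: dict[str, list[SliceSample]]
    source_norm: NormalizationParams
    target_norm: NormalizationParams
    map_type: str

    @property
    def train(self):
        return self.splits["train"]

    @property
    def val(self):
        return self.splits["val"]

    @property
    def test(self):
        return self.splits["test"]


def build_dataset(
    volumes: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray | None]],
    map_type: str,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
    clip: bool = False,
) -> PerfusionDataset:
    """Assemble a dataset from per-patient (source 4D, target 3D, mask) triples.

    Normalization statistics come from the training split only and are then
    applied unchanged to validation and test (out-of-range values pass
    through unless ``clip``).
    """
    if map_type not in MAP_TYPES:
        raise InvalidParameterError(f"unknown map type {map_type!r}")
    assignment = split_patients(sorted(volumes), fractions, seed)
    train_ids = assignment["train"]
    src_norm = fit_normalization([rescale_time(volumes[p][0]) for p in train_ids], "dsc")
    tgt_norm = fit_normalization([np.nan_to_num(volumes[p][1]) for p in train_ids], map_type)
    splits: dict[str, list[SliceSample]] = {}
    for split, ids in assignment.items():
        samples: list[SliceSample] = []
        for p in ids:
            source, target, mask = volumes[p]
            src = src_norm.apply(rescale_time(source), clip=clip)
            tgt = tgt_norm.apply(np.nan_to_num(target), clip=clip)
            samples.extend(make_slices(src, tgt, p, map_type, mask))
        splits[split] = samples
    return PerfusionDataset(splits=splits, source_norm=src_norm, target_norm=tgt_norm, map_type=map_type)


def save_dataset(ds: PerfusionDataset, out_dir: str | Path) -> Path:
    """Write samples as one compressed array file plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {}
    manifest: dict = {
        "map_type": ds.map_type,
        "source_norm": {"vmin": ds.source_norm.vmin, "vmax": ds.source_norm.vmax},
        "target_norm": {"vmin": ds.target_norm.vmin, "vmax": ds.target_norm.vmax},
        "splits": {},
    }
    for split, samples in ds.splits.items():
        manifest["splits"][split] = [
            {"patient": s.patient, "slice": s.slice_index} for s in samples
        ]
        if samples:
            arrays[f"{split}_source"] = np.stack([s.source for s in samples]).astype(np.float32)
            arrays[f"{split}_target"] = np.stack([s.target for s in samples]).astype(np.float32)
    np.savez_compressed(out_dir / "samples.npz", **arrays)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def load_dataset(in_dir: str | Path) -> PerfusionDataset:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    data = np.load(in_dir / "samples.npz")
    splits: dict[str, list[SliceSample]] = {}
    for split, entries in manifest["splits"].items():
        samples = []
        if entries:
            src = data[f"{split}_source"]
            tgt = data[f"{split}_target"]
            for i, e in enumerate(entries):
                samples.append(
                    SliceSample(
                        source=src[i], target=tgt[i], patient=e["patient"],
                        slice_index=e["slice"], map_type=manifest["map_type"],
                    )
                )
        splits[split] = samples
    return PerfusionDataset(
        splits=splits,
        source_norm=NormalizationParams(**manifest["source_norm"], map_type="dsc"),
        target_norm=NormalizationParams(**manifest["target_norm"], map_type=manifest["map_type"]),
        map_type=manifest["map_type"],
    )
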