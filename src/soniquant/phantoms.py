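"""Synthetic fixture generators for all pipeline inputs.

No raw data accompany the study conditions this package models, so every
input modality is emulated programmatically:

* **emissions** — per-burst band tables and raw waveforms, via the
  cavitation plant and tone synthesis;
* **mri** — multi-TR saturation-recovery series with known voxelwise R1
  ground truth, and hemispherically asymmetric R1 maps with target-local
  gadolinium enhancement;
* **outcomes** — exponential tumor-growth tables with lognormal
  measurement noise, and right-censored survival tables.

Generators are deterministic given a seed and are first-class, tested
code: they define the study conditions that the test and acceptance
suites run under.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .relaxometry import (
    DEFAULT_AVERAGES_PER_TR,
    DEFAULT_TR_LADDER_S,
    RelaxometrySeries,
    saturation_recovery,
)

__all__ = [
    "make_relaxometry_series",
    "make_hemispheric_phantom",
    "make_growth_table",
    "make_survival_table",
]


def make_relaxometry_series(
    r1_truth: np.ndarray,
    s0: float = 1000.0,
    noise_fraction: float = 0.01,
    tr_values_s=DEFAULT_TR_LADDER_S,
    seed: int = 0,
) -> RelaxometrySeries:
    """Saturation-recovery series with known R1 ground truth per voxel.

    Additive Gaussian noise with SD = ``noise_fraction * s0``; signals are
    clipped at zero (magnitude images are non-negative).
    """
    rng = np.random.default_rng(seed)
    r1 = np.asarray(r1_truth, dtype=float)
    tr = np.asarray(tr_values_s, dtype=float)
    clean = s0 * (1.0 - np.exp(-tr.reshape((-1,) + (1,) * r1.ndim) * r1))
    noisy = clean + rng.normal(0.0, noise_fraction * s0, size=clean.shape)
    return RelaxometrySeries(
        tr_values_s=tr,
        signal=np.clip(noisy, 0.0, None),
        averages_per_tr=np.asarray(DEFAULT_AVERAGES_PER_TR[: tr.size]),
    )


def make_hemispheric_phantom(
    shape: tuple[int, int] = (64, 64),
    baseline_r1: float = 0.5,
    delta_r1: float = 0.3,
    targets: np.ndarray | None = None,
    radius_mm: float = 1.5,
    voxel_size_mm: float = 0.35,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """2-D R1 map with gadolinium-like enhancement near sonication targets.

    One hemisphere (indices above the midline along axis 0) carries
    ``delta_r1`` added inside ``radius_mm`` of each target. Returns the
    map, the structure labels (a single "brain" structure spanning both
    hemispheres), targets, midline, and the truth delta.
    """
    rng = np.random.default_rng(seed)
    nx, ny = shape
    midline = (nx - 1) / 2.0
    if targets is None:
        xs = np.linspace(nx * 0.6, nx * 0.85, 3)
        ys = np.linspace(ny * 0.3, ny * 0.7, 3)
        targets = np.array([(x, y) for x in xs for y in ys])
    r1 = np.full(shape, baseline_r1)
    ii, jj = np.indices(shape)
    enhanced = np.zeros(shape, dtype=bool)
    for tx, ty in targets:
        d2 = ((ii - tx) * voxel_size_mm) ** 2 + ((jj - ty) * voxel_size_mm) ** 2
        enhanced |= d2 <= radius_mm**2
    enhanced &= ii > midline  # only the sonicated hemisphere
    r1 = r1 + delta_r1 * enhanced
    if noise_sd > 0:
        r1 = r1 + rng.normal(0.0, noise_sd, size=shape)
    labels = {"brain": np.ones(shape, dtype=bool)}
    return {
        "r1": r1,
        "labels": labels,
        "targets": targets,
        "midline": midline,
        "voxel_size_mm": voxel_size_mm,
        "radius_mm": radius_mm,
        "enhanced_mask": enhanced,
        "delta_r1_truth": delta_r1,
    }


def make_growth_table(
    n_subjects: int = 6,
    doubling_days: float = 3.5,
    v0_mm3: float = 10.0,
    times_days=(8, 15, 22, 29),
    noise_cv: float = 0.10,
    group: str = "control",
    seed: int = 0,
) -> pd.DataFrame:
    """Longitudinal tumor-volume table with lognormal measurement noise.

    Volumes follow V0 * 2^(t/Td) per subject, multiplied by lognormal
    noise with the given coefficient of variation (default 10%, a typical
    manual-segmentation repeatability).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times_days, dtype=float)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for s in range(n_subjects):
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.size)
        vols = v0_mm3 * 2.0 ** (t / doubling_days) * noise
        for ti, vi in zip(t, vols):
            rows.append(
                {
                    "subject_id": f"{group}_{s:02d}",
                    "group": group,
                    "time_days": ti,
                    "volume_mm3": vi,
                }
            )
    return pd.DataFrame(rows)


def make_survival_table(
    n_subjects: int = 6,
    median_days: float = 25.0,
    spread_days: float = 2.0,
    censor_fraction: float = 0.0,
    group: str = "control",
    seed: int = 0,
) -> pd.DataFrame:
    """Right-censored survival table centred on a target median.

    Event times are drawn from a lognormal centred on ``median_days``
    (scale set by ``spread_days``); a fraction of subjects is censored at
    a uniform fraction of their event time.
    """
    rng = np.random.default_rng(seed)
    sigma = spread_days / median_days
    times = rng.lognormal(mean=np.log(median_days), sigma=sigma, size=n_subjects)
    times = np.maximum(np.round(times, 1), 1.0)
    events = np.ones(n_subjects, dtype=int)
    n_censor = int(round(censor_fraction * n_subjects))
    if n_censor:
        idx = rng.choice(n_subjects, size=n_censor, replace=False)
        events[idx] = 0
        times[idx] *= rng.uniform(0.5, 0.95, size=n_censor)
    return pd.DataFrame(
        {
            "subject_id": [f"{group}_{i:02d}" for i in range(n_subjects)],
            "group": group,
            "time_days": times,
            "event_flag": events,
        }
    )
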