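"""Canonical haemodynamic response and block-regressor construction.

The BOLD response to a block is modelled as the block's boxcar convolved
with a canonical double-gamma HRF (peak at 6 s, undershoot at 16 s,
undershoot ratio 1/6), sampled at the volume times i*TR.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .design import RunSchedule


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return np.where(t >= 0, h, 0.0)


def block_boxcar(
    schedule: RunSchedule,
    *,
    condition: str | None = None,
    kind: str = "experimental",
    dt: float = 0.1,
) -> np.ndarray:
    """Fine-grained 0/1 boxcar for the blocks matching ``kind``/``condition``."""
    n = int(round(schedule.total_duration / dt))
    box = np.zeros(n)
    for b in schedule.blocks:
        if b.kind != kind:
            continue
        if condition is not None and b.condition != condition:
            continue
        i0 = int(round(b.onset / dt))
        i1 = int(round((b.onset + b.duration) / dt))
        box[i0:i1] = 1.0
    return box


def convolved_regressor(
    schedule: RunSchedule,
    *,
    condition: str | None = None,
    kind: str = "experimental",
    tr: float | None = None,
    n_volumes: int | None = None,
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved block regressor sampled at the TR grid.

    Convolution is done on a ``dt``-resolution grid (so 4/5/6-s blocks that
    are not TR multiples are represented correctly) and then sampled at
    t = 0, TR, 2*TR, ...
    """
    tr = schedule.design.tr if tr is None else tr
    box = block_boxcar(schedule, condition=condition, kind=kind, dt=dt)
    t_hrf = np.arange(0.0, 32.0, dt)
    h = double_gamma_hrf(t_hrf)
    h = h / h.sum() / dt * dt  # unit-sum discrete kernel
    sig = np.convolve(box, h)[: box.size]
    if n_volumes is None:
        n_volumes = int(round(schedule.total_duration / tr))
    idx = np.minimum((np.arange(n_volumes) * tr / dt).round().astype(int), sig.size - 1)
    return sig[idx]
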