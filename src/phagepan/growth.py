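"""One-step growth-curve analysis: burst size and latent period.

The log-titer series is segmented into pre-burst plateau, rise, and
post-burst plateau by exhaustive two-changepoint search minimizing
within-segment variance. Burst size is the linear-scale ratio of plateau
means; the latent period is where the fitted rise crosses the midpoint
between the two log plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_BURST_DETECTABLE = 1.2


class GrowthCurveError(ValueError):
    pass


@dataclass
class GrowthCurve:
    phage_id: str
    time_min: np.ndarray
    pfu_ml: np.ndarray
    moi: float | None = None

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.pfu_ml = np.asarray(self.pfu_ml, dtype=float)
        if self.time_min.shape != self.pfu_ml.shape:
            raise GrowthCurveError("time and titer vectors differ in length")
        if not np.all(np.diff(self.time_min) > 0):
            raise GrowthCurveError("time points must be strictly increasing")
        if np.any(self.pfu_ml <= 0):
            raise GrowthCurveError("titers must be positive")


@dataclass
class BurstEstimate:
    burst_size: float | None
    latent_min: float | None
    pre_segment: tuple[int, int]   # [start, end) indices
    post_segment: tuple[int, int]
    flagged: bool = False
    note: str = ""


def _segment_cost(y: np.ndarray, i: int, j: int) -> float:
    """Within-segment sum of squares for the 3 segments split at i, j."""
    cost = 0.0
    for seg in (y[:i], y[i:j], y[j:]):
        if len(seg):
            cost += float(((seg - seg.mean()) ** 2).sum())
    return cost


def estimate_burst(curve: GrowthCurve, latent_rule: str = "log_midpoint") -> BurstEstimate:
    """Estimate burst size and latent period from a one-step growth curve.

    ``latent_rule``: 'log_midpoint' (time where the rise crosses the
    midpoint of the two log plateaus) or 'rise_midpoint' (mean of the
    rise-segment time points).
    """
    y = np.log10(curve.pfu_ml)
    t = curve.time_min
    n = len(y)
    if n < 5:
        raise GrowthCurveError("need at least five time points")
    # exhaustive two-changepoint search; the middle (rise) segment may be
    # empty. Among cost ties, prefer maximal plateau coverage so the
    # changepoints hug the rise.
    best = None
    for i in range(1, n):
        for j in range(i, n):
            cost = _segment_cost(y, i, j)
            key = (round(cost, 12), -(i + n - j))
            if best is None or key < best[0]:
                best = (key, i, j)
    _, i, j = best
    pre = curve.pfu_ml[:i]
    post = curve.pfu_ml[j:]
    burst = float(post.mean() / pre.mean())
    if burst < MIN_BURST_DETECTABLE:
        return BurstEstimate(None, None, (0, i), (j, n), flagged=True,
                             note=f"no detectable rise (ratio {burst:.2f})")
    lo = float(np.log10(pre).mean())
    hi = float(np.log10(post).mean())
    mid = (lo + hi) / 2
    if latent_rule == "rise_midpoint":
        rise_t = t[i:j]
        latent = float(rise_t.mean()) if len(rise_t) else float((t[i - 1] + t[j]) / 2)
    elif latent_rule == "log_midpoint":
        # linear rise from the last pre point (at the low plateau level)
        # to the first post point (at the high plateau level)
        t0, y0 = t[i - 1], lo
        t1, y1 = t[j], hi
        if y1 == y0:
            latent = float((t0 + t1) / 2)
        else:
            latent = float(t0 + (mid - y0) * (t1 - t0) / (y1 - y0))
    else:
        raise ValueError(f"unknown latent_rule {latent_rule!r}")
    return BurstEstimate(burst, latent, (0, i), (j, n))


def read_growth_tsv(path) -> dict[str, GrowthCurve]:
    """TSV with columns phage_id, time_min, pfu_ml (one row per sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"phage_id": str})
    out = {}
    for pid, sub in df.groupby("phage_id", sort=False):
        sub = sub.sort_values("time_min")
        out[pid] = GrowthCurve(pid, sub["time_min"].to_numpy(), sub["pfu_ml"].to_numpy())
    return out
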