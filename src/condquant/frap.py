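"""Double-normalized FRAP recovery curves and ensemble aggregation.

Raw traces carry three per-frame region means: the bleached ROI, the whole
nucleus and a background box.  Normalization is done twice: background is
subtracted from ROI and nucleus, the ROI is divided by the nucleus (which
cancels any multiplicative whole-field acquisition photobleaching), and the
result is divided by its prebleach mean so the prebleach level is exactly 1.
Per-cell normalized traces are averaged pointwise into an ensemble curve
with a LOESS (locally weighted regression) smooth through the means, and an
optional single-exponential fit reports the mobile fraction and recovery
half-time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_images import ImageStack

__all__ = [
    "FrapTrace",
    "NormalizedTrace",
    "FrapEnsemble",
    "measure_frap",
    "normalize_frap",
    "aggregate_frap",
    "fit_recovery",
]


@dataclass
class FrapTrace:
    """Raw per-frame region means for one bleached cell."""

    time: np.ndarray  # seconds, uniform grid
    roi_mean: np.ndarray
    nucleus_mean: np.ndarray
    background_mean: np.ndarray
    bleach_index: int  # first postbleach frame
    cell_id: str = ""
    roi_radius_um: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.roi_mean) == len(self.nucleus_mean)
                == len(self.background_mean) == n):
            raise ValueError("all series must share a length")
        if self.bleach_index < 1:
            raise ValueError("need at least one prebleach frame")


@dataclass
class NormalizedTrace:
    time: np.ndarray
    value: np.ndarray  # dimensionless; prebleach mean is 1 by construction
    bleach_index: int
    cell_id: str = ""


@dataclass
class FrapEnsemble:
    time: np.ndarray
    mean_curve: np.ndarray
    sd_curve: np.ndarray
    smooth_curve: np.ndarray
    bleach_index: int
    n_cells: int
    traces: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "mean": self.mean_curve,
                "sd": self.sd_curve,
                "smooth": self.smooth_curve,
            }
        )

    def plot(self, path):
        """Recovery curve as mean ± s.d. band with the LOESS smooth."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.fill_between(self.time, self.mean_curve - self.sd_curve,
                        self.mean_curve + self.sd_curve, alpha=0.3,
                        label="mean ± s.d.")
        ax.plot(self.time, self.smooth_curve, lw=2, label="LOESS")
        ax.axvline(self.time[self.bleach_index], ls=":", c="k", lw=1)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("normalized intensity")
        ax.legend(frameon=False, fontsize=8)
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return path


def measure_frap(
    stack_t: ImageStack,
    roi_center: tuple,
    roi_radius_um: float,
    nucleus_mask2d: np.ndarray,
    background_box: tuple,
    bleach_index: int | None = None,
    dt: float = 1.0,
    cell_id: str = "",
) -> FrapTrace:
    """Measure ROI / whole-nucleus / background means on a 2D time-lapse.

    ``roi_center`` is (y, x) pixels; the ROI is a disc of ``roi_radius_um``
    (1 µm bleach spot by default) converted to pixels with the stack's
    lateral pixel size.  ``background_box`` is a half-open (y0, y1, x0, x1)
    region.  When ``bleach_index`` is not supplied it is detected as the
    frame after the maximal one-step drop of the ROI mean; a movie without
    a clear drop raises an error.
    """
    if stack_t.layout != "tyx":
        raise ValueError("measure_frap expects a (t, y, x) time-lapse")
    movie = stack_t.data.astype(np.float64)
    nt, ny, nx = movie.shape
    if nucleus_mask2d.shape != (ny, nx):
        raise ValueError("nucleus_mask2d shape must match the movie frames")
    dy, dx = stack_t.voxel_size[1], stack_t.voxel_size[2]
    ry, rx = roi_radius_um / dy, roi_radius_um / dx
    cy, cx = roi_center
    yy, xx = np.ogrid[:ny, :nx]
    roi = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    if cy - ry < 0 or cy + ry > ny - 1 or cx - rx < 0 or cx + rx > nx - 1:
        raise ValueError("ROI disc extends outside the image")
    y0, y1, x0, x1 = background_box

    roi_mean = movie[:, roi].mean(axis=1)
    nucleus_mean = movie[:, nucleus_mask2d.astype(bool)].mean(axis=1)
    background_mean = movie[:, y0:y1, x0:x1].reshape(nt, -1).mean(axis=1)

    if bleach_index is None:
        drops = -np.diff(roi_mean)
        best = int(np.argmax(drops))
        others = np.delete(drops, best)
        scale = others.std() if others.size else 0.0
        if drops[best] <= 0 or drops[best] <= 3.0 * scale:
            raise ValueError("no bleach found: supply bleach_index explicitly")
        bleach_index = best + 1

    return FrapTrace(
        time=np.arange(nt) * dt,
        roi_mean=roi_mean,
        nucleus_mean=nucleus_mean,
        background_mean=background_mean,
        bleach_index=bleach_index,
        cell_id=cell_id,
        roi_radius_um=roi_radius_um,
    )


def normalize_frap(trace: FrapTrace) -> NormalizedTrace:
    """Double-normalize one trace.

    v(t) = [(roi − bg) / (nucleus − bg)](t), divided by the mean of the
    same quantity over all prebleach frames, so mean(v[prebleach]) == 1
    exactly and any shared multiplicative decay or gain cancels.
    """
    corrected_nucleus = trace.nucleus_mean - trace.background_mean
    bad = np.flatnonzero(corrected_nucleus <= 0)
    if bad.size:
        raise ValueError(
            f"nonpositive background-corrected nucleus signal at frame {bad[0]}"
        )
    ratio = (trace.roi_mean - trace.background_mean) / corrected_nucleus
    pre = ratio[: trace.bleach_index].mean()
    if pre == 0:
        raise ValueError("zero prebleach signal")
    return NormalizedTrace(
        time=trace.time.copy(),
        value=ratio / pre,
        bleach_index=trace.bleach_index,
        cell_id=trace.cell_id,
    )


def aggregate_frap(traces: list[NormalizedTrace], loess_span: float = 0.3) -> FrapEnsemble:
    """Pointwise mean ± s.d. across cells with a LOESS smooth of the mean."""
    if len(traces) < 2:
        raise ValueError("need at least two traces to aggregate")
    t0 = traces[0].time
    b0 = traces[0].bleach_index
    for tr in traces[1:]:
        if len(tr.time) != len(t0) or not np.allclose(tr.time, t0) or tr.bleach_index != b0:
            raise ValueError("traces must share the time grid and bleach frame")
    values = np.stack([tr.value for tr in traces])
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    smooth = lowess(mean, t0, frac=loess_span, return_sorted=False)
    return FrapEnsemble(
        time=t0, mean_curve=mean, sd_curve=sd, smooth_curve=smooth,
        bleach_index=b0, n_cells=len(traces), traces=list(traces),
    )


def fit_recovery(ensemble: FrapEnsemble) -> dict:
    """Single-exponential fit of the postbleach ensemble mean.

    Fits v(t') = v_bleach + (plateau − v_bleach) (1 − exp(−k t')) over the
    postbleach frames (t' measured from the bleach frame) and reports
    mobile_fraction = (plateau − v_bleach) / (1 − v_bleach) and
    halftime = ln 2 / k.
    """
    post = slice(ensemble.bleach_index, None)
    t = ensemble.time[post] - ensemble.time[ensemble.bleach_index]
    v = ensemble.mean_curve[post]
    if len(v) < 5:
        raise ValueError("need at least 5 postbleach frames to fit")

    def model(tp, v_bleach, plateau, k):
        return v_bleach + (plateau - v_bleach) * (1.0 - np.exp(-k * tp))

    span = t[-1] if t[-1] > 0 else 1.0
    p0 = (float(v[0]), float(v[-1]), 1.0 / span * 5.0)
    try:
        popt, _ = curve_fit(model, t, v, p0=p0, maxfev=20000)
    except RuntimeError as err:
        resid = float(np.abs(v - model(t, *p0)).max())
        raise RuntimeError(
            f"recovery fit did not converge (max |residual| at start {resid:.4g})"
        ) from err
    v_bleach, plateau, k = (float(x) for x in popt)
    mobile = (plateau - v_bleach) / (1.0 - v_bleach) if v_bleach < 1.0 else float("nan")
    return {
        "v_bleach": v_bleach,
        "plateau": plateau,
        "rate": k,
        "mobile_fraction": mobile,
        "halftime_s": float(np.log(2.0) / k) if k > 0 else float("inf"),
    }
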