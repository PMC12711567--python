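"""Spherical-Hertz fitting of AFM force-indentation curves with QC.

The contact model is the spherical-indenter Hertz relation in the
reduced-modulus convention,

    F(delta) = (4/3) * E_r * sqrt(R) * delta**1.5,

with probe radius R and indentation depth delta; no Poisson-ratio
assumption is made, so E_r is reported as a reduced modulus.  Fitting
follows the protocol of restricting the least-squares window to samples
whose baseline-corrected force lies between 25% and 75% of the maximum
force, with a jointly estimated contact offset.  QC removes fits with
r^2 < 0.95 and then moduli outside 2 SD of the surviving population.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

__all__ = [
    "ForceCurve",
    "HertzFit",
    "hertz_force",
    "fit_hertz",
    "qc_filter",
    "aggregate_and_compare",
]


def hertz_force(delta_m, e_r_pa, probe_radius_m):
    """Force (N) of a spherical Hertz contact at indentation ``delta_m`` (m).

    Vectorised over ``delta_m``.  Negative indentations are rejected; use
    the fitter for curves that include a pre-contact segment.
    """
    delta = np.asarray(delta_m, float)
    if np.any(delta < 0):
        raise ValueError("indentation must be nonnegative")
    if probe_radius_m <= 0:
        raise ValueError("probe radius must be positive")
    if np.any(np.asarray(e_r_pa) < 0):
        raise ValueError("modulus must be nonnegative")
    out = (4.0 / 3.0) * e_r_pa * math.sqrt(probe_radius_m) * delta ** 1.5
    return out if out.ndim else float(out)


@dataclass
class ForceCurve:
    """One force-indentation record in SI units.

    ``indentation_m`` may start negative (approach / pre-contact segment);
    it must be non-decreasing with at least 4 samples.
    """

    indentation_m: np.ndarray
    force_n: np.ndarray
    probe_radius_m: float = 2.5e-6
    curve_id: int | str = 0
    region_id: str = ""
    sample_id: str = ""
    timepoint: str = ""  # "baseline" | "post"

    def __post_init__(self):
        self.indentation_m = np.asarray(self.indentation_m, float)
        self.force_n = np.asarray(self.force_n, float)
        if self.indentation_m.shape != self.force_n.shape:
            raise ValueError("indentation and force arrays differ in length")
        if self.indentation_m.size < 4:
            raise ValueError("a force curve needs at least 4 samples")
        if np.any(np.diff(self.indentation_m) < 0):
            raise ValueError("indentation must be non-decreasing")
        if self.probe_radius_m <= 0:
            raise ValueError("probe radius must be positive")


@dataclass
class HertzFit:
    """Result of a Hertz fit with its QC state."""

    reduced_modulus_pa: float
    contact_offset_m: float
    r_squared: float
    window: tuple[int, int]        # [start, stop) indices of the fit window
    baseline_n: float
    qc_status: str = "pass"        # pass | fail_fit | fail_r2 | fail_outlier
    curve_id: int | str = 0
    region_id: str = ""
    sample_id: str = ""
    timepoint: str = ""

    @property
    def ok(self) -> bool:
        return self.qc_status == "pass"


# fraction of samples (by index) treated as pre-contact for the baseline,
# and the F_max fraction used to initialise the contact offset
BASELINE_FRACTION = 0.10
CONTACT_INIT_FRACTION = 0.05
WINDOW_LO, WINDOW_HI = 0.25, 0.75


def _model(delta, e_r, delta0, sqrt_r):
    d = np.clip(delta - delta0, 0.0, None)
    return (4.0 / 3.0) * e_r * sqrt_r * d ** 1.5


def fit_hertz(curve: ForceCurve, window=(WINDOW_LO, WINDOW_HI)) -> HertzFit:
    """Fit the spherical Hertz model to one curve.

    Baseline = mean force over the initial 10% of samples (assumed
    pre-contact).  E_r and the contact offset are estimated by nonlinear
    least squares on the samples whose corrected force lies in
    ``[window[0], window[1]] * F_max`` (inclusive); r^2 is the coefficient
    of determination on that window.  F_max and window membership are
    evaluated on a lightly smoothed copy of the force (Savitzky-Golay,
    21-sample quadratic) so that window selection does not correlate with
    the noise — selecting on the raw signal biases the modulus downward at
    low signal-to-noise; the regression itself uses the raw samples.
    Deterministic: fixed initialisation, no randomness.  Failures are
    recorded as ``qc_status='fail_fit'`` with NaN estimates, not raised.
    """
    delta = curve.indentation_m
    n_base = max(1, int(round(BASELINE_FRACTION * delta.size)))
    baseline = float(curve.force_n[:n_base].mean())
    force = curve.force_n - baseline
    if delta.size >= 7:
        win_len = min(21, delta.size if delta.size % 2 else delta.size - 1)
        selector = savgol_filter(force, win_len, 2)
    else:
        selector = force
    fmax = selector.max()
    meta = dict(curve_id=curve.curve_id, region_id=curve.region_id,
                sample_id=curve.sample_id, timepoint=curve.timepoint)

    def failure():
        return HertzFit(float("nan"), float("nan"), float("-inf"), (0, 0),
                        baseline, qc_status="fail_fit", **meta)

    if not np.isfinite(fmax) or fmax <= 0:
        return failure()
    in_win = (selector >= window[0] * fmax) & (selector <= window[1] * fmax)
    idx = np.nonzero(in_win)[0]
    if idx.size < 4:
        return failure()

    above = np.nonzero(selector > CONTACT_INIT_FRACTION * fmax)[0]
    delta0_init = float(delta[above[0]]) if above.size else float(delta[0])
    span = float(delta.max() - delta0_init)
    if span <= 0:
        return failure()
    e_init = 3.0 * fmax / (4.0 * math.sqrt(curve.probe_radius_m) * span ** 1.5)

    sqrt_r = math.sqrt(curve.probe_radius_m)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda d, e, d0: _model(d, e, d0, sqrt_r),
                delta[idx], force[idx],
                p0=[e_init, delta0_init],
                maxfev=10000,
            )
    except RuntimeError:
        return failure()
    e_r, delta0 = float(popt[0]), float(popt[1])
    if not np.isfinite(e_r) or e_r <= 0:
        return failure()
    resid = force[idx] - _model(delta[idx], e_r, delta0, sqrt_r)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((force[idx] - force[idx].mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("-inf")
    return HertzFit(e_r, delta0, r2, (int(idx[0]), int(idx[-1] + 1)),
                    baseline, qc_status="pass", **meta)


def qc_filter(fits, r2_min: float = 0.95, sd_mult: float = 2.0):
    """Two-stage QC exactly in protocol order.

    Stage 1 removes fits with r^2 < ``r2_min`` (failed fits count as
    r^2 = -inf).  Stage 2 computes mean and sample SD (ddof=1) of the
    stage-1 survivors' moduli and removes values strictly outside
    mean +/- sd_mult * SD (boundary inclusive; SD of a single survivor is
    treated as 0).  Returns (survivors, rejected), both with updated
    ``qc_status``; a fit that ever failed never reverts to pass.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("qc_filter requires at least one fit")
    stage1, rejected = [], []
    for f in fits:
        if f.qc_status == "fail_fit" or not np.isfinite(f.r_squared) or f.r_squared < r2_min:
            status = f.qc_status if f.qc_status == "fail_fit" else "fail_r2"
            rejected.append(replace(f, qc_status=status))
        else:
            stage1.append(f)
    if not stage1:
        warnings.warn("no fits survive the r^2 gate", stacklevel=2)
        return [], rejected
    moduli = np.array([f.reduced_modulus_pa for f in stage1])
    mean = moduli.mean()
    sd = moduli.std(ddof=1) if moduli.size > 1 else 0.0
    survivors = []
    for f, m in zip(stage1, moduli):
        if abs(m - mean) <= sd_mult * sd:
            survivors.append(replace(f, qc_status="pass"))
        else:
            rejected.append(replace(f, qc_status="fail_outlier"))
    return survivors, rejected


def aggregate_and_compare(fits, welch: bool = False):
    """Per-sample/timepoint summaries and a two-sided two-sample t-test.

    ``fits`` are surviving :class:`HertzFit` objects carrying sample_id and
    timepoint.  Returns (summary DataFrame, tests DataFrame).  The default
    is the pooled-variance Student's t-test; ``welch=True`` drops the
    equal-variance assumption.  Samples with fewer than 2 surviving curves
    in a timepoint are skipped with a warning.
    """
    rows = [
        {"sample_id": f.sample_id, "timepoint": f.timepoint,
         "modulus_pa": f.reduced_modulus_pa}
        for f in fits
    ]
    if not rows:
        raise ValueError("no fits to aggregate")
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["sample_id", "timepoint"])["modulus_pa"]
        .agg(n="count", mean_pa="mean", sd_pa=lambda v: v.std(ddof=1))
        .reset_index()
    )
    tests = []
    for sample, grp in df.groupby("sample_id"):
        base = grp.loc[grp.timepoint == "baseline", "modulus_pa"].to_numpy()
        post = grp.loc[grp.timepoint == "post", "modulus_pa"].to_numpy()
        if base.size < 2 or post.size < 2:
            warnings.warn(
                f"sample {sample}: fewer than 2 surviving curves in a timepoint; "
                "comparison skipped",
                stacklevel=2,
            )
            continue
        t, p = sps.ttest_ind(base, post, equal_var=not welch)
        tests.append(
            {"sample_id": sample, "t": float(t), "p": float(p),
             "n_baseline": int(base.size), "n_post": int(post.size),
             "mean_shift_pa": float(post.mean() - base.mean())}
        )
    return summary, pd.DataFrame(tests)


def plot_fit(curve: ForceCurve, fit: HertzFit, path):
    """Write a per-curve diagnostic plot (data, fit window, model) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    d_nm = curve.indentation_m * 1e9
    f_nn = (curve.force_n - fit.baseline_n) * 1e9
    ax.plot(d_nm, f_nn, ".", ms=2, label="data")
    if np.isfinite(fit.reduced_modulus_pa):
        dd = np.linspace(curve.indentation_m.min(), curve.indentation_m.max(), 200)
        ff = _model(dd, fit.reduced_modulus_pa, fit.contact_offset_m,
                    math.sqrt(curve.probe_radius_m))
        ax.plot(dd * 1e9, ff * 1e9, "-", lw=1,
                label=f"Hertz fit, E_r={fit.reduced_modulus_pa:.0f} Pa")
        lo, hi = fit.window
        ax.axvspan(d_nm[lo], d_nm[hi - 1], alpha=0.15, color="C2", label="fit window")
    ax.set_xlabel("indentation (nm)")
    ax.set_ylabel("force (nN)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
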