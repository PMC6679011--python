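"""Autocorrelation and model fitting for FCS traces.

The fluorescence autocorrelation function (FAF) is computed in the "+1"
convention,

    G(tau) = <dF(t) dF(t+tau)> / <F>^2 + 1,      dF = F - <F>,

so G decays to 1 at long lags.  Two estimators are provided: a direct
O(n*k) summation at an explicit lag list (the oracle) and a multi-tau
correlator with quasi-logarithmic lag spacing and pairwise binning (the
workhorse for long traces).

The fitted model is the standard 3D free-diffusion FCS form with one or
two components and an optional triplet factor:

    G(tau) = 1 + Tr(tau)/N * sum_i y_i (1 + tau/tauD_i)^-1
                                      (1 + tau/(s^2 tauD_i))^-1/2
    Tr(tau) = (1 - T + T exp(-tau/tau_T)) / (1 - T)

with N the mean molecule number in the detection volume, y_i the
component fractions, tauD_i the diffusion times, s the structure
parameter.  Diffusion times convert to diffusion coefficients through
tauD = w^2 / (4 D), or by referencing a calibration dye of known D
(rhodamine 6G, 280 um^2/s) via D = D_ref * tau_ref / tau_probe.

Model order (1 vs 2 components) is chosen by a nested F-test on the
residual sums of squares at alpha = 0.05; in the nucleolus the slow
(smaller-D) component of a 2-component fit is reported as the
characteristic mobility, the fast component being attributed to free
probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import lmfit
import numpy as np
from scipy import stats

from .fcs_sim import IntensityTrace

#: literature diffusion coefficient of rhodamine 6G in water, um^2/s,
#: used as the calibration reference.
D_RH6G = 280.0

#: default structure parameter when no calibration data fix it.
DEFAULT_S = 5.0


class FitConvergenceError(RuntimeError):
    """Raised when no fit start converges to a usable optimum."""


@dataclass(frozen=True)
class FAFCurve:
    """Lag times (s, strictly increasing, > 0) and G values ("+1"
    convention); ``sd`` holds optional per-point replicate SDs."""

    lags: np.ndarray
    g: np.ndarray
    sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=np.float64)
        g = np.asarray(self.g, dtype=np.float64)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g", g)
        if lags.ndim != 1 or g.shape != lags.shape:
            raise ValueError("lags and g must be 1D arrays of equal length")
        if lags.size and (lags[0] <= 0 or np.any(np.diff(lags) <= 0)):
            raise ValueError("lags must be strictly increasing and positive")
        if not np.all(np.isfinite(g)):
            raise ValueError("g contains non-finite values")
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=np.float64)
            if sd.shape != lags.shape:
                raise ValueError("sd must match lags in shape")
            object.__setattr__(self, "sd", sd)


# --------------------------------------------------------------------------
# autocorrelation estimators
# --------------------------------------------------------------------------


def multi_tau_lag_set(n: int, m: int = 16, max_lag: Optional[int] = None) -> np.ndarray:
    """Integer lags (in samples) of the multi-tau scheme for a trace of
    length ``n``: 1..m at full resolution, then m/2+1..m at each
    successive doubling of the bin width."""
    if max_lag is None:
        max_lag = n - 1
    lags = [k for k in range(1, m + 1) if k <= max_lag]
    spacing = 2
    while spacing * (m // 2 + 1) <= max_lag:
        for k in range(m // 2 + 1, m + 1):
            lag = k * spacing
            if lag <= max_lag:
                lags.append(lag)
        spacing *= 2
    return np.array(sorted(set(lags)), dtype=np.int64)


def _direct_correlate(d: np.ndarray, mean: float, lags: np.ndarray, dt: float) -> FAFCurve:
    n = d.size
    g = np.empty(lags.size)
    for j, k in enumerate(lags):
        k = int(k)
        g[j] = np.dot(d[: n - k], d[k:]) / (n - k) / (mean * mean) + 1.0
    return FAFCurve(lags=lags * dt, g=g)


def _multi_tau_correlate(
    d: np.ndarray, mean: float, dt: float, m: int, max_lag: int
) -> FAFCurve:
    out_lags: list[float] = []
    out_g: list[float] = []
    cur = d.astype(np.float64)
    spacing = 1
    level = 0
    while True:
        ks = range(1, m + 1) if level == 0 else range(m // 2 + 1, m + 1)
        for k in ks:
            lag = k * spacing
            if lag > max_lag or k >= cur.size:
                continue
            out_lags.append(lag * dt)
            out_g.append(
                np.dot(cur[: cur.size - k], cur[k:]) / (cur.size - k) / (mean * mean) + 1.0
            )
        spacing *= 2
        if spacing * (m // 2 + 1) > max_lag or cur.size < 2 * m:
            break
        ncur = cur.size - (cur.size % 2)
        cur = 0.5 * (cur[:ncur:2] + cur[1:ncur:2])
        level += 1
    order = np.argsort(out_lags)
    return FAFCurve(lags=np.asarray(out_lags)[order], g=np.asarray(out_g)[order])


def autocorrelate(
    trace: IntensityTrace,
    scheme: str = "multi_tau",
    m: int = 16,
    max_lag_frac: float = 0.25,
    lags: Optional[Sequence[int]] = None,
) -> FAFCurve:
    """Estimate the FAF of an intensity trace.

    Parameters
    ----------
    scheme
        ``"multi_tau"`` (quasi-logarithmic lags, pairwise binning) or
        ``"direct"`` (exact summation at each requested lag).
    m
        Multi-tau block size: lags per bin-doubling level.
    max_lag_frac
        Curves are truncated at ``max_lag_frac * duration`` (long lags
        of a single trace are statistically meaningless).
    lags
        For the direct scheme only: explicit integer lags in samples;
        defaults to the multi-tau lag set, so the two schemes share lags.
    """
    f = trace.counts
    if f.size < 2 * m:
        raise ValueError(f"trace too short: {f.size} samples < 2 m = {2 * m}")
    mean = f.mean()
    if mean == 0.0:
        raise ValueError("trace has zero mean intensity: G(tau) is undefined")
    d = f - mean
    max_lag = max(1, int(f.size * max_lag_frac))
    if scheme == "direct":
        ilags = (
            np.asarray(lags, dtype=np.int64)
            if lags is not None
            else multi_tau_lag_set(f.size, m=m, max_lag=max_lag)
        )
        if ilags.size == 0 or ilags.min() < 1 or ilags.max() >= f.size:
            raise ValueError("direct lags must lie in [1, n-1]")
        return _direct_correlate(d, mean, ilags, trace.dt)
    if scheme == "multi_tau":
        if lags is not None:
            raise ValueError("explicit lags are only supported by the direct scheme")
        return _multi_tau_correlate(d, mean, trace.dt, m, max_lag)
    raise ValueError(f"unknown scheme {scheme!r}")


def average_fafs(curves: Sequence[FAFCurve]) -> FAFCurve:
    """Pointwise mean of replicate curves on a common lag grid, with the
    across-replicate SD attached for weighted fitting."""
    if not curves:
        raise ValueError("no curves to average")
    lags = curves[0].lags
    for c in curves[1:]:
        if c.lags.shape != lags.shape or not np.allclose(c.lags, lags, rtol=1e-12, atol=0):
            raise ValueError("replicate curves must share an identical lag grid")
    gs = np.stack([c.g for c in curves])
    sd = gs.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(lags)
    return FAFCurve(lags=lags, g=gs.mean(axis=0), sd=sd)


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------


def faf_model(
    lags: np.ndarray,
    N: float,
    fractions: Sequence[float],
    tau_d: Sequence[float],
    s: float = DEFAULT_S,
    triplet: Optional[Tuple[float, float]] = None,
) -> np.ndarray:
    """Evaluate the diffusion FCS model G(tau) at the given lags."""
    if s <= 0:
        raise ValueError("structure parameter s must be > 0")
    if any(t <= 0 for t in tau_d):
        raise ValueError("diffusion times must be > 0")
    lags = np.asarray(lags, dtype=np.float64)
    acc = np.zeros_like(lags)
    for y_i, t_i in zip(fractions, tau_d):
        acc += y_i / ((1.0 + lags / t_i) * np.sqrt(1.0 + lags / (s * s * t_i)))
    if triplet is not None:
        T, tau_t = triplet
        acc *= (1.0 - T + T * np.exp(-lags / tau_t)) / (1.0 - T)
    return 1.0 + acc / N


@dataclass(frozen=True)
class FitResult:
    """Fitted FCS model parameters.

    ``tau_d`` (and the matching ``fractions`` and ``D``) are sorted by
    increasing diffusion time, i.e. fast component first, slow last.
    ``D`` is filled only when a beam waist ``w`` was supplied.
    """

    n_components: int
    N: float
    fractions: Tuple[float, ...]
    tau_d: Tuple[float, ...]
    s: float
    triplet: Optional[Tuple[float, float]]
    D: Optional[Tuple[float, ...]]
    rss: float
    red_chi2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("fitted N must be > 0")
        if len(self.tau_d) != self.n_components:
            raise ValueError("tau_d length must equal n_components")

    @property
    def n_params(self) -> int:
        k = 1 + self.n_components  # N + tau_d's
        if self.n_components == 2:
            k += 1  # free fraction
        if self.triplet is not None:
            k += 2
        return k


def model_gtau(
    lags: Sequence[float],
    N: float,
    fractions: Sequence[float] = (1.0,),
    tau_d: Sequence[float] = (1e-4,),
    s: float = DEFAULT_S,
    triplet: Optional[Tuple[float, float]] = None,
) -> FAFCurve:
    """Model-generated FAF curve (noise-free)."""
    lags = np.asarray(lags, dtype=np.float64)
    return FAFCurve(lags=lags, g=faf_model(lags, N, fractions, tau_d, s, triplet))


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _fit_weights(curve: FAFCurve) -> Optional[np.ndarray]:
    if curve.sd is None:
        return None
    sd = curve.sd
    if np.all(sd > 0):
        return 1.0 / sd
    return None  # degenerate SDs (e.g. identical replicates): uniform


def _single_fit(curve, n_components, triplet, s_value, s_free, tau_starts):
    params = lmfit.Parameters()
    amp0 = max(curve.g[0] - 1.0, 1e-3)
    params.add("N", value=1.0 / amp0, min=1e-8)
    if n_components == 1:
        params.add("tau1", value=tau_starts[0], min=1e-9)
    else:
        params.add("tau1", value=tau_starts[0], min=1e-9)
        params.add("tau2", value=tau_starts[1], min=1e-9)
        params.add("y1", value=0.5, min=0.0, max=1.0)
    if triplet:
        params.add("T", value=0.1, min=0.0, max=0.9999)
        params.add("tau_t", value=max(curve.lags[0], 1e-6), min=1e-9)
    if s_free:
        params.add("s", value=s_value, min=1.0)
    weights = _fit_weights(curve)

    def residual(p):
        tau_ds = [p["tau1"].value] if n_components == 1 else [p["tau1"].value, p["tau2"].value]
        fracs = [1.0] if n_components == 1 else [p["y1"].value, 1.0 - p["y1"].value]
        trip = (p["T"].value, p["tau_t"].value) if triplet else None
        s_val = p["s"].value if s_free else s_value
        r = faf_model(curve.lags, p["N"].value, fracs, tau_ds, s_val, trip) - curve.g
        return r * weights if weights is not None else r

    return lmfit.minimize(residual, params, method="leastsq")


def fit_faf(
    curve: FAFCurve,
    n_components: int = 1,
    triplet: bool = False,
    s_policy: Tuple[str, float] | str = ("fixed", DEFAULT_S),
    w: Optional[float] = None,
) -> FitResult:
    """Weighted nonlinear least-squares fit of the FCS model.

    Multi-start: diffusion-time starting values are taken from a coarse
    logarithmic grid spanning the lag range and the best local optimum
    is returned.  ``s_policy`` is ``("fixed", value)`` or ``"free"``.
    If ``w`` (um) is given, per-component D = w^2/(4 tauD) is attached.

    Raises :class:`FitConvergenceError` if no start converges.
    """
    if curve.lags.size < 10:
        raise ValueError("need at least 10 lag points to fit")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if s_policy == "free":
        s_free, s_value = True, DEFAULT_S
    else:
        mode, s_value = s_policy
        if mode != "fixed" or s_value <= 0:
            raise ValueError(f"invalid s_policy {s_policy!r}")
        s_free = False

    grid = np.geomspace(curve.lags[0], curve.lags[-1], 6)
    starts = (
        [(t,) for t in grid]
        if n_components == 1
        else [(t1, t2) for i, t1 in enumerate(grid) for t2 in grid[i + 1 :]]
    )
    best = None
    for st in starts:
        try:
            res = _single_fit(curve, n_components, triplet, s_value, s_free, st)
        except Exception:
            continue
        if not res.success or not np.isfinite(res.chisqr):
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitConvergenceError(
            f"no {n_components}-component fit converged from {len(starts)} starts"
        )

    p = best.params
    if n_components == 1:
        tau_d = (p["tau1"].value,)
        fracs = (1.0,)
    else:
        tau_d = (p["tau1"].value, p["tau2"].value)
        fracs = (p["y1"].value, 1.0 - p["y1"].value)
        order = np.argsort(tau_d)  # fast first
        tau_d = tuple(tau_d[i] for i in order)
        fracs = tuple(fracs[i] for i in order)
    trip = (p["T"].value, p["tau_t"].value) if triplet else None
    s_val = p["s"].value if s_free else s_value
    d_vals = tuple(tau_to_D(t, w) for t in tau_d) if w is not None else None
    n_pts = curve.lags.size
    n_par = best.nvarys
    return FitResult(
        n_components=n_components,
        N=p["N"].value,
        fractions=fracs,
        tau_d=tau_d,
        s=s_val,
        triplet=trip,
        D=d_vals,
        rss=float(np.sum((faf_model(curve.lags, p["N"].value, fracs, tau_d, s_val, trip) - curve.g) ** 2)),
        red_chi2=float(best.redchi),
        n_points=n_pts,
    )


def select_model(
    curve: FAFCurve,
    candidates: Iterable[int] = (1, 2),
    alpha: float = 0.05,
    **fit_kwargs,
) -> FitResult:
    """Choose between 1- and 2-component fits by a nested F-test.

    The 2-component model is kept only when the reduction in residual
    sum of squares is significant at ``alpha``; ties and degenerate
    cases fall back to the 1-component fit.
    """
    cand = sorted(set(candidates))
    if cand == [1]:
        return fit_faf(curve, n_components=1, **fit_kwargs)
    if cand == [2]:
        return fit_faf(curve, n_components=2, **fit_kwargs)
    if cand != [1, 2]:
        raise ValueError(f"candidates must be a subset of {{1, 2}}, got {cand}")
    fit1 = fit_faf(curve, n_components=1, **fit_kwargs)
    # a 1-component fit that already reproduces the curve at machine
    # precision cannot be significantly improved; skip the F-test (its
    # ratio of two round-off residuals would be meaningless)
    machine_floor = curve.lags.size * (1e-12 * max(1.0, float(np.max(np.abs(curve.g))))) ** 2
    if fit1.rss <= machine_floor:
        return fit1
    fit2 = fit_faf(curve, n_components=2, **fit_kwargs)
    n = curve.lags.size
    df2 = n - fit2.n_params
    d_df = fit2.n_params - fit1.n_params
    if df2 <= 0 or fit2.rss <= 0 or fit2.rss >= fit1.rss:
        return fit1
    f_stat = ((fit1.rss - fit2.rss) / d_df) / (fit2.rss / df2)
    p_val = stats.f.sf(f_stat, d_df, df2)
    return fit2 if p_val < alpha else fit1


# --------------------------------------------------------------------------
# diffusion-time conversion and calibration
# --------------------------------------------------------------------------


def tau_to_D(tau_d: float, w: float) -> float:
    """Diffusion coefficient from diffusion time: D = w^2 / (4 tauD)."""
    if tau_d <= 0 or w <= 0:
        raise ValueError("tau_d and w must be > 0")
    return w * w / (4.0 * tau_d)


def D_to_tau(d_coef: float, w: float) -> float:
    """Diffusion time from diffusion coefficient: tauD = w^2 / (4 D)."""
    if d_coef <= 0 or w <= 0:
        raise ValueError("D and w must be > 0")
    return w * w / (4.0 * d_coef)


def calibrate_D(tau_probe: float, tau_ref: float, d_ref: float = D_RH6G) -> float:
    """Reference-dye calibration: D_probe = D_ref * tau_ref / tau_probe.

    With the default reference this converts a measured probe diffusion
    time into um^2/s using rhodamine 6G (D = 280 um^2/s) measured in the
    same detection volume, bypassing an explicit beam-waist value.
    """
    if tau_probe <= 0 or tau_ref <= 0 or d_ref <= 0:
        raise ValueError("all calibration inputs must be > 0")
    return d_ref * tau_ref / tau_probe


def characteristic_D(fit: FitResult, compartment: str = "nucleolus") -> float:
    """Compartment-characteristic diffusion coefficient of a fit.

    A 1-component fit reports its single D.  For 2-component fits in the
    nucleolus the slow (smallest-D) component is the characteristic
    value -- the fast component is attributed to probe not interacting
    with the dense phase.  Elsewhere the fraction-weighted mean is
    reported; both components remain available on the ``FitResult``.
    """
    if fit.D is None:
        raise ValueError("FitResult carries no D values; fit with w= or calibrate first")
    if fit.n_components == 1:
        return fit.D[0]
    if compartment == "nucleolus":
        return min(fit.D)
    return float(sum(y * d for y, d in zip(fit.fractions, fit.D)))
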