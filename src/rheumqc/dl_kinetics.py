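"""Delayed-luminescence (DL) decay kinetics.

Delayed luminescence is the long-lived, ultraweak photon re-emission of a
material after white-light excitation.  For powdered herbal samples the decay
of the photon-count rate over the 30 s following excitation is well described
by a hyperbolic law

    I(t) = I0 / (1 + t/Tau)**Beta

where ``I0`` is the initial intensity (counts per bin at t = 0), ``Tau`` a
time-scale parameter (seconds) and ``Beta`` a dimensionless index of the
decay rate.  A single derived timescale,

    T = (exp(1/Beta) - 1) * Tau,

summarises each curve.  Measurements are photon counts in consecutive
0.05-s bins (600 bins, 30 s total) recorded in triplicate; the three fitted
parameter sets are averaged into per-sample DL properties.

This module provides the model, a Poisson-likelihood fitter, replicate
aggregation and CSV I/O for curves and fitted properties.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "DLCurve",
    "HyperbolicFit",
    "DLProperties",
    "NoSignalError",
    "model_intensity",
    "decay_time",
    "fit_hyperbolic",
    "average_replicates",
    "simulate_curve",
    "read_curves_csv",
    "fits_to_frame",
    "properties_to_frame",
]

DEFAULT_BIN_WIDTH = 0.05  # seconds
DEFAULT_N_BINS = 600      # 30 s total


class NoSignalError(ValueError):
    """Raised when a curve contains no photon counts to fit."""


@dataclass(frozen=True)
class DLCurve:
    """One excitation-decay record: photon counts on a fixed time grid.

    Bin ``k`` (0-based) covers the interval ``[k*bin_width, (k+1)*bin_width)``.
    """

    sample_id: str
    counts: np.ndarray
    replicate_index: int = 1
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if np.any(counts < 0):
            raise ValueError("photon counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("photon counts must be integral")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def duration(self) -> float:
        """Total record length in seconds."""
        return self.n_bins * self.bin_width

    @property
    def bin_midpoints(self) -> np.ndarray:
        """Midpoint times t_k = (k + 0.5) * bin_width of every bin."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass(frozen=True)
class HyperbolicFit:
    """Fitted hyperbolic-decay parameters for one curve.

    ``fit_quality`` is the Poisson deviance (or weighted SSE) at the optimum,
    divided by the number of bins.  ``T`` is always derived from (Beta, Tau)
    through :func:`decay_time`.
    """

    sample_id: str
    replicate_index: int
    I0: float
    Tau: float
    Beta: float
    T: float
    background: float
    fit_quality: float
    converged: bool

    def __post_init__(self) -> None:
        if self.I0 <= 0 or self.Tau <= 0 or self.Beta <= 0:
            raise ValueError("I0, Tau and Beta must be strictly positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        expected_T = decay_time(self.Beta, self.Tau)
        if not math.isclose(self.T, expected_T, rel_tol=1e-9):
            raise ValueError("T inconsistent with decay_time(Beta, Tau)")


@dataclass(frozen=True)
class DLProperties:
    """Replicate-averaged DL properties of one sample."""

    sample_id: str
    I0: float
    Tau: float
    Beta: float
    T: float
    n_replicates: int

    PROPERTY_NAMES = ("I0", "Tau", "Beta", "T")


def model_intensity(
    t: float | np.ndarray, I0: float, Tau: float, Beta: float
) -> float | np.ndarray:
    """Expected counts per bin at time ``t`` under the hyperbolic decay law.

    Parameters
    ----------
    t : scalar or array, seconds, >= 0
    I0 : initial intensity, counts per bin, > 0
    Tau : time-scale parameter, seconds, > 0
    Beta : decay index, dimensionless, > 0

    Returns
    -------
    ``I0 / (1 + t/Tau)**Beta``; equals ``I0`` at ``t = 0``.
    """
    if Tau <= 0 or Beta <= 0 or I0 <= 0:
        raise ValueError("I0, Tau and Beta must be strictly positive")
    t = np.asarray(t, dtype=float) if np.ndim(t) else float(t)
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be non-negative")
    return I0 / (1.0 + t / Tau) ** Beta


def decay_time(Beta: float, Tau: float) -> float:
    """Derived decay time ``T = (exp(1/Beta) - 1) * Tau``.

    For large ``Beta`` this approaches ``Tau/Beta``; for ``Beta = Tau = 1``
    it equals ``e - 1``.
    """
    if Beta <= 0 or Tau <= 0:
        raise ValueError("Beta and Tau must be strictly positive")
    return float(np.expm1(1.0 / Beta) * Tau)


def _poisson_deviance(counts: np.ndarray, mu: np.ndarray) -> float:
    """Poisson deviance 2*sum(mu - c + c*log(c/mu)); c=0 terms drop the log."""
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts / mu), 0.0)
    return float(2.0 * np.sum(mu - counts + term))


def _wls_objective(counts: np.ndarray, mu: np.ndarray) -> float:
    """Variance-weighted squared error, weights 1/max(c,1) (Poisson variance)."""
    w = 1.0 / np.maximum(counts, 1.0)
    return float(np.sum(w * (counts - mu) ** 2))


def curve_objective(
    curve: DLCurve,
    I0: float,
    Tau: float,
    Beta: float,
    background: float = 0.0,
    objective: Literal["poisson", "wls"] = "poisson",
) -> float:
    """Objective value of a parameter set against a curve (model at midpoints)."""
    mu = model_intensity(curve.bin_midpoints, I0, Tau, Beta) + background
    if objective == "poisson":
        return _poisson_deviance(curve.counts.astype(float), mu)
    if objective == "wls":
        return _wls_objective(curve.counts.astype(float), mu)
    raise ValueError(f"unknown objective {objective!r}")


def _initial_guess(curve: DLCurve) -> tuple[float, float, float]:
    """I0 from the first bin; Beta from the log-log slope at Tau0 = 10 bins."""
    counts = curve.counts.astype(float)
    t = curve.bin_midpoints
    I0 = max(counts[0], 1.0)
    tau0 = 10.0 * curve.bin_width
    pos = counts > 0
    if pos.sum() >= 2:
        x = np.log1p(t[pos] / tau0)
        y = np.log(counts[pos])
        slope = np.polyfit(x, y, 1)[0]
        beta0 = float(np.clip(-slope, 0.05, 15.0))
    else:
        beta0 = 1.0
    return float(I0), tau0, beta0


def fit_hyperbolic(
    curve: DLCurve,
    objective: Literal["poisson", "wls"] = "poisson",
    fit_background: bool = False,
    background: float = 0.0,
    max_iter: int = 500,
    ftol: float = 1e-10,
) -> HyperbolicFit:
    """Fit the hyperbolic decay law to one curve.

    The model is evaluated at bin midpoints and compared to the observed
    counts through the Poisson deviance (default) or variance-weighted least
    squares.  A constant background (counts per bin) can be fixed or
    estimated.  Optimization is bounded L-BFGS-B in log-parameter space with
    a small multi-start over the Tau initialization; non-convergence returns
    ``converged=False`` with a logged warning rather than raising.

    Raises
    ------
    NoSignalError
        If every bin is zero.
    """
    if int(np.count_nonzero(curve.counts)) == 0:
        raise NoSignalError(f"curve {curve.sample_id!r} has no signal (all-zero counts)")
    if np.count_nonzero(curve.counts) < 10:
        warnings.warn(
            f"curve {curve.sample_id!r} has fewer than 10 positive bins; "
            "fit may be unreliable",
            stacklevel=2,
        )

    counts = curve.counts.astype(float)
    t = curve.bin_midpoints
    I0_0, tau0, beta0 = _initial_guess(curve)
    max_count = float(counts.max())

    # bounds in natural scale: I0 in (0, 10*max], Tau in (1e-4, 30], Beta in (0.01, 20]
    lo = np.log([1e-6, 1e-4, 0.01])
    hi = np.log([10.0 * max_count, 30.0, 20.0])
    if fit_background:
        lo = np.append(lo, np.log(1e-9))
        hi = np.append(hi, np.log(max(10.0 * max_count, 1.0)))

    obj_fn = _poisson_deviance if objective == "poisson" else _wls_objective
    if objective not in ("poisson", "wls"):
        raise ValueError(f"unknown objective {objective!r}")

    def loss(logp: np.ndarray) -> float:
        p = np.exp(logp)
        bg = p[3] if fit_background else background
        mu = p[0] / (1.0 + t / p[1]) ** p[2] + bg
        return obj_fn(counts, mu)

    best = None
    # multi-start over Tau (the least identifiable direction from the data alone)
    for tau_start in (tau0, 4.0 * tau0, 0.25 * tau0):
        x0 = np.log([I0_0, tau_start, beta0])
        if fit_background:
            x0 = np.append(x0, np.log(max(background, 0.5)))
        res = optimize.minimize(
            loss,
            np.clip(x0, lo, hi),
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": max_iter, "ftol": ftol},
        )
        if best is None or res.fun < best.fun:
            best = res

    p = np.exp(best.x)
    bg = float(p[3]) if fit_background else float(background)
    converged = bool(best.success)
    if not converged:
        logger.warning(
            "hyperbolic fit did not converge for sample %s replicate %d: %s",
            curve.sample_id,
            curve.replicate_index,
            best.message,
        )
    I0, Tau, Beta = (float(v) for v in p[:3])
    return HyperbolicFit(
        sample_id=curve.sample_id,
        replicate_index=curve.replicate_index,
        I0=I0,
        Tau=Tau,
        Beta=Beta,
        T=decay_time(Beta, Tau),
        background=bg,
        fit_quality=float(best.fun) / curve.n_bins,
        converged=converged,
    )


def average_replicates(fits: Sequence[HyperbolicFit]) -> DLProperties:
    """Arithmetic mean of (I0, Tau, Beta, T) across replicate fits of one sample."""
    if not fits:
        raise ValueError("need at least one fit")
    sample_ids = {f.sample_id for f in fits}
    if len(sample_ids) != 1:
        raise ValueError(f"fits mix sample_ids: {sorted(sample_ids)}")
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError(f"no converged fits for sample {fits[0].sample_id!r}")
    return DLProperties(
        sample_id=fits[0].sample_id,
        I0=float(np.mean([f.I0 for f in converged])),
        Tau=float(np.mean([f.Tau for f in converged])),
        Beta=float(np.mean([f.Beta for f in converged])),
        T=float(np.mean([f.T for f in converged])),
        n_replicates=len(converged),
    )


def simulate_curve(
    I0: float,
    Tau: float,
    Beta: float,
    rng: np.random.Generator,
    sample_id: str = "sim",
    replicate_index: int = 1,
    n_bins: int = DEFAULT_N_BINS,
    bin_width: float = DEFAULT_BIN_WIDTH,
    background: float = 0.0,
    noise: bool = True,
) -> DLCurve:
    """Draw one DL curve: Poisson counts around the hyperbolic model.

    With ``noise=False`` the expected intensity is rounded instead, giving a
    noiseless integer curve for fitter validation.
    """
    t = (np.arange(n_bins) + 0.5) * bin_width
    mu = model_intensity(t, I0, Tau, Beta) + background
    counts = rng.poisson(mu) if noise else np.round(mu).astype(np.int64)
    return DLCurve(
        sample_id=sample_id,
        replicate_index=replicate_index,
        counts=counts,
        bin_width=bin_width,
    )


# ---------------------------------------------------------------------------
# CSV I/O


def read_curves_csv(path, bin_width: float | None = None) -> list[DLCurve]:
    """Read DL curves from CSV.

    Accepted layouts:

    * long format with ``sample_id,replicate,time_s,counts`` columns;
    * single-curve ``time_s,counts``;
    * single-curve ``counts`` only (requires ``bin_width``).
    """
    df = pd.read_csv(path)
    if {"sample_id", "replicate", "counts"}.issubset(df.columns):
        curves = []
        for (sid, rep), grp in df.groupby(["sample_id", "replicate"], sort=True):
            grp = grp.sort_values("time_s") if "time_s" in grp.columns else grp
            bw = _infer_bin_width(grp, bin_width)
            curves.append(
                DLCurve(
                    sample_id=str(sid),
                    replicate_index=int(rep),
                    counts=grp["counts"].to_numpy(),
                    bin_width=bw,
                )
            )
        return curves
    if "counts" in df.columns:
        bw = _infer_bin_width(df, bin_width)
        return [DLCurve(sample_id="sample", counts=df["counts"].to_numpy(), bin_width=bw)]
    raise ValueError(f"unrecognised curve CSV layout: columns {list(df.columns)}")


def _infer_bin_width(df: pd.DataFrame, bin_width: float | None) -> float:
    if "time_s" in df.columns and len(df) >= 2:
        dt = np.diff(np.sort(df["time_s"].to_numpy()))
        return float(np.median(dt))
    if bin_width is None:
        raise ValueError("counts-only CSV requires an explicit bin_width")
    return bin_width


def fits_to_frame(fits: Sequence[HyperbolicFit]) -> pd.DataFrame:
    """Per-replicate fit table (one row per fitted curve)."""
    return pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "replicate": f.replicate_index,
                "I0": f.I0,
                "Tau": f.Tau,
                "Beta": f.Beta,
                "T": f.T,
                "background": f.background,
                "fit_quality": f.fit_quality,
                "converged": f.converged,
            }
            for f in fits
        ]
    )


def properties_to_frame(props: Sequence[DLProperties]) -> pd.DataFrame:
    """Per-sample replicate-averaged DL property table."""
    return pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "I0": p.I0,
                "Tau": p.Tau,
                "Beta": p.Beta,
                "T": p.T,
                "n_replicates": p.n_replicates,
            }
            for p in props
        ]
    )
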