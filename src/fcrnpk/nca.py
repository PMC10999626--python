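"""Non-compartmental analysis of naive-pooled concentration-time profiles.

With destructive sampling (one terminal blood draw per mouse) there is no
per-animal profile, so replicate concentrations are averaged at each
sampling time ("naive pooled" approach) and NCA runs on the single pooled
profile per protein and dose level.  Observations below the limit of
quantitation are treated as missing before pooling; a time point with no
quantifiable replicate is dropped.

Outputs follow standard bolus-dose NCA conventions: the terminal rate
constant ``lambda_z`` from a log-linear regression over an automatically
selected tail window, AUC by the linear-up/log-down trapezoid,
extrapolation to infinity via ``C_last / lambda_z``, and the derived
clearance, mean residence time and steady-state volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NCAResult", "TerminalFit", "pool_naive", "terminal_slope", "nca_params"]


@dataclass(frozen=True)
class TerminalFit:
    """Log-linear terminal-phase regression diagnostics."""

    lambda_z: float          # 1/h
    t_half: float            # h
    n_points: int
    adj_r_squared: float
    intercept_log10: float

    def __post_init__(self) -> None:
        if self.lambda_z <= 0:
            raise ValueError("terminal slope must correspond to declining "
                             "concentrations (lambda_z > 0)")


@dataclass(frozen=True)
class NCAResult:
    """Point estimates of the standard bolus NCA parameters.

    ``cl`` is in L/(kg*h) because dose is per kg and concentration is
    nmol/L (nM); ``vss = cl * mrt``.
    """

    lambda_z: float
    t_half: float
    auc_last: float      # nM*h
    auc_inf: float       # nM*h
    cl: float            # L/(kg*h)
    mrt: float           # h
    vss: float           # L/kg
    n_terminal_points: int
    extrapolated_fraction: float


def pool_naive(dataset: pd.DataFrame) -> pd.DataFrame:
    """Average replicate concentrations per (protein, dose, time).

    Parameters
    ----------
    dataset
        Long-format records with columns ``protein``, ``dose_nmol_per_kg``,
        ``time_h``, ``conc_nM`` and boolean ``blq_flag``.  BLQ rows are
        excluded as missing; times where every replicate is BLQ are
        dropped from the pooled profile.

    Returns
    -------
    DataFrame with columns ``protein``, ``dose_nmol_per_kg``, ``time_h``,
    ``conc_nM`` (the pooled mean) and ``n`` (quantifiable replicates),
    sorted by protein, dose and time.
    """
    if dataset.empty:
        raise ValueError("empty dataset")
    quant = dataset[~dataset["blq_flag"].astype(bool)]
    pooled = (quant.groupby(["protein", "dose_nmol_per_kg", "time_h"], sort=True)
              ["conc_nM"].agg(conc_nM="mean", n="size").reset_index())
    return pooled


def terminal_slope(profile: pd.DataFrame, n_points_range: tuple[int, int] = (3, 6)
                   ) -> TerminalFit:
    """Estimate ``lambda_z`` by log-linear regression on the profile tail.

    The number of terminal points is chosen by best adjusted R^2 over
    windows of ``n_points_range[0]`` .. ``n_points_range[1]`` final
    quantifiable points, a common automatic rule when the vendor
    software's manual selection is unavailable.
    """
    prof = profile.sort_values("time_h")
    t = prof["time_h"].to_numpy(float)
    c = prof["conc_nM"].to_numpy(float)
    if np.any(c <= 0):
        raise ValueError("pooled profile must be strictly positive")
    lo, hi = n_points_range
    if len(t) < lo:
        raise ValueError(f"at least {lo} terminal points required")
    best = None
    for n in range(lo, min(hi, len(t)) + 1):
        tt, cc = t[-n:], np.log10(c[-n:])
        slope, intercept = np.polyfit(tt, cc, 1)
        resid = cc - (slope * tt + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((cc - cc.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if slope >= 0:
            continue
        if best is None or adj > best[0] + 1e-12:
            best = (adj, n, slope, intercept)
    if best is None:
        raise ValueError("no declining terminal window found (non-positive slope)")
    adj, n, slope, intercept = best
    lam = -slope * np.log(10.0)
    return TerminalFit(lambda_z=lam, t_half=np.log(2.0) / lam, n_points=n,
                       adj_r_squared=adj, intercept_log10=intercept)


def _trapz_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """(AUC, AUMC) by the linear-up/log-down trapezoid."""
    auc = aumc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        t1, t2 = t[i], t[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            k = np.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
        else:
            auc += dt * (c1 + c2) / 2.0
            aumc += dt * (t1 * c1 + t2 * c2) / 2.0
    return auc, aumc


def nca_params(profile: pd.DataFrame, dose_nmol_per_kg: float,
               method: str = "lin-up-log-down",
               n_points_range: tuple[int, int] = (3, 6),
               back_extrapolate: bool = True) -> NCAResult:
    """Full bolus NCA of one pooled profile.

    For an i.v. bolus the concentration at the dosing instant is
    back-extrapolated log-linearly through the first two observations
    (standard bolus convention) so the [0, t1] segment contributes to the
    AUC.  ``auc_inf = auc_last + C_last/lambda_z``; ``cl = dose/auc_inf``
    (dose in nmol/kg over nM*h gives L/(kg*h)); ``mrt = aumc_inf/auc_inf``
    and ``vss = cl*mrt``.  A warning is attached when more than 20% of the
    AUC is extrapolated, the usual reliability rule of thumb.
    """
    import warnings

    prof = profile.sort_values("time_h")
    t = prof["time_h"].to_numpy(float)
    c = prof["conc_nM"].to_numpy(float)
    fit = terminal_slope(prof, n_points_range)
    if back_extrapolate and t[0] > 0:
        if len(c) >= 2 and c[1] < c[0]:
            k01 = np.log(c[0] / c[1]) / (t[1] - t[0])
            c0 = c[0] * np.exp(k01 * t[0])
        else:
            c0 = c[0]  # rising start: carry the first observation back
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[c0], c])
    if method == "lin-up-log-down":
        auc_last, aumc_last = _trapz_lin_up_log_down(t, c)
    elif method == "linear":
        auc_last = float(np.trapezoid(c, t))
        aumc_last = float(np.trapezoid(t * c, t))
    else:
        raise ValueError(f"unknown trapezoid method {method!r}")
    c_last, t_last = c[-1], t[-1]
    lam = fit.lambda_z
    auc_inf = auc_last + c_last / lam
    aumc_inf = aumc_last + c_last * t_last / lam + c_last / lam**2
    extrap = (auc_inf - auc_last) / auc_inf
    if extrap > 0.20:
        warnings.warn(f"{100 * extrap:.1f}% of AUC_inf is extrapolated",
                      stacklevel=2)
    cl = dose_nmol_per_kg / auc_inf
    mrt = aumc_inf / auc_inf
    return NCAResult(lambda_z=lam, t_half=fit.t_half, auc_last=auc_last,
                     auc_inf=auc_inf, cl=cl, mrt=mrt, vss=cl * mrt,
                     n_terminal_points=fit.n_points,
                     extrapolated_fraction=extrap)
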