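"""Relaxation-rate estimation from peak-intensity tables.

Mono-exponential R1/R2 fitting, steady-state NOE from saturated/reference
intensity pairs, and R2eff dispersion profiles from constant-time CPMG
intensity tables (with replicate-based error estimation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .spin import CpmgDesign

__all__ = [
    "RelaxationRecord",
    "DispersionProfile",
    "MonoExpFit",
    "fit_monoexponential",
    "compute_noe",
    "r2eff_profile",
]


@dataclass(frozen=True)
class RelaxationRecord:
    """R1/R2/NOE (with errors) for one residue at one field and pH.

    Rates in s^-1, field in MHz.  ``peak_set`` distinguishes major and
    minor conformations where a residue shows multiple peaks.
    """

    residue: int
    r1: float
    r1_err: float
    r2: float
    r2_err: float
    noe: float
    noe_err: float
    field_mhz: float = 800.2
    ph: float | None = None
    peak_set: str = "major"

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("R1 and R2 must be positive")
        if min(self.r1_err, self.r2_err, self.noe_err) < 0:
            raise ValueError("errors must be non-negative")

    @property
    def r2_over_r1(self) -> float:
        return self.r2 / self.r1

    @property
    def r2_over_r1_err(self) -> float:
        """First-order propagated error of the R2/R1 quotient."""
        return self.r2_over_r1 * math.hypot(
            self.r1_err / self.r1, self.r2_err / self.r2
        )


@dataclass
class DispersionProfile:
    """R2eff(nu_cpmg) with errors for one residue at one field."""

    residue: int
    field_mhz: float
    t_relax: float
    nu_cpmg: np.ndarray  # Hz, nonzero, duplicates collapsed
    r2eff: np.ndarray  # s^-1
    r2eff_err: np.ndarray  # s^-1
    i0: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.r2eff)):
            raise ValueError("all R2eff must be finite")
        if not np.all(self.r2eff_err > 0):
            raise ValueError("R2eff errors must be positive")


@dataclass(frozen=True)
class MonoExpFit:
    rate: float
    rate_err: float
    i0: float
    i0_err: float
    chi2: float
    converged: bool = True


def fit_monoexponential(
    delays: np.ndarray,
    intensities: np.ndarray,
    sigma: np.ndarray | float | None = None,
    n_monte_carlo: int = 0,
    seed: int | None = None,
) -> MonoExpFit:
    """Nonlinear least-squares fit of I(t) = I0 exp(-R t).

    Errors come from the fit covariance by default, or from Monte Carlo
    resampling of the intensities when ``n_monte_carlo`` > 0.

    Parameters
    ----------
    delays, intensities:
        Relaxation delays (s) and peak intensities; at least three
        distinct delays and strictly positive intensities are required.
    sigma:
        Intensity uncertainty, scalar or per-point.  Used for weighting
        and for the chi-square; unweighted fit when omitted.
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.shape != y.shape:
        raise ValueError("delays and intensities must have equal length")
    if np.any(t < 0):
        raise ValueError("negative delays")
    if len(np.unique(t)) < 3:
        raise ValueError("at least 3 distinct delays required")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")

    sig = None
    if sigma is not None:
        sig = np.broadcast_to(np.asarray(sigma, dtype=float), y.shape).copy()
        if np.any(sig <= 0):
            sig = None

    # log-linear start values
    slope, intercept = np.polyfit(t, np.log(y), 1)
    p0 = (math.exp(intercept), max(-slope, 1e-3))

    def model(tt, i0, r):
        return i0 * np.exp(-r * tt)

    try:
        popt, pcov = curve_fit(
            model, t, y, p0=p0, sigma=sig, absolute_sigma=sig is not None,
            maxfev=10000,
        )
        converged = np.all(np.isfinite(pcov))
    except RuntimeError:
        return MonoExpFit(p0[1], math.inf, p0[0], math.inf, math.inf, False)

    resid = y - model(t, *popt)
    w = sig if sig is not None else np.ones_like(y)
    chi2 = float(np.sum((resid / w) ** 2))

    if n_monte_carlo > 0:
        rng = np.random.default_rng(seed)
        noise = sig if sig is not None else np.std(resid) * np.ones_like(y)
        draws = []
        for _ in range(n_monte_carlo):
            ysim = model(t, *popt) + rng.normal(0.0, noise)
            try:
                psim, _ = curve_fit(model, t, np.clip(ysim, 1e-12, None),
                                    p0=popt, sigma=sig,
                                    absolute_sigma=sig is not None,
                                    maxfev=5000)
                draws.append(psim)
            except RuntimeError:
                continue
        draws = np.array(draws)
        i0_err, rate_err = draws.std(axis=0, ddof=1)
    else:
        i0_err, rate_err = np.sqrt(np.diag(pcov))

    return MonoExpFit(float(popt[1]), float(rate_err), float(popt[0]),
                      float(i0_err), chi2, bool(converged))


def records_from_tables(
    r1_table: pd.DataFrame,
    r2_table: pd.DataFrame,
    noe_table: pd.DataFrame,
    field_mhz: float = 800.2,
    ph: float | None = None,
    n_monte_carlo: int = 0,
    seed: int | None = None,
) -> list[RelaxationRecord]:
    """Fit every residue's decay and NOE tables into RelaxationRecords.

    Expects the decay schema (residue, delay_s, intensity, sigma) and the
    NOE schema (residue, i_sat, i_ref, sigma_sat, sigma_ref).  Residues
    missing from any table, or with non-converged decays, are skipped.
    """
    records = []
    residues = sorted(
        set(r1_table["residue"]) & set(r2_table["residue"])
        & set(noe_table["residue"])
    )
    for res in residues:
        fits = {}
        ok = True
        for key, tab in (("r1", r1_table), ("r2", r2_table)):
            sub = tab[tab["residue"] == res]
            sig = sub["sigma"].to_numpy() if "sigma" in sub else None
            if sig is not None and not np.all(sig > 0):
                sig = None
            f = fit_monoexponential(
                sub["delay_s"].to_numpy(), sub["intensity"].to_numpy(),
                sigma=sig, n_monte_carlo=n_monte_carlo, seed=seed,
            )
            if not f.converged or not math.isfinite(f.rate_err):
                ok = False
            fits[key] = f
        if not ok:
            continue
        nrow = noe_table[noe_table["residue"] == res].iloc[0]
        noe, noe_err = compute_noe(
            nrow["i_sat"], nrow["i_ref"],
            nrow["sigma_sat"], nrow["sigma_ref"],
        )
        records.append(
            RelaxationRecord(
                residue=int(res),
                r1=fits["r1"].rate, r1_err=fits["r1"].rate_err,
                r2=fits["r2"].rate, r2_err=fits["r2"].rate_err,
                noe=noe, noe_err=max(noe_err, 1e-12),
                field_mhz=field_mhz, ph=ph,
            )
        )
    return records


def compute_noe(
    i_sat: float, i_ref: float, sigma_sat: float, sigma_ref: float
) -> tuple[float, float]:
    """Steady-state heteronuclear NOE = I_sat / I_ref with propagated error.

    sigma = |NOE| * sqrt((s_sat/I_sat)^2 + (s_ref/I_ref)^2); the I_sat=0
    degenerate case returns sigma = s_sat/|I_ref|.
    """
    if i_ref == 0:
        raise ValueError("reference intensity must be nonzero")
    noe = i_sat / i_ref
    if i_sat == 0:
        return 0.0, abs(sigma_sat / i_ref)
    err = abs(noe) * math.hypot(sigma_sat / i_sat, sigma_ref / i_ref)
    return noe, err


def duplicate_noise_estimate(
    table: pd.DataFrame,
) -> dict[float, tuple[float, float]]:
    """Pooled intensity noise from duplicated nu_cpmg points.

    For each field, pools sigma_I = |I_a - I_b|/sqrt(2) over all
    residues and duplicated nu values; returns
    {field_mhz: (sigma_abs, sigma_frac)} where sigma_frac is the
    corresponding fractional (per-intensity) estimate, appropriate when
    the noise is multiplicative.
    """
    out = {}
    fields = (table["field_mhz"].unique() if "field_mhz" in table
              else [math.nan])
    for f in fields:
        sub = (table[np.isclose(table["field_mhz"], f)]
               if "field_mhz" in table else table)
        keys = ["nu_cpmg_hz"] + (["residue"] if "residue" in sub else [])
        abs_vars, frac_vars = [], []
        for _, grp in sub[sub["nu_cpmg_hz"] > 0].groupby(keys):
            v = grp["intensity"].to_numpy()
            if len(v) > 1:
                abs_vars.append(np.var(v, ddof=1))
                frac_vars.append(np.var(v, ddof=1) / np.mean(v) ** 2)
        if abs_vars:
            out[float(f)] = (
                math.sqrt(float(np.mean(abs_vars))),
                math.sqrt(float(np.mean(frac_vars))),
            )
    return out


def r2eff_profile(
    table: pd.DataFrame,
    design: CpmgDesign,
    residue: int | None = None,
    field_mhz: float | None = None,
    sigma_floor: float = 0.0,
    noise_frac: float | None = None,
    pooled_sigma_i: float | None = None,
) -> DispersionProfile:
    """Convert a CPMG intensity table to an R2eff dispersion profile.

    The table needs columns ``nu_cpmg_hz`` and ``intensity`` (optionally
    ``residue`` and ``field_mhz`` when not passed explicitly) and must
    contain the nu=0 reference plane.  R2eff = -(1/T) ln(I_nu / I_0).

    Per-point errors: the replicate scatter at duplicated nu_cpmg
    values, sigma_I = |I_a - I_b|/sqrt(2) rms-pooled over duplicate
    pairs — pass ``pooled_sigma_i`` (e.g. from
    :func:`duplicate_noise_estimate` on the full multi-residue table)
    to use the across-residue pooled value instead of the (noisy)
    within-residue one — or ``noise_frac``·I per point, whichever is
    larger; the absolute ``sigma_floor`` (in s^-1) is a final lower
    bound.  Duplicates are collapsed to their mean intensity.
    """
    df = table
    if residue is not None and "residue" in df.columns:
        df = df[df["residue"] == residue]
    elif "residue" in df.columns:
        ids = df["residue"].unique()
        if len(ids) != 1:
            raise ValueError("table holds several residues; pass residue=")
        residue = int(ids[0])
    if field_mhz is not None and "field_mhz" in df.columns:
        df = df[np.isclose(df["field_mhz"], field_mhz)]
    elif "field_mhz" in df.columns:
        fields = df["field_mhz"].unique()
        if len(fields) != 1:
            raise ValueError("table holds several fields; pass field_mhz=")
        field_mhz = float(fields[0])
    if df.empty:
        raise ValueError("no rows selected")
    if np.any(df["intensity"] <= 0):
        raise ValueError("non-positive intensity in CPMG table")

    ref = df[df["nu_cpmg_hz"] == 0]
    if ref.empty:
        raise ValueError("missing nu_cpmg = 0 reference plane")
    i0 = float(ref["intensity"].mean())

    nz = df[df["nu_cpmg_hz"] > 0]
    grouped = nz.groupby("nu_cpmg_hz")["intensity"]
    nus = np.array(sorted(grouped.groups))
    means = grouped.mean().loc[nus].to_numpy()

    # replicate-based intensity error, pooled over duplicated nu values
    if pooled_sigma_i is not None:
        sigma_i = float(pooled_sigma_i)
    else:
        dup_vars = []
        for nu, vals in grouped:
            v = vals.to_numpy()
            if len(v) > 1:
                dup_vars.append(np.var(v, ddof=1))
        sigma_i = math.sqrt(float(np.mean(dup_vars))) if dup_vars else 0.0
    if noise_frac:
        sigma_i_points = np.maximum(sigma_i, noise_frac * means)
    else:
        sigma_i_points = np.full_like(means, sigma_i)

    T = design.t_relax
    r2eff = -np.log(means / i0) / T
    err = sigma_i_points / (means * T)  # d(R2eff)/dI = -1/(I T)
    err = np.maximum(err, sigma_floor)
    if np.any(err <= 0):
        raise ValueError(
            "zero R2eff error: no replicate scatter and no sigma_floor / "
            "noise_frac configured"
        )
    return DispersionProfile(
        residue=int(residue) if residue is not None else -1,
        field_mhz=float(field_mhz) if field_mhz is not None else math.nan,
        t_relax=T,
        nu_cpmg=nus,
        r2eff=r2eff,
        r2eff_err=err,
        i0=i0,
    )
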