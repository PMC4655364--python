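"""Two-state CPMG relaxation-dispersion fitting.

Per-residue and clustered global fits of two-field dispersion profiles
with the numerical Bloch-McConnell forward model.  The fit parameters
are the exchange rate k_ex, the population product pA*pB, a per-residue
|delta_omega| in ppm (shared across fields; the rad/s value scales with
the field), and one exchange-free r20 per (residue, field).  Because
both states share r20, it enters R2eff as an exact additive constant and
is profiled out analytically at every step of the nonlinear
optimization, leaving only (k_ex, pA*pB, delta_omega...) to search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .rates import DispersionProfile
from .spin import CpmgDesign, SpinSystem, TwoStateExchange, cpmg_exchange_excess

__all__ = [
    "ExchangeDetection",
    "SingleResidueFit",
    "ClusterFit",
    "detect_exchange",
    "fit_single_residue",
    "fit_cluster_global",
    "population_from_product",
    "generate_fit_curves",
    "suggest_cluster",
]

#: multi-start initialization grid (design choice): best chi2 wins,
#: ties resolved toward the smallest k_ex
INIT_KEX = (200.0, 500.0, 1000.0, 2000.0, 4000.0)
INIT_PAPB = (0.005, 0.02, 0.05)

_KEX_BOUNDS = (10.0, 30000.0)
_Q_MAX = 0.25
_DW_MAX = 12.0  # ppm


def population_from_product(q: float) -> float:
    """Major-state population pA from the product q = pA*pB.

    The two-state constraint pA + pB = 1 gives pA*(1-pA) = q, whose
    major root is pA = (1 + sqrt(1 - 4q))/2.  q above 0.25 has no real
    solution.
    """
    if not 0.0 <= q <= 0.25:
        raise ValueError("pA*pB product must lie in [0, 0.25]")
    return 0.5 * (1.0 + math.sqrt(1.0 - 4.0 * q))


def _excess_curves(
    k_ex: float,
    q: float,
    dw_ppm: float,
    profiles: list[DispersionProfile],
) -> list[np.ndarray]:
    p_A = population_from_product(min(q, _Q_MAX))
    out = []
    for prof in profiles:
        dw_rads = SpinSystem(prof.field_mhz).ppm_to_rads(dw_ppm)
        out.append(
            cpmg_exchange_excess(p_A, k_ex, dw_rads, prof.nu_cpmg,
                                 prof.t_relax)
        )
    return out


def _chi2_with_profiled_r20(
    excess: list[np.ndarray], profiles: list[DispersionProfile]
) -> tuple[float, list[float], list[np.ndarray]]:
    """Weighted chi2 with the per-profile r20 at its analytic optimum."""
    chi2 = 0.0
    r20s, resids = [], []
    for exc, prof in zip(excess, profiles):
        w = 1.0 / prof.r2eff_err**2
        r20 = float(np.sum(w * (prof.r2eff - exc)) / np.sum(w))
        resid = (prof.r2eff - exc - r20) / prof.r2eff_err
        chi2 += float(resid @ resid)
        r20s.append(r20)
        resids.append(resid)
    return chi2, r20s, resids


@dataclass
class SingleResidueFit:
    """Two-state fit of one residue's (usually two-field) profiles."""

    residue: int
    k_ex: float
    pApB: float
    delta_omega: float  # ppm
    r20: dict[float, float]  # field_mhz -> s^-1
    chi2: float
    n_points: int
    errors: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def p_A(self) -> float:
        return population_from_product(self.pApB)

    def exchange_for(self, field_mhz: float) -> TwoStateExchange:
        return TwoStateExchange(self.k_ex, self.p_A, self.delta_omega,
                                self.r20[field_mhz])


def _fit_profiles(
    profiles: list[DispersionProfile],
    starts: list[tuple[float, float, float]],
) -> tuple[np.ndarray, float, list[float]]:
    """Multi-start (k_ex, q, dw) fit with r20 profiled out."""

    def resid(x):
        exc = _excess_curves(x[0], x[1], x[2], profiles)
        _, _, rs = _chi2_with_profiled_r20(exc, profiles)
        return np.concatenate(rs)

    lo = [_KEX_BOUNDS[0], 0.0, 0.0]
    hi = [_KEX_BOUNDS[1], _Q_MAX, _DW_MAX]
    best, best_key = None, None
    for kex0, q0, dw0 in starts:
        try:
            r = least_squares(
                resid, x0=[kex0, q0, dw0], bounds=(lo, hi),
                x_scale=[1000.0, 0.01, 1.0], ftol=1e-10, xtol=1e-10,
            )
        except Exception:
            continue
        key = (round(float(2 * r.cost), 9), kex0)  # ties -> smallest kex
        if best is None or key < best_key:
            best, best_key = r, key
    if best is None:
        raise RuntimeError("dispersion fit failed for every start")
    exc = _excess_curves(*best.x, profiles)
    chi2, r20s, _ = _chi2_with_profiled_r20(exc, profiles)
    return best.x, chi2, r20s


def fit_single_residue(
    profiles: list[DispersionProfile],
    init_grid: list[tuple[float, float, float]] | None = None,
    n_monte_carlo: int = 0,
    seed: int = 0,
) -> SingleResidueFit:
    """Fit one residue's dispersion profiles with the two-state model.

    ``profiles`` holds one DispersionProfile per field (a single field
    is accepted with a degeneracy warning).  Multi-start initialization
    over a coarse (k_ex, pA*pB) grid; parameter errors by Monte Carlo
    when ``n_monte_carlo`` > 0.
    """
    if not profiles:
        raise ValueError("no profiles given")
    residues = {p.residue for p in profiles}
    if len(residues) != 1:
        raise ValueError("profiles must belong to a single residue")
    warnings_ = []
    if len(profiles) < 2:
        warnings_.append("single-field data: (kex, pApB, dw) are "
                         "partially degenerate")

    if init_grid is None:
        init_grid = [(k, q, 1.5) for k in INIT_KEX for q in INIT_PAPB]
    x, chi2, r20s = _fit_profiles(profiles, init_grid)

    degenerate = x[2] < 1e-3 or x[1] < 1e-6
    if degenerate:
        warnings_.append("no measurable exchange: kex unidentifiable")
    fit = SingleResidueFit(
        residue=profiles[0].residue,
        k_ex=float(x[0]), pApB=float(x[1]), delta_omega=float(x[2]),
        r20={p.field_mhz: r for p, r in zip(profiles, r20s)},
        chi2=chi2,
        n_points=sum(len(p.nu_cpmg) for p in profiles),
        degenerate=degenerate, warnings=warnings_,
    )
    if n_monte_carlo > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        exc = _excess_curves(*x, profiles)
        calc = [e + r for e, r in zip(exc, r20s)]
        draws = []
        for _ in range(n_monte_carlo):
            sim = []
            for prof, c in zip(profiles, calc):
                sim.append(
                    DispersionProfile(
                        prof.residue, prof.field_mhz, prof.t_relax,
                        prof.nu_cpmg,
                        c + rng.normal(0, prof.r2eff_err),
                        prof.r2eff_err, prof.i0,
                    )
                )
            try:
                xs, _, _ = _fit_profiles(sim, [tuple(x)])
                draws.append(xs)
            except RuntimeError:
                continue
        if len(draws) >= 2:
            arr = np.array(draws)
            sd = arr.std(axis=0, ddof=1)
            fit.errors = {"k_ex": float(sd[0]), "pApB": float(sd[1]),
                          "delta_omega": float(sd[2])}
    return fit


@dataclass
class ExchangeDetection:
    exchanging: bool
    f_stat: float
    p_value: float
    chi2_flat: float
    chi2_exchange: float
    n_points: int


def detect_exchange(
    profiles: list[DispersionProfile], alpha: float = 0.05
) -> ExchangeDetection:
    """F-test of a flat (per-field constant) model against the two-state
    exchange fit.

    Requires at least 6 points per field.  The flat model has one
    parameter per field; the exchange model adds (k_ex, pA*pB, dw).
    """
    for p in profiles:
        if len(p.nu_cpmg) < 6:
            raise ValueError("need >= 6 dispersion points per field")
    chi2_flat = 0.0
    for p in profiles:
        w = 1.0 / p.r2eff_err**2
        mean = np.sum(w * p.r2eff) / np.sum(w)
        chi2_flat += float(np.sum(((p.r2eff - mean) / p.r2eff_err) ** 2))

    fit = fit_single_residue(profiles)
    n = fit.n_points
    p_flat = len(profiles)
    p_ex = p_flat + 3
    dof = n - p_ex
    if chi2_flat <= fit.chi2 or dof <= 0:
        return ExchangeDetection(False, 0.0, 1.0, chi2_flat, fit.chi2, n)
    f = ((chi2_flat - fit.chi2) / (p_ex - p_flat)) / (fit.chi2 / dof)
    p_val = float(stats.f.sf(f, p_ex - p_flat, dof))
    return ExchangeDetection(p_val < alpha, float(f), p_val,
                             chi2_flat, fit.chi2, n)


@dataclass
class ClusterFit:
    """Global two-state fit over a residue cluster: shared (k_ex, pA*pB),
    per-residue |delta_omega|, per-(residue, field) r20."""

    residues: list[int]
    k_ex: float
    pApB: float
    delta_omega: dict[int, float]  # residue -> ppm
    r20: dict[tuple[int, float], float]  # (residue, field) -> s^-1
    chi2: float
    chi2_by_residue: dict[int, float]
    n_points: int
    errors: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def p_A(self) -> float:
        return population_from_product(self.pApB)


def _cluster_resid(x, by_residue, residues):
    kex, q = x[0], x[1]
    parts = []
    for i, res in enumerate(residues):
        profs = by_residue[res]
        exc = _excess_curves(kex, q, x[2 + i], profs)
        _, _, rs = _chi2_with_profiled_r20(exc, profs)
        parts.extend(rs)
    return np.concatenate(parts)


def fit_cluster_global(
    profiles: list[DispersionProfile],
    cluster: list[int] | None = None,
    init_grid: list[tuple[float, float]] | None = None,
    n_monte_carlo: int = 0,
    seed: int = 0,
) -> ClusterFit:
    """Joint fit of a cluster of residues undergoing one concerted
    exchange process.

    k_ex and pA*pB are shared across all residues and fields;
    delta_omega is shared across fields per residue (ppm); r20 is free
    per (residue, field) and profiled out analytically.  Initialization:
    per-residue single fits seed delta_omega, and (k_ex, pA*pB) is
    multi-started from the coarse grid plus the single-fit medians.
    """
    by_residue: dict[int, list[DispersionProfile]] = {}
    for p in profiles:
        by_residue.setdefault(p.residue, []).append(p)
    residues = sorted(by_residue) if cluster is None else sorted(cluster)
    if len(residues) < 3:
        raise ValueError("cluster must contain at least 3 residues")
    for res in residues:
        if res not in by_residue:
            raise ValueError(f"no profiles for cluster residue {res}")

    singles = {}
    for res in residues:
        try:
            singles[res] = fit_single_residue(by_residue[res])
        except RuntimeError:
            singles[res] = None
    dw0 = {
        res: (s.delta_omega if s is not None and s.delta_omega > 1e-3
              else 1.5)
        for res, s in singles.items()
    }
    med_kex = float(np.median(
        [s.k_ex for s in singles.values() if s and not s.degenerate]
        or [1000.0]
    ))
    med_q = float(np.median(
        [s.pApB for s in singles.values() if s and not s.degenerate]
        or [0.02]
    ))
    if init_grid is None:
        init_grid = [(med_kex, med_q)] + [
            (k, q) for k in INIT_KEX for q in INIT_PAPB
        ]

    n_res = len(residues)
    lo = [_KEX_BOUNDS[0], 0.0] + [0.0] * n_res
    hi = [_KEX_BOUNDS[1], _Q_MAX] + [_DW_MAX] * n_res
    x_scale = [1000.0, 0.01] + [1.0] * n_res

    best, best_key = None, None
    for kex0, q0 in init_grid:
        x0 = [min(max(kex0, lo[0]), hi[0]), min(q0, _Q_MAX)] + \
            [dw0[res] for res in residues]
        try:
            r = least_squares(
                _cluster_resid, x0=x0, bounds=(lo, hi), x_scale=x_scale,
                ftol=1e-10, xtol=1e-10, args=(by_residue, residues),
            )
        except Exception:
            continue
        key = (round(float(2 * r.cost), 9), kex0)
        if best is None or key < best_key:
            best, best_key = r, key
    if best is None:
        raise RuntimeError("global cluster fit failed for every start")

    x = best.x
    kex, q = float(x[0]), float(x[1])
    dw = {res: float(x[2 + i]) for i, res in enumerate(residues)}
    chi2_total = 0.0
    chi2_by, r20_map = {}, {}
    for res in residues:
        profs = by_residue[res]
        exc = _excess_curves(kex, q, dw[res], profs)
        c, r20s, _ = _chi2_with_profiled_r20(exc, profs)
        chi2_by[res] = c
        chi2_total += c
        for prof, r20 in zip(profs, r20s):
            r20_map[(res, prof.field_mhz)] = r20

    notes = []
    jtj_cond = np.linalg.cond(best.jac.T @ best.jac)
    if not np.isfinite(jtj_cond) or jtj_cond > 1e12:
        notes.append("ill-conditioned joint fit")
    fit = ClusterFit(
        residues=residues, k_ex=kex, pApB=q, delta_omega=dw, r20=r20_map,
        chi2=chi2_total, chi2_by_residue=chi2_by,
        n_points=sum(len(p.nu_cpmg) for p in profiles), warnings=notes,
    )
    if n_monte_carlo > 0:
        rng = np.random.default_rng(seed)
        calc = {}
        for res in residues:
            profs = by_residue[res]
            exc = _excess_curves(kex, q, dw[res], profs)
            calc[res] = [e + r20_map[(res, p.field_mhz)]
                         for e, p in zip(exc, profs)]
        draws = []
        for _ in range(n_monte_carlo):
            sim_by = {}
            for res in residues:
                sims = []
                for prof, c in zip(by_residue[res], calc[res]):
                    sims.append(DispersionProfile(
                        prof.residue, prof.field_mhz, prof.t_relax,
                        prof.nu_cpmg, c + rng.normal(0, prof.r2eff_err),
                        prof.r2eff_err, prof.i0))
                sim_by[res] = sims
            try:
                r = least_squares(
                    _cluster_resid, x0=x, bounds=(lo, hi),
                    x_scale=x_scale, args=(sim_by, residues),
                )
                draws.append(r.x[:2])
            except Exception:
                continue
        if len(draws) >= 2:
            arr = np.array(draws)
            sd = arr.std(axis=0, ddof=1)
            fit.errors = {"k_ex": float(sd[0]), "pApB": float(sd[1])}
    return fit


def generate_fit_curves(
    exch: TwoStateExchange,
    design: CpmgDesign,
    n_dense: int = 100,
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Dense model curves per field for plotting/reporting.

    Evaluates the same Bloch-McConnell model used in fitting on a dense
    nu_cpmg grid spanning the design range; returns
    {field_mhz: (nu_grid, r2eff)}.  For dense nu values the realized
    pulse count is allowed to differ from the nominal one (the 1%
    compatibility rule applies to measured points, not plot grids).
    """
    nz = design.nonzero_nu
    nu_min, nu_max = min(nz), max(nz)
    # snap the grid to exactly realizable frequencies nu = n/(2T), n even
    T = design.t_relax
    pulse_counts = np.unique(
        np.clip(2.0 * np.round(np.linspace(nu_min, nu_max, n_dense) * T),
                2, None)
    )
    nu_grid = pulse_counts / (2.0 * T)
    out = {}
    for fmhz in design.fields:
        spin = SpinSystem(fmhz)
        dw = spin.ppm_to_rads(exch.delta_omega)
        exc = cpmg_exchange_excess(exch.p_A, exch.k_ex, dw, nu_grid,
                                   design.t_relax)
        out[fmhz] = (nu_grid.copy(), exch.r20 + exc)
    return out


def suggest_cluster(
    fits: list[SingleResidueFit], n_sigma: float = 2.0
) -> list[int]:
    """Residues whose single-fit k_ex values are pairwise compatible with
    the median within ``n_sigma`` Monte Carlo errors.

    Advisory only: cluster membership for global fitting is always an
    explicit user/config decision, never applied silently.
    """
    usable = [f for f in fits if not f.degenerate and "k_ex" in f.errors]
    if not usable:
        return []
    med = float(np.median([f.k_ex for f in usable]))
    return [
        f.residue for f in usable
        if abs(f.k_ex - med) <= n_sigma * max(f.errors["k_ex"], 1e-9)
    ]
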