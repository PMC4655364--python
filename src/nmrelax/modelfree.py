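"""Model-free analysis: overall-tumbling estimation and per-residue
internal-motion fitting.

The workflow mirrors standard backbone practice: (1) select a rigid
residue subset (high NOE, unexceptional R2/R1) and fit isotropic and
axially symmetric rotational-diffusion tensors to the R2/R1 ratios,
choosing between them by F-test; (2) for each residue fit the five
nested motional models M1 (S2), M2 (S2, tau_e), M3 (S2, Rex),
M4 (S2, tau_e, Rex) and M5 (S2, tau_e, S2f) with the tensor fixed and
select among them by a staged chi-square goodness-of-fit / F-test
protocol; (3) obtain parameter errors by Monte Carlo resampling.

Also provides the inertia-tensor utility used as a structural sanity
check on the fitted diffusion anisotropy, with N-H bond vectors taken
from a coordinate file.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .rates import RelaxationRecord
from .spin import DiffusionTensor, MotionalModel, SpinSystem, rates_from_model

__all__ = [
    "DiffusionFitReport",
    "ModelFreeFit",
    "InertiaResult",
    "select_rigid_subset",
    "estimate_diffusion",
    "fit_model",
    "select_model",
    "monte_carlo_errors",
    "inertia_ratio",
    "nh_vectors_from_pdb",
    "atoms_from_pdb",
]

_TAU_E_MAX = {"M2": 3e-9, "M4": 3e-9, "M5": 6e-9}
_REX_MAX = 50.0


# ---------------------------------------------------------------------------
# Rigid-subset selection and diffusion-tensor estimation
# ---------------------------------------------------------------------------

def select_rigid_subset(
    records: list[RelaxationRecord],
    noe_min: float = 0.65,
    iqr_factor: float = 1.5,
) -> list[RelaxationRecord]:
    """Residues suitable for tumbling estimation.

    Keeps records with NOE >= ``noe_min`` (excludes fast internal
    motion) whose R2/R1 lies within ``iqr_factor`` interquartile ranges
    of the median (excludes exchange-broadened outliers).
    """
    high_noe = [r for r in records if r.noe >= noe_min]
    if not high_noe:
        return []
    ratios = np.array([r.r2_over_r1 for r in high_noe])
    q1, med, q3 = np.percentile(ratios, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = med - iqr_factor * iqr, med + iqr_factor * iqr
    return [r for r, x in zip(high_noe, ratios) if lo <= x <= hi]


def _ratio_model(
    tau_m: float,
    d_ratio: float,
    angles: np.ndarray,
    spin: SpinSystem,
) -> np.ndarray:
    """R2/R1 for rigid residues (S2 cancels; computed at S2 = 1)."""
    if d_ratio == 1.0:
        tensor = DiffusionTensor("isotropic", tau_m)
    else:
        kind = "axial_oblate" if d_ratio < 1.0 else "axial_prolate"
        tensor = DiffusionTensor(kind, tau_m, d_ratio)
    m = MotionalModel("M1", S2=1.0)
    out = np.empty(len(angles))
    cache: dict[float, float] = {}
    for i, a in enumerate(angles):
        key = round(float(a), 10)
        if key not in cache:
            r1, r2, _ = rates_from_model(m, tensor, spin, float(a))
            cache[key] = r2 / r1
        out[i] = cache[key]
    return out


def _axis_from_sph(theta: float, phi: float) -> tuple[float, float, float]:
    return (
        math.sin(theta) * math.cos(phi),
        math.sin(theta) * math.sin(phi),
        math.cos(theta),
    )


def _angles_to_axis(vectors: np.ndarray, axis) -> np.ndarray:
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    c = np.abs(vectors @ a)
    return np.arccos(np.clip(c, 0.0, 1.0))


@dataclass
class DiffusionFitReport:
    """Outcome of rotational-diffusion tensor estimation."""

    tensor: DiffusionTensor
    chi2: dict[str, float]
    tau_m_by_model: dict[str, float]
    n_used: int
    residues_used: list[int]
    f_stat: float
    p_value: float
    warnings: list[str] = field(default_factory=list)


def estimate_diffusion(
    records: list[RelaxationRecord],
    orientations: dict[int, tuple[float, float, float]] | None,
    spin: SpinSystem,
    alpha: float = 0.05,
    min_rigid: int = 10,
) -> DiffusionFitReport:
    """Fit isotropic and axial (oblate/prolate) diffusion tensors to the
    R2/R1 ratios of the rigid subset, selecting by F-test.

    ``orientations`` maps residue id to its N-H unit vector in the
    molecule frame; without orientations only the isotropic fit is
    possible (a warning is recorded).
    """
    rigid = select_rigid_subset(records)
    if len(rigid) < min_rigid:
        raise ValueError(
            f"only {len(rigid)} rigid residues (need >= {min_rigid})"
        )
    ratios = np.array([r.r2_over_r1 for r in rigid])
    sigmas = np.array([max(r.r2_over_r1_err, 1e-6) for r in rigid])
    notes: list[str] = []

    def chi2_iso(tau_m: float) -> float:
        model = _ratio_model(tau_m, 1.0, np.zeros(1), spin)[0]
        return float(np.sum(((ratios - model) / sigmas) ** 2))

    # 1-D isotropic fit (coarse grid + refine)
    grid = np.linspace(3e-9, 20e-9, 60)
    tau0 = grid[int(np.argmin([chi2_iso(t) for t in grid]))]
    res = least_squares(
        lambda p: (ratios - _ratio_model(p[0], 1.0, np.zeros(len(rigid)),
                                         spin)) / sigmas,
        x0=[tau0], bounds=([1e-9], [50e-9]),
    )
    tau_iso = float(res.x[0])
    c_iso = float(2 * res.cost)
    chi2 = {"isotropic": c_iso}
    tau_by = {"isotropic": tau_iso}

    if orientations is None:
        notes.append("no orientations supplied: isotropic fit only")
        return DiffusionFitReport(
            DiffusionTensor("isotropic", tau_iso), chi2, tau_by,
            len(rigid), [r.residue for r in rigid],
            f_stat=0.0, p_value=1.0, warnings=notes,
        )

    missing = [r.residue for r in rigid if r.residue not in orientations]
    if missing:
        raise ValueError(f"missing N-H orientations for residues {missing}")
    vecs = np.array([orientations[r.residue] for r in rigid], float)
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)

    def axial_resid(p, lo, hi):
        tau_m, ratio, th, ph = p
        ratio = min(max(ratio, lo), hi)
        ang = _angles_to_axis(vecs, _axis_from_sph(th, ph))
        return (ratios - _ratio_model(tau_m, ratio, ang, spin)) / sigmas

    axis_starts = [
        (0.0, 0.0), (math.pi / 2, 0.0), (math.pi / 2, math.pi / 2),
        (math.pi / 4, math.pi / 4), (math.pi / 3, 4.0),
    ]
    best = {}
    for kind, (lo, hi), r0 in (
        ("axial_oblate", (0.4, 0.999), 0.85),
        ("axial_prolate", (1.001, 2.5), 1.2),
    ):
        best_fit = None
        for th0, ph0 in axis_starts:
            r = least_squares(
                axial_resid, x0=[tau_iso, r0, th0, ph0],
                bounds=([1e-9, lo, 0.0, -math.pi],
                        [50e-9, hi, math.pi, 2 * math.pi]),
                args=(lo, hi),
            )
            if best_fit is None or r.cost < best_fit.cost:
                best_fit = r
        best[kind] = best_fit
        chi2[kind] = float(2 * best_fit.cost)
        tau_by[kind] = float(best_fit.x[0])

    ax_kind = min(("axial_oblate", "axial_prolate"), key=lambda k: chi2[k])
    c_ax = chi2[ax_kind]
    n = len(rigid)
    dof_extra, dof_ax = 3, max(n - 4, 1)
    f_stat = ((c_iso - c_ax) / dof_extra) / (c_ax / dof_ax)
    p_value = float(stats.f.sf(max(f_stat, 0.0), dof_extra, dof_ax))

    if p_value < alpha:
        x = best[ax_kind].x
        tensor = DiffusionTensor(
            ax_kind, float(x[0]), float(x[1]),
            _axis_from_sph(float(x[2]), float(x[3])),
        )
    else:
        tensor = DiffusionTensor("isotropic", tau_iso)
    return DiffusionFitReport(
        tensor, chi2, tau_by, n, [r.residue for r in rigid],
        f_stat=float(f_stat), p_value=p_value, warnings=notes,
    )


# ---------------------------------------------------------------------------
# Per-residue model fitting and selection
# ---------------------------------------------------------------------------

def _pack(model_id: str, x: np.ndarray) -> MotionalModel:
    if model_id == "M1":
        return MotionalModel("M1", S2=float(x[0]))
    if model_id == "M2":
        return MotionalModel("M2", S2=float(x[0]), tau_e=float(x[1]))
    if model_id == "M3":
        return MotionalModel("M3", S2=float(x[0]), Rex=float(x[1]))
    if model_id == "M4":
        return MotionalModel("M4", S2=float(x[0]), tau_e=float(x[1]),
                             Rex=float(x[2]))
    # M5 parameterized as (S2f, S2s, tau_e) so S2 = S2f*S2s <= S2f always
    s2f, s2s, te = float(x[0]), float(x[1]), float(x[2])
    return MotionalModel("M5", S2=s2f * s2s, tau_e=te, S2f=s2f)


_FIT_SETUP = {
    "M1": (["S2"], [0.0], [1.0]),
    "M2": (["S2", "tau_e"], [0.0, 0.0], [1.0, _TAU_E_MAX["M2"]]),
    "M3": (["S2", "Rex"], [0.0, 0.0], [1.0, _REX_MAX]),
    "M4": (["S2", "tau_e", "Rex"], [0.0, 0.0, 0.0],
           [1.0, _TAU_E_MAX["M4"], _REX_MAX]),
    "M5": (["S2f", "S2s", "tau_e"], [0.0, 0.0, 0.0],
           [1.0, 1.0, _TAU_E_MAX["M5"]]),
}


def fit_model(
    record: RelaxationRecord,
    model_id: str,
    tensor: DiffusionTensor,
    nh_angle: float | None,
    spin: SpinSystem,
) -> tuple[MotionalModel, float, dict]:
    """Weighted least-squares fit of one motional model to (R1, R2, NOE).

    chi2 = sum(((obs - calc)/sigma)^2) over the three observables with
    the diffusion tensor held fixed.  Returns (model, chi2, info) where
    info flags non-convergence and parameters at their bounds.
    """
    if model_id not in _FIT_SETUP:
        raise ValueError(f"unknown model {model_id!r}")
    obs = np.array([record.r1, record.r2, record.noe])
    sig = np.array([record.r1_err, record.r2_err, record.noe_err])
    if np.any(sig <= 0):
        raise ValueError("record errors must be positive for fitting")

    names, lo, hi = _FIT_SETUP[model_id]

    def resid(x):
        m = _pack(model_id, x)
        r1, r2, noe = rates_from_model(m, tensor, spin, nh_angle)
        return (obs - np.array([r1, r2, noe])) / sig

    starts: list[list[float]]
    if model_id == "M1":
        starts = [[0.85], [0.4]]
    elif model_id == "M2":
        starts = [[0.85, te] for te in
                  (0.0, 10e-12, 30e-12, 100e-12, 300e-12)] + \
                 [[0.6, 100e-12], [0.4, 1.5e-9]]
    elif model_id == "M3":
        starts = [[0.85, 2.0], [0.85, 10.0]]
    elif model_id == "M4":
        starts = [[0.85, 10e-12, 3.0], [0.85, 100e-12, 3.0],
                  [0.7, 300e-12, 3.0]]
    else:
        starts = [[0.8, 0.4, 1e-9], [0.7, 0.7, 0.3e-9], [0.9, 0.2, 2e-9],
                  [0.85, 0.95, 50e-12]]

    scale = {"S2": 0.1, "S2f": 0.1, "S2s": 0.1, "tau_e": 2e-11,
             "Rex": 1.0}
    x_scale = [scale[n] for n in names]
    best = None
    for x0 in starts:
        try:
            r = least_squares(resid, x0=x0, bounds=(lo, hi), xtol=1e-14,
                              ftol=1e-14, gtol=1e-14, x_scale=x_scale,
                              diff_step=1e-6)
        except Exception:
            continue
        if best is None or r.cost < best.cost:
            best = r
    if best is None:
        raise RuntimeError(f"{model_id} fit failed for residue "
                           f"{record.residue}")
    at_bound = [
        n for n, v, l, h in zip(names, best.x, lo, hi)
        if (v - l) < 1e-12 * max(abs(h), 1) or (h - v) < 1e-9 * abs(h)
    ]
    info = {"converged": bool(best.success), "at_bound": at_bound,
            "x": best.x.copy(), "param_names": names}
    return _pack(model_id, best.x), float(2 * best.cost), info


@dataclass
class ModelFreeFit:
    """Selected motional model for one residue, with selection trace."""

    residue: int
    model_id: str
    model: MotionalModel
    chi2: float
    trace: dict[str, dict]  # per-candidate {"chi2", "p_gof", "f_p", ...}
    param_errors: dict[str, float] = field(default_factory=dict)
    status: str = "ok"  # ok | skipped | failed


_N_OBS = 3
_N_PARAMS = {"M1": 1, "M2": 2, "M3": 2, "M4": 3, "M5": 3}


def _gof_p(chi2_val: float, dof: int) -> float:
    if dof <= 0:
        return math.nan
    return float(stats.chi2.sf(chi2_val, dof))


def _ftest_p(chi2_simple: float, chi2_complex: float,
             p_simple: int, p_complex: int) -> float:
    """Nested-model F-test p-value on chi-square reduction."""
    dof_c = _N_OBS - p_complex
    d_p = p_complex - p_simple
    if dof_c <= 0 or d_p <= 0 or chi2_complex <= 0:
        return 0.0 if chi2_complex < chi2_simple else 1.0
    f = ((chi2_simple - chi2_complex) / d_p) / (chi2_complex / dof_c)
    return float(stats.f.sf(max(f, 0.0), d_p, dof_c))


def select_model(
    record: RelaxationRecord,
    tensor: DiffusionTensor,
    nh_angle: float | None,
    spin: SpinSystem,
    alpha: float = 0.05,
) -> ModelFreeFit:
    """Staged model selection among M1-M5.

    M1 is accepted if its chi-square goodness-of-fit p-value exceeds
    ``alpha``.  Otherwise the two-parameter models (M2, M3) are
    considered: a candidate must improve on M1 significantly (F-test at
    ``alpha``) and itself fit acceptably; the better-fitting qualifying
    candidate wins.  Only if no simpler model qualifies are the
    three-parameter models (M4, M5) compared by chi-square (they fit the
    three observables exactly up to bounds).  Ties resolve toward fewer
    parameters.
    """
    fits: dict[str, tuple[MotionalModel, float, dict]] = {}
    trace: dict[str, dict] = {}
    for mid in ("M1", "M2", "M3", "M4", "M5"):
        try:
            fits[mid] = fit_model(record, mid, tensor, nh_angle, spin)
        except RuntimeError:
            trace[mid] = {"chi2": math.inf, "error": "fit failed"}
    for mid, (_, c, info) in fits.items():
        trace[mid] = {"chi2": c, "p_gof": _gof_p(c, _N_OBS - _N_PARAMS[mid]),
                      "at_bound": info["at_bound"]}

    def make(mid):
        m, c, _ = fits[mid]
        return ModelFreeFit(record.residue, mid, m, c, trace)

    if "M1" in fits and trace["M1"]["p_gof"] > alpha:
        return make("M1")

    c1 = trace.get("M1", {}).get("chi2", math.inf)
    stage2 = []
    for mid in ("M2", "M3"):
        if mid not in fits:
            continue
        c2 = trace[mid]["chi2"]
        f_p = _ftest_p(c1, c2, 1, 2)
        trace[mid]["f_p_vs_M1"] = f_p
        if f_p < alpha and trace[mid]["p_gof"] > alpha:
            stage2.append((c2, mid))
    if stage2:
        return make(min(stage2)[1])

    stage3 = [(trace[mid]["chi2"], mid) for mid in ("M4", "M5")
              if mid in fits]
    if stage3:
        return make(min(stage3)[1])
    # everything failed: fall back to whatever converged, else error out
    if fits:
        best = min(fits, key=lambda k: trace[k]["chi2"])
        out = make(best)
        out.status = "failed"
        return out
    raise RuntimeError(f"no model converged for residue {record.residue}")


def monte_carlo_errors(
    fit: ModelFreeFit,
    record: RelaxationRecord,
    tensor: DiffusionTensor,
    nh_angle: float | None,
    spin: SpinSystem,
    n_iter: int = 500,
    seed: int = 0,
) -> dict[str, float]:
    """Monte Carlo parameter errors for a selected model-free fit.

    Draws ``n_iter`` synthetic (R1, R2, NOE) triples from
    Normal(back-calculated, sigma_obs), refits the selected model and
    returns the standard deviation of each refit parameter.  More than
    10% refit failures raises.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    rng = np.random.default_rng(seed)
    r1c, r2c, noec = rates_from_model(fit.model, tensor, spin, nh_angle)
    draws: list[np.ndarray] = []
    failures = 0
    for _ in range(n_iter):
        sim = RelaxationRecord(
            residue=record.residue,
            r1=max(rng.normal(r1c, record.r1_err), 1e-6),
            r1_err=record.r1_err,
            r2=max(rng.normal(r2c, record.r2_err), 1e-6),
            r2_err=record.r2_err,
            noe=rng.normal(noec, record.noe_err),
            noe_err=record.noe_err,
            field_mhz=record.field_mhz,
        )
        try:
            _, _, info = fit_model(sim, fit.model_id, tensor, nh_angle, spin)
            draws.append(info["x"])
        except RuntimeError:
            failures += 1
    if failures > 0.1 * n_iter:
        raise RuntimeError(
            f"{failures}/{n_iter} Monte Carlo refits failed"
        )
    arr = np.array(draws)
    names = _FIT_SETUP[fit.model_id][0]
    errs = dict(zip(names, arr.std(axis=0, ddof=1)))
    if fit.model_id == "M5":  # report the composite S2 error too
        errs["S2"] = float((arr[:, 0] * arr[:, 1]).std(ddof=1))
    return {k: float(v) for k, v in errs.items()}


def _angle_to(tensor: DiffusionTensor, vector) -> float | None:
    if tensor.kind == "isotropic":
        return None
    u = np.asarray(vector, float)
    u = u / np.linalg.norm(u)
    a = np.asarray(tensor.axis, float)
    return math.acos(min(abs(float(u @ a)), 1.0))


def modelfree_pipeline(
    records: list[RelaxationRecord],
    orientations: dict[int, tuple[float, float, float]] | None,
    spin: SpinSystem,
    alpha: float = 0.05,
    n_refine: int = 1,
) -> tuple[DiffusionFitReport, dict[int, ModelFreeFit]]:
    """Diffusion-tensor estimation with iterative refinement, then
    per-residue model selection.

    The initial rigid subset (NOE / R2-R1-ratio filter) can retain
    residues with modest exchange broadening, which biases the tensor
    and cascades into model misassignment.  After a first round of
    selection, the tensor is therefore re-estimated using only residues
    assigned the pure-tumbling model M1, and selection is repeated
    (``n_refine`` rounds; one is usually enough).
    """
    report = estimate_diffusion(records, orientations, spin, alpha=alpha)

    def run_selection(tensor):
        fits = {}
        for rec in records:
            angle = (_angle_to(tensor, orientations[rec.residue])
                     if orientations and rec.residue in orientations
                     else None)
            if tensor.kind != "isotropic" and angle is None:
                fits[rec.residue] = ModelFreeFit(
                    rec.residue, "", MotionalModel("M1", S2=0.0),
                    math.nan, {}, status="skipped")
                continue
            fits[rec.residue] = select_model(rec, tensor, angle, spin,
                                             alpha=alpha)
        return fits

    fits = run_selection(report.tensor)
    for _ in range(n_refine):
        core = [r for r in records
                if fits[r.residue].model_id == "M1"
                and fits[r.residue].status == "ok"]
        if len(core) < 10:
            break
        refined = estimate_diffusion(core, orientations, spin, alpha=alpha)
        refined.warnings.append(
            f"tensor refined on {len(core)} M1-assigned residues")
        report = refined
        fits = run_selection(report.tensor)
    return report, fits


# ---------------------------------------------------------------------------
# Inertia tensor and coordinate helpers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InertiaResult:
    """Principal moments of inertia, largest first, and the ratios
    normalized to the largest (Ix = 1)."""

    moments: tuple[float, float, float]
    ratios: tuple[float, float, float]


def inertia_ratio(coordinates, masses=None) -> InertiaResult:
    """Principal moments of the mass-weighted inertia tensor.

    Computed about the center of mass and normalized to the largest
    moment.  Unit masses are assumed when ``masses`` is omitted.
    """
    xyz = np.asarray(coordinates, float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or len(xyz) < 3:
        raise ValueError("need >= 3 points of shape (n, 3)")
    m = (np.ones(len(xyz)) if masses is None
         else np.asarray(masses, float))
    com = (m[:, None] * xyz).sum(0) / m.sum()
    r = xyz - com
    # rank check: collinear points give a rank < 2 covariance
    if np.linalg.matrix_rank(r, tol=1e-9 * max(1.0, np.abs(r).max())) < 2:
        raise ValueError("degenerate (collinear) geometry")
    r2 = (r**2).sum(1)
    I = np.einsum("i,ij,ik->jk", m, r, r)
    I = np.diag(m @ r2 * np.ones(3)) - I
    mom = np.sort(np.linalg.eigvalsh(I))[::-1]
    ratios = tuple(float(x / mom[0]) for x in mom)
    return InertiaResult(tuple(float(x) for x in mom), ratios)


def atoms_from_pdb(path) -> tuple[np.ndarray, np.ndarray]:
    """(coordinates, masses) of all atoms in the first model of a PDB file."""
    from Bio.PDB import PDBParser

    masses = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
              "S": 32.06, "P": 30.974}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("x", str(path))
    model = next(iter(structure))
    coords, ms = [], []
    for atom in model.get_atoms():
        coords.append(atom.coord)
        ms.append(masses.get(atom.element.strip().upper(), 12.011))
    return np.array(coords, float), np.array(ms)


def nh_vectors_from_pdb(path) -> dict[int, tuple[float, float, float]]:
    """Backbone amide N->H unit vectors, by residue number, from the
    first model of a PDB file.

    When the amide proton is absent the H position is reconstructed
    from backbone geometry: along the in-plane direction opposite the
    bisector of N->CA and N->C(previous residue).
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("x", str(path))
    model = next(iter(structure))
    out: dict[int, tuple[float, float, float]] = {}
    for chain in model:
        residues = [r for r in chain if "N" in r]
        for prev, res in zip(residues, residues[1:]):
            num = res.id[1]
            n = res["N"].coord
            h = None
            for name in ("H", "HN"):
                if name in res:
                    h = res[name].coord
                    break
            if h is not None:
                v = h - n
            else:
                if "CA" not in res or "C" not in prev:
                    continue
                u1 = res["CA"].coord - n
                u2 = prev["C"].coord - n
                u1 = u1 / np.linalg.norm(u1)
                u2 = u2 / np.linalg.norm(u2)
                v = -(u1 + u2)
            nv = np.linalg.norm(v)
            if nv == 0:
                continue
            out[num] = tuple(float(x) for x in v / nv)
    return out
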