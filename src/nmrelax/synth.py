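"""Seeded synthetic-data generators.

Because raw relaxation data for this class of experiment are rarely
deposited, every analysis stage in the package can be exercised on
synthetic tables generated here: mono-exponential intensity decays,
saturated/reference NOE pairs, constant-time CPMG intensity profiles
computed from the two-state Bloch-McConnell model (including the
reference plane and duplicated nu_cpmg points), and pH-titration shift
trajectories with missing and split peaks.  Each generator is a pure
function of (truth, design, seed) and writes the tabular schemas defined
in :mod:`nmrelax.io`, alongside a ground-truth sidecar for recovery
tests.

Noise model: fractional (multiplicative) Gaussian intensity noise,
I -> I * (1 + eps), eps ~ N(0, noise); this matches the error behaviour
of constant-time intensity ratios and keeps the noise specification to a
single number.  Default 2%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spin import (
    CpmgDesign,
    DiffusionTensor,
    MotionalModel,
    SpinSystem,
    TwoStateExchange,
    bloch_mcconnell_r2eff,
    rates_from_model,
)

__all__ = [
    "ResidueMotion",
    "ExchangeTruth",
    "TitrationResidueTruth",
    "GroundTruth",
    "DEFAULT_R1_DELAYS",
    "DEFAULT_R2_DELAYS",
    "make_relaxation_dataset",
    "make_cpmg_dataset",
    "make_titration_dataset",
    "random_orientations",
    "rigid_residue_truth",
    "modelfree_composition_truth",
]

#: default relaxation delay grids (s); 8 points each
DEFAULT_R1_DELAYS = (0.01, 0.06, 0.14, 0.26, 0.42, 0.62, 0.88, 1.2)
DEFAULT_R2_DELAYS = (0.008, 0.017, 0.034, 0.051, 0.085, 0.119, 0.153, 0.2)


@dataclass(frozen=True)
class ResidueMotion:
    """Ground-truth internal motion of one residue."""

    residue: int
    model: MotionalModel
    nh_vector: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def nh_angle(self, axis: tuple[float, float, float]) -> float:
        v = np.asarray(self.nh_vector, float)
        a = np.asarray(axis, float)
        c = abs(float(v @ a) / (np.linalg.norm(v) * np.linalg.norm(a)))
        return math.acos(min(c, 1.0))


@dataclass(frozen=True)
class ExchangeTruth:
    """Ground-truth two-state exchange for a cluster of residues.

    delta_omega maps residue -> |dw| in ppm (residues absent from the
    map do not exchange); r20 maps (residue, field_mhz) -> exchange-free
    R2, falling back to ``r20_default``.
    """

    k_ex: float
    p_A: float
    delta_omega: dict[int, float] = field(default_factory=dict)
    r20: dict[tuple[int, float], float] = field(default_factory=dict)
    r20_default: float = 15.0

    def exchange_for(
        self, residue: int, field_mhz: float
    ) -> TwoStateExchange:
        dw = self.delta_omega.get(residue, 0.0)
        r20 = self.r20.get((residue, field_mhz), self.r20_default)
        return TwoStateExchange(self.k_ex, self.p_A, dw, r20)


@dataclass(frozen=True)
class TitrationResidueTruth:
    """Two-endpoint sigmoidal shift trajectory plus peak-status rules.

    The residue moves from (dh_base, dn_base) at high pH to
    (dh_acid, dn_acid) at low pH through a single-pKa sigmoid.  It is
    reported missing at pH above ``missing_above`` or below
    ``missing_below``, and emits a second minor peak inside
    ``multiple_window`` (a (low, high) pH pair).
    """

    residue: int
    dh_base: float
    dn_base: float
    dh_acid: float
    dn_acid: float
    pka: float = 3.8
    missing_above: float | None = None
    missing_below: float | None = None
    multiple_window: tuple[float, float] | None = None

    def shifts_at(self, ph: float) -> tuple[float, float]:
        f = 1.0 / (1.0 + 10.0 ** (ph - self.pka))  # acid fraction
        dh = self.dh_base + (self.dh_acid - self.dh_base) * f
        dn = self.dn_base + (self.dn_acid - self.dn_base) * f
        return dh, dn

    def status_at(self, ph: float) -> str:
        if self.missing_above is not None and ph > self.missing_above:
            return "missing"
        if self.missing_below is not None and ph < self.missing_below:
            return "missing"
        if self.multiple_window is not None:
            lo, hi = self.multiple_window
            if lo <= ph <= hi:
                return "multiple"
        return "present"


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to generate (and later to grade) a dataset."""

    tensor: DiffusionTensor
    residues: tuple[ResidueMotion, ...] = ()
    exchange: ExchangeTruth | None = None
    titration: tuple[TitrationResidueTruth, ...] = ()
    noise: float = 0.02
    seed: int = 0
    i0: float = 1000.0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise level must be non-negative")

    def nh_angles(self) -> dict[int, float]:
        return {
            r.residue: r.nh_angle(self.tensor.axis) for r in self.residues
        }

    def true_rates(self, spin: SpinSystem) -> pd.DataFrame:
        rows = []
        for r in self.residues:
            angle = None
            if self.tensor.kind != "isotropic":
                angle = r.nh_angle(self.tensor.axis)
            r1, r2, noe = rates_from_model(r.model, self.tensor, spin, angle)
            rows.append(
                dict(residue=r.residue, model_id=r.model.model_id,
                     S2=r.model.S2, r1=r1, r2=r2, noe=noe)
            )
        return pd.DataFrame(rows)


def _rng(truth: GroundTruth, stream: int) -> np.random.Generator:
    return np.random.default_rng([truth.seed, stream])


def _mult_noise(rng: np.random.Generator, x: np.ndarray, frac: float):
    if frac == 0:
        return np.asarray(x, float)
    return np.asarray(x, float) * (1.0 + rng.normal(0.0, frac, np.shape(x)))


# ---------------------------------------------------------------------------
# Relaxation-decay and NOE tables
# ---------------------------------------------------------------------------

def make_relaxation_dataset(
    truth: GroundTruth,
    spin: SpinSystem,
    r1_delays=DEFAULT_R1_DELAYS,
    r2_delays=DEFAULT_R2_DELAYS,
) -> dict[str, pd.DataFrame]:
    """Generate R1/R2 decay tables and an NOE saturated/reference table.

    Returns ``{"r1": ..., "r2": ..., "noe": ..., "truth_rates": ...}``;
    decay tables have columns (residue, delay_s, intensity, sigma), the
    NOE table (residue, i_sat, i_ref, sigma_sat, sigma_ref), and
    ``truth_rates`` is the noiseless ground-truth sidecar.
    """
    if not truth.residues:
        raise ValueError("truth contains no residues")
    for d in (*r1_delays, *r2_delays):
        if d < 0:
            raise ValueError("negative delays")
    if len(r1_delays) < 5 or len(r2_delays) < 5:
        raise ValueError("at least 5 delays required for R1 and R2 decays")

    rng = _rng(truth, 1)
    rates = truth.true_rates(spin)
    out: dict[str, list] = {"r1": [], "r2": [], "noe": []}
    for _, row in rates.iterrows():
        for key, delays, rate in (
            ("r1", r1_delays, row.r1),
            ("r2", r2_delays, row.r2),
        ):
            ideal = truth.i0 * np.exp(-rate * np.asarray(delays))
            obs = _mult_noise(rng, ideal, truth.noise)
            for t, i in zip(delays, obs):
                out[key].append(
                    dict(residue=int(row.residue), delay_s=t, intensity=i,
                         sigma=truth.noise * truth.i0 * math.exp(-rate * t))
                )
        i_ref = _mult_noise(rng, truth.i0, truth.noise)
        i_sat = _mult_noise(rng, row.noe * truth.i0, truth.noise)
        out["noe"].append(
            dict(residue=int(row.residue), i_sat=float(i_sat),
                 i_ref=float(i_ref),
                 sigma_sat=truth.noise * truth.i0 * abs(row.noe),
                 sigma_ref=truth.noise * truth.i0)
        )
    return {
        "r1": pd.DataFrame(out["r1"]),
        "r2": pd.DataFrame(out["r2"]),
        "noe": pd.DataFrame(out["noe"]),
        "truth_rates": rates,
    }


# ---------------------------------------------------------------------------
# CPMG intensity tables
# ---------------------------------------------------------------------------

def make_cpmg_dataset(
    truth: GroundTruth, design: CpmgDesign
) -> dict[str, pd.DataFrame]:
    """Generate a constant-time CPMG intensity table from two-state truth.

    I(nu) = I0 exp(-R2eff(nu) T) (1 + eps) with R2eff from the numerical
    Bloch-McConnell model; the nu = 0 reference plane carries no decay;
    duplicated nu points get independent noise draws.  Returns
    ``{"cpmg": table, "truth_r2eff": sidecar}`` with table columns
    (residue, field_mhz, nu_cpmg_hz, intensity, replicate).
    """
    if truth.exchange is None:
        raise ValueError("truth has no exchange component")
    if 0.0 not in design.nu_cpmg:
        raise ValueError("design must include the nu_cpmg = 0 reference")
    nz = [n for n in design.nu_cpmg if n > 0]
    if len(nz) == len(set(nz)):
        raise ValueError("design must duplicate at least one nu_cpmg")

    rng = _rng(truth, 2)
    residues = sorted(
        set(truth.exchange.delta_omega)
        | {r.residue for r in truth.residues}
    ) or sorted(truth.exchange.delta_omega)
    rows, sidecar = [], []
    for res in residues:
        for fmhz in design.fields:
            exch = truth.exchange.exchange_for(res, fmhz)
            spin = SpinSystem(fmhz)
            rep_count: dict[float, int] = {}
            for nu in design.nu_cpmg:
                rep = rep_count.get(nu, 0)
                rep_count[nu] = rep + 1
                if nu == 0:
                    ideal = truth.i0
                    r2eff = 0.0
                else:
                    r2eff = bloch_mcconnell_r2eff(
                        exch, nu, spin, design.t_relax
                    )
                    ideal = truth.i0 * math.exp(-r2eff * design.t_relax)
                obs = float(_mult_noise(rng, ideal, truth.noise))
                rows.append(
                    dict(residue=res, field_mhz=fmhz, nu_cpmg_hz=nu,
                         intensity=obs, replicate=rep)
                )
                if nu > 0 and rep == 0:
                    sidecar.append(
                        dict(residue=res, field_mhz=fmhz, nu_cpmg_hz=nu,
                             r2eff=r2eff,
                             delta_omega=exch.delta_omega,
                             k_ex=exch.k_ex, p_A=exch.p_A, r20=exch.r20)
                    )
    return {
        "cpmg": pd.DataFrame(rows),
        "truth_r2eff": pd.DataFrame(sidecar),
    }


# ---------------------------------------------------------------------------
# Titration shift tables
# ---------------------------------------------------------------------------

def make_titration_dataset(
    truth: GroundTruth,
    ph_list,
    shift_noise_h: float = 0.002,
    shift_noise_n: float = 0.01,
) -> pd.DataFrame:
    """Generate a per-pH chemical-shift table with status flags.

    ``ph_list`` is given in descending order (titration from neutral to
    acid).  Columns: residue, ph, dH_ppm, dN_ppm, status, peakset.
    Residues flagged missing carry NaN shifts; in a multiple-peak window
    a second ("minor") peak is emitted halfway between the endpoints.
    """
    ph = list(ph_list)
    if len(ph) < 3:
        raise ValueError("need at least 3 pH points")
    if sorted(ph, reverse=True) != ph:
        raise ValueError("ph_list must be sorted descending")
    if not truth.titration:
        raise ValueError("truth has no titration component")

    rng = _rng(truth, 3)
    rows = []
    for t in truth.titration:
        for p in ph:
            status = t.status_at(p)
            if status == "missing":
                rows.append(dict(residue=t.residue, ph=p, dH_ppm=np.nan,
                                 dN_ppm=np.nan, status=status,
                                 peakset="major"))
                continue
            dh, dn = t.shifts_at(p)
            rows.append(
                dict(residue=t.residue, ph=p,
                     dH_ppm=dh + (rng.normal(0, shift_noise_h)
                                  if truth.noise > 0 else 0.0),
                     dN_ppm=dn + (rng.normal(0, shift_noise_n)
                                  if truth.noise > 0 else 0.0),
                     status=status, peakset="major")
            )
            if status == "multiple":
                mh = 0.5 * (t.dh_base + t.dh_acid)
                mn = 0.5 * (t.dn_base + t.dn_acid)
                rows.append(
                    dict(residue=t.residue, ph=p,
                         dH_ppm=mh + (rng.normal(0, shift_noise_h)
                                      if truth.noise > 0 else 0.0),
                         dN_ppm=mn + (rng.normal(0, shift_noise_n)
                                      if truth.noise > 0 else 0.0),
                         status=status, peakset="minor")
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truth factories for common study designs
# ---------------------------------------------------------------------------

def random_orientations(
    n: int, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """n unit vectors uniform on the sphere."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return [tuple(map(float, row)) for row in v]


def rigid_residue_truth(
    n_residues: int,
    tensor: DiffusionTensor,
    s2_mean: float = 0.91,
    s2_sd: float = 0.02,
    noise: float = 0.02,
    seed: int = 0,
) -> GroundTruth:
    """Rigid (model M1) residues with random N-H orientations.

    Emulates the subset used for diffusion-tensor estimation: pure
    overall tumbling with per-residue S2 drawn N(s2_mean, s2_sd),
    clipped to [0, 1].
    """
    rng = np.random.default_rng([seed, 10])
    vecs = random_orientations(n_residues, rng)
    residues = tuple(
        ResidueMotion(
            residue=i + 1,
            model=MotionalModel(
                "M1", S2=float(np.clip(rng.normal(s2_mean, s2_sd), 0.5, 1.0))
            ),
            nh_vector=vecs[i],
        )
        for i in range(n_residues)
    )
    return GroundTruth(tensor=tensor, residues=residues, noise=noise,
                       seed=seed)


def modelfree_composition_truth(
    tensor: DiffusionTensor,
    noise: float = 0.02,
    seed: int = 0,
    n_m1: int = 28,
    n_m3: int = 8,
    n_m4: int = 4,
    n_m5: int = 7,
    s2_m1: tuple[float, float] = (0.90, 0.04),
) -> GroundTruth:
    """A synthetic protein with the near-neutral-pH motional composition:
    a rigid core (M1, S2 ~ 0.90), exchange-broadened residues (M3, M4
    with Rex of a few s^-1) and flexible termini (M5, S2 ~ 0.28).

    Parameter spreads follow the per-model means and standard deviations
    of the corresponding fitted ensembles; Rex and tau_e magnitudes are
    generator choices in the typical backbone range.
    """
    rng = np.random.default_rng([seed, 11])
    residues = []
    rid = 0

    def nxt():
        nonlocal rid
        rid += 1
        return rid

    vecs = random_orientations(n_m1 + n_m3 + n_m4 + n_m5, rng)
    for _ in range(n_m1):
        s2 = float(np.clip(rng.normal(*s2_m1), 0.6, 0.99))
        residues.append(ResidueMotion(nxt(), MotionalModel("M1", S2=s2),
                                      vecs[rid - 1]))
    for _ in range(n_m3):
        s2 = float(np.clip(rng.normal(0.89, 0.04), 0.6, 0.99))
        rex = float(rng.uniform(3.0, 8.0))
        residues.append(
            ResidueMotion(nxt(), MotionalModel("M3", S2=s2, Rex=rex),
                          vecs[rid - 1])
        )
    for _ in range(n_m4):
        s2 = float(np.clip(rng.normal(0.87, 0.06), 0.6, 0.99))
        rex = float(rng.uniform(3.0, 8.0))
        te = float(rng.uniform(30e-12, 80e-12))
        residues.append(
            ResidueMotion(nxt(),
                          MotionalModel("M4", S2=s2, tau_e=te, Rex=rex),
                          vecs[rid - 1])
        )
    for _ in range(n_m5):
        s2f = float(rng.uniform(0.6, 0.85))
        s2 = float(np.clip(rng.normal(0.28, 0.1), 0.1, s2f - 0.1))
        te = float(rng.uniform(0.8e-9, 2.0e-9))
        residues.append(
            ResidueMotion(nxt(),
                          MotionalModel("M5", S2=s2, tau_e=te, S2f=s2f),
                          vecs[rid - 1])
        )
    return GroundTruth(tensor=tensor, residues=tuple(residues),
                       noise=noise, seed=seed)
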