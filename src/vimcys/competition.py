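"""Competitive zinc binding: Zincon chelator vs protein sites.

The Zincon assay reads out the Zn-Zincon complex at 620 nm.  Adding a
zinc-binding protein diverts Zn2+ from the probe, shifting the A620
titration right.  We model the mixture as a single equilibrium with 1:1
Zn:Zincon stoichiometry and ``n`` independent identical protein sites:

    Zn_T = z + Zincon_T * z/(K_Z + z) + n * P_T * z/(K_P + z)

solved for free zinc ``z`` by bracketed root finding.  The protein's
apparent dissociation constant K_P (and optionally n) is estimated by
nonlinear least squares on paired with/without-protein A620 curves, with
the absorbance scale calibrated on the protein-free curve so that scale
and K_P are not confounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "CompetitionAssay",
    "BindingModel",
    "SpeciesState",
    "solve_species",
    "free_zinc",
    "predict_absorbance",
    "fit_binding",
    "assay_to_frame",
    "frame_to_assay",
]

COMPETITION_COLUMNS = ["curve_id", "protein_total_um", "zn_total_um", "a620"]

#: K_P (uM) at/above which the fit is flagged as showing no competition.
NONCOMPETING_KP_UM = 1e4


@dataclass
class BindingModel:
    """Equilibrium and readout parameters of the competition assay.

    K_D inputs carry explicit unit tags: ``kd_zincon_nm`` in nM (probe,
    default 214 nM), ``kd_protein_um`` in uM.  ``n_sites`` is the number
    of independent identical zinc sites per protein molecule.
    """

    kd_zincon_nm: float = 214.0
    kd_protein_um: float = 1.0
    n_sites: float = 1.0
    abs_scale: float = 0.02  # AU per uM Zn-Zincon
    abs_baseline: float = 0.02  # AU
    noncompeting: bool = False
    kd_protein_stderr_um: float | None = None
    n_sites_stderr: float | None = None

    def __post_init__(self) -> None:
        if self.kd_zincon_nm <= 0 or self.kd_protein_um <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")

    @property
    def kd_zincon_um(self) -> float:
        return self.kd_zincon_nm / 1000.0


@dataclass
class CompetitionAssay:
    """A620 titrations at fixed Zincon, with and without protein."""

    zincon_total: float  # uM
    protein_total: float  # uM (the with-protein curve's concentration)
    points: pd.DataFrame  # columns: zn_total_um, a620, with_protein(bool)

    def curve(self, with_protein: bool) -> pd.DataFrame:
        sub = self.points[self.points["with_protein"] == with_protein]
        return sub.sort_values("zn_total_um").reset_index(drop=True)


@dataclass
class SpeciesState:
    zn_free: float  # uM
    zn_zincon: float  # uM
    zn_protein: float  # uM


def _mass_balance(z: float, zn_total: float, zincon_total: float,
                  sites_total: float, kz: float, kp: float) -> float:
    return (z + zincon_total * z / (kz + z) + sites_total * z / (kp + z)
            - zn_total)


def free_zinc(zn_total: float, zincon_total: float, sites_total: float,
              kz_um: float, kp_um: float) -> float:
    """Free Zn2+ (uM) from the 1-D mass balance, by Brent root finding."""
    if zn_total < 0:
        raise ValueError("zn_total must be non-negative")
    if zn_total == 0:
        return 0.0
    f = lambda z: _mass_balance(z, zn_total, zincon_total, sites_total, kz_um, kp_um)
    # f(0) = -zn_total < 0 and f(zn_total) >= 0, so [0, zn_total] brackets.
    return float(optimize.brentq(f, 0.0, zn_total, xtol=1e-14, rtol=8.9e-16,
                                 maxiter=200))


def solve_species(zn_total: float, assay: CompetitionAssay, model: BindingModel,
                  protein_total: float | None = None) -> SpeciesState:
    """Equilibrium speciation of zinc at one total-zinc concentration."""
    pt = assay.protein_total if protein_total is None else protein_total
    sites = model.n_sites * pt
    z = free_zinc(zn_total, assay.zincon_total, sites,
                  model.kd_zincon_um, model.kd_protein_um)
    zz = assay.zincon_total * z / (model.kd_zincon_um + z)
    zp = sites * z / (model.kd_protein_um + z)
    # In stiff regimes (K_D << totals) the float64 root cannot drive the
    # balance below the gradient * eps floor; assign the tiny remainder to
    # the dominant complex so conservation holds exactly.
    resid = zn_total - (z + zz + zp)
    if resid != 0.0:
        if zz >= zp and zz + resid >= 0.0:
            zz += resid
        elif zp + resid >= 0.0:
            zp += resid
    state = SpeciesState(zn_free=z, zn_zincon=zz, zn_protein=zp)
    final = abs(state.zn_free + state.zn_zincon + state.zn_protein - zn_total)
    if final > 1e-9 * max(1.0, zn_total):
        raise RuntimeError(
            f"mass balance residual {final:.3e} at zn_total={zn_total}"
        )
    return state


def predict_absorbance(state: SpeciesState, model: BindingModel) -> float:
    """A620 = baseline + scale * [Zn-Zincon] (linear chromophore response)."""
    return model.abs_baseline + model.abs_scale * state.zn_zincon


def _predict_curve(zn_totals: np.ndarray, assay: CompetitionAssay,
                   model: BindingModel, protein_total: float) -> np.ndarray:
    out = np.empty_like(zn_totals, dtype=float)
    for i, zt in enumerate(zn_totals):
        st = solve_species(float(zt), assay, model, protein_total=protein_total)
        out[i] = predict_absorbance(st, model)
    return out


def fit_binding(assay: CompetitionAssay, kd_zincon_nm: float = 214.0,
                fit_n_sites: bool = True, n_sites: float = 1.0) -> BindingModel:
    """Estimate the protein's zinc affinity from paired A620 curves.

    Step 1 calibrates ``abs_scale``/``abs_baseline`` by linear regression
    of the protein-free curve on its computed [Zn-Zincon].  Step 2 fits
    ``kd_protein_um`` (log-scale) and optionally ``n_sites`` to the
    with-protein curve by multistart nonlinear least squares, holding the
    Zincon K_D fixed.  A fit driven to very weak affinity (K_P >= 10 mM)
    is flagged ``noncompeting`` rather than treated as an error.
    """
    free_curve = assay.curve(with_protein=False)
    prot_curve = assay.curve(with_protein=True)
    if len(free_curve) < 5 or len(prot_curve) < 5:
        raise ValueError("need >=5 points on both with- and without-protein curves")

    kz = kd_zincon_nm / 1000.0
    zz_free = np.array([
        free_zinc(zt, assay.zincon_total, 0.0, kz, 1.0)
        for zt in free_curve["zn_total_um"]
    ])
    zz_free = assay.zincon_total * zz_free / (kz + zz_free)
    scale, baseline = np.polyfit(zz_free, free_curve["a620"].to_numpy(), 1)

    zt = prot_curve["zn_total_um"].to_numpy()
    a_obs = prot_curve["a620"].to_numpy()

    def resid(theta):
        log_kp = theta[0]
        n = theta[1] if fit_n_sites else n_sites
        m = BindingModel(kd_zincon_nm=kd_zincon_nm, kd_protein_um=10.0 ** log_kp,
                         n_sites=n, abs_scale=scale, abs_baseline=baseline)
        return _predict_curve(zt, assay, m, assay.protein_total) - a_obs

    lo = [-4.0] + ([0.0] if fit_n_sites else [])
    hi = [6.0] + ([10.0] if fit_n_sites else [])
    best = None
    for log_kp0 in (-2.0, -1.0, 0.0, 1.0, 2.0):
        x0 = [log_kp0] + ([max(n_sites, 0.5)] if fit_n_sites else [])
        sol = optimize.least_squares(resid, x0, bounds=(lo, hi))
        if best is None or sol.cost < best.cost:
            best = sol

    log_kp = best.x[0]
    n_hat = float(best.x[1]) if fit_n_sites else float(n_sites)
    kp = 10.0 ** log_kp

    # no-competition comparison: does modelling the protein at all improve
    # on simply predicting the protein-free curve?  (extra-SS F-test)
    m0 = BindingModel(kd_zincon_nm=kd_zincon_nm, kd_protein_um=1.0, n_sites=0.0,
                      abs_scale=scale, abs_baseline=baseline)
    ssr0 = float(np.sum((_predict_curve(zt, assay, m0, 0.0) - a_obs) ** 2))
    ssr = 2.0 * best.cost
    p_extra = len(best.x)
    dof = len(zt) - p_extra
    noncompeting = bool(kp >= NONCOMPETING_KP_UM)
    if dof > 0 and ssr > 0:
        from scipy import stats as _stats
        fstat = max(ssr0 - ssr, 0.0) / p_extra / (ssr / dof)
        p_comp = float(_stats.f.sf(fstat, p_extra, dof))
        noncompeting = noncompeting or p_comp > 0.05

    # covariance from the Jacobian at the optimum
    kp_se = n_se = None
    try:
        J = best.jac
        dof = max(1, len(zt) - len(best.x))
        s2 = 2.0 * best.cost / dof
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.diag(cov))
        kp_se = float(kp * math.log(10.0) * se[0])  # delta method from log10 K_P
        if fit_n_sites:
            n_se = float(se[1])
    except np.linalg.LinAlgError:
        pass

    return BindingModel(
        kd_zincon_nm=kd_zincon_nm, kd_protein_um=kp, n_sites=n_hat,
        abs_scale=float(scale), abs_baseline=float(baseline),
        noncompeting=noncompeting,
        kd_protein_stderr_um=kp_se, n_sites_stderr=n_se,
    )


def assay_to_frame(assay: CompetitionAssay) -> pd.DataFrame:
    df = assay.points.copy()
    df["curve_id"] = np.where(df["with_protein"], "protein", "no_protein")
    df["protein_total_um"] = np.where(df["with_protein"], assay.protein_total, 0.0)
    return df[COMPETITION_COLUMNS]


def frame_to_assay(df: pd.DataFrame, zincon_total: float) -> CompetitionAssay:
    pts = df.copy()
    pts["with_protein"] = pts["protein_total_um"] > 0
    protein_total = pts.loc[pts["with_protein"], "protein_total_um"].max()
    if not np.isfinite(protein_total):
        protein_total = 0.0
    return CompetitionAssay(
        zincon_total=zincon_total, protein_total=float(protein_total),
        points=pts[["zn_total_um", "a620", "with_protein"]],
    )
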