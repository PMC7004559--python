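"""Semi-physiological compartmental PK models driven by a delivery profile.

Each drug is described by amounts (mg) in Liver (L), Blood (B) and Organs
(O); the hepatic-artery infusion enters the Liver directly as the mass rate
``d(t)`` produced by the pump-transport model.  Transport between Blood and
a tissue compartment is passive and linear; across each interface the flux
is ``p * V_tissue * (C_tissue - C_blood)`` with one permeability ``p``
(1/h) per drug per interface, so equal concentrations give zero net flux.
Clearances are first-order on compartment amounts and leave the system
(no enterohepatic recirculation).  Circadian modulation of parameters is
deliberately absent.

Models
------
* Irinotecan (CPT11): 6 states — CPT11 and its active metabolite SN38 in
  L/B/O.  CPT11 is converted to SN38 by Michaelis–Menten kinetics in Liver
  and Organs only (carboxylesterases are not expressed in blood cells),
  with a fixed affinity Km = 59.2 uM.  SN38 exchanges with Blood and is
  cleared in Liver (deactivation to SN38G) and Organs, the latter fixed at
  twice the hepatic rate.
* Oxaliplatin (LOHP): 6 states — free and protein-bound platinum in L/B/O.
  Only free Pt crosses compartment walls; binding/unbinding occurs in all
  compartments; the sole elimination is renal clearance of free blood Pt.
* 5-fluorouracil (FU5): 3 states, linear, with hepatic and renal (blood)
  clearances; protein binding neglected.

Auxiliary cumulative states track the mass delivered and the mass leaving
through each clearance route, so mass balance and clearance-route fractions
are available from the same integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from chronopk.pump import DeliveryProfile
from chronopk.volumes import CompartmentVolumes

__all__ = [
    "IrinotecanParams",
    "OxaliplatinParams",
    "FluorouracilParams",
    "ConcentrationSeries",
    "SimulationResult",
    "simulate_irinotecan",
    "simulate_oxaliplatin",
    "simulate_5fu",
    "simulate",
    "clearance_fractions",
    "KM_FIXED_UM",
    "MW_CPT11",
    "MW_SN38",
]

#: Michaelis constant of hepatic carboxylesterase CPT11 -> SN38 conversion,
#: fixed from in vitro human liver data and never fitted.
KM_FIXED_UM = 59.2
#: Molar masses (g/mol) used to keep the CPT11 -> SN38 conversion mole-consistent.
MW_CPT11 = 586.68
MW_SN38 = 392.40


def _km_mg_l(km_um: float, mw: float) -> float:
    return km_um * mw / 1000.0


@dataclass(frozen=True)
class IrinotecanParams:
    """Rate constants of the irinotecan/SN38 model (1/h unless noted)."""

    k_LB_cpt: float   # Liver<->Blood permeability, CPT11
    k_BO_cpt: float   # Blood<->Organs permeability, CPT11
    k_LB_sn: float    # Liver<->Blood permeability, SN38
    k_BO_sn: float    # Blood<->Organs permeability, SN38
    Vmax_L: float     # maximal hepatic conversion rate (mg/h)
    Vmax_O: float     # maximal organs conversion rate (mg/h)
    Cl_B_cpt: float   # renal clearance of blood CPT11
    Cl_L_cpt: float   # biliary/hepatic clearance of liver CPT11
    Cl_O_cpt: float   # intestinal clearance of organs CPT11
    Cl_L_sn: float    # hepatic SN38 clearance (incl. SN38G deactivation)
    Km_uM: float = KM_FIXED_UM
    mw_cpt11: float = MW_CPT11
    mw_sn38: float = MW_SN38

    @property
    def Cl_O_sn(self) -> float:
        """Organs SN38 clearance, fixed at twice the hepatic rate."""
        return 2.0 * self.Cl_L_sn

    def __post_init__(self) -> None:
        vals = [self.k_LB_cpt, self.k_BO_cpt, self.k_LB_sn, self.k_BO_sn,
                self.Vmax_L, self.Vmax_O, self.Cl_B_cpt, self.Cl_L_cpt,
                self.Cl_O_cpt, self.Cl_L_sn]
        if any(v < 0 for v in vals):
            raise ValueError("irinotecan parameters must be nonnegative")


@dataclass(frozen=True)
class OxaliplatinParams:
    """Rate constants of the free/bound platinum model (1/h)."""

    k_LB: float    # Liver<->Blood permeability, free Pt
    k_BO: float    # Blood<->Organs permeability, free Pt
    k_on: float    # protein binding rate (all compartments)
    k_off: float   # unbinding rate, driven by protein degradation
    Cl_B: float    # renal clearance of free blood Pt (only elimination route)

    def __post_init__(self) -> None:
        if any(v < 0 for v in (self.k_LB, self.k_BO, self.k_on, self.k_off, self.Cl_B)):
            raise ValueError("oxaliplatin parameters must be nonnegative")


@dataclass(frozen=True)
class FluorouracilParams:
    """Rate constants of the linear 5-FU model (1/h)."""

    k_LB: float
    k_BO: float
    Cl_L: float   # hepatic clearance (metabolism + biliary excretion)
    Cl_B: float   # renal clearance

    def __post_init__(self) -> None:
        if any(v < 0 for v in (self.k_LB, self.k_BO, self.Cl_L, self.Cl_B)):
            raise ValueError("5-FU parameters must be nonnegative")


@dataclass(frozen=True)
class ConcentrationSeries:
    """A sampled plasma concentration-time course for one analyte."""

    analyte: str                 # CPT11 | SN38 | Pt_free | Pt_total | FU5
    times_h: np.ndarray
    values_mg_l: np.ndarray
    patient_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values_mg_l, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values_mg_l", v)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("concentrations must be nonnegative")


@dataclass(frozen=True)
class SimulationResult:
    """Full model output: blood series plus mass bookkeeping."""

    series: dict[str, ConcentrationSeries]
    times_h: np.ndarray
    amounts_mg: dict[str, np.ndarray]      # per named state
    cleared_mg: dict[str, np.ndarray]      # cumulative, per clearance route
    delivered_mg: np.ndarray               # cumulative infused mass

    def route_fractions_pct(self, at: float | None = None) -> dict[str, float]:
        """Cumulative clearance per route as percent of delivered dose."""
        idx = -1 if at is None else int(np.searchsorted(self.times_h, at, side="right") - 1)
        dose = self.delivered_mg[-1]
        if dose <= 0:
            return {k: 0.0 for k in self.cleared_mg}
        return {k: 100.0 * float(v[idx]) / float(dose) for k, v in self.cleared_mg.items()}

    def amount_fractions_pct(self, at: float | None = None) -> dict[str, float]:
        """Compartment amounts as percent of delivered dose."""
        idx = -1 if at is None else int(np.searchsorted(self.times_h, at, side="right") - 1)
        dose = self.delivered_mg[-1]
        if dose <= 0:
            return {k: 0.0 for k in self.amounts_mg}
        return {k: 100.0 * float(v[idx]) / float(dose) for k, v in self.amounts_mg.items()}


class IntegrationFailure(RuntimeError):
    pass


_NEG_TOL = -1e-6  # mg; states below this signal integrator failure


def _integrate(rhs, y0, t_grid, rtol=1e-8, atol=1e-10, max_step=np.inf):
    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, method="LSODA",
        t_eval=t_grid, rtol=rtol, atol=atol, max_step=max_step,
    )
    if not sol.success:
        raise IntegrationFailure(sol.message)
    if sol.y.min() < _NEG_TOL:
        raise IntegrationFailure(f"negative state beyond tolerance: min={sol.y.min():.3g} mg")
    return np.clip(sol.y, 0.0, None)


def _delivery_fn(delivery: DeliveryProfile) -> Callable[[float], float]:
    t = delivery.times_h
    r = delivery.rate_mg_h
    return lambda s: float(np.interp(s, t, r, left=0.0, right=0.0))


def _grid(delivery: DeliveryProfile, horizon_h: float, n: int = 800) -> np.ndarray:
    t0 = float(delivery.times_h[0])
    return np.linspace(t0, t0 + horizon_h, n)


def simulate_irinotecan(
    params: IrinotecanParams,
    vols: CompartmentVolumes,
    delivery: DeliveryProfile,
    horizon_h: float = 32.0,
    t_eval: np.ndarray | None = None,
    patient_id: str | None = None,
    rtol: float = 1e-8,
) -> SimulationResult:
    """Integrate the 6-state CPT11/SN38 model; returns blood concentrations.

    SN38 amounts are in mg of SN38; the conversion term is scaled by the
    molar-mass ratio so that moles are conserved.
    """
    V_L, V_B, V_O = vols.V_L, vols.V_B, vols.V_O
    p = params
    km = _km_mg_l(p.Km_uM, p.mw_cpt11)
    ratio = p.mw_sn38 / p.mw_cpt11
    d = _delivery_fn(delivery)

    def rhs(t, y):
        aLc, aBc, aOc, aLs, aBs, aOs = y[:6]
        cLc, cBc, cOc = aLc / V_L, aBc / V_B, aOc / V_O
        cLs, cBs, cOs = aLs / V_L, aBs / V_B, aOs / V_O
        t_lb_c = p.k_LB_cpt * V_L * (cLc - cBc)
        t_bo_c = p.k_BO_cpt * V_O * (cBc - cOc)
        t_lb_s = p.k_LB_sn * V_L * (cLs - cBs)
        t_bo_s = p.k_BO_sn * V_O * (cBs - cOs)
        mm_l = p.Vmax_L * cLc / (km + cLc) if cLc > 0 else 0.0
        mm_o = p.Vmax_O * cOc / (km + cOc) if cOc > 0 else 0.0
        return [
            d(t) - t_lb_c - mm_l - p.Cl_L_cpt * aLc,
            t_lb_c - t_bo_c - p.Cl_B_cpt * aBc,
            t_bo_c - mm_o - p.Cl_O_cpt * aOc,
            mm_l * ratio - t_lb_s - p.Cl_L_sn * aLs,
            t_lb_s - t_bo_s,
            mm_o * ratio + t_bo_s - p.Cl_O_sn * aOs,
            p.Cl_B_cpt * aBc,        # renal CPT11
            p.Cl_L_cpt * aLc,        # biliary CPT11
            p.Cl_O_cpt * aOc,        # intestinal CPT11
            p.Cl_L_sn * aLs,         # hepatic SN38
            p.Cl_O_sn * aOs,         # organs SN38
            d(t),                    # delivered
        ]

    t_grid = _grid(delivery, horizon_h) if t_eval is None else np.asarray(t_eval, dtype=float)
    y = _integrate(rhs, np.zeros(12), t_grid, rtol=rtol, max_step=0.05)
    series = {
        "CPT11": ConcentrationSeries("CPT11", t_grid, y[1] / V_B, patient_id),
        "SN38": ConcentrationSeries("SN38", t_grid, y[4] / V_B, patient_id),
    }
    amounts = dict(zip(["CPT11_L", "CPT11_B", "CPT11_O", "SN38_L", "SN38_B", "SN38_O"], y[:6]))
    cleared = dict(zip(
        ["renal_cpt11", "biliary_cpt11", "intestinal_cpt11", "hepatic_sn38", "organs_sn38"], y[6:11]
    ))
    return SimulationResult(series, t_grid, amounts, cleared, y[11])


def simulate_oxaliplatin(
    params: OxaliplatinParams,
    vols: CompartmentVolumes,
    delivery: DeliveryProfile,
    horizon_h: float = 18.0,
    t_eval: np.ndarray | None = None,
    patient_id: str | None = None,
    rtol: float = 1e-8,
) -> SimulationResult:
    """Integrate the 6-state free/bound platinum model.

    The infused drug enters the Liver in free form; ``Pt_total`` in blood is
    the sum of free and bound amounts over the blood volume.
    """
    V_L, V_B, V_O = vols.V_L, vols.V_B, vols.V_O
    p = params
    d = _delivery_fn(delivery)

    def rhs(t, y):
        fL, fB, fO, bL, bB, bO = y[:6]
        cfL, cfB, cfO = fL / V_L, fB / V_B, fO / V_O
        t_lb = p.k_LB * V_L * (cfL - cfB)
        t_bo = p.k_BO * V_O * (cfB - cfO)
        return [
            d(t) - t_lb - p.k_on * fL + p.k_off * bL,
            t_lb - t_bo - p.k_on * fB + p.k_off * bB - p.Cl_B * fB,
            t_bo - p.k_on * fO + p.k_off * bO,
            p.k_on * fL - p.k_off * bL,
            p.k_on * fB - p.k_off * bB,
            p.k_on * fO - p.k_off * bO,
            p.Cl_B * fB,   # renal free Pt
            d(t),
        ]

    t_grid = _grid(delivery, horizon_h) if t_eval is None else np.asarray(t_eval, dtype=float)
    y = _integrate(rhs, np.zeros(8), t_grid, rtol=rtol, max_step=0.05)
    series = {
        "Pt_free": ConcentrationSeries("Pt_free", t_grid, y[1] / V_B, patient_id),
        "Pt_total": ConcentrationSeries("Pt_total", t_grid, (y[1] + y[4]) / V_B, patient_id),
    }
    amounts = dict(zip(["free_L", "free_B", "free_O", "bound_L", "bound_B", "bound_O"], y[:6]))
    cleared = {"renal_pt": y[6]}
    return SimulationResult(series, t_grid, amounts, cleared, y[7])


def simulate_5fu(
    params: FluorouracilParams,
    vols: CompartmentVolumes,
    delivery: DeliveryProfile,
    horizon_h: float = 14.0,
    t_eval: np.ndarray | None = None,
    patient_id: str | None = None,
    rtol: float = 1e-8,
) -> SimulationResult:
    """Integrate the linear 3-state 5-fluorouracil model."""
    V_L, V_B, V_O = vols.V_L, vols.V_B, vols.V_O
    p = params
    d = _delivery_fn(delivery)

    def rhs(t, y):
        aL, aB, aO = y[:3]
        t_lb = p.k_LB * V_L * (aL / V_L - aB / V_B)
        t_bo = p.k_BO * V_O * (aB / V_B - aO / V_O)
        return [
            d(t) - t_lb - p.Cl_L * aL,
            t_lb - t_bo - p.Cl_B * aB,
            t_bo,
            p.Cl_L * aL,
            p.Cl_B * aB,
            d(t),
        ]

    t_grid = _grid(delivery, horizon_h) if t_eval is None else np.asarray(t_eval, dtype=float)
    y = _integrate(rhs, np.zeros(6), t_grid, rtol=rtol, max_step=0.05)
    series = {"FU5": ConcentrationSeries("FU5", t_grid, y[1] / V_B, patient_id)}
    amounts = dict(zip(["FU5_L", "FU5_B", "FU5_O"], y[:3]))
    cleared = {"hepatic_fu5": y[3], "renal_fu5": y[4]}
    return SimulationResult(series, t_grid, amounts, cleared, y[5])


_SIMULATORS = {
    "CPT11": simulate_irinotecan,
    "LOHP": simulate_oxaliplatin,
    "FU5": simulate_5fu,
}


def simulate(drug: str, params, vols, delivery, **kwargs) -> SimulationResult:
    """Dispatch to the drug-specific simulator."""
    try:
        fn = _SIMULATORS[drug]
    except KeyError:
        raise KeyError(f"unknown drug {drug!r}; expected one of {sorted(_SIMULATORS)}") from None
    return fn(params, vols, delivery, **kwargs)


def clearance_fractions(
    drug: str, params, vols: CompartmentVolumes, delivery: DeliveryProfile,
    horizon_h: float,
) -> dict[str, float]:
    """Percent of the delivered dose eliminated per clearance route by ``horizon_h``.

    For oxaliplatin the tissue-bound amounts (``bound_L``/``bound_O``) are
    also reported, as percent of dose at the horizon.
    """
    res = simulate(drug, params, vols, delivery, horizon_h=horizon_h, rtol=1e-7)
    out = res.route_fractions_pct()
    if drug == "LOHP":
        amt = res.amount_fractions_pct()
        out["bound_L"] = amt["bound_L"]
        out["bound_O"] = amt["bound_O"]
    return out
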