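"""Patient-individualised compartment volumes for the PK models.

Each semi-physiological model partitions the body into Liver (the infusion
site), Blood (the measurement site) and Organs (everything else).  Volumes
are individualised from routine anthropometrics:

* Liver — the BSA-based total-liver-volume regression of Vauthey and
  colleagues, TLV (ml) = -794.41 + 1267.28 * BSA (m^2);
* Blood — Nadler's sex-specific formula from height and weight;
* Organs — total body volume minus liver and blood.  Total body volume is
  obtained from weight and a whole-body density (default 1.04 kg/L, the
  conventional adult value); any of the three formulas can be overridden.

BSA, when not measured, defaults to the Du Bois formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

__all__ = [
    "PatientAnthropometrics",
    "CompartmentVolumes",
    "compute_compartment_volumes",
    "bsa_du_bois",
]

Sex = Literal["male", "female"]


def bsa_du_bois(height_m: float, weight_kg: float) -> float:
    """Du Bois & Du Bois body surface area (m^2)."""
    return 0.007184 * (height_m * 100.0) ** 0.725 * weight_kg**0.425


@dataclass(frozen=True)
class PatientAnthropometrics:
    sex: Sex
    height_m: float
    weight_kg: float
    bsa_m2: float | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.height_m <= 0 or self.weight_kg <= 0:
            raise ValueError("height and weight must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.bsa_m2 is not None and self.bsa_m2 <= 0:
            raise ValueError("bsa must be positive")

    @property
    def bsa(self) -> float:
        return self.bsa_m2 if self.bsa_m2 is not None else bsa_du_bois(self.height_m, self.weight_kg)


@dataclass(frozen=True)
class CompartmentVolumes:
    """Liver / Blood / Organs volumes in litres."""

    V_L: float
    V_B: float
    V_O: float

    def __post_init__(self) -> None:
        if min(self.V_L, self.V_B, self.V_O) <= 0:
            raise ValueError("compartment volumes must all be positive")

    @property
    def total(self) -> float:
        return self.V_L + self.V_B + self.V_O


def _vauthey_liver_l(anthro: PatientAnthropometrics) -> float:
    return (-794.41 + 1267.28 * anthro.bsa) / 1000.0


def _nadler_blood_l(anthro: PatientAnthropometrics) -> float:
    h, w = anthro.height_m, anthro.weight_kg
    if anthro.sex == "male":
        return 0.3669 * h**3 + 0.03219 * w + 0.6041
    return 0.3561 * h**3 + 0.03308 * w + 0.1833


def _body_volume_l(anthro: PatientAnthropometrics, density_kg_l: float = 1.04) -> float:
    return anthro.weight_kg / density_kg_l


def compute_compartment_volumes(
    anthro: PatientAnthropometrics,
    liver_formula: Callable[[PatientAnthropometrics], float] | None = None,
    blood_formula: Callable[[PatientAnthropometrics], float] | None = None,
    body_volume_formula: Callable[[PatientAnthropometrics], float] | None = None,
) -> CompartmentVolumes:
    """Individualised Liver/Blood/Organs volumes (L) for one patient.

    Organs is defined as the remainder of the total body volume, so
    ``V_L + V_B + V_O`` equals the total body volume by construction.
    Raises if any computed volume is non-physiologic (<= 0).
    """
    v_l = (liver_formula or _vauthey_liver_l)(anthro)
    v_b = (blood_formula or _nadler_blood_l)(anthro)
    v_body = (body_volume_formula or _body_volume_l)(anthro)
    v_o = v_body - v_l - v_b
    if v_l <= 0 or v_b <= 0 or v_o <= 0:
        raise ValueError(
            f"non-physiologic volumes for {anthro}: V_L={v_l:.3g}, V_B={v_b:.3g}, V_O={v_o:.3g} L"
        )
    return CompartmentVolumes(V_L=v_l, V_B=v_b, V_O=v_o)
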