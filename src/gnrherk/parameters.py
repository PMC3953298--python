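"""Model parameters for GnRH-receptor signaling to ERK.

All rates are expressed in min^-1 (or uM^-1 min^-1 for bimolecular steps) and
all concentrations in uM.  The default construction is the published best-fit
parameter set for the reduced GnRHR -> Gq effector -> MEK -> ERK -> TF1 ->
transcript cascade; the subset of parameters that was obtained by fitting to
ERK2-GFP translocation and reporter-gene data (rather than carried over from
the parent model) is flagged in :data:`FITTED_PARAMS`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["ParameterSet", "FITTED_PARAMS", "PARAM_NAMES"]

#: Parameters estimated by the genetic fit (the remainder are inherited from
#: the parent 35-ODE model or fixed by construction).
FITTED_PARAMS: tuple[str, ...] = (
    "R0",
    "k2",
    "k_minus2",
    "k_exp_act",
    "k_exp",
    "k_imp_act",
    "k_imp",
    "k_mek",
    "K_MM_MEK",
    "MEK_tot",
)

# Fields that must be strictly positive (Michaelis constants, volumes);
# everything else numeric only needs to be non-negative.
_STRICTLY_POSITIVE = (
    "K_MM_MEK",
    "km_1",
    "km_2",
    "km_3",
    "km_4",
    "km_5",
    "kd_ppEn",
    "K_MM_TF1",
    "K_MM_TF1DT",
    "C_cn",
)


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants, totals, and compartment geometry of the cascade.

    Attributes
    ----------
    R0 : total GnRH receptor concentration, uM.
    k1, k_minus1 : GnRH-receptor association (uM^-1 min^-1) / dissociation
        (min^-1); their ratio sets the receptor Kd of 1 nM.
    k2, k_minus2 : occupied-receptor/G-protein coupling (uM^-1 min^-1) and
        free G-protein pool recovery (min^-1).
    k3, k_minus3 : negative-feedback rate of active ERK on the effector
        (uM^-1 min^-1) and first-order effector deactivation (min^-1).
    GQ_tot : total G-protein pool, uM.
    k_exp_act, k_exp, k_imp_act, k_imp : nuclear export/import rate constants
        (min^-1) for active (pp) and inactive ERK respectively.
    k_mek, K_MM_MEK, k_MEK_basal, MEK_tot : parameters of the algebraic
        Michaelis-Menten MEK-activation step.
    ERK_tot : total ERK, uM, referenced to cytoplasmic volume.
    kcat_1..kcat_5, km_1..km_5, kd_ppEn : catalytic and Michaelis constants
        of the distributive dual-(de)phosphorylation fluxes v1-v5.
    MKP_n, MKP_c : nuclear / cytosolic MAPK-phosphatase concentrations, uM.
    C_cn : cytoplasm-to-nucleus volume ratio (dimensionless).
    d_TF1, k_TF1, K_MM_TF1, d_TF1DT, k_TF1DT, K_MM_TF1DT : transcription-tier
        activation/degradation constants.
    feedback_target : which active-ERK pool drives the negative feedback on
        the effector, ``"ppE_c"`` (default) or ``"ppE_n"``.
    """

    R0: float = 0.1
    k1: float = 5000.0
    k_minus1: float = 5.0
    k2: float = 5.0
    k_minus2: float = 1.0
    k3: float = 5.5
    k_minus3: float = 0.05
    GQ_tot: float = 1.0
    k_exp_act: float = 0.75
    k_exp: float = 0.75
    k_imp_act: float = 0.4
    k_imp: float = 0.2
    k_mek: float = 10.0
    K_MM_MEK: float = 0.05
    k_MEK_basal: float = 0.0
    ERK_tot: float = 0.9
    MEK_tot: float = 0.6
    kcat_1: float = 0.6
    kcat_2: float = 5.0
    kcat_3: float = 4.0
    kcat_4: float = 4.0
    kcat_5: float = 4.0
    km_1: float = 0.05
    km_2: float = 0.0339
    km_3: float = 0.022
    km_4: float = 0.0180
    km_5: float = 0.0782
    kd_ppEn: float = 0.01
    MKP_n: float = 0.05
    MKP_c: float = 0.05
    C_cn: float = 3.0
    d_TF1: float = 0.023
    k_TF1: float = 0.03
    K_MM_TF1: float = 0.4
    d_TF1DT: float = 0.05
    k_TF1DT: float = 0.03
    K_MM_TF1DT: float = 0.5
    feedback_target: str = "ppE_c"

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"parameter {name!r} is not finite: {value}")
            if name in _STRICTLY_POSITIVE:
                if value <= 0:
                    raise ValueError(f"parameter {name!r} must be > 0, got {value}")
            elif value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value}")
        if self.feedback_target not in ("ppE_c", "ppE_n"):
            raise ValueError(
                "feedback_target must be 'ppE_c' or 'ppE_n', "
                f"got {self.feedback_target!r}"
            )

    # -- dict / array views ------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        """Numeric parameters as a flat name -> value mapping."""
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_dict(cls, values: dict[str, float], **kwargs) -> "ParameterSet":
        unknown = set(values) - set(PARAM_NAMES) - {"feedback_target"}
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**values, **kwargs)

    def to_array(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        """Numeric parameters as a vector, in ``names`` order (default: all)."""
        names = PARAM_NAMES if names is None else names
        return np.array([getattr(self, n) for n in names], dtype=float)

    def fitted_values(self) -> np.ndarray:
        return self.to_array(FITTED_PARAMS)

    def with_fitted_values(self, values: np.ndarray) -> "ParameterSet":
        return self.replace(**dict(zip(FITTED_PARAMS, map(float, values))))

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())


#: Ordered numeric parameter names (excludes the feedback_target switch).
PARAM_NAMES: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(ParameterSet) if f.name != "feedback_target"
)
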