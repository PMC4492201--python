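"""Logistic dose-response model for 1-year overall survival under
chemoradiation.

Radiotherapy-attributable survival follows a logistic curve in BED,

    RS(BED) = 1 / (1 + exp[4 gamma50 (1 - BED/D50)]),

with gamma50 the normalized dose-response gradient and D50 the BED giving 50%
1-year survival under radiotherapy alone. Chemotherapy contributes an
independent, purely additive survival CS, so the combined 1-year overall
survival is

    OS = CS + RS (1 - CS)
       = (1 + CS exp[4 gamma50 (1 - BED/D50)]) / (1 + exp[4 gamma50 (1 - BED/D50)]).

Both forms are implemented (they are algebraically identical) so that the
closed form can be verified against the composition. The inverse of the RS
curve gives the *chemo-equivalent BED*: the radiation-alone BED that would
match a given survival level,

    BED = D50 [1 - ln((1 - RS)/RS) / (4 gamma50)].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .trial_data import ValidationError

__all__ = [
    "ModelParameters",
    "radiotherapy_survival",
    "combine_os",
    "overall_survival",
    "chemo_equivalent_bed",
    "bed_for_overall_survival",
]

# exponent clip keeping exp() finite in float64
_XMAX = 700.0


@dataclass(frozen=True)
class ModelParameters:
    """A fitted (or assumed) survival curve: gamma50, D50 and chemo survival CS.

    ``d50`` is in Gy for X-ray curves and Gy(RBE) for charged-particle curves;
    ``cs = 0`` describes radiotherapy alone.
    """

    gamma50: float
    d50: float
    cs: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma50 <= 0:
            raise ValidationError("gamma50 must be strictly positive")
        if self.d50 <= 0:
            raise ValidationError("d50 must be strictly positive")
        if not 0.0 <= self.cs < 1.0:
            raise ValidationError("cs must lie in [0, 1)")


def _exponent(bed, params: ModelParameters):
    return 4.0 * params.gamma50 * (1.0 - np.asarray(bed, dtype=float) / params.d50)


def radiotherapy_survival(bed, params: ModelParameters):
    """1-year survival attributable to radiotherapy alone at a given BED."""
    if np.any(np.asarray(bed) < 0):
        raise ValidationError("bed must be non-negative")
    # expit(-x) = 1/(1+e^x), numerically stable for large |x|
    out = expit(-_exponent(bed, params))
    return out if out.ndim else float(out)


def combine_os(cs, rs):
    """Additive combination of independent chemo and radiotherapy survival."""
    cs = np.asarray(cs, dtype=float)
    rs = np.asarray(rs, dtype=float)
    if np.any((cs < 0) | (cs > 1)) or np.any((rs < 0) | (rs > 1)):
        raise ValidationError("cs and rs must lie in [0, 1]")
    out = cs + rs * (1.0 - cs)
    return out if out.ndim else float(out)


def overall_survival(bed, params: ModelParameters):
    """Combined 1-year overall survival (closed logistic form)."""
    if np.any(np.asarray(bed) < 0):
        raise ValidationError("bed must be non-negative")
    x = np.clip(_exponent(bed, params), -_XMAX, _XMAX)
    ex = np.exp(x)
    out = (1.0 + params.cs * ex) / (1.0 + ex)
    return out if out.ndim else float(out)


def chemo_equivalent_bed(rs_target: float, params: ModelParameters) -> float:
    """BED at which radiotherapy alone reaches survival ``rs_target``.

    Exact inverse of :func:`radiotherapy_survival`.
    """
    if not 0.0 < rs_target < 1.0:
        raise ValidationError("rs_target must lie strictly inside (0, 1)")
    return params.d50 * (
        1.0 - np.log((1.0 - rs_target) / rs_target) / (4.0 * params.gamma50)
    )


def bed_for_overall_survival(os_target: float, params: ModelParameters) -> float:
    """BED at which the combined model reaches overall survival ``os_target``.

    The attainable range is (cs, 1); targets outside it raise.
    """
    if not params.cs < os_target < 1.0:
        raise ValidationError(
            f"os_target must lie in ({params.cs}, 1); got {os_target}"
        )
    rs = (os_target - params.cs) / (1.0 - params.cs)
    return chemo_equivalent_bed(rs, params)
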