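"""Radiobiological models: EQD2, gEUD, LKB NTCP and organ-specific models.

Four forward NTCP models are provided, one per functional organ at risk in a
craniospinal-irradiation evaluation:

* hippocampus — LKB probit on the EQD2 of D40% (neurocognitive impairment),
* scalp — LKB probit on gEUD with volume exponent n (acute grade-2 alopecia),
* hypothalamic-pituitary axis — multivariate parametric time-to-event model
  (endocrine dysfunction),
* cochlea — logistic regression on the median cochlear dose (hearing loss).

All models are forward-evaluation only; no parameter fitting is performed.
Default parameter sets ship in ``data/ntcp_params.yaml`` and can be
overridden from any YAML/JSON registry keyed by organ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .dvh import CumulativeDVH

__all__ = ["FractionationScheme", "LKBParams", "EndocrineParams",
           "LogisticParams", "TCPParams", "load_param_registry",
           "eqd2", "geud", "lkb_ntcp", "hippocampal_ntcp", "scalp_ntcp",
           "endocrine_ntcp", "cochlear_ntcp", "ptv_eud_tcp"]


@dataclass(frozen=True)
class FractionationScheme:
    """Fraction number and tissue alpha/beta ratio for LQ conversions."""

    n_fractions: int
    alpha_beta_Gy: float

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.alpha_beta_Gy <= 0:
            raise ValueError("alpha/beta must be positive")


@dataclass(frozen=True)
class LKBParams:
    """LKB probit parameters: TD50 (Gy), slope m, volume exponent n."""

    TD50_Gy: float
    m: float
    n: float | None = None

    def __post_init__(self) -> None:
        if self.TD50_Gy <= 0:
            raise ValueError("TD50 must be positive")
        if self.m <= 0:
            raise ValueError("m must be positive")


@dataclass(frozen=True)
class EndocrineParams:
    """Multivariate parametric endocrine-dysfunction model parameters.

    ``t_years`` is post-treatment follow-up time; the beta coefficients act
    on age at treatment (years), age squared, and the mean of the D50% of
    hypothalamus and pituitary (Gy).
    """

    gamma: float = 0.56
    const: float = 3.13
    beta_age: float = -0.106
    beta_age2: float = 0.007
    beta_dose: float = -0.049
    t_years: float = 5.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.t_years < 0:
            raise ValueError("follow-up time must be non-negative")


@dataclass(frozen=True)
class LogisticParams:
    """Logistic dose-response coefficients (intercept b0, slope b1)."""

    b0: float = -5.3
    b1: float = 0.085


@dataclass(frozen=True)
class TCPParams:
    """Tumor EUD/TCP parameters; must be supplied explicitly by config."""

    eud_exponent_a: float
    TCD50_Gy: float
    gamma50: float

    def __post_init__(self) -> None:
        if self.TCD50_Gy <= 0:
            raise ValueError("TCD50 must be positive")
        if self.eud_exponent_a == 0:
            raise ValueError("EUD exponent a must be non-zero")


_DEFAULTS = {
    "hippocampus": LKBParams(TD50_Gy=14.88, m=0.54),
    "scalp": LKBParams(TD50_Gy=22.0, m=0.54, n=0.14),
    "hpa": EndocrineParams(),
    "cochlea": LogisticParams(),
}


def load_param_registry(path: str | Path | None = None) -> dict:
    """Load the per-organ NTCP parameter registry.

    With no ``path`` the packaged default registry is used. The file is YAML
    (JSON is a YAML subset) keyed by organ, each entry carrying ``model``
    (lkb / endocrine / logistic / tcp) and its parameters.
    """
    if path is None:
        text = resources.files("csieval").joinpath("data/ntcp_params.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    ctor = {"lkb": LKBParams, "endocrine": EndocrineParams,
            "logistic": LogisticParams, "tcp": TCPParams}
    registry = {}
    for organ, entry in raw.items():
        entry = dict(entry)
        model = entry.pop("model")
        registry[organ] = ctor[model](**entry)
    return registry


def eqd2(total_dose_Gy: float, scheme: FractionationScheme) -> float:
    """Equivalent dose in 2-Gy fractions under the linear-quadratic model.

    With per-fraction dose d = D / n_fractions:
    ``EQD2 = D * (d + a/b) / (2 + a/b)``. A schedule already delivering
    2 Gy/fraction is a fixed point for any alpha/beta.
    """
    if total_dose_Gy < 0:
        raise ValueError("dose must be non-negative")
    d = total_dose_Gy / scheme.n_fractions
    ab = scheme.alpha_beta_Gy
    return total_dose_Gy * (d + ab) / (2.0 + ab)


def geud(dvh: CumulativeDVH, n: float) -> float:
    """Generalized equivalent uniform dose: ``(sum_i v_i d_i^(1/n))^n``.

    ``n`` is the volume-effect exponent (n=1 gives the mean dose; n -> 0+
    approaches the maximum dose). The differential subvolumes v_i are the
    equal per-voxel weights of the bin-free DVH.
    """
    if n == 0:
        raise ValueError("n must be non-zero; use the max dose for the n->0 limit")
    d = dvh.doses_Gy
    a = 1.0 / n
    if np.all(d == 0):
        return 0.0
    # power mean computed in log space via the max for numerical stability
    dmax = d.max()
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, d / dmax, 0.0)
    return float(dmax * np.mean(ratio ** a) ** n)


def lkb_ntcp(effective_dose_Gy: float, params: LKBParams) -> float:
    """LKB probit NTCP: standard-normal CDF of (D_eff - TD50)/(m TD50)."""
    if effective_dose_Gy < 0:
        raise ValueError("effective dose must be non-negative")
    t = (effective_dose_Gy - params.TD50_Gy) / (params.m * params.TD50_Gy)
    return 0.5 * (1.0 + math.erf(t / math.sqrt(2.0)))


def hippocampal_ntcp(d40_total_Gy: float,
                     scheme: FractionationScheme | None = None,
                     params: LKBParams | None = None) -> float:
    """Neurocognitive-impairment NTCP from the hippocampal D40%.

    The D40% is converted to EQD2 (alpha/beta 2 Gy by default) and fed to
    the LKB probit with TD50 = 14.88 Gy, m = 0.54.
    """
    scheme = scheme or FractionationScheme(13, 2.0)
    params = params or _DEFAULTS["hippocampus"]
    return lkb_ntcp(eqd2(d40_total_Gy, scheme), params)


def scalp_ntcp(dvh: CumulativeDVH, params: LKBParams | None = None) -> float:
    """Acute grade-2 alopecia NTCP from the scalp DVH via gEUD (n = 0.14)."""
    params = params or _DEFAULTS["scalp"]
    n = params.n if params.n is not None else 0.14
    return lkb_ntcp(geud(dvh, n), params)


def endocrine_ntcp(hypothalamus_d50_Gy: float, pituitary_d50_Gy: float,
                   age_years: float,
                   params: EndocrineParams | None = None) -> float:
    """Endocrine-dysfunction NTCP from HPA dose, age and follow-up time.

    dose = mean of the hypothalamus and pituitary D50%;
    phi = exp(-(const + b_age*age + b_age2*age^2 + b_dose*dose));
    NTCP = 1 - 1 / (1 + (phi * t)^(1/gamma)).
    """
    params = params or _DEFAULTS["hpa"]
    if hypothalamus_d50_Gy < 0 or pituitary_d50_Gy < 0:
        raise ValueError("doses must be non-negative")
    if age_years <= 0:
        raise ValueError("age must be positive")
    dose = 0.5 * (hypothalamus_d50_Gy + pituitary_d50_Gy)
    phi = math.exp(-(params.const + params.beta_age * age_years
                     + params.beta_age2 * age_years ** 2
                     + params.beta_dose * dose))
    x = phi * params.t_years
    if x == 0.0:
        return 0.0
    return 1.0 - 1.0 / (1.0 + x ** (1.0 / params.gamma))


def cochlear_ntcp(median_dose_Gy: float,
                  params: LogisticParams | None = None) -> float:
    """Hearing-loss NTCP: logistic model on the median cochlear dose."""
    params = params or _DEFAULTS["cochlea"]
    if median_dose_Gy < 0:
        raise ValueError("dose must be non-negative")
    z = params.b0 + params.b1 * median_dose_Gy
    return 1.0 / (1.0 + math.exp(-z))


def ptv_eud_tcp(dvh: CumulativeDVH, params: TCPParams | None) -> tuple[float, float]:
    """Tumor EUD and TCP from a target DVH.

    EUD is the gEUD with tumor exponent a (n = 1/a); TCP uses the logistic
    form ``1 / (1 + (TCD50 / EUD)^(4 gamma50))``. Parameters carry no
    defaults and must come from configuration.
    """
    if params is None:
        raise ValueError(
            "TCP parameters (eud_exponent_a, TCD50_Gy, gamma50) are not built in; "
            "supply a TCPParams instance or a 'tcp' registry entry")
    eud = geud(dvh, 1.0 / params.eud_exponent_a)
    tcp = 1.0 / (1.0 + (params.TCD50_Gy / eud) ** (4.0 * params.gamma50))
    return eud, tcp
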