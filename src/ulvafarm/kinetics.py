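"""Thallus-scale rate laws: limitation factors, growth, losses and N uptake.

All functions are pure and accept scalars or NumPy arrays (broadcasting),
so the reactor and farm integrators can evaluate them over whole reactor
rows in one call.

The combined growth function follows Liebig's law of the minimum over the
resource factors (internal N, internal P — fixed at 1 here — and light),
scaled by the temperature and salinity factors:

    μ = μ_max · f_Temp(T) · f_S(S) · min{f_N_int, f_P_int, f_I}

Nitrogen uptake is Michaelis–Menten in the dissolved concentration with a
linear cell-quota feedback (Droop concept): uptake vanishes as the internal
store fills and saturates at V_max when the store is empty and N is replete.
"""

from __future__ import annotations

import numpy as np

from .params import GrowthParameters

__all__ = [
    "temperature_factor",
    "salinity_factor",
    "light_factor_local",
    "internal_nitrogen_factor",
    "combined_growth_factor",
    "specific_loss_rate",
    "uptake_rate",
]

# f_P_int is not modelled (N-limited environments only); it holds the Liebig
# min() slot so a phosphorus quota model can plug in later.
F_P_INT: float = 1.0


def temperature_factor(T, p: GrowthParameters):
    """Temperature limitation f_Temp(T) ∈ [0, 1].

    Beta-type response: with u = (T_max − T)/(T_max − T_opt),

        f_Temp = [u · exp(1 − u)]**n

    equal to 1 at T = T_opt, 0 at T ≥ T_max (clamped, growth factors are
    fractions), unimodal, with the shape exponent n controlling how sharply
    the response falls away from the optimum.
    """
    T = np.asarray(T, dtype=float)
    u = (p.T_max - T) / (p.T_max - p.T_opt)
    u = np.clip(u, 0.0, None)
    f = np.power(u * np.exp(1.0 - u), p.n)
    return f if f.ndim else float(f)


def salinity_factor(S, p: GrowthParameters):
    """Salinity limitation f_S(S) ∈ [0, 1].

    Gaussian around the optimum S_opt with tolerance width S_sigma;
    symmetric, maximal (= 1) at S = S_opt.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("salinity must be non-negative")
    f = np.exp(-(((S - p.S_opt) / p.S_sigma) ** 2))
    return f if f.ndim else float(f)


def light_factor_local(I, p: GrowthParameters):
    """Light limitation f_I ∈ [0, par_fraction]: Monod × PAR.

        f(I) = I / (K_I + I) · PAR

    I is the irradiance the thalli experience (the reactor-average value
    once self-shading is accounted for). The factor saturates at the PAR
    fraction (0.43), not at 1.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("irradiance must be non-negative")
    f = I / (p.K_I + I) * p.par_fraction
    return f if f.ndim else float(f)


def internal_nitrogen_factor(N_int, p: GrowthParameters):
    """Internal-N (cell quota) limitation f_N_int ∈ [0, 1].

    Normalized Droop form:

        f = (1 − N_int_min / N_int) / (1 − N_int_min / N_int_max)

    0 at the subsistence quota N_int_min, 1 at the storage quota N_int_max,
    monotone increasing in between. Below the critical quota N_int_crit the
    factor is already small, which is where internal N starts to control
    model outcomes.
    """
    N_int = np.asarray(N_int, dtype=float)
    if np.any(N_int < p.N_int_min - 1e-12) or np.any(N_int > p.N_int_max + 1e-12):
        raise ValueError("N_int outside quota bounds [N_int_min, N_int_max]")
    N_int = np.clip(N_int, p.N_int_min, p.N_int_max)
    f = (1.0 - p.N_int_min / N_int) / (1.0 - p.N_int_min / p.N_int_max)
    return f if f.ndim else float(f)


def combined_growth_factor(T, S, I_eff, N_int, p: GrowthParameters):
    """Combined growth function f = f_Temp · f_S · min{f_N_int, f_P_int, f_I}.

    I_eff is the effective (reactor-averaged) irradiance. The resource
    factors compete under Liebig's law of the minimum; temperature and
    salinity scale the result multiplicatively. Result in [0, 1].
    """
    f_res = np.minimum(
        np.minimum(internal_nitrogen_factor(N_int, p), F_P_INT),
        light_factor_local(I_eff, p),
    )
    f = temperature_factor(T, p) * salinity_factor(S, p) * f_res
    arr = np.asarray(f)
    return f if arr.ndim else float(arr)


def specific_loss_rate(T, p: GrowthParameters):
    """Biomass specific loss rate λ(T) = λ20 · θ**(T − 20), h⁻¹.

    λ20 is the loss rate at the 20 °C reference; θ is the empiric
    temperature factor (θ = 1 makes losses temperature-independent). Losses
    by grazing, sporulation and storm fragmentation are not included.
    """
    T = np.asarray(T, dtype=float)
    lam = p.lambda_20 * np.power(p.theta, T - 20.0)
    return lam if lam.ndim else float(lam)


def uptake_rate(N_int, N_ext, p: GrowthParameters):
    """Nitrogen uptake ψ(N_int, N_ext), μmol-N gDW⁻¹ h⁻¹.

        ψ = (N_int_max − N_int)/(N_int_max − N_int_min) · V_max·N_ext/(K_S + N_ext)

    Michaelis–Menten in the dissolved concentration, linearly down-regulated
    as the internal quota fills; bounded by V_max.
    """
    N_int = np.asarray(N_int, dtype=float)
    N_ext = np.asarray(N_ext, dtype=float)
    if np.any(N_ext < 0):
        raise ValueError("N_ext must be non-negative")
    if np.any(N_int < p.N_int_min - 1e-12) or np.any(N_int > p.N_int_max + 1e-12):
        raise ValueError("N_int outside quota bounds [N_int_min, N_int_max]")
    N_int = np.clip(N_int, p.N_int_min, p.N_int_max)
    quota = (p.N_int_max - N_int) / (p.N_int_max - p.N_int_min)
    psi = quota * p.V_max * N_ext / (p.K_S + N_ext)
    return psi if psi.ndim else float(psi)
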