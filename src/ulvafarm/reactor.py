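"""Reactor-scale model: self-shading light averaging and hourly mass balance.

One cage reactor is well mixed, so the irradiance driving growth is the
depth- and biomass-averaged value (Beer–Lambert extinction through water and
through the algal canopy). The state triple (m, N_int, N_ext) advances by
forward Euler at hourly steps, matching the model's native resolution;
growth, biomass losses and quota dilution act only during light hours,
while N uptake and pump-driven water exchange run around the clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kinetics import (
    combined_growth_factor,
    specific_loss_rate,
    uptake_rate,
)
from .params import (
    QUOTA_PER_UMOL,
    EnvironmentSample,
    GrowthParameters,
    PumpSetting,
    ReactorGeometry,
)

__all__ = [
    "ReactorState",
    "stocking_density",
    "average_irradiance",
    "reactor_step",
    "simulate_reactor",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReactorState:
    """Per-reactor state: biomass density m (gDW l⁻¹), internal quota
    N_int (% gN gDW⁻¹), dissolved N in the cage N_ext (μmol-N l⁻¹)."""

    m: float
    N_int: float
    N_ext: float

    def validate(self, p: GrowthParameters) -> "ReactorState":
        if self.m < 0:
            raise ValueError("biomass density m must be non-negative")
        if not p.N_int_min - 1e-9 <= self.N_int <= p.N_int_max + 1e-9:
            raise ValueError("N_int outside quota bounds")
        if self.N_ext < 0:
            raise ValueError("N_ext must be non-negative")
        return self


def stocking_density(m, g: ReactorGeometry):
    """Stocking density SD (gDW m⁻²) per unit illuminated surface.

    SD = m · 1000 · V_cage / illuminated_area  (m in gDW l⁻¹).
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("m must be non-negative")
    sd = m * g.volume_l / g.illuminated_area
    return sd if sd.ndim else float(sd)


def average_irradiance(I0, SD, g: ReactorGeometry, p: GrowthParameters):
    """Biomass-averaged irradiance in a mixed reactor (Beer–Lambert).

        I_avg = I0 / (K_0·Z + K_a·SD) · [1 − exp(−(K_0·Z + K_a·SD))]

    Tends to I0 as the optical depth K_0·Z + K_a·SD → 0 (series limit used
    below a small-argument threshold); strictly decreasing in SD.
    """
    I0 = np.asarray(I0, dtype=float)
    SD = np.asarray(SD, dtype=float)
    if np.any(I0 < 0) or np.any(SD < 0):
        raise ValueError("I0 and SD must be non-negative")
    x = p.K_0 * g.Z + p.K_a * SD
    x = np.asarray(x, dtype=float)
    small = x < 1e-9
    safe = np.where(small, 1.0, x)
    # -expm1(-x)/x is (1 - e^-x)/x computed stably; -> 1 - x/2 for small x
    frac = np.where(small, 1.0 - x / 2.0, -np.expm1(-safe) / safe)
    out = I0 * frac
    return out if out.ndim else float(out)


def _step_arrays(
    m,
    N_int,
    N_ext,
    N_env_local,
    env: EnvironmentSample,
    Q_p: float,
    g: ReactorGeometry,
    p: GrowthParameters,
    dt: float,
):
    """Vectorized forward-Euler update of (m, N_int, N_ext) over one step.

    Arrays broadcast over reactors. Returns the updated arrays plus the
    number of state entries clamped back into their physical bounds.
    """
    m = np.asarray(m, dtype=float)
    N_int = np.asarray(N_int, dtype=float)
    N_ext = np.asarray(N_ext, dtype=float)
    N_env_local = np.asarray(N_env_local, dtype=float)

    psi = uptake_rate(N_int, N_ext, p)  # μmol-N gDW⁻¹ h⁻¹, runs all 24 h

    if env.is_light_hour:
        SD = stocking_density(m, g)
        I_avg = average_irradiance(env.I0, SD, g, p)
        f = combined_growth_factor(env.T, env.S, I_avg, N_int, p)
        mu = p.mu_max * np.asarray(f, dtype=float)
        lam = specific_loss_rate(env.T, p)
    else:
        mu = np.zeros_like(m)
        lam = 0.0

    m_new = m + (mu - lam) * m * dt
    N_int_new = N_int + (psi * QUOTA_PER_UMOL - N_int * mu) * dt
    N_ext_new = N_ext + (Q_p * (N_env_local - N_ext) / g.volume_l - psi * m) * dt

    clamped = int(np.sum(N_int_new < p.N_int_min) + np.sum(N_int_new > p.N_int_max)
                  + np.sum(N_ext_new < 0.0) + np.sum(m_new < 0.0))
    m_new = np.clip(m_new, 0.0, None)
    N_int_new = np.clip(N_int_new, p.N_int_min, p.N_int_max)
    N_ext_new = np.clip(N_ext_new, 0.0, None)
    return m_new, N_int_new, N_ext_new, clamped


def reactor_step(
    state: ReactorState,
    N_env_local: float,
    env: EnvironmentSample,
    pump: PumpSetting,
    g: ReactorGeometry,
    p: GrowthParameters,
    dt: float = 1.0,
) -> ReactorState:
    """Advance one reactor by one explicit-Euler step of length dt hours.

    During light hours: dm/dt = (μ − λ)·m with μ = μ_max·f evaluated at the
    biomass-averaged irradiance of the current stocking density, and the
    quota is diluted by growth, dN_int/dt ∋ −N_int·μ. Uptake
    (ψ, converted μmol → % gN gDW⁻¹) and pump exchange
    Q_p·(N_env − N_ext)/V_cage run every hour. Post-state invariants are
    enforced by clamping (with a logged warning): Euler overshoot near the
    quota bounds is expected, not an error.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.validate(p)
    if N_env_local < 0:
        raise ValueError("N_env_local must be non-negative")
    m, N_int, N_ext, clamped = _step_arrays(
        state.m, state.N_int, state.N_ext, N_env_local, env, pump.Q_p, g, p, dt
    )
    if clamped:
        logger.warning("reactor_step clamped %d state value(s) to bounds", clamped)
    return ReactorState(float(m), float(N_int), float(N_ext))


def simulate_reactor(
    state: ReactorState,
    forcing,
    pump: PumpSetting,
    g: ReactorGeometry,
    p: GrowthParameters,
    N_env_local: float | None = None,
    substeps: int = 1,
    record: bool = False,
):
    """Integrate a single reactor over an hourly forcing table.

    ``forcing`` is a ForcingSeries (or any object with ``.frame`` holding
    columns T, S, I0, is_light, N_up). The ambient concentration seen by the
    pump is ``N_env_local`` when given, otherwise the forcing's upstream-N
    column (held constant within each hour). ``substeps`` refines the Euler
    step to dt = 1/substeps h with forcing frozen within the hour — the
    fine-step reference used to bound discretization error.

    Returns the final ReactorState, or (final_state, trajectory DataFrame)
    when ``record`` is true.
    """
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    frame = forcing.frame if hasattr(forcing, "frame") else forcing
    dt = 1.0 / substeps
    m, N_int, N_ext = state.m, state.N_int, state.N_ext
    rows = []
    clamped_total = 0
    T_arr = frame["T"].to_numpy(dtype=float)
    S_arr = frame["S"].to_numpy(dtype=float)
    I_arr = frame["I0"].to_numpy(dtype=float)
    L_arr = frame["is_light"].to_numpy(dtype=bool)
    N_up = frame["N_up"].to_numpy(dtype=float)
    for i in range(len(frame)):
        env = EnvironmentSample(
            T=float(T_arr[i]), S=float(S_arr[i]),
            I0=float(I_arr[i]) if L_arr[i] else 0.0,
            is_light_hour=bool(L_arr[i]),
        )
        amb = float(N_up[i]) if N_env_local is None else float(N_env_local)
        for _ in range(substeps):
            m, N_int, N_ext, c = _step_arrays(
                m, N_int, N_ext, amb, env, pump.Q_p, g, p, dt
            )
            clamped_total += c
        if record:
            rows.append((frame.index[i], float(m), float(N_int), float(N_ext)))
    if clamped_total:
        logger.warning(
            "simulate_reactor clamped %d state value(s) to bounds", clamped_total
        )
    final = ReactorState(float(m), float(N_int), float(N_ext))
    if record:
        import pandas as pd

        traj = pd.DataFrame(rows, columns=["time", "m", "N_int", "N_ext"])
        traj = traj.set_index("time")
        return final, traj
    return final
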