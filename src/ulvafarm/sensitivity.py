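"""Variance-based global sensitivity analysis of the farm model.

Saltelli cross-sampling generates N·(2k + 2) parameter combinations for k
parameters and base sample size N (blocks A, B, AB_i, BA_i, where AB_i is
A with column i taken from B). Each combination is run through the farm
simulation, and the Sobol first-order (S1) and total (ST) indices are
estimated per parameter and per output quantity with the Saltelli-2010 /
Jansen estimators. Negative estimates are reported raw (they are
Monte-Carlo noise around small true indices); a clipped view is available
for summary tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .farm import FarmConfig, run_cycle
from .forcing import SEASON_STARTS, SyntheticForcingSpec, generate_synthetic_forcing, seasonal_spec
from .params import GrowthParameters, PumpSetting

__all__ = [
    "SimulationFrame",
    "SensitivityProblem",
    "SensitivityResult",
    "default_problem",
    "saltelli_sample",
    "evaluate_batch",
    "sobol_indices",
    "make_farm_evaluator",
    "OUTPUT_NAMES",
]

logger = logging.getLogger(__name__)

OUTPUT_NAMES = ("total_biomass_gDW", "total_n_removed_gN", "mean_final_N_env_uM")


@dataclass(frozen=True)
class SimulationFrame:
    """Simulation frame for the analysis: a 100-reactor farm run for one
    cultivation cycle per season."""

    n_reactors: int = 100
    seasons: tuple[str, ...] = ("winter", "spring", "summer", "autumn")
    cycle_length: int = 14


@dataclass(frozen=True)
class SensitivityProblem:
    """Parameter names, [low, high] ranges, base sample size and seed."""

    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    base_n: int = 16
    seed: int = 0
    frame: SimulationFrame = field(default_factory=SimulationFrame)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.bounds):
            raise ValueError("names and bounds must have equal length")
        if len(self.names) == 0:
            raise ValueError("need at least one parameter")
        for name, (lo, hi) in zip(self.names, self.bounds):
            if not lo < hi:
                raise ValueError(f"invalid range for {name}: [{lo}, {hi}]")
        if self.base_n < 2:
            raise ValueError("base sample size must be >= 2")

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def n_rows(self) -> int:
        return self.base_n * (2 * self.k + 2)


def default_problem(base_n: int = 16, seed: int = 0,
                    frame: SimulationFrame | None = None) -> SensitivityProblem:
    """All model parameters over literature-plausible ranges, plus the
    environmental dilution ratio d."""
    names_bounds = [
        ("mu_max", (0.01, 0.05)),
        ("K_I", (10.0, 100.0)),
        ("T_opt", (14.0, 22.0)),
        ("T_max", (28.0, 35.0)),
        ("n", (1.0, 4.0)),
        ("lambda_20", (0.0005, 0.005)),
        ("theta", (1.0, 1.1)),
        ("K_a", (0.01, 0.3)),
        ("K_0", (0.2, 2.0)),
        ("V_max", (20.0, 100.0)),
        ("K_S", (2.0, 20.0)),
        ("d", (0.0, 0.05)),
    ]
    return SensitivityProblem(
        names=tuple(n for n, _ in names_bounds),
        bounds=tuple(b for _, b in names_bounds),
        base_n=base_n,
        seed=seed,
        frame=frame or SimulationFrame(),
    )


def saltelli_sample(problem: SensitivityProblem) -> np.ndarray:
    """Saltelli cross-sampling design: N·(2k + 2) rows, k columns.

    Row layout (blocks of N): A, B, AB_1..AB_k, BA_1..BA_k. A and B come
    from a scrambled Sobol' sequence in 2k dimensions scaled to the
    parameter ranges; the design is deterministic under the problem seed.
    """
    k, N = problem.k, problem.base_n
    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=problem.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # N need not be 2**m
        base = sampler.random(N)
    lo = np.array([b[0] for b in problem.bounds])
    hi = np.array([b[1] for b in problem.bounds])
    A = lo + base[:, :k] * (hi - lo)
    B = lo + base[:, k:] * (hi - lo)
    blocks = [A, B]
    for i in range(k):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
    for i in range(k):
        BA = B.copy()
        BA[:, i] = A[:, i]
        blocks.append(BA)
    return np.vstack(blocks)


def make_farm_evaluator(
    base_params: GrowthParameters | None = None,
    base_cfg: FarmConfig | None = None,
    frame: SimulationFrame | None = None,
    forcing_spec: SyntheticForcingSpec | None = None,
):
    """Build the model evaluator: parameter dict → 3 output quantities.

    Outputs are total biomass produced (gDW), total N removed into biomass
    (gN) and the mean final ambient N (μM), accumulated over one cycle per
    season on the frame's farm. Names matching GrowthParameters fields
    override the kinetic constants; ``d`` and ``Q_p`` override the farm
    dilution ratio and pump flow. Seasonal forcing is generated once and
    shared across evaluations, so rows are independent and results match a
    serial loop exactly.
    """
    base_params = base_params or GrowthParameters()
    frame = frame or SimulationFrame()
    cfg0 = (base_cfg or FarmConfig()).replace(
        n_reactors=frame.n_reactors, cycle_length=frame.cycle_length
    )
    forcings = {}
    for season in frame.seasons:
        start, spec = seasonal_spec(season, forcing_spec)
        forcings[season] = (
            generate_synthetic_forcing(spec, start=start, days=frame.cycle_length),
            spec.N_up,
        )
    growth_names = set(GrowthParameters.field_names())

    def evaluate(sample: dict[str, float]) -> np.ndarray:
        kin = {k: v for k, v in sample.items() if k in growth_names}
        p = base_params.replace(**kin)
        cfg = cfg0
        if "d" in sample:
            cfg = cfg.replace(d=float(sample["d"]))
        if "Q_p" in sample:
            cfg = cfg.replace(pump=PumpSetting(float(sample["Q_p"])))
        total_b = total_n = 0.0
        final_envs = []
        for season in frame.seasons:
            forcing, n_level = forcings[season]
            season_cfg = cfg.replace(N_env0=n_level, N_ext0=None)
            _, summary = run_cycle(season_cfg, forcing, p)
            total_b += summary.total_production
            total_n += summary.total_n_removed
            final_envs.append(summary.final_N_env.mean())
        return np.array([total_b, total_n, float(np.mean(final_envs))])

    return evaluate


def evaluate_batch(
    design: np.ndarray,
    problem: SensitivityProblem,
    evaluator=None,
) -> np.ndarray:
    """Run every design row through the model; returns (rows, 3) outputs.

    Rows are evaluated independently; a failing simulation is recorded as
    NaN for that row (and logged) rather than aborting the batch.
    """
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[1] != problem.k:
        raise ValueError("design shape does not match the problem")
    evaluator = evaluator or make_farm_evaluator(frame=problem.frame)
    out = np.full((len(design), len(OUTPUT_NAMES)), np.nan)
    for i, row in enumerate(design):
        sample = dict(zip(problem.names, row))
        try:
            out[i] = evaluator(sample)
        except Exception:  # noqa: BLE001 - per-row failures are recorded
            logger.warning("simulation failed for design row %d", i, exc_info=True)
    return out


@dataclass(frozen=True)
class SensitivityResult:
    """First-order and total Sobol indices per parameter per output."""

    table: pd.DataFrame  # columns: parameter, output, S1, ST, S1_conf, ST_conf
    base_n: int
    seed: int

    @property
    def clipped(self) -> pd.DataFrame:
        """Indices clipped into [0, 1] for reporting; raw values retained
        in ``table``."""
        out = self.table.copy()
        out[["S1", "ST"]] = out[["S1", "ST"]].clip(0.0, 1.0)
        return out

    def total_index(self, output: str) -> pd.Series:
        sub = self.table[self.table["output"] == output]
        return sub.set_index("parameter")["ST"]


def sobol_indices(
    problem: SensitivityProblem,
    outputs: np.ndarray,
    output_names: tuple[str, ...] | None = None,
    n_boot: int = 100,
) -> SensitivityResult:
    """Sobol S1/ST estimates from outputs aligned with the Saltelli design.

    S1 uses the Saltelli-2010 estimator, ST the Jansen estimator, both
    averaged over the symmetric AB/BA blocks. Bootstrap over base samples
    gives the confidence half-widths (std of the resampled estimates).
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.ndim == 1:
        outputs = outputs[:, None]
    N, k = problem.base_n, problem.k
    if outputs.shape[0] != N * (2 * k + 2):
        raise ValueError("outputs are not aligned with the Saltelli design")
    names = output_names or OUTPUT_NAMES[: outputs.shape[1]]
    if len(names) != outputs.shape[1]:
        raise ValueError("output_names mismatch")

    fA = outputs[:N]
    fB = outputs[N:2 * N]
    fAB = np.stack([outputs[(2 + i) * N:(3 + i) * N] for i in range(k)])
    fBA = np.stack([outputs[(2 + k + i) * N:(3 + k + i) * N] for i in range(k)])

    def estimate(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a, b = fA[idx], fB[idx]
        ab, ba = fAB[:, idx], fBA[:, idx]
        var = np.var(np.concatenate([a, b]), axis=0, ddof=0)
        var = np.where(var == 0.0, np.nan, var)
        s1 = 0.5 * (np.mean(b * (ab - a), axis=1) + np.mean(a * (ba - b), axis=1)) / var
        st = 0.25 * (np.mean((a - ab) ** 2, axis=1) + np.mean((b - ba) ** 2, axis=1)) / var
        return s1, st  # each (k, n_outputs)

    s1, st = estimate(np.arange(N))
    if n_boot > 0:
        rng = np.random.default_rng(problem.seed)
        s1_bs = np.empty((n_boot,) + s1.shape)
        st_bs = np.empty((n_boot,) + st.shape)
        for b in range(n_boot):
            idx = rng.integers(0, N, size=N)
            s1_bs[b], st_bs[b] = estimate(idx)
        s1_conf = np.nanstd(s1_bs, axis=0)
        st_conf = np.nanstd(st_bs, axis=0)
    else:
        s1_conf = np.zeros_like(s1)
        st_conf = np.zeros_like(st)

    rows = []
    for j, out_name in enumerate(names):
        for i, param in enumerate(problem.names):
            rows.append(
                {
                    "parameter": param,
                    "output": out_name,
                    "S1": float(s1[i, j]),
                    "ST": float(st[i, j]),
                    "S1_conf": float(s1_conf[i, j]),
                    "ST_conf": float(st_conf[i, j]),
                }
            )
    return SensitivityResult(pd.DataFrame(rows), base_n=N, seed=problem.seed)
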