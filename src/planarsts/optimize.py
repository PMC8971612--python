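"""Single-shooting trajectory optimization of sit-to-stand with aCMA-ES.

The decision vector (excitation nodes + duration) is optimized against the
ten-term cost evaluated on forward roll-outs.  The search starts from the
"model sitting in the chair" guess, restarts when a generation budget is
exhausted or the best cost stagnates (improvement below a fixed delta over
a trailing window), and at each restart resets the covariance and
generation counter while re-centering the mean on the best candidate seen
so far.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cmaes import CMAES, default_popsize
from .control import (ControlLayout, T_F_MIN, decode, layout_for_model,
                      sitting_guess)
from .cost import CostBreakdown, CostWeights, compute_terms
from .dynamics import pack_model
from .params import PlanarModel
from .simulate import simulate

#: Large finite cost assigned to candidates whose evaluation is non-finite.
PENALTY_COST = 1e9

#: Added to the cost of roll-outs that hit the divergence cap, so a
#: numerically blown-up candidate can never outrank an honest attempt.
FAILED_ROLLOUT_PENALTY = 1e4


@dataclass
class OptimizerConfig:
    """Budgets and knobs of the restarted aCMA-ES driver.

    Defaults mirror the published protocol: restart past 4000 generations
    or when the best cost improves by less than 1.0 over the trailing 250
    generations; four restarts.  Population and initial step size are
    package choices (config-exposed): the duration gene is affinely mapped
    onto [0, 1] internally so a single sigma fits every gene.
    """

    max_generations: int = 4000
    stagnation_window: int = 250
    stagnation_delta: float = 1.0
    n_restarts: int = 4
    population_size: int | None = None
    initial_sigma: float = 0.15
    restart_sigma: float | None = None  # step size after a restart (None = initial)
    seed: int = 0
    active: bool = True
    bound_penalty: float = 100.0


@dataclass
class OptimizationResult:
    best_vector: np.ndarray
    best_cost: float
    best_breakdown: CostBreakdown | None
    history: list            # per generation: (best cost, mean cost, alpha of best)
    restart_log: list        # (trigger, generation at which it fired)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history,
                            columns=["best_cost", "mean_cost", "alpha_best"])


def stagnation_check(history_window, window: int = 250, delta: float = 1.0) -> bool:
    """True when the best-candidate cost improved less than ``delta``.

    ``history_window`` holds per-generation best costs; windows shorter
    than ``window`` never trigger, and an improvement of exactly ``delta``
    does not trigger (strict comparison).
    """
    if len(history_window) < window:
        return False
    w = list(history_window)[-window:]
    return (w[0] - w[-1]) < delta


class STSProblem:
    """Binds a model + cost weights into a cost-of-decision-vector callable.

    The duration gene is exposed to the optimizer on a [0, 1] scale and
    mapped affinely onto [t_f_min, t_max]; node genes are clamped to
    [0, 1] at decode time with a quadratic out-of-bounds penalty added to
    the cost so the sampler stays informed without rejections.

    ``t_f_min`` bounds the *search space* for the movement duration
    (default 0.8 s): durations far below the human sit-to-stand envelope
    otherwise act as a cost loophole — releasing the seat and ending the
    simulation immediately zeroes the chair term before the fall is ever
    penalized.  Roll-outs themselves accept any duration above the decode
    floor.
    """

    def __init__(self, model: PlanarModel, layout: ControlLayout,
                 weights: CostWeights | None = None,
                 bound_penalty: float = 100.0,
                 integrator=None, t_f_min: float = 0.8):
        self.model = model
        self.layout = layout
        self.weights = weights or CostWeights(tau=layout.t_max / 8.0)
        self.packed = pack_model(model)
        self.bound_penalty = bound_penalty
        self.integrator = integrator
        self.t_f_min = max(float(t_f_min), T_F_MIN)

    # -- gene scaling -------------------------------------------------------

    def scale_to_genes(self, vector: np.ndarray) -> np.ndarray:
        g = np.array(vector, dtype=float)
        g[-1] = (g[-1] - self.t_f_min) / (self.layout.t_max - self.t_f_min)
        return g

    def genes_to_vector(self, genes: np.ndarray) -> np.ndarray:
        v = np.array(genes, dtype=float)
        v[-1] = self.t_f_min + v[-1] * (self.layout.t_max - self.t_f_min)
        return v

    def initial_genes(self) -> np.ndarray:
        return self.scale_to_genes(sitting_guess(self.layout))

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, genes: np.ndarray):
        """Cost, breakdown and roll-out for one candidate gene vector."""
        clipped = np.clip(genes, 0.0, 1.0)
        oob = float(np.sum((genes - clipped) ** 2))
        traj = decode(self.genes_to_vector(clipped), self.layout)
        result = simulate(self.model, traj, integrator=self.integrator,
                          packed=self.packed)
        breakdown = compute_terms(result, self.model, self.weights,
                                  packed=self.packed)
        cost = breakdown.total + self.bound_penalty * oob
        if result.failed:
            cost += FAILED_ROLLOUT_PENALTY
        if not math.isfinite(cost):
            cost = PENALTY_COST
        return cost, breakdown, result

    def __call__(self, genes: np.ndarray) -> float:
        return self.evaluate(genes)[0]


def run(problem, layout: ControlLayout, config: OptimizerConfig | None = None,
        callback=None, stop_when=None) -> OptimizationResult:
    """Restarted aCMA-ES over the decision vector.

    ``problem`` is a callable gene-vector -> cost; if it is an
    :class:`STSProblem` the per-generation history also records alpha of
    the best candidate.  ``stop_when(best_cost, best_breakdown)`` may end
    the search early (e.g. once the transfer succeeds).  Deterministic for
    a fixed config seed.
    """
    cfg = config or OptimizerConfig()
    is_sts = isinstance(problem, STSProblem)
    if hasattr(problem, "initial_genes"):
        x0 = problem.initial_genes()
    else:
        x0 = sitting_guess(layout)
    n = len(x0)
    popsize = cfg.population_size or default_popsize(n)
    rng = np.random.default_rng(cfg.seed)

    history = []
    restart_log = []
    best_genes = np.array(x0, copy=True)
    best_breakdown = None
    # the initial guess itself is a candidate (the search must never
    # return something worse than simply sitting)
    if is_sts:
        best_cost, best_breakdown, _ = problem.evaluate(best_genes)
    else:
        best_cost = float(problem(best_genes))
    if not math.isfinite(best_cost):
        best_cost = PENALTY_COST

    for restart in range(cfg.n_restarts + 1):
        sigma = cfg.initial_sigma if restart == 0 else \
            (cfg.restart_sigma or cfg.initial_sigma)
        es = CMAES(best_genes, sigma, popsize=popsize,
                   active=cfg.active, rng=rng)
        window = []
        trigger = None
        for gen in range(cfg.max_generations):
            xs = es.ask()
            costs = np.empty(len(xs))
            gen_best = math.inf
            gen_best_i = 0
            for i, x in enumerate(xs):
                c = problem(x)
                if not math.isfinite(c):
                    c = PENALTY_COST
                costs[i] = c
                if c < gen_best:
                    gen_best = c
                    gen_best_i = i
            es.tell(xs, costs)

            if gen_best < best_cost:
                best_cost = gen_best
                best_genes = np.array(xs[gen_best_i], copy=True)
                if is_sts:
                    _, best_breakdown, _ = problem.evaluate(best_genes)

            alpha = best_breakdown.alpha if best_breakdown is not None else math.nan
            history.append((float(best_cost), float(np.mean(costs)), float(alpha)))
            window.append(float(best_cost))
            if callback is not None:
                callback(len(history) - 1, best_cost, best_breakdown)
            if stop_when is not None and stop_when(best_cost, best_breakdown):
                trigger = "stop_condition"
                break

            if stagnation_check(window, cfg.stagnation_window, cfg.stagnation_delta):
                trigger = "stagnation"
                break
        if trigger is None:
            trigger = "generation_budget"
        restart_log.append((trigger, len(history)))
        if trigger == "stop_condition" or restart == cfg.n_restarts:
            break

    if hasattr(problem, "genes_to_vector") and is_sts:
        best_vector = problem.genes_to_vector(np.clip(best_genes, 0.0, 1.0))
    else:
        best_vector = best_genes
    return OptimizationResult(best_vector=best_vector, best_cost=float(best_cost),
                              best_breakdown=best_breakdown, history=history,
                              restart_log=restart_log)


def optimize_sts(strength_scale: float = 1.0, assistance: bool = False,
                 seed: int = 0, max_generations: int = 800,
                 population_size: int = 24, n_restarts: int = 0,
                 initial_sigma: float = 0.15, restart_sigma: float | None = 0.05,
                 dt: float = 0.004,
                 stop_alpha: float | None = 0.92, t_max: float = 1.6,
                 model: PlanarModel | None = None):
    """Optimize one sit-to-stand at a given strength deficit.

    Convenience wrapper used by the deficit-sweep workflows: builds the
    default model at ``strength_scale``, runs the restarted aCMA-ES with
    the sitting initial guess, and returns ``(model, OptimizationResult,
    SimulationResult of the best candidate)``.  ``dt`` is the roll-out
    integration step used during the search (a coarser step than the
    analysis default keeps large candidate batches affordable);
    ``stop_alpha`` ends the search early once the transfer is essentially
    complete.
    """
    from .params import IntegratorConfig, build_model, model_config_with_scale

    if model is None:
        model = build_model(model_config_with_scale(strength_scale, assistance))
    layout = layout_for_model(model, t_max)
    integ = IntegratorConfig(dt=dt, qdot_cap=model.integrator.qdot_cap,
                             baumgarte_beta=model.integrator.baumgarte_beta)
    problem = STSProblem(model, layout, integrator=integ)
    cfg = OptimizerConfig(max_generations=max_generations,
                          n_restarts=n_restarts,
                          population_size=population_size,
                          initial_sigma=initial_sigma,
                          restart_sigma=restart_sigma, seed=seed)
    stop = None
    if stop_alpha is not None:
        stop = lambda c, bd: bd is not None and bd.alpha > stop_alpha
    opt = run(problem, layout, cfg, stop_when=stop)
    traj = decode(opt.best_vector, layout)
    best_sim = simulate(model, traj, integrator=integ, packed=problem.packed)
    return model, opt, best_sim
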