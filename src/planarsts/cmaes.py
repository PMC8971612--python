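"""Covariance matrix adaptation evolution strategy (CMA-ES).

A self-contained (mu/mu_w, lambda) CMA-ES with cumulative step-size
adaptation, rank-one and rank-mu covariance updates, and (by default) the
"active" variant that also exploits the worse half of the population
through negative recombination weights (aCMA-ES).  Implementation follows
the standard tutorial formulation of the algorithm; it is deterministic
for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np


def default_popsize(n: int) -> int:
    """The canonical population size 4 + floor(3 ln n)."""
    return 4 + int(3 * math.log(n))


class CMAES:
    """Ask/tell interface; minimization.

    Parameters
    ----------
    x0 : initial distribution mean.
    sigma0 : initial step size (coordinate-wise scale of the search).
    popsize : candidates per generation; defaults to ``4 + 3 ln n``.
    seed : RNG seed; runs are bitwise reproducible for a fixed seed.
    active : enable the negative-weight covariance update (aCMA).
    """

    def __init__(self, x0, sigma0: float, popsize: int | None = None,
                 seed: int = 0, active: bool = True,
                 rng: np.random.Generator | None = None):
        self.mean = np.asarray(x0, dtype=float).copy()
        self.n = len(self.mean)
        self.sigma = float(sigma0)
        self.lam = popsize or default_popsize(self.n)
        self.active = active
        self.rng = rng if rng is not None else np.random.default_rng(seed)

        n, lam = self.n, self.lam
        self.mu = lam // 2
        w_prime = np.log((lam + 1) / 2.0) - np.log(np.arange(1, lam + 1))
        mu_eff = w_prime[:self.mu].sum() ** 2 / (w_prime[:self.mu] ** 2).sum()
        mu_eff_neg = (w_prime[self.mu:].sum() ** 2
                      / (w_prime[self.mu:] ** 2).sum()) if lam > self.mu else 0.0

        self.cs = (mu_eff + 2) / (n + mu_eff + 5)
        self.ds = 1 + 2 * max(0.0, math.sqrt((mu_eff - 1) / (n + 1)) - 1) + self.cs
        self.cc = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
        self.c1 = 2 / ((n + 1.3) ** 2 + mu_eff)
        self.cmu = min(1 - self.c1,
                       2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))

        weights = np.zeros(lam)
        pos = w_prime[:self.mu]
        weights[:self.mu] = pos / pos.sum()
        if active and lam > self.mu:
            alpha_mu = 1 + self.c1 / self.cmu
            alpha_eff = 1 + 2 * mu_eff_neg / (mu_eff + 2)
            alpha_pd = (1 - self.c1 - self.cmu) / (n * self.cmu)
            neg = w_prime[self.mu:]
            weights[self.mu:] = (min(alpha_mu, alpha_eff, alpha_pd)
                                 * neg / np.abs(neg).sum())
        self.weights = weights
        self.mu_eff = mu_eff

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.B = np.eye(n)
        self.D = np.ones(n)
        self.invsqrtC = np.eye(n)
        self.chiN = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))
        self.generation = 0
        self.best_x = self.mean.copy()
        self.best_f = math.inf
        self._pending = None

    # -- API ----------------------------------------------------------------

    def ask(self) -> np.ndarray:
        """Sample a batch of candidate solutions, shape (popsize, n)."""
        z = self.rng.standard_normal((self.lam, self.n))
        y = z @ (self.B * self.D).T  # B diag(D) z
        x = self.mean + self.sigma * y
        self._pending = y
        return x

    def tell(self, solutions: np.ndarray, fitnesses) -> None:
        """Rank the batch and update mean, paths, covariance and step size."""
        f = np.asarray(fitnesses, dtype=float)
        order = np.argsort(f)
        if f[order[0]] < self.best_f:
            self.best_f = float(f[order[0]])
            self.best_x = np.array(solutions[order[0]], copy=True)

        y = (np.asarray(solutions)[order] - self.mean) / self.sigma
        n, lam, mu = self.n, self.lam, self.mu
        w = self.weights

        y_w = w[:mu] @ y[:mu]
        self.mean = self.mean + self.sigma * y_w

        self.ps = ((1 - self.cs) * self.ps
                   + math.sqrt(self.cs * (2 - self.cs) * self.mu_eff)
                   * (self.invsqrtC @ y_w))
        hsig_denom = math.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
        hsig = (np.linalg.norm(self.ps) / hsig_denom
                < (1.4 + 2 / (n + 1)) * self.chiN)
        self.pc = ((1 - self.cc) * self.pc
                   + (math.sqrt(self.cc * (2 - self.cc) * self.mu_eff) * y_w
                      if hsig else 0.0))

        w_circ = w.copy()
        if self.active:
            for i in range(mu, lam):
                norm2 = np.sum((self.invsqrtC @ y[i]) ** 2)
                if norm2 > 0:
                    w_circ[i] = w[i] * n / norm2
        delta_hsig = (1 - hsig) * self.cc * (2 - self.cc)
        c_old = (1 + self.c1 * delta_hsig - self.c1 - self.cmu * w.sum())
        rank_mu = (y.T * w_circ) @ y
        self.C = (c_old * self.C + self.c1 * np.outer(self.pc, self.pc)
                  + self.cmu * rank_mu)

        self.sigma *= math.exp(min(1.0, (self.cs / self.ds)
                                   * (np.linalg.norm(self.ps) / self.chiN - 1)))

        self.C = (self.C + self.C.T) / 2
        eigval, eigvec = np.linalg.eigh(self.C)
        eigval = np.maximum(eigval, 1e-20)
        self.D = np.sqrt(eigval)
        self.B = eigvec
        self.invsqrtC = (eigvec / self.D) @ eigvec.T
        self.generation += 1


def minimize(func, x0, sigma0: float, popsize: int | None = None,
             seed: int = 0, max_generations: int = 1000,
             f_target: float = -math.inf, active: bool = True):
    """Convenience loop; returns (best_x, best_f, n_evaluations)."""
    es = CMAES(x0, sigma0, popsize=popsize, seed=seed, active=active)
    n_eval = 0
    for _ in range(max_generations):
        xs = es.ask()
        fs = [func(x) for x in xs]
        n_eval += len(fs)
        es.tell(xs, fs)
        if es.best_f <= f_target:
            break
    return es.best_x, es.best_f, n_eval
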