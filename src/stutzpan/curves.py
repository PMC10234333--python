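"""Gene-discovery curves and exponential core/pan-genome models.

Adding genomes in random order, the cumulative core size decays and the pan
size grows. Both are summarized by exponential-with-offset models:

* core:      F(n) = kappa * exp(-n / tau) + Omega, with asymptotic core size
  Omega (gene clusters);
* new genes: n_new(g) = kappa_p * exp(-g / tau_p) + theta, with asymptotic
  discovery rate theta (new gene clusters per added genome). theta > 0 is the
  operational definition of an open pan-genome; the pan size at N genomes is
  extrapolated cumulatively, P(N) = P(G_obs) + sum_{g>G_obs} n_new(g).

The core model is fitted to per-g means (the classic variant); a median-based
weighted variant (weights 1/var(g)) is provided as the alternative model tag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .pangenome import PangenomeMatrix


@dataclass
class SamplingCurve:
    """Core/pan/new-gene trajectories over random genome orderings.

    Arrays are shaped (n_permutations, n_genomes); column g-1 holds the value
    after adding the g-th genome of that permutation.
    """

    core: np.ndarray
    pan: np.ndarray
    new_genes: np.ndarray
    seed: int

    @property
    def n_genomes(self) -> int:
        return self.core.shape[1]

    @property
    def n_permutations(self) -> int:
        return self.core.shape[0]

    def g_values(self) -> np.ndarray:
        return np.arange(1, self.n_genomes + 1)


@dataclass
class CoreFit:
    kappa: float
    tau: float
    omega: float
    model: str  # "tettelin" | "willenbrock"
    rss: float
    degenerate: bool = False

    def predict(self, n) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return self.kappa * np.exp(-n / self.tau) + self.omega


@dataclass
class PanFit:
    kappa_p: float
    tau_p: float
    theta_rate: float
    model: str
    rss: float
    g_obs: int
    pan_at_obs: float

    @property
    def open_pangenome(self) -> bool:
        return self.theta_rate > 0

    def new_genes_at(self, g) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        return self.kappa_p * np.exp(-g / self.tau_p) + self.theta_rate


def sample_gene_discovery(matrix: PangenomeMatrix, n_permutations: int = 100,
                          seed: int = 0) -> SamplingCurve:
    """Cumulative core/pan sizes over random genome orderings.

    For each permutation, after adding the first g genomes: core(g) = clusters
    present in all of them, pan(g) = clusters present in at least one. New
    genes at step g is pan(g) - pan(g-1) (pan(0) = 0). Reproducible given the
    seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    presence = matrix.presence
    n_genomes = presence.shape[1]
    if n_genomes < 3:
        raise ValueError("need a matrix with at least 3 genomes")
    rng = np.random.default_rng(seed)
    core = np.empty((n_permutations, n_genomes), dtype=int)
    pan = np.empty_like(core)
    for p in range(n_permutations):
        order = rng.permutation(n_genomes)
        cols = presence[:, order]
        core[p] = np.logical_and.accumulate(cols, axis=1).sum(axis=0)
        pan[p] = np.logical_or.accumulate(cols, axis=1).sum(axis=0)
    new = np.diff(pan, axis=1, prepend=0)
    return SamplingCurve(core=core, pan=pan, new_genes=new, seed=seed)


def _fit_exponential(g: np.ndarray, y: np.ndarray, sigma: np.ndarray | None,
                     g_span: float) -> tuple[float, float, float, float]:
    """Least-squares fit of y = kappa*exp(-g/tau) + offset; returns
    (kappa, tau, offset, rss)."""
    if np.ptp(y) < 1e-9:
        return 0.0, g_span / 3.0, float(y[-1]), 0.0
    p0 = (max(y[0] - y[-1], 1e-3) if y[0] > y[-1] else max(y[0], 1e-3),
          g_span / 3.0, max(float(y[-1]), 0.0))

    def model(n, kappa, tau, offset):
        return kappa * np.exp(-n / tau) + offset

    try:
        popt, _ = curve_fit(model, g, y, p0=p0, sigma=sigma,
                            bounds=([-np.inf, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"exponential fit failed to converge: {exc}") from exc
    rss = float(np.sum((model(g, *popt) - y) ** 2))
    return float(popt[0]), float(popt[1]), float(popt[2]), rss


def fit_core(curve: SamplingCurve, model: str = "tettelin") -> CoreFit:
    """Fit the core-genome decay F(n) = kappa*exp(-n/tau) + Omega.

    ``tettelin`` fits per-g means (unweighted); ``willenbrock`` fits per-g
    medians weighted by 1/var(g) across permutations (variances floored to
    keep weights finite where all permutations agree, e.g. at g = G).
    """
    if model not in ("tettelin", "willenbrock"):
        raise ValueError(f"unknown model {model!r}")
    g = curve.g_values().astype(float)
    if len(np.unique(g)) < 4:
        raise ValueError("need at least 4 distinct g values")
    if model == "tettelin":
        y = curve.core.mean(axis=0)
        sigma = None
    else:
        y = np.median(curve.core, axis=0)
        sigma = np.clip(curve.core.std(axis=0), 1e-3, None)
    degenerate = bool(np.ptp(y) < 1e-9)
    kappa, tau, omega, rss = _fit_exponential(g, y.astype(float), sigma, g[-1])
    return CoreFit(kappa, tau, omega, model, rss, degenerate=degenerate)


def fit_pan(curve: SamplingCurve, model: str = "tettelin") -> PanFit:
    """Fit the new-gene decay n_new(g) = kappa_p*exp(-g/tau_p) + theta.

    The fit uses mean new genes per added genome for g >= 2 (new genes at
    g = 1 is the whole first genome and belongs to the core term, not the
    discovery model).
    """
    g = curve.g_values().astype(float)
    if len(g) < 5:
        raise ValueError("need at least 4 distinct g values beyond the first")
    if model == "tettelin":
        y = curve.new_genes.mean(axis=0)[1:]
        sigma = None
    elif model == "willenbrock":
        y = np.median(curve.new_genes, axis=0)[1:].astype(float)
        sigma = np.clip(curve.new_genes[:, 1:].std(axis=0), 1e-3, None)
    else:
        raise ValueError(f"unknown model {model!r}")
    kappa_p, tau_p, theta, rss = _fit_exponential(g[1:], y.astype(float), sigma, g[-1])
    return PanFit(kappa_p, tau_p, theta, model, rss,
                  g_obs=int(g[-1]), pan_at_obs=float(curve.pan.mean(axis=0)[-1]))


def extrapolate(fit: CoreFit | PanFit, n_target: int) -> float:
    """Model-based expected size at ``n_target`` genomes.

    Core fits are evaluated directly; pan fits accumulate the fitted new-gene
    rate from the observed G to the target.
    """
    if isinstance(fit, CoreFit):
        return float(fit.predict(n_target))
    if n_target < fit.g_obs:
        raise ValueError(f"n_target {n_target} below observed {fit.g_obs} "
                         "(interpolation is not extrapolation)")
    future = np.arange(fit.g_obs + 1, n_target + 1)
    return float(fit.pan_at_obs + fit.new_genes_at(future).sum())


def curve_table(curve: SamplingCurve):
    """Long-format (permutation, g, core, pan, new_genes) table."""
    import pandas as pd
    records = []
    for p in range(curve.n_permutations):
        for gi, g in enumerate(curve.g_values()):
            records.append((p, int(g), int(curve.core[p, gi]),
                            int(curve.pan[p, gi]), int(curve.new_genes[p, gi])))
    return pd.DataFrame(records, columns=["permutation", "g", "core", "pan", "new_genes"])
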