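"""Synthetic-data generator and operating-characteristics engine.

Datasets are drawn from the marginal model ``y ~ N(X delta, S + tau_beta^2 P1
+ tau_omega^2 P2)`` for networks of 2- and 3-arm designs over four treatments
A-D.  Each study receives a single within-study variance sigma^2 drawn as
0.25 * chi-square(1) truncated to [0.009, 0.6] (a standard generator for log
odds ratio variances), and its covariance matrix is ``sigma^2 P_{c_d}``,
i.e. equal within-study variances with correlation 1/2, reflecting equal
allocation across arms.  Three stock layouts are provided:

* ``run1``: 2 studies of each of the five designs ABC, ABD, AB, AC, AD
  (10 studies, 14 contrasts);
* ``run2``: 10 studies of each of the same five designs (50 studies, 70
  contrasts);
* ``run3``: 5 studies of each of all ten 2- and 3-arm designs on {A,B,C,D}
  (50 studies, 70 contrasts) — more designs, so the inconsistency variance
  is better identified.

The engine fits the moment-based RI (or RC) model to each replicate and
reports, per basic parameter: the empirical standard error (SD of the point
estimates), the mean model-based standard error, the coverage of nominal
confidence intervals and the excess kurtosis of the estimates; and, per
variance component, the mean and SD of the truncated and untruncated
estimates.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import fit_consistency_model, fit_full_model
from .inference import gls_estimate
from .network import (
    DesignMatrices,
    Network,
    Study,
    build_design_matrices,
    canonicalize_design,
    pcd_matrix,
)

__all__ = [
    "LAYOUTS",
    "SimulationConfig",
    "sample_within_variance",
    "sample_within_variances",
    "simulate_dataset",
    "excess_kurtosis",
    "run_simulation_study",
]

_RUN12_DESIGNS = ("ABC", "ABD", "AB", "AC", "AD")
_RUN3_DESIGNS = ("ABC", "ABD", "ACD", "BCD", "AB", "AC", "AD", "BC", "BD", "CD")

#: layout name -> list of (treatment tuple, number of studies)
LAYOUTS: dict[str, list[tuple[tuple[str, ...], int]]] = {
    "run1": [(tuple(d), 2) for d in _RUN12_DESIGNS],
    "run2": [(tuple(d), 10) for d in _RUN12_DESIGNS],
    "run3": [(tuple(d), 5) for d in _RUN3_DESIGNS],
}


@dataclass
class SimulationConfig:
    """Study conditions for the operating-characteristics engine.

    ``tau_beta_sq`` / ``tau_omega_sq`` may be scalars or grids; the engine
    runs every combination.  The default grid values {0, 0.024, 0.168}
    correspond to RC-vs-CC I² of 0%, 30% and 75% under this within-study
    variance generator.  ``delta`` defaults to zero for every basic
    parameter; variance-component estimation is location-invariant, so this
    is without loss of generality.
    """

    layout: str = "run1"
    custom_designs: list[tuple[tuple[str, ...], int]] | None = None
    tau_beta_sq: float | Sequence[float] = 0.0
    tau_omega_sq: float | Sequence[float] = 0.0
    delta: np.ndarray | None = None
    n_reps: int = 3000
    seed: int = 0
    var_scale: float = 0.25
    var_bounds: tuple[float, float] = (0.009, 0.6)
    level: float = 0.95

    def design_list(self) -> list[tuple[tuple[str, ...], int]]:
        if self.layout == "custom":
            if not self.custom_designs:
                raise ValueError("layout 'custom' requires custom_designs")
            return list(self.custom_designs)
        try:
            return LAYOUTS[self.layout]
        except KeyError:
            raise ValueError(
                f"unknown layout {self.layout!r}; choose from "
                f"{sorted(LAYOUTS)} or 'custom'"
            ) from None

    def grid(self) -> list[tuple[float, float]]:
        tb = np.atleast_1d(np.asarray(self.tau_beta_sq, dtype=float))
        tw = np.atleast_1d(np.asarray(self.tau_omega_sq, dtype=float))
        return list(itertools.product(tb.tolist(), tw.tolist()))


def sample_within_variance(
    rng: np.random.Generator,
    scale: float = 0.25,
    bounds: tuple[float, float] = (0.009, 0.6),
) -> float:
    """One within-study variance: scale * chi2(1), rejected until in bounds."""
    return float(sample_within_variances(rng, 1, scale=scale, bounds=bounds)[0])


def sample_within_variances(
    rng: np.random.Generator,
    n: int,
    scale: float = 0.25,
    bounds: tuple[float, float] = (0.009, 0.6),
) -> np.ndarray:
    """Vector of n truncated scaled chi-square variances (rejection sampling).

    Bounds are inclusive; acceptance probability is about 0.73 with the
    defaults, so rejection sampling is cheap and exact.
    """
    lo, hi = bounds
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = scale * rng.chisquare(1, size=max(n - filled, 8))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


class _LayoutTemplate:
    """Precomputed structure for repeated simulation from one layout.

    X, P1 and P2 depend only on the layout; per replicate only the
    within-study covariance S and the response y are redrawn.
    """

    def __init__(self, designs: list[tuple[tuple[str, ...], int]]):
        studies = []
        for treatments, n_studies in designs:
            d = canonicalize_design(treatments)
            for i in range(n_studies):
                studies.append(
                    Study(
                        id=f"{d.label}-{i + 1}",
                        design=d,
                        y=np.zeros(d.c_d),
                        S=pcd_matrix(d.c_d),
                    )
                )
        self.network = Network(studies)
        self.dm0 = build_design_matrices(self.network)
        self.pcd_blocks = [
            pcd_matrix(s.design.c_d) for s in self.network.studies
        ]
        self.n_studies = len(self.network.studies)

    def simulate(
        self,
        rng: np.random.Generator,
        tau_beta_sq: float,
        tau_omega_sq: float,
        delta: np.ndarray | None = None,
        var_scale: float = 0.25,
        var_bounds: tuple[float, float] = (0.009, 0.6),
    ) -> DesignMatrices:
        dm0 = self.dm0
        sig2 = sample_within_variances(
            rng, self.n_studies, scale=var_scale, bounds=var_bounds
        )
        S = np.zeros_like(dm0.S)
        for s2, sl, block in zip(sig2, dm0.study_rows, self.pcd_blocks):
            S[sl, sl] = s2 * block
        V = S + tau_beta_sq * dm0.P1 + tau_omega_sq * dm0.P2
        L = np.linalg.cholesky(V)
        mean = 0.0 if delta is None else dm0.X @ np.asarray(delta, dtype=float)
        y = mean + L @ rng.standard_normal(dm0.n_rows)
        return dataclasses.replace(dm0, S=S, y=y)


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Network:
    """Draw one synthetic network dataset under the configured conditions.

    Scalar ``tau_beta_sq`` / ``tau_omega_sq`` are required here (use
    :func:`run_simulation_study` for grids).
    """
    tb = float(np.asarray(config.tau_beta_sq).reshape(-1)[0])
    tw = float(np.asarray(config.tau_omega_sq).reshape(-1)[0])
    if rng is None:
        rng = np.random.default_rng(config.seed)
    template = _LayoutTemplate(config.design_list())
    dm = template.simulate(
        rng, tb, tw, config.delta, config.var_scale, config.var_bounds
    )
    studies = []
    for s, sl in zip(template.network.studies, dm.study_rows):
        studies.append(
            Study(id=s.id, design=s.design, y=dm.y[sl].copy(), S=dm.S[sl, sl].copy())
        )
    return Network(studies)


def excess_kurtosis(samples: np.ndarray) -> float:
    """Sample excess kurtosis m4/m2² − 3 (no small-sample bias correction)."""
    x = np.asarray(samples, dtype=float).reshape(-1)
    if x.size < 4:
        raise ValueError("excess kurtosis needs at least 4 observations")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0.0:
        raise ValueError("zero variance: kurtosis undefined")
    return float(np.mean(d**4) / m2**2 - 3.0)


def run_simulation_study(
    config: SimulationConfig, model: str = "RI"
) -> pd.DataFrame:
    """Operating characteristics of the moment-based fit over a grid.

    For every (tau_beta^2, tau_omega^2) combination, ``n_reps`` datasets are
    simulated and fitted with the requested model ("RI" or "RC").  Grid cells
    use independent child streams spawned from the master seed, so any cell
    is reproducible in isolation.  Replicates where a variance component is
    not identifiable are counted in ``n_failed`` rather than silently
    dropped.

    Returns a tidy frame with one row per (cell, basic parameter):
    ``se_emp``, ``se_model``, ``cover``, ``excess_kurt`` plus
    ``e_tau_*``/``sd_tau_*`` summaries of the truncated estimates (and
    ``e_tau_*_untrunc`` of the raw ones).
    """
    if model not in ("RI", "RC"):
        raise ValueError(f"model must be 'RI' or 'RC', got {model!r}")
    template = _LayoutTemplate(config.design_list())
    c = template.dm0.c
    labels = template.dm0.basic_labels
    delta_true = (
        np.zeros(c) if config.delta is None else np.asarray(config.delta, dtype=float)
    )
    z = stats.norm.ppf(0.5 * (1.0 + config.level))
    grid = config.grid()
    streams = np.random.SeedSequence(config.seed).spawn(len(grid))

    rows = []
    for (tb, tw), ss in zip(grid, streams):
        rng = np.random.default_rng(ss)
        est = np.empty((config.n_reps, c))
        ses = np.empty((config.n_reps, c))
        tb_hat = np.empty(config.n_reps)
        tw_hat = np.empty(config.n_reps)
        tb_un = np.empty(config.n_reps)
        tw_un = np.empty(config.n_reps)
        ok = np.zeros(config.n_reps, dtype=bool)
        for r in range(config.n_reps):
            dm = template.simulate(
                rng, tb, tw, config.delta, config.var_scale, config.var_bounds
            )
            try:
                fit = (
                    fit_full_model(dm) if model == "RI" else fit_consistency_model(dm)
                )
            except Exception:
                continue
            gls = gls_estimate(dm, fit)
            est[r] = gls.delta_hat
            ses[r] = gls.se
            tb_hat[r] = fit.tau_beta_sq
            tw_hat[r] = fit.tau_omega_sq
            tb_un[r] = fit.tau_beta_sq_untrunc
            tw_un[r] = fit.tau_omega_sq_untrunc
            ok[r] = True
        n_ok = int(ok.sum())
        e, s = est[ok], ses[ok]
        for j, lab in enumerate(labels):
            covered = np.abs(e[:, j] - delta_true[j]) <= z * s[:, j]
            rows.append(
                {
                    "layout": config.layout,
                    "model": model,
                    "tau_beta_sq": tb,
                    "tau_omega_sq": tw,
                    "param": lab,
                    "se_emp": float(np.std(e[:, j], ddof=1)) if n_ok > 1 else np.nan,
                    "se_model": float(np.mean(s[:, j])),
                    "cover": float(np.mean(covered)),
                    "excess_kurt": excess_kurtosis(e[:, j]) if n_ok >= 4 else np.nan,
                    "e_tau_beta_sq": float(np.mean(tb_hat[ok])),
                    "sd_tau_beta_sq": float(np.std(tb_hat[ok], ddof=1)),
                    "e_tau_omega_sq": float(np.mean(tw_hat[ok])),
                    "sd_tau_omega_sq": float(np.std(tw_hat[ok], ddof=1)),
                    "e_tau_beta_sq_untrunc": float(np.mean(tb_un[ok])),
                    "e_tau_omega_sq_untrunc": float(np.mean(tw_un[ok])),
                    "sd_tau_beta_sq_untrunc": float(np.std(tb_un[ok], ddof=1)),
                    "sd_tau_omega_sq_untrunc": float(np.std(tw_un[ok], ddof=1)),
                    "n_reps": config.n_reps,
                    "n_failed": config.n_reps - n_ok,
                    "seed": config.seed,
                }
            )
    return pd.DataFrame(rows)
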