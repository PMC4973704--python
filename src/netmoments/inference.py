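"""GLS inference, treatment contrasts, ranking and I²/R statistics.

With the truncated variance components treated as fixed and known, the total
variance of the stacked contrasts is ``V = S + tau_beta^2 P1 + tau_omega^2
P2`` and the basic parameters are estimated by generalized least squares:

    delta_hat = (Xᵀ V⁻¹ X)⁻¹ Xᵀ V⁻¹ y,   Var(delta_hat) = (Xᵀ V⁻¹ X)⁻¹.

``delta_hat`` is approximately multivariate normal; confidence intervals use
standard normal quantiles.  Any other treatment contrast is a linear
combination ``L delta_hat``.  Probabilistic treatment ranking draws effect
vectors from N(delta_hat, Var) with the reference fixed at zero and tallies
the full rank distribution.  The impact of an extra variance component is
summarised by the R statistic — the c-th root of the ratio of confidence
region volumes of two nested fits — and ``I² = (R² − 1)/R² × 100%``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .estimation import MomentFit
from .exceptions import NetworkError
from .network import DesignMatrices, Network, as_design_matrices

__all__ = [
    "GLSResult",
    "gls_estimate",
    "confidence_intervals",
    "contrast",
    "RankResult",
    "rank_probabilities",
    "HeterogeneityImpact",
    "r_statistic",
    "i_squared_comparisons",
]


@dataclass
class GLSResult:
    """Basic-parameter estimates and their covariance for one model fit."""

    treatments: tuple[str, ...]
    delta_hat: np.ndarray  # length c, ordered as treatments[1:]
    cov: np.ndarray  # c x c
    model: str
    V: np.ndarray

    @property
    def reference(self) -> str:
        return self.treatments[0]

    @property
    def c(self) -> int:
        return len(self.delta_hat)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"{self.reference}{t}" for t in self.treatments[1:])

    def relative_to(self, new_reference: str) -> tuple[np.ndarray, np.ndarray]:
        """Re-express all treatment effects relative to another treatment.

        Returns estimates and covariance for the effects of every other
        treatment versus ``new_reference`` (in treatment order), obtained as
        the linear map of the basic parameters implied by consistency.
        """
        if new_reference not in self.treatments:
            raise ValueError(f"unknown treatment {new_reference!r}")
        others = [t for t in self.treatments if t != new_reference]
        L = np.zeros((len(others), self.c))
        pos = {t: k for k, t in enumerate(self.treatments[1:])}
        for i, t in enumerate(others):
            if t != self.reference:
                L[i, pos[t]] += 1.0
            if new_reference != self.reference:
                L[i, pos[new_reference]] -= 1.0
        return contrast(self, L)


def gls_estimate(data: Network | DesignMatrices, fit: MomentFit) -> GLSResult:
    """GLS point estimates and covariance under the fitted variance model.

    Uses the truncated variance components; for a loop-inconsistency fit the
    restricted P2 carries through to V.
    """
    dm = as_design_matrices(data)
    P2 = fit.p2_override if fit.p2_override is not None else dm.P2
    V = dm.S + fit.tau_beta_sq * dm.P1 + fit.tau_omega_sq * P2
    cf = sla.cho_factor(V, lower=True)
    ViX = sla.cho_solve(cf, dm.X)
    M = dm.X.T @ ViX
    try:
        cov = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        raise NetworkError("X'V^{-1}X is singular; basic parameters not identified") from None
    cov = 0.5 * (cov + cov.T)
    delta = cov @ (ViX.T @ dm.y)
    return GLSResult(
        treatments=dm.treatments, delta_hat=delta, cov=cov, model=fit.model, V=V
    )


def confidence_intervals(gls: GLSResult, level: float = 0.95) -> pd.DataFrame:
    """Normal-quantile confidence intervals for the basic parameters."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    se = gls.se
    return pd.DataFrame(
        {
            "parameter": list(gls.labels),
            "estimate": gls.delta_hat,
            "se": se,
            "lower": gls.delta_hat - z * se,
            "upper": gls.delta_hat + z * se,
        }
    )


def contrast(gls: GLSResult, L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear combinations ``L delta_hat`` with covariance ``L Cov Lᵀ``."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if L.shape[1] != gls.c:
        raise ValueError(f"contrast matrix has {L.shape[1]} columns, expected {gls.c}")
    return L @ gls.delta_hat, L @ gls.cov @ L.T


@dataclass
class RankResult:
    """Monte-Carlo rank distribution of the treatments.

    ``probs[t, k]`` estimates the probability that treatment ``t`` occupies
    rank ``k + 1`` (rank 1 = most effective under the stated direction).
    Rows and columns each sum to one up to Monte-Carlo error.
    """

    treatments: tuple[str, ...]
    probs: np.ndarray  # T x T
    n_draws: int
    seed: int | None
    direction: str

    def p_best(self) -> dict[str, float]:
        return {t: float(self.probs[i, 0]) for i, t in enumerate(self.treatments)}

    def to_frame(self) -> pd.DataFrame:
        cols = [f"rank_{k + 1}" for k in range(len(self.treatments))]
        return pd.DataFrame(self.probs, index=list(self.treatments), columns=cols)


def rank_probabilities(
    gls: GLSResult,
    n_draws: int = 10_000,
    seed: int | np.random.Generator | None = None,
    direction: str | None = None,
) -> RankResult:
    """Probabilistic ranking of all treatments from the fitted model.

    Simulates ``n_draws`` effect vectors from N(delta_hat, Cov), appends the
    reference treatment with effect exactly 0, and tallies the frequency of
    every rank for every treatment — not only rank 1, since P(best) alone can
    mislead when the network carries little information.  ``direction`` must
    be explicit (``"smaller_better"`` or ``"larger_better"``): sign
    conventions differ per outcome and a silent default could invert the
    ranking.
    """
    if direction not in ("smaller_better", "larger_better"):
        raise ValueError(
            "direction must be 'smaller_better' or 'larger_better', "
            f"got {direction!r}"
        )
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    else:
        rng, seed_out = np.random.default_rng(seed), seed

    try:
        L = np.linalg.cholesky(gls.cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "covariance of the basic parameters is not positive definite"
        ) from None
    z = rng.standard_normal((n_draws, gls.c))
    draws = gls.delta_hat + z @ L.T

    T = gls.c + 1
    full = np.zeros((n_draws, T))
    full[:, 1:] = draws  # reference (index 0) fixed at effect 0
    keyed = full if direction == "smaller_better" else -full
    # rank position of each treatment in each draw (0 = best)
    order = np.argsort(keyed, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(T)[None, :].repeat(n_draws, 0), axis=1)
    probs = np.zeros((T, T))
    for t in range(T):
        probs[t] = np.bincount(ranks[:, t], minlength=T) / n_draws
    return RankResult(
        treatments=gls.treatments,
        probs=probs,
        n_draws=n_draws,
        seed=seed_out if isinstance(seed_out, int) else None,
        direction=direction,
    )


@dataclass
class HeterogeneityImpact:
    """R statistic and I² for a nested model comparison."""

    R: float
    I2: float  # percentage
    comparison: tuple[str, str]
    dim: int


def r_statistic(
    C_num: np.ndarray,
    C_den: np.ndarray,
    comparison: tuple[str, str] = ("RI", "RC"),
    subset: np.ndarray | list[int] | None = None,
) -> HeterogeneityImpact:
    """R = |C_num C_den⁻¹|^{1/(2 dim)} and I² = (R² − 1)/R² × 100%.

    ``C_num`` is the basic-parameter covariance from the model with the
    additional variance component(s), ``C_den`` from the reduced model; the
    statistic is the dim-th root of the ratio of their confidence-region
    volumes (the confidence level cancels).  ``subset`` restricts both
    matrices to a subset of basic parameters, with ``dim`` reduced
    accordingly.
    """
    C_num = np.atleast_2d(np.asarray(C_num, dtype=float))
    C_den = np.atleast_2d(np.asarray(C_den, dtype=float))
    if subset is not None:
        idx = np.asarray(subset, dtype=int)
        C_num = C_num[np.ix_(idx, idx)]
        C_den = C_den[np.ix_(idx, idx)]
    if C_num.shape != C_den.shape or C_num.shape[0] != C_num.shape[1]:
        raise ValueError("covariance matrices must be square with equal shapes")
    dim = C_num.shape[0]
    sign_n, logdet_n = np.linalg.slogdet(C_num)
    sign_d, logdet_d = np.linalg.slogdet(C_den)
    if sign_n <= 0 or sign_d <= 0:
        raise np.linalg.LinAlgError("covariance matrices must be positive definite")
    R = float(np.exp((logdet_n - logdet_d) / (2.0 * dim)))
    I2 = (R**2 - 1.0) / R**2 * 100.0
    return HeterogeneityImpact(R=R, I2=I2, comparison=comparison, dim=dim)


def i_squared_comparisons(
    data: Network | DesignMatrices,
    subset: np.ndarray | list[int] | None = None,
) -> dict[str, HeterogeneityImpact]:
    """The three standard nested comparisons: RI vs RC, RI vs CC, RC vs CC.

    Fits all three models once and returns the corresponding R/I²
    statistics, quantifying the impact of inconsistency, of inconsistency
    plus heterogeneity, and of heterogeneity alone.
    """
    from .estimation import (
        fit_common_effect_model,
        fit_consistency_model,
        fit_full_model,
    )

    dm = as_design_matrices(data)
    covs = {
        "RI": gls_estimate(dm, fit_full_model(dm)).cov,
        "RC": gls_estimate(dm, fit_consistency_model(dm)).cov,
        "CC": gls_estimate(dm, fit_common_effect_model(dm)).cov,
    }
    out = {}
    for num, den in (("RI", "RC"), ("RI", "CC"), ("RC", "CC")):
        out[f"{num}_vs_{den}"] = r_statistic(
            covs[num], covs[den], comparison=(num, den), subset=subset
        )
    return out
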