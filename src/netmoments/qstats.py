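"""Cochran-type Q statistics and their heterogeneity/inconsistency split.

The whole-network statistic ``Q_net`` (weighted residual sum of squares about
the consistency-model GLS fit, weights ``W = S^{-1}``) decomposes exactly as

    Q_net = sum_d Q_het_d + Q_inc

where ``Q_het_d`` is the same statistic computed within design ``d`` only and
``Q_inc``, obtained by subtraction, is the part attributable to disagreement
between designs.  Matching the observed statistics to their expectations

    E[Q_het_d] = (n_d - 1) c_d + K_d tau_beta^2
    E[Q_net]   = sum_d n_d c_d - c + tau_beta^2 tr(B P1) + tau_omega^2 tr(B P2)

yields the two method-of-moments estimating equations; this module computes
all the pieces (Q statistics, degrees of freedom, ``K_d`` and the trace
constants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import NetworkError
from .network import Design, DesignMatrices, Network, as_design_matrices

__all__ = [
    "QDecomposition",
    "q_het_design",
    "k_constant",
    "q_net",
    "trace_constants",
    "decompose_q",
]

# Negative Q_inc beyond this is a logic error, not round-off.
_NEG_TOL = 1e-8


def _block_weights(S: np.ndarray, study_rows: tuple[slice, ...],
                   study_ids: tuple[str, ...] = ()) -> np.ndarray:
    """Block-diagonal ``W = S^{-1}``, inverting per study.

    Uses a Cholesky factorization per block so that an indefinite or singular
    within-study covariance fails loudly, naming the study.
    """
    W = np.zeros_like(S)
    for k, sl in enumerate(study_rows):
        block = S[sl, sl]
        try:
            L = np.linalg.cholesky(block)
        except np.linalg.LinAlgError:
            sid = study_ids[k] if study_ids else f"#{k}"
            raise np.linalg.LinAlgError(
                f"within-study covariance of study {sid} is not positive definite"
            ) from None
        ident = np.eye(block.shape[0])
        W[sl, sl] = np.linalg.solve(L.T, np.linalg.solve(L, ident))
    return W


def _stacked_identity(n_d: int, c_d: int) -> np.ndarray:
    """Design matrix of the within-design model: n_d stacked identities."""
    return np.tile(np.eye(c_d), (n_d, 1))


def q_het_design(y_d: np.ndarray, S_d: np.ndarray, X_d: np.ndarray) -> float:
    """Within-design Q: weighted RSS about the design-specific GLS mean.

    ``X_d`` is the stacked-identity design matrix; with a single study the
    fit is saturated and the statistic is exactly zero.
    """
    y_d = np.asarray(y_d, dtype=float)
    W_d = np.linalg.inv(S_d)
    n_rows, c_d = X_d.shape
    if n_rows == c_d:  # single study: saturated
        return 0.0
    M = X_d.T @ W_d @ X_d
    beta = np.linalg.solve(M, X_d.T @ (W_d @ y_d))
    r = y_d - X_d @ beta
    return float(r @ W_d @ r)


def k_constant(S_d: np.ndarray, X_d: np.ndarray, P1_d: np.ndarray) -> float:
    """Coefficient of tau_beta^2 in E[Q_het_d]: ``tr(B_d (I ⊗ P_{c_d}))``.

    ``B_d = W_d - W_d X_d (X_dᵀ W_d X_d)^{-1} X_dᵀ W_d``; zero when the
    design has a single study.
    """
    n_rows, c_d = X_d.shape
    if n_rows == c_d:
        return 0.0
    W_d = np.linalg.inv(S_d)
    WX = W_d @ X_d
    M = X_d.T @ WX
    B_d = W_d - WX @ np.linalg.solve(M, WX.T)
    return float(np.sum(B_d * P1_d))


def q_net(y: np.ndarray, S: np.ndarray, X: np.ndarray) -> float:
    """Whole-network Q about the consistency-model GLS fit (weights S^{-1})."""
    W = np.linalg.inv(S)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NetworkError("design matrix is rank deficient")
    WX = W @ X
    M = X.T @ WX
    delta = np.linalg.solve(M, WX.T @ y)
    r = y - X @ delta
    return float(r @ W @ r)


def trace_constants(
    data: Network | DesignMatrices, p2_override: np.ndarray | None = None
) -> tuple[float, float]:
    """``(tr(B P1), tr(B P2))`` with ``B = W - W X (XᵀWX)^{-1} XᵀW``.

    These are the coefficients of ``tau_beta^2`` and ``tau_omega^2`` in
    ``E[Q_net]``.  ``p2_override`` substitutes a restricted inconsistency
    structure (loop-inconsistency models).
    """
    dm = as_design_matrices(data)
    W = _block_weights(dm.S, dm.study_rows, dm.study_ids)
    WX = W @ dm.X
    M = dm.X.T @ WX
    B = W - WX @ np.linalg.solve(M, WX.T)
    P2 = dm.P2 if p2_override is None else p2_override
    return float(np.sum(B * dm.P1)), float(np.sum(B * P2))


@dataclass
class QDecomposition:
    """All Q statistics, degrees of freedom and moment constants for a fit."""

    q_net: float
    q_het_by_design: dict[Design, float]
    k_by_design: dict[Design, float]
    df_het: int
    df_net: int
    tr_bp1: float
    tr_bp2: float

    @property
    def sum_q_het(self) -> float:
        return float(sum(self.q_het_by_design.values()))

    @property
    def q_inc(self) -> float:
        """Inconsistency Q, obtained by subtraction (clipped at round-off)."""
        q = self.q_net - self.sum_q_het
        if q < -_NEG_TOL:
            raise AssertionError(f"Q_inc = {q} < 0: decomposition violated")
        return max(q, 0.0)

    @property
    def sum_k(self) -> float:
        return float(sum(self.k_by_design.values()))

    def table(self, n_d: dict[Design, int] | None = None) -> pd.DataFrame:
        """Per-design summary (design, Q_het, df, K_d)."""
        rows = []
        for d, q in self.q_het_by_design.items():
            rows.append(
                {
                    "design": d.label,
                    "c_d": d.c_d,
                    **({"n_d": n_d[d]} if n_d else {}),
                    "Q_het": q,
                    "K_d": self.k_by_design[d],
                }
            )
        return pd.DataFrame(rows)


def decompose_q(
    data: Network | DesignMatrices, p2_override: np.ndarray | None = None
) -> QDecomposition:
    """Compute the full Q decomposition and all moment constants.

    ``Q_inc = Q_net - sum Q_het >= 0`` because the within-design fits nest the
    network-wide consistency fit.  When every design has a single study the
    heterogeneity equation is degenerate (``sum K_d = 0``, df_het = 0); the
    estimation layer turns that into an identifiability error.
    """
    dm = as_design_matrices(data)
    W = _block_weights(dm.S, dm.study_rows, dm.study_ids)

    q_het: dict[Design, float] = {}
    k_d: dict[Design, float] = {}
    df_het = 0
    for g in dm.groups:
        rows = g.rows
        W_d = W[rows, rows]
        y_d = dm.y[rows]
        X_d = _stacked_identity(g.n_d, g.c_d)
        P1_d = dm.P1[rows, rows]
        if g.n_d == 1:
            q_het[g.design] = 0.0
            k_d[g.design] = 0.0
            continue
        M = X_d.T @ W_d @ X_d
        WX = W_d @ X_d
        beta = np.linalg.solve(M, WX.T @ y_d)
        r = y_d - X_d @ beta
        q_het[g.design] = float(r @ W_d @ r)
        B_d = W_d - WX @ np.linalg.solve(M, WX.T)
        k_d[g.design] = float(np.sum(B_d * P1_d))
        df_het += (g.n_d - 1) * g.c_d

    WX = W @ dm.X
    M = dm.X.T @ WX
    try:
        delta = np.linalg.solve(M, WX.T @ dm.y)
    except np.linalg.LinAlgError:
        raise NetworkError("X'WX is singular; network does not identify delta") from None
    r = dm.y - dm.X @ delta
    qn = float(r @ W @ r)
    B = W - WX @ np.linalg.solve(M, WX.T)
    P2 = dm.P2 if p2_override is None else p2_override
    tr_bp1 = float(np.sum(B * dm.P1))
    tr_bp2 = float(np.sum(B * P2))

    return QDecomposition(
        q_net=qn,
        q_het_by_design=q_het,
        k_by_design=k_d,
        df_het=df_het,
        df_net=dm.n_rows - dm.c,
        tr_bp1=tr_bp1,
        tr_bp2=tr_bp2,
    )
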