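"""Method-of-moments estimation of the two variance components.

The model has a between-study heterogeneity variance ``tau_beta^2`` (variance
of study-level deviations within a design) and an inconsistency variance
``tau_omega^2`` (variance of design-level deviations shared by all studies of
a design).  Both are estimated non-iteratively by matching two quadratic
forms to their expectations:

* first equation:   sum_d Q_het_d = df_het + tau_beta^2 sum_d K_d
* second equation:  Q_net = df_net + tau_beta^2 tr(B P1) + tau_omega^2 tr(B P2)

The untruncated solutions are unbiased but may be negative; they are
truncated at zero before any inference, extending the univariate
DerSimonian-Laird convention.  Three model families are supported:

* RI ("random-effects and inconsistent"): both variances estimated.
* RC ("random-effects and consistent"): tau_omega^2 = 0; tau_beta^2 is by
  default re-estimated from the network equation so that the inconsistency
  sum of squares is attributed to heterogeneity (more precise under
  consistency), with the heterogeneity-only variant available.
* CC ("common-effect and consistent"): both variances zero.

Loop-inconsistency variants restrict the inconsistency structure by zeroing
entries of ``P2`` and rerun the same pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import IdentifiabilityError
from .network import DesignMatrices, Network, as_design_matrices
from .qstats import QDecomposition, decompose_q

__all__ = [
    "MomentFit",
    "estimate_tau_beta",
    "estimate_tau_omega",
    "fit_full_model",
    "fit_consistency_model",
    "fit_common_effect_model",
    "fit_loop_inconsistency",
]

_TINY = 1e-12


@dataclass
class MomentFit:
    """Variance-component estimates and the Q decomposition behind them.

    ``tau_*_sq_untrunc`` are the raw moment solutions (possibly negative,
    unbiased under the model); ``tau_*_sq`` are truncated at zero and are
    what inference uses.  ``flags`` records truncations and degeneracies
    (``truncated_beta``, ``truncated_omega``, ``omega_inestimable``).
    """

    model: str  # "RI", "RC" or "CC"
    tau_beta_sq_untrunc: float
    tau_omega_sq_untrunc: float
    qdecomp: QDecomposition | None
    flags: frozenset[str] = field(default_factory=frozenset)
    p2_override: np.ndarray | None = None

    @property
    def tau_beta_sq(self) -> float:
        return max(self.tau_beta_sq_untrunc, 0.0)

    @property
    def tau_omega_sq(self) -> float:
        return max(self.tau_omega_sq_untrunc, 0.0)

    @property
    def inconsistency_ratio(self) -> float:
        """Ratio tau_omega^2 / tau_beta^2 of the truncated estimates.

        Used to judge the relative sizes of inconsistency and heterogeneity;
        NaN when the heterogeneity estimate is zero.
        """
        if self.tau_beta_sq <= 0.0:
            return float("nan")
        return self.tau_omega_sq / self.tau_beta_sq

    def to_dict(self) -> dict:
        """Flat key-value report of the fit."""
        out = {
            "model": self.model,
            "tau_beta_sq": self.tau_beta_sq,
            "tau_omega_sq": self.tau_omega_sq,
            "tau_beta_sq_untruncated": self.tau_beta_sq_untrunc,
            "tau_omega_sq_untruncated": self.tau_omega_sq_untrunc,
            "tau_beta": float(np.sqrt(self.tau_beta_sq)),
            "tau_omega": float(np.sqrt(self.tau_omega_sq)),
            "flags": sorted(self.flags),
        }
        if self.qdecomp is not None:
            out.update(
                {
                    "Q_net": self.qdecomp.q_net,
                    "Q_het": self.qdecomp.sum_q_het,
                    "Q_inc": self.qdecomp.q_inc,
                    "df_het": self.qdecomp.df_het,
                    "df_net": self.qdecomp.df_net,
                }
            )
        return out


def estimate_tau_beta(qdecomp: QDecomposition) -> float:
    """Untruncated heterogeneity variance from the within-design equation.

    ``tau_beta^2 = (sum Q_het - df_het) / sum K_d``.  Requires replication
    within at least one design (``sum K_d > 0``).
    """
    if qdecomp.sum_k <= _TINY:
        raise IdentifiabilityError(
            "no within-design replication: every design has a single study, "
            "so the between-study heterogeneity variance is not estimable"
        )
    return (qdecomp.sum_q_het - qdecomp.df_het) / qdecomp.sum_k


def estimate_tau_omega(qdecomp: QDecomposition, tau_beta_sq_untrunc: float) -> float:
    """Untruncated inconsistency variance from the network equation.

    ``tau_omega^2 = (Q_net - df_net - tau_beta^2 tr(B P1)) / tr(B P2)``,
    substituting the *untruncated* heterogeneity estimate.  A single-design
    network (or a fully zeroed inconsistency structure) has ``tr(B P2) = 0``
    and the variance is not estimable.
    """
    if qdecomp.tr_bp2 <= _TINY:
        raise IdentifiabilityError(
            "inconsistency variance is not estimable: tr(B P2) = 0 "
            "(no between-design information)"
        )
    return (
        qdecomp.q_net - qdecomp.df_net - tau_beta_sq_untrunc * qdecomp.tr_bp1
    ) / qdecomp.tr_bp2


def _flags_from(tb: float, tw: float, extra: set[str] | None = None) -> frozenset[str]:
    flags = set(extra or ())
    if tb < 0.0:
        flags.add("truncated_beta")
    if tw < 0.0:
        flags.add("truncated_omega")
    return frozenset(flags)


def fit_full_model(data: Network | DesignMatrices) -> MomentFit:
    """Fit the RI model: estimate both variance components, then truncate.

    For a single-design network the inconsistency variance is inestimable;
    it is set to zero with a warning so that the fit degrades gracefully to
    the classical DerSimonian-Laird analysis.
    """
    dm = as_design_matrices(data)
    qd = decompose_q(dm)
    tb = estimate_tau_beta(qd)
    extra: set[str] = set()
    try:
        tw = estimate_tau_omega(qd, tb)
    except IdentifiabilityError as err:
        warnings.warn(str(err) + "; setting tau_omega^2 = 0", stacklevel=2)
        tw = 0.0
        extra.add("omega_inestimable")
    return MomentFit(
        model="RI",
        tau_beta_sq_untrunc=tb,
        tau_omega_sq_untrunc=tw,
        qdecomp=qd,
        flags=_flags_from(tb, tw, extra),
    )


def fit_consistency_model(
    data: Network | DesignMatrices, method: str = "qnet"
) -> MomentFit:
    """Fit the RC model (``tau_omega^2`` constrained to zero).

    ``method="qnet"`` (default) solves the network equation with the
    constraint, ``tau_beta^2 = (Q_net - df_net) / tr(B P1)``: the sum of
    squares that the RI model would attribute to inconsistency is attributed
    to heterogeneity, which is the more precise choice when consistency
    holds.  ``method="het"`` keeps the within-design estimator instead
    ("het-only"), which makes a fitted RI model collapse to this RC fit
    whenever the RI inconsistency estimate is zero.
    """
    dm = as_design_matrices(data)
    qd = decompose_q(dm)
    if method == "qnet":
        if qd.tr_bp1 <= _TINY:
            raise IdentifiabilityError(
                "tr(B P1) = 0: heterogeneity variance is not estimable"
            )
        tb = (qd.q_net - qd.df_net) / qd.tr_bp1
    elif method == "het":
        tb = estimate_tau_beta(qd)
    else:
        raise ValueError(f"method must be 'qnet' or 'het', got {method!r}")
    extra = {"collapsed_to_cc"} if tb <= 0.0 else set()
    return MomentFit(
        model="RC",
        tau_beta_sq_untrunc=tb,
        tau_omega_sq_untrunc=0.0,
        qdecomp=qd,
        flags=_flags_from(tb, 0.0, extra),
    )


def fit_common_effect_model(data: Network | DesignMatrices) -> MomentFit:
    """Fit the CC model: both variance components fixed at zero (V = S)."""
    dm = as_design_matrices(data)
    qd = decompose_q(dm)
    return MomentFit(
        model="CC",
        tau_beta_sq_untrunc=0.0,
        tau_omega_sq_untrunc=0.0,
        qdecomp=qd,
    )


def _validate_p2_override(dm: DesignMatrices, p2: np.ndarray) -> np.ndarray:
    p2 = np.asarray(p2, dtype=float)
    if p2.shape != dm.P2.shape:
        raise ValueError(f"P2 override has shape {p2.shape}, expected {dm.P2.shape}")
    if not np.allclose(p2, p2.T):
        raise ValueError("P2 override must be symmetric")
    allowed = np.isclose(p2, 0.0) | np.isclose(p2, 0.5) | np.isclose(p2, 1.0)
    if not allowed.all():
        raise ValueError("P2 override entries must lie in {0, 1/2, 1}")
    if np.any((dm.P2 == 0.0) & (p2 != 0.0)):
        raise ValueError(
            "P2 override must be zero wherever the rows belong to different designs"
        )
    return p2


def fit_loop_inconsistency(
    data: Network | DesignMatrices, p2_override: np.ndarray
) -> MomentFit:
    """Fit with a restricted inconsistency structure.

    Loop-inconsistency models keep a subset of the design-by-treatment
    inconsistency terms; zeroing the corresponding entries of ``P2`` and
    rerunning the moment pipeline fits them with random inconsistency
    effects.  The ratio of the two point estimates
    (:attr:`MomentFit.inconsistency_ratio`) compares their magnitudes.
    """
    dm = as_design_matrices(data)
    p2 = _validate_p2_override(dm, p2_override)
    qd = decompose_q(dm, p2_override=p2)
    tb = estimate_tau_beta(qd)
    extra: set[str] = set()
    try:
        tw = estimate_tau_omega(qd, tb)
    except IdentifiabilityError as err:
        warnings.warn(str(err) + "; setting tau_omega^2 = 0", stacklevel=2)
        tw = 0.0
        extra.add("omega_inestimable")
    return MomentFit(
        model="RI",
        tau_beta_sq_untrunc=tb,
        tau_omega_sq_untrunc=tw,
        qdecomp=qd,
        flags=_flags_from(tb, tw, extra),
        p2_override=p2,
    )
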