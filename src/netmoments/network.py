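"""Contrast-based network meta-analysis data structures.

A network meta-analysis compares several treatments using trials that each
compare a subset of them.  Data enter in contrast form: every study of design
``d`` (the *design* is the set of treatments the study compares) contributes a
vector of ``c_d = |d| - 1`` estimated treatment effects of the non-baseline
treatments relative to the design's baseline treatment, together with a fixed,
known within-study covariance matrix.  Treatments are ordered
lexicographically and the first treatment overall is the reference ``A``; the
``c`` basic parameters are the average effects of every other treatment
relative to the reference.

This module holds the domain types (:class:`Design`, :class:`Study`,
:class:`Network`) and builds the matrices used throughout estimation: the
basic-parameter design matrix ``X``, the between-study correlation structure
``P1`` (block diagonal by study), the inconsistency structure ``P2`` (block
diagonal by design) and the block-diagonal within-study covariance ``S``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import NetworkError

__all__ = [
    "pcd_matrix",
    "Design",
    "canonicalize_design",
    "Study",
    "Network",
    "DesignGroup",
    "DesignMatrices",
    "build_design_matrices",
    "as_design_matrices",
    "reexpress_contrasts",
]


def pcd_matrix(c_d: int) -> np.ndarray:
    """Correlation-structure matrix with ones on the diagonal, halves off it.

    ``P_{c_d} = (I + J) / 2`` is symmetric positive definite (smallest
    eigenvalue 1/2) and encodes the standard assumption of a common
    heterogeneity (or inconsistency) variance for every treatment comparison.
    """
    if not float(c_d).is_integer() or c_d < 1:
        raise ValueError(f"c_d must be a positive integer, got {c_d!r}")
    c_d = int(c_d)
    return 0.5 * (np.eye(c_d) + np.ones((c_d, c_d)))


@dataclass(frozen=True, order=True)
class Design:
    """The unordered set of treatments compared by a trial.

    Two studies share a design iff their treatment sets are equal.  The
    baseline is the lexicographically first treatment; contrasts are the
    remaining treatments in lexicographic order, each compared to baseline.
    """

    treatments: tuple[str, ...]

    def __post_init__(self) -> None:
        ts = self.treatments
        if len(ts) < 2:
            raise ValueError(f"a design needs at least two treatments, got {ts!r}")
        if list(ts) != sorted(set(ts)):
            raise ValueError(
                f"design treatments must be unique and sorted, got {ts!r}; "
                "use canonicalize_design()"
            )

    @property
    def baseline(self) -> str:
        return self.treatments[0]

    @property
    def others(self) -> tuple[str, ...]:
        """Non-baseline treatments, in contrast order."""
        return self.treatments[1:]

    @property
    def c_d(self) -> int:
        """Number of contrasts contributed per study of this design."""
        return len(self.treatments) - 1

    @property
    def label(self) -> str:
        return "".join(self.treatments) if all(len(t) == 1 for t in self.treatments) else "|".join(self.treatments)

    def contrasts(self) -> list[tuple[str, str]]:
        return [(self.baseline, t) for t in self.others]


def canonicalize_design(treatment_set: Iterable[str]) -> Design:
    """Build a :class:`Design` from any iterable of treatment labels.

    Labels are case-sensitive strings ordered by lexicographic byte order;
    the first becomes the design baseline.  Duplicate labels are collapsed
    (a multi-arm study with a repeated treatment category is not supported
    and must be rejected upstream).
    """
    ts = sorted({str(t) for t in treatment_set})
    if len(ts) < 2:
        raise ValueError(f"a design needs at least two distinct treatments, got {ts!r}")
    return Design(tuple(ts))


@dataclass(eq=False)
class Study:
    """One trial: contrast estimates ``y`` and within-study covariance ``S``.

    ``y[k]`` is the estimated effect of ``design.others[k]`` relative to the
    design baseline.  ``S`` is treated as fixed and known; it must be
    symmetric positive definite.
    """

    id: str
    design: Design
    y: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        c_d = self.design.c_d
        self.y = np.asarray(self.y, dtype=float).reshape(-1)
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if self.y.shape != (c_d,):
            raise ValueError(
                f"study {self.id!r}: y has length {self.y.size}, expected {c_d}"
            )
        if self.S.shape != (c_d, c_d):
            raise ValueError(
                f"study {self.id!r}: S has shape {self.S.shape}, expected {(c_d, c_d)}"
            )
        if not np.allclose(self.S, self.S.T, rtol=1e-10, atol=1e-12):
            raise ValueError(f"study {self.id!r}: S is not symmetric")
        try:
            np.linalg.cholesky(self.S)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"study {self.id!r}: S is not positive definite"
            ) from None


class Network:
    """A connected contrast-based network meta-analysis dataset.

    Studies are grouped by design (designs in order of first appearance,
    studies in input order within a design).  The treatment list is the
    lexicographically sorted union of all design treatment sets, and the
    reference treatment is the first entry.
    """

    def __init__(self, studies: Sequence[Study]):
        studies = list(studies)
        if not studies:
            raise NetworkError("a network needs at least one study")
        ids = [s.id for s in studies]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate study ids: {dupes}")

        self.treatments: tuple[str, ...] = tuple(
            sorted({t for s in studies for t in s.design.treatments})
        )
        self.reference: str = self.treatments[0]
        self.c: int = len(self.treatments) - 1
        if self.c < 1:
            raise NetworkError("a network needs at least two treatments")

        self.designs: list[Design] = []
        by_design: dict[Design, list[Study]] = {}
        for s in studies:
            if s.design not in by_design:
                self.designs.append(s.design)
                by_design[s.design] = []
            by_design[s.design].append(s)
        self._by_design = by_design
        self.studies: list[Study] = [s for d in self.designs for s in by_design[d]]
        self.D: int = len(self.designs)
        self.n_d: dict[Design, int] = {d: len(by_design[d]) for d in self.designs}
        self.n_rows: int = sum(s.design.c_d for s in self.studies)

        self._check_connected()

    def design_studies(self, design: Design) -> list[Study]:
        return list(self._by_design[design])

    def _check_connected(self) -> None:
        # Union-find over treatments; every design merges its members.
        parent = {t: t for t in self.treatments}

        def find(t: str) -> str:
            while parent[t] != t:
                parent[t] = parent[parent[t]]
                t = parent[t]
            return t

        for d in self.designs:
            root = find(d.treatments[0])
            for t in d.treatments[1:]:
                parent[find(t)] = root
        ref_root = find(self.reference)
        stray = sorted(t for t in self.treatments if find(t) != ref_root)
        if stray:
            raise NetworkError(
                "network is disconnected: treatments "
                f"{stray} are not linked to the reference {self.reference!r} "
                "through any chain of shared designs"
            )

    def __repr__(self) -> str:
        return (
            f"Network({len(self.studies)} studies, {self.D} designs, "
            f"{len(self.treatments)} treatments, reference {self.reference!r})"
        )


def reexpress_contrasts(
    treatments: Iterable[str],
    y: np.ndarray,
    S: np.ndarray,
    old_base: str,
    new_base: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Re-express a study's contrasts against a different baseline treatment.

    Contrasts against a baseline ``b`` are stored for the remaining
    treatments in lexicographic order.  Switching baseline is the nonsingular
    linear map ``y'_t = y_t - y_{b'}`` (with the convention ``y_b = 0``);
    the covariance transforms as ``T S Tᵀ``.  All fitted quantities are
    invariant to this choice.
    """
    ts = sorted({str(t) for t in treatments})
    if old_base not in ts or new_base not in ts:
        raise ValueError(f"baselines must belong to the design {ts!r}")
    old_others = [t for t in ts if t != old_base]
    new_others = [t for t in ts if t != new_base]
    y = np.asarray(y, dtype=float).reshape(-1)
    S = np.atleast_2d(np.asarray(S, dtype=float))
    T = np.zeros((len(new_others), len(old_others)))
    for i, t in enumerate(new_others):
        if t != old_base:
            T[i, old_others.index(t)] += 1.0
        if new_base != old_base:
            T[i, old_others.index(new_base)] -= 1.0
    return T @ y, T @ S @ T.T


@dataclass(frozen=True)
class DesignGroup:
    """Row bookkeeping for one design inside the stacked system."""

    design: Design
    rows: slice
    study_rows: tuple[slice, ...]

    @property
    def n_d(self) -> int:
        return len(self.study_rows)

    @property
    def c_d(self) -> int:
        return self.design.c_d


@dataclass
class DesignMatrices:
    """Stacked matrices for the marginal model of the whole network.

    ``y ~ N(X delta, S + tau_beta^2 P1 + tau_omega^2 P2)`` where ``delta``
    holds the ``c`` basic parameters.  ``P1`` has study-diagonal blocks
    ``P_{c_d}``; ``P2`` has design-diagonal blocks ``J_{n_d} (x) P_{c_d}``
    (1 for the same contrast, 1/2 for different contrasts within a design,
    0 across designs).
    """

    treatments: tuple[str, ...]
    X: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    S: np.ndarray
    y: np.ndarray
    groups: tuple[DesignGroup, ...]
    study_rows: tuple[slice, ...] = field(default=())
    study_ids: tuple[str, ...] = field(default=())

    @property
    def reference(self) -> str:
        return self.treatments[0]

    @property
    def c(self) -> int:
        return len(self.treatments) - 1

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def basic_labels(self) -> tuple[str, ...]:
        ref = self.reference
        return tuple(f"{ref}{t}" for t in self.treatments[1:])


def build_design_matrices(network: Network) -> DesignMatrices:
    """Assemble ``X``, ``P1``, ``P2``, ``S`` and the stacked ``y``.

    Row order follows the network's study order (grouped by design).  A row
    for the contrast baseline ``b`` -> treatment ``t`` of some study has +1
    in the column of ``t`` (unless ``t`` is the reference) and -1 in the
    column of ``b`` (unless ``b`` is the reference), expressing the
    consistency relation ``delta_d = (delta^{At} - delta^{Ab}, ...)``.
    """
    n = network.n_rows
    c = network.c
    col = {t: k - 1 for k, t in enumerate(network.treatments)}

    X = np.zeros((n, c))
    P1 = np.zeros((n, n))
    P2 = np.zeros((n, n))
    S = np.zeros((n, n))
    y = np.zeros(n)

    groups: list[DesignGroup] = []
    study_rows: list[slice] = []
    study_ids: list[str] = []
    r = 0
    for d in network.designs:
        studies = network.design_studies(d)
        c_d = d.c_d
        d_start = r
        pcd = pcd_matrix(c_d)
        d_rows: list[slice] = []
        for s in studies:
            sl = slice(r, r + c_d)
            d_rows.append(sl)
            study_rows.append(sl)
            study_ids.append(s.id)
            y[sl] = s.y
            S[sl, sl] = s.S
            P1[sl, sl] = pcd
            for k, t in enumerate(d.others):
                if t != network.reference:
                    X[r + k, col[t]] += 1.0
                if d.baseline != network.reference:
                    X[r + k, col[d.baseline]] -= 1.0
            r += c_d
        d_slice = slice(d_start, r)
        # J_{n_d} (x) P_{c_d}: same contrast -> 1, different contrast -> 1/2
        P2[d_slice, d_slice] = np.tile(pcd, (len(studies), len(studies)))
        groups.append(DesignGroup(d, d_slice, tuple(d_rows)))

    if np.linalg.matrix_rank(X) < c:
        raise NetworkError(
            "design matrix is rank deficient; the network does not identify "
            "all basic parameters"
        )

    return DesignMatrices(
        treatments=network.treatments,
        X=X,
        P1=P1,
        P2=P2,
        S=S,
        y=y,
        groups=tuple(groups),
        study_rows=tuple(study_rows),
        study_ids=tuple(study_ids),
    )


def as_design_matrices(obj: Network | DesignMatrices) -> DesignMatrices:
    """Accept either a :class:`Network` or prebuilt :class:`DesignMatrices`."""
    if isinstance(obj, DesignMatrices):
        return obj
    if isinstance(obj, Network):
        return build_design_matrices(obj)
    raise TypeError(f"expected Network or DesignMatrices, got {type(obj).__name__}")
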