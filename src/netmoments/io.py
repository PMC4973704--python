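"""Reading and writing contrast tables, and report formatting.

The canonical input is a long-format contrast CSV with columns ``study,
base, treat, y, v``: one row per estimated treatment effect (``treat``
versus ``base``) with its variance ``v``.  Multi-arm studies share a
baseline arm, so their contrasts are correlated; the off-diagonal
covariances must be supplied in a second CSV with columns ``study, treat_i,
treat_j, cov``.  A helper converts arm-level 2x2 counts for binary outcomes
into this format (log odds ratios, with the within-study covariance equal
to the variance of the log odds in the baseline arm).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import MomentFit
from .inference import GLSResult, confidence_intervals
from .network import Network, Study, canonicalize_design, reexpress_contrasts

__all__ = [
    "read_contrast_table",
    "write_contrast_table",
    "contrasts_from_binary_arms",
    "fit_report",
    "format_fit_report",
]

_CONTRAST_COLS = ("study", "base", "treat", "y", "v")
_COV_COLS = ("study", "treat_i", "treat_j", "cov")


def read_contrast_table(
    path: str | Path, cov_path: str | Path | None = None
) -> Network:
    """Load a contrast CSV (plus optional covariance CSV) into a Network.

    Within a study all rows must share the same ``base``.  If the supplied
    base is not the lexicographically first treatment of the design, the
    contrasts are re-expressed against the canonical baseline (an exact
    linear map; the fit is invariant).  Every study with three or more arms
    must have covariance rows for all its contrast pairs.
    """
    df = pd.read_csv(path, dtype={"study": str, "base": str, "treat": str})
    missing = [c for c in _CONTRAST_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"contrast table is missing columns {missing}")
    dupes = df.duplicated(subset=["study", "base", "treat"])
    if dupes.any():
        bad = df.loc[dupes, ["study", "base", "treat"]].to_records(index=False)
        raise ValueError(f"duplicate (study, base, treat) rows: {list(bad)}")
    if (df["base"] == df["treat"]).any():
        bad = df.loc[df["base"] == df["treat"], "study"].tolist()
        raise ValueError(f"treat equals base in studies {bad}")

    cov = None
    if cov_path is not None:
        cov = pd.read_csv(
            cov_path, dtype={"study": str, "treat_i": str, "treat_j": str}
        )
        missing = [c for c in _COV_COLS if c not in cov.columns]
        if missing:
            raise ValueError(f"covariance table is missing columns {missing}")

    studies = []
    for sid, g in df.groupby("study", sort=False):
        bases = g["base"].unique()
        if len(bases) != 1:
            raise ValueError(f"study {sid!r} mixes baselines {sorted(bases)}")
        base = bases[0]
        treats = sorted(g["treat"])
        if len(set(treats)) != len(treats):
            raise ValueError(f"study {sid!r} repeats a treatment")
        arms = {base, *treats}
        design = canonicalize_design(arms)
        # contrasts in the supplied base's order
        y = g.set_index("treat").loc[treats, "y"].to_numpy(dtype=float)
        S = np.diag(g.set_index("treat").loc[treats, "v"].to_numpy(dtype=float))
        c_d = len(treats)
        if c_d > 1:
            if cov is None:
                raise ValueError(
                    f"study {sid!r} has {c_d + 1} arms but no covariance table "
                    "was supplied"
                )
            rows = cov[cov["study"] == sid]
            pos = {t: k for k, t in enumerate(treats)}
            seen = set()
            for _, row in rows.iterrows():
                ti, tj = row["treat_i"], row["treat_j"]
                if ti not in pos or tj not in pos:
                    raise ValueError(
                        f"covariance row for study {sid!r} names treatment "
                        f"{ti!r}/{tj!r} not among its contrasts {treats}"
                    )
                S[pos[ti], pos[tj]] = S[pos[tj], pos[ti]] = float(row["cov"])
                seen.add(frozenset((ti, tj)))
            need = {
                frozenset((a, b))
                for i, a in enumerate(treats)
                for b in treats[i + 1 :]
            }
            if need - seen:
                missing_pairs = sorted(tuple(sorted(p)) for p in need - seen)
                raise ValueError(
                    f"study {sid!r} is missing covariance rows for pairs "
                    f"{missing_pairs}"
                )
        if base != design.baseline:
            y, S = reexpress_contrasts(arms, y, S, base, design.baseline)
        studies.append(Study(id=str(sid), design=design, y=y, S=S))
    return Network(studies)


def write_contrast_table(
    network: Network,
    path: str | Path,
    cov_path: str | Path | None = None,
) -> None:
    """Write a Network back to the canonical CSV pair (round-trip exact)."""
    rows, cov_rows = [], []
    for s in network.studies:
        others = s.design.others
        for k, t in enumerate(others):
            rows.append(
                {
                    "study": s.id,
                    "base": s.design.baseline,
                    "treat": t,
                    "y": s.y[k],
                    "v": s.S[k, k],
                }
            )
        for i in range(len(others)):
            for j in range(i + 1, len(others)):
                cov_rows.append(
                    {
                        "study": s.id,
                        "treat_i": others[i],
                        "treat_j": others[j],
                        "cov": s.S[i, j],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
    if cov_path is not None:
        pd.DataFrame(cov_rows, columns=list(_COV_COLS)).to_csv(cov_path, index=False)
    elif cov_rows:
        raise ValueError(
            "network contains multi-arm studies; a cov_path is required to "
            "preserve their covariances"
        )


def contrasts_from_binary_arms(arms: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build contrast and covariance tables from binary arm-level counts.

    ``arms`` needs columns ``study, treat, events, total``.  Per study the
    baseline is the lexicographically first treatment; effects are log odds
    ratios versus baseline, variances the usual 1/a + 1/b + 1/c + 1/d, and
    the covariance between two contrasts of the same study is the variance
    of the log odds in the shared baseline arm.  If any cell of a study is
    zero, 0.5 is added to every cell of that study (continuity correction).
    """
    need = {"study", "treat", "events", "total"}
    if not need.issubset(arms.columns):
        raise ValueError(f"arm table needs columns {sorted(need)}")
    rows, cov_rows = [], []
    for sid, g in arms.groupby("study", sort=False):
        g = g.sort_values("treat")
        if g["treat"].duplicated().any():
            raise ValueError(f"study {sid!r} repeats a treatment arm")
        e = g["events"].to_numpy(dtype=float)
        n = g["total"].to_numpy(dtype=float)
        if np.any(e == 0) or np.any(e == n):
            e = e + 0.5
            n = n + 1.0
        logodds = np.log(e / (n - e))
        var_lo = 1.0 / e + 1.0 / (n - e)
        treats = g["treat"].tolist()
        base, base_var, base_lo = treats[0], var_lo[0], logodds[0]
        for k in range(1, len(treats)):
            rows.append(
                {
                    "study": sid,
                    "base": base,
                    "treat": treats[k],
                    "y": logodds[k] - base_lo,
                    "v": var_lo[k] + base_var,
                }
            )
        for i in range(1, len(treats)):
            for j in range(i + 1, len(treats)):
                cov_rows.append(
                    {
                        "study": sid,
                        "treat_i": treats[i],
                        "treat_j": treats[j],
                        "cov": base_var,
                    }
                )
    return (
        pd.DataFrame(rows, columns=list(_CONTRAST_COLS)),
        pd.DataFrame(cov_rows, columns=list(_COV_COLS)),
    )


def fit_report(
    network: Network,
    fit: MomentFit,
    gls: GLSResult,
    level: float = 0.95,
    i2: dict | None = None,
) -> dict:
    """JSON-serializable summary of a fitted model."""
    ci = confidence_intervals(gls, level)
    report = {
        "network": {
            "studies": len(network.studies),
            "designs": network.D,
            "treatments": list(network.treatments),
            "reference": network.reference,
            "n_contrasts": network.n_rows,
        },
        "fit": fit.to_dict(),
        "level": level,
        "estimates": ci.to_dict(orient="records"),
    }
    if i2 is not None:
        report["I2"] = {
            key: {"R": imp.R, "I2_percent": imp.I2} for key, imp in i2.items()
        }
    return report


def _sig(x: float, digits: int = 4) -> str:
    return f"{x:.{digits}g}"


def format_fit_report(report: dict) -> str:
    """Human-readable text rendering (4 significant figures)."""
    net, fit = report["network"], report["fit"]
    lines = [
        f"Network: {net['studies']} studies, {net['designs']} designs, "
        f"{len(net['treatments'])} treatments (reference {net['reference']})",
        f"Model: {fit['model']}",
        f"tau_beta^2  = {_sig(fit['tau_beta_sq'])} "
        f"(untruncated {_sig(fit['tau_beta_sq_untruncated'])})",
        f"tau_omega^2 = {_sig(fit['tau_omega_sq'])} "
        f"(untruncated {_sig(fit['tau_omega_sq_untruncated'])})",
    ]
    if fit.get("flags"):
        lines.append(f"flags: {', '.join(fit['flags'])}")
    if "Q_net" in fit:
        lines.append(
            f"Q_net = {_sig(fit['Q_net'])} (df {fit['df_net']}), "
            f"Q_het = {_sig(fit['Q_het'])} (df {fit['df_het']}), "
            f"Q_inc = {_sig(fit['Q_inc'])}"
        )
    pct = 100 * report["level"]
    lines.append(f"Basic parameters ({pct:g}% CI):")
    for row in report["estimates"]:
        lines.append(
            f"  {row['parameter']}: {_sig(row['estimate'])} "
            f"(SE {_sig(row['se'])}) "
            f"[{_sig(row['lower'])}, {_sig(row['upper'])}]"
        )
    if "I2" in report:
        for key, val in report["I2"].items():
            lines.append(
                f"I2 {key.replace('_vs_', ' vs ')}: {val['I2_percent']:.0f}% "
                f"(R = {_sig(val['R'])})"
            )
    return "\n".join(lines)


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
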