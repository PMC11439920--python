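"""Pre/post contrasts, effect sizes, and power statistics.

The contrast layer on top of the per-subject alignment values: paired
(within-group) t-tests on post-minus-pre subject ISC, Welch tests on summary
scores, Cohen's d conversions for both designs, and the sensitivity power
analysis (minimal detectable paired effect size via the noncentral t
distribution).

Within-group pre/post tests are paired — one-sample t on the differences
with df = n - 1 — which is what the reported degrees of freedom of the
emulated analysis imply. Between-group comparisons of MCCA values are
deliberately not offered: values from different MCCA models are not
comparable, so only within-group contrasts and summary-score Welch tests
exist here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .alignment import fdr_adjust

__all__ = [
    "SummaryStats",
    "paired_t",
    "welch_t",
    "cohens_d_from_t",
    "cohens_d_pooled",
    "sensitivity_power",
    "two_tailed_p",
    "build_contrast_table",
    "PairingError",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean, standard deviation, and sample size of one group's measure."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")
        if self.n < 2:
            raise ValueError("need at least 2 observations")


class PairingError(ValueError):
    """Pre/post subject rows cannot be matched."""


def two_tailed_p(t: float, df: float) -> float:
    """p = 2 * P(T > |t|) under Student's t with ``df`` degrees of freedom."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * sps.t.sf(abs(t), df))


def paired_t(diffs: np.ndarray) -> tuple[float, int, float]:
    """One-sample t-test on paired differences.

    Returns (t, df, two-sided p) with df = n - 1.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences contain non-finite values")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: zero variance in the differences")
    n = d.size
    t = float(d.mean() / (sd / np.sqrt(n)))
    return t, n - 1, two_tailed_p(t, n - 1)


def welch_t(a: SummaryStats, b: SummaryStats) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("degenerate input: zero variance in both groups")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(t), float(df), two_tailed_p(t, df)


def cohens_d_from_t(t: float, n: int) -> float:
    """Within-subject effect size d = t / sqrt(n) for a paired design."""
    if n < 2:
        raise ValueError("need at least 2 subjects")
    return float(t / np.sqrt(n))


def cohens_d_pooled(a: SummaryStats, b: SummaryStats) -> float:
    """Between-group Cohen's d with the pooled standard deviation."""
    s2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if s2 == 0:
        raise ValueError("degenerate input: pooled standard deviation is zero")
    return float((a.mean - b.mean) / np.sqrt(s2))


def _paired_power(d: float, n: int, alpha: float, two_sided: bool) -> float:
    """Power of a one-sample (paired) t-test at effect size d."""
    df = n - 1
    nc = d * np.sqrt(n)
    if two_sided:
        crit = sps.t.ppf(1 - alpha / 2, df)
        # the opposite-tail term underflows scipy's nct for large nc (it is
        # ~1e-25 there); treat non-finite as zero
        lower = sps.nct.cdf(-crit, df, nc)
        if not np.isfinite(lower):
            lower = 0.0
        return float(sps.nct.sf(crit, df, nc) + lower)
    crit = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(crit, df, nc))


def sensitivity_power(
    n: int,
    alpha: float = 0.05,
    power: float = 0.80,
    two_sided: bool = True,
) -> float:
    """Minimal detectable paired effect size (Cohen's d) at given n.

    Solves for the d whose noncentrality d * sqrt(n) gives the requested
    power for a one-sample t-test at the (two-sided by default) alpha.
    Root-finding tolerance 1e-6.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if not (0 < power < 1):
        raise ValueError("power must be in (0, 1)")
    if power <= alpha:
        raise ValueError("requested power must exceed the type-I rate alpha")
    f = lambda d: _paired_power(d, n, alpha, two_sided) - power
    hi = 1.0
    while f(hi) < 0:
        hi *= 2
        if hi > 1e3:
            raise RuntimeError("power target unreachable")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-6))


def build_contrast_table(subject_table: pd.DataFrame) -> pd.DataFrame:
    """Pre/post paired contrasts per (group, condition) from subject ISC.

    Expects the long-format per-subject table produced by
    :func:`neuralign.alignment.analyze_study` with columns ``group``,
    ``session``, ``condition``, ``subject``, ``isc`` (and optionally
    ``version``, averaged out per subject first). Returns one row per
    group x condition with t, df, two-sided p, paired Cohen's d, n, and a
    BH-adjusted p column across all rows.
    """
    required = {"group", "session", "condition", "subject", "isc"}
    missing = required - set(subject_table.columns)
    if missing:
        raise ValueError(f"subject table lacks columns: {sorted(missing)}")
    df = (
        subject_table.groupby(
            ["group", "condition", "session", "subject"], as_index=False
        )["isc"].mean()
    )
    rows = []
    for (group, condition), sub in df.groupby(["group", "condition"]):
        wide = sub.pivot(index="subject", columns="session", values="isc")
        for session in ("pre", "post"):
            if session not in wide.columns:
                raise PairingError(
                    f"{group}/{condition}: no {session!r} session rows"
                )
        unmatched = wide.index[wide.isna().any(axis=1)].tolist()
        if unmatched:
            raise PairingError(
                f"{group}/{condition}: subjects without both sessions: "
                f"{unmatched}"
            )
        diffs = (wide["post"] - wide["pre"]).to_numpy()
        t, dof, p = paired_t(diffs)
        rows.append(
            dict(
                group=group,
                condition=condition,
                contrast="post-pre",
                t=t,
                df=dof,
                p=p,
                cohens_d=cohens_d_from_t(t, diffs.size),
                n=diffs.size,
                test="paired",
            )
        )
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_adjust(table["p"]).adjusted
    return table
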