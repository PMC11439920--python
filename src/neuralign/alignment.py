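"""Cross-validated intersubject correlation of canonical components.

The alignment statistic: split each condition's recordings into k contiguous
folds; for each fold, fit MAXVAR MCCA on the other folds, project the held-out
fold, compute all pairwise Pearson correlations of each canonical component
across subjects, pool them with Fisher's z, and keep the component with the
strongest pooled test-set correlation. Folds are combined by averaging the
absolute pooled values. Significance comes from a circular-shift bootstrap:
each subject's held-out variates are rotated by an independent random lag —
preserving autocorrelation, destroying cross-subject temporal alignment — and
the full statistic (including the per-fold component selection) is recomputed
for every draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import mcca
from .preprocess import fit_pca, apply_pca

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "FoldResult",
    "AlignmentResult",
    "CellPValueSet",
    "make_folds",
    "crossval_alignment",
    "fisher_pool",
    "inverse_fisher",
    "circular_null",
    "p_from_null",
    "fdr_adjust",
    "subject_isc",
    "analyze_study",
]

R_CLIP = 1.0 - 1e-12  # guard before arctanh


@dataclass(frozen=True)
class FoldPlan:
    """Contiguous, non-overlapping sample ranges partitioning [0, t)."""

    k: int
    boundaries: tuple[tuple[int, int], ...]


@dataclass
class FoldResult:
    """One cross-validation fold's test-set alignment."""

    component: int                 # selected (strongest pooled |z|) component
    corr: np.ndarray               # (M, M) pairwise Pearson r, selected comp
    zbar: float                    # pooled Fisher z over unordered pairs
    subject_z: np.ndarray          # (M,) per-subject mean Fisher z
    zbar_all: np.ndarray           # pooled z per component (selection trace)
    test_variates: np.ndarray      # (M, n_components, t_fold)
    excluded_pairs: int = 0        # pairs dropped for constant variates


@dataclass
class AlignmentResult:
    """Cross-validated intersubject correlation for one condition cell."""

    subjects: list[str]
    folds: list[FoldResult]
    combined: float                      # mean over folds of |zbar|
    subject_values: np.ndarray           # per-subject combined Fisher z
    labels: dict = field(default_factory=dict)
    null: np.ndarray | None = None
    p_value: float | None = None

    @property
    def r_equivalent(self) -> float:
        """The combined statistic mapped back through the inverse Fisher
        transform (reported for significant cells)."""
        return inverse_fisher(self.combined)


@dataclass
class CellPValueSet:
    """Raw and multiplicity-adjusted p-values across condition cells."""

    raw: np.ndarray
    adjusted: np.ndarray
    procedure: str = "benjamini-hochberg"


def make_folds(t: int, k: int = 3) -> FoldPlan:
    """Partition [0, t) into k contiguous ranges with sizes differing <= 1."""
    if t < k:
        raise ValueError(f"cannot split {t} samples into {k} folds")
    base, rem = divmod(t, k)
    bounds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        bounds.append((start, start + size))
        start += size
    return FoldPlan(k=k, boundaries=tuple(bounds))


def fisher_pool(correlations: Iterable[float]) -> float:
    """Mean Fisher z over a set of correlations, |r| clipped to 1 - 1e-12."""
    rs = np.asarray(list(correlations), dtype=float)
    if rs.size == 0:
        raise ValueError("cannot pool an empty set of correlations")
    if np.any(np.abs(rs) > 1 + 1e-9):
        raise ValueError("correlations must lie in [-1, 1]")
    return float(np.mean(np.arctanh(np.clip(rs, -R_CLIP, R_CLIP))))


def inverse_fisher(z: float) -> float:
    """Inverse Fisher transform: z back to a correlation coefficient."""
    return float(np.tanh(z))


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean unit-variance rows; returns (standardized, valid mask)."""
    xc = x - x.mean(axis=-1, keepdims=True)
    sd = xc.std(axis=-1)
    valid = sd > 0
    sd_safe = np.where(valid, sd, 1.0)
    return xc / sd_safe[..., None], valid


def crossval_alignment(
    recordings: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    k: int = 3,
    n_components: int | None = None,
    pca_dim: int | None = None,
    labels: dict | None = None,
) -> AlignmentResult:
    """Cross-validated MCCA intersubject correlation for one cell.

    Per fold: per-subject PCA (optional, fit on the training samples only),
    MAXVAR fit on the training samples, projection of the held-out samples,
    pairwise Pearson correlations per component across subjects, Fisher-z
    pooling, and selection of the component with the strongest pooled
    test-set correlation (ties -> lowest index). Folds are combined by the
    mean of absolute pooled values; per-subject values combine each
    subject's mean Fisher z the same way.

    Pairs whose test variate is constant are excluded from pooling with a
    logged count.
    """
    if isinstance(recordings, Mapping):
        subjects = sorted(recordings.keys())
        mats = [np.asarray(recordings[s], dtype=float) for s in subjects]
    else:
        mats = [np.asarray(r, dtype=float) for r in recordings]
        subjects = [f"s{i}" for i in range(len(mats))]
    m = len(mats)
    if m < 2:
        raise ValueError("alignment needs at least 2 subjects")
    if m < 3:
        logger.warning("M=%d subjects: per-subject values are degenerate", m)
    t = mats[0].shape[1]
    if any(x.shape != mats[0].shape for x in mats):
        raise ValueError("all recordings in a cell must share one shape")

    plan = make_folds(t, k)
    folds: list[FoldResult] = []
    iu = np.triu_indices(m, 1)
    for start, end in plan.boundaries:
        train_idx = np.r_[0:start, end:t]
        trains, tests = [], []
        for x in mats:
            tr, te = x[:, train_idx], x[:, start:end]
            if pca_dim is not None:
                red = fit_pca(tr, pca_dim)
                tr, te = red.transform(tr), apply_pca(red, te)
            trains.append(tr)
            tests.append(te)
        model = mcca.fit_maxvar(
            trains, n_components=n_components, subjects=subjects,
            store_variates=False,
        )
        n_comp = model.n_components
        t_fold = end - start
        variates = np.stack(
            [mcca.project(model, te, s) for te, s in zip(tests, subjects)]
        )  # (M, n_comp, t_fold)
        std, valid = _standardize_rows(variates)
        # (n_comp, M, M) pairwise correlation per component
        corr = np.einsum("mct,nct->cmn", std, std) / t_fold
        excluded = 0
        zbar_all = np.empty(n_comp)
        subj_z_all = np.empty((n_comp, m))
        for c in range(n_comp):
            pv = valid[iu[0], c] & valid[iu[1], c]
            excluded += int((~pv).sum())
            rs = corr[c][iu][pv]
            zbar_all[c] = fisher_pool(rs) if rs.size else 0.0
            zmat = np.arctanh(np.clip(corr[c], -R_CLIP, R_CLIP))
            np.fill_diagonal(zmat, 0.0)
            subj_z_all[c] = zmat.sum(axis=1) / max(m - 1, 1)
        if excluded:
            logger.warning("excluded %d constant-variate pairs", excluded)
        sel = int(np.argmax(np.abs(zbar_all)))
        folds.append(
            FoldResult(
                component=sel,
                corr=corr[sel].copy(),
                zbar=float(zbar_all[sel]),
                subject_z=subj_z_all[sel].copy(),
                zbar_all=zbar_all,
                test_variates=variates,
                excluded_pairs=excluded,
            )
        )

    combined = float(np.mean([abs(f.zbar) for f in folds]))
    subject_values = np.mean(
        np.abs(np.stack([f.subject_z for f in folds])), axis=0
    )
    return AlignmentResult(
        subjects=subjects,
        folds=folds,
        combined=combined,
        subject_values=subject_values,
        labels=labels or {},
    )


def subject_isc(result: AlignmentResult) -> dict[str, float]:
    """Per-subject alignment: each subject's mean Fisher z with all others,
    combined across folds by the mean of absolute values. These scalars are
    what enters the pre/post contrast."""
    return dict(zip(result.subjects, result.subject_values.tolist()))


def circular_null(
    result: AlignmentResult,
    n_shuffles: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AlignmentResult:
    """Circular-shift bootstrap null for an alignment result (in place).

    For each draw and fold, every subject's held-out variates (all
    components) are circularly shifted by an independent uniform random lag
    in [1, t_fold - 1]; pairwise correlations, Fisher pooling, and the
    per-fold strongest-component selection are recomputed, and folds are
    combined exactly as for the observed statistic. Lag 0 is excluded by
    construction, so no draw equals the observed statistic by identity.

    Implemented exactly via FFT circular cross-correlation: the Pearson
    correlation of two circularly shifted standardized series is their
    circular cross-correlation at the lag difference.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = len(result.subjects)
    iu = np.triu_indices(m, 1)
    fold_nulls = []
    for fold in result.folds:
        variates = fold.test_variates            # (M, C, t)
        t_fold = variates.shape[-1]
        if t_fold < 2:
            raise ValueError("test segment shorter than 2 samples")
        std, valid = _standardize_rows(variates)
        f = np.fft.rfft(std, axis=-1)            # (M, C, F)
        # circular ccf c_ij[d] = (1/t) sum_n x_i[n] x_j[(n+d) % t]
        cross = np.conj(f[iu[0]]) * f[iu[1]]     # (P, C, F)
        ccf = np.fft.irfft(cross, n=t_fold, axis=-1) / t_fold
        lags = rng.integers(1, t_fold, size=(n_shuffles, m))
        dmat = (lags[:, iu[0]] - lags[:, iu[1]]) % t_fold   # (S, P)
        # gather r per draw/pair/component
        r = ccf[np.arange(len(iu[0]))[None, :, None],
                np.arange(variates.shape[1])[None, None, :],
                dmat[:, :, None]]                # (S, P, C)
        pv = (valid[iu[0]] & valid[iu[1]]).T     # (C, P) -> transpose below
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
        weights = pv.T[None, :, :]               # (1, P, C)
        denom = np.maximum(weights.sum(axis=1), 1)
        zbar = (z * weights).sum(axis=1) / denom     # (S, C)
        fold_nulls.append(np.max(np.abs(zbar), axis=1))  # selection per draw
    result.null = np.mean(np.stack(fold_nulls), axis=0)
    result.p_value = p_from_null(result.combined, result.null)
    return result


def p_from_null(observed: float, null_draws: np.ndarray) -> float:
    """One-sided exceedance p with the add-one rule:
    (1 + #{null >= observed}) / (1 + n_draws)."""
    null_draws = np.asarray(null_draws, dtype=float)
    if null_draws.size == 0:
        raise ValueError("need at least one null draw")
    return float((1 + np.sum(null_draws >= observed)) / (1 + null_draws.size))


def fdr_adjust(p_values: Iterable[float]) -> CellPValueSet:
    """Benjamini-Hochberg step-up adjustment across condition cells."""
    raw = np.asarray(list(p_values), dtype=float)
    if raw.size == 0:
        raise ValueError("no p-values to adjust")
    if np.any((raw < 0) | (raw > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(raw, method="fdr_bh")[1]
    return CellPValueSet(raw=raw, adjusted=adjusted)


def analyze_study(
    dataset,
    k: int = 3,
    n_components: int | None = None,
    pca_dim: int | None = None,
    n_shuffles: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the alignment analysis on every cell of a study.

    Returns ``(cells, subjects)`` tidy tables. ``cells`` has one row per
    (group, session, version, condition) with the combined statistic and —
    when ``n_shuffles > 0`` — the bootstrap p-value plus its BH-adjusted
    value across all analysed cells. ``subjects`` is the long-format
    per-subject ISC table consumed by the contrast layer.
    """
    cell_rows = []
    subj_rows = []
    for ci, (key, recs) in enumerate(dataset.iter_cells()):
        group, session, version, condition = key
        labels = dict(group=group, session=session, version=version,
                      condition=condition)
        res = crossval_alignment(recs, k=k, n_components=n_components,
                                 pca_dim=pca_dim, labels=labels)
        if n_shuffles > 0:
            cell_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(ci,))
            )
            circular_null(res, n_shuffles=n_shuffles, rng=cell_rng)
        row = dict(labels)
        row.update(
            combined_z=res.combined,
            r_equivalent=res.r_equivalent,
            p=res.p_value,
            **{f"zbar_fold{i}": f.zbar for i, f in enumerate(res.folds)},
            **{f"component_fold{i}": f.component for i, f in enumerate(res.folds)},
        )
        cell_rows.append(row)
        for s, v in subject_isc(res).items():
            subj_rows.append(dict(labels, subject=s, isc=v))
    cells = pd.DataFrame(cell_rows)
    if n_shuffles > 0:
        cells["p_fdr"] = fdr_adjust(cells["p"]).adjusted
    return cells, pd.DataFrame(subj_rows)
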