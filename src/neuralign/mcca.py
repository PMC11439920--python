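"""MAXVAR multiset canonical correlation analysis.

Given M subjects' (D, t) sensor (or PCA-space) matrices Z^m, find per-subject
spatial filters W^m such that the projections Y^m = W^m Z^m — the canonical
variates — are mutually uncorrelated within a subject and maximally
correlated across subjects. The MAXVAR cost is solved stagewise: each
subject's training data is whitened (with a relative eigenvalue floor), the
top eigenvector of the Gram matrix of the row-concatenated whitened data
gives the stage's per-subject directions, and each subject's block is then
deflated so later stages are exactly decorrelated within subject. For M = 2
this reproduces classic two-set CCA component by component.

Spatial-filter weights are not directly interpretable as sensor maps; the
forward-model conversion A = Sigma_z W' Sigma_y turns a component's filter
into its activation pattern in sensor space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .preprocess import PcaReduction

__all__ = ["MccaModel", "ActivationPattern", "fit_maxvar", "project",
           "activation_pattern"]

EIG_FLOOR = 1e-10  # relative eigenvalue floor for the whitening transform


@dataclass
class MccaModel:
    """Fitted MAXVAR model: one weight matrix per subject.

    ``weights[s]`` is (n_components, D) and maps that subject's centered
    data to canonical variates; ``whiteners[s]`` is the sphering transform
    the solution was computed in. Components are ordered by decreasing
    across-subject consistency (the stagewise MAXVAR eigenvalue) on the
    training data.
    """

    subjects: list[str]
    means: dict[str, np.ndarray]
    whiteners: dict[str, np.ndarray]
    weights: dict[str, np.ndarray]
    strength: np.ndarray            # per-component MAXVAR eigenvalue / M
    n_components: int
    training_variates: dict[str, np.ndarray] | None = None
    training_meta: dict = field(default_factory=dict)


@dataclass
class ActivationPattern:
    """Forward model of one canonical component for one subject.

    ``pattern`` lives in the model's input space (D,); ``channel_pattern``
    is the optional back-projection through the subject's PCA loadings to
    the original sensor space.
    """

    subject: str
    component: int
    pattern: np.ndarray
    channel_pattern: np.ndarray | None = None


class RankError(ValueError):
    """A dataset has lower numerical rank than the requested components."""


def _whiten(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and sphere a (D, t) matrix.

    Returns (mean, whitener K with K Zc having identity sample covariance,
    whitened data X). Directions whose eigenvalue falls below
    ``EIG_FLOOR`` times the largest are dropped.
    """
    mean = z.mean(axis=1)
    zc = z - mean[:, None]
    t = z.shape[1]
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    if s[0] == 0:
        raise RankError("dataset has zero variance")
    keep = (s ** 2) > (s[0] ** 2) * EIG_FLOOR
    k = np.sqrt(t) * (u[:, keep] / s[keep]).T
    x = np.sqrt(t) * vt[keep]
    return mean, k, x


def _complement_direction(used: np.ndarray, r: int) -> np.ndarray:
    """Deterministic unit vector orthogonal to the columns of ``used``."""
    for i in range(r):
        e = np.zeros(r)
        e[i] = 1.0
        if used.size:
            e = e - used @ (used.T @ e)
        nrm = np.linalg.norm(e)
        if nrm > 1e-8:
            return e / nrm
    raise RankError("no direction left in the whitened subspace")


def fit_maxvar(
    datasets: Sequence[np.ndarray] | Mapping[str, np.ndarray],
    n_components: int | None = None,
    subjects: Sequence[str] | None = None,
    store_variates: bool = True,
) -> MccaModel:
    """Fit stagewise MAXVAR multiset CCA on equal-length (D, t) matrices.

    Parameters
    ----------
    datasets : sequence or mapping of (D, t) arrays
        One matrix per subject; time lengths must be equal (the
        zero-padding contract upstream guarantees this on real data).
    n_components : int, optional
        Defaults to the smallest post-whitening rank across subjects.
    store_variates : bool
        Keep the training-data canonical variates on the model (used by the
        projection round-trip contract; disable to save memory at scale).

    The sign of each component is fixed per subject so that its training
    variate correlates non-negatively with the across-subject mean variate,
    with a deterministic global sign per component.
    """
    if isinstance(datasets, Mapping):
        subjects = list(datasets.keys())
        mats = [np.asarray(datasets[s], dtype=float) for s in subjects]
    else:
        mats = [np.asarray(d, dtype=float) for d in datasets]
        if subjects is None:
            subjects = [f"s{i}" for i in range(len(mats))]
        subjects = list(subjects)
    m_sets = len(mats)
    if m_sets < 2:
        raise ValueError("MCCA needs at least 2 datasets")
    t = mats[0].shape[1]
    for s, z in zip(subjects, mats):
        if z.ndim != 2:
            raise ValueError(f"dataset {s!r} is not a 2-D (D, t) matrix")
        if z.shape[1] != t:
            raise ValueError(
                f"dataset {s!r} has {z.shape[1]} samples, expected {t}; "
                "recordings must share a common length (zero-pad rejected "
                "segments instead of dropping them)"
            )

    means, whiteners, whitened = {}, {}, []
    ranks = []
    for s, z in zip(subjects, mats):
        mean, k, x = _whiten(z)
        means[s], whiteners[s] = mean, k
        whitened.append(x)
        ranks.append(x.shape[0])
    min_rank = min(ranks)
    if n_components is None:
        n_components = min_rank
    if n_components > min_rank:
        raise RankError(
            f"requested {n_components} components but smallest dataset rank "
            f"is {min_rank}"
        )

    b = np.vstack(whitened)                     # (sum r_m, t)
    g = b @ b.T
    offsets = np.concatenate([[0], np.cumsum(ranks)])
    u_blocks = [np.zeros((r, n_components)) for r in ranks]
    strength = np.zeros(n_components)
    for comp in range(n_components):
        evals, evecs = np.linalg.eigh(g)
        v = evecs[:, -1]
        strength[comp] = evals[-1] / (m_sets * t)
        for mi, r in enumerate(ranks):
            a = v[offsets[mi]:offsets[mi] + r]
            nrm = np.linalg.norm(a)
            if nrm > 1e-9:
                u = a / nrm
            else:  # degenerate block: pick any unused direction
                u = _complement_direction(u_blocks[mi][:, :comp], r)
            u_blocks[mi][:, comp] = u
            rows = slice(offsets[mi], offsets[mi] + r)
            g[rows, :] -= np.outer(u, u @ g[rows, :])
            g[:, rows] -= np.outer(g[:, rows] @ u, u)

    weights = {
        s: u_blocks[mi].T @ whiteners[s]
        for mi, s in enumerate(subjects)
    }

    # Sign convention: per subject, align each training variate with the
    # across-subject mean variate; then fix the shared overall sign.
    variates = {
        s: weights[s] @ (mats[mi] - means[s][:, None])
        for mi, s in enumerate(subjects)
    }
    for comp in range(n_components):
        stack = np.array([variates[s][comp] for s in subjects])
        mean_var = stack.mean(axis=0)
        if np.linalg.norm(mean_var) > 0:
            for mi, s in enumerate(subjects):
                if float(stack[mi] @ mean_var) < 0:
                    weights[s][comp] *= -1
                    variates[s][comp] *= -1
        mean_var = np.mean([variates[s][comp] for s in subjects], axis=0)
        if mean_var[np.argmax(np.abs(mean_var))] < 0:
            for s in subjects:
                weights[s][comp] *= -1
                variates[s][comp] *= -1

    return MccaModel(
        subjects=subjects,
        means=means,
        whiteners=whiteners,
        weights=weights,
        strength=strength,
        n_components=n_components,
        training_variates=variates if store_variates else None,
    )


def project(model: MccaModel, dataset: np.ndarray, subject: str) -> np.ndarray:
    """Apply a subject's spatial filters: Y = W (Z - training mean).

    A pure linear map; projecting the training data reproduces the variates
    computed at fit time.
    """
    if subject not in model.weights:
        raise KeyError(f"unknown subject {subject!r}; model has {model.subjects}")
    z = np.asarray(dataset, dtype=float)
    if z.shape[0] != model.means[subject].shape[0]:
        raise ValueError(
            f"dataset dimension {z.shape[0]} does not match the model's "
            f"{model.means[subject].shape[0]}"
        )
    return model.weights[subject] @ (z - model.means[subject][:, None])


def activation_pattern(
    model: MccaModel,
    dataset: np.ndarray,
    subject: str,
    component: int = 0,
    pca: PcaReduction | None = None,
) -> ActivationPattern:
    """Forward model A = Sigma_z w sigma_y^2 of one canonical component.

    Covariances are computed on the data segment passed in. Only the
    requested component's variance enters (the cross-component covariance is
    zero on training data by construction, and this stays well-defined even
    when the full variate covariance is singular). Pass the subject's
    ``PcaReduction`` to back-project the pattern to original sensor space.
    """
    z = np.asarray(dataset, dtype=float)
    zc = z - z.mean(axis=1, keepdims=True)
    t = z.shape[1]
    sigma_z = zc @ zc.T / t
    w = model.weights[subject][component]
    y = w @ zc
    var_y = float(y @ y) / t
    pattern = sigma_z @ w * var_y
    channel = None
    if pca is not None:
        channel = pca.components.T @ pattern
    return ActivationPattern(
        subject=subject, component=component, pattern=pattern,
        channel_pattern=channel,
    )
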