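"""Shared fixtures: cell builders and the (expensive) null-calibration run.

The calibration fixture simulates 1,000 independent no-signal condition
cells at desk scale and runs the full cross-validated alignment + circular
bootstrap pipeline on each; it is session-scoped because both the type-I
error check and the p-value uniformity check read the same p-values.
"""

from __future__ import annotations

import numpy as np
import pytest

from neuralign.alignment import circular_null, crossval_alignment
from neuralign.syndata import SubjectForwardModel, make_latent_signal
from neuralign import synthesize_subject


def make_noise_cell(rng: np.random.Generator, m: int = 8, channels: int = 8,
                    t: int = 3000) -> list[np.ndarray]:
    """Independent white-noise recordings: a no-shared-signal condition."""
    return [rng.standard_normal((channels, t)) for _ in range(m)]


def make_shared_cell(rng: np.random.Generator, m: int = 6, channels: int = 12,
                     snr: float = 1.0, duration_s: float = 30.0,
                     fs: float = 100.0) -> tuple[dict, dict]:
    """Recordings sharing one band-limited latent; returns (recordings,
    ground-truth mixing per subject)."""
    latent = make_latent_signal(duration_s, fs, rng=rng)
    recs, mixes = {}, {}
    for i in range(m):
        sid = f"s{i}"
        fm = SubjectForwardModel(rng.standard_normal(channels), sid)
        mixes[sid] = fm.mixing
        recs[sid] = synthesize_subject(latent, fm, snr, rng=rng)
    return recs, mixes


@pytest.fixture(scope="session")
def null_calibration_pvalues() -> np.ndarray:
    """Bootstrap p-values for 1,000 no-signal cells (M=8, t=3000, 200
    shuffles each).

    Cell shape mirrors the emulated pipeline's model-complexity-to-data
    ratio: 8 sensor channels reduced by PCA to 4 dimensions against 2,000
    training samples per fold (the full analysis uses 50 PCA dimensions
    against ~24,000).
    """
    pvals = []
    for ci in range(1000):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=20260920, spawn_key=(ci,))
        )
        recs = make_noise_cell(rng, m=8, channels=8, t=3000)
        res = crossval_alignment(recs, k=3, pca_dim=4)
        circular_null(res, n_shuffles=200, rng=rng)
        pvals.append(res.p_value)
    return np.asarray(pvals)
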