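"""Synthetic multi-subject sensor recordings with known shared structure.

Emulates a group x session x stimulus-version x condition MEG design: within
each stimulus cell every subject receives the same band-limited latent signal
through a subject-specific sensor mixing vector, plus independent white noise
per channel. A single alignment-strength knob (the ratio of shared-signal to
noise standard deviation) controls how correlated subjects are, and a
``delta_post`` increment raises that strength post-session for the
intervention group's political conditions only — the ground-truth effect the
downstream contrast layer is meant to recover.

Every recording is reproducible from one master seed through a documented
counter scheme, so any subset of the study regenerates identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import h5py
import numpy as np

from .preprocess import FilterSpec, bandpass, _bandpass_taps

__all__ = [
    "GROUPS",
    "SESSIONS",
    "VERSIONS",
    "CONDITIONS",
    "POLITICAL_CONDITIONS",
    "LatentSignal",
    "SubjectForwardModel",
    "SimulationConfig",
    "StudyDataset",
    "GroundTruth",
    "BadSegmentMask",
    "make_latent_signal",
    "synthesize_subject",
    "synthesize_study",
    "mark_bad_segments",
    "save_study",
    "load_study",
]

GROUPS = ("intervention", "control")
SESSIONS = ("pre", "post")
VERSIONS = ("v1", "v2")
CONDITIONS = (
    "political_congruent",
    "political_incongruent",
    "nonpolitical_congruent",
    "nonpolitical_incongruent",
)
POLITICAL_CONDITIONS = ("political_congruent", "political_incongruent")

# Stimulus cells: one independent latent per (session, version, condition),
# shared by both groups (both groups hear the same narratives).
STIM_CELLS = tuple(
    (s, v, c) for s in SESSIONS for v in VERSIONS for c in CONDITIONS
)

CellKey = tuple[str, str, str, str]            # (group, session, version, condition)
RecordingKey = tuple[str, str, str, str, str]  # ... + subject


@dataclass
class LatentSignal:
    """Band-limited, zero-mean, unit-variance shared time series."""

    samples: np.ndarray
    fs: float
    band: tuple[float, float]


@dataclass
class SubjectForwardModel:
    """Fixed per-subject sensor mixing vector (unitless gains)."""

    mixing: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.ndim != 1 or not np.linalg.norm(self.mixing) > 0:
            raise ValueError("mixing must be a 1-D vector with nonzero norm")


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`synthesize_study`.

    Defaults mirror the emulated study: 248-channel arrays, 90 s per
    condition at 400 Hz, a 0.5-10 Hz latent band, analysed samples of 37
    (intervention) and 42 (control) subjects, and a post-session alignment
    increment restricted to intervention-group political conditions.

    ``snr_by_cell`` maps ``(group, session, condition)`` to an alignment
    strength overriding ``base_snr``; ``delta_post`` is always added on top
    for intervention/post/political cells.

    ``snr_jitter`` is the log-normal standard deviation of a per-recording
    multiplicative jitter on the alignment strength, modelling the
    session-to-session variability of a subject's engagement with the
    stimulus. Without it all subjects are exchangeable and the
    between-subject variance of intersubject-correlation values collapses,
    which no real cohort shows. Set to 0 for exactly exchangeable subjects.
    """

    n_subjects_per_group: int | Mapping[str, int] = field(
        default_factory=lambda: {"intervention": 37, "control": 42}
    )
    n_channels: int = 248
    duration_s: float = 90.0
    fs: float = 400.0
    band: tuple[float, float] = (0.5, 10.0)
    base_snr: float = 0.5
    snr_by_cell: Mapping[tuple[str, str, str], float] | None = None
    delta_post: float = 0.5
    snr_jitter: float = 0.2
    seed: int = 0

    def subjects_per_group(self) -> dict[str, int]:
        if isinstance(self.n_subjects_per_group, Mapping):
            out = {g: int(self.n_subjects_per_group[g]) for g in GROUPS}
        else:
            out = {g: int(self.n_subjects_per_group) for g in GROUPS}
        for g, n in out.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 subjects, got {n}")
        return out

    def snr_for(self, group: str, session: str, condition: str) -> float:
        base = self.base_snr
        if self.snr_by_cell is not None:
            base = self.snr_by_cell.get((group, session, condition), base)
        if (
            group == "intervention"
            and session == "post"
            and condition in POLITICAL_CONDITIONS
        ):
            base = base + self.delta_post
        if base < 0:
            raise ValueError(
                f"alignment strength for {(group, session, condition)} is negative"
            )
        return float(base)


@dataclass
class GroundTruth:
    """What the generator knows: the latent per stimulus cell, each subject's
    mixing vector, and the alignment strength used per cell."""

    latents: dict[tuple[str, str, str], LatentSignal]
    forward_models: dict[str, SubjectForwardModel]
    snr: dict[CellKey, float]


@dataclass
class StudyDataset:
    """The full simulated (or loaded) experiment.

    ``recordings`` maps (group, session, version, condition, subject) to a
    (channels, time) matrix; all matrices within one cell share a shape and
    subject membership is identical across sessions within a group.
    """

    recordings: dict[RecordingKey, np.ndarray]
    fs: float
    ground_truth: GroundTruth | None = None

    def subjects(self, group: str) -> list[str]:
        ids = sorted({k[4] for k in self.recordings if k[0] == group})
        return ids

    def cell_keys(self) -> list[CellKey]:
        return sorted({k[:4] for k in self.recordings})

    def cell(self, group: str, session: str, version: str, condition: str
             ) -> dict[str, np.ndarray]:
        key = (group, session, version, condition)
        out = {
            k[4]: v for k, v in self.recordings.items() if k[:4] == key
        }
        if not out:
            raise KeyError(f"no recordings in cell {key}")
        return dict(sorted(out.items()))

    def iter_cells(self) -> Iterator[tuple[CellKey, dict[str, np.ndarray]]]:
        for key in self.cell_keys():
            yield key, self.cell(*key)


@dataclass
class BadSegmentMask:
    """Half-open ``[start, end)`` sample ranges to reject, per recording."""

    intervals: dict[RecordingKey, list[tuple[int, int]]]

    def n_masked(self, key: RecordingKey) -> int:
        return sum(e - s for s, e in self.intervals.get(key, []))


def _rng(master_seed: int, *spawn_key: int) -> np.random.Generator:
    """Counter-scheme RNG: streams are independent and subset-stable."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=spawn_key)
    )


def make_latent_signal(
    duration_s: float,
    fs: float,
    band: tuple[float, float] = (0.5, 10.0),
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> LatentSignal:
    """Gaussian white noise band-passed to ``band`` and standardized.

    Extra samples are generated on both sides and trimmed after filtering so
    edge transients do not leak into the returned series. Deterministic for
    a given seed (or supplied generator).
    """
    low, high = band
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not fs > 2 * high:
        raise ValueError(f"fs={fs} must exceed twice the band upper edge {high}")
    spec = FilterSpec(low, high)
    spec.validate(fs)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    pad = len(_bandpass_taps(fs, spec))
    white = rng.standard_normal(n + 2 * pad)
    filtered = bandpass(white, fs, spec)[pad:pad + n]
    filtered = filtered - filtered.mean()
    sd = filtered.std()
    if sd == 0:
        raise ValueError("degenerate latent signal (zero variance)")
    return LatentSignal(samples=filtered / sd, fs=float(fs), band=(low, high))


def synthesize_subject(
    latent: LatentSignal,
    forward_model: SubjectForwardModel,
    snr: float,
    noise_seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One subject's (channels, time) recording.

    ``snr * mixing (outer) latent + noise`` with unit-variance white Gaussian
    noise per channel; ``snr`` is the shared-signal-to-noise standard
    deviation ratio in a unit-gain channel. ``snr = 0`` yields pure noise.
    """
    if snr < 0:
        raise ValueError("snr must be non-negative")
    if rng is None:
        rng = np.random.default_rng(noise_seed)
    mixing = forward_model.mixing
    x = latent.samples
    noise = rng.standard_normal((mixing.size, x.size))
    return snr * np.outer(mixing, x) + noise


def synthesize_study(config: SimulationConfig) -> StudyDataset:
    """Generate the full group x session x version x condition study.

    Every subject in a group is recorded in every stimulus cell (both
    counterbalanced versions), sharing that cell's latent with all other
    subjects. Mixing vectors are drawn once per subject and reused across
    sessions and versions. Seed streams: (0, cell) for latents, (1, group,
    subject) for mixings, (2, cell, group, subject) for noise.
    """
    per_group = config.subjects_per_group()
    latents = {
        cell: make_latent_signal(
            config.duration_s, config.fs, config.band,
            rng=_rng(config.seed, 0, i),
        )
        for i, cell in enumerate(STIM_CELLS)
    }

    forward_models: dict[str, SubjectForwardModel] = {}
    for gi, group in enumerate(GROUPS):
        for si in range(per_group[group]):
            sid = f"{group}-{si:02d}"
            mixing = _rng(config.seed, 1, gi, si).standard_normal(config.n_channels)
            forward_models[sid] = SubjectForwardModel(mixing=mixing, subject_id=sid)

    recordings: dict[RecordingKey, np.ndarray] = {}
    snr_used: dict[CellKey, float] = {}
    for ci, (session, version, condition) in enumerate(STIM_CELLS):
        latent = latents[(session, version, condition)]
        for gi, group in enumerate(GROUPS):
            cell_key: CellKey = (group, session, version, condition)
            snr = config.snr_for(group, session, condition)
            snr_used[cell_key] = snr
            for si in range(per_group[group]):
                sid = f"{group}-{si:02d}"
                rng = _rng(config.seed, 2, ci, gi, si)
                # per-recording engagement jitter, drawn before the noise so
                # the stream layout is stable
                mult = float(np.exp(config.snr_jitter * rng.standard_normal()))
                recordings[cell_key + (sid,)] = synthesize_subject(
                    latent, forward_models[sid], snr * mult, rng=rng,
                )
    if not recordings:
        raise ValueError("configuration produced an empty study")
    return StudyDataset(
        recordings=recordings,
        fs=config.fs,
        ground_truth=GroundTruth(latents, forward_models, snr_used),
    )


def mark_bad_segments(
    dataset: StudyDataset, fraction: float, seed: int = 0
) -> BadSegmentMask:
    """Random per-recording bad segments totalling ~``fraction`` of samples.

    The requested total is split over up to three intervals placed in
    disjoint thirds of the recording, so intervals never overlap nor exceed
    the bounds. ``fraction`` must be in [0, 0.5).
    """
    if not (0.0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    intervals: dict[RecordingKey, list[tuple[int, int]]] = {}
    for key in sorted(dataset.recordings):
        t = dataset.recordings[key].shape[-1]
        total = int(round(fraction * t))
        if total == 0:
            intervals[key] = []
            continue
        n_int = min(3, total)
        lengths = [total // n_int] * n_int
        for j in range(total % n_int):
            lengths[j] += 1
        block = t // n_int
        segs = []
        for j, length in enumerate(lengths):
            lo = j * block
            start = lo + int(rng.integers(0, block - length + 1))
            segs.append((start, start + length))
        intervals[key] = segs
    return BadSegmentMask(intervals=intervals)


# ---------------------------------------------------------------------------
# On-disk container (HDF5): one array per recording, attributes for rates,
# labels, and ground truth.

def save_study(dataset: StudyDataset, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = dataset.fs
        rec = f.create_group("recordings")
        for key, arr in dataset.recordings.items():
            rec.create_dataset("/".join(key), data=arr)
        gt = dataset.ground_truth
        if gt is not None:
            lat = f.create_group("latents")
            for (s, v, c), latent in gt.latents.items():
                d = lat.create_dataset(f"{s}/{v}/{c}", data=latent.samples)
                d.attrs["fs"] = latent.fs
                d.attrs["band"] = latent.band
            mix = f.create_group("forward_models")
            for sid, fm in gt.forward_models.items():
                mix.create_dataset(sid, data=fm.mixing)
            snr = f.create_group("snr")
            for cell_key, value in gt.snr.items():
                snr.create_dataset("/".join(cell_key), data=float(value))


def load_study(path: str) -> StudyDataset:
    recordings: dict[RecordingKey, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])

        def visit(name: str, obj: object) -> None:
            if isinstance(obj, h5py.Dataset):
                recordings[tuple(name.split("/"))] = obj[()]

        f["recordings"].visititems(visit)
        gt = None
        if "latents" in f:
            latents = {}
            for s in f["latents"]:
                for v in f["latents"][s]:
                    for c in f["latents"][s][v]:
                        d = f["latents"][s][v][c]
                        latents[(s, v, c)] = LatentSignal(
                            samples=d[()], fs=float(d.attrs["fs"]),
                            band=tuple(d.attrs["band"]),
                        )
            fms = {
                sid: SubjectForwardModel(mixing=f["forward_models"][sid][()],
                                         subject_id=sid)
                for sid in f["forward_models"]
            }
            snr: dict[CellKey, float] = {}

            def visit_snr(name: str, obj: object) -> None:
                if isinstance(obj, h5py.Dataset):
                    snr[tuple(name.split("/"))] = float(obj[()])

            f["snr"].visititems(visit_snr)
            gt = GroundTruth(latents=latents, forward_models=fms, snr=snr)
    return StudyDataset(recordings=recordings, fs=fs, ground_truth=gt)
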