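"""Synthetic parcel-level BOLD-like datasets for the three brain states.

The generator emulates the dimensions and the statistical structure the
empirical analysis assumes: 17 subjects, three states (awake rest, sleep
rest, sleep with an ongoing auditory stimulus), 145 volumes at TR = 2.16 s,
and 1000 parcels grouped into the seven canonical networks.

Each parcel signal is white Gaussian noise shaped by a one-pole low-pass
filter and then band-limited to 0.01-0.23 Hz.  The parcel's low-pass
cutoff is drawn on the log scale,

    log c = log c_state + a_state * u_subject + eps_parcel,

with ``u_subject ~ N(0, 1)`` shared across that subject's parcels and
``eps_parcel ~ N(0, parcel_sd)`` independent per parcel.  This single
mechanism produces the three signatures the analysis measures:

* a lower state cutoff (sleep rest) slows every parcel, lengthening ACW-0
  and lowering the median frequency relative to the awake state;
* a higher cutoff in the stimulated state shortens ACW-0 and raises MF
  again;
* a large shared subject factor ``a_state`` (largest for sleep-stimulus)
  makes the parcels' across-subject metric profiles co-vary, raising the
  inter-parcel topographic similarity.

The defaults are calibration choices of the generator, stored with the
output; they are not empirical claims.  The generator makes no attempt to
model hemodynamics, scanner artifacts, motion, or EEG-defined sleep
staging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_BAND, DEFAULT_TR, TimeSeriesMatrix, bandpass
from .topography import ParcellationScheme

logger = logging.getLogger(__name__)

#: Generator state labels, in the fixed comparison order.
STATES = ("awake", "sleep_rest", "sleep_stim")


@dataclass
class GeneratorSpec:
    """Study dimensions and the state-dependent spectral parameters.

    ``cutoff_hz`` gives each state's nominal low-pass cutoff inside the
    analysis band; ``subject_sd`` the SD of the shared per-subject factor on
    the log-cutoff scale; ``parcel_sd`` the per-parcel log-cutoff jitter.
    """

    n_subjects: int = 17
    n_volumes: int = 145
    tr: float = DEFAULT_TR
    parcellation: ParcellationScheme = field(default_factory=ParcellationScheme.default)
    cutoff_hz: dict = field(
        default_factory=lambda: {"awake": 0.08, "sleep_rest": 0.045, "sleep_stim": 0.09}
    )
    subject_sd: dict = field(
        default_factory=lambda: {"awake": 0.15, "sleep_rest": 0.1, "sleep_stim": 0.5}
    )
    parcel_sd: float = 0.15
    band: tuple[float, float] = DEFAULT_BAND
    burn_in: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        f_lo, f_hi = self.band
        for state in STATES:
            c = self.cutoff_hz[state]
            if not f_lo < c < f_hi:
                raise ValueError(f"cutoff for {state!r} must lie inside the band {self.band}")
        # equality everywhere is allowed so null (no-effect) configurations
        # remain expressible; the default effects order strictly
        if not self.cutoff_hz["sleep_rest"] <= self.cutoff_hz["awake"] <= self.cutoff_hz["sleep_stim"]:
            raise ValueError("cutoffs must order sleep_rest <= awake <= sleep_stim")
        if not self.subject_sd["sleep_stim"] >= self.subject_sd["sleep_rest"]:
            raise ValueError("the shared subject factor cannot shrink under stimulation")
        if self.parcel_sd <= 0 or any(v <= 0 for v in self.subject_sd.values()):
            raise ValueError("all SDs must be positive")
        if self.n_subjects < 1 or self.n_volumes < 30:
            raise ValueError("need at least 1 subject and 30 volumes")


@dataclass
class SyntheticDataset:
    """Per-state, per-subject series plus the latent ground truth."""

    spec: GeneratorSpec
    data: dict  # state -> list[TimeSeriesMatrix], one per subject
    ground_truth: pd.DataFrame

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.data)

    @property
    def subjects(self) -> list[int]:
        return list(range(len(next(iter(self.data.values())))))


def _one_pole_lowpass(white: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """AR(1) shaping of white noise columns with per-column pole ``alpha``."""

    t, p = white.shape
    out = np.empty_like(white)
    prev = white[0] * np.sqrt(1.0 / np.maximum(1.0 - alpha**2, 1e-12))  # stationary start
    for i in range(t):
        prev = alpha * prev + (1.0 - alpha) * white[i]
        out[i] = prev
    return out


def generate_dataset(spec: GeneratorSpec | None = None) -> SyntheticDataset:
    """Generate the three-state dataset defined by ``spec``.

    All randomness flows from ``spec.seed`` through a seed tree, so the
    full dataset regenerates bit-identically.  Per-parcel cutoffs escaping
    the analysis band after the subject effect are re-jittered (bounded
    retries) and finally clipped just inside the band with a warning.
    """

    if spec is None:
        spec = GeneratorSpec()
    scheme = spec.parcellation
    n_parcels = scheme.n_parcels
    f_lo, f_hi = spec.band
    root = np.random.SeedSequence(spec.seed)
    state_seqs = dict(zip(STATES, root.spawn(len(STATES))))
    data: dict[str, list[TimeSeriesMatrix]] = {}
    truth_rows = []
    for state in STATES:
        subj_seqs = state_seqs[state].spawn(spec.n_subjects)
        c_state = spec.cutoff_hz[state]
        a_state = spec.subject_sd[state]
        series = []
        for subject, seq in enumerate(subj_seqs):
            rng = np.random.default_rng(seq)
            u = rng.standard_normal()
            log_c = np.log(c_state) + a_state * u + spec.parcel_sd * rng.standard_normal(n_parcels)
            for _ in range(50):
                bad = (np.exp(log_c) <= f_lo) | (np.exp(log_c) >= f_hi)
                if not bad.any():
                    break
                log_c[bad] = (
                    np.log(c_state) + a_state * u
                    + spec.parcel_sd * rng.standard_normal(int(bad.sum()))
                )
            cutoffs = np.exp(log_c)
            lo, hi = f_lo * 1.001, f_hi * 0.999
            n_clip = int(((cutoffs < lo) | (cutoffs > hi)).sum())
            if n_clip:
                logger.warning(
                    "%s subject %d: clipping %d cutoff(s) to the band after retries",
                    state, subject, n_clip,
                )
                cutoffs = np.clip(cutoffs, lo, hi)
            alpha = np.exp(-2 * np.pi * cutoffs * spec.tr)
            white = rng.standard_normal((spec.burn_in + spec.n_volumes, n_parcels))
            shaped = _one_pole_lowpass(white, alpha)[spec.burn_in:]
            filtered = bandpass(shaped, f_lo, f_hi, dt=spec.tr)
            series.append(
                TimeSeriesMatrix(
                    filtered,
                    dt=spec.tr,
                    unit_ids=scheme.parcel_ids.tolist(),
                    meta={"state": state, "subject": subject},
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "state": state,
                        "subject": subject,
                        "parcel_id": scheme.parcel_ids,
                        "cutoff_hz": cutoffs,
                        "u_subject": u,
                    }
                )
            )
        data[state] = series
    truth = pd.concat(truth_rows, ignore_index=True)
    return SyntheticDataset(spec=spec, data=data, ground_truth=truth)


def subset_fully_asleep(dataset: SyntheticDataset, k: int = 4) -> SyntheticDataset:
    """Deterministic subject subset emulating the fully-asleep subgroup.

    The subset is drawn from the dataset's own master seed, so repeated
    calls select the same subjects.  Downstream use is qualitative
    (direction of state differences), not inferential.
    """

    n = dataset.spec.n_subjects
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} available subjects")
    rng = np.random.default_rng(np.random.SeedSequence([dataset.spec.seed, 0x5EED]))
    keep = np.sort(rng.choice(n, size=k, replace=False))
    data = {state: [runs[i] for i in keep] for state, runs in dataset.data.items()}
    truth = dataset.ground_truth[dataset.ground_truth["subject"].isin(keep)].reset_index(drop=True)
    return SyntheticDataset(spec=dataset.spec, data=data, ground_truth=truth)


def expand_to_voxels(
    ts: TimeSeriesMatrix,
    voxels_per_parcel: int = 10,
    voxel_noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[TimeSeriesMatrix, np.ndarray]:
    """Voxel-level view of a parcel series (shared signal + voxel noise).

    Exists to exercise the voxel -> parcel aggregation and the volumetric
    file path; returns the voxel matrix and the voxel -> parcel label
    vector.
    """

    rng = np.random.default_rng(seed)
    t, p = ts.data.shape
    sig = np.repeat(ts.data, voxels_per_parcel, axis=1)
    noise = voxel_noise_sd * rng.standard_normal(sig.shape)
    labels = np.repeat(np.asarray(ts.unit_ids), voxels_per_parcel)
    vox = TimeSeriesMatrix(
        sig + noise, dt=ts.dt,
        unit_ids=[f"{pid}.{v}" for pid in ts.unit_ids for v in range(voxels_per_parcel)],
        meta=dict(ts.meta),
    )
    return vox, labels
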