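"""Synthetic cohorts and contrast maps for exercising the fROI pipeline.

The generator emulates the structure of a large multi-study false-belief
localizer dataset: a cohort table of neurotypical (NT) and autism-spectrum
(ASD) adults with demographic and acquisition covariates, and per-subject
even-run / odd-run contrast T-maps containing Gaussian activation blobs at
the seven canonical theory-of-mind region centers (RTPJ, LTPJ, PC, DMPFC,
MMPFC, VMPFC, RSTS).

Signal is identical between a subject's two half-maps (stable individual
truth); noise is drawn independently per half.  Per-subject region
amplitude is

    base + group_delta * 1[ASD] + sum(slope * centered covariate)
         + Normal(0, subject_sd)

and the realized blob center is the nominal center plus isotropic Gaussian
jitter shared by both halves.  Ground truth is recorded for every subject
and is never consumed by analysis stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BinaryMask, ScalarVolume, VolumeGrid, mni_grid

__all__ = [
    "CohortConfig",
    "BlobSpec",
    "NoiseSpec",
    "SubjectSimTruth",
    "default_blobs",
    "generate_cohort",
    "simulate_subject_maps",
    "simulate_cohort_maps",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: canonical MNI centers (mm) of the seven theory-of-mind regions
REGION_CENTERS_MM = {
    "RTPJ": (54.0, -52.0, 23.0),
    "LTPJ": (-52.0, -58.0, 25.0),
    "PC": (1.0, -56.0, 34.0),
    "DMPFC": (-1.0, 53.0, 29.0),
    "MMPFC": (1.0, 54.0, 12.0),
    "VMPFC": (1.0, 50.0, -12.0),
    "RSTS": (55.0, -10.0, -16.0),
}

TASK_TYPES = ("TF", "FITB", "MTS")

COHORT_COLUMNS = [
    "id", "group", "age", "gender", "iq", "ados_comm", "ados_soc",
    "coil", "modality", "n_stimuli_per_cond", "mean_words_per_stim",
    "task_type",
]


@dataclass
class CohortConfig:
    """Marginal cohort structure.

    Defaults mirror the aggregated localizer study: 462 NT / 31 ASD,
    197 / 26 male, 74 of 493 on the 32-channel coil, 420 visual vs 73
    auditory, task mixture 304 TF / 101 FITB / 88 MTS, ages ~24 (NT) vs
    ~32 (ASD), IQ recorded for a subset (61 NT, 30 ASD), ADOS scores for
    ASD only.
    """

    n_nt: int = 462
    n_asd: int = 31
    n_male_nt: int | None = None  # default: study fraction 197/462
    n_male_asd: int | None = None  # default: study fraction 26/31
    age_mean_nt: float = 24.4
    age_sd_nt: float = 7.4
    age_mean_asd: float = 32.5
    age_sd_asd: float = 12.4
    age_range: tuple[float, float] = (18.0, 69.0)
    iq_mean: float = 117.0
    iq_sd: float = 13.0
    iq_fraction_nt: float = 61 / 462
    iq_fraction_asd: float = 30 / 31
    ados_comm_mean: float = 3.2
    ados_comm_sd: float = 1.3
    ados_soc_mean: float = 5.9
    ados_soc_sd: float = 2.1
    coil32_fraction: float = 74 / 493
    auditory_fraction: float = 73 / 493
    task_fractions: tuple[float, float, float] = (304 / 493, 101 / 493, 88 / 493)
    n_stimuli_choices: tuple[int, ...] = (10, 12, 16)
    n_stimuli_weights: tuple[float, ...] = (64 / 493, 254 / 493, 175 / 493)
    mean_words_mean: float = 36.0
    mean_words_sd: float = 8.0

    def validate(self):
        if self.n_nt < 0 or self.n_asd < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_male_nt is None:
            self.n_male_nt = int(round(self.n_nt * 197 / 462))
        if self.n_male_asd is None:
            self.n_male_asd = int(round(self.n_asd * 26 / 31))
        if self.n_male_nt > self.n_nt or self.n_male_asd > self.n_asd:
            raise ValueError("male count exceeds group size")


@dataclass
class BlobSpec:
    """One planted activation blob: where, how wide, how strong, and how
    it varies across subjects and covariates."""

    name: str
    center_mm: tuple[float, float, float]
    fwhm_mm: float = 16.0
    base_amplitude: float = 5.0
    group_delta: float = 0.0  # added for ASD subjects
    covariate_effects: tuple[tuple[str, float], ...] = ()
    subject_sd: float = 0.7
    jitter_sd_mm: float = 2.0

    def __post_init__(self):
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be > 0")
        if self.subject_sd < 0 or self.jitter_sd_mm < 0:
            raise ValueError("subject_sd and jitter_sd_mm must be >= 0")


@dataclass
class NoiseSpec:
    """Additive voxelwise Gaussian noise, optionally spatially smoothed
    (variance renormalized back to ``sd`` after smoothing)."""

    sd: float = 1.0
    smooth_fwhm_mm: float = 0.0

    def __post_init__(self):
        if self.sd < 0 or self.smooth_fwhm_mm < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class SubjectSimTruth:
    """Ground truth for one simulated subject (never fed to analyses)."""

    subject_id: str
    amplitudes: dict[str, float]
    centers_mm: dict[str, tuple[float, float, float]]
    noise_seed_even: int
    noise_seed_odd: int


def default_blobs(group_delta: float = 0.0,
                  iq_pc_slope: float = 0.0,
                  **overrides) -> list[BlobSpec]:
    """One blob per canonical region.

    ``iq_pc_slope`` plants an IQ effect on the precuneus amplitude, the
    one demographic effect worth recovering; everything else defaults to
    no covariate dependence.
    """
    blobs = []
    for name, center in REGION_CENTERS_MM.items():
        effects = ()
        if name == "PC" and iq_pc_slope:
            effects = (("iq", iq_pc_slope),)
        blobs.append(BlobSpec(name=name, center_mm=center,
                              group_delta=group_delta,
                              covariate_effects=effects,
                              **overrides))
    return blobs


def _exact_categorical(rng, n, values, counts):
    """Assignment vector with exact per-category counts, shuffled."""
    out = np.repeat(values, counts)
    rng.shuffle(out)
    return out


def _counts_from_fractions(n, fractions):
    """Largest-remainder rounding of fractions to integer counts summing n."""
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(config: CohortConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Generate a cohort covariate table.

    Categorical marginals (gender, coil, modality, task type, stimulus
    count) match the configured counts exactly; continuous covariates are
    sampled from truncated normals.  ADOS scores are present iff ASD.
    Deterministic given (config, seed).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_nt + config.n_asd
    rows = []

    group = np.array(["NT"] * config.n_nt + ["ASD"] * config.n_asd)
    gender = np.empty(n, dtype=object)
    gender[group == "NT"] = _exact_categorical(
        rng, config.n_nt, np.array(["M", "F"], dtype=object),
        [config.n_male_nt, config.n_nt - config.n_male_nt])
    gender[group == "ASD"] = _exact_categorical(
        rng, config.n_asd, np.array(["M", "F"], dtype=object),
        [config.n_male_asd, config.n_asd - config.n_male_asd])

    coil = _exact_categorical(
        rng, n, np.array(["32ch", "12ch"], dtype=object),
        _counts_from_fractions(n, [config.coil32_fraction,
                                   1 - config.coil32_fraction]))
    modality = _exact_categorical(
        rng, n, np.array(["auditory", "visual"], dtype=object),
        _counts_from_fractions(n, [config.auditory_fraction,
                                   1 - config.auditory_fraction]))
    task = _exact_categorical(
        rng, n, np.array(TASK_TYPES, dtype=object),
        _counts_from_fractions(n, config.task_fractions))
    n_stim = _exact_categorical(
        rng, n, np.array(config.n_stimuli_choices),
        _counts_from_fractions(n, config.n_stimuli_weights))

    lo, hi = config.age_range
    age = np.empty(n)
    age[group == "NT"] = _truncated_normal(
        rng, config.age_mean_nt, config.age_sd_nt, lo, hi, config.n_nt)
    age[group == "ASD"] = _truncated_normal(
        rng, config.age_mean_asd, config.age_sd_asd, lo, hi, config.n_asd)

    words = _truncated_normal(rng, config.mean_words_mean,
                              config.mean_words_sd, 20.0, 70.0, n)

    iq = np.full(n, np.nan)
    has_iq = np.zeros(n, dtype=bool)
    has_iq[group == "NT"] = _exact_categorical(
        rng, config.n_nt, np.array([True, False]),
        _counts_from_fractions(config.n_nt, [config.iq_fraction_nt,
                                             1 - config.iq_fraction_nt]))
    has_iq[group == "ASD"] = _exact_categorical(
        rng, config.n_asd, np.array([True, False]),
        _counts_from_fractions(config.n_asd, [config.iq_fraction_asd,
                                              1 - config.iq_fraction_asd]))
    iq[has_iq] = _truncated_normal(rng, config.iq_mean, config.iq_sd,
                                   65.0, 145.0, int(has_iq.sum()))

    ados_comm = np.full(n, np.nan)
    ados_soc = np.full(n, np.nan)
    asd_idx = group == "ASD"
    ados_comm[asd_idx] = np.clip(np.round(rng.normal(
        config.ados_comm_mean, config.ados_comm_sd, config.n_asd)), 0, 8)
    ados_soc[asd_idx] = np.clip(np.round(rng.normal(
        config.ados_soc_mean, config.ados_soc_sd, config.n_asd)), 0, 14)

    table = pd.DataFrame({
        "id": [f"sub-{i:04d}" for i in range(n)],
        "group": group,
        "age": np.round(age, 1),
        "gender": gender,
        "iq": np.round(iq, 1),
        "ados_comm": ados_comm,
        "ados_soc": ados_soc,
        "coil": coil,
        "modality": modality,
        "n_stimuli_per_cond": n_stim.astype(int),
        "mean_words_per_stim": np.round(words, 1),
        "task_type": task,
    })
    return table


def _blob_field(grid: VolumeGrid, center_mm, fwhm_mm, amplitude,
                coords=None) -> np.ndarray:
    sigma = fwhm_mm * FWHM_TO_SIGMA
    if coords is None:
        coords = grid.all_world_coords()
    d2 = np.sum((coords - np.asarray(center_mm)) ** 2, axis=-1)
    return amplitude * np.exp(-d2 / (2.0 * sigma ** 2))


def _smoothed_noise(rng, grid: VolumeGrid, spec: NoiseSpec) -> np.ndarray:
    noise = rng.standard_normal(grid.dims)
    if spec.smooth_fwhm_mm > 0:
        sigma_vox = spec.smooth_fwhm_mm * FWHM_TO_SIGMA / grid.voxel_size
        noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        noise /= max(noise.std(), 1e-12)  # renormalize to unit SD
    return spec.sd * noise


def _subject_amplitude(record, blob: BlobSpec, rng,
                       covariate_means: dict[str, float]) -> float:
    amp = blob.base_amplitude
    if record["group"] == "ASD":
        amp += blob.group_delta
    for cov, slope in blob.covariate_effects:
        value = record[cov]
        if pd.isna(value):
            continue
        amp += slope * (float(value) - covariate_means.get(cov, 0.0))
    amp += rng.normal(0.0, blob.subject_sd)
    return float(amp)


def simulate_subject_maps(record, blobs, noise: NoiseSpec,
                          grid: VolumeGrid, seed,
                          covariate_means: dict[str, float] | None = None,
                          df: int = 100):
    """Simulate one subject's even- and odd-run contrast T-maps.

    The signal component (blob amplitudes and jittered centers) is shared
    between halves; only the additive noise differs.  Returns
    (even_half, odd_half, truth).
    """
    covariate_means = covariate_means or {}
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    subj_ss, even_ss, odd_ss = ss.spawn(3)
    rng_subj = np.random.default_rng(subj_ss)
    rng_even = np.random.default_rng(even_ss)
    rng_odd = np.random.default_rng(odd_ss)
    coords = grid.all_world_coords()
    dims_arr = np.asarray(grid.dims)

    signal = np.zeros(grid.dims)
    amplitudes, centers = {}, {}
    for blob in blobs:
        center_vox = grid.world_to_voxel_continuous(blob.center_mm)
        if np.any(center_vox < -0.5) or np.any(center_vox > dims_arr - 0.5):
            raise ValueError(f"blob {blob.name!r} center {blob.center_mm} "
                             f"outside grid")
        amp = _subject_amplitude(record, blob, rng_subj, covariate_means)
        center = (np.asarray(blob.center_mm)
                  + rng_subj.normal(0.0, blob.jitter_sd_mm, 3))
        signal += _blob_field(grid, center, blob.fwhm_mm, amp, coords)
        amplitudes[blob.name] = amp
        centers[blob.name] = tuple(center)

    even = signal + _smoothed_noise(rng_even, grid, noise)
    odd = signal + _smoothed_noise(rng_odd, grid, noise)
    truth = SubjectSimTruth(
        subject_id=str(record["id"]),
        amplitudes=amplitudes,
        centers_mm={k: tuple(float(x) for x in v) for k, v in centers.items()},
        noise_seed_even=int(even_ss.generate_state(1)[0]) & 0x7FFFFFFF,
        noise_seed_odd=int(odd_ss.generate_state(1)[0]) & 0x7FFFFFFF,
    )
    return (ScalarVolume(grid, even, df=df),
            ScalarVolume(grid, odd, df=df), truth)


def simulate_cohort_maps(cohort: pd.DataFrame, blobs, noise: NoiseSpec,
                         grid: VolumeGrid | None = None, seed: int = 0,
                         df: int = 100):
    """Simulate half-maps for every cohort row.

    Yields (record, even, odd, truth) tuples.  Covariates entering blob
    slopes are centered at the cohort mean, matching the analysis-side
    convention that slopes act on centered covariates.
    """
    grid = grid or mni_grid()
    cov_names = {cov for blob in blobs for cov, _ in blob.covariate_effects}
    cov_means = {c: float(pd.to_numeric(cohort[c], errors="coerce").mean())
                 for c in cov_names}
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(cohort))
    for (_, record), child in zip(cohort.iterrows(), child_seeds):
        even, odd, truth = simulate_subject_maps(
            record, blobs, noise, grid, child, covariate_means=cov_means,
            df=df)
        yield record, even, odd, truth


def write_truth(truths, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [asdict(t) for t in truths]
    path.write_text(json.dumps(payload, indent=1))
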