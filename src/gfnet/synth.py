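"""Synthetic cohorts with known planted structure.

Real cohorts of this kind (tractography streamline counts, source-level MEG
band time series, WAIS-style scores) are rarely shareable, so every
downstream stage is exercised on synthetic data whose ground truth is known:
a planted module partition with controllable intra/inter edge weights and
group shifts for the structural networks, and planted envelope-correlation
targets realized by amplitude-modulating band-limited carriers for the
functional side.

The envelope process is an exponentiated low-pass Gaussian process: strictly
positive (an amplitude must be), slow relative to the carrier band, and with
a closed-form monotone mapping between the latent Gaussian correlation and
the resulting envelope (lognormal) correlation, so any feasible target
correlation matrix can be planted exactly in population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from ._seeds import derive_seed
from .connectome import design_bandpass_fir
from .types import (
    CANONICAL_BANDS,
    BandTimeSeries,
    FrequencyBand,
    SubjectRecord,
    TractographySample,
    get_band,
)

__all__ = [
    "TABLE1_DEFAULTS",
    "CohortSpec",
    "Cohort",
    "generate_gf_scores",
    "generate_tractography_sample",
    "generate_band_timeseries",
    "fc_target_from_partition",
    "generate_cohort",
    "contiguous_partition",
]

#: Published cohort summary statistics used as generator defaults:
#: group sizes, Gf mean +/- SD, age, education years, and sex composition.
TABLE1_DEFAULTS = {
    "n_high": 38,
    "n_avg": 31,
    "gf_high": (117.72, 4.66),
    "gf_avg": (102.98, 6.09),
    "age_high": (25.86, 4.89),
    "age_avg": (24.00, 2.69),
    "edu_high": (14.73, 4.25),
    "edu_avg": (14.56, 5.87),
    "p_female_high": 15 / 38,
    "p_female_avg": 18 / 31,
}


def contiguous_partition(n_rois: int, n_modules: int = 5) -> np.ndarray:
    """Contiguous blocks of near-equal size, labelled 1..k."""
    if n_modules < 1 or n_modules > n_rois:
        raise ValueError("need 1 <= n_modules <= n_rois")
    return np.repeat(np.arange(1, n_modules + 1), -(-n_rois // n_modules))[:n_rois]


@dataclass
class CohortSpec:
    """All knobs of a synthetic cohort; defaults mirror the study design.

    Structural group effects: ``group_degree_shift`` adds a constant to
    every planted edge weight of the high group (raising degree everywhere);
    ``group_inter_shift`` adds only to inter-module weights (lowering
    segregation). Functional group effects: ``band_fc_shift`` maps a band
    name to an additive offset on the high group's planted envelope
    correlations.
    """

    n_rois: int = 90
    n_high: int = TABLE1_DEFAULTS["n_high"]
    n_avg: int = TABLE1_DEFAULTS["n_avg"]
    partition_true: np.ndarray | None = None
    intra_weight_mean: float = 0.5
    inter_weight_mean: float = 0.1
    group_degree_shift: float = 0.0
    group_inter_shift: float = 0.0
    noise_sd: float = 25.0
    bands: list[FrequencyBand] = field(
        default_factory=lambda: list(CANONICAL_BANDS.values())
    )
    fs: float = 150.0
    duration_s: float = 600.0
    fc_intra_corr: float = 0.3
    fc_inter_corr: float = 0.05
    band_fc_shift: dict[str, float] = field(default_factory=dict)
    gf_mean_high: float = TABLE1_DEFAULTS["gf_high"][0]
    gf_sd_high: float = TABLE1_DEFAULTS["gf_high"][1]
    gf_mean_avg: float = TABLE1_DEFAULTS["gf_avg"][0]
    gf_sd_avg: float = TABLE1_DEFAULTS["gf_avg"][1]
    roi_size_range: tuple[float, float] = (200, 2000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high < 2 or self.n_avg < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not (self.intra_weight_mean >= self.inter_weight_mean >= 0):
            raise ValueError("need intra_weight_mean >= inter_weight_mean >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.partition_true is None:
            self.partition_true = contiguous_partition(self.n_rois)
        self.partition_true = np.asarray(self.partition_true, dtype=int)
        if self.partition_true.shape != (self.n_rois,):
            raise ValueError("partition_true must assign every ROI exactly once")
        self.bands = [get_band(b).capped(self.fs) for b in self.bands]
        unknown = set(self.band_fc_shift) - {b.name for b in self.bands}
        if unknown:
            raise ValueError(f"band_fc_shift names unknown bands: {sorted(unknown)}")

    @property
    def roi_labels(self) -> list[str]:
        return [f"ROI{i + 1:03d}" for i in range(self.n_rois)]


def generate_gf_scores(
    n_high: int,
    n_avg: int,
    mean_high: float,
    sd_high: float,
    mean_avg: float,
    sd_avg: float,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Draw a cohort table with normal Gf scores in each group.

    Ages, education years and sex composition are drawn from the
    group-typical summary statistics of the study population; Gf scores are
    exactly N(mean, sd) per group, so downstream summary tests converge to
    the specified population values as n grows.
    """
    if n_high < 2 or n_avg < 2:
        raise ValueError("each group needs n >= 2")
    if sd_high <= 0 or sd_avg <= 0:
        raise ValueError("standard deviations must be positive")
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    groups = [
        ("high", n_high, mean_high, sd_high, TABLE1_DEFAULTS["age_high"],
         TABLE1_DEFAULTS["edu_high"], TABLE1_DEFAULTS["p_female_high"]),
        ("average", n_avg, mean_avg, sd_avg, TABLE1_DEFAULTS["age_avg"],
         TABLE1_DEFAULTS["edu_avg"], TABLE1_DEFAULTS["p_female_avg"]),
    ]
    idx = 0
    for name, n, mu, sd, (age_mu, age_sd), (edu_mu, edu_sd), p_f in groups:
        gf = rng.normal(mu, sd, size=n)
        age = np.maximum(18.0, rng.normal(age_mu, age_sd, size=n))
        edu = np.maximum(0.0, rng.normal(edu_mu, edu_sd, size=n))
        sex = np.where(rng.random(n) < p_f, "F", "M")
        for i in range(n):
            idx += 1
            records.append(
                SubjectRecord(
                    subject_id=f"S{idx:03d}",
                    group=name,
                    gf=float(gf[i]),
                    age=float(age[i]),
                    sex=str(sex[i]),
                    education=float(edu[i]),
                )
            )
    return records


def planted_weight_matrix(spec: CohortSpec, group: str) -> np.ndarray:
    """The noise-free structural weight matrix a group's subjects share."""
    part = spec.partition_true
    same = part[:, None] == part[None, :]
    w = np.where(same, spec.intra_weight_mean, spec.inter_weight_mean).astype(float)
    if group == "high":
        w = w + spec.group_degree_shift
        w = w + np.where(same, 0.0, spec.group_inter_shift)
    elif group != "average":
        raise ValueError(f"group must be high|average, got {group!r}")
    w = np.clip(w, 0.0, None)
    np.fill_diagonal(w, 0.0)
    return w


def cohort_roi_sizes(spec: CohortSpec) -> np.ndarray:
    """Parcel sizes (voxels) shared by all subjects of a cohort."""
    rng = np.random.default_rng(derive_seed(spec.seed, "roi_sizes"))
    lo, hi = spec.roi_size_range
    return rng.integers(int(lo), int(hi) + 1, size=spec.n_rois).astype(float)


def generate_tractography_sample(
    spec: CohortSpec,
    group: str,
    seed: int,
    roi_sizes: np.ndarray | None = None,
) -> TractographySample:
    """One subject's streamline-count matrix and ROI sizes.

    The expected normalized weight between two regions is the planted group
    weight; counts are scaled back up by the pairwise average parcel size so
    the size-normalization path is genuinely exercised. The two directions
    get independent truncated-normal noise, so ``counts[a, b] !=
    counts[b, a]`` in general; with ``noise_sd == 0`` the matrix is exactly
    symmetric and the normalized network equals the planted weights.
    """
    w = planted_weight_matrix(spec, group)
    sizes = cohort_roi_sizes(spec) if roi_sizes is None else np.asarray(roi_sizes, float)
    pair_size = (sizes[:, None] + sizes[None, :]) / 2.0
    base = w * pair_size
    rng = np.random.default_rng(seed)
    if spec.noise_sd > 0:
        counts = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
        counts = np.round(np.clip(counts, 0.0, None))
    else:
        counts = base.copy()
    np.fill_diagonal(counts, 0.0)
    return TractographySample(counts, sizes, spec.roi_labels)


def fc_target_from_partition(
    partition: np.ndarray,
    intra_corr: float,
    inter_corr: float,
    shift: float = 0.0,
) -> np.ndarray:
    """Envelope-correlation target: block structure over a module partition.

    ``shift`` adds a constant to every off-diagonal correlation (the
    functional group effect), clipped into [-0.95, 0.95]. The result must be
    positive semidefinite to be realizable; block-constant matrices with
    intra >= inter >= 0 always are for the magnitudes used here, and the
    constructor raises if a caller-supplied combination is not.
    """
    part = np.asarray(partition, dtype=int)
    same = part[:, None] == part[None, :]
    r = np.where(same, intra_corr, inter_corr).astype(float)
    r += shift
    r = np.clip(r, -0.95, 0.95)
    np.fill_diagonal(r, 1.0)
    if np.linalg.eigvalsh(r).min() < -1e-8:
        raise ValueError("target correlation matrix is not positive semidefinite")
    return r


def _latent_corr_from_envelope_corr(r: np.ndarray, sigma: float) -> np.ndarray:
    """Invert the lognormal correlation map.

    If z_i are standard Gaussian with correlation rho and e_i = exp(sigma
    z_i), then corr(e_i, e_j) = (exp(sigma^2 rho) - 1) / (exp(sigma^2) - 1);
    solving for rho gives the latent correlation that plants a desired
    envelope correlation.
    """
    c = np.expm1(sigma**2)
    rho = np.log1p(np.clip(r, -1.0 / c + 1e-12, None) * c) / sigma**2
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """A factor F with F F^T = corr (eigen route; tolerates singularity)."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-6:
        raise ValueError("correlation matrix is not positive semidefinite")
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def _zero_phase_lowpass(data: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    numtaps = int(round(3 * fs / cutoff))
    numtaps += 1 - numtaps % 2
    taps = signal.firwin(numtaps, cutoff, fs=fs)
    half = (numtaps - 1) // 2
    padded = np.pad(data, [(0, 0), (half, half)], mode="reflect")
    return signal.fftconvolve(padded, taps[None, :], mode="valid", axes=1)


def generate_band_timeseries(
    n_rois: int,
    band: FrequencyBand | str,
    fs: float,
    duration_s: float,
    envelope_corr_target: np.ndarray,
    seed: int = 0,
    envelope_sigma: float = 0.5,
    envelope_cutoff: float | None = None,
    noise_sd: float = 0.0,
    return_envelopes: bool = False,
):
    """Band-limited signals whose amplitude envelopes have planted correlations.

    Each region's signal is a constant-modulus band-limited carrier (the
    cosine of the instantaneous phase of band-filtered white noise)
    multiplied by a strictly positive slow envelope, an exponentiated
    low-pass Gaussian process. The latent Gaussian correlations are chosen
    so the population correlation of the envelopes equals
    ``envelope_corr_target``; the recovered envelope correlations (band-pass
    + Hilbert + Pearson) converge to the target as duration grows.

    Parameters
    ----------
    envelope_corr_target
        Symmetric PSD matrix with unit diagonal.
    envelope_sigma
        Log-amplitude SD of the envelope process (dimensionless); sets the
        depth of amplitude modulation.
    envelope_cutoff
        Low-pass cutoff of the envelope in Hz; defaults to the smaller of
        0.5 Hz and a quarter of the band width, keeping the modulation slow
        relative to the carrier.
    noise_sd
        SD of additive broadband measurement noise.
    return_envelopes
        Also return the true planted envelopes as a second BandTimeSeries.
    """
    band = get_band(band).capped(fs)
    target = np.asarray(envelope_corr_target, dtype=float)
    if target.shape != (n_rois, n_rois):
        raise ValueError("envelope_corr_target must be n_rois x n_rois")
    if not np.allclose(target, target.T, atol=1e-10):
        raise ValueError("envelope_corr_target must be symmetric")
    if not np.allclose(np.diag(target), 1.0):
        raise ValueError("envelope_corr_target must have unit diagonal")
    if np.linalg.eigvalsh(target).min() < -1e-8:
        raise ValueError("envelope_corr_target is not positive semidefinite")

    n_samples = int(round(duration_s * fs))
    if n_samples <= 2 * fs:
        raise ValueError("duration must exceed 2 s")
    cutoff = envelope_cutoff
    if cutoff is None:
        cutoff = min(0.5, (band.hi - band.lo) / 4.0)
    rng = np.random.default_rng(seed)

    # planted envelopes: correlated Gaussians -> low-pass -> exponentiate
    rho = _latent_corr_from_envelope_corr(target, envelope_sigma)
    factor = _psd_factor(rho)
    z = factor @ rng.standard_normal((n_rois, n_samples))
    z = _zero_phase_lowpass(z, fs, cutoff)
    z /= np.maximum(z.std(axis=1, keepdims=True), 1e-300)
    envelopes = np.exp(envelope_sigma * z)

    # constant-modulus band-confined carriers, independent across regions:
    # frequency-modulated cosines whose instantaneous frequency is low-pass
    # noise wandering inside the band. A constant-modulus carrier keeps the
    # signal's analytic magnitude equal to the planted envelope; extracting
    # the phase of raw filtered noise instead suffers phase slips whose
    # broadband distortion would shrink recovered envelope correlations.
    bw = band.hi - band.lo
    center = (band.hi + band.lo) / 2.0
    f_dev = 0.25 * bw / 2.0
    fm_noise = rng.standard_normal((n_rois, n_samples))
    fm = _zero_phase_lowpass(fm_noise, fs, cutoff)
    fm /= np.maximum(fm.std(axis=1, keepdims=True), 1e-300)
    inst_freq = np.clip(center + f_dev * fm, band.lo + 0.05 * bw, band.hi - 0.05 * bw)
    phase0 = rng.uniform(0, 2 * np.pi, size=(n_rois, 1))
    phase = phase0 + 2 * np.pi * np.cumsum(inst_freq, axis=1) / fs
    carriers = np.cos(phase)

    data = envelopes * carriers
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    labels = [f"ROI{i + 1:03d}" for i in range(n_rois)]
    ts = BandTimeSeries(data, fs, band, labels)
    if return_envelopes:
        return ts, BandTimeSeries(envelopes, fs, band, labels)
    return ts


@dataclass
class Cohort:
    """A fully generated synthetic cohort.

    Structural samples are materialized eagerly (they are small); band time
    series are generated on demand per subject and band from deterministic
    derived seeds, since a full five-band, ten-minute cohort is large.
    """

    spec: CohortSpec
    records: list[SubjectRecord]
    samples: dict[str, TractographySample]

    @property
    def groups(self) -> np.ndarray:
        return np.array([r.group for r in self.records])

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def fc_target(self, band: FrequencyBand | str, group: str) -> np.ndarray:
        band = get_band(band)
        shift = self.spec.band_fc_shift.get(band.name, 0.0) if group == "high" else 0.0
        return fc_target_from_partition(
            self.spec.partition_true,
            self.spec.fc_intra_corr,
            self.spec.fc_inter_corr,
            shift=shift,
        )

    def band_timeseries(
        self, subject_id: str, band: FrequencyBand | str, duration_s: float | None = None
    ) -> BandTimeSeries:
        band = get_band(band).capped(self.spec.fs)
        rec = next(r for r in self.records if r.subject_id == subject_id)
        return generate_band_timeseries(
            self.spec.n_rois,
            band,
            self.spec.fs,
            self.spec.duration_s if duration_s is None else duration_s,
            self.fc_target(band, rec.group),
            seed=derive_seed(self.spec.seed, "ts", subject_id, band.name),
        )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the cohort table and every subject's tractography sample."""
    records = generate_gf_scores(
        spec.n_high,
        spec.n_avg,
        spec.gf_mean_high,
        spec.gf_sd_high,
        spec.gf_mean_avg,
        spec.gf_sd_avg,
        seed=derive_seed(spec.seed, "gf"),
    )
    sizes = cohort_roi_sizes(spec)
    samples = {
        r.subject_id: generate_tractography_sample(
            spec, r.group, derive_seed(spec.seed, "tract", r.subject_id), roi_sizes=sizes
        )
        for r in records
    }
    return Cohort(spec=spec, records=records, samples=samples)
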