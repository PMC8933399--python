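"""Core domain types shared across the pipeline.

The common currency is the :class:`WeightedNetwork` — an undirected weighted
graph over a fixed set of labelled regions of interest (ROIs). Structural
networks carry nonnegative normalized streamline weights; functional networks
carry Pearson correlations of band-limited amplitude envelopes, hence values
in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FrequencyBand",
    "CANONICAL_BANDS",
    "TractographySample",
    "WeightedNetwork",
    "BandTimeSeries",
    "CommunityPartition",
    "DegreeVector",
    "SegregationVector",
    "GlobalMetrics",
    "SubjectRecord",
]

#: Tolerance within which a weight matrix must be symmetric.
SYMMETRY_ATOL = 1e-10


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency band with edges in Hz, e.g. alpha 8-12 Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})"
            )

    def capped(self, fs: float, fraction: float = 0.95) -> "FrequencyBand":
        """Return the band with its upper edge capped at ``fraction * fs/2``.

        The gamma band (32-75 Hz) sits exactly at the Nyquist frequency of a
        150 Hz recording; filters cannot realize an edge there, so the upper
        edge is pulled just inside Nyquist. Bands already inside Nyquist are
        returned unchanged.
        """
        hi_max = fraction * fs / 2.0
        if self.hi <= hi_max:
            return self
        if self.lo >= hi_max:
            raise ValueError(
                f"band {self.name!r} ({self.lo}-{self.hi} Hz) lies outside the "
                f"usable range for fs={fs} Hz"
            )
        return FrequencyBand(self.name, self.lo, hi_max)


#: The five canonical bands of resting-state MEG analysis.
CANONICAL_BANDS: dict[str, FrequencyBand] = {
    "delta": FrequencyBand("delta", 0.1, 2.0),
    "theta": FrequencyBand("theta", 2.0, 8.0),
    "alpha": FrequencyBand("alpha", 8.0, 12.0),
    "beta": FrequencyBand("beta", 12.0, 32.0),
    "gamma": FrequencyBand("gamma", 32.0, 75.0),
}


def get_band(band: "FrequencyBand | str") -> FrequencyBand:
    """Resolve a band given either a FrequencyBand or a canonical name."""
    if isinstance(band, FrequencyBand):
        return band
    try:
        return CANONICAL_BANDS[band]
    except KeyError:
        raise ValueError(
            f"unknown band {band!r}; canonical bands are {sorted(CANONICAL_BANDS)}"
        ) from None


def _default_labels(n: int) -> list[str]:
    return [f"ROI{i + 1:03d}" for i in range(n)]


def _check_labels(labels: Sequence[str], n: int) -> list[str]:
    labels = list(labels)
    if len(labels) != n:
        raise ValueError(f"expected {n} ROI labels, got {len(labels)}")
    if len(set(labels)) != n:
        raise ValueError("duplicate ROI labels")
    return labels


@dataclass
class TractographySample:
    """Raw per-subject tractography output.

    ``counts[a, b]`` is the streamline count seeded in region ``a`` reaching
    region ``b``; the two directions are estimated independently, so the
    matrix is asymmetric in general. ``roi_sizes`` are parcel sizes in voxels,
    used to normalize away the tendency of larger parcels to collect more
    streamlines.
    """

    counts: np.ndarray
    roi_sizes: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.roi_sizes = np.asarray(self.roi_sizes, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        n = self.counts.shape[0]
        if self.roi_sizes.shape != (n,):
            raise ValueError("roi_sizes length must match counts dimension")
        if np.any(self.counts < 0):
            raise ValueError("streamline counts must be nonnegative")
        if np.any(self.roi_sizes <= 0):
            raise ValueError("ROI sizes must be positive")
        if not self.roi_labels:
            self.roi_labels = _default_labels(n)
        self.roi_labels = _check_labels(self.roi_labels, n)

    @property
    def n(self) -> int:
        return self.counts.shape[0]


@dataclass
class WeightedNetwork:
    """Symmetric weighted adjacency with labelled nodes and zero diagonal."""

    weights: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    modality: str = "structural"
    band: FrequencyBand | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if not np.allclose(w, w.T, atol=SYMMETRY_ATOL, rtol=0):
            raise ValueError("weights must be symmetric (to 1e-10)")
        w = (w + w.T) / 2.0  # make symmetry exact
        np.fill_diagonal(w, 0.0)
        if self.modality == "structural":
            if np.any(w < 0):
                raise ValueError("structural weights must be nonnegative")
        elif self.modality == "functional":
            if np.any(w < -1 - 1e-9) or np.any(w > 1 + 1e-9):
                raise ValueError("functional weights must lie in [-1, 1]")
        else:
            raise ValueError(f"modality must be structural|functional, got {self.modality!r}")
        self.weights = w
        if not self.roi_labels:
            self.roi_labels = _default_labels(w.shape[0])
        self.roi_labels = _check_labels(self.roi_labels, w.shape[0])

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def clipped_nonnegative(self) -> "WeightedNetwork":
        """Return a copy with negative weights clipped to zero.

        Envelope correlations can be negative but the modularity, segregation
        and path metrics are defined on nonnegative weights; clipping is the
        standard preprocessing in amplitude-envelope MEG work.
        """
        w = np.clip(self.weights, 0.0, None)
        return WeightedNetwork(w, list(self.roi_labels), "structural", self.band)


@dataclass
class BandTimeSeries:
    """Region-by-sample array with its sampling rate and band tag."""

    data: np.ndarray
    fs: float
    band: FrequencyBand | None = None
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain non-finite values")
        if self.data.shape[1] <= 2 * self.fs:
            raise ValueError(
                f"need more than 2 s of signal ({int(2 * self.fs)} samples), "
                f"got {self.data.shape[1]}"
            )
        if not self.roi_labels:
            self.roi_labels = _default_labels(self.data.shape[0])
        self.roi_labels = _check_labels(self.roi_labels, self.data.shape[0])

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class CommunityPartition:
    """Non-overlapping node -> module assignment with its modularity Q.

    Modules are labelled 1..k; ``assignment[i]`` is the module of node i.
    """

    assignment: np.ndarray
    q: float

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if a.ndim != 1:
            raise ValueError("assignment must be a 1-D array of module labels")
        labels = np.unique(a)
        if labels.size == 0 or labels[0] < 1:
            raise ValueError("modules must be labelled 1..k")
        self.assignment = a

    @property
    def n_modules(self) -> int:
        return int(np.unique(self.assignment).size)

    def as_mapping(self, roi_labels: Sequence[str]) -> dict[str, int]:
        return {lab: int(m) for lab, m in zip(roi_labels, self.assignment)}


@dataclass
class DegreeVector:
    """Weighted degree (strength) per ROI: sum of the node's edge weights."""

    values: np.ndarray
    roi_labels: list[str]


@dataclass
class SegregationVector:
    """Within-module strength over total strength per ROI, in [0, 1].

    Isolated nodes (total strength 0) have no defined ratio and are marked
    NaN; downstream tests drop them explicitly.
    """

    values: np.ndarray
    roi_labels: list[str]

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class GlobalMetrics:
    """The four whole-graph summary measures."""

    char_path_length: float
    global_efficiency: float
    local_efficiency: float
    density: float
    n_unreachable_pairs: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "char_path_length": self.char_path_length,
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
            "density": self.density,
            "n_unreachable_pairs": self.n_unreachable_pairs,
        }


@dataclass
class SubjectRecord:
    """One cohort-table row: identity, group, Gf score and covariates."""

    subject_id: str
    group: str  # "high" | "average"
    gf: float
    age: float
    sex: str  # "F" | "M"
    education: float

    def __post_init__(self) -> None:
        if self.group not in ("high", "average"):
            raise ValueError(f"group must be high|average, got {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F|M, got {self.sex!r}")
        if not np.isfinite(self.gf):
            raise ValueError("Gf score must be finite")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.education < 0:
            raise ValueError("education years must be nonnegative")
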