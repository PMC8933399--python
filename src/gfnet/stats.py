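"""Group construction and the statistical layer.

The central test is a Monte-Carlo label-permutation procedure on node-level
metrics: rather than testing each region independently, it counts how many
regions have a positive (and how many a negative) high-minus-average median
difference and asks whether those counts are extreme relative to counts
obtained when group labels are permuted. Modularity gets its own null built
by shuffling the weights of the group-mean matrix; global graph measures are
compared by ANCOVA with sex as a second factor and age and education as
covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .graph import leading_eigenvector_communities
from .types import SubjectRecord, WeightedNetwork

__all__ = [
    "GroupSplit",
    "MCSResult",
    "ModularityNullResult",
    "AncovaResult",
    "assign_gf_groups",
    "welch_t_from_summary",
    "bartlett_test",
    "mcs_node_metric_test",
    "modularity_null_test",
    "ancova_global_metric",
    "sc_fc_similarity_test",
]


@dataclass
class GroupSplit:
    """Cohort split into high and average scorers at the mean score."""

    high_ids: list[str]
    avg_ids: list[str]
    mean_high: float
    sd_high: float
    mean_avg: float
    sd_avg: float
    separation_sd_units: float
    warning: str | None = None


@dataclass
class MCSResult:
    """Outcome of the Monte-Carlo permutation test on a node metric."""

    median_diff: np.ndarray
    n_pos: int
    n_neg: int
    perm_counts_pos: np.ndarray
    perm_counts_neg: np.ndarray
    p_pos: float
    p_neg: float
    alpha_corrected: float
    n_perm: int
    seed: int
    dropped_rois: list[str] = field(default_factory=list)

    @property
    def significant_pos(self) -> bool:
        return self.p_pos < self.alpha_corrected

    @property
    def significant_neg(self) -> bool:
        return self.p_neg < self.alpha_corrected


@dataclass
class ModularityNullResult:
    """Observed modularity against a weight-shuffle null distribution."""

    q_observed: float
    q_permuted: np.ndarray
    percentile: float
    significant: bool
    n_perm: int
    seed: int


@dataclass
class AncovaResult:
    """Per-term F tests of a linear model with factors and covariates."""

    term_names: list[str]
    f_stats: np.ndarray
    p_values: np.ndarray
    df_model: float
    df_resid: float
    alpha_corrected: float

    def p_for(self, term: str) -> float:
        return float(self.p_values[self.term_names.index(term)])


def assign_gf_groups(
    records: Sequence[SubjectRecord], sd_standard: float = 15.0
) -> GroupSplit:
    """Split a cohort at its mean Gf score.

    Subjects strictly above the cohort mean form the high group, the rest
    the average group. The separation between the group means is reported in
    units of the standardized test SD (15 for WAIS-style scores); a
    separation below one SD triggers a warning, not an error, since the
    psychometric meaningfulness of the split is advisory.
    """
    if len(records) < 4:
        raise ValueError("need at least 4 subjects to form two groups")
    gf = np.array([r.gf for r in records], dtype=float)
    if not np.all(np.isfinite(gf)):
        raise ValueError("non-finite Gf scores")
    if np.ptp(gf) == 0:
        raise ValueError("all Gf scores identical: no split possible")
    mean_all = gf.mean()
    high = [r for r in records if r.gf > mean_all]
    avg = [r for r in records if r.gf <= mean_all]
    gh = np.array([r.gf for r in high])
    ga = np.array([r.gf for r in avg])
    sep = abs(gh.mean() - ga.mean()) / sd_standard
    warning = None
    if sep < 1.0:
        warning = (
            f"group means are only {sep:.2f} standardized SDs apart "
            "(< 1.0); the split may not be psychometrically meaningful"
        )
        warnings.warn(warning, UserWarning, stacklevel=2)
    return GroupSplit(
        high_ids=[r.subject_id for r in high],
        avg_ids=[r.subject_id for r in avg],
        mean_high=float(gh.mean()),
        sd_high=float(gh.std(ddof=1)),
        mean_avg=float(ga.mean()),
        sd_avg=float(ga.std(ddof=1)),
        separation_sd_units=float(sep),
        warning=warning,
    )


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch two-sample t statistic and degrees of freedom from summaries.

    ``t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)`` with Welch-Satterthwaite df.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df)


def bartlett_test(group1: Sequence[float], group2: Sequence[float]) -> tuple[float, float]:
    """Bartlett's test of equal variances between two groups.

    The pre-check run before the node-metric permutation test: a chi-square
    statistic on 1 degree of freedom with its upper-tail p-value.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if g1.var(ddof=1) == 0 or g2.var(ddof=1) == 0:
        raise ValueError("zero within-group variance: Bartlett test undefined")
    stat, p = sstats.bartlett(g1, g2)
    return float(stat), float(p)


def mcs_node_metric_test(
    metric_by_subject: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 10_000,
    alpha: float = 0.05,
    n_tests_for_bonferroni: int = 2,
    seed: int = 0,
    roi_labels: Sequence[str] | None = None,
) -> MCSResult:
    """Permutation test on the whole-brain distribution of a node metric.

    Parameters
    ----------
    metric_by_subject
        subjects x ROIs matrix of the metric (degree, segregation, ...).
        ROIs with any undefined (NaN) value are dropped listwise and listed
        in the result.
    groups
        Per-subject labels, "high" or "average"; sizes are preserved under
        permutation.
    n_perm
        Number of label permutations building the null (study default
        10,000).
    alpha, n_tests_for_bonferroni
        The corrected level is ``alpha / n_tests_for_bonferroni`` — 0.05/2
        for a single structural network tested on both tails, 0.05/10 across
        five functional bands and two tails.

    Notes
    -----
    The observed statistic is the pair of counts (regions with median
    difference above zero, below zero); each tail's p-value is the add-one
    smoothed proportion of permutations whose count reaches the observed
    one. Median differences exactly zero count in neither tail.
    """
    data = np.asarray(metric_by_subject, dtype=float)
    if data.ndim != 2:
        raise ValueError("metric_by_subject must be subjects x ROIs")
    groups = np.asarray(groups)
    if groups.shape[0] != data.shape[0]:
        raise ValueError("groups length must match the number of subjects")
    if not set(np.unique(groups)) <= {"high", "average"}:
        raise ValueError("group labels must be 'high' or 'average'")
    n_high = int((groups == "high").sum())
    n_avg = int((groups == "average").sum())
    if n_high < 2 or n_avg < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_tests_for_bonferroni < 1:
        raise ValueError("Bonferroni denominator must be positive")

    labels_all = (
        list(roi_labels)
        if roi_labels is not None
        else [f"ROI{i + 1:03d}" for i in range(data.shape[1])]
    )
    defined = ~np.any(np.isnan(data), axis=0)
    dropped = [lab for lab, ok in zip(labels_all, defined) if not ok]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} ROI(s) with undefined values: "
            + ", ".join(dropped[:5]),
            UserWarning,
            stacklevel=2,
        )
    data = data[:, defined]

    high_mask = groups == "high"
    med_diff = np.median(data[high_mask], axis=0) - np.median(data[~high_mask], axis=0)
    n_pos = int((med_diff > 0).sum())
    n_neg = int((med_diff < 0).sum())

    rng = np.random.default_rng(seed)
    n_subj = data.shape[0]
    high_pos = np.flatnonzero(high_mask)
    avg_pos = np.flatnonzero(~high_mask)
    perm_pos = np.empty(n_perm, dtype=int)
    perm_neg = np.empty(n_perm, dtype=int)
    chunk = max(1, min(n_perm, int(2e6 // max(1, n_subj * data.shape[1]) + 1), 500))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((c, n_subj)), axis=1)
        gathered_high = data[perms[:, high_pos]]  # (c, n_high, n_rois)
        gathered_avg = data[perms[:, avg_pos]]
        d = np.median(gathered_high, axis=1) - np.median(gathered_avg, axis=1)
        perm_pos[done : done + c] = (d > 0).sum(axis=1)
        perm_neg[done : done + c] = (d < 0).sum(axis=1)
        done += c

    # A permutation counts against the observed tail only if it strictly
    # exceeds it: with a maximal observed count no permutation can, so p
    # attains the add-one floor. An observed count of zero is never evidence
    # and gets p = 1 outright.
    p_pos = 1.0 if n_pos == 0 else (1 + int((perm_pos > n_pos).sum())) / (n_perm + 1)
    p_neg = 1.0 if n_neg == 0 else (1 + int((perm_neg > n_neg).sum())) / (n_perm + 1)
    return MCSResult(
        median_diff=med_diff,
        n_pos=n_pos,
        n_neg=n_neg,
        perm_counts_pos=perm_pos,
        perm_counts_neg=perm_neg,
        p_pos=float(p_pos),
        p_neg=float(p_neg),
        alpha_corrected=alpha / n_tests_for_bonferroni,
        n_perm=n_perm,
        seed=seed,
        dropped_rois=dropped,
    )


def modularity_null_test(
    mean_net: WeightedNetwork | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    percentile_rule: float = 99.9,
    method: str = "weight_shuffle",
) -> ModularityNullResult:
    """Is the observed modularity higher than that of an equivalent random net?

    Each permutation shuffles the upper-triangle weights of the group-mean
    matrix uniformly at random (preserving the weight multiset and
    symmetry), recomputes the leading-eigenvector modularity, and the
    observed Q is called significant only if it exceeds the 99.9th
    percentile of the permuted values. ``method="degree_rewire"`` instead
    swaps pairs of edges preserving each node's binary degree, offered as an
    alternative null.
    """
    w = mean_net.weights if isinstance(mean_net, WeightedNetwork) else np.asarray(
        mean_net, dtype=float
    )
    part = leading_eigenvector_communities(w)
    q_obs = part.q
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    rng = np.random.default_rng(seed)
    q_perm = np.empty(n_perm)
    for b in range(n_perm):
        if method == "weight_shuffle":
            shuffled = rng.permutation(vals)
        elif method == "degree_rewire":
            shuffled = _degree_preserving_shuffle(vals, iu, ju, n, rng)
        else:
            raise ValueError(f"unknown null method {method!r}")
        wp = np.zeros((n, n))
        wp[iu, ju] = shuffled
        wp += wp.T
        q_perm[b] = leading_eigenvector_communities(wp).q
    threshold = np.percentile(q_perm, percentile_rule)
    significant = bool(q_obs > threshold)
    percentile = float(100.0 * np.mean(q_perm < q_obs))
    return ModularityNullResult(
        q_observed=float(q_obs),
        q_permuted=q_perm,
        percentile=percentile,
        significant=significant,
        n_perm=n_perm,
        seed=seed,
    )


def _degree_preserving_shuffle(vals, iu, ju, n, rng) -> np.ndarray:
    """Shuffle weights only among edges, keeping the binary topology fixed."""
    present = vals > 0
    out = vals.copy()
    out[present] = rng.permutation(vals[present])
    return out


def ancova_global_metric(
    values: Sequence[float],
    group: Sequence[str],
    sex: Sequence[str],
    age: Sequence[float],
    education: Sequence[float],
    alpha: float = 0.05,
    n_comparisons: int = 24,
) -> AncovaResult:
    """ANCOVA of one global graph measure across Gf groups.

    Linear model ``value ~ group + sex + age + education`` with type-II
    F-tests per term. The corrected level divides alpha by the number of
    comparisons performed across measures and networks (four measures by
    five functional bands plus one structural network = 24 by default).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "group": list(group),
            "sex": list(sex),
            "age": np.asarray(age, dtype=float),
            "education": np.asarray(education, dtype=float),
        }
    )
    for col in ("group", "sex"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    if df["value"].var(ddof=1) == 0:
        raise ValueError("degenerate input: all metric values identical")
    model = smf.ols("value ~ C(group) + C(sex) + age + education", data=df)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name columns involved in the collinearity via QR diagnostics
        _, r = np.linalg.qr(exog)
        bad = [
            model.exog_names[i]
            for i in range(exog.shape[1])
            if abs(r[i, i]) < 1e-8 * abs(r[0, 0])
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = model.fit()
    if fit.ssr < 1e-12 * max(1.0, float(np.abs(df["value"]).max()) ** 2):
        raise ValueError("degenerate fit: zero residual variance")
    table = anova_lm(fit, typ=2)
    terms = [t for t in table.index if t != "Residual"]
    return AncovaResult(
        term_names=terms,
        f_stats=table.loc[terms, "F"].to_numpy(dtype=float),
        p_values=table.loc[terms, "PR(>F)"].to_numpy(dtype=float),
        df_model=float(fit.df_model),
        df_resid=float(fit.df_resid),
        alpha_corrected=alpha / n_comparisons,
    )


def sc_fc_similarity_test(
    sc_by_subject: Sequence[WeightedNetwork | np.ndarray],
    fc_by_subject_band: dict[str, Sequence[WeightedNetwork | np.ndarray]],
    groups: Sequence[str],
    sex: Sequence[str],
    age: Sequence[float],
    education: Sequence[float],
    alpha: float = 0.05,
    n_comparisons: int = 5,
) -> dict[str, tuple[np.ndarray, AncovaResult]]:
    """Per-band group comparison of structural-functional coupling.

    For each subject and band, the Pearson correlation between the
    vectorized upper triangles of the structural and functional matrices
    measures how similar the two networks are; those per-subject r values
    then enter the same ANCOVA as the global measures.
    """
    n_subj = len(sc_by_subject)
    results: dict[str, tuple[np.ndarray, AncovaResult]] = {}
    sc_vecs = [_upper_vec(m) for m in sc_by_subject]
    for band, fcs in fc_by_subject_band.items():
        if len(fcs) != n_subj:
            raise ValueError(f"band {band!r}: subject lists do not match")
        r = np.empty(n_subj)
        for i, (sv, fm) in enumerate(zip(sc_vecs, fcs)):
            fv = _upper_vec(fm)
            if sv.std() == 0 or fv.std() == 0:
                raise ValueError(
                    f"constant matrix for subject {i} in band {band!r}: "
                    "correlation undefined"
                )
            r[i] = np.corrcoef(sv, fv)[0, 1]
        res = ancova_global_metric(
            r, groups, sex, age, education, alpha=alpha, n_comparisons=n_comparisons
        )
        results[band] = (r, res)
    return results


def _upper_vec(m: WeightedNetwork | np.ndarray) -> np.ndarray:
    w = m.weights if isinstance(m, WeightedNetwork) else np.asarray(m, dtype=float)
    iu, ju = np.triu_indices(w.shape[0], k=1)
    return w[iu, ju]
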