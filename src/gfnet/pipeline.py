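"""End-to-end orchestration: cohort -> connectomes -> metrics -> inference.

Stages run in the analysis order of the study design: structural and
functional connectivity construction, degree permutation tests, group-level
community structure with its modularity null, segregation-coefficient
permutation tests, global graph measures with ANCOVA, and the per-subject
structural-functional similarity comparison. A master seed expands into
per-stage seeds (see :mod:`gfnet._seeds`), so identical config + seed gives
an identical report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from ._seeds import derive_seed
from .connectome import (
    bandpass_and_envelope,
    build_functional_connectivity,
    build_structural_connectivity,
)
from .graph import (
    global_metrics,
    leading_eigenvector_communities,
    segregation_coefficient,
    weighted_degree,
)
from .io import (
    read_cohort_table,
    read_timeseries,
    read_tractography,
    write_cohort_table,
    write_timeseries,
    write_tractography,
)
from .stats import (
    ancova_global_metric,
    assign_gf_groups,
    bartlett_test,
    mcs_node_metric_test,
    modularity_null_test,
    sc_fc_similarity_test,
)
from .synth import Cohort, CohortSpec, generate_cohort
from .types import WeightedNetwork, get_band

__all__ = ["RunConfig", "run_pipeline", "write_synthetic_cohort", "load_cohort_dir"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    ``mode`` is "synthetic" (generate a cohort from ``spec``) or "files"
    (load a cohort directory produced by :func:`write_synthetic_cohort` or
    laid out the same way). The Bonferroni denominators default to the
    study's: 2 for the structural degree test (two tails), 10 for the
    functional ones (five bands x two tails), 24 for the global-measure
    ANCOVAs (four measures x six networks).
    """

    mode: str = "synthetic"
    spec: CohortSpec = field(default_factory=CohortSpec)
    data_dir: str | None = None
    bands: list[str] | None = None
    n_perm_node: int = 10_000
    n_perm_modularity: int = 1000
    alpha: float = 0.05
    bonferroni_structural: int = 2
    bonferroni_functional: int = 10
    n_global_comparisons: int = 24
    prune_fraction: float = 0.01
    run_ancova: bool = True
    run_sc_fc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not self.data_dir:
            raise ValueError("files mode needs data_dir")
        for name, v in (
            ("bonferroni_structural", self.bonferroni_structural),
            ("bonferroni_functional", self.bonferroni_functional),
            ("n_global_comparisons", self.n_global_comparisons),
        ):
            if v < 1:
                raise ValueError(f"{name} must be positive")
        if self.bands is None:
            self.bands = [b.name for b in self.spec.bands]
        for b in self.bands:
            get_band(b)  # raises on unknown band names

    def config_hash(self) -> str:
        d = asdict(self)
        d["spec"]["partition_true"] = list(map(int, d["spec"]["partition_true"]))
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_synthetic_cohort(cohort: Cohort, out_dir, bands=None, duration_s=None) -> Path:
    """Materialize a synthetic cohort as the on-disk layout files mode reads."""
    out = Path(out_dir)
    (out / "sc").mkdir(parents=True, exist_ok=True)
    (out / "ts").mkdir(exist_ok=True)
    write_cohort_table(out / "cohort.csv", cohort.records)
    for sid, sample in cohort.samples.items():
        write_tractography(
            out / "sc" / f"{sid}_counts.csv", out / "sc" / f"{sid}_sizes.csv", sample
        )
    band_names = bands if bands is not None else [b.name for b in cohort.spec.bands]
    for sid in cohort.subject_ids:
        for bname in band_names:
            ts = cohort.band_timeseries(sid, bname, duration_s=duration_s)
            write_timeseries(out / "ts" / f"{sid}_{bname}.csv", ts)
    return out


def load_cohort_dir(data_dir, bands: list[str]):
    """Load a cohort directory: records, tractography samples, time series."""
    root = Path(data_dir)
    records = read_cohort_table(root / "cohort.csv")
    samples = {}
    timeseries = {}
    for r in records:
        samples[r.subject_id] = read_tractography(
            root / "sc" / f"{r.subject_id}_counts.csv",
            root / "sc" / f"{r.subject_id}_sizes.csv",
        )
        for bname in bands:
            p = root / "ts" / f"{r.subject_id}_{bname}.csv"
            if p.exists():
                timeseries[(r.subject_id, bname)] = read_timeseries(p)
    return records, samples, timeseries


def _mcs_to_dict(res, roi_labels, include_distributions=False) -> dict:
    d = {
        "median_diff": res.median_diff.tolist(),
        "n_pos": res.n_pos,
        "n_neg": res.n_neg,
        "p_pos": res.p_pos,
        "p_neg": res.p_neg,
        "alpha_corrected": res.alpha_corrected,
        "significant_pos": res.significant_pos,
        "significant_neg": res.significant_neg,
        "n_perm": res.n_perm,
        "seed": res.seed,
        "dropped_rois": res.dropped_rois,
    }
    if include_distributions:
        d["perm_counts_pos"] = res.perm_counts_pos.tolist()
        d["perm_counts_neg"] = res.perm_counts_neg.tolist()
    return d


def _modnull_to_dict(res) -> dict:
    return {
        "q_observed": res.q_observed,
        "percentile": res.percentile,
        "significant": res.significant,
        "q_permuted_max": float(res.q_permuted.max()),
        "q_permuted_mean": float(res.q_permuted.mean()),
        "n_perm": res.n_perm,
        "seed": res.seed,
    }


def _ancova_to_dict(res) -> dict:
    return {
        "terms": res.term_names,
        "f": res.f_stats.tolist(),
        "p": res.p_values.tolist(),
        "df_model": res.df_model,
        "df_resid": res.df_resid,
        "alpha_corrected": res.alpha_corrected,
    }


def run_pipeline(config: RunConfig, include_distributions: bool = False) -> dict:
    """Execute every stage and return the serializable run report.

    The report round-trips through JSON losslessly; permutation
    distributions are included only on request (they dominate the size).
    """
    seed = config.seed
    bands = list(config.bands)

    # --- stage: cohort -----------------------------------------------------
    if config.mode == "synthetic":
        cohort = generate_cohort(config.spec)
        records = cohort.records
        samples = cohort.samples
        ts_source = lambda sid, b: cohort.band_timeseries(sid, b)  # noqa: E731
    else:
        records, samples, timeseries = load_cohort_dir(config.data_dir, bands)
        missing = [
            (r.subject_id, b)
            for r in records
            for b in bands
            if (r.subject_id, b) not in timeseries
        ]
        if missing:
            raise FileNotFoundError(f"missing time series for {missing[:3]} ...")
        ts_source = lambda sid, b: timeseries[(sid, b)]  # noqa: E731

    split = assign_gf_groups(records)
    groups = np.array([r.group for r in records])
    sids = [r.subject_id for r in records]
    roi_labels = samples[sids[0]].roi_labels

    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": seed,
            "gfnet_version": __version__,
            "mode": config.mode,
            "bands": bands,
        },
        "group_split": {
            "n_high": len(split.high_ids),
            "n_avg": len(split.avg_ids),
            "mean_high": split.mean_high,
            "mean_avg": split.mean_avg,
            "separation_sd_units": split.separation_sd_units,
            "warning": split.warning,
        },
    }

    # --- stage: structural connectomes ------------------------------------
    sc_nets = {sid: build_structural_connectivity(samples[sid]) for sid in sids}
    sc_degree = np.vstack([weighted_degree(sc_nets[sid]).values for sid in sids])

    bart_stat, bart_p = bartlett_test(
        sc_degree[groups == "high"].mean(axis=1),
        sc_degree[groups == "average"].mean(axis=1),
    )
    report["structural"] = {
        "bartlett": {"statistic": bart_stat, "p": bart_p},
        "degree_mcs": _mcs_to_dict(
            mcs_node_metric_test(
                sc_degree,
                groups,
                n_perm=config.n_perm_node,
                alpha=config.alpha,
                n_tests_for_bonferroni=config.bonferroni_structural,
                seed=derive_seed(seed, "mcs", "structural", "degree"),
                roi_labels=roi_labels,
            ),
            roi_labels,
            include_distributions,
        ),
    }

    # --- stage: functional connectomes -------------------------------------
    fc_nets: dict[str, dict[str, WeightedNetwork]] = {}
    for bname in bands:
        fc_nets[bname] = {}
        for sid in sids:
            ts = ts_source(sid, bname)
            env = bandpass_and_envelope(ts, bname)
            fc_nets[bname][sid] = build_functional_connectivity(env)

    report["functional"] = {}
    for bname in bands:
        nets = {sid: fc_nets[bname][sid].clipped_nonnegative() for sid in sids}
        deg = np.vstack([weighted_degree(nets[sid]).values for sid in sids])
        report["functional"][bname] = {
            "degree_mcs": _mcs_to_dict(
                mcs_node_metric_test(
                    deg,
                    groups,
                    n_perm=config.n_perm_node,
                    alpha=config.alpha,
                    n_tests_for_bonferroni=config.bonferroni_functional,
                    seed=derive_seed(seed, "mcs", bname, "degree"),
                    roi_labels=roi_labels,
                ),
                roi_labels,
                include_distributions,
            )
        }

    # --- stage: community structure & modularity null ----------------------
    def group_mean(nets: dict[str, WeightedNetwork], which: str) -> np.ndarray:
        sel = [sid for sid, g in zip(sids, groups) if g == which]
        return np.mean([nets[s].weights for s in sel], axis=0)

    report["modularity"] = {}
    modality_nets: dict[str, dict[str, WeightedNetwork]] = {"structural": sc_nets}
    for bname in bands:
        modality_nets[f"functional_{bname}"] = {
            sid: fc_nets[bname][sid].clipped_nonnegative() for sid in sids
        }
    grand_partitions = {}
    for modality, nets in modality_nets.items():
        entry = {}
        for which in ("high", "average"):
            mean_w = group_mean(nets, which)
            entry[which] = _modnull_to_dict(
                modularity_null_test(
                    mean_w,
                    n_perm=config.n_perm_modularity,
                    seed=derive_seed(seed, "modnull", modality, which),
                )
            )
        grand_mean = np.mean([nets[s].weights for s in sids], axis=0)
        part = leading_eigenvector_communities(grand_mean)
        grand_partitions[modality] = part
        entry["grand_partition"] = {
            "assignment": part.assignment.tolist(),
            "q": part.q,
            "n_modules": part.n_modules,
        }
        report["modularity"][modality] = entry

    # --- stage: segregation MCS --------------------------------------------
    report["segregation"] = {}
    for modality, nets in modality_nets.items():
        part = grand_partitions[modality]
        seg = np.vstack(
            [segregation_coefficient(nets[sid], part).values for sid in sids]
        )
        n_tests = (
            config.bonferroni_structural
            if modality == "structural"
            else config.bonferroni_functional
        )
        report["segregation"][modality] = _mcs_to_dict(
            mcs_node_metric_test(
                seg,
                groups,
                n_perm=config.n_perm_node,
                alpha=config.alpha,
                n_tests_for_bonferroni=n_tests,
                seed=derive_seed(seed, "mcs", modality, "segregation"),
                roi_labels=roi_labels,
            ),
            roi_labels,
            include_distributions,
        )

    # --- stage: global measures + ANCOVA ------------------------------------
    sex = [r.sex for r in records]
    age = [r.age for r in records]
    edu = [r.education for r in records]
    report["global"] = {}
    for modality, nets in modality_nets.items():
        gm = {sid: global_metrics(nets[sid], config.prune_fraction) for sid in sids}
        entry: dict = {
            "per_subject_mean": {
                k: float(np.mean([gm[sid].as_dict()[k] for sid in sids]))
                for k in (
                    "char_path_length",
                    "global_efficiency",
                    "local_efficiency",
                    "density",
                )
            }
        }
        if config.run_ancova:
            entry["ancova"] = {}
            for k in (
                "char_path_length",
                "global_efficiency",
                "local_efficiency",
                "density",
            ):
                values = [gm[sid].as_dict()[k] for sid in sids]
                try:
                    res = ancova_global_metric(
                        values,
                        groups,
                        sex,
                        age,
                        edu,
                        alpha=config.alpha,
                        n_comparisons=config.n_global_comparisons,
                    )
                    entry["ancova"][k] = _ancova_to_dict(res)
                except ValueError as exc:
                    entry["ancova"][k] = {"degenerate": str(exc)}
        report["global"][modality] = entry

    # --- stage: SC-FC similarity --------------------------------------------
    if config.run_sc_fc and bands:
        sc_list = [sc_nets[sid] for sid in sids]
        fc_by_band = {b: [fc_nets[b][sid] for sid in sids] for b in bands}
        try:
            sim = sc_fc_similarity_test(
                sc_list,
                fc_by_band,
                groups,
                sex,
                age,
                edu,
                alpha=config.alpha,
                n_comparisons=max(1, len(bands)),
            )
            report["sc_fc_similarity"] = {
                b: {"r_mean": float(np.mean(r)), "ancova": _ancova_to_dict(res)}
                for b, (r, res) in sim.items()
            }
        except ValueError as exc:
            report["sc_fc_similarity"] = {"degenerate": str(exc)}

    return report
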