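"""End-to-end orchestration: time series -> correlation -> degree-matched
networks -> metrics (+ null-normalized ratios) -> paired group statistics.

``run_pipeline`` takes a :class:`PipelineConfig` and either an on-disk
dataset directory (per-subject TSV files named ``<subject>_<condition>.tsv``
with JSON sidecars) or an in-memory dataset mapping, and produces a
:class:`ResultBundle`: the long-format metric table, per-metric paired
comparison tables, null-normalized ratio tables, per-subject five-number
summaries, optional behavioral/motion correlations, and a manifest that
records every setting needed to re-run the analysis identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .graphs import METRIC_NAMES, Network, compute_metric_set
from .groupstats import (
    AFTER,
    BEFORE,
    behavioral_correlation,
    make_metric_table,
    paired_comparison_by_level,
    subject_summary,
)
from .netbuild import DegreeGrid, feasible_degree_grid, nested_networks
from .nulls import ensemble_mean_metrics, normalized_ratio, null_ensemble
from .timeseries import (
    CorrelationMatrix,
    RoiTimeSeries,
    gated_correlation_matrix,
    modwt_bandpass,
    read_roi_tsv,
)

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "export_tables"]

Key = Tuple[str, str]

#: metrics compared between conditions by default
DEFAULT_METRICS = (
    "entropy",
    "geodesic",
    "clustering",
    "global_efficiency",
    "local_efficiency",
    "degree_variance",
    "degree_kurtosis",
)
#: metrics normalized against the null-ensemble mean
RATIO_METRICS = ("geodesic", "clustering", "global_efficiency", "local_efficiency")

_CONFIG_FIELDS = {
    "input_dir",
    "output_dir",
    "alpha_gate",
    "wavelet",
    "scale",
    "null_size",
    "grid_cap",
    "seed",
    "k_min",
    "k_max",
    "metrics",
    "compute_nulls",
    "subjects",
    "scores_csv",
}


@dataclass
class PipelineConfig:
    """All pipeline settings; serializable to/from a single YAML file."""

    input_dir: Optional[str] = None
    output_dir: Optional[str] = None
    alpha_gate: float = 0.05
    wavelet: str = "db4"
    scale: int = 3
    null_size: int = 30
    grid_cap: int = 16
    seed: int = 0
    k_min: Optional[int] = None  # override: skip the feasibility search
    k_max: Optional[int] = None
    metrics: Tuple[str, ...] = DEFAULT_METRICS
    compute_nulls: bool = True
    subjects: Optional[Tuple[str, ...]] = None  # inclusion list
    scores_csv: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = [m for m in self.metrics if m not in METRIC_NAMES]
        if unknown:
            raise ValueError(f"unknown metrics {unknown}; choose from {METRIC_NAMES}")
        if (self.k_min is None) != (self.k_max is None):
            raise ValueError("k_min and k_max overrides must be given together")
        if self.k_min is not None and self.k_min > self.k_max:  # type: ignore[operator]
            raise ValueError("k_min must not exceed k_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("metrics", "subjects"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("metrics", "subjects"):
            if data[key] is not None:
                data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class ResultBundle:
    """Everything ``run_pipeline`` produces, ready for export or inspection."""

    metric_table: pd.DataFrame
    comparisons: Dict[str, pd.DataFrame]
    ratio_table: Optional[pd.DataFrame]
    ratio_comparisons: Dict[str, pd.DataFrame]
    summaries: pd.DataFrame
    levels: List[int]
    eta_used: Dict[Tuple[str, str, int], float]
    excluded_subjects: List[str]
    behavioral: Optional[pd.DataFrame]
    manifest: Dict


def _load_dataset(input_dir: str | Path) -> Dict[Key, RoiTimeSeries]:
    root = Path(input_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"input directory {root} does not exist")
    dataset: Dict[Key, RoiTimeSeries] = {}
    for tsv in sorted(root.glob("*_*.tsv")):
        subject, condition = tsv.stem.rsplit("_", 1)
        if condition not in (BEFORE, AFTER):
            continue
        dataset[(subject, condition)] = read_roi_tsv(tsv)
    if not dataset:
        raise FileNotFoundError(f"no '<subject>_<condition>.tsv' files under {root}")
    return dataset


def _correlations(
    dataset: Dict[Key, RoiTimeSeries], config: PipelineConfig
) -> Dict[Key, CorrelationMatrix]:
    cms = {}
    for key, ts in sorted(dataset.items()):
        coeffs = modwt_bandpass(ts, scale=config.scale, wavelet=config.wavelet)
        cms[key] = gated_correlation_matrix(coeffs, alpha=config.alpha_gate)
    return cms


def _build_grid(
    cms: Dict[Key, CorrelationMatrix], config: PipelineConfig
) -> DegreeGrid:
    if config.k_min is not None:
        levels = list(range(config.k_min, config.k_max + 1))  # type: ignore[arg-type]
        if len(levels) > config.grid_cap:
            levels = levels[-config.grid_cap :]
        networks: Dict[Tuple[str, str, int], Network] = {}
        eta: Dict[Tuple[str, str, int], float] = {}
        for (subj, cond), cm in sorted(cms.items()):
            for k, (net, e) in nested_networks(cm, levels).items():
                networks[(subj, cond, k)] = net
                eta[(subj, cond, k)] = e
        return DegreeGrid(levels=levels, networks=networks, eta_used=eta)
    return feasible_degree_grid(
        cms,
        ensemble_seed=config.seed,
        null_size=config.null_size,
        grid_cap=config.grid_cap,
    )


def _null_seed(config_seed: int, subj: str, cond: str, level: int) -> int:
    ss = np.random.SeedSequence(
        entropy=config_seed,
        spawn_key=(abs(hash((subj, cond, level))) % (2**31),),
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    config: PipelineConfig,
    dataset: Optional[Dict[Key, RoiTimeSeries]] = None,
) -> ResultBundle:
    """Run the full analysis; ``dataset`` may be passed in memory or loaded
    from ``config.input_dir``."""
    if dataset is None:
        if config.input_dir is None:
            raise ValueError("either a dataset or config.input_dir is required")
        dataset = _load_dataset(config.input_dir)
    if config.subjects is not None:
        dataset = {
            (s, c): ts for (s, c), ts in dataset.items() if s in config.subjects
        }
    subjects = sorted({s for s, _ in dataset})
    for s in subjects:
        have = {c for s2, c in dataset if s2 == s}
        if have != {BEFORE, AFTER}:
            raise ValueError(f"subject {s} lacks a condition: has {sorted(have)}")

    cms = _correlations(dataset, config)
    grid = _build_grid(cms, config)

    rows = []
    ratio_rows = []
    for (subj, cond, level), net in sorted(grid.networks.items()):
        want_full = any(
            m in config.metrics
            for m in ("geodesic", "clustering", "global_efficiency", "local_efficiency")
        )
        if want_full or config.compute_nulls:
            ms = compute_metric_set(net)
            values = ms.as_dict()
        else:  # cheap path: degree-based metrics only
            from .graphs import degree_distribution, degree_moments, shannon_entropy

            var, kur = degree_moments(net)
            values = {
                "entropy": shannon_entropy(degree_distribution(net)),
                "degree_variance": var,
                "degree_kurtosis": kur,
                "mean_degree": float(net.degrees().mean()),
            }
        for metric in config.metrics:
            val = values.get(metric)
            if val is None:
                continue  # e.g. kurtosis undefined on a regular graph
            rows.append((subj, cond, level, metric, float(val)))
        if config.compute_nulls:
            seed = _null_seed(config.seed, subj, cond, level)
            ens = null_ensemble(net, size=config.null_size, seed=seed)
            means = ensemble_mean_metrics(
                [compute_metric_set(m) for m in ens.members]
            )
            for metric in RATIO_METRICS:
                if metric not in config.metrics:
                    continue
                ratio = normalized_ratio(values[metric], means[metric])
                if ratio is not None:
                    ratio_rows.append((subj, cond, level, metric, float(ratio)))

    table = make_metric_table(rows)
    comparisons = {
        m: paired_comparison_by_level(table, m)
        for m in config.metrics
        if m in set(table["metric"])
    }
    ratio_table = make_metric_table(ratio_rows) if ratio_rows else None
    ratio_comparisons = (
        {
            m: comp
            for m in sorted(set(ratio_table["metric"]))
            if not (comp := paired_comparison_by_level(ratio_table, m, strict=False)).empty
        }
        if ratio_table is not None
        else {}
    )
    summaries = subject_summary(table)

    behavioral = None
    if config.scores_csv is not None:
        behavioral = _behavioral_report(table, config.scores_csv)

    manifest = {
        "package": "entronet",
        "version": "0.1.0",
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "levels": grid.levels,
        "subjects": subjects,
        "excluded_subjects": grid.excluded_subjects,
        "conventions": {
            "entropy_log_base": "e (nats)",
            "kurtosis": "Pearson m4/m2^2 (no -3)",
            "quartiles": "median_unbiased order-statistic interpolation",
            "correlation_df": "nominal n_obs - 2 on wavelet coefficients",
            "multiple_testing": "none across levels (per-level p with flags)",
        },
    }
    return ResultBundle(
        metric_table=table,
        comparisons=comparisons,
        ratio_table=ratio_table,
        ratio_comparisons=ratio_comparisons,
        summaries=summaries,
        levels=grid.levels,
        eta_used=grid.eta_used,
        excluded_subjects=grid.excluded_subjects,
        behavioral=behavioral,
        manifest=manifest,
    )


def _behavioral_report(table: pd.DataFrame, scores_csv: str | Path) -> pd.DataFrame:
    """Correlate per-subject metric changes (after - before, averaged over
    levels) with each score delta column (e.g. cadss_delta, bprs_delta,
    fd_delta)."""
    scores = pd.read_csv(scores_csv)
    if "subject" not in scores.columns:
        raise ValueError("scores CSV needs a 'subject' column")
    scores = scores.set_index("subject")
    per_subj = (
        table.pivot_table(
            index=["metric", "subject"], columns="condition", values="value"
        )
        .assign(delta=lambda d: d[AFTER] - d[BEFORE])
        .reset_index()
    )
    records = []
    for metric, grp in per_subj.groupby("metric"):
        grp = grp.set_index("subject")
        common = grp.index.intersection(scores.index)
        for col in scores.columns:
            x = scores.loc[common, col].to_numpy(float)
            y = grp.loc[common, "delta"].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            r, p = behavioral_correlation(x[ok], y[ok])
            records.append(
                {"metric": metric, "score": col, "n": int(ok.sum()), "r": r, "p": p}
            )
    return pd.DataFrame.from_records(records)


def export_tables(
    bundle: ResultBundle,
    out_dir: str | Path,
    metrics: Optional[Sequence[str]] = None,
) -> List[Path]:
    """Write the bundle as CSV/JSON files; returns the paths written.

    An empty metric selection writes nothing and warns (exit is still
    success).  Comparison tables carry per-level means +- SD for original
    (and, when available, null-normalized) networks, with p-value flags.
    """
    out = Path(out_dir)
    if metrics is not None and len(metrics) == 0:
        warnings.warn("empty metric selection; nothing exported", stacklevel=2)
        return []
    out.mkdir(parents=True, exist_ok=True)
    chosen = set(metrics) if metrics is not None else None
    written: List[Path] = []

    def _keep(name: str) -> bool:
        return chosen is None or name in chosen

    tab = bundle.metric_table
    if chosen is not None:
        tab = tab[tab["metric"].isin(chosen)]
    path = out / "metric_table.csv"
    tab.to_csv(path, index=False)
    written.append(path)

    for metric, comp in bundle.comparisons.items():
        if not _keep(metric):
            continue
        path = out / f"comparison_{metric}.csv"
        comp.to_csv(path)
        written.append(path)
    for metric, comp in bundle.ratio_comparisons.items():
        if not _keep(metric):
            continue
        path = out / f"comparison_ratio_{metric}.csv"
        comp.to_csv(path)
        written.append(path)

    path = out / "subject_summaries.csv"
    bundle.summaries.to_csv(path)
    written.append(path)

    if bundle.behavioral is not None:
        path = out / "behavioral_correlations.csv"
        bundle.behavioral.to_csv(path, index=False)
        written.append(path)

    path = out / "manifest.json"
    path.write_text(json.dumps(bundle.manifest, indent=2) + "\n")
    written.append(path)
    return written
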