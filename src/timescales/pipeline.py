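"""End-to-end orchestration of the empirical and model analyses.

The empirical pipeline runs band-pass filtering, per-parcel ACW-0 / ACW-50 /
MF maps, network and cortex means per subject, assumption checks, the two
planned paired contrasts per family (awake-rest vs sleep-rest and
sleep-rest vs sleep-stimulus, Bonferroni factor 2), topographic-similarity
matrices with their paired comparison, the ACW-MF correlation control, and
the fully-asleep-subset direction check.  The model experiment runs the
paired three-condition simulation set for one stimulus scenario and the
per-region Wilcoxon summary.

All outputs are deterministic given (configuration, seed): reports carry no
timestamps and numbers are written with a fixed format, so a rerun is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import DEFAULT_BAND, TimeSeriesMatrix, bandpass, metric_map
from .model import ModelConfig, run_condition_set, region_wilcoxon_summary
from .stats import ac_mf_correlation, assumption_checks, compare_states, stars
from .synthetic import STATES, GeneratorSpec, SyntheticDataset, generate_dataset, subset_fully_asleep
from .topography import CORTEX, ParcelMetricTable, compare_similarity, similarity_matrix

logger = logging.getLogger(__name__)

#: The two planned contrasts per family, in the fixed (a, b) order; the
#: paired t is mean(a - b), so negative t means the later state is larger.
CONTRASTS = (("awake", "sleep_rest"), ("sleep_rest", "sleep_stim"))

#: Metrics entering the primary contrast table.
PRIMARY_METRICS = ("acw0", "mf")


@dataclass
class PipelineConfig:
    """Empirical-pipeline settings."""

    band: tuple[float, float] = DEFAULT_BAND
    n_comparisons: int = 2  # the Bonferroni factor: two planned contrasts per family
    metrics: tuple[str, ...] = ("acw0", "acw50", "mf")
    subset_k: int = 4


@dataclass
class AnalysisReport:
    """Result tables of one empirical-pipeline run."""

    region_means: pd.DataFrame
    contrasts: pd.DataFrame
    assumptions: pd.DataFrame
    similarity: pd.DataFrame
    acmf: pd.DataFrame
    subset_directions: pd.DataFrame
    run_info: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "region_means", "contrasts", "assumptions", "similarity", "acmf",
            "subset_directions",
        ):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
        (outdir / "run_info.json").write_text(json.dumps(self.run_info, indent=2, sort_keys=True))


def _metric_tables(
    dataset: SyntheticDataset, config: PipelineConfig
) -> dict[tuple[str, str], ParcelMetricTable]:
    """Band-pass every run and sweep the per-parcel metrics."""

    tables: dict[tuple[str, str], ParcelMetricTable] = {}
    for state, runs in dataset.data.items():
        per_metric = {m: [] for m in config.metrics}
        for ts in runs:
            filtered = bandpass(ts, *config.band)
            for m in config.metrics:
                per_metric[m].append(metric_map(filtered, m, band=config.band))
        for m in config.metrics:
            tables[(state, m)] = ParcelMetricTable(
                values=np.vstack(per_metric[m]), metric=m, state=state
            )
    return tables


def _region_means(tables, scheme, states, metrics) -> pd.DataFrame:
    rows = []
    families = list(scheme.networks) + [CORTEX]
    for state in states:
        for metric in metrics:
            values = tables[(state, metric)].values
            for family in families:
                cols = scheme.parcels_in(family)
                means = np.nanmean(values[:, cols], axis=1)
                for subject, v in enumerate(means):
                    rows.append(
                        {
                            "state": state, "metric": metric, "region": family,
                            "subject": subject, "value": float(v),
                        }
                    )
    return pd.DataFrame(rows)


def run_empirical_pipeline(
    dataset: SyntheticDataset | GeneratorSpec | None = None,
    config: PipelineConfig | None = None,
    outdir=None,
) -> AnalysisReport:
    """Full empirical analysis of a three-state dataset.

    ``dataset`` may be an existing dataset or a generator spec (generated
    on the fly).  Subjects missing any state would break the paired design;
    the synthetic generator always yields complete subjects, and loaders
    should drop incomplete ones before calling in here.
    """

    if dataset is None:
        dataset = GeneratorSpec()
    if isinstance(dataset, GeneratorSpec):
        dataset = generate_dataset(dataset)
    config = config or PipelineConfig()
    scheme = dataset.spec.parcellation
    states = list(dataset.data)
    logger.info(
        "pipeline: %d subjects, %d parcels, states %s, band %s",
        dataset.spec.n_subjects, scheme.n_parcels, states, config.band,
    )

    tables = _metric_tables(dataset, config)
    region_means = _region_means(tables, scheme, states, config.metrics)
    families = list(scheme.networks) + [CORTEX]

    # paired contrasts (two per family per metric) with Bonferroni(n=2)
    contrast_rows, assumption_rows = [], []
    pivot = region_means.pivot_table(
        index="subject", columns=["state", "metric", "region"], values="value"
    )
    for family in families:
        for metric in PRIMARY_METRICS:
            if metric not in config.metrics:
                continue
            samples = {s: pivot[(s, metric, family)].to_numpy() for s in states}
            rep = assumption_checks(samples)
            for s in states:
                assumption_rows.append(
                    {
                        "region": family, "metric": metric, "state": s,
                        "shapiro_p": rep.shapiro_p[s], "levene_p": rep.levene_p,
                        "pass": rep.shapiro_pass[s] and rep.levene_pass,
                    }
                )
            for a, b in CONTRASTS:
                if a not in samples or b not in samples:
                    continue
                cmp = compare_states(
                    samples[a], samples[b], label=f"{a} vs {b}",
                    n_comparisons=config.n_comparisons,
                )
                contrast_rows.append(
                    {
                        "region": family, "metric": metric, "contrast": cmp.label,
                        "mean_a": cmp.mean_a, "mean_b": cmp.mean_b, "t": cmp.t,
                        "p_raw": cmp.p_raw, "p_bonf": cmp.p_bonf,
                        "stars": stars(cmp.p_bonf), "direction": cmp.direction,
                    }
                )
    contrasts = pd.DataFrame(contrast_rows)
    assumptions = pd.DataFrame(assumption_rows)

    # topographic similarity per family, with the rest-vs-stimulus comparison
    similarity_rows = []
    for family in families:
        for metric in PRIMARY_METRICS:
            if metric not in config.metrics:
                continue
            sims = {
                s: similarity_matrix(tables[(s, metric)], scheme, scope=family)
                for s in states
            }
            row = {"region": family, "metric": metric}
            for s in states:
                row[f"median_r_{s}"] = sims[s].median_r
            if "sleep_rest" in sims and "sleep_stim" in sims:
                cmp = compare_similarity(sims["sleep_rest"], sims["sleep_stim"])
                row.update({"t_rest_vs_stim": cmp.t, "p_rest_vs_stim": cmp.p,
                            "stars": stars(cmp.p), "n_pairs": cmp.n_pairs})
            similarity_rows.append(row)
    similarity = pd.DataFrame(similarity_rows)

    # control analysis: across-subject ACW-MF correlation per family and state
    acmf_rows = []
    if {"acw0", "mf"} <= set(config.metrics):
        for family in families:
            for s in states:
                r, r2, p = ac_mf_correlation(
                    pivot[(s, "acw0", family)].to_numpy(), pivot[(s, "mf", family)].to_numpy()
                )
                acmf_rows.append(
                    {"region": family, "state": s, "r": r, "r_squared": r2, "p": p}
                )
    acmf = pd.DataFrame(acmf_rows)

    # control analysis: direction of changes in the fully-asleep subset
    subset_rows = []
    if config.subset_k and config.subset_k < dataset.spec.n_subjects:
        sub = subset_fully_asleep(dataset, k=config.subset_k)
        sub_tables = _metric_tables(sub, config)
        sub_means = _region_means(sub_tables, scheme, states, PRIMARY_METRICS)
        spv = sub_means.pivot_table(
            index="subject", columns=["state", "metric", "region"], values="value"
        )
        for family in families:
            for metric in PRIMARY_METRICS:
                for a, b in CONTRASTS:
                    diff = float(
                        (spv[(b, metric, family)] - spv[(a, metric, family)]).mean()
                    )
                    subset_rows.append(
                        {
                            "region": family, "metric": metric, "contrast": f"{a} vs {b}",
                            "mean_change": diff,
                            "direction": "increase" if diff > 0 else "decrease",
                        }
                    )
    subset_directions = pd.DataFrame(subset_rows)

    spec_dict = {
        k: v for k, v in asdict(dataset.spec).items() if k != "parcellation"
    }
    run_info = {
        "version": __version__,
        "seed": dataset.spec.seed,
        "generator_spec": json.loads(json.dumps(spec_dict, default=str)),
        "pipeline_config": {"band": list(config.band), "n_comparisons": config.n_comparisons,
                            "metrics": list(config.metrics), "subset_k": config.subset_k},
    }
    run_info["config_hash"] = hashlib.sha256(
        json.dumps(run_info, sort_keys=True).encode()
    ).hexdigest()[:16]

    report = AnalysisReport(
        region_means=region_means, contrasts=contrasts, assumptions=assumptions,
        similarity=similarity, acmf=acmf, subset_directions=subset_directions,
        run_info=run_info,
    )
    if outdir is not None:
        report.save(outdir)
    return report


@dataclass
class ModelReport:
    """Result tables of one model experiment."""

    acw_tables: dict  # condition -> runs x regions DataFrame
    wilcoxon: pd.DataFrame
    long_table: pd.DataFrame
    run_info: dict = field(default_factory=dict)

    @property
    def n_significant_decrease(self) -> int:
        return self.wilcoxon.attrs["n_significant_decrease"]

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for condition, table in self.acw_tables.items():
            table.to_csv(outdir / f"acw0_{condition}.csv", index=False, float_format="%.10g")
        self.wilcoxon.to_csv(outdir / "wilcoxon.csv", index=False, float_format="%.10g")
        self.long_table.to_csv(outdir / "acw0_long.csv", index=False, float_format="%.10g")
        (outdir / "run_info.json").write_text(json.dumps(self.run_info, indent=2, sort_keys=True))


def run_model_experiment(
    scenario: str = "sine25",
    n_runs: int = 30,
    seed: int = 0,
    config: ModelConfig | None = None,
    alpha: float = 0.05,
    outdir=None,
) -> ModelReport:
    """Paired three-condition simulation set plus the Wilcoxon summary."""

    config = config or ModelConfig()
    tables = run_condition_set(config, scenario=scenario, n_runs=n_runs, seed=seed)
    wil = region_wilcoxon_summary(tables["sleep_rest"], tables["sleep_stim"], alpha=alpha)
    long_rows = []
    for condition, table in tables.items():
        melted = table.melt(var_name="region", value_name="acw0_ms")
        melted.insert(0, "condition", condition)
        melted.insert(1, "run", np.tile(np.arange(len(table)), table.shape[1]))
        long_rows.append(melted)
    long_table = pd.concat(long_rows, ignore_index=True)
    run_info = {
        "version": __version__, "scenario": scenario, "n_runs": n_runs, "seed": seed,
        "alpha": alpha, "duration_s": config.duration, "discard_s": config.discard,
        "dt_s": config.dt, "n_regions": config.n_regions,
        "n_significant_decrease": wil.attrs["n_significant_decrease"],
    }
    report = ModelReport(acw_tables=tables, wilcoxon=wil, long_table=long_table, run_info=run_info)
    if outdir is not None:
        report.save(outdir)
    return report
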