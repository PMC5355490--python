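"""End-to-end pipeline: simulate/read -> filter -> partition -> distributions
-> centiles -> reference comparison, with a manifest for reproducibility.

Filter order is plausibility -> pacing -> minimum-record, so the 10,000-count
rule is evaluated on analyzable samples.  The pacing stage needs labeled
windows to train its classifier; it runs when ground-truth labels are
available (simulated cohorts, or a labels CSV supplied alongside real data)
and is skipped, with a log line, otherwise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as vcio
from .ages import (
    MAX_AGE_DAYS,
    assign_coarse_groups,
    assign_day_groups,
    group_table,
)
from .centiles import (
    CentileTable,
    build_centile_table,
    smooth_centiles_over_age,
)
from .distributions import (
    MIN_OBS_PER_PATIENT_GROUP,
    AgeGroupDistribution,
    PatientAgeDistribution,
    ValueHistogram,
    smooth_pmf,
    VALUE_BINS,
)
from .quality import (
    DEFAULT_TARGET_INCLUSION,
    DEFAULT_WINDOW_LENGTH,
    apply_pacing_filter,
    calibrate_pacing_threshold,
    minimum_record_filter,
    plausibility_filter,
    train_pacing_classifier,
    windowed_features,
)
from .reference import (
    comparison_report,
    load_reference_table,
    reference_percentile_difference,
)
from .synthetic import (
    LABEL_PACED,
    ArtifactSpec,
    CohortConfig,
    LabeledStream,
    inject_artifacts,
    simulate_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class SimulateBlock:
    """Cohort generation parameters for a pipeline run."""

    n_patients: int = 50
    implausible_rate: float = 0.002
    paced_fraction: float = 0.05
    paced_rate: float = 80.0
    paced_jitter: float = 0.5
    variables: tuple[str, ...] = ("HR", "SBP", "MBP", "DBP")


@dataclass
class PipelineConfig:
    outdir: str = "vitalcentiles_out"
    seed: int = 0
    # exactly one of (observations_path [+ metadata_path]) or simulate
    observations_path: Optional[str] = None
    metadata_path: Optional[str] = None
    labels_path: Optional[str] = None
    simulate: Optional[SimulateBlock] = None
    reference_path: Optional[str] = None
    min_records: int = MIN_OBS_PER_PATIENT_GROUP
    pacing_window: int = DEFAULT_WINDOW_LENGTH
    target_inclusion: float = DEFAULT_TARGET_INCLUSION
    pmf_span: float = 0.05
    centile_span: float = 0.3
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_paths = self.observations_path is not None
        has_sim = self.simulate is not None
        if has_paths == has_sim:
            raise ValueError(
                "config must contain exactly one of: input paths, simulate block"
            )
        for name in ("pmf_span", "centile_span"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(simulate=SimulateBlock(**sim) if sim is not None else None, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _acquire_data(config: PipelineConfig):
    if config.simulate is not None:
        sim = config.simulate
        cohort = CohortConfig(
            n_patients=sim.n_patients, seed=config.seed, variables=sim.variables
        )
        metadata, stream = simulate_cohort(cohort)
        spec = ArtifactSpec(
            implausible_rate=sim.implausible_rate,
            paced_fraction=sim.paced_fraction if "HR" in sim.variables else 0.0,
            paced_rate=sim.paced_rate,
            paced_jitter=sim.paced_jitter,
        )
        if spec.implausible_rate > 0 or spec.paced_fraction > 0:
            stream = inject_artifacts(stream, spec, seed=config.seed + 1)
        return metadata, stream.observations, stream.labels
    obs = vcio.read_observations(config.observations_path)
    metadata = vcio.read_metadata(config.metadata_path)
    labels = None
    if config.labels_path:
        lab = vcio.read_labels(config.labels_path)
        merged = obs.merge(lab, on=["patient_id", "time"], how="left")
        labels = merged["label"].fillna("clean").to_numpy()
    return metadata, obs, labels


def _pacing_stage(config: PipelineConfig, stream, labels):
    """Train, calibrate, and apply the pacing filter on the HR sub-stream."""
    hr_mask = (stream["variable"] == "HR").to_numpy()
    hr = stream.loc[hr_mask]
    non_hr = stream.loc[~hr_mask]
    X_parts, y_parts = [], []
    hr_labels = np.asarray(labels)[hr_mask]
    hr_pids = hr["patient_id"].to_numpy()
    for pid, grp in hr.groupby("patient_id", sort=False):
        sel = hr_pids == pid
        vals = grp["value"].to_numpy()
        lab = hr_labels[sel]
        X, starts = windowed_features(vals, config.pacing_window)
        if X.shape[0] == 0:
            continue
        win_paced = np.array(
            [
                (lab[s : s + config.pacing_window] == LABEL_PACED).mean() > 0.5
                for s in starts
            ]
        )
        X_parts.append(X)
        y_parts.append(win_paced)
    if not X_parts:
        return stream, pd.DataFrame(columns=["patient_id", "start", "end"]), {}
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    if np.unique(y).size < 2:
        logger.info("pacing stage: only one window class present; skipping filter")
        return stream, pd.DataFrame(columns=["patient_id", "start", "end"]), {}
    clf = train_pacing_classifier(
        X, y, seed=config.seed, window_length=config.pacing_window
    )
    calibrate_pacing_threshold(clf, X, y, target_inclusion=config.target_inclusion)
    kept_hr, periods = apply_pacing_filter(hr, clf)
    kept = pd.concat([kept_hr, non_hr]).sort_index()
    return kept, periods, dict(clf.metrics)


def build_group_distributions(
    stream: pd.DataFrame,
    metadata: pd.DataFrame,
    min_records: int = MIN_OBS_PER_PATIENT_GROUP,
) -> tuple[list[AgeGroupDistribution], pd.DataFrame]:
    """Quality-filtered stream -> equal-weight age-group distributions.

    Assigns each observation to its age groups from the patient's date of
    birth, keeps patient x group x variable subsets with at least
    ``min_records`` samples, normalizes each into a patient distribution,
    and aggregates with equal patient weight.  Returns the distributions
    plus an exclusion report.
    """
    dob = metadata.set_index("patient_id")["dob"]
    df = stream.copy()
    t = df["time"].to_numpy().astype("datetime64[s]").astype(np.int64)
    b = (
        df["patient_id"].map(dob).to_numpy().astype("datetime64[s]").astype(np.int64)
    )
    age_days = (t - b) / 86_400.0
    in_range = (age_days >= 0) & (age_days <= MAX_AGE_DAYS)
    n_over = int((~in_range).sum())
    if n_over:
        logger.info("excluding %d observations with age outside [0, 18 y]", n_over)
    df = df.loc[in_range]
    age_days = age_days[in_range]
    df = df.assign(
        coarse_group=assign_coarse_groups(age_days),
        day_group=assign_day_groups(age_days),
    )
    dists: list[AgeGroupDistribution] = []
    excluded = []
    for group_col in ("day_group", "coarse_group"):
        sub = df[df[group_col] != ""]
        counts = sub.groupby(["variable", group_col, "patient_id"], sort=True).size()
        for (var, grp_label), patient_counts in counts.groupby(level=[0, 1]):
            eligible = minimum_record_filter(
                patient_counts.droplevel([0, 1]).to_dict(), threshold=min_records
            )
            n_excl = len(patient_counts) - len(eligible)
            if n_excl:
                excluded.append(
                    {"variable": var, "age_group": grp_label, "patients_excluded": n_excl}
                )
            if not eligible:
                continue
            block = sub[
                (sub["variable"] == var)
                & (sub[group_col] == grp_label)
                & sub["patient_id"].isin(eligible)
            ]
            patients = []
            for pid, pgrp in block.groupby("patient_id", sort=True):
                hist = ValueHistogram.from_values(var, pgrp["value"].to_numpy())
                patients.append(
                    PatientAgeDistribution(
                        patient_id=pid, age_group=grp_label, histogram=hist
                    )
                )
            from .distributions import aggregate_equal_weight

            dists.append(aggregate_equal_weight(patients))
    report = pd.DataFrame(
        excluded, columns=["variable", "age_group", "patients_excluded"]
    )
    return dists, report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts under ``config.outdir``.

    Returns a dict with the in-memory results; writes CSVs plus a
    ``manifest.json`` listing every output file with its row count and the
    full configuration, sufficient to re-run the pipeline identically.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed, "files": {}}
    # simulate block stores samplers implicitly; drop non-serializable fields
    files = manifest["files"]

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        files[name] = {"rows": int(len(df))}

    metadata, obs, labels = _acquire_data(config)
    n_in = len(obs)

    obs, n_implausible = plausibility_filter(obs)
    pacing_metrics: dict = {}
    periods = pd.DataFrame(columns=["patient_id", "start", "end"])
    if labels is not None and (obs["variable"] == "HR").any():
        kept_labels = np.asarray(labels)[obs.index.to_numpy()] if len(obs) else labels
        obs, periods, pacing_metrics = _pacing_stage(config, obs, kept_labels)
    else:
        logger.info("no ground-truth labels available; pacing filter skipped")

    filter_report = pd.DataFrame(
        [
            {"rule": "input", "count": n_in},
            {"rule": "implausible_discarded", "count": n_implausible},
            {"rule": "paced_windows_removed", "count": int(len(periods))},
            {"rule": "analyzable", "count": int(len(obs))},
        ]
    )
    _write(filter_report, "filter_report.csv")
    _write(group_table(), "age_groups.csv")

    dists, exclusion_report = build_group_distributions(
        obs, metadata, min_records=config.min_records
    )
    _write(exclusion_report, "exclusions.csv")
    for d in dists:
        d.pmf_smoothed = smooth_pmf(d.pmf, span=config.pmf_span)

    dist_rows = []
    moment_rows = []
    for d in dists:
        occupied = np.nonzero((d.pmf > 0) | (d.pmf_smoothed > 0))[0]
        for i in occupied:
            dist_rows.append(
                {
                    "variable": d.variable,
                    "age_group": d.age_group,
                    "value": int(VALUE_BINS[i]),
                    "pmf": d.pmf[i],
                    "pmf_smoothed": d.pmf_smoothed[i],
                }
            )
        moment_rows.append(
            {
                "variable": d.variable,
                "age_group": d.age_group,
                "n_patients": d.n_patients,
                "skewness": d.skewness,
                "excess_kurtosis": d.excess_kurtosis,
            }
        )
    _write(pd.DataFrame(dist_rows), "distributions.csv")
    _write(pd.DataFrame(moment_rows), "moments.csv")

    from .ages import enumerate_age_groups

    kind_of = {g.label: g.kind for g in enumerate_age_groups()}
    tables: dict[tuple[str, str, str], CentileTable] = {}
    for var in sorted({d.variable for d in dists}):
        for kind in ("day_level", "coarse"):
            group_dists = [
                d for d in dists if d.variable == var and kind_of[d.age_group] == kind
            ]
            if not group_dists:
                continue
            raw = build_centile_table(group_dists)
            smoothed = smooth_centiles_over_age(raw, span=config.centile_span)
            for state, tab in (("raw", raw), ("smoothed", smoothed)):
                name = f"centiles_{var}_{kind}_{state}.csv"
                vcio.write_centile_table(tab, outdir / name)
                files[name] = {"rows": int(len(tab.data))}
                tables[(var, kind, state)] = tab
    if not tables:
        logger.warning(
            "no patient x age-group subset reached %d observations; "
            "centile tables are empty",
            config.min_records,
        )

    comparison = None
    percentile_diff = None
    if config.reference_path:
        ref = load_reference_table(config.reference_path)
        cmp_frames = []
        for var in sorted({d.variable for d in dists}):
            if not (ref.data["variable"] == var).any():
                continue
            cmp_frames.append(
                comparison_report([d for d in dists if d.variable == var], ref)
            )
        if cmp_frames:
            comparison = pd.concat(cmp_frames, ignore_index=True)
            _write(comparison, "comparison.csv")
        if ("SBP", "coarse", "raw") in tables and (ref.data["variable"] == "SBP").any():
            diff_df, mean, sd = reference_percentile_difference(
                tables[("SBP", "coarse", "raw")], ref, level=5
            )
            diff_df = diff_df.assign(summary_mean=mean, summary_sd=sd)
            _write(diff_df, "percentile_difference.csv")
            percentile_diff = (diff_df, mean, sd)

    manifest["config"].pop("simulate", None)
    if config.simulate is not None:
        manifest["config"]["simulate"] = dataclasses.asdict(config.simulate)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return {
        "metadata": metadata,
        "observations": obs,
        "filter_report": filter_report,
        "pacing_metrics": pacing_metrics,
        "distributions": dists,
        "centile_tables": tables,
        "comparison": comparison,
        "percentile_difference": percentile_diff,
        "manifest": manifest,
    }
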