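"""End-to-end study orchestration.

Reproduces the full analysis workflow on real or simulated cohorts: load
tables, strip exogenous metabolites, summarize the cohort, draw a
PMI-stratified training/test split, and — per protocol and per PMI range
(full window and restricted to <= 100 h) — select the component
configuration by repeated cross-validation, fit the age-constrained model,
run the randomization test, predict the held-out test set (SDEP), run
stability selection and the age-corrected univariate profiles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import pearsonr

from . import ocpls2, stability, univariate
from .io_preprocess import (
    ConcentrationTable,
    DEFAULT_EXOGENOUS,
    autoscale,
    exclude_exogenous,
    read_concentration_table,
    read_metadata,
)
from .synthetic import GeneratorConfig, simulate_cohort

__all__ = [
    "SplitPlan",
    "StudyConfig",
    "stratified_split",
    "restrict_range",
    "cohort_summary",
    "run_study",
]

log = logging.getLogger("pfpmi")


@dataclass
class SplitPlan:
    """A stratified training/test partition of a cohort."""

    training_ids: list[str]
    test_ids: list[str]
    pmi_bins: list[float]
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.training_ids) & set(self.test_ids):
            raise ValueError("training and test sets overlap")


def stratified_split(
    metadata: pd.DataFrame,
    train_size: int = 18,
    test_size: int = 6,
    n_bins: int = 4,
    seed: int | None = None,
    max_attempts: int = 100,
) -> SplitPlan:
    """PMI-stratified random split matching the cohort's sex/age make-up.

    PMI is cut into ``n_bins`` equal-frequency bins; each bin contributes
    test members in proportion to its size (largest-remainder rounding),
    drawn uniformly within the bin.  Draws are rejected until the training
    set's male count is within one sample of the cohort proportion and its
    mean age within half a cohort SD of the cohort mean.
    """
    n = len(metadata)
    if train_size + test_size != n:
        raise ValueError(f"train+test must equal the cohort size {n}")
    pmi = metadata["pmi_hours"].to_numpy(dtype=float)
    ids = metadata["sample_id"].astype(str).to_numpy()
    sex = metadata["sex"].to_numpy()
    age = metadata["age_years"].to_numpy(dtype=float)

    edges = np.quantile(pmi, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    bins = np.clip(np.searchsorted(edges, pmi, side="right") - 1, 0, len(edges) - 2)
    bin_sizes = np.bincount(bins, minlength=len(edges) - 1)
    if np.any(bin_sizes == 0):
        raise ValueError("empty PMI bin; reduce n_bins")

    # largest-remainder allocation of test slots per bin
    quota = test_size * bin_sizes / n
    alloc = np.floor(quota).astype(int)
    rem = test_size - alloc.sum()
    order = np.argsort(-(quota - alloc))
    alloc[order[:rem]] += 1

    rng = np.random.default_rng(seed)
    male_frac = np.mean(sex == "M")
    mean_age, sd_age = age.mean(), age.std(ddof=1)
    for attempt in range(max_attempts):
        test_idx: list[int] = []
        for b, k in enumerate(alloc):
            members = np.flatnonzero(bins == b)
            if k > len(members):
                raise ValueError("test allocation exceeds bin size")
            test_idx.extend(rng.choice(members, size=k, replace=False))
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        males_train = np.sum(sex[train_mask] == "M")
        if abs(males_train - male_frac * train_size) > 1:
            continue
        if abs(age[train_mask].mean() - mean_age) > 0.5 * sd_age:
            continue
        return SplitPlan(
            training_ids=list(ids[train_mask]),
            test_ids=list(ids[sorted(test_idx)]),
            pmi_bins=[float(e) for e in edges],
            seed=seed,
        )
    raise ValueError(
        f"no split satisfying the sex/age balance found in {max_attempts} "
        "attempts; try another seed or fewer bins"
    )


def restrict_range(
    metadata: pd.DataFrame,
    tables: dict[str, ConcentrationTable] | None = None,
    max_pmi: float = 100.0,
) -> tuple[pd.DataFrame, dict[str, ConcentrationTable] | None]:
    """Keep samples with PMI <= max_pmi in the metadata and aligned tables."""
    pmi = metadata["pmi_hours"].to_numpy(dtype=float)
    if max_pmi <= pmi.min():
        n_left = int(np.sum(pmi <= max_pmi))
        raise ValueError(f"only {n_left} sample(s) at PMI <= {max_pmi}")
    keep = pmi <= max_pmi
    n_left = int(keep.sum())
    if n_left < 6:
        raise ValueError(f"only {n_left} samples remain below {max_pmi} h")
    if n_left < 10:
        warnings.warn(f"only {n_left} samples remain below {max_pmi} h")
    meta_r = metadata.loc[keep].reset_index(drop=True)
    if tables is None:
        return meta_r, None
    kept_ids = set(meta_r["sample_id"].astype(str))
    out = {}
    for proto, table in tables.items():
        mask = [sid in kept_ids for sid in table.sample_ids]
        out[proto] = ConcentrationTable(
            sample_ids=[s for s, m in zip(table.sample_ids, mask) if m],
            metabolite_names=list(table.metabolite_names),
            values=table.values[np.asarray(mask)],
            protocol=table.protocol,
        )
    return meta_r, out


def cohort_summary(metadata: pd.DataFrame) -> dict:
    """Mean/SD of age and PMI, sex counts, and the PMI-age correlation."""
    age = metadata["age_years"].to_numpy(dtype=float)
    pmi = metadata["pmi_hours"].to_numpy(dtype=float)
    r, p = pearsonr(pmi, age)
    return {
        "n": len(metadata),
        "age_mean": float(age.mean()),
        "age_sd": float(age.std(ddof=1)),
        "age_min": float(age.min()),
        "age_max": float(age.max()),
        "pmi_mean": float(pmi.mean()),
        "pmi_sd": float(pmi.std(ddof=1)),
        "pmi_min": float(pmi.min()),
        "pmi_max": float(pmi.max()),
        "n_male": int(np.sum(metadata["sex"] == "M")),
        "n_female": int(np.sum(metadata["sex"] == "F")),
        "pmi_age_r": float(r),
        "pmi_age_p": float(p),
    }


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    seed: int = 0
    # inputs: either file paths per protocol + metadata path, or simulation
    table_paths: dict[str, str] = field(default_factory=dict)
    metadata_path: str | None = None
    simulate: GeneratorConfig | None = None
    exclusions: tuple[str, ...] = DEFAULT_EXOGENOUS
    constraint: str = "age_years"
    ranges: tuple[float | None, ...] = (None, 100.0)   # None = full window
    train_size: int = 18
    test_size: int = 6
    split_bins: int = 4
    max_predictive: int = 2
    max_non_predictive: int = 1
    cv_k: int = 5
    cv_repetitions: int = 20
    n_permutations: int = 999
    stability: stability.StabilitySettings = field(
        default_factory=stability.StabilitySettings
    )
    run_randomization: bool = True
    run_stability: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = GeneratorConfig(**raw["simulate"])
        if "stability" in raw and raw["stability"] is not None:
            raw["stability"] = stability.StabilitySettings(**raw["stability"])
        for key in ("exclusions", "ranges"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_inputs(config: StudyConfig):
    if config.simulate is not None:
        meta, tables, _ = simulate_cohort(config.simulate)
        return meta, tables
    if not config.table_paths or config.metadata_path is None:
        raise ValueError("config must give either simulate or table/metadata paths")
    meta = read_metadata(config.metadata_path)
    tables = {
        proto: read_concentration_table(path, protocol=proto)
        for proto, path in config.table_paths.items()
    }
    return meta, tables


def _align(table: ConcentrationTable, ids: list[str]) -> np.ndarray:
    idx = [table.sample_ids.index(s) for s in ids]
    return table.values[idx]


def _analyze_dataset(
    table: ConcentrationTable,
    meta: pd.DataFrame,
    split: SplitPlan,
    config: StudyConfig,
    seed_seq: np.random.SeedSequence,
) -> dict:
    """Model one protocol x range dataset end to end."""
    meta_idx = meta.set_index(meta["sample_id"].astype(str))
    ids_all = [s for s in table.sample_ids]
    train_ids = [s for s in split.training_ids if s in ids_all]
    test_ids = [s for s in split.test_ids if s in ids_all]

    y_tr = meta_idx.loc[train_ids, "pmi_hours"].to_numpy(dtype=float)
    z_tr = meta_idx.loc[train_ids, config.constraint].to_numpy(dtype=float)[:, None]
    X_tr_raw = _align(table, train_ids)

    scaled = autoscale(
        ConcentrationTable(train_ids, table.metabolite_names, X_tr_raw,
                           protocol=table.protocol)
    )
    names = scaled.metabolite_names

    ss = seed_seq.spawn(4)
    n_pred, n_orth = ocpls2.select_components(
        X_tr_raw[:, [table.metabolite_names.index(m) for m in names]],
        y_tr,
        z_tr,
        max_predictive=config.max_predictive,
        max_non_predictive=config.max_non_predictive,
        k=config.cv_k,
        repetitions=config.cv_repetitions,
        seed=ss[0],
    )
    model = ocpls2.fit(scaled.values, y_tr, z_tr, n_pred, n_orth,
                       metabolite_names=names)
    sdec, r2 = ocpls2.performance_metrics(y_tr, ocpls2.predict(model, scaled.values))
    X_for_cv = X_tr_raw[:, [table.metabolite_names.index(m) for m in names]]
    q2, sdecv = ocpls2.repeated_cv(
        X_for_cv, y_tr, z_tr, n_pred, n_orth,
        k=config.cv_k, repetitions=config.cv_repetitions,
        rng=np.random.default_rng(ss[1]),
    )

    p_r2 = p_q2 = None
    if config.run_randomization:
        p_r2, p_q2 = ocpls2.randomization_test(
            scaled.values, y_tr, z_tr, n_pred, n_orth,
            n_permutations=config.n_permutations,
            k=config.cv_k, repetitions=config.cv_repetitions,
            seed=ss[2],
        )

    sdep = None
    test_pred = {}
    if test_ids:
        y_te = meta_idx.loc[test_ids, "pmi_hours"].to_numpy(dtype=float)
        X_te = _align(table, test_ids)
        scaled_te = autoscale(
            ConcentrationTable(test_ids, table.metabolite_names, X_te,
                               protocol=table.protocol),
            reference=scaled,
        )
        y_hat = ocpls2.predict(model, scaled_te.values)
        sdep = float(np.sqrt(np.mean((y_te - y_hat) ** 2)))
        test_pred = {sid: float(v) for sid, v in zip(test_ids, y_hat)}

    stab_report = None
    if config.run_stability:
        stab_settings = dataclasses.replace(
            config.stability, n_predictive=n_pred, n_non_predictive=n_orth
        )
        stab_report = stability.run_stability_selection(
            X_for_cv, y_tr, z_tr,
            settings=stab_settings,
            seed=ss[3],
            metabolite_names=names,
        )

    ids_used = train_ids + test_ids
    prof = univariate.profile_table(
        ConcentrationTable(
            ids_used, names,
            _align(table, ids_used)[:, [table.metabolite_names.index(m) for m in names]],
            protocol=table.protocol,
        ),
        meta_idx.loc[ids_used, "pmi_hours"].to_numpy(dtype=float),
        meta_idx.loc[ids_used, config.constraint].to_numpy(dtype=float),
    )
    if stab_report is not None:
        prof = prof.merge(
            stab_report[["metabolite", "selection_frequency", "null_frequency",
                         "p_value", "relevant"]].rename(
                columns={"p_value": "stability_p"}),
            on="metabolite", how="left",
        )

    performance = ocpls2.ModelPerformance(
        r2=r2, q2=q2, sdec=sdec, sdecv=sdecv, sdep=sdep,
        p_r2=p_r2, p_q2=p_q2,
        n_predictive=n_pred, n_non_predictive=n_orth,
    )
    return {
        "performance": dataclasses.asdict(performance),
        "n_training": len(train_ids),
        "n_test": len(test_ids),
        "test_predictions": test_pred,
        "n_relevant": int(stab_report["relevant"].sum()) if stab_report is not None else None,
        "stability": stab_report,
        "profiles": prof,
    }


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full workflow; returns (and optionally writes) the report.

    The report nests results per protocol and per PMI range; the restricted
    range reuses the full-range split minus the samples above the cutoff.
    Numbers follow the reporting precision of the field: R2/Q2 are left at
    full precision in the report and rounded only for display.
    """
    meta, tables = _load_inputs(config)
    tables = {p: exclude_exogenous(t, config.exclusions) for p, t in tables.items()}
    summary = cohort_summary(meta)
    log.info("cohort: %s", summary)

    root = np.random.SeedSequence(config.seed)
    ss_split, ss_models = root.spawn(2)
    split = stratified_split(
        meta,
        train_size=config.train_size,
        test_size=config.test_size,
        n_bins=config.split_bins,
        seed=ss_split,
    )

    report: dict = {
        "seed": config.seed,
        "cohort_summary": summary,
        "split": {
            "training_ids": split.training_ids,
            "test_ids": split.test_ids,
            "pmi_bins": split.pmi_bins,
        },
        "datasets": {},
    }
    model_seeds = ss_models.spawn(len(tables) * len(config.ranges))
    i = 0
    for proto, table in tables.items():
        for max_pmi in config.ranges:
            label = f"{proto}_full" if max_pmi is None else f"{proto}_le{int(max_pmi)}"
            if max_pmi is None:
                meta_r, table_r = meta, table
            else:
                meta_r, tabs = restrict_range(meta, {proto: table}, max_pmi)
                table_r = tabs[proto]
            log.info("dataset %s: n=%d", label, len(meta_r))
            result = _analyze_dataset(table_r, meta_r, split, config, model_seeds[i])
            i += 1
            report["datasets"][label] = result
    if outdir is not None:
        _write_report(report, Path(outdir))
    return report


def _write_report(report: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    serializable = {
        "seed": report["seed"],
        "cohort_summary": report["cohort_summary"],
        "split": report["split"],
        "datasets": {},
    }
    for label, res in report["datasets"].items():
        serializable["datasets"][label] = {
            k: v for k, v in res.items() if k not in ("stability", "profiles")
        }
        if res["stability"] is not None:
            res["stability"].to_csv(outdir / f"stability_{label}.csv", index=False)
        res["profiles"].to_csv(outdir / f"profiles_{label}.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(serializable, fh, indent=1)
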