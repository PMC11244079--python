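"""Two-stage classification of unknown pips and allocation reporting.

Stage 1 discriminates wild vs domestic morphotypes on a balanced reference
(an identical number of randomly selected pips per status class), using
stepwise variable selection, linear classification functions and
leave-one-out cross-validation.  Stage 2 takes only the unknowns classified
as domestic and assigns each to one of the individual modern cultivars with a
multi-class LDA under equal priors.  Reporting aggregates assignments per
site: integer-rounded wild/domestic percentages, per-cultivar count tables
(with a minimum-count filter for the headline table), and percentage
breakdowns of assigned pips by berry colour and by the geographic origin of
the assigned cultivar.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import config as _config
from .efd import FEATURE_NAMES, features
from .lda import (
    LabelledFeatures,
    LDAModel,
    LOOCVResult,
    StepEvent,
    classify,
    fit_lda,
    loocv,
    stepwise_select,
    trace_to_frame,
)
from .outline import resample_outline, trace_outline
from .synthetic import ShapeClassSpec, generate_cultivar_metadata, iter_population

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceSet",
    "Stage1Result",
    "Stage2Result",
    "AllocationReport",
    "balance_reference",
    "stage1_wild_domestic",
    "stage2_cultivar_assignment",
    "allocation_report",
    "round_half_away",
    "run_pipeline",
    "PipelineResult",
]


@dataclass
class ReferenceSet:
    """Reference features with status labels and cultivar metadata.

    ``features.y`` holds "wild"/"domestic"; ``cultivar_labels`` carries the
    cultivar id of each domestic sample and None for wild samples.
    """

    features: LabelledFeatures
    cultivar_labels: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.cultivar_labels = np.asarray(self.cultivar_labels, dtype=object)
        if len(self.cultivar_labels) != self.features.n:
            raise ValueError("cultivar_labels length mismatch")
        known = set(self.metadata["cultivar_id"])
        for status, cv in zip(self.features.y, self.cultivar_labels):
            if status == "domestic":
                if cv is None or cv not in known:
                    raise ValueError(
                        f"domestic sample with unknown cultivar id {cv!r}"
                    )
            elif cv is not None:
                raise ValueError("wild sample must not carry a cultivar id")


def balance_reference(
    ref: ReferenceSet, n_per_class: int, seed: Optional[int] = None
) -> ReferenceSet:
    """Random subsample to exactly ``n_per_class`` pips per status class."""
    rng = np.random.default_rng(seed)
    keep: List[np.ndarray] = []
    for status in ("wild", "domestic"):
        idx = np.flatnonzero(ref.features.y == status)
        if len(idx) < n_per_class:
            raise ValueError(
                f"cannot balance: {len(idx)} {status} samples available, "
                f"{n_per_class} requested"
            )
        keep.append(np.sort(rng.choice(idx, size=n_per_class, replace=False)))
    sel = np.concatenate(keep)
    return ReferenceSet(
        features=LabelledFeatures(
            ref.features.X[sel],
            ref.features.y[sel],
            ref.features.sample_ids[sel],
        ),
        cultivar_labels=ref.cultivar_labels[sel],
        metadata=ref.metadata,
    )


@dataclass
class Stage1Result:
    assignments: pd.DataFrame  # sample_id, site, status, posterior
    model: LDAModel
    trace: List[StepEvent]
    loocv: LOOCVResult
    resubstitution_accuracy: float


def _analysis_params(params: Optional[dict]) -> dict:
    base = _config.default_config()["analysis"]
    base.update(params or {})
    return base


def stage1_wild_domestic(
    ref: ReferenceSet,
    unknowns: LabelledFeatures,
    params: Optional[dict] = None,
) -> Stage1Result:
    """Wild/domestic discrimination of unknowns against the reference.

    Runs stepwise selection and fits classification functions on the
    reference status labels, reports LOOCV and resubstitution accuracy, and
    assigns every unknown to wild or domestic.  ``unknowns.y`` is used as the
    site label of each unknown sample.
    """
    if unknowns.n == 0:
        raise ValueError("no unknown samples to classify")
    p = _analysis_params(params)
    data = ref.features
    selected, trace = stepwise_select(
        data, p["f_enter"], p["f_remove"], p["tolerance_min"]
    )
    model = fit_lda(data, selected, p["priors"])
    cv = loocv(data, selected, p["priors"])
    resub = classify(model, data.X)
    resub_acc = float(np.mean(resub.labels == data.y))
    res = classify(model, unknowns.X)
    post = np.array(
        [
            res.posteriors[i, list(model.groups).index(lab)]
            if lab is not None
            else np.nan
            for i, lab in enumerate(res.labels)
        ]
    )
    assignments = pd.DataFrame(
        {
            "sample_id": unknowns.sample_ids,
            "site": unknowns.y,
            "status": res.labels,
            "posterior": post,
        }
    )
    return Stage1Result(assignments, model, trace, cv, resub_acc)


@dataclass
class Stage2Result:
    assignments: pd.DataFrame  # sample_id, site, cultivar_id, posterior
    model: LDAModel
    trace: List[StepEvent]
    dropped_cultivars: List[str]


def stage2_cultivar_assignment(
    ref: ReferenceSet,
    domestic_unknowns: LabelledFeatures,
    params: Optional[dict] = None,
) -> Stage2Result:
    """Assign domestic-classified unknowns to individual cultivars.

    Trains a multi-class LDA (equal priors) with cultivar id as the group
    label on the domestic reference samples.  Cultivars with fewer than
    ``min_per_cultivar`` reference samples are dropped with a warning.
    ``domestic_unknowns.y`` carries site labels.
    """
    p = _analysis_params(params)
    dom = np.flatnonzero(ref.features.y == "domestic")
    if dom.size == 0:
        raise ValueError("reference contains no domestic samples")
    cultivars = ref.cultivar_labels[dom]
    counts = pd.Series(cultivars).value_counts()
    small = sorted(counts[counts < p["min_per_cultivar"]].index)
    for cv_id in small:
        logger.warning(
            "cultivar %s has %d reference samples (< %d); dropped",
            cv_id,
            counts[cv_id],
            p["min_per_cultivar"],
        )
    keep = np.array([c not in small for c in cultivars])
    dom = dom[keep]
    data = LabelledFeatures(
        ref.features.X[dom],
        ref.cultivar_labels[dom].astype(str),
        ref.features.sample_ids[dom],
    )
    if data.n - data.n_groups <= data.p:
        raise ValueError(
            f"insufficient reference degrees of freedom: n={data.n}, "
            f"g={data.n_groups}, p={data.p}"
        )
    if p.get("stepwise_stage2", True):
        selected, trace = stepwise_select(
            data, p["f_enter"], p["f_remove"], p["tolerance_min"]
        )
    else:
        selected, trace = list(range(data.p)), []
    model = fit_lda(data, selected, "equal")
    res = classify(model, domestic_unknowns.X)
    groups = list(model.groups)
    post = np.array(
        [
            res.posteriors[i, groups.index(lab)] if lab is not None else np.nan
            for i, lab in enumerate(res.labels)
        ]
    )
    assignments = pd.DataFrame(
        {
            "sample_id": domestic_unknowns.sample_ids,
            "site": domestic_unknowns.y,
            "cultivar_id": res.labels,
            "posterior": post,
        }
    )
    return Stage2Result(assignments, model, trace, [str(s) for s in small])


def round_half_away(x) -> np.ndarray:
    """Integer rounding, halves away from zero (0.5 -> 1, -0.5 -> -1)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def _percent_table(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=1)
    pct = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    return pct.fillna(0.0).apply(round_half_away)


@dataclass
class AllocationReport:
    """Aggregated counts and integer percentages of the assignments."""

    status_counts: pd.DataFrame  # site x {domestic, wild}
    status_percent: pd.DataFrame
    cultivar_counts: pd.DataFrame  # cultivar x (sites..., total); unfiltered
    cultivar_counts_filtered: pd.DataFrame  # total >= min_count
    colour_percent: pd.DataFrame  # site x colour, over assigned pips
    region_percent: pd.DataFrame  # site x origin region, over assigned pips
    min_count: int = 10


def allocation_report(
    assignments: pd.DataFrame,
    metadata: pd.DataFrame,
    min_count: int = 10,
) -> AllocationReport:
    """Aggregate per-site assignment results into the published-style report.

    ``assignments`` needs columns sample_id, site, status and cultivar_id
    (cultivar_id empty/None exactly for wild pips).  Percentages are rounded
    half away from zero; colour and region percentages weight by assigned
    pips, not by distinct cultivars.
    """
    df = assignments.copy()
    sites = list(pd.unique(df["site"]))

    status_counts = (
        pd.crosstab(df["site"], df["status"])
        .reindex(index=sites)
        .reindex(columns=["domestic", "wild"], fill_value=0)
    )
    status_percent = _percent_table(status_counts)

    assigned = df[df["status"] == "domestic"].dropna(subset=["cultivar_id"])
    meta = metadata.set_index("cultivar_id")
    missing = sorted(set(assigned["cultivar_id"]) - set(meta.index))
    if missing:
        raise KeyError(f"assigned cultivars missing from metadata: {missing}")

    cultivar_counts = (
        pd.crosstab(assigned["cultivar_id"], assigned["site"])
        .reindex(columns=sites, fill_value=0)
    )
    cultivar_counts["total"] = cultivar_counts.sum(axis=1)
    cultivar_counts = cultivar_counts.sort_values("total", ascending=False)
    filtered = cultivar_counts[cultivar_counts["total"] >= min_count]

    assigned = assigned.assign(
        colour=assigned["cultivar_id"].map(meta["colour"]),
        origin_region=assigned["cultivar_id"].map(meta["origin_region"]),
    )
    colour_counts = pd.crosstab(assigned["site"], assigned["colour"]).reindex(
        index=sites, fill_value=0
    )
    region_counts = pd.crosstab(
        assigned["site"], assigned["origin_region"]
    ).reindex(index=sites, fill_value=0)

    return AllocationReport(
        status_counts=status_counts,
        status_percent=status_percent,
        cultivar_counts=cultivar_counts,
        cultivar_counts_filtered=filtered,
        colour_percent=_percent_table(colour_counts),
        region_percent=_percent_table(region_counts),
        min_count=min_count,
    )


# ---------------------------------------------------------------------------
# End-to-end orchestration on generated data
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    reference: ReferenceSet
    stage1: Stage1Result
    stage2: Stage2Result
    report: AllocationReport
    truth: pd.DataFrame  # per-unknown true class / cultivar
    config: dict
    seed: int
    elapsed_s: float = 0.0
    outputs: Dict[str, str] = field(default_factory=dict)


def _extract_features_stream(specs, image_size, seed, n_points, min_object_px):
    ids, labels, X = [], [], []
    for sample_id, label, _coefs, sil in iter_population(
        specs, image_size=image_size, seed=seed
    ):
        outline = resample_outline(trace_outline(sil, min_object_px), n_points)
        ids.append(sample_id)
        labels.append(label)
        X.append(features(outline))
    return np.array(ids), np.array(labels, dtype=object), np.vstack(X)


def _cultivar_specs(cfg: dict, metadata: pd.DataFrame, n_each: int, seed: int):
    """Per-cultivar shape classes around the domestic template."""
    from .synthetic import _default_covariance, _template

    gen = cfg["generator"]
    rng = np.random.default_rng(seed)
    base = _template("domestic", cfg)
    sd = np.repeat(np.array(gen["coefficient_sd"], dtype=float), 4)
    between = gen["between_cultivar_factor"] * sd
    within_cov = _default_covariance(cfg, factor=gen["within_cultivar_factor"])
    specs = []
    for cv_id in metadata["cultivar_id"]:
        mean = base + between * rng.standard_normal(len(base))
        specs.append(
            ShapeClassSpec(cv_id, mean, within_cov, n_each, gen["length_px"])
        )
    return specs


def run_pipeline(
    config: Optional[dict] = None,
    seed: int = 0,
    out_dir=None,
) -> PipelineResult:
    """Generate the study populations, run both stages, and report.

    Executes simulate -> extract -> features -> stage 1 -> stage 2 -> report
    on synthetic data drawn under ``config`` (defaults to the full-scale
    default configuration).  Fully reproducible from ``seed``; if ``out_dir``
    is given, writes features, assignments, count tables, model JSON and a
    manifest there.
    """
    t0 = time.monotonic()
    cfg = _config.merge_config(_config.default_config(), config)
    if config and "sites" in config:  # site tables override wholesale
        cfg["sites"] = {k: dict(v) for k, v in config["sites"].items()}
    gen, ana, refcfg = cfg["generator"], cfg["analysis"], cfg["reference"]
    image_size, n_points = gen["image_size"], ana["n_points"]
    min_px = ana["min_object_px"]
    master = np.random.default_rng(seed)
    seeds = {
        name: int(master.integers(2**31))
        for name in ("metadata", "cultivars", "wild_ref", "dom_ref", "unknowns", "balance")
    }

    metadata = generate_cultivar_metadata(
        refcfg["n_cultivars"], seed=seeds["metadata"]
    )
    cv_specs = _cultivar_specs(
        cfg, metadata, refcfg["domestic_per_cultivar"], seeds["cultivars"]
    )
    from .synthetic import _default_covariance, _template

    wild_spec = ShapeClassSpec(
        "wild",
        _template("wild", cfg),
        _default_covariance(cfg),
        refcfg["n_wild_pool"],
        gen["length_px"],
    )

    logger.info("extracting reference features")
    w_ids, _, w_X = _extract_features_stream(
        [wild_spec], image_size, seeds["wild_ref"], n_points, min_px
    )
    d_ids, d_cv, d_X = _extract_features_stream(
        cv_specs, image_size, seeds["dom_ref"], n_points, min_px
    )
    reference = ReferenceSet(
        features=LabelledFeatures(
            np.vstack([w_X, d_X]),
            np.array(["wild"] * len(w_ids) + ["domestic"] * len(d_ids), dtype=object),
            np.concatenate([w_ids, d_ids]),
        ),
        cultivar_labels=np.array(
            [None] * len(w_ids) + list(d_cv), dtype=object
        ),
        metadata=metadata,
    )

    logger.info("generating unknowns")
    unk_rng = np.random.default_rng(seeds["unknowns"])
    site_specs, site_names, true_rows = [], [], []
    for site, scfg in cfg["sites"].items():
        n = int(scfg["n"])
        n_wild = int(round(scfg["wild_fraction"] * n))
        if n_wild:
            site_specs.append(
                ShapeClassSpec(
                    f"{site}-wild",
                    wild_spec.mean_coefficients,
                    wild_spec.covariance,
                    n_wild,
                    gen["length_px"],
                )
            )
            site_names.extend([site] * n_wild)
            true_rows.extend([(site, "wild", None)] * n_wild)
        picks = unk_rng.choice(len(cv_specs), size=n - n_wild, replace=True)
        picks, pick_counts = np.unique(picks, return_counts=True)
        for ci, cnt in zip(picks, pick_counts):
            s = cv_specs[ci]
            site_specs.append(
                ShapeClassSpec(
                    f"{site}-{s.label}",
                    s.mean_coefficients,
                    s.covariance,
                    int(cnt),
                    s.length_px,
                )
            )
            site_names.extend([site] * int(cnt))
            true_rows.extend([(site, "domestic", s.label)] * int(cnt))
    u_ids, _, u_X = _extract_features_stream(
        site_specs, image_size, int(unk_rng.integers(2**31)), n_points, min_px
    )
    truth = pd.DataFrame(
        true_rows, columns=["site", "true_class", "true_cultivar"]
    ).assign(sample_id=u_ids)
    unknowns = LabelledFeatures(u_X, np.array(site_names, dtype=object), u_ids)

    logger.info("stage 1: wild/domestic discrimination")
    balanced = balance_reference(reference, refcfg["n_per_class"], seeds["balance"])
    s1 = stage1_wild_domestic(balanced, unknowns, ana)

    logger.info("stage 2: cultivar assignment")
    dom_mask = np.array([s == "domestic" for s in s1.assignments["status"]])
    dom_unknowns = LabelledFeatures(
        unknowns.X[dom_mask],
        unknowns.y[dom_mask],
        unknowns.sample_ids[dom_mask],
    )
    s2 = stage2_cultivar_assignment(reference, dom_unknowns, ana)

    merged = s1.assignments.merge(
        s2.assignments[["sample_id", "cultivar_id"]], on="sample_id", how="left"
    )
    merged["cultivar_id"] = merged["cultivar_id"].where(
        merged["status"] == "domestic", None
    )
    report = allocation_report(merged, metadata, ana["min_count"])

    result = PipelineResult(
        reference=reference,
        stage1=s1,
        stage2=s2,
        report=report,
        truth=truth,
        config=cfg,
        seed=seed,
        elapsed_s=time.monotonic() - t0,
    )
    if out_dir is not None:
        result.outputs = _write_outputs(result, merged, out_dir)
    return result


def _write_outputs(result: PipelineResult, merged: pd.DataFrame, out_dir) -> Dict[str, str]:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    feats = pd.DataFrame(result.reference.features.X, columns=FEATURE_NAMES)
    feats.insert(0, "sample_id", result.reference.features.sample_ids)
    feats.insert(1, "status", result.reference.features.y)
    _save = lambda name, df: (df.to_csv(out / name, index=False), paths.update({name: str(out / name)}))
    _save("reference_features.csv", feats)
    _save("assignments.csv", merged)
    result.report.cultivar_counts.to_csv(out / "cultivar_counts.csv")
    paths["cultivar_counts.csv"] = str(out / "cultivar_counts.csv")
    result.report.cultivar_counts_filtered.to_csv(out / "cultivar_counts_min10.csv")
    paths["cultivar_counts_min10.csv"] = str(out / "cultivar_counts_min10.csv")
    for name, frame in (
        ("status_counts.csv", result.report.status_counts),
        ("status_percent.csv", result.report.status_percent),
        ("colour_percent.csv", result.report.colour_percent),
        ("region_percent.csv", result.report.region_percent),
    ):
        frame.to_csv(out / name)
        paths[name] = str(out / name)
    (out / "stage1_model.json").write_text(result.stage1.model.to_json())
    (out / "stage2_model.json").write_text(result.stage2.model.to_json())
    trace_to_frame(result.stage1.trace).to_csv(out / "stage1_trace.csv", index=False)
    result.stage1.loocv.confusion.to_csv(out / "stage1_loocv_confusion.csv")
    manifest = {
        "seed": result.seed,
        "elapsed_s": result.elapsed_s,
        "loocv_accuracy": result.stage1.loocv.accuracy,
        "resubstitution_accuracy": result.stage1.resubstitution_accuracy,
        "dropped_cultivars": result.stage2.dropped_cultivars,
        "config": result.config,
        "outputs": sorted(paths),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    paths["manifest.json"] = str(out / "manifest.json")
    return paths
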