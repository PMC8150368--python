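"""End-to-end orchestration: generate -> screen -> quantify -> model -> report.

A single seeded, configurable run of the whole authentication workflow on
either the synthetic study (default) or externally supplied peak tables and
compound databases.  Every stage logs its counts (features in, hits out,
variables dropped) and all outputs are stamped with the configuration hash
and seed.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as cm
from . import io as oio
from . import quant as qt
from . import screening as sc
from . import synth

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; defaults follow the study design."""

    seed: int = 1
    output_dir: str | None = None
    peak_dir: str | None = None  # read peak tables instead of generating
    db_path: str | None = None  # read compound DB instead of the default panel
    metadata_path: str | None = None
    scaling: str = "pareto"  # a scaling method, or "rank" to auto-select
    n_orthogonal: int | str = "auto"  # Q2-rule selection by default
    max_orthogonal: int = 3
    train_fraction: float = 0.8
    cv_folds: int = 7
    n_permutations: int = 20
    vip_threshold: float = 1.0
    iqr_drop: float | None = None
    prevalence: float = 0.8
    removal_list: tuple[str, ...] = synth.DEFAULT_REMOVAL_LIST
    effect_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")
        if self.seed is None:
            raise ValueError("a seed is required")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "removal_list" in data:
            data["removal_list"] = tuple(data["removal_list"])
        return cls(**data)


@dataclass
class RunReport:
    """Everything one run produced, in memory."""

    config: PipelineConfig
    metadata: pd.DataFrame
    target_hits: list
    suspect_hits: list
    retained_compounds: list[str]
    feature_matrix: cm.FeatureMatrix
    univariate: pd.DataFrame
    pca_explained: np.ndarray
    scaling_ranking: list[tuple[str, float]]
    scaling_method: str
    train_ids: list
    test_ids: list
    model: cm.OplsdaModel
    n_orthogonal: int
    accuracy_internal: float
    accuracy_external: float
    rmsep: float
    auc: float
    permutation: dict
    markers: pd.DataFrame
    vplot: pd.DataFrame
    validation: pd.DataFrame
    concentrations: pd.DataFrame
    audit: dict
    log: list[str]
    truth: dict | None = None

    def summary(self) -> dict:
        m = self.model
        return {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "scaling_method": self.scaling_method,
            "n_orthogonal": self.n_orthogonal,
            "n_samples": int((~self.metadata.is_blank & ~self.metadata.is_qc).sum()),
            "n_variables": len(self.feature_matrix.variable_ids),
            "train_test": [len(self.train_ids), len(self.test_ids)],
            "r2x": round(float(m.r2x), 4),
            "r2y": round(float(m.r2y), 4),
            "q2y": round(float(m.q2y), 4),
            "rmsee": round(float(m.rmsee), 4),
            "rmsep": round(float(self.rmsep), 4),
            "accuracy_internal": round(self.accuracy_internal, 4),
            "accuracy_external": round(self.accuracy_external, 4),
            "auc": round(self.auc, 4),
            "n_markers": int(len(self.markers)),
            "pca_explained_2pc": round(float(self.pca_explained[:2].sum()), 4),
        }

    def content_hash(self) -> str:
        blob = (
            yaml.safe_dump(self.summary(), sort_keys=True)
            + self.markers.round(10).to_csv()
            + self.validation.round(10).to_csv()
        )
        return hashlib.sha256(blob.encode()).hexdigest()


def _extract_is_areas(
    features: dict[str, list[sc.PeakFeature]],
    is_entry: sc.CompoundEntry,
    mz_tol_mda: float = 5.0,
    rt_tol_min: float = 0.2,
) -> pd.Series:
    """Internal-standard area per sample, matched by m/z and retention time.

    The IS is spiked at a known concentration; unlike screening hits its
    extraction does not require MS/MS confirmation.
    """
    areas = {}
    for sample_id, sample_features in features.items():
        best = None
        for f in sample_features:
            if (
                abs(f.mz - is_entry.theoretical_mz) * 1000.0 < mz_tol_mda
                and is_entry.expected_rt is not None
                and abs(f.rt - is_entry.expected_rt) < rt_tol_min
            ):
                if best is None or f.area > best.area:
                    best = f
        if best is not None:
            areas[sample_id] = best.area
    return pd.Series(areas, dtype=float)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow under ``config`` and return the run report."""
    log: list[str] = []
    rng_seed = int(config.seed)

    # ------------------------------------------------------------------ inputs
    if config.db_path is not None:
        panel = oio.read_compound_db(config.db_path)
    else:
        panel = synth.default_panel()
    design = synth.StudyDesign()
    noise = synth.NoiseConfig(effect_multiplier=config.effect_multiplier)

    truth = None
    if config.peak_dir is not None:
        features = oio.read_peak_tables(config.peak_dir)
        if config.metadata_path is None:
            raise ValueError("metadata_path is required with peak_dir")
        metadata = pd.read_csv(config.metadata_path, sep="\t", index_col=0)
        calibration = synth.generate_calibration_series(panel, design, noise, rng_seed)
    else:
        study = synth.generate_study(design, panel, noise, rng_seed)
        features, metadata, truth = study.features, study.metadata, study.truth
        calibration = synth.generate_calibration_series(panel, design, noise, rng_seed + 1)
    n_features = sum(len(v) for v in features.values())
    log.append(f"inputs: {len(features)} injections, {n_features} features")

    # --------------------------------------------------------------- screening
    target_entries = [
        s.entry for s in panel if s.entry.role == "target" and not s.internal_standard
    ]
    suspect_entries = [s.entry for s in panel if s.entry.role == "suspect"]
    is_entry = next(s.entry for s in panel if s.internal_standard)
    rt_model = sc.RetentionTimeModel.from_targets(target_entries)
    audit: dict = {"target": {}, "suspect": {}}
    target_hits = sc.target_screen(features, target_entries, audit=audit["target"])
    suspect_hits = sc.suspect_screen(
        features, suspect_entries, rt_model=rt_model, audit=audit["suspect"]
    )
    log.append(
        f"screening: {len(target_hits)} target hits, {len(suspect_hits)} suspect hits; "
        f"rejections {audit}"
    )

    # ------------------------------------------------- prevalence/blank filter
    all_hits = target_hits + suspect_hits
    retained = cm_retained = sc.prevalence_and_blank_filter(
        all_hits, metadata, min_prevalence=config.prevalence
    )
    log.append(f"prevalence/blank filter: {len(retained)} compounds retained")

    # ---------------------------------------------------------- feature matrix
    non_blank = metadata.index[~metadata.is_blank]
    areas = pd.DataFrame(0.0, index=list(non_blank), columns=retained)
    for h in all_hits:
        if h.sample_id in areas.index and h.compound.name in areas.columns:
            areas.loc[h.sample_id, h.compound.name] = h.feature.area
    is_areas = _extract_is_areas(features, is_entry)
    fm = cm.normalize_to_is(
        areas,
        is_areas.reindex(areas.index),
        classes=metadata.class_label,
        vintage=metadata.vintage,
        qc=metadata.is_qc,
    )
    log.append(
        f"feature matrix: {len(fm.sample_ids)} samples x {len(fm.variable_ids)} variables"
    )

    # ------------------------------------------------------- univariate screen
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        univariate = cm.univariate_screen(fm)
    log.append(f"univariate screen: {int(univariate.significant.sum())} significant")

    # --------------------------------------------------------------- PCA on QC
    _, _, explained = cm.run_pca(cm.scale_matrix(fm, "pareto"), n_components=2)
    log.append(f"PCA: first two components explain {explained[:2].sum():.1%}")

    # --------------------------------------------- confounder removal, scaling
    fm_model = cm.drop_confounded_variables(fm, list(config.removal_list))
    log.append(
        f"confounder removal: {len(fm.variable_ids)} -> {len(fm_model.variable_ids)} variables"
    )
    if config.iqr_drop:
        fm_model = cm.iqr_variable_filter(fm_model, config.iqr_drop)
        log.append(f"IQR filter: {len(fm_model.variable_ids)} variables kept")

    sub = fm_model.non_qc()
    ranking: list[tuple[str, float]] = []
    if config.scaling == "rank":
        ranking = cm.rank_scaling_methods(
            sub, train_fraction=config.train_fraction, seed=rng_seed
        )
        scaling_method = ranking[0][0]
        log.append(f"scaling ranking: {ranking}; selected {scaling_method}")
    else:
        scaling_method = config.scaling

    # ------------------------------------------------------- split, fit, check
    scaled_all = cm.scale_matrix(sub, scaling_method)
    train_ids, test_ids = cm.kennard_stone_split(scaled_all, config.train_fraction)
    log.append(f"Kennard-Stone split: {len(train_ids)}/{len(test_ids)}")
    scaler = cm.ColumnScaler(scaling_method).fit(sub.values.loc[train_ids])
    x_train = scaler.transform(sub.values.loc[train_ids])
    x_test = scaler.transform(sub.values.loc[test_ids])
    y_train = sub.classes.loc[train_ids]
    y_test = sub.classes.loc[test_ids]

    if config.n_orthogonal == "auto":
        n_orthogonal = cm.select_n_orthogonal(
            x_train, y_train, max_orthogonal=config.max_orthogonal,
            folds=config.cv_folds, seed=rng_seed,
        )
    else:
        n_orthogonal = int(config.n_orthogonal)
    model = cm.fit_oplsda(x_train, y_train, n_orthogonal)
    model.q2y = cm.cross_validate_q2(
        x_train, y_train, n_orthogonal, folds=config.cv_folds, seed=rng_seed
    )
    _, _, accuracy_internal = cm.predict_class_maxdist(model, x_train, y_train)
    _, rmsep, accuracy_external = cm.predict_class_maxdist(model, x_test, y_test)
    model.rmsep = rmsep
    scores_all = model.predict_scores(scaler.transform(sub.values))
    auc = cm.roc_auc(scores_all, sub.classes)
    if config.n_permutations >= 1:
        permutation = cm.permutation_test(
            x_train, y_train, n_orthogonal,
            n_perm=config.n_permutations, seed=rng_seed, folds=config.cv_folds,
        )
    else:
        permutation = {"actual": (model.r2y, model.q2y), "permuted": []}
    log.append(
        f"OPLS-DA: 1+{n_orthogonal} components, R2X={model.r2x:.3f} R2Y={model.r2y:.3f} "
        f"Q2Y={model.q2y:.3f} RMSEE={model.rmsee:.4f} RMSEP={rmsep:.4f} "
        f"acc(int/ext)={accuracy_internal:.2%}/{accuracy_external:.2%} AUC={auc:.3f}"
    )

    markers = cm.select_markers(model, config.vip_threshold)
    vplot = cm.vplot_table(model)
    log.append(f"markers: {len(markers)} variables with VIP > {config.vip_threshold}")

    # ----------------------------------------------------------- quantification
    validation_rows = []
    curves: dict[str, qt.CalibrationCurve] = {}
    lodloq: dict[str, tuple[float, float]] = {}
    for analyte, grp in calibration.solvent.groupby("analyte"):
        curve = qt.fit_calibration(
            list(zip(grp.concentration, grp.response)), analyte=analyte
        )
        curves[analyte] = curve
        mgrp = calibration.matrix[calibration.matrix.analyte == analyte]
        mcurve = qt.fit_calibration(
            list(zip(mgrp.concentration, mgrp.response)), analyte=analyte
        )
        me = qt.matrix_effect(mcurve.slope, curve.slope)
        fitted = curve.intercept + curve.slope * np.asarray(curve.concentrations)
        residual_sd = float(np.std(np.asarray(curve.responses) - fitted, ddof=2))
        noise_scale = residual_sd if residual_sd > 0 else 1e-6 * curve.slope
        lod, loq = qt.estimate_lod_loq(curve, noise_scale)
        lodloq[analyte] = (lod, loq)
        prec = calibration.precision[calibration.precision.analyte == analyte]
        rsd_low = qt.precision_rsd(prec[prec.level == 0.5].response.to_numpy())
        rsd_high = qt.precision_rsd(prec[prec.level == 5.0].response.to_numpy())
        validation_rows.append(
            qt.ValidationReport(
                analyte=analyte, r_squared=curve.r_squared, matrix_effect=me,
                lod=lod, loq=loq, rsd_low=rsd_low, rsd_high=rsd_high,
            )
        )
    validation = pd.DataFrame([asdict(v) for v in validation_rows]).set_index("analyte")

    quant_rows = []
    fm_all = fm  # IS-normalized responses for targets
    for h in target_hits:
        if h.sample_id not in fm_all.values.index:
            continue
        analyte = h.compound.name
        if analyte not in curves or analyte not in fm_all.values.columns:
            continue
        response = fm_all.values.loc[h.sample_id, analyte]
        lod, loq = lodloq[analyte]
        result = qt.quantify(response, curves[analyte], lod=lod, loq=loq)
        quant_rows.append(
            (h.sample_id, analyte, result.concentration, result.flag)
        )
    concentrations = pd.DataFrame(
        quant_rows, columns=["sample_id", "analyte", "concentration_mg_l", "flag"]
    )
    log.append(
        f"quantification: {len(curves)} calibration curves, "
        f"{len(concentrations)} sample-analyte concentrations"
    )

    report = RunReport(
        config=config,
        metadata=metadata,
        target_hits=target_hits,
        suspect_hits=suspect_hits,
        retained_compounds=retained,
        feature_matrix=fm_model,
        univariate=univariate,
        pca_explained=explained,
        scaling_ranking=ranking,
        scaling_method=scaling_method,
        train_ids=list(train_ids),
        test_ids=list(test_ids),
        model=model,
        n_orthogonal=n_orthogonal,
        accuracy_internal=accuracy_internal,
        accuracy_external=accuracy_external,
        rmsep=rmsep,
        auc=auc,
        permutation=permutation,
        markers=markers,
        vplot=vplot,
        validation=validation,
        concentrations=concentrations,
        audit=audit,
        log=log,
        truth=truth,
    )
    if config.output_dir is not None:
        _write_outputs(report, Path(config.output_dir))
    return report


def _write_outputs(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": report.config.config_hash(), "seed": report.config.seed}
    oio.hits_to_frame(report.target_hits).to_csv(
        outdir / "target_hits.tsv", sep="\t", index=False
    )
    oio.hits_to_frame(report.suspect_hits).to_csv(
        outdir / "suspect_hits.tsv", sep="\t", index=False
    )
    report.feature_matrix.values.to_csv(outdir / "feature_matrix.tsv", sep="\t")
    report.univariate.to_csv(outdir / "univariate_screen.tsv", sep="\t")
    report.markers.to_csv(outdir / "marker_table.tsv", sep="\t")
    report.vplot.to_csv(outdir / "vplot.tsv", sep="\t")
    report.validation.to_csv(outdir / "validation_report.tsv", sep="\t")
    report.concentrations.to_csv(outdir / "concentrations.tsv", sep="\t", index=False)
    perm = pd.DataFrame(report.permutation["permuted"], columns=["r2y", "q2y"])
    perm.to_csv(outdir / "permutation_test.tsv", sep="\t", index_label="permutation")
    # row-wise range-scaled heatmap coordinates
    values = report.feature_matrix.values
    span = values.max(axis=1) - values.min(axis=1)
    heat = values.sub(values.min(axis=1), axis=0).div(span.replace(0, 1.0), axis=0)
    heat.to_csv(outdir / "heatmap.tsv", sep="\t")
    oio.write_summary(
        {**stamp, **report.summary(), "log": report.log}, outdir / "summary.yaml"
    )
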