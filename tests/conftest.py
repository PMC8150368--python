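import warnings

import numpy as np
import pandas as pd
import pytest

from oenomics import chemometrics as cm
from oenomics import screening as sc
from oenomics import synth
from oenomics.chem import IsotopePattern, MolecularFormula, theoretical_isotope_pattern


@pytest.fixture(scope="session")
def panel():
    return synth.default_panel()


@pytest.fixture(scope="session")
def default_study(panel):
    """One generated default study (27+19 samples, QCs, blanks), seed 42."""
    return synth.generate_study(synth.StudyDesign(), panel, seed=42)


@pytest.fixture(scope="session")
def screened_study(panel, default_study):
    """Target and suspect hits on the default study."""
    targets = [s.entry for s in panel if s.entry.role == "target" and not s.internal_standard]
    suspects = [s.entry for s in panel if s.entry.role == "suspect"]
    rt_model = sc.RetentionTimeModel.from_targets(targets)
    target_hits = sc.target_screen(default_study.features, targets)
    suspect_hits = sc.suspect_screen(default_study.features, suspects, rt_model=rt_model)
    return target_hits, suspect_hits


def observed_envelope(formula: str, perturbation: float = 0.0) -> IsotopePattern:
    """The theoretical envelope of ``formula`` with A+1 shifted by ``perturbation``."""
    theo = theoretical_isotope_pattern(MolecularFormula.parse(formula), 3)
    peaks = list(theo.peaks)
    peaks[1] = (peaks[1][0], min(1.0, max(1e-6, peaks[1][1] + perturbation)))
    return IsotopePattern(tuple(peaks))


def make_feature(
    compound: sc.CompoundEntry,
    sample_id: str = "S1",
    mz_offset_mda: float = 0.0,
    rt_offset: float = 0.0,
    area: float = 5.0e4,
    intensity: float = 5.0e3,
    envelope_perturbation: float = 0.0,
    fragments: tuple | None = None,
) -> sc.PeakFeature:
    """A feature matching ``compound`` exactly, with controlled deviations."""
    rt = compound.expected_rt if compound.expected_rt is not None else (
        compound.predicted_rt if compound.predicted_rt is not None else 3.0
    )
    if fragments is None:
        fragments = tuple((f, 500.0) for f in compound.qualifier_fragments)
    return sc.PeakFeature(
        sample_id=sample_id,
        mz=compound.theoretical_mz + mz_offset_mda / 1000.0,
        rt=rt + rt_offset,
        area=area,
        intensity=intensity,
        isotope_envelope=observed_envelope(str(compound.formula), envelope_perturbation),
        msms_fragments=fragments,
    )


def run_study_model(seed: int, effect_multiplier: float = 1.0) -> dict:
    """Generate, screen and model one synthetic study; no permutation stage.

    Shared by the stochastic reproduction tests; returns the quantities the
    study design is meant to pin down (accuracies, AUC, marker recovery).
    """
    panel = synth.default_panel()
    design = synth.StudyDesign()
    noise = synth.NoiseConfig(effect_multiplier=effect_multiplier)
    study = synth.generate_study(design, panel, noise, seed)
    targets = [s.entry for s in panel if s.entry.role == "target" and not s.internal_standard]
    suspects = [s.entry for s in panel if s.entry.role == "suspect"]
    rt_model = sc.RetentionTimeModel.from_targets(targets)
    hits = sc.target_screen(study.features, targets) + sc.suspect_screen(
        study.features, suspects, rt_model=rt_model
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        retained = sc.prevalence_and_blank_filter(hits, study.metadata)
    samples = study.metadata.index[~study.metadata.is_blank]
    areas = pd.DataFrame(0.0, index=list(samples), columns=retained)
    is_areas = pd.Series(np.nan, index=list(samples))
    for h in hits:
        if h.sample_id in areas.index:
            areas.loc[h.sample_id, h.compound.name] = h.feature.area
    is_entry = next(s.entry for s in panel if s.internal_standard)
    for sid, feats in study.features.items():
        if sid not in is_areas.index:
            continue
        candidates = [
            f.area for f in feats
            if abs(f.mz - is_entry.theoretical_mz) * 1000 < 5.0
            and abs(f.rt - is_entry.expected_rt) < 0.2
        ]
        if candidates:
            is_areas[sid] = max(candidates)
    fm = cm.normalize_to_is(
        areas, is_areas, classes=study.metadata.class_label,
        vintage=study.metadata.vintage, qc=study.metadata.is_qc,
    )
    fm = cm.drop_confounded_variables(fm, list(synth.DEFAULT_REMOVAL_LIST))
    sub = fm.non_qc()
    scaled = cm.scale_matrix(sub, "pareto")
    train_ids, test_ids = cm.kennard_stone_split(scaled, 0.8)
    scaler = cm.ColumnScaler("pareto").fit(sub.values.loc[train_ids])
    x_train = scaler.transform(sub.values.loc[train_ids])
    x_test = scaler.transform(sub.values.loc[test_ids])
    y_train = sub.classes.loc[train_ids]
    y_test = sub.classes.loc[test_ids]
    n_o = cm.select_n_orthogonal(x_train, y_train, max_orthogonal=3, seed=seed)
    model = cm.fit_oplsda(x_train, y_train, n_o)
    _, _, acc_int = cm.predict_class_maxdist(model, x_train, y_train)
    _, rmsep, acc_ext = cm.predict_class_maxdist(model, x_test, y_test)
    scores_all = model.predict_scores(scaler.transform(sub.values))
    auc = cm.roc_auc(scores_all, sub.classes)
    markers = cm.select_markers(model)
    truth = study.truth["markers"]
    recovered = all(
        name in markers.index and markers.loc[name, "class"] == cls
        for name, cls in truth.items()
    )
    return {
        "model": model,
        "split": (len(train_ids), len(test_ids)),
        "accuracy_internal": acc_int,
        "accuracy_external": acc_ext,
        "rmsep": rmsep,
        "auc": auc,
        "markers": markers,
        "truth_markers": truth,
        "markers_recovered": recovered,
        "feature_matrix": sub,
        "x_train": x_train,
        "y_train": y_train,
    }
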