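"""End-to-end experiment: phantom cohort -> (optional U-Net) masks ->
radiomic features -> sparse selection -> three classifier arms ->
statistical evaluation, reproducible from one config and master seed.

The default experiment extracts features from the true phantom masks so the
statistical pipeline is studied in isolation; ``use_trained_seg`` inserts
the trained U-Net instead, to study segmentation-error propagation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinstats, evaluation, model, radiomics, segmentation, selection
from .errors import ConfigError
from .phantom import (CLINICAL_FEATURES, PhantomConfig, clinical_design_matrix,
                      generate_cohort)

ARMS = ("clinical", "radiomics", "combined")

# fixed per-stage seed offsets so stages can be rerun in isolation
_SEED_OFFSETS = {"phantom": 11, "split": 23, "rnn": 37, "seg": 53}


@dataclass
class ExperimentConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seg: segmentation.SegConfig | None = None
    quantization: radiomics.QuantizationSpec = field(default_factory=radiomics.QuantizationSpec)
    selection_k: int = 100
    n_pos_train: int = 57
    n_neg_train: int = 100
    rnn: model.RNNConfig = field(default_factory=model.RNNConfig)
    arms: tuple[str, ...] = ARMS
    seed: int = 0
    use_trained_seg: bool = False
    combined_fusion: str = "timestep"  # or "late": average of arm probabilities
    dca_grid: tuple[float, float, float] = (0.01, 0.50, 0.01)  # start, stop, step


def validate_config(config: ExperimentConfig) -> ExperimentConfig:
    """Fill per-stage seeds from the master seed and check cross-field
    consistency; raises ConfigError listing every violation."""
    errors = []
    if not config.arms:
        errors.append("arms: must request at least one model arm")
    for a in config.arms:
        if a not in ARMS:
            errors.append(f"arms: unknown arm {a!r}")
    n = config.phantom.n_subjects
    n_pos = int(round(n * config.phantom.prevalence)) if config.phantom.exact_count \
        else int(n * config.phantom.prevalence)
    if config.n_pos_train > n_pos:
        errors.append(f"split: {config.n_pos_train} training positives requested, "
                      f"cohort yields ~{n_pos}")
    if config.n_neg_train > n - n_pos:
        errors.append(f"split: {config.n_neg_train} training negatives requested, "
                      f"cohort yields ~{n - n_pos}")
    n_candidates = model.N_RADIOMIC + len(CLINICAL_FEATURES)
    if config.selection_k > n_candidates:
        errors.append(f"selection_k: {config.selection_k} exceeds {n_candidates} candidates")
    if config.use_trained_seg and config.seg is None:
        errors.append("use_trained_seg: requires a seg config")
    if config.combined_fusion not in ("timestep", "late"):
        errors.append(f"combined_fusion: unknown mode {config.combined_fusion!r}")
    if errors:
        raise ConfigError("; ".join(errors))
    cfg = dataclasses.replace(config)
    cfg.phantom = dataclasses.replace(config.phantom,
                                      seed=config.seed + _SEED_OFFSETS["phantom"])
    cfg.rnn = dataclasses.replace(config.rnn, seed=config.seed + _SEED_OFFSETS["rnn"])
    if cfg.seg is not None:
        cfg.seg = dataclasses.replace(cfg.seg, seed=config.seed + _SEED_OFFSETS["seg"])
    return cfg


@dataclass
class ExperimentReport:
    arms: dict            # arm -> {auc, ci, threshold metrics}
    delong: dict          # "a_vs_b" -> {p, diff}
    dca: pd.DataFrame
    table1: pd.DataFrame
    split: dict
    selection: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "arms": self.arms,
            "delong": self.delong,
            "split": self.split,
            "selection": self.selection,
            "provenance": self.provenance,
        }


def _trained_masks(cohort, cfg: ExperimentConfig) -> list[np.ndarray]:
    """Train the U-Net on the first subjects' slices and segment everyone."""
    train_subjects = cohort.subjects[:min(30, len(cohort.subjects))]
    pairs = []
    for sub in train_subjects:
        level, width = segmentation.robust_window(sub.dwi)
        norm = segmentation.normalize_intensity(sub.dwi, level, width)
        for z in range(norm.shape[0]):
            if sub.true_mask[z].sum() > 0:
                pairs.append((norm[z], sub.true_mask[z].astype(float)))
    seg = segmentation.train_unet(pairs, cfg.seg)
    masks = []
    for sub in cohort.subjects:
        level, width = segmentation.robust_window(sub.dwi)
        norm = segmentation.normalize_intensity(sub.dwi, level, width)
        raw = segmentation.segment_volume(seg, norm)
        cleaned, _excluded = segmentation.postprocess_mask(raw)
        masks.append(cleaned)
    return masks


def run_experiment(config: ExperimentConfig,
                   out_dir: str | Path | None = None) -> ExperimentReport:
    """Run all stages and assemble the evaluation report."""
    cfg = validate_config(config)
    cohort = generate_cohort(cfg.phantom, with_images=True)
    labels = cohort.clinical["recurrence"].to_numpy()

    features = cohort.features
    if cfg.use_trained_seg:
        masks = _trained_masks(cohort, cfg)
        rows = []
        for sub, msk in zip(cohort.subjects, masks):
            rows.append(radiomics.extract_features(
                sub.adc, msk.astype(bool), cfg.quantization,
                subject_id=sub.id, enforce_min_size=False).to_series())
        features = pd.DataFrame(rows)
    if features is None:
        rows = []
        for sub in cohort.subjects:
            rows.append(radiomics.extract_features(
                sub.adc, sub.true_mask.astype(bool), cfg.quantization,
                subject_id=sub.id, enforce_min_size=False).to_series())
        features = pd.DataFrame(rows)

    split = model.build_split(labels, cfg.n_pos_train, cfg.n_neg_train,
                              seed=cfg.seed + _SEED_OFFSETS["split"])
    tr, te = split.train_idx, split.test_idx
    clin = clinical_design_matrix(cohort.clinical)

    # sparse selection on the training cohort only
    candidates = pd.concat([features.reset_index(drop=True),
                            clin.reset_index(drop=True)], axis=1)
    cand_train = pd.DataFrame(
        selection.standardize_columns(candidates.iloc[tr].to_numpy()),
        columns=list(candidates.columns))
    sel = selection.select_features(cand_train, labels[tr], K=cfg.selection_k)
    sel_radiomic = [i for i in sel.selected if i < model.N_RADIOMIC]

    # radiomic matrix with unselected positions zero-masked (layout preserved)
    masked = features.to_numpy().copy()
    drop = np.setdiff1d(np.arange(model.N_RADIOMIC), np.array(sel_radiomic, dtype=int))
    masked[:, drop] = 0.0

    preds: dict[str, np.ndarray] = {}
    train_preds: dict[str, np.ndarray] = {}
    arm_reports: dict[str, dict] = {}
    order = [a for a in ("clinical", "radiomics", "combined") if a in cfg.arms]
    for arm in order:
        if arm == "clinical":
            clf = model.train_clinical_logistic(clin.iloc[tr], labels[tr])
            p_tr = clf.predict(clin.iloc[tr])
            p_te = clf.predict(clin.iloc[te])
        elif arm == "radiomics":
            clf = model.train_rnn(masked[tr], labels[tr], cfg.rnn)
            p_tr = clf.predict(masked[tr])
            p_te = clf.predict(masked[te])
        elif cfg.combined_fusion == "late" and {"clinical", "radiomics"} <= set(order):
            # late fusion: average the two single-modality probabilities
            p_tr = 0.5 * (train_preds["clinical"] + train_preds["radiomics"])
            p_te = 0.5 * (preds["clinical"] + preds["radiomics"])
        else:  # combined: clinical block as extra timestep, kept out of masking
            X = np.hstack([masked, clin.to_numpy()])
            clf = model.train_rnn(X[tr], labels[tr], cfg.rnn)
            p_tr = clf.predict(X[tr])
            p_te = clf.predict(X[te])
        roc = evaluation.roc_auc(p_te, labels[te])
        thr = evaluation.youden_threshold(p_tr, labels[tr])
        metrics = evaluation.confusion_metrics(p_te, labels[te], thr)
        preds[arm] = p_te
        train_preds[arm] = p_tr
        arm_reports[arm] = {
            "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
            "threshold": thr, **metrics,
        }

    delong = {}
    arms = list(cfg.arms)
    for i in range(len(arms)):
        for j in range(i + 1, len(arms)):
            p, diff = evaluation.delong_test(preds[arms[i]], preds[arms[j]], labels[te])
            delong[f"{arms[i]}_vs_{arms[j]}"] = {"p": p, "auc_diff": diff}

    start, stop, step = cfg.dca_grid
    grid = np.round(np.arange(start, stop + step / 2, step), 10)
    dca_rows = {"threshold": grid}
    for arm in cfg.arms:
        curve = evaluation.decision_curve(preds[arm], labels[te], grid)
        dca_rows[f"nb_{arm}"] = curve.nb_model
        dca_rows["nb_treat_all"] = curve.nb_treat_all
        dca_rows["nb_treat_none"] = curve.nb_treat_none
    dca = pd.DataFrame(dca_rows)

    table1 = clinstats.table_one(cohort.clinical)

    report = ExperimentReport(
        arms=arm_reports,
        delong=delong,
        dca=dca,
        table1=table1,
        split={"n_train": len(tr), "n_test": len(te),
               "test_positives": split.n_pos_test, "test_negatives": split.n_neg_test},
        selection={"n_selected": len(sel.selected),
                   "n_clinical": len(sel.selected) - len(sel_radiomic),
                   "n_radiomic": len(sel_radiomic),
                   "names": [sel.names[i] for i in sel.selected]},
        provenance={"seed": config.seed, "n_subjects": cfg.phantom.n_subjects,
                    "prevalence": cfg.phantom.prevalence,
                    "arms": list(cfg.arms), "selection_k": cfg.selection_k,
                    "use_trained_seg": cfg.use_trained_seg},
    )
    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _write_report(report: ExperimentReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    report.dca.to_csv(out / "dca.csv", index=False)
    report.table1.to_csv(out / "table1.csv", index=False)
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for arm, rep in report.arms.items():
            ax.plot([], [], label=f"{arm}: AUC {rep['auc']:.3f}")
        ax.legend()
        ax.set_title("Model AUCs (test cohort)")
        fig.savefig(out / "roc.svg")
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 4))
        for col in report.dca.columns:
            if col != "threshold":
                ax.plot(report.dca["threshold"], report.dca[col], label=col)
        ax.set_xlabel("threshold probability")
        ax.set_ylabel("net benefit")
        ax.legend(fontsize=7)
        fig.savefig(out / "dca.svg")
        plt.close(fig)
    except Exception:   # plotting is best-effort; the JSON/CSV artifacts are canonical
        pass
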