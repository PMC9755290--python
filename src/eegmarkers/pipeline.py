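"""End-to-end orchestration: synth -> preprocess -> features -> selection ->
classification -> AUC comparison -> entropy decomposition."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import decompose as dec
from . import selection as sel
from .features import (CATEGORIES, REDUCED_PROFILE, FeatureProfile,
                       extract_features)
from .montage import PairClassification
from .preprocess import FilterSpec, ValidityPolicy, average_reference, \
    bandpass, check_sufficiency
from .records import NREM, WAKE, EEGRecord
from .synth import CohortConfig, generate_dataset

log = logging.getLogger("eegmarkers")

SCHEMA_VERSION = "eegmarkers-csv-v1"

#: matched-type comparisons of entropy vs spectral categories
COMPARISON_PAIRS = (
    ("fcEntropy", "fcSpectral"),
    ("scEntropy", "scSpectralA"),
    ("scEntropy", "scSpectralR"),
)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 7
    train_regime: str = "AS_like"
    val_regimes: tuple[str, ...] = ("NT_like", "DUP_like")
    n_participants: int = 10
    n_channels: int = 19
    fs: float = 125.0
    duration_s: float = 120.0
    complexity_gap: float = 0.9
    profile: str = "reduced"            # "full" | "reduced"
    selection_method: str = "pca"       # "pca" | "lmm"
    cv_folds: int = 10
    penalty: str = "l1"
    run_decomposition: bool = False
    n_surrogates: int = 200
    decomposition_segments: int = 20
    decomposition_channel: str = "Cz"
    out_dir: str | None = None

    def cohort_configs(self) -> tuple[CohortConfig, list[CohortConfig]]:
        def make(regime: str) -> CohortConfig:
            return CohortConfig(
                regime=regime,
                n_participants=self.n_participants,
                n_channels=self.n_channels,
                fs=self.fs,
                duration_s=self.duration_s,
                complexity_gap=self.complexity_gap,
                seed=self.seed,
            )
        return make(self.train_regime), [make(r) for r in self.val_regimes]

    def feature_profile(self) -> FeatureProfile:
        if self.profile == "reduced":
            return REDUCED_PROFILE
        if self.profile == "full":
            return FeatureProfile()
        raise ValueError(f"unknown profile {self.profile!r}")


def preprocess_record(
    record: EEGRecord,
    spec: FilterSpec = FilterSpec(),
    policy: ValidityPolicy = ValidityPolicy(),
) -> tuple[EEGRecord, dict]:
    """Filter, average-reference, and report data sufficiency."""
    rec = bandpass(record, spec)
    rec = average_reference(rec)
    report = check_sufficiency(rec, policy)
    return rec, report


def build_feature_table(
    records: list[EEGRecord],
    profile: FeatureProfile,
    pairs: PairClassification | None = None,
    preprocess: bool = True,
    filter_spec: FilterSpec = FilterSpec(),
) -> pd.DataFrame:
    """Preprocess and extract the canonical features of every record."""
    pairs = pairs or PairClassification()
    tidy_frames = []
    for rec in records:
        if preprocess:
            rec, report = preprocess_record(rec, filter_spec)
            if not report["usable"]:
                log.warning("record %s fails sufficiency (%d valid windows)",
                            rec.recording_id, report["n_valid_windows"])
        tidy_frames.append(extract_features(rec, pairs, profile))
    return sel.aggregate(pd.concat(tidy_frames, ignore_index=True))


def classify_and_compare(
    table: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Selection, per-category RLR training, cross-cohort evaluation and
    entropy-vs-spectral AUC comparisons with BH-FDR across comparisons."""
    ztable = sel.zscore_pooled(table)
    if config.selection_method == "pca":
        selection = sel.pca_select(ztable, config.train_regime)
    elif config.selection_method == "lmm":
        selection = sel.lmm_select(ztable, config.train_regime)
    else:
        raise ValueError(f"unknown selection method {config.selection_method!r}")
    spec = clf.RLRSpec(cv_folds=config.cv_folds, penalty=config.penalty)
    train = ztable[ztable["cohort"] == config.train_regime]
    models: dict[str, clf.RLRModel] = {}
    auc_rows = []
    for category in CATEGORIES:
        try:
            model = clf.fit_rlr(train, selection, category, spec, config.seed)
        except ValueError as exc:
            log.warning("category %s skipped: %s", category, exc)
            continue
        models[category] = model
        for cohort, sub in ztable.groupby("cohort"):
            res = clf.evaluate(model, sub)
            auc_rows.append({
                "category": category, "cohort": cohort,
                "role": "train" if cohort == config.train_regime
                else "validation",
                "auc": res.auc, "accuracy": res.accuracy,
                "precision": res.precision, "recall": res.recall,
                "specificity": res.specificity,
                "cv_auc": model.cv_auc if cohort == config.train_regime
                else float("nan"),
                "n_per_class": min(res.n_per_class.values()),
                "lambda": model.lambda_,
            })
    auc_table = pd.DataFrame(auc_rows)
    comp_rows = []
    for cohort in auc_table["cohort"].unique():
        sub = auc_table[auc_table["cohort"] == cohort].set_index("category")
        for ent_cat, spec_cat in COMPARISON_PAIRS:
            if ent_cat not in sub.index or spec_cat not in sub.index:
                continue
            N = int(sub.loc[ent_cat, "n_per_class"])
            comp = clf.compare_aucs(
                float(sub.loc[ent_cat, "auc"]), N,
                float(sub.loc[spec_cat, "auc"]), N,
            )
            comp_rows.append({
                "cohort": cohort, "entropy_category": ent_cat,
                "spectral_category": spec_cat,
                "entropy_auc": comp.auc1, "spectral_auc": comp.auc2,
                "z_entropy": comp.z1, "z_spectral": comp.z2,
                "z_diff": comp.z_diff, "p": comp.p_two_tailed,
            })
    comparisons = pd.DataFrame(comp_rows)
    if len(comparisons):
        adj, rej = clf.fdr_bh(comparisons["p"].to_numpy())
        comparisons["p_fdr"] = adj
        comparisons["significant"] = rej
    return {
        "ztable": ztable, "selection": selection, "models": models,
        "auc_table": auc_table, "comparisons": comparisons,
    }


def run_decomposition(
    records: list[EEGRecord],
    config: RunConfig,
    taus_ms: tuple[float, ...] = (8.0, 16.0, 32.0, 64.0, 128.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant PermEn decomposition on the training cohort."""
    from .preprocess import downsample

    by_part: dict[str, dict[str, EEGRecord]] = {}
    for rec in records:
        if rec.cohort != config.train_regime:
            continue
        by_part.setdefault(rec.participant_id, {})[rec.state] = rec
    frames = []
    ss = np.random.SeedSequence([config.seed, 5150])
    for (pid, both), child in zip(sorted(by_part.items()),
                                  ss.spawn(len(by_part))):
        if WAKE not in both or NREM not in both:
            continue
        rng = np.random.default_rng(child)
        segs = {}
        skip = False
        for state in (WAKE, NREM):
            rec = both[state]
            if rec.fs != 125.0:
                rec = downsample(rec, 125.0)
            try:
                ci = rec.channel_labels.index(config.decomposition_channel)
            except ValueError:
                ci = 0
            try:
                segs[state] = dec.draw_segments(
                    rec.data[ci], rec.fs,
                    n_segments=config.decomposition_segments,
                    mask=rec.artifact_mask, seed=rng,
                )
            except ValueError:
                skip = True
        if skip:
            continue
        taus = [max(int(round(t * 125.0 / 1000.0)), 1) for t in taus_ms]
        comp = dec.decompose_permen(
            segs[WAKE], segs[NREM], taus, fs=125.0,
            n_surrogates=config.n_surrogates,
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
        )
        frames.append(comp.as_frame(participant=pid))
    if not frames:
        return pd.DataFrame(), pd.DataFrame()
    components = pd.concat(frames, ignore_index=True)
    stats = dec.component_stats(components)
    return components, stats


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns all result tables.

    With ``config.out_dir`` set, the manifest, feature table, AUC table,
    comparison table and selection summary are written as UTF-8 CSV/JSON
    files with a schema-version header.
    """
    stage = "synth"
    try:
        train_cfg, val_cfgs = config.cohort_configs()
        records, manifest = generate_dataset(train_cfg, val_cfgs, config.seed)
        stage = "features"
        table = build_feature_table(records, config.feature_profile())
        stage = "classify"
        results = classify_and_compare(table, config)
        results["feature_table"] = table
        results["manifest"] = manifest
        if config.run_decomposition:
            stage = "decompose"
            components, dstats = run_decomposition(records, config)
            results["decomposition"] = components
            results["decomposition_stats"] = dstats
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    if config.out_dir:
        _write_outputs(results, config)
    return results


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_output_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _write_outputs(results: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    _write_csv(results["manifest"], out / "manifest.csv")
    _write_csv(results["feature_table"], out / "features.csv")
    _write_csv(results["auc_table"], out / "auc.csv")
    _write_csv(results["comparisons"], out / "comparisons.csv")
    if "decomposition" in results and len(results["decomposition"]):
        _write_csv(results["decomposition"], out / "decomposition.csv")
        _write_csv(results["decomposition_stats"],
                   out / "decomposition_stats.csv")
    (out / "selection.json").write_text(
        json.dumps(results["selection"].to_json_dict(), indent=1)
    )
    (out / "config.json").write_text(json.dumps(asdict(config), indent=1,
                                                default=str))
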