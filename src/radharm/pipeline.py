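"""The experimental engine: grouped stratified cross-validation with
cumulative training-set augmentation, OPNCB harmonization, the
acquisition-dependence screen, LASSO feature selection, a linear SVM, and
method comparisons.

One *trial* is one train/test split of the early-development dataset
(grouped by patient so no patient crosses the split, stratified by
endpoint at scan level).  Augmentation scans from patients absent from the
trial's test set are available to that trial; a cumulative fraction of
them (per-trial seeded shuffle, nested across fractions) is added to the
training set.  Within a trial:

1. rare-protocol exclusion on the training set (min 3 scans per level);
2. OPNCB harmonization in the requested mode;
3. the Kruskal-Wallis screen on the harmonized augmentation training data
   drops acquisition-dependent features (skipped for un-augmented
   baselines, which have no augmentation data to screen);
4. standardization to zero mean / unit variance on training statistics;
5. LASSO (alpha = 0.05) selects features with nonzero coefficients;
6. a linear SVM (C = 1) is trained on the selected features;
7. test scans with unseen protocols are excluded, the rest are harmonized
   with training-fitted estimators only, standardized with training
   statistics, and scored.

Every training-derived artifact (estimators, screen, scaler, selection,
SVM) depends only on the training partition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import ACQUISITION_PARAMETERS, CohortTable
from .combat import CombatError, RoutingError
from .opncb import (
    HarmonizationMode,
    OpncbError,
    exclude_rare_protocols,
    exclude_unseen_test_protocols,
    fit_opncb,
    harmonize,
)
from .screen import ScreenConfig, ScreenError, screen_features
from .stats import (
    auc_from_scores,
    delong_test,
    holm_bonferroni,
    poisson_confidence_interval,
    t_confidence_interval,
    wilcoxon_signed_rank,
)

AUGMENTATION_FRACTIONS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.50, 0.75, 1.00)


@dataclass
class PipelineConfig:
    k_folds: int = 5
    n_repeats: int = 10
    lasso_alpha: float = 0.05
    svm_C: float = 1.0
    fractions: tuple[float, ...] = AUGMENTATION_FRACTIONS
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    parameters: tuple[str, ...] = ACQUISITION_PARAMETERS
    min_protocol_n: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        fr = list(self.fractions)
        if fr != sorted(fr) or not all(0 < f <= 1 for f in fr):
            raise ValueError("fractions must be ascending and in (0, 1]")


@dataclass
class TrialSplit:
    trial_id: str
    train_scan_ids: list[str]          # early-development training scans
    test_scan_ids: list[str]           # early-development test scans
    available_aug_scan_ids: list[str]  # aug scans from non-test patients
    aug_shuffle: list[str]             # seeded permutation of the above
    aug_seed: int


def make_splits(early: CohortTable, aug: CohortTable,
                config: PipelineConfig, seed: int | None = None) -> list[TrialSplit]:
    """Grouped (by patient) stratified (by scan-level endpoint) K-fold
    splits of the early-development cohort, repeated ``n_repeats`` times;
    deterministic given the seed.

    Augmentation scans of any patient present in a trial's test set are
    unavailable to that trial.
    """
    seed = config.seed if seed is None else seed
    y = early.endpoint_binary()
    if y.min() == y.max():
        raise ValueError("early cohort must contain both endpoint classes")
    groups = early.df["patient_id"].to_numpy()
    scan_ids = np.array(early.scan_ids())
    aug_ids = np.array(aug.scan_ids())
    aug_patients = aug.df["patient_id"].to_numpy()
    ss = np.random.SeedSequence([seed, 0x5eed])
    fold_seeds = ss.generate_state(config.n_repeats * (config.k_folds + 1))
    splits: list[TrialSplit] = []
    i_seed = 0
    for r in range(config.n_repeats):
        skf = StratifiedGroupKFold(n_splits=config.k_folds, shuffle=True,
                                   random_state=int(fold_seeds[i_seed] % (2**31)))
        i_seed += 1
        for f, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y, groups)):
            test_patients = set(groups[te])
            avail = aug_ids[~np.isin(aug_patients, list(test_patients))]
            aug_seed = int(np.random.SeedSequence([seed, r, f]).generate_state(1)[0]
                           % (2**31))
            shuffled = list(np.random.default_rng(aug_seed).permutation(avail))
            if len(set(groups[tr]) & test_patients):
                raise AssertionError("patient overlap between train and test")
            splits.append(TrialSplit(
                trial_id=f"r{r:02d}f{f}",
                train_scan_ids=[str(s) for s in scan_ids[tr]],
                test_scan_ids=[str(s) for s in scan_ids[te]],
                available_aug_scan_ids=[str(s) for s in avail],
                aug_shuffle=[str(s) for s in shuffled],
                aug_seed=aug_seed,
            ))
    return splits


def augment_training(split: TrialSplit, fraction: float) -> list[str]:
    """Training scan ids at a given cumulative augmentation fraction: the
    early training scans plus the first ceil(fraction * n_available) scans
    of the trial's fixed shuffle, so smaller fractions are nested inside
    larger ones."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    k = math.ceil(fraction * len(split.aug_shuffle))
    return list(split.train_scan_ids) + split.aug_shuffle[:k]


@dataclass
class TrialResult:
    trial_id: str
    mode: str
    fraction: float
    status: str                        # OK | SKIPPED_no_features | SKIPPED_harmonization_failed
    n_selected: int = 0
    selected_features: list[str] = field(default_factory=list)
    test_scan_ids: list[str] = field(default_factory=list)
    test_labels: np.ndarray = field(default_factory=lambda: np.array([]))
    test_scores: np.ndarray = field(default_factory=lambda: np.array([]))
    metrics: dict = field(default_factory=dict)
    independent_fraction: float = float("nan")
    parameter_order: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _classification_metrics(labels: np.ndarray, scores: np.ndarray) -> dict:
    """ROC-AUC from decision scores; sensitivity / specificity / weighted
    accuracy at the SVM decision boundary (score 0)."""
    labels = np.asarray(labels).astype(bool)
    pred = np.asarray(scores) > 0
    tp = int((pred & labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    try:
        auc = auc_from_scores(labels, scores)
    except ValueError:
        auc = float("nan")
    return {
        "roc_auc": auc,
        "sensitivity": sens,
        "specificity": spec,
        "weighted_accuracy": (sens + spec) / 2,
    }


def run_trial(training: CohortTable, test: CohortTable,
              mode: HarmonizationMode | str, config: PipelineConfig,
              use_screen: bool = True, trial_id: str = "",
              fraction: float = float("nan")) -> TrialResult:
    """Run one harmonize -> screen -> select -> classify -> score trial."""
    mode = HarmonizationMode(mode)
    res = TrialResult(trial_id=trial_id, mode=mode.value, fraction=fraction,
                      status="OK")
    try:
        excl = exclude_rare_protocols(training, config.parameters,
                                      min_n=config.min_protocol_n)
        training = training.subset(excl.retained)
        for sid, rule, p, lv in excl.excluded:
            res.notes.append(f"train scan {sid} excluded ({rule} {p}={lv})")
        if training.endpoint_binary().min() == training.endpoint_binary().max():
            raise OpncbError("training set lost one endpoint class to exclusions")
        plan = fit_opncb(training, config.parameters, mode,
                         screen_config=config.screen, min_n=config.min_protocol_n)
        dropped = {t[0] for t in plan.training_exclusions}
        if dropped:
            training = training.subset([s for s in training.scan_ids()
                                        if s not in dropped])
        train_h = harmonize(plan, training, is_test=False)
        res.parameter_order = dict(plan.parameter_order)
    except (OpncbError, CombatError, ScreenError, RoutingError) as exc:
        res.status = "SKIPPED_harmonization_failed"
        res.notes.append(str(exc))
        return res

    features = list(train_h.feature_names)
    if use_screen:
        try:
            rep = screen_features(train_h, config.screen)
        except ScreenError as exc:
            res.status = "SKIPPED_harmonization_failed"
            res.notes.append(f"screen failed: {exc}")
            return res
        res.independent_fraction = rep.independent_fraction
        features = rep.independent_features()
        if not features:
            res.status = "SKIPPED_no_features"
            res.notes.append("screen left no acquisition-independent feature")
            return res

    X = train_h.df[features].to_numpy(float)
    y = train_h.endpoint_binary()
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        lasso = Lasso(alpha=config.lasso_alpha, max_iter=10000).fit(Xs, y)
    sel = np.abs(lasso.coef_) > 1e-10
    if not sel.any():
        res.status = "SKIPPED_no_features"
        res.notes.append("LASSO selected no feature")
        return res
    res.selected_features = [f for f, s in zip(features, sel) if s]
    res.n_selected = int(sel.sum())
    svm = SVC(kernel="linear", C=config.svm_C).fit(Xs[:, sel], y)

    try:
        texcl = exclude_unseen_test_protocols(test, plan)
        for sid, rule, p, lv in texcl.excluded:
            res.notes.append(f"test scan {sid} excluded ({rule} {p}={lv})")
        test_kept = test.subset(texcl.retained)
        if len(test_kept) == 0:
            res.status = "SKIPPED_harmonization_failed"
            res.notes.append("every test scan had an unseen protocol")
            return res
        test_h = harmonize(plan, test_kept, is_test=True)
    except (RoutingError, CombatError) as exc:
        res.status = "SKIPPED_harmonization_failed"
        res.notes.append(f"test harmonization failed: {exc}")
        return res

    Xt = scaler.transform(test_h.df[features].to_numpy(float))[:, sel]
    scores = svm.decision_function(Xt)
    res.test_scan_ids = test_h.scan_ids()
    res.test_labels = test_h.endpoint_binary()
    res.test_scores = scores
    res.metrics = _classification_metrics(res.test_labels, scores)
    return res


# -- learning curves -------------------------------------------------------


@dataclass
class LearningCurveResult:
    """Aggregated curve cells plus the log-law fit per mode.

    ``cells`` rows: (mode, fraction, mean_auc, ci_lo, ci_hi, n_ok);
    fraction 0.0 is the un-augmented baseline.  ``log_fit`` maps mode ->
    dict(a, b, r2) for mean AUC = a + b ln(fraction) over fraction > 0
    cells, or ``{"status": "NOT_FIT"}`` when the response is degenerate.
    """

    cells: pd.DataFrame
    log_fit: dict
    trials: list[TrialResult]


def _aggregate_cells(trials: list[TrialResult]) -> pd.DataFrame:
    rows = []
    frame = pd.DataFrame([{"mode": t.mode, "fraction": t.fraction,
                           "auc": t.metrics.get("roc_auc", float("nan")),
                           "ok": t.status == "OK"} for t in trials])
    for (mode, frac), grp in frame.groupby(["mode", "fraction"]):
        aucs = grp.loc[grp["ok"], "auc"].to_numpy()
        aucs = aucs[np.isfinite(aucs)]
        if len(aucs) == 0:
            continue  # cell omitted: no trial could train a model
        mean, lo, hi = t_confidence_interval(aucs)
        rows.append({"mode": mode, "fraction": frac, "mean_auc": mean,
                     "ci_lo": lo, "ci_hi": hi, "n_ok": len(aucs)})
    return pd.DataFrame(rows)


def _fit_log_law(cells: pd.DataFrame, mode: str) -> dict:
    sub = cells[(cells["mode"] == mode) & (cells["fraction"] > 0)]
    if len(sub) < 2:
        return {"status": "NOT_FIT"}
    x = np.log(sub["fraction"].to_numpy(float))
    yv = sub["mean_auc"].to_numpy(float)
    if np.allclose(yv, yv[0]):
        return {"status": "NOT_FIT"}
    b, a = np.polyfit(x, yv, 1)
    pred = a + b * x
    ss_res = float(((yv - pred) ** 2).sum())
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    return {"status": "FIT", "a": float(a), "b": float(b),
            "r2": 1.0 - ss_res / ss_tot}


def run_learning_curve(early: CohortTable, aug: CohortTable,
                       modes, config: PipelineConfig,
                       seed: int | None = None,
                       include_baseline: bool = True,
                       splits: list[TrialSplit] | None = None) -> LearningCurveResult:
    """Run every (trial x fraction x mode) combination plus the
    un-augmented baseline and aggregate mean test AUC per cell."""
    modes = [HarmonizationMode(m) for m in modes]
    if splits is None:
        splits = make_splits(early, aug, config, seed)
    full = CohortTable(pd.concat([early.df, aug.df], ignore_index=True),
                       list(early.feature_names))
    trials: list[TrialResult] = []
    for sp in splits:
        test = full.subset(sp.test_scan_ids)
        if include_baseline:
            base_train = full.subset(sp.train_scan_ids)
            trials.append(run_trial(base_train, test, HarmonizationMode.COLLECTIVE,
                                    config, use_screen=False,
                                    trial_id=sp.trial_id, fraction=0.0))
        for frac in config.fractions:
            ids = augment_training(sp, frac)
            train = full.subset(ids)
            for mode in modes:
                trials.append(run_trial(train, test, mode, config,
                                        use_screen=True,
                                        trial_id=sp.trial_id, fraction=frac))
    cells = _aggregate_cells(trials)
    log_fit = {m.value: _fit_log_law(cells, m.value) for m in modes}
    return LearningCurveResult(cells=cells, log_fit=log_fit, trials=trials)


# -- method comparison -----------------------------------------------------


@dataclass
class StatsReport:
    """Pairwise method comparisons at one augmentation fraction."""

    delong: pd.DataFrame         # per (pair, trial): auc diff, raw and adjusted p
    delong_summary: pd.DataFrame  # per pair: fraction of trials adjusted p<=alpha
    wilcoxon: pd.DataFrame       # per (pair, metric): statistic, p, n
    metric_cis: pd.DataFrame     # per (mode, metric): mean, lo, hi (t or Poisson)
    log: list[str] = field(default_factory=list)


def compare_methods(results_by_mode: dict[str, list[TrialResult]],
                    alpha: float = 0.05) -> StatsReport:
    """DeLong paired ROC comparisons per trial (Holm-adjusted across the
    method pairs within each trial), Wilcoxon signed-rank comparisons of
    metrics across trials where all models were trained, and confidence
    intervals (t for continuous metrics, Poisson for selected-feature
    counts)."""
    log: list[str] = []
    modes = list(results_by_mode)
    by_trial: dict[str, dict[str, TrialResult]] = {}
    for mode, results in results_by_mode.items():
        for t in results:
            by_trial.setdefault(t.trial_id, {})[mode] = t
    pairs = [(a, b) for i, a in enumerate(modes) for b in modes[i + 1:]]

    delong_rows = []
    for trial_id, per_mode in sorted(by_trial.items()):
        raw: dict[tuple[str, str], tuple[float, float]] = {}
        for a, b in pairs:
            ta, tb = per_mode.get(a), per_mode.get(b)
            if ta is None or tb is None or ta.status != "OK" or tb.status != "OK":
                continue
            common = sorted(set(ta.test_scan_ids) & set(tb.test_scan_ids))
            if not common:
                continue
            ia = [ta.test_scan_ids.index(s) for s in common]
            ib = [tb.test_scan_ids.index(s) for s in common]
            labels = ta.test_labels[ia]
            if labels.min() == labels.max():
                log.append(f"{trial_id} {a} vs {b}: degenerate test set, dropped")
                continue
            diff, var, p = delong_test(labels, ta.test_scores[ia], tb.test_scores[ib])
            raw[(a, b)] = (diff, p)
        if raw:
            adj = holm_bonferroni([p for _, p in raw.values()])
            for ((a, b), (diff, p)), pa in zip(raw.items(), adj):
                delong_rows.append({"trial_id": trial_id, "pair": f"{a} vs {b}",
                                    "auc_diff": diff, "p": p, "p_adj": float(pa)})
    delong = pd.DataFrame(delong_rows)
    if len(delong):
        summary = delong.groupby("pair").agg(
            n_trials=("p_adj", "size"),
            significant_fraction=("p_adj", lambda s: float((s <= alpha).mean())),
            mean_auc_diff=("auc_diff", "mean"),
        ).reset_index()
    else:
        summary = pd.DataFrame(columns=["pair", "n_trials", "significant_fraction",
                                        "mean_auc_diff"])

    # Wilcoxon on trials where all compared models ran
    complete = [tid for tid, pm in by_trial.items()
                if all(m in pm and pm[m].status == "OK" for m in modes)]
    metric_names = ("roc_auc", "weighted_accuracy", "sensitivity", "specificity")
    wil_rows = []
    for a, b in pairs:
        for metric in metric_names:
            va = np.array([by_trial[t][a].metrics.get(metric, np.nan) for t in complete])
            vb = np.array([by_trial[t][b].metrics.get(metric, np.nan) for t in complete])
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() < 2 or np.all(va[ok] == vb[ok]):
                continue
            try:
                stat, p = wilcoxon_signed_rank(va[ok], vb[ok])
            except ValueError:
                continue
            wil_rows.append({"pair": f"{a} vs {b}", "metric": metric,
                             "statistic": stat, "p": p, "n": int(ok.sum())})
    wilcoxon = pd.DataFrame(wil_rows)

    ci_rows = []
    for mode in modes:
        ok_trials = [t for t in results_by_mode[mode] if t.status == "OK"]
        for metric in metric_names:
            vals = [t.metrics.get(metric, np.nan) for t in ok_trials]
            vals = [v for v in vals if np.isfinite(v)]
            if vals:
                mean, lo, hi = t_confidence_interval(vals)
                ci_rows.append({"mode": mode, "metric": metric, "mean": mean,
                                "ci_lo": lo, "ci_hi": hi, "n": len(vals),
                                "ci_kind": "t"})
        counts = [t.n_selected for t in ok_trials]
        if counts:
            mean, lo, hi = poisson_confidence_interval(counts)
            ci_rows.append({"mode": mode, "metric": "n_selected", "mean": mean,
                            "ci_lo": lo, "ci_hi": hi, "n": len(counts),
                            "ci_kind": "poisson"})
    metric_cis = pd.DataFrame(ci_rows)
    return StatsReport(delong=delong, delong_summary=summary, wilcoxon=wilcoxon,
                       metric_cis=metric_cis, log=log)
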