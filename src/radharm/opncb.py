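"""Optimized Permutation Nested ComBat (OPNCB).

Multiple acquisition parameters are harmonized sequentially, one ComBat fit
per parameter, each step consuming the previous step's output.  The order
of parameters is chosen by exhaustively scoring every permutation: each
candidate chain is fitted and applied to the training data, the
Kruskal-Wallis dependence screen is run on the result, and the permutation
leaving the most acquisition-independent features wins (ties broken
lexicographically for determinism).

Three modes handle the biological heterogeneity of augmented training sets:

* COLLECTIVE - one chain over all training scans, no biological
  distinction.
* COVARIATE  - one chain with the scan's dataset label (early /
  benign-augmentation / malignant-augmentation) as a categorical covariate:
  dataset-specific intercepts, shared acquisition corrections.
* SEPARATE   - three independent chains, one per dataset, each with its own
  optimized order; test scans (always early-development) are routed through
  the early-development chain only.

The scoring screen runs on the augmentation subsets; for chains whose data
contain no augmentation scans (the early chain in SEPARATE mode) the same
Kruskal-Wallis machinery is applied across parameter levels within those
scans instead, since the dependence screen proper is undefined there.

Scan-exclusion rules: a (parameter, level) group with fewer than ``min_n``
training scans cannot support a ComBat fit, so such scans are removed
iteratively until a fixed point; test scans carrying a level absent from
the fitted chain have no estimator and are excluded.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .cohort import ACQUISITION_PARAMETERS, CohortTable, DatasetLabel
from .combat import CombatError, CombatModel, adjust_training, apply_from_training, fit_combat
from .screen import ScreenConfig, ScreenError, kruskal_wallis_matrix, screen_features


class HarmonizationMode(str, Enum):
    COLLECTIVE = "collective"
    COVARIATE = "covariate"
    SEPARATE = "separate"


class OpncbError(ValueError):
    pass


@dataclass
class ExclusionReport:
    """Outcome of a scan-exclusion rule: retained and excluded scan ids,
    the latter with (rule, parameter, level) reasons."""

    retained: list[str]
    excluded: list[tuple[str, str, str, str]]  # (scan_id, rule, parameter, level)

    @property
    def excluded_ids(self) -> list[str]:
        return [e[0] for e in self.excluded]


def exclude_rare_protocols(cohort: CohortTable, parameters=ACQUISITION_PARAMETERS,
                           min_n: int = 3) -> ExclusionReport:
    """Iteratively drop scans in any (parameter, level) group smaller than
    ``min_n``, re-checking after every pass until a fixed point.

    Removing one rare group can push another group below the threshold, so
    a single pass is not enough; the fixed point is reached in at most
    one pass per removed scan.
    """
    df = cohort.df
    keep = pd.Series(True, index=df.index)
    excluded: list[tuple[str, str, str, str]] = []
    changed = True
    while changed:
        changed = False
        for p in parameters:
            counts = df.loc[keep, p].value_counts()
            rare = counts.index[counts < min_n]
            if len(rare):
                mask = keep & df[p].isin(rare)
                for i in df.index[mask]:
                    excluded.append((str(df.at[i, "scan_id"]), "min_n", p,
                                     str(df.at[i, p])))
                keep &= ~mask
                changed = True
    retained = df.loc[keep, "scan_id"].astype(str).tolist()
    if not retained:
        raise OpncbError("rare-protocol exclusion removed every scan")
    return ExclusionReport(retained=retained, excluded=excluded)


@dataclass
class HarmonizationPlan:
    """A fitted OPNCB harmonizer.

    ``chains`` maps a chain key to an ordered list of CombatModels; in
    COLLECTIVE/COVARIATE mode there is a single chain keyed ``"ALL"``, in
    SEPARATE mode one chain per dataset label.  ``parameter_order`` holds
    the winning permutation per chain (parameters skipped for having a
    single level are absent, logged in ``skipped``).  ``criterion_value``
    is the count of acquisition-independent features the winning orders
    achieved on the harmonized training data.
    """

    mode: HarmonizationMode
    parameters: tuple[str, ...]
    screen_config: ScreenConfig
    parameter_order: dict[str, list[str]]
    chains: dict[str, list[CombatModel]]
    criterion_value: int
    skipped: dict[str, list[str]] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    #: training scans dropped during fitting (SEPARATE mode re-applies the
    #: rare-protocol rule within each subset); (scan_id, chain, rule, param, level)
    training_exclusions: list[tuple[str, str, str, str, str]] = field(default_factory=list)

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "mode": self.mode.value,
            "parameters": list(self.parameters),
            "screen_config": {
                "alpha": self.screen_config.alpha,
                "min_group_n": self.screen_config.min_group_n,
                "parameters": list(self.screen_config.parameters),
            },
            "parameter_order": self.parameter_order,
            "chains": {k: [json.loads(m.to_json()) for m in ms]
                       for k, ms in self.chains.items()},
            "criterion_value": self.criterion_value,
            "skipped": self.skipped,
            "log": self.log,
            "training_exclusions": [list(t) for t in self.training_exclusions],
        })

    @classmethod
    def from_json(cls, s: str) -> "HarmonizationPlan":
        d = json.loads(s)
        sc = d["screen_config"]
        return cls(
            mode=HarmonizationMode(d["mode"]),
            parameters=tuple(d["parameters"]),
            screen_config=ScreenConfig(alpha=sc["alpha"],
                                       min_group_n=sc["min_group_n"],
                                       parameters=tuple(sc["parameters"])),
            parameter_order={k: list(v) for k, v in d["parameter_order"].items()},
            chains={k: [CombatModel.from_json(json.dumps(m)) for m in ms]
                    for k, ms in d["chains"].items()},
            criterion_value=int(d["criterion_value"]),
            skipped={k: list(v) for k, v in d["skipped"].items()},
            log=list(d["log"]),
            training_exclusions=[tuple(t) for t in d.get("training_exclusions", [])],
        )

    def trained_levels(self, chain_key: str) -> dict[str, set[str]]:
        """Parameter -> set of levels the chain has estimators for."""
        out: dict[str, set[str]] = {}
        for m in self.chains[chain_key]:
            out[m.batch_parameter] = set(m.batch_levels)
        return out

    def test_chain_key(self) -> str:
        """Chain used for test scans: the early-development chain in
        SEPARATE mode, the single chain otherwise."""
        return DatasetLabel.EARLY.value if self.mode is HarmonizationMode.SEPARATE \
            else "ALL"


def exclude_unseen_test_protocols(test: CohortTable,
                                  plan: HarmonizationPlan) -> ExclusionReport:
    """Drop test scans carrying a level absent from the chain that would
    harmonize them (no estimator was trained for that protocol)."""
    levels = plan.trained_levels(plan.test_chain_key())
    df = test.df
    keep = pd.Series(True, index=df.index)
    excluded: list[tuple[str, str, str, str]] = []
    for p, lvset in levels.items():
        bad = keep & ~df[p].astype(str).isin(lvset)
        for i in df.index[bad]:
            excluded.append((str(df.at[i, "scan_id"]), "unseen_protocol", p,
                             str(df.at[i, p])))
        keep &= ~bad
    retained = df.loc[keep, "scan_id"].astype(str).tolist()
    return ExclusionReport(retained=retained, excluded=excluded)


# -- fitting ---------------------------------------------------------------


def _usable_parameters(df: pd.DataFrame, parameters, log: list[str],
                       chain_key: str) -> list[str]:
    usable = []
    for p in parameters:
        if df[p].nunique() < 2:
            log.append(f"{chain_key}: parameter {p} skipped (single level)")
        else:
            usable.append(p)
    return usable


def _fit_chain(sub: CohortTable, order: list[str],
               covariates: np.ndarray | None) -> tuple[list[CombatModel], np.ndarray]:
    """Fit and apply one sequential chain; returns models and harmonized
    feature block."""
    Y = sub.feature_matrix()
    models: list[CombatModel] = []
    for p in order:
        batch = sub.df[p].astype(str).tolist()
        model = fit_combat(
            Y, batch,
            covariates=None if covariates is None else list(covariates),
            batch_parameter=p,
            covariate_parameter=None if covariates is None else "dataset_label",
        )
        Y = adjust_training(model, Y, batch,
                            covariates=None if covariates is None else list(covariates))
        models.append(model)
    return models, Y


def _score_harmonized(sub: CohortTable, Y: np.ndarray, parameters,
                      cfg: ScreenConfig) -> int:
    """Number of acquisition-independent features in a harmonized block.

    Uses the dependence screen on the augmentation subsets when present;
    otherwise (early-development-only data) applies the same Kruskal-Wallis
    test across parameter levels within the block itself.
    """
    harmonized = sub.with_features(Y)
    has_aug = harmonized.df["dataset_label"].isin(
        [DatasetLabel.AUG_BENIGN.value, DatasetLabel.AUG_MALIGNANT.value]
    ).any()
    if has_aug:
        rep = screen_features(harmonized, ScreenConfig(
            alpha=cfg.alpha, min_group_n=cfg.min_group_n, parameters=tuple(parameters)))
        return int((~rep.dependent).sum())
    dependent = np.zeros(harmonized.n_features, dtype=bool)
    for p in parameters:
        lv = harmonized.df[p].astype(str).to_numpy()
        counts = pd.Series(lv).value_counts()
        keep_levels = counts.index[counts >= cfg.min_group_n]
        if len(keep_levels) < 2:
            continue
        mask = np.isin(lv, keep_levels)
        _, pv = kruskal_wallis_matrix(Y[mask], lv[mask])
        dependent |= pv <= cfg.alpha
    return int((~dependent).sum())


def _optimize_chain(sub: CohortTable, parameters, covariates,
                    cfg: ScreenConfig, chain_key: str,
                    log: list[str]) -> tuple[list[str], list[CombatModel], int]:
    usable = _usable_parameters(sub.df, parameters, log, chain_key)
    if not usable:
        log.append(f"{chain_key}: no harmonizable parameter; identity chain")
        return [], [], _score_harmonized(sub, sub.feature_matrix(), parameters, cfg)
    best: tuple[int, tuple[str, ...], list[CombatModel]] | None = None
    for perm in sorted(itertools.permutations(usable)):
        try:
            models, Y = _fit_chain(sub, list(perm), covariates)
            score = _score_harmonized(sub, Y, parameters, cfg)
        except (CombatError, ScreenError) as exc:
            log.append(f"{chain_key}: permutation {perm} disqualified: {exc}")
            continue
        # strict > keeps the lexicographically first permutation on ties
        if best is None or score > best[0]:
            best = (score, perm, models)
    if best is None:
        raise OpncbError(
            f"{chain_key}: every parameter permutation failed to harmonize"
        )
    score, perm, models = best
    return list(perm), models, score


def fit_opncb(training: CohortTable, parameters=ACQUISITION_PARAMETERS,
              mode: HarmonizationMode | str = HarmonizationMode.COLLECTIVE,
              screen_config: ScreenConfig | None = None,
              min_n: int = 3) -> HarmonizationPlan:
    """Fit an OPNCB plan on (already rare-protocol-excluded) training data.

    In SEPARATE mode the min-``min_n`` rule is re-applied within each
    dataset subset, each subset gets its own exhaustive permutation search,
    and the criterion is scored on the union of the harmonized subsets.
    """
    mode = HarmonizationMode(mode)
    cfg = screen_config or ScreenConfig(parameters=tuple(parameters))
    log: list[str] = []
    skipped: dict[str, list[str]] = {}

    if mode in (HarmonizationMode.COLLECTIVE, HarmonizationMode.COVARIATE):
        cov = training.df["dataset_label"].to_numpy() \
            if mode is HarmonizationMode.COVARIATE else None
        order, models, score = _optimize_chain(training, parameters, cov, cfg,
                                               "ALL", log)
        skipped["ALL"] = [p for p in parameters if p not in order]
        return HarmonizationPlan(
            mode=mode, parameters=tuple(parameters), screen_config=cfg,
            parameter_order={"ALL": order}, chains={"ALL": models},
            criterion_value=score, skipped=skipped, log=log,
        )

    # SEPARATE: per-dataset chains, each independently optimized
    orders: dict[str, list[str]] = {}
    chains: dict[str, list[CombatModel]] = {}
    harmonized_parts: list[CohortTable] = []
    training_exclusions: list[tuple[str, str, str, str, str]] = []
    for label in DatasetLabel:
        sub = training.select_dataset(label)
        if len(sub) == 0:
            log.append(f"{label.value}: empty subset, no chain fitted")
            orders[label.value], chains[label.value] = [], []
            skipped[label.value] = list(parameters)
            continue
        excl = exclude_rare_protocols(sub, parameters, min_n=min_n)
        for sid, rule, p, lv in excl.excluded:
            log.append(f"{label.value}: scan {sid} excluded ({rule} {p}={lv})")
            training_exclusions.append((sid, label.value, rule, p, lv))
        sub = sub.subset(excl.retained)
        order, models, _ = _optimize_chain(sub, parameters, None, cfg, label.value, log)
        orders[label.value] = order
        chains[label.value] = models
        skipped[label.value] = [p for p in parameters if p not in order]
        Y = sub.feature_matrix()
        for m in models:
            Y = adjust_training(m, Y, sub.df[m.batch_parameter].astype(str).tolist())
        harmonized_parts.append(sub.with_features(Y))
    if not harmonized_parts:
        raise OpncbError("SEPARATE mode: no dataset subset could be harmonized")
    merged = CohortTable(
        pd.concat([p.df for p in harmonized_parts], ignore_index=True),
        list(training.feature_names),
    )
    score = _score_harmonized(merged, merged.feature_matrix(), parameters, cfg)
    return HarmonizationPlan(
        mode=mode, parameters=tuple(parameters), screen_config=cfg,
        parameter_order=orders, chains=chains, criterion_value=score,
        skipped=skipped, log=log, training_exclusions=training_exclusions,
    )


def harmonize(plan: HarmonizationPlan, cohort: CohortTable,
              is_test: bool = False) -> CohortTable:
    """Apply a fitted plan.

    Training scans go through their own chain (the dataset's chain in
    SEPARATE mode) via the training-adjustment path; test scans go through
    the test chain (the early-development chain in SEPARATE mode) using
    only training-fitted statistics.  When ``is_test``, unseen-protocol
    scans must already have been excluded.
    """
    if is_test:
        key = plan.test_chain_key()
        Y = cohort.feature_matrix()
        cov = cohort.df["dataset_label"].tolist() \
            if plan.mode is HarmonizationMode.COVARIATE else None
        for m in plan.chains[key]:
            Y = apply_from_training(m, Y, cohort.df[m.batch_parameter].astype(str).tolist(),
                                    covariates=cov)
        return cohort.with_features(Y)

    if plan.mode in (HarmonizationMode.COLLECTIVE, HarmonizationMode.COVARIATE):
        cov = cohort.df["dataset_label"].tolist() \
            if plan.mode is HarmonizationMode.COVARIATE else None
        Y = cohort.feature_matrix()
        for m in plan.chains["ALL"]:
            Y = adjust_training(m, Y, cohort.df[m.batch_parameter].astype(str).tolist(),
                                covariates=cov)
        return cohort.with_features(Y)

    # SEPARATE training: route each dataset through its own chain
    parts = []
    for label in DatasetLabel:
        sub = cohort.select_dataset(label)
        if len(sub) == 0:
            continue
        Y = sub.feature_matrix()
        for m in plan.chains.get(label.value, []):
            Y = adjust_training(m, Y, sub.df[m.batch_parameter].astype(str).tolist())
        parts.append(sub.with_features(Y))
    merged = pd.concat([p.df for p in parts], ignore_index=True)
    # restore the input row order
    order = {sid: i for i, sid in enumerate(cohort.df["scan_id"])}
    merged = merged.sort_values("scan_id", key=lambda s: s.map(order),
                                ignore_index=True)
    return CohortTable(merged, list(cohort.feature_names), cohort.provenance)
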