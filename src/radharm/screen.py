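"""Kruskal-Wallis acquisition-dependence screening of radiomic features.

For each feature and each acquisition parameter, scans in an augmentation
subset (later-development benign or malignant) are grouped by the
parameter's levels and compared with the tie-corrected Kruskal-Wallis test.
A feature is acquisition dependent if the test is significant (p <= alpha)
for either subset on any parameter.  Early-development scans are never
tested: their mixture of undeveloped benign and malignant tissue is an
extra source of variability the test cannot attribute.

The screen also ships its own null validation: "uniform groups" of scans
that share every parameter level are randomly bipartitioned into two
pseudo-levels, and the screen is run on that synthetic parameter; under the
null nearly all features should come out independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ACQUISITION_PARAMETERS, CohortTable, DatasetLabel

#: sentinel p-value for (feature, parameter, subset) cells that cannot be
#: tested (fewer than two usable levels); never implies dependence.
NOT_TESTABLE = np.nan

SUBSETS = (DatasetLabel.AUG_BENIGN.value, DatasetLabel.AUG_MALIGNANT.value)


class ScreenError(ValueError):
    pass


@dataclass
class ScreenConfig:
    alpha: float = 0.05
    min_group_n: int = 2
    parameters: tuple[str, ...] = ACQUISITION_PARAMETERS

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ScreenError("alpha must be in (0, 1)")


def kruskal_wallis_matrix(X: np.ndarray, groups: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Tie-corrected Kruskal-Wallis H and chi-square p per feature column.

    Vectorized over the F columns of ``X`` (n x F); ``groups`` assigns each
    row to a level.  Columns that are entirely tied (constant) get H=0,
    p=1: a constant feature cannot exhibit acquisition dependence.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, F = X.shape
    levels, inv = np.unique(groups, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise ScreenError("Kruskal-Wallis needs at least two groups")
    ranks = stats.rankdata(X, axis=0)  # average ranks for ties, per column
    # per-group rank sums via one-hot aggregation
    onehot = np.zeros((k, n))
    onehot[inv, np.arange(n)] = 1.0
    group_n = onehot.sum(axis=1)  # (k,)
    rank_sums = onehot @ ranks    # (k, F)
    H = 12.0 / (n * (n + 1)) * ((rank_sums**2) / group_n[:, None]).sum(axis=0) \
        - 3.0 * (n + 1)
    # tie correction per column: 1 - sum(t^3 - t) / (n^3 - n)
    Xs = np.sort(X, axis=0)
    new_block = np.vstack([np.ones((1, F), bool), Xs[1:] != Xs[:-1]])
    block_id = np.cumsum(new_block, axis=0)  # tie-block label per sorted row
    correction = np.empty(F)
    for g in range(F):  # per-column bincount; columns are independent
        t = np.bincount(block_id[:, g])
        correction[g] = 1.0 - (t**3 - t).sum() / (n**3 - n)
    Hc = np.where(correction > 0, H / np.where(correction > 0, correction, 1.0), 0.0)
    p = np.where(correction > 0, stats.chi2.sf(Hc, k - 1), 1.0)
    # guard tiny negative H from roundoff
    Hc = np.maximum(Hc, 0.0)
    return Hc, p


@dataclass
class DependenceReport:
    """Per-(feature, parameter, subset) p-values and derived summaries.

    ``pvalues`` is a DataFrame indexed by feature with MultiIndex columns
    (parameter, subset); untestable cells are NaN.  ``dependent`` flags a
    feature when any tested cell is <= alpha.
    """

    pvalues: pd.DataFrame
    alpha: float
    parameters: tuple[str, ...]
    log: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.pvalues.index)

    @property
    def dependent(self) -> pd.Series:
        return (self.pvalues <= self.alpha).any(axis=1)

    @property
    def independent_fraction(self) -> float:
        return float((~self.dependent).mean())

    def dependence_frequency(self, parameter: str, subset: str | None = None) -> float:
        """Fraction of features significant for a parameter (optionally one
        subset only)."""
        cols = self.pvalues[parameter]
        if subset is not None:
            cols = cols[[subset]] if subset in cols.columns else cols.iloc[:, :0]
        return float((cols <= self.alpha).any(axis=1).mean())

    def independent_features(self) -> list[str]:
        return list(self.pvalues.index[~self.dependent])

    def to_frame(self) -> pd.DataFrame:
        return self.pvalues.copy()


def screen_features(cohort: CohortTable, config: ScreenConfig | None = None,
                    subsets: Sequence[str] = SUBSETS) -> DependenceReport:
    """Run the acquisition-dependence screen on a (harmonized) cohort.

    Only the augmentation subsets are tested; EARLY scans present in the
    cohort are ignored.  Raw per-test p-values are compared with alpha with
    no multiplicity adjustment.
    """
    cfg = config or ScreenConfig()
    log: list[str] = []
    present = [s for s in subsets if (cohort.df["dataset_label"] == s).any()]
    if not present:
        raise ScreenError(
            "screen undefined: cohort contains no augmentation scans "
            f"(looked for {list(subsets)})"
        )
    cols = pd.MultiIndex.from_product([cfg.parameters, present],
                                      names=["parameter", "subset"])
    pmat = pd.DataFrame(np.nan, index=list(cohort.feature_names), columns=cols)
    for s in present:
        sub = cohort.df[cohort.df["dataset_label"] == s]
        X = sub[cohort.feature_names].to_numpy(float)
        for p in cfg.parameters:
            lv = sub[p].astype(str).to_numpy()
            counts = pd.Series(lv).value_counts()
            keep_levels = counts.index[counts >= cfg.min_group_n]
            if len(keep_levels) < 2:
                log.append(f"{s}/{p}: NOT_TESTABLE (<2 usable levels)")
                continue
            small = counts.index[counts < cfg.min_group_n]
            mask = np.isin(lv, keep_levels)
            if len(small):
                log.append(
                    f"{s}/{p}: dropped level(s) {sorted(small)} below "
                    f"min_group_n={cfg.min_group_n}"
                )
            if counts[keep_levels].min() < 5:
                log.append(f"{s}/{p}: small-group test (min n="
                           f"{int(counts[keep_levels].min())})")
            _, pv = kruskal_wallis_matrix(X[mask], lv[mask])
            pmat[(p, s)] = pv
    return DependenceReport(pvalues=pmat, alpha=cfg.alpha,
                            parameters=tuple(cfg.parameters), log=log)


def validate_screen(cohort: CohortTable, n_splits: int = 5, seed: int = 0,
                    config: ScreenConfig | None = None,
                    min_group_size: int = 8) -> tuple[float, tuple[float, float], pd.DataFrame]:
    """Null validation of the screen on uniform-protocol groups.

    Scans sharing every configured parameter level ("uniform groups", size
    >= ``min_group_size``) are repeatedly bipartitioned at random into two
    pseudo-levels of a synthetic parameter; the screen runs with that single
    parameter.  Returns the mean independent-feature fraction over all
    group x split runs, its 95% t-distribution CI, and the per-run table.
    Deterministic given ``seed``.
    """
    cfg = config or ScreenConfig()
    rng = np.random.default_rng(seed)
    df = cohort.df
    aug = df[df["dataset_label"].isin(SUBSETS)]
    if aug.empty:
        aug = df  # a cohort of only uniform scans, dataset split still applies below
    key = aug[list(cfg.parameters)].astype(str).agg("|".join, axis=1)
    fractions = []
    rows = []
    for gkey, idx in key.groupby(key).groups.items():
        if len(idx) < min_group_size:
            continue
        sub = cohort.subset(df.loc[idx, "scan_id"].tolist())
        for split in range(n_splits):
            perm = rng.permutation(len(sub))
            half = len(sub) // 2
            pseudo = np.array(["p0"] * len(sub), dtype=object)
            pseudo[perm[half:]] = "p1"
            mini = sub.df.copy()
            mini["PSEUDO"] = pseudo
            mini_cohort = CohortTable(mini, list(sub.feature_names))
            mini_cfg = ScreenConfig(alpha=cfg.alpha, min_group_n=cfg.min_group_n,
                                    parameters=("PSEUDO",))
            try:
                rep = screen_features(mini_cohort, mini_cfg)
            except ScreenError:
                continue
            tested = rep.pvalues.notna().any(axis=1)
            if not tested.any():
                continue  # degenerate split (all groups below min_group_n)
            frac = rep.independent_fraction
            fractions.append(frac)
            rows.append({"group": gkey, "split": split, "n_scans": len(sub),
                         "independent_fraction": frac})
    if not fractions:
        raise ScreenError(
            f"no uniform group of size >= {min_group_size} found; "
            "screen validation impossible"
        )
    arr = np.asarray(fractions)
    mean = float(arr.mean())
    if len(arr) > 1 and arr.std(ddof=1) > 0:
        half = stats.t.ppf(0.975, len(arr) - 1) * arr.std(ddof=1) / np.sqrt(len(arr))
    else:
        half = 0.0
    return mean, (mean - half, mean + half), pd.DataFrame(rows)


def tabulate_dependence(reports: dict[str, DependenceReport]) -> pd.DataFrame:
    """Comparison table of dependence frequencies across methods.

    Rows: one per acquisition parameter, plus a deduplicated per-subset
    total (a feature dependent on several parameters counts once) and a
    method total (union over subsets).  Columns: (method, subset) percent.
    """
    methods = list(reports)
    base = reports[methods[0]].feature_names
    for m in methods[1:]:
        if reports[m].feature_names != base:
            raise ScreenError("reports do not share a feature list")
    out: dict[tuple[str, str], dict[str, float]] = {}
    for m in methods:
        rep = reports[m]
        for s in rep.pvalues.columns.get_level_values("subset").unique():
            col: dict[str, float] = {}
            sub = rep.pvalues.xs(s, axis=1, level="subset")
            for p in rep.parameters:
                if p in sub.columns:
                    col[p] = 100.0 * float((sub[p] <= rep.alpha).mean())
                else:
                    col[p] = 0.0
            col["Dataset total"] = 100.0 * float((sub <= rep.alpha).any(axis=1).mean())
            col["Method total"] = 100.0 * float(rep.dependent.mean())
            out[(m, s)] = col
    table = pd.DataFrame(out)
    table.columns.names = ["method", "subset"]
    return table
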