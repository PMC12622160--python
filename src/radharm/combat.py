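"""Empirical-Bayes ComBat location-scale harmonization for one categorical
batch parameter, with optional categorical covariates, and application of a
fitted model to unseen samples.

The model for feature g of scan j in batch i is

    y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg

where gamma (additive shift) and delta (multiplicative scale) are batch
effects, shrunk per batch toward across-feature normal / inverse-gamma
priors estimated by method of moments.  Fitting follows the standard
parametric EB recipe: OLS on a batch one-hot + reference-coded covariate
design, pooled residual variance over all N scans (divide by N),
standardization, per-batch sample moments (ddof=1), moment-matched
hyperpriors, and iteration of the conditional posterior means to a 1e-4
maximum relative change.  These conventions reproduce the reference
implementation to numerical precision, which the test suite checks against
R's ``sva::ComBat``.

Features with zero variance inside any batch cannot support a scale
estimate; they are passed through unadjusted (recorded in the model), as
the reference implementation does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class CombatError(ValueError):
    """Invalid design for ComBat fitting or application."""


class RoutingError(CombatError):
    """A sample carries a batch/covariate level the model was not fitted on."""


def _aprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(sdat: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-4, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate conditional posterior means for one batch.

    sdat: n_i x F standardized data for this batch.  Convergence is the
    reference implementation's maximum relative change criterion.
    """
    n = sdat.shape[0]
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    count = 0
    change = 1.0
    while change > conv:
        if count >= max_iter:
            raise CombatError(
                f"EB iteration failed to converge in {max_iter} iterations"
            )
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
        change = max(
            np.max(np.abs(g_new - g_old) / g_old),
            np.max(np.abs(d_new - d_old) / d_old),
        )
        g_old, d_old = g_new, d_new
        count += 1
    return g_old, d_old, count


def _covariate_design(levels: Sequence[str], level_order: Sequence[str],
                      reference: str) -> np.ndarray:
    """Reference-coded dummy matrix (N x (L-1)) for a categorical covariate."""
    cols = [lv for lv in level_order if lv != reference]
    arr = np.asarray(levels, dtype=object)
    return np.column_stack([(arr == lv).astype(float) for lv in cols]) if cols \
        else np.empty((len(arr), 0))


@dataclass
class CombatModel:
    """A fitted ComBat estimator, applicable to unseen samples.

    All arrays are indexed feature-last so that e.g. ``gamma_star[i]`` is
    the EB location effect of batch level ``batch_levels[i]`` across
    features.  ``covariate_reference`` records the reference level used in
    the covariate coding so test-time designs reconstruct exactly.
    """

    batch_parameter: str
    batch_levels: list[str]
    level_counts: list[int]
    covariate_parameter: str | None
    covariate_levels: list[str]          # full level registry (incl. reference)
    covariate_reference: str | None
    alpha: np.ndarray                     # (F,) grand mean
    beta: np.ndarray                      # (C-1, F) covariate coefficients
    var_pooled: np.ndarray                # (F,)
    gamma_star: np.ndarray                # (L, F)
    delta2_star: np.ndarray               # (L, F)
    passthrough: np.ndarray               # (F,) bool: unadjusted features
    n_iterations: list[int] = field(default_factory=list)
    tol: float = 1e-4

    # -- (de)serialization ------------------------------------------------

    def to_json(self) -> str:
        d = {
            "batch_parameter": self.batch_parameter,
            "batch_levels": self.batch_levels,
            "level_counts": self.level_counts,
            "covariate_parameter": self.covariate_parameter,
            "covariate_levels": self.covariate_levels,
            "covariate_reference": self.covariate_reference,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "passthrough": self.passthrough.astype(int).tolist(),
            "n_iterations": self.n_iterations,
            "tol": self.tol,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "CombatModel":
        d = json.loads(s)
        return cls(
            batch_parameter=d["batch_parameter"],
            batch_levels=list(d["batch_levels"]),
            level_counts=[int(x) for x in d["level_counts"]],
            covariate_parameter=d["covariate_parameter"],
            covariate_levels=list(d["covariate_levels"]),
            covariate_reference=d["covariate_reference"],
            alpha=np.asarray(d["alpha"], float),
            beta=np.asarray(d["beta"], float).reshape(-1, len(d["alpha"])),
            var_pooled=np.asarray(d["var_pooled"], float),
            gamma_star=np.asarray(d["gamma_star"], float),
            delta2_star=np.asarray(d["delta2_star"], float),
            passthrough=np.asarray(d["passthrough"], int).astype(bool),
            n_iterations=[int(x) for x in d["n_iterations"]],
            tol=float(d["tol"]),
        )

    # -- internals --------------------------------------------------------

    def _batch_index(self, batch: Sequence[str]) -> np.ndarray:
        lut = {lv: i for i, lv in enumerate(self.batch_levels)}
        idx = np.empty(len(batch), dtype=int)
        unseen = []
        for j, b in enumerate(batch):
            i = lut.get(str(b))
            if i is None:
                unseen.append((j, str(b)))
                idx[j] = -1
            else:
                idx[j] = i
        if unseen:
            raise RoutingError(
                f"batch parameter {self.batch_parameter!r}: unseen level(s) "
                f"{sorted({b for _, b in unseen})} at sample positions "
                f"{[j for j, _ in unseen][:10]}"
            )
        return idx

    def _stand_mean(self, n: int, covariates: Sequence[str] | None) -> np.ndarray:
        """(n, F) per-sample standardization mean alpha + X beta."""
        sm = np.tile(self.alpha, (n, 1))
        if self.covariate_parameter is not None:
            if covariates is None:
                raise RoutingError(
                    f"model was fitted with covariate {self.covariate_parameter!r}; "
                    "covariate levels are required at application time"
                )
            cov = [str(c) for c in covariates]
            unseen = sorted(set(cov) - set(self.covariate_levels))
            if unseen:
                raise RoutingError(
                    f"covariate {self.covariate_parameter!r}: unseen level(s) {unseen}"
                )
            X = _covariate_design(cov, self.covariate_levels, self.covariate_reference)
            sm = sm + X @ self.beta
        return sm


def fit_combat(features: np.ndarray, batch: Sequence[str],
               covariates: Sequence[str] | None = None,
               batch_parameter: str = "batch",
               covariate_parameter: str | None = None,
               tol: float = 1e-4, max_iter: int = 1000) -> CombatModel:
    """Fit parametric EB ComBat on a scans x F feature matrix.

    ``batch`` gives each scan's level of the batch parameter; ``covariates``
    optionally gives each scan's level of a single categorical covariate
    (here: the dataset label).  Deterministic; raises on designs ComBat
    cannot support.
    """
    Y = np.asarray(features, dtype=float)
    if Y.ndim != 2:
        raise CombatError("features must be a 2-D scans x features matrix")
    if not np.all(np.isfinite(Y)):
        raise CombatError("features must be finite")
    N, F = Y.shape
    batch = [str(b) for b in batch]
    if len(batch) != N:
        raise CombatError("batch length does not match feature rows")

    levels = sorted(set(batch))
    if len(levels) < 2:
        raise CombatError(
            f"batch parameter {batch_parameter!r} has a single level: "
            "nothing to harmonize"
        )
    counts = {lv: batch.count(lv) for lv in levels}
    small = [lv for lv, c in counts.items() if c < 3]
    if small:
        raise CombatError(
            f"batch parameter {batch_parameter!r}: level(s) {small} have fewer "
            "than three scans; ComBat cannot estimate a correction"
        )

    B = np.column_stack([[1.0 if b == lv else 0.0 for b in batch] for lv in levels])
    n_batch = len(levels)

    cov_levels: list[str] = []
    cov_ref: str | None = None
    if covariates is not None:
        cov = [str(c) for c in covariates]
        if len(cov) != N:
            raise CombatError("covariates length does not match feature rows")
        uniq, cnts = np.unique(cov, return_counts=True)
        cov_levels = list(uniq)
        if len(cov_levels) < 2:
            # a constant covariate adds nothing; drop it
            covariates = None
            cov_levels, cov_ref = [], None
        else:
            # most frequent level as reference (ties: lexicographically first)
            cov_ref = str(uniq[np.lexsort((uniq, -cnts))[0]])
    if covariates is not None:
        X = _covariate_design(cov, cov_levels, cov_ref)
        if covariate_parameter is None:
            covariate_parameter = "covariate"
    else:
        X = np.empty((N, 0))
        covariate_parameter = None

    design = np.hstack([B, X])
    if design.shape[1] >= N:
        raise CombatError("more design columns than scans; cannot fit")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise CombatError(
            f"design is rank deficient: covariate {covariate_parameter!r} is "
            f"confounded with batch parameter {batch_parameter!r}"
        )

    # OLS; batch one-hot block spans the intercept
    B_hat = np.linalg.solve(design.T @ design, design.T @ Y)  # (L + C-1, F)
    w = np.array([counts[lv] for lv in levels], float) / N
    alpha = w @ B_hat[:n_batch]                               # (F,)
    resid = Y - design @ B_hat
    var_pooled = (resid**2).mean(axis=0)                      # divide by N

    # features constant within some batch (or with zero pooled variance)
    passthrough = np.zeros(F, dtype=bool)
    for lv in levels:
        m = np.array([b == lv for b in batch])
        passthrough |= Y[m].var(axis=0, ddof=0) == 0.0
    passthrough |= var_pooled <= 0.0
    active = ~passthrough

    stand_mean = alpha[None, :] + X @ B_hat[n_batch:]
    gamma_star = np.zeros((n_batch, F))
    delta2_star = np.ones((n_batch, F))
    iters: list[int] = []
    if not active.any():
        # nothing to adjust: every feature is constant within some batch
        # level; the model passes all features through unchanged
        return CombatModel(
            batch_parameter=batch_parameter, batch_levels=levels,
            level_counts=[counts[lv] for lv in levels],
            covariate_parameter=covariate_parameter, covariate_levels=cov_levels,
            covariate_reference=cov_ref, alpha=alpha, beta=B_hat[n_batch:],
            var_pooled=var_pooled, gamma_star=gamma_star,
            delta2_star=delta2_star, passthrough=passthrough,
            n_iterations=iters, tol=tol,
        )
    sd = np.sqrt(var_pooled[active])
    Z = (Y[:, active] - stand_mean[:, active]) / sd[None, :]

    # per-batch moments of the standardized data
    gamma_hat = np.vstack([
        Z[np.array([b == lv for b in batch])].mean(axis=0) for lv in levels
    ])
    delta2_hat = np.vstack([
        Z[np.array([b == lv for b in batch])].var(axis=0, ddof=1) for lv in levels
    ])
    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    for i, lv in enumerate(levels):
        a = _aprior(delta2_hat[i])
        b_ = _bprior(delta2_hat[i])
        m = np.array([x == lv for x in batch])
        g_star, d_star, it = _it_sol(Z[m], gamma_hat[i], delta2_hat[i],
                                     gamma_bar[i], t2[i], a, b_,
                                     conv=tol, max_iter=max_iter)
        gamma_star[i, active] = g_star
        delta2_star[i, active] = d_star
        iters.append(it)

    beta = B_hat[n_batch:]
    return CombatModel(
        batch_parameter=batch_parameter,
        batch_levels=levels,
        level_counts=[counts[lv] for lv in levels],
        covariate_parameter=covariate_parameter,
        covariate_levels=cov_levels,
        covariate_reference=cov_ref,
        alpha=alpha,
        beta=beta,
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        passthrough=passthrough,
        n_iterations=iters,
        tol=tol,
    )


def _apply(model: CombatModel, features: np.ndarray, batch: Sequence[str],
           covariates: Sequence[str] | None) -> np.ndarray:
    Y = np.asarray(features, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != model.alpha.shape[0]:
        raise CombatError(
            f"feature matrix must be 2-D with {model.alpha.shape[0]} columns"
        )
    idx = model._batch_index([str(b) for b in batch])
    sm = model._stand_mean(Y.shape[0], covariates)
    active = ~model.passthrough
    sd = np.sqrt(model.var_pooled[active])
    Z = (Y[:, active] - sm[:, active]) / sd[None, :]
    g = model.gamma_star[idx][:, active]
    d = np.sqrt(model.delta2_star[idx][:, active])
    out = Y.copy()
    out[:, active] = ((Z - g) / d) * sd[None, :] + sm[:, active]
    return out


def adjust_training(model: CombatModel, features: np.ndarray, batch: Sequence[str],
                    covariates: Sequence[str] | None = None) -> np.ndarray:
    """Harmonize the (training) data the model was fitted on."""
    return _apply(model, features, batch, covariates)


def apply_from_training(model: CombatModel, features: np.ndarray, batch: Sequence[str],
                        covariates: Sequence[str] | None = None) -> np.ndarray:
    """Harmonize unseen samples using only training-fitted statistics.

    No statistic of the incoming data is computed: each sample is
    standardized with the training alpha/beta/var_pooled and adjusted with
    the training EB effects for its batch level, so the output for one scan
    is invariant to which other scans accompany it (a single scan is fine).
    Samples whose batch (or covariate) level was not seen in training raise
    :class:`RoutingError`; the caller is responsible for excluding them.
    """
    return _apply(model, features, batch, covariates)
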