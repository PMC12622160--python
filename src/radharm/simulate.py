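"""Synthetic cohort generator with biology-dependent acquisition effects.

Emulates the statistical structure of a clinical pulmonary-nodule (PN)
radiomics cohort: a patient -> nodule -> scan hierarchy with repeat scans,
an early-development dataset with low malignancy prevalence, two
later-development augmentation datasets with confirmed endpoints (some of
them follow-ups of early-development nodules), dataset-specific acquisition
protocol frequencies in which contrast enhancement (CE) is confounded with
malignancy, and additive/multiplicative batch effects that may differ
between benign and malignant tissue.

Feature model for scan s, feature g:

    y_sg = mu_g + kappa_g * rho(s) * 1[malignant]
         + sum_p gamma[p, level_p(s), T(s), g]
         + (prod_p delta[p, level_p(s), T(s), g]) * eps_sg

with eps_sg ~ N(0, sigma_g^2), T(s) the tissue context ("early" for
early-development scans regardless of endpoint, else "benign"/"malignant"),
and rho(s) = rho < 1 for early-development scans (an early malignant PN has
not yet developed the full malignant phenotype), 1 otherwise.

Default counts reproduce the cohort scale the analysis assumes (187 / 36 /
189 scans; 16.6% of early scans malignant, so the pooled pool is 53.4%
malignant).  Default protocol frequencies and effect magnitudes are
package-invented and documented as such: CE frequency 0.1 / 0.2 / 0.7 in
the early / benign-augmentation / malignant-augmentation datasets; additive
shifts of 0.3-2 noise-SD units; scale factors within [0.8, 1.5].
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (
    ACQUISITION_PARAMETERS,
    CohortTable,
    DatasetLabel,
    EndpointLabel,
    cohort_from_records,
    ScanRecord,
)

CONTEXTS = ("early", "benign", "malignant")


class ConfigError(ValueError):
    pass


@dataclass
class EffectSpec:
    """How one acquisition parameter perturbs features.

    ``levels[0]`` is the reference level (no effect).  ``freqs`` maps each
    dataset label to level probabilities.  Every non-reference level
    carries a *shared* effect -- identical in all tissue contexts -- on a
    ``shared_affected`` fraction of features, with additive magnitudes
    (units of noise SD, random sign) from ``shared_gamma`` and scale
    factors from ``shared_delta``.  When the generator runs with
    ``biology_dependent=True``, an *extra* context-specific component is
    layered on top per tissue context (additive shifts add, scale factors
    multiply); this is the mechanism by which, e.g., contrast enhancement
    perturbs malignant tissue more strongly than benign tissue.
    """

    levels: tuple[str, ...]
    freqs: dict[str, tuple[float, ...]]
    shared_affected: float = 0.0
    shared_gamma: tuple[float, float] = (0.5, 1.5)
    shared_delta: tuple[float, float] = (0.9, 1.3)
    extra_affected: dict[str, float] = field(default_factory=lambda: {c: 0.0 for c in CONTEXTS})
    extra_gamma: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {c: (1.0, 2.0) for c in CONTEXTS})
    extra_delta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {c: (1.1, 1.5) for c in CONTEXTS})

    def validate(self) -> None:
        for ds, p in self.freqs.items():
            if len(p) != len(self.levels):
                raise ConfigError(f"freqs for {ds} must match levels")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ConfigError(f"freqs for {ds} must sum to 1")
        if self.shared_delta[0] <= 0:
            raise ConfigError("delta must be positive")
        for ctx in CONTEXTS:
            for d in (self.extra_affected, self.extra_gamma, self.extra_delta):
                if ctx not in d:
                    raise ConfigError(f"missing extra-effect entry for context {ctx!r}")
            if self.extra_delta[ctx][0] <= 0:
                raise ConfigError("delta must be positive")


def _default_effect_specs() -> dict[str, EffectSpec]:
    e, b, m = DatasetLabel.EARLY.value, DatasetLabel.AUG_BENIGN.value, \
        DatasetLabel.AUG_MALIGNANT.value
    return {
        # CE: rare in early scans, frequent in malignant augmentation scans
        # (administered on clinical concern); a broad shared effect plus a
        # strong malignant-tissue extra (contrast accumulates in tumors).
        "CE": EffectSpec(
            levels=("no", "yes"),
            freqs={e: (0.9, 0.1), b: (0.8, 0.2), m: (0.3, 0.7)},
            shared_affected=0.5, shared_gamma=(0.5, 1.5), shared_delta=(0.9, 1.3),
            extra_affected={"early": 0.0, "benign": 0.0, "malignant": 0.3},
            extra_gamma={c: (1.0, 2.0) for c in CONTEXTS},
            extra_delta={c: (1.1, 1.5) for c in CONTEXTS},
        ),
        # focal spot: moderate, biology-independent effect
        "FOCAL_SPOT": EffectSpec(
            levels=("small", "large"),
            freqs={e: (0.5, 0.5), b: (0.5, 0.5), m: (0.5, 0.5)},
            shared_affected=0.5, shared_gamma=(0.5, 1.5), shared_delta=(0.8, 1.3),
        ),
        # KVP: weak effect on a small feature subset
        "KVP": EffectSpec(
            levels=("120", "100"),
            freqs={e: (0.6, 0.4), b: (0.6, 0.4), m: (0.6, 0.4)},
            shared_affected=0.1, shared_gamma=(0.3, 0.8), shared_delta=(0.95, 1.1),
        ),
        # manufacturer: perturbs malignant-tissue features predominantly
        "MANUFACTURER": EffectSpec(
            levels=("A", "B"),
            freqs={e: (0.6, 0.4), b: (0.6, 0.4), m: (0.6, 0.4)},
            shared_affected=0.0,
            extra_affected={"early": 0.0, "benign": 0.0, "malignant": 0.45},
            extra_gamma={c: (0.5, 1.5) for c in CONTEXTS},
            extra_delta={c: (0.9, 1.2) for c in CONTEXTS},
        ),
    }


@dataclass
class DatasetShape:
    n_patients: int
    n_nodules: int
    n_scans: int

    def validate(self, name: str) -> None:
        if not (1 <= self.n_patients <= self.n_nodules <= self.n_scans):
            raise ConfigError(
                f"{name}: need 1 <= patients <= nodules <= scans, got "
                f"{self.n_patients}/{self.n_nodules}/{self.n_scans}"
            )


@dataclass
class GeneratorConfig:
    """Cohort-generator configuration; defaults are the study conditions."""

    early: DatasetShape = field(default_factory=lambda: DatasetShape(58, 82, 187))
    aug_benign: DatasetShape = field(default_factory=lambda: DatasetShape(21, 28, 36))
    aug_malignant: DatasetShape = field(default_factory=lambda: DatasetShape(58, 59, 189))
    n_features: int = 107
    prevalence_early: float = 0.195        # malignant fraction of early nodules
    scan_prevalence_early: float | None = 0.166  # malignant fraction of early scans
    n_followup_benign: int = 5             # early benign nodules re-scanned in AUG_BENIGN
    n_followup_malignant: int = 16         # early malignant nodules re-scanned in AUG_MALIGNANT
    n_signal_features: int = 8
    kappa_range: tuple[float, float] = (1.0, 2.0)  # class shift, noise-SD units
    # later-development scans differ from early scans in many features
    # (growth, density change) independent of endpoint
    dev_shift_fraction: float = 0.5
    dev_shift_range: tuple[float, float] = (0.5, 1.5)
    attenuation: float = 0.4               # rho: class-signal multiplier for early scans
    noise_sd: float = 1.0
    biology_dependent: bool = True
    early_context_by_endpoint: bool = False
    effect_specs: dict[str, EffectSpec] = field(default_factory=_default_effect_specs)

    def validate(self) -> None:
        self.early.validate("early")
        self.aug_benign.validate("aug_benign")
        self.aug_malignant.validate("aug_malignant")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ConfigError("attenuation must be in [0, 1]")
        if not 0.0 < self.prevalence_early < 1.0:
            raise ConfigError("prevalence_early must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if set(self.effect_specs) != set(ACQUISITION_PARAMETERS):
            raise ConfigError(
                f"effect_specs must cover exactly {list(ACQUISITION_PARAMETERS)}"
            )
        for name, spec in self.effect_specs.items():
            spec.validate()
        if self.n_signal_features > self.n_features:
            raise ConfigError("more signal features than features")
        if self.n_followup_malignant > self.aug_malignant.n_nodules:
            raise ConfigError("too many malignant follow-up nodules")
        if self.n_followup_benign > self.aug_benign.n_nodules:
            raise ConfigError("too many benign follow-up nodules")

    def digest(self) -> str:
        def enc(o):
            if isinstance(o, (DatasetShape, EffectSpec)):
                return asdict(o)
            raise TypeError(o)
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=enc).encode()
        ).hexdigest()[:12]


def default_config() -> GeneratorConfig:
    return GeneratorConfig()


def load_config(path) -> GeneratorConfig:
    """Load a GeneratorConfig from a YAML or JSON mapping.

    Top-level scalar fields override the defaults; dataset shapes are given
    as ``[patients, nodules, scans]`` triples under ``early`` /
    ``aug_benign`` / ``aug_malignant``.  Per-parameter effect
    specifications beyond the defaults are a Python-API concern.
    """
    import pathlib

    import yaml

    raw = yaml.safe_load(pathlib.Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    cfg = GeneratorConfig()
    for key, value in raw.items():
        if key in ("early", "aug_benign", "aug_malignant"):
            setattr(cfg, key, DatasetShape(*[int(v) for v in value]))
        elif key in ("kappa_range", "dev_shift_range"):
            setattr(cfg, key, tuple(float(v) for v in value))
        elif hasattr(cfg, key) and key != "effect_specs":
            setattr(cfg, key, value)
        else:
            raise ConfigError(f"{path}: unknown config field {key!r}")
    cfg.validate()
    return cfg


def small_config(scale: float = 1.0, n_features: int = 107,
                 **overrides) -> GeneratorConfig:
    """Convenience: the default conditions scaled down (or up) in size."""
    def sc(shape: DatasetShape) -> DatasetShape:
        return DatasetShape(
            max(2, round(shape.n_patients * scale)),
            max(2, round(shape.n_nodules * scale)),
            max(4, round(shape.n_scans * scale)),
        )
    cfg = GeneratorConfig(
        early=sc(DatasetShape(58, 82, 187)),
        aug_benign=sc(DatasetShape(21, 28, 36)),
        aug_malignant=sc(DatasetShape(58, 59, 189)),
        n_features=n_features,
    )
    cfg.n_followup_benign = min(cfg.n_followup_benign, cfg.aug_benign.n_nodules // 2)
    cfg.n_followup_malignant = min(cfg.n_followup_malignant,
                                   cfg.aug_malignant.n_nodules // 2)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def null_config(scale: float = 1.0, n_features: int = 107) -> GeneratorConfig:
    """Study-shaped config with every effect switched off: no acquisition
    effects, no class signal, no development shift.  Used to study the
    screen's behaviour under the global null."""
    cfg = small_config(scale=scale, n_features=n_features)
    cfg.n_signal_features = 0
    cfg.dev_shift_fraction = 0.0
    for spec in cfg.effect_specs.values():
        spec.shared_affected = 0.0
        for c in CONTEXTS:
            spec.extra_affected[c] = 0.0
    return cfg


@dataclass
class GroundTruth:
    """The generating parameters behind a synthetic cohort.

    ``gamma[p][level][ctx]`` / ``delta[p][level][ctx]`` are per-feature
    additive / multiplicative acquisition effects (reference level: 0 / 1).
    ``kappa`` is the benign->malignant mean shift (zero off the signal
    subset).  Together with ``noise_seed`` and the cohort's metadata the
    feature block is exactly reconstructable.
    """

    mu: np.ndarray
    kappa: np.ndarray
    signal_features: np.ndarray       # indices into the feature vector
    dev_shift: np.ndarray             # later-development mean shift (any endpoint)
    attenuation: float
    noise_sd: float
    gamma: dict[str, dict[str, dict[str, np.ndarray]]]
    delta: dict[str, dict[str, dict[str, np.ndarray]]]
    scan_context: dict[str, str]      # scan_id -> tissue context
    noise_seed: int

    def expected_mean(self, endpoint: str, dataset: str,
                      acquisition: Mapping[str, str]) -> np.ndarray:
        """Noise-free feature mean for a scan with the given metadata."""
        ctx = self.context_for(dataset, endpoint)
        rho = self.attenuation if dataset == DatasetLabel.EARLY.value else 1.0
        y = self.mu.copy()
        if dataset != DatasetLabel.EARLY.value:
            y = y + self.dev_shift
        if endpoint == EndpointLabel.MALIGNANT.value:
            y = y + self.kappa * rho
        for p, lv in acquisition.items():
            y = y + self.gamma[p][str(lv)][ctx]
        return y

    def context_for(self, dataset: str, endpoint: str) -> str:
        if dataset == DatasetLabel.EARLY.value:
            return "early"
        return "benign" if endpoint == EndpointLabel.BENIGN.value else "malignant"

    def reconstruct(self, meta: pd.DataFrame) -> np.ndarray:
        """Recompute the feature block for the cohort's metadata rows (in
        generation order) from the stored parameters and noise seed."""
        rng = np.random.default_rng(self.noise_seed)
        eps = rng.normal(0.0, self.noise_sd, size=(len(meta), len(self.mu)))
        Y = np.empty_like(eps)
        for i, row in enumerate(meta.itertuples(index=False)):
            ctx = self.scan_context[row.scan_id]
            scale = np.ones(len(self.mu))
            for p in ACQUISITION_PARAMETERS:
                scale = scale * self.delta[p][str(getattr(row, p))][ctx]
            acq = {p: getattr(row, p) for p in ACQUISITION_PARAMETERS}
            Y[i] = self.expected_mean(row.endpoint_label, row.dataset_label, acq) \
                + scale * eps[i]
        return Y


def _allocate(n_items: int, n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly allocate n_items into n_bins, each bin getting >= 1."""
    if n_items < n_bins:
        raise ConfigError(f"cannot place {n_items} items into {n_bins} bins (need >=1 each)")
    counts = np.ones(n_bins, dtype=int)
    extra = rng.choice(n_bins, size=n_items - n_bins, replace=True)
    np.add.at(counts, extra, 1)
    return counts


def _draw_effects(cfg: GeneratorConfig, rng: np.random.Generator):
    """Per-(parameter, level, context) feature-effect arrays: a shared
    (biology-independent) draw, plus context-specific extras when the
    generator is biology dependent."""
    F = cfg.n_features
    gamma: dict = {}
    delta: dict = {}
    for p in ACQUISITION_PARAMETERS:
        spec = cfg.effect_specs[p]
        gamma[p], delta[p] = {}, {}
        ref = spec.levels[0]
        gamma[p][ref] = {c: np.zeros(F) for c in CONTEXTS}
        delta[p][ref] = {c: np.ones(F) for c in CONTEXTS}
        for lv in spec.levels[1:]:
            g_s, d_s = _draw_component(F, spec.shared_affected, spec.shared_gamma,
                                       spec.shared_delta, cfg.noise_sd, rng)
            gamma[p][lv], delta[p][lv] = {}, {}
            for ctx in CONTEXTS:
                if cfg.biology_dependent:
                    g_x, d_x = _draw_component(
                        F, spec.extra_affected[ctx], spec.extra_gamma[ctx],
                        spec.extra_delta[ctx], cfg.noise_sd, rng)
                    gamma[p][lv][ctx] = g_s + g_x
                    delta[p][lv][ctx] = d_s * d_x
                else:
                    gamma[p][lv][ctx] = g_s
                    delta[p][lv][ctx] = d_s
    return gamma, delta


def _draw_component(F: int, frac: float, gamma_range, delta_range, sd: float,
                    rng: np.random.Generator):
    """One effect component: an affected-feature mask, additive shifts with
    random signs (noise-SD units) and multiplicative scales.  Draws a fixed
    number of variates regardless of the mask so the random stream, hence
    the cohort, only depends on (config, seed)."""
    mask = rng.random(F) < frac
    g = np.zeros(F)
    d = np.ones(F)
    sign = rng.choice([-1.0, 1.0], size=F)
    g[mask] = (sign * rng.uniform(*gamma_range, size=F) * sd)[mask]
    d[mask] = rng.uniform(*delta_range, size=F)[mask]
    return g, d


def generate_cohort(config: GeneratorConfig | None = None,
                    seed: int = 0) -> tuple[CohortTable, GroundTruth]:
    """Generate a cohort and its ground truth; deterministic given
    (config, seed)."""
    cfg = config or default_config()
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    s_struct, s_effect, s_noise = [np.random.default_rng(c) for c in ss.spawn(3)]
    noise_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))

    F = cfg.n_features
    feature_names = [f"feat_{i:03d}" for i in range(F)]

    # ---- early-development structure -----------------------------------
    e = cfg.early
    n_mal_nod = int(round(cfg.prevalence_early * e.n_nodules))
    n_mal_nod = min(max(n_mal_nod, 1), e.n_nodules - 1)
    if cfg.scan_prevalence_early is not None:
        n_mal_scans = int(round(cfg.scan_prevalence_early * e.n_scans))
    else:
        n_mal_scans = int(round(n_mal_nod / e.n_nodules * e.n_scans))
    n_ben_nod = e.n_nodules - n_mal_nod
    n_ben_scans = e.n_scans - n_mal_scans
    if n_mal_scans < n_mal_nod or n_ben_scans < n_ben_nod:
        raise ConfigError("early scan counts incompatible with nodule counts")

    early_patients = [f"P{i:04d}" for i in range(e.n_patients)]
    nod_owner = list(range(e.n_patients)) + list(
        s_struct.choice(e.n_patients, size=e.n_nodules - e.n_patients, replace=True)
    )
    early_nodules = [f"N{i:04d}" for i in range(e.n_nodules)]
    mal_idx = s_struct.choice(e.n_nodules, size=n_mal_nod, replace=False)
    is_mal = np.zeros(e.n_nodules, dtype=bool)
    is_mal[mal_idx] = True
    scans_per_mal = _allocate(n_mal_scans, n_mal_nod, s_struct)
    scans_per_ben = _allocate(n_ben_scans, n_ben_nod, s_struct)

    rows: list[ScanRecord] = []
    scan_context: dict[str, str] = {}
    sid = 0

    def protocols(dataset: str) -> dict[str, str]:
        acq = {}
        for p in ACQUISITION_PARAMETERS:
            spec = cfg.effect_specs[p]
            acq[p] = str(s_struct.choice(spec.levels, p=spec.freqs[dataset]))
        return acq

    def add_scan(patient: str, nodule: str, dataset: DatasetLabel,
                 endpoint: EndpointLabel) -> None:
        nonlocal sid
        scan_id = f"S{sid:05d}"
        sid += 1
        acq = protocols(dataset.value)
        rec = ScanRecord(scan_id, patient, nodule, dataset, endpoint, acq,
                         np.zeros(F))
        rows.append(rec)
        if dataset is DatasetLabel.EARLY and not (
            cfg.early_context_by_endpoint and endpoint is EndpointLabel.MALIGNANT
        ):
            scan_context[scan_id] = "early"
        else:
            scan_context[scan_id] = (
                "benign" if endpoint is EndpointLabel.BENIGN else "malignant"
            )

    mal_counter = ben_counter = 0
    for i in range(e.n_nodules):
        pat = early_patients[nod_owner[i]]
        if is_mal[i]:
            k = scans_per_mal[mal_counter]; mal_counter += 1
            ep = EndpointLabel.MALIGNANT
        else:
            k = scans_per_ben[ben_counter]; ben_counter += 1
            ep = EndpointLabel.BENIGN
        for _ in range(k):
            add_scan(pat, early_nodules[i], DatasetLabel.EARLY, ep)

    # ---- augmentation structure (follow-ups of early nodules + new) ----
    def build_aug(shape: DatasetShape, dataset: DatasetLabel,
                  endpoint: EndpointLabel, followup_pool: np.ndarray,
                  n_followup: int, tag: str) -> None:
        n_followup = min(n_followup, len(followup_pool), shape.n_nodules)
        fu = s_struct.choice(followup_pool, size=n_followup, replace=False) \
            if n_followup else np.array([], dtype=int)
        fu_patients = {early_patients[nod_owner[i]] for i in fu}
        n_new_nod = shape.n_nodules - n_followup
        # patient totals are approximate (a follow-up patient may own several
        # nodules); scan and nodule counts are exact
        n_new_pat = min(shape.n_patients - len(fu_patients), n_new_nod)
        if n_new_pat < 1 or n_new_nod < n_new_pat:
            raise ConfigError(
                f"{dataset.value}: follow-up overlap leaves an infeasible "
                f"new-patient/new-nodule allocation"
            )
        new_patients = [f"P_{tag}{i:04d}" for i in range(n_new_pat)]
        new_owner = list(range(n_new_pat)) + list(
            s_struct.choice(n_new_pat, size=n_new_nod - n_new_pat, replace=True)
        )
        nodules = [(early_patients[nod_owner[i]], early_nodules[i]) for i in fu]
        nodules += [(new_patients[new_owner[j]], f"N_{tag}{j:04d}")
                    for j in range(n_new_nod)]
        per_nod = _allocate(shape.n_scans, shape.n_nodules, s_struct)
        for (pat, nod), k in zip(nodules, per_nod):
            for _ in range(k):
                add_scan(pat, nod, dataset, endpoint)

    build_aug(cfg.aug_benign, DatasetLabel.AUG_BENIGN, EndpointLabel.BENIGN,
              np.where(~is_mal)[0], cfg.n_followup_benign, "B")
    build_aug(cfg.aug_malignant, DatasetLabel.AUG_MALIGNANT, EndpointLabel.MALIGNANT,
              np.where(is_mal)[0], cfg.n_followup_malignant, "M")

    # ---- feature values -------------------------------------------------
    mu = s_effect.normal(0.0, 2.0, size=F)
    kappa = np.zeros(F)
    sig_idx = np.sort(s_effect.choice(F, size=cfg.n_signal_features, replace=False))
    kappa[sig_idx] = s_effect.choice([-1.0, 1.0], size=cfg.n_signal_features) * \
        s_effect.uniform(*cfg.kappa_range, size=cfg.n_signal_features) * cfg.noise_sd
    dev_shift, _ = _draw_component(F, cfg.dev_shift_fraction, cfg.dev_shift_range,
                                   (1.0, 1.0), cfg.noise_sd, s_effect)
    gamma, delta = _draw_effects(cfg, s_effect)

    gt = GroundTruth(
        mu=mu, kappa=kappa, signal_features=sig_idx, dev_shift=dev_shift,
        attenuation=cfg.attenuation, noise_sd=cfg.noise_sd,
        gamma=gamma, delta=delta, scan_context=scan_context,
        noise_seed=noise_seed,
    )

    rng_noise = np.random.default_rng(noise_seed)
    eps = rng_noise.normal(0.0, cfg.noise_sd, size=(len(rows), F))
    final_rows = []
    for i, rec in enumerate(rows):
        ctx = scan_context[rec.scan_id]
        scale = np.ones(F)
        for p in ACQUISITION_PARAMETERS:
            scale = scale * delta[p][rec.acquisition[p]][ctx]
        y = gt.expected_mean(rec.endpoint_label.value, rec.dataset_label.value,
                             rec.acquisition) + scale * eps[i]
        final_rows.append(ScanRecord(rec.scan_id, rec.patient_id, rec.nodule_id,
                                     rec.dataset_label, rec.endpoint_label,
                                     rec.acquisition, y))

    cohort = cohort_from_records(
        final_rows, feature_names,
        provenance=f"synthetic:config={cfg.digest()}:seed={seed}",
    )
    return cohort, gt


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Per-dataset and total patient / nodule / scan counts with percent
    malignant at each level (a patient counts as malignant if any of their
    nodules has a malignant endpoint).

    Scan counts are additive across datasets; patient and nodule counts are
    not, because augmentation datasets contain follow-up scans of
    early-development nodules.
    """
    df = cohort.df
    mal = EndpointLabel.MALIGNANT.value

    def stats(sub: pd.DataFrame) -> dict[str, float]:
        pat = sub.groupby("patient_id")["endpoint_label"].agg(lambda s: (s == mal).any())
        nod = sub.groupby("nodule_id")["endpoint_label"].agg(lambda s: (s == mal).any())
        return {
            "patients": len(pat), "patients_pct_cancer": 100.0 * pat.mean() if len(pat) else 0.0,
            "nodules": len(nod), "nodules_pct_cancer": 100.0 * nod.mean() if len(nod) else 0.0,
            "scans": len(sub),
            "scans_pct_cancer": 100.0 * (sub["endpoint_label"] == mal).mean() if len(sub) else 0.0,
        }

    out = {}
    for label in DatasetLabel:
        sub = df[df["dataset_label"] == label.value]
        out[label.value] = stats(sub)
    out["Total"] = stats(df)
    table = pd.DataFrame(out).T
    for c in ("patients", "nodules", "scans"):
        table[c] = table[c].astype(int)
    return table
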