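"""Internal and external validation of the CPM pipeline.

Implements leakage-free k-fold cross-validation repeated over
iterations, a permutation-based MAE null, consensus-network extraction
(edges persisting in every fold of every iteration), external
validation with frozen standardization parameters, the dummy-mean
baseline, and group-wise evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from plvcpm.cpm import (
    CpmModel,
    EdgeStandardization,
    FrozenSVR,
    PredictiveNetwork,
    ScaleParams,
    apply_edge_standardization,
    equivalent_scale_params,
    features_from_strengths,
    fit_edge_standardization,
    fit_svr,
    select_edges,
    standardize_scores,
    strength_matrix,
)


@dataclass
class Dataset:
    """Edge matrix plus targets and optional covariates for validation."""

    edges: np.ndarray  # subjects x n_edges, raw (unstandardized) weights
    z_scores: np.ndarray  # standardized target scores
    covariates: np.ndarray | None = None  # subjects x k, for partial selection
    groups: np.ndarray | None = None  # subject group labels
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.z_scores = np.asarray(self.z_scores, dtype=float)
        if self.edges.ndim != 2 or self.edges.shape[0] != self.z_scores.shape[0]:
            raise ValueError("edges must be subjects x n_edges matching z_scores")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.n_subjects:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != self.n_subjects:
                raise ValueError("covariate rows must match number of subjects")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)

    @property
    def n_subjects(self) -> int:
        return self.edges.shape[0]


@dataclass
class ValidationReport:
    """Aggregated predictive performance across folds and iterations."""

    r_mean: float
    r_sd: float
    mae_mean: float
    mae_sd: float
    r2_mean: float
    r2_sd: float
    dummy_mae: float
    k: int = 0
    n_iterations: int = 0
    perm_p: float | None = None
    per_group: dict[str, dict[str, float]] | None = None
    edge_counts: list[int] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "r_mean": self.r_mean,
            "r_sd": self.r_sd,
            "mae_mean": self.mae_mean,
            "mae_sd": self.mae_sd,
            "r2_mean": self.r2_mean,
            "r2_sd": self.r2_sd,
            "dummy_mae": self.dummy_mae,
            "k": self.k,
            "n_iterations": self.n_iterations,
            "perm_p": self.perm_p,
            "per_group": self.per_group,
            "edge_counts": list(self.edge_counts),
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# metrics


def metrics(pred: Sequence[float], obs: Sequence[float]) -> tuple[float, float, float]:
    """Pearson r, mean absolute error, and held-out R-squared.

    R-squared is 1 - SS_res/SS_tot against the observed mean and can be
    negative on held-out data. Constant predictions carry no linear
    association and score r = 0 by convention.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(obs) == 0:
        raise ValueError("observed values are constant; r undefined")
    mae = float(np.mean(np.abs(pred - obs)))
    ss_res = float(((obs - pred) ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    if np.ptp(pred) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(pred, obs)[0, 1])
    return r, mae, r2


def dummy_baseline(train_targets: Sequence[float], test_targets: Sequence[float]) -> float:
    """MAE of predicting the training-set mean for every test subject."""
    train = np.asarray(train_targets, dtype=float)
    test = np.asarray(test_targets, dtype=float)
    if train.size == 0 or test.size == 0:
        raise ValueError("train and test target sets must be non-empty")
    return float(np.mean(np.abs(test - train.mean())))


def groupwise_eval(
    pred: Sequence[float],
    obs: Sequence[float],
    groups: Sequence,
    min_n: int = 3,
) -> dict[str, dict[str, float]]:
    """Per-group r and MAE; groups below ``min_n`` subjects are omitted."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    groups = np.asarray(groups)
    out: dict[str, dict[str, float]] = {}
    for g in sorted(set(groups.tolist()), key=str):
        mask = groups == g
        if mask.sum() < min_n:
            continue
        r, mae, r2 = metrics(pred[mask], obs[mask])
        out[str(g)] = {"r": r, "mae": mae, "r2": r2, "n": int(mask.sum())}
    return out


# ---------------------------------------------------------------------------
# folds


def make_folds(n_subjects: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold assignment: a permutation split into k near-equal parts."""
    if n_subjects < k:
        raise ValueError(f"cannot split {n_subjects} subjects into {k} folds")
    assign = np.empty(n_subjects, dtype=int)
    perm = rng.permutation(n_subjects)
    for f, chunk in enumerate(np.array_split(perm, k)):
        assign[chunk] = f
    return assign


# ---------------------------------------------------------------------------
# fold-level training


@dataclass
class _FoldFit:
    """Everything fitted on one training fold (never sees test subjects)."""

    edge_std: EdgeStandardization
    network: PredictiveNetwork
    regressor: FrozenSVR | None  # None -> dummy fallback (training mean)
    train_mean: float

    def predict(self, raw_edges: np.ndarray, feature_mode: str) -> np.ndarray:
        raw_edges = np.atleast_2d(raw_edges)
        if self.regressor is None:
            return np.full(raw_edges.shape[0], self.train_mean)
        z = apply_edge_standardization(raw_edges, self.edge_std)
        feats = features_from_strengths(strength_matrix(z, self.network), feature_mode)
        return self.regressor.predict(feats)


def fit_fold(
    train_edges: np.ndarray,
    train_z: np.ndarray,
    q: float = 0.01,
    feature_mode: str = "combined",
    covariates: np.ndarray | None = None,
    svr_params: dict | None = None,
) -> _FoldFit:
    """Standardize, select and fit on training subjects only.

    When selection returns no edges (or the resulting features are
    degenerate) the fold falls back to the dummy mean predictor; this
    arises routinely under null data where nothing survives FDR.
    """
    std = fit_edge_standardization(train_edges)
    z_train = apply_edge_standardization(train_edges, std)
    network = select_edges(z_train, train_z, q=q, covariates=covariates)
    regressor = None
    if network.n_selected > 0:
        feats = features_from_strengths(strength_matrix(z_train, network), feature_mode)
        if np.any(np.ptp(feats, axis=0) > 0):
            regressor = fit_svr(feats, train_z, **(svr_params or {}))
    return _FoldFit(
        edge_std=std,
        network=network,
        regressor=regressor,
        train_mean=float(np.mean(train_z)),
    )


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    dataset: Dataset,
    k: int = 5,
    n_iterations: int = 100,
    q: float = 0.01,
    feature_mode: str = "combined",
    svr_params: dict | None = None,
    seed: int = 0,
    collect_predictions: bool = False,
) -> tuple[ValidationReport, list[PredictiveNetwork]]:
    """Repeated k-fold CV with per-iteration reshuffled fold plans.

    Within each fold the edge standardization, edge selection and SVR
    are fitted on the training folds only; the held-out fold is scored
    with the frozen fold fit. Metrics are aggregated as mean +/- SD over
    all folds x iterations. Returns the report and the per-fold
    predictive networks (k * n_iterations of them).
    """
    n = dataset.n_subjects
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} subjects for k={k} CV, got {n}")
    rng = np.random.default_rng(seed)
    rs, maes, r2s, dummies = [], [], [], []
    networks: list[PredictiveNetwork] = []
    all_pred = np.empty(n) if collect_predictions else None
    for _ in range(n_iterations):
        assign = make_folds(n, k, rng)
        for f in range(k):
            test = assign == f
            train = ~test
            cov_train = dataset.covariates[train] if dataset.covariates is not None else None
            fit = fit_fold(
                dataset.edges[train],
                dataset.z_scores[train],
                q=q,
                feature_mode=feature_mode,
                covariates=cov_train,
                svr_params=svr_params,
            )
            pred = fit.predict(dataset.edges[test], feature_mode)
            r, mae, r2 = metrics(pred, dataset.z_scores[test])
            rs.append(r)
            maes.append(mae)
            r2s.append(r2)
            dummies.append(dummy_baseline(dataset.z_scores[train], dataset.z_scores[test]))
            networks.append(fit.network)
            if collect_predictions:
                all_pred[test] = pred
    report = ValidationReport(
        r_mean=float(np.mean(rs)),
        r_sd=float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0,
        mae_mean=float(np.mean(maes)),
        mae_sd=float(np.std(maes, ddof=1)) if len(maes) > 1 else 0.0,
        r2_mean=float(np.mean(r2s)),
        r2_sd=float(np.std(r2s, ddof=1)) if len(r2s) > 1 else 0.0,
        dummy_mae=float(np.mean(dummies)),
        k=k,
        n_iterations=n_iterations,
        edge_counts=[net.n_selected for net in networks],
        seed=seed,
    )
    if collect_predictions and dataset.groups is not None:
        report.per_group = groupwise_eval(all_pred, dataset.z_scores, dataset.groups)
    return report, networks


def permutation_test(
    dataset: Dataset,
    k: int = 5,
    n_perm: int = 1000,
    q: float = 0.01,
    feature_mode: str = "combined",
    svr_params: dict | None = None,
    seed: int = 0,
    observed_mae: float | None = None,
    perm_iterations: int = 1,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for the cross-validated MAE.

    Target scores are shuffled ``n_perm`` times; the full CV procedure
    (standardization, selection, SVR) is repeated per permutation with
    a reshuffled fold plan, yielding a null MAE distribution. The
    p-value uses the add-one convention
    ``p = (1 + #{null <= observed}) / (1 + n_perm)``, small when the
    observed error beats the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seq = np.random.SeedSequence(seed)
    obs_seed, perm_seed = seq.spawn(2)
    if observed_mae is None:
        report, _ = cross_validate(
            dataset, k=k, n_iterations=perm_iterations, q=q,
            feature_mode=feature_mode, svr_params=svr_params,
            seed=obs_seed.generate_state(1)[0],
        )
        observed_mae = report.mae_mean
    rng = np.random.default_rng(perm_seed.generate_state(1)[0])
    null_maes = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = Dataset(
            edges=dataset.edges,
            z_scores=rng.permutation(dataset.z_scores),
            covariates=dataset.covariates,
        )
        rep, _ = cross_validate(
            shuffled, k=k, n_iterations=perm_iterations, q=q,
            feature_mode=feature_mode, svr_params=svr_params,
            seed=rng.integers(2**31),
        )
        null_maes[b] = rep.mae_mean
    p = (1.0 + float(np.sum(null_maes <= observed_mae))) / (1.0 + n_perm)
    return p, null_maes


# ---------------------------------------------------------------------------
# consensus + final model


def consensus_network(networks: Sequence[PredictiveNetwork]) -> PredictiveNetwork:
    """Edges persisting in every fold of every iteration (set intersection)."""
    if not networks:
        raise ValueError("need at least one network to form a consensus")
    pos = frozenset.intersection(*(frozenset(n.pos_edges) for n in networks))
    neg = frozenset.intersection(*(frozenset(n.neg_edges) for n in networks))
    return PredictiveNetwork(pos_edges=pos, neg_edges=neg)


def train_final_model(
    dataset: Dataset,
    scale_params: ScaleParams,
    network: PredictiveNetwork,
    feature_mode: str = "combined",
    svr_params: dict | None = None,
) -> CpmModel:
    """Freeze a CPM on the full training set over a given (consensus) network."""
    std = fit_edge_standardization(dataset.edges)
    z = apply_edge_standardization(dataset.edges, std)
    feats = features_from_strengths(strength_matrix(z, network), feature_mode)
    if network.n_selected == 0 or not np.any(np.ptp(feats, axis=0) > 0):
        raise ValueError("cannot train a final model on an empty/degenerate network")
    regressor = fit_svr(feats, dataset.z_scores, **(svr_params or {}))
    return CpmModel(
        scale_params=scale_params,
        edge_std=std,
        network=network,
        regressor=regressor,
        feature_mode=feature_mode,
    )


def external_validate(
    model: CpmModel,
    consensus: PredictiveNetwork,
    edges: np.ndarray,
    raw_scores: Sequence[float],
    scale: str,
    groups: Sequence | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> ValidationReport:
    """Apply a frozen model + consensus network to an independent cohort.

    Raw scores on a different scale are standardized with the
    range-equivalent of the training scale parameters; edges are
    standardized with the frozen training parameters. The p-value on r
    comes from a percentile bootstrap of subject pairs against r = 0.
    """
    from plvcpm.cpm import SCALE_RANGES

    if scale not in SCALE_RANGES:
        raise ValueError(f"unknown scale {scale!r}")
    params = model.scale_params
    if scale != params.scale:
        params = equivalent_scale_params(params, SCALE_RANGES[scale], scale=scale)
    obs = standardize_scores(np.asarray(raw_scores, dtype=float), params)

    frozen = CpmModel(
        scale_params=model.scale_params,
        edge_std=model.edge_std,
        network=consensus,
        regressor=model.regressor,
        feature_mode=model.feature_mode,
    )
    pred = frozen.predict_z(np.atleast_2d(np.asarray(edges, dtype=float)))
    r, mae, r2 = metrics(pred, obs)

    rng = np.random.default_rng(seed)
    n = obs.shape[0]
    boot_r = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        if np.ptp(obs[idx]) == 0 or np.ptp(pred[idx]) == 0:
            boot_r[b] = 0.0
        else:
            boot_r[b] = np.corrcoef(pred[idx], obs[idx])[0, 1]
    frac_le = (1.0 + np.sum(boot_r <= 0)) / (1.0 + n_boot)
    frac_ge = (1.0 + np.sum(boot_r >= 0)) / (1.0 + n_boot)
    boot_p = float(min(1.0, 2.0 * min(frac_le, frac_ge)))

    report = ValidationReport(
        r_mean=r, r_sd=0.0, mae_mean=mae, mae_sd=0.0, r2_mean=r2, r2_sd=0.0,
        # the dummy predicts the training mean, which is 0 in z units
        dummy_mae=float(np.mean(np.abs(obs))),
        k=0, n_iterations=0, perm_p=boot_p, seed=seed,
    )
    if groups is not None:
        report.per_group = groupwise_eval(pred, obs, np.asarray(groups))
    return report
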