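"""Core connectome-based predictive modelling machinery.

Covers score harmonization across psychometric scales, per-edge
standardization with frozen training parameters, FDR-controlled edge
selection split into positive/negative correlation tails, summed
edge-strength features, and the epsilon-SVR regressor, plus JSON
(de)serialization of the frozen model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests

from plvcpm._edges import n_edges as _n_edges
from plvcpm._edges import vectorize

#: Maximum raw score per supported scale.
SCALE_RANGES: dict[str, float] = {"BDI": 63.0, "HDRS": 52.0}

FEATURE_MODES = ("pos", "neg", "combined", "both")


# ---------------------------------------------------------------------------
# score harmonization


@dataclass(frozen=True)
class ScaleParams:
    """Distribution mean/SD of a score on a named scale, with its range."""

    scale: str
    mean: float
    sd: float
    range_max: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if self.range_max <= 0:
            raise ValueError(f"range_max must be positive, got {self.range_max}")

    @classmethod
    def from_scores(cls, scale: str, raw_scores: Sequence[float]) -> "ScaleParams":
        raw = np.asarray(raw_scores, dtype=float)
        if raw.size < 2:
            raise ValueError("need at least 2 scores to estimate scale parameters")
        sd = float(np.std(raw, ddof=1))
        if sd == 0:
            raise ValueError("scores are constant; scale SD undefined")
        return cls(scale=scale, mean=float(np.mean(raw)), sd=sd, range_max=SCALE_RANGES[scale])


def standardize_scores(raw, params: ScaleParams):
    """Z-transform raw scores: (raw - mean) / sd."""
    return (np.asarray(raw, dtype=float) - params.mean) / params.sd


def unstandardize_scores(z, params: ScaleParams):
    """Inverse of :func:`standardize_scores`."""
    return np.asarray(z, dtype=float) * params.sd + params.mean


def equivalent_scale_params(src: ScaleParams, target_range: float, scale: str | None = None) -> ScaleParams:
    """Rescale mean and SD proportionally to a new scale range (rule of three).

    Mapping a mean/SD fitted on one scale onto another of different
    range multiplies both by ``target_range / src.range_max``, so the
    z-score of the scale minimum (raw = 0) is preserved exactly.
    """
    if target_range <= 0:
        raise ValueError(f"target_range must be positive, got {target_range}")
    ratio = target_range / src.range_max
    return ScaleParams(
        scale=scale if scale is not None else src.scale,
        mean=src.mean * ratio,
        sd=src.sd * ratio,
        range_max=target_range,
    )


# ---------------------------------------------------------------------------
# edge standardization


@dataclass
class EdgeStandardization:
    """Per-edge mean/SD fitted on a training set, reapplied frozen.

    Degenerate edges (zero variance across training subjects) are
    flagged and map to z = 0 at application time.
    """

    means: np.ndarray
    sds: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if not (self.means.shape == self.sds.shape == self.degenerate.shape):
            raise ValueError("means/sds/degenerate must have equal lengths")

    @property
    def n_edges(self) -> int:
        return self.means.shape[0]


def fit_edge_standardization(train_edges: np.ndarray) -> EdgeStandardization:
    """Fit per-edge mean and sample (n-1) SD across training subjects."""
    x = np.asarray(train_edges, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a subjects x edges matrix with >= 2 subjects")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    degenerate = sds == 0
    sds = np.where(degenerate, 1.0, sds)
    return EdgeStandardization(means, sds, degenerate)


def apply_edge_standardization(edges: np.ndarray, std: EdgeStandardization) -> np.ndarray:
    """Z-transform edges with frozen training parameters (degenerate -> 0)."""
    x = np.asarray(edges, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[None, :]
    if x.shape[1] != std.n_edges:
        raise ValueError(
            f"edge dimension {x.shape[1]} does not match fitted standardization "
            f"({std.n_edges} edges)"
        )
    z = (x - std.means) / std.sds
    z[:, std.degenerate] = 0.0
    return z[0] if one_d else z


# ---------------------------------------------------------------------------
# edge selection


@dataclass
class PredictiveNetwork:
    """Disjoint positive-tail and negative-tail edge index sets."""

    pos_edges: frozenset[int] = field(default_factory=frozenset)
    neg_edges: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.pos_edges = frozenset(int(e) for e in self.pos_edges)
        self.neg_edges = frozenset(int(e) for e in self.neg_edges)
        if self.pos_edges & self.neg_edges:
            raise ValueError("positive and negative tails must be disjoint")

    @property
    def n_selected(self) -> int:
        return len(self.pos_edges) + len(self.neg_edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PredictiveNetwork):
            return NotImplemented
        return self.pos_edges == other.pos_edges and self.neg_edges == other.neg_edges


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of y (columns) after OLS on covariates plus intercept."""
    n = y.shape[0]
    design = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def edge_score_correlations(
    z_edges: np.ndarray,
    z_scores: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge Pearson (or partial Pearson) r with scores and two-sided p.

    With covariates, both the edges and the scores are residualized on
    the covariates (plus intercept) and the correlation of residuals is
    tested on n - k - 2 degrees of freedom. Constant edges get r = 0,
    p = 1.
    """
    x = np.asarray(z_edges, dtype=float)
    y = np.asarray(z_scores, dtype=float)
    if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.shape[0]:
        raise ValueError("z_edges must be subjects x edges, z_scores a matching vector")
    n = x.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 subjects for edge selection, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("scores are constant; correlation undefined")

    k = 0
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match number of subjects")
        k = cov.shape[1]
        x = _residualize(x, cov)
        y = _residualize(y[:, None], cov)[:, 0]

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    constant = sx == 0
    denom = np.where(constant, 1.0, sx) * sy
    r = (xc * yc[:, None]).sum(axis=0) / denom
    r = np.clip(np.where(constant, 0.0, r), -1.0, 1.0)

    dof = n - k - 2
    if dof < 1:
        raise ValueError(f"insufficient degrees of freedom ({dof}) for the correlation test")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(constant, 1.0, p)
    return r, p


def select_edges(
    z_edges: np.ndarray,
    z_scores: np.ndarray,
    q: float = 0.01,
    covariates: np.ndarray | None = None,
) -> PredictiveNetwork:
    """Retain edges significantly correlated with scores at p_FDR < q.

    Benjamini-Hochberg FDR is applied across all edges; survivors are
    split by correlation sign into the positive (high) and negative
    (low) tails.
    """
    r, p = edge_score_correlations(z_edges, z_scores, covariates)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    pos = frozenset(np.flatnonzero(reject & (r > 0)).tolist())
    neg = frozenset(np.flatnonzero(reject & (r < 0)).tolist())
    return PredictiveNetwork(pos_edges=pos, neg_edges=neg)


# ---------------------------------------------------------------------------
# strength features


@dataclass(frozen=True)
class StrengthFeatures:
    """Summed z-edge strength over each tail; summed_index = pos - neg."""

    pos_strength: float
    neg_strength: float

    @property
    def summed_index(self) -> float:
        return self.pos_strength - self.neg_strength


def network_strength(z_edge_vector: np.ndarray, network: PredictiveNetwork) -> StrengthFeatures:
    """Sum z-scores over each tail of the predictive network."""
    z = np.asarray(z_edge_vector, dtype=float)
    idx_pos = sorted(network.pos_edges)
    idx_neg = sorted(network.neg_edges)
    if (idx_pos and idx_pos[-1] >= z.shape[-1]) or (idx_neg and idx_neg[-1] >= z.shape[-1]):
        raise ValueError("network edge index out of range for the given edge vector")
    pos = float(z[idx_pos].sum()) if idx_pos else 0.0
    neg = float(z[idx_neg].sum()) if idx_neg else 0.0
    return StrengthFeatures(pos_strength=pos, neg_strength=neg)


def strength_matrix(z_edges: np.ndarray, network: PredictiveNetwork) -> np.ndarray:
    """Subjects x 2 array of (pos_strength, neg_strength)."""
    z = np.atleast_2d(np.asarray(z_edges, dtype=float))
    idx_pos = sorted(network.pos_edges)
    idx_neg = sorted(network.neg_edges)
    pos = z[:, idx_pos].sum(axis=1) if idx_pos else np.zeros(z.shape[0])
    neg = z[:, idx_neg].sum(axis=1) if idx_neg else np.zeros(z.shape[0])
    return np.column_stack([pos, neg])


def features_from_strengths(strengths: np.ndarray, feature_mode: str) -> np.ndarray:
    """Map (pos, neg) strength columns to the regression design per mode."""
    s = np.atleast_2d(np.asarray(strengths, dtype=float))
    if feature_mode == "pos":
        return s[:, [0]]
    if feature_mode == "neg":
        return s[:, [1]]
    if feature_mode == "combined":
        return (s[:, 0] - s[:, 1])[:, None]
    if feature_mode == "both":
        return s
    raise ValueError(f"unknown feature_mode {feature_mode!r}; known: {FEATURE_MODES}")


# ---------------------------------------------------------------------------
# regressor


@dataclass
class FrozenSVR:
    """Serializable epsilon-SVR predictor in dual form.

    Holds the support vectors, dual coefficients and intercept of a
    fitted scikit-learn SVR so the exact predictor can round-trip
    through JSON without pickling.
    """

    kernel: str
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float = 1.0
    coef0: float = 0.0
    degree: int = 3
    C: float = 1.0
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_coef = np.asarray(self.dual_coef, dtype=float).ravel()

    def _kernel_matrix(self, x: np.ndarray) -> np.ndarray:
        sv = self.support_vectors
        if self.kernel == "linear":
            return x @ sv.T
        if self.kernel == "rbf":
            d2 = ((x[:, None, :] - sv[None, :, :]) ** 2).sum(axis=-1)
            return np.exp(-self.gamma * d2)
        if self.kernel == "poly":
            return (self.gamma * (x @ sv.T) + self.coef0) ** self.degree
        raise ValueError(f"unsupported kernel {self.kernel!r}")

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self._kernel_matrix(x) @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "coef0": self.coef0,
            "degree": self.degree,
            "C": self.C,
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrozenSVR":
        return cls(**{**d, "support_vectors": np.array(d["support_vectors"]),
                      "dual_coef": np.array(d["dual_coef"])})


def fit_svr(
    features: np.ndarray,
    targets: np.ndarray,
    kernel: str = "linear",
    C: float = 1.0,
    epsilon: float = 0.1,
    gamma: str | float = "scale",
) -> FrozenSVR:
    """Fit an epsilon-SVR; deterministic given data and hyperparameters."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(targets, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and targets must have matching numbers of subjects")
    if x.shape[0] < 5:
        raise ValueError(f"need >= 5 subjects to fit the SVR, got {x.shape[0]}")
    if np.all(np.ptp(x, axis=0) == 0):
        raise ValueError("degenerate features: all training feature columns are constant")
    svr = SVR(kernel=kernel, C=C, epsilon=epsilon, gamma=gamma)
    svr.fit(x, y)
    return FrozenSVR(
        kernel=kernel,
        support_vectors=svr.support_vectors_,
        dual_coef=svr.dual_coef_,
        intercept=float(svr.intercept_[0]),
        gamma=float(svr._gamma),
        coef0=svr.coef0,
        degree=svr.degree,
        C=C,
        epsilon=epsilon,
    )


# ---------------------------------------------------------------------------
# the assembled model


@dataclass
class CpmModel:
    """Frozen CPM: scale parameters, edge standardization, network, SVR."""

    scale_params: ScaleParams
    edge_std: EdgeStandardization
    network: PredictiveNetwork
    regressor: FrozenSVR
    feature_mode: str = "combined"

    def __post_init__(self) -> None:
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")

    def features(self, z_edges: np.ndarray) -> np.ndarray:
        return features_from_strengths(strength_matrix(z_edges, self.network), self.feature_mode)

    def predict_z(self, edge_matrix: np.ndarray) -> np.ndarray:
        """Predicted standardized scores from raw (unstandardized) edges."""
        z = apply_edge_standardization(np.atleast_2d(edge_matrix), self.edge_std)
        return self.regressor.predict(self.features(z))

    def to_dict(self) -> dict:
        return {
            "scale_params": {
                "scale": self.scale_params.scale,
                "mean": self.scale_params.mean,
                "sd": self.scale_params.sd,
                "range_max": self.scale_params.range_max,
            },
            "edge_std": {
                "means": self.edge_std.means.tolist(),
                "sds": self.edge_std.sds.tolist(),
                "degenerate": self.edge_std.degenerate.astype(int).tolist(),
            },
            "network": {
                "pos_edges": sorted(self.network.pos_edges),
                "neg_edges": sorted(self.network.neg_edges),
            },
            "regressor": self.regressor.to_dict(),
            "feature_mode": self.feature_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CpmModel":
        return cls(
            scale_params=ScaleParams(**d["scale_params"]),
            edge_std=EdgeStandardization(
                means=np.array(d["edge_std"]["means"]),
                sds=np.array(d["edge_std"]["sds"]),
                degenerate=np.array(d["edge_std"]["degenerate"], dtype=bool),
            ),
            network=PredictiveNetwork(
                pos_edges=frozenset(d["network"]["pos_edges"]),
                neg_edges=frozenset(d["network"]["neg_edges"]),
            ),
            regressor=FrozenSVR.from_dict(d["regressor"]),
            feature_mode=d["feature_mode"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "CpmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def predict_scores(model: CpmModel, connectome) -> float:
    """Predicted standardized score for one connectome (matrix or Connectome)."""
    matrix = getattr(connectome, "matrix", connectome)
    m = np.asarray(matrix, dtype=float)
    expected_edges = model.edge_std.n_edges
    if m.ndim == 2 and m.shape[0] == m.shape[1]:
        edges = vectorize(m)
    elif m.ndim == 1:
        edges = m
    else:
        raise ValueError(f"connectome has unexpected shape {m.shape}")
    if edges.shape[0] != expected_edges:
        raise ValueError(
            f"connectome yields {edges.shape[0]} edges, model expects {expected_edges}"
        )
    return float(model.predict_z(edges)[0])


def expected_n_edges(n_regions: int) -> int:
    return _n_edges(n_regions)
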