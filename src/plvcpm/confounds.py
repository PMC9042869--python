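"""Confounding-variable screening and partial correlation.

A candidate confound (continuous or 0/1-coded binary) is correlated
with the target scores and with every edge; it is flagged when the
association with the scores crosses an effect-size OR significance
threshold. Flagged variables are then partialled out of edge selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: A variable is flagged when |r| with the scores reaches this even if
#: non-significant, or when p falls below alpha.
EFFECT_SIZE_FLAG = 0.15


@dataclass
class ConfoundReport:
    variable: str
    r_with_score: float
    p_with_score: float
    n_edges_associated: int
    treated_as_confound: bool
    kind: str = "continuous"

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "r_with_score": self.r_with_score,
            "p_with_score": self.p_with_score,
            "n_edges_associated": self.n_edges_associated,
            "treated_as_confound": self.treated_as_confound,
            "kind": self.kind,
        }


def partial_corr(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (plus intercept)
    by OLS; the Pearson correlation of the residuals is tested on
    n - k - 2 degrees of freedom. With no covariates this reduces
    exactly to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.shape[0]
    k = 0
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match x/y length")
        k = cov.shape[1]
        design = np.column_stack([np.ones(n), cov])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
        beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
        x = x - design @ beta_x
        y = y - design @ beta_y
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    dof = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return r, p


def screen_confound(
    values: np.ndarray,
    z_scores: np.ndarray,
    z_edges: np.ndarray | None = None,
    kind: str = "continuous",
    alpha: float = 0.05,
    effect_size_flag: float = EFFECT_SIZE_FLAG,
    variable: str = "",
) -> ConfoundReport:
    """Screen one candidate variable against scores and edges.

    The point-biserial correlation for binary variables is the Pearson
    correlation on the 0/1 coding, so one code path serves both kinds.
    """
    values = np.asarray(values, dtype=float)
    z_scores = np.asarray(z_scores, dtype=float)
    if values.shape != z_scores.shape:
        raise ValueError("values and z_scores must have equal length")
    if np.ptp(values) == 0:
        raise ValueError(f"candidate confound {variable or 'variable'} is constant")
    if kind not in ("continuous", "binary"):
        raise ValueError(f"unknown kind {kind!r}")
    if kind == "binary" and not set(np.unique(values)) <= {0.0, 1.0}:
        raise ValueError("binary confound must be coded 0/1")

    r_score, p_score = partial_corr(values, z_scores)

    n_edges_assoc = 0
    if z_edges is not None:
        z_edges = np.asarray(z_edges, dtype=float)
        if z_edges.shape[0] != values.shape[0]:
            raise ValueError("z_edges rows must match values length")
        from plvcpm.cpm import edge_score_correlations

        _, p_edges = edge_score_correlations(z_edges, values)
        n_edges_assoc = int(np.sum(p_edges < alpha))

    flagged = abs(r_score) >= effect_size_flag or p_score < alpha
    return ConfoundReport(
        variable=variable,
        r_with_score=r_score,
        p_with_score=p_score,
        n_edges_associated=n_edges_assoc,
        treated_as_confound=bool(flagged),
        kind=kind,
    )
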