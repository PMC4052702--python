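"""Single-response partial least squares (PLS1) via NIPALS, with VIP scores.

The model projects autoscaled expression profiles onto a small number of
latent variables that maximize covariance with the centered disease-status
response. For a single response the NIPALS inner iteration collapses to a
closed-form step per component ``a``::

    w_a = X_a' y_a / ||X_a' y_a||        (unit-norm weight)
    t_a = X_a w_a                        (sample scores)
    p_a = X_a' t_a / (t_a' t_a)          (x-loadings)
    q_a = y_a' t_a / (t_a' t_a)          (y-loading)
    X_{a+1} = X_a - t_a p_a'             (deflation)
    y_{a+1} = y_a - q_a t_a

``SSY_a = q_a^2 (t_a' t_a)`` is the response sum of squares explained by
component ``a``; the sequential-projection structure guarantees
``||y||^2 = sum_a SSY_a + ||y_residual||^2`` exactly.

Variable importance on the projection aggregates squared weights across
components, weighted by explained response variance::

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a )

and satisfies the normalization identity ``sum_j VIP_j^2 = p`` because the
weight columns are unit-norm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleLabels

logger = logging.getLogger(__name__)

__all__ = [
    "Preprocessing",
    "PLSModel",
    "VIPScores",
    "autoscale",
    "nipals_pls",
    "vip",
    "sample_scores",
]

#: early-stop tolerance on ||X'y|| during deflation
DEFAULT_TOL = 1e-12


@dataclass
class Preprocessing:
    """Record of the column scaling applied before model fitting."""

    probe_ids: list[str]          # probes retained in X, in column order
    dropped_probes: list[str]     # zero-variance probes excluded
    mean: np.ndarray              # per retained probe
    scale: np.ndarray | None      # per retained probe sd (None if centered only)
    y_mean: float                 # mean of the 0/1 status coding
    scaled: bool


@dataclass
class PLSModel:
    weights: np.ndarray        # W, p x A, unit-norm columns
    scores: np.ndarray         # T, n x A, mutually orthogonal columns
    x_loadings: np.ndarray     # P, p x A
    y_loadings: np.ndarray     # q, length A
    ssy: np.ndarray            # explained-y sum of squares per component
    preprocessing: Preprocessing
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def probe_ids(self) -> list[str]:
        return self.preprocessing.probe_ids

    def fitted_y(self) -> np.ndarray:
        """Fitted centered response, ``sum_a q_a t_a``."""
        return self.scores @ self.y_loadings


@dataclass
class VIPScores:
    probe_ids: list[str]
    vip: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.vip, index=self.probe_ids, name="vip")


def autoscale(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray, Preprocessing]:
    """Autoscale X (samples x probes) and center the 0/1 response.

    Each retained probe column gets mean 0 and (if ``scale``) unit
    variance (ddof=1). Zero-variance probes cannot be scaled and are
    excluded from X; they are listed in the returned record.
    """
    if matrix.sample_ids != labels.sample_ids:
        raise ValueError("matrix and labels are not aligned; call io.align first")
    X = matrix.values.T.astype(float)  # n x p
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all probes have zero variance; nothing to model")
    dropped = [pid for pid, k in zip(matrix.probe_ids, keep) if not k]
    if dropped:
        logger.info("excluding %d zero-variance probes from PLS", len(dropped))
    kept_ids = [pid for pid, k in zip(matrix.probe_ids, keep) if k]
    Xk = X[:, keep] - mean[keep]
    if scale:
        Xk = Xk / sd[keep]
    y01 = labels.y
    y = y01 - y01.mean()
    prep = Preprocessing(
        probe_ids=kept_ids,
        dropped_probes=dropped,
        mean=mean[keep],
        scale=sd[keep] if scale else None,
        y_mean=float(y01.mean()),
        scaled=scale,
    )
    return Xk, y, prep


def nipals_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    preprocessing: Preprocessing | None = None,
    sample_ids: list[str] | None = None,
    tol: float = DEFAULT_TOL,
) -> PLSModel:
    """Extract ``n_components`` PLS1 latent variables by NIPALS deflation.

    If the covariance ``||X_a' y_a||`` falls below ``tol`` before all
    requested components are extracted (rank exhausted or response fully
    explained), the model stops early with a warning and returns the
    components obtained so far.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]} entries")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )
    Xa = X.copy()
    ya = y.copy()
    W, T, P, q, ssy = [], [], [], [], []
    for a in range(n_components):
        cov = Xa.T @ ya
        norm = np.linalg.norm(cov)
        if norm <= tol:
            warnings.warn(
                f"NIPALS stopped early at component {a + 1}: remaining "
                f"covariance {norm:.2e} below tolerance; returning {a} components",
                stacklevel=2,
            )
            break
        w = cov / norm
        t = Xa @ w
        tt = float(t @ t)
        if tt <= tol:
            warnings.warn(
                f"NIPALS stopped early at component {a + 1}: degenerate scores",
                stacklevel=2,
            )
            break
        pa = Xa.T @ t / tt
        qa = float(ya @ t) / tt
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
        W.append(w)
        T.append(t)
        P.append(pa)
        q.append(qa)
        ssy.append(qa * qa * tt)
    A = len(W)
    if preprocessing is None:
        preprocessing = Preprocessing(
            probe_ids=[f"x{j}" for j in range(p)],
            dropped_probes=[],
            mean=np.zeros(p),
            scale=None,
            y_mean=0.0,
            scaled=False,
        )
    return PLSModel(
        weights=np.column_stack(W) if A else np.empty((p, 0)),
        scores=np.column_stack(T) if A else np.empty((n, 0)),
        x_loadings=np.column_stack(P) if A else np.empty((p, 0)),
        y_loadings=np.asarray(q),
        ssy=np.asarray(ssy),
        preprocessing=preprocessing,
        sample_ids=list(sample_ids) if sample_ids is not None else [],
    )


def vip(model: PLSModel) -> VIPScores:
    """Variable importance on the projection for every retained probe."""
    if model.n_components < 1:
        raise ValueError("model has no components; cannot compute VIP")
    total = float(model.ssy.sum())
    if total <= 0:
        raise ValueError("model explains no response variance; cannot rank probes")
    p = model.weights.shape[0]
    contrib = (model.weights**2) @ model.ssy  # per probe
    scores = np.sqrt(p * contrib / total)
    return VIPScores(probe_ids=model.probe_ids, vip=scores)


def sample_scores(model: PLSModel, labels: SampleLabels | None = None) -> pd.DataFrame:
    """Per-sample latent-variable coordinates (``t_1 .. t_A``).

    A scatter of the first three columns colored by class reproduces the
    sample-classification view of the latent space.
    """
    cols = {f"t_{a + 1}": model.scores[:, a] for a in range(model.n_components)}
    ids = model.sample_ids or [f"s{i}" for i in range(model.scores.shape[0])]
    df = pd.DataFrame(cols, index=pd.Index(ids, name="sample_id"))
    if labels is not None:
        df.insert(0, "class", labels.status.loc[ids].to_numpy())
    return df.reset_index()
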