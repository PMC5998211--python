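"""PLS-DA fitting and VIP (variable importance in projection) scoring.

The class response is encoded 0/1 (case = 1) and centered; components are
extracted sequentially by NIPALS with X-deflation.  VIP through component
``a`` is

    VIP_j = sqrt( p * sum_{k<=a} ss_y[k] * W[j,k]^2 / sum_{k<=a} ss_y[k] )

where ``ss_y[k]`` is the response sum of squares explained by component
``k`` and the weight columns ``W[:,k]`` have unit norm, so the mean square
of VIPs over markers equals 1 at every cumulative depth.  The "global" VIP
of a marker is the maximum of its cumulative VIPs over depths 1..A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ClassDegeneracyError, ConfigurationError
from .table import CASE, FeatureTable, ProcessedTable

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class PLSModel:
    """Fitted PLS-DA decomposition.

    Attributes
    ----------
    weights : ndarray, (p, A)
        Unit-norm weight vectors, one column per component.
    scores : ndarray, (n, A)
        X-scores; column ``a`` is the deflated X projected on ``weights[:, a]``.
    x_loadings : ndarray, (p, A)
    y_loadings : ndarray, (A,)
    ss_y : ndarray, (A,)
        Response sum of squares explained by each component (nonnegative).
    """

    weights: np.ndarray
    scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    ss_y: np.ndarray
    marker_names: list[str]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


@dataclass
class VipReport:
    """Per-marker cumulative VIPs (one column per depth) and global VIP."""

    marker_names: list[str]
    cumulative: np.ndarray  # (p, A); column a-1 = VIP through component a
    global_vip: np.ndarray  # (p,)

    def to_frame(self) -> pd.DataFrame:
        """Table sorted by global VIP descending (ties by marker name)."""
        data = {"marker": self.marker_names}
        for a in range(self.cumulative.shape[1]):
            data[f"comp{a + 1}"] = self.cumulative[:, a]
        data["global"] = self.global_vip
        df = pd.DataFrame(data)
        return df.sort_values(
            ["global", "marker"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)


def encode_response(groups: np.ndarray) -> np.ndarray:
    """Centered 0/1 response, case = 1."""
    y = (np.asarray(groups, dtype=object) == CASE).astype(float)
    if y.all() or not y.any():
        raise ClassDegeneracyError("PLS-DA requires both classes")
    return y - y.mean()


def fit_plsda(
    table: FeatureTable | ProcessedTable, n_components: int = 3
) -> PLSModel:
    """Fit a two-class PLS-DA model by sequential NIPALS extraction.

    Deterministic for fixed input: each component is initialized from the
    response vector.  If the deflated X becomes (numerically) orthogonal to
    the response before ``n_components`` components are extracted, the model
    is returned with fewer components and a warning is issued.
    """
    X = np.asarray(table.intensities, dtype=float)
    y = encode_response(table.groups)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ConfigurationError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], "
            f"got {n_components}"
        )

    Xa = X.copy()
    ss_total = float(y @ y)
    W, T, P, Q, SS = [], [], [], [], []
    for _ in range(n_components):
        w, t, q = _nipals_component(Xa, y)
        if w is None:
            warnings.warn(
                f"deflated X orthogonal to response; returning {len(W)} of "
                f"{n_components} requested components",
                stacklevel=2,
            )
            break
        tt = float(t @ t)
        p_load = Xa.T @ t / tt
        Xa = Xa - np.outer(t, p_load)
        W.append(w)
        T.append(t)
        P.append(p_load)
        Q.append(q)
        SS.append(q * q * tt)
    if not W:
        raise ClassDegeneracyError("response orthogonal to X; nothing to fit")
    return PLSModel(
        weights=np.column_stack(W),
        scores=np.column_stack(T),
        x_loadings=np.column_stack(P),
        y_loadings=np.asarray(Q),
        ss_y=np.asarray(SS),
        marker_names=list(table.markers),
    )


def _nipals_component(X: np.ndarray, y: np.ndarray):
    """One NIPALS round against a single centered response column.

    With a univariate response the inner loop converges after one pass;
    the loop is retained with the documented tolerance for fidelity to the
    sequential algorithm.
    """
    u = y.astype(float)
    w_old = None
    for _ in range(_NIPALS_MAX_ITER):
        xu = X.T @ u
        norm = np.linalg.norm(xu)
        if norm < 1e-12 * max(1.0, np.abs(X).max(initial=0.0)):
            return None, None, None
        w = xu / norm
        t = X @ w
        tt = float(t @ t)
        if tt == 0:
            return None, None, None
        q = float(y @ t) / tt
        if q == 0:
            return None, None, None
        u = y * q  # single-column Y: u stays proportional to y
        if w_old is not None and np.linalg.norm(w - w_old) < _NIPALS_TOL:
            break
        w_old = w
    return w, t, q


def vip_scores(model: PLSModel, through_component: int) -> np.ndarray:
    """Cumulative VIP per marker through the given component depth."""
    a = through_component
    if not 1 <= a <= model.n_components:
        raise ConfigurationError(
            f"through_component must be in [1, {model.n_components}], got {a}"
        )
    p = model.weights.shape[0]
    ss = model.ss_y[:a]
    w2 = model.weights[:, :a] ** 2
    return np.sqrt(p * (w2 @ ss) / ss.sum())


def global_vip(model: PLSModel) -> np.ndarray:
    """Per-marker maximum of the cumulative VIPs over depths 1..A."""
    cum = np.column_stack([vip_scores(model, a) for a in range(1, model.n_components + 1)])
    return cum.max(axis=1)


def vip_report(model: PLSModel) -> VipReport:
    cum = np.column_stack([vip_scores(model, a) for a in range(1, model.n_components + 1)])
    return VipReport(
        marker_names=list(model.marker_names),
        cumulative=cum,
        global_vip=cum.max(axis=1),
    )


def select_by_vip(report: VipReport, threshold: float = 2.0) -> list[str]:
    """Markers with global VIP >= threshold, sorted by global VIP descending
    (ties broken lexicographically by name)."""
    if threshold < 0:
        raise ConfigurationError(f"threshold must be >= 0, got {threshold}")
    keep = [
        (name, g)
        for name, g in zip(report.marker_names, report.global_vip)
        if g >= threshold
    ]
    keep.sort(key=lambda item: (-item[1], item[0]))
    return [name for name, _ in keep]
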