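"""Ridge-regression BLUP (RR-BLUP) for genomic prediction.

Model: y = mu 1 + X a + e with all marker effects a drawn from a common
normal distribution.  The effects solve Henderson's mixed-model equations

    [[1'1, 1'X ], [X'1, X'X + lambda I]] [mu, a]' = [1'y, X'y]'

with penalty lambda = sigma2_e / sigma2_a.  Under the common-variance
assumption sigma2_a = sigma2_g / m, which gives

    lambda = m (1 - h2) / h2

from the number of markers m and the heritability h2 of the estimation set.
Predicted genotypic values are g-hat = mu-hat + X_new a-hat.

Implementation notes: marker columns are centered before solving, which
makes the intercept orthogonal to the markers; because only the intercept
is unpenalized, the marker-effect solutions (and therefore all predictions)
are identical to those of the raw uncentered equations.  The solver uses
the m-dimensional normal equations when m is moderate and the equivalent
N-dimensional kernel system otherwise; both paths agree to solver
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla


def lambda_from_h2(m: int, h2: float) -> float:
    """RR-BLUP penalty lambda = m (1 - h2) / h2."""
    if m < 1:
        raise ValueError("need at least one marker")
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie strictly between 0 and 1")
    return m * (1.0 - h2) / h2


@dataclass
class RRBLUPResults:
    """Fitted RR-BLUP model: overall mean, marker effects and the centering
    constants required to reproduce predictions."""

    mu: float
    effects: pd.Series          # indexed by marker id
    lam: float
    col_means: np.ndarray
    marker_ids: np.ndarray

    @property
    def a_hat(self) -> np.ndarray:
        return self.effects.to_numpy()

    def predict(self, X_new) -> np.ndarray | pd.Series:
        """Predicted genotypic values mu + (X_new - centering) a-hat."""
        index = None
        if isinstance(X_new, pd.DataFrame):
            unknown = [c for c in X_new.columns if c not in set(self.marker_ids)]
            if unknown:
                raise KeyError(f"unknown markers: {unknown[:10]}")
            missing = [c for c in self.marker_ids if c not in set(X_new.columns)]
            if missing:
                raise KeyError(f"markers absent from X_new: {missing[:10]}")
            index = X_new.index
            X_new = X_new[list(self.marker_ids)].to_numpy(dtype=float)
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != len(self.marker_ids):
            raise ValueError("marker dimension mismatch")
        g = self.mu + (X_new - self.col_means) @ self.a_hat
        return pd.Series(g, index=index) if index is not None else g


class RRBLUP:
    """RR-BLUP model: BLUE vector ``y`` (length N) against marker dosages
    ``X`` (N x m) with a fixed penalty ``lam``."""

    def __init__(self, y, X, lam: float):
        if isinstance(y, pd.Series):
            y = y.to_numpy()
        self.y = np.asarray(y, dtype=float).ravel()
        if isinstance(X, pd.DataFrame):
            self.marker_ids = X.columns.to_numpy()
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.marker_ids = np.array([f"m{j}" for j in range(X.shape[1])])
        self.X = X
        if self.X.shape[0] != len(self.y):
            raise ValueError("y and X have different numbers of lines")
        if len(self.y) < 2:
            raise ValueError("need at least 2 lines")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise ValueError("missing values in y or X; impute first")
        if lam <= 0:
            raise ValueError("lambda must be > 0")
        self.lam = float(lam)

    def fit(self) -> RRBLUPResults:
        y, X, lam = self.y, self.X, self.lam
        n, m = X.shape
        col_means = X.mean(axis=0)
        Xc = X - col_means
        yc = y - y.mean()
        if m <= 4 * n:
            # m-dimensional normal equations (SPD)
            G = Xc.T @ Xc + lam * np.eye(m)
            a = sla.cho_solve(sla.cho_factor(G, lower=True), Xc.T @ yc)
        else:
            # equivalent N-dimensional kernel system
            K = Xc @ Xc.T + lam * np.eye(n)
            a = Xc.T @ sla.cho_solve(sla.cho_factor(K, lower=True), yc)
        return RRBLUPResults(
            mu=float(y.mean()), effects=pd.Series(a, index=self.marker_ids),
            lam=lam, col_means=col_means, marker_ids=self.marker_ids)
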