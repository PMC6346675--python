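"""Geographic distances and matrix regression for isolation-by-distance.

Haversine great-circle distances between hunt-unit midpoints feed a
multiple regression on distance matrices (MRM): ordinary least squares on
the lower-triangle vectorizations, with significance assessed by jointly
permuting the rows and columns of the response matrix (Mantel-style).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .popstats import PairwiseMatrix

__all__ = ["EARTH_RADIUS_KM", "MRMResult", "MatrixRegression", "haversine_km",
           "haversine_matrix", "mrm"]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km on a sphere of radius 6,371 km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((lat2 - lat1) / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2)
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def haversine_matrix(herds: pd.DataFrame) -> PairwiseMatrix:
    """Pairwise haversine distances between unit midpoints (km).

    ``herds`` must carry ``unit, lat, lon`` columns; a missing midpoint is an
    error naming the unit.
    """
    bad = herds.loc[herds["lat"].isna() | herds["lon"].isna(), "unit"]
    if len(bad):
        raise ValueError("missing midpoint for unit(s): " + ", ".join(map(str, bad)))
    units = list(herds["unit"])
    lat = np.radians(herds["lat"].to_numpy(float))
    lon = np.radians(herds["lon"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2.0) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(units, d, kind="km")


@dataclasses.dataclass
class MRMResult:
    coefficients: np.ndarray   # intercept first, then one per predictor
    r_squared: float
    p_overall: float           # permutation p for the model R^2
    p_coefficients: np.ndarray # one-tailed permutation p per slope
    n_permutations: int
    seed: int


def _tril(mat: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


class MatrixRegression(BaseEstimator):
    """Multiple regression on distance matrices (MRM), permutation-tested.

    OLS is run on the lower-triangle vectorizations (diagonal excluded) of
    the response and predictor matrices.  Significance comes from jointly
    permuting the rows and columns of the response matrix ``n_permutations``
    times; p-values use the add-one rule
    p = (#{permuted statistic >= observed} + 1) / (n_permutations + 1).
    The overall test statistic is R²; per-coefficient tests are one-tailed
    on the slope (positive association, the isolation-by-distance
    direction).

    Attributes (after ``fit``): ``coef_`` (intercept first), ``r_squared_``,
    ``p_overall_``, ``p_coef_``, ``result_``.
    """

    def __init__(self, n_permutations=999, seed=0):
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, response: PairwiseMatrix, predictors):
        if isinstance(predictors, PairwiseMatrix):
            predictors = [predictors]
        if self.n_permutations < 99:
            raise ValueError("use at least 99 permutations")
        units = response.units
        for p in predictors:
            if list(p.units) != list(units):
                raise ValueError("response and predictor matrices must share units")
        n = len(units)
        y = _tril(response.values)
        X = np.column_stack([np.ones(y.size)] + [_tril(p.values) for p in predictors])
        for c in range(1, X.shape[1]):
            if np.ptp(X[:, c]) == 0:
                raise ValueError(f"predictor {c} is constant")

        XtX_inv = np.linalg.pinv(X.T @ X)
        hat = XtX_inv @ X.T

        def stats(yv):
            beta = hat @ yv
            resid = yv - X @ beta
            ss_tot = ((yv - yv.mean()) ** 2).sum()
            r2 = 1.0 - (resid @ resid) / ss_tot if ss_tot > 0 else 0.0
            return beta, r2

        beta_obs, r2_obs = stats(y)
        rng = np.random.default_rng(self.seed)
        exceed_r2 = 0
        exceed_beta = np.zeros(len(predictors), dtype=int)
        for _ in range(self.n_permutations):
            perm = rng.permutation(n)
            yp = _tril(response.values[np.ix_(perm, perm)])
            beta_p, r2_p = stats(yp)
            if r2_p >= r2_obs:
                exceed_r2 += 1
            exceed_beta += beta_p[1:] >= beta_obs[1:]

        m = self.n_permutations
        self.coef_ = beta_obs
        self.r_squared_ = float(r2_obs)
        self.p_overall_ = (exceed_r2 + 1) / (m + 1)
        self.p_coef_ = (exceed_beta + 1) / (m + 1)
        self.result_ = MRMResult(beta_obs, self.r_squared_, self.p_overall_,
                                 self.p_coef_, m, self.seed)
        return self


def mrm(response: PairwiseMatrix, predictors, n_perm: int = 999, seed: int = 0) -> MRMResult:
    """Functional wrapper over :class:`MatrixRegression`."""
    return MatrixRegression(n_permutations=n_perm, seed=seed).fit(response, predictors).result_
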