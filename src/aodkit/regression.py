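"""Scikit-learn-style estimators for VO2-power and VO2-frequency relations.

The linear power -> O2-demand relation Y = a + b*P is the workhorse of
accumulated-O2-deficit estimation: it is fitted on submaximal steady-state
measurements and extrapolated to supramaximal powers.  :class:`LinearDemand`
fits it by closed-form least squares, optionally with a forced intercept
(gross-efficiency, net-efficiency and common-intercept methods all reduce to
the forced-intercept case).  :class:`FrequencyPolynomial` fits the cubic (or
quadratic) dependence of loadless-pedaling VO2, and of the relation intercept,
on pedaling frequency.

Both estimators follow the sklearn contract (get_params/set_params, fitted
attributes with trailing underscores, ``fit`` returning self) and compose with
sklearn model-selection utilities.  X is the (n, 1) column of powers in W
(frequencies in Hz for the polynomial); y is VO2 in mmol s^-1.  The fitted
slope is exposed in umol J^-1, the field's customary unit.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import NonPhysicalPowerError, SingularDesignError


class LinearDemand(RegressorMixin, BaseEstimator):
    """Linear VO2-power relation Y = a + b*P by (possibly constrained) OLS.

    Parameters
    ----------
    fixed_intercept : float or None, default None
        If None, both intercept and slope are free (ordinary least squares,
        closed form).  If a value a0 (mmol s^-1) is given, the intercept is
        forced and the slope minimises ``sum((y - a0 - b*P)**2)``, i.e.
        ``b = sum(P*(y - a0)) / sum(P**2)``.

    Attributes
    ----------
    intercept_ : float
        Fitted intercept a, mmol s^-1.
    slope_ : float
        Fitted slope b, umol J^-1 (1000 x the slope in mmol s^-1 W^-1).
    n_points_ : int
        Number of points used.

    Examples
    --------
    >>> est = LinearDemand().fit([[100.], [200.]], [1.0, 2.0])
    >>> est.intercept_, est.slope_
    (0.0, 10.0)
    """

    def __init__(self, fixed_intercept: float | None = None):
        self.fixed_intercept = fixed_intercept

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=1, y_numeric=True)
        if X.shape[1] != 1:
            raise ValueError("X must be a single column of powers in W")
        P = X[:, 0].astype(float)
        y = np.asarray(y, dtype=float)

        if self.fixed_intercept is None:
            if np.unique(P).size < 2:
                raise SingularDesignError(
                    "free-intercept fit needs >= 2 distinct power values")
            Pm, ym = P.mean(), y.mean()
            sxx = float(np.sum((P - Pm) ** 2))
            sxy = float(np.sum((P - Pm) * (y - ym)))
            b = sxy / sxx
            a = ym - b * Pm
        else:
            spp = float(np.sum(P ** 2))
            if spp == 0.0:
                raise SingularDesignError(
                    "forced-intercept fit needs at least one non-zero power")
            a = float(self.fixed_intercept)
            b = float(np.sum(P * (y - a))) / spp

        self.intercept_ = float(a)
        self.slope_ = float(b * 1000.0)       # umol J^-1
        self.n_points_ = int(P.size)
        return self

    def predict(self, X):
        """O2 demand (mmol s^-1) at powers X (W)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.intercept_ + self.slope_ * X[:, 0] / 1000.0

    def demand_at_power(self, power: float) -> float:
        """Scalar convenience: demand a + b*P/1000 at one power in W."""
        check_is_fitted(self)
        if power < 0:
            raise ValueError(f"power must be >= 0, got {power}")
        return self.intercept_ + self.slope_ * power / 1000.0

    def invert(self, demand: float) -> float:
        """Power (W) eliciting a given O2 demand: P = (Y - a)/b * 1000."""
        check_is_fitted(self)
        if self.slope_ <= 0:
            raise SingularDesignError("cannot invert a non-positive slope")
        if demand < self.intercept_:
            raise NonPhysicalPowerError(
                f"demand {demand} below intercept {self.intercept_} "
                "maps to a negative power")
        return (demand - self.intercept_) / self.slope_ * 1000.0


class FrequencyPolynomial(RegressorMixin, BaseEstimator):
    """Polynomial VO2 vs pedaling frequency, degree 2 or 3.

    Loadless-pedaling VO2 and the intercepts of the power relation both grow
    steeply with pedaling frequency, compatible with a cubic (a quadratic
    fits nearly as well).  Coefficients are stored ascending (c0 + c1*f +
    c2*f**2 [+ c3*f**3]).
    """

    def __init__(self, degree: int = 3):
        self.degree = degree

    def fit(self, X, y):
        if self.degree not in (2, 3):
            raise ValueError("degree must be 2 or 3")
        X, y = validate_data(self, X, y, y_numeric=True)
        f = X[:, 0].astype(float)
        y = np.asarray(y, dtype=float)
        if np.unique(f).size < self.degree + 1:
            raise SingularDesignError(
                f"degree-{self.degree} fit needs >= {self.degree + 1} "
                "distinct frequencies")
        V = np.vander(f, self.degree + 1, increasing=True)
        coef, _, _, _ = np.linalg.lstsq(V, y, rcond=None)
        self.coef_ = coef
        self.domain_ = (float(f.min()), float(f.max()))
        resid = y - V @ coef
        sst = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 1.0
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        f = X[:, 0].astype(float)
        return np.vander(f, self.degree + 1, increasing=True) @ self.coef_
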