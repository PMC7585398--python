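"""Statistical progression criteria for the ΔG event analysis.

Two rule families are implemented, both as scikit-learn style estimators
so they compose with sklearn tooling:

* :class:`FixedCutoff` — flag progression when ΔG ≤ −c for a fixed loss
  c in µm (c = 5 is the clinical "rule of 5"; c ∈ {3,…,8} is the usual
  sweep).
* :class:`QuantileRegressionCutoff` — an event cutoff learnt from
  short-interval test-retest pairs: quantile regression of follow-up G
  on baseline G at a lower-tail level τ (default 0.05, i.e. the 95th
  percentile of loss). The cutoff is the signed distance from the fitted
  conditional-quantile line to the identity line,
  ``cutoff(G_b) = (intercept + slope·G_b) − G_b``, so it can shrink or
  grow with baseline thickness when test-retest variability does.

Both flags are inclusive at the boundary (ΔG equal to the cutoff flags).
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_is_fitted
from statsmodels.regression.quantile_regression import QuantReg
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .errors import ParameterError
from .profiles import VisitPair

MIN_QR_PAIRS = 20


def _as_pairs(X, y=None):
    """Accept (n,2) [g_baseline, g_followup] arrays or separate x, y."""
    X = np.asarray(X, dtype=float)
    if y is not None:
        return X.ravel(), np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != 2:
        raise ParameterError("expected an (n, 2) array of (g_baseline, g_followup)")
    return X[:, 0], X[:, 1]


class FixedCutoff(BaseEstimator):
    """Progression rule: flag iff ΔG ≤ −c.

    Parameters
    ----------
    c : float
        Loss magnitude in µm that triggers the flag; must be > 0.
    """

    def __init__(self, c: float = 5.0):
        self.c = c

    @property
    def label(self) -> str:
        return f"fixed:{self.c:g}"

    def fit(self, X=None, y=None):
        if not self.c > 0:
            raise ParameterError("fixed cutoff c must be > 0")
        self.c_ = float(self.c)
        return self

    def flag(self, delta_g: float, g_baseline: float = None) -> bool:
        if not np.isfinite(delta_g):
            raise ParameterError("delta_g must be finite")
        if not self.c > 0:
            raise ParameterError("fixed cutoff c must be > 0")
        return bool(delta_g <= -self.c)

    def predict(self, X) -> np.ndarray:
        """Flags for an (n,) array of ΔG or an (n,2) array of G pairs."""
        X = np.asarray(X, dtype=float)
        dg = X[:, 1] - X[:, 0] if X.ndim == 2 else X
        if not self.c > 0:
            raise ParameterError("fixed cutoff c must be > 0")
        return dg <= -self.c


class QuantileRegressionCutoff(BaseEstimator):
    """Event cutoff from quantile regression of follow-up G on baseline G.

    Parameters
    ----------
    tau : float
        Lower-tail quantile level in (0, 1); 0.05 corresponds to the
        95th percentile of loss.

    Attributes
    ----------
    intercept_, slope_ : float
        Coefficients of the fitted conditional-quantile line
        ``q_tau(G_f | G_b) = intercept_ + slope_ · G_b``.
    n_pairs_ : int
        Number of test-retest pairs the model was fitted on.
    """

    def __init__(self, tau: float = 0.05):
        self.tau = tau

    @property
    def label(self) -> str:
        return f"qr:{self.tau:g}"

    def fit(self, X, y=None):
        """Fit on test-retest pairs: X = (n,2) [G_b, G_f] or X = G_b with y = G_f."""
        if not 0 < self.tau < 1:
            raise ParameterError("tau must lie in (0, 1)")
        x, yy = _as_pairs(X, y)
        if x.size < MIN_QR_PAIRS:
            raise ParameterError(f"need >= {MIN_QR_PAIRS} test-retest pairs, got {x.size}")
        if np.ptp(x) == 0:
            raise ParameterError("degenerate design: all baseline G values are equal")
        exog = np.column_stack([np.ones_like(x), x])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IterationLimitWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            result = QuantReg(yy, exog).fit(q=self.tau, max_iter=5000)
        self.intercept_ = float(result.params[0])
        self.slope_ = float(result.params[1])
        self.n_pairs_ = int(x.size)
        return self

    def cutoff(self, g_baseline) -> np.ndarray:
        """Signed ΔG cutoff (µm) at the given baseline G."""
        check_is_fitted(self, "slope_")
        g_baseline = np.asarray(g_baseline, dtype=float)
        return self.intercept_ + self.slope_ * g_baseline - g_baseline

    def flag(self, delta_g: float, g_baseline: float) -> bool:
        if g_baseline is None:
            raise ParameterError("quantile-regression criterion requires baseline G")
        return bool(delta_g <= float(self.cutoff(g_baseline)))

    def predict(self, X) -> np.ndarray:
        """Flags for an (n,2) array of (g_baseline, g_followup)."""
        x, yy = _as_pairs(X)
        return (yy - x) <= self.cutoff(x)

    def to_json(self) -> str:
        check_is_fitted(self, "slope_")
        return json.dumps({"tau": self.tau, "intercept": self.intercept_,
                           "slope": self.slope_})

    @classmethod
    def from_json(cls, text: str) -> "QuantileRegressionCutoff":
        payload = json.loads(text)
        model = cls(tau=payload["tau"])
        model.intercept_ = float(payload["intercept"])
        model.slope_ = float(payload["slope"])
        model.n_pairs_ = int(payload.get("n_pairs", MIN_QR_PAIRS))
        return model


# --------------------------------------------------------------------------
# functional wrappers


def flag_fixed(delta_g: float, cutoff) -> bool:
    """True iff ΔG ≤ −c (inclusive). ``cutoff`` may be a float or FixedCutoff."""
    model = cutoff if isinstance(cutoff, FixedCutoff) else FixedCutoff(float(cutoff))
    return model.flag(delta_g)


def fit_qr(pairs, tau: float = 0.05) -> QuantileRegressionCutoff:
    """Fit the QR cutoff on (g_baseline, g_followup) tuples or VisitPairs."""
    if len(pairs) and isinstance(pairs[0], VisitPair):
        data = np.array([(p.g_baseline, p.g_followup) for p in pairs])
    else:
        data = np.asarray(pairs, dtype=float)
    return QuantileRegressionCutoff(tau=tau).fit(data)


def flag_qr(pair, model: QuantileRegressionCutoff) -> bool:
    """Apply a fitted QR cutoff to a VisitPair."""
    try:
        check_is_fitted(model, "slope_")
    except NotFittedError as exc:
        raise NotFittedError("quantile-regression cutoff must be fitted first") from exc
    return model.flag(pair.delta_g, pair.g_baseline)
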