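"""Per-intensity regression of clipping error on PMT offset and gain.

The censoring estimators require every single scan, which standard
acquisition does not save.  The regression system fills that gap: on a
learning sample of stacks acquired at many (gain, offset) combinations it
computes the total per-intensity error E_k = U_k + L_k and fits, for each
grayscale level k, an ordinary least-squares model

    E_k = beta0_k + beta_offset_k * offset_units
               + beta_gain_k * exp(gain_V_std / g0),

where ``offset_units`` and ``gain_V_std`` are the *standardized* PMT
parameters (signal depends linearly on offset and exponentially on gain).
The fitted system predicts pixel errors for any new averaged image from
its scanning protocol alone.

The estimator is scikit-learn compatible (``get_params``/``set_params``,
fitted attributes with trailing underscores); module-level helpers build
the design from scan stacks and run the grouped leave-one-out test in
which all images sharing one (gain, offset) setting are held out
together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .calibration import CalibrationRecord, IDENTITY_CALIBRATION, standardize
from .censored import error_profile
from .exceptions import CrossValidationError, InsufficientDataError
from .simulate import ScanStack

__all__ = [
    "TrainingRecord",
    "PerIntensityErrorRegression",
    "build_training_records",
    "fit_error_model",
    "predict_pixel_error",
    "loo_cv",
    "LooResult",
]


@dataclass
class TrainingRecord:
    """One learning image: standardized parameters plus per-level errors.

    ``E``, ``U``, ``L`` are length-(c_a+1) arrays with NaN at levels not
    present in the image.  ``group`` keys records acquired at identical
    nominal PMT settings, which must be held out together in
    cross-validation.
    """

    image_id: str
    offset_units: float
    gain_V_std: float
    E: np.ndarray
    U: np.ndarray | None = None
    L: np.ndarray | None = None
    group: tuple = field(default=())

    def __post_init__(self) -> None:
        if not self.group:
            self.group = (round(self.gain_V_std, 3), round(self.offset_units, 3))


class PerIntensityErrorRegression(BaseEstimator, RegressorMixin):
    """Independent OLS fits of E_k on (1, offset_units, exp(gain/g0)).

    Parameters
    ----------
    g0 : float
        Gain e-folding scale in volts for the exponential regressor.
    n_min : int
        Minimum number of observations for a level to be fitted.
    ceiling : int
        Reliability ceiling: levels above it are never fitted (the
        topmost intensities are too strongly clipped to estimate).
    c_a : int
        Upper grayscale threshold; levels run over [0..c_a].

    Attributes (after ``fit``)
    --------------------------
    coef_ : (c_a+1, 3) array, rows [beta0, beta_offset, beta_gain]
    coef_se_ : (c_a+1, 3) standard errors of the coefficients
    r2_ : (c_a+1,) coefficient of determination per level
    n_obs_ : (c_a+1,) observations used per level
    dof_ : (c_a+1,) residual degrees of freedom per level
    sign_ : (c_a+1,) +1 where the upper error dominates on the training
        set (correction raises the intensity), -1 where the lower error
        dominates (correction lowers it)
    fitted_levels_ : boolean mask of fitted levels
    unfitted_reason_ : dict level -> reason for skipped levels
    """

    def __init__(self, g0: float = 100.0, n_min: int = 5, ceiling: int = 250,
                 c_a: int = 255):
        self.g0 = g0
        self.n_min = n_min
        self.ceiling = ceiling
        self.c_a = c_a

    # -- design helpers -----------------------------------------------------
    def _gain_regressor(self, gain_V_std):
        return np.exp(np.asarray(gain_V_std, dtype=float) / self.g0)

    def _design(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(
                "X must be (n_images, 2): columns [offset_units, gain_V_std]"
            )
        return np.column_stack(
            [np.ones(len(X)), X[:, 0], self._gain_regressor(X[:, 1])]
        )

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y, U=None, L=None):
        """Fit one OLS model per intensity level.

        ``X`` is (n_images, 2) with columns [offset_units, gain_V_std];
        ``y`` is (n_images, c_a+1) of per-level total errors with NaN
        where a level is absent from an image.  ``U``/``L`` (same shape)
        are optional upper/lower components used to set the dominance
        sign; without them the sign defaults to +1 above the grayscale
        midpoint and -1 below.
        """
        A = self._design(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[0] != A.shape[0]:
            raise ValueError("y must be (n_images, c_a+1)")
        n_levels = self.c_a + 1
        if y.shape[1] != n_levels:
            raise ValueError(f"y must have {n_levels} columns")

        self.coef_ = np.full((n_levels, 3), np.nan)
        self.coef_se_ = np.full((n_levels, 3), np.nan)
        self.r2_ = np.full(n_levels, np.nan)
        self.n_obs_ = np.zeros(n_levels, dtype=int)
        self.dof_ = np.zeros(n_levels, dtype=int)
        self.fitted_levels_ = np.zeros(n_levels, dtype=bool)
        self.unfitted_reason_ = {}

        n_required = max(self.n_min, 4)
        for k in range(n_levels):
            rows = np.isfinite(y[:, k])
            self.n_obs_[k] = int(rows.sum())
            if k > self.ceiling:
                self.unfitted_reason_[k] = "above_ceiling"
                continue
            if self.n_obs_[k] < n_required:
                self.unfitted_reason_[k] = "too_few_observations"
                continue
            Ak, yk = A[rows], y[rows, k]
            beta, _, rank, _ = np.linalg.lstsq(Ak, yk, rcond=None)
            if rank < 3:
                self.unfitted_reason_[k] = "rank_deficient_design"
                continue
            resid = yk - Ak @ beta
            ss_res = float(resid @ resid)
            ss_tot = float(np.sum((yk - yk.mean()) ** 2))
            dof = len(yk) - 3
            self.coef_[k] = beta
            self.dof_[k] = dof
            self.r2_[k] = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
            if dof > 0:
                s2 = ss_res / dof
                cov = s2 * np.linalg.inv(Ak.T @ Ak)
                self.coef_se_[k] = np.sqrt(np.diag(cov))
            self.fitted_levels_[k] = True

        self.sign_ = np.where(np.arange(n_levels) >= n_levels // 2, 1, -1)
        if U is not None and L is not None:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                mean_u = np.nanmean(np.asarray(U, float), axis=0)
                mean_l = np.nanmean(np.asarray(L, float), axis=0)
            known = np.isfinite(mean_u) & np.isfinite(mean_l)
            self.sign_[known] = np.where(mean_u[known] >= mean_l[known], 1, -1)
        return self

    def coefficient_ci(self, level: int, confidence: float = 0.99):
        """Two-sided confidence intervals for one level's coefficients."""
        check_is_fitted(self, "coef_")
        if not self.fitted_levels_[level] or self.dof_[level] <= 0:
            raise InsufficientDataError(f"level {level} not fitted with dof > 0")
        t = stats.t.ppf(0.5 + confidence / 2.0, self.dof_[level])
        half = t * self.coef_se_[level]
        return np.column_stack([self.coef_[level] - half, self.coef_[level] + half])

    # -- prediction ---------------------------------------------------------
    def predict(self, X):
        """Predicted error for every level, per row of ``X``.

        Returns an (n_images, c_a+1) array: the regression value clamped
        at 0 on fitted levels, linear interpolation across k between
        fitted levels elsewhere (constant extension beyond the outermost
        fitted levels).  All-NaN rows only occur for an unfitted model.
        """
        check_is_fitted(self, "coef_")
        A = self._design(X)
        n_levels = self.c_a + 1
        raw = A @ np.where(np.isfinite(self.coef_), self.coef_, 0.0).T
        raw = np.maximum(raw, 0.0)
        out = np.full((A.shape[0], n_levels), np.nan)
        fitted = np.flatnonzero(self.fitted_levels_)
        if fitted.size == 0:
            return out
        ks = np.arange(n_levels)
        for i in range(A.shape[0]):
            out[i] = np.interp(ks, fitted, raw[i, fitted])
        return out

    def predict_level(self, offset_units: float, gain_V_std: float, k: int) -> float:
        """Predicted error at a single intensity level."""
        return float(self.predict([[offset_units, gain_V_std]])[0, int(k)])


# ---------------------------------------------------------------------------
# module-level wrappers over the estimator
# ---------------------------------------------------------------------------

def build_training_records(
    stacks: list[ScanStack],
    calibrations: dict[str, CalibrationRecord] | CalibrationRecord | None = None,
    ceiling: int = 250,
) -> list[TrainingRecord]:
    """Censoring-estimate every stack and standardize its parameters.

    ``calibrations`` maps microscope ids to calibration records (or is a
    single record applied to all stacks; identity if omitted).  Each
    stack's error profile supplies the per-level dependent variable; the
    group key is the stack's nominal (gain, offset) pair so that repeat
    acquisitions at one setting stay together in cross-validation.
    """
    records = []
    for i, stack in enumerate(stacks):
        if calibrations is None:
            record = IDENTITY_CALIBRATION
        elif isinstance(calibrations, CalibrationRecord):
            record = calibrations
        else:
            record = calibrations[stack.microscope_id]
        gain_std, off_units = standardize(
            stack.config.gain_V, stack.config.offset_pct, record
        )
        profile = error_profile(stack, ceiling=ceiling, keep_maps=False)
        records.append(
            TrainingRecord(
                image_id=f"stack{i:03d}",
                offset_units=off_units,
                gain_V_std=gain_std,
                E=profile.E,
                U=profile.U,
                L=profile.L,
                group=(
                    round(stack.config.gain_V, 3),
                    round(stack.config.offset_pct, 3),
                ),
            )
        )
    return records


def _records_to_xy(records: list[TrainingRecord], c_a: int = 255):
    X = np.array([[r.offset_units, r.gain_V_std] for r in records])
    y = np.vstack([r.E for r in records])
    U = np.vstack([r.U if r.U is not None else np.full(c_a + 1, np.nan) for r in records])
    L = np.vstack([r.L if r.L is not None else np.full(c_a + 1, np.nan) for r in records])
    return X, y, U, L


def fit_error_model(
    records: list[TrainingRecord],
    n_min: int = 5,
    g0: float = 100.0,
    ceiling: int = 250,
    c_a: int = 255,
) -> PerIntensityErrorRegression:
    """Fit the per-intensity regression on a list of training records."""
    if len(records) < 3:
        raise InsufficientDataError("need at least 3 training records")
    X, y, U, L = _records_to_xy(records, c_a)
    model = PerIntensityErrorRegression(g0=g0, n_min=n_min, ceiling=ceiling, c_a=c_a)
    return model.fit(X, y, U=U, L=L)


def predict_pixel_error(
    model: PerIntensityErrorRegression,
    k: int,
    gain_V: float,
    offset_pct: float,
    calibration: CalibrationRecord | None = None,
) -> float:
    """Predicted error at level ``k`` for nominal instrument settings."""
    record = calibration if calibration is not None else IDENTITY_CALIBRATION
    gain_std, off_units = standardize(gain_V, offset_pct, record)
    return model.predict_level(off_units, gain_std, k)


@dataclass
class LooResult:
    """Grouped leave-one-out deviations between computed and predicted E_k."""

    deviations: pd.DataFrame  # columns: group, image_id, k, computed, predicted, abs_dev

    def per_level(self) -> pd.DataFrame:
        g = self.deviations.groupby("k")["abs_dev"]
        return pd.DataFrame({"mean_dev": g.mean(), "max_dev": g.max(), "n": g.size()})

    @property
    def mean_abs_dev(self) -> float:
        return float(self.deviations["abs_dev"].mean())

    @property
    def max_abs_dev(self) -> float:
        return float(self.deviations["abs_dev"].max())


def loo_cv(
    records: list[TrainingRecord],
    n_min: int = 5,
    g0: float = 100.0,
    ceiling: int = 250,
    c_a: int = 255,
) -> LooResult:
    """Grouped leave-one-out test of the regression system.

    All records sharing one nominal (gain, offset) setting form a group;
    each group in turn is excluded entirely from training and predicted,
    and the absolute deviation |computed - predicted| is recorded per
    level.
    """
    groups = {}
    for r in records:
        groups.setdefault(r.group, []).append(r)
    if len(groups) < 3:
        raise CrossValidationError("grouped leave-one-out needs >= 3 groups")
    rows = []
    for key, held_out in groups.items():
        training = [r for r in records if r.group != key]
        model = fit_error_model(training, n_min=n_min, g0=g0, ceiling=ceiling, c_a=c_a)
        for r in held_out:
            pred = model.predict([[r.offset_units, r.gain_V_std]])[0]
            ks = np.flatnonzero(np.isfinite(r.E) & np.isfinite(pred) & model.fitted_levels_)
            for k in ks:
                rows.append(
                    {
                        "group": str(key),
                        "image_id": r.image_id,
                        "k": int(k),
                        "computed": float(r.E[k]),
                        "predicted": float(pred[k]),
                        "abs_dev": float(abs(r.E[k] - pred[k])),
                    }
                )
    return LooResult(deviations=pd.DataFrame(rows))
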