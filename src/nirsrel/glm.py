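"""Channel-wise GLM with Cochrane-Orcutt serial-correlation correction,
one-sided activation tests, and Benjamini-Yekutieli FDR.

The design matrix holds one HRF-convolved boxcar per stimulation
condition, an HRF-convolved delta regressor-of-no-interest at the control
trial onsets, and an intercept. Estimation is a two-stage OLS: stage one
fits the raw model, a first-order autoregressive coefficient is estimated
from its residuals, the model is quasi-differenced with that coefficient
(classical Cochrane-Orcutt: the first sample is dropped), and stage two
OLS on the transformed model yields the reported betas, standard errors
and t statistics. Activation is a one-sided t test per channel (upper
tail for the functional component and HbO, lower tail for HbR), with the
Benjamini-Yekutieli step-up procedure controlling FDR across channels
under arbitrary dependence.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import DesignSpec
from .errors import EstimationError, InputError
from .hrf import block_regressor, canonical_hrf, impulse_regressor

CONTROL_LABEL = "control"
INTERCEPT_LABEL = "intercept"

#: Tail of the one-sided activation test per haemodynamic measure:
#: cortical activation raises the functional component and HbO but
#: lowers HbR.
_TAILS = {"functional": "upper", "hbo": "upper", "hbr": "lower"}


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_samples, n_regressors)
    labels: tuple
    fs: float

    @property
    def condition_labels(self) -> tuple:
        return tuple(l for l in self.labels if l not in (CONTROL_LABEL, INTERCEPT_LABEL))


@dataclass
class GLMFit:
    """Stage-two estimates for one channel series."""

    labels: tuple
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    dof: int
    rho: float

    def coef(self, label: str) -> tuple:
        i = self.labels.index(label)
        return float(self.beta[i]), float(self.se[i]), float(self.t[i])


@dataclass
class ActivationMap:
    """Per-channel t map plus the FDR-significant channel set (1-based)."""

    session: int
    condition: str
    measure: str
    t_values: np.ndarray
    p_values: np.ndarray
    significant: tuple


def build_design_matrix(design: DesignSpec, fs: float,
                        hrf_duration_s: float = 32.0) -> DesignMatrix:
    """Assemble the GLM design matrix for one recording."""
    n = design.n_samples(fs)
    kernel = canonical_hrf(fs, hrf_duration_s)
    columns, labels = [], []
    for condition in design.conditions:
        columns.append(
            block_regressor(design.onsets[condition], design.block_duration_s, n, fs, kernel)
        )
        labels.append(condition)
    columns.append(impulse_regressor(design.control_onsets, n, fs, kernel))
    labels.append(CONTROL_LABEL)
    columns.append(np.ones(n))
    labels.append(INTERCEPT_LABEL)
    return DesignMatrix(matrix=np.column_stack(columns), labels=tuple(labels), fs=fs)


def _ols(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, y - X @ beta


def lag1_autocorrelation(residuals: np.ndarray) -> float:
    """rho_hat = sum(e_t * e_{t-1}) / sum(e_t^2)."""
    e = np.asarray(residuals, dtype=float)
    denom = float(e @ e)
    if denom == 0.0:
        return 0.0
    return float(e[1:] @ e[:-1] / denom)


def fit_glm_cochrane_orcutt(y: np.ndarray, dm: DesignMatrix,
                            iterate: bool = False, max_iter: int = 50,
                            tol: float = 1e-4) -> GLMFit:
    """Two-stage OLS with Cochrane-Orcutt AR(1) correction.

    All-zero regressors (e.g. the control column of a design without
    control trials) are dropped with a warning and reported as NaN. The
    default is the single estimate-transform-refit cycle; ``iterate``
    repeats until the AR coefficient stabilises.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(dm.matrix, dtype=float)
    if len(y) != X.shape[0]:
        raise InputError(f"series length {len(y)} != design rows {X.shape[0]}")
    keep = ~np.all(X == 0.0, axis=0)
    if not keep.all():
        dropped = [dm.labels[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(f"dropping degenerate all-zero regressor(s): {dropped}",
                      stacklevel=2)
    Xk = X[:, keep]
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise EstimationError("design matrix is rank deficient after dropping zero columns")

    beta1, resid = _ols(y, Xk)
    # Numerically-zero residuals (an exact fit) carry no serial structure;
    # their rounding noise must not drive the AR estimate.
    if float(resid @ resid) <= 1e-20 * max(float(y @ y), 1e-300):
        rho = 0.0
    else:
        rho = lag1_autocorrelation(resid)
    for _ in range(max_iter if iterate else 1):
        ys = y[1:] - rho * y[:-1]
        Xs = Xk[1:] - rho * Xk[:-1]
        beta, resid_s = _ols(ys, Xs)
        if not iterate:
            break
        new_rho = lag1_autocorrelation(y - Xk @ beta)
        if abs(new_rho - rho) < tol:
            rho = new_rho
            ys = y[1:] - rho * y[:-1]
            Xs = Xk[1:] - rho * Xk[:-1]
            beta, resid_s = _ols(ys, Xs)
            break
        rho = new_rho

    rank = np.linalg.matrix_rank(Xs)
    dof = (len(y) - 1) - rank
    if dof <= 0:
        raise EstimationError("non-positive residual degrees of freedom")
    sigma2 = float(resid_s @ resid_s) / dof
    cov = sigma2 * np.linalg.inv(Xs.T @ Xs)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)

    full = {"beta": np.full(len(dm.labels), np.nan),
            "se": np.full(len(dm.labels), np.nan),
            "t": np.full(len(dm.labels), np.nan)}
    full["beta"][keep] = beta
    full["se"][keep] = se
    full["t"][keep] = t
    return GLMFit(labels=tuple(dm.labels), beta=full["beta"], se=full["se"],
                  t=full["t"], dof=int(dof), rho=rho)


def one_sided_p(t_values, dof, measure: str):
    """One-sided p-values with the tail direction appropriate to the measure."""
    if measure not in _TAILS:
        raise InputError(f"unknown haemodynamic measure {measure!r}; expected one of {sorted(_TAILS)}")
    t_values = np.asarray(t_values, dtype=float)
    if _TAILS[measure] == "upper":
        p = stats.t.sf(t_values, dof)
    else:
        p = stats.t.cdf(t_values, dof)
    return np.where(np.isnan(t_values), np.nan, p)


def test_activation(fit: GLMFit, condition: str, measure: str) -> float:
    """One-sided activation p-value for one condition's beta weight."""
    _, _, t = fit.coef(condition)
    return float(one_sided_p(t, fit.dof, measure))


def fdr_correct(p_values, q: float = 0.05) -> frozenset:
    """Benjamini-Yekutieli step-up; returns the 0-based rejected indices.

    Rejects hypotheses 1..i for the largest i with
    p_(i) <= (i/m) * q / c(m), c(m) = sum_{j=1..m} 1/j, valid under
    arbitrary dependence between the channel-wise tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return frozenset()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    thresholds = np.arange(1, m + 1) * q / (m * c_m)
    below = np.nonzero(p[order] <= thresholds)[0]
    if below.size == 0:
        return frozenset()
    k = int(below[-1])
    return frozenset(int(i) for i in order[: k + 1])


def group_level_map(betas: np.ndarray, measure: str, q: float = 0.05,
                    condition: str = "", session: int = 0) -> ActivationMap:
    """Random-effects group map: per-channel one-sample one-sided t test
    on subject betas, then Benjamini-Yekutieli FDR across channels."""
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 2 or betas.shape[0] < 2:
        raise InputError("group analysis needs a (subjects >= 2) x channels beta matrix")
    n = betas.shape[0]
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0.0, np.where(mean == 0.0, 0.0, np.sign(mean) * np.inf), t)
    p = one_sided_p(t, n - 1, measure)
    rejected = fdr_correct(p, q)
    significant = tuple(sorted(i + 1 for i in rejected))
    return ActivationMap(session=session, condition=condition, measure=measure,
                         t_values=t, p_values=p, significant=significant)


def subject_activation_channels(p_values, q: float = 0.05) -> tuple:
    """FDR-significant channel numbers (1-based) from a per-channel p vector."""
    return tuple(sorted(i + 1 for i in fdr_correct(p_values, q)))
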