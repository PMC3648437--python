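"""Robust removal of per-array scale effects, and per-array Z-scores.

Fluorescence arrays probed with different sera carry multiplicative
technical effects (serum IgG titre, labelling, scanner gain).  On the log2
scale these become additive per-array offsets, estimated here from the
designated control spots with a two-factor linear model

    log2 y_ij = mu + a_i + f_j + e_ij        (i = array, j = control spot)

fitted by iteratively reweighted least squares with Huber weights, under the
sum-to-zero identifiability constraints sum_i a_i = sum_j f_j = 0.  The
estimated array effect a_i is then subtracted from every feature on array i,
so biological (non-control) spots do not influence the correction.

Z-scores standardize each array column of the normalized log2 matrix
(sample standard deviation, ddof=1); reactivity calls use the conventional
z >= 3 cut-off, boundary inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceWarning, ValidationError
from .io import ExperimentSet

_MAD_TO_SD = 0.6744897501960817  # Phi^{-1}(3/4): MAD / this = consistent sigma-hat


def _huber_irls(
    X: np.ndarray,
    y: np.ndarray,
    c: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, bool, int]:
    """IRLS for a linear model with Huber weights w(u) = min(1, c/|u|).

    Residuals are standardized by the MAD-based scale re-estimated each
    iteration.  Returns (coefficients, converged, n_iterations).
    """
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = y - X @ beta
        scale = np.median(np.abs(r - np.median(r))) / _MAD_TO_SD
        if scale < 1e-12:
            converged = True  # an (essentially) exact fit
            break
        u = np.abs(r) / scale
        w = np.where(u <= c, 1.0, c / np.maximum(u, 1e-300))
        A = X.T @ (w[:, None] * X)
        b = X.T @ (w * y)
        beta_new = np.linalg.solve(A, b)
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if step < tol:
            converged = True
            break
    return beta, converged, it


def _sum_coded(n: int) -> np.ndarray:
    """Sum-to-zero dummy coding: n levels -> (n, n-1) design block."""
    Z = np.zeros((n, n - 1))
    Z[np.arange(n - 1), np.arange(n - 1)] = 1.0
    Z[-1, :] = -1.0
    return Z


@dataclass
class NormalizationResult:
    """Normalized log2 matrix, estimated array effects, and Z-scores."""

    experiment: ExperimentSet
    normalized_log2: pd.DataFrame
    array_effect: pd.Series  # log2 units, sums to zero
    converged: bool
    n_iter: int
    zscore: pd.DataFrame | None = field(default=None)

    def compute_zscore(self) -> pd.DataFrame:
        """Fill and return per-array Z-scores of the normalized log2 matrix."""
        x = self.normalized_log2
        sd = x.std(axis=0, ddof=1)
        zero = sd[sd <= 0]
        if len(zero):
            raise ValidationError(
                f"array {zero.index[0]!r} has zero standard deviation; Z-scores undefined"
            )
        self.zscore = (x - x.mean(axis=0)) / sd
        return self.zscore

    def flag_reactive(self, z_cut: float = 3.0) -> pd.DataFrame:
        """Boolean matrix of reactive calls, z >= z_cut (boundary inclusive)."""
        z = self.zscore if self.zscore is not None else self.compute_zscore()
        return z >= z_cut

    def as_experiment(self) -> ExperimentSet:
        """Re-wrap the normalized (linear scale) matrix as an ExperimentSet."""
        return ExperimentSet(
            features=self.experiment.features,
            samples=self.experiment.samples,
            net_signal=2.0 ** self.normalized_log2,
        )

    def summary(self) -> str:
        lines = [
            "Robust array-effect normalization",
            f"  arrays: {len(self.array_effect)}   "
            f"converged: {self.converged} in {self.n_iter} iterations",
            "  array effects (log2):",
        ]
        for sid, a in self.array_effect.items():
            lines.append(f"    {sid:<12s} {a:+.4f}")
        return "\n".join(lines)


class RLMArrayNormalizer:
    """Model object for the robust two-factor array-effect fit.

    Parameters
    ----------
    experiment : ExperimentSet
        Net-signal matrix; must designate >= 2 control features unless
        ``controls_only=False``, in which case the model is fitted on the
        full matrix.
    huber_c : float
        Huber tuning constant; 1.345 gives 95% efficiency under Gaussian
        errors.  ``numpy.inf`` reduces the fit to ordinary least squares.
    """

    def __init__(
        self,
        experiment: ExperimentSet,
        huber_c: float = 1.345,
        tol: float = 1e-8,
        max_iter: int = 50,
        controls_only: bool = True,
    ) -> None:
        self.experiment = experiment
        self.huber_c = float(huber_c)
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        self.controls_only = bool(controls_only)

    def fit(self) -> NormalizationResult:
        exp = self.experiment
        if exp.n_samples < 2:
            raise ValidationError("normalization needs at least 2 arrays")
        if self.controls_only:
            ctrl = exp.control_features
            if len(ctrl) < 2:
                raise ValidationError(
                    f"normalization needs >= 2 control features, found {len(ctrl)}"
                )
            sub = exp.net_signal.loc[ctrl]
        else:
            sub = exp.net_signal
        if (sub.to_numpy() <= 0).any():
            raise ValidationError("control spots must have positive signal on all arrays")

        nf, na = sub.shape
        ZA = _sum_coded(na)
        ZF = _sum_coded(nf)
        # one observation per (control spot, array), flattened array-major
        array_idx = np.repeat(np.arange(na), nf)
        feat_idx = np.tile(np.arange(nf), na)
        y = np.log2(sub.to_numpy()).ravel(order="F")
        X = np.column_stack([np.ones(y.size), ZA[array_idx], ZF[feat_idx]])
        beta, converged, n_iter = _huber_irls(
            X, y, c=self.huber_c, tol=self.tol, max_iter=self.max_iter
        )
        if not converged:
            warnings.warn(
                f"array-effect IRLS did not converge in {self.max_iter} iterations; "
                "returning last iterate",
                ConvergenceWarning,
                stacklevel=2,
            )
        a_free = beta[1:na]
        effects = np.append(a_free, -a_free.sum())
        array_effect = pd.Series(effects, index=sub.columns, name="array_effect_log2")
        normalized = np.log2(exp.net_signal) - array_effect
        return NormalizationResult(
            experiment=exp,
            normalized_log2=normalized,
            array_effect=array_effect,
            converged=converged,
            n_iter=n_iter,
        )


def rlm_normalize(
    experiment: ExperimentSet,
    huber_c: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 50,
    controls_only: bool = True,
) -> NormalizationResult:
    """Functional entry point; see :class:`RLMArrayNormalizer`."""
    return RLMArrayNormalizer(
        experiment, huber_c=huber_c, tol=tol, max_iter=max_iter, controls_only=controls_only
    ).fit()


def zscore(result: NormalizationResult) -> NormalizationResult:
    """Fill the Z-score matrix on ``result`` and return it."""
    result.compute_zscore()
    return result


def flag_reactive(result: NormalizationResult, z_cut: float = 3.0) -> pd.DataFrame:
    """Boolean reactivity matrix at the given Z cut-off (default 3.0, inclusive)."""
    return result.flag_reactive(z_cut=z_cut)
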