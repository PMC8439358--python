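"""Linear frequency detectors: canonical correlation and sparse regression.

CCA scores each candidate stimulus by the leading canonical correlation
between the multichannel window ``X`` and that stimulus's harmonic
reference ``Y_k``; the decision is ``argmax_k rho_k``.

The LASSO detector regresses each channel onto the union of all
stimuli's harmonic sin/cos regressors under an L1 penalty; the decision
is the frequency whose coefficients, summed over harmonics and averaged
over channels, contribute most.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .epochs import StimulusGrid, ValidationError
from .preprocessing import DEFAULT_N_HARMONICS, ReferenceSet, build_references

__all__ = [
    "CCAResult",
    "LassoEstimate",
    "DetectionResult",
    "cca_fit",
    "cca_classify",
    "lasso_fit",
    "lasso_design",
    "lasso_classify",
    "lambda_max",
    "calibrate_lambda",
    "CCADetector",
    "LassoDetector",
]


@dataclass(frozen=True)
class CCAResult:
    """Canonical correlations (descending) and the paired weight vectors."""

    rho: np.ndarray          # [r], descending, in [0, 1]
    wx: np.ndarray           # [p, r]
    wy: np.ndarray           # [q, r]


@dataclass(frozen=True)
class LassoEstimate:
    """L1-penalized least-squares fit over the stacked harmonic design.

    ``beta`` follows the design's column order: for each frequency, for
    each harmonic, a sin and a cos coefficient.  ``objective_history``
    records the penalized objective after every coordinate-descent sweep.
    """

    beta: np.ndarray
    lam: float
    n_frequencies: int
    n_harmonics: int
    objective_history: np.ndarray
    converged: bool

    def harmonic_coefficients(self, *, absolute: bool = False) -> np.ndarray:
        """Per-(frequency, harmonic) coefficients beta_{f,h}.

        The sin and cos coefficients of each harmonic are combined by a
        signed sum (default) or a sum of absolute values.
        """
        b = self.beta.reshape(self.n_frequencies, self.n_harmonics, 2)
        return np.abs(b).sum(axis=2) if absolute else b.sum(axis=2)

    def contributions(self, *, absolute: bool = False) -> np.ndarray:
        """Per-frequency contribution: sum of beta_{f,h} over harmonics."""
        return self.harmonic_coefficients(absolute=absolute).sum(axis=1)


@dataclass(frozen=True)
class DetectionResult:
    """Per-stimulus scores and the decided (1-based) stimulus index.

    The decision is always the smallest index attaining the maximal
    score; ``degenerate`` marks windows with no usable signal (zero
    variance, or an all-zero sparse fit), ``low_confidence`` marks
    decisions whose best score falls under a caller-chosen threshold.
    """

    scores: np.ndarray
    decided: int
    kind: str
    degenerate: bool = False
    low_confidence: bool = False


def _center_rows(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=1, keepdims=True)


def _inv_sqrt(c: np.ndarray) -> np.ndarray:
    vals, vecs = linalg.eigh(c)
    vals = np.clip(vals, np.finfo(float).tiny, None)
    return (vecs / np.sqrt(vals)) @ vecs.T


def cca_fit(x: np.ndarray, y: np.ndarray, *, ridge: float = 1e-9) -> CCAResult:
    """Canonical correlation analysis between two row-variable matrices.

    Rows are variables, columns are the T paired samples; both views are
    centered internally.  Solved by whitening both covariances and taking
    the SVD of the whitened cross-covariance; a small ridge (``ridge``
    times the covariance trace, spread over the diagonal) keeps nearly
    rank-deficient windows solvable, with a warning.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValidationError(
            f"views have {x.shape[1]} and {y.shape[1]} samples; must match"
        )
    t = x.shape[1]
    if t <= x.shape[0] + y.shape[0]:
        raise ValidationError(
            f"need more samples ({t}) than total variables "
            f"({x.shape[0] + y.shape[0]})"
        )
    xc, yc = _center_rows(x), _center_rows(y)
    cxx = xc @ xc.T / (t - 1)
    cyy = yc @ yc.T / (t - 1)
    cxy = xc @ yc.T / (t - 1)
    for c, label in ((cxx, "x"), (cyy, "y")):
        vals = linalg.eigvalsh(c)
        if vals[0] <= 1e-12 * max(vals[-1], 1e-300):
            warnings.warn(
                f"rank-deficient covariance in the {label} view; "
                "regularized solve", RuntimeWarning, stacklevel=2,
            )
        c += ridge * np.trace(c) / c.shape[0] * np.eye(c.shape[0])
    ixx, iyy = _inv_sqrt(cxx), _inv_sqrt(cyy)
    u, s, vt = linalg.svd(ixx @ cxy @ iyy, full_matrices=False)
    return CCAResult(rho=np.clip(s, 0.0, 1.0), wx=ixx @ u, wy=iyy @ vt.T)


def cca_classify(window: np.ndarray, refs: ReferenceSet) -> DetectionResult:
    """Decide the stimulus of one window by maximal canonical correlation."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[1] != refs.length:
        raise ValidationError(
            f"window has {window.shape[1]} samples, references {refs.length}"
        )
    if np.allclose(window.var(axis=1), 0.0):
        k = refs.grid.k
        return DetectionResult(
            scores=np.zeros(k), decided=1, kind="cca_rho", degenerate=True
        )
    scores = np.asarray(
        [cca_fit(window, refs[k]).rho[0] for k in range(refs.grid.k)]
    )
    return DetectionResult(
        scores=scores, decided=int(np.argmax(scores)) + 1, kind="cca_rho"
    )


def _soft_threshold(z: float, threshold: float) -> float:
    if z > threshold:
        return z - threshold
    if z < -threshold:
        return z + threshold
    return 0.0


class LassoConvergenceError(RuntimeError):
    """Coordinate descent exhausted its sweeps; carries the last iterate."""

    def __init__(self, message: str, estimate: "LassoEstimate"):
        super().__init__(message)
        self.estimate = estimate


def lasso_fit(
    y: np.ndarray,
    x: np.ndarray,
    lam: float,
    *,
    n_frequencies: int | None = None,
    n_harmonics: int | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
) -> LassoEstimate:
    """Minimize ``||y - X b||_2^2 + lam * ||b||_1`` by coordinate descent.

    Cyclic sweeps with exact soft-threshold updates; converged when the
    largest coefficient change in a sweep falls below ``tol``.  The
    design is expected column-normalized (zero-norm columns are skipped).
    """
    if lam < 0:
        raise ValidationError("lam must be >= 0")
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    if y.size != n:
        raise ValidationError(f"y has {y.size} samples, design has {n} rows")
    if n_frequencies is None or n_harmonics is None:
        n_frequencies, n_harmonics = m // 2, 1
    col_sq = np.einsum("ij,ij->j", x, x)
    beta = np.zeros(m)
    resid = y.copy()
    history = []
    converged = False
    for _ in range(max_sweeps):
        max_change = 0.0
        for j in range(m):
            if col_sq[j] == 0.0:
                continue
            old = beta[j]
            z = x[:, j] @ resid + col_sq[j] * old
            new = _soft_threshold(z, lam / 2) / col_sq[j]
            if new != old:
                resid -= x[:, j] * (new - old)
                beta[j] = new
                max_change = max(max_change, abs(new - old))
        history.append(resid @ resid + lam * np.abs(beta).sum())
        if max_change < tol:
            converged = True
            break
    estimate = LassoEstimate(
        beta=beta,
        lam=lam,
        n_frequencies=n_frequencies,
        n_harmonics=n_harmonics,
        objective_history=np.asarray(history),
        converged=converged,
    )
    if not converged:
        raise LassoConvergenceError(
            f"coordinate descent did not converge in {max_sweeps} sweeps",
            estimate,
        )
    return estimate


def lasso_design(refs: ReferenceSet) -> np.ndarray:
    """Stacked harmonic design ``[T, K * Nh * 2]`` with unit-norm columns.

    Column order: frequency-major, then harmonic, then (sin, cos) —
    matching :meth:`LassoEstimate.harmonic_coefficients`.
    """
    cols = []
    for k in range(refs.grid.k):
        matrix = refs[k]  # rows: sin h1, cos h1, sin h2, ...
        for row in matrix:
            cols.append(row / np.linalg.norm(row))
    return np.asarray(cols).T


def lambda_max(y: np.ndarray, x: np.ndarray) -> float:
    """Smallest penalty at which the LASSO solution is exactly zero."""
    return 2 * np.abs(x.T @ np.asarray(y, dtype=float).ravel()).max()


#: Default penalty as a fraction of the all-channels-pooled lambda_max.
DEFAULT_LAMBDA_FRACTION = 0.05


def lasso_classify(
    window: np.ndarray,
    refs: ReferenceSet,
    lam: float | None = None,
    *,
    absolute: bool = False,
) -> DetectionResult:
    """Decide the stimulus of one window from per-channel sparse fits.

    Every channel is centered and fitted with the same penalty; the score
    of frequency ``f`` is the mean over channels of its summed harmonic
    coefficients.  When ``lam`` is None a single penalty is derived from
    the window as ``DEFAULT_LAMBDA_FRACTION`` times the largest
    per-channel deactivation bound (see :func:`calibrate_lambda` for an
    accuracy-driven choice).
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[1] != refs.length:
        raise ValidationError(
            f"window has {window.shape[1]} samples, references {refs.length}"
        )
    x = lasso_design(refs)
    channels = window - window.mean(axis=1, keepdims=True)
    if lam is None:
        lam = DEFAULT_LAMBDA_FRACTION * max(
            (lambda_max(ch, x) for ch in channels), default=0.0
        )
    scores = np.zeros(refs.grid.k)
    any_active = False
    for ch in channels:
        est = lasso_fit(
            ch, x, lam,
            n_frequencies=refs.grid.k, n_harmonics=refs.n_harmonics,
        )
        any_active = any_active or np.any(est.beta != 0.0)
        scores += est.contributions(absolute=absolute)
    scores /= max(window.shape[0], 1)
    return DetectionResult(
        scores=scores,
        decided=int(np.argmax(scores)) + 1,
        kind="lasso_contribution",
        degenerate=not any_active,
    )


def calibrate_lambda(
    epochs,
    refs: ReferenceSet,
    candidates: np.ndarray | list[float],
    *,
    absolute: bool = False,
) -> float:
    """Grid-search the penalty maximizing detection accuracy.

    Runs :func:`lasso_classify` on the first ``refs.length`` samples of
    every trial in ``epochs`` for each candidate penalty and returns the
    candidate with the highest fraction of correct decisions (ties go to
    the smaller penalty).
    """
    best_lam, best_acc = None, -1.0
    for lam in candidates:
        correct = 0
        for i in range(epochs.n_trials):
            window = epochs.data[i, :, : refs.length]
            result = lasso_classify(window, refs, float(lam), absolute=absolute)
            correct += int(result.decided == epochs.labels[i])
        acc = correct / max(epochs.n_trials, 1)
        if acc > best_acc:
            best_lam, best_acc = float(lam), acc
    return best_lam


@dataclass
class CCADetector:
    """Evaluation-facing CCA detector; builds references per window length."""

    grid: StimulusGrid
    sample_rate: float = 256.0
    n_harmonics: int = DEFAULT_N_HARMONICS
    name: str = "CCA"
    _refs_cache: dict = field(default_factory=dict, repr=False)

    def _refs(self, length: int) -> ReferenceSet:
        if length not in self._refs_cache:
            self._refs_cache[length] = build_references(
                self.grid, self.n_harmonics, length, self.sample_rate
            )
        return self._refs_cache[length]

    def classify(self, window: np.ndarray) -> DetectionResult:
        return cca_classify(window, self._refs(window.shape[1]))


@dataclass
class LassoDetector:
    """Evaluation-facing LASSO detector with a shared penalty.

    Scores use coefficient magnitudes by default: a window that does not
    start at stimulus onset carries an arbitrary phase, which splits each
    harmonic's energy between its sin and cos coefficients with arbitrary
    signs — a signed sum can cancel on the true frequency.  Set
    ``absolute=False`` for the literal signed-sum contribution rule.
    """

    grid: StimulusGrid
    sample_rate: float = 256.0
    n_harmonics: int = DEFAULT_N_HARMONICS
    lam: float | None = None
    absolute: bool = True
    name: str = "LASSO"
    _refs_cache: dict = field(default_factory=dict, repr=False)

    def _refs(self, length: int) -> ReferenceSet:
        if length not in self._refs_cache:
            self._refs_cache[length] = build_references(
                self.grid, self.n_harmonics, length, self.sample_rate
            )
        return self._refs_cache[length]

    def classify(self, window: np.ndarray) -> DetectionResult:
        return lasso_classify(
            window, self._refs(window.shape[1]), self.lam, absolute=self.absolute
        )
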