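"""External validation and robustness checks for QSAR models.

External test-set statistics follow the Golbraikh–Tropsha battery:

* r_pred² = 1 − PRESS/SD, where PRESS is the squared prediction error
  over the test set and SD refers the test activities to the
  *training* mean, so the statistic penalises both scatter and offset;
* r_test², the conventional squared Pearson correlation;
* through-origin regression slopes k (observed on predicted) and k′
  (predicted on observed), and the through-origin r_0²;
* the modified statistic r_m² = r_test² · (1 − √(r_test² − r_0²)),
  which shrinks toward zero as the through-origin fit departs from
  the ordinary one.

A model is accepted when r_pred² > 0.5, r_test² > 0.6,
(r_test² − r_0²)/r_test² < 0.1, and at least one of k, k′ lies in
[0.85, 1.15].

Robustness checks: bootstrap refitting (resampled training rows,
fixed component count) and y-randomisation (activities permuted, LOO
q² recomputed — significant q² on scrambled data indicates chance
correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pls_model import fit_pls, internal_stats, loo_q2

__all__ = [
    "ExternalValidationReport",
    "RandomizationResult",
    "BootstrapResult",
    "rm_squared",
    "external_stats",
    "golbraikh_tropsha_check",
    "bootstrap",
    "y_randomization",
]


@dataclass
class ExternalValidationReport:
    """Test-set statistics and acceptance verdicts."""

    r_pred2: float
    r_test2: float
    r0_2: float
    r0_2_prime: float  # through-origin r² in the swapped orientation
    k: float
    k_prime: float
    rm2: float
    ratio: float  # (r_test2 - r0_2) / r_test2
    sd: float  # Σ(y_test − ȳ_train)²
    press_ext: float  # Σ(y_test − ŷ_test)²
    criteria: dict[str, bool] = field(default_factory=dict)


@dataclass
class RandomizationResult:
    """LOO q² values after repeated activity scrambling."""

    n_runs: int
    q2_values: list[float]
    seed: int | None

    @property
    def q2_min(self) -> float:
        return min(self.q2_values)

    @property
    def q2_max(self) -> float:
        return max(self.q2_values)


@dataclass
class BootstrapResult:
    """In-sample r² and SEE over bootstrap refits."""

    r_bs2: float
    see_bs: float
    r2_runs: list[float]
    see_runs: list[float]
    seed: int | None


def rm_squared(r_test2: float, r0_2: float) -> float:
    """Modified external r²: r_test² · (1 − √(r_test² − r_0²)).

    When r_0² exceeds r_test² (through-origin fit nominally better),
    the difference is clamped at zero with a warning, giving
    r_m² = r_test².
    """
    diff = r_test2 - r0_2
    if diff < 0:
        warnings.warn(
            f"r0_2={r0_2:.4f} exceeds r_test2={r_test2:.4f}; clamping difference at 0",
            stacklevel=2,
        )
        diff = 0.0
    return r_test2 * (1.0 - np.sqrt(diff))


def _through_origin_slope(y: np.ndarray, x: np.ndarray) -> float:
    """Least-squares slope of y = k·x."""
    denom = float((x * x).sum())
    if denom <= 0:
        raise ValueError("through-origin slope undefined for all-zero regressor")
    return float((x * y).sum() / denom)


def external_stats(
    y_obs_test: np.ndarray,
    y_pred_test: np.ndarray,
    y_train_mean: float,
) -> ExternalValidationReport:
    """Compute the full external-validation report for a test set.

    ``k`` is the slope of observed-versus-predicted through the
    origin, ``k_prime`` the swapped orientation; ``r0_2`` is the
    through-origin r² in the observed-on-predicted orientation (the
    alternate orientation is reported as ``r0_2_prime``).
    """
    y = np.asarray(y_obs_test, dtype=float).ravel()
    yhat = np.asarray(y_pred_test, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted test vectors differ in length")
    if len(y) < 3:
        raise ValueError("external validation needs at least 3 test compounds")
    if y.std() <= 1e-12:
        raise ValueError("test-set activity variance is zero")

    press = float(((y - yhat) ** 2).sum())
    sd = float(((y - y_train_mean) ** 2).sum())
    r_pred2 = 1.0 - press / sd
    degenerate = yhat.std() <= 1e-12
    if degenerate:
        warnings.warn("constant test predictions; reporting r_test2 = 0", stacklevel=2)
        r_test2 = 0.0
    else:
        r_test2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    k = _through_origin_slope(y, yhat)
    k_prime = _through_origin_slope(yhat, y)
    tss = float(((y - y.mean()) ** 2).sum())
    r0_2 = 1.0 - float(((y - k * yhat) ** 2).sum()) / tss
    tss_hat = float(((yhat - yhat.mean()) ** 2).sum())
    r0_2_prime = (
        float("nan") if degenerate
        else 1.0 - float(((yhat - k_prime * y) ** 2).sum()) / tss_hat
    )
    ratio = (r_test2 - r0_2) / r_test2 if r_test2 > 0 else float("inf")
    rm2 = rm_squared(r_test2, min(r0_2, r_test2)) if degenerate else rm_squared(r_test2, r0_2)
    report = ExternalValidationReport(
        r_pred2=r_pred2,
        r_test2=r_test2,
        r0_2=r0_2,
        r0_2_prime=r0_2_prime,
        k=k,
        k_prime=k_prime,
        rm2=rm2,
        ratio=ratio,
        sd=sd,
        press_ext=press,
    )
    report.criteria = golbraikh_tropsha_check(report)
    return report


def golbraikh_tropsha_check(report: ExternalValidationReport) -> dict[str, bool]:
    """Acceptance verdicts for the external-validation criteria.

    All four predicates must hold for the overall verdict: strict
    r_pred² > 0.5 and r_test² > 0.6, relative through-origin gap below
    0.1, and a through-origin slope (either orientation) within
    [0.85, 1.15].
    """
    verdicts = {
        "r_pred2_gt_half": report.r_pred2 > 0.5,
        "r_test2_gt_0.6": report.r_test2 > 0.6,
        "r0_ratio_lt_0.1": report.ratio < 0.1,
        "slope_near_unity": (0.85 <= report.k <= 1.15) or (0.85 <= report.k_prime <= 1.15),
    }
    verdicts["overall"] = all(verdicts.values())
    return verdicts


def bootstrap(
    X: np.ndarray,
    y: np.ndarray,
    pcs: int,
    n_runs: int = 100,
    seed: int | None = None,
    block_ids: np.ndarray | None = None,
    scaling: str = "block",
) -> BootstrapResult:
    """Bootstrap the training set and refit at a fixed component count.

    Each run resamples rows with replacement and records the in-sample
    r² and SEE; resamples with (near-)zero activity variance are
    redrawn. Deterministic for a given seed.
    """
    if n_runs < 2:
        raise ValueError("bootstrap needs at least 2 runs")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    rng = np.random.default_rng(seed)
    r2_runs: list[float] = []
    see_runs: list[float] = []
    attempts = 0
    while len(r2_runs) < n_runs:
        attempts += 1
        if attempts > 20 * n_runs:
            raise RuntimeError("too many degenerate bootstrap resamples")
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.std() <= 1e-12:
            continue
        model = fit_pls(X[idx], yb, pcs, block_ids, scaling)
        stats = internal_stats(model, X[idx], yb)
        r2_runs.append(stats.r_ncv2)
        see_runs.append(stats.see)
    return BootstrapResult(
        r_bs2=float(np.mean(r2_runs)),
        see_bs=float(np.mean(see_runs)),
        r2_runs=r2_runs,
        see_runs=see_runs,
        seed=seed,
    )


def y_randomization(
    X: np.ndarray,
    y: np.ndarray,
    pcs: int,
    n_runs: int = 50,
    seed: int | None = None,
    block_ids: np.ndarray | None = None,
    scaling: str = "block",
) -> RandomizationResult:
    """Scramble activities and recompute LOO q² at a fixed model size.

    A robust model shows scrambled q² well below the unscrambled one;
    on null data the scrambled q² values centre below zero.
    """
    if n_runs < 1:
        raise ValueError("y-randomization needs at least 1 run")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    q2_values = []
    for _ in range(n_runs):
        y_perm = rng.permutation(y)
        q2, _ = loo_q2(X, y_perm, pcs, block_ids, scaling)
        q2_values.append(q2)
    return RandomizationResult(n_runs=n_runs, q2_values=q2_values, seed=seed)
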