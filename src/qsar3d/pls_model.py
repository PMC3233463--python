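"""Partial least squares on lattice descriptors, with LOO validation.

The regression target is pIC50; the descriptors are the concatenated
field columns. Latent components are extracted by NIPALS (via
scikit-learn) after centring and an optional column scaling:

* ``"block"`` (default) — CoMFA-standard scaling: every field block is
  rescaled so all blocks carry equal total variance, preventing a
  high-variance field (e.g. steric energies) from dominating a
  multi-field model. Predictions are then invariant to multiplying a
  whole block by a constant.
* ``"autoscale"`` — unit variance per column.
* ``"none"`` — raw columns.

Internal statistics follow the conventional QSAR report: LOO
cross-validated q² = 1 − PRESS/Σ(y−ȳ)², the non-cross-validated r²,
the standard error of estimate SEE = √(SS_res/(n − PCs − 1)), and the
F statistic with (PCs, n − PCs − 1) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .fields import ColumnMeta, block_labels

__all__ = [
    "PLSModel",
    "ModelStats",
    "fit_pls",
    "loo_q2",
    "select_components",
    "internal_stats",
    "field_contributions",
    "save_model",
    "load_model",
]


@dataclass
class PLSModel:
    """Fitted latent-variable regression in original column units."""

    n_components: int
    coefficients: np.ndarray  # per column, pIC50 per descriptor unit
    intercept: float
    x_mean: np.ndarray
    scale_weights: np.ndarray
    y_mean: float
    scaling: str
    metadata: list[ColumnMeta] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients + self.intercept


@dataclass
class ModelStats:
    """Internal model statistics in the conventional table shape."""

    pcs: int
    q2: float | None = None
    press: float | None = None
    r_ncv2: float | None = None
    see: float | None = None
    f_value: float | None = None
    r_bs2: float | None = None
    see_bs: float | None = None
    field_contributions: dict[str, float] = field(default_factory=dict)


def save_model(model: PLSModel, prefix: str) -> None:
    """Serialise a model as ``<prefix>.json`` + ``<prefix>.npz``.

    Scalars and column metadata go to JSON; coefficient and scaling
    vectors to a compressed npz.
    """
    import json
    from pathlib import Path

    meta = None
    if model.metadata is not None:
        meta = [
            {"method": m.method, "kind": m.kind, "point_index": m.point_index}
            for m in model.metadata
        ]
    Path(f"{prefix}.json").write_text(
        json.dumps(
            {
                "n_components": model.n_components,
                "intercept": model.intercept,
                "y_mean": model.y_mean,
                "scaling": model.scaling,
                "metadata": meta,
            },
            indent=2,
        )
    )
    np.savez_compressed(
        f"{prefix}.npz",
        coefficients=model.coefficients,
        x_mean=model.x_mean,
        scale_weights=model.scale_weights,
    )


def load_model(prefix: str) -> PLSModel:
    import json

    with open(f"{prefix}.json") as fh:
        head = json.load(fh)
    arrays = np.load(f"{prefix}.npz")
    meta = head["metadata"]
    metadata = (
        None if meta is None else [ColumnMeta(m["method"], m["kind"], m["point_index"]) for m in meta]
    )
    return PLSModel(
        n_components=head["n_components"],
        coefficients=arrays["coefficients"],
        intercept=head["intercept"],
        x_mean=arrays["x_mean"],
        scale_weights=arrays["scale_weights"],
        y_mean=head["y_mean"],
        scaling=head["scaling"],
        metadata=metadata,
    )


def _scale_weights(Xc: np.ndarray, block_ids: np.ndarray | None, scaling: str) -> np.ndarray:
    p = Xc.shape[1]
    if scaling == "none":
        return np.ones(p)
    if scaling == "autoscale":
        sd = Xc.std(axis=0, ddof=1)
        return np.where(sd > 1e-12, 1.0 / np.where(sd > 1e-12, sd, 1.0), 0.0)
    if scaling == "block":
        if block_ids is None:
            block_ids = np.zeros(p, dtype=int)
        w = np.ones(p)
        for b in np.unique(block_ids):
            mask = block_ids == b
            total_var = Xc[:, mask].var(axis=0, ddof=1).sum()
            w[mask] = 1.0 / np.sqrt(total_var) if total_var > 1e-12 else 0.0
        return w
    raise ValueError(f"unknown scaling {scaling!r} (none | autoscale | block)")


def _preprocess(
    X: np.ndarray, block_ids: np.ndarray | None, scaling: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    w = _scale_weights(Xc, block_ids, scaling)
    return Xc * w, x_mean, w


def _fit_sklearn(Xs: np.ndarray, y: np.ndarray, k: int) -> PLSRegression:
    pls = PLSRegression(n_components=k, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xs, y)
    return pls


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    block_ids: np.ndarray | None = None,
    scaling: str = "block",
    metadata: list[ColumnMeta] | None = None,
) -> PLSModel:
    """Fit a PLS model with the requested number of latent components.

    With components equal to the rank of the centred descriptor
    matrix, training predictions coincide with least squares on the
    same column space.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n < n_components + 2:
        raise ValueError(f"need at least n_components + 2 = {n_components + 2} samples, got {n}")
    Xs, x_mean, w = _preprocess(X, block_ids, scaling)
    sv = np.linalg.svd(Xs, compute_uv=False)
    rank = int((sv > max(n, p) * sv[0] * 1e-12).sum()) if sv.size and sv[0] > 0 else 0
    if n_components > rank:
        raise ValueError(
            f"descriptor matrix rank {rank} is below the requested "
            f"{n_components} components; use fewer components"
        )
    pls = _fit_sklearn(Xs, y, n_components)
    coef = w * np.asarray(pls.coef_).reshape(-1)
    # intercept via an exact evaluation of the fitted affine map at x = 0
    zero_row = (np.zeros((1, p)) - x_mean) * w
    intercept = float(pls.predict(zero_row).ravel()[0])
    return PLSModel(
        n_components=n_components,
        coefficients=coef,
        intercept=intercept,
        x_mean=x_mean,
        scale_weights=w,
        y_mean=float(y.mean()),
        scaling=scaling,
        metadata=metadata,
    )


def loo_q2(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    block_ids: np.ndarray | None = None,
    scaling: str = "block",
) -> tuple[float, float]:
    """Leave-one-out cross-validated q² and PRESS.

    Every fold refits the whole pipeline (centring and scaling
    included) without the held-out sample. q² = 1 − PRESS / Σ(y−ȳ)²
    with ȳ the training-set mean activity; q² ≤ 1, and is negative
    when LOO predictions are worse than predicting the mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("LOO cross-validation needs at least 3 samples")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 1e-14:
        raise ValueError("activity variance is zero; q2 undefined")
    if n_components > min(n - 2, p):
        raise ValueError(
            f"n_components={n_components} too large for LOO with n={n}, p={p}"
        )
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xs, x_mean, w = _preprocess(X[mask], block_ids, scaling)
        pls = _fit_sklearn(Xs, y[mask], n_components)
        xi = (X[i] - x_mean) * w
        press += float((y[i] - pls.predict(xi[None, :]).ravel()[0]) ** 2)
    return 1.0 - press / tss, press


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    max_pcs: int,
    block_ids: np.ndarray | None = None,
    scaling: str = "block",
    parsimony_tol: float = 0.005,
) -> tuple[int, list[float]]:
    """Choose the component count by the LOO q² profile.

    Returns the smallest count whose q² is within ``parsimony_tol`` of
    the profile maximum — mirroring the usual audit that adding
    components beyond the optimum yields no further improvement — plus
    the full q²-vs-components profile.
    """
    if max_pcs < 1:
        raise ValueError("max_pcs must be >= 1")
    n, p = np.asarray(X).shape
    upper = min(max_pcs, n - 2, p)
    profile = [loo_q2(X, y, k, block_ids, scaling)[0] for k in range(1, upper + 1)]
    qmax = max(profile)
    for k, q in enumerate(profile, start=1):
        if q >= qmax - parsimony_tol:
            return k, profile
    raise AssertionError("unreachable")


def internal_stats(model: PLSModel, X: np.ndarray, y: np.ndarray) -> ModelStats:
    """Non-cross-validated fit statistics: r², SEE and F.

    SEE uses the n − PCs − 1 denominator; F is computed from r² with
    (PCs, n − PCs − 1) degrees of freedom. A degenerate constant
    prediction reports r² = 0 with a warning rather than NaN.
    """
    y = np.asarray(y, dtype=float).ravel()
    fitted = model.predict(X)
    n = len(y)
    pcs = model.n_components
    if n <= pcs + 1:
        raise ValueError(f"need n > PCs + 1 (n={n}, PCs={pcs})")
    ss_res = float(((y - fitted) ** 2).sum())
    if fitted.std() < 1e-12 or y.std() < 1e-12:
        warnings.warn("constant fitted values; reporting r_ncv2 = 0", stacklevel=2)
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    see = float(np.sqrt(ss_res / (n - pcs - 1)))
    if 1.0 - r2 < 1e-15:
        f_value = float("inf")
    else:
        f_value = (r2 / pcs) / ((1.0 - r2) / (n - pcs - 1))
    return ModelStats(pcs=pcs, r_ncv2=r2, see=see, f_value=float(f_value))


def field_contributions(
    model: PLSModel,
    X: np.ndarray,
    metadata: list[ColumnMeta],
    train_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Relative contribution of each field kind to the model.

    Per block: Σ_columns |coefficient × training sd|, normalised over
    blocks to sum to one — the conventional "relative contribution"
    entries of a QSAR statistics table.
    """
    X = np.asarray(X, dtype=float)
    rows = X if train_mask is None else X[np.asarray(train_mask, bool)]
    sd = rows.std(axis=0, ddof=1)
    weight = np.abs(model.coefficients * sd)
    labels = block_labels(metadata)
    totals: dict[str, float] = {}
    for b in np.unique(labels):
        mask = labels == b
        kind = metadata[int(np.flatnonzero(mask)[0])].kind
        totals[kind] = totals.get(kind, 0.0) + float(weight[mask].sum())
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("all model coefficients are zero; contributions undefined")
    return {k: v / grand for k, v in totals.items()}
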