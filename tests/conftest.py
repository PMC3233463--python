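"""Shared fixtures: synthetic study contexts and hand-written fixtures."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qsar3d.pipeline import RunConfig, prepare_descriptors
from qsar3d.synthetic_data import make_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: field kinds matching the default planted receptor
RECOVERY_KINDS = ("steric", "electrostatic", "acceptor")

METHANE_SDF = """\
methane
  handmade 3D

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6300    0.6300    0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6300   -0.6300    0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6300    0.6300   -0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6300   -0.6300   -0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
$$$$
"""

FLAT_SDF = """\
flat
  handmade

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0000    1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
$$$$
"""

WATER_MOL2 = """\
@<TRIPOS>MOLECULE
water
 3 2 1 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
      1 O1          0.0000    0.0000    0.1173 O.3     1  WAT1       -0.8340
      2 H1          0.7572    0.0000   -0.4692 H       1  WAT1        0.4170
      3 H2         -0.7572    0.0000   -0.4692 H       1  WAT1        0.4170
@<TRIPOS>BOND
     1    1    2 1
     2    1    3 1
"""


@pytest.fixture(scope="session")
def planted():
    """A full-size planted study: 105 compounds, 77/28 split, noise 0.1."""
    ctx = make_dataset(105, seed=11, noise_sd=0.1)
    cfg = RunConfig(
        method="comsia", comsia_kinds=RECOVERY_KINDS, max_pcs=6,
        seed=11, template_id="syn000",
    )
    ctx["config"] = cfg
    ctx.update(prepare_descriptors(cfg, ctx["dataset"]))
    return ctx


@pytest.fixture(scope="session")
def planted_small():
    """A small planted study for cheap end-to-end checks."""
    ctx = make_dataset(30, seed=23, noise_sd=0.1)
    cfg = RunConfig(
        method="comsia", comsia_kinds=RECOVERY_KINDS, max_pcs=4,
        seed=23, template_id="syn000",
    )
    ctx["config"] = cfg
    ctx.update(prepare_descriptors(cfg, ctx["dataset"]))
    return ctx


# ---------------------------------------------------------------------------
# independent oracles


def nipals_predict(X, y, X_new, n_components):
    """Hand-written PLS1 NIPALS recursion (centring only, no scaling)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    x_mean, y_mean = X.mean(axis=0), y.mean()
    Xk = X - x_mean
    yk = y - y_mean
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = Xk.T @ yk
        w = w / np.linalg.norm(w)
        t = Xk @ w
        tt = float(t @ t)
        p = Xk.T @ t / tt
        q = float(yk @ t) / tt
        Xk = Xk - np.outer(t, p)
        yk = yk - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    W = np.column_stack(W)
    P = np.column_stack(P)
    Q = np.array(Q)
    beta = W @ np.linalg.solve(P.T @ W, Q)
    return (np.atleast_2d(X_new) - x_mean) @ beta + y_mean


def loo_q2_bruteforce(X, y, n_components):
    """LOO q² by explicit per-fold NIPALS refit."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        yhat = nipals_predict(X[mask], y[mask], X[i][None, :], n_components)[0]
        press += (y[i] - yhat) ** 2
    return 1.0 - press / ((y - y.mean()) ** 2).sum(), press


def comsia_bruteforce(mol, points, kind, alpha=0.3):
    """Naive double loop over atoms × points for the similarity index."""
    prop = {
        "steric": lambda a: a.vdw_radius**3,
        "electrostatic": lambda a: a.partial_charge,
        "hydrophobic": lambda a: a.hydrophobicity,
        "donor": lambda a: float(a.is_hbd),
        "acceptor": lambda a: float(a.is_hba),
    }[kind]
    out = []
    for q in np.atleast_2d(points):
        total = 0.0
        for a in mol.atoms:
            r2 = sum((c - p) ** 2 for c, p in zip(a.coords, q))
            total += prop(a) * np.exp(-alpha * r2)
        out.append(-total)
    return np.array(out)
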