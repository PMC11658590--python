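"""Analytic Hierarchy Process weights with Saaty consistency checking.

A pairwise-comparison matrix A is positive and reciprocal
(a_ji = 1/a_ij, a_ii = 1). The priority vector is the normalised
principal eigenvector of A, found by power iteration; consistency is
measured by CI = (λmax − n)/(n − 1) and CR = CI / RI(n) against Saaty's
random-index table. A CR above 0.1 conventionally signals inconsistent
judgments — this implementation warns rather than rejects, leaving the
call to the analyst.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AHPResult",
    "weights_from_matrix",
    "validate_matrix",
    "load_matrix_csv",
    "save_weights_csv",
    "RANDOM_INDEX",
]

#: Saaty random consistency index RI(n) for n = 1..10
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
                7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

RECIPROCAL_TOL = 1e-9


@dataclass(frozen=True)
class AHPResult:
    weights: np.ndarray
    lambda_max: float
    ci: float
    cr: float
    names: tuple[str, ...] | None = None


def _check_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("pairwise matrix must be square")
    n = m.shape[0]
    if n < 2:
        raise ValueError("pairwise matrix needs at least 2 factors")
    if n > max(RANDOM_INDEX):
        raise ValueError(
            f"random index undefined for n={n}; split the hierarchy into "
            "sub-groups of at most 10 factors"
        )
    if np.any(m <= 0):
        raise ValueError("pairwise entries must be positive")
    if not np.allclose(np.diag(m), 1.0, atol=RECIPROCAL_TOL):
        raise ValueError("diagonal entries must be 1")
    if not np.allclose(m * m.T, 1.0, atol=1e-6):
        raise ValueError("matrix is not reciprocal (a_ji != 1/a_ij)")
    return m


def weights_from_matrix(
    m, names: tuple[str, ...] | None = None, *,
    method: str = "eigenvector", tol: float = 1e-12, max_iter: int = 500,
) -> AHPResult:
    """Priority weights from a reciprocal pairwise-comparison matrix.

    ``method="eigenvector"`` (default) runs power iteration to ``tol``;
    ``method="geometric"`` uses the row geometric mean, handy as a
    sensitivity cross-check. λmax is the Rayleigh quotient at the
    returned vector; for a perfectly consistent matrix λmax = n and
    CI = CR = 0.
    """
    m = _check_matrix(m)
    n = m.shape[0]
    if method == "geometric":
        w = np.exp(np.mean(np.log(m), axis=1))
        w /= w.sum()
    elif method == "eigenvector":
        w = np.full(n, 1.0 / n)
        for _ in range(max_iter):
            nxt = m @ w
            nxt /= nxt.sum()
            if np.max(np.abs(nxt - w)) < tol:
                w = nxt
                break
            w = nxt
    else:
        raise ValueError(f"unknown method {method!r}")

    lam = float((m @ w) @ w / (w @ w))
    ci = (lam - n) / (n - 1)
    if -1e-9 < ci < 0:  # numerical noise around perfect consistency
        ci = 0.0
    ri = RANDOM_INDEX[n]
    cr = ci / ri if ri > 0 else 0.0
    if cr > 0.1:
        warnings.warn(
            f"consistency ratio {cr:.3f} exceeds 0.1; judgments look inconsistent",
            stacklevel=2,
        )
    return AHPResult(w, lam, ci, cr, names)


def validate_matrix(m) -> dict:
    """Non-mutating diagnostics: reciprocality violations and CR."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("pairwise matrix must be square")
    if m.shape[0] < 2:
        raise ValueError("pairwise matrix needs at least 2 factors")
    violations = []
    n = m.shape[0]
    for i in range(n):
        if abs(m[i, i] - 1.0) > RECIPROCAL_TOL:
            violations.append((i, i, float(m[i, i])))
        for j in range(i + 1, n):
            if abs(m[i, j] * m[j, i] - 1.0) > 1e-6:
                violations.append((i, j, float(m[i, j] * m[j, i])))
    out = {"n": n, "violations": violations}
    if not violations and np.all(m > 0) and n <= max(RANDOM_INDEX):
        out["cr"] = weights_from_matrix(m).cr
    return out


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def load_matrix_csv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Square CSV with a header row (and index column) of factor names."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column factor names differ")
    return df.to_numpy(dtype=float), tuple(df.columns)


def save_weights_csv(results: dict[str, AHPResult], path: str | Path) -> None:
    """Write per-group weights as (factor, group, weight) rows."""
    rows = []
    for group, res in results.items():
        names = res.names or tuple(f"f{i}" for i in range(len(res.weights)))
        for name, w in zip(names, res.weights):
            rows.append({"factor": name, "group": group, "weight": w})
    pd.DataFrame(rows).to_csv(path, index=False)
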