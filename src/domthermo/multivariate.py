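"""Matrix-correlation and ordination-linkage statistics.

First-principles implementations of the permutation machinery used to link
molecular composition to community composition: the Mantel test between two
distance matrices, Procrustes superposition with a PROTEST Monte Carlo test,
classical principal-coordinates ordination (PCoA), and vector fitting of
external variables onto an ordination (the "envfit" construction).

All permutation p-values are one-sided with the add-one Monte Carlo
estimator p = (1 + #{permuted statistic at least as extreme}) / (1 + n_perm)
and are reproducible under a fixed seed; ``exhaustive=True`` enumerates all
n! relabelings instead (identity included), feasible for n <= 8.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _all_perms
from math import factorial
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int


@dataclass
class ProcrustesResult:
    m12_squared: float
    p_value: float
    n_permutations: int


@dataclass
class Ordination:
    """Sample scores on centered axes plus eigenvalue metadata."""

    scores: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.scores)


@dataclass
class EnvfitResult:
    variable: str
    direction: np.ndarray  # unit vector in ordination space
    r_squared: float
    p_value: float
    n_permutations: int


def _as_square(d: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list]:
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        m = d.to_numpy(dtype=float)
    else:
        m = np.asarray(d, dtype=float)
        labels = list(range(m.shape[0]))
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    return m, labels


def _tri(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices_from(m, k=-1)
    return m[i, j]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("zero variance in distance vector")
    return float((a @ b) / denom)


def _perm_iter(n: int, n_perm: int, exhaustive: bool, seed: int | None):
    if exhaustive:
        yield from (np.array(p) for p in _all_perms(range(n)))
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            yield rng.permutation(n)


def mantel(
    d1: pd.DataFrame | np.ndarray,
    d2: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the strictly-lower-triangle vectors; the
    one-sided p permutes rows and columns of ``d2`` simultaneously.
    """
    m1, l1 = _as_square(d1)
    m2, l2 = _as_square(d2)
    if l1 != l2:
        raise ValueError("distance matrices must share sample labels and order")
    n = m1.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    v1 = _tri(m1)
    r_obs = _pearson(v1, _tri(m2))
    hits = 0
    total = 0
    for perm in _perm_iter(n, n_perm, exhaustive, seed):
        total += 1
        if _pearson(v1, _tri(m2[np.ix_(perm, perm)])) >= r_obs - 1e-12:
            hits += 1
    if exhaustive:
        p = hits / total
    else:
        p = (1 + hits) / (1 + total)
    return MantelResult(r=r_obs, p_value=p, n_permutations=total)


def _center_scale(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    norm = np.sqrt((x**2).sum())
    if norm == 0:
        raise ValueError("degenerate configuration: all points coincide")
    return x / norm


def _m12sq(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes residual after centering, unit-scaling, rotation."""
    xs = _center_scale(x)
    ys = _center_scale(y)
    sv = np.linalg.svd(xs.T @ ys, compute_uv=False)
    return float(max(0.0, 1.0 - sv.sum() ** 2))


def procrustes(
    c1: Ordination | np.ndarray,
    c2: Ordination | np.ndarray,
    n_perm: int = 999,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> ProcrustesResult:
    """Symmetric Procrustes superposition with the PROTEST permutation test.

    m12^2 in [0, 1] is the residual sum of squares after optimally rotating
    and scaling one centered configuration onto the other (0 = identical
    shapes).  The test permutes the sample rows of the second configuration
    and counts residuals at least as small as observed.
    """
    x = c1.scores.to_numpy() if isinstance(c1, Ordination) else np.asarray(c1, float)
    y = c2.scores.to_numpy() if isinstance(c2, Ordination) else np.asarray(c2, float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("configurations must have the same samples")
    k = min(x.shape[1], y.shape[1])
    x, y = x[:, :k], y[:, :k]
    obs = _m12sq(x, y)
    hits = 0
    total = 0
    for perm in _perm_iter(x.shape[0], n_perm, exhaustive, seed):
        total += 1
        if _m12sq(x, y[perm]) <= obs + 1e-12:
            hits += 1
    p = hits / total if exhaustive else (1 + hits) / (1 + total)
    return ProcrustesResult(m12_squared=obs, p_value=p, n_permutations=total)


def pcoa(d: pd.DataFrame | np.ndarray, k: int = 2) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers -D^2/2, takes the top-k eigenpairs, and scales the
    eigenvectors by the square roots of their (non-negative) eigenvalues.
    Negative eigenvalues — possible for semimetric dissimilarities like
    Bray-Curtis — are retained in the metadata but excluded from scores.
    """
    m, labels = _as_square(d)
    n = m.shape[0]
    if n < 3:
        raise ValueError("ordination needs at least 3 samples")
    if not 1 <= k <= n - 1:
        raise ValueError("k must be in [1, n-1]")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (m**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scores = np.zeros((n, k))
    for a in range(k):
        if evals[a] > 0:
            scores[:, a] = evecs[:, a] * np.sqrt(evals[a])
    cols = [f"PCo{a + 1}" for a in range(k)]
    return Ordination(
        scores=pd.DataFrame(scores, index=labels, columns=cols),
        eigenvalues=evals,
    )


def envfit(
    ordination: Ordination,
    variables: pd.DataFrame | pd.Series,
    n_perm: int = 999,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> list[EnvfitResult]:
    """Fit external variables as vectors onto ordination axes.

    Each centered variable is regressed on the sample scores; r^2 is the
    fraction of its variance explained, the direction is the unit-normalized
    coefficient vector, and significance comes from permuting the variable's
    values across samples (one-sided on r^2).
    """
    scores = ordination.scores.to_numpy(dtype=float)
    if scores.shape[1] < 2:
        raise ValueError("ordination must have at least 2 axes")
    if isinstance(variables, pd.Series):
        variables = variables.to_frame()
    xc = scores - scores.mean(axis=0)
    # Hat-style projector for r^2 under each permutation
    pinv = np.linalg.pinv(xc)
    results = []
    for name in variables.columns:
        v = variables[name].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise ValueError(f"variable {name!r} has zero variance")

        def r2_of(vec: np.ndarray) -> tuple[float, np.ndarray]:
            vc = vec - vec.mean()
            coef = pinv @ vc
            fitted = xc @ coef
            return float((fitted @ fitted) / (vc @ vc)), coef

        r2_obs, coef = r2_of(v)
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else np.zeros_like(coef)
        hits = 0
        total = 0
        for perm in _perm_iter(len(v), n_perm, exhaustive, seed):
            total += 1
            if r2_of(v[perm])[0] >= r2_obs - 1e-12:
                hits += 1
        p = hits / total if exhaustive else (1 + hits) / (1 + total)
        results.append(
            EnvfitResult(
                variable=str(name), direction=direction, r_squared=r2_obs,
                p_value=p, n_permutations=total,
            )
        )
    return results
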