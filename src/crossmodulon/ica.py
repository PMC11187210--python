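"""Robust independent component analysis of an omics compendium.

A compendium X (features x samples) is decomposed as X ~ M A, where the
columns of M are independently modulated feature-weight signatures and
the rows of A their condition-dependent activities.  Single FastICA
runs are not reproducible — the algorithm is seeded stochastic — so the
decomposition here is a consensus over many restarts: components pooled
across runs are clustered by absolute-correlation distance and each
cluster found in at least half the runs contributes its centrotype as
one robust component.

Usage follows the model/results convention::

    decomp = RobustICA(X, k=12, n_runs=10, seed=0).fit()
    decomp.M, decomp.A, decomp.component_ev, decomp.summary()
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning


@dataclass
class Decomposition:
    """Robust (M, A) factor pair with explained-variance accounting.

    M columns have unit norm and are sign-oriented so the
    largest-magnitude weight is positive; A is the least-squares
    projection of the centered compendium onto M.
    """

    M: pd.DataFrame
    A: pd.DataFrame
    k: int
    n_runs: int
    seed: int
    component_ev: np.ndarray = field(default=None)
    cumulative_ev: float = float("nan")
    cluster_sizes: list = field(default_factory=list)
    n_converged: int = 0

    @property
    def n_components(self) -> int:
        return self.M.shape[1]

    def reconstruct(self) -> pd.DataFrame:
        return self.M @ self.A

    def summary(self) -> pd.DataFrame:
        """Per-component table: explained variance, restart support, size."""
        return pd.DataFrame(
            {
                "component": list(self.M.columns),
                "explained_variance": self.component_ev,
                "runs_support": self.cluster_sizes,
            }
        ).set_index("component")


def _orient_and_normalise(m: np.ndarray) -> np.ndarray:
    """Unit-norm columns, largest-magnitude weight positive."""
    m = m / np.linalg.norm(m, axis=0, keepdims=True)
    idx = np.argmax(np.abs(m), axis=0)
    signs = np.sign(m[idx, np.arange(m.shape[1])])
    signs[signs == 0] = 1.0
    return m * signs


def _center(X: pd.DataFrame) -> pd.DataFrame:
    return X.sub(X.mean(axis=1), axis=0)


class RobustICA:
    """Consensus FastICA decomposition of a features x samples matrix.

    Parameters
    ----------
    X
        Compendium (already log-transformed and reference-centered); row
        means are removed before whitening.
    k
        Whitening dimensionality and per-run component count; must be
        below min(n_features, n_samples).
    n_runs
        Number of FastICA restarts pooled into the consensus.
    seed
        Master seed; per-run sub-seeds derive from it.
    eps
        DBSCAN neighborhood radius on the 1 - |Pearson r| distance.
    min_cluster_frac
        A cluster must appear in at least this fraction of runs
        (default half) to yield a robust component.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        k: int,
        n_runs: int = 10,
        seed: int = 0,
        *,
        eps: float = 0.1,
        min_cluster_frac: float = 0.5,
        max_iter: int = 1000,
        tol: float = 1e-6,
        max_retries: int = 3,
    ):
        if k >= min(X.shape):
            raise ValueError(
                f"k={k} must be below min(n_features, n_samples)={min(X.shape)}"
            )
        if n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        self.X = X
        self.k = int(k)
        self.n_runs = int(n_runs)
        self.seed = int(seed)
        self.eps = eps
        self.min_cluster_frac = min_cluster_frac
        self.max_iter = max_iter
        self.tol = tol
        self.max_retries = max_retries

    def _single_run(self, sub_seed: int) -> np.ndarray | None:
        """One FastICA restart; returns features x k weights or None."""
        ica = FastICA(
            n_components=self.k,
            whiten="unit-variance",
            random_state=sub_seed,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                S = ica.fit_transform(self._Xdc)
            except ConvergenceWarning:
                return None
        return S

    def fit(self) -> Decomposition:
        self._Xc = _center(self.X)
        # FastICA additionally removes the mean over the feature axis;
        # pre-removing it keeps each run's sources in a space consistent
        # across runs (the ALS pass below maps back to the row-centered X)
        xc = self._Xc.to_numpy()
        self._Xdc = xc - xc.mean(axis=0, keepdims=True)
        rng = np.random.default_rng(self.seed)
        sub_seeds = rng.integers(0, 2**31 - 1, size=self.n_runs + self.max_retries)
        runs: list[np.ndarray] = []
        next_seed = 0
        attempts = 0
        while len(runs) < self.n_runs and next_seed < len(sub_seeds):
            S = self._single_run(int(sub_seeds[next_seed]))
            next_seed += 1
            attempts += 1
            if S is not None:
                runs.append(_orient_and_normalise(S))
        if not runs:
            raise RuntimeError("no FastICA run converged")
        if len(runs) < self.n_runs:
            warnings.warn(
                f"only {len(runs)} of {self.n_runs} ICA runs converged",
                RuntimeWarning,
            )
        pooled = np.hstack(runs)  # features x (k * n_converged)
        M, cluster_sizes = self._consensus(pooled, len(runs))
        # one alternating-least-squares pass: sklearn's FastICA removes the
        # per-sample mean over features, so centrotypes live in a slightly
        # shifted space; regressing Xc back onto the projected activities
        # realigns M with the row-centered data it must reconstruct
        Xc = self._Xc.to_numpy()
        A = np.linalg.pinv(M) @ Xc
        M = _orient_and_normalise(Xc @ np.linalg.pinv(A))
        features = self.X.index
        comp_names = [f"ic_{i}" for i in range(M.shape[1])]
        M_df = pd.DataFrame(M, index=features, columns=comp_names)
        A_df = pd.DataFrame(
            np.linalg.pinv(M) @ Xc,
            index=comp_names,
            columns=self.X.columns,
        )
        decomp = Decomposition(
            M=M_df,
            A=A_df,
            k=self.k,
            n_runs=self.n_runs,
            seed=self.seed,
            cluster_sizes=cluster_sizes,
            n_converged=len(runs),
        )
        decomp.component_ev = component_explained_variance(decomp, self.X)
        decomp.cumulative_ev = cumulative_explained_variance(decomp, self.X)
        return decomp

    def _consensus(self, pooled: np.ndarray, n_converged: int):
        """Cluster pooled run components; centrotype per stable cluster."""
        corr = np.corrcoef(pooled.T)
        dist = np.clip(1.0 - np.abs(corr), 0.0, None)
        np.fill_diagonal(dist, 0.0)
        min_size = max(2, math.ceil(n_converged * self.min_cluster_frac))
        if n_converged == 1:
            return pooled, [1] * pooled.shape[1]
        labels = DBSCAN(
            eps=self.eps, min_samples=min_size, metric="precomputed"
        ).fit_predict(dist)
        centrotypes, sizes = [], []
        for lab in sorted(set(labels) - {-1}):
            members = np.flatnonzero(labels == lab)
            # centrotype: member most correlated with the rest of its cluster
            sub = np.abs(corr[np.ix_(members, members)])
            centro = members[np.argmax(sub.sum(axis=1))]
            centrotypes.append(pooled[:, centro])
            sizes.append(int(members.size))
        if not centrotypes:
            raise RuntimeError(
                "no component was reproducible across runs; "
                "consider lowering k or increasing n_runs"
            )
        order = np.argsort(sizes)[::-1]
        M = _orient_and_normalise(
            np.column_stack([centrotypes[i] for i in order])
        )
        return M, [sizes[i] for i in order]


def run_robust_ica(
    X: pd.DataFrame, k: int, n_runs: int = 10, seed: int = 0, **kwargs
) -> Decomposition:
    """Functional wrapper around :class:`RobustICA`."""
    return RobustICA(X, k, n_runs, seed, **kwargs).fit()


def component_explained_variance(decomp: Decomposition, X: pd.DataFrame) -> np.ndarray:
    """Per-component EV on the centered matrix.

    EV_j = 1 - ||Xc - m_j a_j||_F^2 / ||Xc||_F^2, one component at a
    time; components are not exactly orthogonal so these need not sum to
    the cumulative EV.
    """
    Xc = _center(X).to_numpy()
    total = float((Xc**2).sum())
    if total == 0:
        raise ValueError("zero-variance matrix has no explained variance")
    M = decomp.M.to_numpy()
    A = decomp.A.to_numpy()
    evs = np.empty(M.shape[1])
    for j in range(M.shape[1]):
        resid = Xc - np.outer(M[:, j], A[j])
        evs[j] = max(0.0, 1.0 - float((resid**2).sum()) / total)
    return evs


def cumulative_explained_variance(decomp: Decomposition, X: pd.DataFrame) -> float:
    """EV of the full reconstruction M A."""
    Xc = _center(X).to_numpy()
    total = float((Xc**2).sum())
    if total == 0:
        raise ValueError("zero-variance matrix has no explained variance")
    resid = Xc - decomp.M.to_numpy() @ decomp.A.to_numpy()
    return max(0.0, 1.0 - float((resid**2).sum()) / total)


def select_dimensionality(
    X: pd.DataFrame,
    candidate_ks,
    n_runs: int = 10,
    seed: int = 0,
    **kwargs,
):
    """Pick the ICA dimensionality by the robust-component plateau.

    Robust ICA is run at each candidate k; the score of a candidate is
    its number of robust components with more than one thresholded
    member (single-feature components are artifacts of over-splitting).
    Returns the smallest k whose score comes within one component of the
    maximum, plus the per-candidate diagnostics.
    """
    from .imodulons import threshold_component

    ks = sorted(int(k) for k in candidate_ks)
    counts: dict[int, int] = {}
    any_converged = False
    for k in ks:
        try:
            d = run_robust_ica(X, k, n_runs, seed, **kwargs)
        except RuntimeError:
            counts[k] = 0
            continue
        any_converged = True
        n_multi = 0
        for col in d.M.columns:
            _, members = threshold_component(d.M[col])
            if len(members) > 1:
                n_multi += 1
        counts[k] = n_multi
    if not any_converged:
        if len(ks) == 1:
            return ks[0], counts
        raise ValueError(f"all candidate dimensionalities degenerate: {counts}")
    best = max(counts.values())
    chosen = min(k for k, c in counts.items() if c >= best - 1)
    return chosen, counts
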