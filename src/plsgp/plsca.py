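"""Two-block canonical partial least squares and percentile marker selection.

Given column-standardized marker and trait blocks X (n x m) and Y (n x t),
each component finds unit-norm loading vectors (u, v) maximizing
Cov(Xu, Yv) — the leading singular pair of X'Y — and then deflates *both*
blocks on their own latent scores (canonical mode), which makes successive
latent scores orthogonal within each block.

Marker prioritization truncates the loading vector u of each component at a
percentile of its empirical distribution.  One-tailed selection keeps the
markers with the highest positive loadings (positive pleiotropy); two-tailed
selection keeps both tails, capturing markers whose effects oppose each
other across traits (negative pleiotropy).  Selections are combined across
components by union and binarized into 0/1 weights for the weighted
relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LoadingsSet:
    """Per-component loadings and score covariances from a PLS-CA fit."""

    u: np.ndarray          # (n_markers, n_components), unit columns
    v: np.ndarray          # (n_traits, n_components), unit columns
    score_cov: np.ndarray  # (n_components,) covariance of t_k = X_k u_k, s_k
    x_scale: tuple[np.ndarray, np.ndarray]  # column means, sds of X
    y_scale: tuple[np.ndarray, np.ndarray]

    @property
    def n_components(self) -> int:
        return self.u.shape[1]


@dataclass(frozen=True)
class SelectionScenario:
    """mode in {one_tailed, two_tailed}; percentile in (0, 100)."""

    mode: str
    percentile: float
    n_components: int

    def __post_init__(self) -> None:
        if self.mode not in ("one_tailed", "two_tailed"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

    def label(self) -> str:
        return f"{self.mode}_p{self.percentile:g}_c{self.n_components}"


@dataclass
class MarkerWeightVector:
    """Binary per-marker weights produced by a selection scenario."""

    weights: np.ndarray
    scenario: SelectionScenario | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isin(self.weights, (0.0, 1.0)).all():
            raise ValueError("weights must be 0/1")
        if self.weights.sum() < 1:
            raise ValueError("no markers selected")

    @property
    def n_selected(self) -> int:
        return int(self.weights.sum())


def standardize(block: np.ndarray, name: str = "block"
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale columns to zero mean, unit variance (ddof 1)."""
    block = np.asarray(block, dtype=float)
    mean = block.mean(axis=0)
    sd = block.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"constant column(s) in {name}: indices "
                         f"{zero[:5].tolist()}")
    return (block - mean) / sd, mean, sd


def fit_plsca(X: np.ndarray, Y: np.ndarray, n_components: int,
              scale: bool = True) -> LoadingsSet:
    """Fit canonical two-block PLS by SVD of the cross-product.

    Sign convention: each (u_k, v_k) pair is flipped jointly so the
    largest-magnitude entry of v_k is positive, making selection tails
    reproducible across platforms.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, t = Y.shape
    if n_components > t:
        raise ValueError("n_components exceeds number of traits")
    if scale:
        Xk, xm, xs = standardize(X, "X (markers)")
        Yk, ym, ys = standardize(Y, "Y (traits)")
    else:
        Xk, xm, xs = X.copy(), np.zeros(X.shape[1]), np.ones(X.shape[1])
        Yk, ym, ys = Y.copy(), np.zeros(t), np.ones(t)

    U = np.empty((X.shape[1], n_components))
    V = np.empty((t, n_components))
    score_cov = np.empty(n_components)
    for k in range(n_components):
        C = Xk.T @ Yk
        # leading singular pair of the (m x t) cross-product; t is small so
        # work in the t x t space
        uu, ss, vvt = np.linalg.svd(C, full_matrices=False)
        u, v = uu[:, 0], vvt[0]
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            u, v = -u, -v
        tk = Xk @ u
        sk = Yk @ v
        U[:, k], V[:, k] = u, v
        score_cov[k] = float(tk @ sk) / (n - 1)
        # canonical deflation: regress each block on its own score
        Xk = Xk - np.outer(tk, tk @ Xk) / (tk @ tk)
        Yk = Yk - np.outer(sk, sk @ Yk) / (sk @ sk)
    return LoadingsSet(U, V, score_cov, (xm, xs), (ym, ys))


def _quantile(values: np.ndarray, percentile: float) -> float:
    """Empirical quantile, linear interpolation at h = 1 + (p/100)(n-1)."""
    return float(np.quantile(values, percentile / 100.0,
                             method="linear"))


def select_one_tailed(loadings: np.ndarray, percentile: float) -> np.ndarray:
    """Indices of loadings >= the percentile threshold (upper tail).

    For n distinct loadings the selected count has the closed form
    n - ceil(h) + 1 if h = 1 + (p/100)(n-1) is integral, else n - floor(h);
    ties at the threshold are all included.
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.size < 2:
        raise ValueError("need at least 2 loadings")
    thr = _quantile(loadings, percentile)
    return np.flatnonzero(loadings >= thr)


def select_two_tailed(loadings: np.ndarray, percentile: float) -> np.ndarray:
    """Union of the upper tail at p and the lower tail at 100-p."""
    loadings = np.asarray(loadings, dtype=float)
    if loadings.size < 2:
        raise ValueError("need at least 2 loadings")
    hi = _quantile(loadings, percentile)
    lo = _quantile(loadings, 100.0 - percentile)
    return np.flatnonzero((loadings >= hi) | (loadings <= lo))


def combine_components(selections: list[np.ndarray],
                       n_markers: int) -> np.ndarray:
    """Union of per-component index sets as a 0/1 weight vector."""
    if not selections:
        raise ValueError("no component selections given")
    w = np.zeros(n_markers)
    for idx in selections:
        w[np.asarray(idx, dtype=int)] = 1.0
    if w.sum() == 0:
        raise ValueError("empty union of selections")
    return w


def scenario_weights(X: np.ndarray, Y: np.ndarray,
                     scenario: SelectionScenario,
                     loadings: LoadingsSet | None = None
                     ) -> MarkerWeightVector:
    """Fit PLS-CA (unless given) and apply the scenario's tail selection."""
    if loadings is None:
        loadings = fit_plsca(X, Y, scenario.n_components)
    if loadings.n_components < scenario.n_components:
        raise ValueError("loadings have fewer components than the scenario")
    select = (select_one_tailed if scenario.mode == "one_tailed"
              else select_two_tailed)
    sets = [select(loadings.u[:, k], scenario.percentile)
            for k in range(scenario.n_components)]
    w = combine_components(sets, loadings.u.shape[0])
    return MarkerWeightVector(w, scenario)


def one_tailed_count(n: int, percentile: float) -> int:
    """Closed-form selected count for n *distinct* loadings."""
    h = 1.0 + (percentile / 100.0) * (n - 1)
    if float(h).is_integer():
        return n - int(h) + 1
    return n - int(np.floor(h))
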