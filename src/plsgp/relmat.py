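"""Relationship matrices: pedigree A, VanRaden G and weighted G_w.

The genomic relationship matrix follows VanRaden's first method,

    G = Z Z' / (2 * sum_i p_i (1 - p_i)),

with Z = M - P the dosage matrix centered by twice the alternative-allele
frequency of the analyzed sample.  The weighted matrix keeps the form used
for trait-specific relationship matrices,

    G_w = Z W Z' / sum_i w_i,

with a diagonal weight matrix W; with 0/1 weights this is the cross-product
over the selected markers divided by the number selected.  Note the two
denominators differ deliberately: G_w carries no heterozygosity term, so its
scale is not VanRaden's (a rescale flag is provided for convenience).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import GenotypeMatrix, Pedigree


@dataclass
class RelMatrix:
    """Labeled dense symmetric relationship matrix."""

    labels: list[str]
    values: np.ndarray
    kind: str  # pedigree_A | vanraden_G | weighted_Gw
    jitter: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("labels do not match matrix shape")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ValueError("relationship matrix is asymmetric")

    def align(self, ids: list[str]) -> "RelMatrix":
        """Reorder/subset to the given ids (all must be present)."""
        index = {s: i for i, s in enumerate(self.labels)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"ids missing from relationship matrix: "
                           f"{missing[:5]}")
        rows = np.array([index[s] for s in ids])
        return RelMatrix(list(ids), self.values[np.ix_(rows, rows)],
                         self.kind, self.jitter)


def ensure_psd(rel: RelMatrix, eps: float = 1e-6,
               tol: float = 1e-8) -> RelMatrix:
    """Add a small diagonal jitter if the smallest eigenvalue is < tol.

    G is rank deficient whenever markers < individuals or genotypes are
    duplicated; the jitter makes downstream factorizations safe and is
    recorded on the returned matrix.
    """
    w = np.linalg.eigvalsh(rel.values)
    if w[0] >= tol:
        return rel
    shift = eps + max(0.0, -w[0])
    return RelMatrix(rel.labels, rel.values + shift * np.eye(len(rel.labels)),
                     rel.kind, rel.jitter + shift)


def filter_markers(g: GenotypeMatrix, min_maf: float = 0.0,
                   min_call_rate: float = 0.0) -> GenotypeMatrix:
    """Keep markers with MAF >= min_maf and call rate >= min_call_rate."""
    if not (0.0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    if not (0.0 <= min_call_rate <= 1.0):
        raise ValueError("min_call_rate must be in [0, 1]")
    p = g.allele_freqs
    maf = np.minimum(p, 1.0 - p)
    with np.errstate(invalid="ignore"):
        keep = (maf >= min_maf) & (g.call_rates >= min_call_rate)
    keep &= ~np.isnan(p)  # all-missing markers never pass
    if not keep.any():
        raise ValueError("all markers removed by filtering; "
                         "lower min_maf/min_call_rate")
    return g.subset_markers(keep)


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the marker mean dosage (allele freqs kept)."""
    if np.isnan(g.dosages).all(axis=0).any():
        raise ValueError("all-missing marker column; filter before imputing")
    dos = g.dosages.copy()
    means = np.nanmean(dos, axis=0)
    idx = np.where(np.isnan(dos))
    dos[idx] = means[idx[1]]
    return GenotypeMatrix(list(g.individual_ids), list(g.marker_ids), dos)


def centered_dosages(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (Z, P, denom): Z = M - P, P = 2p, denom = 2*sum p(1-p)."""
    if np.isnan(g.dosages).any():
        raise ValueError("genotypes contain missing values; impute first")
    p = g.dosages.mean(axis=0) / 2.0
    Z = g.dosages - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    return Z, 2.0 * p, denom


def build_A(ped: Pedigree) -> RelMatrix:
    """Numerator relationship matrix by the recursive tabular method."""
    ids = ped.ids
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, rec in enumerate(ped.records):
        s = index.get(rec.sire) if rec.sire is not None else None
        d = index.get(rec.dam) if rec.dam is not None else None
        for j in range(i):
            a = 0.0
            if s is not None:
                a += 0.5 * A[j, s]
            if d is not None:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None
                         else 0.0)
    return RelMatrix(ids, A, "pedigree_A")


def build_G(g: GenotypeMatrix, jitter: float = 0.0) -> RelMatrix:
    """VanRaden genomic relationship matrix from complete genotypes."""
    Z, _, denom = centered_dosages(g)
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: VanRaden denominator is 0")
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0
    if jitter:
        G = G + jitter * np.eye(G.shape[0])
    return RelMatrix(list(g.individual_ids), G, "vanraden_G", jitter)


def build_Gw(g: GenotypeMatrix, weights: np.ndarray,
             vanraden_scale: bool = False, jitter: float = 0.0) -> RelMatrix:
    """Weighted relationship matrix G_w = Z W Z' / sum(w).

    With ``vanraden_scale`` the denominator is instead 2*sum_{selected}
    p(1-p) computed over markers with nonzero weight (off by default; the
    plain sum-of-weights denominator is the printed definition).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (g.n_markers,):
        raise ValueError("weight vector length does not match marker count")
    if (w < 0).any():
        raise ValueError("negative marker weight")
    if w.sum() <= 0:
        raise ValueError("sum of weights is zero")
    Z, P, _ = centered_dosages(g)
    if vanraden_scale:
        p = P / 2.0
        denom = 2.0 * float(np.sum(w * p * (1.0 - p)))
        if denom <= 0:
            raise ValueError("selected markers are all monomorphic")
    else:
        denom = float(w.sum())
    G = (Z * w) @ Z.T / denom
    G = (G + G.T) / 2.0
    if jitter:
        G = G + jitter * np.eye(G.shape[0])
    return RelMatrix(list(g.individual_ids), G, "weighted_Gw", jitter)


def matrix_correlation(a: RelMatrix, b: RelMatrix) -> float:
    """Pearson correlation of the lower triangles (diagonal included)."""
    if a.labels != b.labels:
        raise ValueError("relationship matrices have different labels")
    il = np.tril_indices(len(a.labels))
    x, y = a.values[il], b.values[il]
    return float(np.corrcoef(x, y)[0, 1])


def grm_summaries(g: GenotypeMatrix, rel: RelMatrix,
                  n_bins: int = 50) -> dict:
    """Observed heterozygosity plus diagonal/off-diagonal histograms."""
    obs = ~np.isnan(g.dosages)
    het = float((g.dosages == 1.0)[obs].sum() / obs.sum())
    diag = np.diag(rel.values)
    off = rel.values[np.tril_indices(len(rel.labels), k=-1)]
    return {
        "heterozygosity": het,
        "diag_hist": np.histogram(diag, bins=n_bins),
        "offdiag_hist": np.histogram(off, bins=n_bins),
        "mean_diag": float(diag.mean()),
        "mean_offdiag": float(off.mean()) if off.size else float("nan"),
    }
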