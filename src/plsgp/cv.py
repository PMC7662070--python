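"""Cross-validated accuracy and scenario comparison.

Ten-fold cross-validation with *in-fold* marker selection: within each
fold the PLS-CA loadings are computed from training individuals only, the
weighted relationship matrix is then built over all individuals, and the
multi-trait sampler is fit with the validation individuals' phenotypes
masked (data augmentation), so their GEBVs arise purely through
relatedness.  Accuracy is the Pearson correlation between reference
breeding values and cross-validated GEBVs, computed per fold and then
averaged (the fold SD is the reported spread).

Scenario grids cover the benchmarks (univariate BLUP/GBLUP, multivariate
MVBLUP/MVGBLUP) and every selection cell (mode x percentile x components);
scenarios are ranked by full-data DIC, and accuracy-DIC / accuracy-marker-
count correlations summarize how well model fit predicts accuracy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import (MCMCConfig, compute_dic, gibbs_multitrait,
                    gibbs_univariate, summarize_posterior)
from .genio import GenotypeMatrix
from .plsca import (MarkerWeightVector, SelectionScenario, fit_plsca,
                    scenario_weights)
from .relmat import RelMatrix, build_G, build_Gw


@dataclass
class CVPlan:
    """Random partition of individuals into folds of near-equal size."""

    n_folds: int
    assignment: pd.Series  # fold index per individual id
    seed: int

    def fold_ids(self, k: int) -> list[str]:
        return list(self.assignment.index[self.assignment == k])


@dataclass
class ScenarioResult:
    """Accuracy and model-fit record for one prediction scenario."""

    name: str
    accuracy: pd.DataFrame        # folds x traits, per-fold correlations
    accuracy_mean: pd.Series
    accuracy_sd: pd.Series
    dic: float | None = None
    n_selected: int | None = None
    scenario: SelectionScenario | None = None
    flags: list[str] = field(default_factory=list)


def make_folds(ids: list[str], n_folds: int = 10, seed: int = 0) -> CVPlan:
    ids = [str(s) for s in ids]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(ids):
        raise ValueError("more folds than individuals")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xf01d]))
    perm = rng.permutation(len(ids))
    assign = np.empty(len(ids), dtype=int)
    # remainder spread one-per-fold so sizes differ by at most 1
    assign[perm] = np.arange(len(ids)) % n_folds
    return CVPlan(n_folds, pd.Series(assign, index=ids), seed)


def _fold_weights(X: np.ndarray, Y: np.ndarray,
                  scenario: SelectionScenario) -> MarkerWeightVector:
    """In-fold PLS-CA weights; fold-constant markers get weight 0."""
    sd = X.std(axis=0, ddof=1)
    poly = sd > 0
    if not poly.all():
        w = np.zeros(X.shape[1])
        sub = scenario_weights(X[:, poly], Y, scenario)
        w[np.flatnonzero(poly)] = sub.weights
        return MarkerWeightVector(w, scenario)
    return scenario_weights(X, Y, scenario)


def run_cv(genotypes: GenotypeMatrix | None, Y: pd.DataFrame,
           reference: pd.DataFrame, plan: CVPlan,
           scenario: SelectionScenario | None = None,
           kernel: RelMatrix | None = None,
           mcmc: MCMCConfig | None = None,
           univariate: bool = False,
           name: str | None = None) -> ScenarioResult:
    """Cross-validated prediction accuracy for one scenario.

    ``Y`` holds (corrected) phenotypes, ``reference`` the values accuracy
    is measured against (true breeding values on synthetic data, full-data
    EBVs on real data); both are indexed by individual id.  Either a fixed
    ``kernel`` (benchmarks) or a ``scenario`` with ``genotypes`` (in-fold
    selection) must be given.
    """
    mcmc = mcmc or MCMCConfig()
    ids = [str(i) for i in Y.index]
    if scenario is None and kernel is None:
        raise ValueError("provide a kernel or a selection scenario")
    if scenario is not None and genotypes is None:
        raise ValueError("selection scenarios need genotypes")
    if genotypes is not None:
        genotypes = genotypes.subset_individuals(ids)

    accs = np.full((plan.n_folds, Y.shape[1]), np.nan)
    flags = []
    n_selected = None
    for k in range(plan.n_folds):
        val = [i for i in ids if plan.assignment[i] == k]
        train = [i for i in ids if plan.assignment[i] != k]
        if len(val) < 3:
            flags.append(f"fold {k}: <3 validation individuals, skipped")
            continue
        if scenario is not None:
            # leakage guard: PLS-CA sees training rows only
            tr_idx = [ids.index(i) for i in train]
            assert set(train).isdisjoint(val)
            Xtr = genotypes.dosages[tr_idx]
            Ytr = Y.loc[train].to_numpy(dtype=float)
            if np.isnan(Ytr).any():
                raise ValueError("PLS-CA requires complete training "
                                 "phenotypes")
            w = _fold_weights(Xtr, Ytr, scenario)
            n_selected = w.n_selected
            fold_kernel = build_Gw(genotypes, w.weights)
        else:
            fold_kernel = kernel
        Ymask = Y.copy()
        Ymask.loc[val] = np.nan
        if univariate:
            gebv_cols = {}
            for j, tr in enumerate(Y.columns):
                fit = gibbs_univariate(Ymask[tr], fold_kernel,
                                       MCMCConfig(**{**mcmc.__dict__,
                                                     "seed": mcmc.seed
                                                     + 1000 * k + j}))
                gebv_cols[tr] = pd.Series(fit["gebv_mean"][:, 0],
                                          index=fit["ids"])
            gebv = pd.DataFrame(gebv_cols)
        else:
            fit = gibbs_multitrait(Ymask, fold_kernel,
                                   MCMCConfig(**{**mcmc.__dict__,
                                                 "seed": mcmc.seed
                                                 + 1000 * k}))
            gebv = pd.DataFrame(fit["gebv_mean"], index=fit["ids"],
                                columns=Y.columns)
        for j, tr in enumerate(Y.columns):
            ref = reference.loc[val].iloc[:, j].to_numpy(dtype=float)
            pred = gebv.loc[val, tr].to_numpy(dtype=float)
            ok = ~np.isnan(ref)
            if ok.sum() >= 3 and np.std(pred[ok]) > 0 and np.std(ref[ok]) > 0:
                accs[k, j] = np.corrcoef(ref[ok], pred[ok])[0, 1]

    acc = pd.DataFrame(accs, columns=list(Y.columns))
    label = name or (scenario.label() if scenario is not None
                     else (kernel.kind if kernel is not None else "scenario"))
    return ScenarioResult(
        name=label, accuracy=acc,
        accuracy_mean=acc.mean(axis=0, skipna=True),
        accuracy_sd=acc.std(axis=0, ddof=1),
        n_selected=n_selected, scenario=scenario, flags=flags,
    )


def full_data_dic(genotypes: GenotypeMatrix | None, Y: pd.DataFrame,
                  scenario: SelectionScenario | None = None,
                  kernel: RelMatrix | None = None,
                  mcmc: MCMCConfig | None = None) -> tuple[float, int | None]:
    """DIC of the full-data multivariate fit used for scenario ranking."""
    mcmc = mcmc or MCMCConfig()
    n_selected = None
    if scenario is not None:
        ids = [str(i) for i in Y.index]
        genotypes = genotypes.subset_individuals(ids)
        w = _fold_weights(genotypes.dosages, Y.to_numpy(dtype=float),
                          scenario)
        n_selected = w.n_selected
        kernel = build_Gw(genotypes, w.weights)
    fit = gibbs_multitrait(Y, kernel, mcmc)
    dic, _ = compute_dic(fit)
    return dic, n_selected


def run_scenario_grid(genotypes: GenotypeMatrix, Y: pd.DataFrame,
                      reference: pd.DataFrame, pedigree_kernel: RelMatrix,
                      plan: CVPlan,
                      percentiles: tuple[float, ...] = (90, 80, 70, 60, 50),
                      components: tuple[int, ...] | None = None,
                      modes: tuple[str, ...] = ("one_tailed", "two_tailed"),
                      mcmc: MCMCConfig | None = None,
                      with_dic: bool = True) -> list[ScenarioResult]:
    """Benchmarks plus the full mode x percentile x components grid."""
    mcmc = mcmc or MCMCConfig()
    if components is None:
        components = tuple(range(1, Y.shape[1] + 1))
    G = build_G(genotypes.subset_individuals([str(i) for i in Y.index]))
    results = []
    bench = [("BLUP", pedigree_kernel, True), ("GBLUP", G, True),
             ("MVBLUP", pedigree_kernel, False), ("MVGBLUP", G, False)]
    for bname, kern, uni in bench:
        res = run_cv(None, Y, reference, plan, kernel=kern, mcmc=mcmc,
                     univariate=uni, name=bname)
        if with_dic and not uni:
            res.dic, _ = full_data_dic(None, Y, kernel=kern, mcmc=mcmc)
        results.append(res)
    for mode, pct, nc in itertools.product(modes, percentiles, components):
        scen = SelectionScenario(mode, pct, nc)
        try:
            res = run_cv(genotypes, Y, reference, plan, scenario=scen,
                         mcmc=mcmc)
            if with_dic:
                res.dic, res.n_selected = full_data_dic(
                    genotypes, Y, scenario=scen, mcmc=mcmc)
        except Exception as exc:  # record the failure, keep the grid going
            res = ScenarioResult(scen.label(),
                                 pd.DataFrame(columns=list(Y.columns)),
                                 pd.Series(dtype=float),
                                 pd.Series(dtype=float),
                                 scenario=scen, flags=[f"failed: {exc}"])
        results.append(res)
    results.sort(key=lambda r: (r.dic is None, r.dic))
    return results


def results_table(results: list[ScenarioResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"scenario": r.name, "dic": r.dic, "n_selected": r.n_selected}
        for tr in r.accuracy_mean.index:
            row[f"acc_{tr}"] = r.accuracy_mean[tr]
            row[f"sd_{tr}"] = r.accuracy_sd[tr]
        rows.append(row)
    return pd.DataFrame(rows)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank sum with (possibly tied) ranks.

    Enumerates the null distribution of W+ by dynamic programming over
    the doubled ranks (mid-ranks are half-integers, so doubling makes
    them integers).
    """
    r2 = np.round(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2.0 * w_plus))
    p_le = float(dist[:w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray,
                         exact_max_n: int = 25) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W+, two-sided p).

    Zero differences are dropped, ties mid-ranked.  The null distribution
    is enumerated exactly for n <= ``exact_max_n`` nonzero differences;
    larger samples use the normal approximation with continuity correction
    and a tie correction in the variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        import warnings

        warnings.warn("all differences are zero; p = 1")
        return 0.0, 1.0
    ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return w_plus, _signed_rank_exact_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    # variance with tie correction
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 \
        - (counts ** 3 - counts).sum() / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    from scipy.stats import norm

    return w_plus, float(2.0 * norm.sf(abs(z)))


def accuracy_dic_correlations(results: list[ScenarioResult]
                              ) -> pd.DataFrame:
    """Per-trait correlation of scenario accuracy with DIC and n_selected.

    Only selection scenarios (those with a DIC and a marker count) enter;
    constant columns give NaN with a flag column.
    """
    sel = [r for r in results
           if r.dic is not None and r.n_selected is not None]
    if len(sel) < 3:
        raise ValueError("need at least 3 scenarios with DIC and counts")
    dic = np.array([r.dic for r in sel])
    nm = np.array([r.n_selected for r in sel], dtype=float)
    traits = list(sel[0].accuracy_mean.index)
    rows = []
    for tr in traits:
        acc = np.array([r.accuracy_mean[tr] for r in sel])
        row = {"trait": tr}
        for label, other in (("dic", dic), ("n_markers", nm)):
            ok = ~np.isnan(acc)
            if np.std(acc[ok]) == 0 or np.std(other[ok]) == 0:
                row[f"cor_{label}"] = np.nan
                row[f"flag_{label}"] = "constant"
            else:
                row[f"cor_{label}"] = float(
                    np.corrcoef(acc[ok], other[ok])[0, 1])
                row[f"flag_{label}"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
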