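"""Synthetic family-structured breeding populations with known truth.

The generator emulates the two population types common in tree breeding
programs: full-sib families from pair crosses of founders, and
open-pollinated (half-sib) families where only the dam is recorded and the
pollen parent is an anonymous draw from the founder allele pool.  Markers
are unlinked biallelic SNPs; founders are drawn marker-wise from
binomial(2, p) with p uniform on a configurable band, offspring by
Mendelian gene dropping.  Clonal replication (ramets) duplicates a
genotype's breeding value across field positions.

Trait architecture: a subset of markers are pleiotropic QTLs whose effect
rows are drawn from a multivariate normal whose correlation is calibrated
so the realized genetic correlation approaches the target as the QTL count
grows; per-trait effects are then rescaled so realized additive variances
hit the target heritabilities exactly (phenotypic variance normalized to 1
per trait before design effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genio import GenotypeMatrix, Pedigree, PhenotypeTable, make_pedigree


@dataclass
class SimConfig:
    """Study-design and genetic-architecture settings for one simulation."""

    n_founders: int = 40
    mating: str = "full_sib"          # full_sib | half_sib_open_pollinated
    n_families: int = 42              # full-sib families (pair crosses)
    n_per_family: int = 10
    n_dams: int = 30                  # open-pollinated dams
    n_per_dam: int = 20
    n_ramets: int = 1                 # clonal replicates per genotype
    n_markers: int = 2000
    founder_freq_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 200
    pleiotropy: float = 1.0           # fraction of QTLs affecting all traits
    sign_flip_prob: float = 0.0       # negative-pleiotropy sign flips
    target_h2: tuple[float, ...] = (0.1, 0.4, 0.4)
    target_rG: np.ndarray | None = None   # defaults to identity
    n_replicates: int = 2
    n_blocks_per_replicate: int = 5
    replicate_sd: float = 0.5
    block_sd: float = 0.3
    residual_corr: np.ndarray | None = None  # defaults to identity
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def n_traits(self) -> int:
        return len(self.target_h2)

    def rg_matrix(self) -> np.ndarray:
        t = self.n_traits
        R = (np.eye(t) if self.target_rG is None
             else np.asarray(self.target_rG, dtype=float))
        if R.shape != (t, t) or np.abs(R - R.T).max() > 1e-12 \
                or np.abs(np.diag(R) - 1).max() > 1e-12:
            raise ValueError("target_rG must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R)[0] < -1e-10:
            raise ValueError("target_rG is not positive semidefinite")
        return R

    def validate(self) -> None:
        lo, hi = self.founder_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("founder frequency range must lie inside (0,1)")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl exceeds n_markers")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0,1)")
        if any(not 0.0 < h < 1.0 for h in self.target_h2):
            raise ValueError("target_h2 entries must lie in (0,1)")
        if self.n_ramets < 1 or self.n_founders < 2:
            raise ValueError("counts must be positive")
        self.rg_matrix()


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for recovery tests."""

    breeding_values: np.ndarray   # genotypes x traits
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray       # n_qtl x traits
    Sigma_a: np.ndarray           # empirical covariance of breeding values
    Sigma_e: np.ndarray
    h2: np.ndarray                # realized sigma_a^2/(sigma_a^2+sigma_e^2)
    genotype_ids: list[str] = field(default_factory=list)

    @property
    def rG(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.Sigma_a))
        return self.Sigma_a / np.outer(d, d)


def _gamete(parent_dosages: np.ndarray, rng: np.random.Generator
            ) -> np.ndarray:
    """One transmitted allele per marker: P(alt) = dosage/2."""
    return rng.binomial(1, parent_dosages / 2.0).astype(float)


def simulate_genotypes(config: SimConfig
                       ) -> tuple[GenotypeMatrix, Pedigree]:
    """Founder + progeny genotypes and the consistent pedigree."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 0x5e9]))
    lo, hi = config.founder_freq_range
    p = rng.uniform(lo, hi, size=config.n_markers)
    founders = rng.binomial(2, p, size=(config.n_founders, config.n_markers)
                            ).astype(float)
    founder_ids = [f"F{i:03d}" for i in range(config.n_founders)]
    ped_rows = [(fid, "0", "0") for fid in founder_ids]
    rows, ids = [], []

    if config.mating == "full_sib":
        for fam in range(config.n_families):
            s, d = rng.choice(config.n_founders, size=2, replace=False)
            for k in range(config.n_per_family):
                child = _gamete(founders[s], rng) + _gamete(founders[d], rng)
                cid = f"G{fam:03d}_{k:02d}"
                rows.append(child)
                ids.append(cid)
                ped_rows.append((cid, founder_ids[s], founder_ids[d]))
    elif config.mating == "half_sib_open_pollinated":
        dams = rng.choice(config.n_founders, size=config.n_dams,
                          replace=config.n_dams > config.n_founders)
        for fam, d in enumerate(dams):
            for k in range(config.n_per_dam):
                # anonymous pollen parent drawn from the founder allele pool
                pollen = rng.binomial(1, p).astype(float)
                child = _gamete(founders[d], rng) + pollen
                cid = f"G{fam:03d}_{k:02d}"
                rows.append(child)
                ids.append(cid)
                ped_rows.append((cid, "0", founder_ids[d]))
    else:
        raise ValueError(f"unknown mating design {config.mating!r}")

    dos = np.vstack([founders, np.array(rows)])
    all_ids = founder_ids + ids
    if config.missing_rate > 0:
        mask = rng.random(dos.shape) < config.missing_rate
        dos = dos.copy()
        dos[mask] = np.nan
    geno = GenotypeMatrix(all_ids, [f"M{j:05d}" for j in range(config.n_markers)],
                          dos)
    return geno, make_pedigree(ped_rows)


def build_effects(config: SimConfig, genotypes: GenotypeMatrix,
                  rng: np.random.Generator | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Sample QTL indices and a traits-calibrated effect matrix.

    Returns (qtl_indices, effects) with effects of shape (n_qtl, n_traits).
    The pleiotropic correlation target is inflated by the mixture factor
    (q_p + q_r/t) / q_p so that the blend of pleiotropic and single-trait
    QTLs has the requested correlation in expectation; an unattainable
    combination (inflated matrix not PSD or entries outside [-1,1]) raises.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed, 0xeff]))
    t, q = config.n_traits, config.n_qtl
    R = config.rg_matrix()
    qtl = rng.choice(config.n_markers, size=q, replace=False)
    q_p = int(round(config.pleiotropy * q))
    q_r = q - q_p
    effects = np.zeros((q, t))
    if q_p:
        if q_r:
            infl = (q_p + q_r / t) / q_p
            Rstar = R * infl
            np.fill_diagonal(Rstar, 1.0)
            if np.abs(Rstar).max() > 1.0 + 1e-12 \
                    or np.linalg.eigvalsh(Rstar)[0] < -1e-10:
                raise ValueError(
                    "target_rG unattainable at this pleiotropy fraction")
        else:
            Rstar = R
        L = np.linalg.cholesky(Rstar + 1e-12 * np.eye(t))
        effects[:q_p] = rng.standard_normal((q_p, t)) @ L.T
        if config.sign_flip_prob > 0:
            # negative pleiotropy: flip this QTL's non-primary trait effects
            primary = rng.integers(t, size=q_p)
            flip = rng.random((q_p, t)) < config.sign_flip_prob
            flip[np.arange(q_p), primary] = False
            effects[:q_p][flip] *= -1.0
    for i in range(q_r):
        effects[q_p + i, i % t] = rng.standard_normal()
    return qtl, effects


def _rescale_effects(dosages: np.ndarray, qtl: np.ndarray,
                     effects: np.ndarray, sigma_a: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal rescale so realized per-trait BV variance = sigma_a^2."""
    Zq = dosages[:, qtl] - dosages[:, qtl].mean(axis=0)
    bv = Zq @ effects
    sd = bv.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("degenerate breeding values; increase n_qtl")
    scale = sigma_a / sd
    return effects * scale, bv * scale


def simulate_phenotypes(genotypes: GenotypeMatrix, qtl: np.ndarray,
                        effects: np.ndarray, config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[PhenotypeTable, SimTruth]:
    """Field-trial phenotypes: design effects + breeding value + residual.

    Phenotypic variance per trait is normalized to 1 before design effects:
    sigma_a^2 = h2, Sigma_e diagonal (1 - h2) unless residual correlations
    are configured.  Ramets of a genotype share its breeding value and
    differ in residual and design placement.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed, 0xbe7]))
    if np.isnan(genotypes.dosages).any():
        # truth is defined on the complete underlying genotypes
        raise ValueError("simulate phenotypes before applying missingness "
                         "or impute first")
    t = config.n_traits
    h2 = np.asarray(config.target_h2, dtype=float)
    sigma_a = np.sqrt(h2)
    effects, bv = _rescale_effects(genotypes.dosages, qtl, effects, sigma_a)
    sig_e = np.sqrt(1.0 - h2)  # h2 = sigma_a^2 / (sigma_a^2 + sigma_e^2)
    Re = (np.eye(t) if config.residual_corr is None
          else np.asarray(config.residual_corr, dtype=float))
    Sigma_e = Re * np.outer(sig_e, sig_e)
    Le = np.linalg.cholesky(Sigma_e + 1e-12 * np.eye(t))

    n = genotypes.n_individuals
    rep_eff = rng.normal(0.0, config.replicate_sd,
                         size=(config.n_replicates, t))
    blk_eff = rng.normal(0.0, config.block_sd,
                         size=(config.n_replicates,
                               config.n_blocks_per_replicate, t))
    recs = []
    values = []
    for i, gid in enumerate(genotypes.individual_ids):
        for r in range(config.n_ramets):
            rep = int(rng.integers(config.n_replicates))
            blk = int(rng.integers(config.n_blocks_per_replicate))
            e = Le @ rng.standard_normal(t)
            y = rep_eff[rep] + blk_eff[rep, blk] + bv[i] + e
            recs.append((gid, f"rep{rep}", f"rep{rep}_blk{blk}"))
            values.append(y)
    import pandas as pd

    df = pd.DataFrame(recs, columns=["id", "replicate", "block"])
    trait_cols = [f"trait{j + 1}" for j in range(t)]
    df[trait_cols] = np.array(values)
    pheno = PhenotypeTable(df, "id", ["replicate", "block"], trait_cols)

    Sigma_a = np.cov(bv, rowvar=False, ddof=0).reshape(t, t)
    realized_h2 = np.diag(Sigma_a) / (np.diag(Sigma_a) + np.diag(Sigma_e))
    truth = SimTruth(bv, qtl, effects, Sigma_a, Sigma_e, realized_h2,
                     list(genotypes.individual_ids))
    return pheno, truth


def simulate_study(config: SimConfig
                   ) -> tuple[GenotypeMatrix, Pedigree, PhenotypeTable,
                              SimTruth]:
    """Full pipeline: genotypes -> effects -> phenotypes (+ missingness)."""
    geno, ped = simulate_genotypes(
        SimConfig(**{**config.__dict__, "missing_rate": 0.0}))
    rng_eff = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 0xeff]))
    qtl, effects = build_effects(config, geno, rng_eff)
    pheno, truth = simulate_phenotypes(geno, qtl, effects, config)
    if config.missing_rate > 0:
        rng_miss = np.random.default_rng(np.random.SeedSequence(
            [config.seed, 0x3155]))
        dos = geno.dosages.copy()
        dos[rng_miss.random(dos.shape) < config.missing_rate] = np.nan
        geno = GenotypeMatrix(list(geno.individual_ids),
                              list(geno.marker_ids), dos)
    return geno, ped, pheno, truth
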