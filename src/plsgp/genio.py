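"""Readers, writers and core data containers.

File conventions: tab-separated text with a header row, ``NA`` as the
missing-value sentinel.  Genotypes are dosage-coded 0/1/2 counting the
*alternative* allele (0 = reference homozygote, 1 = heterozygote,
2 = alternative homozygote).  Pedigrees are three columns (id, sire, dam)
with ``0`` or an empty field for an unknown parent.
"""

from __future__ import annotations

import csv
import graphlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan
UNKNOWN_PARENT = "0"


class ParseError(ValueError):
    """Malformed input file."""


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, self-ancestry)."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with missingness.

    Dosages are floats so that ``NaN`` can encode missing calls; observed
    values are restricted to {0, 1, 2}.  Allele frequencies and call rates
    are computed over non-missing calls; a marker with no calls at all has
    an undefined (NaN) allele frequency and call rate 0.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # (n_ind, n_mark) float, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise ValueError("id lists do not match dosage dimensions")
        if len(set(self.individual_ids)) != n:
            raise ParseError("duplicate individual ids")
        if len(set(self.marker_ids)) != m:
            raise ParseError("duplicate marker ids")
        obs = self.dosages[~np.isnan(self.dosages)]
        # raw calls are {0,1,2}; mean-imputed cells may be fractional
        if obs.size and ((obs < 0) | (obs > 2)).any():
            bad = obs[(obs < 0) | (obs > 2)][0]
            raise ParseError(f"dosage value {bad!r} outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        """Per-marker alternative-allele frequency over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            marker_ids=[self.marker_ids[i] for i in keep],
            dosages=self.dosages[:, keep].copy(),
        )

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.individual_ids)}
        rows = [index[s] for s in ids]
        return GenotypeMatrix(list(ids), list(self.marker_ids),
                              self.dosages[rows].copy())


@dataclass
class PedigreeRecord:
    id: str
    sire: str | None
    dam: str | None


@dataclass
class Pedigree:
    """Topologically sorted pedigree (ancestors before descendants)."""

    records: list[PedigreeRecord]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PhenotypeTable:
    """Observation-level phenotypes with design factors.

    One row per measurement unit (e.g. ramet); ``factors`` columns are
    categorical, ``traits`` columns numeric with NaN for missing records.
    """

    data: pd.DataFrame
    id_col: str
    factor_cols: list[str]
    trait_cols: list[str]

    def __post_init__(self) -> None:
        if not self.trait_cols:
            raise ValueError("at least one trait column required")
        for c in self.factor_cols:
            self.data[c] = self.data[c].astype("category")
        for c in self.trait_cols:
            self.data[c] = pd.to_numeric(self.data[c])

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data[self.id_col].astype(str))


def _sort_pedigree(records: list[PedigreeRecord]) -> list[PedigreeRecord]:
    by_id = {r.id: r for r in records}
    ts: graphlib.TopologicalSorter = graphlib.TopologicalSorter()
    for r in records:
        parents = [p for p in (r.sire, r.dam) if p is not None]
        ts.add(r.id, *parents)
    try:
        order = list(ts.static_order())
    except graphlib.CycleError as exc:
        raise PedigreeError(f"pedigree contains a cycle: {exc.args[1]}") from exc
    out = []
    for name in order:
        if name not in by_id:
            warnings.warn(f"parent {name!r} has no pedigree record; "
                          "added as founder")
            by_id[name] = PedigreeRecord(name, None, None)
        out.append(by_id[name])
    return out


def make_pedigree(rows: list[tuple[str, str, str]]) -> Pedigree:
    """Build a sorted Pedigree from (id, sire, dam) string triples."""
    records = []
    seen = set()
    for ident, sire, dam in rows:
        ident = str(ident)
        if ident in seen:
            raise ParseError(f"duplicate pedigree id {ident!r}")
        seen.add(ident)
        records.append(PedigreeRecord(
            ident,
            None if str(sire) in (UNKNOWN_PARENT, "", "nan") else str(sire),
            None if str(dam) in (UNKNOWN_PARENT, "", "nan") else str(dam),
        ))
    return Pedigree(_sort_pedigree(records))


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ParseError("pedigree file needs three columns (id, sire, dam)")
    rows = [tuple(r) for r in df.iloc[:, :3].itertuples(index=False)]
    return make_pedigree(rows)


def write_pedigree(ped: Pedigree, path) -> None:
    df = pd.DataFrame(
        [(r.id, r.sire or UNKNOWN_PARENT, r.dam or UNKNOWN_PARENT)
         for r in ped.records],
        columns=["id", "sire", "dam"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path, format: str = "delimited",
                   strict: bool = True) -> GenotypeMatrix:
    """Read a genotype matrix from TSV (individuals x markers) or VCF.

    The delimited layout has marker ids in the header and individual ids in
    the first column.  VCF input is restricted to biallelic sites and uses
    only the GT field; the dosage counts copies of the alternative allele.
    ``strict`` requires raw calls in {0,1,2,NA}; pass ``strict=False`` when
    reading back mean-imputed matrices with fractional dosages.
    """
    if format == "delimited":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                         keep_default_na=False,
                         float_precision="round_trip")
        vals = df.to_numpy(dtype=object)
        dos = np.empty(vals.shape, dtype=float)
        for j in range(vals.shape[1]):
            for i in range(vals.shape[0]):
                v = vals[i, j]
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    dos[i, j] = np.nan
                    continue
                try:
                    f = float(v)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"bad genotype {v!r} at row {df.index[i]!r}, "
                        f"column {df.columns[j]!r}") from None
                if (f not in (0.0, 1.0, 2.0)) if strict \
                        else not 0.0 <= f <= 2.0:
                    raise ParseError(
                        f"bad genotype {v!r} at row {df.index[i]!r}, "
                        f"column {df.columns[j]!r}")
                dos[i, j] = f
        return GenotypeMatrix([str(s) for s in df.index],
                              [str(s) for s in df.columns], dos)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, columns = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ParseError(
                f"multiallelic record at {var.CHROM}:{var.POS} not supported")
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        marker_ids.append(name)
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                continue
            col[i] = float(sum(1 for a in alleles if a > 0))
        columns.append(col)
    vcf.close()
    dos = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, marker_ids, dos)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosages, index=g.individual_ids, columns=g.marker_ids)
    # integers where observed, NA where missing
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g",
              index_label="id")


def read_phenotypes(path, role_map: dict[str, str]) -> PhenotypeTable:
    """Read a phenotype/design table.

    ``role_map`` assigns each used column a role in {id, factor, trait};
    unmapped columns are dropped with a warning.
    """
    roles = set(role_map.values())
    if "id" not in roles:
        raise ParseError("role_map must assign an 'id' column")
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col, role in role_map.items():
        if col not in df.columns:
            raise ParseError(f"column {col!r} not present in {path}")
        if role not in ("id", "factor", "trait"):
            raise ParseError(f"unknown role {role!r} for column {col!r}")
    unmapped = [c for c in df.columns if c not in role_map]
    if unmapped:
        warnings.warn(f"ignoring unmapped columns {unmapped}")
    id_col = next(c for c, r in role_map.items() if r == "id")
    factor_cols = [c for c, r in role_map.items() if r == "factor"]
    trait_cols = [c for c, r in role_map.items() if r == "trait"]
    for c in trait_cols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (TypeError, ValueError) as exc:
            bad = df[c][pd.to_numeric(df[c], errors="coerce").isna()
                        & df[c].notna()]
            raise ParseError(
                f"non-numeric trait value {bad.iloc[0]!r} in column {c!r}, "
                f"row {bad.index[0]}") from exc
    df[id_col] = df[id_col].astype(str)
    keep = [id_col] + factor_cols + trait_cols
    return PhenotypeTable(df[keep].copy(), id_col, factor_cols, trait_cols)


def write_phenotypes(tbl: PhenotypeTable, path) -> None:
    tbl.data.to_csv(path, sep="\t", na_rep="NA", index=False,
                    float_format="%.17g")


def write_square_matrix(labels: list[str], values: np.ndarray, path,
                        tol: float = 1e-10) -> None:
    """Write a labeled symmetric matrix as TSV at 17 significant digits."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("matrix is not square")
    if np.abs(values - values.T).max(initial=0.0) > tol:
        raise ValueError("matrix is asymmetric beyond tolerance")
    df = pd.DataFrame(values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="id",
              quoting=csv.QUOTE_MINIMAL)


def read_square_matrix(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ParseError("matrix file is not square")
    return [str(s) for s in df.index], df.to_numpy(dtype=float)
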