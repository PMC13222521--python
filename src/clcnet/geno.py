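"""Genotype and phenotype handling.

Genotypes are alt-allele dosages coded 0/1/2 with 3 marking a missing call.
The missing code is kept literally when genotypes are fed to the prediction
network (the model is expected to learn to treat it as a distinct state);
statistical routines (r², GRM, GWAS) instead treat 3 as missing data.

Coordinates are 1-based inclusive (VCF convention). Within each chromosome
SNPs are kept in non-decreasing position order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_CODE = 3

__all__ = [
    "MISSING_CODE",
    "GenotypeMatrix",
    "PhenotypeTable",
    "TraitStandardizer",
    "PruneParams",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "join_samples",
    "ld_prune",
    "fit_standardizer",
    "apply_standardizer",
    "allele_frequencies",
    "minor_allele_frequencies",
    "imputed_dosages",
]


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype inputs."""


@dataclass
class GenotypeMatrix:
    """n samples × m SNPs of integer codes {0,1,2,3} plus a SNP map."""

    values: np.ndarray
    sample_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise GenotypeError("genotype matrix must have at least one sample and one SNP")
        if not np.isin(self.values, (0, 1, 2, 3)).all():
            raise GenotypeError("genotype codes must be in {0,1,2,3}")
        if len(self.sample_ids) != n:
            raise GenotypeError("sample_ids length mismatch")
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos) == m):
            raise GenotypeError("SNP map length mismatch")
        if len(set(self.snp_ids)) != m:
            raise GenotypeError("duplicate snp_id in SNP map")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise GenotypeError(f"positions not sorted within chromosome {c!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_indices(self, c) -> np.ndarray:
        return np.flatnonzero(self.chrom == c)

    def subset_samples(self, rows) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return replace(
            self, values=self.values[rows], sample_ids=self.sample_ids[rows]
        )

    def subset_snps(self, cols) -> "GenotypeMatrix":
        cols = np.asarray(cols)
        return replace(
            self,
            values=self.values[:, cols],
            snp_ids=self.snp_ids[cols],
            chrom=self.chrom[cols],
            pos=self.pos[cols],
        )


@dataclass
class PhenotypeTable:
    """Per-sample trait table; NaN marks a missing phenotype record."""

    sample_ids: np.ndarray
    traits: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if len(self.sample_ids) != len(self.traits):
            raise GenotypeError("phenotype sample_ids length mismatch")

    @property
    def trait_names(self) -> list:
        return list(self.traits.columns)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.asarray(vcf.samples, dtype=object)
    codes, snp_ids, chroms, poss = [], [], [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise GenotypeError(
                f"multi-allelic site at record {i + 1} ({var.CHROM}:{var.POS}); "
                "only biallelic SNPs are supported"
            )
        row = np.empty(len(sample_ids), dtype=np.int8)
        for j, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                row[j] = MISSING_CODE
            elif a > 1 or b > 1:
                raise GenotypeError(
                    f"allele index >1 at record {i + 1}; multi-allelic calls unsupported"
                )
            else:
                row[j] = a + b
        codes.append(row)
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        snp_ids.append(sid)
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not codes:
        raise GenotypeError(f"no variant records in {path}")
    if len(set(snp_ids)) != len(snp_ids):
        raise GenotypeError("duplicate snp_id in VCF")
    values = np.column_stack(codes)
    chroms = np.asarray(chroms, dtype=object)
    poss = np.asarray(poss, dtype=np.int64)
    snp_ids = np.asarray(snp_ids, dtype=object)
    # reorder to position order within chromosome, chromosome order of appearance
    rank = {c: k for k, c in enumerate(dict.fromkeys(chroms))}
    order = np.lexsort((poss, np.array([rank[c] for c in chroms])))
    return GenotypeMatrix(values[:, order], sample_ids, snp_ids[order],
                          chroms[order], poss[order])


def _read_matrix(path, map_path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeError(f"cannot parse genotype matrix {path}: {exc}") from exc
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "chrom", "pos"):
        if col not in snp_map.columns:
            raise GenotypeError(f"SNP map {map_path} lacks column {col!r}")
    if snp_map["snp_id"].duplicated().any():
        dup = snp_map.loc[snp_map["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise GenotypeError(f"duplicate snp_id {dup!r} in SNP map")
    if set(df.columns) != set(snp_map["snp_id"]):
        raise GenotypeError("genotype matrix header and SNP map disagree on SNP ids")
    df = df[snp_map["snp_id"].tolist()]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        bad = np.flatnonzero(~np.isfinite(values.astype(float)).all(axis=1))
        if len(bad):
            raise GenotypeError(f"non-numeric genotype value at data line {bad[0] + 1}")
        values = values.astype(np.int64)
    return GenotypeMatrix(
        values.astype(np.int8),
        df.index.to_numpy(dtype=object),
        snp_map["snp_id"].to_numpy(dtype=object),
        snp_map["chrom"].to_numpy(dtype=object),
        snp_map["pos"].to_numpy(),
    )


def read_genotypes(path, format: str = "matrix", map_path=None) -> GenotypeMatrix:
    """Read genotypes from a VCF or a delimited sample×SNP matrix.

    Parameters
    ----------
    path : path to the VCF or the matrix file (samples as rows, header of
        snp_ids, first column sample id, tab-separated).
    format : {"vcf", "matrix"}
    map_path : companion SNP map (tab-separated snp_id/chrom/pos) for the
        matrix dialect; defaults to ``<path stem>.map.tsv`` next to *path*.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        if map_path is None:
            base = str(path)
            for suf in (".geno.tsv", ".tsv", ".txt"):
                if base.endswith(suf):
                    base = base[: -len(suf)]
                    break
            map_path = base + ".map.tsv"
        return _read_matrix(path, map_path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(G: GenotypeMatrix, prefix) -> tuple:
    """Write ``<prefix>.geno.tsv`` and ``<prefix>.map.tsv``; returns paths."""
    prefix = str(prefix)
    geno_path, map_path = prefix + ".geno.tsv", prefix + ".map.tsv"
    pd.DataFrame(G.values, index=G.sample_ids, columns=G.snp_ids).to_csv(
        geno_path, sep="\t", index_label="sample_id"
    )
    pd.DataFrame({"snp_id": G.snp_ids, "chrom": G.chrom, "pos": G.pos}).to_csv(
        map_path, sep="\t", index=False
    )
    return geno_path, map_path


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id":
        raise GenotypeError("phenotype table must start with a sample_id column")
    df = df.set_index("sample_id")
    return PhenotypeTable(df.index.to_numpy(dtype=object), df)


def write_phenotypes(P: PhenotypeTable, path) -> None:
    out = P.traits.copy()
    out.insert(0, "sample_id", P.sample_ids)
    out.to_csv(path, sep="\t", index=False)


def join_samples(G: GenotypeMatrix, P: PhenotypeTable, trait: str):
    """Restrict to samples present in both inputs with an observed trait value.

    Output order follows the genotype matrix. Returns ``(G_sub, y)``.
    """
    if trait not in P.trait_names:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    tvals = pd.Series(P.traits[trait].to_numpy(), index=P.sample_ids)
    tvals = tvals[~tvals.index.duplicated()]
    keep_rows, y = [], []
    for i, sid in enumerate(G.sample_ids):
        if sid in tvals.index and np.isfinite(tvals[sid]):
            keep_rows.append(i)
            y.append(float(tvals[sid]))
    if not keep_rows:
        raise GenotypeError("no shared samples with an observed trait value")
    return G.subset_samples(np.asarray(keep_rows)), np.asarray(y, dtype=float)


# ---------------------------------------------------------------------------
# allele statistics helpers (missing-aware)
# ---------------------------------------------------------------------------

def allele_frequencies(values: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per SNP ignoring missing calls (NaN if all missing)."""
    v = np.array(values, dtype=float)
    v[np.asarray(values) == MISSING_CODE] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(v, axis=0) / 2.0


def minor_allele_frequencies(values: np.ndarray) -> np.ndarray:
    p = allele_frequencies(values)
    return np.minimum(p, 1.0 - p)


def imputed_dosages(values: np.ndarray) -> np.ndarray:
    """Float dosages with missing calls replaced by the per-SNP mean dosage."""
    v = np.array(values, dtype=float)
    miss = np.asarray(values) == MISSING_CODE
    v[miss] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(v, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    idx = np.where(miss)
    v[idx] = col_mean[idx[1]]
    return v


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

@dataclass
class PruneParams:
    """Windowed greedy LD-pruning parameters (window/step in SNP counts)."""

    window_snps: int = 100
    step_snps: int = 10
    r2_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not (self.window_snps >= self.step_snps >= 1):
            raise ValueError("require window_snps >= step_snps >= 1")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in [0,1]")


def ld_prune(G: GenotypeMatrix, params: PruneParams | None = None, seed: int = 0) -> np.ndarray:
    """Greedy windowed LD pruning per chromosome.

    Windows of ``window_snps`` consecutive SNPs advance by ``step_snps``;
    within each window, whenever two still-retained SNPs have r² above the
    threshold the member with the smaller minor-allele frequency is dropped
    (ties: the larger index). The algorithm is deterministic; *seed* is
    accepted for interface stability but unused. Returns sorted kept indices.
    """
    from .popgen import pairwise_r2, r2_matrix

    params = params or PruneParams()
    kept: list[int] = []
    for c in G.chromosomes:
        idx = G.chrom_indices(c)
        mc = len(idx)
        if mc == 1:
            kept.extend(idx.tolist())
            continue
        cols = G.values[:, idx]
        maf = minor_allele_frequencies(cols)
        # precompute pairwise-deletion r² for the chromosome (desk-scale m)
        r2 = r2_matrix(cols)
        keep = np.ones(mc, dtype=bool)
        start = 0
        while True:
            stop = min(start + params.window_snps, mc)
            win = range(start, stop)
            for a in win:
                if not keep[a]:
                    continue
                for b in range(a + 1, stop):
                    if not keep[b]:
                        continue
                    r2ab = r2[a, b]
                    if np.isfinite(r2ab) and r2ab > params.r2_threshold:
                        if maf[a] < maf[b]:
                            drop = a
                        elif maf[b] < maf[a]:
                            drop = b
                        else:
                            drop = max(a, b)
                        keep[drop] = False
                        if drop == a:
                            break
            if stop >= mc:
                break
            start += params.step_snps
        kept.extend(idx[keep].tolist())
    return np.asarray(sorted(kept), dtype=np.int64)


# ---------------------------------------------------------------------------
# phenotype standardization
# ---------------------------------------------------------------------------

@dataclass
class TraitStandardizer:
    """z-score parameters estimated on internal-training rows only.

    Sample standard deviation (n−1 denominator) is used, consistently with
    the correlation code elsewhere in the package.
    """

    mean: float
    sd: float


def fit_standardizer(y: np.ndarray, train_rows) -> TraitStandardizer:
    y = np.asarray(y, dtype=float)
    rows = np.asarray(train_rows)
    if len(rows) < 2:
        raise ValueError("need at least two training rows to standardize")
    yt = y[rows]
    sd = float(np.std(yt, ddof=1))
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("zero variance on training rows; cannot standardize")
    return TraitStandardizer(mean=float(np.mean(yt)), sd=sd)


def apply_standardizer(s: TraitStandardizer, y: np.ndarray) -> np.ndarray:
    return (np.asarray(y, dtype=float) - s.mean) / s.sd
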