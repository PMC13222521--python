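"""Per-SNP attribution, comparison with GWAS, and gene-window mapping.

SNP importance is estimated by a permutation-sampling Shapley scheme: for
each explained sample and each sampled (background row, feature
permutation) pair, features are switched one by one from the background
value to the sample's value and the prediction increments are credited to
the switched feature. Averaging over draws gives additive attributions
whose per-row sum telescopes exactly to prediction(x) − mean prediction of
the sampled backgrounds. Per-SNP importance is the mean absolute
attribution over the explained rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import GWASResult

__all__ = [
    "AttributionResult", "GeneWindowHit", "snp_attribution",
    "attribution_vs_gwas", "read_gff_genes", "map_top_snps_to_genes",
]


@dataclass
class AttributionResult:
    """Mean |attribution| per SNP, with per-row attributions retained."""

    mean_abs: np.ndarray            # (m,)
    attributions: np.ndarray        # (n_explain, m)
    baseline: float                 # mean prediction over sampled backgrounds
    predictions: np.ndarray         # (n_explain,) model predictions
    snp_ids: np.ndarray | None = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def completeness_gap(self) -> np.ndarray:
        """|Σ attributions − (prediction − baseline)| per explained row."""
        return np.abs(self.attributions.sum(axis=1) - (self.predictions - self.baseline))

    def to_frame(self) -> pd.DataFrame:
        d = {"importance": self.mean_abs}
        if self.snp_ids is not None:
            d = {"snp_id": self.snp_ids, "chrom": self.chrom, "pos": self.pos, **d}
        return pd.DataFrame(d)


def snp_attribution(predict, X_background: np.ndarray, X_explain: np.ndarray,
                    n_permutations: int = 16, seed: int = 0,
                    snp_ids=None, chrom=None, pos=None) -> AttributionResult:
    """Sampling-based Shapley attributions for a prediction function.

    Parameters
    ----------
    predict : callable mapping an (k, m) array to (k,) predictions
        (e.g. ``CLCNetResults.predict``).
    X_background : rows drawn from the training distribution.
    X_explain : rows to be explained.
    n_permutations : background/permutation draws per explained row.
    """
    Xb = np.atleast_2d(np.asarray(X_background, dtype=float))
    Xe = np.atleast_2d(np.asarray(X_explain, dtype=float))
    if len(Xb) == 0:
        raise ValueError("empty background set")
    n_ex, m = Xe.shape
    rng = np.random.default_rng(seed)
    # one shared set of (background, permutation) draws for every explained
    # row, so attributions are independent of the order of explain rows
    draws = [(Xb[rng.integers(len(Xb))], rng.permutation(m))
             for _ in range(n_permutations)]
    attr = np.zeros((n_ex, m))
    base_preds = []
    for i in range(n_ex):
        x = Xe[i]
        acc = np.zeros(m)
        tri = np.tri(m + 1, m, k=-1, dtype=bool)
        for b, order in draws:
            # walk: row k has the first k features (in permuted order) set to x
            mask = np.empty_like(tri)
            mask[:, order] = tri
            walk = np.where(mask, x, b)
            preds = np.asarray(predict(walk), dtype=float)
            acc[order] += np.diff(preds)
            base_preds.append(preds[0])
        attr[i] = acc / n_permutations
    predictions = np.asarray(predict(Xe), dtype=float)
    return AttributionResult(
        mean_abs=np.abs(attr).mean(axis=0),
        attributions=attr,
        baseline=float(np.mean(base_preds)),
        predictions=predictions,
        snp_ids=None if snp_ids is None else np.asarray(snp_ids, dtype=object),
        chrom=None if chrom is None else np.asarray(chrom, dtype=object),
        pos=None if pos is None else np.asarray(pos, dtype=np.int64),
    )


def attribution_vs_gwas(attr: AttributionResult, gwas: GWASResult) -> dict:
    """Correlate SNP importance with −log10(p) and |beta| on shared SNPs."""
    if attr.snp_ids is None:
        raise ValueError("attribution result carries no snp_ids to match on")
    at = pd.DataFrame({"snp_id": attr.snp_ids, "importance": attr.mean_abs})
    merged = at.merge(gwas.table[["snp_id", "beta", "p"]], on="snp_id")
    merged = merged[np.isfinite(merged["p"]) & np.isfinite(merged["beta"])]
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared SNPs between attribution and GWAS")
    imp = merged["importance"].to_numpy()
    neglogp = -np.log10(merged["p"].to_numpy())
    absbeta = np.abs(merged["beta"].to_numpy())
    return {
        "n_shared": len(merged),
        "spearman_neglogp": float(stats.spearmanr(imp, neglogp).statistic),
        "pearson_neglogp": float(stats.pearsonr(imp, neglogp).statistic),
        "spearman_absbeta": float(stats.spearmanr(imp, absbeta).statistic),
        "pearson_absbeta": float(stats.pearsonr(imp, absbeta).statistic),
    }


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneWindowHit:
    snp_id: str
    gene_id: str
    distance: int           # 0 inside the gene, else bp to nearest boundary
    chrom: str
    snp_pos: int


class GFFParseError(ValueError):
    pass


def read_gff_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file → DataFrame(gene_id, chrom, start, end).

    Only ``gene`` rows are kept; the ID attribute (or gene_id) names the
    gene. Malformed lines raise :class:`GFFParseError` with the line number.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GFFParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(parts)}"
                )
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise GFFParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise GFFParseError(
                    f"{path}: line {lineno}: gene feature without ID attribute"
                )
            genes.append({"gene_id": gid, "chrom": parts[0],
                          "start": start, "end": end})
    return pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end"])


def map_top_snps_to_genes(attr: AttributionResult, genes, top_frac: float = 0.05,
                          window: int = 100_000) -> list:
    """Map the top ⌈top_frac·m⌉ SNPs by importance to genes within ±window bp.

    *genes* may be a GFF3 path or a DataFrame from :func:`read_gff_genes`.
    The window is inclusive at both ends; distance is 0 inside a gene.
    """
    if attr.snp_ids is None or attr.pos is None:
        raise ValueError("attribution result lacks SNP coordinates")
    if not isinstance(genes, pd.DataFrame):
        genes = read_gff_genes(genes)
    m = len(attr.mean_abs)
    n_top = math.ceil(top_frac * m)
    top = np.argsort(-attr.mean_abs, kind="stable")[:n_top]
    hits = []
    for i in top:
        c, p = attr.chrom[i], int(attr.pos[i])
        sub = genes[genes["chrom"] == c]
        for _, g in sub.iterrows():
            if g["start"] - window <= p <= g["end"] + window:
                if g["start"] <= p <= g["end"]:
                    dist = 0
                else:
                    dist = int(min(abs(p - g["start"]), abs(p - g["end"])))
                hits.append(GeneWindowHit(str(attr.snp_ids[i]), str(g["gene_id"]),
                                          dist, str(c), p))
    return hits
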