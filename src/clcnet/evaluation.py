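"""Repeated nested cross-validation, metrics and model comparison.

The evaluation protocol: 10-fold CV repeated with several partition seeds
(default 42/84/162, 30 cells total). Within every outer-training set an
internal 80/20 train/validation split is drawn; the phenotype standardizer,
the SNP selection and the model are all fitted on the internal training
rows only, the validation rows are used for monitoring, and metrics are
computed on the untouched test fold. Paired two-tailed t-tests over the
shared (repeat, fold) cells with Benjamini–Hochberg FDR adjustment compare
models; ablation variants toggle local/global selection and the
contrastive weight; the SNP-position shuffle experiment applies one global
column permutation to probe whether performance relies on chromosomal
structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .geno import (
    GenotypeMatrix,
    apply_standardizer,
    fit_standardizer,
)
from .model import CLCNet
from .select import (
    DEFAULT_GBDT_PARAMS,
    chromosome_aware_select,
    gwas_select,
    pca_select_apply,
    pca_select_fit,
    select_global,
    select_local,
)
from .training import TrainConfig

__all__ = [
    "CVCell", "CVPlan", "make_cv_plan",
    "metric_pcc", "metric_mse", "metric_spearman",
    "run_cv", "paired_compare", "bh_adjust", "significance_stars",
    "compare_models", "rank_models", "shuffle_snp_columns",
    "ABLATION_VARIANTS", "run_ablation", "leakage_audit",
]

DEFAULT_PARTITION_SEEDS = (42, 84, 162)


@dataclass
class CVCell:
    repeat_seed: int
    fold: int
    test_idx: np.ndarray
    inner_train_idx: np.ndarray
    inner_valid_idx: np.ndarray


@dataclass
class CVPlan:
    n: int
    n_folds: int
    seeds: tuple
    cells: list

    def __iter__(self):
        return iter(self.cells)

    def __len__(self):
        return len(self.cells)


def make_cv_plan(n: int, seeds=DEFAULT_PARTITION_SEEDS, n_folds: int = 10,
                 inner_valid_frac: float = 0.2) -> CVPlan:
    """Repeated k-fold plan with a seeded inner 80/20 split per outer fold."""
    if n < 2 * n_folds:
        raise ValueError(f"n={n} too small for {n_folds}-fold CV")
    cells = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        for f, test in enumerate(folds):
            outer = np.setdiff1d(perm, test)
            outer = outer[rng.permutation(len(outer))]
            n_valid = int(round(inner_valid_frac * len(outer)))
            n_valid = max(1, min(n_valid, len(outer) - 1))
            inner_valid = np.sort(outer[:n_valid])
            inner_train = np.sort(outer[n_valid:])
            cells.append(CVCell(seed, f, np.sort(test), inner_train, inner_valid))
    return CVPlan(n, n_folds, tuple(seeds), cells)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def metric_pcc(y, y_hat) -> float:
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if len(y) < 3 or np.std(y) <= 0 or np.std(y_hat) <= 0:
        return float("nan")
    return float(stats.pearsonr(y, y_hat).statistic)


def metric_mse(y, y_hat) -> float:
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    return float(np.mean((y - y_hat) ** 2))


def metric_spearman(y, y_hat) -> float:
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if len(y) < 3 or np.std(y) <= 0 or np.std(y_hat) <= 0:
        return float("nan")
    return float(stats.spearmanr(y, y_hat).statistic)


# ---------------------------------------------------------------------------
# one CV cell
# ---------------------------------------------------------------------------

def _fit_selection(G, ys, cell, selection, gbdt_params, use_local, use_global,
                   shared_fits=None):
    """Returns (feature builder rows→matrix, selection descriptor)."""
    tr = cell.inner_train_idx
    if selection == "none":
        return (lambda rows: G.values[rows].astype(float)), None
    if selection == "ca":
        local_sets = global_set = None
        if shared_fits is not None:
            local_sets, global_set = shared_fits
        sel = chromosome_aware_select(
            G, ys, tr, gbdt_params, use_local=use_local, use_global=use_global,
            local_sets=local_sets if use_local else None,
            global_set=global_set if use_global else None,
        )
        kept = sel.kept_indices
        return (lambda rows: G.values[np.ix_(rows, kept)].astype(float)), sel
    if selection == "gwas":
        sel = gwas_select(G, ys, tr)
        kept = sel.kept_indices
        if len(kept) == 0:
            raise ValueError("GWAS selection kept no SNP for this cell")
        return (lambda rows: G.values[np.ix_(rows, kept)].astype(float)), sel
    if selection == "pca":
        proj = pca_select_fit(G, tr)
        return (lambda rows: pca_select_apply(proj, G, rows)), proj
    raise ValueError(f"unknown selection method {selection!r}")


def _fit_predict(model, Xtr, ytr, Xva, yva, Xte, scale, train_config, seed):
    if model.startswith("clcnet"):
        res = CLCNet(Xtr, ytr, Xva, yva, scale=scale, seed=seed).fit(train_config)
        return res.predict(Xte), res
    if model == "ridge":
        from sklearn.linear_model import Ridge

        m = Ridge(alpha=1.0).fit(Xtr, ytr)
        return m.predict(Xte), m
    if model == "gbdt":
        import lightgbm as lgb

        m = lgb.LGBMRegressor(
            **DEFAULT_GBDT_PARAMS, random_state=seed, n_jobs=1, verbose=-1,
            deterministic=True, force_row_wise=True,
        ).fit(Xtr, ytr)
        return m.predict(Xte), m
    raise ValueError(f"unknown model spec {model!r}")


def run_cv(G: GenotypeMatrix, y: np.ndarray, plan: CVPlan, model: str = "clcnet",
           selection: str = "ca", scale: float = 0.125,
           train_config: TrainConfig | None = None,
           gbdt_params: dict | None = None, use_local: bool = True,
           use_global: bool = True, model_tag: str | None = None,
           return_fits: bool = False):
    """Leakage-safe repeated CV; returns a MetricRecord DataFrame.

    Per cell: standardizer and selection fit on the internal training rows,
    the model trained on them (validation rows only monitored), metrics on
    the untouched test fold (standardized scale). Failed cells are recorded
    with NaN metrics and the failure reason.
    """
    y = np.asarray(y, dtype=float)
    tag = model_tag or f"{model}+{selection}"
    records, fits = [], []
    for cell in plan:
        rec = {"model": tag, "repeat_seed": cell.repeat_seed, "fold": cell.fold,
               "n_test": len(cell.test_idx)}
        try:
            std = fit_standardizer(y, cell.inner_train_idx)
            ys = apply_standardizer(std, y)
            build, sel = _fit_selection(G, ys, cell, selection, gbdt_params,
                                        use_local, use_global)
            pred, fitted = _fit_predict(
                model, build(cell.inner_train_idx), ys[cell.inner_train_idx],
                build(cell.inner_valid_idx), ys[cell.inner_valid_idx],
                build(cell.test_idx), scale, train_config, seed=0,
            )
            yte = ys[cell.test_idx]
            rec.update(pcc=metric_pcc(yte, pred), mse=metric_mse(yte, pred),
                       spearman=metric_spearman(yte, pred), error="")
            fits.append((cell, std, sel, fitted))
        except Exception as exc:  # record and continue
            rec.update(pcc=np.nan, mse=np.nan, spearman=np.nan, error=str(exc))
            fits.append((cell, None, None, None))
        records.append(rec)
    df = pd.DataFrame(records)
    return (df, fits) if return_fits else df


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

def paired_compare(records_a: pd.DataFrame, records_b: pd.DataFrame,
                   metric: str = "pcc") -> dict:
    """Two-tailed paired t-test over identical (repeat, fold) cells."""
    keys = ["repeat_seed", "fold"]
    a = records_a.sort_values(keys).reset_index(drop=True)
    b = records_b.sort_values(keys).reset_index(drop=True)
    if len(a) != len(b) or not (a[keys].values == b[keys].values).all():
        raise ValueError("records do not share identical (repeat, fold) cells")
    av = a[metric].to_numpy(dtype=float)
    bv = b[metric].to_numpy(dtype=float)
    mask = np.isfinite(av - bv)
    d = (av - bv)[mask]
    if len(d) < 2:
        raise ValueError("fewer than two finite paired differences")
    mean_diff = float(np.mean(d))
    sd = np.std(d, ddof=1)
    if sd == 0:
        p = 1.0 if mean_diff == 0 else float(np.finfo(float).tiny)
        if mean_diff != 0:
            warnings.warn("zero-variance paired differences; p set to smallest "
                          "representable positive value")
        t = float("inf") if mean_diff > 0 else (-float("inf") if mean_diff else 0.0)
    else:
        res = stats.ttest_rel(av[mask], bv[mask])
        t, p = float(res.statistic), float(res.pvalue)
    return {"mean_diff": mean_diff, "t": t, "p": p, "n_cells": len(d)}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def significance_stars(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"


def compare_models(records: pd.DataFrame, reference: str, metric: str = "pcc") -> pd.DataFrame:
    """Reference-vs-each-other-model paired tests with BH-FDR adjustment."""
    others = [m for m in records["model"].unique() if m != reference]
    ref = records[records["model"] == reference]
    rows = []
    for m in others:
        r = paired_compare(ref, records[records["model"] == m], metric)
        rows.append({"model": m, **r})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df["stars"] = [significance_stars(q) for q in df["p_adj"]]
    return df


def rank_models(records: pd.DataFrame, metric: str = "pcc") -> pd.DataFrame:
    """Rank models by descending mean metric; ties share averaged ranks."""
    means = records.groupby("model")[metric].mean()
    ranks = stats.rankdata(-means.to_numpy(), method="average")
    return pd.DataFrame({"model": means.index, f"mean_{metric}": means.to_numpy(),
                         "rank": ranks}).sort_values("rank").reset_index(drop=True)


# ---------------------------------------------------------------------------
# SNP position shuffle
# ---------------------------------------------------------------------------

def shuffle_snp_columns(G: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """One global column permutation, identical across samples.

    Genotype columns (and their snp_ids) are permuted while the map's
    (chrom, pos) slots stay in place, so every sample keeps its multiset of
    genotype codes but positional identity is scrambled and dimensions are
    unchanged.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(G.n_snps)
    return GenotypeMatrix(
        G.values[:, perm], G.sample_ids.copy(), G.snp_ids[perm],
        G.chrom.copy(), G.pos.copy(),
    )


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------

# tag -> (use_local, use_global, use_contrastive)
ABLATION_VARIANTS = {
    "CLCNet":   (True,  True,  True),
    "CLCNet_1": (True,  False, True),
    "CLCNet_2": (True,  False, False),
    "CLCNet_3": (False, True,  True),
    "CLCNet_4": (False, True,  False),
}


def run_ablation(G: GenotypeMatrix, y: np.ndarray, plan: CVPlan,
                 scale: float = 0.125, train_config: TrainConfig | None = None,
                 gbdt_params: dict | None = None,
                 variants: dict | None = None) -> pd.DataFrame:
    """All ablation variants on shared splits (paired-test ready).

    The local and global selector fits are computed once per cell and shared
    across variants, since every variant sees identical training rows.
    """
    variants = variants or ABLATION_VARIANTS
    y = np.asarray(y, dtype=float)
    train_config = train_config or TrainConfig()
    records = []
    for cell in plan:
        std = fit_standardizer(y, cell.inner_train_idx)
        ys = apply_standardizer(std, y)
        tr = cell.inner_train_idx
        local_sets = select_local(G, ys, tr, gbdt_params)
        global_set = select_global(G, ys, tr, gbdt_params)
        for tag, (use_l, use_g, use_c) in variants.items():
            rec = {"model": tag, "repeat_seed": cell.repeat_seed, "fold": cell.fold,
                   "n_test": len(cell.test_idx)}
            try:
                sel = chromosome_aware_select(
                    G, ys, tr, gbdt_params, use_local=use_l, use_global=use_g,
                    local_sets=local_sets, global_set=global_set,
                )
                kept = sel.kept_indices
                cfg = replace(train_config,
                              contrastive_weight=train_config.contrastive_weight
                              if use_c else 0.0)
                Xall = G.values[:, kept].astype(float)
                res = CLCNet(Xall[tr], ys[tr], Xall[cell.inner_valid_idx],
                             ys[cell.inner_valid_idx], scale=scale).fit(cfg)
                pred = res.predict(Xall[cell.test_idx])
                yte = ys[cell.test_idx]
                rec.update(pcc=metric_pcc(yte, pred), mse=metric_mse(yte, pred),
                           spearman=metric_spearman(yte, pred), error="")
            except Exception as exc:
                rec.update(pcc=np.nan, mse=np.nan, spearman=np.nan, error=str(exc))
            records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# leakage audit
# ---------------------------------------------------------------------------

def leakage_audit(G: GenotypeMatrix, y: np.ndarray, plan: CVPlan,
                  selection: str = "ca", scale: float = 0.03125,
                  train_config: TrainConfig | None = None,
                  gbdt_params: dict | None = None, seed: int = 123) -> bool:
    """Verify that test-fold data never influences fitting.

    For every cell, the test rows' phenotypes and genotypes are replaced by
    seeded garbage and the cell is re-fit; the standardizer, the selected
    SNP set and every trained network parameter must be bit-identical.
    Returns True when the audit passes, else raises AssertionError.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    for cell in plan:
        single = CVPlan(plan.n, plan.n_folds, plan.seeds, [cell])
        _, fits_a = run_cv(G, y, single, model="clcnet", selection=selection,
                           scale=scale, train_config=train_config,
                           gbdt_params=gbdt_params, return_fits=True)
        y_mod = y.copy()
        y_mod[cell.test_idx] = rng.normal(50.0, 9.0, size=len(cell.test_idx))
        G_mod = GenotypeMatrix(
            G.values.copy(), G.sample_ids, G.snp_ids, G.chrom, G.pos
        )
        G_mod.values[cell.test_idx] = rng.integers(
            0, 4, size=(len(cell.test_idx), G.n_snps)
        ).astype(G.values.dtype)
        _, fits_b = run_cv(G_mod, y_mod, single, model="clcnet", selection=selection,
                           scale=scale, train_config=train_config,
                           gbdt_params=gbdt_params, return_fits=True)
        (_, std_a, sel_a, fit_a), (_, std_b, sel_b, fit_b) = fits_a[0], fits_b[0]
        assert std_a is not None and std_b is not None, "cell failed during audit"
        assert std_a.mean == std_b.mean and std_a.sd == std_b.sd, \
            "standardizer depends on test rows"
        if selection in ("ca", "gwas"):
            assert np.array_equal(sel_a.kept_indices, sel_b.kept_indices), \
                "selected SNP set depends on test rows"
        elif selection == "pca":
            assert np.array_equal(sel_a.loadings, sel_b.loadings), \
                "PCA loadings depend on test rows"
        for k in fit_a.network.params:
            assert np.array_equal(fit_a.network.params[k], fit_b.network.params[k]), \
                f"trained parameter {k} depends on test rows"
    return True
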