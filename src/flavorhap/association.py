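"""Local association scan between variant dosages and metabolite phenotypes.

The scan is an ordinary linear model phenotype ~ dosage (+ optional
subpopulation indicator covariates) per variant, with:

- a Shapiro-Wilk gate (alpha 0.01) in front of a rank-based inverse-normal
  transform (Blom offset) for non-normal phenotypes;
- a 2% minor-allele-frequency floor (kept low to retain rare alleles);
- Benjamini-Hochberg FDR across the scanned set, with significance tiers at
  q <= 0.05 and q <= 0.01;
- PVE as the difference of likelihood-ratio R^2 between the model with and
  without the variant (for a Gaussian linear model without covariates this is
  exactly the OLS R^2 of phenotype ~ dosage);
- LD as the squared Pearson correlation of dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NormalizedPhenotype:
    values: pd.Series
    was_transformed: bool
    shapiro_p: float


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal transform; ties get average ranks."""
    r = stats.rankdata(values, method="average")
    n = values.size
    return stats.norm.ppf((r - 3.0 / 8.0) / (n + 0.25))


def normalize_phenotype(values: pd.Series, shapiro_alpha: float = 0.01) -> NormalizedPhenotype:
    """Quantile-normalize a phenotype when Shapiro-Wilk rejects normality.

    Missing values stay missing; ranks (hence genotype-phenotype order) are
    preserved exactly.
    """
    values = pd.Series(values, dtype=float)
    obs = values.dropna()
    if len(obs) < 3:
        raise ValueError(f"need >= 3 non-missing values, got {len(obs)}")
    if np.ptp(obs.to_numpy()) == 0:
        raise ValueError("phenotype is constant; normality is untestable")
    shapiro_p = float(stats.shapiro(obs.to_numpy()).pvalue)
    if shapiro_p >= shapiro_alpha:
        return NormalizedPhenotype(values=values, was_transformed=False, shapiro_p=shapiro_p)
    out = values.copy()
    out.loc[obs.index] = rank_inverse_normal(obs.to_numpy())
    return NormalizedPhenotype(values=out, was_transformed=True, shapiro_p=shapiro_p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _gaussian_loglik(rss: float, n: int) -> float:
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def pve(
    phenotype: np.ndarray, dosage: np.ndarray, covariates: np.ndarray | None = None
) -> float:
    """Phenotypic variance explained: likelihood-ratio R^2 of the full model
    minus that of the model without the dosage term.

    R^2_LR(model) = 1 - exp(-(2/n)(ll_model - ll_null)) with the
    intercept-only model as null.
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(dosage, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(x)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        mask &= ~np.isnan(covariates).any(axis=1)
    y, x = y[mask], x[mask]
    n = y.size
    ones = np.ones((n, 1))
    if covariates is None:
        reduced = ones
    else:
        reduced = np.column_stack([ones, covariates[mask]])
    full = np.column_stack([reduced, x])
    if n <= full.shape[1]:
        raise ValueError(f"n={n} too small for {full.shape[1]} parameters")
    ll_null = _gaussian_loglik(_ols_rss(ones, y), n)
    ll_reduced = _gaussian_loglik(_ols_rss(reduced, y), n)
    ll_full = _gaussian_loglik(_ols_rss(full, y), n)
    r2_full = 1.0 - np.exp(-2.0 / n * (ll_full - ll_null))
    r2_reduced = 1.0 - np.exp(-2.0 / n * (ll_reduced - ll_null))
    return float(r2_full - r2_reduced)


def ld_r2(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite r^2)."""
    x = np.asarray(dosage_i, dtype=float)
    y = np.asarray(dosage_j, dtype=float)
    mask = ~np.isnan(x) & ~np.isnan(y)
    if mask.sum() < 3:
        raise ValueError("need >= 3 jointly observed genotype pairs")
    x, y = x[mask], y[mask]
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("dosage vector has zero variance on the joint set")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def subpopulation_covariates(subpops: pd.Series) -> np.ndarray:
    """Indicator (dummy) covariates for subpopulation membership, dropping the
    first level to avoid collinearity with the intercept."""
    dummies = pd.get_dummies(subpops.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def scan(
    dosages: pd.DataFrame,
    phenotype: NormalizedPhenotype | pd.Series,
    maf_min: float = 0.02,
    covariates: np.ndarray | None = None,
    variant_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-variant association scan.

    ``dosages``: accessions x variants ({0,1,2}, NaN missing). Returns a frame
    with maf, p, neg_log10_p, q, pve and tier (ns / fdr05 / fdr01); variants
    below the MAF floor or with zero dosage variance are skipped.
    """
    y_series = phenotype.values if isinstance(phenotype, NormalizedPhenotype) else phenotype
    y_all = pd.Series(y_series, dtype=float).reindex(dosages.index).to_numpy()

    rows = []
    for vid in dosages.columns:
        x_all = dosages[vid].to_numpy(dtype=float)
        mask = ~np.isnan(x_all) & ~np.isnan(y_all)
        if covariates is not None:
            mask &= ~np.isnan(covariates).any(axis=1)
        x, y = x_all[mask], y_all[mask]
        n = x.size
        if n < 3:
            continue
        p_alt = x.mean() / 2.0
        maf = min(p_alt, 1.0 - p_alt)
        if maf < maf_min:
            continue
        if np.var(x) == 0:
            continue  # monomorphic after missing removal
        if covariates is None:
            X = np.column_stack([np.ones(n), x])
        else:
            X = np.column_stack([np.ones(n), covariates[mask], x])
        if n <= X.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        df = n - X.shape[1]
        xtx_inv = np.linalg.pinv(X.T @ X)
        if rss == 0.0:
            p_val = np.finfo(float).tiny
        else:
            se = np.sqrt(rss / df * xtx_inv[-1, -1])
            t = beta[-1] / se
            p_val = float(2.0 * stats.t.sf(abs(t), df))
            p_val = max(p_val, np.finfo(float).tiny)
        pve_val = pve(y, x, covariates[mask] if covariates is not None else None)
        rows.append(
            {
                "variant_id": vid,
                "n": n,
                "maf": maf,
                "beta": float(beta[-1]),
                "p": p_val,
                "neg_log10_p": -np.log10(p_val),
                "pve": pve_val,
            }
        )
    result = pd.DataFrame(
        rows, columns=["variant_id", "n", "maf", "beta", "p", "neg_log10_p", "pve"]
    )
    if len(result) > 0:
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["tier"] = np.where(
            result["q"] <= 0.01, "fdr01", np.where(result["q"] <= 0.05, "fdr05", "ns")
        )
    else:
        result["q"] = []
        result["tier"] = []
    if variant_classes is not None:
        result["vclass"] = result["variant_id"].map(variant_classes)
    return result
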