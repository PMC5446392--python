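"""Covariate-adjusted differential methylation and MVP calling.

Per-probe ordinary least squares on the M scale (logit2 of beta) with
group, sex, age, the selected batch-marker probe betas and SVD surrogate
components as covariates; effects are reported on the raw beta scale
(case - control mean difference). Benjamini-Hochberg adjustment and a
genome-wide threshold (default adjusted p < 1e-7) define the MVPs
(methylation variable positions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .simulate import logit2
from .types import BatchMarkerResult, BetaMatrix, validate_sample_sheet

__all__ = ["ModelSpec", "surrogate_components", "fit_probe_models", "adjust_fdr", "call_mvps", "run_methwas"]


@dataclass
class ModelSpec:
    """Model configuration for the per-probe association fits."""

    outcome_scale: str = "M"  # "M" (logit2) or "beta"
    covariates: tuple[str, ...] = ("group", "sex", "age")
    n_surrogates: int = 2
    fdr_method: str = "fdr_bh"
    mvp_threshold: float = 1e-7
    threshold_on: str = "adjusted"  # "adjusted" (strict) or "raw"

    def __post_init__(self) -> None:
        if self.n_surrogates < 0:
            raise ValueError("n_surrogates must be >= 0")
        if not 0 < self.mvp_threshold < 1:
            raise ValueError("mvp_threshold must lie in (0, 1)")
        if self.outcome_scale not in ("M", "beta"):
            raise ValueError("outcome_scale must be 'M' or 'beta'")


def _analysis_samples(sheet: pd.DataFrame) -> pd.DataFrame:
    """Sample-sheet rows used for association fitting (re-batch copies excluded)."""
    validate_sample_sheet(sheet)
    keep = sheet["rebatch_of"].isna() | (sheet["rebatch_of"] == "")
    return sheet.loc[keep].reset_index(drop=True)


def _design_matrix(
    sheet: pd.DataFrame,
    covariate_betas: pd.DataFrame | None,
    surrogates: np.ndarray | None,
    include_group: bool = True,
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(sheet))]
    names = ["intercept"]
    if include_group:
        cols.append((sheet["group"].to_numpy() == "case").astype(float))
        names.append("group")
    cols.append((sheet["sex"].to_numpy() == "M").astype(float))
    names.append("sex")
    cols.append(sheet["age"].to_numpy(dtype=float))
    names.append("age")
    if covariate_betas is not None:
        for probe in covariate_betas.index:
            cols.append(covariate_betas.loc[probe].to_numpy(dtype=float))
            names.append(f"batchcov_{probe}")
    if surrogates is not None and surrogates.size:
        for j in range(surrogates.shape[1]):
            cols.append(surrogates[:, j])
            names.append(f"sv{j + 1}")
    X = np.column_stack(cols)
    # drop collinear columns (never the intercept or group)
    keep = list(range(X.shape[1]))
    while np.linalg.matrix_rank(X[:, keep]) < len(keep):
        for j in reversed(keep):
            if names[j] in ("intercept", "group"):
                continue
            trial = [c for c in keep if c != j]
            if np.linalg.matrix_rank(X[:, trial]) == np.linalg.matrix_rank(X[:, keep]):
                warnings.warn(f"design column {names[j]} collinear; dropped", stacklevel=3)
                keep = trial
                break
        else:
            raise ValueError("design matrix irreparably rank-deficient")
    return X[:, keep], [names[j] for j in keep]


def _group_p_values(M: np.ndarray, X: np.ndarray, gi: int) -> np.ndarray:
    """Vectorised two-sided t-test p on the group coefficient, probes x samples M."""
    n, q = X.shape
    coefs = np.linalg.pinv(X) @ M.T
    resid = M.T - X @ coefs
    dof = n - q
    s2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(s2 * xtx_inv[gi, gi], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coefs[gi] / se, 0.0)
    return 2.0 * sps.t.sf(np.abs(t), df=dof)


def surrogate_components(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    known_covariates: pd.DataFrame | None = None,
    k: int = 2,
    protect_p: float = 0.2,
) -> np.ndarray:
    """Top-k SVD surrogate components of the nuisance-covariate residuals.

    Two-pass, signal-protected estimation. Pass 1 fits the full model
    (with the case/control contrast) per probe and sets aside probes with
    group p below ``protect_p``; pass 2 residualises the remaining,
    null-behaving probes' M-values against the nuisance design (intercept,
    sex, age, batch-covariate probes — deliberately NOT the group contrast,
    otherwise group-correlated cell-composition structure could never be
    corrected) and returns the orthonormal per-sample scores of the top
    ``k`` singular vectors of that residual matrix. The protection step
    keeps genuinely associated probes from dragging the components toward
    the case/control direction, which would distort null probes when the
    components are partialled out. Components stand in for unmeasured
    structure such as blood cellular heterogeneity.
    """
    samples = _analysis_samples(sheet)
    if k >= len(samples):
        raise ValueError("k must be smaller than the number of analysis samples")
    if k == 0:
        return np.empty((len(samples), 0))
    M = logit2(beta.values[samples["sample_id"]].to_numpy())
    if protect_p > 0:
        X_full, names = _design_matrix(samples, known_covariates, None, include_group=True)
        p = _group_p_values(M, X_full, names.index("group"))
        mask = p > protect_p
        if mask.sum() < max(50, int(0.1 * M.shape[0])):
            warnings.warn("too few null-behaving probes; using all probes for surrogates", stacklevel=2)
            mask = np.ones(M.shape[0], dtype=bool)
        M = M[mask]
    X, _ = _design_matrix(samples, known_covariates, None, include_group=False)
    coef, _, _, _ = np.linalg.lstsq(X, M.T, rcond=None)
    resid = M.T - X @ coef  # samples x probes
    if np.allclose(resid, 0):
        warnings.warn("residual matrix is zero; no surrogate components", stacklevel=2)
        return np.empty((len(samples), 0))
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum())
    if rank < k:
        warnings.warn(f"residual rank {rank} < k={k}; returning {rank} components", stacklevel=2)
        k = rank
    return u[:, :k]


def fit_probe_models(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    spec: ModelSpec,
    batch: BatchMarkerResult | None = None,
    annot: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-probe OLS association with the case/control contrast.

    Outcome is the M-value (or raw beta); p_raw is the two-sided t-test on
    the group coefficient; ``effect`` is always the raw beta-scale
    mean(case) - mean(control). Batch-covariate probes are included as
    design columns and excluded from the tested probe set. Probes with zero
    outcome variance get p_raw = 1.
    """
    samples = _analysis_samples(sheet)
    ids = samples["sample_id"]
    missing = [s for s in ids if s not in set(beta.sample_ids)]
    if missing:
        raise ValueError(f"samples missing from beta matrix: {missing}")
    if samples[["group", "sex", "age"]].isna().any().any():
        raise ValueError("missing covariate values")

    cov_betas = None
    cov_probes: list[str] = []
    if batch is not None and batch.selected_covariates:
        cov_probes = [p for p in batch.selected_covariates if p in set(beta.probe_ids)]
        cov_betas = beta.values.loc[cov_probes, ids]

    sur = None
    if spec.n_surrogates > 0:
        sur = surrogate_components(beta, sheet, cov_betas, k=spec.n_surrogates)

    X, names = _design_matrix(samples, cov_betas, sur)
    gi = names.index("group")
    test_probes = beta.probe_ids.difference(cov_probes, sort=False)
    B = beta.values.loc[test_probes, ids].to_numpy()
    Y = logit2(B) if spec.outcome_scale == "M" else B

    n, q = X.shape
    pinv = np.linalg.pinv(X)
    coefs = pinv @ Y.T  # q x probes
    resid = Y.T - X @ coefs
    dof = n - q
    if dof < 1:
        raise ValueError("not enough samples for the design")
    s2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(s2 * xtx_inv[gi, gi], 0.0))
    group_coef = coefs[gi]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, group_coef / se, 0.0)
    p_raw = 2.0 * sps.t.sf(np.abs(t), df=dof)
    zero_var = Y.var(axis=1) == 0
    p_raw[zero_var] = 1.0

    case_mask = samples["group"].to_numpy() == "case"
    effect = B[:, case_mask].mean(axis=1) - B[:, ~case_mask].mean(axis=1)

    table = pd.DataFrame(
        {
            "probe_id": test_probes,
            "effect": effect,
            "coef": group_coef,
            "p_raw": p_raw,
            "p_adj": np.nan,
            "is_mvp": False,
        }
    )
    if annot is not None:
        an = annot.set_index("probe_id")
        table.insert(1, "chrom", an.reindex(table["probe_id"])["chrom"].to_numpy())
        table.insert(2, "pos", an.reindex(table["probe_id"])["pos"].to_numpy())
    return table


def adjust_fdr(p_raw, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def call_mvps(table: pd.DataFrame, threshold: float = 1e-7, on: str = "adjusted") -> pd.DataFrame:
    """Flag MVPs at the genome-wide threshold (default adjusted p < 1e-7)."""
    out = table.copy()
    if out["p_adj"].isna().any():
        out["p_adj"] = adjust_fdr(out["p_raw"].to_numpy())
    col = "p_adj" if on == "adjusted" else "p_raw"
    out["is_mvp"] = out[col] < threshold
    return out


def run_methwas(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    spec: ModelSpec | None = None,
    batch: BatchMarkerResult | None = None,
    annot: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit, adjust and call in one step; returns the completed MVP table."""
    spec = spec or ModelSpec()
    table = fit_probe_models(beta, sheet, spec, batch=batch, annot=annot)
    table["p_adj"] = adjust_fdr(table["p_raw"].to_numpy(), method=spec.fdr_method)
    return call_mvps(table, threshold=spec.mvp_threshold, on="adjusted" if spec.threshold_on == "adjusted" else "raw")
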