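"""Batch-marker discovery, covariate selection and probe filtering.

The batch procedure exploits re-hybridised sample pairs: a per-probe paired
t-test (original vs re-batch) flags batch-sensitive probes at genome-wide
significance, then an iterative ranking scheme reduces them to a minimal,
loci-independent covariate set — each round picks the most significant
remaining probe, and every other candidate is re-tested after regressing
its paired differences on those of the already-selected probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import expit2, logit2
from .types import BatchMarkerResult, BetaMatrix, validate_annotation, validate_sample_sheet

__all__ = [
    "paired_batch_test",
    "select_covariate_markers",
    "greedy_detection_filter",
    "filter_probes",
    "normalize_between_samples",
    "rebatch_pairs",
    "FilterLog",
]


def rebatch_pairs(sheet: pd.DataFrame) -> list[tuple[str, str]]:
    """(original, re-batch) sample-id pairs recorded in the sample sheet."""
    validate_sample_sheet(sheet)
    mask = sheet["rebatch_of"].notna() & (sheet["rebatch_of"] != "")
    return [(ref, sid) for sid, ref in sheet.loc[mask, ["sample_id", "rebatch_of"]].itertuples(index=False)]


def _paired_differences(beta: BetaMatrix, sheet: pd.DataFrame) -> pd.DataFrame:
    pairs = rebatch_pairs(sheet)
    if len(pairs) < 2:
        raise ValueError("need at least 2 re-batch pairs")
    for orig, rb in pairs:
        for sid in (orig, rb):
            if sid not in beta.sample_ids:
                raise ValueError(f"paired sample {sid} missing from beta matrix")
    orig = beta.values[[o for o, _ in pairs]].to_numpy()
    rb = beta.values[[r for _, r in pairs]].to_numpy()
    return pd.DataFrame(orig - rb, index=beta.probe_ids, columns=[o for o, _ in pairs])


def paired_batch_test(beta: BetaMatrix, sheet: pd.DataFrame, threshold: float = 1e-7) -> BatchMarkerResult:
    """Per-probe paired t-test of original vs re-batch beta values.

    Probes with two-sided p below ``threshold`` become batch-marker
    candidates. Probes whose paired differences are identically zero get
    p = 1 (no evidence of a batch effect); probes with zero variance around
    a non-zero mean are flagged degenerate and excluded from candidacy.
    """
    diffs = _paired_differences(beta, sheet)
    d = diffs.to_numpy()
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    p = np.ones(d.shape[0])
    degen = (sd == 0) & (mean != 0)
    ok = sd > 0
    t = np.zeros(d.shape[0])
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df=n - 1)
    pser = pd.Series(p, index=diffs.index)
    pser[degen] = np.nan
    candidates = list(pser.index[(pser < threshold).fillna(False)])
    return BatchMarkerResult(
        candidate_p=pser,
        candidates=candidates,
        degenerate_probes=list(pser.index[degen]),
    )


def _adjusted_intercept_p(y: np.ndarray, X_sel: np.ndarray) -> float:
    """Two-sided t-test on the intercept of OLS of y on selected differences."""
    n = y.size
    X = np.column_stack([np.ones(n)] + ([X_sel] if X_sel.size else []))
    q = X.shape[1]
    if n - q < 1:
        return np.nan
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - rank
    if dof < 1:
        return np.nan
    s2 = resid @ resid / dof
    if s2 <= 0:
        return 1.0 if abs(coef[0]) < 1e-12 else 0.0
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(s2 * xtx_inv[0, 0])
    t = coef[0] / se
    return float(2.0 * sps.t.sf(abs(t), df=dof))


def select_covariate_markers(
    result: BatchMarkerResult,
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    adjusted_alpha: float = 0.001,
    max_covariates: int = 20,
) -> BatchMarkerResult:
    """Iterative-ranking selection of loci-independent batch covariates.

    Repeatedly picks the candidate with the smallest current (adjusted) p,
    then re-tests every remaining candidate's paired batch effect after
    regressing its paired differences on those of the selected probes
    (t-test on the residual-model intercept), until no remaining candidate
    is significant at ``adjusted_alpha``. The first pick uses the discovery
    p-values (all candidates are genome-wide significant by construction);
    subsequent rounds use the adjusted p-values, for which ``adjusted_alpha``
    is an ordinary significance level: with a dozen pairs an adjusted effect
    can only reach nominal, never genome-wide, significance, and with ~50
    null-behaving candidates re-tested each round a strict level (default
    0.001) keeps the chance of a spurious extra covariate near 5% per run.
    Collinear selections are dropped with a warning.
    """
    if not result.candidates:
        raise ValueError("no batch-marker candidates to select from")
    diffs = _paired_differences(beta, sheet)
    current = result.candidate_p.loc[result.candidates].copy()
    selected: list[str] = []
    trace: list[tuple[str, int]] = []
    remaining = list(result.candidates)
    while remaining:
        sig = current.loc[remaining]
        sig = sig[sig < adjusted_alpha]
        if sig.empty:
            break
        pick = sig.idxmin()
        X_prev = diffs.loc[selected].to_numpy().T if selected else np.empty((diffs.shape[1], 0))
        X_new = diffs.loc[[pick]].to_numpy().T
        X_try = np.column_stack([np.ones(diffs.shape[1]), X_prev, X_new])
        if np.linalg.matrix_rank(X_try) < X_try.shape[1]:
            warnings.warn(f"covariate {pick} collinear with selection; dropped", stacklevel=2)
            remaining.remove(pick)
            current.loc[pick] = np.nan
            continue
        selected.append(pick)
        if len(selected) > max_covariates:
            raise RuntimeError(
                f"covariate selection exceeded cap ({max_covariates}); "
                "batch structure too diffuse for a marker-based correction"
            )
        remaining.remove(pick)
        X_sel = diffs.loc[selected].to_numpy().T
        n_sig = 0
        for probe in remaining:
            padj = _adjusted_intercept_p(diffs.loc[probe].to_numpy(), X_sel)
            current.loc[probe] = padj
            if not np.isnan(padj) and padj < adjusted_alpha:
                n_sig += 1
        trace.append((pick, n_sig))
        if len(trace) >= 2 and trace[-1][1] >= trace[-2][1] + 1:
            # significance counts must shrink; a growing count signals an
            # unstable adjustment model
            warnings.warn("remaining-significant count did not shrink", stacklevel=2)
    return BatchMarkerResult(
        candidate_p=result.candidate_p,
        candidates=list(result.candidates),
        selected_covariates=selected,
        selection_trace=trace,
        degenerate_probes=list(result.degenerate_probes),
    )


@dataclass
class FilterLog:
    """Per-rule removal counts from probe filtering."""

    removed: dict[str, int] = field(default_factory=dict)
    removed_probes: dict[str, list[str]] = field(default_factory=dict)
    removed_samples: list[str] = field(default_factory=list)
    retained_covariates: list[str] = field(default_factory=list)


def greedy_detection_filter(
    beta: BetaMatrix, threshold: float = 0.05, log: FilterLog | None = None
) -> BetaMatrix:
    """Iterative worst-offender removal of detection failures.

    Each round removes the probe row or sample column with the largest
    fraction of cells failing detection (p > ``threshold``), recomputing
    after each removal, until no failing cell remains. Fractions rather
    than raw counts keep long sample columns from dominating sparse random
    failures; ties go to the probe (probes are cheap, samples are precious).
    """
    if beta.detection_p is None:
        raise ValueError("detection p-values required")
    vals = beta.values.copy()
    det = beta.detection_p.copy()
    dropped_probes: list[str] = []
    dropped_samples: list[str] = []
    fail = det.to_numpy() > threshold
    while fail.any():
        by_probe = fail.mean(axis=1)
        by_sample = fail.mean(axis=0)
        if by_probe.max() >= by_sample.max():
            i = int(by_probe.argmax())
            dropped_probes.append(det.index[i])
            keep = np.ones(det.shape[0], dtype=bool)
            keep[i] = False
            det, vals = det.iloc[keep], vals.iloc[keep]
        else:
            j = int(by_sample.argmax())
            dropped_samples.append(det.columns[j])
            keep = np.ones(det.shape[1], dtype=bool)
            keep[j] = False
            det, vals = det.iloc[:, keep], vals.iloc[:, keep]
        fail = det.to_numpy() > threshold
    if vals.size == 0:
        warnings.warn("greedy detection filter removed everything", stacklevel=2)
    if log is not None:
        log.removed["detection"] = len(dropped_probes)
        log.removed_probes["detection"] = dropped_probes
        log.removed_samples = dropped_samples
    return BetaMatrix(vals, det)


def filter_probes(
    beta: BetaMatrix,
    annot: pd.DataFrame,
    batch: BatchMarkerResult | None = None,
    batch_p_cut: float = 0.01,
    detection_threshold: float = 0.05,
) -> tuple[BetaMatrix, FilterLog]:
    """Apply the probe-exclusion rules in fixed order.

    Drops, with per-rule counts logged: SNP-affected probes; sex-chromosome
    probes; detection failures (greedy filter); non-CpG-context probes;
    batch-unstable probes (paired-batch p < ``batch_p_cut``). Selected batch
    covariates are retained in the matrix (they are needed as model
    covariates) but recorded as excluded from the association test set.
    """
    validate_annotation(annot)
    an = annot.set_index("probe_id")
    missing = [p for p in beta.probe_ids if p not in an.index]
    if missing:
        raise ValueError(f"probes missing from annotation: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    an = an.loc[beta.probe_ids]
    log = FilterLog()
    cur = beta

    for rule, mask in (
        ("snp_affected", an["snp_affected"].to_numpy(dtype=bool)),
        ("sex_chrom", an["sex_chrom"].to_numpy(dtype=bool)),
    ):
        drop = pd.Index(beta.probe_ids)[mask].intersection(cur.probe_ids)
        log.removed[rule] = len(drop)
        log.removed_probes[rule] = list(drop)
        cur = cur.subset_probes(cur.probe_ids.difference(drop))

    if cur.detection_p is not None:
        cur = greedy_detection_filter(cur, detection_threshold, log=log)
    else:
        log.removed["detection"] = 0

    noncpg = pd.Index(beta.probe_ids)[~an["cpg_context"].to_numpy(dtype=bool)].intersection(cur.probe_ids)
    log.removed["non_cpg"] = len(noncpg)
    log.removed_probes["non_cpg"] = list(noncpg)
    cur = cur.subset_probes(cur.probe_ids.difference(noncpg))

    if batch is not None:
        unstable = batch.candidate_p[batch.candidate_p < batch_p_cut].index
        covs = set(batch.selected_covariates)
        drop = [p for p in unstable if p in set(cur.probe_ids) and p not in covs]
        log.removed["batch_unstable"] = len(drop)
        log.removed_probes["batch_unstable"] = drop
        log.retained_covariates = [c for c in batch.selected_covariates if c in set(cur.probe_ids)]
        cur = cur.subset_probes(cur.probe_ids.difference(drop))
    else:
        log.removed["batch_unstable"] = 0
    return cur, log


def normalize_between_samples(beta: BetaMatrix, method: str = "none") -> BetaMatrix:
    """Optional between-sample quantile normalization.

    ``quantile`` maps each sample's sorted values onto the across-sample
    mean sorted profile (rank order within a sample is preserved); ``none``
    is a bit-identical pass-through.
    """
    if beta.values.size == 0:
        raise ValueError("empty beta matrix")
    if method == "none":
        return beta
    if method != "quantile":
        raise ValueError(f"unknown normalization method: {method}")
    if beta.values.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input", stacklevel=2)
        return beta
    v = beta.values.to_numpy(dtype=float)
    order = np.argsort(v, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(v.shape[0])
    for j in range(v.shape[1]):
        ranks[order[:, j], j] = rows
    mean_profile = np.sort(v, axis=0).mean(axis=1)
    out = mean_profile[ranks]
    return BetaMatrix(pd.DataFrame(out, index=beta.probe_ids, columns=beta.sample_ids), beta.detection_p)
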