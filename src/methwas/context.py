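"""Genomic context of MVPs: co-methylation and annotation enrichment.

Co-methylation asks whether CpGs within +/-500 bp of an MVP move in the
same direction (sign of the case - control difference) more often than
CpGs around randomly chosen non-MVP probes; enrichment compares the MVP
set against the array background for annotation classes (promoters,
candidate clefting regions) with chi-square (Yates) or Fisher exact tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import chi2_yates_2x2, fisher_exact_2x2
from .types import validate_annotation

__all__ = ["ComethylationReport", "EnrichmentReport", "comethylation", "class_enrichment", "candidate_enrichment"]


@dataclass
class ComethylationReport:
    n_mvps_used: int
    n_neighbours: int
    n_concordant: int
    concordance: float
    bg_n_neighbours: int
    bg_n_concordant: int
    bg_concordance: float
    p: float
    window_bp: int
    min_abs_diff: float
    n_mvps_without_neighbours: int = 0


@dataclass
class EnrichmentReport:
    class_label: str
    mvp_in: int
    mvp_out: int
    bg_in: int
    bg_out: int
    test: str
    statistic: float
    p: float
    mvp_fraction: float
    bg_fraction: float
    fisher_p: float | None = None


def _window_concordance(centers: pd.DataFrame, others: pd.DataFrame, window_bp: int) -> tuple[int, int, int]:
    """Count (concordant, total, centers-without-neighbours) over closed windows."""
    conc = tot = empty = 0
    by_chrom = {c: g.sort_values("pos") for c, g in others.groupby("chrom")}
    for chrom, pos, eff in centers[["chrom", "pos", "effect"]].itertuples(index=False):
        g = by_chrom.get(chrom)
        if g is None:
            empty += 1
            continue
        lo = np.searchsorted(g["pos"].to_numpy(), pos - window_bp, side="left")
        hi = np.searchsorted(g["pos"].to_numpy(), pos + window_bp, side="right")
        neigh = g.iloc[lo:hi]
        neigh = neigh[neigh["pos"] != pos]
        if neigh.empty:
            empty += 1
            continue
        signs = np.sign(neigh["effect"].to_numpy())
        conc += int((signs == np.sign(eff)).sum())
        tot += len(neigh)
    return conc, tot, empty


def comethylation(
    mvps: pd.DataFrame,
    all_effects: pd.DataFrame,
    annot: pd.DataFrame,
    window_bp: int = 500,
    min_abs_diff: float = 0.0,
    n_background: int | None = None,
    seed: int = 0,
) -> ComethylationReport:
    """Sign concordance of CpGs neighbouring MVPs vs a random background.

    ``mvps`` are the called MVP rows; ``all_effects`` carries effects for
    every tested probe. Neighbours are non-MVP probes on the same chromosome
    within the closed window [pos - window_bp, pos + window_bp]. Concordance
    is pooled over MVPs; a Fisher two-sided test compares concordant vs
    discordant counts in MVP windows against windows around ``n_background``
    seeded random non-MVP probes (default 10x the MVP count). MVPs may be
    restricted to |effect| > ``min_abs_diff``.
    """
    validate_annotation(annot)
    an = annot.set_index("probe_id")[["chrom", "pos"]]
    eff = all_effects.set_index("probe_id")[["effect"]]
    if not set(eff.index) <= set(an.index):
        raise ValueError("coordinates missing for some probes")

    mvp_ids = mvps.loc[mvps["is_mvp"], "probe_id"] if "is_mvp" in mvps else mvps["probe_id"]
    mvp_tab = eff.loc[eff.index.isin(set(mvp_ids))]
    if min_abs_diff > 0:
        mvp_tab = mvp_tab[mvp_tab["effect"].abs() > min_abs_diff]
    if mvp_tab.empty:
        raise ValueError("no MVPs to analyse (after |effect| restriction)")

    non_mvp = eff.loc[~eff.index.isin(set(mvp_ids))]
    others = non_mvp.join(an).reset_index()
    centers = mvp_tab.join(an).reset_index()

    conc, tot, empty = _window_concordance(centers, others, window_bp)
    if tot == 0:
        raise ValueError("no MVP neighbours found within the window")

    rng = np.random.default_rng(seed)
    n_bg = n_background if n_background is not None else 10 * len(centers)
    n_bg = min(n_bg, len(others))
    bg_idx = rng.choice(len(others), size=n_bg, replace=False)
    bg_centers = others.iloc[bg_idx]
    # background neighbours come from the same non-MVP pool (centers excluded
    # per window by position, mirroring the MVP windows)
    bg_conc, bg_tot, _ = _window_concordance(bg_centers, others, window_bp)
    if bg_tot == 0:
        warnings.warn("background windows contained no neighbours; Fisher p undefined", stacklevel=2)
        p = float("nan")
        bg_rate = float("nan")
    else:
        p = fisher_exact_2x2(conc, tot - conc, bg_conc, bg_tot - bg_conc)
        bg_rate = bg_conc / bg_tot
    return ComethylationReport(
        n_mvps_used=len(centers),
        n_neighbours=tot,
        n_concordant=conc,
        concordance=conc / tot,
        bg_n_neighbours=bg_tot,
        bg_n_concordant=bg_conc,
        bg_concordance=bg_rate,
        p=p,
        window_bp=window_bp,
        min_abs_diff=min_abs_diff,
        n_mvps_without_neighbours=empty,
    )


def _enrichment_counts(mvps, background, annot, class_label):
    validate_annotation(annot)
    if class_label not in annot.columns:
        raise ValueError(f"unknown annotation class: {class_label}")
    an = annot.set_index("probe_id")[class_label].astype(bool)
    mvp_ids = mvps.loc[mvps["is_mvp"], "probe_id"] if "is_mvp" in mvps else mvps["probe_id"]
    mvp_ids = pd.Index(mvp_ids)
    if mvp_ids.empty:
        raise ValueError("empty MVP set")
    bg_ids = pd.Index(background["probe_id"]).difference(mvp_ids)
    if bg_ids.empty:
        raise ValueError("empty background set")
    a = int(an.reindex(mvp_ids).sum())
    b = len(mvp_ids) - a
    c = int(an.reindex(bg_ids).sum())
    d = len(bg_ids) - c
    return a, b, c, d


def class_enrichment(
    mvps: pd.DataFrame, background: pd.DataFrame, annot: pd.DataFrame, class_label: str
) -> EnrichmentReport:
    """Chi-square (Yates) enrichment of MVPs in an annotation class.

    2x2 table: (MVP vs non-MVP background) x (in-class vs out-of-class).
    When any expected cell is below 5, a Fisher exact p is reported
    alongside the chi-square result.
    """
    a, b, c, d = _enrichment_counts(mvps, background, annot, class_label)
    stat, p = chi2_yates_2x2(a, b, c, d)
    n = a + b + c + d
    expected_min = min((a + b) * (a + c), (a + b) * (b + d), (c + d) * (a + c), (c + d) * (b + d)) / n
    fisher_p = None
    if expected_min < 5:
        warnings.warn("expected cell < 5; reporting Fisher exact p alongside", stacklevel=2)
        fisher_p = fisher_exact_2x2(a, b, c, d)
    return EnrichmentReport(
        class_label=class_label,
        mvp_in=a,
        mvp_out=b,
        bg_in=c,
        bg_out=d,
        test="chi2_yates",
        statistic=stat,
        p=p,
        mvp_fraction=a / (a + b),
        bg_fraction=c / (c + d),
        fisher_p=fisher_p,
    )


def candidate_enrichment(mvps: pd.DataFrame, background: pd.DataFrame, annot: pd.DataFrame) -> EnrichmentReport:
    """Fisher exact enrichment of MVPs in candidate genes/regions."""
    a, b, c, d = _enrichment_counts(mvps, background, annot, "candidate_region")
    if a + c == 0:
        raise ValueError("no probes carry the candidate_region flag")
    p = fisher_exact_2x2(a, b, c, d)
    return EnrichmentReport(
        class_label="candidate_region",
        mvp_in=a,
        mvp_out=b,
        bg_in=c,
        bg_out=d,
        test="fisher",
        statistic=float("nan"),
        p=p,
        mvp_fraction=a / (a + b),
        bg_fraction=c / (c + d),
    )
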