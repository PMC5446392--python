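"""Synthetic data with known ground truth for every pipeline stage.

Emulates (a) a 450K-style methylation cohort: bimodal per-probe baselines,
local co-methylation blocks, planted case/control effects on the logit
scale, re-hybridised ("re-batch") sample pairs carrying planted batch
offsets, Dirichlet cell-composition confounding and M-scale noise;
(b) barcoded bisulfite-amplicon reads with incomplete conversion, base
errors and indels; (c) clone-level bisulfite sequences; (d) paired
blood/lip methylation values with a target correlation.

A single master seed is expanded into per-component sub-streams so each
artifact is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Amplicon, BetaMatrix, ReadRecord

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_amplicon_reads",
    "generate_clones",
    "generate_paired_tissue",
    "make_barcodes",
    "CloneSet",
    "SimulatedReads",
]

_EPS = 1e-6


def logit2(beta: np.ndarray) -> np.ndarray:
    """M-value transform: log2(beta / (1 - beta)), clipped away from {0, 1}."""
    b = np.clip(np.asarray(beta, dtype=float), _EPS, 1 - _EPS)
    return np.log2(b / (1 - b))


def expit2(m: np.ndarray) -> np.ndarray:
    """Inverse M-value transform."""
    return 1.0 / (1.0 + 2.0 ** (-np.asarray(m, dtype=float)))


@dataclass
class CohortConfig:
    """Study design and effect magnitudes for the cohort generator.

    Defaults mirror the modelled study design: 67 cases vs 59 controls on a
    three-batch array run with 6 + 6 re-submitted samples, at desk scale
    (20k probes instead of ~450k).
    """

    n_case: int = 67
    n_control: int = 59
    n_probes: int = 20000
    n_true_mvps: int = 20
    effect_size: float = 0.10  # beta-scale case - control difference
    n_batches: int = 3
    n_batch_probes: int = 50
    batch_shift: float = 0.15  # beta-scale offset at batch probes
    n_rebatch_pairs: int = 6  # re-submitted samples PER GROUP
    n_batch_factors: int = 1  # independent latent batch factors
    batch_factor_sd: float = 0.15  # per-pair spread of the latent factor
    n_cell_types: int = 5
    confound_strength: float = 0.0  # group shift of the first Dirichlet mean
    cell_profile_sd: float = 0.5  # M-scale spread of cell-type profiles
    dirichlet_concentration: float = 60.0
    block_size_bp: int = 500  # co-methylation window; blocks never exceed it
    block_latent_sd: float = 0.05  # M-scale shared within-block signal
    neighbor_effect_frac: float = 0.03  # case effect leaking to block mates
    effect_heterogeneity: float = 0.0  # 0 = all MVPs at effect_size
    noise_sd: float = 0.06  # M-scale i.i.d. measurement noise
    bad_probe_frac: float = 0.002  # probes that fail detection in many samples
    detection_fail_rate: float = 1e-5  # isolated background detection failures
    frac_snp: float = 0.02
    frac_sex_chrom: float = 0.02
    frac_non_cpg: float = 0.01
    frac_promoter: float = 0.47
    frac_candidate: float = 0.01
    mvp_promoter_frac: float | None = None  # None: same as background
    mvp_candidate_frac: float | None = None
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_case,
            self.n_control,
            self.n_probes,
            self.n_true_mvps,
            self.n_batches,
            self.n_batch_probes,
            self.n_rebatch_pairs,
            self.n_cell_types,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_true_mvps + self.n_batch_probes > self.n_probes:
            raise ValueError("n_true_mvps + n_batch_probes exceeds n_probes")
        if not -1 < self.effect_size < 1:
            raise ValueError("effect_size must lie in (-1, 1)")
        for name in ("detection_fail_rate", "frac_snp", "frac_sex_chrom", "frac_non_cpg", "frac_promoter", "frac_candidate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_rebatch_pairs > min(self.n_case, self.n_control):
            raise ValueError("more re-batch pairs than samples per group")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    true_mvp_probes: list[str]
    true_batch_probes: list[str]
    true_effect: pd.Series  # per-probe planted beta-scale case - control difference
    batch_loadings: pd.Series  # beta-scale loading at batch probes
    batch_factor_of: pd.Series  # batch probe -> latent factor index
    planted_batch_offsets: pd.DataFrame  # batch probes x re-batch sample ids
    cell_proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    block_of: pd.Series  # probe -> block id


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _layout_blocks(cfg: CohortConfig, rng: np.random.Generator):
    """Assign probes to co-methylation blocks and genomic coordinates.

    Blocks hold 1-5 probes, span at most ``block_size_bp`` and are separated
    by 10 kb so windows never bridge blocks; blocks rotate over 22 autosomes
    (sex-flagged probes are relabelled chrX afterwards).
    """
    sizes: list[int] = []
    total = 0
    while total < cfg.n_probes:
        s = int(rng.integers(1, 6))
        s = min(s, cfg.n_probes - total)
        sizes.append(s)
        total += s
    block_of = np.repeat(np.arange(len(sizes)), sizes)
    chroms = np.empty(cfg.n_probes, dtype=object)
    pos = np.empty(cfg.n_probes, dtype=int)
    next_pos = {}
    i = 0
    for b, s in enumerate(sizes):
        chrom = f"chr{(b % 22) + 1}"
        start = next_pos.get(chrom, 1000)
        step = max(cfg.block_size_bp // max(s, 1), 2)
        for j in range(s):
            chroms[i] = chrom
            pos[i] = start + j * step
            i += 1
        next_pos[chrom] = start + cfg.block_size_bp + 10_000
    return block_of, chroms, pos, sizes


def generate_cohort(config: CohortConfig) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a full case/control methylation cohort.

    Returns ``(beta, sample_sheet, probe_annotation, ground_truth)``.
    Beta values are clipped to [0, 1]; planted MVP and batch probes are
    placed on clean autosomal CpG probes with intermediate baselines so the
    configured beta-scale shifts survive without truncation.
    """
    cfg = config
    cfg.validate()
    rngs = _spawn(cfg.seed, 8)
    r_layout, r_base, r_cells, r_effects, r_noise, r_batch, r_det, r_annot = rngs

    n = cfg.n_probes
    probe_ids = np.array([f"cg{i:07d}" for i in range(n)])
    block_of, chroms, pos, block_sizes = _layout_blocks(cfg, r_layout)

    # --- probe roles: MVPs on multi-probe blocks, batch probes elsewhere ---
    first_of_block = np.searchsorted(np.cumsum([0] + block_sizes)[:-1], np.arange(len(block_sizes)))
    block_start = np.concatenate([[0], np.cumsum(block_sizes)[:-1]])
    multi_blocks = [b for b, s in enumerate(block_sizes) if s >= 2]
    r_layout.shuffle(multi_blocks)
    if cfg.n_true_mvps > len(multi_blocks):
        raise ValueError("not enough multi-probe blocks for the requested MVPs")
    mvp_blocks = multi_blocks[: cfg.n_true_mvps]
    mvp_idx = np.array([block_start[b] for b in mvp_blocks], dtype=int)
    taken = set(mvp_blocks)
    avail = np.array([i for i in range(n) if block_of[i] not in taken])
    batch_idx = r_layout.choice(avail, size=cfg.n_batch_probes, replace=False)

    # --- baselines: bimodal across the array, intermediate at planted probes ---
    comp = r_base.choice(3, size=n, p=[0.42, 0.42, 0.16])
    centers = np.array([logit2(0.08), logit2(0.92), 0.0])
    m0 = centers[comp] + r_base.normal(0, 0.8, size=n)
    inter = r_base.uniform(0.20, 0.65, size=n)
    planted = np.zeros(n, dtype=bool)
    planted[mvp_idx] = True
    # block mates of MVPs also need headroom for the leaked effect
    for b in mvp_blocks:
        planted[block_start[b] : block_start[b] + block_sizes[b]] = True
    planted[batch_idx] = True
    m0[planted] = logit2(inter[planted])
    base_beta = expit2(m0)

    # --- planted case effects (beta-scale targets, applied on the M scale) ---
    true_effect = np.zeros(n)
    h = cfg.effect_heterogeneity
    mags = cfg.effect_size * r_effects.uniform(1 - h, 1, size=cfg.n_true_mvps)
    signs = r_effects.choice([-1.0, 1.0], size=cfg.n_true_mvps)
    for b, mag, sign in zip(mvp_blocks, mags, signs):
        lo, size = block_start[b], block_sizes[b]
        idx = np.arange(lo, lo + size)
        eff = np.full(size, sign * mag * cfg.neighbor_effect_frac)
        eff[0] = sign * mag  # the MVP probe itself carries the full effect
        true_effect[idx] = eff

    # --- samples ---
    n_samp = cfg.n_case + cfg.n_control
    sample_ids = np.array([f"S{i:03d}" for i in range(n_samp)])
    group = np.array(["case"] * cfg.n_case + ["control"] * cfg.n_control)
    is_case = (group == "case").astype(float)
    sex = r_cells.choice(["M", "F"], size=n_samp)
    age = np.round(np.clip(r_cells.normal(5.3, 2.0, size=n_samp), 0.5, None), 1)
    batch = np.array([f"B{i % max(cfg.n_batches, 1)}" for i in range(n_samp)])

    # --- cell composition (Dirichlet, group-shifted mean) ---
    k = max(cfg.n_cell_types, 1)
    mean_ctl = np.full(k, 1.0 / k)
    mean_case = mean_ctl.copy()
    if k > 1 and cfg.confound_strength:
        d = min(cfg.confound_strength, 1.0 - mean_ctl[0])
        mean_case[0] += d
        mean_case[1:] -= d / (k - 1)
    props = np.empty((n_samp, k))
    for i in range(n_samp):
        mu = mean_case if group[i] == "case" else mean_ctl
        props[i] = r_cells.dirichlet(mu * cfg.dirichlet_concentration)
    cell_off = r_cells.normal(0, cfg.cell_profile_sd, size=(n, k))

    # --- assemble the clean (pre-noise, pre-batch) beta signal ---
    n_blocks = len(block_sizes)
    block_latent = r_effects.normal(0, cfg.block_latent_sd, size=(n_blocks, n_samp))
    shared_m = m0[:, None] + block_latent[block_of, :]
    clean = np.zeros((n, n_samp))
    for j in range(k):
        clean += props[:, j][None, :] * expit2(shared_m + cell_off[:, j][:, None])

    # case effect applied on the logit scale of the mixed signal, with the
    # shift calibrated at each probe's realised mean baseline so the planted
    # beta-scale difference is exact in expectation
    eff_rows = np.where(true_effect != 0)[0]
    if eff_rows.size:
        baseline = clean[eff_rows].mean(axis=1)
        target = np.clip(baseline + true_effect[eff_rows], _EPS, 1 - _EPS)
        delta_m = logit2(target) - logit2(baseline)
        case_cols = is_case.astype(bool)
        block_case = clean[np.ix_(eff_rows, case_cols)]
        clean[np.ix_(eff_rows, case_cols)] = expit2(logit2(block_case) + delta_m[:, None])

    noise = r_noise.normal(0, cfg.noise_sd, size=(n, n_samp))
    beta = expit2(logit2(clean) + noise)

    # --- re-batch duplicates: same clean signal, fresh noise + batch offsets ---
    case_pos = np.where(group == "case")[0][: cfg.n_rebatch_pairs]
    ctl_pos = np.where(group == "control")[0][: cfg.n_rebatch_pairs]
    rb_pos = np.concatenate([case_pos, ctl_pos])
    rb_ids = np.array([f"{sample_ids[i]}_rb" for i in rb_pos])

    # heterogeneous loading magnitudes: the cleanest (largest-loading) probes
    # anchor the covariate selection; the mean magnitude equals batch_shift
    # heterogeneous loading magnitudes: the cleanest (largest-loading) probes
    # anchor the covariate selection; the mean magnitude equals batch_shift
    loadings = (
        cfg.batch_shift
        * r_batch.uniform(0.75, 1.25, size=cfg.n_batch_probes)
        * r_batch.choice([-1.0, 1.0], size=cfg.n_batch_probes)
    )
    factor_of = np.arange(cfg.n_batch_probes) % max(cfg.n_batch_factors, 1)
    rb_noise = r_noise.normal(0, cfg.noise_sd, size=(n, rb_pos.size))
    rb_beta = expit2(logit2(clean[:, rb_pos]) + rb_noise)
    offsets = np.zeros((cfg.n_batch_probes, rb_pos.size))
    for f in range(max(cfg.n_batch_factors, 1)):
        fac = r_batch.normal(1.0, cfg.batch_factor_sd, size=rb_pos.size)
        rows = factor_of == f
        offsets[rows, :] = loadings[rows][:, None] * fac[None, :]
    rb_beta[batch_idx, :] = rb_beta[batch_idx, :] + offsets
    clipped = (rb_beta < 0).any() or (rb_beta > 1).any()
    if clipped:
        import warnings

        warnings.warn("planted batch offsets pushed beta outside [0, 1]; clipped", stacklevel=2)
    rb_beta = np.clip(rb_beta, 0.0, 1.0)

    all_ids = np.concatenate([sample_ids, rb_ids])
    all_beta = np.concatenate([beta, rb_beta], axis=1)

    # --- detection p-values: failures cluster in consistently bad probes,
    # with a rare isolated background, as on real arrays ---
    det = r_det.beta(1, 200, size=all_beta.shape)
    n_bad = int(round(cfg.bad_probe_frac * n))
    flaggable_idx = np.where(~planted)[0]
    bad_probes = r_det.choice(flaggable_idx, size=min(n_bad, flaggable_idx.size), replace=False)
    fail = r_det.random(all_beta.shape) < cfg.detection_fail_rate
    fail[bad_probes, :] |= r_det.random((bad_probes.size, all_beta.shape[1])) < 0.4
    det[fail] = r_det.uniform(0.051, 0.5, size=int(fail.sum()))

    # --- sample sheet ---
    sheet = pd.DataFrame(
        {
            "sample_id": all_ids,
            "group": np.concatenate([group, group[rb_pos]]),
            "sex": np.concatenate([sex, sex[rb_pos]]),
            "age": np.concatenate([age, age[rb_pos]]),
            "batch": np.concatenate([batch, np.full(rb_pos.size, "RB")]),
            "rebatch_of": [""] * n_samp + list(sample_ids[rb_pos]),
            "tissue": "blood",
        }
    )

    # --- probe annotation ---
    flaggable = ~planted  # planted signal stays on clean autosomal CpG probes
    snp = np.zeros(n, dtype=bool)
    sexc = np.zeros(n, dtype=bool)
    noncpg = np.zeros(n, dtype=bool)
    cand_idx = np.where(flaggable)[0]
    r_annot.shuffle(cand_idx)
    n_snp = int(round(cfg.frac_snp * n))
    n_sex = int(round(cfg.frac_sex_chrom * n))
    n_ncpg = int(round(cfg.frac_non_cpg * n))
    snp[cand_idx[:n_snp]] = True
    sexc[cand_idx[n_snp : n_snp + n_sex]] = True
    noncpg[cand_idx[n_snp + n_sex : n_snp + n_sex + n_ncpg]] = True
    chroms = chroms.copy()
    chroms[sexc] = "chrX"
    promoter = r_annot.random(n) < cfg.frac_promoter
    candidate = r_annot.random(n) < cfg.frac_candidate
    if cfg.mvp_promoter_frac is not None:
        promoter[mvp_idx] = r_annot.random(mvp_idx.size) < cfg.mvp_promoter_frac
    if cfg.mvp_candidate_frac is not None:
        candidate[mvp_idx] = r_annot.random(mvp_idx.size) < cfg.mvp_candidate_frac
    annot = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chroms,
            "pos": pos,
            "strand": "+",
            "snp_affected": snp,
            "sex_chrom": sexc,
            "cpg_context": ~noncpg,
            "promoter": promoter,
            "candidate_region": candidate,
        }
    )

    bm = BetaMatrix(
        pd.DataFrame(all_beta, index=probe_ids, columns=all_ids),
        pd.DataFrame(det, index=probe_ids, columns=all_ids),
    )
    truth = GroundTruth(
        true_mvp_probes=list(probe_ids[mvp_idx]),
        true_batch_probes=list(probe_ids[batch_idx]),
        true_effect=pd.Series(true_effect, index=probe_ids),
        batch_loadings=pd.Series(loadings, index=probe_ids[batch_idx]),
        batch_factor_of=pd.Series(factor_of, index=probe_ids[batch_idx]),
        planted_batch_offsets=pd.DataFrame(offsets, index=probe_ids[batch_idx], columns=rb_ids),
        cell_proportions=pd.DataFrame(props, index=sample_ids, columns=[f"cell{j}" for j in range(k)]),
        block_of=pd.Series(block_of, index=probe_ids),
    )
    return bm, sheet, annot, truth


# ---------------------------------------------------------------------------
# bisulfite amplicon reads
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def make_barcodes(n: int, length: int = 8, seed: int = 0) -> list[str]:
    """Deterministic set of ``n`` distinct fixed-length barcodes."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen = set()
    while len(out) < n:
        bc = "".join(rng.choice(_BASES, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


@dataclass
class SimulatedReads:
    records: list[ReadRecord]
    barcode_map: dict[str, str]  # barcode -> sample_id
    planted_counts: pd.DataFrame  # sample, amplicon, cpg_index, n_meth, n_total


def _bisulfite_read(ref: str, cpg_offsets: set[int], meth_by_offset: dict[int, bool], conversion_failure: float, rng) -> str:
    out = []
    for i, b in enumerate(ref):
        if b == "C":
            if i in cpg_offsets:
                out.append("C" if meth_by_offset[i] else "T")
            else:
                out.append("C" if rng.random() < conversion_failure else "T")
        else:
            out.append(b)
    return "".join(out)


def generate_amplicon_reads(
    panel: list[Amplicon],
    truth: dict[str, dict[str, np.ndarray]],
    n_reads: int,
    base_error: float = 0.0,
    indel_rate: float = 0.0,
    conversion_failure: float = 0.0,
    seed: int = 0,
    barcode_map: dict[str, str] | None = None,
    mean_quality: float = 37.0,
    quality_sd: float = 3.0,
) -> SimulatedReads:
    """Simulate barcoded bisulfite-amplicon FASTQ reads.

    ``truth`` maps sample_id -> amplicon_id -> per-CpG methylation fractions.
    Each read is a bisulfite conversion of the amplicon reference: non-CpG
    cytosines convert C->T unless conversion fails (rate ``conversion_failure``),
    CpG cytosines stay C with their true methylation probability; substitution
    and indel noise is then applied and a sample barcode prepended.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    for rate in (base_error, indel_rate, conversion_failure):
        if not 0 <= rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
    for amp in panel:
        if not amp.cpg_offsets:
            raise ValueError(f"amplicon {amp.amplicon_id} has no CpGs")
    samples = sorted(truth)
    if barcode_map is None:
        bcs = make_barcodes(len(samples), seed=seed)
        barcode_map = {bc: s for bc, s in zip(bcs, samples)}
    bc_of = {s: bc for bc, s in barcode_map.items()}
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    records: list[ReadRecord] = []
    planted = []
    rid = 0
    for sample in samples:
        for amp in panel:
            fracs = np.asarray(truth[sample][amp.amplicon_id], dtype=float)
            if fracs.size != len(amp.cpg_offsets):
                raise ValueError("truth fractions must match the amplicon's CpG count")
            cpg_set = set(amp.cpg_offsets)
            n_meth = np.zeros(fracs.size, dtype=int)
            for _ in range(n_reads):
                states = rng.random(fracs.size) < fracs
                n_meth += states
                meth = dict(zip(amp.cpg_offsets, states))
                seq = _bisulfite_read(amp.ref_seq.upper(), cpg_set, meth, conversion_failure, rng)
                if base_error > 0:
                    chars = np.array(list(seq))
                    hit = rng.random(len(chars)) < base_error
                    if hit.any():
                        repl = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
                        cur = chars[hit]
                        same = repl == cur
                        repl[same] = _BASES[(np.searchsorted(_BASES, cur[same]) + 1) % 4]
                        chars[hit] = repl
                        seq = "".join(chars)
                if indel_rate > 0:
                    out = []
                    for ch in seq:
                        r = rng.random()
                        if r < indel_rate / 2:
                            continue  # deletion
                        out.append(ch)
                        if indel_rate / 2 <= r < indel_rate:
                            out.append(str(rng.choice(_BASES)))  # insertion
                    seq = "".join(out)
                bc = bc_of[sample]
                full = bc + seq
                quals = np.clip(np.round(rng.normal(mean_quality, quality_sd, size=len(full))), 2, 41).astype(int)
                records.append(ReadRecord(f"read{rid:08d}", full, list(quals), barcode=bc))
                rid += 1
            for ci in range(fracs.size):
                planted.append((sample, amp.amplicon_id, ci, int(n_meth[ci]), n_reads))
    counts = pd.DataFrame(planted, columns=["sample_id", "amplicon_id", "cpg_index", "n_meth", "n_total"])
    return SimulatedReads(records, barcode_map, counts)


# ---------------------------------------------------------------------------
# clone-level bisulfite sequencing and paired tissue
# ---------------------------------------------------------------------------


@dataclass
class CloneSet:
    """Cloned bisulfite-sequencing calls for one individual."""

    sample_id: str
    group: str
    calls: np.ndarray  # clones x CpGs, binary

    def methylation_fraction(self) -> float:
        from .stats import clone_methylation

        return clone_methylation(self.calls)


def generate_clones(
    n_samples_per_group: tuple[int, int, int] = (8, 7, 3),
    n_clones: int = 32,
    n_cpgs: int = 33,
    group_meth_prob: tuple[float, float, float] = (0.6, 0.3, 0.3),
    group_names: tuple[str, str, str] = ("affected", "non_penetrant", "non_carrier"),
    seed: int = 0,
) -> list[CloneSet]:
    """Clone-level promoter bisulfite data for three penetrance groups.

    Each clone is an independent Bernoulli vector of CpG states with its
    group's methylation probability.
    """
    if n_clones <= 0 or n_cpgs <= 0:
        raise ValueError("need at least one clone and one CpG")
    if any(not 0 <= p <= 1 for p in group_meth_prob):
        raise ValueError("group methylation probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[CloneSet] = []
    i = 0
    for name, count, prob in zip(group_names, n_samples_per_group, group_meth_prob):
        for _ in range(count):
            calls = (rng.random((n_clones, n_cpgs)) < prob).astype(float)
            out.append(CloneSet(f"P{i:02d}", name, calls))
            i += 1
    return out


def generate_paired_tissue(
    n_individuals: int = 18,
    n_sites: int = 11,
    correlation: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired blood/lip methylation values with a target Pearson r.

    Blood values are drawn from a bimodal Beta(0.4, 0.4); lip values add
    Gaussian noise scaled so the pooled correlation approaches the target,
    then both are clipped to [0, 1].
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if not -1 <= correlation <= 1:
        raise ValueError("correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    m = n_sites * n_individuals
    blood = rng.beta(0.4, 0.4, size=m)
    base = blood if correlation >= 0 else 1.0 - blood
    if abs(correlation) >= 1 - 1e-12:
        lip = base.copy()
    else:
        sd_x = np.sqrt(0.4 * 0.4 / (0.8**2 * 1.8))  # sd of Beta(0.4, 0.4)
        sd_n = sd_x * np.sqrt(1.0 / correlation**2 - 1.0) if correlation != 0 else 10.0
        lip = np.clip(base + rng.normal(0, sd_n, size=m), 0.0, 1.0)
    return pd.DataFrame(
        {
            "site_id": np.repeat([f"amp{j:02d}" for j in range(n_sites)], n_individuals),
            "individual": np.tile([f"I{i:02d}" for i in range(n_individuals)], n_sites),
            "blood": blood,
            "lip": lip,
        }
    )
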