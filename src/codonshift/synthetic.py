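"""Synthetic CDS sets and abundance cohorts with known ground truth.

The generator emulates the statistical structure the whole analysis assumes
about a human-like transcriptome and a case/control expression study:

* per-gene GC3 content drawn from a two-component normal mixture
  (defaults 35 +/- 6 and 70 +/- 6 percent, weights 0.4/0.6 — the two peaks
  of the human GC3 histogram);
* two planted, functionally opposed gene groups: GP1 (AU3-rich, drawn from
  the low-GC3 component) and GP2 (GC3-rich, high component);
* control cohorts in which log2 abundance is positively coupled to GC3
  content (GC3 codons preferred in normal tissue);
* disease cohorts generated under the *causal* employment-shift model: the
  control expectation shifted by ``beta`` log2 units per unit of centred
  AU3 fraction, favouring AU3-rich transcripts;
* independent per-gene/per-sample log-normal noise.

Every dataset carries a :class:`GroundTruth` sufficient to predict the sign
of each downstream statistic and to re-estimate the generator parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cec import AbundanceMatrix
from .codon_core import CodingSequence
from .enrichment import GeneSetCollection
from .genetic_code import SENSE_CODONS, STOP_CODONS, SYNONYMOUS_FAMILIES

#: human-like amino-acid frequencies (percent, order = sorted one-letter
#: codes); rounded literature consensus values, normalised at use
HUMAN_AA_FREQ: dict[str, float] = {
    "A": 7.0, "C": 2.3, "D": 4.7, "E": 7.1, "F": 3.7, "G": 6.6, "H": 2.6,
    "I": 4.3, "K": 5.7, "L": 10.0, "M": 2.1, "N": 3.6, "P": 6.3, "Q": 4.8,
    "R": 5.6, "S": 8.3, "T": 5.4, "V": 6.0, "W": 1.2, "Y": 2.7,
}


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic CDS set."""

    n_genes: int = 1200
    length_log_mean: float = float(np.log(300.0))   # log codon count
    length_log_sd: float = 0.35
    min_codons: int = 60
    gc3_components: tuple[tuple[float, float, float], ...] = (
        (35.0, 6.0, 0.4),   # (mean %, sd %, weight): AU3-rich peak
        (70.0, 6.0, 0.6),   # GC3-rich peak
    )
    gp1_frac: float = 0.10
    gp2_frac: float = 0.10
    aa_freq: tuple[tuple[str, float], ...] = tuple(sorted(HUMAN_AA_FREQ.items()))
    seed: int = 0

    def __post_init__(self) -> None:
        weights = [w for _, _, w in self.gc3_components]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not (0 <= self.gp1_frac and 0 <= self.gp2_frac
                and self.gp1_frac + self.gp2_frac <= 1):
            raise ValueError("gp1_frac/gp2_frac must be fractions summing to <= 1")
        for m, s, _ in self.gc3_components:
            if not (0 < m <= 100) or s <= 0:
                raise ValueError("component means must lie in (0,100], sd > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic control/disease abundance cohort.

    Per-patient heterogeneity enters through random slopes: each sample's
    effective GC3 coupling is N(coupling, coupling_sd) and each disease
    sample's effective shift is N(beta, beta_sd) — patients differ in their
    differentiation state and in how far the employment shift has
    progressed.  Genes outside the planted GP1/GP2 groups get their
    per-sample noise multiplied by ``extra_noise_factor``: their expression
    is dominated by programs unrelated to codon composition, which is what
    makes subset-restricted scoring worthwhile on real cohorts.
    """

    n_control: int = 25
    n_disease: int = 25
    base_log2_mean: float = 5.0
    base_log2_sd: float = 1.5
    control_gc3_coupling: float = 5.0   # log2 units per unit centred GC3 fraction
    coupling_sd: float = 1.0            # per-sample SD of the coupling
    beta: float = 9.0                   # causal AU3 coefficient (disease)
    beta_sd: float = 1.0                # per-sample SD of the disease shift
    noise_sd: float = 0.5               # per-gene/per-sample log2 noise
    extra_noise_factor: float = 3.0     # noise multiplier outside GP1 u GP2
    n_noise_blocks: int = 10            # co-regulated blocks of non-group genes
    block_sd: float = 2.5               # per-sample log2 SD of each block effect
    seed: int = 0
    base_seed: int | None = None        # share per-gene baselines across studies

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_disease < 2:
            raise ValueError("need >= 2 samples per arm")
        if self.noise_sd < 0 or self.coupling_sd < 0 or self.beta_sd < 0:
            raise ValueError("noise/slope SDs must be non-negative")
        if self.extra_noise_factor < 1:
            raise ValueError("extra_noise_factor must be >= 1")


def strong_effect_cohort(seed: int = 0, **overrides) -> "CohortSpec":
    """Preset reaching near-perfect GP1-subset diagnostic separation
    (the defaults)."""
    return CohortSpec(seed=seed, **overrides)


def weak_effect_cohort(seed: int = 0, **overrides) -> "CohortSpec":
    """Preset with a marginal employment shift (GP1-subset diagnostics in
    the mid-80s-percent regime)."""
    params = dict(beta=3.0, beta_sd=1.0)
    params.update(overrides)
    return CohortSpec(seed=seed, **params)


@dataclass
class GroundTruth:
    """Everything needed to predict downstream statistics of a dataset."""

    gene_ids: list[str]
    target_gc3_pct: list[float]
    realized_gc3_pct: list[float]        # stop-inclusive denominator convention
    realized_au3_pct: list[float]
    gp1: list[str]
    gp2: list[str]
    genome_params: dict = field(default_factory=dict)
    cohort_params: dict = field(default_factory=dict)
    true_log2_fold: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "target_gc3_pct": self.target_gc3_pct,
                "realized_gc3_pct": self.realized_gc3_pct,
                "realized_au3_pct": self.realized_au3_pct,
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )
        df["group"] = "none"
        df.loc[df.index.isin(self.gp1), "group"] = "GP1"
        df.loc[df.index.isin(self.gp2), "group"] = "GP2"
        return df


# ---------------------------------------------------------------------------
# CDS generation
# ---------------------------------------------------------------------------

def _codon_class_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per (amino acid index, wobble class) codon lookup arrays.

    Returns (codon_idx[aa, cls, slot], counts[aa, cls], aa order) where
    cls 0 = A/T-ending, 1 = G/C-ending and codon_idx indexes SENSE_CODONS.
    """
    aas = sorted(HUMAN_AA_FREQ)
    max_slots = 4
    idx = np.full((len(aas), 2, max_slots), -1, dtype=int)
    counts = np.zeros((len(aas), 2), dtype=int)
    codon_pos = {c: i for i, c in enumerate(SENSE_CODONS)}
    for a, aa in enumerate(aas):
        for codon in SYNONYMOUS_FAMILIES[aa]:
            cls = 1 if codon[2] in "GC" else 0
            if counts[a, cls] < max_slots:
                idx[a, cls, counts[a, cls]] = codon_pos[codon]
                counts[a, cls] += 1
    return idx, counts, np.array(aas)


_CODON_IDX, _CLASS_COUNTS, _AA_ORDER = _codon_class_tables()
_SENSE_ARR = np.array(SENSE_CODONS)


def generate_cds_set(spec: GenomeSpec) -> tuple[list[CodingSequence], GroundTruth]:
    """Draw a synthetic CDS set with per-gene GC3 targets from the mixture.

    Each gene: ATG start, amino acids sampled from ``aa_freq``, each
    synonymous codon's wobble class chosen G/C-ending with probability equal
    to the gene's target GC3 (single-class families use their only option),
    a uniform stop codon appended.  Planted GP1 genes draw their target from
    the low-GC3 component, GP2 from the high one.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]

    # mixture component per gene, with GP1/GP2 planted into the extremes
    comps = np.array(spec.gc3_components)          # (k, 3)
    low_comp = int(np.argmin(comps[:, 0]))
    high_comp = int(np.argmax(comps[:, 0]))
    comp_of_gene = rng.choice(len(comps), size=n, p=comps[:, 2])
    n_gp1 = int(round(spec.gp1_frac * n))
    n_gp2 = int(round(spec.gp2_frac * n))
    planted = rng.choice(n, size=n_gp1 + n_gp2, replace=False)
    gp1_idx, gp2_idx = planted[:n_gp1], planted[n_gp1:]
    comp_of_gene[gp1_idx] = low_comp
    comp_of_gene[gp2_idx] = high_comp

    target = rng.normal(comps[comp_of_gene, 0], comps[comp_of_gene, 1])
    target = np.clip(target, 0.5, 100.0)

    n_sense = np.maximum(
        spec.min_codons,
        np.round(np.exp(rng.normal(spec.length_log_mean, spec.length_log_sd, n))).astype(int),
    )

    aa_names = [a for a, _ in spec.aa_freq]
    if aa_names != list(_AA_ORDER):
        raise ValueError("aa_freq must cover the 20 amino acids in sorted order")
    p_aa = np.array([f for _, f in spec.aa_freq], dtype=float)
    p_aa = p_aa / p_aa.sum()

    n_draw = n_sense - 1                              # minus the fixed ATG
    total = int(n_draw.sum())
    gene_of_pos = np.repeat(np.arange(n), n_draw)
    aa_idx = rng.choice(len(p_aa), size=total, p=p_aa)
    # Met and Trp have no A/T-ending codon, so a fraction f of positions is
    # forced G/C-ending; the free-position probability is corrected so that
    # the realized sense GC3 matches the drawn target on average
    forced_frac = float(p_aa[_CLASS_COUNTS[:, 0] == 0].sum())
    t_free = np.clip(
        (target / 100.0 - forced_frac) / (1.0 - forced_frac), 0.0, 1.0
    )
    want_gc = (rng.random(total) < t_free[gene_of_pos]).astype(int)
    # nearest-feasible fallback for single-class families (Met, Trp)
    avail = _CLASS_COUNTS[aa_idx, want_gc]
    infeasible = avail == 0
    want_gc[infeasible] = 1 - want_gc[infeasible]
    avail = _CLASS_COUNTS[aa_idx, want_gc]
    slot = (rng.random(total) * avail).astype(int)
    codon_idx = _CODON_IDX[aa_idx, want_gc, slot]
    codon_strs = _SENSE_ARR[codon_idx]

    stop_arr = np.array(STOP_CODONS)
    stops = stop_arr[rng.integers(0, len(STOP_CODONS), size=n)]

    offsets = np.concatenate([[0], np.cumsum(n_draw)])
    seqs: list[CodingSequence] = []
    realized_gc3 = np.empty(n)
    realized_au3 = np.empty(n)
    for i, gid in enumerate(gene_ids):
        body = codon_strs[offsets[i]: offsets[i + 1]]
        seq = "ATG" + "".join(body) + stops[i]
        n_codons = n_sense[i] + 1
        gc = 1 + int(want_gc[offsets[i]: offsets[i + 1]].sum())  # +1 for ATG
        realized_gc3[i] = 100.0 * gc / n_codons
        realized_au3[i] = 100.0 * (n_sense[i] - gc) / n_codons
        seqs.append(CodingSequence(gene_id=gid, sequence=seq))

    truth = GroundTruth(
        gene_ids=gene_ids,
        target_gc3_pct=[float(t) for t in target],
        realized_gc3_pct=[float(v) for v in realized_gc3],
        realized_au3_pct=[float(v) for v in realized_au3],
        gp1=[gene_ids[i] for i in sorted(gp1_idx)],
        gp2=[gene_ids[i] for i in sorted(gp2_idx)],
        genome_params={
            "n_genes": n, "seed": spec.seed,
            "gc3_components": [list(c) for c in spec.gc3_components],
            "gp1_frac": spec.gp1_frac, "gp2_frac": spec.gp2_frac,
            "length_log_mean": spec.length_log_mean,
            "length_log_sd": spec.length_log_sd,
        },
    )
    return seqs, truth


def write_fasta(seqs, path: str | Path, width: int = 70) -> None:
    """Plain FASTA writer with fixed line width (byte-stable output)."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.gene_id}\n")
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i: i + width] + "\n")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    truth: GroundTruth, spec: CohortSpec
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Control/disease abundance cohort under the causal shift model.

    Control sample s, gene g:
        log2 a = base_g + c_s * (gc3_g - mean gc3)/100 + sigma_g * N(0, 1)
    with per-sample coupling c_s ~ N(coupling, coupling_sd) and noise scale
    sigma_g = noise_sd inside GP1/GP2 and noise_sd * extra_noise_factor
    outside.  Disease sample s adds b_s * (au3_g - mean au3)/100 with
    b_s ~ N(beta, beta_sd).  Non-group genes are additionally partitioned
    into ``n_noise_blocks`` co-regulated blocks, each receiving an
    independent N(0, block_sd) per-sample offset — the tissue-composition
    and pathway-activity variability that dominates genes not governed by
    the compositional program.  Blocks are contiguous in GC3 rank: real
    co-regulated programs are composition-coherent, which is what makes
    whole-transcriptome codon-employment readouts noisier than
    group-restricted ones.  The expected per-gene log2 fold change
    (beta * centred AU3 fraction) is stored in the returned GroundTruth.
    """
    rng = np.random.default_rng(spec.seed)
    gc3 = np.array(truth.realized_gc3_pct)
    au3 = np.array(truth.realized_au3_pct)
    n = len(truth.gene_ids)
    base_rng = rng if spec.base_seed is None else np.random.default_rng(spec.base_seed)
    base = base_rng.normal(spec.base_log2_mean, spec.base_log2_sd, size=n)
    gc3_cov = (gc3 - gc3.mean()) / 100.0
    au3_cov = (au3 - au3.mean()) / 100.0
    in_group = np.isin(truth.gene_ids, list(truth.gp1) + list(truth.gp2))
    sigma = np.where(in_group, spec.noise_sd,
                     spec.noise_sd * spec.extra_noise_factor)
    # block membership: -1 for group genes; non-group genes split into
    # contiguous GC3-rank chunks (composition-coherent programs)
    block = np.full(n, -1)
    free = np.flatnonzero(~in_group)
    if spec.n_noise_blocks > 0 and free.size:
        order = free[np.argsort(gc3[free], kind="stable")]
        chunks = np.array_split(order, spec.n_noise_blocks)
        for b, chunk in enumerate(chunks):
            block[chunk] = b
    shift = spec.beta * au3_cov

    def _sample(extra: np.ndarray) -> np.ndarray:
        eps = sigma * rng.normal(0, 1, size=n)
        if spec.n_noise_blocks > 0 and spec.block_sd > 0 and free.size:
            block_eff = rng.normal(0, spec.block_sd, size=spec.n_noise_blocks)
            eps = eps + np.where(block >= 0, block_eff[block], 0.0)
        return base + extra + eps

    cols, data, labels = [], [], {}
    for i in range(spec.n_control):
        sid = f"ctrl_{i:03d}"
        cols.append(sid)
        labels[sid] = "control"
        c_s = rng.normal(spec.control_gc3_coupling, spec.coupling_sd)
        data.append(_sample(c_s * gc3_cov))
    for i in range(spec.n_disease):
        sid = f"dis_{i:03d}"
        cols.append(sid)
        labels[sid] = "disease"
        c_s = rng.normal(spec.control_gc3_coupling, spec.coupling_sd)
        b_s = rng.normal(spec.beta, spec.beta_sd)
        data.append(_sample(c_s * gc3_cov + b_s * au3_cov))
    values = pd.DataFrame(
        2.0 ** np.column_stack(data),
        index=pd.Index(truth.gene_ids, name="gene_id"),
        columns=cols,
    )
    cohort_truth = GroundTruth(
        gene_ids=truth.gene_ids,
        target_gc3_pct=truth.target_gc3_pct,
        realized_gc3_pct=truth.realized_gc3_pct,
        realized_au3_pct=truth.realized_au3_pct,
        gp1=truth.gp1,
        gp2=truth.gp2,
        genome_params=truth.genome_params,
        cohort_params={
            "n_control": spec.n_control, "n_disease": spec.n_disease,
            "control_gc3_coupling": spec.control_gc3_coupling,
            "coupling_sd": spec.coupling_sd,
            "beta": spec.beta, "beta_sd": spec.beta_sd,
            "noise_sd": spec.noise_sd,
            "extra_noise_factor": spec.extra_noise_factor,
            "seed": spec.seed, "base_seed": spec.base_seed,
            "base_log2_mean": spec.base_log2_mean,
            "base_log2_sd": spec.base_log2_sd,
        },
        true_log2_fold={g: float(s) for g, s in zip(truth.gene_ids, shift)},
    )
    return AbundanceMatrix(values=values, labels=labels), cohort_truth


def make_gene_sets(
    truth: GroundTruth,
    n_decoys: int = 8,
    decoy_size: int = 40,
    seed: int = 0,
) -> GeneSetCollection:
    """Gene sets for enrichment tests: the planted GP1 and GP2 memberships
    plus random decoy sets drawn from the unplanted genes."""
    rng = np.random.default_rng(seed)
    planted = set(truth.gp1) | set(truth.gp2)
    pool = [g for g in truth.gene_ids if g not in planted]
    sets: dict[str, tuple[str, tuple[str, ...]]] = {
        "GP1_planted": ("planted AU3-rich group", tuple(truth.gp1)),
        "GP2_planted": ("planted GC3-rich group", tuple(truth.gp2)),
    }
    for d in range(n_decoys):
        members = rng.choice(pool, size=min(decoy_size, len(pool)), replace=False)
        sets[f"decoy_{d:02d}"] = ("random decoy set", tuple(sorted(members)))
    return GeneSetCollection(sets=sets)


def recover_generator_coefficients(
    abundance: AbundanceMatrix, truth: GroundTruth
) -> dict[str, dict[str, float]]:
    """Re-estimate beta and the control GC3 coupling by least squares.

    beta: regress the per-gene log2 fold change (disease mean minus control
    mean) on the centred AU3 fraction; coupling: regress the control-mean
    log2 abundance on the centred GC3 fraction (the unknown per-gene
    baseline acts as residual noise).  The two covariates are near-
    perfectly anti-correlated, so single-covariate fits are used — a joint
    fit would be ill-conditioned.  Standard errors combine the regression
    SE with the between-patient spread of per-sample slope estimates, which
    accounts for the generator's random slopes.
    """
    log2a = np.log2(abundance.values.to_numpy(dtype=float))
    cols = list(abundance.sample_ids)
    is_ctrl = np.array([abundance.labels[c] == "control" for c in cols])
    ctrl_mean = log2a[:, is_ctrl].mean(axis=1)
    dis_mean = log2a[:, ~is_ctrl].mean(axis=1)
    au3 = np.array(truth.realized_au3_pct)
    gc3 = np.array(truth.realized_gc3_pct)
    au3_cov = (au3 - au3.mean()) / 100.0
    gc3_cov = (gc3 - gc3.mean()) / 100.0

    def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        X = np.column_stack([np.ones_like(x), x])
        XtX_inv = np.linalg.inv(X.T @ X)
        coef = XtX_inv @ (X.T @ y)
        resid = y - X @ coef
        s2 = (resid**2).sum() / (len(y) - 2)
        return float(coef[1]), float(np.sqrt(s2 * XtX_inv[1, 1]))

    def _between_se(x: np.ndarray, Y: np.ndarray, baseline: np.ndarray) -> float:
        slopes = [_ols(x, Y[:, j] - baseline)[0] for j in range(Y.shape[1])]
        n = len(slopes)
        return float(np.std(slopes, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    beta_est, beta_se = _ols(au3_cov, dis_mean - ctrl_mean)
    beta_between = _between_se(au3_cov, log2a[:, ~is_ctrl], ctrl_mean)
    cpl_est, cpl_se = _ols(gc3_cov, ctrl_mean)
    cpl_between = _between_se(gc3_cov, log2a[:, is_ctrl], np.zeros_like(ctrl_mean))
    return {
        "beta": {
            "estimate": beta_est,
            "se": float(np.hypot(beta_se, beta_between)),
        },
        "control_gc3_coupling": {
            "estimate": cpl_est,
            "se": float(np.hypot(cpl_se, cpl_between)),
        },
    }
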