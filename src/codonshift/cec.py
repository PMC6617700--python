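"""Codon employment coefficients (CEC) and derived cohort statistics.

The CEC of a codon, in one sample, is the Pearson correlation across genes
between the codon's percentage in each transcript and the transcript's
abundance.  Codons preferred by abundant transcripts get positive CECs;
codons typical of low-abundance transcripts get negative ones.  Built on
top of that:

* cohort aggregation (mean +/- SEM over per-sample CEC vectors),
* the employment shift between two cohorts (average relative CEC change,
  in percent of the control values, summarised over AU3 and GC3 codons),
* CorrCEC — per-transcript correlation of its 61-codon composition with
  the control and disease CEC vectors (negative score: composition matches
  the control employment; positive: the disease employment).

Abundances are log2(1+x)-transformed before correlation by default; raw
mode is available everywhere via ``transform="raw"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genetic_code import AU3_CODONS, GC3_CODONS, SENSE_CODONS

Transform = Literal["log2p1", "raw"]

#: minimum shared genes between composition and abundance (configurable floor)
MIN_SHARED_GENES = 10


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Genes x samples abundance table with optional control/disease labels."""

    values: pd.DataFrame                       # genes x samples, non-negative
    labels: dict[str, str] | None = None       # sample_id -> control|disease
    transform: Transform = "log2p1"            # provenance of downstream use

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)}")
        if self.labels is not None:
            unknown = set(self.labels) - set(self.values.columns)
            if unknown:
                raise ValueError(f"labels for unknown samples: {sorted(unknown)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_with_label(self, label: str) -> list[str]:
        if self.labels is None:
            raise ValueError("abundance matrix has no labels")
        return [s for s in self.sample_ids if self.labels.get(s) == label]


@dataclass(frozen=True)
class CECVector:
    """61 per-codon Pearson coefficients for one sample (or cohort tag)."""

    sample_id: str
    r: pd.Series                  # indexed by SENSE_CODONS; NaN = undefined
    n_genes: int

    def defined(self) -> pd.Series:
        return self.r.dropna()


@dataclass(frozen=True)
class CohortCEC:
    mean: pd.Series               # 61 entries, NaN-aware mean over samples
    sem: pd.Series
    n_samples: int
    per_sample: pd.DataFrame = field(repr=False, default=None)  # samples x 61


@dataclass(frozen=True)
class EmploymentShift:
    """Relative CEC change disease vs control, in % of the control values."""

    au3_shift_pct: float
    gc3_shift_pct: float
    per_codon: pd.Series          # 61 entries; NaN where |control| < epsilon
    excluded: tuple[str, ...]     # codons dropped by the epsilon floor


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _apply_transform(x: np.ndarray, transform: Transform) -> np.ndarray:
    if transform == "log2p1":
        return np.log2(1.0 + x)
    if transform == "raw":
        return np.asarray(x, dtype=float)
    raise ValueError(f"unknown transform {transform!r}")


def columnwise_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each column of X and y; NaN for zero variance.

    Exactly constant vectors are flagged undefined explicitly (float
    summation of identical values need not centre to exactly zero).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[~np.isfinite(r)] = np.nan
    r[np.ptp(X, axis=0) == 0] = np.nan
    if np.ptp(y) == 0:
        r[:] = np.nan
    return np.clip(r, -1.0, 1.0)


def _composition_pct(comp: pd.DataFrame) -> pd.DataFrame:
    """Extract the 61 codon-percentage columns in canonical order."""
    missing = [c for c in SENSE_CODONS if c not in comp.columns]
    if missing:
        raise ValueError(f"composition table lacks codon columns: {missing[:5]}...")
    return comp[list(SENSE_CODONS)]


def align_genes(
    comp: pd.DataFrame, abundance: AbundanceMatrix, subset: Sequence[str] | None = None
) -> pd.Index:
    """Intersection of composition and abundance gene universes (optionally
    restricted to a subset); order follows the composition table."""
    shared = comp.index.intersection(abundance.gene_ids)
    if subset is not None:
        shared = shared.intersection(pd.Index(subset))
    n_unmatched = len(comp.index) - len(comp.index.intersection(abundance.gene_ids))
    if n_unmatched:
        warnings.warn(f"{n_unmatched} composition genes absent from abundance table")
    if len(shared) < MIN_SHARED_GENES:
        warnings.warn(
            f"only {len(shared)} genes shared between composition and abundance"
        )
    return shared


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_cec(
    comp: pd.DataFrame,
    abundance: pd.Series,
    subset: Sequence[str] | None = None,
    transform: Transform = "log2p1",
) -> CECVector:
    """CEC vector of one sample: per sense codon, the Pearson correlation
    across genes between codon percentage and (transformed) abundance.

    Invariant under positive affine transforms of the (transformed)
    abundance.  Zero-variance columns — constant codon percentage, or a
    constant abundance vector — give NaN entries, never silent zeros.
    """
    genes = comp.index.intersection(abundance.index)
    if subset is not None:
        genes = genes.intersection(pd.Index(subset))
    if len(genes) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(genes)}")
    X = _composition_pct(comp.loc[genes]).to_numpy(dtype=float)
    y = abundance.loc[genes].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("abundance contains non-finite values")
    y = _apply_transform(y, transform)
    r = columnwise_pearson(X, y)
    name = abundance.name if abundance.name is not None else "sample"
    return CECVector(
        sample_id=str(name),
        r=pd.Series(r, index=list(SENSE_CODONS)),
        n_genes=int(len(genes)),
    )


def per_sample_cec(
    comp: pd.DataFrame,
    abundance: AbundanceMatrix,
    samples: Sequence[str] | None = None,
    subset: Sequence[str] | None = None,
    transform: Transform = "log2p1",
) -> pd.DataFrame:
    """Samples x 61 matrix of per-sample CEC vectors (vectorised)."""
    cols = list(samples) if samples is not None else list(abundance.sample_ids)
    genes = align_genes(comp, abundance, subset)
    if len(genes) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(genes)}")
    X = _composition_pct(comp.loc[genes]).to_numpy(dtype=float)
    Y = _apply_transform(
        abundance.values.loc[genes, cols].to_numpy(dtype=float), transform
    )
    # r[s, c] = corr(X[:, c], Y[:, s]) for every sample at once
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))           # (61,)
    sy = np.sqrt((Yc**2).sum(axis=0))           # (n_samples,)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Yc.T @ Xc) / np.outer(sy, sx)
    R[~np.isfinite(R)] = np.nan
    R[np.ptp(Y, axis=0) == 0, :] = np.nan   # constant sample
    R[:, np.ptp(X, axis=0) == 0] = np.nan   # constant codon column
    return pd.DataFrame(np.clip(R, -1, 1), index=cols, columns=list(SENSE_CODONS))


def cohort_cec(
    comp: pd.DataFrame,
    abundance: AbundanceMatrix,
    label: str | None = None,
    subset: Sequence[str] | None = None,
    transform: Transform = "log2p1",
    aggregate: Literal["per_sample", "mean_abundance"] = "per_sample",
) -> CohortCEC:
    """Aggregate CEC over a cohort: per-sample CEC vectors averaged (default)
    with SEM = sd/sqrt(n); undefined entries are excluded pairwise.

    ``aggregate="mean_abundance"`` instead computes one CEC on the mean
    abundance profile of the cohort.
    """
    if label is not None:
        cols = abundance.samples_with_label(label)
        if not cols:
            raise ValueError(f"no samples labelled {label!r}")
    else:
        cols = list(abundance.sample_ids)
    if len(cols) < 2 and aggregate == "per_sample":
        raise ValueError(f"need >= 2 samples for cohort aggregation, got {len(cols)}")
    if aggregate == "mean_abundance":
        mean_ab = abundance.values[cols].mean(axis=1)
        vec = compute_cec(comp, mean_ab, subset=subset, transform=transform)
        zeros = pd.Series(0.0, index=vec.r.index)
        return CohortCEC(mean=vec.r, sem=zeros, n_samples=len(cols),
                         per_sample=vec.r.to_frame().T)
    per = per_sample_cec(comp, abundance, cols, subset=subset, transform=transform)
    n_def = per.notna().sum(axis=0)
    mean = per.mean(axis=0, skipna=True)
    sd = per.std(axis=0, ddof=1, skipna=True)
    sem = sd / np.sqrt(n_def.clip(lower=1))
    return CohortCEC(mean=mean, sem=sem, n_samples=len(cols), per_sample=per)


def employment_shift(
    control: CohortCEC, disease: CohortCEC, epsilon: float = 0.01
) -> EmploymentShift:
    """Per-codon relative CEC change, 100*(disease - control)/|control|,
    summarised as means over the AU3 and GC3 sense-codon groups.

    Codons with |control CEC| < epsilon (or undefined in either cohort) are
    excluded from the group means and reported.
    """
    c = control.mean
    d = disease.mean
    denom = c.abs()
    valid = (denom >= epsilon) & c.notna() & d.notna()
    per_codon = pd.Series(np.nan, index=c.index)
    per_codon[valid] = 100.0 * (d[valid] - c[valid]) / denom[valid]
    excluded = tuple(c.index[~valid])

    au3 = per_codon[[x for x in AU3_CODONS]]
    gc3 = per_codon[[x for x in GC3_CODONS]]
    if au3.notna().sum() == 0 or gc3.notna().sum() == 0:
        raise ValueError("all codons of a wobble group excluded by the epsilon floor")
    return EmploymentShift(
        au3_shift_pct=float(au3.mean(skipna=True)),
        gc3_shift_pct=float(gc3.mean(skipna=True)),
        per_codon=per_codon,
        excluded=excluded,
    )


def corrcec(
    comp: pd.DataFrame,
    control_cec: CohortCEC,
    disease_cec: CohortCEC,
    subset: Sequence[str] | None = None,
    scalar: Literal["difference", "delta_corr"] = "difference",
) -> pd.DataFrame:
    """Per-transcript correlation of composition to codon employment.

    For every gene: Pearson r between its 61-codon percentage vector and the
    control cohort CEC (``r_control``), the same against the disease CEC
    (``r_disease``), and ``score``.  Default scalar is the difference
    r_disease - r_control (negative: composition matches the control
    employment; positive: the disease employment).  ``delta_corr`` instead
    correlates the composition against the disease-minus-control CEC vector.
    Codons undefined in either CEC vector are excluded pairwise; genes with
    fewer than 3 usable codons are skipped with a warning.
    """
    genes = comp.index if subset is None else comp.index.intersection(pd.Index(subset))
    X = _composition_pct(comp.loc[genes]).to_numpy(dtype=float)
    c = control_cec.mean.to_numpy(dtype=float)
    d = disease_cec.mean.to_numpy(dtype=float)
    mask = np.isfinite(c) & np.isfinite(d)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 jointly defined CEC entries")
    Xm = X[:, mask]
    keep = np.isfinite(Xm).all(axis=1) & (Xm.std(axis=1) > 0)
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} genes skipped in CorrCEC (degenerate rows)")
    r_ctrl = _rowwise_pearson(Xm[keep], c[mask])
    r_dis = _rowwise_pearson(Xm[keep], d[mask])
    if scalar == "difference":
        score = r_dis - r_ctrl
    elif scalar == "delta_corr":
        score = _rowwise_pearson(Xm[keep], d[mask] - c[mask])
    else:
        raise ValueError(f"unknown scalar {scalar!r}")
    return pd.DataFrame(
        {"r_control": r_ctrl, "r_disease": r_dis, "score": score},
        index=genes[keep],
    )


def _rowwise_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each row of X and the vector y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)
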