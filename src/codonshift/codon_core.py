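"""Codon-level composition statistics for coding sequences.

Parses CDS FASTA files and computes the per-transcript quantities everything
else is built on: codon counts, 61-codon percentage profiles, wobble-position
(GC3 / AU3) content, per-amino-acid synonymous-codon fractions, RSCU, GC3
distribution summaries (median, full width at half maximum) and cross-gene
codon-codon correlation matrices including a split-half control.

Counting conventions
--------------------
* The 61-entry percentage profile is taken over *sense* codons only.
* GC3% and AU3% use the total codon count (stop included) as denominator,
  with stop codons excluded from both numerators.  This is the convention
  under which a 117-codon transcript with 85 G/C-ending and 31 A/T-ending
  sense codons reads 72.65% GC3 and 26.50% AU3.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import (
    AU3_CODONS,
    CODON_TO_AA,
    DEGENERATE_SENSE_CODONS,
    FAMILY_SIZES,
    GC3_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
)

logger = logging.getLogger(__name__)

Policy = Literal["strict", "lenient"]

_VALID_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingSequence:
    """A validated coding sequence (A/C/G/T, length a multiple of 3)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0 or len(self.sequence) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} is not a "
                "positive multiple of 3"
            )
        if not _VALID_BASES.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(f"{self.gene_id}: invalid characters {bad}")

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def codons(self) -> list[str]:
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass(frozen=True)
class RejectedRecord:
    gene_id: str
    reason: str


@dataclass
class ParseResult:
    """Sequences accepted by :func:`parse_cds` plus the rejection report."""

    records: list[CodingSequence]
    rejected: list[RejectedRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class CodonCountTable:
    gene_id: str
    counts: dict[str, int]
    n_sense: int
    n_stop: int

    @property
    def n_codons(self) -> int:
        return self.n_sense + self.n_stop


@dataclass(frozen=True)
class CompositionProfile:
    """Per-gene sense-codon percentages and wobble-position content."""

    gene_id: str
    pct: dict[str, float]          # 61 sense-codon percentages (of n_sense)
    gc3_pct: float                 # % of all codons (stop incl. in denominator)
    au3_pct: float
    n_codons: int
    n_sense: int

    @property
    def valid_pct(self) -> bool:
        return self.n_sense > 0


@dataclass(frozen=True)
class AminoAcidCodonFractions:
    """Fraction each synonymous codon takes of its amino acid, per gene.

    Defined only for amino acids with at least one codon in the gene.
    """

    gene_id: str
    fractions: dict[tuple[str, str], float]  # (aa, codon) -> fraction


@dataclass(frozen=True)
class RSCUTable:
    values: dict[str, float]       # codon -> RSCU; missing => family absent
    family_sizes: dict[str, int]


@dataclass(frozen=True)
class DistributionSummary:
    values: np.ndarray
    median: float
    min: float
    max: float
    fwhm: float | None             # None when undefined (degenerate histogram)
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass(frozen=True)
class CodonCorrelationMatrix:
    codons: tuple[str, ...]
    r: pd.DataFrame                # rows x cols = codons; NaN where undefined
    mode: Literal["full", "split_half"]


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def normalize_sequence(raw: str) -> str:
    """Upper-case and convert RNA (U) to DNA (T)."""
    return str(raw).upper().replace("U", "T")


def parse_cds(fasta_source, policy: Policy = "strict") -> ParseResult:
    """Read a CDS FASTA into validated :class:`CodingSequence` records.

    ``policy='strict'`` rejects records whose length is not a multiple of 3
    or that contain ambiguity codes; ``'lenient'`` trims a trailing partial
    codon and drops triplets containing ambiguity codes.  Duplicate ids keep
    the first record (with a warning).  Raises ``ValueError`` when no record
    survives.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown policy {policy!r}")

    records: list[CodingSequence] = []
    rejected: list[RejectedRecord] = []
    seen: set[str] = set()

    try:
        fasta_iter = SeqIO.parse(fasta_source, "fasta")
        parsed = list(fasta_iter)
    except (OSError, IOError):
        raise
    if not parsed:
        raise ValueError(f"no FASTA records found in {fasta_source!r}")

    for rec in parsed:
        gene_id = rec.id
        if gene_id in seen:
            warnings.warn(f"duplicate FASTA id {gene_id!r}: keeping first record")
            continue
        seq = normalize_sequence(str(rec.seq))
        if len(seq) % 3 != 0:
            if policy == "strict":
                rejected.append(
                    RejectedRecord(gene_id, f"length {len(seq)} not a multiple of 3")
                )
                continue
            seq = seq[: len(seq) - len(seq) % 3]
        if not _VALID_BASES.issuperset(seq):
            if policy == "strict":
                bad = sorted(set(seq) - _VALID_BASES)
                rejected.append(RejectedRecord(gene_id, f"ambiguity codes {bad}"))
                continue
            triplets = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            seq = "".join(t for t in triplets if _VALID_BASES.issuperset(t))
        if not seq:
            rejected.append(RejectedRecord(gene_id, "empty after filtering"))
            continue
        seen.add(gene_id)
        records.append(CodingSequence(gene_id=gene_id, sequence=seq))

    for rej in rejected:
        logger.warning("rejected %s: %s", rej.gene_id, rej.reason)
    if not records:
        raise ValueError("no valid coding sequences after filtering")
    return ParseResult(records=records, rejected=rejected)


# ---------------------------------------------------------------------------
# counts and profiles
# ---------------------------------------------------------------------------

def count_codons(seq: CodingSequence) -> CodonCountTable:
    """Tally non-overlapping frame-0 triplets of one coding sequence."""
    tally = Counter(seq.codons())
    n_stop = sum(tally.get(s, 0) for s in STOP_CODONS)
    n_sense = seq.n_codons - n_stop
    return CodonCountTable(
        gene_id=seq.gene_id, counts=dict(tally), n_sense=n_sense, n_stop=n_stop
    )


def composition_profile(counts: CodonCountTable) -> CompositionProfile:
    """61-codon percentage profile plus GC3%/AU3% of one gene.

    Percentages in ``pct`` are of sense codons; ``gc3_pct``/``au3_pct`` use
    all codons (stop included) as denominator and exclude stop codons from
    the numerators, so ``gc3 + au3 + stop-fraction = 100``.
    """
    n_codons = counts.n_codons
    if n_codons < 1:
        raise ValueError(f"{counts.gene_id}: empty count table")
    gc3 = sum(counts.counts.get(c, 0) for c in GC3_CODONS)
    au3 = sum(counts.counts.get(c, 0) for c in AU3_CODONS)
    if counts.n_sense > 0:
        pct = {
            c: 100.0 * counts.counts.get(c, 0) / counts.n_sense for c in SENSE_CODONS
        }
    else:
        pct = {c: float("nan") for c in SENSE_CODONS}
    return CompositionProfile(
        gene_id=counts.gene_id,
        pct=pct,
        gc3_pct=100.0 * gc3 / n_codons,
        au3_pct=100.0 * au3 / n_codons,
        n_codons=n_codons,
        n_sense=counts.n_sense,
    )


def per_aa_fractions(counts: CodonCountTable) -> AminoAcidCodonFractions:
    """Fraction of each amino acid's codons taken by each synonymous codon."""
    fractions: dict[tuple[str, str], float] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        total = sum(counts.counts.get(c, 0) for c in family)
        if total == 0:
            continue
        for c in family:
            fractions[(aa, c)] = counts.counts.get(c, 0) / total
    return AminoAcidCodonFractions(gene_id=counts.gene_id, fractions=fractions)


def rscu(counts: CodonCountTable | Iterable[CodonCountTable]) -> RSCUTable:
    """Relative synonymous codon usage of a gene or a pooled gene set.

    RSCU of a codon is its count divided by the mean count over its
    synonymous family; families with zero total are reported as missing.
    """
    if isinstance(counts, CodonCountTable):
        tables = [counts]
    else:
        tables = list(counts)
    pooled: Counter[str] = Counter()
    for t in tables:
        pooled.update(t.counts)
    values: dict[str, float] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        total = sum(pooled.get(c, 0) for c in family)
        if total == 0:
            continue
        mean = total / len(family)
        for c in family:
            values[c] = pooled.get(c, 0) / mean
    return RSCUTable(values=values, family_sizes=dict(FAMILY_SIZES))


def composition_table(seqs: Iterable[CodingSequence]) -> pd.DataFrame:
    """Per-gene composition DataFrame: 61 codon pct columns (fixed
    alphabetical order) plus gc3_pct, au3_pct, n_codons, n_sense.

    This is the tabular form most downstream statistics consume.
    """
    rows = []
    index = []
    for seq in seqs:
        prof = composition_profile(count_codons(seq))
        index.append(prof.gene_id)
        rows.append(
            [prof.pct[c] for c in SENSE_CODONS]
            + [prof.gc3_pct, prof.au3_pct, prof.n_codons, prof.n_sense]
        )
    cols = list(SENSE_CODONS) + ["gc3_pct", "au3_pct", "n_codons", "n_sense"]
    df = pd.DataFrame(rows, index=pd.Index(index, name="gene_id"), columns=cols)
    return df


# ---------------------------------------------------------------------------
# GC3 distribution summary
# ---------------------------------------------------------------------------

def _fwhm_from_histogram(
    centers: np.ndarray, counts: np.ndarray
) -> float | None:
    """Full width at half maximum by linear interpolation of the half-max
    crossings around the global histogram maximum; None when undefined."""
    if counts.max() <= 0:
        return None
    k = int(np.argmax(counts))
    half = counts[k] / 2.0
    # walk left from the mode to the first crossing below half
    left = None
    for i in range(k, -1, -1):
        if counts[i] < half:
            # crossing between i and i+1
            x0, x1 = centers[i], centers[i + 1]
            y0, y1 = counts[i], counts[i + 1]
            left = x0 + (half - y0) / (y1 - y0) * (x1 - x0)
            break
    right = None
    for i in range(k, len(counts)):
        if counts[i] < half:
            x0, x1 = centers[i - 1], centers[i]
            y0, y1 = counts[i - 1], counts[i]
            right = x0 + (half - y0) / (y1 - y0) * (x1 - x0)
            break
    if left is None or right is None:
        return None
    return float(right - left)


def gc3_distribution_summary(
    values: Sequence[float] | Iterable[CompositionProfile],
    bin_width: float = 1.0,
    smooth_window: int = 3,
) -> DistributionSummary:
    """Summarise a per-gene GC3% distribution (median, min/max, FWHM).

    ``values`` may be raw percentages or CompositionProfile objects.  The
    histogram spans [0, 100] at the given bin width; an optional moving
    average (default window 3, pass 1 to disable) is applied before the
    half-maximum search.  Median/min/max come from the raw values.
    """
    vals = np.asarray(
        [v.gc3_pct if isinstance(v, CompositionProfile) else float(v) for v in values],
        dtype=float,
    )
    if vals.size < 2:
        raise ValueError("need at least 2 values for a distribution summary")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(100.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if vals.max() == vals.min():
        # a point mass has no width
        fwhm = None
    else:
        smooth = counts.astype(float)
        if smooth_window and smooth_window > 1:
            kernel = np.ones(smooth_window) / smooth_window
            smooth = np.convolve(smooth, kernel, mode="same")
        fwhm = _fwhm_from_histogram(centers, smooth)
    return DistributionSummary(
        values=vals,
        median=float(np.median(vals)),
        min=float(vals.min()),
        max=float(vals.max()),
        fwhm=fwhm,
        bin_edges=edges,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# codon-codon correlation matrices
# ---------------------------------------------------------------------------

def fractions_table(
    seqs: Iterable[CodingSequence], codons: Sequence[str] | None = None
) -> pd.DataFrame:
    """Genes x codons table of per-amino-acid synonymous fractions.

    NaN where the gene lacks the codon's amino acid entirely.  Default codon
    set: the 59 sense codons of degenerate families.
    """
    codons = tuple(codons) if codons is not None else DEGENERATE_SENSE_CODONS
    rows, index = [], []
    for seq in seqs:
        fr = per_aa_fractions(count_codons(seq))
        index.append(seq.gene_id)
        rows.append([fr.fractions.get((CODON_TO_AA[c], c), np.nan) for c in codons])
    return pd.DataFrame(rows, index=pd.Index(index, name="gene_id"), columns=list(codons))


def _split_sequence(seq: CodingSequence) -> tuple[CodingSequence, CodingSequence]:
    """Split into two halves by codon index (extra codon goes to the first
    half); any terminal stop codon is stripped before splitting."""
    codons = seq.codons()
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if len(codons) < 2:
        raise ValueError(f"{seq.gene_id}: too short to split")
    cut = (len(codons) + 1) // 2
    return (
        CodingSequence(seq.gene_id, "".join(codons[:cut])),
        CodingSequence(seq.gene_id, "".join(codons[cut:])),
    )


def pairwise_pearson(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between columns of two aligned
    DataFrames; NaN where fewer than 3 complete pairs or zero variance."""
    out = np.full((a.shape[1], b.shape[1]), np.nan)
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    for i in range(av.shape[1]):
        x = av[:, i]
        for j in range(bv.shape[1]):
            y = bv[:, j]
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 3:
                continue
            xm, ym = x[mask], y[mask]
            sx, sy = xm.std(), ym.std()
            if sx == 0 or sy == 0:
                continue
            out[i, j] = np.corrcoef(xm, ym)[0, 1]
    return pd.DataFrame(out, index=a.columns, columns=b.columns)


def codon_correlation_matrix(
    seqs: Sequence[CodingSequence],
    mode: Literal["full", "split_half"] = "full",
    codons: Sequence[str] | None = None,
) -> CodonCorrelationMatrix:
    """Cross-gene correlation of per-amino-acid synonymous codon fractions.

    ``full``: every codon against every codon on the whole sequences.
    ``split_half``: sequences are halved by codon index and codon *i* of the
    first halves is correlated against codon *j* of the second halves.
    Codons with zero variance across genes yield NaN rows/columns.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 genes for a correlation matrix")
    codon_set = tuple(codons) if codons is not None else DEGENERATE_SENSE_CODONS
    if mode == "full":
        tab = fractions_table(seqs, codon_set)
        r = pairwise_pearson(tab, tab)
    elif mode == "split_half":
        halves = [_split_sequence(s) for s in seqs]
        tab1 = fractions_table((h[0] for h in halves), codon_set)
        tab2 = fractions_table((h[1] for h in halves), codon_set)
        r = pairwise_pearson(tab1, tab2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CodonCorrelationMatrix(codons=codon_set, r=r, mode=mode)


def correlation_sign_summary(mat: CodonCorrelationMatrix) -> dict[str, float]:
    """Mean off-diagonal r within the GC3 group, within the AU3 group and
    between the groups — the qualitative signature of the full matrix."""
    gc3 = [c for c in mat.codons if c in GC3_CODONS]
    au3 = [c for c in mat.codons if c in AU3_CODONS]
    r = mat.r

    def _mean_block(rows, cols, exclude_diag):
        block = r.loc[rows, cols].to_numpy(dtype=float)
        if exclude_diag and rows == cols:
            np.fill_diagonal(block, np.nan)
        return float(np.nanmean(block))

    return {
        "within_gc3": _mean_block(gc3, gc3, exclude_diag=mat.mode == "full"),
        "within_au3": _mean_block(au3, au3, exclude_diag=mat.mode == "full"),
        "between": _mean_block(gc3, au3, exclude_diag=False),
    }
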