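"""Readers, writers, the pipeline configuration and the end-to-end runner.

All tabular outputs are TSV with a fixed alphabetical 61-codon column/row
order and numbers printed at a declared precision (6 significant digits by
default) so that byte-identical reruns are meaningful.  Every pipeline run
writes a JSON manifest recording inputs, parameters, seeds and the sha256
checksum of each artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cec as cec_mod
from . import codon_core, diagnostics, enrichment, synthetic
from .cec import AbundanceMatrix
from .enrichment import GeneSetCollection
from .genetic_code import AU3_CODONS

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_abundance(
    path: str | Path,
    fmt: str | None = None,
    missing: str = "drop-gene",
    labels: dict[str, str] | None = None,
) -> AbundanceMatrix:
    """Read a genes x samples abundance table (first column gene ids,
    header = sample ids).  ``fmt`` defaults from the file extension
    (csv -> comma, anything else -> tab).  Duplicate gene ids are an error;
    non-numeric cells are an error with coordinates; missing values are
    handled per ``missing`` ("drop-gene" or "impute-zero")."""
    path = Path(path)
    sep = "," if (fmt == "csv" or (fmt is None and path.suffix == ".csv")) else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene ids in {path.name}: {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric value in {path.name} at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        if missing == "drop-gene":
            n_before = len(df)
            df = df.dropna(axis=0)
            logger.info("dropped %d genes with missing values", n_before - len(df))
        elif missing == "impute-zero":
            df = df.fillna(0.0)
        else:
            raise ValueError(f"unknown missing-value policy {missing!r}")
    return AbundanceMatrix(values=df, labels=labels)


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, label) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"],
                     dtype=str, comment="#")
    # tolerate a header row
    if df.iloc[0]["sample_id"].lower() in ("sample_id", "sample"):
        df = df.iloc[1:]
    return dict(zip(df["sample_id"], df["label"]))


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set_id <tab> description <tab> members...)."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            sid, name, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(f"{path}: set {sid!r} has repeated members (deduplicated)")
            sets[sid] = (name, tuple(unique))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    logger.info("read %d gene sets from %s", len(sets), path)
    return GeneSetCollection(sets=sets)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line (blank lines and # comments ignored)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
              index_label=index_label or df.index.name)


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def enrichment_frame(results) -> pd.DataFrame:
    rows = [
        {
            "set_id": r.set_id, "name": r.name, "size": r.size, "ES": r.es,
            "NES": r.nes, "p_perm": r.p_perm, "fdr_bh": r.fdr_bh,
            "direction": r.direction, "leading_edge": ",".join(r.leading_edge),
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index("set_id")


def shift_frame(shift: cec_mod.EmploymentShift, control, disease) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "control_cec": control.mean,
            "disease_cec": disease.mean,
            "rel_change_pct": shift.per_codon,
        }
    )
    df["group"] = ["AU3" if c in AU3_CODONS else "GC3" for c in df.index]
    df.index.name = "codon"
    return df


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of the end-to-end workflow.

    With ``fasta=None`` a synthetic genome/cohort is generated instead of
    reading input files (the bundled preset used by the examples).
    """

    out_dir: str = "codonshift_out"
    fasta: str | None = None
    abundance: str | None = None
    labels: str | None = None
    gmt: str | None = None
    gp1: str | None = None                 # optional precomputed subset list
    transform: str = "log2p1"
    epsilon: float = 0.01
    n_perm: int = 1000
    fdr_cut: float = 0.01
    train_frac: float = 0.8
    n_reps: int = 200
    run_enrichment: bool = True
    run_diagnostics: bool = True
    # synthetic preset parameters (used when fasta is None)
    n_genes: int = 800
    n_control: int = 20
    n_disease: int = 20
    beta: float = 9.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def validate(self) -> None:
        for attr in ("fasta", "abundance", "labels", "gmt", "gp1"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} path does not exist: {p}")
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must be in (0, 1)")
        if self.n_perm < 1 or self.n_reps < 1:
            raise ValueError("n_perm and n_reps must be positive")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run compose -> (enrichment/group derivation) -> CEC/shift/CorrCEC ->
    diagnostics, writing every artifact plus a JSON manifest.

    Returns the manifest dict.  Reruns with the same config are
    byte-identical.  On stage failure the manifest records the failure
    point and the exception is re-raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stages": {},
        "artifacts": {},
        "seeds": {"master": config.seed},
    }

    def _register(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": sha256_of(path)
        }

    current_stage = "setup"
    try:
        # --- inputs -------------------------------------------------------
        current_stage = "inputs"
        if config.fasta is not None:
            seqs = list(codon_core.parse_cds(config.fasta))
            truth = None
            label_map = read_labels(config.labels) if config.labels else None
            abundance = read_abundance(config.abundance, labels=label_map)
        else:
            genome = synthetic.GenomeSpec(n_genes=config.n_genes, seed=config.seed)
            seqs, truth = synthetic.generate_cds_set(genome)
            cohort_spec = synthetic.CohortSpec(
                n_control=config.n_control, n_disease=config.n_disease,
                beta=config.beta, seed=config.seed + 1,
            )
            abundance, truth = synthetic.generate_cohort(truth, cohort_spec)
            fasta_path = out / "genome.fa"
            synthetic.write_fasta(seqs, fasta_path)
            _register("genome_fasta", fasta_path)
            truth_path = out / "ground_truth.json"
            truth.to_json(truth_path)
            _register("ground_truth", truth_path)
            ab_path = out / "abundance.tsv"
            write_table(abundance.values, ab_path)
            _register("abundance", ab_path)
            lab_path = out / "labels.tsv"
            lab_path.write_text(
                "".join(f"{s}\t{l}\n" for s, l in abundance.labels.items())
            )
            _register("labels", lab_path)
        manifest["stages"]["inputs"] = "completed"

        # --- composition --------------------------------------------------
        current_stage = "compose"
        comp = codon_core.composition_table(seqs)
        comp_path = out / "profiles.tsv"
        write_table(comp, comp_path)
        _register("profiles", comp_path)
        manifest["stages"]["compose"] = "completed"

        # --- enrichment / GP1 derivation ----------------------------------
        gp1: list[str] | None = None
        if config.gp1 is not None:
            gp1 = read_gene_list(config.gp1)
            manifest["stages"]["enrich"] = "skipped (subset supplied)"
        elif config.run_enrichment:
            current_stage = "enrich"
            if config.gmt is not None:
                sets = read_gene_sets(config.gmt)
            elif truth is not None:
                sets = synthetic.make_gene_sets(truth, seed=config.seed + 2)
            else:
                sets = None
            if sets is not None:
                ranked = enrichment.rank_by_gc3(comp)
                results = enrichment.preranked_enrichment(
                    ranked, sets, n_perm=config.n_perm, seed=config.seed + 3
                )
                enr_path = out / "enrichment.tsv"
                write_table(enrichment_frame(results), enr_path)
                _register("enrichment", enr_path)
                gp1_set, gp2_set = enrichment.derive_groups(
                    results, fdr_cut=config.fdr_cut
                )
                write_gene_list(gp1_set, out / "gp1.txt")
                write_gene_list(gp2_set, out / "gp2.txt")
                _register("gp1", out / "gp1.txt")
                _register("gp2", out / "gp2.txt")
                gp1 = sorted(gp1_set)
                manifest["stages"]["enrich"] = "completed"
            else:
                manifest["stages"]["enrich"] = "skipped (no gene sets)"

        # --- CEC / shift / CorrCEC ----------------------------------------
        current_stage = "cec"
        ctrl = cec_mod.cohort_cec(comp, abundance, "control",
                                  transform=config.transform)
        dis = cec_mod.cohort_cec(comp, abundance, "disease",
                                 transform=config.transform)
        cec_table = pd.DataFrame(
            {
                "control_mean": ctrl.mean, "control_sem": ctrl.sem,
                "disease_mean": dis.mean, "disease_sem": dis.sem,
            }
        )
        cec_table.index.name = "codon"
        write_table(cec_table, out / "cec.tsv")
        _register("cec", out / "cec.tsv")
        shift = cec_mod.employment_shift(ctrl, dis, epsilon=config.epsilon)
        write_table(shift_frame(shift, ctrl, dis), out / "shift.tsv")
        _register("shift", out / "shift.tsv")
        manifest["shift"] = {
            "au3_shift_pct": shift.au3_shift_pct,
            "gc3_shift_pct": shift.gc3_shift_pct,
        }
        corr = cec_mod.corrcec(comp, ctrl, dis)
        write_table(corr, out / "corrcec.tsv", index_label="gene_id")
        _register("corrcec", out / "corrcec.tsv")
        manifest["stages"]["cec"] = "completed"

        # --- diagnostics ---------------------------------------------------
        if config.run_diagnostics:
            current_stage = "diagnose"
            subset = tuple(gp1) if gp1 else None
            ds = diagnostics.CohortDataset(
                abundance=abundance, comp=comp, subset=subset,
                transform=config.transform,
            )
            perf = diagnostics.cross_validated_diagnostics(
                ds, train_frac=config.train_frac, n_reps=config.n_reps,
                seed=config.seed + 4,
            )
            perf_path = out / "diagnostics.json"
            perf_path.write_text(json.dumps(
                {
                    "sensitivity": perf.sensitivity,
                    "specificity": perf.specificity,
                    "sensitivity_sd": perf.sensitivity_sd,
                    "specificity_sd": perf.specificity_sd,
                    "n_reps": perf.n_reps,
                    "subset_size": len(subset) if subset else None,
                },
                indent=1,
            ))
            _register("diagnostics", perf_path)
            manifest["stages"]["diagnose"] = "completed"
    except Exception as exc:  # record failure point, keep partial artifacts
        manifest["stages"][current_stage] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
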