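"""Readers and writers for the pipeline's TSV dialects, plus configuration.

All tables are UTF-8 TSV with "." decimals; masked cells are empty strings.
The gene-fitness dialect mirrors the public Fitness-Browser download:
locusId, sysName, desc, then one column per experiment, with a sibling file
holding t-scores in the same layout. Readers tolerate extra columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_counts",
    "read_experiments",
    "read_fitness_tables",
    "read_annotations",
    "read_identity",
    "read_medium",
    "write_fitness_tables",
    "write_calls",
]

EXPERIMENT_COLUMNS = [
    "sample_id",
    "condition_name",
    "condition_class",
    "chain_length",
    "replicate",
    "t0_sample_id",
]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, serializable to/from JSON."""

    fitness_threshold: float = 1.0
    t_threshold: float = 4.0
    pseudocount: float = 0.5
    variance_floor: float = 0.25
    knn_k: int = 2
    e_value_cutoff: float = 0.001
    tsne_perplexity: float = 25.0
    tsne_iterations: int = 50_000
    tsne_early_exaggeration: float = 100.0
    atp_per_gln: float = 1.0
    po_nadh: float = 2.5
    po_fadh2: float = 1.5
    h_per_atp: float = 4.0
    control_rule: str = "fitness_lt_1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fitness_threshold", "t_threshold", "pseudocount", "variance_floor", "e_value_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _read_tsv(path, required: set[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"locus": str}, keep_default_na=True)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{what} file {path} missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s file %s has a valid header but no rows", what, path)
    logger.info("read %d rows from %s", len(df), path)
    return df


def read_experiments(path) -> pd.DataFrame:
    df = _read_tsv(path, set(EXPERIMENT_COLUMNS), "experiment metadata")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    return df


def read_counts(path, experiments: pd.DataFrame | None = None) -> pd.DataFrame:
    df = _read_tsv(path, {"barcode", "locus", "position_fraction"}, "counts")
    if df["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in counts table")
    df["locus"] = df["locus"].replace("", np.nan)
    sample_cols = [c for c in df.columns if c not in ("barcode", "locus", "position_fraction")]
    for col in sample_cols:
        if not df.empty and not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ValueError(f"non-numeric counts in column {col}, lines {[i + 2 for i in bad[:5]]}")
    if experiments is not None:
        needed = set(experiments["sample_id"]) | set(experiments["t0_sample_id"])
        missing = needed - set(sample_cols)
        if missing:
            raise ValueError(f"counts columns missing for samples in metadata: {sorted(missing)[:5]}")
    return df


def read_fitness_tables(fitness_path, t_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fitness-Browser dialect: locusId, sysName, desc, one column per
    experiment; empty cells are masked. Returns aligned (fitness, t) frames
    indexed by locus."""
    out = []
    for path in (fitness_path, t_path):
        df = pd.read_csv(path, sep="\t")
        missing = {"locusId"} - set(df.columns)
        if missing:
            raise ValueError(f"fitness table {path} missing columns {sorted(missing)}")
        if df["locusId"].duplicated().any():
            raise ValueError(f"duplicate locusId rows in {path}")
        data_cols = [c for c in df.columns if c not in ("locusId", "sysName", "desc")]
        mat = df.set_index("locusId")[data_cols]
        # tolerate extra non-numeric metadata columns in public downloads;
        # a numeric column with stray bad cells still errors
        keep = []
        for col in data_cols:
            coerced = pd.to_numeric(mat[col], errors="coerce")
            source_na = mat[col].isna()
            if (coerced.isna() & ~source_na).all() and not mat[col].empty:
                logger.info("ignoring non-numeric column %r in %s", col, path)
                continue
            if (coerced.isna() & ~source_na).any():
                raise ValueError(f"non-numeric cells in column {col} of {path}")
            keep.append(col)
        mat = mat[keep].apply(pd.to_numeric)
        mat.index.name = "locus"
        out.append(mat)
    fit, t = out
    if not fit.index.equals(t.index) or list(fit.columns) != list(t.columns):
        raise ValueError("fitness and t-score tables are not aligned")
    return fit, t


def write_fitness_tables(fitness: pd.DataFrame, t: pd.DataFrame, fitness_path, t_path) -> None:
    for mat, path in ((fitness, fitness_path), (t, t_path)):
        out = mat.copy()
        out.insert(0, "desc", "")
        out.insert(0, "sysName", out.index)
        out.index.name = "locusId"
        out.reset_index().to_csv(path, sep="\t", index=False, na_rep="")


def read_annotations(path) -> pd.DataFrame:
    df = _read_tsv(path, {"locus", "category"}, "annotation")
    if df["locus"].duplicated().any():
        raise ValueError("duplicate loci in annotation table")
    return df


def read_identity(path) -> pd.DataFrame:
    return _read_tsv(path, {"locus_a", "locus_b", "percent_identity", "e_value"}, "identity")


def read_medium(path):
    """Medium TSV (compound, formula, mM) -> MediumMix."""
    from .yields import CompoundSpec, MediumMix

    df = _read_tsv(path, {"compound", "formula", "mM"}, "medium")
    pairs = [(CompoundSpec(r["compound"], r["formula"]), float(r["mM"])) for _, r in df.iterrows()]
    return MediumMix.from_pairs(pairs)


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.reset_index().to_csv(path, sep="\t", index=False, na_rep="")
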