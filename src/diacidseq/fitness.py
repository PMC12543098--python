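"""Gene-fitness and t-score estimation from BarSeq count tables.

The estimator follows the standard pooled-fitness construction: each strain's
fitness is the log2 ratio of its (library-size-scaled) reads in the condition
sample to its reads in the time-zero control; a gene's fitness is the
weighted average over its insertion strains in the central 10-90% of the
gene; per-experiment values are normalized so the median gene has fitness 0;
and the t-score divides the gene fitness by a floored standard error derived
from the variance across independent mutants of the same gene.

The public surface is statsmodels-shaped: build a :class:`BarSeqFitness`
model from the count and experiment tables, call :meth:`BarSeqFitness.fit`,
and work with the returned :class:`BarSeqFitnessResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "strain_fitness",
    "gene_fitness",
    "normalize_experiment",
    "t_score",
    "average_replicates",
    "BarSeqFitness",
    "BarSeqFitnessResults",
]

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_VARIANCE_FLOOR = 0.25
CENTRAL_MIN = 0.10
CENTRAL_MAX = 0.90


def strain_fitness(c_sample, c_t0, pseudocount: float = DEFAULT_PSEUDOCOUNT, scale: float = 1.0):
    """log2 ratio of scaled sample reads to time-zero reads.

    ``scale`` is the library-size factor (total t0 reads / total sample
    reads) applied to the sample counts so both columns are on the same
    sequencing depth. Vectorized over arrays.
    """
    c_sample = np.asarray(c_sample, dtype=float)
    c_t0 = np.asarray(c_t0, dtype=float)
    if not (np.isfinite(c_sample).all() and np.isfinite(c_t0).all()):
        raise ValueError("counts must be finite")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    return np.log2((c_sample * scale + pseudocount) / (c_t0 + pseudocount))


def _central(position_fraction) -> np.ndarray:
    pf = np.asarray(position_fraction, dtype=float)
    return (pf >= CENTRAL_MIN) & (pf <= CENTRAL_MAX)


def gene_fitness(strain_values, weights, position_fraction):
    """Weighted mean strain fitness over insertions in the central 10-90%.

    Returns ``(fitness_raw, n_strains)``; a gene with no passing strain is
    reported as missing (``NaN``, n=0), never as zero.
    """
    f = np.asarray(strain_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = _central(position_fraction)
    if (w[keep] <= 0).any():
        raise ValueError("weights must be > 0")
    if not keep.any():
        return float("nan"), 0
    f, w = f[keep], w[keep]
    return float(np.sum(w * f) / np.sum(w)), int(keep.sum())


def normalize_experiment(values):
    """Center one experiment's raw gene fitness on its median, so the
    typical gene has fitness zero."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one gene value")
    return v - np.nanmedian(v)


def _weighted_variance(f: np.ndarray, w: np.ndarray) -> float:
    """Weighted sample variance with the n/(n-1) small-sample correction."""
    n = len(f)
    if n < 2:
        return 0.0
    mean = np.sum(w * f) / np.sum(w)
    return float(np.sum(w * (f - mean) ** 2) / np.sum(w) * n / (n - 1))


def t_score(fitness: float, strain_values, weights, variance_floor: float = DEFAULT_VARIANCE_FLOOR) -> float:
    """t = fitness / sqrt(max(s^2, floor) / n).

    ``s^2`` is the weighted variance of strain fitness within the gene; the
    floor guards genes whose few mutants happen to agree exactly. A single
    mutant uses the floor alone.
    """
    if variance_floor <= 0:
        raise ValueError("variance_floor must be > 0")
    f = np.asarray(strain_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(f)
    if n == 0:
        return float("nan")
    s2 = _weighted_variance(f, w)
    return float(fitness / np.sqrt(max(s2, variance_floor) / n))


def average_replicates(gene_table: pd.DataFrame, experiments: pd.DataFrame):
    """Collapse per-experiment gene records to a locus x condition matrix.

    ``gene_table`` has one row per (locus, sample_id) with columns fitness,
    t_score, n_strains. Replicates are averaged unweighted (fitness and t
    alike); a condition with no passing experiment for a locus is a masked
    (NaN) cell.
    """
    if gene_table.duplicated(["locus", "sample_id"]).any():
        raise ValueError("duplicated (locus, sample_id) rows")
    cond_of = experiments.set_index("sample_id")["condition_name"]
    tbl = gene_table.assign(condition=gene_table["sample_id"].map(cond_of))
    if tbl["condition"].isna().any():
        bad = tbl.loc[tbl["condition"].isna(), "sample_id"].unique()
        raise ValueError(f"samples missing from experiment table: {bad[:5]}")
    fitness = tbl.pivot_table(index="locus", columns="condition", values="fitness", aggfunc="mean")
    t = tbl.pivot_table(index="locus", columns="condition", values="t_score", aggfunc="mean")
    order = [c for c in experiments["condition_name"].unique() if c in fitness.columns]
    return fitness[order], t[order]


class BarSeqFitness:
    """Pooled-fitness model for one organism's BarSeq experiment set.

    Parameters
    ----------
    counts : DataFrame with columns barcode, locus (empty/NaN = intergenic),
        position_fraction, then one integer column per sample id.
    experiments : DataFrame with columns sample_id, condition_name,
        condition_class, chain_length, replicate, t0_sample_id (and
        optionally organism).
    pseudocount, variance_floor : estimator tuning; see module docstring.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        experiments: pd.DataFrame,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    ):
        required = {"barcode", "locus", "position_fraction"}
        if not required <= set(counts.columns):
            raise ValueError(f"counts table missing columns {required - set(counts.columns)}")
        self.strains = counts[["barcode", "locus", "position_fraction"]].copy()
        self.strains["locus"] = self.strains["locus"].replace("", np.nan)
        sample_ids = list(experiments["sample_id"]) + list(experiments["t0_sample_id"].unique())
        missing = [s for s in sample_ids if s not in counts.columns]
        if missing:
            raise ValueError(f"count columns missing for samples: {missing[:5]}")
        self.counts = counts[sorted(set(sample_ids), key=sample_ids.index)].astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.experiments = experiments.reset_index(drop=True)
        self.pseudocount = float(pseudocount)
        self.variance_floor = float(variance_floor)

    @classmethod
    def from_simulation(cls, sim, **kwargs) -> "BarSeqFitness":
        """Build directly from a :class:`~diacidseq.simulate.SimCounts`."""
        counts = pd.concat([sim.strains, sim.counts], axis=1)
        return cls(counts, sim.experiments, **kwargs)

    def fit(self) -> "BarSeqFitnessResults":
        strains = self.strains
        central = _central(strains["position_fraction"])
        genic = strains["locus"].notna().to_numpy() & central
        locus_arr = strains["locus"].to_numpy()

        records = []
        for _, exp in self.experiments.iterrows():
            c_sample = self.counts[exp["sample_id"]].to_numpy(dtype=float)
            c_t0 = self.counts[exp["t0_sample_id"]].to_numpy(dtype=float)
            tot_sample = c_sample.sum()
            if tot_sample == 0:
                raise ValueError(f"sample {exp['sample_id']} has zero total reads")
            scale = c_t0.sum() / tot_sample
            f_strain = strain_fitness(c_sample, c_t0, self.pseudocount, scale)
            # inverse-variance weights for a log-ratio of counts
            w = 1.0 / (1.0 / (c_t0 + self.pseudocount) + 1.0 / (c_sample * scale + self.pseudocount))

            df = pd.DataFrame(
                {"locus": locus_arr[genic], "f": f_strain[genic], "w": w[genic]}
            )
            grouped = df.groupby("locus", sort=True)
            raw = grouped.apply(
                lambda g: pd.Series(
                    {
                        "fitness": np.sum(g["w"] * g["f"]) / np.sum(g["w"]),
                        "s2": _weighted_variance(g["f"].to_numpy(), g["w"].to_numpy()),
                        "n_strains": len(g),
                    }
                ),
                include_groups=False,
            )
            raw["fitness"] = normalize_experiment(raw["fitness"].to_numpy())
            raw["t_score"] = raw["fitness"] / np.sqrt(
                np.maximum(raw["s2"], self.variance_floor) / raw["n_strains"]
            )
            raw["sample_id"] = exp["sample_id"]
            records.append(raw.reset_index())

        gene_table = pd.concat(records, ignore_index=True)
        gene_table["n_strains"] = gene_table["n_strains"].astype(int)
        fitness_mat, t_mat = average_replicates(gene_table, self.experiments)
        return BarSeqFitnessResults(self, gene_table, fitness_mat, t_mat)


class BarSeqFitnessResults:
    """Estimates from :meth:`BarSeqFitness.fit`.

    Attributes
    ----------
    gene_table : per-(locus, sample) fitness, t_score, n_strains, s2.
    fitness_matrix, t_matrix : locus x condition replicate-averaged values
        with NaN marking masked (no passing experiment) cells.
    """

    def __init__(self, model, gene_table, fitness_matrix, t_matrix):
        self.model = model
        self.gene_table = gene_table
        self.fitness_matrix = fitness_matrix
        self.t_matrix = t_matrix

    @property
    def conditions(self) -> pd.DataFrame:
        cols = ["condition_name", "condition_class", "chain_length"]
        if "organism" in self.model.experiments.columns:
            cols.append("organism")
        return self.model.experiments[cols].drop_duplicates().reset_index(drop=True)

    def phenotype_calls(self, annotations: pd.DataFrame | None = None, **kwargs) -> pd.DataFrame:
        from .phenotypes import classify_matrix

        return classify_matrix(
            self.fitness_matrix, self.t_matrix, self.conditions, annotations=annotations, **kwargs
        )

    def cohort_summary(self, annotations: pd.DataFrame | None = None, **kwargs):
        from .phenotypes import summarize_cohort

        calls = self.phenotype_calls(annotations=annotations, **kwargs)
        return summarize_cohort(calls)

    def masked_correlation(self, locus_a: str, locus_b: str):
        from .profiles import masked_pearson

        return masked_pearson(
            self.fitness_matrix.loc[locus_a].to_numpy(),
            self.fitness_matrix.loc[locus_b].to_numpy(),
        )

    def summary(self) -> str:
        """Human-readable estimation summary."""
        n_loci, n_cond = self.fitness_matrix.shape
        n_exp = len(self.model.experiments)
        masked = int(self.fitness_matrix.isna().sum().sum())
        strongest = self.fitness_matrix.stack().abs().idxmax()
        lines = [
            "BarSeq gene fitness estimation",
            "=" * 46,
            f"loci                 {n_loci}",
            f"conditions           {n_cond} ({n_exp} experiments)",
            f"masked cells         {masked}",
            f"pseudocount          {self.model.pseudocount}",
            f"variance floor       {self.model.variance_floor}",
            f"largest |fitness|    {self.fitness_matrix.loc[strongest]:+.2f} "
            f"({strongest[0]} on {strongest[1]})",
        ]
        return "\n".join(lines)

    def to_fitness_browser_tsv(self, fitness_path, t_path, descriptions: pd.DataFrame | None = None) -> None:
        """Write Fitness-Browser-style tables: locusId, sysName, desc, then
        one column per condition; sibling file for t-scores."""
        for mat, path in ((self.fitness_matrix, fitness_path), (self.t_matrix, t_path)):
            out = mat.reset_index().rename(columns={"locus": "locusId"})
            out.insert(1, "sysName", out["locusId"])
            desc = ""
            if descriptions is not None:
                desc = out["locusId"].map(descriptions.set_index("locus")["desc"]).fillna("")
            out.insert(2, "desc", desc)
            out.to_csv(path, sep="\t", index=False, na_rep="")
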