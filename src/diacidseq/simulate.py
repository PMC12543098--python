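"""Synthetic barcoded transposon libraries and BarSeq read-count tables.

Generates pooled-mutant libraries with known per-gene true fitness so the
whole downstream pipeline (fitness estimation, phenotype classification,
profile comparison) can be exercised and validated without sequencing data.

The model: each barcoded strain i carries an insertion in gene g(i) (or is
intergenic); its abundance in the time-zero pool is log-normal; after growth
under a condition its abundance is multiplied by ``2**f_true(g(i))`` where
``f_true`` is the gene's true fitness in log2 units for that condition.
Reads are a multinomial draw over strains at a fixed sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LibrarySpec",
    "TrueFitnessSpec",
    "SimCounts",
    "generate_library",
    "simulate_counts",
    "diacid_world",
    "simulate_scenario",
]


@dataclass(frozen=True)
class LibrarySpec:
    """Shape of a barcoded transposon library.

    Parameters
    ----------
    n_genes : number of genes in the genome.
    strains_per_gene_mean : expected insertions per gene; actual counts are
        Poisson-distributed, conditioned on at least one insertion.
    intergenic_fraction : fraction of strains carrying insertions outside any
        gene (these have no locus and true fitness 0).
    gene_length_bp : nominal gene length (uniform); only used for reporting.
    seed : RNG seed for reproducible libraries.
    """

    n_genes: int = 200
    strains_per_gene_mean: float = 15.0
    intergenic_fraction: float = 0.2
    gene_length_bp: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.strains_per_gene_mean <= 0:
            raise ValueError("strains_per_gene_mean must be > 0")
        if not 0.0 <= self.intergenic_fraction < 1.0:
            raise ValueError("intergenic_fraction must be in [0, 1)")
        if self.gene_length_bp < 1:
            raise ValueError("gene_length_bp must be >= 1")


@dataclass(frozen=True)
class TrueFitnessSpec:
    """Ground truth for a set of growth experiments.

    ``f_true`` maps (locus, condition_name) to true fitness in log2 units per
    experiment (generations are folded into the fitness unit, so a gene with
    f_true = -4 ends the experiment at 2**-4 of its neutral relative
    abundance). Intergenic strains always behave neutrally.
    """

    f_true: pd.DataFrame  # index: locus, columns: condition names
    depth_t0: int = 1_000_000
    depth_sample: int = 1_000_000
    abundance_sigma: float = 1.0  # log-normal sigma of t0 strain abundances

    def __post_init__(self) -> None:
        if self.depth_t0 < 1 or self.depth_sample < 1:
            raise ValueError("sequencing depths must be >= 1")
        if not np.isfinite(self.f_true.to_numpy(dtype=float)).all():
            raise ValueError("f_true must be finite")


@dataclass
class SimCounts:
    """A strain table plus read counts for every sequenced sample."""

    strains: pd.DataFrame  # columns: barcode, locus, position_fraction
    counts: pd.DataFrame  # index aligned with strains, one column per sample
    experiments: pd.DataFrame  # sample_id, condition_name, condition_class,
    # chain_length, replicate, t0_sample_id
    truth: pd.DataFrame | None = None  # locus x condition f_true, if known


_BASES = np.array(list("ACGT"))


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    # draw until unique; collisions at 4^20 are effectively impossible but
    # uniqueness is an invariant, so enforce it
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        chunk = rng.integers(0, 4, size=(n - len(out), length))
        for row in chunk:
            bc = "".join(_BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def generate_library(spec: LibrarySpec) -> pd.DataFrame:
    """Draw a strain table (no counts yet) from a :class:`LibrarySpec`.

    Strains per gene are Poisson(mean) conditioned >= 1; insertion positions
    are uniform within the gene. Intergenic strains have a null locus.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    loci = [f"GENE{i + 1:05d}" for i in range(spec.n_genes)]

    # Poisson conditioned on >= 1 by redrawing zeros
    per_gene = rng.poisson(spec.strains_per_gene_mean, size=spec.n_genes)
    while (per_gene == 0).any():
        zeros = per_gene == 0
        per_gene[zeros] = rng.poisson(spec.strains_per_gene_mean, size=zeros.sum())

    n_genic = int(per_gene.sum())
    # intergenic_fraction is the fraction of ALL strains that are intergenic
    if spec.intergenic_fraction > 0:
        n_intergenic = int(round(n_genic * spec.intergenic_fraction / (1 - spec.intergenic_fraction)))
    else:
        n_intergenic = 0
    n_total = n_genic + n_intergenic

    locus_col = np.repeat(loci, per_gene).tolist() + [None] * n_intergenic
    pos = rng.uniform(0.0, 1.0, size=n_total)
    barcodes = _random_barcodes(rng, n_total)
    strains = pd.DataFrame(
        {"barcode": barcodes, "locus": locus_col, "position_fraction": pos}
    )
    return strains


def _expected_proportions(
    strains: pd.DataFrame,
    abundance: np.ndarray,
    f_true: pd.Series,
) -> np.ndarray:
    """Post-growth relative abundances given per-gene true fitness."""
    f = np.zeros(len(strains))
    locus = strains["locus"]
    genic = locus.notna().to_numpy()
    f[genic] = f_true.reindex(locus[genic]).to_numpy(dtype=float)
    b = abundance * np.exp2(f)
    return b / b.sum()


def simulate_counts(
    strains: pd.DataFrame,
    truth: TrueFitnessSpec,
    experiments: pd.DataFrame,
    mode: str = "multinomial",
    seed: int = 0,
) -> SimCounts:
    """Simulate a BarSeq count table for a library under known true fitness.

    Parameters
    ----------
    strains : strain table from :func:`generate_library`.
    truth : :class:`TrueFitnessSpec` with the locus x condition f_true table.
    experiments : experiment metadata (sample_id, condition_name,
        condition_class, chain_length, replicate, t0_sample_id). Each distinct
        t0_sample_id becomes a sequenced time-zero sample whose abundances the
        conditions of that replicate grow from.
    mode : "multinomial" samples reads at the requested depth; "expectation"
        writes rounded expected counts with no sampling noise.

    Every locus in the strain table must appear in ``truth.f_true`` (missing
    conditions are an error); intergenic strains are neutral everywhere.
    """
    if mode not in ("multinomial", "expectation"):
        raise ValueError(f"unknown mode {mode!r}")
    genic_loci = set(strains["locus"].dropna())
    missing = genic_loci - set(truth.f_true.index)
    if missing:
        raise ValueError(f"loci absent from truth table: {sorted(missing)[:5]} ...")
    missing_cond = set(experiments["condition_name"]) - set(truth.f_true.columns)
    if missing_cond:
        raise ValueError(f"conditions absent from truth table: {sorted(missing_cond)}")

    rng = np.random.default_rng(seed)
    n = len(strains)
    counts: dict[str, np.ndarray] = {}

    def draw(depth: int, p: np.ndarray) -> np.ndarray:
        if mode == "multinomial":
            return rng.multinomial(depth, p)
        return np.rint(depth * p).astype(np.int64)

    for t0_id, group in experiments.groupby("t0_sample_id", sort=False):
        abundance = rng.lognormal(mean=0.0, sigma=truth.abundance_sigma, size=n)
        p0 = abundance / abundance.sum()
        counts[t0_id] = draw(truth.depth_t0, p0)
        for _, row in group.iterrows():
            f_cond = truth.f_true[row["condition_name"]]
            p = _expected_proportions(strains, abundance, f_cond)
            counts[row["sample_id"]] = draw(truth.depth_sample, p)

    count_df = pd.DataFrame(counts, index=strains.index)
    return SimCounts(strains=strains.copy(), counts=count_df, experiments=experiments.copy(), truth=truth.f_true)


# ---------------------------------------------------------------------------
# The built-in "diacid world" scenario
# ---------------------------------------------------------------------------

DA_CHAINS = (4, 5, 6, 7, 8, 9, 10, 12)
FA_CHAINS = (4, 5, 6, 7, 8, 9, 10, 12)


def _condition_table(organism: str = "org1") -> pd.DataFrame:
    """Condition taxonomy mirroring one organism's experiment set: DA and FA
    chain lengths C4-C10 + C12, acetate, protocatechuate, and a D-glucose
    control, each in biological duplicate."""
    rows = []
    for c in DA_CHAINS:
        rows.append((f"C{c}_DA", "DA", c))
    for c in FA_CHAINS:
        rows.append((f"C{c}_FA", "FA", c))
    rows.append(("acetate", "other", None))
    rows.append(("protocatechuate", "aromatic", None))
    rows.append(("D-glucose", "control", None))
    conditions = pd.DataFrame(rows, columns=["condition_name", "condition_class", "chain_length"])
    conditions["organism"] = organism
    return conditions


def _experiment_table(conditions: pd.DataFrame, n_replicates: int = 2) -> pd.DataFrame:
    rows = []
    org = conditions["organism"].iloc[0]
    for rep in range(1, n_replicates + 1):
        t0_id = f"{org}_t0_r{rep}"
        for _, c in conditions.iterrows():
            rows.append(
                {
                    "sample_id": f"{org}_{c.condition_name}_r{rep}",
                    "condition_name": c.condition_name,
                    "condition_class": c.condition_class,
                    "chain_length": c.chain_length,
                    "replicate": rep,
                    "t0_sample_id": t0_id,
                    "organism": org,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DiacidWorld:
    """A fully specified synthetic scenario: library, truth, annotations."""

    conditions: pd.DataFrame
    experiments: pd.DataFrame
    truth: pd.DataFrame  # locus x condition f_true
    annotations: pd.DataFrame  # locus, category
    library_spec: LibrarySpec = field(default_factory=LibrarySpec)


def diacid_world(
    n_genes: int = 200,
    n_da_only: int = 30,
    n_fa_only: int = 20,
    n_both: int = 10,
    n_control_driven: int = 5,
    defect_fitness: float = -4.0,
    include_repressor: bool = True,
    organism: str = "org1",
    strains_per_gene_mean: float = 15.0,
    seed: int = 0,
) -> DiacidWorld:
    """Build the pathway-structured ground truth used throughout the tests.

    The scenario encodes the biology the pipeline is meant to detect:

    - DA-only catabolic genes (ligases/dehydrogenases) with strong fitness
      defects (default -4) on a contiguous range of dicarboxylate chain
      lengths and nowhere else;
    - FA-only genes, symmetric on fatty-acid chain lengths;
    - genes with defects on both substrate classes;
    - one IclR-family-repressor-like gene with a very strong positive score
      (+13.55) on glutarate (C5 DA) and +4.7 on protocatechuate, mimicking a
      de-repressed catabolic operon;
    - control-driven genes with a defect only on the glucose control (these
      must never be called "specific");
    - the remainder neutral everywhere.
    """
    n_structured = n_da_only + n_fa_only + n_both + n_control_driven + int(include_repressor)
    if n_structured > n_genes:
        raise ValueError("n_genes too small for the requested structured genes")
    rng = np.random.default_rng(seed)

    conditions = _condition_table(organism)
    experiments = _experiment_table(conditions)
    loci = [f"{organism.upper()}_{i + 1:05d}" for i in range(n_genes)]
    truth = pd.DataFrame(0.0, index=pd.Index(loci, name="locus"), columns=conditions["condition_name"].tolist())

    da_conds = [f"C{c}_DA" for c in DA_CHAINS]
    fa_conds = [f"C{c}_FA" for c in FA_CHAINS]

    def chain_window(pool: list[str]) -> list[str]:
        # a contiguous chain-length window of width 2-4: chain-length
        # specificity as seen for real ligases/dehydrogenases
        width = int(rng.integers(2, 5))
        start = int(rng.integers(0, len(pool) - width + 1))
        return pool[start : start + width]

    categories: dict[str, str] = {}
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = loci[cursor : cursor + k]
        cursor += k
        return out

    for locus in take(n_da_only):
        truth.loc[locus, chain_window(da_conds)] = defect_fitness
        categories[locus] = str(rng.choice(["β-oxidation", "β-oxidation", "transporter", "regulator"]))
    for locus in take(n_fa_only):
        truth.loc[locus, chain_window(fa_conds)] = defect_fitness
        categories[locus] = str(rng.choice(["β-oxidation", "β-oxidation", "transporter"]))
    for locus in take(n_both):
        truth.loc[locus, chain_window(da_conds)] = defect_fitness
        truth.loc[locus, chain_window(fa_conds)] = defect_fitness
        categories[locus] = "β-oxidation"
    if include_repressor:
        (repressor,) = take(1)
        truth.loc[repressor, "C5_DA"] = 13.55
        truth.loc[repressor, "protocatechuate"] = 4.7
        categories[repressor] = "regulator"
    for locus in take(n_control_driven):
        truth.loc[locus, "D-glucose"] = -2.0
        categories[locus] = "other"

    annotations = pd.DataFrame(
        {"locus": loci, "category": [categories.get(l, "other") for l in loci]}
    )
    lib = LibrarySpec(
        n_genes=n_genes,
        strains_per_gene_mean=strains_per_gene_mean,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return DiacidWorld(
        conditions=conditions,
        experiments=experiments,
        truth=truth,
        annotations=annotations,
        library_spec=lib,
    )


def simulate_scenario(
    world: DiacidWorld,
    depth: int = 1_000_000,
    mode: str = "multinomial",
    seed: int = 0,
) -> SimCounts:
    """Generate the library and count table for a :class:`DiacidWorld`."""
    strains = generate_library(world.library_spec)
    # rename library loci into the scenario's locus namespace so truth and
    # annotations join directly
    lib_loci = sorted(strains["locus"].dropna().unique())
    if len(lib_loci) != len(world.truth.index):
        raise ValueError("library and truth gene counts disagree")
    mapping = dict(zip(lib_loci, world.truth.index))
    strains = strains.assign(locus=strains["locus"].map(mapping))
    spec = TrueFitnessSpec(f_true=world.truth, depth_t0=depth, depth_sample=depth)
    sim = simulate_counts(strains, spec, world.experiments, mode=mode, seed=seed)
    return sim


def write_counts_tsv(sim: SimCounts, path) -> None:
    """Counts TSV: barcode, locus, position_fraction, one column per sample."""
    out = pd.concat([sim.strains, sim.counts], axis=1)
    out["locus"] = out["locus"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def write_experiments_tsv(sim: SimCounts, path) -> None:
    sim.experiments.to_csv(path, sep="\t", index=False)


def write_truth_tsv(sim: SimCounts, path) -> None:
    if sim.truth is None:
        raise ValueError("no ground truth attached")
    long = sim.truth.stack().rename("f_true").reset_index()
    long.columns = ["locus", "condition_name", "f_true"]
    long.to_csv(path, sep="\t", index=False)
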