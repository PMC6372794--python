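"""Strain- and gene-level fitness from barcode counts.

Strain fitness is the log2 ratio of a barcode's pseudocounted frequency in a
sample to its frequency in the pooled reference (the first control passage):

    f_is = log2((n_is + ps) / (D_s + ps*B)) - log2((n0_i + ps) / (D0 + ps*B))

with B the number of pool barcodes, D the sample depth, and n0/D0 the counts
and depth pooled over the reference replicates.  The pseudocount enters both
numerator and depth so frequencies stay normalized; ps = 0 is allowed
explicitly and recovers exact log ratios.

Gene fitness averages the usable strains inserted in the central window of
the ORF (default central 80%), weighted by default with the delta-method
inverse variance of a log count ratio, 1/(1/(n_is+ps) + 1/(n0_i+ps)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import INTERGENIC

WEIGHTINGS = ("precision", "reference_count", "uniform")
CENTERS = ("median", "none")


@dataclass
class FitnessParams:
    pseudocount: float = 0.5
    min_reference_count: int = 3
    central_window: tuple[float, float] = (0.10, 0.90)
    weighting: str = "precision"
    center: str = "median"

    def __post_init__(self) -> None:
        lo, hi = self.central_window
        if not (0.0 <= lo <= hi <= 1.0):
            raise InputError("central_window must lie within [0, 1]")
        if self.pseudocount < 0:
            raise InputError("pseudocount must be >= 0")
        if self.min_reference_count < 0:
            raise InputError("min_reference_count must be >= 0")
        if self.weighting not in WEIGHTINGS:
            raise InputError(f"weighting must be one of {WEIGHTINGS}")
        if self.center not in CENTERS:
            raise InputError(f"center must be one of {CENTERS}")


@dataclass
class StrainFitness:
    """Per-(barcode, non-reference sample) fitness with usability flags."""

    fitness: pd.DataFrame  # barcodes x samples, log2 units
    usable: pd.Series  # per barcode: pooled reference count >= threshold
    ref_counts: pd.Series  # n0 per barcode
    ref_depth: float  # D0


@dataclass
class GeneFitness:
    """Per-(gene, sample) weighted-average fitness."""

    fitness: pd.DataFrame  # loci x samples; only loci with >= 1 eligible strain
    n_strains_used: pd.Series  # per locus


def strain_fitness(
    counts: pd.DataFrame, sheet: pd.DataFrame, params: FitnessParams
) -> StrainFitness:
    """Compute strain fitness against the pooled reference group."""
    ref_samples = list(sheet.loc[sheet["is_reference"], "sample_id"])
    if not ref_samples:
        raise InputError("sample sheet designates no reference samples")
    missing = [s for s in sheet["sample_id"] if s not in counts.columns]
    if missing:
        raise InputError(f"sheet samples absent from count table: {missing}")
    depths = counts.sum(axis=0)
    zero = depths[depths == 0]
    if len(zero):
        raise InputError(f"zero-depth sample(s): {list(zero.index)}")

    ps = params.pseudocount
    n_barcodes = counts.shape[0]
    n0 = counts[ref_samples].sum(axis=1)
    d0 = float(depths[ref_samples].sum())
    other = [s for s in sheet["sample_id"] if s not in set(ref_samples)]

    with np.errstate(divide="ignore"):
        ref_log = np.log2((n0 + ps).to_numpy() / (d0 + ps * n_barcodes))
        fit = {}
        for s in other:
            num = np.log2(
                (counts[s] + ps).to_numpy() / (float(depths[s]) + ps * n_barcodes)
            )
            fit[s] = num - ref_log
    fitness = pd.DataFrame(fit, index=counts.index)
    usable = n0 >= params.min_reference_count
    return StrainFitness(fitness=fitness, usable=usable, ref_counts=n0, ref_depth=d0)


def gene_fitness(
    strains: StrainFitness,
    counts: pd.DataFrame,
    pool: pd.DataFrame,
    params: FitnessParams,
) -> GeneFitness:
    """Aggregate strain fitness to genes.

    A strain contributes iff it is usable (reference count at threshold) and
    its orf_fraction lies inside the central window (endpoints inclusive).
    Genes with no eligible strain carry no value, never 0.
    """
    missing = set(pool["barcode"]) - set(strains.fitness.index)
    if missing:
        raise InputError(
            f"pool barcodes absent from strain fitness table: {sorted(missing)[:5]}"
        )
    meta = pool.set_index("barcode")[["locus", "orf_fraction"]].loc[strains.fitness.index]
    lo, hi = params.central_window
    eligible = (
        (meta["locus"] != INTERGENIC)
        & meta["orf_fraction"].between(lo, hi, inclusive="both")
        & strains.usable
    )

    ps = params.pseudocount
    samples = strains.fitness.columns
    n0 = strains.ref_counts
    if params.weighting == "uniform":
        weights = pd.DataFrame(1.0, index=strains.fitness.index, columns=samples)
    elif params.weighting == "reference_count":
        weights = pd.DataFrame(
            np.tile((n0 + ps).to_numpy()[:, None], (1, len(samples))),
            index=strains.fitness.index,
            columns=samples,
        )
    else:  # precision: inverse delta-method variance of the log ratio
        n_s = counts.loc[strains.fitness.index, samples]
        weights = 1.0 / (1.0 / (n_s + ps) + 1.0 / ((n0 + ps).to_numpy()[:, None]))

    f = strains.fitness[eligible]
    w = weights[eligible]
    locus = meta.loc[eligible, "locus"]
    num = (f * w).groupby(locus).sum()
    den = w.groupby(locus).sum()
    fitness = num / den
    n_used = eligible.groupby(meta["locus"]).sum()
    n_used = n_used[(n_used.index != INTERGENIC) & (n_used > 0)]
    fitness = fitness.loc[n_used.index]
    fitness.index.name = "locus"
    return GeneFitness(fitness=fitness, n_strains_used=n_used.astype(int))


def center_fitness(genes: GeneFitness, method: str = "median") -> GeneFitness:
    """Per-sample compositional centering of gene fitness.

    ``median`` subtracts each sample's median gene fitness (idempotent);
    ``none`` is the identity.  Centering absorbs the arbitrary renormalization
    constant a pooled competition imposes on every log ratio in a sample.
    """
    if method == "none":
        return genes
    if method != "median":
        raise InputError(f"unknown centering method {method!r}")
    n_valid = genes.fitness.notna().sum(axis=0)
    if (n_valid < 3).any():
        bad = list(n_valid[n_valid < 3].index)
        raise InputError(f"too few genes to center sample(s): {bad}")
    centered = genes.fitness - genes.fitness.median(axis=0)
    return GeneFitness(fitness=centered, n_strains_used=genes.n_strains_used)
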