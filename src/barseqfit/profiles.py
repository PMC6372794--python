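"""Temporal fitness profiles: replicate aggregation, the replicate-SD noise
filter, cheesecloth-minus-control normalization, and top-k ranking.

A profile set holds, per gene, the replicate mean and sample SD of gene
fitness on the full (condition x passage) grid — 10 cells at the default
design.  A gene is eliminated when its largest SD across the grid exceeds
its largest absolute mean fitness (a pure noise signature); surviving genes
are normalized per passage by subtracting the control-condition mean, which
cancels condition-independent growth effects, and ranked by their largest
absolute normalized fitness at any cheesecloth passage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import CONDITIONS

logger = logging.getLogger(__name__)


@dataclass
class ProfileSet:
    """Replicate mean/SD per gene on the (condition, passage) grid.

    ``mean`` and ``sd`` share a MultiIndex column layout (condition, passage);
    ``n_replicates`` maps each grid cell to its replicate count.  The
    reference cell (control, reference passage) carries mean 0, SD 0 by
    definition when a pooled reference was used.
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    n_replicates: dict[tuple[str, int], int]

    @property
    def passages(self) -> list[int]:
        return sorted({p for (_c, p) in self.mean.columns})


@dataclass
class SdFilterResult:
    kept: pd.Index
    removed: pd.Index
    stats: pd.DataFrame  # per gene: max_sd, max_abs_fitness, unevaluable, removed


def aggregate_replicates(
    genes: pd.DataFrame,
    sheet: pd.DataFrame,
    reference_zero: bool = True,
) -> ProfileSet:
    """Aggregate per-sample gene fitness into per-(condition, passage) cells.

    ``genes`` is a loci x samples fitness table whose columns are the
    non-reference samples of ``sheet``.  Mean and sample SD (n-1 denominator)
    are taken over the replicates of each cell.  With ``reference_zero``
    (pooled-reference convention) the reference cell is 0/0 by definition;
    samples with passage 0 (optional time-zero aliquots) are ignored.
    """
    sheet = sheet[sheet["passage"] > 0]
    ref = sheet[sheet["is_reference"]]
    if ref.empty:
        raise InputError("sheet designates no reference group")
    ref_cell = ("control", int(ref["passage"].iloc[0]))
    n_passages = int(sheet["passage"].max())
    grid = [(c, p) for c in CONDITIONS for p in range(1, n_passages + 1)]

    non_ref = sheet.loc[~sheet["is_reference"], "sample_id"]
    missing = [s for s in non_ref if s not in genes.columns]
    if missing:
        raise InputError(f"sheet samples absent from gene fitness table: {missing}")

    mean_cols: dict[tuple[str, int], pd.Series] = {}
    sd_cols: dict[tuple[str, int], pd.Series] = {}
    n_reps: dict[tuple[str, int], int] = {}
    for cell in grid:
        condition, passage = cell
        members = sheet[
            (sheet["condition"] == condition) & (sheet["passage"] == passage)
        ]["sample_id"]
        if members.empty:
            raise InputError(f"no samples for grid cell {cell}")
        if cell == ref_cell and reference_zero:
            mean_cols[cell] = pd.Series(0.0, index=genes.index)
            sd_cols[cell] = pd.Series(0.0, index=genes.index)
            n_reps[cell] = len(members)
            continue
        block = genes[list(members)]
        mean_cols[cell] = block.mean(axis=1)
        sd_cols[cell] = block.std(axis=1, ddof=1) if block.shape[1] >= 2 else pd.Series(np.nan, index=genes.index)
        n_reps[cell] = block.shape[1]

    columns = pd.MultiIndex.from_tuples(grid, names=["condition", "passage"])
    mean = pd.DataFrame({c: mean_cols[c] for c in grid})
    mean.columns = columns
    sd = pd.DataFrame({c: sd_cols[c] for c in grid})
    sd.columns = columns
    mean.index.name = sd.index.name = "locus"
    return ProfileSet(mean=mean, sd=sd, n_replicates=n_reps)


def sd_filter(profiles: ProfileSet) -> SdFilterResult:
    """Eliminate genes whose largest replicate SD across the grid exceeds
    their largest absolute mean fitness.

    Ties are kept (strict inequality), so an all-zero gene survives.  Genes
    with any missing SD (fewer than 2 replicates somewhere) cannot be
    evaluated; they are kept and flagged.
    """
    max_sd = profiles.sd.max(axis=1)
    max_abs = profiles.mean.abs().max(axis=1)
    unevaluable = profiles.sd.isna().any(axis=1) | profiles.mean.isna().any(axis=1)
    removed_mask = (max_sd > max_abs) & ~unevaluable
    stats = pd.DataFrame(
        {
            "max_sd": max_sd,
            "max_abs_fitness": max_abs,
            "unevaluable": unevaluable,
            "removed": removed_mask,
        }
    )
    n_unev = int(unevaluable.sum())
    if n_unev:
        logger.warning("sd_filter: %d gene(s) unevaluable (missing SD), kept", n_unev)
    return SdFilterResult(
        kept=profiles.mean.index[~removed_mask],
        removed=profiles.mean.index[removed_mask],
        stats=stats,
    )


def condition_normalize(profiles: ProfileSet) -> pd.DataFrame:
    """Per-passage cheesecloth-minus-control normalized profiles.

    Returns a loci x passages table g with g_t = mean_cheesecloth(t) -
    mean_control(t).  Genes with an incomplete grid are dropped with a log
    entry.
    """
    passages = profiles.passages
    cheese = profiles.mean[[("cheesecloth", p) for p in passages]]
    control = profiles.mean[[("control", p) for p in passages]]
    g = pd.DataFrame(
        cheese.to_numpy() - control.to_numpy(),
        index=profiles.mean.index,
        columns=pd.Index(passages, name="passage"),
    )
    incomplete = g.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "condition_normalize: dropping %d gene(s) with incomplete grids",
            int(incomplete.sum()),
        )
        g = g[~incomplete]
    return g


def rank_and_select(norm: pd.DataFrame, k: int = 250) -> pd.DataFrame:
    """Rank genes by max_t |g_t| and return the top min(k, n).

    Deterministic total order: descending score, ties broken by locus.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    score = norm.abs().max(axis=1)
    ranked = (
        pd.DataFrame({"locus": score.index, "score": score.to_numpy()})
        .sort_values(["score", "locus"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked.head(min(k, len(ranked))).set_index("locus")
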