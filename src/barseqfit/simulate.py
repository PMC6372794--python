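"""Forward simulator of a serial-passage adhesion selection assayed by BarSeq.

The simulated experiment mirrors a pooled barcoded transposon library grown
through five daily passages, with and without an adhesion sink (cheesecloth)
submerged in the culture.  Each cycle, a strain's planktonic frequency is
thinned by its capture probability ``a`` (cheesecloth condition only), the
culture regrows to saturation (pure renormalization — BarSeq observes
composition, not absolute numbers), and a multinomial read sample is drawn
for every (condition, passage, replicate).  Planted phenotype classes give
each gene a capture schedule and growth penalty; the truth labels let
downstream recovery be scored exactly.

Only composition dynamics are modeled: no rosettes, no cloth saturation, no
spatial structure, no PCR chimeras.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .barcodes import FlankSpec
from .errors import BarcodeSpaceExhaustedError, InputError
from .io import INTERGENIC

CLASSES = (
    "neutral",
    "nonadhesive_strong",
    "nonadhesive_mild",
    "hyperadhesive",
    "recovery",
    "growth_defect",
)

DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "neutral": 0.90,
    "nonadhesive_strong": 0.03,
    "nonadhesive_mild": 0.02,
    "hyperadhesive": 0.02,
    "recovery": 0.02,
    "growth_defect": 0.01,
}

# Per-cycle capture probabilities.  The mild class sits just below the
# wild-type capture rate (a modest adhesion defect); the recovery class is
# strongly captured early and escapes capture late, so its profile dips and
# then returns to slightly positive — the shape reported for smooth-LPS
# mutants.  None means "wild-type capture" (resolved against wt_capture).
DEFAULT_CLASS_CAPTURE: dict[str, object] = {
    "neutral": None,
    "nonadhesive_strong": 0.0,
    "nonadhesive_mild": 0.5,
    "hyperadhesive": 0.85,
    "recovery": (0.9, 0.7, 0.4, 0.1, 0.0),
    "growth_defect": None,
}

DEFAULT_GROWTH_PENALTY: dict[str, float] = {"growth_defect": -0.15}


@dataclass
class SimulationConfig:
    """Study conditions for the simulated passaging experiment.

    Defaults emulate the deposited dataset's structure: ~1000 genes at ~3
    insertions each plus intergenic strains, 2 conditions x 5 passages x 3
    replicates, 200k reads per sample, with the first control passage as the
    reference group.  ``doublings_per_cycle`` defaults to 3.9 ~ log2 of the
    ~15-fold daily dilution.
    """

    n_genes: int = 1000
    insertions_per_gene_mean: float = 3.0
    intergenic_fraction: float = 0.15
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    wt_capture: float = 0.6
    class_capture: dict[str, object] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_CAPTURE)
    )
    growth_penalty: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROWTH_PENALTY)
    )
    doublings_per_cycle: float = 3.9
    n_passages: int = 5
    n_replicates: int = 3
    reads_per_sample: int = 200_000
    abundance_lognormal_sigma: float = 0.8
    barcode_length: int = 20
    genome_length: int = 4_000_000
    overdispersion: float = 0.0  # Dirichlet-multinomial; 0 disables
    emit_t0: bool = False  # optional explicit pre-passage sample
    seed: int | None = None

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise InputError("n_genes must be positive")
        if self.insertions_per_gene_mean <= 0:
            raise InputError("insertions_per_gene_mean must be positive")
        if not 0 <= self.intergenic_fraction < 1:
            raise InputError("intergenic_fraction must be in [0, 1)")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"class_proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise InputError(f"unknown phenotype class(es): {sorted(unknown)}")
        if not 0 <= self.wt_capture < 1:
            raise InputError("wt_capture must be in [0, 1)")
        for cls in CLASSES:
            sched = self.capture_schedule(cls)
            if len(sched) != self.n_passages:
                raise InputError(
                    f"capture schedule for {cls!r} has length {len(sched)}, "
                    f"expected n_passages={self.n_passages}"
                )
            if np.any(sched < 0) or np.any(sched > 1):
                raise InputError(f"capture values for {cls!r} outside [0, 1]")
        if self.reads_per_sample <= 0:
            raise InputError("reads_per_sample must be positive")
        if self.abundance_lognormal_sigma < 0:
            raise InputError("abundance_lognormal_sigma must be >= 0")
        if self.n_passages < 1 or self.n_replicates < 1:
            raise InputError("n_passages and n_replicates must be >= 1")

    def capture_schedule(self, cls: str) -> np.ndarray:
        """Per-passage capture probabilities for a phenotype class."""
        value = self.class_capture.get(cls)
        if value is None:
            value = self.wt_capture
        if np.isscalar(value):
            return np.full(self.n_passages, float(value))
        return np.asarray(value, dtype=float)

    def class_growth_penalty(self, cls: str) -> float:
        return float(self.growth_penalty.get(cls, 0.0))


def load_config(path) -> SimulationConfig:
    """Load a flat YAML mapping of SimulationConfig fields."""
    import yaml

    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise InputError(f"config {path}: expected a flat mapping")
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"config {path}: unknown key(s) {sorted(unknown)}")
    config = SimulationConfig(**raw)
    config.validate()
    return config


def gene_names(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    for _ in range(n):
        for attempt in range(100):
            bc = "".join(bases[rng.integers(0, 4, size=length)])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
                break
        else:
            raise BarcodeSpaceExhaustedError(
                f"no unique {length}-nt barcode after 100 attempts"
            )
    return out


def build_pool(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Draw a barcoded insertion pool.

    Per-gene strain counts are zero-truncated Poisson(insertions_per_gene_mean);
    each strain gets a unique random barcode, a genomic position, and an
    orf_fraction uniform on (0, 1).  Additional intergenic strains (no gene,
    no orf_fraction) are added so they make up ``intergenic_fraction`` of all
    strains.  Deterministic given seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    lam = config.insertions_per_gene_mean
    k = rng.poisson(lam, size=config.n_genes)
    while np.any(k == 0):  # condition on >= 1 insertion per gene
        zero = k == 0
        k[zero] = rng.poisson(lam, size=int(zero.sum()))
    loci = np.repeat(gene_names(config.n_genes), k)
    n_genic = len(loci)
    f = config.intergenic_fraction
    n_inter = int(round(n_genic * f / (1.0 - f))) if f > 0 else 0
    n_total = n_genic + n_inter

    orf_fraction = rng.uniform(0.0, 1.0, size=n_genic)
    while np.any(orf_fraction == 0.0):  # open interval
        zero = orf_fraction == 0.0
        orf_fraction[zero] = rng.uniform(0.0, 1.0, size=int(zero.sum()))

    pool = pd.DataFrame(
        {
            "barcode": _random_barcodes(rng, n_total, config.barcode_length),
            "scaffold": "chr1",
            "strand": rng.choice(["+", "-"], size=n_total),
            "position": rng.integers(1, config.genome_length + 1, size=n_total),
            "locus": np.concatenate([loci, np.repeat(INTERGENIC, n_inter)]),
            "orf_fraction": np.concatenate(
                [orf_fraction, np.full(n_inter, np.nan)]
            ),
        }
    )
    pool = pool.sort_values("position", kind="stable").reset_index(drop=True)
    return pool


def assign_gene_classes(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Assign each gene a phenotype class with its realized parameters.

    Sampling follows ``class_proportions``; the returned truth table records,
    per gene, the class, the growth penalty, and the per-passage capture
    schedule actually used.  Intergenic strains are implicitly neutral and do
    not appear here (they carry no gene).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    classes = sorted(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    assigned = rng.choice(classes, size=config.n_genes, p=probs)
    schedules = {c: config.capture_schedule(c) for c in CLASSES}
    truth = pd.DataFrame({"locus": gene_names(config.n_genes), "class": assigned})
    truth["growth_penalty"] = [config.class_growth_penalty(c) for c in assigned]
    for t in range(config.n_passages):
        truth[f"capture_{t + 1}"] = [schedules[c][t] for c in assigned]
    return truth


def _strain_parameters(
    pool: pd.DataFrame, truth: pd.DataFrame, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-strain capture matrix (S x P) and growth multipliers (S,)."""
    genic = set(truth["locus"])
    pool_genes = set(pool.loc[pool["locus"] != INTERGENIC, "locus"])
    if pool_genes != genic:
        raise InputError("pool and truth labels cover different gene universes")
    cls_by_locus = dict(zip(truth["locus"], truth["class"]))
    sched_cols = [c for c in truth.columns if c.startswith("capture_")]
    sched_by_locus = {
        row["locus"]: np.array([row[c] for c in sched_cols], dtype=float)
        for _, row in truth.iterrows()
    }
    pen_by_locus = dict(zip(truth["locus"], truth["growth_penalty"]))

    wt_sched = config.capture_schedule("neutral")
    capture = np.empty((len(pool), config.n_passages))
    penalty = np.empty(len(pool))
    for i, locus in enumerate(pool["locus"]):
        if locus == INTERGENIC:
            capture[i] = wt_sched
            penalty[i] = 0.0
        else:
            capture[i] = sched_by_locus[locus]
            penalty[i] = pen_by_locus[locus]
    growth = 2.0 ** (config.doublings_per_cycle * (1.0 + penalty))
    return capture, growth


def deterministic_frequencies(
    pool: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    initial: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Iterate the expected-composition recursion with sampling disabled.

    Returns, per condition, an array of shape (n_passages + 1, n_strains)
    of strain frequencies; row 0 is the initial composition.  Useful for
    analytic checks: with one fully nonadhesive strain among neutrals the
    cheesecloth log2 frequency gain relative to neutral strains is exactly
    -log2(1 - wt_capture) per passage.
    """
    if pool.empty:
        raise InputError("empty pool")
    capture, growth = _strain_parameters(pool, truth, config)
    if initial is None:
        x0 = np.full(len(pool), 1.0 / len(pool))
    else:
        x0 = np.asarray(initial, dtype=float)
        x0 = x0 / x0.sum()
    out: dict[str, np.ndarray] = {}
    for condition in bio.CONDITIONS:
        traj = np.empty((config.n_passages + 1, len(pool)))
        traj[0] = x0
        x = x0.copy()
        for t in range(config.n_passages):
            if condition == "cheesecloth":
                x = x * (1.0 - capture[:, t])
            x = x * growth
            x = x / x.sum()
            traj[t + 1] = x
        out[condition] = traj
    return out


def _replicate_letters(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n <= len(letters):
        return list(letters[:n])
    return [f"R{i + 1}" for i in range(n)]


def simulate_counts(
    pool: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the count table and sample sheet for the full design.

    Each replicate draws its own initial log-normal abundance vector, shared
    between the two conditions of that replicate (both start from the same
    thawed library aliquot).  Each (condition, passage) sample is a
    multinomial draw of ``reads_per_sample`` reads from the current
    composition (Dirichlet-multinomial when ``overdispersion`` > 0).  The
    three control passage-1 samples form the reference group.  Deterministic
    given seed; replicates use distinct derived substreams.
    """
    config.validate()
    if pool.empty:
        raise InputError("empty pool")
    if config.reads_per_sample <= 0:
        raise InputError("reads_per_sample must be positive")
    capture, growth = _strain_parameters(pool, truth, config)
    n_strains = len(pool)
    letters = _replicate_letters(config.n_replicates)
    children = np.random.SeedSequence(seed).spawn(config.n_replicates)

    columns: dict[str, np.ndarray] = {}
    for r, (letter, child) in enumerate(zip(letters, children)):
        rng = np.random.default_rng(child)
        x0 = rng.lognormal(0.0, config.abundance_lognormal_sigma, size=n_strains)
        x0 = x0 / x0.sum()
        if config.emit_t0:
            columns[f"T0{letter}"] = _draw_reads(rng, x0, config)
        for condition in bio.CONDITIONS:
            x = x0.copy()
            prefix = "PYE" if condition == "control" else "Cheese"
            for t in range(config.n_passages):
                if condition == "cheesecloth":
                    x = x * (1.0 - capture[:, t])
                x = x * growth
                x = x / x.sum()
                columns[f"{prefix}{t + 1}{letter}"] = _draw_reads(rng, x, config)

    rows = []
    if config.emit_t0:
        for letter in letters:
            rows.append(("T0" + letter, "control", 0, letter, False))
    for condition in bio.CONDITIONS:
        prefix = "PYE" if condition == "control" else "Cheese"
        for passage in range(1, config.n_passages + 1):
            for letter in letters:
                rows.append(
                    (
                        f"{prefix}{passage}{letter}",
                        condition,
                        passage,
                        letter,
                        condition == "control" and passage == 1,
                    )
                )
    sheet = pd.DataFrame(rows, columns=bio.SHEET_COLUMNS)
    counts = pd.DataFrame(
        {row[0]: columns[row[0]] for row in rows},
        index=pd.Index(pool["barcode"], name="barcode"),
        dtype="int64",
    )
    return counts, sheet


def _draw_reads(
    rng: np.random.Generator, composition: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    p = composition / composition.sum()
    if config.overdispersion > 0:
        concentration = 1.0 / config.overdispersion
        p = rng.dirichlet(np.maximum(p * concentration, 1e-12))
    return rng.multinomial(config.reads_per_sample, p)


def emit_reads(
    counts: pd.DataFrame,
    pool: pd.DataFrame,
    flanks: FlankSpec,
    out_dir,
    seed: int,
    error_rate: float = 0.0,
    stagger_length: int = 4,
    tail_length: int = 10,
) -> dict[str, Path]:
    """Write per-sample FASTQ files realizing a count table.

    Each read is: random stagger + pre-flank + barcode + post-flank + random
    tail, constant Phred+33 quality.  Exactly ``count`` copies per barcode,
    in a seeded shuffled order, with optional per-base substitution errors.
    Returns sample_id -> path.
    """
    barcode_lengths = pool["barcode"].str.len().unique()
    if len(barcode_lengths) != 1 or barcode_lengths[0] != flanks.barcode_length:
        raise InputError(
            f"flank spec barcode_length {flanks.barcode_length} does not match "
            f"pool barcode length(s) {sorted(barcode_lengths)}"
        )
    missing = set(counts.index) - set(pool["barcode"])
    if missing:
        raise InputError(f"count-table barcodes absent from pool: {sorted(missing)[:5]}")
    out_dir = bio.ensure_dir(out_dir)
    bases = np.array(list("ACGT"))
    paths: dict[str, Path] = {}
    children = np.random.SeedSequence(seed).spawn(len(counts.columns))
    for sample_id, child in zip(counts.columns, children):
        rng = np.random.default_rng(child)
        col = counts[sample_id]
        reads = np.repeat(col.index.to_numpy(), col.to_numpy())
        rng.shuffle(reads)
        read_len = (
            stagger_length
            + len(flanks.pre)
            + flanks.barcode_length
            + len(flanks.post)
            + tail_length
        )
        qual = "I" * read_len
        path = out_dir / f"{sample_id}.fastq"
        records = []
        for i, barcode in enumerate(reads):
            stagger = "".join(bases[rng.integers(0, 4, size=stagger_length)])
            tail = "".join(bases[rng.integers(0, 4, size=tail_length)])
            seq = stagger + flanks.pre + barcode + flanks.post + tail
            if error_rate > 0:
                seq_arr = np.array(list(seq))
                hit = rng.random(read_len) < error_rate
                if hit.any():
                    # substitute with a uniformly chosen *different* base
                    for j in np.flatnonzero(hit):
                        choices = [b for b in "ACGT" if b != seq_arr[j]]
                        seq_arr[j] = choices[rng.integers(0, 3)]
                    seq = "".join(seq_arr)
            records.append((f"{sample_id}:{i}", seq, qual))
        bio.write_fastq(records, path)
        paths[sample_id] = path
    return paths


def simulate_experiment(config: SimulationConfig, seed: int):
    """Convenience wrapper: pool, truth, counts, sheet from one seed."""
    ss = np.random.SeedSequence(seed)
    s_pool, s_truth, s_counts = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]
    pool = build_pool(config, s_pool)
    truth = assign_gene_classes(config, s_truth)
    counts, sheet = simulate_counts(pool, truth, config, s_counts)
    return pool, truth, counts, sheet
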