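"""Read-level barcode extraction, per-sample counting, and QC statistics.

Amplicon reads carry a random barcode between two fixed flanking sequences
(stagger + pre-flank + barcode + post-flank + tail).  Extraction is a
substring search with an optional per-flank Hamming mismatch budget; the
leftmost valid placement wins and no indels are considered.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, TextIO

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqFormatError, InputError, SampleSheetError

ACGT = frozenset("ACGT")

# Flanks of the published barcoded-HiMar amplicon design (N20 between an
# 18 nt upstream and a 7 nt downstream constant region).  They are defaults,
# not assumptions: any amplicon structure can be described by a FlankSpec.
DEFAULT_PRE = "GTCGACCTGCAGCGTACG"
DEFAULT_POST = "AGAGACC"


@dataclass(frozen=True)
class FlankSpec:
    """Constant sequences bracketing the random barcode in each read."""

    pre: str = DEFAULT_PRE
    post: str = DEFAULT_POST
    barcode_length: int = 20
    max_flank_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.pre or not self.post:
            raise InputError("flank sequences must be nonempty")
        if self.barcode_length < 1:
            raise InputError("barcode_length must be >= 1")
        if self.max_flank_mismatches < 0:
            raise InputError("max_flank_mismatches must be >= 0")


@dataclass(frozen=True)
class QCStats:
    """Per-sample counting summary."""

    total_reads: int
    reads_with_barcode: int
    distinct_barcodes: int


def _hamming_le(a: str, b: str, budget: int) -> bool:
    """True if Hamming(a, b) <= budget; a and b must have equal length."""
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return False
    return True


def _pre_occurrences(read: str, pre: str, budget: int) -> Iterator[int]:
    """Yield start offsets of pre-flank matches, leftmost first."""
    if budget == 0:
        start = read.find(pre)
        while start != -1:
            yield start
            start = read.find(pre, start + 1)
    else:
        for start in range(len(read) - len(pre) + 1):
            if _hamming_le(read[start : start + len(pre)], pre, budget):
                yield start


def extract_barcode(read_sequence: str, flanks: FlankSpec) -> str | None:
    """Extract the barcode from one read, or return None.

    The barcode is the ``barcode_length``-nt substring between the leftmost
    occurrence of the pre-flank and an occurrence of the post-flank starting
    exactly ``barcode_length`` after the pre-flank ends, each flank allowing
    at most ``max_flank_mismatches`` mismatches.  Barcodes containing
    characters outside ACGT (e.g. N) are rejected.  Absence is a value, not
    an error.
    """
    if not read_sequence:
        raise InputError("empty read sequence")
    seq = read_sequence
    m = flanks.max_flank_mismatches
    blen = flanks.barcode_length
    for start in _pre_occurrences(seq, flanks.pre, m):
        bc_start = start + len(flanks.pre)
        post_start = bc_start + blen
        post_end = post_start + len(flanks.post)
        if post_end > len(seq):
            continue
        if not _hamming_le(seq[post_start:post_end], flanks.post, m):
            continue
        barcode = seq[bc_start:post_start]
        if set(barcode) <= ACGT:
            return barcode
        return None  # placement found but barcode ambiguous: discard read
    return None


def parse_fastq(handle: TextIO) -> Iterator[str]:
    """Yield read sequences from a FASTQ stream, validating record shape."""
    try:
        for idx, (_title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"record {idx}: sequence/quality length mismatch"
                )
            yield seq
    except ValueError as exc:  # Biopython signals truncated/corrupt records
        raise FastqFormatError(str(exc)) from exc


def count_sample(
    reads: Iterable[str], flanks: FlankSpec
) -> tuple[dict[str, int], QCStats]:
    """Count extracted barcodes over an iterable of read sequences.

    Returns the barcode -> count mapping and QC statistics (total reads,
    reads yielding a barcode, distinct barcodes).  Counting is invariant to
    read order.
    """
    counts: Counter[str] = Counter()
    total = 0
    for seq in reads:
        total += 1
        barcode = extract_barcode(seq, flanks)
        if barcode is not None:
            counts[barcode] += 1
    stats = QCStats(
        total_reads=total,
        reads_with_barcode=sum(counts.values()),
        distinct_barcodes=len(counts),
    )
    return dict(counts), stats


def count_fastq_file(path, flanks: FlankSpec) -> tuple[dict[str, int], QCStats]:
    with open(path) as handle:
        return count_sample(parse_fastq(handle), flanks)


def assemble_count_table(
    per_sample_counts: Mapping[str, Mapping[str, int]],
    pool: pd.DataFrame,
    sheet: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble a barcode-by-sample count table restricted to pool barcodes.

    Every pool barcode appears as a row (zero-filled where unobserved) so
    that downstream pseudocount arithmetic is well defined.  The unmapped
    report gives, per sample, reads whose barcode is absent from the pool.
    """
    known = set(sheet["sample_id"])
    extra = set(per_sample_counts) - known
    if extra:
        raise SampleSheetError(
            f"samples in counts but not in sheet: {sorted(extra)}"
        )
    barcodes = pool["barcode"]
    pool_set = set(barcodes)
    table = pd.DataFrame(0, index=pd.Index(barcodes, name="barcode"), columns=[])
    report_rows = []
    for sample_id in sheet["sample_id"]:
        counts = per_sample_counts.get(sample_id, {})
        col = pd.Series(counts, dtype="int64").reindex(barcodes, fill_value=0)
        table[sample_id] = col.to_numpy()
        unmapped = sum(c for bc, c in counts.items() if bc not in pool_set)
        total = sum(counts.values())
        report_rows.append(
            {
                "sample_id": sample_id,
                "unmapped_reads": unmapped,
                "unmapped_fraction": unmapped / total if total else 0.0,
            }
        )
    return table, pd.DataFrame(report_rows)


def top_percentile_share(sample_counts: pd.Series, p: float = 1.0) -> float:
    """Proportion of a sample's reads carried by the top p% of barcodes.

    Barcodes are ranked by descending count with lexicographic tie-break;
    the top ceil(p/100 * B) barcodes are taken, B being the number of pool
    barcodes (rows of the table, observed or not).
    """
    total = int(sample_counts.sum())
    if total <= 0:
        raise InputError("sample has zero total reads")
    n_top = math.ceil(p / 100.0 * len(sample_counts))
    ranked = sample_counts.sort_index().sort_values(ascending=False, kind="stable")
    return float(ranked.iloc[:n_top].sum()) / total
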