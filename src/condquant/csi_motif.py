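"""k-mer enrichment ranking for a barcoded in vitro DNA selection (CSI/SELEX).

Reads are demultiplexed by 5' barcode, the 20-bp randomized central region
between the constant flanks is extracted, k-mers (k = 6 by default, the
length of the GGCCCC binding site the selection identified) are counted
over sliding windows, and each k-mer's frequency in the selected pool is
divided by its frequency in the fusion-negative control pool with a
symmetric pseudofrequency.  The ranked table and the per-round enrichment
trajectory are the outputs.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "LibraryDesign",
    "KmerTable",
    "demultiplex",
    "extract_variable_region",
    "extract_regions",
    "count_kmers",
    "compute_enrichment",
    "round_trajectory",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LibraryDesign:
    """The fixed architecture of the selection library.

    Each read is ``barcode + left_flank + variable region (20 bp randomized)
    + right_flank``.
    """

    barcodes: dict  # sample -> DNA
    left_flank: str
    right_flank: str
    variable_length: int = 20
    rounds: tuple = (1, 2, 3)

    def __post_init__(self) -> None:
        if not self.left_flank or not self.right_flank:
            raise ValueError("flanks must be non-empty")
        if self.variable_length <= 0:
            raise ValueError("variable_length must be positive")


@dataclass
class KmerTable:
    """Sliding-window k-mer counts of one (sample, round) pool."""

    sample: str
    round: int
    k: int
    counts: Counter = field(default_factory=Counter)
    total_positions: int = 0

    def frequency(self, kmer: str) -> float:
        if self.total_positions == 0:
            return 0.0
        return self.counts.get(kmer, 0) / self.total_positions


def _hamming(a: str, b: str) -> int:
    return sum(c1 != c2 for c1, c2 in zip(a, b))


def _check_prefix_free(barcodes: dict, max_mismatch: int) -> None:
    items = list(barcodes.items())
    for i, (sa, a) in enumerate(items):
        for sb, b in items:
            if sa == sb:
                continue
            if _hamming(a, b[: len(a)]) <= 2 * max_mismatch:
                raise ValueError(
                    f"barcodes {sa!r}/{sb!r} are not prefix-free at "
                    f"{max_mismatch} mismatches"
                )


def _iter_reads(path: str | Path):
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield str(record.seq)


def demultiplex(
    fastq_paths, design: LibraryDesign, max_barcode_mismatch: int = 0
) -> tuple[dict, dict]:
    """Assign reads to samples by 5' barcode.

    Returns ``(reads_by_sample, tally)`` where tally counts assigned /
    unassigned / ambiguous reads.  A read matching more than one barcode at
    the allowed mismatch level is dropped as ambiguous.
    """
    _check_prefix_free(design.barcodes, max_barcode_mismatch)
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    reads: dict = {sample: [] for sample in design.barcodes}
    tally = {"assigned": 0, "unassigned": 0, "ambiguous": 0}
    for path in fastq_paths:
        for seq in _iter_reads(path):
            hits = [
                sample
                for sample, bc in design.barcodes.items()
                if len(seq) >= len(bc) and _hamming(seq[: len(bc)], bc) <= max_barcode_mismatch
            ]
            if len(hits) == 1:
                reads[hits[0]].append(seq)
                tally["assigned"] += 1
            elif not hits:
                tally["unassigned"] += 1
            else:
                tally["ambiguous"] += 1
    return reads, tally


def extract_variable_region(
    read: str,
    design: LibraryDesign,
    barcode_length: int | None = None,
    max_flank_mismatch: int = 1,
) -> str | None:
    """Extract the randomized region from one read, or None to reject.

    The left flank must match (≤ ``max_flank_mismatch`` mismatches)
    immediately after the barcode, the right flank immediately after the
    variable region; regions containing non-ACGT characters are rejected.
    When ``barcode_length`` is None it is inferred by exact barcode match.
    """
    if barcode_length is None:
        for bc in design.barcodes.values():
            if read.startswith(bc):
                barcode_length = len(bc)
                break
        else:
            return None
    lf, rf, L = design.left_flank, design.right_flank, design.variable_length
    start = barcode_length
    if len(read) < start + len(lf) + L + len(rf):
        return None
    if _hamming(read[start : start + len(lf)], lf) > max_flank_mismatch:
        return None
    region = read[start + len(lf) : start + len(lf) + L]
    tail = read[start + len(lf) + L : start + len(lf) + L + len(rf)]
    if _hamming(tail, rf) > max_flank_mismatch:
        return None
    if not set(region) <= set("ACGT"):
        return None
    return region


def extract_regions(
    reads: list, design: LibraryDesign, barcode_length: int | None = None,
    max_flank_mismatch: int = 1,
) -> tuple[list, int]:
    """Batch extraction; returns (regions, n_rejected)."""
    regions, rejected = [], 0
    for read in reads:
        region = extract_variable_region(read, design, barcode_length, max_flank_mismatch)
        if region is None:
            rejected += 1
        else:
            regions.append(region)
    return regions, rejected


def count_kmers(
    regions: list,
    k: int = 6,
    count_reverse_complement: bool = False,
    sample: str = "",
    round: int = 0,
) -> KmerTable:
    """Count k-mers over all sliding windows (step 1) of the regions.

    With ``count_reverse_complement`` each window also increments its
    reverse complement; ``total_positions`` counts every increment so that
    the counts always sum to it.
    """
    counts: Counter = Counter()
    total = 0
    for region in regions:
        if len(region) < k:
            continue
        for i in range(len(region) - k + 1):
            w = region[i : i + k]
            counts[w] += 1
            total += 1
            if count_reverse_complement:
                counts[reverse_complement(w)] += 1
                total += 1
    return KmerTable(sample=sample, round=round, k=k, counts=counts,
                     total_positions=total)


def compute_enrichment(
    pos: KmerTable,
    neg: KmerTable,
    pseudofrequency: float | None = None,
    universe=None,
) -> pd.DataFrame:
    """Rank k-mers by selected-vs-control frequency ratio.

    enrichment = (freq_pos + p) / (freq_neg + p) with the symmetric
    pseudofrequency p (default 1 / max(total positions) of the two pools).
    Rows cover every k-mer observed in either pool (plus ``universe`` if
    given), sorted by descending enrichment with lexicographic tie-break;
    ``rank`` is 1-based.
    """
    if pos.k != neg.k:
        raise ValueError("k must match between the two tables")
    if pos.total_positions == 0:
        raise ValueError("empty positive k-mer table")
    p = pseudofrequency
    if p is None:
        p = 1.0 / max(pos.total_positions, max(neg.total_positions, 1))
    kmers = set(pos.counts) | set(neg.counts)
    if universe is not None:
        kmers |= set(universe)
    rows = []
    for kmer in kmers:
        fp = pos.frequency(kmer)
        fn = neg.frequency(kmer)
        rows.append((kmer, fp, fn, (fp + p) / (fn + p)))
    df = pd.DataFrame(rows, columns=["kmer", "freq_pos", "freq_neg", "enrichment"])
    df = df.sort_values(["enrichment", "kmer"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def round_trajectory(
    pos_tables: dict, neg_tables: dict, pseudofrequency: float | None = None
) -> pd.DataFrame:
    """Per-k-mer enrichment across rounds against the matched control round.

    ``pos_tables`` and ``neg_tables`` map round → :class:`KmerTable`; every
    positive round needs its matched negative.  The output has one row per
    k-mer observed in any round, one ``enrichment_r<round>`` column per
    round, and a ``monotone`` flag marking strictly increasing trajectories.
    """
    rounds = sorted(pos_tables)
    if len(rounds) < 2:
        raise ValueError("need at least two rounds for a trajectory")
    missing = [r for r in rounds if r not in neg_tables]
    if missing:
        raise ValueError(f"missing negative-control round(s): {missing}")
    per_round = {
        r: compute_enrichment(pos_tables[r], neg_tables[r], pseudofrequency)
        .set_index("kmer")["enrichment"]
        for r in rounds
    }
    kmers = sorted(set().union(*(s.index for s in per_round.values())))
    data = {f"enrichment_r{r}": per_round[r].reindex(kmers, fill_value=1.0)
            for r in rounds}
    df = pd.DataFrame(data, index=pd.Index(kmers, name="kmer"))
    cols = [f"enrichment_r{r}" for r in rounds]
    vals = df[cols].to_numpy()
    df["monotone"] = (np.diff(vals, axis=1) > 0).all(axis=1)
    return df.reset_index()
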