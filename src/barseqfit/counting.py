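"""Barcode counting: demultiplex reads, assign barcodes, filter low counts.

The matching rules are deliberately strict — a read is binned to a sample
only if its first six bases equal a multiplex tag exactly, and it increments
a strain only if the 20-mer at the barcode offset equals that strain's
barcode exactly.  No mismatch tolerance and no quality filtering anywhere.
Barcodes shared by more than one gene are excluded before counting and their
reads tallied separately as ambiguous.
"""

from __future__ import annotations

import gzip
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .pool import DEFAULT_LAYOUT, ReadLayout, StrainSpec

__all__ = [
    "SampleAccounting",
    "demultiplex",
    "assign_barcodes",
    "count_sample",
    "filter_counts",
    "parse_fastq",
    "ambiguous_barcodes",
]


@dataclass
class SampleAccounting:
    """Read accounting for one sample: assigned + unassigned + ambiguous
    equals the number of demultiplexed reads."""

    demultiplexed: int = 0
    assigned: int = 0
    unassigned: int = 0
    ambiguous: int = 0

    def check(self) -> None:
        if self.assigned + self.unassigned + self.ambiguous != self.demultiplexed:
            raise AssertionError(f"accounting identity violated: {self}")


def parse_fastq(path) -> Iterable[tuple[str, str, str]]:
    """Iterate (title, sequence, quality) from a plain or gzipped FASTQ."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        yield from FastqGeneralIterator(fh)


def demultiplex(
    reads: Iterable[tuple[str, str, str] | str],
    tag_map: Mapping,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> tuple[dict, int]:
    """Bin reads by exact match of the leading 6-mer against known tags.

    ``tag_map`` maps sample key -> tag.  Returns ``(bins, unmatched)`` where
    ``bins`` maps sample key -> list of read sequences.  Reads are accepted
    as (title, seq, qual) tuples or bare sequences.
    """
    tags = list(tag_map.values())
    if len(set(tags)) != len(tags):
        dupes = [t for t, c in Counter(tags).items() if c > 1]
        raise ValueError(f"duplicate multiplex tags: {dupes}")
    if any(len(t) != layout.tag_length for t in tags):
        raise ValueError(f"all tags must be {layout.tag_length} bases")
    by_tag = {tag: sample for sample, tag in tag_map.items()}
    bins: dict = {sample: [] for sample in tag_map}
    unmatched = 0
    for rec in reads:
        seq = rec[1] if isinstance(rec, tuple) else rec
        sample = by_tag.get(seq[: layout.tag_length])
        if sample is None:
            unmatched += 1
        else:
            bins[sample].append(seq)
    return bins, unmatched


def ambiguous_barcodes(catalog: Sequence[StrainSpec]) -> set[str]:
    """Barcodes carried by more than one catalog entry (to be discarded)."""
    c = Counter(st.barcode for st in catalog)
    return {bc for bc, n in c.items() if n > 1}


def assign_barcodes(
    seqs: Iterable[str],
    catalog: Sequence[StrainSpec],
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> tuple[pd.Series, SampleAccounting]:
    """Count exact barcode matches for one demultiplexed sample.

    Returns a per-strain count vector (indexed by strain_id, catalog order)
    and the sample's accounting.  Reads whose barcode belongs to more than
    one gene are tallied as ambiguous; reads too short or matching no
    catalog barcode are unassigned.
    """
    ambiguous = ambiguous_barcodes(catalog)
    lookup = {
        st.barcode: st.strain_id for st in catalog if st.barcode not in ambiguous
    }
    counts: Counter = Counter()
    acc = SampleAccounting()
    lo, hi = layout.barcode_offset, layout.barcode_offset + layout.barcode_length
    for seq in seqs:
        acc.demultiplexed += 1
        if len(seq) < hi:
            acc.unassigned += 1
            continue
        bc = seq[lo:hi]
        if bc in ambiguous:
            acc.ambiguous += 1
        elif bc in lookup:
            counts[lookup[bc]] += 1
            acc.assigned += 1
        else:
            acc.unassigned += 1
    acc.check()
    vec = pd.Series(
        [counts.get(st.strain_id, 0) for st in catalog],
        index=pd.Index([st.strain_id for st in catalog], name="strain_id"),
        dtype=int,
    )
    return vec, acc


def count_sample(
    reads: Iterable[tuple[str, str, str] | str],
    catalog: Sequence[StrainSpec],
    tag_map: Mapping,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> tuple[pd.DataFrame, dict, int]:
    """Demultiplex + assign in one pass over a multiplexed read stream.

    Returns (counts table with one column per sample, per-sample accounting,
    unmatched-tag count).
    """
    bins, unmatched = demultiplex(reads, tag_map, layout)
    cols = {}
    accounting = {}
    for sample, seqs in bins.items():
        cols[sample], accounting[sample] = assign_barcodes(seqs, catalog, layout)
    counts = pd.DataFrame(cols)
    if isinstance(next(iter(tag_map)), tuple):
        counts.columns = pd.MultiIndex.from_tuples(
            counts.columns, names=["condition", "replicate", "timepoint"]
        )
    return counts, accounting, unmatched


def filter_counts(
    counts: pd.DataFrame, min_total: int = 20, scope: str = "screen"
) -> pd.DataFrame:
    """Drop strains with fewer than ``min_total`` reads summed across samples.

    The retention rule is a row sum >= min_total (strict "<" drops).  With
    ``scope="screen"`` (default) the sum is taken per screen — per
    (condition, replicate) group when columns carry that MultiIndex — and a
    strain is kept only where its screen passes, i.e. the table is restricted
    to strains passing in at least one screen and callers fitting per screen
    should re-apply per replicate.  ``scope="all"`` sums the whole row.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    if counts.empty:
        return counts
    if scope == "all" or not isinstance(counts.columns, pd.MultiIndex):
        keep = counts.sum(axis=1) >= min_total
        return counts.loc[keep]
    if scope != "screen":
        raise ValueError(f"scope must be 'screen' or 'all', got {scope!r}")
    screen_sums = counts.T.groupby(level=["condition", "replicate"]).sum().T
    keep = (screen_sums >= min_total).any(axis=1)
    return counts.loc[keep]


def passing_screens(
    counts: pd.DataFrame, min_total: int = 20
) -> pd.DataFrame:
    """Boolean strains × screens table of the per-screen count filter."""
    screen_sums = counts.T.groupby(level=["condition", "replicate"]).sum().T
    return screen_sums >= min_total
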