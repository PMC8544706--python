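"""Read filtering, exact-match counting, and RPM normalisation.

Adapter-trimmed reads are length-filtered (default 18–26 nt), matched exactly
against the isomiR lookup table, and counted.  A read matching k identities
contributes 1/k to each (equal fractional split) so that the total assigned
count equals the number of matched reads.  Per-sample counts are normalised to
reads per million (RPM); the denominator is, by default, the reads matched to
the isomiR space, with the length-filtered total as the alternative.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .nomenclature import render_label, to_dna
from .reference import LookupTable

__all__ = [
    "FilterStats",
    "SampleTally",
    "ExpressionMatrix",
    "read_fastq_sequences",
    "filter_reads",
    "count_reads",
    "normalize_rpm",
    "quantify_cohort",
    "read_sample_sheet",
]

_DNA = frozenset("ACGT")


@dataclass
class FilterStats:
    kept: int = 0
    discarded_length: int = 0
    discarded_alphabet: int = 0

    @property
    def discarded(self) -> int:
        return self.discarded_length + self.discarded_alphabet


@dataclass
class SampleTally:
    """Per-sample accounting: filtered = matched + unmatched, exactly."""

    filter_stats: FilterStats
    matched: int
    unmatched: int


def read_fastq_sequences(path):
    """Yield read sequences from a FASTQ file (plain or gzip)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq)


def filter_reads(reads, min_len: int = 18, max_len: int = 26):
    """Keep reads with min_len <= length <= max_len, in order.

    Returns ``(kept_sequences, FilterStats)``.  Sequences are normalised to
    DNA uppercase; reads with non-ACGU/T characters are discarded and counted,
    not raised.
    """
    stats = FilterStats()
    kept = []
    for read in reads:
        seq = to_dna(read)
        if not set(seq) <= _DNA:
            stats.discarded_alphabet += 1
            continue
        if not (min_len <= len(seq) <= max_len):
            stats.discarded_length += 1
            continue
        stats.kept += 1
        kept.append(seq)
    return kept, stats


def count_reads(reads, lookup: LookupTable):
    """Count length-filtered reads against the lookup table.

    Returns ``(counts, matched, unmatched)`` where ``counts`` maps identity
    label -> fractional count (1/k per read matching k identities), ``matched``
    and ``unmatched`` are integer read tallies.  Conservation holds exactly on
    the integers (matched + unmatched = reads seen) and to floating precision
    on the fractional counts (sum(counts) ~= matched).
    """
    counts: dict[str, float] = {}
    matched = 0
    unmatched = 0
    for seq, n in Counter(to_dna(r) for r in reads).items():
        ids = lookup.get(seq)
        if not ids:
            unmatched += n
            continue
        matched += n
        share = n / len(ids)
        for ident in ids:
            label = render_label(ident)
            counts[label] = counts.get(label, 0.0) + share
    return counts, matched, unmatched


@dataclass
class ExpressionMatrix:
    """Identity-by-sample raw counts with per-sample matched-read totals.

    ``counts`` rows are identity labels, columns sample ids.  ``rpm`` rescales
    each column to 1e6 using the chosen denominator; samples whose denominator
    is zero stay all-zero and are listed in ``zero_samples``.
    """

    counts: pd.DataFrame
    matched: pd.Series
    filtered: pd.Series
    unmatched: pd.Series
    rpm_denominator: str = "matched"

    def __post_init__(self):
        if self.rpm_denominator not in ("matched", "filtered"):
            raise ValueError("rpm_denominator must be 'matched' or 'filtered'")
        self.counts = self.counts.sort_index()

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    @property
    def denominator(self) -> pd.Series:
        base = self.matched if self.rpm_denominator == "matched" else self.filtered
        return base.reindex(self.counts.columns)

    @property
    def zero_samples(self) -> list[str]:
        den = self.denominator
        return list(den.index[den <= 0])

    @property
    def rpm(self) -> pd.DataFrame:
        den = self.denominator.astype(float).replace(0.0, np.nan)
        out = self.counts.div(den, axis=1) * 1e6
        return out.fillna(0.0)

    def detected(
        self,
        samples=None,
        min_mean_rpm: float = 1.0,
        min_nonzero_fraction: float = 0.25,
    ) -> pd.Series:
        """Cohort detection rule: mean RPM >= threshold and non-zero in at
        least the given fraction of samples (both configurable)."""
        rpm = self.rpm if samples is None else self.rpm[list(samples)]
        mean_ok = rpm.mean(axis=1) >= min_mean_rpm
        frac_ok = (rpm > 0).mean(axis=1) >= min_nonzero_fraction
        return mean_ok & frac_ok


def normalize_rpm(
    counts_by_sample: dict,
    tallies: dict,
    rpm_denominator: str = "matched",
) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from per-sample count dicts."""
    counts = pd.DataFrame(counts_by_sample).fillna(0.0)
    counts.index.name = "label"
    matched = pd.Series({s: t.matched for s, t in tallies.items()}, dtype=int)
    filtered = pd.Series({s: t.filter_stats.kept for s, t in tallies.items()}, dtype=int)
    unmatched = pd.Series({s: t.unmatched for s, t in tallies.items()}, dtype=int)
    return ExpressionMatrix(counts, matched, filtered, unmatched, rpm_denominator)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: ``sample_id  fastq_path  group`` plus optional
    ``*_status`` mutation columns."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "fastq_path", "group"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return sheet


def quantify_cohort(
    fastq_by_sample: dict,
    lookup: LookupTable,
    min_len: int | None = None,
    max_len: int | None = None,
    rpm_denominator: str = "matched",
):
    """FASTQ paths -> (ExpressionMatrix, per-sample tallies).

    Length bounds default to the lookup table's enumeration bounds so that the
    filter and the matchable space agree.
    """
    min_len = lookup.bounds.min_len if min_len is None else min_len
    max_len = lookup.bounds.max_len if max_len is None else max_len
    counts_by_sample = {}
    tallies = {}
    for sample, fastq in fastq_by_sample.items():
        kept, stats = filter_reads(read_fastq_sequences(fastq), min_len, max_len)
        counts, matched, unmatched = count_reads(kept, lookup)
        counts_by_sample[sample] = counts
        tallies[sample] = SampleTally(stats, matched, unmatched)
    matrix = normalize_rpm(counts_by_sample, tallies, rpm_denominator)
    return matrix, tallies
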