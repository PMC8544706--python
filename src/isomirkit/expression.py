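"""Cohort-level expression summaries: means, orphans, ratios, census.

The isomiR/canonical expression ratio is computed on cohort-mean RPM: for each
isomiR with a detected canonical form, ratio = mean(isomiR) / mean(canonical).
miRNAs without isomiRs and orphan isomiRs (isomiRs whose canonical form is
undetected in the cohort) are excluded.  The reporting filter keeps isomiRs
with mean expression strictly above 20 RPM and ratio strictly above 1.

The census reproduces the standard mature-miRNA bookkeeping: how many
canonical miRNAs have isomiRs, how many isomiRs have a detectable canonical
form vs. are orphans, and the per-category breakdown of the classified
isomiRs (with the mixed class split by its deviation combinations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .nomenclature import (
    canonical_label,
    classify,
    parent_of,
    parse_label,
)

__all__ = [
    "group_means",
    "detect_orphans",
    "compute_ratios",
    "filter_ratio_table",
    "census",
    "MatureMiRNACensus",
]


def group_means(matrix, samples) -> pd.Series:
    """Arithmetic mean RPM over a non-empty sample subset."""
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample subset")
    return matrix.rpm[samples].mean(axis=1)


def detect_orphans(matrix, samples=None, **detection) -> set:
    """IsomiR labels whose parent's canonical form fails the detection rule.

    A parent whose canonical label is absent from the matrix altogether also
    orphans its isomiRs (reported with a warning: the annotation may simply
    not include the canonical form).
    """
    det = matrix.detected(samples=samples, **detection)
    detected_labels = set(det.index[det])
    orphans = set()
    missing_parents = set()
    for label in det.index[det]:
        ident = parse_label(label)
        if ident.is_canonical:
            continue
        can = canonical_label(ident.mature_name)
        if can not in det.index:
            missing_parents.add(ident.mature_name)
            orphans.add(label)
        elif can not in detected_labels:
            orphans.add(label)
    if missing_parents:
        warnings.warn(
            "canonical form absent from the matrix for: "
            + ", ".join(sorted(missing_parents)),
            stacklevel=2,
        )
    return orphans


def compute_ratios(means: pd.Series, orphans=frozenset(), detected=None) -> pd.DataFrame:
    """Per-isomiR ratio table over one cohort's mean RPM.

    ``detected`` (optional) restricts both isomiRs and canonical forms to
    labels passing the detection rule.  Orphan isomiRs and isomiRs whose
    canonical mean is zero are excluded (ratio undefined).  Ratios are kept at
    full precision; round on report.
    """
    if detected is not None:
        means = means[means.index.isin(set(detected))]
    rows = []
    index = set(means.index)
    for label, value in means.items():
        if label in orphans:
            continue
        ident = parse_label(label)
        if ident.is_canonical:
            continue
        can = canonical_label(ident.mature_name)
        if can not in index:
            continue
        can_mean = float(means[can])
        if can_mean <= 0:
            continue
        rows.append(
            {
                "label": label,
                "isomir_mean": float(value),
                "canonical_mean": can_mean,
                "ratio": float(value) / can_mean,
            }
        )
    out = pd.DataFrame(rows, columns=["label", "isomir_mean", "canonical_mean", "ratio"])
    return out.sort_values("ratio", ascending=False).reset_index(drop=True)


def filter_ratio_table(
    records: pd.DataFrame, min_isomir_mean: float = 20.0, min_ratio: float = 1.0
) -> pd.DataFrame:
    """Keep records with isomir_mean > min_isomir_mean and ratio > min_ratio
    (both strict)."""
    mask = (records["isomir_mean"] > min_isomir_mean) & (records["ratio"] > min_ratio)
    return records[mask].reset_index(drop=True)


@dataclass
class MatureMiRNACensus:
    """Counts of canonical/isomiR forms detected in one cohort.

    ``category_counts`` keys are the five simple classes; ``mixed_counts`` maps
    a sorted tuple of deviations to its count.  Percentages are computed over
    each block (all mature forms; classified isomiRs).
    """

    n_canonical_with_isomir: int
    n_canonical_without_isomir: int
    n_isomir_with_canonical: int
    n_orphan_isomir: int
    category_counts: dict = field(default_factory=dict)
    mixed_counts: dict = field(default_factory=dict)
    isomirs_per_parent: dict = field(default_factory=dict)

    @property
    def n_canonical(self) -> int:
        return self.n_canonical_with_isomir + self.n_canonical_without_isomir

    @property
    def n_isomir(self) -> int:
        return self.n_isomir_with_canonical + self.n_orphan_isomir

    @property
    def n_mature(self) -> int:
        return self.n_canonical + self.n_isomir

    @property
    def n_mixed(self) -> int:
        return sum(self.mixed_counts.values())

    @property
    def n_classified(self) -> int:
        """Total classified isomiRs (simple categories + mixed)."""
        return sum(self.category_counts.values()) + self.n_mixed

    def category_percent(self, category: str, decimals: int = 1) -> float:
        """Share of one class among classified isomiRs, in percent."""
        if category == "mixed":
            n = self.n_mixed
        else:
            n = self.category_counts.get(category, 0)
        return round(100.0 * n / self.n_classified, decimals)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("canonical miRNA with isomiR(s)", self.n_canonical_with_isomir),
            ("canonical miRNA without isomiR", self.n_canonical_without_isomir),
            ("isomiR with canonical miRNA", self.n_isomir_with_canonical),
            ("orphan isomiR", self.n_orphan_isomir),
            ("total mature miRNAs", self.n_mature),
        ]
        for cat in ("end-site", "start-site", "shifted", "3p-nta", "5p-nta"):
            if self.category_counts.get(cat):
                rows.append((cat, self.category_counts[cat]))
        for detail, n in sorted(self.mixed_counts.items()):
            rows.append(("mixed: " + " + ".join(detail), n))
        return pd.DataFrame(rows, columns=["group", "count"])


def census(matrix, samples=None, **detection) -> MatureMiRNACensus:
    """Census of the detected mature-miRNA content of a cohort."""
    det = matrix.detected(samples=samples, **detection)
    detected_labels = [label for label in det.index if det[label]]
    canonical_parents = set()
    isomirs = []
    for label in detected_labels:
        ident = parse_label(label)
        if ident.is_canonical:
            canonical_parents.add(ident.mature_name)
        else:
            isomirs.append(ident)
    parents_with_isomir = {i.mature_name for i in isomirs} & canonical_parents
    category_counts: dict[str, int] = {}
    mixed_counts: dict[tuple, int] = {}
    isomirs_per_parent: dict[str, int] = {}
    n_with_canonical = 0
    n_orphan = 0
    for ident in isomirs:
        if ident.mature_name in canonical_parents:
            n_with_canonical += 1
            isomirs_per_parent[ident.mature_name] = (
                isomirs_per_parent.get(ident.mature_name, 0) + 1
            )
            cat = classify(ident)
            if cat.category == "mixed":
                key = tuple(sorted(cat.mixed_detail))
                mixed_counts[key] = mixed_counts.get(key, 0) + 1
            else:
                category_counts[cat.category] = category_counts.get(cat.category, 0) + 1
        else:
            n_orphan += 1
    return MatureMiRNACensus(
        n_canonical_with_isomir=len(parents_with_isomir),
        n_canonical_without_isomir=len(canonical_parents - parents_with_isomir),
        n_isomir_with_canonical=n_with_canonical,
        n_orphan_isomir=n_orphan,
        category_counts=category_counts,
        mixed_counts=mixed_counts,
        isomirs_per_parent=isomirs_per_parent,
    )
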