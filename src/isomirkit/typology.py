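"""Candidate selection and the four-class trend x abundance typology.

Candidate miRNAs are those with at least one isoform that is both
differentially expressed between the two groups and more expressed than the
canonical form (the same isoform must satisfy both).  Each candidate is then
placed in a 2x2 typology:

    class a: similar trend,  similar relative abundance
    class b: similar trend,  different relative abundance
    class c: opposite trend, similar relative abundance
    class d: opposite trend, different relative abundance

Trend concordance asks whether the significantly changed mature forms of the
miRNA all move in the same direction.  Relative-abundance concordance asks
whether the most-expressed mature form (arg-max of group-mean RPM) is the same
in both groups — the decidable surrogate for comparing whole within-miRNA
abundance distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .nomenclature import parent_of, parse_label

__all__ = [
    "CandidateSet",
    "TypologyRecord",
    "select_candidates",
    "trend_concordance",
    "abundance_concordance",
    "assign_class",
    "build_typology",
]

_CLASS_MAP = {
    ("similar", "similar"): "a",
    ("similar", "different"): "b",
    ("opposite", "similar"): "c",
    ("opposite", "different"): "d",
}


@dataclass(frozen=True)
class CandidateSet:
    qualifying_isomirs: frozenset
    mirnas: frozenset


def select_candidates(de_labels, ratio_labels) -> CandidateSet:
    """Intersect significant isomiR labels with ratio>1 isomiR labels.

    ``de_labels`` may include canonical forms; only isomiR labels qualify.
    Candidate miRNAs are the distinct parents of the qualifying isomiRs.
    """
    de_isomirs = {l for l in de_labels if not parse_label(l).is_canonical}
    qualifying = frozenset(de_isomirs & set(ratio_labels))
    return CandidateSet(qualifying, frozenset(parent_of(l) for l in qualifying))


def trend_concordance(
    de_records: pd.DataFrame,
    mirna: str,
    form_trends: dict | None = None,
    flat_discordant: bool = False,
) -> str:
    """"similar" if the changed mature forms of ``mirna`` agree in direction.

    Default rule: all significant mature forms (canonical and isomiRs) in
    ``de_records`` share one regulation sign; a single significant form is
    similar by definition.  ``form_trends`` overrides the evidence with an
    explicit per-label mapping to {"up", "down", "flat"} (e.g. encoded from
    per-form plots); with ``flat_discordant`` a flat form alongside a changed
    one counts as an opposite trend.
    """
    if form_trends is not None:
        trends = {t for label, t in form_trends.items() if parent_of(label) == mirna}
        changed = trends - {"flat"}
        if not changed:
            raise ValueError(f"{mirna}: no changed mature form in form_trends")
        if len(changed) > 1:
            return "opposite"
        if flat_discordant and "flat" in trends:
            return "opposite"
        return "similar"
    labels = [l for l in de_records.index if parent_of(l) == mirna]
    if not labels:
        raise ValueError(f"{mirna}: no significant mature form")
    signs = set(de_records.loc[labels, "regulation"])
    return "similar" if len(signs) == 1 else "opposite"


def abundance_concordance(means_a: pd.Series, means_b: pd.Series, mirna: str):
    """Compare the top-expressed mature form of ``mirna`` between groups.

    Returns ``(verdict, top_a, top_b)``; ties are broken lexicographically
    with a warning.  A group in which no mature form of the miRNA is expressed
    is an error.
    """
    tops = []
    for means, tag in ((means_a, "a"), (means_b, "b")):
        forms = means[[l for l in means.index if parent_of(l) == mirna]]
        forms = forms[forms > 0]
        if forms.empty:
            raise ValueError(f"{mirna}: not detected in group {tag}")
        peak = forms.max()
        winners = sorted(forms.index[forms == peak])
        if len(winners) > 1:
            warnings.warn(
                f"{mirna}: tie for top form in group {tag} ({winners}); "
                "lexicographic winner used",
                stacklevel=2,
            )
        tops.append(winners[0])
    verdict = "similar" if tops[0] == tops[1] else "different"
    return verdict, tops[0], tops[1]


def assign_class(trend: str, abundance: str) -> str:
    """Map (trend, abundance) concordance to class a/b/c/d."""
    try:
        return _CLASS_MAP[(trend, abundance)]
    except KeyError:
        raise ValueError(f"invalid concordance pair ({trend!r}, {abundance!r})") from None


@dataclass(frozen=True)
class TypologyRecord:
    mirna: str
    class_label: str
    trend: str
    abundance: str
    top_form_group_a: str
    top_form_group_b: str
    de_isoform_signs: tuple = ()


def build_typology(
    de_significant: pd.DataFrame,
    ratio_table: pd.DataFrame,
    means_a: pd.Series,
    means_b: pd.Series,
    min_ratio: float = 1.0,
    form_trends: dict | None = None,
    flat_discordant: bool = False,
) -> pd.DataFrame:
    """Full typology pipeline: candidates, concordances, class per miRNA."""
    ratio_labels = set(ratio_table.loc[ratio_table["ratio"] > min_ratio, "label"])
    cand = select_candidates(list(de_significant.index), ratio_labels)
    rows = []
    for mirna in sorted(cand.mirnas):
        trend = trend_concordance(
            de_significant, mirna, form_trends=form_trends, flat_discordant=flat_discordant
        )
        abundance, top_a, top_b = abundance_concordance(means_a, means_b, mirna)
        signs = tuple(
            (l, de_significant.loc[l, "regulation"])
            for l in de_significant.index
            if parent_of(l) == mirna
        )
        rows.append(
            {
                "mirna": mirna,
                "class": assign_class(trend, abundance),
                "trend": trend,
                "abundance": abundance,
                "top_form_a": top_a,
                "top_form_b": top_b,
                "de_isoform_signs": signs,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "class",
            "trend",
            "abundance",
            "top_form_a",
            "top_form_b",
            "de_isoform_signs",
        ],
    ).set_index("mirna")
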