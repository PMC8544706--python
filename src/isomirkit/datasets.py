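"""Bundled worked-example tables from published melanoma small-RNA cohorts.

Four fixed inputs ship with the package, transcribed from cohort-level
summary tables of formalin-fixed (FFPE) benign nevus vs. early-stage cutaneous
melanoma sequencing and of TCGA skin cutaneous melanoma:

* ``ffpe_isomir_ratios`` — isomiR / canonical expression ratios (mean RPM over
  20 melanomas) for the 39 isomiRs with ratio > 1 and mean expression > 20;
* ``ffpe_de_mature_mirnas`` — the 55 mature miRNAs differentially expressed
  between melanoma and nevi (moderated t, BH-adjusted p, log2 fold change);
* ``ffpe_census_counts`` — the mature-miRNA census of the FFPE cohort;
* ``tcga_mutation_isomirs`` — label / sequence / class triples (with test
  statistics) for mature miRNAs associated with NF1, BRAF and NRAS mutation
  status, used here as golden inputs for the labeling algebra;
* ``ffpe_abundance_statements`` / ``ffpe_form_trends`` — the per-miRNA top
  expressed form per group and per-form expression trends, as stated for the
  ten candidate miRNAs, encoded for the typology stage.

These are inputs for worked examples and regression tests, not outputs of
this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "ffpe_isomir_ratios",
    "ffpe_de_mature_mirnas",
    "ffpe_census_counts",
    "ffpe_census",
    "tcga_mutation_isomirs",
    "ffpe_top_forms",
    "ffpe_form_trends",
    "ffpe_de_significant",
]


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files("isomirkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", **kw)


def ffpe_isomir_ratios() -> pd.DataFrame:
    """39 isomiRs with mean RPM > 20 and isomiR/canonical ratio > 1."""
    return _read("ffpe_isomir_ratios.tsv")


def ffpe_de_mature_mirnas() -> pd.DataFrame:
    """55 differentially expressed mature miRNAs (melanoma vs. nevi)."""
    return _read("ffpe_de_mature_mirnas.tsv")


def ffpe_de_significant(alpha: float = 0.05) -> pd.DataFrame:
    """Rows of the DE table passing ``p_adj < alpha`` at printed precision.

    The table prints adjusted p-values with two significant digits; a row
    whose printed value rounds to exactly ``alpha`` may sit on either side of
    it, so it is retained (its unrounded value is consistent with being
    below the gate).
    """
    de = ffpe_de_mature_mirnas()
    printed_ulp = 10.0 ** (pd.Series(de["p_adj"]).apply(
        lambda p: int(f"{p:e}".split("e")[1]) - 1
    ))
    keep = (de["p_adj"] < alpha) | ((de["p_adj"] - alpha).abs() <= printed_ulp / 2)
    return de[keep].reset_index(drop=True)


def ffpe_census_counts() -> pd.Series:
    """Raw census counts keyed by block / category."""
    df = _read("ffpe_census_counts.tsv")
    return df.set_index("key")["count"]


def ffpe_census():
    """The FFPE cohort census as a :class:`~isomirkit.expression.MatureMiRNACensus`."""
    from .expression import MatureMiRNACensus

    c = ffpe_census_counts()
    category = {
        k: int(c[k]) for k in ("end-site", "start-site", "shifted", "3p-nta") if k in c
    }
    mixed = {}
    for key, n in c.items():
        if key.startswith("mixed:"):
            detail = tuple(sorted(key.split(":", 1)[1].split("+")))
            mixed[detail] = int(n)
    return MatureMiRNACensus(
        n_canonical_with_isomir=int(c["canonical_with_isomir"]),
        n_canonical_without_isomir=int(c["canonical_without_isomir"]),
        n_isomir_with_canonical=int(c["isomir_with_canonical"]),
        n_orphan_isomir=int(c["orphan_isomir"]),
        category_counts=category,
        mixed_counts=mixed,
    )


def tcga_mutation_isomirs(contrast: str | None = None) -> pd.DataFrame:
    """Golden label/sequence/class triples from the mutation contrasts."""
    df = _read("tcga_mutation_isomirs.tsv")
    if contrast is not None:
        df = df[df["contrast"] == contrast].reset_index(drop=True)
    return df


def ffpe_top_forms() -> pd.DataFrame:
    """Most-expressed mature form per candidate miRNA, per group."""
    return _read("ffpe_abundance_statements.tsv").set_index("mirna")


def ffpe_form_trends() -> dict:
    """Per-form expression trends (up/down/flat) for the candidate miRNAs."""
    df = _read("ffpe_form_trends.tsv")
    return dict(zip(df["label"], df["trend"]))
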