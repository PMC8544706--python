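"""Synthetic hairpin references and two-group small-RNA cohorts with truth.

The generator emulates the data model every pipeline stage consumes: random
hairpins carry mature arms; each arm expresses a mixture of isoforms whose
default shares reflect what small RNA-seq of tissue typically shows — the
canonical form holding a minority share, end-site variants (+/-1, +/-2)
dominating, a substantial uridylated fraction, and small start-site and
shifted fractions.  Parent abundances are log-normal across miRNAs; per-sample
biological variability multiplies each parent by a log-normal factor.  Group
effects are applied to isoform proportions on the log2 scale and renormalised,
so RPM semantics stay exact under multinomial read sampling.

Reads are emitted error-free by default (the quantification contract is exact
matching); an optional substitution rate exists to exercise the unmatched-read
tally.  Everything is deterministic given the design seed.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import IsomirIdentity, classify, infer_identity, render_label, render_sequence
from .reference import EnumerationBounds, HairpinRecord, MatureArm
from .quantify import ExpressionMatrix

__all__ = [
    "SimulationDesign",
    "SimulatedCohort",
    "simulate_reference",
    "build_isoform_profile",
    "simulate_cohort",
    "write_cohort",
    "plant_typology_design",
    "end_to_end_recovery",
]

# Default within-arm isoform shares; invalid candidates (e.g. a uridylation
# that coincides with the template) are dropped and the rest renormalised.
DEFAULT_ISOFORM_SHARES = {
    (0, 0, ""): 0.30,          # canonical
    (0, -1, ""): 0.20,         # dominant end-site trimming
    (0, 1, ""): 0.10,
    (0, -2, ""): 0.10,
    (0, 2, ""): 0.06,
    (0, 0, "T"): 0.09,         # 3' uridylation
    (0, -1, "T"): 0.06,
    (1, 0, ""): 0.04,          # start-site
    (-1, 0, ""): 0.02,
    (1, 1, ""): 0.02,          # shifted
    (-1, -1, ""): 0.01,
}


@dataclass(frozen=True)
class SimulationDesign:
    """Study design for a two-group synthetic cohort.

    ``de_spec`` lists ``(label, log2_effect)`` pairs: group A's proportion of
    that identity is scaled by 2**effect (then renormalised); group B keeps
    the base proportions.  ``mutation_spec`` maps a gene name to
    ``(mutant_fraction, [(label, log2_effect), ...])``; mutant samples get the
    extra effects on top of their group profile.
    """

    seed: int
    n_hairpins: int = 10
    arms_per_hairpin: int = 1
    n_samples_a: int = 10
    n_samples_b: int = 10
    reads_per_sample: int = 100_000
    hairpin_len_range: tuple = (60, 110)
    arm_len_range: tuple = (20, 23)
    abundance_mu: float = 5.0
    abundance_sigma: float = 1.5
    within_sample_sigma: float = 0.4
    isoform_shares: dict = field(default_factory=lambda: dict(DEFAULT_ISOFORM_SHARES))
    isoform_share_overrides: dict = field(default_factory=dict)
    de_spec: tuple = ()
    orphan_fraction: float = 0.0
    mutation_spec: dict = field(default_factory=dict)
    error_rate: float = 0.0

    def __post_init__(self):
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be > 0")
        if self.arms_per_hairpin not in (1, 2):
            raise ValueError("arms_per_hairpin must be 1 or 2")
        total = sum(self.isoform_shares.values())
        if any(v < 0 for v in self.isoform_shares.values()) or not math.isclose(
            total, 1.0, rel_tol=1e-9
        ):
            raise ValueError("isoform shares must be >= 0 and sum to 1")


def _rng(design: SimulationDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([design.seed, stream]))


_BASES = np.array(list("ACGT"))


def simulate_reference(design: SimulationDesign) -> list[HairpinRecord]:
    """Random hairpins (uniform base composition) with non-overlapping arms."""
    rng = _rng(design, 0)
    records = []
    lo, hi = design.hairpin_len_range
    alo, ahi = design.arm_len_range
    for h in range(design.n_hairpins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_BASES, size=length))
        arm_lens = [int(rng.integers(alo, ahi + 1)) for _ in range(design.arms_per_hairpin)]
        if design.arms_per_hairpin == 1:
            max_start = length - arm_lens[0]
            if max_start < 0:
                raise ValueError("hairpin too short for its arm")
            start = int(rng.integers(0, max_start + 1))
            arms = [MatureArm(f"syn-miR-{h + 1}-5p", start, start + arm_lens[0])]
        else:
            # 5p arm in the left half, 3p arm in the right half, with a gap
            gap = 4
            if arm_lens[0] + arm_lens[1] + gap > length:
                raise ValueError("hairpin too short for two arms")
            s1 = int(rng.integers(0, length - arm_lens[0] - arm_lens[1] - gap + 1))
            s2 = int(
                rng.integers(s1 + arm_lens[0] + gap, length - arm_lens[1] + 1)
            )
            arms = [
                MatureArm(f"syn-miR-{h + 1}-5p", s1, s1 + arm_lens[0]),
                MatureArm(f"syn-miR-{h + 1}-3p", s2, s2 + arm_lens[1]),
            ]
        records.append(HairpinRecord(f"syn-hairpin-{h + 1}", seq, tuple(arms)))
    return records


def build_isoform_profile(
    record: HairpinRecord,
    arm: MatureArm,
    shares: dict,
    bounds: EnumerationBounds | None = None,
) -> dict:
    """Map identity label -> within-arm share, keeping only valid identities.

    A candidate is valid when rendering its sequence and re-inferring the
    identity round-trips (this silently drops e.g. a uridylation whose first
    base matches the template, which the lookup would read as a templated
    extension).  Shares are renormalised over the survivors.
    """
    bounds = bounds or EnumerationBounds()
    profile = {}
    for (a, b, nta3), share in shares.items():
        if share <= 0:
            continue
        ident = IsomirIdentity(arm.mature_name, a, b, nta3)
        try:
            seq = render_sequence(ident, record)
        except ValueError:
            continue
        if not (bounds.min_len <= len(seq) <= bounds.max_len):
            continue
        if infer_identity(seq, record, arm, bounds) != ident:
            continue
        profile[render_label(ident)] = share
    if not profile:
        raise ValueError(f"no valid isoform for arm {arm.mature_name}")
    total = sum(profile.values())
    return {k: v / total for k, v in profile.items()}


def _apply_effects(props: pd.Series, effects) -> pd.Series:
    scaled = props.copy()
    for label, lfc in effects:
        if label not in scaled.index:
            raise ValueError(f"de_spec references unknown identity {label!r}")
        scaled[label] = scaled[label] * 2.0**lfc
    return scaled / scaled.sum()


@dataclass
class SimulatedCohort:
    """A simulated two-group cohort plus its ground truth."""

    reference: list
    design: SimulationDesign
    samples: pd.DataFrame           # sample_id, group, <gene>_status...
    counts: pd.DataFrame            # identity label x sample read counts
    proportions: pd.DataFrame       # truth: expected proportion per group
    truth: pd.DataFrame             # label, group means, log2 effect, category
    sequences: dict                 # identity label -> read sequence (DNA)

    def expression_matrix(self) -> ExpressionMatrix:
        """Exact-count expression matrix (bypasses FASTQ rendering/matching)."""
        n = self.counts.sum(axis=0).astype(int)
        return ExpressionMatrix(
            counts=self.counts.astype(float),
            matched=n,
            filtered=n,
            unmatched=pd.Series(0, index=self.counts.columns, dtype=int),
        )

    def samples_of(self, group: str) -> list[str]:
        return list(self.samples.loc[self.samples["group"] == group, "sample_id"])


def simulate_cohort(
    reference: list, design: SimulationDesign, bounds: EnumerationBounds | None = None
) -> SimulatedCohort:
    """Draw a two-group cohort of read counts from the design's proportions."""
    bounds = bounds or EnumerationBounds()
    rng = _rng(design, 1)

    arms = [(rec, arm) for rec in reference for arm in rec.arms]
    parent_weight = {}
    base = {}
    sequences = {}
    parent_names = [arm.mature_name for _, arm in arms]
    n_orphans = int(round(design.orphan_fraction * len(arms)))
    orphan_parents = set(
        rng.choice(np.array(parent_names, dtype=object), size=n_orphans, replace=False)
    ) if n_orphans else set()
    for rec, arm in arms:
        weight = float(rng.lognormal(design.abundance_mu, design.abundance_sigma))
        shares = design.isoform_share_overrides.get(arm.mature_name, design.isoform_shares)
        profile = build_isoform_profile(rec, arm, shares, bounds)
        if arm.mature_name in orphan_parents:
            can = f"{arm.mature_name}|0|0"
            profile.pop(can, None)
            total = sum(profile.values())
            profile = {k: v / total for k, v in profile.items()}
        parent_weight[arm.mature_name] = weight
        for label, share in profile.items():
            base[label] = weight * share
            ident = _ident_for(label, arm)
            sequences[label] = render_sequence(ident, rec)
    base = pd.Series(base).sort_index()
    base = base / base.sum()

    props_b = base
    props_a = _apply_effects(base, design.de_spec)
    proportions = pd.DataFrame({"A": props_a, "B": props_b})

    sample_rows = []
    count_cols = {}
    parents = pd.Index([l.split("|", 1)[0] for l in base.index])
    mutation_status: dict[str, np.ndarray] = {}
    n_total = design.n_samples_a + design.n_samples_b
    for gene, (frac, _effects) in design.mutation_spec.items():
        mutation_status[gene] = rng.random(n_total) < frac
    idx = 0
    for group, n_samples in (("A", design.n_samples_a), ("B", design.n_samples_b)):
        for i in range(n_samples):
            sample_id = f"{group}{i + 1}"
            props = proportions[group]
            for gene, (_frac, effects) in design.mutation_spec.items():
                if mutation_status[gene][idx]:
                    props = _apply_effects(props, effects)
            # per-sample biological noise at the parent level
            factors = pd.Series(
                np.exp(rng.normal(0.0, design.within_sample_sigma, size=len(parent_weight))),
                index=sorted(parent_weight),
            )
            noisy = props.to_numpy() * factors.reindex(parents).to_numpy()
            noisy = noisy / noisy.sum()
            draws = rng.multinomial(design.reads_per_sample, noisy)
            count_cols[sample_id] = draws
            row = {"sample_id": sample_id, "group": group}
            for gene in design.mutation_spec:
                row[f"{gene.lower()}_status"] = (
                    "mut" if mutation_status[gene][idx] else "wt"
                )
            sample_rows.append(row)
            idx += 1

    counts = pd.DataFrame(count_cols, index=base.index)
    truth = pd.DataFrame(
        {
            "label": base.index,
            "proportion_a": props_a.to_numpy(),
            "proportion_b": props_b.to_numpy(),
            "log2_effect": np.log2(props_a.to_numpy() / props_b.to_numpy()),
            "category": [_category_of(l) for l in base.index],
        }
    ).set_index("label")
    return SimulatedCohort(
        reference=reference,
        design=design,
        samples=pd.DataFrame(sample_rows),
        counts=counts,
        proportions=proportions,
        truth=truth,
        sequences=sequences,
    )


def _ident_for(label: str, arm: MatureArm) -> IsomirIdentity:
    from .nomenclature import parse_label

    return parse_label(label)


def _category_of(label: str) -> str:
    from .nomenclature import parse_label

    return classify(parse_label(label)).describe()


def write_cohort(cohort: SimulatedCohort, outdir, gzip_fastq: bool = False) -> dict:
    """Write hairpins.fa, arms.tsv, per-sample FASTQ, samplesheet.tsv, truth.tsv.

    Reads are rendered from the drawn identity counts; with a non-zero design
    error rate, random substitutions are applied (such reads generally fall
    out of the exact-match space and surface in the unmatched tally).
    Returns the path map.  Deterministic given the design seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sampledir = outdir / "samples"
    sampledir.mkdir(exist_ok=True)
    design = cohort.design
    rng = _rng(design, 2)

    fasta = outdir / "hairpins.fa"
    with open(fasta, "w") as fh:
        for rec in cohort.reference:
            fh.write(f">{rec.hairpin_id}\n{rec.sequence}\n")
    arms_tsv = outdir / "arms.tsv"
    with open(arms_tsv, "w") as fh:
        fh.write("hairpin_id\tmature_name\tstart\tend\n")
        for rec in cohort.reference:
            for arm in rec.arms:
                fh.write(f"{rec.hairpin_id}\t{arm.mature_name}\t{arm.start}\t{arm.end}\n")

    fastq_paths = {}
    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    for sample_id in cohort.counts.columns:
        path = sampledir / f"{sample_id}{suffix}"
        opener = gzip.open if gzip_fastq else open
        with opener(path, "wt") as fh:
            read_no = 0
            for label, n in cohort.counts[sample_id].items():
                seq = cohort.sequences[label]
                for _ in range(int(n)):
                    read_no += 1
                    out_seq = seq
                    if design.error_rate > 0 and rng.random() < design.error_rate:
                        pos = int(rng.integers(0, len(seq)))
                        alt = rng.choice([b for b in "ACGT" if b != seq[pos]])
                        out_seq = seq[:pos] + alt + seq[pos + 1 :]
                    fh.write(
                        f"@{sample_id}_{read_no}\n{out_seq}\n+\n{'I' * len(out_seq)}\n"
                    )
        fastq_paths[sample_id] = path

    sheet = cohort.samples.copy()
    sheet.insert(1, "fastq_path", [str(fastq_paths[s]) for s in sheet["sample_id"]])
    sheet_path = outdir / "samplesheet.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)
    truth_path = outdir / "truth.tsv"
    cohort.truth.to_csv(truth_path, sep="\t")
    return {
        "hairpins": fasta,
        "arms": arms_tsv,
        "samplesheet": sheet_path,
        "truth": truth_path,
        "fastq": fastq_paths,
    }


# Within-arm shares used when planting typology classes: the dominant
# end-site isomiR out-expresses the canonical form (ratio 2), as the ratio
# analysis requires of candidate miRNAs.
CANDIDATE_ISOFORM_SHARES = {
    (0, 0, ""): 0.20,
    (0, -1, ""): 0.40,
    (0, 1, ""): 0.10,
    (0, -2, ""): 0.10,
    (0, 0, "T"): 0.10,
    (1, 0, ""): 0.05,
    (0, 2, ""): 0.05,
}


def plant_typology_design(
    base: SimulationDesign,
    min_parent_share: float = 0.005,
    max_parent_share: float = 0.05,
):
    """Derive a design planting one miRNA per typology class (a, b, c, d).

    Four parents holding a minor share of the library (so that compositional
    renormalisation barely perturbs the planted effects) get the candidate
    isoform profile; the effects are then:

    * class a — every form scaled up 4x (same trend, top form unchanged);
    * class b — as a, plus an extra boost to a minor isoform so it overtakes
      the dominant form in group A only (different top form);
    * class c — one minor isoform up, another down, neither overtaking
      (opposite trend, same top form);
    * class d — one isoform up far enough to overtake, another down
      (opposite trend, different top form).

    Returns ``(design, expected)`` where ``expected`` maps each planted
    parent to its designed class.
    """
    reference = simulate_reference(base)
    probe = simulate_cohort(reference, base)
    shares = probe.truth["proportion_b"].groupby(lambda l: l.split("|")[0]).sum()
    ordered = shares.sort_values().index
    eligible = [p for p in ordered if min_parent_share <= shares[p] <= max_parent_share]
    if len(eligible) < 4:
        # fall back to the smallest parents above a depth floor so planting
        # still works on unlucky abundance draws
        floor = 10.0 / max(base.reads_per_sample, 1)
        eligible = [p for p in ordered if shares[p] >= floor][:4]
    if len(eligible) < 4:
        raise ValueError("reference has fewer than 4 usable parents to plant on")
    pa, pb, pc, pd_ = eligible[:4]
    overrides = {p: dict(CANDIDATE_ISOFORM_SHARES) for p in (pa, pb, pc, pd_)}
    design_base = replace(base, isoform_share_overrides=overrides)
    cohort0 = simulate_cohort(reference, design_base)
    forms = {
        p: [l for l in cohort0.truth.index if l.split("|", 1)[0] == p]
        for p in (pa, pb, pc, pd_)
    }
    de_spec = [(l, 2.0) for l in forms[pa]]
    de_spec += [(l, 4.8 if l.endswith("|0|+1") else 2.0) for l in forms[pb]]
    de_spec += [(f"{pc}|0|+1", 1.8), (f"{pc}|0|-2", -2.0)]
    de_spec += [(f"{pd_}|0|+1", 2.5), (f"{pd_}|0|-2", -2.0)]
    design = replace(design_base, de_spec=tuple(de_spec))
    return design, {pa: "a", pb: "b", pc: "c", pd_: "d"}


def end_to_end_recovery(
    design: SimulationDesign,
    workdir=None,
    bounds: EnumerationBounds | None = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    true_effect_threshold: float = 1.0,
) -> dict:
    """Simulate, quantify, test and classify; report recovery against truth.

    When ``workdir`` is given the cohort is written as FASTQ and re-quantified
    through the exact-match path; otherwise the drawn counts are used
    directly.  The report carries: the per-category census agreement with the
    design, the largest absolute error of estimated within-cohort isoform
    proportions, the power and empirical FDR of the differential stage
    (truth = |log2 effect| >= ``true_effect_threshold``), and the typology
    table with the top forms it is based on.
    """
    from . import differential, expression, typology
    from .reference import build_lookup
    from .quantify import quantify_cohort

    bounds = bounds or EnumerationBounds()
    reference = simulate_reference(design)
    cohort = simulate_cohort(reference, design, bounds)
    if workdir is not None:
        paths = write_cohort(cohort, workdir)
        lookup = build_lookup(reference, bounds)
        matrix, _tallies = quantify_cohort(
            {s: paths["fastq"][s] for s in cohort.counts.columns}, lookup
        )
    else:
        matrix = cohort.expression_matrix()

    samples_a = cohort.samples_of("A")
    samples_b = cohort.samples_of("B")
    means_a = expression.group_means(matrix, samples_a)
    means_b = expression.group_means(matrix, samples_b)

    # proportion recovery, against the pooled truth proportions
    est = matrix.rpm.mean(axis=1) / 1e6
    truth_mean = (
        design.n_samples_a * cohort.truth["proportion_a"]
        + design.n_samples_b * cohort.truth["proportion_b"]
    ) / (design.n_samples_a + design.n_samples_b)
    common = est.index.intersection(truth_mean.index)
    prop_err = (est[common] - truth_mean[common]).abs()

    # census vs designed categories
    cen = expression.census(matrix)
    truth_cats = cohort.truth["category"].value_counts().to_dict()

    de = differential.moderated_t(matrix, samples_a, samples_b)
    sig = differential.de_filter(
        de, differential.ContrastConfig(fc_threshold=fc_threshold, alpha=alpha)
    )
    truth_eff = cohort.truth["log2_effect"].reindex(de.index).fillna(0.0)
    is_true = truth_eff.abs() >= true_effect_threshold
    discoveries = set(sig.index)
    tp = sum(1 for l in discoveries if is_true.get(l, False))
    power = tp / max(1, int(is_true.sum()))
    fdr = (len(discoveries) - tp) / max(1, len(discoveries))

    ratios = expression.compute_ratios(means_a, orphans=expression.detect_orphans(matrix))
    typo = typology.build_typology(sig, ratios, means_a, means_b)

    return {
        "census": cen,
        "truth_category_counts": truth_cats,
        "max_abs_proportion_error": float(prop_err.max()) if len(prop_err) else float("nan"),
        "de_table": de,
        "significant": sig,
        "power": power,
        "empirical_fdr": fdr,
        "n_true_effects": int(is_true.sum()),
        "typology": typo,
        "matrix": matrix,
        "cohort": cohort,
    }
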