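"""Hairpin references, isomiR search-space enumeration, exact-match lookup.

A hairpin (pre-miRNA stem-loop) carries one or two annotated mature arms.  The
arm interval on the hairpin is the coordinate frame for every isomiR offset.
From each arm the full isomiR search space is enumerated: every templated
window within the configured 5'/3' shift bounds and length range, plus
non-templated-addition (NTA) variants whose template-adjacent base differs
from the hairpin (a base matching the hairpin is always read as a templated
extension).  The resulting exact-match lookup table maps each distinct
sequence to the complete set of identities that can produce it.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .nomenclature import IsomirIdentity, parse_label, render_label, to_dna, to_rna

__all__ = [
    "MatureArm",
    "HairpinRecord",
    "EnumerationBounds",
    "LookupTable",
    "load_reference",
    "enumerate_isomir_space",
    "build_lookup",
    "hairpin_from_isoforms",
]

_DNA = frozenset("ACGT")

MIN_HAIRPIN_LEN = 40
MIN_ARM_LEN, MAX_ARM_LEN = 18, 26


@dataclass(frozen=True)
class MatureArm:
    """A mature miRNA interval on its hairpin, 0-based half-open."""

    mature_name: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"{self.mature_name}: arm start {self.start} < 0")
        length = self.end - self.start
        if not (MIN_ARM_LEN <= length <= MAX_ARM_LEN):
            raise ValueError(
                f"{self.mature_name}: arm length {length} outside "
                f"[{MIN_ARM_LEN}, {MAX_ARM_LEN}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HairpinRecord:
    """A validated hairpin sequence (DNA internally) with its mature arms."""

    hairpin_id: str
    sequence: str
    arms: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "sequence", to_dna(self.sequence))
        object.__setattr__(self, "arms", tuple(self.arms))
        if len(self.sequence) < MIN_HAIRPIN_LEN:
            raise ValueError(
                f"{self.hairpin_id}: hairpin length {len(self.sequence)} < {MIN_HAIRPIN_LEN}"
            )
        if not set(self.sequence) <= _DNA:
            bad = sorted(set(self.sequence) - _DNA)
            raise ValueError(f"{self.hairpin_id}: non-ACGU/T characters {bad}")
        seen_intervals = []
        for arm in self.arms:
            if arm.end > len(self.sequence):
                raise ValueError(
                    f"arm out of bounds: {arm.mature_name} [{arm.start},{arm.end}) "
                    f"on hairpin {self.hairpin_id} of length {len(self.sequence)}"
                )
            for other in seen_intervals:
                if arm.start < other.end and other.start < arm.end:
                    raise ValueError(
                        f"{self.hairpin_id}: arms {other.mature_name} and "
                        f"{arm.mature_name} overlap"
                    )
            seen_intervals.append(arm)

    def arm(self, mature_name: str) -> MatureArm:
        for a in self.arms:
            if a.mature_name == mature_name:
                return a
        raise KeyError(f"no arm {mature_name!r} on hairpin {self.hairpin_id}")

    def canonical_sequence(self, mature_name: str) -> str:
        a = self.arm(mature_name)
        return self.sequence[a.start : a.end]


@dataclass(frozen=True)
class EnumerationBounds:
    """Limits of the enumerated isomiR space.

    Defaults cover every label observed in practice for this kind of data
    (|offset| up to 4, NTA up to 2 bases, U/A additions) with one unit of
    margin; all are configurable.  ``nta_alphabet`` accepts RNA or DNA letters.
    """

    max_start_shift: int = 5
    max_end_shift: int = 5
    min_len: int = 18
    max_len: int = 26
    max_nta_len: int = 3
    nta_alphabet: tuple = ("U", "A")
    allow_5p_nta: bool = False
    max_5p_nta_len: int = 2

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        for name in ("max_start_shift", "max_end_shift", "max_nta_len", "max_5p_nta_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(
            self, "nta_alphabet", tuple(sorted({to_dna(b) for b in self.nta_alphabet}))
        )
        if not set(self.nta_alphabet) <= _DNA:
            raise ValueError("nta_alphabet must be a subset of {A,C,G,U}")


def load_reference(hairpin_fasta, arm_table) -> list[HairpinRecord]:
    """Load hairpins (FASTA, id = first token) and arm annotations (TSV).

    The arm table needs columns ``hairpin_id  mature_name  start  end``
    (0-based half-open).  U and T are interchangeable in the FASTA.  Missing
    hairpins, out-of-bounds arms and duplicate mature names are hard errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(hairpin_fasta), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate hairpin id {rec.id!r} in FASTA")
        seqs[rec.id] = str(rec.seq)
    arms = pd.read_csv(arm_table, sep="\t", dtype={"hairpin_id": str, "mature_name": str})
    required = {"hairpin_id", "mature_name", "start", "end"}
    if not required <= set(arms.columns):
        raise ValueError(f"arm table must have columns {sorted(required)}")
    if arms["mature_name"].duplicated().any():
        dup = arms.loc[arms["mature_name"].duplicated(), "mature_name"].iloc[0]
        raise ValueError(f"duplicate mature_name {dup!r} in arm table")
    by_hairpin: dict[str, list[MatureArm]] = defaultdict(list)
    for row in arms.itertuples(index=False):
        if row.hairpin_id not in seqs:
            raise ValueError(
                f"arm {row.mature_name!r} references missing hairpin {row.hairpin_id!r}"
            )
        by_hairpin[row.hairpin_id].append(
            MatureArm(row.mature_name, int(row.start), int(row.end))
        )
    records = []
    for hid, seq in seqs.items():
        records.append(HairpinRecord(hid, seq, tuple(by_hairpin.get(hid, ()))))
    return records


def _nta_variants(base_seq, alphabet, max_nta, max_total):
    """All candidate NTA strings of length 1..max_nta fitting the length cap;
    the template-adjacency filter is applied by the caller."""
    room = max_total - len(base_seq)
    for k in range(1, min(max_nta, room) + 1):
        for tup in itertools.product(alphabet, repeat=k):
            yield "".join(tup)


def enumerate_isomir_space(record: HairpinRecord, bounds: EnumerationBounds) -> set:
    """Every (sequence, identity) pair reachable from the record's arms.

    Templated windows: 5' offset a and 3' offset b each within +/- the shift
    bounds, window inside the hairpin, window length within [min_len, max_len].
    For each window, 3' NTA variants append 1..max_nta_len bases from the NTA
    alphabet whose first base differs from the hairpin base following the
    window (when one exists), keeping total length <= max_len; 5' NTA variants
    are analogous at the 5' end when enabled.  NTAs at the two ends are not
    combined.
    """
    out = set()
    hp = record.sequence
    for arm in record.arms:
        for a in range(-bounds.max_start_shift, bounds.max_start_shift + 1):
            for b in range(-bounds.max_end_shift, bounds.max_end_shift + 1):
                lo, hi = arm.start + a, arm.end + b
                if lo < 0 or hi > len(hp):
                    continue
                if not (bounds.min_len <= hi - lo <= bounds.max_len):
                    continue
                window = hp[lo:hi]
                out.add((window, IsomirIdentity(arm.mature_name, a, b)))
                nxt = hp[hi] if hi < len(hp) else None
                for nta in _nta_variants(
                    window, bounds.nta_alphabet, bounds.max_nta_len, bounds.max_len
                ):
                    if nxt is not None and nta[0] == nxt:
                        continue
                    out.add((window + nta, IsomirIdentity(arm.mature_name, a, b, nta3=nta)))
                if bounds.allow_5p_nta:
                    prev = hp[lo - 1] if lo > 0 else None
                    for nta in _nta_variants(
                        window, bounds.nta_alphabet, bounds.max_5p_nta_len, bounds.max_len
                    ):
                        if prev is not None and nta[-1] == prev:
                            continue
                        out.add(
                            (nta + window, IsomirIdentity(arm.mature_name, a, b, nta5=nta))
                        )
    return out


@dataclass
class LookupTable:
    """Exact map from read sequence (DNA) to the identities producing it.

    A sequence may map to identities from different miRNAs or different
    offsets on the same hairpin; the table holds all of them.  The table is a
    pure function of (records, bounds) and can always be rebuilt from those.
    """

    mapping: dict = field(default_factory=dict)
    bounds: EnumerationBounds = field(default_factory=EnumerationBounds)

    def get(self, sequence: str) -> frozenset:
        return self.mapping.get(to_dna(sequence), frozenset())

    def __contains__(self, sequence: str) -> bool:
        return to_dna(sequence) in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def identities(self) -> set:
        out = set()
        for ids in self.mapping.values():
            out |= ids
        return out

    def labels(self) -> list[str]:
        return sorted(render_label(i) for i in self.identities)

    def to_tsv(self, path) -> None:
        """Write ``sequence<TAB>label[;label...]`` (sequences rendered as RNA)."""
        with open(path, "w") as fh:
            fh.write("sequence\tidentities\n")
            for seq in sorted(self.mapping):
                labels = ";".join(sorted(render_label(i) for i in self.mapping[seq]))
                fh.write(f"{to_rna(seq)}\t{labels}\n")


def build_lookup(records, bounds: EnumerationBounds | None = None) -> LookupTable:
    """Build the exact-match lookup table over all records' isomiR spaces."""
    bounds = bounds or EnumerationBounds()
    acc: dict[str, set] = defaultdict(set)
    for record in records:
        for seq, ident in enumerate_isomir_space(record, bounds):
            acc[seq].add(ident)
    return LookupTable({seq: frozenset(ids) for seq, ids in acc.items()}, bounds)


def hairpin_from_isoforms(
    mature_name: str,
    labeled_sequences: dict,
    fill_priority: str = "CGAT",
    min_length: int = MIN_HAIRPIN_LEN,
) -> HairpinRecord:
    """Reconstruct a minimal synthetic hairpin consistent with labeled isoforms.

    Given observed (label, sequence) pairs of one mature miRNA, overlays their
    templated cores to recover the canonical arm and whatever flanking template
    the offsets imply, records the "must differ from template" constraints of
    every NTA, and fills unconstrained positions with a synthetic filler base.
    The result is a synthetic scaffold — sufficient for round-tripping the
    given isoforms, not a biological precursor sequence.

    Raises ``ValueError`` if the isoforms disagree on the canonical length or
    on any template base.
    """
    parsed = []
    canonical_lengths = set()
    for label, seq in labeled_sequences.items():
        ident = parse_label(label) if isinstance(label, str) else label
        if ident.mature_name != mature_name:
            raise ValueError(f"label {label} does not belong to {mature_name}")
        s = to_dna(seq)
        core_len = len(s) - len(ident.nta3) - len(ident.nta5)
        canonical_lengths.add(core_len + ident.start_offset - ident.end_offset)
        parsed.append((ident, s))
    if len(canonical_lengths) != 1:
        raise ValueError(
            f"{mature_name}: isoforms imply conflicting canonical lengths "
            f"{sorted(canonical_lengths)}"
        )
    arm_len = canonical_lengths.pop()
    left = max([0] + [-i.start_offset for i, _ in parsed])
    right = max([0] + [i.end_offset for i, _ in parsed])
    total = max(min_length, left + arm_len + right)
    template: list = [None] * total
    forbidden: dict[int, set] = defaultdict(set)
    for ident, seq in parsed:
        n5, n3 = len(ident.nta5), len(ident.nta3)
        core = seq[n5 : len(seq) - n3] if n3 else seq[n5:]
        pos0 = left + ident.start_offset
        for i, ch in enumerate(core):
            if template[pos0 + i] not in (None, ch):
                raise ValueError(
                    f"{mature_name}: isoforms disagree on template position {pos0 + i}"
                )
            template[pos0 + i] = ch
        if n3:
            forbidden[pos0 + len(core)].add(ident.nta3[0])
        if n5 and pos0 - 1 >= 0:
            forbidden[pos0 - 1].add(ident.nta5[-1])
    for pos, bad in forbidden.items():
        if pos < total and template[pos] in bad:
            raise ValueError(
                f"{mature_name}: NTA constraint violated at template position {pos}"
            )
    for pos in range(total):
        if template[pos] is None:
            template[pos] = next(c for c in fill_priority if c not in forbidden.get(pos, ()))
    return HairpinRecord(
        hairpin_id=f"{mature_name}-scaffold",
        sequence="".join(template),
        arms=(MatureArm(mature_name, left, left + arm_len),),
    )
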