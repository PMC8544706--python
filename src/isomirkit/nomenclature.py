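"""IsomiR identity algebra: labels, sequences, inference, classification.

An isomiR is described relative to its canonical mature miRNA by a 5' offset,
a 3' offset, and optional non-templated additions (NTA) at either end.  Offsets
follow the standard sign convention: 0 means the same terminus as the canonical
form; a positive value means the terminus is shifted toward the 3' end of the
hairpin, a negative value toward the 5' end.  So ``start_offset = +1`` trims one
base off the 5' end, ``end_offset = +1`` extends the 3' end by one templated
base, and ``start_offset = end_offset = -1`` slides the whole window one base
toward 5' ("shifted" isomiR).

Labels look like ``hsa-miR-203a-3p|+1|0(+1U)``: name, 5' offset, 3' offset,
then a parenthesised NTA suffix.  Homopolymeric NTAs collapse to ``(+2U)``;
heterogeneous NTAs are rendered base-by-base, e.g. ``(+UA)``.  A 5' NTA, for
which no established printed syntax exists, is rendered as a second suffix
``(5p+1U)`` / ``(5p+UA)``; this dialect round-trips through :func:`parse_label`.

Sequences are stored internally as DNA (``ACGT``); RNA input (``U``) is accepted
everywhere and user-facing renderings can use :func:`to_rna`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "IsomirIdentity",
    "IsomirCategory",
    "LabelError",
    "render_label",
    "parse_label",
    "render_sequence",
    "infer_identity",
    "classify",
    "to_dna",
    "to_rna",
    "parent_of",
    "canonical_label",
]

_DNA = frozenset("ACGT")


class LabelError(ValueError):
    """Malformed isomiR label; ``position`` is the index of the offending token."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def to_dna(seq: str) -> str:
    """Normalise a nucleotide string to uppercase DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render an internal DNA string as RNA (T -> U)."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True, order=True)
class IsomirIdentity:
    """One isomiR of one mature miRNA: (parent, 5' offset, 3' offset, NTAs).

    ``nta3``/``nta5`` are stored as DNA.  By construction their template-adjacent
    base must differ from the hairpin base it would otherwise copy (a base that
    matches the template is a templated extension, never an NTA).
    """

    mature_name: str
    start_offset: int = 0
    end_offset: int = 0
    nta3: str = ""
    nta5: str = ""

    def __post_init__(self):
        object.__setattr__(self, "nta3", to_dna(self.nta3))
        object.__setattr__(self, "nta5", to_dna(self.nta5))
        for nta in (self.nta3, self.nta5):
            if not set(nta) <= _DNA:
                raise ValueError(f"NTA string {nta!r} contains non-ACGU characters")

    @property
    def is_canonical(self) -> bool:
        return (
            self.start_offset == 0
            and self.end_offset == 0
            and not self.nta3
            and not self.nta5
        )

    @property
    def label(self) -> str:
        return render_label(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return render_label(self)


# --- label rendering -------------------------------------------------------


def _fmt_offset(n: int) -> str:
    return f"+{n}" if n > 0 else str(n)


def _fmt_nta(nta_dna: str) -> str:
    rna = to_rna(nta_dna)
    if len(set(rna)) == 1:
        return f"+{len(rna)}{rna[0]}"
    return "+" + rna


def render_label(identity: IsomirIdentity) -> str:
    """Render ``name|start|end`` plus NTA suffixes, ASCII signs throughout."""
    out = (
        f"{identity.mature_name}|{_fmt_offset(identity.start_offset)}"
        f"|{_fmt_offset(identity.end_offset)}"
    )
    if identity.nta3:
        out += f"({_fmt_nta(identity.nta3)})"
    if identity.nta5:
        out += f"(5p{_fmt_nta(identity.nta5)})"
    return out


_LABEL_RE = re.compile(
    r"^(?P<name>[^|()]+)\|(?P<start>[+-]?\d+)\|(?P<end>[+-]?\d+)(?P<rest>.*)$"
)
_SUFFIX_RE = re.compile(r"\((?P<fivep>5p)?\+(?:(?P<n>\d+)(?P<base>[ACGU])|(?P<seq>[ACGU]{1,}))\)")


def parse_label(label: str) -> IsomirIdentity:
    """Inverse of :func:`render_label`.

    Accepts the Unicode minus sign as printed in typography-heavy sources in
    addition to the ASCII hyphen.  Raises :class:`LabelError` pointing at the
    first offending token.
    """
    ascii_label = label.replace("−", "-").replace("’", "'")
    m = _LABEL_RE.match(ascii_label)
    if m is None:
        # locate the first structural problem for the error message
        bar = ascii_label.find("|")
        raise LabelError(f"malformed label {label!r}", bar if bar >= 0 else 0)
    name = m.group("name")
    start = int(m.group("start"))
    end = int(m.group("end"))
    nta3 = ""
    nta5 = ""
    pos = m.start("rest")
    rest = m.group("rest")
    while rest:
        sm = _SUFFIX_RE.match(rest)
        if sm is None:
            raise LabelError(f"malformed NTA suffix in {label!r}", pos)
        nta = sm.group("seq") or sm.group("base") * int(sm.group("n") or 0)
        if sm.group("fivep"):
            if nta5:
                raise LabelError(f"duplicate 5' NTA suffix in {label!r}", pos)
            nta5 = nta
        else:
            if nta3:
                raise LabelError(f"duplicate 3' NTA suffix in {label!r}", pos)
            nta3 = nta
        pos += sm.end()
        rest = rest[sm.end():]
    return IsomirIdentity(name, start, end, nta3, nta5)


def parent_of(label: str) -> str:
    """Parent mature-miRNA name of a label (text before the first ``|``)."""
    return label.split("|", 1)[0]


def canonical_label(mirna: str) -> str:
    return f"{mirna}|0|0"


# --- sequence rendering / inference ---------------------------------------


def render_sequence(identity: IsomirIdentity, record) -> str:
    """Reconstruct the isomiR sequence (DNA) from a hairpin record.

    The templated core is the hairpin substring
    ``[arm.start + start_offset, arm.end + end_offset)``; ``nta5`` is prepended
    and ``nta3`` appended.  Raises ``ValueError`` if the window leaves the
    hairpin or an NTA base coincides with the template (which would make it a
    templated extension instead).
    """
    arm = record.arm(identity.mature_name)
    seq = record.sequence
    lo = arm.start + identity.start_offset
    hi = arm.end + identity.end_offset
    if lo < 0 or hi > len(seq) or hi - lo < 1:
        raise ValueError(
            f"window [{lo},{hi}) of {identity.label} falls outside hairpin "
            f"{record.hairpin_id} (length {len(seq)})"
        )
    if identity.nta3 and hi < len(seq) and identity.nta3[0] == seq[hi]:
        raise ValueError(
            f"{identity.label}: first 3' NTA base equals the template base; "
            "this is a templated extension, not an NTA"
        )
    if identity.nta5 and lo > 0 and identity.nta5[-1] == seq[lo - 1]:
        raise ValueError(
            f"{identity.label}: template-adjacent 5' NTA base equals the "
            "template base; this is a templated extension, not an NTA"
        )
    return identity.nta5 + seq[lo:hi] + identity.nta3


def infer_identity(sequence: str, record, arm, bounds) -> IsomirIdentity | None:
    """Decompose a read into an isomiR identity on one arm, or ``None``.

    Templated precedence: among all valid decompositions the one with the
    longest templated 3' extent (fewest 3' NTA bases) wins, then the longest
    templated 5' extent.  Ties between alternative 5' placements of the same
    core are broken by the smallest ``|start_offset|``, then the smaller
    offset — in practice the windows of a single arm make this unique.
    """
    seq = to_dna(sequence)
    if not set(seq) <= _DNA:
        return None
    if not (bounds.min_len <= len(seq) <= bounds.max_len):
        return None
    hp = record.sequence
    max5 = bounds.max_5p_nta_len if bounds.allow_5p_nta else 0
    for n3 in range(0, min(bounds.max_nta_len, len(seq) - 1) + 1):
        for n5 in range(0, min(max5, len(seq) - 1 - n3) + 1):
            core = seq[n5 : len(seq) - n3] if n3 else seq[n5:]
            if not core:
                continue
            for a in sorted(
                range(-bounds.max_start_shift, bounds.max_start_shift + 1),
                key=lambda x: (abs(x), x),
            ):
                lo = arm.start + a
                hi = lo + len(core)
                b = hi - arm.end
                if lo < 0 or hi > len(hp) or abs(b) > bounds.max_end_shift:
                    continue
                if hp[lo:hi] != core:
                    continue
                if n3 and hi < len(hp) and seq[len(seq) - n3] == hp[hi]:
                    continue  # would be a templated extension
                if n5 and lo > 0 and seq[n5 - 1] == hp[lo - 1]:
                    continue
                return IsomirIdentity(
                    arm.mature_name, a, b, seq[len(seq) - n3 :] if n3 else "", seq[:n5]
                )
    return None


# --- classification --------------------------------------------------------

CATEGORIES = ("canonical", "start-site", "end-site", "shifted", "3p-nta", "5p-nta", "mixed")

_HUMAN = {
    "start-site": "start-site",
    "end-site": "end-site",
    "shifted": "shifted",
    "3p-nta": "3' non-templated addition",
    "5p-nta": "5' non-templated addition",
}
_DETAIL_ORDER = ("start-site", "end-site", "shifted", "3p-nta", "5p-nta")


@dataclass(frozen=True)
class IsomirCategory:
    """One of the canonical/five-variant/mixed classes, with mixed breakdown."""

    category: str
    mixed_detail: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "mixed") != (len(self.mixed_detail) >= 2):
            raise ValueError("mixed_detail must hold >= 2 deviations iff category is mixed")

    def describe(self) -> str:
        """Human-readable class, e.g. ``mixed: start-site + end-site``."""
        if self.category == "canonical":
            return "canonical"
        if self.category != "mixed":
            return _HUMAN[self.category]
        parts = [_HUMAN[d] for d in _DETAIL_ORDER if d in self.mixed_detail]
        return "mixed: " + " + ".join(parts)


def classify(identity: IsomirIdentity) -> IsomirCategory:
    """Assign the identity to exactly one class.

    A simultaneous equal shift of both ends with no NTA is "shifted" (length
    preserved); that same deviation inside a compound variant contributes
    "shifted" to the mixed detail rather than separate start/end entries.
    """
    deviations = set()
    s, e = identity.start_offset, identity.end_offset
    if s != 0 and s == e:
        deviations.add("shifted")
    else:
        if s != 0:
            deviations.add("start-site")
        if e != 0:
            deviations.add("end-site")
    if identity.nta3:
        deviations.add("3p-nta")
    if identity.nta5:
        deviations.add("5p-nta")
    if not deviations:
        return IsomirCategory("canonical")
    if len(deviations) == 1:
        return IsomirCategory(next(iter(deviations)))
    return IsomirCategory("mixed", frozenset(deviations))


def normalize_type_string(text: str) -> str:
    """Canonicalise a printed class description to :meth:`IsomirCategory.describe` form.

    Tolerates typographic apostrophes, ``non-template`` vs ``non-templated``,
    and missing spaces around ``+``.
    """
    t = text.strip().lower().replace("’", "'").replace("′", "'")
    t = t.replace("non-template ", "non-templated ")
    t = re.sub(r"\s*\+\s*", " + ", t)
    t = re.sub(r"mixed\s*:\s*", "mixed: ", t)
    t = re.sub(r"\s+", " ", t)
    return t
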