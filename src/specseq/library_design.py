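"""Randomized-core binding-site library definitions.

A Spec-seq library is a pool of short duplex DNAs sharing fixed 5'/3' flanks
around a partially randomized core, e.g. the monomeric homeodomain library
``TAANNN``: the TAAT-proximal ``TAA`` bases are held constant and the three
3' bases are fully randomized, giving 4^3 = 64 variants.  Everything
downstream (counting, energies, regression) indexes variants by their core
sequence, so enumeration order must be deterministic: lexicographic
throughout.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable

BASES = "ACGT"

#: hard bound on the number of randomized positions (4^12 ~ 1.7e7 variants)
MAX_RANDOMIZED = 12

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PatternError(ValueError):
    """Core pattern contains a character outside {A, C, G, T, N}."""


class EnumerationBoundError(ValueError):
    """Core pattern has more randomized positions than the enumeration bound."""


class MembershipError(KeyError):
    """A sequence was required to be a library variant but is not."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (case-folded to upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def enumerate_library(core_pattern: str) -> list[str]:
    """Enumerate all concretizations of a core pattern, sorted lexicographically.

    ``N`` positions take all four bases; fixed positions are copied through.
    ``itertools.product`` over the N slots in left-to-right order already
    yields lexicographic order of the full variant strings, because all
    non-N positions are identical across variants.
    """
    pattern = core_pattern.upper()
    bad = set(pattern) - set("ACGTN")
    if bad:
        raise PatternError(
            f"invalid characters {sorted(bad)} in core pattern {core_pattern!r}"
        )
    n_random = pattern.count("N")
    if n_random > MAX_RANDOMIZED:
        raise EnumerationBoundError(
            f"{n_random} randomized positions exceed the bound of {MAX_RANDOMIZED}"
        )
    slots = [BASES if b == "N" else b for b in pattern]
    return ["".join(p) for p in itertools.product(*slots)]


@dataclass(frozen=True)
class SpecseqLibrary:
    """A Spec-seq library: fixed flanks around a randomized core.

    Parameters
    ----------
    name : str
        Free-form label (e.g. ``"HD-monomer-fwd"``).
    flank5, flank3 : str
        Conserved sequences 5' and 3' of the core.  Reads with any mismatch
        here are discarded by the read processor.
    core_pattern : str
        Pattern over {A, C, G, T, N}; N marks randomized positions.
    strand : str
        ``"forward"`` or ``"reverse"``.  A reverse-strand library carries the
        reverse-complemented pattern; :meth:`to_forward` maps its variants
        back into forward-motif space for reporting.
    """

    name: str
    flank5: str
    core_pattern: str
    flank3: str
    strand: str = "forward"
    variants: tuple[str, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"strand must be forward/reverse, got {self.strand!r}")
        object.__setattr__(self, "flank5", self.flank5.upper())
        object.__setattr__(self, "flank3", self.flank3.upper())
        object.__setattr__(self, "core_pattern", self.core_pattern.upper())
        for label, seq in (("flank5", self.flank5), ("flank3", self.flank3)):
            bad = set(seq) - set("ACGT")
            if bad:
                raise PatternError(f"invalid characters {sorted(bad)} in {label}")
        object.__setattr__(
            self, "variants", tuple(enumerate_library(self.core_pattern))
        )

    # -- derived views -------------------------------------------------

    @property
    def core_length(self) -> int:
        return len(self.core_pattern)

    @property
    def read_length(self) -> int:
        return len(self.flank5) + self.core_length + len(self.flank3)

    @property
    def variable_positions(self) -> tuple[int, ...]:
        """0-based core positions that are randomized (N)."""
        return tuple(i for i, b in enumerate(self.core_pattern) if b == "N")

    @property
    def fixed_positions(self) -> dict[int, str]:
        """0-based core position -> fixed base, for non-N positions."""
        return {i: b for i, b in enumerate(self.core_pattern) if b != "N"}

    @property
    def variant_set(self) -> frozenset[str]:
        return frozenset(self.variants)

    def full_sequence(self, variant: str) -> str:
        return self.flank5 + variant + self.flank3

    def to_forward(self, variant: str) -> str:
        """Map a variant into forward-motif space.

        Identity on forward libraries; reverse complement on reverse-strand
        libraries.  This is the bijection that lets energies measured on a
        reverse library be reported on the forward motif.
        """
        if variant not in self.variant_set:
            raise MembershipError(f"{variant!r} is not a variant of {self.name}")
        return variant if self.strand == "forward" else reverse_complement(variant)

    def variant_map(self) -> dict[str, str]:
        """variant -> forward-motif-space sequence, for the whole library."""
        return {v: self.to_forward(v) for v in self.variants}

    # -- transforms ----------------------------------------------------

    def reverse_complement(self) -> "SpecseqLibrary":
        """The same physical library read on the opposite strand.

        Flanks swap roles (and are reverse complemented), the core pattern is
        reverse complemented, and the strand flag flips.  Applying twice is
        the identity on variants and strand.
        """
        return SpecseqLibrary(
            name=self.name,
            flank5=reverse_complement(self.flank3),
            core_pattern=reverse_complement(self.core_pattern),
            flank3=reverse_complement(self.flank5),
            strand="reverse" if self.strand == "forward" else "forward",
        )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "flank5": self.flank5,
            "core_pattern": self.core_pattern,
            "flank3": self.flank3,
            "strand": self.strand,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpecseqLibrary":
        return cls(
            name=d["name"],
            flank5=d["flank5"],
            core_pattern=d["core_pattern"],
            flank3=d["flank3"],
            strand=d.get("strand", "forward"),
        )

    @classmethod
    def from_json(cls, path) -> "SpecseqLibrary":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


@dataclass(frozen=True)
class VariantNeighborhood:
    """All library variants within ``max_mismatch`` of a reference variant.

    Mismatches are counted only at the library's randomized (N) positions:
    fixed positions can never differ between valid variants.
    """

    reference: str
    max_mismatch: int
    members: frozenset[str]

    def __contains__(self, variant: str) -> bool:
        return variant in self.members

    def __len__(self) -> int:
        return len(self.members)


def hamming_neighborhood(
    reference: str, library: SpecseqLibrary, max_mismatch: int
) -> VariantNeighborhood:
    """Variants of ``library`` within ``max_mismatch`` substitutions of ``reference``.

    Distance is Hamming distance restricted to the variable positions (which,
    within a valid library, equals the full Hamming distance).
    """
    reference = reference.upper()
    if reference not in library.variant_set:
        raise MembershipError(
            f"reference {reference!r} is not a variant of library {library.name!r}"
        )
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    varpos = library.variable_positions
    members = frozenset(
        v
        for v in library.variants
        if sum(v[p] != reference[p] for p in varpos) <= max_mismatch
    )
    return VariantNeighborhood(reference, max_mismatch, members)
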