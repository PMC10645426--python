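"""Turn raw gel-fraction reads into per-variant counts.

Spec-seq reads are short fixed-layout amplicons: ``flank5 + core + flank3``
(plus whatever trails 3' of the construct).  Matching is positional and
exact — any substitution inside a conserved flank disqualifies the read, and
a core that is not a valid library variant (e.g. a mutated fixed base) is
likewise rejected.  Rejections are tallied by reason, never fatal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

from .library_design import SpecseqLibrary

REJECT_REASONS = ("too_short", "invalid_base", "flank_mismatch", "unknown_variant")

FRACTIONS = ("bound", "unbound")


class MatchResult(NamedTuple):
    variant: str | None
    reason: str | None

    @property
    def accepted(self) -> bool:
        return self.variant is not None


def match_read(read: str, library: SpecseqLibrary) -> MatchResult:
    """Match one read against the library layout at the expected offset.

    Returns the core variant on success, else ``None`` plus a reject-reason
    code from :data:`REJECT_REASONS`.  Checks run in layout order: length,
    alphabet, 5' flank, 3' flank, core membership.
    """
    read = read.upper()
    n5 = len(library.flank5)
    nc = library.core_length
    n3 = len(library.flank3)
    if len(read) < n5 + nc + n3:
        return MatchResult(None, "too_short")
    window = read[: n5 + nc + n3]
    if set(window) - set("ACGTN"):
        return MatchResult(None, "invalid_base")
    if window[:n5] != library.flank5 or window[n5 + nc :] != library.flank3:
        return MatchResult(None, "flank_mismatch")
    core = window[n5 : n5 + nc]
    if core not in library.variant_set:
        return MatchResult(None, "unknown_variant")
    return MatchResult(core, None)


@dataclass
class FractionCounts:
    """Per-variant read counts in the bound and unbound gel fractions.

    ``counts`` maps every library variant to ``(n_bound, n_unbound)``; values
    are floats so exact expected counts from the simulator can flow through
    the same container.  ``discarded`` tallies rejected reads per fraction by
    reason.
    """

    library: SpecseqLibrary
    counts: dict[str, tuple[float, float]]
    discarded: dict[str, Counter] = field(
        default_factory=lambda: {f: Counter() for f in FRACTIONS}
    )

    def __post_init__(self) -> None:
        missing = self.library.variant_set - set(self.counts)
        for v in missing:
            self.counts[v] = (0.0, 0.0)
        extra = set(self.counts) - self.library.variant_set
        if extra:
            raise KeyError(f"counts contain non-library variants: {sorted(extra)[:5]}")

    @property
    def totals(self) -> tuple[float, float]:
        nb = sum(c[0] for c in self.counts.values())
        nu = sum(c[1] for c in self.counts.values())
        return nb, nu

    def n_discarded(self, fraction: str) -> int:
        return sum(self.discarded[fraction].values())

    def to_frame(self) -> pd.DataFrame:
        """Counts table sorted by variant: columns variant, n_bound, n_unbound."""
        rows = [
            (v, self.counts[v][0], self.counts[v][1])
            for v in self.library.variants
        ]
        return pd.DataFrame(rows, columns=["variant", "n_bound", "n_unbound"])


def count_fractions(
    bound_reads: Iterable[str],
    unbound_reads: Iterable[str],
    library: SpecseqLibrary,
) -> FractionCounts:
    """Count accepted reads per variant in each fraction.

    Order-independent by construction; malformed reads are tallied under
    their reject reason.  Variants never observed keep (0, 0).
    """
    counts: dict[str, list[float]] = {v: [0.0, 0.0] for v in library.variants}
    discarded = {f: Counter() for f in FRACTIONS}
    for idx, stream in ((0, bound_reads), (1, unbound_reads)):
        fraction = FRACTIONS[idx]
        for read in stream:
            res = match_read(read, library)
            if res.accepted:
                counts[res.variant][idx] += 1
            else:
                discarded[fraction][res.reason] += 1
    return FractionCounts(
        library=library,
        counts={v: (c[0], c[1]) for v, c in counts.items()},
        discarded=discarded,
    )


def qc_summary(fc: FractionCounts) -> dict:
    """Per-fraction totals, discard fractions, and variant coverage.

    Coverage is the fraction of library variants with at least one read in
    *both* fractions.
    """
    nb, nu = fc.totals
    covered = sum(
        1 for v in fc.library.variants if fc.counts[v][0] >= 1 and fc.counts[v][1] >= 1
    )
    out: dict = {
        "library": fc.library.name,
        "n_variants": len(fc.library.variants),
        "coverage": covered / len(fc.library.variants),
    }
    for fraction, accepted in zip(FRACTIONS, (nb, nu)):
        n_disc = fc.n_discarded(fraction)
        total = accepted + n_disc
        out[fraction] = {
            "n_accepted": accepted,
            "n_discarded": n_disc,
            "discard_reasons": dict(fc.discarded[fraction]),
            "discard_fraction": (n_disc / total) if total else 0.0,
        }
    return out
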