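"""In-silico restriction digestion and fragment size selection.

Analytical model of the enrichment step: wild-type molecules carry an intact
NsiI site and are cut into sub-fragments that fall outside the gel
size-selection window, while digestion-resistant (mutant or integrant)
molecules survive as a single PstI fragment that is retained.

Recognition is exact-match on palindromic 6-mers, so a single strand scan
covers both strands.  Cut positions are placed at a fixed offset within each
recognition site (both NsiI ATGCA^T and PstI CTGCA^G leave 3' overhangs after
position 5); fragment lengths between sites are offset-independent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: cut offset (bases from site start, top strand) for each recognition 6-mer
DEFAULT_CUT_OFFSETS = {"ATGCAT": 5, "CTGCAG": 5}
NSII = "ATGCAT"
PSTI = "CTGCAG"

_VALID = re.compile(r"^[ACGT]*$")


@dataclass(frozen=True)
class Fragment:
    """A digestion product, 0-based half-open on the parent sequence."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def digest(
    sequence: str,
    enzymes: list[str],
    cut_offsets: dict[str, int] | None = None,
) -> list[Fragment]:
    """Cut at every exact occurrence of each recognition sequence.

    Returns fragments in coordinate order, tiling the input exactly (the two
    terminal fragments are bounded by the sequence ends rather than by cut
    sites).  Overlapping site occurrences are all honoured.
    """
    if not _VALID.match(sequence):
        raise ValueError("sequence must contain only uppercase A/C/G/T")
    offsets = dict(DEFAULT_CUT_OFFSETS)
    if cut_offsets:
        offsets.update(cut_offsets)
    cuts: set[int] = set()
    for enzyme in enzymes:
        if enzyme not in offsets:
            raise ValueError(f"no cut offset known for recognition sequence {enzyme!r}")
        for m in re.finditer(f"(?={re.escape(enzyme)})", sequence):
            cuts.add(m.start() + offsets[enzyme])
    bounds = [0] + sorted(c for c in cuts if 0 < c < len(sequence)) + [len(sequence)]
    if len(sequence) == 0:
        return []
    return [Fragment(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def internal_fragments(fragments: list[Fragment], sequence_length: int) -> list[Fragment]:
    """Fragments bounded by cut sites on both sides (excludes the two ends)."""
    return [f for f in fragments if f.start > 0 and f.end < sequence_length]


def size_select(
    fragments: list[Fragment], window: tuple[int, int] = (1264, 1371)
) -> list[Fragment]:
    """Retain fragments whose length falls inside the gel excision window.

    The default window corresponds to the 1,264 and 1,371 bp marker bands
    between which the sample lane is excised, retaining the 1,332 bp
    digestion-resistant PstI fragment and discarding both wild-type NsiI
    sub-fragments (488 and 844 bp).
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("size window must satisfy min < max")
    return [f for f in fragments if lo <= f.length <= hi]


def write_fragments_tsv(fragments: list[Fragment], path) -> None:
    """BED-like TSV (0-based half-open) of digestion fragments."""
    with open(path, "w") as fh:
        fh.write("start\tend\tlength\n")
        for f in fragments:
            fh.write(f"{f.start}\t{f.end}\t{f.length}\n")
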