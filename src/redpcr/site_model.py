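"""Model of the *SMAD4* c.1494_1499 NsiI recognition site.

The NsiI recognition sequence (ATGCAT) within *SMAD4* exon 11 spans the last
base of codon Leu498, all of codon Cys499 and the first two bases of codon
Ile500 (cDNA numbering on transcript NM_005359.6).  Because the site is a
palindrome, every single-nucleotide substitution that destroys the site has a
*reciprocal* partner: the substitution at the mirror position with both
alleles complemented.  A strand-symmetric technical artifact (e.g. oxidative
G>T damage) produces correlated levels across a reciprocal pair, whereas
genuine clonal selection of a protein change does not.

This module enumerates the 18 digestion-escaping substitutions, annotates
their protein consequences from the standard genetic code, and exposes the
reciprocal-pair mapping used by the artifact-discrimination stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

NSII_SITE = "ATGCAT"
BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon, '*' for a stop codon."""
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


@dataclass(frozen=True)
class SiteModel:
    """The 6-bp NsiI window at *SMAD4* c.1494_1499.

    ``codon498_prefix`` supplies the first two bases of codon 498 and
    ``codon500_suffix`` the third base of codon 500; both lie outside the
    restriction site and are configurable sequence context.  The defaults
    (CTA = Leu498, ATA = Ile500) are consistent with every protein label the
    assay's variant spectrum pins down.
    """

    site_sequence: str = NSII_SITE
    cdna_start: int = 1494
    codon498_prefix: str = "CT"
    codon500_suffix: str = "A"
    codon_phase: dict = field(
        default_factory=lambda: {
            1494: (498, 3),
            1495: (499, 1),
            1496: (499, 2),
            1497: (499, 3),
            1498: (500, 1),
            1499: (500, 2),
        }
    )

    def __post_init__(self) -> None:
        if len(self.site_sequence) != 6 or any(b not in BASES for b in self.site_sequence):
            raise ValueError(f"site_sequence must be a 6-mer over ACGT, got {self.site_sequence!r}")
        if _revcomp(self.site_sequence) != self.site_sequence:
            raise ValueError("site_sequence must be palindromic (its own reverse complement)")
        if len(self.codon498_prefix) != 2 or len(self.codon500_suffix) != 1:
            raise ValueError("codon498_prefix must be a 2-mer and codon500_suffix a 1-mer")

    @property
    def cdna_end(self) -> int:
        return self.cdna_start + 5

    def ref_base(self, cdna_position: int) -> str:
        self._check_position(cdna_position)
        return self.site_sequence[cdna_position - self.cdna_start]

    def ref_codon(self, codon_number: int) -> str:
        """Reference codon sequence assembled from the site and its context."""
        if codon_number == 498:
            return self.codon498_prefix + self.site_sequence[0]
        if codon_number == 499:
            return self.site_sequence[1:4]
        if codon_number == 500:
            return self.site_sequence[4:6] + self.codon500_suffix
        raise ValueError(f"codon {codon_number} is outside the NsiI window")

    def _check_position(self, cdna_position: int) -> None:
        if not self.cdna_start <= cdna_position <= self.cdna_end:
            raise ValueError(
                f"c.{cdna_position} is outside the NsiI site "
                f"(c.{self.cdna_start}_{self.cdna_end})"
            )


@dataclass(frozen=True, order=True)
class Substitution:
    """A single-nucleotide change within the NsiI site, e.g. c.1498A>G."""

    cdna_position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("alt_base must differ from ref_base")
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ValueError("ref/alt must be one of A, C, G, T")

    @property
    def cdna_change(self) -> str:
        return f"c.{self.cdna_position}{self.ref_base}>{self.alt_base}"

    def site_position(self, model: SiteModel) -> int:
        """1-based position within the 6-bp site."""
        return self.cdna_position - model.cdna_start + 1

    def mutated_site(self, model: SiteModel) -> str:
        i = self.cdna_position - model.cdna_start
        if model.site_sequence[i] != self.ref_base:
            raise ValueError(f"{self.cdna_change}: ref does not match site sequence")
        return model.site_sequence[:i] + self.alt_base + model.site_sequence[i + 1 :]


@dataclass(frozen=True)
class ProteinConsequence:
    codon_number: int
    ref_aa: str  # three-letter code; 'Ter' for stop
    alt_aa: str
    consequence_class: str  # missense | nonsense | synonymous
    hgvs_p: str
    context_dependent: bool = False


def enumerate_escaping_substitutions(model: SiteModel | None = None) -> list[Substitution]:
    """All single-base changes in the site; each abolishes exact-match NsiI
    recognition, so the assay enriches all of them equally.

    Ordered by cDNA position, then alphabetically by alternate base, so that
    downstream tables are bit-stable.
    """
    model = model or SiteModel()
    subs = []
    for offset in range(6):
        pos = model.cdna_start + offset
        ref = model.site_sequence[offset]
        for alt in BASES:
            if alt != ref:
                subs.append(Substitution(pos, ref, alt))
    assert all(s.mutated_site(model) != model.site_sequence for s in subs)
    return subs


def annotate_consequence(model: SiteModel, sub: Substitution) -> ProteinConsequence:
    """Protein consequence of a site substitution under the standard code.

    Consequences at c.1494 other than A>G depend on the configured
    ``codon498_prefix`` (the variant spectrum only pins down A>G, synonymous
    under both CTA and TTA); these are flagged ``context_dependent``.
    """
    model._check_position(sub.cdna_position)
    codon_number, pos_in_codon = model.codon_phase[sub.cdna_position]
    ref_codon = model.ref_codon(codon_number)
    if ref_codon[pos_in_codon - 1] != sub.ref_base:
        raise ValueError(f"{sub.cdna_change}: ref base inconsistent with codon {codon_number}")
    alt_codon = (
        ref_codon[: pos_in_codon - 1] + sub.alt_base + ref_codon[pos_in_codon:]
    )
    ref_aa1 = _translate_codon(ref_codon)
    alt_aa1 = _translate_codon(alt_codon)
    ref_aa = seq3(ref_aa1) if ref_aa1 != "*" else "Ter"
    alt_aa = seq3(alt_aa1) if alt_aa1 != "*" else "Ter"
    if alt_aa1 == "*":
        consequence = "nonsense"
        hgvs_p = f"p.{ref_aa}{codon_number}*"
    elif alt_aa1 == ref_aa1:
        consequence = "synonymous"
        hgvs_p = f"p.{ref_aa}{codon_number}="
    else:
        consequence = "missense"
        hgvs_p = f"p.{ref_aa}{codon_number}{alt_aa}"
    context_dependent = sub.cdna_position == 1494 and sub.alt_base != "G"
    return ProteinConsequence(codon_number, ref_aa, alt_aa, consequence, hgvs_p, context_dependent)


def reciprocal_partner(model: SiteModel, sub: Substitution) -> Substitution:
    """The mirror-image substitution on the palindrome.

    Site position p maps to 7 - p and ref/alt map to their Watson-Crick
    complements; the map is a fixed-point-free involution pairing the 18
    substitutions into 9 reciprocal pairs.
    """
    model._check_position(sub.cdna_position)
    p = sub.site_position(model)
    partner_pos = model.cdna_start + (7 - p) - 1
    return Substitution(partner_pos, _COMPLEMENT[sub.ref_base], _COMPLEMENT[sub.alt_base])


def site_catalogue(model: SiteModel | None = None) -> pd.DataFrame:
    """Catalogue of the 18 escaping substitutions with annotations.

    Columns: cdna_change, site_position, hgvs_p, consequence_class,
    context_dependent, reciprocal_partner.
    """
    model = model or SiteModel()
    rows = []
    for sub in enumerate_escaping_substitutions(model):
        cons = annotate_consequence(model, sub)
        partner = reciprocal_partner(model, sub)
        rows.append(
            {
                "cdna_change": sub.cdna_change,
                "site_position": sub.site_position(model),
                "hgvs_p": cons.hgvs_p,
                "consequence_class": cons.consequence_class,
                "context_dependent": cons.context_dependent,
                "reciprocal_partner": partner.cdna_change,
            }
        )
    return pd.DataFrame(rows)


def substitution_from_cdna_change(model: SiteModel, cdna_change: str) -> Substitution:
    """Parse a label like 'c.1498A>G' back into a Substitution."""
    body = cdna_change.removeprefix("c.")
    ref_alt = body[-3:]
    pos = int(body[:-3])
    ref, alt = ref_alt[0], ref_alt[2]
    model._check_position(pos)
    if model.ref_base(pos) != ref:
        raise ValueError(f"{cdna_change}: ref base does not match the site")
    return Substitution(pos, ref, alt)
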