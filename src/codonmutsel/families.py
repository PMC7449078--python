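"""Synonymous codon families.

All mutation-bias (ΔM) and selection-bias (Δη) parameters in this package are
defined per synonymous codon family: the set of codons encoding one amino
acid, with serine split into its two mutationally disconnected groups
(TCN, labelled ``S``, and AGY, labelled ``Z`` — the two groups are separated
by more than one nucleotide change, so a single-step mutation model treats
them as independent families). Single-codon amino acids (Met, Trp) and stop
codons carry no synonymous choice and are excluded.

With the standard genetic code this yields 19 families covering 59 codons.
Under the alternative yeast nuclear code (NCBI table 12) CTG encodes serine;
because CTG is not a one-step neighbour of the other serine codons it is
dropped entirely, and the leucine family is flagged as excluded from
cross-genome comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

STANDARD = "standard"
ALT_YEAST = "alternative-yeast-nuclear"

_NUCS = set("ACGT")


@dataclass(frozen=True)
class CodonFamily:
    """One synonymous codon family."""

    label: str
    amino_acid: str
    codons: tuple[str, ...]
    excluded_from_comparison: bool = False

    @property
    def size(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class CodonFamilyTable:
    """Ordered collection of synonymous codon families for one genetic code."""

    families: tuple[CodonFamily, ...]
    genetic_code: str = STANDARD
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        seen: dict[str, str] = {}
        for fam in self.families:
            for codon in fam.codons:
                if codon in seen:
                    raise ValueError(f"codon {codon} in two families")
                if len(codon) != 3 or set(codon) - _NUCS:
                    raise ValueError(f"invalid codon {codon!r}")
                seen[codon] = fam.label
        object.__setattr__(self, "_index", self._build_index())

    def _build_index(self) -> dict:
        codons: list[str] = []
        fam_of: dict[str, str] = {}
        slices: dict[str, np.ndarray] = {}
        for fam in self.families:
            start = len(codons)
            codons.extend(fam.codons)
            slices[fam.label] = np.arange(start, start + fam.size)
            for c in fam.codons:
                fam_of[c] = fam.label
        return {
            "codons": tuple(codons),
            "fam_of": fam_of,
            "slices": slices,
            "by_label": {f.label: f for f in self.families},
            "codon_pos": {c: i for i, c in enumerate(codons)},
        }

    # -- lookups -----------------------------------------------------------
    @property
    def codons(self) -> tuple[str, ...]:
        """All sense codons, family-blocked, alphabetical within family."""
        return self._index["codons"]

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f.label for f in self.families)

    def family(self, label: str) -> CodonFamily:
        return self._index["by_label"][label]

    def family_of(self, codon: str) -> str | None:
        """Family label for a codon, or None for excluded codons (ATG, TGG, stops)."""
        return self._index["fam_of"].get(codon)

    def slice(self, label: str) -> np.ndarray:
        """Positions of a family's codons in the global codon ordering."""
        return self._index["slices"][label]

    def codon_position(self, codon: str) -> int:
        return self._index["codon_pos"][codon]

    def two_codon_families(self, include_z: bool = True) -> tuple[CodonFamily, ...]:
        fams = tuple(f for f in self.families if f.size == 2)
        if not include_z:
            fams = tuple(f for f in fams if f.label != "Z")
        return fams

    # -- constructors ------------------------------------------------------
    @classmethod
    def standard(cls) -> "CodonFamilyTable":
        return cls(_families_from_ncbi(1), STANDARD)

    @classmethod
    def alternative_yeast(cls) -> "CodonFamilyTable":
        """NCBI table 12: CTG → Ser.

        CTG is two mutational steps from the TCN serine block, so it is
        removed outright; leucine loses a codon relative to the standard code
        and is flagged excluded from cross-code parameter comparisons.
        """
        return cls(_families_from_ncbi(12), ALT_YEAST)

    @classmethod
    def for_code(cls, genetic_code: str) -> "CodonFamilyTable":
        if genetic_code == STANDARD:
            return cls.standard()
        if genetic_code == ALT_YEAST:
            return cls.alternative_yeast()
        raise ValueError(f"unknown genetic code {genetic_code!r}")


def _families_from_ncbi(table_id: int) -> tuple[CodonFamily, ...]:
    fwd = CodonTable.unambiguous_dna_by_id[table_id].forward_table
    groups: dict[str, list[str]] = {}
    for codon, aa in sorted(fwd.items()):
        if aa in ("M", "W"):
            continue
        if aa == "S":
            if codon == "CTG":  # alt yeast code: not a one-step Ser neighbour
                continue
            label = "S" if codon.startswith("TC") else "Z"
        else:
            label = aa
        groups.setdefault(label, []).append(codon)
    fams = []
    for label in sorted(groups):
        aa = "S" if label == "Z" else label
        excluded = table_id == 12 and label == "L"
        fams.append(CodonFamily(label, aa, tuple(sorted(groups[label])), excluded))
    return tuple(fams)
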