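"""Domain-architecture screens.

Two complementary screens over Pfam-style domain annotations:

* **Atypical combinations** — a fused gene model typically joins the domain
  repertoires of two real genes, creating a domain pairing never seen in
  related species. A focal protein is flagged when it carries a combination
  absent from every reference species and rare (below a count threshold)
  within the focal species itself.

* **Family length outliers** — within a large gene family defined by one
  Pfam domain (collagens, C-type lectins, ...), member protein lengths are
  tightly distributed; members below the first or above the eighth decile
  of the family's length distribution are curation candidates.

The census counts *proteins*, not domain instances: a collagen with three
Collagen domains contributes one to the Collagen count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

from .model import AnnotationError, DomainHit

logger = logging.getLogger(__name__)

PAIR_MODE = "pair"
FULL_SET_MODE = "full-set"

TOO_LONG = "too-long"
TOO_SHORT = "too-short"


@dataclass
class DomainArchitecture:
    """The deduplicated domain families of one protein and their 2-subsets."""

    protein_id: str
    families: frozenset[str]

    @property
    def combinations(self) -> set[frozenset[str]]:
        return {frozenset(p) for p in combinations(sorted(self.families), 2)}


@dataclass
class CombinationCensus:
    """Per-species occurrence counts of domain combinations.

    Keys are frozensets of family accessions: 2-element sets in ``pair``
    mode, whole architectures in ``full-set`` mode. Counts are numbers of
    proteins containing the combination (each protein contributes <= 1).
    """

    species: str
    mode: str = PAIR_MODE
    counts: dict[frozenset[str], int] = field(default_factory=dict)
    members: dict[frozenset[str], set[str]] = field(default_factory=dict)

    @classmethod
    def from_architectures(cls, species: str,
                           architectures: list[DomainArchitecture],
                           mode: str = PAIR_MODE) -> "CombinationCensus":
        census = cls(species=species, mode=mode)
        for arch in architectures:
            if mode == PAIR_MODE:
                keys = arch.combinations
            elif mode == FULL_SET_MODE:
                keys = {arch.families} if arch.families else set()
            else:
                raise AnnotationError(f"unknown census mode {mode!r}")
            for key in keys:
                census.counts[key] = census.counts.get(key, 0) + 1
                census.members.setdefault(key, set()).add(arch.protein_id)
        return census


def build_architectures(domain_hits: list[DomainHit]) -> list[DomainArchitecture]:
    """Collapse per-domain hits into one architecture per protein."""
    fams: dict[str, set[str]] = {}
    for hit in domain_hits:
        fams.setdefault(hit.protein_id, set()).add(hit.domain_family)
    return [DomainArchitecture(pid, frozenset(f))
            for pid, f in sorted(fams.items())]


def screen_atypical_combinations(
        focal: CombinationCensus,
        references: list[CombinationCensus],
        max_count: int = 10) -> dict[str, list[frozenset[str]]]:
    """Proteins carrying a combination unique to the focal species and rare.

    A combination triggers when it is absent from every reference census and
    occurs in fewer than *max_count* focal proteins. Returns a mapping
    candidate protein id -> sorted list of triggering combinations.
    """
    for ref in references:
        if ref.mode != focal.mode:
            raise AnnotationError(
                f"census mode mismatch: focal={focal.mode} vs "
                f"{ref.species}={ref.mode}")
    candidates: dict[str, list[frozenset[str]]] = {}
    for combo, count in focal.counts.items():
        if count >= max_count:
            continue
        if any(combo in ref.counts for ref in references):
            continue
        for pid in focal.members[combo]:
            candidates.setdefault(pid, []).append(combo)
    return {pid: sorted(combos, key=sorted)
            for pid, combos in sorted(candidates.items())}


@dataclass
class GeneFamily:
    """A Pfam-defined gene family with member protein lengths."""

    family_accession: str
    member_proteins: list[tuple[str, int]]

    def decile(self, q: float) -> float:
        """Nearest-rank percentile: the value at rank ceil(q * n), 1-based."""
        values = sorted(length for _, length in self.member_proteins)
        rank = max(1, math.ceil(q * len(values)))
        return values[rank - 1]

    @property
    def first_decile(self) -> float:
        return self.decile(0.1)

    @property
    def eighth_decile(self) -> float:
        return self.decile(0.8)


def assign_families(architectures: list[DomainArchitecture],
                    protein_lengths: dict[str, int],
                    family_accessions: list[str]) -> list[GeneFamily]:
    """Group proteins into the listed Pfam-defined families.

    A protein joins every listed family whose accession appears among its
    domain families (multi-domain proteins can belong to several families).
    """
    if not family_accessions:
        raise AnnotationError("family_accessions must be non-empty")
    families = []
    for acc in family_accessions:
        members = [(a.protein_id, protein_lengths[a.protein_id])
                   for a in architectures
                   if acc in a.families and a.protein_id in protein_lengths]
        families.append(GeneFamily(acc, sorted(members)))
    return families


def screen_family_length_outliers(
        families: list[GeneFamily],
        min_members: int = 10) -> dict[str, list[tuple[str, str]]]:
    """Flag family members outside the first/eighth length deciles.

    Inequalities are strict, so members sitting exactly on a decile are
    kept. Families below *min_members* are skipped (deciles on a handful of
    members are meaningless) with a log line. Returns candidate protein id
    -> list of (family_accession, direction); a protein outlying in several
    families lists each trigger.
    """
    out: dict[str, list[tuple[str, str]]] = {}
    for fam in families:
        if len(fam.member_proteins) < min_members:
            logger.info("skipping family %s: only %d members",
                        fam.family_accession, len(fam.member_proteins))
            continue
        d1, d8 = fam.first_decile, fam.eighth_decile
        for pid, length in fam.member_proteins:
            if length < d1:
                out.setdefault(pid, []).append((fam.family_accession, TOO_SHORT))
            elif length > d8:
                out.setdefault(pid, []).append((fam.family_accession, TOO_LONG))
    return dict(sorted(out.items()))
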