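"""Antibody-side HLA compatibility metrics.

Three mismatch counts between a recipient and a donor genotype:

* amino-acid mismatch — donor residue configurations (interlocus for
  class I, intralocus for class II) absent from the recipient;
* eplet mismatch — donor-carried eplets (registry-defined residue
  patches) absent from the recipient's self set, optionally restricted
  to antibody-verified entries;
* Snow — amino-acid mismatches restricted to positions that are exposed
  on a donor allele carrying the residue, i.e. whose surface score and
  protrusion rank both strictly surpass the Snowflake/Snowball
  thresholds.

Note on "surpass": strict inequality is used throughout, so a position
whose exposure equals a threshold exactly is NOT exposed.  The identity
Snow(0.00/0.00) == amino-acid mismatches therefore holds only when all
exposure values are strictly positive; synthetic fixtures avoid exact
zeros for this reason.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple

from .alleles import (
    CLASS1_LOCI,
    CLASS2_LOCI,
    UNKNOWN,
    AlleleStore,
    Genotype,
    ResiduePair,
    residues_of,
)

#: position -> (surface_score, protrusion_rank) for one allele protein
AlleleExposure = Mapping[int, Tuple[float, float]]


@dataclass(frozen=True)
class SnowThresholds:
    snowflake: float = 0.0
    snowball: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.snowflake, self.snowball):
            if not 0.0 <= v <= 1.0:
                raise ValueError("Snow thresholds must lie in [0, 1]")


@dataclass
class CompatibilityScores:
    """The molecular mismatch metrics for one recipient-donor pair."""

    aa_mm: float = 0.0
    eplet_mm_all: float = 0.0
    eplet_mm_abv: float = 0.0
    snow: float = 0.0
    pirche_ii: float = 0.0
    pirche_iic: float = 0.0
    per_locus: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        return {
            "aa_mm": self.aa_mm,
            "eplet_mm_all": self.eplet_mm_all,
            "eplet_mm_abv": self.eplet_mm_abv,
            "snow": self.snow,
            "pirche_ii": self.pirche_ii,
            "pirche_iic": self.pirche_iic,
        }


# --------------------------------------------------------------------------
# Amino-acid mismatch

def aa_mismatch_detail(
    recipient: Genotype, donor: Genotype, store: AlleleStore
) -> FrozenSet[ResiduePair]:
    """Donor (group/locus, position, residue) pairs absent in the recipient."""
    return residues_of(donor, store) - residues_of(recipient, store)


def aa_mismatch(
    recipient: Genotype, donor: Genotype, store: AlleleStore
) -> Tuple[int, Dict[str, int]]:
    """Count of donor residue configurations absent from the recipient.

    Returns (total, per-group counts); class I is one pooled interlocus
    group, class II loci are counted intralocus.
    """
    detail = aa_mismatch_detail(recipient, donor, store)
    per_group: Dict[str, int] = {}
    for group, _pos, _res in detail:
        per_group[group] = per_group.get(group, 0) + 1
    return len(detail), per_group


# --------------------------------------------------------------------------
# Eplet mismatch

@dataclass(frozen=True)
class EpletDefinition:
    name: str
    locus_group: str  # 'class1', 'DRB1', 'DQB1' or 'class2' (shared DRB1/DQB1)
    requirements: FrozenSet[Tuple[int, str]]
    antibody_verified: bool

    def __post_init__(self) -> None:
        if not self.requirements:
            raise ValueError(f"eplet {self.name}: empty requirements")

    def loci(self) -> Tuple[str, ...]:
        if self.locus_group == "class1":
            return CLASS1_LOCI
        if self.locus_group == "class2":
            return CLASS2_LOCI
        return (self.locus_group,)


class EpletRegistry:
    def __init__(self, eplets: Iterable[EpletDefinition]):
        self.eplets: List[EpletDefinition] = list(eplets)
        names = [e.name for e in self.eplets]
        if len(names) != len(set(names)):
            raise ValueError("duplicate eplet names in registry")

    def __len__(self) -> int:
        return len(self.eplets)

    @classmethod
    def from_csv(cls, path, store: AlleleStore | None = None) -> "EpletRegistry":
        """Load from CSV: name, locus_group, antibody_verified, requirements.

        Requirements use the compact "9K;12A" position-residue syntax.
        If a store is given, requirement positions are checked against
        its alignments at load time.
        """
        eplets = []
        with open(path) as fh:
            for row in csv.DictReader(fh):
                reqs = frozenset(
                    (int(item[:-1]), item[-1].upper())
                    for item in row["requirements"].split(";")
                    if item
                )
                eplets.append(
                    EpletDefinition(
                        name=row["name"],
                        locus_group=row["locus_group"],
                        requirements=reqs,
                        antibody_verified=str(row["antibody_verified"]).strip().lower()
                        in ("1", "true", "yes"),
                    )
                )
        registry = cls(eplets)
        if store is not None:
            registry.validate_positions(store)
        return registry

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "locus_group", "antibody_verified", "requirements"])
            for e in self.eplets:
                reqs = ";".join(f"{p}{r}" for p, r in sorted(e.requirements))
                w.writerow([e.name, e.locus_group, int(e.antibody_verified), reqs])

    def validate_positions(self, store: AlleleStore) -> None:
        maxpos: Dict[str, int] = {}
        for allele in store.alleles():
            maxpos[allele.locus] = max(maxpos.get(allele.locus, 0), max(allele.residues))
        for e in self.eplets:
            limit = max((maxpos.get(l, 0) for l in e.loci()), default=0)
            for pos, _res in e.requirements:
                if pos > limit:
                    raise ValueError(
                        f"eplet {e.name}: position {pos} outside the "
                        f"{e.locus_group} alignment (max {limit})"
                    )


def _carries(allele_residues: Mapping[int, str], eplet: EpletDefinition) -> bool:
    return all(allele_residues.get(p) == r for p, r in eplet.requirements)


def eplet_set(
    genotype: Genotype, store: AlleleStore, registry: EpletRegistry
) -> FrozenSet[str]:
    """Eplets carried by any allele of the genotype (interlocus pooled)."""
    carried: Set[str] = set()
    for eplet in registry.eplets:
        for locus in eplet.loci():
            if locus not in genotype.alleles:
                continue
            for name in set(genotype.at(locus)):
                if _carries(store.get(name).residues, eplet):
                    carried.add(eplet.name)
    return frozenset(carried)


def eplet_mismatch(
    recipient: Genotype,
    donor: Genotype,
    store: AlleleStore,
    registry: EpletRegistry,
    verified_only: bool = False,
) -> Tuple[int, FrozenSet[str]]:
    """Donor eplets absent from the recipient's self set.

    Returns (count, mismatched eplet names); with ``verified_only`` the
    mismatch set is filtered to antibody-verified registry entries.
    """
    mismatched = eplet_set(donor, store, registry) - eplet_set(recipient, store, registry)
    if verified_only:
        verified = {e.name for e in registry.eplets if e.antibody_verified}
        mismatched = frozenset(mismatched & verified)
    return len(mismatched), mismatched


# --------------------------------------------------------------------------
# Snow

def snow_score(
    recipient: Genotype,
    donor: Genotype,
    store: AlleleStore,
    exposure: Mapping[str, AlleleExposure],
    thresholds: SnowThresholds,
) -> Tuple[int, FrozenSet[ResiduePair]]:
    """Exposed amino-acid mismatch count.

    A mismatched (group, position, residue) counts iff at least one
    donor allele carrying that residue at that position has
    surface_score > snowflake AND protrusion_rank > snowball in its
    allele-specific exposure map.
    """
    mismatches = aa_mismatch_detail(recipient, donor, store)
    donor_alleles = donor.distinct_alleles()
    for name in donor_alleles:
        if name not in exposure:
            raise KeyError(f"no exposure map for donor allele {name}")
    exposed: Set[ResiduePair] = set()
    for group, pos, res in mismatches:
        for name in donor_alleles:
            allele = store.get(name)
            allele_group = "class1" if allele.locus in CLASS1_LOCI else allele.locus
            if allele_group != group or allele.residues.get(pos) != res:
                continue
            sp = exposure[name].get(pos)
            if sp is None:
                continue
            surf, prot = sp
            if surf > thresholds.snowflake and prot > thresholds.snowball:
                exposed.add((group, pos, res))
                break
    return len(exposed), frozenset(exposed)


def snow_mismatch_exposures(
    recipient: Genotype,
    donor: Genotype,
    store: AlleleStore,
    exposure: Mapping[str, AlleleExposure],
) -> List[List[Tuple[float, float]]]:
    """Candidate (surface, protrusion) pairs per mismatched configuration.

    The Snow score at thresholds (sf, sb) is the number of mismatches
    with surface > sf AND protrusion > sb on at least one donor allele
    carrying the residue, i.e. ``sum(any(s > sf and p > sb for s, p in
    cands) for cands in result)``.  Used to evaluate whole threshold
    grids from a single mismatch-enumeration pass.
    """
    mismatches = aa_mismatch_detail(recipient, donor, store)
    out: List[List[Tuple[float, float]]] = []
    for group, pos, res in mismatches:
        candidates: List[Tuple[float, float]] = []
        for name in donor.distinct_alleles():
            allele = store.get(name)
            allele_group = "class1" if allele.locus in CLASS1_LOCI else allele.locus
            if allele_group != group or allele.residues.get(pos) != res:
                continue
            sp = exposure[name].get(pos)
            if sp is not None:
                candidates.append(sp)
        if candidates:
            out.append(candidates)
    return out
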