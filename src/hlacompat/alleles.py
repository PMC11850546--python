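"""Aligned HLA allele protein sequences, genotypes and locus groups.

Sequences are stored on 1-based mature-protein alignment columns.  The
class I loci (A, B, C) are assumed to share one alignment coordinate
system (as provided by the input file); class II loci each keep their
own.  Missing residues are recorded as :data:`UNKNOWN` and can be filled
by :func:`complete_sequences`, an iterative nearest-neighbour completion
over jointly known positions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple

UNKNOWN = "X"

CLASS1_LOCI = ("A", "B", "C")
CLASS2_LOCI = ("DRB1", "DQB1")
SUPPORTED_LOCI = CLASS1_LOCI + CLASS2_LOCI

ResiduePair = Tuple[str, int, str]  # (group-or-locus, position, residue)


@dataclass
class AlleleSequence:
    locus: str
    name: str
    residues: Dict[int, str]  # 1-based alignment position -> 1-letter code or UNKNOWN

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.name}: empty residue map")
        if min(self.residues) < 1:
            raise ValueError(f"{self.name}: positions must be >= 1")

    def known_positions(self) -> Set[int]:
        return {p for p, r in self.residues.items() if r != UNKNOWN}

    def unknown_positions(self) -> Set[int]:
        return {p for p, r in self.residues.items() if r == UNKNOWN}

    def protein(self) -> str:
        """Contiguous sequence over positions 1..max; errors on UNKNOWN."""
        top = max(self.residues)
        chars = []
        for p in range(1, top + 1):
            r = self.residues.get(p, UNKNOWN)
            if r == UNKNOWN:
                raise ValueError(f"{self.name}: position {p} is unknown; complete sequences first")
            chars.append(r)
        return "".join(chars)


@dataclass
class LocusGroup:
    group_id: str
    loci: Tuple[str, ...]
    shared_alignment: bool


CLASS1_GROUP = LocusGroup("class1", CLASS1_LOCI, shared_alignment=True)


class AlleleStore:
    """Mapping of allele name -> :class:`AlleleSequence`, grouped by locus."""

    def __init__(self, alleles: Iterable[AlleleSequence] = ()) -> None:
        self._alleles: Dict[str, AlleleSequence] = {}
        for a in alleles:
            self.add(a)

    def add(self, allele: AlleleSequence) -> None:
        if allele.name in self._alleles:
            raise ValueError(f"duplicate allele name {allele.name}")
        self._alleles[allele.name] = allele

    def __contains__(self, name: str) -> bool:
        return name in self._alleles

    def __len__(self) -> int:
        return len(self._alleles)

    def get(self, name: str) -> AlleleSequence:
        try:
            return self._alleles[name]
        except KeyError:
            raise KeyError(f"unknown allele {name!r}") from None

    def names(self, locus: str | None = None) -> List[str]:
        return sorted(
            n for n, a in self._alleles.items() if locus is None or a.locus == locus
        )

    def loci(self) -> List[str]:
        return sorted({a.locus for a in self._alleles.values()})

    def alleles(self) -> List[AlleleSequence]:
        return [self._alleles[n] for n in self.names()]


@dataclass(frozen=True, eq=False)
class Genotype:
    """Unordered allele pair per locus (equal names = homozygous)."""

    alleles: Mapping[str, Tuple[str, str]]

    def __post_init__(self) -> None:
        normalized = {
            locus: tuple(sorted(pair)) for locus, pair in dict(self.alleles).items()
        }
        object.__setattr__(self, "alleles", normalized)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genotype) and self.alleles == other.alleles

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.alleles.items())))

    def at(self, locus: str) -> Tuple[str, str]:
        return self.alleles[locus]

    def loci(self) -> List[str]:
        return sorted(self.alleles)

    def distinct_alleles(self, loci: Iterable[str] | None = None) -> List[str]:
        out: Dict[str, None] = {}
        for locus in sorted(self.alleles):
            if loci is not None and locus not in loci:
                continue
            for name in self.alleles[locus]:
                out.setdefault(name, None)
        return list(out)

    def validate(self, store: AlleleStore) -> None:
        for locus, pair in self.alleles.items():
            for name in pair:
                allele = store.get(name)
                if allele.locus != locus:
                    raise ValueError(f"allele {name} is not at locus {locus}")


# --------------------------------------------------------------------------
# I/O

def _locus_of(name: str) -> str:
    if "*" not in name:
        raise ValueError(f"allele name {name!r} lacks a locus prefix (expected LOCUS*...)")
    return name.split("*", 1)[0]


def load_alleles(path) -> AlleleStore:
    """Load an aligned allele store from FASTA or long-format CSV.

    FASTA records are placed on the alignment by 1-based column index;
    gap characters ('-', '.', 'X') are recorded as UNKNOWN.  The CSV
    format has columns name, position, residue (sparse positions allowed)
    and an optional locus column.
    """
    path = str(path)
    if path.lower().endswith((".fa", ".fasta", ".faa")):
        return _load_fasta(path)
    return _load_csv(path)


def _load_fasta(path: str) -> AlleleStore:
    from Bio import SeqIO

    store = AlleleStore()
    lengths: Dict[str, int] = {}
    for record in SeqIO.parse(path, "fasta"):
        name = record.id
        locus = _locus_of(name)
        seq = str(record.seq).upper()
        if locus in lengths and lengths[locus] != len(seq):
            raise ValueError(
                f"{path}: inconsistent alignment length for locus {locus} "
                f"({lengths[locus]} vs {len(seq)} in {name})"
            )
        lengths[locus] = len(seq)
        residues = {
            i + 1: (UNKNOWN if c in "-.X" else c) for i, c in enumerate(seq)
        }
        store.add(AlleleSequence(locus=locus, name=name, residues=residues))
    if len(store) == 0:
        raise ValueError(f"{path}: no FASTA records")
    return store


def _load_csv(path: str) -> AlleleStore:
    rows: Dict[str, Dict[int, str]] = {}
    loci: Dict[str, str] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh):
            name = row["name"]
            rows.setdefault(name, {})[int(row["position"])] = row["residue"].upper()
            loci[name] = row.get("locus") or _locus_of(name)
    store = AlleleStore()
    for name, residues in rows.items():
        store.add(AlleleSequence(locus=loci[name], name=name, residues=residues))
    return store


def save_alleles_fasta(store: AlleleStore, path) -> None:
    with open(path, "w") as fh:
        for allele in store.alleles():
            top = max(allele.residues)
            seq = "".join(allele.residues.get(p, UNKNOWN) for p in range(1, top + 1))
            fh.write(f">{allele.name}\n{seq}\n")


# --------------------------------------------------------------------------
# Nearest-neighbour sequence completion

MIN_JOINT_COVERAGE = 0.5  # donors must share >= 50% of the target's known positions


def _hamming(a: AlleleSequence, b: AlleleSequence) -> Tuple[int, int]:
    """(mismatches, joint known positions) over jointly known positions."""
    joint = a.known_positions() & b.known_positions()
    mism = sum(1 for p in joint if a.residues[p] != b.residues[p])
    return mism, len(joint)


def complete_sequences(store: AlleleStore) -> AlleleStore:
    """Fill UNKNOWN residues by iterative nearest neighbour per locus.

    The donor is the same-locus allele with the fewest mismatches over
    jointly known positions (ties broken by lexicographically smallest
    name) that is known at at least one missing position; copied
    residues become known and the search iterates until nothing is
    missing or no donor can fill a position.
    """
    completed = AlleleStore(
        AlleleSequence(a.locus, a.name, dict(a.residues)) for a in store.alleles()
    )
    for locus in completed.loci():
        names = completed.names(locus)
        for name in names:
            target = completed.get(name)
            while target.unknown_positions():
                missing = target.unknown_positions()
                known = target.known_positions()
                best: Tuple[float, str] | None = None
                for other_name in names:
                    if other_name == name:
                        continue
                    other = completed.get(other_name)
                    fillable = missing & other.known_positions()
                    if not fillable:
                        continue
                    mism, joint = _hamming(target, other)
                    if known and joint < MIN_JOINT_COVERAGE * len(known):
                        continue
                    cand = (mism, other_name)
                    if best is None or cand < best:
                        best = cand
                if best is None:
                    pos = min(missing)
                    raise ValueError(
                        f"cannot complete allele {name}: no donor covers position {pos}"
                    )
                donor = completed.get(best[1])
                for p in missing & donor.known_positions():
                    target.residues[p] = donor.residues[p]
    return completed


# --------------------------------------------------------------------------
# Residue configuration sets

def residues_of(
    genotype: Genotype,
    store: AlleleStore,
    loci: Iterable[str] | None = None,
) -> FrozenSet[ResiduePair]:
    """Set of (group-or-locus, position, residue) pairs for a genotype.

    Class I loci (A, B, C) are pooled into one interlocus 'class1'
    position space; class II loci are kept per locus.  Set semantics
    make homozygous loci contribute once.
    """
    genotype.validate(store)
    use = set(loci) if loci is not None else set(genotype.loci())
    pairs: Set[ResiduePair] = set()
    for locus in genotype.loci():
        if locus not in use or locus not in SUPPORTED_LOCI:
            continue
        group = "class1" if locus in CLASS1_LOCI else locus
        for name in set(genotype.at(locus)):
            allele = store.get(name)
            for pos, res in allele.residues.items():
                if res != UNKNOWN:
                    pairs.add((group, pos, res))
    return frozenset(pairs)


def load_typings_csv(path) -> Dict[str, Dict[str, Tuple[str, str]]]:
    """Read subject typings: subject_id, locus, allele1, allele2 columns."""
    out: Dict[str, Dict[str, Tuple[str, str]]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh):
            pair = tuple(sorted((row["allele1"], row["allele2"])))
            out.setdefault(row["subject_id"], {})[row["locus"]] = pair
    return out
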