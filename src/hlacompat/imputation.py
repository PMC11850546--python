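"""Haplotype-frequency imputation of high-resolution genotypes.

Low-resolution typings (first-field allele codes, e.g. ``A*02``) are
expanded into weighted high-resolution genotype distributions using a
population haplotype-frequency table.  Unordered haplotype pairs are
weighted by Hardy–Weinberg probabilities (2·f1·f2, or f² for identical
haplotypes), normalised per subject, filtered at a normalised weight of
1% and renormalised.  Compatibility scores are then aggregated over the
recipient × donor genotype cross product by weighted summation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

from .alleles import Genotype

PAIR_WEIGHT_THRESHOLD = 0.01  # normalised haplotype-pair filter

Haplotype = Tuple[str, ...]  # one allele name per configured locus


@dataclass
class HaplotypeTable:
    loci: Tuple[str, ...]
    populations: Dict[str, Dict[Haplotype, float]]

    def __post_init__(self) -> None:
        # renormalise per population; frequencies need not sum to 1 on input
        for pop, haps in self.populations.items():
            total = sum(haps.values())
            if total <= 0 or any(f <= 0 for f in haps.values()):
                raise ValueError(f"population {pop}: frequencies must be positive")
            self.populations[pop] = {h: f / total for h, f in haps.items()}

    @classmethod
    def from_csv(cls, path) -> "HaplotypeTable":
        """Columns: population, allele_<LOCUS> per locus, frequency."""
        with open(path) as fh:
            reader = csv.DictReader(fh)
            loci = tuple(
                c[len("allele_"):] for c in reader.fieldnames if c.startswith("allele_")
            )
            populations: Dict[str, Dict[Haplotype, float]] = {}
            for row in reader:
                hap = tuple(row[f"allele_{l}"] for l in loci)
                populations.setdefault(row["population"], {})[hap] = float(row["frequency"])
        return cls(loci=loci, populations=populations)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["population"] + [f"allele_{l}" for l in self.loci] + ["frequency"])
            for pop, haps in self.populations.items():
                for hap, f in sorted(haps.items()):
                    w.writerow([pop, *hap, f"{f:.10g}"])


@dataclass
class GenotypeDistribution:
    subject_id: str
    population: str
    genotypes: List[Tuple[Genotype, float]]

    def __post_init__(self) -> None:
        total = sum(w for _g, w in self.genotypes)
        if self.genotypes and abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.subject_id}: weights sum to {total}, expected 1")

    @classmethod
    def degenerate(cls, subject_id: str, genotype: Genotype,
                   population: str = "") -> "GenotypeDistribution":
        return cls(subject_id, population, [(genotype, 1.0)])


def _first_field(code: str) -> str:
    return code.split(":", 1)[0]


def _code_matches(allele_name: str, low_res_code: str) -> bool:
    """An allele is compatible with a low-res code iff first fields agree."""
    return _first_field(allele_name) == _first_field(low_res_code)


def _pair_compatible(
    h1: Haplotype,
    h2: Haplotype,
    typing: Mapping[str, Tuple[str, str]],
    loci: Sequence[str],
) -> bool:
    """Per typed locus the unordered haplotype allele pair must match the
    unordered typing code pair under some assignment."""
    for locus, (c1, c2) in typing.items():
        if locus not in loci:
            continue
        i = loci.index(locus)
        a1, a2 = h1[i], h2[i]
        direct = _code_matches(a1, c1) and _code_matches(a2, c2)
        crossed = _code_matches(a1, c2) and _code_matches(a2, c1)
        if not (direct or crossed):
            return False
    return True


def impute(
    subject_id: str,
    typing: Mapping[str, Tuple[str, str]],
    population: str,
    table: HaplotypeTable,
) -> GenotypeDistribution:
    """Weighted high-resolution genotype distribution for one subject.

    ``typing`` maps locus -> unordered pair of low-resolution codes;
    untyped table loci are imputed freely.
    """
    if population not in table.populations:
        raise KeyError(f"unknown population {population!r}")
    haps = sorted(table.populations[population].items())
    pairs: List[Tuple[Haplotype, Haplotype, float]] = []
    for i, (h1, f1) in enumerate(haps):
        for h2, f2 in haps[i:]:
            if not _pair_compatible(h1, h2, typing, table.loci):
                continue
            weight = f1 * f2 if h1 == h2 else 2.0 * f1 * f2
            pairs.append((h1, h2, weight))
    if not pairs:
        raise ValueError(f"{subject_id}: no haplotype pair compatible with typing {dict(typing)}")
    total = sum(w for _a, _b, w in pairs)
    pairs = [(h1, h2, w / total) for h1, h2, w in pairs]
    pairs = [p for p in pairs if p[2] >= PAIR_WEIGHT_THRESHOLD]
    if not pairs:
        raise ValueError(f"{subject_id}: all haplotype pairs fell below the 1% filter")
    total = sum(w for _a, _b, w in pairs)

    merged: Dict[Genotype, float] = {}
    for h1, h2, w in pairs:
        genotype = Genotype({l: (h1[i], h2[i]) for i, l in enumerate(table.loci)})
        merged[genotype] = merged.get(genotype, 0.0) + w / total
    genotypes = sorted(merged.items(), key=lambda kv: (-kv[1], repr(kv[0].alleles)))
    return GenotypeDistribution(subject_id, population, genotypes)


def aggregate_scores(
    recipient_dist: GenotypeDistribution,
    donor_dist: GenotypeDistribution,
    score_fn: Callable[[Genotype, Genotype], Mapping[str, float] | float],
) -> Dict[str, float]:
    """Weighted sum of scores over the genotype cross product.

    ``score_fn`` may return a single number (reported under 'score') or
    a mapping of metric name -> value; weights are w_recipient × w_donor
    and sum to 1 over the cross product.
    """
    totals: Dict[str, float] = {}
    for r_geno, w_r in recipient_dist.genotypes:
        for d_geno, w_d in donor_dist.genotypes:
            try:
                result = score_fn(r_geno, d_geno)
            except Exception as exc:
                raise RuntimeError(
                    f"score function failed for pair ({recipient_dist.subject_id}, "
                    f"{donor_dist.subject_id}) genotypes {r_geno.alleles} / {d_geno.alleles}"
                ) from exc
            if not isinstance(result, Mapping):
                result = {"score": float(result)}
            w = w_r * w_d
            for key, value in result.items():
                totals[key] = totals.get(key, 0.0) + w * float(value)
    return totals


def write_distribution_csv(dist: GenotypeDistribution, path) -> None:
    loci = sorted({l for g, _w in dist.genotypes for l in g.loci()})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "population", "weight"]
                   + [f"{l}_{i}" for l in loci for i in (1, 2)])
        for genotype, weight in dist.genotypes:
            row = [dist.subject_id, dist.population, f"{weight:.10g}"]
            for l in loci:
                row.extend(genotype.at(l))
            w.writerow(row)
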