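"""Seeded generators for every fixture the package consumes.

These stand in for the access-restricted inputs of a real registry
study: allele stores with planted polymorphisms, idealised lattice
structures with known buried/exposed residues, motif-driven
peptide-binding data, small haplotype pools, eplet registries, and
proportional-hazards cohorts with known coefficients.  Everything is
deterministic given the :class:`SimulationSpec` seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .alleles import (
    CLASS1_LOCI,
    SUPPORTED_LOCI,
    AlleleSequence,
    AlleleStore,
    Genotype,
)
from .binding import AA20, BindingExample, GrooveConfiguration, groove_from_allele
from .matching import EpletDefinition, EpletRegistry, SnowThresholds
from .imputation import HaplotypeTable
from .scoring import PairScoringBackend
from .structures import Atom, Structure
from .survival import EVENT_COL, TIME_COL, log_transform

DEFAULT_CLINICAL_COVARIATES = (
    "donor_age", "recipient_age", "donor_black", "recipient_black",
    "living_donor", "cmv_mismatch", "tacrolimus", "prev_tx",
)


@dataclass(frozen=True)
class SimulationSpec:
    seed: int = 0
    n_subjects: int = 1000
    alleles_per_locus: int = 8
    sequence_length: int = 100
    n_polymorphic: int = 20
    n_haplotypes: int = 12
    population: str = "SYN1"
    binding_motif: Tuple[str, str] = ("K", "Y")  # anchors at core P1 and P9
    coefficients: Mapping[str, float] = field(default_factory=dict)  # per log1p(score)
    clinical_coefficients: Mapping[str, float] = field(default_factory=dict)
    censoring: float = 0.8  # target censored fraction
    generative_thresholds: SnowThresholds = SnowThresholds(0.30, 0.50)
    pirche_rank_threshold: float = 300.0
    weibull_shape: float = 1.2
    baseline_scale_years: float = 20.0
    admin_cutoff_years: float = 15.0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.alleles_per_locus, self.sequence_length,
               self.n_polymorphic, self.n_haplotypes) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.censoring < 1.0:
            raise ValueError("censoring must lie in [0, 1)")


def _rng(spec_seed: int, stream: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{spec_seed}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "little"))


# --------------------------------------------------------------------------
# Allele store

@dataclass
class GeneratedAlleles:
    store: AlleleStore
    polymorphic_positions: Dict[str, List[int]]
    consensus: Dict[str, str]


def gen_allele_store(spec: SimulationSpec) -> GeneratedAlleles:
    """Random but seeded alleles per locus sharing a consensus.

    Alleles differ only at the planted polymorphic positions; class I
    loci share one consensus (their alignment space is pooled
    interlocus), class II loci each draw their own.
    """
    rng = _rng(spec.seed, "alleles")
    letters = np.array(list(AA20))
    L = spec.sequence_length
    class1_consensus = "".join(rng.choice(letters, size=L))
    store = AlleleStore()
    polymorphic: Dict[str, List[int]] = {}
    consensus: Dict[str, str] = {}
    for locus in SUPPORTED_LOCI:
        cons = class1_consensus if locus in CLASS1_LOCI else "".join(rng.choice(letters, size=L))
        consensus[locus] = cons
        positions = sorted(rng.choice(np.arange(1, L + 1), size=spec.n_polymorphic, replace=False))
        polymorphic[locus] = [int(p) for p in positions]
        # 2-3 residue alphabet per polymorphic position, consensus included
        alphabets = {}
        for p in positions:
            extra = rng.choice([a for a in AA20 if a != cons[p - 1]],
                               size=int(rng.integers(1, 3)), replace=False)
            alphabets[p] = [cons[p - 1], *extra]
        for i in range(spec.alleles_per_locus):
            residues = {pos: cons[pos - 1] for pos in range(1, L + 1)}
            for p in positions:
                residues[p] = str(rng.choice(alphabets[p]))
            store.add(AlleleSequence(locus=locus, name=f"{locus}*{i + 1:02d}:01",
                                     residues=residues))
    return GeneratedAlleles(store=store, polymorphic_positions=polymorphic, consensus=consensus)


# --------------------------------------------------------------------------
# Structures

CLUSTER_SIZE = 11          # 1 buried core + 10 shell atoms
CLUSTER_SHELL_RADIUS = 4.6  # Angstrom; shell occludes the core, stays exposed itself
CLUSTER_SPACING = 80.0      # clusters do not interact (SASA or 15 A neighbourhoods)


def _golden_spiral(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack((np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)))


def gen_structure_for_length(n_residues: int, chain_id: str = "A") -> Tuple[Structure, Dict[int, str]]:
    """Toy structure of isolated core+shell clusters with known exposure.

    Each cluster is one central atom ('buried': occluded by the shell
    and near every covering ellipsoid's centre) surrounded by ten shell
    atoms on a sphere ('exposed': solvent-reachable, on the ellipsoid
    boundary).  Clusters are spaced far apart so neither the rolling
    ball nor the 15 A protrusion neighbourhoods couple them.  Residues
    are single-carbon glycines; labels cover every residue.
    """
    shell = _golden_spiral(CLUSTER_SIZE - 1) * CLUSTER_SHELL_RADIUS
    atoms: List[Atom] = []
    chain: Dict[int, str] = {}
    labels: Dict[int, str] = {}
    for idx in range(1, n_residues + 1):
        cluster, member = divmod(idx - 1, CLUSTER_SIZE)
        full = (cluster + 1) * CLUSTER_SIZE <= n_residues
        origin = np.array([cluster * CLUSTER_SPACING, 0.0, 0.0])
        if full:
            coords = origin if member == 0 else origin + shell[member - 1]
        else:  # partial trailing cluster: shell positions only, unlabelled
            coords = origin + shell[member]
        atoms.append(Atom(serial=idx, element="C", coords=coords,
                          residue_index=idx, residue_name="GLY", chain_id=chain_id))
        chain[idx] = "G"
        if full:  # truth labels only for complete clusters
            labels[idx] = "buried" if member == 0 else "exposed"
    return Structure(atoms=atoms, chain_sequences={chain_id: chain}), labels


def gen_structures(generated: GeneratedAlleles) -> Dict[str, Tuple[Structure, Dict[int, str]]]:
    """One lattice structure (plus truth labels) per allele."""
    out = {}
    for allele in generated.store.alleles():
        out[allele.name] = gen_structure_for_length(max(allele.residues))
    return out


def gen_exposure_maps(
    generated: GeneratedAlleles, seed: int = 0, floor: float = 0.02
) -> Dict[str, Dict[int, Tuple[float, float]]]:
    """Synthetic allele exposure maps: U(floor, 1) surface and protrusion.

    Values are strictly positive so the Snow(0.00/0.00) == amino-acid
    mismatch identity holds on these fixtures.
    """
    maps = {}
    for allele in generated.store.alleles():
        rng = _rng(seed, f"exposure:{allele.name}")
        positions = sorted(allele.residues)
        surf = rng.uniform(floor, 1.0, size=len(positions))
        prot = rng.uniform(floor, 1.0, size=len(positions))
        maps[allele.name] = {p: (float(s), float(pr)) for p, s, pr in zip(positions, surf, prot)}
    return maps


# --------------------------------------------------------------------------
# Eplet registry / haplotype table

def gen_eplet_registry(generated: GeneratedAlleles, spec: SimulationSpec,
                       n_eplets: int = 30) -> EpletRegistry:
    rng = _rng(spec.seed, "eplets")
    eplets = []
    groups = ["class1", "DRB1", "DQB1"]
    for i in range(n_eplets):
        group = groups[int(rng.integers(0, len(groups)))]
        locus = {"class1": CLASS1_LOCI[int(rng.integers(0, 3))]}.get(group, group)
        allele = generated.store.get(
            generated.store.names(locus)[int(rng.integers(0, spec.alleles_per_locus))]
        )
        pool = generated.polymorphic_positions[locus]
        size = int(rng.integers(1, min(3, len(pool)) + 1))
        positions = rng.choice(pool, size=size, replace=False)
        reqs = frozenset((int(p), allele.residues[int(p)]) for p in positions)
        eplets.append(EpletDefinition(
            name=f"EP{i:03d}_{group}", locus_group=group, requirements=reqs,
            antibody_verified=bool(rng.random() < 0.5),
        ))
    return EpletRegistry(eplets)


def gen_haplotype_table(generated: GeneratedAlleles, spec: SimulationSpec) -> HaplotypeTable:
    rng = _rng(spec.seed, "haplotypes")
    loci = tuple(SUPPORTED_LOCI)
    haps = {}
    while len(haps) < spec.n_haplotypes:
        hap = tuple(
            generated.store.names(l)[int(rng.integers(0, spec.alleles_per_locus))] for l in loci
        )
        haps.setdefault(hap, None)
    freqs = rng.dirichlet(np.ones(spec.n_haplotypes))
    table = {h: float(f) for h, f in zip(haps, np.maximum(freqs, 1e-4))}
    return HaplotypeTable(loci=loci, populations={spec.population: table})


def sample_genotype(table: HaplotypeTable, population: str, rng: np.random.Generator) -> Genotype:
    haps = sorted(table.populations[population].items())
    freqs = np.array([f for _h, f in haps])
    i, j = rng.choice(len(haps), size=2, p=freqs / freqs.sum())
    h1, h2 = haps[i][0], haps[j][0]
    return Genotype({l: (h1[k], h2[k]) for k, l in enumerate(table.loci)})


def low_res_typing(genotype: Genotype, loci: Sequence[str] = ("A", "B", "DRB1")) -> Dict[str, Tuple[str, str]]:
    out = {}
    for locus in loci:
        a1, a2 = genotype.at(locus)
        out[locus] = tuple(sorted((a1.split(":")[0], a2.split(":")[0])))
    return out


# --------------------------------------------------------------------------
# Binding data and stub predictors

def gen_grooves(generated: GeneratedAlleles,
                positions: Sequence[int] | None = None) -> Dict[str, GrooveConfiguration]:
    return {
        name: groove_from_allele(generated.store.get(name), positions)
        for name in generated.store.names("DRB1")
    }


def gen_binding_data(
    spec: SimulationSpec,
    grooves: Mapping[str, GrooveConfiguration],
    n_examples: int = 2000,
    binder_fraction: float = 0.35,
    binder_ic50: float = 100.0,
    nonbinder_ic50: float = 20_000.0,
    noise_sigma: float = 0.4,
) -> List[BindingExample]:
    """Motif-driven binding data with lognormal IC50 noise.

    Binders carry the planted anchor motif (default K at core position
    1, Y at position 9) at a random core offset.  Grooves modulate the
    rule: every alanine among the groove residues multiplies IC50 by
    0.85, so alanine-rich grooves are more permissive.
    """
    rng = _rng(spec.seed, "binding")
    letters = np.array(list(AA20))
    presenters = sorted(grooves)
    a1, a9 = spec.binding_motif
    out = []
    for _ in range(n_examples):
        pep = list(rng.choice(letters, size=15))
        is_binder = rng.random() < binder_fraction
        if is_binder:
            o = int(rng.integers(0, 7))
            pep[o], pep[o + 8] = a1, a9
        presenter = presenters[int(rng.integers(0, len(presenters)))]
        base = binder_ic50 if is_binder else nonbinder_ic50
        modifier = 0.85 ** grooves[presenter].residues.count("A")
        ic50 = float(np.clip(base * modifier * np.exp(rng.normal(0.0, noise_sigma)),
                             0.1, 5e4))
        out.append(BindingExample(peptide="".join(pep), presenter=presenter, ic50=ic50))
    return out


def gen_proteome(spec: SimulationSpec, n_proteins: int = 40, length: int = 120) -> List[str]:
    rng = _rng(spec.seed, "proteome")
    letters = np.array(list(AA20))
    return ["".join(rng.choice(letters, size=length)) for _ in range(n_proteins)]


class SaturatingBindingStub:
    """Declares every peptide a maximal binder (rank floor, affinity 1)."""

    def __init__(self, rank: float = 0.1):
        self.rank = rank

    def predict_many(self, peptides, presenter):
        n = len(peptides)
        return np.zeros(n, dtype=int), np.ones(n), np.full(n, self.rank)

    def promiscuity(self, presenter, threshold_permille) -> float:
        return 1.0


class HashBindingStub:
    """Cheap deterministic predictor for cohort-scale simulations.

    The permille rank of (core-at-offset-0, presenter) is a stable hash
    mapped uniformly onto (0, 1000]; affinity is the complementary
    fraction.  Statistically this behaves like a calibrated but
    information-free predictor, which is exactly what large simulated
    cohorts need from the T-cell arm when the planted signal lives in
    the rank threshold count.
    """

    def predict_many(self, peptides, presenter):
        n = len(peptides)
        ranks = np.empty(n)
        for i, pep in enumerate(peptides):
            h = hashlib.sha256(f"{pep[:9]}|{presenter}".encode()).digest()
            ranks[i] = (int.from_bytes(h[:4], "little") % 1000) + 1.0
        return np.zeros(n, dtype=int), 1.0 - ranks / 1000.0, ranks

    def promiscuity(self, presenter, threshold_permille) -> float:
        return min(1.0, threshold_permille / 1000.0)


# --------------------------------------------------------------------------
# Cohorts

@dataclass
class CohortTruth:
    spec: SimulationSpec
    coefficients: Dict[str, float]
    clinical_coefficients: Dict[str, float]
    expected_event_rate: float
    censor_rate_per_year: float


def _clinical_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame({
        "donor_age": np.clip(rng.normal(40, 12, n), 10, 75),
        "recipient_age": np.clip(rng.normal(51, 14, n), 18, 80),
        "donor_black": rng.random(n) < 0.12,
        "recipient_black": rng.random(n) < 0.24,
        "living_donor": rng.random(n) < 0.33,
        "cmv_mismatch": rng.random(n) < 0.17,
        "tacrolimus": rng.random(n) < 0.74,
        "prev_tx": rng.poisson(0.15, n),
    }).astype(float)


def _solve_censor_rate(event_times: np.ndarray, cutoff: float, target_censored: float) -> float:
    """Exponential dropout rate whose expected censored fraction hits target."""

    def censored_fraction(rate: float) -> float:
        surv = np.exp(-rate * np.minimum(event_times, cutoff)) * (event_times <= cutoff)
        return float(1.0 - surv.mean())

    if censored_fraction(0.0) >= target_censored:
        return 0.0
    lo, hi = 0.0, 1.0
    while censored_fraction(hi) < target_censored and hi < 1e3:
        hi *= 2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) < target_censored:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_cohort(
    spec: SimulationSpec,
    generated: GeneratedAlleles | None = None,
    backend: PairScoringBackend | None = None,
    table: HaplotypeTable | None = None,
) -> Tuple[pd.DataFrame, List[Tuple[Genotype, Genotype]], CohortTruth, PairScoringBackend]:
    """Proportional-hazards cohort with known coefficients.

    Genotype pairs are drawn from the haplotype table; compatibility
    scores are computed through the real scoring backend; survival
    times follow a Weibull PH model whose log-hazard is linear in the
    log-transformed scores named in ``spec.coefficients`` plus any
    clinical coefficients; censoring combines an administrative cutoff
    with exponential dropout calibrated to the target censored
    fraction.
    """
    generated = generated if generated is not None else gen_allele_store(spec)
    table = table if table is not None else gen_haplotype_table(generated, spec)
    if backend is None:
        backend = PairScoringBackend(
            generated.store,
            gen_exposure_maps(generated, spec.seed),
            model=HashBindingStub(),
        )
    rng = _rng(spec.seed, "cohort")
    n = spec.n_subjects
    pairs = [
        (sample_genotype(table, spec.population, rng),
         sample_genotype(table, spec.population, rng))
        for _ in range(n)
    ]
    df = _clinical_covariates(n, rng)
    thr = spec.generative_thresholds
    df["aa_mm"] = backend.aa_vector(pairs)
    df["snow"] = backend.snow_vector(pairs, thr.snowflake, thr.snowball)
    if backend.model is not None:
        df["pirche_ii"] = backend.pirche_vector(pairs, spec.pirche_rank_threshold)
    if backend.registry is not None:
        ep = np.array([backend.eplets(r, d) for r, d in pairs], dtype=float)
        df["eplet_mm_all"], df["eplet_mm_abv"] = ep[:, 0], ep[:, 1]

    lp = np.zeros(n)
    for metric, coef in spec.coefficients.items():
        if metric not in df.columns:
            raise ValueError(f"coefficient refers to unknown metric {metric!r}")
        lp += coef * log_transform(df[metric].to_numpy())
    for cov, coef in spec.clinical_coefficients.items():
        lp += coef * df[cov].to_numpy()
    lp -= lp.mean()  # centred so the baseline scale sets the time range

    shape, scale = spec.weibull_shape, spec.baseline_scale_years
    event_times = scale * (rng.exponential(1.0, n) / np.exp(lp)) ** (1.0 / shape)
    censor_rate = _solve_censor_rate(event_times, spec.admin_cutoff_years, spec.censoring)
    dropout = (rng.exponential(1.0 / censor_rate, n) if censor_rate > 0
               else np.full(n, np.inf))
    censor_times = np.minimum(dropout, spec.admin_cutoff_years)
    follow_up = np.minimum(event_times, censor_times)
    df[EVENT_COL] = event_times <= censor_times
    df[TIME_COL] = np.maximum(follow_up, 1e-4)

    truth = CohortTruth(
        spec=spec,
        coefficients=dict(spec.coefficients),
        clinical_coefficients=dict(spec.clinical_coefficients),
        expected_event_rate=1.0 - spec.censoring,
        censor_rate_per_year=censor_rate,
    )
    return df, pairs, truth, backend
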