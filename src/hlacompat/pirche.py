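"""PIRCHE-II scoring: indirectly recognisable donor HLA-derived epitopes.

Donor HLA proteins (HLA-A, -B, -C, -DRB1, -DQB1 by default) are cut
into 15-mers whose 9-mer substrings are candidate binding cores.  Cores
occurring anywhere in the recipient's own HLA proteins (target plus
presenting loci) are self and discarded.  The remaining allo cores are
scored against each recipient HLA-DRB1 presenting allele:

* v4 mode counts allo cores whose best containing 15-mer achieves a
  final permille rank at or below the configured rank threshold;
* v3 mode counts allo cores whose best predicted IC50 is below the
  1000 nM affinity threshold (using the in-package predictor, hence
  "v3-mode": it does not reproduce published v3 scores).

The score is the sum of per-presenter counts (homozygous presenters and
homozygous donor loci contribute once).  The promiscuity-corrected
score divides each presenter's count by its background binding
promiscuity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np

from .alleles import AlleleStore, Genotype
from .binding import (
    CORE_LENGTH,
    PEPTIDE_LENGTH,
    BindingModel,
    denormalize_affinity,
    predict_many,
    promiscuity,
)

logger = logging.getLogger(__name__)

DEFAULT_TARGET_LOCI = ("A", "B", "C", "DRB1", "DQB1")
DEFAULT_PRESENTING_LOCI = ("DRB1",)


@dataclass(frozen=True)
class PircheConfig:
    mode: str = "v4"  # 'v4' (rank threshold) or 'v3' (affinity threshold)
    rank_threshold_permille: float = 300.0
    affinity_threshold_nM: float = 1000.0
    target_loci: Tuple[str, ...] = DEFAULT_TARGET_LOCI
    presenting_loci: Tuple[str, ...] = DEFAULT_PRESENTING_LOCI

    def __post_init__(self) -> None:
        if self.mode not in ("v4", "v3"):
            raise ValueError("mode must be 'v4' or 'v3'")
        if self.rank_threshold_permille <= 0 or self.affinity_threshold_nM <= 0:
            raise ValueError("thresholds must be positive")


def _proteins(genotype: Genotype, store: AlleleStore, loci: Sequence[str]) -> Dict[str, str]:
    """Distinct allele name -> contiguous protein over the given loci."""
    out: Dict[str, str] = {}
    for locus in loci:
        if locus not in genotype.alleles:
            continue
        for name in set(genotype.at(locus)):
            out[name] = store.get(name).protein()
    return out


def _kmers(protein: str, k: int) -> Set[str]:
    return {protein[i : i + k] for i in range(len(protein) - k + 1)}


def enumerate_allo_cores(
    recipient: Genotype,
    donor: Genotype,
    store: AlleleStore,
    config: PircheConfig = PircheConfig(),
) -> FrozenSet[Tuple[str, str]]:
    """Non-self donor 9-mer cores as (core, source locus) pairs.

    Self-ness is tested at the 9-mer level against every recipient
    protein over target plus presenting loci; homozygous donor loci
    contribute once by set semantics.
    """
    self_loci = tuple(dict.fromkeys(config.target_loci + config.presenting_loci))
    self_cores: Set[str] = set()
    for protein in _proteins(recipient, store, self_loci).values():
        self_cores |= _kmers(protein, CORE_LENGTH)
    allo: Set[Tuple[str, str]] = set()
    for locus in config.target_loci:
        if locus not in donor.alleles:
            continue
        for name in set(donor.at(locus)):
            for core in _kmers(store.get(name).protein(), CORE_LENGTH):
                if core not in self_cores:
                    allo.add((core, locus))
    return frozenset(allo)


def _core_best_values(
    allo_cores: Sequence[str],
    donor_peptides: Sequence[str],
    model: BindingModel,
    presenter: str,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per allo core: best (lowest) rank and best (highest) affinity
    over the donor 15-mers containing the core as a substring."""
    containing: Dict[str, List[int]] = {c: [] for c in allo_cores}
    for j, pep in enumerate(donor_peptides):
        for o in range(PEPTIDE_LENGTH - CORE_LENGTH + 1):
            sub = pep[o : o + CORE_LENGTH]
            if sub in containing:
                containing[sub].append(j)
    predictor = getattr(model, "predict_many", None)
    if callable(predictor):  # duck-typed stub models
        _offsets, affinities, ranks = predictor(list(donor_peptides), presenter)
    else:
        _offsets, affinities, ranks = predict_many(model, list(donor_peptides), presenter)
    affinities, ranks = np.asarray(affinities), np.asarray(ranks)
    best_rank = np.empty(len(allo_cores))
    best_aff = np.empty(len(allo_cores))
    for i, core in enumerate(allo_cores):
        idx = containing[core]
        if not idx:  # cannot happen for cores derived from these peptides
            best_rank[i], best_aff[i] = np.inf, -np.inf
            continue
        best_rank[i] = ranks[idx].min()
        best_aff[i] = affinities[idx].max()
    return best_rank, best_aff


def _presenters(recipient: Genotype, config: PircheConfig) -> List[str]:
    names: Dict[str, None] = {}
    for locus in config.presenting_loci:
        if locus not in recipient.alleles:
            continue
        for name in set(recipient.at(locus)):
            names.setdefault(name, None)
    return list(names)


def pirche_ii(
    recipient: Genotype,
    donor: Genotype,
    store: AlleleStore,
    model: BindingModel,
    config: PircheConfig = PircheConfig(),
) -> Tuple[int, Dict[str, int]]:
    """PIRCHE-II score: summed per-presenter allo-core binder counts."""
    allo = sorted(enumerate_allo_cores(recipient, donor, store, config))
    presenters = _presenters(recipient, config)
    if not allo or not presenters:
        return 0, {p: 0 for p in presenters}
    cores = [c for c, _l in allo]
    unique_cores = sorted(set(cores))
    donor_peptides = sorted(
        {pep for prot in _proteins(donor, store, config.target_loci).values()
         for pep in _kmers(prot, PEPTIDE_LENGTH)}
    )
    detail: Dict[str, int] = {}
    for presenter in presenters:
        best_rank, best_aff = _core_best_values(unique_cores, donor_peptides, model, presenter)
        if config.mode == "v4":
            binder = best_rank <= config.rank_threshold_permille
        else:
            ic50 = np.array([denormalize_affinity(a) for a in best_aff])
            binder = ic50 < config.affinity_threshold_nM
        # count unique (core, locus) pairs whose core binds
        binder_cores = {unique_cores[i] for i in np.flatnonzero(binder)}
        detail[presenter] = sum(1 for c, _l in allo if c in binder_cores)
    return sum(detail.values()), detail


def pirche_iic(
    recipient: Genotype,
    donor: Genotype,
    store: AlleleStore,
    model: BindingModel,
    config: PircheConfig = PircheConfig(),
    promiscuity_threshold_permille: float | None = None,
) -> float:
    """Promiscuity-corrected score: sum of count_p / promiscuity_p."""
    threshold = (
        promiscuity_threshold_permille
        if promiscuity_threshold_permille is not None
        else config.rank_threshold_permille
    )
    _total, detail = pirche_ii(recipient, donor, store, model, config)
    corrected = 0.0
    for presenter, count in detail.items():
        prom = model_promiscuity(model, presenter, threshold)
        if prom <= 0.0:
            logger.warning("presenter %s has zero promiscuity; contributes 0", presenter)
            continue
        corrected += count / prom
    return corrected


def model_promiscuity(model: BindingModel, presenter: str, threshold_permille: float) -> float:
    """Dispatch allowing stub models to supply their own promiscuity."""
    fn = getattr(model, "promiscuity", None)
    if callable(fn):
        return float(fn(presenter, threshold_permille))
    return promiscuity(model, presenter, threshold_permille)
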