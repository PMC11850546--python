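"""Cohort-scale compatibility scoring with caching.

Threshold optimisation re-scores every recipient-donor pair at many
Snowflake/Snowball/rank grid points.  The expensive work (mismatch
enumeration, peptide binding prediction) does not depend on the
thresholds, so this backend computes it once per distinct genotype pair
and evaluates any grid point as a fast array reduction:

* Snow: per pair, the candidate (surface, protrusion) exposures of each
  mismatched residue configuration; the score at (sf, sb) counts
  mismatches with some candidate strictly above both thresholds.
* PIRCHE: per pair, the pooled array of best permille ranks per
  (presenter, allo core, source locus); the v4 score at rank threshold
  t counts entries <= t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .alleles import AlleleStore, Genotype
from .matching import (
    AlleleExposure,
    EpletRegistry,
    SnowThresholds,
    aa_mismatch,
    eplet_mismatch,
    snow_mismatch_exposures,
    snow_score,
)
from .pirche import PircheConfig, enumerate_allo_cores, _proteins, _kmers
from .binding import PEPTIDE_LENGTH, CORE_LENGTH, predict_many


def _genotype_key(genotype: Genotype) -> Tuple:
    return tuple(sorted(genotype.alleles.items()))


class PairScoringBackend:
    """Caches per-pair score ingredients for threshold-grid evaluation."""

    def __init__(
        self,
        store: AlleleStore,
        exposure: Mapping[str, AlleleExposure],
        model=None,
        registry: EpletRegistry | None = None,
        pirche_config: PircheConfig = PircheConfig(),
    ) -> None:
        self.store = store
        self.exposure = exposure
        self.model = model
        self.registry = registry
        self.pirche_config = pirche_config
        self._snow_cache: Dict[Tuple, List[np.ndarray]] = {}
        self._aa_cache: Dict[Tuple, int] = {}
        self._eplet_cache: Dict[Tuple, Tuple[int, int]] = {}
        self._rank_cache: Dict[Tuple, np.ndarray] = {}
        # (presenter, peptide) -> (affinity, rank)
        self._prediction_cache: Dict[Tuple[str, str], Tuple[float, float]] = {}

    # -- Snow / amino acid ------------------------------------------------

    def _pair_key(self, recipient: Genotype, donor: Genotype) -> Tuple:
        return (_genotype_key(recipient), _genotype_key(donor))

    def _snow_candidates(self, recipient: Genotype, donor: Genotype) -> List[np.ndarray]:
        key = self._pair_key(recipient, donor)
        if key not in self._snow_cache:
            cands = snow_mismatch_exposures(recipient, donor, self.store, self.exposure)
            self._snow_cache[key] = [np.asarray(c, dtype=float) for c in cands]
        return self._snow_cache[key]

    def aa(self, recipient: Genotype, donor: Genotype) -> int:
        key = self._pair_key(recipient, donor)
        if key not in self._aa_cache:
            self._aa_cache[key] = aa_mismatch(recipient, donor, self.store)[0]
        return self._aa_cache[key]

    def snow(self, recipient: Genotype, donor: Genotype, snowflake: float, snowball: float) -> int:
        count = 0
        for cand in self._snow_candidates(recipient, donor):
            if np.any((cand[:, 0] > snowflake) & (cand[:, 1] > snowball)):
                count += 1
        return count

    def eplets(self, recipient: Genotype, donor: Genotype) -> Tuple[int, int]:
        """(all, antibody-verified) eplet mismatch counts."""
        if self.registry is None:
            raise ValueError("no eplet registry configured")
        key = self._pair_key(recipient, donor)
        if key not in self._eplet_cache:
            all_mm, _ = eplet_mismatch(recipient, donor, self.store, self.registry, False)
            abv_mm, _ = eplet_mismatch(recipient, donor, self.store, self.registry, True)
            self._eplet_cache[key] = (all_mm, abv_mm)
        return self._eplet_cache[key]

    # -- PIRCHE -----------------------------------------------------------

    def _predict_cached(self, peptides: Sequence[str], presenter: str) -> Dict[str, Tuple[float, float]]:
        missing = [p for p in peptides if (presenter, p) not in self._prediction_cache]
        if missing:
            predictor = getattr(self.model, "predict_many", None)
            if callable(predictor):
                _o, aff, ranks = predictor(missing, presenter)
            else:
                _o, aff, ranks = predict_many(self.model, missing, presenter)
            for p, a, r in zip(missing, np.asarray(aff), np.asarray(ranks)):
                self._prediction_cache[(presenter, p)] = (float(a), float(r))
        return {p: self._prediction_cache[(presenter, p)] for p in peptides}

    def _pair_ranks(self, recipient: Genotype, donor: Genotype) -> np.ndarray:
        """Pooled best ranks per (presenter, allo core, source locus)."""
        if self.model is None:
            raise ValueError("no binding model configured")
        key = self._pair_key(recipient, donor)
        if key in self._rank_cache:
            return self._rank_cache[key]
        cfg = self.pirche_config
        allo = sorted(enumerate_allo_cores(recipient, donor, self.store, cfg))
        presenters = sorted(
            {n for locus in cfg.presenting_loci if locus in recipient.alleles
             for n in recipient.at(locus)}
        )
        if not allo or not presenters:
            self._rank_cache[key] = np.empty(0)
            return self._rank_cache[key]
        donor_peptides = sorted(
            {pep for prot in _proteins(donor, self.store, cfg.target_loci).values()
             for pep in _kmers(prot, PEPTIDE_LENGTH)}
        )
        containing: Dict[str, List[str]] = {}
        for pep in donor_peptides:
            for o in range(PEPTIDE_LENGTH - CORE_LENGTH + 1):
                containing.setdefault(pep[o : o + CORE_LENGTH], []).append(pep)
        ranks: List[float] = []
        for presenter in presenters:
            pred = self._predict_cached(donor_peptides, presenter)
            for core, _locus in allo:
                best = min(pred[p][1] for p in containing.get(core, ()))
                ranks.append(best)
        out = np.asarray(ranks)
        self._rank_cache[key] = out
        return out

    def pirche(self, recipient: Genotype, donor: Genotype, rank_threshold_permille: float) -> int:
        ranks = self._pair_ranks(recipient, donor)
        return int(np.sum(ranks <= rank_threshold_permille))

    # -- combined ---------------------------------------------------------

    def scores(
        self,
        recipient: Genotype,
        donor: Genotype,
        thresholds: SnowThresholds = SnowThresholds(),
        rank_threshold_permille: float | None = None,
    ) -> Dict[str, float]:
        out: Dict[str, float] = {
            "aa_mm": float(self.aa(recipient, donor)),
            "snow": float(self.snow(recipient, donor, thresholds.snowflake, thresholds.snowball)),
        }
        if self.registry is not None:
            all_mm, abv_mm = self.eplets(recipient, donor)
            out["eplet_mm_all"] = float(all_mm)
            out["eplet_mm_abv"] = float(abv_mm)
        if self.model is not None:
            rank_t = (
                rank_threshold_permille
                if rank_threshold_permille is not None
                else self.pirche_config.rank_threshold_permille
            )
            out["pirche_ii"] = float(self.pirche(recipient, donor, rank_t))
        return out

    # -- cohort-level vectors ---------------------------------------------

    def _snow_flat(self, pairs: Sequence[Tuple[Genotype, Genotype]]):
        """Flattened candidate exposures for fast grid evaluation.

        Cached by the identity of ``pairs`` (the sequence must not be
        mutated between calls).  Returns (surface, protrusion,
        mismatch-group id, pair id per group, n_pairs).
        """
        cache_key = (id(pairs), len(pairs))
        cached = getattr(self, "_flat_cache", None)
        if cached is None:
            cached = self._flat_cache = {}
        if cache_key in cached:
            return cached[cache_key]
        surf, prot, group_of_cand, pair_of_group = [], [], [], []
        g = 0
        for i, (r, d) in enumerate(pairs):
            for cand in self._snow_candidates(r, d):
                surf.append(cand[:, 0])
                prot.append(cand[:, 1])
                group_of_cand.append(np.full(len(cand), g))
                pair_of_group.append(i)
                g += 1
        flat = (
            np.concatenate(surf) if surf else np.empty(0),
            np.concatenate(prot) if prot else np.empty(0),
            np.concatenate(group_of_cand).astype(int) if group_of_cand else np.empty(0, int),
            np.asarray(pair_of_group, dtype=int),
            len(pairs),
        )
        cached[cache_key] = flat
        return flat

    def snow_vector(
        self, pairs: Sequence[Tuple[Genotype, Genotype]], snowflake: float, snowball: float
    ) -> np.ndarray:
        surf, prot, group_of_cand, pair_of_group, n = self._snow_flat(pairs)
        if surf.size == 0:
            return np.zeros(n)
        hit_groups = np.unique(group_of_cand[(surf > snowflake) & (prot > snowball)])
        return np.bincount(pair_of_group[hit_groups], minlength=n).astype(float)

    def pirche_vector(
        self, pairs: Sequence[Tuple[Genotype, Genotype]], rank_threshold_permille: float
    ) -> np.ndarray:
        return np.array(
            [self.pirche(r, d, rank_threshold_permille) for r, d in pairs], dtype=float
        )

    def aa_vector(self, pairs: Sequence[Tuple[Genotype, Genotype]]) -> np.ndarray:
        return np.array([self.aa(r, d) for r, d in pairs], dtype=float)
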