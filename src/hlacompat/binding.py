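"""Peptide–HLA-DRB1 binding prediction with an ANN ensemble.

A pool of small feed-forward networks (two hidden ReLU layers, Adam) is
trained on BLOSUM-62 encoded 9-mer binding cores concatenated with the
presenting molecule's binding-groove residues; the best ``keep``
networks by held-out error form the ensemble.  At prediction time each
network votes for a binding core among the seven 9-mer offsets of a
15-mer; networks agreeing on the majority core contribute their
predicted affinity (averaged) and their permille rank against a
human-proteome background of random 15-mers (combined by geometric
mean).

Training targets are IC50 values normalised by 1 - log(IC50)/log(50000)
clipped to [0, 1] (the de-facto community transform).  Core labels are
not observed: they are initialised from an anchor-propensity heuristic
and re-assigned from the network's own predictions every 100 training
iterations (self-consistent core supervision).
"""

from __future__ import annotations

import csv
import pickle
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AA20)
PEPTIDE_LENGTH = 15
CORE_LENGTH = 9
N_OFFSETS = PEPTIDE_LENGTH - CORE_LENGTH + 1  # 7
IC50_CEILING = 50_000.0
MODEL_VERSION = "hlacompat-frost-1"

# Kyte-Doolittle hydropathy, used only to seed the core assignment.
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def _blosum62_rows() -> Dict[str, np.ndarray]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    rows: Dict[str, np.ndarray] = {}
    for a in AA20:
        rows[a] = np.array([mat[a, b] for b in AA20], dtype=float) / 10.0
    return rows


_BLOSUM_ROWS = _blosum62_rows()


def default_groove_positions() -> List[int]:
    with resources.files("hlacompat.data").joinpath("groove_positions.csv").open() as fh:
        rows = [r for r in fh if not r.startswith("#")]
    return [int(r["position"]) for r in csv.DictReader(rows)]


@dataclass(frozen=True)
class GrooveConfiguration:
    """Residues of a presenting allele at the configured groove positions."""

    allele: str
    residues: str
    positions: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.positions):
            raise ValueError(
                f"{self.allele}: {len(self.residues)} groove residues for "
                f"{len(self.positions)} positions"
            )


def groove_from_allele(allele_seq, positions: Sequence[int] | None = None) -> GrooveConfiguration:
    """Build a groove configuration from an :class:`AlleleSequence`."""
    positions = list(positions) if positions is not None else default_groove_positions()
    residues = []
    for p in positions:
        r = allele_seq.residues.get(p)
        if r is None or r == "X":
            raise ValueError(f"{allele_seq.name}: groove position {p} is undefined")
        residues.append(r)
    return GrooveConfiguration(allele_seq.name, "".join(residues), tuple(positions))


def derive_groove_positions(structure, peptide_chain: str, receptor_chain: str,
                            cutoff: float = 4.0) -> List[int]:
    """Receptor residues with a heavy atom within ``cutoff`` A of the peptide."""
    from scipy.spatial import cKDTree

    pep = np.array([a.coords for a in structure.atoms if a.chain_id == peptide_chain])
    if pep.size == 0:
        raise ValueError(f"no atoms in peptide chain {peptide_chain!r}")
    tree = cKDTree(pep)
    positions = set()
    for atom in structure.atoms:
        if atom.chain_id != receptor_chain or atom.element == "H":
            continue
        if tree.query(atom.coords)[0] <= cutoff:
            positions.add(atom.residue_index)
    return sorted(positions)


@dataclass(frozen=True)
class BindingExample:
    peptide: str
    presenter: str
    ic50: float

    def __post_init__(self) -> None:
        if len(self.peptide) != PEPTIDE_LENGTH or set(self.peptide) - _AA_SET:
            raise ValueError(f"peptide must be a 15-mer over the 20-letter alphabet: {self.peptide!r}")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")

    @property
    def normalized_affinity(self) -> float:
        return normalize_affinity(self.ic50)


@dataclass(frozen=True)
class BindingPrediction:
    peptide: str
    presenter: str
    core: str
    core_offset: int
    normalized_affinity: float
    rank_permille: float

    def __post_init__(self) -> None:
        if self.peptide[self.core_offset : self.core_offset + CORE_LENGTH] != self.core:
            raise ValueError("core is not a substring of peptide at the stated offset")


def normalize_affinity(ic50: float) -> float:
    """1 - log(IC50)/log(50000), clipped to [0, 1]."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    return float(np.clip(1.0 - np.log(ic50) / np.log(IC50_CEILING), 0.0, 1.0))


def denormalize_affinity(affinity: float) -> float:
    """Inverse of :func:`normalize_affinity` (IC50 in nM)."""
    return float(IC50_CEILING ** (1.0 - affinity))


def encode(core: str, groove: GrooveConfiguration) -> np.ndarray:
    """BLOSUM-62 row per core position then per groove position."""
    if len(core) != CORE_LENGTH:
        raise ValueError("core must be a 9-mer")
    parts = []
    for c in core + groove.residues:
        try:
            parts.append(_BLOSUM_ROWS[c])
        except KeyError:
            raise ValueError(f"invalid amino acid letter {c!r}") from None
    return np.concatenate(parts)


_ROW_MATRIX = np.stack([_BLOSUM_ROWS[a] for a in AA20])  # (20, 20)
_CODE = np.full(128, -1, dtype=np.int8)
for _i, _a in enumerate(AA20):
    _CODE[ord(_a)] = _i


def _peptide_codes(peptides: Sequence[str]) -> np.ndarray:
    flat = np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8)
    codes = _CODE[flat].reshape(len(peptides), PEPTIDE_LENGTH)
    if (codes < 0).any():
        raise ValueError("peptide contains a letter outside the 20-letter alphabet")
    return codes


def _encode_offsets(peptides: Sequence[str], groove: GrooveConfiguration) -> np.ndarray:
    """Feature matrix for every (peptide, offset): shape (n*7, dim)."""
    n = len(peptides)
    codes = _peptide_codes(peptides)
    groove_part = np.concatenate([_BLOSUM_ROWS[c] for c in groove.residues])
    X = np.empty((n * N_OFFSETS, CORE_LENGTH * 20 + groove_part.size))
    for o in range(N_OFFSETS):
        core_feats = _ROW_MATRIX[codes[:, o : o + CORE_LENGTH]].reshape(n, CORE_LENGTH * 20)
        X[o::N_OFFSETS, : CORE_LENGTH * 20] = core_feats
    X[:, CORE_LENGTH * 20 :] = groove_part
    return X


def anchor_offsets(peptides: Sequence[str]) -> np.ndarray:
    """Hydrophobic-anchor propensity core offsets (P1 + P9 hydropathy).

    Provided as a diagnostic/baseline register guess; ensemble training
    deliberately starts from random registers instead, because a
    propensity prior becomes a self-consistent wrong register whenever
    the true anchors are hydrophilic.
    """
    offsets = np.empty(len(peptides), dtype=int)
    for i, pep in enumerate(peptides):
        scores = [
            _KYTE_DOOLITTLE[pep[o]] + _KYTE_DOOLITTLE[pep[o + CORE_LENGTH - 1]]
            for o in range(N_OFFSETS)
        ]
        offsets[i] = int(np.argmax(scores))
    return offsets


@dataclass
class _Network:
    regressor: object
    heldout_mse: float
    seed: int

    def predict_offsets(self, X_offsets: np.ndarray, n: int) -> np.ndarray:
        """(n, 7) affinity matrix from a stacked offset feature matrix."""
        return self.regressor.predict(X_offsets).reshape(n, N_OFFSETS)


@dataclass
class BindingModel:
    networks: List[_Network]
    grooves: Dict[str, GrooveConfiguration]
    candidate_scores: List[float]
    seed: int
    iterations: int
    version: str = MODEL_VERSION
    # presenter -> dict(peptides=list[str], affinities=(n_networks, n) sorted per network)
    background: Dict[str, Dict[str, object]] = field(default_factory=dict)

    def groove(self, presenter: str) -> GrooveConfiguration:
        try:
            return self.grooves[presenter]
        except KeyError:
            raise KeyError(f"no groove configuration for presenter {presenter!r}") from None


def train_ensemble(
    examples: Sequence[BindingExample],
    grooves: Mapping[str, GrooveConfiguration],
    pool_size: int = 512,
    keep: int = 128,
    iterations: int = 1000,
    seed: int = 0,
    hidden: Tuple[int, int] = (64, 32),
    reassign_every: int = 100,
    test_fraction: float = 0.2,
    binder_cutoff_nM: float = 500.0,
) -> BindingModel:
    """Train ``pool_size`` networks and keep the ``keep`` best.

    Each network gets its own random initialisation and train/test split
    (derived from ``seed``); selection is by held-out MSE on normalised
    affinities.  Core supervision is self-consistent: binder examples
    (IC50 below ``binder_cutoff_nM``) train on a single assigned core
    that is re-derived from the network's own predictions every
    ``reassign_every`` iterations, while non-binders contribute every
    core offset as a negative example (any register of a non-binder is
    a non-binding core), which anchors the register search.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.neural_network import MLPRegressor

    if keep > pool_size:
        raise ValueError("keep must not exceed pool_size")
    if len(examples) < 100:
        raise ValueError("need at least 100 training examples")

    peptides = [e.peptide for e in examples]
    presenters = [e.presenter for e in examples]
    targets = np.array([e.normalized_affinity for e in examples])
    for p in set(presenters):
        if p not in grooves:
            raise KeyError(f"no groove configuration for presenter {p!r}")

    # all-offset features, grouped per presenter, computed once
    X_all = np.empty((len(examples) * N_OFFSETS, (CORE_LENGTH + len(next(iter(grooves.values())).positions)) * 20))
    for p in set(presenters):
        idx = [i for i, pr in enumerate(presenters) if pr == p]
        Xp = _encode_offsets([peptides[i] for i in idx], grooves[p])
        for k, i in enumerate(idx):
            X_all[i * N_OFFSETS : (i + 1) * N_OFFSETS] = Xp[k * N_OFFSETS : (k + 1) * N_OFFSETS]
    binder_cut = normalize_affinity(binder_cutoff_nM)
    is_binder = targets >= binder_cut

    def training_rows(offsets: np.ndarray, rows: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(feature row indices into X_all, targets) for a training split."""
        idx_parts, y_parts = [], []
        binder_rows = rows[is_binder[rows]]
        nonbinder_rows = rows[~is_binder[rows]]
        if len(binder_rows):
            idx_parts.append(binder_rows * N_OFFSETS + offsets[binder_rows])
            y_parts.append(targets[binder_rows])
        if len(nonbinder_rows):
            idx_parts.append(
                (np.repeat(nonbinder_rows, N_OFFSETS) * N_OFFSETS
                 + np.tile(np.arange(N_OFFSETS), len(nonbinder_rows)))
            )
            y_parts.append(np.repeat(targets[nonbinder_rows], N_OFFSETS))
        return np.concatenate(idx_parts), np.concatenate(y_parts)

    root = np.random.SeedSequence(seed)
    net_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(pool_size)]

    networks: List[_Network] = []
    n = len(examples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for net_seed in net_seeds:
            rng = np.random.default_rng(net_seed)
            perm = rng.permutation(n)
            n_test = max(1, int(round(test_fraction * n)))
            test_rows, train_rows = perm[:n_test], perm[n_test:]
            # random initial registers per network: a Gibbs-style search
            # that the per-network ensemble diversity depends on
            offsets = rng.integers(0, N_OFFSETS, n)
            reg = MLPRegressor(
                hidden_layer_sizes=hidden,
                activation="relu",
                solver="adam",
                random_state=net_seed,
                max_iter=max(1, min(reassign_every, iterations)),
                warm_start=True,
                batch_size=512,  # large minibatches keep the BLAS busy
                tol=0.0,
                n_iter_no_change=10**9,
            )
            done = 0
            while done < iterations:
                chunk = min(reassign_every, iterations - done)
                reg.max_iter = max(1, chunk)
                feat_idx, y = training_rows(offsets, train_rows)
                reg.fit(X_all[feat_idx], y)
                done += chunk
                if done < iterations:  # self-consistent core re-assignment
                    binder_rows = train_rows[is_binder[train_rows]]
                    if len(binder_rows):
                        pred = reg.predict(
                            X_all[np.repeat(binder_rows, N_OFFSETS) * N_OFFSETS
                                  + np.tile(np.arange(N_OFFSETS), len(binder_rows))]
                        )
                        offsets[binder_rows] = pred.reshape(len(binder_rows), N_OFFSETS).argmax(axis=1)
            # held-out error: predicted affinity is the max over offsets
            pred_test = reg.predict(
                X_all[np.repeat(test_rows, N_OFFSETS) * N_OFFSETS
                      + np.tile(np.arange(N_OFFSETS), len(test_rows))]
            ).reshape(len(test_rows), N_OFFSETS).max(axis=1)
            mse = float(np.mean((pred_test - targets[test_rows]) ** 2))
            networks.append(_Network(regressor=reg, heldout_mse=mse, seed=net_seed))

    order = np.argsort([net.heldout_mse for net in networks], kind="stable")
    selected = [networks[i] for i in order[:keep]]
    return BindingModel(
        networks=selected,
        grooves=dict(grooves),
        candidate_scores=[net.heldout_mse for net in networks],
        seed=seed,
        iterations=iterations,
    )


# --------------------------------------------------------------------------
# Rank background

def sample_background_peptides(
    proteome: Sequence[str], n_background: int, seed: int
) -> List[str]:
    """Uniform sample of 15-mers over all valid proteome positions."""
    starts: List[Tuple[int, int]] = []
    for i, prot in enumerate(proteome):
        for s in range(len(prot) - PEPTIDE_LENGTH + 1):
            starts.append((i, s))
    if not starts:
        raise ValueError("proteome contains no sequence of length >= 15")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(starts), size=n_background)
    return [proteome[starts[k][0]][starts[k][1] : starts[k][1] + PEPTIDE_LENGTH] for k in picks]


def _network_affinities(
    model: BindingModel, peptides: Sequence[str], presenter: str, batch: int = 2000
) -> np.ndarray:
    """(n_networks, n_peptides) max-over-offset affinities."""
    groove = model.groove(presenter)
    out = np.empty((len(model.networks), len(peptides)))
    for start in range(0, len(peptides), batch):
        chunk = peptides[start : start + batch]
        X = _encode_offsets(chunk, groove)
        for k, net in enumerate(model.networks):
            out[k, start : start + len(chunk)] = net.predict_offsets(X, len(chunk)).max(axis=1)
    return out


def build_rank_background(
    model: BindingModel,
    proteome: Sequence[str],
    n_background: int = 10_000,
    seed: int = 0,
    presenters: Iterable[str] | None = None,
) -> BindingModel:
    """Attach sorted background rank tables per presenter (in place).

    All networks share one background peptide sample; each network's
    predicted (max-over-offset) affinities are stored sorted for
    O(log n) rank queries.  The voting pipeline is then run on the
    background itself and the resulting raw geometric-mean ranks are
    stored sorted: the final reported rank maps a query's raw geometric
    mean through this empirical distribution, so that "r permille"
    keeps its meaning (r/1000 of random human 15-mers score at least as
    well) even though a geometric mean of uniform ranks is itself not
    uniform.
    """
    peptides = sample_background_peptides(proteome, n_background, seed)
    for presenter in presenters if presenters is not None else model.grooves:
        aff = _network_affinities(model, peptides, presenter)
        model.background[presenter] = {
            "peptides": peptides,
            "sorted_affinities": np.sort(aff, axis=1),
        }
        _o, _a, raw = predict_many(model, peptides, presenter, calibrated=False)
        model.background[presenter]["sorted_raw_final"] = np.sort(raw)
    return model


def _ranks_permille(sorted_bg: np.ndarray, affinities: np.ndarray) -> np.ndarray:
    """Permille ranks with the >= tie convention and a 1000/n floor.

    ``sorted_bg``: (n_networks, n_bg) ascending; ``affinities``:
    (n_networks, n_peptides).  rank = 1000 * #{bg >= a} / n_bg.
    """
    n_bg = sorted_bg.shape[1]
    ranks = np.empty_like(affinities)
    for k in range(sorted_bg.shape[0]):
        geq = n_bg - np.searchsorted(sorted_bg[k], affinities[k], side="left")
        ranks[k] = 1000.0 * np.maximum(geq, 1) / n_bg
    return ranks


def predict_many(
    model: BindingModel, peptides: Sequence[str], presenter: str, batch: int = 2000,
    calibrated: bool = True,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised ensemble prediction.

    Returns (core_offsets, normalized_affinities, ranks_permille), each
    of shape (n_peptides,).  Per peptide: each network votes its best
    offset; the modal offset wins (ties -> lowest offset); affinity is
    the mean over agreeing networks; ranks from the agreeing networks
    are combined by geometric mean and, with ``calibrated`` (the
    default), mapped through the background's empirical distribution of
    that same statistic so the reported permille stays uniform on
    random peptides.
    """
    bg = model.background.get(presenter)
    if bg is None:
        raise KeyError(f"no rank background for presenter {presenter!r}; "
                       "call build_rank_background first")
    groove = model.groove(presenter)
    n = len(peptides)
    n_nets = len(model.networks)
    core_offsets = np.empty(n, dtype=int)
    affinities = np.empty(n)
    ranks = np.empty(n)
    sorted_bg = bg["sorted_affinities"]
    for start in range(0, n, batch):
        chunk = peptides[start : start + batch]
        X = _encode_offsets(chunk, groove)
        per_net = np.stack(
            [net.predict_offsets(X, len(chunk)) for net in model.networks]
        )  # (n_nets, m, 7)
        best_offsets = per_net.argmax(axis=2)  # (n_nets, m)
        for j in range(len(chunk)):
            votes = np.bincount(best_offsets[:, j], minlength=N_OFFSETS)
            modal = int(votes.argmax())  # argmax returns the lowest tied offset
            agree = np.flatnonzero(best_offsets[:, j] == modal)
            aff_agree = per_net[agree, j, modal]
            net_ranks = _ranks_permille(sorted_bg[agree], aff_agree[:, None]).ravel()
            core_offsets[start + j] = modal
            affinities[start + j] = float(aff_agree.mean())
            ranks[start + j] = float(np.exp(np.mean(np.log(net_ranks))))
    if calibrated:
        raw_bg = bg.get("sorted_raw_final")
        if raw_bg is None:
            raise KeyError(f"rank background for {presenter!r} lacks the final-rank "
                           "calibration table; rebuild with build_rank_background")
        n_bg = len(raw_bg)
        counts = np.searchsorted(raw_bg, ranks, side="right")
        ranks = 1000.0 * np.maximum(counts, 1) / n_bg
    return core_offsets, affinities, ranks


def predict(model: BindingModel, peptide: str, presenter: str) -> BindingPrediction:
    """Single-peptide convenience wrapper around :func:`predict_many`."""
    offsets, affinities, ranks = predict_many(model, [peptide], presenter)
    o = int(offsets[0])
    return BindingPrediction(
        peptide=peptide,
        presenter=presenter,
        core=peptide[o : o + CORE_LENGTH],
        core_offset=o,
        normalized_affinity=float(affinities[0]),
        rank_permille=float(ranks[0]),
    )


def promiscuity(model: BindingModel, presenter: str, threshold_permille: float) -> float:
    """Fraction of background peptides with final rank <= threshold."""
    bg = model.background.get(presenter)
    if bg is None:
        raise KeyError(f"no rank background for presenter {presenter!r}")
    _o, _a, ranks = predict_many(model, bg["peptides"], presenter)
    return float(np.mean(ranks <= threshold_permille))


# --------------------------------------------------------------------------
# Serialisation and data I/O

def save_model(model: BindingModel, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"version": model.version, "model": model}, fh)


def load_model(path) -> BindingModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != MODEL_VERSION:
        raise ValueError(f"unsupported model artifact version {payload.get('version')!r}")
    return payload["model"]


def load_binding_csv(path, columns: Mapping[str, str] | None = None) -> List[BindingExample]:
    """Read binding data; default columns peptide, presenter, ic50_nM."""
    cols = {"peptide": "peptide", "presenter": "presenter", "ic50": "ic50_nM"}
    if columns:
        cols.update(columns)
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            out.append(
                BindingExample(
                    peptide=row[cols["peptide"]].upper(),
                    presenter=row[cols["presenter"]],
                    ic50=float(row[cols["ic50"]]),
                )
            )
    return out
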