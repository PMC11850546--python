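"""Encoding, affinity transform, ensemble mechanics and rank calibration."""

import numpy as np
import pytest

from hlacompat.binding import (
    BindingExample,
    BindingPrediction,
    GrooveConfiguration,
    build_rank_background,
    default_groove_positions,
    denormalize_affinity,
    encode,
    normalize_affinity,
    predict,
    predict_many,
    promiscuity,
    sample_background_peptides,
    save_model,
    load_model,
    train_ensemble,
    _ranks_permille,
)
from hlacompat.synthetic import SimulationSpec, gen_binding_data, gen_proteome


@pytest.fixture(scope="module")
def tiny_model(grooves):
    """Smoke-scale ensemble shared across the mechanical tests."""
    spec = SimulationSpec(seed=3)
    from hlacompat.synthetic import gen_allele_store, gen_grooves

    generated = gen_allele_store(spec)
    grooves = gen_grooves(generated)
    examples = gen_binding_data(spec, grooves, n_examples=300)
    model = train_ensemble(examples, grooves, pool_size=4, keep=2,
                           iterations=40, seed=0, reassign_every=20)
    proteome = gen_proteome(spec, n_proteins=10)
    build_rank_background(model, proteome, n_background=500, seed=1)
    return model, examples


ALL_A_GROOVE = GrooveConfiguration("X", "A" * 25, tuple(default_groove_positions()))


def test_encode_shape_and_blocks():
    vec = encode("A" * 9, ALL_A_GROOVE)
    assert vec.shape == (680,)
    blocks = vec.reshape(34, 20)
    assert np.allclose(blocks, blocks[0])  # every position is alanine


def test_encode_single_substitution_changes_one_block():
    v1 = encode("A" * 9, ALL_A_GROOVE)
    v2 = encode("A" * 4 + "K" + "A" * 4, ALL_A_GROOVE)
    diff_blocks = np.flatnonzero(
        np.any(v1.reshape(34, 20) != v2.reshape(34, 20), axis=1)
    )
    assert list(diff_blocks) == [4]


def test_encode_invalid_letter():
    with pytest.raises(ValueError, match="invalid"):
        encode("A" * 8 + "Z", ALL_A_GROOVE)


@pytest.mark.parametrize("ic50,expected", [
    (50_000.0, 0.0),
    (1.0, 1.0),
    (1000.0, 1.0 - np.log(1000) / np.log(50_000)),
])
def test_normalize_affinity_endpoints(ic50, expected):
    assert normalize_affinity(ic50) == pytest.approx(expected, abs=1e-9)
    if 0 < expected < 1:
        assert denormalize_affinity(normalize_affinity(ic50)) == pytest.approx(ic50, rel=1e-9)


def test_normalize_affinity_rejects_nonpositive():
    with pytest.raises(ValueError):
        normalize_affinity(0.0)


def test_binding_example_validation():
    with pytest.raises(ValueError, match="15-mer"):
        BindingExample("SHORT", "X", 100.0)
    with pytest.raises(ValueError, match="positive"):
        BindingExample("A" * 15, "X", -1.0)


def test_prediction_core_consistency():
    with pytest.raises(ValueError, match="substring"):
        BindingPrediction("A" * 15, "X", "K" * 9, 0, 0.5, 100.0)


def test_ensemble_size_and_metadata(tiny_model):
    model, _ = tiny_model
    assert len(model.networks) == 2
    assert len(model.candidate_scores) == 4


def test_ensemble_selection_keeps_best(tiny_model):
    model, _ = tiny_model
    kept = sorted(net.heldout_mse for net in model.networks)
    assert max(kept) <= min(
        s for s in model.candidate_scores if s not in kept
    ) + 1e-12


def test_keep_exceeding_pool_raises(grooves):
    with pytest.raises(ValueError, match="keep"):
        train_ensemble([], grooves, pool_size=2, keep=4)


def test_same_seed_reproduces(grooves):
    spec = SimulationSpec(seed=3)
    from hlacompat.synthetic import gen_allele_store, gen_grooves

    generated = gen_allele_store(spec)
    grooves = gen_grooves(generated)
    examples = gen_binding_data(spec, grooves, n_examples=150)
    m1 = train_ensemble(examples, grooves, pool_size=2, keep=1, iterations=20, seed=9)
    m2 = train_ensemble(examples, grooves, pool_size=2, keep=1, iterations=20, seed=9)
    assert [n.seed for n in m1.networks] == [n.seed for n in m2.networks]
    proteome = gen_proteome(spec, n_proteins=5)
    build_rank_background(m1, proteome, n_background=200, seed=4)
    build_rank_background(m2, proteome, n_background=200, seed=4)
    p = examples[0]
    pred1 = predict(m1, p.peptide, p.presenter)
    pred2 = predict(m2, p.peptide, p.presenter)
    assert pred1 == pred2


def test_geometric_mean_rank_arithmetic():
    sorted_bg = np.array([[0.1, 0.2, 0.9], [0.1, 0.2, 0.9]])
    # affinities chosen so network ranks are 1000*1/3 and 1000*3/3
    ranks = _ranks_permille(sorted_bg, np.array([[0.95], [0.05]]))
    assert ranks[0, 0] == pytest.approx(1000 / 3)
    assert ranks[1, 0] == pytest.approx(1000.0)


def test_rank_tie_and_floor_conventions(tiny_model):
    model, examples = tiny_model
    presenter = examples[0].presenter
    bg = model.background[presenter]
    n_bg = len(bg["peptides"])
    # a peptide never outranks itself: query equal to the strongest
    # background affinity still has rank >= 1000/n
    strongest = bg["sorted_affinities"][:, -1]
    ranks = _ranks_permille(bg["sorted_affinities"], strongest[:, None])
    assert np.all(ranks >= 1000.0 / n_bg - 1e-12)
    # rank floor for a query stronger than everything
    ranks_hi = _ranks_permille(bg["sorted_affinities"],
                               np.full((len(model.networks), 1), 2.0))
    assert np.allclose(ranks_hi, 1000.0 / n_bg)


def test_rank_monotone_in_affinity(tiny_model):
    model, examples = tiny_model
    presenter = examples[0].presenter
    sorted_bg = model.background[presenter]["sorted_affinities"][:1]
    qs = np.linspace(0, 1, 25)[None, :]
    ranks = _ranks_permille(sorted_bg, qs)[0]
    assert np.all(np.diff(ranks) <= 1e-12)


def test_predict_invariant_to_network_order(tiny_model):
    model, examples = tiny_model
    e = examples[0]
    base = predict(model, e.peptide, e.presenter)
    model.networks.reverse()
    for k in model.background:
        model.background[k]["sorted_affinities"] = \
            model.background[k]["sorted_affinities"][::-1].copy()
    flipped = predict(model, e.peptide, e.presenter)
    model.networks.reverse()
    for k in model.background:
        model.background[k]["sorted_affinities"] = \
            model.background[k]["sorted_affinities"][::-1].copy()
    assert flipped.core == base.core
    assert flipped.normalized_affinity == pytest.approx(base.normalized_affinity)
    assert flipped.rank_permille == pytest.approx(base.rank_permille)


def test_background_sampling_deterministic_and_valid():
    proteome = ["A" * 20, "C" * 14, "D" * 40]  # the 14-mer contributes nothing
    peps = sample_background_peptides(proteome, 50, seed=3)
    assert len(peps) == 50
    assert all(len(p) == 15 for p in peps)
    assert not any("C" in p for p in peps)
    assert peps == sample_background_peptides(proteome, 50, seed=3)
    with pytest.raises(ValueError, match="15"):
        sample_background_peptides(["SHORT"], 10, seed=0)


def test_promiscuity_bounds(tiny_model):
    model, examples = tiny_model
    presenter = examples[0].presenter
    assert promiscuity(model, presenter, 1000.0) == pytest.approx(1.0)
    # the strongest background peptide qualifies at its own final rank;
    # note the per-network 1000/n floor is not attained by the geometric
    # mean unless all networks agree on the top peptide
    bg = model.background[presenter]["peptides"]
    _o, _a, ranks = predict_many(model, bg, presenter)
    n_bg = len(bg)
    assert promiscuity(model, presenter, ranks.min()) >= 1.0 / n_bg


def test_missing_background_raises(tiny_model, grooves):
    model, examples = tiny_model
    missing = [p for p in model.grooves if p not in model.background]
    model2_background = dict(model.background)
    model.background.pop(examples[0].presenter)
    try:
        with pytest.raises(KeyError, match="background"):
            predict(model, examples[0].peptide, examples[0].presenter)
    finally:
        model.background.update(model2_background)


def test_derive_groove_positions_contact_rule():
    """Receptor residues within 4 A of the peptide chain are reported."""
    from hlacompat.binding import derive_groove_positions
    from hlacompat.structures import Atom, Structure

    atoms = [Atom(1, "C", np.array([0.0, 0.0, 0.0]), 1, "ALA", "P")]
    # receptor residues at 3, 5 and 20 A from the peptide atom
    for idx, dist in ((1, 3.0), (2, 5.0), (3, 20.0)):
        atoms.append(Atom(idx + 1, "C", np.array([dist, 0.0, 0.0]), idx, "GLY", "B"))
    st = Structure(atoms, {"P": {1: "A"}, "B": {1: "G", 2: "G", 3: "G"}})
    assert derive_groove_positions(st, "P", "B") == [1]
    assert derive_groove_positions(st, "P", "B", cutoff=6.0) == [1, 2]


def test_model_artifact_roundtrip(tmp_path, tiny_model):
    model, examples = tiny_model
    path = tmp_path / "frost.pkl"
    save_model(model, path)
    back = load_model(path)
    e = examples[0]
    assert predict(back, e.peptide, e.presenter) == predict(model, e.peptide, e.presenter)
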