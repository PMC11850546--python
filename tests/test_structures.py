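"""Geometry: SASA, protrusion ranking, exposure maps, PDB I/O."""

import numpy as np
import pytest

from hlacompat.structures import (
    MAX_SASA,
    VDW_RADII,
    Atom,
    ExposureMap,
    Structure,
    exposure_map,
    golden_spiral_points,
    predict_exposure,
    read_pdb,
    residue_surface_scores,
    sasa,
    snowball_protrusion,
    train_exposure_model,
    write_pdb,
)
from hlacompat.synthetic import gen_structure_for_length

PROBE = 1.4


def single_atom(element="C"):
    a = Atom(1, element, np.zeros(3), 1, "GLY", "A")
    return Structure([a], {"A": {1: "G"}})


def carbon_pair(separation):
    atoms = [
        Atom(1, "C", np.zeros(3), 1, "GLY", "A"),
        Atom(2, "C", np.array([separation, 0.0, 0.0]), 2, "GLY", "A"),
    ]
    return Structure(atoms, {"A": {1: "G", 2: "G"}})


def sphere_cluster(radius, n_shell=60):
    pts = golden_spiral_points(n_shell) * radius
    atoms = [Atom(i + 1, "C", p, i + 1, "GLY", "A") for i, p in enumerate(pts)]
    atoms.append(Atom(n_shell + 1, "C", np.zeros(3), n_shell + 1, "GLY", "A"))
    return Structure(atoms, {"A": {i + 1: "G" for i in range(n_shell + 1)}})


@pytest.mark.parametrize("element", sorted(VDW_RADII))
def test_isolated_sphere_closed_form(element):
    r = VDW_RADII[element] + PROBE
    area = sasa(single_atom(element))[0]
    assert area == pytest.approx(4 * np.pi * r**2, rel=0.02)


def test_nonoverlapping_atoms_add(  ):
    total = sasa(carbon_pair(100.0)).sum()
    assert total == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=1e-6)


def test_overlapping_pair_matches_spherecap_oracle():
    """Two carbons at 2 A vs a dense Monte-Carlo sphere-cap oracle."""
    d = 2.0
    r = 1.7 + PROBE
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(10**6, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= r
    # accessible fraction of atom 1's expanded sphere: points outside atom 2's
    inside = np.linalg.norm(pts - np.array([d, 0.0, 0.0]), axis=1) < r
    oracle = 2 * (1 - inside.mean()) * 4 * np.pi * r**2  # symmetric pair
    assert sasa(carbon_pair(d)).sum() == pytest.approx(oracle, rel=0.02)


def test_unknown_element_raises():
    s = Structure([Atom(1, "ZZ", np.zeros(3), 1, "GLY", "A")], {"A": {1: "G"}})
    with pytest.raises(KeyError, match="ZZ"):
        sasa(s)


def test_isolated_residue_clips_to_one():
    scores = residue_surface_scores(single_atom(), sasa(single_atom()))
    assert scores[("A", 1)] == 1.0


def test_occlusion_never_increases_surface():
    sparse = carbon_pair(10.0)
    crowded = carbon_pair(2.5)
    s_sparse = residue_surface_scores(sparse, sasa(sparse))[("A", 1)]
    s_crowded = residue_surface_scores(crowded, sasa(crowded))[("A", 1)]
    assert s_crowded < s_sparse


def test_buried_residue_in_occluding_shell():
    st, labels = gen_structure_for_length(11)  # one full cluster
    scores = residue_surface_scores(st, sasa(st))
    buried = [i for i, l in labels.items() if l == "buried"]
    assert buried and all(scores[("A", i)] < 0.05 for i in buried)


def test_sphere_cluster_rank_endpoints():
    """Furthest shell atoms rank ~1, the centred atom ~0."""
    st = sphere_cluster(10.0)
    prot = snowball_protrusion(st, neighborhood_radius=21.0)
    assert prot[("A", 61)] < 0.05
    assert min(prot[("A", i + 1)] for i in range(60)) > 0.8


def test_spike_attains_structure_maximum():
    """An atom displaced to radius 14 A outside a radius-7 cluster is the
    unambiguous furthest point of every covering ellipsoid."""
    st = sphere_cluster(7.0)
    spike = Atom(99, "C", np.array([14.0, 14.0, 14.0]) / np.sqrt(3.0), 62, "GLY", "A")
    chain = dict(st.chain_sequences["A"])
    chain[62] = "G"
    st2 = Structure(st.atoms + [spike], {"A": chain})
    prot = snowball_protrusion(st2, neighborhood_radius=30.0)
    assert prot[("A", 62)] == max(prot.values()) == 1.0


def oracle_protrusion(coords, radius, min_n=10):
    """Plain-loop re-implementation: neighbourhood ranks, medians, max."""
    n = len(coords)
    ranks_per_atom = [[] for _ in range(n)]
    for c in range(n):
        members = [j for j in range(n) if np.linalg.norm(coords[j] - coords[c]) <= radius]
        if len(members) < min_n:
            continue
        cloud = coords[members]
        mu = cloud.mean(axis=0)
        cov = np.zeros((3, 3))
        for x in cloud - mu:
            cov += np.outer(x, x)
        cov /= len(cloud)
        evals, evecs = np.linalg.eigh(cov)
        proj = (cloud - mu) @ evecs
        semi = np.maximum(np.sqrt(np.maximum(evals, 0.0)), 0.5)
        radii = np.sqrt(((proj / semi) ** 2).sum(axis=1))
        lo, hi = radii.min(), radii.max()
        for j, r in zip(members, radii):
            ranks_per_atom[j].append(0.0 if hi - lo < 1e-12 else (r - lo) / (hi - lo))
    return np.array([np.median(r) for r in ranks_per_atom])


def test_protrusion_equals_exhaustive_oracle():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 12, size=(30, 3))
    atoms = [Atom(i + 1, "C", c, i + 1, "GLY", "A") for i, c in enumerate(coords)]
    st = Structure(atoms, {"A": {i + 1: "G" for i in range(30)}})
    got = snowball_protrusion(st)
    expected = oracle_protrusion(coords, 15.0)
    for i in range(30):
        assert got[("A", i + 1)] == pytest.approx(expected[i], abs=1e-12)


def test_rigid_motion_invariance():
    """Translation is exact; rotation is limited by the fixed quadrature
    grid (surface) and near-degenerate principal axes (protrusion)."""
    st, _ = gen_structure_for_length(22)
    em1 = exposure_map(st)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])

    def moved(transform):
        return Structure(
            [Atom(a.serial, a.element, transform(a.coords),
                  a.residue_index, a.residue_name, a.chain_id) for a in st.atoms],
            st.chain_sequences,
        )

    em_t = exposure_map(moved(lambda c: c + np.array([5.0, -3.0, 11.0])))
    for key in em1.scores:
        assert em_t.scores[key][0] == pytest.approx(em1.scores[key][0], abs=1e-9)
        assert em_t.scores[key][1] == pytest.approx(em1.scores[key][1], abs=1e-9)

    em_r = exposure_map(moved(lambda c: R @ c))
    for key in em1.scores:
        assert em_r.scores[key][0] == pytest.approx(em1.scores[key][0], abs=0.02)
        assert em_r.scores[key][1] == pytest.approx(em1.scores[key][1], abs=0.02)


def test_exposure_map_total_and_deterministic():
    st, _ = gen_structure_for_length(22)
    em1, em2 = exposure_map(st), exposure_map(st)
    assert em1.scores == em2.scores
    assert set(em1.scores) == {("A", i + 1) for i in range(22)}
    for s, p in em1.scores.values():
        assert 0.0 <= s <= 1.0 and 0.0 <= p <= 1.0


def test_pdb_roundtrip(tmp_path):
    st, _ = gen_structure_for_length(20)
    path = tmp_path / "toy.pdb"
    write_pdb(st, path)
    back = read_pdb(path)
    assert len(back.atoms) == len(st.atoms)
    assert np.abs(back.coords - st.coords).max() < 1.5e-3
    assert back.chain_sequences == st.chain_sequences


def test_read_pdb_altloc_and_filters(tmp_path):
    lines = [
        "ATOM      1  N  AALA A   1      11.104   6.134  -6.504  0.50 10.00           N",
        "ATOM      2  N  BALA A   1      11.204   6.234  -6.604  0.50 10.00           N",
        "ATOM      3  CA  ALA A   1      12.560   6.351  -6.500  1.00 10.00           C",
        "HETATM    4  O   HOH A 101      10.000  10.000  10.000  1.00 10.00           O",
        "END",
    ]
    path = tmp_path / "alt.pdb"
    path.write_text("\n".join(lines) + "\n")
    st = read_pdb(path)
    assert len(st.atoms) == 2  # altloc B and water dropped
    assert st.chain_sequences == {"A": {1: "A"}}


def test_read_pdb_empty_raises(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("END\n")
    with pytest.raises(ValueError, match="no ATOM"):
        read_pdb(path)


def test_exposure_model_learns_deterministic_rule():
    """A hydrophobicity-window rule is recovered with held-out RMSE < 0.1."""
    rng = np.random.default_rng(5)
    from hlacompat.binding import AA20, _KYTE_DOOLITTLE

    def rule(seq, pos):
        window = seq[max(0, pos - 2): pos + 3]
        h = np.mean([_KYTE_DOOLITTLE[c] for c in window])
        v = 0.5 + h / 10.0
        return (float(np.clip(v, 0, 1)), float(np.clip(1 - v, 0, 1)))

    seqs = ["".join(rng.choice(list(AA20), size=40)) for _ in range(20)]
    examples = [(s, p, rule(s, p)) for s in seqs for p in range(40)]
    train, test = examples[:640], examples[640:]
    model = train_exposure_model(train, window=5, seed=0)
    errs = []
    for s, p, (ys, yp) in test:
        pred = predict_exposure(model, s).scores[("A", p + 1)]
        errs.append((pred[0] - ys) ** 2)
        errs.append((pred[1] - yp) ** 2)
    assert np.sqrt(np.mean(errs)) < 0.1


def test_exposure_model_constant_targets():
    rng = np.random.default_rng(6)
    from hlacompat.binding import AA20

    seqs = ["".join(rng.choice(list(AA20), size=30)) for _ in range(10)]
    examples = [(s, p, (0.42, 0.42)) for s in seqs for p in range(30)]
    model = train_exposure_model(examples, window=5, seed=0)
    pred = predict_exposure(model, seqs[0])
    vals = np.array(list(pred.scores.values()))
    assert np.abs(vals - 0.42).max() < 0.02


def test_exposure_model_memorizes_training_allele():
    """Predicting a sequence seen in training reproduces its targets."""
    rng = np.random.default_rng(8)
    from hlacompat.binding import AA20

    seqs = ["".join(rng.choice(list(AA20), size=30)) for _ in range(12)]
    targets = {s: np.round(rng.uniform(0.1, 0.9, size=(30, 2)), 2) for s in seqs}
    examples = [(s, p, tuple(targets[s][p])) for s in seqs for p in range(30)]
    model = train_exposure_model(examples, window=7, seed=1, hidden=(64,))
    pred = predict_exposure(model, seqs[0])
    errs = [(pred.scores[("A", p + 1)][k] - targets[seqs[0]][p][k]) ** 2
            for p in range(30) for k in (0, 1)]
    assert np.sqrt(np.mean(errs)) < 0.05


def test_exposure_model_window_validation():
    with pytest.raises(ValueError):
        train_exposure_model([("ACDEF", 1, (0.5, 0.5))] * 250, window=4)
    with pytest.raises(ValueError):
        train_exposure_model([("ACDEF", 1, (0.5, 0.5))] * 250, window=7)


def test_exposure_map_csv_roundtrip(tmp_path):
    st, _ = gen_structure_for_length(11)
    em = exposure_map(st)
    path = tmp_path / "map.csv"
    em.to_csv(path, st)
    back = ExposureMap.from_csv(path)
    for key, (s, p) in em.scores.items():
        assert back.scores[key] == (pytest.approx(s, abs=1e-6), pytest.approx(p, abs=1e-6))
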