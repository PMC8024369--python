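"""synthetic_data: generators for structures, trajectories, melting curves,
scattering profiles and the on-disk study bundle.

Everything here is synthetic by construction; the tests check that the
generators hit their documented ground truth exactly.
"""

import json

import numpy as np
import pytest

from bundlestab.meltfit import fit_melt, model_ellipticity
from bundlestab.saxs import form_factor, read_dat
from bundlestab.structures import read_structure
from bundlestab.synthetic_data import (DEFAULT_BASELINES, DEFAULT_PANEL_TM,
                                       DEFAULT_TM_TABLE_HYPERSTABLE,
                                       DEFAULT_TM_TABLE_PARENT,
                                       STANDIN_EXPOSED_POLAR, STANDIN_TARGETS,
                                       StudyTruth, build_helix_bundle,
                                       bundle_hash, default_study_truth,
                                       gen_melt_curve, gen_saxs, gen_study,
                                       gen_trajectories)
from bundlestab.unfolding import (endpoint_rmsd, kabsch_rmsd,
                                  read_trajectory_xyz, select_atoms)


# --- helix bundle generator ----------------------------------------------

def test_helix_geometry_ca_spacing():
    s = build_helix_bundle(1, 10)
    ca = select_atoms(s, "CA")
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    # ideal alpha-helix: consecutive Calpha ~3.8 A apart
    assert np.all(np.abs(d - 3.8) < 0.15)


def test_helix_bundle_deterministic():
    a = build_helix_bundle(4, 20)
    b = build_helix_bundle(4, 20)
    assert np.array_equal(a.coordinates(), b.coordinates())


def test_helix_bundle_chain_split(small_bundle):
    assert [c.chain_id for c in small_bundle.chains] == ["A", "B"]
    assert len(small_bundle.chain("A").residues) == 40
    assert len(small_bundle.chain("B").residues) == 40


def test_helix_bundle_core_more_buried(small_bundle):
    """Residues whose Cbeta points at the bundle axis are on average less
    solvent-exposed than those pointing outward."""
    from bundlestab.sasa import shrake_rupley_sasa
    areas = shrake_rupley_sasa(small_bundle)
    flat = small_bundle.atoms()
    centre = np.array([5.0, 5.0, 0.0])  # 2x2 grid, 10 A spacing
    per_res = {}
    for (cid, res, atom), a in zip(flat, areas):
        key = (cid, res.seq_number)
        per_res.setdefault(key, {"area": 0.0})
        per_res[key]["area"] += a
        per_res[key][atom.name] = np.asarray(atom.position)
    inward, outward = [], []
    for rec in per_res.values():
        if "CB" not in rec:
            continue
        axis_dir = centre - rec["CA"]
        axis_dir[2] = 0.0
        cb_dir = rec["CB"] - rec["CA"]
        (inward if np.dot(cb_dir, axis_dir) > 0 else outward).append(
            rec["area"])
    assert np.mean(inward) < np.mean(outward)


def test_helix_bundle_sequence_length_validation():
    with pytest.raises(ValueError):
        build_helix_bundle(2, 10, sequence="A" * 19)


# --- buried-screen stand-in ----------------------------------------------

def test_standin_is_c2_dimer(standin):
    ca_a = np.array([at.position for r in standin.chain("A").residues
                     for at in r.atoms])
    ca_b = np.array([at.position for r in standin.chain("B").residues
                     for at in r.atoms])
    assert ca_a.shape == ca_b.shape
    # the second chain is a rigid (proper-rotation) image of the first
    assert kabsch_rmsd(ca_a, ca_b) < 1e-6


def test_standin_sequence_truth(standin):
    from bundlestab.structures import extract_sequence
    seq = extract_sequence(standin, "A")
    one = dict(STANDIN_TARGETS)
    one.update(STANDIN_EXPOSED_POLAR)
    for pos, aa in one.items():
        assert seq[pos - 1] == aa, pos


# --- study truth ----------------------------------------------------------

def test_study_truth_validation():
    labels = ["a", "b"]
    stability = {"a": 0.0, "b": 1.0}
    with pytest.raises(ValueError):
        StudyTruth(labels, stability, {"a": 60.0, "b": 50.0},
                   {"a": 2.0, "b": 1.0}, 0)  # tm not increasing
    with pytest.raises(ValueError):
        StudyTruth(labels, stability, {"a": 50.0, "b": 60.0},
                   {"a": 1.0, "b": 2.0}, 0)  # drift not decreasing


def test_default_study_truth_panel():
    truth = default_study_truth(42)
    assert set(truth.labels) == set(DEFAULT_PANEL_TM)
    assert truth.tm == DEFAULT_PANEL_TM
    vals = np.array(list(truth.stability.values()))
    assert vals.min() == 0.0 and vals.max() == 1.0
    # drift strictly decreasing in Tm
    order = sorted(truth.labels, key=truth.tm.get)
    drifts = [truth.drift[l] for l in order]
    assert all(b < a for a, b in zip(drifts, drifts[1:]))


# --- trajectory generator -------------------------------------------------

def _two_label_truth(drift_hi=0.0):
    return StudyTruth(["lo", "hi"], {"lo": 0.0, "hi": 1.0},
                      {"lo": 50.0, "hi": 60.0},
                      {"lo": 1.0, "hi": drift_hi}, master_seed=5)


def test_gen_trajectories_zero_drift_is_static():
    s = build_helix_bundle(2, 10)
    ca = select_atoms(s, "CA")
    trajs = gen_trajectories(s, _two_label_truth(0.0), n_seeds=3, n_frames=10)
    for tr in trajs["hi"]:
        assert endpoint_rmsd(tr, ca) == pytest.approx(0.0, abs=1e-12)
    for tr in trajs["lo"]:
        assert endpoint_rmsd(tr, ca) > 0.1


def test_gen_trajectories_deterministic():
    s = build_helix_bundle(2, 10)
    truth = _two_label_truth(0.2)
    a = gen_trajectories(s, truth, n_seeds=2, n_frames=5)
    b = gen_trajectories(s, truth, n_seeds=2, n_frames=5)
    assert np.array_equal(a["lo"][1].frames, b["lo"][1].frames)


def test_gen_trajectories_drift_ordering():
    s = build_helix_bundle(2, 10)
    ca = select_atoms(s, "CA")
    truth = StudyTruth(["w", "m", "s"], {"w": 0.0, "m": 0.5, "s": 1.0},
                       {"w": 50.0, "m": 55.0, "s": 60.0},
                       {"w": 2.5, "m": 1.5, "s": 0.5}, master_seed=3)
    trajs = gen_trajectories(s, truth, n_seeds=8, n_frames=20)
    means = {l: np.mean([endpoint_rmsd(t, ca) for t in trajs[l]])
             for l in truth.labels}
    assert means["s"] < means["m"] < means["w"]


def test_gen_trajectories_validation():
    s = build_helix_bundle(2, 10)
    with pytest.raises(ValueError):
        gen_trajectories(s, _two_label_truth(0.2), n_seeds=0)


# --- melting-curve generator ----------------------------------------------

def test_gen_melt_curve_noiseless_matches_model():
    curve = gen_melt_curve(69.8)
    expected = model_ellipticity(curve.temperature,
                                 (69.8, 300e3, *DEFAULT_BASELINES))
    np.testing.assert_array_equal(curve.ellipticity, expected)


def test_gen_melt_curve_fit_round_trip():
    fit = fit_melt(gen_melt_curve(73.3, label="x"))
    assert fit.tm == pytest.approx(73.3, abs=1e-4)


def test_gen_melt_curve_seeds_differ():
    a = gen_melt_curve(69.8, noise_sd=0.05, seed=1)
    b = gen_melt_curve(69.8, noise_sd=0.05, seed=2)
    assert not np.array_equal(a.ellipticity, b.ellipticity)


def test_gen_melt_curve_t_range_validation():
    with pytest.raises(ValueError):
        gen_melt_curve(129.0)  # default range 20-110 does not span tm


# --- SAXS generator -------------------------------------------------------

def test_gen_saxs_noiseless_exact():
    q = np.linspace(0.1, 2.0, 50)
    prof = gen_saxs("sphere", {"radius": 3.0}, q_grid=q,
                    noise_model=(0.0, 0.0))
    clean = form_factor("sphere", {"radius": 3.0}, q)
    np.testing.assert_array_equal(prof.intensity, clean.intensity)


def test_gen_saxs_sigma_column():
    q = np.linspace(0.1, 2.0, 50)
    prof = gen_saxs("sphere", {"radius": 3.0}, q_grid=q,
                    noise_model=(0.05, 1e-3), seed=0)
    clean = form_factor("sphere", {"radius": 3.0}, q)
    np.testing.assert_allclose(
        prof.sigma, np.maximum(0.05 * clean.intensity, 1e-3), rtol=1e-12)


def test_gen_saxs_deterministic():
    a = gen_saxs("sphere", {"radius": 3.0}, seed=9)
    b = gen_saxs("sphere", {"radius": 3.0}, seed=9)
    assert np.array_equal(a.intensity, b.intensity)


# --- study bundle ---------------------------------------------------------

def test_gen_study_layout(study_bundle):
    out, truth = study_bundle
    assert (out / "structure.pdb").exists()
    assert (out / "truth.json").exists()
    n_labels = len(DEFAULT_PANEL_TM)
    assert len(list((out / "trajectories").glob("*.xyz"))) == n_labels * 10
    n_curves = len(DEFAULT_TM_TABLE_PARENT) + len(DEFAULT_TM_TABLE_HYPERSTABLE)
    assert len(list((out / "melt").glob("*.csv"))) == n_curves
    assert len(list(out.glob("secmals_*.tsv"))) == 2
    assert len(list((out / "saxs").glob("*.dat"))) == 2


def test_gen_study_truth_round_trip(study_bundle):
    out, truth = study_bundle
    on_disk = json.loads((out / "truth.json").read_text())
    assert on_disk == truth
    assert truth["melt_tm_C"]["SUWA_N22E/H86K"] == 129.0
    assert truth["buried_positions"] == [26, 74, 78, 79, 86]


def test_gen_study_files_readable(study_bundle):
    out, truth = study_bundle
    s = read_structure(out / "structure.pdb")
    assert {c.chain_id for c in s.chains} == {"A", "B"}
    tr = read_trajectory_xyz(next(iter(sorted(
        (out / "trajectories").glob("*.xyz")))))
    assert tr.frames.shape[0] == truth["n_frames"] + 1
    prof = read_dat(out / "saxs" / "sphere_R3.dat")
    assert len(prof.q) == 200


def test_gen_study_melt_curves_recover_truth(study_bundle):
    out, truth = study_bundle
    rows = (out / "melt" / "WA20.csv").read_text().splitlines()[1:]
    t, e = np.array([[float(v) for v in r.split(",")] for r in rows]).T
    from bundlestab.meltfit import MeltCurve
    fit = fit_melt(MeltCurve(t, e))
    assert fit.tm == pytest.approx(truth["melt_tm_C"]["WA20"], abs=0.1)


def test_gen_study_reproducible_hash(study_bundle, tmp_path):
    out, _ = study_bundle
    gen_study(tmp_path / "again", master_seed=42)
    assert bundle_hash(out) == bundle_hash(tmp_path / "again")
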