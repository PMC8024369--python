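"""Synthetic inputs with known ground truth for every pipeline stage.

Generates idealised four-helix-bundle dimer structures, replicate unfolding
trajectories whose endpoint drift decreases with an assigned stability,
two-state melting curves with sloping baselines and Gaussian noise, SAXS
profiles from analytic form factors with heteroscedastic noise, and SEC-MALS
peak tables — everything the analysis needs, without wet-lab data or
downloads.  Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from ._ideal import AA1_TO_3, build_cb, build_side_chain, place_atom
from .meltfit import MeltCurve, model_ellipticity
from .saxs import SAXSProfile, form_factor, write_dat
from .structures import Atom, Chain, Residue, Structure, element_radius
from .unfolding import Trajectory

# ideal alpha-helix parameters
HELIX_RISE = 1.5          # Å per residue
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS_CA = 2.3     # Å
HELIX_RADIUS_N = 1.6
HELIX_RADIUS_C = 1.7
GRID_SPACING = 10.0       # Å between helix axes


def _helix_point(t: float, radius: float, phase_deg: float, rise: float,
                 origin: np.ndarray, direction: float) -> np.ndarray:
    """Point on an ideal helix at residue parameter t (axis along z)."""
    ang = np.deg2rad(phase_deg + HELIX_TWIST * t)
    return origin + np.array([radius * np.cos(ang), radius * np.sin(ang),
                              direction * rise * t])


def _helix_residues(n_res: int, origin: np.ndarray, phase_deg: float,
                    direction: float, start_number: int,
                    sequence: str) -> list[Residue]:
    """Idealised helical residues with full backbone and side chains."""
    residues = []
    for k in range(n_res):
        name3 = AA1_TO_3[sequence[k]]
        n_pos = _helix_point(k - 0.35, HELIX_RADIUS_N, phase_deg,
                             HELIX_RISE, origin, direction)
        ca_pos = _helix_point(k, HELIX_RADIUS_CA, phase_deg,
                              HELIX_RISE, origin, direction)
        c_pos = _helix_point(k + 0.40, HELIX_RADIUS_C, phase_deg,
                             HELIX_RISE, origin, direction)
        o_pos = place_atom(n_pos, ca_pos, c_pos, 1.231, 120.8, 133.0)
        atoms = [Atom("N", "N", n_pos, element_radius("N")),
                 Atom("CA", "C", ca_pos, element_radius("C")),
                 Atom("C", "C", c_pos, element_radius("C")),
                 Atom("O", "O", o_pos, element_radius("O"))]
        for an, el, pos in build_side_chain(name3, n_pos, ca_pos, c_pos):
            atoms.append(Atom(an, el, pos, element_radius(el)))
        residues.append(Residue(name3, start_number + k, atoms))
    return residues


def build_helix_bundle(n_helices: int = 4, residues_per_helix: int = 20,
                       sequence: str | None = None,
                       spacing: float = GRID_SPACING) -> Structure:
    """Idealised helix bundle on a square grid, split into two chains.

    Each helix: 1.5 Å rise and 100° twist per residue, Cα radius 2.3 Å;
    backbone plus Cβ only.  Helices are packed on a square grid with 10 Å
    inter-axis spacing, alternating up/down, with phases facing the bundle
    centre.  Helices are split evenly between chains A and B to mimic an
    intermolecularly folded dimer.  Deterministic.
    """
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    if sequence is None:
        sequence = "A" * (n_helices * residues_per_helix)
    if len(sequence) != n_helices * residues_per_helix:
        raise ValueError("sequence length must equal n_helices * "
                         "residues_per_helix")
    side = int(np.ceil(np.sqrt(n_helices)))
    centre = np.array([(side - 1) / 2.0 * spacing,
                       (side - 1) / 2.0 * spacing, 0.0])
    all_res: list[list[Residue]] = []
    for h in range(n_helices):
        gx, gy = h % side, h // side
        origin = np.array([gx * spacing, gy * spacing, 0.0])
        inward = centre - origin
        phase = float(np.degrees(np.arctan2(inward[1], inward[0]))) \
            if np.linalg.norm(inward[:2]) > 1e-9 else 0.0
        direction = 1.0 if h % 2 == 0 else -1.0
        seq_h = sequence[h * residues_per_helix:(h + 1) * residues_per_helix]
        residues = []
        for k in range(residues_per_helix):
            name3 = AA1_TO_3[seq_h[k]]
            n_pos = _helix_point(k - 0.35, HELIX_RADIUS_N, phase, HELIX_RISE,
                                 origin, direction)
            ca_pos = _helix_point(k, HELIX_RADIUS_CA, phase, HELIX_RISE,
                                  origin, direction)
            c_pos = _helix_point(k + 0.40, HELIX_RADIUS_C, phase, HELIX_RISE,
                                 origin, direction)
            o_pos = place_atom(n_pos, ca_pos, c_pos, 1.231, 120.8, 133.0)
            atoms = [Atom("N", "N", n_pos, element_radius("N")),
                     Atom("CA", "C", ca_pos, element_radius("C")),
                     Atom("C", "C", c_pos, element_radius("C")),
                     Atom("O", "O", o_pos, element_radius("O"))]
            if name3 != "GLY":
                cb = build_cb(n_pos, ca_pos, c_pos)
                atoms.append(Atom("CB", "C", cb, element_radius("C")))
            residues.append(Residue(name3, k + 1, atoms))
        all_res.append(residues)
    half = max(1, n_helices // 2) if n_helices > 1 else 1
    chains = []
    for ci, helix_ids in enumerate([range(0, half), range(half, n_helices)]):
        residues = []
        offset = 0
        for h in helix_ids:
            for r in all_res[h]:
                residues.append(Residue(r.name, r.seq_number + offset, r.atoms))
            offset += residues_per_helix
        if residues:
            chains.append(Chain("AB"[ci], residues))
    return Structure("helix-bundle", chains)


# --- synthetic stand-in for the buried-residue screen ---------------------

STANDIN_TARGETS = {26: "H", 74: "H", 78: "E", 79: "S", 86: "H"}
STANDIN_EXPOSED_POLAR = {17: "K", 35: "E", 62: "K", 80: "Q",
                         110: "E", 155: "K"}
STANDIN_SPACING = 8.5  # Å inter-axis; typical antiparallel helix packing


def synthetic_buried_screen_standin(spacing: float = STANDIN_SPACING
                                    ) -> Structure:
    """SYNTHETIC stand-in structure for the buried-hydrophilic screen.

    A designed C2-symmetric eight-helix bundle dimer (four antiparallel
    idealised helices per chain, full side chains, binary-patterned
    sequence: bulky hydrophobics facing the core, alanine facing solvent).
    The hydrophilic positions {26, 74, 78, 79, 86} sit on the two interior
    helices with side chains facing the packed core — buried by
    construction, the ground truth the screen must recover — while decoy
    hydrophilic residues ({17, 35, 62, 80, 110, 155}) face outward and stay
    exposed.  This is a synthetic designed object, not the deposited
    crystal structure of any real protein; it reproduces the buried-polar
    pattern of natural-like bundles so the screen can be exercised offline.
    """
    # chain A helix layout on a row; chain B is the C2 image (second row).
    # (first_res, last_res, grid_column, direction up/down, z offset)
    helices = [
        (1, 45, 1, +1.0, 0.0),       # interior; carries position 26
        (46, 100, 2, -1.0, 66.0),    # interior; carries 74, 78, 79, 86
        (101, 145, 0, +1.0, 0.0),    # flanking
        (146, 190, 3, -1.0, 66.0),   # flanking
    ]
    # side-chain orientation each helix should point toward the bundle core
    inward_deg = [90.0, 90.0, 0.0, 180.0]

    def centred_phase(start: int, positions: list[int], want: float) -> float:
        rel = [HELIX_TWIST * (p - start) for p in positions]
        mean = float(np.degrees(np.arctan2(
            np.mean(np.sin(np.deg2rad(rel))),
            np.mean(np.cos(np.deg2rad(rel))))))
        return want - mean

    phases = [centred_phase(1, [26], 90.0),
              centred_phase(46, [74, 78, 79, 86], 90.0),
              0.0, 180.0]

    # binary-patterned sequence: residue size graded by angular distance
    # from the core direction, overridden at target and decoy positions
    seq: dict[int, str] = {}
    for hi, (s0, e0, _col, _dirn, _z0) in enumerate(helices):
        for p in range(s0, e0 + 1):
            ang = (phases[hi] + HELIX_TWIST * (p - s0)) % 360.0
            dev = abs(((ang - inward_deg[hi] + 180.0) % 360.0) - 180.0)
            seq[p] = ("F" if dev < 45 else
                      "L" if dev < 90 else
                      "M" if dev < 120 else "A")
    for p, aa in STANDIN_TARGETS.items():
        seq[p] = aa
    for p, aa in STANDIN_EXPOSED_POLAR.items():
        seq[p] = aa

    res_a: list[Residue] = []
    for hi, (s0, e0, col, dirn, z0) in enumerate(helices):
        origin = np.array([col * spacing, 0.0, z0])
        sub = "".join(seq[p] for p in range(s0, e0 + 1))
        res_a += _helix_residues(e0 - s0 + 1, origin, phases[hi], dirn,
                                 s0, sub)
    chain_a = Chain("A", res_a)
    # C2 about the z axis through the bundle centre
    rot = np.diag([-1.0, -1.0, 1.0])
    t = np.array([3 * spacing, spacing, 0.0])
    res_b = [Residue(r.name, r.seq_number,
                     [Atom(a.name, a.element, rot @ a.position + t, a.radius)
                      for a in r.atoms]) for r in res_a]
    chain_b = Chain("B", res_b)
    return Structure("synthetic-bundle-standin", [chain_a, chain_b])


# --- study truth and trajectory generation --------------------------------

@dataclasses.dataclass
class StudyTruth:
    labels: list[str]
    stability: dict[str, float]   # latent, arbitrary units
    tm: dict[str, float]          # °C, strictly increasing in stability
    drift: dict[str, float]       # Å, strictly decreasing in stability
    master_seed: int

    def __post_init__(self):
        order = sorted(self.labels, key=lambda l: self.stability[l])
        tms = [self.tm[l] for l in order]
        drifts = [self.drift[l] for l in order]
        if any(b <= a for a, b in zip(tms, tms[1:])):
            raise ValueError("tm must increase strictly with stability")
        if any(b >= a for a, b in zip(drifts, drifts[1:])):
            raise ValueError("drift must decrease strictly with stability")


# Assigned melting temperatures for the default 8-construct panel (°C):
# the parental bundle and seven single/double substitutions spanning the
# destabilised-to-stabilised range observed for this fold family.
DEFAULT_PANEL_TM = {
    "WT": 69.8, "N22K": 60.9, "N22L": 65.0, "H86S": 68.6,
    "H74V/S79F": 69.9, "N22E": 70.8, "N22A": 72.7, "H86K": 73.3,
}


def default_study_truth(master_seed: int = 42,
                        tm_by_label: dict[str, float] | None = None,
                        drift_range: tuple[float, float] = (0.5, 2.5),
                        ) -> StudyTruth:
    """Eight-construct panel: Tm affine in latent stability, drift linear
    and decreasing in it."""
    tm_by_label = dict(tm_by_label or DEFAULT_PANEL_TM)
    labels = list(tm_by_label)
    tms = np.array([tm_by_label[l] for l in labels])
    lo, hi = float(tms.min()), float(tms.max())
    stability = {l: (tm_by_label[l] - lo) / (hi - lo) for l in labels}
    d_hi, d_lo = drift_range[1], drift_range[0]
    drift = {l: d_hi - (d_hi - d_lo) * stability[l] for l in labels}
    return StudyTruth(labels, stability, tm_by_label, drift, master_seed)


def gen_trajectories(struct: Structure, truth: StudyTruth,
                     n_seeds: int = 10, n_frames: int = 50,
                     ) -> dict[str, list[Trajectory]]:
    """Replicate diffusion trajectories per construct, Cα only.

    Frames accumulate seeded Gaussian displacements scaled so the expected
    per-coordinate endpoint spread equals the construct's drift scale; the
    endpoint RMSD is therefore an increasing function of drift, i.e. a
    decreasing function of the assigned stability.  Deliberately a
    different stochastic process from the Monte-Carlo surrogate simulator
    so the two can cross-validate.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    from .unfolding import select_atoms
    ca = select_atoms(struct, "CA")
    out: dict[str, list[Trajectory]] = {}
    ss = np.random.SeedSequence(truth.master_seed)
    child = {l: s for l, s in zip(truth.labels, ss.spawn(len(truth.labels)))}
    for label in truth.labels:
        drift = truth.drift[label]
        step_sd = drift / np.sqrt(n_frames)
        trajs = []
        for seed in child[label].spawn(n_seeds):
            rng = np.random.default_rng(seed)
            frames = [ca.copy()]
            cur = ca.copy()
            for _ in range(n_frames):
                cur = cur + rng.normal(0.0, step_sd, size=cur.shape)
                frames.append(cur.copy())
            trajs.append(Trajectory(np.array(frames), label=label))
        out[label] = trajs
    return out


# --- melting curves -------------------------------------------------------

DEFAULT_BASELINES = (-20.0, 0.01, -2.0, 0.002)  # θN, mN (per K), θD, mD


def gen_melt_curve(tm: float, dh: float = 300e3,
                   baselines: tuple[float, float, float, float] = DEFAULT_BASELINES,
                   t_range: tuple[float, float] = (20.0, 110.0),
                   n_points: int = 100, noise_sd: float = 0.0,
                   seed: int = 0, label: str = "") -> MeltCurve:
    """Two-state melting curve on a uniform grid with Gaussian noise.

    tm in °C, dh in J/mol; baselines are (θN, mN, θD, mD) with slopes per
    Kelvin.  noise_sd is in ellipticity units.
    """
    if not t_range[0] < tm < t_range[1]:
        raise ValueError("t_range must span tm")
    t = np.linspace(t_range[0], t_range[1], n_points)
    y = model_ellipticity(t, (tm, dh, *baselines))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=len(t))
    return MeltCurve(t, y, label=label)


# --- SAXS profiles --------------------------------------------------------

def gen_saxs(shape: str, params: dict, q_grid=None,
             noise_model: tuple[float, float] = (0.01, 1e-6),
             i0: float = 1.0, concentration: float = 1.0,
             seed: int = 0, label: str = "") -> SAXSProfile:
    """Analytic form-factor profile with heteroscedastic Gaussian noise.

    noise_model = (relative sd, absolute floor); the σ column reports the
    true per-point noise level used.
    """
    if q_grid is None:
        q_grid = np.linspace(0.05, 5.0, 200)
    clean = form_factor(shape, params, q_grid, i0=i0,
                        concentration=concentration, label=label)
    rel, floor = noise_model
    sigma = np.maximum(rel * clean.intensity, floor)
    i_noisy = clean.intensity.copy()
    if rel > 0 or floor > 0:
        rng = np.random.default_rng(seed)
        i_noisy = clean.intensity + rng.normal(0.0, 1.0, len(sigma)) * sigma
    sigma_col = np.where(sigma > 0, sigma, 1e-12)
    return SAXSProfile(np.asarray(q_grid, float), i_noisy, sigma_col,
                       concentration, label or shape)


# --- study bundle ---------------------------------------------------------

# SEC-MALS default peak tables (peak id, Mw kDa, mass fraction %)
DEFAULT_PEAKS = {
    "ROWA": [("i", 22.8, 77.0), ("ii", 45.3, 21.0), ("iii", 72.8, 2.0)],
    "ROSA": [("i", 23.4, 64.0), ("ii", 49.2, 18.0), ("iii", 81.2, 7.0),
             ("iv", 238.0, 11.0)],
}
DEFAULT_MONOMER_KDA = {"ROWA": 12.5, "ROSA": 12.6}

# default melting-temperature tables (°C) for the two construct families
DEFAULT_TM_TABLE_PARENT = {
    "WA20": 69.8, "N22A": 72.7, "N22E": 70.8, "N22K": 60.9, "N22L": 65.0,
    "H86K": 73.3, "H86S": 68.6, "H74V/S79F": 69.9, "N22A/H86K": 80.4,
    "N22E/H86K": 71.7,
}
DEFAULT_TM_TABLE_HYPERSTABLE = {
    "SUWA": 124.7, "SUWA_N22A": 128.5, "SUWA_N22E": 125.8,
    "SUWA_H86K": 125.6, "SUWA_N22A/H86K": 128.5, "SUWA_N22E/H86K": 129.0,
}


def _safe_name(label: str) -> str:
    return label.replace("/", "-")


def gen_study(out_dir: str | Path, master_seed: int = 42,
              n_seeds: int = 10, n_frames: int = 30,
              melt_noise_sd: float = 0.0) -> dict:
    """Write a complete on-disk study bundle with ground truth.

    Contents: the synthetic bundle structure (PDB), per-construct replicate
    Cα trajectories (XYZ), melting-curve CSVs for both construct families,
    SEC-MALS peak TSVs, SAXS .dat profiles (sphere and cylinder), and
    truth.json recording every generating parameter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .structures import write_structure
    struct = synthetic_buried_screen_standin()
    write_structure(struct, out / "structure.pdb")

    truth = default_study_truth(master_seed)
    trajs = gen_trajectories(struct, truth, n_seeds=n_seeds,
                             n_frames=n_frames)
    traj_dir = out / "trajectories"
    traj_dir.mkdir(exist_ok=True)
    for label, runs in trajs.items():
        for k, tr in enumerate(runs):
            lines = []
            for frame in tr.frames:
                lines.append(str(len(frame)))
                lines.append(f"{label} frame")
                for x, y, z in frame:
                    lines.append(f"CA {x:.4f} {y:.4f} {z:.4f}")
            (traj_dir / f"{_safe_name(label)}_seed{k}.xyz").write_text(
                "\n".join(lines) + "\n")

    melt_dir = out / "melt"
    melt_dir.mkdir(exist_ok=True)
    rng_seed = np.random.SeedSequence(master_seed + 1)
    seeds = iter(rng_seed.generate_state(64))
    for table, t_range in ((DEFAULT_TM_TABLE_PARENT, (20.0, 110.0)),
                           (DEFAULT_TM_TABLE_HYPERSTABLE, (90.0, 150.0))):
        for label, tm in table.items():
            curve = gen_melt_curve(tm, t_range=t_range, n_points=120,
                                   noise_sd=melt_noise_sd,
                                   seed=int(next(seeds) % (2 ** 31)),
                                   label=label)
            lines = ["temperature_C,ellipticity"]
            lines += [f"{t:.4f},{e:.6f}" for t, e in
                      zip(curve.temperature, curve.ellipticity)]
            (melt_dir / f"{_safe_name(label)}.csv").write_text(
                "\n".join(lines) + "\n")

    for sample, peaks in DEFAULT_PEAKS.items():
        lines = ["peak_id\tmw_kda\tmass_fraction_pct"]
        lines += [f"{pid}\t{mw}\t{frac}" for pid, mw, frac in peaks]
        (out / f"secmals_{sample}.tsv").write_text("\n".join(lines) + "\n")

    saxs_dir = out / "saxs"
    saxs_dir.mkdir(exist_ok=True)
    prof_sphere = gen_saxs("sphere", {"radius": 3.0}, seed=master_seed + 7,
                           label="sphere_R3")
    prof_cyl = gen_saxs("cylinder", {"radius": 1.5, "length": 12.0},
                        seed=master_seed + 8, label="cylinder_r1.5_L12")
    write_dat(prof_sphere, saxs_dir / "sphere_R3.dat")
    write_dat(prof_cyl, saxs_dir / "cylinder_r1.5_L12.dat")

    truth_doc = {
        "master_seed": master_seed,
        "panel": {l: {"tm_C": truth.tm[l], "stability": truth.stability[l],
                      "drift_A": truth.drift[l]} for l in truth.labels},
        "melt_tm_C": {**DEFAULT_TM_TABLE_PARENT,
                      **DEFAULT_TM_TABLE_HYPERSTABLE},
        "melt_dh_J_mol": 300e3,
        "melt_noise_sd": melt_noise_sd,
        "secmals_monomer_kda": DEFAULT_MONOMER_KDA,
        "saxs": {"sphere_R3": {"shape": "sphere", "radius_nm": 3.0},
                 "cylinder_r1.5_L12": {"shape": "cylinder",
                                       "radius_nm": 1.5, "length_nm": 12.0}},
        "buried_positions": sorted(STANDIN_TARGETS),
        "exposed_polar_positions": sorted(STANDIN_EXPOSED_POLAR),
        "n_seeds": n_seeds,
        "n_frames": n_frames,
    }
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=2,
                                               sort_keys=True) + "\n")
    return truth_doc


def bundle_hash(out_dir: str | Path) -> str:
    """SHA-256 over every file in a bundle, for determinism checks."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).rglob("*")):
        if path.is_file():
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()
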