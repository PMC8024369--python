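"""Stability scoring from high-temperature unfolding trajectories.

The unfolding indicator is the root-mean-square deviation between a
structure before and after a high-temperature run, after optimal rigid
superposition (Kabsch).  Smaller endpoint RMSD over replicate runs with
different random seeds indicates a more unfolding-resistant variant; the
module aggregates replicates, ranks candidates, and ships a coarse-grained
Cα Monte-Carlo surrogate simulator so the whole pipeline can be exercised
without a molecular-dynamics engine (which it is emphatically not).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .structures import Structure


@dataclasses.dataclass
class Trajectory:
    frames: np.ndarray        # (n_frames, n_atoms, 3) Å
    frame_interval: float = 1.0
    label: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")


@dataclasses.dataclass
class MutantScore:
    label: str
    replicate_rmsds: tuple[float, ...]
    mean_rmsd: float
    std_rmsd: float
    n_replicates: int
    flags: set = dataclasses.field(default_factory=set)
    rank: int | None = None
    delta_vs_wt: float | None = None


def kabsch_superpose(ref: np.ndarray, mov: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of mov onto ref.

    Returns (rotation R, translation t, rmsd) with det(R) = +1 (reflections
    excluded by sign-correcting the smallest singular value) such that
    R @ mov_i + t best matches ref_i in least squares.
    """
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must share shape (n, 3)")
    if ref.shape[0] < 2:
        raise ValueError("need at least 2 points")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    p = ref - ref_c
    q = mov - mov_c
    h = q.T @ p
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ref_c - rot @ mov_c
    diff = (mov @ rot.T + t) - ref
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return rot, t, rmsd


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return kabsch_superpose(a, b)[2]


def select_atoms(struct: Structure, selection: str = "CA"
                 ) -> np.ndarray:
    """Coordinates of a named atom selection ('CA' or 'heavy')."""
    if selection == "heavy":
        return struct.coordinates()
    pos = [a.position for cid, res, a in struct.atoms() if a.name == selection]
    if len(pos) == 0:
        raise ValueError(f"selection {selection!r} matched no atoms")
    return np.array(pos)


def endpoint_rmsd(traj: Trajectory, initial: np.ndarray) -> float:
    """Kabsch RMSD between the initial coordinates and the final frame."""
    initial = np.asarray(initial, float)
    final = traj.frames[-1]
    if initial.shape != final.shape:
        raise ValueError("initial coordinates do not match trajectory atoms")
    if initial.shape[0] < 3:
        raise ValueError("need at least 3 atoms for a meaningful RMSD")
    return kabsch_rmsd(initial, final)


def aggregate_replicates(rmsds: list[float], label: str) -> MutantScore:
    """Mean and sample std (n-1 denominator; 0 when n = 1) over seeds."""
    if len(rmsds) == 0:
        raise ValueError("no replicate RMSD values")
    arr = np.asarray(rmsds, float)
    std = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return MutantScore(label=label, replicate_rmsds=tuple(float(x) for x in arr),
                       mean_rmsd=float(arr.mean()), std_rmsd=std,
                       n_replicates=len(arr))


def rank_candidates(scores: list[MutantScore], wild_type: MutantScore,
                    top_k: int) -> list[MutantScore]:
    """Ascending mean RMSD among unflagged candidates; top_k returned.

    Ties broken by smaller replicate std, then label.  Each returned score
    carries its rank and its mean-RMSD difference versus the wild type.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if not scores:
        raise ValueError("no candidates to rank")
    eligible = [s for s in scores if not s.flags]
    eligible.sort(key=lambda s: (s.mean_rmsd, s.std_rmsd, s.label))
    ranked = []
    for i, s in enumerate(eligible[:top_k], start=1):
        ranked.append(dataclasses.replace(
            s, rank=i, delta_vs_wt=s.mean_rmsd - wild_type.mean_rmsd))
    return ranked


# --- coarse-grained surrogate unfolding simulator ------------------------

CONTACT_CUTOFF = 8.0        # Å, native Cα-Cα contact definition
CONTACT_MIN_SEPARATION = 3  # residues
CONTACT_TOLERANCE = 1.2     # contact intact while within 1.2x native distance
BOND_K = 20.0               # harmonic virtual-bond restraint strength
MOVE_SD = 0.3               # Å, single-atom Gaussian displacement


def _native_contacts(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(ca)
    pairs = []
    dists = []
    for i in range(n):
        for j in range(i + CONTACT_MIN_SEPARATION, n):
            d = np.linalg.norm(ca[i] - ca[j])
            if d < CONTACT_CUTOFF:
                pairs.append((i, j))
                dists.append(d)
    return np.array(pairs, dtype=int).reshape(-1, 2), np.array(dists)


def _energy_terms(ca: np.ndarray, pairs: np.ndarray, native_d: np.ndarray,
                  bond_d: np.ndarray) -> float:
    e = 0.0
    if len(pairs):
        d = np.linalg.norm(ca[pairs[:, 0]] - ca[pairs[:, 1]], axis=1)
        e -= float(np.sum(d <= CONTACT_TOLERANCE * native_d))
    bonds = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    e += float(BOND_K * np.sum((bonds - bond_d) ** 2))
    return e


def surrogate_unfold(struct: Structure, temperature_factor: float,
                     n_steps: int, seed: int, label: str = "",
                     n_frames: int = 100) -> Trajectory:
    """Cα-level Metropolis Monte-Carlo unfolding run.

    Gō-style energy: −1 per intact native contact (Cα pairs < 8 Å, ≥3
    residues apart, intact while within 1.2× the native distance) plus a
    harmonic restraint on consecutive-Cα virtual bonds.  Single-atom
    Gaussian moves accepted with probability exp(−ΔE/temperature_factor).
    Fully reproducible from the seed.
    """
    if temperature_factor < 0:
        raise ValueError("temperature_factor must be >= 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    ca = select_atoms(struct, "CA").copy()
    pairs, native_d = _native_contacts(ca)
    bond_d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    rng = np.random.default_rng(seed)
    stride = max(1, n_steps // n_frames)
    frames = [ca.copy()]
    e_cur = _energy_terms(ca, pairs, native_d, bond_d)
    n_atoms = len(ca)
    for step in range(1, n_steps + 1):
        idx = int(rng.integers(n_atoms))
        move = rng.normal(0.0, MOVE_SD, size=3)
        old = ca[idx].copy()
        ca[idx] = old + move
        e_new = _energy_terms(ca, pairs, native_d, bond_d)
        de = e_new - e_cur
        accept = de <= 0
        u = rng.random()  # drawn unconditionally: keeps the stream aligned
        if not accept and temperature_factor > 0:
            accept = u < np.exp(-de / temperature_factor)
        if accept:
            e_cur = e_new
        else:
            ca[idx] = old
        if step % stride == 0:
            frames.append(ca.copy())
    if len(frames) < 2:
        frames.append(ca.copy())
    return Trajectory(np.array(frames), frame_interval=stride, label=label)


# --- trajectory I/O -------------------------------------------------------

def read_trajectory_pdb(path: str | Path, selection: str = "CA",
                        label: str = "") -> Trajectory:
    """Multi-model PDB file -> Trajectory of the chosen atom selection."""
    import gemmi
    st = gemmi.read_pdb(str(Path(path)))
    frames = []
    for model in st:
        pos = []
        for ch in model:
            for res in ch:
                for at in res:
                    if at.element.is_hydrogen:
                        continue
                    if selection == "heavy" or at.name == selection:
                        pos.append([at.pos.x, at.pos.y, at.pos.z])
        frames.append(pos)
    return Trajectory(np.array(frames, float), label=label or Path(path).stem)


def read_trajectory_xyz(path: str | Path, label: str = "") -> Trajectory:
    """Plain XYZ frames (count line, comment line, atom lines) -> Trajectory."""
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2:i + 2 + n]
        frames.append([[float(x) for x in ln.split()[1:4]] for ln in block])
        i += 2 + n
    return Trajectory(np.array(frames, float), label=label or Path(path).stem)
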