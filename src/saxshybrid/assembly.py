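"""C2-symmetric rigid-body assembly against a scattering curve.

Two homodimers (an "upper" CBS-module-like dimer and a "lower"
nucleotide-binding-like dimer) are placed on a shared two-fold axis; the
relative rotation phi about the axis and the axial separation t are scanned
on a grid, clash-free candidates are ranked by the reduced chi-square of the
combined Debye curve against the data, a chi-square gate selects survivors,
and near-ties are ordered by morphological complementarity (buried
interface area minus a near-clash penalty).

Three search scenarios are supported: (1) both dimers rigid; (2) the upper
dimer predefined and the lower subunit free, its C2 mate generated by the
two-fold operation; (3) the roles reversed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .config import DEFAULT_CONFIG, Config
from .coordinates import CoordinateModel, concat_models
from .curves import ScatteringCurve
from .scattering import FitResult, ModelCurve, fit_scale_chi2

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# C2 axis detection
# --------------------------------------------------------------------------

@dataclass
class SymmetryAxis:
    direction: np.ndarray
    center: np.ndarray
    rotation_angle_found: float   # degrees


def detect_c2_axis(dimer: CoordinateModel,
                   chain_pair: tuple[str, str] | None = None,
                   angle_tol: float = 5.0,
                   min_common: int = 20) -> SymmetryAxis:
    """Recover the two-fold axis relating two chains of a dimer.

    A least-squares rotation mapping chain A onto chain B over residues with
    matching numbers is computed; its rotation angle must be within
    ``angle_tol`` of 180 degrees. The axis passes through the midpoint of
    the two chain centroids.
    """
    chains = list(dict.fromkeys(dimer.chain))
    if chain_pair is None:
        if len(chains) < 2:
            raise ValueError("dimer needs two chains")
        chain_pair = (chains[0], chains[1])
    A = dimer.select_chains([chain_pair[0]])
    B = dimer.select_chains([chain_pair[1]])
    common, ia, ib = np.intersect1d(A.resnum, B.resnum, return_indices=True)
    if len(common) < min_common:
        raise ValueError(f"insufficient matched residues ({len(common)} < {min_common})")
    P, Q = A.xyz[ia], B.xyz[ib]
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    angle = np.degrees(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)))
    if abs(angle - 180.0) > angle_tol:
        raise ValueError(f"not a C2 dimer: rotation angle {angle:.1f} degrees")
    evals, evecs = np.linalg.eig(R)
    k = int(np.argmin(np.abs(evals - 1.0)))
    u = np.real(evecs[:, k])
    u /= np.linalg.norm(u)
    center = 0.5 * (A.centroid(False) + B.centroid(False))
    return SymmetryAxis(direction=u, center=center,
                        rotation_angle_found=float(angle))


def _rotation_to_z(u: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector u to +z."""
    u = u / np.linalg.norm(u)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(u, z)
    s = np.linalg.norm(v)
    c = float(u @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else Rotation.from_euler("x", 180, degrees=True).as_matrix()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def _canonicalize(dimer: CoordinateModel, chain_pair=None) -> CoordinateModel:
    """Axis to +z, axis through the origin, body centroid at z = 0."""
    ax = detect_c2_axis(dimer, chain_pair)
    R = _rotation_to_z(ax.direction)
    out = dimer.translated(-ax.center).rotated(R)
    return out.translated([0.0, 0.0, -out.centroid(False)[2]])


def _rot_z(deg: float) -> np.ndarray:
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


def _c2_xyz(xyz: np.ndarray) -> np.ndarray:
    out = xyz.copy()
    out[:, :2] *= -1.0
    return out


# --------------------------------------------------------------------------
# fast Debye evaluation for grid searches
# --------------------------------------------------------------------------

class _FastDebye:
    """Precomputed sinc kernel over distance bins: I(q) = N + 2 K @ counts."""

    def __init__(self, q: np.ndarray, r_max: float, bin_w: float):
        self.bin_w = bin_w
        self.edges = np.arange(0.0, r_max + 2 * bin_w, bin_w)
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        self.K = np.sinc(np.outer(q, centers) / np.pi)
        self.q = q

    def counts(self, d: np.ndarray) -> np.ndarray:
        return np.histogram(d, bins=self.edges)[0]

    def intensity(self, n_particles: int, counts: np.ndarray) -> np.ndarray:
        return n_particles + 2.0 * (self.K @ counts)


def _fit(I_m: np.ndarray, data: ScatteringCurve) -> FitResult:
    return fit_scale_chi2(ModelCurve(data.q, I_m), data)


# --------------------------------------------------------------------------
# candidates
# --------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    scenario: int = 1
    bat_conformation: str = "twisted"      # or "flat"; label only
    chi2_gate: float = 2.0                 # 2.5 for phosphatase complexes

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if self.chi2_gate <= 0:
            raise ValueError("chi2 gate must be positive")


@dataclass
class AssemblyCandidate:
    phi: float                 # degrees, rotation about the shared axis
    t_axial: float             # A, centroid separation along the axis
    chi2: float
    clash_count: int
    scale: float = 1.0
    interface_area: float | None = None
    complementarity: float | None = None
    subunit_pose: tuple | None = None      # (r, azimuth, euler) for scenarios 2/3
    model: CoordinateModel | None = None


def build_assembly_model(up: CoordinateModel, lo_body: CoordinateModel,
                         phi: float, t: float) -> CoordinateModel:
    """Assemble canonicalized dimers at (phi, t); lower-dimer chains are
    renamed with a trailing prime to keep identities unique."""
    lower = lo_body.rotated(_rot_z(phi)).translated([0, 0, -t / 2.0])
    lower = replace(lower, chain=np.array([str(c) + "'" for c in lower.chain],
                                          dtype=object))
    return concat_models([up.translated([0, 0, t / 2.0]), lower])


def enumerate_assemblies(bat_dimer: CoordinateModel,
                         cnmp_dimer: CoordinateModel,
                         data: ScatteringCurve,
                         config: Config = DEFAULT_CONFIG,
                         keep_models: int = 5) -> list[AssemblyCandidate]:
    """Grid scan of (phi, t) for two C2 dimers on a shared axis.

    phi runs over [0, 180) (phi and phi + 180 are equivalent under C2); for
    each phi, t runs from the contact separation - 5 A to contact + 25 A.
    Candidates with any inter-body pair below the clash distance are flagged
    and excluded from ranking. Returns all candidates sorted by chi2, with
    coordinates attached to the best ``keep_models``.
    """
    a = config["assembly"]
    up = _canonicalize(bat_dimer)
    lo_body = _canonicalize(cnmp_dimer)
    clash = a["clash_dist"]

    xu, xl0 = up.xyz, lo_body.xyz
    extent = np.linalg.norm(xu, axis=1).max() + np.linalg.norm(xl0, axis=1).max()
    t_max_guess = extent + a["t_above_contact"] + 10.0
    fd = _FastDebye(data.q, extent + t_max_guess, config["debye"]["hist_bin"])
    c_up = fd.counts(pdist(xu))
    c_lo = fd.counts(pdist(xl0))          # intra distances are phi-invariant
    n_tot = len(xu) + len(xl0)

    cands: list[AssemblyCandidate] = []
    for phi in np.arange(0.0, 180.0, a["phi_step"]):
        xl = xl0 @ _rot_z(phi).T
        dxy2 = ((xu[:, None, :2] - xl[None, :, :2]) ** 2).sum(axis=2)
        dz0 = xu[:, 2][:, None] - xl[None, :, 2]
        # contact: smallest t with all cross distances >= clash
        near = dxy2 < clash ** 2
        if near.any():
            t_c = float(np.max(np.sqrt(clash ** 2 - dxy2[near]) - dz0[near]))
            t_c = max(t_c, 0.0)
        else:
            t_c = 0.0
        ts = np.arange(t_c - a["t_below_contact"],
                       t_c + a["t_above_contact"] + 1e-9, a["t_step"])
        for t in ts:
            if t < 0:
                continue
            d2 = dxy2 + (dz0 + t) ** 2
            n_clash = int((d2 < clash ** 2).sum())
            if n_clash > 0:
                cands.append(AssemblyCandidate(phi=float(phi), t_axial=float(t),
                                               chi2=np.inf, clash_count=n_clash))
                continue
            counts = c_up + c_lo + fd.counts(np.sqrt(d2).ravel())
            fit = _fit(fd.intensity(n_tot, counts), data)
            cands.append(AssemblyCandidate(phi=float(phi), t_axial=float(t),
                                           chi2=fit.chi2, clash_count=0,
                                           scale=fit.scale))
    cands.sort(key=lambda c: c.chi2)
    if not any(np.isfinite(c.chi2) for c in cands):
        log.warning("all candidates clash: empty survivor set")
    for c in cands[:keep_models]:
        if np.isfinite(c.chi2):
            c.model = build_assembly_model(up, lo_body, c.phi, c.t_axial)
    return cands


# --------------------------------------------------------------------------
# scenario search
# --------------------------------------------------------------------------

def _local_phi_minima(cands: list[AssemblyCandidate], phi_step: float):
    """Best candidate per phi value, then up to two distinct local minima."""
    by_phi: dict[float, AssemblyCandidate] = {}
    for c in cands:
        if np.isfinite(c.chi2) and (c.phi not in by_phi or c.chi2 < by_phi[c.phi].chi2):
            by_phi[c.phi] = c
    phis = sorted(by_phi)
    minima = []
    for i, p in enumerate(phis):
        left = by_phi[phis[i - 1]].chi2 if i > 0 else np.inf
        right = by_phi[phis[i + 1]].chi2 if i < len(phis) - 1 else np.inf
        if by_phi[p].chi2 <= left and by_phi[p].chi2 <= right:
            minima.append(by_phi[p])
    minima.sort(key=lambda c: c.chi2)
    out: list[AssemblyCandidate] = []
    for m in minima:
        if all(abs(m.phi - o.phi) > phi_step + 1e-9 for o in out):
            out.append(m)
        if len(out) == 2:
            break
    return out


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    candidates: list[AssemblyCandidate]
    survivors: list[AssemblyCandidate]        # clash-free, below the chi2 gate
    rotamer_pair: list[AssemblyCandidate]     # up to two distinct phi minima
    best: AssemblyCandidate | None


def scenario_search(spec: ScenarioSpec,
                    bat_input: CoordinateModel,
                    cnmp_input: CoordinateModel,
                    data: ScatteringCurve,
                    config: Config = DEFAULT_CONFIG,
                    seed: int = 0) -> ScenarioResult:
    """Run one of the three modeling scenarios and gate by chi-square.

    Scenario 1 takes two dimers; scenarios 2/3 take the predefined dimer
    plus a single free subunit whose mate is generated by the predefined
    partner's two-fold operation. Survivors whose chi2 lies within the
    configured tie window of the best are reordered by morphological
    complementarity.
    """
    a = config["assembly"]
    up = lo_body = None
    if spec.scenario == 1:
        cands = enumerate_assemblies(bat_input, cnmp_input, data, config=config)
        up = _canonicalize(bat_input)
        lo_body = _canonicalize(cnmp_input)
        group_upper = list(dict.fromkeys(up.chain))
    else:
        predefined = _canonicalize(bat_input if spec.scenario == 2 else cnmp_input)
        free = cnmp_input if spec.scenario == 2 else bat_input
        cands = _free_subunit_search(predefined, free, data, config, seed,
                                     predefined_on_top=(spec.scenario == 2))
        group_upper = list(dict.fromkeys(predefined.chain))

    survivors = [c for c in cands
                 if c.clash_count == 0 and np.isfinite(c.chi2)
                 and c.chi2 < spec.chi2_gate]
    rotamers = _local_phi_minima(survivors, a["phi_step"])

    if survivors:
        best_chi2 = survivors[0].chi2
        tied = [c for c in survivors if c.chi2 - best_chi2 < a["chi2_tie_window"]]
        for c in tied:
            if c.model is None and spec.scenario == 1:
                c.model = build_assembly_model(up, lo_body, c.phi, c.t_axial)
            if c.model is None:
                continue
            present = list(dict.fromkeys(c.model.chain))
            groupA = [ch for ch in present if ch in group_upper]
            groupB = [ch for ch in present if ch not in group_upper]
            if c.interface_area is None:
                c.interface_area = interface_area(c.model, groupA, groupB,
                                                  config=config)
            c.complementarity = complementarity_score(c.model, groupA, groupB,
                                                      config=config)
        tied.sort(key=lambda c: -(c.complementarity
                                  if c.complementarity is not None else -1e18))
        survivors = tied + survivors[len(tied):]
    best = survivors[0] if survivors else None
    return ScenarioResult(spec=spec, candidates=cands, survivors=survivors,
                          rotamer_pair=rotamers, best=best)


def _free_subunit_search(predefined: CoordinateModel, free: CoordinateModel,
                         data: ScatteringCurve, config: Config, seed: int,
                         predefined_on_top: bool) -> list[AssemblyCandidate]:
    """Scenarios 2/3: place one free subunit (radial offset, azimuth, Euler
    orientation, axial offset), duplicate it by the C2 operation, score the
    combined model. The pose grid is deterministically subsampled to the
    configured candidate budget."""
    a = config["assembly"]
    clash = a["clash_dist"]
    sub0 = replace(free, xyz=free.xyz - free.centroid(False))
    half_z = np.abs(predefined.xyz[:, 2]).max()
    sub_r = np.linalg.norm(sub0.xyz, axis=1).max()

    phis = np.arange(0.0, 180.0, a["phi_step"] * 2)
    radii = np.arange(0.0, a["radial_max"] + 1e-9, a["radial_step"])
    eul = np.arange(0.0, 360.0, a["euler_step"])
    eul_b = np.arange(0.0, 180.0 + 1e-9, a["euler_step"])
    t0 = max(half_z - sub_r, 0.0)
    ts = np.arange(t0, half_z + sub_r + a["t_above_contact"] + 1e-9,
                   a["t_step"] * 2)
    grid = list(itertools.product(phis, radii, ts, eul, eul_b, eul))
    budget = int(a["max_candidates"])
    if len(grid) > budget:
        rng = np.random.default_rng(seed)
        grid = [grid[i] for i in sorted(rng.choice(len(grid), size=budget,
                                                   replace=False))]
    sign = -1.0 if predefined_on_top else 1.0

    extent = half_z + sub_r + a["radial_max"] + ts[-1] + 20.0
    fd = _FastDebye(data.q, 2 * extent, config["debye"]["hist_bin"])
    c_pre = fd.counts(pdist(predefined.xyz))
    c_sub = fd.counts(pdist(sub0.xyz)) if len(sub0) > 1 else np.zeros(len(fd.K[0]), int)
    n_tot = len(predefined) + 2 * len(sub0)
    tree_pre = cKDTree(predefined.xyz)

    cands: list[AssemblyCandidate] = []
    for phi, r, t, ea, eb, ec in grid:
        Rsub = Rotation.from_euler("zyz", [ea, eb, ec], degrees=True).as_matrix()
        pos = _rot_z(phi) @ np.array([r, 0.0, 0.0]) + np.array([0.0, 0.0, sign * t])
        xyz1 = sub0.xyz @ Rsub.T + pos
        xyz2 = _c2_xyz(xyz1)
        d12 = cKDTree(xyz1).query(xyz2, k=1)[0]
        d1p = tree_pre.query(xyz1, k=1)[0]
        d2p = tree_pre.query(xyz2, k=1)[0]
        n_clash = int((d12 < clash).sum() + (d1p < clash).sum() + (d2p < clash).sum())
        pose = (float(r), float(phi), (float(ea), float(eb), float(ec)))
        if n_clash > 0:
            cands.append(AssemblyCandidate(phi=float(phi), t_axial=float(t),
                                           chi2=np.inf, clash_count=n_clash,
                                           subunit_pose=pose))
            continue
        cross = np.concatenate([
            np.linalg.norm(xyz1[:, None, :] - xyz2[None, :, :], axis=2).ravel(),
            np.linalg.norm(predefined.xyz[:, None, :] - xyz1[None, :, :], axis=2).ravel(),
            np.linalg.norm(predefined.xyz[:, None, :] - xyz2[None, :, :], axis=2).ravel(),
        ])
        counts = c_pre + 2 * c_sub + fd.counts(cross)
        fit = _fit(fd.intensity(n_tot, counts), data)
        m1 = replace(sub0, xyz=xyz1, chain=np.full(len(sub0), "X", dtype=object))
        m2 = replace(sub0, xyz=xyz2, chain=np.full(len(sub0), "Y", dtype=object))
        cands.append(AssemblyCandidate(phi=float(phi), t_axial=float(t),
                                       chi2=fit.chi2, clash_count=0,
                                       scale=fit.scale, subunit_pose=pose,
                                       model=concat_models([predefined, m1, m2])))
    cands.sort(key=lambda c: c.chi2)
    for c in cands[20:]:
        c.model = None          # bound memory; leaders keep coordinates
    return cands


# --------------------------------------------------------------------------
# buried surface and complementarity
# --------------------------------------------------------------------------

_ELEMENT_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _radii(model: CoordinateModel, config: Config) -> np.ndarray:
    a = config["assembly"]
    if model.granularity == "atomic":
        out = np.empty(len(model))
        for i, rn in enumerate(model.resname):
            name = str(rn).split(":")[-1].strip()
            el = name[0] if name and name[0] in _ELEMENT_RADII else None
            out[i] = _ELEMENT_RADII.get(el, 1.8)
        return out
    return np.full(len(model), a["bead_radius"])


def sasa(xyz: np.ndarray, radii: np.ndarray, probe: float,
         n_points: int) -> float:
    """Shrake-Rupley solvent-accessible surface area (A^2)."""
    pts = _fibonacci_sphere(n_points)
    R = radii + probe
    tree = cKDTree(xyz)
    total = 0.0
    max_r = R.max()
    for i in range(len(xyz)):
        nbrs = [j for j in tree.query_ball_point(xyz[i], R[i] + max_r) if j != i]
        surf = xyz[i] + pts * R[i]
        if nbrs:
            d = np.linalg.norm(surf[:, None, :] - xyz[nbrs][None, :, :], axis=2)
            exposed = np.all(d >= R[nbrs][None, :], axis=1)
        else:
            exposed = np.ones(n_points, bool)
        total += exposed.mean() * 4.0 * np.pi * R[i] ** 2
    return float(total)


def interface_area(model: CoordinateModel, groupA, groupB,
                   probe: float | None = None,
                   config: Config = DEFAULT_CONFIG) -> float:
    """Buried area between two chain groups, PISA convention:
    [SASA(A) + SASA(B) - SASA(A u B)] / 2."""
    if set(groupA) & set(groupB):
        raise ValueError("chain groups overlap")
    a = config["assembly"]
    probe = a["probe"] if probe is None else probe
    n_pts = int(a["sasa_points"])
    A = model.select_chains(groupA)
    B = model.select_chains(groupB)
    rA, rB = _radii(A, config), _radii(B, config)
    sA = sasa(A.xyz, rA, probe, n_pts)
    sB = sasa(B.xyz, rB, probe, n_pts)
    sAB = sasa(np.vstack([A.xyz, B.xyz]), np.concatenate([rA, rB]), probe, n_pts)
    return max(0.0, (sA + sB - sAB) / 2.0)


def _count_close(xa, xb, cutoff):
    return int(cKDTree(xa).count_neighbors(cKDTree(xb), cutoff))


def complementarity_score(model: CoordinateModel, groupA, groupB,
                          config: Config = DEFAULT_CONFIG) -> float:
    """Buried interface area minus a penalty for near-clash contacts
    (inter-group pairs between 3.0 and 3.5 A)."""
    a = config["assembly"]
    area = interface_area(model, groupA, groupB, config=config)
    A = model.select_chains(groupA)
    B = model.select_chains(groupB)
    n_hi = _count_close(A.xyz, B.xyz, a["near_clash_hi"])
    n_lo = _count_close(A.xyz, B.xyz, a["near_clash_lo"])
    return float(area - a["near_clash_penalty"] * (n_hi - n_lo))
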