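"""Ab initio dummy-residue shape reconstruction by simulated annealing,
plus ensemble alignment, normalized spatial discrepancy (NSD) and
occupancy-grid consensus averaging.

The reconstruction grows a chain-compatible model (one bead per residue,
3.8 A target bond length) inside a search sphere of radius Dmax/2 and
anneals single-bead Gaussian moves against

    E = chi2(Debye model vs curve) + w_bond * sum (d_adjacent - 3.8)^2
        + w_clash * #(non-adjacent pairs closer than 3.0 A).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .analysis import find_dmax, guinier_fit
from .config import DEFAULT_CONFIG, Config
from .coordinates import CoordinateModel, bead_model
from .curves import ScatteringCurve

log = logging.getLogger(__name__)


@dataclass
class AnnealSchedule:
    T0_factor: float = 1.0       # T0 = T0_factor * initial energy
    cooling: float = 0.8
    steps_per_stage: int | None = None   # default 100 * n_residues
    max_stages: int = 60
    seed: int = 0
    min_accept: float = 0.02     # stop once the stage acceptance rate falls below

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling must be in (0, 1)")
        if self.steps_per_stage is not None and self.steps_per_stage < 1:
            raise ValueError("steps_per_stage must be >= 1")


@dataclass
class BeadModel:
    model: CoordinateModel
    chi2: float
    energy: float
    search_radius: float
    converged: bool


def _sinc(x):
    # sin(x)/x without np.sinc's rescaling overhead
    out = np.sin(x)
    np.divide(out, x, out=out, where=x != 0)
    out[x == 0] = 1.0
    return out


def _chi2_of(I_m, I_d, w):
    denom = np.sum(I_m ** 2 * w)
    c = np.sum(I_m * I_d * w) / denom
    return np.sum(((c * I_m - I_d) ** 2) * w) / (len(I_d) - 1)


def _self_avoiding_walk(n, radius, rng, bond, min_sep):
    """Random chain inside a sphere; restarts individual steps on dead ends."""
    pts = np.empty((n, 3))
    pts[0] = rng.normal(size=3)
    pts[0] *= (radius * 0.3) / max(np.linalg.norm(pts[0]), 1e-9)
    for i in range(1, n):
        for _ in range(200):
            d = rng.normal(size=3)
            d *= bond / np.linalg.norm(d)
            cand = pts[i - 1] + d
            if np.linalg.norm(cand) > radius:
                continue
            if i > 1 and np.min(np.linalg.norm(pts[: i - 1] - cand, axis=1)) < min_sep:
                continue
            pts[i] = cand
            break
        else:
            # restart from a random placed bead
            j = rng.integers(0, i)
            pts[i] = pts[j] + rng.normal(size=3) * 0.1
    return pts


def reconstruct_beads(curve: ScatteringCurve, n_residues: int,
                      schedule: AnnealSchedule | None = None,
                      dmax: float | None = None,
                      config: Config = DEFAULT_CONFIG) -> BeadModel:
    """Anneal a dummy-residue chain against a curve; deterministic per seed.

    ``dmax`` sets the search-sphere diameter; when absent it is estimated
    from the curve via the Dmax scan.
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    schedule = schedule or AnnealSchedule()
    b = config["beads"]
    guinier_fit(curve, config=config)  # raises early if no Guinier region
    if dmax is None:
        dmax, _ = find_dmax(curve, config=config)
    radius = dmax / 2.0
    rng = np.random.default_rng(schedule.seed)

    cw = curve.windowed()
    n_q = min(int(b["n_q_anneal"]), len(cw))
    idx = np.unique(np.linspace(0, len(cw) - 1, n_q).astype(int))
    q = cw.q[idx]
    I_d = cw.I[idx]
    w = 1.0 / cw.sigma[idx] ** 2

    bond = b["bond_length"]
    clash = b["clash_dist"]
    w_bond, w_clash = b["w_bond"], b["w_clash"]
    sigma_step = b["step_sigma"]

    xyz = _self_avoiding_walk(n_residues, radius, rng, bond, clash)
    n = n_residues
    D = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    I_m = _sinc(q[:, None, None] * D[None, :, :]).sum(axis=(1, 2))

    d_adj = np.diagonal(D, offset=1)
    Eb = w_bond * float(np.sum((d_adj - bond) ** 2))
    clash_mask = D < clash
    np.fill_diagonal(clash_mask, False)
    n_clash = (clash_mask.sum() - 2 * np.sum(np.diagonal(clash_mask, offset=1))) / 2
    Ec = w_clash * float(n_clash)

    E = float(_chi2_of(I_m, I_d, w)) + Eb + Ec
    T = schedule.T0_factor * max(E, 1e-6)
    steps = schedule.steps_per_stage or 100 * n

    best_xyz, best_E = xyz.copy(), E
    others = np.arange(n)
    masks = []
    for k in range(n):
        mk = others != k
        if k > 0:
            mk &= others != k - 1
        if k < n - 1:
            mk &= others != k + 1
        masks.append(mk)
    for stage in range(schedule.max_stages):
        ks = rng.integers(0, n, size=steps)
        moves = rng.normal(0.0, sigma_step, size=(steps, 3))
        accepts = rng.random(steps)
        n_acc = 0
        for s in range(steps):
            k = ks[s]
            new_pos = xyz[k] + moves[s]
            if np.linalg.norm(new_pos) > 1.05 * radius:
                continue
            old_row = D[k]
            diff = xyz - new_pos
            new_row = np.sqrt(np.einsum("ij,ij->i", diff, diff))
            new_row[k] = 0.0
            # Debye delta: bead k's cross terms appear twice in the double sum
            # (the j = k entry contributes zero to the difference)
            rows = np.concatenate([new_row, old_row])
            S = _sinc(np.multiply.outer(q, rows))
            dI = 2.0 * (S[:, :n].sum(axis=1) - S[:, n:].sum(axis=1))
            I_new = I_m + dI
            dEb = 0.0
            if k > 0:
                dEb += (new_row[k - 1] - bond) ** 2 - (old_row[k - 1] - bond) ** 2
            if k < n - 1:
                dEb += (new_row[k + 1] - bond) ** 2 - (old_row[k + 1] - bond) ** 2
            dEb *= w_bond
            mask = masks[k]
            dEc = w_clash * float(np.sum(new_row[mask] < clash)
                                  - np.sum(old_row[mask] < clash))
            E_new = float(_chi2_of(I_new, I_d, w)) + Eb + dEb + Ec + dEc
            dE = E_new - E
            if dE <= 0 or accepts[s] < np.exp(-dE / T):
                xyz[k] = new_pos
                D[k, :] = new_row
                D[:, k] = new_row
                I_m = I_new
                Eb += dEb
                Ec += dEc
                E = E_new
                n_acc += 1
                if E < best_E - 1e-12:
                    best_E = E
                    best_xyz = xyz.copy()
        T *= schedule.cooling
        # frozen: essentially no moves are being accepted any more
        if n_acc < schedule.min_accept * steps:
            break

    xyz = best_xyz
    _refine_bonds(xyz, bond, config)
    model = bead_model(xyz, chain="A")
    # final exact chi2 on the full curve
    from .scattering import debye_intensity, fit_scale_chi2
    fit = fit_scale_chi2(debye_intensity(model, cw.q, config=config), cw)
    converged = fit.chi2 <= b["chi2_ceiling"]
    if not converged:
        log.warning("bead reconstruction did not converge: chi2 = %.2f", fit.chi2)
    return BeadModel(model=model, chi2=fit.chi2, energy=float(best_E),
                     search_radius=radius, converged=converged)


def _refine_bonds(xyz: np.ndarray, bond: float, config: Config,
                  n_iter: int = 200) -> None:
    """Project adjacent-bead distances into the allowed band in place."""
    lo, hi = config["beads"]["bond_lo"], config["beads"]["bond_hi"]
    for _ in range(n_iter):
        d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        bad = (d < lo) | (d > hi)
        if not bad.any():
            return
        for i in np.where(bad)[0]:
            v = xyz[i + 1] - xyz[i]
            dn = np.linalg.norm(v)
            corr = (bond - dn) / max(dn, 1e-9) * v / 2.0
            xyz[i] -= corr
            xyz[i + 1] += corr


# --------------------------------------------------------------------------
# alignment and NSD
# --------------------------------------------------------------------------

@dataclass
class AlignResult:
    R: np.ndarray
    t: np.ndarray
    inverted: bool
    nsd: float

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        x = -xyz if self.inverted else xyz
        return x @ self.R.T + self.t


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation minimizing |R P - Q| for paired centered points."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    return Vt.T @ np.diag([1.0, 1.0, d]) @ U.T


def _nsd_points(A: np.ndarray, B: np.ndarray) -> float:
    ta, tb = cKDTree(A), cKDTree(B)
    d_ab, _ = tb.query(A)          # each a to nearest b
    d_ba, _ = ta.query(B)
    # average nearest-neighbor distance within each set
    da = np.mean(cKDTree(A).query(A, k=2)[0][:, 1])
    db = np.mean(cKDTree(B).query(B, k=2)[0][:, 1])
    nsd2 = 0.5 * (np.mean(d_ab ** 2) / db ** 2 + np.mean(d_ba ** 2) / da ** 2)
    return float(np.sqrt(nsd2))


def _principal_axes(X: np.ndarray) -> np.ndarray:
    C = np.cov((X - X.mean(axis=0)).T)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    U = evecs[:, order]
    if np.linalg.det(U) < 0:
        U[:, 2] *= -1.0
    return U


def align_models(A: CoordinateModel, B: CoordinateModel,
                 allow_inversion: bool = False,
                 n_icp: int = 10) -> AlignResult:
    """Rigid transform of B onto A minimizing NSD.

    Starts from the 4 proper principal-axis sign combinations (8 with
    inversion) and refines each by nearest-neighbor ICP with Kabsch updates.
    """
    Xa, Xb = A.xyz, B.xyz
    ca, cb = Xa.mean(axis=0), Xb.mean(axis=0)
    Ua = _principal_axes(Xa)
    degenerate = False
    Ca = np.cov((Xa - ca).T)
    ev = np.sort(np.linalg.eigvalsh(Ca))
    if ev[1] < 1e-9 * max(ev[2], 1e-30):
        degenerate = True
        log.warning("degenerate (collinear) model: centroid-only alignment")

    best: AlignResult | None = None
    inversions = (False, True) if allow_inversion else (False,)
    signs = [np.diag(s) for s in
             ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1])]
    tree_a = cKDTree(Xa)
    for inv in inversions:
        Xb0 = -Xb if inv else Xb
        cb0 = Xb0.mean(axis=0)
        Ub = _principal_axes(Xb0)
        starts = [np.eye(3)]
        if not degenerate:
            starts += [Ua @ S @ Ub.T for S in signs]
        for R in starts:
            t = ca - R @ cb0
            for _ in range(0 if degenerate else n_icp):
                Y = Xb0 @ R.T + t
                _, nn = tree_a.query(Y)
                P = Xb0 - cb0
                Q = Xa[nn] - Xa[nn].mean(axis=0)
                R = _kabsch(P, Q)
                t = Xa[nn].mean(axis=0) - R @ cb0
            Y = Xb0 @ R.T + t
            val = _nsd_points(Xa, Y)
            if best is None or val < best.nsd:
                best = AlignResult(R=R, t=t, inverted=inv, nsd=val)
    return best


def nsd(A: CoordinateModel, B: CoordinateModel,
        align: bool = True, allow_inversion: bool = False) -> float:
    """Normalized spatial discrepancy between two bead models.

    NSD^2 = 1/2 [ (1/(N_A d_B^2)) sum_a min_b |a-b|^2
                + (1/(N_B d_A^2)) sum_b min_a |b-a|^2 ],
    d_X the mean nearest-neighbor distance within model X; computed after
    optimal superposition unless ``align`` is disabled.
    """
    if align:
        return align_models(A, B, allow_inversion=allow_inversion).nsd
    return _nsd_points(A.xyz, B.xyz)


# --------------------------------------------------------------------------
# ensemble averaging
# --------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    models: list
    nsd_matrix: np.ndarray
    mean_nsd: float
    reference_index: int
    kept: np.ndarray            # indices of models surviving the outlier cut
    averaged_model: CoordinateModel


def average_ensemble(models: list[CoordinateModel],
                     config: Config = DEFAULT_CONFIG) -> EnsembleResult:
    """All-pairs NSD, outlier rejection at mean + 2 SD, alignment to the most
    typical model, and an occupancy-grid consensus thresholded to enclose the
    median single-model volume."""
    k = len(models)
    if k < 2:
        raise ValueError("need at least 2 models")
    e = config["ensemble"]
    M = np.zeros((k, k))
    aligns = {}
    for i in range(k):
        for j in range(i + 1, k):
            res = align_models(models[i], models[j])
            M[i, j] = M[j, i] = res.nsd
            aligns[(i, j)] = res
    mean_per = M.sum(axis=1) / (k - 1)
    mu, sd = mean_per.mean(), mean_per.std()
    kept = np.where(mean_per <= mu + e["outlier_sd"] * sd + 1e-12)[0]
    if len(kept) < 2:
        kept = np.argsort(mean_per)[:2]
    sub_mean = np.array([M[i, kept].sum() / max(len(kept) - 1, 1) for i in kept])
    ref = int(kept[np.argmin(sub_mean)])

    # align survivors onto the reference frame
    voxel = e["voxel"]
    aligned = []
    for i in kept:
        if i == ref:
            aligned.append(models[i].xyz)
        else:
            a, b = (ref, i) if ref < i else (i, ref)
            res = aligns[(a, b)]
            if a == ref:
                aligned.append(res.apply(models[i].xyz))
            else:
                aligned.append(align_models(models[ref], models[i]).apply(models[i].xyz))

    def vox_keys(X):
        return set(map(tuple, np.floor(X / voxel).astype(int)))

    per_model = [vox_keys(X) for X in aligned]
    counts: dict[tuple, int] = {}
    for s in per_model:
        for v in s:
            counts[v] = counts.get(v, 0) + 1
    target = int(np.median([len(s) for s in per_model]))
    thr = 1
    for c in range(1, len(kept) + 1):
        n_at = sum(1 for v in counts.values() if v >= c)
        thr = c
        if n_at <= target:
            break
    centers = np.array([(np.array(v) + 0.5) * voxel
                        for v, cnt in counts.items() if cnt >= thr])
    consensus = bead_model(centers, chain="A")
    return EnsembleResult(models=models, nsd_matrix=M,
                          mean_nsd=float(M[np.triu_indices(k, 1)].mean()),
                          reference_index=ref, kept=kept,
                          averaged_model=consensus)
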