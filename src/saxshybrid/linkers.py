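"""Dummy-residue completion of rigid assemblies: disordered interdomain
linkers and C-terminal tails grown as biased self-avoiding chains and
selected against the scattering curve.

A chain is grown bead by bead at fixed 3.8 A steps. End-anchored linkers
steer each step inside a cone aimed at the target anchor whose half-angle
narrows as the remaining contour approaches the remaining gap; free tails
step uniformly. Chains clashing with their context or failing closure are
rejected. The best-scoring linker set is mirrored by the assembly's
two-fold operation, preserving exact C2 symmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import DEFAULT_CONFIG, Config
from .coordinates import CoordinateModel, bead_model, concat_models
from .curves import ScatteringCurve
from .scattering import debye_intensity, fit_scale_chi2

log = logging.getLogger(__name__)


@dataclass
class LinkerSpec:
    """One missing segment: start anchor position, optional end anchor
    (absent for a free tail), residue count and the clash context."""

    start: np.ndarray
    n_residues: int
    end: np.ndarray | None = None
    context: CoordinateModel | None = None
    chain: str = "A"
    start_resnum: int = 1

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        if self.end is not None:
            self.end = np.asarray(self.end, dtype=float)
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")

    def feasible(self, bond: float = 3.8) -> bool:
        if self.end is None:
            return True
        return float(np.linalg.norm(self.start - self.end)) <= bond * (self.n_residues + 1)


@dataclass
class LinkerChain:
    xyz: np.ndarray            # (n_residues, 3)
    closure_error: float       # 0 for free tails

    def __len__(self) -> int:
        return len(self.xyz)


def _uniform_dir(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _cone_dir(axis: np.ndarray, half_angle_rad: float, rng) -> np.ndarray:
    """Uniform direction within a cone about `axis`."""
    axis = axis / np.linalg.norm(axis)
    cos_max = np.cos(half_angle_rad)
    c = rng.uniform(cos_max, 1.0)
    s = np.sqrt(1.0 - c * c)
    az = rng.uniform(0.0, 2.0 * np.pi)
    # orthonormal frame around the axis
    a = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return c * axis + s * (np.cos(az) * e1 + np.sin(az) * e2)


def sample_linker(spec: LinkerSpec, n_trials: int = 1000, seed: int = 0,
                  max_accept: int | None = None,
                  config: Config = DEFAULT_CONFIG) -> list[LinkerChain]:
    """Grow up to ``n_trials`` chains, returning the accepted ones
    (optionally stopping after ``max_accept``); deterministic per seed."""
    lk = config["linkers"]
    bond, clash = lk["bond_length"], lk["clash_dist"]
    if not spec.feasible(bond):
        gap = float(np.linalg.norm(spec.start - spec.end))
        raise ValueError(
            f"infeasible linker: anchor gap {gap:.1f} A exceeds contour "
            f"{bond * (spec.n_residues + 1):.1f} A")
    rng = np.random.default_rng(seed)
    ctx_tree = None
    if spec.context is not None:
        # the anchor residues are bonded into the rigid bodies: context
        # particles in their immediate vicinity cannot be clash partners
        excl = lk["anchor_exclusion"]
        keep = np.linalg.norm(spec.context.xyz - spec.start, axis=1) > excl
        if spec.end is not None:
            keep &= np.linalg.norm(spec.context.xyz - spec.end, axis=1) > excl
        if keep.any():
            ctx_tree = cKDTree(spec.context.xyz[keep])
    wide = np.radians(lk["cone_wide_deg"])
    narrow = np.radians(lk["cone_narrow_deg"])
    slack_wide = lk["slack_wide"]
    accepted: list[LinkerChain] = []
    n = spec.n_residues
    step_retries = int(lk["step_retries"])
    for _ in range(n_trials):
        pts = np.empty((n, 3))
        prev = spec.start
        ok = True
        for k in range(n):
            hops_left = n - k          # this hop .. last bead
            placed = False
            for _attempt in range(step_retries):
                if spec.end is None:
                    d = _uniform_dir(rng)
                else:
                    to_end = spec.end - prev
                    gap = np.linalg.norm(to_end)
                    contour_left = bond * (hops_left + 1)  # incl. final hop
                    if gap > contour_left:
                        break                              # dead end
                    slack = contour_left / max(gap, 1e-9)
                    if slack >= slack_wide:
                        half = wide
                    else:
                        frac = (slack - 1.0) / (slack_wide - 1.0)
                        half = narrow + max(frac, 0.0) * (wide - narrow)
                    d = _cone_dir(to_end if gap > 1e-9 else _uniform_dir(rng),
                                  half, rng)
                cand = prev + bond * d
                if ctx_tree is not None and ctx_tree.query(cand, k=1)[0] < clash:
                    continue
                if k >= 2 and np.min(np.linalg.norm(pts[: k - 1] - cand,
                                                    axis=1)) < clash:
                    continue
                placed = True
                break
            if not placed:
                ok = False
                break
            pts[k] = cand
            prev = cand
        if not ok:
            continue
        if spec.end is not None:
            err = abs(float(np.linalg.norm(pts[-1] - spec.end)) - bond)
            if err > lk["closure_tol"]:
                continue
        else:
            err = 0.0
        accepted.append(LinkerChain(xyz=pts, closure_error=err))
        if max_accept is not None and len(accepted) >= max_accept:
            break
    if not accepted:
        raise RuntimeError(
            f"no accepted chains in {n_trials} trials (acceptance rate 0/{n_trials}); "
            "loosen the spec or increase n_trials")
    return accepted


@dataclass
class HybridModel:
    model: CoordinateModel
    chi2_full: float
    linkers: list[LinkerChain]           # protomer-1 chains, mirrored for protomer 2


def _c2_xyz(xyz: np.ndarray) -> np.ndarray:
    out = xyz.copy()
    out[:, :2] *= -1.0
    return out


def build_hybrid(assembly: CoordinateModel,
                 specs: list[LinkerSpec],
                 data: ScatteringCurve,
                 ensemble_size: int = 20,
                 seed: int = 0,
                 n_trials_per_chain: int = 2000,
                 config: Config = DEFAULT_CONFIG) -> HybridModel:
    """Sample ``ensemble_size`` linker/tail sets for protomer 1, mirror each
    by the C2 operation (z axis), score the completed model against the data
    and return the best single conformer.

    The assembly must already sit in its canonical frame (C2 axis = z).
    """
    rng = np.random.default_rng(seed)
    best: HybridModel | None = None
    for trial in range(ensemble_size):
        chains = []
        try:
            for j, spec in enumerate(specs):
                sub_seed = int(rng.integers(0, 2 ** 31 - 1))
                ctx = spec.context if spec.context is not None else assembly
                spec_ctx = LinkerSpec(spec.start, spec.n_residues, spec.end,
                                      ctx, spec.chain, spec.start_resnum)
                chains.append(sample_linker(spec_ctx, n_trials=n_trials_per_chain,
                                            seed=sub_seed, max_accept=1,
                                            config=config)[0])
        except RuntimeError:
            continue
        parts = [assembly]
        for j, ch in enumerate(chains):
            parts.append(bead_model(ch.xyz, chain=f"L{j}",
                                    start_resnum=specs[j].start_resnum))
            parts.append(bead_model(_c2_xyz(ch.xyz), chain=f"M{j}",
                                    start_resnum=specs[j].start_resnum))
        full = concat_models(parts)
        fit = fit_scale_chi2(debye_intensity(full, data.q, config=config), data)
        if best is None or fit.chi2 < best.chi2_full:
            best = HybridModel(model=full, chi2_full=fit.chi2, linkers=chains)
    if best is None:
        raise RuntimeError("no clash-free linker set found for any ensemble member")
    return best
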