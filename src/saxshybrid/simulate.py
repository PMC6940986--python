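"""Ground-truth toy structures and simulated SEC-SAXS-like curves.

The flagship shape is a two-domain homodimer with exact two-fold (C2)
symmetry: a dimer of "upper" blocks stacked on a dimer of "lower" blocks
along a shared axis, with an adjustable inter-dimer rotation (phi), axial
separation (t) and per-block twist — the architecture of a CBS-module dimer
sitting on a cyclic-nucleotide-binding-domain dimer. Curves carry
multiplicative-plus-floor Gaussian noise emulating the signal-to-noise decay
of an in-line size-exclusion SAXS measurement.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .config import DEFAULT_CONFIG, Config
from .coordinates import CoordinateModel, bead_model, concat_models, write_bead_pdb
from .curves import ScatteringCurve, write_curve
from .scattering import debye_intensity, model_rg


@dataclass
class ToyStructureSpec:
    """Parameters of a synthetic ground-truth particle.

    shape: "sphere" | "ellipsoid" | "two_domain_c2_dimer".
    For the dimer, each of the four blocks is a bead-filled ellipsoid with
    ``block_semi_axes``; monomers sit ``lateral_offset`` from the C2 axis and
    the two dimers are ``separation`` apart along it, the lower dimer rotated
    by ``phi_deg`` about the axis and the upper blocks twisted by
    ``twist_deg`` about their radial direction.
    """

    shape: str = "two_domain_c2_dimer"
    radius: float = 20.0                       # sphere radius, A
    semi_axes: tuple = (20.0, 20.0, 20.0)      # ellipsoid semi-axes, A
    block_semi_axes: tuple = (38.0, 16.0, 11.0)
    lateral_offset: float = 25.0               # A, monomer centroid off-axis
    separation: float = 36.0                   # A, inter-dimer axial distance
    twist_deg: float = 0.0
    phi_deg: float = 40.0
    n_beads: int = 1600                        # total bead budget (~4 A spacing)
    include_linkers: bool = False
    linker_residues: int = 33
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.twist_deg <= 90.0):
            raise ValueError("twist angle must be in [0, 90] degrees")


@dataclass
class NoiseSpec:
    """sigma(q) = rel_error * I(q) + floor_frac * I(0), Gaussian."""

    rel_error: float = 0.02
    floor_frac: float = 0.001
    seed: int = 0


@dataclass
class SimulatedDataset:
    truth_model: CoordinateModel
    truth: dict
    noiseless: ScatteringCurve
    noisy: ScatteringCurve


def default_q_grid(config: Config = DEFAULT_CONFIG, n_q: int | None = None) -> np.ndarray:
    qc = config["qgrid"]
    return np.linspace(qc["q_min"], qc["q_max"], n_q or int(qc["n_q"]))


# --------------------------------------------------------------------------
# structure builders
# --------------------------------------------------------------------------

def _ellipsoid_lattice(semi_axes, n_beads: int) -> np.ndarray:
    """Quasi-uniform bead filling of an ellipsoid on a cubic lattice whose
    spacing is chosen to yield approximately n_beads points."""
    a, b, c = semi_axes
    vol = 4.0 / 3.0 * np.pi * a * b * c
    s = (vol / max(n_beads, 1)) ** (1.0 / 3.0)
    nx = int(np.ceil(a / s)) + 1
    ny = int(np.ceil(b / s)) + 1
    nz = int(np.ceil(c / s)) + 1
    gx = (np.arange(-nx, nx) + 0.5) * s
    gy = (np.arange(-ny, ny) + 0.5) * s
    gz = (np.arange(-nz, nz) + 0.5) * s
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / c) ** 2 <= 1.0
    out = pts[inside]
    if len(out) < 20:
        raise ValueError("n_beads too small for this shape (fewer than 20 beads)")
    return out


def _c2(xyz: np.ndarray) -> np.ndarray:
    """Two-fold rotation about the z axis: (x, y, z) -> (-x, -y, z)."""
    out = xyz.copy()
    out[:, 0] *= -1.0
    out[:, 1] *= -1.0
    return out


def generate_structure(spec: ToyStructureSpec) -> CoordinateModel:
    """Build the bead model for a spec; dimers are exactly C2 by construction."""
    if spec.shape == "sphere":
        xyz = _ellipsoid_lattice((spec.radius,) * 3, spec.n_beads)
        return bead_model(xyz, chain="A")
    if spec.shape == "ellipsoid":
        xyz = _ellipsoid_lattice(spec.semi_axes, spec.n_beads)
        return bead_model(xyz, chain="A")
    if spec.shape != "two_domain_c2_dimer":
        raise ValueError(f"unknown shape {spec.shape!r}")

    n_block = max(spec.n_beads // 4, 20)
    block = _ellipsoid_lattice(spec.block_semi_axes, n_block)
    t2 = spec.separation / 2.0
    off = np.array([spec.lateral_offset, 0.0, 0.0])

    # upper (CBS-module-like) monomer: the twist pivots the block about its
    # own centroid (tilt out of the disk plane plus in-plane rotation),
    # turning the flat disk into a twisted one
    Rtw = Rotation.from_euler("yz", [spec.twist_deg, spec.twist_deg],
                              degrees=True).as_matrix()
    upper = block @ Rtw.T + off + np.array([0.0, 0.0, t2])
    # lower (nucleotide-binding-like) monomer, whole dimer rotated by phi
    lower = block + off + np.array([0.0, 0.0, -t2])
    lower = lower @ Rotation.from_euler("z", spec.phi_deg, degrees=True).as_matrix().T

    parts = [
        bead_model(upper, chain="A"),
        bead_model(_c2(upper), chain="B"),
        bead_model(lower, chain="C"),
        bead_model(_c2(lower), chain="D"),
    ]
    if spec.include_linkers:
        # straight interpolated bead chain between the block centroids of one
        # protomer, mirrored by the C2 operation
        a = upper.mean(axis=0)
        b = lower.mean(axis=0)
        ts = np.linspace(0.0, 1.0, spec.linker_residues + 2)[1:-1]
        link = a[None, :] + ts[:, None] * (b - a)[None, :]
        parts.append(bead_model(link, chain="E", start_resnum=512))
        parts.append(bead_model(_c2(link), chain="F", start_resnum=512))
    return concat_models(parts)


# --------------------------------------------------------------------------
# curve simulation
# --------------------------------------------------------------------------

def simulate_curve(model: CoordinateModel,
                   q_grid: np.ndarray | None = None,
                   noise: NoiseSpec | None = None,
                   label: str = "simulated",
                   truth_extra: dict | None = None,
                   config: Config = DEFAULT_CONFIG) -> SimulatedDataset:
    """Noiseless Debye curve plus a Gaussian-noise replicate; deterministic
    for a fixed noise seed."""
    noise = noise or NoiseSpec()
    q = default_q_grid(config) if q_grid is None else np.asarray(q_grid, float)
    mc = debye_intensity(model, q, config=config)
    I0 = debye_intensity(model, np.array([0.0]), config=config).I[0]
    sig = noise.rel_error * np.abs(mc.I) + noise.floor_frac * I0
    rng = np.random.default_rng(noise.seed)
    noisy_I = mc.I + rng.normal(0.0, 1.0, len(q)) * sig
    # unit placeholder uncertainties when the simulation is noise-free
    sig_store = np.where(sig > 0, sig, 1.0)
    truth = {
        "Rg": model_rg(model),
        "Dmax": float(pdist(model.xyz).max()) if len(model) > 1 else 0.0,
        "I0": float(I0),
    }
    if truth_extra:
        truth.update(truth_extra)
    return SimulatedDataset(
        truth_model=model,
        truth=truth,
        noiseless=ScatteringCurve(q, mc.I, sig_store, label=label + " (noiseless)"),
        noisy=ScatteringCurve(q, noisy_I, sig_store, label=label + " (noisy)"),
    )


# --------------------------------------------------------------------------
# benchmark fixture suite
# --------------------------------------------------------------------------

def make_benchmark_suite(out_dir: str, seed: int = 0,
                         n_q: int = 256,
                         config: Config = DEFAULT_CONFIG) -> pd.DataFrame:
    """Emit the fixed fixture set: sphere, dumbbell, flat dimer, twisted
    dimer, dimer with linkers, and a degenerate two-phi-minima target.

    Each fixture gets a truth PDB, noiseless/noisy curves (.dat) and a row in
    the TSV manifest. Regeneration with the same seed is byte-identical.
    """
    os.makedirs(out_dir, exist_ok=True)
    q = default_q_grid(config, n_q=n_q)
    rows = []

    def emit(name, model, truth_extra, noise_seed, mixture_with=None):
        ds = simulate_curve(model, q, NoiseSpec(seed=noise_seed),
                            label=name, truth_extra=truth_extra, config=config)
        if mixture_with is not None:
            # equal-weight two-state mixture: the chi2 landscape in phi is bimodal
            alt = debye_intensity(mixture_with, q, config=config)
            mixed = 0.5 * (debye_intensity(model, q, config=config).I + alt.I)
            sig = 0.02 * np.abs(mixed) + 0.001 * mixed[0]
            rng = np.random.default_rng(noise_seed)
            noisy = mixed + rng.normal(0.0, 1.0, len(q)) * sig
            ds.noiseless = ScatteringCurve(q, mixed, np.where(sig > 0, sig, 1.0),
                                           label=name + " (noiseless)")
            ds.noisy = ScatteringCurve(q, noisy, ds.noiseless.sigma,
                                       label=name + " (noisy)")
        pdb = os.path.join(out_dir, f"{name}.pdb")
        dat0 = os.path.join(out_dir, f"{name}_noiseless.dat")
        dat1 = os.path.join(out_dir, f"{name}_noisy.dat")
        write_bead_pdb(model, pdb)
        write_curve(ds.noiseless, dat0)
        write_curve(ds.noisy, dat1)
        # manifest records file names relative to its own directory so that
        # regeneration is byte-identical wherever the suite is written
        row = {"fixture": name, "pdb": f"{name}.pdb",
               "noiseless": f"{name}_noiseless.dat",
               "noisy": f"{name}_noisy.dat", "seed": noise_seed}
        row.update({k: v for k, v in ds.truth.items()})
        if truth_extra:
            row.update(truth_extra)
        rows.append(row)
        return ds

    sphere = generate_structure(ToyStructureSpec(shape="sphere", radius=20.0,
                                                 n_beads=500, seed=seed))
    emit("sphere", sphere, {"volume_nm3": 4 / 3 * np.pi * 20.0 ** 3 / 1000}, seed + 1)

    ball = _ellipsoid_lattice((10.0,) * 3, 120)
    dumbbell = bead_model(np.vstack([ball + [0, 0, 30.0], ball - [0, 0, 30.0]]))
    emit("dumbbell", dumbbell, {"volume_nm3": 2 * 4 / 3 * np.pi * 1.0}, seed + 2)

    spec_flat = ToyStructureSpec(twist_deg=0.0, phi_deg=40.0, seed=seed)
    flat = generate_structure(spec_flat)
    emit("flat_dimer", flat, {"phi": spec_flat.phi_deg, "t": spec_flat.separation,
                              "conformation": "flat"}, seed + 3)

    spec_tw = ToyStructureSpec(twist_deg=30.0, phi_deg=40.0, seed=seed)
    twisted = generate_structure(spec_tw)
    emit("twisted_dimer", twisted,
         {"phi": spec_tw.phi_deg, "t": spec_tw.separation,
          "conformation": "twisted"}, seed + 4)

    spec_lk = ToyStructureSpec(twist_deg=0.0, phi_deg=40.0,
                               include_linkers=True, seed=seed)
    linked = generate_structure(spec_lk)
    emit("dimer_with_linkers", linked,
         {"phi": spec_lk.phi_deg, "t": spec_lk.separation,
          "conformation": "flat"}, seed + 5)

    m1 = generate_structure(ToyStructureSpec(twist_deg=0.0, phi_deg=30.0, seed=seed))
    m2 = generate_structure(ToyStructureSpec(twist_deg=0.0, phi_deg=90.0, seed=seed))
    emit("two_phi_minima", m1, {"phi": 30.0, "phi_alt": 90.0,
                                "t": spec_flat.separation,
                                "conformation": "flat"}, seed + 6, mixture_with=m2)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    for col in ("pdb", "noiseless", "noisy"):
        manifest[col] = [os.path.join(out_dir, v) for v in manifest[col]]
    return manifest
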