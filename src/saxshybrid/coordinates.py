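"""Coordinate models: atomic or one-bead-per-residue (dummy residue) particles.

The container is deliberately flat — parallel numpy arrays plus identity
records — because everything downstream (Debye sums, SASA, annealing moves)
wants vectorized positions, not an object hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import gemmi
import numpy as np

from .curves import RESIDUE_MASS

# 3-letter -> 1-letter for mass lookup of bead models
THREE_TO_ONE = {
    "GLY": "G", "ALA": "A", "SER": "S", "PRO": "P", "VAL": "V", "THR": "T",
    "CYS": "C", "LEU": "L", "ILE": "I", "ASN": "N", "ASP": "D", "GLN": "Q",
    "LYS": "K", "GLU": "E", "MET": "M", "HIS": "H", "PHE": "F", "ARG": "R",
    "TYR": "Y", "TRP": "W",
}
_MEAN_RESIDUE_MASS = float(np.mean(list(RESIDUE_MASS.values())))


@dataclass
class CoordinateModel:
    """Particles with chain/residue identity, positions (A), masses (Da) and
    scattering weights f (dimensionless, uniform 1.0 by default)."""

    chain: np.ndarray          # str array
    resnum: np.ndarray         # int array; insertion codes folded into resname key
    resname: np.ndarray        # str array (residue name + optional icode)
    xyz: np.ndarray            # (N, 3) float, Angstrom
    mass: np.ndarray           # float, Da
    f: np.ndarray              # scattering weight per particle
    granularity: str = "residue-bead"   # or "atomic"

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = len(self.xyz)
        if n == 0:
            raise ValueError("a model needs at least one particle")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        for name in ("chain", "resnum", "resname", "mass", "f"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.xyz)

    # ---- geometry helpers -------------------------------------------------
    def centroid(self, mass_weighted: bool = True) -> np.ndarray:
        w = self.mass if mass_weighted else np.ones(len(self))
        return np.average(self.xyz, axis=0, weights=w)

    def translated(self, t: np.ndarray) -> "CoordinateModel":
        return replace(self, xyz=self.xyz + np.asarray(t, dtype=float))

    def rotated(self, R: np.ndarray, center: np.ndarray | None = None) -> "CoordinateModel":
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        return replace(self, xyz=(self.xyz - c) @ np.asarray(R).T + c)

    def select_chains(self, chains) -> "CoordinateModel":
        m = np.isin(self.chain, list(chains))
        if not m.any():
            raise ValueError(f"no particles in chains {chains!r}")
        return CoordinateModel(self.chain[m], self.resnum[m], self.resname[m],
                               self.xyz[m], self.mass[m], self.f[m],
                               granularity=self.granularity)

    def with_chain(self, chain_id: str) -> "CoordinateModel":
        return replace(self, chain=np.full(len(self), chain_id, dtype=object))


def concat_models(models) -> CoordinateModel:
    models = list(models)
    return CoordinateModel(
        np.concatenate([m.chain for m in models]),
        np.concatenate([m.resnum for m in models]),
        np.concatenate([m.resname for m in models]),
        np.vstack([m.xyz for m in models]),
        np.concatenate([m.mass for m in models]),
        np.concatenate([m.f for m in models]),
        granularity=models[0].granularity,
    )


def bead_model(xyz: np.ndarray, chain: str = "A", start_resnum: int = 1,
               resname: str = "DUM", mass: float | None = None) -> CoordinateModel:
    """Build a uniform dummy-residue model from bare positions."""
    xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
    n = len(xyz)
    m = _MEAN_RESIDUE_MASS if mass is None else mass
    return CoordinateModel(
        np.full(n, chain, dtype=object),
        np.arange(start_resnum, start_resnum + n),
        np.full(n, resname, dtype=object),
        xyz,
        np.full(n, m),
        np.ones(n),
        granularity="residue-bead",
    )


def read_coordinates(path: str, granularity: str = "residue-bead") -> CoordinateModel:
    """Read a PDB file (first MODEL only) as an atomic or residue-bead model.

    Bead granularity keeps one bead per residue at the C-alpha position,
    falling back to the geometric centroid of the residue's atoms; alternate
    locations keep the highest-occupancy conformer; insertion codes are folded
    into the residue identity.
    """
    st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no parseable coordinates")
    model = st[0]
    chains, resnums, resnames, xyz, masses = [], [], [], [], []
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            rid = res.name + (f"^{icode}" if icode else "")
            # highest-occupancy conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                k = atom.name
                if k not in best or atom.occ > best[k].occ:
                    best[k] = atom
            atoms = list(best.values())
            if not atoms:
                continue
            if granularity == "atomic":
                for atom in atoms:
                    chains.append(chain.name)
                    resnums.append(res.seqid.num)
                    resnames.append(rid + ":" + atom.name)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    masses.append(atom.element.weight)
            else:
                ca = best.get("CA")
                if ca is not None:
                    pos = [ca.pos.x, ca.pos.y, ca.pos.z]
                else:
                    pos = np.mean([[a.pos.x, a.pos.y, a.pos.z] for a in atoms], axis=0)
                one = THREE_TO_ONE.get(res.name)
                chains.append(chain.name)
                resnums.append(res.seqid.num)
                resnames.append(rid)
                xyz.append(list(pos))
                masses.append(RESIDUE_MASS[one] if one else _MEAN_RESIDUE_MASS)
    if not xyz:
        raise ValueError(f"{path}: no parseable coordinates")
    n = len(xyz)
    return CoordinateModel(
        np.array(chains, dtype=object), np.array(resnums), np.array(resnames, dtype=object),
        np.array(xyz), np.array(masses), np.ones(n),
        granularity=granularity,
    )


def write_bead_pdb(model: CoordinateModel, path: str) -> None:
    """Write a bead (or atomic) model as PDB with one CA pseudo-atom per particle."""
    with open(path, "w") as fh:
        serial = 1
        for i in range(len(model)):
            x, y, z = model.xyz[i]
            resname = str(model.resname[i])[:3].ljust(3) or "DUM"
            chain = str(model.chain[i])[:1] or "A"
            fh.write(
                f"ATOM  {serial % 100000:5d}  CA  {resname} {chain}"
                f"{int(model.resnum[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
            serial += 1
        fh.write("END\n")
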