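"""1D SAXS curves: container, text I/O, instrument geometry and sequence mass.

Curves are 3-column whitespace text (q [1/A], I, sigma) with '#' comments,
the dialect used by SASBDB depositions and the ATSAS suite. Intensities are
treated as arbitrary units throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

# hc in keV * Angstrom, for converting photon energy to wavelength
HC_KEV_A = 12.3984

# standard average residue masses (Da); a chain adds one water
WATER_MASS = 18.0153
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}


@dataclass
class ScatteringGeometry:
    """Instrument geometry relating detector angle to momentum transfer.

    Parameters
    ----------
    wavelength : float or None
        X-ray wavelength in Angstrom. May be omitted if `energy` is given.
    scattering_angle : float
        Full scattering angle 2-theta in degrees, in [0, 180).
    energy : float or None
        Photon energy in keV; converted to wavelength as hc/E with
        hc = 12.3984 keV*A when `wavelength` is absent.
    """

    wavelength: float | None = None
    scattering_angle: float = 0.0
    energy: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength is None:
            if self.energy is None:
                raise ValueError("either wavelength or energy is required")
            self.wavelength = HC_KEV_A / float(self.energy)
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not (0.0 <= self.scattering_angle < 180.0):
            raise ValueError("scattering angle 2-theta must be in [0, 180)")


def q_from_angle(geometry: ScatteringGeometry) -> float:
    """Momentum transfer q = 4 pi sin(theta) / lambda, theta = half of 2-theta."""
    theta = np.radians(geometry.scattering_angle / 2.0)
    return float(4.0 * np.pi * np.sin(theta) / geometry.wavelength)


@dataclass
class ScatteringCurve:
    """A measured or simulated 1D profile (q, I, sigma).

    Invariants enforced on construction: equal lengths >= 3, strictly
    increasing q (rows are sorted if needed), strictly positive sigma.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    label: str = ""
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.I) == len(self.sigma)):
            raise ValueError("q, I, sigma must have equal length")
        if len(self.q) < 3:
            raise ValueError("a curve needs at least 3 points")
        order = np.argsort(self.q)
        if not np.all(order == np.arange(len(self.q))):
            self.q, self.I, self.sigma = self.q[order], self.I[order], self.sigma[order]
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q values must be strictly increasing (duplicates found)")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma must be positive")

    def __len__(self) -> int:
        return len(self.q)

    def windowed(self) -> "ScatteringCurve":
        """Restrict the curve to its analysis window (no-op if unset)."""
        if self.window is None:
            return self
        lo, hi = self.window
        m = (self.q >= lo) & (self.q <= hi)
        return ScatteringCurve(self.q[m], self.I[m], self.sigma[m],
                               label=self.label, window=self.window)


_FLOAT_RE = re.compile(r"^[-+0-9.eEdD]+$")


def read_curve(path: str) -> ScatteringCurve:
    """Read a 3+ column whitespace text curve; extra columns are ignored.

    Comment ('#') and non-numeric header lines are skipped; rows with
    non-positive sigma are dropped with a warning.
    """
    rows: list[tuple[float, float, float]] = []
    label = ""
    window = None
    n_bad_sigma = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*label:\s*(.*)", line)
                if m:
                    label = m.group(1).strip()
                m = re.match(r"#\s*window:\s*([-\d.eE+]+)\s+([-\d.eE+]+)", line)
                if m:
                    window = (float(m.group(1)), float(m.group(2)))
                continue
            parts = line.split()
            if len(parts) < 3 or not all(_FLOAT_RE.match(p) for p in parts[:3]):
                continue  # header text
            try:
                q, i, s = (float(p.replace("D", "E").replace("d", "e"))
                           for p in parts[:3])
            except ValueError:
                continue
            if s <= 0:
                n_bad_sigma += 1
                continue
            rows.append((q, i, s))
    if n_bad_sigma:
        log.warning("%s: dropped %d rows with non-positive sigma", path, n_bad_sigma)
    if len(rows) < 3:
        raise ValueError(f"{path}: fewer than 3 valid data rows")
    arr = np.array(rows)
    return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2], label=label, window=window)


def write_curve(curve: ScatteringCurve, path: str) -> None:
    """Write a curve in the 3-column dialect read by :func:`read_curve`."""
    with open(path, "w") as fh:
        fh.write(f"# label: {curve.label}\n")
        if curve.window is not None:
            fh.write(f"# window: {curve.window[0]:.6g} {curve.window[1]:.6g}\n")
        fh.write("# q(1/A)  I(a.u.)  sigma\n")
        for q, i, s in zip(curve.q, curve.I, curve.sigma):
            fh.write(f"{q:.8g} {i:.8g} {s:.8g}\n")


def subtract_background(sample: ScatteringCurve,
                        buffer: ScatteringCurve,
                        q_tol: float = 1e-6) -> ScatteringCurve:
    """Point-wise buffer subtraction with uncertainty propagation in quadrature."""
    if len(sample) != len(buffer) or np.any(np.abs(sample.q - buffer.q) > q_tol):
        raise ValueError("sample and buffer are on different q grids")
    return ScatteringCurve(
        sample.q.copy(),
        sample.I - buffer.I,
        np.sqrt(sample.sigma ** 2 + buffer.sigma ** 2),
        label=sample.label,
        window=sample.window,
    )


@dataclass
class SequenceMassResult:
    sequence: str
    mass: float  # average molecular mass, Da


def sequence_mass(sequence: str) -> SequenceMassResult:
    """Average molecular mass of a one-letter protein sequence plus one water."""
    total = WATER_MASS
    for aa in sequence.upper():
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown amino-acid letter: {aa!r}") from None
    return SequenceMassResult(sequence=sequence, mass=total)
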