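"""Central configuration: every tolerance, grid step and penalty weight used
across the pipeline, overridable from a single YAML file.

Defaults are the package's documented choices (see docs/methods.md); code
elsewhere never hard-codes a number that appears here.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import yaml

_DEFAULTS: dict[str, Any] = {
    "debye": {
        # pairwise-distance histogram bin width (Angstrom)
        "hist_bin": 0.1,
    },
    "guinier": {
        "srg_min": 0.3,
        "srg_max": 1.3,
        "max_iter": 20,
    },
    "pr": {
        "n_r": 101,
        # log10 range scanned for the smoothness weight alpha
        "alpha_log_min": -4.0,
        "alpha_log_max": 2.0,
        "alpha_n": 13,
    },
    "dmax_scan": {
        "step": 2.0,           # Angstrom
        "lo_factor": 2.0,      # scan starts at lo_factor * Rg
        "hi_factor": 4.0,
        "w_neg": 10.0,
        "w_rough": 1.0,
    },
    "porod": {
        "exponent_srg_lo": 2.5,
        "exponent_srg_hi": 6.0,
    },
    "beads": {
        "bond_length": 3.8,    # Angstrom, adjacent dummy residues
        "bond_lo": 3.0,
        "bond_hi": 4.6,
        "clash_dist": 3.0,
        "w_bond": 10.0,
        "w_clash": 10.0,
        "step_sigma": 1.0,     # Gaussian move size, Angstrom
        "chi2_ceiling": 5.0,   # convergence flag threshold
        "n_q_anneal": 50,      # coarse q grid used inside annealing
    },
    "ensemble": {
        "voxel": 2.0,          # Angstrom, consensus occupancy grid
        "outlier_sd": 2.0,
    },
    "assembly": {
        "phi_step": 5.0,       # degrees
        "t_step": 1.0,         # Angstrom
        "t_below_contact": 5.0,
        "t_above_contact": 25.0,
        "clash_dist": 3.0,
        "euler_step": 30.0,    # degrees, scenarios 2/3 free-subunit search
        "radial_step": 2.0,    # Angstrom
        "radial_max": 40.0,
        "max_candidates": 20000,
        "chi2_tie_window": 0.2,
        "near_clash_lo": 3.0,
        "near_clash_hi": 3.5,
        "near_clash_penalty": 50.0,
        "sasa_points": 960,
        "probe": 1.4,          # Angstrom
        "bead_radius": 3.5,    # Angstrom, SASA radius of a residue bead
    },
    "linkers": {
        "bond_length": 3.8,
        "bond_tol": 0.2,
        "clash_dist": 3.0,
        "closure_tol": 0.5,
        # context beads this close to an anchor are not clash partners
        # (the anchor residue is covalently part of the rigid body)
        "anchor_exclusion": 8.0,
        # direction redraws allowed per bead before the chain is rejected
        "step_retries": 50,
        "cone_wide_deg": 90.0,
        "cone_narrow_deg": 15.0,
        "slack_wide": 2.0,     # remaining contour / gap ratio above which cone is wide
    },
    "noise": {
        "rel_error": 0.02,
        "floor_frac": 0.001,
    },
    "qgrid": {
        "q_min": 0.004,
        "q_max": 0.42,
        "n_q": 512,
    },
}


@dataclass
class Config:
    """Nested dict of all tunables with attribute-free dict access."""

    values: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(_DEFAULTS))

    def __getitem__(self, section: str) -> dict[str, Any]:
        return self.values[section]

    @classmethod
    def load(cls, path: str) -> "Config":
        """Load a YAML file and deep-merge it over the defaults."""
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = cls()
        _merge(cfg.values, user)
        return cfg


def _merge(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


DEFAULT_CONFIG = Config()
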