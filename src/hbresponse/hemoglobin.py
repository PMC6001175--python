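"""Optical hemoglobin biomarkers.

Near-infrared absorption reconstructed at four wavelengths (740, 780, 808,
830 nm) is unmixed into oxy- and deoxy-hemoglobin concentration maps via the
Beer-Lambert relation; the tumor region of interest (ROI) is summarised by the
maximum of each map, replicate acquisitions are averaged after motion
exclusion, and longitudinal change is expressed as a percentage of the
pretreatment (baseline) value (%tHb; analogously %US for tumor size).

Image reconstruction itself is out of scope: absorption maps are taken as
given (or simulated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "WAVELENGTHS_NM",
    "ExtinctionTable",
    "DEFAULT_EXTINCTION",
    "AbsorptionMap",
    "HbMap",
    "unmix_chromophores",
    "max_over_roi",
    "average_replicate_max",
    "percent_tHb",
    "percent_us",
    "write_absorption_map",
    "read_absorption_map",
]

#: Laser-diode wavelengths of the imager, nm.
WAVELENGTHS_NM = (740, 780, 808, 830)

#: ln(10) × 1e-6 — converts ε (L·mol⁻¹·cm⁻¹) times C (μmol/L) into μa (cm⁻¹)
#: under the decadic-extinction convention used throughout this module.
_MU_A_SCALE = float(np.log(10.0) * 1e-6)


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of oxy-/deoxy-hemoglobin (L·mol⁻¹·cm⁻¹).

    The coefficients are configuration, not ground truth: any published
    compilation may be substituted so long as the 4×2 design matrix retains
    full rank. Decadic convention (absorbance base 10); the ln(10) factor is
    applied when forming absorption coefficients.
    """

    wavelengths: tuple[int, ...] = WAVELENGTHS_NM
    epsilon_oxy: tuple[float, ...] = ()
    epsilon_deoxy: tuple[float, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.wavelengths) != 4:
            raise ValueError("extinction table must cover exactly 4 wavelengths")
        if len(self.epsilon_oxy) != 4 or len(self.epsilon_deoxy) != 4:
            raise ValueError("need one oxy and one deoxy coefficient per wavelength")
        if min(self.epsilon_oxy) <= 0 or min(self.epsilon_deoxy) <= 0:
            raise ValueError("extinction coefficients must be positive")
        if np.linalg.matrix_rank(self.design_matrix()) < 2:
            raise ValueError("extinction design matrix is rank deficient")

    def design_matrix(self) -> np.ndarray:
        """4×2 matrix mapping (C_oxy, C_deoxy) in μmol/L to μa in cm⁻¹."""
        eps = np.column_stack([self.epsilon_oxy, self.epsilon_deoxy])
        return _MU_A_SCALE * eps


#: Compiled oxy/deoxy-hemoglobin extinction coefficients at the four diode
#: wavelengths, from the OMLC (Prahl) hemoglobin tabulation, L·mol⁻¹·cm⁻¹.
DEFAULT_EXTINCTION = ExtinctionTable(
    wavelengths=WAVELENGTHS_NM,
    epsilon_oxy=(446.0, 710.0, 866.1, 974.0),
    epsilon_deoxy=(1115.9, 1075.4, 737.3, 693.0),
    source="OMLC compiled hemoglobin spectra (S. Prahl), tabulated values",
)


@dataclass
class AbsorptionMap:
    """Reconstructed absorption maps μa(λ) (cm⁻¹) plus the tumor ROI.

    ``mu_a`` maps wavelength (nm) to an array; all arrays must be congruent in
    shape and nonnegative. ``roi`` is a flat-index sequence into the grid.
    """

    mu_a: Mapping[int, np.ndarray]
    roi: Sequence[int] = field(default_factory=list)
    voxel_size_cm: float = 0.25

    def __post_init__(self) -> None:
        self.mu_a = {int(k): np.asarray(v, dtype=float) for k, v in self.mu_a.items()}
        shapes = {v.shape for v in self.mu_a.values()}
        if len(shapes) != 1:
            raise ValueError("absorption grids are not congruent in shape")
        for lam, grid in self.mu_a.items():
            if np.any(grid < 0):
                raise ValueError(f"negative absorption at {lam} nm")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.mu_a.values())).shape


@dataclass
class HbMap:
    """Voxelwise oxyHb / deoxyHb concentration maps (μmol/L); tHb = sum."""

    oxy: np.ndarray
    deoxy: np.ndarray
    roi: Sequence[int] = field(default_factory=list)

    @property
    def tHb(self) -> np.ndarray:
        return self.oxy + self.deoxy


def unmix_chromophores(
    amap: AbsorptionMap, table: ExtinctionTable = DEFAULT_EXTINCTION
) -> HbMap:
    """Unmix four-wavelength absorption into hemoglobin concentrations.

    Solves, per voxel, the overdetermined Beer-Lambert system
    ``μa(λ) = ln(10)·(ε_oxy(λ)·C_oxy + ε_deoxy(λ)·C_deoxy)·1e-6`` by least
    squares subject to nonnegative concentrations. The unconstrained solution
    is used where it is already nonnegative; voxels violating nonnegativity
    are re-solved with NNLS.
    """
    missing = set(table.wavelengths) - set(amap.mu_a)
    if missing:
        raise ValueError(f"absorption map lacks wavelengths {sorted(missing)}")
    A = table.design_matrix()
    shape = amap.shape
    B = np.stack([amap.mu_a[lam].ravel() for lam in table.wavelengths])  # 4 × nvox
    C, *_ = np.linalg.lstsq(A, B, rcond=None)  # 2 × nvox
    bad = np.where((C < -1e-12).any(axis=0))[0]
    for j in bad:
        C[:, j], _ = nnls(A, B[:, j])
    C = np.clip(C, 0.0, None)
    return HbMap(
        oxy=C[0].reshape(shape), deoxy=C[1].reshape(shape), roi=list(amap.roi)
    )


def max_over_roi(hbmap: HbMap, roi: Sequence[int] | None = None):
    """Componentwise maxima of tHb / oxyHb / deoxyHb over the ROI voxels.

    The three maxima may occur at different voxels, so the tHb maximum need
    not equal the sum of the oxyHb and deoxyHb maxima.
    """
    idx = np.asarray(roi if roi is not None else hbmap.roi, dtype=int)
    if idx.size == 0:
        raise ValueError("empty ROI")
    t = hbmap.tHb.ravel()[idx]
    o = hbmap.oxy.ravel()[idx]
    d = hbmap.deoxy.ravel()[idx]
    return float(t.max()), float(o.max()), float(d.max())


def average_replicate_max(
    replicates: Sequence[float], motion_flags: Sequence[bool] | None = None
) -> float:
    """Average the replicate maxima, excluding motion-corrupted acquisitions.

    Each patient visit yields 5-10 quality images; acquisitions with patient
    motion (detected from coregistered ultrasound) are flagged and excluded.
    """
    reps = np.asarray(replicates, dtype=float)
    if motion_flags is None:
        flags = np.zeros(reps.shape, dtype=bool)
    else:
        flags = np.asarray(motion_flags, dtype=bool)
        if flags.shape != reps.shape:
            raise ValueError("motion_flags length must match replicates")
    kept = reps[~flags]
    if kept.size == 0:
        raise ValueError("no quality replicates: all acquisitions motion-flagged")
    return float(kept.mean())


def percent_tHb(baseline: float, value_at_cycle: float, ndigits: int | None = None) -> float:
    """Total hemoglobin at a visit as a percentage of the pretreatment value.

    %tHb quantifies the remaining tumor vascular fraction during treatment.
    Full precision is returned by default; pass ``ndigits=0`` for the integer
    display convention (e.g. "42%").
    """
    if baseline <= 0:
        raise ValueError("baseline tHb must be positive")
    pct = 100.0 * (value_at_cycle / baseline)  # exact 100 when value == baseline
    return round(pct, ndigits) if ndigits is not None else pct


def percent_us(baseline_dim: float, post_dim: float) -> float:
    """Largest post-treatment tumor dimension as a percentage of baseline."""
    if baseline_dim <= 0:
        raise ValueError("baseline dimension must be positive")
    return 100.0 * post_dim / baseline_dim


def write_absorption_map(amap: AbsorptionMap, directory) -> None:
    """Write one plain-text array per wavelength plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for lam, grid in amap.mu_a.items():
        np.savetxt(directory / f"mu_a_{lam}nm.txt", grid.reshape(grid.shape[0], -1))
    sidecar = {
        "shape": list(amap.shape),
        "voxel_size_cm": amap.voxel_size_cm,
        "roi": [int(i) for i in amap.roi],
        "wavelengths_nm": sorted(amap.mu_a),
    }
    (directory / "map.json").write_text(json.dumps(sidecar, indent=1))


def read_absorption_map(directory) -> AbsorptionMap:
    """Read an absorption map written by :func:`write_absorption_map`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "map.json").read_text())
    shape = tuple(sidecar["shape"])
    mu_a = {
        lam: np.loadtxt(directory / f"mu_a_{lam}nm.txt").reshape(shape)
        for lam in sidecar["wavelengths_nm"]
    }
    return AbsorptionMap(
        mu_a=mu_a, roi=sidecar["roi"], voxel_size_cm=sidecar["voxel_size_cm"]
    )
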