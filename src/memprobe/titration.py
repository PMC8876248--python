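"""Synthetic fluorescence titrations with known ground truth.

Emulates a partition titration: a dye at fixed total concentration is
titrated with lipid vesicles and its fluorescence follows the partition
binding curve; noise is multiplicative Gaussian because fluorescence
error scales with the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .partition import PartitionModel

__all__ = ["TitrationSeries", "generate_titration", "default_lipid_concs"]


@dataclass
class TitrationSeries:
    """Lipid concentrations (mol/dm^3) and fluorescence intensities."""

    lipid_concs: np.ndarray
    intensities: np.ndarray
    replicate_id: str = ""

    def __post_init__(self):
        self.lipid_concs = np.asarray(self.lipid_concs, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.lipid_concs.shape != self.intensities.shape:
            raise ValueError("lipid_concs and intensities must have equal length")
        if np.any(self.lipid_concs < 0):
            raise ValueError("lipid concentrations must be >= 0")


def default_lipid_concs(c_min: float = 1e-5, c_max: float = 1e-2,
                        n: int = 12, include_zero: bool = True) -> np.ndarray:
    """n log-spaced lipid concentrations, optionally prepended with 0."""
    concs = np.logspace(np.log10(c_min), np.log10(c_max), n)
    return np.concatenate([[0.0], concs]) if include_zero else concs


def generate_titration(
    model: PartitionModel,
    lipid_concs,
    noise_cv: float = 0.02,
    seed: int = 0,
    replicate_id: str = "",
) -> TitrationSeries:
    """Noisy titration from a known partition model.

    intensities = model(conc) * (1 + noise_cv * xi), xi ~ N(0,1), seeded.
    """
    c = np.asarray(lipid_concs, dtype=float)
    if np.any(c < 0):
        raise ValueError("lipid concentrations must be >= 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    clean = model.intensity(c)
    noisy = clean * (1.0 + noise_cv * rng.standard_normal(c.size))
    return TitrationSeries(c, noisy, replicate_id=replicate_id)
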