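"""Protein copy-number quantification and binding-interval arithmetic.

A densitometry standard curve (known recombinant-protein amounts vs band
intensities) calibrates sample band intensities to nanograms; standardising
to colony-forming units yields molecules per cell.  Dividing the chromosome
length by the number of binding units gives the expected genome-wide
binding interval — e.g. 30,000 dimers on a ~7 Mbp chromosome corresponds to
one binding unit every ~230 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import constants, stats

from .errors import InsufficientDataError, ValidationError
from .genome_io import GenomeContext

logger = logging.getLogger(__name__)


@dataclass
class StandardCurve:
    amounts_ng: np.ndarray
    intensities: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    def amount_from_intensity(self, intensity: float) -> float:
        """Invert the calibration line; returns nanograms."""
        if self.slope == 0:
            raise ValidationError("degenerate standard curve (zero slope)")
        return (intensity - self.intercept) / self.slope


def fit_standard_curve(amounts_ng, intensities) -> StandardCurve:
    """Least-squares line intensity = slope * amount + intercept.

    Requires >= 3 calibration points with strictly positive amounts; a
    non-positive slope is allowed but warned about, since band intensity
    should grow with loaded protein.
    """
    a = np.asarray(amounts_ng, dtype=float)
    i = np.asarray(intensities, dtype=float)
    if a.size != i.size:
        raise ValidationError("amounts and intensities must have equal length")
    if a.size < 3:
        raise InsufficientDataError(f"need >= 3 calibration points, got {a.size}")
    if np.any(a <= 0):
        raise ValidationError("calibration amounts must be strictly positive")
    if np.all(i == i[0]):
        logger.warning("constant band intensities: slope 0, calibration degenerate")
        return StandardCurve(a, i, 0.0, float(i[0]), 0.0)
    fit = stats.linregress(a, i)
    if fit.slope <= 0:
        logger.warning("standard curve slope %.3g <= 0; check calibration", fit.slope)
    return StandardCurve(a, i, float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2))


def molecules_per_cell(
    sample_intensity: float,
    curve: StandardCurve,
    lane_cfu: float,
    monomer_mass_da: float = 48_000.0,
) -> float:
    """Convert a sample band intensity to molecules per cell.

    ng in lane = (intensity - intercept) / slope; molecules = ng * 1e-9 g /
    (monomer mass in g/mol) * N_A; per-cell = molecules / CFU in the lane.
    Default monomer mass 48 kDa (an EGFP fusion of a small DNA-binding
    protein); override for other constructs (e.g. 47 kDa for an mCherry
    fusion).
    """
    if lane_cfu <= 0:
        raise ValidationError(f"lane_cfu must be positive, got {lane_cfu}")
    if monomer_mass_da <= 0:
        raise ValidationError("monomer mass must be positive")
    ng = curve.amount_from_intensity(sample_intensity)
    if ng <= 0:
        raise ValidationError(
            f"intensity {sample_intensity} maps to non-positive mass ({ng:.3g} ng)"
        )
    molecules = ng * 1e-9 / monomer_mass_da * constants.Avogadro
    return molecules / lane_cfu


def expected_binding_interval(
    copies_per_cell: float,
    ctx: GenomeContext,
    monomers_per_binding_unit: int = 1,
) -> float:
    """Expected spacing (bp) if every binding unit occupied the chromosome.

    ``copies_per_cell / monomers_per_binding_unit`` binding units tile a
    chromosome of length L at L / n_units bp each.  The default of 1 means
    the input is already expressed in binding units (e.g. dimers); pass 2 to
    convert monomer counts to dimers explicitly — no hidden stoichiometry
    factor is ever applied.
    """
    if copies_per_cell <= 0:
        raise ValidationError("copies_per_cell must be positive")
    if monomers_per_binding_unit < 1:
        raise ValidationError("monomers_per_binding_unit must be >= 1")
    n_units = copies_per_cell / monomers_per_binding_unit
    return ctx.length_bp / n_units
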