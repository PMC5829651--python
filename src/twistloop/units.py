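"""Reduced-unit system and genome <-> bead coordinate mapping.

All geometry is expressed in units of the bead diameter sigma (1 sigma = 10 nm
for a 10-nm chromatin fibre, spanning roughly 400 bp of genomic sequence).
Energies are in units of kT and time in units of tau = gamma * sigma^2 / kT,
the diffusion time of a generic fibre bead.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class UnitSystem:
    """Conversion constants between reduced simulation units and physical ones.

    Parameters
    ----------
    sigma_nm
        Physical length of one sigma, in nanometres.
    bp_per_bead
        Genomic span represented by one fibre bead, in base pairs.
    kT
        Thermal energy unit; 1 by construction in reduced units.
    """

    sigma_nm: float = 10.0
    bp_per_bead: int = 400
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise ValueError(f"sigma_nm must be > 0, got {self.sigma_nm}")
        if self.bp_per_bead <= 0:
            raise ValueError(f"bp_per_bead must be > 0, got {self.bp_per_bead}")

    def to_nm(self, value_sigma: float) -> float:
        """Convert a length in sigma to nanometres."""
        return value_sigma * self.sigma_nm

    def to_sigma(self, value_nm: float) -> float:
        """Convert a length in nanometres to sigma."""
        return value_nm / self.sigma_nm

    # -- genome <-> bead mapping (0-based, half-open genomic intervals) -----

    def bead_of(self, bp: int) -> int:
        """Bead index containing genomic coordinate ``bp``."""
        if bp < 0:
            raise ValueError("genomic coordinates are 0-based and non-negative")
        return bp // self.bp_per_bead

    def bp_of(self, bead: int) -> int:
        """Start (inclusive) of the genomic interval covered by ``bead``."""
        if bead < 0:
            raise ValueError("bead indices are 0-based and non-negative")
        return bead * self.bp_per_bead

    def n_beads_for(self, length_bp: int) -> int:
        """Number of beads representing a fibre of ``length_bp`` base pairs."""
        if length_bp <= 0:
            raise ValueError("length_bp must be positive")
        return length_bp // self.bp_per_bead
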