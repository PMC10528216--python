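"""Dual-wavelength UV quantitation of capsid and DNA content.

The integrated 280/260 nm peak absorbances of the monomeric virus peak are
a linear mixture of two absorbers: the protein capsid shell (molar
extinction, M^-1 cm^-1) and the encapsidated single-stranded DNA (mass
extinction, mL mg^-1 cm^-1)::

    A280 = eps_cap280 * c_cap + eps_dna280 * w_dna
    A260 = eps_cap260 * c_cap + eps_dna260 * w_dna

Solving this 2x2 system gives the capsid molar concentration ``c_cap``
(mol/L) and the DNA mass concentration ``w_dna`` (mg/mL) in the loaded
sample.  From these follow the capsid number concentration (Cp/mL), the
mean encapsidated DNA mass per capsid ``w_dna / c_cap`` (Da) and, through
the standard ssDNA mass formula ``M = n_nt * 303.7 + 79.0`` Da, the genome
size in kilo-nucleotides.

Extinction coefficients are configuration, not constants: DNA extinction
is sequence-independent and capsid-protein extinction varies only mildly
across serotypes, so one coefficient set serves many vectors, but the set
in use must always be echoed in reports.  The packaged defaults are
literature values for AAV capsids and single-stranded DNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chromatogram import IntegratedPeak
from .errors import ConditioningError, DomainError, InconsistencyError

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23  # mol^-1
NT_MASS_DA = 303.7  # average ssDNA nucleotide residue mass, Da
SSDNA_END_MASS_DA = 79.0  # end-group correction of the ssDNA mass formula, Da


@dataclass(frozen=True)
class ExtinctionSet:
    """Extinction coefficients of the two absorbers at both wavelengths.

    ``eps_cap*`` are per-capsid molar coefficients (M^-1 cm^-1);
    ``eps_dna*`` are DNA mass coefficients (mL mg^-1 cm^-1).
    """

    eps_cap280: float
    eps_cap260: float
    eps_dna280: float
    eps_dna260: float
    max_condition: float = 1e6

    def __post_init__(self) -> None:
        for name in ("eps_cap280", "eps_cap260", "eps_dna280", "eps_dna260"):
            if getattr(self, name) <= 0:
                raise DomainError(f"extinction coefficient {name} must be positive")
        if self.condition_number() > self.max_condition:
            raise ConditioningError(
                f"extinction matrix condition number {self.condition_number():.3g} "
                f"exceeds cap {self.max_condition:.3g}"
            )

    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.eps_cap280, self.eps_dna280], [self.eps_cap260, self.eps_dna260]]
        )

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix()))

    def as_dict(self) -> dict[str, float]:
        return {
            "eps_cap280_per_M_per_cm": self.eps_cap280,
            "eps_cap260_per_M_per_cm": self.eps_cap260,
            "eps_dna280_mL_per_mg_per_cm": self.eps_dna280,
            "eps_dna260_mL_per_mg_per_cm": self.eps_dna260,
        }


#: Literature defaults: intact AAV capsid molar extinction (280 nm about
#: 6.61e6 M^-1 cm^-1, 260/280 ratio about 0.56 for the protein shell) and
#: single-stranded DNA mass extinction (A260 of 1 at about 37 ug/mL, i.e.
#: 27 mL mg^-1 cm^-1, with a 280/260 ratio near 0.53).
DEFAULT_EXTINCTION = ExtinctionSet(
    eps_cap280=6.61e6,
    eps_cap260=3.72e6,
    eps_dna280=14.3,
    eps_dna260=27.0,
)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Flow-cell path length (cm) and injected sample volume (mL).

    These map integrated peak area (mAU·mL) to absorbance referenced to the
    loaded sample, so that the linear system yields concentrations in the
    injected sample rather than in the flow cell.
    """

    path_length_cm: float = 1.0
    injection_volume_ml: float = 0.01

    def __post_init__(self) -> None:
        if self.path_length_cm <= 0 or self.injection_volume_ml <= 0:
            raise DomainError("path length and injection volume must be positive")


@dataclass(frozen=True)
class UVQuantResult:
    """Concentrations and genome metrics derived from one integrated peak."""

    c_cap: float  # mol/L in the loaded sample
    w_dna: float  # mg/mL in the loaded sample
    cp_per_ml: float  # capsid number concentration, Cp/mL
    genome_mass_da: float  # mean encapsidated DNA mass per capsid, Da
    genome_size_knt: float  # kilo-nucleotides
    flags: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------


def effective_absorbance(
    peak: IntegratedPeak, geom: AcquisitionGeometry
) -> tuple[float, float]:
    """Normalize integrated areas (mAU·mL) to sample-referenced AU.

    ``A_ch = S_ch / (1000 * path_length * injection_volume)``: dividing by
    the injected volume spreads the integrated signal back over the loaded
    sample; 1000 converts mAU to AU.
    """
    denom = 1000.0 * geom.path_length_cm * geom.injection_volume_ml
    a280 = peak.A280_int / denom
    a260 = peak.A260_int / denom
    if a280 < 0 or a260 < 0:
        logger.warning("negative effective absorbance (A280=%.3g, A260=%.3g)", a280, a260)
    return a280, a260


def solve_capsid_dna(
    a280: float,
    a260: float,
    ext: ExtinctionSet,
    clamp_rel_tol: float = 0.02,
) -> tuple[float, float, tuple[str, ...]]:
    """Invert the two-channel linear system for ``(c_cap, w_dna)``.

    Small negative solutions are measurement noise: a component that is
    negative but within ``clamp_rel_tol`` of the magnitude it would take at
    a 260/280 ratio of 0.6 (a pure-protein-like reference spectrum at the
    same A280) is clamped to zero and flagged.  Larger negative values mean
    the two channels are mutually inconsistent and raise.

    Returns ``(c_cap mol/L, w_dna mg/mL, flags)``.
    """
    m = ext.matrix()
    c_cap, w_dna = np.linalg.solve(m, np.array([a280, a260]))

    # reference magnitudes at a 260/280 ratio of 0.6 with the same A280
    ref = np.abs(np.linalg.solve(m, np.array([a280, 0.6 * a280])))
    tol_c, tol_w = clamp_rel_tol * ref

    flags: list[str] = []
    if c_cap < 0:
        if c_cap >= -tol_c:
            flags.append("c_cap_clamped_to_zero")
            c_cap = 0.0
        else:
            raise InconsistencyError(
                f"A280={a280:.4g}, A260={a260:.4g} imply c_cap={c_cap:.4g} mol/L "
                f"< -{tol_c:.4g}; channels are inconsistent with the extinction set"
            )
    if w_dna < 0:
        if w_dna >= -tol_w:
            flags.append("w_dna_clamped_to_zero")
            w_dna = 0.0
        else:
            raise InconsistencyError(
                f"A280={a280:.4g}, A260={a260:.4g} imply w_dna={w_dna:.4g} mg/mL "
                f"< -{tol_w:.4g}; channels are inconsistent with the extinction set"
            )
    return float(c_cap), float(w_dna), tuple(flags)


def ssdna_mass(n_nt: float) -> float:
    """Molecular mass (Da) of a single-stranded DNA of ``n_nt`` nucleotides."""
    if n_nt < 0:
        raise DomainError("nucleotide count must be non-negative")
    return n_nt * NT_MASS_DA + SSDNA_END_MASS_DA


def genome_size_from_mass(genome_mass_da: float) -> float:
    """Invert the ssDNA mass formula to a genome size in kilo-nucleotides.

    Masses below the end-group correction (79 Da) map to 0 knt — the
    empty-capsid case after clamping.
    """
    if genome_mass_da < 0:
        raise DomainError("genome mass must be non-negative")
    return max(0.0, genome_mass_da - SSDNA_END_MASS_DA) / NT_MASS_DA / 1000.0


def round_sig(x: float, n_sig: int) -> float:
    """Round-half-even to ``n_sig`` significant figures (display only;
    internal values keep full precision)."""
    if x == 0:
        return 0.0
    from decimal import ROUND_HALF_EVEN, Decimal

    d = Decimal(repr(x))
    shift = n_sig - 1 - d.adjusted()
    return float(d.quantize(Decimal(1).scaleb(-shift), rounding=ROUND_HALF_EVEN))


def capsid_number_concentration(c_cap: float) -> float:
    """Capsid number concentration (Cp/mL) from molar concentration (mol/L)."""
    if c_cap < 0:
        raise DomainError("capsid molar concentration must be non-negative")
    return c_cap * AVOGADRO / 1000.0


def quantify_peak(
    peak: IntegratedPeak,
    ext: ExtinctionSet,
    geom: AcquisitionGeometry,
    clamp_rel_tol: float = 0.02,
) -> UVQuantResult:
    """Full UV branch: integrated peak -> concentrations and genome size."""
    a280, a260 = effective_absorbance(peak, geom)
    c_cap, w_dna, flags = solve_capsid_dna(a280, a260, ext, clamp_rel_tol=clamp_rel_tol)
    flags = list(flags)
    if c_cap > 0:
        # w_dna/c_cap: mg/mL is numerically g/L, so (g/L)/(mol/L) = g/mol = Da
        genome_mass = w_dna / c_cap
    else:
        genome_mass = 0.0
        flags.append("no_capsid_signal")
    genome_knt = genome_size_from_mass(genome_mass)
    if 0 < genome_mass < SSDNA_END_MASS_DA:
        flags.append("genome_mass_below_end_group")
    return UVQuantResult(
        c_cap=c_cap,
        w_dna=w_dna,
        cp_per_ml=capsid_number_concentration(c_cap),
        genome_mass_da=genome_mass,
        genome_size_knt=genome_knt,
        flags=tuple(flags),
    )
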