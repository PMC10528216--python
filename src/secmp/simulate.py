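"""Forward simulator: SEC-UV chromatograms and MP event lists from a
ground-truth species mixture.

Every analysis stage in this package is validated closed-loop against this
simulator.  A :class:`SpeciesMix` lists the species loaded on the column —
monomeric capsids (empty, partial or full), capsid aggregates, free DNA and
free protein contaminants — each with a particle mass, a per-particle DNA
mass, a number concentration in the loaded sample, and a chromatographic
elution position.  The chromatogram model is a sum of Gaussian elution
peaks whose integrated channel areas follow exactly the two-absorber
linear model the analysis inverts::

    area_ch (mAU*mL) = 1000 * l * V_inj * (eps_cap_ch * c + eps_dna_ch * w)

with the capsid term dropped for free-DNA species and the DNA term dropped
for free-protein species.  The MP model draws events among capsid-bearing
species with probability proportional to number concentration (the
instrument dilutes every sample to a common working concentration, so only
proportions matter) and adds Gaussian per-event mass error.

Typical sample morphology: capsid aggregates elute early (about 7 mL on
the reference column), monomeric virions at 8-9 mL, and small-molecule
contaminants after 10 mL.  Aggregate particle masses fall above the 6 MDa
counting ceiling, so badly placed UV integration windows pick them up
while MP counting does not — reproducing the method's dominant real-world
failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .chromatogram import Chromatogram
from .errors import DomainError
from .mp_analysis import MPRun
from .uv_quant import AVOGADRO, AcquisitionGeometry, ExtinctionSet

SpeciesKind = Literal["capsid", "dna", "protein"]


@dataclass(frozen=True)
class Species:
    """One component of the loaded sample.

    ``number_conc`` is particles (or molecules) per mL of the loaded
    sample.  For ``kind="dna"`` the capsid absorbance terms vanish; for
    ``kind="protein"`` the DNA terms vanish and ``molar_ext_scale`` scales
    the capsid-family molar extinction down to the contaminant's size.
    """

    label: str
    kind: SpeciesKind
    mass_kda: float  # particle mass as seen by MP
    genome_mass_da: float  # DNA mass carried per particle (0 for empty)
    number_conc: float  # particles/mL in the loaded sample
    elution_ml: float  # apex elution volume
    sigma_v_ml: float = 0.10  # chromatographic peak width
    full: bool = False  # carries the complete genome
    monomer: bool = True  # counts toward the monomeric-virion totals
    molar_ext_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_kda <= 0 or self.sigma_v_ml <= 0:
            raise DomainError(f"species {self.label}: mass and sigma_v must be positive")
        if self.number_conc < 0 or self.genome_mass_da < 0:
            raise DomainError(f"species {self.label}: concentrations and masses are non-negative")


@dataclass(frozen=True)
class SpeciesMix:
    species: tuple[Species, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))

    def capsids(self, monomer_only: bool = False) -> list[Species]:
        return [
            s
            for s in self.species
            if s.kind == "capsid" and (s.monomer or not monomer_only)
        ]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise for both instruments.

    ``mp_mass_sd_kda`` defaults to 120 kDa, which reproduces the 110-135
    kDa fitted peak widths seen for homogeneous capsid populations.
    """

    chrom_noise_sd_mau: float = 0.1
    drift_slope_mau_per_ml: float = 0.05
    mp_mass_sd_kda: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_noise_sd_mau < 0 or self.mp_mass_sd_kda < 0:
            raise DomainError("noise SDs must be non-negative")


ZERO_NOISE = NoiseModel(chrom_noise_sd_mau=0.0, drift_slope_mau_per_ml=0.0, mp_mass_sd_kda=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Exact answer key for a mix, using the analysis modules' definitions."""

    total_cp_per_ml: float
    percent_full: float
    genome_occupancy: float
    effective_titer: float
    w_dna_mg_per_ml: float
    c_cap_mol_per_l: float


# ---------------------------------------------------------------------------
# concentration bookkeeping


def _molar_conc(number_per_ml: float) -> float:
    """particles/mL -> mol/L."""
    return number_per_ml * 1000.0 / AVOGADRO


def _dna_mass_conc(number_per_ml: float, genome_mass_da: float) -> float:
    """particles/mL carrying ``genome_mass_da`` each -> mg/mL (= g/L)."""
    return _molar_conc(number_per_ml) * genome_mass_da


def ground_truth(mix: SpeciesMix, m_genome_da: float | None = None) -> GroundTruth:
    """Exact totals over the monomeric capsid species.

    ``m_genome_da`` is the full-genome reference mass for the occupancy
    ratio; by default the largest per-particle DNA mass in the mix.
    """
    monomers = mix.capsids(monomer_only=True)
    if not monomers:
        raise DomainError("mix contains no monomeric capsid species")
    total = sum(s.number_conc for s in monomers)
    if total <= 0:
        raise DomainError("monomeric capsid concentration is zero")
    full = sum(s.number_conc for s in monomers if s.full)
    dna = sum(_dna_mass_conc(s.number_conc, s.genome_mass_da) for s in monomers)
    c_cap = _molar_conc(total)
    if m_genome_da is None:
        m_genome_da = max((s.genome_mass_da for s in monomers), default=0.0)
    occupancy = dna / (c_cap * m_genome_da) if m_genome_da > 0 else 0.0
    pct = full / total
    return GroundTruth(
        total_cp_per_ml=total,
        percent_full=pct,
        genome_occupancy=occupancy,
        effective_titer=total * pct,
        w_dna_mg_per_ml=dna,
        c_cap_mol_per_l=c_cap,
    )


# ---------------------------------------------------------------------------
# forward models


def simulate_chromatogram(
    mix: SpeciesMix,
    ext: ExtinctionSet,
    geom: AcquisitionGeometry,
    noise: NoiseModel = ZERO_NOISE,
    grid: np.ndarray | None = None,
) -> Chromatogram:
    """Sum-of-Gaussians elution model with the exact two-absorber areas.

    The grid must cover every species apex +/- 5 chromatographic sigma so
    no peak is truncated.
    """
    if grid is None:
        grid = np.arange(4.0, 13.0, 0.002)
    grid = np.asarray(grid, dtype=float)
    for s in mix.species:
        if s.number_conc == 0:
            continue
        if s.elution_ml - 5 * s.sigma_v_ml < grid[0] or s.elution_ml + 5 * s.sigma_v_ml > grid[-1]:
            raise DomainError(
                f"grid [{grid[0]}, {grid[-1]}] mL does not cover species "
                f"{s.label!r} apex {s.elution_ml} mL +/- 5 sigma"
            )

    scale = 1000.0 * geom.path_length_cm * geom.injection_volume_ml
    a280 = np.zeros_like(grid)
    a260 = np.zeros_like(grid)
    for s in mix.species:
        if s.number_conc == 0:
            continue
        c = _molar_conc(s.number_conc) * s.molar_ext_scale
        w = _dna_mass_conc(s.number_conc, s.genome_mass_da)
        if s.kind == "capsid":
            area280 = scale * (ext.eps_cap280 * c + ext.eps_dna280 * w)
            area260 = scale * (ext.eps_cap260 * c + ext.eps_dna260 * w)
        elif s.kind == "dna":
            area280 = scale * ext.eps_dna280 * w
            area260 = scale * ext.eps_dna260 * w
        else:  # free protein
            area280 = scale * ext.eps_cap280 * c
            area260 = scale * ext.eps_cap260 * c
        shape = np.exp(-0.5 * ((grid - s.elution_ml) / s.sigma_v_ml) ** 2)
        shape /= s.sigma_v_ml * np.sqrt(2.0 * np.pi)
        a280 += area280 * shape
        a260 += area260 * shape

    rng = np.random.default_rng(noise.seed)
    drift = noise.drift_slope_mau_per_ml * (grid - grid[0])
    a280 = a280 + drift + rng.normal(0.0, noise.chrom_noise_sd_mau, len(grid))
    a260 = a260 + drift + rng.normal(0.0, noise.chrom_noise_sd_mau, len(grid))
    return Chromatogram(
        volume=grid, a280=a280, a260=a260, meta={"seed": noise.seed, "simulated": True}
    )


def simulate_mp_events(
    mix: SpeciesMix, n_events: int, noise: NoiseModel = ZERO_NOISE
) -> MPRun:
    """Draw per-particle masses among capsid-bearing species.

    Species are sampled with probability proportional to number
    concentration; each event mass is the species mass plus Gaussian
    measurement error.  Event count is an instrument setting, independent
    of absolute concentration.
    """
    if n_events < 1:
        raise DomainError("need at least one MP event")
    capsids = mix.capsids()
    weights = np.array([s.number_conc for s in capsids], dtype=float)
    if not capsids or weights.sum() <= 0:
        raise DomainError("mix contains no capsid-bearing species to detect")
    rng = np.random.default_rng(noise.seed + 1)  # decorrelate from chromatogram noise
    probs = weights / weights.sum()
    idx = rng.choice(len(capsids), size=n_events, p=probs)
    masses = np.array([capsids[i].mass_kda for i in idx])
    masses = masses + rng.normal(0.0, noise.mp_mass_sd_kda, n_events)
    return MPRun(masses=masses, meta={"seed": noise.seed, "simulated": True})


# ---------------------------------------------------------------------------
# reference mixes


#: empty AAV capsid shell mass, kDa (60-subunit shell of the reference
#: serotype as measured by MP for a homogeneous empty preparation)
EMPTY_CAPSID_KDA = 3760.0


def demo_mix_single_full(
    cp_per_ml: float = 1.14e13, genome_nt: int = 2763
) -> SpeciesMix:
    """A high-purity, fully packaged preparation with typical impurities."""
    from .uv_quant import ssdna_mass

    g = ssdna_mass(genome_nt)
    full_mass = EMPTY_CAPSID_KDA + g / 1000.0
    return SpeciesMix(
        species=(
            Species("full", "capsid", full_mass, g, cp_per_ml, 8.5, 0.15, full=True),
            Species(
                "aggregate",
                "capsid",
                2 * full_mass,
                2 * g,
                0.04 * cp_per_ml,
                7.0,
                0.12,
                monomer=False,
            ),
            Species("free_dna", "dna", 500.0, 8.0e5, 0.3 * cp_per_ml, 10.5, 0.2),
            Species(
                "protein_frag",
                "protein",
                60.0,
                0.0,
                2.0 * cp_per_ml,
                11.2,
                0.2,
                molar_ext_scale=0.01,
            ),
        )
    )


def demo_mix_heterogeneous(
    total_cp_per_ml: float = 1.0e13, genome_nt: int = 4787, percent_full: float = 0.10
) -> SpeciesMix:
    """A heterogeneous, partially packaged preparation.

    Five species: full and empty monomers, two partially packaged
    populations, and an aggregate; plus free-DNA and protein contaminants.
    """
    from .uv_quant import ssdna_mass

    g = ssdna_mass(genome_nt)
    full_mass = EMPTY_CAPSID_KDA + g / 1000.0
    p_empty = 0.30
    p_part1 = 0.35
    p_part2 = 1.0 - p_empty - p_part1 - percent_full
    if p_part2 < 0:
        raise DomainError("percent_full too large for the demo composition")
    mk = lambda frac, gm, label, full: Species(
        label,
        "capsid",
        EMPTY_CAPSID_KDA + gm / 1000.0,
        gm,
        frac * total_cp_per_ml,
        8.6,
        0.15,
        full=full,
    )
    return SpeciesMix(
        species=(
            mk(percent_full, g, "full", True),
            mk(p_empty, 0.0, "empty", False),
            mk(p_part1, 0.35 * g, "partial_low", False),
            mk(p_part2, 0.78 * g, "partial_high", False),
            Species(
                "aggregate",
                "capsid",
                2 * full_mass,
                2 * g,
                0.05 * total_cp_per_ml,
                7.0,
                0.12,
                monomer=False,
            ),
            Species("free_dna", "dna", 500.0, 8.0e5, 0.5 * total_cp_per_ml, 10.5, 0.2),
            Species(
                "protein_frag",
                "protein",
                60.0,
                0.0,
                2.0 * total_cp_per_ml,
                11.2,
                0.2,
                molar_ext_scale=0.01,
            ),
        )
    )


# ---------------------------------------------------------------------------
# text export (round-trips with the loaders)


def write_chromatogram(chrom: Chromatogram, path) -> None:
    """Write the delimited format :func:`~secmp.chromatogram.load_chromatogram` reads."""
    import pandas as pd

    df = pd.DataFrame(
        {"volume_mL": chrom.volume, "a280_mAU": chrom.a280, "a260_mAU": chrom.a260}
    )
    with open(path, "w") as fh:
        seed = chrom.meta.get("seed")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def write_mp_events(run: MPRun, path) -> None:
    """Write the delimited format :func:`~secmp.mp_analysis.load_mp_events` reads."""
    import pandas as pd

    df = pd.DataFrame({"mass_kDa": run.masses})
    with open(path, "w") as fh:
        seed = run.meta.get("seed")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.10g")
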