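"""Three-scenario decision logic and titer report assembly.

The mass-photometry assessment of the monomeric virion population selects
one of three analysis branches:

1. a single homogeneous peak — the UV branch alone yields the titer and
   genome size;
2. exactly two homogeneous peaks (empty + full) — %full comes from the
   DNA-mass balance ``w_dna / (c_cap * M_genome)``;
3. anything broader — %full comes from raw particle counting,
   ``n_full / n_total``.

In every branch the effective titer of fully packaged virions is the total
capsid number concentration times %full.  Values of %full above 100% are
reported and flagged, never clamped: they are a diagnostic of integration
or baseline error, not a quantity to hide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import uv_quant
from .errors import ConfigurationError, DomainError, InsufficientDataError
from .mp_analysis import (
    DEFAULT_SIGMA_MAX_KDA,
    GaussianPeakFit,
    MassWindow,
    WindowCounts,
    is_homogeneous,
)
from .uv_quant import UVQuantResult

#: attached to every counting-branch report next to the DNA-occupancy value
OCCUPANCY_CAVEAT = (
    "DNA occupancy assumes the measured DNA is spread uniformly over all "
    "capsids; for heterogeneous, partially packaged samples it has no "
    "meaningful interpretation and must not be read as a particle fraction."
)


@dataclass(frozen=True)
class GenomeSpec:
    """Expected genome: nucleotide count and/or mass (Da).

    Either field may be given; the mass is derivable from the count via the
    ssDNA mass formula, or from the spacing of the MP empty/full peaks.
    """

    n_nt: int | None = None
    m_genome_da: float | None = None

    def resolve_mass(self) -> float:
        if self.m_genome_da is not None:
            if self.m_genome_da <= 0:
                raise DomainError("genome mass must be positive")
            return self.m_genome_da
        if self.n_nt is not None:
            return uv_quant.ssdna_mass(self.n_nt)
        raise ConfigurationError("genome spec needs n_nt or m_genome_da")


@dataclass(frozen=True)
class ScenarioCall:
    """Which analysis branch applies, with the evidence that justified it."""

    scenario: int  # 1, 2 or 3
    n_accepted_peaks: int
    homogeneous: tuple[bool, ...]
    fits: tuple[GaussianPeakFit, ...] = ()

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise DomainError("scenario must be 1, 2 or 3")


@dataclass(frozen=True)
class TiterReport:
    """Final quantitation of one sample."""

    scenario: int
    c_cap: float  # mol/L
    cp_per_ml: float  # total capsids, Cp/mL
    percent_full: float | None  # fraction in [0, inf); None if not asserted
    genome_size_knt: float | None
    effective_titer: float | None  # fully packaged particles / mL
    replicate_mean: float | None = None
    replicate_sd: float | None = None
    dna_occupancy: float | None = None  # counting branch only; see notes
    counts: WindowCounts | None = None
    warnings: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()
    provenance: Mapping[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "scenario": self.scenario,
            "c_cap_mol_per_L": self.c_cap,
            "total_capsids_cp_per_ml": self.cp_per_ml,
            "percent_full": self.percent_full,
            "genome_size_knt": self.genome_size_knt,
            "effective_titer_per_ml": self.effective_titer,
            "replicate_mean": self.replicate_mean,
            "replicate_sd": self.replicate_sd,
            "dna_occupancy": self.dna_occupancy,
            "warnings": list(self.warnings),
            "notes": list(self.notes),
            "provenance": dict(self.provenance),
        }
        if self.counts is not None:
            d["counts"] = {
                "n_full": self.counts.n_full,
                "n_total": self.counts.n_total,
                "full_window_kda": [self.counts.full_window.lo, self.counts.full_window.hi],
                "total_window_kda": [self.counts.total_window.lo, self.counts.total_window.hi],
            }
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = [f"scenario            : {self.scenario}"]
        lines.append(f"total capsids       : {self.cp_per_ml:.3g} Cp/mL")
        if self.percent_full is not None:
            lines.append(f"percent full        : {100 * self.percent_full:.3g} %")
        if self.genome_size_knt is not None:
            lines.append(f"genome size         : {self.genome_size_knt:.3g} knt")
        if self.effective_titer is not None:
            lines.append(f"effective titer     : {self.effective_titer:.3g} /mL")
        if self.replicate_mean is not None:
            sd = f" +/- {100 * self.replicate_sd:.2g}" if self.replicate_sd is not None else ""
            lines.append(f"replicate %full     : {100 * self.replicate_mean:.3g}{sd} %")
        if self.dna_occupancy is not None:
            lines.append(f"DNA occupancy       : {100 * self.dna_occupancy:.3g} % (non-interpretable)")
        for w in self.warnings:
            lines.append(f"warning             : {w}")
        for n in self.notes:
            lines.append(f"note                : {n}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------


def classify_scenario(
    fits: Sequence[GaussianPeakFit],
    total: MassWindow | None = None,
    sigma_max: float = DEFAULT_SIGMA_MAX_KDA,
    n_events: int | None = None,
) -> ScenarioCall:
    """Map a list of fitted MP peaks to the analysis branch.

    Scenario 1: exactly one accepted peak and it is homogeneous.
    Scenario 2: exactly two accepted peaks, both homogeneous.
    Scenario 3: everything else (broad peaks, >2 modes, or no accepted
    mode despite events being present).
    """
    if n_events is not None and n_events == 0:
        raise InsufficientDataError("no MP events to classify")
    accepted = [f for f in fits if f.converged]
    homo = tuple(is_homogeneous(f, sigma_max) for f in accepted)
    if len(accepted) == 1 and homo[0]:
        scenario = 1
    elif len(accepted) == 2 and all(homo):
        scenario = 2
    else:
        scenario = 3
    return ScenarioCall(
        scenario=scenario,
        n_accepted_peaks=len(accepted),
        homogeneous=homo,
        fits=tuple(accepted),
    )


def analyze_scenario1(
    uv: UVQuantResult,
    expected: GenomeSpec | None = None,
    genome_tol_knt: float = 0.1,
    provenance: Mapping[str, object] | None = None,
) -> TiterReport:
    """Single homogeneous species: titer and genome size from UV alone.

    A genome size of zero means empty capsids and an effective titer of
    zero; a positive genome size means every capsid carries that genome, so
    the effective titer equals the total capsid titer.  If an expected
    genome is supplied, a mismatch beyond ``genome_tol_knt`` is flagged.
    """
    if uv.c_cap <= 0:
        raise DomainError("no capsid signal: c_cap = 0 in the UV solution")
    warnings = list(uv.flags)
    notes: list[str] = []
    if uv.genome_size_knt == 0:
        effective = 0.0
        notes.append("empty capsids: no encapsidated DNA detected")
    else:
        effective = uv.cp_per_ml
        if expected is not None:
            exp_knt = uv_quant.genome_size_from_mass(expected.resolve_mass())
            if abs(uv.genome_size_knt - exp_knt) > genome_tol_knt:
                warnings.append(
                    f"measured genome {uv.genome_size_knt:.3f} knt differs from "
                    f"expected {exp_knt:.3f} knt by more than {genome_tol_knt} knt"
                )
    return TiterReport(
        scenario=1,
        c_cap=uv.c_cap,
        cp_per_ml=uv.cp_per_ml,
        percent_full=None,
        genome_size_knt=uv.genome_size_knt,
        effective_titer=effective,
        warnings=tuple(warnings),
        notes=tuple(notes),
        provenance=dict(provenance or {}),
    )


def analyze_scenario2(
    uv: UVQuantResult,
    genome: GenomeSpec,
    provenance: Mapping[str, object] | None = None,
) -> TiterReport:
    """Empty + full two-species mixture: %full from the DNA-mass balance.

    ``%full = w_dna / (c_cap * M_genome)`` — the measured DNA mass per
    capsid over the genome mass.  Values above 1 are kept and flagged.
    """
    if uv.c_cap <= 0:
        raise DomainError("no capsid signal: c_cap = 0 in the UV solution")
    m_genome = genome.resolve_mass()
    pct = uv.genome_mass_da / m_genome
    warnings = list(uv.flags)
    if pct > 1.0:
        warnings.append(
            f"percent_full = {100 * pct:.3g}% exceeds 100%: likely integration or "
            "baseline error"
        )
    return TiterReport(
        scenario=2,
        c_cap=uv.c_cap,
        cp_per_ml=uv.cp_per_ml,
        percent_full=pct,
        genome_size_knt=uv.genome_size_knt,
        effective_titer=uv.cp_per_ml * pct,
        warnings=tuple(warnings),
        provenance=dict(provenance or {}),
    )


def analyze_scenario3(
    uv: UVQuantResult,
    mp_fraction: float,
    counts: WindowCounts,
    genome: GenomeSpec | None = None,
    replicate_fractions: Sequence[float] | None = None,
    provenance: Mapping[str, object] | None = None,
) -> TiterReport:
    """Heterogeneous sample: %full from raw MP particle counting.

    The DNA-mass %full (as in scenario 2) is additionally reported as
    "DNA occupancy", explicitly labelled non-interpretable for such
    samples.
    """
    if uv.c_cap <= 0:
        raise DomainError("no capsid signal: c_cap = 0 in the UV solution")
    if counts.n_total < 1:
        raise InsufficientDataError("zero total MP count")
    if not (0.0 <= mp_fraction <= 1.0):
        raise DomainError("counting fraction must lie in [0, 1]")
    occupancy = None
    notes = []
    if genome is not None:
        occupancy = uv.genome_mass_da / genome.resolve_mass()
        notes.append(OCCUPANCY_CAVEAT)
    rep_mean = rep_sd = None
    if replicate_fractions:
        from .mp_analysis import replicate_summary

        rep_mean, rep_sd = replicate_summary(list(replicate_fractions))
    return TiterReport(
        scenario=3,
        c_cap=uv.c_cap,
        cp_per_ml=uv.cp_per_ml,
        percent_full=mp_fraction,
        genome_size_knt=uv.genome_size_knt,
        effective_titer=uv.cp_per_ml * mp_fraction,
        replicate_mean=rep_mean,
        replicate_sd=rep_sd,
        dna_occupancy=occupancy,
        counts=counts,
        warnings=tuple(uv.flags),
        notes=tuple(notes),
        provenance=dict(provenance or {}),
    )


def mixture_expectation(
    components: Sequence[tuple[float, float, bool]],
) -> tuple[float, float]:
    """Expected totals for a volume mixture of characterized samples.

    ``components`` is a list of ``(cp_per_ml, volume_fraction, is_full)``.
    Returns ``(expected total Cp/mL, expected fraction full)``: the
    volume-weighted capsid concentration, and the full components' share
    of it.
    """
    if not components:
        raise DomainError("need at least one mixture component")
    fsum = sum(f for _, f, _ in components)
    if abs(fsum - 1.0) > 1e-9:
        raise DomainError(f"volume fractions sum to {fsum}, not 1")
    total = sum(cp * f for cp, f, _ in components)
    full = sum(cp * f for cp, f, is_full in components if is_full)
    if total <= 0:
        raise DomainError("mixture has no capsids")
    return total, full / total
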