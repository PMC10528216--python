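"""Mass-photometry single-particle analysis.

A mass-photometry (MP) run is a list of per-particle mass estimates (kDa),
one per landing event.  This module histograms those events, fits Gaussian
peaks to the mass distribution, classifies peak homogeneity (a homogeneous
capsid population shows a fitted sigma of at most 150 kDa), and counts
particles in mass windows to form the fraction of fully packaged virions::

    %full = n_full / n_total

where ``n_full`` counts events within a closed window centred on the
theoretical fully packaged virion mass (default half-width 150 kDa, e.g.
[5.10, 5.40] MDa for a 5.25 MDa virion) and ``n_total`` counts events in
the monomeric-virion range (default [3, 6] MDa).  Counting operates on raw
events, never on fitted peak areas: the histogram directly enumerates
particles, which is the more defensible estimate for broad, partially
packaged distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lmfit.models import GaussianModel

from .errors import DomainError, InsufficientDataError, ParseError

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_KDA = 25.0
DEFAULT_SIGMA_MAX_KDA = 150.0
DEFAULT_HALF_WIDTH_KDA = 150.0
DEFAULT_TOTAL_WINDOW = (3000.0, 6000.0)
MIN_EVENTS_FOR_FIT = 50
MASS_SANITY_KDA = (0.0, 20000.0)


@dataclass(frozen=True)
class MassWindow:
    """Closed particle-mass window ``[lo, hi]`` in kDa.

    Closed on both ends: an event exactly at the boundary is counted in.
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise DomainError(f"invalid mass window: lo={self.lo} >= hi={self.hi}")

    def contains(self, masses: np.ndarray) -> np.ndarray:
        return (masses >= self.lo) & (masses <= self.hi)

    def nested_in(self, other: "MassWindow") -> bool:
        return other.lo <= self.lo and self.hi <= other.hi


@dataclass(frozen=True)
class MPRun:
    """One MP acquisition: per-particle masses (kDa) plus annotations."""

    masses: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", m)
        if m.ndim != 1:
            raise DomainError("MP masses must form a 1-D list")
        if not np.all(np.isfinite(m)):
            raise DomainError("MP masses must be finite")

    def __len__(self) -> int:
        return len(self.masses)


@dataclass(frozen=True)
class GaussianPeakFit:
    """One fitted Gaussian component of the mass distribution."""

    mu: float  # kDa
    sigma: float  # kDa
    count: int  # events attributed to the peak (fitted area / bin width)
    fit_window: MassWindow
    redchi: float  # reduced chi-square of the histogram fit
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged:
            if self.sigma <= 0:
                raise DomainError("fitted sigma must be positive")
            if self.count < 0:
                raise DomainError("fitted count must be non-negative")


@dataclass(frozen=True)
class WindowCounts:
    """Raw event tallies behind a %full estimate."""

    n_full: int
    n_total: int
    full_window: MassWindow
    total_window: MassWindow

    def __post_init__(self) -> None:
        if not (0 <= self.n_full <= self.n_total):
            raise DomainError("need 0 <= n_full <= n_total")
        if not self.full_window.nested_in(self.total_window):
            raise DomainError("full window must be nested in the total window")


# ---------------------------------------------------------------------------
# loading


def load_mp_events(path, mass_column: str | None = None) -> MPRun:
    """Read a per-event mass list from delimited text.

    One mass per row; the unit is declared in the header column name
    (``*_kDa`` or ``*_MDa``; MDa values are converted to kDa on load).
    Masses outside a 0-20 MDa sanity range are kept (windowed counters do
    the filtering) but logged.
    """
    from .chromatogram import read_delimited

    try:
        df = read_delimited(path)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot parse MP event table: {exc}", path=str(path))
    if df.shape[0] == 0:
        raise ParseError("MP event file contains no events", path=str(path))

    if mass_column is None:
        candidates = [c for c in df.columns if "mass" in c.lower()]
        if not candidates:
            candidates = list(df.columns[:1])
        mass_column = candidates[0]
    if mass_column not in df.columns:
        raise ParseError(f"missing mass column {mass_column!r}", path=str(path))

    raw = df[mass_column]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.index[vals.isna()]
    if len(bad):
        raise ParseError(
            f"non-numeric mass {raw[bad[0]]!r}", path=str(path), line=int(bad[0]) + 2
        )
    masses = vals.to_numpy(dtype=float)
    if mass_column.lower().endswith("mda"):
        masses = masses * 1000.0

    n_out = int(np.sum((masses < MASS_SANITY_KDA[0]) | (masses > MASS_SANITY_KDA[1])))
    if n_out:
        logger.info("%d events outside the 0-20 MDa sanity range kept in %s", n_out, path)
    return MPRun(masses=masses, meta={"source": str(path), "mass_column": mass_column})


# ---------------------------------------------------------------------------
# histogramming and fitting


def histogram(
    run: MPRun, bin_width: float = DEFAULT_BIN_WIDTH_KDA, window: MassWindow | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Counts per half-open mass bin over ``window`` (closed overall range).

    Returns ``(edges, counts)`` with ``len(edges) == len(counts) + 1``.
    The sum of counts equals the number of events inside the window.
    """
    if bin_width <= 0:
        raise DomainError("bin width must be positive")
    if window is None:
        window = MassWindow(*DEFAULT_TOTAL_WINDOW)
    n_bins = max(1, math.ceil((window.hi - window.lo) / bin_width - 1e-9))
    edges = window.lo + bin_width * np.arange(n_bins + 1)
    in_range = run.masses[window.contains(run.masses)]
    counts, _ = np.histogram(in_range, bins=edges)
    return edges, counts


def _moving_average3(x: np.ndarray) -> np.ndarray:
    if len(x) < 3:
        return x.astype(float)
    kernel = np.ones(3) / 3.0
    return np.convolve(x, kernel, mode="same")


def detect_and_fit_peaks(
    run: MPRun,
    search: MassWindow | None = None,
    max_peaks: int = 4,
    bin_width: float = DEFAULT_BIN_WIDTH_KDA,
    min_events: int = MIN_EVENTS_FOR_FIT,
) -> list[GaussianPeakFit]:
    """Detect modes in the smoothed mass histogram and fit each with a
    Gaussian on the unsmoothed histogram.

    Mode detection runs on a 3-bin moving average; candidate modes must
    rise above their surroundings by more than counting noise (prominence
    of at least ``5 * sqrt(height)``), which rejects flat or noise-only
    distributions.  Each accepted mode is then fit by least squares within
    mode +/- 3 provisional sigma on the raw histogram.  Fits are returned
    sorted by mass; ties in prominence are broken toward lower mass.
    """
    from scipy.signal import find_peaks

    if search is None:
        search = MassWindow(*DEFAULT_TOTAL_WINDOW)
    n_in = int(np.sum(search.contains(run.masses)))
    if n_in < min_events:
        raise InsufficientDataError(
            f"only {n_in} events in [{search.lo}, {search.hi}] kDa; need >= {min_events}"
        )

    edges, counts = histogram(run, bin_width=bin_width, window=search)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = _moving_average3(counts)

    idx, props = find_peaks(smooth, prominence=3.0)
    if len(idx) == 0:
        return []
    # noise-aware prominence gate
    keep = props["prominences"] >= 5.0 * np.sqrt(np.maximum(smooth[idx], 1.0))
    idx, prom = idx[keep], props["prominences"][keep]
    if len(idx) == 0:
        return []
    # strongest first; ties toward lower mass, then keep at most max_peaks
    order = np.lexsort((centers[idx], -prom))
    idx = idx[order][:max_peaks]

    fits: list[GaussianPeakFit] = []
    for i in np.sort(idx):
        mode = centers[i]
        sigma0 = _provisional_sigma(centers, smooth, i, bin_width)
        lo = max(search.lo, mode - 3.0 * sigma0)
        hi = min(search.hi, mode + 3.0 * sigma0)
        sel = (centers >= lo) & (centers <= hi)
        if np.sum(sel) < 4:
            sel = slice(max(0, i - 3), i + 4)
        x, y = centers[sel], counts[sel].astype(float)
        model = GaussianModel()
        params = model.make_params(
            amplitude=max(float(np.sum(y) * bin_width), 1.0), center=mode, sigma=sigma0
        )
        params["sigma"].set(min=bin_width / 4.0)
        params["center"].set(min=lo, max=hi)
        try:
            res = model.fit(y, params, x=x)
            ok = res.success and res.params["sigma"].value > 0
        except Exception:
            ok = False
        if not ok:
            fits.append(
                GaussianPeakFit(
                    mu=float(mode),
                    sigma=float(sigma0),
                    count=0,
                    fit_window=MassWindow(lo, hi),
                    redchi=float("nan"),
                    converged=False,
                )
            )
            continue
        mu = float(res.params["center"].value)
        sigma = float(res.params["sigma"].value)
        count = max(0, int(round(res.params["amplitude"].value / bin_width)))
        fits.append(
            GaussianPeakFit(
                mu=mu,
                sigma=sigma,
                count=count,
                fit_window=MassWindow(lo, hi),
                redchi=float(res.redchi),
            )
        )
    fits.sort(key=lambda f: f.mu)
    return fits


def _provisional_sigma(
    centers: np.ndarray, smooth: np.ndarray, i: int, bin_width: float
) -> float:
    """Half-width-at-half-maximum estimate of sigma around mode ``i``."""
    half = smooth[i] / 2.0
    left = i
    while left > 0 and smooth[left] > half:
        left -= 1
    right = i
    while right < len(smooth) - 1 and smooth[right] > half:
        right += 1
    fwhm = max(centers[right] - centers[left], bin_width)
    return max(fwhm / 2.3548, bin_width)


def is_homogeneous(fit: GaussianPeakFit, sigma_max: float = DEFAULT_SIGMA_MAX_KDA) -> bool:
    """Whether a fitted peak is narrow enough to be a single species
    (sigma <= 150 kDa by default, boundary inclusive)."""
    if not fit.converged:
        return False
    return fit.sigma <= sigma_max


# ---------------------------------------------------------------------------
# counting


def count_in_window(run: MPRun, window: MassWindow) -> int:
    """Number of events with ``lo <= mass <= hi``."""
    return int(np.sum(window.contains(run.masses)))


def full_window(m_theory: float, half_width: float = DEFAULT_HALF_WIDTH_KDA) -> MassWindow:
    """The fully-packaged counting window ``m_theory +/- half_width`` (kDa)."""
    if half_width <= 0:
        raise DomainError("half width must be positive")
    return MassWindow(m_theory - half_width, m_theory + half_width)


def fraction_full(
    run: MPRun,
    m_theory: float,
    half_width: float = DEFAULT_HALF_WIDTH_KDA,
    total: MassWindow | None = None,
) -> tuple[float, WindowCounts]:
    """Fraction of fully packaged virions by raw event counting.

    ``m_theory`` is the theoretical mass (kDa) of the fully packaged virion
    (capsid shell plus genome); events within ``m_theory +/- half_width``
    count as full, events within ``total`` count toward the denominator.
    """
    if total is None:
        total = MassWindow(*DEFAULT_TOTAL_WINDOW)
    fw = full_window(m_theory, half_width)
    if not fw.nested_in(total):
        raise DomainError(
            f"full window [{fw.lo}, {fw.hi}] not nested in total window "
            f"[{total.lo}, {total.hi}]"
        )
    n_total = count_in_window(run, total)
    if n_total < 1:
        raise InsufficientDataError("no events inside the total counting window")
    n_full = count_in_window(run, fw)
    counts = WindowCounts(n_full=n_full, n_total=n_total, full_window=fw, total_window=total)
    return n_full / n_total, counts


def replicate_summary(fractions: Sequence[float]) -> tuple[float, float | None]:
    """Mean and sample (n-1) standard deviation over replicate fractions.

    A single replicate yields ``(value, None)``.
    """
    if len(fractions) == 0:
        raise DomainError("need at least one replicate")
    arr = np.asarray(fractions, dtype=float)
    if len(arr) == 1:
        return float(arr[0]), None
    return float(arr.mean()), float(arr.std(ddof=1))


def genome_mass_from_peaks(full_fit: GaussianPeakFit, empty_fit: GaussianPeakFit) -> float:
    """Genome mass (Da) as the mass difference between the full- and
    empty-capsid MP peaks."""
    diff_kda = full_fit.mu - empty_fit.mu
    if diff_kda <= 0:
        raise DomainError(
            f"full-capsid peak ({full_fit.mu} kDa) must lie above the empty peak "
            f"({empty_fit.mu} kDa)"
        )
    return diff_kda * 1000.0
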