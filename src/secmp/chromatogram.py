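"""Loading, baseline correction and peak integration of dual-wavelength
SEC-UV chromatograms.

A chromatogram is a pair of absorbance traces (280 nm and 260 nm, in mAU)
sampled on a strictly increasing elution-volume grid (mL).  The monomeric
virus peak is isolated by a user-chosen volume window; its baseline is a
straight line through two user-supplied anchor points per channel (or a
constant), mirroring how an analyst drops a ruler under the peak.  All
volume windows in this package are half-open ``[v_start, v_end)``;
numerically the trapezoid integral is insensitive to the right endpoint
convention, but the convention matters for bookkeeping and is stated once
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError, PeakNotFoundError

logger = logging.getLogger(__name__)

#: default warning threshold (mAU) for non-zero trace values at the window
#: edges of an integration — a symptom of a mis-set baseline
EDGE_WARN_MAU = 1.0


@dataclass(frozen=True)
class Chromatogram:
    """Dual-channel SEC-UV trace on a common elution-volume grid.

    Parameters
    ----------
    volume:
        Strictly increasing elution volumes, mL.
    a280, a260:
        Absorbance traces in mAU, same length as ``volume``.
    meta:
        Free-form acquisition annotations (column id, flow rate, seed, ...).
    """

    volume: np.ndarray
    a280: np.ndarray
    a260: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.volume, dtype=float)
        a280 = np.asarray(self.a280, dtype=float)
        a260 = np.asarray(self.a260, dtype=float)
        object.__setattr__(self, "volume", v)
        object.__setattr__(self, "a280", a280)
        object.__setattr__(self, "a260", a260)
        if v.ndim != 1 or len(v) < 2:
            raise DomainError("chromatogram needs a 1-D volume grid with >= 2 points")
        if len(a280) != len(v) or len(a260) != len(v):
            raise DomainError("absorbance traces must match the volume grid length")
        if not np.all(np.isfinite(v)) or not np.all(np.isfinite(a280)) or not np.all(np.isfinite(a260)):
            raise DomainError("chromatogram contains non-finite values")
        if not np.all(np.diff(v) > 0):
            raise DomainError("elution-volume grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.volume)

    def channel(self, name: str) -> np.ndarray:
        if name == "a280":
            return self.a280
        if name == "a260":
            return self.a260
        raise KeyError(name)


@dataclass(frozen=True)
class PeakWindow:
    """Half-open elution-volume window ``[v_start, v_end)`` in mL."""

    v_start: float
    v_end: float

    def __post_init__(self) -> None:
        if not (self.v_start < self.v_end):
            raise DomainError(f"invalid window: v_start={self.v_start} >= v_end={self.v_end}")

    @property
    def width(self) -> float:
        return self.v_end - self.v_start


Anchor = tuple[float, float]  # (volume mL, absorbance mAU)


@dataclass(frozen=True)
class BaselineSpec:
    """Per-channel baseline: either a constant (mAU) or a straight line
    through two ``(volume, absorbance)`` anchor points."""

    a280: float | tuple[Anchor, Anchor] = 0.0
    a260: float | tuple[Anchor, Anchor] = 0.0

    def _validate_channel(self, spec, vmin: float, vmax: float, name: str) -> None:
        if isinstance(spec, (int, float)):
            return
        (v1, _), (v2, _) = spec
        if not (v1 < v2):
            raise DomainError(f"{name} baseline: left anchor volume must be below right anchor")
        if v1 < vmin or v2 > vmax:
            raise DomainError(
                f"{name} baseline anchors ({v1}, {v2}) outside chromatogram range [{vmin}, {vmax}]"
            )

    def evaluate(self, channel: str, volume: np.ndarray) -> np.ndarray:
        """Baseline value at each grid point, mAU."""
        spec = getattr(self, channel)
        if isinstance(spec, (int, float)):
            return np.full_like(volume, float(spec))
        (v1, a1), (v2, a2) = spec
        slope = (a2 - a1) / (v2 - v1)
        return a1 + slope * (volume - v1)


@dataclass(frozen=True)
class IntegratedPeak:
    """Integrated absorbances over one peak window, mAU·mL per channel."""

    A280_int: float
    A260_int: float
    window: PeakWindow

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A280_int) and np.isfinite(self.A260_int)):
            raise DomainError("integrated absorbances must be finite")


# ---------------------------------------------------------------------------
# loading

DEFAULT_DIALECT = {"volume": "volume_mL", "a280": "a280_mAU", "a260": "a260_mAU"}


def read_delimited(path) -> pd.DataFrame:
    """Read a comma- or tab-separated table with a header row.

    The delimiter is taken from the header line (``sep=None`` sniffing
    misbehaves on single-column files), ``#`` lines are comments.
    """
    with open(path) as fh:
        header = ""
        while not header.strip() or header.lstrip().startswith("#"):
            header = fh.readline()
            if header == "":
                raise ParseError("file is empty", path=str(path))
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, comment="#")


def load_chromatogram(path, dialect: Mapping[str, str] | None = None) -> Chromatogram:
    """Read a delimited-text chromatogram export.

    ``dialect`` maps the logical channels ``volume``/``a280``/``a260`` to the
    column names in the file.  Comma and tab separators are auto-detected; a
    header row is required.  Channels other than the 280/260 pair are ignored
    with a logged notice.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    try:
        df = read_delimited(path)
    except FileNotFoundError:
        raise
    except ParseError:
        raise
    except Exception as exc:  # malformed delimiter/quoting
        raise ParseError(f"cannot parse chromatogram table: {exc}", path=str(path))

    for logical in ("volume", "a280", "a260"):
        col = dialect[logical]
        if col not in df.columns:
            raise ParseError(f"missing required channel column {col!r}", path=str(path))
    extra = [c for c in df.columns if c not in dialect.values()]
    if extra:
        logger.info("ignoring extra channels %s in %s", extra, path)

    cols = {}
    for logical in ("volume", "a280", "a260"):
        raw = df[dialect[logical]]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.index[vals.isna() & raw.notna()]
        if len(bad):
            # +2: header line plus 1-based indexing
            raise ParseError(
                f"non-numeric value {raw[bad[0]]!r} in column {dialect[logical]!r}",
                path=str(path),
                line=int(bad[0]) + 2,
            )
        if vals.isna().any():
            raise ParseError(f"empty cells in column {dialect[logical]!r}", path=str(path))
        cols[logical] = vals.to_numpy(dtype=float)

    return Chromatogram(
        volume=cols["volume"], a280=cols["a280"], a260=cols["a260"], meta={"source": str(path)}
    )


# ---------------------------------------------------------------------------
# baseline and integration


def subtract_baseline(chrom: Chromatogram, spec: BaselineSpec) -> Chromatogram:
    """Subtract the per-channel baseline pointwise; the grid is unchanged."""
    vmin, vmax = chrom.volume[0], chrom.volume[-1]
    spec._validate_channel(spec.a280, vmin, vmax, "a280")
    spec._validate_channel(spec.a260, vmin, vmax, "a260")
    return Chromatogram(
        volume=chrom.volume,
        a280=chrom.a280 - spec.evaluate("a280", chrom.volume),
        a260=chrom.a260 - spec.evaluate("a260", chrom.volume),
        meta=dict(chrom.meta),
    )


def _window_grid(chrom: Chromatogram, window: PeakWindow) -> np.ndarray:
    """Grid points inside the window, with interpolated endpoints."""
    v = chrom.volume
    lo = max(window.v_start, v[0])
    hi = min(window.v_end, v[-1])
    if lo >= hi:
        raise DomainError(
            f"window [{window.v_start}, {window.v_end}) does not overlap grid "
            f"[{v[0]}, {v[-1]}]"
        )
    interior = v[(v > lo) & (v < hi)]
    return np.concatenate(([lo], interior, [hi]))


def integrate_peak(
    chrom: Chromatogram, window: PeakWindow, edge_warn_mau: float = EDGE_WARN_MAU
) -> IntegratedPeak:
    """Trapezoidal integral of both channels over the window, mAU·mL.

    The caller is expected to have subtracted the baseline already; trace
    values above ``edge_warn_mau`` at the window edges are logged as a
    warning since they usually indicate a mis-set baseline or boundary.
    """
    grid = _window_grid(chrom, window)
    out = {}
    for name in ("a280", "a260"):
        trace = np.interp(grid, chrom.volume, chrom.channel(name))
        if max(abs(trace[0]), abs(trace[-1])) > edge_warn_mau:
            logger.warning(
                "channel %s is %.3g / %.3g mAU at the window edges; baseline may be mis-set",
                name,
                trace[0],
                trace[-1],
            )
        out[name] = float(np.trapezoid(trace, grid))
    return IntegratedPeak(A280_int=out["a280"], A260_int=out["a260"], window=window)


def suggest_boundaries(chrom: Chromatogram, search_window: PeakWindow) -> PeakWindow:
    """Advisory peak window: the valley-to-valley span around the tallest
    apex of the summed channels inside ``search_window``.

    Boundary placement in this workflow is ultimately an analyst decision;
    this helper only automates the common case of a well-separated peak.
    """
    grid = _window_grid(chrom, search_window)
    total = np.interp(grid, chrom.volume, chrom.a280 + chrom.a260)
    # interior strict local maxima
    interior = np.arange(1, len(total) - 1)
    is_max = (total[interior] > total[interior - 1]) & (total[interior] >= total[interior + 1])
    maxima = interior[is_max]
    if len(maxima) == 0:
        raise PeakNotFoundError("no local maximum inside the search window")
    apex = maxima[np.argmax(total[maxima])]

    left = apex
    while left > 0 and total[left - 1] <= total[left]:
        left -= 1
    right = apex
    while right < len(total) - 1 and total[right + 1] <= total[right]:
        right += 1
    if right <= left:
        raise PeakNotFoundError("degenerate apex in search window")
    return PeakWindow(float(grid[left]), float(grid[right]))
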