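"""GC-MS compound identification: spectral match values and retention indices.

Match values score the similarity of a resolved electron-ionization stick
spectrum against a library spectrum on the conventional 0–999 scale, with
999 an identical match.  The score is a weighted squared-cosine: intensities
are weighted as ``mz**m * I**n`` so that higher-m/z fragments — more
compound-specific in GC-EI spectra — carry more weight.  The default
exponents (m=3, n=0.6) follow the Stein–Scott optimization and are
configurable.

Retention indices are computed from an n-alkane ladder (C10 = 1000, C11 =
1100, …) by piecewise-linear interpolation of retention times (van den
Dool / Kratz, as appropriate for temperature-programmed GC).  Identification
accepts the best spectral match whose retention index lies within a ±window
(default ±10 index units) of the library value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MassSpectrum",
    "SpectralLibraryEntry",
    "AlkaneSeries",
    "MatchResult",
    "match_value",
    "retention_index",
    "identify",
    "read_msp",
    "write_msp",
    "read_alkane_ladder",
    "write_alkane_ladder",
]

DEFAULT_MASS_EXPONENT = 3.0
DEFAULT_INTENSITY_EXPONENT = 0.6


class SpectrumError(ValueError):
    """Raised for invalid spectra or ladders."""


@dataclass(frozen=True)
class MassSpectrum:
    """A centroided stick spectrum: (m/z, intensity) pairs.

    m/z values must be unique and positive; at least one peak must have
    positive intensity.
    """

    peaks: tuple

    def __init__(self, peaks) -> None:
        peaks = tuple((float(mz), float(i)) for mz, i in peaks)
        if not peaks:
            raise SpectrumError("spectrum has no peaks")
        mzs = [p[0] for p in peaks]
        if any(mz <= 0 for mz in mzs):
            raise SpectrumError("m/z values must be positive")
        if len(set(mzs)) != len(mzs):
            raise SpectrumError("duplicate m/z values in spectrum")
        if any(not math.isfinite(i) or i < 0 for _, i in peaks):
            raise SpectrumError("intensities must be finite and nonnegative")
        if all(i == 0 for _, i in peaks):
            raise SpectrumError("spectrum has all-zero intensities")
        object.__setattr__(self, "peaks", peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    def scaled(self, factor: float) -> "MassSpectrum":
        return MassSpectrum([(mz, i * factor) for mz, i in self.peaks])


@dataclass(frozen=True)
class SpectralLibraryEntry:
    """A reference spectrum with its library retention index."""

    name: str
    spectrum: MassSpectrum
    reference_ri: float

    def __post_init__(self) -> None:
        if self.reference_ri <= 0:
            raise SpectrumError(f"reference RI must be > 0 for {self.name!r}")


@dataclass(frozen=True)
class AlkaneSeries:
    """An n-alkane retention ladder: carbon numbers and retention times.

    Carbons are an ascending subset of 10..40; retention times are strictly
    increasing seconds.
    """

    carbons: tuple
    retention_times: tuple

    def __init__(self, carbons, retention_times) -> None:
        carbons = tuple(int(c) for c in carbons)
        rts = tuple(float(t) for t in retention_times)
        if len(carbons) != len(rts):
            raise SpectrumError("carbons and retention_times length mismatch")
        if len(carbons) < 2:
            raise SpectrumError("ladder needs at least two alkanes")
        if any(c < 10 or c > 40 for c in carbons):
            raise SpectrumError("carbon numbers must lie in 10..40")
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise SpectrumError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise SpectrumError("retention times must be strictly increasing")
        object.__setattr__(self, "carbons", carbons)
        object.__setattr__(self, "retention_times", rts)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of a library search for one query spectrum."""

    name: str
    match_value: float
    ri_deviation: float
    accepted: bool


def _weighted_vectors(
    query: MassSpectrum,
    reference: MassSpectrum,
    mass_exponent: float,
    intensity_exponent: float,
    mz_decimals: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Align the two spectra on a shared (rounded) m/z grid and weight them.

    GC-EI spectra are nominal-mass, so m/z values are rounded to the nearest
    integer by default before alignment; peaks absent from one spectrum
    contribute zero to its vector.
    """
    def collapse(spec: MassSpectrum) -> dict[float, float]:
        d: dict[float, float] = {}
        for mz, inten in spec.peaks:
            key = round(mz, mz_decimals) if mz_decimals else float(round(mz))
            d[key] = d.get(key, 0.0) + inten
        return d

    q, r = collapse(query), collapse(reference)
    grid = sorted(set(q) | set(r))
    u = np.array(
        [mz**mass_exponent * q.get(mz, 0.0) ** intensity_exponent for mz in grid]
    )
    v = np.array(
        [mz**mass_exponent * r.get(mz, 0.0) ** intensity_exponent for mz in grid]
    )
    return u, v


def match_value(
    query: MassSpectrum,
    reference: MassSpectrum,
    mass_exponent: float = DEFAULT_MASS_EXPONENT,
    intensity_exponent: float = DEFAULT_INTENSITY_EXPONENT,
) -> int:
    """Weighted dot-product similarity on the 0–999 integer scale.

    ``999 * (u·v)² / (u·u v·v)`` with weighted intensities
    ``u_k = mz_k**mass_exponent * I_k**intensity_exponent``, rounded half-up
    to an integer.  Symmetric in its arguments and invariant to scaling
    either spectrum by a positive constant; a spectrum against itself scores
    exactly 999.
    """
    u, v = _weighted_vectors(query, reference, mass_exponent, intensity_exponent)
    uu = float(u @ u)
    vv = float(v @ v)
    if uu == 0.0 or vv == 0.0:
        raise SpectrumError("spectrum reduces to all-zero weighted intensities")
    cos2 = float(u @ v) ** 2 / (uu * vv)
    cos2 = min(cos2, 1.0)  # guard rounding overshoot
    return int(math.floor(999.0 * cos2 + 0.5))


def retention_index(rt: float, ladder: AlkaneSeries) -> float:
    """Retention index by piecewise-linear interpolation of the ladder.

    For ``t_n <= rt <= t_{n+1}``:
    ``RI = 100*c_n + 100*(c_{n+1}-c_n) * (rt-t_n)/(t_{n+1}-t_n)``.
    Retention times outside the ladder raise (no extrapolation).
    """
    rts = np.asarray(ladder.retention_times)
    if not (rts[0] <= rt <= rts[-1]):
        raise SpectrumError(
            f"retention time {rt} outside ladder range [{rts[0]}, {rts[-1]}]"
        )
    n = int(np.searchsorted(rts, rt, side="right")) - 1
    n = min(n, len(rts) - 2)
    c0, c1 = ladder.carbons[n], ladder.carbons[n + 1]
    t0, t1 = rts[n], rts[n + 1]
    return 100.0 * c0 + 100.0 * (c1 - c0) * (rt - t0) / (t1 - t0)


def identify(
    query: MassSpectrum,
    query_ri: float,
    library: Sequence[SpectralLibraryEntry],
    min_match: float = 700.0,
    ri_window: float = 10.0,
    mass_exponent: float = DEFAULT_MASS_EXPONENT,
    intensity_exponent: float = DEFAULT_INTENSITY_EXPONENT,
) -> Optional[MatchResult]:
    """Best accepted library hit for a query spectrum, or ``None``.

    Only entries whose reference retention index lies within ``ri_window``
    of ``query_ri`` are considered; among those the highest match value
    wins, ties broken by smaller |RI deviation| then lexicographic name.
    The hit is returned only if its match value reaches ``min_match``.
    """
    if ri_window <= 0:
        raise SpectrumError("ri_window must be > 0")
    best: Optional[tuple] = None
    for entry in library:
        dev = query_ri - entry.reference_ri
        if abs(dev) > ri_window:
            continue
        mv = match_value(query, entry.spectrum, mass_exponent, intensity_exponent)
        key = (-mv, abs(dev), entry.name)
        if best is None or key < best[0]:
            best = (key, entry, mv, dev)
    if best is None:
        return None
    _, entry, mv, dev = best
    if mv < min_match:
        return None
    return MatchResult(name=entry.name, match_value=mv, ri_deviation=dev, accepted=True)


# ---------------------------------------------------------------------------
# MSP-style library I/O
# ---------------------------------------------------------------------------

def write_msp(entries: Sequence[SpectralLibraryEntry], path: str | Path) -> None:
    """Write a library as MSP-style text blocks (NAME / RI / Num Peaks)."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(f"NAME: {e.name}\n")
            fh.write(f"RI: {e.reference_ri:.6g}\n")
            fh.write(f"Num Peaks: {len(e.spectrum.peaks)}\n")
            for mz, inten in e.spectrum.peaks:
                fh.write(f"{mz:.6g} {inten:.6g};\n")
            fh.write("\n")


def read_msp(path: str | Path) -> list[SpectralLibraryEntry]:
    entries: list[SpectralLibraryEntry] = []
    name: Optional[str] = None
    ri: Optional[float] = None
    peaks: list[tuple[float, float]] = []

    def flush() -> None:
        nonlocal name, ri, peaks
        if name is not None:
            if ri is None:
                raise SpectrumError(f"library entry {name!r} missing RI")
            entries.append(
                SpectralLibraryEntry(name=name, spectrum=MassSpectrum(peaks),
                                     reference_ri=ri)
            )
        name, ri, peaks = None, None, []

    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                continue
            upper = line.upper()
            if upper.startswith("NAME:"):
                flush()
                name = line.split(":", 1)[1].strip()
            elif upper.startswith("RI:"):
                ri = float(line.split(":", 1)[1])
            elif upper.startswith("NUM PEAKS:"):
                continue
            else:
                for pair in line.rstrip(";").split(";"):
                    pair = pair.strip()
                    if pair:
                        mz_s, i_s = pair.split()
                        peaks.append((float(mz_s), float(i_s)))
    flush()
    return entries


def write_alkane_ladder(ladder: AlkaneSeries, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("carbon\tretention_time\n")
        for c, t in zip(ladder.carbons, ladder.retention_times):
            fh.write(f"{c}\t{t:.6g}\n")


def read_alkane_ladder(path: str | Path) -> AlkaneSeries:
    carbons, rts = [], []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if "carbon" not in header:
            raise SpectrumError("alkane ladder file must have a carbon/retention_time header")
        for line in fh:
            if line.strip():
                c, t = line.split("\t")
                carbons.append(int(c))
                rts.append(float(t))
    return AlkaneSeries(carbons, rts)
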