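"""Length-frequency construction from individual catch records.

Length-based stock assessment works from binned catch-at-length
compositions.  This module turns raw length measurements (one row per
fish) into :class:`LengthFrequency` tables using fixed class intervals
chosen from the maximum recorded body length, and computes the
length-based indicators (mean catch length above the length at peak
selectivity, 95th percentile, maximum length) used to judge size
structure.

Binning convention: bins are left-closed/right-open ``[lo, lo + d)``,
anchored at ``floor(min_length / d) * d``; a fish exactly on the top
edge of the last bin is included in it.  The class-interval rule is a
step function of L_max: 0.3 cm up to 12 cm, 0.5 cm up to 20 cm, 1.0 cm
up to 35 cm, 2.0 cm above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LengthRecord",
    "LengthFrequency",
    "LengthIndicators",
    "assign_class_interval",
    "build_length_frequency",
    "compute_length_indicators",
    "read_records_csv",
    "read_lf_csv",
    "write_lf_csv",
]

#: class-interval rule: (upper bound on L_max in cm, interval in cm)
_CLASS_INTERVAL_STEPS = ((12.0, 0.3), (20.0, 0.5), (35.0, 1.0))
_CLASS_INTERVAL_LARGEST = 2.0


@dataclass(frozen=True)
class LengthRecord:
    """A single measured fish."""

    species_id: str
    year: int
    length_cm: float
    weight_g: float | None = None

    def __post_init__(self) -> None:
        if not self.length_cm > 0:
            raise ValueError(f"length_cm must be positive, got {self.length_cm}")
        if self.weight_g is not None and not self.weight_g > 0:
            raise ValueError(f"weight_g must be positive, got {self.weight_g}")


@dataclass(frozen=True)
class LengthFrequency:
    """Binned catch-at-length composition for one species-year.

    ``bin_midpoints`` are strictly increasing with constant spacing equal
    to ``class_interval_cm``; ``counts`` are per-bin totals.
    """

    species_id: str
    year: int
    class_interval_cm: float
    bin_midpoints: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        mids = np.asarray(self.bin_midpoints, dtype=float)
        cnts = np.asarray(self.counts)
        object.__setattr__(self, "bin_midpoints", mids)
        object.__setattr__(self, "counts", cnts)
        if mids.ndim != 1 or mids.size < 1:
            raise ValueError("bin_midpoints must be a non-empty 1-d array")
        if cnts.shape != mids.shape:
            raise ValueError("counts and bin_midpoints must have the same shape")
        if np.any(cnts < 0):
            raise ValueError("counts must be non-negative")
        d = self.class_interval_cm
        if not d > 0:
            raise ValueError("class_interval_cm must be positive")
        if mids.size > 1:
            spac = np.diff(mids)
            if np.any(spac <= 0) or not np.allclose(spac, d, rtol=0, atol=1e-9 * max(d, 1.0)):
                raise ValueError(
                    "bin midpoints must be strictly increasing with spacing equal "
                    "to the class interval"
                )

    @property
    def n_total(self) -> int:
        return int(np.sum(self.counts))

    @property
    def bin_edges(self) -> np.ndarray:
        d = self.class_interval_cm
        return np.concatenate([self.bin_midpoints - d / 2, [self.bin_midpoints[-1] + d / 2]])

    @property
    def l_max_observed(self) -> float:
        """Upper edge of the highest non-empty bin."""
        nz = np.nonzero(self.counts)[0]
        if nz.size == 0:
            raise ValueError("length frequency has no counts")
        return float(self.bin_midpoints[nz[-1]] + self.class_interval_cm / 2)

    def trimmed(self) -> "LengthFrequency":
        """Drop empty bins below the first and above the last non-empty bin."""
        nz = np.nonzero(self.counts)[0]
        if nz.size == 0:
            raise ValueError("length frequency has no counts")
        sl = slice(nz[0], nz[-1] + 1)
        return LengthFrequency(
            self.species_id, self.year, self.class_interval_cm,
            self.bin_midpoints[sl], self.counts[sl],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species_id,
                "year": self.year,
                "class_interval_cm": self.class_interval_cm,
                "bin_midpoint_cm": self.bin_midpoints,
                "count": self.counts,
            }
        )


@dataclass(frozen=True)
class LengthIndicators:
    """Size-structure indicators of a catch composition.

    ``l_mean_cm`` is the count-weighted mean length of the catch at or
    above the length at peak selectivity L_c; ``l_95th_cm`` the weighted
    95th percentile over all bins; ``l_max_cm`` the upper edge of the
    highest non-empty bin.  ``degenerate`` flags the case where no bin
    lies at or above L_c (indicators then refer to an empty catch and
    l_mean is NaN).
    """

    l_mean_cm: float
    l_95th_cm: float
    l_max_cm: float
    degenerate: bool = False


def assign_class_interval(l_max: float) -> float:
    """Class interval (cm) for a species with maximum observed length ``l_max``.

    Step rule: 0.3 cm for L_max <= 12, 0.5 cm for 12 < L_max <= 20,
    1.0 cm for 20 < L_max <= 35, 2.0 cm for L_max > 35.
    """
    if not l_max > 0 or not math.isfinite(l_max):
        raise ValueError(f"l_max must be a positive finite length, got {l_max}")
    for upper, interval in _CLASS_INTERVAL_STEPS:
        if l_max <= upper:
            return interval
    return _CLASS_INTERVAL_LARGEST


def _as_lengths(records: Iterable[LengthRecord] | pd.DataFrame,
                species_id: str, year: int) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        sub = records[(records["species"] == species_id) & (records["year"] == year)]
        lengths = sub["length_cm"].to_numpy(dtype=float)
    else:
        lengths = np.array(
            [r.length_cm for r in records if r.species_id == species_id and r.year == year],
            dtype=float,
        )
    return lengths


def build_length_frequency(
    records: Iterable[LengthRecord] | pd.DataFrame,
    species_id: str,
    year: int,
    class_interval_cm: float | None = None,
) -> LengthFrequency:
    """Bin individual length records for one species-year.

    The class interval defaults to :func:`assign_class_interval` of the
    maximum recorded length.  Bins span the observed length range; every
    record falls into exactly one bin and the counts sum to the number
    of records.  Months within a year are pooled.
    """
    lengths = _as_lengths(records, species_id, year)
    if lengths.size == 0:
        raise ValueError(f"no records for species {species_id!r}, year {year}")
    if np.any(lengths <= 0):
        raise ValueError("all lengths must be positive")
    d = class_interval_cm if class_interval_cm is not None else assign_class_interval(lengths.max())
    lo = math.floor(lengths.min() / d) * d
    n_bins = max(int(math.ceil((lengths.max() - lo) / d)), 1)
    # np.histogram is left-closed/right-open except the last bin, which is
    # closed — exactly the convention wanted here.
    edges = lo + d * np.arange(n_bins + 1)
    if edges[-1] < lengths.max():  # guard against float round-off at the top edge
        edges = np.append(edges, edges[-1] + d)
    counts, _ = np.histogram(lengths, bins=edges)
    mids = edges[:-1] + d / 2
    lf = LengthFrequency(species_id, year, d, mids, counts.astype(int))
    if int(np.count_nonzero(lf.counts)) < 2:
        raise ValueError(
            "length frequency needs at least 2 non-empty bins; "
            "the records span a single class"
        )
    assert lf.n_total == lengths.size
    return lf


def compute_length_indicators(lf: LengthFrequency, l_c: float) -> LengthIndicators:
    """Length-based indicators of ``lf`` given the length at peak selectivity.

    L_mean is computed over bins with midpoint >= ``l_c`` (the catch the
    gear retains fully); the 95th percentile uses the weighted empirical
    CDF over all bins with linear interpolation inside a bin, treating
    counts as spread uniformly across each bin.
    """
    if l_c < 0:
        raise ValueError("l_c must be non-negative")
    counts = np.asarray(lf.counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("length frequency has no counts")
    l_max = lf.l_max_observed

    above = lf.bin_midpoints >= l_c
    n_above = counts[above].sum()
    if n_above <= 0:
        return LengthIndicators(math.nan, _weighted_percentile(lf, 95.0), l_max, degenerate=True)
    l_mean = float(np.average(lf.bin_midpoints[above], weights=counts[above]))
    l_95 = _weighted_percentile(lf, 95.0)
    return LengthIndicators(l_mean, l_95, l_max)


def _weighted_percentile(lf: LengthFrequency, q: float) -> float:
    """Percentile of the binned distribution, uniform within bins."""
    counts = np.asarray(lf.counts, dtype=float)
    edges = lf.bin_edges
    cum = np.concatenate([[0.0], np.cumsum(counts)]) / counts.sum()
    target = q / 100.0
    k = int(np.searchsorted(cum, target, side="left"))
    k = min(max(k, 1), len(edges) - 1)
    f_lo, f_hi = cum[k - 1], cum[k]
    if f_hi == f_lo:  # empty bin exactly at the target: step to its upper edge
        return float(edges[k])
    frac = (target - f_lo) / (f_hi - f_lo)
    return float(edges[k - 1] + frac * (edges[k] - edges[k - 1]))


def read_records_csv(path) -> pd.DataFrame:
    """Read an individual-records CSV (columns species,year,length_cm[,weight_g])."""
    df = pd.read_csv(path)
    missing = {"species", "year", "length_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"records CSV is missing columns: {sorted(missing)}")
    if (df["length_cm"] <= 0).any():
        raise ValueError("records CSV contains non-positive lengths")
    df["year"] = df["year"].astype(int)
    return df


def write_lf_csv(lfs: Sequence[LengthFrequency] | LengthFrequency, path) -> None:
    if isinstance(lfs, LengthFrequency):
        lfs = [lfs]
    pd.concat([lf.to_frame() for lf in lfs], ignore_index=True).to_csv(path, index=False)


def read_lf_csv(path) -> list[LengthFrequency]:
    """Read a binned length-frequency CSV back into containers."""
    df = pd.read_csv(path)
    out = []
    for (sp, yr), grp in df.groupby(["species", "year"], sort=True):
        grp = grp.sort_values("bin_midpoint_cm")
        out.append(
            LengthFrequency(
                str(sp), int(yr), float(grp["class_interval_cm"].iloc[0]),
                grp["bin_midpoint_cm"].to_numpy(dtype=float),
                grp["count"].to_numpy(dtype=int),
            )
        )
    return out
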