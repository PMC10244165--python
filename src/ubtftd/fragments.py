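"""In-silico fragment-analysis screen.

Models the capillary-electrophoresis readout of the exon 12-14 PCR screen:
a wild-type allele runs as a single peak at the amplicon size (617 bp for the
packaged locus) and a TD-bearing allele as a second peak displaced by the
total inserted length (e.g. 665 bp for a 48-bp duplication).  Sizes are
assumed already calibrated against the size standard; the GeneScan 1200-type
ladder imposes an upper sizing bound above which mutant calls are flagged.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ConfigError, TDSpecError

__all__ = [
    "FragmentTrace",
    "PeakCall",
    "expected_mutant_size",
    "call_peaks",
    "SIZE_STANDARD_MAX",
]

#: upper bound of the size standard; peaks above it are sized but flagged
SIZE_STANDARD_MAX = 1200.0


@dataclasses.dataclass
class FragmentTrace:
    """An electropherogram as (size, height) points with increasing sizes."""

    sizes: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.sizes.size != self.heights.size or self.sizes.size == 0:
            raise ConfigError("trace requires matching non-empty size/height arrays")
        if np.any(np.diff(self.sizes) <= 0):
            raise ConfigError("trace sizes must be strictly increasing")
        if np.any(self.heights < 0):
            raise ConfigError("trace heights must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FragmentTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(df["size"].to_numpy(), df["height"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"size": self.sizes, "height": self.heights}).to_csv(
            path, sep="\t", index=False
        )


@dataclasses.dataclass
class PeakCall:
    size: float
    height: float
    classification: str  # wild-type | mutant | stutter | noise
    td_size: int | None = None
    beyond_size_standard: bool = False


def expected_mutant_size(wt_amplicon: float, total_inserted_length: int) -> float:
    """Mutant fragment size: wild-type amplicon plus total inserted length."""
    if wt_amplicon <= 0:
        raise ConfigError("wild-type amplicon size must be positive")
    if wt_amplicon + total_inserted_length <= 0:
        raise TDSpecError("negative total inserted length exceeds amplicon")
    return wt_amplicon + total_inserted_length


def call_peaks(
    trace: FragmentTrace,
    wt_size: float,
    min_height_fraction: float = 0.05,
    min_abs_height: float = 10.0,
    wt_tolerance: float = 2.0,
    stutter_window: float = 1.5,
    stutter_max_ratio: float = 0.15,
) -> tuple[list[PeakCall], bool]:
    """Call and classify peaks in a fragment trace.

    Local maxima above ``min_height_fraction`` of the trace maximum are kept.
    The peak nearest ``wt_size`` (within ``wt_tolerance``) is the wild-type
    allele; small satellites within ``stutter_window`` bp of a >=1/0.15-fold
    taller neighbour are stutter; remaining peaks larger than the wild type
    are mutant alleles with TD size = round(peak - wt).  Returns the calls
    and a ``no_wt`` flag (True when no wild-type peak was found: possible
    hemizygous/homozygous mutant or failed reaction).
    """
    h = trace.heights
    if h.max() <= 0:
        return [], True
    threshold = max(min_height_fraction * h.max(), min_abs_height)
    idx, _ = find_peaks(h, height=threshold, prominence=0.25 * threshold)
    if idx.size == 0:
        return [], True
    peak_sizes = trace.sizes[idx]
    peak_heights = h[idx]

    # wild-type: nearest to wt_size within tolerance
    wt_i: int | None = None
    dist = np.abs(peak_sizes - wt_size)
    cand = np.where(dist <= wt_tolerance)[0]
    if cand.size:
        wt_i = int(cand[np.argmin(dist[cand])])

    calls: list[PeakCall] = []
    for i in range(peak_sizes.size):
        size, height = float(peak_sizes[i]), float(peak_heights[i])
        if i == wt_i:
            calls.append(PeakCall(size, height, "wild-type"))
            continue
        # stutter: close to a much taller neighbouring peak
        neighbours = np.abs(peak_sizes - size) <= stutter_window
        neighbours[i] = False
        if np.any(neighbours) and height < stutter_max_ratio * peak_heights[neighbours].max():
            calls.append(PeakCall(size, height, "stutter"))
            continue
        if size > wt_size + wt_tolerance:
            calls.append(
                PeakCall(
                    size,
                    height,
                    "mutant",
                    td_size=int(round(size - wt_size)),
                    beyond_size_standard=size > SIZE_STANDARD_MAX,
                )
            )
        else:
            calls.append(PeakCall(size, height, "noise"))
    return calls, wt_i is None


def peak_calls_to_frame(calls: list[PeakCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "size": [c.size for c in calls],
            "height": [c.height for c in calls],
            "classification": [c.classification for c in calls],
            "td_size": [c.td_size for c in calls],
            "beyond_size_standard": [c.beyond_size_standard for c in calls],
        }
    )
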