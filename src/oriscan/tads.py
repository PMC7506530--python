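"""Origin density and initiation signal across topologically associating
domains (TADs).

Each TAD is divided into 100 equal bins; bins 1-10 and 91-100 (1-based) are
borders and bins 41-60 are centres. Origins are assigned to bins by their
summit (midpoint when no summit is available), densities are normalised to
the bin length and averaged with equal weight per TAD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GenomicInterval

N_BINS = 100
BORDER_BINS = np.array(list(range(10)) + list(range(90, 100)))  # 0-based
CENTRE_BINS = np.arange(40, 60)                                 # bins 41-60, 1-based


@dataclass
class TadProfile:
    bins: np.ndarray          # length 100; density (per Mb) or summed signal
    n_tads: int
    n_skipped: int = 0
    n_assigned: int = 0       # origins / signal intervals that fell inside TADs

    @property
    def border_centre_ratio(self) -> float:
        centre = float(self.bins[CENTRE_BINS].sum())
        if centre == 0:
            raise ValueError("zero signal in centre bins; ratio undefined")
        return float(self.bins[BORDER_BINS].sum()) / centre


def _bin_index(pos: int, tad: GenomicInterval) -> int | None:
    if pos < tad.start or pos >= tad.end:
        return None
    b = (pos - tad.start) * N_BINS // tad.length
    b = min(b, N_BINS - 1)
    if tad.strand == "-":
        b = N_BINS - 1 - b
    return b


def tad_density_profile(
    origins: Sequence[GenomicInterval],
    tads: Sequence[GenomicInterval],
    points: Sequence[int] | None = None,
) -> TadProfile:
    """Average origin density per bin (origins per Mb) across all TADs.

    Origins are assigned by ``points`` (e.g. summits) when given, otherwise
    by midpoint. Each TAD contributes its per-bin density with equal
    weight; TADs shorter than 100 bp are skipped and counted.
    """
    pos = [p for p in points] if points is not None else [o.midpoint for o in origins]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for o, p in zip(origins, pos):
        by_chrom.setdefault(o.chrom, []).append((p, 1))
    return _profile(by_chrom, tads, density=True)


def tad_signal_profile(
    signal: Sequence[GenomicInterval],
    tads: Sequence[GenomicInterval],
) -> TadProfile:
    """Per-bin summed signal (interval scores assigned by midpoint) over TADs."""
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for iv in signal:
        by_chrom.setdefault(iv.chrom, []).append(
            (iv.midpoint, iv.score if iv.score is not None else 0.0)
        )
    return _profile(by_chrom, tads, density=False)


def _profile(
    by_chrom: dict[str, list[tuple[int, float]]],
    tads: Sequence[GenomicInterval],
    density: bool,
) -> TadProfile:
    total = np.zeros(N_BINS)
    n_tads = n_skipped = n_assigned = 0
    for tad in tads:
        if tad.length < N_BINS:
            n_skipped += 1
            continue
        counts = np.zeros(N_BINS)
        for p, w in by_chrom.get(tad.chrom, []):
            b = _bin_index(p, tad)
            if b is not None:
                counts[b] += w
                n_assigned += 1
        if density:
            bin_len = tad.length / N_BINS
            counts = counts / bin_len * 1e6  # per Mb
        total += counts
        n_tads += 1
    if n_tads == 0:
        raise ValueError("no usable TADs")
    bins = total / n_tads if density else total
    return TadProfile(bins, n_tads, n_skipped, n_assigned)


def normalize_profile_to_centre(profile: TadProfile) -> np.ndarray:
    """Bins divided by the mean of the centre bins (output centre mean = 1)."""
    centre_mean = float(profile.bins[CENTRE_BINS].mean())
    if centre_mean == 0:
        raise ValueError("zero centre mean; normalisation undefined")
    return profile.bins / centre_mean
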