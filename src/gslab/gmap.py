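"""Genetic maps in centimorgan coordinates.

A :class:`GeneticMap` places markers on chromosomes by genetic distance only;
no physical (base-pair) coordinates are used anywhere in the package. Conifer
genome assemblies are too fragmented for reliable physical maps, so all
recombination modelling works from total map length (~20 Morgans for the
Pinaceae) downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneticMap", "make_genetic_map"]


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions (cM) on one or more chromosomes.

    Parameters
    ----------
    chrom_lengths : ndarray of float
        Length of each chromosome in centimorgans.
    chrom : ndarray of int
        Chromosome index (0-based) of each marker; non-decreasing.
    pos_cm : ndarray of float
        Position of each marker in cM, sorted ascending within chromosome.
    marker_ids : list of str
        One identifier per marker.
    """

    chrom_lengths: np.ndarray
    chrom: np.ndarray
    pos_cm: np.ndarray
    marker_ids: list = field(default_factory=list)

    def __post_init__(self):
        lengths = np.asarray(self.chrom_lengths, dtype=float)
        chrom = np.asarray(self.chrom, dtype=np.int64)
        pos = np.asarray(self.pos_cm, dtype=float)
        object.__setattr__(self, "chrom_lengths", lengths)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_cm", pos)
        if lengths.ndim != 1 or lengths.size == 0 or np.any(lengths <= 0):
            raise ValueError("chromosome lengths must be a non-empty positive vector")
        if chrom.shape != pos.shape:
            raise ValueError("chrom and pos_cm must have the same length")
        if len(self.marker_ids) != pos.size:
            raise ValueError("need exactly one marker id per position")
        if np.any((chrom < 0) | (chrom >= lengths.size)):
            raise ValueError("marker chromosome index out of range")
        if np.any(np.diff(chrom) < 0):
            raise ValueError("markers must be grouped by chromosome in ascending order")
        if np.any(pos < 0) or np.any(pos > lengths[chrom]):
            raise ValueError("marker positions must lie within [0, chromosome length]")
        for c in range(lengths.size):
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions on chromosome {c} are not sorted")

    @property
    def n_markers(self) -> int:
        return int(self.pos_cm.size)

    @property
    def n_chromosomes(self) -> int:
        return int(self.chrom_lengths.size)

    @property
    def total_length_cm(self) -> float:
        """Total map length L in centimorgans."""
        return float(self.chrom_lengths.sum())

    @property
    def total_length_morgans(self) -> float:
        return self.total_length_cm / 100.0

    def chromosome_slices(self) -> list:
        """Return per-chromosome marker index slices (in map order)."""
        out = []
        start = 0
        for c in range(self.n_chromosomes):
            n = int(np.sum(self.chrom == c))
            out.append(slice(start, start + n))
            start += n
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "marker": list(self.marker_ids),
                "chromosome": self.chrom + 1,
                "position_cM": self.pos_cm,
            }
        )


def make_genetic_map(
    n_chromosomes: int,
    total_length_cm: float,
    n_markers: int,
    seed: int,
) -> GeneticMap:
    """Draw a uniform random marker map.

    Chromosomes get equal lengths summing to ``total_length_cm``; markers are
    allocated to chromosomes as evenly as possible (remainder to the first
    chromosomes) and positioned uniformly, then sorted. Deterministic given
    ``seed``.
    """
    if n_chromosomes <= 0 or n_markers <= 0 or total_length_cm <= 0:
        raise ValueError("n_chromosomes, n_markers and total_length_cm must be positive")
    if n_markers < n_chromosomes:
        raise ValueError("need at least one marker per chromosome")
    rng = np.random.default_rng(seed)
    lengths = np.full(n_chromosomes, total_length_cm / n_chromosomes)
    base, extra = divmod(n_markers, n_chromosomes)
    counts = np.full(n_chromosomes, base, dtype=int)
    counts[:extra] += 1
    chrom = np.repeat(np.arange(n_chromosomes), counts)
    pos = np.empty(n_markers)
    start = 0
    for c in range(n_chromosomes):
        p = np.sort(rng.uniform(0.0, lengths[c], counts[c]))
        pos[start : start + counts[c]] = p
        start += counts[c]
    width = len(str(n_markers))
    ids = [f"M{i + 1:0{width}d}" for i in range(n_markers)]
    return GeneticMap(lengths, chrom, pos, ids)
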