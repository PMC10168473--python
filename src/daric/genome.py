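"""Binned-genome coordinate model and per-bin data containers.

Everything downstream (O/E matrices, compartment labels, PIS tracks,
domain segmentations) is indexed against a :class:`BinnedGenome`: a fixed
bin width tiled across an ordered set of chromosomes, with a boolean gap
mask marking unmappable reference regions that are excluded from all
signal computation.

Coordinates are 0-based, half-open throughout, matching BED/bedGraph and
the juicer dump text layout (positions are bin starts in base pairs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BinnedGenome",
    "OEMatrix",
    "CompartmentTrack",
    "SignalTrack",
    "PISTrack",
    "A",
    "B",
    "UNDEFINED",
]

# compartment label codes
A = 1
B = -1
UNDEFINED = 0


@dataclass(frozen=True)
class BinnedGenome:
    """Fixed-width binning of a genome with a gap mask.

    Parameters
    ----------
    chrom_names
        Ordered chromosome identifiers.
    chrom_lengths
        Chromosome lengths in base pairs, same order as ``chrom_names``.
    bin_size
        Bin width in base pairs. The last bin of each chromosome may be
        shorter than ``bin_size``.
    gap_mask
        Global per-bin boolean array, ``True`` where the bin overlaps an
        unmappable/gap region. Defaults to no gaps.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int
    gap_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths))
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.gap_mask is None:
            object.__setattr__(self, "gap_mask", np.zeros(self.n_bins, dtype=bool))
        else:
            gm = np.asarray(self.gap_mask, dtype=bool)
            if gm.shape != (self.n_bins,):
                raise ValueError(
                    f"gap_mask length {gm.shape} != total bin count {self.n_bins}"
                )
            object.__setattr__(self, "gap_mask", gm)

    # -- bin bookkeeping ---------------------------------------------------

    def n_bins_chrom(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[self._index(chrom)] / self.bin_size)

    @property
    def bins_per_chrom(self) -> tuple[int, ...]:
        return tuple(math.ceil(l / self.bin_size) for l in self.chrom_lengths)

    @property
    def n_bins(self) -> int:
        return sum(self.bins_per_chrom)

    @property
    def chrom_offsets(self) -> dict[str, int]:
        """Global bin index of each chromosome's first bin."""
        offsets, cum = {}, 0
        for name, n in zip(self.chrom_names, self.bins_per_chrom):
            offsets[name] = cum
            cum += n
        return offsets

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the global bin axis covering one chromosome."""
        start = self.chrom_offsets[chrom]
        return slice(start, start + self.n_bins_chrom(chrom))

    def _index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def bin_start(self, chrom: str, local_bin: int) -> int:
        return local_bin * self.bin_size

    def bin_end(self, chrom: str, local_bin: int) -> int:
        return min((local_bin + 1) * self.bin_size, self.chrom_lengths[self._index(chrom)])

    def with_gaps_from_intervals(self, intervals) -> "BinnedGenome":
        """Return a copy whose gap mask marks every bin overlapping an interval.

        ``intervals`` is an iterable of ``(chrom, start, end)`` in 0-based
        half-open base-pair coordinates; chromosomes not in the genome are
        ignored (assembly gap files often carry extra scaffolds).
        """
        mask = self.gap_mask.copy()
        offsets = self.chrom_offsets
        for chrom, start, end in intervals:
            if chrom not in self:
                continue
            n = self.n_bins_chrom(chrom)
            lo = max(0, int(start) // self.bin_size)
            hi = min(n, -(-int(end) // self.bin_size))
            mask[offsets[chrom] + lo: offsets[chrom] + hi] = True
        return replace(self, gap_mask=mask)

    def same_binning(self, other: "BinnedGenome") -> bool:
        return (
            self.chrom_names == other.chrom_names
            and self.chrom_lengths == other.chrom_lengths
            and self.bin_size == other.bin_size
        )


@dataclass
class OEMatrix:
    """Per-chromosome symmetric observed/expected contact matrix.

    ``values`` is dense ``n x n`` (n = bins on the chromosome); ``valid``
    is False where the dump file had no entry or a non-finite value.
    Rows/columns of gap bins are entirely invalid.
    """

    chrom: str
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("O/E matrix must be square")
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask shape mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check(self, atol: float = 1e-9) -> None:
        """Assert symmetry and non-negativity on valid entries."""
        both = self.valid & self.valid.T
        if not np.allclose(self.values[both], self.values.T[both], atol=atol):
            raise ValueError("matrix not symmetric on valid entries")
        if np.any(self.values[self.valid] < 0):
            raise ValueError("negative O/E value on a valid entry")


class SignalTrack:
    """A real-valued per-bin signal over a whole genome; NaN marks no-data.

    Base class for PIS, residual (ΔPIS) and significance-score tracks.
    """

    def __init__(self, genome: BinnedGenome, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (genome.n_bins,):
            raise ValueError(
                f"track length {values.shape} != genome bin count {genome.n_bins}"
            )
        self.genome = genome
        self.values = values

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.genome.chrom_slice(chrom)]

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def _require_same_genome(self, other: "SignalTrack") -> None:
        if not self.genome.same_binning(other.genome):
            raise ValueError("tracks are on different genomes/binnings")

    def copy_with(self, values: np.ndarray, cls=None):
        cls = cls or type(self)
        return cls(self.genome, values)


class PISTrack(SignalTrack):
    """Preferential Interaction Score per bin: log2 of the mean O/E contact
    with A-compartment bins over the mean O/E contact with B-compartment
    bins on the same chromosome. Positive values mean preferential
    interaction with the active (A) compartment."""

    def __init__(self, genome, values, sample: str = "", smoothed: bool = False):
        super().__init__(genome, values)
        self.sample = sample
        self.smoothed = smoothed

    def copy_with(self, values, cls=None):
        if cls is None or cls is PISTrack:
            return PISTrack(self.genome, values, sample=self.sample, smoothed=self.smoothed)
        return cls(self.genome, values)


class CompartmentTrack:
    """Per-bin A/B compartment label with optional eigenvector values.

    Labels are ``A`` (+1), ``B`` (-1) or ``UNDEFINED`` (0); gap bins are
    always undefined.
    """

    def __init__(self, genome: BinnedGenome, labels: np.ndarray, eigen: np.ndarray | None = None):
        labels = np.asarray(labels, dtype=np.int8)
        if labels.shape != (genome.n_bins,):
            raise ValueError("label track length != genome bin count")
        labels = labels.copy()
        labels[genome.gap_mask] = UNDEFINED
        self.genome = genome
        self.labels = labels
        self.eigen = None if eigen is None else np.asarray(eigen, dtype=float)

    def chrom_labels(self, chrom: str) -> np.ndarray:
        return self.labels[self.genome.chrom_slice(chrom)]

    def class_counts(self, chrom: str) -> tuple[int, int]:
        lab = self.chrom_labels(chrom)
        return int(np.sum(lab == A)), int(np.sum(lab == B))
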