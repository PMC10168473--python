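"""Readers and writers for the plain-text formats the pipeline speaks.

Input: juicer ``dump oe`` 3-column text (one matrix per chromosome),
bedGraph compartment eigenvector tracks, BED gap/annotation intervals.
Output: bedGraph signal tracks (PIS, residual, significance score) and
BED domain calls. All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import math
import os
import warnings

import numpy as np
import pandas as pd

from .genome import A, B, UNDEFINED, BinnedGenome, CompartmentTrack, OEMatrix, SignalTrack

__all__ = [
    "read_oe_dump",
    "read_compartments",
    "read_bed_intervals",
    "read_gaps",
    "write_track",
    "read_track",
    "write_domains",
    "read_domains",
]


class ParseError(ValueError):
    """Malformed input file content."""


class CoordinateError(ValueError):
    """Positions inconsistent with the genome binning."""


# ---------------------------------------------------------------------------
# juicer dump text


def read_oe_dump(path: str, chrom: str, genome: BinnedGenome) -> OEMatrix:
    """Read one chromosome's O/E matrix from juicer ``dump oe`` text.

    Rows are ``pos1 pos2 value`` with positions in base pairs at bin
    starts (multiples of the bin size). Entries absent from the file, and
    entries whose value is non-finite, are marked invalid. The matrix is
    mirrored across the diagonal; gap-bin rows/columns are invalidated.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    n = genome.n_bins_chrom(chrom)
    length = genome.chrom_lengths[genome._index(chrom)]
    bs = genome.bin_size
    values = np.zeros((n, n), dtype=float)
    valid = np.zeros((n, n), dtype=bool)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                p1, p2 = int(parts[0]), int(parts[1])
                v = float(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed row {line!r}") from None
            for p in (p1, p2):
                if p % bs != 0:
                    raise CoordinateError(
                        f"{path}:{lineno}: position {p} not a multiple of bin size {bs}"
                    )
                if not (0 <= p < length):
                    raise CoordinateError(
                        f"{path}:{lineno}: position {p} outside chromosome {chrom} "
                        f"(length {length})"
                    )
            i, j = p1 // bs, p2 // bs
            if math.isfinite(v):
                values[i, j] = values[j, i] = v
                valid[i, j] = valid[j, i] = True

    gap = genome.gap_mask[genome.chrom_slice(chrom)]
    valid[gap, :] = False
    valid[:, gap] = False
    values[~valid] = 0.0
    return OEMatrix(chrom=chrom, values=values, valid=valid)


def write_oe_dump(oe: OEMatrix, path: str, genome: BinnedGenome) -> None:
    """Write the upper triangle of valid entries in juicer dump layout."""
    bs = genome.bin_size
    iu, ju = np.triu_indices(oe.n)
    keep = oe.valid[iu, ju]
    with open(path, "w") as fh:
        for i, j in zip(iu[keep], ju[keep]):
            fh.write(f"{i * bs}\t{j * bs}\t{oe.values[i, j]:.10g}\n")


# ---------------------------------------------------------------------------
# bedGraph / BED


def _read_table(path: str, ncols: int, names):
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#", usecols=range(ncols),
            names=names, skiprows=_count_track_lines(path),
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=names)
    return df


def _count_track_lines(path: str) -> int:
    k = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                k += 1
            else:
                break
    return k


def read_bed_intervals(path: str):
    """Yield (chrom, start, end) triples from a BED3+ file."""
    df = _read_table(path, 3, ["chrom", "start", "end"])
    return list(df.itertuples(index=False, name=None))


def read_gaps(path: str, genome: BinnedGenome) -> BinnedGenome:
    """Return a genome whose gap mask covers the intervals of a BED file."""
    return genome.with_gaps_from_intervals(read_bed_intervals(path))


def read_compartments(
    path: str, genome: BinnedGenome, orientation: str = "as_is"
) -> CompartmentTrack:
    """Read A/B compartment calls from a 4-column bedGraph eigenvector track.

    A positive value labels the bin A under ``as_is`` orientation; ``flip``
    exchanges A and B (use when the eigenvector sign is anti-correlated
    with gene density — that orientation check is upstream of this tool).
    Bins not covered, bins with value exactly 0, and gap bins are
    ``undefined``.
    """
    if orientation not in ("as_is", "flip"):
        raise ValueError(f"orientation must be as_is|flip, got {orientation!r}")
    df = _read_table(path, 4, ["chrom", "start", "end", "value"])
    labels = np.full(genome.n_bins, UNDEFINED, dtype=np.int8)
    eigen = np.full(genome.n_bins, np.nan)
    covered = np.zeros(genome.n_bins, dtype=bool)
    offsets = genome.chrom_offsets
    bs = genome.bin_size
    sign = -1 if orientation == "flip" else 1
    for chrom, start, end, value in df.itertuples(index=False, name=None):
        if chrom not in genome:
            continue
        if start % bs != 0 or (end % bs != 0 and end != genome.chrom_lengths[genome._index(chrom)]):
            raise CoordinateError(
                f"{path}: interval {chrom}:{start}-{end} not aligned to {bs} bp bins"
            )
        lo = offsets[chrom] + start // bs
        hi = offsets[chrom] + -(-end // bs)
        if covered[lo:hi].any():
            raise ParseError(f"{path}: overlapping intervals at {chrom}:{start}-{end}")
        covered[lo:hi] = True
        eigen[lo:hi] = value
        v = sign * value
        labels[lo:hi] = A if v > 0 else (B if v < 0 else UNDEFINED)
    return CompartmentTrack(genome, labels, eigen=eigen)


def write_track(
    track: SignalTrack,
    path: str,
    fmt: str = "bedGraph",
    merge_equal: bool = False,
    header: list[str] | None = None,
) -> None:
    """Write a signal track as bedGraph; NaN bins are omitted.

    ``merge_equal`` collapses runs of adjacent bins with identical values
    into single intervals.
    """
    if fmt != "bedGraph":
        raise ValueError(f"unsupported track format {fmt!r}")
    genome = track.genome
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        for chrom in genome.chrom_names:
            vals = track.chrom_values(chrom)
            n = len(vals)
            i = 0
            while i < n:
                if not np.isfinite(vals[i]):
                    i += 1
                    continue
                j = i + 1
                if merge_equal:
                    while j < n and np.isfinite(vals[j]) and vals[j] == vals[i]:
                        j += 1
                fh.write(
                    f"{chrom}\t{genome.bin_start(chrom, i)}\t"
                    f"{genome.bin_end(chrom, j - 1)}\t{vals[i]:.8g}\n"
                )
                i = j


def read_track(path: str, genome: BinnedGenome, cls=SignalTrack):
    """Read a bedGraph file back into a signal track (NaN where uncovered)."""
    df = _read_table(path, 4, ["chrom", "start", "end", "value"])
    values = np.full(genome.n_bins, np.nan)
    offsets = genome.chrom_offsets
    bs = genome.bin_size
    for chrom, start, end, value in df.itertuples(index=False, name=None):
        if chrom not in genome:
            continue
        if start % bs != 0:
            raise CoordinateError(f"{path}: start {start} not bin-aligned")
        lo = offsets[chrom] + start // bs
        hi = offsets[chrom] + -(-end // bs)
        values[lo:hi] = value
    return cls(genome, values)


def write_domains(seg, path: str, fmt: str = "BED", header: list[str] | None = None) -> None:
    """Write a domain segmentation as BED6+3.

    Columns: chrom, start, end, state label, mean significance score
    scaled to [0, 1000], strand '.', then mean residual, mean score and a
    significant flag as extra fields.
    """
    if fmt != "BED":
        raise ValueError(f"unsupported domain format {fmt!r}")
    genome = seg.genome
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        for d in seg.domains:
            score = d.mean_score
            bed_score = 0 if not np.isfinite(score) else int(round(min(max(score, 0.0), 20.0) * 50))
            fh.write(
                f"{d.chrom}\t{genome.bin_start(d.chrom, d.start_bin)}\t"
                f"{genome.bin_end(d.chrom, d.end_bin - 1)}\t{d.state}\t{bed_score}\t.\t"
                f"{d.mean_residual:.6g}\t{score:.6g}\t{int(d.significant)}\n"
            )


def read_domains(path: str, genome: BinnedGenome):
    """Read a BED domain file written by :func:`write_domains`."""
    from .segmentation import Domain, DomainSegmentation

    names = ["chrom", "start", "end", "state", "score", "strand", "mean_residual",
             "mean_score", "significant"]
    df = _read_table(path, 9, names)
    bs = genome.bin_size
    domains = []
    for row in df.itertuples(index=False):
        domains.append(
            Domain(
                chrom=row.chrom,
                start_bin=int(row.start) // bs,
                end_bin=-(-int(row.end) // bs),
                state=str(row.state),
                mean_residual=float(row.mean_residual),
                mean_score=float(row.mean_score),
                significant=bool(int(row.significant)),
            )
        )
    return DomainSegmentation(genome=genome, domains=domains)


def ensure_parent(path: str) -> None:
    parent = os.path.dirname(os.path.abspath(path))
    if parent and not os.path.isdir(parent):
        os.makedirs(parent, exist_ok=True)
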