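"""Data model and I/O for binned contact matrices, loop lists and result tables.

Conventions used throughout the package:

* bins are 0-based and half-open: bin ``i`` covers ``[i * bin_size, (i + 1) * bin_size)``;
* contact matrices are intrachromosomal and stored upper-triangular (``i <= j``);
* interaction distance is ``d = j - i`` in units of bins;
* dense per-replicate matrices are carried internally as "banded" float arrays of
  shape ``(n_bins, max_dist + 1)`` where ``band[i, d]`` holds the value at pixel
  ``(i, i + d)`` and out-of-range entries are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "ContactMatrix",
    "Loop",
    "LoopList",
    "filter_sparse_rows",
    "read_contacts",
    "read_loops_bedpe",
    "write_loops_bedpe",
    "write_results",
    "read_results",
    "banded_valid_mask",
]


@dataclass(frozen=True)
class StudyDesign:
    """Replicate-to-condition assignment plus the tested distance range.

    Parameters
    ----------
    condition_of:
        Mapping from replicate id to condition label.  Order of insertion
        defines both replicate order and (by first appearance) condition order.
    bin_size:
        Base pairs per matrix bin.
    min_dist_bins, max_dist_bins:
        Inclusive tested interaction-distance range in bins.  Interactions
        outside this range are never tested.
    """

    condition_of: dict
    bin_size: int = 10_000
    min_dist_bins: int = 4
    max_dist_bins: int = 500

    def __post_init__(self):
        if len(self.conditions) < 2:
            raise ValueError("a study design needs at least 2 conditions")
        for c in self.conditions:
            if not self.replicates_of(c):
                raise ValueError(f"condition {c!r} has no replicates")
        if self.min_dist_bins < 1:
            raise ValueError("min_dist_bins must be >= 1")
        if self.max_dist_bins <= self.min_dist_bins:
            raise ValueError("max_dist_bins must exceed min_dist_bins")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def replicates(self) -> list:
        return list(self.condition_of)

    @property
    def conditions(self) -> list:
        seen = []
        for c in self.condition_of.values():
            if c not in seen:
                seen.append(c)
        return seen

    def replicates_of(self, condition) -> list:
        return [r for r, c in self.condition_of.items() if c == condition]


@dataclass
class ContactMatrix:
    """Sparse upper-triangular binned counts for one replicate on one chromosome."""

    chrom: str
    n_bins: int
    bin_i: np.ndarray
    bin_j: np.ndarray
    count: np.ndarray
    replicate_id: str | None = None

    @classmethod
    def from_triplets(cls, chrom, n_bins, bin_i, bin_j, count, replicate_id=None):
        """Canonicalize raw triplets: mirror to upper triangle, sum duplicates."""
        bin_i = np.asarray(bin_i, dtype=np.int64)
        bin_j = np.asarray(bin_j, dtype=np.int64)
        count = np.asarray(count, dtype=np.int64)
        if bin_i.size:
            if bin_i.min() < 0 or bin_j.min() < 0:
                raise ValueError("negative bin index")
            if max(bin_i.max(), bin_j.max()) >= n_bins:
                raise ValueError("bin index beyond declared n_bins")
            if count.min() < 0:
                raise ValueError("negative count")
        lo = np.minimum(bin_i, bin_j)
        hi = np.maximum(bin_i, bin_j)
        key = lo * n_bins + hi
        order = np.argsort(key, kind="stable")
        key, lo, hi, count = key[order], lo[order], hi[order], count[order]
        uniq, start = np.unique(key, return_index=True)
        summed = np.add.reduceat(count, start) if count.size else count
        return cls(chrom, n_bins, lo[start], hi[start], summed, replicate_id)

    @property
    def n_entries(self) -> int:
        return len(self.count)

    def to_banded(self, max_dist: int) -> np.ndarray:
        """Dense banded float array (NaN where (i, i+d) falls outside the matrix)."""
        band = np.zeros((self.n_bins, max_dist + 1))
        band[~banded_valid_mask(self.n_bins, max_dist)] = np.nan
        d = self.bin_j - self.bin_i
        keep = d <= max_dist
        band[self.bin_i[keep], d[keep]] = self.count[keep]
        return band

    @classmethod
    def from_banded(cls, band, chrom="chrS", replicate_id=None):
        n_bins = band.shape[0]
        i, d = np.nonzero(np.nan_to_num(band) != 0)
        return cls(chrom, n_bins, i, i + d, band[i, d].astype(np.int64), replicate_id)

    def to_dense(self) -> np.ndarray:
        m = np.zeros((self.n_bins, self.n_bins))
        m[self.bin_i, self.bin_j] = self.count
        m[self.bin_j, self.bin_i] = self.count
        return m


def banded_valid_mask(n_bins: int, max_dist: int) -> np.ndarray:
    """Boolean mask of banded entries whose (i, i+d) lies inside the matrix."""
    i = np.arange(n_bins)[:, None]
    d = np.arange(max_dist + 1)[None, :]
    return i + d < n_bins


@dataclass
class Loop:
    chrom: str
    pixels: frozenset
    loop_id: str
    condition: str | None = None
    category: str | None = None

    def __post_init__(self):
        if not self.pixels:
            raise ValueError(f"loop {self.loop_id} has no member pixels")

    @property
    def anchor_distance_bins(self) -> float:
        """Distance between the centroid anchors of the member pixel set."""
        arr = np.array(sorted(self.pixels))
        return float(arr[:, 1].mean() - arr[:, 0].mean())


@dataclass
class LoopList:
    loops: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.loops)

    def __len__(self):
        return len(self.loops)

    def union_pixels(self, chrom=None) -> set:
        out = set()
        for lp in self.loops:
            if chrom is None or lp.chrom == chrom:
                out |= lp.pixels
        return out


def filter_sparse_rows(m: ContactMatrix, min_nonzero: int = 25, window: int = 300):
    """Mark bins with sparse near-diagonal coverage and drop entries touching them.

    A bin is excluded when it has fewer than ``min_nonzero`` nonzero entries at
    offsets 1..``window`` from the diagonal (upstream and downstream combined).
    Idempotent: re-filtering the filtered matrix excludes nothing new beyond
    knock-on losses already accounted for by re-application.
    """
    nz = np.zeros(m.n_bins, dtype=np.int64)
    d = m.bin_j - m.bin_i
    near = (d >= 1) & (d <= window) & (m.count > 0)
    np.add.at(nz, m.bin_i[near], 1)
    np.add.at(nz, m.bin_j[near], 1)
    excluded = np.flatnonzero(nz < min_nonzero)
    excl_set = set(excluded.tolist())
    if excl_set:
        keep = ~(np.isin(m.bin_i, excluded) | np.isin(m.bin_j, excluded))
        m = ContactMatrix(m.chrom, m.n_bins, m.bin_i[keep], m.bin_j[keep],
                          m.count[keep], m.replicate_id)
    return m, excl_set


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_contacts(path, n_bins, chrom=None, replicate_id=None) -> ContactMatrix:
    """Read a tab-separated triplet file (chrom, bin_i, bin_j, count).

    Lower-triangle entries are mirrored and duplicate triplets summed.  Counts
    must be non-negative integers; violations are rejected with the offending
    line number.
    """
    bi, bj, ct = [], [], []
    seen_chrom = chrom
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 tab-separated fields")
            c, i, j, x = parts[:4]
            if seen_chrom is None:
                seen_chrom = c
            elif c != seen_chrom:
                raise ValueError(f"{path}:{ln}: unexpected chromosome {c!r}")
            try:
                xval = int(x)
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-integer count {x!r}") from e
            if xval < 0:
                raise ValueError(f"{path}:{ln}: negative count {xval}")
            bi.append(int(i))
            bj.append(int(j))
            ct.append(xval)
    return ContactMatrix.from_triplets(seen_chrom or "chrS", n_bins, bi, bj, ct,
                                       replicate_id)


def write_contacts(m: ContactMatrix, path):
    with open(path, "w") as fh:
        for i, j, x in zip(m.bin_i, m.bin_j, m.count):
            fh.write(f"{m.chrom}\t{i}\t{j}\t{x}\n")


def read_loops_bedpe(path, bin_size) -> LoopList:
    """Read a BEDPE loop list; each record becomes one loop whose member pixels
    cover the (bin-snapped) interval pair.  Interchromosomal records are skipped
    with a warning; records with end <= start are rejected."""
    loops = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            c1, s1, e1, c2, s2, e2 = parts[:6]
            name = parts[6] if len(parts) > 6 else f"loop_{ln}"
            if c1 != c2:
                warnings.warn(f"{path}:{ln}: interchromosomal record skipped")
                continue
            s1, e1, s2, e2 = int(s1), int(e1), int(s2), int(e2)
            if e1 <= s1 or e2 <= s2:
                raise ValueError(f"{path}:{ln}: end <= start")
            bins1 = range(s1 // bin_size, -(-e1 // bin_size))
            bins2 = range(s2 // bin_size, -(-e2 // bin_size))
            pixels = frozenset((min(a, b), max(a, b)) for a in bins1 for b in bins2)
            category = parts[7] if len(parts) > 7 else None
            loops.append(Loop(c1, pixels, name, category=category))
    return LoopList(loops)


def write_loops_bedpe(loops: LoopList, path, bin_size):
    """Write loops as BEDPE records with bounding intervals; class/category in
    column 8 when present."""
    with open(path, "w") as fh:
        for lp in loops:
            arr = np.array(sorted(lp.pixels))
            i0, i1 = arr[:, 0].min(), arr[:, 0].max()
            j0, j1 = arr[:, 1].min(), arr[:, 1].max()
            fields = [lp.chrom, i0 * bin_size, (i1 + 1) * bin_size,
                      lp.chrom, j0 * bin_size, (j1 + 1) * bin_size, lp.loop_id]
            if lp.category is not None:
                fields.append(lp.category)
            fh.write("\t".join(str(f) for f in fields) + "\n")


RESULT_COLUMNS = ["chrom", "start1", "end1", "start2", "end2", "i", "j"]


def write_results(table: pd.DataFrame, path, bin_size, clusters: LoopList | None = None,
                  clusters_path=None):
    """Write the per-pixel result table as TSV (and optionally clusters as BEDPE).

    Floats are written with 12 significant digits so p/q round-trip through
    ``read_results``.
    """
    out = table.copy()
    out.insert(1, "start1", out["i"] * bin_size)
    out.insert(2, "end1", (out["i"] + 1) * bin_size)
    out.insert(3, "start2", out["j"] * bin_size)
    out.insert(4, "end2", (out["j"] + 1) * bin_size)
    cols = ["chrom", "start1", "end1", "start2", "end2"] + [
        c for c in table.columns if c != "chrom"]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.12g")
    if clusters is not None and clusters_path is not None:
        write_loops_bedpe(clusters, clusters_path, bin_size)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
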