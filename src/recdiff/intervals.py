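"""Genomic containers, interval algebra, and file I/O.

Every module in the package works with the small set of containers defined
here: a :class:`GenomeLayout` (chromosome names and lengths), a
:class:`RecombinationMap` (piecewise-constant per-base per-generation rates),
a :class:`BinnedTrack` (fixed-width bins carrying one numeric value each), and
a :class:`RegionSet` (labelled half-open intervals, e.g. hotspots or outlier
windows).

Coordinate convention
---------------------
All coordinates are 0-based, half-open (BED convention).  VCF positions are
1-based on disk and converted on read/write; TSV/BED interval files are
written and read as-is.  Using a single internal convention removes an entire
class of off-by-one errors between the map, scan, and SV layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "MapFormatError",
    "GenomeLayout",
    "RecombinationMap",
    "BinnedTrack",
    "RegionSet",
    "read_recmap",
    "write_recmap",
    "read_linkage_map",
    "write_linkage_map",
    "bin_average",
    "linkage_to_track",
    "intersect",
    "overlap_flags",
    "merge_regions",
    "read_bed",
    "write_bed",
    "write_snp_vcf",
    "read_snp_vcf",
    "write_sv_vcf",
    "read_sv_vcf",
]


class MapFormatError(ValueError):
    """Raised when an interval file violates its format contract."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with lengths in bp.

    All downstream coordinates must fall within ``[0, length)``.  The layout
    also fixes chromosome identity for permutation tests that reposition
    intervals while keeping them on their original chromosome.
    """

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths", dict(self.lengths))
        if not self.lengths:
            raise ValueError("layout needs at least one chromosome")
        for name, length in self.lengths.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths.values()))

    def __getitem__(self, chrom: str) -> int:
        return int(self.lengths[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.lengths[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside [0, {self.lengths[chrom]})"
            )


_MAP_COLS = ["chrom", "start", "end", "rate"]


@dataclass
class RecombinationMap:
    """Per-chromosome sorted, non-overlapping intervals with a rate each.

    Rates are per-base, per-generation recombination rates (the output scale
    of LD-based estimators such as Pyrho).  ``population`` and ``subset``
    identify which replicate subset of which population the map came from.
    """

    df: pd.DataFrame
    population: str | None = None
    subset: str | int | None = None

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing = [c for c in _MAP_COLS if c not in df.columns]
        if missing:
            raise MapFormatError(f"map missing columns {missing}")
        df = df[_MAP_COLS].astype(
            {"chrom": str, "start": np.int64, "end": np.int64, "rate": float}
        )
        if (df["start"] >= df["end"]).any():
            raise MapFormatError("map interval with start >= end")
        if not np.isfinite(df["rate"]).all():
            raise ValueError("non-finite recombination rate")
        if (df["rate"] < 0).any():
            raise ValueError("negative recombination rate")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for _, sub in df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if len(s) > 1 and (s[1:] < e[:-1]).any():
                raise MapFormatError("overlapping intervals in recombination map")
        self.df = df

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))


@dataclass
class BinnedTrack:
    """Fixed-width genomic bins with one value per bin.

    Bins tile each chromosome from 0 in steps of ``width``; the final bin may
    be short at the chromosome end.  Missing values are explicit NaN.
    """

    df: pd.DataFrame  # chrom, start, end, value
    width: int

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        df = df.astype({"chrom": str, "start": np.int64, "end": np.int64, "value": float})
        self.df = df[["chrom", "start", "end", "value"]]

    def values_for(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "value"].to_numpy()

    def same_grid(self, other: "BinnedTrack") -> bool:
        if self.width != other.width or len(self.df) != len(other.df):
            return False
        return bool(
            (self.df["chrom"].to_numpy() == other.df["chrom"].to_numpy()).all()
            and (self.df["start"].to_numpy() == other.df["start"].to_numpy()).all()
        )


_REGION_COLS = ["chrom", "start", "end"]


@dataclass
class RegionSet:
    """Half-open labelled intervals (hotspots, outlier windows, ...).

    Regions may overlap unless the set is declared ``merged``.  Optional
    ``name`` and ``score`` columns carry labels (e.g. spot kind) and scores
    (e.g. peak z) into BED output.
    """

    df: pd.DataFrame
    merged: bool = False

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing = [c for c in _REGION_COLS if c not in df.columns]
        if missing:
            raise MapFormatError(f"region set missing columns {missing}")
        df = df.astype({"chrom": str, "start": np.int64, "end": np.int64})
        if (df["start"] >= df["end"]).any():
            raise MapFormatError("region with start >= end")
        self.df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )

    @property
    def n(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls) -> "RegionSet":
        return cls(pd.DataFrame({"chrom": pd.Series(dtype=str),
                                 "start": pd.Series(dtype=np.int64),
                                 "end": pd.Series(dtype=np.int64)}))

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple], columns: Sequence[str] = ("chrom", "start", "end")
    ) -> "RegionSet":
        return cls(pd.DataFrame(list(intervals), columns=list(columns)))


# ---------------------------------------------------------------------------
# TSV / BED readers and writers
# ---------------------------------------------------------------------------


def read_recmap(path, population=None, subset=None) -> RecombinationMap:
    """Read a (chrom, start, end, rate) TSV into a validated map.

    Extra columns beyond the first four are ignored; malformed rows raise
    :class:`MapFormatError`.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise MapFormatError(f"{path}: expected >= 4 tab-separated columns")
    df = df.iloc[:, :4]
    df.columns = _MAP_COLS
    try:
        df = df.astype({"start": np.int64, "end": np.int64, "rate": float})
    except (ValueError, TypeError) as exc:
        raise MapFormatError(f"{path}: malformed row ({exc})") from exc
    return RecombinationMap(df, population=population, subset=subset)


def write_recmap(rmap: RecombinationMap, path) -> None:
    rmap.df.to_csv(path, sep="\t", header=False, index=False)


def read_linkage_map(path) -> pd.DataFrame:
    """Read a pedigree/linkage map TSV (chrom, start, end, cM/Mb)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "cmmb"])
    df = df.astype({"chrom": str, "start": np.int64, "end": np.int64, "cmmb": float})
    if (df["cmmb"] < 0).any():
        raise ValueError("negative cM/Mb in linkage map")
    if (df["start"] >= df["end"]).any():
        raise MapFormatError("linkage window with start >= end")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_linkage_map(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "cmmb"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> RegionSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    names = ["chrom", "start", "end", "name", "score"][: df.shape[1]]
    df = df.iloc[:, : len(names)]
    df.columns = names
    df = df.astype({"start": np.int64, "end": np.int64})
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return RegionSet(df)


def write_bed(regions: RegionSet, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score"] if c in regions.df.columns]
    regions.df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def _bin_frame(df: pd.DataFrame, value_col: str, width: int,
               layout: GenomeLayout | None) -> pd.DataFrame:
    """Length-weighted mean of interval values over fixed-width bins.

    The mean is taken over covered bases only (bedtools ``map -o mean``
    semantics); bins with zero coverage get NaN.  The last bin of each
    chromosome may be short and is kept.
    """
    out = []
    chroms = layout.chroms if layout is not None else list(dict.fromkeys(df["chrom"]))
    for chrom in chroms:
        sub = df[df["chrom"] == chrom]
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        vals = sub[value_col].to_numpy(float)
        if layout is not None:
            span = layout[chrom]
            if len(ends) and ends.max() > span:
                raise ValueError(f"interval beyond chromosome end on {chrom}")
        else:
            if not len(ends):
                continue
            span = int(ends.max())
        n_bins = math.ceil(span / width)
        bin_starts = np.arange(n_bins, dtype=np.int64) * width
        bin_ends = np.minimum(bin_starts + width, span)
        sums = np.zeros(n_bins)
        lens = np.zeros(n_bins)
        if len(starts):
            cuts = np.unique(np.concatenate([bin_starts, bin_ends, starts, ends]))
            cuts = cuts[(cuts >= 0) & (cuts <= span)]
            seg_start = cuts[:-1]
            seg_len = np.diff(cuts)
            idx = np.searchsorted(starts, seg_start, side="right") - 1
            covered = (idx >= 0) & (seg_start < ends[np.clip(idx, 0, None)])
            bin_id = seg_start // width
            np.add.at(sums, bin_id[covered],
                      vals[idx[covered]] * seg_len[covered])
            np.add.at(lens, bin_id[covered], seg_len[covered])
        value = np.full(n_bins, np.nan)
        np.divide(sums, lens, out=value, where=lens > 0)
        out.append(pd.DataFrame({"chrom": chrom, "start": bin_starts,
                                 "end": bin_ends, "value": value}))
    if not out:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64),
                             "value": pd.Series(dtype=float)})
    return pd.concat(out, ignore_index=True)


def bin_average(rmap: RecombinationMap, width: int,
                layout: GenomeLayout | None = None) -> BinnedTrack:
    """Average a recombination map into non-overlapping fixed-width bins."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    return BinnedTrack(_bin_frame(rmap.df, "rate", width, layout), width)


def linkage_to_track(linkage: pd.DataFrame, width: int,
                     layout: GenomeLayout | None = None) -> BinnedTrack:
    """Project a linkage map (cM/Mb windows) onto a fixed-width bin grid."""
    return BinnedTrack(_bin_frame(linkage, "cmmb", width, layout), width)


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def overlap_flags(a: RegionSet, b: RegionSet) -> np.ndarray:
    """For each region of ``a`` (in a.df order): does it overlap any region of b?

    Overlap requires at least one shared base under half-open coordinates.
    """
    flags = np.zeros(a.n, dtype=bool)
    for chrom, sub_b in b.df.groupby("chrom", sort=False):
        sel = a.df["chrom"] == chrom
        if not sel.any():
            continue
        bs = np.sort(sub_b["start"].to_numpy(np.int64))
        be = np.sort(sub_b["end"].to_numpy(np.int64))
        a_start = a.df.loc[sel, "start"].to_numpy(np.int64)
        a_end = a.df.loc[sel, "end"].to_numpy(np.int64)
        # count of b with b.start < a.end  minus  count of b with b.end <= a.start
        n_lt = np.searchsorted(bs, a_end, side="left")
        n_le = np.searchsorted(be, a_start, side="right")
        flags[np.flatnonzero(sel.to_numpy())] = n_lt > n_le
    return flags


def intersect(a: RegionSet, b: RegionSet) -> tuple[pd.DataFrame, np.ndarray]:
    """All overlapping region pairs plus per-``a``-region overlap flags."""
    pairs = []
    for chrom, sub_a in a.df.groupby("chrom", sort=False):
        sub_b = b.df[b.df["chrom"] == chrom]
        if sub_b.empty:
            continue
        bs = sub_b["start"].to_numpy(np.int64)
        be = sub_b["end"].to_numpy(np.int64)
        for ia, (s, e) in zip(sub_a.index, zip(sub_a["start"], sub_a["end"])):
            hit = np.flatnonzero((bs < e) & (be > s))
            for ib in hit:
                pairs.append((chrom, s, e, int(bs[ib]), int(be[ib]), ia,
                              int(sub_b.index[ib])))
    pairs_df = pd.DataFrame(
        pairs,
        columns=["chrom", "a_start", "a_end", "b_start", "b_end", "a_index", "b_index"],
    )
    return pairs_df, overlap_flags(a, b)


def merge_regions(a: RegionSet, max_gap: int = 0) -> RegionSet:
    """Union regions on the same chromosome whose gap is <= ``max_gap`` bp.

    Output is sorted and non-overlapping; idempotent.  Extra columns are
    dropped (a merged region no longer has a single label).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    rows = []
    for chrom, sub in a.df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= max_gap:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    if not rows:
        out = RegionSet.empty()
        out.merged = True
        return out
    return RegionSet(pd.DataFrame(rows, columns=_REGION_COLS), merged=True)


# ---------------------------------------------------------------------------
# VCF I/O (pysam)
# ---------------------------------------------------------------------------


def _vcf_header(layout: GenomeLayout, samples: Sequence[str],
                sv: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in layout.chroms:
        header.contigs.add(chrom, length=layout[chrom])
    header.formats.add("GT", 1, "String", "Genotype")
    if sv:
        header.info.add("SVTYPE", 1, "String", "Type of structural variant")
        header.info.add("SVLEN", 1, "Integer", "Length of structural variant")
        header.info.add("END", 1, "Integer", "End position on the reference")
    for s in samples:
        header.add_sample(s)
    return header


def _set_gt(record, samples, genotypes) -> None:
    for sample, g in zip(samples, genotypes):
        if g < 0:
            record.samples[sample]["GT"] = (None, None)
        else:
            record.samples[sample]["GT"] = (0, 1) if g == 1 else ((0, 0) if g == 0 else (1, 1))


def write_snp_vcf(path, layout: GenomeLayout, snp_df: pd.DataFrame,
                  genotypes: np.ndarray, samples: Sequence[str]) -> None:
    """Write biallelic SNPs with GT calls to an uncompressed VCF 4.2 file.

    ``snp_df`` needs ``chrom`` and 0-based ``pos`` columns, one row per site;
    ``genotypes`` is sites x samples with alt-allele dosages 0/1/2 and -1 for
    missing.
    """
    header = _vcf_header(layout, samples, sv=False)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, row in enumerate(snp_df.itertuples(index=False)):
            rec = vcf.new_record(contig=row.chrom, start=int(row.pos),
                                 stop=int(row.pos) + 1, alleles=("A", "T"))
            _set_gt(rec, samples, genotypes[i])
            vcf.write(rec)


def read_snp_vcf(path) -> tuple[GenomeLayout, pd.DataFrame, np.ndarray, list[str]]:
    """Read a biallelic SNP VCF: (layout, site table, dosage matrix, samples)."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        lengths = {c: vcf.header.contigs[c].length for c in vcf.header.contigs}
        rows, geno = [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            rows.append((rec.contig, rec.start))
            g = np.full(len(samples), -1, dtype=np.int8)
            for j, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is not None and None not in gt:
                    g[j] = sum(gt)
            geno.append(g)
    layout = GenomeLayout(lengths)
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    G = np.array(geno, dtype=np.int8) if geno else np.zeros((0, len(samples)), np.int8)
    return layout, df, G, samples


_SV_ALT = {"DEL": "<DEL>", "INS": "<INS>", "INV": "<INV>"}


def sv_ref_span(svtype: str, pos: int, length: int) -> tuple[int, int]:
    """Reference span occupied by an SV (half-open).

    Deletions and inversions occupy ``[pos, pos + length)`` on the reference;
    insertions are anchored at ``pos`` with a 1 bp reference span because the
    inserted sequence is absent from the reference.
    """
    if svtype in ("DEL", "INV"):
        return pos, pos + length
    return pos, pos + 1


def write_sv_vcf(path, layout: GenomeLayout, sv_df: pd.DataFrame,
                 genotypes: np.ndarray | None = None,
                 samples: Sequence[str] | None = None) -> None:
    """Write an SV catalogue (SVTYPE/SVLEN/END INFO keys) to VCF 4.2.

    ``sv_df`` needs chrom, 0-based pos, svtype in {DEL, INS, INV}, length.
    """
    samples = list(samples) if samples is not None else []
    header = _vcf_header(layout, samples, sv=True)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, row in enumerate(sv_df.itertuples(index=False)):
            if row.svtype not in _SV_ALT:
                raise ValueError(f"unknown SVTYPE {row.svtype!r}")
            _, end = sv_ref_span(row.svtype, int(row.pos), int(row.length))
            rec = vcf.new_record(contig=row.chrom, start=int(row.pos), stop=end,
                                 alleles=("N", _SV_ALT[row.svtype]))
            rec.info["SVTYPE"] = row.svtype
            rec.info["SVLEN"] = int(row.length)
            rec.stop = end  # pysam writes the reserved END INFO key from stop
            if genotypes is not None:
                _set_gt(rec, samples, genotypes[i])
            vcf.write(rec)


def read_sv_vcf(path) -> tuple[GenomeLayout, pd.DataFrame, np.ndarray, list[str]]:
    """Read an SV VCF; records with unknown SVTYPE are rejected with a warning."""
    import warnings

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        lengths = {c: vcf.header.contigs[c].length for c in vcf.header.contigs}
        rows, geno = [], []
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype not in _SV_ALT:
                warnings.warn(f"rejecting record at {rec.contig}:{rec.pos} "
                              f"with SVTYPE={svtype!r}")
                continue
            rows.append((rec.contig, rec.start, svtype, abs(int(rec.info["SVLEN"]))))
            g = np.full(len(samples), -1, dtype=np.int8)
            for j, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is not None and None not in gt:
                    g[j] = sum(gt)
            geno.append(g)
    layout = GenomeLayout(lengths)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "svtype", "length"])
    G = np.array(geno, dtype=np.int8) if geno else np.zeros((0, len(samples)), np.int8)
    return layout, df, G, samples
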