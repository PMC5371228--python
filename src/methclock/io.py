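"""Reading and writing the text formats the pipeline touches.

Formats handled:

* bismark-style coverage files — six tab-separated columns
  ``chrom  start  end  methylation_pct  count_meth  count_unmeth``; treated
  as 1-based on disk and shifted to the internal 0-based convention on
  read.  Counts are authoritative; the percentage column is validated
  (within 0.5 percentage points) but never used numerically.  Multiple
  records for one site (several sequencing runs of a sample) are collapsed
  by summing reads.
* BED3/BED6 interval files for region annotations (half-open, 0-based).
* TSV sample metadata and TSV fraction-matrix export (``NA`` for missing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import (
    MethylationMatrix,
    normalize_chrom,
    site_id,
    sort_site_ids,
    validate_meta,
)

REGION_LABELS = frozenset(
    {
        "TSS/promoter",
        "5'UTR",
        "body",
        "exon",
        "intron",
        "intergenic",
        "shelf",
        "island",
        "shore",
        "enhancer",
        "bivalent",
        "H3K27me3",
        "H3K9ac",
        "H3K27ac",
        "H3K4me1",
        "H3K4me3",
        "H3K36me3",
        "DNase",
        "promoter",
    }
)


# ----------------------------------------------------------------------
# coverage files
# ----------------------------------------------------------------------

def read_coverage_file(path: str | Path, assume_one_based: bool = True) -> pd.DataFrame:
    """Parse one sample's coverage file into per-site count records.

    Returns a DataFrame indexed by site id with columns ``chrom``, ``pos``
    (0-based), ``meth`` and ``unmeth``; duplicate site records are merged
    by summing reads.  Malformed lines raise with the offending line
    number.
    """
    path = Path(path)
    records: dict[str, list] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path.name}:{lineno}: expected 6 tab-separated columns")
            chrom_raw, start_s, _end, pct_s, meth_s, unmeth_s = parts[:6]
            try:
                start = int(start_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
                pct = float(pct_s)
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed numeric field ({exc})") from None
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path.name}:{lineno}: negative read count")
            pos = start - 1 if assume_one_based else start
            if pos < 0:
                raise ValueError(f"{path.name}:{lineno}: negative position after conversion")
            total = meth + unmeth
            if total > 0:
                frac_pct = 100.0 * meth / total
                if abs(frac_pct - pct) > 0.5:
                    raise ValueError(
                        f"{path.name}:{lineno}: percentage column {pct} disagrees with "
                        f"counts ({frac_pct:.2f}) by more than 0.5 points"
                    )
            chrom = normalize_chrom(chrom_raw)
            sid = site_id(chrom, pos)
            if sid in records:
                rec = records[sid]
                rec[2] += meth
                rec[3] += unmeth
            else:
                records[sid] = [chrom, pos, meth, unmeth]
    df = pd.DataFrame.from_dict(
        records, orient="index", columns=["chrom", "pos", "meth", "unmeth"]
    )
    df.index.name = "site"
    return df


def write_coverage_file(path: str | Path, matrix: MethylationMatrix, sample: str) -> None:
    """Write one sample's counts as a 1-based coverage file (missing cells skipped)."""
    meth = matrix.meth.loc[sample]
    unmeth = matrix.unmeth.loc[sample]
    sites = matrix.sites
    with open(path, "w") as fh:
        for sid in matrix.site_ids:
            m, u = int(meth[sid]), int(unmeth[sid])
            if m + u == 0:
                continue
            chrom, pos = sites.loc[sid, "chrom"], int(sites.loc[sid, "pos"])
            pct = 100.0 * m / (m + u)
            fh.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{pct:.6g}\t{m}\t{u}\n")


def assemble_matrix(
    records: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Combine per-sample coverage records into a counts matrix.

    The site set is the union across samples (cells absent in a sample are
    missing, i.e. zero depth), ordered by (chrom, pos).  Metadata rows
    without data are dropped with a warning; data without metadata is an
    error.
    """
    if len(records) == 0:
        raise ValueError("no coverage records supplied")
    sample_ids = list(records)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in records")
    all_sites = sort_site_ids(set().union(*(set(df.index) for df in records.values())))
    meth = pd.DataFrame(0, index=sample_ids, columns=all_sites, dtype=int)
    unmeth = pd.DataFrame(0, index=sample_ids, columns=all_sites, dtype=int)
    for sample, df in records.items():
        meth.loc[sample, df.index] = df["meth"].to_numpy()
        unmeth.loc[sample, df.index] = df["unmeth"].to_numpy()
    meth.index.name = unmeth.index.name = "sample_id"

    meta = validate_meta(metadata)
    extra = [s for s in meta.index if s not in set(sample_ids)]
    if extra:
        warnings.warn(f"metadata rows without coverage data dropped: {extra}")
        meta = meta.drop(index=extra)
    meta = validate_meta(meta, samples=sample_ids)
    return MethylationMatrix(meth, unmeth), meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    return validate_meta(meta)


def write_metadata(path: str | Path, meta: pd.DataFrame) -> None:
    meta.reset_index().to_csv(path, sep="\t", index=False)


def write_fraction_matrix(path: str | Path, fractions: pd.DataFrame) -> None:
    """Export a samples x sites fraction table as TSV with ``NA`` for missing."""
    fractions.to_csv(path, sep="\t", na_rep="NA")


def read_fraction_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_cohort(
    directory: str | Path, matrix: MethylationMatrix, meta: pd.DataFrame
) -> None:
    """Write a cohort as per-sample coverage files plus a metadata TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sample in matrix.samples:
        write_coverage_file(directory / f"{sample}.cov", matrix, sample)
    write_metadata(directory / "metadata.tsv", meta)


def read_cohort(directory: str | Path) -> tuple[MethylationMatrix, pd.DataFrame]:
    directory = Path(directory)
    meta = read_metadata(directory / "metadata.tsv")
    records = {
        p.stem: read_coverage_file(p) for p in sorted(directory.glob("*.cov"))
    }
    return assemble_matrix(records, meta)


# ----------------------------------------------------------------------
# BED intervals and region annotation
# ----------------------------------------------------------------------

@dataclass
class IntervalSet:
    """Half-open 0-based intervals grouped per chromosome, kept merged."""

    by_chrom: dict[str, np.ndarray] = field(default_factory=dict)  # (k, 2) arrays

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            if end <= start:
                continue
            grouped.setdefault(normalize_chrom(chrom), []).append((int(start), int(end)))
        out = {}
        for chrom, ivals in grouped.items():
            out[chrom] = _merge(np.array(sorted(ivals), dtype=np.int64))
        return cls(out)

    def contains(self, chrom: str, pos: int) -> bool:
        ivals = self.by_chrom.get(normalize_chrom(chrom))
        if ivals is None or len(ivals) == 0:
            return False
        i = np.searchsorted(ivals[:, 0], pos, side="right") - 1
        return i >= 0 and pos < ivals[i, 1]

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for chrom in set(self.by_chrom) & set(other.by_chrom):
            merged = _intersect_arrays(self.by_chrom[chrom], other.by_chrom[chrom])
            if len(merged):
                out[chrom] = merged
        return IntervalSet(out)


def _merge(ivals: np.ndarray) -> np.ndarray:
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6; returns chrom, start, end (+ name, score, strand if present)."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{Path(path).name}:{lineno}: BED needs >= 3 columns")
            row = {
                "chrom": normalize_chrom(parts[0]),
                "start": int(parts[1]),
                "end": int(parts[2]),
            }
            if len(parts) >= 6:
                row["name"], row["score"], row["strand"] = parts[3], parts[4], parts[5]
            rows.append(row)
    return pd.DataFrame(rows)


def promoter_intervals(genes: pd.DataFrame, upstream: int = 2000) -> IntervalSet:
    """Strand-aware promoter windows upstream of protein-coding gene starts.

    ``genes`` is a BED6-style table; for ``+`` genes the window is
    ``[start - upstream, start)``, for ``-`` genes ``[end, end + upstream)``.
    """
    records = []
    for _, g in genes.iterrows():
        strand = g.get("strand", "+")
        if strand == "-":
            records.append((g["chrom"], int(g["end"]), int(g["end"]) + upstream))
        else:
            records.append((g["chrom"], max(0, int(g["start"]) - upstream), int(g["start"])))
    return IntervalSet.from_records(records)


def annotate_sites(
    sites: pd.DataFrame,
    tracks: Mapping[str, IntervalSet],
    genes: pd.DataFrame | None = None,
    promoter_upstream: int = 2000,
) -> pd.DataFrame:
    """Assign region labels to sites by interval membership.

    ``tracks`` maps label -> intervals.  Derived labels: ``enhancer`` =
    H3K27ac intersect H3K4me1; ``bivalent`` = H3K4me3 intersect H3K27me3;
    ``promoter`` = strand-aware 2 kb windows upstream of the gene starts in
    ``genes``.  A site may carry several labels.  Returns a boolean
    DataFrame (sites x labels).
    """
    unknown = set(tracks) - REGION_LABELS
    if unknown:
        raise ValueError(f"unknown region labels: {sorted(unknown)}")
    tracks = dict(tracks)
    if "H3K27ac" in tracks and "H3K4me1" in tracks and "enhancer" not in tracks:
        tracks["enhancer"] = tracks["H3K27ac"].intersect(tracks["H3K4me1"])
    if "H3K4me3" in tracks and "H3K27me3" in tracks and "bivalent" not in tracks:
        tracks["bivalent"] = tracks["H3K4me3"].intersect(tracks["H3K27me3"])
    if genes is not None:
        tracks["promoter"] = promoter_intervals(genes, upstream=promoter_upstream)

    out = pd.DataFrame(False, index=sites.index, columns=sorted(tracks))
    for label, iset in tracks.items():
        out[label] = [
            iset.contains(c, p) for c, p in zip(sites["chrom"], sites["pos"])
        ]
    return out
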