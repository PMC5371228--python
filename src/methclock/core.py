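"""Core containers shared across the pipeline.

The central object is :class:`MethylationMatrix`: a samples x CpG-sites
count matrix (methylated / unmethylated read counts) with a derived
methylation-fraction view.  Sites are keyed by ``"chrom:pos"`` strings with
0-based positions and chromosome labels normalized by stripping a leading
``chr``.  A cell is *missing* when its total read depth is zero (dropout in
sparse bisulfite data); imputation (see :mod:`methclock.filters`) stores an
explicit fraction table on top of the counts.

Sample metadata travels as a plain :class:`pandas.DataFrame` indexed by
sample id with columns ``age_days``, ``sex``, ``strain``, ``treatment`` and
``study`` (the batch label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ("age_days", "sex", "strain", "treatment", "study")

TREATMENTS = ("none", "dwarf", "calorie_restriction", "rapamycin")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so mm9/mm10/hg19 labels agree."""
    chrom = str(chrom)
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def site_id(chrom: str, pos: int) -> str:
    return f"{normalize_chrom(chrom)}:{int(pos)}"


def parse_site_id(sid: str) -> tuple[str, int]:
    chrom, _, pos = sid.rpartition(":")
    return chrom, int(pos)


def chrom_sort_key(chrom: str) -> tuple[int, float, str]:
    """Numeric chromosomes first in numeric order, then others lexically."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (0, int(c), "")
    return (1, np.inf, c)


def sort_site_ids(site_ids: Iterable[str]) -> list[str]:
    return sorted(site_ids, key=lambda s: (*chrom_sort_key(parse_site_id(s)[0]), parse_site_id(s)[1]))


def sites_frame(site_ids: Sequence[str]) -> pd.DataFrame:
    """Decode ``chrom:pos`` ids into a (chrom, pos) table indexed by id."""
    parsed = [parse_site_id(s) for s in site_ids]
    return pd.DataFrame(
        {"chrom": [c for c, _ in parsed], "pos": [p for _, p in parsed]},
        index=pd.Index(site_ids, name="site"),
    )


@dataclass
class MethylationMatrix:
    """Per-(sample, site) methylation read counts with a fraction view.

    Parameters
    ----------
    meth, unmeth
        Integer DataFrames (samples x sites) of methylated and
        unmethylated read counts.  Must share index and columns.
    imputed_fractions
        Optional fraction table replacing the count-derived fractions
        (set by the imputation step of the filtering profiles).  When
        present it must be complete (no missing cells).
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    imputed_fractions: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index) or not self.meth.columns.equals(
            self.unmeth.columns
        ):
            raise ValueError("meth and unmeth matrices must share samples and sites")
        if (self.meth.to_numpy() < 0).any() or (self.unmeth.to_numpy() < 0).any():
            raise ValueError("read counts must be nonnegative")
        if self.meth.index.has_duplicates:
            dups = self.meth.index[self.meth.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.imputed_fractions is not None:
            if not self.imputed_fractions.index.equals(self.meth.index) or not (
                self.imputed_fractions.columns.equals(self.meth.columns)
            ):
                raise ValueError("imputed fractions must match the count matrices")

    # ------------------------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.meth.index

    @property
    def site_ids(self) -> pd.Index:
        return self.meth.columns

    @property
    def sites(self) -> pd.DataFrame:
        return sites_frame(list(self.meth.columns))

    @property
    def depth(self) -> pd.DataFrame:
        return self.meth + self.unmeth

    @property
    def fraction(self) -> pd.DataFrame:
        """Methylation fraction; NaN where depth is zero, unless imputed."""
        if self.imputed_fractions is not None:
            return self.imputed_fractions
        depth = self.depth
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.meth / depth
        return frac.where(depth > 0)

    @property
    def missing(self) -> pd.DataFrame:
        return self.depth == 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.meth.shape

    # ------------------------------------------------------------------
    def sorted_sites(self) -> "MethylationMatrix":
        order = sort_site_ids(list(self.meth.columns))
        return self.subset(sites=order)

    def subset(
        self,
        samples: Sequence[str] | None = None,
        sites: Sequence[str] | None = None,
    ) -> "MethylationMatrix":
        meth, unmeth = self.meth, self.unmeth
        imp = self.imputed_fractions
        if samples is not None:
            meth, unmeth = meth.loc[list(samples)], unmeth.loc[list(samples)]
            imp = imp.loc[list(samples)] if imp is not None else None
        if sites is not None:
            meth, unmeth = meth[list(sites)], unmeth[list(sites)]
            imp = imp[list(sites)] if imp is not None else None
        return MethylationMatrix(meth, unmeth, imp)

    def observed(self, min_reads: int = 1) -> pd.DataFrame:
        """Boolean table: cell counts as observed at the given depth floor."""
        return self.depth >= min_reads


def validate_meta(meta: pd.DataFrame, samples: Iterable[str] | None = None) -> pd.DataFrame:
    """Check a metadata table and align it to a sample list.

    Every sample must have exactly one metadata row with a positive age.
    """
    if meta.index.name != "sample_id" and "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing columns: {missing_cols}")
    if (meta["age_days"] <= 0).any():
        bad = meta.index[meta["age_days"] <= 0].tolist()
        raise ValueError(f"non-positive age_days for samples: {bad}")
    if samples is not None:
        samples = list(samples)
        absent = [s for s in samples if s not in meta.index]
        if absent:
            raise ValueError(f"samples without metadata: {absent}")
        meta = meta.loc[samples]
    return meta


DAYS_PER_MONTH = 365.25 / 12.0
"""Month length used for every days<->months conversion (365.25 / 12)."""


def days_to_months(days):
    return np.asarray(days, dtype=float) / DAYS_PER_MONTH


def months_to_days(months):
    return np.asarray(months, dtype=float) * DAYS_PER_MONTH
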