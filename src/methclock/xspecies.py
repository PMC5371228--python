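"""Cross-species ortholog mapping, region enrichment and overlap testing.

Mouse CpG sites are lifted to the other genome through a precomputed
coordinate-mapping table (the output of a liftOver-style tool, consumed as
TSV) and intersected with an array-probe manifest.  Mouse sites landing on
the same probe are collapsed by averaging their methylation fractions.
Enrichment of age-associated sites in genomic regions uses one marginal
2x2 Fisher exact test per region; cross-species overlap of age-site sets
is scored with an upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MethylationMatrix, normalize_chrom, site_id

logger = logging.getLogger(__name__)


@dataclass
class OrthologMap:
    """Mouse site -> array probe assignment after coordinate lifting.

    ``table`` has one row per mapped mouse site with columns
    ``mouse_site``, ``probe_id``, ``dst_chrom``, ``dst_pos``.  Groups of
    mouse sites sharing a probe are collapsed downstream by averaging.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table["mouse_site"].duplicated().any():
            raise ValueError("a mouse site maps to more than one probe after collapse")

    @property
    def groups(self) -> pd.core.groupby.generic.DataFrameGroupBy:
        return self.table.groupby("probe_id", sort=True)

    @property
    def probe_ids(self) -> list[str]:
        return sorted(self.table["probe_id"].unique())


def build_ortholog_space(
    mouse_sites: pd.DataFrame,
    mapping_table: pd.DataFrame,
    probe_manifest: pd.DataFrame,
    slop: int = 0,
) -> OrthologMap:
    """Intersect lifted mouse coordinates with array-probe coordinates.

    ``mapping_table``: chrom_src, pos_src, chrom_dst, pos_dst;
    ``probe_manifest``: probe_id, chrom, pos.  A lifted site matches a
    probe when it lands within ``slop`` bases of the probe coordinate
    (default exact).  Sites without a lift record or probe hit are
    excluded and logged.
    """
    mapping = mapping_table.copy()
    mapping["chrom_src"] = mapping["chrom_src"].map(normalize_chrom)
    mapping["chrom_dst"] = mapping["chrom_dst"].map(normalize_chrom)
    mapping["mouse_site"] = [
        site_id(c, p) for c, p in zip(mapping["chrom_src"], mapping["pos_src"])
    ]
    wanted = {site_id(c, p) for c, p in zip(mouse_sites["chrom"], mouse_sites["pos"])}
    mapping = mapping[mapping["mouse_site"].isin(wanted)]
    unlifted = len(wanted) - mapping["mouse_site"].nunique()
    if unlifted:
        logger.info("%d mouse sites without a lift record excluded", unlifted)

    manifest = probe_manifest.copy()
    manifest["chrom"] = manifest["chrom"].map(normalize_chrom)

    rows = []
    by_chrom = {c: g.sort_values("pos") for c, g in manifest.groupby("chrom")}
    for _, rec in mapping.iterrows():
        probes = by_chrom.get(rec["chrom_dst"])
        if probes is None:
            continue
        pos = rec["pos_dst"]
        lo = np.searchsorted(probes["pos"].to_numpy(), pos - slop, side="left")
        hi = np.searchsorted(probes["pos"].to_numpy(), pos + slop, side="right")
        if hi > lo:
            # nearest probe within the slop window (exact match when slop=0)
            cand = probes.iloc[lo:hi]
            best = cand.iloc[(cand["pos"] - pos).abs().argmin()]
            rows.append(
                {
                    "mouse_site": rec["mouse_site"],
                    "probe_id": best["probe_id"],
                    "dst_chrom": rec["chrom_dst"],
                    "dst_pos": int(rec["pos_dst"]),
                }
            )
    if not rows:
        raise ValueError("empty intersection between lifted sites and probe manifest")
    table = pd.DataFrame(rows)
    dropped = mapping["mouse_site"].nunique() - len(table)
    if dropped:
        logger.info("%d lifted sites without a probe hit excluded", dropped)
    return OrthologMap(table)


def collapse_to_probes(matrix: MethylationMatrix | pd.DataFrame, ortho: OrthologMap) -> pd.DataFrame:
    """Average each probe group's nonmissing mouse-site fractions per sample.

    Accepts a count matrix or a plain fraction DataFrame; a probe value is
    missing only when every group member is missing.
    """
    frac = matrix.fraction if isinstance(matrix, MethylationMatrix) else matrix
    out = {}
    for probe_id, grp in ortho.groups:
        members = [s for s in grp["mouse_site"] if s in frac.columns]
        if not members:
            continue
        out[probe_id] = frac[members].mean(axis=1)  # skips NaN per row
    return pd.DataFrame(out, index=frac.index)


def fisher_enrichment(table: np.ndarray) -> tuple[float, float]:
    """Odds ratio (a*d)/(b*c) and two-sided Fisher exact p for a 2x2 table.

    A zero margin leaves the OR undefined (NaN) with p = 1.
    """
    a, b, c, d = np.asarray(table, dtype=float).ravel()
    if min(a + b, c + d, a + c, b + d) == 0:
        return float("nan"), 1.0
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def region_enrichment(
    age_flags: pd.Series,
    annotation: pd.DataFrame,
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """Marginal per-region 2x2 enrichment of age-associated sites.

    For each region the table is (age-associated vs not) x (in-region vs
    not-in-region for that region alone), so a multi-label site counts
    once per test.  Returns a DataFrame with a, b, c, d, odds_ratio and
    Fisher p per region, where a = age-associated sites in the region.
    """
    if regions is None:
        regions = list(annotation.columns)
    missing = [r for r in regions if r not in annotation.columns]
    if missing:
        raise ValueError(f"regions without annotation: {missing}")
    flags = age_flags.reindex(annotation.index)
    if flags.isna().any():
        raise ValueError("age_flags and annotation cover different site sets")
    flags = flags.astype(bool)
    rows = []
    for region in regions:
        in_region = annotation[region].astype(bool)
        a = int((flags & in_region).sum())
        b = int((flags & ~in_region).sum())
        c = int((~flags & in_region).sum())
        d = int((~flags & ~in_region).sum())
        odds, p = fisher_enrichment([a, b, c, d])
        rows.append({"region": region, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    return pd.DataFrame(rows).set_index("region")


def overlap_test(n_universe: int, n_set_a: int, n_set_b: int, n_overlap: int) -> float:
    """Upper-tail hypergeometric probability of seeing >= n_overlap shared sites.

    X ~ Hypergeom(N=n_universe, K=n_set_a, n=n_set_b); returns P(X >= n_overlap).
    """
    if not (0 <= n_overlap <= min(n_set_a, n_set_b) <= n_universe):
        raise ValueError("inconsistent overlap counts")
    if max(n_set_a, n_set_b) > n_universe:
        raise ValueError("set larger than universe")
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_set_a, n_set_b))
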