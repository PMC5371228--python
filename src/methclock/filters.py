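"""Site/sample filtering and imputation profiles for bisulfite matrices.

Three profiles are used at different stages of the analysis:

* **cross-species** — pooled RRBS studies: a cell is observed at >= 5
  reads, sites must be < 20% missing across all pooled samples and map
  uniquely to autosomes 1-19; samples missing > 40% of the surviving
  sites are then dropped.
* **clock** — the training matrix: observed at >= 2 reads, site present
  in >= 97% of samples, autosomes 1-19, standard deviation of observed
  fractions > 0 and <= 0.20; samples missing > 30% of kept sites dropped.
* **relaxed projection** — single-time-point or treated cohorts projected
  onto the clock's site set: any site with >= 1 read counts as observed.

All profiles end with site-mean imputation of the remaining missing cells
(the mean is taken over the profile's observed cells, after sample
removal), so the emitted matrix is complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core import MethylationMatrix

AUTOSOMES = frozenset(str(c) for c in range(1, 20))


@dataclass
class FilterProfile:
    """Thresholds of one filtering profile; fractions are in [0, 1]."""

    min_reads: int
    max_site_missing: float | None = None  # site removed if missing frac >= this... see rule
    min_sample_presence: float | None = None  # site kept if present in >= this frac of samples
    chrom_whitelist: frozenset[str] = AUTOSOMES
    sd_min: float | None = None  # exclusive lower bound
    sd_max: float | None = None  # inclusive upper bound
    max_sample_missing: float = 1.0  # sample removed if missing frac > this

    def __post_init__(self) -> None:
        for name in ("max_site_missing", "min_sample_presence", "max_sample_missing"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def load_profile(path) -> FilterProfile:
    """Read threshold overrides from a YAML mapping of FilterProfile fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "chrom_whitelist" in raw:
        raw["chrom_whitelist"] = frozenset(str(c) for c in raw["chrom_whitelist"])
    return FilterProfile(**raw)


CROSS_SPECIES_PROFILE = FilterProfile(
    min_reads=5, max_site_missing=0.20, max_sample_missing=0.40
)
CLOCK_PROFILE = FilterProfile(
    min_reads=2, min_sample_presence=0.97, sd_min=0.0, sd_max=0.20, max_sample_missing=0.30
)


@dataclass
class FilterReport:
    """Bookkeeping of one filtering pass; counts reconcile exactly."""

    sites_in: int
    samples_in: int
    sites_out: int = 0
    samples_out: int = 0
    site_removals: dict[str, int] = field(default_factory=dict)
    sample_removals: dict[str, int] = field(default_factory=dict)
    imputed_cells: int = 0

    def check_conservation(self) -> None:
        assert self.sites_out + sum(self.site_removals.values()) == self.sites_in
        assert self.samples_out + sum(self.sample_removals.values()) == self.samples_in


def _apply_profile(
    matrix: MethylationMatrix, profile: FilterProfile
) -> tuple[MethylationMatrix, FilterReport]:
    report = FilterReport(sites_in=matrix.shape[1], samples_in=matrix.shape[0])
    sites = matrix.sites
    keep = pd.Series(True, index=matrix.site_ids)

    # rule 1: unique mapping onto whitelisted chromosomes
    dup = sites.duplicated(subset=["chrom", "pos"], keep=False)
    bad_chrom = ~sites["chrom"].isin(profile.chrom_whitelist)
    removed = (dup | bad_chrom) & keep
    report.site_removals["chromosome_or_duplicate"] = int(removed.sum())
    keep &= ~removed

    observed = matrix.observed(profile.min_reads)

    # rule 2: per-site presence across samples
    presence = observed.mean(axis=0)
    if profile.max_site_missing is not None:
        fail = (1.0 - presence) >= profile.max_site_missing  # keep iff missing < threshold
        removed = fail & keep
        report.site_removals["missingness"] = int(removed.sum())
        keep &= ~removed
    if profile.min_sample_presence is not None:
        fail = presence < profile.min_sample_presence
        removed = fail & keep
        report.site_removals["presence"] = int(removed.sum())
        keep &= ~removed

    # rule 3: standard deviation of observed fractions (n-1 denominator)
    if profile.sd_min is not None or profile.sd_max is not None:
        frac = matrix.fraction.where(observed)
        sd = frac.std(axis=0, ddof=1).fillna(0.0)
        fail = pd.Series(False, index=keep.index)
        if profile.sd_min is not None:
            fail |= sd <= profile.sd_min
        if profile.sd_max is not None:
            fail |= sd > profile.sd_max
        removed = fail & keep
        report.site_removals["stdev"] = int(removed.sum())
        keep &= ~removed

    kept_sites = list(keep.index[keep])
    if not kept_sites:
        raise ValueError(f"all sites removed by filtering: {report}")

    # rule 4: sample removal on the kept sites
    sample_missing = 1.0 - observed[kept_sites].mean(axis=1)
    drop_samples = sample_missing > profile.max_sample_missing
    report.sample_removals["missingness"] = int(drop_samples.sum())
    kept_samples = list(drop_samples.index[~drop_samples])
    if not kept_samples:
        raise ValueError("all samples removed by filtering")

    sub = matrix.subset(samples=kept_samples, sites=kept_sites)
    imputed, n_imputed = impute_site_mean(sub, min_reads=profile.min_reads)
    if imputed.shape[1] < len(kept_sites):
        report.site_removals["unimputable"] = len(kept_sites) - imputed.shape[1]
    report.sites_out = imputed.shape[1]
    report.samples_out = len(kept_samples)
    report.imputed_cells = n_imputed
    report.check_conservation()
    return imputed, report


def impute_site_mean(
    matrix: MethylationMatrix, min_reads: int = 1
) -> tuple[MethylationMatrix, int]:
    """Fill unobserved cells with the site mean of observed fractions.

    Sites with no observed cell at all cannot be imputed and are dropped
    with a warning.
    """
    observed = matrix.observed(min_reads)
    frac = matrix.fraction.where(observed)
    site_mean = frac.mean(axis=0)
    dead = site_mean.index[site_mean.isna()]
    if len(dead):
        warnings.warn(f"{len(dead)} sites with no observed cells dropped during imputation")
        matrix = matrix.subset(sites=[s for s in matrix.site_ids if s not in set(dead)])
        observed = matrix.observed(min_reads)
        frac = matrix.fraction.where(observed)
        site_mean = frac.mean(axis=0)
    n_imputed = int((~observed).to_numpy().sum())
    filled = frac.fillna(site_mean)
    return (
        MethylationMatrix(matrix.meth, matrix.unmeth, imputed_fractions=filled),
        n_imputed,
    )


def pool_matrices(matrices: Sequence[MethylationMatrix]) -> MethylationMatrix:
    """Stack studies: union of sites, concatenated samples, absent cells missing."""
    all_sites: list[str] = []
    seen: set[str] = set()
    for m in matrices:
        for s in m.site_ids:
            if s not in seen:
                seen.add(s)
                all_sites.append(s)
    meth = pd.concat(
        [m.meth.reindex(columns=all_sites, fill_value=0) for m in matrices]
    )
    unmeth = pd.concat(
        [m.unmeth.reindex(columns=all_sites, fill_value=0) for m in matrices]
    )
    return MethylationMatrix(meth.astype(int), unmeth.astype(int)).sorted_sites()


def filter_cross_species(
    matrices: Sequence[MethylationMatrix],
    profile: FilterProfile = CROSS_SPECIES_PROFILE,
) -> tuple[MethylationMatrix, FilterReport]:
    """Apply the cross-species profile to >= 2 pooled studies."""
    if len(matrices) < 2:
        raise ValueError("cross-species filtering needs matrices from >= 2 studies")
    pooled = pool_matrices(matrices)
    return _apply_profile(pooled, profile)


def filter_clock(
    matrix: MethylationMatrix, profile: FilterProfile = CLOCK_PROFILE
) -> tuple[MethylationMatrix, FilterReport]:
    """Apply the clock-training profile to one (already pooled) matrix."""
    return _apply_profile(matrix, profile)


def project_relaxed(
    matrix: MethylationMatrix, target_sites: Sequence[str], min_reads: int = 1
) -> MethylationMatrix:
    """Project a cohort onto the clock's site set with a relaxed depth rule.

    Any site with >= ``min_reads`` reads counts as observed; missing cells
    are imputed with the site mean over this matrix's observed cells.
    """
    target = [s for s in target_sites if s in set(matrix.site_ids)]
    if not target:
        raise ValueError("no overlap between matrix sites and target sites")
    sub = matrix.subset(sites=target)
    imputed, _ = impute_site_mean(sub, min_reads=min_reads)
    return imputed
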