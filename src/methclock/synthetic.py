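"""Synthetic methylome cohorts with known ground truth.

The generator emulates the statistical structure of pooled RRBS/WGBS mouse
liver methylomes: per-CpG binomial read counts at Poisson depth, a subset
of sites whose latent methylation fraction drifts linearly with log2(age in
days) (gaining or losing methylation), study-level batch location/scale
distortions, dropout/missingness, an optional contraction of fractions
toward 0.5 with log-age (rising methylome disorder), and a treatment that
multiplicatively slows the age drift (``effective_age = rate * age``).

Every downstream stage of the pipeline — filtering, batch correction,
age-association testing, the elastic-net clock and the longevity
evaluation — is validated against the ground truth recorded here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MethylationMatrix, site_id, validate_meta


@dataclass
class BatchEffect:
    """Additive location shift and multiplicative noise scale of one study."""

    batch_id: str
    location_shift: float = 0.0
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


@dataclass
class CohortSpec:
    """Parameters of a simulated cohort.

    ``slope_scale`` is the methylation-fraction change per unit log2(age in
    days) at age-drifting sites; ``treatment_rate`` multiplies the age axis
    for treated samples (a rate < 1 slows the epigenetic clock);
    ``entropy_drift`` is the exponential rate at which latent fractions
    contract toward 0.5 per unit log2(age), producing rising per-sample
    disorder.
    """

    n_samples: int = 100
    n_sites: int = 500
    n_age_sites: int = 100
    frac_gain: float = 0.5
    slope_scale: float = 0.04
    noise_sd: float = 0.02
    mean_depth: float = 20.0
    missing_rate: float = 0.05
    batches: Sequence[BatchEffect] = field(default_factory=lambda: [BatchEffect("study1")])
    treatment_rate: float = 1.0
    entropy_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.batches = [
            b if isinstance(b, BatchEffect) else BatchEffect(*b) for b in self.batches
        ]
        if self.n_age_sites > self.n_sites:
            raise ValueError("n_age_sites cannot exceed n_sites")
        if not 0.0 <= self.frac_gain <= 1.0:
            raise ValueError("frac_gain must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if not 0.0 < self.treatment_rate <= 1.0:
            raise ValueError("treatment_rate must be in (0, 1]")
        if len(self.batches) == 0:
            raise ValueError("at least one batch required")


@dataclass
class GroundTruth:
    """Planted per-site and per-sample truth of a simulated cohort."""

    site_truth: pd.DataFrame  # is_age_site, slope, baseline
    sample_truth: pd.DataFrame  # age_days, effective_age_days, study, treatment
    planted_overlap: int | None = None  # orthologous pairs only

    @property
    def age_site_ids(self) -> list[str]:
        return list(self.site_truth.index[self.site_truth["is_age_site"]])


def default_ages(n: int, rng: np.random.Generator, lo_days: float = 6.0, hi_days: float = 790.0) -> np.ndarray:
    """Log-uniform ages spanning roughly 0.2-26 months."""
    return np.exp(rng.uniform(np.log(lo_days), np.log(hi_days), size=n))


def default_metadata_plan(spec: CohortSpec, treated_fraction: float = 0.0) -> pd.DataFrame:
    """Round-robin batch assignment, alternating sex, optional treatment.

    Treated samples are drawn from the tail of the cohort so that callers
    controlling ages can decide which ages receive treatment.
    """
    n = spec.n_samples
    sample_ids = [f"S{i:03d}" for i in range(n)]
    batch_ids = [b.batch_id for b in spec.batches]
    n_treated = int(round(treated_fraction * n))
    treatment = ["none"] * (n - n_treated) + ["treated"] * n_treated
    plan = pd.DataFrame(
        {
            "sample_id": sample_ids,
            # stride sex by the batch count so sex and batch stay unconfounded
            "sex": ["female" if (i // len(batch_ids)) % 2 else "male" for i in range(n)],
            "strain": "C57BL/6",
            "treatment": treatment,
            "study": [batch_ids[i % len(batch_ids)] for i in range(n)],
        }
    )
    return plan


def _site_ids(n_sites: int) -> list[str]:
    # spread sites over autosomes 1-19, positions unique within chromosome
    ids = []
    for i in range(n_sites):
        chrom = 1 + (i % 19)
        pos = 10_000 + 50 * (i // 19)
        ids.append(site_id(str(chrom), pos))
    return ids


def _draw_site_truth(spec: CohortSpec, rng: np.random.Generator, site_ids: list[str],
                     age_site_idx: np.ndarray) -> pd.DataFrame:
    n = spec.n_sites
    is_age = np.zeros(n, dtype=bool)
    is_age[age_site_idx] = True
    slope = np.zeros(n)
    baseline = rng.uniform(0.05, 0.95, size=n)
    n_gain = int(round(spec.frac_gain * len(age_site_idx)))
    gain_idx = age_site_idx[:n_gain]
    loss_idx = age_site_idx[n_gain:]
    # per-site slope magnitude jittered around slope_scale; baselines placed
    # so the drift over log2(age) in [2.5, 9.7] stays inside [0, 1]
    slope[gain_idx] = spec.slope_scale * rng.uniform(0.75, 1.25, size=len(gain_idx))
    slope[loss_idx] = -spec.slope_scale * rng.uniform(0.75, 1.25, size=len(loss_idx))
    baseline[gain_idx] = rng.uniform(0.05, 0.25, size=len(gain_idx))
    baseline[loss_idx] = rng.uniform(0.75, 0.95, size=len(loss_idx))
    return pd.DataFrame(
        {"is_age_site": is_age, "slope": slope, "baseline": baseline},
        index=pd.Index(site_ids, name="site"),
    )


def simulate_cohort(
    spec: CohortSpec,
    ages: Sequence[float] | None = None,
    metadata_plan: pd.DataFrame | None = None,
) -> tuple[MethylationMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a cohort; deterministic given ``spec.seed``.

    Parameters
    ----------
    ages
        Chronological ages in days, one per sample.  Defaults to a
        log-uniform draw spanning ~0.2-26 months.
    metadata_plan
        Table with columns sample_id, sex, strain, treatment, study
        covering all samples.  Defaults to
        :func:`default_metadata_plan`.

    Returns the count matrix, the sample metadata and the planted truth.
    """
    rng = np.random.default_rng(spec.seed)
    site_ids_ = _site_ids(spec.n_sites)
    age_site_idx = rng.choice(spec.n_sites, size=spec.n_age_sites, replace=False)
    site_truth = _draw_site_truth(spec, rng, site_ids_, np.sort(age_site_idx))

    if ages is None:
        ages = default_ages(spec.n_samples, rng)
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != spec.n_samples:
        raise ValueError("ages must supply one age per sample")
    if (ages <= 0).any():
        raise ValueError("ages must be positive")

    if metadata_plan is None:
        metadata_plan = default_metadata_plan(spec)
    plan = metadata_plan.reset_index(drop=True)
    if len(plan) != spec.n_samples:
        raise ValueError("metadata_plan must cover all samples")
    known_batches = {b.batch_id for b in spec.batches}
    unknown = set(plan["study"]) - known_batches
    if unknown:
        raise ValueError(f"metadata_plan references batches not in spec: {sorted(unknown)}")

    meta = plan.copy()
    meta["age_days"] = ages
    meta = validate_meta(meta)

    treated = (plan["treatment"] != "none").to_numpy()
    eff_age = np.where(treated, ages * spec.treatment_rate, ages)

    baseline = site_truth["baseline"].to_numpy()
    slope = site_truth["slope"].to_numpy()
    log_eff = np.log2(eff_age)[:, None]  # (n_samples, 1)
    mu = np.clip(baseline[None, :] + slope[None, :] * log_eff, 0.0, 1.0)

    if spec.entropy_drift > 0:
        # contract toward 0.5 with log-age: disorder rises with age
        contraction = np.exp(-spec.entropy_drift * np.log2(ages))[:, None]
        mu = 0.5 + (mu - 0.5) * contraction

    # batch distortion: location shift on the mean, scale on the noise
    batch_of = plan["study"].to_numpy()
    shift = np.array([next(b.location_shift for b in spec.batches if b.batch_id == s) for s in batch_of])
    scale = np.array([next(b.scale_factor for b in spec.batches if b.batch_id == s) for s in batch_of])
    noise = rng.normal(0.0, spec.noise_sd, size=mu.shape) if spec.noise_sd > 0 else 0.0
    latent = np.clip(mu + shift[:, None] + scale[:, None] * noise, 0.0, 1.0)

    depth = rng.poisson(spec.mean_depth, size=mu.shape)
    if spec.missing_rate > 0:
        depth = np.where(rng.random(mu.shape) < spec.missing_rate, 0, depth)
    meth = rng.binomial(depth, latent)
    unmeth = depth - meth

    sample_ids = plan["sample_id"].tolist()
    matrix = MethylationMatrix(
        pd.DataFrame(meth, index=sample_ids, columns=site_ids_),
        pd.DataFrame(unmeth, index=sample_ids, columns=site_ids_),
    )
    matrix.meth.index.name = matrix.unmeth.index.name = "sample_id"

    sample_truth = pd.DataFrame(
        {
            "age_days": ages,
            "effective_age_days": eff_age,
            "study": batch_of,
            "treatment": plan["treatment"].to_numpy(),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(site_truth=site_truth, sample_truth=sample_truth)
    assert (truth.sample_truth["effective_age_days"] <= truth.sample_truth["age_days"] + 1e-9).all()
    return matrix, meta, truth


@dataclass
class OrthologousPair:
    """Two cohorts over a shared site universe with a planted age-site overlap."""

    matrix_a: MethylationMatrix
    meta_a: pd.DataFrame
    truth_a: GroundTruth
    matrix_b: MethylationMatrix
    meta_b: pd.DataFrame
    truth_b: GroundTruth
    mapping_table: pd.DataFrame  # chrom_src, pos_src, chrom_dst, pos_dst
    probe_manifest: pd.DataFrame  # probe_id, chrom, pos
    planted_overlap: int


def simulate_orthologous_pair(
    spec_a: CohortSpec,
    spec_b: CohortSpec,
    shared_fraction: float,
) -> OrthologousPair:
    """Simulate two species-like cohorts whose age-site sets overlap.

    Both cohorts use the same site universe (``n_sites`` must agree); the
    planted overlap between their age-site sets is
    ``round(shared_fraction * min(n_age_a, n_age_b))``, with
    ``shared_fraction = 1`` and equal age-site counts giving identical sets.
    A one-to-one coordinate-mapping table and probe manifest are emitted so
    the ortholog-space construction can be exercised end to end.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    if spec_a.n_sites != spec_b.n_sites:
        raise ValueError("orthologous pair requires equal n_sites")

    rng = np.random.default_rng(spec_a.seed)
    n = spec_a.n_sites
    idx_a = np.sort(rng.choice(n, size=spec_a.n_age_sites, replace=False))
    k = int(round(shared_fraction * min(spec_a.n_age_sites, spec_b.n_age_sites)))
    shared = np.sort(rng.choice(idx_a, size=k, replace=False))
    # the rest of B's age sites are drawn from all non-forced sites, so the
    # realized overlap is the planted k plus a chance (hypergeometric) excess
    pool = np.setdiff1d(np.arange(n), shared)
    extra = np.sort(rng.choice(pool, size=spec_b.n_age_sites - k, replace=False))
    idx_b = np.sort(np.concatenate([shared, extra]))

    mat_a, meta_a, truth_a = _simulate_with_age_sites(spec_a, idx_a)
    mat_b, meta_b, truth_b = _simulate_with_age_sites(spec_b, idx_b)

    sites = mat_a.sites
    probe_ids = [f"cg{i:06d}" for i in range(n)]
    # destination coordinates: deterministic shifted copy of the source
    mapping = pd.DataFrame(
        {
            "chrom_src": sites["chrom"].to_numpy(),
            "pos_src": sites["pos"].to_numpy(),
            "chrom_dst": sites["chrom"].to_numpy(),
            "pos_dst": sites["pos"].to_numpy() + 1_000_000,
        }
    )
    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy() + 1_000_000,
        }
    )
    planted = len(np.intersect1d(idx_a, idx_b))
    truth_a.planted_overlap = truth_b.planted_overlap = planted
    return OrthologousPair(
        mat_a, meta_a, truth_a, mat_b, meta_b, truth_b, mapping, manifest, planted
    )


def _simulate_with_age_sites(
    spec: CohortSpec, age_site_idx: np.ndarray
) -> tuple[MethylationMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a cohort with a fixed (rather than drawn) age-site index set."""
    rng = np.random.default_rng(spec.seed)
    site_ids_ = _site_ids(spec.n_sites)
    site_truth = _draw_site_truth(spec, rng, site_ids_, age_site_idx)
    ages = default_ages(spec.n_samples, rng)
    plan = default_metadata_plan(spec)
    return _resample_counts(spec, site_truth, ages, plan, rng)


def _resample_counts(
    spec: CohortSpec,
    site_truth: pd.DataFrame,
    ages: np.ndarray,
    plan: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[MethylationMatrix, pd.DataFrame, GroundTruth]:
    treated = (plan["treatment"] != "none").to_numpy()
    eff_age = np.where(treated, ages * spec.treatment_rate, ages)
    baseline = site_truth["baseline"].to_numpy()
    slope = site_truth["slope"].to_numpy()
    mu = np.clip(baseline[None, :] + slope[None, :] * np.log2(eff_age)[:, None], 0.0, 1.0)
    if spec.entropy_drift > 0:
        contraction = np.exp(-spec.entropy_drift * np.log2(ages))[:, None]
        mu = 0.5 + (mu - 0.5) * contraction
    noise = rng.normal(0.0, spec.noise_sd, size=mu.shape) if spec.noise_sd > 0 else 0.0
    latent = np.clip(mu + noise, 0.0, 1.0)
    depth = rng.poisson(spec.mean_depth, size=mu.shape)
    if spec.missing_rate > 0:
        depth = np.where(rng.random(mu.shape) < spec.missing_rate, 0, depth)
    meth = rng.binomial(depth, latent)
    sample_ids = plan["sample_id"].tolist()
    site_ids_ = list(site_truth.index)
    matrix = MethylationMatrix(
        pd.DataFrame(meth, index=sample_ids, columns=site_ids_),
        pd.DataFrame(depth - meth, index=sample_ids, columns=site_ids_),
    )
    meta = plan.copy()
    meta["age_days"] = ages
    meta = validate_meta(meta)
    sample_truth = pd.DataFrame(
        {
            "age_days": ages,
            "effective_age_days": eff_age,
            "study": plan["study"].to_numpy(),
            "treatment": plan["treatment"].to_numpy(),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return matrix, meta, GroundTruth(site_truth=site_truth, sample_truth=sample_truth)
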