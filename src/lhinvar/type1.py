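"""Type I invariance: variance ratio, unimodality and two-SD coverage.

Criterion 1 — the variance of the log10 median-normalized trait must be
smaller than that of log10 median-normalized body mass (ratio > 1).  The
median normalization makes variances comparable across groups whose trait
medians differ by orders of magnitude; on the log scale it is exactly a
constant shift, so the ratio is unchanged by it (asserted at run time), but
the normalized variances themselves are the reported, unit-comparable
quantities.

Criterion 2 — the log10 trait distribution must be unimodal (Hartigan's dip
test, Monte-Carlo p-value) and at least 95% of values must fall within two
standard deviations of the mean (boundary inclusive); coverage strictly
above 94% counts as "marginal".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dip import DipResult, dip_pvalue
from .trait_io import BODY_MASS, InsufficientSample, TraitTable

log = logging.getLogger(__name__)


def log10_median_normalized(values: np.ndarray) -> np.ndarray:
    """log10(x / median(x)) over the finite entries of ``values``."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise InsufficientSample(f"need >= 2 records, got {v.size}")
    med = np.median(v)
    out = np.log10(v / med)
    # exact identity: dividing by a constant shifts logs, variance unchanged
    raw_var = np.var(np.log10(v), ddof=1)
    norm_var = np.var(out, ddof=1)
    if not np.isclose(norm_var, raw_var, rtol=1e-9, atol=1e-12):
        raise AssertionError(
            "median normalization changed the log-variance "
            f"({norm_var!r} vs {raw_var!r}); numerical fault"
        )
    return out


@dataclass(frozen=True)
class VarianceRatioResult:
    """Criterion 1: Var(log10 norm. body mass) / Var(log10 norm. trait)."""

    trait: str
    group: str
    trait_var: float
    mass_var: float
    n_trait: int
    n_mass: int

    @property
    def ratio(self) -> float:
        return self.mass_var / self.trait_var

    @property
    def pass_c1(self) -> bool:
        return self.ratio > 1.0


def normalized_variance_ratio(
    group_table: TraitTable, trait: str, group_name: str | None = None
) -> VarianceRatioResult:
    """Criterion 1 for one trait within one (already subset) group.

    The body-mass variance uses *all* species in the group with a recorded
    mass, not only those that also have the trait: the group has a single
    mass variance against which every trait is compared.
    """
    mass = group_table.df[BODY_MASS].to_numpy(dtype=float)
    tvals = group_table.trait_values(trait)
    if group_name is None:
        labels = group_table.df["group"].unique()
        group_name = labels[0] if len(labels) == 1 else "+".join(sorted(labels))
    lm = log10_median_normalized(mass)
    lt = log10_median_normalized(tvals)
    return VarianceRatioResult(
        trait=trait,
        group=group_name,
        trait_var=float(np.var(lt, ddof=1)),
        mass_var=float(np.var(lm, ddof=1)),
        n_trait=int(lt.size),
        n_mass=int(lm.size),
    )


def coverage_two_sd(x) -> tuple[float, float, float]:
    """(mean, sd, % of values within mean ± 2 sd), boundary inclusive."""
    x = np.asarray(x, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InsufficientSample("coverage needs n >= 2")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        log.warning("coverage_two_sd: zero standard deviation")
        return mean, sd, 100.0
    inside = np.abs(x - mean) <= 2.0 * sd
    return mean, sd, 100.0 * float(np.count_nonzero(inside)) / x.size


@dataclass(frozen=True)
class Type1Result:
    """Criteria 1 and 2 for one trait in one group."""

    variance_ratio: VarianceRatioResult
    dip: DipResult
    mean: float
    sd: float
    coverage: float
    alpha: float = 0.05
    coverage_min: float = 95.0
    marginal_min: float = 94.0
    lenient_marginal: bool = False

    def __post_init__(self):
        # Chebyshev: at least 75% of any sample lies within two sample SDs
        assert self.coverage >= 75.0 - 1e-9 and self.coverage <= 100.0

    @property
    def pass_c1(self) -> bool:
        return self.variance_ratio.pass_c1

    @property
    def pass_unimodal(self) -> bool:
        return self.dip.p >= self.alpha

    @property
    def pass_coverage(self) -> bool:
        return self.coverage >= self.coverage_min

    @property
    def marginal_coverage(self) -> bool:
        return self.marginal_min < self.coverage < self.coverage_min

    @property
    def verdict_type1(self) -> bool:
        cov_ok = self.pass_coverage or (
            self.lenient_marginal and self.marginal_coverage
        )
        return self.pass_c1 and self.pass_unimodal and cov_ok


def evaluate_type1(
    group_table: TraitTable,
    trait: str,
    n_mc: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    coverage_min: float = 95.0,
    marginal_min: float = 94.0,
    lenient_marginal: bool = False,
    dip_min_n: int = 4,
    group_name: str | None = None,
) -> Type1Result:
    """Run criteria 1 and 2 on the log10 trait distribution of a group."""
    vr = normalized_variance_ratio(group_table, trait, group_name=group_name)
    tvals = group_table.trait_values(trait)
    tvals = tvals[np.isfinite(tvals)]
    lx = np.log10(tvals)
    dip = dip_pvalue(lx, n_mc=n_mc, seed=seed, min_n=dip_min_n)
    mean, sd, cov = coverage_two_sd(lx)
    return Type1Result(
        variance_ratio=vr, dip=dip, mean=mean, sd=sd, coverage=cov,
        alpha=alpha, coverage_min=coverage_min, marginal_min=marginal_min,
        lenient_marginal=lenient_marginal,
    )
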