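"""Criterion 5: standardized major axis regression between trait pairs.

SMA fits a line treating both log10 traits symmetrically:
slope = sign(r) · SD_y / SD_x, intercept = mean_y − slope · mean_x.  A pair
is flagged isometric when the correlation is significant and the 95%
confidence interval of the SMA slope contains 1 — the trait ratio is then
constant across the joint range, a candidate dimensionless number.

The slope interval uses the F-based factor
    B = F(0.95; 1, n−2) · (1 − r²) / (n − 2),
    CI = slope · (sqrt(B + 1) ± sqrt(B)),
which is exactly symmetric under swapping x and y (the interval of the
reciprocal slope is the reciprocal interval).  No phylogenetic correction
is applied; a phylogeny-informed reduced major axis would be the natural
extension but is deliberately not performed here.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trait_io import InsufficientSample, TraitTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SMAFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    r2: float
    p_corr: float
    n: int

    def __post_init__(self):
        assert self.slope != 0.0
        assert 0.0 <= self.r2 <= 1.0 + 1e-12


def sma_fit(x, y, min_n: int = 3, alpha: float = 0.05) -> SMAFit:
    """Standardized major axis fit of (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    n = x.size
    if n < min_n:
        raise InsufficientSample(f"SMA needs n >= {min_n}, got {n}")
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        raise ValueError("constant vector; SMA undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0:
        raise ValueError("zero correlation; SMA slope sign undefined")
    slope = float(np.sign(r)) * sy / sx
    intercept = float(np.mean(y)) - slope * float(np.mean(x))
    if abs(r) >= 1.0 - 1e-15:
        p_corr = 0.0
        ci = (slope, slope)  # degenerate at perfect correlation
    else:
        p_corr = float(stats.pearsonr(x, y).pvalue)
        B = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r * r) / (n - 2)
        lo = slope * (np.sqrt(B + 1) - np.sqrt(B))
        hi = slope * (np.sqrt(B + 1) + np.sqrt(B))
        ci = (min(lo, hi), max(lo, hi))
    return SMAFit(slope=slope, intercept=intercept, slope_ci=ci,
                  r2=r * r, p_corr=p_corr, n=n)


@dataclass(frozen=True)
class IsometryVerdict:
    significant: bool
    isometric: bool

    def __post_init__(self):
        assert not (self.isometric and not self.significant)


def judge_isometry(fit: SMAFit, alpha: float = 0.05) -> IsometryVerdict:
    """Isometric iff the slope differs from zero and its CI contains 1."""
    sig = fit.p_corr < alpha
    iso = sig and fit.slope_ci[0] <= 1.0 <= fit.slope_ci[1]
    return IsometryVerdict(significant=sig, isometric=iso)


@dataclass(frozen=True)
class PairScanEntry:
    x_trait: str
    y_trait: str
    fit: SMAFit | None
    verdict: IsometryVerdict | None
    n: int
    skipped: str | None = None  # reason, when not fitted


def scan_pairs(
    group_table: TraitTable,
    traits: list[str] | None = None,
    alpha: float = 0.05,
    min_n: int = 5,
) -> list[PairScanEntry]:
    """SMA over all unordered trait pairs with enough complete cases.

    The earlier trait in ``traits`` order is x.  Pairs with fewer than
    ``min_n`` species carrying both traits are listed as skipped rather
    than silently dropped.
    """
    if traits is None:
        traits = group_table.trait_names
    if len(traits) < 2:
        raise ValueError("need at least two traits to scan pairs")
    out: list[PairScanEntry] = []
    for a, b in itertools.combinations(traits, 2):
        va = group_table.trait_values(a)
        vb = group_table.trait_values(b)
        ok = np.isfinite(va) & np.isfinite(vb)
        n = int(ok.sum())
        if n < min_n:
            out.append(PairScanEntry(a, b, None, None, n,
                                     skipped=f"only {n} complete cases"))
            continue
        try:
            fit = sma_fit(np.log10(va[ok]), np.log10(vb[ok]),
                          min_n=min_n, alpha=alpha)
        except ValueError as exc:
            out.append(PairScanEntry(a, b, None, None, n, skipped=str(exc)))
            continue
        out.append(PairScanEntry(a, b, fit, judge_isometry(fit, alpha), n))
    return out
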