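"""Synthetic phylogenies and trait tables with known ground truth.

The generator emulates the structure of comparative life-history datasets:
log-normally distributed adult body masses; traits that either (a) scale as
a power law of mass, log10 T = log10 a + b·log10 M + eps, with residuals
correlated along the tree under a Pagel-lambda Brownian-motion model,
(b) are invariant — narrow unimodal log-normal distributions independent of
mass, or (c) are bimodal mixtures (to exercise the dip test); plus
independent per-trait missingness to mimic very uneven trait sample sizes.

Trees are pure-birth (Yule) trees, ultrametric by default; terminal
branches can be jittered by a multiplicative lognormal factor to produce
the non-ultrametric case that the depth-proportional GLS weights address.
The BM covariance is normalized to unit mean root-to-tip depth before
scaling by sigma^2, so sigma is a tip-level standard deviation (log10
units) regardless of tree height.

Default condition set: 200 species, unit birth rate, log10 body mass
~ Normal(1.0, 0.78^2) — masses of a few grams to a few hundred grams with
a mass variance of about 0.6 on the log10 scale, matching the spread seen
in broad amphibian compilations — one invariant trait (sigma = 0.05), one
allometric trait (b = 0.4, lambda = 0.8, sigma = 0.1), one bimodal trait
(equal mixture, component separation 5 sigma).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .phylo import PhyloCov, PhyloTree, bm_covariance, pagel_transform
from .trait_io import BODY_MASS, GROUP, SPECIES, TraitTable


@dataclass(frozen=True)
class TraitSpec:
    """Ground-truth description of one simulated trait."""

    name: str
    kind: str  # allometric | invariant | bimodal
    b: float = 0.0            # power-law exponent (allometric only)
    a: float = 1.0            # normalization constant (raw scale)
    sigma: float = 0.1        # residual SD on the log10 scale
    lam: float = 0.0          # Pagel's lambda of the residuals (allometric)
    separation: float = 0.5   # bimodal: distance between component centers
    missing_frac: float = 0.0

    def __post_init__(self):
        if self.kind not in ("allometric", "invariant", "bimodal"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.sigma < 0 or not (0 <= self.missing_frac < 1):
            raise ValueError("sigma >= 0 and missing_frac in [0, 1) required")


@dataclass(frozen=True)
class SynthConfig:
    n_species: int = 200
    birth_rate: float = 1.0
    mass_log_mean: float = 1.0
    mass_log_sd: float = 0.78
    tip_jitter_sd: float = 0.0  # lognormal SD for terminal-branch jitter
    trait_specs: tuple[TraitSpec, ...] = (
        TraitSpec("invariant_trait", "invariant", a=10.0, sigma=0.05),
        TraitSpec("allometric_trait", "allometric", b=0.4, a=1.0,
                  sigma=0.1, lam=0.8),
        TraitSpec("bimodal_trait", "bimodal", a=10.0, sigma=0.1,
                  separation=0.5),
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")


@dataclass
class SynthDataset:
    tree: PhyloTree
    table: TraitTable
    truth: dict[str, dict]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.truth).T


def simulate_yule_tree(
    n_species: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    tip_jitter_sd: float = 0.0,
) -> PhyloTree:
    """Pure-birth tree with ``n_species`` extant tips, labelled S0001..

    ``tip_jitter_sd`` > 0 multiplies every terminal branch by an
    independent lognormal(0, sd) factor, breaking ultrametricity.
    """
    if n_species < 2:
        raise ValueError("need >= 2 species")
    rng = random.Random(int(seed))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=float(birth_rate),
        death_rate=0.0,
        num_extant_tips=int(n_species),
        rng=rng,
    )
    # the simulator stops exactly at the n-th birth, leaving zero-length
    # cherries; run the clock forward by the waiting time to the next
    # (censored) birth so the tree is a proper Yule tree observed at n tips
    extra = rng.expovariate(n_species * float(birth_rate))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"S{i:04d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    if tip_jitter_sd > 0:
        nrng = np.random.default_rng(int(seed) + 1)
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = (leaf.edge.length or 0.0) * float(
                np.exp(nrng.normal(0.0, tip_jitter_sd))
            )
    return PhyloTree(tree)


def simulate_mass(
    n: int, log_mean: float, log_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. log10 body masses (grams on the raw scale)."""
    return rng.normal(log_mean, log_sd, size=n)


def simulate_trait(
    tree: PhyloTree,
    spec: TraitSpec,
    mass_log10: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-tip raw-scale trait values under ``spec`` (tip order of tree)."""
    n = tree.n_tips
    if mass_log10.shape[0] != n:
        raise ValueError("mass vector does not match tip count")
    log_a = np.log10(spec.a)
    if spec.kind == "allometric":
        if spec.sigma == 0:
            eps = np.zeros(n)
        else:
            cov = bm_covariance(tree)
            V = cov.V / float(np.mean(np.diag(cov.V)))  # unit mean tip depth
            W = pagel_transform(PhyloCov(cov.taxa, V), spec.lam).V
            eps = _mvn(spec.sigma ** 2 * W, rng)
        logT = log_a + spec.b * mass_log10 + eps
    elif spec.kind == "invariant":
        logT = rng.normal(log_a, spec.sigma, size=n)
    else:  # bimodal: equal mixture of two narrow components
        comp = rng.random(n) < 0.5
        centers = np.where(comp, log_a - spec.separation / 2,
                           log_a + spec.separation / 2)
        logT = rng.normal(centers, spec.sigma)
    return 10.0 ** logT


def _mvn(S: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one multivariate normal via jittered Cholesky."""
    n = S.shape[0]
    try:
        L = np.linalg.cholesky(S + 1e-12 * np.trace(S) / n * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError("residual covariance not PSD") from exc
    return L @ rng.standard_normal(n)


def apply_missingness(
    table: TraitTable,
    missing_frac: dict[str, float],
    seed: int = 0,
) -> TraitTable:
    """Mask trait entries independently at per-trait rates (reproducible)."""
    import logging

    rng = np.random.default_rng(int(seed))
    df = table.df.copy()
    for trait, frac in missing_frac.items():
        if not 0 <= frac < 1:
            raise ValueError(f"missing_frac for {trait!r} must be in [0, 1)")
        if frac == 0:
            continue
        mask = rng.random(len(df)) < frac
        df.loc[mask, trait] = np.nan
        if df[trait].notna().sum() < 3:
            logging.getLogger(__name__).warning(
                "trait %r left with <3 records after masking", trait)
    return TraitTable(df, dict(table.units))


def make_dataset(config: SynthConfig) -> SynthDataset:
    """Full synthetic dataset: tree + trait table + ground-truth record."""
    tree = simulate_yule_tree(config.n_species, config.birth_rate,
                              seed=config.seed,
                              tip_jitter_sd=config.tip_jitter_sd)
    rng = np.random.default_rng(config.seed)
    tips = tree.tip_labels
    mass_log10 = simulate_mass(len(tips), config.mass_log_mean,
                               config.mass_log_sd, rng)
    df = pd.DataFrame({
        SPECIES: tips,
        GROUP: "synthetic",
        BODY_MASS: 10.0 ** mass_log10,
    })
    units = {BODY_MASS: "g"}
    truth: dict[str, dict] = {}
    for spec in config.trait_specs:
        df[spec.name] = simulate_trait(tree, spec, mass_log10, rng)
        units[spec.name] = "arb"
        truth[spec.name] = asdict(spec)
    table = TraitTable(df, units)
    fracs = {s.name: s.missing_frac for s in config.trait_specs
             if s.missing_frac > 0}
    if fracs:
        table = apply_missingness(table, fracs, seed=config.seed + 1)
    return SynthDataset(tree=tree, table=table, truth=truth)


def write_dataset(ds: SynthDataset, traits_path, tree_path,
                  truth_path=None) -> None:
    """Write the standard CSV + Newick (+ JSON truth) files."""
    from .trait_io import write_trait_table
    import json

    write_trait_table(ds.table, traits_path)
    with open(tree_path, "w") as fh:
        fh.write(ds.tree.as_newick() + "\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(ds.truth, fh, indent=2, sort_keys=True)
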