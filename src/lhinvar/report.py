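"""Run configuration and the end-to-end analysis pipeline.

``run_analysis`` applies, per analysis group: criterion 1 (variance ratio),
criterion 2 (dip test + two-SD coverage), criteria 3/4 (OLS and PGLS of
each trait on body mass) and criterion 5 (SMA pair scan), then aggregates
everything into the invariance verdict grid.  Outputs per group: a type-I
detail TSV, a regression detail TSV, an SMA pair TSV, the verdict grid
(TSV + Markdown), and one JSON bundle holding every statistic, threshold
and seed at full precision.  Errors on individual trait/group combinations
are logged and recorded; the run continues for the remaining traits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import allometry, classifier, isometry, phylo, trait_io, type1
from .trait_io import BODY_MASS, GroupSpec, InsufficientSample, TraitTable

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    traits_path: str = ""
    tree_path: str | None = None
    out_dir: str = "out"
    schema: dict = field(default_factory=dict)
    groups: dict[str, list[str]] = field(default_factory=dict)
    min_max_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    traits: list[str] | None = None      # None = every trait column
    alpha: float = 0.05
    r2_max: float = 0.05
    coverage_min: float = 95.0
    marginal_min: float = 94.0
    lenient_marginal: bool = False
    degraded_type2_ok: bool = False
    regression_min_n: int = 8
    sma_min_n: int = 5
    dip_min_n: int = 4
    dip_n_mc: int = 10_000
    lam_bounds: tuple[float, float] = (0.0, 1.0)
    pgls_weights: str = "depth"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.r2_max <= 1:
            raise ValueError("r2_max must be in [0, 1]")
        if not 75 <= self.marginal_min <= self.coverage_min <= 100:
            raise ValueError("need 75 <= marginal_min <= coverage_min <= 100")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["min_max_pairs"] = [tuple(p) for p in raw.get("min_max_pairs", [])]
        if "lam_bounds" in raw:
            raw["lam_bounds"] = tuple(raw["lam_bounds"])
        return cls(**raw)

    def group_specs(self, labels=None) -> list[GroupSpec]:
        """Analysis groups; with no config, one pooled group of all labels."""
        if not self.groups:
            members = frozenset(labels) if labels else frozenset({"all"})
            return [GroupSpec("all", members)]
        return [GroupSpec(name, frozenset(members))
                for name, members in self.groups.items()]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, classifier.Mark):
        return obj.value
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def _fmt(v, nd=4):
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.{nd}g}"
    return str(v)


def analyze_group(
    table: TraitTable,
    spec: GroupSpec,
    cfg: RunConfig,
    tree: phylo.PhyloTree | None,
) -> dict:
    """All five criteria for one analysis group; returns the JSON record."""
    group_tbl = trait_io.subset_group(table, spec)
    traits = cfg.traits or group_tbl.trait_names
    record: dict = {"group": spec.name, "n_species": len(group_tbl),
                    "traits": {}, "skipped": {}}
    rows: list[classifier.TraitRow] = []
    for ti, trait in enumerate(traits):
        entry: dict = {}
        t1res = None
        t2res = None
        try:
            t1res = type1.evaluate_type1(
                group_tbl, trait,
                n_mc=cfg.dip_n_mc, seed=cfg.seed + 1000 * ti,
                alpha=cfg.alpha, coverage_min=cfg.coverage_min,
                marginal_min=cfg.marginal_min,
                lenient_marginal=cfg.lenient_marginal,
                dip_min_n=cfg.dip_min_n, group_name=spec.name,
            )
            entry["type1"] = t1res
            log.info("criterion1 %s/%s ratio=%.4g pass=%s", spec.name, trait,
                     t1res.variance_ratio.ratio, t1res.pass_c1)
            log.info("criterion2 %s/%s dipD=%.4g p=%.4g coverage=%.4g",
                     spec.name, trait, t1res.dip.D, t1res.dip.p, t1res.coverage)
        except (InsufficientSample, ValueError) as exc:
            record["skipped"][f"{trait}/type1"] = str(exc)
            log.warning("type1 %s/%s skipped: %s", spec.name, trait, exc)
        olsfit = None
        pglsfit = None
        try:
            x, y, sp = trait_io.paired_log10(group_tbl, trait,
                                             min_n=cfg.regression_min_n)
            olsfit = allometry.ols_fit(x, y, min_n=cfg.regression_min_n,
                                       alpha=cfg.alpha)
            entry["ols"] = olsfit
            log.info("criterion3/4 OLS %s/%s slope=%.4g p=%.4g r2=%.4g",
                     spec.name, trait, olsfit.slope, olsfit.p_slope, olsfit.r2)
            if tree is not None:
                common = [s for s in sp if s in set(tree.tip_labels)]
                if len(common) >= cfg.regression_min_n:
                    sub, dropped = phylo.prune_to_taxa(tree, common)
                    cov = phylo.bm_covariance(sub)
                    keep = {s: i for i, s in enumerate(sp)}
                    idx = [keep[t] for t in cov.taxa]
                    pglsfit = allometry.pgls_fit(
                        x[idx], y[idx], cov,
                        weights_mode=cfg.pgls_weights,
                        lam_bounds=cfg.lam_bounds,
                        min_n=cfg.regression_min_n, alpha=cfg.alpha,
                    )
                    entry["pgls"] = pglsfit
                    entry["pgls_excluded"] = sorted(set(sp) - set(common))
                    log.info("criterion3 PGLS %s/%s slope=%.4g p=%.4g "
                             "lambda=%.3f", spec.name, trait, pglsfit.slope,
                             pglsfit.p_slope, pglsfit.lam)
                else:
                    record["skipped"][f"{trait}/pgls"] = (
                        f"only {len(common)} species in tree")
            t2res = allometry.evaluate_type2(
                olsfit, pglsfit, alpha=cfg.alpha, r2_max=cfg.r2_max,
                degraded_ok=cfg.degraded_type2_ok or tree is None,
            )
            entry["type2"] = t2res
        except (InsufficientSample, ValueError) as exc:
            record["skipped"][f"{trait}/regression"] = str(exc)
            log.warning("regression %s/%s skipped: %s", spec.name, trait, exc)
        rows.append(classifier.classify_trait(
            trait, t1res, t2res, lenient_marginal=cfg.lenient_marginal))
        record["traits"][trait] = entry
    try:
        record["sma_pairs"] = isometry.scan_pairs(
            group_tbl, traits=[t for t in traits], alpha=cfg.alpha,
            min_n=cfg.sma_min_n)
    except ValueError as exc:
        record["skipped"]["sma"] = str(exc)
        record["sma_pairs"] = []
    record["report"] = classifier.build_report(
        rows, spec.name, trait_order=traits,
        config_note=(f"alpha={cfg.alpha}, r2_max={cfg.r2_max}, "
                     f"coverage>={cfg.coverage_min}"),
        seeds={"dip_seed": cfg.seed},
    )
    return record


def _type1_tsv(record: dict) -> str:
    head = ["trait", "variance", "mass_var_over_trait_var", "dip_D", "dip_p",
            "pct_within_2sd", "n_trait", "n_mass"]
    lines = ["\t".join(head)]
    for trait, entry in record["traits"].items():
        t1 = entry.get("type1")
        if t1 is None:
            lines.append("\t".join([trait] + ["NA"] * 7))
            continue
        vr = t1.variance_ratio
        lines.append("\t".join([
            trait, _fmt(vr.trait_var), _fmt(vr.ratio), _fmt(t1.dip.D),
            _fmt(t1.dip.p), _fmt(t1.coverage), str(vr.n_trait),
            str(vr.n_mass)]))
    return "\n".join(lines) + "\n"


def _regression_tsv(record: dict) -> str:
    head = ["trait", "model", "df", "r2", "adj_r2", "p", "slope", "ci_s_lo",
            "ci_s_hi", "intercept", "ci_i_lo", "ci_i_hi", "lambda"]
    lines = ["\t".join(head)]
    for trait, entry in record["traits"].items():
        ols = entry.get("ols")
        if ols is not None:
            lines.append("\t".join([
                trait, "OLS", str(ols.df), _fmt(ols.r2), _fmt(ols.adj_r2),
                _fmt(ols.p_slope), _fmt(ols.slope), _fmt(ols.slope_ci[0]),
                _fmt(ols.slope_ci[1]), _fmt(ols.intercept),
                _fmt(ols.intercept_ci[0]), _fmt(ols.intercept_ci[1]), "NA"]))
        else:
            lines.append("\t".join([trait, "OLS"] + ["NA"] * 11))
        pg = entry.get("pgls")
        if pg is not None:
            lines.append("\t".join([
                trait, "PGLS", str(pg.n - 2), "NA", "NA", _fmt(pg.p_slope),
                _fmt(pg.slope), _fmt(pg.slope_ci[0]), _fmt(pg.slope_ci[1]),
                _fmt(pg.intercept), _fmt(pg.intercept_ci[0]),
                _fmt(pg.intercept_ci[1]), _fmt(pg.lam)]))
        else:
            lines.append("\t".join([trait, "PGLS"] + ["NA"] * 11))
    return "\n".join(lines) + "\n"


def _sma_tsv(entries) -> str:
    head = ["x_trait", "y_trait", "n", "r2", "p", "slope", "ci_lo", "ci_hi",
            "intercept", "significant", "isometric", "skipped"]
    lines = ["\t".join(head)]
    for e in entries:
        if e.fit is None:
            lines.append("\t".join([e.x_trait, e.y_trait, str(e.n)]
                                   + ["NA"] * 8 + [e.skipped or ""]))
            continue
        f, v = e.fit, e.verdict
        lines.append("\t".join([
            e.x_trait, e.y_trait, str(e.n), _fmt(f.r2), _fmt(f.p_corr),
            _fmt(f.slope), _fmt(f.slope_ci[0]), _fmt(f.slope_ci[1]),
            _fmt(f.intercept), "+" if v.significant else "-",
            "+" if v.isometric else "-", ""]))
    return "\n".join(lines) + "\n"


def run_analysis(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write the output bundle.

    Returns the in-memory JSON-able result dict; raises RuntimeError only
    when *no* trait in *any* group produced a result.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = trait_io.read_trait_table(cfg.traits_path, cfg.schema)
    if cfg.min_max_pairs:
        table = trait_io.harmonize_min_max(table, cfg.min_max_pairs)
    tree = None
    if cfg.tree_path:
        tree = phylo.read_newick(cfg.tree_path)
    results = {"config": _jsonable(dataclasses.asdict(cfg)), "groups": {}}
    any_result = False
    md_parts = []
    for spec in cfg.group_specs(labels=table.df["group"].unique()):
        rec = analyze_group(table, spec, cfg, tree)
        if any(rec["traits"][t] for t in rec["traits"]):
            any_result = True
        results["groups"][spec.name] = _jsonable(
            {k: v for k, v in rec.items() if k != "report"})
        results["groups"][spec.name]["verdicts"] = _jsonable(
            rec["report"].verdicts())
        (out / f"{spec.name}_type1.tsv").write_text(_type1_tsv(rec))
        (out / f"{spec.name}_regressions.tsv").write_text(_regression_tsv(rec))
        (out / f"{spec.name}_sma.tsv").write_text(_sma_tsv(rec["sma_pairs"]))
        (out / f"{spec.name}_grid.tsv").write_text(rec["report"].render_tsv())
        md_parts.append(rec["report"].render_markdown())
    (out / "invariance_grids.md").write_text("\n".join(md_parts))
    (out / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True) + "\n")
    if not any_result:
        raise RuntimeError("no trait in any group produced a result")
    return results
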