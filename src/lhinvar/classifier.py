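"""Aggregation of criterion results into an invariance verdict grid.

Each trait × group cell gets a mark per criterion — pass "+", marginal
"(+)" (coverage only), fail "−", or not available "–" — and three boolean
verdicts: type I (variance ratio AND unimodality AND coverage), type II
(OLS slope AND PGLS slope AND R²), and type I+II (both).  The marginal
coverage mark promotes to a type I pass only under an explicit lenient
flag; a missing PGLS blocks the type II verdict unless a degraded OLS-only
verdict was requested upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .allometry import Type2Verdict
from .type1 import Type1Result


class Mark(str, Enum):
    PASS = "+"
    MARGINAL = "(+)"
    FAIL = "-"
    NA = "NA"

    @classmethod
    def of(cls, ok: bool | None) -> "Mark":
        if ok is None:
            return cls.NA
        return cls.PASS if ok else cls.FAIL


#: column order of the criterion marks in reports
MARK_COLUMNS = (
    "variance_ratio", "unimodality", "coverage",
    "slope_ols", "slope_pgls", "r2",
)


@dataclass(frozen=True)
class TraitRow:
    trait: str
    marks: dict[str, Mark]
    type_I: bool | None
    type_II: bool | None

    @property
    def type_I_II(self) -> bool | None:
        if self.type_I is None or self.type_II is None:
            return None
        return self.type_I and self.type_II


def classify_trait(
    trait: str,
    t1: Type1Result | None,
    t2: Type2Verdict | None,
    lenient_marginal: bool | None = None,
) -> TraitRow:
    """Combine criterion results for one trait into marks and verdicts.

    Either input may be None (insufficient sample); the corresponding marks
    and verdict become not-available.  ``lenient_marginal`` overrides the
    flag carried by the Type1Result.
    """
    marks: dict[str, Mark] = {c: Mark.NA for c in MARK_COLUMNS}
    type_I: bool | None = None
    if t1 is not None:
        lenient = t1.lenient_marginal if lenient_marginal is None \
            else lenient_marginal
        marks["variance_ratio"] = Mark.of(t1.pass_c1)
        marks["unimodality"] = Mark.of(t1.pass_unimodal)
        if t1.pass_coverage:
            marks["coverage"] = Mark.PASS
        elif t1.marginal_coverage:
            marks["coverage"] = Mark.MARGINAL
        else:
            marks["coverage"] = Mark.FAIL
        cov_ok = t1.pass_coverage or (lenient and t1.marginal_coverage)
        type_I = t1.pass_c1 and t1.pass_unimodal and cov_ok
    type_II: bool | None = None
    if t2 is not None:
        marks["slope_ols"] = Mark.of(t2.pass_ols_slope)
        marks["slope_pgls"] = Mark.of(t2.pass_pgls_slope)
        marks["r2"] = Mark.of(t2.pass_r2)
        type_II = t2.verdict_type2
    return TraitRow(trait=trait, marks=marks, type_I=type_I, type_II=type_II)


@dataclass
class InvarianceReport:
    group: str
    rows: list[TraitRow]
    config_note: str = ""
    seeds: dict[str, int] = field(default_factory=dict)

    def verdicts(self) -> dict[str, dict[str, bool | None]]:
        return {
            r.trait: {"type_I": r.type_I, "type_II": r.type_II,
                      "type_I_II": r.type_I_II}
            for r in self.rows
        }

    def render_markdown(self) -> str:
        def cell(v):
            if isinstance(v, Mark):
                return "–" if v is Mark.NA else v.value
            if v is None:
                return "–"
            return "+" if v else "-"

        head = (["trait"] + list(MARK_COLUMNS)
                + ["type_I", "type_II", "type_I_II"])
        lines = [f"## Group: {self.group}", "",
                 "| " + " | ".join(head) + " |",
                 "|" + "---|" * len(head)]
        for r in self.rows:
            vals = [r.trait] + [cell(r.marks[c]) for c in MARK_COLUMNS] \
                + [cell(r.type_I), cell(r.type_II), cell(r.type_I_II)]
            lines.append("| " + " | ".join(vals) + " |")
        if self.seeds:
            seeds = ", ".join(f"{k}={v}" for k, v in sorted(self.seeds.items()))
            lines += ["", f"_seeds: {seeds}_"]
        if self.config_note:
            lines += ["", f"_{self.config_note}_"]
        return "\n".join(lines) + "\n"

    def render_tsv(self) -> str:
        def cell(v):
            if isinstance(v, Mark):
                return "NA" if v is Mark.NA else v.value
            if v is None:
                return "NA"
            return "+" if v else "-"

        head = (["trait"] + list(MARK_COLUMNS)
                + ["type_I", "type_II", "type_I_II"])
        lines = ["\t".join(head)]
        for r in self.rows:
            lines.append("\t".join(
                [r.trait] + [cell(r.marks[c]) for c in MARK_COLUMNS]
                + [cell(r.type_I), cell(r.type_II), cell(r.type_I_II)]))
        return "\n".join(lines) + "\n"


def build_report(
    rows: list[TraitRow],
    group: str,
    trait_order: list[str] | None = None,
    config_note: str = "",
    seeds: dict[str, int] | None = None,
) -> InvarianceReport:
    """Assemble rows into a deterministic, renderable verdict grid."""
    if not rows:
        raise ValueError("report needs at least one row")
    if trait_order:
        pos = {t: i for i, t in enumerate(trait_order)}
        rows = sorted(rows, key=lambda r: pos.get(r.trait, len(pos)))
    return InvarianceReport(group=group, rows=list(rows),
                            config_note=config_note, seeds=dict(seeds or {}))
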