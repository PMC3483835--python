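"""Deterministic evidence grading of protein-degradation study designs.

A study design is declared as a set of checklist *ticks* (1-10), one per
study-type row: untagged vs tagged protein, steady-state vs kinetic
readout, which inhibitors or genetic interference were applied, whether
labeling (pulse-chase or SILAC) was used.  The engine matches the ticked
set against a fixed rule base of design combinations, reports the most
specific matching rule(s) with their conclusions and compulsory controls,
and grades the overall strength of evidence the design can deliver.

The rule base ships as a versioned YAML data file; conclusion strings are
exact, quotable text rather than paraphrase, because the wording of what
a design can and cannot show is the substance of the appraisal.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import FrozenSet, Iterable, List, Sequence, Tuple

import yaml

from .kinetics import ParameterError

__all__ = [
    "GRADES",
    "Tick",
    "AppraisalRule",
    "AppraisalReport",
    "appraise",
    "required_controls",
    "table_rows",
    "combination_rules",
]

#: Evidence grades from worst to best.
GRADES = ("not_good_approach", "insufficient", "partial", "good_approach", "good_evidence")
_GRADE_RANK = {g: i for i, g in enumerate(GRADES)}


@dataclass(frozen=True)
class Tick:
    """One checklist row: a numbered study-type label."""

    id: int
    label: str
    conclusion: str
    grade: str


@dataclass(frozen=True)
class AppraisalRule:
    """A design-combination rule: tick pattern, conclusion, controls, grade.

    ``pattern`` is a tuple of alternative-groups; the rule matches a tick
    set when every group intersects it.  The ubiquitous ``(1, 2)`` group
    encodes "untagged or tagged".
    """

    name: str
    pattern: Tuple[Tuple[int, ...], ...]
    title: str
    conclusion: str
    grade: str
    required_controls: Tuple[str, ...]
    notes: Tuple[str, ...] = ()

    def matches(self, ticks: FrozenSet[int]) -> bool:
        return all(any(t in ticks for t in group) for group in self.pattern)

    def used_ticks(self, ticks: FrozenSet[int]) -> FrozenSet[int]:
        """The ticked ids this rule actually consumes (for specificity ranking)."""
        used = set()
        for group in self.pattern:
            used.update(t for t in group if t in ticks)
        return frozenset(used)


@lru_cache(maxsize=1)
def _rulebase():
    text = resources.files("turnoverkit").joinpath("data/appraisal_rules.yaml").read_text()
    raw = yaml.safe_load(text)
    rows = {
        int(i): Tick(
            id=int(i),
            label=raw["ticks"][i],
            conclusion=raw["row_conclusions"][i],
            grade=raw["row_grades"][i],
        )
        for i in raw["ticks"]
    }
    rules = tuple(
        AppraisalRule(
            name=r["name"],
            pattern=tuple(tuple(int(t) for t in group) for group in r["pattern"]),
            title=r["title"],
            conclusion=r["conclusion"],
            grade=r["grade"],
            required_controls=tuple(r.get("required_controls") or ()),
            notes=tuple(r.get("notes") or ()),
        )
        for r in raw["rules"]
    )
    return rows, rules


def table_rows() -> Tuple[Tick, ...]:
    """The ten checklist rows in order."""
    rows, _ = _rulebase()
    return tuple(rows[i] for i in sorted(rows))


def combination_rules() -> Tuple[AppraisalRule, ...]:
    """The twelve design-combination rules in rule-base order."""
    _, rules = _rulebase()
    return rules


@dataclass(frozen=True)
class AppraisalReport:
    """Deterministic appraisal of one declared design."""

    ticks: Tuple[int, ...]
    matched_rules: Tuple[AppraisalRule, ...]
    row_conclusions: Tuple[Tick, ...]
    unmatched_ticks: Tuple[int, ...]
    overall_grade: str
    warnings: Tuple[str, ...] = ()

    @property
    def required_controls(self) -> Tuple[str, ...]:
        out: List[str] = []
        for rule in self.matched_rules:
            for c in rule.required_controls:
                if c not in out:
                    out.append(c)
        return tuple(out)

    @property
    def conclusions(self) -> Tuple[str, ...]:
        return tuple(r.conclusion for r in self.matched_rules)

    def render(self) -> str:
        rows, _ = _rulebase()
        lines = []
        tick_labels = "; ".join(f"{i}: {rows[i].label}" for i in self.ticks)
        lines.append(f"Declared design (ticks) — {tick_labels}")
        for w in self.warnings:
            lines.append(f"Warning: {w}")
        lines.append(f"Overall grade: {self.overall_grade}")
        if self.matched_rules:
            for rule in self.matched_rules:
                lines.append(f"Matched design: {rule.title}")
                lines.append(f"  Conclusion: {rule.conclusion}")
                for c in rule.required_controls:
                    lines.append(f"  Required control: {c}")
                for n in rule.notes:
                    lines.append(f"  Note: {n}")
        else:
            lines.append("No design-combination rule matches; per-row conclusions apply.")
        lines.append("Checklist rows ticked:")
        for row in self.row_conclusions:
            lines.append(f"  {row.id}. {row.label} — {row.conclusion}")
        return "\n".join(lines)


def _validate_ticks(ticks: Iterable[int]) -> Tuple[int, ...]:
    try:
        ids = sorted({int(getattr(t, "id", t)) for t in ticks})
    except (TypeError, ValueError) as exc:
        raise ParameterError(f"ticks must be integers 1-10: {exc}") from exc
    if not ids:
        raise ParameterError("tick set must be non-empty")
    bad = [i for i in ids if not 1 <= i <= 10]
    if bad:
        raise ParameterError(f"tick ids outside 1-10: {bad}")
    return tuple(ids)


def appraise(ticks: Iterable[int]) -> AppraisalReport:
    """Grade a declared design and list its compulsory controls.

    Matching is by pattern satisfaction with superset-wins specificity: a
    matching rule is dropped when the ticks it consumes are a strict
    subset of those consumed by another matching rule.  If no combination
    rule matches at all, the per-row conclusions still apply, so every
    valid tick set yields a report.
    """
    ids = _validate_ticks(ticks)
    tick_set = frozenset(ids)
    rows, rules = _rulebase()

    warn: List[str] = []
    if 1 in tick_set and 2 in tick_set:
        msg = "ticks 1 (untagged) and 2 (tagged) are alternatives; matching proceeds with their union"
        warn.append(msg)
        _warnings.warn(msg, stacklevel=2)

    matched = [(r, r.used_ticks(tick_set)) for r in rules if r.matches(tick_set)]
    # superset-wins: drop rules whose consumed ticks are strictly contained
    # in another matching rule's consumed ticks
    kept = [
        r
        for r, used in matched
        if not any(used < other_used for _, other_used in matched)
    ]

    covered = frozenset().union(*(used for _, used in matched)) if matched else frozenset()
    unmatched = tuple(i for i in ids if i not in covered)

    if kept:
        grade = min((r.grade for r in kept), key=_GRADE_RANK.__getitem__)
    else:
        grade = min((rows[i].grade for i in ids), key=_GRADE_RANK.__getitem__)

    return AppraisalReport(
        ticks=ids,
        matched_rules=tuple(kept),
        row_conclusions=tuple(rows[i] for i in ids),
        unmatched_ticks=unmatched,
        overall_grade=grade,
        warnings=tuple(warn),
    )


def required_controls(ticks: Iterable[int]) -> Tuple[str, ...]:
    """Compulsory control statements for a declared design (deterministic order)."""
    return appraise(ticks).required_controls
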