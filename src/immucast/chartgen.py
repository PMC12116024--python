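"""Decision-chart export in DOT (Graphviz) format.

Every chart follows one fixed color convention so that all vaccines read the
same way: blue for to-do actions, green for conditions, red for
contraindications, orange for follow-up visits, purple for vaccines.  The
hex codes are constant across charts; shapes likewise carry meaning (rounded
box = action, diamond = condition, octagon = contraindication).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List

from .errors import EmptyCategory, UnknownCategory
from .logic import format_logic
from .rule_model import ActionType, Rule, Rulebase


class Role(str, Enum):
    TODO = "TODO"
    CONDITION = "CONDITION"
    CONTRAINDICATION = "CONTRAINDICATION"
    FOLLOWUP = "FOLLOWUP"
    VACCINE = "VACCINE"


@dataclass(frozen=True)
class ChartStyle:
    """Total role -> color / shape mapping; constant machine codes."""

    colors: Dict[Role, str] = field(default_factory=lambda: {
        Role.TODO: "#0000FF",
        Role.CONDITION: "#008000",
        Role.CONTRAINDICATION: "#FF0000",
        Role.FOLLOWUP: "#FFA500",
        Role.VACCINE: "#800080",
    })
    shapes: Dict[Role, str] = field(default_factory=lambda: {
        Role.TODO: "box",
        Role.CONDITION: "diamond",
        Role.CONTRAINDICATION: "octagon",
        Role.FOLLOWUP: "box",
        Role.VACCINE: "ellipse",
    })

    def __post_init__(self):
        missing = [r for r in Role if r not in self.colors or r not in self.shapes]
        if missing:
            raise ValueError(f"style must cover every role; missing {missing}")


DEFAULT_STYLE = ChartStyle()


def _action_role(rule: Rule) -> Role:
    if rule.action.type in (ActionType.CONTRAINDICATED, ActionType.PRECAUTION):
        return Role.CONTRAINDICATION
    if rule.action.type is ActionType.SCHEDULE_FOLLOWUP:
        return Role.FOLLOWUP
    return Role.TODO


def _esc(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _node(nid: str, label: str, role: Role, style: ChartStyle) -> str:
    extra = ", style=\"rounded,filled\"" if (
        role in (Role.TODO, Role.FOLLOWUP)) else ", style=filled"
    return (f'  "{nid}" [label="{_esc(label)}", shape={style.shapes[role]}, '
            f'fillcolor="{style.colors[role]}", fontcolor=white{extra}];')


def _chart(graph_id: str, vaccines: List[str], rules: List[Rule],
           style: ChartStyle) -> str:
    """Build one connected DOT digraph: vaccine roots -> per-rule condition
    node -> per-rule action node."""
    lines = [f'digraph "{_esc(graph_id)}" {{',
             "  rankdir=LR;",
             '  node [fontname="Helvetica"];']
    root = f"vaccine:{vaccines[0]}"
    for v in vaccines:
        lines.append(_node(f"vaccine:{v}", v, Role.VACCINE, style))
    for v in vaccines[1:]:
        lines.append(f'  "vaccine:{v}" -> "{root}" [style=dashed];')
    for rule in sorted(rules, key=lambda r: r.id):
        cond_label = (format_logic(rule.logic) if rule.logic is not None
                      else rule.description[:60] or rule.id)
        act = rule.action
        act_label = act.type.value + (f" {act.dose_number}" if act.dose_number else "")
        lines.append(_node(f"{rule.id}:cond", cond_label, Role.CONDITION, style))
        lines.append(_node(f"{rule.id}:act", act_label, _action_role(rule), style))
        lines.append(f'  "{root}" -> "{rule.id}:cond";')
        lines.append(f'  "{rule.id}:cond" -> "{rule.id}:act";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_chart(rb: Rulebase, category: str, style: ChartStyle = DEFAULT_STYLE) -> str:
    """One connected DOT chart for a category; every rule maps to two nodes."""
    cat = rb.category(category)  # raises UnknownCategory
    rules = rb.rules_for(cat.slug)
    if not rules:
        raise EmptyCategory(cat.slug)
    return _chart(cat.name, list(cat.vaccines), rules, style)


def export_all_charts(rb: Rulebase, out_dir, style: ChartStyle = DEFAULT_STYLE) -> int:
    """Write exactly one chart file per vaccine product in the manifest.

    A combination product's chart (MMRV) contains the rules of every category
    that lists it.  Returns the number of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = 0
    for vaccine in rb.vaccines:
        rules: List[Rule] = []
        for cat in rb.categories:
            if vaccine in cat.vaccines:
                rules.extend(rb.rules_for(cat.slug))
        text = _chart(vaccine, [vaccine], rules, style)
        fname = re.sub(r"[^A-Za-z0-9_-]+", "-", vaccine.lower()) + ".dot"
        (out / fname).write_text(text, encoding="utf-8")
        n += 1
    return n


# --- minimal DOT well-formedness check --------------------------------------

_QUOTED = r'"(?:[^"\\]|\\.)*"'
_ATTRS = rf'\[(?:{_QUOTED}|[^\]"])*\]'  # quoted strings may contain ] and ,
_DOT_HEADER = re.compile(rf"^digraph {_QUOTED} \{{$")
_DOT_NODE = re.compile(rf"^  {_QUOTED} {_ATTRS};$")
_DOT_EDGE = re.compile(rf"^  {_QUOTED} -> {_QUOTED}( {_ATTRS})?;$")
_DOT_ATTR = re.compile(rf"^  [a-z]+=.*;$|^  node {_ATTRS};$")


def validate_dot(text: str) -> None:
    """Check the exported chart against the DOT line grammar this module
    emits (header, node/edge/attribute statements, closing brace).  Raises
    ValueError on the first offending line."""
    lines = text.rstrip("\n").split("\n")
    if not _DOT_HEADER.match(lines[0]):
        raise ValueError(f"bad header: {lines[0]!r}")
    if lines[-1] != "}":
        raise ValueError("missing closing brace")
    for ln in lines[1:-1]:
        if not (_DOT_NODE.match(ln) or _DOT_EDGE.match(ln) or _DOT_ATTR.match(ln)):
            raise ValueError(f"bad statement: {ln!r}")
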