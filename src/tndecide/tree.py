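"""Generic chance-tree representation with rollback evaluation.

Trees are immutable value structures; evaluation is pure, so the same tree
can be rolled back or sampled repeatedly (e.g. across probabilistic
sensitivity-analysis draws) without interference.

Branch probabilities at each chance node must sum to one.  Sums within
``RENORM_TOL`` of one (printed tables carry rounding) are silently
renormalized; larger deviations are validation errors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterator, Union

__all__ = [
    "TerminalNode",
    "Branch",
    "ChanceNode",
    "Node",
    "Path_",
    "PathSet",
    "ValidationReport",
    "TreeError",
    "validate_tree",
    "rollback",
    "enumerate_paths",
    "conditional_expectation",
    "tree_to_dict",
    "tree_from_dict",
    "save_tree",
    "load_tree",
]

#: deviation from unit probability sum tolerated (and renormalized away)
RENORM_TOL = 1e-6


class TreeError(ValueError):
    """Raised when an operation is attempted on an invalid tree."""


@dataclass(frozen=True)
class TerminalNode:
    """Leaf of the tree carrying the payoff (utility or QALYs) of one outcome."""

    payoff: float
    label: str = ""
    meta: Any = None


@dataclass(frozen=True)
class Branch:
    probability: float
    child: "Node"
    label: str = ""


@dataclass(frozen=True)
class ChanceNode:
    branches: tuple[Branch, ...]
    label: str = ""


Node = Union[TerminalNode, ChanceNode]


@dataclass(frozen=True)
class Path_:
    """One root-to-terminal path: product probability, payoff, branch labels."""

    probability: float
    payoff: float
    labels: tuple[str, ...]


@dataclass(frozen=True)
class PathSet:
    paths: tuple[Path_, ...]

    def expectation(self) -> float:
        return math.fsum(p.probability * p.payoff for p in self.paths)

    def total_probability(self) -> float:
        return math.fsum(p.probability for p in self.paths)

    def __iter__(self) -> Iterator[Path_]:
        return iter(self.paths)

    def __len__(self) -> int:
        return len(self.paths)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        return "valid tree" if self.ok else "; ".join(self.violations)


def validate_tree(root: Node) -> ValidationReport:
    """Check probability normalization, acyclicity and finite payoffs.

    Violations are collected into the report rather than raised, so a caller
    can present all problems at once.
    """
    report = ValidationReport()
    on_stack: set[int] = set()

    def visit(node: Node, where: str) -> None:
        if isinstance(node, TerminalNode):
            if not math.isfinite(node.payoff):
                report.violations.append(f"{where}: non-finite payoff {node.payoff!r}")
            return
        if not isinstance(node, ChanceNode):
            report.violations.append(f"{where}: unknown node type {type(node).__name__}")
            return
        if id(node) in on_stack:
            report.violations.append(f"{where}: cycle detected")
            return
        if not node.branches:
            report.violations.append(f"{where}: chance node with no branches")
            return
        total = math.fsum(b.probability for b in node.branches)
        for b in node.branches:
            if b.probability < 0:
                report.violations.append(
                    f"{where}: negative probability {b.probability!r} on branch {b.label!r}"
                )
        if abs(total - 1.0) > RENORM_TOL:
            report.violations.append(f"{where}: probabilities sum to {total:.6g}")
        on_stack.add(id(node))
        for i, b in enumerate(node.branches):
            visit(b.child, f"{where}/{b.label or i}")
        on_stack.discard(id(node))

    visit(root, "root")
    return report


def _norm_probs(node: ChanceNode) -> list[float]:
    total = math.fsum(b.probability for b in node.branches)
    if abs(total - 1.0) > RENORM_TOL:
        raise TreeError(
            f"chance node {node.label!r}: probabilities sum to {total:.6g} "
            f"(beyond renormalization tolerance {RENORM_TOL})"
        )
    return [b.probability / total for b in node.branches]


def rollback(root: Node, validate: bool = True) -> float:
    """Expected payoff of the tree: leaves up, probability-weighted sums.

    The workhorse of the whole model — the expected utility (or expected
    QALYs) of a strategy is the rollback value of its assembled tree.
    """
    if validate:
        report = validate_tree(root)
        if not report.ok:
            raise TreeError(f"invalid tree: {report}")
    cache: dict[int, float] = {}

    def value(node: Node) -> float:
        if isinstance(node, TerminalNode):
            return node.payoff
        got = cache.get(id(node))
        if got is not None:
            return got
        probs = _norm_probs(node)
        v = math.fsum(p * value(b.child) for p, b in zip(probs, node.branches))
        cache[id(node)] = v
        return v

    return value(root)


def enumerate_paths(root: Node, validate: bool = True) -> PathSet:
    """Exhaustive root-to-terminal path listing (brute-force oracle for rollback)."""
    if validate:
        report = validate_tree(root)
        if not report.ok:
            raise TreeError(f"invalid tree: {report}")
    out: list[Path_] = []

    def walk(node: Node, prob: float, labels: tuple[str, ...]) -> None:
        if isinstance(node, TerminalNode):
            final = labels + ((node.label,) if node.label else ())
            out.append(Path_(probability=prob, payoff=node.payoff, labels=final))
            return
        probs = _norm_probs(node)
        for p, b in zip(probs, node.branches):
            if p == 0.0:  # zero-probability branches carry no path mass
                continue
            walk(b.child, prob * p, labels + ((b.label,) if b.label else ()))

    walk(root, 1.0, ())
    return PathSet(paths=tuple(out))


def conditional_expectation(
    root: Node, predicate: Callable[[tuple[str, ...]], bool], validate: bool = True
) -> float:
    """Expected payoff restricted to paths whose labels satisfy ``predicate``.

    This is how sub-tree expected utilities (e.g. utility conditional on
    experiencing any complication) are read off the full tree.
    """
    paths = enumerate_paths(root, validate=validate)
    selected = [p for p in paths if predicate(p.labels)]
    total = math.fsum(p.probability for p in selected)
    if total <= 0.0:
        raise TreeError("predicate selects zero total probability")
    return math.fsum(p.probability * p.payoff for p in selected) / total


# ---------------------------------------------------------------------------
# JSON serialization (fixtures, CLI, debugging)
# ---------------------------------------------------------------------------

def tree_to_dict(node: Node) -> dict:
    if isinstance(node, TerminalNode):
        return {"kind": "terminal", "payoff": node.payoff, "label": node.label}
    return {
        "kind": "chance",
        "label": node.label,
        "branches": [
            {"probability": b.probability, "label": b.label, "child": tree_to_dict(b.child)}
            for b in node.branches
        ],
    }


def tree_from_dict(d: dict) -> Node:
    kind = d.get("kind")
    if kind == "terminal":
        return TerminalNode(payoff=float(d["payoff"]), label=d.get("label", ""))
    if kind == "chance":
        return ChanceNode(
            branches=tuple(
                Branch(
                    probability=float(b["probability"]),
                    child=tree_from_dict(b["child"]),
                    label=b.get("label", ""),
                )
                for b in d["branches"]
            ),
            label=d.get("label", ""),
        )
    raise TreeError(f"unknown node kind {kind!r}")


def save_tree(node: Node, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(node), indent=2) + "\n")


def load_tree(path: str | Path) -> Node:
    return tree_from_dict(json.loads(Path(path).read_text()))
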