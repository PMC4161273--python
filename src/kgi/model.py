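"""Arithmetic-node network models.

The classifiers evolved by this package are small "neural networks" in the
grammatical-evolution sense: expression trees whose internal nodes apply one
of four arithmetic activation functions to weighted inputs and whose leaves
reference named features of a knowledge matrix.  Node semantics:

``PADD``
    sum of the weighted inputs.
``PSUB``
    left-to-right sequential subtraction (``v1 - v2 - v3 ...``).
``PMULT``
    product of the weighted inputs.
``PDIV``
    left-to-right protected division: at each step a denominator with
    absolute value below :data:`DIV_EPSILON` makes the running value
    :data:`PROTECTED_VALUE` instead of dividing, keeping evaluation total.

The raw root value is squashed through the logistic function so every model
emits a score in (0, 1); classification thresholds that score (ties go to
the positive class).  Models serialize to a human-readable prefix notation,
e.g. ``PSUB(1.0*F1, -2.0*PDIV(1.0*F2, 1.0*F3))``, and the text round-trips
to a structurally identical tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Union

import numpy as np
from scipy.special import expit

ACTIVATIONS = ("PADD", "PSUB", "PMULT", "PDIV")

#: |denominator| below this triggers division protection.
DIV_EPSILON = 1e-8
#: value a protected division step yields.
PROTECTED_VALUE = 1.0
#: weighted terms and node outputs are clamped to +/- this bound, so no
#: combination of finite inputs can overflow to inf or cancel to NaN
VALUE_CLAMP = 1e100

# characters that cannot appear in a feature name (they are structural in
# the model text format)
_FORBIDDEN_IN_NAME = re.compile(r"[\s(),*]")


class ModelFormatError(ValueError):
    """Raised for malformed model text or invalid tree structure."""


def valid_feature_name(name: str) -> bool:
    """A feature name must be non-empty, not clash with an activation, not
    look like a number, and contain no structural characters."""
    if not name or name in ACTIVATIONS:
        return False
    if _FORBIDDEN_IN_NAME.search(name):
        return False
    try:
        float(name)
    except ValueError:
        return True
    return False


InputSource = Union[str, "Node"]


@dataclass
class Node:
    """One activation node: a function plus ≥2 weighted inputs."""

    function: str
    inputs: list[tuple[float, InputSource]]

    def __post_init__(self) -> None:
        if self.function not in ACTIVATIONS:
            raise ModelFormatError(f"unknown node function {self.function!r}")
        if len(self.inputs) < 2:
            raise ModelFormatError(
                f"{self.function} node needs >=2 inputs, got {len(self.inputs)}"
            )


@dataclass
class NetworkModel:
    """An evolved classifier: a finite tree of activation nodes."""

    root: Node

    @property
    def features_used(self) -> frozenset[str]:
        return frozenset(self._iter_features(self.root))

    @staticmethod
    def _iter_features(node: Node) -> Iterator[str]:
        for _, src in node.inputs:
            if isinstance(src, Node):
                yield from NetworkModel._iter_features(src)
            else:
                yield src

    def n_nodes(self) -> int:
        def count(node: Node) -> int:
            return 1 + sum(
                count(s) for _, s in node.inputs if isinstance(s, Node)
            )

        return count(self.root)

    def to_text(self) -> str:
        return model_to_text(self)

    @classmethod
    def from_text(cls, text: str) -> "NetworkModel":
        return model_from_text(text)


# ---------------------------------------------------------------------------
# evaluation


class MissingFeatureError(KeyError):
    """A model references a feature absent from the supplied values."""


def _combine(function: str, vals: list) -> np.ndarray | float:
    if function == "PADD":
        acc = vals[0]
        for v in vals[1:]:
            acc = acc + v
        return acc
    if function == "PSUB":
        acc = vals[0]
        for v in vals[1:]:
            acc = acc - v
        return acc
    if function == "PMULT":
        acc = vals[0]
        for v in vals[1:]:
            acc = acc * v
        return acc
    # PDIV: protected, left to right
    acc = vals[0]
    for d in vals[1:]:
        small = np.abs(d) < DIV_EPSILON
        safe = np.where(small, 1.0, d)
        acc = np.where(small, PROTECTED_VALUE, acc / safe)
    return acc


def _node_value(node: Node, lookup) -> np.ndarray | float:
    vals = []
    for w, src in node.inputs:
        v = _node_value(src, lookup) if isinstance(src, Node) else lookup(src)
        vals.append(np.clip(w * v, -VALUE_CLAMP, VALUE_CLAMP))
    return np.clip(_combine(node.function, vals), -VALUE_CLAMP, VALUE_CLAMP)


def raw_output(model: NetworkModel, columns: Mapping[str, np.ndarray]):
    """Root value of *model* over feature columns (vectorized over samples).

    ``columns`` maps feature name -> scalar or 1-D array; all arrays must
    share a length.  Missing features raise :class:`MissingFeatureError`.
    """

    def lookup(name: str):
        try:
            return columns[name]
        except KeyError:
            raise MissingFeatureError(name) from None

    return _node_value(model.root, lookup)


def evaluate_scores(model: NetworkModel, columns: Mapping[str, np.ndarray]) -> np.ndarray:
    """Logistic score in (0, 1) for every sample."""
    raw = np.asarray(raw_output(model, columns), dtype=float)
    s = expit(raw)
    # keep the open-interval contract even where expit saturates
    tiny = np.finfo(float).tiny
    return np.clip(s, tiny, 1.0 - np.finfo(float).epsneg)


def evaluate_network(model: NetworkModel, feature_row: Mapping[str, float]) -> float:
    """Score a single sample: logistic of the root value, in (0, 1)."""
    return float(evaluate_scores(model, feature_row))


def classify(score: float, threshold: float = 0.5) -> int:
    """1 iff score >= threshold (the tie goes to the positive class)."""
    return int(score >= threshold)


# ---------------------------------------------------------------------------
# text round-trip

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<punct>[(),*])"
    r"|(?P<number>-?(?:\d+\.\d*|\.\d+|\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[^\s(),*]+))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise ModelFormatError(f"cannot tokenize model text at offset {pos}")
        pos = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))
    return tokens


def model_to_text(model: NetworkModel) -> str:
    """Prefix-notation text; weights printed with full round-trip precision."""

    def render(node: Node) -> str:
        parts = []
        for w, src in node.inputs:
            s = render(src) if isinstance(src, Node) else src
            parts.append(f"{w!r}*{s}")
        return f"{node.function}({', '.join(parts)})"

    return render(model.root)


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def next(self):
        tok = self.peek()
        if tok[0] is None:
            raise ModelFormatError("unexpected end of model text")
        self.i += 1
        return tok

    def expect(self, value: str):
        kind, val = self.next()
        if val != value:
            raise ModelFormatError(f"expected {value!r}, got {val!r}")

    def parse_node(self) -> Node:
        kind, name = self.next()
        if kind != "name" or name not in ACTIVATIONS:
            raise ModelFormatError(f"unknown node function {name!r}")
        self.expect("(")
        inputs = [self.parse_input()]
        while self.peek()[1] == ",":
            self.next()
            inputs.append(self.parse_input())
        self.expect(")")
        return Node(name, inputs)

    def parse_input(self) -> tuple[float, InputSource]:
        kind, val = self.next()
        if kind != "number":
            raise ModelFormatError(f"expected a weight, got {val!r}")
        weight = float(val)
        self.expect("*")
        kind, val = self.peek()
        if kind == "name" and val in ACTIVATIONS:
            return weight, self.parse_node()
        kind, val = self.next()
        if kind != "name" or not valid_feature_name(val):
            raise ModelFormatError(f"invalid feature name {val!r}")
        return weight, val


def model_from_text(text: str) -> NetworkModel:
    parser = _Parser(_tokenize(text))
    root = parser.parse_node()
    if parser.peek()[0] is not None:
        raise ModelFormatError("trailing content after model text")
    return NetworkModel(root)
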