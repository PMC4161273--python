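"""BNF grammar and genotype→phenotype mapping for grammatical evolution.

A genome is a variable-length string of non-negative integer codons.  The
mapper performs a leftmost derivation from the grammar's start symbol: each
time a nonterminal with k > 1 alternatives is expanded, the next codon is
consumed and alternative ``codon mod k`` chosen; single-alternative rules
consume nothing.  When the codon pointer reaches the end of the genome it
wraps back to the start at most ``wrap_limit`` times; a derivation still
incomplete after that is a mapping failure (reported, never raised, so the
evolutionary loop stays total).

The canonical grammar generates the arithmetic-node networks of
:mod:`kgi.model`: 2- or 3-input nodes drawn from PADD/PSUB/PMULT/PDIV, each
input a constant weight times either a feature or a nested node.  Weights
are 1.0, -1.0 or a signed single-decimal constant d.d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import NetworkModel, classify, model_from_text, valid_feature_name

__all__ = [
    "Grammar",
    "Genome",
    "MappingOutcome",
    "GrammarError",
    "default_grammar",
    "map_genome",
    "genome_from_bits",
    "classify",
]

#: exclusive upper bound for codon values drawn at random (16-bit codons)
CODON_MAX = 65536
#: genome length bounds
MIN_GENOME_LEN, MAX_GENOME_LEN = 20, 400

# safety net against grammars whose zero-codon rules loop forever
_MAX_EXPANSIONS = 1_000_000


class GrammarError(ValueError):
    pass


@dataclass(frozen=True)
class Grammar:
    """Context-free grammar: productions map nonterminals to ordered
    alternatives, each alternative an ordered tuple of symbols.  A symbol
    with no production entry is a terminal."""

    start: str
    productions: dict[str, tuple[tuple[str, ...], ...]]

    def __post_init__(self) -> None:
        if self.start not in self.productions:
            raise GrammarError(f"start symbol {self.start!r} has no productions")
        for nt, alts in self.productions.items():
            if not alts:
                raise GrammarError(f"nonterminal {nt!r} has no alternatives")

    def is_nonterminal(self, symbol: str) -> bool:
        return symbol in self.productions

    def alternatives(self, symbol: str) -> tuple[tuple[str, ...], ...]:
        return self.productions[symbol]

    def to_bnf(self) -> str:
        """Plain-text BNF rendering (for docs and run manifests)."""
        lines = []
        for nt, alts in self.productions.items():
            rhs = " | ".join(" ".join(alt) for alt in alts)
            lines.append(f"{nt} ::= {rhs}")
        return "\n".join(lines)


@dataclass
class Genome:
    """Integer-codon genome; ``wrap_limit`` bounds pointer wrap-arounds."""

    codons: np.ndarray
    wrap_limit: int = 2

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=np.int64)
        if self.codons.ndim != 1 or self.codons.size == 0:
            raise GrammarError("genome must be a non-empty 1-D codon sequence")
        if (self.codons < 0).any():
            raise GrammarError("codons must be non-negative")
        if self.wrap_limit < 0:
            raise GrammarError("wrap_limit must be >= 0")

    def __len__(self) -> int:
        return int(self.codons.size)

    def to_text(self) -> str:
        return " ".join(str(int(c)) for c in self.codons)

    @classmethod
    def from_text(cls, text: str, wrap_limit: int = 2) -> "Genome":
        return cls(np.array([int(t) for t in text.split()]), wrap_limit)


@dataclass
class MappingOutcome:
    """Result of mapping a genome: a model, or None on failure."""

    model: Optional[NetworkModel]
    codons_consumed: int
    wrapped: int
    text: Optional[str] = None

    @property
    def success(self) -> bool:
        return self.model is not None


_DIGITS = tuple(str(i) for i in range(10))


def default_grammar(feature_ids: Sequence[str]) -> Grammar:
    """The canonical network grammar over the given feature names.

    ``<var>`` enumerates ``feature_ids`` in order, so the grammar is a
    function of the input matrix's columns.
    """
    feature_ids = list(feature_ids)
    if not feature_ids:
        raise GrammarError("need at least one feature")
    for f in feature_ids:
        if not valid_feature_name(f):
            raise GrammarError(f"invalid feature name {f!r}")
    productions = {
        "<net>": ((("<node>",),)),
        "<node>": (
            ("<func>", "(", "<in>", ",", "<in>", ")"),
            ("<func>", "(", "<in>", ",", "<in>", ",", "<in>", ")"),
        ),
        "<func>": (("PADD",), ("PSUB",), ("PMULT",), ("PDIV",)),
        "<in>": (("<w>", "*", "<var>"), ("<w>", "*", "<node>")),
        "<w>": (("1.0",), ("-1.0",), ("<d>", ".", "<d>"), ("-", "<d>", ".", "<d>")),
        "<d>": tuple((d,) for d in _DIGITS),
        "<var>": tuple((f,) for f in feature_ids),
    }
    # normalize the single-alternative start rule to the common shape
    productions["<net>"] = (("<node>",),)
    return Grammar("<net>", productions)


def map_genome(genome: Genome, grammar: Grammar) -> MappingOutcome:
    """Map codons to a model by modulo-choice leftmost derivation.

    Deterministic in (genome, grammar).  Returns a failure outcome (never
    raises) when the derivation is incomplete after ``wrap_limit`` wraps.
    """
    codons = genome.codons
    n = codons.size
    idx = 0
    wrapped = 0
    consumed = 0
    out: list[str] = []
    stack = [grammar.start]
    expansions = 0
    while stack:
        sym = stack.pop()
        if not grammar.is_nonterminal(sym):
            out.append(sym)
            continue
        expansions += 1
        if expansions > _MAX_EXPANSIONS:
            return MappingOutcome(None, consumed, wrapped)
        alts = grammar.alternatives(sym)
        if len(alts) == 1:
            choice = 0
        else:
            if idx == n:
                if wrapped == genome.wrap_limit:
                    return MappingOutcome(None, consumed, wrapped)
                wrapped += 1
                idx = 0
            choice = int(codons[idx]) % len(alts)
            idx += 1
            consumed += 1
        stack.extend(reversed(alts[choice]))
    text = "".join(out)
    model = model_from_text(text)
    return MappingOutcome(model, consumed, wrapped, text=model.to_text())


def genome_from_bits(bits: str, codon_bits: int = 8, wrap_limit: int = 2) -> Genome:
    """Read a binary-string genome as fixed-width integer codons.

    Provided because grammatical-evolution genomes are classically described
    as bit strings; under the modulo rule the two encodings are equivalent.
    """
    bits = bits.strip()
    if not bits or set(bits) - {"0", "1"}:
        raise GrammarError("bitstring must be non-empty over {0,1}")
    if len(bits) % codon_bits:
        raise GrammarError(
            f"bitstring length {len(bits)} not a multiple of codon_bits={codon_bits}"
        )
    codons = [
        int(bits[i : i + codon_bits], 2) for i in range(0, len(bits), codon_bits)
    ]
    return Genome(np.array(codons), wrap_limit)
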