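"""Independent test oracles.

These re-derive expected results by a different route from the library code
they check: a hard-coded recursive-descent genome mapper for the canonical
grammar, a double-loop gene-set aggregator, and a brute-force pairwise AUC.
They are deliberately slow and simple.
"""

from __future__ import annotations

import numpy as np

from kgi.model import NetworkModel, Node


class OracleMappingFailure(Exception):
    pass


class _CodonStream:
    def __init__(self, codons, wrap_limit):
        self.codons = [int(c) for c in codons]
        self.i = 0
        self.wrapped = 0
        self.wrap_limit = wrap_limit

    def next(self) -> int:
        if self.i == len(self.codons):
            if self.wrapped == self.wrap_limit:
                raise OracleMappingFailure
            self.wrapped += 1
            self.i = 0
        c = self.codons[self.i]
        self.i += 1
        return c


def oracle_map(codons, feature_ids, wrap_limit=2):
    """Recursive-descent mapping of the canonical grammar.

    Mirrors the grammar's leftmost derivation directly in code: one mod-k
    choice per multi-alternative rule, in derivation order.  Returns a
    NetworkModel, or None on failure.
    """
    s = _CodonStream(codons, wrap_limit)
    feats = list(feature_ids)

    def p_node() -> Node:
        arity = 2 + (s.next() % 2)
        func = ("PADD", "PSUB", "PMULT", "PDIV")[s.next() % 4]
        return Node(func, [p_in() for _ in range(arity)])

    def p_in():
        alt = s.next() % 2
        w = p_weight()
        if alt == 0:
            src = feats[s.next() % len(feats)] if len(feats) > 1 else feats[0]
        else:
            src = p_node()
        return (w, src)

    def p_weight() -> float:
        alt = s.next() % 4
        if alt == 0:
            return 1.0
        if alt == 1:
            return -1.0
        if alt == 2:
            return float(f"{s.next() % 10}.{s.next() % 10}")
        return float(f"-{s.next() % 10}.{s.next() % 10}")

    try:
        return NetworkModel(p_node())
    except OracleMappingFailure:
        return None


def oracle_knowledge_matrix(expr_values, gene_ids, sets):
    """Per-sample/per-set double-loop mean aggregation."""
    col = {g: j for j, g in enumerate(gene_ids)}
    n = expr_values.shape[0]
    out = np.zeros((n, len(sets)))
    for k, (_, genes) in enumerate(sets.items()):
        for i in range(n):
            total = 0.0
            for g in genes:
                total += expr_values[i, col[g]]
            out[i, k] = total / len(genes)
    return out


def oracle_auc(scores, labels):
    """Brute-force over all positive/negative pairs, ties count one half."""
    scores = list(map(float, scores))
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
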