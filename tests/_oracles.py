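"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the package's own code paths: explicit frequency
tables for the information measures, exhaustive recoverability checks for
merge loss, and full ancestor enumeration for MICA discovery.
"""

from __future__ import annotations

import math
from fractions import Fraction


def brute_entropy(values: list) -> float:
    """Shannon entropy from an explicit frequency table (no missing values)."""
    n = len(values)
    if n == 0:
        return 0.0
    freq: dict = {}
    for v in values:
        freq[v] = freq.get(v, 0) + 1
    total = 0.0
    for c in freq.values():
        p = Fraction(c, n)
        total -= float(p) * math.log2(float(p))
    return total


def brute_mutual_information(xs: list, ys: list) -> float:
    """Plug-in MI from explicit joint and marginal tables, base 2."""
    n = len(xs)
    assert n == len(ys) and n > 0
    joint: dict = {}
    mx: dict = {}
    my: dict = {}
    for a, b in zip(xs, ys):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        mx[a] = mx.get(a, 0) + 1
        my[b] = my.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log2(p_ab * n * n / (mx[a] * my[b]))
    return mi


def recoverable(xs: list, ms: list) -> bool:
    """True iff x is a deterministic function of the merged values on the
    observed pairs (i.e. no merged value maps back to two x values)."""
    back: dict = {}
    for x, m in zip(xs, ms):
        if m in back and back[m] != x:
            return False
        back[m] = x
    return True


def brute_variable_sets(edges: list[tuple], mapping: list[tuple],
                        node_ic: dict) -> dict:
    """Enumerate every ontology node's variable-descendant set and pick the
    max-IC representative per distinct set of size >= 2.

    *edges* are (child, parent) ontology pairs; *mapping* are
    (variable, entity) pairs.  Ties broken by greater depth then smaller id,
    mirroring the declared convention.  Returns {frozenset_of_variables:
    mica_node}.
    """
    nodes = sorted({x for e in edges for x in e})
    children: dict = {v: set() for v in nodes}
    parents: dict = {v: set() for v in nodes}
    for child, parent in edges:
        children[parent].add(child)
        parents[child].add(parent)

    def descendants(node) -> set:
        out, stack = set(), [node]
        while stack:
            cur = stack.pop()
            for ch in children[cur]:
                if ch not in out:
                    out.add(ch)
                    stack.append(ch)
        return out

    depth: dict = {}

    def get_depth(node) -> int:
        if node not in depth:
            ps = parents[node]
            depth[node] = 1 if not ps else 1 + max(get_depth(p) for p in ps)
        return depth[node]

    entity_vars: dict = {}
    for var, entity in mapping:
        entity_vars.setdefault(entity, set()).add(var)

    var_sets: dict = {}
    for node in nodes:
        covered = set(entity_vars.get(node, set()))
        for d in descendants(node):
            covered |= entity_vars.get(d, set())
        if len(covered) >= 2:
            var_sets.setdefault(frozenset(covered), []).append(node)

    result = {}
    for vs, candidates in var_sets.items():
        best = min(candidates,
                   key=lambda c: (-node_ic[c], -get_depth(c), str(c)))
        result[vs] = best
    return result
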