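"""Independent brute-force oracles for the configurational engine.

Everything here is deliberately written with plain Python sets and
generate-and-filter enumeration — no reuse of the package's scanning,
bit-mask or minimality machinery — so the tests compare two independent
routes to the same definitions.
"""

from __future__ import annotations

import itertools

import geocna as g


def ext_of(conj: dict[str, frozenset[int]], table: g.CaseTable) -> set[str]:
    """Cases whose level lies in the accepted set for every factor."""
    out = set()
    for cid, row in table.levels.iterrows():
        if all(int(row[f]) in lv for f, lv in conj.items()):
            out.add(cid)
    return out


def outcome_ext(outcome: g.Literal, table: g.CaseTable) -> set[str]:
    return ext_of({outcome.factor: outcome.levels}, table)


def all_conjunctions(table: g.CaseTable, outcome: g.Literal, max_order: int):
    """Every conjunction (dict factor -> accepted set) up to max_order with
    non-empty, non-full accepted sets over non-outcome factors."""
    factors = [f for f in table.factors if f != outcome.factor]
    per_factor = {}
    for f in factors:
        dom = sorted(table.domain(f))
        subsets = []
        for r in range(1, len(dom)):
            subsets.extend(frozenset(c) for c in itertools.combinations(dom, r))
        per_factor[f] = subsets
    for k in range(1, max_order + 1):
        for fs in itertools.combinations(factors, k):
            for choice in itertools.product(*(per_factor[f] for f in fs)):
                yield dict(zip(fs, choice))


def subsumes(weaker: dict, stronger: dict) -> bool:
    """True if ``weaker`` is a proper simplification of ``stronger``: its
    factors are a subset and each accepted set is a superset."""
    if weaker == stronger:
        return False
    if not set(weaker) <= set(stronger):
        return False
    return all(weaker[f] >= stronger[f] for f in weaker)


def brute_msc(table: g.CaseTable, outcome: g.Literal, max_order: int,
              threshold: float) -> set[tuple]:
    """All minimally sufficient conditions as canonical keys
    ``((factor, levels-tuple), ...)`` sorted by factor."""
    y = outcome_ext(outcome, table)
    sufficient = []
    for conj in all_conjunctions(table, outcome, max_order):
        e = ext_of(conj, table)
        if not e:
            continue
        if len(e & y) / len(e) + 1e-9 >= threshold:
            sufficient.append(conj)
    minimal = set()
    for conj in sufficient:
        if not any(subsumes(other, conj) for other in sufficient):
            minimal.add(key_of(conj))
    return minimal


def key_of(conj: dict) -> tuple:
    return tuple(sorted((f, tuple(sorted(lv))) for f, lv in conj.items()))


def row_key(row: g.ConditionRow) -> tuple:
    return tuple(
        sorted((l.factor, tuple(sorted(l.levels))) for l in row.conjunction.literals)
    )


def brute_candidates(msc_keys: list[tuple], table: g.CaseTable,
                     outcome: g.Literal, con: float, cov: float,
                     max_disjuncts: int) -> set[tuple]:
    """All redundancy-free disjunctions of MSC rows meeting both thresholds,
    as frozensets of conjunction keys."""
    y = outcome_ext(outcome, table)
    exts = {k: ext_of({f: frozenset(lv) for f, lv in k}, table) for k in msc_keys}
    found = set()
    for k in range(1, max_disjuncts + 1):
        for combo in itertools.combinations(msc_keys, k):
            union = set().union(*(exts[c] for c in combo))
            overlap = union & y
            if len(overlap) / len(y) + 1e-9 < cov:
                continue
            if len(overlap) / len(union) + 1e-9 < con:
                continue
            ok = True
            for c in combo:
                rest = set().union(*(exts[d] & y for d in combo if d != c)) \
                    if k > 1 else set()
                if k > 1 and not ((exts[c] & y) - rest):
                    ok = False
                    break
            if ok:
                found.add(frozenset(combo))
    return found


def formula_key(model: g.SolutionFormula) -> frozenset:
    return frozenset(
        tuple(sorted((l.factor, tuple(sorted(l.levels))) for l in c.literals))
        for c in model.disjuncts
    )
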