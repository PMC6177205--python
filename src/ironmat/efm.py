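"""Elementary flux mode enumeration and per-Cmole yield extraction.

An elementary flux mode (EFM) is a minimal, indecomposable steady-state flux
distribution: ``S v = 0`` over internal metabolites, irreversible fluxes
non-negative, and no other steady-state vector has a strictly smaller support.
Every steady-state flux distribution is a non-negative combination of EFMs,
which makes the EFM set a complete catalogue of the qualitatively distinct
routes an organism can run.

The enumerator uses the classical tableau (double-description) algorithm on
exact rational arithmetic: reversible reactions are split into forward and
backward halves, metabolite constraints are processed one at a time, opposite
-sign row pairs are combined subject to the combinatorial adjacency test, and
the spurious forward+backward two-cycles are discarded at the end.  A brute
-force extreme-ray oracle (exhaustive support-subset rank test) is provided
for independent verification on small networks.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from fractions import Fraction

from ._rational import rank as _rank, solve_homogeneous_ray
from .network import MetabolicNetwork, stoichiometric_matrix

__all__ = [
    "FluxMode",
    "YieldPoint",
    "EFMBudgetError",
    "enumerate_efms",
    "brute_force_extreme_rays",
    "apply_regulatory_rules",
    "mode_yields",
    "limitation_optima",
]


class EFMBudgetError(Exception):
    """The intermediate ray count exceeded the combinatorial budget."""

    def __init__(self, n_rays: int, budget: int, n_constraints_done: int):
        self.n_rays = n_rays
        self.budget = budget
        self.n_constraints_done = n_constraints_done
        super().__init__(
            f"enumeration exceeded budget: {n_rays} intermediate rays > {budget} "
            f"after {n_constraints_done} metabolite constraints"
        )


@dataclass(frozen=True)
class FluxMode:
    """One elementary mode; ``flux`` maps reaction id -> exact rational flux."""

    flux: dict[str, Fraction]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(r for r, v in self.flux.items() if v != 0)

    def normalized(self) -> "FluxMode":
        """Scale so the largest absolute flux equals 1 (canonical form)."""
        mx = max((abs(v) for v in self.flux.values() if v != 0), default=Fraction(1))
        return FluxMode({r: v / mx for r, v in self.flux.items()})

    def scaled_to(self, rid: str, value: Fraction) -> "FluxMode":
        f = self.flux[rid]
        if f == 0:
            raise ValueError(f"mode carries no flux through {rid}")
        s = value / f
        return FluxMode({r: v * s for r, v in self.flux.items()})

    def _key(self, order: list[str]):
        idx = {r: i for i, r in enumerate(order)}
        supp = tuple(sorted(idx[r] for r in self.support))
        vals = tuple(self.flux.get(r, Fraction(0)) for r in order)
        return (supp, vals)


def _split_columns(net: MetabolicNetwork):
    """Column list [(reaction_id, direction)] after splitting reversibles."""
    cols = []
    for r in net.reactions:
        cols.append((r.id, +1))
        if r.reversible:
            cols.append((r.id, -1))
    return cols


def _split_matrix(net: MetabolicNetwork, cols) -> list[list[Fraction]]:
    S = stoichiometric_matrix(net, internal_only=True)
    rows = []
    for mid in S.index:
        row = []
        for rid, direction in cols:
            row.append(direction * S.at[mid, rid])
        rows.append(row)
    return rows


def _collapse(vec: list[Fraction], cols) -> dict[str, Fraction] | None:
    """Map a split-space ray back to signed fluxes; None for pure 2-cycles."""
    flux: dict[str, Fraction] = {}
    for (rid, direction), v in zip(cols, vec):
        if v != 0:
            flux[rid] = flux.get(rid, Fraction(0)) + direction * v
    flux = {r: v for r, v in flux.items() if v != 0}
    if not flux:
        return None  # forward+backward of the same reaction(s) cancelled
    return flux


def _canonical(modes: list[FluxMode], order: list[str]) -> list[FluxMode]:
    normed = {}
    for m in modes:
        n = m.normalized()
        normed[n._key(order)] = n
    return [normed[k] for k in sorted(normed)]


def enumerate_efms(net: MetabolicNetwork, budget: int = 5_000_000) -> list[FluxMode]:
    """All elementary flux modes of ``net`` in canonical order.

    Modes are normalized to max-|flux| = 1 and ordered lexicographically by
    support (reaction order of the network).  Raises :class:`EFMBudgetError`
    if the intermediate ray count exceeds ``budget``.
    """
    cols = _split_columns(net)
    if not cols:
        return []
    S = _split_matrix(net, cols)
    n = len(cols)
    # tableau rows: (flux part, remaining-constraint part)
    rows: list[tuple[list[Fraction], list[Fraction]]] = []
    for j in range(n):
        unit = [Fraction(i == j) for i in range(n)]
        tail = [S[i][j] for i in range(len(S))]
        rows.append((unit, tail))

    for k in range(len(S)):
        zero, pos, neg = [], [], []
        for row in rows:
            t = row[1][k]
            (zero if t == 0 else pos if t > 0 else neg).append(row)
        supports = {id(r): frozenset(i for i, v in enumerate(r[0]) if v != 0) for r in rows}
        new_rows = list(zero)
        for p, q in itertools.product(pos, neg):
            union = supports[id(p)] | supports[id(q)]
            # adjacency: no third tableau row's support fits inside the union
            minimal = True
            for r in rows:
                if r is p or r is q:
                    continue
                if supports[id(r)] <= union:
                    minimal = False
                    break
            if not minimal:
                continue
            a, b = -q[1][k], p[1][k]  # a,b > 0
            flux = [a * x + b * y for x, y in zip(p[0], q[0])]
            tail = [a * x + b * y for x, y in zip(p[1], q[1])]
            new_rows.append((flux, tail))
        if len(new_rows) > budget:
            raise EFMBudgetError(len(new_rows), budget, k)
        rows = new_rows

    # final exact minimality filter (duplicates/supersets from the tableau)
    modes: list[FluxMode] = []
    supp = [frozenset(i for i, v in enumerate(r[0]) if v != 0) for r in rows]
    keep = []
    for i, si in enumerate(supp):
        if not si:
            continue
        if any(sj < si for j, sj in enumerate(supp) if j != i):
            continue
        keep.append(i)
    seen = set()
    for i in keep:
        flux = _collapse(rows[i][0], cols)
        if flux is None:
            continue
        m = FluxMode(flux).normalized()
        key = m._key(net.reaction_ids)
        if key not in seen:
            seen.add(key)
            modes.append(m)
    return _canonical(modes, net.reaction_ids)


def brute_force_extreme_rays(
    net: MetabolicNetwork, max_split_columns: int = 16
) -> list[FluxMode]:
    """Independent oracle: extreme rays of {v : S v = 0, v >= 0} by exhaustive
    support-subset testing.

    A support J carries an extreme ray iff rank(S[:, J]) == |J| - 1 and the
    one-dimensional kernel has a strictly positive generator on J.  Refuses
    networks with more than ``max_split_columns`` columns after splitting.
    """
    cols = _split_columns(net)
    if len(cols) > max_split_columns:
        raise ValueError(
            f"{len(cols)} split columns exceed the brute-force guard "
            f"({max_split_columns})"
        )
    S = _split_matrix(net, cols)
    nrows = len(S)
    ncols = len(cols)
    pair = {}
    for i, (rid, d) in enumerate(cols):
        for j, (rid2, d2) in enumerate(cols):
            if rid == rid2 and d == 1 and d2 == -1:
                pair[i] = j
    modes = []
    for size in range(1, ncols + 1):
        for J in itertools.combinations(range(ncols), size):
            Jset = set(J)
            if any(i in Jset and j in Jset for i, j in pair.items()):
                continue  # both halves of one reversible reaction: 2-cycle
            sub = [[S[r][c] for c in J] for r in range(nrows)]
            if _rank(sub) != size - 1:
                continue
            ray = solve_homogeneous_ray(sub)
            if ray is None:
                continue
            if any(v == 0 for v in ray):
                continue  # true support is smaller; found at its own subset
            if all(v > 0 for v in ray):
                pass
            elif all(v < 0 for v in ray):
                ray = [-v for v in ray]
            else:
                continue
            vec = [Fraction(0)] * ncols
            for c, v in zip(J, ray):
                vec[c] = v
            flux = _collapse(vec, cols)
            if flux is not None:
                modes.append(FluxMode(flux))
    return _canonical(modes, net.reaction_ids)


# ---------------------------------------------------------------------------
# gene-regulatory rule pruning
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|\bAND\b|\bOR\b|\bNOT\b|[A-Za-z_][\w.+-]*", re.I)


class _RuleParser:
    """Recursive-descent parser for Boolean rules over reaction-activity
    literals: ``NOT (R1 AND R2) OR R3``."""

    def __init__(self, text: str):
        self.tokens = _TOKEN_RE.findall(text)
        if "".join(self.tokens).replace(" ", "") != text.replace(" ", ""):
            raise ValueError(f"cannot tokenize rule {text!r}")
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        node = self._or()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens at {self.peek()!r}")
        return node

    def _or(self):
        left = self._and()
        while self.peek() and self.peek().upper() == "OR":
            self.next()
            right = self._and()
            left = ("or", left, right)
        return left

    def _and(self):
        left = self._not()
        while self.peek() and self.peek().upper() == "AND":
            self.next()
            right = self._not()
            left = ("and", left, right)
        return left

    def _not(self):
        if self.peek() and self.peek().upper() == "NOT":
            self.next()
            return ("not", self._not())
        return self._atom()

    def _atom(self):
        tok = self.next()
        if tok == "(":
            node = self._or()
            if self.next() != ")":
                raise ValueError("unbalanced parenthesis")
            return node
        if tok is None or tok in (")", "("):
            raise ValueError("malformed rule")
        return ("lit", tok)


def parse_rule(text: str):
    return _RuleParser(text).parse()


def _eval_rule(node, active: frozenset[str]) -> bool:
    op = node[0]
    if op == "lit":
        return node[1] in active
    if op == "not":
        return not _eval_rule(node[1], active)
    if op == "and":
        return _eval_rule(node[1], active) and _eval_rule(node[2], active)
    if op == "or":
        return _eval_rule(node[1], active) or _eval_rule(node[2], active)
    raise AssertionError(op)


def _rule_literals(node) -> set[str]:
    if node[0] == "lit":
        return {node[1]}
    return set().union(*(_rule_literals(c) for c in node[1:]))


def apply_regulatory_rules(
    modes: list[FluxMode],
    rules: list[str],
    known_reactions: set[str] | None = None,
) -> list[FluxMode]:
    """Keep only modes whose activity pattern satisfies every Boolean rule.

    A reaction is "active" in a mode iff it is in the mode's support.  Unknown
    reaction ids in a rule raise ``ValueError`` (pass ``known_reactions`` to
    enable the check against a network rather than the mode set).
    """
    if not rules:
        return list(modes)
    parsed = [parse_rule(r) for r in rules]
    if known_reactions is not None:
        for text, node in zip(rules, parsed):
            unknown = sorted(_rule_literals(node) - set(known_reactions))
            if unknown:
                raise ValueError(f"rule {text!r} references unknown reactions: {unknown}")
    out = []
    for m in modes:
        act = m.support
        if all(_eval_rule(p, act) for p in parsed):
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# yields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class YieldPoint:
    """Resource requirements of one biomass-producing mode, per Cmole biomass."""

    donor_id: str
    donor_per_cmol_biomass: float
    o2_per_cmol_biomass: float
    mode_id: int


def mode_yields(
    modes: list[FluxMode],
    biomass_rxn: str,
    biomass_cmol_per_flux_unit: float,
    donor_exchanges: dict[str, str],
    o2_exchange: str,
) -> tuple[list[YieldPoint], int]:
    """Per-Cmole donor and O2 requirements of each biomass-producing mode.

    Returns ``(points, n_skipped)`` where skipped modes carry no biomass flux.
    Yield values are invariant to positive rescaling of a mode.  Modes drawing
    on several donors at once are labelled ``"mixed"`` with summed donor moles.
    """
    if biomass_cmol_per_flux_unit <= 0:
        raise ValueError("biomass_cmol_per_flux_unit must be positive")
    points: list[YieldPoint] = []
    skipped = 0
    for i, m in enumerate(modes):
        b = m.flux.get(biomass_rxn, Fraction(0))
        if b <= 0:
            skipped += 1
            continue
        cmol = b * as_frac(biomass_cmol_per_flux_unit)
        active = [
            (donor, abs(m.flux[rid]))
            for donor, rid in donor_exchanges.items()
            if m.flux.get(rid, Fraction(0)) != 0
        ]
        if not active:
            donor_id, donor_amt = "none", Fraction(0)
        elif len(active) == 1:
            donor_id, donor_amt = active[0]
        else:
            donor_id = "mixed"
            donor_amt = sum((a for _, a in active), Fraction(0))
        o2 = abs(m.flux.get(o2_exchange, Fraction(0)))
        points.append(
            YieldPoint(
                donor_id=donor_id,
                donor_per_cmol_biomass=float(donor_amt / cmol),
                o2_per_cmol_biomass=float(o2 / cmol),
                mode_id=i,
            )
        )
    return points, skipped


def as_frac(x) -> Fraction:
    from ._rational import as_fraction

    return as_fraction(x)


def limitation_optima(points: list[YieldPoint], resource: str) -> YieldPoint:
    """The yield point minimizing the named resource per Cmole biomass.

    ``resource`` is ``"oxygen"`` or ``"carbon"``/``"donor"`` (the latter two
    both minimize the donor requirement; "carbon" is the conventional name
    when the donor is an organic substrate).  Ties are broken by the other
    resource, then by mode id.
    """
    if not points:
        raise ValueError("empty yield list")
    if resource == "oxygen":
        key = lambda p: (p.o2_per_cmol_biomass, p.donor_per_cmol_biomass, p.mode_id)
    elif resource in ("carbon", "donor"):
        key = lambda p: (p.donor_per_cmol_biomass, p.o2_per_cmol_biomass, p.mode_id)
    else:
        raise ValueError(f"unknown resource {resource!r}")
    return min(points, key=key)
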