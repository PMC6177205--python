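"""Stoichiometric network data model and I/O.

A :class:`MetabolicNetwork` is the common currency of the package: a list of
metabolites (internal or external/boundary), an ordered list of reactions with
exact rational stoichiometry, optional Boolean gene-regulatory rules, and a
designated biomass reaction.  Networks can be read from a plain tabular (TSV)
dialect or from SBML Level 2/3 files (``boundaryCondition``/``constant``
species are treated as external).

Sign convention: negative stoichiometric coefficients consume, positive
produce.  External metabolites are excluded from the steady-state constraint;
exchange with the environment is modeled by the boundary flag rather than by
explicit exchange fluxes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from ._rational import as_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "NetworkError",
    "FormatError",
    "ValidationError",
    "ValidationReport",
    "load_network",
    "write_network",
    "stoichiometric_matrix",
    "validate_network",
    "compress_network",
]


class NetworkError(Exception):
    """Base class for network construction/IO problems."""


class FormatError(NetworkError):
    """A file could not be parsed in the named dialect."""


class ValidationError(NetworkError):
    """The parsed network violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    is_external: bool = False
    carbon_atoms: int | None = None  # None = unknown


@dataclass
class Reaction:
    id: str
    stoich: dict[str, Fraction]
    reversible: bool = False
    is_exchange: bool = False
    gene_rule: str | None = None

    def __post_init__(self) -> None:
        self.stoich = {m: as_fraction(c) for m, c in self.stoich.items()}
        if not self.stoich:
            raise ValidationError(f"reaction {self.id!r}: empty stoichiometry")
        zero = [m for m, c in self.stoich.items() if c == 0]
        if zero:
            raise ValidationError(f"reaction {self.id!r}: zero coefficient for {zero}")


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ValidationError(f"duplicate reaction ids: {dup}")
        declared = set(met_ids)
        for r in self.reactions:
            missing = sorted(set(r.stoich) - declared)
            if missing:
                raise ValidationError(
                    f"reaction {r.id!r} references undeclared metabolites: {missing}"
                )
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in set(rxn_ids):
            raise ValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not present in network"
            )
        ext = {m.id for m in self.metabolites if m.is_external}
        for r in self.reactions:
            if r.is_exchange and not (set(r.stoich) & ext):
                raise ValidationError(
                    f"exchange reaction {r.id!r} touches no external metabolite"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.is_external]


# ---------------------------------------------------------------------------
# equation strings
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?(?:/\d+)?)\s+)?(\S+)\s*$")


def parse_equation(eq: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``"2 A + B -> C"`` / ``"A <=> B"`` into (stoich, reversible)."""
    if "<=>" in eq:
        lhs, rhs = eq.split("<=>")
        reversible = True
    elif "->" in eq:
        lhs, rhs = eq.split("->")
        reversible = False
    else:
        raise FormatError(f"equation {eq!r}: no '->' or '<=>' arrow")
    stoich: dict[str, Fraction] = {}

    def add(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            m = _TERM_RE.match(term)
            if not m:
                raise FormatError(f"equation {eq!r}: cannot parse term {term!r}")
            coeff = as_fraction(m.group(1)) if m.group(1) else Fraction(1)
            met = m.group(2)
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff
    add(lhs, -1)
    add(rhs, +1)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise FormatError(f"equation {eq!r}: empty after cancellation")
    return stoich, reversible


def format_equation(r: Reaction) -> str:
    def side(items):
        parts = []
        for m, c in items:
            c = abs(c)
            parts.append(m if c == 1 else f"{c} {m}")
        return " + ".join(parts)

    lhs = [(m, c) for m, c in r.stoich.items() if c < 0]
    rhs = [(m, c) for m, c in r.stoich.items() if c > 0]
    arrow = "<=>" if r.reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------
#
# One UTF-8 TSV file with two blocks, each introduced by a section line:
#
#   ## metabolites
#   id  name  external  carbon_atoms
#   ...
#   ## reactions
#   id  equation  reversible  exchange  gene_rule
#   ...
#
# Boolean columns accept 0/1/true/false; carbon_atoms may be blank (unknown).

_MET_COLS = ["id", "name", "external", "carbon_atoms"]
_RXN_COLS = ["id", "equation", "reversible", "exchange", "gene_rule"]


def _parse_bool(s: str, where: str) -> bool:
    s = s.strip().lower()
    if s in {"1", "true", "yes"}:
        return True
    if s in {"0", "false", "no", ""}:
        return False
    raise FormatError(f"{where}: bad boolean {s!r}")


def load_tabular(path: str | Path, biomass_reaction: str | None = None) -> MetabolicNetwork:
    path = Path(path)
    sections: dict[str, list[tuple[int, list[str]]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#") and not line.lstrip().startswith("##"):
            continue
        if line.lstrip().startswith("##"):
            current = line.lstrip("#").strip().lower()
            sections[current] = []
            continue
        if current is None:
            raise FormatError(f"{path}:{lineno}: data before any '## section' line")
        sections[current].append((lineno, line.split("\t")))
    for needed in ("metabolites", "reactions"):
        if needed not in sections or not sections[needed]:
            raise FormatError(f"{path}: missing '## {needed}' section")

    def rows(section: str, cols: list[str]):
        lineno, header = sections[section][0]
        if [h.strip() for h in header[: len(cols)]] != cols:
            raise FormatError(
                f"{path}:{lineno}: '{section}' header must be {cols}, got {header}"
            )
        for lineno, cells in sections[section][1:]:
            cells = cells + [""] * (len(cols) - len(cells))
            yield lineno, dict(zip(cols, (c.strip() for c in cells)))

    mets = []
    for lineno, rec in rows("metabolites", _MET_COLS):
        carbon = rec["carbon_atoms"]
        mets.append(
            Metabolite(
                id=rec["id"],
                name=rec["name"],
                is_external=_parse_bool(rec["external"], f"{path}:{lineno}"),
                carbon_atoms=int(carbon) if carbon else None,
            )
        )
    rxns = []
    for lineno, rec in rows("reactions", _RXN_COLS):
        try:
            stoich, rev_from_eq = parse_equation(rec["equation"])
        except FormatError as e:
            raise FormatError(f"{path}:{lineno}: {e}") from e
        rev = _parse_bool(rec["reversible"], f"{path}:{lineno}") or rev_from_eq
        rxns.append(
            Reaction(
                id=rec["id"],
                stoich=stoich,
                reversible=rev,
                is_exchange=_parse_bool(rec["exchange"], f"{path}:{lineno}"),
                gene_rule=rec["gene_rule"] or None,
            )
        )
    if biomass_reaction is None:
        candidates = [r.id for r in rxns if "biomass" in r.id.lower()]
        biomass_reaction = candidates[0] if candidates else None
    return MetabolicNetwork(mets, rxns, biomass_reaction)


def write_network(net: MetabolicNetwork, path: str | Path) -> None:
    """Write the tabular dialect; ``load_tabular`` round-trips exactly."""
    lines = ["## metabolites", "\t".join(_MET_COLS)]
    for m in net.metabolites:
        lines.append(
            "\t".join(
                [m.id, m.name, "1" if m.is_external else "0",
                 "" if m.carbon_atoms is None else str(m.carbon_atoms)]
            )
        )
    lines += ["## reactions", "\t".join(_RXN_COLS)]
    for r in net.reactions:
        lines.append(
            "\t".join(
                [r.id, format_equation(r), "1" if r.reversible else "0",
                 "1" if r.is_exchange else "0", r.gene_rule or ""]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# SBML import
# ---------------------------------------------------------------------------

def load_sbml(path: str | Path, biomass_reaction: str | None = None) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise FormatError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    model = doc.getModel()
    if model is None:
        raise FormatError(f"{path}: no <model> element")

    mets = []
    n_boundary = 0
    for sp in model.getListOfSpecies():
        external = bool(sp.getBoundaryCondition()) or bool(
            sp.isSetConstant() and sp.getConstant()
        )
        n_boundary += external
        mets.append(Metabolite(id=sp.getId(), name=sp.getName() or "", is_external=external))
    rxns = []
    ext_ids = {m.id for m in mets if m.is_external}
    for rx in model.getListOfReactions():
        stoich: dict[str, Fraction] = {}
        for ref in rx.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) - as_fraction(
                ref.getStoichiometry()
            )
        for ref in rx.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) + as_fraction(
                ref.getStoichiometry()
            )
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            logger.warning("SBML reaction %s has empty net stoichiometry; skipped", rx.getId())
            continue
        rxns.append(
            Reaction(
                id=rx.getId(),
                stoich=stoich,
                reversible=bool(rx.getReversible()),
                is_exchange=bool(set(stoich) & ext_ids),
            )
        )
    # Surface (do not silently normalize) the boundary interpretation.
    logger.info(
        "SBML import of %s: %d species (%d boundary -> external), %d reactions; "
        "external status taken from boundaryCondition/constant flags",
        path, len(mets), n_boundary, len(rxns),
    )
    if biomass_reaction is None:
        candidates = [r.id for r in rxns if "biomass" in r.id.lower()]
        biomass_reaction = candidates[0] if candidates else None
    net = MetabolicNetwork(mets, rxns, biomass_reaction)
    net.notes["sbml_boundary_species"] = n_boundary
    return net


def load_network(
    path: str | Path,
    format: str = "tabular",
    biomass_reaction: str | None = None,
) -> MetabolicNetwork:
    """Load a network from ``tabular`` (TSV dialect) or ``sbml`` files."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        return load_tabular(path, biomass_reaction)
    if format == "sbml":
        return load_sbml(path, biomass_reaction)
    raise ValueError(f"unknown format {format!r} (expected 'tabular' or 'sbml')")


# ---------------------------------------------------------------------------
# stoichiometric matrix
# ---------------------------------------------------------------------------

def stoichiometric_matrix(
    net: MetabolicNetwork, internal_only: bool = True, dtype: str = "fraction"
) -> pd.DataFrame:
    """S matrix as a DataFrame (rows = metabolites, columns = reactions).

    ``dtype="fraction"`` keeps exact rationals (object dtype); ``"float"``
    returns float64 for numeric work.
    """
    if not net.reactions:
        raise ValidationError("no reactions")
    mids = net.internal_metabolite_ids if internal_only else net.metabolite_ids
    data = {}
    for r in net.reactions:
        col = [r.stoich.get(m, Fraction(0)) for m in mids]
        data[r.id] = col
    df = pd.DataFrame(data, index=mids, dtype=object)
    if dtype == "float":
        return df.astype(float)
    return df


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    carbon_imbalance: dict[str, Fraction]   # reaction id -> residual (consumed - produced C)
    dead_end_metabolites: list[str]
    blocked_reactions: list[str]

    @property
    def issues(self) -> list[str]:
        out = [f"carbon imbalance in {r}: residual {v}" for r, v in self.carbon_imbalance.items()]
        out += [f"dead-end metabolite: {m}" for m in self.dead_end_metabolites]
        out += [f"blocked reaction: {r}" for r in self.blocked_reactions]
        return out

    @property
    def ok(self) -> bool:
        return not self.issues


def _flux_range(net: MetabolicNetwork, rid: str, bound: float = 1000.0) -> tuple[float, float]:
    """Min/max steady-state flux of one reaction with |v| <= bound (LP)."""
    S = stoichiometric_matrix(net, internal_only=True, dtype="float")
    A_eq = S.to_numpy()
    n = len(net.reactions)
    b_eq = np.zeros(A_eq.shape[0])
    bounds = [
        (-bound, bound) if r.reversible else (0.0, bound) for r in net.reactions
    ]
    j = net.reaction_ids.index(rid)
    out = []
    for sign in (+1.0, -1.0):
        c = np.zeros(n)
        c[j] = sign
        res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
        out.append(sign * res.fun if res.status == 0 else 0.0)
    vmin, vmax = min(out), max(out)
    return vmin, vmax


def validate_network(net: MetabolicNetwork, flux_tol: float = 1e-9) -> ValidationReport:
    """Report-only diagnostics: carbon balance, dead ends, blocked reactions."""
    carbon: dict[str, Fraction] = {}
    for r in net.reactions:
        if r.is_exchange:
            continue
        atoms = [net.metabolite(m).carbon_atoms for m in r.stoich]
        if any(a is None for a in atoms):
            continue
        # residual: carbon consumed minus carbon produced
        resid = -sum(
            (c * net.metabolite(m).carbon_atoms for m, c in r.stoich.items()),
            Fraction(0),
        )
        if resid != 0:
            carbon[r.id] = resid

    dead = []
    for mid in net.internal_metabolite_ids:
        signs = set()
        for r in net.reactions:
            c = r.stoich.get(mid)
            if c is None or c == 0:
                continue
            if r.reversible:
                signs |= {-1, 1}
            else:
                signs.add(1 if c > 0 else -1)
        if signs and signs != {-1, 1}:
            dead.append(mid)

    blocked = []
    for r in net.reactions:
        vmin, vmax = _flux_range(net, r.id)
        if max(abs(vmin), abs(vmax)) < flux_tol:
            blocked.append(r.id)
    return ValidationReport(carbon, dead, blocked)


# ---------------------------------------------------------------------------
# compression
# ---------------------------------------------------------------------------

def compress_network(
    net: MetabolicNetwork,
) -> tuple[MetabolicNetwork, dict[str, dict[str, Fraction]]]:
    """Remove blocked reactions and lump unbranched chains.

    Returns ``(compressed, mapping)`` where ``mapping[new_id]`` gives the
    original reactions composing each lumped reaction with the multiplier to
    apply when expanding a compressed flux back to the original network
    (see :func:`expand_flux`).  The elementary-mode sets of the original and
    compressed networks correspond one-to-one.
    """
    report = validate_network(net)
    if net.biomass_reaction_id in report.blocked_reactions:
        raise ValidationError("compression would remove the biomass reaction (blocked)")
    reactions = [
        replace_reaction(r) for r in net.reactions if r.id not in set(report.blocked_reactions)
    ]
    mapping: dict[str, dict[str, Fraction]] = {r.id: {r.id: Fraction(1)} for r in reactions}

    def internal_usage(mid: str):
        use = []
        for r in reactions:
            c = r.stoich.get(mid)
            if c:
                use.append((r, c))
        return use

    changed = True
    while changed:
        changed = False
        for mid in [m.id for m in net.metabolites if not m.is_external]:
            use = internal_usage(mid)
            if len(use) != 2:
                continue
            (r1, c1), (r2, c2) = use
            if r1.reversible or r2.reversible:
                continue  # direction ambiguity: leave to the enumerator
            if c1 * c2 >= 0:
                continue  # both produce or both consume: dead end, not a chain
            prod, pc = (r1, c1) if c1 > 0 else (r2, c2)
            cons, cc = (r2, c2) if c1 > 0 else (r1, c1)
            k = pc / (-cc)  # flux of cons per unit flux of prod
            stoich: dict[str, Fraction] = dict(prod.stoich)
            for m, c in cons.stoich.items():
                stoich[m] = stoich.get(m, Fraction(0)) + k * c
            stoich = {m: c for m, c in stoich.items() if c != 0}
            new = Reaction(
                id=f"{prod.id}+{cons.id}",
                stoich=stoich,
                reversible=False,
                is_exchange=prod.is_exchange or cons.is_exchange,
            )
            new_map: dict[str, Fraction] = {}
            for orig, mult in mapping.pop(prod.id).items():
                new_map[orig] = new_map.get(orig, Fraction(0)) + mult
            for orig, mult in mapping.pop(cons.id).items():
                new_map[orig] = new_map.get(orig, Fraction(0)) + k * mult
            mapping[new.id] = new_map
            reactions = [r for r in reactions if r.id not in (prod.id, cons.id)] + [new]
            changed = True
            break

    used = set()
    for r in reactions:
        used |= set(r.stoich)
    mets = [m for m in net.metabolites if m.id in used]
    biomass = net.biomass_reaction_id
    if biomass is not None and biomass not in {r.id for r in reactions}:
        # biomass was lumped into a chain; point at the lumped reaction
        biomass = next(rid for rid, srcs in mapping.items() if net.biomass_reaction_id in srcs)
    compressed = MetabolicNetwork(mets, reactions, biomass)
    return compressed, mapping


def replace_reaction(r: Reaction) -> Reaction:
    return replace(r, stoich=dict(r.stoich))


def expand_flux(
    flux: dict[str, Fraction], mapping: dict[str, dict[str, Fraction]]
) -> dict[str, Fraction]:
    """Expand a flux vector on a compressed network back to original reactions."""
    out: dict[str, Fraction] = {}
    for rid, v in flux.items():
        for orig, mult in mapping[rid].items():
            out[orig] = out.get(orig, Fraction(0)) + v * mult
    return out
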