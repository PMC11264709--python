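"""Kinetic metabolic model: types, parsers, parameter classification, Haldane groups.

A :class:`KineticModel` is a list of species and reactions with explicit
kinetic rate laws over named parameters.  Models can be read from a small
plain-text native format or from an SBML Level 2/3 subset, parameters are
classified by biochemical role from their names (with user overrides), and
reversible reactions whose substrates and products can be paired yield
:class:`HaldaneGroup` objects encoding the thermodynamic identity

    Keq = (Vf / Vr) * (prod Km_products / prod Km_substrates)

which constrains how the group's members may move under mutation.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import sympy
from sympy.parsing.sympy_parser import parse_expr, standard_transformations

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Parameter roles

ROLE_FORWARD_VMAX = "forward_max_velocity"
ROLE_REVERSE_VMAX = "reverse_max_velocity"
ROLE_KCAT = "catalytic_constant"
ROLE_REVERSE_KCAT = "reverse_catalytic_constant"
ROLE_BINDING = "binding_constant"
ROLE_KEQ = "equilibrium_constant"
ROLE_ENZYME_CONC = "enzyme_concentration"
ROLE_OTHER = "other"

ROLES = (
    ROLE_FORWARD_VMAX,
    ROLE_REVERSE_VMAX,
    ROLE_KCAT,
    ROLE_REVERSE_KCAT,
    ROLE_BINDING,
    ROLE_KEQ,
    ROLE_ENZYME_CONC,
    ROLE_OTHER,
)


class ModelError(ValueError):
    """Base class for model construction/parsing problems."""


class ModelSyntaxError(ModelError):
    """Malformed native-format document (carries a line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndeclaredIdentifierError(ModelError):
    """A rate law references an id declared nowhere in the model."""


class UnsupportedFeatureError(ModelError):
    """SBML construct outside the supported subset (events, rules, delays)."""


class RateEvaluationError(ModelError):
    """A rate law evaluated to a non-finite value (e.g. division by zero)."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class Species:
    id: str
    initial_concentration: float = 0.0
    is_boundary: bool = False

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise ModelError(
                f"species {self.id!r}: initial concentration must be >= 0"
            )


@dataclass
class Parameter:
    id: str
    value: float
    scope: str = "global"  # "global" or the owning reaction id
    role: str = ROLE_OTHER
    mutable: bool = True

    def __post_init__(self):
        if self.mutable and self.value <= 0:
            raise ModelError(f"parameter {self.id!r}: mutable value must be > 0")


# restricted namespace for rate-law parsing: the operator set is
# {+, -, *, /, power, exp}; auto_symbol/auto_number need the constructors
_EXPR_GLOBALS = {
    "exp": sympy.exp,
    "Symbol": sympy.Symbol,
    "Integer": sympy.Integer,
    "Float": sympy.Float,
    "Rational": sympy.Rational,
}


class RateExpression:
    """An enzyme-kinetic rate law: a sympy expression over declared ids."""

    __slots__ = ("expr", "symbols", "_lambda", "_lambda_args")

    def __init__(self, expr: sympy.Expr):
        self.expr = expr
        self.symbols = frozenset(str(s) for s in expr.free_symbols)
        self._lambda = None
        self._lambda_args: tuple[str, ...] = ()

    @classmethod
    def parse(cls, text: str, allowed_ids: Iterable[str] | None = None,
              line: int | None = None) -> "RateExpression":
        src = text.replace("^", "**")
        local = {}
        if allowed_ids is not None:
            local = {i: sympy.Symbol(i) for i in allowed_ids}
        try:
            expr = parse_expr(
                src,
                local_dict=local,
                global_dict=dict(_EXPR_GLOBALS),
                transformations=standard_transformations,
            )
        except (SyntaxError, TypeError, sympy.SympifyError) as exc:
            raise ModelSyntaxError(f"cannot parse rate expression {text!r}: {exc}",
                                   line) from exc
        self = cls(sympy.sympify(expr))
        if allowed_ids is not None:
            unknown = self.symbols - set(allowed_ids)
            if unknown:
                raise UndeclaredIdentifierError(
                    "rate expression references undeclared identifier(s): "
                    + ", ".join(sorted(unknown))
                )
        return self

    def evaluate(self, values: Mapping[str, float]) -> float:
        args = tuple(sorted(self.symbols))
        if self._lambda is None or self._lambda_args != args:
            self._lambda_args = args
            self._lambda = sympy.lambdify(
                [sympy.Symbol(a) for a in args], self.expr, modules="numpy"
            )
        try:
            out = float(self._lambda(*(float(values[a]) for a in args)))
        except ZeroDivisionError as exc:
            raise RateEvaluationError(str(exc)) from exc
        return out

    def __str__(self) -> str:
        return sympy.sstr(self.expr)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RateExpression({self})"


@dataclass
class Reaction:
    id: str
    substrates: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    rate: RateExpression | None = None
    local_parameters: list[Parameter] = field(default_factory=list)

    def __post_init__(self):
        for sid, coeff in [*self.substrates, *self.products]:
            if coeff <= 0 or int(coeff) != coeff:
                raise ModelError(
                    f"reaction {self.id!r}: stoichiometric coefficient for "
                    f"{sid!r} must be a positive integer"
                )


@dataclass
class HaldaneGroup:
    reaction_id: str
    vf: str                      # forward max velocity or forward kcat
    vr: str                      # reverse max velocity or reverse kcat
    keq: str                     # equilibrium-constant parameter id
    substrate_kms: list[str]
    product_kms: list[str]

    def members(self) -> tuple[str, ...]:
        return (self.vf, self.vr, self.keq, *self.substrate_kms,
                *self.product_kms)

    def residual(self, values: Mapping[str, float]) -> float:
        """Relative violation of Keq = (Vf/Vr) * prod(KmP) / prod(KmS)."""
        lhs = values[self.keq] * values[self.vr]
        for k in self.substrate_kms:
            lhs *= values[k]
        rhs = values[self.vf]
        for k in self.product_kms:
            rhs *= values[k]
        if rhs == 0:
            return math.inf
        return abs(lhs - rhs) / abs(rhs)


HALDANE_TOL = 1e-9


@dataclass
class KineticModel:
    species: list[Species]
    reactions: list[Reaction]
    global_parameters: list[Parameter]
    haldane_groups: list[HaldaneGroup] = field(default_factory=list)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.reactions:
            raise ModelError("a kinetic model needs at least one reaction")
        for name, ids in (
            ("species", [s.id for s in self.species]),
            ("reaction", [r.id for r in self.reactions]),
            ("parameter", [p.id for p in self.all_parameters()]),
        ):
            dup = {i for i in ids if ids.count(i) > 1}
            if dup:
                raise ModelError(f"duplicate {name} id(s): {sorted(dup)}")

    # -- convenience views ---------------------------------------------------
    def all_parameters(self) -> list[Parameter]:
        out = list(self.global_parameters)
        for r in self.reactions:
            out.extend(r.local_parameters)
        return out

    def parameter(self, pid: str) -> Parameter:
        for p in self.all_parameters():
            if p.id == pid:
                return p
        raise KeyError(pid)

    def parameter_values(self) -> dict[str, float]:
        return {p.id: p.value for p in self.all_parameters()}

    def species_by_id(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def reaction_parameter_ids(self, reaction: Reaction) -> list[str]:
        """Parameters referenced by a reaction (locals first, then globals
        in declaration order)."""
        ids = [p.id for p in reaction.local_parameters]
        syms = reaction.rate.symbols if reaction.rate is not None else frozenset()
        for p in self.global_parameters:
            if p.id in syms and p.id not in ids:
                ids.append(p.id)
        return ids


# ---------------------------------------------------------------------------
# Native plain-text format
#
# Sections "species:", "parameters:", "reactions:"; one entity per line;
# '#' starts a comment.
#   species line:    id  init=<float>  [boundary]
#   parameter line:  id = <float>  [role=<role>]  [fixed]
#   reaction line:   id: 2 S1 + S2 -> P1  rate = <infix expression>


_SPECIES_RE = re.compile(
    r"^(?P<id>\w+)\s+init\s*=\s*(?P<init>[-+0-9.eE]+)(?P<rest>.*)$")
_PARAM_RE = re.compile(
    r"^(?P<id>\w+)\s*=\s*(?P<val>[-+0-9.eE]+)(?P<rest>.*)$")
_REACTION_RE = re.compile(
    r"^(?P<id>\w+)\s*:\s*(?P<lhs>[^>]*?)->(?P<rhs>.*?)\s+rate\s*=\s*(?P<rate>.+)$")
_TERM_RE = re.compile(r"^(?:(?P<coeff>\d+)\s+)?(?P<id>\w+)$")


def _parse_side(text: str, line: int) -> list[tuple[str, int]]:
    text = text.strip()
    if not text:
        return []
    out = []
    for term in text.split("+"):
        m = _TERM_RE.match(term.strip())
        if not m:
            raise ModelSyntaxError(f"bad stoichiometry term {term.strip()!r}", line)
        out.append((m.group("id"), int(m.group("coeff") or 1)))
    return out


def parse_native_model(text: str) -> KineticModel:
    """Parse the native plain-text model format into a :class:`KineticModel`."""
    species: list[Species] = []
    params: list[Parameter] = []
    raw_reactions: list[tuple[int, str, list, list, str]] = []
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        low = line.lower()
        if low in ("species:", "parameters:", "reactions:"):
            section = low[:-1]
            continue
        if section is None:
            raise ModelSyntaxError(f"content before any section header: {line!r}",
                                   lineno)
        if section == "species":
            m = _SPECIES_RE.match(line)
            if not m:
                raise ModelSyntaxError(f"bad species line: {line!r}", lineno)
            rest = m.group("rest").split()
            boundary = "boundary" in rest
            species.append(Species(m.group("id"), float(m.group("init")),
                                   is_boundary=boundary))
        elif section == "parameters":
            m = _PARAM_RE.match(line)
            if not m:
                raise ModelSyntaxError(f"bad parameter line: {line!r}", lineno)
            rest = m.group("rest").split()
            role = ROLE_OTHER
            mutable = True
            for tok in rest:
                if tok.startswith("role="):
                    role = tok[5:]
                    if role not in ROLES:
                        raise ModelSyntaxError(f"unknown role {role!r}", lineno)
                elif tok == "fixed":
                    mutable = False
                else:
                    raise ModelSyntaxError(f"unknown parameter flag {tok!r}",
                                           lineno)
            value = float(m.group("val"))
            if mutable and value <= 0:
                raise ModelSyntaxError(
                    f"parameter {m.group('id')!r}: mutable value must be > 0",
                    lineno)
            params.append(Parameter(m.group("id"), value, role=role,
                                    mutable=mutable))
        else:  # reactions
            m = _REACTION_RE.match(line)
            if not m:
                raise ModelSyntaxError(f"bad reaction line: {line!r}", lineno)
            raw_reactions.append((
                lineno, m.group("id"),
                _parse_side(m.group("lhs"), lineno),
                _parse_side(m.group("rhs"), lineno),
                m.group("rate").strip(),
            ))
    allowed = {s.id for s in species} | {p.id for p in params}
    reactions = []
    for lineno, rid, subs, prods, rate_text in raw_reactions:
        for sid, _ in [*subs, *prods]:
            if sid not in {s.id for s in species}:
                raise ModelSyntaxError(f"reaction {rid!r}: unknown species "
                                       f"{sid!r}", lineno)
        try:
            rate = RateExpression.parse(rate_text, allowed, line=lineno)
        except UndeclaredIdentifierError as exc:
            raise UndeclaredIdentifierError(f"reaction {rid!r}: {exc}") from exc
        reactions.append(Reaction(rid, subs, prods, rate=rate))
    return KineticModel(species, reactions, params)


def serialize_native_model(model: KineticModel) -> str:
    """Write a model back to the native format (round-trip safe)."""
    lines = ["species:"]
    for s in model.species:
        flag = "  boundary" if s.is_boundary else ""
        lines.append(f"  {s.id}  init={s.initial_concentration!r}{flag}")
    lines.append("parameters:")
    for p in model.all_parameters():
        extra = ""
        if p.role != ROLE_OTHER:
            extra += f"  role={p.role}"
        if not p.mutable:
            extra += "  fixed"
        lines.append(f"  {p.id} = {p.value!r}{extra}")
    lines.append("reactions:")
    for r in model.reactions:
        lhs = " + ".join(f"{c} {s}" if c != 1 else s for s, c in r.substrates)
        rhs = " + ".join(f"{c} {s}" if c != 1 else s for s, c in r.products)
        lines.append(f"  {r.id}: {lhs} -> {rhs}  rate = {r.rate}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SBML subset reader / writer (lazy libsbml import)


def _require_libsbml():
    try:
        import libsbml  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise UnsupportedFeatureError(
            "SBML support requires the python-libsbml package") from exc
    return libsbml


def parse_sbml(document: str) -> KineticModel:
    """Read an SBML Level 2/3 document (explicit kinetic laws only).

    Events, rules, constraints, initial assignments and delays are outside
    the supported subset and raise :class:`UnsupportedFeatureError`.
    Compartments are collapsed to volume 1 (their symbols are substituted by
    their numeric size in rate laws).
    """
    libsbml = _require_libsbml()
    doc = libsbml.readSBMLFromString(document)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelSyntaxError(f"SBML read error: {err.getMessage().strip()}")
    # inline function definitions so rate laws are plain expressions
    props = libsbml.ConversionProperties()
    props.addOption("expandFunctionDefinitions", True)
    doc.convert(props)
    sbml = doc.getModel()
    if sbml is None:
        raise ModelSyntaxError("SBML document contains no model")
    for what, n in (
        ("events", sbml.getNumEvents()),
        ("rules", sbml.getNumRules()),
        ("constraints", sbml.getNumConstraints()),
        ("initial assignments", sbml.getNumInitialAssignments()),
    ):
        if n:
            raise UnsupportedFeatureError(f"SBML {what} are not supported")

    comp_size = {}
    for i in range(sbml.getNumCompartments()):
        c = sbml.getCompartment(i)
        comp_size[c.getId()] = c.getSize() if c.isSetSize() else 1.0

    species = []
    for i in range(sbml.getNumSpecies()):
        s = sbml.getSpecies(i)
        if s.isSetInitialConcentration():
            init = s.getInitialConcentration()
        elif s.isSetInitialAmount():
            init = s.getInitialAmount()
        else:
            init = 0.0
        species.append(Species(
            s.getId(), float(init),
            is_boundary=bool(s.getBoundaryCondition() or s.getConstant()),
        ))

    params = []
    for i in range(sbml.getNumParameters()):
        p = sbml.getParameter(i)
        params.append(Parameter(p.getId(), float(p.getValue()),
                                mutable=True if p.getValue() > 0 else False))

    taken = {p.id for p in params} | {s.id for s in species}
    reactions = []
    for i in range(sbml.getNumReactions()):
        r = sbml.getReaction(i)
        kl = r.getKineticLaw()
        if kl is None or kl.getMath() is None:
            raise UnsupportedFeatureError(
                f"reaction {r.getId()!r} has no kinetic law")
        locals_ = []
        rename = {}
        nlp = kl.getNumLocalParameters() or kl.getNumParameters()
        for j in range(nlp):
            lp = (kl.getLocalParameter(j) if kl.getNumLocalParameters()
                  else kl.getParameter(j))
            pid = lp.getId()
            if pid in taken:
                new = f"{r.getId()}_{pid}"
                rename[pid] = new
                pid = new
            taken.add(pid)
            locals_.append(Parameter(pid, float(lp.getValue()),
                                     scope=r.getId(),
                                     mutable=lp.getValue() > 0))
        formula = libsbml.formulaToL3String(kl.getMath())
        allowed = ({s.id for s in species} | {p.id for p in params}
                   | {p.id for p in locals_} | set(rename) | set(comp_size))
        rate = RateExpression.parse(formula, allowed)
        subs = {sympy.Symbol(k): sympy.Symbol(v) for k, v in rename.items()}
        subs.update({sympy.Symbol(c): sympy.Float(v)
                     for c, v in comp_size.items()})
        if subs:
            rate = RateExpression(rate.expr.subs(subs))
        def _side(n, getter):
            out = []
            for j in range(n):
                ref = getter(j)
                st = ref.getStoichiometry()
                if not st:
                    st = 1.0
                out.append((ref.getSpecies(), int(round(st))))
            return out
        reactions.append(Reaction(
            r.getId(),
            _side(r.getNumReactants(), r.getReactant),
            _side(r.getNumProducts(), r.getProduct),
            modifiers=[r.getModifier(j).getSpecies()
                       for j in range(r.getNumModifiers())],
            rate=rate,
            local_parameters=locals_,
        ))
    return KineticModel(species, reactions, params)


def serialize_sbml(model: KineticModel) -> str:
    """Emit a minimal SBML Level 3 document for *model*."""
    libsbml = _require_libsbml()
    doc = libsbml.SBMLDocument(3, 2)
    sbml = doc.createModel()
    sbml.setId("model")
    comp = sbml.createCompartment()
    comp.setId("cell")
    comp.setSize(1.0)
    comp.setConstant(True)
    for s in model.species:
        sp = sbml.createSpecies()
        sp.setId(s.id)
        sp.setCompartment("cell")
        sp.setInitialConcentration(s.initial_concentration)
        sp.setBoundaryCondition(s.is_boundary)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
    for p in model.global_parameters:
        pp = sbml.createParameter()
        pp.setId(p.id)
        pp.setValue(p.value)
        pp.setConstant(True)
    for r in model.reactions:
        rr = sbml.createReaction()
        rr.setId(r.id)
        rr.setReversible(True)
        for sid, coeff in r.substrates:
            ref = rr.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for sid, coeff in r.products:
            ref = rr.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for sid in r.modifiers:
            ref = rr.createModifier()
            ref.setSpecies(sid)
        kl = rr.createKineticLaw()
        for p in r.local_parameters:
            lp = kl.createLocalParameter()
            lp.setId(p.id)
            lp.setValue(p.value)
        math = libsbml.parseL3Formula(str(r.rate).replace("**", "^"))
        kl.setMath(math)
    return libsbml.writeSBMLToString(doc)


# ---------------------------------------------------------------------------
# Parameter classification

_ROLE_PATTERNS: list[tuple[re.Pattern, str]] = [
    (re.compile(r"^keq", re.I), ROLE_KEQ),
    (re.compile(r"^kcat_?r", re.I), ROLE_REVERSE_KCAT),
    (re.compile(r"^kcat", re.I), ROLE_KCAT),
    (re.compile(r"^(vr|vmax_?rev|vmax_?r$|vmax_?r[_\d])", re.I), ROLE_REVERSE_VMAX),
    (re.compile(r"^(vmax|vf|v_)", re.I), ROLE_FORWARD_VMAX),
    (re.compile(r"^(km|ki|k[a-z]+_)", re.I), ROLE_BINDING),
    (re.compile(r"^(e_|conc_)", re.I), ROLE_ENZYME_CONC),
]


def classify_parameters(model: KineticModel,
                        overrides: Mapping[str, str] | None = None
                        ) -> dict[str, str]:
    """Assign every parameter a biochemical role.

    Name heuristics (case-insensitive prefixes) are applied first; user
    *overrides* take precedence; anything unmatched gets role "other".
    A parameter whose id equals a species used only as a reaction modifier
    is treated as an enzyme concentration.
    """
    overrides = dict(overrides or {})
    known = {p.id for p in model.all_parameters()}
    unknown = set(overrides) - known
    if unknown:
        raise ModelError(
            f"role override(s) for unknown parameter id(s): {sorted(unknown)}")
    for role in overrides.values():
        if role not in ROLES:
            raise ModelError(f"unknown role {role!r} in overrides")

    modifier_only = set()
    for s in model.species:
        in_stoich = any(
            s.id in {x for x, _ in r.substrates} | {x for x, _ in r.products}
            for r in model.reactions)
        is_mod = any(s.id in r.modifiers for r in model.reactions)
        if is_mod and not in_stoich:
            modifier_only.add(s.id)

    roles: dict[str, str] = {}
    for p in model.all_parameters():
        if p.id in overrides:
            roles[p.id] = overrides[p.id]
            continue
        if p.id in modifier_only:
            roles[p.id] = ROLE_ENZYME_CONC
            continue
        for pat, role in _ROLE_PATTERNS:
            if pat.match(p.id):
                roles[p.id] = role
                break
        else:
            roles[p.id] = ROLE_OTHER
    return roles


def apply_roles(model: KineticModel, roles: Mapping[str, str]) -> None:
    for p in model.all_parameters():
        p.role = roles.get(p.id, p.role)


# ---------------------------------------------------------------------------
# Haldane groups


def build_haldane_groups(model: KineticModel,
                         roles: Mapping[str, str]) -> list[HaldaneGroup]:
    """Collect per-reaction Haldane groups.

    A reaction is eligible when it carries a forward and a reverse maximal
    velocity (or kcat pair), an equilibrium constant, equal substrate and
    product counts, and exactly one binding constant per reactant.  Binding
    constants are paired to substrates/products by declaration order.
    Ineligible or identity-violating reactions are skipped (logged); their
    binding constants then mutate unconstrained.
    """
    values = model.parameter_values()
    groups: list[HaldaneGroup] = []
    referenced = {pid for r in model.reactions
                  for pid in model.reaction_parameter_ids(r)}
    for r in model.reactions:
        pids = model.reaction_parameter_ids(r)
        # Keq (and sometimes the derived reverse velocity) often does not
        # appear in the rate law itself; informative naming ties it to the
        # reaction via a shared trailing "_<tag>" or the reaction id.
        suffixes = {pid.rsplit("_", 1)[1] for pid in pids if "_" in pid}
        for p in model.global_parameters:
            if p.id in pids or p.id in referenced:
                continue
            if roles.get(p.id) not in (ROLE_KEQ, ROLE_REVERSE_KCAT,
                                       ROLE_REVERSE_VMAX):
                continue
            tag = p.id.rsplit("_", 1)[1] if "_" in p.id else None
            if (tag is not None and tag in suffixes) \
                    or r.id.lower() in p.id.lower():
                pids.append(p.id)
        by_role: dict[str, list[str]] = {}
        for pid in pids:
            by_role.setdefault(roles.get(pid, ROLE_OTHER), []).append(pid)
        vf = (by_role.get(ROLE_FORWARD_VMAX) or by_role.get(ROLE_KCAT) or [None])[0]
        vr = (by_role.get(ROLE_REVERSE_VMAX)
              or by_role.get(ROLE_REVERSE_KCAT) or [None])[0]
        keq = (by_role.get(ROLE_KEQ) or [None])[0]
        kms = by_role.get(ROLE_BINDING, [])
        n_s, n_p = len(r.substrates), len(r.products)
        if vf is None or vr is None or keq is None:
            log.debug("reaction %s: no Haldane group (missing Vf/Vr/Keq)", r.id)
            continue
        if n_s == 0 or n_s != n_p:
            log.info("reaction %s: no Haldane group (substrate/product "
                     "counts %d vs %d cannot be paired)", r.id, n_s, n_p)
            continue
        if len(kms) != n_s + n_p:
            log.info("reaction %s: no Haldane group (%d binding constants "
                     "for %d reactants)", r.id, len(kms), n_s + n_p)
            continue
        group = HaldaneGroup(r.id, vf, vr, keq, kms[:n_s], kms[n_s:])
        res = group.residual(values)
        if res > HALDANE_TOL:
            log.warning("reaction %s: Haldane identity violated at "
                        "construction (relative residual %.3g); skipping "
                        "group, Kms will mutate unconstrained", r.id, res)
            continue
        groups.append(group)
    return groups


def finalize_model(model: KineticModel,
                   overrides: Mapping[str, str] | None = None,
                   exclude: Sequence[str] = ()) -> KineticModel:
    """Classify roles, build Haldane groups, and settle mutability.

    Within a Haldane group the reverse velocity is constraint-derived and the
    equilibrium constant is a thermodynamic property of the reaction, so both
    are marked immutable.  Boundary-held ids in *exclude* are also frozen.
    """
    roles = classify_parameters(model, overrides)
    apply_roles(model, roles)
    model.haldane_groups = build_haldane_groups(model, roles)
    by_id = {p.id: p for p in model.all_parameters()}
    unknown = set(exclude) - set(by_id)
    if unknown:
        raise ModelError(f"cannot exclude unknown parameter(s): {sorted(unknown)}")
    for g in model.haldane_groups:
        by_id[g.vr].mutable = False
        by_id[g.keq].mutable = False
    for pid in exclude:
        by_id[pid].mutable = False
    return model


# ---------------------------------------------------------------------------
# Rate evaluation


def evaluate_rate(reaction: Reaction, concentrations: Mapping[str, float],
                  parameter_values: Mapping[str, float]) -> float:
    """Evaluate one reaction's rate law at the given state (deterministic)."""
    values = {**parameter_values, **concentrations}
    missing = reaction.rate.symbols - set(values)
    if missing:
        raise UndeclaredIdentifierError(
            f"reaction {reaction.id!r}: missing value(s) for {sorted(missing)}")
    try:
        out = reaction.rate.evaluate(values)
    except RateEvaluationError as exc:
        raise RateEvaluationError(
            f"reaction {reaction.id!r}: {exc}") from exc
    if not math.isfinite(out):
        raise RateEvaluationError(
            f"reaction {reaction.id!r}: rate evaluated to {out}")
    return out
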