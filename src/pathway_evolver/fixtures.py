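"""Small kinetic models with analytically known steady states, and toy trees.

These generators make every other module testable without downloads: an
irreversible Michaelis-Menten chain whose steady state has the closed form
S_i* = Km_i v0 / (Vmax_i - v0), a reversible chain constructed to satisfy
the Haldane identity exactly, and a one-input/two-output branch-point model
for multi-target selection.  Parameter names are informative on purpose so
role classification succeeds without overrides.
"""
from __future__ import annotations

from dataclasses import dataclass

from .model import KineticModel, finalize_model, parse_native_model


@dataclass
class FixtureSpec:
    n: int = 3                  # chain length (number of MM steps)
    v0: float = 1.0             # constant source rate
    vmax: float = 2.0           # per-step maximal velocity
    km: float = 1.0             # per-step Michaelis constant
    keq: float = 2.0            # per-step equilibrium constant (reversible)
    reversible: bool = False
    enzyme_conc: bool = False   # split Vmax into kcat x [E]
    allow_failure: bool = False  # permit Vmax <= v0 (no steady state)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("chain length must be >= 1")
        if self.v0 < 0:
            raise ValueError("source rate must be >= 0")
        if (not self.reversible and not self.allow_failure
                and self.vmax <= self.v0):
            raise ValueError(
                "irreversible chain needs Vmax > v0 for a steady state to "
                "exist; set allow_failure=True to build a failure fixture")


def make_linear_chain(spec: FixtureSpec | None = None, **kwargs):
    """Irreversible MM chain with a constant source.

    Returns ``(model, analytic)`` where ``analytic`` holds the closed-form
    steady-state concentrations (``S_i* = Km v0/(Vmax - v0)``) and fluxes
    (all equal to v0).  With ``enzyme_conc=True`` each step's velocity is
    parameterized as kcat_i * E_i with kcat_i * E_i = Vmax.
    """
    spec = spec or FixtureSpec(**kwargs)
    lines = ["species:", "  Xin  init=1.0  boundary"]
    for i in range(1, spec.n + 1):
        lines.append(f"  S{i}  init=0.1")
    lines.append("  Xout  init=0.0  boundary")
    lines.append("parameters:")
    lines.append(f"  v0 = {spec.v0!r}  fixed")
    for i in range(1, spec.n + 1):
        if spec.enzyme_conc:
            lines.append(f"  kcat_{i} = {spec.vmax / 1.0!r}")
            lines.append(f"  E_{i} = 1.0")
        else:
            lines.append(f"  Vmax_{i} = {spec.vmax!r}")
        lines.append(f"  Km_{i} = {spec.km!r}")
    lines.append("reactions:")
    lines.append("  Rsrc: Xin -> S1  rate = v0")
    for i in range(1, spec.n + 1):
        product = f"S{i + 1}" if i < spec.n else "Xout"
        v = f"kcat_{i} * E_{i}" if spec.enzyme_conc else f"Vmax_{i}"
        lines.append(f"  R{i}: S{i} -> {product}  "
                     f"rate = {v} * S{i} / (Km_{i} + S{i})")
    model = finalize_model(parse_native_model("\n".join(lines) + "\n"))
    if spec.vmax > spec.v0:
        s_star = spec.km * spec.v0 / (spec.vmax - spec.v0)
        analytic = {
            "concentrations": {f"S{i}": s_star
                               for i in range(1, spec.n + 1)},
            "fluxes": {"Rsrc": spec.v0,
                       **{f"R{i}": spec.v0 for i in range(1, spec.n + 1)}},
        }
    else:
        analytic = None  # deliberately unsolvable failure fixture
    return model, analytic


def make_reversible_chain(spec: FixtureSpec | None = None,
                          decoy: bool = False, **kwargs):
    """Reversible uni-uni MM chain, Haldane-consistent by construction.

    The boundary input Xin (held at constant concentration, like the
    constant extracellular glucose of real glycolysis models) feeds the
    chain through n reversible Michaelis-Menten steps

        v = E (kcatf S/KmS - kcatr P/KmP) / (1 + S/KmS + P/KmP)

    with kcatr derived from the Haldane identity
    Keq = (kcatf KmP)/(kcatr KmS), and an irreversible MM drain removes the
    final intermediate.  Because the entry step is enzymatic, the steady
    flux depends on every enzyme's parameters — mutations are visible to
    selection on the drain flux.  With ``decoy=True`` a detached two-
    reaction subnetwork is added whose mutable parameters cannot affect the
    main flux: mutations there form the exactly-neutral class.
    """
    spec = spec or FixtureSpec(**{"reversible": True, **kwargs})
    n = spec.n
    lines = ["species:", "  Xin  init=1.0  boundary"]
    for i in range(1, n + 1):
        lines.append(f"  S{i}  init=0.5")
    lines.append("  Xout  init=0.0  boundary")
    if decoy:
        lines += ["  Xd  init=1.0  boundary", "  D1  init=0.5",
                  "  Xd2  init=0.0  boundary"]
    lines.append("parameters:")
    kcatf = spec.vmax
    for i in range(1, n + 1):
        kms = spec.km
        kmp = 2.0 * spec.km      # asymmetric so the group is non-trivial
        kcatr = kcatf * kmp / (spec.keq * kms)
        lines.append(f"  kcatf_{i} = {kcatf!r}")
        lines.append(f"  kcatr_{i} = {kcatr!r}")
        lines.append(f"  Keq_{i} = {spec.keq!r}")
        lines.append(f"  KmS_{i} = {kms!r}")
        lines.append(f"  KmP_{i} = {kmp!r}")
        lines.append(f"  E_{i} = 1.0")
    lines.append(f"  Vmax_d = {4.0 * max(spec.v0, 1.0)!r}")
    lines.append(f"  Km_d = {spec.km!r}")
    if decoy:
        lines += ["  vdec = 1.0  fixed", "  Vmax_dec = 4.0",
                  "  Km_dec = 1.0"]
    lines.append("reactions:")
    for i in range(1, n + 1):
        s = "Xin" if i == 1 else f"S{i - 1}"
        p = f"S{i}"
        lines.append(
            f"  R{i}: {s} -> {p}  rate = E_{i} * "
            f"(kcatf_{i} * {s} / KmS_{i} - kcatr_{i} * {p} / KmP_{i}) "
            f"/ (1 + {s} / KmS_{i} + {p} / KmP_{i})")
    lines.append(f"  Rdrain: S{n} -> Xout  "
                 f"rate = Vmax_d * S{n} / (Km_d + S{n})")
    if decoy:
        lines.append("  Rdsrc: Xd -> D1  rate = vdec")
        lines.append("  Rdecoy: D1 -> Xd2  rate = Vmax_dec * D1 / "
                     "(Km_dec + D1)")
    return finalize_model(parse_native_model("\n".join(lines) + "\n"))


def make_branched_fixture(v0: float = 1.0, vmax1: float = 2.0,
                          vmax2: float = 2.0, km: float = 1.0,
                          enzyme_conc: bool = False) -> KineticModel:
    """One input, a branch point, two competing MM outputs.

    At steady state the input flux v0 splits across the two outputs
    (stoichiometric balance), which makes the fixture the smallest model on
    which multi-target selection weights and the geometric-mean fitness are
    exercised.  Requires vmax1 + vmax2 > v0.
    """
    if vmax1 + vmax2 <= v0:
        raise ValueError("branch outputs cannot absorb the input flux")
    e1 = ("  kcat_b1 = {v1!r}\n  E_b1 = 1.0\n"
          if enzyme_conc else "  Vmax_b1 = {v1!r}\n")
    e2 = ("  kcat_b2 = {v2!r}\n  E_b2 = 1.0\n"
          if enzyme_conc else "  Vmax_b2 = {v2!r}\n")
    v1_expr = "kcat_b1 * E_b1" if enzyme_conc else "Vmax_b1"
    v2_expr = "kcat_b2 * E_b2" if enzyme_conc else "Vmax_b2"
    text = (
        "species:\n"
        "  Xin  init=1.0  boundary\n"
        "  S1  init=0.5\n"
        "  Xout1  init=0.0  boundary\n"
        "  Xout2  init=0.0  boundary\n"
        "parameters:\n"
        f"  v0 = {v0!r}  fixed\n"
        + e1.format(v1=vmax1) + e2.format(v2=vmax2)
        + f"  Km_b1 = {km!r}\n"
        + f"  Km_b2 = {km!r}\n"
        "reactions:\n"
        "  Rsrc: Xin -> S1  rate = v0\n"
        f"  Rout1: S1 -> Xout1  rate = {v1_expr} * S1 / (Km_b1 + S1)\n"
        f"  Rout2: S1 -> Xout2  rate = {v2_expr} * S1 / (Km_b2 + S1)\n"
    )
    return finalize_model(parse_native_model(text))


def make_toy_trees() -> dict[str, str]:
    """Small rooted Newick strings in both branch-length conventions."""
    return {
        "two_leaf": "(A:1.0,B:2.0);",
        "caterpillar": "((A:1.0,B:1.0):0.5,C:1.5);",
        "balanced": "((A:1.0,B:2.0):0.5,(C:0.5,D:1.0):1.5);",
        "zero_branch": "((A:0.0,B:1.0):0.5,C:1.0);",
        "subs_per_site": "(A:0.01,B:0.02);",
    }
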