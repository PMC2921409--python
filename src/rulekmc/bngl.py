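"""Reading and writing the BNGL-subset model dialect.

The dialect covers the surface needed by association / dissociation /
state-change / ring-closure rule sets: ``parameters``, ``molecule types``
(optional), ``species`` (seed), ``reaction rules``, ``observables``
blocks, component internal states (``~s``), explicit bonds (``!n``), the
bound-to-anything (``!+``) and unspecified-bond (``!?``) wildcards,
molecule concatenation (``.``), reactant separation (``+``), and both
``->`` and ``<->`` arrows.  An omitted component is a full wildcard; an
explicitly listed component with no ``!`` is required to be unbound.

Outputs: ``.gdat`` whitespace tables (one column per observable) and
``.info`` key/value run metadata.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .engine import Rule, build_rule
from .graphs import (
    BOUND_ANY,
    UNBOUND,
    WILDCARD,
    ComponentDef,
    MoleculeTypeDef,
    PatternComponent,
    PatternGraph,
    PatternMolecule,
    render_pattern,
)
from .simulate import ObservableDef, SimulationConfig

logger = logging.getLogger(__name__)

_KNOWN_BLOCKS = {
    "parameters", "molecule types", "species", "seed species",
    "reaction rules", "observables", "actions", "model",
}

_NAME = r"[A-Za-z_]\w*"


class ParseError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None) -> None:
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class ModelSpec:
    """A fully resolved model: declarations, seed particles, unidirectional
    rules, observables and the (optional) simulate action."""

    parameters: dict[str, float]
    molecule_types: tuple[MoleculeTypeDef, ...]
    seed_species: tuple[tuple[PatternGraph, int], ...]
    rules: tuple[Rule, ...]
    observables: tuple[ObservableDef, ...]
    actions: Optional[SimulationConfig] = None

    @property
    def types(self) -> dict[str, MoleculeTypeDef]:
        return {mt.name: mt for mt in self.molecule_types}


@dataclass
class RawRule:
    """A parsed rule form prior to reversible expansion."""

    name: str
    lhs: tuple[PatternGraph, ...]
    rhs: tuple[PatternGraph, ...]
    rates: tuple[float, ...]
    reversible: bool


# ---------------------------------------------------------------------------
# arithmetic expressions (+ - * / and parentheses)
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(?:(\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
                    r"|(" + _NAME + r")|([()+\-*/]))")


def eval_expression(expr: str, env: dict[str, float]) -> float:
    tokens: list[str] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m or m.end() == pos:
            if expr[pos:].strip():
                raise ValueError(f"cannot parse expression '{expr}'")
            break
        tokens.append(m.group(0).strip())
        pos = m.end()
    it = iter(range(len(tokens)))
    idx = [0]

    def peek() -> Optional[str]:
        return tokens[idx[0]] if idx[0] < len(tokens) else None

    def take() -> str:
        t = tokens[idx[0]]
        idx[0] += 1
        return t

    def atom() -> float:
        t = peek()
        if t is None:
            raise ValueError(f"unexpected end of expression '{expr}'")
        if t == "(":
            take()
            v = add()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in '{expr}'")
            take()
            return v
        if t == "-":
            take()
            return -atom()
        if t == "+":
            take()
            return atom()
        take()
        if re.fullmatch(_NAME, t):
            if t not in env:
                raise KeyError(t)
            return env[t]
        return float(t)

    def mul() -> float:
        v = atom()
        while peek() in ("*", "/"):
            op = take()
            rhs = atom()
            v = v * rhs if op == "*" else v / rhs
        return v

    def add() -> float:
        v = mul()
        while peek() in ("+", "-"):
            op = take()
            rhs = mul()
            v = v + rhs if op == "+" else v - rhs
        return v

    result = add()
    if idx[0] != len(tokens):
        raise ValueError(f"trailing tokens in expression '{expr}'")
    return result


# ---------------------------------------------------------------------------
# pattern expressions
# ---------------------------------------------------------------------------

_MOL_RE = re.compile(rf"^({_NAME})(?:\((.*)\))?$")
_SUFFIX_RE = re.compile(r"~(\w+)|!(\d+)|!(\+)|!(\?)")


def _split_top(text: str, sep: str) -> list[str]:
    """Split on ``sep`` outside parentheses (and, for '+', not after '!')."""
    parts, depth, cur = [], 0, []
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0 and not (sep == "+" and i > 0 and text[i - 1] == "!"):
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def _parse_component(text: str, allow_multi_state: bool = False):
    m = re.match(rf"^({_NAME})", text)
    if not m:
        raise ValueError(f"cannot parse component '{text}'")
    name = m.group(1)
    rest = text[m.end():]
    states: list[str] = []
    bond = UNBOUND
    bond_seen = False
    pos = 0
    while pos < len(rest):
        sm = _SUFFIX_RE.match(rest, pos)
        if not sm:
            raise ValueError(f"cannot parse component suffix '{rest[pos:]}' in '{text}'")
        if sm.group(1) is not None:
            states.append(sm.group(1))
        elif sm.group(2) is not None:
            bond, bond_seen = int(sm.group(2)), True
        elif sm.group(3) is not None:
            bond, bond_seen = BOUND_ANY, True
        else:
            bond, bond_seen = WILDCARD, True
        pos = sm.end()
    if not allow_multi_state and len(states) > 1:
        raise ValueError(f"component '{text}' lists more than one state")
    return name, states, bond, bond_seen


def parse_pattern(text: str) -> PatternGraph:
    """Parse one dotted molecule expression into a pattern graph."""
    mols = []
    for mol_text in _split_top(text.strip(), "."):
        m = _MOL_RE.match(mol_text.strip())
        if not m:
            raise ValueError(f"cannot parse molecule expression '{mol_text}'")
        name, inner = m.group(1), m.group(2)
        comps = []
        if inner:
            for ctext in inner.split(","):
                cname, states, bond, _ = _parse_component(ctext.strip())
                comps.append(PatternComponent(cname, states[0] if states else None, bond))
        mols.append(PatternMolecule(name, tuple(comps)))
    if not mols:
        raise ValueError(f"empty pattern '{text}'")
    return PatternGraph(tuple(mols))


def parse_reactant_side(text: str) -> tuple[PatternGraph, ...]:
    return tuple(parse_pattern(p) for p in _split_top(text, "+"))


def _parse_molecule_type(text: str) -> MoleculeTypeDef:
    m = _MOL_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse molecule type '{text}'")
    name, inner = m.group(1), m.group(2)
    comps = []
    if inner:
        for ctext in inner.split(","):
            cname, states, bond, bond_seen = _parse_component(ctext.strip(),
                                                              allow_multi_state=True)
            if bond_seen:
                raise ValueError(f"molecule type '{name}' may not declare bonds")
            comps.append(ComponentDef(cname, tuple(states)))
    return MoleculeTypeDef(name, tuple(comps))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _validate_pattern(pattern: PatternGraph, types: dict[str, MoleculeTypeDef],
                      where: str) -> None:
    for pm in pattern.molecules:
        if pm.name not in types:
            raise ValueError(f"{where}: undeclared molecule '{pm.name}'")
        mt = types[pm.name]
        by_name: dict[str, int] = {}
        for pc in pm.components:
            by_name[pc.name] = by_name.get(pc.name, 0) + 1
        for cname, n in by_name.items():
            declared = [cd for cd in mt.components if cd.name == cname]
            if not declared:
                raise ValueError(f"{where}: undeclared component '{pm.name}.{cname}'")
            if n > len(declared):
                raise ValueError(
                    f"{where}: component '{pm.name}.{cname}' listed {n} times "
                    f"but declared {len(declared)} times")
        for pc in pm.components:
            if pc.state is not None:
                allowed = set()
                for cd in mt.components:
                    if cd.name == pc.name:
                        allowed.update(cd.states)
                if pc.state not in allowed:
                    raise ValueError(
                        f"{where}: state '~{pc.state}' not declared for "
                        f"'{pm.name}.{pc.name}'")


def _infer_molecule_types(seed_patterns: Sequence[PatternGraph],
                          all_patterns: Sequence[PatternGraph]) -> tuple[MoleculeTypeDef, ...]:
    """Fallback when the molecule types block is absent: component layout
    from the seed species, allowed states from every state mentioned."""
    states_seen: dict[tuple[str, str], set[str]] = {}
    for pat in all_patterns:
        for pm in pat.molecules:
            for pc in pm.components:
                if pc.state is not None:
                    states_seen.setdefault((pm.name, pc.name), set()).add(pc.state)
    types: dict[str, MoleculeTypeDef] = {}
    for pat in seed_patterns:
        for pm in pat.molecules:
            if pm.name in types:
                continue
            comps = tuple(
                ComponentDef(pc.name,
                             tuple(sorted(states_seen.get((pm.name, pc.name), ()))))
                for pc in pm.components)
            types[pm.name] = MoleculeTypeDef(pm.name, comps)
    return tuple(types.values())


# ---------------------------------------------------------------------------
# reversible expansion
# ---------------------------------------------------------------------------

def expand_reversible(raw_rules: Sequence[RawRule]) -> list[Rule]:
    """Expand each ``<->`` form into two unidirectional rules (forward
    before reverse, input order preserved); ``->`` forms pass through."""
    out: list[Rule] = []
    for raw in raw_rules:
        if raw.reversible:
            if len(raw.rates) != 2:
                raise ValueError(
                    f"rule '{raw.name}': reversible rule needs exactly two rates")
            out.append(build_rule(raw.name, raw.lhs, raw.rhs, raw.rates[0]))
            out.append(build_rule(raw.name + "_rev", raw.rhs, raw.lhs, raw.rates[1]))
        else:
            if len(raw.rates) != 1:
                raise ValueError(
                    f"rule '{raw.name}': irreversible rule needs exactly one rate")
            out.append(build_rule(raw.name, raw.lhs, raw.rhs, raw.rates[0]))
    return out


# ---------------------------------------------------------------------------
# the model file
# ---------------------------------------------------------------------------

_ACTION_RE = re.compile(rf"^({_NAME})\s*\(\s*(?:\{{(.*)\}}\s*)?\)\s*;?\s*$")


def _parse_action(line: str, env: dict[str, float], lineno: int) -> Optional[SimulationConfig]:
    m = _ACTION_RE.match(line)
    if not m:
        raise ParseError(f"cannot parse action command '{line}'", lineno)
    cmd, args_text = m.group(1), m.group(2) or ""
    if cmd not in ("simulate_rm", "simulate"):
        logger.warning("ignoring unsupported action command '%s'", cmd)
        return None
    args: dict[str, float] = {}
    for part in filter(None, (p.strip() for p in args_text.split(","))):
        if "=>" not in part:
            raise ParseError(f"cannot parse action argument '{part}'", lineno)
        key, val = (x.strip().strip("\"'") for x in part.split("=>", 1))
        try:
            args[key] = eval_expression(val, env)
        except (ValueError, KeyError):
            logger.warning("ignoring non-numeric action argument '%s'", part)
    t_end = args.get("t_end", 10.0)
    n_report = int(args.get("n_steps", args.get("n_report", 20)))
    cfg = SimulationConfig(t_end=t_end, n_report=n_report,
                           seed=int(args.get("seed", 0)))
    if "max_events" in args:
        cfg.max_events = int(args["max_events"])
    return cfg


def parse_model(text: str) -> ModelSpec:
    """Parse BNGL-subset source into a fully resolved :class:`ModelSpec`.

    Reversible rules are already expanded in the result; parameter
    arithmetic is evaluated; every name is validated against the molecule
    type declarations.
    """
    param_lines: list[tuple[int, str, str]] = []
    type_lines: list[tuple[int, str]] = []
    species_lines: list[tuple[int, str]] = []
    rule_lines: list[tuple[int, str]] = []
    obs_lines: list[tuple[int, str]] = []
    action_lines: list[tuple[int, str]] = []

    block: Optional[str] = None
    for lineno, rawline in enumerate(text.splitlines(), start=1):
        line = rawline.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("begin "):
            name = line[len("begin "):].strip()
            if name not in _KNOWN_BLOCKS:
                raise ParseError(f"unknown block '{name}'", lineno)
            if name != "model":
                if block is not None:
                    raise ParseError(f"nested block '{name}'", lineno)
                block = name
            continue
        if line.startswith("end "):
            name = line[len("end "):].strip()
            if name != "model":
                if block != name:
                    raise ParseError(f"'end {name}' does not close '{block}'", lineno)
                block = None
            continue
        if block == "parameters":
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ParseError(f"cannot parse parameter line '{line}'", lineno)
            param_lines.append((lineno, parts[0], parts[1]))
        elif block == "molecule types":
            type_lines.append((lineno, line))
        elif block in ("species", "seed species"):
            species_lines.append((lineno, line))
        elif block == "reaction rules":
            rule_lines.append((lineno, line))
        elif block == "observables":
            obs_lines.append((lineno, line))
        elif block == "actions" or block is None:
            action_lines.append((lineno, line))

    # parameters: iterate substitution until closure
    params: dict[str, float] = {}
    pending = list(param_lines)
    while pending:
        progressed = False
        remaining = []
        for lineno, name, expr in pending:
            try:
                params[name] = eval_expression(expr, params)
                progressed = True
            except KeyError:
                remaining.append((lineno, name, expr))
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
        if not progressed:
            lineno, name, expr = remaining[0]
            raise ParseError(
                f"parameter '{name}' references undefined names in '{expr}'", lineno)
        pending = remaining

    # molecule types
    mol_types: list[MoleculeTypeDef] = []
    for lineno, line in type_lines:
        try:
            mol_types.append(_parse_molecule_type(line))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc

    # seed species
    seeds: list[tuple[PatternGraph, int]] = []
    for lineno, line in species_lines:
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"species line needs a pattern and a count: '{line}'", lineno)
        try:
            pattern = parse_pattern(parts[0])
            count = eval_expression(parts[1], params)
        except (ValueError, KeyError) as exc:
            raise ParseError(str(exc), lineno) from exc
        if count < 0 or abs(count - round(count)) > 1e-9:
            raise ParseError(f"seed copy number must be a nonnegative integer, got {count}",
                             lineno)
        seeds.append((pattern, int(round(count))))

    # reaction rules
    raw_rules: list[RawRule] = []
    for lineno, line in rule_lines:
        try:
            raw_rules.append(_parse_rule_line(line, params, len(raw_rules) + 1))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc

    # observables
    observables: list[ObservableDef] = []
    for lineno, line in obs_lines:
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"observable line needs type, name and pattern(s): '{line}'",
                             lineno)
        obs_type, name = parts[0], parts[1]
        if obs_type not in ("Molecules", "Species"):
            raise ParseError(f"unknown observable type '{obs_type}'", lineno)
        try:
            patterns = tuple(parse_pattern(p.rstrip(",")) for p in parts[2:])
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
        observables.append(ObservableDef(name, obs_type, patterns))

    # actions
    config: Optional[SimulationConfig] = None
    for lineno, line in action_lines:
        cfg = _parse_action(line, params, lineno)
        if cfg is not None:
            config = cfg

    # molecule types: declared or inferred
    all_patterns = [p for p, _ in seeds]
    for raw in raw_rules:
        all_patterns.extend(raw.lhs)
        all_patterns.extend(raw.rhs)
    for obs in observables:
        all_patterns.extend(obs.patterns)
    if not mol_types:
        mol_types = list(_infer_molecule_types([p for p, _ in seeds], all_patterns))
    types = {mt.name: mt for mt in mol_types}
    if len(types) != len(mol_types):
        raise ParseError("duplicate molecule type declaration")

    for pat, _ in seeds:
        _validate_pattern(pat, types, f"species '{render_pattern(pat)}'")
    for raw in raw_rules:
        for pat in list(raw.lhs) + list(raw.rhs):
            _validate_pattern(pat, types, f"rule '{raw.name}'")
    for obs in observables:
        for pat in obs.patterns:
            _validate_pattern(pat, types, f"observable '{obs.name}'")

    rules = tuple(expand_reversible(raw_rules))
    return ModelSpec(parameters=params, molecule_types=tuple(mol_types),
                     seed_species=tuple(seeds), rules=rules,
                     observables=tuple(observables), actions=config)


def _parse_rule_line(line: str, env: dict[str, float], index: int) -> RawRule:
    name = f"R{index}"
    m = re.match(rf"^({_NAME})\s*:\s*(.*)$", line)
    if m:
        name, line = m.group(1), m.group(2)
    line = line.replace("<->", " <-> ")
    line = re.sub(r"(?<!<)->", " -> ", line)
    tokens = line.split()
    arrow = None
    for i, t in enumerate(tokens):
        if t in ("->", "<->"):
            arrow = i
            break
    if arrow is None:
        raise ValueError(f"rule has no arrow: '{line}'")
    lhs_text = "".join(tokens[:arrow])
    rest = tokens[arrow + 1:]
    if not rest:
        raise ValueError(f"rule has no right-hand side: '{line}'")
    rhs_parts = [rest[0]]
    j = 1
    while j + 1 < len(rest) + 1 and j < len(rest) and rest[j] == "+":
        if j + 1 >= len(rest):
            raise ValueError(f"dangling '+' on rule RHS: '{line}'")
        rhs_parts.append(rest[j + 1])
        j += 2
    rhs_text = "+".join(rhs_parts)
    rate_text = " ".join(rest[j:]).strip()
    if not rate_text:
        raise ValueError(f"rule has no rate expression: '{line}'")
    rates = []
    for expr in rate_text.split(","):
        try:
            rates.append(eval_expression(expr.strip(), env))
        except KeyError as exc:
            raise ValueError(f"unknown parameter {exc} in rule rate '{expr.strip()}'")
    for r in rates:
        if r < 0:
            raise ValueError(f"negative rule rate {r}")
    lhs = parse_reactant_side(lhs_text)
    rhs = parse_reactant_side(rhs_text)
    return RawRule(name=name, lhs=lhs, rhs=rhs, rates=tuple(rates),
                   reversible=tokens[arrow] == "<->")


def parse_model_file(path) -> ModelSpec:
    return parse_model(Path(path).read_text())


# ---------------------------------------------------------------------------
# rendering (round-trip support; fixtures emit models through this)
# ---------------------------------------------------------------------------

def render_model(model: ModelSpec) -> str:
    out = ["begin model", "begin parameters"]
    for name, val in model.parameters.items():
        out.append(f"  {name} {val!r}")
    out.append("end parameters")
    out.append("begin molecule types")
    for mt in model.molecule_types:
        comps = ",".join(cd.name + "".join(f"~{s}" for s in cd.states)
                         for cd in mt.components)
        out.append(f"  {mt.name}({comps})")
    out.append("end molecule types")
    out.append("begin species")
    for pattern, count in model.seed_species:
        out.append(f"  {render_pattern(pattern)} {count}")
    out.append("end species")
    out.append("begin reaction rules")
    for rule in model.rules:
        lhs = " + ".join(render_pattern(p) for p in rule.lhs)
        rhs = " + ".join(render_pattern(p) for p in rule.rhs)
        out.append(f"  {rule.name}: {lhs} -> {rhs} {rule.k!r}")
    out.append("end reaction rules")
    out.append("begin observables")
    for obs in model.observables:
        pats = " ".join(render_pattern(p) for p in obs.patterns)
        out.append(f"  {obs.obs_type} {obs.name} {pats}")
    out.append("end observables")
    out.append("end model")
    if model.actions is not None:
        cfg = model.actions
        out.append(f"simulate_rm({{t_end=>{cfg.t_end!r},n_steps=>{cfg.n_report},"
                   f"seed=>{cfg.seed}}});")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# .gdat / .info
# ---------------------------------------------------------------------------

def write_gdat(times: Sequence[float], values, names: Sequence[str], path) -> None:
    """Whitespace table: '# time <names...>' header then one row per report
    time, scientific notation with 8+ significant digits."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.ndim == 1:
        values = values.reshape(len(times), -1) if values.size else values.reshape(0, 0)
    if values.shape[0] != len(times):
        raise ValueError(f"{len(times)} times but {values.shape[0]} value rows")
    if values.size and values.shape[1] != len(names):
        raise ValueError(f"{len(names)} names but {values.shape[1]} value columns")
    with open(path, "w") as fh:
        header = "".join(f" {n:>16s}" for n in ["time", *names])
        fh.write("#" + header + "\n")
        for t, row in zip(times, values if values.size else [[]] * len(times)):
            fh.write(" " + "".join(f" {x: .8e}" for x in [t, *row]) + "\n")


def read_gdat(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing gdat header")
    names = header[1:].split()
    if not names or names[0] != "time":
        raise ValueError(f"{path}: gdat header must start with 'time'")
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return np.zeros(0), np.zeros((0, len(names) - 1)), names[1:]
    return data[:, 0], data[:, 1:], names[1:]


_INFO_KEY_ORDER = ["model", "seed", "t_end", "n_report", "events", "wall_time_s",
                   "truncated"]


def write_info(meta: dict, path) -> None:
    """Run metadata as 'key: value' lines, documented keys first in fixed
    order, any extra keys after in insertion order."""
    keys = [k for k in _INFO_KEY_ORDER if k in meta]
    keys += [k for k in meta if k not in _INFO_KEY_ORDER]
    with open(path, "w") as fh:
        for k in keys:
            fh.write(f"{k}: {meta[k]}\n")


def read_info(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            key, _, val = line.partition(":")
            out[key.strip()] = val.strip()
    return out
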