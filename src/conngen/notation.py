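"""Symbolic annotations and DOT export of network diagrams.

Projections carry compact rule symbols (delta for one-to-one, Omega for
all-to-all, X for explicit lists, p for pairwise Bernoulli, N_syn / K_in /
K_out for the fixed-count rules, p(r) for distance-modulated Bernoulli)
plus constraint flags: the letter A (autapses) or M (multapses) means
*allowed*; the struck-out letter means *prohibited*.  Parameter notes mark
weights and delays as constant (overline) or sampled from a distribution
(~D).  ASCII fallbacks ("delta", "!A", "w=const", "w~D") are available for
renderers without Unicode support.

Diagrams are exported as DOT graphs: node shape encodes the role (square
for generic, triangle for excitatory, circle for inhibitory, hexagon for
stimulating devices, parallelogram for recorders), a double frame
(peripheries=2) marks population nodes, edge style is solid for
deterministic and dashed for probabilistic rules, and bidirectional
symmetric connections get arrowheads on both ends.
"""

from __future__ import annotations

from .config import DETERMINISTIC_RULES, NetworkConfig, ProjectionSpec, SUPPORTED_RULES
from .core import Role

__all__ = ["projection_annotation", "export_dot"]

_STRIKE = "̶"      # combining long stroke overlay
_OVERLINE = "̅"    # combining overline

_RULE_SYMBOL = {
    "one_to_one": ("δ", "delta"),
    "all_to_all": ("Ω", "Omega"),
    "explicit": ("X", "X"),
    "pairwise_bernoulli": ("p", "p"),
    "fixed_total": ("N_syn", "N_syn"),
    "fixed_in": ("K_in", "K_in"),
    "fixed_out": ("K_out", "K_out"),
    "spatial_bernoulli": ("p(r)", "p(r)"),
}

# rules whose definition permits multapses (so the flag is informative)
_MULTAPSE_CAPABLE = ("fixed_total", "fixed_in", "fixed_out", "explicit")

_ROLE_SHAPE = {
    Role.generic: "square",
    Role.excitatory: "triangle",
    Role.inhibitory: "circle",
    Role.stimulator: "hexagon",
    Role.recorder: "parallelogram",
}


def _flag(letter: str, allowed: bool, ascii_mode: bool) -> str:
    if allowed:
        return letter
    return f"!{letter}" if ascii_mode else letter + _STRIKE


def _param_note(symbol: str, spec, ascii_mode: bool) -> str:
    if spec.kind == "constant":
        return f"{symbol}=const" if ascii_mode else symbol + _OVERLINE
    letter = (spec.distribution or "D")[:1].upper()
    return f"{symbol}~{letter}" if ascii_mode else f"{symbol}∼{letter}"


def projection_annotation(proj: ProjectionSpec, ascii_mode: bool = False,
                          same_pop: bool | None = None) -> str:
    """Deterministic annotation string for a projection.

    Example: fixed in-degree with autapses prohibited and multapses allowed
    renders as ``"K_in, !A, M"`` in ASCII mode.  The autapse flag appears
    only for within-population projections (for disjoint populations
    autapses cannot occur by definition); the multapse flag only for rules
    that can produce multapses.
    """
    if proj.rule not in SUPPORTED_RULES:
        raise ValueError(f"unsupported rule {proj.rule!r}")
    symbol = _RULE_SYMBOL[proj.rule][1 if ascii_mode else 0]
    parts = [symbol]
    if same_pop is None:
        same_pop = proj.source == proj.target
    if same_pop and proj.autapses is not None:
        parts.append(_flag("A", proj.autapses, ascii_mode))
    if proj.rule in _MULTAPSE_CAPABLE and proj.multapses is not None:
        parts.append(_flag("M", proj.multapses, ascii_mode))
    if proj.weight is not None:
        parts.append(_param_note("w", proj.weight, ascii_mode))
    if proj.delay is not None:
        parts.append(_param_note("d", proj.delay, ascii_mode))
    return ", ".join(parts)


def export_dot(config: NetworkConfig, ascii_mode: bool = True) -> str:
    """Render a network config as a DOT digraph.

    Node shape encodes the role, ``peripheries=2`` marks populations
    (size > 1), solid/dashed edges distinguish deterministic from
    probabilistic rules, edge labels carry the annotation strings, and
    ``dir=both`` renders bidirectional symmetric connections.
    """
    lines = ["digraph network {", "  rankdir=LR;"]
    for pop in config.populations:
        shape = _ROLE_SHAPE[Role(pop.role)]
        peripheries = 2 if pop.size > 1 else 1
        lines.append(
            f'  "{pop.name}" [shape={shape}, peripheries={peripheries}, '
            f'label="{pop.name}"];')
    for proj in config.projections:
        style = "solid" if proj.rule in DETERMINISTIC_RULES else "dashed"
        label = projection_annotation(proj, ascii_mode=ascii_mode)
        attrs = [f"style={style}", f'label="{label}"']
        if proj.bidirectional:
            attrs.append("dir=both")
        lines.append(f'  "{proj.source}" -> "{proj.target}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
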