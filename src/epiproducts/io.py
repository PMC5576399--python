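"""Serialization and rendering: YAML model documents, DOT diagrams,
LaTeX equation export, CSV trajectories.

The model document is a declarative YAML/JSON dialect listing
compartments, arcs with infix rate strings, aggregate definitions, and
the naming convention. Round-tripping (write then read) yields a model
structurally identical to the original, parallel arcs included. Rate
strings use ``* / + - **`` and parentheses; symbols are identifiers with
optional ``_`` subscript chains (``beta_12``, ``N_M``).
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Mapping

import sympy as sp
import yaml

from .core import SINK, SOURCE, CompartmentalModel, Naming, _Terminal
from .dynamics import ODESystem, Trajectory
from .rates import RateSyntaxError, parse_rate

__all__ = [
    "SCHEMA_VERSION",
    "ModelDocumentError",
    "model_to_dict",
    "model_from_dict",
    "write_model",
    "read_model",
    "to_dot",
    "odes_to_latex",
    "odes_to_text",
    "trajectory_to_csv",
]

SCHEMA_VERSION = 1


class ModelDocumentError(ValueError):
    """A model document violates the schema; the message names the field."""


def _labels_out(labels) -> object:
    return labels[0] if len(labels) == 1 else list(labels)


def _endpoint_out(end) -> object:
    if end is SOURCE:
        return "SOURCE"
    if end is SINK:
        return "SINK"
    return _labels_out(end)


def model_to_dict(model: CompartmentalModel) -> dict:
    """Serialize a model to a plain document (YAML/JSON-ready)."""
    doc: dict = {
        "schema": SCHEMA_VERSION,
        "name": model.name,
        "compartments": [_labels_out(c) for c in model.labels()],
    }
    if model.naming.explicit or model.naming.subscript_maps:
        naming: dict = {}
        if model.naming.explicit:
            naming["names"] = {
                " ".join(k): v for k, v in model.naming.explicit.items()
            }
        if model.naming.subscript_maps:
            naming["subscripts"] = [dict(m) for m in model.naming.subscript_maps]
        doc["naming"] = naming
    if model.aggregates:
        doc["aggregates"] = {
            name: [_labels_out(m) for m in members]
            for name, members in model.aggregates.items()
        }
    arcs = []
    for arc in model.arcs:
        entry: dict = {
            "from": _endpoint_out(arc.source),
            "to": _endpoint_out(arc.target),
            "rate": str(arc.rate),
        }
        if arc.args:
            entry["args"] = [_labels_out(a) for a in arc.args]
        arcs.append(entry)
    doc["arcs"] = arcs
    return doc


def _labels_in(value, where: str):
    if isinstance(value, str):
        return (value,)
    if isinstance(value, (list, tuple)):
        return tuple(str(v) for v in value)
    raise ModelDocumentError(f"{where}: expected a label or list of labels")


def model_from_dict(doc: Mapping) -> CompartmentalModel:
    """Build a model from a document, validating the schema as it goes."""
    if not isinstance(doc, Mapping):
        raise ModelDocumentError("document: expected a mapping")
    schema = doc.get("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise ModelDocumentError(f"schema: unsupported version {schema!r}")
    naming = Naming()
    ndoc = doc.get("naming") or {}
    if ndoc:
        explicit = {
            tuple(k.split()): v for k, v in (ndoc.get("names") or {}).items()
        }
        maps = tuple(dict(m) for m in ndoc.get("subscripts") or ())
        naming = Naming(explicit=explicit, subscript_maps=maps)
    model = CompartmentalModel(str(doc.get("name", "model")), naming)
    comps = doc.get("compartments")
    if not isinstance(comps, list) or not comps:
        raise ModelDocumentError("compartments: expected a non-empty list")
    for i, c in enumerate(comps):
        model.add_compartment(_labels_in(c, f"compartments[{i}]"))
    for name, members in (doc.get("aggregates") or {}).items():
        model.define_aggregate(
            str(name),
            [_labels_in(m, f"aggregates[{name}]") for m in members],
        )
    arcs = doc.get("arcs", [])
    if not isinstance(arcs, list):
        raise ModelDocumentError("arcs: expected a list")
    for i, entry in enumerate(arcs):
        where = f"arcs[{i}]"
        if not isinstance(entry, Mapping):
            raise ModelDocumentError(f"{where}: expected a mapping")
        for key in ("from", "to", "rate"):
            if key not in entry:
                raise ModelDocumentError(f"{where}.{key}: missing")
        src = entry["from"]
        tgt = entry["to"]
        src = SOURCE if src == "SOURCE" else _labels_in(src, f"{where}.from")
        tgt = SINK if tgt == "SINK" else _labels_in(tgt, f"{where}.to")
        try:
            rate = parse_rate(str(entry["rate"]))
        except RateSyntaxError as exc:
            raise ModelDocumentError(f"{where}.rate: {exc}") from exc
        args = entry.get("args")
        if args is not None:
            args = [_labels_in(a, f"{where}.args") for a in args]
        model.add_arc(src, tgt, rate, args=args)
    return model


def write_model(model: CompartmentalModel, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(model_to_dict(model), sort_keys=False), encoding="utf-8"
    )


def read_model(path) -> CompartmentalModel:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return model_from_dict(doc)


def to_dot(model: CompartmentalModel, rankdir: str = "LR") -> str:
    """Render the model diagram as Graphviz DOT text.

    One node per compartment (display names), one edge per arc labeled
    with its rate; SOURCE and SINK are drawn as point nodes. Output is
    deterministic for a given model (fixed node and arc order), so
    diagrams are reproducible byte for byte.
    """
    lines = [f'digraph "{model.name}" {{', f"  rankdir={rankdir};"]
    used_terminals = set()
    for arc in model.arcs:
        for end in (arc.source, arc.target):
            if isinstance(end, _Terminal):
                used_terminals.add(end.name)
    for c in model.labels():
        lines.append(f'  "{model.display_name(c)}" [shape=circle];')
    for t in sorted(used_terminals):
        lines.append(f'  "{t}" [shape=point];')

    def node(end):
        return end.name if isinstance(end, _Terminal) else model.display_name(end)

    for arc in model.arcs:
        lines.append(
            f'  "{node(arc.source)}" -> "{node(arc.target)}" '
            f'[label="{sp.sstr(arc.rate)}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def odes_to_text(system: ODESystem) -> str:
    return "\n".join(f"d{x}/dt = {sp.sstr(system.rhs[x])}" for x in system.states)


def odes_to_latex(system: ODESystem) -> str:
    """LaTeX align* block of the system."""
    body = " \\\\\n".join(
        rf"\frac{{d{sp.latex(sp.Symbol(x))}}}{{dt}} &= {sp.latex(system.rhs[x])}"
        for x in system.states
    )
    return "\\begin{align*}\n" + body + "\n\\end{align*}\n"


def trajectory_to_csv(traj: Trajectory, path=None) -> str:
    """Write a trajectory as CSV with a header row of display names."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["t", *traj.states])
    for i, t in enumerate(traj.t):
        writer.writerow([f"{t:.10g}"] + [f"{v:.10g}" for v in traj.y[:, i]])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
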