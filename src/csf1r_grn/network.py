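"""Topology of the CSF1R-centered pro-inflammatory gene regulatory network.

The network couples 11 components — the ligand CSF1, six transcription
factors (STAT1, STAT3, IRF8, PU1, NFKB, CEBPA) and four cell-membrane
receptors (IL6R, TNFR1, CSF1R, CSF3R) — through 42 signed regulations,
each acting either on transcription of the target's mRNA or on the
post-translational switch between inactive and active protein forms.
Lipopolysaccharide (LPS), the pro-inflammatory stimulus, appears as an
external input node named ``"LPS"`` rather than as a component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx

__all__ = [
    "Component",
    "Regulation",
    "NetworkDefinition",
    "NetworkValidationError",
    "load_network",
    "default_network",
    "write_network",
    "write_sif",
    "feedback_loops",
    "Cycle",
]

LPS = "LPS"

ROLES = ("ligand", "transcription_factor", "receptor")
SIGNS = ("activation", "inhibition")
LEVELS = ("transcriptional", "post_translational")


class NetworkValidationError(ValueError):
    """A network file or object violates the schema or its invariants."""


@dataclass(frozen=True)
class Component:
    name: str
    role: str
    has_active_form: bool

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise NetworkValidationError(
                f"component {self.name!r}: unknown role {self.role!r}"
            )


@dataclass(frozen=True)
class Regulation:
    """One signed, typed edge; ``id`` is the row number of the packaged table."""

    id: int
    source: str
    target: str
    sign: str
    level: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise NetworkValidationError(f"regulation {self.id}: bad sign {self.sign!r}")
        if self.level not in LEVELS:
            raise NetworkValidationError(f"regulation {self.id}: bad level {self.level!r}")


@dataclass
class NetworkDefinition:
    components: list[Component]
    regulations: list[Regulation]
    version: str = "1.0"

    def __post_init__(self) -> None:
        self._by_name = {c.name: c for c in self.components}
        if len(self._by_name) != len(self.components):
            raise NetworkValidationError("duplicate component names")
        seen: set[tuple[str, str, str]] = set()
        for r in self.regulations:
            for end, nm in (("source", r.source), ("target", r.target)):
                if nm != LPS and nm not in self._by_name:
                    raise NetworkValidationError(
                        f"regulation {r.id}: unknown {end} component {nm!r}"
                    )
            if r.target == LPS:
                raise NetworkValidationError(f"regulation {r.id}: LPS cannot be a target")
            key = (r.source, r.target, r.level)
            if key in seen:
                raise NetworkValidationError(f"regulation {r.id}: duplicate edge {key}")
            seen.add(key)
            if r.level == "post_translational":
                tgt = self._by_name[r.target]
                if not tgt.has_active_form:
                    raise NetworkValidationError(
                        f"regulation {r.id}: post-translational edge targets "
                        f"{r.target}, which has no active form"
                    )

    def component(self, name: str) -> Component:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown component {name!r}") from None

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def regulations_on(self, target: str, level: str | None = None) -> list[Regulation]:
        """Incoming edges of ``target``, optionally restricted to one level."""
        return [
            r
            for r in self.regulations
            if r.target == target and (level is None or r.level == level)
        ]

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "components": [
                {"name": c.name, "role": c.role, "has_active_form": c.has_active_form}
                for c in self.components
            ],
            "regulations": [
                {
                    "id": r.id,
                    "source": r.source,
                    "target": r.target,
                    "sign": r.sign,
                    "level": r.level,
                    "description": r.description,
                }
                for r in self.regulations
            ],
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkDefinition):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def graph(self) -> nx.MultiDiGraph:
        """Directed multigraph view (LPS included as a node when referenced)."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.names)
        for r in self.regulations:
            g.add_edge(r.source, r.target, id=r.id, sign=r.sign, level=r.level)
        return g


def _parse(doc: dict, origin: str) -> NetworkDefinition:
    try:
        comps = [
            Component(c["name"], c["role"], bool(c["has_active_form"]))
            for c in doc["components"]
        ]
        regs = [
            Regulation(
                int(r["id"]), r["source"], r["target"], r["sign"], r["level"],
                r.get("description", ""),
            )
            for r in doc["regulations"]
        ]
    except (KeyError, TypeError) as exc:
        raise NetworkValidationError(f"{origin}: malformed network document ({exc})") from exc
    return NetworkDefinition(comps, regs, version=str(doc.get("version", "1.0")))


def load_network(path: str | Path) -> NetworkDefinition:
    """Read and validate a network JSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    return _parse(doc, str(path))


def default_network() -> NetworkDefinition:
    """The packaged 11-component / 42-regulation network."""
    doc = json.loads(
        resources.files("csf1r_grn.data").joinpath("network.json").read_text()
    )
    net = _parse(doc, "packaged network")
    _check_packaged_invariants(net)
    return net


def _check_packaged_invariants(net: NetworkDefinition) -> None:
    roles = [c.role for c in net.components]
    if len(net.components) != 11 or roles.count("ligand") != 1 \
            or roles.count("transcription_factor") != 6 or roles.count("receptor") != 4:
        raise NetworkValidationError("packaged network: wrong component census")
    ids = sorted(r.id for r in net.regulations)
    if ids != list(range(1, 43)):
        raise NetworkValidationError("packaged network: regulation ids must cover 1..42")
    active = {c.name for c in net.components if c.has_active_form}
    if active != {"STAT1", "STAT3", "CSF1R", "NFKB", "CEBPA"}:
        raise NetworkValidationError("packaged network: wrong active-form set")
    inhib = {(r.source, r.target) for r in net.regulations if r.sign == "inhibition"}
    if inhib != {("IRF8", "STAT1"), ("LPS", "CEBPA")}:
        raise NetworkValidationError("packaged network: wrong inhibitory edge set")


def write_network(net: NetworkDefinition, path: str | Path) -> None:
    """Write a network to JSON; ``load_network`` round-trips it exactly."""
    with open(path, "w") as fh:
        json.dump(net.to_dict(), fh, indent=1)
        fh.write("\n")


def write_sif(net: NetworkDefinition, path: str | Path) -> None:
    """Tab-separated edge list (source, sign, target), one edge per line."""
    with open(path, "w") as fh:
        for r in net.regulations:
            fh.write(f"{r.source}\t{r.sign}\t{r.target}\n")


@dataclass(frozen=True)
class Cycle:
    nodes: tuple[str, ...]  # without the closing repeat
    positive: bool

    def __len__(self) -> int:
        return len(self.nodes)


def _edge_signs(net: NetworkDefinition) -> dict[tuple[str, str], set[str]]:
    signs: dict[tuple[str, str], set[str]] = {}
    for r in net.regulations:
        signs.setdefault((r.source, r.target), set()).add(r.sign)
    return signs


def feedback_loops(net: NetworkDefinition, max_length: int) -> list[Cycle]:
    """All simple directed cycles among components, up to ``max_length`` nodes.

    Each cycle is annotated positive or negative by the parity of its
    inhibitory edges; an edge that is both activating and inhibiting at
    different levels counts with each sign (such cycles are reported once
    per sign combination that exists — the packaged network has none).
    LPS, being an input rather than a component, takes part in no loop.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    g = nx.DiGraph()
    g.add_nodes_from(net.names)
    signs = _edge_signs(net)
    for (s, t) in signs:
        if s != LPS:
            g.add_edge(s, t)
    out: list[Cycle] = []
    for nodes in nx.simple_cycles(g, length_bound=max_length):
        n_inhib = sum(
            "inhibition" in signs[(nodes[i], nodes[(i + 1) % len(nodes)])]
            for i in range(len(nodes))
        )
        # canonical rotation: start at lexicographically smallest node
        k = min(range(len(nodes)), key=lambda i: nodes[i])
        rot = tuple(nodes[k:] + nodes[:k])
        out.append(Cycle(rot, positive=(n_inhib % 2 == 0)))
    out.sort(key=lambda c: (len(c), c.nodes))
    return out
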