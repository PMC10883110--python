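"""Cortical mapping of selected channel pairs and network export.

Electrodes are mapped onto cortical anatomy (gyrus + Brodmann area and
MNI-style coordinates) through an automatic electrode-to-cortex lookup
table rather than source localization. The optimal-feature-subset
channel pairs of each microstate become the edges of the MI functional
connectivity network (MIFCN), weighted by the MCS-VS group-average MI
difference (positive = stronger in MCS), and are exported as plain-text
``.node`` / ``.edge`` files compatible with common brain-network viewers
plus a JSON edge report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .montage import LOBE_COLOR_CLASS, MONTAGE_32, MontageEntry


class MissingElectrodeError(KeyError):
    def __init__(self, label: str, known: list[str]):
        super().__init__(label)
        self.label = label
        self.known = known

    def __str__(self) -> str:
        return f"unknown electrode '{self.label}'; known labels: {', '.join(self.known)}"


@dataclass
class ElectrodeAtlas:
    """Electrode label -> (anatomy, gyrus+BA, coordinates, lobe) mapping."""

    entries: dict[str, MontageEntry]

    def __post_init__(self) -> None:
        for lab, e in self.entries.items():
            if e.lobe not in LOBE_COLOR_CLASS:
                raise ValueError(f"{lab}: lobe must be one of {list(LOBE_COLOR_CLASS)}")
            if not all(np.isfinite(e.coords)):
                raise ValueError(f"{lab}: coordinates must be finite")

    @property
    def labels(self) -> list[str]:
        return list(self.entries)


def default_atlas() -> ElectrodeAtlas:
    """The packaged 32-electrode 10-20 atlas."""
    return ElectrodeAtlas(entries=dict(MONTAGE_32))


def map_electrode(label: str, atlas: ElectrodeAtlas) -> MontageEntry:
    """Case-insensitive lookup of one electrode's cortical projection."""
    entry = atlas.entries.get(label.upper())
    if entry is None:
        raise MissingElectrodeError(label, atlas.labels)
    return entry


@dataclass
class MifcnNode:
    label: str
    coords: tuple[float, float, float]
    lobe: str
    color_class: int


@dataclass
class MifcnEdge:
    pair: tuple[str, str]
    weight: float  # group-average MI difference (MCS - VS)

    @property
    def sign(self) -> int:
        """+1 when MCS has the stronger MI flow, -1 when VS does."""
        return 1 if self.weight > 0 else (-1 if self.weight < 0 else 0)


@dataclass
class Mifcn:
    nodes: list[MifcnNode]
    edges: list[MifcnEdge]
    state: int
    state_name: str = ""


def build_mifcn(
    ofs_pairs: list[tuple[int, int]],
    diff: np.ndarray,
    atlas: ElectrodeAtlas,
    state: int,
    channel_labels: list[str],
    state_name: str = "",
) -> Mifcn:
    """One edge per selected channel pair, weighted by the difference matrix."""
    diff = np.asarray(diff, dtype=np.float64)
    node_labels: list[str] = []
    edges: list[MifcnEdge] = []
    for i, j in ofs_pairs:
        lab_i, lab_j = channel_labels[i], channel_labels[j]
        for lab in (lab_i, lab_j):
            map_electrode(lab, atlas)  # raises MissingElectrodeError if absent
            if lab.upper() not in node_labels:
                node_labels.append(lab.upper())
        edges.append(MifcnEdge(pair=(lab_i.upper(), lab_j.upper()), weight=float(diff[i, j])))
    nodes = []
    for lab in node_labels:
        e = atlas.entries[lab]
        nodes.append(
            MifcnNode(label=lab, coords=e.coords, lobe=e.lobe,
                      color_class=LOBE_COLOR_CLASS[e.lobe])
        )
    return Mifcn(nodes=nodes, edges=edges, state=state, state_name=state_name)


def export_network(net: Mifcn, out_prefix: str | Path) -> dict[str, Path]:
    """Write ``.node``, ``.edge`` and JSON report files.

    ``.node``: one ``x y z color size label`` line per node; ``.edge``:
    the square weighted adjacency over the node order.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    node_path = out_prefix.with_suffix(".node")
    edge_path = out_prefix.with_suffix(".edge")
    json_path = out_prefix.with_suffix(".json")

    with open(node_path, "w") as fh:
        for nd in net.nodes:
            x, y, z = nd.coords
            fh.write(f"{x:.1f}\t{y:.1f}\t{z:.1f}\t{nd.color_class}\t1\t{nd.label}\n")

    index = {nd.label: i for i, nd in enumerate(net.nodes)}
    adj = np.zeros((len(net.nodes), len(net.nodes)))
    for e in net.edges:
        i, j = index[e.pair[0]], index[e.pair[1]]
        adj[i, j] = adj[j, i] = e.weight
    np.savetxt(edge_path, adj, fmt="%.9f", delimiter="\t")

    atlas = default_atlas()
    report = {
        "state": net.state,
        "state_name": net.state_name,
        "edges": [
            {
                "pair": list(e.pair),
                "brodmann": [
                    atlas.entries[e.pair[0]].gyrus_ba if e.pair[0] in atlas.entries else None,
                    atlas.entries[e.pair[1]].gyrus_ba if e.pair[1] in atlas.entries else None,
                ],
                "weight": e.weight,
                "stronger_in": "MCS" if e.sign > 0 else ("VS" if e.sign < 0 else "equal"),
            }
            for e in net.edges
        ],
    }
    json_path.write_text(json.dumps(report, indent=1))
    return {"node": node_path, "edge": edge_path, "json": json_path}


def read_network(out_prefix: str | Path) -> Mifcn:
    """Round-trip reader for exported ``.node`` / ``.edge`` files."""
    out_prefix = Path(out_prefix)
    nodes = []
    with open(out_prefix.with_suffix(".node")) as fh:
        for line in fh:
            x, y, z, color, _size, label = line.split()
            lobe = next(
                (k for k, v in LOBE_COLOR_CLASS.items() if v == int(color)), "frontal"
            )
            nodes.append(
                MifcnNode(label=label, coords=(float(x), float(y), float(z)),
                          lobe=lobe, color_class=int(color))
            )
    adj = np.atleast_2d(np.loadtxt(out_prefix.with_suffix(".edge"), delimiter="\t"))
    meta = json.loads(out_prefix.with_suffix(".json").read_text())
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if adj[i, j] != 0:
                edges.append(MifcnEdge(pair=(nodes[i].label, nodes[j].label), weight=float(adj[i, j])))
    return Mifcn(nodes=nodes, edges=edges, state=int(meta.get("state", 0)),
                 state_name=meta.get("state_name", ""))
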