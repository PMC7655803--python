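"""Plain-text interchange: edge lists, manifests, metric tables.

One network is stored as a TSV edge list (node_i, node_j, weight); a
cohort adds a manifest TSV (subject_id, group, side, updrs, network_path)
pointing at the per-network files.  Everything round-trips through pandas.
"""

from __future__ import annotations

import os
from pathlib import Path

import networkx as nx
import pandas as pd

from mitotopo.cohort import SubjectRecord, SyntheticCohort
from mitotopo.errors import InvalidParameterError
from mitotopo.network import MitoNetwork

__all__ = [
    "write_edgelist",
    "read_edgelist",
    "write_cohort",
    "read_manifest",
]

_MANIFEST_COLUMNS = ["subject_id", "group", "side", "updrs", "network_path"]


def write_edgelist(network: MitoNetwork, path) -> None:
    """TSV edge list: node_i, node_j, weight (isolated nodes as i == j, w=0)."""
    rows = [
        {"node_i": u, "node_j": v, "weight": d.get("weight", 1)}
        for u, v, d in network.graph.edges(data=True)
    ]
    for v in network.graph.nodes():
        if network.graph.degree(v) == 0:
            rows.append({"node_i": v, "node_j": v, "weight": 0})
    pd.DataFrame(
        rows, columns=["node_i", "node_j", "weight"]
    ).to_csv(path, sep="\t", index=False)


def read_edgelist(path, **net_kwargs) -> MitoNetwork:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        if row.node_i == row.node_j:
            g.add_node(row.node_i)  # isolated-node sentinel
        else:
            g.add_edge(row.node_i, row.node_j, weight=int(row.weight))
    return MitoNetwork(graph=g, **net_kwargs)


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write per-network edge lists plus the subject manifest TSV.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.subjects:
        for net in rec.networks:
            rel = f"{net.network_id}.tsv"
            write_edgelist(net, outdir / rel)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "side": net.side,
                    "updrs": rec.updrs,
                    "network_path": rel,
                }
            )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest


def read_manifest(manifest_path) -> list[SubjectRecord]:
    """Load a manifest TSV and its networks into subject records."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParameterError(
            f"manifest lacks columns: {sorted(missing)}"
        )
    records: dict[str, SubjectRecord] = {}
    for row in df.itertuples(index=False):
        sid = str(row.subject_id)
        if sid not in records:
            updrs = float(row.updrs) if pd.notna(row.updrs) else None
            records[sid] = SubjectRecord(
                subject_id=sid, group=str(row.group), updrs=updrs
            )
        net = read_edgelist(
            manifest_path.parent / row.network_path,
            subject_id=sid,
            side=str(row.side),
            network_id=os.path.splitext(os.path.basename(row.network_path))[0],
        )
        records[sid].networks.append(net)
    return list(records.values())
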