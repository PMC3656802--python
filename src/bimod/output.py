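"""Result artifacts: node-level TSV table, GraphML for visualisation, and a
versioned, checksummed JSON archive of a complete run.

All float formatting is pinned to 6 significant digits so repeated runs with
the same seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from typing import TYPE_CHECKING

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from .model import ModuleSearchResults

__all__ = ["write_tsv", "write_graphml", "save_state", "load_state", "ArchiveError"]

log = logging.getLogger(__name__)

ARCHIVE_FORMAT = "bimod-run"
ARCHIVE_VERSION = 1


class ArchiveError(ValueError):
    """State archive is missing, tampered with, or from an unknown version."""


def _fmt(x: float | None) -> str:
    if x is None:
        return "NA"
    return format(float(x), ".6g")


def write_tsv(result: "ModuleSearchResults", path: str) -> None:
    """One row per node of each significant module.

    Columns: module rank (1-based, by score), node ID, node type, node score
    (reactions) or weight (metabolites), module score, p, q.
    """
    sig = result.significant_modules
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("module\tnode_id\tnode_type\tnode_value\tmodule_score\tp_value\tq_value\n")
        for rank, mod in enumerate(sig, start=1):
            rows = [(r, "reaction", result.scores.s[r]) for r in sorted(mod.reaction_ids)]
            rows += [(c, "metabolite", float(result.scores.w[c]))
                     for c in sorted(mod.metabolite_ids)]
            for node, kind, val in rows:
                fh.write(
                    f"{rank}\t{node}\t{kind}\t{_fmt(val)}\t{_fmt(mod.score)}"
                    f"\t{_fmt(mod.p_value)}\t{_fmt(mod.q_value)}\n"
                )
    if not sig:
        log.info("no significant modules: %s contains only the header line", path)


def write_graphml(result: "ModuleSearchResults", network, path: str) -> None:
    """GraphML of the union of significant modules.

    Nodes carry type, score/weight, module rank and q-value; edges are those
    of the original network between nodes of the same module.
    """
    g = nx.Graph()
    for rank, mod in enumerate(result.significant_modules, start=1):
        for r in sorted(mod.reaction_ids):
            g.add_node(r, type="reaction", value=float(result.scores.s[r]),
                       module=rank, q_value=float(mod.q_value))
        for c in sorted(mod.metabolite_ids):
            g.add_node(c, type="metabolite", value=float(result.scores.w[c]),
                       module=rank, q_value=float(mod.q_value))
        for u, v in network.graph.subgraph(mod.node_ids).edges:
            g.add_edge(u, v)
    nx.write_graphml(g, path, named_key_ids=True)


def _canonical(payload: dict) -> str:
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def save_state(result: "ModuleSearchResults", path: str) -> None:
    """Serialise a full run (inputs, configuration, modules, metadata) to a
    checksummed JSON archive."""
    payload = result.to_payload()
    blob = _canonical(payload)
    doc = {
        "format": ARCHIVE_FORMAT,
        "version": ARCHIVE_VERSION,
        "sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "payload": payload,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_state(path: str) -> "ModuleSearchResults":
    """Load an archive written by :func:`save_state`, verifying its version
    and checksum, and rebuild the results object exactly."""
    from .model import ModuleSearchResults

    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ArchiveError(f"{path} is not a valid archive: {exc}") from None
    if doc.get("format") != ARCHIVE_FORMAT:
        raise ArchiveError(f"{path} is not a {ARCHIVE_FORMAT} archive")
    if doc.get("version") != ARCHIVE_VERSION:
        raise ArchiveError(
            f"{path} has version {doc.get('version')!r}; this build reads "
            f"version {ARCHIVE_VERSION}"
        )
    blob = _canonical(doc.get("payload", {}))
    digest = hashlib.sha256(blob.encode()).hexdigest()
    if digest != doc.get("sha256"):
        raise ArchiveError(f"{path} failed its checksum; file corrupted or edited")
    return ModuleSearchResults.from_payload(doc["payload"])
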