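"""Candidate ceRNA network assembly.

DE-restricted lncRNA-miRNA pairs are joined to miRNA-mRNA targets that are
supported by all three prediction tables; a lncRNA and mRNA competing for
the same miRNA form a candidate triplet. Identifier matching is string-based
after case-normalization and whitespace trimming — no alias resolution.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import write_sif

logger = logging.getLogger(__name__)


def _canon(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.casefold()


@dataclasses.dataclass
class CeRNANetwork:
    """Edges of the assembled network plus a node table (id, class)."""

    lnc_mir: pd.DataFrame   # columns: regulator (lncRNA), target (miRNA)
    mir_mrna: pd.DataFrame  # columns: regulator (miRNA), target (mRNA)
    nodes: pd.DataFrame     # columns: node, kind

    @property
    def is_empty(self) -> bool:
        return len(self.lnc_mir) == 0 and len(self.mir_mrna) == 0

    def to_sif(self, path: str | Path) -> Path:
        edges = [(r.regulator, "sponges", r.target) for r in self.lnc_mir.itertuples()]
        edges += [(r.regulator, "represses", r.target) for r in self.mir_mrna.itertuples()]
        return write_sif(edges, path)


def restrict_to_deg(table: pd.DataFrame, deg: Iterable[str]) -> pd.DataFrame:
    """Keep rows whose regulator AND target are differentially expressed."""
    deg = {str(f).strip().casefold() for f in deg}
    keep = _canon(table["regulator"]).isin(deg) & _canon(table["target"]).isin(deg)
    out = table.loc[keep].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    logger.info("restrict_to_deg: kept %d/%d rows", len(out), len(table))
    return out


def intersect_targets(*tables: pd.DataFrame) -> pd.DataFrame:
    """Rows present in every table (matched on canonicalized id pairs)."""
    if len(tables) < 2:
        raise ValueError("need at least two tables to intersect")
    keys = [set(zip(_canon(t["regulator"]), _canon(t["target"]))) for t in tables]
    common = set.intersection(*keys)
    first = tables[0]
    mask = [
        (r, t) in common
        for r, t in zip(_canon(first["regulator"]), _canon(first["target"]))
    ]
    out = first.loc[mask].reset_index(drop=True)
    out.attrs["source"] = "intersection"
    return out


def assemble_network(
    lnc_mir: pd.DataFrame,
    mir_mrna: pd.DataFrame,
    up: Iterable[str] | None = None,
    down: Iterable[str] | None = None,
) -> CeRNANetwork:
    """Prune to miRNAs bridging >=1 lncRNA and >=1 mRNA; drop isolated nodes.

    If DE sets are given, both edge tables are first restricted to them.
    Input row order never matters: edges are sorted before return.
    """
    if up is not None or down is not None:
        deg = set(up or set()) | set(down or set())
        lnc_mir = restrict_to_deg(lnc_mir, deg)
        mir_mrna = restrict_to_deg(mir_mrna, deg)

    lnc_mir = lnc_mir.drop_duplicates(["regulator", "target"])
    mir_mrna = mir_mrna.drop_duplicates(["regulator", "target"])
    bridging = set(lnc_mir["target"]) & set(mir_mrna["regulator"])
    lnc_mir = (
        lnc_mir[lnc_mir["target"].isin(bridging)]
        .sort_values(["regulator", "target"], kind="stable")
        .reset_index(drop=True)
    )
    mir_mrna = (
        mir_mrna[mir_mrna["regulator"].isin(bridging)]
        .sort_values(["regulator", "target"], kind="stable")
        .reset_index(drop=True)
    )
    nodes = (
        [(n, "lncRNA") for n in sorted(set(lnc_mir["regulator"]))]
        + [(n, "miRNA") for n in sorted(bridging)]
        + [(n, "mRNA") for n in sorted(set(mir_mrna["target"]))]
    )
    net = CeRNANetwork(lnc_mir, mir_mrna, pd.DataFrame(nodes, columns=["node", "kind"]))
    if net.is_empty:
        logger.warning("assemble_network: empty ceRNA network")
    return net


def enumerate_triplets(network: CeRNANetwork) -> list[tuple[str, str, str]]:
    """All lncRNA-miRNA-mRNA paths, deduplicated, in lexicographic order."""
    partners: dict[str, set[str]] = {}
    for row in network.lnc_mir.itertuples():
        partners.setdefault(row.target, set()).add(row.regulator)
    triplets = set()
    for row in network.mir_mrna.itertuples():
        for lnc in partners.get(row.regulator, ()):
            triplets.add((lnc, row.regulator, row.target))
    return sorted(triplets)


def node_attributes(network: CeRNANetwork, de_direction: dict[str, str] | None = None) -> pd.DataFrame:
    """Node table with class and (optional) DE direction annotation."""
    nodes = network.nodes.copy()
    if de_direction:
        nodes["direction"] = [de_direction.get(n, "ns") for n in nodes["node"]]
    return nodes


def planted_triplet_paths(
    network: CeRNANetwork, triplets: Sequence[tuple[str, str, str]]
) -> list[tuple[str, str, str]]:
    """Subset of ``triplets`` realized as connected paths in the network."""
    present = set(enumerate_triplets(network))
    return [t for t in triplets if t in present]
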