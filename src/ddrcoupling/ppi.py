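"""Within-panel protein-protein interaction evidence from STRING-format
flat files.

Works on locally supplied files in the detailed-links dialect
(whitespace-delimited with a header: ``protein1 protein2 ...
experimental database combined_score``, scores scaled 0-1000) and the
alias dialect (``protein_id<TAB>alias<TAB>source``).  Panel gene symbols
are mapped to canonical protein identifiers through the alias table,
edges are filtered to pairs where both partners map into the panel, and
experimental-channel evidence is tabulated at multiple thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["PPIEdge", "map_aliases", "filter_panel_edges"]


@dataclass(frozen=True)
class PPIEdge:
    gene_a: str
    gene_b: str
    combined_score: int
    experimental_score: int
    database_score: int

    def __post_init__(self):
        for name in ("combined_score", "experimental_score", "database_score"):
            v = getattr(self, name)
            if not 0 <= v <= 1000:
                raise ValueError(f"{name}={v} outside [0, 1000]")
        if not self.gene_a < self.gene_b:
            raise ValueError("edges must be stored with gene_a < gene_b")


def map_aliases(
    alias_path: str | Path, panel_symbols: tuple[str, ...]
) -> tuple[dict[str, str], list[str]]:
    """Map panel gene symbols to canonical protein identifiers.

    The alias file has rows (protein_id, alias, source).  Returns the
    symbol -> protein map and the list of unmapped symbols.  A symbol
    aliased to several distinct proteins is an error listing the
    candidates.
    """
    table = pd.read_csv(
        alias_path,
        sep="\t",
        comment=None,
        header=0,
        names=["protein_id", "alias", "source"],
        dtype=str,
    )
    wanted = set(panel_symbols)
    hits = table[table["alias"].isin(wanted)].drop_duplicates(
        subset=["protein_id", "alias"]
    )
    mapping: dict[str, str] = {}
    for symbol, grp in hits.groupby("alias"):
        proteins = sorted(grp["protein_id"].unique())
        if len(proteins) > 1:
            raise ValueError(
                f"symbol {symbol!r} maps to multiple proteins: {proteins}"
            )
        mapping[symbol] = proteins[0]
    unmapped = [s for s in panel_symbols if s not in mapping]
    return mapping, unmapped


def filter_panel_edges(
    links_path: str | Path,
    id_map: dict[str, str],
    thresholds: tuple[int, ...] = (1, 150, 400, 700, 900),
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Filter a detailed-links file to within-panel edges and count
    experimental-channel evidence per threshold.

    Returns ``(edge_table, threshold_counts, skipped_rows)``.  Directed
    duplicates collapse to one unordered edge (scores must agree; the
    maximum is kept if they do not).  Counts are of pairs whose
    experimental score is >= the threshold (the ">0" convention is
    threshold 1).
    """
    protein_to_gene = {v: k for k, v in id_map.items()}
    edges: dict[tuple[str, str], dict[str, int]] = {}
    skipped = 0
    with open(links_path) as fh:
        header = fh.readline().split()
        try:
            i_p1 = header.index("protein1")
            i_p2 = header.index("protein2")
            i_exp = header.index("experimental")
            i_db = header.index("database")
            i_comb = header.index("combined_score")
        except ValueError as err:
            raise ValueError(f"links header missing column: {err}")
        for line in fh:
            parts = line.split()
            if len(parts) != len(header):
                skipped += 1
                continue
            g1 = protein_to_gene.get(parts[i_p1])
            g2 = protein_to_gene.get(parts[i_p2])
            if g1 is None or g2 is None or g1 == g2:
                continue
            try:
                scores = {
                    "experimental_score": int(parts[i_exp]),
                    "database_score": int(parts[i_db]),
                    "combined_score": int(parts[i_comb]),
                }
            except ValueError:
                skipped += 1
                continue
            key = (g1, g2) if g1 < g2 else (g2, g1)
            if key in edges:
                for k, v in scores.items():
                    edges[key][k] = max(edges[key][k], v)
            else:
                edges[key] = scores

    edge_table = pd.DataFrame(
        [
            {"gene_a": a, "gene_b": b, **scores}
            for (a, b), scores in sorted(edges.items())
        ],
        columns=[
            "gene_a",
            "gene_b",
            "experimental_score",
            "database_score",
            "combined_score",
        ],
    )
    counts = pd.DataFrame(
        {
            "threshold": list(thresholds),
            "n_pairs": [
                int((edge_table["experimental_score"] >= t).sum())
                if len(edge_table)
                else 0
                for t in thresholds
            ],
        }
    )
    return edge_table, counts, skipped
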