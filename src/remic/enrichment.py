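"""Gene-set over-representation analysis of gene clusters.

Clusters of significant genes are tested against a GMT collection
(e.g. KEGG pathways exported as GMT) with the one-sided Fisher exact
test on the 2x2 table (overlap, query-only, set-only, neither), using
all genes of the interaction network as the background, followed by
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "fisher_enrichment",
    "benjamini_hochberg",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (one GMT row per set)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        members = frozenset(members)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = members
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, members...)."""
    path = Path(path)
    coll = GeneSetCollection()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT row needs >= 3 tab-separated columns"
                )
            members = [m for m in fields[2:] if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set without members")
            coll.add(fields[0], members, fields[1])
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, members in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    query: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided over-representation Fisher test of ``query`` in each set.

    Gene sets are intersected with the background before testing; the 2x2
    table for a set with K background members, query size n, overlap k and
    background size N is (k, n-k, K-k, N-n-K+k). Returns records sorted by
    p with columns set_name, k, n, K, N, p, q, rank.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query genes must be contained in the background")
    N = len(background)
    n = len(query)
    rows = []
    for name, members in sets.sets.items():
        bg_members = members & background
        K = len(bg_members)
        k = len(query & bg_members)
        table = [[k, n - k], [K - k, N - n - K + k]]
        p = 1.0 if K == 0 else float(fisher_exact(table, alternative="greater")[1])
        rows.append((name, k, n, K, N, p))
    df = pd.DataFrame(rows, columns=["set_name", "k", "n", "K", "N", "p"])
    df["q"] = benjamini_hochberg(df["p"].to_numpy()) if len(df) else []
    df = df.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
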