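"""Metabolite-set over-representation analysis (ORA).

A hit list of discriminant metabolites is tested against named metabolite
sets (pathways or chemical classes) with the hypergeometric upper-tail
probability, Benjamini-Hochberg corrected across sets. Sets are read from
the GMT format (one set per line: name, description, member ids); the
universe is the metabolites that survived preprocessing, not the full
catalog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats as sps

from dilimet.stats import bh_fdr


@dataclass
class MetaboliteSetCollection:
    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        trimmed = {}
        for name, members in self.sets.items():
            inter = set(members) & self.universe
            if not inter:
                warnings.warn(f"dropping empty metabolite set {name!r} "
                              "(no members in universe)", stacklevel=2)
                continue
            trimmed[name] = inter
        self.sets = trimmed

    @staticmethod
    def from_gmt(path: str | Path, universe) -> "MetaboliteSetCollection":
        sets = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = set(parts[2:])
        return MetaboliteSetCollection(sets=sets, universe=set(universe))

    def to_gmt(self, path: str | Path) -> None:
        lines = [f"{name}\tna\t" + "\t".join(sorted(members))
                 for name, members in self.sets.items()]
        Path(path).write_text("\n".join(lines) + "\n")


def default_metabolite_sets(catalog: pd.DataFrame,
                            universe=None) -> MetaboliteSetCollection:
    """Sets derived from the catalog's metabolite classes (glutathione /
    gamma-glutamyl cycle, phospholipids, lysophospholipids, TG, DG, fatty
    acids, acylcarnitines, amino acids)."""
    if universe is None:
        universe = catalog.index[~catalog["is_background"]]
    sets: dict[str, set[str]] = {}
    for fid, cls in catalog["metabolite_class"].items():
        if cls in ("other", "background"):
            continue
        sets.setdefault(cls, set()).add(fid)
    return MetaboliteSetCollection(sets=sets, universe=set(universe))


def ora(hits, collection: MetaboliteSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of a hit list against each set.

    For a universe of M metabolites, a set of K and a hit list of N with
    overlap k, p = P(X >= k) under Hypergeometric(M, K, N); q is BH across
    sets. Rows are sorted by p.
    """
    hits = set(hits)
    outside = hits - collection.universe
    if outside:
        raise ValueError(f"hits outside universe: {sorted(outside)[:5]}")
    m = len(collection.universe)
    n_hits = len(hits)
    rows = []
    for name, members in sorted(collection.sets.items()):
        k = len(hits & members)
        p = float(sps.hypergeom.sf(k - 1, m, len(members), n_hits))
        rows.append({"set": name, "overlap": k, "set_size": len(members),
                     "n_hits": n_hits, "universe": m, "p": min(p, 1.0)})
    result = pd.DataFrame(rows).set_index("set")
    result["q"] = bh_fdr(result["p"].to_numpy()) if len(result) else []
    return result.sort_values(["p", "set"], kind="stable")
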