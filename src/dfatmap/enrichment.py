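"""Hypergeometric over-representation analysis against GMT gene-set collections."""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .deg import adjust_pvalues

__all__ = ["read_gmt", "write_gmt", "ora"]


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file into ``{set name: (description, members)}``.

    Duplicate members within a set are kept once (first occurrence).
    """
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            if name in out:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            out[name] = (desc, list(dict.fromkeys(members)))
    return out


def write_gmt(collection: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def ora(
    gene_list,
    universe,
    collection: dict[str, tuple[str, list[str]]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    For a universe of N genes, a set with K members in the universe and a
    list of n genes with k in the set, p = P(X >= k) for
    X ~ Hypergeometric(N, K, n).  BH adjustment across the tested sets;
    results sorted ascending by p.
    """
    universe = pd.Index(pd.unique(pd.Index(universe)))
    gene_list = pd.Index(pd.unique(pd.Index(gene_list)))
    if len(universe) == 0 or len(gene_list) == 0:
        raise ValueError("universe and gene list must be non-empty")
    outside = gene_list.difference(universe)
    if len(outside):
        raise ValueError(f"list genes outside the universe, e.g. {list(outside[:5])}")

    n_univ = len(universe)
    n_list = len(gene_list)
    rows = []
    for name, (_desc, members) in collection.items():
        in_univ = universe.intersection(pd.Index(members))
        overlap = gene_list.intersection(in_univ)
        k, big_k = len(overlap), len(in_univ)
        p = float(hypergeom.sf(k - 1, n_univ, big_k, n_list)) if big_k else 1.0
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": big_k,
                "list_size": n_list,
                "universe_size": n_univ,
                "p": min(p, 1.0),
                "genes": ";".join(sorted(overlap)),
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["p_adj"] = adjust_pvalues(res["p"].to_numpy(), method="bh")
        res = res.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
        res = res[
            ["set", "overlap", "set_size", "list_size", "universe_size",
             "p", "p_adj", "genes"]
        ]
    return res
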