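"""Gene-set over-representation by the hypergeometric upper tail.

A gene list (e.g. the annotated selected probes) is tested against named
gene sets (GMT format) over a background universe — conventionally all
annotated genes on the array, not just the genes appearing in the
collection.  The raw p-value per set is ``P(X >= overlap)`` for a
hypergeometric draw of ``len(list)`` genes from the universe with the set's
in-universe genes as successes (identical to a one-sided Fisher exact
test); an EASE-style variant that deducts one overlapping gene before
taking the tail is available.  Bonferroni (default) or Benjamini-Hochberg
correction is applied across sets.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "hypergeom_p",
    "enrich",
    "pathway_multiplicity",
    "MultiplicityResult",
]


class GeneSetCollection(Mapping):
    """Named, non-empty gene sets with optional descriptions (GMT model)."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        self._sets: dict[str, tuple[str, ...]] = {}
        for name, genes in sets.items():
            genes = tuple(genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            self._sets[name] = genes
        self._descriptions = {
            name: (descriptions or {}).get(name, "") for name in self._sets
        }

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def description(self, name: str) -> str:
        return self._descriptions[name]

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, tuple[str, ...]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: GMT lines need name, description "
                        "and at least one gene"
                    )
                name = fields[0]
                if name in sets:
                    raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
                genes = tuple(g.strip() for g in fields[2:] if g.strip())
                if not genes:
                    raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
                sets[name] = genes
                descriptions[name] = fields[1]
        return cls(sets, descriptions)

    def write_gmt(self, path) -> None:
        with open(path, "w") as handle:
            for name, genes in self._sets.items():
                handle.write(
                    "\t".join([name, self._descriptions[name], *genes]) + "\n"
                )


def hypergeom_p(
    overlap: int, list_size: int, set_size: int, universe_size: int
) -> float:
    """Upper-tail P(X >= overlap) for the over-representation null.

    X counts set members in a uniform draw of ``list_size`` genes from a
    universe of ``universe_size`` containing ``set_size`` set members.
    """
    for label, value in (
        ("overlap", overlap),
        ("list_size", list_size),
        ("set_size", set_size),
        ("universe_size", universe_size),
    ):
        if value < 0:
            raise ValueError(f"{label} must be non-negative")
    if overlap > min(list_size, set_size):
        raise ValueError(
            f"overlap {overlap} exceeds min(list_size, set_size) = "
            f"{min(list_size, set_size)}"
        )
    if max(list_size, set_size) > universe_size:
        raise ValueError("list and set sizes cannot exceed the universe size")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, list_size))


def enrich(
    gene_list: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    correction: str = "bonferroni",
    alpha: float = 0.05,
    ease: bool = False,
) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in every set of ``collection``.

    Genes outside the universe are dropped with a warning; each set is
    intersected with the universe before testing.  ``ease=True`` deducts
    one overlapping gene before the tail computation (the conservative
    EASE score).  Returns one row per set sorted by adjusted then raw
    p-value.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    if correction not in ("bonferroni", "bh"):
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    genes: list[str] = []
    seen: set[str] = set()
    dropped = 0
    for g in gene_list:
        if g in seen:
            continue
        seen.add(g)
        if g in universe_set:
            genes.append(g)
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"{dropped} gene(s) outside the universe dropped from the list",
            stacklevel=2,
        )
    gene_set = set(genes)
    n_list = len(genes)
    n_universe = len(universe_set)

    rows = []
    for name in collection:
        members = set(collection[name]) & universe_set
        overlap_genes = tuple(sorted(members & gene_set))
        overlap = len(overlap_genes)
        effective = max(overlap - 1, 0) if ease else overlap
        p = hypergeom_p(effective, n_list, len(members), n_universe)
        rows.append(
            {
                "set_name": name,
                "description": collection.description(name),
                "overlap": overlap,
                "set_size": len(members),
                "list_size": n_list,
                "universe_size": n_universe,
                "p_value": p,
                "overlap_genes": overlap_genes,
            }
        )
    result = pd.DataFrame(rows)
    m = len(result)
    if correction == "bonferroni":
        result["p_adjusted"] = np.minimum(1.0, result["p_value"] * m)
    else:
        result["p_adjusted"] = multipletests(
            result["p_value"].to_numpy(), method="fdr_bh"
        )[1]
    result["significant"] = result["p_adjusted"] < alpha
    result = result.sort_values(
        ["p_adjusted", "p_value", "set_name"], kind="mergesort"
    ).reset_index(drop=True)
    return result


@dataclass(frozen=True)
class MultiplicityResult:
    """How many significant sets each list gene belongs to.

    ``histogram`` maps multiplicity (>= 1) to the number of genes with that
    multiplicity; genes in no significant set are excluded from the
    histogram but listed in ``genes_without_set``.
    """

    histogram: pd.Series
    per_gene: pd.Series
    genes_without_set: tuple[str, ...]


def pathway_multiplicity(
    results: pd.DataFrame, gene_list: Iterable[str]
) -> MultiplicityResult:
    """Count, per list gene, the significant sets that contain it."""
    genes = list(dict.fromkeys(gene_list))
    counts = dict.fromkeys(genes, 0)
    significant = results[results["significant"]]
    for members in significant["overlap_genes"]:
        for g in members:
            if g in counts:
                counts[g] += 1
    per_gene = pd.Series(counts, dtype=int, name="n_significant_sets")
    nonzero = per_gene[per_gene > 0]
    histogram = nonzero.value_counts().sort_index()
    histogram.index.name = "multiplicity"
    zero = tuple(g for g in genes if counts[g] == 0)
    return MultiplicityResult(
        histogram=histogram, per_gene=per_gene, genes_without_set=zero
    )
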