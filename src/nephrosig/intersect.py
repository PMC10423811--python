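"""Candidate-gene discovery: intersect cohort DEG lists with metabolism genes.

A candidate must be differentially expressed in the same direction in
every cohort and belong to the metabolic gene universe (the union of the
eight ferroptosis-related metabolic pathway sets). Genes that change
direction between cohorts are excluded and logged. Venn-region counts are
emitted for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .genesets import GeneSet, Registry

__all__ = ["IntersectionResult", "intersect_degs"]


@dataclass(frozen=True)
class IntersectionResult:
    compartment: str
    up_candidates: tuple[str, ...]
    down_candidates: tuple[str, ...]
    conflicting: tuple[str, ...]
    venn_counts: dict
    provenance: dict  # candidate -> {"sets": [...], "per_cohort": {...}}

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for direction, genes in (("up", self.up_candidates), ("down", self.down_candidates)):
            for g in genes:
                prov = self.provenance.get(g, {})
                rows.append(
                    {
                        "gene": g,
                        "direction": direction,
                        "metabolic_sets": ";".join(prov.get("sets", [])),
                        **{
                            f"{cohort}_{k}": v
                            for cohort, d in prov.get("per_cohort", {}).items()
                            for k, v in d.items()
                        },
                    }
                )
        return pd.DataFrame(rows)


def intersect_degs(
    deg_lists: Mapping[str, Mapping[str, list[str]]],
    metabolic_union: GeneSet,
    *,
    compartment: str = "glomerular",
    registry: Registry | None = None,
    de_tables: Mapping[str, pd.DataFrame] | None = None,
) -> IntersectionResult:
    """Intersect per-cohort signed DEG lists with the metabolic universe.

    ``deg_lists`` maps cohort name -> {"up": [...], "down": [...]}. Needs
    at least two cohorts. Candidates must be up (resp. down) in *all*
    cohorts and in ``metabolic_union``; direction-conflicting genes are
    excluded and reported. ``registry`` (optional) annotates each candidate
    with the metabolic sets containing it; ``de_tables`` (optional,
    cohort -> fit_moderated_t output) adds per-cohort log2FC and adj p.
    """
    if len(metabolic_union) == 0:
        raise ValueError("metabolic union is empty")
    if len(deg_lists) < 2:
        raise ValueError("need DEG lists from >=2 cohorts")

    cohorts = sorted(deg_lists)
    ups = {c: set(deg_lists[c].get("up", [])) for c in cohorts}
    downs = {c: set(deg_lists[c].get("down", [])) for c in cohorts}

    up_all = set.intersection(*ups.values())
    down_all = set.intersection(*downs.values())
    any_up = set.union(*ups.values())
    any_down = set.union(*downs.values())
    conflicting = sorted(any_up & any_down)
    up_all -= set(conflicting)
    down_all -= set(conflicting)

    metabolic = metabolic_union.as_set()
    up_candidates = tuple(sorted(up_all & metabolic))
    down_candidates = tuple(sorted(down_all & metabolic))

    venn = {
        "cohorts": cohorts,
        "up": {
            **{c: len(ups[c]) for c in cohorts},
            "shared": len(up_all),
            "shared_and_metabolic": len(up_candidates),
        },
        "down": {
            **{c: len(downs[c]) for c in cohorts},
            "shared": len(down_all),
            "shared_and_metabolic": len(down_candidates),
        },
        "metabolic_universe": len(metabolic),
        "conflicting": len(conflicting),
    }

    provenance: dict[str, dict] = {}
    for g in up_candidates + down_candidates:
        entry: dict = {}
        if registry is not None:
            entry["sets"] = [
                name for name in registry.sets_containing(g)
                if registry.category(name) == "metabolic"
            ]
        if de_tables is not None:
            entry["per_cohort"] = {
                c: {
                    "log2fc": float(t.loc[g, "log2fc"]),
                    "adj_pvalue": float(t.loc[g, "adj_pvalue"]),
                }
                for c, t in de_tables.items()
                if g in t.index
            }
        provenance[g] = entry

    return IntersectionResult(
        compartment=compartment,
        up_candidates=up_candidates,
        down_candidates=down_candidates,
        conflicting=tuple(conflicting),
        venn_counts=venn,
        provenance=provenance,
    )
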