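"""Local over-representation analysis (ORA) against GMT gene-set collections.

A query gene list (e.g. genes of the top 25% high-IR transcripts) is tested
against each set with the one-sided hypergeometric tail P(X >= k), where k is
the overlap, m the set size, n the query size and N the background universe.
p-values are Bonferroni-corrected over the number of sets tested. The
background defaults to the genes that survived the expression filter, so the
null matches the tested population. Everything is file-local: no service
calls, ever.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str]) -> "GeneSetCollection":
        """Load a GMT file (name, description, genes...; tab-separated) and
        restrict every set to ``universe``, dropping sets left empty."""
        universe = set(universe)
        sets: dict[str, set[str]] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT lines need >= 3 tab-separated fields")
            name, _desc, *genes = parts
            restricted = set(genes) & universe
            if restricted:
                sets[name] = restricted
        return cls(sets=sets, universe=universe)

    @classmethod
    def from_dict(
        cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str]
    ) -> "GeneSetCollection":
        universe = set(universe)
        restricted = {
            name: set(genes) & universe for name, genes in sets.items()
        }
        return cls(
            sets={n: g for n, g in restricted.items() if g}, universe=universe
        )


def select_top_fraction(
    ranked_transcripts: Sequence[str],
    transcript_to_gene: Mapping[str, str],
    fraction: float = 0.25,
) -> list[str]:
    """Gene symbols of the top fraction of an already-ranked transcript list.

    Takes ``ceil(fraction * len(list))`` transcripts, maps them to gene
    symbols and de-duplicates preserving rank order. Transcripts without a
    symbol are dropped (their count is reported in a warning).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    top = list(ranked_transcripts)[: math.ceil(fraction * len(ranked_transcripts))]
    genes: list[str] = []
    n_missing = 0
    for tid in top:
        sym = transcript_to_gene.get(tid)
        if not sym:
            n_missing += 1
        elif sym not in genes:
            genes.append(sym)
    if n_missing:
        warnings.warn(
            f"{n_missing} transcript(s) without a gene symbol were dropped",
            stacklevel=2,
        )
    return genes


def ora_test(query: Iterable[str], gsc: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in every set of ``gsc``.

    Query genes outside the universe are dropped with a warning. Returns one
    row per set — overlap ``k``, set size ``m``, query size ``n``, universe
    size ``N``, tail p = P(X >= k), Bonferroni-adjusted p (capped at 1) and
    fold enrichment (k/n)/(m/N) — sorted by adjusted then raw p.
    """
    query = list(dict.fromkeys(query))
    inside = [g for g in query if g in gsc.universe]
    if len(inside) < len(query):
        warnings.warn(
            f"{len(query) - len(inside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
    if not inside:
        warnings.warn("empty query after restriction to the universe", stacklevel=2)
        return pd.DataFrame(
            columns=["set", "k", "m", "n", "N", "p", "p_bonferroni", "fold_enrichment"]
        ).set_index("set")

    N = len(gsc.universe)
    n = len(inside)
    qset = set(inside)
    n_tests = len(gsc.sets)
    rows = []
    for name, members in gsc.sets.items():
        m = len(members)
        k = len(qset & members)
        # P(X >= k) for X ~ Hypergeom(N, m, n)
        p = float(stats.hypergeom.sf(k - 1, N, m, n))
        rows.append(
            {
                "set": name,
                "k": k,
                "m": m,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
                "p_bonferroni": min(1.0, p * n_tests),
                "fold_enrichment": (k / n) / (m / N),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    return out.sort_values(["p_bonferroni", "p"])
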