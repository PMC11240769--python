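"""Over-representation analysis of a candidate list against gene sets.

For a candidate list drawn from a finite universe and a collection of named
gene sets (GMT format), each set is scored by

* ``observed``  — candidates that are members of the set,
* ``expected``  — list size x (set size in universe / universe size),
* ``fold_enrichment`` — observed / expected (computed from the unrounded
  expected value),
* ``p_value``   — hypergeometric upper tail P(X >= observed) for drawing the
  list without replacement from the universe,
* ``fdr``       — Benjamini-Hochberg step-up adjustment across all sets in
  the collection.

Only over-representation is tested (one-sided).  The universe is caller
supplied — typically all features passing the expression filter — since
results are only interpretable relative to what could have been detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named, de-duplicated gene sets with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class EnrichmentRow:
    category: str
    observed: int
    expected: float
    fold_enrichment: float
    p_value: float
    fdr: float


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then members."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EnrichmentError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise EnrichmentError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise EnrichmentError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def ora(
    candidates: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection | Mapping[str, frozenset[str]],
) -> list[EnrichmentRow]:
    """Over-representation analysis; rows sorted by ascending p-value."""
    cand = frozenset(candidates)
    uni = frozenset(universe)
    if not uni:
        raise EnrichmentError("universe is empty")
    stray = cand - uni
    if stray:
        raise EnrichmentError(
            f"candidates not in universe: {sorted(stray)[:10]}"
            + ("..." if len(stray) > 10 else "")
        )
    mapping = sets.sets if isinstance(sets, GeneSetCollection) else dict(sets)
    names = list(mapping)
    n_uni, n_list = len(uni), len(cand)
    observed, expected, folds, pvals = [], [], [], []
    for name in names:
        members = frozenset(mapping[name]) & uni
        k_set = len(members)
        obs = len(cand & members)
        exp = n_list * k_set / n_uni
        if exp == 0:
            if obs > 0:
                raise EnrichmentError(
                    f"set {name!r}: observed {obs} with expected 0 — list not within universe"
                )
            fold = 0.0
        else:
            fold = obs / exp
        # upper tail P(X >= obs) for hypergeom(M=universe, n=set, N=list)
        p = float(hypergeom.sf(obs - 1, n_uni, k_set, n_list))
        observed.append(obs)
        expected.append(exp)
        folds.append(fold)
        pvals.append(min(p, 1.0))
    if names:
        fdr = multipletests(pvals, method="fdr_bh")[1]
    else:
        fdr = []
    rows = [
        EnrichmentRow(
            category=name,
            observed=observed[i],
            expected=expected[i],
            fold_enrichment=folds[i],
            p_value=pvals[i],
            fdr=float(fdr[i]),
        )
        for i, name in enumerate(names)
    ]
    rows.sort(key=lambda r: (r.p_value, r.category))
    return rows


def ora_frame(
    candidates: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection | Mapping[str, frozenset[str]],
) -> pd.DataFrame:
    """`ora` as a DataFrame with columns category, observed, expected, fold_enrichment, p_value, fdr."""
    rows = ora(candidates, universe, sets)
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["category", "observed", "expected", "fold_enrichment", "p_value", "fdr"],
    )


__all__ = [
    "EnrichmentError",
    "EnrichmentRow",
    "GeneSetCollection",
    "ora",
    "ora_frame",
    "read_gmt",
    "write_gmt",
]
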