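"""Over-representation analysis of a candidate list against gene sets.

Builds a 10,000-feature universe, a 100-feature candidate list, and a
95-member gene set containing 10 of the candidates — the arithmetic of a
published enrichment-table row: expected = 100 x 95 / 10000 = 0.95, fold
enrichment = 10 / 0.95 = 10.53 — then scores it with the exact
hypergeometric tail and Benjamini-Hochberg FDR.
"""

from liqtrace import ora_frame

universe = [f"u{i}" for i in range(10_000)]
candidates = universe[:100]
sets = {
    "ribosome_like": frozenset(candidates[:10]) | frozenset(universe[100:185]),
    "random_like": frozenset(universe[50:150]),
}

df = ora_frame(candidates, universe, sets)
print(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\nfold_enrichment = observed / expected; p_value is the hypergeometric "
      "upper tail P(X >= observed); fdr is BH-adjusted across the collection.")
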